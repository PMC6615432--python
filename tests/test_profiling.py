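"""Phenotype indices, the community phenotype matrix, and signatures."""
import numpy as np
import pandas as pd
import pytest

import phenosig as ps
from phenosig.errors import ConsistencyError, UndefinedIndexError
from phenosig.fixtures import printed_mapping_levels
from tests.conftest import random_instance


def _index_of(coll, name, identity=99.0):
    m = ps.map_phylotype(ps.Phylotype(name, name, identity), coll)
    return ps.phenotype_index(m)


class TestPhenotypeIndex:
    def test_one_of_four_strains_gives_quarter_index(self, table2):
        """A species where a single strain out of four encodes the complete
        de novo B12 pathway gets a 0.25 prototrophy index."""
        coll, _ = table2
        assert _index_of(coll, "Akkermansia muciniphila")["B12"] == pytest.approx(0.25)

    def test_four_of_six_strains_give_two_thirds(self, table2):
        coll, _ = table2
        idx = _index_of(coll, "Faecalibacterium prausnitzii")
        assert idx["B2"] == pytest.approx(2 / 3)
        assert round(idx["B2"], 2) == 0.67

    def test_all_prototrophic_neighborhood_hits_one(self, table2):
        coll, _ = table2
        idx = _index_of(coll, "Parabacteroides distasonis")
        assert all(v == 1.0 for v in idx.values)

    def test_unmapped_phylotype_has_no_index(self, small_collection):
        m = ps.map_phylotype(ps.Phylotype("p", "Nowhere atall", 80.0), small_collection)
        with pytest.raises(UndefinedIndexError):
            ps.phenotype_index(m)

    @pytest.mark.parametrize("name", ["table2", "table3"])
    def test_whole_printed_matrix_reproduced(self, name, request):
        """Every cell of both printed 20 x 8 index matrices is reproduced
        after 2-decimal rounding (the core worked-example regression)."""
        coll, prof = ps.table_fixture(name)
        printed = ps.printed_index_matrix(name)
        levels = printed_mapping_levels(name)
        mappings, _ = ps.map_profile(prof, coll)
        assert len(mappings) == 20
        for m in mappings:
            assert m.mapping_level == levels[m.phylotype_id]
            idx = ps.phenotype_index(m)
            for v, value in zip(idx.panel, idx.values):
                assert abs(round(value, 2) - printed.loc[m.phylotype_id, v]) < 1e-9, (
                    m.phylotype_id, v, value,
                )


class TestCommunityPhenotypeMatrix:
    def test_fixture_cpm_has_one_row_per_mapped_phylotype(self, table2):
        coll, prof = table2
        mappings, _ = ps.map_profile(prof, coll)
        cpm = ps.community_phenotype_matrix(mappings, prof)
        assert cpm.phenotypes.shape == (20, 8)
        assert cpm.abundance.sum() == pytest.approx(1.0, abs=1e-9)

    def test_empty_profile_gives_empty_cpm(self):
        prof = ps.CommunityProfile("s", {})
        cpm = ps.community_phenotype_matrix([], prof)
        assert cpm.phenotypes.empty and cpm.mapped_fraction == 0.0

    def test_mismatched_mappings_rejected(self, table2):
        coll, prof = table2
        mappings, _ = ps.map_profile(prof, coll)
        with pytest.raises(ConsistencyError):
            ps.community_phenotype_matrix(mappings[:-1], prof)

    def test_split_phylotype_keeps_identical_phenotype_rows(self, small_collection):
        whole = ps.CommunityProfile(
            "s", {"a": 1.0}, phylotypes={"a": ps.Phylotype("a", "GenA one", 99.0)}
        )
        split = ps.CommunityProfile(
            "s", {"a1": 0.5, "a2": 0.5},
            phylotypes={
                "a1": ps.Phylotype("a1", "GenA one", 99.0),
                "a2": ps.Phylotype("a2", "GenA one", 99.0),
            },
        )
        m_w, _ = ps.map_profile(whole, small_collection)
        m_s, _ = ps.map_profile(split, small_collection)
        cpm_w = ps.community_phenotype_matrix(m_w, whole)
        cpm_s = ps.community_phenotype_matrix(m_s, split)
        np.testing.assert_allclose(
            cpm_s.phenotypes.loc["a1"], cpm_w.phenotypes.loc["a"]
        )
        np.testing.assert_allclose(
            cpm_s.phenotypes.loc["a2"], cpm_w.phenotypes.loc["a"]
        )


class TestCommunitySignature:
    def test_single_phylotype_quarter_index(self, table2):
        coll, _ = table2
        prof = ps.CommunityProfile(
            "s", {"p": 1.0},
            phylotypes={"p": ps.Phylotype("p", "Akkermansia muciniphila", 99.0)},
        )
        m, _ = ps.map_profile(prof, coll)
        sig = ps.community_signature(ps.community_phenotype_matrix(m, prof))
        assert sig.cpi["B12"] == pytest.approx(25.0)
        assert sig.auxotrophy["B12"] == pytest.approx(75.0)

    def test_two_phylotype_weighted_sum(self, small_collection):
        # B3 indices: GenA one -> 1, GenA two -> 0
        prof = ps.CommunityProfile(
            "s", {"x": 0.6, "y": 0.4},
            phylotypes={
                "x": ps.Phylotype("x", "GenA one", 99.0),
                "y": ps.Phylotype("y", "GenA two", 99.0),
            },
        )
        m, _ = ps.map_profile(prof, small_collection)
        sig = ps.community_signature(ps.community_phenotype_matrix(m, prof))
        assert sig.cpi["B3"] == pytest.approx(60.0)

    def test_fixture_b12_auxotrophy_matches_hand_summation(self, table2):
        """Abundance-weighted B12 auxotrophy of the renormalized 20-species
        community, against an independent hand summation over printed rows."""
        coll, prof = table2
        m, _ = ps.map_profile(prof, coll)
        sig = ps.community_signature(ps.community_phenotype_matrix(m, prof))
        # independent literal arithmetic over the printed abundance column
        # and (exact-fraction) B12 indices: only 8 rows have index < 1
        terms = [
            26.3 * (1 - 1 / 4),    # one of four strains prototrophic
            10.2 * 1.0,
            4.5 * (1 - 1 / 4),
            3.0 * (1 - 181 / 224),  # family-level average
            1.6 * 1.0,
            1.6 * 1.0,
            0.9 * 1.0,
            0.8 * 1.0,
        ]
        total = 79.7  # sum of the printed abundance column
        oracle = 100.0 * sum(terms) / total
        assert sig.auxotrophy["B12"] == pytest.approx(oracle, abs=1e-9)

    def test_conservation_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            coll, prof = random_instance(rng, max_phylotypes=20, max_genomes=8)
            m, mf = ps.map_profile(prof, coll)
            sig = ps.community_signature(ps.community_phenotype_matrix(m, prof))
            np.testing.assert_allclose(
                sig.cpi + sig.auxotrophy, 100.0 * mf, atol=1e-9
            )

    def test_all_prototroph_community_has_zero_auxotrophy(self):
        genomes = [
            ps.ReferenceGenome(f"g{i}", f"S s{i}", "S", "F", (1,) * 8)
            for i in range(4)
        ]
        coll = ps.ReferenceCollection(genomes)
        prof = ps.CommunityProfile("s", {f"S s{i}": 0.25 for i in range(4)})
        m, _ = ps.map_profile(prof, coll)
        sig = ps.community_signature(ps.community_phenotype_matrix(m, prof))
        assert (sig.auxotrophy == 0.0).all()

    def test_vectorized_cpi_equals_naive_double_sum(self):
        """The pandas/numpy CPI equals sum_i sum_m A_i w_im p_mv computed
        with explicit Python loops."""
        rng = np.random.default_rng(11)
        for _ in range(25):
            coll, prof = random_instance(rng, max_phylotypes=15, max_genomes=10)
            mappings, _ = ps.map_profile(prof, coll)
            sig = ps.community_signature(
                ps.community_phenotype_matrix(mappings, prof)
            )
            genome_by_id = {g.genome_id: g for g in coll.genomes}
            naive = np.zeros(8)
            for m in mappings:
                if not m.mapped:
                    continue
                a = prof.abundances[m.phylotype_id]
                for gid, w in m.weights.items():
                    naive += a * w * np.asarray(genome_by_id[gid].phenotypes)
            np.testing.assert_allclose(sig.cpi.to_numpy(), 100 * naive, atol=1e-12)


class TestGroupAggregation:
    def _sig(self, sample, value, group):
        s = pd.Series([value] * 8, index=list(ps.DEFAULT_PANEL))
        return ps.CommunitySignature(sample, 100 - s, s, 1.0, group)

    def test_mean_and_sample_sd(self):
        sigs = [self._sig(f"s{i}", v, "AD") for i, v in enumerate((20.0, 30.0, 25.0))]
        (g,) = ps.aggregate_group(sigs)
        assert g.group == "AD" and g.n == 3
        assert g.mean["B1"] == pytest.approx(25.0)
        assert g.sd["B1"] == pytest.approx(5.0)  # n-1 estimator

    def test_single_replicate_reports_zero_sd(self):
        (g,) = ps.aggregate_group([self._sig("s", 40.0, "AN")])
        assert g.n == 1 and g.mean["B1"] == 40.0 and g.sd["B1"] == 0.0

    def test_empty_group_omitted_with_warning(self, caplog):
        sigs = [self._sig("s1", 10.0, None), self._sig("s2", 20.0, None)]
        with caplog.at_level("WARNING", logger="phenosig"):
            out = ps.aggregate_group(sigs, groups={"s1": "AD", "s2": "AD", "zz": "AE"})
        assert [g.group for g in out] == ["AD"]
        assert any("AE" in m for m in caplog.messages)

    def test_replicate_mean_recovers_designed_auxotrophy(self):
        """Six replicates at depth 1e5 from a community designed with 30%
        B1 auxotrophy average within 3 SD of the target."""
        design = ps.StudyDesign(
            seed=23, n_species=30, strain_heterogeneity=0.0,
            groups={"AD": 6}, target_auxotrophy={"B1": 0.30},
        )
        coll = ps.generate_reference_collection(design)
        profiles, truth = ps.generate_study(design, coll)
        sigs = []
        for p in profiles:
            m, _ = ps.map_profile(p, coll)
            sigs.append(ps.community_signature(ps.community_phenotype_matrix(m, p)))
        (g,) = ps.aggregate_group(sigs)
        assert truth.auxotrophy["AD"]["B1"] == pytest.approx(0.30, abs=1e-12)
        assert abs(g.mean["B1"] - 30.0) <= 3 * max(g.sd["B1"], 1e-6)
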