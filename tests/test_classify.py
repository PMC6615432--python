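"""Auxotrophy-pattern classes and deficient-vs-excess group comparison."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phenosig as ps
from phenosig.classify import classify_taxon
from phenosig.errors import ConfigError, InsufficientReplicationError
from phenosig.profiling import PhenotypeIndexVector


def _vec(pid, values):
    return PhenotypeIndexVector(pid, tuple(float(v) for v in values))


class TestClassification:
    def test_single_b12_auxotrophy_is_mono(self):
        c = classify_taxon(_vec("Muribaculum intestinale", (1, 1, 1, 1, 1, 1, 1, 0)))
        assert c.kind == "mono_auxotroph"
        assert c.aux_vitamins == ("B12",)
        assert c.label == "mono_auxotroph:B12"

    def test_all_ones_is_omni_prototroph(self):
        c = classify_taxon(_vec("Parabacteroides distasonis", (1,) * 8))
        assert c.kind == "omni_prototroph"

    def test_seven_auxotrophies_is_multi(self):
        c = classify_taxon(_vec("Flavonifractor plautii", (0, 0, 0, 0, 0, 0, 0, 1)))
        assert c.kind == "multi_auxotroph"
        assert len(c.aux_vitamins) == 7

    def test_two_auxotrophies_below_multi_min_is_oligo(self):
        c = classify_taxon(_vec("Coprococcus eutactus", (1, 1, 1, 1, 1, 0, 1, 0)))
        assert c.kind == "oligo_auxotroph"
        assert c.aux_vitamins == ("B7", "B12")

    def test_fractional_index_is_ambiguous_under_strict_defaults(self):
        c = classify_taxon(_vec("Akkermansia muciniphila", (1, 1, 1, 1, 1, 1, 1, 0.25)))
        assert c.kind == "ambiguous"
        assert c.ambiguous_vitamins == ("B12",)

    def test_relaxed_thresholds_resolve_fractional_index(self):
        c = classify_taxon(
            _vec("Akkermansia muciniphila", (1, 1, 1, 1, 1, 1, 1, 0.25)),
            aux_threshold=0.3, proto_threshold=0.8,
        )
        assert c.kind == "mono_auxotroph" and c.aux_vitamins == ("B12",)

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ConfigError):
            classify_taxon(_vec("x", (1,) * 8), aux_threshold=0.8, proto_threshold=0.5)

    @settings(max_examples=80, derandomize=True, deadline=None)
    @given(bits=st.lists(st.integers(0, 1), min_size=8, max_size=8))
    def test_binary_vectors_classified_by_direct_inspection(self, bits):
        c = classify_taxon(_vec("x", bits))
        k = bits.count(0)
        expected = {0: "omni_prototroph", 1: "mono_auxotroph", 2: "oligo_auxotroph"}.get(
            k, "multi_auxotroph"
        )
        assert c.kind == expected
        assert not c.ambiguous_vitamins


class TestClassSummary:
    def test_fixture_mono_b12_aggregate(self, table2):
        """In the mouse-community fixture the unambiguous B12 mono-auxotrophs
        are M. intestinale and B. stercorirosoris; their printed abundances
        dominate the class total."""
        coll, prof = table2
        mappings, _ = ps.map_profile(prof, coll)
        classes = [ps.classify_taxon(ps.phenotype_index(m)) for m in mappings]
        summary = ps.class_abundance_summary(prof, classes)
        expected = 100 * (10.2 + 0.9) / 79.7
        assert summary["mono_auxotroph:B12"] == pytest.approx(expected, abs=1e-6)
        by_id = {c.phylotype_id: c for c in classes}
        assert by_id["Muribaculum intestinale"].label == "mono_auxotroph:B12"
        assert by_id["Bacteroides stercorirosoris"].label == "mono_auxotroph:B12"
        assert by_id["Coprococcus eutactus"].kind == "oligo_auxotroph"

    def test_single_omni_prototroph_at_full_abundance(self):
        prof = ps.CommunityProfile("s", {"x": 1.0})
        classes = [classify_taxon(_vec("x", (1,) * 8))]
        summary = ps.class_abundance_summary(prof, classes)
        assert summary.to_dict() == {"omni_prototroph": pytest.approx(100.0)}

    def test_all_half_indices_land_in_ambiguous(self):
        prof = ps.CommunityProfile("s", {"x": 0.5, "y": 0.5})
        classes = [classify_taxon(_vec(p, (0.5,) * 8)) for p in ("x", "y")]
        summary = ps.class_abundance_summary(prof, classes)
        assert summary.to_dict() == {"ambiguous": pytest.approx(100.0)}

    def test_classes_partition_mapped_abundance(self, table3):
        coll, prof = table3
        mappings, mf = ps.map_profile(prof, coll)
        classes = [ps.classify_taxon(ps.phenotype_index(m)) for m in mappings if m.mapped]
        summary = ps.class_abundance_summary(prof, classes)
        assert summary.sum() == pytest.approx(100.0 * 1.0, abs=1e-6)
        assert len(classes) == len(prof.abundances)


def _profiles(values, label):
    """One two-species profile per value; the focal species' abundance is
    the value, the filler takes the rest."""
    return [
        ps.CommunityProfile(f"{label}{i}", {"Focal sp": v, "Filler sp": 1 - v}, group_label=label)
        for i, v in enumerate(values)
    ]


class TestCompareGroups:
    def test_identical_groups_show_no_signal(self):
        profs = _profiles([0.010, 0.020, 0.015], "x")
        out = ps.compare_groups(profs, profs)
        assert (out["fold_change"].dropna() == 1.0).all()
        assert not (out["p_value"].dropna() < 0.05).any()

    def test_complete_separation_three_v_three(self):
        """3 vs 3 with complete separation: exact two-sided Mann-Whitney
        p = 2/C(6,3) = 0.1 (rank enumeration), fold change 2.33."""
        d = _profiles([0.0010, 0.0020, 0.0015], "D")
        e = _profiles([0.0030, 0.0040, 0.0035], "E")
        out = ps.compare_groups(d, e)
        row = out.loc["Focal sp"]
        assert row["p_value"] == pytest.approx(0.1)
        assert row["fold_change"] == pytest.approx(0.0035 / 0.0015, rel=1e-6)
        assert row["p_value"] > 0.04  # not significant at the screening level

    def test_detection_filter_flags_untested(self):
        d = _profiles([1e-5, 2e-5, 1.5e-5], "D")
        e = _profiles([3e-5, 4e-5, 3.5e-5], "E")
        out = ps.compare_groups(d, e)  # focal below 0.01% on both sides
        assert not out.loc["Focal sp", "tested"]
        assert np.isnan(out.loc["Focal sp", "p_value"])

    def test_p_values_symmetric_under_label_exchange(self):
        rng = np.random.default_rng(3)
        d = _profiles(rng.uniform(0.001, 0.01, 6), "D")
        e = _profiles(rng.uniform(0.001, 0.01, 6), "E")
        p_de = ps.compare_groups(d, e)["p_value"]
        p_ed = ps.compare_groups(e, d)["p_value"]
        pd.testing.assert_series_equal(p_de, p_ed)

    def test_insufficient_replication_rejected(self):
        profs = _profiles([0.01], "x")
        with pytest.raises(InsufficientReplicationError):
            ps.compare_groups(profs, profs)

    def test_welch_alternative_runs(self):
        d = _profiles([0.0010, 0.0020, 0.0015], "D")
        e = _profiles([0.0030, 0.0040, 0.0035], "E")
        out = ps.compare_groups(d, e, test="welch")
        assert 0 < out.loc["Focal sp", "p_value"] < 0.05

    def test_bh_correction_column(self):
        d = _profiles([0.0010, 0.0020, 0.0015], "D")
        e = _profiles([0.0030, 0.0040, 0.0035], "E")
        out = ps.compare_groups(d, e, bh_correction=True)
        assert "p_adjusted" in out.columns
        assert (out["p_adjusted"].dropna() >= out["p_value"].dropna() - 1e-12).all()

    def test_injected_twofold_shift_ranks_first(self):
        """A 2-fold abundance shift injected into one species of a 15-per-side
        synthetic study is the top-ranked comparison in >= 95% of seeds."""
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            design = ps.StudyDesign(
                seed=500 + seed, n_species=15, strain_heterogeneity=0.0,
                groups={"D": 15, "E": 15},
                base_concentration=5.0,  # even-ish community: every taxon tested
                effects=(ps.InjectedEffect("Genus01 sp002", frozenset({"E"}), 2.0),),
            )
            coll = ps.generate_reference_collection(design)
            profiles, _ = ps.generate_study(design, coll)
            out = ps.compare_groups(
                [p for p in profiles if p.group_label == "D"],
                [p for p in profiles if p.group_label == "E"],
            )
            if out["p_value"].idxmin() == "Genus01 sp002":
                hits += 1
        assert hits >= round(0.95 * n_seeds)
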