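import numpy as np
import pytest

import phenosig as ps


@pytest.fixture(scope="session")
def table2():
    return ps.table_fixture("table2")


@pytest.fixture(scope="session")
def table3():
    return ps.table_fixture("table3")


@pytest.fixture
def small_collection():
    """Two genera, three species: GenA {Sp one: 3 genomes, Sp two: 1},
    GenB {Sp three: 2}. Panel-wide patterns chosen so species, genus and
    family averages are all distinct."""
    P = ps.DEFAULT_PANEL
    mk = ps.ReferenceGenome
    genomes = [
        mk("a1", "GenA one", "GenA", "FamX", (1, 1, 1, 1, 1, 1, 1, 1)),
        mk("a2", "GenA one", "GenA", "FamX", (1, 0, 1, 1, 1, 1, 1, 0)),
        mk("a3", "GenA one", "GenA", "FamX", (0, 0, 1, 1, 1, 1, 1, 0)),
        mk("b1", "GenA two", "GenA", "FamX", (0, 0, 0, 0, 0, 0, 0, 1)),
        mk("c1", "GenB three", "GenB", "FamX", (1, 1, 0, 0, 1, 0, 1, 1)),
        mk("c2", "GenB three", "GenB", "FamX", (1, 1, 0, 0, 1, 0, 1, 0)),
    ]
    return ps.ReferenceCollection(genomes, panel=P)


def random_instance(rng, max_phylotypes=50, max_genomes=20):
    """Random collection + profile pair for property checks: every
    phylotype maps at species level; abundances Dirichlet; a random slice
    of abundance is diverted to an unmappable phylotype."""
    n_sp = int(rng.integers(1, max_phylotypes + 1))
    genomes = []
    for i in range(n_sp):
        sp = f"G{i % 5} sp{i}"
        n = int(rng.integers(1, max_genomes + 1))
        for j in range(n):
            genomes.append(
                ps.ReferenceGenome(
                    f"{sp}.g{j}", sp, f"G{i % 5}", f"F{(i % 5) // 3}",
                    tuple(int(x) for x in rng.integers(0, 2, 8)),
                )
            )
    coll = ps.ReferenceCollection(genomes)
    names = sorted({g.species for g in coll.genomes})
    weights = rng.dirichlet(np.ones(len(names)))
    abund = dict(zip(names, weights))
    if rng.random() < 0.5:  # divert some mass to an unmapped phylotype
        frac = float(rng.uniform(0, 0.3))
        abund = {k: v * (1 - frac) for k, v in abund.items()}
        abund["no such taxon"] = frac
    prof = ps.CommunityProfile("rand", abund)
    return coll, prof
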