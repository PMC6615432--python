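"""Worked-example fixtures: the two published 20-species phenotype tables.

Two binary phenotype matrices are packaged, one for the most abundant 20
species of a humanized gnotobiotic mouse community ("table2") and one for an
anaerobic fecal subculture community ("table3"). Each printed row gives a
matching species, its mapping level (S species / G genus / F family), the
genome count of its phylogenetic neighborhood, eight prototrophy indices and
its relative abundance (%).

The printed tables carry *derived* fractional indices (0.25, 0.67, ...); the
BPM itself is strictly binary, so each row is expanded into per-genome
binary vectors that reproduce the printed index after averaging:

* species rows -- n genomes, round(index * n) prototrophs listed first;
* flat-realizable genus/family rows -- singleton species per genome (the
  hierarchical equal-per-species weights then reduce to a flat average);
* the two genus rows whose printed indices are not representable as k/n
  under hierarchical weighting (a 23-genome and a 3-genome genus) carry an
  explicit multi-species structure, solved by hand, that reproduces every
  printed cell to 2 decimals -- including the constraint that a separately
  printed species-level member of the same genus (with its own printed
  vector) sits inside the genus neighborhood.

Taxonomy above genus is synthetic ("<Genus>aceae"): only one fixture row
maps at family level and it must own its family exclusively, so real family
assignments (which would pool several fixture genera) are deliberately not
used. Identity percentages are synthetic stand-ins consistent with each
row's printed mapping level (99 / 96.5 / 92).
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ConfigError
from .mapping import CommunityProfile, Phylotype
from .panel import DEFAULT_PANEL
from .reference import ReferenceCollection, ReferenceGenome, genus_token

_LEVEL_IDENTITY = {"S": 99.0, "G": 96.5, "F": 92.0}
_LEVEL_RANK = {"S": "species", "G": "genus", "F": "family"}


@dataclass(frozen=True)
class _Row:
    name: str           # printed matching species / taxon name
    level: str          # S | G | F
    genomes: int
    indices: tuple[float, ...]
    abundance: float    # printed percent


# fmt: off
TABLE2_ROWS: tuple[_Row, ...] = (
    _Row("Akkermansia muciniphila",      "S", 4,   (1, 1, 1, 1, 1, 1, 1, 0.25), 26.3),
    _Row("Muribaculum intestinale",      "S", 1,   (1, 1, 1, 1, 1, 1, 1, 0),    10.2),
    _Row("Faecalibacterium prausnitzii", "S", 6,   (0, 0.67, 0, 0, 1, 0, 0, 1),  9.8),
    _Row("Bacteroides xylanisolvens",    "S", 4,   (1, 1, 1, 1, 1, 1, 1, 0.25),  4.5),
    _Row("Blautia glucerasea",           "S", 1,   (1, 0, 1, 0, 1, 0, 1, 1),     3.6),
    _Row("Parabacteroides distasonis",   "S", 4,   (1, 1, 1, 1, 1, 1, 1, 1),     3.1),
    _Row("Murimonas intestini",          "F", 224, (0.48, 0.56, 0.7, 0.25, 1, 0.15, 0.49, 0.81), 3.0),
    _Row("Phascolarctobacterium faecium","G", 1,   (1, 1, 0, 1, 1, 1, 1, 1),     2.5),
    _Row("Bacteroides fragilis",         "S", 6,   (1, 1, 1, 1, 1, 1, 1, 1),     2.3),
    _Row("Bacteroides uniformis",        "S", 7,   (1, 1, 1, 1, 1, 1, 1, 1),     2.2),
    _Row("Bacteroides vulgatus",         "S", 6,   (1, 1, 1, 1, 1, 1, 1, 1),     2.0),
    _Row("Coprococcus eutactus",         "S", 1,   (1, 1, 1, 1, 1, 0, 1, 0),     1.6),
    _Row("Sutterella massiliensis",      "G", 4,   (0, 1, 0, 0, 1, 0.5, 1, 0),   1.6),
    _Row("[Eubacterium] rectale",        "S", 3,   (1, 1, 1, 1, 1, 0, 0, 1),     1.4),
    _Row("Bacteroides stercoris",        "S", 2,   (1, 1, 1, 1, 1, 1, 1, 1),     1.2),
    _Row("Blautia faecis",               "G", 23,  (0.75, 0.31, 0.77, 0.07, 1, 0.19, 0.86, 1), 1.1),
    _Row("Bacteroides stercorirosoris",  "S", 1,   (1, 1, 1, 1, 1, 1, 1, 0),     0.9),
    _Row("Bacteroides cellulosilyticus", "S", 3,   (1, 1, 1, 1, 1, 1, 1, 1),     0.8),
    _Row("Ruminococcus champanellensis", "S", 2,   (0, 0, 1, 0, 1, 0, 1, 0),     0.8),
    _Row("Parabacteroides goldsteinii",  "S", 3,   (1, 1, 1, 1, 1, 1, 1, 1),     0.8),
)

TABLE3_ROWS: tuple[_Row, ...] = (
    _Row("Bacteroides thetaiotaomicron", "S", 3,  (1, 1, 1, 1, 1, 1, 1, 0),    25.5),
    _Row("Escherichia fergusonii",       "S", 5,  (1, 1, 1, 1, 1, 1, 1, 0),    21.0),
    _Row("Flavonifractor plautii",       "S", 3,  (0, 0, 0, 0, 0, 0, 0, 1),     6.9),
    _Row("Peptoniphilus grossensis",     "S", 2,  (0, 1, 0.5, 0, 0, 0, 1, 0),   6.7),
    _Row("Finegoldia magna",             "S", 6,  (1, 0, 0, 0, 1, 0, 1, 0),     5.0),
    _Row("Bacteroides faecis",           "S", 2,  (1, 1, 1, 1, 1, 1, 1, 0),     4.5),
    _Row("Bacteroides vulgatus",         "S", 6,  (1, 1, 1, 1, 1, 1, 1, 1),     3.1),
    _Row("Bacteroides caccae",           "S", 3,  (1, 1, 1, 1, 1, 1, 1, 0),     3.1),
    _Row("Clostridium perfringens",      "S", 4,  (1, 1, 1, 0, 0, 0, 1, 1),     2.5),
    _Row("Phascolarctobacterium faecium","G", 1,  (1, 1, 0, 1, 1, 1, 1, 1),     1.8),
    _Row("Bacteroides massiliensis",     "S", 1,  (1, 1, 1, 1, 1, 1, 1, 0),     1.7),
    _Row("Bacteroides uniformis",        "S", 7,  (1, 1, 1, 1, 1, 1, 1, 1),     1.7),
    _Row("Agathobaculum desmolans",      "S", 1,  (0, 0, 0, 0, 0, 0, 0, 1),     1.2),
    _Row("Akkermansia muciniphila",      "S", 4,  (1, 1, 1, 1, 1, 1, 1, 0.25),  1.2),
    _Row("Pseudoflavonifractor phocaeensis", "G", 3, (0, 0.5, 0, 0, 0, 0, 0, 0.5), 1.2),
    _Row("Bacteroides ovatus",           "S", 7,  (1, 1, 1, 1, 1, 1, 1, 0),     1.0),
    _Row("Parabacteroides merdae",       "S", 4,  (1, 1, 1, 1, 1, 1, 1, 1),     0.9),
    _Row("Eggerthella lenta",            "S", 3,  (1, 0, 0, 0.67, 1, 0, 1, 0),  0.6),
    _Row("Flintibacter butyricus",       "S", 3,  (0, 0, 0, 0, 0, 0, 0, 1),     0.2),
    _Row("Pseudoflavonifractor capillosus", "S", 1, (0, 0, 0, 0, 0, 0, 0, 1),   0.2),
)
# fmt: on

#: Hand-solved genus structures for G rows whose printed indices are not k/n
#: under hierarchical weighting. Per species: (species name or None for a
#: generated placeholder, genome count, per-vitamin prototroph counts).
#: Species listed with a name are the genus' separately printed species-level
#: members and are NOT re-created (their genomes come from their own S row).
_GENUS_STRUCTURES: dict[str, tuple[tuple[str | None, int, tuple[int, ...]], ...]] = {
    # 23 genomes: printed (0.75, 0.31, 0.77, 0.07, 1, 0.19, 0.86, 1)
    "Blautia": (
        ("Blautia glucerasea", 1, (1, 0, 1, 0, 1, 0, 1, 1)),
        (None, 6, (6, 6, 5, 2, 6, 2, 6, 6)),
        (None, 6, (2, 2, 0, 0, 6, 0, 3, 6)),
        (None, 5, (5, 1, 5, 0, 5, 3, 5, 5)),
        (None, 5, (2, 0, 5, 0, 5, 0, 4, 5)),
    ),
    # 3 genomes: printed (0, 0.5, 0, 0, 0, 0, 0, 0.5)
    "Pseudoflavonifractor": (
        ("Pseudoflavonifractor capillosus", 1, (0, 0, 0, 0, 0, 0, 0, 1)),
        (None, 2, (0, 2, 0, 0, 0, 0, 0, 0)),
    ),
}

_TABLES = {"table2": TABLE2_ROWS, "table3": TABLE3_ROWS}


def _family_of(genus: str) -> str:
    return f"{genus}aceae"


def _binary_rows(n: int, counts: tuple[int, ...]) -> list[tuple[int, ...]]:
    """Expand per-vitamin prototroph counts into n binary vectors,
    prototrophs first."""
    return [tuple(1 if j < k else 0 for k in counts) for j in range(n)]


def _species_genomes(species: str, genus: str, n: int, counts: tuple[int, ...]):
    family = _family_of(genus)
    return [
        ReferenceGenome(f"{species}.g{j + 1}", species, genus, family, vec)
        for j, vec in enumerate(_binary_rows(n, counts))
    ]


def table_fixture(name: str) -> tuple[ReferenceCollection, CommunityProfile]:
    """Reference collection + single-sample community profile for one of
    the packaged worked examples ('table2' or 'table3').

    The profile's abundances are the printed percentages renormalized to
    sum to 1; every printed index is reproduced cell-for-cell (2-decimal
    rounding) when the profile is run through mapping + phenotype indexing.
    """
    if name not in _TABLES:
        raise ConfigError(f"unknown fixture {name!r}; choose from {sorted(_TABLES)}")
    rows = _TABLES[name]
    genomes: list[ReferenceGenome] = []
    built_genera: set[str] = set()
    species_rows = {r.name: r for r in rows if r.level == "S"}
    placeholder = 0

    def build_structured_genus(genus: str) -> None:
        nonlocal placeholder
        for sp_name, n, counts in _GENUS_STRUCTURES[genus]:
            if sp_name is None:
                placeholder += 1
                sp_name = f"{genus} sp. PB{placeholder:02d}"
                genomes.extend(_species_genomes(sp_name, genus, n, counts))
            else:
                # printed species-level member: created from its own S row
                row = species_rows[sp_name]
                counts_from_row = tuple(round(t * row.genomes) for t in row.indices)
                genomes.extend(_species_genomes(sp_name, genus, row.genomes, counts_from_row))
        built_genera.add(genus)

    for r in rows:
        genus = genus_token(r.name)
        if r.level == "S":
            if genus in _GENUS_STRUCTURES:
                if genus not in built_genera:
                    build_structured_genus(genus)
                continue
            counts = tuple(round(t * r.genomes) for t in r.indices)
            genomes.extend(_species_genomes(r.name, genus, r.genomes, counts))
        elif r.level == "G":
            if genus in _GENUS_STRUCTURES:
                if genus not in built_genera:
                    build_structured_genus(genus)
                continue
            # flat-realizable genus: one singleton species per genome
            counts = tuple(round(t * r.genomes) for t in r.indices)
            for vec in _binary_rows(r.genomes, counts):
                placeholder += 1
                sp = f"{genus} sp. PB{placeholder:02d}"
                genomes.append(
                    ReferenceGenome(f"{sp}.g1", sp, genus, _family_of(genus), vec)
                )
        else:  # family-level row: 1 genus of singleton species, flat average
            counts = tuple(round(t * r.genomes) for t in r.indices)
            per_vitamin = _binary_rows(r.genomes, counts)
            for vec_i, vec in enumerate(per_vitamin):
                sp = f"{genus} sp. PB-F{vec_i + 1:03d}"
                genomes.append(
                    ReferenceGenome(f"{sp}.g1", sp, genus, _family_of(genus), vec)
                )
    collection = ReferenceCollection(genomes, panel=DEFAULT_PANEL)
    phylotypes = {
        r.name: Phylotype(r.name, r.name, _LEVEL_IDENTITY[r.level])
        for r in rows
    }
    profile = CommunityProfile.from_percent(
        sample_id=name,
        percents={r.name: r.abundance for r in rows},
        phylotypes=phylotypes,
    )
    return collection, profile


def fixture_path(filename: str):
    """Path to a packaged fixture TSV (e.g. ``table2_bpm.tsv``,
    ``table2_profile.tsv``, ``copy_numbers_synthetic.tsv``)."""
    from importlib.resources import files

    path = files("phenosig").joinpath("data", filename)
    if not path.is_file():
        raise ConfigError(f"no packaged fixture named {filename!r}")
    return path


def printed_index_matrix(name: str) -> pd.DataFrame:
    """The printed phylotype x vitamin prototrophy indices (regression
    reference for the whole-matrix reproduction test)."""
    rows = _TABLES.get(name)
    if rows is None:
        raise ConfigError(f"unknown fixture {name!r}")
    return pd.DataFrame(
        [r.indices for r in rows],
        index=pd.Index([r.name for r in rows], name="phylotype_id"),
        columns=list(DEFAULT_PANEL),
        dtype=float,
    )


def printed_abundances(name: str) -> pd.Series:
    rows = _TABLES.get(name)
    if rows is None:
        raise ConfigError(f"unknown fixture {name!r}")
    return pd.Series({r.name: r.abundance for r in rows}, name="abundance_pct")


def printed_mapping_levels(name: str) -> pd.Series:
    rows = _TABLES.get(name)
    if rows is None:
        raise ConfigError(f"unknown fixture {name!r}")
    return pd.Series({r.name: _LEVEL_RANK[r.level] for r in rows}, name="level")
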