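"""Reference collection of genomes with taxonomy and binary vitamin phenotypes.

The binary phenotype matrix (BPM) assigns each reference genome a 0/1 call per
vitamin: 1 = prototrophy (complete de novo biosynthesis pathway), 0 =
auxotrophy (dependent on exogenous salvage). Calls are produced upstream by
genomic metabolic reconstruction; this module only loads, validates and
indexes them. Phenotypes are strictly binary at genome level; fractional
prototrophy indices (e.g. 0.25 for a species where one of four strains is a
prototroph) exist only as derived averages downstream, never in the BPM.

Taxonomy is stored as explicit species/genus/family strings -- phylotypes are
only ever mapped at these three ranks, so no tree is needed. Names are matched
case-insensitively after trimming bracket conventions ("[Eubacterium]
rectale"); exact normalized string match only, no fuzzy matching.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConsistencyError, FormatError, UnknownTaxonError
from .panel import DEFAULT_PANEL, VitaminPanel

logger = logging.getLogger(__name__)

RANKS = ("species", "genus", "family")

TAXONOMY_COLUMNS = ("genome_id", "species", "genus", "family")

_BRACKETS = re.compile(r"[\[\]]")
_WS = re.compile(r"\s+")


def normalize_name(name: str) -> str:
    """Normalize a taxon name for lookup: strip brackets, collapse
    whitespace, casefold."""
    return _WS.sub(" ", _BRACKETS.sub("", name)).strip().casefold()


def genus_token(name: str) -> str:
    """First word of a (possibly bracketed) binomial, e.g. the genus of
    '[Eubacterium] rectale' is 'Eubacterium'."""
    return _BRACKETS.sub("", name).strip().split()[0] if name.strip() else ""


@dataclass(frozen=True)
class ReferenceGenome:
    """One genome row of the BPM: id, 3-rank taxonomy, binary phenotypes."""

    genome_id: str
    species: str
    genus: str
    family: str
    phenotypes: tuple[int, ...]

    def __post_init__(self) -> None:
        for rank in ("species", "genus", "family"):
            if not getattr(self, rank).strip():
                raise FormatError(f"genome {self.genome_id!r}: empty {rank} name")
        if any(v not in (0, 1) for v in self.phenotypes):
            raise FormatError(
                f"genome {self.genome_id!r}: phenotype values must be 0/1, "
                f"got {self.phenotypes}"
            )


@dataclass(frozen=True)
class GenomeNeighborhood:
    """The genomes a phylotype's phenotype is averaged over, grouped
    hierarchically (genus -> species -> genomes) so that weighting can split
    level by level."""

    rank: str
    name: str
    #: genus -> species -> genomes; for rank "species" there is exactly one
    #: genus entry holding one species.
    groups: tuple[tuple[str, tuple[tuple[str, tuple[ReferenceGenome, ...]], ...]], ...]

    def genomes(self) -> tuple[ReferenceGenome, ...]:
        return tuple(
            g for _, species in self.groups for _, genomes in species for g in genomes
        )

    @property
    def n_genomes(self) -> int:
        return len(self.genomes())

    def species_sizes(self) -> dict[str, int]:
        return {
            sp: len(genomes)
            for _, species in self.groups
            for sp, genomes in species
        }


class ReferenceCollection:
    """An indexed set of reference genomes sharing one vitamin panel.

    Indexes by species, genus and family are built eagerly; construction
    enforces unique genome ids and a consistent taxonomy (each species under
    a single genus, each genus under a single family).
    """

    def __init__(self, genomes, panel: VitaminPanel = DEFAULT_PANEL):
        self.panel = panel
        self.genomes: tuple[ReferenceGenome, ...] = tuple(genomes)
        for g in self.genomes:
            if len(g.phenotypes) != len(panel):
                raise FormatError(
                    f"genome {g.genome_id!r} has {len(g.phenotypes)} phenotype "
                    f"values for a {len(panel)}-vitamin panel"
                )
        problems = taxonomy_inconsistencies(self.to_frame()) if self.genomes else []
        if problems:
            raise ConsistencyError("; ".join(problems))
        seen: set[str] = set()
        for g in self.genomes:
            if g.genome_id in seen:
                raise ConsistencyError(f"duplicate genome_id {g.genome_id!r}")
            seen.add(g.genome_id)
        # canonical display names + nested index, keyed by normalized names
        self._species: dict[str, dict] = {}
        self._genus: dict[str, dict] = {}
        self._family: dict[str, dict] = {}
        for g in sorted(self.genomes, key=lambda g: g.genome_id):
            sp, gn, fa = normalize_name(g.species), normalize_name(g.genus), normalize_name(g.family)
            s = self._species.setdefault(
                sp, {"name": g.species, "genus": gn, "family": fa, "genomes": []}
            )
            s["genomes"].append(g)
            ge = self._genus.setdefault(gn, {"name": g.genus, "family": fa, "species": {}})
            ge["species"].setdefault(sp, s)
            f = self._family.setdefault(fa, {"name": g.family, "genera": {}})
            f["genera"].setdefault(gn, ge)

    def __len__(self) -> int:
        return len(self.genomes)

    # -- lookups ---------------------------------------------------------

    def species_names(self) -> list[str]:
        return sorted(e["name"] for e in self._species.values())

    def genus_names(self) -> list[str]:
        return sorted(e["name"] for e in self._genus.values())

    def family_names(self) -> list[str]:
        return sorted(e["name"] for e in self._family.values())

    def resolve(self, name: str, rank: str) -> str | None:
        """Resolve ``name`` to a canonical taxon name at ``rank``.

        A species binomial resolves at genus/family rank through its genus
        token, so a phylotype whose best 16S match is a species absent from
        the collection can still map at a coarser rank. Returns None when
        nothing matches.
        """
        if rank not in RANKS:
            raise UnknownTaxonError(f"unknown rank {rank!r}")
        norm = normalize_name(name)
        if rank == "species":
            e = self._species.get(norm)
            return e["name"] if e else None
        token = normalize_name(genus_token(name)) if name.strip() else ""
        if rank == "genus":
            if norm in self._species:
                return self._genus[self._species[norm]["genus"]]["name"]
            if norm in self._genus:
                return self._genus[norm]["name"]
            if token and token in self._genus:
                return self._genus[token]["name"]
            return None
        # family
        for key in (norm, token):
            if key and key in self._species:
                return self._family[self._species[key]["family"]]["name"]
            if key and key in self._genus:
                return self._family[self._genus[key]["family"]]["name"]
            if key and key in self._family:
                return self._family[key]["name"]
        return None

    def neighborhood(self, name: str, rank: str) -> GenomeNeighborhood:
        """Genome set at ``rank`` for taxon ``name``, grouped genus ->
        species -> genomes (sorted for determinism)."""
        norm = normalize_name(name)

        def species_tuple(entries) -> tuple:
            return tuple(
                (e["name"], tuple(sorted(e["genomes"], key=lambda g: g.genome_id)))
                for e in sorted(entries, key=lambda e: e["name"])
            )

        if rank == "species":
            e = self._species.get(norm)
            if e is None:
                raise UnknownTaxonError(f"species {name!r} not in collection")
            genus_name = self._genus[e["genus"]]["name"]
            return GenomeNeighborhood(rank, e["name"], ((genus_name, species_tuple([e])),))
        if rank == "genus":
            e = self._genus.get(norm)
            if e is None:
                raise UnknownTaxonError(f"genus {name!r} not in collection")
            return GenomeNeighborhood(rank, e["name"], ((e["name"], species_tuple(e["species"].values())),))
        if rank == "family":
            e = self._family.get(norm)
            if e is None:
                raise UnknownTaxonError(f"family {name!r} not in collection")
            groups = tuple(
                (ge["name"], species_tuple(ge["species"].values()))
                for ge in sorted(e["genera"].values(), key=lambda ge: ge["name"])
            )
            return GenomeNeighborhood(rank, e["name"], groups)
        raise UnknownTaxonError(f"unknown rank {rank!r}")

    # -- serialization ---------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (g.genome_id, g.species, g.genus, g.family, *g.phenotypes)
            for g in self.genomes
        ]
        return pd.DataFrame(rows, columns=list(TAXONOMY_COLUMNS) + list(self.panel))


def taxonomy_inconsistencies(df: pd.DataFrame) -> list[str]:
    """Species mapped to >1 genus, or genus mapped to >1 family."""
    problems = []
    if df.empty:
        return problems
    norm = df.assign(
        _sp=df["species"].map(normalize_name),
        _gn=df["genus"].map(normalize_name),
        _fa=df["family"].map(normalize_name),
    )
    for sp, sub in norm.groupby("_sp"):
        if sub["_gn"].nunique() > 1:
            problems.append(
                f"species {sub['species'].iloc[0]!r} appears under genera "
                f"{sorted(sub['genus'].unique())}"
            )
    for gn, sub in norm.groupby("_gn"):
        if sub["_fa"].nunique() > 1:
            problems.append(
                f"genus {sub['genus'].iloc[0]!r} appears under families "
                f"{sorted(sub['family'].unique())}"
            )
    return problems


def load_reference_collection(path, panel: VitaminPanel | None = None) -> ReferenceCollection:
    """Load a BPM TSV: columns genome_id, species, genus, family, then one
    0/1 column per panel vitamin.

    If ``panel`` is None the vitamin columns are taken from the header (every
    column after ``family``, in file order).
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in TAXONOMY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    vitamin_cols = [c for c in df.columns if c not in TAXONOMY_COLUMNS]
    if panel is None:
        panel = VitaminPanel(tuple(vitamin_cols)) if vitamin_cols else DEFAULT_PANEL
    else:
        absent = [v for v in panel if v not in vitamin_cols]
        if absent:
            raise FormatError(f"{path}: missing vitamin columns {absent}")
    if df.empty:
        logger.warning("%s: BPM file contains a header but no genomes", path)
        return ReferenceCollection([], panel=panel)
    dup = df["genome_id"][df["genome_id"].duplicated()]
    if not dup.empty:
        raise ConsistencyError(f"{path}: duplicate genome_id {dup.iloc[0]!r}")
    genomes = []
    for i, row in df.iterrows():
        values = []
        for v in panel:
            cell = str(row[v]).strip()
            if cell not in ("0", "1"):
                raise FormatError(
                    f"{path}: row {i + 2}, column {v!r}: expected 0/1, got {cell!r}"
                )
            values.append(int(cell))
        genomes.append(
            ReferenceGenome(row["genome_id"], row["species"], row["genus"], row["family"], tuple(values))
        )
    return ReferenceCollection(genomes, panel=panel)


def write_reference_collection(collection: ReferenceCollection, path) -> None:
    collection.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class ValidationReport:
    """Report-only summary of a collection: sizes, per-vitamin prototroph
    counts, and any taxonomy inconsistencies."""

    n_genomes: int
    n_species: int
    n_genera: int
    n_families: int
    genomes_per_species: dict[str, int]
    prototroph_counts: pd.Series
    inconsistencies: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.inconsistencies

    def to_text(self) -> str:
        lines = [
            f"genomes: {self.n_genomes}  species: {self.n_species}  "
            f"genera: {self.n_genera}  families: {self.n_families}",
            "prototroph counts per vitamin:",
        ]
        for v, n in self.prototroph_counts.items():
            lines.append(f"  {v}: {n} prototrophs / {self.n_genomes - n} auxotrophs")
        if self.inconsistencies:
            lines.append("taxonomy inconsistencies:")
            lines.extend(f"  {p}" for p in self.inconsistencies)
        return "\n".join(lines)


def validate_collection(c: ReferenceCollection) -> ValidationReport:
    df = c.to_frame()
    return validate_reference_frame(df, panel=c.panel)


def validate_reference_frame(df: pd.DataFrame, panel: VitaminPanel = DEFAULT_PANEL) -> ValidationReport:
    """Validate a raw BPM frame (may contain inconsistencies a constructed
    ReferenceCollection would reject)."""
    counts = (
        df[list(panel)].astype(int).sum()
        if not df.empty
        else pd.Series(0, index=list(panel))
    )
    per_species = (
        df.groupby(df["species"].map(normalize_name))["genome_id"].count().to_dict()
        if not df.empty
        else {}
    )
    return ValidationReport(
        n_genomes=len(df),
        n_species=df["species"].map(normalize_name).nunique() if not df.empty else 0,
        n_genera=df["genus"].map(normalize_name).nunique() if not df.empty else 0,
        n_families=df["family"].map(normalize_name).nunique() if not df.empty else 0,
        genomes_per_species=per_species,
        prototroph_counts=counts,
        inconsistencies=taxonomy_inconsistencies(df),
    )
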