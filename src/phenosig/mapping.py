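"""Mapping phylotypes onto the reference collection at species/genus/family.

A phylotype arrives with the name of its best 16S match and the percent
identity of that match. Identity decides the mapping rank (defaults: >=98%
species, >=95% genus, >=90% family -- the family floor is a conventional 16S
cutoff, the other two follow standard phylotype-calling practice), and the
phylotype's phenotype is then averaged over its phylogenetic neighborhood at
that rank with hierarchical equal weights:

* species level -- equal weight to every strain genome of the species;
* genus level  -- equal weight per species within the genus, split equally
  among that species' genomes;
* family level -- equal per genus, then per species, then per genome.

A phylotype whose name does not resolve at its assigned rank is downgraded
one rank at a time (species -> genus -> family) with a logged warning rather
than discarded, which preserves abundance coverage. Phylotypes that resolve
nowhere are flagged unmapped and excluded from phenotype prediction; their
abundance is reported as the unmapped remainder.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import ConfigError, ConsistencyError, DataError
from .reference import RANKS, GenomeNeighborhood, ReferenceCollection

logger = logging.getLogger(__name__)

ABUNDANCE_TOL = 1e-9


@dataclass(frozen=True)
class MappingThresholds:
    """Percent-identity floors per rank; must be strictly decreasing."""

    species: float = 98.0
    genus: float = 95.0
    family: float = 90.0

    def __post_init__(self) -> None:
        if not (self.species > self.genus > self.family):
            raise ConfigError(
                "mapping thresholds must be strictly decreasing "
                f"(species > genus > family), got {self}"
            )
        for rank in RANKS:
            t = getattr(self, rank)
            if not 0 <= t <= 100:
                raise ConfigError(f"{rank} threshold {t} outside [0, 100]")


DEFAULT_THRESHOLDS = MappingThresholds()


@dataclass(frozen=True)
class Phylotype:
    """A 16S-defined taxon: best reference match plus percent identity
    and/or an explicitly declared rank."""

    phylotype_id: str
    best_match_name: str
    best_match_identity: float | None = None
    declared_rank: str | None = None

    def __post_init__(self) -> None:
        if self.best_match_identity is None and self.declared_rank is None:
            raise ConfigError(
                f"phylotype {self.phylotype_id!r}: need identity or declared_rank"
            )
        if self.best_match_identity is not None and not (
            0 <= self.best_match_identity <= 100
        ):
            raise DataError(
                f"phylotype {self.phylotype_id!r}: identity "
                f"{self.best_match_identity} outside [0, 100]"
            )
        if self.declared_rank is not None and self.declared_rank not in RANKS:
            raise ConfigError(
                f"phylotype {self.phylotype_id!r}: bad declared_rank "
                f"{self.declared_rank!r}"
            )


@dataclass
class CommunityProfile:
    """Relative abundances of one sample's phylotypes (fractions summing
    to 1). Phylotype metadata rides along in ``phylotypes``; ids without an
    entry are treated as species names declared at species rank, which is
    how simulated studies label their taxa."""

    sample_id: str
    abundances: dict[str, float]
    group_label: str | None = None
    phylotypes: dict[str, Phylotype] | None = None

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.abundances.values()):
            bad = min(self.abundances, key=self.abundances.get)
            raise DataError(
                f"sample {self.sample_id!r}: negative abundance for {bad!r}"
            )
        total = sum(self.abundances.values())
        if self.abundances and not math.isclose(total, 1.0, abs_tol=ABUNDANCE_TOL):
            raise DataError(
                f"sample {self.sample_id!r}: abundances sum to {total!r}, not 1"
            )

    @classmethod
    def from_percent(cls, sample_id, percents: dict[str, float], **kw) -> "CommunityProfile":
        """Build from percent values; renormalizes so fractions sum to 1
        exactly (avoids silent 100x errors from percent/fraction mixups)."""
        total = sum(percents.values())
        if total <= 0:
            raise DataError(f"sample {sample_id!r}: non-positive total abundance")
        return cls(sample_id, {k: v / total for k, v in percents.items()}, **kw)

    def phylotype(self, phylotype_id: str) -> Phylotype:
        if self.phylotypes and phylotype_id in self.phylotypes:
            return self.phylotypes[phylotype_id]
        return Phylotype(phylotype_id, phylotype_id, declared_rank="species")


@dataclass(frozen=True)
class MappingResult:
    """Where a phylotype landed: rank, canonical matched name, its genome
    neighborhood and per-genome weights (sum to 1 when mapped)."""

    phylotype_id: str
    mapping_level: str  # species | genus | family | unmapped
    matched_name: str = ""
    neighborhood: GenomeNeighborhood | None = None
    weights: dict[str, float] = field(default_factory=dict)
    downgraded: bool = False

    @property
    def mapped(self) -> bool:
        return self.mapping_level != "unmapped"


def assign_mapping_level(identity: float, thresholds: MappingThresholds = DEFAULT_THRESHOLDS) -> str:
    """Rank implied by percent identity; 'unmapped' below the family floor."""
    if not 0 <= identity <= 100:
        raise DataError(f"identity {identity} outside [0, 100]")
    if identity >= thresholds.species:
        return "species"
    if identity >= thresholds.genus:
        return "genus"
    if identity >= thresholds.family:
        return "family"
    return "unmapped"


def hierarchical_weights(neighborhood: GenomeNeighborhood) -> dict[str, float]:
    """Equal-per-child recursive weights over a neighborhood.

    At species rank weight splits equally over genomes; at genus rank
    equally over species then genomes; at family rank equally over genera,
    then species, then genomes.
    """
    weights: dict[str, float] = {}
    if neighborhood.rank == "species":
        genomes = neighborhood.genomes()
        for g in genomes:
            weights[g.genome_id] = 1.0 / len(genomes)
        return weights
    if neighborhood.rank == "genus":
        (_, species_groups), = neighborhood.groups
        for _, genomes in species_groups:
            for g in genomes:
                weights[g.genome_id] = 1.0 / (len(species_groups) * len(genomes))
        return weights
    # family
    n_genera = len(neighborhood.groups)
    for _, species_groups in neighborhood.groups:
        for _, genomes in species_groups:
            for g in genomes:
                weights[g.genome_id] = 1.0 / (n_genera * len(species_groups) * len(genomes))
    return weights


def map_phylotype(
    p: Phylotype,
    collection: ReferenceCollection,
    thresholds: MappingThresholds = DEFAULT_THRESHOLDS,
) -> MappingResult:
    """Map one phylotype, falling back one rank at a time when its name does
    not resolve at the assigned rank."""
    if p.declared_rank is not None:
        start = p.declared_rank
    else:
        start = assign_mapping_level(p.best_match_identity, thresholds)
    if start == "unmapped":
        return MappingResult(p.phylotype_id, "unmapped")
    for rank in RANKS[RANKS.index(start):]:
        resolved = collection.resolve(p.best_match_name, rank)
        if resolved is not None:
            if rank != start:
                logger.warning(
                    "phylotype %s: %r not found at %s level, downgraded to %s (%r)",
                    p.phylotype_id, p.best_match_name, start, rank, resolved,
                )
            neigh = collection.neighborhood(resolved, rank)
            return MappingResult(
                p.phylotype_id,
                rank,
                matched_name=resolved,
                neighborhood=neigh,
                weights=hierarchical_weights(neigh),
                downgraded=rank != start,
            )
    logger.warning(
        "phylotype %s: %r unmapped at all ranks", p.phylotype_id, p.best_match_name
    )
    return MappingResult(p.phylotype_id, "unmapped")


def map_profile(
    profile: CommunityProfile,
    collection: ReferenceCollection,
    thresholds: MappingThresholds = DEFAULT_THRESHOLDS,
) -> tuple[list[MappingResult], float]:
    """Map every phylotype of a sample.

    Returns one MappingResult per phylotype (unmapped ones retained,
    flagged) and the mapped fraction: the total relative abundance of
    phylotypes that resolved at some rank.
    """
    results = [
        map_phylotype(profile.phylotype(pid), collection, thresholds)
        for pid in profile.abundances
    ]
    mapped_fraction = sum(
        profile.abundances[m.phylotype_id] for m in results if m.mapped
    )
    return results, mapped_fraction


# -- profile TSV I/O -----------------------------------------------------


def load_profiles(
    path,
    metadata_path=None,
) -> tuple[dict[str, Phylotype], list[CommunityProfile]]:
    """Read a wide profile TSV: ``phylotype_id  best_match_name
    identity_pct  <sample_1> ... <sample_n>``.

    Sample columns may be percent or fractions; each column is renormalized
    to sum to 1. An optional metadata TSV (``sample_id  group``) attaches
    diet-group labels.
    """
    df = pd.read_csv(path, sep="\t", dtype={"phylotype_id": str, "best_match_name": str})
    required = ["phylotype_id", "best_match_name", "identity_pct"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ConsistencyError(f"{path}: missing columns {missing}")
    if df["phylotype_id"].duplicated().any():
        dup = df["phylotype_id"][df["phylotype_id"].duplicated()].iloc[0]
        raise ConsistencyError(f"{path}: duplicate phylotype_id {dup!r}")
    phylotypes = {
        r.phylotype_id: Phylotype(
            r.phylotype_id,
            r.best_match_name,
            None if pd.isna(r.identity_pct) else float(r.identity_pct),
            declared_rank="species" if pd.isna(r.identity_pct) else None,
        )
        for r in df.itertuples()
    }
    groups: dict[str, str] = {}
    if metadata_path is not None:
        meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
        if not {"sample_id", "group"} <= set(meta.columns):
            raise ConsistencyError(f"{metadata_path}: need columns sample_id, group")
        groups = dict(zip(meta["sample_id"], meta["group"]))
    sample_cols = [c for c in df.columns if c not in required]
    profiles = []
    for col in sample_cols:
        values = dict(zip(df["phylotype_id"], df[col].astype(float)))
        profiles.append(
            CommunityProfile.from_percent(
                col, values, group_label=groups.get(col), phylotypes=phylotypes
            )
        )
    return phylotypes, profiles


def write_profiles(
    phylotypes: dict[str, Phylotype],
    profiles: list[CommunityProfile],
    path,
    percent: bool = True,
) -> None:
    ids = sorted(phylotypes)
    scale = 100.0 if percent else 1.0
    out = pd.DataFrame({
        "phylotype_id": ids,
        "best_match_name": [phylotypes[i].best_match_name for i in ids],
        "identity_pct": [phylotypes[i].best_match_identity for i in ids],
    })
    for prof in profiles:
        out[prof.sample_id] = [scale * prof.abundances.get(i, 0.0) for i in ids]
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_metadata(profiles: list[CommunityProfile], path) -> None:
    pd.DataFrame(
        {"sample_id": [p.sample_id for p in profiles],
         "group": [p.group_label or "" for p in profiles]}
    ).to_csv(path, sep="\t", index=False)
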