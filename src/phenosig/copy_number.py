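"""Optional 16S rRNA gene copy-number renormalization.

Read counts over-represent taxa with many rRNA operon copies. Given a table
of mean copy numbers per taxon (rrnDB-style: taxon, rank, mean copy number),
each phylotype's relative abundance is divided by the copy number of its
best-matching taxon -- species entry preferred, then genus, then family, then
a collection-wide default -- and the sample is rescaled to sum to one:

    A'_i = (A_i / c_i) / sum_j (A_j / c_j)

The stage is OFF by default: copy-number catalogs are incomplete and
imprecise, so renormalization is an explicit opt-in preprocessing step, not
part of the core projection. The default fallback copy number is the
unweighted mean of all table entries.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .errors import DataError, FormatError
from .mapping import CommunityProfile, Phylotype
from .reference import ReferenceCollection, genus_token, normalize_name

logger = logging.getLogger(__name__)

_RANKS = ("species", "genus", "family")


@dataclass
class CopyNumberTable:
    """Mean 16S copy number per (rank, normalized taxon name)."""

    entries: dict[tuple[str, str], float]
    default_copy_number: float

    def __post_init__(self) -> None:
        bad = [k for k, v in self.entries.items() if not v > 0]
        if bad or not self.default_copy_number > 0:
            raise DataError(f"copy numbers must be positive; offending: {bad or 'default'}")

    def lookup(
        self,
        species: str | None = None,
        genus: str | None = None,
        family: str | None = None,
    ) -> tuple[float, str]:
        """Best-match copy number and the rank it matched at ('default'
        when nothing matched)."""
        for rank, name in zip(_RANKS, (species, genus, family)):
            if name:
                value = self.entries.get((rank, normalize_name(name)))
                if value is not None:
                    return value, rank
        return self.default_copy_number, "default"


def load_copy_number_table(path) -> CopyNumberTable:
    """Read a ``taxon  rank  mean_copy_number`` TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"taxon": str, "rank": str})
    missing = {"taxon", "rank", "mean_copy_number"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    entries: dict[tuple[str, str], float] = {}
    for i, row in df.iterrows():
        rank = str(row["rank"]).strip().lower()
        if rank not in _RANKS:
            raise FormatError(f"{path}: row {i + 2}: unknown rank {row['rank']!r}")
        value = float(row["mean_copy_number"])
        if not value > 0:
            raise DataError(f"{path}: row {i + 2}: non-positive copy number {value}")
        entries[(rank, normalize_name(str(row["taxon"])))] = value
    if not entries:
        raise FormatError(f"{path}: empty copy-number table")
    default = sum(entries.values()) / len(entries)
    return CopyNumberTable(entries, default)


def lookup_copy_number(
    p: Phylotype,
    table: CopyNumberTable,
    collection: ReferenceCollection | None = None,
) -> float:
    """Copy number for a phylotype via its best-match name.

    The species candidate is the full match name, the genus candidate its
    first token; the family candidate is resolved through the reference
    collection when one is supplied.
    """
    family = collection.resolve(p.best_match_name, "family") if collection else None
    value, rank = table.lookup(
        species=p.best_match_name,
        genus=genus_token(p.best_match_name),
        family=family,
    )
    if rank == "default":
        logger.warning(
            "phylotype %s: no copy-number match for %r, using default %.3g",
            p.phylotype_id, p.best_match_name, value,
        )
    return value


def renormalize_profile(
    profile: CommunityProfile,
    table: CopyNumberTable,
    collection: ReferenceCollection | None = None,
) -> CommunityProfile:
    """Divide each abundance by its taxon copy number and rescale to 1."""
    adjusted = {
        pid: a / lookup_copy_number(profile.phylotype(pid), table, collection)
        for pid, a in profile.abundances.items()
    }
    total = sum(adjusted.values())
    if total <= 0:
        raise DataError(f"sample {profile.sample_id!r}: empty profile after renormalization")
    return CommunityProfile(
        sample_id=profile.sample_id,
        abundances={pid: v / total for pid, v in adjusted.items()},
        group_label=profile.group_label,
        phylotypes=profile.phylotypes,
    )
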