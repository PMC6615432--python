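"""Community phenotype profiling: from mapped phylotypes to auxotrophy signatures.

Per phylotype i, the prototrophy index for vitamin v is the weighted average
of genome binaries over its phylogenetic neighborhood,

    p_iv = sum_m w_im * p_mv,    p_iv in [0, 1],

a probabilistic estimate that a cell of that phylotype carries the complete
de novo pathway. Stacking the indices gives the Community Phenotype Matrix
(CPM, phylotypes x vitamins). Weighting rows by relative abundance A_i gives
per-sample totals:

    CPI_v        = 100 * sum_i A_i * p_iv          (prototrophy, %)
    auxotrophy_v = 100 * sum_i A_i * (1 - p_iv)    (auxotrophy representation, %)

Sums run over mapped phylotypes only, so CPI_v + auxotrophy_v equals
100 * mapped_fraction, and the unmapped remainder is reported explicitly.
Whether to renormalize percentages by the mapped fraction is a presentation
choice; both raw and renormalized values are exposed.

Replicate groups are summarized by the arithmetic mean and the n-1 sample
standard deviation of each vitamin's auxotrophy percentage.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConsistencyError, UndefinedIndexError
from .mapping import CommunityProfile, MappingResult
from .panel import DEFAULT_PANEL, VitaminPanel

logger = logging.getLogger(__name__)

CONSERVATION_TOL = 1e-9


@dataclass(frozen=True)
class PhenotypeIndexVector:
    """Per-vitamin prototrophy probabilities of one phylotype."""

    phylotype_id: str
    values: tuple[float, ...]
    panel: VitaminPanel = DEFAULT_PANEL

    def __getitem__(self, vitamin: str) -> float:
        return self.values[self.panel.index(vitamin)]

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.panel), name=self.phylotype_id)


def phenotype_index(m: MappingResult, panel: VitaminPanel = DEFAULT_PANEL) -> PhenotypeIndexVector:
    """Weighted average of binary genome phenotypes over the neighborhood."""
    if not m.mapped or m.neighborhood is None:
        raise UndefinedIndexError(
            f"phylotype {m.phylotype_id!r} is unmapped; phenotype index undefined"
        )
    values = np.zeros(len(panel))
    for g in m.neighborhood.genomes():
        values += m.weights[g.genome_id] * np.asarray(g.phenotypes, dtype=float)
    return PhenotypeIndexVector(m.phylotype_id, tuple(values), panel)


@dataclass
class CommunityPhenotypeMatrix:
    """Phylotypes x vitamins prototrophy indices for one sample, with the
    companion abundance column (mapped phylotypes only)."""

    sample_id: str
    phenotypes: pd.DataFrame  # index: phylotype_id, columns: vitamins
    abundance: pd.Series      # index: phylotype_id, fractions
    unmapped_abundance: float = 0.0
    group_label: str | None = None

    @property
    def mapped_fraction(self) -> float:
        return float(self.abundance.sum())


def community_phenotype_matrix(
    mappings: list[MappingResult],
    profile: CommunityProfile,
    panel: VitaminPanel = DEFAULT_PANEL,
) -> CommunityPhenotypeMatrix:
    """Assemble the CPM for one sample from its mapping results."""
    ids = {m.phylotype_id for m in mappings}
    if ids != set(profile.abundances):
        raise ConsistencyError(
            f"sample {profile.sample_id!r}: mapping results cover {len(ids)} "
            f"phylotypes but the profile has {len(profile.abundances)}"
        )
    rows, abund, unmapped = {}, {}, 0.0
    for m in mappings:
        a = profile.abundances[m.phylotype_id]
        if m.mapped:
            rows[m.phylotype_id] = phenotype_index(m, panel).values
            abund[m.phylotype_id] = a
        else:
            unmapped += a
    order = sorted(rows)
    phen = pd.DataFrame(
        [rows[i] for i in order], index=pd.Index(order, name="phylotype_id"),
        columns=list(panel), dtype=float,
    )
    return CommunityPhenotypeMatrix(
        sample_id=profile.sample_id,
        phenotypes=phen,
        abundance=pd.Series({i: abund[i] for i in order}, dtype=float, name="abundance"),
        unmapped_abundance=unmapped,
        group_label=profile.group_label,
    )


@dataclass
class CommunitySignature:
    """Per-sample, per-vitamin community totals (percent scale)."""

    sample_id: str
    cpi: pd.Series          # prototrophy, % of whole community
    auxotrophy: pd.Series   # auxotrophy representation, % of whole community
    mapped_fraction: float  # fraction in [0, 1]
    group_label: str | None = None

    @property
    def cpi_renormalized(self) -> pd.Series:
        """CPI as % of the mapped sub-community."""
        if self.mapped_fraction == 0:
            return self.cpi * math.nan
        return self.cpi / self.mapped_fraction

    @property
    def auxotrophy_renormalized(self) -> pd.Series:
        if self.mapped_fraction == 0:
            return self.auxotrophy * math.nan
        return self.auxotrophy / self.mapped_fraction


def community_signature(cpm: CommunityPhenotypeMatrix) -> CommunitySignature:
    """CPI_v = 100 * sum_i A_i p_iv and its auxotrophy complement."""
    a = cpm.abundance.to_numpy()
    p = cpm.phenotypes.to_numpy()
    cpi = 100.0 * (a @ p) if len(a) else np.zeros(p.shape[1])
    aux = 100.0 * (a @ (1.0 - p)) if len(a) else np.zeros(p.shape[1])
    return CommunitySignature(
        sample_id=cpm.sample_id,
        cpi=pd.Series(cpi, index=cpm.phenotypes.columns),
        auxotrophy=pd.Series(aux, index=cpm.phenotypes.columns),
        mapped_fraction=cpm.mapped_fraction,
        group_label=cpm.group_label,
    )


@dataclass
class GroupSignature:
    """Replicate-group mean +- SD of per-vitamin auxotrophy percentages."""

    group: str
    mean: pd.Series
    sd: pd.Series
    n: int


def aggregate_group(
    signatures: list[CommunitySignature],
    groups: dict[str, str] | None = None,
    value: str = "auxotrophy",
) -> list[GroupSignature]:
    """Mean and n-1 SD of auxotrophy (or 'cpi') per group per vitamin.

    ``groups`` maps sample_id -> label; defaults to each signature's own
    group_label. Groups with no samples are omitted with a warning.
    """
    labels = {}
    for s in signatures:
        label = (groups or {}).get(s.sample_id, s.group_label)
        if label is None:
            raise ConsistencyError(f"sample {s.sample_id!r} has no group label")
        labels.setdefault(label, []).append(s)
    if groups:
        for label in set(groups.values()) - set(labels):
            logger.warning("group %r has no samples; omitted", label)
    out = []
    for label in sorted(labels):
        members = labels[label]
        frame = pd.DataFrame([getattr(s, value) for s in members])
        sd = frame.std(ddof=1) if len(members) > 1 else frame.iloc[0] * 0.0
        out.append(GroupSignature(label, frame.mean(), sd, len(members)))
    return out


# -- tabular output ------------------------------------------------------


def signatures_to_frame(
    signatures: list[CommunitySignature], raw_fractions: bool = False
) -> pd.DataFrame:
    """Tidy sample x vitamin table: CPI, auxotrophy, renormalized variants,
    mapped fraction. Percent scale unless ``raw_fractions``."""
    scale = 0.01 if raw_fractions else 1.0
    rows = []
    for s in signatures:
        for v in s.cpi.index:
            rows.append({
                "sample_id": s.sample_id,
                "group": s.group_label or "",
                "vitamin": v,
                "cpi": scale * s.cpi[v],
                "auxotrophy": scale * s.auxotrophy[v],
                "cpi_renorm": scale * s.cpi_renormalized[v],
                "auxotrophy_renorm": scale * s.auxotrophy_renormalized[v],
                "mapped_fraction": (
                    s.mapped_fraction if raw_fractions else 100.0 * s.mapped_fraction
                ),
            })
    return pd.DataFrame(rows)


def group_signatures_to_frame(groups: list[GroupSignature]) -> pd.DataFrame:
    rows = []
    for g in groups:
        for v in g.mean.index:
            rows.append({
                "group": g.group, "vitamin": v,
                "mean_auxotrophy": g.mean[v], "sd": g.sd[v], "n": g.n,
            })
    return pd.DataFrame(rows)


def cpm_to_frame(cpms: list[CommunityPhenotypeMatrix]) -> pd.DataFrame:
    rows = []
    for cpm in cpms:
        frame = cpm.phenotypes.copy()
        frame.insert(0, "abundance", cpm.abundance)
        frame.insert(0, "sample_id", cpm.sample_id)
        rows.append(frame.reset_index())
    return pd.concat(rows, ignore_index=True)
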