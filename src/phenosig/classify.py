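"""Auxotrophy-pattern classes and diet-group comparisons.

A taxon's per-vitamin prototrophy indices are turned into calls: auxotrophic
when the index is <= ``aux_threshold`` (default 0), prototrophic when it is
>= ``proto_threshold`` (default 1), ambiguous in between. Under these strict
defaults only taxa with fully binary index vectors get unambiguous calls,
which restricts class membership to unambiguous auxotrophy; relaxed
thresholds (say 0.2/0.8) are available for exploratory use. Classes:

* ``omni_prototroph``  -- prototrophic for every vitamin on the panel;
* ``mono_auxotroph``   -- auxotrophic for exactly one vitamin;
* ``oligo_auxotroph``  -- 1 < k < ``multi_min`` auxotrophies (all unambiguous);
* ``multi_auxotroph``  -- k >= ``multi_min`` (default 3) auxotrophies;
* ``ambiguous``        -- any vitamin call ambiguous.

Group comparison follows the deficient-versus-excess aggregation design:
per species passing a detection filter (mean abundance >= 0.01% on at least
one side), group means, the excess/deficient fold change and a two-sided
p-value are reported. The default test is the exact Mann-Whitney U (normal
approximation above 20 samples per side) -- a nonparametric default suited to
compositional percent data at n around 15; Welch's t is the alternative.
Raw p-values are reported by default; Benjamini-Hochberg is optional.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, ConsistencyError, InsufficientReplicationError
from .mapping import CommunityProfile
from .profiling import PhenotypeIndexVector

EXACT_MAX_N = 20
DEFAULT_MIN_ABUNDANCE = 1e-4  # fraction; == 0.01%


@dataclass(frozen=True)
class PhenotypeClass:
    """One taxon's auxotrophy-pattern class and the calls behind it."""

    phylotype_id: str
    kind: str  # omni_prototroph | mono_auxotroph | oligo_auxotroph | multi_auxotroph | ambiguous
    aux_vitamins: tuple[str, ...] = ()
    ambiguous_vitamins: tuple[str, ...] = ()
    aux_threshold: float = 0.0
    proto_threshold: float = 1.0

    @property
    def label(self) -> str:
        if self.kind == "mono_auxotroph":
            return f"mono_auxotroph:{self.aux_vitamins[0]}"
        return self.kind


def classify_taxon(
    idx: PhenotypeIndexVector,
    aux_threshold: float = 0.0,
    proto_threshold: float = 1.0,
    multi_min: int = 3,
) -> PhenotypeClass:
    """Classify one taxon from its prototrophy index vector."""
    if not (0 <= aux_threshold < proto_threshold <= 1):
        raise ConfigError(
            f"need 0 <= aux_threshold < proto_threshold <= 1, got "
            f"({aux_threshold}, {proto_threshold})"
        )
    if multi_min < 2:
        raise ConfigError(f"multi_min must be >= 2, got {multi_min}")
    aux, ambiguous = [], []
    for v, value in zip(idx.panel, idx.values):
        if value <= aux_threshold:
            aux.append(v)
        elif value < proto_threshold:
            ambiguous.append(v)
    common = dict(
        aux_vitamins=tuple(aux),
        ambiguous_vitamins=tuple(ambiguous),
        aux_threshold=aux_threshold,
        proto_threshold=proto_threshold,
    )
    if ambiguous:
        kind = "ambiguous"
    elif not aux:
        kind = "omni_prototroph"
    elif len(aux) == 1:
        kind = "mono_auxotroph"
    elif len(aux) >= multi_min:
        kind = "multi_auxotroph"
    else:
        kind = "oligo_auxotroph"
    return PhenotypeClass(idx.phylotype_id, kind, **common)


def class_abundance_summary(
    profile: CommunityProfile, classes: list[PhenotypeClass]
) -> pd.Series:
    """Aggregate relative abundance (%) per class label.

    Classes must cover exactly the (mapped) phylotypes they are summed over;
    phylotypes of the profile without a class are reported under
    ``unclassified`` (the unmapped remainder).
    """
    by_id = {c.phylotype_id: c for c in classes}
    extra = set(by_id) - set(profile.abundances)
    if extra:
        raise ConsistencyError(f"classes for phylotypes absent from profile: {sorted(extra)[:3]}")
    totals: dict[str, float] = {}
    for pid, a in profile.abundances.items():
        label = by_id[pid].label if pid in by_id else "unclassified"
        totals[label] = totals.get(label, 0.0) + 100.0 * a
    return pd.Series(totals).sort_index()


def classes_to_frame(classes: list[PhenotypeClass]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "phylotype_id": c.phylotype_id,
            "class": c.label,
            "aux_vitamins": ",".join(c.aux_vitamins),
            "ambiguous_vitamins": ",".join(c.ambiguous_vitamins),
            "aux_threshold": c.aux_threshold,
            "proto_threshold": c.proto_threshold,
        }
        for c in classes
    ])


def _two_sample_p(x: np.ndarray, y: np.ndarray, test: str) -> float:
    if test == "mannwhitney":
        has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
        method = "exact" if max(len(x), len(y)) <= EXACT_MAX_N and not has_ties else "asymptotic"
        return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)
    if test == "welch":
        return float(stats.ttest_ind(x, y, equal_var=False).pvalue)
    raise ConfigError(f"unknown test {test!r} (choose mannwhitney or welch)")


def compare_groups(
    profiles_d: list[CommunityProfile],
    profiles_e: list[CommunityProfile],
    min_abundance: float = DEFAULT_MIN_ABUNDANCE,
    test: str = "mannwhitney",
    species: list[str] | None = None,
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Per-species comparison of relative abundance between two aggregated
    sample sets (e.g. vitamin-deficient vs vitamin-excess diets).

    Returns a frame indexed by phylotype id with group means (fractions),
    their difference, the E/D fold change, the two-sided p-value and a
    ``tested`` flag; species below the detection filter on both sides are
    retained untested (p = NaN).
    """
    if len(profiles_d) < 2 or len(profiles_e) < 2:
        raise InsufficientReplicationError(
            f"need >= 2 samples per side, got {len(profiles_d)} and {len(profiles_e)}"
        )
    ids = sorted(
        set().union(*(p.abundances for p in profiles_d + profiles_e))
        if species is None
        else species
    )
    mat_d = np.array([[p.abundances.get(i, 0.0) for i in ids] for p in profiles_d])
    mat_e = np.array([[p.abundances.get(i, 0.0) for i in ids] for p in profiles_e])
    mean_d, mean_e = mat_d.mean(axis=0), mat_e.mean(axis=0)
    rows = []
    for j, pid in enumerate(ids):
        tested = max(mean_d[j], mean_e[j]) >= min_abundance
        p = _two_sample_p(mat_d[:, j], mat_e[:, j], test) if tested else np.nan
        fold = mean_e[j] / mean_d[j] if mean_d[j] > 0 else np.nan
        rows.append({
            "species": pid,
            "mean_d": mean_d[j],
            "mean_e": mean_e[j],
            "diff": mean_e[j] - mean_d[j],
            "fold_change": fold,
            "p_value": p,
            "tested": tested,
        })
    out = pd.DataFrame(rows).set_index("species")
    if bh_correction:
        from statsmodels.stats.multitest import multipletests

        adj = np.full(len(out), np.nan)
        mask = out["tested"].to_numpy()
        if mask.any():
            adj[mask] = multipletests(out.loc[mask, "p_value"], method="fdr_bh")[1]
        out["p_adjusted"] = adj
    return out
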