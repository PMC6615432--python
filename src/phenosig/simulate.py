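"""Synthetic reference collections and multi-replicate community studies.

The generator emulates the structure of a B-vitamin diet study: a reference
collection of gut-resident genomes with strain-level phenotype heterogeneity
(e.g. a species where one of four strains is a B12 prototroph), and a
multi-group, multi-replicate community experiment with compositional noise.

Noise model (the standard overdispersed model for 16S replicates):

* one base composition per study, drawn from a symmetric Dirichlet whose
  concentration controls community evenness (gut communities are uneven;
  the default 0.5 gives a realistic handful of dominant taxa);
* per replicate, a composition drawn from Dirichlet(theta * group mean),
  where theta (``replicate_concentration``, default 1000) sets the
  between-replicate spread of cultures or animals seeded from one pooled
  inoculum -- together with the multinomial read draw at ``depth`` this is a
  Dirichlet-multinomial;
* read counts drawn multinomially at the sequencing depth (default 1e5
  reads, a typical amplicon sample) and converted to relative abundances.

``depth=None`` is the noise-free expectation path: each replicate equals
its group's expected composition exactly, which is what ties the returned
StudyTruth to pipeline output (truth-consistency). Injected effects multiply
a species' expected abundance in selected groups before renormalization.
Every draw goes through one numpy Generator seeded from the mandatory design
seed, so studies are reproducible across platforms.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from types import MappingProxyType
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError
from .mapping import CommunityProfile
from .panel import DEFAULT_PANEL, VitaminPanel
from .reference import ReferenceCollection, ReferenceGenome

#: Default per-vitamin prototroph probabilities. Most B-vitamin auxotrophy
#: sits at 20-30% of gut species by abundance, with B12 auxotrophy the
#: clear outlier near half the community.
DEFAULT_PROTOTROPH_PROB: Mapping[str, float] = MappingProxyType({
    "B1": 0.75, "B2": 0.75, "B3": 0.75, "B5": 0.75,
    "B6": 0.80, "B7": 0.70, "B9": 0.80, "B12": 0.50,
})

#: The seven diet/media formulations with five replicates each.
DEFAULT_GROUPS: Mapping[str, int] = MappingProxyType({
    "AD": 5, "AN": 5, "AE": 5, "4D4N": 5, "4E4N": 5, "7D1N": 5, "7E1N": 5,
})

DEFICIENT_GROUPS = ("AD", "4D4N", "7D1N")
EXCESS_GROUPS = ("AE", "4E4N", "7E1N")

SPECIES_PER_GENUS = 4
GENERA_PER_FAMILY = 3


@dataclass(frozen=True)
class InjectedEffect:
    """Multiply one species' expected abundance by ``fold`` in ``groups``."""

    species: str
    groups: frozenset[str]
    fold: float

    def __post_init__(self) -> None:
        if not self.fold > 0:
            raise ConfigError(f"effect fold must be > 0, got {self.fold}")


@dataclass(frozen=True)
class StudyDesign:
    """Everything needed to regenerate a study deterministically."""

    seed: int
    n_species: int = 40
    min_genomes: int = 1
    max_genomes: int = 7
    prototroph_prob: Mapping[str, float] | float = field(
        default_factory=lambda: DEFAULT_PROTOTROPH_PROB
    )
    strain_heterogeneity: float = 0.1
    groups: Mapping[str, int] = field(default_factory=lambda: DEFAULT_GROUPS)
    depth: int | None = 100_000
    base_concentration: float = 0.5
    replicate_concentration: float | None = 1000.0
    effects: tuple[InjectedEffect, ...] = ()
    target_auxotrophy: Mapping[str, float] | None = None
    panel: VitaminPanel = DEFAULT_PANEL

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("design seed is mandatory")
        if self.n_species < 1:
            raise ConfigError(f"n_species must be >= 1, got {self.n_species}")
        if not 1 <= self.min_genomes <= self.max_genomes:
            raise ConfigError("need 1 <= min_genomes <= max_genomes")
        if not 0 <= self.strain_heterogeneity <= 1:
            raise ConfigError("strain_heterogeneity must be in [0, 1]")
        for v, p in self._prob_map().items():
            if not 0 <= p <= 1:
                raise ConfigError(f"prototroph probability for {v} outside [0, 1]")
        if any(n < 1 for n in self.groups.values()):
            raise ConfigError("replicate counts must be >= 1")
        if self.depth is not None and self.depth < 1:
            raise ConfigError("depth must be >= 1 (or None for noise-free)")
        if self.base_concentration <= 0:
            raise ConfigError("base_concentration must be > 0")
        if self.replicate_concentration is not None and self.replicate_concentration <= 0:
            raise ConfigError("replicate_concentration must be > 0 (or None)")
        if self.target_auxotrophy and len(self.target_auxotrophy) > 1:
            raise ConfigError("target_auxotrophy supports a single vitamin")

    def _prob_map(self) -> dict[str, float]:
        if isinstance(self.prototroph_prob, (int, float)):
            return {v: float(self.prototroph_prob) for v in self.panel}
        return {v: float(self.prototroph_prob[v]) for v in self.panel}


@dataclass
class StudyTruth:
    """Ground truth of a generated study, recomputable from the design."""

    seed: int
    base_composition: pd.Series                 # species -> expected fraction
    group_composition: dict[str, pd.Series]     # after injected effects
    species_index: pd.DataFrame                 # species x vitamin mean phenotype
    auxotrophy: dict[str, pd.Series]            # group -> vitamin -> true fraction
    effects: tuple[InjectedEffect, ...] = ()

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "base_composition": self.base_composition.to_dict(),
            "group_composition": {g: s.to_dict() for g, s in self.group_composition.items()},
            "species_index": self.species_index.to_dict(orient="index"),
            "auxotrophy": {g: s.to_dict() for g, s in self.auxotrophy.items()},
            "effects": [
                {"species": e.species, "groups": sorted(e.groups), "fold": e.fold}
                for e in self.effects
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _rng(design: StudyDesign, stream: int) -> np.random.Generator:
    # independent, platform-stable streams per stage
    return np.random.default_rng([design.seed % (2**31), stream])


def generate_reference_collection(design: StudyDesign) -> ReferenceCollection:
    """Deterministic synthetic collection: species grouped 4-per-genus,
    genera 3-per-family; per species a base binary vector drawn from the
    per-vitamin prototroph probabilities; with probability
    ``strain_heterogeneity`` a multi-genome species gets mixed binaries for
    one random vitamin. The first species is forced omni-prototrophic
    whenever all prototroph probabilities are positive."""
    rng = _rng(design, 1)
    probs = np.array([design._prob_map()[v] for v in design.panel])
    genomes = []
    for i in range(design.n_species):
        genus = f"Genus{i // SPECIES_PER_GENUS + 1:02d}"
        family = f"Family{i // (SPECIES_PER_GENUS * GENERA_PER_FAMILY) + 1:02d}"
        species = f"{genus} sp{i + 1:03d}"
        n = int(rng.integers(design.min_genomes, design.max_genomes + 1))
        base = (rng.random(len(design.panel)) < probs).astype(int)
        if i == 0 and np.all(probs > 0):
            base[:] = 1
        vectors = np.tile(base, (n, 1))
        # strain heterogeneity only makes sense for vitamins whose phenotype
        # is not pinned by a 0/1 prototroph probability
        free = np.flatnonzero((probs > 0) & (probs < 1))
        if n > 1 and free.size and rng.random() < design.strain_heterogeneity:
            v = int(rng.choice(free))
            k = int(rng.integers(1, n))  # 1..n-1 prototrophs: guaranteed mixed
            vectors[:, v] = 0
            vectors[:k, v] = 1
        for j in range(n):
            genomes.append(
                ReferenceGenome(
                    f"{species}.g{j + 1}", species, genus, family,
                    tuple(int(x) for x in vectors[j]),
                )
            )
    return ReferenceCollection(genomes, panel=design.panel)


def species_index_matrix(collection: ReferenceCollection) -> pd.DataFrame:
    """Species x vitamin mean binary phenotype (the species-level
    prototrophy indices the pipeline will assign at species rank)."""
    frame = collection.to_frame()
    return frame.groupby("species")[list(collection.panel)].mean()


def _rescale_for_target(
    base: pd.Series, q: pd.Series, target: float
) -> pd.Series:
    """Rescale auxotroph-carrying species so the community auxotrophy
    fraction sum_i b_i q_i hits ``target`` exactly (q = 1 - species index)."""
    carriers = q > 0
    t_a = float((base[carriers] * q[carriers]).sum())
    s_a = float(base[carriers].sum())
    s_b = float(base[~carriers].sum())
    if s_a <= 0 or t_a <= 0 or target >= t_a / s_a:
        raise ConfigError(
            f"target auxotrophy {target} not reachable "
            f"(max {t_a / s_a if s_a > 0 else 0:.3f})"
        )
    lam = target * s_b / (t_a - target * s_a)
    if lam <= 0:
        raise ConfigError(f"target auxotrophy {target} not reachable")
    scaled = base.copy()
    scaled[carriers] *= lam
    return scaled / scaled.sum()


def generate_study(
    design: StudyDesign, collection: ReferenceCollection
) -> tuple[list[CommunityProfile], StudyTruth]:
    """One profile per replicate per group, plus the ground-truth ledger."""
    rng = _rng(design, 2)
    index = species_index_matrix(collection)
    species = list(index.index)
    for e in design.effects:
        if e.species not in species:
            raise ConfigError(f"injected effect on unknown species {e.species!r}")
    base = pd.Series(rng.dirichlet(np.full(len(species), design.base_concentration)), index=species)
    if design.target_auxotrophy:
        (vitamin, target), = design.target_auxotrophy.items()
        q = 1.0 - index[vitamin]
        base = _rescale_for_target(base, q, float(target))
    group_comp: dict[str, pd.Series] = {}
    for label in design.groups:
        comp = base.copy()
        for e in design.effects:
            if label in e.groups:
                comp[e.species] *= e.fold
        group_comp[label] = comp / comp.sum()
    profiles = []
    for label, n_rep in design.groups.items():
        expected = group_comp[label].to_numpy()
        for r in range(n_rep):
            if design.depth is None:
                frac = expected
            else:
                p = (
                    rng.dirichlet(design.replicate_concentration * expected)
                    if design.replicate_concentration is not None
                    else expected
                )
                counts = rng.multinomial(design.depth, p / p.sum())
                frac = counts / design.depth
            profiles.append(
                CommunityProfile(
                    sample_id=f"{label}-r{r + 1}",
                    abundances=dict(zip(species, frac)),
                    group_label=label,
                )
            )
    auxotrophy = {
        label: pd.Series(
            comp.to_numpy() @ (1.0 - index.to_numpy()), index=list(design.panel)
        )
        for label, comp in group_comp.items()
    }
    truth = StudyTruth(
        seed=design.seed,
        base_composition=base,
        group_composition=group_comp,
        species_index=index,
        auxotrophy=auxotrophy,
        effects=design.effects,
    )
    return profiles, truth


def generate_copy_number_table_frame(
    design: StudyDesign, collection: ReferenceCollection
) -> pd.DataFrame:
    """Synthetic species-level 16S copy numbers (uniform 1-10, one decimal),
    emitted alongside simulated studies so the optional renormalization
    stage has an input to exercise."""
    rng = _rng(design, 3)
    species = sorted({g.species for g in collection.genomes})
    return pd.DataFrame({
        "taxon": species,
        "rank": "species",
        "mean_copy_number": np.round(rng.uniform(1.0, 10.0, len(species)), 1),
    })


def null_design(seed: int, **overrides) -> StudyDesign:
    """A no-effect design over the deficient/excess aggregation groups;
    convenience for calibration studies."""
    defaults = dict(
        seed=seed,
        n_species=10,
        groups={g: 5 for g in DEFICIENT_GROUPS + EXCESS_GROUPS},
        strain_heterogeneity=0.0,
    )
    defaults.update(overrides)
    return StudyDesign(**defaults)
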