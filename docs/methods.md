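# Methods

## Model

The projection treats a 16S community profile as a mixture over reference
genomes. Phylotype i with relative abundance A_i is mapped to a taxon at
rank r_i (species, genus or family) and inherits a distribution w_i over
the genomes of that taxon's neighborhood; each genome m carries a binary
phenotype p_mv per vitamin v (1 = complete de novo pathway, 0 = salvage
dependence). The per-phylotype prototrophy index

    p_iv = sum_m w_im p_mv

is the probability that a cell of phylotype i is a v-prototroph under the
mixture; the community phenotype index and auxotrophy representation are
its abundance-weighted totals,

    CPI_v = 100 * sum_i A_i p_iv,
    AUX_v = 100 * sum_i A_i (1 - p_iv),

summed over mapped phylotypes. CPI_v + AUX_v = 100 * mapped_fraction by
construction, an identity the tests enforce at 1e-9 on random instances.

Assumptions worth stating plainly: (i) the reference calls are correct and
complete for the taxa they cover — phenotype inference from sequence is
upstream and out of scope; (ii) a phylotype behaves like a uniform draw
from its neighborhood, i.e. equal weight per child taxon at each level,
which is the maximally noncommittal choice given no strain-resolution
below the mapping rank; (iii) relative 16S read abundance stands in for
relative cell abundance (see copy-number correction below for the known
bias).

## Mapping rules

Identity thresholds default to species >= 98%, genus >= 95%, family >= 90%.
The first two follow standard phylotype-calling practice for V3-V4
amplicons; no established family floor exists, so 90% — a conventional
16S family-level cutoff — is used and exposed as a parameter. Boundaries
are inclusive. Names are matched after normalization (case-folding,
bracket trimming, whitespace collapse); matching is exact, never fuzzy.
A species binomial resolves at genus/family rank through its first token,
so a phylotype whose best-match species is absent from the collection
degrades one rank at a time (species -> genus -> family) with a logged
warning instead of being dropped; this preserves abundance coverage.
Phylotypes resolving nowhere are excluded from prediction, and the mapped
fraction is always reported so users can renormalize. When two reference
entries could tie for a name, index iteration is over sorted keys, making
the resolution deterministic (first by lexicographic order).

Hierarchical weights: at genus rank each of the S species gets 1/S, split
equally over its n_s genomes, so genome weights are (1/S)(1/n_s) — tested
against a flat enumeration oracle over random structures; family rank adds
one more equal split over genera. Weights are independent of abundance,
which is why copy-number renormalization and mapping commute for the final
CPI (also tested).

## Percent versus fraction

All abundances are fractions internally and renormalized to sum to one on
load, whatever the input scale; reports emit percent with 4 decimals (a
`raw_fractions` switch emits fractions). This removes the classic silent
100x error when percent tables are fed to fraction code.

## Copy-number renormalization

A'_i = (A_i / c_i) / sum_j (A_j / c_j), where c_i is the best-match mean
16S copy number (species, then genus, then family, then the table-wide
unweighted mean as default). The stage is off by default: copy-number
catalogs are incomplete, and turning an optional correction on silently
would change every downstream percentage. Properties tested: output
validity, identity under uniform copy numbers, strict monotonicity in any
single taxon's copy number, and element-wise agreement with a brute-force
divide-and-rescale oracle at 1e-12.

## Classification and group comparison

Calls per vitamin: auxotrophic if index <= aux_threshold (default 0),
prototrophic if >= proto_threshold (default 1), else ambiguous. The strict
defaults restrict classes to unambiguous patterns: omni_prototroph, mono-,
oligo- (1 < k < 3) and multi-auxotroph (k >= 3). The oligo class exists
because a fully unambiguous 2-vitamin auxotroph fits neither mono nor
multi under the k >= 3 convention; collapsing it into "ambiguous" would
mislabel taxa whose calls are perfectly determinate. Relaxed thresholds
(e.g. 0.2/0.8) are available for exploratory use and documented as such.

Group comparison defaults to the exact two-sided Mann-Whitney U (normal
approximation above 20 per side, or in the presence of ties), a
nonparametric choice suited to compositional percent data at n around 15
per side; Welch's t is offered as the parametric alternative. Species
enter the test only when their mean abundance reaches 0.01% on at least
one side. Raw p-values are reported by default — the comparison is a
screen, not a confirmatory analysis — with Benjamini-Hochberg correction
behind a flag. Both group means and their difference are reported, since
"increase" can mean either.

## Synthetic studies

The generator emulates a seven-group diet/media study (AD/AN/AE plus four
mixed formulations, five replicates each by default):

* **Collection**: n_species (default 40) grouped four per genus, three
  genera per family; genomes per species uniform on 1..7 (matching the
  strain counts seen in curated gut collections); per-vitamin prototroph
  probabilities default to 0.75 for most vitamins, 0.8 for B6/B9, 0.7 for
  B7 and 0.5 for B12, mirroring observed community auxotrophy levels;
  strain heterogeneity 0.1 (mixed binaries are the exception, not the
  rule), applied only to vitamins whose prototrophy is not pinned at 0 or
  1. One omni-prototroph is guaranteed whenever all probabilities are
  positive.
* **Composition**: a single base composition from a symmetric
  Dirichlet(0.5) — uneven, a few dominant taxa, as in real gut profiles.
  `target_auxotrophy` rescales the auxotroph-carrying species by the
  closed-form factor lambda = f S_B / (T_A - f S_A) so the designed
  community auxotrophy fraction is hit exactly (exact for any index
  values, not just binary ones).
* **Noise**: per replicate, composition ~ Dirichlet(theta * group mean)
  with theta = 1000 by default — replicates are cultures or co-housed
  animals seeded from one pooled inoculum, so modest overdispersion — then
  a multinomial read draw at depth 1e5. `replicate_concentration=None`
  isolates pure sequencing noise; `depth=None` is the analytic expectation
  path used by the truth-consistency test (tolerance 1e-9).

What the generator does not emulate: ecological dynamics (no actual
vitamin exchange, growth or competition), chimeras/contamination,
compositional zero-inflation beyond what the DM model produces, and
phylogenetic correlation of phenotypes across genera. Passing tests
therefore demonstrate that the *projection arithmetic and inference
machinery* behave correctly under realistic compositional noise — not
that real communities satisfy the mixture assumptions.

## Worked-example fixtures

The two packaged 20-species tables carry printed fractional indices that
are derived averages; the BPM is binary, so each row is expanded into
genomes: species rows get round(index * n) prototrophs listed first (any
realization has the same mean, which is all downstream math uses).
Genus/family rows whose flat k/n realization cannot reproduce a printed
cell under hierarchical weighting (one 23-genome genus, one 3-genome
genus) carry explicit multi-species structures, solved by hand and locked
by a regression test that checks all 320 cells after 2-decimal rounding —
including the printed species-level members that sit inside those genus
neighborhoods. Families are synthetic "<Genus>aceae" strings: only one
fixture row maps at family rank and its 224-genome family must not absorb
other fixture genera, as real family assignments would. Fixture identity
percentages (99 / 96.5 / 92) are stand-ins consistent with each row's
printed mapping level.

## Numerical choices

* Abundance sum tolerance 1e-9; weight normalization asserted at 1e-12.
* Replicate SD uses the n-1 estimator; n = 1 groups report SD 0 with the
  n flag set.
* Index display rounding is 2 decimals (matching the printed tables);
  full float precision is carried internally.
* All randomness flows through `numpy.random.default_rng` seeded from the
  mandatory design seed with fixed per-stage stream offsets, so studies
  are bit-reproducible across platforms; the pipeline proper is
  deterministic and byte-reproduces its output files on re-run.
* Problem sizes in the test suite (25-50 phylotypes, up to 20 genomes
  each for property checks; 30-species studies for recovery; 10-species,
  15-per-side studies for the 1,000-repetition null calibration) were
  chosen to exercise every code path at desk scale.

## Known limitations

* The projection inherits every bias of the reference collection; taxa
  absent from it degrade to coarser ranks where phenotype conservation is
  weaker (heterogeneous genera yield fractional, low-information indices).
* Mapped-fraction renormalization is a presentation choice; both raw and
  renormalized percentages are emitted because neither convention is
  canonical.
* The group comparison treats replicates as exchangeable; cage effects or
  repeated measures are out of scope.
* BIOM input is not supported; profiles arrive as TSV.
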