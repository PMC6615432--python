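# phenosig

Phylotype-to-phenotype projection of 16S rRNA community profiles onto a
reference **binary phenotype matrix (BPM)** of B-vitamin biosynthesis calls.

Most members of a gut microbial community either carry the complete de novo
biosynthesis pathway for a B-vitamin-derived cofactor (prototrophs, call 1)
or depend on salvaging the vitamin from the diet or from neighbors
(auxotrophs, call 0). Given (a) a per-sample table of 16S phylotypes with
relative abundances and the percent identity of their best reference match
and (b) a reference collection of genomes with species/genus/family taxonomy
and 0/1 phenotype calls per vitamin, `phenosig` answers: *what fraction of
this community, by abundance, is auxotrophic for each vitamin, and does that
fraction move when the vitamin supply changes?*

## Method

1. **Mapping.** Each phylotype is assigned a taxonomic rank from its percent
   identity (defaults: ≥98% species, ≥95% genus, ≥90% family; below that,
   unmapped and excluded) and attached to its *phylogenetic neighborhood* —
   the reference genomes under the matched taxon at that rank.
2. **Phenotype index.** The phylotype's prototrophy index per vitamin v is a
   weighted average of genome binaries over the neighborhood,
   p<sub>iv</sub> = Σ<sub>m</sub> w<sub>im</sub> p<sub>mv</sub> ∈ [0, 1],
   with hierarchical equal weights: equal per strain genome at species rank;
   equal per species, then per genome, at genus rank; equal per genus, then
   species, then genome, at family rank. A species with one prototrophic
   strain out of four gets index 0.25.
3. **Community signature.** Rows stack into the community phenotype matrix
   (CPM); weighting by relative abundance A<sub>i</sub> gives the community
   phenotype index CPI<sub>v</sub> = 100·Σ<sub>i</sub> A<sub>i</sub>
   p<sub>iv</sub> (% prototrophy) and the auxotrophy representation
   100·Σ<sub>i</sub> A<sub>i</sub>(1 − p<sub>iv</sub>). The two always sum
   to 100 × mapped fraction.
4. **Aggregation & comparison.** Replicates are summarized as mean ± SD per
   group; species abundances are compared between aggregated group sets
   (e.g. vitamin-deficient vs vitamin-excess diets) with an exact two-sided
   Mann–Whitney U test behind a ≥0.01% detection filter.

Optional preprocessing divides abundances by taxon-specific mean 16S gene
copy numbers (rrnDB-style table) and rescales — off by default.

A synthetic-study generator (Dirichlet base composition, per-replicate
Dirichlet-multinomial noise, optional injected fold changes, full ground
truth) makes every stage testable end to end without external data.

## Worked example

Two 20-species reference matrices are packaged: a humanized-gnotobiotic-mouse
community (`table2`) and an anaerobic fecal subculture community (`table3`),
each with printed prototrophy indices and abundances.

```python
import phenosig as ps

collection, profile = ps.table_fixture("table2")
mappings, mapped = ps.map_profile(profile, collection)
cpm = ps.community_phenotype_matrix(mappings, profile)
signature = ps.community_signature(cpm)
print(f"mapped fraction: {100 * mapped:.1f}%")
for v in signature.auxotrophy.index:
    print(f"{v:>4}: {signature.auxotrophy[v]:5.1f}% auxotrophic")
```

prints

```
mapped fraction: 100.0%
  B1:  17.6% auxotrophic
  B2:  12.2% auxotrophic
  B3:  18.9% auxotrophic
  B5:  23.9% auxotrophic
  B6:   0.0% auxotrophic
  B7:  26.9% auxotrophic
  B9:  16.2% auxotrophic
 B12:  48.7% auxotrophic
```

Most vitamins sit near 20–30% auxotrophy; B12 is the outlier at roughly half
the community — it is the one B-vitamin whose cofactor many species can
bypass entirely, so its pathway is readily lost. The 48.65% value is exactly
reproduced by a hand summation over the printed rows (8 of the 20 phylotypes
carry B12 indices below 1).

The same flow is available from the shell: `phenosig run -c config.yaml`,
with per-stage subcommands `map`, `profile`, `renorm`, `classify`,
`compare`, `simulate`, `validate`.

## Analysis scripts

`analysis/01–04` form a narrative pipeline: build and validate the
worked-example matrices, project both communities, simulate a seven-group
(deficient/normal/excess) diet study with five replicates per group, and
test the stability of the auxotrophic community fraction across supply
extremes. Tables land under `results/`.

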