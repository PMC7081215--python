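# adipoloc

Statistical machinery for asking whether a GWAS signal for a
fat-distribution trait and an adipose-tissue eQTL signal at the same
locus point at the same causal variant — and whether the credible
variants sit in regulatory chromatin — together with the adipocyte
histomorphometry statistics (cell size distributions, depot cell
counts, distribution-shift tests) used to phenotype adipose tissue.
Everything runs on synthetic locus and diameter data produced by the
package itself, so no cohort genotypes, eQTL releases, or microscopy
output are required.

Intended users: statistical geneticists and computational biologists
who want a small, fully testable implementation of LD-aware
colocalization scoring and its surrounding pipeline.

## What it computes

**Fine-mapping.** Given per-variant summary statistics (β, SE) and an
LD matrix R for one locus, each causal configuration C is scored with
the multivariate-normal z-likelihood z ~ N(0, R + R_C diag(s²) R_C′),
s²ᵢ = W/seᵢ², enumerated exhaustively up to `max_k` causal variants
and normalized into per-variant posterior inclusion probabilities
(PIPs). For a single causal variant this reduces exactly to the
Wakefield approximate Bayes factor

  ABF = √(se²/(se²+W)) · exp(z²W / 2(se²+W)).

**Colocalization.** With GWAS PIPs gᵢ and eQTL PIPs eⱼ, the classic
colocalization posterior is CLPP = Σᵢ gᵢeᵢ. The LD-aware score used
here also credits variant *pairs* in strong LD:

  mCLPP = Σᵢⱼ gᵢ eⱼ r²ᵢⱼ ,

so two signals tagging the same haplotype count as colocalized even
when their point estimates land on different variants. Always
CLPP ≤ mCLPP ≤ 1; a locus is called colocalized at mCLPP > 0.8.

**Annotation enrichment.** The mean PIP of (credible-set) variants
inside an annotation (e.g. H3K27ac peaks) is compared against a null
built by shifting the whole track by random offsets up to ±500 kb
(1000 permutations, circular wrap), giving an empirical p-value.

**Cellularity.** From per-cell diameters D: volume V = 4/3·π·(D/2)³,
mean cell weight = mean volume × triglyceride density (0.915 g/mL),
cells per depot = depot mass / mean cell weight, plus binned size
distributions, two-sample Kolmogorov–Smirnov curve-shift tests, and a
covariate-adjusted biweight midcorrelation for expression–trait
analyses.

## Worked example

```sh
adipoloc run --seed 1 --out demo_run
```

simulates one locus (100 variants over 1 Mb, n = 5000, one causal
variant shared by both traits at 5% variance explained each), then
fine-maps, colocalizes, tests enrichment, and summarizes two simulated
diameter samples. It prints:

```
adipoloc run report
===================

colocalization: CLPP=0.9966  mCLPP=0.9996  colocalized=True (threshold 0.8)
lead pair: GWAS var0050  eQTL var0050
99% credible set: 1 variants (mass 0.9994)
annotation enrichment: stat=0.9994  empirical p=0.002997 (1000 permutations)
cellularity [WT_SAT]: mean diameter 40.8 um, 5.44e+06 cells/depot
cellularity [KO_SAT]: mean diameter 35.7 um, 9.83e+06 cells/depot
KS test between groups: D=0.1655  p=3.237e-24
```

Reading it: both traits put essentially all posterior mass on the true
causal variant `var0050`, so CLPP is already high and the LD-weighted
mCLPP slightly higher — the locus colocalizes. The 99% credible set
collapses to that one variant; its posterior mass falls inside the
causally-centred annotation far more often than random track shifts
allow (p ≈ 0.003). The two diameter samples (configured to the
wild-type and knockout subcutaneous means 40.4 and 36.1 µm) differ
clearly in distribution (KS p ≈ 3e-24); the smaller-celled sample
packs ~1.8× more cells into the same depot mass.

Every stage is also available as a library function
(`adipoloc.colocalize_locus`, `adipoloc.enumerate_posteriors`,
`adipoloc.shift_permutation_test`, `adipoloc.depot_cell_count`, …) and
as individual CLI subcommands (`simulate`, `finemap`, `coloc`,
`enrich`, `cellularity`, `ks-compare`) over plain-text TSV/BED/CSV
files.

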