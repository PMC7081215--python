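# Methods

This note documents the models, defaults and design choices behind
adipoloc, in the order the pipeline runs. Nothing here states an
empirical result beyond what the test suite and `scripts/acceptance.py`
themselves compute.

## Synthetic locus generator (`locus_sim`)

The generator exists so that every downstream stage can be exercised
and validated without cohort data. Its components are deliberately
simple stand-ins for real data-generating processes, chosen for
having closed-form properties a test can check.

**Haplotypes.** A first-order Markov copy scheme along the locus: the
allele at variant j copies the allele at j−1 with probability
`ld_decay` (default 0.95) and is otherwise drawn fresh from a
per-variant refresh frequency, uniform on [0.05, 0.95]. This yields
distance-decaying, block-like LD with a closed form for adjacent
pairs: Cov(X_{j−1}, X_j) = c·v_{j−1}, hence r²_{j−1,j} =
c²·v_{j−1}/v_j with v = p(1−p). The suite checks realized mean
adjacent r² against this expectation over 20 seeds. The scheme is not
a coalescent: it has no recombination hotspots, no allele-frequency
spectrum, and LD decays geometrically. Columns that come out
monomorphic in-sample are redrawn a bounded number of times (this
breaks the Markov coupling to the *next* column for that rare event;
with the default frequency range and thousands of haplotypes it
essentially never triggers).

**Phenotypes.** Trait = Σ (standardized dosage × effect) + Gaussian
noise, with the noise variance set from the *realized* genetic
variance so the in-sample variance fraction equals the requested h²
(default 0.05 per trait) up to the noise draw itself. Defaults: one
causal variant in the locus middle, shared between the GWAS and
expression traits (the colocalizing scenario); n = 5000 individuals,
m = 100 variants over 1 Mb.

**Summary statistics.** Textbook per-variant simple OLS with
intercept: β = cov(x,y)/var(x), SE from residual variance on n−2 df,
z = β/SE. Cross-checked against statsmodels in the suite.

**Annotations.** `n_intervals` (default 10) intervals of
`interval_length_bp` (default 2000 bp — typical ChIP-seq peak width
for marks like H3K27ac). `null` mode places intervals uniformly;
`causal-centered` mode forces one interval to contain each causal
position (the enriched scenario). Note a structural property of shift
nulls: the smallest attainable empirical p approximately equals the
track's merged coverage fraction of the window, because a random
joint shift re-covers the top-PIP variant with that probability. At
the defaults (≈2% coverage) p ≈ 0.02 is reachable; tracks covering
≥5% of the window cannot yield p ≤ 0.05 no matter how concentrated
the posterior.

**Adipocyte diameters.** Lognormal with standard moment inversion
(σ² = ln(1+(sd/mean)²), µ = ln(mean) − σ²/2) so the sampled
arithmetic mean and SD target the configured values, e.g. the
wild-type subcutaneous 40.4 ± 17.6 µm versus knockout 36.1 ± 12.1 µm,
at 2000 cells per sample. The lognormal guarantees positivity and the
right skew typical of adipocyte size data, but real diameter
distributions can be multimodal (small/large cell populations), which
a single lognormal cannot represent; KS-power results on these
samples therefore speak to location/shape shifts of unimodal
distributions only.

**Seeding.** One global seed expands into fixed per-stage substreams
(haplotypes, GWAS phenotype, eQTL phenotype, annotation, diameters —
append-only order), so adding a stage never perturbs earlier draws
and all outputs are bit-reproducible for a fixed config.

## Fine-mapping (`finemap`)

Exhaustive enumeration of causal configurations of size 0..`max_k`,
with a hard guard at 2×10⁶ configurations. This is exact at
desk-scale loci and testable against brute force; it deliberately
replaces the stochastic search that production fine-mappers use at
biobank scale.

Likelihood: z ~ N(0, R + R_C diag(s²_C) R_C′) with per-variant prior
effect variance s²ᵢ = W/seᵢ² on the z scale. W defaults to 0.1² on
the standardized effect scale. Priors: each variant causal with
probability p (default 1/m, clipped to ≤ 0.5 so a one-variant locus
keeps a proper prior); configuration prior p^|C|(1−p)^(m−|C|).
Posteriors normalized by log-sum-exp; PIPᵢ = Σ posteriors of
configurations containing i.

For |C| = 1 the likelihood ratio against the null reduces — by the
determinant lemma and Sherman–Morrison, independently of R — to the
Wakefield ABF of the candidate variant. Consequently an r²-only LD
matrix (which carries no allele-phase signs) still supports `max_k=1`
fine-mapping via the ABF route; `max_k ≥ 2` requires signed r, and
the implementation refuses to invent signs.

Numerics: R gets a 1e-4 ridge on the diagonal before factorization
(condition number > 1e8 triggers a warning); likelihoods are computed
by Cholesky in log space. The test oracle re-derives posteriors with
direct dense determinants and inverses and density *ratios* against
the null (raw multivariate-normal densities underflow beyond m ≈ 10).

Credible sets: variants ranked by descending PIP (ties broken by
position, then id), accumulated until the cumulative PIP, normalized
by total PIP mass, first reaches the level (default 0.99). The
alternative "stop before exceeding the level" reading would yield a
set one variant smaller in edge cases; the standard
smallest-set-reaching-the-level rule is used.

## Colocalization (`coloc`)

CLPP = Σᵢ gᵢeᵢ; mCLPP = Σᵢⱼ gᵢeⱼ r²ᵢⱼ over *all* ordered pairs
including i = j. Diagonal inclusion is the only reading under which
the score behaves as a colocalization posterior: it makes
mCLPP ≥ CLPP (unit diagonal, non-negative weights) and keeps the
score at 1 when both posteriors concentrate on the same variant.
Scores are clipped to [0, 1] with a warning if multi-causal PIP
vectors (which may sum above 1 across variants) push the sums above
1; the default pipeline runs `max_k=1`, where total PIP mass is the
posterior of non-null and the clip never activates. The
colocalization call uses mCLPP > 0.8 by default; the threshold is
configurable.

## Annotation enrichment (`enrich`)

Test statistic: mean fine-mapping posterior of variants overlapping
any annotation interval (half-open point-in-interval test; 0 when
nothing overlaps, making the test one-sided "greater"). Null: one
integer offset per permutation, uniform on ±`max_shift_bp` (default
500 kb), applied *jointly* to all intervals — preserving
inter-interval spacing and hence the track's autocorrelation — with
circular wrap at the window edges so annotated bp are conserved.
Implementation shifts the variant positions by the negated offset
modulo the window, which is the same operation without interval
splitting. Default 1000 permutations; empirical p = (1+r)/(1+n) so p
is never 0. The credible-set variant zeroes posteriors outside the
set before testing, so only credible mass drives the statistic.

## Cellularity (`cellularity`)

Volume V = 4/3·π·(D/2)³ per cell; mean cell weight = mean(V) × ρ
with ρ = 0.915 g/mL (triolein density; the literature value is
sometimes misprinted as g/L, which is off by 10³ and physically
implausible for a lipid — the unit here is configurable but defaults
to g/mL); cells per depot = depot mass / mean cell weight
(1 µm³ = 1e-12 mL). The mean-volume convention is the mean of
per-cell volumes; by Jensen's inequality this exceeds the volume of
the mean diameter for any spread, so counts are correspondingly
smaller — the alternative convention is exposed as an option. Pixel
lengths convert at 0.3953 µm/px (×20 objective default).

Size distributions use left-closed right-open bins, default 0–150 µm
in 5 µm steps. The two-sample KS test computes D = sup|ECDF_a −
ECDF_b| exactly and takes p from the asymptotic Kolmogorov
distribution at effective size n_a·n_b/(n_a+n_b); this is a slightly
different finite-n approximation than scipy's `asymp` mode, and the
suite cross-checks the two loosely while checking D exactly.

Biweight midcorrelation: classic 9-MAD tuning, weights (1−u²)²·1{|u|<1}
with u = (x−median)/(9·MAD); expression is residualized on the
covariate (e.g. BMI) by OLS before correlating with the trait;
p-values from the two-sided Student t on n−2 df. A zero MAD (over
half the values identical) raises with a recommendation to fall back
to Pearson rather than silently switching.

## Pipeline and formats (`pipeline`, `io`, `cli`)

One validated config (pydantic schema; unknown keys rejected) drives
simulation → fine-mapping → colocalization → enrichment →
cellularity for a single locus per run. Every intermediate is
plain, diffable text (TSV/BED/CSV/JSON) with a comment header stating
coordinate convention and units; a manifest records the config hash,
per-file checksums, versions and per-stage wall-clock, written
atomically. Identical config + seed reproduces byte-identical numeric
outputs.

## Problem sizes used in the checks

The acceptance computation and heavier suite scenarios use 20–50
replicate loci at n = 5000 individuals, 100 variants over 1 Mb,
h² = 0.05 per trait; enrichment calibration uses 500 synthetic
meta-replicates at 200 permutations and power sweeps 50 loci at 1000
permutations; KS power uses 2000 cells per group. These sizes were
chosen as the smallest at which the Monte-Carlo properties under test
are stable.

## Known limitations

- The haplotype model is not a population-genetic simulator; LD decays
  geometrically and allele frequencies are uniform by construction.
- Exhaustive enumeration caps locus size/`max_k` (guard at 2×10⁶
  configurations); this package is for desk-scale loci, not
  genome-wide scans.
- mCLPP with multi-causal PIPs (sum > 1) is clipped rather than
  renormalized; interpretation is cleanest at `max_k = 1`.
- The shift-permutation p-value floor is set by annotation coverage
  (see above), a property of the method, not the implementation.
- Diameter samples are unimodal lognormals; bimodal cellularity
  phenotypes are out of the generator's reach.
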