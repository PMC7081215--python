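"""Synthetic locus and histomorphometry data generator.

Every downstream stage (fine-mapping, colocalization, enrichment,
cellularity) is exercised on data from this module, so real cohort
genotypes, eQTL tables or microscopy output are never required.  All
generative choices here are stand-ins for real data-producing processes
and are documented as such in the methods note:

* Haplotypes follow a first-order Markov copy scheme along the locus:
  each allele copies its left neighbour with probability ``ld_decay``
  and is otherwise redrawn from a per-variant refresh frequency.  This
  gives block-like, distance-decaying LD with a closed-form expectation
  for adjacent-pair r^2 (see :func:`expected_adjacent_r2`), which makes
  the generator itself testable.
* Quantitative phenotypes are linear in standardized genotype dosages
  plus Gaussian noise, with the noise scaled so the *realized* genetic
  variance fraction equals the requested h2.
* Adipocyte diameters are lognormal, moment-matched to a requested
  arithmetic mean and SD (e.g. SAT 40.4 +/- 17.6 um).

Randomness: one global seed expands into fixed per-stage substreams
(haplotypes, gwas-phenotype, eqtl-phenotype, annotation, diameters, in
that order), so adding a stage never perturbs earlier draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import AnnotationTrack, DiameterSample, Haplotypes, LDMatrix, SummaryStats

# Fixed substream indices; append-only so existing draws never shift.
_STAGES = {
    "haplotypes": 0,
    "pheno_gwas": 1,
    "pheno_eqtl": 2,
    "annotation": 3,
    "diameters": 4,
}

_MONOMORPHIC_RETRIES = 100


def substream(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage random generator derived from one seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STAGES[stage]]))


@dataclass
class CausalArchitecture:
    """Which variants are causal for each trait and how strongly.

    ``effect_sizes`` are standardized per-causal effects, aligned
    positionally with each trait's causal index list (the two lists must
    have the same length).  ``shared`` asserts the two causal sets are
    identical -- the scenario in which a GWAS and an eQTL signal truly
    colocalize.
    """

    causal_indices_gwas: tuple[int, ...]
    causal_indices_eqtl: tuple[int, ...]
    effect_sizes: tuple[float, ...] = ()
    h2_gwas: float = 0.05
    h2_eqtl: float = 0.05
    shared: bool = True

    def __post_init__(self) -> None:
        self.causal_indices_gwas = tuple(int(i) for i in self.causal_indices_gwas)
        self.causal_indices_eqtl = tuple(int(i) for i in self.causal_indices_eqtl)
        if not self.effect_sizes:
            self.effect_sizes = tuple(1.0 for _ in self.causal_indices_gwas)
        self.effect_sizes = tuple(float(b) for b in self.effect_sizes)
        if len(self.effect_sizes) != len(self.causal_indices_gwas) or len(
            self.causal_indices_gwas
        ) != len(self.causal_indices_eqtl):
            raise ValueError("effect sizes must align with causal index lists")
        for h2 in (self.h2_gwas, self.h2_eqtl):
            if not 0 <= h2 < 1:
                raise ValueError(f"h2 must lie in [0, 1), got {h2}")
        if self.shared and self.causal_indices_gwas != self.causal_indices_eqtl:
            raise ValueError("shared architecture requires identical causal sets")


@dataclass
class SimConfig:
    """Full parameterization of one simulated locus."""

    n_individuals: int = 5000
    m_variants: int = 100
    locus_span_bp: int = 1_000_000
    ld_decay: float = 0.95
    seed: int = 0
    architecture: CausalArchitecture = field(
        default_factory=lambda: CausalArchitecture((50,), (50,))
    )
    # ~peak-width intervals (typical ChIP-seq H3K27ac peaks span 1-2 kb);
    # total track coverage also sets the attainable floor of a shift-null p
    n_intervals: int = 10
    interval_length_bp: int = 2_000
    enrichment_mode: str = "null"  # "null" | "causal-centered"
    min_freq: float = 0.05
    max_freq: float = 0.95

    def __post_init__(self) -> None:
        for name in ("n_individuals", "m_variants", "locus_span_bp"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.ld_decay < 1:
            raise ValueError("ld_decay must lie in [0, 1)")
        if self.enrichment_mode not in ("null", "causal-centered"):
            raise ValueError(f"unknown enrichment_mode {self.enrichment_mode!r}")
        bad = [i for i in set(self.architecture.causal_indices_gwas)
               | set(self.architecture.causal_indices_eqtl) if not 0 <= i < self.m_variants]
        if bad:
            raise ValueError(f"causal indices {bad} outside [0, {self.m_variants})")


def simulate_haplotypes(config: SimConfig) -> Haplotypes:
    """Markov-copy haplotypes: 2n binary rows over m variants.

    Allele j of each haplotype copies allele j-1 with probability
    ``ld_decay`` and is otherwise a fresh Bernoulli draw from that
    variant's refresh frequency (uniform on [min_freq, max_freq]).
    Columns that come out monomorphic are redrawn a bounded number of
    times before the generator gives up.
    """
    rng = substream(config.seed, "haplotypes")
    n_hap = 2 * config.n_individuals
    m = config.m_variants
    refresh = rng.uniform(config.min_freq, config.max_freq, size=m)
    copy = rng.random(size=(n_hap, m)) < config.ld_decay
    fresh = (rng.random(size=(n_hap, m)) < refresh).astype(np.uint8)

    # positions are drawn before any monomorphic redraw so that
    # _locus_positions can replay the stream deterministically
    positions = np.sort(rng.choice(config.locus_span_bp, size=m, replace=False))

    alleles = np.empty((n_hap, m), dtype=np.uint8)
    alleles[:, 0] = fresh[:, 0]
    for j in range(1, m):
        alleles[:, j] = np.where(copy[:, j], alleles[:, j - 1], fresh[:, j])

    for j in range(m):
        for attempt in range(_MONOMORPHIC_RETRIES + 1):
            freq = alleles[:, j].mean()
            if 0 < freq < 1:
                break
            if attempt == _MONOMORPHIC_RETRIES:
                raise RuntimeError(
                    f"variant column {j} stayed monomorphic after "
                    f"{_MONOMORPHIC_RETRIES} redraws (refresh freq {refresh[j]:.3f})"
                )
            redraw = (rng.random(n_hap) < refresh[j]).astype(np.uint8)
            if j == 0:
                alleles[:, 0] = redraw
            else:
                b = rng.random(n_hap) < config.ld_decay
                alleles[:, j] = np.where(b, alleles[:, j - 1], redraw)

    return Haplotypes(alleles=alleles, positions=positions)


def expected_adjacent_r2(haps: Haplotypes, ld_decay: float) -> float:
    """Closed-form mean adjacent-pair r^2 of the copy scheme.

    For the Markov copy scheme, Cov(X_{j-1}, X_j) = c * Var(X_{j-1})
    with c the copy probability, hence r^2_{j-1,j} = c^2 * v_{j-1}/v_j
    where v_j = p_j (1 - p_j).  Evaluated at the realized marginal
    frequencies; used as the Monte-Carlo oracle for the generator.
    """
    v = haps.allele_freqs * (1 - haps.allele_freqs)
    return float(ld_decay**2 * np.mean(v[:-1] / v[1:]))


def compute_ld(haps: Haplotypes, variant_ids: list[str] | None = None) -> LDMatrix:
    """Squared (and signed) Pearson correlation of allele columns."""
    if haps.n_haplotypes < 2:
        raise ValueError("need at least 2 haplotypes to compute LD")
    x = haps.alleles.astype(float)
    sd = x.std(axis=0)
    if np.any(sd == 0):
        raise ValueError(f"variant column {int(np.argmax(sd == 0))} has zero variance")
    r = np.corrcoef(x, rowvar=False)
    if r.ndim == 0:  # single variant
        r = np.array([[1.0]])
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    ids = variant_ids if variant_ids is not None else default_variant_ids(haps.m)
    return LDMatrix(values=r**2, variant_ids=ids, signed_r=r)


def default_variant_ids(m: int) -> list[str]:
    return [f"var{j:04d}" for j in range(m)]


def _one_phenotype(
    gstd: np.ndarray,
    causal: tuple[int, ...],
    effects: tuple[float, ...],
    h2: float,
    rng: np.random.Generator,
) -> np.ndarray:
    n = gstd.shape[0]
    if h2 == 0 or not causal:
        return rng.standard_normal(n)
    g = gstd[:, list(causal)] @ np.asarray(effects)
    vg = g.var()
    if vg == 0:
        raise ValueError("causal genotypes carry no variance; cannot target h2 > 0")
    noise = rng.standard_normal(n)
    noise *= np.sqrt(vg * (1 - h2) / h2) / noise.std()
    return g + noise


def simulate_phenotypes(
    haps: Haplotypes, arch: CausalArchitecture, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Two quantitative traits from one genotype matrix.

    Each trait is (standardized dosage) @ effects + Gaussian noise, with
    the noise rescaled so the realized genetic variance fraction equals
    the requested h2 exactly up to the noise draw's own sampling.
    """
    g = haps.genotypes()
    mu, sd = g.mean(axis=0), g.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("constant genotype column; cannot standardize")
    gstd = (g - mu) / sd
    y_gwas = _one_phenotype(
        gstd, arch.causal_indices_gwas, arch.effect_sizes, arch.h2_gwas,
        substream(seed, "pheno_gwas"),
    )
    y_eqtl = _one_phenotype(
        gstd, arch.causal_indices_eqtl, arch.effect_sizes, arch.h2_eqtl,
        substream(seed, "pheno_eqtl"),
    )
    return y_gwas, y_eqtl


def marginal_summary_stats(
    haps: Haplotypes, pheno: np.ndarray, variant_ids: list[str] | None = None
) -> SummaryStats:
    """Per-variant simple linear regression of phenotype on dosage.

    Textbook OLS with intercept, vectorized across variants:
    beta_j = cov(x_j, y) / var(x_j), se_j from the residual variance on
    n - 2 degrees of freedom.
    """
    g = haps.genotypes()
    y = np.asarray(pheno, dtype=float)
    n = g.shape[0]
    if y.shape != (n,):
        raise ValueError("phenotype length must equal individual count")
    if n < 3:
        raise ValueError("need at least 3 individuals for per-variant OLS")
    xc = g - g.mean(axis=0)
    yc = y - y.mean()
    sxx = (xc**2).sum(axis=0)
    if np.any(sxx == 0):
        raise ValueError(f"variant column {int(np.argmax(sxx == 0))} is constant")
    beta = (xc * yc[:, None]).sum(axis=0) / sxx
    rss = (yc**2).sum() - beta**2 * sxx
    rss = np.maximum(rss, 0.0)
    sigma2 = rss / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    # a perfect fit gives se = 0; floor it so z stays finite and maximal
    tiny = np.finfo(float).tiny
    se = np.maximum(se, np.sqrt(tiny))
    ids = variant_ids if variant_ids is not None else default_variant_ids(haps.m)
    return SummaryStats(
        variant_ids=ids, positions=haps.positions, beta=beta, se=se, z=beta / se, n=n
    )


def simulate_annotation_track(config: SimConfig, arch: CausalArchitecture) -> AnnotationTrack:
    """Interval track on the locus, optionally centred on causal variants.

    ``null`` mode places every interval uniformly; ``causal-centered``
    forces one interval to contain each causal variant position (the
    enriched scenario) and places the remainder uniformly.
    """
    span, length = config.locus_span_bp, config.interval_length_bp
    if config.n_intervals == 0:
        return AnnotationTrack(intervals=[], label="simulated")
    if length >= span:
        raise ValueError("interval_length_bp must be smaller than locus_span_bp")
    rng = substream(config.seed, "annotation")
    intervals: list[tuple[int, int]] = []
    n_free = config.n_intervals
    if config.enrichment_mode == "causal-centered":
        causal = sorted(set(arch.causal_indices_gwas) | set(arch.causal_indices_eqtl))
        if len(causal) > config.n_intervals:
            raise ValueError("need at least one interval per causal variant")
        positions = _locus_positions(config)
        for idx in causal:
            pos = int(positions[idx])
            lo = max(0, pos - length + 1)
            hi = min(span - length, pos)
            if hi < lo:
                raise ValueError("interval cannot fit around causal position")
            start = int(rng.integers(lo, hi + 1))
            intervals.append((start, start + length))
        n_free -= len(causal)
    starts = rng.integers(0, span - length + 1, size=n_free)
    intervals.extend((int(s), int(s) + length) for s in starts)
    return AnnotationTrack(intervals=intervals, label="simulated")


def _locus_positions(config: SimConfig) -> np.ndarray:
    """Variant positions exactly as :func:`simulate_haplotypes` draws them.

    Replays the haplotype substream's draw order (refresh frequencies,
    copy mask, fresh alleles, positions) without materializing alleles.
    """
    rng = substream(config.seed, "haplotypes")
    n_hap, m = 2 * config.n_individuals, config.m_variants
    rng.uniform(config.min_freq, config.max_freq, size=m)
    rng.random(size=(n_hap, m))
    rng.random(size=(n_hap, m))
    return np.sort(rng.choice(config.locus_span_bp, size=m, replace=False))


def simulate_diameters(
    mean_um: float,
    sd_um: float,
    n_cells: int,
    seed: int,
    depot: str = "SAT",
    animal_id: str = "sim",
    depot_mass_g: float = 0.5,
) -> DiameterSample:
    """Lognormal adipocyte diameters moment-matched to mean/SD in um.

    Standard moment inversion: sigma^2 = ln(1 + (sd/mean)^2),
    mu = ln(mean) - sigma^2 / 2, so the sampled arithmetic mean and SD
    target the requested values while diameters stay positive and
    right-skewed, as adipocyte size distributions are.
    """
    if mean_um <= 0 or sd_um <= 0:
        raise ValueError("mean and sd must be positive")
    if n_cells < 1:
        raise ValueError("n_cells must be at least 1")
    rng = substream(seed, "diameters")
    sigma2 = np.log1p((sd_um / mean_um) ** 2)
    mu = np.log(mean_um) - sigma2 / 2
    d = rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n_cells)
    return DiameterSample(
        diameters_um=d, depot=depot, animal_id=animal_id, depot_mass_g=depot_mass_g
    )
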