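"""GWAS-eQTL colocalization scores: CLPP and the LD-modified mCLPP.

The colocalization posterior probability (CLPP) of eCAVIAR credits only
variants that are causal for *both* traits:

    CLPP = sum_i g_i e_i

with g_i, e_j the per-variant causal probabilities (PIPs) of the GWAS
and expression traits.  The modified score additionally credits variant
*pairs* in strong LD, so two association signals tagging the same
haplotype still count as colocalized even when fine-mapping puts their
point masses on different variants:

    mCLPP = sum_{i,j} g_i e_j LD_ij

where LD_ij is r^2 between variants i and j.  The double sum runs over
all ordered pairs including i = j, hence mCLPP >= CLPP always (unit
diagonal), and mCLPP = CLPP exactly under identity LD.  A locus is
called colocalized when mCLPP exceeds a threshold (default 0.8).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .finemap import PosteriorSet, enumerate_posteriors
from .types import LDMatrix, SummaryStats


@dataclass
class ColocResult:
    clpp: float
    mclpp: float
    lead_pair: tuple[str, str]  # (gwas variant, eqtl variant) maximizing g_i e_j LD_ij
    colocalized: bool
    threshold: float
    gwas_posteriors: PosteriorSet | None = None
    eqtl_posteriors: PosteriorSet | None = None


def _check_aligned(g: PosteriorSet, e: PosteriorSet) -> None:
    if g.variant_ids != e.variant_ids:
        diff = set(g.variant_ids) ^ set(e.variant_ids)
        raise ValueError(
            "posterior sets must cover identical variants in identical order; "
            f"symmetric difference: {sorted(diff) if diff else 'same set, different order'}"
        )


def _clip_unit(x: float, what: str) -> float:
    if x > 1.0 + 1e-9:
        warnings.warn(
            f"{what} = {x:.4f} > 1 (PIPs from a multi-causal run sum above 1); clipping"
        )
    return float(min(max(x, 0.0), 1.0))


def compute_clpp(g: PosteriorSet, e: PosteriorSet) -> float:
    """eCAVIAR-style CLPP: sum over variants of g_i * e_i."""
    _check_aligned(g, e)
    return _clip_unit(float(g.pip @ e.pip), "CLPP")


def compute_mclpp(g: PosteriorSet, e: PosteriorSet, ld: LDMatrix) -> float:
    """LD-weighted CLPP: full double sum of g_i e_j r^2_ij over pairs."""
    _check_aligned(g, e)
    if ld.variant_ids != g.variant_ids:
        raise ValueError("LD matrix variants do not match posterior sets")
    return _clip_unit(float(g.pip @ ld.values @ e.pip), "mCLPP")


def lead_pair(g: PosteriorSet, e: PosteriorSet, ld: LDMatrix) -> tuple[str, str]:
    """Variant pair contributing the largest g_i e_j LD_ij term."""
    contrib = np.outer(g.pip, e.pip) * ld.values
    i, j = np.unravel_index(int(np.argmax(contrib)), contrib.shape)
    return g.variant_ids[i], e.variant_ids[j]


def colocalize_locus(
    gwas_stats: SummaryStats,
    eqtl_stats: SummaryStats,
    ld: LDMatrix,
    max_k: int = 1,
    prior_per_variant: float | None = None,
    prior_variance_w: float = 0.01,
    threshold: float = 0.8,
) -> ColocResult:
    """Fine-map both traits, then score CLPP and mCLPP.

    Both traits are fine-mapped with the same configuration (priors,
    max_k) against the shared LD matrix; the locus is flagged as
    colocalized when mCLPP exceeds the threshold.
    """
    if gwas_stats.variant_ids != eqtl_stats.variant_ids:
        diff = set(gwas_stats.variant_ids) ^ set(eqtl_stats.variant_ids)
        raise ValueError(f"trait variant lists differ; symmetric difference: {sorted(diff)}")
    g = enumerate_posteriors(gwas_stats, ld, max_k, prior_per_variant, prior_variance_w)
    e = enumerate_posteriors(eqtl_stats, ld, max_k, prior_per_variant, prior_variance_w)
    clpp = compute_clpp(g, e)
    mclpp = compute_mclpp(g, e, ld)
    return ColocResult(
        clpp=clpp,
        mclpp=mclpp,
        lead_pair=lead_pair(g, e, ld),
        colocalized=mclpp > threshold,
        threshold=threshold,
        gwas_posteriors=g,
        eqtl_posteriors=e,
    )
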