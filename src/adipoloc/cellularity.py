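"""Adipocyte histomorphometry and robust trait-correlation statistics.

From per-cell diameter tables this module derives spherical cell
volumes (V = 4/3 pi (D/2)^3), mean cell weight via the triglyceride
density, total adipocyte number per depot (depot mass / mean cell
weight), binned size distributions, and Kolmogorov-Smirnov comparisons
of diameter distributions between groups.  A covariate-adjusted
biweight midcorrelation links expression residuals to clinical traits.

Units: diameters in um, volumes in um^3, masses in grams, density in
g/mL (1 um^3 = 1e-12 mL).  The default density 0.915 g/mL is the
standard triolein value.  The default pixel scale 0.3953 um/px applies
to a x20 objective.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from .types import DiameterSample

MICRONS_PER_PIXEL_20X = 0.3953
TRIGLYCERIDE_DENSITY_G_PER_ML = 0.915
ML_PER_UM3 = 1e-12
DEFAULT_BIN_EDGES_UM = np.arange(0.0, 150.0 + 5.0, 5.0)  # 0-150 um in 5 um steps


@dataclass
class CellularityResult:
    mean_diameter_um: float
    mean_volume_um3: float
    mean_cell_weight_g: float
    cells_per_depot: float
    depot_mass_g: float
    density_g_per_ml: float


def pixels_to_microns(lengths_px, scale: float = MICRONS_PER_PIXEL_20X) -> np.ndarray:
    """Convert pixel lengths to micrometres."""
    lengths_px = np.asarray(lengths_px, dtype=float)
    if scale <= 0:
        raise ValueError("scale must be positive")
    if np.any(lengths_px < 0):
        raise ValueError("lengths must be non-negative")
    return lengths_px * scale


def adipocyte_volume(diameter_um) -> np.ndarray | float:
    """Spherical volume from diameter: V = 4/3 pi (D/2)^3, in um^3."""
    d = np.asarray(diameter_um, dtype=float)
    if np.any(d < 0):
        raise ValueError("diameter must be non-negative")
    v = (4.0 / 3.0) * np.pi * (d / 2.0) ** 3
    return float(v) if v.ndim == 0 else v


def depot_cell_count(
    sample: DiameterSample,
    density_g_per_ml: float = TRIGLYCERIDE_DENSITY_G_PER_ML,
    volume_of_mean_diameter: bool = False,
) -> CellularityResult:
    """Total adipocyte number in a depot from diameters and depot mass.

    mean cell weight = mean cell volume (mL) x density;
    count = depot mass / mean cell weight.  ``volume_of_mean_diameter``
    switches the mean-volume convention from the mean of per-cell
    volumes (default) to the volume of the mean diameter (the two
    differ under Jensen's inequality for any spread of diameters).
    """
    if sample.n_cells < 1:
        raise ValueError("need at least one diameter")
    if density_g_per_ml <= 0:
        raise ValueError("density must be positive")
    if not sample.depot_mass_g > 0:
        raise ValueError("depot mass must be positive")
    mean_d = float(sample.diameters_um.mean())
    if volume_of_mean_diameter:
        mean_v = float(adipocyte_volume(mean_d))
    else:
        mean_v = float(np.mean(adipocyte_volume(sample.diameters_um)))
    if mean_v == 0:
        raise ValueError("mean adipocyte volume is zero")
    mean_w = mean_v * ML_PER_UM3 * density_g_per_ml
    return CellularityResult(
        mean_diameter_um=mean_d,
        mean_volume_um3=mean_v,
        mean_cell_weight_g=mean_w,
        cells_per_depot=sample.depot_mass_g / mean_w,
        depot_mass_g=sample.depot_mass_g,
        density_g_per_ml=density_g_per_ml,
    )


def size_distribution(
    sample: DiameterSample, bin_edges: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Binned diameter distribution: (edges, counts, fractions).

    Left-closed right-open bins; cells outside the edges are dropped
    with a warning and fractions renormalize over the included cells.
    """
    if sample.n_cells == 0:
        raise ValueError("empty diameter sample")
    edges = DEFAULT_BIN_EDGES_UM if bin_edges is None else np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    d = sample.diameters_um
    inside = (d >= edges[0]) & (d < edges[-1])
    if not inside.all():
        import warnings

        warnings.warn(f"{int((~inside).sum())} cells outside bin range were clipped")
    counts, _ = np.histogram(d[inside], bins=edges)
    total = counts.sum()
    fractions = counts / total if total else counts.astype(float)
    return edges, counts, fractions


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test for a distribution shift.

    D = sup |ECDF_a - ECDF_b|; the p-value uses the asymptotic
    Kolmogorov distribution at effective size n_a n_b / (n_a + n_b).
    Sensitive to any difference in distribution shape or location,
    which makes it the natural test for shifts in adipocyte size
    distribution curves.
    """
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least 2 values")
    grid = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, grid, side="right") / a.size
    cdf_b = np.searchsorted(b, grid, side="right") / b.size
    d_stat = float(np.abs(cdf_a - cdf_b).max())
    en = a.size * b.size / (a.size + b.size)
    p = float(special.kolmogorov(np.sqrt(en) * d_stat))
    return d_stat, min(max(p, 0.0), 1.0)


def _biweight(x: np.ndarray) -> np.ndarray:
    """Tukey biweight deviations: w_i (x_i - median) with 9-MAD tuning."""
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        raise ValueError(
            "MAD is zero (over half the values are identical); "
            "biweight midcorrelation is undefined -- consider a Pearson fallback"
        )
    u = (x - med) / (9.0 * mad)
    w = (1 - u**2) ** 2 * (np.abs(u) < 1)
    return w * (x - med)


def bicor(x, y) -> float:
    """Biweight midcorrelation: robust correlation with 9-MAD weights."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("samples must have equal length")
    ax, ay = _biweight(x), _biweight(y)
    denom = np.sqrt((ax**2).sum() * (ay**2).sum())
    if denom == 0:
        raise ValueError("zero biweight spread; correlation undefined")
    return float(np.clip((ax * ay).sum() / denom, -1.0, 1.0))


def adjusted_bicor(expression, covariate, trait) -> tuple[float, float]:
    """Covariate-adjusted robust expression-trait correlation.

    Residualizes expression on the covariate (e.g. BMI) by OLS with
    intercept, then correlates the residuals against the trait using
    the biweight midcorrelation; the p-value is the two-sided Student
    test of t = r sqrt((n-2)/(1-r^2)) on n - 2 degrees of freedom.
    """
    e = np.asarray(expression, dtype=float)
    c = np.asarray(covariate, dtype=float)
    t = np.asarray(trait, dtype=float)
    n = e.size
    if n < 5:
        raise ValueError("need at least 5 observations")
    if c.shape != e.shape or t.shape != e.shape:
        raise ValueError("expression, covariate and trait must align")
    if np.ptp(c) == 0:
        raise ValueError("covariate is constant; adjustment is undefined")
    design = np.column_stack([np.ones(n), c])
    coef, *_ = np.linalg.lstsq(design, e, rcond=None)
    resid = e - design @ coef
    r = bicor(resid, t)
    if abs(r) >= 1.0:
        return r, 0.0
    t_stat = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * stats.t.sf(abs(t_stat), df=n - 2)
    return r, float(p)
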