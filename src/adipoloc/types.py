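"""Shared data containers for locus-level analyses.

Coordinate conventions: positions are base-pair integers on a single
locus; annotation intervals are 0-based half-open, BED semantics.
Diameters are micrometres unless a pixel scale is applied explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SummaryStats:
    """Per-variant marginal association results for one trait at one locus.

    ``z`` must equal ``beta / se``; validation enforces consistency to 1e-6
    so files edited by hand cannot silently desynchronise the two.
    """

    variant_ids: list[str]
    positions: np.ndarray  # bp, int
    beta: np.ndarray
    se: np.ndarray
    z: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.beta = np.asarray(self.beta, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        m = len(self.variant_ids)
        if not (len(self.positions) == len(self.beta) == len(self.se) == len(self.z) == m):
            raise ValueError("SummaryStats arrays must have equal length")
        if np.any(self.se <= 0):
            bad = self.variant_ids[int(np.argmax(self.se <= 0))]
            raise ValueError(f"standard error must be positive (variant {bad!r})")
        if np.any(np.abs(self.z - self.beta / self.se) > 1e-6):
            bad = self.variant_ids[int(np.argmax(np.abs(self.z - self.beta / self.se) > 1e-6))]
            raise ValueError(f"z inconsistent with beta/se (variant {bad!r})")

    @property
    def m(self) -> int:
        return len(self.variant_ids)


@dataclass
class LDMatrix:
    """Symmetric linkage-disequilibrium matrix over the locus variants.

    ``values`` holds r^2 in [0, 1] with unit diagonal (what the mCLPP
    weighting consumes).  ``signed_r`` optionally carries the signed
    correlation needed by multi-causal fine-mapping; when absent, the
    fine-mapper caps the causal configuration size at 1.
    """

    values: np.ndarray  # m x m r^2
    variant_ids: list[str]
    signed_r: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        m = len(self.variant_ids)
        if self.values.shape != (m, m):
            raise ValueError("LD matrix shape does not match variant list")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-8):
            raise ValueError("LD matrix diagonal must be 1")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError(
                "LD entries outside [0, 1]; a signed-r matrix was supplied where r^2 was expected"
            )
        if self.signed_r is not None:
            self.signed_r = np.asarray(self.signed_r, dtype=float)
            if self.signed_r.shape != (m, m):
                raise ValueError("signed-r matrix shape does not match variant list")

    @property
    def m(self) -> int:
        return len(self.variant_ids)


@dataclass
class AnnotationTrack:
    """Genomic interval set (0-based half-open bp) for one epigenomic mark."""

    intervals: list[tuple[int, int]]
    label: str = ""

    def __post_init__(self) -> None:
        for start, end in self.intervals:
            if start >= end:
                raise ValueError(f"interval start must be < end, got ({start}, {end})")
        self.intervals = sorted((int(s), int(e)) for s, e in self.intervals)

    @property
    def total_bp(self) -> int:
        return sum(e - s for s, e in self.intervals)


@dataclass
class DiameterSample:
    """Per-cell adipocyte diameters for one depot of one animal."""

    diameters_um: np.ndarray
    depot: str = "SAT"
    animal_id: str = ""
    depot_mass_g: float = float("nan")

    def __post_init__(self) -> None:
        self.diameters_um = np.asarray(self.diameters_um, dtype=float)
        if self.diameters_um.size and np.any(self.diameters_um <= 0):
            raise ValueError("diameters must be positive")

    @property
    def n_cells(self) -> int:
        return int(self.diameters_um.size)


@dataclass
class Haplotypes:
    """Binary haplotype matrix: 2n haplotypes x m variants."""

    alleles: np.ndarray  # uint8, {0,1}
    positions: np.ndarray  # bp, strictly increasing
    allele_freqs: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.alleles.ndim != 2:
            raise ValueError("allele matrix must be 2-D")
        if self.positions.shape != (self.alleles.shape[1],):
            raise ValueError("positions must align with variant columns")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.allele_freqs is None:
            self.allele_freqs = self.alleles.mean(axis=0)
        self.allele_freqs = np.asarray(self.allele_freqs, dtype=float)
        if np.any((self.allele_freqs <= 0) | (self.allele_freqs >= 1)):
            bad = int(np.argmax((self.allele_freqs <= 0) | (self.allele_freqs >= 1)))
            raise ValueError(f"variant column {bad} is monomorphic")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def m(self) -> int:
        return self.alleles.shape[1]

    def genotypes(self) -> np.ndarray:
        """Diploid dosages: haplotypes 2i and 2i+1 form individual i."""
        a = self.alleles
        if a.shape[0] % 2:
            raise ValueError("odd haplotype count cannot be paired into diploids")
        return (a[0::2] + a[1::2]).astype(float)
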