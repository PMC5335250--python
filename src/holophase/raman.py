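"""Raman spectrum preprocessing and pairwise significance maps.

Single-point Raman spectra of live immune cells are restricted to the
fingerprint region (900-1700 cm-1) and normalised to unit total
intensity to cancel excitation-power fluctuations. Pairwise per-
wavenumber Welch t-tests between cell classes produce significance maps
whose flagged intervals mark the bands where two classes differ
chemically (e.g. lipid CH2 deformation near 1455 cm-1, nucleic-acid
bands near 1585 cm-1, amide I near 1665 cm-1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RamanSpectrum",
    "SignificanceMap",
    "CoverageError",
    "crop_and_normalize",
    "resample_to_grid",
    "pairwise_ttest",
    "default_grid",
    "read_spectrum_csv",
    "write_spectrum_csv",
]

FINGERPRINT_LO = 900.0
FINGERPRINT_HI = 1700.0


class CoverageError(ValueError):
    """Spectrum does not cover the requested wavenumber range."""


def default_grid() -> np.ndarray:
    """Shared analysis grid: 1 cm-1 spacing over [900, 1700] (801 points)."""
    return np.arange(FINGERPRINT_LO, FINGERPRINT_HI + 1.0, 1.0)


@dataclass(frozen=True)
class RamanSpectrum:
    """A single-cell Raman spectrum on a strictly increasing wavenumber axis."""

    wavenumbers_cm1: np.ndarray
    intensities: np.ndarray
    cell_id: str | None = None
    class_label: str | None = None

    def __post_init__(self):
        wn = np.asarray(self.wavenumbers_cm1, dtype=float)
        it = np.asarray(self.intensities, dtype=float)
        if wn.ndim != 1 or it.ndim != 1 or wn.shape != it.shape:
            raise ValueError("wavenumbers and intensities must be equal-length 1D")
        if wn.size < 2 or np.any(np.diff(wn) <= 0):
            raise ValueError("wavenumbers must be strictly increasing")
        if not (np.all(np.isfinite(wn)) and np.all(np.isfinite(it))):
            raise ValueError("spectrum contains non-finite values")
        if np.any(it < 0):
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "wavenumbers_cm1", wn)
        object.__setattr__(self, "intensities", it)


@dataclass(frozen=True)
class SignificanceMap:
    """Per-wavenumber p-values with contiguous sub-threshold intervals."""

    wavenumbers_cm1: np.ndarray
    p_values: np.ndarray
    threshold: float
    flagged_regions: list[tuple[float, float]] = field(default_factory=list)


def crop_and_normalize(
    spec: RamanSpectrum, lo: float = FINGERPRINT_LO, hi: float = FINGERPRINT_HI
) -> RamanSpectrum:
    """Restrict to [lo, hi] and divide by the total retained intensity.

    The output sums to exactly 1, making spectra comparable across
    acquisitions regardless of incident power.
    """
    wn = spec.wavenumbers_cm1
    if wn[0] > lo or wn[-1] < hi:
        raise CoverageError(
            f"spectrum covers [{wn[0]}, {wn[-1]}] cm-1, need [{lo}, {hi}]"
        )
    keep = (wn >= lo) & (wn <= hi)
    intens = spec.intensities[keep]
    total = intens.sum()
    if total <= 0:
        raise ValueError("non-positive total intensity in crop window")
    return RamanSpectrum(
        wavenumbers_cm1=wn[keep],
        intensities=intens / total,
        cell_id=spec.cell_id,
        class_label=spec.class_label,
    )


def resample_to_grid(specs: list[RamanSpectrum], grid: np.ndarray) -> np.ndarray:
    """Linear interpolation of spectra onto a shared grid, one row per cell."""
    grid = np.asarray(grid, dtype=float)
    out = np.empty((len(specs), grid.size))
    for i, spec in enumerate(specs):
        wn = spec.wavenumbers_cm1
        if wn[0] > grid[0] or wn[-1] < grid[-1]:
            raise CoverageError(
                f"spectrum {spec.cell_id!r} covers [{wn[0]}, {wn[-1]}], "
                f"grid needs [{grid[0]}, {grid[-1]}] (extrapolation refused)"
            )
        out[i] = np.interp(grid, wn, spec.intensities)
    return out


def pairwise_ttest(
    group_a: np.ndarray,
    group_b: np.ndarray,
    alpha: float,
    wavenumbers_cm1: np.ndarray | None = None,
) -> SignificanceMap:
    """Per-wavenumber Welch two-sample t-test between two spectral matrices.

    Columns where both groups have zero variance get p = 0 if the means
    differ and p = 1 otherwise. Contiguous runs with p < alpha merge
    into ``flagged_regions`` (cm-1 intervals).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError("groups must be 2D matrices with matching columns")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 spectra per group")
    if wavenumbers_cm1 is None:
        wavenumbers_cm1 = np.arange(a.shape[1], dtype=float)
    wn = np.asarray(wavenumbers_cm1, dtype=float)

    with np.errstate(invalid="ignore", divide="ignore"):
        result = stats.ttest_ind(a, b, axis=0, equal_var=False)
        p = np.asarray(result.pvalue, dtype=float)
    degenerate = ~np.isfinite(p)
    if np.any(degenerate):
        means_differ = ~np.isclose(a.mean(axis=0), b.mean(axis=0))
        p[degenerate & means_differ] = 0.0
        p[degenerate & ~means_differ] = 1.0

    below = p < alpha
    regions: list[tuple[float, float]] = []
    idx = np.flatnonzero(below)
    if idx.size:
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate(([idx[0]], idx[breaks + 1]))
        ends = np.concatenate((idx[breaks], [idx[-1]]))
        regions = [(float(wn[s]), float(wn[e])) for s, e in zip(starts, ends)]
    return SignificanceMap(
        wavenumbers_cm1=wn, p_values=p, threshold=alpha, flagged_regions=regions
    )


def read_spectrum_csv(path, cell_id=None, class_label=None) -> RamanSpectrum:
    """Read a two-column (wavenumber_cm1, intensity) CSV."""
    df = pd.read_csv(path)
    return RamanSpectrum(
        wavenumbers_cm1=df.iloc[:, 0].to_numpy(float),
        intensities=df.iloc[:, 1].to_numpy(float),
        cell_id=cell_id,
        class_label=class_label,
    )


def write_spectrum_csv(spec: RamanSpectrum, path) -> None:
    pd.DataFrame(
        {"wavenumber_cm1": spec.wavenumbers_cm1, "intensity": spec.intensities}
    ).to_csv(path, index=False)
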