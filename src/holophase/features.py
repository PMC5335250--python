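"""Descriptor extraction from quantitative phase maps.

Three descriptor families summarise a single-cell phase map for
classification:

* pixel-intensity histogram — a dedicated first bin counts exactly-zero
  (background) pixels, so cell area is encoded directly; the remaining
  bins tile (0, range_max] uniformly. The zero bin is what lets the
  first principal component read off cell size.
* grey-level co-occurrence texture — the image is quantized to a small
  number of grey levels over its own range and the joint distribution of
  level pairs at a pixel offset yields the four Haralick-style
  statistics contrast, correlation, energy (sum of squared GLCM
  entries) and homogeneity; either a single 0-degree offset (4 values)
  or all four directions 0/45/90/135 degrees (16 values).
* concatenations — histogram + texture, or Raman spectrum + histogram,
  optionally with each block rescaled to unit sum so neither family
  dominates the joint vector.

Per-image min-max quantization makes all four texture statistics
invariant to multiplying the phase map by a positive constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .reconstruct import PhaseMap

__all__ = [
    "PROVENANCES",
    "HistogramDescriptor",
    "TextureDescriptor",
    "DescriptorVector",
    "intensity_histogram",
    "glcm",
    "texture_stats",
    "texture_descriptor",
    "concat_descriptor",
    "ANGLE_OFFSETS",
    "STAT_NAMES",
]

PROVENANCES = ("RAMAN", "HIST", "TEXTURE4", "TEXTURE16", "HIST+TEXTURE", "RAMAN+HIST")

# (drow, dcol) for 0, 45, 90, 135 degrees at distance 1; rows grow downward
ANGLE_OFFSETS: dict[int, tuple[int, int]] = {
    0: (0, 1),
    45: (-1, 1),
    90: (-1, 0),
    135: (-1, -1),
}
STAT_NAMES = ("contrast", "correlation", "energy", "homogeneity")


@dataclass(frozen=True)
class HistogramDescriptor:
    """Pixel-value histogram with an explicit exactly-zero bin.

    ``counts[0]`` equals ``zero_count``; bins 1..n-1 are right-closed
    uniform intervals over (0, range_max] given by ``bin_edges``.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    zero_count: int

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=int)
        if np.any(counts < 0) or counts[0] != self.zero_count:
            raise ValueError("inconsistent histogram counts")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "bin_edges", np.asarray(self.bin_edges, float))

    @property
    def n_pixels(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class TextureDescriptor:
    """The four co-occurrence statistics, with the directions they used."""

    contrast: float
    correlation: float
    energy: float
    homogeneity: float
    directions: tuple[int, ...] = (0,)

    def __post_init__(self):
        if self.contrast < 0:
            raise ValueError("contrast must be non-negative")
        if not (0 < self.energy <= 1 + 1e-12):
            raise ValueError("energy must lie in (0, 1]")
        if not (0 < self.homogeneity <= 1 + 1e-12):
            raise ValueError("homogeneity must lie in (0, 1]")
        if abs(self.correlation) > 1 + 1e-9:
            raise ValueError("|correlation| must be <= 1")

    def as_vector(self) -> np.ndarray:
        return np.array(
            [self.contrast, self.correlation, self.energy, self.homogeneity]
        )


@dataclass(frozen=True)
class DescriptorVector:
    """A per-cell feature vector tagged with its provenance and label."""

    values: np.ndarray
    provenance: str
    cell_id: str | None = None
    class_label: str | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or not np.all(np.isfinite(v)):
            raise ValueError("descriptor values must be a finite 1D vector")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size


def _phase_array(phase) -> np.ndarray:
    if isinstance(phase, PhaseMap):
        return phase.phase_rad
    return np.asarray(phase, dtype=float)


def intensity_histogram(
    phase, n_bins: int = 64, range_max: float = None
) -> HistogramDescriptor:
    """Histogram of phase values with a dedicated exactly-zero bin.

    Bins 1..n_bins-1 uniformly tile (0, range_max], right-closed; values
    above range_max are clipped into the last bin. Counts always sum to
    the pixel count. ``range_max`` should be shared across a cohort so
    descriptor vectors are comparable.
    """
    arr = _phase_array(phase)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if not np.all(np.isfinite(arr)):
        raise ValueError("phase map contains non-finite values")
    if np.any(arr < 0):
        raise ValueError("phase map contains negative values")
    if range_max is None:
        range_max = float(arr.max()) if arr.max() > 0 else 1.0
    if range_max <= 0:
        raise ValueError("range_max must be positive")
    flat = arr.ravel()
    zero = flat == 0.0
    zero_count = int(zero.sum())
    counts = np.zeros(n_bins, dtype=int)
    counts[0] = zero_count
    pos = flat[~zero]
    if pos.size:
        width = range_max / (n_bins - 1)
        idx = np.ceil(pos / width).astype(int)  # (0, w] -> 1
        idx = np.clip(idx, 1, n_bins - 1)
        counts[1:] = np.bincount(idx, minlength=n_bins)[1:]
    edges = np.linspace(0.0, range_max, n_bins)
    return HistogramDescriptor(bin_edges=edges, counts=counts, zero_count=zero_count)


def _quantize(image: np.ndarray, n_levels: int) -> np.ndarray:
    lo, hi = float(image.min()), float(image.max())
    if hi == lo:
        warnings.warn(
            "constant image: all co-occurrence mass falls on level (0, 0)",
            stacklevel=3,
        )
        return np.zeros(image.shape, dtype=np.intp)
    q = ((image - lo) / (hi - lo) * n_levels).astype(np.intp)
    return np.clip(q, 0, n_levels - 1)


def glcm(
    image,
    n_levels: int = 8,
    offsets: list[tuple[int, int]] | None = None,
) -> dict[tuple[int, int], np.ndarray]:
    """Grey-level co-occurrence probability matrices, one per offset.

    The image is quantized to ``n_levels`` equal-width levels over its
    own [min, max]; for each (drow, dcol) offset, every in-bounds pixel
    pair (p, p+offset) is counted once (non-symmetric pairing) and the
    count matrix is normalized to sum to 1.
    """
    image = _phase_array(image)
    if image.ndim != 2:
        raise ValueError("image must be 2D")
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    if offsets is None:
        offsets = [ANGLE_OFFSETS[0]]
    q = _quantize(image, n_levels)
    rows, cols = q.shape
    out: dict[tuple[int, int], np.ndarray] = {}
    for drow, dcol in offsets:
        if (drow, dcol) == (0, 0):
            raise ValueError("offset (0, 0) is not a pixel pair")
        r0, r1 = max(0, -drow), min(rows, rows - drow)
        c0, c1 = max(0, -dcol), min(cols, cols - dcol)
        if r0 >= r1 or c0 >= c1:
            raise ValueError(f"offset {(drow, dcol)} leaves no in-bounds pairs")
        a = q[r0:r1, c0:c1].ravel()
        b = q[r0 + drow : r1 + drow, c0 + dcol : c1 + dcol].ravel()
        counts = np.bincount(a * n_levels + b, minlength=n_levels * n_levels)
        p = counts.reshape(n_levels, n_levels).astype(float)
        out[(drow, dcol)] = p / p.sum()
    return out


def texture_stats(
    p: np.ndarray, directions: tuple[int, ...] = (0,)
) -> TextureDescriptor:
    """Contrast, correlation, energy and homogeneity of one GLCM.

    contrast    = sum_ij (i-j)^2 P(i,j)
    correlation = sum_ij (i-mu_i)(j-mu_j) P(i,j) / (sigma_i sigma_j)
    energy      = sum_ij P(i,j)^2
    homogeneity = sum_ij P(i,j) / (1 + |i-j|)

    Zero-variance marginals make correlation undefined; it is reported
    as 1.0 (the constant-image limit) with a warning.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError("GLCM must be square")
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("GLCM must be normalized to sum to 1")
    n = p.shape[0]
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    contrast = float(((i - j) ** 2 * p).sum())
    energy = float((p**2).sum())
    homogeneity = float((p / (1.0 + np.abs(i - j))).sum())
    mu_i = float((i * p).sum())
    mu_j = float((j * p).sum())
    var_i = float(((i - mu_i) ** 2 * p).sum())
    var_j = float(((j - mu_j) ** 2 * p).sum())
    if var_i <= 0 or var_j <= 0:
        warnings.warn(
            "zero-variance GLCM marginal: correlation undefined, reporting 1.0",
            stacklevel=2,
        )
        correlation = 1.0
    else:
        correlation = float(
            (((i - mu_i) * (j - mu_j) * p).sum()) / np.sqrt(var_i * var_j)
        )
    return TextureDescriptor(
        contrast=contrast,
        correlation=correlation,
        energy=energy,
        homogeneity=homogeneity,
        directions=directions,
    )


def texture_descriptor(phase, mode: int = 4, n_levels: int = 8) -> np.ndarray:
    """Texture feature vector of a phase map.

    mode 4: the four statistics at the 0-degree distance-1 offset.
    mode 16: the statistics at 0/45/90/135 degrees, concatenated
    angle-major, statistic-minor (contrast, correlation, energy,
    homogeneity within each angle).
    """
    if mode not in (4, 16):
        raise ValueError("mode must be 4 or 16")
    angles = (0,) if mode == 4 else (0, 45, 90, 135)
    offsets = [ANGLE_OFFSETS[a] for a in angles]
    mats = glcm(phase, n_levels=n_levels, offsets=offsets)
    parts = []
    for angle in angles:
        stats = texture_stats(mats[ANGLE_OFFSETS[angle]], directions=(angle,))
        parts.append(stats.as_vector())
    return np.concatenate(parts)


def concat_descriptor(
    a: DescriptorVector, b: DescriptorVector, block_norm: bool = False
) -> DescriptorVector:
    """Concatenate two descriptors of the same cell into one vector.

    With ``block_norm`` each block is rescaled to unit sum first, so
    families on very different scales (e.g. pixel counts vs normalized
    Raman intensities) contribute comparably.
    """
    if a.cell_id != b.cell_id:
        raise ValueError(f"cell_id mismatch: {a.cell_id!r} vs {b.cell_id!r}")

    def _block(vec: np.ndarray) -> np.ndarray:
        if not block_norm:
            return vec
        total = vec.sum()
        if total == 0:
            raise ValueError("cannot block-normalize an all-zero block")
        return vec / total

    values = np.concatenate([_block(a.values), _block(b.values)])
    return DescriptorVector(
        values=values,
        provenance=f"{a.provenance}+{b.provenance}",
        cell_id=a.cell_id,
        class_label=a.class_label,
    )
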