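"""Synthetic immune-cell cohorts: phase phantoms, holograms, Raman spectra.

Every downstream stage of the pipeline is testable without instrument
data through this module. Three cell classes are emulated:

* ``CD4`` — CD4+ T-cell-like: small, low integrated phase, uniform
  morphology (tight parameter distributions, weak internal texture).
* ``BCELL`` — B-cell-like: similar size to CD4 but with markedly larger
  within-class variability in size and peak phase.
* ``MONO`` — monocyte-like: clearly larger projected area, larger total
  optical path difference, coarser internal texture.

A phantom is a truncated-paraboloid phase dome (closed-form volume
``pi * R^2 * h / 2``) plus a band-limited Gaussian random field standing
in for intracellular structure; phase is exactly zero outside the cell
disc. Holograms are rendered as two-beam off-axis interference of a unit
amplitude pure-phase object with a tilted plane reference, with additive
Gaussian noise and detector quantization. Raman spectra are sums of
Gaussian bands at the fingerprint positions that discriminate these
classes (938, 1129, 1259, 1304, 1421, 1455, 1585, 1665 cm-1) over a
smooth baseline, with class-specific band heights.

All randomness derives from explicit seeds: a cohort seed is split into
per-cell (phantom, hologram, spectrum) streams via ``SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .raman import RamanSpectrum, default_grid
from .reconstruct import Hologram, PhaseMap

__all__ = [
    "CLASS_LABELS",
    "CellPhantom",
    "OpticalConfig",
    "RamanClassProfile",
    "Cohort",
    "UnknownClassError",
    "CLASS_MORPHOLOGY",
    "DEFAULT_RAMAN_PROFILES",
    "make_phantom",
    "render_phase_field",
    "interference_intensity",
    "render_hologram",
    "simulate_spectrum",
    "make_cohort",
]

CLASS_LABELS = ("CD4", "BCELL", "MONO")


class UnknownClassError(ValueError):
    """Cell class label outside the supported set."""


@dataclass(frozen=True)
class CellPhantom:
    """Parametric single-cell phase object.

    The dome peaks at ``max_phase_rad`` and is exactly zero outside a
    disc of ``radius_px``; ``texture_seed`` makes the internal random
    texture a pure function of the phantom.
    """

    class_label: str
    radius_px: float
    max_phase_rad: float
    texture_amplitude_rad: float
    texture_correlation_length_px: float
    center: tuple[float, float] | None = None
    texture_seed: int = 0

    def __post_init__(self):
        if self.class_label not in CLASS_LABELS:
            raise UnknownClassError(f"unknown class label: {self.class_label!r}")
        if self.radius_px <= 0:
            raise ValueError("radius_px must be positive")
        if self.max_phase_rad < 0:
            raise ValueError("max_phase_rad must be non-negative")
        if self.texture_amplitude_rad < 0:
            raise ValueError("texture_amplitude_rad must be non-negative")
        if self.texture_correlation_length_px <= 0:
            raise ValueError("texture_correlation_length_px must be positive")


@dataclass(frozen=True)
class OpticalConfig:
    """Off-axis interferometer model parameters.

    ``carrier_freq`` is the reference-beam tilt in cycles/pixel (fx along
    columns, fy along rows) and must stay below Nyquist so the +1 order
    does not alias. ``noise_sigma`` is additive intensity noise on the
    same scale as the interference term (unit object amplitude, so the
    noiseless intensity spans [0, (1+a)^2]).
    """

    wavelength_m: float = 532e-9
    carrier_freq: tuple[float, float] = (0.2, 0.2)
    reference_amplitude: float = 1.0
    noise_sigma: float = 0.02
    detector_shape: tuple[int, int] = (512, 512)
    bit_depth: int = 8

    def __post_init__(self):
        fx, fy = self.carrier_freq
        if not (0 < abs(fx) < 0.5 and 0 < abs(fy) < 0.5):
            raise ValueError(
                f"carrier frequency {self.carrier_freq} must satisfy 0 < |f| < 0.5 "
                "cycles/pixel (below Nyquist)"
            )
        if self.reference_amplitude <= 0:
            raise ValueError("reference_amplitude must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.bit_depth < 1:
            raise ValueError("bit_depth must be positive")
        if min(self.detector_shape) < 64:
            raise ValueError("detector dimensions must be >= 64")


@dataclass(frozen=True)
class RamanClassProfile:
    """Band model of one class's Raman fingerprint.

    Peaks are Gaussian in wavenumber; the baseline polynomial is
    evaluated in the reduced coordinate u = (wn - 1300)/400 (so its
    coefficients are O(1) over the fingerprint region).
    """

    peak_centers_cm1: tuple[float, ...]
    peak_heights: tuple[float, ...]
    peak_widths_cm1: tuple[float, ...]
    baseline: tuple[float, ...] = (0.6, -0.05, 0.1)
    noise_sigma: float = 0.03

    def __post_init__(self):
        c = np.asarray(self.peak_centers_cm1, float)
        h = np.asarray(self.peak_heights, float)
        w = np.asarray(self.peak_widths_cm1, float)
        if not (c.size == h.size == w.size):
            raise ValueError("peak parameter lists must have equal length")
        if np.any(c < 900) or np.any(c > 1700):
            raise ValueError("peak centers must lie within [900, 1700] cm-1")
        if np.any(w <= 0):
            raise ValueError("peak widths must be positive")
        if np.any(h < 0):
            raise ValueError("peak heights must be non-negative")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


# Morphology parameter distributions per class: (mean, sd) for the dome
# radius and peak phase, texture amplitude/correlation length, and the
# clipping floor keeping draws physical. Chosen once to realise the
# qualitative contrasts described in the module docstring.
CLASS_MORPHOLOGY: dict[str, dict[str, tuple[float, float]]] = {
    "CD4": {
        "radius_px": (28.0, 1.5),
        "max_phase_rad": (2.2, 0.12),
        "texture_amplitude_rad": (0.05, 0.01),
        "texture_correlation_length_px": (6.0, 0.5),
    },
    "BCELL": {
        "radius_px": (30.0, 3.5),
        "max_phase_rad": (2.4, 0.30),
        "texture_amplitude_rad": (0.10, 0.03),
        "texture_correlation_length_px": (6.0, 0.5),
    },
    "MONO": {
        "radius_px": (45.0, 3.5),
        "max_phase_rad": (3.2, 0.25),
        "texture_amplitude_rad": (0.30, 0.05),
        "texture_correlation_length_px": (10.0, 1.0),
    },
}

_BAND_CENTERS = (938.0, 1129.0, 1259.0, 1304.0, 1421.0, 1455.0, 1585.0, 1665.0)
_BAND_WIDTHS = (9.0,) * 8

DEFAULT_RAMAN_PROFILES: dict[str, RamanClassProfile] = {
    "CD4": RamanClassProfile(
        peak_centers_cm1=_BAND_CENTERS,
        peak_heights=(0.85, 0.80, 0.70, 0.80, 0.55, 1.20, 0.75, 1.45),
        peak_widths_cm1=_BAND_WIDTHS,
    ),
    "BCELL": RamanClassProfile(
        peak_centers_cm1=_BAND_CENTERS,
        peak_heights=(0.85, 0.80, 0.88, 0.97, 0.55, 1.02, 0.95, 1.25),
        peak_widths_cm1=_BAND_WIDTHS,
    ),
    "MONO": RamanClassProfile(
        peak_centers_cm1=_BAND_CENTERS,
        peak_heights=(1.15, 1.05, 0.95, 1.05, 0.78, 1.20, 0.70, 1.45),
        peak_widths_cm1=_BAND_WIDTHS,
    ),
}


def _positive_normal(rng, mean, sd, floor):
    return float(max(rng.normal(mean, sd), floor))


def make_phantom(
    class_label: str,
    rng_seed,
    morphology: dict[str, dict[str, tuple[float, float]]] | None = None,
) -> CellPhantom:
    """Draw a phantom from its class's parameter distributions.

    Deterministic given the seed. ``morphology`` overrides the default
    class parameter table (same structure), which is how effect-size
    sweeps are expressed.
    """
    if class_label not in CLASS_LABELS:
        raise UnknownClassError(f"unknown class label: {class_label!r}")
    table = (morphology or CLASS_MORPHOLOGY)[class_label]
    rng = np.random.default_rng(rng_seed)
    radius = _positive_normal(rng, *table["radius_px"], floor=5.0)
    peak = _positive_normal(rng, *table["max_phase_rad"], floor=0.2)
    tex_amp = max(float(rng.normal(*table["texture_amplitude_rad"])), 0.0)
    tex_len = _positive_normal(
        rng, *table["texture_correlation_length_px"], floor=1.0
    )
    texture_seed = int(rng.integers(0, 2**31 - 1))
    return CellPhantom(
        class_label=class_label,
        radius_px=radius,
        max_phase_rad=peak,
        texture_amplitude_rad=tex_amp,
        texture_correlation_length_px=tex_len,
        center=None,
        texture_seed=texture_seed,
    )


def render_phase_field(phantom: CellPhantom, shape: tuple[int, int]) -> PhaseMap:
    """Render the phantom's phase over a field of the given shape.

    Truncated-paraboloid dome of height ``max_phase_rad`` plus a
    Gaussian random field smoothed to the phantom's correlation length,
    tapered by the dome profile so texture vanishes at the rim. Values
    are clipped at zero inside the disc and exactly zero outside it.
    """
    rows, cols = shape
    if phantom.center is None:
        cr, cc = (rows - 1) / 2.0, (cols - 1) / 2.0
    else:
        cr, cc = phantom.center
    r = phantom.radius_px
    if cr - r < 0 or cr + r > rows - 1 or cc - r < 0 or cc + r > cols - 1:
        raise ValueError(
            f"phantom (center=({cr:.1f},{cc:.1f}), radius={r:.1f}) exceeds "
            f"field {shape}"
        )
    yy, xx = np.mgrid[:rows, :cols]
    r2 = ((yy - cr) ** 2 + (xx - cc) ** 2) / r**2
    inside = r2 < 1.0
    profile = np.where(inside, 1.0 - r2, 0.0)
    field = phantom.max_phase_rad * profile
    if phantom.texture_amplitude_rad > 0:
        rng = np.random.default_rng(phantom.texture_seed)
        noise = gaussian_filter(
            rng.standard_normal(shape), phantom.texture_correlation_length_px
        )
        std = noise[inside].std()
        if std > 0:
            noise = noise / std * phantom.texture_amplitude_rad
            field = field + noise * profile
    field = np.where(inside, np.clip(field, 0.0, None), 0.0)
    return PhaseMap(phase_rad=field, roi_origin=(0, 0), wavelength_m=None)


def interference_intensity(phase: np.ndarray, cfg: OpticalConfig) -> np.ndarray:
    """Noiseless, unquantized off-axis interference intensity.

    ``I = |O + R|^2`` with a unit-amplitude pure-phase object
    ``O = exp(i*phase)`` and tilted plane reference
    ``R = a * exp(i*2*pi*(fx*x + fy*y))``.
    """
    phase = np.asarray(phase, dtype=float)
    rows, cols = phase.shape
    fx, fy = cfg.carrier_freq
    a = cfg.reference_amplitude
    yy, xx = np.mgrid[:rows, :cols]
    carrier = 2.0 * np.pi * (fx * xx + fy * yy)
    return 1.0 + a**2 + 2.0 * a * np.cos(carrier - phase)


def render_hologram(phase: PhaseMap, cfg: OpticalConfig, rng_seed) -> Hologram:
    """Render a quantized, noisy off-axis hologram of a phase field.

    Additive Gaussian intensity noise (``noise_sigma``) precedes
    quantization to ``bit_depth`` levels over [0, (1+a)^2]. Deterministic
    given the seed.
    """
    intensity = interference_intensity(phase.phase_rad, cfg)
    if cfg.noise_sigma > 0:
        rng = np.random.default_rng(rng_seed)
        intensity = intensity + rng.normal(
            0.0, cfg.noise_sigma, size=intensity.shape
        )
    full_scale = (1.0 + cfg.reference_amplitude) ** 2
    levels = 2**cfg.bit_depth - 1
    dn = np.round(np.clip(intensity, 0.0, full_scale) / full_scale * levels)
    return Hologram(pixels=dn, wavelength_m=cfg.wavelength_m)


def simulate_spectrum(
    profile: RamanClassProfile,
    grid_cm1: np.ndarray | None = None,
    rng_seed=0,
    cell_id: str | None = None,
    class_label: str | None = None,
) -> RamanSpectrum:
    """Simulate one noisy spectrum from a class band profile.

    Sum of Gaussian bands + polynomial baseline + additive Gaussian
    noise, clipped at zero. Deterministic given the seed.
    """
    grid = default_grid() if grid_cm1 is None else np.asarray(grid_cm1, float)
    if grid[0] > 900.0 or grid[-1] < 1700.0:
        raise ValueError(
            f"grid [{grid[0]}, {grid[-1]}] must cover the fingerprint region "
            "[900, 1700] cm-1"
        )
    u = (grid - 1300.0) / 400.0
    intensity = np.polynomial.polynomial.polyval(u, np.asarray(profile.baseline))
    for c, h, w in zip(
        profile.peak_centers_cm1, profile.peak_heights, profile.peak_widths_cm1
    ):
        intensity = intensity + h * np.exp(-0.5 * ((grid - c) / w) ** 2)
    if profile.noise_sigma > 0:
        rng = np.random.default_rng(rng_seed)
        intensity = intensity + rng.normal(0.0, profile.noise_sigma, grid.shape)
    intensity = np.clip(intensity, 0.0, None)
    return RamanSpectrum(
        wavenumbers_cm1=grid,
        intensities=intensity,
        cell_id=cell_id,
        class_label=class_label,
    )


@dataclass(frozen=True)
class Cohort:
    """Paired holograms, spectra and labels for a synthetic cohort."""

    holograms: list[Hologram]
    spectra: list[RamanSpectrum]
    labels: list[str]
    phantoms: list[CellPhantom] = field(default_factory=list)
    phase_fields: list[PhaseMap] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.labels)


def make_cohort(
    n_per_class: tuple[int, int, int],
    cfg: OpticalConfig | None = None,
    seed: int = 0,
    morphology=None,
    profiles: dict[str, RamanClassProfile] | None = None,
    keep_phase_fields: bool = True,
) -> Cohort:
    """Generate a paired hologram + spectrum + label cohort.

    ``n_per_class`` follows the class order (CD4, BCELL, MONO); the
    default study-sized cohort is (60, 86, 67). Phantom centres are
    jittered uniformly within +-8 px of the field centre. All randomness
    splits deterministically from ``seed``.
    """
    if cfg is None:
        cfg = OpticalConfig()
    if profiles is None:
        profiles = DEFAULT_RAMAN_PROFILES
    if len(n_per_class) != len(CLASS_LABELS):
        raise ValueError("n_per_class must give one count per class")
    if any(n < 2 for n in n_per_class):
        raise ValueError(
            "need at least 2 cells per class (leave-one-out is undefined below that)"
        )
    rows, cols = cfg.detector_shape
    root = np.random.SeedSequence(seed)
    total = int(sum(n_per_class))
    streams = root.spawn(3 * total)

    holograms, spectra, labels, phantoms, fields = [], [], [], [], []
    cell = 0
    for label, n in zip(CLASS_LABELS, n_per_class):
        for _ in range(n):
            s_ph, s_holo, s_raman = streams[3 * cell : 3 * cell + 3]
            phantom = make_phantom(label, s_ph, morphology=morphology)
            jitter_rng = np.random.default_rng(s_ph.spawn(1)[0])
            dr, dc = jitter_rng.uniform(-8.0, 8.0, size=2)
            phantom = replace(
                phantom, center=((rows - 1) / 2.0 + dr, (cols - 1) / 2.0 + dc)
            )
            pf = render_phase_field(phantom, cfg.detector_shape)
            holograms.append(render_hologram(pf, cfg, s_holo))
            spectra.append(
                simulate_spectrum(
                    profiles[label],
                    rng_seed=s_raman,
                    cell_id=f"cell_{cell:04d}",
                    class_label=label,
                )
            )
            labels.append(label)
            phantoms.append(phantom)
            if keep_phase_fields:
                fields.append(pf)
            cell += 1
    return Cohort(
        holograms=holograms,
        spectra=spectra,
        labels=labels,
        phantoms=phantoms,
        phase_fields=fields,
    )
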