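"""File formats: TIFF holograms/phase maps, CSV spectra and manifests."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .raman import RamanSpectrum, read_spectrum_csv, write_spectrum_csv
from .reconstruct import Hologram, PhaseMap
from .synthetic import Cohort

__all__ = [
    "write_hologram_tiff",
    "read_hologram_tiff",
    "write_phase_tiff",
    "read_phase_tiff",
    "write_cohort",
    "read_spectrum_csv",
    "write_spectrum_csv",
]


def write_hologram_tiff(holo: Hologram, path) -> None:
    """Single-channel TIFF; 8/16-bit unsigned if the DN range allows."""
    px = holo.pixels
    if px.max() <= 255 and np.allclose(px, np.round(px)):
        data = px.astype(np.uint8)
    elif px.max() <= 65535 and np.allclose(px, np.round(px)):
        data = px.astype(np.uint16)
    else:
        data = px.astype(np.float32)
    tifffile.imwrite(path, data)


def read_hologram_tiff(path, wavelength_m: float = 532e-9) -> Hologram:
    return Hologram(
        pixels=tifffile.imread(path).astype(float), wavelength_m=wavelength_m
    )


def write_phase_tiff(pm: PhaseMap, path) -> None:
    """32-bit float TIFF plus a JSON sidecar with ROI/wavelength metadata."""
    path = Path(path)
    tifffile.imwrite(path, pm.phase_rad.astype(np.float32))
    sidecar = {
        "roi_origin": list(pm.roi_origin),
        "wavelength_m": pm.wavelength_m,
        "units": "radian",
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_phase_tiff(path) -> PhaseMap:
    path = Path(path)
    phase = tifffile.imread(path).astype(float)
    sidecar_path = path.with_suffix(".json")
    roi_origin, wavelength = (0, 0), None
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        roi_origin = tuple(sidecar.get("roi_origin", (0, 0)))
        wavelength = sidecar.get("wavelength_m")
    return PhaseMap(phase_rad=phase, roi_origin=roi_origin, wavelength_m=wavelength)


def write_cohort(cohort: Cohort, out_dir) -> pd.DataFrame:
    """Write holograms (TIFF), spectra (CSV) and the cohort manifest CSV."""
    out = Path(out_dir)
    (out / "holograms").mkdir(parents=True, exist_ok=True)
    (out / "spectra").mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (holo, spec, label) in enumerate(
        zip(cohort.holograms, cohort.spectra, cohort.labels)
    ):
        cell_id = spec.cell_id or f"cell_{i:04d}"
        holo_path = out / "holograms" / f"{cell_id}.tiff"
        spec_path = out / "spectra" / f"{cell_id}.csv"
        write_hologram_tiff(holo, holo_path)
        write_spectrum_csv(spec, spec_path)
        rows.append(
            {
                "cell_id": cell_id,
                "class": label,
                "hologram_path": str(holo_path.relative_to(out)),
                "spectrum_path": str(spec_path.relative_to(out)),
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "cohort.csv", index=False)
    return manifest
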