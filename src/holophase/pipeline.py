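"""End-to-end orchestration: generate -> reconstruct -> featurize -> classify.

Also embeds the published reference tables of the three-class immune-cell
discrimination experiment (Raman confusion matrix and per-technique
pairwise sensitivities/specificities) and recomputes every derived
metric from them, so the metric layer can be validated digit-for-digit
against the printed values.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, features, raman, reconstruct, synthetic

logger = logging.getLogger("holophase")

__all__ = [
    "RunConfig",
    "MODALITIES",
    "featurize_cohort",
    "run_pipeline",
    "validate_reference_metrics",
    "REFERENCE_RAMAN_CONFUSION",
    "REFERENCE_PAIRWISE_TABLE",
]

MODALITIES = ("RAMAN", "HIST", "TEXTURE4", "TEXTURE16", "HIST+TEXTURE4", "RAMAN+HIST")

# Published reference results for the CD4+ T cell / B cell / monocyte
# experiment: the Raman LOOCV confusion matrix (rows = actual,
# cols = predicted, class order CD4, BCELL, MONO) ...
REFERENCE_RAMAN_CONFUSION = np.array(
    [
        [46, 1, 1],
        [7, 69, 1],
        [1, 1, 51],
    ]
)

# ... and the printed pairwise sensitivity/specificity table (%) for
# each technique, pairs in the order (CD4 v BCELL), (CD4 v MONO),
# (BCELL v MONO).
REFERENCE_PAIRWISE_TABLE = {
    "raman": {"sens": (86.8, 97.9, 98.6), "spec": (98.6, 98.1, 98.1)},
    "histogram": {"sens": (93.8, 98.7, 100.0), "spec": (85.4, 100.0, 100.0)},
    "texture": {"sens": (78.0, 98.5, 100.0), "spec": (62.2, 97.0, 100.0)},
    "combined": {"sens": (81.3, 100.0, 98.6), "spec": (88.3, 100.0, 100.0)},
}

REFERENCE_AVERAGES = {
    "raman": (94.4, 98.3),
    "histogram": (97.5, 95.1),
    "texture": (92.2, 86.4),
    "combined": (93.3, 96.1),
}


@dataclass(frozen=True)
class RunConfig:
    """Fully serializable description of one pipeline run."""

    seed: int = 0
    n_per_class: tuple[int, int, int] = (60, 86, 67)
    optical: synthetic.OpticalConfig = field(default_factory=synthetic.OpticalConfig)
    n_hist_bins: int = 64
    glcm_levels: int = 8
    roi_size: int = 220
    pcs: dict = field(default_factory=dict)  # modality -> k override
    modalities: tuple[str, ...] = MODALITIES
    out_dir: str = "holophase_run"

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["optical"] = dataclasses.asdict(self.optical)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        optical = payload.pop("optical", {})
        optical["carrier_freq"] = tuple(optical.get("carrier_freq", (0.2, 0.2)))
        optical["detector_shape"] = tuple(optical.get("detector_shape", (512, 512)))
        payload["optical"] = synthetic.OpticalConfig(**optical)
        payload["n_per_class"] = tuple(payload.get("n_per_class", (60, 86, 67)))
        payload["modalities"] = tuple(payload.get("modalities", MODALITIES))
        return cls(**payload)


def featurize_cohort(
    phase_maps: list[reconstruct.PhaseMap],
    spectra: list[raman.RamanSpectrum],
    labels: list[str],
    n_hist_bins: int = 64,
    glcm_levels: int = 8,
    grid: np.ndarray | None = None,
    modalities: tuple[str, ...] = MODALITIES,
) -> dict[str, classify.LabeledDataset]:
    """Build one labeled descriptor matrix per requested modality.

    The histogram range is shared across the cohort (99.9th percentile
    of all positive phase values) so vectors are comparable; cross-family
    concatenations are block-normalized to unit sum per family.
    """
    n = len(labels)
    if not (len(phase_maps) == len(spectra) == n):
        raise ValueError("phase_maps, spectra and labels must be paired")
    cell_ids = [
        s.cell_id if s.cell_id is not None else f"cell_{i:04d}"
        for i, s in enumerate(spectra)
    ]
    positive = np.concatenate(
        [pm.phase_rad[pm.phase_rad > 0].ravel() for pm in phase_maps]
    )
    if positive.size == 0:
        raise ValueError("cohort contains no positive phase signal")
    range_max = float(np.percentile(positive, 99.9))

    hist = np.stack(
        [
            features.intensity_histogram(pm, n_hist_bins, range_max).counts.astype(float)
            for pm in phase_maps
        ]
    )
    need_t4 = any(m in modalities for m in ("TEXTURE4", "HIST+TEXTURE4"))
    t4 = (
        np.stack([features.texture_descriptor(pm, 4, glcm_levels) for pm in phase_maps])
        if need_t4
        else None
    )
    t16 = (
        np.stack([features.texture_descriptor(pm, 16, glcm_levels) for pm in phase_maps])
        if "TEXTURE16" in modalities
        else None
    )
    if grid is None:
        grid = raman.default_grid()
    normalized = [raman.crop_and_normalize(s) for s in spectra]
    raman_matrix = raman.resample_to_grid(normalized, grid)

    def _concat(block_a, prov_a, block_b, prov_b):
        rows = []
        for i in range(n):
            a = features.DescriptorVector(block_a[i], prov_a, cell_ids[i], labels[i])
            b = features.DescriptorVector(block_b[i], prov_b, cell_ids[i], labels[i])
            rows.append(features.concat_descriptor(a, b, block_norm=True).values)
        return np.stack(rows)

    builders = {
        "RAMAN": lambda: raman_matrix,
        "HIST": lambda: hist,
        "TEXTURE4": lambda: t4,
        "TEXTURE16": lambda: t16,
        "HIST+TEXTURE4": lambda: _concat(hist, "HIST", t4, "TEXTURE4"),
        "RAMAN+HIST": lambda: _concat(raman_matrix, "RAMAN", hist, "HIST"),
    }
    out = {}
    for modality in modalities:
        if modality not in builders:
            raise ValueError(f"unknown modality {modality!r}")
        out[modality] = classify.LabeledDataset(
            X=builders[modality](),
            y=tuple(labels),
            provenance=modality,
            classes=tuple(
                c for c in synthetic.CLASS_LABELS if c in labels
            ),
        )
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def reconstruct_cohort(
    cohort: synthetic.Cohort, params: reconstruct.ReconstructionParams | None = None
) -> list[reconstruct.PhaseMap]:
    """Reconstruct every hologram of a cohort into a cropped phase map."""
    return [reconstruct.reconstruct(h, params) for h in cohort.holograms]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and write all artifacts under out_dir.

    Returns the run manifest: config echo, per-modality metric summary
    and a checksummed list of every written file. Deterministic for a
    fixed config (byte-identical CSV outputs across runs).
    """
    out = Path(config.out_dir)
    results_dir = out / "results"
    results_dir.mkdir(parents=True, exist_ok=True)
    logger.info("run_pipeline: seed=%d n_per_class=%s", config.seed, config.n_per_class)
    config.to_yaml(out / "config.yaml")

    logger.info("stage generate: %d cells", sum(config.n_per_class))
    cohort = synthetic.make_cohort(
        config.n_per_class, cfg=config.optical, seed=config.seed
    )
    logger.info("stage reconstruct")
    params = reconstruct.ReconstructionParams(roi_size=config.roi_size)
    phase_maps = reconstruct_cohort(cohort, params)
    logger.info("stage featurize: %s", config.modalities)
    datasets = featurize_cohort(
        phase_maps,
        cohort.spectra,
        cohort.labels,
        n_hist_bins=config.n_hist_bins,
        glcm_levels=config.glcm_levels,
        modalities=config.modalities,
    )

    summary = {}
    for modality, data in datasets.items():
        k = config.pcs.get(modality)
        cm, metrics = classify.run_modality(data, modality, k=k)
        tag = modality.lower().replace("+", "_")
        pd.DataFrame(
            cm.counts, index=list(cm.classes), columns=list(cm.classes)
        ).to_csv(results_dir / f"{tag}_confusion.csv")
        rows = [
            {
                "pair": f"{a} v {b}",
                "sensitivity_pct": v["sensitivity_pct"],
                "specificity_pct": v["specificity_pct"],
            }
            for (a, b), v in metrics.pairs.items()
        ]
        rows.append(
            {
                "pair": "Average",
                "sensitivity_pct": metrics.average_sensitivity_pct,
                "specificity_pct": metrics.average_specificity_pct,
            }
        )
        pd.DataFrame(rows).to_csv(results_dir / f"{tag}_metrics.csv", index=False)
        model = classify.fit_pca(data.X, min(3, data.d, data.n - 1))
        scores = classify.project(model, data.X)
        score_df = pd.DataFrame(
            scores, columns=[f"PC{i + 1}" for i in range(scores.shape[1])]
        )
        score_df.insert(0, "class", list(data.y))
        score_df.to_csv(results_dir / f"{tag}_scores.csv", index=False)
        summary[modality] = {
            "average_sensitivity_pct": metrics.average_sensitivity_pct,
            "average_specificity_pct": metrics.average_specificity_pct,
            "confusion": cm.counts.tolist(),
        }
        logger.info(
            "modality %s: avg sens %.1f%%, avg spec %.1f%%",
            modality,
            metrics.average_sensitivity_pct,
            metrics.average_specificity_pct,
        )

    artifacts = sorted(p for p in out.rglob("*") if p.is_file() and p.name != "manifest.csv")
    manifest_rows = [
        {"artifact": str(p.relative_to(out)), "sha256": _sha256(p)} for p in artifacts
    ]
    pd.DataFrame(manifest_rows).to_csv(out / "manifest.csv", index=False)
    manifest = {
        "config": str(out / "config.yaml"),
        "modalities": summary,
        "artifacts": manifest_rows,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def validate_reference_metrics() -> dict:
    """Recompute every metric derivable from the embedded reference tables.

    Applies the pairwise sensitivity/specificity formulas to the
    reference Raman confusion matrix and the rounded-mean averaging rule
    to every technique column; reports computed vs expected per check.
    """
    report = {}
    cm = classify.ConfusionMatrix(
        counts=REFERENCE_RAMAN_CONFUSION, classes=("CD4", "BCELL", "MONO")
    )
    metrics = classify.pairwise_metrics(cm)
    pair_keys = [("CD4", "BCELL"), ("CD4", "MONO"), ("BCELL", "MONO")]
    for idx, key in enumerate(pair_keys):
        computed = metrics.pairs[key]
        expected_sens = REFERENCE_PAIRWISE_TABLE["raman"]["sens"][idx]
        expected_spec = REFERENCE_PAIRWISE_TABLE["raman"]["spec"][idx]
        report[f"raman_{key[0]}_v_{key[1]}"] = {
            "computed": (computed["sensitivity_pct"], computed["specificity_pct"]),
            "expected": (expected_sens, expected_spec),
            "pass": computed["sensitivity_pct"] == expected_sens
            and computed["specificity_pct"] == expected_spec,
        }
    report["raman_average"] = {
        "computed": (metrics.average_sensitivity_pct, metrics.average_specificity_pct),
        "expected": REFERENCE_AVERAGES["raman"],
        "pass": (metrics.average_sensitivity_pct, metrics.average_specificity_pct)
        == REFERENCE_AVERAGES["raman"],
    }
    for technique, cols in REFERENCE_PAIRWISE_TABLE.items():
        avg = tuple(
            classify.round_half_up(sum(vals) / len(vals)) for vals in (cols["sens"], cols["spec"])
        )
        report[f"{technique}_column_average"] = {
            "computed": avg,
            "expected": REFERENCE_AVERAGES[technique],
            "pass": avg == REFERENCE_AVERAGES[technique],
        }
    report["all_pass"] = all(
        v["pass"] for k, v in report.items() if isinstance(v, dict)
    )
    return report
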