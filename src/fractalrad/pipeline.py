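"""End-to-end orchestration: simulate → extract → select → classify → stats.

A :class:`PipelineConfig` bundles every stage's settings plus one global
seed; :func:`run_all` executes the stages in order and writes all outputs
(cohort manifest, feature CSV, importance ranking, classification report
JSON, group-statistics CSV, log) into a run directory together with a
copy of the config, so any run can be reproduced from its own output
directory.  The global seed fans out to per-stage seeds by fixed offsets;
the random-forest seed stays at its conventional fixed value (42) unless
overridden.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as _classify
from . import io as frio
from . import stats as _stats
from . import synthetic as _syn
from .classical import ExtractionConfig, extract_all
from .core import GrayImage, ROIMask

__all__ = [
    "PipelineConfig",
    "run_all",
    "extract_table",
    "load_external_cohort",
]

log = logging.getLogger("fractalrad")


@dataclass(frozen=True)
class PipelineConfig:
    """All stage settings of one reproducible run."""

    seed: int = 0
    out_dir: str = "fractalrad_run"
    # synthetic stage
    n_patients_per_class: int = 10
    images_per_patient: int = 5
    image_size_exponent: int = 6
    # extraction stage
    n_levels: int = 32
    families: tuple[str, ...] = ("fos", "glcm", "gldm", "glrlm", "glszm", "ngtdm", "fdta")
    fdta_levels: int = 3
    fdta_box_sizes: tuple[int, ...] = (2, 4, 8)
    # selection stage
    n_trees: int = 200
    forest_seed: int = 42
    k_max: int = 40
    # classification stage
    knn_k: int = 7
    holdout_fraction: float = 0.25
    grouping: str = "image"  # or "patient"
    # stats stage
    per_patient_stats: bool = False
    # optional external cohort (skips the synthetic stage)
    input_dir: str | None = None

    def extraction_config(self) -> ExtractionConfig:
        return ExtractionConfig(
            n_levels=self.n_levels,
            families=self.families,
            fdta_levels=self.fdta_levels,
            fdta_box_sizes=self.fdta_box_sizes,
        )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        data = json.loads(text)
        data["families"] = tuple(data["families"])
        data["fdta_box_sizes"] = tuple(data["fdta_box_sizes"])
        return cls(**data)


def load_external_cohort(directory: str | Path) -> list[_syn.LabeledSample]:
    """Load a cohort directory (NIfTI pairs + manifest.csv) written by
    :func:`fractalrad.synthetic.write_cohort` or following the same layout."""
    directory = Path(directory)
    manifest = directory / "manifest.csv"
    if not manifest.exists():
        raise FileNotFoundError(f"no manifest.csv in {directory}")
    df = frio.read_manifest(manifest)
    samples = []
    for _, row in df.iterrows():
        image = frio.read_gray_image(row["image_path"], id=row["sample_id"])
        mask = frio.read_nifti_mask(row["mask_path"])
        truth = _syn.ClassParams(
            hurst_target=float(row.get("hurst_target", 0.5)),
            intensity_sd=float(row.get("intensity_sd", 1.0)),
            gap_fraction=float(row.get("gap_fraction", 0.0)),
        )
        samples.append(
            _syn.LabeledSample(
                image=image,
                mask=mask,
                label=int(row["label"]),
                patient_id=str(row["patient_id"]),
                sample_id=str(row["sample_id"]),
                truth=truth,
            )
        )
    return samples


def extract_table(
    samples: list[_syn.LabeledSample], config: ExtractionConfig | None = None
) -> pd.DataFrame:
    """Feature table (one row per sample) with label and patient columns."""
    rows = []
    for s in samples:
        try:
            fv = extract_all(s.image, s.mask, config)
        except Exception as exc:
            raise RuntimeError(f"feature extraction failed for sample {s.sample_id}") from exc
        row = {"sample_id": s.sample_id, "patient_id": s.patient_id, "label": s.label}
        row.update(fv.as_dict())
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")


def run_all(config: PipelineConfig) -> Path:
    """Execute the full pipeline and return the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json())
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        if config.input_dir is not None:
            log.info("loading external cohort from %s", config.input_dir)
            samples = load_external_cohort(config.input_dir)
        else:
            log.info("simulating cohort (seed=%d)", config.seed)
            spec = _syn.CohortSpec(
                n_patients_per_class=config.n_patients_per_class,
                images_per_patient=config.images_per_patient,
                image_size_exponent=config.image_size_exponent,
                seed=config.seed,
            )
            samples = _syn.generate_cohort(spec)
            _syn.write_cohort(samples, out / "cohort")
        log.info("cohort: %d samples", len(samples))

        table = extract_table(samples, config.extraction_config())
        table.to_csv(out / "features.csv")
        meta = {
            "n_levels": config.n_levels,
            "families": list(config.families),
            "fdta_levels": config.fdta_levels,
            "fdta_box_sizes": list(config.fdta_box_sizes),
        }
        (out / "extraction_settings.json").write_text(json.dumps(meta, indent=2))
        labels = table["label"].to_numpy()
        patients = table["patient_id"].to_numpy()
        feats = table.drop(columns=["label", "patient_id"])
        log.info("extracted %d features per sample", feats.shape[1])

        ranking = _classify.rank_features(
            feats, labels, n_trees=config.n_trees, seed=config.forest_seed
        )
        pd.Series(ranking.scores).loc[ranking.order].rename("importance").to_csv(
            out / "ranking.csv", index_label="feature"
        )
        subset = _classify.select_top(ranking, config.k_max)
        log.info("selected top %d features", len(subset))

        report = _classify.evaluate(
            feats,
            labels,
            subset=subset,
            k=config.knn_k,
            holdout_fraction=config.holdout_fraction,
            split_seed=config.seed + 1,
            grouping=config.grouping,
            groups=patients if config.grouping == "patient" else None,
        )
        (out / "report.json").write_text(json.dumps(report.as_dict(), indent=2))
        log.info(
            "kNN holdout: accuracy=%.3f auc=%.3f cv_accuracy=%.3f",
            report.accuracy, report.auc, report.cv_accuracy,
        )

        comparisons, n_sig = _stats.summarize_all(
            feats, labels, per_patient_groups=patients if config.per_patient_stats else None
        )
        _stats.comparisons_to_frame(comparisons).to_csv(out / "stats.csv", index=False)
        log.info("%d of %d features significant at p < 0.05", n_sig, feats.shape[1])
    finally:
        log.removeHandler(handler)
        handler.close()
    return out
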