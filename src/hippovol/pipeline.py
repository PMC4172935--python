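"""The umbrella pipeline: segment -> volumetry -> hippocampus -> classify.

Consumes a directory of spatially normalized, skull-stripped coronal slice
PNGs plus a ``labels.csv`` (subject_id, class_label) as written by the
``simulate`` command — or any user-supplied preprocessed images of the same
layout — and produces the feature CSV, the cross-validation report and a
structured run log.  Deterministic under a fixed config and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as hio
from .classify import ClassifierConfig, EvaluationReport, FeatureTable, crossvalidate
from .errors import ValidationError
from .hippocampus import HippocampusConfig, hippocampus_pipeline
from .preprocess import SliceImage, ThreshRange, average_scans, estimate_thresh, segment_tissues
from .volumetry import tissue_volumes

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a pipeline run.

    ``thresh`` fixes the GM range globally; when None it is estimated per
    slice (three-class Otsu).  ``subset`` selects the feature configuration
    used for classification.
    """

    input_dir: str | Path
    output_dir: str | Path
    thresh: ThreshRange | None = None
    hippocampus: HippocampusConfig = field(default_factory=HippocampusConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    subset: str = "all"
    k: int = 10
    seed: int = 0
    save_intermediates: bool = False


def _load_subject(input_dir: Path, subject_id: str) -> SliceImage:
    """One slice per subject; repeat scans (``*_rep*.png``) are averaged."""
    reps = sorted(input_dir.glob(f"{subject_id}_rep*.png"))
    if reps:
        return average_scans([hio.read_slice_png(p) for p in reps])
    single = input_dir / f"{subject_id}.png"
    if not single.exists():
        raise ValidationError(f"no image found for subject {subject_id!r}")
    return hio.read_slice_png(single)


def extract_features(
    image: SliceImage,
    thresh: ThreshRange | None = None,
    hippo_config: HippocampusConfig | None = None,
) -> dict:
    """Per-subject feature vector from one slice.

    Segments tissues (estimating the GM range when not supplied), counts
    tissue pixels and runs the hippocampus chain for both sides.
    """
    t = thresh if thresh is not None else estimate_thresh(image)
    label_map = segment_tissues(image, t)
    vols = tissue_volumes([label_map])
    left, right = hippocampus_pipeline(image, t, hippo_config)
    return {
        "vol_gm": vols.vol_gm,
        "vol_wm": vols.vol_wm,
        "vol_csf": vols.vol_csf,
        "left_area": left.area,
        "right_area": right.area,
        "thresh_lo": t.lo,
        "thresh_hi": t.hi,
    }


def run_pipeline(config: PipelineConfig) -> tuple[pd.DataFrame, EvaluationReport]:
    """Run the full flow over a cohort directory.

    Writes ``features.csv``, ``report.json`` and ``run_log.json`` into the
    output directory; returns the feature frame and the evaluation report.
    Per-subject extraction failures are logged and the subject excluded.
    """
    input_dir = Path(config.input_dir)
    output_dir = Path(config.output_dir)
    if not input_dir.is_dir():
        raise ValidationError(f"input directory does not exist: {input_dir}")
    labels_path = input_dir / "labels.csv"
    if not labels_path.exists():
        raise ValidationError(f"missing labels table: {labels_path}")
    output_dir.mkdir(parents=True, exist_ok=True)

    labels = pd.read_csv(labels_path)
    if not {"subject_id", "class_label"} <= set(labels.columns):
        raise ValidationError("labels.csv needs subject_id and class_label columns")

    rows, excluded, warnings_log = [], [], []
    for rec in labels.to_dict("records"):
        sid = str(rec["subject_id"])
        try:
            image = _load_subject(input_dir, sid)
            feats = extract_features(image, config.thresh, config.hippocampus)
        except Exception as exc:  # noqa: BLE001 - exclusion policy per subject
            logger.warning("excluding subject %s: %s", sid, exc)
            excluded.append(sid)
            warnings_log.append(f"excluded {sid}: {exc}")
            continue
        rows.append({"subject_id": sid, **feats, "label": int(rec["class_label"])})

    if not rows:
        raise ValidationError("no subject could be processed")
    frame = pd.DataFrame(rows)
    hio.write_features_csv(frame, output_dir / "features.csv")

    table = FeatureTable(frame, subset=config.subset)
    report = crossvalidate(table, k=config.k, config=config.classifier, seed=config.seed)
    hio.write_json(report.to_dict(), output_dir / "report.json")
    hio.write_json(
        {
            "n_subjects": len(frame),
            "excluded": excluded,
            "warnings": warnings_log,
            "seed": config.seed,
            "k": report.k,
            "subset": config.subset,
            "thresh": None
            if config.thresh is None
            else {"lo": config.thresh.lo, "hi": config.thresh.hi},
            "opening_radius": config.hippocampus.opening_radius,
            "margin": config.hippocampus.margin,
        },
        output_dir / "run_log.json",
    )
    return frame, report
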