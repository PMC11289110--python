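"""End-to-end evaluation: catalog + predictions -> tidy metrics.

Glues the modules together the way the CLI and the analysis scripts use
them: for every image in a catalog, obtain a predicted mask (from a mask
directory or by running a backend), optionally postprocess it, rasterize
the ground-truth annotations, and compute pixel- and cyst-wise metrics,
zone attributions and the DT-pair IoU distribution.
"""

from __future__ import annotations

from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .io import DatasetCatalog, ImageRecord, connected_components, rasterize, read_mask
from .metrics import (
    CystConfusion,
    DtIouDistribution,
    MatchConfig,
    ZoneConfig,
    dt_iou_distribution,
    match_cysts,
    pixel_confusion,
    zone_attribution,
)
from .postprocessing import MorphConfig, fill_holes, morphology
from .preprocessing import normalize, remove_green
from .segmentation import binarize, predict_image
from .evaluation import records_to_frame

__all__ = ["EvaluationResult", "mask_dir_predictions", "backend_predictions", "evaluate_catalog"]


class EvaluationResult:
    """Per-image records plus pooled zone and IoU-distribution summaries."""

    def __init__(self, records: pd.DataFrame, per_zone: dict[int, CystConfusion],
                 iou_distribution: DtIouDistribution):
        self.records = records
        self.per_zone = per_zone
        self.iou_distribution = iou_distribution


def mask_dir_predictions(mask_dir: str | Path) -> Callable[[DatasetCatalog, ImageRecord], np.ndarray]:
    """Prediction source reading ``<mask_dir>/<image_id>.png`` files."""
    mask_dir = Path(mask_dir)

    def get(catalog: DatasetCatalog, record: ImageRecord) -> np.ndarray:
        path = mask_dir / f"{record.image_id}.png"
        if not path.exists():
            raise FileNotFoundError(f"no predicted mask for {record.image_id}: {path}")
        return read_mask(path)

    return get


def backend_predictions(backend, threshold: float = 0.5,
                        preprocess_input: bool = True) -> Callable:
    """Prediction source running a segmentation backend on each image.

    Applies the evaluation-time preprocessing (green muting +
    normalization, no augmentation) unless ``preprocess_input`` is False.
    """

    def get(catalog: DatasetCatalog, record: ImageRecord) -> np.ndarray:
        image = catalog.load_image(record)
        if preprocess_input:
            image = normalize(remove_green(image))
        return binarize(predict_image(backend, image), threshold)

    return get


def evaluate_catalog(
    catalog: DatasetCatalog,
    get_prediction: Callable[[DatasetCatalog, ImageRecord], np.ndarray],
    morph_config: MorphConfig | None = None,
    match_config: MatchConfig | None = None,
    zone_config: ZoneConfig | None = None,
    fill: bool = True,
    connectivity: int = 8,
    image_shape: tuple[int, int] | None = None,
) -> EvaluationResult:
    """Evaluate predictions against rasterized annotations for a catalog.

    ``image_shape`` (height, width) avoids reading each image when all
    images share one size; otherwise shapes are taken from the images.
    Hole filling runs on every prediction (cysts contain no holes);
    ``morph_config`` adds optional opening/closing.
    """
    zone_config = zone_config or ZoneConfig()
    per_zone: dict[int, CystConfusion] = {
        z: CystConfusion(0, 0, 0) for z in range(1, zone_config.n_zones + 1)
    }
    confusions = []
    rows = []
    for record in catalog:
        pred = np.asarray(get_prediction(catalog, record)).astype(bool)
        if fill:
            pred = fill_holes(pred)
        if morph_config is not None:
            pred = morphology(pred, morph_config)
        if image_shape is not None and pred.shape != image_shape:
            raise ValueError(
                f"{record.image_id}: prediction shape {pred.shape} != {image_shape}"
            )
        annotations = catalog.load_annotations(record)
        gt = rasterize(annotations, width=pred.shape[1], height=pred.shape[0])
        pc = pixel_confusion(pred, gt)
        pred_lc = connected_components(pred, connectivity)
        gt_lc = connected_components(gt, connectivity)
        cc = match_cysts(pred_lc, gt_lc, match_config)
        confusions.append(cc)
        for z, zc in zone_attribution(cc, pred_lc, gt_lc, zone_config).items():
            per_zone[z] = CystConfusion(
                per_zone[z].dt + zc.dt, per_zone[z].ms + zc.ms, per_zone[z].wr + zc.wr
            )
        rows.append({
            "image_id": record.image_id,
            "experiment_id": record.experiment_id,
            "treatment_id": record.treatment_id,
            "tubule_id": record.tubule_id,
            "pixel": pc,
            "cyst": cc,
        })
    records = records_to_frame(rows)
    return EvaluationResult(records=records, per_zone=per_zone,
                            iou_distribution=dt_iou_distribution(confusions))
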