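"""Cross-validation folds and metric aggregation.

Images from the same engineered tubule are strongly correlated, so the
tubule is the unit of cross-validation: LOTO (Leave One Tubule Out)
builds one fold per tubule, testing on all of that tubule's images and
splitting the remaining tubules 80/20 into train and validation sets —
at tubule level, never image level, so no tubule leaks across splits.

Aggregation is micro within a group (confusion counts are summed and the
metrics recomputed from the sums, which keeps images with few cysts from
dominating) and macro across groups (mean with a 95% normal-approximation
confidence half-width).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import DatasetCatalog
from .metrics import CystConfusion, PixelConfusion, cyst_metrics, pixel_metrics

__all__ = [
    "LotoFold",
    "build_loto_folds",
    "records_to_frame",
    "aggregate",
    "summarize_groups",
    "treatment_report",
    "metric_spread",
]

TubuleKey = tuple[str, str, str]

METRIC_COLUMNS = ["iou", "precision", "recall", "iou_cyst", "precision_cyst", "recall_cyst"]
COUNT_COLUMNS = ["tp", "fp", "fn", "dt", "ms", "wr"]


@dataclass(frozen=True)
class LotoFold:
    """One leave-one-tubule-out fold (tubule keys, not image ids)."""

    test: TubuleKey
    train: tuple[TubuleKey, ...]
    val: tuple[TubuleKey, ...]


def build_loto_folds(
    catalog: DatasetCatalog,
    val_fraction: float = 0.2,
    seed: int = 0,
) -> list[LotoFold]:
    """One fold per tubule; remaining tubules split ~80/20 train/val.

    The validation count is ceil(val_fraction * n_rest), at least 1.
    Fold construction is reproducible under the seed and invariant to
    catalog row order (tubule keys are sorted before shuffling).
    """
    tubules = catalog.tubule_keys()
    if len(tubules) < 3:
        raise ValueError(f"need at least 3 tubules for LOTO folds, got {len(tubules)}")
    if not 0.0 < val_fraction < 1.0:
        raise ValueError("val_fraction must be in (0, 1)")
    folds = []
    for i, test in enumerate(tubules):
        rest = [t for t in tubules if t != test]
        rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        order = rng.permutation(len(rest))
        n_val = max(1, math.ceil(val_fraction * len(rest)))
        val = tuple(sorted(rest[j] for j in order[:n_val]))
        train = tuple(sorted(rest[j] for j in order[n_val:]))
        folds.append(LotoFold(test=test, train=train, val=val))
    return folds


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def records_to_frame(records: list[dict]) -> pd.DataFrame:
    """Tidy per-image frame from dicts carrying keys + confusion objects.

    Each dict must have ``image_id``, grouping keys, and either confusion
    objects under ``pixel``/``cyst`` or raw tp/fp/fn/dt/ms/wr counts.
    """
    rows = []
    for rec in records:
        row = {k: v for k, v in rec.items() if k not in ("pixel", "cyst")}
        pix = rec.get("pixel")
        if isinstance(pix, PixelConfusion):
            row.update(tp=pix.tp, fp=pix.fp, fn=pix.fn)
        cyst = rec.get("cyst")
        if isinstance(cyst, CystConfusion):
            row.update(dt=cyst.dt, ms=cyst.ms, wr=cyst.wr)
        rows.append(row)
    df = pd.DataFrame(rows)
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"records are missing count columns: {missing}")
    return df


def _metrics_from_counts(row) -> dict[str, float]:
    iou, pr, re = pixel_metrics(
        PixelConfusion(int(row["tp"]), int(row["fp"]), int(row["fn"])))
    iou_c, pr_c, re_c = cyst_metrics(
        CystConfusion(int(row["dt"]), int(row["ms"]), int(row["wr"])))
    return {"iou": iou, "precision": pr, "recall": re,
            "iou_cyst": iou_c, "precision_cyst": pr_c, "recall_cyst": re_c}


def aggregate(records: pd.DataFrame, by: str | list[str]) -> pd.DataFrame:
    """Micro-aggregate confusion counts per group and recompute metrics.

    Returns one row per group with the summed counts and the six metrics;
    groups with no member rows simply do not appear.
    """
    by = [by] if isinstance(by, str) else list(by)
    missing = [c for c in by + COUNT_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records frame is missing columns: {missing}")
    grouped = records.groupby(by, as_index=False)[COUNT_COLUMNS].sum()
    metrics = grouped.apply(_metrics_from_counts, axis=1, result_type="expand")
    return pd.concat([grouped, metrics], axis=1)


def summarize_groups(per_group: pd.DataFrame) -> pd.DataFrame:
    """Macro summary across groups: mean and 95% CI half-width per metric.

    Undefined (NaN) group metrics are excluded from the mean; the
    half-width is 1.96 * sd / sqrt(n) over the defined groups (0 when a
    single group defines the metric).
    """
    rows = []
    for metric in METRIC_COLUMNS:
        vals = per_group[metric].dropna().to_numpy()
        if len(vals) == 0:
            rows.append({"metric": metric, "mean": math.nan,
                         "ci95_half_width": math.nan, "n_groups": 0})
            continue
        half = 1.96 * vals.std(ddof=1) / math.sqrt(len(vals)) if len(vals) > 1 else 0.0
        rows.append({"metric": metric, "mean": float(vals.mean()),
                     "ci95_half_width": float(half), "n_groups": len(vals)})
    return pd.DataFrame(rows)


def treatment_report(records: pd.DataFrame) -> pd.DataFrame:
    """Six metrics per treatment (micro within treatment)."""
    return aggregate(records, by="treatment_id")


def metric_spread(per_group: pd.DataFrame) -> dict[str, float]:
    """Max pairwise difference (max - min) per metric across groups.

    Used for the treatment-invariance check: a robust model shows a small
    spread of each metric across treatments.
    """
    out = {}
    for metric in METRIC_COLUMNS:
        vals = per_group[metric].dropna().to_numpy()
        out[metric] = float(vals.max() - vals.min()) if len(vals) else math.nan
    return out
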