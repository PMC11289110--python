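"""Pixel-wise and cyst-wise segmentation metrics.

Pixel-wise IoU/precision/recall come from per-pixel TP/FP/FN counts.
Cyst-wise metrics lift the same formulas to the object level: connected
components of the predicted and ground-truth masks are resolved into

* DT (detected) — a ground-truth cyst matched one-to-one to a prediction,
* MS (missed)   — a ground-truth cyst with no matched prediction,
* WR (wrong)    — a predicted cyst with no matched ground truth,

under the multi-overlap rules: several predictions overlapping one
ground-truth cyst count as one DT plus WR for the rest; one prediction
overlapping N ground-truth cysts counts as one DT plus N-1 MS.  The
default detection rule is any overlap of at least one pixel; an IoU
threshold tau is available to study stricter notions of detection.

Cyst-wise IoU = DT/(DT+MS+WR), Pr = DT/(DT+WR), Re = DT/(DT+MS).

Object-level performance is stratified into six equal-cardinality size
zones of the cyst-area distribution (areas in um^2); the defaults are
the published boundaries 34.7 / 53.3 / 78.7 / 120.9 / 207.5 um^2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import LabeledComponents, as_bool_mask, connected_components

__all__ = [
    "PixelConfusion",
    "MatchedPair",
    "CystConfusion",
    "MetricsRecord",
    "MatchConfig",
    "ZoneConfig",
    "DEFAULT_ZONE_BOUNDARIES_UM2",
    "pixel_confusion",
    "pixel_metrics",
    "match_cysts",
    "cyst_metrics",
    "compute_metrics",
    "assign_zone",
    "zone_attribution",
    "compute_zone_boundaries",
    "DtIouDistribution",
    "dt_iou_distribution",
]

DEFAULT_ZONE_BOUNDARIES_UM2 = (34.7, 53.3, 78.7, 120.9, 207.5)


# ---------------------------------------------------------------------------
# Confusion containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PixelConfusion:
    """Per-pixel true positives, false positives, false negatives."""

    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other: "PixelConfusion") -> "PixelConfusion":
        return PixelConfusion(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


@dataclass(frozen=True)
class MatchedPair:
    """A matched (predicted, ground-truth) component pair."""

    pred_id: int
    gt_id: int
    iou: float
    intersection: int


@dataclass(frozen=True)
class CystConfusion:
    """Object-level DT/MS/WR counts with the matched pairs behind DT."""

    dt: int
    ms: int
    wr: int
    pairs: tuple[MatchedPair, ...] = ()

    def __post_init__(self) -> None:
        if min(self.dt, self.ms, self.wr) < 0:
            raise ValueError("DT/MS/WR must be non-negative")
        if self.pairs and len(self.pairs) != self.dt:
            raise ValueError("DT must equal the number of matched pairs")

    def __add__(self, other: "CystConfusion") -> "CystConfusion":
        return CystConfusion(self.dt + other.dt, self.ms + other.ms,
                             self.wr + other.wr, self.pairs + other.pairs)


@dataclass(frozen=True)
class MetricsRecord:
    """The six metrics plus the confusions they were computed from.

    Undefined metrics (zero denominator) are NaN and are excluded from
    aggregation rather than coerced to 0 or 1.
    """

    iou: float
    precision: float
    recall: float
    iou_cyst: float
    precision_cyst: float
    recall_cyst: float
    pixel: PixelConfusion
    cyst: CystConfusion

    def as_dict(self) -> dict[str, float]:
        return {
            "iou": self.iou, "precision": self.precision, "recall": self.recall,
            "iou_cyst": self.iou_cyst, "precision_cyst": self.precision_cyst,
            "recall_cyst": self.recall_cyst,
        }


# ---------------------------------------------------------------------------
# Pixel-wise
# ---------------------------------------------------------------------------

def pixel_confusion(pred: np.ndarray, gt: np.ndarray) -> PixelConfusion:
    """Count TP/FP/FN pixels between a predicted and a ground-truth mask."""
    pred = as_bool_mask(pred)
    gt = as_bool_mask(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    tp = int(np.count_nonzero(pred & gt))
    fp = int(np.count_nonzero(pred & ~gt))
    fn = int(np.count_nonzero(~pred & gt))
    return PixelConfusion(tp, fp, fn)


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def pixel_metrics(confusion: PixelConfusion) -> tuple[float, float, float]:
    """(IoU, precision, recall) from pixel counts; NaN when undefined."""
    tp, fp, fn = confusion.tp, confusion.fp, confusion.fn
    return (_ratio(tp, tp + fn + fp), _ratio(tp, tp + fp), _ratio(tp, tp + fn))


# ---------------------------------------------------------------------------
# Cyst-wise matching
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MatchConfig:
    """Detection rule for the object-level matching.

    ``tau = 0`` (default) means any overlap of at least one pixel counts;
    ``tau > 0`` requires the pairwise pixel IoU to exceed tau.
    """

    tau: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.tau < 1.0:
            raise ValueError(f"tau must be in [0, 1), got {self.tau}")


def _overlap_table(pred: LabeledComponents, gt: LabeledComponents) -> np.ndarray:
    """(n_pred + 1, n_gt + 1) pixel-intersection counts, index 0 = background."""
    np_, ng = pred.n_components, gt.n_components
    joint = pred.labels.astype(np.int64) * (ng + 1) + gt.labels
    counts = np.bincount(joint.ravel(), minlength=(np_ + 1) * (ng + 1))
    return counts.reshape(np_ + 1, ng + 1)


def match_cysts(
    pred: LabeledComponents | np.ndarray,
    gt: LabeledComponents | np.ndarray,
    config: MatchConfig | None = None,
) -> CystConfusion:
    """Resolve predicted vs ground-truth components into DT/MS/WR.

    A one-to-one pairing is built greedily over all candidate pairs that
    satisfy the detection rule, in descending pairwise pixel IoU (ties
    broken by larger intersection, then lower component ids).  Matched
    pairs are DT; leftover ground-truth components are MS and leftover
    predictions WR, which reproduces the one-DT-rest-WR / one-DT-rest-MS
    resolution of multiple overlaps.
    """
    if isinstance(pred, np.ndarray):
        pred = connected_components(pred)
    if isinstance(gt, np.ndarray):
        gt = connected_components(gt)
    if pred.labels.shape != gt.labels.shape:
        raise ValueError("pred and gt masks must share shape")
    config = config or MatchConfig()

    inter = _overlap_table(pred, gt)
    candidates: list[tuple[float, int, int, int]] = []
    pred_ids, gt_ids = np.nonzero(inter[1:, 1:])
    for pi, gi in zip(pred_ids + 1, gt_ids + 1):
        overlap = int(inter[pi, gi])
        union = int(pred.areas[pi - 1] + gt.areas[gi - 1] - overlap)
        iou = overlap / union
        if overlap >= 1 and iou > config.tau:
            candidates.append((iou, overlap, int(pi), int(gi)))
    # descending IoU, then descending intersection, then ascending ids
    candidates.sort(key=lambda c: (-c[0], -c[1], c[2], c[3]))

    used_pred: set[int] = set()
    used_gt: set[int] = set()
    pairs: list[MatchedPair] = []
    for iou, overlap, pi, gi in candidates:
        if pi in used_pred or gi in used_gt:
            continue
        used_pred.add(pi)
        used_gt.add(gi)
        pairs.append(MatchedPair(pred_id=pi, gt_id=gi, iou=iou, intersection=overlap))

    dt = len(pairs)
    ms = gt.n_components - dt
    wr = pred.n_components - dt
    return CystConfusion(dt=dt, ms=ms, wr=wr, pairs=tuple(pairs))


def cyst_metrics(confusion: CystConfusion) -> tuple[float, float, float]:
    """(IoU_cyst, Pr_cyst, Re_cyst); NaN when a denominator is zero."""
    dt, ms, wr = confusion.dt, confusion.ms, confusion.wr
    return (_ratio(dt, dt + ms + wr), _ratio(dt, dt + wr), _ratio(dt, dt + ms))


def compute_metrics(
    pred: np.ndarray,
    gt: np.ndarray,
    match_config: MatchConfig | None = None,
    connectivity: int = 8,
) -> MetricsRecord:
    """All six metrics for one (prediction, ground truth) mask pair."""
    pc = pixel_confusion(pred, gt)
    cc = match_cysts(
        connected_components(pred, connectivity),
        connected_components(gt, connectivity),
        match_config,
    )
    iou, pr, re = pixel_metrics(pc)
    iou_c, pr_c, re_c = cyst_metrics(cc)
    return MetricsRecord(iou=iou, precision=pr, recall=re, iou_cyst=iou_c,
                         precision_cyst=pr_c, recall_cyst=re_c, pixel=pc, cyst=cc)


# ---------------------------------------------------------------------------
# Size zones
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ZoneConfig:
    """Cyst-area stratification into len(boundaries) + 1 zones.

    Zones are left-closed/right-open on the ascending boundary list; the
    last zone is unbounded above.  Areas are in um^2 and pixel areas are
    converted through ``microns_per_pixel``.
    """

    boundaries: tuple[float, ...] = DEFAULT_ZONE_BOUNDARIES_UM2
    microns_per_pixel: float = 0.5

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        if b.ndim != 1 or len(b) == 0 or np.any(np.diff(b) <= 0):
            raise ValueError("boundaries must be a non-empty strictly ascending sequence")
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be positive")

    @property
    def n_zones(self) -> int:
        return len(self.boundaries) + 1

    def area_px_to_um2(self, area_px: float) -> float:
        return float(area_px) * self.microns_per_pixel ** 2


def assign_zone(area_um2: float, config: ZoneConfig | None = None) -> int:
    """Zone index 1..n for a cyst area in um^2 (left-closed intervals)."""
    config = config or ZoneConfig()
    if area_um2 <= 0:
        raise ValueError(f"area must be positive, got {area_um2}")
    return int(np.searchsorted(np.asarray(config.boundaries), area_um2, side="right")) + 1


def zone_attribution(
    confusion: CystConfusion,
    pred: LabeledComponents,
    gt: LabeledComponents,
    zones: ZoneConfig | None = None,
) -> dict[int, CystConfusion]:
    """Split DT/MS/WR counts into size zones.

    The actual (ground-truth) size places DT and MS cysts; the predicted
    size places WR cysts, since a wrong prediction has no ground-truth
    counterpart.  Per-zone counts sum to the global counts.
    """
    zones = zones or ZoneConfig()
    per_zone = {z: [0, 0, 0] for z in range(1, zones.n_zones + 1)}
    matched_gt = {p.gt_id for p in confusion.pairs}
    matched_pred = {p.pred_id for p in confusion.pairs}
    for p in confusion.pairs:
        z = assign_zone(zones.area_px_to_um2(gt.areas[p.gt_id - 1]), zones)
        per_zone[z][0] += 1
    for gid in range(1, gt.n_components + 1):
        if gid not in matched_gt:
            z = assign_zone(zones.area_px_to_um2(gt.areas[gid - 1]), zones)
            per_zone[z][1] += 1
    for pid in range(1, pred.n_components + 1):
        if pid not in matched_pred:
            z = assign_zone(zones.area_px_to_um2(pred.areas[pid - 1]), zones)
            per_zone[z][2] += 1
    return {
        z: CystConfusion(dt=v[0], ms=v[1], wr=v[2]) for z, v in per_zone.items()
    }


def compute_zone_boundaries(areas_um2, n_zones: int = 6) -> tuple[float, ...]:
    """Equal-cardinality zone boundaries: the k/n quantiles, k = 1..n-1.

    The induced left-closed zones differ in count by at most one on the
    input sample.  Degenerate samples (ties collapsing boundaries) are
    flagged with a warning.
    """
    areas = np.asarray(list(areas_um2), dtype=float)
    if n_zones < 1:
        raise ValueError("n_zones must be >= 1")
    if len(areas) < n_zones:
        raise ValueError(f"need at least {n_zones} areas, got {len(areas)}")
    qs = np.arange(1, n_zones) / n_zones
    boundaries = np.quantile(areas, qs)
    if np.any(np.diff(boundaries) <= 0):
        warnings.warn(
            "tied areas collapse one or more zone boundaries; zones will not "
            "have equal cardinality",
            stacklevel=2,
        )
    return tuple(float(b) for b in boundaries)


# ---------------------------------------------------------------------------
# DT-pair IoU distribution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DtIouDistribution:
    """Sorted IoUs of all matched (DT) pairs, with exceedance queries."""

    ious: tuple[float, ...]

    def fraction_above(self, threshold: float) -> float:
        if not self.ious:
            return math.nan
        return float(np.mean(np.asarray(self.ious) > threshold))


def dt_iou_distribution(confusions) -> DtIouDistribution:
    """Pool matched-pair IoUs from many images into one distribution."""
    ious = sorted(p.iou for c in confusions for p in c.pairs)
    return DtIouDistribution(ious=tuple(ious))
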