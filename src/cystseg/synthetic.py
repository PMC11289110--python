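"""Synthetic fluorescence scenes with exact ground truth.

The generator emulates what an annotator sees in an engineered-tubule
acquisition: a red tissue band (the tubule), point-like blue nuclei that
crowd around cyst rims, dark globular cyst lumens inside the band, and a
green channel that carries only noise.  Cysts are mildly rotated
ellipses; their areas follow a long-tailed log-normal distribution
(median ~78 um^2, range ~30-2000 um^2) and their count per image a
truncated Poisson with median 4, matching the statistics of real
engineered-tubule datasets.

The perturber turns a ground-truth mask into a "prediction" with a known
log of drops, splits, spurious blobs and boundary jitter, so that the
object-level DT/MS/WR outcome is known by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .io import (
    AnnotationSet,
    DatasetCatalog,
    ImageRecord,
    connected_components,
    rasterize,
    save_labelme,
    write_image,
    write_mask,
)

__all__ = [
    "CystGeometry",
    "SceneConfig",
    "SyntheticScene",
    "PerturbConfig",
    "PerturbationLog",
    "CystPlacementError",
    "generate_scene",
    "perturb_mask",
    "write_dataset",
]


class CystPlacementError(RuntimeError):
    """Raised when the requested number of cysts cannot be placed."""

    def __init__(self, requested: int, achieved: int):
        self.requested = requested
        self.achieved = achieved
        super().__init__(
            f"could only place {achieved} of {requested} requested cysts; "
            "reduce n_cysts or enlarge the canvas"
        )


@dataclass(frozen=True)
class CystGeometry:
    """An elliptical cyst lumen: center (x, y), semi-axes (a, b), rotation."""

    center: tuple[float, float]
    axes: tuple[float, float]
    rotation: float  # radians, counter-clockwise

    @property
    def area_px(self) -> float:
        return math.pi * self.axes[0] * self.axes[1]

    def polygon(self, n_vertices: int = 64) -> np.ndarray:
        """Dense polygon approximation in Labelme (x, y) convention."""
        t = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
        a, b = self.axes
        c, s = math.cos(self.rotation), math.sin(self.rotation)
        x = self.center[0] + a * np.cos(t) * c - b * np.sin(t) * s
        y = self.center[1] + a * np.cos(t) * s + b * np.sin(t) * c
        return np.column_stack([x, y])


@dataclass(frozen=True)
class SceneConfig:
    """Generator parameters; identical config + seed gives identical scenes.

    ``n_cysts`` may be a fixed integer or None, in which case the count is
    drawn from a Poisson(4) truncated at ``max_cysts``.  Areas are
    log-normal in um^2 with the configured median, clipped to
    [area_min_um2, area_max_um2], and converted to pixels through
    ``microns_per_pixel``.
    """

    width: int = 256
    height: int = 256
    n_cysts: int | None = None
    cysts_per_image_mean: float = 4.0
    max_cysts: int = 12
    area_median_um2: float = 78.0
    area_sigma_log: float = 0.85
    area_min_um2: float = 30.0
    area_max_um2: float = 2000.0
    microns_per_pixel: float = 0.5
    aspect_max: float = 1.8
    placement_margin: float = 8.0
    nuclei_density: float = 0.0015  # nuclei per tissue pixel
    tissue_intensity: float = 180.0
    lumen_intensity: float = 25.0
    green_noise: float = 30.0
    seed: int = 0


@dataclass(frozen=True)
class SyntheticScene:
    """Generator output: image, exact mask, geometry, and provenance."""

    image: np.ndarray  # (H, W, 3) uint8
    gt_mask: np.ndarray  # (H, W) bool
    cyst_geometries: tuple[CystGeometry, ...]
    config: SceneConfig

    def annotation_set(self, image_id: str = "scene") -> AnnotationSet:
        polys = tuple(g.polygon() for g in self.cyst_geometries)
        return AnnotationSet(image_id=image_id, polygons=polys,
                             labels=("cyst",) * len(polys))


def _band_center(cols: np.ndarray, config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    phase = rng.uniform(0.0, 2.0 * math.pi)
    amp = 0.05 * config.height
    return config.height / 2.0 + amp * np.sin(2.0 * math.pi * cols / config.width + phase)


def _sample_geometry(config: SceneConfig, rng: np.random.Generator,
                     area_px: float | None = None) -> tuple[float, float, float]:
    """Sample (a, b, rotation) for one cyst."""
    if area_px is None:
        mu = math.log(config.area_median_um2)
        area_um2 = float(np.clip(rng.lognormal(mu, config.area_sigma_log),
                                 config.area_min_um2, config.area_max_um2))
        area_px = area_um2 / config.microns_per_pixel ** 2
    aspect = rng.uniform(1.0, config.aspect_max)
    a = math.sqrt(area_px * aspect / math.pi)
    b = math.sqrt(area_px / (aspect * math.pi))
    return a, b, rng.uniform(0.0, math.pi)


def _place_cysts(config: SceneConfig, rng: np.random.Generator,
                 n_cysts: int, band_center: np.ndarray,
                 band_half: float, strict: bool = True) -> list[CystGeometry]:
    placed: list[CystGeometry] = []
    max_attempts = 200
    for _ in range(n_cysts):
        ok = False
        for _attempt in range(max_attempts):
            a, b, rot = _sample_geometry(config, rng)
            margin = a + 2.0
            if margin >= config.width - margin:
                continue  # cyst larger than the canvas allows; resample
            cx = rng.uniform(margin, config.width - margin)
            cy_center = float(np.interp(cx, np.arange(config.width), band_center))
            lo = cy_center - band_half + margin
            hi = cy_center + band_half - margin
            if hi <= lo:
                continue
            cy = rng.uniform(lo, hi)
            if all(
                math.hypot(cx - g.center[0], cy - g.center[1])
                > a + max(g.axes) + config.placement_margin
                for g in placed
            ):
                placed.append(CystGeometry((cx, cy), (a, b), rot))
                ok = True
                break
        if not ok:
            if strict:
                raise CystPlacementError(requested=n_cysts, achieved=len(placed))
            break  # sampled count: settle for what fits on this canvas
    return placed


def _stamp_points(canvas: np.ndarray, xs: np.ndarray, ys: np.ndarray,
                  amplitude: float, radius: int = 2) -> None:
    """Add Gaussian blobs (nuclei) at the given (x, y) positions in place."""
    h, w = canvas.shape
    g = np.arange(-radius, radius + 1)
    stamp = amplitude * np.exp(-(g[:, None] ** 2 + g[None, :] ** 2) / (radius * 0.9) ** 2)
    for x, y in zip(xs, ys):
        r, c = int(round(y)), int(round(x))
        r0, r1 = max(r - radius, 0), min(r + radius + 1, h)
        c0, c1 = max(c - radius, 0), min(c + radius + 1, w)
        if r0 >= r1 or c0 >= c1:
            continue
        canvas[r0:r1, c0:c1] += stamp[r0 - (r - radius):r1 - (r - radius),
                                      c0 - (c - radius):c1 - (c - radius)]


def generate_scene(config: SceneConfig) -> SyntheticScene:
    """Render one synthetic tubule acquisition with exact ground truth.

    The ground-truth mask is the rasterization of the cyst polygons, so
    the scene is consistent with what flows through the annotation
    readers.  Raises :class:`CystPlacementError` when a requested cyst
    count cannot be placed within a bounded number of attempts (the
    exception reports the achieved count).
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.height, config.width
    cols = np.arange(w)
    band_center = _band_center(cols, config, rng)
    band_half = 0.30 * h

    strict = config.n_cysts is not None
    if strict:
        n_cysts = int(config.n_cysts)
    else:
        n_cysts = int(min(rng.poisson(config.cysts_per_image_mean), config.max_cysts))

    cysts = _place_cysts(config, rng, n_cysts, band_center, band_half, strict=strict)
    annotations = AnnotationSet("scene", tuple(g.polygon() for g in cysts),
                                ("cyst",) * len(cysts))
    gt_mask = rasterize(annotations, w, h)

    rr = np.arange(h)[:, None].astype(float)
    tissue = np.abs(rr - band_center[None, :]) <= band_half

    red = np.full((h, w), 14.0) + rng.normal(0.0, 4.0, (h, w))
    red[tissue] = config.tissue_intensity * (1.0 + 0.10 * rng.normal(size=int(tissue.sum())))
    red[gt_mask] = config.lumen_intensity + rng.normal(0.0, 4.0, int(gt_mask.sum()))

    blue = np.full((h, w), 8.0) + rng.normal(0.0, 3.0, (h, w))
    n_nuclei = rng.poisson(config.nuclei_density * float(tissue.sum()))
    if n_nuclei > 0:
        t_rows, t_cols = np.nonzero(tissue)
        idx = rng.integers(0, len(t_rows), n_nuclei)
        _stamp_points(blue, t_cols[idx].astype(float), t_rows[idx].astype(float),
                      amplitude=190.0)
    for g in cysts:
        # nuclei ring hugging the lumen rim
        n_rim = max(8, int(0.8 * math.pi * (g.axes[0] + g.axes[1])))
        t = rng.uniform(0.0, 2.0 * math.pi, n_rim)
        scale = rng.uniform(1.10, 1.35, n_rim)
        c, s = math.cos(g.rotation), math.sin(g.rotation)
        ex = g.axes[0] * np.cos(t) * scale
        ey = g.axes[1] * np.sin(t) * scale
        xs = g.center[0] + ex * c - ey * s
        ys = g.center[1] + ex * s + ey * c
        _stamp_points(blue, xs, ys, amplitude=220.0)
    blue[gt_mask] *= 0.10  # lumens are dark in the nuclear channel too

    green = rng.uniform(0.0, config.green_noise, (h, w))

    image = np.stack([red, green, blue], axis=-1)
    image = np.clip(image, 0.0, 255.0).astype(np.uint8)
    return SyntheticScene(image=image, gt_mask=gt_mask,
                          cyst_geometries=tuple(cysts), config=config)


# ---------------------------------------------------------------------------
# Mask perturbation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PerturbConfig:
    """Controlled corruption of a ground-truth mask.

    Rates act as exact fractions of the component count
    (``n_affected = round(rate * n)``, random selection), and
    ``spurious_rate`` as an exact rounded blob count; this keeps the
    object-level outcome deterministic given the log.  ``boundary_jitter``
    erodes or dilates each kept component (coin flip) by a disc of that
    radius.
    """

    drop_rate: float = 0.0
    spurious_rate: float = 0.0
    split_rate: float = 0.0
    boundary_jitter: int = 0
    cut_width: int = 2
    spurious_area_px: tuple[float, float] = (20.0, 130.0)
    spurious_margin: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("drop_rate", "split_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.spurious_rate < 0:
            raise ValueError("spurious_rate must be >= 0")
        if self.boundary_jitter < 0:
            raise ValueError("boundary_jitter must be >= 0")


@dataclass
class PerturbationLog:
    """What happened to each ground-truth component, plus spurious blobs."""

    actions: dict[int, str] = field(default_factory=dict)  # component id -> kept/dropped/split
    fragments: dict[int, int] = field(default_factory=dict)  # split id -> fragment count
    spurious_areas: list[int] = field(default_factory=list)

    @property
    def n_dropped(self) -> int:
        return sum(1 for a in self.actions.values() if a == "dropped")

    @property
    def n_split(self) -> int:
        return sum(1 for a in self.actions.values() if a == "split")

    @property
    def n_spurious(self) -> int:
        return len(self.spurious_areas)


def _disc(radius: int) -> np.ndarray:
    g = np.arange(-radius, radius + 1)
    return (g[:, None] ** 2 + g[None, :] ** 2) <= radius ** 2


def perturb_mask(gt: np.ndarray, config: PerturbConfig) -> tuple[np.ndarray, PerturbationLog]:
    """Corrupt a ground-truth mask into a synthetic prediction.

    Returns the predicted mask and a log stating, per ground-truth
    component, whether it was kept, dropped or split (with the resulting
    fragment count), and the areas of all spurious blobs added.  Spurious
    blobs are placed disjoint from every ground-truth component by at
    least ``spurious_margin`` pixels.
    """
    rng = np.random.default_rng(config.seed)
    lc = connected_components(gt, connectivity=8)
    n = lc.n_components
    log = PerturbationLog()

    perm = rng.permutation(n) + 1  # component ids in random order
    n_drop = int(round(config.drop_rate * n))
    n_split = min(int(round(config.split_rate * n)), n - n_drop)
    drop_ids = set(perm[:n_drop].tolist())
    split_ids = set(perm[n_drop:n_drop + n_split].tolist())

    pred = np.zeros_like(lc.labels, dtype=bool)
    for cid in range(1, n + 1):
        comp = lc.labels == cid
        if cid in drop_ids:
            log.actions[cid] = "dropped"
            continue
        if cid in split_ids:
            rows, cols = np.nonzero(comp)
            cr, cc = rows.mean(), cols.mean()
            theta = rng.uniform(0.0, math.pi)
            # distance from the line through the centroid with normal (cos, sin)
            dist = (rows - cr) * math.cos(theta) + (cols - cc) * math.sin(theta)
            cut = np.abs(dist) < config.cut_width / 2.0
            comp = comp.copy()
            comp[rows[cut], cols[cut]] = False
            log.actions[cid] = "split"
            log.fragments[cid] = connected_components(comp, 8).n_components
        else:
            log.actions[cid] = "kept"
        if config.boundary_jitter > 0:
            op = ndimage.binary_dilation if rng.random() < 0.5 else ndimage.binary_erosion
            comp = op(comp, structure=_disc(config.boundary_jitter))
        pred |= comp

    n_spurious = int(round(config.spurious_rate))
    if n_spurious > 0:
        h, w = pred.shape
        rr, cc_grid = np.mgrid[0:h, 0:w]
        occupied = lc.mask() | pred
        for _ in range(n_spurious):
            # distance to anything already present (GT or earlier blobs), so
            # spurious blobs keep the margin from each other too
            dist = (ndimage.distance_transform_edt(~occupied)
                    if occupied.any() else None)
            for _attempt in range(200):
                area = rng.uniform(*config.spurious_area_px)
                a, b, rot = _sample_geometry_spurious(area, rng)
                m = a + 1.0
                if w - m <= m or h - m <= m:
                    continue
                cx = rng.uniform(m, w - m)
                cy = rng.uniform(m, h - m)
                if dist is not None and dist[int(cy), int(cx)] < a + config.spurious_margin:
                    continue
                c, s = math.cos(rot), math.sin(rot)
                dx, dy = cc_grid + 0.5 - cx, rr + 0.5 - cy
                u = (dx * c + dy * s) / a
                v = (-dx * s + dy * c) / b
                blob = (u ** 2 + v ** 2) <= 1.0
                if blob.any() and not (blob & occupied).any():
                    pred |= blob
                    occupied |= blob
                    log.spurious_areas.append(int(blob.sum()))
                    break
    return pred, log


def _sample_geometry_spurious(area_px: float, rng: np.random.Generator) -> tuple[float, float, float]:
    aspect = rng.uniform(1.0, 1.6)
    a = math.sqrt(area_px * aspect / math.pi)
    b = math.sqrt(area_px / (aspect * math.pi))
    return a, b, rng.uniform(0.0, math.pi)


# ---------------------------------------------------------------------------
# Dataset writer
# ---------------------------------------------------------------------------

def write_dataset(
    out_dir: str | Path,
    n_tubules: int = 8,
    images_per_tubule: int = 3,
    n_treatments: int = 4,
    n_experiments: int = 2,
    scene_config: SceneConfig | None = None,
    seed: int = 0,
) -> DatasetCatalog:
    """Write a synthetic dataset in the on-disk layout real data uses.

    Produces ``images/*.png``, ``masks/*.png``, ``annotations/*.json``
    (Labelme dialect) and ``catalog.csv``; tubules are assigned
    round-robin to treatments and experiments so treatment- and
    experiment-level reports have several groups.
    """
    out = Path(out_dir)
    for sub in ("images", "masks", "annotations"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    base = scene_config or SceneConfig()
    master = np.random.default_rng(seed)
    records: list[ImageRecord] = []
    for t in range(n_tubules):
        experiment = f"E{t % n_experiments + 1}"
        treatment = f"T{t % n_treatments + 1}"
        tubule = f"tub{t + 1:02d}"
        for z in range(images_per_tubule):
            image_id = f"{experiment}_{treatment}_{tubule}_z{z}"
            scene_seed = int(master.integers(0, 2 ** 31 - 1))
            scene = generate_scene(replace(base, seed=scene_seed))
            write_image(scene.image, out / "images" / f"{image_id}.png")
            write_mask(scene.gt_mask, out / "masks" / f"{image_id}.png")
            save_labelme(
                scene.annotation_set(image_id),
                out / "annotations" / f"{image_id}.json",
                image_path=f"../images/{image_id}.png",
                image_height=base.height,
                image_width=base.width,
            )
            records.append(ImageRecord(
                image_id=image_id,
                experiment_id=experiment,
                treatment_id=treatment,
                tubule_id=tubule,
                z_index=z,
                image_path=f"images/{image_id}.png",
                annotation_path=f"annotations/{image_id}.json",
            ))
    catalog = DatasetCatalog(records=records, root=out)
    catalog.to_csv(out / "catalog.csv")
    return catalog
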