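"""Core data types and I/O: Labelme annotations, masks, images, catalogs.

Binary masks are plain boolean ``(H, W)`` numpy arrays throughout the
package; connected-component structure is derived on demand with an
explicit connectivity (8-connected by default, so a diagonally joined
blob counts as one cyst).

Coordinates are (row, col), 0-based, origin at the top-left corner.
Labelme stores polygon vertices as (x, y) = (col, row) floats; the
rasterizer converts internally.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

__all__ = [
    "AnnotationSet",
    "ImageRecord",
    "DatasetCatalog",
    "LabeledComponents",
    "LabelmeParseError",
    "UnsupportedShapeError",
    "load_labelme",
    "save_labelme",
    "rasterize",
    "connected_components",
    "as_bool_mask",
    "read_mask",
    "write_mask",
    "read_image",
    "write_image",
]

CATALOG_COLUMNS = [
    "image_id",
    "experiment_id",
    "treatment_id",
    "tubule_id",
    "z_index",
    "image_path",
    "annotation_path",
]


class LabelmeParseError(ValueError):
    """Raised when a Labelme JSON file is malformed."""


class UnsupportedShapeError(ValueError):
    """Raised when an annotation shape is not a polygon."""


@dataclass(frozen=True)
class AnnotationSet:
    """Polygonal cyst annotations for one image.

    Each polygon is an ``(n, 2)`` float array of (x, y) vertices in pixel
    coordinates, vertex order preserved from the source file.  All labels
    are "cyst" in this dataset; labels are kept for provenance.
    """

    image_id: str
    polygons: tuple[np.ndarray, ...]
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for poly in self.polygons:
            if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
                raise ValueError(
                    f"polygon must be an (n>=3, 2) vertex array, got shape {poly.shape}"
                )


@dataclass(frozen=True)
class ImageRecord:
    """One acquired image with its position in the experiment hierarchy.

    Several z-stack images belong to one engineered tubule; the tubule is
    the grouping unit for cross-validation.  ``tubule_id`` is unique
    within an (experiment, treatment) pair, so the globally unique tubule
    key is the triple.
    """

    image_id: str
    experiment_id: str
    treatment_id: str
    tubule_id: str
    z_index: int
    image_path: str
    annotation_path: str = ""

    @property
    def tubule_key(self) -> tuple[str, str, str]:
        return (self.experiment_id, self.treatment_id, self.tubule_id)


@dataclass
class DatasetCatalog:
    """All image records of a dataset plus lazy access to annotations."""

    records: list[ImageRecord] = field(default_factory=list)
    root: Path | None = None

    def __post_init__(self) -> None:
        ids = [r.image_id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate image_id in catalog: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def tubule_keys(self) -> list[tuple[str, str, str]]:
        """Sorted unique (experiment, treatment, tubule) keys."""
        return sorted({r.tubule_key for r in self.records})

    def _resolve(self, path: str) -> Path:
        p = Path(path)
        if not p.is_absolute() and self.root is not None:
            p = self.root / p
        return p

    def load_image(self, record: ImageRecord) -> np.ndarray:
        return read_image(self._resolve(record.image_path))

    def load_annotations(self, record: ImageRecord) -> AnnotationSet:
        if not record.annotation_path:
            return AnnotationSet(record.image_id, ())
        return load_labelme(self._resolve(record.annotation_path), image_id=record.image_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records], columns=CATALOG_COLUMNS)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DatasetCatalog":
        path = Path(path)
        df = pd.read_csv(path, dtype=str).fillna("")
        missing = [c for c in CATALOG_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"catalog {path} missing columns: {missing}")
        records = [
            ImageRecord(
                image_id=row.image_id,
                experiment_id=row.experiment_id,
                treatment_id=row.treatment_id,
                tubule_id=row.tubule_id,
                z_index=int(row.z_index),
                image_path=row.image_path,
                annotation_path=row.annotation_path,
            )
            for row in df.itertuples()
        ]
        return cls(records=records, root=path.parent)


# ---------------------------------------------------------------------------
# Labelme annotations
# ---------------------------------------------------------------------------

def load_labelme(path: str | Path, image_id: str | None = None) -> AnnotationSet:
    """Parse a Labelme-dialect JSON file into an :class:`AnnotationSet`.

    Only shapes of type ``polygon`` are supported; anything else raises
    :class:`UnsupportedShapeError` because the annotation protocol for
    cysts is polygonal outlines.
    """
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise LabelmeParseError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(payload, dict) or "shapes" not in payload:
        raise LabelmeParseError(f"{path}: missing required key 'shapes'")
    shapes = payload["shapes"]
    if not isinstance(shapes, list):
        raise LabelmeParseError(f"{path}: key 'shapes' must be a list")

    polygons: list[np.ndarray] = []
    labels: list[str] = []
    for i, shape in enumerate(shapes):
        stype = shape.get("shape_type", "polygon")
        if stype != "polygon":
            raise UnsupportedShapeError(
                f"{path}: shape {i} has type {stype!r}; only 'polygon' is supported"
            )
        if "points" not in shape:
            raise LabelmeParseError(f"{path}: shape {i} missing key 'points'")
        pts = np.asarray(shape["points"], dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
            raise LabelmeParseError(
                f"{path}: shape {i} key 'points' must be >=3 (x, y) pairs"
            )
        polygons.append(pts)
        labels.append(str(shape.get("label", "cyst")))
    if image_id is None:
        image_id = str(payload.get("imagePath", path.stem))
    return AnnotationSet(image_id=image_id, polygons=tuple(polygons), labels=tuple(labels))


def save_labelme(
    annotations: AnnotationSet,
    path: str | Path,
    image_path: str = "",
    image_height: int | None = None,
    image_width: int | None = None,
) -> None:
    """Write an :class:`AnnotationSet` as Labelme-dialect JSON."""
    labels = annotations.labels or ("cyst",) * len(annotations.polygons)
    payload = {
        "version": "5.0.0",
        "flags": {},
        "shapes": [
            {
                "label": label,
                "points": [[float(x), float(y)] for x, y in poly],
                "group_id": None,
                "shape_type": "polygon",
                "flags": {},
            }
            for poly, label in zip(annotations.polygons, labels)
        ],
        "imagePath": image_path or annotations.image_id,
        "imageData": None,
        "imageHeight": image_height,
        "imageWidth": image_width,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def _centers_in_polygon(poly: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Even-odd ray cast: which points (xs, ys) lie inside the polygon.

    Edges half-open in y so a ray through a shared vertex is counted once;
    together with the strict ``x < intersection`` rule this yields the
    usual top-left fill convention for points exactly on an edge.
    """
    inside = np.zeros(xs.shape, dtype=bool)
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        if y1 == y2:
            continue
        crosses = (y1 > ys) != (y2 > ys)
        with np.errstate(invalid="ignore"):
            x_at = x1 + (ys - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (xs < x_at)
    return inside


def rasterize(annotations: AnnotationSet, width: int, height: int) -> np.ndarray:
    """Rasterize polygons to a boolean mask using the pixel-center rule.

    A pixel (row r, col c) is foreground iff its center (c + 0.5, r + 0.5)
    falls inside any polygon; overlapping polygons union.  A polygon whose
    bounding box misses the image entirely contributes nothing (with a
    warning).
    """
    if width <= 0 or height <= 0:
        raise ValueError("width and height must be positive")
    mask = np.zeros((height, width), dtype=bool)
    for poly in annotations.polygons:
        xmin, ymin = poly.min(axis=0)
        xmax, ymax = poly.max(axis=0)
        c0 = max(int(np.floor(xmin - 0.5)), 0)
        c1 = min(int(np.ceil(xmax + 0.5)), width)
        r0 = max(int(np.floor(ymin - 0.5)), 0)
        r1 = min(int(np.ceil(ymax + 0.5)), height)
        if c0 >= c1 or r0 >= r1:
            warnings.warn(
                f"polygon with bounds x[{xmin:.1f},{xmax:.1f}] y[{ymin:.1f},{ymax:.1f}] "
                "lies outside the image and was skipped",
                stacklevel=2,
            )
            continue
        rr, cc = np.mgrid[r0:r1, c0:c1]
        inside = _centers_in_polygon(poly, cc + 0.5, rr + 0.5)
        mask[r0:r1, c0:c1] |= inside
    return mask


# ---------------------------------------------------------------------------
# Connected components
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LabeledComponents:
    """Connected components of a binary mask.

    ``labels`` is an integer image with 0 for background and 1..n for the
    components in deterministic scan order; ``areas[i]`` is the pixel count
    of component ``i + 1``.
    """

    labels: np.ndarray
    areas: np.ndarray
    connectivity: int

    @property
    def n_components(self) -> int:
        return len(self.areas)

    def mask(self) -> np.ndarray:
        return self.labels > 0


def as_bool_mask(mask: np.ndarray) -> np.ndarray:
    """Coerce an array to a 2-D boolean mask (nonzero = foreground)."""
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {arr.shape}")
    return arr.astype(bool, copy=False) if arr.dtype == bool else arr != 0


def connected_components(mask: np.ndarray, connectivity: int = 8) -> LabeledComponents:
    """Label connected components (8-connected by default)."""
    mask = as_bool_mask(mask)
    if connectivity == 8:
        structure = np.ones((3, 3), dtype=bool)
    elif connectivity == 4:
        structure = ndimage.generate_binary_structure(2, 1)
    else:
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    labels, n = ndimage.label(mask, structure=structure)
    areas = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    return LabeledComponents(labels=labels, areas=areas, connectivity=connectivity)


# ---------------------------------------------------------------------------
# Image / mask files
# ---------------------------------------------------------------------------

def read_image(path: str | Path) -> np.ndarray:
    """Read an RGB image as an (H, W, 3) uint8 array."""
    with Image.open(path) as img:
        return np.asarray(img.convert("RGB"))


def write_image(image: np.ndarray, path: str | Path) -> None:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) image, got {image.shape}")
    Image.fromarray(image.astype(np.uint8), mode="RGB").save(path)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a single-channel mask PNG; any nonzero pixel is foreground."""
    with Image.open(path) as img:
        return np.asarray(img.convert("L")) > 0


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as an 8-bit PNG with 0 = background, 255 = cyst."""
    mask = as_bool_mask(mask)
    Image.fromarray((mask * np.uint8(255))).save(path)
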