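"""Mask postprocessing: flood-fill hole filling and opening/closing.

Cysts do not typically contain holes, so enclosed background inside a
predicted cyst is converted to foreground.  Opening (erosion then
dilation) removes small noisy detections; closing (dilation then
erosion) merges over-segmented fragments of one cyst.  Both use a
circular structuring element whose size ``k`` — interpreted as the disc
diameter in pixels — is left to the domain expert.

Disc discretization: the structuring element is the set of integer
offsets within Euclidean distance (k - 1) / 2 of the center, so k = 1 is
the identity and k = 3 the 4-connected cross.  Pixels outside the image
are background; operations run on a padded canvas (cropped afterwards)
so that closing stays extensive for cysts touching the image border.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import as_bool_mask

__all__ = ["MorphConfig", "disc_element", "fill_holes", "morphology", "postprocess"]


@dataclass(frozen=True)
class MorphConfig:
    """Which morphological operation to apply, and with what disc size."""

    operation: str = "none"  # none | opening | closing
    k: int = 3

    def __post_init__(self) -> None:
        if self.operation not in ("none", "opening", "closing"):
            raise ValueError(f"operation must be none|opening|closing, got {self.operation!r}")
        if self.k < 1:
            raise ValueError(f"structuring element size k must be >= 1, got {self.k}")


def disc_element(k: int) -> np.ndarray:
    """Boolean disc footprint of diameter ``k`` (radius (k-1)/2)."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    radius = (k - 1) / 2.0
    n = int(np.floor(radius))
    g = np.arange(-n, n + 1)
    return (g[:, None] ** 2 + g[None, :] ** 2) <= radius ** 2 + 1e-9


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Convert enclosed background to foreground (flood fill from the border).

    Background components with a 4-connected path to the image border are
    untouched; foreground never shrinks.  Idempotent.
    """
    return ndimage.binary_fill_holes(as_bool_mask(mask))


def morphology(mask: np.ndarray, config: MorphConfig) -> np.ndarray:
    """Apply opening or closing with a circular structuring element.

    Closing is extensive (output contains the input) and opening
    anti-extensive (output contained in the input); both are idempotent
    at fixed k.
    """
    mask = as_bool_mask(mask)
    if config.operation == "none" or config.k == 1:
        return mask.copy()
    footprint = disc_element(config.k)
    # Work on a canvas padded with background so the dilation of closing can
    # extend past the frame before being eroded back: this is the
    # infinite-background convention under which closing is extensive.
    pad = config.k
    padded = np.pad(mask, pad, mode="constant", constant_values=False)
    if config.operation == "opening":
        out = ndimage.binary_opening(padded, structure=footprint)
    else:
        out = ndimage.binary_closing(padded, structure=footprint)
    return out[pad:-pad, pad:-pad]


def postprocess(mask: np.ndarray, config: MorphConfig | None = None) -> np.ndarray:
    """Full postprocessing pipeline: hole filling, then optional morphology."""
    out = fill_holes(mask)
    if config is not None:
        out = morphology(out, config)
    return out
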