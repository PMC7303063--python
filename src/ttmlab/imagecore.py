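"""Image containers, luminance conversion, and visual-field geometry.

Everything downstream works on a :class:`LuminanceImage`: a single plane of
luminance in [0, 1] plus the two numbers that tie pixels to the visual
field — the pixels-per-degree scale (``ppd``) and the point of fixation in
pixel coordinates.  Eccentricity (angular distance from fixation, in
degrees) is the organizing variable of the whole model: pooling regions
grow linearly with it.

Coordinate convention: 0-based ``(row, col)``, pixel centers at integer
coordinates; the fixation may be fractional (subpixel).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Rec. 709 / sRGB luma weights for (R, G, B).
REC709_WEIGHTS = (0.2126, 0.7152, 0.0722)


@dataclass
class LuminanceImage:
    """A 2-D luminance field tied to visual-field geometry.

    Parameters
    ----------
    pixels
        2-D float array of luminance values in [0, 1].
    ppd
        Pixels per degree of visual angle; strictly positive.
    fixation
        ``(row, col)`` of the point of gaze in 0-based pixel coordinates.
        May be fractional and may lie outside the image (flagged by
        :attr:`fixation_inside`).
    color_planes
        Optional ``(H, W, 3)`` original color image in [0, 1], kept for
        per-channel processing; the luminance plane is always the default
        processing path.
    meta
        Provenance dictionary (e.g. the conversion weights used).
    """

    pixels: np.ndarray
    ppd: float
    fixation: tuple[float, float]
    color_planes: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels contain non-finite values")
        if self.pixels.min() < -1e-9 or self.pixels.max() > 1 + 1e-9:
            raise ValueError(
                "luminance must lie in [0, 1]; "
                f"got range [{self.pixels.min():.4g}, {self.pixels.max():.4g}]"
            )
        self.pixels = np.clip(self.pixels, 0.0, 1.0)
        self.ppd = float(self.ppd)
        if not (self.ppd > 0):
            raise ValueError(f"ppd must be strictly positive, got {self.ppd}")
        self.fixation = (float(self.fixation[0]), float(self.fixation[1]))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def fixation_inside(self) -> bool:
        """Whether the fixation point falls inside the pixel grid."""
        r, c = self.fixation
        h, w = self.shape
        return 0 <= r <= h - 1 and 0 <= c <= w - 1

    def with_fixation(self, fixation: tuple[float, float]) -> "LuminanceImage":
        """A copy of this image refixated at ``fixation``."""
        return LuminanceImage(
            self.pixels.copy(), self.ppd, fixation,
            None if self.color_planes is None else self.color_planes.copy(),
            dict(self.meta),
        )


def to_luminance(
    image: np.ndarray | LuminanceImage,
    weights: Sequence[float] = REC709_WEIGHTS,
    *,
    ppd: float | None = None,
    fixation: tuple[float, float] | None = None,
    keep_color: bool = False,
) -> LuminanceImage:
    """Convert a 1- or 3-plane raster to a :class:`LuminanceImage`.

    Integer rasters are rescaled by their dtype maximum (e.g. 255 for
    8-bit); float rasters are assumed to already lie in [0, 1].  3-plane
    input is combined with ``weights`` (default Rec. 709).  Converting an
    already-converted image is the identity.

    Raises
    ------
    ValueError
        For non-finite pixels, an unsupported plane count, or out-of-range
        float input.
    """
    if isinstance(image, LuminanceImage):
        # Idempotent on already-converted images.
        return image

    arr = np.asarray(image)
    if not np.all(np.isfinite(arr)):
        raise ValueError("raster contains non-finite pixels")
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64) / float(np.iinfo(arr.dtype).max)
    else:
        arr = arr.astype(np.float64)

    color = None
    if arr.ndim == 2:
        plane = arr
    elif arr.ndim == 3 and arr.shape[2] == 3:
        w = np.asarray(weights, dtype=np.float64)
        if w.shape != (3,):
            raise ValueError("weights must be a triple for 3-plane input")
        plane = arr @ w
        color = arr
    elif arr.ndim == 3 and arr.shape[2] == 1:
        plane = arr[:, :, 0]
    else:
        raise ValueError(
            f"unsupported raster layout {arr.shape}; expected HxW or HxWx3"
        )

    h, wd = plane.shape
    if fixation is None:
        fixation = ((h - 1) / 2.0, (wd - 1) / 2.0)
    if ppd is None:
        ppd = 32.0
    return LuminanceImage(
        plane,
        ppd,
        fixation,
        color_planes=color if keep_color else None,
        meta={"luminance_weights": tuple(float(x) for x in weights)},
    )


def eccentricity_map(image: LuminanceImage) -> np.ndarray:
    """Per-pixel eccentricity in degrees of visual angle.

    The value at pixel ``(r, c)`` is the Euclidean pixel distance from the
    fixation point divided by ``ppd``; exactly zero at fixation.
    """
    if image.ppd is None or not (image.ppd > 0):
        raise ValueError("image has no valid ppd")
    h, w = image.shape
    fr, fc = image.fixation
    rr = np.arange(h, dtype=np.float64)[:, None] - fr
    cc = np.arange(w, dtype=np.float64)[None, :] - fc
    return np.hypot(rr, cc) / image.ppd


# ---------------------------------------------------------------------------
# Raster I/O.  ppd and fixation are carried in a sidecar JSON because PNG
# and TIFF cannot portably embed them.
# ---------------------------------------------------------------------------

def _sidecar_path(path: str) -> str:
    return os.path.splitext(path)[0] + ".json"


def save_image(image: LuminanceImage, path: str) -> None:
    """Write a luminance image as 16-bit PNG/TIFF plus a geometry sidecar."""
    import imageio.v3 as iio

    arr = np.round(image.pixels * 65535.0).astype(np.uint16)
    iio.imwrite(path, arr)
    meta = {
        "ppd": image.ppd,
        "fixation": list(image.fixation),
        **{k: v for k, v in image.meta.items() if _json_safe(v)},
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=1)


def load_image(path: str, *, ppd: float | None = None,
               fixation: tuple[float, float] | None = None) -> LuminanceImage:
    """Read a PNG/TIFF raster, merging geometry from its sidecar JSON.

    Explicit ``ppd`` / ``fixation`` arguments override the sidecar.
    """
    import imageio.v3 as iio

    arr = iio.imread(path)
    meta = {}
    side = _sidecar_path(path)
    if os.path.exists(side):
        with open(side) as fh:
            meta = json.load(fh)
    if ppd is None:
        ppd = meta.get("ppd")
    if fixation is None and "fixation" in meta:
        fixation = tuple(meta["fixation"])
    return to_luminance(arr, ppd=ppd, fixation=fixation)


def _json_safe(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False
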