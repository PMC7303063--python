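"""Seeded synthetic stimulus generator.

Produces every display class the downstream experiments need — letter
arrays, crowding/search displays, colored-square change-detection (VWM)
arrays, change pairs, and plain textures — with full determinism under a
seed and a ground-truth record sufficient to re-render the display.

Letters are rasterized from a built-in stroke-segment font (no system
font dependency), anti-aliased by a 1-pixel coverage ramp, so the same
spec and seed produce bit-identical pixels on any platform.  All
geometry is expressed in degrees of visual angle and converted through
the spec's ``ppd``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ttmlab.imagecore import LuminanceImage

# ---------------------------------------------------------------------------
# stroke font: segments ((x0, y0), (x1, y1)) in a unit cell, y up
# ---------------------------------------------------------------------------

STROKE_FONT: dict[str, list] = {
    "A": [((0.0, 0.0), (0.5, 1.0)), ((0.5, 1.0), (1.0, 0.0)),
          ((0.25, 0.5), (0.75, 0.5))],
    "C": [((1.0, 1.0), (0.0, 1.0)), ((0.0, 1.0), (0.0, 0.0)),
          ((0.0, 0.0), (1.0, 0.0))],
    "E": [((1.0, 1.0), (0.0, 1.0)), ((0.0, 1.0), (0.0, 0.0)),
          ((0.0, 0.0), (1.0, 0.0)), ((0.0, 0.5), (0.7, 0.5))],
    "F": [((1.0, 1.0), (0.0, 1.0)), ((0.0, 1.0), (0.0, 0.0)),
          ((0.0, 0.5), (0.7, 0.5))],
    "H": [((0.0, 0.0), (0.0, 1.0)), ((1.0, 0.0), (1.0, 1.0)),
          ((0.0, 0.5), (1.0, 0.5))],
    "I": [((0.5, 0.0), (0.5, 1.0))],
    "K": [((0.0, 0.0), (0.0, 1.0)), ((0.0, 0.5), (1.0, 1.0)),
          ((0.0, 0.5), (1.0, 0.0))],
    "L": [((0.0, 1.0), (0.0, 0.0)), ((0.0, 0.0), (1.0, 0.0))],
    "N": [((0.0, 0.0), (0.0, 1.0)), ((0.0, 1.0), (1.0, 0.0)),
          ((1.0, 0.0), (1.0, 1.0))],
    "O": [((0.0, 0.0), (1.0, 0.0)), ((1.0, 0.0), (1.0, 1.0)),
          ((1.0, 1.0), (0.0, 1.0)), ((0.0, 1.0), (0.0, 0.0))],
    "S": [((1.0, 1.0), (0.0, 1.0)), ((0.0, 1.0), (0.0, 0.5)),
          ((0.0, 0.5), (1.0, 0.5)), ((1.0, 0.5), (1.0, 0.0)),
          ((1.0, 0.0), (0.0, 0.0))],
    "T": [((0.0, 1.0), (1.0, 1.0)), ((0.5, 1.0), (0.5, 0.0))],
    "U": [((0.0, 1.0), (0.0, 0.0)), ((0.0, 0.0), (1.0, 0.0)),
          ((1.0, 0.0), (1.0, 1.0))],
    "V": [((0.0, 1.0), (0.5, 0.0)), ((0.5, 0.0), (1.0, 1.0))],
    "X": [((0.0, 0.0), (1.0, 1.0)), ((0.0, 1.0), (1.0, 0.0))],
    "Y": [((0.0, 1.0), (0.5, 0.5)), ((1.0, 1.0), (0.5, 0.5)),
          ((0.5, 0.5), (0.5, 0.0))],
    "Z": [((0.0, 1.0), (1.0, 1.0)), ((1.0, 1.0), (0.0, 0.0)),
          ((0.0, 0.0), (1.0, 0.0))],
}

DEFAULT_LETTERS = tuple(sorted(STROKE_FONT))

#: 9 maximally spaced hues (HSV hue i/9, full saturation and value).
def _default_palette() -> list[tuple[float, float, float]]:
    import colorsys

    return [colorsys.hsv_to_rgb(i / 9.0, 1.0, 1.0) for i in range(9)]


@dataclass(frozen=True)
class StimulusSpec:
    """Geometry and content of a synthetic display.

    All sizes are in degrees of visual angle; ``shape`` is the raster size
    in pixels and ``fixation`` defaults to the image center.
    """

    kind: str = "letter_array"
    item_size: float = 0.8  # deg
    spacing: float = 1.5  # deg, center-to-center
    grid_shape: tuple[int, int] = (3, 4)
    n_items: int = 12
    content: tuple = DEFAULT_LETTERS
    eccentricity: float = 4.0  # deg; ring radius for vwm arrays
    ppd: float = 16.0
    shape: tuple[int, int] = (128, 128)
    fixation: tuple[float, float] | None = None
    rng_seed: int = 0

    def fix_px(self) -> tuple[float, float]:
        if self.fixation is not None:
            return self.fixation
        return ((self.shape[0] - 1) / 2.0, (self.shape[1] - 1) / 2.0)


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def _segments_for(letter: str, rotation_deg: float = 0.0) -> list:
    segs = STROKE_FONT[letter]
    if rotation_deg == 0.0:
        return segs
    th = math.radians(rotation_deg)
    c, s = math.cos(th), math.sin(th)

    def rot(p):
        x, y = p[0] - 0.5, p[1] - 0.5
        return (0.5 + c * x - s * y, 0.5 + s * x + c * y)

    return [(rot(a), rot(b)) for a, b in segs]


def _bar_segments(orientation_deg: float) -> list:
    """A bar through the cell center at the given orientation
    (0 = vertical, positive = clockwise tilt)."""
    th = math.radians(orientation_deg)
    dx, dy = math.sin(th) * 0.5, math.cos(th) * 0.5
    return [((0.5 - dx, 0.5 - dy), (0.5 + dx, 0.5 + dy))]


def _draw_segments(canvas: np.ndarray, segments: list, center_px: tuple,
                   size_px: float, thickness_px: float, ink: float) -> None:
    """Alpha-composite anti-aliased stroke segments onto the canvas.

    ``segments`` are in the unit cell (y up); the cell is scaled to
    ``size_px`` and centered at ``center_px`` (row, col).
    """
    r_c, c_c = center_px
    half = size_px / 2.0 + thickness_px + 1.0
    r0 = max(0, int(math.floor(r_c - half)))
    r1 = min(canvas.shape[0], int(math.ceil(r_c + half)) + 1)
    c0 = max(0, int(math.floor(c_c - half)))
    c1 = min(canvas.shape[1], int(math.ceil(c_c + half)) + 1)
    if r0 >= r1 or c0 >= c1:
        return
    rows = np.arange(r0, r1, dtype=np.float64)[:, None]
    cols = np.arange(c0, c1, dtype=np.float64)[None, :]
    # unit-cell coords: x right, y up (image rows grow downward)
    x = (cols - c_c) / size_px + 0.5
    y = (r_c - rows) / size_px + 0.5
    cov = np.zeros((r1 - r0, c1 - c0))
    for (x0, y0), (x1, y1) in segments:
        vx, vy = x1 - x0, y1 - y0
        L2 = vx * vx + vy * vy
        if L2 == 0:
            t = np.zeros_like(x)
        else:
            t = np.clip(((x - x0) * vx + (y - y0) * vy) / L2, 0.0, 1.0)
        dx = (x - (x0 + t * vx)) * size_px
        dy = (y - (y0 + t * vy)) * size_px
        dist = np.hypot(dx, dy)
        c = np.clip(thickness_px / 2.0 + 0.5 - dist, 0.0, 1.0)
        cov = np.maximum(cov, c)
    region = canvas[r0:r1, c0:c1]
    canvas[r0:r1, c0:c1] = region * (1 - cov) + ink * cov


def _render_record(record: dict) -> np.ndarray:
    """Re-render a luminance stimulus from its ground-truth record."""
    spec = record["spec"]
    canvas = np.full(spec.shape, record["background"], dtype=np.float64)
    for item in record["items"]:
        _draw_segments(
            canvas,
            item["segments"],
            (item["row"], item["col"]),
            spec.item_size * spec.ppd,
            record["thickness_px"],
            item["ink"],
        )
    return canvas


def _finish(canvas: np.ndarray, spec: StimulusSpec) -> LuminanceImage:
    return LuminanceImage(np.clip(canvas, 0.0, 1.0), spec.ppd, spec.fix_px())


# ---------------------------------------------------------------------------
# letter arrays
# ---------------------------------------------------------------------------

def make_letter_array(spec: StimulusSpec) -> tuple[LuminanceImage, dict]:
    """Rows and columns of dark letters on a light background.

    The grid is centered on fixation.  Ground truth lists letter identity
    and cell center for every position.
    """
    rows, cols = spec.grid_shape
    if rows < 1 or cols < 1 or not spec.content:
        raise ValueError("grid shape and letter set must be non-empty")
    if spec.item_size > spec.spacing and rows * cols > 1:
        raise ValueError(
            f"letters of {spec.item_size} deg overlap at {spec.spacing} deg spacing"
        )
    for letter in spec.content:
        if letter not in STROKE_FONT:
            raise ValueError(f"letter {letter!r} not in the stroke font")
    rng = np.random.default_rng(spec.rng_seed)
    bg, ink = 0.9, 0.1
    fr, fc = spec.fix_px()
    sp_px = spec.spacing * spec.ppd
    thickness_px = max(1.0, 0.12 * spec.item_size * spec.ppd)
    items = []
    for i in range(rows):
        for j in range(cols):
            letter = str(rng.choice(list(spec.content)))
            r = fr + (i - (rows - 1) / 2.0) * sp_px
            c = fc + (j - (cols - 1) / 2.0) * sp_px
            items.append({
                "index": len(items), "letter": letter, "cell": (i, j),
                "row": r, "col": c, "ink": ink, "role": "letter",
                "segments": _segments_for(letter),
            })
    record = {"spec": spec, "items": items, "background": bg,
              "thickness_px": thickness_px}
    return _finish(_render_record(record), spec), record


# ---------------------------------------------------------------------------
# search arrays
# ---------------------------------------------------------------------------

SEARCH_CONDITIONS = ("feature_popout", "t_among_l", "conjunction")


def _search_item(condition: str, role: str, rng) -> dict:
    """Content of one search item (segments + ink), before placement."""
    if condition == "feature_popout":
        # vertical distractor bars, tilted target
        ori = 45.0 if role == "target" else 0.0
        return {"segments": _bar_segments(ori), "ink": 0.1, "orientation": ori}
    if condition == "t_among_l":
        rot = float(rng.choice([0.0, 90.0, 180.0, 270.0]))
        letter = "T" if role == "target" else "L"
        return {"segments": _segments_for(letter, rot), "ink": 0.1,
                "letter": letter, "rotation": rot}
    if condition == "conjunction":
        # target: dark tilted; distractors split dark-vertical / light-tilted
        if role == "target":
            ori, ink = 45.0, 0.1
        elif rng.random() < 0.5:
            ori, ink = 0.0, 0.1
        else:
            ori, ink = 45.0, 0.75
        return {"segments": _bar_segments(ori), "ink": ink, "orientation": ori}
    raise ValueError(f"unknown search condition {condition!r}; "
                     f"expected one of {SEARCH_CONDITIONS}")


def _place_items(spec: StimulusSpec, n: int, rng, min_sep_deg: float) -> list:
    """Non-overlapping jittered positions (px), rejection-sampled."""
    h, w = spec.shape
    margin = spec.item_size * spec.ppd * 0.75 + 2
    min_sep_px = min_sep_deg * spec.ppd
    placed: list[tuple[float, float]] = []
    tries = 0
    while len(placed) < n:
        tries += 1
        if tries > 20000:
            raise ValueError(
                f"cannot place {n} items of {spec.item_size} deg in a "
                f"{h}x{w} px field without overlap"
            )
        r = rng.uniform(margin, h - 1 - margin)
        c = rng.uniform(margin, w - 1 - margin)
        if all(math.hypot(r - pr, c - pc) >= min_sep_px for pr, pc in placed):
            placed.append((r, c))
    return placed


def make_search_array(
    spec: StimulusSpec,
    condition: str = "t_among_l",
    target_present: bool = True,
) -> tuple[LuminanceImage, dict]:
    """A visual-search display: one target among distractors (or none).

    Exactly one target is present iff ``target_present``; items are placed
    without overlap with seed-driven positional jitter.
    """
    if spec.n_items < 1:
        raise ValueError("n_items must be >= 1")
    rng = np.random.default_rng(spec.rng_seed)
    positions = _place_items(spec, spec.n_items, rng,
                             max(spec.item_size * 1.3, spec.spacing * 0.5))
    target_idx = int(rng.integers(spec.n_items)) if target_present else -1
    items = []
    for i, (r, c) in enumerate(positions):
        role = "target" if i == target_idx else "distractor"
        content = _search_item(condition, role, rng)
        items.append({"index": i, "role": role, "row": r, "col": c, **content})
    record = {
        "spec": spec, "items": items, "background": 0.5,
        "thickness_px": max(1.0, 0.12 * spec.item_size * spec.ppd),
        "condition": condition, "target_present": bool(target_present),
        "target_index": target_idx,
    }
    return _finish(_render_record(record), spec), record


# ---------------------------------------------------------------------------
# VWM arrays of colored squares and change pairs
# ---------------------------------------------------------------------------

VWM_BACKGROUND = 0.5


def make_vwm_array(
    n_items: int,
    palette: list | None = None,
    spec: StimulusSpec | None = None,
) -> tuple[np.ndarray, dict]:
    """Colored squares on a uniform gray background (RGB raster).

    Items sit on a ring of radius ``spec.eccentricity`` around fixation
    with angular jitter, colors drawn from the palette with replacement.
    """
    spec = spec or StimulusSpec(kind="vwm_array")
    if palette is None:
        palette = _default_palette()
    if n_items > 0 and len(palette) == 0:
        raise ValueError("palette must be non-empty")
    rng = np.random.default_rng(spec.rng_seed)
    h, w = spec.shape
    raster = np.full((h, w, 3), VWM_BACKGROUND, dtype=np.float64)
    fr, fc = spec.fix_px()
    size_px = spec.item_size * spec.ppd
    rad_px = spec.eccentricity * spec.ppd
    # ring placement: evenly spaced base angles + seeded jitter
    max_on_ring = max(1, int(2 * math.pi * rad_px / (size_px * 1.6)))
    if n_items > max_on_ring:
        raise ValueError(
            f"{n_items} items do not fit on the {spec.eccentricity} deg ring "
            f"without overlap (max {max_on_ring})"
        )
    phase = rng.uniform(0, 2 * math.pi)
    items = []
    for i in range(n_items):
        ang = phase + 2 * math.pi * i / max(n_items, 1)
        ang += rng.uniform(-0.5, 0.5) * (2 * math.pi / max(n_items, 1) * 0.3)
        r = fr + rad_px * math.sin(ang)
        c = fc + rad_px * math.cos(ang)
        color_idx = int(rng.integers(len(palette)))
        items.append({"index": i, "row": r, "col": c,
                      "color_index": color_idx,
                      "color": tuple(palette[color_idx])})
    for item in items:
        _paint_square(raster, item, size_px)
    record = {"spec": spec, "items": items, "palette": [tuple(p) for p in palette],
              "background": VWM_BACKGROUND, "size_px": size_px}
    return raster, record


def _paint_square(raster: np.ndarray, item: dict, size_px: float) -> None:
    h, w = raster.shape[:2]
    r, c = item["row"], item["col"]
    half = size_px / 2.0
    rows = np.arange(h, dtype=np.float64)[:, None]
    cols = np.arange(w, dtype=np.float64)[None, :]
    # anti-aliased box coverage
    cov_r = np.clip(half + 0.5 - np.abs(rows - r), 0.0, 1.0)
    cov_c = np.clip(half + 0.5 - np.abs(cols - c), 0.0, 1.0)
    cov = (cov_r * cov_c)[:, :, None]
    color = np.asarray(item["color"])[None, None, :]
    raster[:] = raster * (1 - cov) + color * cov


def make_change_pair(
    base: StimulusSpec,
    change_index: int = 0,
    new_color_index: int | None = None,
    n_items: int = 8,
    palette: list | None = None,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Two VWM arrays identical except for the color of one square.

    Returns (raster A, raster B, change record); the change record gives
    the changed item's location and the color delta.
    """
    if palette is None:
        palette = _default_palette()
    a, rec = make_vwm_array(n_items, palette, base)
    if not (0 <= change_index < len(rec["items"])):
        raise ValueError(f"change index {change_index} out of range")
    item = rec["items"][change_index]
    old_idx = item["color_index"]
    if new_color_index is None:
        new_color_index = (old_idx + len(palette) // 2) % len(palette)
    if new_color_index == old_idx:
        raise ValueError("new color equals the old color: not a change")
    b = np.full_like(a, VWM_BACKGROUND)
    size_px = rec["size_px"]
    for i, it in enumerate(rec["items"]):
        it2 = dict(it)
        if i == change_index:
            it2["color_index"] = new_color_index
            it2["color"] = tuple(palette[new_color_index])
        _paint_square(b, it2, size_px)
    change = {
        "index": change_index,
        "row": item["row"],
        "col": item["col"],
        "size_px": size_px,
        "old_color": tuple(palette[old_idx]),
        "new_color": tuple(palette[new_color_index]),
    }
    return a, b, change


# ---------------------------------------------------------------------------
# textures
# ---------------------------------------------------------------------------

def make_texture(
    kind: str = "binary_noise",
    shape: tuple[int, int] = (128, 128),
    seed: int = 0,
    ppd: float = 32.0,
    fixation: tuple[float, float] | None = None,
    *,
    density: float = 0.5,
    cycles_per_deg: float = 2.0,
    orientation_deg: float = 0.0,
) -> LuminanceImage:
    """Plain textures used as synthesis targets and noise references.

    ``binary_noise``: iid Bernoulli(density) pixels at 0/1.
    ``white_noise``: iid uniform [0, 1].
    ``grating``: full-contrast sinusoid at ``cycles_per_deg``.
    ``constant``: uniform field at ``density``.
    """
    rng = np.random.default_rng(seed)
    if fixation is None:
        fixation = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    if kind == "binary_noise":
        px = (rng.random(shape) < density).astype(np.float64)
    elif kind == "white_noise":
        px = rng.random(shape)
    elif kind == "grating":
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]].astype(np.float64)
        th = math.radians(orientation_deg)
        u = xx * math.cos(th) + yy * math.sin(th)
        px = 0.5 + 0.5 * np.cos(2 * np.pi * cycles_per_deg * u / ppd)
    elif kind == "constant":
        px = np.full(shape, float(density))
    else:
        raise ValueError(f"unknown texture kind {kind!r}")
    return LuminanceImage(px, ppd, fixation)


def phase_scramble(image: LuminanceImage, seed: int) -> LuminanceImage:
    """Randomize Fourier phases while keeping the amplitude spectrum.

    The standard reference ensemble for statistic normalization: same
    second-order content, scrambled structure.
    """
    rng = np.random.default_rng(seed)
    X = np.fft.fft2(image.pixels)
    phases = np.exp(2j * np.pi * rng.random(image.shape))
    # enforce Hermitian symmetry so the result is real
    Y = np.abs(X) * phases
    y = np.real(np.fft.ifft2(Y))
    y = y - y.mean() + image.pixels.mean()
    return LuminanceImage(np.clip(y, 0.0, 1.0), image.ppd, image.fixation)
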