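"""Statistic-space discriminability between stimuli at a given fixation.

Human discriminability of two peripheral stimuli is modeled as distance
between their summary-statistic encodings: if two patches have nearly
the same statistics, peripheral vision cannot tell them apart; large
statistic separation predicts easy peripheral identification, and hence
efficient visual search when target-present and target-absent patches
separate well.

Distances are Euclidean over per-statistic z-scores.  The z-scales come
from a seeded reference ensemble of phase-scrambled variants of the
input class (statistics with zero ensemble variance are dropped and
counted); the resulting distance is a proper metric on encodings that
share one normalization.

Because humans define discriminability behaviorally and the model can
only supply a monotone stand-in, everything here predicts *orderings*
(pop-out vs. conjunction search, near vs. far fixation), never absolute
reaction-time slopes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ttmlab.imagecore import LuminanceImage, to_luminance
from ttmlab.pooling import PoolingScheme, build_pooling_scheme, _partition_window
from ttmlab.statistics import (
    StatConfig,
    StatField,
    StatVector,
    compute_region_stats,
    compute_stat_field,
)
from ttmlab.pyramid import build_pyramid
from ttmlab.stimuli import (
    StimulusSpec,
    _bar_segments,
    _draw_segments,
    _segments_for,
    phase_scramble,
)

STD_EPS = 1e-9  # ensemble std below this -> statistic dropped from z-scoring


# ---------------------------------------------------------------------------
# normalization ensembles
# ---------------------------------------------------------------------------

@dataclass
class EnsembleNorm:
    """Per-statistic scales from a seeded phase-scrambled ensemble."""

    stds: np.ndarray  # (n_regions, n_stats)
    valid: np.ndarray  # (n_regions, n_stats) bool: kept for z-scoring
    n_dropped: int
    n_members: int
    seed: int
    scheme_key: tuple = ()


def make_ensemble_norm(
    image: LuminanceImage,
    scheme: PoolingScheme,
    config: StatConfig | None = None,
    n: int = 100,
    seed: int = 0,
) -> EnsembleNorm:
    """Estimate per-statistic standard deviations over ``n`` seeded
    phase-scrambled variants of ``image``."""
    config = config or StatConfig()
    vals = []
    valid = None
    for k in range(n):
        scr = phase_scramble(image, seed * 100003 + k)
        f = compute_stat_field(scr, scheme, config)
        vals.append(f.values_matrix())
        v = f.valid_matrix()
        valid = v if valid is None else (valid & v)
    arr = np.stack(vals)
    stds = arr.std(axis=0)
    keep = valid & (stds > STD_EPS)
    return EnsembleNorm(
        stds=stds,
        valid=keep,
        n_dropped=int(np.sum(valid & ~keep)),
        n_members=n,
        seed=seed,
        scheme_key=scheme.geometry_key(),
    )


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

@dataclass
class DiscriminabilityReport:
    raw_distance: float
    per_region: dict
    n_stats_used: int
    condition: dict = field(default_factory=dict)


def stat_distance(
    a: StatField,
    b: StatField,
    norm: EnsembleNorm | None = None,
) -> DiscriminabilityReport:
    """Euclidean distance between z-scored statistic fields.

    With ``norm=None`` the statistics are compared on their raw scales
    (correlations are already dimensionless).  The z-scored form is a
    metric: zero iff the encodings agree on every kept statistic,
    symmetric, and satisfying the triangle inequality.
    """
    if a.config != b.config or list(a.region_ids) != list(b.region_ids):
        raise ValueError("stat fields are not comparable (config/regions differ)")
    va = a.values_matrix()
    vb = b.values_matrix()
    keep = a.valid_matrix() & b.valid_matrix()
    if norm is not None:
        if norm.scheme_key and a.scheme_key and norm.scheme_key != a.scheme_key:
            raise ValueError("normalization ensemble built under another scheme")
        keep = keep & norm.valid
        z = np.where(keep, (va - vb) / np.where(norm.valid, norm.stds, 1.0), 0.0)
    else:
        z = np.where(keep, va - vb, 0.0)
    per_region = {
        rid: float(np.linalg.norm(z[i])) for i, rid in enumerate(a.region_ids)
    }
    return DiscriminabilityReport(
        raw_distance=float(np.linalg.norm(z)),
        per_region=per_region,
        n_stats_used=int(keep.sum()),
    )


# ---------------------------------------------------------------------------
# crowded-patch encoder
# ---------------------------------------------------------------------------

def _patch_weights(shape: tuple[int, int], diameter_px: float) -> np.ndarray:
    """Smooth circular pooling window centered in the patch."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    r = np.hypot(yy - (h - 1) / 2, xx - (w - 1) / 2)
    # cos^2 taper with half-power at diameter/2
    return _partition_window(r, diameter_px, 1.0)


def encode_patch(image: LuminanceImage, pooling_diameter_deg: float,
                 config: StatConfig | None = None) -> StatVector:
    """Statistics of one pooling region covering a stimulus patch.

    The region's diameter follows the linear law at the patch's
    eccentricity: this is the "what a single peripheral pooling region
    sees" encoder used for crowded-patch discriminability.
    """
    config = config or StatConfig()
    w = _patch_weights(image.shape, pooling_diameter_deg * image.ppd)
    pyr = build_pyramid(image, config.n_scales, config.n_orientations)
    return compute_region_stats(pyr, w, config)


JITTER_DEG = 0.15  # positional uncertainty of each flanker, in deg


def _render_patch(kind: str, center_role: str, spacing: float, item_size: float,
                  ppd: float, shape: tuple[int, int], rng) -> LuminanceImage:
    """A crowding patch: one item at the center, four flankers around it.

    Flanker positions carry a fixed angular jitter (JITTER_DEG) so the
    within-class stimulus variability does not vanish at tight spacings.
    """
    canvas = np.full(shape, 0.5)
    thickness = max(1.0, 0.12 * item_size * ppd)
    cy, cx = (shape[0] - 1) / 2, (shape[1] - 1) / 2

    def item(role):
        if kind == "feature_popout":
            ori = 45.0 if role == "target" else 0.0
            return _bar_segments(ori)
        if kind == "t_among_l":
            rot = float(rng.choice([0.0, 90.0, 180.0, 270.0]))
            return _segments_for("T" if role == "target" else "L", rot)
        raise ValueError(f"unknown patch kind {kind!r}")

    positions = [(cy, cx)]
    roles = [center_role]
    for dy, dx in ((-1, 0), (1, 0), (0, -1), (0, 1)):
        jy = rng.uniform(-JITTER_DEG, JITTER_DEG) * ppd
        jx = rng.uniform(-JITTER_DEG, JITTER_DEG) * ppd
        positions.append((cy + dy * spacing * ppd + jy, cx + dx * spacing * ppd + jx))
        roles.append("distractor")
    for (py, px), role in zip(positions, roles):
        _draw_segments(canvas, item(role), (py, px), item_size * ppd,
                       thickness, 0.1)
    return LuminanceImage(np.clip(canvas, 0, 1), ppd,
                          ((shape[0] - 1) / 2, (shape[1] - 1) / 2))


def search_difficulty_proxy(
    condition: dict,
    n_seeds: int = 10,
    *,
    config: StatConfig | None = None,
    g: float = 0.5,
    d0: float = 1.0,
    n_norm: int = 100,
) -> tuple[float, float]:
    """Discriminability (d'-style) of target-present vs target-absent
    crowded patches; larger values predict easier (more efficient) search.

    Present and absent patches are drawn with seed-varying flanker
    rotations and positional jitter, and the proxy is the separation of
    the two class means in z-scored statistic space divided by the RMS
    within-class spread — discriminability in the signal-detection sense.
    Close flankers inject their variability into the pooled statistics
    and drive the proxy down (crowding); an orientation pop-out target
    separates the classes far beyond the flanker-induced spread.

    ``condition`` keys: ``kind`` (feature_popout | t_among_l),
    ``eccentricity`` (deg), ``spacing`` (deg, center-to-flanker),
    ``item_size`` (deg, default 0.8), ``ppd`` (default 16).

    Returns (proxy, bootstrap-free dispersion: the RMS within-class
    spread on the same scale).
    """
    if n_seeds < 2:
        raise ValueError("n_seeds must be >= 2")
    config = config or StatConfig()
    kind = condition["kind"]
    ecc = float(condition["eccentricity"])
    spacing = float(condition["spacing"])
    item_size = float(condition.get("item_size", 0.8))
    ppd = float(condition.get("ppd", 16.0))
    pool_diam = max(d0, g * ecc)
    # patch must contain the flankers and the pooling window
    half_deg = max(spacing + item_size, pool_diam / 2 + item_size)
    size = int(2 ** math.ceil(math.log2(2 * half_deg * ppd)))
    size = max(size, 32)
    shape = (size, size)
    if spacing + item_size / 2 > size / ppd / 2:
        raise ValueError("flankers at this spacing exceed the patch field")

    # z-scales from phase-scrambled target-absent patches
    w = _patch_weights(shape, pool_diam * ppd)
    rng0 = np.random.default_rng(10_000)
    ref = _render_patch(kind, "distractor", spacing, item_size, ppd, shape, rng0)
    ens = []
    for k in range(n_norm):
        scr = phase_scramble(ref, 777 + k)
        pyr = build_pyramid(scr, config.n_scales, config.n_orientations)
        ens.append(compute_region_stats(pyr, w, config).values)
    stds = np.stack(ens).std(axis=0)
    keep = stds > STD_EPS

    zp, za = [], []
    mask = keep.copy()
    for s in range(n_seeds):
        present = _render_patch(kind, "target", spacing, item_size, ppd, shape,
                                np.random.default_rng(20_000 + 2 * s))
        absent = _render_patch(kind, "distractor", spacing, item_size, ppd,
                               shape, np.random.default_rng(20_001 + 2 * s))
        vp = encode_patch(present, pool_diam, config)
        va = encode_patch(absent, pool_diam, config)
        mask &= vp.valid & va.valid
        zp.append(vp.values)
        za.append(va.values)
    zp = np.stack(zp)[:, mask] / stds[mask]
    za = np.stack(za)[:, mask] / stds[mask]
    sep = float(np.linalg.norm(zp.mean(axis=0) - za.mean(axis=0)))
    within = float(np.sqrt(0.5 * (np.mean(np.sum((zp - zp.mean(0)) ** 2, axis=1))
                                  + np.mean(np.sum((za - za.mean(0)) ** 2, axis=1)))))
    return sep / max(within, 1e-9), within


# ---------------------------------------------------------------------------
# change visibility
# ---------------------------------------------------------------------------

def change_visibility(
    pair: tuple,
    fixation: tuple[float, float],
    *,
    ppd: float | None = None,
    config: StatConfig | None = None,
    norm: EnsembleNorm | None = None,
    norm_n: int = 40,
    scheme_kwargs: dict | None = None,
) -> dict:
    """Per-region statistic distance between a change pair at a fixation.

    Returns a dict with the per-region distance map, the max-region
    ``score``, and bookkeeping.  The score rises as fixation approaches
    the change: nearer fixation means smaller pooling regions around the
    changed item, so the change is no longer averaged away.
    """
    a, b = pair
    img_a = a if isinstance(a, LuminanceImage) else to_luminance(a, ppd=ppd)
    img_b = b if isinstance(b, LuminanceImage) else to_luminance(b, ppd=ppd)
    if img_a.shape != img_b.shape:
        raise ValueError("change pair images differ in geometry")
    img_a = img_a.with_fixation(fixation)
    img_b = img_b.with_fixation(fixation)
    config = config or StatConfig()
    scheme = build_pooling_scheme(img_a, **(scheme_kwargs or {}))
    fa = compute_stat_field(img_a, scheme, config)
    fb = compute_stat_field(img_b, scheme, config)
    if norm is None:
        norm = make_ensemble_norm(img_a, scheme, config, n=norm_n, seed=31)
    rep = stat_distance(fa, fb, norm)
    best = max(rep.per_region, key=rep.per_region.get)
    return {
        "per_region": rep.per_region,
        "score": rep.per_region[best],
        "argmax_region": best,
        "raw_distance": rep.raw_distance,
        "scheme": scheme,
    }
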