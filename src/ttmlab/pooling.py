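"""Eccentricity-scaled pooling lattice over the visual field.

Statistics are pooled over smooth, overlapping regions whose nominal
diameter follows the linear law ``D(e) = max(d0, g * e)``: a foveal floor
of ``d0`` degrees, then linear growth with eccentricity at rate ``g``
(the crowding-zone convention).

The lattice is built so that the region weights form an exact partition
of unity.  A warped radial coordinate ``v = phi(e)`` is chosen with
``phi'(e) = 1 / D(e)`` — linear in eccentricity inside the foveal floor,
logarithmic beyond — so that unit-spaced windows in ``v`` have half-power
width exactly ``D(e)`` in the visual field.  Radial and angular windows
are flat-top raised-cosine profiles whose transitions are complementary,
so the windows in each coordinate sum to one identically; the region
weights are their products.  A central foveal disk and an outer catch-all
ring take up the two complements, so every pixel is covered.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from ttmlab.imagecore import LuminanceImage, eccentricity_map


def _partition_window(x: np.ndarray, spacing: float, overlap: float) -> np.ndarray:
    """Flat-top raised-cosine window centered at 0.

    Value 1 on the plateau ``|x| <= (spacing - t)/2``, cos^2 falloff over a
    transition of width ``t = overlap * spacing``, 0 beyond.  Windows
    repeated every ``spacing`` sum to exactly 1; half-power points sit at
    ``|x| = spacing / 2`` regardless of ``overlap``.
    """
    t = overlap * spacing
    a = (spacing - t) / 2.0
    d = np.abs(x)
    out = np.zeros_like(d)
    out[d <= a] = 1.0
    ramp = (d > a) & (d < a + t)
    out[ramp] = np.cos(np.pi / 2 * (d[ramp] - a) / t) ** 2
    return out


class _RadialWarp:
    """The warp v = phi(e) with phi'(e) = 1 / max(d0, g*e)."""

    def __init__(self, g: float, d0: float):
        self.g = g
        self.d0 = d0
        # spacing in log-e chosen so half-power width is exactly g*e there
        self.w_u = 2.0 * math.asinh(g / 2.0)
        self.e_star = d0 / self.w_u
        self.v_star = self.e_star / d0

    def fwd(self, e: np.ndarray) -> np.ndarray:
        e = np.asarray(e, dtype=np.float64)
        lin = e / self.d0
        with np.errstate(divide="ignore"):
            log = self.v_star + np.log(np.maximum(e, 1e-12) / self.e_star) / self.w_u
        return np.where(e <= self.e_star, lin, log)

    def inv(self, v: float) -> float:
        if v <= self.v_star:
            return v * self.d0
        return self.e_star * math.exp((v - self.v_star) * self.w_u)


@dataclass
class PoolingRegion:
    id: str
    center_ecc: float  # degrees
    center_angle: float  # degrees, polar angle of region center
    nominal_diameter: float  # degrees, between radial half-power points
    weights: np.ndarray  # full-image weight map
    kind: str  # "fovea" | "ring" | "outer"

    @property
    def support(self) -> np.ndarray:
        return self.weights > 1e-12


@dataclass
class PoolingScheme:
    regions: list
    g: float
    d0: float
    overlap: float
    n_theta: int
    ppd: float
    fixation: tuple[float, float]
    shape: tuple[int, int]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self._index = {r.id: i for i, r in enumerate(self.regions)}

    def __len__(self) -> int:
        return len(self.regions)

    def region(self, region_id: str) -> PoolingRegion:
        if region_id not in self._index:
            raise KeyError(f"unknown region id {region_id!r}")
        return self.regions[self._index[region_id]]

    def weight_sum(self) -> np.ndarray:
        """Pixelwise sum of all region weights (partition-of-unity audit)."""
        total = np.zeros(self.shape)
        for r in self.regions:
            total += r.weights
        return total

    def geometry_key(self) -> tuple:
        """Hashable fingerprint used to check two schemes are compatible."""
        return (self.shape, round(self.ppd, 9), tuple(round(f, 6) for f in self.fixation),
                round(self.g, 9), round(self.d0, 9), round(self.overlap, 9), self.n_theta)


def build_pooling_scheme(
    image: LuminanceImage,
    g: float = 0.5,
    d0: float = 1.0,
    overlap: float = 0.5,
    n_theta: int | None = None,
) -> PoolingScheme:
    """Tile the visual field of ``image`` with eccentricity-scaled regions.

    Parameters
    ----------
    g
        Diameter growth rate per degree of eccentricity (dimensionless).
    d0
        Foveal floor: nominal diameter (deg) of the central region and of
        every region inside eccentricity ``~ d0 / g``.
    overlap
        Fraction of the window spacing occupied by the cosine cross-fade
        between neighboring regions (0 < overlap <= 1).
    n_theta
        Number of angular sectors per ring; default ``ceil(2*pi / g)``,
        which makes rings slightly elongated radially.
    """
    if not (g > 0 and d0 > 0):
        raise ValueError("g and d0 must be strictly positive")
    if not (0 < overlap <= 1):
        raise ValueError("overlap must lie in (0, 1]")
    if n_theta is None:
        n_theta = max(4, int(math.ceil(2 * math.pi / g)))

    ecc = eccentricity_map(image)
    max_ecc = float(ecc.max())
    warp = _RadialWarp(g, d0)
    if warp.fwd(max_ecc) < 0.75:
        raise ValueError(
            f"image too small to contain the foveal region: max eccentricity "
            f"{max_ecc:.3g} deg is inside the d0={d0} deg foveal floor"
        )

    h, w = image.shape
    fr, fc = image.fixation
    ang = np.degrees(
        np.arctan2(
            np.arange(h, dtype=np.float64)[:, None] - fr,
            np.arange(w, dtype=np.float64)[None, :] - fc,
        )
    )
    v = warp.fwd(ecc)

    # ring centers at v = 1, 2, ... while the window still reaches the image
    ks = []
    k = 1
    while k - (1 + overlap) / 2.0 <= warp.fwd(max_ecc):
        ks.append(k)
        k += 1

    # angular windows (degrees), circularly wrapped
    th_spacing = 360.0 / n_theta
    ang_windows = []
    for j in range(n_theta):
        d = (ang - j * th_spacing + 180.0) % 360.0 - 180.0
        ang_windows.append(_partition_window(d, th_spacing, overlap))

    regions: list[PoolingRegion] = []
    radial_sum = np.zeros_like(v)
    for k in ks:
        rad = _partition_window(v - k, 1.0, overlap)
        radial_sum += rad
        e_lo, e_c, e_hi = warp.inv(k - 0.5), warp.inv(k), warp.inv(k + 0.5)
        for j in range(n_theta):
            wmap = rad * ang_windows[j]
            if not np.any(wmap > 1e-12):
                continue
            regions.append(
                PoolingRegion(
                    id=f"ring{k}_sec{j}",
                    center_ecc=e_c,
                    center_angle=j * th_spacing,
                    nominal_diameter=e_hi - e_lo,
                    weights=wmap,
                    kind="ring",
                )
            )

    residual = np.clip(1.0 - radial_sum, 0.0, 1.0)
    inner = v < 1.0
    fovea = np.where(inner, residual, 0.0)
    outer = np.where(~inner, residual, 0.0)
    if np.any(fovea > 1e-12):  # the fixation may lie outside the image
        regions.insert(
            0,
            PoolingRegion(
                id="fovea",
                center_ecc=0.0,
                center_angle=0.0,
                nominal_diameter=d0,
                weights=fovea,
                kind="fovea",
            ),
        )
    if np.any(outer > 1e-12):
        regions.append(
            PoolingRegion(
                id="outer",
                center_ecc=warp.inv(ks[-1] + 1) if ks else max_ecc,
                center_angle=0.0,
                nominal_diameter=g * warp.inv(ks[-1] + 1) if ks else max_ecc,
                weights=outer,
                kind="outer",
            )
        )

    return PoolingScheme(
        regions=regions,
        g=g,
        d0=d0,
        overlap=overlap,
        n_theta=n_theta,
        ppd=image.ppd,
        fixation=image.fixation,
        shape=image.shape,
    )


def region_weights(scheme: PoolingScheme, region_id: str) -> np.ndarray:
    """Full-image weight map of one region (non-negative, zero off support)."""
    return scheme.region(region_id).weights


def linear_growth_audit(scheme: PoolingScheme) -> dict:
    """Regress nominal diameter on center eccentricity for ring regions
    entirely beyond the foveal floor; returns slope, intercept and R^2.
    """
    warp = _RadialWarp(scheme.g, scheme.d0)
    pts = {}
    for r in scheme.regions:
        if r.kind != "ring":
            continue
        # keep rings whose full half-power span lies in the logarithmic zone
        if warp.fwd(r.center_ecc) - 0.5 >= warp.v_star:
            pts[r.center_ecc] = r.nominal_diameter
    if len(pts) < 2:
        return {"slope": float("nan"), "intercept": float("nan"),
                "r_squared": float("nan"), "n_rings": len(pts)}
    x = np.array(sorted(pts))
    y = np.array([pts[e] for e in sorted(pts)])
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return {"slope": float(slope), "intercept": float(intercept),
            "r_squared": r2, "n_rings": len(x)}


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def save_scheme(scheme: PoolingScheme, json_path: str, h5_path: str | None = None):
    geom = {
        "g": scheme.g,
        "d0": scheme.d0,
        "overlap": scheme.overlap,
        "n_theta": scheme.n_theta,
        "ppd": scheme.ppd,
        "fixation": list(scheme.fixation),
        "shape": list(scheme.shape),
        "regions": [
            {
                "id": r.id,
                "kind": r.kind,
                "center_ecc_deg": r.center_ecc,
                "center_angle_deg": r.center_angle,
                "nominal_diameter_deg": r.nominal_diameter,
            }
            for r in scheme.regions
        ],
    }
    with open(json_path, "w") as fh:
        json.dump(geom, fh, indent=1)
    if h5_path is not None:
        import h5py

        with h5py.File(h5_path, "w") as f:
            for r in scheme.regions:
                f.create_dataset(r.id, data=r.weights.astype(np.float32),
                                 compression="gzip")


def plot_scheme(scheme: PoolingScheme, image: LuminanceImage | None = None, ax=None):
    """Overlay region outlines (half-power contours) on the image."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if image is not None:
        ax.imshow(image.pixels, cmap="gray", vmin=0, vmax=1)
    for r in scheme.regions:
        if r.kind != "ring":
            continue
        ax.contour(r.weights, levels=[0.5], colors="tab:orange", linewidths=0.8)
    ax.plot(scheme.fixation[1], scheme.fixation[0], "r+", markersize=10)
    ax.set_xticks([])
    ax.set_yticks([])
    return ax
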