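"""The summary-statistic encoding: per-region statistic vectors.

For every pooling region the encoder measures, with the region's smooth
weight map (renormalized to sum 1 at each pyramid scale):

* ``marginal`` — weighted mean, variance, skewness, kurtosis and the
  min/max of the pooled luminance;
* ``highpass`` — weighted variance of the highpass residual;
* ``lowpass_energy`` — weighted variance of the lowpass image at each
  of the S + 1 levels;
* ``band_energy`` — weighted mean and variance of every band magnitude;
* ``autocorr`` — central M x M weighted autocorrelation of the lowpass
  image at every scale (S + 1 maps), deduplicated by point symmetry;
* ``mag_corr_orientation`` — weighted correlations of oriented band
  magnitudes across orientation pairs within each scale;
* ``mag_corr_position`` — weighted autocorrelation (central M x M) of
  each band's magnitude;
* ``mag_corr_scale`` — weighted correlations of band magnitudes with the
  upsampled magnitudes of the adjacent coarser scale;
* ``phase_corr_scale`` — weighted correlation of each band's real part
  with the real part of the phase-doubled, upsampled coarser band.

All correlations are weighted Pearson correlations, hence in [-1, 1];
any correlation involving a signal whose weighted variance falls below
``VAR_EPS`` is defined to be 0 (the degenerate-variance rule), which
keeps statistic vectors comparable across regions.

Every statistic also has a hand-derived gradient with respect to the
underlying pyramid maps; the mongrel synthesizer drives these through
the pyramid adjoint to get image-domain gradients.  The forward values
and the gradients are computed by the same code path, so the synthesis
loss is exactly the encoding it claims to match.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from ttmlab.imagecore import LuminanceImage
from ttmlab.pooling import PoolingScheme
from ttmlab.pyramid import OrientedPyramid, build_pyramid

VAR_EPS = 1e-8  # weighted variance below this counts as degenerate
MAG_EPS = 1e-12  # smoothing of |z| = sqrt(re^2 + im^2 + MAG_EPS^2)
SUPPORT_EPS = 1e-12


# ---------------------------------------------------------------------------
# configuration and layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StatConfig:
    """Encoder configuration: pyramid scales/orientations and the
    autocorrelation neighborhood size M (odd)."""

    n_scales: int = 4
    n_orientations: int = 4
    acorr_m: int = 7

    def __post_init__(self):
        if self.acorr_m < 1 or self.acorr_m % 2 == 0:
            raise ValueError("acorr_m must be odd and >= 1")
        if self.n_scales < 1 or self.n_orientations < 1:
            raise ValueError("n_scales and n_orientations must be >= 1")


def _offsets(m: int) -> list[tuple[int, int]]:
    """Canonical half-plane offsets of the central m x m neighborhood.

    (0, 0) first, then one representative of each (d, -d) pair:
    (m*m + 1) // 2 offsets in total.
    """
    h = m // 2
    offs = [(0, 0)]
    for dy in range(0, h + 1):
        for dx in range(-h, h + 1):
            if dy == 0 and dx <= 0:
                continue
            offs.append((dy, dx))
    return offs


class StatLayout:
    """Entry registry for one configuration: group slices and labels.

    The total count is the closed form::

        6 + 1 + (S+1) + 2*S*O + (S+1)*A + S*O*(O-1)/2 + S*O*A + 2*(S-1)*O^2

    with ``A = (M^2 + 1) / 2`` unique central autocorrelation offsets
    (marginals, highpass variance, lowpass variances, band magnitude
    means/variances, then the correlation groups).
    """

    MARGINAL_NAMES = ("mean", "var", "skew", "kurt", "min", "max")

    def __init__(self, config: StatConfig):
        self.config = config
        S, O, M = config.n_scales, config.n_orientations, config.acorr_m
        self.offsets = _offsets(M)
        A = len(self.offsets)
        labels: list[str] = []
        groups: dict[str, slice] = {}

        def add_group(name: str, entry_labels: list[str]):
            start = len(labels)
            labels.extend(f"{name}:{el}" for el in entry_labels)
            groups[name] = slice(start, len(labels))

        add_group("marginal", list(self.MARGINAL_NAMES))
        add_group("highpass", ["var"])
        add_group("lowpass_energy", [f"low{k}:var" for k in range(S + 1)])
        add_group(
            "band_energy",
            [f"s{s}o{o}:{nm}" for s in range(S) for o in range(O)
             for nm in ("mag_mean", "mag_var")],
        )
        add_group(
            "autocorr",
            [f"low{k}@({dy},{dx})" for k in range(S + 1) for dy, dx in self.offsets],
        )
        add_group(
            "mag_corr_orientation",
            [f"s{s}:o{o1}xo{o2}" for s in range(S) for o1 in range(O)
             for o2 in range(o1 + 1, O)],
        )
        add_group(
            "mag_corr_position",
            [f"s{s}o{o}@({dy},{dx})" for s in range(S) for o in range(O)
             for dy, dx in self.offsets],
        )
        add_group(
            "mag_corr_scale",
            [f"s{s}o{o1}xs{s+1}o{o2}" for s in range(S - 1) for o1 in range(O)
             for o2 in range(O)],
        )
        add_group(
            "phase_corr_scale",
            [f"s{s}o{o1}xs{s+1}o{o2}" for s in range(S - 1) for o1 in range(O)
             for o2 in range(O)],
        )
        self.labels = labels
        self.groups = groups
        self.count = len(labels)
        self.n_acorr_offsets = A

    def group_names(self) -> list[str]:
        return list(self.groups)


@lru_cache(maxsize=8)
def get_layout(config: StatConfig) -> StatLayout:
    return StatLayout(config)


def stat_count(config: StatConfig | None = None) -> int:
    """Total number of statistics per pooling region (closed form)."""
    config = config or StatConfig()
    S, O, M = config.n_scales, config.n_orientations, config.acorr_m
    A = (M * M + 1) // 2
    return (6 + 1 + (S + 1) + 2 * S * O + (S + 1) * A
            + S * O * (O - 1) // 2 + S * O * A + 2 * (S - 1) * O * O)


# ---------------------------------------------------------------------------
# stat containers
# ---------------------------------------------------------------------------

@dataclass
class StatVector:
    """One region's statistics: a flat vector plus a validity mask.

    Entries are invalid (masked False, stored 0) when the region's support
    at the relevant scale is smaller than the M x M neighborhood.
    """

    values: np.ndarray
    valid: np.ndarray
    config: StatConfig
    region_id: str = ""

    @property
    def layout(self) -> StatLayout:
        return get_layout(self.config)

    @property
    def degenerate(self) -> bool:
        return not bool(self.valid.all())

    @property
    def count(self) -> int:
        return int(self.values.size)

    def group(self, name: str) -> np.ndarray:
        return self.values[self.layout.groups[name]]

    def __getattr__(self, name):
        if name in StatLayout.MARGINAL_NAMES:
            i = StatLayout.MARGINAL_NAMES.index(name)
            return float(self.values[i])
        raise AttributeError(name)


@dataclass
class StatField:
    """One StatVector per pooling region, plus provenance."""

    vectors: list
    region_ids: list
    config: StatConfig
    scheme_key: tuple = ()
    image_id: str = ""

    def __post_init__(self):
        if len(self.vectors) != len(self.region_ids):
            raise ValueError("vectors and region_ids differ in length")
        self._by_id = dict(zip(self.region_ids, self.vectors))

    def __len__(self):
        return len(self.vectors)

    def vector(self, region_id: str) -> StatVector:
        return self._by_id[region_id]

    def values_matrix(self) -> np.ndarray:
        return np.stack([v.values for v in self.vectors])

    def valid_matrix(self) -> np.ndarray:
        return np.stack([v.valid for v in self.vectors])


# ---------------------------------------------------------------------------
# weighted primitives (forward + gradient)
# ---------------------------------------------------------------------------

def _wmean(w, x):
    return float(np.sum(w * x))


def _wvar(w, x, mu):
    return float(np.sum(w * (x - mu) ** 2))


def _wcorr(w, a, b):
    """Weighted Pearson correlation; 0 under the degenerate-variance rule.

    Returns (value, cache) where cache holds what the backward pass needs.
    """
    ma = float(np.sum(w * a))
    mb = float(np.sum(w * b))
    da = a - ma
    db = b - mb
    va = float(np.sum(w * da * da))
    vb = float(np.sum(w * db * db))
    if va < VAR_EPS or vb < VAR_EPS:
        return 0.0, None
    cov = float(np.sum(w * da * db))
    denom = np.sqrt(va * vb)
    c = cov / denom
    return c, (da, db, va, vb, cov, denom)


def _wcorr_grad(w, cache, g):
    """Gradients (ga, gb) of g * corr w.r.t. a and b."""
    if cache is None:
        return None, None
    da, db, va, vb, cov, denom = cache
    ga = g * (w * db / denom - (cov / denom / va) * w * da)
    gb = g * (w * da / denom - (cov / denom / vb) * w * db)
    return ga, gb


def _shift_stack(padded: np.ndarray, m: int, offsets) -> tuple[np.ndarray, tuple]:
    """Stack of all shifted core windows of a padded crop: (A, n)."""
    hh = padded.shape[0] - 2 * m
    ww = padded.shape[1] - 2 * m
    sw = np.lib.stride_tricks.sliding_window_view(padded, (hh, ww))
    iy = np.array([m + dy for dy, _ in offsets])
    ix = np.array([m + dx for _, dx in offsets])
    return sw[iy, ix].reshape(len(offsets), hh * ww), (hh, ww)


def _batch_shift_corr(padded: np.ndarray, w_core: np.ndarray, m: int, offsets):
    """Weighted correlation of the core window against every shifted copy.

    ``vals[k]`` is corr(core, shift_k) under the degenerate-variance rule;
    ``cache`` feeds :func:`_batch_shift_corr_grad`.
    """
    B, (hh, ww) = _shift_stack(padded, m, offsets)
    wf = w_core.ravel()
    mu = B @ wf
    vb = (B * B) @ wf - mu * mu
    a = B[0]
    cov = B @ (wf * a) - mu[0] * mu
    ok = (vb >= VAR_EPS) & (vb[0] >= VAR_EPS)
    denom = np.sqrt(np.where(ok, vb[0] * vb, 1.0))
    vals = np.where(ok, cov / denom, 0.0)
    return vals, (B, wf, mu, vb, cov, ok, denom, hh, ww)


def _batch_shift_corr_grad(cache, padded_shape, m: int, offsets,
                           seeds: np.ndarray) -> np.ndarray | None:
    """dL/d(padded map) for seeds = dL/dcorr per offset."""
    B, wf, mu, vb, cov, ok, denom, hh, ww = cache
    s = np.where(ok, seeds, 0.0)
    if not np.any(s):
        return None
    a = B[0]
    alpha = s / denom
    beta = np.where(ok, s * cov / (denom * vb), 0.0)
    gamma = float(np.sum(s * cov / denom) / vb[0]) if vb[0] >= VAR_EPS else 0.0
    wda = wf * (a - mu[0])
    ga = wf * (alpha @ B - float(alpha @ mu)) - gamma * wda
    gb_all = alpha[:, None] * wda[None, :] - beta[:, None] * (
        wf[None, :] * (B - mu[:, None])
    )
    buf = np.zeros(padded_shape)
    buf[m:m + hh, m:m + ww] += ga.reshape(hh, ww)
    for k, (dy, dx) in enumerate(offsets):
        if alpha[k] == 0.0 and beta[k] == 0.0:
            continue
        buf[m + dy:m + dy + hh, m + dx:m + dx + ww] += gb_all[k].reshape(hh, ww)
    return buf


def _batch_cross_corr(F: np.ndarray, G: np.ndarray, wf: np.ndarray):
    """All-pairs weighted correlations between two map stacks (p,n) x (q,n)."""
    muF = F @ wf
    muG = G @ wf
    vF = (F * F) @ wf - muF * muF
    vG = (G * G) @ wf - muG * muG
    cov = (F * wf) @ G.T - np.outer(muF, muG)
    ok = (vF[:, None] >= VAR_EPS) & (vG[None, :] >= VAR_EPS)
    denom = np.sqrt(np.where(ok, np.outer(vF, vG), 1.0))
    C = np.where(ok, cov / denom, 0.0)
    return C, (muF, muG, vF, vG, cov, ok, denom)


def _batch_cross_corr_grad(F, G, wf, cache, seeds):
    """Gradients (gF, gG) for seeds = dL/dcorr over all pairs."""
    muF, muG, vF, vG, cov, ok, denom = cache
    S = np.where(ok, seeds, 0.0)
    if not np.any(S):
        return None, None
    A_ = S / denom
    T = S * cov / denom
    rF = np.where(vF >= VAR_EPS, T.sum(axis=1) / np.maximum(vF, VAR_EPS), 0.0)
    rG = np.where(vG >= VAR_EPS, T.sum(axis=0) / np.maximum(vG, VAR_EPS), 0.0)
    gF = wf[None, :] * (A_ @ G - (A_ @ muG)[:, None]) \
        - (wf[None, :] * (F - muF[:, None])) * rF[:, None]
    gG = wf[None, :] * (A_.T @ F - (A_.T @ muF)[:, None]) \
        - (wf[None, :] * (G - muG[:, None])) * rG[:, None]
    return gF, gG


# ---------------------------------------------------------------------------
# derived pyramid maps shared across regions
# ---------------------------------------------------------------------------

class DerivedMaps:
    """Magnitudes, real parts, and upsampled coarse-scale companions."""

    def __init__(self, pyr: OrientedPyramid):
        S, O = pyr.n_scales, pyr.n_orientations
        self.pyr = pyr
        self.mag = [
            [np.sqrt(np.real(b) ** 2 + np.imag(b) ** 2 + MAG_EPS**2) for b in lvl]
            for lvl in pyr.bands
        ]
        self.re = [[np.real(b) for b in lvl] for lvl in pyr.bands]
        ones = np.ones((2, 2))
        # fine-resolution companions of scale s+1, for s = 0..S-2
        self.up_mag = [
            [np.kron(self.mag[s + 1][o], ones) for o in range(O)]
            for s in range(S - 1)
        ]
        self.pd_up = []
        self._pd_cache = []
        for s in range(S - 1):
            row, cache_row = [], []
            for o in range(O):
                z = pyr.bands[s + 1][o]
                a, b = np.real(z), np.imag(z)
                r = self.mag[s + 1][o]
                q = (a * a - b * b) / r  # Re(z^2 / |z|): phase-doubled
                row.append(np.kron(q, ones))
                cache_row.append((a, b, r, q))
            self.pd_up.append(row)
            self._pd_cache.append(cache_row)


def _block_sum(x: np.ndarray) -> np.ndarray:
    h, w = x.shape
    return x.reshape(h // 2, 2, w // 2, 2).sum(axis=(1, 3))


def _block_mean(x: np.ndarray) -> np.ndarray:
    return _block_sum(x) / 4.0


# ---------------------------------------------------------------------------
# per-region pooling contexts
# ---------------------------------------------------------------------------

class RegionPools:
    """A region's weight maps, crops and validity at every pyramid level."""

    def __init__(self, weights: np.ndarray, n_levels: int, m_half: int):
        w = np.asarray(weights, dtype=np.float64)
        tot = w.sum()
        if not (tot > 0):
            raise ValueError("region weight map sums to zero")
        w = w / tot
        self.m = m_half
        self.rows: list[np.ndarray] = []
        self.cols: list[np.ndarray] = []
        self.w_core: list[np.ndarray] = []
        self.n_support: list[int] = []
        for k in range(n_levels):
            sup_r, sup_c = np.nonzero(w > SUPPORT_EPS)
            r0, r1 = int(sup_r.min()), int(sup_r.max()) + 1
            c0, c1 = int(sup_c.min()), int(sup_c.max()) + 1
            h, wd = w.shape
            self.rows.append(np.arange(r0 - m_half, r1 + m_half) % h)
            self.cols.append(np.arange(c0 - m_half, c1 + m_half) % wd)
            wc = w[r0:r1, c0:c1]
            wc = wc / wc.sum()
            self.w_core.append(wc)
            # Kish effective sample size: pixels that carry real mass
            self.n_support.append(float(1.0 / np.sum(wc**2)))
            if k < n_levels - 1:
                w = _block_mean(w)
                w = w / w.sum()

    def crop(self, level: int, arr: np.ndarray) -> np.ndarray:
        """Padded (wrap-indexed) crop of a level-``level`` map."""
        return arr[np.ix_(self.rows[level], self.cols[level])]

    def core(self, padded: np.ndarray) -> np.ndarray:
        m = self.m
        return padded[m:padded.shape[0] - m, m:padded.shape[1] - m]

    def shifted(self, padded: np.ndarray, dy: int, dx: int) -> np.ndarray:
        m = self.m
        return padded[m + dy:padded.shape[0] - m + dy,
                      m + dx:padded.shape[1] - m + dx]

    def valid_at(self, level: int, m_full: int) -> bool:
        """Correlation statistics need an effective support of at least
        the M x M neighborhood at this level."""
        return self.n_support[level] >= m_full * m_full


# ---------------------------------------------------------------------------
# the engine
# ---------------------------------------------------------------------------

class StatEngine:
    """Computes statistic vectors (and optionally their gradients).

    The engine is constructed once per (pyramid config, pooling scheme)
    and reused; it holds the per-region crop indices.
    """

    def __init__(self, config: StatConfig, region_weight_maps: list[np.ndarray]):
        self.config = config
        self.layout = get_layout(config)
        m_half = config.acorr_m // 2
        n_levels = config.n_scales + 1
        self.pools = [RegionPools(w, n_levels, m_half) for w in region_weight_maps]

    # -- forward ---------------------------------------------------------

    def region_stats(self, derived: DerivedMaps, i_region: int,
                     grad_sink: "GradSink | None" = None) -> tuple[np.ndarray, np.ndarray]:
        """Statistics (values, valid) of one region.

        When ``grad_sink`` is given, its ``seed`` array (dL/dstat) is
        consumed and gradients are accumulated into the sink's map-domain
        gradient buffers.
        """
        cfg = self.config
        lay = self.layout
        S, O, M = cfg.n_scales, cfg.n_orientations, cfg.acorr_m
        pyr = derived.pyr
        pools = self.pools[i_region]
        vals = np.zeros(lay.count)
        valid = np.ones(lay.count, dtype=bool)
        idx = 0
        gs = grad_sink

        # marginal, on the source image
        img = pyr.source
        if img is None:
            raise ValueError("pyramid lacks its source image (needed for marginals)")
        w0 = pools.w_core[0]
        xpad = pools.crop(0, img)
        x = pools.core(xpad)
        mu = _wmean(w0, x)
        v = _wvar(w0, x, mu)
        if v >= VAR_EPS:
            d = x - mu
            mu3 = float(np.sum(w0 * d**3))
            mu4 = float(np.sum(w0 * d**4))
            skew = mu3 / v**1.5
            kurt = mu4 / v**2
        else:
            skew = kurt = 0.0
        wsup = w0 > SUPPORT_EPS
        vals[idx:idx + 6] = [mu, v, skew, kurt,
                             float(x[wsup].min()), float(x[wsup].max())]
        if gs is not None:
            gs.seed_range(idx, idx + 6, vals)
            g_m, g_v, g_s, g_k = gs.seed[idx:idx + 4]
            gx = g_m * w0 + g_v * 2 * w0 * (x - mu)
            if v >= VAR_EPS and (g_s or g_k):
                d = x - mu
                dmu3 = 3 * w0 * (d**2 - v)
                dmu4 = 4 * w0 * (d**3 - mu3)
                dv = 2 * w0 * d
                gx = gx + g_s * (dmu3 / v**1.5 - 1.5 * mu3 / v**2.5 * dv)
                gx = gx + g_k * (dmu4 / v**2 - 2 * mu4 / v**3 * dv)
            gs.add(("img",), pools, 0, gx, core_only=True)
        idx += 6

        # highpass variance
        hp = pools.core(pools.crop(0, pyr.highpass))
        mu_h = _wmean(w0, hp)
        v_h = _wvar(w0, hp, mu_h)
        vals[idx] = v_h
        if gs is not None:
            gs.seed_range(idx, idx + 1, vals)
            gs.add(("high",), pools, 0,
                   gs.seed[idx] * 2 * w0 * (hp - mu_h), core_only=True)
        idx += 1

        A = lay.n_acorr_offsets

        def block_seeds(i0: int, i1: int) -> np.ndarray | None:
            """Seeds (dL/dstat) of a just-filled block; None without sink."""
            if gs is None:
                return None
            gs.seed_range(i0, i1, vals)
            return gs.seed[i0:i1]

        # lowpass variances
        for k in range(S + 1):
            wk = pools.w_core[k]
            lc = pools.core(pools.crop(k, pyr.lowpass_maps[k]))
            mu_l = _wmean(wk, lc)
            vals[idx] = _wvar(wk, lc, mu_l)
            if gs is not None:
                gs.seed_range(idx, idx + 1, vals)
                if gs.seed[idx] != 0.0:
                    gs.add(("low", k), pools, k,
                           gs.seed[idx] * 2 * wk * (lc - mu_l), core_only=True)
            idx += 1

        # band magnitude means and variances
        for s in range(S):
            wk = pools.w_core[s]
            for o in range(O):
                mc = pools.core(pools.crop(s, derived.mag[s][o]))
                mu_m = _wmean(wk, mc)
                vals[idx] = mu_m
                vals[idx + 1] = _wvar(wk, mc, mu_m)
                if gs is not None:
                    gs.seed_range(idx, idx + 2, vals)
                    g_mu, g_v = gs.seed[idx], gs.seed[idx + 1]
                    if g_mu != 0.0 or g_v != 0.0:
                        gs.add(("mag", s, o), pools, s,
                               g_mu * wk + g_v * 2 * wk * (mc - mu_m),
                               core_only=True)
                idx += 2

        # lowpass autocorrelations
        for k in range(S + 1):
            if not pools.valid_at(k, M):
                valid[idx:idx + A] = False
                idx += A
                continue
            lpad = pools.crop(k, pyr.lowpass_maps[k])
            cvals, cache = _batch_shift_corr(lpad, pools.w_core[k], pools.m,
                                             lay.offsets)
            vals[idx:idx + A] = cvals
            seeds = block_seeds(idx, idx + A)
            if seeds is not None and np.any(seeds):
                gbuf = _batch_shift_corr_grad(cache, lpad.shape, pools.m,
                                              lay.offsets, seeds)
                gs.add(("low", k), pools, k, gbuf, core_only=False)
            idx += A

        # magnitude cross-orientation correlations (upper-triangle pairs)
        iu = np.triu_indices(O, k=1)
        for s in range(S):
            if not pools.valid_at(s, M):
                n_pairs = O * (O - 1) // 2
                valid[idx:idx + n_pairs] = False
                idx += n_pairs
                continue
            wf = pools.w_core[s].ravel()
            mpads = [pools.crop(s, derived.mag[s][o]) for o in range(O)]
            Mstack = np.stack([pools.core(p).ravel() for p in mpads])
            n_pairs = O * (O - 1) // 2
            C, cache = _batch_cross_corr(Mstack, Mstack, wf)
            vals[idx:idx + n_pairs] = C[iu]
            seeds = block_seeds(idx, idx + n_pairs)
            if seeds is not None and np.any(seeds):
                Smat = np.zeros((O, O))
                Smat[iu] = seeds
                gF, gG = _batch_cross_corr_grad(Mstack, Mstack, wf, cache, Smat)
                if gF is not None:
                    core_shape = pools.core(mpads[0]).shape
                    for o in range(O):
                        gs.add(("mag", s, o), pools, s,
                               (gF[o] + gG[o]).reshape(core_shape), core_only=True)
            idx += n_pairs

        # magnitude autocorrelation (position)
        for s in range(S):
            okp = pools.valid_at(s, M)
            wk = pools.w_core[s]
            for o in range(O):
                if not okp:
                    valid[idx:idx + A] = False
                    idx += A
                    continue
                mpad = pools.crop(s, derived.mag[s][o])
                cvals, cache = _batch_shift_corr(mpad, wk, pools.m, lay.offsets)
                vals[idx:idx + A] = cvals
                seeds = block_seeds(idx, idx + A)
                if seeds is not None and np.any(seeds):
                    gbuf = _batch_shift_corr_grad(cache, mpad.shape, pools.m,
                                                  lay.offsets, seeds)
                    gs.add(("mag", s, o), pools, s, gbuf, core_only=False)
                idx += A

        # magnitude correlation across adjacent scales + phase correlation
        for s in range(S - 1):
            if not pools.valid_at(s, M):
                valid[idx:idx + O * O] = False
                idx += O * O
                continue
            wk = pools.w_core[s]
            wf = wk.ravel()
            core_shape = pools.w_core[s].shape
            Fm = np.stack([
                pools.core(pools.crop(s, derived.mag[s][o])).ravel()
                for o in range(O)
            ])
            Gm = np.stack([
                pools.core(pools.crop(s, derived.up_mag[s][o])).ravel()
                for o in range(O)
            ])
            C, cache = _batch_cross_corr(Fm, Gm, wf)
            vals[idx:idx + O * O] = C.ravel()
            seeds = block_seeds(idx, idx + O * O)
            if seeds is not None and np.any(seeds):
                gF, gG = _batch_cross_corr_grad(Fm, Gm, wf, cache,
                                                seeds.reshape(O, O))
                if gF is not None:
                    for o in range(O):
                        gs.add(("mag", s, o), pools, s,
                               gF[o].reshape(core_shape), core_only=True)
                        gs.add(("up_mag", s, o), pools, s,
                               gG[o].reshape(core_shape), core_only=True)
            idx += O * O

        for s in range(S - 1):
            if not pools.valid_at(s, M):
                valid[idx:idx + O * O] = False
                idx += O * O
                continue
            wk = pools.w_core[s]
            wf = wk.ravel()
            core_shape = pools.w_core[s].shape
            Fr = np.stack([
                pools.core(pools.crop(s, derived.re[s][o])).ravel()
                for o in range(O)
            ])
            Gp = np.stack([
                pools.core(pools.crop(s, derived.pd_up[s][o])).ravel()
                for o in range(O)
            ])
            C, cache = _batch_cross_corr(Fr, Gp, wf)
            vals[idx:idx + O * O] = C.ravel()
            seeds = block_seeds(idx, idx + O * O)
            if seeds is not None and np.any(seeds):
                gF, gG = _batch_cross_corr_grad(Fr, Gp, wf, cache,
                                                seeds.reshape(O, O))
                if gF is not None:
                    for o in range(O):
                        gs.add(("re", s, o), pools, s,
                               gF[o].reshape(core_shape), core_only=True)
                        gs.add(("pd_up", s, o), pools, s,
                               gG[o].reshape(core_shape), core_only=True)
            idx += O * O

        assert idx == lay.count
        return vals, valid

    def all_stats(self, derived: DerivedMaps) -> tuple[np.ndarray, np.ndarray]:
        out_v, out_m = [], []
        for i in range(len(self.pools)):
            v, m = self.region_stats(derived, i)
            out_v.append(v)
            out_m.append(m)
        return np.stack(out_v), np.stack(out_m)


class GradSink:
    """Accumulates map-domain gradients during a backward pass.

    ``seed`` is dL/dstat for the region currently being processed; the
    buffers hold dL/dmap for every pyramid-derived map.
    """

    def __init__(self, derived: DerivedMaps, target: np.ndarray | None = None,
                 lam: np.ndarray | None = None):
        pyr = derived.pyr
        S, O = pyr.n_scales, pyr.n_orientations
        self.derived = derived
        self.seed: np.ndarray | None = None
        # autoseed mode: dL/dstat = 2 * lam * (stat - target) for the
        # squared-error synthesis objective, filled in as values appear
        self.target = target
        self.lam = lam
        self.autoseed = target is not None
        self.g_img = np.zeros(pyr.source_shape)
        self.g_high = np.zeros(pyr.source_shape)
        self.g_low = [np.zeros_like(lm) for lm in pyr.lowpass_maps]
        self.g_mag = [[np.zeros_like(derived.mag[s][o]) for o in range(O)]
                      for s in range(S)]
        self.g_re = [[np.zeros_like(derived.re[s][o]) for o in range(O)]
                     for s in range(S)]
        self.g_up_mag = [[np.zeros_like(derived.up_mag[s][o]) for o in range(O)]
                         for s in range(S - 1)]
        self.g_pd_up = [[np.zeros_like(derived.pd_up[s][o]) for o in range(O)]
                        for s in range(S - 1)]

    def begin_region(self, i_region: int, n_stats: int):
        """Reset the per-region seed vector (autoseed mode)."""
        self._region = i_region
        self.seed = np.zeros(n_stats)

    def seed_one(self, idx: int, val: float) -> float:
        if self.autoseed:
            self.seed[idx] = 2.0 * self.lam[self._region, idx] * (
                val - self.target[self._region, idx])
        return self.seed[idx]

    def seed_range(self, i0: int, i1: int, vals: np.ndarray) -> None:
        if self.autoseed:
            self.seed[i0:i1] = 2.0 * self.lam[self._region, i0:i1] * (
                vals[i0:i1] - self.target[self._region, i0:i1])

    def _target(self, key):
        kind = key[0]
        if kind == "img":
            return self.g_img
        if kind == "high":
            return self.g_high
        if kind == "low":
            return self.g_low[key[1]]
        if kind == "mag":
            return self.g_mag[key[1]][key[2]]
        if kind == "re":
            return self.g_re[key[1]][key[2]]
        if kind == "up_mag":
            return self.g_up_mag[key[1]][key[2]]
        if kind == "pd_up":
            return self.g_pd_up[key[1]][key[2]]
        raise KeyError(key)

    def add(self, key, pools: RegionPools, level: int, buf: np.ndarray,
            core_only: bool):
        if buf is None:
            return
        tgt = self._target(key)
        m = pools.m
        if core_only:
            rows = pools.rows[level][m:pools.rows[level].size - m]
            cols = pools.cols[level][m:pools.cols[level].size - m]
        else:
            rows = pools.rows[level]
            cols = pools.cols[level]
        np.add.at(tgt, (rows[:, None], cols[None, :]), buf)

    def to_image_grad(self, ops) -> np.ndarray:
        """Collapse all map gradients into an image-domain gradient."""
        derived = self.derived
        pyr = derived.pyr
        S, O = pyr.n_scales, pyr.n_orientations
        # fold upsampled companions back onto the coarse maps
        for s in range(S - 1):
            for o in range(O):
                self.g_mag[s + 1][o] += _block_sum(self.g_up_mag[s][o])
                gq = _block_sum(self.g_pd_up[s][o])
                a, b, r, q = derived._pd_cache[s][o]
                ga = gq * (2 * a / r - q * a / (r * r))
                gb = gq * (-2 * b / r - q * b / (r * r))
                z = pyr.bands[s + 1][o]
                self.g_re[s + 1][o] += ga
                # imaginary-part gradient is carried separately below
                if not hasattr(self, "_g_im"):
                    self._g_im = [[np.zeros_like(derived.re[t][u])
                                   for u in range(O)] for t in range(S)]
                self._g_im[s + 1][o] += gb
        if not hasattr(self, "_g_im"):
            self._g_im = [[np.zeros_like(derived.re[t][u])
                           for u in range(O)] for t in range(S)]
        # magnitude -> complex band
        band_grads = []
        for s in range(S):
            row = []
            for o in range(O):
                z = pyr.bands[s][o]
                r = derived.mag[s][o]
                gre = self.g_re[s][o] + self.g_mag[s][o] * np.real(z) / r
                gim = self._g_im[s][o] + self.g_mag[s][o] * np.imag(z) / r
                row.append(gre + 1j * gim)
            band_grads.append(row)
        gx = ops.adjoint(band_grads, self.g_low, self.g_high)
        return gx + self.g_img


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def compute_region_stats(
    pyramid: OrientedPyramid,
    weights: np.ndarray,
    config: StatConfig | None = None,
) -> StatVector:
    """Statistic vector of a single pooling region.

    ``weights`` is a non-negative map over the source image (it is
    renormalized to sum 1 internally and downsampled per scale).
    """
    config = config or StatConfig(n_scales=pyramid.n_scales,
                                  n_orientations=pyramid.n_orientations)
    if (config.n_scales, config.n_orientations) != (
            pyramid.n_scales, pyramid.n_orientations):
        raise ValueError("config does not match the pyramid's S, O")
    if weights.shape != pyramid.source_shape:
        raise ValueError("weight map shape does not match the image")
    engine = StatEngine(config, [weights])
    derived = DerivedMaps(pyramid)
    vals, valid = engine.region_stats(derived, 0)
    return StatVector(vals, valid, config)


def compute_stat_field(
    image: LuminanceImage,
    scheme: PoolingScheme,
    config: StatConfig | None = None,
) -> StatField:
    """The full peripheral encoding: one StatVector per pooling region."""
    config = config or StatConfig()
    if scheme.shape != image.shape:
        raise ValueError(
            f"scheme was built for shape {scheme.shape}, image is {image.shape}"
        )
    if abs(scheme.ppd - image.ppd) > 1e-9 or (
        abs(scheme.fixation[0] - image.fixation[0]) > 1e-6
        or abs(scheme.fixation[1] - image.fixation[1]) > 1e-6
    ):
        raise ValueError("scheme geometry (ppd / fixation) does not match image")
    pyr = build_pyramid(image, config.n_scales, config.n_orientations)
    engine = StatEngine(config, [r.weights for r in scheme.regions])
    derived = DerivedMaps(pyr)
    vecs = []
    for i, r in enumerate(scheme.regions):
        vals, valid = engine.region_stats(derived, i)
        vecs.append(StatVector(vals, valid, config, region_id=r.id))
    return StatField(
        vectors=vecs,
        region_ids=[r.id for r in scheme.regions],
        config=config,
        scheme_key=scheme.geometry_key(),
    )


def compute_stat_field_per_channel(
    image: LuminanceImage,
    scheme: PoolingScheme,
    config: StatConfig | None = None,
) -> dict:
    """Opt-in color path: one StatField per R/G/B plane.

    The default encoding is luminance-only; this runs the identical
    encoder on each stored color plane (the image must have been
    converted with ``keep_color=True``).
    """
    if image.color_planes is None:
        raise ValueError("image carries no color planes; convert with keep_color")
    out = {}
    for i, name in enumerate("RGB"):
        chan = LuminanceImage(np.clip(image.color_planes[:, :, i], 0, 1),
                              image.ppd, image.fixation)
        out[name] = compute_stat_field(chan, scheme, config)
    return out


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_stat_field(field_: StatField, path: str) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["n_scales"] = field_.config.n_scales
        f.attrs["n_orientations"] = field_.config.n_orientations
        f.attrs["acorr_m"] = field_.config.acorr_m
        f.attrs["image_id"] = field_.image_id
        f.attrs["scheme_key"] = repr(field_.scheme_key)
        f.create_dataset("values", data=field_.values_matrix())
        f.create_dataset("valid", data=field_.valid_matrix())
        f.create_dataset(
            "region_ids",
            data=np.array(field_.region_ids, dtype=h5py.string_dtype()),
        )


def load_stat_field(path: str) -> StatField:
    import h5py
    from ast import literal_eval

    with h5py.File(path, "r") as f:
        config = StatConfig(
            n_scales=int(f.attrs["n_scales"]),
            n_orientations=int(f.attrs["n_orientations"]),
            acorr_m=int(f.attrs["acorr_m"]),
        )
        values = f["values"][()]
        valid = f["valid"][()]
        ids = [s.decode() for s in f["region_ids"][()]]
        key = literal_eval(f.attrs["scheme_key"])
    vecs = [StatVector(values[i], valid[i].astype(bool), config, region_id=ids[i])
            for i in range(len(ids))]
    return StatField(vectors=vecs, region_ids=ids, config=config, scheme_key=key)


def export_csv_summary(field_: StatField, path: str) -> None:
    """Per-region scalar summary (marginals + group RMS) as CSV."""
    lay = get_layout(field_.config)
    cols = ["region_id", "mean", "var", "skew", "kurt", "min", "max"] + [
        f"rms_{g}" for g in lay.group_names()
    ]
    with open(path, "w") as fh:
        fh.write(",".join(cols) + "\n")
        for v in field_.vectors:
            row = [v.region_id] + [f"{x:.6g}" for x in v.values[:6]]
            for gname in lay.group_names():
                gv = v.group(gname)
                row.append(f"{float(np.sqrt(np.mean(gv ** 2))):.6g}")
            fh.write(",".join(row) + "\n")
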