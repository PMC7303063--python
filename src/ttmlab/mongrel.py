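"""Mongrel synthesis: images that match a target statistic field but are
otherwise random.

A mongrel visualizes what the peripheral encoding keeps and loses: it
has (approximately) the same per-region summary statistics as the
original stimulus for a given fixation, with everything the statistics
do not constrain filled in by noise.  Many different mongrels share one
encoding — they are metamers of the model.

Synthesis minimizes the squared statistic error

    L(x) = sum_regions sum_stats  lam * (stat(x) - target)^2

directly over image pixels with box constraints x in [0, 1], using
L-BFGS-B with the encoder's hand-derived analytic gradients (statistic
-> pyramid maps -> image via the pyramid adjoint).  Per-statistic
weights ``lam`` normalize each statistic group by its natural scale so
no group dominates.  The optimizer runs in ``iters`` outer rounds of a
few quasi-Newton steps each; after each round the per-group relative
residual is recorded, giving the residual trace.

Residual convention: correlation-valued groups are already on a unit
scale, so their residual is the RMS deviation; dimensionful groups
(marginal moments, highpass variance) are normalized by the RMS of
their target values.  ``converged`` means every group residual is at or
below ``tol``.

The fovea is normally "seen": when the source pixels are available
(:func:`mongrelize`), pixels on the foveal plateau are clamped to the
original; :func:`synthesize_mongrel` on a bare target synthesizes the
fovea like any other region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from ttmlab.imagecore import LuminanceImage
from ttmlab.pooling import PoolingScheme, build_pooling_scheme
from ttmlab.statistics import (
    DerivedMaps,
    GradSink,
    StatConfig,
    StatEngine,
    StatField,
    compute_stat_field,
    get_layout,
)
from ttmlab.pyramid import get_ops

#: groups whose entries are correlations (unit scale -> absolute RMS residual)
CORRELATION_GROUPS = (
    "autocorr",
    "mag_corr_orientation",
    "mag_corr_position",
    "mag_corr_scale",
    "phase_corr_scale",
)


@dataclass
class MongrelResult:
    image: LuminanceImage
    residual_trace: list  # per outer iteration: {group: relative error}
    converged: bool
    seed: int
    iterations: int
    loss: float = np.nan

    def final_residuals(self) -> dict:
        return self.residual_trace[-1] if self.residual_trace else {}


def _group_scales(layout, targets: np.ndarray, valid: np.ndarray) -> dict:
    """Natural scale of each statistic group (for weighting and residuals)."""
    scales = {}
    for name, sl in layout.groups.items():
        if name in CORRELATION_GROUPS:
            scales[name] = 1.0
        else:
            t = targets[:, sl][valid[:, sl]]
            rms = float(np.sqrt(np.mean(t**2))) if t.size else 1.0
            scales[name] = max(rms, 1e-3)
    return scales


def _entry_weights(layout, targets, valid, scales) -> np.ndarray:
    """Per-(region, stat) loss weights: 1 / (n_group * scale^2); min/max
    marginals carry no gradient and get weight 0."""
    n_regions, n_stats = targets.shape
    lam = np.zeros((n_regions, n_stats))
    for name, sl in layout.groups.items():
        n_g = sl.stop - sl.start
        lam[:, sl] = 1.0 / (n_g * scales[name] ** 2)
    i_min = layout.labels.index("marginal:min")
    i_max = layout.labels.index("marginal:max")
    lam[:, i_min] = 0.0
    lam[:, i_max] = 0.0
    lam[~valid] = 0.0
    return lam


def _residuals(layout, vals, targets, valid, scales,
               region_masses: np.ndarray | None = None) -> dict:
    """Per-group relative residual, with regions weighted by pixel mass.

    Statistics of a region covering six pixels are sampling noise; the
    audit therefore weights each region's contribution by the number of
    pixels it pools over.
    """
    n_regions = vals.shape[0]
    if region_masses is None:
        rw = np.ones(n_regions)
    else:
        rw = np.asarray(region_masses, dtype=np.float64)
    out = {}
    for name, sl in layout.groups.items():
        m = valid[:, sl]
        if not m.any():
            out[name] = 0.0
            continue
        d2 = (vals[:, sl] - targets[:, sl]) ** 2
        num = float(np.sum(rw[:, None] * d2 * m))
        den = float(np.sum(rw[:, None] * m))
        out[name] = float(np.sqrt(num / den) / scales[name])
    return out


def _spectral_init(rng, shape, ops, layout, config, targets, masses, mu0, var0):
    """White noise reshaped so each pyramid band carries the target's
    (mass-weighted global) energy — a spectrally plausible starting point."""
    S, O = config.n_scales, config.n_orientations
    w_r = masses / masses.sum()

    def gidx(label):
        return layout.labels.index(label)

    x = rng.standard_normal(shape)
    pyr = ops.forward(x)
    for s in range(S):
        for o in range(O):
            t_mean = float(w_r @ targets[:, gidx(f"band_energy:s{s}o{o}:mag_mean")])
            t_var = float(w_r @ targets[:, gidx(f"band_energy:s{s}o{o}:mag_var")])
            t_energy = max(t_var + t_mean**2, 0.0)
            cur = float(np.mean(np.abs(pyr.bands[s][o]) ** 2)) + 1e-12
            pyr.bands[s][o] = pyr.bands[s][o] * np.sqrt(t_energy / cur)
    t_lo = float(w_r @ targets[:, gidx(f"lowpass_energy:low{S}:var")])
    lo = pyr.lowpass
    cur = float(np.var(lo)) + 1e-12
    pyr.lowpass = (lo - lo.mean()) * np.sqrt(max(t_lo, 0.0) / cur) + mu0
    pyr.lowpass_maps[-1] = pyr.lowpass
    t_hi = float(w_r @ targets[:, gidx("highpass:var")])
    cur = float(np.var(pyr.highpass)) + 1e-12
    pyr.highpass = pyr.highpass * np.sqrt(max(t_hi, 0.0) / cur)
    x = ops.reconstruct(pyr)
    # keep the global marginal sensible after the reshaping
    x = (x - x.mean()) / max(x.std(), 1e-6) * np.sqrt(max(var0, 1e-6)) + mu0
    return np.clip(x, 0.0, 1.0)


def synthesize_mongrel(
    target: StatField,
    scheme: PoolingScheme,
    seed: int = 0,
    iters: int = 50,
    tol: float = 0.05,
    *,
    fovea_image: np.ndarray | None = None,
    inner_steps: int = 8,
    adapt_every: int = 10,
    verbose: bool = False,
) -> MongrelResult:
    """Synthesize an image matching ``target`` under ``scheme``.

    Deterministic: identical (target, scheme, seed, config) reproduce the
    result bit-exactly.  Non-convergence is reported via the ``converged``
    flag, not an exception.

    Parameters
    ----------
    fovea_image
        Optional source pixels; where the foveal region's weight exceeds
        1/2 the output is clamped to them (the fovea is "seen").
    """
    if target.scheme_key and target.scheme_key != scheme.geometry_key():
        raise ValueError("target StatField was computed under a different scheme")
    if list(target.region_ids) != [r.id for r in scheme.regions]:
        raise ValueError("target regions do not match the pooling scheme")

    config = target.config
    layout = get_layout(config)
    targets = target.values_matrix()
    valid = target.valid_matrix()
    # skewness/kurtosis are undefined for (near-)constant target regions;
    # drop them from the objective and the residual audit there
    i_var = layout.labels.index("marginal:var")
    i_skew = layout.labels.index("marginal:skew")
    i_kurt = layout.labels.index("marginal:kurt")
    near_const = targets[:, i_var] < 1e-6
    valid = valid.copy()
    valid[near_const, i_skew] = False
    valid[near_const, i_kurt] = False
    scales = _group_scales(layout, targets, valid)
    lam = _entry_weights(layout, targets, valid, scales)

    shape = scheme.shape
    ops = get_ops(shape, config.n_scales, config.n_orientations)
    engine = StatEngine(config, [r.weights for r in scheme.regions])

    # seeded initialization: white noise spectrally shaped to the target's
    # global (mass-weighted) band energies, matched in mean and variance
    masses = np.array([r.weights.sum() for r in scheme.regions])
    means = targets[:, layout.labels.index("marginal:mean")]
    varis = targets[:, layout.labels.index("marginal:var")]
    mu0 = float(np.sum(masses * means) / masses.sum())
    var0 = float(np.sum(masses * (varis + means**2)) / masses.sum() - mu0**2)
    rng = np.random.default_rng(seed)
    x = _spectral_init(rng, shape, ops, layout, config, targets, masses, mu0, var0)

    lb = np.zeros(x.size)
    ub = np.ones(x.size)
    if fovea_image is not None:
        fov = scheme.regions[0]
        if fov.kind != "fovea":
            raise ValueError("scheme has no foveal region")
        clamp = (fov.weights > 0.5).ravel()
        src = np.asarray(fovea_image, dtype=np.float64).ravel()
        lb[clamp] = src[clamp]
        ub[clamp] = src[clamp]
        x = x.ravel()
        x[clamp] = src[clamp]
        x = x.reshape(shape)

    n_regions = len(scheme.regions)

    def loss_grad(flat: np.ndarray):
        img = flat.reshape(shape)
        pyr = ops.forward(img)
        derived = DerivedMaps(pyr)
        sink = GradSink(derived, target=targets, lam=lam)
        total = 0.0
        for i in range(n_regions):
            sink.begin_region(i, layout.count)
            vals, _ = engine.region_stats(derived, i, grad_sink=sink)
            d = vals - targets[i]
            total += float(np.sum(lam[i] * d * d))
        g = sink.to_image_grad(ops)
        return total, g.ravel()

    def measure(flat: np.ndarray):
        img = flat.reshape(shape)
        pyr = ops.forward(img)
        derived = DerivedMaps(pyr)
        vals, msk = engine.all_stats(derived)
        return _residuals(layout, vals, targets, valid & msk, scales, masses)

    # quasi-Newton descent in blocks; the callback records the residual
    # trace every ``inner_steps`` iterations and stops early once within
    # tolerance.  Between blocks the per-group weights are boosted in
    # proportion to how far each group still is from tolerance (a penalty
    # re-weighting that keeps one stubborn group from being ignored).
    trace: list[dict] = []
    state = {"nit": 0}
    bounds = list(zip(lb, ub))
    lam0 = lam
    flat = x.ravel()
    fun = np.nan
    n_blocks = max(1, iters // adapt_every)
    rounds_per_block = adapt_every

    def callback(v):
        state["nit"] += 1
        if state["nit"] % inner_steps == 0:
            resid = measure(v)
            trace.append(resid)
            if verbose:
                worst = max(resid, key=resid.get)
                print(f"round {len(trace):3d}  worst {worst} {resid[worst]:.4f}")
            if max(resid.values()) <= tol:
                state["x"] = np.array(v, copy=True)
                raise StopIteration

    done = False
    for blk in range(n_blocks):
        rounds_left = min(rounds_per_block, iters - blk * rounds_per_block)
        if rounds_left <= 0:
            break
        try:
            res = minimize(
                loss_grad,
                flat,
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                callback=callback,
                options={"maxiter": rounds_left * inner_steps, "ftol": 1e-16,
                         "gtol": 1e-14, "maxcor": 30},
            )
            flat = np.clip(res.x, lb, ub)
            fun = float(res.fun)
        except StopIteration:  # early convergence inside the callback
            if "x" in state:
                flat = np.clip(state["x"], lb, ub)
            done = True
        if done or (trace and max(trace[-1].values()) <= tol):
            done = True
            break
        # boost lagging groups for the next block
        if blk < n_blocks - 1 and trace:
            resid = trace[-1]
            lam = lam0.copy()
            for name, sl in layout.groups.items():
                boost = min(max(resid[name] / tol, 1.0), 30.0) ** 2
                lam[:, sl] *= boost

    resid = measure(flat)
    if not trace or trace[-1] != resid:
        trace.append(resid)
    converged = max(resid.values()) <= tol
    used = int(np.ceil(state["nit"] / inner_steps))

    image = LuminanceImage(flat.reshape(shape), scheme.ppd, scheme.fixation)
    return MongrelResult(
        image=image,
        residual_trace=trace,
        converged=converged,
        seed=seed,
        iterations=used,
        loss=fun,
    )


def mongrelize(
    image: LuminanceImage,
    seed: int = 0,
    *,
    scheme: PoolingScheme | None = None,
    config: StatConfig | None = None,
    iters: int = 50,
    tol: float = 0.05,
    synthesize_fovea: bool = False,
    **kwargs,
) -> MongrelResult:
    """Encode ``image`` at its fixation and synthesize a mongrel of it."""
    scheme = scheme or build_pooling_scheme(image)
    config = config or StatConfig()
    target = compute_stat_field(image, scheme, config)
    fov = None if synthesize_fovea else image.pixels
    return synthesize_mongrel(target, scheme, seed=seed, iters=iters, tol=tol,
                              fovea_image=fov, **kwargs)


def metamer_pair(
    target: StatField,
    seeds: tuple[int, int],
    scheme: PoolingScheme,
    *,
    iters: int = 50,
    tol: float = 0.05,
    **kwargs,
) -> tuple[MongrelResult, MongrelResult, dict]:
    """Two mongrels of one target from different seeds, plus a divergence
    report: pixel RMS difference and statistic-space distance.

    Distinct seeds should give visibly different images (pixel RMS well
    above zero) whose encodings both sit within tolerance of the target —
    the model's metamers.
    """
    s1, s2 = seeds  # equal seeds are allowed: identical runs, zero divergence
    r1 = synthesize_mongrel(target, scheme, seed=s1, iters=iters, tol=tol, **kwargs)
    r2 = synthesize_mongrel(target, scheme, seed=s2, iters=iters, tol=tol, **kwargs)
    pix_rms = float(np.sqrt(np.mean((r1.image.pixels - r2.image.pixels) ** 2)))
    f1 = compute_stat_field(r1.image, scheme, target.config)
    f2 = compute_stat_field(r2.image, scheme, target.config)
    m = f1.valid_matrix() & f2.valid_matrix()
    d = (f1.values_matrix() - f2.values_matrix())[m]
    report = {
        "pixel_rms": pix_rms,
        "stat_distance": float(np.linalg.norm(d)),
        "stat_rms": float(np.sqrt(np.mean(d**2))),
        "converged": (r1.converged, r2.converged),
        "residuals": (r1.final_residuals(), r2.final_residuals()),
    }
    return r1, r2, report
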