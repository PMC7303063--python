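"""The decision-complexity laboratory.

Visual tasks are treated as classification over a perceptual encoding,
with an explicit cap on how intricate the decision boundary may be.
The budget takes one of three forms:

* ``max_hyperplanes k`` — the boundary is carved from at most k linear
  separators (cells of the arrangement are labeled by training majority);
* ``max_dimensions d`` — at most d feature dimensions may enter an
  otherwise unrestricted classifier;
* ``curvature kappa`` — an RBF decision function whose kernel bandwidth
  is floored at 1/kappa, bounding how sharply the boundary can bend.

On top of the budgeted classifier the module provides task composition
(two 2-alternative tasks become one 4-alternative dual task, with the
attendant cost under a fixed budget), the tracking-task hypothesis count
C(n, k) - 1, and the change-detection experiments: how far apart are the
encodings of arrays that differ in one item, and which procedural scenes
are confusable at that same encoding precision.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import comb

from ttmlab.imagecore import to_luminance
from ttmlab.pooling import build_pooling_scheme
from ttmlab.statistics import StatConfig, compute_stat_field
from ttmlab.stimuli import StimulusSpec, make_vwm_array, _default_palette


# ---------------------------------------------------------------------------
# task specs and composition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaskClass:
    """One labeled class: a seeded generator of feature vectors."""

    label: str
    sampler: object  # callable (rng, n) -> (n, d) array
    prior: float = 1.0


@dataclass(frozen=True)
class TaskSpec:
    """A classification task over an encoding.

    ``classes`` are labeled generative specs; the loss is 0-1.  A task
    with a single class is a placeholder (identity under composition).
    """

    classes: tuple
    encoder: str = "identity"

    def __post_init__(self):
        if len(self.classes) < 1:
            raise ValueError("a task needs at least one class")

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def priors(self) -> np.ndarray:
        p = np.array([c.prior for c in self.classes], dtype=np.float64)
        return p / p.sum()

    def sample(self, rng: np.random.Generator, n_per_class: int):
        xs, ys = [], []
        for i, c in enumerate(self.classes):
            x = np.asarray(c.sampler(rng, n_per_class), dtype=np.float64)
            xs.append(x)
            ys.append(np.full(len(x), i))
        return np.concatenate(xs), np.concatenate(ys)


def gaussian_task(means, cov_scale: float = 1.0, labels=None,
                  encoder: str = "identity") -> TaskSpec:
    """Toy task: one spherical Gaussian per class."""
    means = [np.asarray(m, dtype=np.float64) for m in means]
    labels = labels or [f"c{i}" for i in range(len(means))]

    def make_sampler(mu):
        def sampler(rng, n):
            return mu[None, :] + math.sqrt(cov_scale) * rng.standard_normal(
                (n, mu.size))
        return sampler

    return TaskSpec(
        classes=tuple(
            TaskClass(label=l, sampler=make_sampler(m))
            for l, m in zip(labels, means)
        ),
        encoder=encoder,
    )


def xor_task(separation: float = 4.0, noise: float = 1.0) -> TaskSpec:
    """Four clusters on the corners of a square, labels in XOR pattern:
    no single hyperplane separates the classes."""
    h = separation / 2.0

    def make_sampler(centers):
        def sampler(rng, n):
            k = len(centers)
            picks = rng.integers(k, size=n)
            base = np.asarray(centers)[picks]
            return base + noise * rng.standard_normal((n, 2))
        return sampler

    return TaskSpec(classes=(
        TaskClass("same", make_sampler([(-h, -h), (h, h)])),
        TaskClass("diff", make_sampler([(-h, h), (h, -h)])),
    ))


def compose_tasks(t1: TaskSpec, t2: TaskSpec) -> TaskSpec:
    """Product task: perform both component tasks at once.

    Class count multiplies (two 2-alternative tasks become one
    4-alternative dual task); each composed class concatenates features
    drawn from its component classes.
    """
    if t1.encoder != t2.encoder:
        raise ValueError(
            f"encoders {t1.encoder!r} and {t2.encoder!r} are not concatenable"
        )

    def make_sampler(c1, c2):
        def sampler(rng, n):
            x1 = np.asarray(c1.sampler(rng, n), dtype=np.float64)
            x2 = np.asarray(c2.sampler(rng, n), dtype=np.float64)
            return np.concatenate([x1, x2], axis=1)
        return sampler

    classes = tuple(
        TaskClass(
            label=f"{c1.label}&{c2.label}",
            sampler=make_sampler(c1, c2),
            prior=c1.prior * c2.prior,
        )
        for c1, c2 in itertools.product(t1.classes, t2.classes)
    )
    return TaskSpec(classes=classes, encoder=t1.encoder)


# ---------------------------------------------------------------------------
# tracking combinatorics
# ---------------------------------------------------------------------------

def mot_hypothesis_count(n: int, k: int) -> int:
    """Competing hypotheses when tracking k of n items: C(n, k) - 1.

    On each frame the tracker must distinguish the true target set from
    every other k-subset of the n items.
    """
    if k < 0 or n < 0 or k > n:
        raise ValueError(f"need 0 <= k <= n, got n={n}, k={k}")
    return int(comb(n, k, exact=True)) - 1


# ---------------------------------------------------------------------------
# budgeted classifiers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComplexityBudget:
    """An explicit cap on decision-boundary complexity."""

    form: str  # "max_hyperplanes" | "max_dimensions" | "curvature" | "unlimited"
    value: float = np.inf

    def __post_init__(self):
        if self.form not in ("max_hyperplanes", "max_dimensions", "curvature",
                             "unlimited"):
            raise ValueError(f"unknown budget form {self.form!r}")
        if self.form != "unlimited" and not (self.value >= 1 or
                                             (self.form == "curvature" and self.value > 0)):
            raise ValueError("budget value must be >= 1 (curvature: > 0)")


class HyperplaneArrangementClassifier:
    """At most k linear separators; cells labeled by training majority.

    Candidate hyperplanes come from axis-aligned stumps at feature
    quantiles, seeded random projections through data-pair midpoints,
    and class-mean differences on random subsets.  The k-subset of
    candidates is chosen by beam search on training accuracy (parity
    tasks such as XOR defeat pure greedy selection); shorter plane sets
    stay in the beam, so the classifier never uses more complexity than
    helps and training accuracy is non-decreasing in the budget.
    """

    def __init__(self, k: int, n_candidates: int = 200, beam_width: int = 8,
                 seed: int = 0):
        self.k = int(k)
        self.n_candidates = n_candidates
        self.beam_width = beam_width
        self.seed = seed

    def _candidates(self, X, y, rng):
        n, d = X.shape
        planes = []
        # axis-aligned "stump" planes at per-feature quantiles
        qs = np.linspace(0.1, 0.9, 9)
        for j in range(min(d, 20)):
            e = np.zeros(d)
            e[j] = 1.0
            for t in np.quantile(X[:, j], qs):
                planes.append((e.copy(), float(t)))
        self._n_stumps = len(planes)
        # random directions through midpoints of random data pairs
        while len(planes) < self.n_candidates // 2:
            wdir = rng.standard_normal(d)
            wdir /= np.linalg.norm(wdir)
            i, j = rng.integers(n, size=2)
            mid = (X[i] + X[j]) / 2.0
            planes.append((wdir, float(wdir @ mid)))
        # mean-difference planes on random class-pair subsets
        labels = np.unique(y)
        while len(planes) < self.n_candidates:
            a, b = rng.choice(labels, size=2, replace=True)
            ia = np.flatnonzero(y == a)
            ib = np.flatnonzero(y == b)
            sa = X[rng.choice(ia, size=min(50, ia.size), replace=False)]
            sb = X[rng.choice(ib, size=min(50, ib.size), replace=False)]
            wdir = sa.mean(axis=0) - sb.mean(axis=0)
            nrm = np.linalg.norm(wdir)
            if nrm < 1e-12:
                wdir = rng.standard_normal(d)
                nrm = np.linalg.norm(wdir)
            wdir /= nrm
            mid = (sa.mean(axis=0) + sb.mean(axis=0)) / 2
            planes.append((wdir, float(wdir @ mid)))
        return planes

    @staticmethod
    def _cell_codes(X, planes):
        if not planes:
            return np.zeros(len(X), dtype=np.int64)
        W = np.stack([p[0] for p in planes])
        b = np.array([p[1] for p in planes])
        bits = (X @ W.T > b[None, :]).astype(np.int64)
        return bits @ (1 << np.arange(len(planes), dtype=np.int64))

    @staticmethod
    def _majority_fit(codes, y, n_classes):
        table = {}
        for c in np.unique(codes):
            sel = y[codes == c]
            counts = np.bincount(sel, minlength=n_classes)
            table[int(c)] = int(np.argmax(counts))
        return table

    def fit(self, X, y):
        rng = np.random.default_rng(self.seed)
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.int64)
        self.n_classes_ = int(y.max()) + 1
        self.default_ = int(np.argmax(np.bincount(y)))
        cands = self._candidates(X, y, rng)
        # precompute each candidate's sign pattern over the training set
        W = np.stack([p[0] for p in cands])
        b = np.array([p[1] for p in cands])
        bits = (X @ W.T > b[None, :]).T.astype(np.int64)  # (n_cand, n)

        nc = self.n_classes_

        def acc_of(idx_tuple) -> float:
            if idx_tuple:
                codes = np.zeros(len(y), dtype=np.int64)
                for pos, ci in enumerate(idx_tuple):
                    codes |= bits[ci] << pos
            else:
                codes = np.zeros(len(y), dtype=np.int64)
            joint = np.bincount(codes * nc + y,
                                minlength=(int(codes.max()) + 1) * nc)
            per_cell = joint.reshape(-1, nc)
            return float(per_cell.max(axis=1).sum() / len(y))

        best_set: tuple = ()
        best_acc = acc_of(())
        beams = [((), best_acc)]
        for level in range(self.k):
            pool: dict = {}
            for planes, _acc in beams:
                for ci in range(len(cands)):
                    if ci in planes:
                        continue
                    trial = planes + (ci,)
                    key = tuple(sorted(trial))
                    if key in pool:
                        continue
                    pool[key] = (trial, acc_of(trial))
            if level == 1:
                # parity-style boundaries are built from planes that are
                # individually uninformative, so no beam of good singles
                # reaches them: search all pairs over a pruned subset
                # (every stump + the strongest singles)
                singles = sorted(range(len(cands)),
                                 key=lambda ci: -acc_of((ci,)))
                subset = sorted(set(range(self._n_stumps)) | set(singles[:60]))
                for ii, ci in enumerate(subset):
                    for cj in subset[ii + 1:]:
                        key = (min(ci, cj), max(ci, cj))
                        if key not in pool:
                            pool[key] = (key, acc_of(key))
            if not pool:
                break
            states = sorted(pool.values(), key=lambda t: (-t[1], t[0]))
            beams = states[:self.beam_width]
            if beams[0][1] > best_acc + 1e-12:
                best_set, best_acc = beams[0]
        self.planes_ = [cands[ci] for ci in best_set]
        codes = self._cell_codes(X, self.planes_)
        self.table_ = self._majority_fit(codes, y, self.n_classes_)
        return self

    def predict(self, X):
        codes = self._cell_codes(np.asarray(X, dtype=np.float64), self.planes_)
        return np.array([self.table_.get(int(c), self.default_) for c in codes])


@dataclass
class FittedTask:
    model: object
    accuracy: float
    se: float
    budget: ComplexityBudget
    n_train: int
    n_test: int
    seed: int
    meta: dict = field(default_factory=dict)


def fit_budgeted_classifier(
    task: TaskSpec,
    budget: ComplexityBudget,
    n_train: int = 2000,
    n_test: int = 2000,
    seed: int = 0,
) -> FittedTask:
    """Fit a classifier whose decision boundary respects the budget and
    report held-out accuracy with its binomial standard error.

    ``n_train`` / ``n_test`` are per class.
    """
    rng = np.random.default_rng(seed)
    Xtr, ytr = task.sample(rng, n_train)
    Xte, yte = task.sample(rng, n_test)

    if budget.form == "max_hyperplanes":
        model = HyperplaneArrangementClassifier(int(budget.value), seed=seed)
        model.fit(Xtr, ytr)
    elif budget.form == "max_dimensions":
        from sklearn.feature_selection import SelectKBest, f_classif
        from sklearn.pipeline import Pipeline
        from sklearn.svm import SVC

        d = min(int(budget.value), Xtr.shape[1])
        model = Pipeline([
            ("select", SelectKBest(f_classif, k=d)),
            ("clf", SVC(kernel="rbf", C=10.0, gamma="scale")),
        ])
        model.fit(Xtr, ytr)
    elif budget.form == "curvature":
        from sklearn.svm import SVC

        # kernel length-scale floored at 1/kappa: gamma <= kappa^2 / 2
        gamma = float(budget.value) ** 2 / 2.0
        model = SVC(kernel="rbf", C=10.0, gamma=gamma)
        model.fit(Xtr, ytr)
    elif budget.form == "unlimited":
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        from sklearn.svm import SVC

        # model selection between a linear and an RBF rule on a validation
        # split; with no budget the family is free
        n_val = max(200, len(Xtr) // 5)
        perm = rng.permutation(len(Xtr))
        tr, va = perm[n_val:], perm[:n_val]
        cands = [LinearDiscriminantAnalysis(), SVC(kernel="rbf", C=10.0,
                                                   gamma="scale")]
        best, best_acc = None, -1.0
        for mdl in cands:
            mdl.fit(Xtr[tr], ytr[tr])
            acc = float(np.mean(mdl.predict(Xtr[va]) == ytr[va]))
            if acc > best_acc:
                best, best_acc = mdl, acc
        model = best
        model.fit(Xtr, ytr)
    else:  # pragma: no cover
        raise ValueError(budget.form)

    pred = model.predict(Xte)
    acc = float(np.mean(pred == yte))
    se = float(math.sqrt(max(acc * (1 - acc), 1e-12) / len(yte)))
    return FittedTask(model=model, accuracy=acc, se=se, budget=budget,
                      n_train=n_train, n_test=n_test, seed=seed)


# ---------------------------------------------------------------------------
# encoders for image-level experiments
# ---------------------------------------------------------------------------

def statistic_encoder(
    ppd: float = 16.0,
    config: StatConfig | None = None,
    g: float = 0.5,
    d0: float = 1.0,
):
    """The in-repo perceptual encoder: raster -> flat statistic vector.

    The vector is made intrinsically bounded so that Euclidean distance
    is meaningful across stimulus classes: correlations, means and
    variances of [0, 1] luminances are already bounded, and the two
    unbounded entries per region (skewness, kurtosis — numerically
    explosive on near-uniform regions) are squashed through
    ``v / (1 + |v|)``.  The pooling scheme (hence the vector length) is
    fixed by the first image encoded; a different raster geometry later
    is an error.
    """
    config = config or StatConfig()
    state: dict = {}

    def encode(raster: np.ndarray) -> np.ndarray:
        from ttmlab.statistics import get_layout

        img = to_luminance(raster, ppd=ppd)
        if "scheme" not in state:
            state["scheme"] = build_pooling_scheme(img, g=g, d0=d0)
            state["shape"] = img.shape
            lay = get_layout(config)
            squash = np.zeros(lay.count, dtype=bool)
            squash[lay.labels.index("marginal:skew")] = True
            squash[lay.labels.index("marginal:kurt")] = True
            state["squash"] = squash
        if img.shape != state["shape"]:
            raise ValueError("encoder requires a fixed raster geometry")
        f = compute_stat_field(img, state["scheme"], config)
        vals = np.where(f.valid_matrix(), f.values_matrix(), 0.0)
        sq = state["squash"]
        vals[:, sq] = vals[:, sq] / (1.0 + np.abs(vals[:, sq]))
        return vals.ravel()

    return encode


# ---------------------------------------------------------------------------
# VWM and scene confusability experiments
# ---------------------------------------------------------------------------

def vwm_experiment(
    encoder,
    n_items_grid=(2, 4, 8),
    palette=None,
    n_arrays: int = 30,
    seed: int = 0,
    spec: StimulusSpec | None = None,
) -> dict:
    """Encoding distance between colored-square arrays that differ in the
    color of exactly one item.

    Holding the encoding precision fixed, a change-detection task is only
    as easy as these one-item distances are large.  Returns per-``n`` the
    mean/std of the one-item-change distance and, for reference, the mean
    distance between fully independent arrays of the same size.
    """
    palette = palette or _default_palette()
    spec = spec or StimulusSpec(kind="vwm_array", item_size=0.8,
                                eccentricity=3.0, ppd=16.0, shape=(128, 128))
    rng = np.random.default_rng(seed)
    out = {}
    dim = None
    for n in n_items_grid:
        one, indep = [], []
        for t in range(n_arrays):
            s = int(rng.integers(2**31 - 1))
            base_spec = replace(spec, rng_seed=s)
            a, rec = make_vwm_array(n, palette, base_spec)
            # recolor one random item
            idx = int(rng.integers(n))
            old = rec["items"][idx]["color_index"]
            new = int((old + 1 + rng.integers(len(palette) - 1)) % len(palette))
            from ttmlab.stimuli import make_change_pair

            a2, b2, _ = make_change_pair(base_spec, change_index=idx,
                                         new_color_index=new, n_items=n,
                                         palette=palette)
            va, vb = encoder(a2), encoder(b2)
            if dim is None:
                dim = va.size
            if va.size != dim or vb.size != dim:
                raise ValueError("encoder dimension varies across inputs")
            one.append(float(np.linalg.norm(va - vb)))
            # independent array of the same size for reference
            c, _ = make_vwm_array(n, palette,
                                  replace(spec, rng_seed=s + 500_000_001))
            indep.append(float(np.linalg.norm(va - encoder(c))))
        out[int(n)] = {
            "one_item_mean": float(np.mean(one)),
            "one_item_std": float(np.std(one)),
            "independent_mean": float(np.mean(indep)),
        }
    return out


def scene_confusability(
    encoder,
    probes: list,
    threshold: float,
) -> dict:
    """Which probes are within ``threshold`` of each other in encoding
    space — the confusable-set report at a given precision.

    ``probes`` is a list of rasters (or arrays already encoded if 1-D).
    ``threshold`` is typically the one-item-change distance from
    :func:`vwm_experiment`: the precision at which an eight-item array
    change goes unnoticed.
    """
    if len(probes) == 0:
        raise ValueError("probe set is empty")
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    vecs = []
    for p in probes:
        arr = np.asarray(p)
        vecs.append(arr.astype(np.float64) if arr.ndim == 1 else encoder(p))
    V = np.stack(vecs)
    D = np.linalg.norm(V[:, None, :] - V[None, :, :], axis=2)
    sets = {
        i: sorted(int(j) for j in np.flatnonzero((D[i] <= threshold)) if j != i)
        for i in range(len(probes))
    }
    return {"confusable": sets, "distances": D}
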