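import itertools

import numpy as np
import pytest
from scipy.stats import norm

from ttmlab.decision import (
    ComplexityBudget,
    TaskClass,
    TaskSpec,
    compose_tasks,
    fit_budgeted_classifier,
    gaussian_task,
    mot_hypothesis_count,
    scene_confusability,
    statistic_encoder,
    vwm_experiment,
    xor_task,
)
from ttmlab.stimuli import StimulusSpec


class TestMOTCombinatorics:
    def test_printed_tracking_example(self):
        assert mot_hypothesis_count(9, 4) == 125

    def test_track_all_items_leaves_no_alternatives(self):
        assert mot_hypothesis_count(6, 6) == 0
        assert mot_hypothesis_count(0, 0) == 0

    def test_agrees_with_exhaustive_enumeration(self):
        for n in range(13):
            for k in range(n + 1):
                subsets = sum(1 for _ in itertools.combinations(range(n), k))
                assert mot_hypothesis_count(n, k) == subsets - 1, (n, k)

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            mot_hypothesis_count(3, 5)


class TestComposition:
    def test_two_2afc_become_4afc(self):
        t = gaussian_task([[-1], [1]])
        assert compose_tasks(t, t).n_classes == 4

    def test_product_rule_and_identity(self):
        t2 = gaussian_task([[-1], [1]])
        t3 = gaussian_task([[-1, 0], [1, 0], [0, 1]])
        assert compose_tasks(t2, t3).n_classes == 6
        one = TaskSpec(classes=(TaskClass("only", lambda rng, n:
                                          rng.standard_normal((n, 1))),))
        assert compose_tasks(t2, one).n_classes == 2

    def test_composed_samples_concatenate_features(self, rng):
        t2 = gaussian_task([[-1.0], [1.0]])
        t3 = gaussian_task([[0.0, 5.0], [0.0, -5.0]])
        dual = compose_tasks(t2, t3)
        X, y = dual.sample(rng, 10)
        assert X.shape == (40, 3)
        assert dual.priors().sum() == pytest.approx(1.0)

    def test_incompatible_encoders_rejected(self):
        a = gaussian_task([[0], [1]], encoder="identity")
        b = gaussian_task([[0], [1]], encoder="statistic")
        with pytest.raises(ValueError, match="encoder"):
            compose_tasks(a, b)

    def test_dual_task_cost_under_fixed_budget(self):
        """A budget-k classifier on the composed task does no better than
        the worse of the component tasks on matched budgets."""
        t1 = gaussian_task([[-1.5, 0.0], [1.5, 0.0]])
        t2 = gaussian_task([[0.0, -1.5], [0.0, 1.5]])
        budget = ComplexityBudget("max_hyperplanes", 1)
        a1 = fit_budgeted_classifier(t1, budget, seed=5).accuracy
        a2 = fit_budgeted_classifier(t2, budget, seed=5).accuracy
        dual = compose_tasks(t1, t2)
        ad = fit_budgeted_classifier(dual, budget, seed=5).accuracy
        assert ad <= min(a1, a2) + 0.02


class TestBudgetedClassifier:
    def test_separated_gaussians_single_hyperplane(self):
        task = gaussian_task([[-2.0, 0.0], [2.0, 0.0]])  # means 4 sigma apart
        ft = fit_budgeted_classifier(task, ComplexityBudget("max_hyperplanes", 1),
                                     n_test=2000, seed=1)
        assert ft.accuracy >= 0.95

    def test_xor_needs_two_hyperplanes(self):
        xt = xor_task()
        f1 = fit_budgeted_classifier(xt, ComplexityBudget("max_hyperplanes", 1),
                                     seed=1)
        f2 = fit_budgeted_classifier(xt, ComplexityBudget("max_hyperplanes", 2),
                                     seed=1)
        assert f1.accuracy <= 0.80
        assert f2.accuracy >= 0.95

    def test_accuracy_monotone_in_hyperplane_budget(self):
        xt = xor_task()
        fits = [fit_budgeted_classifier(xt, ComplexityBudget("max_hyperplanes", k),
                                        seed=3) for k in range(1, 6)]
        accs = [f.accuracy for f in fits]
        # non-decreasing at the statistical resolution of the test set
        for a, b, f in zip(accs, accs[1:], fits[1:]):
            assert b >= a - f.se

    def test_unlimited_budget_near_bayes(self):
        for sep in (2.0, 4.0):
            task = gaussian_task([[0.0, 0.0], [sep, 0.0]])
            ft = fit_budgeted_classifier(task, ComplexityBudget("unlimited"),
                                         seed=2)
            bayes = norm.cdf(sep / 2)
            assert abs(ft.accuracy - bayes) <= 0.02

    def test_dimension_budget_selects_informative_axes(self):
        # class signal only in dims 0-1 of 6; d=2 budget suffices
        means = [np.r_[[-2.0, -2.0], np.zeros(4)], np.r_[[2.0, 2.0], np.zeros(4)]]
        task = gaussian_task(means)
        ft = fit_budgeted_classifier(task, ComplexityBudget("max_dimensions", 2),
                                     seed=4)
        assert ft.accuracy >= 0.95

    def test_curvature_budget_limits_fit(self):
        # concentric-rings task: a straight (low-curvature) boundary fails
        def ring(r):
            def sampler(rng, n):
                th = rng.uniform(0, 2 * np.pi, n)
                rad = r + 0.1 * rng.standard_normal(n)
                return np.c_[rad * np.cos(th), rad * np.sin(th)]
            return sampler

        task = TaskSpec(classes=(TaskClass("inner", ring(1.0)),
                                 TaskClass("outer", ring(2.0))))
        lo = fit_budgeted_classifier(task, ComplexityBudget("curvature", 0.05),
                                     seed=6)
        hi = fit_budgeted_classifier(task, ComplexityBudget("curvature", 5.0),
                                     seed=6)
        assert hi.accuracy > lo.accuracy + 0.1
        assert hi.accuracy >= 0.95

    def test_unknown_budget_rejected(self):
        with pytest.raises(ValueError):
            ComplexityBudget("max_neurons", 3)


@pytest.fixture(scope="module")
def stat_encoder():
    return statistic_encoder(ppd=16.0)


class TestVWMExperiment:
    def test_array_vs_itself_distance_zero(self, stat_encoder):
        from ttmlab.stimuli import make_vwm_array

        raster, _ = make_vwm_array(4, None, StimulusSpec(
            kind="vwm_array", item_size=0.8, eccentricity=3.0, ppd=16.0,
            shape=(128, 128), rng_seed=1))
        v = stat_encoder(raster)
        assert np.linalg.norm(v - stat_encoder(raster)) == 0.0

    def test_one_item_change_smaller_than_full_redraw(self, stat_encoder):
        res = vwm_experiment(stat_encoder, n_items_grid=(8,), n_arrays=12,
                             seed=2)
        assert res[8]["one_item_mean"] < res[8]["independent_mean"]
        assert res[8]["one_item_mean"] > 0

    def test_reports_direction_across_set_sizes(self, stat_encoder):
        res = vwm_experiment(stat_encoder, n_items_grid=(2, 4, 8), n_arrays=8,
                             seed=3)
        assert set(res) == {2, 4, 8}
        for n in (2, 4, 8):
            assert res[n]["one_item_mean"] > 0


class TestSceneConfusability:
    def test_threshold_extremes(self):
        vecs = [np.array([0.0, 0.0]), np.array([1.0, 0.0]), np.array([0.0, 2.0])]
        enc = lambda v: v
        zero = scene_confusability(enc, vecs, 0.0)
        assert all(len(s) == 0 for s in zero["confusable"].values())
        inf = scene_confusability(enc, vecs, np.inf)
        assert all(len(s) == 2 for s in inf["confusable"].values())

    def test_empty_probes_rejected(self):
        with pytest.raises(ValueError):
            scene_confusability(lambda v: v, [], 1.0)

    def test_jittered_scene_inside_vwm_threshold(self, stat_encoder):
        """Small item jitter stays within the one-item-change precision,
        while a fully different layout falls outside, for most probes."""
        from ttmlab.stimuli import make_search_array
        from dataclasses import replace

        res = vwm_experiment(stat_encoder, n_items_grid=(8,), n_arrays=10,
                             seed=5)
        threshold = res[8]["one_item_mean"]
        spec = StimulusSpec(n_items=10, item_size=0.6, spacing=1.0, ppd=16.0,
                            shape=(128, 128))
        hits = 0
        n_probes = 15
        for s in range(n_probes):
            base, rec = make_search_array(replace(spec, rng_seed=s), "t_among_l")
            # jitter: re-render with item positions nudged by ~0.05 deg
            import copy

            rec2 = copy.deepcopy(rec)
            nudge = np.random.default_rng(1000 + s)
            for it in rec2["items"]:
                it["row"] += nudge.uniform(-0.8, 0.8)
                it["col"] += nudge.uniform(-0.8, 0.8)
            from ttmlab.stimuli import _render_record

            jit = _render_record(rec2)
            other, _ = make_search_array(replace(spec, rng_seed=1000 + s),
                                         "t_among_l")
            v0 = stat_encoder(np.dstack([base.pixels] * 3))
            vj = stat_encoder(np.dstack([jit] * 3))
            vo = stat_encoder(np.dstack([other.pixels] * 3))
            d_jit = np.linalg.norm(v0 - vj)
            d_other = np.linalg.norm(v0 - vo)
            if d_jit <= threshold < d_other:
                hits += 1
        assert hits >= 0.8 * n_probes
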