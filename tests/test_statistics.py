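"""Encoder tests, anchored by naive double-loop oracles.

The oracles recompute every weighted moment and correlation with
explicit Python loops over full maps (circular shifts via np.roll),
sharing no code with the batched engine.
"""

import numpy as np
import pytest

from ttmlab.imagecore import LuminanceImage
from ttmlab.pooling import build_pooling_scheme
from ttmlab.pyramid import build_pyramid
from ttmlab.statistics import (
    VAR_EPS,
    DerivedMaps,
    StatConfig,
    StatField,
    compute_region_stats,
    compute_stat_field,
    get_layout,
    load_stat_field,
    save_stat_field,
    stat_count,
)
from ttmlab.stimuli import make_letter_array, make_texture, StimulusSpec

from oracle_utils import naive_downsample, naive_moments, naive_wcorr


# ---------------------------------------------------------------------------
# oracle equivalence on 16x16 inputs
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def oracle_setup():
    rng = np.random.default_rng(7)
    x = rng.random((16, 16))
    cfg = StatConfig(n_scales=2, n_orientations=3, acorr_m=3)
    pyr = build_pyramid(x, 2, 3)
    yy, xx = np.mgrid[0:16, 0:16]
    w = np.exp(-((yy - 8) ** 2 + (xx - 7) ** 2) / (2 * 4.0**2))
    vec = compute_region_stats(pyr, w, cfg)
    derived = DerivedMaps(pyr)
    # weights per level, as documented: block mean then renormalize
    w_levels = [w / w.sum()]
    for _ in range(2):
        nxt = naive_downsample(w_levels[-1])
        w_levels.append(nxt / nxt.sum())
    return cfg, pyr, derived, w_levels, vec


class TestOracleEquivalence:
    TOL = 1e-10

    def test_marginal_moments(self, oracle_setup):
        cfg, pyr, derived, w_levels, vec = oracle_setup
        mu, var, skew, kurt = naive_moments(w_levels[0], pyr.source)
        assert vec.mean == pytest.approx(mu, abs=self.TOL)
        assert vec.var == pytest.approx(var, abs=self.TOL)
        assert vec.skew == pytest.approx(skew, abs=self.TOL)
        assert vec.kurt == pytest.approx(kurt, abs=self.TOL)

    def test_highpass_and_lowpass_variances(self, oracle_setup):
        cfg, pyr, derived, w_levels, vec = oracle_setup
        _, var_h, _, _ = naive_moments(w_levels[0], pyr.highpass)
        assert vec.group("highpass")[0] == pytest.approx(var_h, abs=self.TOL)
        for k in range(3):
            _, var_l, _, _ = naive_moments(w_levels[k], pyr.lowpass_maps[k])
            assert vec.group("lowpass_energy")[k] == pytest.approx(
                var_l, abs=self.TOL)

    def test_autocorrelation_entries(self, oracle_setup):
        cfg, pyr, derived, w_levels, vec = oracle_setup
        lay = get_layout(cfg)
        got = vec.group("autocorr")
        i = 0
        for k in range(3):
            lmap = pyr.lowpass_maps[k]
            for dy, dx in lay.offsets:
                expect = naive_wcorr(w_levels[k], lmap,
                                     np.roll(lmap, (-dy, -dx), axis=(0, 1)))
                assert got[i] == pytest.approx(expect, abs=self.TOL), (k, dy, dx)
                i += 1

    def test_magnitude_correlations(self, oracle_setup):
        cfg, pyr, derived, w_levels, vec = oracle_setup
        lay = get_layout(cfg)
        # cross-orientation
        got = vec.group("mag_corr_orientation")
        i = 0
        for s in range(2):
            for o1 in range(3):
                for o2 in range(o1 + 1, 3):
                    expect = naive_wcorr(w_levels[s], derived.mag[s][o1],
                                         derived.mag[s][o2])
                    assert got[i] == pytest.approx(expect, abs=self.TOL)
                    i += 1
        # position (shifted copies)
        got = vec.group("mag_corr_position")
        i = 0
        for s in range(2):
            for o in range(3):
                m = derived.mag[s][o]
                for dy, dx in lay.offsets:
                    expect = naive_wcorr(w_levels[s], m,
                                         np.roll(m, (-dy, -dx), axis=(0, 1)))
                    assert got[i] == pytest.approx(expect, abs=self.TOL)
                    i += 1

    def test_cross_scale_and_phase_correlations(self, oracle_setup):
        cfg, pyr, derived, w_levels, vec = oracle_setup
        got_m = vec.group("mag_corr_scale")
        got_p = vec.group("phase_corr_scale")
        i = 0
        for o1 in range(3):
            for o2 in range(3):
                em = naive_wcorr(w_levels[0], derived.mag[0][o1],
                                 derived.up_mag[0][o2])
                ep = naive_wcorr(w_levels[0], derived.re[0][o1],
                                 derived.pd_up[0][o2])
                assert got_m[i] == pytest.approx(em, abs=self.TOL)
                assert got_p[i] == pytest.approx(ep, abs=self.TOL)
                i += 1

    def test_zero_offset_self_correlation_is_one(self, oracle_setup):
        cfg, pyr, derived, w_levels, vec = oracle_setup
        lay = get_layout(cfg)
        pos = vec.group("mag_corr_position")
        A = lay.n_acorr_offsets
        for blk in range(2 * 3):
            assert pos[blk * A] == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# counts and invariants
# ---------------------------------------------------------------------------

class TestStatCount:
    def test_default_within_the_thousand_budget(self):
        assert stat_count(StatConfig()) <= 1000

    def test_closed_form_matches_layout_and_vector(self, tiny_image):
        for cfg in (StatConfig(2, 3, 3), StatConfig(2, 2, 5), StatConfig(1, 1, 1)):
            assert stat_count(cfg) == get_layout(cfg).count
        cfg = StatConfig(2, 3, 3)
        pyr = build_pyramid(tiny_image, 2, 3)
        vec = compute_region_stats(pyr, np.ones(tiny_image.shape), cfg)
        assert vec.count == stat_count(cfg)

    def test_minimum_configuration(self):
        # S=1, O=1, M=1: marginals + highpass var + 2 lowpass vars +
        # mag mean/var + 1 autocorr offset per lowpass + 1 position entry
        assert stat_count(StatConfig(1, 1, 1)) == 6 + 1 + 2 + 2 + 2 + 0 + 1 + 0

    def test_count_strictly_increasing_in_m(self):
        counts = [stat_count(StatConfig(4, 4, m)) for m in (3, 5, 7, 9)]
        assert all(b > a for a, b in zip(counts, counts[1:]))


class TestStatField:
    def test_uniform_image_marginals(self):
        img = LuminanceImage(np.full((64, 64), 0.35), 16.0, (31.5, 31.5))
        scheme = build_pooling_scheme(img)
        field = compute_stat_field(img, scheme)
        for v in field.vectors:
            assert v.mean == pytest.approx(0.35, abs=1e-12)
            assert v.var == pytest.approx(0.0, abs=1e-12)
            # degenerate-variance rule: correlation groups all zero
            for g in ("autocorr", "mag_corr_orientation", "phase_corr_scale"):
                assert np.all(np.abs(v.group(g)[v.layout.groups[g].start
                                                - v.layout.groups[g].start:])
                              <= 1e-9)

    def test_geometry_mismatch_rejected(self, small_image):
        scheme = build_pooling_scheme(small_image)
        other = LuminanceImage(np.zeros((64, 64)), 8.0, (31.5, 31.5))
        with pytest.raises(ValueError, match="geometry"):
            compute_stat_field(other, scheme)

    def test_deterministic_and_region_bijective(self, small_image):
        scheme = build_pooling_scheme(small_image)
        f1 = compute_stat_field(small_image, scheme)
        f2 = compute_stat_field(small_image, scheme)
        assert np.array_equal(f1.values_matrix(), f2.values_matrix())
        assert f1.region_ids == [r.id for r in scheme.regions]

    def test_periodic_translation_leaves_interior_stats_stable(self):
        """Translating a periodic texture by its full period changes each
        interior region's statistics by under 2 percent relative."""
        rng = np.random.default_rng(3)
        tile = rng.random((16, 16))
        big = np.tile(tile, (8, 8))
        img = LuminanceImage(big, 16.0, (63.5, 63.5))
        scheme = build_pooling_scheme(img)
        f0 = compute_stat_field(img, scheme)
        shifted = LuminanceImage(np.roll(big, (16, 16), axis=(0, 1)),
                                 16.0, (63.5, 63.5))
        f1 = compute_stat_field(shifted, scheme)
        d = f0.values_matrix() - f1.values_matrix()
        keep = f0.valid_matrix() & f1.valid_matrix()
        rel = np.linalg.norm(d[keep]) / np.linalg.norm(f0.values_matrix()[keep])
        assert rel < 0.02

    def test_hdf5_round_trip(self, tmp_path, small_image):
        scheme = build_pooling_scheme(small_image)
        f = compute_stat_field(small_image, scheme)
        path = str(tmp_path / "field.h5")
        save_stat_field(f, path)
        back = load_stat_field(path)
        assert np.array_equal(back.values_matrix(), f.values_matrix())
        assert back.region_ids == f.region_ids
        assert back.scheme_key == f.scheme_key


def test_per_channel_color_path(rng):
    from ttmlab.imagecore import to_luminance
    from ttmlab.statistics import compute_stat_field_per_channel

    raster = rng.random((64, 64, 3))
    img = to_luminance(raster, ppd=16.0, fixation=(31.5, 31.5), keep_color=True)
    scheme = build_pooling_scheme(img)
    fields = compute_stat_field_per_channel(img, scheme)
    assert set(fields) == {"R", "G", "B"}
    for f in fields.values():
        assert len(f) == len(scheme)
    gray = to_luminance(rng.random((64, 64)), ppd=16.0, fixation=(31.5, 31.5))
    with pytest.raises(ValueError, match="color"):
        compute_stat_field_per_channel(gray, scheme)


class TestEncodingAmbiguity:
    def test_texture_information_kept_arrangement_lost(self):
        """Two draws of the same noise process encode more similarly than
        a noise draw vs. a structured letter array."""
        sch_img = make_texture("binary_noise", (128, 128), seed=1, ppd=16.0)
        scheme = build_pooling_scheme(sch_img)
        f_a = compute_stat_field(sch_img, scheme)
        f_b = compute_stat_field(
            make_texture("binary_noise", (128, 128), seed=2, ppd=16.0), scheme)
        letters, _ = make_letter_array(StimulusSpec(
            grid_shape=(4, 4), spacing=1.6, item_size=0.9, ppd=16.0,
            shape=(128, 128), rng_seed=3))
        f_c = compute_stat_field(letters, scheme)
        keep = f_a.valid_matrix() & f_b.valid_matrix() & f_c.valid_matrix()
        d_ab = np.linalg.norm((f_a.values_matrix() - f_b.values_matrix())[keep])
        d_ac = np.linalg.norm((f_a.values_matrix() - f_c.values_matrix())[keep])
        assert d_ab < d_ac
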