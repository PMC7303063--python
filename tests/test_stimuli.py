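import numpy as np
import pytest

from ttmlab.stimuli import (
    StimulusSpec,
    make_change_pair,
    make_letter_array,
    make_search_array,
    make_texture,
    make_vwm_array,
    phase_scramble,
    _render_record,
)


class TestLetterArray:
    def test_grid_count_and_layout(self):
        spec = StimulusSpec(grid_shape=(3, 4), spacing=1.5, item_size=0.8,
                            ppd=16.0, shape=(128, 128), rng_seed=3)
        img, rec = make_letter_array(spec)
        assert len(rec["items"]) == 12
        assert {it["cell"] for it in rec["items"]} == {
            (i, j) for i in range(3) for j in range(4)}
        # dark letters on light background
        assert img.pixels.max() > 0.85 and img.pixels.min() < 0.15

    def test_determinism_and_ground_truth_rerender(self):
        spec = StimulusSpec(grid_shape=(2, 3), rng_seed=11, shape=(128, 128))
        img1, rec1 = make_letter_array(spec)
        img2, rec2 = make_letter_array(spec)
        assert np.array_equal(img1.pixels, img2.pixels)
        assert np.array_equal(_render_record(rec1), img1.pixels)

    def test_single_letter_centered_at_fixation(self):
        spec = StimulusSpec(grid_shape=(1, 1), content=("I",), item_size=1.0,
                            ppd=16.0, shape=(64, 64), rng_seed=0)
        img, _ = make_letter_array(spec)
        ink = 0.9 - img.pixels
        yy, xx = np.mgrid[0:64, 0:64]
        cy = float((ink * yy).sum() / ink.sum())
        cx = float((ink * xx).sum() / ink.sum())
        assert abs(cy - img.fixation[0]) < 0.5
        assert abs(cx - img.fixation[1]) < 0.5

    def test_overlap_and_empty_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            make_letter_array(StimulusSpec(item_size=2.0, spacing=1.0))
        with pytest.raises(ValueError):
            make_letter_array(StimulusSpec(content=()))


class TestSearchArray:
    @pytest.mark.parametrize("condition", ["feature_popout", "t_among_l",
                                           "conjunction"])
    @pytest.mark.parametrize("present", [True, False])
    def test_target_count_contract(self, condition, present):
        spec = StimulusSpec(n_items=12, item_size=0.6, ppd=16.0,
                            shape=(128, 128), rng_seed=5)
        _, rec = make_search_array(spec, condition, present)
        n_targets = sum(1 for it in rec["items"] if it["role"] == "target")
        assert n_targets == (1 if present else 0)
        assert len(rec["items"]) == 12

    def test_popout_target_orientation_differs(self):
        spec = StimulusSpec(n_items=10, item_size=0.6, ppd=16.0,
                            shape=(128, 128), rng_seed=2)
        _, rec = make_search_array(spec, "feature_popout", True)
        oris = {it["role"]: set() for it in rec["items"]}
        for it in rec["items"]:
            oris[it["role"]].add(it["orientation"])
        assert oris["target"].isdisjoint(oris["distractor"])

    def test_two_seeds_give_different_positions(self):
        spec = StimulusSpec(n_items=8, item_size=0.6, ppd=16.0,
                            shape=(128, 128))
        from dataclasses import replace
        _, r1 = make_search_array(replace(spec, rng_seed=1), "t_among_l")
        _, r2 = make_search_array(replace(spec, rng_seed=2), "t_among_l")
        p1 = np.array([(it["row"], it["col"]) for it in r1["items"]])
        p2 = np.array([(it["row"], it["col"]) for it in r2["items"]])
        # min displacement over the matched-index pairing is positive
        assert np.linalg.norm(p1 - p2, axis=1).min() > 0

    def test_infeasible_density_rejected(self):
        spec = StimulusSpec(n_items=500, item_size=1.0, ppd=16.0,
                            shape=(64, 64))
        with pytest.raises(ValueError, match="without overlap"):
            make_search_array(spec, "t_among_l")


class TestVWM:
    def test_eight_squares_on_gray(self):
        spec = StimulusSpec(kind="vwm_array", item_size=0.8, eccentricity=3.0,
                            ppd=16.0, shape=(128, 128), rng_seed=4)
        raster, rec = make_vwm_array(8, None, spec)
        assert raster.shape == (128, 128, 3)
        assert len(rec["items"]) == 8
        corner = raster[:4, :4]
        assert np.allclose(corner, 0.5)

    def test_zero_items_is_uniform_gray(self):
        raster, rec = make_vwm_array(0, None, StimulusSpec(kind="vwm_array"))
        assert np.allclose(raster, 0.5)
        assert rec["items"] == []

    def test_empty_palette_rejected(self):
        with pytest.raises(ValueError, match="palette"):
            make_vwm_array(4, [], StimulusSpec(kind="vwm_array"))


class TestChangePair:
    def setup_method(self):
        self.spec = StimulusSpec(kind="vwm_array", item_size=0.8,
                                 eccentricity=3.0, ppd=16.0, shape=(128, 128),
                                 rng_seed=9)

    def test_difference_confined_to_changed_item(self):
        a, b, ch = make_change_pair(self.spec, change_index=3)
        diff = np.abs(a - b).sum(axis=2)
        ys, xs = np.nonzero(diff > 1e-12)
        assert len(ys) > 0
        half = ch["size_px"] / 2 + 1.5  # antialiasing margin
        assert np.all(np.abs(ys - ch["row"]) <= half)
        assert np.all(np.abs(xs - ch["col"]) <= half)
        # changed area is about one item's area
        area = (diff > 1e-12).sum()
        assert area <= (ch["size_px"] + 3) ** 2

    def test_identity_change_rejected(self):
        a, rec = make_vwm_array(8, None, self.spec)
        old = rec["items"][2]["color_index"]
        with pytest.raises(ValueError, match="not a change"):
            make_change_pair(self.spec, change_index=2, new_color_index=old)


class TestTextures:
    def test_kinds(self):
        assert set(np.unique(make_texture("binary_noise", seed=1).pixels)) == {0.0, 1.0}
        g = make_texture("grating", cycles_per_deg=2.0)
        assert g.pixels.min() == pytest.approx(0.0, abs=1e-9)
        assert g.pixels.max() == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(make_texture("constant", density=0.3).pixels, 0.3)
        with pytest.raises(ValueError):
            make_texture("marble")

    def test_phase_scramble_keeps_mean_changes_arrangement(self):
        img = make_texture("binary_noise", seed=3)
        scr = phase_scramble(img, seed=4)
        assert scr.pixels.mean() == pytest.approx(img.pixels.mean(), abs=0.02)
        assert np.abs(scr.pixels - img.pixels).mean() > 0.05

    def test_same_spec_two_ppd_geometrically_similar(self):
        # letters at 2x ppd are 2x as large in pixels: compare ink areas
        s16 = StimulusSpec(grid_shape=(1, 1), content=("O",), item_size=1.0,
                           ppd=16.0, shape=(64, 64), rng_seed=0)
        s32 = StimulusSpec(grid_shape=(1, 1), content=("O",), item_size=1.0,
                           ppd=32.0, shape=(128, 128), rng_seed=0)
        i16, _ = make_letter_array(s16)
        i32, _ = make_letter_array(s32)
        ink16 = (0.9 - i16.pixels).sum()
        ink32 = (0.9 - i32.pixels).sum()
        # stroke ink scales with size * thickness ~ 4x
        assert ink32 / ink16 == pytest.approx(4.0, rel=0.25)
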