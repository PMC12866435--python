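import numpy as np
import pytest

from evtricoloc.io import RunConfig
from evtricoloc.synthetic import SceneConfig, generate_scene, random_coverage_mask
from evtricoloc.uptake import (
    Background,
    UptakeMeasurement,
    TypeColoc,
    colocalize,
    detect_cfse_positive,
    estimate_background,
    flag_outliers,
    measure_uptake,
    rotation_null,
    summarize_condition,
)


class TestEstimateBackground:
    def test_constant_background(self):
        img = np.full((20, 20), 10.0)
        mask = np.ones((20, 20), dtype=bool)
        bg = estimate_background(img, mask)
        assert bg.mean == 10.0 and bg.sd == 0.0

    def test_two_value_mean(self):
        img = np.tile([8.0, 12.0], (20, 10))
        bg = estimate_background(img, np.ones_like(img, dtype=bool))
        assert bg.mean == 10.0

    def test_matches_masked_mean_oracle(self, rng):
        img = rng.uniform(0, 500, size=(40, 40))
        mask = rng.uniform(size=(40, 40)) > 0.5
        bg = estimate_background(img, mask)
        vals = [img[r, c] for r in range(40) for c in range(40) if mask[r, c]]
        assert abs(bg.mean - np.mean(vals)) < 1e-9
        assert abs(bg.sd - np.std(vals, ddof=1)) < 1e-9

    def test_too_few_noncell_pixels_advises_threshold_review(self):
        img = np.zeros((10, 10))
        mask = np.zeros((10, 10), dtype=bool)
        mask[0, 0] = True
        with pytest.raises(ValueError, match="threshold"):
            estimate_background(img, mask)


class TestDetectCfsePositive:
    def _image_with_components(self, sizes):
        """Horizontal runs of given pixel counts, separated by blank rows."""
        img = np.zeros((4 * len(sizes) + 4, 200))
        for i, size in enumerate(sizes):
            rows, rem = divmod(size, 100)
            r = 4 * i + 2
            img[r : r + rows, :100] = 100.0
            if rem:
                img[r + rows, :rem] = 100.0
        return img

    def test_sixty_pixel_object_kept_sixty_one_removed(self):
        img = self._image_with_components([60, 61])
        det = detect_cfse_positive(img, Background(0.0, 1.0, 100), k=3, gate_px=60)
        assert det.n_objects == 1
        assert det.n_gated == 1
        assert det.area_px == 60

    def test_blank_channel_yields_zero_area(self, rng):
        img = rng.normal(100, 5, size=(64, 64)).clip(0)
        bg = Background(float(img.mean()), float(img.std(ddof=1)), img.size)
        det = detect_cfse_positive(img, bg, k=5, gate_px=60)
        assert det.area_px <= 2  # at most stray single-pixel noise excursions

    def test_planted_puncta_kept_debris_gated(self):
        stack, truth = generate_scene(SceneConfig(seed=9, n_puncta=40, n_debris=3))
        from evtricoloc.segmentation import build_cell_masks, max_project

        proj = max_project(stack)
        masks = build_cell_masks(proj)
        bg = estimate_background(proj.channel("cfse"), masks.noncell_mask)
        det = detect_cfse_positive(proj.channel("cfse"), bg)
        assert det.n_gated >= 3
        assert not (det.cfse_mask & truth.debris_mask).any()
        assert 36 <= det.n_objects <= 44  # ~40 planted puncta, noise tolerance

    def test_monotone_in_k_and_gate(self, rng):
        img = rng.normal(100, 20, size=(128, 128)).clip(0)
        img[20:40, 20:40] += 300
        bg = Background(100.0, 20.0, 1000)
        areas_k = [detect_cfse_positive(img, bg, k=k).area_px for k in (1, 2, 3, 5)]
        assert all(a >= b for a, b in zip(areas_k, areas_k[1:]))
        areas_g = [detect_cfse_positive(img, bg, k=2, gate_px=g).area_px for g in (500, 100, 30, 5)]
        assert all(a >= b for a, b in zip(areas_g, areas_g[1:]))


class TestColocalize:
    def test_full_containment(self):
        cfse = np.zeros((50, 50), dtype=bool)
        cfse[:10, :10] = True  # 100 px
        gfap = np.zeros((50, 50), dtype=bool)
        gfap[:25, :40] = True  # 1000 px
        res = colocalize(cfse, {"gfap": gfap})["gfap"]
        assert res.colocalized_px == 100
        assert res.normalized == pytest.approx(0.1)

    def test_disjoint_masks_zero(self):
        cfse = np.zeros((10, 10), dtype=bool)
        cfse[0] = True
        other = np.zeros((10, 10), dtype=bool)
        other[5] = True
        assert colocalize(cfse, {"t": other})["t"].colocalized_px == 0

    def test_zero_area_type_reported_missing(self):
        cfse = np.ones((5, 5), dtype=bool)
        res = colocalize(cfse, {"iba1": np.zeros((5, 5), dtype=bool)})["iba1"]
        assert res.normalized is None

    def test_matches_pixel_loop_oracle(self, rng):
        cfse = rng.uniform(size=(48, 48)) > 0.8
        masks = {n: rng.uniform(size=(48, 48)) > 0.6 for n in ("gfap", "btub")}
        res = colocalize(cfse, masks)
        for name, mask in masks.items():
            count = sum(
                1 for r in range(48) for c in range(48) if cfse[r, c] and mask[r, c]
            )
            assert res[name].colocalized_px == count

    def test_disjoint_types_sum_bounded_by_total(self, rng):
        cfse = rng.uniform(size=(64, 64)) > 0.7
        a = rng.uniform(size=(64, 64)) > 0.5
        masks = {"gfap": a, "btub": ~a}
        res = colocalize(cfse, masks)
        assert res["gfap"].colocalized_px + res["btub"].colocalized_px <= cfse.sum()


class TestRotationNull:
    def test_full_frame_mask_invariant(self, rng):
        cfse = rng.uniform(size=(32, 32)) > 0.9
        full = np.ones((32, 32), dtype=bool)
        obs = colocalize(cfse, {"t": full})["t"]
        null = rotation_null(cfse, {"t": full})["t"]
        assert null.cfse_fraction == obs.cfse_fraction == 1.0

    def test_half_plane_construction(self):
        cfse = np.zeros((40, 40), dtype=bool)
        cfse[:, :20] = True
        left = np.zeros((40, 40), dtype=bool)
        left[:, :20] = True
        assert colocalize(cfse, {"t": left})["t"].cfse_fraction == 1.0
        null = rotation_null(cfse, {"t": left})["t"]
        # rotated left half becomes a horizontal half: coincidental overlap = 50%
        assert null.cfse_fraction == pytest.approx(0.5)

    def test_direction_configurable(self, rng):
        cfse = rng.uniform(size=(30, 30)) > 0.8
        mask = rng.uniform(size=(30, 30)) > 0.5
        ccw = rotation_null(cfse, {"t": mask}, direction="ccw")["t"]
        cw = rotation_null(cfse, {"t": mask}, direction="cw")["t"]
        assert ccw.colocalized_px != cw.colocalized_px or ccw == cw  # both valid rotations

    def test_independent_signals_colocalize_at_coverage(self):
        """Two independent signals at 50% coverage colocalize ~50%."""
        fractions = []
        for seed in range(40):
            mask = random_coverage_mask((128, 128), 0.5, seed)
            rng = np.random.default_rng(1000 + seed)
            cfse = rng.uniform(size=(128, 128)) > 0.9
            fractions.append(colocalize(cfse, {"t": mask})["t"].cfse_fraction)
        se = np.std(fractions, ddof=1) / np.sqrt(len(fractions))
        assert abs(np.mean(fractions) - 0.5) < 3 * se + 0.01


class TestFlagOutliers:
    def test_single_gross_outlier_flagged(self):
        flags = flag_outliers([10, 10, 10, 10, 100])
        assert flags.tolist() == [False, False, False, False, True]

    def test_identical_values_unflagged(self):
        assert not flag_outliers([5.0] * 6).any()

    def test_too_few_values_warns(self):
        with pytest.warns(UserWarning):
            flags = flag_outliers([1.0, 2.0])
        assert not flags.any()

    def test_false_flag_rate_near_alpha(self):
        """Grubbs at alpha=0.05 flags ~5% of clean Gaussian datasets."""
        rng = np.random.default_rng(0)
        n_sims = 300
        flagged = sum(flag_outliers(rng.normal(size=20), alpha=0.05).any() for _ in range(n_sims))
        rate = flagged / n_sims
        se = np.sqrt(0.05 * 0.95 / n_sims)
        assert abs(rate - 0.05) < 3 * se


def _make_measurement(image_id, condition, value, bg=100.0):
    m = UptakeMeasurement(image_id=image_id, condition=condition)
    m.background_mean = bg
    m.cfse_area_per_cell_area = value
    m.total_cfse_area_px = int(value * 1000)
    m.cell_area_px = 1000
    m.coloc = {"gfap": TypeColoc(10, 0.01, 0.5)}
    m.null_coloc = {"gfap": TypeColoc(5, 0.005, 0.25)}
    return m


class TestSummarizeCondition:
    def test_pbs_subtracted_mean_is_zero(self):
        ms = [_make_measurement(f"i{i}", "PBS", 2.0) for i in range(4)]
        ms += [_make_measurement(f"e{i}", "EV", 5.0) for i in range(4)]
        ms += [_make_measurement(f"c{i}", "CFSE", 2.5) for i in range(4)]
        table = summarize_condition(ms)
        pbs = table[table["condition"] == "PBS"].iloc[0]
        assert pbs["cfse_area_per_cell_area_ctrl_sub"] == 0.0

    def test_control_subtraction_arithmetic(self):
        ms = [_make_measurement(f"i{i}", "PBS", 2.0) for i in range(3)]
        ms += [_make_measurement(f"e{i}", "EV", 5.0) for i in range(3)]
        table = summarize_condition(ms, dye_control="missing")
        ev = table[table["condition"] == "EV"].iloc[0]
        assert ev["cfse_area_per_cell_area_ctrl_sub"] == pytest.approx(3.0)

    def test_exceeds_both_controls_flag(self):
        ms = [_make_measurement(f"p{i}", "PBS", 2.0) for i in range(3)]
        ms += [_make_measurement(f"c{i}", "CFSE", 3.0) for i in range(3)]
        ms += [_make_measurement(f"hi{i}", "EV-high", 6.0) for i in range(3)]
        ms += [_make_measurement(f"lo{i}", "EV-low", 3.0) for i in range(3)]
        table = summarize_condition(ms).set_index("condition")
        assert bool(table.loc["EV-high", "exceeds_both_controls"])
        assert not bool(table.loc["EV-low", "exceeds_both_controls"])

    def test_missing_control_condition_rejected(self):
        ms = [_make_measurement("a", "EV", 1.0) for _ in range(3)]
        with pytest.raises(ValueError, match="control"):
            summarize_condition(ms)

    def test_outlier_excluded_from_summary_but_flagged(self):
        ms = [_make_measurement(f"i{i}", "PBS", 2.0, bg=100.0) for i in range(5)]
        bad = _make_measurement("bad", "PBS", 50.0, bg=10000.0)
        table = summarize_condition(ms + [bad], dye_control="missing")
        assert bad.outlier_flag
        assert table.iloc[0]["n_images"] == 5
        assert table.iloc[0]["cfse_area_per_cell_area_mean"] == pytest.approx(2.0)


class TestRecoveryOnSyntheticScene:
    def test_planted_fractions_recovered(self, default_scene, default_projection, default_masks):
        """Full-pipeline CFSE-area shares per type match the planted truth."""
        _, truth = default_scene
        m = measure_uptake(default_projection, default_masks, RunConfig())
        for t in ("gfap", "btub", "iba1"):
            got = m.coloc[t].cfse_fraction
            assert got == pytest.approx(truth.true_cfse_fraction[t], abs=0.05)

    def test_noiseless_scene_with_true_masks_exact(self):
        """With noise off and ground-truth masks supplied, normalized
        colocalization equals the planted value almost exactly."""
        cfg = SceneConfig(seed=21, photon_noise=False, read_noise_sd=0.0, n_debris=0)
        stack, truth = generate_scene(cfg)
        from evtricoloc.segmentation import max_project

        proj = max_project(stack)
        clean_bg = truth.noncell_mask & ~truth.cfse_footprint_mask
        bg = estimate_background(proj.channel("cfse"), clean_bg)
        det = detect_cfse_positive(proj.channel("cfse"), bg, k=3, gate_px=10**9)
        res = colocalize(det.cfse_mask, {t: truth.masks[t] for t in ("gfap", "btub", "iba1")})
        for t in ("gfap", "btub", "iba1"):
            want = truth.true_normalized_coloc[t]
            assert res[t].normalized == pytest.approx(want, rel=0.02)
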