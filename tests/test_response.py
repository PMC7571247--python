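"""Response maps: grid evaluation, 4D stacking, recommendation extraction."""

import numpy as np
import pandas as pd
import pytest

from wavemap import (
    CleanRecord,
    NoiseSchedule,
    VolumetricResponse,
    best_settings,
    family_summary,
    make_emg_like_signal,
    make_phantom_image,
    max_achievable_curve,
    recommend_across_families,
    spatial_map,
    volumetric_response,
)
from wavemap.response import best_values_flat

SHORT_SCHEDULE = NoiseSchedule(levels=[0.1, 0.4, 0.8], kind="schedule_2d")


def constant_tensor(fill, n_eta=1, n_items=1, metric="corr", family="daubechies"):
    t = np.full((5, 5, n_eta, n_items), float(fill))
    sched = NoiseSchedule(levels=np.linspace(0.1, 1.0, n_eta), kind="schedule_2d")
    return VolumetricResponse(tensor=t, metric=metric, family=family, schedule=sched)


class TestSpatialMap:
    def test_clean_input_gives_near_zero_mse(self):
        # 128 px keeps edge coefficients a minority of the finest band, so the
        # MAD noise estimate on a clean record is exactly 0 and denoising is
        # the identity up to float error
        phantom = make_phantom_image(128, "piecewise", 7)
        srm = spatial_map(phantom, phantom, "daubechies", "mse")
        feasible = srm.values[~np.isnan(srm.values)]
        assert feasible.size >= 10
        assert np.all(feasible <= 1e-6)

    def test_bit_stable(self, piecewise_phantom, rng):
        degraded = piecewise_phantom.copy_with(
            np.clip(piecewise_phantom.data + rng.normal(0, 0.1, piecewise_phantom.shape), 0, 1)
        )
        a = spatial_map(piecewise_phantom, degraded, "symlet", "corr")
        b = spatial_map(piecewise_phantom, degraded, "symlet", "corr")
        np.testing.assert_array_equal(a.values, b.values)

    def test_haar_grid_fully_feasible_on_long_signal(self, rng):
        sig = CleanRecord(rng.standard_normal(4096), kind="signal")
        noisy = sig.copy_with(sig.data + rng.normal(0, 0.2, 4096))
        srm = spatial_map(sig, noisy, "daubechies", "corr", n_orders=1)
        assert not np.any(np.isnan(srm.values[:, 0]))
        # full grid: Haar column feasible everywhere, coif5 level 5 too (4096 >= 29*32)
        full = spatial_map(sig, noisy, "coiflet", "mse")
        assert not np.any(np.isnan(full.values))

    def test_frame_labels(self, piecewise_phantom):
        srm = spatial_map(piecewise_phantom, piecewise_phantom, "coiflet", "psnr")
        frame = srm.to_frame()
        assert list(frame.index) == [1, 2, 3, 4, 5]
        assert frame.index.name == "level" and frame.columns.name == "order"


class TestVolumetricResponse:
    def test_shape_and_determinism(self):
        bank = [
            make_phantom_image(32, "piecewise", 1),
            make_phantom_image(32, "smooth_textured", 2),
        ]
        vr = volumetric_response(bank, "daubechies", SHORT_SCHEDULE, "corr", master_seed=9)
        assert vr.tensor.shape == (5, 5, 3, 2)
        rerun = volumetric_response(bank, "daubechies", SHORT_SCHEDULE, "corr", master_seed=9)
        np.testing.assert_array_equal(vr.tensor, rerun.tensor)
        other = volumetric_response(bank, "daubechies", SHORT_SCHEDULE, "corr", master_seed=10)
        assert np.nansum(np.abs(vr.tensor - other.tensor)) > 0

    def test_multi_metric_pass_matches_single(self):
        bank = [make_phantom_image(32, "piecewise", 1)]
        multi = volumetric_response(bank, "symlet", SHORT_SCHEDULE, ("corr", "mse"), 3)
        single = volumetric_response(bank, "symlet", SHORT_SCHEDULE, "corr", 3)
        np.testing.assert_array_equal(multi["corr"].tensor, single.tensor)

    def test_corr_cells_bounded_by_one(self):
        bank = [make_phantom_image(32, "smooth_textured", 4)]
        vr = volumetric_response(bank, "coiflet", SHORT_SCHEDULE, "corr", 5)
        assert np.nanmax(vr.tensor) <= 1.0

    def test_degradation_lowers_mean_corr(self):
        bank = [make_phantom_image(64, "smooth_textured", 6)]
        sched = NoiseSchedule(levels=[0.0, 1.0], kind="schedule_2d")
        vr = volumetric_response(bank, "daubechies", sched, "corr", 7)
        assert np.nanmean(vr.tensor[:, :, 0, :]) > np.nanmean(vr.tensor[:, :, 1, :])

    def test_signals_swept_with_1d_schedule(self):
        bank = [make_emg_like_signal(1024, 2, 3)]
        sched = NoiseSchedule(levels=[0.5, 5.0], kind="schedule_1d")
        vr = volumetric_response(bank, "symlet", sched, "mse", 11)
        assert vr.tensor.shape == (5, 5, 2, 1)
        assert np.sum(~np.isnan(vr.tensor)) > 0


class TestBestSettings:
    @pytest.mark.parametrize("level", range(1, 6))
    @pytest.mark.parametrize("order", range(1, 6))
    def test_planted_optimum_recovered_everywhere(self, level, order):
        vr = constant_tensor(0.5)
        vr.tensor[level - 1, order - 1, 0, 0] = 0.9
        row = best_settings(vr).table.iloc[0]
        assert (row["level"], row["order"]) == (level, order)
        assert row["best_value"] == pytest.approx(0.9)

    def test_separable_construction_recovered(self):
        vr = constant_tensor(0.0)
        for k in range(1, 6):
            for n in range(1, 6):
                vr.tensor[k - 1, n - 1, 0, 0] = 1 - 0.01 * abs(k - 3) - 0.02 * abs(n - 2)
        row = best_settings(vr).table.iloc[0]
        assert (row["level"], row["order"]) == (3, 2)
        # brute-force oracle over the 25 cells agrees
        flat = vr.tensor[:, :, 0, 0]
        k_best, n_best = np.unravel_index(np.argmax(flat), flat.shape)
        assert (k_best + 1, n_best + 1) == (3, 2)

    def test_tie_broken_lowest_level_then_order(self):
        vr = constant_tensor(0.1)
        vr.tensor[1, 2, 0, 0] = 0.8  # level 2
        vr.tensor[3, 1, 0, 0] = 0.8  # level 4
        row = best_settings(vr).table.iloc[0]
        assert row["level"] == 2 and row["order"] == 3
        vr.tensor[1, 0, 0, 0] = 0.8  # same level, lower order wins
        row = best_settings(vr).table.iloc[0]
        assert row["level"] == 2 and row["order"] == 1

    def test_single_cell_and_all_missing(self):
        vr = constant_tensor(np.nan)
        vr.tensor[2, 4, 0, 0] = 0.42
        row = best_settings(vr).table.iloc[0]
        assert (row["level"], row["order"], row["best_value"]) == (3, 5, 0.42)
        assert row["n_feasible_cells"] == 1
        empty = constant_tensor(np.nan)
        with pytest.raises(ValueError, match="missing"):
            best_settings(empty)

    def test_minimized_metrics_use_argmin(self):
        vr = constant_tensor(0.5, metric="mse")
        vr.tensor[4, 4, 0, 0] = 0.001
        row = best_settings(vr).table.iloc[0]
        assert (row["level"], row["order"]) == (5, 5)

    def test_reported_value_matches_tensor_reread(self):
        bank = [make_phantom_image(32, "piecewise", 8)]
        vr = volumetric_response(bank, "daubechies", SHORT_SCHEDULE, "corr", 2)
        for _, row in best_settings(vr).table.iterrows():
            i = int(np.argmin(np.abs(vr.schedule.levels - row["eta"])))
            value = np.nanmean(vr.tensor[int(row["level"]) - 1, int(row["order"]) - 1, i, :])
            assert row["best_value"] == pytest.approx(value, rel=1e-12)


class TestCurvesAndSummaries:
    def test_curve_length_and_single_cell(self):
        vr = constant_tensor(np.nan, n_eta=1)
        vr.tensor[0, 0, 0, 0] = 0.77
        curve = max_achievable_curve(vr)
        assert curve.shape == (1,) and curve[0] == 0.77
        vr3 = constant_tensor(0.5, n_eta=4)
        assert max_achievable_curve(vr3).shape == (4,)

    def test_family_summary_identical_and_shifted(self):
        base = constant_tensor(0.5, n_eta=2, n_items=2)
        same = {f: constant_tensor(0.5, n_eta=2, n_items=2, family=f)
                for f in ("daubechies", "symlet", "coiflet")}
        tbl = family_summary(same)
        assert len(tbl) == 3
        assert np.allclose(tbl["difference_from_best"], 0.0)
        shifted = dict(same)
        up = constant_tensor(0.51, n_eta=2, n_items=2, family="symlet")
        shifted["symlet"] = up
        tbl = family_summary(shifted)
        diff = tbl.set_index("family")["difference_from_best"]
        assert diff["symlet"] == pytest.approx(0.0)
        assert diff["daubechies"] == pytest.approx(-0.01)
        assert diff["coiflet"] == pytest.approx(-0.01)
        _ = base  # silence lint

    def test_family_summary_rejects_misaligned(self):
        a = constant_tensor(0.5, n_eta=2)
        b = constant_tensor(0.5, n_eta=3, family="symlet")
        with pytest.raises(ValueError, match="share"):
            family_summary({"daubechies": a, "symlet": b})

    def test_best_values_flat_shape(self):
        vr = constant_tensor(0.5, n_eta=3, n_items=2)
        assert best_values_flat(vr).shape == (6,)

    def test_recommend_across_families_picks_winner(self):
        vrs = {
            "daubechies": constant_tensor(0.5, n_eta=2),
            "symlet": constant_tensor(0.6, n_eta=2, family="symlet"),
            "coiflet": constant_tensor(0.4, n_eta=2, family="coiflet"),
        }
        out = recommend_across_families(vrs)
        assert isinstance(out, pd.DataFrame)
        assert list(out["family"]) == ["symlet", "symlet"]
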