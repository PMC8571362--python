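"""Robust Z-scoring, the five-model screen battery, taxonomy and validation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lipidgi.screen import (
    classify_gi_type,
    fit_screen_models,
    median_robust_z,
    qc_filter_images,
    robust_z_scores,
    screen_scan,
    total_experiments,
    treatment_label,
    validate_gi_calls,
)


def _mini_screen(control_values, treated_value):
    """One array, control spots plus one treated spot, one image each."""
    n_ctrl = len(control_values)
    layout = pd.DataFrame({
        "array_id": "a1",
        "spot_id": list(range(1, n_ctrl + 2)),
        "gene_a": ["CTRL"] * n_ctrl + ["GX"],
        "gene_b": ["CTRL"] * (n_ctrl + 1),
        "role": ["negative-control"] * n_ctrl + ["treatment"],
    })
    meas = pd.DataFrame({
        "array_id": "a1",
        "spot_id": list(range(1, n_ctrl + 2)),
        "image_id": [f"i{i}" for i in range(n_ctrl + 1)],
        "replicate": 1,
        "mean_cell_intensity": list(control_values) + [treated_value],
        "cell_count": 50,
        "sharpness": 1.0,
        "background": 100.0,
    })
    return layout, meas


class TestRobustZ:
    controls = [10.0, 12.0, 11.0, 13.0, 14.0]

    def _z(self, treated, **kw):
        layout, meas = _mini_screen(self.controls, treated)
        zt = robust_z_scores(meas, layout, **kw)
        return float(zt.loc[zt.treatment == "CTRL__GX", "z"].iloc[0])

    def test_treated_at_control_median_scores_zero(self):
        assert self._z(np.median(self.controls)) == pytest.approx(0.0)

    def test_one_scaled_mad_above_median_scores_one(self):
        mad = stats.median_abs_deviation(self.controls, scale="normal")
        assert self._z(np.median(self.controls) + mad) == pytest.approx(1.0)

    def test_matches_hand_evaluated_definition(self):
        # z = (treated - median(controls)) / scaledMAD(controls)
        med = np.median(self.controls)
        mad = stats.median_abs_deviation(self.controls, scale="normal")
        assert self._z(20.0) == pytest.approx((20.0 - med) / mad)
        raw = stats.median_abs_deviation(self.controls)
        assert self._z(20.0, scaled_mad=False) == pytest.approx((20.0 - med) / raw)

    @pytest.mark.parametrize("shift,scale", [(5.0, 1.0), (0.0, 3.0), (-2.0, 0.5)])
    def test_affine_invariance_of_array_intensities(self, shift, scale):
        z0 = self._z(20.0)
        layout, meas = _mini_screen(
            [scale * c + shift for c in self.controls], scale * 20.0 + shift
        )
        zt = robust_z_scores(meas, layout)
        z1 = float(zt.loc[zt.treatment == "CTRL__GX", "z"].iloc[0])
        assert z1 == pytest.approx(z0, abs=1e-10)

    def test_zero_control_mad_excludes_array(self):
        layout, meas = _mini_screen([10.0] * 5, 20.0)
        zt = robust_z_scores(meas, layout)
        assert len(zt) == 0

    def test_median_z_per_treatment(self, small_screen):
        filt, _ = qc_filter_images(
            small_screen.measurements, min_cells=20,
            min_sharpness=0.8, max_background=150,
        )
        med = median_robust_z(robust_z_scores(filt, small_screen.layout))
        # planted single effects show through within sampling error
        assert med[treatment_label("GA", "CTRL")] == pytest.approx(1.0, abs=0.75)
        assert med[treatment_label("GC", "CTRL")] == pytest.approx(-2.4, abs=0.75)


class TestQcFilter:
    def test_clean_input_passes_unchanged(self, rng):
        layout, meas = _mini_screen([10, 11, 12, 13], 20.0)
        out, report = qc_filter_images(meas, min_cells=20)
        assert len(out) == len(meas)
        assert report["pass_rate"] == 1.0

    def test_zero_cell_images_removed(self):
        layout, meas = _mini_screen([10, 11, 12, 13], 20.0)
        meas.loc[0, "cell_count"] = 0
        out, report = qc_filter_images(meas, min_cells=20)
        assert len(out) == len(meas) - 1
        assert "i0" not in set(out.image_id)

    def test_planted_failure_rate_recovered(self, small_screen):
        _, report = qc_filter_images(
            small_screen.measurements, min_cells=20,
            min_sharpness=0.8, max_background=150,
        )
        planted_pass = 1.0 - small_screen.qc_truth.planted_fail.mean()
        assert report["pass_rate"] == pytest.approx(planted_pass, abs=0.01)

    def test_experiment_bookkeeping(self):
        assert total_experiments(42, 384) == 16128
        with pytest.raises(ValueError):
            total_experiments(0, 384)


class TestScreenFit:
    def test_exact_additive_data_gives_null_interaction(self, rng):
        za = 1.0 + rng.normal(0, 0.05, 8)
        zb = -0.8 + rng.normal(0, 0.05, 8)
        zab = 0.2 + rng.normal(0, 0.05, 8)  # = 1.0 - 0.8 exactly in expectation
        zc = rng.normal(0, 0.05, 8)
        fit = fit_screen_models(za, zb, zab, zc)
        assert fit.results.best_model == 3
        assert abs(fit.interaction_value) < 0.2

    def test_all_treatments_at_baseline_selects_null_model(self, rng):
        vals = [rng.normal(0, 0.3, 8) for _ in range(4)]
        fit = fit_screen_models(*vals)
        assert fit.results.best_model == 0

    def test_planted_interaction_recovered_within_3_se(self, rng):
        za = 1.0 + rng.normal(0, 0.5, 8)
        zb = 0.5 + rng.normal(0, 0.5, 8)
        zab = 1.0 + 0.5 + 2.0 + rng.normal(0, 0.5, 8)
        zc = rng.normal(0, 0.5, 8)
        fit = fit_screen_models(za, zb, zab, zc)
        assert fit.results.best_model == 4
        se = fit.results.fits[4].coefficients.loc["x_a:x_b", "se"]
        assert abs(fit.interaction_value - 2.0) < 3 * se

    def test_balanced_cell_mean_identity(self, rng):
        # with equal replicate counts and no outliers the interaction
        # coefficient equals the two-way cell-mean contrast exactly
        def noise():
            # bounded magnitudes keep all Huber weights at one
            return rng.choice([-1, 1], 8) * rng.uniform(0.07, 0.1, 8)

        za = 1.0 + noise()
        zb = -0.5 + noise()
        zab = 2.0 + noise()
        zc = noise()
        fit = fit_screen_models(za, zb, zab, zc)
        expected = zab.mean() - za.mean() - zb.mean() + zc.mean()
        assert fit.interaction_value == pytest.approx(expected, abs=1e-6)

    def test_too_few_replicates_inestimable(self, rng):
        assert fit_screen_models([1.0, 1.1], [0.5] * 8, [2.0] * 8, [0.0] * 8) is None


class TestTaxonomy:
    def test_joint_beyond_additive_expectation_is_aggravating(self):
        assert classify_gi_type(1.0, 0.8, 1.0, 0.5) == "negative-aggravating"

    def test_joint_at_most_severe_single_is_alleviating(self):
        assert classify_gi_type(-2.4, 0.5, -0.59, 0.5) == "positive-alleviating"

    def test_joint_healthier_than_worst_single_is_suppressive(self):
        assert classify_gi_type(-2.0, -0.2, 1.2, 0.5) == "positive-suppressive"

    def test_both_singles_near_zero_is_emergent(self):
        assert classify_gi_type(0.1, -0.2, 2.0, 0.5) == "emergent"

    def test_stable_under_pair_relabeling(self, rng):
        for _ in range(50):
            ba, bb, bab = rng.normal(0, 2, 3)
            assert classify_gi_type(ba, bb, bab, 0.4) == classify_gi_type(bb, ba, bab, 0.4)

    def test_exactly_one_label(self, rng):
        labels = {
            "negative-aggravating", "positive-alleviating",
            "positive-suppressive", "emergent",
        }
        for _ in range(100):
            ba, bb, bab = rng.normal(0, 2, 3)
            assert classify_gi_type(ba, bb, bab, 0.3) in labels

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError):
            classify_gi_type(1.0, 1.0, 1.0, -0.1)


class TestScreenScan:
    def test_end_to_end_recovers_planted_interaction(self, small_screen):
        filt, _ = qc_filter_images(
            small_screen.measurements, min_cells=20,
            min_sharpness=0.8, max_background=150,
        )
        table = screen_scan(robust_z_scores(filt, small_screen.layout))
        assert len(table) == 15  # C(6,2)
        row = table[table.pair == "GA__GB"].iloc[0]
        assert row.classification == "GI"
        assert row.best_model == 4
        assert row.gi_type == "negative-aggravating"
        se_proxy = 1.0
        assert row.interaction_value == pytest.approx(2.0, abs=se_proxy)
        # no spurious interaction calls among the null pairs
        assert (table.loc[table.pair != "GA__GB", "classification"] != "GI").all()

    def test_family_pools_three_terms_per_pair(self, small_screen):
        filt, _ = qc_filter_images(small_screen.measurements, min_cells=20)
        table = screen_scan(robust_z_scores(filt, small_screen.layout))
        assert (table.p_a_fdr.dropna() >= table.p_a.dropna() - 1e-12).all()
        assert table.p_ab_fdr.notna().sum() == 15


class TestValidation:
    def _primary(self):
        return pd.DataFrame({
            "pair": ["APOB__HMGCR", "GX__GY", "GZ__GW"],
            "interaction_value": [2.18, -1.5, 1.0],
            "p_ab_fdr": [1.47e-3, 1e-4, 1e-4],
        })

    def test_same_sign_significant_replication_validates(self):
        validation = pd.DataFrame({
            "pair": ["APOB__HMGCR"],
            "interaction_value": [0.97],
            "p_ab_fdr": [1.27e-3],
        })
        out = validate_gi_calls(self._primary(), validation)
        assert bool(out.loc[out.pair == "APOB__HMGCR", "validated"].iloc[0])

    def test_sign_flip_never_validates(self):
        validation = pd.DataFrame({
            "pair": ["GX__GY"], "interaction_value": [0.9], "p_ab_fdr": [1e-6],
        })
        out = validate_gi_calls(self._primary(), validation)
        assert not out.validated.iloc[0]

    def test_weak_replication_p_never_validates(self):
        validation = pd.DataFrame({
            "pair": ["GZ__GW"], "interaction_value": [0.8], "p_ab_fdr": [0.02],
        })
        out = validate_gi_calls(self._primary(), validation)
        assert not out.validated.iloc[0]

    def test_unknown_pair_skipped(self):
        validation = pd.DataFrame({
            "pair": ["NOT__THERE"], "interaction_value": [0.8], "p_ab_fdr": [1e-4],
        })
        out = validate_gi_calls(self._primary(), validation)
        assert len(out) == 0
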