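"""Amplitude extraction, robust regression, group tests and the ANOVA control."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from beliefgrid.erp import (
    extract_p3,
    extract_spn,
    factorial_control,
    group_test,
    robust_regress,
    single_trial_regression,
    znormalize,
)
from beliefgrid.simulate import EpochSet


def _epochs(data, sfreq=128.0, electrodes=("FCz", "C3")):
    data = np.asarray(data, dtype=np.float32)
    n_t = data.shape[2]
    times = -1500.0 + np.arange(n_t) * 1000.0 / sfreq
    meta = pd.DataFrame({"participant": [1] * data.shape[0],
                         "block": [1] * data.shape[0],
                         "trial": range(1, data.shape[0] + 1)})
    return EpochSet(data=data, times_ms=times, electrodes=electrodes,
                    sfreq=sfreq, meta=meta)


class TestExtraction:
    def test_flat_epoch_is_baseline_corrected_to_zero(self):
        ep = _epochs(np.full((3, 2, 385), 7.0))
        assert np.allclose(extract_p3(ep, "FCz"), 0.0)
        assert np.allclose(extract_spn(ep, "C3"), 0.0)

    def test_noiseless_bump_recovers_its_peak(self):
        # 160 Hz sampling places a sample exactly at the 350 ms peak
        times = -1500.0 + np.arange(481) * 1000.0 / 160.0
        bump = 2.5 * np.exp(-0.5 * ((times - 350.0) / 40.0) ** 2)
        ep = _epochs(np.tile(bump, (2, 2, 1)), sfreq=160.0)
        assert np.allclose(extract_p3(ep, "FCz"), 2.5, atol=1e-4)

    def test_linear_ramp_closed_form(self):
        # v(t) = -a (t + 1500)/1500 on the whole epoch: window mean -5a/6,
        # baseline mean -a/15, so the SPN amplitude is -23a/30.
        a = 3.0
        times = -1500.0 + np.arange(385) * 1000.0 / 128.0
        ramp = -a * (times + 1500.0) / 1500.0
        ep = _epochs(np.tile(ramp, (2, 2, 1)))
        assert np.allclose(extract_spn(ep, "C3"), -23 * a / 30, atol=0.02)

    def test_window_outside_epoch_raises(self):
        short = _epochs(np.zeros((2, 2, 10)), sfreq=128.0)  # covers ~70 ms
        with pytest.raises(ValueError, match="outside epoch"):
            extract_p3(short, "FCz")

    def test_unknown_electrode_raises(self):
        with pytest.raises(KeyError):
            extract_p3(_epochs(np.zeros((2, 2, 385))), "Oz")


class TestZnormalize:
    def test_per_participant_moments(self, rng):
        vals = rng.normal(5, 3, 40)
        pids = np.repeat([1, 2], 20)
        z = znormalize(vals, pids)
        for pid in (1, 2):
            assert z[pids == pid].mean() == pytest.approx(0.0, abs=1e-12)
            assert z[pids == pid].std(ddof=0) == pytest.approx(1.0, abs=1e-12)

    def test_scale_invariance(self, rng):
        vals = rng.normal(size=30)
        pids = np.zeros(30)
        assert np.allclose(znormalize(3.7 * vals, pids), znormalize(vals, pids))

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="zero amplitude variance"):
            znormalize(np.ones(10), np.zeros(10))


class TestRobustRegress:
    def test_noiseless_line_recovered_exactly(self, rng):
        x = rng.normal(size=50)
        coefs = robust_regress(2.0 * x, x[:, None])
        assert coefs[0] == pytest.approx(0.0, abs=1e-10)
        assert coefs[1] == pytest.approx(2.0, abs=1e-10)

    def test_resists_gross_outliers(self, rng):
        x = rng.normal(size=200)
        y = x + 0.1 * rng.normal(size=200)
        y[:10] += 25.0  # 5% gross contamination
        beta_rob = robust_regress(y, x[:, None])[1]
        beta_ols = np.polyfit(x, y, 1)[0]
        assert abs(beta_rob - 1.0) < abs(beta_ols - 1.0)
        assert abs(beta_rob - 1.0) < 0.05

    def test_matches_statsmodels_bisquare(self, rng):
        x = rng.normal(size=120, scale=1.3)
        y = 0.5 + 0.8 * x + rng.standard_t(3, size=120)
        ours = robust_regress(y, x[:, None])
        X = sm.add_constant(x)
        theirs = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight(c=4.685)).fit().params
        assert np.allclose(ours, theirs, atol=5e-3)

    def test_collinear_design_names_columns(self, rng):
        x = rng.normal(size=40)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(ValueError, match="collinear"):
            robust_regress(x, X)

    def test_underdetermined_raises(self):
        with pytest.raises(ValueError, match="observations"):
            robust_regress(np.ones(3), np.ones((3, 2)))


class TestGroupTest:
    def test_zero_betas_are_non_significant(self):
        res = group_test(pd.DataFrame({"I": np.zeros(10)}), n_comparisons=4)
        assert not res.significant.iloc[0]
        assert np.isnan(res.t.iloc[0])

    def test_planted_shift_detected_and_bonferroni_capped(self, rng):
        null = rng.normal(0.0, 0.1, 16)
        betas = pd.DataFrame({"I": rng.normal(0.5, 0.1, 16),
                              "S": null - null.mean()})  # exactly null effect
        res = group_test(betas, n_comparisons=4).set_index("predictor")
        assert res.loc["I", "significant"]
        assert not res.loc["S", "significant"]
        assert res.p_corrected.le(1.0).all()
        assert (res.df == 15).all()

    def test_too_few_participants_raise(self):
        with pytest.raises(ValueError, match="at least 3"):
            group_test(pd.DataFrame({"I": [0.1, 0.2]}), n_comparisons=4)


def _amp_var_tables(rng, n_participants=6, n_trials=60, effect=0.0):
    rows_a, rows_v = [], []
    for pid in range(1, n_participants + 1):
        I = rng.normal(size=n_trials)
        amp = effect * I + rng.normal(size=n_trials)
        trial = np.tile(np.arange(1, 16), n_trials // 15 + 1)[:n_trials]
        block = np.repeat(np.arange(1, n_trials // 15 + 2), 15)[:n_trials]
        base = {"participant": pid, "block": block, "trial": trial}
        rows_a.append(pd.DataFrame(base | {"electrode": "FCz", "amplitude": amp}))
        rows_v.append(pd.DataFrame(base | {"I": I, "I_KL": np.abs(I), "S": rng.normal(size=n_trials)}))
    return pd.concat(rows_a, ignore_index=True), pd.concat(rows_v, ignore_index=True)


class TestSingleTrialRegression:
    def test_update_size_measures_are_mutually_exclusive(self, rng):
        amps, var = _amp_var_tables(rng)
        with pytest.raises(ValueError, match="never both"):
            single_trial_regression(amps, var, ("I", "I_KL"))

    def test_recovers_planted_effect(self, rng):
        amps, var = _amp_var_tables(rng, effect=0.5)
        res = single_trial_regression(amps, var, ("I", "S"), n_comparisons=4)
        grp = res.group.set_index("predictor")
        assert grp.loc["I", "mean_beta"] == pytest.approx(0.5 / np.sqrt(1.25), abs=0.06)
        assert grp.loc["I", "significant"]
        assert not grp.loc["S", "significant"]


class TestFactorialControl:
    def test_update_size_effect_without_stage_effect(self, rng):
        amps, var = _amp_var_tables(rng, n_participants=8, n_trials=120, effect=1.0)
        res = factorial_control(amps, var)
        assert res.table.loc["update_size", "p"] < 0.01
        assert res.table.loc["stage", "p"] > 0.05
        assert set(res.cell_means.stage.unique()) == {"early", "middle", "late"}

    def test_null_amplitudes_yield_null_anova(self, rng):
        amps, var = _amp_var_tables(rng, n_participants=8, n_trials=120, effect=0.0)
        res = factorial_control(amps, var)
        assert res.table.p.min() > 0.01

    def test_invariant_to_trial_order(self, rng):
        amps, var = _amp_var_tables(rng, n_trials=75)
        perm = rng.permutation(len(amps))
        shuffled = factorial_control(amps.iloc[perm].reset_index(drop=True), var)
        plain = factorial_control(amps, var)
        pd.testing.assert_frame_equal(shuffled.table, plain.table)

    def test_empty_cell_names_participant(self, rng):
        amps, var = _amp_var_tables(rng, n_participants=4, n_trials=60)
        # force participant 2's late-stage trials to all be small updates
        late = (var.participant == 2) & (var.trial > 10)
        var.loc[late, "I"] = var[var.participant == 2].I.min() - 1.0
        with pytest.raises(ValueError, match="2"):
            factorial_control(amps, var)
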