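"""History regression: design matrix, penalised fit, derived summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from seqbias import (
    CW,
    ObserverParams,
    accuracy_summaries,
    apply_exclusion_criteria,
    assign_correct_labels,
    build_design_matrix,
    build_session,
    conditioned_psychometric,
    derive_history_summaries,
    fit_lasso_logistic,
    generate_counterbalanced_sequence,
    lag1_params,
    simulate_session,
)
from seqbias.history import HistoryFit


@pytest.fixture(scope="module")
def sim_10k():
    """10k neutral trials from a lag-1 stimulus-kernel observer."""
    seq = generate_counterbalanced_sequence(10_000, seed=11)
    seq = assign_correct_labels(seq, seed=12)
    p = lag1_params(0.4, 0.0, slope=20.0, lapse_cw=0.0, lapse_ccw=0.0)
    return simulate_session(p, seq, seed=13)


@pytest.fixture(scope="module")
def null_10k():
    seq = generate_counterbalanced_sequence(10_000, seed=21)
    seq = assign_correct_labels(seq, seed=22)
    p = ObserverParams(slope=20.0, lapse_cw=0.0, lapse_ccw=0.0)
    return simulate_session(p, seq, seed=23)


class TestDesignMatrix:
    def test_row_and_column_counts(self, session_design):
        data = simulate_session(ObserverParams(), session_design, seed=1)
        dm = build_design_matrix(data, "neutral")
        assert dm.X.shape == (593, 15)  # 600 trials - 7 burn-in lags
        assert sum(c.startswith(("stim_", "choice_")) for c in dm.columns) == 14

    def test_row_by_row_lag_audit(self):
        """Audit every retained row of a 20-trial fixture against a direct
        Python enumeration of the lag structure (with one missed response)."""
        rng = np.random.default_rng(0)
        n = 20
        ori = rng.choice([1, -1], n)
        resp = rng.choice([1, -1], n).astype(float)
        resp[9] = np.nan  # missed trial
        df = pd.DataFrame(
            {
                "participant_id": "p1",
                "environment": "neutral",
                "trial": np.arange(1, n + 1),
                "orientation": ori,
                "contrast": np.resize([0.0, 0.06, 0.12], n),
                "signed_contrast": ori * np.resize([0.0, 0.06, 0.12], n),
                "response": resp,
                "is_correct": 0,
            }
        )
        dm = build_design_matrix(df, "neutral", n_lags=3)
        r_filled = np.nan_to_num(resp)
        expected_rows = [t for t in range(3, n) if np.isfinite(resp[t])]
        assert len(dm.y) == len(expected_rows)
        for row, t in enumerate(expected_rows):
            assert dm.X[row, dm.columns.index("contrast")] == df["signed_contrast"][t]
            for k in (1, 2, 3):
                assert dm.X[row, dm.columns.index(f"stim_{k}")] == ori[t - k]
                assert dm.X[row, dm.columns.index(f"choice_{k}")] == r_filled[t - k]
            assert dm.y[row] == (resp[t] == CW)

    def test_lags_do_not_cross_environment_boundary(self, session_design):
        data = simulate_session(ObserverParams(), session_design, seed=2)
        dm = build_design_matrix(data, "repeating")
        # first retained repeating trial is environment trial 8 (index 7);
        # its lag-7 stimulus is the first repeating trial, not a neutral one
        rep = data[data["environment"] == "repeating"].sort_values("trial")
        assert dm.trial_index[0] == rep["trial"].iloc[7]
        assert dm.X[0, dm.columns.index("stim_7")] == rep["orientation"].iloc[0]

    def test_small_dataset_flagged(self):
        df = pd.DataFrame(
            {
                "participant_id": "p1",
                "environment": "neutral",
                "trial": np.arange(1, 31),
                "orientation": np.resize([1, -1], 30),
                "contrast": 0.12,
                "response": np.resize([1, -1], 30).astype(float),
                "is_correct": 1,
            }
        )
        dm = build_design_matrix(df, "neutral")
        assert dm.warning is not None and "analyzable" in dm.warning


class TestLassoFit:
    def test_null_observer_weights_near_zero(self, null_10k):
        fit = fit_lasso_logistic(build_design_matrix(null_10k, "neutral"), lapse_mode="none")
        hist = np.concatenate([fit.stim_kernel(), fit.choice_kernel()])
        assert np.abs(hist).max() <= 0.05
        assert fit.converged

    def test_generating_kernel_recovered(self, sim_10k):
        fit = fit_lasso_logistic(build_design_matrix(sim_10k, "neutral"), lapse_mode="none")
        assert fit.weights["stim_1"] == pytest.approx(0.4, abs=0.1)
        assert fit.weights["contrast"] == pytest.approx(20.0, rel=0.15)

    def test_huge_lambda_shrinks_history_to_zero(self, sim_10k):
        fit = fit_lasso_logistic(
            build_design_matrix(sim_10k, "neutral"), lam=1e3, lapse_mode="none"
        )
        hist = np.concatenate([fit.stim_kernel(), fit.choice_kernel()])
        assert np.abs(hist).max() < 1e-6
        # unpenalised terms survive
        assert fit.weights["contrast"] > 1.0

    def test_tiny_lambda_matches_unpenalised_logistic(self, sim_10k):
        dm = build_design_matrix(sim_10k, "neutral")
        fit = fit_lasso_logistic(dm, lam=1e-10, lapse_mode="none")
        Xd = sm.add_constant(dm.X)
        ref = sm.Logit(dm.y, Xd).fit(disp=0)
        mine = np.array(
            [fit.weights["intercept"]] + [fit.weights[c] for c in dm.columns]
        )
        assert np.allclose(mine, ref.params, atol=2e-3)

    def test_lapse_grid_recovers_lapse_rates(self):
        seq = generate_counterbalanced_sequence(20_000, seed=31)
        seq = assign_correct_labels(seq, seed=32)
        p = ObserverParams(slope=20.0, lapse_cw=0.08, lapse_ccw=0.04)
        data = simulate_session(p, seq, seed=33)
        fit = fit_lasso_logistic(build_design_matrix(data, "neutral"))
        assert fit.lapse_cw == pytest.approx(0.08, abs=0.03)
        assert fit.lapse_ccw == pytest.approx(0.04, abs=0.03)

    def test_degenerate_single_class_rejected(self):
        df = pd.DataFrame(
            {
                "participant_id": "p1",
                "environment": "neutral",
                "trial": np.arange(1, 101),
                "orientation": np.resize([1, -1], 100),
                "contrast": 0.18,
                "response": 1.0,
                "is_correct": 1,
            }
        )
        with pytest.raises(ValueError, match="one response class"):
            fit_lasso_logistic(build_design_matrix(df, "neutral"))


def _fit_from_kernels(ws, wc, env="neutral"):
    weights = {"intercept": 0.0, "contrast": 10.0}
    for k, (a, b) in enumerate(zip(ws, wc), start=1):
        weights[f"stim_{k}"] = a
        weights[f"choice_{k}"] = b
    return HistoryFit(
        participant_id="p1",
        environment=env,
        lam=0.001,
        weights=weights,
        lapse_cw=0.0,
        lapse_ccw=0.0,
        converged=True,
        objective=0.0,
        n_lags=len(ws),
    )


class TestSummaries:
    def test_prev_correct_incorrect_definitions(self):
        fn = _fit_from_kernels([0.3], [0.2])
        fr = _fit_from_kernels([0.3], [0.2], env="repeating")
        s = derive_history_summaries(fn, fr)
        assert s["prev_correct_neutral"].iloc[0] == pytest.approx(0.5)
        assert s["prev_incorrect_neutral"].iloc[0] == pytest.approx(-0.1)
        assert (s["adaptation"] == 0).all()

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        ws=st.lists(st.floats(-1, 1), min_size=3, max_size=3),
        wc=st.lists(st.floats(-1, 1), min_size=3, max_size=3),
    )
    def test_transformation_is_involution_consistent(self, ws, wc):
        # (stim, choice) -> (correct, incorrect) -> back recovers the kernels
        fit = _fit_from_kernels(ws, wc)
        pc = fit.prev_correct_kernel()
        pi = fit.prev_incorrect_kernel()
        assert np.allclose((pc - pi) / 2, ws)
        assert np.allclose((pc + pi) / 2, wc)

    def test_prev_correct_equals_reparameterised_refit(self, sim_10k):
        """Fitting with explicit previous-correct / previous-incorrect
        regressors (an exact linear reparameterisation) reproduces
        w_stim + w_choice, unpenalised."""
        dm = build_design_matrix(sim_10k, "neutral", n_lags=2)
        fit = fit_lasso_logistic(dm, lam=1e-10, lapse_mode="none")
        X2 = dm.X.copy()
        for k in (1, 2):
            s_col = dm.columns.index(f"stim_{k}")
            r_col = dm.columns.index(f"choice_{k}")
            s, r = dm.X[:, s_col], dm.X[:, r_col]
            X2[:, s_col] = (s + r) / 2  # previous-correct regressor
            X2[:, r_col] = (r - s) / 2  # previous-incorrect regressor
        ref = sm.Logit(dm.y, sm.add_constant(X2)).fit(disp=0)
        for k in (1, 2):
            pc = fit.weights[f"stim_{k}"] + fit.weights[f"choice_{k}"]
            assert pc == pytest.approx(ref.params[dm.columns.index(f"stim_{k}") + 1], abs=2e-3)


class TestBehavioralSummaries:
    def test_null_zero_contrast_chance(self, null_10k):
        acc = accuracy_summaries(null_10k)
        zero = acc["by_contrast"].query("contrast == 0")
        assert zero["accuracy"].iloc[0] == pytest.approx(0.5, abs=0.02)

    def test_perfect_observer(self, session_design):
        df = session_design.to_frame("p1")
        df["signed_contrast"] = df["orientation"] * df["contrast"]
        df["response"] = df["correct_label"].astype(float)
        df["is_correct"] = 1
        acc = accuracy_summaries(df)
        nz = acc["by_contrast"].query("contrast > 0")
        assert (nz["accuracy"] == 1.0).all()

    def test_adapted_observer_beats_chance_on_repeating_zero_contrast(
        self, session_design
    ):
        p = lag1_params(0.4, 0.4, slope=20.0)  # prev-correct kernel 0.8
        df = simulate_session(p, session_design, seed=3)
        acc = accuracy_summaries(df)
        zero_rep = acc["by_contrast"].query("environment == 'repeating' and contrast == 0")
        assert zero_rep["accuracy"].iloc[0] > 0.5

    def test_conditioned_psychometric_separation_larger_when_adapted(
        self, session_design
    ):
        params = {
            "neutral": ObserverParams(slope=20.0),
            "repeating": lag1_params(0.5, 0.3, slope=20.0),
        }
        df = simulate_session(params, session_design, seed=4)
        curves = conditioned_psychometric(df)
        sep = {}
        for env, d in curves.groupby("environment"):
            piv = d.pivot_table(
                index="signed_contrast", columns="prev_orientation", values="p_cw"
            )
            sep[env] = float((piv[1] - piv[-1]).mean())
        assert sep["repeating"] > sep["neutral"] + 0.05

    def test_conditioned_psychometric_null_curves_coincide(self, null_10k):
        curves = conditioned_psychometric(null_10k)
        piv = curves.pivot_table(
            index="signed_contrast", columns="prev_orientation", values="p_cw"
        )
        assert np.abs(piv[1] - piv[-1]).max() < 0.06

    def test_model_prediction_attached(self, sim_10k):
        dm_fit = fit_lasso_logistic(
            build_design_matrix(sim_10k, "neutral"), lapse_mode="none"
        )
        curves = conditioned_psychometric(sim_10k, fits={"neutral": dm_fit})
        assert curves["p_cw_model"].notna().all()
        # model tracks the empirical curve
        err = (curves["p_cw"] - curves["p_cw_model"]).abs().mean()
        assert err < 0.05


class TestExclusions:
    @staticmethod
    def _participant(pid, acc_neutral=0.9, acc_repeating=0.9, n_missed=0):
        n = 600
        rng = np.random.default_rng(hash(pid) % 2**31)
        frames = []
        for env, acc in (("neutral", acc_neutral), ("repeating", acc_repeating)):
            correct = (rng.random(n) < acc).astype(int)
            resp = np.where(correct == 1, 1.0, -1.0)
            frames.append(
                pd.DataFrame(
                    {
                        "participant_id": pid,
                        "environment": env,
                        "trial": np.arange(1, n + 1),
                        "orientation": 1,
                        "contrast": 0.12,
                        "correct_label": 1,
                        "response": resp,
                        "is_correct": correct,
                    }
                )
            )
        df = pd.concat(frames, ignore_index=True)
        if n_missed:
            idx = df.index[:n_missed]
            df.loc[idx, "response"] = np.nan
            df.loc[idx, "is_correct"] = 0
        return df

    def test_rules_fire_individually(self):
        data = pd.concat(
            [
                self._participant("ok"),
                self._participant("low_env", acc_repeating=0.60),
                self._participant("missed", n_missed=61),
                self._participant("low_overall", acc_neutral=0.5, acc_repeating=0.5),
            ],
            ignore_index=True,
        )
        kept, report = apply_exclusion_criteria(data)
        report = report.set_index("participant_id")
        assert not report.loc["ok", "excluded"]
        assert report.loc["low_env", "rules_fired"] == "3"
        assert "2" in report.loc["missed", "rules_fired"]
        assert "1" in report.loc["low_overall", "rules_fired"]
        assert set(kept["participant_id"]) == {"ok"}

    def test_sixty_missed_is_retained(self):
        data = self._participant("edge", n_missed=60)
        _, report = apply_exclusion_criteria(data)
        assert not report["excluded"].iloc[0]
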