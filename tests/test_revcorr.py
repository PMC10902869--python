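"""Reverse correlation: z-scoring, bin fits, outlier filtering, summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats as sps

from seqbias import (
    ObserverParams,
    build_session,
    fit_bin,
    lag1_params,
    remove_outliers_iqr,
    reverse_correlation,
    simulate_session,
    summarize_revcorr,
    zero_contrast_energy_stacks,
    zscore_energy,
)
from seqbias.design import DesignConfig
from seqbias.revcorr import _irls_2param, stacks_from_frame


class TestZscore:
    def test_groups_standardised(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "participant_id": "p1",
                "environment": np.repeat(["neutral", "repeating"], 50),
                "prev_stim": np.resize([1, -1], 100),
                "orientation_deg": 10,
                "sf_cpd": 1.0,
                "energy": rng.gamma(2, 1, 100),
            }
        )
        out = zscore_energy(df)
        g = out.groupby(["environment", "prev_stim"])["z_energy"]
        assert np.abs(g.mean()).max() < 1e-10
        assert np.abs(g.std(ddof=1) - 1).max() < 1e-10

    def test_constant_group_dropped(self, caplog):
        df = pd.DataFrame(
            {
                "participant_id": "p1",
                "environment": "neutral",
                "prev_stim": [1] * 5 + [-1] * 5,
                "orientation_deg": 0,
                "sf_cpd": 1.0,
                "energy": [2.0] * 5 + [1, 2, 3, 4, 5],
            }
        )
        with caplog.at_level("WARNING"):
            out = zscore_energy(df)
        assert len(out) == 5
        assert (out["prev_stim"] == -1).all()
        assert any("degenerate" in r.message for r in caplog.records)

    def test_hand_computed_five_values(self):
        vals = np.array([2.0, 4.0, 4.0, 4.0, 6.0])
        df = pd.DataFrame(
            {
                "participant_id": "p1",
                "environment": "neutral",
                "prev_stim": 1,
                "orientation_deg": 0,
                "sf_cpd": 1.0,
                "energy": vals,
            }
        )
        out = zscore_energy(df)
        expected = (vals - 4.0) / np.sqrt(8.0 / 4.0)  # sample SD, ddof=1
        assert np.allclose(out["z_energy"], expected)


class TestFitBin:
    def test_simulation_oracle(self):
        rng = np.random.default_rng(1)
        z = rng.standard_normal(10_000)
        p = 1 / (1 + np.exp(-0.5))  # beta0=0.5, beta1=0
        y = (rng.random(10_000) < p).astype(float)
        fit = fit_bin(z, y)
        assert fit.beta0 == pytest.approx(0.5, abs=0.07)
        assert fit.beta1 == pytest.approx(0.0, abs=0.07)
        assert not fit.separated

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(2)
        z = rng.standard_normal(500)
        y = (rng.random(500) < 1 / (1 + np.exp(-(0.3 + 0.8 * z)))).astype(float)
        fit = fit_bin(z, y)
        ref = sm.Logit(y, sm.add_constant(z)).fit(disp=0)
        assert fit.beta0 == pytest.approx(ref.params[0], abs=1e-6)
        assert fit.beta1 == pytest.approx(ref.params[1], abs=1e-6)

    def test_vectorised_equals_per_column(self):
        rng = np.random.default_rng(3)
        z = rng.standard_normal((300, 6))
        y = (rng.random(300) < 0.5).astype(float)
        b0, b1, sep = _irls_2param(z, y)
        for c in range(6):
            f = fit_bin(z[:, c], y)
            assert b0[c] == pytest.approx(f.beta0, abs=1e-8)
            assert b1[c] == pytest.approx(f.beta1, abs=1e-8)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            fit_bin(np.arange(10.0), np.ones(10))

    def test_separation_flagged_and_truncated(self):
        z = np.linspace(-2, 2, 40)
        y = (z > 0).astype(float)  # perfectly label-matched
        fit = fit_bin(z, y)
        assert fit.separated
        assert abs(fit.beta1) <= 10.0


class TestIqrFilter:
    @staticmethod
    def _frame(values):
        return pd.DataFrame(
            {"prev_stim": 1, "environment": "neutral", "beta0": values}
        )

    def test_obvious_outlier_removed(self):
        df = self._frame(list(range(1, 11)) + [100])
        kept, report = remove_outliers_iqr(df, "beta0")
        assert 100 not in kept["beta0"].to_numpy()
        assert len(kept) == 10
        # brute-force quartile oracle (linear interpolation)
        v = np.array(sorted(range(1, 11)) + [100], float)
        q1, q3 = np.percentile(v, [25, 75])
        assert report["n_removed"].iloc[0] == int(
            ((v < q1 - 1.5 * (q3 - q1)) | (v > q3 + 1.5 * (q3 - q1))).sum()
        )

    def test_identical_values_all_kept(self):
        kept, _ = remove_outliers_iqr(self._frame([3.0] * 8), "beta0")
        assert len(kept) == 8

    def test_small_pool_unfiltered(self, caplog):
        with caplog.at_level("WARNING"):
            kept, report = remove_outliers_iqr(self._frame([0.0, 1.0, 99.0]), "beta0")
        assert len(kept) == 3
        assert not report["filtered"].iloc[0]

    def test_gaussian_tail_fraction_matches_tukey_expectation(self):
        rng = np.random.default_rng(4)
        df = self._frame(rng.standard_normal(10_000))
        kept, report = remove_outliers_iqr(df, "beta0")
        removed = report["n_removed"].iloc[0] / 10_000
        # fences at +/-2.698 sigma -> 2 * norm.sf(2.698) ~ 0.70% expected
        expected = 2 * sps.norm.sf(2.698)
        assert removed == pytest.approx(expected, abs=0.004)


class TestSummaries:
    @staticmethod
    def _random_bins(seed=0, n_cells=40):
        rng = np.random.default_rng(seed)
        o = rng.choice(np.arange(-89, 91), n_cells)
        rows = []
        for prev in (1, -1):
            for env in ("neutral", "repeating"):
                rows.append(
                    pd.DataFrame(
                        {
                            "participant_id": "p1",
                            "environment": env,
                            "prev_stim": prev,
                            "orientation_deg": o,
                            "sf_cpd": 1.0,
                            "beta0": rng.normal(0.2 * prev, 0.3, n_cells),
                            "beta1": rng.normal(0.1, 0.3, n_cells),
                            "separated": False,
                            "n": 50,
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)

    def test_label_symmetry(self):
        """Flipping orientations, responses and previous-stimulus labels
        negates the bias summaries and swaps the CW/CCW sensitivity classes."""
        bins = self._random_bins(5)
        flipped = bins.assign(
            prev_stim=-bins["prev_stim"],
            orientation_deg=-bins["orientation_deg"],
            beta0=-bins["beta0"],
        )
        a = summarize_revcorr(bins)
        b = summarize_revcorr(flipped)
        ka = a.bias.set_index(["environment", "prev_stim"])["bias"]
        kb = b.bias.set_index(["environment", "prev_stim"])["bias"]
        for (env, prev), v in ka.items():
            assert kb.loc[(env, -prev)] == pytest.approx(-v)
        sa = a.sensitivity.set_index(["environment", "prev_stim", "energy_class"])[
            "sensitivity"
        ]
        sb = b.sensitivity.set_index(["environment", "prev_stim", "energy_class"])[
            "sensitivity"
        ]
        swap = {"cw": "ccw", "ccw": "cw"}
        for (env, prev, cls), v in sa.items():
            assert sb.loc[(env, -prev, swap[cls])] == pytest.approx(v)

    def test_edge_orientations_excluded_from_classes(self):
        bins = self._random_bins(6)
        bins.loc[:, "orientation_deg"] = np.resize([0, 90, 45, -45], len(bins))
        res = summarize_revcorr(bins)
        # only the +/-45 cells enter the class averages
        assert (res.sensitivity["n_cells"] <= (bins.groupby(["environment", "prev_stim"]).size() // 2).max()).all()
        assert set(res.sensitivity["energy_class"]) == {"cw", "ccw"}


@pytest.fixture(scope="module")
def zero_contrast_setup(bank64):
    cfg = DesignConfig(n_blocks_per_env=2, trials_per_block=100, contrasts=(0.0,))
    sd = build_session(cfg, seed=41)
    stacks, means = zero_contrast_energy_stacks(sd, bank64, seed=42)
    return sd, stacks, means


class TestEndToEnd:
    def test_positive_contrast_trials_rejected(self, session_design, bank64):
        stacks, _ = zero_contrast_energy_stacks(session_design, bank64, seed=1)
        data = simulate_session(ObserverParams(), session_design, seed=2)
        stacks[0].trial = stacks[0].trial + 1  # misalign onto nonzero trials
        with pytest.raises(ValueError, match="0%"):
            reverse_correlation(data, stacks)

    def test_decision_bias_observer_dissociation(self, zero_contrast_setup):
        sd, stacks, _ = zero_contrast_setup
        p = lag1_params(0.4, 0.4, slope=20.0, lapse_cw=0.02, lapse_ccw=0.02)
        data = simulate_session(p, sd, seed=43)
        res = reverse_correlation(data, stacks)
        bias = res.bias.set_index(["environment", "prev_stim"])["bias"]
        for env in ("neutral", "repeating"):
            assert bias.loc[(env, 1)] > bias.loc[(env, -1)]
        eff = res.history_sensitivity_effect.set_index("environment")[
            "history_sensitivity_effect"
        ]
        assert abs(eff).max() < 0.12  # no sensitivity modulation generated

    def test_gain_asymmetric_observer_positive_effect(self, zero_contrast_setup):
        sd, stacks, means = zero_contrast_setup
        p = ObserverParams(
            slope=20.0, lapse_cw=0.02, lapse_ccw=0.02,
            energy_beta=1.0, gain_consistent=1.5, gain_inconsistent=0.5,
        )
        data = simulate_session(p, sd, energies=means, seed=44)
        res = reverse_correlation(data, stacks)
        eff = res.history_sensitivity_effect.set_index("environment")[
            "history_sensitivity_effect"
        ]
        assert eff.loc["repeating"] > 0

    def test_stack_frame_round_trip(self, zero_contrast_setup):
        _, stacks, _ = zero_contrast_setup
        sub = stacks[0]
        small = pd.concat([sub.to_frame()], ignore_index=True)
        back = stacks_from_frame(small)[0]
        assert np.allclose(back.energy, sub.energy)
        assert (back.trial == sub.trial).all()
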