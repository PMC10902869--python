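"""Lasso-regularised logistic history-bias regression and derived summaries.

The probability of a clockwise response is modelled per participant and
environment as

    P(cw) = lapse_cw + (1 - lapse_cw - lapse_ccw) * logistic(
                b0 + b_c * signed_contrast
                + sum_{k=1..7} w_stim[k] * s_{t-k} + w_choice[k] * r_{t-k})

with an L1 penalty ``lambda = 0.001`` on the 14 history weights only (the
current-stimulus slope, the intercept and the lapse rates are unpenalised).
The objective is the mean negative log-likelihood plus the penalty; lapse
rates are estimated by a bounded grid search (0-0.2 in steps of 0.01,
coarse-to-fine) wrapped around the penalised fit, selecting by penalised
likelihood.  The inner solver is FISTA with backtracking and adaptive
restart, run simultaneously for all lapse candidates.

Derived summaries: with +/-1 coding the previous-correct-choice weight at
lag k equals ``w_stim[k] + w_choice[k]`` and the previous-incorrect-choice
weight equals ``w_choice[k] - w_stim[k]``; adaptation is the repeating-
minus-neutral difference of the previous-correct weight.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd

from .design import CW

LAMBDA_DEFAULT = 0.001
N_LAGS_DEFAULT = 7
LOW_CONTRAST_MAX = 0.06  # exclusive upper bound: low contrast = {0, 0.02, 0.04}


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -700, 700)))


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class HistoryDesignMatrix:
    """Per-environment regression design.

    ``X`` columns are ``["contrast", "stim_1".."stim_7", "choice_1".."choice_7"]``
    (the intercept is added by the fitter); ``y`` is the clockwise-response
    indicator.  The first ``n_lags`` trials of the environment and trials
    with a missing response are excluded from the rows; lags never cross the
    environment boundary.  Missed responses occupy lag positions with a
    0-coded choice regressor.
    """

    X: np.ndarray
    y: np.ndarray
    columns: list[str]
    environment: str
    participant_id: str
    n_lags: int
    trial_index: np.ndarray  # session trial numbers of the retained rows
    warning: str | None = None


def build_design_matrix(
    data: pd.DataFrame, env: str, n_lags: int = N_LAGS_DEFAULT
) -> HistoryDesignMatrix:
    """Lagged design matrix for one participant and one environment."""
    pids = data["participant_id"].unique()
    if len(pids) != 1:
        raise ValueError("build_design_matrix expects a single participant")
    d = data[data["environment"] == env].sort_values("trial")
    if d.empty:
        raise ValueError(f"no trials for environment {env!r}")
    s = d["orientation"].to_numpy(float)
    resp = d["response"].to_numpy(float)
    if "signed_contrast" in d:
        x = d["signed_contrast"].to_numpy(float)
    else:
        x = s * d["contrast"].to_numpy(float)
    n = len(d)
    r_filled = np.where(np.isfinite(resp), resp, 0.0)  # missed -> 0-coded lag
    keep = np.arange(n) >= n_lags
    keep &= np.isfinite(resp)
    cols = [x]
    names = ["contrast"]
    for k in range(1, n_lags + 1):
        lag = np.zeros(n)
        lag[k:] = s[:-k]
        cols.append(lag)
        names.append(f"stim_{k}")
    for k in range(1, n_lags + 1):
        lag = np.zeros(n)
        lag[k:] = r_filled[:-k]
        cols.append(lag)
        names.append(f"choice_{k}")
    X = np.column_stack(cols)[keep]
    y = (resp[keep] == CW).astype(float)
    warning = None
    if keep.sum() < 50:
        warning = f"only {int(keep.sum())} analyzable trials in {env}"
    return HistoryDesignMatrix(
        X=X,
        y=y,
        columns=names,
        environment=env,
        participant_id=str(pids[0]),
        n_lags=n_lags,
        trial_index=d["trial"].to_numpy()[keep],
        warning=warning,
    )


# ---------------------------------------------------------------------------
# penalised fit
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class HistoryFit:
    """Fitted history-bias model for one participant and environment."""

    participant_id: str
    environment: str
    lam: float
    weights: dict[str, float]  # intercept, contrast, stim_1.., choice_1..
    lapse_cw: float
    lapse_ccw: float
    converged: bool
    objective: float
    n_lags: int
    meta: dict = dataclasses.field(default_factory=dict)

    def stim_kernel(self) -> np.ndarray:
        return np.array([self.weights[f"stim_{k}"] for k in range(1, self.n_lags + 1)])

    def choice_kernel(self) -> np.ndarray:
        return np.array([self.weights[f"choice_{k}"] for k in range(1, self.n_lags + 1)])

    def prev_correct_kernel(self) -> np.ndarray:
        return self.stim_kernel() + self.choice_kernel()

    def prev_incorrect_kernel(self) -> np.ndarray:
        return self.choice_kernel() - self.stim_kernel()

    def predict_proba(self, X: np.ndarray, columns: list[str]) -> np.ndarray:
        w = np.array([self.weights[c] for c in columns])
        eta = self.weights["intercept"] + X @ w
        a = 1.0 - self.lapse_cw - self.lapse_ccw
        return self.lapse_cw + a * _logistic(eta)


def _batch_objective(Xd, y, W, gam, a, lam, pen):
    eta = Xd @ W.T
    p = gam[None, :] + a[None, :] * _logistic(eta)
    p = np.clip(p, 1e-12, 1 - 1e-12)
    nll = -(y[:, None] * np.log(p) + (1 - y[:, None]) * np.log(1 - p)).mean(axis=0)
    return nll + lam * np.abs(W[:, pen]).sum(axis=1)


def _fista_batch(
    Xd: np.ndarray,
    y: np.ndarray,
    lapse_pairs: np.ndarray,
    lam: float,
    pen: np.ndarray,
    W0: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Solve the penalised fit for every lapse pair simultaneously.

    Returns (W, objective, converged) with one row per lapse pair.
    Deterministic: initialisation at zero (or the supplied warm start),
    fixed backtracking schedule.
    """
    n, d = Xd.shape
    g = len(lapse_pairs)
    gam = lapse_pairs[:, 0]
    a = 1.0 - lapse_pairs[:, 0] - lapse_pairs[:, 1]
    W = np.zeros((g, d)) if W0 is None else np.array(W0, copy=True)
    V = W.copy()
    tmom = np.ones(g)
    smax = np.linalg.norm(Xd, 2)
    step = np.full(g, 4.0 * n / (smax**2 + 1e-12))

    def smooth_nll(Wm):
        eta = Xd @ Wm.T
        p = np.clip(gam[None] + a[None] * _logistic(eta), 1e-12, 1 - 1e-12)
        return -(y[:, None] * np.log(p) + (1 - y[:, None]) * np.log(1 - p)).mean(axis=0)

    def grad(Wm):
        eta = Xd @ Wm.T
        s = _logistic(eta)
        p = np.clip(gam[None] + a[None] * s, 1e-12, 1 - 1e-12)
        dl = (p - y[:, None]) / (p * (1 - p)) * (a[None] * s * (1 - s))
        return dl.T @ Xd / n

    F = smooth_nll(W) + lam * np.abs(W[:, pen]).sum(axis=1)
    converged = np.zeros(g, dtype=bool)
    for _ in range(max_iter):
        fV = smooth_nll(V)
        gV = grad(V)
        for _bt in range(60):
            Wn = V - step[:, None] * gV
            thr = step * lam
            Wn[:, pen] = np.sign(Wn[:, pen]) * np.maximum(
                np.abs(Wn[:, pen]) - thr[:, None], 0.0
            )
            fn = smooth_nll(Wn)
            diff = Wn - V
            rhs = fV + (gV * diff).sum(axis=1) + (diff**2).sum(axis=1) / (2 * step)
            bad = fn > rhs + 1e-12
            if not bad.any():
                break
            step[bad] *= 0.5
        Fn = fn + lam * np.abs(Wn[:, pen]).sum(axis=1)
        inc = Fn > F
        tmom[inc] = 1.0  # adaptive restart
        tnew = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * tmom**2))
        V = Wn + ((tmom - 1.0) / tnew)[:, None] * (Wn - W)
        converged = (np.abs(Fn - F) <= tol * np.maximum(1.0, np.abs(F))) & (
            np.abs(Wn - W).max(axis=1) <= 1e-6
        )
        W, F, tmom = Wn, Fn, tnew
        if converged.all():
            break
    return W, F, converged


def _lapse_pairs(values_cw, values_ccw):
    pairs = [
        (gc, gd)
        for gc, gd in itertools.product(values_cw, values_ccw)
        if gc + gd < 0.999
    ]
    return np.array(pairs)


def _select_lapse_pair(
    pairs: np.ndarray, F: np.ndarray, n: int, plateau_ll: float
) -> int:
    """Index of the preferred lapse pair: penalised likelihood with a
    parsimony tie-break.  Among pairs within ``plateau_ll`` log-likelihood
    units of the optimum (the surface is typically a flat ridge trading
    lapse rates against the contrast slope), the smallest total lapse wins;
    remaining ties go to the better objective."""
    tol = plateau_ll / n
    candidates = np.flatnonzero(F <= F.min() + tol)
    sums = pairs[candidates].sum(axis=1)
    order = np.lexsort((F[candidates], sums))
    return int(candidates[order[0]])


def fit_lasso_logistic(
    dm: HistoryDesignMatrix,
    lam: float = LAMBDA_DEFAULT,
    lapse_mode: str = "grid",
    lapse_max: float = 0.2,
    lapse_step: float = 0.01,
    coarse_step: float = 0.04,
    lapse_plateau_ll: float = 2.0,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> HistoryFit:
    """Penalised maximum-likelihood fit of the history-bias model.

    Deterministic given the design matrix.  ``lapse_mode="none"`` fixes both
    lapse rates at zero (plain penalised logistic regression).
    Separation or non-convergence is flagged via ``converged=False``; the
    weights are still returned.
    """
    X, y = dm.X, dm.y
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate design: only one response class present")
    # unpenalised intercept column first; scale the contrast column to unit SD
    # for conditioning (the returned slope is rescaled back)
    c_sd = X[:, 0].std()
    c_scale = c_sd if c_sd > 0 else 1.0
    Xd = np.column_stack([np.ones(len(y)), X.copy()])
    Xd[:, 1] = Xd[:, 1] / c_scale
    d = Xd.shape[1]
    pen = np.zeros(d, dtype=bool)
    pen[2:] = True  # history columns only

    if lapse_mode == "none":
        pairs = np.array([[0.0, 0.0]])
        W, F, conv = _fista_batch(Xd, y, pairs, lam, pen, tol=tol, max_iter=max_iter)
        best = 0
        meta_grid = {"lapse_mode": "none"}
    elif lapse_mode == "grid":
        coarse = np.round(np.arange(0.0, lapse_max + 1e-9, coarse_step), 10)
        pairs = _lapse_pairs(coarse, coarse)
        W, F, conv = _fista_batch(Xd, y, pairs, lam, pen, tol=tol, max_iter=max_iter)
        b = _select_lapse_pair(pairs, F, len(y), lapse_plateau_ll)
        bg, bd = pairs[b]
        fine_cw = np.round(
            np.clip(bg + np.arange(-coarse_step + lapse_step, coarse_step, lapse_step), 0, lapse_max),
            10,
        )
        fine_ccw = np.round(
            np.clip(bd + np.arange(-coarse_step + lapse_step, coarse_step, lapse_step), 0, lapse_max),
            10,
        )
        pairs2 = _lapse_pairs(np.unique(fine_cw), np.unique(fine_ccw))
        W2, F2, conv2 = _fista_batch(
            Xd, y, pairs2, lam, pen,
            W0=np.repeat(W[b : b + 1], len(pairs2), axis=0),
            tol=tol, max_iter=max_iter,
        )
        pairs = np.vstack([pairs, pairs2])
        W = np.vstack([W, W2])
        F = np.concatenate([F, F2])
        conv = np.concatenate([conv, conv2])
        best = _select_lapse_pair(pairs, F, len(y), lapse_plateau_ll)
        meta_grid = {
            "lapse_mode": "grid",
            "grid": f"0..{lapse_max} step {lapse_step} (coarse-to-fine)",
            "plateau_tie_break_ll": lapse_plateau_ll,
        }
    else:
        raise ValueError(f"unknown lapse_mode {lapse_mode!r}")

    w = W[best].copy()
    # separation heuristic in the scaled space (contrast column at unit SD)
    converged = bool(conv[best]) and float(np.abs(w).max()) < 30.0
    w[1] = w[1] / c_scale
    weights = {"intercept": float(w[0])}
    for name, val in zip(dm.columns, w[1:]):
        weights[name] = float(val)
    return HistoryFit(
        participant_id=dm.participant_id,
        environment=dm.environment,
        lam=lam,
        weights=weights,
        lapse_cw=float(pairs[best][0]),
        lapse_ccw=float(pairs[best][1]),
        converged=converged,
        objective=float(F[best]),
        n_lags=dm.n_lags,
        meta={
            "penalty": "mean NLL + lambda * sum|w_history| (history columns only)",
            "n_rows": int(len(y)),
            "warning": dm.warning,
            **meta_grid,
        },
    )


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def derive_history_summaries(
    fit_neutral: HistoryFit, fit_repeating: HistoryFit
) -> pd.DataFrame:
    """Previous-correct/incorrect weights per lag and their adaptation.

    adaptation[k] = previous-correct weight in the repeating environment
    minus previous-correct weight in the neutral environment.
    """
    if not (fit_neutral.converged and fit_repeating.converged):
        raise ValueError("both fits must be converged")
    lags = np.arange(1, fit_neutral.n_lags + 1)
    pc_n = fit_neutral.prev_correct_kernel()
    pc_r = fit_repeating.prev_correct_kernel()
    return pd.DataFrame(
        {
            "lag": lags,
            "prev_correct_neutral": pc_n,
            "prev_incorrect_neutral": fit_neutral.prev_incorrect_kernel(),
            "prev_correct_repeating": pc_r,
            "prev_incorrect_repeating": fit_repeating.prev_incorrect_kernel(),
            "adaptation": pc_r - pc_n,
        }
    )


def accuracy_summaries(data: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Accuracy tables: per block, per contrast x environment, low contrast.

    Low contrast is defined as contrast < 0.06, i.e. levels {0, 0.02, 0.04}.
    Missed responses are excluded from the denominators; empty cells are
    simply absent from the tables.
    """
    d = data[np.isfinite(data["response"].astype(float))].copy()

    def _acc(g):
        return pd.Series({"accuracy": g["is_correct"].mean(), "n": len(g)})

    keys = ["participant_id"]
    by_block = (
        d.groupby(keys + ["environment", "block"])[["is_correct"]]
        .agg(accuracy=("is_correct", "mean"), n=("is_correct", "size"))
        .reset_index()
    )
    by_contrast = (
        d.groupby(keys + ["environment", "contrast"])[["is_correct"]]
        .agg(accuracy=("is_correct", "mean"), n=("is_correct", "size"))
        .reset_index()
    )
    low = d[d["contrast"] < LOW_CONTRAST_MAX]
    low_contrast = (
        low.groupby(keys + ["environment"])[["is_correct"]]
        .agg(accuracy=("is_correct", "mean"), n=("is_correct", "size"))
        .reset_index()
    )
    return {"by_block": by_block, "by_contrast": by_contrast, "low_contrast": low_contrast}


def conditioned_psychometric(
    data: pd.DataFrame,
    fits: dict[str, HistoryFit] | None = None,
    n_lags: int = N_LAGS_DEFAULT,
) -> pd.DataFrame:
    """P(clockwise) vs signed contrast, split by previous stimulus x environment.

    Empirical proportions per bin; when per-environment fits are supplied the
    model-predicted probability (averaged over the trials in each bin) is
    attached as ``p_cw_model``.
    """
    d = data.copy().sort_values(["participant_id", "environment", "trial"])
    d["prev_orientation"] = d.groupby(["participant_id", "environment"])[
        "orientation"
    ].shift(1)
    d = d[np.isfinite(d["response"].astype(float)) & np.isfinite(d["prev_orientation"])]
    d["cw"] = (d["response"] == CW).astype(float)
    if "signed_contrast" not in d:
        d["signed_contrast"] = d["orientation"] * d["contrast"]
    if fits is not None:
        d["p_model"] = np.nan
        for pid in d["participant_id"].unique():
            for env, fit in fits.items():
                dm = build_design_matrix(
                    data[data["participant_id"] == pid], env, n_lags=n_lags
                )
                p = fit.predict_proba(dm.X, dm.columns)
                sel = (d["participant_id"] == pid) & (d["environment"] == env)
                pred = pd.Series(p, index=dm.trial_index)
                d.loc[sel, "p_model"] = d.loc[sel, "trial"].map(pred)
    group = ["participant_id", "environment", "prev_orientation", "signed_contrast"]
    agg = {"p_cw": ("cw", "mean"), "n": ("cw", "size")}
    if fits is not None:
        agg["p_cw_model"] = ("p_model", "mean")
    return d.groupby(group).agg(**agg).reset_index()


def apply_exclusion_criteria(
    data: pd.DataFrame,
    min_accuracy: float = 0.65,
    max_missed_frac: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Participant-level exclusion rules.

    1. overall accuracy >= 65% (responded trials),
    2. missed responses <= 5% of session trials (60 of 1200),
    3. accuracy >= 65% in each environment separately.

    Returns the filtered dataset and a per-participant report naming the
    rules that fired.
    """
    reports = []
    keep_ids = []
    for pid, d in data.groupby("participant_id"):
        resp = d["response"].astype(float)
        answered = d[np.isfinite(resp)]
        n_missed = int((~np.isfinite(resp)).sum())
        acc = answered["is_correct"].mean() if len(answered) else np.nan
        env_acc = answered.groupby("environment")["is_correct"].mean()
        rules = []
        if not acc >= min_accuracy:
            rules.append(1)
        if n_missed > max_missed_frac * len(d):
            rules.append(2)
        if any(not (a >= min_accuracy) for a in env_acc):
            rules.append(3)
        reports.append(
            {
                "participant_id": pid,
                "n_trials": len(d),
                "n_missed": n_missed,
                "accuracy": float(acc),
                "accuracy_neutral": float(env_acc.get("neutral", np.nan)),
                "accuracy_repeating": float(env_acc.get("repeating", np.nan)),
                "excluded": bool(rules),
                "rules_fired": ";".join(map(str, rules)),
            }
        )
        if not rules:
            keep_ids.append(pid)
    report = pd.DataFrame(reports)
    filtered = data[data["participant_id"].isin(keep_ids)].copy()
    return filtered, report
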