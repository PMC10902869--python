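"""Generative 2AFC observer with psychometric, lapse, history and gain components.

The observer responds clockwise with probability

    P(cw) = lapse_cw + (1 - lapse_cw - lapse_ccw) * logistic(eta),

    eta = intercept + slope * signed_contrast
          + sum_k w_stim[k] * s_{t-k} + sum_k w_choice[k] * r_{t-k}
          + energy term (0%-contrast trials only)

with stimuli and responses coded +/-1 and history lags zero-padded at the
start of each environment (no carry-over across the neutral -> repeating
switch).  The optional energy term implements a prediction-dependent gain on
orientation-energy channels: writing E+ / E- for the z-scored class-mean
energies of the predicted / unpredicted orientation (the prediction being
the previous trial's orientation),

    eta += prev_orientation * energy_beta * (gain_consistent * E+
                                             - gain_inconsistent * E-).

With equal gains this reduces to a pure stimulus-driven sensitivity
``energy_beta * (z_cw - z_ccw)`` with no history dependence; a gain
asymmetry produces a perceptual confirmation bias (higher sensitivity to
evidence consistent with the prediction).
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping

import numpy as np
import pandas as pd

from .design import CW, CCW, SessionDesign, TrialSequence

N_LAGS_DEFAULT = 7


def _logistic(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -700, 700)))


@dataclasses.dataclass
class ObserverParams:
    """Generative parameters of one simulated participant.

    ``slope`` is in log-odds per unit signed Michelson contrast; history
    kernels ``w_stim`` / ``w_choice`` are log-odds per +/-1-coded lagged
    stimulus / choice, ordered lag 1..7.
    """

    intercept: float = 0.0
    slope: float = 20.0
    lapse_cw: float = 0.025
    lapse_ccw: float = 0.025
    w_stim: np.ndarray = dataclasses.field(
        default_factory=lambda: np.zeros(N_LAGS_DEFAULT)
    )
    w_choice: np.ndarray = dataclasses.field(
        default_factory=lambda: np.zeros(N_LAGS_DEFAULT)
    )
    energy_beta: float = 0.0
    gain_consistent: float = 1.0
    gain_inconsistent: float = 1.0

    def __post_init__(self) -> None:
        self.w_stim = np.atleast_1d(np.asarray(self.w_stim, dtype=float))
        self.w_choice = np.atleast_1d(np.asarray(self.w_choice, dtype=float))
        if len(self.w_stim) != len(self.w_choice):
            raise ValueError("w_stim and w_choice must have equal length")
        if self.lapse_cw < 0 or self.lapse_ccw < 0:
            raise ValueError("lapse rates must be nonnegative")
        if self.lapse_cw + self.lapse_ccw >= 1:
            raise ValueError("lapse_cw + lapse_ccw must be < 1")

    @property
    def n_lags(self) -> int:
        return len(self.w_stim)

    @property
    def uses_energy(self) -> bool:
        return self.energy_beta != 0.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["w_stim"] = list(map(float, self.w_stim))
        d["w_choice"] = list(map(float, self.w_choice))
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ObserverParams":
        return cls(**dict(d))


def lag1_params(w_stim1: float = 0.0, w_choice1: float = 0.0, n_lags: int = N_LAGS_DEFAULT, **kw) -> ObserverParams:
    """Convenience constructor with only the lag-1 kernel entries set."""
    ws = np.zeros(n_lags)
    wc = np.zeros(n_lags)
    ws[0] = w_stim1
    wc[0] = w_choice1
    return ObserverParams(w_stim=ws, w_choice=wc, **kw)


def _env_params(
    params: ObserverParams | Mapping[str, ObserverParams], env: str
) -> ObserverParams:
    if isinstance(params, ObserverParams):
        return params
    return params[env]


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = np.std(v, ddof=1) if len(v) > 1 else 0.0
    if sd == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def _simulate_environment(
    p: ObserverParams,
    seq: TrialSequence,
    energy_rows: pd.DataFrame | None,
    rng: np.random.Generator,
) -> pd.DataFrame:
    if seq.correct_label is None:
        raise ValueError("sequence must have correct labels assigned")
    n = len(seq)
    s = seq.orientations.astype(float)
    x = seq.signed_contrasts()
    # stimulus-history and psychometric parts are response-independent
    eta0 = p.intercept + p.slope * x
    for k in range(1, p.n_lags + 1):
        eta0[k:] += p.w_stim[k - 1] * s[:-k]

    if p.uses_energy:
        if energy_rows is None:
            raise ValueError(
                "observer has energy_beta != 0: per-trial orientation energies "
                "for 0%-contrast trials are required"
            )
        zero = np.flatnonzero(seq.contrasts == 0)
        er = energy_rows.set_index("trial_in_env")
        missing = [t for t in zero if t not in er.index]
        if missing:
            raise ValueError(
                f"energies missing for 0%-contrast trials {missing[:5]} "
                f"({len(missing)} total) in {seq.env}"
            )
        z_cw = np.full(n, np.nan)
        z_ccw = np.full(n, np.nan)
        z_cw[zero] = _zscore(er.loc[zero, "e_cw"].to_numpy(float))
        z_ccw[zero] = _zscore(er.loc[zero, "e_ccw"].to_numpy(float))
        pred = np.zeros(n)
        pred[1:] = s[:-1]
        e_pred = np.where(pred == CW, z_cw, z_ccw)
        e_unpred = np.where(pred == CW, z_ccw, z_cw)
        term = pred * p.energy_beta * (
            p.gain_consistent * e_pred - p.gain_inconsistent * e_unpred
        )
        term = np.where((seq.contrasts == 0) & (pred != 0) & np.isfinite(term), term, 0.0)
        eta0 = eta0 + term

    u = rng.random(n)
    r = np.empty(n, dtype=int)
    a = 1.0 - p.lapse_cw - p.lapse_ccw
    wc = p.w_choice
    n_lags = p.n_lags
    for t in range(n):
        eta = eta0[t]
        for k in range(1, min(n_lags, t) + 1):
            eta += wc[k - 1] * r[t - k]
        pcw = p.lapse_cw + a * _logistic(eta)
        r[t] = CW if u[t] < pcw else CCW

    df = seq.to_frame()
    df["signed_contrast"] = x
    df["response"] = r
    df["is_correct"] = (r == seq.correct_label).astype(int)
    return df


def simulate_session(
    params: ObserverParams | Mapping[str, ObserverParams],
    design: SessionDesign | TrialSequence,
    energies: pd.DataFrame | None = None,
    seed: int = 0,
    participant_id: str = "sim",
) -> pd.DataFrame:
    """Simulate one observer on a session design.

    Parameters
    ----------
    params : a single :class:`ObserverParams`, or a mapping
        ``{"neutral": ..., "repeating": ...}`` for environment-specific
        parameters (e.g. an adapted observer with larger kernels in the
        repeating environment).
    design : a full :class:`SessionDesign` or a single environment's
        :class:`TrialSequence`.
    energies : required when any environment's ``energy_beta != 0``; a frame
        with columns ``environment``, ``trial_in_env`` (0-based within the
        environment), ``e_cw``, ``e_ccw`` (class-mean orientation energies of
        the rendered 0%-contrast stimuli).  Energies are z-scored per
        environment and class before entering the decision variable.
    seed : seed of the response noise.

    Returns
    -------
    DataFrame with one row per trial: participant_id, environment, block,
    trial (1-based within session), orientation, contrast, signed_contrast,
    correct_label, response, is_correct.
    """
    rng = np.random.default_rng(seed)
    if isinstance(design, TrialSequence):
        envs = [design]
    else:
        envs = [design.neutral, design.repeating]
    frames = []
    block_offset = 0
    trial_offset = 0
    for seq in envs:
        p = _env_params(params, seq.env)
        rows = None
        if energies is not None:
            rows = energies[energies["environment"] == seq.env]
        f = _simulate_environment(p, seq, rows if p.uses_energy else None, rng)
        f["trial_in_env"] = np.arange(len(f))
        f["block"] = f["block"] + block_offset
        f["trial"] = f["trial"] + trial_offset
        block_offset = int(f["block"].max())
        trial_offset = int(f["trial"].max())
        frames.append(f)
    out = pd.concat(frames, ignore_index=True)
    out["participant_id"] = participant_id
    return out


# ---------------------------------------------------------------------------
# parameter-recovery simulation
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class RecoveryResult:
    """Refitted history weights across simulated response sets."""

    weights: pd.DataFrame  # one row per simulation
    generating: dict[str, float]
    bias: pd.Series  # mean refit - generating value, per regressor

    @property
    def n_sims(self) -> int:
        return len(self.weights)


def recovery_simulation(
    params: ObserverParams,
    sequence: TrialSequence,
    n_sims: int = 100,
    seed: int = 0,
    lam: float = 0.001,
    n_lags: int | None = None,
    lapse_mode: str = "grid",
) -> RecoveryResult:
    """Simulate ``n_sims`` response sets on ``sequence`` and refit each.

    Mirrors the regularisation check of the analysis pipeline: responses are
    generated from known parameters on the (autocorrelated) repeating
    sequence and the lasso history regression is repeated on each simulated
    set, yielding the distribution of recovered weights and their bias.
    """
    from .history import build_design_matrix, fit_lasso_logistic

    if n_lags is None:
        n_lags = params.n_lags
    ss = np.random.SeedSequence(seed).generate_state(n_sims, dtype=np.uint32)
    rows = []
    for i in range(n_sims):
        try:
            data = simulate_session(params, sequence, seed=int(ss[i]) & 0x7FFFFFFF)
            dm = build_design_matrix(data, sequence.env, n_lags=n_lags)
            fit = fit_lasso_logistic(dm, lam=lam, lapse_mode=lapse_mode)
        except Exception as err:  # propagate with the simulation index
            raise RuntimeError(f"recovery simulation {i} failed: {err}") from err
        row = {"sim": i, **fit.weights, "lapse_cw": fit.lapse_cw, "lapse_ccw": fit.lapse_ccw}
        for k in range(1, n_lags + 1):
            row[f"prev_correct_{k}"] = row[f"stim_{k}"] + row[f"choice_{k}"]
        rows.append(row)
    weights = pd.DataFrame(rows).set_index("sim")
    generating = {"intercept": params.intercept, "contrast": params.slope}
    for k in range(1, n_lags + 1):
        ws = params.w_stim[k - 1] if k <= params.n_lags else 0.0
        wchoice = params.w_choice[k - 1] if k <= params.n_lags else 0.0
        generating[f"stim_{k}"] = ws
        generating[f"choice_{k}"] = wchoice
        generating[f"prev_correct_{k}"] = ws + wchoice
    bias = pd.Series(
        {k: float(weights[k].mean() - v) for k, v in generating.items() if k in weights}
    )
    return RecoveryResult(weights=weights, generating=generating, bias=bias)
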