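"""Reverse correlation of choices on noise-driven orientation energy.

Restricted to 0%-contrast (target-absent) trials: responses there are driven
only by internal biases and by arbitrary orientation-energy fluctuations of
the noise, so regressing choices on the energy separates a
stimulus-independent decision bias (the intercept beta0) from
stimulus-dependent sensitivity (the slope beta1 on z-scored energy).

Pipeline per participant:

1. z-score the energy of every (orientation, SF) cell within each
   (participant, previous-stimulus orientation, environment) group;
2. fit ``P(cw) = logistic(beta0 + beta1 * z)`` per cell and condition;
3. pool the estimates per (previous stimulus, environment) across
   participants and cells and remove Tukey-fence outliers
   (1.5 x IQR, linear-interpolation quartiles);
4. average beta0 over all cells (it is stimulus-independent) and beta1
   within the clockwise (1..89 deg) and counterclockwise (-89..-1 deg)
   orientation classes, all spatial frequencies.

The history effect on sensitivity (per environment) is the sensitivity to
clockwise energy after a clockwise previous stimulus minus that after a
counterclockwise previous stimulus.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .design import CW, CCW
from .stimulus import FilterBank

logger = logging.getLogger(__name__)

BETA_CAP = 10.0  # separation truncation for per-bin estimates


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class EnergyStack:
    """Per-trial energy profiles of one participant's environment.

    ``energy`` has shape (n_trials, n_orientations, n_sfs) and is indexed by
    ``trial`` (session-wide trial numbers of the 0%-contrast trials).
    """

    participant_id: str
    environment: str
    trial: np.ndarray
    energy: np.ndarray
    orientations_deg: np.ndarray
    sfs_cpd: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        t, o, f = np.meshgrid(
            self.trial, self.orientations_deg, self.sfs_cpd, indexing="ij"
        )
        return pd.DataFrame(
            {
                "participant_id": self.participant_id,
                "environment": self.environment,
                "trial": t.ravel(),
                "orientation_deg": o.ravel(),
                "sf_cpd": np.round(f.ravel(), 6),
                "energy": self.energy.ravel(),
            }
        )


def stacks_from_frame(df: pd.DataFrame) -> list[EnergyStack]:
    """Rebuild :class:`EnergyStack` objects from a long energy table."""
    out = []
    for (pid, env), d in df.groupby(["participant_id", "environment"]):
        trials = np.sort(d["trial"].unique())
        orientations = np.sort(d["orientation_deg"].unique())
        sfs = np.sort(d["sf_cpd"].unique())
        piv = d.pivot_table(
            index="trial", columns=["orientation_deg", "sf_cpd"], values="energy"
        ).loc[trials]
        energy = piv.to_numpy().reshape(len(trials), len(orientations), len(sfs))
        out.append(
            EnergyStack(
                participant_id=str(pid),
                environment=str(env),
                trial=trials,
                energy=energy,
                orientations_deg=orientations,
                sfs_cpd=sfs,
            )
        )
    return out


@dataclasses.dataclass
class RevCorrResult:
    """Bin-level fits plus bias/sensitivity summaries."""

    bins: pd.DataFrame
    bias: pd.DataFrame
    sensitivity: pd.DataFrame
    history_sensitivity_effect: pd.DataFrame
    report: dict


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def zscore_energy(
    df: pd.DataFrame,
    keys: tuple[str, ...] = (
        "participant_id",
        "environment",
        "prev_stim",
        "orientation_deg",
        "sf_cpd",
    ),
    value: str = "energy",
    ddof: int = 1,
) -> pd.DataFrame:
    """Z-score energies within each grouping cell (sample SD, ddof=1).

    Zero-variance groups are dropped (logged); groups need >= 2 members.
    """
    g = df.groupby(list(keys))[value]
    mean = g.transform("mean")
    sd = g.transform("std", ddof=ddof)
    count = g.transform("size")
    bad = (sd == 0) | ~np.isfinite(sd) | (count < 2)
    n_dropped = int(bad.sum())
    if n_dropped:
        logger.warning("dropping %d rows in degenerate z-score groups", n_dropped)
    out = df[~bad].copy()
    out["z_energy"] = (out[value] - mean[~bad]) / sd[~bad]
    return out


def _irls_2param(
    z: np.ndarray, y: np.ndarray, max_iter: int = 60, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised Newton-Raphson logistic fits y ~ 1 + z, one per column of z.

    Returns (beta0, beta1, separated).  Estimates diverging past
    ``BETA_CAP`` are truncated there and flagged.
    """
    z = np.atleast_2d(z.T).T  # ensure (n, C)
    n, c = z.shape
    b0 = np.zeros(c)
    b1 = np.zeros(c)
    for _ in range(max_iter):
        eta = np.clip(b0[None, :] + z * b1[None, :], -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu) + 1e-12
        r = y[:, None] - mu
        g0 = r.sum(axis=0)
        g1 = (z * r).sum(axis=0)
        h00 = w.sum(axis=0)
        h01 = (w * z).sum(axis=0)
        h11 = (w * z * z).sum(axis=0)
        det = np.maximum(h00 * h11 - h01**2, 1e-12)
        db0 = (h11 * g0 - h01 * g1) / det
        db1 = (h00 * g1 - h01 * g0) / det
        np.clip(db0, -5, 5, out=db0)
        np.clip(db1, -5, 5, out=db1)
        b0 += db0
        b1 += db1
        if max(np.abs(db0).max(), np.abs(db1).max()) < tol:
            break
    separated = (np.abs(b0) > BETA_CAP) | (np.abs(b1) > BETA_CAP) | ~np.isfinite(b0) | ~np.isfinite(b1)
    b0 = np.clip(np.nan_to_num(b0), -BETA_CAP, BETA_CAP)
    b1 = np.clip(np.nan_to_num(b1), -BETA_CAP, BETA_CAP)
    return b0, b1, separated


@dataclasses.dataclass
class RevCorrBinFit:
    """Logistic fit of one (orientation, SF) cell in one condition."""

    beta0: float
    beta1: float
    orientation_deg: float
    sf_cpd: float
    prev_stim: int
    environment: str
    participant_id: str
    separated: bool
    n: int


def fit_bin(z_energy: np.ndarray, responses_cw: np.ndarray, **cell_meta) -> RevCorrBinFit:
    """Maximum-likelihood logistic fit of one bin; deterministic.

    ``responses_cw`` is a 0/1 clockwise indicator; both classes must be
    present.  Separation is flagged and the estimates truncated at
    ``|beta| = 10`` (such fits are excluded downstream).
    """
    z = np.asarray(z_energy, float)
    y = np.asarray(responses_cw, float)
    if len(np.unique(y)) < 2:
        raise ValueError("both response classes must be present")
    b0, b1, sep = _irls_2param(z[:, None], y)
    meta = {
        "orientation_deg": np.nan,
        "sf_cpd": np.nan,
        "prev_stim": 0,
        "environment": "",
        "participant_id": "",
    }
    meta.update(cell_meta)
    return RevCorrBinFit(
        beta0=float(b0[0]),
        beta1=float(b1[0]),
        separated=bool(sep[0]),
        n=len(y),
        **meta,
    )


def remove_outliers_iqr(
    df: pd.DataFrame,
    value: str,
    keys: tuple[str, ...] = ("prev_stim", "environment"),
    factor: float = 1.5,
    min_pool: int = 4,
    quartile_method: str = "linear",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove values outside the Tukey fences, pooled per condition.

    Fences are ``[Q1 - factor*IQR, Q3 + factor*IQR]`` with
    linear-interpolation quartiles by default.  Pools smaller than
    ``min_pool`` are left unfiltered (with a warning entry in the report).
    """
    keep = np.ones(len(df), dtype=bool)
    rows = []
    for cond, d in df.groupby(list(keys)):
        v = d[value].to_numpy(float)
        if len(v) < min_pool:
            logger.warning("pool %s too small for outlier filtering (n=%d)", cond, len(v))
            rows.append({"condition": cond, "n": len(v), "n_removed": 0, "filtered": False})
            continue
        q1, q3 = np.percentile(v, [25, 75], method=quartile_method)
        iqr = q3 - q1
        lo, hi = q1 - factor * iqr, q3 + factor * iqr
        bad = (v < lo) | (v > hi)
        keep[df.index.get_indexer(d.index)] = ~bad
        rows.append(
            {"condition": cond, "n": len(v), "n_removed": int(bad.sum()), "filtered": True}
        )
    return df[keep].copy(), pd.DataFrame(rows)


def summarize_revcorr(
    bins: pd.DataFrame,
    iqr_factor: float = 1.5,
    quartile_method: str = "linear",
) -> RevCorrResult:
    """Condition summaries from bin-level fits.

    Separation-truncated fits are excluded, then the 1.5 x IQR rule is
    applied to the pooled beta0 and beta1 estimates per (previous stimulus,
    environment).  beta0 is averaged over all orientations and SFs; beta1
    within the CW (1..89 deg) / CCW (-89..-1 deg) orientation classes
    (0 and 90 deg excluded) and all SFs, per participant and condition.
    """
    ok = bins[~bins["separated"]].copy()
    b0f, rep0 = remove_outliers_iqr(
        ok.reset_index(drop=True), "beta0",
        factor=iqr_factor, quartile_method=quartile_method,
    )
    b1f, rep1 = remove_outliers_iqr(
        ok.reset_index(drop=True), "beta1",
        factor=iqr_factor, quartile_method=quartile_method,
    )
    bias = (
        b0f.groupby(["participant_id", "environment", "prev_stim"])
        .agg(bias=("beta0", "mean"), n_cells=("beta0", "size"))
        .reset_index()
    )
    o = b1f["orientation_deg"]
    b1f = b1f.assign(
        energy_class=np.select(
            [(o >= 1) & (o <= 89), (o <= -1) & (o >= -89)], ["cw", "ccw"], default="edge"
        )
    )
    sens = (
        b1f[b1f["energy_class"] != "edge"]
        .groupby(["participant_id", "environment", "prev_stim", "energy_class"])
        .agg(sensitivity=("beta1", "mean"), n_cells=("beta1", "size"))
        .reset_index()
    )
    cw_sens = sens[sens["energy_class"] == "cw"].pivot_table(
        index=["participant_id", "environment"], columns="prev_stim", values="sensitivity"
    )
    effect = cw_sens.reset_index()
    if CW in cw_sens.columns and CCW in cw_sens.columns:
        effect["history_sensitivity_effect"] = cw_sens[CW].to_numpy() - cw_sens[CCW].to_numpy()
    else:
        effect["history_sensitivity_effect"] = np.nan
        logger.warning("missing previous-stimulus condition; sensitivity effect absent")
    effect = effect[["participant_id", "environment", "history_sensitivity_effect"]]
    report = {
        "n_bins": int(len(bins)),
        "n_separated": int(bins["separated"].sum()),
        "outliers_beta0": rep0.to_dict("records"),
        "outliers_beta1": rep1.to_dict("records"),
    }
    return RevCorrResult(
        bins=bins, bias=bias, sensitivity=sens,
        history_sensitivity_effect=effect, report=report,
    )


# ---------------------------------------------------------------------------
# end-to-end driver
# ---------------------------------------------------------------------------


def reverse_correlation(
    behavior: pd.DataFrame,
    stacks: list[EnergyStack],
    min_trials: int = 10,
    iqr_factor: float = 1.5,
    quartile_method: str = "linear",
    ddof: int = 1,
) -> RevCorrResult:
    """Full reverse-correlation pipeline on 0%-contrast trials.

    ``behavior`` provides the responses and the previous-stimulus
    conditioning (the latent orientation of the preceding trial, whatever
    its contrast); ``stacks`` provide the per-trial energy profiles of the
    0%-contrast stimuli.  Trials with contrast > 0 must not appear in the
    stacks (asserted).
    """
    rows = []
    skipped = []
    for stack in stacks:
        b = behavior[
            (behavior["participant_id"] == stack.participant_id)
            & (behavior["environment"] == stack.environment)
        ].sort_values("trial")
        if b.empty:
            skipped.append((stack.participant_id, stack.environment, "no behavior"))
            continue
        b = b.set_index("trial")
        contr = b.loc[stack.trial, "contrast"].to_numpy(float)
        if (contr > 0).any():
            raise ValueError("energy stacks must contain 0%-contrast trials only")
        prev = b["orientation"].shift(1).reindex(stack.trial).to_numpy(float)
        resp = b.loc[stack.trial, "response"].to_numpy(float)
        for prev_sign in (CW, CCW):
            m = (prev == prev_sign) & np.isfinite(resp)
            if m.sum() < max(min_trials, 2):
                skipped.append(
                    (stack.participant_id, stack.environment, f"prev={prev_sign}: n={m.sum()}")
                )
                continue
            e = stack.energy[m]  # (T, O, S)
            y = (resp[m] == CW).astype(float)
            if len(np.unique(y)) < 2:
                skipped.append(
                    (stack.participant_id, stack.environment, f"prev={prev_sign}: one class")
                )
                continue
            mu = e.mean(axis=0)
            sd = e.std(axis=0, ddof=ddof)
            valid = sd > 0
            z = np.zeros_like(e)
            z[:, valid] = (e[:, valid] - mu[valid]) / sd[valid]
            zc = z.reshape(len(y), -1)
            b0, b1, sep = _irls_2param(zc, y)
            og, fg = np.meshgrid(stack.orientations_deg, stack.sfs_cpd, indexing="ij")
            cell_ok = valid.ravel()
            rows.append(
                pd.DataFrame(
                    {
                        "participant_id": stack.participant_id,
                        "environment": stack.environment,
                        "prev_stim": prev_sign,
                        "orientation_deg": og.ravel()[cell_ok],
                        "sf_cpd": np.round(fg.ravel()[cell_ok], 6),
                        "beta0": b0[cell_ok],
                        "beta1": b1[cell_ok],
                        "separated": sep[cell_ok],
                        "n": int(m.sum()),
                    }
                )
            )
    if not rows:
        raise ValueError("no analyzable (participant, environment, previous stimulus) cells")
    bins = pd.concat(rows, ignore_index=True)
    result = summarize_revcorr(bins, iqr_factor=iqr_factor, quartile_method=quartile_method)
    result.report["skipped_conditions"] = skipped
    return result


def zero_contrast_energy_stacks(
    design,
    bank: FilterBank,
    seed: int = 0,
    participant_id: str = "sim",
    dtype: type = np.complex64,
) -> tuple[list[EnergyStack], pd.DataFrame]:
    """Render every 0%-contrast stimulus of a session and compute energies.

    Returns the per-environment :class:`EnergyStack` list and a frame of
    class-mean energies (``e_cw`` / ``e_ccw`` per trial) for the generative
    observer's prediction-gain link.
    """
    from .design import SessionDesign
    from .stimulus import class_mean_energies, render_stimulus

    assert isinstance(design, SessionDesign)
    seeds = np.random.SeedSequence(seed).generate_state(design.n_trials, dtype=np.uint32)
    stacks = []
    mean_rows = []
    trial_offset = 0
    for seq in (design.neutral, design.repeating):
        zero = np.flatnonzero(seq.contrasts == 0)
        rasters = np.stack(
            [
                render_stimulus(
                    None, 0.0, bank.params, seed=int(seeds[trial_offset + t]) & 0x7FFFFFFF
                ).raster
                for t in zero
            ]
        )
        energy = bank.energies(rasters, dtype=dtype)
        e_cw, e_ccw = class_mean_energies(energy, bank)
        stacks.append(
            EnergyStack(
                participant_id=participant_id,
                environment=seq.env,
                trial=zero + 1 + trial_offset,  # 1-based session trial numbers
                energy=energy,
                orientations_deg=bank.orientations_deg.copy(),
                sfs_cpd=bank.sfs_cpd.copy(),
            )
        )
        mean_rows.append(
            pd.DataFrame(
                {
                    "participant_id": participant_id,
                    "environment": seq.env,
                    "trial_in_env": zero,
                    "e_cw": e_cw,
                    "e_ccw": e_ccw,
                }
            )
        )
        trial_offset += len(seq)
    return stacks, pd.concat(mean_rows, ignore_index=True)
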