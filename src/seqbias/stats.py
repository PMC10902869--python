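"""Group-level contrasts: paired/Welch t-tests, within-subject ANOVA with
two-level factors, rank and product-moment correlations, and linear
trajectory fits.

All factors in the repeated-measures ANOVA are two-level, so every effect
has a single numerator degree of freedom and equals the squared paired t of
the corresponding within-subject contrast (sphericity is trivially
satisfied); the implementation computes the effects that way, which is
numerically identical to the classical sums-of-squares decomposition.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclasses.dataclass
class ContrastResult:
    """One test statistic with its degrees of freedom and p-value."""

    name: str
    statistic: float
    df1: float
    df2: float | None
    p_value: float
    n: int
    direction: int  # sign of the effect (0 when undefined)
    method: str

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def paired_t(
    x: np.ndarray, y: np.ndarray, alternative: str = "two-sided"
) -> ContrastResult:
    """Classical paired t-test on the differences x - y.

    Raises ``ValueError`` for fewer than 3 pairs, missing values, or
    zero-variance differences (the statistic is undefined there).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length (paired)")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("missing values in paired data")
    d = x - y
    if np.ptp(d) == 0:
        raise ValueError("zero-variance differences: paired t undefined")
    res = sps.ttest_rel(x, y, alternative=alternative)
    return ContrastResult(
        name="paired_t",
        statistic=float(res.statistic),
        df1=float(len(x) - 1),
        df2=None,
        p_value=float(res.pvalue),
        n=len(x),
        direction=int(np.sign(d.mean())),
        method=f"paired t ({alternative})",
    )


def welch_t(
    x: np.ndarray, y: np.ndarray, alternative: str = "two-sided"
) -> ContrastResult:
    """Two-sample Welch t-test (unequal variances, fractional df)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 observations per group")
    res = sps.ttest_ind(x, y, equal_var=False, alternative=alternative)
    return ContrastResult(
        name="welch_t",
        statistic=float(res.statistic),
        df1=float(res.df),
        df2=None,
        p_value=float(res.pvalue),
        n=len(x) + len(y),
        direction=int(np.sign(x.mean() - y.mean())),
        method=f"Welch t ({alternative})",
    )


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    within: list[str],
    subject: str = "participant_id",
) -> dict[str, ContrastResult]:
    """Repeated-measures ANOVA for 1-3 two-level within factors.

    ``data`` is long-format with one value per subject x cell; cells must be
    complete.  Returns main effects and all interactions, keyed e.g.
    ``"A"``, ``"B"``, ``"A:B"``.  A single factor reduces to the squared
    paired t-test.
    """
    if len(within) not in (1, 2, 3):
        raise ValueError("rm_anova supports 1-3 within factors")
    piv = data.pivot_table(index=subject, columns=within, values=dv, aggfunc="mean")
    expected = 2 ** len(within)
    if piv.shape[1] != expected or piv.isna().any().any():
        raise ValueError("incomplete within-participant cells")
    levels = {f: sorted(data[f].unique()) for f in within}
    for f in within:
        if len(levels[f]) != 2:
            raise ValueError(f"factor {f!r} must have exactly 2 levels")
    n = len(piv)
    if n < 2:
        raise ValueError("need at least 2 participants")
    out: dict[str, ContrastResult] = {}
    cols = list(piv.columns)
    for k in range(1, len(within) + 1):
        for combo in itertools.combinations(within, k):
            w = np.ones(len(cols))
            for i, col in enumerate(cols):
                key = col if isinstance(col, tuple) else (col,)
                for f in combo:
                    # +1 for the second sorted level, -1 for the first
                    w[i] *= 1.0 if key[within.index(f)] == levels[f][1] else -1.0
            scores = piv.to_numpy() @ w / len(cols)
            m = scores.mean()
            sd = scores.std(ddof=1)
            tiny = 1e-10 * max(1.0, float(np.abs(piv.to_numpy()).max()))
            if abs(m) <= tiny and sd <= tiny:
                # numerically null contrast (e.g. a constant factor)
                m, f_stat, p = 0.0, 0.0, 1.0
            elif sd <= tiny:
                f_stat, p = float("inf"), 0.0
            else:
                f_stat = (m / (sd / np.sqrt(n))) ** 2
                p = float(sps.f.sf(f_stat, 1, n - 1))
            out[":".join(combo)] = ContrastResult(
                name=":".join(combo),
                statistic=float(f_stat),
                df1=1.0,
                df2=float(n - 1),
                p_value=p,
                n=n,
                direction=int(np.sign(m)),
                method="repeated-measures ANOVA (1-df contrast)",
            )
    return out


def correlation(
    x: np.ndarray, y: np.ndarray, method: str = "spearman"
) -> ContrastResult:
    """Spearman rank or Pearson product-moment correlation with p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    if method == "spearman":
        r, p = sps.spearmanr(x, y)
    elif method == "pearson":
        r, p = sps.pearsonr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return ContrastResult(
        name=f"{method}_correlation",
        statistic=float(r),
        df1=float(len(x) - 2),
        df2=None,
        p_value=float(p),
        n=len(x),
        direction=int(np.sign(r)),
        method=method,
    )


def linear_trajectory_fit(
    weights: np.ndarray, x: np.ndarray | None = None
) -> tuple[float, float]:
    """Ordinary least-squares line through a weight trajectory.

    The abscissa defaults to 0, 1, 2, ... (first trial/block of the
    environment at 0), so the intercept is the starting level and the slope
    the per-step change (the learning-rate decomposition: fast initial jump
    vs gradual drift).  Returns ``(intercept, slope)``.
    """
    w = np.asarray(weights, float)
    if len(w) < 2:
        raise ValueError("need at least 2 points for a line")
    if x is None:
        x = np.arange(len(w), dtype=float)
    slope, intercept = np.polyfit(np.asarray(x, float), w, 1)
    return float(intercept), float(slope)
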