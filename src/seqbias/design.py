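"""Trial-sequence and session-design generation for a two-environment 2AFC task.

A session consists of an initial *neutral* environment, in which the grating
orientation (clockwise / counterclockwise of vertical) is serially
counterbalanced so that every condition is preceded equally often by every
other condition and the orientation repetition probability is 0.5, followed
by a *repeating* environment in which the orientation follows a two-state
Markov chain with repetition probability 0.8 (resampled until the empirical
repetition frequency lies within a stated tolerance of the target).

Six Michelson contrast levels (including 0%) are crossed with the two
orientations.  In the repeating environment the contrast sequence is a
balanced permutation drawn independently of the orientation chain.  On
0%-contrast trials the rewarded response is random in the neutral
environment, while in the repeating environment it equals the trial's latent
orientation, so that it follows the sequential regularity.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np
import pandas as pd

#: The six Michelson contrast levels of the target grating.
CONTRAST_LEVELS: tuple[float, ...] = (0.0, 0.02, 0.04, 0.06, 0.12, 0.18)

#: Orientation codes: +1 = clockwise (+45 deg), -1 = counterclockwise (-45 deg).
CW: int = 1
CCW: int = -1

ENVIRONMENTS: tuple[str, str] = ("neutral", "repeating")


@dataclasses.dataclass(frozen=True)
class Condition:
    """A stimulus condition: orientation sign and Michelson contrast."""

    orientation: int
    contrast: float

    def __post_init__(self) -> None:
        if self.orientation not in (CW, CCW):
            raise ValueError(
                f"orientation must be {CW} (clockwise) or {CCW} "
                f"(counterclockwise), got {self.orientation}"
            )
        if not 0.0 <= self.contrast <= 1.0:
            raise ValueError(f"contrast must lie in [0, 1], got {self.contrast}")


def default_conditions(
    contrasts: Sequence[float] = CONTRAST_LEVELS,
) -> list[Condition]:
    """The full condition set: 2 orientations x the given contrast levels."""
    return [Condition(o, c) for o in (CW, CCW) for c in contrasts]


@dataclasses.dataclass
class TrialSequence:
    """Ordered latent orientations, contrasts and rewarded labels of one environment.

    Attributes
    ----------
    env : {"neutral", "repeating"}
    blocks : 1-based block index per trial.
    orientations : latent orientation sign (+1/-1) per trial.  For 0%-contrast
        trials this is the orientation of the condition (neutral) or of the
        underlying Markov chain (repeating); no grating is actually shown.
    contrasts : Michelson contrast per trial.
    correct_label : rewarded response per trial, or ``None`` before
        :func:`assign_correct_labels` has run.
    seed : seed used by the generator, for provenance.
    """

    env: str
    blocks: np.ndarray
    orientations: np.ndarray
    contrasts: np.ndarray
    correct_label: np.ndarray | None
    seed: int

    def __post_init__(self) -> None:
        if self.env not in ENVIRONMENTS:
            raise ValueError(f"env must be one of {ENVIRONMENTS}, got {self.env!r}")
        self.blocks = np.asarray(self.blocks, dtype=int)
        self.orientations = np.asarray(self.orientations, dtype=int)
        self.contrasts = np.asarray(self.contrasts, dtype=float)
        n = len(self.orientations)
        if len(self.blocks) != n or len(self.contrasts) != n:
            raise ValueError("blocks, orientations and contrasts must share length")
        if self.correct_label is not None:
            self.correct_label = np.asarray(self.correct_label, dtype=int)
            if len(self.correct_label) != n:
                raise ValueError("correct_label length mismatch")

    def __len__(self) -> int:
        return len(self.orientations)

    @property
    def n_trials(self) -> int:
        return len(self)

    def repetition_frequency(self) -> float:
        """Fraction of successive trials on which the orientation repeats."""
        o = self.orientations
        if len(o) < 2:
            return float("nan")
        return float(np.mean(o[1:] == o[:-1]))

    def signed_contrasts(self) -> np.ndarray:
        return self.orientations * self.contrasts

    def to_frame(self, participant_id: str = "sim") -> pd.DataFrame:
        cols = {
            "participant_id": participant_id,
            "environment": self.env,
            "block": self.blocks,
            "trial": np.arange(1, len(self) + 1),
            "orientation": self.orientations,
            "contrast": self.contrasts,
        }
        if self.correct_label is not None:
            cols["correct_label"] = self.correct_label
        return pd.DataFrame(cols)


@dataclasses.dataclass
class SessionDesign:
    """A complete 12-block session: neutral blocks followed by repeating blocks."""

    neutral: TrialSequence
    repeating: TrialSequence
    p_rep_target: float = 0.8
    p_rep_tolerance: float = 0.02

    @property
    def n_trials(self) -> int:
        return len(self.neutral) + len(self.repeating)

    @property
    def environments(self) -> dict[str, TrialSequence]:
        # Fixed order: neutral precedes repeating.
        return {"neutral": self.neutral, "repeating": self.repeating}

    def to_frame(self, participant_id: str = "sim") -> pd.DataFrame:
        """Session-wide trial table with 1-based block and trial numbering."""
        fn = self.neutral.to_frame(participant_id)
        fr = self.repeating.to_frame(participant_id)
        fr["block"] = fr["block"] + int(self.neutral.blocks.max(initial=0))
        fr["trial"] = fr["trial"] + len(self.neutral)
        return pd.concat([fn, fr], ignore_index=True)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def _eulerian_walk(adjacency: list[list[int]], start: int) -> list[int]:
    """Hierholzer's algorithm on a directed multigraph given as adjacency lists.

    The adjacency lists are consumed.  Returns the node walk (edges + 1 long).
    """
    stack = [start]
    walk: list[int] = []
    while stack:
        v = stack[-1]
        if adjacency[v]:
            stack.append(adjacency[v].pop())
        else:
            walk.append(stack.pop())
    walk.reverse()
    return walk


def _extra_cycle_edges(
    k: int, n_extra: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """``n_extra`` distinct, degree-balanced directed edges over k nodes.

    Built from circulant shifts — shift d contributes the k edges
    (i, i+d mod k), which are pairwise disjoint across shifts and balanced at
    every node — plus self-loops on distinct nodes for any remainder below k
    (also balanced).  Valid for any 0 <= n_extra < k**2.
    """
    if n_extra == 0:
        return []
    if not 0 < n_extra < k * k:
        raise ValueError("n_extra must lie in [0, k**2)")
    a, b = divmod(n_extra, k)
    pool = np.arange(1, k) if b else np.arange(k)  # keep shift 0 free for loops
    shifts = rng.choice(pool, size=a, replace=False)
    edges = [(i, (i + int(d)) % k) for d in shifts for i in range(k)]
    if b:
        for v in rng.choice(k, size=b, replace=False):
            edges.append((int(v), int(v)))
    return edges


def generate_counterbalanced_sequence(
    n_trials: int,
    conditions: Sequence[Condition] | None = None,
    seed: int = 0,
    env: str = "neutral",
) -> TrialSequence:
    """Serially counterbalanced condition sequence.

    Constructs an Eulerian circuit on the complete directed multigraph over
    the conditions (self-loops included), so that over the ``n_trials - 1``
    first-order transitions every ordered condition pair occurs equally often
    up to a difference of one (exact when ``n_trials - 1`` is divisible by
    the squared number of conditions).

    Raises
    ------
    ValueError
        If ``n_trials`` is too small for every ordered transition to occur at
        least once (fewer than ``len(conditions)**2 + 1`` trials).
    """
    if conditions is None:
        conditions = default_conditions()
    conditions = list(conditions)
    k = len(conditions)
    if k == 0:
        raise ValueError("conditions must be non-empty")
    if n_trials < 1:
        raise ValueError("n_trials must be positive")
    rng = np.random.default_rng(seed)
    if k == 1:
        idx = np.zeros(n_trials, dtype=int)
    else:
        n_edges = n_trials - 1
        if n_edges < k * k:
            raise ValueError(
                f"n_trials={n_trials} cannot visit all {k * k} ordered condition "
                f"transitions at least once; need at least {k * k + 1} trials"
            )
        q, n_extra = divmod(n_edges, k * k)
        extra = _extra_cycle_edges(k, n_extra, rng)
        adjacency: list[list[int]] = [[] for _ in range(k)]
        for u in range(k):
            adjacency[u].extend([v for v in range(k) for _ in range(q)])
        for u, v in extra:
            adjacency[u].append(v)
        for lst in adjacency:
            rng.shuffle(lst)
        walk = _eulerian_walk(adjacency, int(rng.integers(k)))
        if len(walk) != n_trials:  # pragma: no cover - guarded by construction
            raise RuntimeError("Eulerian walk did not cover all transitions")
        idx = np.array(walk, dtype=int)
    orientations = np.array([conditions[i].orientation for i in idx])
    contrasts = np.array([conditions[i].contrast for i in idx])
    return TrialSequence(
        env=env,
        blocks=np.ones(n_trials, dtype=int),
        orientations=orientations,
        contrasts=contrasts,
        correct_label=None,
        seed=seed,
    )


def condition_transition_counts(
    seq: TrialSequence, conditions: Sequence[Condition] | None = None
) -> np.ndarray:
    """Tally of ordered condition-pair transitions, shape (k, k)."""
    if conditions is None:
        conditions = default_conditions()
    index = {(c.orientation, round(c.contrast, 10)): i for i, c in enumerate(conditions)}
    ids = np.array(
        [
            index[(int(o), round(float(c), 10))]
            for o, c in zip(seq.orientations, seq.contrasts)
        ]
    )
    k = len(conditions)
    counts = np.zeros((k, k), dtype=int)
    np.add.at(counts, (ids[:-1], ids[1:]), 1)
    return counts


def generate_markov_sequence(
    n_trials: int,
    p_rep: float = 0.8,
    tolerance: float = 0.02,
    seed: int = 0,
    max_iter: int = 10_000,
) -> TrialSequence:
    """Markov orientation sequence with target repetition probability ``p_rep``.

    The first orientation is drawn uniformly; each subsequent orientation
    repeats the previous one with probability ``p_rep``.  The whole sequence
    is resampled (with an incremented seed) until the empirical repetition
    frequency falls within ``tolerance`` of the target.

    Contrasts are left unassigned (NaN); combine with a balanced contrast
    permutation via :func:`build_session`.
    """
    if not 0.0 <= p_rep <= 1.0:
        raise ValueError(f"p_rep must lie in [0, 1], got {p_rep}")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if n_trials < 2:
        raise ValueError("n_trials must be at least 2")
    freq = float("nan")
    for it in range(max_iter):
        rng = np.random.default_rng(seed + it)
        first = CW if rng.random() < 0.5 else CCW
        repeats = rng.random(n_trials - 1) < p_rep
        flips = np.where(repeats, 1, -1)
        orientations = np.concatenate(([first], first * np.cumprod(flips)))
        freq = float(np.mean(repeats))
        if abs(freq - p_rep) <= tolerance:
            return TrialSequence(
                env="repeating",
                blocks=np.ones(n_trials, dtype=int),
                orientations=orientations,
                contrasts=np.full(n_trials, np.nan),
                correct_label=None,
                seed=seed + it,
            )
    raise RuntimeError(
        f"no sequence within +/-{tolerance} of p_rep={p_rep} after {max_iter} "
        f"resamples (last achieved repetition frequency {freq:.4f})"
    )


def balanced_contrasts(
    n_trials: int,
    contrasts: Sequence[float] = CONTRAST_LEVELS,
    seed: int = 0,
) -> np.ndarray:
    """Random contrast sequence with (near-)equal counts per level."""
    rng = np.random.default_rng(seed)
    levels = np.asarray(contrasts, dtype=float)
    q, r = divmod(n_trials, len(levels))
    seq = np.tile(levels, q)
    if r:
        seq = np.concatenate([seq, rng.choice(levels, size=r, replace=False)])
    return rng.permutation(seq)


def assign_correct_labels(seq: TrialSequence, seed: int = 0) -> TrialSequence:
    """Attach the rewarded response to every trial.

    Trials with contrast > 0 are rewarded for reporting the true orientation.
    0%-contrast trials are rewarded at random (uniform) in the neutral
    environment; in the repeating environment the reward follows the latent
    orientation of the Markov chain, so it depends stochastically on the
    previous stimulus.
    """
    if np.isnan(seq.contrasts).any():
        raise ValueError("contrasts must be assigned before correct labels")
    rng = np.random.default_rng(seed)
    labels = seq.orientations.copy()
    zero = seq.contrasts == 0
    if seq.env == "neutral":
        labels[zero] = rng.choice(np.array([CW, CCW]), size=int(zero.sum()))
    return dataclasses.replace(seq, correct_label=labels)


# ---------------------------------------------------------------------------
# session construction
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class DesignConfig:
    """Parameters of the two-environment session design."""

    n_blocks_per_env: int = 6
    trials_per_block: int = 100
    p_rep: float = 0.8
    tolerance: float = 0.02
    contrasts: tuple[float, ...] = CONTRAST_LEVELS
    max_iter: int = 10_000

    def validate(self) -> None:
        if self.n_blocks_per_env < 1:
            raise ValueError(f"n_blocks_per_env must be >= 1, got {self.n_blocks_per_env}")
        if self.trials_per_block < 1:
            raise ValueError(f"trials_per_block must be >= 1, got {self.trials_per_block}")
        if not 0.0 <= self.p_rep <= 1.0:
            raise ValueError(f"p_rep must lie in [0, 1], got {self.p_rep}")
        if self.tolerance <= 0:
            raise ValueError(f"tolerance must be positive, got {self.tolerance}")
        if len(self.contrasts) == 0:
            raise ValueError("contrasts must be non-empty")
        if any(not 0.0 <= c <= 1.0 for c in self.contrasts):
            raise ValueError(f"contrasts must lie in [0, 1], got {self.contrasts}")
        if self.max_iter < 1:
            raise ValueError(f"max_iter must be >= 1, got {self.max_iter}")


def _block_index(n_trials: int, trials_per_block: int) -> np.ndarray:
    return np.arange(n_trials) // trials_per_block + 1


def _derive_seeds(seed: int, n: int) -> list[int]:
    """Deterministic sub-seeds below 2**31."""
    state = np.random.SeedSequence(int(seed)).generate_state(n, dtype=np.uint32)
    return [int(s) & 0x7FFFFFFF for s in state]


def build_session(config: DesignConfig | None = None, seed: int = 0) -> SessionDesign:
    """A complete session: counterbalanced neutral blocks, then Markov blocks.

    Contrast counts are equal (up to the rounding inherent in serial
    counterbalancing) within each environment.  When the environment is too
    short for full serial counterbalancing (fewer trials than the squared
    number of conditions), the neutral sequence degrades to a balanced random
    permutation of conditions.
    """
    config = config or DesignConfig()
    config.validate()
    s_neutral, s_markov, s_contrast, s_lab_n, s_lab_r = _derive_seeds(seed, 5)
    n_env = config.n_blocks_per_env * config.trials_per_block
    conditions = default_conditions(config.contrasts)
    k = len(conditions)
    if n_env >= k * k + 1:
        neutral = generate_counterbalanced_sequence(n_env, conditions, seed=s_neutral)
    else:
        rng = np.random.default_rng(s_neutral)
        q, r = divmod(n_env, k)
        idx = np.tile(np.arange(k), q)
        if r:
            idx = np.concatenate([idx, rng.choice(k, size=r, replace=False)])
        idx = rng.permutation(idx)
        neutral = TrialSequence(
            env="neutral",
            blocks=np.ones(n_env, dtype=int),
            orientations=np.array([conditions[i].orientation for i in idx]),
            contrasts=np.array([conditions[i].contrast for i in idx]),
            correct_label=None,
            seed=s_neutral,
        )
    neutral.blocks = _block_index(n_env, config.trials_per_block)

    if n_env >= 2:
        repeating = generate_markov_sequence(
            n_env, config.p_rep, config.tolerance, seed=s_markov, max_iter=config.max_iter
        )
    else:
        rng = np.random.default_rng(s_markov)
        repeating = TrialSequence(
            env="repeating",
            blocks=np.ones(n_env, dtype=int),
            orientations=rng.choice(np.array([CW, CCW]), size=n_env),
            contrasts=np.full(n_env, np.nan),
            correct_label=None,
            seed=s_markov,
        )
    repeating.blocks = _block_index(n_env, config.trials_per_block)
    repeating.contrasts = balanced_contrasts(n_env, config.contrasts, seed=s_contrast)

    neutral = assign_correct_labels(neutral, seed=s_lab_n)
    repeating = assign_correct_labels(repeating, seed=s_lab_r)
    return SessionDesign(
        neutral=neutral,
        repeating=repeating,
        p_rep_target=config.p_rep,
        p_rep_tolerance=config.tolerance,
    )
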