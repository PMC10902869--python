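"""Configuration, seeding, serialization and the end-to-end pipeline.

``run_end_to_end`` chains the full analysis on a synthetic cohort:

    design -> stimuli/energies -> simulated behavior -> exclusions
           -> history fits -> reverse-correlation summaries -> group stats

writing tidy CSV/JSON outputs plus a manifest recording the package
version, per-stage seeds and SHA-256 hashes of every file.  Every stage's
seed is derived deterministically from the master seed and a stage tag, so
reruns with the same configuration and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import CONTRAST_LEVELS, DesignConfig, build_session
from .history import (
    accuracy_summaries,
    apply_exclusion_criteria,
    build_design_matrix,
    derive_history_summaries,
    fit_lasso_logistic,
)
from .observer import ObserverParams, simulate_session
from .revcorr import EnergyStack, reverse_correlation, zero_contrast_energy_stacks
from .stats import correlation, paired_t, rm_anova
from .stimulus import FilterBank, StimulusParams

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid pipeline configuration (CLI exit code 2)."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name (CLI exit code 3)."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


def stage_seed(master_seed: int, tag: str) -> int:
    """Deterministic sub-seed (< 2**31) from the master seed and a stage tag."""
    state = np.random.SeedSequence(
        [int(master_seed), zlib.crc32(tag.encode())]
    ).generate_state(1, dtype=np.uint32)
    return int(state[0]) & 0x7FFFFFFF


@dataclasses.dataclass
class ObserverConfig:
    """Synthetic cohort: per-environment base observers plus idiosyncratic
    jitter on intercept and lag-1 kernels (shared across environments, as
    inherent biases are a property of the participant)."""

    n_participants: int = 20
    neutral: ObserverParams = dataclasses.field(
        default_factory=lambda: ObserverParams(
            slope=20.0,
            lapse_cw=0.025,
            lapse_ccw=0.025,
            w_stim=np.array([0.1, 0, 0, 0, 0, 0, 0]),
            w_choice=np.array([0.1, 0, 0, 0, 0, 0, 0]),
            energy_beta=1.0,
        )
    )
    repeating: ObserverParams = dataclasses.field(
        default_factory=lambda: ObserverParams(
            slope=20.0,
            lapse_cw=0.025,
            lapse_ccw=0.025,
            w_stim=np.array([0.4, 0.2, 0.1, 0, 0, 0, 0]),
            w_choice=np.array([0.2, 0.1, 0, 0, 0, 0, 0]),
            energy_beta=1.0,
            gain_consistent=1.25,
            gain_inconsistent=0.75,
        )
    )
    kernel_jitter_sd: float = 0.15
    intercept_jitter_sd: float = 0.2


@dataclasses.dataclass
class AnalysisConfig:
    n_lags: int = 7
    lam: float = 0.001
    lapse_mode: str = "grid"
    iqr_factor: float = 1.5
    quartile_method: str = "linear"
    min_trials: int = 10
    energy_dtype: str = "complex64"


@dataclasses.dataclass
class PipelineConfig:
    """Full pipeline configuration; round-trips losslessly through YAML."""

    design: DesignConfig = dataclasses.field(default_factory=DesignConfig)
    stimulus: StimulusParams = dataclasses.field(
        default_factory=lambda: StimulusParams(pixels_per_degree=6.4)
    )
    observers: ObserverConfig = dataclasses.field(default_factory=ObserverConfig)
    analysis: AnalysisConfig = dataclasses.field(default_factory=AnalysisConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for env in ("neutral", "repeating"):
            d["observers"][env] = getattr(self.observers, env).to_dict()
        d["design"]["contrasts"] = list(self.design.contrasts)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        try:
            design = DesignConfig(**{**d.get("design", {})})
            design.contrasts = tuple(design.contrasts)
            stim = StimulusParams(**d.get("stimulus", {}))
            obs_d = dict(d.get("observers", {}))
            for env in ("neutral", "repeating"):
                if env in obs_d:
                    obs_d[env] = ObserverParams.from_dict(obs_d[env])
            observers = ObserverConfig(**obs_d)
            analysis = AnalysisConfig(**d.get("analysis", {}))
        except (TypeError, ValueError) as err:
            raise ConfigError(str(err)) from err
        return cls(design=design, stimulus=stim, observers=observers, analysis=analysis)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def validate(self) -> None:
        try:
            self.design.validate()
        except ValueError as err:
            raise ConfigError(str(err)) from err
        if self.observers.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _jitter_params(
    base: ObserverParams, d_intercept: float, d_stim: float, d_choice: float
) -> ObserverParams:
    p = dataclasses.replace(base)
    p.intercept = base.intercept + d_intercept
    p.w_stim = base.w_stim.copy()
    p.w_choice = base.w_choice.copy()
    p.w_stim[0] += d_stim
    p.w_choice[0] += d_choice
    return p


def run_end_to_end(
    config: PipelineConfig | None = None,
    seed: int = 0,
    out_dir: str | Path = "seqbias_out",
) -> dict:
    """Run the complete synthetic-cohort pipeline and return the manifest."""
    config = config or PipelineConfig()
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": int(seed),
        "config": config.to_dict(),
        "stages": [],
    }

    def record(stage: str, files: list[Path], stage_seed_val: int | None = None):
        manifest["stages"].append(
            {
                "stage": stage,
                "seed": stage_seed_val,
                "outputs": {f.name: _sha256(f) for f in files},
            }
        )
        logger.info("stage %s complete (%d files)", stage, len(files))

    n_p = config.observers.n_participants
    pids = [f"p{i:03d}" for i in range(1, n_p + 1)]
    dtype = np.complex64 if config.analysis.energy_dtype == "complex64" else np.complex128

    # 1. design ------------------------------------------------------------
    stage = "design"
    try:
        s0 = stage_seed(seed, stage)
        designs = {pid: build_session(config.design, seed=s0 + i) for i, pid in enumerate(pids)}
        design_df = pd.concat(
            [d.to_frame(pid) for pid, d in designs.items()], ignore_index=True
        )
        f = out / "design.csv"
        design_df.to_csv(f, index=False)
        record(stage, [f], s0)
    except Exception as err:
        raise StageError(stage, err) from err

    # 2. stimuli / energies ------------------------------------------------
    stage = "energies"
    try:
        s0 = stage_seed(seed, stage)
        bank = FilterBank(config.stimulus)
        stacks: list[EnergyStack] = []
        mean_frames = []
        for i, pid in enumerate(pids):
            st, means = zero_contrast_energy_stacks(
                designs[pid], bank, seed=s0 + i, participant_id=pid, dtype=dtype
            )
            stacks.extend(st)
            mean_frames.append(means)
        means_df = pd.concat(mean_frames, ignore_index=True)
        f = out / "energy_class_means.csv"
        means_df.to_csv(f, index=False)
        record(stage, [f], s0)
    except Exception as err:
        raise StageError(stage, err) from err

    # 3. behavior ----------------------------------------------------------
    stage = "behavior"
    try:
        s0 = stage_seed(seed, stage)
        rng = np.random.default_rng(stage_seed(seed, "observer_jitter"))
        frames = []
        for i, pid in enumerate(pids):
            di, ds, dc = (
                rng.normal(0, config.observers.intercept_jitter_sd),
                rng.normal(0, config.observers.kernel_jitter_sd),
                rng.normal(0, config.observers.kernel_jitter_sd),
            )
            params = {
                "neutral": _jitter_params(config.observers.neutral, di, ds, dc),
                "repeating": _jitter_params(config.observers.repeating, di, ds, dc),
            }
            frames.append(
                simulate_session(
                    params,
                    designs[pid],
                    energies=means_df[means_df["participant_id"] == pid],
                    seed=s0 + i,
                    participant_id=pid,
                )
            )
        behavior = pd.concat(frames, ignore_index=True)
        f = out / "behavior.csv"
        behavior.to_csv(f, index=False)
        record(stage, [f], s0)
    except Exception as err:
        raise StageError(stage, err) from err

    # 4. exclusions ---------------------------------------------------------
    stage = "exclusions"
    try:
        behavior_kept, report = apply_exclusion_criteria(behavior)
        f = out / "exclusions.csv"
        report.to_csv(f, index=False)
        record(stage, [f])
        kept_ids = set(behavior_kept["participant_id"].unique())
    except Exception as err:
        raise StageError(stage, err) from err

    # 5. history fits --------------------------------------------------------
    stage = "history_fits"
    try:
        fits = {}
        fit_rows = []
        summary_frames = []
        for pid in sorted(kept_ids):
            d = behavior_kept[behavior_kept["participant_id"] == pid]
            for env in ("neutral", "repeating"):
                dm = build_design_matrix(d, env, n_lags=config.analysis.n_lags)
                fit = fit_lasso_logistic(
                    dm, lam=config.analysis.lam, lapse_mode=config.analysis.lapse_mode
                )
                fits[(pid, env)] = fit
                fit_rows.append(
                    {
                        "participant_id": pid,
                        "environment": env,
                        "lapse_cw": fit.lapse_cw,
                        "lapse_ccw": fit.lapse_ccw,
                        "converged": fit.converged,
                        **fit.weights,
                    }
                )
            s = derive_history_summaries(fits[(pid, "neutral")], fits[(pid, "repeating")])
            s.insert(0, "participant_id", pid)
            summary_frames.append(s)
        f1 = out / "history_fits.json"
        f1.write_text(json.dumps(fit_rows, indent=1, sort_keys=True))
        summaries = pd.concat(summary_frames, ignore_index=True)
        f2 = out / "history_summaries.csv"
        summaries.to_csv(f2, index=False)
        acc = accuracy_summaries(behavior_kept)
        f3 = out / "accuracy_low_contrast.csv"
        acc["low_contrast"].to_csv(f3, index=False)
        record(stage, [f1, f2, f3])
    except Exception as err:
        raise StageError(stage, err) from err

    # 6. reverse correlation -------------------------------------------------
    stage = "revcorr"
    try:
        kept_stacks = [s for s in stacks if s.participant_id in kept_ids]
        rc = reverse_correlation(
            behavior_kept,
            kept_stacks,
            min_trials=config.analysis.min_trials,
            iqr_factor=config.analysis.iqr_factor,
            quartile_method=config.analysis.quartile_method,
        )
        f1 = out / "revcorr_bias.csv"
        rc.bias.to_csv(f1, index=False)
        f2 = out / "revcorr_sensitivity.csv"
        rc.sensitivity.to_csv(f2, index=False)
        f3 = out / "revcorr_effect.csv"
        rc.history_sensitivity_effect.to_csv(f3, index=False)
        record(stage, [f1, f2, f3])
    except Exception as err:
        raise StageError(stage, err) from err

    # 7. group statistics ----------------------------------------------------
    stage = "group_stats"
    try:
        rows = []

        def attempt(name, fn):
            try:
                res = fn()
                if isinstance(res, dict):
                    for k, v in res.items():
                        rows.append({"contrast": f"{name}:{k}", **v.to_dict()})
                else:
                    rows.append({"contrast": name, **res.to_dict()})
            except ValueError as e:
                rows.append({"contrast": name, "error": str(e)})

        lag1 = summaries[summaries["lag"] == 1]
        attempt(
            "adaptation_prev_correct_lag1",
            lambda: paired_t(
                lag1["prev_correct_repeating"].to_numpy(),
                lag1["prev_correct_neutral"].to_numpy(),
            ),
        )
        attempt(
            "bias_prev_by_env",
            lambda: rm_anova(rc.bias, "bias", ["prev_stim", "environment"]),
        )
        attempt(
            "sensitivity_class_prev_env",
            lambda: rm_anova(
                rc.sensitivity, "sensitivity",
                ["energy_class", "prev_stim", "environment"],
            ),
        )
        low = acc["low_contrast"]
        low_rep = low[low["environment"] == "repeating"].set_index("participant_id")
        merged = lag1.set_index("participant_id").join(low_rep, how="inner")
        attempt(
            "adaptation_vs_low_contrast_accuracy",
            lambda: correlation(
                merged["adaptation"].to_numpy(), merged["accuracy"].to_numpy(),
                method="spearman",
            ),
        )
        f = out / "group_stats.csv"
        pd.DataFrame(rows).to_csv(f, index=False)
        record(stage, [f])
    except Exception as err:
        raise StageError(stage, err) from err

    fm = out / "manifest.json"
    fm.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

TINY_CONFIG = PipelineConfig(
    design=DesignConfig(n_blocks_per_env=2, trials_per_block=100),
    stimulus=StimulusParams(pixels_per_degree=6.4),
    observers=ObserverConfig(n_participants=2),
)

STANDARD_CONFIG = PipelineConfig()


def generate_fixtures(size: str, seed: int = 0, out_dir: str | Path = "fixtures") -> dict:
    """Write deterministic synthetic fixtures.

    ``tiny``: 2 participants x 2 blocks/environment at a 64 x 64 raster,
    including per-trial energy tables.  ``standard``: 20 participants at the
    full 12-block session scale (design and behavior tables; energy profiles
    are computed on demand by the pipeline).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if size == "tiny":
        cfg = TINY_CONFIG
    elif size == "standard":
        cfg = STANDARD_CONFIG
    else:
        raise ConfigError(f"unknown fixture size {size!r}")
    n_p = cfg.observers.n_participants
    pids = [f"p{i:03d}" for i in range(1, n_p + 1)]
    s_design = stage_seed(seed, "design")
    s_energy = stage_seed(seed, "energies")
    s_beh = stage_seed(seed, "behavior")
    designs = {pid: build_session(cfg.design, seed=s_design + i) for i, pid in enumerate(pids)}
    files = {}
    design_df = pd.concat([d.to_frame(pid) for pid, d in designs.items()], ignore_index=True)
    design_df.to_csv(out / "design.csv", index=False)
    files["design"] = out / "design.csv"
    bank = FilterBank(cfg.stimulus) if size == "tiny" else None
    frames = []
    energy_frames = []
    for i, pid in enumerate(pids):
        energies = None
        if bank is not None:
            stacks, energies = zero_contrast_energy_stacks(
                designs[pid], bank, seed=s_energy + i, participant_id=pid
            )
            energy_frames.extend(s.to_frame() for s in stacks)
        params = {
            "neutral": cfg.observers.neutral,
            "repeating": cfg.observers.repeating,
        }
        if cfg.observers.neutral.uses_energy and energies is None:
            # standard fixture: history-only observers (no rendered stimuli)
            params = {
                env: dataclasses.replace(p, energy_beta=0.0)
                for env, p in params.items()
            }
        frames.append(
            simulate_session(
                params, designs[pid], energies=energies, seed=s_beh + i, participant_id=pid
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(out / "behavior.csv", index=False)
    files["behavior"] = out / "behavior.csv"
    if energy_frames:
        pd.concat(energy_frames, ignore_index=True).to_csv(out / "energy.csv", index=False)
        files["energy"] = out / "energy.csv"
    return {k: str(v) for k, v in files.items()}
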