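"""Configuration, file formats, and the end-to-end pipeline runner.

The runner chains the stages: simulate -> extract movement traces -> apply
trial exclusions -> time-lock and average per participant -> cluster-based
permutation test per lock -> response-time model, and collects everything
into a serializable result bundle with provenance (seeds, config, versions).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster_stats import ClusterResult, PermutationSpec, cluster_test
from .delta_extraction import (
    DeltaTrace,
    align_to_events,
    extract_delta_trace,
    write_frame_stack,
)
from .epoching import (
    ExclusionConfig,
    ExclusionReport,
    WindowPolicy,
    average_condition,
    build_analysis_matrix,
    epoch_trace,
    filter_trials,
)
from .rt_model import RTModelResult, fit_rt_model, summarize_rt
from .synthetic_data import (
    ByCondition,
    GeneratorConfig,
    ShiftedLognormal,
    TrialEvents,
    TruncatedNormal,
    generate_dataset,
)

logger = logging.getLogger(__name__)

EVENT_COLUMNS = [
    "participant_id",
    "item_id",
    "condition",
    "question_onset",
    "critical_word_onset",
    "question_offset",
    "response_onset",
    "response_offset",
    "correct",
    "hesitation",
    "onset_phoneme",
]
_TIME_COLUMNS = EVENT_COLUMNS[3:8]

__all__ = [
    "RunConfig",
    "ResultBundle",
    "LockResult",
    "read_events",
    "write_events",
    "run_pipeline",
    "plot_traces",
    "events_from_row",
]


class EventsFormatError(ValueError):
    """Raised for structurally invalid events tables."""


# ---------------------------------------------------------------------------
# events table round trip
# ---------------------------------------------------------------------------

def write_events(events: pd.DataFrame, path: str | Path) -> Path:
    """Write an events table as CSV, times with 6 decimal places."""
    path = Path(path)
    df = events.copy()
    for col in _TIME_COLUMNS:
        df[col] = df[col].map(lambda v: f"{v:.6f}")
    df.to_csv(path, index=False)
    return path


def read_events(path: str | Path) -> pd.DataFrame:
    """Read and validate an events CSV.

    Missing required columns raise; rows violating the event-order
    invariants are dropped with a warning that lists their (1-based) row
    numbers.
    """
    df = pd.read_csv(Path(path))
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise EventsFormatError(f"events file lacks required columns: {missing}")
    for col in _TIME_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("correct", "hesitation"):
        if df[col].dtype != bool:
            df[col] = df[col].astype(str).str.lower().map(
                {"true": True, "false": False, "1": True, "0": False}
            )
    bad = (
        df[_TIME_COLUMNS].isna().any(axis=1)
        | df[["correct", "hesitation"]].isna().any(axis=1)
        | ~(df["question_onset"] < df["critical_word_onset"])
        | ~(df["critical_word_onset"] < df["question_offset"])
        | ~(df["response_onset"] > df["critical_word_onset"])
        | ~(df["response_offset"] > df["response_onset"])
    )
    if bad.any():
        rows = [int(i) + 2 for i in np.flatnonzero(bad.to_numpy())]  # header = line 1
        warnings.warn(f"dropping {len(rows)} malformed events rows (lines {rows})",
                      stacklevel=2)
        df = df[~bad]
    df["correct"] = df["correct"].astype(bool)
    df["hesitation"] = df["hesitation"].astype(bool)
    return df.reset_index(drop=True)


def events_from_row(row) -> TrialEvents:
    """Rehydrate a TrialEvents object from one events-table row."""
    return TrialEvents(
        participant_id=int(row["participant_id"]),
        item_id=int(row["item_id"]),
        condition=str(row["condition"]),
        question_onset=float(row["question_onset"]),
        critical_word_onset=float(row["critical_word_onset"]),
        question_offset=float(row["question_offset"]),
        response_onset=float(row["response_onset"]),
        response_offset=float(row["response_offset"]),
        correct=bool(row["correct"]),
        hesitation=bool(row["hesitation"]),
        onset_phoneme=str(row["onset_phoneme"]),
    )


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything needed for one end-to-end run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    exclusion: ExclusionConfig = field(default_factory=ExclusionConfig)
    locks: tuple = ("TL1", "TL2", "TL3")
    permutation: PermutationSpec = field(default_factory=PermutationSpec)
    normalization: str = "none"
    render: bool = True  # False short-circuits to the latent kinematics
    min_trials: int = 1
    clip: dict | None = None  # lock -> (lo, hi) seconds, optional
    out_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.locks:
            raise ValueError("locks must be nonempty")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        gen = _generator_from_dict(d.pop("generator", {}) or {})
        exc_d = d.pop("exclusion", {}) or {}
        if "excluded_phonemes" in exc_d:
            exc_d["excluded_phonemes"] = frozenset(exc_d["excluded_phonemes"])
        exclusion = ExclusionConfig(**exc_d)
        locks = tuple(d.pop("locks", ("TL1", "TL2", "TL3")))
        perm_d = dict(d.pop("permutation", {}) or {})
        if perm_d.get("alpha_final") is None:
            perm_d["alpha_final"] = 0.05 / len(locks)
        permutation = PermutationSpec(**perm_d)
        clip = d.pop("clip", None)
        if clip is not None:
            clip = {k: tuple(v) for k, v in clip.items()}
        return cls(generator=gen, exclusion=exclusion, locks=locks,
                   permutation=permutation, clip=clip, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (frozenset, set, tuple)):
                return sorted(obj) if isinstance(obj, (frozenset, set)) else list(obj)
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            return obj

        return enc(self)


def _dist_from_dict(d: dict):
    if "median" in d:
        return ShiftedLognormal(**d)
    return TruncatedNormal(**d)


def _generator_from_dict(d: dict) -> GeneratorConfig:
    d = dict(d)
    for name in ("word_onset", "word_to_offset", "rt", "prep_lead"):
        if name in d and isinstance(d[name], dict):
            sub = d[name]
            d[name] = ByCondition(
                early_planning=_dist_from_dict(sub["early_planning"]),
                late_planning=_dist_from_dict(sub["late_planning"]),
            )
    if "answer_duration" in d and isinstance(d["answer_duration"], dict):
        d["answer_duration"] = TruncatedNormal(**d["answer_duration"])
    return GeneratorConfig(**d)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class LockResult:
    lock: str
    times: np.ndarray
    grand_mean: dict  # condition -> T vector
    matrices: dict  # condition -> P x T matrix
    cluster: ClusterResult

    def to_dict(self) -> dict:
        return {
            "lock": self.lock,
            "n_timepoints": len(self.times),
            "window_s": [float(self.times[0]), float(self.times[-1])],
            "cluster": self.cluster.to_dict(),
        }


@dataclass
class ResultBundle:
    exclusion: ExclusionReport
    locks: dict  # lock -> LockResult
    rt_summary: dict
    rt_model: RTModelResult | None
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "exclusion": self.exclusion.to_dict(),
            "locks": {k: v.to_dict() for k, v in self.locks.items()},
            "rt_summary": self.rt_summary,
            "rt_model": None if self.rt_model is None else self.rt_model.to_dict(),
            "provenance": self.provenance,
        }

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "bundle.json", "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
        for lock, res in self.locks.items():
            df = pd.DataFrame({"time_s": res.times})
            for cond, vec in res.grand_mean.items():
                df[f"mean_delta_{cond}"] = vec
            df["t"] = res.cluster.tseries.t_values
            df.to_csv(out / f"grand_average_{lock}.csv", index=False)
        return out / "bundle.json"


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0]) for child in ss.spawn(n)]


def traces_from_stacks(stacks, events_table: pd.DataFrame,
                       normalization: str) -> list[DeltaTrace]:
    """Extract and event-align one delta trace per rendered stack."""
    traces = []
    for stack, (_, row) in zip(stacks, events_table.iterrows()):
        ev = events_from_row(row)
        traces.append(align_to_events(extract_delta_trace(stack, normalization), ev))
    return traces


def analyze_lock(
    traces: list[DeltaTrace],
    kept: pd.DataFrame,
    lock: str,
    spec: PermutationSpec,
    policy: WindowPolicy,
) -> LockResult:
    """Epoch kept trials, average per participant/condition, run the test."""
    by_trial = {(t.participant_id, t.item_id): t for t in traces}
    epochs: dict[tuple, list] = {}
    for _, row in kept.iterrows():
        trace = by_trial.get((int(row["participant_id"]), int(row["item_id"])))
        if trace is None:
            logger.warning("no trace for trial P%s/I%s; skipped",
                           row["participant_id"], row["item_id"])
            continue
        ep = epoch_trace(trace, events_from_row(row), lock)
        epochs.setdefault((ep.participant_id, ep.condition), []).append(ep)
    averages = [average_condition(group) for group in epochs.values()]
    matrices, times = build_analysis_matrix(averages, lock, policy)
    conds = sorted(matrices)
    result = cluster_test(matrices[conds[0]], matrices[conds[1]],
                          grid_times=times, spec=spec, lock=lock)
    grand = {c: m.mean(axis=0) for c, m in matrices.items()}
    return LockResult(lock=lock, times=times, grand_mean=grand,
                      matrices=matrices, cluster=result)


def run_pipeline(config: RunConfig) -> ResultBundle:
    """Execute the full analysis and (optionally) write the result bundle."""
    gen_seed, perm_seed = _spawn_seeds(config.seed, 2)
    gen_cfg = dataclasses.replace(config.generator, seed=gen_seed)

    logger.info("simulating dataset (render=%s)", config.render)
    objects, events = generate_dataset(gen_cfg, render=config.render)
    if config.render:
        traces = traces_from_stacks(objects, events, config.normalization)
    else:
        traces = [k.as_delta_trace() for k in objects]

    kept, report = filter_trials(events, config.exclusion)
    logger.info("kept %d of %d trials", report.n_kept, report.n_input)

    spec = dataclasses.replace(config.permutation, seed=perm_seed)
    policy_clip = config.clip or {}
    locks = {}
    for lock in config.locks:
        policy = WindowPolicy(min_trials=config.min_trials,
                              clip=policy_clip.get(lock))
        locks[lock] = analyze_lock(traces, kept, lock, spec, policy)

    rt_summary = summarize_rt(kept)
    try:
        rt_result = fit_rt_model(kept)
    except Exception as exc:
        logger.warning("RT model fit failed: %s", exc)
        rt_result = None

    cfg_dict = config.to_dict()
    provenance = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "master_seed": config.seed,
        "generator_seed": gen_seed,
        "permutation_seed": perm_seed,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest(),
        "config": cfg_dict,
    }
    bundle = ResultBundle(exclusion=report, locks=locks,
                          rt_summary=rt_summary, rt_model=rt_result,
                          provenance=provenance)
    if config.out_dir:
        bundle.write(config.out_dir)
    return bundle


def simulate_to_disk(gen_cfg: GeneratorConfig, out_dir: str | Path) -> Path:
    """Render the dataset and write TIFF stacks plus the events CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stacks, events = generate_dataset(gen_cfg, render=True)
    for stack in stacks:
        name = f"P{stack.participant_id}_I{stack.item_id}_{stack.condition}.tif"
        write_frame_stack(stack, out / name)
    write_events(events, out / "events.csv")
    return out


def plot_traces(bundle: ResultBundle, lock: str, path: str | Path) -> Path:
    """Grand-average traces per condition with significant clusters shaded."""
    if lock not in bundle.locks:
        raise KeyError(f"bundle has no results for lock {lock!r}")
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    res = bundle.locks[lock]
    fig, ax = plt.subplots(figsize=(7, 4))
    t_ms = res.times * 1000.0
    colors = {"early_planning": "tab:blue", "late_planning": "tab:orange"}
    for cond, vec in res.grand_mean.items():
        ax.plot(t_ms, vec, label=cond.replace("_", " "),
                color=colors.get(cond))
    for c in res.cluster.significant_clusters:
        ax.axvspan(c.start_time * 1000.0, c.end_time * 1000.0,
                   color="tab:green" if c.sign > 0 else "tab:red", alpha=0.2)
    ax.axvline(0.0, color="k", lw=0.8, ls="--")
    ax.set_xlabel(f"time relative to {lock} (ms)")
    ax.set_ylabel("frame-to-frame change (a.u.)")
    ax.legend(frameon=False)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path)
    plt.close(fig)
    return path
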