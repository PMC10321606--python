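"""Synthetic articulatory-ultrasound data generator.

Produces trial timelines (question / critical-word / response events with
condition-dependent, right-skewed response times), latent tongue-speed
kinematics (declining baseline while listening, a condition-dependent
preparatory ramp, and an articulation burst), and rendered ultrasound-like
grayscale frame stacks whose frame-to-frame pixel change tracks the latent
speed.  Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .delta_extraction import DeltaTrace, FrameStack

logger = logging.getLogger(__name__)

EARLY = "early_planning"
LATE = "late_planning"
CONDITIONS = (EARLY, LATE)

#: Onset consonants that ultrasound picks up poorly; trials flagged with one
#: of these are meant to be excluded downstream.
EXCLUDED_PHONEMES = ("d", "f", "ɣ", "ɦ", "m", "p", "r", "v", "ʋ")
ADMISSIBLE_PHONEMES = ("b", "t", "k", "s", "n", "l", "x", "w", "j", "z")

__all__ = [
    "EARLY",
    "LATE",
    "CONDITIONS",
    "EXCLUDED_PHONEMES",
    "ADMISSIBLE_PHONEMES",
    "TruncatedNormal",
    "ShiftedLognormal",
    "ByCondition",
    "GeneratorConfig",
    "TrialEvents",
    "KinematicTrace",
    "sample_trial_timeline",
    "generate_kinematics",
    "render_frame_stack",
    "generate_trial",
    "generate_dataset",
    "events_to_table",
]


class ConditionError(ValueError):
    """Raised for an unknown condition label."""


class ConfigurationError(ValueError):
    """Raised when generator parameters violate their invariants."""


def _check_condition(condition: str) -> str:
    if condition not in CONDITIONS:
        raise ConditionError(
            f"unknown condition {condition!r}; expected one of {CONDITIONS}"
        )
    return condition


@dataclass(frozen=True)
class TruncatedNormal:
    """Normal(mean, sd) resampling/clipping below ``minimum``; sd=0 is exact."""

    mean: float
    sd: float
    minimum: float = -np.inf

    def sample(self, rng: np.random.Generator) -> float:
        if self.sd == 0:
            return max(self.mean, self.minimum)
        return max(float(rng.normal(self.mean, self.sd)), self.minimum)


@dataclass(frozen=True)
class ShiftedLognormal:
    """Right-skewed distribution parameterized by its target mean and median.

    ``X = shift + exp(mu + sigma * Z)`` with ``shift`` and ``mu`` solved in
    closed form so that E[X] = mean and median(X) = median for the given
    ``sigma``:  exp(mu) = (mean - median) / (exp(sigma^2 / 2) - 1).
    """

    mean: float
    median: float
    sigma: float = 0.8

    def __post_init__(self) -> None:
        if not self.mean > self.median:
            raise ConfigurationError(
                "shifted lognormal needs mean > median (right skew)"
            )
        if self.sigma <= 0:
            raise ConfigurationError("sigma must be positive")

    @property
    def scale(self) -> float:
        return (self.mean - self.median) / (math.exp(self.sigma**2 / 2.0) - 1.0)

    @property
    def shift(self) -> float:
        return self.median - self.scale

    def sample(self, rng: np.random.Generator, size: int | None = None):
        z = rng.standard_normal(size)
        return self.shift + self.scale * np.exp(self.sigma * z)


@dataclass(frozen=True)
class ByCondition:
    """Container for per-condition distribution parameters."""

    early_planning: object
    late_planning: object

    def get(self, condition: str):
        _check_condition(condition)
        return getattr(self, condition)


def _default_word_onset() -> ByCondition:
    return ByCondition(
        early_planning=TruncatedNormal(1.619, 0.740, minimum=0.3),
        late_planning=TruncatedNormal(1.788, 0.950, minimum=0.3),
    )


def _default_word_to_offset() -> ByCondition:
    return ByCondition(
        early_planning=TruncatedNormal(2.839, 0.655, minimum=0.5),
        late_planning=TruncatedNormal(2.669, 0.866, minimum=0.5),
    )


def _default_rt() -> ByCondition:
    return ByCondition(
        early_planning=ShiftedLognormal(mean=0.626, median=0.407, sigma=0.8),
        late_planning=ShiftedLognormal(mean=0.900, median=0.741, sigma=0.8),
    )


def _default_prep_lead() -> ByCondition:
    return ByCondition(
        early_planning=TruncatedNormal(1.2, 0.15, minimum=0.05),
        late_planning=TruncatedNormal(0.3, 0.08, minimum=0.02),
    )


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic dataset, with defaults calibrated to the
    study-scale timeline and response-time statistics."""

    n_participants: int = 25
    n_trials_per_condition: int | dict[str, int] = 29
    frame_rate_hz: float = 91.65
    image_height_px: int = 57
    image_width_px: int = 842

    # trial timeline (seconds)
    word_onset: ByCondition = field(default_factory=_default_word_onset)
    word_to_offset: ByCondition = field(default_factory=_default_word_to_offset)
    rt: ByCondition = field(default_factory=_default_rt)
    answer_duration: TruncatedNormal = TruncatedNormal(0.8, 0.15, minimum=0.2)
    question_onset_s: float = 0.5  # absolute trial-clock time of the sync pulse
    pre_window_s: float = 0.5  # recording starts this long before question onset
    post_window_s: float = 1.5  # and ends this long after response offset

    # kinematics (arbitrary speed units)
    baseline_level: float = 1.0
    baseline_jitter_sd: float = 0.25
    baseline_decline_per_s: float = 0.06
    prep_lead: ByCondition = field(default_factory=_default_prep_lead)
    prep_amplitude: float = 2.0
    prep_plateau_margin_s: float = 0.1  # ramp settles this long before speech
    # preparation cannot begin until planning has progressed past retrieval:
    # ramp onset never precedes critical word onset by less than this
    prep_min_delay_after_word_s: float = 1.8
    burst_amplitude: float = 6.0
    burst_duration_s: float = 0.8
    speed_noise_sd: float = 0.3
    # participant-level heterogeneity (applied identically to both
    # conditions, so condition exchangeability under a null config holds)
    participant_amp_sigma: float = 0.35  # lognormal sd of amplitude scaling
    participant_lead_sd: float = 0.2  # additive shift of prep-lead means (s)
    participant_baseline_sd: float = 0.2  # additive shift of baseline level

    # exclusion mechanisms (probabilities)
    p_incorrect: float = 0.081
    p_hesitation: float = 0.115
    p_excluded_phoneme: float = 0.049

    # rendering
    pixel_noise_sd: float = 4.0
    ridge_sigma_px: float = 2.5
    ridge_amplitude: float = 180.0
    ridge_gain_px: float = 0.2  # pixels of ridge travel per unit speed per frame
    background_level: float = 20.0
    contour_rel_amplitude: float = 0.12

    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = {
            "frame_rate_hz": self.frame_rate_hz,
            "image_height_px": self.image_height_px,
            "image_width_px": self.image_width_px,
            "burst_duration_s": self.burst_duration_s,
            "pre_window_s": self.pre_window_s,
            "post_window_s": self.post_window_s,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ConfigurationError(f"{name} must be positive, got {value}")
        nonneg = {
            "baseline_level": self.baseline_level,
            "baseline_decline_per_s": self.baseline_decline_per_s,
            "prep_amplitude": self.prep_amplitude,
            "burst_amplitude": self.burst_amplitude,
            "speed_noise_sd": self.speed_noise_sd,
            "pixel_noise_sd": self.pixel_noise_sd,
            "participant_amp_sigma": self.participant_amp_sigma,
            "participant_lead_sd": self.participant_lead_sd,
            "participant_baseline_sd": self.participant_baseline_sd,
        }
        for name, value in nonneg.items():
            if value < 0:
                raise ConfigurationError(f"{name} must be nonnegative, got {value}")
        for name, p in [
            ("p_incorrect", self.p_incorrect),
            ("p_hesitation", self.p_hesitation),
            ("p_excluded_phoneme", self.p_excluded_phoneme),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {p}")
        if self.image_height_px < 4 * self.ridge_sigma_px:
            raise ConfigurationError(
                f"image_height_px={self.image_height_px} too small for ridge "
                f"width sigma={self.ridge_sigma_px}"
            )

    def trials_for(self, condition: str) -> int:
        _check_condition(condition)
        if isinstance(self.n_trials_per_condition, dict):
            return int(self.n_trials_per_condition[condition])
        return int(self.n_trials_per_condition)


def null_config(**overrides) -> GeneratorConfig:
    """A config in which the two conditions are statistically exchangeable
    (identical timeline, RT, and preparation parameters)."""
    cfg = GeneratorConfig(**overrides)
    cfg.word_onset = ByCondition(
        cfg.word_onset.early_planning, cfg.word_onset.early_planning
    )
    cfg.word_to_offset = ByCondition(
        cfg.word_to_offset.early_planning, cfg.word_to_offset.early_planning
    )
    cfg.rt = ByCondition(cfg.rt.early_planning, cfg.rt.early_planning)
    cfg.prep_lead = ByCondition(
        cfg.prep_lead.early_planning, cfg.prep_lead.early_planning
    )
    return cfg


@dataclass
class TrialEvents:
    """Event times (absolute trial clock, seconds) and annotations of one trial.

    Question onset coincides with the sync pulse.  The response time is
    ``response_onset - question_offset`` and may be negative when the answer
    overlaps the end of the question.
    """

    participant_id: int
    item_id: int
    condition: str
    question_onset: float
    critical_word_onset: float
    question_offset: float
    response_onset: float
    response_offset: float
    correct: bool
    hesitation: bool
    onset_phoneme: str

    def __post_init__(self) -> None:
        _check_condition(self.condition)
        if not (self.question_onset < self.critical_word_onset < self.question_offset):
            raise ValueError("event order violated: onset < word onset < offset")
        if self.response_onset <= self.critical_word_onset:
            raise ValueError("response_onset must follow critical_word_onset")
        if self.response_offset <= self.response_onset:
            raise ValueError("response_offset must follow response_onset")

    @property
    def response_time(self) -> float:
        return self.response_onset - self.question_offset

    def lock_time(self, lock: str) -> float:
        return {
            "TL1": self.question_offset,
            "TL2": self.critical_word_onset,
            "TL3": self.response_onset,
        }[lock]


@dataclass
class KinematicTrace:
    """Latent tongue-speed ground truth, one value per inter-frame step.

    Timestamps sit at the inter-frame midpoints of the trial's frame grid
    (absolute clock), matching the sampling of the extracted delta trace.
    """

    timestamps: np.ndarray
    speed: np.ndarray  # nonnegative, length n_frames - 1
    frame_rate_hz: float
    sync_frame_index: int
    participant_id: int
    item_id: int
    condition: str

    @property
    def n_frames(self) -> int:
        return len(self.speed) + 1

    def as_delta_trace(self) -> DeltaTrace:
        """View the latent speed as an (already aligned) movement trace."""
        return DeltaTrace(
            timestamps=self.timestamps.copy(),
            values=self.speed.copy(),
            frame_rate_hz=self.frame_rate_hz,
            normalization="none",
            participant_id=self.participant_id,
            item_id=self.item_id,
            condition=self.condition,
            sync_time=self.timestamps[0],  # informational only
        )


def sample_trial_timeline(
    config: GeneratorConfig,
    condition: str,
    rng: np.random.Generator,
    participant_id: int = 0,
    item_id: int = 0,
) -> TrialEvents:
    """Draw one trial's event times and annotation flags."""
    _check_condition(condition)
    q_on = config.question_onset_s
    word_on = q_on + config.word_onset.get(condition).sample(rng)
    q_off = word_on + config.word_to_offset.get(condition).sample(rng)
    rt = float(config.rt.get(condition).sample(rng))
    # keep the response after the critical word even for extreme negative RTs
    rt = max(rt, word_on - q_off + 0.05)
    r_on = q_off + rt
    r_off = r_on + config.answer_duration.sample(rng)

    correct = bool(rng.random() >= config.p_incorrect)
    hesitation = bool(rng.random() < config.p_hesitation)
    if rng.random() < config.p_excluded_phoneme:
        phoneme = str(rng.choice(EXCLUDED_PHONEMES))
    else:
        phoneme = str(rng.choice(ADMISSIBLE_PHONEMES))

    return TrialEvents(
        participant_id=participant_id,
        item_id=item_id,
        condition=condition,
        question_onset=q_on,
        critical_word_onset=word_on,
        question_offset=q_off,
        response_onset=r_on,
        response_offset=r_off,
        correct=correct,
        hesitation=hesitation,
        onset_phoneme=phoneme,
    )


def _frame_grid(events: TrialEvents, config: GeneratorConfig):
    """Frame times and sync index for one trial's recording window."""
    fps = config.frame_rate_hz
    duration = (events.response_offset + config.post_window_s) - (
        events.question_onset - config.pre_window_s
    )
    n_frames = int(math.ceil(duration * fps))
    sync_index = int(math.ceil(config.pre_window_s * fps))
    # anchor the grid so the sync frame falls exactly on question onset
    start = events.question_onset - sync_index / fps
    frame_times = start + np.arange(n_frames) / fps
    return frame_times, sync_index


def speed_profile(
    times: np.ndarray,
    events: TrialEvents,
    config: GeneratorConfig,
    prep_lead: float,
    baseline_level: float | None = None,
) -> np.ndarray:
    """Deterministic part of the speed trace evaluated at ``times``.

    baseline (flat before the question, declining linearly during it, held
    after question offset) + piecewise-linear preparatory ramp to a plateau
    at response onset + raised-cosine articulation burst, decaying after
    response offset.
    """
    t = np.asarray(times, dtype=float)
    b0 = config.baseline_level if baseline_level is None else baseline_level
    q_on, q_off = events.question_onset, events.question_offset
    r_on, r_off = events.response_onset, events.response_offset

    elapsed = np.clip(t - q_on, 0.0, q_off - q_on)
    baseline = np.maximum(b0 - config.baseline_decline_per_s * elapsed, 0.0)

    ramp_start = r_on - prep_lead
    earliest = max(
        q_on, events.critical_word_onset + config.prep_min_delay_after_word_s
    )
    if ramp_start < earliest:
        logger.debug("prep ramp start %.3f clipped to %.3f", ramp_start, earliest)
        ramp_start = earliest
    # articulators settle into position shortly before the acoustic onset
    plateau_at = r_on - min(config.prep_plateau_margin_s, 0.5 * prep_lead)
    ramp_start = min(ramp_start, plateau_at - 1e-3)
    rise = np.clip((t - ramp_start) / max(plateau_at - ramp_start, 1e-9), 0.0, 1.0)
    plateau_end = r_off
    decay = np.clip(1.0 - (t - plateau_end) / 0.5, 0.0, 1.0)
    ramp = config.prep_amplitude * rise * decay

    phase = np.clip((t - r_on) / config.burst_duration_s, 0.0, 1.0)
    burst = config.burst_amplitude * np.sin(np.pi * phase) ** 2

    return np.maximum(baseline + ramp + burst, 0.0)


def generate_kinematics(
    events: TrialEvents, config: GeneratorConfig, rng: np.random.Generator
) -> KinematicTrace:
    """Latent speed for one trial on the trial's inter-frame midpoint grid."""
    frame_times, sync_index = _frame_grid(events, config)
    mids = 0.5 * (frame_times[:-1] + frame_times[1:])
    prep_lead = config.prep_lead.get(events.condition).sample(rng)
    b0 = max(
        config.baseline_level + rng.normal(0.0, config.baseline_jitter_sd), 0.0
    ) if config.baseline_jitter_sd > 0 else config.baseline_level
    speed = speed_profile(mids, events, config, prep_lead, baseline_level=b0)
    if config.speed_noise_sd > 0:
        speed = speed + np.abs(rng.normal(0.0, config.speed_noise_sd, mids.shape))
    return KinematicTrace(
        timestamps=mids,
        speed=np.maximum(speed, 0.0),
        frame_rate_hz=config.frame_rate_hz,
        sync_frame_index=sync_index,
        participant_id=events.participant_id,
        item_id=events.item_id,
        condition=events.condition,
    )


def _reflect(positions: np.ndarray, bound: float) -> np.ndarray:
    """Fold an unbounded trajectory into [-bound, bound] by reflection."""
    if bound <= 0:
        return np.zeros_like(positions)
    x = np.mod(positions + bound, 4.0 * bound)
    return np.where(x < 2.0 * bound, x - bound, 3.0 * bound - x)


def render_frame_stack(
    trace: KinematicTrace,
    config: GeneratorConfig,
    rng: np.random.Generator,
    chunk: int = 256,
) -> FrameStack:
    """Render a trial as an 8-bit grayscale stack.

    Each frame shows background speckle plus a bright ridge (column-wise
    Gaussian profile around a smooth baseline contour).  The ridge's
    vertical displacement advances by ``ridge_gain_px * speed`` pixels per
    frame step (reflecting off a band limit so it stays in view), so the
    inter-frame pixel change grows with the latent speed.
    """
    h, w = config.image_height_px, config.image_width_px
    if h < 4 * config.ridge_sigma_px:
        raise ConfigurationError("image height too small for the ridge profile")
    n = trace.n_frames
    cols = np.arange(w)
    contour = h / 2.0 + config.contour_rel_amplitude * h * np.sin(
        2.0 * np.pi * 1.5 * cols / w + 0.7
    )
    travel = np.concatenate(
        [[0.0], np.cumsum(config.ridge_gain_px * trace.speed)]
    )
    bound = max(h / 2.0 - config.contour_rel_amplitude * h - 4 * config.ridge_sigma_px, 1.0)
    disp = _reflect(travel, bound)

    rows = np.arange(h, dtype=np.float64)
    frames = np.empty((n, h, w), dtype=np.uint8)
    two_sig2 = 2.0 * config.ridge_sigma_px**2
    for k0 in range(0, n, chunk):
        k1 = min(k0 + chunk, n)
        centers = contour[None, None, :] + disp[k0:k1, None, None]
        block = config.background_level + config.ridge_amplitude * np.exp(
            -((rows[None, :, None] - centers) ** 2) / two_sig2
        )
        if config.pixel_noise_sd > 0:
            block = block + rng.normal(0.0, config.pixel_noise_sd, block.shape)
        frames[k0:k1] = np.clip(np.rint(block), 0, 255).astype(np.uint8)

    return FrameStack(
        frames=frames,
        frame_rate_hz=config.frame_rate_hz,
        sync_frame_index=trace.sync_frame_index,
        participant_id=trace.participant_id,
        item_id=trace.item_id,
        condition=trace.condition,
    )


def personalize(config: GeneratorConfig, rng: np.random.Generator) -> GeneratorConfig:
    """Draw one participant's private parameter modifiers.

    A lognormal scale on the preparation/burst amplitudes and additive
    shifts of the prep-lead means and baseline level.  Both conditions get
    the same modifiers, so a null (exchangeable-conditions) config stays
    exchangeable.
    """
    from dataclasses import replace as _replace

    scale = float(np.exp(rng.normal(0.0, config.participant_amp_sigma)))
    lead_shift = float(rng.normal(0.0, config.participant_lead_sd))
    base_shift = float(rng.normal(0.0, config.participant_baseline_sd))

    def shifted(tn: TruncatedNormal) -> TruncatedNormal:
        return _replace(tn, mean=max(tn.mean + lead_shift, tn.minimum))

    return _replace(
        config,
        prep_amplitude=config.prep_amplitude * scale,
        burst_amplitude=config.burst_amplitude * scale,
        baseline_level=max(config.baseline_level + base_shift, 0.05),
        prep_lead=ByCondition(
            early_planning=shifted(config.prep_lead.get(EARLY)),
            late_planning=shifted(config.prep_lead.get(LATE)),
        ),
    )


def generate_trial(
    config: GeneratorConfig,
    condition: str,
    rng: np.random.Generator,
    participant_id: int = 0,
    item_id: int = 0,
    render: bool = True,
):
    """Convenience: timeline -> kinematics -> (optionally) rendered stack."""
    events = sample_trial_timeline(config, condition, rng, participant_id, item_id)
    trace = generate_kinematics(events, config, rng)
    stack = render_frame_stack(trace, config, rng) if render else None
    return events, trace, stack


def events_to_table(events: Iterable[TrialEvents], sync_indices=None) -> pd.DataFrame:
    rows = []
    for ev in events:
        rows.append(
            {
                "participant_id": ev.participant_id,
                "item_id": ev.item_id,
                "condition": ev.condition,
                "question_onset": ev.question_onset,
                "critical_word_onset": ev.critical_word_onset,
                "question_offset": ev.question_offset,
                "response_onset": ev.response_onset,
                "response_offset": ev.response_offset,
                "correct": ev.correct,
                "hesitation": ev.hesitation,
                "onset_phoneme": ev.onset_phoneme,
            }
        )
    df = pd.DataFrame(rows)
    if sync_indices is not None:
        df["sync_frame_index"] = list(sync_indices)
    return df


def generate_dataset(
    config: GeneratorConfig,
    render: bool = True,
) -> tuple[list, pd.DataFrame]:
    """Generate the full design: participants x conditions x trials.

    Items are counterbalanced: item ``i`` is early-planning for participant
    ``p`` iff ``(i + p)`` is even, so every item occurs in both conditions
    across participants.  Returns the per-trial objects (``FrameStack`` if
    ``render`` else ``KinematicTrace``) and the events table.
    """
    rng = np.random.default_rng(config.seed)
    n_ep = config.trials_for(EARLY)
    n_lp = config.trials_for(LATE)
    n_items = n_ep + n_lp
    objects = []
    all_events = []
    sync_indices = []
    for p in range(1, config.n_participants + 1):
        p_cfg = personalize(config, rng)
        ep_items = [i for i in range(1, n_items + 1) if (i + p) % 2 == 0][:n_ep]
        lp_items = [i for i in range(1, n_items + 1) if (i + p) % 2 == 1][:n_lp]
        # top up from the other parity if counts are unbalanced
        leftovers = [
            i for i in range(1, n_items + 1) if i not in ep_items and i not in lp_items
        ]
        while len(ep_items) < n_ep:
            ep_items.append(leftovers.pop(0))
        while len(lp_items) < n_lp:
            lp_items.append(leftovers.pop(0))
        for condition, items in ((EARLY, ep_items), (LATE, lp_items)):
            for item in items:
                events, trace, stack = generate_trial(
                    p_cfg, condition, rng, participant_id=p, item_id=item,
                    render=render,
                )
                all_events.append(events)
                sync_indices.append(trace.sync_frame_index)
                objects.append(stack if render else trace)
    table = events_to_table(all_events, sync_indices)
    return objects, table
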