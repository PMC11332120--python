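"""Trial-level cohort generator with the statistical structure the analysis assumes.

The generator is the study's generative twin: a Day-1 auditory-only pre-test,
fourteen daily audiovisual McGurk exposure sessions, a Day-16 post-test and
approximately monthly long-term tests, with responses produced by the causal
inference model itself.  Each participant draws a common-cause probability from a
class-specific Beta distribution — a bimodal mixture that reproduces the observed
split into fusion perceivers (~95% exposure fusion) and auditory perceivers (~6%)
— experiences exposure trials simulated from the integrated AV distribution, and
recalibrates after the first exposure day by the day's realized fusion fraction.
Auditory-only tests are then simulated from the shifted representation A'.

Long-term trajectories: persistent participants keep their shift; decaying
participants relax it so their fusion probability follows a * exp(b * t) exactly
(the family the decay fitter assumes); an optional "absent" class attenuates the
shift from the start, emulating fusion perceivers in whom recalibration never
consolidates — off by default because it deliberately leaves the model's
generative family.  Auditory perceivers shift (essentially) nothing and realize
absent trajectories on their own.

Response noise is a small lapse rate: a lapsed report is uniform over the three
categories other than the perceived one.  Control syllables are answered
correctly at a configurable accuracy.  Everything is reproducible from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import cims_model as cm
from .dataset_io import (
    ScheduleSpec,
    StimulusSpec,
    TRIAL_COLUMNS,
    main_schedule,
    main_stimuli,
    replication_schedule,
    replication_stimuli,
)

__all__ = [
    "CohortConfig",
    "generate_cohort",
    "generate_replication_cohort",
    "generate_null_fusion_counts",
]

#: Open-choice wrong answers for control syllables (all code as Other).
_CONTROL_ERRORS = ("fa", "na", "wa", "ha")

#: Closed-list label for each token in the replication experiment.
_TOKEN_TO_CHOICE = {
    "baba": "BaBa",
    "gaga": "GaGa",
    "dada": "DaDa",
    "pa": "Pa",
    "ka": "Ka",
    "ta": "Ta",
}


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings; the defaults are the main-study conditions.

    ``p_common_high``/``p_common_low`` are (mean, sd) of the Beta distributions
    the two perceiver classes draw their common-cause probability from.  They are
    placed where the model's exposure fusion rate matches the study's bimodal
    rates (~95% for fusion perceivers, ~6% for auditory perceivers) under the
    default geometry.  ``trajectory_mixture`` applies to fusion perceivers;
    ``decay_b_per_month`` is the per-month log rate of the decaying class (the
    default corresponds to a ~42% loss per month).
    """

    n_participants: int = 28
    proportion_fusion_perceivers: float = 0.5
    p_common_high: tuple[float, float] = (0.62, 0.025)
    p_common_low: tuple[float, float] = (0.38, 0.025)
    #: P(fusion class) for the weaker, secondary McGurk stimulus (S2: 4 of 28).
    prob_fusion_class_secondary: float = 4 / 28
    trajectory_mixture: Mapping[str, float] = field(
        default_factory=lambda: {"persistent": 0.3, "decaying": 0.7, "absent": 0.0}
    )
    decay_b_per_month: float = -0.545
    decay_scale: str = "fir"  # "fir": relax on the probability scale; "shift": on the fraction
    absent_shift_attenuation: float = 0.02
    control_accuracy: float = 0.96
    lapse_rate: float = 0.01
    n_longterm_tests: int = 6
    schedule: ScheduleSpec = field(default_factory=main_schedule)
    model: cm.ModelConfig = field(default_factory=cm.ModelConfig)

    def __post_init__(self) -> None:
        total = sum(self.trajectory_mixture.values())
        if abs(total - 1.0) > 1e-9 or min(self.trajectory_mixture.values()) < 0:
            raise ValueError("trajectory mixture must be non-negative and sum to 1")
        for p in (
            self.proportion_fusion_perceivers,
            self.prob_fusion_class_secondary,
            self.control_accuracy,
            self.lapse_rate,
        ):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.decay_scale not in ("fir", "shift"):
            raise ValueError("decay_scale must be 'fir' or 'shift'")


def _beta_params(mean: float, sd: float) -> tuple[float, float]:
    nu = mean * (1 - mean) / sd**2 - 1
    if nu <= 0:
        raise ValueError("Beta sd too large for the given mean")
    return mean * nu, (1 - mean) * nu


def _truth_columns() -> list[str]:
    return [
        "participant_id",
        "stimulus_id",
        "perceiver_class",
        "p_common",
        "day1_shift_fraction",
        "trajectory_class",
        "decay_b",
    ]


class _Lapser:
    """Applies report lapses: a lapsed response is uniform over the other
    categories definable for the stimulus context (controls have no Visual or
    Fusion category, only Auditory vs Other)."""

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def apply(self, categories: list[str], available: tuple[str, ...]) -> list[str]:
        if self.rate == 0:
            return categories
        out = list(categories)
        for i in range(len(out)):
            if self.rng.random() < self.rate:
                others = [c for c in available if c != out[i]]
                out[i] = others[self.rng.integers(len(others))]
        return out


def _category_of(token: str, stim: StimulusSpec, parent: StimulusSpec | None) -> str:
    src = parent if (stim.is_auditory_only and parent is not None) else stim
    if token == stim.auditory_token:
        return "Auditory"
    if src.visual_token is not None and token == src.visual_token:
        return "Visual"
    if src.expected_fusion_token is not None and token == src.expected_fusion_token:
        return "Fusion"
    return "Other"


def _raw_for(category: str, stim: StimulusSpec, parent: StimulusSpec | None, forced: bool) -> str:
    src = parent if (stim.is_auditory_only and parent is not None) else stim
    token = {
        "Auditory": stim.auditory_token,
        "Visual": src.visual_token,
        "Fusion": src.expected_fusion_token,
    }.get(category)
    if token is None:
        return "Other" if forced else "na"
    return _TOKEN_TO_CHOICE.get(token, token) if forced else token


def _simulate_cohort(
    config: CohortConfig,
    stimuli: Mapping[str, StimulusSpec],
    target_ids: tuple[str, ...],
    forced_choice: bool,
    completed_days: list[int] | None,
    primary_exact_split: bool,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    schedule = config.schedule
    model = config.model
    lapser = _Lapser(config.lapse_rate, rng)
    high_ab = _beta_params(*config.p_common_high)
    low_ab = _beta_params(*config.p_common_low)
    traj_names = list(config.trajectory_mixture)
    traj_probs = np.array([config.trajectory_mixture[k] for k in traj_names])

    n = config.n_participants
    # primary-stimulus classes: exact split for the main design, Bernoulli otherwise
    if primary_exact_split:
        n_fus = round(n * config.proportion_fusion_perceivers)
        primary_fusion = rng.permutation(np.array([True] * n_fus + [False] * (n - n_fus)))
    else:
        primary_fusion = rng.random(n) < config.proportion_fusion_perceivers

    # per-stimulus fixed geometry
    geo = {}
    for sid in target_ids:
        stim = stimuli[sid]
        space = model.space_for(stim)
        a, v = model.encoders_for(space)
        pooled = cm.pool_av(a, v)
        aud_id = next(s.stimulus_id for s in stimuli.values() if s.parent_id == sid)
        geo[sid] = (stim, space, a, v, pooled, aud_id)

    rows: list[tuple] = []
    truth: list[tuple] = []

    def emit(pid, phase, day, months, stim_id, categories):
        stim = stimuli[stim_id]
        parent = stimuli.get(stim.parent_id) if stim.parent_id else None
        src = parent if (stim.is_auditory_only and parent is not None) else stim
        available = ("Auditory", "Other") if src.expected_fusion_token is None else (
            "Auditory", "Visual", "Fusion", "Other"
        )
        for cat in lapser.apply(categories, available):
            raw = _raw_for(cat, stim, parent, forced_choice)
            if raw == "na":
                raw = _CONTROL_ERRORS[rng.integers(len(_CONTROL_ERRORS))]
            rows.append((pid, phase, day, months, stim_id, raw, cat))

    def controls(pid, phase, day, months):
        counts = schedule.expected_counts(phase, day)
        for stim_id, reps in counts.items():
            stim = stimuli[stim_id]
            if stim.role != "control":
                continue
            correct = rng.random(reps) < config.control_accuracy
            cats = ["Auditory" if c else "Other" for c in correct]
            emit(pid, phase, day, months, stim_id, cats)

    def aud_test(pid, phase, day, months, dists):
        counts = schedule.expected_counts(phase, day)
        for sid, (stim, space, a, v, pooled, aud_id) in geo.items():
            reps = counts.get(aud_id, 0)
            if reps == 0:
                continue
            percepts = cm.simulate_posttest(dists[sid], space, reps, rng)
            aud_stim = stimuli[aud_id]
            parent = stimuli[aud_stim.parent_id]
            cats = [_category_of(t, aud_stim, parent) for t in percepts]
            emit(pid, phase, day, months, aud_id, cats)
        controls(pid, phase, day, months)

    for i in range(n):
        pid = f"p{i + 1:03d}"
        trajectory = traj_names[rng.choice(len(traj_names), p=traj_probs)]
        days = completed_days[i] if completed_days is not None else schedule.exposure_days

        p_common: dict[str, float] = {}
        a_base: dict[str, cm.EncodingDistribution] = {}
        av: dict[str, cm.EncodingDistribution] = {}
        fusion_class: dict[str, bool] = {}
        for sid in target_ids:
            is_primary = sid == target_ids[0]
            fus = bool(primary_fusion[i]) if is_primary else bool(
                rng.random() < config.prob_fusion_class_secondary
            )
            ab = high_ab if fus else low_ab
            p = float(rng.beta(*ab))
            stim, space, a, v, pooled, aud_id = geo[sid]
            p_common[sid] = p
            fusion_class[sid] = fus
            a_base[sid] = a
            av[sid] = cm.integrate_causal(a, pooled, p, model.integration)

        # Day 1: auditory-only pre-test from the unshifted A
        aud_test(pid, "pretest", schedule.pretest_day, np.nan, a_base)

        # Days 2..: audiovisual exposure; percept statistics stay stationary
        # (the shift is expressed in the auditory-only tests)
        day1_fraction: dict[str, float] = {}
        for d_idx, day in enumerate(schedule.exposure_day_range, start=1):
            if d_idx > days:
                break
            counts = schedule.expected_counts("exposure", day)
            for sid, (stim, space, a, v, pooled, aud_id) in geo.items():
                reps = counts.get(sid, 0)
                if reps == 0:
                    continue
                percepts, _errors = cm.simulate_exposure_trials(
                    a, v, p_common[sid], space, reps, rng, model.integration
                )
                if d_idx == 1:
                    day1_fraction[sid] = float(
                        np.mean(percepts == stim.expected_fusion_token)
                    )
                cats = [_category_of(t, stim, None) for t in percepts]
                emit(pid, "exposure", day, np.nan, sid, cats)

        # error-driven recalibration keyed to the first exposure day
        shift0: dict[str, float] = {}
        a_shift: dict[str, cm.EncodingDistribution] = {}
        for sid in target_ids:
            f = day1_fraction.get(sid, 0.0)
            if trajectory == "absent":
                f *= config.absent_shift_attenuation
            shift0[sid] = f
            a_shift[sid] = cm.shift_auditory(a_base[sid], av[sid], f)

        # 24-h post-test (t = 0 months since final exposure)
        aud_test(pid, "posttest_24h", schedule.posttest_day, np.nan, a_shift)

        # monthly long-term tests
        for t in range(1, config.n_longterm_tests + 1):
            day = schedule.posttest_day + schedule.longterm_interval_days * t
            if trajectory == "decaying":
                dists = {}
                for sid in target_ids:
                    stim, space, a, v, pooled, aud_id = geo[sid]
                    if config.decay_scale == "fir":
                        fir0 = cm.posttest_fusion_probability(a_shift[sid], space)
                        target = fir0 * float(np.exp(config.decay_b_per_month * t))
                        f_t = cm.shift_fraction_for_fusion_probability(
                            a, av[sid], space, target
                        )
                    else:
                        f_t = shift0[sid] * float(np.exp(config.decay_b_per_month * t))
                    dists[sid] = cm.shift_auditory(a, av[sid], f_t)
            else:
                dists = a_shift
            aud_test(pid, "longterm", day, float(t), dists)

        for sid in target_ids:
            cls = "fusion_perceiver" if fusion_class[sid] else "auditory_perceiver"
            traj = trajectory if fusion_class[sid] else "absent"
            truth.append(
                (
                    pid,
                    sid,
                    cls,
                    p_common[sid],
                    shift0[sid],
                    traj,
                    config.decay_b_per_month if traj == "decaying" else 0.0,
                )
            )

    trials = pd.DataFrame(rows, columns=list(TRIAL_COLUMNS))
    return trials, pd.DataFrame(truth, columns=_truth_columns())


def generate_cohort(
    config: CohortConfig | None = None, seed: int | np.random.Generator = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a main-design cohort.

    Returns (trials, truth): a coded trial table in the standard layout (raw
    responses included, so the coding stage can be exercised end-to-end) and a
    ground-truth sidecar with each participant's class, common-cause probability,
    realized day-1 shift fraction and trajectory class per McGurk stimulus.
    """
    config = config or CohortConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _simulate_cohort(
        config,
        main_stimuli(),
        ("S1", "S2"),
        forced_choice=False,
        completed_days=None,
        primary_exact_split=True,
        rng=rng,
    )


def generate_replication_cohort(
    config: CohortConfig | None = None,
    seed: int | np.random.Generator = 0,
    completed_days: list[int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a forced-choice replication cohort (n = 13, stimuli S1 and S3).

    Responses are closed-list labels; during exposure one response per stimulus
    per day is recorded (participants answered only after the final repetition).
    ``completed_days`` gives each participant's number of completed exposure days
    (default: one participant at 12 days, four at 13, the rest at 14); no trials
    are emitted past a participant's last completed day.  Perceiver classes are
    drawn independently per stimulus, so a participant can fuse one pairing and
    not the other.
    """
    if config is None:
        config = CohortConfig(
            n_participants=13,
            proportion_fusion_perceivers=6 / 13,
            prob_fusion_class_secondary=10 / 13,
            schedule=replication_schedule(),
            n_longterm_tests=0,
        )
    if completed_days is None:
        n = config.n_participants
        completed_days = ([12] + [13] * 4 + [14] * max(n - 5, 0))[:n]
    if len(completed_days) != config.n_participants:
        raise ValueError("completed_days must have one entry per participant")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _simulate_cohort(
        config,
        replication_stimuli(),
        ("S1", "S3"),
        forced_choice=True,
        completed_days=list(completed_days),
        primary_exact_split=False,
        rng=rng,
    )


def generate_null_fusion_counts(
    n_participants: int = 28,
    n_trials: int = 10,
    base_rates: tuple[float, float] = (0.35, 0.15),
    participant_sd: float = 0.5,
    n_replicates: int = 1,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Binomial pre/post counts with no pre/post change in either class.

    A calibration null for the mixed model: each participant has a fusion
    probability logit(base rate of their class) + a Normal(0, participant_sd)
    random intercept, identical in the pre and post phases.  Returns a long table
    (replicate, participant, cls, time, fusion, total).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    half = n_participants // 2
    classes = ["fusion_perceiver"] * half + ["auditory_perceiver"] * (n_participants - half)
    logits = {
        "fusion_perceiver": np.log(base_rates[0] / (1 - base_rates[0])),
        "auditory_perceiver": np.log(base_rates[1] / (1 - base_rates[1])),
    }
    rows = []
    for rep in range(n_replicates):
        for i, cls in enumerate(classes):
            eta = logits[cls] + rng.normal(0.0, participant_sd)
            p = 1.0 / (1.0 + np.exp(-eta))
            for time in ("pre", "post"):
                fusion = int(rng.binomial(n_trials, p))
                rows.append((f"r{rep:03d}", f"p{i + 1:03d}", cls, time, fusion, n_trials))
    return pd.DataFrame(
        rows, columns=["replicate", "participant", "cls", "time", "fusion", "total"]
    )
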