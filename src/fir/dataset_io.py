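"""Trial-record data model, delimited-table I/O, schedule validation, exclusions.

A study is a long table of trials: one presented stimulus and the coded percept it
elicited, for one participant on one day.  The main design is an auditory-only
pre-test on Day 1, fourteen daily audiovisual McGurk exposure sessions on Days 2-15,
an auditory-only post-test on Day 16 (>= 24 h after the last exposure), and
approximately monthly auditory-only long-term tests thereafter.  Long-term timing is
expressed in months since the final audiovisual exposure, with the 24-h post-test at
t = 0.

Tables are plain CSV (UTF-8, header row, one trial per row).  Because deposited
datasets may use different column names, :func:`read_trials` accepts a column-mapping
dict instead of hard-coding the layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

CATEGORIES = ("Auditory", "Visual", "Fusion", "Other")
PHASES = ("pretest", "exposure", "posttest_24h", "longterm")
AUDITORY_ONLY_PHASES = ("pretest", "posttest_24h", "longterm")

#: Canonical column order of a trial table.
TRIAL_COLUMNS = (
    "participant_id",
    "phase",
    "day_index",
    "months_since_exposure",
    "stimulus_id",
    "raw_response",
    "coded_category",
)


class SchemaError(ValueError):
    """A required column is missing or a field violates the trial schema."""


@dataclass(frozen=True)
class StimulusSpec:
    """One stimulus token pair.

    ``visual_token`` is ``None`` for auditory-only stimuli; ``expected_fusion_token``
    is defined only for incongruent audiovisual (McGurk) stimuli.  An auditory-only
    stimulus that is the auditory component of a McGurk stimulus carries the parent's
    id in ``parent_id`` so the percept coder can use the parent's visual and fusion
    tokens (coding of auditory-only and McGurk trials is identical).
    """

    stimulus_id: str
    talker: str
    auditory_token: str
    visual_token: str | None = None
    expected_fusion_token: str | None = None
    n_syllables: int = 1
    role: str = "target"  # "target" | "control"
    parent_id: str | None = None

    def __post_init__(self) -> None:
        if self.n_syllables < 1:
            raise SchemaError("n_syllables must be a positive integer")
        if self.role not in ("target", "control"):
            raise SchemaError(f"unknown stimulus role {self.role!r}")
        if self.visual_token is None:
            if self.expected_fusion_token is not None:
                raise SchemaError(
                    "expected_fusion_token is defined only for audiovisual stimuli"
                )
        else:
            if (
                self.expected_fusion_token is not None
                and self.visual_token == self.auditory_token
            ):
                raise SchemaError(
                    "congruent audiovisual stimuli have no expected fusion token"
                )

    @property
    def is_auditory_only(self) -> bool:
        return self.visual_token is None


@dataclass(frozen=True)
class TrialRecord:
    participant_id: str
    phase: str
    day_index: int
    stimulus_id: str
    months_since_exposure: float | None = None
    raw_response: str | None = None
    coded_category: str | None = None

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise SchemaError(f"unknown phase {self.phase!r}")
        if self.day_index < 1:
            raise SchemaError("day_index is 1-based")
        if self.coded_category is not None and self.coded_category not in CATEGORIES:
            raise SchemaError(f"unknown coded_category {self.coded_category!r}")
        if self.phase == "longterm" and self.months_since_exposure is None:
            raise SchemaError("longterm trials need months_since_exposure")


@dataclass(frozen=True)
class ScheduleSpec:
    """Expected repetition counts per phase.

    Each phase maps ``stimulus_id -> repetitions`` per administration of that phase
    (the pre-test happens once; each exposure day and each long-term test uses its
    phase's counts).  ``exposure_overrides`` maps an absolute ``day_index`` to
    replacement counts for specific stimuli on that day — the main experiment
    presented only nine repetitions of its second McGurk stimulus on Days 8-13.
    """

    pretest: Mapping[str, int]
    exposure: Mapping[str, int]
    posttest: Mapping[str, int]
    longterm: Mapping[str, int]
    exposure_overrides: Mapping[int, Mapping[str, int]] = field(default_factory=dict)
    exposure_days: int = 14
    longterm_interval_days: int = 30

    @property
    def pretest_day(self) -> int:
        return 1

    @property
    def exposure_day_range(self) -> range:
        return range(2, 2 + self.exposure_days)

    @property
    def posttest_day(self) -> int:
        return 2 + self.exposure_days

    def expected_counts(self, phase: str, day_index: int) -> dict[str, int]:
        """Expected (stimulus -> repetitions) for one phase administration."""
        if phase == "pretest":
            return dict(self.pretest)
        if phase == "posttest_24h":
            return dict(self.posttest)
        if phase == "longterm":
            return dict(self.longterm)
        if phase == "exposure":
            counts = dict(self.exposure)
            counts.update(self.exposure_overrides.get(day_index, {}))
            return counts
        raise SchemaError(f"unknown phase {phase!r}")


def _control_specs(n: int = 25) -> list[StimulusSpec]:
    # 25 control syllables from talkers other than the McGurk talkers: 13 ba,
    # 2 baba, 5 da, 5 ga.
    tokens = ["ba"] * 13 + ["baba"] * 2 + ["da"] * 5 + ["ga"] * 5
    return [
        StimulusSpec(
            stimulus_id=f"ctrl_{i + 1:02d}",
            talker=f"control_talker_{i + 1:02d}",
            auditory_token=tok,
            n_syllables=2 if tok == "baba" else 1,
            role="control",
        )
        for i, tok in enumerate(tokens[:n])
    ]


def main_stimuli() -> dict[str, StimulusSpec]:
    """Stimulus registry for the main experiment.

    S1: talker AM's auditory *baba* + visual *gaga*, expected fusion *dada*.
    S2: talker AN's auditory *ba* + visual *ga*, expected fusion *da*.
    Plus the auditory-only components and 25 control syllables.
    """
    specs = [
        StimulusSpec("S1", "AM", "baba", "gaga", "dada", n_syllables=2),
        StimulusSpec("S2", "AN", "ba", "ga", "da"),
        StimulusSpec("S1_Aud", "AM", "baba", n_syllables=2, parent_id="S1"),
        StimulusSpec("S2_Aud", "AN", "ba", parent_id="S2"),
    ]
    specs.extend(_control_specs())
    return {s.stimulus_id: s for s in specs}


def replication_stimuli() -> dict[str, StimulusSpec]:
    """Stimulus registry for the forced-choice replication experiment.

    S1 as in the main experiment; S3: talker AN's auditory *pa* + visual *ka*,
    expected fusion *ta*; four control stimuli (two *baba*, two *pa* talkers).
    """
    specs = [
        StimulusSpec("S1", "AM", "baba", "gaga", "dada", n_syllables=2),
        StimulusSpec("S3", "AN", "pa", "ka", "ta"),
        StimulusSpec("S1_Aud", "AM", "baba", n_syllables=2, parent_id="S1"),
        StimulusSpec("S3_Aud", "AN", "pa", parent_id="S3"),
        StimulusSpec("ctrl_baba_1", "control_talker_m1", "baba", n_syllables=2, role="control"),
        StimulusSpec("ctrl_baba_2", "control_talker_m2", "baba", n_syllables=2, role="control"),
        StimulusSpec("ctrl_pa_1", "control_talker_f1", "pa", role="control"),
        StimulusSpec("ctrl_pa_2", "control_talker_f2", "pa", role="control"),
    ]
    return {s.stimulus_id: s for s in specs}


def main_schedule() -> ScheduleSpec:
    """The main-experiment schedule.

    Pre-test (Day 1): 5 reps S1_Aud + 10 reps S2_Aud + 25 controls (one rep each).
    Exposure (Days 2-15): 5 reps S1 + 10 reps S2, except 9 reps S2 on Days 8-13.
    Post-test (Day 16) and monthly long-term tests: same stimuli as the pre-test.
    """
    aud = {"S1_Aud": 5, "S2_Aud": 10}
    aud.update({f"ctrl_{i:02d}": 1 for i in range(1, 26)})
    return ScheduleSpec(
        pretest=aud,
        exposure={"S1": 5, "S2": 10},
        posttest=dict(aud),
        longterm=dict(aud),
        exposure_overrides={d: {"S2": 9} for d in range(8, 14)},
    )


def replication_schedule() -> ScheduleSpec:
    """Replication schedule: 10+10 target reps and 20 control trials per test.

    During exposure, participants responded only after the final repetition of each
    audiovisual stimulus, so exactly one response per stimulus per exposure day is
    expected in the trial table.
    """
    aud = {
        "S1_Aud": 10,
        "S3_Aud": 10,
        "ctrl_baba_1": 5,
        "ctrl_baba_2": 5,
        "ctrl_pa_1": 5,
        "ctrl_pa_2": 5,
    }
    return ScheduleSpec(
        pretest=aud,
        exposure={"S1": 1, "S3": 1},
        posttest=dict(aud),
        longterm=dict(aud),
    )


# ---------------------------------------------------------------------------
# table I/O


def trials_to_frame(trials: Iterable[TrialRecord]) -> pd.DataFrame:
    rows = [
        (
            t.participant_id,
            t.phase,
            t.day_index,
            np.nan if t.months_since_exposure is None else t.months_since_exposure,
            t.stimulus_id,
            "" if t.raw_response is None else t.raw_response,
            "" if t.coded_category is None else t.coded_category,
        )
        for t in trials
    ]
    return pd.DataFrame(rows, columns=list(TRIAL_COLUMNS))


def frame_to_trials(frame: pd.DataFrame) -> list[TrialRecord]:
    out = []
    for row in frame.itertuples(index=False):
        months = getattr(row, "months_since_exposure")
        out.append(
            TrialRecord(
                participant_id=str(row.participant_id),
                phase=row.phase,
                day_index=int(row.day_index),
                months_since_exposure=None if pd.isna(months) else float(months),
                stimulus_id=str(row.stimulus_id),
                raw_response=row.raw_response or None,
                coded_category=row.coded_category or None,
            )
        )
    return out


def validate_trials(frame: pd.DataFrame) -> pd.DataFrame:
    """Validate phases/categories of a trial table in place; return the table.

    Raises :class:`SchemaError` naming the first offending row.
    """
    bad_phase = ~frame["phase"].isin(PHASES)
    if bad_phase.any():
        i = int(np.flatnonzero(bad_phase.to_numpy())[0])
        raise SchemaError(f"row {i}: unknown phase {frame['phase'].iloc[i]!r}")
    coded = frame["coded_category"].fillna("")
    bad_cat = ~coded.isin(CATEGORIES + ("",))
    if bad_cat.any():
        i = int(np.flatnonzero(bad_cat.to_numpy())[0])
        raise SchemaError(
            f"row {i}: unknown coded_category {frame['coded_category'].iloc[i]!r}"
        )
    lt = frame["phase"] == "longterm"
    if lt.any() and frame.loc[lt, "months_since_exposure"].isna().any():
        i = int(frame.index[lt & frame["months_since_exposure"].isna()][0])
        raise SchemaError(f"row {i}: longterm trial without months_since_exposure")
    return frame


def read_trials(
    path,
    column_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a CSV trial table into the canonical column layout.

    Parameters
    ----------
    path
        CSV file with a header row.
    column_map
        Optional mapping ``canonical_name -> column_name_in_file`` for deposits
        that use a different layout.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if column_map:
        rename = {v: k for k, v in column_map.items()}
        raw = raw.rename(columns=rename)
    missing = [c for c in TRIAL_COLUMNS if c not in raw.columns and c != "months_since_exposure"]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if "months_since_exposure" not in raw.columns:
        raw["months_since_exposure"] = ""
    frame = raw.loc[:, list(TRIAL_COLUMNS)].copy()
    frame["day_index"] = frame["day_index"].astype(int)
    months = frame["months_since_exposure"].map(lambda v: np.nan if v == "" else v)
    frame["months_since_exposure"] = months.astype(float)
    return validate_trials(frame)


def write_trials(frame: pd.DataFrame, path) -> None:
    """Write a trial table as CSV (inverse of :func:`read_trials`)."""
    out = frame.loc[:, list(TRIAL_COLUMNS)]
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# schedule validation and exclusions


def validate_schedule(frame: pd.DataFrame, schedule: ScheduleSpec) -> pd.DataFrame:
    """Report every (participant, day, stimulus) repetition count deviating from
    the schedule.

    Pure report: the returned table has columns participant_id, phase, day_index,
    stimulus_id, expected, observed and is empty iff the table conforms.  Stimuli
    scheduled but absent on a day a participant was tested are reported with
    observed = 0; long-term tests are validated per administered day.
    """
    deviations = []
    obs = (
        frame.groupby(["participant_id", "phase", "day_index", "stimulus_id"])
        .size()
        .to_dict()
    )
    days = frame[["participant_id", "phase", "day_index"]].drop_duplicates()
    for row in days.itertuples(index=False):
        expected = schedule.expected_counts(row.phase, int(row.day_index))
        seen_stims = set(
            frame.loc[
                (frame["participant_id"] == row.participant_id)
                & (frame["day_index"] == row.day_index)
                & (frame["phase"] == row.phase),
                "stimulus_id",
            ]
        )
        for stim in sorted(set(expected) | seen_stims):
            want = expected.get(stim, 0)
            got = obs.get((row.participant_id, row.phase, row.day_index, stim), 0)
            if want != got:
                deviations.append(
                    (row.participant_id, row.phase, int(row.day_index), stim, want, got)
                )
    return pd.DataFrame(
        deviations,
        columns=["participant_id", "phase", "day_index", "stimulus_id", "expected", "observed"],
    )


def exclude_low_performers(
    frame: pd.DataFrame,
    stimuli: Mapping[str, StimulusSpec],
    control_accuracy_threshold: float = 0.80,
) -> tuple[list[str], pd.DataFrame]:
    """Split participants on pre-test control accuracy.

    A control response is correct when it was coded *Auditory* (the response onset
    matched the spoken control token).  Participants with accuracy below the
    threshold are excluded.  Returns (kept participant ids, exclusion table with
    per-participant accuracies and an ``excluded`` flag).
    """
    control_ids = {s.stimulus_id for s in stimuli.values() if s.role == "control"}
    ctrl = frame[(frame["phase"] == "pretest") & frame["stimulus_id"].isin(control_ids)]
    all_participants = frame["participant_id"].unique()
    missing = set(all_participants) - set(ctrl["participant_id"].unique())
    if missing:
        raise ValueError(
            f"participant(s) with zero pre-test control trials: {sorted(missing)}"
        )
    acc = (
        (ctrl["coded_category"] == "Auditory")
        .groupby(ctrl["participant_id"])
        .mean()
        .rename("control_accuracy")
        .reset_index()
    )
    acc["excluded"] = acc["control_accuracy"] < control_accuracy_threshold
    kept = sorted(acc.loc[~acc["excluded"], "participant_id"])
    return kept, acc
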