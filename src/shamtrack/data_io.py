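"""Tabular layout of a blinding study and serialisation of pipeline results.

A study directory holds three UTF-8, RFC-4180 CSV files:

``probes.csv``
    One row per probe slot: ``participant_id, current_mA, condition,
    session_order, probe_index, probe_time_s, response, confidence``.
    ``response`` is ``yes``/``no``/``missing`` (the 4,500 ms response window
    can lapse); ``confidence`` is a 0-10 rating, empty when missing.
``trials.csv``
    One row per reaction-time trial: ``participant_id, current_mA,
    condition, session_order, block, trial_index, correct, rt_ms``.
    Block 1 is the 100-trial pre-stimulation baseline; blocks 2-4 span the
    stimulation window.
``participants.csv``
    One row per participant-session: side-effect ratings (1-5 for headache,
    tingling, itching, burning and pain) and the participant's single
    end-of-study guess (``guess_correct``), repeated on both session rows.

This layout emulates the structure an online-probe blinding study deposits;
mapping a concrete deposit's native files onto it is the job of a thin,
study-specific adapter (see :func:`read_study` notes).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SIDE_EFFECTS",
    "ParticipantSession",
    "ParticipantRecord",
    "StudyValidationError",
    "read_study",
    "write_study",
    "write_results",
]

SIDE_EFFECTS = ("headache", "tingling", "itching", "burning", "pain")
CONDITIONS = ("active", "sham")
N_PROBES = 32
N_BASELINE_TRIALS = 100

PROBE_COLUMNS = [
    "participant_id", "current_mA", "condition", "session_order",
    "probe_index", "probe_time_s", "response", "confidence",
]
TRIAL_COLUMNS = [
    "participant_id", "current_mA", "condition", "session_order",
    "block", "trial_index", "correct", "rt_ms",
]
PARTICIPANT_COLUMNS = [
    "participant_id", "current_mA", "condition", "session_order",
    *SIDE_EFFECTS, "guess_correct",
]


class StudyValidationError(ValueError):
    """Raised when study files violate the documented schema.

    ``problems`` lists human-readable messages, each naming the offending
    file and row (1-based, header excluded).
    """

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        preview = "\n  ".join(self.problems[:20])
        more = "" if len(self.problems) <= 20 else f"\n  ... {len(self.problems) - 20} more"
        super().__init__(f"{len(self.problems)} validation problem(s):\n  {preview}{more}")


@dataclass
class ParticipantSession:
    """One participant's single stimulation session.

    ``responses`` holds the 32 probe answers as strings (``yes``/``no``/
    ``missing``); ``confidence`` the matching 0-10 ratings with NaN at
    missing slots.  ``rt_trials`` is a DataFrame with columns
    ``block, trial_index, correct, rt_ms``.
    """

    participant_id: str
    current_mA: float
    condition: str
    session_order: int
    responses: np.ndarray
    confidence: np.ndarray
    rt_trials: pd.DataFrame
    side_effects: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=object)
        self.confidence = np.asarray(self.confidence, dtype=float)
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if len(self.responses) != N_PROBES or len(self.confidence) != N_PROBES:
            raise ValueError(f"expected exactly {N_PROBES} probe slots")
        valid = self.confidence[~np.isnan(self.confidence)]
        if valid.size and (valid.min() < 0 or valid.max() > 10):
            raise ValueError("confidence ratings must lie in [0, 10]")
        for name, rating in self.side_effects.items():
            if name not in SIDE_EFFECTS:
                raise ValueError(f"unknown side effect {name!r}")
            if not 1 <= rating <= 5:
                raise ValueError(f"{name} rating {rating} outside [1, 5]")


@dataclass
class ParticipantRecord:
    """Both sessions of one participant plus the end-of-study guess."""

    participant_id: str
    sessions: dict[str, ParticipantSession]
    guess_correct: bool

    def __post_init__(self) -> None:
        if set(self.sessions) != set(CONDITIONS):
            raise ValueError("record needs exactly one active and one sham session")

    @property
    def current_mA(self) -> float:
        return self.sessions["active"].current_mA

    @property
    def active(self) -> ParticipantSession:
        return self.sessions["active"]

    @property
    def sham(self) -> ParticipantSession:
        return self.sessions["sham"]


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _require_files(path: Path, names: Iterable[str]) -> None:
    missing = [n for n in names if not (path / n).is_file()]
    if missing:
        raise FileNotFoundError(
            f"study directory {path} is missing {', '.join(missing)}"
        )


def _validate_probes(df: pd.DataFrame, problems: list[str]) -> None:
    for i, row in enumerate(df.itertuples(index=False), start=1):
        if row.response not in ("yes", "no", "missing"):
            problems.append(f"probes.csv row {i}: bad response {row.response!r}")
        if row.response == "missing":
            if not np.isnan(row.confidence):
                problems.append(
                    f"probes.csv row {i}: confidence given for a missing response"
                )
        elif np.isnan(row.confidence) or not 0 <= row.confidence <= 10:
            problems.append(
                f"probes.csv row {i}: confidence {row.confidence} outside [0, 10]"
            )


def _validate_participants(df: pd.DataFrame, problems: list[str]) -> None:
    for i, row in enumerate(df.itertuples(index=False), start=1):
        for eff in SIDE_EFFECTS:
            rating = getattr(row, eff)
            if not (float(rating).is_integer() and 1 <= rating <= 5):
                problems.append(
                    f"participants.csv row {i}: {eff} rating {rating} outside [1, 5]"
                )


def read_study(path: str | Path) -> list[ParticipantRecord]:
    """Read and validate a study directory into participant records.

    Raises :class:`FileNotFoundError` if a required CSV is absent and
    :class:`StudyValidationError` (listing file and row of every offence)
    if any value violates the schema.  Row counts are conserved: every
    probe and trial row ends up in exactly one session.
    """
    path = Path(path)
    _require_files(path, ("probes.csv", "trials.csv", "participants.csv"))
    read = lambda name: pd.read_csv(
        path / name, dtype={"participant_id": str}, float_precision="round_trip"
    )
    probes = read("probes.csv")
    trials = read("trials.csv")
    participants = read("participants.csv")

    problems: list[str] = []
    _validate_probes(probes, problems)
    _validate_participants(participants, problems)
    if problems:
        # field-level violations: report them all before attempting assembly
        raise StudyValidationError(problems)

    records: list[ParticipantRecord] = []
    probe_groups = dict(iter(probes.groupby(["participant_id", "condition"], sort=False)))
    trial_groups = dict(iter(trials.groupby(["participant_id", "condition"], sort=False)))

    for pid, prows in participants.groupby("participant_id", sort=False):
        sessions: dict[str, ParticipantSession] = {}
        for row in prows.itertuples(index=False):
            key = (pid, row.condition)
            pgroup = probe_groups.get(key)
            if pgroup is None or len(pgroup) != N_PROBES:
                n = 0 if pgroup is None else len(pgroup)
                problems.append(
                    f"probes.csv: participant {pid} {row.condition} has {n} probe rows"
                    f" (expected {N_PROBES})"
                )
                continue
            pgroup = pgroup.sort_values("probe_index")
            tgroup = trial_groups.get(key, trials.iloc[0:0])
            n_baseline = int((tgroup["block"] == 1).sum())
            if n_baseline != N_BASELINE_TRIALS:
                problems.append(
                    f"trials.csv: participant {pid} {row.condition} block 1 has"
                    f" {n_baseline} trials (expected {N_BASELINE_TRIALS})"
                )
            rt = (
                tgroup[["block", "trial_index", "correct", "rt_ms"]]
                .sort_values(["block", "trial_index"])
                .reset_index(drop=True)
            )
            sessions[row.condition] = ParticipantSession(
                participant_id=pid,
                current_mA=float(row.current_mA),
                condition=row.condition,
                session_order=int(row.session_order),
                responses=pgroup["response"].to_numpy(dtype=object),
                confidence=pgroup["confidence"].to_numpy(dtype=float),
                rt_trials=rt,
                side_effects={eff: int(getattr(row, eff)) for eff in SIDE_EFFECTS},
            )
        guesses = set(prows["guess_correct"].astype(bool))
        if len(guesses) != 1:
            problems.append(
                f"participants.csv: participant {pid} has inconsistent guess_correct"
            )
        if set(sessions) != set(CONDITIONS):
            problems.append(
                f"participants.csv: participant {pid} lacks one of {CONDITIONS}"
            )
            continue
        records.append(
            ParticipantRecord(
                participant_id=pid,
                sessions=sessions,
                guess_correct=bool(prows["guess_correct"].iloc[0]),
            )
        )
    if problems:
        raise StudyValidationError(problems)
    return records


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _session_sort_key(rec: ParticipantRecord, cond: str) -> ParticipantSession:
    return rec.sessions[cond]


def write_study(records: Sequence[ParticipantRecord], path: str | Path) -> None:
    """Write records back to the three-CSV study layout (inverse of read)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    probe_rows, trial_rows, part_rows = [], [], []
    for rec in records:
        for cond in CONDITIONS:
            s = rec.sessions[cond]
            for k in range(N_PROBES):
                probe_rows.append(
                    (s.participant_id, s.current_mA, cond, s.session_order,
                     k + 1, 30.0 * (k + 1), s.responses[k], s.confidence[k])
                )
            for t in s.rt_trials.itertuples(index=False):
                trial_rows.append(
                    (s.participant_id, s.current_mA, cond, s.session_order,
                     int(t.block), int(t.trial_index), int(t.correct), float(t.rt_ms))
                )
            part_rows.append(
                (s.participant_id, s.current_mA, cond, s.session_order,
                 *(s.side_effects[eff] for eff in SIDE_EFFECTS),
                 int(rec.guess_correct))
            )
    pd.DataFrame(probe_rows, columns=PROBE_COLUMNS).to_csv(
        path / "probes.csv", index=False
    )
    pd.DataFrame(trial_rows, columns=TRIAL_COLUMNS).to_csv(
        path / "trials.csv", index=False
    )
    pd.DataFrame(part_rows, columns=PARTICIPANT_COLUMNS).to_csv(
        path / "participants.csv", index=False
    )


def sessions_equal(a: ParticipantSession, b: ParticipantSession) -> bool:
    """Value equality, treating NaN confidence as equal to NaN."""
    return (
        a.participant_id == b.participant_id
        and a.current_mA == b.current_mA
        and a.condition == b.condition
        and a.session_order == b.session_order
        and list(a.responses) == list(b.responses)
        and np.array_equal(a.confidence, b.confidence, equal_nan=True)
        and a.side_effects == b.side_effects
        and a.rt_trials.reset_index(drop=True).equals(b.rt_trials.reset_index(drop=True))
    )


def records_equal(a: ParticipantRecord, b: ParticipantRecord) -> bool:
    return (
        a.participant_id == b.participant_id
        and a.guess_correct == b.guess_correct
        and all(sessions_equal(a.sessions[c], b.sessions[c]) for c in CONDITIONS)
    )


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

GROUP_CURVE_COLUMNS = [
    "current_mA", "condition", "probe_index", "probe_time_s",
    "median", "ci_low", "ci_high", "n_available",
]
SENSITIVITY_COLUMNS = [
    "participant_id", "current_mA", "condition", "reference",
    "peak_r", "peak_lag", "n_interpolated",
]
CLASSIFIER_COLUMNS = [
    "classifier", "condition", "auc", "ci_low", "ci_high",
    "p_value", "n_pos", "n_neg",
]


def write_results(results, path: str | Path) -> None:
    """Serialise a :class:`~shamtrack.pipeline.StudyResults` bundle.

    Emits ``sensitivity.csv``, ``group_curves.csv``, ``classifiers.csv``
    and ``stats.json`` with deterministic column order; re-reading the CSVs
    reproduces the in-memory values to full precision (floats are written
    with shortest-round-trip repr).
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    sens = results.sensitivity
    if len(sens) == 0:
        sens = pd.DataFrame(columns=SENSITIVITY_COLUMNS)
    sens[SENSITIVITY_COLUMNS].to_csv(path / "sensitivity.csv", index=False)

    curve_rows = []
    for (strength, cond), curve in sorted(results.group_curves.items()):
        for k in range(len(curve.median)):
            curve_rows.append(
                (strength, cond, k + 1, curve.probe_times_s[k], curve.median[k],
                 curve.ci_low[k], curve.ci_high[k], int(curve.n_available[k]))
            )
    pd.DataFrame(curve_rows, columns=GROUP_CURVE_COLUMNS).to_csv(
        path / "group_curves.csv", index=False
    )

    cls_rows = [
        (ev.classifier, ev.condition, ev.auc, ev.ci_low, ev.ci_high,
         ev.p_value, ev.n_pos, ev.n_neg)
        for ev in results.classifier_evals
    ]
    pd.DataFrame(cls_rows, columns=CLASSIFIER_COLUMNS).to_csv(
        path / "classifiers.csv", index=False
    )

    with open(path / "stats.json", "w") as fh:
        json.dump(
            {name: res.to_dict() for name, res in results.stats.items()},
            fh, indent=2, sort_keys=True,
        )
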