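"""Weighted perception scores and bootstrapped group confidence bands.

Each probe answer is collapsed into a single *weighted score*: the yes/no
response contributes a sign (+1 for "on", -1 for "off") which is multiplied
by the 0-10 confidence rating, giving a value from +10 (high confidence the
stimulation is on) to -10 (high confidence it is off).

At the group level, the per-probe median weighted score is plotted with a
95% bootstrap confidence band (participants resampled with replacement,
5,000 resamples, percentile interval).  Probes where the active and sham
bands do not overlap mark time points at which blinding demonstrably
failed.  No multiplicity correction is applied across the 32 per-probe
comparisons; the band comparison is descriptive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data_io import ParticipantSession

__all__ = [
    "ProbeSeries",
    "GroupCurve",
    "weighted_score",
    "probe_series_from_session",
    "bootstrap_group_curve",
    "nonoverlap_probes",
]


@dataclass
class ProbeSeries:
    """One session's 32 weighted scores over time (NaN where missing)."""

    values: np.ndarray
    participant_id: str
    condition: str
    current_mA: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        finite = self.values[~np.isnan(self.values)]
        if finite.size and np.max(np.abs(finite)) > 10:
            raise ValueError("weighted scores must lie in [-10, 10]")


@dataclass
class GroupCurve:
    """Per-probe median weighted score with a bootstrap confidence band."""

    probe_times_s: np.ndarray
    median: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_available: np.ndarray  # non-missing scores contributing per probe
    condition: str
    n_participants: int
    n_boot: int
    seed: int | None
    level: float = 0.95

    @property
    def all_missing(self) -> np.ndarray:
        """Probes where no participant contributed a score (flagged NaN)."""
        return self.n_available == 0


def weighted_score(response: str, confidence: float) -> float:
    """Signed perception score: +confidence for "yes", -confidence for "no"."""
    if not 0 <= confidence <= 10:
        raise ValueError(f"confidence {confidence} outside [0, 10]")
    if response == "yes":
        return float(confidence)
    if response == "no":
        return -float(confidence)
    raise ValueError(f"response must be 'yes' or 'no', got {response!r}")


def probe_series_from_session(session: ParticipantSession) -> ProbeSeries:
    """Weighted-score series of one session; missing probes become NaN."""
    values = np.full(len(session.responses), np.nan)
    for k, (resp, conf) in enumerate(zip(session.responses, session.confidence)):
        if resp != "missing":
            values[k] = weighted_score(resp, conf)
    return ProbeSeries(
        values=values,
        participant_id=session.participant_id,
        condition=session.condition,
        current_mA=session.current_mA,
    )


def bootstrap_group_curve(
    series: list[ProbeSeries],
    n_boot: int = 5000,
    level: float = 0.95,
    seed: int | None = None,
    probe_times_s: np.ndarray | None = None,
) -> GroupCurve:
    """Median weighted score per probe with a percentile bootstrap band.

    Participants are resampled with replacement ``n_boot`` times; each
    resample's per-probe median is taken over the available (non-missing)
    scores, and the band is the (2.5th, 97.5th) percentile interval at the
    default 95% level.  The reported point estimate is the observed
    (non-bootstrap) median.  Probes at which every score is missing are
    flagged through ``n_available == 0`` (NaN estimates), never silently
    zeroed.
    """
    if len(series) < 2:
        if len(series) == 1:
            # Degenerate single-participant "group": band collapses onto
            # that participant's own values.
            v = series[0].values
            return GroupCurve(
                probe_times_s=_times(v.size, probe_times_s),
                median=v.copy(), ci_low=v.copy(), ci_high=v.copy(),
                n_available=(~np.isnan(v)).astype(int),
                condition=series[0].condition, n_participants=1,
                n_boot=n_boot, seed=seed, level=level,
            )
        raise ValueError("bootstrap_group_curve needs at least one series")
    conditions = {s.condition for s in series}
    if len(conditions) != 1:
        raise ValueError(f"all series must share one condition, got {conditions}")
    values = np.vstack([s.values for s in series])  # (n_participants, n_probes)
    n, n_probes = values.shape
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    with warnings.catch_warnings():
        # all-NaN probes are legitimate here; they are flagged below
        warnings.simplefilter("ignore", category=RuntimeWarning)
        boot_medians = np.nanmedian(values[idx], axis=1)  # (n_boot, n_probes)
        observed = np.nanmedian(values, axis=0)
        alpha = 100 * (1 - level) / 2
        lo = np.nanpercentile(boot_medians, alpha, axis=0)
        hi = np.nanpercentile(boot_medians, 100 - alpha, axis=0)
    n_available = (~np.isnan(values)).sum(axis=0)
    empty = n_available == 0
    observed[empty] = np.nan
    lo[empty] = np.nan
    hi[empty] = np.nan
    return GroupCurve(
        probe_times_s=_times(n_probes, probe_times_s),
        median=observed, ci_low=lo, ci_high=hi,
        n_available=n_available, condition=conditions.pop(),
        n_participants=n, n_boot=n_boot, seed=seed, level=level,
    )


def _times(n_probes: int, probe_times_s: np.ndarray | None) -> np.ndarray:
    if probe_times_s is not None:
        return np.asarray(probe_times_s, dtype=float)
    return 30.0 * np.arange(1, n_probes + 1)


def nonoverlap_probes(a: GroupCurve, b: GroupCurve) -> np.ndarray:
    """Indices (0-based) of probes whose confidence bands do not overlap.

    Intervals are closed: bands that merely touch count as overlapping,
    which is conservative when claiming a blinding failure.  Symmetric in
    its arguments.
    """
    if not np.array_equal(a.probe_times_s, b.probe_times_s):
        raise ValueError("curves are on different probe schedules")
    with np.errstate(invalid="ignore"):
        apart = (a.ci_low > b.ci_high) | (b.ci_low > a.ci_high)
    return np.flatnonzero(apart)
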