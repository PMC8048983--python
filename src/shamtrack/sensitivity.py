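"""Cross-correlation sensitivity: how well a participant tracks stimulation.

A participant's weighted-score series is compared with the *ideal response
curve* of a protocol by normalised lagged cross-correlation: both series
are linearly detrended, then the coefficient at lag m is

    r(m) = sum_n x(n) * y(n + m) / sqrt(sum x^2 * sum y^2),

computed over the zero-padded overlap (the MATLAB ``xcorr`` "coeff"
normalisation: one global normaliser, no per-lag re-centering).  Positive
lags mean the response series lags behind the ideal.  The signed maximum
over lags -31..+31 is the participant's *sensitivity* to that protocol;
large coefficients mean the participant tracked the on/off time course
closely, values near the chance level mean they could not.

Sliding over lags absorbs reporting delay; because the maximum is taken
over 63 lags, even pure noise yields a positive expected peak, so peak
coefficients are compared between conditions (congruent vs. incongruent
ideal, 1 vs. 2 mA, ...) rather than against zero.

A 32-sample series admits lags -31..+31; lags of +/-32 would have zero
overlap and coefficient 0 by construction, so the lag range is capped at
``n - 1``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.signal

from .data_io import ParticipantRecord
from .protocol import IdealCurve, ProtocolSpec, build_ideal_curve
from .scores import ProbeSeries, probe_series_from_session

__all__ = [
    "SensitivityResult",
    "detrend",
    "xcorr_coeff",
    "interpolate_missing",
    "peak_sensitivity",
    "sensitivity_table",
]


@dataclass
class SensitivityResult:
    """Peak lagged cross-correlation for one (session, reference) pair."""

    participant_id: str
    condition: str
    reference: str  # "congruent" or "incongruent"
    peak_r: float
    peak_lag: int
    lags: np.ndarray
    full_r_by_lag: np.ndarray
    n_interpolated: int = 0
    current_mA: float = float("nan")


def detrend(series: np.ndarray) -> np.ndarray:
    """Subtract the least-squares straight line from a series.

    The residual is orthogonal to both the constant and the linear ramp.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1 or series.size < 2:
        raise ValueError("detrend needs a 1-d series of length >= 2")
    if np.isnan(series).any():
        raise ValueError("detrend cannot handle missing values")
    return scipy.signal.detrend(series, type="linear")


def xcorr_coeff(x: np.ndarray, y: np.ndarray, max_lag: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Normalised cross-correlation of two equal-length series.

    Returns ``(lags, r)`` for lags ``-max_lag..+max_lag`` where
    ``r[m] = sum_n x[n] y[n+m] / sqrt(sum x^2 sum y^2)`` over the
    zero-padded overlap.  A positive lag shifts ``y`` earlier, i.e. ``y``
    resembles ``x`` delayed.  Coefficients at extreme lags shrink toward 0
    because the overlap shrinks while the normaliser is global.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    n = x.size
    if max_lag is None:
        max_lag = n - 1
    if not 0 <= max_lag <= n - 1:
        raise ValueError(f"max_lag must lie in [0, {n - 1}]")
    denom = np.sqrt(np.dot(x, x) * np.dot(y, y))
    if denom == 0:
        raise ValueError("cross-correlation undefined: a series is all zero")
    # full[k] = sum_j x[j] y[j + (n-1-k)]  =>  r(m) = full[n-1-m]
    full = np.correlate(x, y, mode="full")
    lags = np.arange(-max_lag, max_lag + 1)
    r = full[n - 1 - lags] / denom
    return lags, r


def interpolate_missing(values: np.ndarray) -> tuple[np.ndarray, int]:
    """Fill NaN probes by linear interpolation from their neighbours.

    End gaps take the nearest valid value.  Returns the completed vector
    and the number of interpolated points.  Interpolation is the least
    structured completion compatible with the cross-correlation's need for
    complete vectors; the count is surfaced so heavily-lapsed series can
    be audited.
    """
    values = np.asarray(values, dtype=float)
    missing = np.isnan(values)
    n_missing = int(missing.sum())
    if n_missing == 0:
        return values.copy(), 0
    if n_missing == values.size:
        raise ValueError("cannot interpolate a fully missing series")
    idx = np.arange(values.size)
    filled = values.copy()
    filled[missing] = np.interp(idx[missing], idx[~missing], values[~missing])
    return filled, n_missing


def _peak_index(lags: np.ndarray, r: np.ndarray) -> int:
    """Index of the signed maximum; ties go to the smallest |lag|, then the
    negative lag."""
    candidates = np.flatnonzero(r == np.max(r))
    keys = sorted(candidates, key=lambda i: (abs(int(lags[i])), int(lags[i])))
    return int(keys[0])


def peak_sensitivity(
    response: ProbeSeries | np.ndarray,
    ideal: IdealCurve,
    max_lag: int = 31,
    reference: str = "congruent",
    per_lag_pearson: bool = False,
) -> SensitivityResult:
    """Peak cross-correlation between a response series and an ideal curve.

    Both series are detrended before correlating; missing responses are
    linearly interpolated first.  The signed maximum coefficient and its
    lag are returned (positive lag = participant lags the ideal).

    ``per_lag_pearson=True`` switches to a sensitivity-analysis variant
    that computes a true Pearson correlation over the overlapping samples
    at each lag (re-centred and re-normalised per lag) instead of the
    global-normaliser ``xcorr``/"coeff" semantics used by default.
    """
    if isinstance(response, ProbeSeries):
        values = response.values
        pid, cond, mA = response.participant_id, response.condition, response.current_mA
    else:
        values = np.asarray(response, dtype=float)
        pid, cond, mA = "", "", float("nan")
    if values.size != ideal.values.size:
        raise ValueError("response and ideal are on different probe schedules")
    filled, n_interp = interpolate_missing(values)
    x = detrend(ideal.values.astype(float))
    y = detrend(filled)
    if per_lag_pearson:
        lags, r = _per_lag_pearson(x, y, max_lag)
    else:
        lags, r = xcorr_coeff(x, y, max_lag)
    i = _peak_index(lags, r)
    return SensitivityResult(
        participant_id=pid, condition=cond, reference=reference,
        peak_r=float(r[i]), peak_lag=int(lags[i]),
        lags=lags, full_r_by_lag=r, n_interpolated=n_interp, current_mA=mA,
    )


def _per_lag_pearson(x: np.ndarray, y: np.ndarray, max_lag: int) -> tuple[np.ndarray, np.ndarray]:
    n = x.size
    lags = np.arange(-max_lag, max_lag + 1)
    r = np.zeros(lags.size)
    for i, m in enumerate(lags):
        if m >= 0:
            a, b = x[: n - m], y[m:]
        else:
            a, b = x[-m:], y[: n + m]
        if a.size < 3 or np.std(a) == 0 or np.std(b) == 0:
            r[i] = 0.0
            continue
        r[i] = float(np.corrcoef(a, b)[0, 1])
    return lags, r


def sensitivity_table(
    records: list[ParticipantRecord],
    protocols: dict[float, tuple[ProtocolSpec, ProtocolSpec]],
    max_lag: int = 31,
    per_lag_pearson: bool = False,
) -> pd.DataFrame:
    """Congruent and incongruent peak coefficients for every session.

    ``protocols`` maps current strength (mA) to its (active, sham)
    protocol pair.  Each session contributes two rows: one against its own
    condition's ideal curve (*congruent*) and one against the opposite
    condition's (*incongruent*); a full study of 64 participants therefore
    yields 256 rows.
    """
    rows = []
    ideals: dict[tuple[float, str], IdealCurve] = {}
    for strength, (active, sham) in protocols.items():
        ideals[(strength, "active")] = build_ideal_curve(active)
        ideals[(strength, "sham")] = build_ideal_curve(sham)
    for rec in records:
        for cond in ("active", "sham"):
            series = probe_series_from_session(rec.sessions[cond])
            other = "sham" if cond == "active" else "active"
            for reference, ideal_cond in (("congruent", cond), ("incongruent", other)):
                res = peak_sensitivity(
                    series, ideals[(rec.current_mA, ideal_cond)],
                    max_lag=max_lag, reference=reference,
                    per_lag_pearson=per_lag_pearson,
                )
                rows.append(
                    (rec.participant_id, rec.current_mA, cond, reference,
                     res.peak_r, res.peak_lag, res.n_interpolated)
                )
    return pd.DataFrame(
        rows,
        columns=["participant_id", "current_mA", "condition", "reference",
                 "peak_r", "peak_lag", "n_interpolated"],
    )
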