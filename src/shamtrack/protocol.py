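"""Stimulation protocols, probe schedules and ideal response curves.

Transcranial direct current stimulation (tDCS) studies typically pair an
*active* protocol (30 s ramp-up, 10 min plateau, 30 s ramp-down) with a
*fade-in, short-stimulation, fade-out* sham (30 s ramp-up, 20 s plateau,
30 s ramp-down) intended to produce matched scalp sensations.  Blinding is
probed online: every 30 s the participant answers "Is the stimulation on?"
and rates their confidence on a 0-10 scale, 32 probes covering a 16 min
observation window.

This module encodes protocol timing, derives the probe schedule, and builds
the *ideal response curve* for a protocol: the weighted-score time series of
a hypothetical participant who reports the presence and absence of current
with perfect accuracy (+10 while any current flows, -10 otherwise).  Ramp
periods count as "on": current flows during ramps, so the active on/off
boundary falls at the end of the ramp-down (660 s for the default active
protocol).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "ProtocolSpec",
    "IdealCurve",
    "probe_schedule",
    "build_ideal_curve",
    "DEFAULT_PROTOCOLS",
    "protocols_for_strength",
    "load_protocols",
]

#: Weighted-score value assigned to a perfectly confident "on" report.
IDEAL_ON = 10.0
#: Weighted-score value assigned to a perfectly confident "off" report.
IDEAL_OFF = -10.0


@dataclass(frozen=True)
class ProtocolSpec:
    """Timing and amplitude of one stimulation condition.

    Parameters
    ----------
    name
        Label, e.g. ``"active_2mA"``.
    ramp_up_s, plateau_s, ramp_down_s
        Durations of the three protocol phases in seconds.  Current flows
        throughout all three, ramping linearly during the ramps.
    current_mA
        Plateau amplitude in milliamps.
    probe_interval_s
        Spacing of the online blinding probes (default 30 s).
    n_probes
        Number of probes in the observation window (default 32, spanning
        16 min at the default interval).
    """

    name: str
    ramp_up_s: float
    plateau_s: float
    ramp_down_s: float
    current_mA: float
    probe_interval_s: float = 30.0
    n_probes: int = 32

    def __post_init__(self) -> None:
        for field in ("ramp_up_s", "plateau_s", "ramp_down_s"):
            if getattr(self, field) < 0:
                raise ValueError(f"{field} must be >= 0, got {getattr(self, field)}")
        if self.current_mA < 0:
            raise ValueError(f"current_mA must be >= 0, got {self.current_mA}")
        if self.probe_interval_s <= 0:
            raise ValueError("probe_interval_s must be positive")
        if self.n_probes < 0:
            raise ValueError("n_probes must be >= 0")

    @property
    def on_duration_s(self) -> float:
        """Total time during which any current flows (ramps included)."""
        return self.ramp_up_s + self.plateau_s + self.ramp_down_s

    @property
    def window_s(self) -> float:
        """Length of the probed observation window."""
        return self.n_probes * self.probe_interval_s

    @property
    def condition(self) -> str:
        """``"active"`` or ``"sham"``, inferred from the name."""
        return "sham" if "sham" in self.name.lower() else "active"


@dataclass(frozen=True)
class IdealCurve:
    """Weighted-score series of a perfectly accurate reporter.

    ``values[k]`` is +10 if current flows at ``probe_times_s[k]`` and -10
    otherwise.  On-probes form a contiguous prefix because current is on
    from t = 0 until the end of the ramp-down.
    """

    values: np.ndarray
    probe_times_s: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(
            self, "probe_times_s", np.asarray(self.probe_times_s, dtype=float)
        )
        if self.values.shape != self.probe_times_s.shape:
            raise ValueError("values and probe_times_s must have equal length")
        if not np.all(np.isin(self.values, (IDEAL_ON, IDEAL_OFF))):
            raise ValueError(f"ideal values must be {IDEAL_ON} or {IDEAL_OFF}")

    @property
    def on_mask(self) -> np.ndarray:
        return self.values == IDEAL_ON


def probe_schedule(spec: ProtocolSpec) -> np.ndarray:
    """Probe times in seconds: 30, 60, ..., 30 * n_probes.

    Probe *k* (1-based) is timestamped at the end of the k-th interval;
    each interval is closed at its right edge.
    """
    return spec.probe_interval_s * np.arange(1, spec.n_probes + 1, dtype=float)


def build_ideal_curve(spec: ProtocolSpec) -> IdealCurve:
    """Ideal response curve for one protocol.

    A probe at time *t* takes the value +10 if any current flows at *t*
    (``t <= on_duration_s``, ramps counted as on) and -10 otherwise.
    """
    times = probe_schedule(spec)
    on = times <= spec.on_duration_s
    values = np.where(on, IDEAL_ON, IDEAL_OFF)
    return IdealCurve(values=values, probe_times_s=times)


def _default(name: str, plateau_s: float, current_mA: float) -> ProtocolSpec:
    return ProtocolSpec(
        name=name,
        ramp_up_s=30.0,
        plateau_s=plateau_s,
        ramp_down_s=30.0,
        current_mA=current_mA,
    )


#: The four shipped protocols: 10 min active plateau vs. 20 s sham plateau,
#: each at 1 mA and 2 mA, all with 30 s ramps.
DEFAULT_PROTOCOLS: dict[str, ProtocolSpec] = {
    "active_2mA": _default("active_2mA", 600.0, 2.0),
    "sham_2mA": _default("sham_2mA", 20.0, 2.0),
    "active_1mA": _default("active_1mA", 600.0, 1.0),
    "sham_1mA": _default("sham_1mA", 20.0, 1.0),
}


def protocols_for_strength(current_mA: float) -> tuple[ProtocolSpec, ProtocolSpec]:
    """(active, sham) protocol pair for a current strength in mA."""
    key = f"{current_mA:g}mA"
    try:
        return (DEFAULT_PROTOCOLS[f"active_{key}"], DEFAULT_PROTOCOLS[f"sham_{key}"])
    except KeyError:
        raise KeyError(f"no default protocols at {current_mA} mA") from None


def load_protocols(path: str | Path) -> dict[str, ProtocolSpec]:
    """Load protocol specs from a YAML or JSON mapping of name -> fields."""
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping of protocol name -> fields")
    specs = {}
    for name, fields in raw.items():
        specs[name] = ProtocolSpec(name=name, **fields)
    return specs
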