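"""Synthetic blinding-study generator.

Emulates a two-strength (1 mA / 2 mA), two-session (active / sham)
online-probe blinding study — 32 participants per strength, each with one
active and one sham session — so that every stage of the pipeline can be
exercised without real data.

The perception model is deliberately minimal.  Scalp sensation is a
*perceived intensity*: the instantaneous current amplitude (linear ramps,
plateau) attenuated by an exponential habituation factor, with a short
lingering tail after current offset.  At each probe the participant
detects the sensation through a noisy logistic comparison against a
personal threshold; the yes/no answer is a coin flip at the detection
probability and the reported confidence grows with the distance of that
probability from chance.  Inter-individual variability enters through a
log-normal population of detection gains (shifted upward in the 2 mA
group) and habituation time constants, both shared across a participant's
two sessions up to small session-level jitter.

Optional couplings connect perception to the behavioural measures: a
distraction term slows reaction times in proportion to the mean detection
salience of a block (active 2 mA only), and the end-of-study guess can be
coupled to how accurately the participant tracked the stimulation
(``guess_coupling = 0`` makes the guess independent of sensitivity while
still matching a realistic overall accuracy).  Each coupling is a switch
so each qualitative finding can be reproduced or ablated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import SIDE_EFFECTS, ParticipantRecord, ParticipantSession, write_study
from .protocol import DEFAULT_PROTOCOLS, ProtocolSpec, build_ideal_curve, probe_schedule

__all__ = [
    "PerceptionParams",
    "PopulationParams",
    "StudyDesign",
    "perceived_intensity",
    "simulate_participant",
    "sample_population",
    "simulate_study",
    "simulate_study_to_dir",
]

BLOCK_BOUNDS_S = {2: (0.0, 330.0), 3: (330.0, 660.0), 4: (660.0, 960.0)}
N_STIM_BLOCK_TRIALS = 60

# Ex-Gaussian reaction-time parameters (canonical simple-RT values, ms).
RT_MU, RT_SIGMA, RT_TAU = 450.0, 50.0, 100.0
RT_P_CORRECT = 0.95

# Side-effect latent means and their sensitivity to the stimulation "dose"
# (current x fraction of the maximal on-time).  Only itching is strongly
# dose-dependent, so active > sham emerges for itching alone.
SIDE_EFFECT_BASE = {
    "headache": 1.2, "tingling": 2.2, "itching": 1.4, "burning": 1.7, "pain": 1.2,
}
SIDE_EFFECT_DOSE_SLOPE = {
    "headache": 0.0, "tingling": 0.05, "itching": 0.6, "burning": 0.05, "pain": 0.0,
}
SIDE_EFFECT_NOISE_SD = 0.7


@dataclass(frozen=True)
class PerceptionParams:
    """One participant-session's perceptual parameters.

    gain
        Slope of the logistic detection function (0 = random responder).
    threshold_mA
        Perceived-intensity level at which detection is at chance.
    habituation_tau_s
        Time constant of the exponential decay of perceived intensity
        during sustained current.
    persistence_s
        Duration of the lingering sensation after current offset.
    confidence_noise / response_noise
        SDs of Gaussian noise on the reported confidence (0-10 scale) and
        inside the logistic (probe-to-probe perceptual noise).
    lapse_rate
        Probability that a probe response is missing (response window
        lapsed).
    """

    gain: float
    threshold_mA: float = 0.4
    habituation_tau_s: float = 500.0
    persistence_s: float = 30.0
    confidence_noise: float = 1.5
    response_noise: float = 1.0
    lapse_rate: float = 0.02

    def __post_init__(self) -> None:
        for name in ("gain", "threshold_mA", "habituation_tau_s", "persistence_s",
                     "confidence_noise", "response_noise", "lapse_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.lapse_rate > 0.2:
            raise ValueError("lapse_rate above 0.2 is not a plausible study")


@dataclass(frozen=True)
class PopulationParams:
    """Distribution of :class:`PerceptionParams` across participants.

    Gains are log-normal (median ``gain_median``, log-SD ``gain_log_sd``)
    with the 2 mA group's median multiplied by ``gain_2mA_multiplier``, so
    current strength classifies sensitivity.  A participant's gain is
    shared across both sessions up to log-normal jitter of SD
    ``session_jitter_sd``, inducing a positive within-participant
    active-sham sensitivity correlation.  Habituation time constants are
    log-normal and shared exactly across sessions.
    """

    gain_median: float = 6.0
    gain_log_sd: float = 0.6
    gain_2mA_multiplier: float = 1.4
    session_jitter_sd: float = 0.15
    tau_median_s: float = 500.0
    tau_log_sd: float = 0.25
    threshold_mA: float = 0.4
    persistence_s: float = 30.0
    confidence_noise: float = 1.5
    response_noise: float = 1.0
    lapse_rate: float = 0.02


@dataclass(frozen=True)
class StudyDesign:
    """Layout and couplings of one simulated study."""

    n_per_strength: int = 32
    strengths: tuple[float, ...] = (1.0, 2.0)
    protocols: dict = field(default_factory=lambda: dict(DEFAULT_PROTOCOLS))
    counterbalance: bool = True
    guess_coupling: float = 0.0  # kappa: 0 = guess independent of sensitivity
    guess_base_rate: float = 0.75  # overall P(correct guess) at kappa = 0
    distraction_coupling_ms: float = 60.0  # RT slowing per unit detection salience
    population: PopulationParams = field(default_factory=PopulationParams)

    def __post_init__(self) -> None:
        if not 0 <= self.guess_coupling <= 1:
            raise ValueError("guess_coupling must lie in [0, 1]")
        if self.n_per_strength < 1:
            raise ValueError("n_per_strength must be >= 1")

    def protocol_pair(self, strength: float) -> tuple[ProtocolSpec, ProtocolSpec]:
        key = f"{strength:g}mA"
        return self.protocols[f"active_{key}"], self.protocols[f"sham_{key}"]


def perceived_intensity(
    t: np.ndarray | float, spec: ProtocolSpec, params: PerceptionParams
) -> np.ndarray | float:
    """Perceived scalp sensation at time(s) ``t`` seconds from ramp onset.

    During stimulation this is the instantaneous current amplitude (linear
    ramp up, plateau, linear ramp down) attenuated by
    ``exp(-t / habituation_tau_s)``.  From the end of the plateau the
    sensation decays linearly from its attenuated plateau-end level to
    zero over ``ramp_down_s + persistence_s`` — a lingering tail that
    outlasts the current by ``persistence_s`` — keeping the curve
    continuous in ``t``.
    """
    t = np.asarray(t, dtype=float)
    ru, pl, rd = spec.ramp_up_s, spec.plateau_s, spec.ramp_down_s
    amp = spec.current_mA
    t_plateau_end = ru + pl
    with np.errstate(over="ignore"):
        hab = np.exp(-t / params.habituation_tau_s)

    # piecewise amplitude up to the plateau end
    rising = np.clip(t / ru, 0.0, 1.0) * amp if ru > 0 else np.full_like(t, amp)
    s_on = np.where(t <= t_plateau_end, np.minimum(rising, amp) * hab, 0.0)

    # decay tail from the attenuated plateau-end level
    tail_len = rd + params.persistence_s
    level_end = amp * np.exp(-t_plateau_end / params.habituation_tau_s)
    if tail_len > 0:
        frac = np.clip(1.0 - (t - t_plateau_end) / tail_len, 0.0, 1.0)
    else:
        frac = np.where(t > t_plateau_end, 0.0, 1.0)
    s_off = np.where(t > t_plateau_end, level_end * frac, 0.0)

    out = np.where(t < 0, 0.0, s_on + s_off)
    return float(out) if out.ndim == 0 else out


def _logistic(x: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):  # saturates cleanly to 0/1
        return 1.0 / (1.0 + np.exp(-x))


#: Lag-1 autocorrelation of the perceptual noise across successive probes.
#: Percepts are coherent in time: a participant who currently feels (or no
#: longer feels) the stimulation tends to keep reporting so at the next
#: probe rather than flickering every 30 s.
NOISE_AR1_RHO = 0.8


def _ar1_noise(n: int, sd: float, rho: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation ``sd``."""
    if sd == 0:
        return np.zeros(n)
    out = np.empty(n)
    out[0] = rng.normal(0.0, sd)
    innov_sd = sd * np.sqrt(1.0 - rho**2)
    for k in range(1, n):
        out[k] = rho * out[k - 1] + rng.normal(0.0, innov_sd)
    return out


def _block_salience(block: int, times: np.ndarray, p_on: np.ndarray) -> float:
    """How strongly the participant felt stimulation during a block.

    Mean over the block's probes of max(2 * p_on - 1, 0), where p_on is the
    participant's realised (noisy) detection probability: 0 when nothing
    registered, approaching 1 when the whole block was confidently felt.
    Using the same percept that drives the probe answers couples the
    distraction-induced slowing to the participant's actual sensitivity,
    not merely to the delivered current.
    """
    lo, hi = BLOCK_BOUNDS_S[block]
    in_block = (times > lo) & (times <= hi)
    if not in_block.any():
        return 0.0
    return float(np.mean(np.maximum(2.0 * p_on[in_block] - 1.0, 0.0)))


def _simulate_session(
    design: StudyDesign,
    params: PerceptionParams,
    spec: ProtocolSpec,
    pid: str,
    session_order: int,
    strength: float,
    rng: np.random.Generator,
) -> tuple[ParticipantSession, float]:
    """One session; returns (session, tracking accuracy vs own ideal)."""
    times = probe_schedule(spec)
    intensity = perceived_intensity(times, spec, params)
    eps = _ar1_noise(times.size, params.response_noise, NOISE_AR1_RHO, rng)
    p_on = _logistic(params.gain * (intensity - params.threshold_mA) + eps)
    says_yes = rng.random(times.size) < p_on
    confidence = np.clip(
        10.0 * np.abs(2.0 * p_on - 1.0) + rng.normal(0.0, params.confidence_noise, times.size),
        0.0, 10.0,
    )
    lapsed = rng.random(times.size) < params.lapse_rate
    responses = np.where(lapsed, "missing", np.where(says_yes, "yes", "no")).astype(object)
    conf_out = np.where(lapsed, np.nan, confidence)

    ideal_on = build_ideal_curve(spec).on_mask
    valid = ~lapsed
    accuracy = float((says_yes[valid] == ideal_on[valid]).mean()) if valid.any() else 0.5

    # Reaction-time blocks: ex-Gaussian trials; sustained sensation can
    # distract, slowing the stimulation blocks of the active 2 mA session.
    trial_rows = []
    for block in (1, 2, 3, 4):
        n = 100 if block == 1 else N_STIM_BLOCK_TRIALS
        rts = rng.normal(RT_MU, RT_SIGMA, n) + rng.exponential(RT_TAU, n)
        if (
            block > 1
            and design.distraction_coupling_ms > 0
            and spec.condition == "active"
            and strength == 2.0
        ):
            rts = rts + design.distraction_coupling_ms * _block_salience(
                block, times, p_on
            )
        correct = (rng.random(n) < RT_P_CORRECT).astype(int)
        for j in range(n):
            trial_rows.append((block, j + 1, correct[j], float(np.round(rts[j], 3))))
    rt_trials = pd.DataFrame(trial_rows, columns=["block", "trial_index", "correct", "rt_ms"])

    dose = spec.current_mA * spec.on_duration_s / 660.0
    side_effects = {}
    for eff in SIDE_EFFECTS:
        latent = (
            SIDE_EFFECT_BASE[eff]
            + SIDE_EFFECT_DOSE_SLOPE[eff] * dose
            + rng.normal(0.0, SIDE_EFFECT_NOISE_SD)
        )
        side_effects[eff] = int(np.clip(round(latent), 1, 5))

    session = ParticipantSession(
        participant_id=pid,
        current_mA=strength,
        condition=spec.condition,
        session_order=session_order,
        responses=responses,
        confidence=conf_out,
        rt_trials=rt_trials,
        side_effects=side_effects,
    )
    return session, accuracy


def simulate_participant(
    design: StudyDesign,
    params: PerceptionParams,
    strength: float,
    seed: int | np.random.Generator,
    participant_id: str = "P001",
    active_first: bool = True,
    session_params: tuple[PerceptionParams, PerceptionParams] | None = None,
) -> ParticipantRecord:
    """Simulate both sessions and the end-of-study guess of one participant.

    ``params`` are the participant-level perceptual parameters; optional
    ``session_params`` override them per (active, sham) session (used for
    the shared-gain session jitter).  The guess is correct with
    probability ``guess_base_rate + kappa * (tracking accuracy - 0.5)``,
    clipped to [0, 1], where the tracking accuracy is the fraction of
    non-missing probes on which the response matched the participant's own
    condition's ideal curve, averaged over the two sessions.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    active_spec, sham_spec = design.protocol_pair(strength)
    if session_params is None:
        session_params = (params, params)
    order = [("active", active_spec, session_params[0]),
             ("sham", sham_spec, session_params[1])]
    if not active_first:
        order.reverse()
    sessions: dict[str, ParticipantSession] = {}
    accuracies = []
    for i, (cond, spec, sp) in enumerate(order, start=1):
        session, acc = _simulate_session(
            design, sp, spec, participant_id, i, strength, rng
        )
        sessions[cond] = session
        accuracies.append(acc)
    p_correct = float(np.clip(
        design.guess_base_rate
        + design.guess_coupling * (float(np.mean(accuracies)) - 0.5),
        0.0, 1.0,
    ))
    guess_correct = bool(rng.random() < p_correct)
    return ParticipantRecord(
        participant_id=participant_id, sessions=sessions, guess_correct=guess_correct
    )


def sample_population(
    pop: PopulationParams, strength: float, n: int, rng: np.random.Generator
) -> list[PerceptionParams]:
    """Draw participant-level perceptual parameters for one strength group."""
    mult = pop.gain_2mA_multiplier if strength == 2.0 else 1.0
    median = pop.gain_median * mult
    if median > 0:
        gains = np.exp(rng.normal(np.log(median), pop.gain_log_sd, n))
    else:
        gains = np.zeros(n)  # population of pure random responders
    taus = np.exp(rng.normal(np.log(pop.tau_median_s), pop.tau_log_sd, n))
    return [
        PerceptionParams(
            gain=float(g), threshold_mA=pop.threshold_mA,
            habituation_tau_s=float(tau), persistence_s=pop.persistence_s,
            confidence_noise=pop.confidence_noise,
            response_noise=pop.response_noise, lapse_rate=pop.lapse_rate,
        )
        for g, tau in zip(gains, taus)
    ]


def simulate_study(
    design: StudyDesign, seed: int
) -> tuple[list[ParticipantRecord], pd.DataFrame]:
    """Simulate a full study; returns (records, ground-truth table).

    The truth table records each participant's drawn parameters (columns
    ``participant_id, current_mA, gain, habituation_tau_s, ...``) for
    parameter-recovery checks.  Fixed seed gives a byte-identical study.
    """
    root = np.random.SeedSequence(seed)
    records: list[ParticipantRecord] = []
    truth_rows = []
    counter = 0
    for strength in design.strengths:
        pop_rng = np.random.default_rng(root.spawn(1)[0])
        plist = sample_population(design.population, strength, design.n_per_strength, pop_rng)
        for i, params in enumerate(plist):
            counter += 1
            pid = f"P{counter:03d}"
            prng = np.random.default_rng(root.spawn(1)[0])
            jitter = np.exp(
                prng.normal(0.0, design.population.session_jitter_sd, 2)
            )
            sp = (
                replace(params, gain=params.gain * float(jitter[0])),
                replace(params, gain=params.gain * float(jitter[1])),
            )
            active_first = (i % 2 == 0) if design.counterbalance else True
            rec = simulate_participant(
                design, params, strength, prng, participant_id=pid,
                active_first=active_first, session_params=sp,
            )
            records.append(rec)
            truth_rows.append(
                (pid, strength, params.gain, sp[0].gain, sp[1].gain,
                 params.habituation_tau_s, params.threshold_mA)
            )
    truth = pd.DataFrame(
        truth_rows,
        columns=["participant_id", "current_mA", "gain", "gain_active",
                 "gain_sham", "habituation_tau_s", "threshold_mA"],
    )
    return records, truth


def simulate_study_to_dir(
    design: StudyDesign, seed: int, path: str | Path
) -> tuple[list[ParticipantRecord], pd.DataFrame]:
    """Simulate and write a study directory (three data CSVs + truth.csv).

    ``truth.csv`` holds the synthetic ground-truth parameters; it is not
    part of the analysis schema and :func:`~shamtrack.data_io.read_study`
    ignores it.
    """
    records, truth = simulate_study(design, seed)
    path = Path(path)
    write_study(records, path)
    truth.to_csv(path / "truth.csv", index=False)
    return records, truth
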