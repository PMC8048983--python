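"""Inferential statistics over reaction times, side effects and sensitivity.

The battery mirrors a standard within-subjects blinding analysis:

* ΔRT — each block's median correct-trial reaction time minus the
  pre-stimulation baseline block's median; paired one-tailed t tests of
  active vs. sham per block (Bonferroni-adjusted alpha 0.05/3 ≈ 0.017) and
  one-tailed Welch t tests between current strengths.
* Wilcoxon signed-rank tests of the five ordinal side-effect ratings.
* A mixed 2x2 ANOVA (between: current strength; within: stimulation type)
  and a fully within-subject 2x2 ANOVA (stimulation type x congruence) on
  the peak cross-correlation coefficients, with partial eta squared.
* Pearson correlations between congruent sensitivity and ΔRT in the final
  stimulation block, per (strength, condition) stratum.

Because one-tailed bookkeeping conventions vary, every t-based result also
carries both the one- and two-tailed p-values in ``extras``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .data_io import SIDE_EFFECTS, ParticipantRecord, ParticipantSession

__all__ = [
    "TestResult",
    "rt_block_summaries",
    "delta_rt",
    "paired_t",
    "welch_t",
    "mixed_anova",
    "repeated_anova_2x2",
    "wilcoxon_signed_rank",
    "pearson_corr",
    "sensitivity_rt_correlations",
    "run_inferential_battery",
    "BONFERRONI_3",
]

#: Bonferroni-adjusted alpha for families of three block-wise tests.
BONFERRONI_3 = 0.05 / 3


@dataclass
class TestResult:
    """One test statistic with its inference and effect size."""

    name: str
    stat_name: str  # "t", "F", "Z", "W", or "r"
    statistic: float
    df: float | tuple[float, float] | None
    p_value: float
    effect_size: float | None = None
    effect_name: str | None = None  # "cohen_d", "partial_eta_sq", ...
    tails: str = "two"
    alpha_adjusted: float | None = None
    degenerate: bool = False
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        df = list(self.df) if isinstance(self.df, tuple) else self.df
        return {
            "name": self.name, "stat_name": self.stat_name,
            "statistic": _jsonable(self.statistic), "df": _jsonable(df),
            "p_value": _jsonable(self.p_value),
            "effect_size": _jsonable(self.effect_size),
            "effect_name": self.effect_name, "tails": self.tails,
            "alpha_adjusted": self.alpha_adjusted,
            "degenerate": self.degenerate,
            "extras": {k: _jsonable(v) for k, v in self.extras.items()},
        }


def _jsonable(v):
    if isinstance(v, (list, tuple)):
        return [_jsonable(x) for x in v]
    if isinstance(v, (np.floating, np.integer)):
        v = v.item()
    if isinstance(v, float) and not math.isfinite(v):
        return None
    return v


# ---------------------------------------------------------------------------
# reaction times
# ---------------------------------------------------------------------------

def rt_block_summaries(session: ParticipantSession) -> pd.DataFrame:
    """Median correct-trial RT and correct-trial count per block (1-4)."""
    correct = session.rt_trials[session.rt_trials["correct"] == 1]
    rows = []
    for block in (1, 2, 3, 4):
        rts = correct.loc[correct["block"] == block, "rt_ms"]
        rows.append(
            (session.participant_id, session.condition, block,
             float(rts.median()) if len(rts) else float("nan"), int(len(rts)))
        )
    return pd.DataFrame(
        rows, columns=["participant_id", "condition", "block", "median_rt_ms", "n_correct"]
    )


def delta_rt(session: ParticipantSession) -> dict[int, float]:
    """ΔRT per stimulation block: median_b - median_baseline for b in 2-4.

    A block with zero correct trials yields NaN (flagged missing); group
    tests drop such entries pairwise.
    """
    med = rt_block_summaries(session).set_index("block")["median_rt_ms"]
    return {b: float(med[b] - med[1]) for b in (2, 3, 4)}


# ---------------------------------------------------------------------------
# t tests
# ---------------------------------------------------------------------------

def _tail_ps(t: float, df: float) -> tuple[float, float]:
    """(two-tailed, one-tailed-in-stated-direction) p-values for a t value."""
    p_two = float(2 * scipy.stats.t.sf(abs(t), df))
    p_one = float(scipy.stats.t.sf(t, df))  # directional: statistic > 0
    return p_two, p_one


def paired_t(
    x: np.ndarray, y: np.ndarray, tails: str = "two",
    name: str = "paired_t", alpha_adjusted: float | None = None,
) -> TestResult:
    """Repeated-measures t test of x vs. y with Cohen's d for paired data.

    ``tails="one"`` reports the p-value for the directional hypothesis
    mean(x) > mean(y); the opposite tail and the two-tailed value are in
    ``extras``.  Cohen's d = mean(x - y) / SD(x - y).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    d = x[keep] - y[keep]
    n = d.size
    if n < 2:
        raise ValueError("need at least 2 complete pairs")
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return TestResult(name, "t", 0.0, n - 1, 1.0, 0.0, "cohen_d",
                              tails, alpha_adjusted, degenerate=True)
        raise ValueError("zero variance of differences with nonzero mean")
    t = d.mean() / (sd / np.sqrt(n))
    p_two, p_one = _tail_ps(t, n - 1)
    return TestResult(
        name=name, stat_name="t", statistic=float(t), df=float(n - 1),
        p_value=p_one if tails == "one" else p_two,
        effect_size=float(d.mean() / sd), effect_name="cohen_d",
        tails=tails, alpha_adjusted=alpha_adjusted,
        extras={"p_two_tailed": p_two, "p_one_tailed": p_one, "n": n},
    )


def welch_t(
    x: np.ndarray, y: np.ndarray, tails: str = "two",
    name: str = "welch_t", alpha_adjusted: float | None = None,
) -> TestResult:
    """Welch's unequal-variance t test with Welch-Satterthwaite fractional df."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise ValueError("zero variance in both groups")
    se2 = vx / x.size + vy / y.size
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / (
        (vx / x.size) ** 2 / (x.size - 1) + (vy / y.size) ** 2 / (y.size - 1)
    )
    p_two, p_one = _tail_ps(float(t), float(df))
    # Cohen's d with the pooled SD, the common reporting convention.
    sp = np.sqrt(((x.size - 1) * vx + (y.size - 1) * vy) / (x.size + y.size - 2))
    return TestResult(
        name=name, stat_name="t", statistic=float(t), df=float(df),
        p_value=p_one if tails == "one" else p_two,
        effect_size=float((x.mean() - y.mean()) / sp) if sp > 0 else None,
        effect_name="cohen_d", tails=tails, alpha_adjusted=alpha_adjusted,
        extras={"p_two_tailed": p_two, "p_one_tailed": p_one,
                "n1": int(x.size), "n2": int(y.size)},
    )


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------

def _two_group_f(x1: np.ndarray, x2: np.ndarray, estimate: str, name: str) -> TestResult:
    """F test (1, n-2) from a pooled two-group analysis of per-subject scores.

    ``estimate="difference"`` tests mean(x1) - mean(x2) = 0 (between-group
    contrast); ``estimate="grand_mean"`` tests the unweighted marginal mean
    (x1.mean() + x2.mean())/2 = 0 against the same pooled error, which is
    the Type III within/interaction test in a 2x2 mixed design.
    """
    n1, n2 = x1.size, x2.size
    df2 = n1 + n2 - 2
    sp2 = ((n1 - 1) * x1.var(ddof=1) + (n2 - 1) * x2.var(ddof=1)) / df2
    if estimate == "difference":
        est, se2 = x1.mean() - x2.mean(), sp2 * (1 / n1 + 1 / n2)
    else:
        est, se2 = (x1.mean() + x2.mean()) / 2, sp2 * (1 / n1 + 1 / n2) / 4
    if se2 == 0:
        # no residual variance: effect exactly absent (F=0) or perfectly
        # separating (F=inf)
        return TestResult(name, "F", 0.0 if est == 0 else float("inf"),
                          (1.0, float(df2)), 1.0 if est == 0 else 0.0,
                          effect_size=0.0 if est == 0 else 1.0,
                          effect_name="partial_eta_sq", degenerate=True)
    F = float(est**2 / se2)
    return TestResult(
        name=name, stat_name="F", statistic=F, df=(1.0, float(df2)),
        p_value=float(scipy.stats.f.sf(F, 1, df2)),
        effect_size=F / (F + df2), effect_name="partial_eta_sq",
    )


def mixed_anova(
    df: pd.DataFrame,
    dv: str = "peak_r",
    within: str = "condition",
    between: str = "current_mA",
    subject: str = "participant_id",
) -> dict[str, TestResult]:
    """Mixed 2x2 ANOVA: one between-subject and one within-subject factor.

    Returns results keyed ``between``, ``within`` and ``interaction``, each
    an F test on (1, n-2) degrees of freedom with partial eta squared.
    With two levels per factor the classical (Type III, balanced-equivalent)
    decomposition reduces to pooled two-group t tests on per-subject
    summaries: the between effect on subject means, the interaction on
    within-difference scores, and the within main effect on the unweighted
    grand mean of those difference scores.  Requires a complete
    within-pairing (both within levels for every subject).
    """
    counts = df.groupby(subject)[within].nunique()
    if (counts != 2).any() or df[within].nunique() != 2 or df[between].nunique() != 2:
        raise ValueError("mixed_anova needs a complete 2x2 design")
    w1, w2 = sorted(df[within].unique())
    cells = df.pivot_table(index=[subject, between], columns=within, values=dv,
                           aggfunc="first").reset_index()
    g1, g2 = sorted(cells[between].unique())
    means = (cells[w1] + cells[w2]) / 2
    diffs = cells[w1] - cells[w2]
    in_g1 = (cells[between] == g1).to_numpy()
    return {
        "between": _two_group_f(
            means[in_g1].to_numpy(), means[~in_g1].to_numpy(),
            "difference", "mixed_anova_between"),
        "within": _two_group_f(
            diffs[in_g1].to_numpy(), diffs[~in_g1].to_numpy(),
            "grand_mean", "mixed_anova_within"),
        "interaction": _two_group_f(
            diffs[in_g1].to_numpy(), diffs[~in_g1].to_numpy(),
            "difference", "mixed_anova_interaction"),
    }


def _contrast_f(c: np.ndarray, name: str) -> TestResult:
    """F test (= squared one-sample t) that a per-subject contrast is zero."""
    n = c.size
    sd = c.std(ddof=1)
    if sd == 0:
        return TestResult(name, "F", 0.0 if c.mean() == 0 else float("inf"),
                          (1.0, float(n - 1)), 1.0 if c.mean() == 0 else 0.0,
                          effect_size=0.0 if c.mean() == 0 else 1.0,
                          effect_name="partial_eta_sq", degenerate=True)
    t = c.mean() / (sd / np.sqrt(n))
    F = float(t**2)
    p = float(scipy.stats.f.sf(F, 1, n - 1))
    return TestResult(
        name=name, stat_name="F", statistic=F, df=(1.0, float(n - 1)),
        p_value=p, effect_size=F / (F + (n - 1)), effect_name="partial_eta_sq",
    )


def repeated_anova_2x2(
    df: pd.DataFrame,
    dv: str = "peak_r",
    factor_a: str = "condition",
    factor_b: str = "reference",
    subject: str = "participant_id",
) -> dict[str, TestResult]:
    """Fully within-subject 2x2 ANOVA via per-subject contrasts.

    With two two-level within factors each ANOVA effect is exactly the
    square of a one-sample t test on the corresponding per-subject
    contrast (main effects: marginal-mean differences; interaction: the
    difference of differences), each on (1, n-1) degrees of freedom.
    Partial eta squared is F / (F + df2).
    """
    cells = df.pivot_table(index=subject, columns=[factor_a, factor_b],
                           values=dv, aggfunc="first")
    if cells.shape[1] != 4 or cells.isna().any().any():
        raise ValueError("repeated_anova_2x2 needs all four cells per subject")
    a1, a2 = sorted(df[factor_a].unique())
    b1, b2 = sorted(df[factor_b].unique())
    m = cells.to_numpy()
    cols = list(cells.columns)
    v = {ab: m[:, cols.index(ab)] for ab in ((a1, b1), (a1, b2), (a2, b1), (a2, b2))}
    eff_a = (v[(a1, b1)] + v[(a1, b2)] - v[(a2, b1)] - v[(a2, b2)]) / 2
    eff_b = (v[(a1, b1)] + v[(a2, b1)] - v[(a1, b2)] - v[(a2, b2)]) / 2
    eff_ab = (v[(a1, b1)] - v[(a1, b2)]) - (v[(a2, b1)] - v[(a2, b2)])
    return {
        factor_a: _contrast_f(eff_a, f"rm_anova_{factor_a}"),
        factor_b: _contrast_f(eff_b, f"rm_anova_{factor_b}"),
        "interaction": _contrast_f(eff_ab, f"rm_anova_{factor_a}_x_{factor_b}"),
    }


# ---------------------------------------------------------------------------
# nonparametrics & correlation
# ---------------------------------------------------------------------------

def wilcoxon_signed_rank(a: np.ndarray, b: np.ndarray, name: str = "wilcoxon") -> TestResult:
    """Wilcoxon signed-rank test of paired samples.

    Zero differences are dropped (classical Wilcoxon procedure) and tied
    absolute differences receive averaged ranks.  The p-value is exact
    (full enumeration of sign assignments) when the retained sample has
    n <= 25 and no rank ties; otherwise the normal approximation with
    continuity and tie corrections is used.  The signed Z statistic (from
    W+ = rank sum of positive differences) is always reported, so swapping
    the samples negates Z.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        return TestResult(name, "Z", 0.0, None, 1.0, degenerate=True,
                          extras={"n_nonzero": 0})
    ranks = scipy.stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4
    _, tie_counts = np.unique(ranks, return_counts=True)
    sigma2 = n * (n + 1) * (2 * n + 1) / 24 - (tie_counts**3 - tie_counts).sum() / 48
    sigma = np.sqrt(sigma2)
    cc = 0.5 * np.sign(w_plus - mu) if w_plus != mu else 0.0
    z = (w_plus - mu - cc) / sigma if sigma > 0 else 0.0
    has_ties = (tie_counts > 1).any()
    if n <= 25 and not has_ties:
        p = float(scipy.stats.wilcoxon(d, zero_method="wilcox", method="exact").pvalue)
        method = "exact"
    else:
        p = float(2 * scipy.stats.norm.sf(abs(z)))
        method = "normal_approx"
    return TestResult(
        name=name, stat_name="Z", statistic=float(z), df=None, p_value=p,
        extras={"W_plus": w_plus, "n_nonzero": int(n), "method": method},
    )


def pearson_corr(x: np.ndarray, y: np.ndarray, name: str = "pearson") -> TestResult:
    """Pearson correlation with the t-based two-sided p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3 or np.std(x) == 0 or np.std(y) == 0:
        return TestResult(name, "r", float("nan"), None, float("nan"),
                          degenerate=True, extras={"n": int(n)})
    r, p = scipy.stats.pearsonr(x, y)
    return TestResult(name=name, stat_name="r", statistic=float(r),
                      df=float(n - 2), p_value=float(p), extras={"n": int(n)})


def sensitivity_rt_correlations(
    sens_table: pd.DataFrame, delta_rt3: pd.DataFrame
) -> dict[str, TestResult]:
    """Pearson correlation of congruent peak_r with block-3 ΔRT per stratum.

    ``delta_rt3`` needs columns participant_id, condition, delta_rt_ms.
    One result per (current strength, condition) stratum; strata with
    fewer than 3 complete pairs or a constant variable are flagged
    degenerate.
    """
    congruent = sens_table[sens_table["reference"] == "congruent"]
    merged = congruent.merge(delta_rt3, on=["participant_id", "condition"])
    out = {}
    for (strength, cond), sub in merged.groupby(["current_mA", "condition"], sort=True):
        key = f"sensitivity_rt_corr_{strength:g}mA_{cond}"
        out[key] = pearson_corr(
            sub["peak_r"].to_numpy(), sub["delta_rt_ms"].to_numpy(), name=key
        )
    return out


# ---------------------------------------------------------------------------
# the full battery
# ---------------------------------------------------------------------------

def _delta_rt_frame(records: list[ParticipantRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        for cond in ("active", "sham"):
            for block, val in delta_rt(rec.sessions[cond]).items():
                rows.append((rec.participant_id, rec.current_mA, cond, block, val))
    return pd.DataFrame(
        rows, columns=["participant_id", "current_mA", "condition", "block", "delta_rt_ms"]
    )


def run_inferential_battery(
    records: list[ParticipantRecord], sens_table: pd.DataFrame
) -> dict[str, TestResult]:
    """The full inferential battery over a study; keys name each test."""
    stats: dict[str, TestResult] = {}
    drt = _delta_rt_frame(records)

    # ΔRT: active vs sham per block within each strength (one-tailed,
    # directional hypothesis: active slows more than sham).
    for strength, sub in drt.groupby("current_mA", sort=True):
        wide = sub.pivot_table(index=["participant_id", "block"], columns="condition",
                               values="delta_rt_ms").reset_index()
        for block in (2, 3, 4):
            w = wide[wide["block"] == block]
            name = f"delta_rt_paired_t_{strength:g}mA_block{block}"
            stats[name] = paired_t(
                w["active"].to_numpy(), w["sham"].to_numpy(), tails="one",
                name=name, alpha_adjusted=BONFERRONI_3,
            )

    # ΔRT between strengths (one-tailed: higher current slows more).
    strengths = sorted(drt["current_mA"].unique())
    if len(strengths) == 2:
        lo, hi = strengths
        for cond in ("active", "sham"):
            for block in (2, 3, 4):
                sub = drt[(drt["condition"] == cond) & (drt["block"] == block)]
                name = f"delta_rt_welch_t_{cond}_block{block}"
                stats[name] = welch_t(
                    sub.loc[sub["current_mA"] == hi, "delta_rt_ms"].to_numpy(),
                    sub.loc[sub["current_mA"] == lo, "delta_rt_ms"].to_numpy(),
                    tails="one", name=name, alpha_adjusted=BONFERRONI_3,
                )

    # Side effects: Wilcoxon active vs sham per effect within each strength.
    by_strength: dict[float, list[ParticipantRecord]] = {}
    for rec in records:
        by_strength.setdefault(rec.current_mA, []).append(rec)
    for strength, recs in sorted(by_strength.items()):
        for eff in SIDE_EFFECTS:
            a = np.array([r.active.side_effects[eff] for r in recs], float)
            s = np.array([r.sham.side_effects[eff] for r in recs], float)
            name = f"side_effect_wilcoxon_{eff}_{strength:g}mA"
            stats[name] = wilcoxon_signed_rank(a, s, name=name)

    congruent = sens_table[sens_table["reference"] == "congruent"]

    # Sensitivity: active vs sham paired t over all participants.
    wide = congruent.pivot_table(index="participant_id", columns="condition",
                                 values="peak_r")
    stats["peak_r_paired_t_active_vs_sham"] = paired_t(
        wide["active"].to_numpy(), wide["sham"].to_numpy(),
        name="peak_r_paired_t_active_vs_sham",
    )
    stats["peak_r_corr_active_vs_sham"] = pearson_corr(
        wide["active"].to_numpy(), wide["sham"].to_numpy(),
        name="peak_r_corr_active_vs_sham",
    )

    # Mixed ANOVA: current strength (between) x stimulation type (within).
    if congruent["current_mA"].nunique() == 2:
        stats.update(
            {f"mixed_anova_{k}": v for k, v in mixed_anova(congruent).items()}
        )

    # Fully-within 2x2: stimulation type x congruence.
    rm = repeated_anova_2x2(sens_table)
    stats["rm_anova_condition"] = rm["condition"]
    stats["rm_anova_congruence"] = rm["reference"]
    stats["rm_anova_interaction"] = rm["interaction"]

    # Guess accuracy: Welch t of congruent peak_r, correct vs incorrect.
    guess = {rec.participant_id: rec.guess_correct for rec in records}
    cg = congruent.assign(guess_correct=congruent["participant_id"].map(guess))
    for cond, sub in cg.groupby("condition", sort=True):
        name = f"guess_welch_t_{cond}"
        corr_scores = sub.loc[sub["guess_correct"], "peak_r"].to_numpy()
        incorr_scores = sub.loc[~sub["guess_correct"].astype(bool), "peak_r"].to_numpy()
        if corr_scores.size >= 2 and incorr_scores.size >= 2:
            stats[name] = welch_t(corr_scores, incorr_scores, name=name)

    # Sensitivity vs block-3 ΔRT, per (strength, condition).
    drt3 = drt[drt["block"] == 3][["participant_id", "condition", "delta_rt_ms"]]
    stats.update(sensitivity_rt_correlations(sens_table, drt3))
    return stats
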