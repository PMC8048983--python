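"""ROC/AUC evaluation of binary classifiers of sensitivity.

Three binary splits of the peak cross-correlation coefficients are
evaluated, separately within the active and sham conditions:

``congruence``
    Does a coefficient come from the congruent or the incongruent
    cross-correlation?  (positive class: congruent)
``current_strength``
    Does a congruent coefficient come from the 2 mA or the 1 mA group?
    (positive class: 2 mA)
``guess_accuracy``
    Does a congruent coefficient belong to a participant whose
    end-of-study guess was correct?  (positive class: correct; 1 mA and
    2 mA participants pooled, with a per-strength breakdown also emitted)

AUC is the Mann-Whitney probability that a random positive-class score
exceeds a random negative-class one (ties counted half), identical to the
trapezoidal area under the empirical ROC.  The positive-class orientation
is fixed a priori and never flipped to force AUC >= 0.5.  Confidence
intervals and p-values against the chance value 0.5 use the Hanley-McNeil
normal approximation by default, with a seeded case-resampling bootstrap
interval available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.metrics import roc_curve

from .data_io import ParticipantRecord

__all__ = ["ClassifierEval", "roc_auc", "auc_inference", "run_classifiers"]


@dataclass
class ClassifierEval:
    """ROC curve, AUC and inference for one binary classifier."""

    classifier: str
    condition: str
    auc: float
    n_pos: int
    n_neg: int
    roc_points: np.ndarray  # (k, 2) array of (fpr, tpr), (0,0) .. (1,1)
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    p_value: float = float("nan")
    ci_method: str = ""
    notes: dict = field(default_factory=dict)


def roc_auc(scores: np.ndarray, labels: np.ndarray,
            classifier: str = "", condition: str = "") -> ClassifierEval:
    """Empirical ROC staircase and its area.

    ``labels`` is a binary vector (1 = positive class).  The area is
    computed by the trapezoidal rule over the full staircase, which with
    the tie-aware staircase equals the Mann-Whitney statistic
    ``P(score_pos > score_neg) + 0.5 P(tie)``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-d and equal length")
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to build a ROC curve")
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ClassifierEval(
        classifier=classifier, condition=condition, auc=auc,
        n_pos=n_pos, n_neg=n_neg,
        roc_points=np.column_stack([fpr, tpr]),
    )


def hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Standard error of an AUC (Hanley & McNeil 1982 exponential model)."""
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (
        auc * (1 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def auc_inference(
    ev: ClassifierEval,
    level: float = 0.95,
    method: str = "hanley_mcneil",
    scores: np.ndarray | None = None,
    labels: np.ndarray | None = None,
    n_boot: int = 2000,
    seed: int | None = None,
) -> ClassifierEval:
    """Attach a confidence interval and a p-value against AUC = 0.5.

    The p-value is a two-sided normal test with the null standard error
    evaluated at AUC = 0.5 (same Hanley-McNeil formula).  With
    ``method="bootstrap"`` the interval is instead the percentile interval
    over ``n_boot`` case resamples of (scores, labels); the p-value is
    still the normal approximation.
    """
    if ev.n_pos < 2 or ev.n_neg < 2:
        raise ValueError("AUC inference needs at least 2 cases per class")
    z = scipy.stats.norm.ppf(0.5 + level / 2)
    se0 = hanley_mcneil_se(0.5, ev.n_pos, ev.n_neg)
    ev.p_value = float(2 * scipy.stats.norm.sf(abs(ev.auc - 0.5) / se0))
    if method == "hanley_mcneil":
        se = hanley_mcneil_se(ev.auc, ev.n_pos, ev.n_neg)
        ev.ci_low = float(np.clip(ev.auc - z * se, 0.0, 1.0))
        ev.ci_high = float(np.clip(ev.auc + z * se, 0.0, 1.0))
    elif method == "bootstrap":
        if scores is None or labels is None:
            raise ValueError("bootstrap CI needs the original scores and labels")
        scores = np.asarray(scores, dtype=float)
        labels = np.asarray(labels).astype(int)
        rng = np.random.default_rng(seed)
        aucs = []
        for _ in range(n_boot):
            idx = rng.integers(0, scores.size, scores.size)
            ls = labels[idx]
            if ls.min() == ls.max():
                continue  # degenerate resample: one class absent
            aucs.append(roc_auc(scores[idx], ls).auc)
        alpha = 100 * (1 - level) / 2
        ev.ci_low = float(np.percentile(aucs, alpha))
        ev.ci_high = float(np.percentile(aucs, 100 - alpha))
    else:
        raise ValueError(f"unknown CI method {method!r}")
    ev.ci_method = method
    return ev


def _evaluate(scores, labels, classifier, condition, method, n_boot, seed):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if labels.size == 0 or labels.min() == labels.max():
        return None  # stratum is single-class: evaluation flagged absent
    if min(labels.sum(), labels.size - labels.sum()) < 2:
        return None  # too few cases in a class for any inference
    ev = roc_auc(scores, labels, classifier=classifier, condition=condition)
    return auc_inference(
        ev, method=method, scores=scores, labels=labels, n_boot=n_boot, seed=seed
    )


def run_classifiers(
    sens_table: pd.DataFrame,
    records: list[ParticipantRecord],
    ci_method: str = "hanley_mcneil",
    n_boot: int = 2000,
    seed: int | None = None,
) -> list[ClassifierEval]:
    """Evaluate the three sensitivity classifiers in both conditions.

    Returns up to six primary evaluations (3 classifiers x 2 conditions)
    plus per-strength breakdowns of the guess-accuracy classifier (noted
    via ``classifier="guess_accuracy_{strength}mA"``).  A stratum whose
    labels are single-class is omitted rather than fabricated; remaining
    evaluations are still produced.
    """
    guess = {rec.participant_id: rec.guess_correct for rec in records}
    df = sens_table.copy()
    df["guess_correct"] = df["participant_id"].map(guess).astype(bool)
    evals: list[ClassifierEval] = []
    for cond, sub in df.groupby("condition", sort=True):
        congruent = sub[sub["reference"] == "congruent"]
        candidates = [
            ("congruence", sub["peak_r"], (sub["reference"] == "congruent")),
            ("current_strength", congruent["peak_r"], (congruent["current_mA"] == 2.0)),
            ("guess_accuracy", congruent["peak_r"], congruent["guess_correct"]),
        ]
        for strength, s_sub in congruent.groupby("current_mA", sort=True):
            candidates.append(
                (f"guess_accuracy_{strength:g}mA", s_sub["peak_r"], s_sub["guess_correct"])
            )
        for name, scores, labels in candidates:
            ev = _evaluate(
                scores.to_numpy(), labels.to_numpy(), name, cond,
                ci_method, n_boot, seed,
            )
            if ev is not None:
                evals.append(ev)
    return evals
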