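"""End-to-end analysis of a blinding study.

Glues the stages together: weighted-score group curves with bootstrap
bands per (strength, condition), the set of non-overlapping probes per
strength, the congruent/incongruent sensitivity table, the three ROC
classifiers, and the inferential battery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import classify, data_io, infer_stats, scores, sensitivity
from .data_io import ParticipantRecord
from .protocol import DEFAULT_PROTOCOLS, ProtocolSpec

__all__ = ["AnalysisConfig", "StudyResults", "analyze_study", "analyze_directory"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable analysis settings (defaults reproduce the standard run)."""

    n_boot: int = 5000
    ci_level: float = 0.95
    seed: int | None = None
    auc_ci_method: str = "hanley_mcneil"  # or "bootstrap"
    auc_n_boot: int = 2000
    max_lag: int = 31
    per_lag_pearson: bool = False


@dataclass
class StudyResults:
    """Everything one analysis run produces."""

    group_curves: dict[tuple[float, str], scores.GroupCurve]
    nonoverlap: dict[float, list[int]]  # per strength, 0-based probe indices
    sensitivity: pd.DataFrame
    classifier_evals: list[classify.ClassifierEval]
    stats: dict[str, infer_stats.TestResult]
    config: AnalysisConfig = field(default_factory=AnalysisConfig)


def _protocols_by_strength(
    records: list[ParticipantRecord], protocols: dict[str, ProtocolSpec]
) -> dict[float, tuple[ProtocolSpec, ProtocolSpec]]:
    strengths = sorted({rec.current_mA for rec in records})
    out = {}
    for strength in strengths:
        key = f"{strength:g}mA"
        try:
            out[strength] = (protocols[f"active_{key}"], protocols[f"sham_{key}"])
        except KeyError:
            raise KeyError(f"no protocol pair named active_{key}/sham_{key}") from None
    return out


def analyze_study(
    records: list[ParticipantRecord],
    protocols: dict[str, ProtocolSpec] | None = None,
    config: AnalysisConfig = AnalysisConfig(),
) -> StudyResults:
    """Run the full pipeline over in-memory records."""
    if not records:
        raise ValueError("no participant records to analyze")
    protocols = protocols if protocols is not None else DEFAULT_PROTOCOLS
    by_strength = _protocols_by_strength(records, protocols)

    group_curves: dict[tuple[float, str], scores.GroupCurve] = {}
    nonoverlap: dict[float, list[int]] = {}
    for strength in by_strength:
        recs = [r for r in records if r.current_mA == strength]
        for cond in ("active", "sham"):
            series = [scores.probe_series_from_session(r.sessions[cond]) for r in recs]
            group_curves[(strength, cond)] = scores.bootstrap_group_curve(
                series, n_boot=config.n_boot, level=config.ci_level, seed=config.seed
            )
        nonoverlap[strength] = scores.nonoverlap_probes(
            group_curves[(strength, "active")], group_curves[(strength, "sham")]
        ).tolist()

    sens = sensitivity.sensitivity_table(
        records, by_strength, max_lag=config.max_lag,
        per_lag_pearson=config.per_lag_pearson,
    )
    evals = classify.run_classifiers(
        sens, records, ci_method=config.auc_ci_method,
        n_boot=config.auc_n_boot, seed=config.seed,
    )
    stats = infer_stats.run_inferential_battery(records, sens)
    return StudyResults(
        group_curves=group_curves, nonoverlap=nonoverlap, sensitivity=sens,
        classifier_evals=evals, stats=stats, config=config,
    )


def analyze_directory(
    study_dir: str | Path,
    out_dir: str | Path | None = None,
    protocols: dict[str, ProtocolSpec] | None = None,
    config: AnalysisConfig = AnalysisConfig(),
) -> StudyResults:
    """Read a study directory, analyze it, optionally write result files."""
    records = data_io.read_study(study_dir)
    results = analyze_study(records, protocols=protocols, config=config)
    if out_dir is not None:
        data_io.write_results(results, out_dir)
    return results
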