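# shamtrack

Online assessment of sham blinding in transcranial direct current
stimulation (tDCS) studies.

Most tDCS experiments rely on a *fade-in, short-stimulation, fade-out*
sham protocol and check blinding with a single **end-of-study guess**
("which session was sham?").  `shamtrack` implements an alternative,
time-resolved assessment built on *online probes*: during and after
stimulation the participant is asked every 30 s "Is the stimulation on?"
(yes/no) and "How sure are you?" (0–10), giving 32 probe points over a
16 min window.  The package quantifies, for each participant-session, how
well those answers track the true on/off time course of the current — and
evaluates which variables (congruence, current strength, the end-of-study
guess) actually classify that sensitivity.

## Method

**Weighted scores.** Each probe answer becomes a signed score
*w* = (±1 for yes/no) × confidence ∈ [−10, +10].  Per condition, the
group median score per probe is plotted with a 95% bootstrap confidence
band (participants resampled with replacement, 5,000 resamples,
percentile interval); probes where the active and sham bands do not
overlap mark failed blinding.

**Sensitivity.** A participant's weighted-score series *y* is compared
with the protocol's *ideal response curve* *x* (+10 while any current
flows — ramps included — and −10 otherwise) by normalised lagged
cross-correlation after linear detrending:

```
r(m) = Σₙ x(n) · y(n+m) / √(Σ x² · Σ y²),   m = −31 … +31
```

(the MATLAB `xcorr`/"coeff" convention: zero padding, one global
normaliser).  The signed maximum over lags, **peak r**, is the
participant's sensitivity; its lag absorbs reporting delay.  Each session
gets a *congruent* coefficient (own condition's ideal) and an
*incongruent* one (opposite condition's ideal).

**Classification.** ROC curves ask how well three binary variables
separate peak-r values: congruent vs. incongruent, 2 mA vs. 1 mA, and
correct vs. incorrect end-of-study guess.  AUC is the Mann–Whitney
probability P(score₊ > score₋) + ½P(tie); confidence intervals and
p-values against AUC = 0.5 use the Hanley–McNeil normal approximation
(participant bootstrap available).

**Inference.** The accompanying battery covers ΔRT (block median
reaction time minus baseline; paired and Welch t tests, one-tailed where
the hypothesis is directional, Bonferroni-adjusted α = 0.05/3), Wilcoxon
signed-rank tests of five side-effect ratings, a mixed 2×2 ANOVA (current
strength × stimulation type) and a fully within-subject 2×2 ANOVA
(stimulation type × congruence) with partial η², and per-stratum Pearson
correlations between sensitivity and ΔRT.

**Synthetic studies.** `shamtrack.synth` generates complete studies (64
participants: 32 at 1 mA, 32 at 2 mA, one active and one sham session
each) from a minimal perception model: current amplitude attenuated by
exponential habituation, detected through a noisy logistic threshold,
with log-normal inter-individual gains.  Every coupling (guess ↔
sensitivity, sensation ↔ reaction-time distraction) is a switch, so each
qualitative phenomenon can be produced or ablated at will.  See
`docs/methods.md` for the model and its limits.

## Worked example

```python
from shamtrack import AnalysisConfig, StudyDesign, analyze_study, simulate_study

records, truth = simulate_study(StudyDesign(), seed=1)
results = analyze_study(records, config=AnalysisConfig(n_boot=5000, seed=1))

sens = results.sensitivity
congruent = sens[sens.reference == "congruent"]
print("mean congruent peak r:  %.3f" % congruent.peak_r.mean())
print("mean incongruent peak r: %.3f"
      % sens[sens.reference == "incongruent"].peak_r.mean())
print("non-overlapping probes at 2 mA:", len(results.nonoverlap[2.0]))
for ev in results.classifier_evals:
    if ev.classifier == "guess_accuracy":
        print("guess-accuracy AUC (%s): %.2f [%.2f, %.2f], p = %.2f"
              % (ev.condition, ev.auc, ev.ci_low, ev.ci_high, ev.p_value))
```

prints

```
mean congruent peak r:  0.593
mean incongruent peak r: 0.465
non-overlapping probes at 2 mA: 20
guess-accuracy AUC (active): 0.45 [0.26, 0.64], p = 0.60
guess-accuracy AUC (sham): 0.52 [0.33, 0.71], p = 0.85
```

Participants track their own protocol better than the opposite one
(congruent > incongruent), blinding fails for 20 of the 32 probes at
2 mA — yet the end-of-study guess classifies sensitivity at chance: the
traditional blinding check misses what the online probes see.

## Command line

```sh
shamtrack simulate --out study/ --seed 7            # synthetic study (CSV)
shamtrack analyze study/ --out results/ --seed 7    # full pipeline
```

`analyze` expects a directory with `probes.csv`, `trials.csv` and
`participants.csv` (schema documented in `shamtrack.data_io`) and writes
`sensitivity.csv`, `group_curves.csv`, `classifiers.csv` and
`stats.json`.  Mapping an existing deposit's native file layout onto this
schema is the job of a small study-specific adapter.

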