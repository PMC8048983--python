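# Methods

This note documents the models, conventions and design choices behind
`shamtrack`: what each stage computes, which knobs matter, what the
synthetic-data generator does and does not emulate, and the numerical
edge cases.

## Protocols and the ideal response curve

A protocol is ramp-up / plateau / ramp-down with a plateau amplitude in
mA.  The shipped defaults are the standard pairing: a 10 min active
plateau and a 20 s sham plateau, both with 30 s linear ramps, at 1 mA and
2 mA.  Probes are timestamped at the *end* of each 30 s interval
(30 s, 60 s, …, 960 s); intervals are closed on the right.  This
convention is arbitrary but used consistently everywhere — probe k at
30·k seconds.

The ideal response curve assigns +10 to a probe if **any** current flows
at its timestamp (ramps count as "on", with a closed boundary at the end
of the ramp-down) and −10 otherwise.  Treating ramps as on is the only
reading under which the active on/off boundary falls at 660 s, the point
at which the stimulation block structure places the end of ramp-down.
The ±10 encoding puts the ideal on the weighted-score scale; because the
cross-correlation normalisation is scale-free this choice cannot affect
any coefficient (asserted by test).

## Weighted scores and group bands

`weighted_score(yes, c) = +c`, `weighted_score(no, c) = −c`.  Missing
probes (the response window can lapse) stay missing — they are excluded
from that probe's group median rather than imputed, because imputing
would fabricate perception data and the median tolerates missingness.

Group bands resample **participants** with replacement (n_boot = 5000 by
default, seeded) and take percentile intervals of the per-probe median;
the reported point estimate is the observed median.  Percentile intervals
are used because nothing more specific is warranted for a bounded,
discrete-ish score.  A probe where every participant is missing is
flagged (`n_available == 0`, NaN estimates), never zeroed.  Band
comparison uses closed intervals — curves that merely touch still
overlap, which is the conservative direction when claiming that blinding
failed at a probe.  No multiplicity correction is applied across the 32
per-probe comparisons; the band plot is treated as descriptive, and any
per-probe claim should be read accordingly.

## The sensitivity statistic

Both series are linearly detrended (least squares; residual orthogonal to
constant and ramp), then cross-correlated with zero padding and a single
global normaliser `sqrt(sum x^2 * sum y^2)` — the MATLAB
`xcorr`/"coeff" semantics.  There is **no** per-lag re-centering or
re-normalisation, so coefficients at extreme lags shrink toward zero by
construction.  A true per-lag Pearson variant (re-centred and
re-normalised over the overlap at each lag) is available behind
`per_lag_pearson=True` for sensitivity analysis; it is not the primary
statistic.

Conventions, fixed once:

* **Lag range** is −31…+31.  A 32-sample series admits nothing wider;
  lags of ±32 would have empty overlap and coefficient 0 regardless.
* **Lag sign**: positive lag means the response lags the ideal (a
  response equal to the ideal shifted one probe later peaks at +1).
* **Peak** is the signed maximum, not the maximum absolute value.
* **Ties** in the maximum (possible with coarse data) break toward the
  smallest |lag|, then toward the negative lag.
* **Missing probes** are linearly interpolated before detrending (end
  gaps take the nearest valid value); the interpolation count is carried
  through to `sensitivity.csv` so heavily-lapsed series can be audited.
  Cross-correlation needs complete vectors and interpolation is the least
  structured completion.
* A series that is constant (zero after detrending) has no defined
  coefficient and raises; callers see the error rather than a fabricated
  number.

Because the peak is a maximum over 63 lags, pure noise does **not**
score zero: random ±c responses average a peak near 0.31 (SD ≈ 0.08;
frozen as a regression band in the tests).  Peak coefficients are
therefore compared *between* conditions (congruent vs. incongruent,
2 mA vs. 1 mA…), never against zero.

## Classifier evaluation

AUC is computed as the trapezoidal area under the full empirical ROC
staircase, which equals the Mann–Whitney probability with ties counted
half (the tests verify the identity against pair enumeration).  The
positive class is fixed a priori — congruent / 2 mA / correct guess —
and never flipped to force AUC ≥ 0.5.  The guess-accuracy classifier
pools 1 mA and 2 mA participants; per-strength breakdowns are also
emitted.  Strata whose labels are single-class (or have fewer than two
cases in a class) are omitted with the rest still produced.

Inference uses the Hanley–McNeil SE by default: CI = AUC ± z·SE clipped
to [0, 1]; the p-value is a two-sided normal test against AUC = 0.5 with
the null SE evaluated at 0.5.  A seeded participant-bootstrap percentile
CI (2,000 resamples) is available via `auc_ci_method="bootstrap"`.  These
are approximations — at AUC near the boundaries the normal CI degenerates
(SE → 0 at AUC = 1) — and exact agreement with any particular software's
CIs should not be expected.

## Inferential battery

* ΔRT_b = median correct-trial RT of block b minus the baseline block's
  median, b ∈ {2, 3, 4}; blocks with no correct trials yield NaN and are
  dropped pairwise.  Active-vs-sham paired t tests are one-tailed
  (directional hypothesis: active slows more), Bonferroni-adjusted
  α = 0.05/3; because one-tailed bookkeeping conventions differ, both
  tails' p-values are always reported in `extras`.
* Welch t uses the Welch–Satterthwaite fractional df; Cohen's d is
  reported with the pooled SD.
* The mixed 2×2 ANOVA (between: current strength; within: stimulation
  type) is computed in closed form: with two levels per factor the
  classical decomposition reduces exactly to pooled two-group t tests on
  per-subject means (between), difference scores (interaction) and the
  unweighted grand mean of difference scores (within); F = t² on
  (1, n−2) df, partial η² = F/(F + df₂).  The closed form is verified
  against an independent ANOVA implementation and a manual
  sums-of-squares oracle in the tests, and — unlike a generic ANOVA
  routine — degrades gracefully on zero-variance input (F = 0 when the
  effect is exactly absent, F = ∞ when it perfectly separates).
* The fully within-subject 2×2 ANOVA (stimulation type × congruence)
  likewise uses per-subject contrasts: each effect is a one-sample t on
  the corresponding contrast, F = t² on (1, n−1) df.
* Wilcoxon signed-rank drops zero differences (classical procedure) and
  averages tied ranks; p is exact (full sign enumeration) for n ≤ 25
  with no rank ties, otherwise the normal approximation with continuity
  and tie corrections.  The signed Z from W⁺ is always reported, so
  swapping the samples negates Z.
* Sensitivity–ΔRT Pearson correlations are computed per
  (strength, condition) stratum on block 3 (the end of the stimulation
  period); strata with fewer than 3 complete pairs or a constant
  variable are flagged degenerate, not silently skipped.

The weighted-score series that is detrended and correlated is the only
series the analysis constructs; raw ±1 responses are never analysed
separately from their confidence weighting.

## The synthetic-data generator

The generator emulates the *structure* the analysis assumes — not skin
biophysics.  Perceived intensity is the instantaneous current amplitude
(linear ramps, plateau) attenuated by `exp(−t/τ)` habituation; from the
end of the plateau the sensation decays linearly to zero over
ramp-down + persistence, a lingering tail that outlasts the current and
keeps the curve continuous.  At each probe the participant detects this
intensity through a logistic with gain g and threshold θ plus AR(1)
perceptual noise; the answer is a coin flip at that probability, and the
reported confidence is `10·|2p−1|` plus Gaussian noise, clipped to
[0, 10].  The noise is AR(1) (lag-1 correlation 0.8 across probes)
rather than i.i.d. because percepts are coherent in time: a participant
who has stopped feeling the stimulation keeps saying so, rather than
flickering every 30 s.  With i.i.d. noise the long near-threshold
stretch of a 1 mA active session degenerates into coin-flipping that no
real participant produces.

Defaults (population level):

| parameter | default | units | why |
|---|---|---|---|
| gain median | 6.0 | 1/mA | logistic steep enough that responses form coherent on/off runs, yet the log-normal spread (log-SD 0.6) spans near-random to near-perfect trackers |
| gain 2 mA multiplier | 1.4 | — | higher currents are easier to feel, so current strength classifies sensitivity |
| session jitter | 0.15 | log-SD | gain shared within participant up to jitter, inducing a positive active–sham sensitivity correlation |
| habituation τ median | 500 | s | with θ = 0.4 mA the perceived offset of a 2 mA active session falls in the ramp-down tail (~660 s) and of a 1 mA session near 6 min — the published perceived-offset boundaries of these protocols |
| threshold θ | 0.4 | mA | below the 1 mA plateau, far above zero: both strengths are felt at onset |
| persistence | 30 | s | sensation briefly outlasts the current |
| response noise σ_r | 1.0 | logit units | probe-to-probe perceptual noise |
| confidence noise σ_c | 1.5 | score units | reported confidence is not a clean function of detection |
| lapse rate | 0.02 | — | occasional missed response windows |

Reaction times are ex-Gaussian (μ 450 ms, σ 50 ms, τ 100 ms; 100
baseline trials, 60 per stimulation block, 95% correct) — canonical
simple-RT values, as the analysis only consumes block medians.  The
*distraction coupling* (default 60 ms) slows a block's trials in
proportion to the participant's realised detection salience of that
block (mean of max(2p−1, 0) over its probes), active 2 mA only.  Tying
the slowing to the same noisy percept that drives the probe answers is
what makes sensitive participants — and only they — slow down, producing
a positive sensitivity–ΔRT correlation in the 2 mA active stratum and
none elsewhere.  A consequence worth knowing: with the coupling on, the
synthetic 2 mA active blocks are also slower *on average* than sham,
which is a stronger mean effect than a real study need show; set
`distraction_coupling_ms=0` to ablate both.

The end-of-study guess is correct with probability
`guess_base_rate + κ·(tracking accuracy − 0.5)` clipped to [0, 1], where
the tracking accuracy is the fraction of non-missing probes matching the
participant's own ideal curve, averaged over both sessions.  The base
rate (default 0.75) reproduces a realistic overall guess accuracy, and
the default κ = 0 decouples the guess from sensitivity entirely — the
regime in which the guess-accuracy classifier must and does sit at
chance AUC.  Side-effect ratings are ordinal clips of a Gaussian latent
with a dose term (current × on-time fraction) that is strong only for
itching, so only itching reliably separates active from sham.

What the generator does **not** emulate: sequential/order effects across
sessions, learning or expectation, any relationship between side-effect
ratings and probe responses, electrode-site specifics, or non-stationary
lapse behaviour.  Passing tests therefore show that the *pipeline*
behaves correctly on data with the assumed structure — they are not
evidence about any particular real dataset.

## Problem sizes and determinism

The test suite and the acceptance script run everything at the design's
native size (64 participants, 32 probes, 5,000 bootstrap resamples) for
single runs; Monte Carlo calibrations use 200–1,000 replicates with
study-size or statistic-size scaled to keep each check in seconds.  All
randomness flows from explicit seeds through `numpy.random.Generator`;
a fixed seed reproduces a study byte-for-byte, including its CSVs.

## Known limitations

* The Hanley–McNeil CI is a normal approximation; near-boundary AUCs get
  degenerate intervals.
* The cross-correlation's global normalisation makes peak values depend
  on series length and on-time geometry; comparisons are only meaningful
  within a fixed probe schedule.
* The exact Wilcoxon path is skipped in the presence of rank ties (the
  normal approximation with tie correction is used instead), so p-values
  for heavily tied ordinal data are approximate.
* The perception model is deliberately minimal; its parameters are not
  intended to be fit to real data, only to generate structurally
  faithful test beds (parameter estimation happens solely through the
  cross-correlation statistic).
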