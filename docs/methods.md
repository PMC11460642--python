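# Methods

This note documents the models, conventions and numerical choices behind
`cogload`: what the simulator generates, how the analysis chain interprets
it, and where design decisions were genuinely open.

## Task battery and scheduling semantics

The battery is fixed: a 2-minute stimulus-free baseline, then four 2-minute
task blocks (S, SV, C, CV) of 30 stimuli each, 0.5 s exposure, with fixed
2 s or uniform 2–5 s inter-stimulus intervals and, in cognitive blocks, 6
red targets among 24 non-targets.

Three timing conventions are ours, because the published design leaves them
open:

* **ISI convention.** The inter-stimulus interval is the *offset-to-onset*
  gap (stimulus disappears, gap elapses, next appears). Consecutive onsets
  in fixed mode are therefore 2.5 s apart, and the first stimulus appears
  after one gap. This matches the usual usage in reaction-time paradigms.
* **Block padding.** In fixed mode the 30th stimulus ends at 75 s; the
  remaining time to 120 s is stimulus-free. In random mode a gap sequence
  can overrun 120 s (worst case 165 s, typically ≤128 s); the block window
  is then extended to the last stimulus offset so the stated stimulus count
  is always preserved and every block has a well-defined window.
* **Target placement and colours.** The 6 target slots in cognitive blocks
  are a uniform draw without replacement (no adjacency constraint);
  non-target colours cycle round-robin through black/green/yellow/blue.

Seeding is hierarchical: a session seed spawns per-block sub-seeds through a
counter-based `SeedSequence` derivation, so any block is reproducible in
isolation.

## Synthetic participant model

The simulator is deliberately minimal: each physiological channel has
exactly the degrees of freedom the analysis chain measures, so every
analysis output has a known injected value.

* **Heart rhythm.** IBI_i = μ + A·sin(2πf·t_i) + ε_i, with μ = 800 ms,
  a slow sinusoid (A = 20 ms, f = 0.1 Hz) as the long-range SDNN driver, and
  white Gaussian jitter ε (σ = 30 ms, scaled per block) driving the
  short-range metrics. Closed forms used for calibration: SDNN → σ,
  rMSSD → σ√2, and pNNx → 100·2Φ(−x/(σ√2)) as the beat count grows.
  Intervals are clipped to the physiological 300–2000 ms range. The beat
  train is continuous across blocks; an interval spanning a boundary is
  drawn with the next block's jitter factor and assigned (by the analysis
  convention below) to the block of its first beat.
* **Block modulation.** Jitter factors {S 1.12, SV 0.94, C 1.10, CV 0.96}
  encode the study condition the battery is meant to elicit: vagally
  mediated HRV slightly up in fixed-interval tasks and down in vigilance
  tasks, on the order of ±10 % versus baseline.
* **ECG.** A triangular QRS template (80 ms wide, unit amplitude) at each
  beat, apex on the nearest sample, plus white noise (default SD 0.1, i.e.
  10:1 SNR). No P/T waves, respiration coupling or motion artifacts — beat
  *timing* is the quantity of interest, not morphology.
* **EDA.** Tonic level = 2 µS × block factor {S 2.22, SV 1.82, C 2.37,
  CV 1.75} with linear 5 s cross-fades at block boundaries; these factors
  produce baseline-relative percent changes of roughly +122/+82/+137/+75 %,
  the magnitude pattern the battery elicits (tasks above baseline,
  fixed-interval above vigilance). Each stimulus elicits an SCR with
  probability 0.5, modeled as a Bateman kernel a·(e^(−t/τd) − e^(−t/τr))
  with τr = 0.75 s, τd = 2 s (standard EDA modeling constants), peak
  amplitude 0.3 µS, 2 s latency.
* **Behaviour.** Reaction times are log-normal per (block, stimulus class)
  with medians 544/569/737/709/754/735 ms for S/SV/Ct/Cn/CVt/CVn and
  σ = 0.1 on the log scale (IQR ≈ 75 ms at the simple-task median); misses
  occur with probability 0.02. Draws that would overrun the next stimulus
  onset are truncated and flagged in the ground truth. The participant
  always presses the rule-correct button; error behaviour is out of scope.
* **Sampling.** All four channels share one clock at 500 Hz (configurable).
  Trigger pulses are 50 ms, response pulses 100 ms, ±1 V; Button-1
  (simple/target) is −1 V, Button-2 (non-target) +1 V, following the
  convention that downward deflections mark target responses.

All cohort members share these defaults and differ only by seed, so
between-participant variance comes entirely from sampling noise. Real
cohorts add stable individual differences (baseline HRV and SCL levels,
speed-accuracy trade-offs, habituation across blocks); passing tests here
show the *pipeline* preserves injected effects, not that the effect sizes
generalize to humans.

## Analysis conventions

* **R-peak detection** uses the classic band-pass → derivative → square →
  moving-window integration chain with running signal/noise threshold
  estimates, a 200 ms refractory period, and refinement to the raw-signal
  maximum within ±50 ms. On template ECG at 10:1 SNR this recovers ≥99 % of
  beats within ±10 ms.
* **IBI cleaning** drops intervals outside 300–2000 ms or deviating >25 %
  from the centered running median of five. Successive-difference metrics
  are computed only across *adjacent* retained pairs, so a rejected
  interval never manufactures a spurious difference.
* **pNNx** uses strict inequality ("more than x ms") with the number of
  successive differences as denominator; SDNN uses the n−1 (sample)
  denominator. Per-block metrics take the intervals whose first beat falls
  in [block start, block end).
* **SCL** is the plain block mean including phasic activity. **SCR scoring**
  is trough-to-peak: the maximum rise above the value at 1 s post-onset,
  within 1–5 s, threshold 0.05 µS, at most one SCR per stimulus. Two known
  artifacts of this simple rule: a block's first stimulus can pick up the
  tonic cross-fade as a false response, and with dense stimulation the
  overlapping decay of prior SCRs shrinks measured rise amplitudes
  (detection recall is unaffected at the default event rate).
* **RT matching** accepts the first press in (onset + 100 ms,
  onset + 2000 ms]; earlier presses are anticipations, and each press is
  consumed at most once. Category medians use correct responses only.
* **Percent change** is 100·(task − baseline)/baseline per participant and
  metric; a zero baseline raises rather than propagating infinities. RT has
  no baseline block and is analyzed as raw medians.
* **Vagal-tone split** thresholds at the cohort mean or median of baseline
  rMSSD; values exactly at the threshold go to "low" (the rule matters only
  under ties, which continuous data essentially never produce).

## Statistical layer

Routing follows the conventional within-subject plan at α = 0.05: if
Shapiro–Wilk rejects normality in any condition, the Friedman test (with
tie-corrected mid-ranks; Kendall's W = χ²/(n(k−1))) and median (IQR)
descriptives; otherwise repeated-measures ANOVA with mean ± SD,
Greenhouse–Geisser correction when Mauchly rejects sphericity, and partial
η² = SS_effect/(SS_effect + SS_error). Post hoc comparisons are Wilcoxon
signed-rank on all pairs with Bonferroni adjustment (min(1, p·m)) — chosen
to stay consistent with the nonparametric omnibus. The group × task mixed
design uses the standard split-plot decomposition (delegated to `pingouin`,
verified in the tests against an independent sums-of-squares oracle);
a fully tied Friedman table is defined as "no effect" (χ² = 0, p = 1) since
the tie-corrected statistic is 0/0 there. All-zero difference pairs in the
post hoc are flagged degenerate rather than tested.

## Problem sizes and determinism

Tests run everything on seeded generators: the oracle-equivalence checks use
1,000 random IBI series; calibration checks use 600-beat (rMSSD) and
2,000-beat (pNN50) series with Monte-Carlo tolerance bands of 3 standard
errors, inflated by √2 for the 1-dependence of successive differences;
end-to-end recovery runs a 6-participant cohort in the test suite and the
full 25-participant cohort in `scripts/acceptance.py`; the Friedman type-I
calibration uses 2,000 null cohorts of 25×4. The full
simulate → analyze → stats pipeline for 25 participants at 500 Hz completes
in well under five minutes on one CPU.

## Known limitations

* No inter-participant heterogeneity beyond sampling noise (see above).
* The ECG model cannot probe detector robustness to morphology variants,
  ectopy or electrode artifacts; the cleaning stage is exercised only by
  synthetic spurious/missed beats.
* The EDA model omits slow tonic drift and spontaneous (non-stimulus)
  fluctuations, so SCL estimates are cleaner than field data.
* Frequency-domain and nonlinear HRV are intentionally out of scope.
* Hardware concerns (display latency, analog calibration, real sampling
  clocks) are not modeled; the trigger channel is taken as exact.
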