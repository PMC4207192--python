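# Methods

## The assay being modelled

An isolated segment of mouse colon, perfused in an organ bath and
pressurised to an intraluminal pressure of about 5 mmHg, spontaneously
generates colonic peristaltic motor complexes (CPMCs): discrete propagating
contractions seen by a luminal pressure transducer as large transient
pressure waves. A compound run is a cumulative concentration–response
protocol of successive 15-min phases — vehicle, three increasing bath
concentrations (0.3/3/30 µM by default), washout — with pressure sampled at
100 Hz. Time-matched vehicle-only control experiments run alongside and
supply the null distribution against which drug effects are judged.

## Synthetic trace generator

Real recordings of this preparation are proprietary, so the package carries
a generative model with ground-truth event annotations. Its components, and
what they stand for:

* **Event timing.** Onsets follow a stationary renewal process with
  inter-onset interval `event_duration + Gamma(shape, scale)`, mean exactly
  `mean_interval` (161.4 s default). A gamma renewal (shape 4 default) gives
  the sub-Poisson regularity a rhythmic preparation shows; the additive
  `event_duration` offset doubles as a refractory period, so events can
  never overlap and the renewal mean is preserved exactly (a
  rejection-redraw of close onsets would truncate the interval distribution
  and bias the mean upward by several percent). The process is warmed up for
  20 mean intervals before the phase window so that counts in the window are
  stationary; only onsets inside the window are rendered and annotated, and
  the final pulse may be cut by the phase edge (its annotation records the
  visible peak).
* **Pulse shape.** Each event adds a smooth, compactly supported pulse: a
  raised-cosine *pedestal* carrying a narrower concentric raised-cosine
  *crest*, peaking at `event_amplitude` jittered by a unit-mean lognormal
  (CV 0.10 default). A single raised cosine cannot simultaneously match the
  long above-threshold residence time and the comparatively modest area of a
  real CPMC wave (a sustained pressurisation with a sharper contraction peak
  on top); the two-component shape reproduces both while keeping the
  waveform smooth and detector-neutral.
* **Noise and baseline.** White Gaussian noise (SD 1 mmHg) on a 5 mmHg
  baseline.
* **Vehicle drift.** Preparations deteriorate slowly; amplitude is
  multiplied by `(1 + drift_per_phase)^phase_index` in *every* run, drug and
  control alike (−2%/phase default; the magnitude is a modelling choice
  exposed in the config, as only the existence of a small time-dependent
  amplitude change is documented for the real assay).
* **Drug action.** A compound is a set of Hill effects on generator
  parameters: scaling `s(c) = 1 + (Emax − 1)·cⁿ/(cⁿ + EC50ⁿ)`, applied
  multiplicatively (excitatory) or by division (inhibitory, so parameters
  stay positive for Emax ≥ 1). The washout phase returns instantaneously to
  zero concentration while retaining cumulative drift.

### Default calibration

The defaults are calibrated so that the *full pipeline* — simulate, estimate
baseline, detect, quantify — reproduces the real assay's baseline
statistics on a 99-phase cohort: frequency ≈ 5.6/900 s, TI ≈ 161.4 s,
TIQ ≈ 661 s, amplitude ≈ 49 mmHg, AUC ≈ 6410 mmHg·s. Frequency and TI pin
`mean_interval` = 161.4 s; TIQ and AUC jointly determine the pulse geometry
(duration 59 s, pedestal fraction 0.65, crest width fraction 0.31); the
configured peak (45.25 mmHg) is slightly below the 49 mmHg measured
amplitude because the percentile baseline estimator sits ~1 mmHg below the
true baseline and the peak sample rides the noise. This calibration was
solved once, numerically, against the pipeline itself and frozen. Two small
systematic offsets are inherent and acceptable: detected frequency runs
~0.1 events below the renewal mean (edge events whose onset-threshold
crossing or minimum duration does not fit in the window are dropped), and
measured TI deviates from the renewal mean by ~±2% (interval
window-sampling bias vs. dropped edge intervals).

### What the generator does not emulate

No spatial propagation (a single pressure channel is modelled), no bath
pharmacokinetics (concentration steps are instantaneous), no slow waveform
morphology changes, no inter-tissue heterogeneity beyond amplitude jitter,
and the within-tissue variability parameters (amplitude CV, interval shape)
are calibration choices — the real assay reports only cohort-level
dispersion. Tests passing on synthetic data therefore validate the
*analysis chain* (detection, metrics, decision rule, scoring), not the
biology of any particular preparation.

## Event detection and metrics

The baseline is the 10th percentile of the phase's samples (robust to the
events, slightly low-biased in noise by construction; a warning is emitted
when fewer than 5% of samples sit near the trace minimum, i.e. the phase
never shows quiescence and the estimate is unreliable). Detection is by
hysteresis: an event opens above baseline + 10 mmHg and closes below
baseline + 5 mmHg; candidate regions closer than 2 s are merged, regions
shorter than 5 s are dropped, and edge-truncated events are kept if their
visible portion passes the duration criterion. Thresholds are sized ~5–10×
the default noise SD and well below the ~49 mmHg typical amplitude.

Per phase: frequency = event count; TI = mean onset-to-onset difference
(NaN with < 2 events); TIQ = total time at or below baseline + 5 mmHg, so
TIQ + time-above-band ≡ phase duration; amplitude = mean of (peak −
baseline) over events (the peak is referenced to baseline, not absolute
pressure — a config switch restores absolute readings); AUC = trapezoidal
integral of `max(pressure − baseline, 0)` over the whole phase, in mmHg·s
(the area under a pressure–time curve; baseline-subtracted for robustness
to slow drift). Undefined metrics propagate as NaN markers, never as
silent zeros. Phases use 0-based, half-open `[start, end)` time indexing.

## Decision rule

For TIQ and amplitude, each drug phase's value is expressed as
`100 × (drug − vehicle)/vehicle` relative to the run's *first* (vehicle)
phase — the simplest reading of "corresponding vehicle" under a cumulative
protocol. Controls contribute, per drug-phase index and metric, their own
vehicle-relative changes; the null distribution stores the
across-experiment mean and sample SD (n−1). A phase is positive on a
metric iff `|change − control mean| > 2 × control SD` — two-sided (control
bands are symmetric about the mean) and strict. A compound is positive if
*either* metric is positive (OR rule), assessed at the highest tested
concentration (max-dose scheme) and at the highest concentration within the
50-fold clinical exposure window (therapeutic scheme). A compound with an
empty window is negative-by-window at the therapeutic dose: there is no
admissible evidence at clinically relevant exposure. A planner utility
flags compounds already positive at their lowest concentration for a rerun
at 10-fold lower concentrations; it never merges runs. No multiplicity
correction is applied across the two metrics — the 2-SD rule is used as
the screen defines it.

## Concordance scoring

Clinical findings are restricted to a controlled vocabulary; only diarrhea,
constipation and loose stools count as motility GADRs (nausea does not — a
nausea-only compound is clinically negative here). Categories follow the
usual 2×2: positive/GADR → TP, negative/GADR → FN, positive/no-GADR → FP,
negative/no-GADR → TN; predictive capacity = (TP+TN)/total, displayed to
the nearest percent but stored at full precision. Sensitivity = TP/(TP+FN)
and specificity = TN/(TN+FP). Two schemes are compared by building the 2×2
correct-vs-incorrect table and applying the exact conditional (Fisher)
test; for the published max-dose (7/8) vs therapeutic (9/6) split on 15
compounds this gives p ≈ 0.72. Three panel compounds carry total rather
than free plasma exposure (protein binding unknown, presumed negligible);
their windows use the stated values unchanged and reports flag them.

## Charcoal-meal arm

Transit % = 100 × distance/length (bounded [0, 100]); gastric emptying =
full − empty stomach weight, computed and reported but never classified.
Dose groups are compared to vehicle with a two-sided Wilcoxon–Mann–Whitney
test (two-sided chosen as the conservative default; the direction of a
significant effect is read from the medians, matching the median-based
reporting convention). The exact null distribution is used for tie-free
groups up to size 12 (scipy's exact method — identical to full enumeration,
verified against a brute-force oracle); with ties, direct enumeration over
mid-rank assignments when the assignment count is ≤ 10⁵, otherwise the
tie-corrected normal approximation. Identical constant samples give p = 1.
A compound is assay-positive iff any dose whose measured plasma
concentration falls within the 50-fold window shows a significant change;
effects seen only beyond the window are disregarded. The synthetic transit
generator draws from Normal(53.3, 12.2) truncated to [0, 100] — the
historical vehicle baseline of the source transit database, used as a
calibration value only since that database is proprietary.

## Fixture tables and reproduction

The packaged CSVs transcribe the published 15-compound panel: clinical
findings, % subjects affected and exposure ranges; in vitro tested
concentrations, per-scheme assay positivity and printed outcomes; and
charcoal-meal effects with a within-window flag (one compound's transit
inhibition occurred only at > 1000-fold exposure and is printed with that
caveat) and printed outcomes. `reproduce_paper()` recomputes every GADR
flag, exposure window and category from these inputs and raises, naming
the offending compounds, if any recomputed category disagrees with the
transcribed outcome column. Assay positivity itself is data (transcribed
from the published per-compound results), not something recomputable from
raw traces — those were never released.

## Problem sizes and numerical choices

The calibration cohort is 99 phases of 900 s at 100 Hz (≈ 8.9 M samples),
matching the size of the real baseline characterisation cohort; the
acceptance script runs it in a couple of seconds. Property tests use
500-phase renewal checks, 120-config detector sweeps and 2000-pair null
calibrations of the rank-sum test. All randomness flows from explicit
seeds through `numpy.random.Generator` streams (`spawn` for independent
substreams); identical seeds give byte-identical traces. Tolerances:
calibration is asserted within 3 cohort SEMs per metric; detector
amplitudes within 1% of annotations; exact-test oracles to 1e-9 relative.
Degenerate inputs (zero amplitude → flat trace, < 2 events → NaN metrics,
empty windows, all-tied rank-sum samples) have explicit, tested behaviour.

## Known limitations

The 2-SD rule's false-positive rate under its own empirical null is not a
fixed 5% — with only 4 control experiments the control SD is a noisy
estimate, and the demo reports (rather than asserts) control-cohort
self-positivity. The generator's pulse geometry is one of many that satisfy
the five calibration targets; conclusions that depend on fine waveform
morphology should not be drawn from it. The fixture-based concordance
reproduces published arithmetic exactly but cannot re-derive the underlying
trace-level positivity calls.
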