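# Methods

## Signal model and protocol

A recording is an SmO₂ time series (%, native 0.5 Hz) over an incremental
multi-stage cycling protocol: work stages of 300 s separated by 60 s of
passive rest, workload starting at 1.0 W·kg⁻¹ and rising 0.5 W·kg⁻¹ per
stage. Time is seconds from recording start; phase intervals are half-open
[start, end), so t = 300 belongs to the first rest and t = 360 to the
second work stage. Peak workload Wpeak is the last fully completed stage's
power plus the completed fraction of the final increment; stage workloads
are expressed as %Wpeak. Workload increments are kept as exact decimals of
W·kg⁻¹; absolute watts are rounded only for display.

## Preprocessing

The analysis series is the native signal smoothed with a symmetric moving
average of 5 s total span and resampled to 1 Hz. Since 1 Hz exceeds the
native rate, "to 1 Hz" is an upsample; we smooth on the native grid and
then interpolate linearly, recording both choices in trace metadata. Edge
windows shrink rather than truncate, so the final-30-s work baseline is
never shortened. Missing samples (NaN) are excluded from window means; an
all-missing window stays missing, and resampled points bracketed by a
missing smoothed sample stay missing (no interpolation across gaps).

Quality screening flags both endpoints of any sample-to-sample jump larger
than 10 %SmO₂ — roughly an order of magnitude above the rest-phase slopes
the generator produces — and is idempotent because flagging never alters
the signal. A bout whose recovery window has more than 50% missing/flagged
samples is excluded (MISSING when samples are absent, QUALITY_FAIL when
they are present but flagged).

## Bout extraction

- **Baseline Y_A**: arithmetic mean of usable samples in the last 30 s of
  work. Computed on the smoothed series, like everything downstream, so the
  parametric and nonparametric estimates come from one pipeline.
- **Peak Y_B**: earliest sample in the recovery window with no *strictly*
  higher sample in the following 30 s (equal values do not disqualify an
  earlier peak; ties go to the earliest time). Implemented with a monotone
  deque (sliding-window maximum, O(n)); the tests hold it against an O(n²)
  brute-force scan. A peak whose 30-s lookahead is cut short by the window
  edge is accepted but flagged `truncated_lookahead`.
- **HRT**: first crossing of Y_A + (Y_B − Y_A)/2 after work end, linearly
  interpolated between the bracketing samples. Interpolation removes the
  ±1 s quantization a first-sample-at-threshold rule would carry at 1 Hz.
  HRT is invariant under positive affine rescaling of the signal.
- **Stage selection**: per participant × trial × site, the stage nearest
  each target %Wpeak within ±6% (configurable); under the default 7-stage
  ramp the targets 50/75/100% are hit exactly.

## Monoexponential fit

y(t) = y₀ + A(1 − e^−(t−TD)/τ) for t ≥ TD (y₀ below), fitted by bounded
least squares on the segment from work end to the detected peak, with a
deterministic multi-start grid τ ∈ {2, 5, 10, 20, 40, 80} s ×
TD ∈ {0, 5, 15} s to avoid local minima. TD is bounded below by zero; fits
pinned at TD = 0 are valid. Pseudo-R² = 1 − SS_res/SS_tot with SS_tot about
the segment mean. Acceptance requires pseudo-R² ≥ 0.85 and a plausible mean
response time 0 < MRT = TD + τ < t_peak. Note that a slow bout in a
truncated recovery window can fit perfectly in shape yet fail the MRT
bound; that is the intended behaviour of the plausibility rule, and the
clean-data tests assert exactly this split. The analytic half-recovery time
of an accepted fit is TD + τ·ln 2.

## Reliability battery

All agreement statistics come from the two-way mean squares of the
participants × k-trials matrix (rows with a missing trial dropped
listwise, n ≥ 3):

- ICC(2,1) — two-way random effects, absolute agreement, single measure —
  with the F-based (McGraw–Wong) 95% CI; interpretation bands 0.5 / 0.75 /
  0.9.
- SEM = √MS_E, in seconds, rather than SD·√(1−ICC): the ANOVA form is the
  agreement-consistent companion to ICC(2,1). CI from chi-square bounds on
  MS_E; MDC = 1.96·√2·SEM exactly.
- Between-participant CV uses participant trial means (trials pooled within
  participant by mean before medians/CV; switchable in principle, recorded
  here); within-participant CV is the RMS of per-participant trial CVs.
- Quartiles use linear interpolation between order statistics (type 7);
  reported Q₁–Q₃ depend on this rule, hence it is fixed and documented.

The descriptive table counts participants with at least one usable trial;
the reliability table counts complete pairs, so its n is never larger.

## Synthetic data generator

The generator is the package's stand-in for study recordings and defines
the default study conditions: 21 participants × 2 trials × 4 sites over a
7-stage ramp, body mass drawn from N(69.6, 11.3²) kg. The clean signal is
piecewise exponential: during work SmO₂ relaxes toward
baseline − depth·(%Wpeak/100) with time constant `deoxy_tau_s`; during
rest, after a site-specific onset delay, it relaxes back toward the
pre-work baseline (no overshoot by default; an overshoot parameter exists)
with τ(p) = τ_base·(1 + slope·(p − 0.5)), p the fractional %Wpeak.
Integration splits each 2-s sample step at phase-boundary events, so the
emitted samples follow the exact piecewise-exponential solution with no
onset quantization.

Accessory sites (PS, DL) continue recovering for `work_onset_delay_s`
(30/45 s) into the next work stage — the muscle-pump effect that motivates
their extended recovery window — so their peaks fall inside that window.

Variability structure: participant τ-factor lognormal(0, 0.35) shared
across sites (recovery speed is a whole-body trait, which also stabilizes
between-site comparisons), an extra per-site participant jitter
lognormal(0, 0.12), a per-trial factor lognormal(0, 0.20), participant
amplitude factor lognormal(0, 0.10), baseline shift N(0, 3 %), and additive
Gaussian sample noise of 1.5 %SmO₂, clipped to [0, 100]. Lognormal factors
keep τ positive; the default site profiles

| site | τ_base (s) | slope | delay (s) | depth (%) | baseline (%) |
|------|-----------|-------|-----------|-----------|--------------|
| VL   | 11.5      | 2.26  | 0         | 40        | 70           |
| RF   | 23.1      | 1.75  | 2         | 35        | 70           |
| PS   | 30.3      | 1.23  | 5         | 25        | 65           |
| DL   | 40.4      | 0.43  | 8         | 20        | 60           |

were set once so that the analytic HRT (delay + τ·ln 2, window truncation
included) lands in the ranges reported for trained cyclists — fastest VL,
ordering VL < RF < PS < DL, slowing with workload except in the DL.

Seeding is counter-based: each participant/site/trial draws from its own
`SeedSequence([seed, stream, indices…])`, so adding a participant never
perturbs existing traces and identical configs give byte-identical CSVs.

What the generator does **not** emulate: optical physics and adipose-layer
effects, non-exponential (e.g. sigmoidal or biphasic) recoveries, drift,
cadence coupling, or correlated noise. Passing tests therefore demonstrate
the correctness of the extraction and reliability machinery under the
assumed signal model, not device-level validity on real recordings.

## Numerical choices and problem sizes

Closed-form HRT checks use single-bout schedules whose first rest lasts
≥ 12τ, so the recovery effectively completes and the extracted HRT can be
compared to τ·ln 2 (tolerance: one analysis sample, 1 s; residual error is
dominated by the ~0.1–0.3 s smoothing shift of the onset corner).
Parameter-recovery fits use the raw noiseless segment, where the model is
exact. The peak-rule equivalence check runs 1,000 random-walk series; the
ICC variance-component check uses a 500-row matrix (Monte-Carlo tolerance
0.05). Full-study runs (168 traces, ~2,700 s each) take a few seconds.

## Known limitations

- The τ(p) workload dependence is linear in %Wpeak; real kinetics may be
  convex at high intensity.
- The MRT plausibility bound couples acceptance to window length, so
  nonconformity fractions are not comparable between sites with different
  window rules.
- SEM via √MS_E and the trial-pooling choice for descriptives are each one
  of two defensible conventions; both are fixed and documented above.
- Out of scope by design: expired-gas/V̇O₂ analysis, the mixed-effects
  workload×site model and its contrasts, skinfold covariates, total[HbMb],
  and physiological interpretation.
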