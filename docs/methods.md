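# Methods

## The coupled-CPG model

Two planar oscillators share one vector-field family

    dx/dt = y
    dy/dt = γ² a − γ² x + γ y − γ x² y + γ² α_ji y_j

built so that (a, 0) is the unique fixed point and the linearisation has
trace γ(1 − a²) and determinant γ²: Hopf bifurcations occur exactly at
a = ±1, enclosing a limit-cycle band.  In rescaled time τ = γt the
oscillator is a unit-μ van der Pol system, so the free-running period is
≈ 6.66/γ s and the cycle spans x ≈ [−2, 2] essentially independently of a
inside the band.  The respiratory oscillator (γ₁ ≈ 2–3, a₁ ∈ [−0.1, 0.1])
therefore always breathes at ~γ₁/6.66 Hz, while the laryngeal oscillator
(γ₂ = 25, a₂ ∈ [−1, 1]) crosses its Hopf boundaries exactly at the ends of
the drive range.

Conventions this package fixes where the source is silent:

* **Time units** — seconds; γ carries units of 1/s.
* **Coupling indices** — α₂₁ = 4 is laryngeal→respiratory (it must be the
  strong one: only the fast oscillator breaking breaths into minibreaths
  explains twitters), α₁₂ = 0.015 respiratory→laryngeal.  The reverse
  assignment was tested and rejected: feeding 4·y₁ into the stiff laryngeal
  equation diverges numerically for all tested grids.
* **Initial conditions** — the instantaneous fixed point
  (a₁(0), 0, a₂(0), 0) plus a perturbation of 1e-3 on x₁ and x₂
  (configurable), so limit cycles are entered from rest.
* **Integration** — classic fixed-step RK4, dt = 0.01 s, 500 burn-in +
  2,000 kept steps for sweep cells (all configurable).  Time-dependent
  drives are evaluated at t, t + dt/2, t + dt within each step.  Blow-ups
  abort with the step index (single runs) or mark the cell as `error`
  (sweeps); states are never clipped.
* **Determinism** — the integrator accepts a `seed` argument for interface
  uniformity with the stochastic stages, but the model has no noise terms.

Numerical behaviour worth knowing: the integrator shows textbook 4th-order
self-convergence (error ratio ≈ 16 per dt halving), but over a 20 s window
the accumulated phase error of the fast laryngeal cycle at dt = 0.01 is
O(1) in state space.  Endpoint states of long runs are therefore not
comparable across step sizes; phase-insensitive statistics (amplitudes,
spectra, breath intervals — everything classification uses) are stable.

## Regime classification

The published regions carry no numeric cutoffs, so the classifier is this
package's design, built on the duration/frequency reading (regimes are
identified from the respiratory trace x₁, whose rhythm sets call duration):

1. **twitter** — the minibreath-scale band (≥ `fast_band_hz` = 1.5 Hz)
   holds at least `resp_mod_min` = 0.5 of x₁'s non-DC power (respiration is
   broken into minibreaths).
2. **trill** — the mean interval between prominent x₁ maxima
   (prominence ≥ 1.5, spacing ≥ 0.3 s) is shorter than 1/1.35 of the intact
   γ₁-implied period 6.66/γ₁, while the laryngeal trace oscillates in the
   fast band (high-passed x₂ peak-to-peak ≥ `lar_osc_min` = 0.5): breaths
   are shortened but not broken.
3. **contact** otherwise — slow intact breathing; *immature* below mean
   drive 0.5, *mature* above.

`fast_band_hz` is deliberately a fixed 1.5 Hz rather than a multiple of the
γ₁-implied breathing frequency: the relaxation-shaped breath has strong
harmonics at 2×–4× its fundamental, so any cutoff tied to the fundamental
leaks slow-cycle power into the "fast" band.  1.5 Hz sits between the
fastest intact breathing fundamental in the swept range (~0.5 Hz at
γ₁ = 3) and the slowest laryngeal modulation observed (~2 Hz).

An important empirical fact about the model under *sustained* drive: the
laryngeal oscillator is excited over essentially the whole interior of the
drive range (its Hopf boundaries sit exactly at a₂ = ±1 and the weak
respiratory forcing pushes the effective drive across them), so laryngeal
amplitude itself carries no regime information.  What distinguishes the
regimes is whether that laryngeal activity *disrupts respiration* — which
is γ₁-dependent, because the minibreath response amplitude scales with γ₁².
That is precisely the developmental axis: slow (heavy) lungs decouple
breathing from laryngeal interference.

## Regime diagram and developmental sweep

The default sweep covers γ₁ ∈ [1.2, 2.4] (step 0.025) × I ∈ [0, 1]
(step 0.01) at constant drive per cell, batched so the whole grid
integrates in seconds.  This γ₁ window is where the constant-drive model
transitions from "contact everywhere" to "twitter-dominated": below ~1.4
the laryngeal cycle cannot disturb the slow breath anywhere; above ~2.2
almost every interior cell is minibreath-broken.  The nominal γ₁ range 2–3
and the 3.4/3.1/2.8 demonstration values describe ramped-drive runs, where
the finite ramp time shifts the transition upward; under the sweep protocol
the dynamic range sits lower, and the sweep must cover it to expose the
developmental trend.  Proportions per γ₁ row are the fractions of the
I-range labelled with each type; trill+twitter width shrinks monotonically
(within one-cell speckle) as γ₁ decreases, and contact mirrors it.

## Day map

PND = β₀ + β₁ γ₁ is fitted by minimising the summed squared difference
between simulated trill/twitter proportions (over the whole γ₁ grid) and
the observed proportions linearly interpolated at the mapped days (clamped
at the ends of the observed span).  The optimiser is a coarse grid over
endpoint mappings followed by Nelder–Mead — the objective is cheap and
interpolation kinks defeat gradient methods.  R² is reported pooled over
both call types (default) and per type.

**Known limitation.** Against developmental proportions on the data's
scale (trill+twitter ≈ 0.45 at day 1, → 0 by day 60), the constant-drive
diagram's proportions are structurally too large: wherever the laryngeal
cycle entrains respiration the fast regimes cover ~0.9 of the I-range.  No
affine day map can reconcile that scale mismatch, so the pooled R² of the
full pipeline is strongly negative rather than near the fit quality
reported for the original recordings — whose sweep protocol internals
(initialisation, classification cutoffs) are not public.  The package
reproduces the *structure* (regime layout and both monotone developmental
trends) and reports the fit quality it actually measures.

## Wilson–Cowan lung loop

    τ dE/dt = −E + S(c_ee E − c_ei I + E₁ − k V)
    τ dI/dt = −I + S(c_ie E − c_ii I + E₂)
    m d²V/dt² = −d dV/dt − s V + μ E,     S(x) = 1/(1+e^−x)

E₁ = E₂ = −2, τ = 0.31 s, k = 5, μ = 1 are the published values; the
within-network weights (16, 4, 10, 3) and mechanics (s = 0.5, d = 0.3) are
this package's architecture-level choices, since the source specifies the
architecture (excitatory–inhibitory network driving a lung whose volume
feeds back negatively on the excitatory unit) but not the full functional
forms — the implementation is an architecture-faithful stand-in.  The
defaults are chosen so the *mechanical recoil*, not the neural time
constant, paces the loop: weak resting inhibition keeps the excitatory unit
excitable at the subthreshold bias, inflation (k·V) switches it off, and
the lung's underdamped, compliant recoil (deliberately not the
critically-damped scale, which parks the loop at a fixed point) sets when
it re-ignites.  That is what makes the rhythm inherit the lung's inertia:
the period rises strictly with mass (7.3 s → 14.6 s over 1×–4×), the claim
the module exists to establish.  Cycle period is the mean inter-peak
interval of the post-transient volume; fewer than three complete cycles or
a flat trace raise `NoOscillationError`, distinct from numerical failure.

## Heliox statistics

* **Grouping** — consecutive same-type syllables with gaps ≤ 0.5 s form one
  call; a type change always splits.  Overlapping syllables are an input
  error.
* **Proportions** — per (subject, consecutive-session pair, condition):
  count of type / total calls in that condition; the abscissa is the mean
  of the paired days.
* **Occurrence GLM** — binomial, logit link, one row per call
  (syllable-level via the input table if desired); intercept + subject
  dummies (first subject is reference) + heliox indicator.  Effect size:
  in-sample AUC ratio of full vs condition-free models (no
  cross-validation — a model-comparison statistic, not a prediction claim).
  The ratio divides by (AUC₀ − 0.5) and is undefined (signalled) when
  subject identity alone does not beat chance; summaries over replications
  should use medians.
* **Duration model** — contact-syllable durations as fractions of the same
  subject's same-day air mean (days lacking air calls are dropped and
  reported); OLS with the same design.  β₃ is the fractional change
  (−0.11 = 11% shortening).  Cohen's f² from full-vs-reduced R²; power is
  re-derived analytically from the noncentral-F distribution of the partial
  F-test (no external power software).  The air-mean normalisation shares a
  noisy denominator within day cells, so empirical β₃ dispersion runs ~10%
  above the model SE — visible in the calibration rates.
* **Call rate** — Wilcoxon signed-rank on paired per-session rates;
  identical pairs give p = 1 by convention.
* **Spectra** — Welch PSD (1024-sample Hann segments, 50% overlap,
  mean-removed; all logged in config).  F0 = first spectral peak,
  F1 = second; the F1/F0 ratio in dB integrates ±1 bin around each peak
  (off-bin tones leak into neighbours) and equals 20·log₁₀ of the amplitude
  ratio, computed as 10·log₁₀ of the power ratio — on a PSD the amplitude
  and power conventions coincide numerically.
* **Respiration rate** — peaks (prominence ≥ 0.2 of range) inside the
  merged call windows, divided by total call duration; 100 Hz sampling.
* **Multiple testing** — none: raw per-model p-values are reported,
  mirroring how the individual tests are used.

## Synthetic generators: what they emulate and what they do not

The developmental generator produces 13 subjects / 244 sessions over days
1–60; call types follow a day-dependent multinomial logit (contact rising
from ~0.5 to ~0.95; trill and twitter falling to a few percent) with
per-subject intercept noise (sd 0.3 logits); contact syllable durations are
log-normal with median 0.5 s + day/60 s; trill and twitter are
multi-syllable with short medians (0.12 s, 0.05 s).  The heliox generator
produces 3 subjects with 19/19/27 sessions (every other day,
counterbalanced order); heliox adds trill/twitter log-odds boosts and
multiplies contact durations by 0.89.  The default boosts (0.515, 0.569)
are solved so that, under the session design and the pipeline's own
estimator (mean of per-cell proportions), the expected relative increases
equal the study conditions +36.5% and +41.8%.  Per-session call counts are
negative binomial (overdispersed; the real distributions are unpublished —
these are stated conventions, not measured values).

What the generators do **not** emulate: real marmoset acoustics beyond a
harmonic stack, arousal autocorrelation within sessions, subject-specific
developmental *rates*, and — critically — the discriminability structure
that sets the published AUC-ratio effect sizes (0.134, 0.266) and Cohen's
f² (0.13).  Passing tests therefore demonstrate that the pipeline recovers
known injected effects with calibrated uncertainty (recovery within 2 SE in
≥ 90/100 seeds; type-I ≤ 7% at nominal 5%), not that it would reproduce
those recording-specific effect-size magnitudes.

## Problem sizes

Default test and acceptance runs use: the 40 × 50 (γ₁ × I) sweep at the
full 500 + 2,000-step protocol; ten heliox realisations (~3,000 calls each)
for the condition-effect readouts; 100 seeds of a reduced design
(3 subjects × 8 sessions, ~30 calls per condition, flat day mixture so the
injected multinomial log-odds equals the binary-GLM estimand exactly) for
the calibration rates.  The whole suite runs in about two minutes on one
CPU; the acceptance script in under one.
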