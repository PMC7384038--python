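# Methods

This note documents the models behind `fluctlight`, the defaults and why
they were chosen, what the synthetic generators do and do not emulate, and
the numerical conventions of each fitter.

## The fluctuating-light (FL) assay

A dark-acclimated leaf is stepped through four constant-light phases —
very low light (VLL, 57 μmol photons m⁻² s⁻¹, 10 min), first low light
(LL1, 166, 10 min), high light (HL, 1466, 3.5 min) and a second low light
(LL2, 166) prolonged until NPQ is steady — with saturating pulses every
30 s (8000 μmol photons m⁻² s⁻¹) reading F′ and Fm′. The ECS variant used
for proton-flux analysis runs LL1 → HL (1287) → LL2 → 30 s darkness, with
its clock starting at LL1 onset, which places the LL2 I535 analysis window
at 900–1100 s. The two HL intensities (1466 vs 1287) are kept as separate
protocol presets (`fl_protocol`, `dirk_protocol`); the package does not
attempt to reconcile them.

A pulse falling exactly on a segment boundary belongs to the segment it
terminates, so the 210-s HL phase contains exactly 7 pulses at the 30-s
cadence. "End of segment" always means the last pulse of that segment.

## Quenching model of the PAM simulator

The generator is phenomenological, not mechanistic: it reproduces the
kinetic structure that the downstream fitters assume, with retrievable
ground truth, and nothing more.

Each reversible NPQ component q ∈ {qE, qZ} relaxes with first-order
kinetics toward a light-dependent target

    q*(I) = A · I / (I + K),      K = light_half_sat (default 250),

using τ_on when rising and τ_off when falling. Defaults: qE
τ_on = τ_off = 25 s (within the expected 20–30 s range); qZ τ_off = 400 s
(the qZ relaxation scale resolved by the LL2 fit) and τ_on = 60 s.
The asymmetric qZ constants reflect the underlying xanthophyll cycle —
zeaxanthin forms within ~1–2 min under lumen acidification but is
epoxidised back over many minutes — and they make the 10-min VLL/LL1
phases reach quasi-steady state, which the FL-photodamage statistic
(difference between two steady levels) structurally assumes. Persistent
quenching qI accumulates linearly over each HL segment by a configurable
step (default 0) and never relaxes; it is a step pool rather than a
kinetic one because only its LL2 steady-state signature is analysed.

Fluorescence synthesis per pulse:

    NPQ = qE + qZ + qI
    Fm′ = Fm_dark / (1 + NPQ)
    Φ2  = Φ2_max · 1/(1 + NPQ) · 1/(1 + I/I_sat),   I_sat = 700
    F′  = Fm′ · (1 − Φ2)

with Φ2_max ≡ (Fm_dark − F0_dark)/Fm_dark so that dark-reference Fv/Fm
round-trips exactly. The Φ2 expression is a lake-model-flavoured
simulator convention chosen to give the right orderings (F′ < Fm′ ≤ Fm,
light saturation of PSII); it is not a calibrated photosystem model.
Noise is multiplicative Gaussian on F′ and Fm′ (PAM noise scales with
signal), independently per channel, with F′ clipped to (0, Fm′] to keep
physical ordering. NPQ reconstructed from a noise-free trace equals the
generating NPQ to machine precision — the round-trip identity the unit
tests assert at 1e−9.

The emitted PSI-efficiency channel is Φ_PSI = Φ2·(1 + c·I/(I+K)) with
`cef_boost` c = 0 by default (so Φ_PSI/Φ2 ≡ 1); the CEF/LEF analysis is
exercised mainly on constructed series.

## LL2 decay fitting

Model: NPQ(t) = A_fast·e^(−t/τ_fast) + A_slow·e^(−t/τ_slow) + offset,
t from LL2 onset. Numerical choices:

* τ_fast is bounded to [10, 40] s and *never* reported without that
  interval: with 30-s pulses it is unidentifiable, only its amplitude is.
  A `fix_tau_fast` mode holds it at a supplied value instead.
* τ_slow is searched in [60, 3000] s; estimates within 1% of the upper
  bound are flagged `censored_` (drought can push qZ lifetimes beyond
  what a finite LL2 resolves).
* Multi-start: 8 starts log-spaced in τ_slow over its bounds, amplitudes
  and offset initialised by linear least squares at each start;
  Levenberg–Marquardt (lmfit) refinement; best residual norm wins, ties
  broken by smaller τ_slow. The start grid is fixed, so fits are
  deterministic. Amplitudes and offset are bounded below by 0; a
  negative-offset fit triggers a warning rather than an error.
* Confidence limits are ±t₀.₉₇₅ × stderr from the LM covariance;
  parameter p-values are the corresponding Wald tests, mirroring what
  `nls`-style fitting reports.
* Constant input is degenerate by definition: A = 0, offset = mean,
  `degenerate_` flag set; fewer than 8 points is an error.
* An independent grid-search oracle (dense lifetime grid + linear solve,
  in the test suite) must agree with the fitter's residual norm within 1%
  on noise-free instances.

Derived statistics: FL-photodamage = offset − NPQ(end LL1), using the
fitted offset as the LL2 steady state because it is robust to truncated
traces (a `steady="last-k"` option averages the last k = 4 pulses
instead, for sensitivity analysis). HL-induced NPQ defaults to
NPQ(end HL) − NPQ(end LL1) (configurable to the end-HL value alone), and
the qZ amplitude is 100·A_slow over that quantity. Adding a constant to
the whole NPQ series leaves FL-photodamage unchanged.

## ECS / DIRK

Simulator: in the light the ECS signal relaxes toward
baseline + (1 − f_ΔpH)·pmf with rate gH⁺; on light→dark it decays with
the same rate toward baseline − f_ΔpH·pmf. The total drop equals pmf;
the drop down to baseline is the ΔΨ component and the undershoot the ΔpH
component. Dark (relaxation) stretches are sampled at 1 kHz and lit
stretches at 10 Hz, as instruments do; the fast rate must put ≥ 20
samples within one lifetime 1/gH⁺. Noise is additive (the detector noise
of a transmittance difference does not scale with the small signal).

Analyzer: the light steady level is the mean over the final 5 s before
the last light→dark transition; the quasi-stable level the mean of the
final 25% of the 30-s dark window; the baseline the mean of the
pre-illumination dark record. gH⁺ is 1/τ of a single-exponential fit over
the whole dark window (lower variance than an initial-slope estimate; an
initial-slope `method="slope"` is provided as a cross-check, using the
secant over the first ~20% amplitude drop). ΔΨ and ΔpH fractions are
computed from the three levels and sum to one by construction. pmf is
relative (a.u.) only — no calibration to volts or pH units is attempted.
A coarse binned-means check flags non-monotone decays.

The I535 decomposition fits constant + fast exponential + linear slope
over the 900–1100 s window, with the amplitude referenced to the onset of
the containing light segment (LL2 starts at 810 s on the DIRK clock) so
that it is comparable across window choices. The lifetime is bounded to
[5, 200] s and scanned on a deterministic grid with a linear solve before
nonlinear polishing; a purely linear input therefore degenerates cleanly
to amplitude 0.

## Drought time course and phase calling

The generator emulates a pot-drying experiment: day 0 is the last
watering day; DS soil water decays exponentially toward a ~15% plateau;
well-watered plants fluctuate around constants (25 g day⁻¹ transpiration,
NPQ 1.0, Fv/Fm 0.82). Treatment effects switch on at the configured onset
days (defaults 8/13/18 over 24 days) and ramp: transpiration decays
exponentially (30% per day), NPQ rises saturatingly by up to 0.6, Fv/Fm
falls 0.02 per day and FL-photodamage rises 0.05 per day. Replicate noise
defaults (e.g. 0.08 NPQ, 1.2 g transpiration) were set so that the
first post-onset day separates treatments by ~2.5–5 replicate standard
deviations — a clearly expressed but noisy experiment, appropriate for
exercising the detector at 4–5 replicates. Daily PAR is shared across
plants within a day, and NPQ responds linearly to it, with a drought
extra slope that builds up in step with the NPQ rise; this mimics a
greenhouse under natural light and feeds the NPQ-vs-PAR slope analysis.

What the generator does **not** emulate: within-plant autocorrelation
across days, heteroscedastic or non-Gaussian replicate scatter,
cultivar-specific effect sizes, missing days, or any coupling between the
drought table and the PAM/ECS kinetics. Passing tests therefore show
that the estimators recover the assumed structure at realistic
noise/replication, not that real wheat data satisfy those assumptions.

Onset detection tests each day with OLS on treatment (+ cultivar when two
are present, reporting the treatment contrast only). The onset is the
first day that is (a) significant at α = 0.05, (b) in the expected
direction (transpiration down; NPQ and FL-photodamage up; Fv/Fm down),
and (c) persistent for 2 consecutive days. The persistence rule
suppresses single-day flukes; the direction rule keeps the family-wise
false-onset probability of a 24-day, three-parameter null course at a few
percent without any cross-day multiplicity correction (per-day testing
with uncorrected asterisks is the convention this mirrors; a Holm
step-down across days is available via `correct_across_days`). With a
single replicate and one cultivar no test is possible and the detector
falls back to absolute effect thresholds, with a warning. The damage
criterion uses FL-photodamage in chamber mode and Fv/Fm in greenhouse
mode (`damage_channel`).

Phase labels follow from the onsets: before the transpiration onset
Phase I, then II, from the NPQ onset III, from the damage onset IV;
absent onsets truncate the sequence, and coincident onsets collapse the
intermediate phases. Labels are by construction non-decreasing in time.

## Slope comparisons

Both the greenhouse NPQ-vs-PAR analysis and the A_CO2-vs-LEF light-curve
comparison use OLS with a group × covariate interaction; with two groups
the interaction Wald p-value is identical to the F-test of the
common-slope vs separate-slopes models (asserted in the tests). The LEF
range bound (default 85 μmol e⁻ m⁻² s⁻¹, the drought-reachable range) is
inclusive. A heteroscedasticity-robust (HC3) option exists; pooled
replicates are the default, per-plant means an option. LEF uses the
conventional 0.5 PSII excitation fraction and a fixed absorptivity of
0.86 unless SPAD-derived values are supplied — both exposed as
parameters, since neither constant is universal.

## Problem sizes used in the validation suites

Recovery and calibration suites run at desk scale: 50 seeds for the
onset-detection hit-rate and null-silence checks (4 replicates, 2
cultivars, 24 days), 30 seeds per cell for fitter-bias grids, 200
replicates for type-I-error calibration of the interaction tests, and a
2×2×3 noise-free grid for biexponential recovery. These sizes give
Monte-Carlo standard errors comfortably below the asserted margins
(e.g. ±1.5 percentage points at n = 200 for a 5% rate).

## Known limitations

* The quenching simulator has no electron-transport or xanthophyll-cycle
  chemistry; qE/qZ/qI are labels for kinetic pools, and conclusions about
  mechanism cannot be drawn from fits to it.
* τ_fast is structurally unidentifiable at 30-s pulse spacing; the
  reported interval is honest but wide, and the qE amplitude absorbs any
  misfit of the fast lifetime.
* DIRK assumes a clean single-exponential dark decay; overlapping
  processes (e.g. zeaxanthin-related absorbance drift into the 515–550 nm
  band) would bias gH⁺ and the partition.
* The phase classifier assumes the canonical onset ordering
  (transpiration ≤ NPQ ≤ damage); orderings outside it are rejected
  rather than reinterpreted.
* 77 K peak heights are window maxima without deconvolution; strongly
  shifted or overlapping emission bands would need a component fit that
  is out of scope here.
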