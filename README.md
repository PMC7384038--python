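# fluctlight

Analysis toolkit for photosynthetic acclimation measurements under
fluctuating light (FL), aimed at plant ecophysiologists and phenotyping
groups working on drought responses in crops. It covers the complete
measurement chain of a four-phase FL assay — pulse-amplitude-modulated
(PAM) chlorophyll fluorescence, electrochromic-shift (ECS) proton-flux
analysis, multi-day drought monitoring, and combined gas-exchange /
fluorescence light curves — together with seeded synthetic generators for
every input kind, so each estimator can be validated against known ground
truth without instrument data.

## What it computes

**Fluorescence parameters.** From saturating-pulse records: Fv/Fm =
(Fm − F0)/Fm, NPQ = (Fm − Fm′)/Fm′, Φ_PSII = (Fm′ − F′)/Fm′, linear
electron flow LEF = Φ_PSII · PAR · Abs · f_PSII (f_PSII = 0.5 by
convention), leaf absorptivity from SPAD readings via
Abs = (89.2 − 56.8 e^(−0.0723·SPAD))/100, relative CEF/LEF from the
Φ_PSI/Φ_PSII ratio normalised to a very-low-light baseline, leaf relative
water content, and the 77 K F685/F741 emission-peak ratio.

**NPQ relaxation kinetics.** The FL protocol steps a leaf through
VLL (57) → LL1 (166) → HL (1466) → LL2 (166 μmol photons m⁻² s⁻¹) with
saturating pulses every 30 s. The LL2 NPQ decay is decomposed as

    NPQ(t) = A_fast·exp(−t/τ_fast) + A_slow·exp(−t/τ_slow) + offset

where the fast term is energy-dependent quenching (qE) and the slow term
zeaxanthin-dependent quenching (qZ). Because the 30-s pulse cadence cannot
resolve a 20–30 s lifetime, τ_fast is reported only as a bounded interval;
the amplitudes and τ_slow are well identified. Derived statistics:
**FL-photodamage** = (fitted LL2 steady-state NPQ) − (NPQ at the end of
LL1), i.e. the HL-induced quenching that does not relax, and the **qZ
amplitude** as a percentage of HL-induced NPQ.

**DIRK / ECS.** Dark-interval relaxation kinetics of the 515–550 nm
signal give the ATP-synthase proton conductivity gH⁺ (1/τ of the decay),
the proton motive force pmf (total light→dark drop), and its ΔΨ/ΔpH
partition (drop to the dark baseline vs. undershoot below it; the
fractions sum to 1 by construction). The 535-nm transmittance during LL2
is decomposed into a fast exponential plus a slow linear phase, the
latter a proxy for LHCII aggregation.

**Drought phases.** Per-day drought-vs-control tests (two-factor OLS with
cultivar) detect the onset of persistent effects in transpiration, NPQ and
photodamage; days are then labelled Phase I–IV (soil drying only →
transpiration decline → NPQ rise → photodamage). NPQ-vs-PAR and
A_CO2-vs-LEF regression slopes are compared between groups by ANCOVA-style
interaction tests, the latter restricted to LEF ≤ 85 μmol e⁻ m⁻² s⁻¹.

Fit-shaped components are scikit-learn-style estimators
(`NPQDecayFitter`, `DIRKAnalyzer`, `I535Decomposer`, `OnsetDetector`,
`DroughtPhaseClassifier`, `SlopeComparison`) with `fit`/`predict` and
trailing-underscore attributes; plain functions wrap them.

## Worked example

```python
import fluctlight as fl

params = fl.QuenchingParams(A_qE=1.2, A_qZ=0.8, qI=0.1, noise_sd=0.01, seed=42)
trace = fl.simulate_pam_trace(params)           # four-phase FL protocol
res = fl.analyze_fl_trace(trace)
print(f"NPQ end of LL1 {res.npq_end_ll1:.3f}, end of HL {res.npq_end_hl:.3f}")
print(f"FL-photodamage {res.fl_photodamage:.3f}")
print(f"qZ amplitude {res.qz_amplitude_pct:.1f}% of HL-induced NPQ, "
      f"lifetime {res.qz_lifetime:.0f} s")

ecs = fl.simulate_ecs_trace(gH_plus=20.0, pmf=1.0, f_dpH=0.6,
                            noise_sd=0.01, seed=42)
d = fl.dirk_analyze(ecs)
print(f"gH+ {d.gh_plus_:.1f} s-1, pmf {d.pmf_:.3f} a.u., "
      f"dpH fraction {d.dph_fraction_:.3f}")
```

prints

```
NPQ end of LL1 0.809, end of HL 1.811
FL-photodamage 0.093
qZ amplitude 36.5% of HL-induced NPQ, lifetime 370 s
gH+ 19.9 s-1, pmf 0.997 a.u., dpH fraction 0.601
```

The trace was generated with a persistent-quenching step of 0.1 per HL
exposure and 1% multiplicative noise: the FL-photodamage statistic reads
it back as 0.093, and the qZ share and lifetime (generated at 400 s)
are recovered from 30-s-sampled pulses. The DIRK estimates match the
generating gH⁺ = 20 s⁻¹, pmf = 1.0 and ΔpH fraction 0.6 to within 1%.

The same chain is available from a shell:

```sh
fluctlight run --config examples/demo.yaml      # full synthetic pipeline
fluctlight simulate --kind pam --out trace.csv
fluctlight fl-analyze trace.csv --out fl.csv
```

Subcommands: `simulate`, `fl-analyze`, `dirk`, `phases`, `light-curve`,
`run`. All tables are plain CSV with a `.meta.yaml` sidecar carrying the
protocol and ground truth; `run` writes a manifest sufficient to
re-create every output byte-identically.

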