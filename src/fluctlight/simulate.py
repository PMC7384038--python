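"""Synthetic generators for PAM, ECS/I535, drought, gas-exchange and 77 K data.

Every generator carries its ground truth alongside the trace so parameter
recovery can be checked exactly.  The quenching model is deliberately
phenomenological: each reversible NPQ component (qE, qZ) relaxes with
first-order kinetics toward a light-dependent target, and the persistent
component (qI) accumulates irreversibly during high-light segments.  No
mechanistic electron-transport model is implied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .protocols import LightProtocol, fl_protocol, dirk_protocol

__all__ = [
    "QuenchingParams",
    "PAMTrace",
    "ECSTrace",
    "DroughtEffects",
    "DroughtNoise",
    "simulate_pam_trace",
    "simulate_ecs_trace",
    "simulate_drought_timecourse",
    "simulate_gas_exchange",
    "simulate_spectrum_77k",
]


# --------------------------------------------------------------------------
# PAM fluorometry
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class QuenchingParams:
    """Ground-truth quenching kinetics for the PAM simulator.

    ``A_qE``/``A_qZ`` are the asymptotic amplitudes of the fast
    (energy-dependent) and slow (zeaxanthin-dependent) components at
    saturating light; each component relaxes toward the light-dependent
    target ``A * I / (I + light_half_sat)`` with time constant ``tau_*_on``
    when rising and ``tau_*_off`` when falling.  ``qI`` is the persistent
    quenching added per completed high-light segment.  The qZ induction
    constant is faster than its relaxation (zeaxanthin forms in ~1 min but
    is epoxidised back over many minutes), so low-light phases of the
    standard protocol reach quasi-steady state.
    """

    A_qE: float = 2.0
    tau_qE_on: float = 25.0
    tau_qE_off: float = 25.0
    A_qZ: float = 0.8
    tau_qZ_on: float = 60.0
    tau_qZ_off: float = 400.0
    qI: float = 0.0
    light_half_sat: float = 250.0
    Fm_dark: float = 1.0
    F0_dark: float = 0.17
    noise_sd: float = 0.0
    seed: int = 0
    # Phi2 model constants (simulator convention, see docs/methods.md)
    phi2_light_half_sat: float = 700.0
    # relative cyclic-flow boost applied to the emitted PSI efficiency channel
    cef_boost: float = 0.0

    def __post_init__(self) -> None:
        for name in ("A_qE", "A_qZ", "qI", "noise_sd", "cef_boost"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("tau_qE_on", "tau_qE_off", "tau_qZ_on", "tau_qZ_off",
                     "light_half_sat", "phi2_light_half_sat"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0 <= self.F0_dark < self.Fm_dark):
            raise ValueError("need 0 <= F0_dark < Fm_dark")

    @property
    def phi2_max(self) -> float:
        """Maximal PSII yield implied by the dark reference: (Fm - F0)/Fm."""
        return (self.Fm_dark - self.F0_dark) / self.Fm_dark


@dataclass
class PAMTrace:
    """Pulse-indexed fluorescence record under a declared protocol.

    ``data`` has one row per saturating pulse with columns
    ``t, segment, par, fprime, fmprime, phi_psi``; ``truth`` (present for
    simulated traces) adds the noise-free ``npq_true, phi2_true, qe, qz, qi``.
    """

    data: pd.DataFrame
    protocol: LightProtocol
    f0_dark: float
    fm_dark: float
    truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        t = self.data["t"].to_numpy()
        if len(t) and not np.all(np.diff(t) > 0):
            raise ValueError("pulse times must be strictly increasing")
        if not (0 < self.f0_dark <= self.fm_dark):
            raise ValueError("need 0 < F0 <= Fm in the dark reference")
        bad = self.data.index[self.data["fprime"] > self.data["fmprime"]]
        if len(bad):
            raise ValueError(f"Fprime > Fmprime at rows {list(bad[:5])}")


def _target(A: float, intensity: float, half_sat: float) -> float:
    return A * intensity / (intensity + half_sat) if intensity > 0 else 0.0


def simulate_pam_trace(
    params: QuenchingParams,
    protocol: LightProtocol | None = None,
) -> PAMTrace:
    """Simulate a saturating-pulse fluorescence trace under ``protocol``.

    qE and qZ follow first-order kinetics toward their light-dependent
    targets; qI accumulates linearly over each HL segment (labels starting
    with ``"HL"``).  At each pulse:

        NPQ_true = qE + qZ + qI
        Fm'      = Fm_dark / (1 + NPQ_true)
        Phi2     = phi2_max / (1 + NPQ_true) / (1 + I / I_sat)
        F'       = Fm' * (1 - Phi2)

    Multiplicative Gaussian noise of relative sd ``params.noise_sd`` is
    applied independently to F' and Fm'.  The emitted PSI-efficiency channel
    is ``phi_psi = phi2 * (1 + cef_boost * I / (I + light_half_sat))``.
    """
    if protocol is None:
        protocol = fl_protocol()
    if protocol.total_duration < protocol.pulse_interval:
        raise ValueError(
            "protocol shorter than one pulse interval: no pulses would be recorded"
        )
    rng = np.random.default_rng(params.seed)
    pulses = protocol.pulse_times()

    # integrate piecewise-constant light exactly, stretch by stretch
    bounds = protocol.boundaries()
    events = np.unique(np.concatenate([bounds, pulses]))
    pulse_set = set(pulses.tolist())
    qe = qz = qi = 0.0
    state_at_pulse: dict[float, tuple[float, float, float]] = {}
    for t0, t1 in zip(events[:-1], events[1:]):
        seg = protocol.segment_at(0.5 * (t0 + t1))
        dt = t1 - t0
        tgt_e = _target(params.A_qE, seg.intensity, params.light_half_sat)
        tgt_z = _target(params.A_qZ, seg.intensity, params.light_half_sat)
        tau_e = params.tau_qE_on if qe < tgt_e else params.tau_qE_off
        tau_z = params.tau_qZ_on if qz < tgt_z else params.tau_qZ_off
        qe = tgt_e + (qe - tgt_e) * np.exp(-dt / tau_e)
        qz = tgt_z + (qz - tgt_z) * np.exp(-dt / tau_z)
        if seg.label.startswith("HL"):
            qi += params.qI * dt / seg.duration
        if t1 in pulse_set:
            state_at_pulse[t1] = (qe, qz, qi)

    rows = []
    for t in pulses:
        seg = protocol.segment_at(t)
        qe_t, qz_t, qi_t = state_at_pulse[t]
        npq = qe_t + qz_t + qi_t
        phi2 = params.phi2_max / (1.0 + npq) / (1.0 + seg.intensity / params.phi2_light_half_sat)
        fmprime = params.Fm_dark / (1.0 + npq)
        fprime = fmprime * (1.0 - phi2)
        phi_psi = phi2 * (
            1.0 + params.cef_boost * seg.intensity / (seg.intensity + params.light_half_sat)
        )
        rows.append((t, seg.label, seg.intensity, fprime, fmprime, phi_psi,
                     npq, phi2, qe_t, qz_t, qi_t))

    cols = ["t", "segment", "par", "fprime", "fmprime", "phi_psi",
            "npq_true", "phi2_true", "qe", "qz", "qi"]
    df = pd.DataFrame(rows, columns=cols)
    truth = df[["t", "segment", "npq_true", "phi2_true", "qe", "qz", "qi"]].copy()

    if params.noise_sd > 0:
        df["fprime"] *= 1.0 + rng.normal(0.0, params.noise_sd, len(df))
        df["fmprime"] *= 1.0 + rng.normal(0.0, params.noise_sd, len(df))
        # keep the physical ordering 0 < F' <= Fm' even under noise
        df["fprime"] = np.clip(df["fprime"], 1e-9, df["fmprime"])

    data = df[["t", "segment", "par", "fprime", "fmprime", "phi_psi"]].copy()
    return PAMTrace(
        data=data,
        protocol=protocol,
        f0_dark=params.F0_dark,
        fm_dark=params.Fm_dark,
        truth=truth,
    )


# --------------------------------------------------------------------------
# ECS / I535
# --------------------------------------------------------------------------

@dataclass
class ECSTrace:
    """Electrochromic-shift record: ``data`` columns t, segment, ecs, i535,
    light_state; negative times are the pre-illumination dark baseline.
    """

    data: pd.DataFrame
    protocol: LightProtocol
    sampling_rate: float
    truth: dict | None = None


def simulate_ecs_trace(
    gH_plus: float = 20.0,
    pmf: float = 1.0,
    f_dpH: float = 0.6,
    i535_fast_amp: float = 0.5,
    i535_slow_slope: float = -0.002,
    protocol: LightProtocol | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    sampling_rate: float = 1000.0,
    base_rate: float = 10.0,
    baseline_duration: float = 30.0,
    i535_fast_lifetime: float = 60.0,
) -> ECSTrace:
    """Simulate a 515-550 nm differential-transmittance (ECS) trace.

    During light the ECS signal relaxes with rate ``gH_plus`` toward
    ``baseline + (1 - f_dpH) * pmf``.  On light->dark it decays with the same
    rate toward ``baseline - f_dpH * pmf``: the total drop from the light
    steady state to the post-decay quasi-stable level is ``pmf``, of which
    the electric-field fraction (down to the old baseline) is ``1 - f_dpH``
    and the undershoot below baseline is the ``f_dpH`` fraction.  The I535
    channel decays biphasically during LL2: a fast exponential
    (``i535_fast_amp``, lifetime ``i535_fast_lifetime``) plus a linear drift
    of slope ``i535_slow_slope``.  Noise is additive Gaussian.

    As on a real instrument, dark (relaxation) segments are sampled at the
    fast ``sampling_rate`` — which must place at least 20 samples within one
    relaxation lifetime 1/gH+ — while illuminated stretches and the
    pre-illumination baseline use the slower ``base_rate``.
    """
    if not 0.0 <= f_dpH <= 1.0:
        raise ValueError("f_dpH must be in [0, 1]")
    if gH_plus <= 0:
        raise ValueError("gH_plus must be > 0")
    if sampling_rate * (1.0 / gH_plus) < 20:
        raise ValueError(
            f"sampling_rate {sampling_rate} Hz gives <20 samples per relaxation "
            f"lifetime 1/gH+ = {1.0 / gH_plus:.3g} s"
        )
    if protocol is None:
        protocol = dirk_protocol()
    rng = np.random.default_rng(seed)

    baseline = 0.0
    level_light = baseline + (1.0 - f_dpH) * pmf
    level_dark = baseline - f_dpH * pmf

    # stretches of constant target: (t_start, t_end, label, lit, target)
    stretches = [(-baseline_duration, 0.0, "BASELINE", False, baseline)]
    bounds = protocol.boundaries()
    seen_light = False
    for seg, s, e in zip(protocol.segments, bounds[:-1], bounds[1:]):
        lit = seg.intensity > 0
        seen_light = seen_light or lit
        tgt = level_light if lit else (level_dark if seen_light else baseline)
        stretches.append((float(s), float(e), seg.label, lit, tgt))

    t_parts, ecs_parts, labels, light = [], [], [], []
    x0 = baseline
    for s, e, label, lit, tgt in stretches:
        rate = base_rate if lit or label == "BASELINE" else sampling_rate
        tt = np.arange(s, e, 1.0 / rate)
        xx = tgt + (x0 - tgt) * np.exp(-gH_plus * (tt - s))
        x0 = tgt + (x0 - tgt) * np.exp(-gH_plus * (e - s))
        t_parts.append(tt)
        ecs_parts.append(xx)
        labels.extend([label] * len(tt))
        light.extend([lit] * len(tt))
    t = np.concatenate(t_parts)
    ecs = np.concatenate(ecs_parts)
    light = np.asarray(light, dtype=bool)
    seg_labels = labels

    # I535: flat plateau before LL2, biphasic decay inside LL2, hold after
    i535 = np.full_like(t, 1.0 + i535_fast_amp)
    if "LL2" in protocol.labels:
        t_ll2 = protocol.segment_start("LL2")
        t_end = protocol.segment_end("LL2")
        in_ll2 = (t > t_ll2) & (t <= t_end)
        rel = t[in_ll2] - t_ll2
        i535[in_ll2] = (
            1.0
            + i535_fast_amp * np.exp(-rel / i535_fast_lifetime)
            + i535_slow_slope * rel
        )
        after = t > t_end
        if after.any() and in_ll2.any():
            i535[after] = i535[in_ll2][-1]

    if noise_sd > 0:
        ecs = ecs + rng.normal(0.0, noise_sd, len(t))
        i535 = i535 + rng.normal(0.0, noise_sd, len(t))

    data = pd.DataFrame(
        {"t": t, "segment": seg_labels, "ecs": ecs, "i535": i535, "light_state": light}
    )
    truth = {
        "gH_plus": gH_plus,
        "pmf": pmf,
        "f_dpH": f_dpH,
        "f_dPsi": 1.0 - f_dpH,
        "i535_fast_amp": i535_fast_amp,
        "i535_fast_lifetime": i535_fast_lifetime,
        "i535_slow_slope": i535_slow_slope,
    }
    return ECSTrace(data=data, protocol=protocol, sampling_rate=sampling_rate, truth=truth)


# --------------------------------------------------------------------------
# Drought time courses
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DroughtEffects:
    """Divergence of drought-stressed (DS) from well-watered (WW) plants.

    Each effect switches on at its onset day and then ramps; magnitudes are
    chosen so that the first post-onset day already separates the groups by
    several replicate standard deviations, as in a slowly developing but
    clearly expressed pot-drying experiment.  Set all to 0 for a null
    time course.
    """

    transpiration_decay: float = 0.30      # per-day exponential decay after onset
    npq_rise: float = 0.60                 # asymptotic NPQ increment
    npq_rise_tau: float = 2.5              # days
    fvfm_drop_per_day: float = 0.02
    damage_rise_per_day: float = 0.05      # FL-photodamage increment per day
    # extra NPQ-vs-PAR slope under drought; builds up with the NPQ rise so
    # the light response diverges gradually, like the mean NPQ itself
    npq_par_slope_shift: float = 0.0006

    def null(self) -> "DroughtEffects":
        return DroughtEffects(0.0, 0.0, self.npq_rise_tau, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class DroughtNoise:
    """Replicate-level Gaussian noise (additive, per plant per day)."""

    soil_water: float = 1.5
    transpiration: float = 1.2
    npq: float = 0.08
    fvfm: float = 0.008
    fl_photodamage: float = 0.02


_WW_BASE = {
    "soil_water": 90.0,          # % field capacity
    "transpiration": 25.0,       # g water day-1
    "npq": 1.0,
    "fvfm": 0.82,
    "fl_photodamage": 0.03,
}


def simulate_drought_timecourse(
    onsets: tuple[int, int, int] = (8, 13, 18),
    n_days: int = 24,
    n_reps: int = 4,
    cultivars: tuple[str, ...] = ("UK", "IR"),
    effects: DroughtEffects | None = None,
    noise: DroughtNoise | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a per-plant per-day drought monitoring table.

    Day 0 is the last day of watering.  DS soil water declines toward a
    plateau from day 1; transpiration, NPQ and photodamage (FL-photodamage
    and Fv/Fm) diverge from WW at ``onsets = (transpiration, npq, damage)``.
    Daily PAR is shared by all plants of a day; NPQ responds linearly to PAR
    so the table supports the NPQ-vs-PAR slope analysis.

    Returns a DataFrame with columns ``cultivar, treatment, replicate, day,
    par, soil_water, transpiration, npq, fvfm, fl_photodamage`` and ground
    truth in ``df.attrs["truth"]``.
    """
    t_on, n_on, d_on = onsets
    if not (0 < t_on < n_on < d_on <= n_days):
        raise ValueError(
            f"onsets must satisfy 0 < transpiration ({t_on}) < npq ({n_on}) "
            f"< damage ({d_on}) <= n_days ({n_days})"
        )
    effects = effects if effects is not None else DroughtEffects()
    noise = noise if noise is not None else DroughtNoise()
    rng = np.random.default_rng(seed)

    days = np.arange(0, n_days + 1)
    par_day = rng.uniform(400.0, 1400.0, len(days))  # midday sunlight, shared

    rows = []
    for cultivar in cultivars:
        for treatment in ("WW", "DS"):
            for rep in range(1, n_reps + 1):
                for day, par in zip(days, par_day):
                    r = dict(_WW_BASE)
                    if treatment == "DS":
                        r["soil_water"] = 15.0 + 75.0 * np.exp(-day / 7.0)
                        since_t = max(0, day - t_on + 1)
                        if since_t > 0:
                            r["transpiration"] *= np.exp(
                                -effects.transpiration_decay * since_t
                            )
                        since_n = max(0, day - n_on + 1)
                        if since_n > 0:
                            r["npq"] += effects.npq_rise * (
                                1.0 - np.exp(-since_n / effects.npq_rise_tau)
                            )
                        since_d = max(0, day - d_on + 1)
                        if since_d > 0:
                            r["fvfm"] -= min(0.15, effects.fvfm_drop_per_day * since_d)
                            r["fl_photodamage"] += min(
                                0.5, effects.damage_rise_per_day * since_d
                            )
                    # NPQ tracks daily light; DS plants respond more steeply
                    slope = 0.0008
                    if treatment == "DS" and day >= n_on:
                        ramp = 1.0 - np.exp(-(day - n_on + 1) / effects.npq_rise_tau)
                        slope += effects.npq_par_slope_shift * ramp
                    r["npq"] += slope * (par - 800.0)

                    rows.append(
                        {
                            "cultivar": cultivar,
                            "treatment": treatment,
                            "replicate": rep,
                            "day": int(day),
                            "par": par,
                            "soil_water": r["soil_water"]
                            + rng.normal(0, noise.soil_water),
                            "transpiration": max(
                                0.5,
                                r["transpiration"] + rng.normal(0, noise.transpiration),
                            ),
                            "npq": max(0.0, r["npq"] + rng.normal(0, noise.npq)),
                            "fvfm": float(
                                np.clip(r["fvfm"] + rng.normal(0, noise.fvfm), 0, 1)
                            ),
                            "fl_photodamage": r["fl_photodamage"]
                            + rng.normal(0, noise.fl_photodamage),
                        }
                    )
    df = pd.DataFrame(rows)
    null_effects = all(
        getattr(effects, f) == 0
        for f in ("transpiration_decay", "npq_rise", "fvfm_drop_per_day",
                  "damage_rise_per_day")
    )
    df.attrs["truth"] = {
        "transpiration_onset": None if null_effects else t_on,
        "npq_onset": None if null_effects else n_on,
        "damage_onset": None if null_effects else d_on,
        "n_days": n_days,
    }
    return df


# --------------------------------------------------------------------------
# Gas exchange light curves
# --------------------------------------------------------------------------

def simulate_gas_exchange(
    slopes: dict[str, float] | None = None,
    intercepts: dict[str, float] | None = None,
    par_steps: tuple[float, ...] = (25, 50, 100, 200, 400, 600, 900, 1200, 1500),
    phi2_max: float = 0.8,
    phi2_half_sat: dict[str, float] | None = None,
    abs_frac: float = 0.86,
    psii_fraction: float = 0.5,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a light curve with simultaneous fluorescence and gas exchange.

    Per condition, Phi2 saturates with PAR; LEF follows the conventional
    product ``phi2 * par * abs_frac * psii_fraction`` and net CO2 assimilation
    is linear in LEF (condition-specific slope) plus Gaussian noise —
    a lower slope mimics diversion of electron flow to alternative sinks.

    Returns columns ``condition, par, phi2, a_co2, gs`` with the generating
    parameters in ``df.attrs["truth"]``.
    """
    slopes = slopes or {"WW": 0.10, "DS": 0.05}
    intercepts = intercepts or {c: -1.0 for c in slopes}
    phi2_half_sat = phi2_half_sat or {c: 400.0 for c in slopes}
    rng = np.random.default_rng(seed)
    rows = []
    for cond, slope in slopes.items():
        for par in par_steps:
            phi2 = phi2_max / (1.0 + par / phi2_half_sat[cond])
            lef = phi2 * par * abs_frac * psii_fraction
            a_co2 = intercepts[cond] + slope * lef + rng.normal(0, noise_sd)
            gs = max(5.0, 40.0 + 3.0 * a_co2 + rng.normal(0, 2.0))
            rows.append(
                {"condition": cond, "par": float(par), "phi2": phi2,
                 "a_co2": a_co2, "gs": gs}
            )
    df = pd.DataFrame(rows)
    df.attrs["truth"] = {
        "slopes": dict(slopes),
        "intercepts": dict(intercepts),
        "abs_frac": abs_frac,
        "psii_fraction": psii_fraction,
    }
    return df


# --------------------------------------------------------------------------
# 77 K emission spectra
# --------------------------------------------------------------------------

def simulate_spectrum_77k(
    f685_height: float = 1.0,
    f741_height: float = 1.0,
    width685: float = 8.0,
    width741: float = 12.0,
    wavelengths: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-Gaussian 77 K chlorophyll emission spectrum (PSII 685 nm, PSI 741 nm)."""
    if wavelengths is None:
        wavelengths = np.arange(650.0, 780.5, 0.5)
    rng = np.random.default_rng(seed)
    intensity = (
        f685_height * np.exp(-0.5 * ((wavelengths - 685.0) / width685) ** 2)
        + f741_height * np.exp(-0.5 * ((wavelengths - 741.0) / width741) ** 2)
    )
    if noise_sd > 0:
        intensity = np.clip(intensity + rng.normal(0, noise_sd, len(wavelengths)), 0, None)
    df = pd.DataFrame({"wavelength": wavelengths, "intensity": intensity})
    df.attrs["truth"] = {"f685_height": f685_height, "f741_height": f741_height}
    return df
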