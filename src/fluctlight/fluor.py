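"""Point-wise photosynthetic parameters from fluorescence and ancillary data.

All ratio parameters (Fv/Fm, NPQ, PhiPSII, relative CEF/LEF, F685/F741) are
invariant to a common positive rescaling of the underlying signals; NPQ is
deliberately *not* clipped at zero so replicate noise stays symmetric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "compute_fvfm",
    "compute_npq",
    "compute_phi2",
    "spad_to_abs",
    "compute_lef",
    "relative_cef_lef",
    "CEFLEFResult",
    "relative_water_content",
    "f685_f741_ratio",
]


def _asarray(x):
    return np.asarray(x, dtype=float)


def compute_fvfm(f0, fm):
    """Maximal PSII efficiency of a dark-acclimated leaf, (Fm - F0)/Fm."""
    f0, fm = _asarray(f0), _asarray(fm)
    if np.any(f0 <= 0) or np.any(fm <= 0):
        raise ValueError("F0 and Fm must be positive")
    if np.any(f0 > fm):
        raise ValueError("F0 must not exceed Fm")
    out = (fm - f0) / fm
    return float(out) if out.ndim == 0 else out


def compute_npq(fm, fmprime):
    """Non-photochemical quenching, (Fm - Fm')/Fm'.

    Under noise Fm' can exceed Fm, giving slightly negative NPQ; the value
    is returned as-is.
    """
    fm, fmprime = _asarray(fm), _asarray(fmprime)
    if np.any(fm <= 0) or np.any(fmprime <= 0):
        raise ValueError("Fm and Fm' must be positive")
    out = (fm - fmprime) / fmprime
    return float(out) if out.ndim == 0 else out


def compute_phi2(fprime, fmprime):
    """PSII operating efficiency under illumination, (Fm' - F')/Fm'."""
    fprime, fmprime = _asarray(fprime), _asarray(fmprime)
    if np.any(fprime <= 0):
        raise ValueError("F' must be positive")
    if np.any(fprime > fmprime):
        raise ValueError("F' must not exceed Fm'")
    out = (fmprime - fprime) / fmprime
    return float(out) if out.ndim == 0 else out


def spad_to_abs(spad):
    """Leaf absorptivity (fraction) from a SPAD chlorophyll-meter reading.

    Uses the empirical calibration Abs[%] = 89.2 - 56.8 * exp(-0.0723 * SPAD)
    and returns the fraction Abs/100, which saturates at 0.892.
    """
    spad = _asarray(spad)
    if np.any(spad < 0):
        raise ValueError("SPAD must be >= 0")
    out = (89.2 - 56.8 * np.exp(-0.0723 * spad)) / 100.0
    return float(out) if out.ndim == 0 else out


def compute_lef(phi2, par, abs_frac=0.86, psii_fraction=0.5):
    """Linear electron flow, phi2 * PAR * absorptivity * PSII fraction.

    ``psii_fraction`` is the conventional 0.5 split of absorbed photons
    between the photosystems; ``abs_frac`` defaults to the fixed 0.86 used
    when SPAD readings do not differ between groups.
    """
    phi2, par = _asarray(phi2), _asarray(par)
    if np.any(phi2 < 0) or np.any(phi2 > 1):
        raise ValueError("phi2 must be in [0, 1]")
    if np.any(par < 0):
        raise ValueError("PAR must be >= 0")
    if not (0 < abs_frac <= 1 and 0 < psii_fraction <= 1):
        raise ValueError("abs_frac and psii_fraction must be in (0, 1]")
    out = phi2 * par * abs_frac * psii_fraction
    return float(out) if out.ndim == 0 else out


@dataclass
class CEFLEFResult:
    """Baseline-normalised PSI/PSII efficiency ratio (relative CEF/LEF)."""

    series: pd.Series               # per pulse, normalised to the baseline tail
    segment_means: dict[str, float]  # tail mean of the relative ratio per segment
    baseline_segment: str
    vll_ll1_increment_pct: float | None
    excluded_pulses: list[int]


def relative_cef_lef(
    phi_psi,
    phi2,
    segments,
    baseline_segment: str = "VLL",
    tail_pulses: int = 4,
) -> CEFLEFResult:
    """Relative cyclic/linear electron-flow proxy from photosystem efficiencies.

    The ratio PhiPSI/PhiPSII is normalised by its mean over the final
    ``tail_pulses`` pulses of the baseline (VLL) segment, where cyclic flow
    is presumed minimal; segment means are likewise taken over each
    segment's final pulses, and the VLL->LL1 increment is reported in
    percent.  Pulses with phi2 == 0 are excluded with a warning.
    """
    phi_psi, phi2 = _asarray(phi_psi), _asarray(phi2)
    segments = pd.Series(list(segments))
    if not (len(phi_psi) == len(phi2) == len(segments)):
        raise ValueError("phi_psi, phi2 and segments must share the pulse index")
    if baseline_segment not in set(segments):
        raise ValueError(
            f"baseline segment {baseline_segment!r} absent; have {sorted(set(segments))}"
        )
    bad = np.nonzero(phi2 == 0)[0]
    if len(bad):
        warnings.warn(
            f"excluding {len(bad)} pulse(s) with phi2 == 0: indices {list(bad[:5])}"
        )
    keep = phi2 != 0
    ratio = pd.Series(np.full(len(phi2), np.nan))
    ratio[keep] = phi_psi[keep] / phi2[keep]

    def tail_mean(label: str) -> float:
        vals = ratio[(segments == label).to_numpy() & keep]
        return float(vals.tail(tail_pulses).mean())

    norm = tail_mean(baseline_segment)
    rel = ratio / norm
    seg_means = {
        label: tail_mean(label) / norm for label in pd.unique(segments)
    }
    incr = None
    if "LL1" in seg_means and baseline_segment in seg_means:
        incr = 100.0 * (seg_means["LL1"] / seg_means[baseline_segment] - 1.0)
    return CEFLEFResult(
        series=rel,
        segment_means=seg_means,
        baseline_segment=baseline_segment,
        vll_ll1_increment_pct=incr,
        excluded_pulses=list(bad),
    )


def relative_water_content(fw: float, dw: float, tw: float) -> float:
    """Leaf relative water content in percent, (FW - DW)/(TW - DW) * 100."""
    if tw == dw:
        raise ValueError("turgid and dry weight coincide (TW == DW)")
    if not (dw <= fw <= tw and dw < tw):
        raise ValueError(f"need DW <= FW <= TW, got DW={dw}, FW={fw}, TW={tw}")
    return 100.0 * (fw - dw) / (tw - dw)


def f685_f741_ratio(
    wavelength,
    intensity,
    window_685: tuple[float, float] = (675.0, 695.0),
    window_741: tuple[float, float] = (730.0, 755.0),
) -> float:
    """PSII/PSI 77 K emission peak ratio: max in the 685-nm window over max
    in the 741-nm window.  No smoothing is applied."""
    wl, inten = _asarray(wavelength), _asarray(intensity)
    if np.any(np.diff(wl) <= 0):
        raise ValueError("wavelengths must be strictly increasing")
    if np.any(inten < 0):
        raise ValueError("intensities must be >= 0")
    for lo, hi in (window_685, window_741):
        if wl[0] > lo or wl[-1] < hi:
            raise ValueError(
                f"wavelength grid [{wl[0]}, {wl[-1]}] does not cover window ({lo}, {hi})"
            )
    m685 = inten[(wl >= window_685[0]) & (wl <= window_685[1])].max()
    m741 = inten[(wl >= window_741[0]) & (wl <= window_741[1])].max()
    return float(m685 / m741)
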