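"""Dark-interval relaxation kinetics (DIRK) of the electrochromic shift.

When actinic light is switched off, the trans-thylakoid field collapses as
protons flow out through the ATP synthase: the 515-550 nm differential
transmittance decays exponentially with rate gH+ (the ATP-synthase proton
conductivity).  The total drop from the light steady state to the
post-decay quasi-stable level measures the proton motive force (pmf, in
arbitrary units); the part of the drop down to the pre-illumination dark
baseline is the electric (delta-Psi) fraction and the undershoot below the
baseline the osmotic (delta-pH) fraction — the two fractions sum to one by
construction.  The 535-nm transmittance during LL2 decays biphasically; its
slow, approximately linear phase tracks LHCII trimer aggregation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .simulate import ECSTrace

__all__ = [
    "DIRKAnalyzer",
    "dirk_analyze",
    "gh_ratio",
    "I535Decomposer",
    "i535_decompose",
]


def _exp_decay(t, amp, rate, floor):
    return floor + amp * np.exp(-rate * t)


class DIRKAnalyzer(BaseEstimator):
    """Estimate gH+, pmf and the delta-pH / delta-Psi partition from an ECS trace.

    Parameters
    ----------
    dark_window : float, default 30 s
        Length of the dark interval analysed after the light-off transition.
    steady_window : float, default 5 s
        Averaging window for the light steady-state level just before the
        transition.
    tail_fraction : float, default 0.25
        Final fraction of the dark window averaged for the quasi-stable
        post-decay level.
    method : {"exp", "slope"}
        ``"exp"``: gH+ = 1/tau of a single-exponential fit over the whole
        dark window (default; uses all points, lower variance).
        ``"slope"``: initial-slope estimator, gH+ = -(dECS/dt at t0)/amplitude,
        from a line through the first quarter of the window — a cross-check.

    Attributes (after ``fit``)
    --------------------------
    gh_plus_, pmf_, dph_fraction_, dpsi_fraction_ : float
    baseline_, light_level_, quasi_stable_ : signal levels (a.u.)
    converged_, monotone_ : diagnostics
    """

    def __init__(
        self,
        dark_window: float = 30.0,
        steady_window: float = 5.0,
        tail_fraction: float = 0.25,
        method: str = "exp",
    ):
        self.dark_window = dark_window
        self.steady_window = steady_window
        self.tail_fraction = tail_fraction
        self.method = method

    def fit(self, trace: ECSTrace):
        if self.method not in ("exp", "slope"):
            raise ValueError(f"method must be 'exp' or 'slope', got {self.method!r}")
        df = trace.data
        t = df["t"].to_numpy()
        ecs = df["ecs"].to_numpy()
        on = df["light_state"].to_numpy().astype(bool)

        if not on.any():
            raise ValueError("trace contains no illuminated samples")
        first_on = int(np.argmax(on))
        # last on->off transition with data after it
        offs = np.nonzero(on[:-1] & ~on[1:])[0]
        if len(offs) == 0:
            raise ValueError("no light->dark transition found in trace")
        i_off = int(offs[-1]) + 1  # first dark sample
        t_off = t[i_off]
        dark = (t >= t_off) & (t <= t_off + self.dark_window) & ~on
        if t[dark].max() - t_off < 0.9 * self.dark_window:
            raise ValueError(
                f"only {t[dark].max() - t_off:.1f} s of dark data after the "
                f"transition; need {self.dark_window} s"
            )

        if first_on == 0:
            warnings.warn("no pre-illumination baseline; using 0 as dark baseline")
            baseline = 0.0
        else:
            baseline = float(np.mean(ecs[:first_on]))
        pre = (t < t_off) & (t >= t_off - self.steady_window) & on
        light_level = float(np.mean(ecs[pre]))

        td = t[dark] - t_off
        yd = ecs[dark]
        n_tail = max(1, int(np.ceil(self.tail_fraction * len(td))))
        quasi_stable = float(np.mean(yd[-n_tail:]))

        amp0 = light_level - quasi_stable
        # crude rate init from the 1/e crossing
        below = np.nonzero(yd - quasi_stable < amp0 / np.e)[0]
        rate0 = 1.0 / max(td[below[0]], td[1]) if len(below) else 1.0 / max(td[-1], 1e-6)
        try:
            popt, _ = optimize.curve_fit(
                _exp_decay, td, yd, p0=(amp0, rate0, quasi_stable), maxfev=10000
            )
            converged = True
        except RuntimeError:
            popt = (amp0, rate0, quasi_stable)
            converged = False
            warnings.warn("exponential fit of the dark decay did not converge")
        amp, rate, floor = popt

        if self.method == "slope":
            # window: samples until ~20% of the decay amplitude is lost, so
            # the secant slope still approximates the initial tangent
            drop = np.nonzero(yd < yd[0] - 0.2 * amp)[0]
            n_head = max(3, int(drop[0]) if len(drop) else len(td) // 4)
            sl = stats.linregress(td[:n_head], yd[:n_head])
            rate = -sl.slope / amp if amp != 0 else np.nan

        # monotonicity beyond noise: coarse bin means must not rise materially
        n_bins = min(6, len(yd) // 3)
        if n_bins >= 2:
            chunks = np.array_split(yd, n_bins)
            means = np.array([c.mean() for c in chunks])
            sems = np.array([c.std(ddof=1) / np.sqrt(len(c)) if len(c) > 1 else 0.0
                             for c in chunks])
            tol = 3.0 * float(np.max(sems)) + 1e-12
            monotone = bool(np.all(np.diff(means) < tol))
        else:
            monotone = True
        if not monotone:
            warnings.warn("dark-interval ECS decay is not monotone beyond noise")

        pmf = light_level - quasi_stable
        if pmf <= 0:
            raise ValueError(
                f"non-positive ECS drop across the dark interval ({pmf:.3g}); "
                "cannot partition pmf"
            )
        dpsi = (light_level - baseline) / pmf
        self.gh_plus_ = float(rate)
        self.pmf_ = float(pmf)
        self.dpsi_fraction_ = float(dpsi)
        self.dph_fraction_ = float(1.0 - dpsi)  # sums to 1 by construction
        self.baseline_ = baseline
        self.light_level_ = light_level
        self.quasi_stable_ = quasi_stable
        self.decay_amplitude_ = float(amp)
        self.converged_ = converged
        self.monotone_ = monotone
        self.t_off_ = float(t_off)
        return self


def dirk_analyze(trace: ECSTrace, dark_window: float = 30.0, **kwargs) -> DIRKAnalyzer:
    """Run DIRK analysis on an ECS trace; thin wrapper over :class:`DIRKAnalyzer`."""
    return DIRKAnalyzer(dark_window=dark_window, **kwargs).fit(trace)


def gh_ratio(ll1: DIRKAnalyzer, ll2: DIRKAnalyzer) -> float:
    """Ratio of ATP-synthase proton conductivities, gH+(LL1) / gH+(LL2)."""
    for r, name in ((ll1, "LL1"), (ll2, "LL2")):
        if not getattr(r, "converged_", False):
            raise RuntimeError(f"{name} DIRK fit did not converge")
    if ll2.gh_plus_ == 0:
        raise ZeroDivisionError("LL2 gH+ is zero")
    return ll1.gh_plus_ / ll2.gh_plus_


class I535Decomposer(BaseEstimator):
    """Biphasic decomposition of the 535-nm transmittance during LL2.

    Model: ``i535(t) = const + amp * exp(-(t - t0)/lifetime) + slope * (t - t0)``
    over the analysis window (protocol clock; default 900-1100 s).  The slow
    linear slope is the LHCII-aggregation proxy.  Fitting is a deterministic
    lifetime grid search with a linear solve for the other terms, polished
    by bounded nonlinear least squares.

    Attributes: ``fast_amplitude_, fast_lifetime_, slow_slope_, const_,
    conf_int_, residual_norm_, converged_, window_``.
    """

    def __init__(
        self,
        window: tuple[float, float] = (900.0, 1100.0),
        lifetime_bounds: tuple[float, float] = (5.0, 200.0),
        n_grid: int = 40,
    ):
        self.window = window
        self.lifetime_bounds = lifetime_bounds
        self.n_grid = n_grid

    @staticmethod
    def _design(t, lifetime):
        return np.column_stack([np.ones_like(t), np.exp(-t / lifetime), t])

    def fit(self, trace: ECSTrace):
        df = trace.data
        lo, hi = self.window
        sel = (df["t"] >= lo) & (df["t"] <= hi)
        t = df.loc[sel, "t"].to_numpy()
        y = df.loc[sel, "i535"].to_numpy()
        if len(t) < 20:
            raise ValueError(
                f"need >= 20 samples in window [{lo}, {hi}] s, got {len(t)}"
            )
        # reference the fast amplitude to the onset of the decay (start of the
        # light segment containing the window), not to the window edge
        t0 = t[0]
        try:
            seg = trace.protocol.segment_at(0.5 * (lo + hi))
            t0 = trace.protocol.segment_start(seg.label)
        except (AttributeError, ValueError, KeyError):
            pass
        tr = t - t0

        best = None
        for life in np.geomspace(*self.lifetime_bounds, self.n_grid):
            X = self._design(tr, life)
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss = float(np.sum((X @ coef - y) ** 2))
            if best is None or rss < best[0]:
                best = (rss, life, coef)
        _, life0, (c0, a0, m0) = best

        def model(t_, const, amp, life, slope):
            return const + amp * np.exp(-t_ / life) + slope * t_

        try:
            popt, pcov = optimize.curve_fit(
                model,
                tr,
                y,
                p0=(c0, a0, life0, m0),
                bounds=(
                    [-np.inf, -np.inf, self.lifetime_bounds[0], -np.inf],
                    [np.inf, np.inf, self.lifetime_bounds[1], np.inf],
                ),
                maxfev=20000,
            )
            perr = np.sqrt(np.diag(pcov))
            converged = True
        except RuntimeError:
            popt = (c0, a0, life0, m0)
            perr = np.full(4, np.nan)
            converged = False
            warnings.warn("I535 decomposition did not converge; grid solution kept")

        const, amp, life, slope = popt
        dof = max(1, len(t) - 4)
        half = stats.t.ppf(0.975, dof) * perr
        names = ("const", "fast_amplitude", "fast_lifetime", "slow_slope")
        self.const_ = float(const)
        self.fast_amplitude_ = float(amp)
        self.fast_lifetime_ = float(life)
        self.slow_slope_ = float(slope)
        self.conf_int_ = {
            n: (float(p - h), float(p + h)) for n, p, h in zip(names, popt, half)
        }
        self.residual_norm_ = float(np.linalg.norm(model(tr, *popt) - y))
        self.converged_ = converged
        self.window_ = (float(lo), float(hi))
        return self


def i535_decompose(
    trace: ECSTrace, window: tuple[float, float] = (900.0, 1100.0), **kwargs
) -> I535Decomposer:
    """Decompose the LL2 I535 decay; thin wrapper over :class:`I535Decomposer`."""
    return I535Decomposer(window=window, **kwargs).fit(trace)
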