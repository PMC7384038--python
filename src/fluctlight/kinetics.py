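"""Segmentation and NPQ relaxation kinetics for the fluctuating-light assay.

The LL2 NPQ decay is decomposed into a fast component (qE, lifetime of tens
of seconds) and a slow component (qZ, minutes) above a steady-state offset:

    NPQ(t) = A_fast * exp(-t / tau_fast) + A_slow * exp(-t / tau_slow) + offset

with t counted from the start of LL2.  Because saturating pulses are 30 s
apart while qE relaxes in 20-30 s, tau_fast is not identifiable from the
pulse train: it is constrained to a declared interval and always reported
together with that interval, never as a bare point estimate.  The fitted
offset is the steady-state LL2 NPQ; the offset minus the NPQ at the end of
LL1 is the FL-photodamage statistic (the portion of high-light-induced
quenching that does not relax).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .fluor import compute_npq, compute_phi2
from .protocols import LightProtocol
from .simulate import PAMTrace

__all__ = [
    "segment_trace",
    "segment_end_values",
    "NPQDecayFitter",
    "fit_npq_decay",
    "fl_photodamage",
    "qz_metrics",
    "FLAnalysisResult",
    "analyze_fl_trace",
]


class MissingSegmentError(ValueError):
    """A trace does not cover one or more protocol segments."""


def segment_trace(trace: PAMTrace, protocol: LightProtocol | None = None) -> pd.DataFrame:
    """Assign every pulse to its protocol segment and derive NPQ and Phi2.

    Returns a DataFrame with one row per pulse: ``t, segment, par, npq,
    phi2`` (plus ``phi_psi`` when the trace carries a PSI channel).  Raises
    :class:`MissingSegmentError` naming any protocol segment with no pulses
    (e.g. a trace truncated before HL), and ``ValueError`` for pulses
    outside the protocol time range.
    """
    protocol = protocol or trace.protocol
    t = trace.data["t"].to_numpy()
    if np.any(t < 0) or np.any(t > protocol.total_duration):
        raise ValueError(
            f"pulses outside protocol range [0, {protocol.total_duration}] s"
        )
    labels = [protocol.segment_at(ti).label for ti in t]
    out = pd.DataFrame(
        {
            "t": t,
            "segment": labels,
            "par": [protocol.segment_at(ti).intensity for ti in t],
            "npq": compute_npq(trace.fm_dark, trace.data["fmprime"].to_numpy()),
            "phi2": compute_phi2(
                trace.data["fprime"].to_numpy(), trace.data["fmprime"].to_numpy()
            ),
        }
    )
    if "phi_psi" in trace.data:
        out["phi_psi"] = trace.data["phi_psi"].to_numpy()
    missing = [s.label for s in protocol.segments if s.label not in set(labels)]
    if missing:
        raise MissingSegmentError(
            f"trace has no pulses in segment(s) {missing}; covered: "
            f"{sorted(set(labels))}"
        )
    return out


def segment_end_values(segments: pd.DataFrame, column: str = "npq") -> dict[str, float]:
    """Value of ``column`` at the last pulse of each segment."""
    return {
        label: float(grp[column].iloc[-1])
        for label, grp in segments.groupby("segment", sort=False)
    }


class NPQDecayFitter(BaseEstimator):
    """Double-exponential decomposition of the LL2 NPQ relaxation.

    Parameters
    ----------
    tau_fast_bounds : (float, float), default (10, 40) s
        Identifiability interval for the fast (qE) lifetime; the estimate is
        only meaningful as "somewhere in this interval".
    tau_slow_bounds : (float, float), default (60, 3000) s
        Search interval for the slow (qZ) lifetime.  Fits ending within 1%
        of the upper bound are flagged ``censored_`` (lifetimes beyond the
        sampling horizon cannot be resolved).
    n_starts : int, default 8
        Multi-start count; starts are log-spaced in tau_slow over its
        bounds, amplitudes initialised by linear least squares at each
        start.  The start grid is fixed, so fitting is deterministic.
    fix_tau_fast : float or None
        If given, tau_fast is held at this value instead of varying within
        its bounds.

    Attributes (after ``fit``)
    --------------------------
    a_fast_, tau_fast_, a_slow_, tau_slow_, offset_ : float
    stderr_, conf_int_, p_values_ : dict per parameter (95% limits)
    residual_norm_, converged_, degenerate_, censored_ : diagnostics
    tau_fast_interval_ : the declared tau_fast bounds, always reported
    """

    _PARAMS = ("a_fast", "tau_fast", "a_slow", "tau_slow", "offset")

    def __init__(
        self,
        tau_fast_bounds: tuple[float, float] = (10.0, 40.0),
        tau_slow_bounds: tuple[float, float] = (60.0, 3000.0),
        n_starts: int = 8,
        fix_tau_fast: float | None = None,
    ):
        self.tau_fast_bounds = tau_fast_bounds
        self.tau_slow_bounds = tau_slow_bounds
        self.n_starts = n_starts
        self.fix_tau_fast = fix_tau_fast

    # -- model ----------------------------------------------------------
    @staticmethod
    def _model(t, a_fast, tau_fast, a_slow, tau_slow, offset):
        return (
            a_fast * np.exp(-t / tau_fast)
            + a_slow * np.exp(-t / tau_slow)
            + offset
        )

    def _lin_amplitudes(self, t, y, tau_fast, tau_slow):
        """Least-squares amplitudes/offset for fixed lifetimes (clipped >= 0)."""
        basis = np.column_stack(
            [np.exp(-t / tau_fast), np.exp(-t / tau_slow), np.ones_like(t)]
        )
        coef, *_ = np.linalg.lstsq(basis, y, rcond=None)
        return np.clip(coef, 0.0, None)

    # -- fitting --------------------------------------------------------
    def fit(self, t, y):
        """Fit the decay; ``t`` in seconds from LL2 start, ``y`` the NPQ series."""
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
        if t.ndim == 2 and t.shape[1] == 1:  # sklearn-style column input
            t = t.ravel()
        if len(t) != len(y):
            raise ValueError("t and y must have equal length")
        if len(t) < 8:
            raise ValueError(f"need >= 8 points to fit a double exponential, got {len(t)}")
        if np.any(np.diff(t) <= 0) or t[0] < 0:
            raise ValueError("t must be non-negative and strictly increasing")
        if self.tau_fast_bounds[1] >= self.tau_slow_bounds[0]:
            raise ValueError("tau_fast bounds must lie below tau_slow bounds")

        self.n_points_ = len(t)
        self.tau_fast_interval_ = tuple(self.tau_fast_bounds)

        if np.ptp(y) < 1e-12:
            self._set_degenerate(float(np.mean(y)))
            return self

        best = None
        tau_slow_starts = np.geomspace(*self.tau_slow_bounds, self.n_starts)
        tau_fast_start = (
            self.fix_tau_fast
            if self.fix_tau_fast is not None
            else float(np.sqrt(np.prod(self.tau_fast_bounds)))
        )
        for tau_s0 in tau_slow_starts:
            a_f0, a_s0, off0 = self._lin_amplitudes(t, y, tau_fast_start, tau_s0)
            params = lmfit.Parameters()
            params.add("a_fast", value=max(a_f0, 1e-6), min=0.0)
            params.add(
                "tau_fast",
                value=tau_fast_start,
                min=self.tau_fast_bounds[0],
                max=self.tau_fast_bounds[1],
                vary=self.fix_tau_fast is None,
            )
            params.add("a_slow", value=max(a_s0, 1e-6), min=0.0)
            params.add(
                "tau_slow",
                value=tau_s0,
                min=self.tau_slow_bounds[0],
                max=self.tau_slow_bounds[1],
            )
            params.add("offset", value=max(off0, 0.0), min=0.0)

            def resid(p):
                return (
                    self._model(
                        t, p["a_fast"], p["tau_fast"], p["a_slow"], p["tau_slow"],
                        p["offset"],
                    )
                    - y
                )

            try:
                res = lmfit.minimize(resid, params, method="leastsq")
            except Exception:
                continue
            norm = float(np.linalg.norm(res.residual))
            key = (round(norm, 12), float(res.params["tau_slow"].value))
            if best is None or key < best[0]:
                best = (key, res, norm)

        if best is None:
            self._set_degenerate(float(np.mean(y)))
            self.converged_ = False
            warnings.warn("NPQ decay fit failed to converge from every start")
            return self

        _, res, norm = best
        for name in self._PARAMS:
            setattr(self, f"{name}_", float(res.params[name].value))
        dof = max(1, len(t) - res.nvarys)
        self.stderr_, self.conf_int_, self.p_values_ = {}, {}, {}
        for name in self._PARAMS:
            par = res.params[name]
            se = par.stderr if par.stderr is not None else np.nan
            self.stderr_[name] = float(se) if se is not None else np.nan
            half = stats.t.ppf(0.975, dof) * self.stderr_[name]
            self.conf_int_[name] = (par.value - half, par.value + half)
            with np.errstate(divide="ignore", invalid="ignore"):
                tval = par.value / se if se else np.nan
            self.p_values_[name] = (
                float(2 * stats.t.sf(abs(tval), dof)) if np.isfinite(tval) else np.nan
            )
        self.residual_norm_ = norm
        self.converged_ = bool(res.success)
        self.degenerate_ = False
        self.censored_ = self.tau_slow_ > 0.99 * self.tau_slow_bounds[1]
        if self.offset_ < 0:
            warnings.warn(f"fitted steady-state NPQ offset is negative ({self.offset_:.3g})")
        return self

    def _set_degenerate(self, offset: float) -> None:
        self.a_fast_ = 0.0
        self.a_slow_ = 0.0
        self.tau_fast_ = float(np.sqrt(np.prod(self.tau_fast_bounds)))
        self.tau_slow_ = float(np.sqrt(np.prod(self.tau_slow_bounds)))
        self.offset_ = offset
        self.stderr_ = {p: np.nan for p in self._PARAMS}
        self.conf_int_ = {p: (np.nan, np.nan) for p in self._PARAMS}
        self.p_values_ = {p: np.nan for p in self._PARAMS}
        self.residual_norm_ = 0.0
        self.converged_ = True
        self.degenerate_ = True
        self.censored_ = False

    def predict(self, t):
        """Fitted NPQ at times ``t``."""
        t = np.asarray(t, dtype=float)
        if t.ndim == 2 and t.shape[1] == 1:
            t = t.ravel()
        return self._model(
            t, self.a_fast_, self.tau_fast_, self.a_slow_, self.tau_slow_, self.offset_
        )

    def summary(self) -> dict:
        out = {p: getattr(self, f"{p}_") for p in self._PARAMS}
        out.update(
            tau_fast_interval=self.tau_fast_interval_,
            residual_norm=self.residual_norm_,
            converged=self.converged_,
            degenerate=self.degenerate_,
            censored=self.censored_,
            n_points=self.n_points_,
        )
        return out


def fit_npq_decay(t, npq, **kwargs) -> NPQDecayFitter:
    """Fit the LL2 NPQ relaxation; thin wrapper over :class:`NPQDecayFitter`."""
    return NPQDecayFitter(**kwargs).fit(t, npq)


def _require_usable(fit: NPQDecayFitter) -> None:
    if not (fit.converged_ or fit.degenerate_):
        raise RuntimeError("NPQ decay fit did not converge; metrics undefined")


def fl_photodamage(
    segments: pd.DataFrame,
    fit: NPQDecayFitter,
    steady: str = "offset",
    last_k: int = 4,
) -> float:
    """High-light-induced persistent quenching: steady-state LL2 NPQ minus
    NPQ at the end of LL1.

    ``steady="offset"`` (default) takes the fitted decay offset — robust to
    trace truncation; ``steady="last-k"`` averages the final ``last_k`` LL2
    pulses instead, for sensitivity analysis.
    """
    _require_usable(fit)
    ends = segment_end_values(segments)
    if "LL1" not in ends:
        raise MissingSegmentError("no LL1 segment in trace")
    if steady == "offset":
        ss = fit.offset_
    elif steady == "last-k":
        ll2 = segments.loc[segments["segment"] == "LL2", "npq"]
        if ll2.empty:
            raise MissingSegmentError("no LL2 segment in trace")
        ss = float(ll2.tail(last_k).mean())
    else:
        raise ValueError(f"steady must be 'offset' or 'last-k', got {steady!r}")
    return float(ss - ends["LL1"])


def qz_metrics(
    segments: pd.DataFrame,
    fit: NPQDecayFitter,
    hl_induced: str = "hl_minus_ll1",
) -> tuple[float, float]:
    """qZ amplitude as percent of HL-induced NPQ, and the qZ lifetime.

    HL-induced NPQ defaults to (NPQ at end of HL) - (NPQ at end of LL1);
    ``hl_induced="hl"`` uses the end-of-HL value alone.  Returns
    ``(nan, tau_slow)`` with a warning when the HL-induced NPQ is not
    positive.
    """
    _require_usable(fit)
    ends = segment_end_values(segments)
    for needed in ("HL", "LL1"):
        if needed not in ends:
            raise MissingSegmentError(f"no {needed} segment in trace")
    if hl_induced == "hl_minus_ll1":
        denom = ends["HL"] - ends["LL1"]
    elif hl_induced == "hl":
        denom = ends["HL"]
    else:
        raise ValueError(f"hl_induced must be 'hl_minus_ll1' or 'hl', got {hl_induced!r}")
    if denom <= 0:
        warnings.warn(
            f"HL-induced NPQ is not positive ({denom:.3g}); qZ amplitude undefined"
        )
        return float("nan"), float(fit.tau_slow_)
    return 100.0 * fit.a_slow_ / denom, float(fit.tau_slow_)


@dataclass
class FLAnalysisResult:
    """End-to-end summary of one fluctuating-light trace."""

    npq_end_vll: float
    npq_end_ll1: float
    npq_end_hl: float
    fit: NPQDecayFitter
    fl_photodamage: float
    qz_amplitude_pct: float
    qz_lifetime: float

    def to_row(self) -> dict:
        row = {
            "npq_end_vll": self.npq_end_vll,
            "npq_end_ll1": self.npq_end_ll1,
            "npq_end_hl": self.npq_end_hl,
            "fl_photodamage": self.fl_photodamage,
            "qz_amplitude_pct": self.qz_amplitude_pct,
            "qz_lifetime": self.qz_lifetime,
        }
        row.update({f"fit_{k}": v for k, v in self.fit.summary().items()})
        return row


def analyze_fl_trace(
    trace: PAMTrace,
    protocol: LightProtocol | None = None,
    steady: str = "offset",
    hl_induced: str = "hl_minus_ll1",
    **fit_kwargs,
) -> FLAnalysisResult:
    """Run the full FL analysis on one trace: segment, fit the LL2 decay,
    and derive the FL-photodamage and qZ metrics."""
    protocol = protocol or trace.protocol
    segments = segment_trace(trace, protocol)
    ends = segment_end_values(segments)
    ll2 = segments[segments["segment"] == "LL2"]
    if ll2.empty:
        raise MissingSegmentError("no LL2 segment in trace")
    t_rel = ll2["t"].to_numpy() - protocol.segment_start("LL2")
    fit = fit_npq_decay(t_rel, ll2["npq"].to_numpy(), **fit_kwargs)
    damage = fl_photodamage(segments, fit, steady=steady)
    qz_pct, qz_tau = qz_metrics(segments, fit, hl_induced=hl_induced)
    return FLAnalysisResult(
        npq_end_vll=ends.get("VLL", float("nan")),
        npq_end_ll1=ends["LL1"],
        npq_end_hl=ends["HL"],
        fit=fit,
        fl_photodamage=damage,
        qz_amplitude_pct=qz_pct,
        qz_lifetime=qz_tau,
    )
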