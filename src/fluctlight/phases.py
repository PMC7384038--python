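"""Drought-phase classification from multi-day monitoring tables.

A slowly drying pot passes through four phases defined by when a persistent
drought-vs-control effect appears in successive physiological parameters:

* Phase I   — soil water declines; transpiration, NPQ and photodamage unchanged.
* Phase II  — transpiration decreases.
* Phase III — NPQ increases, still without extra photodamage.
* Phase IV  — photodamage (Fv/Fm decline or FL-photodamage rise) appears.

Onsets are detected per parameter by a per-day treatment-vs-control test
(two-factor linear model with cultivar as the second factor when present),
requiring the effect to be significant, in the physiologically expected
direction, and persistent over consecutive days.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from sklearn.base import BaseEstimator

__all__ = [
    "SlopeComparison",
    "npq_par_slope_test",
    "OnsetDetector",
    "detect_onsets",
    "classify_phases",
    "PhaseCall",
    "DroughtPhaseClassifier",
]

PHASES = ("I", "II", "III", "IV")

# physiologically expected sign of the drought effect per criterion
_DIRECTIONS = {"transpiration": -1, "npq": +1, "fl_photodamage": +1, "fvfm": -1}


class SlopeComparison(BaseEstimator):
    """Test equality of per-group regression slopes (ANCOVA interaction).

    Fits ``y ~ x * group`` by OLS within ``x_range`` and tests the
    group-by-covariate interaction.  With two groups the reported p-value is
    the interaction-term Wald test, identical to the F-test comparing the
    common-slope and separate-slopes models.

    Attributes: ``slopes_``, ``intercepts_`` (per group), ``slope_diff_``
    (two-group case), ``p_value_``, ``x_range_``, ``n_per_group_``.
    """

    def __init__(self, x_range: tuple[float, float] | None = None, robust: bool = False):
        self.x_range = x_range
        self.robust = robust

    def fit(self, df: pd.DataFrame, x: str = "x", y: str = "y", group: str = "group"):
        data = df[[x, y, group]].dropna().rename(columns={x: "_x", y: "_y", group: "_g"})
        if self.x_range is not None:
            lo, hi = self.x_range
            data = data[(data["_x"] >= lo) & (data["_x"] <= hi)]
            if data.empty:
                raise ValueError(f"no records within x range [{lo}, {hi}]")
        counts = data.groupby("_g").size()
        if len(counts) < 2:
            raise ValueError(f"need >= 2 groups, got {list(counts.index)}")
        low = counts[counts < 3]
        if len(low):
            raise ValueError(
                f"need >= 3 in-range records per group; too few in {dict(low)}"
            )
        var = data.groupby("_g")["_x"].var()
        flat = var[var <= 0]
        if len(flat):
            raise ValueError(f"degenerate covariate (zero variance) in group(s) "
                             f"{list(flat.index)}")

        cov_type = "HC3" if self.robust else "nonrobust"
        full = smf.ols("_y ~ _x * C(_g)", data=data).fit(cov_type=cov_type)
        reduced = smf.ols("_y ~ _x + C(_g)", data=data).fit(cov_type=cov_type)

        groups = sorted(counts.index)
        base = groups[0]
        slopes = {base: float(full.params["_x"])}
        for g in groups[1:]:
            slopes[g] = float(full.params["_x"] + full.params[f"_x:C(_g)[T.{g}]"])
        intercepts = {base: float(full.params["Intercept"])}
        for g in groups[1:]:
            intercepts[g] = float(
                full.params["Intercept"] + full.params[f"C(_g)[T.{g}]"]
            )
        if len(groups) == 2:
            term = f"_x:C(_g)[T.{groups[1]}]"
            p = float(full.pvalues[term])
            self.slope_diff_ = float(full.params[term])
        else:
            p = float(full.compare_f_test(reduced)[1])
            self.slope_diff_ = None

        self.slopes_ = slopes
        self.intercepts_ = intercepts
        self.p_value_ = p
        self.model_ = full
        self.x_range_ = self.x_range or (float(data["_x"].min()), float(data["_x"].max()))
        self.n_per_group_ = dict(counts)
        return self


def npq_par_slope_test(
    records: pd.DataFrame,
    par_range: tuple[float, float] | None = None,
    **kwargs,
) -> SlopeComparison:
    """Compare NPQ-vs-PAR regression slopes between groups.

    ``records`` needs columns ``par``, ``npq`` and ``group`` (e.g. WW / DS).
    Thin wrapper over :class:`SlopeComparison`.
    """
    return SlopeComparison(x_range=par_range, **kwargs).fit(
        records, x="par", y="npq", group="group"
    )


class OnsetDetector(BaseEstimator):
    """Detect the first day of a persistent drought effect per parameter.

    For each monitored parameter and day, the drought-vs-control contrast is
    tested with an additive two-factor linear model (treatment + cultivar;
    treatment only when a single cultivar is present) and the treatment
    effect (DS - WW mean difference) extracted.  The onset is the first day
    whose effect is significant at ``alpha``, has the physiologically
    expected sign, and stays significant for ``persistence`` consecutive
    days.  The sign restriction keeps the family-wise false-onset rate of a
    null time course low without any cross-day multiplicity correction
    (matching per-day testing conventions); an optional Holm step-down
    correction across days is available.

    With a single replicate per group no test is possible: the detector
    falls back to an absolute effect-size threshold with a warning.
    """

    def __init__(
        self,
        parameters: tuple[str, ...] = ("transpiration", "npq", "fl_photodamage"),
        alpha: float = 0.05,
        persistence: int = 2,
        damage_channel: str = "fl_photodamage",
        correct_across_days: bool = False,
        effect_thresholds: dict | None = None,
    ):
        self.parameters = parameters
        self.alpha = alpha
        self.persistence = persistence
        self.damage_channel = damage_channel
        self.correct_across_days = correct_across_days
        self.effect_thresholds = effect_thresholds

    def _resolved_parameters(self) -> list[str]:
        out = []
        for p in self.parameters:
            if p in ("damage", "fl_photodamage", "fvfm"):
                out.append(self.damage_channel if p == "damage" else p)
            else:
                out.append(p)
        return out

    def fit(self, tc: pd.DataFrame):
        required = {"treatment", "day"}
        missing = required - set(tc.columns)
        if missing:
            raise ValueError(f"time course lacks columns {sorted(missing)}")
        params = self._resolved_parameters()
        for p in params:
            if p not in tc.columns:
                raise ValueError(f"parameter column {p!r} not in time course")
        days = np.sort(tc["day"].unique())
        if not np.array_equal(days, np.arange(days.min(), days.max() + 1)):
            raise ValueError("days must form a contiguous integer range")
        two_cultivars = "cultivar" in tc.columns and tc["cultivar"].nunique() > 1

        single_rep = False
        if "replicate" in tc.columns:
            single_rep = (
                tc.groupby(["treatment", "day"])["replicate"].nunique().min() < 2
                and not two_cultivars
            )
        if single_rep:
            warnings.warn(
                "single replicate per group: falling back to effect-size "
                "threshold mode (no significance testing possible)"
            )
        thresholds = self.effect_thresholds or {}

        pvals = pd.DataFrame(index=days, columns=params, dtype=float)
        effects = pd.DataFrame(index=days, columns=params, dtype=float)
        for day in days:
            sub = tc[tc["day"] == day]
            for p in params:
                ds = sub.loc[sub["treatment"] == "DS", p]
                ww = sub.loc[sub["treatment"] == "WW", p]
                eff = float(ds.mean() - ww.mean())
                effects.loc[day, p] = eff
                if single_rep:
                    thr = thresholds.get(p, np.inf)
                    pvals.loc[day, p] = 0.0 if abs(eff) > thr else 1.0
                    continue
                if two_cultivars:
                    model = smf.ols(f"{p} ~ C(treatment) + C(cultivar)", data=sub).fit()
                else:
                    model = smf.ols(f"{p} ~ C(treatment)", data=sub).fit()
                term = [c for c in model.params.index if c.startswith("C(treatment)")][0]
                pvals.loc[day, p] = float(model.pvalues[term])

        if self.correct_across_days:
            from statsmodels.stats.multitest import multipletests

            for p in params:
                ok = pvals[p].notna()
                pvals.loc[ok, p] = multipletests(
                    pvals.loc[ok, p].to_numpy(), method="holm"
                )[1]

        onsets: dict[str, int | None] = {}
        for p in params:
            direction = _DIRECTIONS.get(p, +1)
            sig = (
                (pvals[p] < self.alpha)
                & (np.sign(effects[p]) == direction)
            ).to_numpy()
            onset = None
            need = self.persistence
            for i in range(len(days) - need + 1):
                if sig[i : i + need].all():
                    onset = int(days[i])
                    break
            onsets[p] = onset

        self.p_values_ = pvals
        self.effects_ = effects
        self.onsets_ = onsets
        self.days_ = days
        self.parameters_ = params
        return self


def detect_onsets(
    tc: pd.DataFrame,
    alpha: float = 0.05,
    persistence: int = 2,
    **kwargs,
) -> dict[str, int | None]:
    """Per-criterion onset days of a persistent drought effect; thin wrapper
    over :class:`OnsetDetector`."""
    det = OnsetDetector(alpha=alpha, persistence=persistence, **kwargs).fit(tc)
    return det.onsets_


@dataclass
class PhaseCall:
    """Per-day drought-phase labels plus the onsets that generated them."""

    phases: pd.Series  # index day, values in {"I", "II", "III", "IV"}
    onsets: dict

    def phase_days(self, phase: str) -> list[int]:
        return list(self.phases.index[self.phases == phase])


def classify_phases(
    onsets: dict | tuple,
    n_days: int,
    first_day: int = 1,
) -> PhaseCall:
    """Map onset days to per-day phase labels over days ``first_day..n_days``.

    ``onsets`` is ``(transpiration, npq, damage)`` (entries may be None) or
    a dict with those keys (``fl_photodamage``/``fvfm`` accepted for the
    damage slot).  Days before the transpiration onset are Phase I; from it
    to the NPQ onset Phase II; then Phase III; from the damage onset Phase
    IV.  Absent onsets truncate the sequence; out-of-order onsets raise.
    """
    if isinstance(onsets, dict):
        damage = next(
            (onsets[k] for k in ("damage", "fl_photodamage", "fvfm") if k in onsets),
            None,
        )
        triple = (onsets.get("transpiration"), onsets.get("npq"), damage)
    else:
        triple = tuple(onsets)
        if len(triple) != 3:
            raise ValueError("expected (transpiration, npq, damage) onsets")
    names = ("transpiration", "npq", "damage")
    present = [(n, d) for n, d in zip(names, triple) if d is not None]
    for (n1, d1), (n2, d2) in zip(present, present[1:]):
        if d2 < d1:
            raise ValueError(
                f"onsets out of order: {n2} onset (day {d2}) precedes "
                f"{n1} onset (day {d1})"
            )

    days = np.arange(first_day, n_days + 1)
    labels = np.array(["I"] * len(days), dtype=object)
    for phase, onset in zip(("II", "III", "IV"), triple):
        if onset is not None:
            labels[days >= onset] = phase
    phases = pd.Series(labels, index=days, name="phase")
    return PhaseCall(phases=phases, onsets={k: v for k, v in zip(names, triple)})


class DroughtPhaseClassifier(BaseEstimator):
    """Onset detection plus phase labelling as one fit/predict estimator.

    ``fit`` detects onsets on a monitoring table; ``predict(days)`` returns
    the phase label for each requested day.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        persistence: int = 2,
        damage_channel: str = "fl_photodamage",
    ):
        self.alpha = alpha
        self.persistence = persistence
        self.damage_channel = damage_channel

    def fit(self, tc: pd.DataFrame):
        det = OnsetDetector(
            alpha=self.alpha,
            persistence=self.persistence,
            damage_channel=self.damage_channel,
            parameters=("transpiration", "npq", "damage"),
        ).fit(tc)
        self.detector_ = det
        self.onsets_ = {
            "transpiration": det.onsets_.get("transpiration"),
            "npq": det.onsets_.get("npq"),
            "damage": det.onsets_.get(self.damage_channel),
        }
        n_days = int(det.days_.max())
        self.phase_call_ = classify_phases(
            (self.onsets_["transpiration"], self.onsets_["npq"], self.onsets_["damage"]),
            n_days=n_days,
            first_day=int(max(1, det.days_.min())),
        )
        return self

    def predict(self, days) -> np.ndarray:
        days = np.asarray(days, dtype=int)
        ph = self.phase_call_.phases
        out = []
        for d in days:
            if d in ph.index:
                out.append(ph.loc[d])
            elif d < ph.index.min():
                out.append("I")
            else:
                out.append(ph.iloc[-1])
        return np.array(out, dtype=object)
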