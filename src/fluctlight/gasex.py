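"""Light-curve analysis coupling gas exchange with fluorescence.

Net CO2 assimilation plotted against linear electron flow is close to
linear at sub-saturating light; a reduced slope under drought indicates
that a larger share of photosynthetic electron flow feeds alternative
sinks (photorespiration, Mehler reaction) rather than carbon fixation.
Slopes are compared within a bounded LEF range — by default up to and
including 85 umol e- m-2 s-1, the range drought-stressed leaves can reach.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .fluor import compute_lef
from .phases import SlopeComparison

__all__ = ["LightCurveResult", "aco2_lef_slopes"]


@dataclass
class LightCurveResult:
    """Per-step LEF table plus the per-condition A_CO2-vs-LEF regression."""

    table: pd.DataFrame              # input rows + computed lef, range flag
    slopes: dict[str, float]         # a_co2 per unit lef, per condition
    intercepts: dict[str, float]
    slope_diff: float | None         # two-condition case
    p_value: float                   # slope-equality (interaction) test
    lef_max: float
    comparison: SlopeComparison


def aco2_lef_slopes(
    table: pd.DataFrame,
    abs_frac: float = 0.86,
    lef_max: float = 85.0,
    psii_fraction: float = 0.5,
    per_plant_means: bool = False,
    robust: bool = False,
) -> LightCurveResult:
    """Compare A_CO2-vs-LEF slopes between conditions within ``lef <= lef_max``.

    ``table`` needs columns ``condition, par, phi2, a_co2`` (replicated rows
    are pooled by default; ``per_plant_means=True`` averages over a
    ``plant`` column first).  LEF is computed as
    ``phi2 * par * abs_frac * psii_fraction``; the range bound is inclusive.
    Raises when any condition has fewer than 3 in-range points.
    """
    required = {"condition", "par", "phi2", "a_co2"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"gas-exchange table lacks columns {sorted(missing)}")
    df = table.copy()
    df["lef"] = compute_lef(
        df["phi2"].to_numpy(), df["par"].to_numpy(), abs_frac, psii_fraction
    )
    if per_plant_means:
        if "plant" not in df.columns:
            raise ValueError("per_plant_means requires a 'plant' column")
        df = (
            df.groupby(["condition", "plant", "par"], as_index=False)
            .mean(numeric_only=True)
        )
    df["in_range"] = df["lef"] <= lef_max
    in_range = df[df["in_range"]]
    counts = in_range.groupby("condition").size()
    if in_range.empty or len(counts) < df["condition"].nunique() or (counts < 3).any():
        raise ValueError(
            f"need >= 3 points with lef <= {lef_max} per condition; "
            f"in-range counts: {counts.to_dict()}"
        )
    cmp = SlopeComparison(x_range=(0.0, lef_max), robust=robust).fit(
        df, x="lef", y="a_co2", group="condition"
    )
    return LightCurveResult(
        table=df,
        slopes=cmp.slopes_,
        intercepts=cmp.intercepts_,
        slope_diff=cmp.slope_diff_,
        p_value=cmp.p_value_,
        lef_max=lef_max,
        comparison=cmp,
    )
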