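"""Readers/writers for trace tables, config parsing, and the run pipeline.

All tabular formats are comma-separated text with a one-line header; a
sidecar YAML file (``<table>.meta.yaml``) carries the protocol, dark
reference and any simulator ground truth.  Times are seconds, days are
integers counted from the last day of watering (day 0).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .protocols import LightProtocol, fl_protocol, dirk_protocol
from .simulate import (
    DroughtEffects,
    DroughtNoise,
    ECSTrace,
    PAMTrace,
    QuenchingParams,
    simulate_drought_timecourse,
    simulate_ecs_trace,
    simulate_gas_exchange,
    simulate_pam_trace,
)

__all__ = [
    "KINDS",
    "read_trace",
    "write_trace",
    "RunConfig",
    "load_config",
    "run_pipeline",
]

_SCHEMAS = {
    "pam": ["t", "segment", "par", "fprime", "fmprime"],
    "ecs": ["t", "segment", "ecs", "i535", "light_state"],
    "drought": ["treatment", "replicate", "day", "soil_water", "transpiration", "npq"],
    "gasex": ["condition", "par", "phi2", "a_co2"],
    "spectrum": ["wavelength", "intensity"],
}
KINDS = tuple(_SCHEMAS)


def _meta_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.yaml")


def _check_schema(df: pd.DataFrame, kind: str, path: Path) -> None:
    missing = [c for c in _SCHEMAS[kind] if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing column(s) {missing} for kind {kind!r} "
            f"(required: {_SCHEMAS[kind]}, found: {list(df.columns)})"
        )


def _first_violation(mask: pd.Series) -> int:
    """1-based data row number (header excluded) of the first True entry."""
    return int(np.nonzero(mask.to_numpy())[0][0]) + 1


def write_trace(obj, path) -> Path:
    """Write a trace/table as CSV plus a ``.meta.yaml`` sidecar; returns the path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta: dict = {}
    if isinstance(obj, PAMTrace):
        obj.data.to_csv(path, index=False)
        meta = {
            "kind": "pam",
            "protocol": obj.protocol.to_dict(),
            "f0_dark": obj.f0_dark,
            "fm_dark": obj.fm_dark,
        }
        if obj.truth is not None:
            meta["truth"] = {
                k: obj.truth[k].tolist() for k in obj.truth.columns if k != "segment"
            }
    elif isinstance(obj, ECSTrace):
        obj.data.to_csv(path, index=False)
        meta = {
            "kind": "ecs",
            "protocol": obj.protocol.to_dict(),
            "sampling_rate": obj.sampling_rate,
        }
        if obj.truth is not None:
            meta["truth"] = obj.truth
    elif isinstance(obj, pd.DataFrame):
        obj.to_csv(path, index=False)
        meta = {"kind": obj.attrs.get("kind", "table")}
        if "truth" in obj.attrs:
            meta["truth"] = obj.attrs["truth"]
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    with open(_meta_path(path), "w") as fh:
        yaml.safe_dump(_plain(meta), fh, sort_keys=False)
    return path


def _plain(obj):
    """Recursively convert numpy scalars for YAML serialisation."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def read_trace(path, kind: str):
    """Read and validate a trace/table of the given kind.

    Kinds: ``pam`` -> :class:`PAMTrace`, ``ecs`` -> :class:`ECSTrace`,
    ``drought``/``gasex``/``spectrum`` -> validated DataFrame.  Schema
    mismatches name the missing columns; invariant violations name the
    offending data row.
    """
    if kind not in KINDS:
        raise ValueError(f"unknown kind {kind!r}; supported kinds: {list(KINDS)}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such trace file: {path}")
    df = pd.read_csv(path)
    _check_schema(df, kind, path)
    meta = {}
    mp = _meta_path(path)
    if mp.exists():
        with open(mp) as fh:
            meta = yaml.safe_load(fh) or {}

    if kind == "pam":
        bad = df["fprime"] > df["fmprime"]
        if bad.any():
            raise ValueError(
                f"{path}: Fprime > Fmprime on row {_first_violation(bad)}"
            )
        nonpos = (df["fprime"] <= 0) | (df["fmprime"] <= 0)
        if nonpos.any():
            raise ValueError(
                f"{path}: non-positive fluorescence on row {_first_violation(nonpos)}"
            )
        if "protocol" not in meta:
            raise ValueError(f"{path}: sidecar {mp.name} with a protocol is required")
        protocol = LightProtocol.from_dict(meta["protocol"])
        truth = None
        if "truth" in meta:
            truth = pd.DataFrame(meta["truth"])
            truth["segment"] = df["segment"].to_numpy()
        return PAMTrace(
            data=df,
            protocol=protocol,
            f0_dark=float(meta["f0_dark"]),
            fm_dark=float(meta["fm_dark"]),
            truth=truth,
        )

    if kind == "ecs":
        if "protocol" not in meta:
            raise ValueError(f"{path}: sidecar {mp.name} with a protocol is required")
        return ECSTrace(
            data=df,
            protocol=LightProtocol.from_dict(meta["protocol"]),
            sampling_rate=float(meta.get("sampling_rate", 10.0)),
            truth=meta.get("truth"),
        )

    if kind == "drought":
        if "fvfm" in df.columns:
            bad = (df["fvfm"] < 0) | (df["fvfm"] > 1)
            if bad.any():
                raise ValueError(
                    f"{path}: Fv/Fm outside [0, 1] on row {_first_violation(bad)}"
                )
        df.attrs["truth"] = meta.get("truth", {})
        return df

    if kind == "gasex":
        for cond, grp in df.groupby("condition"):
            if not grp["par"].is_monotonic_increasing:
                raise ValueError(
                    f"{path}: PAR not strictly increasing within condition {cond!r}"
                )
        return df

    # spectrum
    wl = df["wavelength"].to_numpy()
    if np.any(np.diff(wl) <= 0):
        bad_row = int(np.nonzero(np.diff(wl) <= 0)[0][0]) + 2
        raise ValueError(f"{path}: wavelengths not strictly increasing at row {bad_row}")
    neg = df["intensity"] < 0
    if neg.any():
        raise ValueError(f"{path}: negative intensity on row {_first_violation(neg)}")
    return df


# --------------------------------------------------------------------------
# Run configuration and end-to-end pipeline
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Parameters for an end-to-end synthetic run.

    Defaults are the standard measurement conventions: 57/166/1466
    umol photons m-2 s-1 light phases with 30-s pulses, absorptivity 0.86,
    LEF comparison bound 85 umol e- m-2 s-1, I535 window 900-1100 s,
    onset testing at alpha 0.05 with 2-day persistence.
    """

    seed: int = 0
    outdir: str = "results"
    ll2_duration: float = 1800.0
    quenching: dict = field(default_factory=dict)
    ecs: dict = field(default_factory=dict)
    drought: dict = field(default_factory=dict)
    gasex: dict = field(default_factory=dict)
    tau_fast_bounds: tuple = (10.0, 40.0)
    tau_slow_bounds: tuple = (60.0, 3000.0)
    alpha: float = 0.05
    persistence: int = 2
    damage_channel: str = "fl_photodamage"
    abs_frac: float = 0.86
    lef_max: float = 85.0
    i535_window: tuple = (900.0, 1100.0)
    verbosity: int = 1

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**d)
        for name in ("tau_fast_bounds", "tau_slow_bounds", "i535_window"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg


def load_config(path) -> RunConfig:
    """Load a YAML run configuration."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such config file: {path}")
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh) or {})


def run_pipeline(config: RunConfig) -> dict:
    """Simulate all five data kinds and run every analysis stage.

    Writes result tables and a machine-readable manifest into
    ``config.outdir``; identical config + seed gives byte-identical outputs.
    Returns a dict of the result objects.  Any stage failure is re-raised
    with the stage name prepended.
    """
    from .dirk import dirk_analyze, i535_decompose
    from .gasex import aco2_lef_slopes
    from .kinetics import analyze_fl_trace
    from .phases import OnsetDetector, classify_phases

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    stage = "setup"
    try:
        stage = "simulate"
        qp = QuenchingParams(**{"seed": config.seed, **config.quenching})
        protocol = fl_protocol(ll2_duration=config.ll2_duration)
        pam = simulate_pam_trace(qp, protocol)
        write_trace(pam, out / "pam_trace.csv")
        ecs = simulate_ecs_trace(seed=config.seed, **config.ecs)
        write_trace(ecs, out / "ecs_trace.csv")
        tc = simulate_drought_timecourse(seed=config.seed, **config.drought)
        tc.attrs["kind"] = "drought"
        write_trace(tc, out / "drought_timecourse.csv")
        gx = simulate_gas_exchange(seed=config.seed, **config.gasex)
        gx.attrs["kind"] = "gasex"
        write_trace(gx, out / "gas_exchange.csv")

        stage = "fl-analysis"
        fl = analyze_fl_trace(
            pam,
            tau_fast_bounds=config.tau_fast_bounds,
            tau_slow_bounds=config.tau_slow_bounds,
        )
        pd.DataFrame([fl.to_row()]).to_csv(out / "fl_results.csv", index=False)
        results["fl"] = fl

        stage = "dirk"
        dk = dirk_analyze(ecs)
        i5 = i535_decompose(ecs, window=config.i535_window)
        pd.DataFrame(
            [
                {
                    "gh_plus": dk.gh_plus_,
                    "pmf": dk.pmf_,
                    "dph_fraction": dk.dph_fraction_,
                    "dpsi_fraction": dk.dpsi_fraction_,
                    "i535_fast_amplitude": i5.fast_amplitude_,
                    "i535_fast_lifetime": i5.fast_lifetime_,
                    "i535_slow_slope": i5.slow_slope_,
                }
            ]
        ).to_csv(out / "dirk_results.csv", index=False)
        results["dirk"], results["i535"] = dk, i5

        stage = "phases"
        det = OnsetDetector(
            alpha=config.alpha,
            persistence=config.persistence,
            damage_channel=config.damage_channel,
            parameters=("transpiration", "npq", "damage"),
        ).fit(tc)
        call = classify_phases(
            (
                det.onsets_.get("transpiration"),
                det.onsets_.get("npq"),
                det.onsets_.get(config.damage_channel),
            ),
            n_days=int(det.days_.max()),
        )
        call.phases.rename_axis("day").reset_index().to_csv(
            out / "phase_calls.csv", index=False
        )
        det.p_values_.rename_axis("day").to_csv(out / "onset_pvalues.csv")
        results["phases"] = call

        stage = "light-curve"
        lc = aco2_lef_slopes(gx, abs_frac=config.abs_frac, lef_max=config.lef_max)
        lc.table.to_csv(out / "light_curve.csv", index=False)
        results["light_curve"] = lc
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "package": "fluctlight",
        "version": __version__,
        "seed": config.seed,
        "config": _plain(
            {f: getattr(config, f) for f in config.__dataclass_fields__}
        ),
        "outputs": sorted(
            p.name for p in out.iterdir() if p.is_file() and p.name != "manifest.json"
        ),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return results
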