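"""Configuration files, run orchestration and artifact I/O.

Scenario configurations are flat YAML/JSON mappings, optionally inheriting
from a named preset via a ``preset:`` key; unknown keys are rejected
(fail-closed) so that a typo cannot silently fall back to a default.
Every run writes a manifest with a deterministic hash of the fully
resolved configuration, the trajectory as tidy CSV and the event log as
JSON lines.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cycle_engine import (
    CultureTrajectory,
    GrowthParams,
    PatternType,
    PhaseDurations,
    ScenarioConfig,
    StarchParams,
    simulate_culture,
)
from .lightfield import AttenuationModel, calibrate_attenuation
from .presets import get_preset
from .stats import (
    DivisionStats,
    division_number,
    doubling_time,
    fold_retardation,
    mass_doubling_time,
    mass_multiplication_factor,
    percent_of_control,
)
from .synthetic_data import OD_PER_UG_ML

__all__ = [
    "load_config",
    "config_to_dict",
    "config_hash",
    "run_simulate",
    "run_stats",
    "run_calibrate",
]

_CSV_FLOAT_FORMAT = "%.12g"  # round-trips at 12 significant digits

_NESTED = {
    "phase": PhaseDurations,
    "growth": GrowthParams,
    "starch": StarchParams,
}
_TOP_KEYS = {f.name for f in dataclasses.fields(ScenarioConfig)} | {"preset"}


def config_to_dict(cfg: ScenarioConfig) -> dict:
    """Fully resolved configuration as a plain JSON/YAML-serializable dict."""
    d: dict = {}
    for f in dataclasses.fields(ScenarioConfig):
        v = getattr(cfg, f.name)
        if isinstance(v, PatternType):
            v = v.value
        elif isinstance(v, (PhaseDurations, GrowthParams, StarchParams)):
            v = dataclasses.asdict(v)
        elif isinstance(v, AttenuationModel):
            v = {"c1": v.c1, "c2": v.c2}
        elif f.name == "light_schedule" and v is not None:
            v = [list(seg) for seg in v]
        elif f.name == "cohort_fractions":
            v = {int(k): float(x) for k, x in dict(v).items()}
        elif f.name == "retardation":
            v = list(v)
        d[f.name] = v
    return d


def config_from_dict(raw: dict) -> ScenarioConfig:
    """Build a scenario from a flat mapping, resolving ``preset:`` inheritance.

    Unknown keys raise a ``ValueError`` naming every offending key.
    """
    raw = dict(raw)
    unknown = sorted(set(raw) - _TOP_KEYS)
    if unknown:
        raise ValueError(f"unknown configuration keys: {', '.join(unknown)}")
    if "preset" not in raw:
        missing = sorted({"pattern", "I_i"} - set(raw))
        if missing:
            raise ValueError(
                "configuration without a 'preset' must specify: " + ", ".join(missing)
            )
    base = get_preset(raw.pop("preset")) if "preset" in raw else ScenarioConfig()
    merged = config_to_dict(base)
    merged.update(raw)

    kwargs: dict = {}
    for key, val in merged.items():
        if key == "pattern":
            kwargs[key] = val if isinstance(val, PatternType) else PatternType(val)
        elif key in _NESTED:
            if isinstance(val, dict):
                cls = _NESTED[key]
                known = {f.name for f in dataclasses.fields(cls)}
                bad = sorted(set(val) - known)
                if bad:
                    raise ValueError(f"unknown {key} keys: {', '.join(bad)}")
                kwargs[key] = cls(**val)
            else:
                kwargs[key] = val
        elif key == "attenuation":
            if isinstance(val, dict):
                kwargs[key] = AttenuationModel(c1=val["c1"], c2=val["c2"])
            else:
                kwargs[key] = val
        elif key == "light_schedule":
            kwargs[key] = None if val is None else tuple(tuple(s) for s in val)
        elif key == "cohort_fractions":
            kwargs[key] = {int(k): float(v) for k, v in dict(val).items()}
        elif key == "retardation":
            kwargs[key] = tuple(val)
        else:
            kwargs[key] = val
    return ScenarioConfig(**kwargs)


def load_config(path: str | Path) -> ScenarioConfig:
    """Load a YAML or JSON scenario configuration file."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError(f"configuration in {path} must be a mapping")
    return config_from_dict(raw)


def config_hash(cfg: ScenarioConfig) -> str:
    """Deterministic sha256 of the canonical JSON form of the configuration."""
    canon = json.dumps(config_to_dict(cfg), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()


def write_trajectory(traj: CultureTrajectory, outdir: str | Path) -> dict[str, str]:
    """Write trajectory CSV, event-log JSONL and manifest; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    csv_path = outdir / "trajectory.csv"
    traj.data.to_csv(csv_path, index=False, float_format=_CSV_FLOAT_FORMAT)
    ev_path = outdir / "events.jsonl"
    with ev_path.open("w") as fh:
        for e in traj.events:
            fh.write(
                json.dumps(
                    {"time": e.time, "event": e.kind, "k": e.k, "payload": e.payload}
                )
                + "\n"
            )
    manifest = {
        "scenario": traj.config.name,
        "config_hash": config_hash(traj.config),
        "package_version": __version__,
        "truncated": traj.truncated,
        "outputs": {"trajectory": csv_path.name, "events": ev_path.name},
    }
    man_path = outdir / "manifest.json"
    man_path.write_text(json.dumps(manifest, indent=2) + "\n")
    return {"trajectory": str(csv_path), "events": str(ev_path), "manifest": str(man_path)}


def run_simulate(config_path: str | Path, outdir: str | Path) -> CultureTrajectory:
    """Load a config, simulate, and write all artifacts."""
    cfg = load_config(config_path)
    traj = simulate_culture(cfg)
    write_trajectory(traj, outdir)
    return traj


def _series_stats(df: pd.DataFrame, path: str) -> tuple[float, float, float, float, float, float]:
    for col in ("time_h", "cell_conc_1e6_per_ml"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    t0, t1 = float(df["time_h"].iloc[0]), float(df["time_h"].iloc[-1])
    n0, n1 = float(df["cell_conc_1e6_per_ml"].iloc[0]), float(df["cell_conc_1e6_per_ml"].iloc[-1])
    if n1 <= n0:
        idx = int(df["cell_conc_1e6_per_ml"].idxmax())
        raise ValueError(
            f"{path}: cell counts do not increase over the declared cycle "
            f"(first {n0}, last {n1}; maximum at row {idx}) — doubling time undefined"
        )
    if "od750" in df.columns:
        od0, od1 = float(df["od750"].iloc[0]), float(df["od750"].iloc[-1])
    elif "dry_matter_ug_per_ml" in df.columns:
        od0 = float(df["dry_matter_ug_per_ml"].iloc[0]) * OD_PER_UG_ML
        od1 = float(df["dry_matter_ug_per_ml"].iloc[-1]) * OD_PER_UG_ML
    else:
        raise ValueError(
            f"{path}: need an 'od750' or 'dry_matter_ug_per_ml' column for mass statistics"
        )
    return t0, t1, n0, n1, od0, od1


def run_stats(
    series_csv: str | Path, control_csv: str | Path | None = None
) -> dict[str, object]:
    """Division/mass statistics of one series, optionally versus a control.

    The series is one full division cycle in tidy CSV form (columns
    ``time_h``, ``cell_conc_1e6_per_ml`` and ``od750`` or dry matter).
    With a control, percent-of-control and fold-retardation columns are
    included for both the division number and the mass factor.
    """
    df = pd.read_csv(series_csv)
    t0, t1, n0, n1, od0, od1 = _series_stats(df, str(series_csv))
    stats = DivisionStats(
        division_number=division_number(n0, n1),
        doubling_time=doubling_time(t0, t1, n0, n1),
        mass_multiplication_factor=mass_multiplication_factor(od0, od1),
        mass_doubling_time=mass_doubling_time(t0, t1, od0, od1),
    )
    out: dict[str, object] = {"treated": stats.rounded(), "raw": dataclasses.asdict(stats)}
    if control_csv is not None:
        cdf = pd.read_csv(control_csv)
        ct0, ct1, cn0, cn1, cod0, cod1 = _series_stats(cdf, str(control_csv))
        c_dn = division_number(cn0, cn1)
        c_td = doubling_time(ct0, ct1, cn0, cn1)
        c_mm = mass_multiplication_factor(cod0, cod1)
        c_mtd = mass_doubling_time(ct0, ct1, cod0, cod1)
        out["control"] = DivisionStats(
            division_number=c_dn,
            doubling_time=c_td,
            mass_multiplication_factor=c_mm,
            mass_doubling_time=c_mtd,
        ).rounded()
        out["comparison"] = {
            "division_percent_of_control": percent_of_control(stats.division_number, c_dn),
            "division_fold_retardation": fold_retardation(stats.doubling_time, c_td),
            "mass_percent_of_control": percent_of_control(
                stats.mass_multiplication_factor, c_mm
            ),
            "mass_fold_retardation": fold_retardation(stats.mass_doubling_time, c_mtd),
        }
    return out


def run_calibrate(anchors_csv: str | Path) -> AttenuationModel:
    """Fit the attenuation model from a CSV of (incident, mean, dry_matter)."""
    df = pd.read_csv(anchors_csv)
    for col in ("incident", "mean", "dry_matter"):
        if col not in df.columns:
            raise ValueError(f"{anchors_csv}: missing required column {col!r}")
    anchors = list(
        zip(df["incident"].astype(float), df["mean"].astype(float), df["dry_matter"].astype(float))
    )
    return calibrate_attenuation(anchors)
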