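"""Readers, writers, unit conversions, and scenario configuration.

CSV schemas
-----------
concentration curve : time_h, value_pct_id [, sd_pct_id, n]
uptake assay        : config, phenotype, dose_mg_per_ml, time_h, value, replicate
trajectory          : time_h, xb, xp, xt, mb, mp, mt, eliminated,
                      blood_total, peripheral_total, tumor_total

Floats are written with 17 significant digits so write/read round-trips
are lossless.  Scenario configs are YAML or JSON with a closed key set.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError
from .sixcomp import PhenotypeMap, ScalingPolicy, Trajectory
from .two_compartment import ConcentrationCurve, TwoCompartmentParams
from .uptake import validate_assay_table

__all__ = [
    "convert_id_per_g_to_id",
    "convert_id_to_id_per_g",
    "read_curve",
    "write_curve",
    "read_assay",
    "write_assay",
    "read_trajectory",
    "write_trajectory",
    "read_scenario",
    "write_manifest",
]

_FLOAT_FMT = "%.17g"


def convert_id_per_g_to_id(
    value: float, tumor_volume_mm3: float = 225.0, density_g_per_cm3: float = 1.0
) -> float:
    """Convert %ID/g to %ID using tissue volume (mm^3) and density (g/cm^3).

    mass [g] = volume/1000 [cm^3] * density, and %ID = %ID/g * mass.
    """
    if tumor_volume_mm3 <= 0 or density_g_per_cm3 <= 0:
        raise ValueError("volume and density must be positive")
    return value * (tumor_volume_mm3 / 1000.0) * density_g_per_cm3


def convert_id_to_id_per_g(
    value: float, tumor_volume_mm3: float = 225.0, density_g_per_cm3: float = 1.0
) -> float:
    """Inverse of :func:`convert_id_per_g_to_id`."""
    if tumor_volume_mm3 <= 0 or density_g_per_cm3 <= 0:
        raise ValueError("volume and density must be positive")
    return value / ((tumor_volume_mm3 / 1000.0) * density_g_per_cm3)


def _require_columns(df: pd.DataFrame, cols: tuple[str, ...], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def read_curve(path) -> ConcentrationCurve:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ("time_h", "value_pct_id"), path)
    return ConcentrationCurve(
        times=df["time_h"].to_numpy(float),
        values=df["value_pct_id"].to_numpy(float),
        sds=df["sd_pct_id"].to_numpy(float) if "sd_pct_id" in df.columns else None,
        n_replicates=df["n"].to_numpy(int) if "n" in df.columns else None,
    )


def write_curve(curve: ConcentrationCurve, path) -> None:
    data = {"time_h": curve.times, "value_pct_id": curve.values}
    if curve.sds is not None:
        data["sd_pct_id"] = curve.sds
    if curve.n_replicates is not None:
        data["n"] = curve.n_replicates
    pd.DataFrame(data).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_assay(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    try:
        df = validate_assay_table(df)
    except SchemaError as err:
        raise SchemaError(f"{path}: {err}") from err
    # integral times/doses print without a decimal point; restore dtypes
    for col in ("dose_mg_per_ml", "time_h", "value"):
        df[col] = df[col].astype(float)
    df["replicate"] = df["replicate"].astype(int)
    return df


def write_assay(df: pd.DataFrame, path) -> None:
    validate_assay_table(df).to_csv(path, index=False, float_format=_FLOAT_FMT)


_TRAJ_COLUMNS = ("time_h", "xb", "xp", "xt", "mb", "mp", "mt", "eliminated")


def read_trajectory(path) -> Trajectory:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, _TRAJ_COLUMNS, path)
    return Trajectory(
        times=df["time_h"].to_numpy(float),
        xb=df["xb"].to_numpy(float),
        xp=df["xp"].to_numpy(float),
        xt=df["xt"].to_numpy(float),
        mb=df["mb"].to_numpy(float),
        mp=df["mp"].to_numpy(float),
        mt=df["mt"].to_numpy(float),
        eliminated=df["eliminated"].to_numpy(float),
        X0=float(df["xb"].iloc[0]),
    )


def write_trajectory(traj: Trajectory, path) -> None:
    traj.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


_SCENARIO_KEYS = {
    "two_compartment",
    "phenotype_map",
    "scaling",
    "k_factors",
    "np_config",
    "t_end_h",
    "n_points",
}
_TWO_COMP_KEYS = {"lambda_b", "lambda_p", "K_pb", "X0"}


def read_scenario(path) -> dict[str, Any]:
    """Load and validate a simulation scenario config (YAML or JSON).

    Returns a dict with keys: two_compartment (TwoCompartmentParams),
    phenotype_map (PhenotypeMap), scaling (ScalingPolicy), k_factors
    (tuple), np_config (str), t_end_h (float), n_points (int).
    """
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, Mapping):
        raise SchemaError(f"{path}: scenario must be a mapping")
    unknown = set(raw) - _SCENARIO_KEYS
    if unknown:
        raise SchemaError(
            f"{path}: unknown key(s) {sorted(unknown)}; allowed: {sorted(_SCENARIO_KEYS)}"
        )
    tc = raw.get("two_compartment", {})
    unknown_tc = set(tc) - _TWO_COMP_KEYS
    if unknown_tc:
        raise SchemaError(
            f"{path}: unknown two_compartment key(s) {sorted(unknown_tc)}; "
            f"allowed: {sorted(_TWO_COMP_KEYS)}"
        )
    for key in ("lambda_b", "lambda_p", "K_pb"):
        if key not in tc:
            raise SchemaError(f"{path}: two_compartment requires {key}")
    two_comp = TwoCompartmentParams.from_eigen(
        tc["lambda_b"], tc["lambda_p"], tc["K_pb"], X0=tc.get("X0", 100.0)
    )
    pm = raw.get("phenotype_map", {})
    pheno_map = PhenotypeMap(
        blood=pm.get("blood", "M0"),
        peripheral=pm.get("peripheral", "M1"),
        tumor=pm.get("tumor", "M1"),
    )
    policy = ScalingPolicy(y=raw.get("scaling", {}).get("y", 0.0005))
    kf = raw.get("k_factors", {})
    k_factors = (kf.get("kb", 40.0), kf.get("kp", 40.0), kf.get("kt", 40.0))
    return {
        "two_compartment": two_comp,
        "phenotype_map": pheno_map,
        "scaling": policy,
        "k_factors": k_factors,
        "np_config": raw.get("np_config", "BNF-Plain"),
        "t_end_h": float(raw.get("t_end_h", 48.0)),
        "n_points": int(raw.get("n_points", 481)),
    }


def write_manifest(outdir, *, inputs: Mapping[str, Any], parameters: Mapping[str, Any],
                   seed: int | None = None) -> Path:
    """Write a reproducibility manifest next to a run's outputs."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "software": "immunopk",
        "version": __version__,
        "seed": seed,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "parameters": _jsonable(parameters),
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "__dataclass_fields__"):
        return {f: _jsonable(getattr(obj, f)) for f in obj.__dataclass_fields__}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
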