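"""In vitro macrophage uptake kinetics: two-state internalization/efflux model.

Nanoparticles in a macrophage culture partition between an extracellular
pool ``x_out`` and an intracellular pool ``x_in`` with first-order
exchange:

    dx_out/dt = -K_in x_out + K_out x_in
    dx_in/dt  =  K_in x_out - K_out x_in,    x_out(0) = X0, x_in(0) = 0.

The internalized amount relaxes mono-exponentially to a nonzero plateau
K_in X0/(K_in+K_out) (intracellular biodegradation is neglected over the
24-h assay window).  K_in and K_out are per hour.

Fitted rate constants for bionized nanoferrite (BNF) particles in
RAW264.7 macrophages — three surface configurations (Plain, trastuzumab-
and IgG-conjugated) by three polarization states (M0/M1/M2) by three iron
doses — ship as a bundled table, along with the dose-averaged entries used
to parameterize the in vivo model.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import lmfit
import numpy as np
import pandas as pd

from .errors import (
    CorruptedFixtureError,
    IllPosedParametersError,
    InsufficientDataError,
    MissingParameterError,
    SchemaError,
)
from .two_compartment import FitResult, _profile_se

__all__ = [
    "UptakeParams",
    "PHENOTYPES",
    "NP_CONFIGS",
    "DOSES_MG_PER_ML",
    "xin_analytic",
    "xout_analytic",
    "fit_uptake",
    "average_rates_over_doses",
    "load_bundled_rate_tables",
    "rate_entry",
    "validate_assay_table",
]

PHENOTYPES = ("M0", "M1", "M2")
NP_CONFIGS = ("BNF-Plain", "BNF-Her", "BNF-IgG")
DOSES_MG_PER_ML = (0.125, 0.25, 0.5)

ASSAY_COLUMNS = ("config", "phenotype", "dose_mg_per_ml", "time_h", "value", "replicate")

_RATE_FIXTURE = "uptake_rates.csv"
_RATE_FIXTURE_SHA256 = "0c782682df56777ed2bd7995e6a57c7c1e8ecc05632c91aeeba4c192a3e67f86"


@dataclass(frozen=True)
class UptakeParams:
    """Internalization/efflux rates (per hour) and initial extracellular amount."""

    K_in: float
    K_out: float
    X0: float = 1.0

    def __post_init__(self) -> None:
        if self.K_in < 0 or self.K_out < 0:
            raise IllPosedParametersError("K_in and K_out must be >= 0")


def _check_well_posed(params: UptakeParams) -> None:
    if params.K_in + params.K_out <= 0:
        raise IllPosedParametersError("K_in + K_out must be positive")


def xin_analytic(params: UptakeParams, t) -> np.ndarray | float:
    """Internalized amount x_in(t) = K_in X0 (1 - e^{-(K_in+K_out) t})/(K_in+K_out)."""
    _check_well_posed(params)
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    ktot = params.K_in + params.K_out
    out = params.K_in * params.X0 / ktot * (1.0 - np.exp(-ktot * t_arr))
    return out if t_arr.shape else float(out)


def xout_analytic(params: UptakeParams, t) -> np.ndarray | float:
    """Extracellular amount x_out(t) = X0 (K_out + K_in e^{-(K_in+K_out) t})/(K_in+K_out)."""
    _check_well_posed(params)
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    ktot = params.K_in + params.K_out
    out = params.X0 / ktot * (params.K_out + params.K_in * np.exp(-ktot * t_arr))
    return out if t_arr.shape else float(out)


def validate_assay_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check an uptake-assay table against the expected schema."""
    missing = [c for c in ASSAY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"assay table missing columns: {missing}")
    if (df["value"] < 0).any():
        raise SchemaError("assay values must be nonnegative")
    bad_ph = set(df["phenotype"]) - set(PHENOTYPES)
    if bad_ph:
        raise SchemaError(f"unknown phenotypes: {sorted(bad_ph)}")
    return df


def fit_uptake(
    series: pd.DataFrame,
    weighting: str = "auto",
    mode: str = "all",
    X0: float = 1.0,
) -> FitResult:
    """Fit (K_in, K_out) to one internalization time course.

    ``series`` holds replicate measurements of internalized amount for a
    single (config, phenotype, dose) with columns ``time_h``, ``value``
    (``replicate`` optional).  Values must be on the scale of ``X0``
    (normalize each series to its initial dose so X0 = 1).

    mode="all" fits every replicate value, weighted by inverse replicate
    variance per time point when available; mode="mean" fits per-time
    means weighted by the standard error of the mean.  Boundary estimates
    (typically K_out = 0 for M1 macrophages) are flagged and reported with
    profile-based standard errors.
    """
    if mode not in ("all", "mean"):
        raise ValueError(f"unknown mode {mode!r}")
    if weighting not in ("auto", "inverse_variance", "uniform"):
        raise ValueError(f"unknown weighting scheme {weighting!r}")
    if "time_h" not in series.columns or "value" not in series.columns:
        raise SchemaError("series needs columns time_h and value")

    grouped = series.groupby("time_h")["value"]
    means = grouped.mean()
    sds = grouped.std(ddof=1)
    counts = grouped.count()
    if len(means) < 3:
        raise InsufficientDataError(f"need >= 3 distinct time points, got {len(means)}")
    if not np.all(np.isfinite(series["value"])):
        raise InsufficientDataError("non-finite values")
    if (series["value"] == 0).all():
        raise InsufficientDataError("all values are zero; rates unidentifiable")

    sd_ok = np.all(np.isfinite(sds.values)) and np.all(sds.values > 0)
    use_iv = weighting == "inverse_variance" or (weighting == "auto" and sd_ok)
    if weighting == "inverse_variance" and not sd_ok:
        raise ValueError("inverse_variance weighting requires replicate spread at every time")

    if mode == "mean":
        t = means.index.to_numpy(float)
        y = means.to_numpy(float)
        w = (np.sqrt(counts.values) / sds.values) if use_iv else np.ones_like(y)
        scheme = "inverse_variance" if use_iv else "uniform"
    else:
        t = series["time_h"].to_numpy(float)
        y = series["value"].to_numpy(float)
        if use_iv:
            per_t = dict(zip(means.index, sds.values))
            w = np.array([1.0 / per_t[ti] for ti in t])
            scheme = "inverse_variance"
        else:
            w = np.ones_like(y)
            scheme = "uniform"

    def residual(p: lmfit.Parameters):
        kin, kout = p["K_in"].value, p["K_out"].value
        ktot = kin + kout
        if ktot <= 0:
            return (0.0 - y) * w
        model = kin * X0 / ktot * (1.0 - np.exp(-ktot * t))
        return (model - y) * w

    # starts bracket the plateau/slow-rise regimes seen across the assays
    best = None
    for kin0 in (1e-4, 1e-3, 1e-2):
        for kout0 in (0.0, 0.05, 0.2):
            pars = lmfit.Parameters()
            pars.add("K_in", value=kin0, min=0.0)
            pars.add("K_out", value=kout0, min=0.0)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    res = lmfit.minimize(residual, pars, method="least_squares")
            except Exception:
                continue
            wss = float(np.sum(np.asarray(res.residual) ** 2))
            if best is None or wss < best[0] - 1e-14 * (1 + best[0]):
                best = (wss, res)
    if best is None:
        raise InsufficientDataError("all fit starts failed")
    wss, res = best

    vals = {k: max(float(res.params[k].value), 0.0) for k in ("K_in", "K_out")}
    errs = {
        k: float(res.params[k].stderr) if res.params[k].stderr is not None else math.inf
        for k in vals
    }
    atol = 1e-8
    flags = {k: vals[k] <= atol for k in vals}
    vals = {k: 0.0 if flags[k] else v for k, v in vals.items()}
    dof = max(len(t) - 2, 1)

    for name in [k for k, f in flags.items() if f]:

        def prof(delta: float, _name=name) -> float:
            pars = lmfit.Parameters()
            for k in ("K_in", "K_out"):
                if k == _name:
                    pars.add(k, value=delta, vary=False)
                else:
                    pars.add(k, value=max(vals[k], 1e-6), min=0.0)
            r = lmfit.minimize(residual, pars, method="least_squares")
            return float(np.sum(np.asarray(r.residual) ** 2))

        errs[name] = _profile_se(prof, wss, dof, start=1e-3, upper=1e2)

    return FitResult(
        estimates=vals,
        standard_errors=errs,
        boundary_flags=flags,
        residual_sum=wss,
        converged=bool(res.success),
        weighting=scheme,
        n_points=len(t),
    )


def average_rates_over_doses(per_dose: Sequence[UptakeParams]) -> UptakeParams:
    """Arithmetic mean of per-dose (K_in, K_out) estimates.

    The in vivo model uses one rate pair per (configuration, phenotype);
    it is the plain average over the three assay doses.
    """
    entries = list(per_dose)
    if len(entries) != 3:
        raise ValueError(f"expected exactly 3 per-dose entries, got {len(entries)}")
    return UptakeParams(
        K_in=float(np.mean([e.K_in for e in entries])),
        K_out=float(np.mean([e.K_out for e in entries])),
        X0=entries[0].X0,
    )


def load_bundled_rate_tables() -> pd.DataFrame:
    """Load the bundled BNF/RAW264.7 rate table (checksummed).

    Returns a DataFrame with columns config, phenotype, dose ('0.125',
    '0.250', '0.500' or 'average'), K_in, K_in_se, K_out, K_out_se —
    54 per-dose rate values plus the 18 dose averages.
    """
    ref = resources.files("immunopk.data") / _RATE_FIXTURE
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _RATE_FIXTURE_SHA256:
        raise CorruptedFixtureError(
            f"{_RATE_FIXTURE} checksum mismatch: {digest} != {_RATE_FIXTURE_SHA256}"
        )
    from io import BytesIO

    df = pd.read_csv(BytesIO(raw), dtype={"dose": str})
    return df


def rate_entry(
    table: pd.DataFrame,
    config: str,
    phenotype: str,
    dose: str = "average",
) -> UptakeParams:
    """Look up one (K_in, K_out) pair from a rate table."""
    mask = (
        (table["config"] == config)
        & (table["phenotype"] == phenotype)
        & (table["dose"] == dose)
    )
    sub = table[mask]
    if len(sub) != 1:
        raise MissingParameterError(
            f"no unique rate entry for ({config}, {phenotype}, {dose})"
        )
    row = sub.iloc[0]
    return UptakeParams(K_in=float(row["K_in"]), K_out=float(row["K_out"]))
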