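"""Two-compartment blood pharmacokinetics: analytic solutions, eigenvalue
algebra, and weighted least-squares fitting.

The model is the classical central/peripheral disposition scheme

    dxb/dt = -(K_el + K_bp) xb + K_pb xp
    dxp/dt = K_bp xb - K_pb xp,        xb(0) = X0, xp(0) = 0,

whose blood solution is a biexponential with eigenvalue magnitudes
``lambda_b`` (fast, distributive phase) and ``lambda_p`` (slow,
post-distributive phase).  The eigenvalues and micro-rate constants are
linked by

    lambda_b + lambda_p = K_el + K_bp + K_pb
    lambda_b * lambda_p = K_el * K_pb

so fitting the blood curve for (lambda_b, lambda_p, K_pb) determines
K_el and K_bp algebraically.  All rates are per hour; amounts are in
percent of injected dose (%ID).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import lmfit
import numpy as np

from .errors import (
    InconsistentEigenstructureError,
    InsufficientDataError,
    UnsupportedParameterizationError,
)

__all__ = [
    "TwoCompartmentParams",
    "ConcentrationCurve",
    "FitResult",
    "xb_analytic",
    "xp_analytic",
    "derive_dependent_rates",
    "eigenvalues_from_rates",
    "fit_blood_pk",
]

_IDENTITY_RTOL = 1e-6


def derive_dependent_rates(
    lambda_b: float, lambda_p: float, K_pb: float
) -> tuple[float, float]:
    """Derive (K_el, K_bp) from the fitted eigenvalues and K_pb.

    Uses the product rule K_el = lambda_b*lambda_p/K_pb and the trace rule
    K_bp = lambda_b + lambda_p - K_el - K_pb.  K_pb must lie between the
    two eigenvalues; otherwise K_bp would be negative (or the blood curve
    would dip below zero), which no rate matrix can produce.
    """
    if not lambda_b > lambda_p >= 0:
        raise UnsupportedParameterizationError(
            f"need lambda_b > lambda_p >= 0, got ({lambda_b}, {lambda_p})"
        )
    if K_pb <= 0:
        raise InconsistentEigenstructureError(f"K_pb must be positive, got {K_pb}")
    if not lambda_p <= K_pb <= lambda_b:
        raise InconsistentEigenstructureError(
            f"K_pb={K_pb} outside the eigenvalue interval "
            f"[{lambda_p}, {lambda_b}]; no valid rate matrix exists"
        )
    K_el = lambda_b * lambda_p / K_pb
    K_bp = lambda_b + lambda_p - K_el - K_pb
    return K_el, K_bp


def eigenvalues_from_rates(
    K_el: float, K_bp: float, K_pb: float
) -> tuple[float, float]:
    """Eigenvalue magnitudes (lambda_b, lambda_p) of the 2x2 rate matrix.

    Roots of lambda^2 - (K_el+K_bp+K_pb) lambda + K_el*K_pb = 0, returned
    sorted descending.  Computed with the numerically stable form of the
    quadratic formula so the small root does not suffer cancellation.
    """
    if min(K_el, K_bp, K_pb) < 0:
        raise InconsistentEigenstructureError("rate constants must be nonnegative")
    s = K_el + K_bp + K_pb
    p = K_el * K_pb
    disc = s * s - 4.0 * p
    # disc >= (K_el - K_pb)^2 >= 0 for nonnegative rates; clip roundoff
    root = math.sqrt(max(disc, 0.0))
    lam_b = 0.5 * (s + root)
    lam_p = p / lam_b if lam_b > 0 else 0.0
    return lam_b, lam_p


@dataclass(frozen=True)
class TwoCompartmentParams:
    """Rates and eigenvalues of the blood/peripheral model (all per hour).

    The five rate quantities are redundant (two identities link them), so
    prefer the :meth:`from_eigen` or :meth:`from_rates` constructors which
    derive the dependent pair exactly.  Direct construction checks the
    identities to a relative tolerance of 1e-6.
    """

    lambda_b: float
    lambda_p: float
    K_pb: float
    K_el: float
    K_bp: float
    X0: float = 100.0

    def __post_init__(self) -> None:
        for name in ("lambda_b", "lambda_p", "K_pb", "K_el", "K_bp"):
            if getattr(self, name) < 0:
                raise UnsupportedParameterizationError(f"{name} must be >= 0")
        if not self.lambda_b > self.lambda_p:
            raise UnsupportedParameterizationError(
                "lambda_b must exceed lambda_p (repeated-eigenvalue case unsupported)"
            )
        if not self.lambda_p <= self.K_pb <= self.lambda_b:
            raise InconsistentEigenstructureError(
                "K_pb must lie between lambda_p and lambda_b"
            )
        scale = self.lambda_b + self.lambda_p
        if abs(scale) > 0:
            trace_err = abs(scale - (self.K_el + self.K_bp + self.K_pb)) / scale
            if trace_err > _IDENTITY_RTOL:
                raise InconsistentEigenstructureError(
                    f"trace identity violated (rel. err {trace_err:.2e})"
                )
        prod = self.lambda_b * self.lambda_p
        ref = max(prod, self.K_el * self.K_pb)
        if ref > 0 and abs(prod - self.K_el * self.K_pb) / ref > _IDENTITY_RTOL:
            raise InconsistentEigenstructureError("product identity violated")

    @classmethod
    def from_eigen(
        cls, lambda_b: float, lambda_p: float, K_pb: float, X0: float = 100.0
    ) -> "TwoCompartmentParams":
        """Build from fitted (lambda_b, lambda_p, K_pb), deriving K_el and K_bp."""
        K_el, K_bp = derive_dependent_rates(lambda_b, lambda_p, K_pb)
        return cls(lambda_b, lambda_p, K_pb, K_el, K_bp, X0)

    @classmethod
    def from_rates(
        cls, K_el: float, K_bp: float, K_pb: float, X0: float = 100.0
    ) -> "TwoCompartmentParams":
        """Build from micro-rate constants, deriving the eigenvalues."""
        lam_b, lam_p = eigenvalues_from_rates(K_el, K_bp, K_pb)
        if lam_b == lam_p:
            raise UnsupportedParameterizationError("repeated eigenvalues unsupported")
        return cls(lam_b, lam_p, K_pb, K_el, K_bp, X0)


def xb_analytic(params: TwoCompartmentParams, t) -> np.ndarray | float:
    """Blood amount xb(t) in %ID; biexponential closed form.

    xb(t) = X0 [ (lambda_b - K_pb) e^{-lambda_b t}
               - (lambda_p - K_pb) e^{-lambda_p t} ] / (lambda_b - lambda_p)
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    lb, lp, kpb = params.lambda_b, params.lambda_p, params.K_pb
    out = (
        params.X0
        / (lb - lp)
        * ((lb - kpb) * np.exp(-lb * t_arr) - (lp - kpb) * np.exp(-lp * t_arr))
    )
    return out if t_arr.shape else float(out)


def xp_analytic(params: TwoCompartmentParams, t) -> np.ndarray | float:
    """Peripheral amount xp(t) = K_bp X0 (e^{-lambda_b t} - e^{-lambda_p t})/(lambda_p - lambda_b)."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    lb, lp = params.lambda_b, params.lambda_p
    out = params.K_bp * params.X0 / (lp - lb) * (np.exp(-lb * t_arr) - np.exp(-lp * t_arr))
    return out if t_arr.shape else float(out)


@dataclass(frozen=True)
class ConcentrationCurve:
    """A blood concentration-time series in hours / %ID.

    ``sds`` are per-point standard deviations (used for inverse-variance
    weighting) and ``n_replicates`` the per-point replicate counts; both
    optional.
    """

    times: np.ndarray
    values: np.ndarray
    sds: np.ndarray | None = None
    n_replicates: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.sds is not None:
            object.__setattr__(self, "sds", np.asarray(self.sds, dtype=float))
        if self.n_replicates is not None:
            object.__setattr__(
                self, "n_replicates", np.asarray(self.n_replicates, dtype=int)
            )
        n = len(self.times)
        for name in ("values", "sds", "n_replicates"):
            arr = getattr(self, name)
            if arr is not None and len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != times length {n}")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.times < 0) or np.any(self.values < 0):
            raise ValueError("times and values must be nonnegative")
        if self.sds is not None and np.any(self.sds < 0):
            raise ValueError("sds must be nonnegative")


@dataclass(frozen=True)
class FitResult:
    """Outcome of a weighted least-squares fit.

    ``estimates`` and ``standard_errors`` are keyed by parameter name;
    ``boundary_flags`` marks estimates pinned to a box constraint, whose
    standard errors are profile-based rather than covariance-based.
    ``residual_sum`` is the weighted sum of squared residuals.
    """

    estimates: Mapping[str, float]
    standard_errors: Mapping[str, float]
    boundary_flags: Mapping[str, bool]
    residual_sum: float
    converged: bool
    weighting: str = "uniform"
    n_points: int = 0

    def __post_init__(self) -> None:
        for k, v in self.estimates.items():
            if v < 0:
                raise ValueError(f"estimate {k} negative: {v}")
        for k, v in self.standard_errors.items():
            if np.isfinite(v) and v < 0:
                raise ValueError(f"standard error {k} negative: {v}")


# --- fitting ---------------------------------------------------------------

#: Deterministic multi-start grid (per hour). K_pb starts at the geometric
#: mean of the eigenvalue starts, keeping it inside [lambda_p, lambda_b].
_LAMBDA_B_STARTS = (1.0, 5.0, 20.0, 50.0)
_LAMBDA_P_STARTS = (0.01, 0.05, 0.2)

_BOUNDARY_ATOL = 1e-8


def _resolve_weights(curve: ConcentrationCurve, weighting: str) -> tuple[np.ndarray, str]:
    """Weight vector for the requested scheme.

    "pooled_cv" pools the per-point coefficients of variation into one
    proportional-error scale and weights by 1/(cv * value): per-point
    sample SDs from 2-3 replicates are themselves ~50% uncertain, and
    weighting by them directly understates the parameter errors by about
    a factor of two (verified by simulation), while the pooled scheme
    keeps inverse-variance efficiency with honest covariance.  "auto"
    selects pooled_cv when SDs are available, else uniform.
    """
    if weighting not in ("auto", "pooled_cv", "inverse_variance", "uniform"):
        raise ValueError(f"unknown weighting scheme {weighting!r}")
    usable = (
        curve.sds is not None
        and np.all(np.isfinite(curve.sds))
        and np.all(curve.sds > 0)
    )
    if weighting in ("inverse_variance", "pooled_cv") and not usable:
        raise ValueError(f"{weighting} weighting requires positive per-point sds")
    if weighting == "inverse_variance":
        return 1.0 / curve.sds, "inverse_variance"
    if weighting == "pooled_cv" or (weighting == "auto" and usable):
        pos = curve.values > 0
        if not np.any(pos):
            return np.ones_like(curve.values), "uniform"
        cv = float(np.sqrt(np.mean((curve.sds[pos] / curve.values[pos]) ** 2)))
        return 1.0 / (cv * np.maximum(curve.values, 1e-12)), "pooled_cv"
    return np.ones_like(curve.values), "uniform"


def _biexp_residual(p: lmfit.Parameters, t: np.ndarray, y: np.ndarray, w: np.ndarray, X0: float):
    lb, lp, kpb = p["lambda_b"].value, p["lambda_p"].value, p["K_pb"].value
    if lb == lp:  # measure-zero collision during optimization
        lb += 1e-12
    model = X0 / (lb - lp) * ((lb - kpb) * np.exp(-lb * t) - (lp - kpb) * np.exp(-lp * t))
    return (model - y) * w


def _profile_se(
    objective, best_wss: float, dof: int, start: float, upper: float
) -> float:
    """Profile-likelihood standard error for a parameter pinned at zero.

    Finds the displacement at which the re-optimized weighted SSR rises by
    one estimated residual variance (delta-chi2 = wss/dof), by bisection on
    an increasing profile.
    """
    target = best_wss * (1.0 + 1.0 / max(dof, 1)) + 1e-30
    lo, hi = 0.0, max(start, 1e-6)
    for _ in range(60):  # expand until bracketed
        if objective(hi) >= target or hi > upper:
            break
        hi *= 2.0
    else:
        return math.inf
    if objective(hi) < target:
        return math.inf
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if objective(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def fit_blood_pk(
    curve: ConcentrationCurve,
    weighting: str = "auto",
) -> FitResult:
    """Fit the biexponential blood solution for (lambda_b, lambda_p, K_pb).

    The injected dose is fixed at X0 = 100 %ID (data must be normalized).
    Initialization is a fixed multi-start grid, so the result is
    deterministic; the best weighted residual wins, ties going to the
    smaller lambda_b.  After the fit the eigenvalues are sorted
    (lambda_b > lambda_p is a labeling convention) and the dependent rates
    K_el, K_bp are derived, with delta-method standard errors.  Estimates
    pinned at a box constraint are flagged and given profile-based errors.
    """
    t, y = curve.times, curve.values
    if len(t) < 4:
        raise InsufficientDataError(f"need >= 4 time points, got {len(t)}")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
        raise InsufficientDataError("non-finite times or values")
    X0 = 100.0
    w, scheme = _resolve_weights(curve, weighting)

    best = None
    for lb0 in _LAMBDA_B_STARTS:
        for lp0 in _LAMBDA_P_STARTS:
            pars = lmfit.Parameters()
            pars.add("lambda_b", value=lb0, min=0.0)
            pars.add("lambda_p", value=lp0, min=0.0)
            pars.add("K_pb", value=math.sqrt(lb0 * lp0), min=0.0)
            try:
                with warnings.catch_warnings():
                    # perfect (noise-free) data can make the covariance
                    # numerically indefinite; stderr then comes out nan
                    warnings.simplefilter("ignore", RuntimeWarning)
                    res = lmfit.minimize(
                        _biexp_residual,
                        pars,
                        args=(t, y, w, X0),
                        method="least_squares",
                    )
            except Exception:
                continue
            wss = float(np.sum(np.asarray(res.residual) ** 2))
            if (
                best is None
                or wss < best[0] - 1e-12 * (1 + best[0])
                or (abs(wss - best[0]) <= 1e-12 * (1 + best[0])
                    and res.params["lambda_b"].value < best[1].params["lambda_b"].value)
            ):
                best = (wss, res)
    if best is None:
        raise InsufficientDataError("all fit starts failed")
    wss, res = best

    vals = {k: float(res.params[k].value) for k in ("lambda_b", "lambda_p", "K_pb")}
    errs = {
        k: float(res.params[k].stderr) if res.params[k].stderr is not None else math.inf
        for k in vals
    }
    # eigenvalue ordering is a labeling convention
    if vals["lambda_b"] < vals["lambda_p"]:
        vals["lambda_b"], vals["lambda_p"] = vals["lambda_p"], vals["lambda_b"]
        errs["lambda_b"], errs["lambda_p"] = errs["lambda_p"], errs["lambda_b"]

    dof = max(len(t) - 3, 1)
    flags = {k: abs(v) <= _BOUNDARY_ATOL for k, v in vals.items()}
    # a pinned estimate is reported as exactly zero (its uncertainty is
    # one-sided and comes from the profile below)
    vals = {k: 0.0 if flags[k] else max(v, 0.0) for k, v in vals.items()}

    # profile-based SE for parameters pinned at zero
    for name in [k for k, f in flags.items() if f]:

        def prof(delta: float, _name=name) -> float:
            pars = lmfit.Parameters()
            for k in ("lambda_b", "lambda_p", "K_pb"):
                if k == _name:
                    pars.add(k, value=delta, vary=False)
                else:
                    pars.add(k, value=max(vals[k], 1e-6), min=0.0)
            r = lmfit.minimize(
                _biexp_residual, pars, args=(t, y, w, X0), method="least_squares"
            )
            return float(np.sum(np.asarray(r.residual) ** 2))

        errs[name] = _profile_se(prof, wss, dof, start=0.01, upper=1e3)

    # dependent rates by the algebraic identities, clamped at the physical
    # boundary (roundoff can push K_bp infinitesimally negative)
    lb, lp, kpb = vals["lambda_b"], vals["lambda_p"], vals["K_pb"]
    kpb_eff = min(max(kpb, lp), lb) if lb > lp else kpb
    K_el = lb * lp / kpb_eff if kpb_eff > 0 else 0.0
    K_bp = max(lb + lp - K_el - kpb_eff, 0.0)
    vals["K_el"], vals["K_bp"] = K_el, K_bp
    flags["K_el"] = K_el <= _BOUNDARY_ATOL
    flags["K_bp"] = K_bp <= _BOUNDARY_ATOL

    # delta-method errors for the derived pair
    if all(np.isfinite(errs[k]) for k in ("lambda_b", "lambda_p", "K_pb")) and kpb_eff > 0:
        cov = getattr(res, "covar", None)
        order = list(res.var_names) if cov is not None else None
        g_el = np.array([lp / kpb_eff, lb / kpb_eff, -lb * lp / kpb_eff**2])
        g_bp = np.array([1.0, 1.0, 0.0]) - g_el - np.array([0.0, 0.0, 1.0])
        if cov is not None and order == ["lambda_b", "lambda_p", "K_pb"]:
            errs["K_el"] = float(np.sqrt(max(g_el @ cov @ g_el, 0.0)))
            errs["K_bp"] = float(np.sqrt(max(g_bp @ cov @ g_bp, 0.0)))
        else:  # no covariance: propagate as if independent
            var = np.array([errs["lambda_b"], errs["lambda_p"], errs["K_pb"]]) ** 2
            errs["K_el"] = float(np.sqrt(np.sum(g_el**2 * var)))
            errs["K_bp"] = float(np.sqrt(np.sum(g_bp**2 * var)))
    else:
        errs["K_el"] = errs["K_bp"] = math.inf

    return FitResult(
        estimates=vals,
        standard_errors=errs,
        boundary_flags=flags,
        residual_sum=wss,
        converged=bool(res.success),
        weighting=scheme,
        n_points=len(t),
    )
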