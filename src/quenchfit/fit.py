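"""Single-cell dose-response curve fitting.

Each cell's fluorescence trace F(c) over the agonist ladder is fitted with a
four-parameter logistic (Hill) curve.  Because the reporter is a
halide-quenched YFP, fluorescence *decreases* with agonist concentration:
``F_max`` is the plateau at the lowest concentration (unquenched) and
``F_min`` the plateau at the highest (fully quenched).

    F(c) = F_max + (F_min - F_max) / (1 + (EC50 / c)**slope)

with F(0) := F_max (the c -> 0 limit).  EC50 is the half-maximal agonist
concentration in µM and ``slope`` the Hill coefficient nH.  Fitting is
bounded nonlinear least squares with EC50 handled in log10 space for
conditioning; a brute-force grid search over (log10 EC50, slope) with
plateaus solved linearly is provided as an independent reference
(:func:`grid_fit`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "FitResult",
    "curve_model",
    "fit_dose_response",
    "fit_table",
    "r_squared",
    "dynamic_range",
    "normalize_curve",
    "grid_fit",
]

# Optimization bounds: wide enough for debris traces not to diverge, narrow
# enough to keep the solver conditioned.  EC50 in µM.
EC50_BOUNDS = (1e-3, 1e6)
SLOPE_BOUNDS = (0.05, 20.0)


@dataclass
class FitResult:
    """Fitted parameters and derived quality measures for one cell."""

    cell_id: object
    F_max: float
    F_min: float
    ec50: float
    slope: float
    r2: float
    dF: float
    converged: bool
    sse: float = field(default=np.nan)

    def as_dict(self) -> dict:
        return {
            "cell_id": self.cell_id,
            "F_max": self.F_max,
            "F_min": self.F_min,
            "ec50": self.ec50,
            "slope": self.slope,
            "r2": self.r2,
            "dF": self.dF,
            "converged": self.converged,
            "sse": self.sse,
        }


def curve_model(c, F_max, F_min, ec50, slope):
    """Evaluate the sigmoidal quench model at concentration(s) ``c`` (µM).

    Returns ``F_max`` at c == 0 (the limit) and decays monotonically to
    ``F_min`` as c -> inf when ``F_min <= F_max``.  Raises ``ValueError``
    for non-positive EC50 or slope, or negative concentrations.
    """
    if ec50 <= 0 or slope <= 0:
        raise ValueError(f"EC50 and slope must be positive (got {ec50}, {slope})")
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    # occupancy w in [0, 1): computed in log space to avoid overflow for
    # extreme EC50/c ratios
    w = np.zeros_like(c)
    pos = c > 0
    with np.errstate(over="ignore"):
        expo = slope * (np.log(ec50) - np.log(c[pos]))
        w[pos] = 1.0 / (1.0 + np.exp(np.clip(expo, -700, 700)))
    out = F_max + (F_min - F_max) * w
    return out if out.ndim else float(out)


def r_squared(F, predicted) -> float:
    """Coefficient of determination 1 - SSE/SST, SST about the mean of F.

    A zero-variance trace has undefined R²; NaN is returned as a sentinel
    which the quality filters treat as a failure.
    """
    F = np.asarray(F, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    sst = float(np.sum((F - F.mean()) ** 2))
    if sst == 0.0:
        return float("nan")
    sse = float(np.sum((F - predicted) ** 2))
    return 1.0 - sse / sst


def dynamic_range(F_min: float, F_max: float) -> float:
    """Percent fluorescence change ΔF = 100 · (F_max − F_min) / F_max."""
    if F_max <= 0:
        raise ValueError(f"F_max must be positive (got {F_max})")
    return 100.0 * (F_max - F_min) / F_max


def normalize_curve(F, F_min: float, F_max: float):
    """Rescale a trace to ~[0, 1] using fitted plateaus: (F − F_min)/(F_max − F_min)."""
    if F_max == F_min:
        raise ValueError("degenerate plateaus: F_max == F_min")
    return (np.asarray(F, dtype=float) - F_min) / (F_max - F_min)


def _validate_trace(conc, F):
    conc = np.asarray(conc, dtype=float)
    F = np.asarray(F, dtype=float)
    if conc.shape != F.shape or conc.ndim != 1:
        raise ValueError("concentration and fluorescence vectors must match")
    if len(conc) < 5:
        raise ValueError(f"need >= 5 points, got {len(conc)}")
    if np.any(conc < 0):
        raise ValueError("concentrations must be non-negative")
    if np.any(np.diff(conc) <= 0):
        raise ValueError("concentrations must be strictly increasing")
    if np.all(conc == conc[0]):
        raise ValueError("constant concentrations")
    return conc, F


def _model_theta(c, theta):
    F_max, F_min, log_ec50, slope = theta
    return curve_model(c, F_max, F_min, 10.0**log_ec50, slope)


def _occupancy(c, log_ec50, slope):
    """w(c) = 1/(1 + (EC50/c)^slope) with w(0) = 0, computed in log space."""
    w = np.zeros_like(c)
    pos = c > 0
    with np.errstate(over="ignore"):
        expo = slope * np.log(10) * (log_ec50 - np.log10(c[pos]))
        w[pos] = 1.0 / (1.0 + np.exp(np.clip(expo, -700, 700)))
    return w


def _jac_theta(c, theta):
    """Analytic Jacobian of the model wrt (F_max, F_min, log10 EC50, slope)."""
    F_max, F_min, log_ec50, slope = theta
    w = _occupancy(c, log_ec50, slope)
    dw_de = -w * (1.0 - w)  # derivative wrt the log-space exponent
    J = np.empty((c.size, 4))
    J[:, 0] = 1.0 - w
    J[:, 1] = w
    amp = F_min - F_max
    J[:, 2] = amp * dw_de * slope * np.log(10)
    de_dslope = np.zeros_like(c)
    pos = c > 0
    de_dslope[pos] = np.log(10) * (log_ec50 - np.log10(c[pos]))
    J[:, 3] = amp * dw_de * de_dslope
    return J


def _initial_guess(conc, F):
    F_max0 = float(np.max(F))
    F_min0 = float(np.min(F))
    half = 0.5 * (F_max0 + F_min0)
    pos = conc > 0
    if pos.any():
        idx = np.argmin(np.abs(F[pos] - half))
        ec50_0 = float(conc[pos][idx])
    else:  # cannot happen for a valid ladder, defensive
        ec50_0 = 1.0
    ec50_0 = float(np.clip(ec50_0, *EC50_BOUNDS))
    return np.array([F_max0, F_min0, np.log10(ec50_0), 1.0])


def fit_dose_response(conc, F, cell_id=None) -> FitResult:
    """Bounded least-squares fit of the quench curve to one trace.

    Initialization from the data (plateaus from min/max, EC50 from the
    half-range crossing, slope 1).  Non-convergence is recorded in
    ``converged`` rather than raised; R² and ΔF are computed on the
    returned parameters.
    """
    conc, F = _validate_trace(conc, F)
    theta0 = _initial_guess(conc, F)
    f_hi = 2.0 * max(float(np.max(F)), 1e-12)
    lower = [0.0, 0.0, np.log10(EC50_BOUNDS[0]), SLOPE_BOUNDS[0]]
    upper = [f_hi, f_hi, np.log10(EC50_BOUNDS[1]), SLOPE_BOUNDS[1]]
    theta0 = np.clip(theta0, lower, upper)

    def residuals(theta):
        return _model_theta(conc, theta) - F

    theta, converged, best_sse = theta0, False, np.inf

    def solve(start, max_nfev):
        nonlocal theta, converged, best_sse
        try:
            res = least_squares(
                residuals,
                start,
                jac=lambda th: _jac_theta(conc, th),
                bounds=(lower, upper),
                method="trf",
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
                max_nfev=max_nfev,
            )
        except Exception:
            return
        if np.all(np.isfinite(res.x)) and res.cost < best_sse:
            theta, best_sse = res.x, res.cost
            converged = bool(res.success)

    pos = conc[conc > 0]
    # traces with no usable dynamic range (flat cells, < 5% span) sit in a
    # degenerate valley where any midpoint/slope fits equally; a short solve
    # suffices since any fit of them fails the downstream dF filter
    span_frac = (float(np.max(F)) - float(np.min(F))) / max(float(np.max(F)), 1e-12)
    flat = span_frac < 0.05
    solve(theta0, 60 if flat else 500)

    # The half-range heuristic can land in the basin of a spurious
    # out-of-ladder minimum on noisy traces; when the solution rails the
    # midpoint outside the sampled span or pins a parameter at its bound,
    # retry from ladder-spanning starts and keep the best SSE.
    in_span = (np.log10(pos[0]) - 0.5 <= theta[2] <= np.log10(pos[-1]) + 0.5)
    railed = (theta[1] <= lower[1] + 1e-12 or theta[0] >= upper[0] - 1e-9
              or theta[3] <= lower[3] + 1e-9 or theta[3] >= upper[3] - 1e-9)
    if not flat and not (converged and in_span and not railed):
        for le in np.linspace(np.log10(pos[0]), np.log10(pos[-1]), 4):
            solve(np.clip([theta0[0], theta0[1], le, 1.0], lower, upper), 250)

    F_max, F_min, log_ec50, slope = theta
    pred = _model_theta(conc, theta)
    sse = float(np.sum((pred - F) ** 2))
    r2 = r_squared(F, pred)
    dF = dynamic_range(F_min, F_max) if F_max > 0 else float("nan")
    return FitResult(
        cell_id=cell_id,
        F_max=float(F_max),
        F_min=float(F_min),
        ec50=float(10.0**log_ec50),
        slope=float(slope),
        r2=r2,
        dF=dF,
        converged=converged,
        sse=sse,
    )


def fit_table(traces: pd.DataFrame) -> pd.DataFrame:
    """Fit every row of a trace table; returns one fit row per cell.

    The trace table uses the interchange layout: a ``cell_id`` column plus
    one ``F_<conc>`` column per ladder point (see :mod:`quenchfit.io`).
    """
    from .io import trace_concentrations

    conc, cols = trace_concentrations(traces)
    rows = []
    for _, row in traces.iterrows():
        res = fit_dose_response(conc, row[cols].to_numpy(dtype=float),
                                cell_id=row["cell_id"])
        rows.append(res.as_dict())
    fits = pd.DataFrame(rows)
    if "well_id" in traces.columns:
        fits.insert(1, "well_id", traces["well_id"].to_numpy())
    return fits


def grid_fit(conc, F, n_ec50=241, n_slope=120,
             log_ec50_range=(-3.0, 6.0), slope_range=SLOPE_BOUNDS):
    """Exhaustive reference fit: grid search over (log10 EC50, slope).

    For each grid node the model is linear in the plateaus,
    F = F_max·(1−w) + F_min·w with w the occupancy, so the plateaus are
    solved exactly by box-constrained linear least squares over the same
    plateau bounds the iterative fitter uses.  Returns (theta, sse) with
    theta = (F_max, F_min, EC50, slope).  Deliberately independent of the
    iterative solver in :func:`fit_dose_response`; used as an oracle in
    tests and validation.
    """
    conc, F = _validate_trace(conc, F)
    f_hi = 2.0 * max(float(np.max(F)), 1e-12)  # same plateau box as the fitter
    log_ec50s = np.linspace(*log_ec50_range, n_ec50)
    slopes = np.linspace(slope_range[0], slope_range[1], n_slope)
    LE, S = np.meshgrid(log_ec50s, slopes, indexing="ij")  # (G1, G2)
    pos = conc > 0
    log_c = np.log(conc[pos])
    # occupancy per grid node and ladder point: (G1, G2, n_pos)
    expo = S[..., None] * (LE[..., None] * np.log(10) - log_c)
    w_pos = 1.0 / (1.0 + np.exp(np.clip(expo, -700, 700)))
    w = np.zeros(LE.shape + conc.shape)
    w[..., pos] = w_pos
    # plateaus by box-constrained 2-variable least squares of
    # F ~ F_max*(1-w) + F_min*w: enumerate the unconstrained solution and
    # every clamped-edge candidate, keep the feasible minimum per node
    u = 1.0 - w
    S11 = (u * u).sum(-1)
    S12 = (u * w).sum(-1)
    S22 = (w * w).sum(-1)
    b1 = (u * F).sum(-1)
    b2 = (w * F).sum(-1)
    sumF2 = float(np.sum(F * F))
    det = S11 * S22 - S12 * S12
    ok = det > 1e-12
    fx0 = np.where(ok, (S22 * b1 - S12 * b2) / np.where(ok, det, 1.0), np.nan)
    fn0 = np.where(ok, (S11 * b2 - S12 * b1) / np.where(ok, det, 1.0), np.nan)
    feasible = ok & (fx0 >= 0) & (fx0 <= f_hi) & (fn0 >= 0) & (fn0 <= f_hi)
    fx0 = np.where(feasible, fx0, np.nan)
    fn0 = np.where(feasible, fn0, np.nan)

    def clamp01(x):
        return np.clip(x, 0.0, f_hi)

    with np.errstate(divide="ignore", invalid="ignore"):
        candidates = [
            (fx0, fn0),
            (clamp01(b1 / S11), np.zeros_like(b1)),                    # F_min = 0
            (clamp01((b1 - f_hi * S12) / S11), np.full_like(b1, f_hi)),  # F_min = hi
            (np.zeros_like(b2), clamp01(b2 / S22)),                    # F_max = 0
            (np.full_like(b2, f_hi), clamp01((b2 - f_hi * S12) / S22)),  # F_max = hi
        ]
    sse = np.full(S11.shape, np.inf)
    F_max = np.zeros(S11.shape)
    F_min = np.zeros(S11.shape)
    for fx, fn in candidates:
        s = (sumF2 - 2.0 * (fx * b1 + fn * b2)
             + fx * fx * S11 + 2.0 * fx * fn * S12 + fn * fn * S22)
        s = np.where(np.isfinite(s), np.maximum(s, 0.0), np.inf)
        better = s < sse
        sse = np.where(better, s, sse)
        F_max = np.where(better, fx, F_max)
        F_min = np.where(better, fn, F_min)
    i, j = np.unravel_index(np.argmin(sse), sse.shape)
    theta = (float(F_max[i, j]), float(F_min[i, j]),
             float(10.0 ** log_ec50s[i]), float(slopes[j]))
    return theta, float(sse[i, j])
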