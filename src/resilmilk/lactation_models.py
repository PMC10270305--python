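"""Per-lactation milk-yield models.

Two models are fitted to each first-parity lactation:

1. the Wood curve ``DMY = a * DIM^b * exp(-c * DIM)``, fitted by least
   squares on *all* observed days (perturbations included), describing the
   lactation as it actually happened; and
2. an "expected" lactation curve — a 4th-order polynomial in DIM fitted by
   quantile regression at conditional quantile tau = 0.7 on days 11-340 —
   describing production in the hypothetical absence of perturbations.
   Because most deviations from an undisturbed trajectory are downward
   (illness, heat stress), a quantile above the median tracks the
   unperturbed level rather than the perturbed average.

Residuals from both models feed the downstream feature extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import least_squares, linprog

from .data_io import LactationSeries

#: DIM window on which the expected curve is fitted and evaluated.
EXPECTED_WINDOW = (11, 340)
EXPECTED_TAU = 0.7
_POLY_DEGREE = 4
_DIM_SCALE = 340.0  # conditioning: fit polynomial in dim/340


@dataclass
class WoodParams:
    """Fitted Wood-curve parameters (a: kg scale, b: shape, c: decay/day)."""

    a: float
    b: float
    c: float
    converged: bool = True
    rss: float = float("nan")

    def __post_init__(self):
        if self.a <= 0:
            raise ValueError("Wood parameter a must be > 0")


@dataclass
class ExpectedCurve:
    """Quantile-regression expected curve: quartic in DIM, tau = 0.7.

    ``coefficients`` are (c0..c4) of the polynomial in raw DIM;
    predictions are clipped at 0 kg since a quartic can go negative
    outside its support.
    """

    coefficients: np.ndarray
    tau: float = EXPECTED_TAU
    fit_window: tuple[int, int] = EXPECTED_WINDOW

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (_POLY_DEGREE + 1,):
            raise ValueError("expected curve needs exactly 5 coefficients")
        if not 0.0 < self.tau < 1.0:
            raise ValueError("tau must lie in (0,1)")

    def predict(self, dim) -> np.ndarray:
        """Evaluate the curve, clipped at 0 kg."""
        dim = np.asarray(dim, dtype=float)
        raw = np.polyval(self.coefficients[::-1], dim)
        return np.maximum(raw, 0.0)


@dataclass
class ModelFit:
    """Residual bundle for one fitted model on one lactation."""

    kind: str  # "wood" | "expected"
    dims: np.ndarray
    observed: np.ndarray
    predicted: np.ndarray
    rmse: float = field(init=False)
    r2: float = field(init=False)

    def __post_init__(self):
        self.dims = np.asarray(self.dims, dtype=int)
        self.observed = np.asarray(self.observed, dtype=float)
        self.predicted = np.asarray(self.predicted, dtype=float)
        r = self.residuals
        self.rmse = float(np.sqrt(np.mean(r**2))) if r.size else float("nan")
        sst = float(np.sum((self.observed - self.observed.mean()) ** 2))
        ssr = float(np.sum(r**2))
        self.r2 = 1.0 - ssr / sst if sst > 0 else float("nan")

    @property
    def residuals(self) -> np.ndarray:
        return self.observed - self.predicted


def wood_predict(p: WoodParams, dim) -> np.ndarray | float:
    """Evaluate the Wood curve a * dim^b * exp(-c*dim) at dim >= 1."""
    dim_arr = np.asarray(dim, dtype=float)
    if np.any(dim_arr <= 0):
        raise ValueError("Wood curve is defined for dim >= 1 only")
    out = p.a * dim_arr**p.b * np.exp(-p.c * dim_arr)
    return float(out) if np.isscalar(dim) or dim_arr.ndim == 0 else out


def fit_wood(series: LactationSeries) -> WoodParams:
    """Least-squares Wood fit on all observed days with dim >= 1.

    Initialised by ordinary least squares on the log-linearised model
    ``log dmy = log a + b log dim - c dim`` (positive-yield rows), then
    refined with a bounded trust-region nonlinear solver.  Deterministic:
    no random restarts.  Raises on an all-zero series.
    """
    mask = series.dims >= 1
    dims = series.dims[mask].astype(float)
    dmy = series.dmy[mask]
    if dims.size < 3:
        raise ValueError("degenerate series: fewer than 3 usable records")
    if np.all(dmy == 0):
        raise ValueError("degenerate series: all daily yields are zero")

    pos = dmy > 0
    X = np.column_stack(
        [np.ones(pos.sum()), np.log(dims[pos]), -dims[pos]]
    )
    coef, *_ = np.linalg.lstsq(X, np.log(dmy[pos]), rcond=None)
    a0 = float(np.exp(coef[0]))
    b0 = float(coef[1])
    c0 = float(coef[2])
    x0 = np.array([max(a0, 1e-6), np.clip(b0, -4.9, 4.9), np.clip(c0, 0.0, 0.9)])

    def resid(theta):
        a, b, c = theta
        return a * dims**b * np.exp(-c * dims) - dmy

    def jac(theta):
        a, b, c = theta
        base = dims**b * np.exp(-c * dims)
        return np.column_stack([base, a * base * np.log(dims), -a * base * dims])

    sol = least_squares(
        resid,
        x0,
        jac=jac,
        bounds=([1e-9, -5.0, 0.0], [np.inf, 5.0, 1.0]),
        method="trf",
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
    )
    a, b, c = sol.x
    return WoodParams(
        a=float(a),
        b=float(b),
        c=float(c),
        converged=bool(sol.success),
        rss=float(2.0 * sol.cost),
    )


def wood_geometry(p: WoodParams, horizon: int = 305) -> dict:
    """Shape summaries of a fitted Wood curve.

    The unconstrained maximum of the Wood curve sits at dim = b/c; here the
    peak is clipped to [1, horizon] (b <= 0 gives a monotone-decreasing
    curve with its maximum at day 1, c = 0 a non-decreasing one peaking at
    the horizon).  Cumulative yields are daily sums, matching the daily
    sampling of the data.
    """
    if p.b <= 0:
        peak_dim = 1.0
    elif p.c <= 0:
        peak_dim = float(horizon)
    else:
        peak_dim = float(np.clip(p.b / p.c, 1.0, horizon))
    peak_yield = wood_predict(p, peak_dim)
    y1 = wood_predict(p, 1)
    yh = wood_predict(p, horizon)
    slope_to_peak = (peak_yield - y1) / (peak_dim - 1.0) if peak_dim > 1.0 else 0.0
    slope_after_peak = (
        (yh - peak_yield) / (horizon - peak_dim) if peak_dim < horizon else 0.0
    )
    days = np.arange(1, horizon + 1, dtype=float)
    daily = wood_predict(p, days)
    cum50 = float(np.sum(daily[:50]))
    cum_h = float(np.sum(daily))
    return {
        "peak_dim": float(peak_dim),
        "peak_yield": float(peak_yield),
        "slope_to_peak": float(slope_to_peak),
        "slope_after_peak": float(slope_after_peak),
        "cum_yield_50": cum50,
        "cum_yield_305": cum_h,
    }


def _pinball_polyfit_primal(x: np.ndarray, y: np.ndarray, tau: float) -> np.ndarray:
    """Pinball-loss polynomial quantile fit as the primal LP.

    Minimises sum_i rho_tau(y_i - X beta) with rho_tau(u) = u (tau - 1[u<0])
    via the standard split-residual formulation, solved with the
    deterministic HiGHS solver.
    """
    n = x.size
    V = np.vander(x, _POLY_DEGREE + 1, increasing=True)
    k = V.shape[1]
    # variables: beta (free, split +/-), u >= 0, v >= 0
    # y = V beta + u - v ; minimise tau * 1'u + (1-tau) * 1'v
    c = np.concatenate(
        [np.zeros(2 * k), tau * np.ones(n), (1.0 - tau) * np.ones(n)]
    )
    A_eq = sparse.hstack(
        [
            sparse.csc_matrix(V),
            -sparse.csc_matrix(V),
            sparse.eye(n, format="csc"),
            -sparse.eye(n, format="csc"),
        ],
        format="csc",
    )
    res = linprog(
        c,
        A_eq=A_eq,
        b_eq=y,
        bounds=[(0, None)] * (2 * k + 2 * n),
        method="highs",
    )
    if not res.success:
        raise RuntimeError(f"quantile fit failed: {res.message}")
    return res.x[:k] - res.x[k : 2 * k]


def _pinball_polyfit(x: np.ndarray, y: np.ndarray, tau: float) -> np.ndarray:
    """Exact pinball-loss polynomial quantile fit.

    Solves the dual LP of quantile regression — maximise y'a subject to
    X'a = (1 - tau) X'1 and a in [0,1]^n — whose basic optimum leaves
    exactly as many fractional a_i as there are coefficients; those are the
    interpolated observations and determine beta.  Falls back to the primal
    split-residual LP when the dual vertex is degenerate (fewer fractional
    points than coefficients, e.g. data lying exactly on a quartic).
    Deterministic throughout; returns coefficients in the scaled basis.
    """
    V = np.vander(x, _POLY_DEGREE + 1, increasing=True)
    res = linprog(
        -y,
        A_eq=sparse.csc_matrix(V.T),
        b_eq=(1.0 - tau) * V.sum(axis=0),
        bounds=[(0.0, 1.0)] * x.size,
        method="highs",
    )
    if res.success:
        a = res.x
        interp = np.where((a > 1e-7) & (a < 1.0 - 1e-7))[0]
        if interp.size >= _POLY_DEGREE + 1:
            beta, *_ = np.linalg.lstsq(V[interp], y[interp], rcond=None)
            # guard against a degenerate vertex giving a non-optimal basis
            fitted_loss = _pinball_loss(y - V @ beta, tau)
            if abs(fitted_loss - (-res.fun - (1.0 - tau) * y.sum())) < 1e-6 * max(
                1.0, abs(fitted_loss)
            ):
                return beta
    return _pinball_polyfit_primal(x, y, tau)


def _pinball_loss(u: np.ndarray, tau: float) -> float:
    return float(np.sum(u * (tau - (u < 0))))


def fit_expected_curve(series: LactationSeries, tau: float = EXPECTED_TAU) -> ExpectedCurve:
    """Fit the quartic quantile-regression expected curve on days 11-340."""
    lo, hi = EXPECTED_WINDOW
    mask = (series.dims >= lo) & (series.dims <= hi)
    dims = series.dims[mask].astype(float)
    dmy = series.dmy[mask]
    if dims.size < _POLY_DEGREE + 1:
        raise ValueError("insufficient window data: need >= 5 records in day 11-340")
    beta_scaled = _pinball_polyfit(dims / _DIM_SCALE, dmy, tau)
    # convert from the x = dim/340 basis back to raw-dim coefficients
    coeffs = beta_scaled / _DIM_SCALE ** np.arange(_POLY_DEGREE + 1)
    return ExpectedCurve(coefficients=coeffs, tau=tau)


def expected_residuals(series: LactationSeries, curve: ExpectedCurve) -> ModelFit:
    """Daily deviations from the expected curve on the fit window."""
    lo, hi = curve.fit_window
    mask = (series.dims >= lo) & (series.dims <= hi)
    dims = series.dims[mask]
    observed = series.dmy[mask]
    predicted = curve.predict(dims)
    return ModelFit(kind="expected", dims=dims, observed=observed, predicted=predicted)


def wood_residuals(series: LactationSeries, p: WoodParams) -> ModelFit:
    """Residuals of the Wood fit on all observed days with dim >= 1."""
    mask = series.dims >= 1
    dims = series.dims[mask]
    observed = series.dmy[mask]
    predicted = wood_predict(p, dims.astype(float))
    return ModelFit(kind="wood", dims=dims, observed=observed, predicted=predicted)
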