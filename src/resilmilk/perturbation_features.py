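"""Perturbation detection and the 40 milk-yield sensor features.

A perturbation is a maximal run of at least 5 consecutive observed days on
which the daily yield falls below the expected lactation curve (a missing
day breaks the run), provided yield drops below 85% of the expected level
on at least one of those days — shallow runs happen constantly around a
0.7-quantile curve and are counted separately (ExpNeg_5d).  An episode is
*major* when yield additionally drops below 70% of expected at least once,
otherwise *minor*.  Each episode is split at its deepest day into a
development phase (decline, deepest day included) and a recovery phase.

The feature set comprises 40 values in six categories:

1. Wood-curve shape (6): peak yield and timing, slopes, cumulative yields.
2. Wood residuals (6): variability of yield around the fitted Wood curve.
3. Expected-curve shape (4): peak, slope to peak, persistency.
4. Expected-curve residuals (11): distributional and run statistics of the
   daily deviations from the expected curve.
5. Perturbations (11): counts, phase durations and milk losses.
6. Resilience indicators (2): log variance (LnVar) and lag-1
   autocorrelation of the expected-curve residuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats

from .data_io import LactationSeries
from .lactation_models import (
    EXPECTED_WINDOW,
    ExpectedCurve,
    ModelFit,
    WoodParams,
    expected_residuals,
    fit_expected_curve,
    fit_wood,
    wood_geometry,
    wood_residuals,
)

MIN_EPISODE_DAYS = 5
#: an episode counts as a perturbation only if yield drops below this
#: fraction of the expected level on at least one day; shallower runs are
#: ordinary variability (they still count in ExpNeg_5d).
PERT_THRESHOLD = 0.85
#: a perturbation is major when yield drops below this fraction at least once.
MAJOR_THRESHOLD = 0.70
#: numerical guard: a residual counts as negative only below -NEG_TOL kg,
#: so observations lying on the fitted curve (within float error) never
#: register as deficit days.
NEG_TOL = 1e-6


@dataclass
class Perturbation:
    """One detected below-expected episode."""

    start_dim: int
    end_dim: int
    deepest_dim: int
    severity: str  # "minor" | "major"
    milk_loss: float  # kg, summed expected - observed over the episode
    deepest_deficit: float  # kg at deepest_dim

    def __post_init__(self):
        if not self.start_dim <= self.deepest_dim <= self.end_dim:
            raise ValueError("deepest day must lie within the episode")
        if self.severity not in ("minor", "major"):
            raise ValueError(f"unknown severity {self.severity!r}")

    @property
    def duration(self) -> int:
        return self.end_dim - self.start_dim + 1

    @property
    def dev_days(self) -> int:
        """Development phase length; the deepest day counts as development."""
        return self.deepest_dim - self.start_dim + 1

    @property
    def rec_days(self) -> int:
        return self.end_dim - self.deepest_dim


#: (name, category, unit, definition) for all 40 features, in export order.
FEATURE_CATALOG: list[tuple[str, int, str, str]] = [
    # category 1 — Wood-curve shape
    ("WoodPeakYield", 1, "kg", "Wood-curve yield at its peak"),
    ("WoodPeakDIM", 1, "days", "day in milk of the Wood-curve peak"),
    ("WoodSlopeToPeak", 1, "kg/day", "mean daily rise from day 1 to the peak"),
    ("WoodSlopeAfterPeak", 1, "kg/day", "mean daily decline from peak to day 305"),
    ("WoodCumYield50", 1, "kg", "cumulative Wood-curve yield, days 1-50"),
    ("WoodCumYield305", 1, "kg", "cumulative Wood-curve yield, days 1-305"),
    # category 2 — Wood residuals
    ("WoodResVar", 2, "kg^2", "variance of Wood-curve residuals"),
    ("WoodResAClag1", 2, "-", "lag-1 autocorrelation of Wood residuals"),
    ("WoodResSkew", 2, "-", "skewness of Wood residuals"),
    ("WoodResMaxAbs", 2, "kg", "largest absolute Wood residual"),
    ("WoodResMeanAbs", 2, "kg", "mean absolute Wood residual"),
    ("WoodResRMSE", 2, "kg", "root mean squared Wood residual"),
    # category 3 — expected-curve shape
    ("ExpPeakYield", 3, "kg", "expected-curve maximum on days 11-340"),
    ("ExpPeakDIM", 3, "days", "day in milk of the expected-curve maximum"),
    ("ExpSlopeToPeak", 3, "kg/day", "mean daily rise from day 11 to the peak"),
    ("ExpPersistency", 3, "kg/day", "(value@305 - value@200)/105"),
    # category 4 — expected-curve residuals
    ("ExpRMSE", 4, "kg", "RMSE of expected-curve residuals"),
    ("ExpR2", 4, "-", "R^2 of the expected curve on days 11-340"),
    ("ExpMeanAbsRes", 4, "kg", "mean absolute expected-curve residual"),
    ("ExpSkew", 4, "-", "skewness of expected-curve residuals"),
    ("ExpMaxNegRes", 4, "kg", "most negative expected-curve residual"),
    ("ExpMeanRes", 4, "kg", "mean expected-curve residual"),
    ("ExpPercNegative", 4, "%", "share of days with negative residual"),
    ("ExpPercLower85", 4, "%", "share of days with yield below 85% of expected"),
    ("ExpPercLower70", 4, "%", "share of days with yield below 70% of expected"),
    ("ExpNeg_5d", 4, "count", "runs of >=5 consecutive negative-residual days"),
    ("ExpAutoCorr", 4, "count", "sign changes of the residual sequence"),
    # category 5 — perturbations
    ("PertNoTotal", 5, "count", "number of perturbations"),
    ("PertNoMinor", 5, "count", "number of minor perturbations"),
    ("PertNoMajor", 5, "count", "number of major perturbations"),
    ("PertMinDaysDev", 5, "days", "mean development-phase length, minor"),
    ("PertMinDaysRec", 5, "days", "mean recovery-phase length, minor"),
    ("PertMajDaysDev", 5, "days", "mean development-phase length, major"),
    ("PertMajDaysRec", 5, "days", "mean recovery-phase length, major"),
    ("PertMinMilkLoss", 5, "kg", "summed milk loss over minor perturbations"),
    ("PertMajMilkLoss", 5, "kg", "summed milk loss over major perturbations"),
    ("PertTotalLoss", 5, "kg", "summed milk loss over all perturbations"),
    ("PertDeepest", 5, "kg", "deepest daily deficit of the costliest perturbation"),
    # category 6 — resilience indicators
    ("LnVar", 6, "ln(kg^2)", "natural log of expected-residual variance"),
    ("ExpAClag1", 6, "-", "lag-1 autocorrelation of expected residuals"),
]

FEATURE_NAMES = [name for name, *_ in FEATURE_CATALOG]
CATEGORY_SIZES = {1: 6, 2: 6, 3: 4, 4: 11, 5: 11, 6: 2}


@dataclass
class FeatureVector:
    """The 40 named sensor features / resilience indicators for one cow."""

    animal_id: str
    values: dict

    def __post_init__(self):
        missing = [n for n in FEATURE_NAMES if n not in self.values]
        extra = [n for n in self.values if n not in FEATURE_NAMES]
        if missing or extra:
            raise ValueError(f"bad feature set: missing={missing} extra={extra}")

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_row(self) -> dict:
        row = {"animal_id": self.animal_id}
        row.update({n: self.values[n] for n in FEATURE_NAMES})
        return row


def _consecutive_negative_runs(dims: np.ndarray, residuals: np.ndarray, min_len: int):
    """Yield (slice-index arrays) of maximal runs of consecutive-dim negative
    residuals of length >= min_len."""
    runs = []
    current: list[int] = []
    for i in range(dims.size):
        neg = residuals[i] < -NEG_TOL
        contiguous = bool(current) and dims[i] == dims[current[-1]] + 1
        if neg and (not current or contiguous):
            current.append(i)
        elif neg:
            if len(current) >= min_len:
                runs.append(np.array(current))
            current = [i]
        else:
            if len(current) >= min_len:
                runs.append(np.array(current))
            current = []
    if len(current) >= min_len:
        runs.append(np.array(current))
    return runs


def detect_perturbations(
    fit: ModelFit,
    min_len: int = MIN_EPISODE_DAYS,
    pert_threshold: float = PERT_THRESHOLD,
    major_threshold: float = MAJOR_THRESHOLD,
) -> list[Perturbation]:
    """Find perturbation episodes in an expected-curve residual set.

    A candidate episode is a maximal run of at least ``min_len``
    consecutive observed days below the expected curve (a missing day
    breaks the run).  The run is a perturbation only if yield drops below
    ``pert_threshold`` (85%) of the expected level on at least one day —
    shallow runs are routine variability, not disturbances.  Severity is
    major iff min(observed/expected) additionally drops below
    ``major_threshold`` (70%).  The deepest day is the earliest day of the
    maximum deficit.
    """
    residuals = fit.residuals
    perts = []
    for idx in _consecutive_negative_runs(fit.dims, residuals, min_len):
        deficit = -residuals[idx]  # positive kg below expected
        deepest_local = int(np.argmax(deficit))  # earliest on ties
        with np.errstate(divide="ignore"):
            ratio = np.where(
                fit.predicted[idx] > 0,
                fit.observed[idx] / fit.predicted[idx],
                1.0,
            )
        if float(ratio.min()) >= pert_threshold:
            continue
        severity = "major" if float(ratio.min()) < major_threshold else "minor"
        perts.append(
            Perturbation(
                start_dim=int(fit.dims[idx[0]]),
                end_dim=int(fit.dims[idx[-1]]),
                deepest_dim=int(fit.dims[idx[deepest_local]]),
                severity=severity,
                milk_loss=float(deficit.sum()),
                deepest_deficit=float(deficit[deepest_local]),
            )
        )
    return perts


def _lag1_autocorrelation(dims: np.ndarray, residuals: np.ndarray) -> float:
    """Lag-1 autocorrelation; only truly consecutive-day pairs contribute
    to the cross term (gaps excluded), the denominator is the full sum of
    squared deviations."""
    if residuals.size < 3:
        return float("nan")
    centred = residuals - residuals.mean()
    denom = float(np.sum(centred**2))
    if denom == 0:
        return float("nan")
    consecutive = np.diff(dims) == 1
    num = float(np.sum(centred[:-1][consecutive] * centred[1:][consecutive]))
    return num / denom


def _sign_changes(residuals: np.ndarray) -> int:
    """Count sign flips in the residual sequence (zeros count as positive)."""
    signs = np.where(residuals < 0, -1, 1)
    return int(np.sum(signs[:-1] != signs[1:]))


def wood_residual_features(fit: ModelFit) -> dict:
    """Category 2: variability of yield around the fitted Wood curve."""
    r = fit.residuals
    return {
        "WoodResVar": float(np.var(r, ddof=1)),
        "WoodResAClag1": _lag1_autocorrelation(fit.dims, r),
        "WoodResSkew": float(_stats.skew(r)),
        "WoodResMaxAbs": float(np.max(np.abs(r))),
        "WoodResMeanAbs": float(np.mean(np.abs(r))),
        "WoodResRMSE": fit.rmse,
    }


def curve_shape_features(wood: WoodParams, exp_curve: ExpectedCurve) -> dict:
    """Categories 1 and 3: shape of the Wood and expected curves."""
    geo = wood_geometry(wood)
    out = {
        "WoodPeakYield": geo["peak_yield"],
        "WoodPeakDIM": geo["peak_dim"],
        "WoodSlopeToPeak": geo["slope_to_peak"],
        "WoodSlopeAfterPeak": geo["slope_after_peak"],
        "WoodCumYield50": geo["cum_yield_50"],
        "WoodCumYield305": geo["cum_yield_305"],
    }
    lo, hi = exp_curve.fit_window
    grid = np.arange(lo, hi + 1)
    values = exp_curve.predict(grid)
    peak_local = int(np.argmax(values))
    peak_dim = int(grid[peak_local])
    peak_yield = float(values[peak_local])
    slope_to_peak = (
        (peak_yield - float(values[0])) / (peak_dim - lo) if peak_dim > lo else 0.0
    )
    persistency = float(exp_curve.predict(305) - exp_curve.predict(200)) / 105.0
    out.update(
        {
            "ExpPeakYield": peak_yield,
            "ExpPeakDIM": float(peak_dim),
            "ExpSlopeToPeak": float(slope_to_peak),
            "ExpPersistency": persistency,
        }
    )
    return out


def expected_residual_features(fit: ModelFit) -> dict:
    """Category 4: distribution and run statistics of expected residuals."""
    r = fit.residuals
    n = r.size
    with np.errstate(divide="ignore", invalid="ignore"):
        frac85 = np.mean(fit.observed < PERT_THRESHOLD * fit.predicted)
        frac70 = np.mean(fit.observed < MAJOR_THRESHOLD * fit.predicted)
    runs5 = _consecutive_negative_runs(fit.dims, r, MIN_EPISODE_DAYS)
    return {
        "ExpRMSE": fit.rmse,
        "ExpR2": fit.r2,
        "ExpMeanAbsRes": float(np.mean(np.abs(r))),
        "ExpSkew": float(_stats.skew(r)),
        "ExpMaxNegRes": float(np.min(r)),
        "ExpMeanRes": float(np.mean(r)),
        "ExpPercNegative": float(np.mean(r < -NEG_TOL) * 100.0),
        "ExpPercLower85": float(frac85 * 100.0),
        "ExpPercLower70": float(frac70 * 100.0),
        "ExpNeg_5d": float(len(runs5)),
        "ExpAutoCorr": float(_sign_changes(r)),
    }


def perturbation_features(perts: list[Perturbation]) -> dict:
    """Category 5: counts, phase durations and milk losses.

    Aggregates over an absent class (no minor, or no major, episodes) are 0
    rather than missing, so downstream regressions stay complete-case.
    """
    minor = [p for p in perts if p.severity == "minor"]
    major = [p for p in perts if p.severity == "major"]

    def _mean(vals):
        return float(np.mean(vals)) if vals else 0.0

    min_loss = float(sum(p.milk_loss for p in minor))
    maj_loss = float(sum(p.milk_loss for p in major))
    deepest = max(perts, key=lambda p: p.milk_loss).deepest_deficit if perts else 0.0
    return {
        "PertNoTotal": float(len(perts)),
        "PertNoMinor": float(len(minor)),
        "PertNoMajor": float(len(major)),
        "PertMinDaysDev": _mean([p.dev_days for p in minor]),
        "PertMinDaysRec": _mean([p.rec_days for p in minor]),
        "PertMajDaysDev": _mean([p.dev_days for p in major]),
        "PertMajDaysRec": _mean([p.rec_days for p in major]),
        "PertMinMilkLoss": min_loss,
        "PertMajMilkLoss": maj_loss,
        "PertTotalLoss": min_loss + maj_loss,
        "PertDeepest": float(deepest),
    }


def resilience_indicators(fit: ModelFit) -> dict:
    """Category 6: LnVar and lag-1 autocorrelation of expected residuals."""
    r = fit.residuals
    var = float(np.var(r, ddof=1))
    if var <= 0:
        raise ValueError("degenerate residuals: zero variance, LnVar undefined")
    return {
        "LnVar": float(np.log(var)),
        "ExpAClag1": _lag1_autocorrelation(fit.dims, r),
    }


def extract_expected_features(series: LactationSeries) -> dict:
    """Categories 4-6 only (expected-curve based), skipping the Wood fit.

    Cheaper than :func:`extract_all` for large power studies that only need
    the perturbation and residual features.
    """
    curve = fit_expected_curve(series)
    efit = expected_residuals(series, curve)
    values = {}
    values.update(expected_residual_features(efit))
    values.update(perturbation_features(detect_perturbations(efit)))
    values.update(resilience_indicators(efit))
    return values


def extract_all(series: LactationSeries) -> FeatureVector:
    """Fit both models and compute the full 40-feature vector for one cow."""
    try:
        wood = fit_wood(series)
        curve = fit_expected_curve(series)
        wfit = wood_residuals(series, wood)
        efit = expected_residuals(series, curve)
        perts = detect_perturbations(efit)
        values = {}
        values.update(curve_shape_features(wood, curve))
        values.update(wood_residual_features(wfit))
        values.update(expected_residual_features(efit))
        values.update(perturbation_features(perts))
        values.update(resilience_indicators(efit))
    except ValueError as exc:
        raise ValueError(f"animal {series.animal_id}: {exc}") from exc
    return FeatureVector(animal_id=series.animal_id, values=values)
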