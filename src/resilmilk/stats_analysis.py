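"""Linear-model comparison of sensor features across breeds and herd groups.

Each of the 40 features is min-max standardised and regressed on either

* breed proportions + a crossbred (heterosis) indicator + the cow's
  standardised average daily yield (breed contrast; purebred HOL forms the
  intercept, so breed coefficients are deviations from HOL), or
* a herd-group indicator (SEL50 vs SEL99) + average daily yield.

Before the final fit, the 0.5% most influential observations per feature
model are removed using Cook's distance with the mean squared error in its
1/n form:

    D_i = r_i^2 / (p * MSE) * h_ii / (1 - h_ii)^2,   MSE = (1/n) sum r_i^2.

Significance uses a Bonferroni threshold alpha = 0.05 / 40 = 0.00125
(strict inequality), and results are summarised as the percentage of
significant features per contrast term and feature category.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .perturbation_features import FEATURE_CATALOG, FEATURE_NAMES

logger = logging.getLogger(__name__)

#: Non-HOL breed covariates in model order.
BREED_TERMS = ("SIM", "MON", "BSW", "SRB", "NRF", "MRY", "BBL", "JER", "GRO", "DFR", "AYR")

FEATURE_CATEGORY = {name: cat for name, cat, *_ in FEATURE_CATALOG}


@dataclass(frozen=True)
class AnalysisConfig:
    alpha: float = 0.05 / 40  # Bonferroni over the 40 features = 0.00125
    removal_quantile: float = 0.995
    min_feature_coverage: float = 0.5  # features missing for more are skipped


@dataclass
class RegressionFit:
    """OLS fit bundle: coefficients, residual diagnostics, leverages."""

    response: np.ndarray
    terms: list
    beta: np.ndarray
    se: np.ndarray
    pvalues: np.ndarray
    residuals: np.ndarray
    leverage: np.ndarray
    n: int
    p: int
    mse: float = field(init=False)  # 1/n form

    def __post_init__(self):
        self.mse = float(np.mean(self.residuals**2))

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"term": self.terms, "beta": self.beta, "se": self.se, "p": self.pvalues}
        )


@dataclass
class CooksResult:
    distances: np.ndarray
    cutoff: float
    removal_mask: np.ndarray  # True = remove


def minmax_standardize(values) -> np.ndarray:
    """Scale a vector to [0,1] by (x - min)/(max - min)."""
    x = np.asarray(values, dtype=float)
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi <= lo:
        raise ValueError("degenerate feature: constant vector cannot be standardised")
    return (x - lo) / (hi - lo)


def fit_linear(design: pd.DataFrame, response) -> RegressionFit:
    """Ordinary least squares with two-sided t-test p-values and leverages.

    The design must already contain its intercept column and be full rank;
    rank deficiency raises naming the collinear columns.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(response, dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify dependent columns via QR pivoting on the diagonal of R
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = [design.columns[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise ValueError(f"rank-deficient design; collinear columns: {bad or 'unknown'}")
    res = sm.OLS(y, X).fit()
    leverage = res.get_influence().hat_matrix_diag
    return RegressionFit(
        response=y,
        terms=list(design.columns),
        beta=np.asarray(res.params),
        se=np.asarray(res.bse),
        pvalues=np.asarray(res.pvalues),
        residuals=np.asarray(res.resid),
        leverage=np.asarray(leverage),
        n=int(res.nobs),
        p=X.shape[1],
    )


def cooks_distance(fit: RegressionFit, removal_quantile: float = 0.995) -> CooksResult:
    """Cook's distance per observation and the influential-point mask.

    Removes the top ``round((1 - removal_quantile) * n)`` observations by
    distance (ties to the earlier index), i.e. exactly 0.5% at the default
    quantile for n divisible by 200.  ``cutoff`` records the linear-
    interpolation percentile of the distances at the removal quantile.
    Observations with leverage 1 get infinite distance and are always
    removed first.
    """
    r, h = fit.residuals, fit.leverage
    # a (numerically) perfect fit has no influential points; without this
    # guard the 0/0 ratio r_i^2/MSE amplifies float noise to O(1) distances
    scale = float(np.mean(fit.response**2)) + 1.0
    if fit.mse <= 1e-20 * scale:
        d = np.zeros(fit.n)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            d = r**2 / (fit.p * fit.mse) * h / (1.0 - h) ** 2
        d = np.where(h >= 1.0, np.inf, d)
    finite = d[np.isfinite(d)]
    cutoff = float(np.percentile(finite, removal_quantile * 100)) if finite.size else np.nan
    k = int(round((1.0 - removal_quantile) * fit.n))
    mask = np.zeros(fit.n, dtype=bool)
    if k > 0:
        order = np.argsort(-d, kind="stable")  # stable: ties keep earlier index
        mask[order[:k]] = True
    return CooksResult(distances=d, cutoff=cutoff, removal_mask=mask)


def significance_summary(
    results: pd.DataFrame, terms, alpha: float
) -> pd.DataFrame:
    """Percentage of significantly different features per term and category.

    ``results`` has one row per (feature, term) with a p-value.  Returns a
    table with one row per term per category 1-6 plus a total row, each
    carrying n_significant, n_total and the percentage.
    """
    rows = []
    for term in terms:
        sub = results[results["term"] == term].copy()
        sub["category"] = sub["feature"].map(FEATURE_CATEGORY)
        for cat, grp in sub.groupby("category"):
            n_sig = int((grp["p"] < alpha).sum())
            n_tot = len(grp)
            rows.append(
                {
                    "term": term,
                    "category": int(cat),
                    "n_significant": n_sig,
                    "n_total": n_tot,
                    "percent": 100.0 * n_sig / n_tot if n_tot else np.nan,
                }
            )
        n_sig = int((sub["p"] < alpha).sum())
        rows.append(
            {
                "term": term,
                "category": 0,  # 0 = all categories combined
                "n_significant": n_sig,
                "n_total": len(sub),
                "percent": 100.0 * n_sig / len(sub) if len(sub) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def _fit_one_feature(design: pd.DataFrame, y_std: np.ndarray, config: AnalysisConfig):
    """Fit, remove influential points, refit; returns the refit and mask.

    If the removal discards every representative of a sparse term (e.g. a
    breed with a handful of cows), that column is constant in the reduced
    data and is dropped from the refit with a log entry.
    """
    fit0 = fit_linear(design, y_std)
    cooks = cooks_distance(fit0, config.removal_quantile)
    keep = ~cooks.removal_mask
    sub = design.loc[keep].reset_index(drop=True)
    degenerate = [
        c for c in sub.columns if c != "intercept" and sub[c].nunique() == 1
    ]
    if degenerate:
        logger.warning(
            "terms %s lost all variation after influence removal; dropped",
            degenerate,
        )
        sub = sub.drop(columns=degenerate)
    refit = fit_linear(sub, y_std[keep])
    return refit, cooks


def breed_design(table: pd.DataFrame) -> pd.DataFrame:
    """Design matrix for the breed contrast.

    One proportion column per non-HOL breed present in the data (1 for a
    purebred of that breed, 0.5 for its HOL crossbred), a crossbred
    indicator for the heterosis effect, and the min-max standardised
    average daily yield.  A purebred HOL row is all-zero apart from the
    intercept, which therefore estimates the HOL baseline.
    """
    n = len(table)
    design = pd.DataFrame({"intercept": np.ones(n)})
    present = [b for b in BREED_TERMS if (table["main_breed"] == b).any()]
    for breed in present:
        prop = np.zeros(n)
        is_breed = (table["main_breed"] == breed).to_numpy()
        prop[is_breed & (table["class"] == "purebred").to_numpy()] = 1.0
        prop[is_breed & (table["class"] == "crossbred").to_numpy()] = 0.5
        design[breed] = prop
    cross = (table["class"] == "crossbred").astype(float).to_numpy()
    if cross.any():  # an all-purebred table would make the column degenerate
        design["cross"] = cross
    design["aDMY"] = minmax_standardize(table["avg_dmy"])
    return design


def run_breed_analysis(
    table: pd.DataFrame, config: AnalysisConfig = AnalysisConfig()
):
    """Per-feature breed-contrast regressions with influence filtering.

    ``table`` is the subset-A analysis table: one row per cow with
    ``class``, ``main_breed``, ``avg_dmy`` and the 40 feature columns.
    Returns ``(results, summary, fits)`` where ``results`` has one row per
    (feature, term) with beta/se/p/significant, ``summary`` is the
    per-term-per-category percentage table and ``fits`` maps feature name
    to its post-removal :class:`RegressionFit`.
    """
    design = breed_design(table)
    rows, fits = [], {}
    for feature in FEATURE_NAMES:
        if feature not in table.columns:
            continue
        y = table[feature].to_numpy(dtype=float)
        ok = np.isfinite(y)
        if ok.mean() < config.min_feature_coverage:
            logger.warning("feature %s missing for >50%% of animals; skipped", feature)
            continue
        try:
            y_std = minmax_standardize(y[ok])
        except ValueError:
            logger.warning("feature %s constant; skipped", feature)
            continue
        refit, _ = _fit_one_feature(
            design.loc[ok].reset_index(drop=True), y_std, config
        )
        fits[feature] = refit
        for term, beta, se, p in zip(refit.terms, refit.beta, refit.se, refit.pvalues):
            rows.append(
                {
                    "feature": feature,
                    "term": term,
                    "beta": beta,
                    "se": se,
                    "p": p,
                    "significant": bool(p < config.alpha),
                }
            )
    results = pd.DataFrame(rows)
    contrast_terms = [t for t in results["term"].unique() if t not in ("intercept", "aDMY")]
    summary = significance_summary(results, contrast_terms, config.alpha)
    return results, summary, fits


def herd_design(table: pd.DataFrame) -> pd.DataFrame:
    """Design for the herd contrast: intercept + SEL indicator + aDMY.

    ``SEL`` is 1 for cows in SEL50 herds and 0 in SEL99 herds, so the
    coefficient is the SEL50 - SEL99 difference.
    """
    n = len(table)
    return pd.DataFrame(
        {
            "intercept": np.ones(n),
            "SEL": (table["sel_label"] == "SEL50").astype(float).to_numpy(),
            "aDMY": minmax_standardize(table["avg_dmy"]),
        }
    )


def run_herd_analysis(
    table: pd.DataFrame,
    config: AnalysisConfig = AnalysisConfig(),
    hol_only: bool = False,
):
    """Per-feature SEL50-vs-SEL99 regressions.

    ``table`` is the subset-B cow table with ``sel_label``, ``avg_dmy`` and
    the feature columns.  With ``hol_only=True`` the contrast is restricted
    to purebred HOL cows (requires ``class`` and ``main_breed`` columns),
    isolating herd environment from breed composition.
    """
    if hol_only:
        table = table[
            (table["class"] == "purebred") & (table["main_breed"] == "HOL")
        ].reset_index(drop=True)
    for label in ("SEL50", "SEL99"):
        if not (table["sel_label"] == label).any():
            raise ValueError(f"herd group {label} is empty")
    design = herd_design(table)
    rows, fits = [], {}
    for feature in FEATURE_NAMES:
        if feature not in table.columns:
            continue
        y = table[feature].to_numpy(dtype=float)
        ok = np.isfinite(y)
        if ok.mean() < config.min_feature_coverage:
            logger.warning("feature %s missing for >50%% of animals; skipped", feature)
            continue
        try:
            y_std = minmax_standardize(y[ok])
        except ValueError:
            logger.warning("feature %s constant; skipped", feature)
            continue
        refit, _ = _fit_one_feature(
            design.loc[ok].reset_index(drop=True), y_std, config
        )
        fits[feature] = refit
        for term, beta, se, p in zip(refit.terms, refit.beta, refit.se, refit.pvalues):
            rows.append(
                {
                    "feature": feature,
                    "term": term,
                    "beta": beta,
                    "se": se,
                    "p": p,
                    "significant": bool(p < config.alpha),
                }
            )
    results = pd.DataFrame(rows)
    summary = significance_summary(results, ["SEL"], config.alpha)
    return results, summary, fits
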