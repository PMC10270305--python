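"""Convenience glue: population -> feature table -> analysis inputs."""

from __future__ import annotations

import pandas as pd

from .stats_analysis import run_breed_analysis
from .synthetic_data import SimConfig, simulate_population

from .cohort_selection import classify_table
from .perturbation_features import extract_all, extract_expected_features
from .synthetic_data import SimResult


def features_table(series_list, expected_only: bool = False) -> pd.DataFrame:
    """Extract the feature vector for every series into one table.

    ``expected_only=True`` computes just the expected-curve features
    (categories 4-6), roughly halving the per-cow cost.
    """
    rows = []
    for series in series_list:
        if expected_only:
            row = dict(animal_id=series.animal_id, **extract_expected_features(series))
        else:
            row = extract_all(series).as_row()
        row["herd_id"] = series.herd_id
        rows.append(row)
    return pd.DataFrame(rows)


def population_feature_table(
    result: SimResult, expected_only: bool = False
) -> pd.DataFrame:
    """Feature table for a simulated population, joined with per-cow traits
    (class, main breed, average yield, herd) needed by the analyses."""
    feats = features_table(result.series, expected_only=expected_only)
    classes = classify_table(result.animal_meta)
    table = feats.merge(classes, on="animal_id").merge(
        result.animal_traits.drop(columns=["herd_id"]), on="animal_id"
    )
    return table


def breed_effect_replicate(
    seed: int,
    breed: str = "MRY",
    rate_multiplier: float = 0.5,
    n_herds: int = 200,
    cows_per_herd: tuple[int, int] = (80, 120),
) -> dict:
    """One replicate of the end-to-end breed-effect recovery experiment.

    Simulates a two-breed population (HOL plus ``breed``, purebreds and
    crossbreds, ~100 cows per herd) in which the named breed's perturbation
    rate is multiplied by ``rate_multiplier``, runs the full pipeline —
    expected-curve fits, perturbation detection, breed regression with
    influence filtering — and returns the fitted coefficient of the breed
    on the perturbation count (PertNoTotal) with its p-value.
    """
    cfg = SimConfig(
        seed=seed,
        n_herds=n_herds,
        cows_per_herd=cows_per_herd,
        herd_hol_mix=((0.5, 0.95, 1.0), (0.5, 0.10, 0.60)),
        pert_rate_multiplier={breed: rate_multiplier},
        breed_mean_dmy={"HOL": 27.2, breed: 20.4},
    )
    result = simulate_population(cfg, include_dmy_table=False)
    table = population_feature_table(result, expected_only=True)
    table = table[table["class"].isin(["purebred", "crossbred"])].reset_index(drop=True)
    results, _, _ = run_breed_analysis(table)
    row = results[
        (results["feature"] == "PertNoTotal") & (results["term"] == breed)
    ].iloc[0]
    return {
        "n_cows": int(len(table)),
        "beta": float(row["beta"]),
        "p": float(row["p"]),
        "significant": bool(row["significant"]),
        "correct_sign": bool(row["beta"] < 0) if rate_multiplier < 1 else bool(row["beta"] > 0),
    }
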