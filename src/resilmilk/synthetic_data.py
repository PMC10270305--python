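"""Synthetic lactation populations with known ground truth.

Real automated-milking-system datasets are proprietary, so every pipeline
stage here is exercised on simulated herds whose generating process mirrors
the structure the analysis assumes:

* per-cow Wood-shaped mean curves, with breed-specific yield levels
  (Holstein-Friesian highest at ~27 kg/day, Groninger Whiteheaded lowest
  at ~15 kg/day) and mild cow-to-cow shape variation;
* sporadic multi-day perturbations applied multiplicatively — a linear
  decline over a development phase to the episode's depth, then an
  exponential return over the recovery phase;
* stationary AR(1) day-to-day noise on top of the perturbed curve;
* sporadic missing days; herds of 50-300 cows whose Holstein fraction is
  drawn from a configurable mixture, so both nearly-pure-HOL (SEL99-like)
  and low-HOL (SEL50-like) herds arise.

The generator records per-lactation ground truth (true Wood parameters and
every injected episode), which :func:`truth_feature_oracle` converts into
the exact perturbation-feature values expected in the zero-noise limit.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import signal as _signal

from .data_io import AnimalMeta, LactationSeries

#: Default per-breed mean daily yield targets, kg/day.  Purebred means for
#: breeds commonly kept purebred; plausible levels for the rest.
BREED_MEAN_DMY = {
    "HOL": 27.2, "MRY": 20.4, "JER": 18.1, "MON": 20.4, "SIM": 22.3,
    "DFR": 21.0, "BSW": 21.8, "GRO": 14.9, "SRB": 22.0, "NRF": 24.0,
    "BBL": 22.0, "AYR": 21.0,
}


@dataclass
class SimConfig:
    """All knobs of the population generator.  ``seed`` is mandatory."""

    seed: int
    n_herds: int = 10
    cows_per_herd: tuple[int, int] = (50, 300)
    breed_mean_dmy: dict = field(default_factory=lambda: dict(BREED_MEAN_DMY))
    wood_b_mean: float = 0.20
    wood_b_sd: float = 0.03
    wood_c_mean: float = 0.0030
    wood_c_sd: float = 0.0004
    cow_scale_sd: float = 0.12  # lognormal sd of per-cow yield level
    noise_sigma: float = 1.8  # kg, stationary daily-noise sd at the HOL yield level
    noise_ref_dmy: float = 27.2  # sd scales linearly with cow mean yield / this
    noise_rho: float = 0.3  # AR(1) coefficient of daily noise
    pert_rate: float = 1.5  # expected perturbations per lactation
    pert_depth_range: tuple[float, float] = (0.55, 0.95)  # floor as fraction
    pert_geom_p: float = 0.12  # duration = 5 + Geometric(p) - 1, capped
    pert_max_duration: int = 50
    pert_dev_fraction: float = 0.35  # share of episode in the development phase
    missing_rate: float = 0.02
    #: (weight, low, high) uniform components for herd mean-HOL targets.
    herd_hol_mix: tuple = ((0.5, 0.95, 1.0), (0.3, 0.30, 0.95), (0.2, 0.0, 0.50))
    cross_fraction: float = 0.5  # share of non-HOL cows that are HOL crossbreds
    #: per-breed multiplier on the perturbation rate (effect injection).
    pert_rate_multiplier: dict = field(default_factory=dict)
    min_length: int = 305
    max_length: int = 340
    calving_year_range: tuple[int, int] = (2015, 2020)
    #: "wood" uses the Wood curve as the unperturbed base throughout.
    #: "quartic" replaces the base on days 11-340 with its least-squares
    #: quartic approximation, making the true curve exactly representable
    #: by the expected-curve model — used for zero-noise oracle checks,
    #: since no quartic reproduces a Wood curve exactly.
    base_curve: str = "wood"

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        lo, hi = self.pert_depth_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("perturbation depths must lie in (0,1)")
        for name in ("noise_sigma", "pert_rate", "missing_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class TruthPerturbation:
    start_dim: int
    end_dim: int
    deepest_dim: int
    depth: float  # floor as fraction of the unperturbed curve
    dev_days: int
    rec_days: int
    loss_kg: float  # noise-free milk loss over the episode
    deepest_deficit_kg: float

    @property
    def detectable(self) -> bool:
        """Counts as a perturbation: reaches below 85% of the base curve."""
        return self.depth < 0.85

    @property
    def severity(self) -> str:
        return "major" if self.depth < 0.70 else "minor"


@dataclass
class LactationTruth:
    animal_id: str
    herd_id: str
    wood: tuple[float, float, float]  # (a, b, c)
    sigma: float
    rho: float
    perturbations: list = field(default_factory=list)
    breed_composition: dict = field(default_factory=dict)


@dataclass
class SimResult:
    """Everything :func:`simulate_population` produces."""

    dmy_table: pd.DataFrame
    animal_meta: list  # of AnimalMeta
    animal_traits: pd.DataFrame  # per-cow sorting traits for cohort selection
    herd_meta: pd.DataFrame
    truth: dict  # animal_id -> LactationTruth
    series: list  # of LactationSeries, in animal order


def _wood_curve(a: float, b: float, c: float, dims: np.ndarray) -> np.ndarray:
    return a * dims**b * np.exp(-c * dims)


def _perturbation_profile(depth: float, dev_days: int, rec_days: int) -> np.ndarray:
    """Multiplicative profile of one episode, strictly below 1 throughout.

    Linear decline to ``depth`` over the development phase (deepest day is
    its last day), then an exponential return 1 - (1-depth)*exp(-3u/rec)
    that approaches but never reaches 1 inside the episode.
    """
    dev = np.array([1.0 - (1.0 - depth) * (i + 1) / dev_days for i in range(dev_days)])
    u = np.arange(1, rec_days + 1)
    rec = 1.0 - (1.0 - depth) * np.exp(-3.0 * u / max(rec_days, 1))
    return np.concatenate([dev, rec])


def _draw_perturbations(cfg: SimConfig, rate: float, length: int, rng) -> list[dict]:
    """Sample non-overlapping episode windows within days 11-340."""
    n = rng.poisson(rate)
    lo, hi = 11, min(340, length)
    placed: list[dict] = []
    for _ in range(n):
        dur = min(5 + int(rng.geometric(cfg.pert_geom_p)) - 1, cfg.pert_max_duration)
        if hi - lo + 1 < dur:
            continue
        depth = float(rng.uniform(*cfg.pert_depth_range))
        for _attempt in range(20):
            start = int(rng.integers(lo, hi - dur + 2))
            end = start + dur - 1
            if all(end < p["start"] - 1 or start > p["end"] + 1 for p in placed):
                dev = max(1, int(round(cfg.pert_dev_fraction * dur)))
                dev = min(dev, dur - 1) if dur > 1 else 1
                placed.append(
                    {"start": start, "end": end, "depth": depth,
                     "dev": dev, "rec": dur - dev}
                )
                break
    return sorted(placed, key=lambda p: p["start"])


def simulate_lactation(
    cfg: SimConfig,
    animal_id: str,
    herd_id: str,
    wood: tuple[float, float, float],
    rng: np.random.Generator,
    pert_rate: float | None = None,
    calving_date: _dt.date | None = None,
    noise_sigma: float | None = None,
) -> tuple[LactationSeries, LactationTruth]:
    """Generate one lactation and its ground truth.

    The series is the base curve times the product of episode profiles plus
    AR(1) noise, floored at 0 kg, with missing days deleted.  Truth losses
    are computed on the noise-free curve.  ``noise_sigma`` overrides the
    config value (the population generator scales it with yield level).
    """
    a, b, c = wood
    length = int(rng.integers(cfg.min_length, cfg.max_length + 1))
    dims = np.arange(1, length + 1)
    base = _wood_curve(a, b, c, dims.astype(float))
    if cfg.base_curve == "quartic":
        lo, hi = 11, min(340, length)
        win = slice(lo - 1, hi)
        V = np.vander(dims[win] / 340.0, 5, increasing=True)
        coeffs, *_ = np.linalg.lstsq(V, base[win], rcond=None)
        base[win] = np.maximum(V @ coeffs, 0.0)
    elif cfg.base_curve != "wood":
        raise ValueError(f"unknown base_curve {cfg.base_curve!r}")

    rate = cfg.pert_rate if pert_rate is None else pert_rate
    windows = _draw_perturbations(cfg, rate, length, rng)
    profile = np.ones(length)
    truth_perts = []
    for w in windows:
        prof = _perturbation_profile(w["depth"], w["dev"], w["rec"])
        sl = slice(w["start"] - 1, w["end"])
        profile[sl] = prof
        deepest_dim = w["start"] + w["dev"] - 1
        loss = float(np.sum(base[sl] * (1.0 - prof)))
        truth_perts.append(
            TruthPerturbation(
                start_dim=w["start"],
                end_dim=w["end"],
                deepest_dim=deepest_dim,
                depth=w["depth"],
                dev_days=w["dev"],
                rec_days=w["rec"],
                loss_kg=loss,
                deepest_deficit_kg=float(base[deepest_dim - 1] * (1.0 - w["depth"])),
            )
        )

    sigma = cfg.noise_sigma if noise_sigma is None else noise_sigma
    if sigma > 0:
        # stationary AR(1): e_t = rho e_{t-1} + shock_t, Var(e_t) = sigma^2
        innov_sd = sigma * np.sqrt(1.0 - cfg.noise_rho**2)
        x = np.empty(length)
        x[0] = rng.normal(0.0, sigma)
        x[1:] = rng.normal(0.0, innov_sd, size=length - 1)
        noise = _signal.lfilter([1.0], [1.0, -cfg.noise_rho], x)
    else:
        noise = np.zeros(length)

    dmy = np.maximum(base * profile + noise, 0.0)

    keep = rng.random(length) >= cfg.missing_rate
    keep[0] = True  # the series always starts within 5 days of calving
    series = LactationSeries(
        animal_id=animal_id,
        dims=dims[keep],
        dmy=dmy[keep],
        herd_id=herd_id,
        parity=1,
        calving_date=calving_date,
    )
    truth = LactationTruth(
        animal_id=animal_id,
        herd_id=herd_id,
        wood=(a, b, c),
        sigma=sigma,
        rho=cfg.noise_rho,
        perturbations=truth_perts,
    )
    return series, truth


def _draw_breed_composition(cfg: SimConfig, hol_target: float, alt_breed: str, rng):
    """Breed fractions in eighths for one cow of a herd with the given
    HOL-fraction target."""
    c = cfg.cross_fraction
    # p solves p + 0.5 * c * (1 - p) = hol_target, the herd's mean HOL share
    p_hol = float(np.clip((hol_target - 0.5 * c) / (1.0 - 0.5 * c), 0.0, 1.0))
    if rng.random() < p_hol:
        return {"HOL": 1.0}
    if rng.random() < c:
        return {"HOL": 0.5, alt_breed: 0.5}
    return {alt_breed: 1.0}


def _cow_wood_params(cfg: SimConfig, composition: dict, rng):
    """Wood parameters hitting the cow's breed-weighted mean-yield target;
    returns (a, b, c, target_mean_dmy)."""
    target = sum(
        frac * cfg.breed_mean_dmy.get(breed, 21.0)
        for breed, frac in composition.items()
    )
    target *= float(np.exp(rng.normal(0.0, cfg.cow_scale_sd)))
    b = float(np.clip(rng.normal(cfg.wood_b_mean, cfg.wood_b_sd), 0.05, 0.5))
    c = float(np.clip(rng.normal(cfg.wood_c_mean, cfg.wood_c_sd), 5e-4, 0.01))
    dims = np.arange(1, 306, dtype=float)
    shape_mean = float(np.mean(dims**b * np.exp(-c * dims)))
    a = target / shape_mean
    return a, b, c, target


def simulate_population(cfg: SimConfig, include_dmy_table: bool = True) -> SimResult:
    """Generate a multi-herd population of first-parity lactations.

    ``include_dmy_table=False`` skips materialising the long daily-record
    table (cheap for large power studies that work from the series
    objects directly).
    """
    rng = np.random.default_rng(cfg.seed)
    weights = np.array([w for w, _, _ in cfg.herd_hol_mix], dtype=float)
    weights /= weights.sum()
    alt_breeds = [b for b in cfg.breed_mean_dmy if b != "HOL"]

    dmy_rows = []
    metas: list[AnimalMeta] = []
    trait_rows = []
    herd_rows = []
    truth: dict[str, LactationTruth] = {}
    all_series: list[LactationSeries] = []
    year_lo, year_hi = cfg.calving_year_range

    for h in range(cfg.n_herds):
        herd_id = f"H{h:04d}"
        comp_idx = rng.choice(len(weights), p=weights)
        _, lo, hi = cfg.herd_hol_mix[comp_idx]
        hol_target = float(rng.uniform(lo, hi))
        n_cows = int(rng.integers(cfg.cows_per_herd[0], cfg.cows_per_herd[1] + 1))
        alt_breed = alt_breeds[int(rng.integers(len(alt_breeds)))]

        herd_hol_fracs = []
        herd_afc, herd_dmy = [], []
        year_counts: dict[int, int] = {}
        for i in range(n_cows):
            animal_id = f"{herd_id}C{i:04d}"
            comp = _draw_breed_composition(cfg, hol_target, alt_breed, rng)
            afc = int(rng.integers(680, 821))
            year = int(rng.integers(year_lo, year_hi + 1))
            calving = _dt.date(year, 1, 1) + _dt.timedelta(
                days=int(rng.integers(0, 365))
            )
            birth = calving - _dt.timedelta(days=afc)
            mult = sum(
                frac * cfg.pert_rate_multiplier.get(breed, 1.0)
                for breed, frac in comp.items()
            )
            a_w, b_w, c_w, target = _cow_wood_params(cfg, comp, rng)
            # day-to-day noise scales with production level, the same
            # mean-variance coupling the aDMY covariate corrects for
            sigma_cow = cfg.noise_sigma * target / cfg.noise_ref_dmy
            series, cow_truth = simulate_lactation(
                cfg, animal_id, herd_id, (a_w, b_w, c_w), rng,
                pert_rate=cfg.pert_rate * mult, calving_date=calving,
                noise_sigma=sigma_cow,
            )
            cow_truth.breed_composition = comp
            truth[animal_id] = cow_truth
            all_series.append(series)

            metas.append(
                AnimalMeta(
                    animal_id=animal_id,
                    birth_date=birth,
                    first_calving_date=calving,
                    age_at_first_calving=afc,
                    breed_composition=comp,
                )
            )
            avg_dmy = float(series.dmy.mean())
            herd_hol_fracs.append(comp.get("HOL", 0.0))
            herd_afc.append(afc)
            herd_dmy.append(avg_dmy)
            year_counts[year] = year_counts.get(year, 0) + 1
            trait_rows.append(
                {
                    "animal_id": animal_id,
                    "herd_id": herd_id,
                    "age_at_first_calving": afc,
                    "avg_dmy": avg_dmy,
                    "calving_date": calving.isoformat(),
                }
            )
            if include_dmy_table:
                dmy_rows.append(
                    pd.DataFrame(
                        {
                            "animal_id": animal_id,
                            "herd_id": herd_id,
                            "parity": 1,
                            "calving_date": calving.isoformat(),
                            "dim": series.dims,
                            "dmy_kg": series.dmy,
                        }
                    )
                )

        max_year = max(year_counts.values())
        herd_rows.append(
            {
                "herd_id": herd_id,
                "herd_size": n_cows,
                "mean_hol_fraction": float(np.mean(herd_hol_fracs)),
                "mean_afc": float(np.mean(herd_afc)),
                "mean_dmy": float(np.mean(herd_dmy)),
                "total_animals": n_cows,
                "max_animals_year": max_year,
            }
        )

    traits = pd.DataFrame(trait_rows)
    herd_df = pd.DataFrame(herd_rows)
    max_mates = herd_df.set_index("herd_id")["max_animals_year"]
    traits["max_herd_mates"] = traits["herd_id"].map(max_mates)

    if include_dmy_table:
        dmy_df = pd.concat(dmy_rows, ignore_index=True)
    else:
        dmy_df = pd.DataFrame(
            columns=["animal_id", "herd_id", "parity", "calving_date", "dim", "dmy_kg"]
        )
    return SimResult(
        dmy_table=dmy_df,
        animal_meta=metas,
        animal_traits=traits,
        herd_meta=herd_df,
        truth=truth,
        series=all_series,
    )


def truth_feature_oracle(truth: LactationTruth) -> dict:
    """Exact perturbation-feature values implied by the injected episodes.

    Mirrors the category-5 aggregation rules on the noise-free truth, so a
    zero-noise pipeline run must reproduce these values.
    """
    perts = [p for p in truth.perturbations if p.detectable]
    minor = [p for p in perts if p.severity == "minor"]
    major = [p for p in perts if p.severity == "major"]

    def _mean(vals):
        return float(np.mean(vals)) if vals else 0.0

    min_loss = float(sum(p.loss_kg for p in minor))
    maj_loss = float(sum(p.loss_kg for p in major))
    deepest = (
        max(perts, key=lambda p: p.loss_kg).deepest_deficit_kg if perts else 0.0
    )
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


def load_config(path) -> SimConfig:
    """Read a flat YAML file of :class:`SimConfig` fields."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("cows_per_herd", "pert_depth_range", "calving_year_range"):
        if key in raw:
            raw[key] = tuple(raw[key])
    if "herd_hol_mix" in raw:
        raw["herd_hol_mix"] = tuple(tuple(c) for c in raw["herd_hol_mix"])
    return SimConfig(**raw)


def write_population(result: SimResult, outdir) -> None:
    """Write the generated population as the pipeline's CSV schemas."""
    import pathlib

    from .data_io import write_animal_meta

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.dmy_table.to_csv(outdir / "dmy.csv", index=False)
    write_animal_meta(result.animal_meta, outdir / "animal_meta.csv")
    result.herd_meta.to_csv(outdir / "herd_meta.csv", index=False)

    truth_rows = []
    for animal_id, t in result.truth.items():
        a, b, c = t.wood
        for p in t.perturbations:
            truth_rows.append(
                {
                    "animal_id": animal_id, "a": a, "b": b, "c": c,
                    "sigma": t.sigma, "rho": t.rho,
                    "start_dim": p.start_dim, "end_dim": p.end_dim,
                    "deepest_dim": p.deepest_dim, "depth": p.depth,
                    "loss_kg": p.loss_kg,
                }
            )
        if not t.perturbations:
            truth_rows.append(
                {
                    "animal_id": animal_id, "a": a, "b": b, "c": c,
                    "sigma": t.sigma, "rho": t.rho,
                    "start_dim": np.nan, "end_dim": np.nan,
                    "deepest_dim": np.nan, "depth": np.nan, "loss_kg": np.nan,
                }
            )
    pd.DataFrame(truth_rows).to_csv(outdir / "truth.csv", index=False)
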