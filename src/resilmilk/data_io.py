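"""Reading, assembling and filtering daily milk yield (DMY) records.

The raw input is a long table with one row per cow per day in milk (DIM),
plus per-animal metadata carrying calving dates and breed composition in
eighths.  This module turns those tables into per-lactation series and
applies the eligibility rules used throughout the pipeline: enough recorded
days, an early enough start after calving, no long runs of missing days,
and a recent enough first calving.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The 12 recognised breed codes plus UNK for unknown ancestry.
BREED_CODES = (
    "HOL", "MRY", "JER", "MON", "SIM", "DFR",
    "BSW", "GRO", "SRB", "NRF", "BBL", "AYR",
)
UNKNOWN_BREED = "UNK"

DMY_COLUMNS = ("animal_id", "herd_id", "parity", "calving_date", "dim", "dmy")


@dataclass(frozen=True)
class MilkRecord:
    """One daily milk yield observation.

    dim is days in milk, 0-based (day of calving = 0); dmy is kg/day.
    """

    animal_id: str
    herd_id: str
    dim: int
    dmy: float
    parity: int = 1
    calving_date: _dt.date | None = None

    def __post_init__(self):
        if self.dim < 0:
            raise ValueError(f"dim must be >= 0, got {self.dim}")
        if self.dmy < 0:
            raise ValueError(f"dmy must be >= 0, got {self.dmy}")


@dataclass(frozen=True)
class AnimalMeta:
    """Per-animal metadata: dates and breed composition in eighths."""

    animal_id: str
    birth_date: _dt.date | None = None
    first_calving_date: _dt.date | None = None
    age_at_first_calving: int | None = None  # days
    breed_composition: dict = field(default_factory=dict)

    def validate_breed_fractions(self) -> None:
        total = sum(self.breed_composition.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"breed fractions for {self.animal_id} sum to {total}, not 1"
            )
        for code, frac in self.breed_composition.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction {frac} for {code} outside [0,1]")


@dataclass(frozen=True)
class HerdMeta:
    """Herd-level summary used for herd-group selection."""

    herd_id: str
    herd_size: int
    mean_hol_fraction: float

    def __post_init__(self):
        if self.herd_size < 1:
            raise ValueError("herd_size must be >= 1")
        if not 0.0 <= self.mean_hol_fraction <= 1.0:
            raise ValueError("mean_hol_fraction outside [0,1]")


@dataclass
class LactationSeries:
    """One cow's first-parity lactation: ordered (dim, dmy) pairs."""

    animal_id: str
    dims: np.ndarray
    dmy: np.ndarray
    herd_id: str = ""
    parity: int = 1
    calving_date: _dt.date | None = None
    meta_missing: bool = False

    def __post_init__(self):
        self.dims = np.asarray(self.dims, dtype=int)
        self.dmy = np.asarray(self.dmy, dtype=float)
        if self.dims.shape != self.dmy.shape:
            raise ValueError("dims and dmy must have equal length")
        if self.dims.size and np.any(np.diff(self.dims) <= 0):
            raise ValueError("dims must be strictly increasing")

    def __len__(self) -> int:
        return int(self.dims.size)

    @property
    def records(self) -> list[tuple[int, float]]:
        return list(zip(self.dims.tolist(), self.dmy.tolist()))


def _parse_date(value) -> _dt.date | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, _dt.date):
        return value
    ts = pd.Timestamp(value)
    return ts.date()


def read_dmy_table(path, schema: dict | None = None) -> list[MilkRecord]:
    """Read a daily-milk-yield CSV into :class:`MilkRecord` rows.

    Parameters
    ----------
    path
        CSV with header row.  Canonical columns: ``animal_id, herd_id,
        parity, calving_date, dim, dmy_kg`` (dates ISO-8601).
    schema
        Optional map from canonical names (``animal_id``, ``herd_id``,
        ``dim``, ``dmy``, ``parity``, ``calving_date``) to the actual
        column names in the file.

    Malformed rows (non-numeric dim/dmy, negative values) are counted and
    logged, never silently dropped.
    """
    schema = dict(schema or {})
    schema.setdefault("dmy", "dmy_kg")
    df = pd.read_csv(path, dtype={0: str})

    colmap = {}
    for canonical in ("animal_id", "herd_id", "dim", "dmy"):
        actual = schema.get(canonical, canonical)
        if actual not in df.columns:
            raise ValueError(f"column {canonical} not found (looked for '{actual}')")
        colmap[canonical] = actual
    for canonical in ("parity", "calving_date"):
        actual = schema.get(canonical, canonical)
        if actual in df.columns:
            colmap[canonical] = actual

    records: list[MilkRecord] = []
    n_bad = 0
    for _, row in df.iterrows():
        try:
            kwargs = dict(
                animal_id=str(row[colmap["animal_id"]]),
                herd_id=str(row[colmap["herd_id"]]),
                dim=int(row[colmap["dim"]]),
                dmy=float(row[colmap["dmy"]]),
            )
            if "parity" in colmap:
                kwargs["parity"] = int(row[colmap["parity"]])
            if "calving_date" in colmap:
                kwargs["calving_date"] = _parse_date(row[colmap["calving_date"]])
            records.append(MilkRecord(**kwargs))
        except (ValueError, TypeError) as exc:
            n_bad += 1
            logger.warning("skipping malformed row %s: %s", dict(row), exc)
    if n_bad:
        logger.warning("read_dmy_table: %d malformed rows skipped", n_bad)
    n_zero = sum(1 for r in records if r.dmy == 0)
    if n_zero:
        # zero yields are retained as data (possibly perturbation days)
        logger.info("read_dmy_table: %d zero-yield records retained", n_zero)
    return records


def write_dmy_table(records, path) -> None:
    """Write records in the canonical CSV schema (round-trips with read)."""
    df = pd.DataFrame(
        {
            "animal_id": [r.animal_id for r in records],
            "herd_id": [r.herd_id for r in records],
            "parity": [r.parity for r in records],
            "calving_date": [
                r.calving_date.isoformat() if r.calving_date else "" for r in records
            ],
            "dim": [r.dim for r in records],
            "dmy_kg": [r.dmy for r in records],
        }
    )
    df.to_csv(path, index=False)


def read_animal_meta(path) -> list[AnimalMeta]:
    """Read long-format animal metadata (one row per breed component)."""
    df = pd.read_csv(path, dtype={"animal_id": str})
    metas = []
    for animal_id, grp in df.groupby("animal_id", sort=True):
        first = grp.iloc[0]
        comp = {
            str(row.breed_code): float(row.fraction_eighths) / 8.0
            for row in grp.itertuples()
        }
        birth = _parse_date(first.get("birth_date"))
        calving = _parse_date(first.get("first_calving_date"))
        age = None
        if birth is not None and calving is not None:
            age = (calving - birth).days
        metas.append(
            AnimalMeta(
                animal_id=str(animal_id),
                birth_date=birth,
                first_calving_date=calving,
                age_at_first_calving=age,
                breed_composition=comp,
            )
        )
    return metas


def write_animal_meta(metas, path) -> None:
    rows = []
    for m in metas:
        for code, frac in sorted(m.breed_composition.items()):
            rows.append(
                {
                    "animal_id": m.animal_id,
                    "birth_date": m.birth_date.isoformat() if m.birth_date else "",
                    "first_calving_date": m.first_calving_date.isoformat()
                    if m.first_calving_date
                    else "",
                    "breed_code": code,
                    "fraction_eighths": round(frac * 8),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def assemble_lactations(records, meta=None) -> list[LactationSeries]:
    """Group records into per-animal lactation series sorted by dim.

    Duplicate (animal, dim) rows keep the first occurrence; the duplicate
    count is logged.  Animals present in ``records`` but absent from
    ``meta`` get ``meta_missing=True`` rather than being dropped.
    """
    meta_ids = {m.animal_id for m in meta} if meta is not None else None
    by_animal: dict[str, list[MilkRecord]] = {}
    for rec in records:
        by_animal.setdefault(rec.animal_id, []).append(rec)

    series_list = []
    n_dup_total = 0
    for animal_id in sorted(by_animal):
        recs = sorted(by_animal[animal_id], key=lambda r: r.dim)
        dims, dmys = [], []
        for r in recs:
            if dims and r.dim == dims[-1]:
                n_dup_total += 1
                continue  # keep-first tie break
            dims.append(r.dim)
            dmys.append(r.dmy)
        first = recs[0]
        series_list.append(
            LactationSeries(
                animal_id=animal_id,
                dims=np.array(dims),
                dmy=np.array(dmys),
                herd_id=first.herd_id,
                parity=first.parity,
                calving_date=first.calving_date,
                meta_missing=(meta_ids is not None and animal_id not in meta_ids),
            )
        )
    if n_dup_total:
        logger.warning("assemble_lactations: %d duplicate (animal, dim) rows dropped",
                       n_dup_total)
    return series_list


def eligibility_filter(
    series: LactationSeries,
    min_days: int = 100,
    max_start_dim: int = 5,
    max_gap: int = 5,
    min_calving_year: int = 2010,
) -> tuple[bool, list[str]]:
    """Apply the lactation eligibility rules.

    A series passes iff it has at least ``min_days`` recorded daily values,
    its first record falls within ``max_start_dim`` days of calving, no run
    of more than ``max_gap`` consecutive days is missing between the first
    and last record, and the calving year is at least ``min_calving_year``.
    Trailing truncation (dry-off or culling) is not counted as a gap.

    Returns ``(pass, reasons)`` where ``reasons`` lists every violated rule:
    ``empty``, ``min_days``, ``start_dim``, ``gap``, ``calving_year``.
    """
    reasons: list[str] = []
    if len(series) == 0:
        return False, ["empty"]
    if len(series) < min_days:
        reasons.append("min_days")
    if int(series.dims[0]) > max_start_dim:
        reasons.append("start_dim")
    gaps = np.diff(series.dims) - 1  # missing days between successive records
    if gaps.size and int(gaps.max()) > max_gap:
        reasons.append("gap")
    if series.calving_date is not None and series.calving_date.year < min_calving_year:
        reasons.append("calving_year")
    return (not reasons), reasons
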