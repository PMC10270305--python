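"""Cohort construction: breed classification and representative sampling.

Two study groups are built from the filtered lactations:

* **Subset A** (breed contrast): purebred cows (>= 7/8 of a single breed)
  and Holstein-Friesian (HOL) crossbreds (exactly 4/8 HOL + 4/8 of one
  other known breed).  Because purebred HOL dominates such populations, the
  HOL purebreds are thinned to a fixed representative sample with a
  deterministic sort-and-stride scheme; rare breeds are dropped.
* **Subset B** (herd contrast): herds of 50-300 cows whose mean HOL
  fraction is either below 50% (SEL50) or at least 99% (SEL99); the
  plentiful SEL99 herds are thinned with the same scheme on herd-level
  traits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import AnimalMeta, UNKNOWN_BREED

PUREBRED_MIN_FRACTION = 7.0 / 8.0
SEL50_MAX_HOL = 0.50
SEL99_MIN_HOL = 0.99
HERD_SIZE_RANGE = (50, 300)

#: Animal-level sorting traits for the HOL thinning, in round order.
SUBSET_A_TRAITS = ("age_at_first_calving", "avg_dmy", "calving_date", "max_herd_mates")
#: Herd-level sorting traits for the SEL99 thinning, in round order.
SUBSET_B_TRAITS = ("mean_afc", "mean_dmy", "total_animals", "max_animals_year")


@dataclass(frozen=True)
class BreedClassification:
    animal_id: str
    cls: str  # "purebred" | "crossbred" | "other"
    main_breed: str  # breed with the largest fraction


def classify_animal(meta: AnimalMeta) -> BreedClassification:
    """Classify a cow as purebred, HOL-crossbred, or other.

    Purebred: some breed holds at least 7/8 of the genes.  Crossbred:
    exactly half HOL and half one other *known* breed.  Anything else is
    "other" and excluded from the breed contrast.  ``main_breed`` is the
    breed with the largest fraction (ties broken alphabetically); for
    crossbreds it names the non-HOL half.
    """
    meta.validate_breed_fractions()
    comp = meta.breed_composition
    main_breed = min(comp, key=lambda k: (-comp[k], k))

    for breed, frac in sorted(comp.items()):
        if frac >= PUREBRED_MIN_FRACTION - 1e-12:
            return BreedClassification(meta.animal_id, "purebred", breed)

    hol = comp.get("HOL", 0.0)
    if abs(hol - 0.5) < 1e-12:
        partners = [
            b
            for b, f in comp.items()
            if b not in ("HOL", UNKNOWN_BREED) and abs(f - 0.5) < 1e-12
        ]
        if partners:
            return BreedClassification(meta.animal_id, "crossbred", sorted(partners)[0])
    return BreedClassification(meta.animal_id, "other", main_breed)


def classify_table(metas) -> pd.DataFrame:
    """Vector form of :func:`classify_animal`."""
    rows = [classify_animal(m) for m in metas]
    return pd.DataFrame(
        {
            "animal_id": [r.animal_id for r in rows],
            "class": [r.cls for r in rows],
            "main_breed": [r.main_breed for r in rows],
        }
    )


def stratified_uniform_sample(
    pool: pd.DataFrame,
    traits,
    per_round: int,
    id_col: str = "animal_id",
) -> list:
    """Deterministic sort-and-stride sampling over successive traits.

    Round k sorts the remaining pool by trait k (ascending, stable, ties by
    id) and takes one row every n/per_round rows — indices
    ``round(i * n / per_round)`` for i = 0..per_round-1, collisions resolved
    to the next free index — then removes the selected rows before the next
    round.  With 4 traits this returns exactly ``4 * per_round`` unique ids
    while covering the low end of every trait's range (index 0 is always
    taken).
    """
    traits = list(traits)
    if len(pool) < len(traits) * per_round:
        raise ValueError(
            f"pool of {len(pool)} too small for {len(traits)} x {per_round} selection"
        )
    remaining = pool.reset_index(drop=True)
    selected: list = []
    for trait in traits:
        ordered = remaining.sort_values(
            [trait, id_col], kind="mergesort"
        ).reset_index(drop=True)
        n_k = len(ordered)
        taken: set[int] = set()
        for i in range(per_round):
            j = int(round(i * n_k / per_round))
            while j in taken:
                j += 1
            if j >= n_k:
                j = 0
                while j in taken:
                    j += 1
            taken.add(j)
        idx = sorted(taken)
        selected.extend(ordered.loc[idx, id_col].tolist())
        remaining = ordered.drop(index=idx).reset_index(drop=True)
    return selected


def build_subset_A(
    animals: pd.DataFrame,
    features: pd.DataFrame,
    min_group: int = 10,
    hol_sample: int = 22100,
) -> pd.DataFrame:
    """Build the breed-contrast analysis table.

    ``animals`` must carry ``animal_id, class, main_breed`` plus the four
    sorting traits; ``features`` is the per-animal feature table.  Keeps
    purebreds and crossbreds only; thins HOL purebreds to ``hol_sample``
    cows (4 rounds of hol_sample/4) when more are available; drops breeds
    with fewer than ``min_group`` purebred+crossbred animals combined (HOL,
    the baseline, is always kept).
    """
    kept = animals[animals["class"].isin(["purebred", "crossbred"])].copy()

    hol_pure = kept[(kept["class"] == "purebred") & (kept["main_breed"] == "HOL")]
    if len(hol_pure) > hol_sample:
        per_round = hol_sample // 4
        chosen = stratified_uniform_sample(hol_pure, SUBSET_A_TRAITS, per_round)
        drop_ids = set(hol_pure["animal_id"]) - set(chosen)
        kept = kept[~kept["animal_id"].isin(drop_ids)]

    counts = kept[kept["main_breed"] != "HOL"].groupby("main_breed")["animal_id"].nunique()
    small = set(counts[counts < min_group].index)
    if small:
        kept = kept[~((kept["main_breed"].isin(small)))]

    out = kept.merge(features, on="animal_id", how="inner")
    return out.reset_index(drop=True)


def label_herd(herd_size: int, mean_hol_fraction: float) -> tuple[str, str]:
    """Assign SEL50 / SEL99 / excluded with a reason code."""
    lo, hi = HERD_SIZE_RANGE
    if herd_size < lo:
        return "excluded", "herd too small"
    if herd_size > hi:
        return "excluded", "herd too large"
    if mean_hol_fraction < SEL50_MAX_HOL:
        return "SEL50", "mean HOL below 50%"
    if mean_hol_fraction >= SEL99_MIN_HOL:
        return "SEL99", "mean HOL at least 99%"
    return "excluded", "mid-range HOL"


def build_subset_B(
    herds: pd.DataFrame,
    n_sel99: int = 180,
) -> pd.DataFrame:
    """Label herds and thin the SEL99 group to ``n_sel99`` herds.

    ``herds`` must carry ``herd_id, herd_size, mean_hol_fraction`` plus the
    four herd-level sorting traits.  All SEL50 herds are kept; when more
    than ``n_sel99`` SEL99 herds qualify they are thinned with 4 rounds of
    n_sel99/4.  Returns the herd table with ``sel_label``, ``reason`` and
    ``selected`` columns.
    """
    out = herds.copy()
    labels = [label_herd(int(r.herd_size), float(r.mean_hol_fraction))
              for r in out.itertuples()]
    out["sel_label"] = [lab for lab, _ in labels]
    out["reason"] = [why for _, why in labels]
    out["selected"] = out["sel_label"] == "SEL50"

    sel99 = out[out["sel_label"] == "SEL99"]
    if len(sel99) > n_sel99:
        chosen = stratified_uniform_sample(
            sel99, SUBSET_B_TRAITS, n_sel99 // 4, id_col="herd_id"
        )
        out.loc[out["herd_id"].isin(chosen), "selected"] = True
    else:
        out.loc[out["sel_label"] == "SEL99", "selected"] = True
    return out
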