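"""Closed-form germination and agronomic indices from daily counts.

All index functions take the daily incremental counts ``d`` (seeds newly
germinated on each counting day), the counting days themselves, and the
number of seeds sown ``n_sown``.  ``daily_counts`` derives these from a
:class:`~germtime.data.TimeCourse`; a non-daily schedule can be resampled
onto 24 h steps first.

Conventions:

* G%   — final cumulative germination as a percentage of seeds sown.
* GE   — germination energy, Σ d_j / day_j (counts per day, summed).
* MGT  — mean germination time, Σ d_j·day_j / Σ d_j (days).
* MGR  — mean germination rate, 1/MGT (day⁻¹).
* GI   — germination index with linearly decreasing weights D−j+1
         (the classical 10-day assay uses weights 10, 9, …, 1).
* GRI  — germination rate index, Σ G_j / j with G_j the incremental daily
         germination percentage.
* TGI  — Timson index; by default the mean of the cumulative daily
         germination percentages over the assay (``mode="cumulative"``);
         ``mode="incremental"`` divides the final percentage by the number
         of days instead.
* SVI-I / SVI-II — seedling length (cm) or dry weight (mg) × G%.
* MMC  — (fresh − dry) / dry weight.

Undefined quantities (MGT/MGR with zero germination) raise
:class:`~germtime.data.UndefinedValue` rather than returning 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import (
    ExperimentDataset,
    SeedlingTraits,
    TimeCourse,
    Treatment,
    UndefinedValue,
    ValidationError,
    fraction_at_time,
    pool_replicates,
)

__all__ = [
    "IndexReport",
    "daily_counts",
    "germination_percentage",
    "germination_energy",
    "mean_germination_time",
    "mean_germination_rate",
    "germination_index",
    "germination_rate_index",
    "timson_index",
    "seed_vigor_index_I",
    "seed_vigor_index_II",
    "mean_moisture_content",
    "compute_indices",
    "indices_report",
]

HOURS_PER_DAY = 24.0


def daily_counts(tc: TimeCourse, resample: bool = False):
    """Daily incremental counts (d_1..d_D), counting days, and seeds sown.

    The time-course must be on a daily schedule (observations at 24, 48, …
    hours); with ``resample=True`` any schedule is first evaluated at 24 h
    steps through the step function ``fraction_at_time``.
    """
    times = np.asarray(tc.times)
    days = times / HOURS_PER_DAY
    if not resample:
        if not np.allclose(days, np.round(days)) or not np.allclose(
            days, np.arange(1, len(days) + 1)
        ):
            raise ValidationError(
                "daily schedule required: observations must be at 24, 48, ... h "
                "(pass resample=True to evaluate on 24 h steps)"
            )
        day_idx = np.round(days).astype(int)
        cum = np.asarray(tc.cum_germinated)
    else:
        n_days = int(np.ceil(times[-1] / HOURS_PER_DAY))
        day_idx = np.arange(1, n_days + 1)
        cum = np.array(
            [
                round(fraction_at_time(tc, d * HOURS_PER_DAY) * tc.n_sown)
                for d in day_idx
            ],
            dtype=int,
        )
    d = np.diff(np.concatenate([[0], cum]))
    return d, day_idx, tc.n_sown


def germination_percentage(d, n_sown: int) -> float:
    """G% = 100 · (seeds germinated) / (seeds sown)."""
    if n_sown <= 0:
        raise ValidationError("n_sown must be > 0")
    total = int(np.sum(d))
    if total > n_sown:
        raise ValidationError(f"germinated ({total}) exceeds seeds sown ({n_sown})")
    return 100.0 * total / n_sown


def germination_energy(d, days) -> float:
    """GE = Σ d_j / day_j (incremental count over its counting day)."""
    d = np.asarray(d, dtype=float)
    days = np.asarray(days, dtype=float)
    return float(np.sum(d / days))


def mean_germination_time(d, days) -> float:
    """MGT = Σ d_j·day_j / Σ d_j, in days."""
    d = np.asarray(d, dtype=float)
    total = d.sum()
    if total <= 0:
        raise UndefinedValue("MGT undefined: no seed germinated")
    return float(np.sum(d * np.asarray(days, dtype=float)) / total)


def mean_germination_rate(mgt: float) -> float:
    """MGR = 1 / MGT, in day⁻¹."""
    if mgt <= 0:
        raise UndefinedValue("MGR undefined: MGT must be > 0")
    return 1.0 / mgt


def germination_index(d, n_days: int) -> float:
    """GI = Σ (D − day_j + 1)·d_j — early germination weighted most.

    Generalizes the classical 10-day weights (10·n1 + 9·n2 + … + 1·n10)
    to an assay of D days.
    """
    if n_days < 1:
        raise ValidationError("n_days must be ≥ 1")
    d = np.asarray(d, dtype=float)
    days = np.arange(1, len(d) + 1)
    if len(d) > n_days:
        raise ValidationError("more daily counts than assay days")
    return float(np.sum((n_days - days + 1) * d))


def germination_rate_index(d, days, n_sown: int) -> float:
    """GRI = Σ G_j / j with G_j the incremental daily germination percent."""
    d = np.asarray(d, dtype=float)
    g_pct = 100.0 * d / n_sown
    return float(np.sum(g_pct / np.asarray(days, dtype=float)))


def timson_index(d, n_sown: int, mode: str = "cumulative") -> float:
    """Timson germination index, ΣG ÷ T.

    ``cumulative`` (default): mean of the cumulative daily germination
    percentages over the assay.  ``incremental``: final germination
    percentage divided by the number of days.
    """
    d = np.asarray(d, dtype=float)
    n_days = len(d)
    if n_days == 0:
        raise ValidationError("at least one counting day required")
    cum_pct = 100.0 * np.cumsum(d) / n_sown
    if mode == "cumulative":
        return float(np.sum(cum_pct) / n_days)
    if mode == "incremental":
        return float(cum_pct[-1] / n_days)
    raise ValueError(f"mode must be 'cumulative' or 'incremental', got {mode!r}")


def seed_vigor_index_I(seedling_length_cm: float, g_pct: float) -> float:
    """SVI-I = seedling length (cm) × germination %."""
    if seedling_length_cm < 0:
        raise ValidationError("seedling length must be ≥ 0")
    return seedling_length_cm * g_pct


def seed_vigor_index_II(dry_weight_mg: float, g_pct: float) -> float:
    """SVI-II = seedling dry weight (mg) × germination %."""
    if dry_weight_mg < 0:
        raise ValidationError("dry weight must be ≥ 0")
    return dry_weight_mg * g_pct


def mean_moisture_content(fresh_mg: float, dry_mg: float) -> float:
    """MMC = (fresh − dry) / dry, dimensionless."""
    if dry_mg <= 0:
        raise ValidationError("dry weight must be > 0")
    if fresh_mg < dry_mg:
        raise ValidationError("fresh weight must be ≥ dry weight")
    return (fresh_mg - dry_mg) / dry_mg


@dataclass
class IndexReport:
    """All indices for one treatment (or one dish)."""

    treatment: Treatment
    replicate: str | None
    g_pct: float
    ge: float
    mgt: float | None
    mgr: float | None
    gi: float
    gri: float
    tgi: float
    svi1: float | None = None
    svi2: float | None = None
    mmc: float | None = None


def compute_indices(
    tc: TimeCourse,
    traits: SeedlingTraits | None = None,
    resample: bool = False,
    tgi_mode: str = "cumulative",
    replicate: str | None = None,
) -> IndexReport:
    """All germination indices for one (possibly pooled) time-course."""
    d, days, n_sown = daily_counts(tc, resample=resample)
    g_pct = germination_percentage(d, n_sown)
    try:
        mgt = mean_germination_time(d, days)
        mgr = mean_germination_rate(mgt)
    except UndefinedValue:
        mgt = mgr = None
    svi1 = svi2 = mmc = None
    if traits is not None:
        svi1 = seed_vigor_index_I(traits.seedling_length_cm, g_pct)
        svi2 = seed_vigor_index_II(traits.dry_weight_mg, g_pct)
        mmc = mean_moisture_content(traits.fresh_weight_mg, traits.dry_weight_mg)
    return IndexReport(
        treatment=tc.treatment,
        replicate=replicate,
        g_pct=g_pct,
        ge=germination_energy(d, days),
        mgt=mgt,
        mgr=mgr,
        gi=germination_index(d, int(days[-1])),
        gri=germination_rate_index(d, days, n_sown),
        tgi=timson_index(d, n_sown, mode=tgi_mode),
        svi1=svi1,
        svi2=svi2,
        mmc=mmc,
    )


def indices_report(
    ds: ExperimentDataset,
    per_dish: bool = False,
    resample: bool = False,
    tgi_mode: str = "cumulative",
) -> list[IndexReport]:
    """Index reports for every treatment (pooled by default) or every dish.

    Trait-based indices (SVI-I, SVI-II, MMC) use the mean trait values across
    a treatment's dishes in pooled mode, the matching dish's traits in
    per-dish mode; they are absent when no traits are available.
    """
    trait_map = {(t.treatment, t.replicate): t for t in ds.traits}
    reports = []
    for treatment in ds.treatments:
        dishes = ds.by_treatment(treatment)
        if per_dish:
            for tc in dishes:
                reports.append(
                    compute_indices(
                        tc,
                        traits=trait_map.get((treatment, tc.replicate)),
                        resample=resample,
                        tgi_mode=tgi_mode,
                        replicate=tc.replicate,
                    )
                )
        else:
            pooled = pool_replicates(dishes)
            t_list = [t for (tr, _), t in trait_map.items() if tr == treatment]
            mean_traits = None
            if t_list:
                mean_traits = SeedlingTraits(
                    treatment=treatment,
                    replicate="pooled",
                    seedling_length_cm=float(np.mean([t.seedling_length_cm for t in t_list])),
                    fresh_weight_mg=float(np.mean([t.fresh_weight_mg for t in t_list])),
                    dry_weight_mg=float(np.mean([t.dry_weight_mg for t in t_list])),
                )
            reports.append(
                compute_indices(
                    pooled,
                    traits=mean_traits,
                    resample=resample,
                    tgi_mode=tgi_mode,
                    replicate=None,
                )
            )
    return reports
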