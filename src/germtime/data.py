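"""Core data model for germination time-course experiments.

A germination experiment scores, at scheduled times after imbibition, the
cumulative number of seeds in each dish whose radicle has emerged.  Dishes
(replicates) are nested in treatments, a treatment being one combination of
incubation temperature (°C) and osmotic water potential (MPa, imposed with
an osmoticum such as PEG-6000 and hence never positive).

All times are hours since imbibition.  Germination fractions are always
relative to the number of seeds sown in the dish; no viability correction
is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GermtimeError",
    "SchemaError",
    "ValidationError",
    "FractionNeverReached",
    "UndefinedValue",
    "Treatment",
    "TimeCourse",
    "SeedlingTraits",
    "ExperimentDataset",
    "fraction_at_time",
    "time_to_fraction",
    "pool_replicates",
    "read_dataset",
    "write_dataset",
    "read_traits",
    "write_traits",
    "DATA_COLUMNS",
    "TRAITS_COLUMNS",
]

DATA_COLUMNS = [
    "temperature_C",
    "water_potential_MPa",
    "replicate",
    "time_h",
    "n_sown",
    "germinated_cum",
]
TRAITS_COLUMNS = [
    "temperature_C",
    "water_potential_MPa",
    "replicate",
    "seedling_length_cm",
    "fresh_weight_mg",
    "dry_weight_mg",
]


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class GermtimeError(Exception):
    """Base class for all germtime errors."""


class SchemaError(GermtimeError):
    """An input file does not match the documented column schema."""


class ValidationError(GermtimeError):
    """Data violate an invariant (non-monotone counts, duplicates, ...)."""


class FractionNeverReached(GermtimeError):
    """A requested germination fraction exceeds the final observed fraction.

    Carries ``achieved``, the maximum fraction the dish reached, so callers
    can decide whether to skip the dish or fail.
    """

    def __init__(self, requested: float, achieved: float, context: str = ""):
        self.requested = requested
        self.achieved = achieved
        msg = f"fraction never reached: requested g={requested:g}, final fraction {achieved:g}"
        if context:
            msg += f" ({context})"
        super().__init__(msg)


class UndefinedValue(GermtimeError):
    """A quantity is mathematically undefined for this input (e.g. MGT with
    zero germination); distinct from zero."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class Treatment:
    """One (temperature, water potential) experimental condition.

    Parameters
    ----------
    temperature : float
        Incubation temperature in °C.
    water_potential : float
        Osmotic potential of the medium in MPa; must be ≤ 0 (osmotica can
        only lower the water potential of pure water).
    """

    temperature: float
    water_potential: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.temperature):
            raise ValidationError(f"temperature must be finite, got {self.temperature!r}")
        if not np.isfinite(self.water_potential):
            raise ValidationError(f"water_potential must be finite, got {self.water_potential!r}")
        if self.water_potential > 0:
            raise ValidationError(
                f"water_potential must be ≤ 0 MPa (osmotica only lower Ψ), got {self.water_potential}"
            )
        if not (0.0 <= self.temperature <= 60.0):
            warnings.warn(
                f"temperature {self.temperature} °C is outside the physically "
                "plausible 0–60 °C range for germination assays",
                stacklevel=3,
            )


@dataclass(frozen=True)
class TimeCourse:
    """Cumulative germination counts for one dish over an observation schedule.

    ``times`` are hours since imbibition, strictly increasing and positive;
    ``cum_germinated`` is aligned with ``times``, non-decreasing, and bounded
    by ``n_sown``.
    """

    treatment: Treatment
    replicate: str
    n_sown: int
    times: tuple[float, ...]
    cum_germinated: tuple[int, ...]

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.times)
        cum = tuple(int(c) for c in self.cum_germinated)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "cum_germinated", cum)
        object.__setattr__(self, "replicate", str(self.replicate))
        object.__setattr__(self, "n_sown", int(self.n_sown))
        if self.n_sown < 1:
            raise ValidationError(f"n_sown must be ≥ 1, got {self.n_sown}")
        if len(times) != len(cum) or len(times) < 1:
            raise ValidationError("times and cum_germinated must have equal length ≥ 1")
        arr = np.asarray(times)
        if not np.all(arr > 0):
            raise ValidationError("observation times must be > 0 hours")
        if not np.all(np.diff(arr) > 0):
            raise ValidationError(
                f"observation times must be strictly increasing (dish {self._label()})"
            )
        carr = np.asarray(cum)
        if np.any(np.diff(carr) < 0):
            i = int(np.flatnonzero(np.diff(carr) < 0)[0]) + 1
            raise ValidationError(
                f"cumulative count decreases at t={times[i]:g} h in dish {self._label()}"
            )
        if carr[0] < 0 or carr[-1] > self.n_sown:
            raise ValidationError(
                f"cumulative counts must lie in [0, n_sown={self.n_sown}] (dish {self._label()})"
            )

    def _label(self) -> str:
        return (
            f"T={self.treatment.temperature:g}°C, "
            f"Ψ={self.treatment.water_potential:g} MPa, rep {self.replicate}"
        )

    @property
    def final_fraction(self) -> float:
        return self.cum_germinated[-1] / self.n_sown

    @property
    def fractions(self) -> np.ndarray:
        """Cumulative germination fraction at each observation."""
        return np.asarray(self.cum_germinated, dtype=float) / self.n_sown


@dataclass(frozen=True)
class SeedlingTraits:
    """Per-dish seedling measurements used for vigor and moisture indices."""

    treatment: Treatment
    replicate: str
    seedling_length_cm: float
    fresh_weight_mg: float
    dry_weight_mg: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "replicate", str(self.replicate))
        if self.dry_weight_mg <= 0:
            raise ValidationError(f"dry_weight must be > 0 mg, got {self.dry_weight_mg}")
        if self.fresh_weight_mg < self.dry_weight_mg:
            raise ValidationError(
                "fresh_weight must be ≥ dry_weight (moisture content would be negative): "
                f"FW={self.fresh_weight_mg}, DW={self.dry_weight_mg}"
            )
        if self.seedling_length_cm < 0:
            raise ValidationError("seedling_length must be ≥ 0 cm")


@dataclass
class ExperimentDataset:
    """All time-courses (and optional seedling traits) for one seed lot."""

    timecourses: list[TimeCourse] = field(default_factory=list)
    traits: list[SeedlingTraits] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[tuple[Treatment, str]] = set()
        for tc in self.timecourses:
            key = (tc.treatment, tc.replicate)
            if key in seen:
                raise ValidationError(
                    f"duplicate (treatment, replicate): {tc._label()}"
                )
            seen.add(key)

    @property
    def treatments(self) -> list[Treatment]:
        """Distinct treatments, sorted by temperature then Ψ descending."""
        return sorted(
            {tc.treatment for tc in self.timecourses},
            key=lambda tr: (tr.temperature, -tr.water_potential),
        )

    def by_treatment(self, treatment: Treatment) -> list[TimeCourse]:
        return [tc for tc in self.timecourses if tc.treatment == treatment]

    def temperatures(self) -> list[float]:
        return sorted({tr.temperature for tr in self.treatments})

    def potentials(self) -> list[float]:
        return sorted({tr.water_potential for tr in self.treatments}, reverse=True)


# ---------------------------------------------------------------------------
# Time-course evaluation
# ---------------------------------------------------------------------------

def fraction_at_time(tc: TimeCourse, t: float) -> float:
    """Observed germination fraction at time ``t`` (hours).

    Step-function evaluation: the cumulative count at the latest observation
    not after ``t``, divided by seeds sown; 0 before the first observation.
    """
    if t < 0:
        raise ValueError(f"t must be ≥ 0, got {t}")
    idx = int(np.searchsorted(tc.times, t, side="right")) - 1
    if idx < 0:
        return 0.0
    return tc.cum_germinated[idx] / tc.n_sown


def time_to_fraction(tc: TimeCourse, g: float) -> float:
    """Germination time t(g): earliest time the cumulative fraction reaches ``g``.

    The cumulative fraction is treated as piecewise linear between
    observations (and between (0, 0) and the first observation).  On flat
    segments the earliest time is returned.  If the dish never reaches ``g``,
    :class:`FractionNeverReached` is raised carrying the achieved maximum.
    """
    if not (0.0 < g < 1.0):
        raise ValueError(f"g must be in (0, 1), got {g}")
    times = np.concatenate([[0.0], np.asarray(tc.times)])
    fracs = np.concatenate([[0.0], tc.fractions])
    if fracs[-1] < g:
        raise FractionNeverReached(g, float(fracs[-1]), context=tc._label())
    # first index where fraction >= g; interpolate on the rising segment
    i = int(np.argmax(fracs >= g))
    if fracs[i] == g:
        # earliest-time tie-break: walk back over any flat segment at level g
        while i > 0 and fracs[i - 1] == g:
            i -= 1
        return float(times[i])
    t0, t1 = times[i - 1], times[i]
    f0, f1 = fracs[i - 1], fracs[i]
    return float(t0 + (g - f0) / (f1 - f0) * (t1 - t0))


def pool_replicates(tcs: list[TimeCourse]) -> TimeCourse:
    """Sum counts and seeds sown across replicate dishes of one treatment.

    Pooling weights each dish by its number of seeds sown; all dishes must
    share the treatment and the observation schedule (no resampling).
    """
    if not tcs:
        raise ValueError("no timecourses to pool")
    first = tcs[0]
    if len(tcs) == 1:
        return first
    for tc in tcs[1:]:
        if tc.treatment != first.treatment:
            raise ValidationError("cannot pool dishes from different treatments")
        if tc.times != first.times:
            raise ValidationError(
                f"mismatched observation schedules for {tc._label()}: "
                f"{tc.times} vs {first.times}"
            )
    cum = np.sum([tc.cum_germinated for tc in tcs], axis=0)
    return TimeCourse(
        treatment=first.treatment,
        replicate="+".join(tc.replicate for tc in tcs),
        n_sown=sum(tc.n_sown for tc in tcs),
        times=first.times,
        cum_germinated=tuple(int(c) for c in cum),
    )


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------

def _sniff_sep(path, dialect: str | None) -> str:
    if dialect in ("csv", ","):
        return ","
    if dialect in ("tsv", "\t"):
        return "\t"
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_dataset(path, dialect: str | None = None, time_unit: str = "hours") -> ExperimentDataset:
    """Read a germination time-course table from delimited text.

    Required columns: ``temperature_C, water_potential_MPa, replicate,
    time_h, n_sown, germinated_cum``.  ``time_unit`` may be ``"hours"``
    (default) or ``"days"``; day values are converted to hours (×24) on
    ingest so everything downstream is in hours.
    """
    if time_unit not in ("hours", "days"):
        raise ValueError(f"time_unit must be 'hours' or 'days', got {time_unit!r}")
    df = pd.read_csv(path, sep=_sniff_sep(path, dialect), dtype={"replicate": str})
    missing = [c for c in DATA_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if df[DATA_COLUMNS].isna().any().any():
        bad = [c for c in DATA_COLUMNS if df[c].isna().any()]
        raise SchemaError(f"missing values in required column(s): {', '.join(bad)}")
    if time_unit == "days":
        df = df.assign(time_h=df["time_h"] * 24.0)

    dup = df.duplicated(
        subset=["temperature_C", "water_potential_MPa", "replicate", "time_h"]
    )
    if dup.any():
        row = df[dup].iloc[0]
        raise ValidationError(
            "duplicate observation for "
            f"T={row['temperature_C']:g}°C, Ψ={row['water_potential_MPa']:g} MPa, "
            f"rep {row['replicate']}, t={row['time_h']:g} h"
        )

    timecourses = []
    for (temp, psi, rep), grp in df.groupby(
        ["temperature_C", "water_potential_MPa", "replicate"], sort=True
    ):
        grp = grp.sort_values("time_h")
        n_sown = grp["n_sown"].astype(int).unique()
        if len(n_sown) != 1:
            raise ValidationError(
                f"n_sown varies within dish T={temp:g}°C, Ψ={psi:g} MPa, rep {rep}"
            )
        timecourses.append(
            TimeCourse(
                treatment=Treatment(float(temp), float(psi)),
                replicate=str(rep),
                n_sown=int(n_sown[0]),
                times=tuple(grp["time_h"].astype(float)),
                cum_germinated=tuple(grp["germinated_cum"].astype(int)),
            )
        )
    return ExperimentDataset(timecourses=timecourses)


def write_dataset(ds: ExperimentDataset, path, dialect: str | None = None):
    """Write a dataset as delimited text, re-readable by :func:`read_dataset`.

    Row order is deterministic: temperature ascending, Ψ descending,
    replicate, time.
    """
    rows = []
    order = sorted(
        ds.timecourses,
        key=lambda tc: (
            tc.treatment.temperature,
            -tc.treatment.water_potential,
            tc.replicate,
        ),
    )
    for tc in order:
        for t, c in zip(tc.times, tc.cum_germinated):
            rows.append(
                (
                    tc.treatment.temperature,
                    tc.treatment.water_potential,
                    tc.replicate,
                    t,
                    tc.n_sown,
                    c,
                )
            )
    df = pd.DataFrame(rows, columns=DATA_COLUMNS)
    df.to_csv(path, sep=_sniff_sep(path, dialect), index=False)
    return path


def read_traits(path, dialect: str | None = None) -> list[SeedlingTraits]:
    """Read a per-dish seedling traits table (lengths in cm, weights in mg)."""
    df = pd.read_csv(path, sep=_sniff_sep(path, dialect), dtype={"replicate": str})
    missing = [c for c in TRAITS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    out = []
    for _, row in df.iterrows():
        out.append(
            SeedlingTraits(
                treatment=Treatment(
                    float(row["temperature_C"]), float(row["water_potential_MPa"])
                ),
                replicate=str(row["replicate"]),
                seedling_length_cm=float(row["seedling_length_cm"]),
                fresh_weight_mg=float(row["fresh_weight_mg"]),
                dry_weight_mg=float(row["dry_weight_mg"]),
            )
        )
    return out


def write_traits(traits: list[SeedlingTraits], path, dialect: str | None = None):
    rows = [
        (
            tr.treatment.temperature,
            tr.treatment.water_potential,
            tr.replicate,
            tr.seedling_length_cm,
            tr.fresh_weight_mg,
            tr.dry_weight_mg,
        )
        for tr in sorted(
            traits,
            key=lambda tr: (
                tr.treatment.temperature,
                -tr.treatment.water_potential,
                tr.replicate,
            ),
        )
    ]
    pd.DataFrame(rows, columns=TRAITS_COLUMNS).to_csv(
        path, sep=_sniff_sep(path, dialect), index=False
    )
    return path
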