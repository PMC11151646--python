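"""Inverse side of the threshold models: repeated probit regression.

The estimation scheme, for hydrotime and hydrothermal-time alike, is:

1. extract germination times t(g) for a set of percentiles g from each
   (pooled) treatment time-course by linear interpolation;
2. for a candidate time constant θ, map every observation onto the
   threshold axis, x = Ψ − θ/tg (hydrotime at fixed T) or
   x = Ψ − θHT/((T−Tb)·tg) (hydrothermal);
3. regress probit(g) = Φ⁻¹(g) on x by ordinary least squares — under the
   model the relation is exactly linear with slope 1/σΨb and x-intercept
   Ψb(50);
4. keep the θ that maximizes R² (coarse log-spaced grid, then
   golden-section refinement; ties broken toward smaller θ).

Cardinal temperatures come from the classical two-branch regression of
GR(50) = 1/t(50) on temperature: the sub-optimal branch rises linearly
from Tb with slope 1/θT1, the supra-optimal branch falls to Tc with slope
−1/θT2, and To is the intersection of the two lines.

All fits are deterministic: the same data and the same grid specification
give bit-identical results.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import linregress, norm

from .data import (
    ExperimentDataset,
    FractionNeverReached,
    GermtimeError,
    Treatment,
    ValidationError,
    pool_replicates,
    time_to_fraction,
)
from .models import HydroTimeParams, HydrothermalParams, ThermalTimeParams

__all__ = [
    "ProbitFit",
    "CardinalEstimate",
    "SearchGrid",
    "DEFAULT_PERCENTILES",
    "probit_points",
    "fit_probit_line",
    "fit_hydrotime_at_T",
    "fit_thermaltime",
    "fit_htt",
    "fit_supra_kT",
]

log = logging.getLogger("germtime")

DEFAULT_PERCENTILES: tuple[float, ...] = tuple(np.round(np.arange(0.1, 0.95, 0.1), 2))

_INVPHI = (math.sqrt(5.0) - 1.0) / 2.0


class FitError(GermtimeError):
    """A fit could not be performed (insufficient or degenerate data)."""


@dataclass(frozen=True)
class ProbitFit:
    """One probit regression: probit(g) = slope·x + intercept.

    ``se`` is the residual standard error, ``f_stat`` the regression F
    statistic (= t² for a single predictor), ``p_value`` the two-sided
    significance of the slope.
    """

    slope: float
    intercept: float
    r2: float
    se: float
    f_stat: float
    t_stat: float
    p_value: float
    n_points: int

    @property
    def psi_b50(self) -> float:
        """Median base water potential, −intercept/slope (MPa)."""
        return -self.intercept / self.slope

    @property
    def sigma_psib(self) -> float:
        """Base-water-potential standard deviation, 1/slope (MPa)."""
        return 1.0 / self.slope


@dataclass(frozen=True)
class CardinalEstimate:
    """Cardinal temperatures from the two-branch GR(50)-vs-T regression."""

    Tb: float | None
    To: float | None
    Tc: float | None
    sub_slope: float | None = None
    supra_slope: float | None = None
    r2_sub: float | None = None
    r2_supra: float | None = None
    flags: tuple[str, ...] = field(default=())


@dataclass(frozen=True)
class SearchGrid:
    """Specification of the 1-D θ search: coarse log grid + golden section."""

    lo: float = 1.0
    hi: float = 1e5
    n: int = 64
    rel_tol: float = 1e-4
    log_spaced: bool = True

    def points(self) -> np.ndarray:
        if self.log_spaced:
            return np.geomspace(self.lo, self.hi, self.n)
        return np.linspace(self.lo, self.hi, self.n)


# ---------------------------------------------------------------------------
# Percentile extraction
# ---------------------------------------------------------------------------

def probit_points(
    ds: ExperimentDataset,
    percentiles: tuple[float, ...] = DEFAULT_PERCENTILES,
    pooled: bool = True,
    temperatures: tuple[float, ...] | None = None,
) -> list[tuple[float, float, float, float]]:
    """(g, tg, Ψ, T) observations for probit fitting.

    Germination times come from pooled replicates per treatment (default) or
    from each dish.  Percentiles a treatment never reaches are skipped with a
    logged reason; g = 0 or 1 never enter probit space because requested
    percentiles must be interior.
    """
    for g in percentiles:
        if not (0.0 < g < 1.0):
            raise ValueError(f"percentiles must be in (0, 1), got {g}")
    points = []
    for treatment in ds.treatments:
        if temperatures is not None and treatment.temperature not in temperatures:
            continue
        dishes = ds.by_treatment(treatment)
        units = [pool_replicates(dishes)] if pooled else dishes
        for tc in units:
            if tc.cum_germinated[-1] == 0:
                log.info("skipping dish with zero germination: %s", tc._label())
                continue
            for g in percentiles:
                try:
                    tg = time_to_fraction(tc, g)
                except FractionNeverReached as exc:
                    log.info(
                        "percentile g=%g unreachable in %s (max %.3f)",
                        g, tc._label(), exc.achieved,
                    )
                    continue
                if tg <= 0:
                    continue
                points.append(
                    (g, tg, treatment.water_potential, treatment.temperature)
                )
    if len(points) < 3:
        raise FitError(
            f"insufficient data: only {len(points)} usable (g, tg) observations"
        )
    return points


# ---------------------------------------------------------------------------
# Probit OLS
# ---------------------------------------------------------------------------

def fit_probit_line(points: list[tuple[float, float]]) -> ProbitFit:
    """Ordinary least squares of Φ⁻¹(g) on x for (g, x) pairs."""
    if len(points) < 3:
        raise FitError(f"at least 3 points required, got {len(points)}")
    g = np.array([p[0] for p in points], dtype=float)
    x = np.array([p[1] for p in points], dtype=float)
    if np.ptp(x) == 0:
        raise FitError("no variation in predictor")
    y = norm.ppf(g)
    res = linregress(x, y)
    n = len(points)
    resid = y - (res.slope * x + res.intercept)
    ssr = float(np.sum(resid**2))
    se = math.sqrt(ssr / (n - 2)) if n > 2 else 0.0
    if res.stderr == 0.0:
        t_stat, f_stat, p = math.inf, math.inf, 0.0
    else:
        t_stat = res.slope / res.stderr
        f_stat = t_stat**2
        p = float(res.pvalue)
    return ProbitFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        se=se,
        f_stat=float(f_stat),
        t_stat=float(t_stat),
        p_value=p,
        n_points=n,
    )


def _r2_or_none(pts: list[tuple[float, float]]) -> float:
    """Objective for the θ search: R² of the probit line, −inf if degenerate."""
    try:
        return fit_probit_line(pts).r2
    except FitError:
        return -math.inf


def _golden_max(f, a: float, b: float, rel_tol: float) -> tuple[float, float]:
    """Deterministic golden-section maximization of f on [a, b]."""
    c = b - _INVPHI * (b - a)
    d = a + _INVPHI * (b - a)
    fc, fd = f(c), f(d)
    while (b - a) > rel_tol * max(abs(a), abs(b), 1.0):
        if fc >= fd:  # tie toward smaller θ
            b, d, fd = d, c, fc
            c = b - _INVPHI * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + _INVPHI * (b - a)
            fd = f(d)
    return (c, fc) if fc >= fd else (d, fd)


def _search_theta(objective, grid: SearchGrid) -> tuple[float, float]:
    """Coarse grid then golden refinement; returns (θ*, objective(θ*)).

    The refined optimum can only improve on the best grid candidate (the
    bracket around it is refined and the better of the two kept).
    """
    thetas = grid.points()
    vals = np.array([objective(t) for t in thetas])
    if not np.any(np.isfinite(vals)):
        raise FitError("all candidate fits degenerate across the θ grid")
    i = int(np.argmax(vals))  # first max → smaller θ on ties
    lo = thetas[max(i - 1, 0)]
    hi = thetas[min(i + 1, len(thetas) - 1)]
    best_theta, best_val = float(thetas[i]), float(vals[i])
    if hi > lo:
        t_ref, v_ref = _golden_max(objective, lo, hi, grid.rel_tol)
        if v_ref > best_val:
            best_theta, best_val = float(t_ref), float(v_ref)
    return best_theta, best_val


# ---------------------------------------------------------------------------
# Hydrotime fit at one temperature (Table-2 style)
# ---------------------------------------------------------------------------

def fit_hydrotime_at_T(
    ds: ExperimentDataset,
    T: float,
    percentiles: tuple[float, ...] = DEFAULT_PERCENTILES,
    theta_grid: SearchGrid = SearchGrid(),
    pooled: bool = True,
) -> tuple[HydroTimeParams, ProbitFit]:
    """Repeated probit estimation of (θH, Ψb(50), σΨb) at one temperature.

    For each candidate θH the observations are mapped to x = Ψ − θH/tg and
    probit(g) is regressed on x; the θH maximizing R² wins.
    """
    pts = probit_points(ds, percentiles, pooled=pooled, temperatures=(T,))
    psis = {p[2] for p in pts}
    if len(psis) < 2:
        raise FitError(
            f"insufficient germination for HT fit at T={T} °C: "
            f"usable percentiles at only {len(psis)} Ψ level(s)"
        )

    def objective(theta: float) -> float:
        return _r2_or_none([(g, psi - theta / tg) for g, tg, psi, _ in pts])

    theta, _ = _search_theta(objective, theta_grid)
    fit = fit_probit_line([(g, psi - theta / tg) for g, tg, psi, _ in pts])
    params = HydroTimeParams(
        theta_H=theta, psi_b50=fit.psi_b50, sigma_psib=fit.sigma_psib
    )
    return params, fit


# ---------------------------------------------------------------------------
# Thermal time / cardinal temperatures
# ---------------------------------------------------------------------------

def _gr50_by_temperature(
    ds: ExperimentDataset, psi: float, percentile: float = 0.5
) -> dict[float, float]:
    """GR(percentile) = 1/t(percentile) per temperature at one Ψ, pooled."""
    out: dict[float, float] = {}
    for treatment in ds.treatments:
        if treatment.water_potential != psi:
            continue
        pooled = pool_replicates(ds.by_treatment(treatment))
        try:
            tg = time_to_fraction(pooled, percentile)
        except FractionNeverReached as exc:
            log.info(
                "GR%d unavailable at T=%g °C, Ψ=%g MPa (max fraction %.3f)",
                round(percentile * 100), treatment.temperature, psi, exc.achieved,
            )
            continue
        out[treatment.temperature] = 1.0 / tg
    return out


def fit_thermaltime(
    ds: ExperimentDataset,
    psi: float = 0.0,
    to_hint: float | None = None,
    percentile: float = 0.5,
) -> tuple[ThermalTimeParams, CardinalEstimate]:
    """Cardinal temperatures and thermal-time constants from GR(50) vs T.

    Temperatures at or below the GR-maximizing temperature (or ``to_hint``)
    form the sub-optimal branch, those at or above it the supra-optimal
    branch; the peak temperature belongs to both.  Tb and Tc are the
    x-intercepts of the branch regressions, To their intersection,
    θT1 = 1/sub_slope and θT2 = −1/supra_slope.
    """
    gr = _gr50_by_temperature(ds, psi, percentile)
    if len(gr) < 3:
        raise FitError(
            f"≥3 temperatures with GR{round(percentile*100)} required at Ψ={psi} MPa, "
            f"got {len(gr)}"
        )
    temps = np.array(sorted(gr))
    rates = np.array([gr[t] for t in temps])
    if np.ptp(rates) == 0:
        raise FitError("no thermal response: GR is constant across temperatures")
    t_peak = to_hint if to_hint is not None else float(temps[int(np.argmax(rates))])

    flags: list[str] = []

    def branch(mask) -> tuple[float, float, float] | None:
        if int(mask.sum()) < 2:
            return None
        res = linregress(temps[mask], rates[mask])
        return float(res.slope), float(res.intercept), float(res.rvalue**2)

    sub = branch(temps <= t_peak)
    supra = branch(temps >= t_peak)

    Tb = To = Tc = None
    sub_slope = supra_slope = r2_sub = r2_supra = None
    theta_T1 = theta_T2 = None
    if sub is not None and sub[0] > 0:
        sub_slope, sub_icpt, r2_sub = sub
        Tb = -sub_icpt / sub_slope
        theta_T1 = 1.0 / sub_slope
    else:
        flags.append("sub-optimal branch absent or non-increasing")
    if supra is not None and supra[0] < 0:
        supra_slope, supra_icpt, r2_supra = supra
        Tc = -supra_icpt / supra_slope
        theta_T2 = -1.0 / supra_slope
    else:
        flags.append("supra-optimal branch absent or non-decreasing")
    if sub_slope is not None and supra_slope is not None:
        To = (supra_icpt - sub_icpt) / (sub_slope - supra_slope)
    elif Tb is not None or Tc is not None:
        To = t_peak
        flags.append("To from GR-maximizing temperature (one branch only)")

    if Tb is None and Tc is None:
        raise FitError("no thermal response: neither branch could be fit")

    params = ThermalTimeParams(
        Tb=Tb if Tb is not None else -math.inf,
        Tc=Tc if Tc is not None else math.inf,
        theta_T1=theta_T1,
        theta_T2=theta_T2,
    )
    card = CardinalEstimate(
        Tb=Tb, To=To, Tc=Tc,
        sub_slope=sub_slope, supra_slope=supra_slope,
        r2_sub=r2_sub, r2_supra=r2_supra,
        flags=tuple(flags),
    )
    return params, card


# ---------------------------------------------------------------------------
# Hydrothermal-time fit
# ---------------------------------------------------------------------------

def _htt_x(points, theta: float, Tb: float):
    return [
        (g, psi - theta / ((T - Tb) * tg))
        for g, tg, psi, T in points
        if T > Tb
    ]


def fit_htt(
    ds: ExperimentDataset,
    Tb: float | str = "estimate",
    percentiles: tuple[float, ...] = DEFAULT_PERCENTILES,
    theta_grid: SearchGrid = SearchGrid(),
    To: float | None = None,
    pooled: bool = True,
) -> tuple[HydrothermalParams, ProbitFit]:
    """Repeated probit estimation of the hydrothermal-time parameters.

    Only sub-optimal treatments (T ≤ To) enter the fit; To defaults to the
    GR50-maximizing temperature at the least-negative Ψ in the data (all
    temperatures are used if GR50 is unavailable there).  With ``Tb`` fixed
    the search is 1-D in θHT; with ``Tb="estimate"`` a coarse grid of Tb
    candidates below the coldest treatment is scanned, each with the 1-D
    θHT search, and the best (θHT, Tb) pair refined.
    """
    if To is None:
        psi_top = max(tr.water_potential for tr in ds.treatments)
        gr = _gr50_by_temperature(ds, psi_top)
        if gr:
            To = max(gr, key=lambda t: gr[t])
            log.info("To defaulted to GR50-maximizing temperature %g °C", To)
    temps_all = sorted({tr.temperature for tr in ds.treatments})
    sub_temps = tuple(t for t in temps_all if To is None or t <= To)
    pts = probit_points(ds, percentiles, pooled=pooled, temperatures=sub_temps)
    if len({p[2] for p in pts}) < 2 or len({p[3] for p in pts}) < 2:
        raise FitError(
            "HTT fit needs ≥2 water-potential levels and ≥2 sub-optimal "
            "temperatures with usable percentiles"
        )

    def theta_search_at(tb: float) -> tuple[float, float]:
        def objective(theta: float) -> float:
            return _r2_or_none(_htt_x(pts, theta, tb))

        return _search_theta(objective, theta_grid)

    if Tb == "estimate":
        t_min = min(p[3] for p in pts)
        tb_grid = np.linspace(t_min - 30.0, t_min - 0.5, 30)
        results = [(tb, *theta_search_at(tb)) for tb in tb_grid]
        finite = [r for r in results if math.isfinite(r[2])]
        if not finite:
            raise FitError("HTT fit failed: all candidate (θHT, Tb) fits degenerate")
        best = max(finite, key=lambda r: r[2])
        i = results.index(best)
        lo = results[max(i - 1, 0)][0]
        hi = results[min(i + 1, len(results) - 1)][0]
        tb_best, _ = _golden_max(
            lambda tb: theta_search_at(tb)[1], lo, hi, theta_grid.rel_tol
        )
        if theta_search_at(tb_best)[1] < best[2]:
            tb_best = best[0]
    elif isinstance(Tb, (int, float)):
        tb_best = float(Tb)
    else:
        raise ValueError(f"Tb must be a number or 'estimate', got {Tb!r}")

    theta, best_r2 = theta_search_at(tb_best)
    if not math.isfinite(best_r2):
        raise FitError(
            f"HTT fit failed at Tb={tb_best:g}: probit regression degenerate "
            f"({len(pts)} points)"
        )
    fit = fit_probit_line(_htt_x(pts, theta, tb_best))
    params = HydrothermalParams(
        theta_HT=theta,
        Tb=tb_best,
        psi_b50=fit.psi_b50,
        sigma_psib=fit.sigma_psib,
        To=To if (To is not None and To > tb_best) else None,
    )
    return params, fit


def fit_supra_kT(
    ds: ExperimentDataset,
    params: HydrothermalParams,
    percentiles: tuple[float, ...] = DEFAULT_PERCENTILES,
    pooled: bool = True,
) -> float | None:
    """Supra-optimal Ψb(50) shift slope kT (MPa/°C).

    For each temperature above To, Ψb(50)(T) is back-solved from every
    usable (g, tg, Ψ) observation via
    Ψb(50)(T) = Ψ − θHT/((To−Tb)·tg) − σΨb·Φ⁻¹(g), averaged per
    temperature, and regressed on T − To; the OLS slope is kT.  Returns
    None (logged) with fewer than 2 supra-optimal temperatures.
    """
    if params.To is None:
        raise ValueError("params.To must be set for the supra-optimal fit")
    temps_all = sorted({tr.temperature for tr in ds.treatments})
    supra = tuple(t for t in temps_all if t > params.To)
    if len(supra) < 2:
        log.info("kT absent: only %d supra-optimal temperature(s)", len(supra))
        return None
    try:
        pts = probit_points(ds, percentiles, pooled=pooled, temperatures=supra)
    except FitError:
        log.info("kT absent: no usable supra-optimal observations")
        return None
    span = params.To - params.Tb
    per_T: dict[float, list[float]] = {}
    for g, tg, psi, T in pts:
        psib = psi - params.theta_HT / (span * tg) - params.sigma_psib * norm.ppf(g)
        per_T.setdefault(T, []).append(psib)
    if len(per_T) < 2:
        log.info("kT absent: <2 supra-optimal temperatures with usable points")
        return None
    temps = np.array(sorted(per_T))
    psib_mean = np.array([np.mean(per_T[t]) for t in temps])
    res = linregress(temps - params.To, psib_mean)
    return float(res.slope)
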