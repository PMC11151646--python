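"""Forward side of the thermal-time, hydrotime and hydrothermal-time models.

Population-threshold germination models assume each seed i carries a base
water potential ψ_b,i below which it cannot germinate, distributed
Normal(Ψb(50), σΨb) across the lot, while the time constants (θ) are shared.
Seed i completes germination when its accumulated thermal / hydro /
hydrothermal time reaches the lot constant:

    sub-optimal thermal time    θT1 = (T − Tb)·t
    supra-optimal thermal time  θT2 = (Tc − T)·t
    hydrotime                   θH  = (Ψ − ψb)·t          (fixed T)
    hydrothermal time           θHT = (Ψ − ψb)(T − Tb)·t  (Tb < T ≤ To)

which yields the probit-linear germination surface

    probit(g) = [Ψ − θHT / ((T − Tb)·t) − Ψb(50)] / σΨb

with probit = Φ⁻¹, the standard normal quantile (no +5 offset).  Above the
optimum temperature To the standard extension shifts the median threshold
upward, Ψb(50)(T) = Ψb(50) + kT·(T − To), and accumulates thermal time at
the optimum, (To − Tb); it is applied only when both To and kT are set.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import json

from scipy.stats import norm

from .data import GermtimeError, ValidationError

__all__ = [
    "ThermalTimeParams",
    "HydroTimeParams",
    "HydrothermalParams",
    "tt_constant_sub",
    "tt_constant_supra",
    "ht_constant",
    "htt_constant",
    "gr_tt",
    "gr_ht",
    "predicted_fraction",
    "predicted_time",
]


class ThresholdError(GermtimeError):
    """A driving variable is at or below its threshold (T ≤ Tb, Ψ ≤ ψb, ...)."""


# ---------------------------------------------------------------------------
# Parameter sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThermalTimeParams:
    """Thermal-time constants and cardinal temperatures (°C, °C·h)."""

    Tb: float
    Tc: float
    theta_T1: float | None = None
    theta_T2: float | None = None

    def __post_init__(self) -> None:
        if self.Tb >= self.Tc:
            raise ValidationError(f"Tb ({self.Tb}) must be < Tc ({self.Tc})")
        for name in ("theta_T1", "theta_T2"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValidationError(f"{name} must be > 0, got {v}")


@dataclass(frozen=True)
class HydroTimeParams:
    """Hydrotime constant (MPa·h) and base-water-potential distribution (MPa)."""

    theta_H: float
    psi_b50: float
    sigma_psib: float

    def __post_init__(self) -> None:
        if self.theta_H <= 0:
            raise ValidationError(f"theta_H must be > 0, got {self.theta_H}")
        if self.sigma_psib <= 0:
            raise ValidationError(f"sigma_psib must be > 0, got {self.sigma_psib}")


@dataclass(frozen=True)
class HydrothermalParams:
    """Hydrothermal-time parameter set.

    ``theta_HT`` in MPa·°C·h, temperatures in °C, potentials in MPa.  ``To``,
    ``Tc`` and ``kT`` (MPa/°C, the supra-optimal upward shift of Ψb(50)) are
    optional; the supra-optimal branch is active only when To and kT are set.
    """

    theta_HT: float
    Tb: float
    psi_b50: float
    sigma_psib: float
    To: float | None = None
    Tc: float | None = None
    kT: float | None = None

    def __post_init__(self) -> None:
        if self.theta_HT <= 0:
            raise ValidationError(f"theta_HT must be > 0, got {self.theta_HT}")
        if self.sigma_psib <= 0:
            raise ValidationError(f"sigma_psib must be > 0, got {self.sigma_psib}")
        if self.To is not None and self.To <= self.Tb:
            raise ValidationError(f"To ({self.To}) must be > Tb ({self.Tb})")
        if self.Tc is not None and self.To is not None and self.Tc <= self.To:
            raise ValidationError(f"Tc ({self.Tc}) must be > To ({self.To})")

    # JSON round-trip with unit-annotated keys
    _JSON_KEYS = {
        "theta_HT": "theta_HT_MPa_C_h",
        "Tb": "Tb_C",
        "psi_b50": "psi_b50_MPa",
        "sigma_psib": "sigma_psib_MPa",
        "To": "To_C",
        "Tc": "Tc_C",
        "kT": "kT_MPa_per_C",
    }

    def to_json_dict(self) -> dict:
        d = asdict(self)
        return {self._JSON_KEYS[k]: v for k, v in d.items() if v is not None}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "HydrothermalParams":
        with open(path) as fh:
            raw = json.load(fh)
        rev = {v: k for k, v in cls._JSON_KEYS.items()}
        known = {rev[k]: v for k, v in raw.items() if k in rev}
        return cls(**known)


# ---------------------------------------------------------------------------
# Time constants and germination rates
# ---------------------------------------------------------------------------

def tt_constant_sub(T: float, Tb: float, tg: float) -> float:
    """Sub-optimal thermal time θT1 = (T − Tb)·tg, in °C·h."""
    if tg <= 0:
        raise ValueError(f"tg must be > 0, got {tg}")
    if T <= Tb:
        raise ThresholdError(f"T={T} °C is at or below base temperature Tb={Tb} °C")
    return (T - Tb) * tg


def tt_constant_supra(T: float, Tc: float, tg: float) -> float:
    """Supra-optimal thermal time θT2 = (Tc − T)·tg, in °C·h."""
    if tg <= 0:
        raise ValueError(f"tg must be > 0, got {tg}")
    if T >= Tc:
        raise ThresholdError(f"T={T} °C is at or above ceiling temperature Tc={Tc} °C")
    return (Tc - T) * tg


def ht_constant(psi: float, psi_b: float, tg: float) -> float:
    """Hydrotime θH = (Ψ − ψb)·tg, in MPa·h."""
    if tg <= 0:
        raise ValueError(f"tg must be > 0, got {tg}")
    if psi <= psi_b:
        raise ThresholdError(f"Ψ={psi} MPa is at or below base water potential ψb={psi_b} MPa")
    return (psi - psi_b) * tg


def htt_constant(psi: float, psi_b: float, T: float, Tb: float, tg: float) -> float:
    """Hydrothermal time θHT = (Ψ − ψb)(T − Tb)·tg, in MPa·°C·h."""
    if tg <= 0:
        raise ValueError(f"tg must be > 0, got {tg}")
    if psi <= psi_b:
        raise ThresholdError(f"Ψ={psi} MPa is at or below base water potential ψb={psi_b} MPa")
    if T <= Tb:
        raise ThresholdError(f"T={T} °C is at or below base temperature Tb={Tb} °C")
    return (psi - psi_b) * (T - Tb) * tg


def gr_tt(theta_T1: float, T: float, Tb: float) -> float:
    """Thermal-time germination rate GR = (T − Tb)/θT1, in h⁻¹ (0 below Tb)."""
    if theta_T1 <= 0:
        raise ValueError(f"theta_T1 must be > 0, got {theta_T1}")
    if T <= Tb:
        return 0.0
    return (T - Tb) / theta_T1


def gr_ht(theta_H: float, psi: float, psi_b: float) -> float:
    """Hydrotime germination rate GR = (Ψ − ψb)/θH, in h⁻¹ (0 below ψb)."""
    if theta_H <= 0:
        raise ValueError(f"theta_H must be > 0, got {theta_H}")
    if psi <= psi_b:
        return 0.0
    return (psi - psi_b) / theta_H


# ---------------------------------------------------------------------------
# Probit germination surface
# ---------------------------------------------------------------------------

def _effective(params: HydrothermalParams, T: float) -> tuple[float, float]:
    """(thermal span, median base potential) at temperature T.

    Above To (when the supra extension is active) thermal time accumulates
    at the optimum span To−Tb and Ψb(50) rises linearly with slope kT.
    """
    supra = params.To is not None and params.kT is not None and T > params.To
    if supra:
        return params.To - params.Tb, params.psi_b50 + params.kT * (T - params.To)
    return T - params.Tb, params.psi_b50


def predicted_fraction(params: HydrothermalParams, psi: float, T: float, t: float) -> float:
    """Germinated fraction g at time t under (Ψ, T).

    g = Φ( (Ψ − θHT/((T−Tb)·t) − Ψb(50)) / σΨb ); 0 at or below Tb, and 0
    at or above Tc when a ceiling is set.
    """
    if t <= 0:
        if t < 0:
            raise ValueError(f"t must be ≥ 0, got {t}")
        return 0.0
    if T <= params.Tb:
        return 0.0
    if params.Tc is not None and T >= params.Tc:
        return 0.0
    span, psi_b50 = _effective(params, T)
    z = (psi - params.theta_HT / (span * t) - psi_b50) / params.sigma_psib
    return float(norm.cdf(z))


def predicted_time(params: HydrothermalParams, psi: float, T: float, g: float) -> float:
    """Time t(g) for fraction g to germinate — the inverse of
    :func:`predicted_fraction` in t.

    t(g) = θHT / ((T−Tb)·(Ψ − Ψb(50) − σΨb·Φ⁻¹(g))).  Fractions beyond the
    asymptote Φ((Ψ−Ψb(50))/σΨb) never germinate at this Ψ and raise
    :class:`ThresholdError`.
    """
    if not (0.0 < g < 1.0):
        raise ValueError(f"g must be in (0, 1), got {g}")
    if T <= params.Tb:
        raise ThresholdError(f"T={T} °C is at or below base temperature Tb={params.Tb} °C")
    if params.Tc is not None and T >= params.Tc:
        raise ThresholdError(f"T={T} °C is at or above ceiling temperature Tc={params.Tc} °C")
    span, psi_b50 = _effective(params, T)
    denom = span * (psi - psi_b50 - params.sigma_psib * norm.ppf(g))
    if denom <= 0:
        raise ThresholdError(
            f"unreachable fraction: g={g:g} exceeds the asymptotic germinated "
            f"fraction at Ψ={psi} MPa, T={T} °C"
        )
    return params.theta_HT / denom
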