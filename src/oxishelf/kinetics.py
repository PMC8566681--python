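"""Zero-order log-linear oxidation kinetics and shelf-life extrapolation.

Across elevated temperatures the induction period follows the empirical
OSI-convention law (called "Arrhenius" in the oxidative-stability
literature, although temperature enters in plain °C, not reciprocal
kelvin):

    log10 IP = Log IP_0 − k_0 · T

Fitting this line to IPs measured at three or more accelerated
temperatures (typically 70/90/100 °C) and evaluating it at ambient
temperature yields the predicted shelf-life.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .detect import DetectionConfig, IPMeasurement, two_tangent_ip
from .errors import InsufficientDataError, ExtrapolationError, OxishelfError
from .simulate import KineticLaw, OxidationCurve


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


@dataclass(frozen=True)
class KineticFit:
    """Fitted temperature law: intercept Log IP_0 (log10 h), rate constant
    k_0 (per °C) and the coefficient of determination of the line.

    Parameters carry 4 decimals — the precision at which such fits are
    reported — so downstream extrapolations match published tables.
    """

    log_ip0: float
    k0: float
    r_squared: float
    n_points: int
    temperatures_used: tuple[float, ...]

    def as_law(self) -> KineticLaw:
        return KineticLaw(log_ip0=self.log_ip0, k0=self.k0)


@dataclass(frozen=True)
class ShelfLifeEstimate:
    """Extrapolated IP at an ambient temperature, in hours and whole days."""

    temperature: float
    ip_hours: float
    days: int


@dataclass(frozen=True)
class PipelineResult:
    """Full provenance of a simulate/measure -> detect -> fit -> extrapolate run."""

    measurements: tuple[IPMeasurement, ...]
    fit: KineticFit
    estimate: ShelfLifeEstimate


def fit_kinetics(measurements: list[IPMeasurement]) -> KineticFit:
    """OLS of log10(IP) on temperature (°C).

    Censored measurements (no onset before the instrument limit) are
    excluded with a warning, mirroring how practitioners substitute another
    temperature when a run exceeds the limit.  Requires at least 3 usable
    measurements at distinct temperatures, all with IP > 0.

    Log IP_0 is the intercept, k_0 the negated slope, and R² the squared
    Pearson correlation of log10 IP with temperature (identical to the
    regression R² for a simple OLS line); all reported to 4 decimals.
    """
    usable = [m for m in measurements if not m.censored]
    dropped = len(measurements) - len(usable)
    if dropped:
        warnings.warn(
            f"excluded {dropped} censored measurement(s) from kinetic fit",
            stacklevel=2,
        )
    for m in usable:
        if m.ip <= 0:
            raise OxishelfError(f"non-positive IP {m.ip} at {m.temperature} °C")
    temps = np.array([m.temperature for m in usable], dtype=float)
    if len(set(temps.tolist())) < 3:
        raise InsufficientDataError(
            f"kinetic fit needs >= 3 distinct temperatures, got {len(set(temps.tolist()))}"
        )
    log_ip = np.log10([m.ip for m in usable])
    res = stats.linregress(temps, log_ip)
    return KineticFit(
        log_ip0=round(float(res.intercept), 4),
        k0=round(-float(res.slope), 4),
        r_squared=round(float(res.rvalue) ** 2, 4),
        n_points=len(usable),
        temperatures_used=tuple(sorted(temps.tolist())),
    )


def extrapolate_shelf_life(
    fit: KineticFit | KineticLaw, temperature: float
) -> ShelfLifeEstimate:
    """Evaluate the fitted law at an ambient temperature.

    ip_hours = 10**(Log IP_0 − k_0·T).  The day count rounds the
    extrapolated IP to the nearest whole hour before dividing by 24 and
    rounding again (halves away from zero); this whole-hour pre-rounding is
    the convention that reproduces published shelf-life tables.

    Only downward extrapolation is allowed: ``temperature`` must lie below
    the lowest temperature used in the fit.
    """
    temps = getattr(fit, "temperatures_used", ())
    if temps and temperature >= min(temps):
        raise ExtrapolationError(
            f"ambient temperature {temperature} °C is not below the fitted "
            f"range (min {min(temps)} °C); only downward extrapolation is valid"
        )
    ip_hours = 10.0 ** (fit.log_ip0 - fit.k0 * temperature)
    days = round_half_away(round_half_away(ip_hours) / 24.0)
    return ShelfLifeEstimate(temperature=temperature, ip_hours=ip_hours, days=days)


def pipeline_shelf_life(
    curves: list[OxidationCurve],
    config: DetectionConfig | None = None,
    ambient: float = 25.0,
) -> PipelineResult:
    """Chain detection -> kinetic fit -> extrapolation over a curve set.

    Stage failures propagate as the underlying typed errors, wrapped with
    the stage and temperature for context.
    """
    measurements = []
    for curve in curves:
        try:
            measurements.append(two_tangent_ip(curve, config))
        except OxishelfError as exc:
            raise type(exc)(
                f"detection stage ({curve.temperature:g} °C): {exc}"
            ) from exc
    try:
        fit = fit_kinetics(measurements)
    except OxishelfError as exc:
        raise type(exc)(f"kinetics stage: {exc}") from exc
    try:
        estimate = extrapolate_shelf_life(fit, ambient)
    except OxishelfError as exc:
        raise type(exc)(f"extrapolation stage: {exc}") from exc
    return PipelineResult(
        measurements=tuple(measurements), fit=fit, estimate=estimate
    )
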