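"""Synthetic oxygen-pressure curves with known induction periods.

Accelerated-oxidation instruments seal an oil sample in a heated chamber
under elevated oxygen pressure and record the headspace pressure over time.
The pressure first decays slowly (baseline oxygen uptake), then drops
rapidly once autoxidation propagates.  This module generates such curves
with a closed-form ground-truth induction period (IP), so the two-tangent
detector and the kinetics stages can be validated without instrument data.

Model (noiseless):

    P(t) = p0 − m1·t − d / (1 + exp(−s·(t − t_c)))

a baseline line of slope −m1 minus a logistic consumption term of depth
``d``, steepness ``s`` and centre ``t_c``.  The two-tangent IP of this
curve — the intersection of the baseline line with the tangent at the
steepest-descent point — is exactly

    IP = t_c − 2 / s

independent of ``d`` and ``m1`` (the logistic tangent at its inflection
has slope −m1 − d·s/4 and passes d/2 below the baseline).  Homoscedastic
Gaussian noise is added on top, seeded for bit-for-bit reproducibility.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

#: Operating temperature range of the emulated instrument, °C.
TEMPERATURE_RANGE = (50.0, 110.0)


@dataclass(frozen=True)
class CurveParams:
    """Parameters of one simulated oxidation run.

    p0        initial oxygen pressure, kPa (instruments run at 600–800 kPa)
    m1        baseline consumption slope, kPa/h
    d         total pressure drop of the accelerated phase, kPa
    s         logistic steepness, 1/h
    t_c       logistic centre time, h
    duration  record length, h
    dt        sampling interval, h
    noise_sd  additive Gaussian noise, kPa
    seed      RNG seed (identical seeds give identical curves)
    """

    p0: float = 800.0
    m1: float = 0.5
    d: float = 200.0
    s: float = 1.0
    t_c: float = 36.6
    duration: float | None = None
    dt: float = 0.05
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p0 <= 0 or self.d <= 0 or self.s <= 0 or self.dt <= 0:
            raise ParameterError("p0, d, s and dt must all be positive")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")
        if self.duration is None:
            object.__setattr__(self, "duration", 1.6 * self.t_c)
        if not 0 < self.t_c < self.duration:
            raise ParameterError(
                f"t_c={self.t_c} must lie inside (0, duration={self.duration})"
            )
        if self.true_ip <= 0:
            raise ParameterError(
                "induction period not representable: t_c - 2/s <= 0"
            )

    @property
    def true_ip(self) -> float:
        """Closed-form two-tangent IP of the noiseless curve, h."""
        return self.t_c - 2.0 / self.s


@dataclass(frozen=True)
class KineticLaw:
    """Log-linear temperature law  log10 IP = log_ip0 − k0·T  (T in °C).

    k0 > 0 gives the physically expected behaviour (IP shrinks with
    temperature); k0 = 0 is accepted for degenerate test laws.
    """

    log_ip0: float
    k0: float

    def ip_at(self, temperature: float) -> float:
        """Induction period in hours at ``temperature`` °C."""
        return 10.0 ** (self.log_ip0 - self.k0 * temperature)


@dataclass(frozen=True)
class OxidationCurve:
    """A recorded (or simulated) oxygen-pressure time series.

    ``true_ip`` is the simulator's ground truth and is None for curves
    read from real measurements.
    """

    times: np.ndarray
    pressures: np.ndarray
    temperature: float
    true_ip: float | None = None
    params: CurveParams | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        pressures = np.asarray(self.pressures, dtype=float)
        if times.shape != pressures.shape or times.ndim != 1:
            raise ParameterError("times and pressures must be equal-length 1-D arrays")
        if times.size < 2:
            raise ParameterError("curve needs at least 2 samples")
        if np.any(np.diff(times) <= 0):
            raise ParameterError("times must be strictly increasing")
        lo, hi = TEMPERATURE_RANGE
        if not lo <= self.temperature <= hi:
            raise ParameterError(
                f"temperature {self.temperature} °C outside instrument range {lo}-{hi}"
            )
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "pressures", pressures)

    @property
    def duration(self) -> float:
        return float(self.times[-1])

    @property
    def n_samples(self) -> int:
        return int(self.times.size)


def noiseless_pressure(params: CurveParams, times: np.ndarray) -> np.ndarray:
    """Evaluate the generating model without noise."""
    t = np.asarray(times, dtype=float)
    logistic = params.d / (1.0 + np.exp(-params.s * (t - params.t_c)))
    return params.p0 - params.m1 * t - logistic


def simulate_curve(params: CurveParams, temperature: float) -> OxidationCurve:
    """Simulate one oxidation run at ``temperature`` °C.

    The sampling grid is ``0, dt, 2·dt, … <= duration``; noise is drawn
    from a generator seeded with ``params.seed`` so identical parameters
    reproduce identical curves bit-for-bit.
    """
    lo, hi = TEMPERATURE_RANGE
    if not lo <= temperature <= hi:
        raise ParameterError(
            f"temperature {temperature} °C outside instrument range {lo}-{hi}"
        )
    n = int(np.floor(params.duration / params.dt)) + 1
    times = np.arange(n) * params.dt
    pressures = noiseless_pressure(params, times)
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        pressures = pressures + rng.normal(0.0, params.noise_sd, size=n)
    return OxidationCurve(
        times=times,
        pressures=pressures,
        temperature=temperature,
        true_ip=params.true_ip,
        params=params,
    )


def simulate_temperature_series(
    law: KineticLaw,
    temperatures: list[float],
    template: CurveParams | None = None,
) -> list[OxidationCurve]:
    """Simulate one curve per temperature so that the ground-truth IPs follow
    ``law`` exactly.

    For each temperature T the logistic centre is placed at
    ``t_c = 10**(log_ip0 − k0·T) + 2/s`` (hence ``true_ip == law.ip_at(T)``)
    and the record is extended to at least 1.5 × t_c.  Per-curve seeds are
    ``template.seed + index`` so replicate series stay reproducible.
    """
    template = template or CurveParams()
    curves = []
    for i, temp in enumerate(temperatures):
        lo, hi = TEMPERATURE_RANGE
        if not lo <= temp <= hi:
            raise ParameterError(
                f"temperature {temp} °C outside instrument range {lo}-{hi}"
            )
        t_c = law.ip_at(temp) + 2.0 / template.s
        # record length scales with the breakpoint, never below 1.5 x t_c
        duration = 1.6 * t_c
        params = dataclasses.replace(
            template, t_c=t_c, duration=duration, seed=template.seed + i
        )
        curves.append(simulate_curve(params, temp))
    return curves
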