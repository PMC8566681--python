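"""Two-tangent induction-period detection on oxygen-pressure curves.

The induction period (IP) is the time at which the rate of oxygen
consumption changes abruptly.  The two-tangent construction locates it as
the intersection of

* the **baseline tangent** — a least-squares line through the early,
  slowly-decaying part of the record, and
* the **oxidation tangent** — a least-squares line through a short window
  centred on the steepest-descent point of the smoothed curve.

Smoothing and derivative estimation use moving local-linear fits
(Savitzky–Golay, polynomial order 1), which tolerate the kPa-level noise
of real records; raw finite differences would not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .errors import (
    BreakpointOutOfRecordError,
    DetectionError,
    NoOnsetError,
    ParameterError,
)
from .simulate import OxidationCurve


@dataclass(frozen=True)
class DetectionConfig:
    """Tuning knobs of the two-tangent detector.

    smoothing_window      samples per local-linear smoothing fit (odd);
                          None -> max(5, 0.5 h / dt), rounded up to odd
    baseline_span         (start, end) fractions of the elapsed time up to
                          the steepest point used for the baseline tangent;
                          the default skips the first 5% (equilibration
                          transients) and stops at 50%
    tangent_halfwidth     samples on each side of the steepest point for
                          the oxidation tangent; None -> max(5, n // 100)
                          capped at 0.25 h worth of samples (a wide window
                          flattens the fitted tangent where the consumption
                          curve bends, biasing the IP low)
    min_slope_separation  minimum |slope difference| between the tangents,
                          kPa/h; below it the curve has no detectable onset
    censor_limit          optional run limit in hours (instruments cap runs,
                          typically at 240 h): a curve with no onset before
                          the limit yields a flagged censored measurement
                          instead of an error
    """

    smoothing_window: int | None = None
    baseline_span: tuple[float, float] = (0.05, 0.5)
    tangent_halfwidth: int | None = None
    min_slope_separation: float = 1.0
    censor_limit: float | None = None

    def __post_init__(self) -> None:
        a, b = self.baseline_span
        if not 0 <= a < b <= 1:
            raise ParameterError("baseline_span must satisfy 0 <= start < end <= 1")
        if self.smoothing_window is not None and (
            self.smoothing_window < 3 or self.smoothing_window % 2 == 0
        ):
            raise ParameterError("smoothing_window must be odd and >= 3")
        if self.tangent_halfwidth is not None and self.tangent_halfwidth < 1:
            raise ParameterError("tangent_halfwidth must be >= 1")


@dataclass(frozen=True)
class IPMeasurement:
    """An induction period at one temperature, with fit diagnostics.

    ``censored`` marks measurements where no onset occurred before the
    configured run limit; ``ip`` then holds the limit, a lower bound.
    """

    ip: float
    temperature: float
    diagnostics: dict = field(default_factory=dict)
    censored: bool = False

    def __post_init__(self) -> None:
        if not self.censored and self.ip <= 0:
            raise DetectionError(f"non-positive induction period: {self.ip}")


def _default_window(n: int, dt: float) -> int:
    w = max(5, int(round(0.5 / dt)))
    if w % 2 == 0:
        w += 1
    return min(w, n - 1 if (n - 1) % 2 == 1 else n - 2)


def _uniform_dt(times: np.ndarray) -> float:
    steps = np.diff(times)
    dt = float(np.median(steps))
    if not np.allclose(steps, dt, rtol=1e-6, atol=1e-9):
        raise ParameterError("detection requires uniformly sampled curves")
    return dt


def smoothed_derivative(curve: OxidationCurve, window: int) -> np.ndarray:
    """dP/dt estimated as the slope of a local least-squares line.

    Each interior sample gets the slope of the degree-1 least-squares fit
    over the ``window`` samples centred on it; near the ends the fit of the
    terminal window is evaluated (one-sided behaviour).
    """
    n = curve.n_samples
    if window >= n:
        raise ParameterError(f"window {window} must be smaller than series length {n}")
    if window < 3 or window % 2 == 0:
        raise ParameterError("window must be odd and >= 3")
    dt = _uniform_dt(curve.times)
    return savgol_filter(
        curve.pressures, window_length=window, polyorder=1, deriv=1,
        delta=dt, mode="interp",
    )


def two_tangent_ip(
    curve: OxidationCurve, config: DetectionConfig | None = None
) -> IPMeasurement:
    """Detect the induction period of ``curve`` by the two-tangent method.

    Steps: (1) estimate the smoothed derivative by moving local-linear
    fits; (2) locate the steepest-descent time t* (earliest sample on
    ties, so detection is deterministic); (3) fit the oxidation tangent
    over +/- ``tangent_halfwidth`` samples around t*; (4) fit the baseline
    tangent over the ``baseline_span`` fractions of the record up to t*;
    (5) intersect the two lines.  The IP is reported to 2 decimals (the
    print precision of published IP tables) with full diagnostics.

    Raises :class:`NoOnsetError` when the tangents are nearly parallel and
    :class:`BreakpointOutOfRecordError` when the intersection falls outside
    the record — unless ``config.censor_limit`` is set and the record
    reaches it, in which case a flagged censored measurement is returned.
    """
    cfg = config or DetectionConfig()
    n = curve.n_samples
    if n < 50:
        raise DetectionError(f"curve has only {n} samples; need >= 50")
    times, pressures = curve.times, curve.pressures
    dt = _uniform_dt(times)

    window = cfg.smoothing_window or _default_window(n, dt)
    deriv = smoothed_derivative(curve, window)
    i_star = int(np.argmin(deriv))  # argmin takes the earliest tie
    t_star = float(times[i_star])

    diagnostics: dict = {"steepest_time": t_star, "smoothing_window": window}

    def _censored(reason: str) -> IPMeasurement | None:
        if cfg.censor_limit is not None and curve.duration >= cfg.censor_limit:
            diagnostics["censor_reason"] = reason
            return IPMeasurement(
                ip=float(cfg.censor_limit),
                temperature=curve.temperature,
                diagnostics=diagnostics,
                censored=True,
            )
        return None

    # a flat record's derivative has its (tied) minimum at the very first
    # sample, leaving no room for a baseline: there is no onset to find
    if i_star < max(3, window // 2):
        censored = _censored("no steepest-descent point inside the record")
        if censored is not None:
            return censored
        raise NoOnsetError(
            "no oxidation onset detected: steepest descent at the record start"
        )

    halfwidth = cfg.tangent_halfwidth or max(
        5, min(n // 100, max(1, int(round(0.25 / dt))))
    )
    lo = max(0, i_star - halfwidth)
    hi = min(n, i_star + halfwidth + 1)
    slope_ox, icept_ox = np.polyfit(times[lo:hi], pressures[lo:hi], 1)

    t0 = float(times[0])
    a, b = cfg.baseline_span
    base_lo = t0 + a * (t_star - t0)
    base_hi = t0 + b * (t_star - t0)
    mask = (times >= base_lo) & (times <= base_hi)
    if int(mask.sum()) < 3:
        censored = _censored("no baseline precedes the steepest-descent point")
        if censored is not None:
            return censored
        raise NoOnsetError(
            "no oxidation onset detected: fewer than 3 baseline samples "
            "precede the steepest-descent point"
        )
    slope_base, icept_base = np.polyfit(times[mask], pressures[mask], 1)

    diagnostics.update({
        "baseline_slope": float(slope_base),
        "baseline_intercept": float(icept_base),
        "tangent_slope": float(slope_ox),
        "tangent_intercept": float(icept_ox),
        "tangent_halfwidth": halfwidth,
    })

    if abs(slope_base - slope_ox) < cfg.min_slope_separation:
        censored = _censored("no oxidation onset before run limit")
        if censored is not None:
            return censored
        raise NoOnsetError(
            "no oxidation onset detected: tangent slopes differ by "
            f"{abs(slope_base - slope_ox):.3g} kPa/h "
            f"(< {cfg.min_slope_separation})"
        )

    ip = (icept_base - icept_ox) / (slope_ox - slope_base)
    if cfg.censor_limit is not None and ip > cfg.censor_limit:
        censored = _censored("intersection beyond run limit")
        if censored is not None:
            return censored
    if not t0 < ip <= curve.duration:
        raise BreakpointOutOfRecordError(
            f"breakpoint outside record: intersection at {ip:.2f} h, "
            f"record spans ({t0:g}, {curve.duration:g}] h"
        )
    return IPMeasurement(
        ip=round(float(ip), 2),
        temperature=curve.temperature,
        diagnostics=diagnostics,
    )
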