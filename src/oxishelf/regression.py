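"""Correlation screen and grouped shelf-life regression models.

Shelf-lives estimated by accelerated oxidation testing are screened
against label-available oil properties (fatty-acid classes, iodine value,
smoke point, acid value) by Pearson correlation, and predicted by a
multiple linear regression with a binary group indicator:

    y = b0 + b1·X1 + b2·X2

where X1 is a composition predictor (SFA%, UFA%, SFA/UFA ratio or PUFA%)
and X2 ∈ {0, 1} splits the oils into two families whose shelf-life/UFA
lines run parallel but offset — a grouping attributed to differing
tocopherol profiles, supplied as data rather than inferred.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .errors import InsufficientDataError, OxishelfError, ParameterError

#: Predictor name -> OilRecord attribute.
PREDICTORS = {
    "SFAs": "sfa",
    "UFAs": "ufa",
    "PUFAs": "pufa",
    "SFAs/UFAs": "sfa_ufa_ratio",
}


@dataclass(frozen=True)
class OilRecord:
    """One oil's assembled properties for the correlation/regression stage.

    Shelf-lives are in days; log IPs in log10 hours (optional — a censored
    accelerated run leaves the corresponding entry None); group_x2 is the
    binary family indicator (None when the oil is excluded from modelling).
    """

    oil_id: str
    shelf_life_20: float
    shelf_life_25: float
    sfa: float
    ufa: float
    pufa: float
    iodine_value: float | None = None
    smoke_point: float | None = None
    acid_value: float | None = None
    log_ip_70: float | None = None
    log_ip_90: float | None = None
    log_ip_100: float | None = None
    group_x2: int | None = None

    def __post_init__(self) -> None:
        if self.group_x2 not in (None, 0, 1):
            raise ParameterError(f"group_x2 must be 0, 1 or None, got {self.group_x2}")
        if self.shelf_life_20 <= 0 or self.shelf_life_25 <= 0:
            raise ParameterError(f"{self.oil_id}: shelf-lives must be positive")

    @property
    def sfa_ufa_ratio(self) -> float:
        return self.sfa / self.ufa


@dataclass(frozen=True)
class GroupedRegressionModel:
    """OLS fit of shelf-life on (predictor, group indicator) with intercept.

    multiple_r is sqrt(R²); p_value is the overall F-test on (2, n−3)
    degrees of freedom.  Coefficients are stored at full precision;
    :meth:`equation` renders them integer-rounded, the way such models are
    printed.
    """

    predictor_name: str
    response: int
    b0: float
    b1: float
    b2: float
    multiple_r: float
    p_value: float
    n: int

    def equation(self) -> str:
        def term(coef: float, name: str) -> str:
            sign = "+" if coef >= 0 else "-"
            return f" {sign} {abs(round(coef)):,d}{name}"
        lead = f"y = {round(self.b1):,d}X1" if self.b1 < 0 else f"y = {round(self.b1):,d}X1"
        return lead + term(self.b2, "X2") + term(self.b0, "")


@dataclass(frozen=True)
class GroupLine:
    """Per-group simple regression line of shelf-life on a predictor."""

    group: int
    slope: float
    intercept: float
    r: float
    p_value: float
    n: int


def pearson_with_significance(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Sample Pearson r and its two-tailed p-value.

    Significance comes from t = r·sqrt((n−2)/(1−r²)) on n−2 degrees of
    freedom (the classical test, as implemented by scipy).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be equal-length 1-D sequences")
    if x.size < 3:
        raise InsufficientDataError("correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise OxishelfError("undefined correlation: a variable has zero variance")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def _response_values(records: Sequence[OilRecord], response: int) -> np.ndarray:
    if response not in (20, 25):
        raise ParameterError(f"response must be 20 or 25 (°C), got {response}")
    attr = f"shelf_life_{response}"
    return np.array([getattr(r, attr) for r in records], dtype=float)


def _predictor_values(records: Sequence[OilRecord], predictor_name: str) -> np.ndarray:
    try:
        attr = PREDICTORS[predictor_name]
    except KeyError:
        raise ParameterError(
            f"unknown predictor {predictor_name!r}; choose from {sorted(PREDICTORS)}"
        ) from None
    return np.array([getattr(r, attr) for r in records], dtype=float)


def fit_grouped_model(
    records: Sequence[OilRecord], predictor_name: str, response: int
) -> GroupedRegressionModel:
    """Fit y = b0 + b1·X1 + b2·X2 by ordinary least squares.

    Requires >= 4 records with both X2 groups represented and a
    full-rank design.  A constant response is handled gracefully
    (multiple_r = 0, p = 1: nothing to explain).
    """
    records = [r for r in records if r.group_x2 is not None]
    if len(records) < 4:
        raise InsufficientDataError("grouped model needs >= 4 records")
    x1 = _predictor_values(records, predictor_name)
    x2 = np.array([r.group_x2 for r in records], dtype=float)
    y = _response_values(records, response)
    if len(set(x2.tolist())) < 2:
        raise InsufficientDataError(
            "design degeneracy: only one X2 group present"
        )
    X = sm.add_constant(np.column_stack([x1, x2]))
    if np.linalg.matrix_rank(X) < 3:
        raise OxishelfError(
            f"rank-deficient design: {predictor_name} is collinear with the "
            "group indicator"
        )
    if np.ptp(y) == 0:
        # no variance to explain; coefficients are 0 around the mean level
        return GroupedRegressionModel(
            predictor_name=predictor_name, response=response,
            b0=float(y[0]), b1=0.0, b2=0.0,
            multiple_r=0.0, p_value=1.0, n=len(records),
        )
    fit = sm.OLS(y, X).fit()
    b0, b1, b2 = (float(v) for v in fit.params)
    return GroupedRegressionModel(
        predictor_name=predictor_name, response=response,
        b0=b0, b1=b1, b2=b2,
        multiple_r=math.sqrt(max(float(fit.rsquared), 0.0)),
        p_value=float(fit.f_pvalue),
        n=len(records),
    )


def predict_shelf_life(
    model: GroupedRegressionModel, x1: float, x2: int
) -> int:
    """Plug-in prediction y = b0 + b1·x1 + b2·x2, to the nearest day.

    A negative prediction is outside the calibrated range: it is returned
    as-is (not clamped) with a warning.
    """
    if x2 not in (0, 1):
        raise ParameterError(f"x2 must be 0 or 1, got {x2}")
    y = model.b0 + model.b1 * x1 + model.b2 * x2
    if y < 0:
        warnings.warn(
            f"negative shelf-life prediction ({y:.1f} days): input outside "
            "the model's calibrated range",
            stacklevel=2,
        )
    return int(math.copysign(math.floor(abs(y) + 0.5), y))


def simple_group_regressions(
    records: Sequence[OilRecord], predictor_name: str, response: int
) -> dict[int, GroupLine]:
    """Independent OLS line per X2 group (the two-curve scatter models)."""
    records = [r for r in records if r.group_x2 is not None]
    lines: dict[int, GroupLine] = {}
    for group in (0, 1):
        members = [r for r in records if r.group_x2 == group]
        if len(members) < 3:
            raise InsufficientDataError(
                f"group {group} has only {len(members)} oils; need >= 3"
            )
        x = _predictor_values(members, predictor_name)
        y = _response_values(members, response)
        res = stats.linregress(x, y)
        lines[group] = GroupLine(
            group=group,
            slope=float(res.slope),
            intercept=float(res.intercept),
            r=float(res.rvalue),
            p_value=float(res.pvalue),
            n=len(members),
        )
    return lines
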