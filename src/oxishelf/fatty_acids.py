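"""Fatty-acid composition: profiles, saturation classes and calculated iodine value.

An oil's composition is expressed as percentages of total fatty acid methyl
esters (FAMEs), keyed by the shorthand ``Cx:y`` where ``x`` is the carbon
count and ``y`` the number of double bonds.  From these the module derives

* saturation-class aggregates — SFA (y = 0), MUFA (y = 1), PUFA (y >= 2)
  and UFA = MUFA + PUFA;
* the *calculated iodine value* (AOCS Cd 1c-85): a weighted sum of the
  unsaturated fatty-acid percentages, in g I2 per 100 g oil.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Mapping

from .errors import ProfileError

#: Fatty acids the package knows about (the ones reported for common
#: expeller-pressed seed oils).  Unknown codes are rejected, not ignored.
FATTY_ACID_CODES: tuple[str, ...] = (
    "C14:0", "C16:0", "C16:1", "C17:0", "C18:0", "C18:1",
    "C18:2", "C18:3", "C20:0", "C20:1", "C22:0", "C22:1",
)

#: AOCS calculated-IV coefficients (g I2 absorbed per 1% of the acid).
#: Saturated acids carry no double bonds and contribute nothing.
IODINE_COEFFICIENTS: Mapping[str, float] = {
    "C16:1": 0.95,
    "C18:1": 0.86,
    "C18:2": 1.732,
    "C18:3": 2.616,
    "C20:1": 0.785,
    "C22:1": 0.723,
}

_CODE_RE = re.compile(r"^C(\d{1,2}):(\d{1,2})$")

# Percentages are printed rounded, so the total may exceed 100 slightly.
_TOTAL_LIMIT = 101.0

#: Strings treated as "not detected" in input tables.
_ND_TOKENS = frozenset({"", "nd", "n.d.", "na", "n/a", "-"})


def double_bond_count(code: str) -> int:
    """Number of double bonds encoded in a ``Cx:y`` fatty-acid code."""
    m = _CODE_RE.match(code)
    if m is None:
        raise ProfileError(f"unrecognised fatty-acid code: {code!r}")
    return int(m.group(2))


@dataclass(frozen=True)
class FattyAcidProfile:
    """Fatty-acid composition of one oil, as % of total FAMEs.

    Absent ("not detected") acids are simply omitted from ``percentages``
    (or stored as 0, equivalently).  Construction validates the vocabulary,
    non-negativity and the total.
    """

    oil_id: str
    percentages: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, float] = {}
        for code, value in self.percentages.items():
            if code not in FATTY_ACID_CODES:
                raise ProfileError(
                    f"{self.oil_id or 'profile'}: unknown fatty-acid code {code!r}"
                )
            v = float(value)
            if not math.isfinite(v):
                raise ProfileError(f"{self.oil_id}: non-finite percentage for {code}")
            if v < 0:
                raise ProfileError(
                    f"{self.oil_id}: negative percentage for {code}: {v}"
                )
            clean[code] = v
        total = sum(clean.values())
        if total > _TOTAL_LIMIT:
            raise ProfileError(
                f"{self.oil_id}: percentages total {total:.2f} exceeds {_TOTAL_LIMIT}"
            )
        object.__setattr__(self, "percentages", clean)

    def get(self, code: str) -> float:
        """Percentage of ``code``, 0.0 if not detected."""
        if code not in FATTY_ACID_CODES:
            raise ProfileError(f"unknown fatty-acid code {code!r}")
        return self.percentages.get(code, 0.0)

    @property
    def total(self) -> float:
        return sum(self.percentages.values())


@dataclass(frozen=True)
class ClassSummary:
    """Saturation-class aggregates in % of total FAMEs (UFA = MUFA + PUFA)."""

    sfa: float
    ufa: float
    mufa: float
    pufa: float


def aggregate_classes(profile: FattyAcidProfile, ndigits: int | None = 2) -> ClassSummary:
    """Sum the profile into SFA / MUFA / PUFA / UFA classes.

    Class membership is derived from the double-bond count in the code, so
    extending :data:`FATTY_ACID_CODES` extends the classes automatically.
    Results are rounded to ``ndigits`` (2 by default, the print precision of
    composition tables); pass ``None`` for full precision.
    """
    sfa = mufa = pufa = 0.0
    for code, pct in profile.percentages.items():
        bonds = double_bond_count(code)
        if bonds == 0:
            sfa += pct
        elif bonds == 1:
            mufa += pct
        else:
            pufa += pct
    ufa = mufa + pufa
    if ndigits is not None:
        sfa, ufa, mufa, pufa = (round(v, ndigits) for v in (sfa, ufa, mufa, pufa))
    return ClassSummary(sfa=sfa, ufa=ufa, mufa=mufa, pufa=pufa)


def iodine_value(profile: FattyAcidProfile, ndigits: int | None = 1) -> float:
    """Calculated iodine value, g I2 / 100 g oil.

    IV = 0.95 %C16:1 + 0.86 %C18:1 + 1.732 %C18:2 + 2.616 %C18:3
         + 0.785 %C20:1 + 0.723 %C22:1

    Absent acids contribute 0; a profile of only saturated acids has IV 0.
    Rounded to 1 decimal by default (the precision oils tables print);
    pass ``ndigits=None`` for the unrounded value.
    """
    iv = sum(
        coef * profile.percentages.get(code, 0.0)
        for code, coef in IODINE_COEFFICIENTS.items()
    )
    return round(iv, ndigits) if ndigits is not None else iv


def validate_profile(raw: Mapping[str, object], oil_id: str = "") -> FattyAcidProfile:
    """Normalise a raw mapping (e.g. a CSV row) into a :class:`FattyAcidProfile`.

    "ND", blank and None entries are mapped to 0 (not-detected); numeric
    strings are parsed.  Raises :class:`ProfileError` for unknown codes,
    non-numeric values, negative percentages or totals above 101%.
    """
    percentages: dict[str, float] = {}
    for code, value in raw.items():
        if value is None:
            continue
        if isinstance(value, str):
            token = value.strip()
            if token.lower() in _ND_TOKENS:
                continue
            try:
                value = float(token)
            except ValueError:
                raise ProfileError(
                    f"{oil_id or 'profile'}: non-numeric value {token!r} for {code}"
                ) from None
        else:
            value = float(value)  # type: ignore[arg-type]
            if math.isnan(value):
                continue
        if value != 0.0:
            percentages[code] = value
    return FattyAcidProfile(oil_id=oil_id, percentages=percentages)
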