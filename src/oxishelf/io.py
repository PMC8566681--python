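"""CSV/JSON input-output and packaged reference tables.

Formats
-------
composition CSV   one row per oil: ``oil_id`` plus fatty-acid code columns;
                  "ND" and blank cells mean not-detected
IP CSV            long format: ``oil_id, temperature_C, ip_hours, censored``
curve CSV         two columns ``time_h, pressure_kPa`` with a JSON sidecar
                  holding temperature, seed, ground-truth IP and the
                  simulation parameters

The packaged reference tables reproduce, verbatim, the published
composition, property, induction-period and kinetics tables for ten
expeller-pressed seed oils; they drive the reproduction workflow and the
test-suite oracles.
"""

from __future__ import annotations

import dataclasses
import json
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .detect import IPMeasurement
from .errors import SchemaError
from .fatty_acids import FATTY_ACID_CODES, FattyAcidProfile, validate_profile
from .regression import OilRecord
from .simulate import CurveParams, OxidationCurve

_DATA = resources.files("oxishelf.data")


def _fixture_path(name: str) -> Path:
    path = Path(str(_DATA / name))
    if not path.exists():
        raise SchemaError(f"packaged fixture missing: {name}")
    return path


# ---------------------------------------------------------------------------
# composition tables

def _read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, **kwargs)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file") from None


def read_composition_csv(path: str | Path) -> list[FattyAcidProfile]:
    """Read a composition table into validated profiles."""
    df = _read_table(path, dtype=str)
    if "oil_id" not in df.columns:
        raise SchemaError(f"{path}: missing required column 'oil_id'")
    if df["oil_id"].duplicated().any():
        dupes = df.loc[df["oil_id"].duplicated(), "oil_id"].tolist()
        raise SchemaError(f"{path}: duplicate oil_id values: {dupes}")
    code_cols = [c for c in df.columns if c in FATTY_ACID_CODES]
    if not code_cols:
        raise SchemaError(f"{path}: no fatty-acid code columns found")
    profiles = []
    for _, row in df.iterrows():
        raw = {c: row[c] for c in code_cols}
        profiles.append(validate_profile(raw, oil_id=str(row["oil_id"])))
    return profiles


def write_composition_csv(profiles: Iterable[FattyAcidProfile], path: str | Path) -> None:
    """Write profiles with one column per known code; absent acids as 'ND'."""
    rows = []
    for p in profiles:
        row: dict[str, object] = {"oil_id": p.oil_id}
        for code in FATTY_ACID_CODES:
            v = p.percentages.get(code)
            row[code] = "ND" if v is None else f"{v:g}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# IP tables

def read_ip_csv(path: str | Path) -> dict[str, list[IPMeasurement]]:
    """Read a long-format IP table into measurements grouped by oil."""
    df = _read_table(path)
    required = {"oil_id", "temperature_C", "ip_hours", "censored"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {sorted(missing)}")
    out: dict[str, list[IPMeasurement]] = {}
    for _, row in df.iterrows():
        censored = bool(int(row["censored"]))
        ip = float(row["ip_hours"]) if not pd.isna(row["ip_hours"]) else float("nan")
        out.setdefault(str(row["oil_id"]), []).append(
            IPMeasurement(
                ip=ip,
                temperature=float(row["temperature_C"]),
                censored=censored,
            )
        )
    return out


def write_ip_csv(measurements: dict[str, list[IPMeasurement]], path: str | Path) -> None:
    rows = [
        {
            "oil_id": oil,
            "temperature_C": m.temperature,
            "ip_hours": "" if m.censored and np.isnan(m.ip) else m.ip,
            "censored": int(m.censored),
        }
        for oil, ms in measurements.items()
        for m in ms
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# curves

def write_curve(curve: OxidationCurve, base: str | Path) -> tuple[Path, Path]:
    """Write ``<base>.csv`` (time_h, pressure_kPa) and ``<base>.json`` sidecar."""
    base = Path(base)
    csv_path = base.with_suffix(".csv")
    json_path = base.with_suffix(".json")
    pd.DataFrame(
        {"time_h": curve.times, "pressure_kPa": curve.pressures}
    ).to_csv(csv_path, index=False, float_format="%.10g")
    sidecar = {
        "temperature_C": curve.temperature,
        "true_ip_h": curve.true_ip,
        "params": dataclasses.asdict(curve.params) if curve.params else None,
    }
    json_path.write_text(json.dumps(sidecar, indent=2) + "\n")
    return csv_path, json_path


def read_curve(csv_path: str | Path) -> OxidationCurve:
    """Read a curve CSV, picking up the JSON sidecar when present."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    for col in ("time_h", "pressure_kPa"):
        if col not in df.columns:
            raise SchemaError(f"{csv_path}: missing required column '{col}'")
    temperature, true_ip, params = 70.0, None, None
    sidecar_path = csv_path.with_suffix(".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        temperature = float(sidecar.get("temperature_C", temperature))
        true_ip = sidecar.get("true_ip_h")
        if sidecar.get("params"):
            params = CurveParams(**sidecar["params"])
    return OxidationCurve(
        times=df["time_h"].to_numpy(float),
        pressures=df["pressure_kPa"].to_numpy(float),
        temperature=temperature,
        true_ip=true_ip,
        params=params,
    )


# ---------------------------------------------------------------------------
# packaged reference tables

def load_reference_profiles() -> list[FattyAcidProfile]:
    """Fatty-acid compositions of the ten reference oils."""
    return read_composition_csv(_fixture_path("reference_composition.csv"))


def load_reference_classes() -> pd.DataFrame:
    """Published SFA/UFA/PUFA class sums (%), indexed by oil_id."""
    return pd.read_csv(_fixture_path("reference_classes.csv"), index_col="oil_id")


def load_reference_properties() -> pd.DataFrame:
    """Published iodine values, smoke points and acid values, by oil_id."""
    return pd.read_csv(_fixture_path("reference_properties.csv"), index_col="oil_id")


def load_reference_ips() -> dict[str, list[IPMeasurement]]:
    """Published induction periods at 70/90/100 °C (peanut 70 °C censored)."""
    return read_ip_csv(_fixture_path("reference_ips.csv"))


def load_reference_kinetics() -> pd.DataFrame:
    """Published kinetic parameters, shelf-lives and group assignments."""
    return pd.read_csv(_fixture_path("reference_kinetics.csv"), index_col="oil_id")


def build_oil_records(include_excluded: bool = False) -> list[OilRecord]:
    """Assemble per-oil records from the packaged reference tables.

    Pumpkin seed oil — excluded from the published correlation and
    regression analyses because its chlorophyll load confounds shelf-life —
    is omitted unless ``include_excluded`` is set (its group_x2 stays None
    either way).
    """
    classes = load_reference_classes()
    props = load_reference_properties()
    kin = load_reference_kinetics()
    ips = load_reference_ips()
    records = []
    for oil_id, row in kin.iterrows():
        group = row["group_x2"]
        group = None if pd.isna(group) else int(group)
        if group is None and not include_excluded:
            continue
        by_temp = {m.temperature: m for m in ips[oil_id]}

        def log_ip(temp: float) -> float | None:
            m = by_temp.get(temp)
            if m is None or m.censored:
                return None
            return float(np.log10(m.ip))

        records.append(
            OilRecord(
                oil_id=str(oil_id),
                shelf_life_20=float(row["shelf_life_20_days"]),
                shelf_life_25=float(row["shelf_life_25_days"]),
                sfa=float(classes.loc[oil_id, "sfa"]),
                ufa=float(classes.loc[oil_id, "ufa"]),
                pufa=float(classes.loc[oil_id, "pufa"]),
                iodine_value=float(props.loc[oil_id, "iodine_value"]),
                smoke_point=float(props.loc[oil_id, "smoke_point_C"]),
                acid_value=float(props.loc[oil_id, "acid_value"]),
                log_ip_70=log_ip(70.0),
                log_ip_90=log_ip(90.0),
                log_ip_100=log_ip(100.0),
                group_x2=group,
            )
        )
    return records


def write_records_csv(records: Iterable[OilRecord], path: str | Path) -> None:
    """Tidy one-row-per-oil CSV of assembled records."""
    pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(path, index=False)


def read_records_csv(path: str | Path) -> list[OilRecord]:
    df = pd.read_csv(path)
    if "oil_id" not in df.columns:
        raise SchemaError(f"{path}: missing required column 'oil_id'")
    records = []
    for _, row in df.iterrows():
        kwargs = {k: (None if pd.isna(v) else v) for k, v in row.items()}
        kwargs["oil_id"] = str(kwargs["oil_id"])
        if kwargs.get("group_x2") is not None:
            kwargs["group_x2"] = int(kwargs["group_x2"])
        records.append(OilRecord(**kwargs))
    return records
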