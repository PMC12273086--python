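"""Shared domain types, tabular I/O, and schema validation.

The pipeline's carrier format is plain UTF-8 CSV with a header row. Four
tables describe an EHR extract:

* ``patients.csv`` — ``patient_id, org_id, age, gender, race_group,
  dx_mdd, dx_bd, dx_gad, dx_ptsd, dx_scz, dx_adhd, dx_pd``
* ``visits.csv`` — ``patient_id, date, cgi_s, gaf``
* ``hospitalisations.csv`` — ``patient_id, date``
* ``splits.csv`` — ``org_id, split``

Dates are ISO-8601 calendar days on disk and integer day offsets from
1970-01-01 in memory (all study windows are whole-day). Missing CGI-S/GAF
ratings are empty cells on disk and pandas ``NA`` in memory.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

DIAGNOSES = ("mdd", "bd", "gad", "ptsd", "scz", "adhd", "pd")
DX_COLUMNS = tuple(f"dx_{d}" for d in DIAGNOSES)
GENDERS = ("female", "male", "unknown")
RACE_GROUPS = ("white", "non_white", "unknown")
SPLITS = ("derivation", "validation")

_EPOCH = _dt.date(1970, 1, 1)

PATIENT_COLUMNS = ("patient_id", "org_id", "age", "gender", "race_group") + DX_COLUMNS
VISIT_COLUMNS = ("patient_id", "date", "cgi_s", "gaf")
HOSP_COLUMNS = ("patient_id", "date")
SPLIT_COLUMNS = ("org_id", "split")

TABLE_FILES = {
    "patients": "patients.csv",
    "visits": "visits.csv",
    "hospitalisations": "hospitalisations.csv",
    "splits": "splits.csv",
}


class SchemaError(ValueError):
    """A table is missing a required column or has an unusable layout."""


class ValidationError(ValueError):
    """A cell violates a field constraint; the message names the row."""


def day_to_date(day: int) -> str:
    return (_EPOCH + _dt.timedelta(days=int(day))).isoformat()


def date_to_day(value: str) -> int:
    return (_dt.date.fromisoformat(str(value)) - _EPOCH).days


@dataclass
class Dataset:
    """Typed in-memory EHR extract with referential integrity enforced.

    ``visits`` and ``hospitalisations`` carry an integer ``day`` column;
    ``patients`` carries boolean diagnosis flags. ``validate()`` raises
    :class:`ValidationError` / :class:`SchemaError` on any invariant breach.
    """

    patients: pd.DataFrame
    visits: pd.DataFrame
    hospitalisations: pd.DataFrame
    splits: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=list(SPLIT_COLUMNS)))

    def validate(self) -> "Dataset":
        _check_columns(self.patients, PATIENT_COLUMNS, "patients")
        _check_columns(self.visits, ("patient_id", "day", "cgi_s", "gaf"), "visits")
        _check_columns(self.hospitalisations, ("patient_id", "day"), "hospitalisations")
        _check_columns(self.splits, SPLIT_COLUMNS, "splits")

        p = self.patients
        if p["patient_id"].duplicated().any():
            dup = p.loc[p["patient_id"].duplicated(), "patient_id"].iloc[0]
            raise ValidationError(f"patients: duplicate patient_id {dup!r}")
        if (p["age"] < 0).any():
            row = int(np.flatnonzero(p["age"].to_numpy() < 0)[0])
            raise ValidationError(f"patients row {row}: age must be >= 0")
        _check_category(p, "gender", GENDERS)
        _check_category(p, "race_group", RACE_GROUPS)
        dx = p[list(DX_COLUMNS)].astype(bool)
        if not dx.any(axis=1).all():
            row = int(np.flatnonzero(~dx.any(axis=1).to_numpy())[0])
            raise ValidationError(
                f"patients row {row}: at least one diagnosis flag must be true"
            )

        known = set(p["patient_id"])
        for name, tbl in (("visits", self.visits), ("hospitalisations", self.hospitalisations)):
            unknown = ~tbl["patient_id"].isin(known)
            if unknown.any():
                row = int(np.flatnonzero(unknown.to_numpy())[0])
                raise ValidationError(
                    f"{name} row {row}: unknown patient_id "
                    f"{tbl['patient_id'].iloc[row]!r}"
                )

        v = self.visits
        _check_range(v, "cgi_s", 1, 7)
        _check_range(v, "gaf", 1, 100)
        neither = v["cgi_s"].isna() & v["gaf"].isna()
        if neither.any():
            row = int(np.flatnonzero(neither.to_numpy())[0])
            raise ValidationError(
                f"visits row {row}: at least one of cgi_s, gaf must be present"
            )

        s = self.splits
        bad = ~s["split"].isin(SPLITS)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"splits row {row}: split must be one of {SPLITS}, "
                f"got {s['split'].iloc[row]!r}"
            )
        if s["org_id"].duplicated().any():
            dup = s.loc[s["org_id"].duplicated(), "org_id"].iloc[0]
            raise ValidationError(f"splits: org_id {dup!r} assigned to more than one split")
        if len(s):
            missing = set(p["org_id"]) - set(s["org_id"])
            if missing:
                raise ValidationError(f"splits: orgs without a split assignment: {sorted(missing)}")
        return self

    def split_patients(self, split: str) -> pd.DataFrame:
        """Patients belonging to organisations assigned to ``split``."""
        orgs = set(self.splits.loc[self.splits["split"] == split, "org_id"])
        return self.patients[self.patients["org_id"].isin(orgs)].reset_index(drop=True)

    def __eq__(self, other: object) -> bool:  # field-wise equality for tests
        if not isinstance(other, Dataset):
            return NotImplemented
        return all(
            getattr(self, n).reset_index(drop=True).equals(getattr(other, n).reset_index(drop=True))
            for n in ("patients", "visits", "hospitalisations", "splits")
        )


def _check_columns(df: pd.DataFrame, required, table: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing column(s) {missing}")


def _check_category(df: pd.DataFrame, col: str, allowed) -> None:
    bad = ~df[col].isin(allowed)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"patients row {row}: {col} must be one of {tuple(allowed)}, "
            f"got {df[col].iloc[row]!r}"
        )


def _check_range(df: pd.DataFrame, col: str, lo: int, hi: int) -> None:
    vals = df[col]
    bad = vals.notna() & ((vals < lo) | (vals > hi))
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"visits row {row}: {col}={vals.iloc[row]} outside range [{lo},{hi}]"
        )


def load_schema_config(path: str | Path) -> dict:
    """Read a YAML config with optional column remapping and race recoding.

    Keys: ``columns: {table: {canonical_name: file_name}}`` and
    ``race_map: {raw_value: white|non_white|unknown}``.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return cfg


def read_dataset(
    paths: str | Path | Mapping[str, str | Path],
    schema_config: dict | None = None,
) -> Dataset:
    """Load, type and validate the four CSV tables.

    ``paths`` is either a directory containing the standard file names or a
    mapping from table name to file path. A missing ``splits`` table yields
    an empty split assignment.
    """
    if isinstance(paths, (str, Path)):
        base = Path(paths)
        paths = {k: base / v for k, v in TABLE_FILES.items()}
    cfg = schema_config or {}
    colmap = cfg.get("columns", {})
    race_map = cfg.get("race_map", {})

    def load(table: str, required) -> pd.DataFrame:
        path = Path(paths[table])
        if table == "splits" and not path.exists():
            return pd.DataFrame(columns=list(SPLIT_COLUMNS))
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        rename = {v: k for k, v in colmap.get(table, {}).items()}
        df = df.rename(columns=rename)
        _check_columns(df, required, table)
        return df[list(required)]

    patients = load("patients", PATIENT_COLUMNS)
    visits = load("visits", VISIT_COLUMNS)
    hosp = load("hospitalisations", HOSP_COLUMNS)
    splits = load("splits", SPLIT_COLUMNS)

    patients = patients.assign(age=pd.to_numeric(patients["age"]))
    if race_map:
        patients["race_group"] = patients["race_group"].map(
            lambda r: race_map.get(r, r)
        )
    for c in DX_COLUMNS:
        patients[c] = _parse_bool(patients[c], c)

    visits = pd.DataFrame(
        {
            "patient_id": visits["patient_id"],
            "day": visits["date"].map(date_to_day),
            "cgi_s": _parse_optional_int(visits["cgi_s"]),
            "gaf": _parse_optional_int(visits["gaf"]),
        }
    )
    hosp = pd.DataFrame(
        {"patient_id": hosp["patient_id"], "day": hosp["date"].map(date_to_day)}
    )
    return Dataset(patients, visits, hosp, splits).validate()


def write_dataset(ds: Dataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the four tables as CSV such that read_dataset round-trips exactly."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    p = ds.patients.copy()
    for c in DX_COLUMNS:
        p[c] = p[c].astype(bool).map({True: "1", False: "0"})
    paths["patients"] = out / TABLE_FILES["patients"]
    p[list(PATIENT_COLUMNS)].to_csv(paths["patients"], index=False)

    v = ds.visits.copy()
    v["date"] = v["day"].map(day_to_date)
    v["cgi_s"] = v["cgi_s"].astype("Int64").astype(str).replace("<NA>", "")
    v["gaf"] = v["gaf"].astype("Int64").astype(str).replace("<NA>", "")
    paths["visits"] = out / TABLE_FILES["visits"]
    v[list(VISIT_COLUMNS)].to_csv(paths["visits"], index=False)

    h = ds.hospitalisations.copy()
    h["date"] = h["day"].map(day_to_date)
    paths["hospitalisations"] = out / TABLE_FILES["hospitalisations"]
    h[list(HOSP_COLUMNS)].to_csv(paths["hospitalisations"], index=False)

    paths["splits"] = out / TABLE_FILES["splits"]
    ds.splits[list(SPLIT_COLUMNS)].to_csv(paths["splits"], index=False)
    return paths


def _parse_bool(col: pd.Series, name: str) -> pd.Series:
    mapping = {"1": True, "0": False, "true": True, "false": False,
               "True": True, "False": False}
    out = col.map(mapping)
    if out.isna().any():
        row = int(np.flatnonzero(out.isna().to_numpy())[0])
        raise ValidationError(f"patients row {row}: {name}={col.iloc[row]!r} is not boolean")
    return out.astype(bool)


def _parse_optional_int(col: pd.Series) -> pd.Series:
    return pd.to_numeric(col.replace("", np.nan)).astype("Int64")
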