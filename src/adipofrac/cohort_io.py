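"""Reading, validation and inclusion filtering of individual-level cohorts.

A cohort is one row per subject: sex, age, anthropometry (height/weight
and/or BMI), previously-diagnosed hypertension and diabetes flags, and
the lifestyle/social covariates used for adjustment (education, marital
status, tobacco, alcohol).

Inclusion rules applied at load time:

* adults only — age ≥ 18 by default ("over eighteen" is read inclusively;
  configurable to strict),
* BMI ≥ 18.5 kg/m² (underweight excluded),
* optionally, pregnant subjects excluded when a ``pregnant`` column is
  present.

Rows failing a rule — or rows whose sex/age/BMI cannot be parsed — are
dropped, never crash the load, and are recorded in the cohort's
exclusion log as ``(id, reason)`` pairs.

Input is UTF-8 comma-separated text with a header row and decimal
points; arbitrary source column names are handled through a mapping
(dict, or YAML/JSON file) from the canonical names to the file's names.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import yaml

MIN_BMI = 18.5
DEFAULT_MIN_AGE = 18.0

#: Canonical column names; height in metres, weight in kg, bmi in kg/m².
CANONICAL_COLUMNS = (
    "id",
    "sex",
    "age",
    "height",
    "weight",
    "bmi",
    "hypertension",
    "diabetes",
    "education",
    "marital",
    "tobacco",
    "alcohol",
    "pregnant",
)
REQUIRED_COLUMNS = ("sex", "age")

#: Maximum tolerated discrepancy between a given BMI and weight/height².
BMI_CONSISTENCY_TOL = 0.1

_SEX_LABELS = {
    "male": "male", "m": "male", "0": "male",
    "female": "female", "f": "female", "1": "female",
}
_TRUE = {"1", "true", "yes", "y", "t"}
_FALSE = {"0", "false", "no", "n", "f", ""}


class SchemaError(ValueError):
    """A required column is missing or the column mapping is invalid."""


@dataclass
class Subject:
    """One person's record after validation."""

    id: str
    sex: str
    age: float
    bmi: float
    hypertension: bool | None = None
    diabetes: bool | None = None
    height: float | None = None
    weight: float | None = None
    education: str | None = None
    marital: str | None = None
    tobacco: str | None = None
    alcohol: str | None = None


@dataclass
class Cohort:
    """An ordered collection of validated subjects plus its audit trail."""

    data: pd.DataFrame
    provenance: str = ""
    exclusion_log: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.data)

    def __iter__(self) -> Iterator[Subject]:
        fields = [f for f in Subject.__dataclass_fields__ if f in self.data.columns]
        for _, row in self.data.iterrows():
            kwargs = {f: row[f] for f in fields}
            kwargs = {k: (None if pd.isna(v) else v) for k, v in kwargs.items()}
            yield Subject(**kwargs)

    def to_frame(self) -> pd.DataFrame:
        return self.data.copy()


def bmi_from_weight_height(weight, height):
    """Body mass index, weight (kg) / height (m) squared.

    Raises ``ValueError`` for non-positive weight or height.
    """
    w = np.asarray(weight, dtype=float)
    h = np.asarray(height, dtype=float)
    if np.any(~np.isfinite(w)) or np.any(~np.isfinite(h)):
        raise ValueError("weight and height must be finite")
    if np.any(w <= 0) or np.any(h <= 0):
        raise ValueError("weight and height must be positive")
    out = w / h**2
    return float(out) if out.ndim == 0 else out


def _read_mapping(schema_config) -> dict[str, str]:
    if schema_config is None:
        return {}
    if isinstance(schema_config, dict):
        return dict(schema_config)
    path = Path(schema_config)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def _parse_bool(value) -> bool | None:
    if pd.isna(value):
        return None
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValueError(f"unparseable boolean: {value!r}")


def _parse_float(value) -> float | None:
    if pd.isna(value) or str(value).strip() == "":
        return None
    return float(value)


def load_cohort(
    path,
    schema_config=None,
    *,
    min_age: float = DEFAULT_MIN_AGE,
    age_inclusive: bool = True,
    min_bmi: float = MIN_BMI,
) -> Cohort:
    """Load a cohort CSV, applying the inclusion filters.

    Parameters
    ----------
    path : str or Path
        CSV file with a header row.
    schema_config : dict or str/Path, optional
        Mapping from canonical column names (``sex``, ``age``, ``bmi``,
        ``height``, ``weight``, ``hypertension``, ``diabetes``,
        ``education``, ``marital``, ``tobacco``, ``alcohol``,
        ``pregnant``) to the file's column names; or a YAML/JSON file
        holding that mapping. Unmapped canonical names fall back to
        identically-named columns.
    min_age, age_inclusive :
        Age filter; ≥ 18 by default. With ``age_inclusive=False`` the
        rule becomes strictly greater than ``min_age``.
    min_bmi :
        BMI inclusion floor (kg/m²).

    Row order is preserved; every excluded row appears exactly once in
    the returned cohort's ``exclusion_log``.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    mapping = _read_mapping(schema_config)
    unknown = set(mapping) - set(CANONICAL_COLUMNS)
    if unknown:
        raise SchemaError(f"unknown canonical keys in mapping: {sorted(unknown)}")
    colmap = {}
    for canon in CANONICAL_COLUMNS:
        src = mapping.get(canon, canon)
        if src in raw.columns:
            colmap[canon] = src
        elif canon in mapping:
            raise SchemaError(f"mapped column {src!r} (for {canon!r}) not in file")
    missing = [c for c in REQUIRED_COLUMNS if c not in colmap]
    if missing:
        raise SchemaError(f"required columns missing from {path.name}: {missing}")
    if "bmi" not in colmap and not {"height", "weight"} <= set(colmap):
        raise SchemaError("need either a bmi column or both height and weight")

    records: list[dict] = []
    exclusions: list[tuple[str, str]] = []
    seen_ids: set[str] = set()
    for i, row in raw.iterrows():
        rid = str(row[colmap["id"]]) if "id" in colmap else f"row{i + 1}"
        if rid in seen_ids:
            exclusions.append((rid, "duplicate_id"))
            continue

        reason = None
        rec: dict = {"id": rid}
        try:
            rec["sex"] = _SEX_LABELS[str(row[colmap["sex"]]).strip().lower()]
        except KeyError:
            reason = "unparseable_sex"
        if reason is None:
            try:
                age = _parse_float(row[colmap["age"]])
                if age is None:
                    raise ValueError
                rec["age"] = age
            except (ValueError, TypeError):
                reason = "unparseable_age"
        if reason is None:
            try:
                bmi = _parse_float(row[colmap["bmi"]]) if "bmi" in colmap else None
                height = _parse_float(row[colmap["height"]]) if "height" in colmap else None
                weight = _parse_float(row[colmap["weight"]]) if "weight" in colmap else None
                if height is not None and weight is not None:
                    derived = bmi_from_weight_height(weight, height)
                    if bmi is None:
                        bmi = derived
                    elif abs(bmi - derived) > BMI_CONSISTENCY_TOL:
                        reason = "bmi_inconsistent_with_height_weight"
                if reason is None and bmi is None:
                    reason = "missing_bmi"
                rec["bmi"], rec["height"], rec["weight"] = bmi, height, weight
            except (ValueError, TypeError):
                reason = "unparseable_bmi"
        if reason is None and "pregnant" in colmap:
            try:
                if _parse_bool(row[colmap["pregnant"]]):
                    reason = "pregnant"
            except ValueError:
                reason = "unparseable_pregnant"
        if reason is None:
            ok_age = rec["age"] >= min_age if age_inclusive else rec["age"] > min_age
            if not ok_age:
                reason = f"under_{min_age:g}"
            elif rec["bmi"] < min_bmi:
                reason = f"bmi_below_{min_bmi:g}"
        if reason is None:
            for canon in ("hypertension", "diabetes"):
                if canon in colmap:
                    try:
                        rec[canon] = _parse_bool(row[colmap[canon]])
                    except ValueError:
                        reason = f"unparseable_{canon}"
                        break

        if reason is not None:
            exclusions.append((rid, reason))
            continue
        seen_ids.add(rid)
        # covariates are kept verbatim (possibly missing); complete-case
        # deletion happens at regression time, not at load
        for canon in ("education", "marital", "tobacco", "alcohol"):
            rec[canon] = row[colmap[canon]] if canon in colmap else None
        records.append(rec)

    columns = [
        "id", "sex", "age", "height", "weight", "bmi",
        "hypertension", "diabetes", "education", "marital", "tobacco", "alcohol",
    ]
    data = pd.DataFrame(records, columns=columns)
    return Cohort(data=data, provenance=str(path), exclusion_log=exclusions)


def write_cohort(cohort: Cohort, path) -> None:
    """Write the canonical cohort CSV (booleans as 0/1, UTF-8)."""
    out = cohort.data.copy()
    for col in ("hypertension", "diabetes"):
        if col in out.columns:
            out[col] = out[col].map({True: 1, False: 0})
    out.to_csv(path, index=False)


def write_exclusion_log(cohort: Cohort, path) -> None:
    pd.DataFrame(cohort.exclusion_log, columns=["id", "reason"]).to_csv(path, index=False)
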