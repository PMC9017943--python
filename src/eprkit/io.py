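"""Reading and writing delimited EPR extracts, catalogs and reference tables.

File dialect: UTF-8, comma-delimited, ISO-8601 dates, one row per
administration, empty cell = missing. The extract is denormalized: center
category/region travel on each row (as real pharmacy exports do), and the
centers table is rebuilt at load time. The extraction date is carried in a
JSON sidecar ``<path>.meta.json``; when absent it defaults to the latest
administration date in the file.

Loading never silently drops a row: every input row either becomes a record
or a fatal row error in the :class:`LoadReport` (rows with an unusable
administration date or blank center/patient identifiers are fatal, because
every downstream rule orders records by patient and date). Any other
unparseable or out-of-domain cell is set to missing and reported as a
field-level error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import (
    CATEGORIES,
    COLUMN_TYPES,
    COLUMNS,
    MANDATORY_COLUMNS,
    ORDER_COLUMN,
    REGIONS,
    DrugCatalog,
    ExtractTable,
    SchemaError,
)
from ._text import normalize_text

_INT_DOMAIN = {
    "birth_year": (1900, 2100),
    "ecog": (0, 4),
    "treatment_line": (1, None),
    "cycle_number": (1, None),
    "frequency_days": (1, None),
    "estimated_duration_days": (0, None),
}


@dataclass
class LoadReport:
    """Row accounting for one extract load."""

    path: str
    n_rows: int = 0
    n_records: int = 0
    fatal_rows: list[dict] = field(default_factory=list)
    field_errors: list[dict] = field(default_factory=list)

    @property
    def n_fatal_rows(self) -> int:
        return len(self.fatal_rows)

    @property
    def n_field_errors(self) -> int:
        return len(self.field_errors)

    def check_conservation(self) -> None:
        assert self.n_rows == self.n_records + self.n_fatal_rows

    def to_json(self) -> dict:
        return {
            "path": self.path,
            "n_rows": self.n_rows,
            "n_records": self.n_records,
            "n_fatal_rows": self.n_fatal_rows,
            "n_field_errors": self.n_field_errors,
            "fatal_rows": self.fatal_rows,
            "field_errors": self.field_errors,
        }


def _meta_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def _parse_typed(
    raw: pd.DataFrame, report: LoadReport
) -> pd.DataFrame:
    """Parse string cells into typed columns, recording field errors."""
    out = pd.DataFrame(index=raw.index)
    for col, kind in COLUMN_TYPES.items():
        if col not in raw.columns:
            if kind == "int":
                out[col] = pd.Series(pd.NA, index=raw.index, dtype="Int64")
            elif kind == "float":
                out[col] = np.nan
            elif kind == "date":
                out[col] = pd.NaT
            else:
                out[col] = pd.Series(pd.NA, index=raw.index, dtype="object")
            continue
        s = raw[col].astype(str).str.strip()
        blank = (s == "") | (s.str.lower() == "nan")
        if kind == "str":
            parsed = s.where(~blank, pd.NA)
            out[col] = parsed.astype("object")
            continue
        if kind == "date":
            parsed = pd.to_datetime(s.where(~blank), format="mixed", errors="coerce")
            bad = parsed.isna() & ~blank
        elif kind == "float":
            parsed = pd.to_numeric(s.where(~blank), errors="coerce")
            bad = parsed.isna() & ~blank
            if col == "dose_mg":
                nonpos = parsed.notna() & ~(parsed > 0)
                bad |= nonpos
                parsed = parsed.where(~nonpos)
        else:  # int
            parsed = pd.to_numeric(s.where(~blank), errors="coerce")
            nonint = parsed.notna() & (parsed != parsed.round())
            bad = (parsed.isna() & ~blank) | nonint
            parsed = parsed.where(~nonint)
            lo, hi = _INT_DOMAIN.get(col, (None, None))
            if lo is not None:
                oob = parsed.notna() & (parsed < lo)
                bad |= oob
                parsed = parsed.where(~oob)
            if hi is not None:
                oob = parsed.notna() & (parsed > hi)
                bad |= oob
                parsed = parsed.where(~oob)
            parsed = parsed.round().astype("Int64")
        for idx in raw.index[bad]:
            report.field_errors.append(
                {"row": int(idx), "column": col, "value": raw.at[idx, col],
                 "error": "unparseable or out-of-domain value; set to missing"}
            )
        out[col] = parsed.where(~bad) if bad.any() else parsed
        if kind == "float":
            out[col] = out[col].astype("float64")
    return out


def _normalize_enum(value, vocab: tuple[str, ...]) -> str | None:
    norm = normalize_text(None if pd.isna(value) else str(value))
    if norm is None:
        return None
    by_norm = {normalize_text(v): v for v in vocab}
    return by_norm.get(norm)


def _build_centers(records: pd.DataFrame, report: LoadReport) -> pd.DataFrame:
    rows = []
    for cid, sub in records.groupby("center_id", sort=True):
        cat_raw = sub["center_category"].dropna()
        reg_raw = sub["center_region"].dropna()
        cat = _normalize_enum(cat_raw.iloc[0], CATEGORIES) if len(cat_raw) else None
        reg = _normalize_enum(reg_raw.iloc[0], REGIONS) if len(reg_raw) else None
        if len(cat_raw) and cat is None:
            report.field_errors.append(
                {"row": None, "column": "center_category", "value": cat_raw.iloc[0],
                 "error": f"unknown category for center {cid}; set to missing"}
            )
        if len(reg_raw) and reg is None:
            report.field_errors.append(
                {"row": None, "column": "center_region", "value": reg_raw.iloc[0],
                 "error": f"unknown region for center {cid}; set to missing"}
            )
        rows.append({"center_id": str(cid), "category": cat, "region": reg})
    return pd.DataFrame(rows, columns=["center_id", "category", "region"], dtype="object")


def read_extract(
    path: str | Path, catalog: DrugCatalog | None = None
) -> tuple[ExtractTable, LoadReport]:
    """Load a delimited extract file.

    Returns the extract plus a :class:`LoadReport`. Missing mandatory columns
    raise :class:`SchemaError`; an empty file yields an empty extract. The
    ``catalog`` argument is accepted for interface symmetry with the writer
    and future per-load validation; codification itself is a separate step.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    report = LoadReport(path=str(path))
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raw = pd.DataFrame(columns=list(MANDATORY_COLUMNS))
    missing = [c for c in MANDATORY_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"extract {path} is missing mandatory columns: {missing}")
    report.n_rows = len(raw)

    records = _parse_typed(raw, report)

    # fatal rows: no usable administration date or blank identifiers
    fatal = records["administration_date"].isna()
    fatal |= records["center_id"].isna() | records["patient_id"].isna()
    for idx in records.index[fatal]:
        report.fatal_rows.append(
            {"row": int(idx),
             "error": "missing administration_date, center_id or patient_id"}
        )
    records = records.loc[~fatal].reset_index(drop=True)
    report.n_records = len(records)
    report.check_conservation()

    if records["record_id"].isna().any():
        gen = pd.Series(
            [f"r{i:07d}" for i in range(len(records))], index=records.index
        )
        records["record_id"] = records["record_id"].where(
            records["record_id"].notna(), gen
        )
    records[ORDER_COLUMN] = np.arange(len(records))

    centers = _build_centers(records, report)

    meta = _meta_path(path)
    if meta.exists():
        with open(meta, encoding="utf-8") as fh:
            extraction_date = date.fromisoformat(json.load(fh)["extraction_date"])
    elif records["administration_date"].notna().any():
        extraction_date = records["administration_date"].max().date()
    else:
        extraction_date = date.today()

    return ExtractTable(records, centers, extraction_date), report


def write_extract(extract: ExtractTable, path: str | Path) -> None:
    """Write an extract so that :func:`read_extract` round-trips it."""
    path = Path(path)
    df = extract.records.copy()
    lookup = extract.center_lookup()
    cid = df["center_id"].astype(str)
    df["center_category"] = [lookup.get(c, (None, None))[0] for c in cid]
    df["center_region"] = [lookup.get(c, (None, None))[1] for c in cid]
    out = pd.DataFrame(index=df.index)
    for col, kind in COLUMN_TYPES.items():
        s = df[col] if col in df.columns else pd.Series(pd.NA, index=df.index)
        if kind == "date":
            s = pd.to_datetime(s).dt.strftime("%Y-%m-%d")
            out[col] = s.where(s.notna(), "")
        elif kind == "int":
            out[col] = s.astype("Int64").astype(object).where(s.notna(), "")
        else:
            out[col] = s.where(s.notna(), "")
    out.to_csv(path, index=False)
    with open(_meta_path(path), "w", encoding="utf-8") as fh:
        json.dump({"extraction_date": extract.extraction_date.isoformat()}, fh)
        fh.write("\n")


# -- catalogs and reference tables ---------------------------------------


def _read_two_col(path, key: str, val: str) -> dict[str, str]:
    df = pd.read_csv(path, dtype=str)
    return dict(zip(df[key].str.strip(), df[val].str.strip()))


def _read_one_col(path, col: str) -> set[str]:
    df = pd.read_csv(path, dtype=str)
    return set(df[col].str.strip())


def default_catalog() -> DrugCatalog:
    """The drug catalog shipped with the package.

    The brand map and the other-cancer drug list are editable seed data
    (plain CSV under ``eprkit/data``), not an authoritative formulary.
    """
    root = resources.files("eprkit").joinpath("data")
    return DrugCatalog(
        inn_by_brand=_read_two_col(root / "drug_brands.csv", "brand", "inn"),
        other_cancer_drugs=_read_one_col(root / "other_cancer_drugs.csv", "inn"),
        drugs_of_interest=_read_one_col(root / "drugs_of_interest.csv", "inn"),
        inn_aliases=_read_two_col(root / "inn_aliases.csv", "alias", "inn"),
    )


def read_catalog(directory: str | Path) -> DrugCatalog:
    """Load a catalog from a directory of CSVs (same layout as the shipped
    seed data; ``inn_aliases.csv`` optional)."""
    d = Path(directory)
    aliases_path = d / "inn_aliases.csv"
    return DrugCatalog(
        inn_by_brand=_read_two_col(d / "drug_brands.csv", "brand", "inn"),
        other_cancer_drugs=_read_one_col(d / "other_cancer_drugs.csv", "inn"),
        drugs_of_interest=_read_one_col(d / "drugs_of_interest.csv", "inn"),
        inn_aliases=_read_two_col(aliases_path, "alias", "inn")
        if aliases_path.exists()
        else {},
    )


def read_national_reference(path: str | Path):
    """Load a national reference table (columns: cancer, category, region,
    n, reference_year)."""
    from .assessment import NationalReference

    df = pd.read_csv(path, dtype={"cancer": str, "category": str, "region": str})
    year = int(df["reference_year"].iloc[0]) if len(df) else 0
    counts = df[["cancer", "category", "region", "n"]].copy()
    counts["n"] = counts["n"].astype(int)
    return NationalReference(counts=counts, reference_year=year)


def write_national_reference(reference, path: str | Path) -> None:
    df = reference.counts.copy()
    df["reference_year"] = reference.reference_year
    df.to_csv(path, index=False)
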