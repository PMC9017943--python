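"""Data schema for multi-center electronic pharmacy record (EPR) extracts.

An extract is a flat table with one row per injectable-drug administration,
as exported by hospital pharmacy software. This module fixes the column
schema, the controlled vocabularies (center category, region, disease stage,
diagnosis, response, gender), the canonical within-patient ordering, and the
in-memory containers used throughout the pipeline: :class:`ExtractTable`,
:class:`DrugCatalog` and :class:`Center`.

Vocabulary conventions
----------------------
Disease stage uses a three-level coding ``early < locally_advanced <
metastatic`` ordered by severity; real EPR dialects write many variants
("métastatique", "stade IV", ...) which the standardization step maps onto
this vocabulary. Center categories are GH_NFPH (general and not-for-profit
hospitals), UH (university hospitals), CCC (comprehensive cancer centers)
and PH (private hospitals); regions are the six coarse geographic strata
used for coverage and representativeness auditing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

CATEGORIES = ("GH_NFPH", "UH", "CCC", "PH")
REGIONS = ("North", "East", "SouthEast", "SouthWest", "West", "ParisArea")
STAGES = ("early", "locally_advanced", "metastatic")
STAGE_SEVERITY = {s: i for i, s in enumerate(STAGES)}
DIAGNOSES = ("breast_cancer", "lung_cancer", "other")
RESPONSES = ("CR", "PR", "SD", "PD")
GENDERS = ("F", "M")

#: Exclusion rule identifiers, in precedence order. R1-R5 are applied by the
#: exclusion engine; R6 is applied after stage/line inference.
RULES = (
    "R1_truncated",
    "R2_name_mismatch",
    "R3_duplicate_injection",
    "R4_multi_primary",
    "R5_other_cancer_drug",
    "R6_stage_unresolved",
)

MATCH_STATUSES = ("matched", "inn_only", "brand_conflict", "unknown_drug")

# column -> parse kind; order defines the on-disk column order
COLUMN_TYPES: dict[str, str] = {
    "record_id": "str",
    "center_id": "str",
    "center_category": "str",
    "center_region": "str",
    "patient_id": "str",
    "birth_year": "int",
    "gender": "str",
    "weight_kg": "float",
    "height_cm": "float",
    "ecog": "int",
    "diagnosis": "str",
    "disease_stage": "str",
    "metastasis_sites": "str",
    "oncogenic_driver": "str",
    "drug_raw": "str",
    "drug_inn": "str",
    "drug_brand": "str",
    "drug_match_status": "str",
    "dose_mg": "float",
    "administration_date": "date",
    "treatment_line": "int",
    "cycle_number": "int",
    "frequency_days": "int",
    "regimen_label": "str",
    "estimated_duration_days": "int",
    "response": "str",
    "response_date": "date",
    "discontinuation_motive": "str",
    "discontinuation_date": "date",
    "trial_name": "str",
}

COLUMNS = tuple(COLUMN_TYPES)

#: Columns that must be present in the header of an extract file.
MANDATORY_COLUMNS = (
    "center_id",
    "patient_id",
    "drug_raw",
    "dose_mg",
    "administration_date",
)

#: Internal bookkeeping column holding the original row order (tie-break key).
ORDER_COLUMN = "_order"


class SchemaError(ValueError):
    """The extract file does not conform to the documented schema."""


@dataclass(frozen=True)
class Center:
    """One participating medical center."""

    center_id: str
    category: str | None = None
    region: str | None = None

    def __post_init__(self) -> None:
        if self.category is not None and self.category not in CATEGORIES:
            raise SchemaError(f"unknown center category: {self.category!r}")
        if self.region is not None and self.region not in REGIONS:
            raise SchemaError(f"unknown center region: {self.region!r}")


@dataclass
class DrugCatalog:
    """Drug reference data used for codification and exclusion.

    Parameters
    ----------
    inn_by_brand
        Brand name -> INN map. Every brand maps to exactly one INN.
    other_cancer_drugs
        INNs specific to cancers other than the cohorts of interest; one
        administration of any of them removes the patient (rule R5).
    drugs_of_interest
        The cohort-defining INNs; every retained patient received at least
        one of them.
    inn_aliases
        Optional spelling variants ("trastuzumab emtansin", "T-DM1", ...)
        mapped onto canonical INNs.
    """

    inn_by_brand: dict[str, str]
    other_cancer_drugs: set[str]
    drugs_of_interest: set[str]
    inn_aliases: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = self.drugs_of_interest & self.other_cancer_drugs
        if overlap:
            raise SchemaError(
                f"drugs of interest listed as other-cancer drugs: {sorted(overlap)}"
            )

    @property
    def known_inns(self) -> set[str]:
        """Every INN the catalog can resolve."""
        return (
            set(self.inn_by_brand.values())
            | self.other_cancer_drugs
            | self.drugs_of_interest
            | set(self.inn_aliases.values())
        )


def empty_records() -> pd.DataFrame:
    """Return an empty records DataFrame with the full typed schema."""
    data: dict[str, pd.Series] = {}
    for col, kind in COLUMN_TYPES.items():
        if kind == "int":
            data[col] = pd.Series(dtype="Int64")
        elif kind == "float":
            data[col] = pd.Series(dtype="float64")
        elif kind == "date":
            data[col] = pd.Series(dtype="datetime64[ns]")
        else:
            data[col] = pd.Series(dtype="object")
    df = pd.DataFrame(data)
    df[ORDER_COLUMN] = pd.Series(dtype="int64")
    return df


def canonical_sort(records: pd.DataFrame) -> pd.DataFrame:
    """Sort records into the canonical deterministic order.

    Keys: center, patient, administration date, INN (lexical, missing last),
    cycle number, then original row order. All downstream rules assume this
    ordering; same-day ties are therefore reproducible across runs.
    """
    if ORDER_COLUMN not in records.columns:
        records = records.copy()
        records[ORDER_COLUMN] = np.arange(len(records))
    out = records.sort_values(
        by=[
            "center_id",
            "patient_id",
            "administration_date",
            "drug_inn",
            "cycle_number",
            ORDER_COLUMN,
        ],
        kind="stable",
        na_position="last",
    )
    return out.reset_index(drop=True)


def patient_keys(records: pd.DataFrame) -> pd.Series:
    """``center_id|patient_id`` key for each record (patient ids are only
    unique within a center)."""
    return records["center_id"].astype(str) + "|" + records["patient_id"].astype(str)


@dataclass
class ExtractTable:
    """A multi-center collection of administration records plus center metadata.

    ``records`` follows the schema in :data:`COLUMN_TYPES`; ``centers`` has
    columns ``center_id``, ``category``, ``region``.
    """

    records: pd.DataFrame
    centers: pd.DataFrame
    extraction_date: date

    def __post_init__(self) -> None:
        if ORDER_COLUMN not in self.records.columns:
            self.records = self.records.copy()
            self.records[ORDER_COLUMN] = np.arange(len(self.records))

    # -- basic accessors ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_patients(self) -> int:
        if self.records.empty:
            return 0
        return patient_keys(self.records).nunique()

    def sorted(self) -> "ExtractTable":
        """Return a copy with records in canonical order."""
        return ExtractTable(
            canonical_sort(self.records), self.centers.copy(), self.extraction_date
        )

    def iter_patients(self) -> Iterator[tuple[str, pd.DataFrame]]:
        """Yield ``(patient_key, records)`` with records in canonical order."""
        rec = canonical_sort(self.records)
        keys = patient_keys(rec)
        for key, sub in rec.groupby(keys.values, sort=True):
            yield key, sub

    def patient_cancers(self) -> pd.Series:
        """Primary cancer per patient: first non-missing diagnosis in
        canonical order, ``"unknown"`` if never recorded."""
        rec = canonical_sort(self.records)
        keys = patient_keys(rec)
        diag = rec["diagnosis"]

        def first_diag(s: pd.Series) -> str:
            nonnull = s.dropna()
            return str(nonnull.iloc[0]) if len(nonnull) else "unknown"

        if rec.empty:
            return pd.Series(dtype="object")
        return diag.groupby(keys.values, sort=True).apply(first_diag)

    def subset_patients(self, keys_to_keep: set[str]) -> "ExtractTable":
        """Restrict to the given ``center|patient`` keys (centers kept)."""
        mask = patient_keys(self.records).isin(keys_to_keep)
        return ExtractTable(
            self.records.loc[mask].reset_index(drop=True),
            self.centers.copy(),
            self.extraction_date,
        )

    def subset_by_cancer(self, cancer: str) -> "ExtractTable":
        cancers = self.patient_cancers()
        keep = set(cancers.index[cancers == cancer])
        return self.subset_patients(keep)

    def center_lookup(self) -> Mapping[str, tuple[str | None, str | None]]:
        """center_id -> (category, region), missing values as None."""
        out: dict[str, tuple[str | None, str | None]] = {}
        for row in self.centers.itertuples(index=False):
            cat = None if pd.isna(row.category) else str(row.category)
            reg = None if pd.isna(row.region) else str(row.region)
            out[str(row.center_id)] = (cat, reg)
        return out

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        """Check the structural invariants; raise :class:`SchemaError`."""
        rec = self.records
        missing_cols = [c for c in COLUMNS if c not in rec.columns]
        if missing_cols:
            raise SchemaError(f"records missing columns: {missing_cols}")
        if self.centers["center_id"].duplicated().any():
            raise SchemaError("duplicate center_id in centers table")
        known = set(self.centers["center_id"].astype(str))
        used = set(rec["center_id"].dropna().astype(str))
        orphans = used - known
        if orphans:
            raise SchemaError(f"records reference unknown centers: {sorted(orphans)}")
        if rec["administration_date"].isna().any():
            raise SchemaError("administration_date must be present on every record")
        bad_dose = rec["dose_mg"].notna() & ~(rec["dose_mg"] > 0)
        if bad_dose.any():
            raise SchemaError("dose_mg must be positive when present")


def centers_frame(centers: list[Center]) -> pd.DataFrame:
    """Build the centers table from :class:`Center` objects."""
    return pd.DataFrame(
        {
            "center_id": [c.center_id for c in centers],
            "category": [c.category for c in centers],
            "region": [c.region for c in centers],
        },
        dtype="object",
    )
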