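"""Codification of free-text fields from heterogeneous EPR dialects.

Hospital pharmacy systems record drugs, stages, genders and responses as
free text with vendor- and language-specific spellings. This step maps them
onto the package's controlled vocabularies through data-driven synonym
tables (plain CSVs, French and English seeds shipped with the package) and
resolves drug names through the catalog's brand->INN map.

Matching is exact after normalization (case, whitespace, diacritics) — no
fuzzy string distance. Unknown values surface in the codification report as
``unknown_drug`` / unmapped counts instead of being silently miscoded. No
record is ever dropped here; patient removal is the exclusion engine's job.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from ._text import normalize_text
from .schema import DrugCatalog, ExtractTable

MATCHED = "matched"
INN_ONLY = "inn_only"
BRAND_CONFLICT = "brand_conflict"
UNKNOWN_DRUG = "unknown_drug"


@dataclass
class SynonymTables:
    """Normalized-text -> canonical-code maps for the coded fields."""

    stage: dict[str, str]
    gender: dict[str, str]
    response: dict[str, str]
    diagnosis: dict[str, str]

    @classmethod
    def default(cls) -> "SynonymTables":
        root = resources.files("eprkit").joinpath("data")

        def load(name: str, value_col: str) -> dict[str, str]:
            df = pd.read_csv(root / name, dtype=str)
            return {
                normalize_text(k): v
                for k, v in zip(df["text"], df[value_col])
            }

        return cls(
            stage=load("stage_synonyms.csv", "stage"),
            gender=load("gender_synonyms.csv", "gender"),
            response=load("response_synonyms.csv", "response"),
            diagnosis=load("diagnosis_synonyms.csv", "diagnosis"),
        )


@dataclass
class CodificationReport:
    """Per-status drug match counts and per-field mapping counts."""

    n_records: int = 0
    drug_status_counts: dict[str, int] = field(
        default_factory=lambda: {
            MATCHED: 0, INN_ONLY: 0, BRAND_CONFLICT: 0, UNKNOWN_DRUG: 0
        }
    )
    field_mapped: dict[str, int] = field(default_factory=dict)
    field_unmapped: dict[str, int] = field(default_factory=dict)

    def check_conservation(self) -> None:
        assert sum(self.drug_status_counts.values()) == self.n_records

    def to_json(self) -> dict:
        return {
            "n_records": self.n_records,
            "drug_status_counts": dict(self.drug_status_counts),
            "field_mapped": dict(self.field_mapped),
            "field_unmapped": dict(self.field_unmapped),
        }


def _norm_maps(catalog: DrugCatalog):
    """Pre-normalized lookup maps: (name->INN incl. aliases, brand->INN)."""
    inns = {normalize_text(i): i for i in catalog.known_inns}
    inns.update({normalize_text(a): i for a, i in catalog.inn_aliases.items()})
    brands = {normalize_text(b): i for b, i in catalog.inn_by_brand.items()}
    return inns, brands


def _resolve_drug(raw, brand, inns, brands) -> tuple[str | None, str]:
    nraw = normalize_text(None if pd.isna(raw) else raw)
    nbrand = normalize_text(None if pd.isna(brand) else brand)
    raw_inn, via_brand = None, False
    if nraw is not None:
        if nraw in inns:
            raw_inn = inns[nraw]
        elif nraw in brands:
            raw_inn, via_brand = brands[nraw], True
    brand_inn = brands.get(nbrand) if nbrand is not None else None
    if raw_inn is None and brand_inn is None:
        return None, UNKNOWN_DRUG
    if raw_inn is None:
        return brand_inn, MATCHED
    if brand_inn is None:
        return raw_inn, MATCHED if via_brand else INN_ONLY
    return raw_inn, MATCHED if brand_inn == raw_inn else BRAND_CONFLICT


def normalize_drug(
    raw_name: str | None,
    brand_field: str | None,
    catalog: DrugCatalog,
) -> tuple[str | None, str]:
    """Resolve a free-text drug name to an INN.

    The raw name may be an INN, an alias spelling, or a brand name; the
    optional brand field is resolved through the brand map. Status:

    - ``matched``: INN resolved with brand evidence in agreement (the raw
      name was itself a brand, or the brand field maps to the same INN);
    - ``inn_only``: INN resolved, no usable brand evidence;
    - ``brand_conflict``: the brand field maps to a *different* INN than the
      one recorded/parsed — the removal trigger behind rule R2;
    - ``unknown_drug``: nothing resolved; never raises.
    """
    inns, brands = _norm_maps(catalog)
    return _resolve_drug(raw_name, brand_field, inns, brands)


def codify_extract(
    extract: ExtractTable,
    catalog: DrugCatalog,
    synonyms: SynonymTables | None = None,
) -> tuple[ExtractTable, CodificationReport]:
    """Codify every record: fill ``drug_inn``/``drug_match_status`` and map
    stage, gender, response and diagnosis onto the fixed vocabularies.

    Idempotent (canonical codes are their own synonyms) and conservative:
    the output has exactly the input's records; unresolved values are left
    missing and counted in the report.
    """
    synonyms = synonyms or SynonymTables.default()
    rec = extract.records.copy()
    report = CodificationReport(n_records=len(rec))

    inns, brands = _norm_maps(catalog)
    resolved = [
        _resolve_drug(r, b, inns, brands)
        for r, b in zip(rec["drug_raw"], rec["drug_brand"])
    ]
    rec["drug_inn"] = pd.Series(
        [inn for inn, _ in resolved], index=rec.index, dtype="object"
    )
    rec["drug_match_status"] = pd.Series(
        [st for _, st in resolved], index=rec.index, dtype="object"
    )
    for _, st in resolved:
        report.drug_status_counts[st] += 1

    field_tables = {
        "disease_stage": synonyms.stage,
        "gender": synonyms.gender,
        "response": synonyms.response,
        "diagnosis": synonyms.diagnosis,
    }
    for col, table in field_tables.items():
        mapped = unmapped = 0
        values = []
        for v in rec[col]:
            norm = normalize_text(None if pd.isna(v) else v)
            if norm is None:
                values.append(pd.NA)
            elif norm in table:
                values.append(table[norm])
                mapped += 1
            else:
                values.append(pd.NA)
                unmapped += 1
        rec[col] = pd.Series(values, index=rec.index, dtype="object")
        report.field_mapped[col] = mapped
        report.field_unmapped[col] = unmapped

    report.check_conservation()
    out = ExtractTable(rec, extract.centers.copy(), extract.extraction_date)
    return out, report
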