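"""Shared fixtures: catalogs, synonym tables, a session-wide synthetic
pipeline run, and a builder for hand-crafted patient record frames."""

from __future__ import annotations

from datetime import date

import numpy as np
import pandas as pd
import pytest

from eprkit.io import default_catalog
from eprkit.inference import run_inference
from eprkit.exclusions import apply_exclusions
from eprkit.schema import COLUMN_TYPES, ExtractTable, ORDER_COLUMN, centers_frame, Center
from eprkit.standardize import SynonymTables, codify_extract
from eprkit.synthetic import SyntheticConfig, generate_extract


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def synonyms():
    return SynonymTables.default()


def build_records(rows: list[dict]) -> pd.DataFrame:
    """Build a full-schema records frame from sparse row dicts.

    Unspecified fields are missing; ``record_id`` defaults to the row
    index, dates may be given as ISO strings.
    """
    if not rows:
        from eprkit.schema import empty_records

        return empty_records()
    full = []
    for i, row in enumerate(rows):
        base = {col: None for col in COLUMN_TYPES}
        base["record_id"] = f"t{i:04d}"
        base["center_id"] = "C001"
        base["patient_id"] = "P0001"
        base["drug_raw"] = "trastuzumab"
        base["dose_mg"] = 100.0
        base.update(row)
        full.append(base)
    df = pd.DataFrame(full)
    for col, kind in COLUMN_TYPES.items():
        if kind == "int":
            df[col] = pd.array(
                [pd.NA if pd.isna(v) else int(v) for v in df[col]], dtype="Int64"
            )
        elif kind == "float":
            df[col] = pd.to_numeric(df[col], errors="coerce").astype("float64")
        elif kind == "date":
            df[col] = pd.to_datetime(df[col])
        else:
            df[col] = pd.Series(
                [pd.NA if pd.isna(v) else str(v) for v in df[col]],
                index=df.index, dtype="object",
            )
    df[ORDER_COLUMN] = np.arange(len(df))
    return df


def build_extract(rows: list[dict], centers: list[Center] | None = None) -> ExtractTable:
    records = build_records(rows)
    if centers is None:
        ids = sorted(set(records["center_id"].astype(str)))
        centers = [Center(i, "CCC", "ParisArea") for i in ids]
    return ExtractTable(records, centers_frame(centers), date(2020, 1, 1))


@pytest.fixture
def records_builder():
    return build_records


@pytest.fixture
def extract_builder():
    return build_extract


@pytest.fixture(scope="session")
def synthetic_run(catalog):
    """One full pipeline run on the default synthetic cohort (600 patients)."""
    config = SyntheticConfig(seed=20240131 % 1000)
    extract, truth = generate_extract(config, catalog)
    codified, cod_report = codify_extract(extract, catalog)
    cleaned, flow = apply_exclusions(codified, catalog)
    analyzable, flow, audit = run_inference(cleaned, flow)
    return {
        "config": config,
        "extract": extract,
        "truth": truth,
        "codified": codified,
        "cod_report": cod_report,
        "cleaned": cleaned,
        "flow": flow,
        "analyzable": analyzable,
        "audit": audit,
    }
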