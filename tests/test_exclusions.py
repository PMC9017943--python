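"""Five-rule exclusion engine and flow-chart accounting."""

from __future__ import annotations

from collections import Counter

import pytest
from scipy import stats

from eprkit.exclusions import (
    apply_exclusions,
    detect_other_cancer_treatment,
    detect_truncated_start,
    PreconditionError,
)
from eprkit.schema import DrugCatalog
from eprkit.standardize import codify_extract
from eprkit.synthetic import SyntheticConfig, generate_extract


def _cycles(records_builder, cycles, dates=None):
    rows = []
    for i, c in enumerate(cycles):
        rows.append(
            {
                "administration_date": dates[i] if dates else f"2019-0{i + 1}-01",
                "cycle_number": c,
                "drug_inn": "trastuzumab",
            }
        )
    return records_builder(rows)


@pytest.mark.parametrize(
    "cycles,expected",
    [
        ([4, 5, 6], True),     # history starts mid-regimen
        ([1, 2, 3], False),    # complete start
        ([None, None], False),  # cannot assert truncation without cycles
        ([None, 2, 3], True),  # smallest observed cycle in first episode is 2
    ],
)
def test_detect_truncated_start(records_builder, cycles, expected):
    assert detect_truncated_start(_cycles(records_builder, cycles)) is expected


def test_truncation_judged_on_first_episode_only(records_builder):
    """A later regimen legitimately restarts cycle numbering above 1 after
    a drug switch; only the first episode's cycles matter."""
    rows = [
        {"administration_date": "2019-01-01", "cycle_number": 1,
         "drug_inn": "trastuzumab"},
        {"administration_date": "2019-01-22", "cycle_number": 2,
         "drug_inn": "trastuzumab"},
        # second episode (different drug set) observed from cycle 3
        {"administration_date": "2019-02-12", "cycle_number": 3,
         "drug_inn": "trastuzumab emtansine"},
    ]
    assert detect_truncated_start(records_builder(rows)) is False


def test_detect_other_cancer_treatment(records_builder, catalog):
    listed = records_builder(
        [{"administration_date": "2019-01-01", "drug_inn": "rituximab"}]
    )
    assert detect_other_cancer_treatment(listed, catalog) is True
    unlisted = records_builder(
        [
            {"administration_date": "2019-01-01", "drug_inn": "trastuzumab"},
            {"administration_date": "2019-01-01", "drug_inn": "paclitaxel"},
        ]
    )
    assert detect_other_cancer_treatment(unlisted, catalog) is False
    empty_list = DrugCatalog(
        inn_by_brand={"Mabthera": "rituximab"},
        other_cancer_drugs=set(),
        drugs_of_interest={"trastuzumab"},
    )
    assert detect_other_cancer_treatment(listed, empty_list) is False


def _six_patient_extract(extract_builder):
    """One unambiguous violation of each rule R1-R5 plus one clean patient."""
    rows = []

    def patient(pid, specs):
        for spec in specs:
            rows.append({"patient_id": pid, "diagnosis": "breast_cancer", **spec})

    patient("TRUNC", [
        {"administration_date": "2019-01-01", "drug_raw": "trastuzumab",
         "cycle_number": 4},
        {"administration_date": "2019-01-22", "drug_raw": "trastuzumab",
         "cycle_number": 5},
    ])
    patient("BRAND", [
        {"administration_date": "2019-01-01", "drug_raw": "trastuzumab",
         "drug_brand": "Avastin", "cycle_number": 1},
    ])
    patient("DUP", [
        {"administration_date": "2019-01-01", "drug_raw": "trastuzumab",
         "cycle_number": 1},
        {"administration_date": "2019-01-01", "drug_raw": "trastuzumab",
         "cycle_number": 1},
    ])
    patient("MULTI", [
        {"administration_date": "2019-01-01", "drug_raw": "trastuzumab",
         "cycle_number": 1},
        {"administration_date": "2019-01-22", "drug_raw": "trastuzumab",
         "cycle_number": 2, "diagnosis": "lung_cancer"},
    ])
    patient("OTHER", [
        {"administration_date": "2019-01-01", "drug_raw": "trastuzumab",
         "cycle_number": 1},
        {"administration_date": "2019-01-22", "drug_raw": "rituximab",
         "cycle_number": 1},
    ])
    patient("CLEAN", [
        {"administration_date": "2019-01-01", "drug_raw": "trastuzumab",
         "cycle_number": 1},
        {"administration_date": "2019-01-22", "drug_raw": "trastuzumab",
         "cycle_number": 2},
    ])
    return extract_builder(rows)


def test_apply_exclusions_six_patient_fixture(catalog, extract_builder):
    extract = _six_patient_extract(extract_builder)
    codified, _ = codify_extract(extract, catalog)
    kept, flow = apply_exclusions(codified, catalog)
    assert flow.n_extracted == 6
    assert flow.n_analyzable == 1
    assert flow.excluded_by_rule() == {
        "R1_truncated": 1,
        "R2_name_mismatch": 1,
        "R3_duplicate_injection": 1,
        "R4_multi_primary": 1,
        "R5_other_cancer_drug": 1,
    }
    flow.check_conservation()
    assert kept.n_patients == 1


def test_rule_precedence_r1_before_r3(catalog, extract_builder):
    """A patient violating both R1 and R3 is counted once, under R1."""
    extract = extract_builder([
        {"administration_date": "2019-01-01", "drug_raw": "trastuzumab",
         "cycle_number": 3},
        {"administration_date": "2019-01-01", "drug_raw": "trastuzumab",
         "cycle_number": 3},
    ])
    codified, _ = codify_extract(extract, catalog)
    _, flow = apply_exclusions(codified, catalog)
    assert flow.excluded_by_rule() == {"R1_truncated": 1}


def test_uncodified_extract_rejected(extract_builder, catalog):
    extract = extract_builder(
        [{"administration_date": "2019-01-01", "drug_raw": "trastuzumab"}]
    )
    with pytest.raises(PreconditionError):
        apply_exclusions(extract, catalog)


def test_truncation_count_is_binomial(catalog):
    """With only truncation injected at rate 0.1, the R1 count lies in the
    exact binomial 99% interval for n = 1,000 patients."""
    config = SyntheticConfig(
        seed=11,
        n_centers_by_stratum={("CCC", "ParisArea"): 5},
        patients_per_center=200,
        truncation_rate=0.1,
        duplicate_injection_rate=0.0,
        brand_mismatch_rate=0.0,
        multi_primary_rate=0.0,
        other_drug_contamination_rate=0.0,
    )
    extract, truth = generate_extract(config, catalog)
    codified, _ = codify_extract(extract, catalog)
    _, flow = apply_exclusions(codified, catalog)
    r1 = flow.excluded_by_rule().get("R1_truncated", 0)
    lo = stats.binom.ppf(0.005, 1000, 0.1)
    hi = stats.binom.ppf(0.995, 1000, 0.1)
    assert lo <= r1 <= hi
    # and the engine finds exactly the injected patients
    injected = Counter(truth.error_rule_by_patient.values())
    assert r1 == injected["R1_truncated"]


def test_adding_clean_patient_changes_no_exclusion_count(catalog, extract_builder):
    extract = _six_patient_extract(extract_builder)
    codified, _ = codify_extract(extract, catalog)
    _, flow_before = apply_exclusions(codified, catalog)

    import numpy as np
    import pandas as pd

    from eprkit.schema import ExtractTable, ORDER_COLUMN

    rows = list(codified.records.to_dict(orient="records"))
    extra = dict(rows[-1])
    extra.update({
        "patient_id": "CLEAN2", "record_id": "x9999",
        "administration_date": pd.Timestamp("2019-03-01"), "cycle_number": 1,
    })
    rec = pd.concat(
        [codified.records, pd.DataFrame([extra])], ignore_index=True
    )
    rec[ORDER_COLUMN] = np.arange(len(rec))
    bigger = ExtractTable(rec, codified.centers, codified.extraction_date)
    _, flow_after = apply_exclusions(bigger, catalog)
    assert flow_after.excluded_by_rule() == flow_before.excluded_by_rule()
    assert flow_after.n_analyzable == flow_before.n_analyzable + 1
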