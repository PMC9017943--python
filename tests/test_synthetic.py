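"""Generator determinism, clean-data limits, rate realization, and the
national reference construction."""

from __future__ import annotations

from collections import Counter

import pytest
from scipy import stats

from eprkit.assessment import coverage_rates, patient_counts_by_stratum
from eprkit.exclusions import apply_exclusions
from eprkit.io import write_extract
from eprkit.schema import patient_keys
from eprkit.standardize import codify_extract
from eprkit.synthetic import (
    SyntheticConfig,
    generate_extract,
    generate_national_reference,
)


def _clean_config(**overrides):
    base = dict(
        truncation_rate=0.0, duplicate_injection_rate=0.0,
        brand_mismatch_rate=0.0, multi_primary_rate=0.0,
        other_drug_contamination_rate=0.0,
        stage_missing_rate_bc=0.0, stage_missing_rate_lc=0.0,
        line_missing_rate_bc=0.0, line_missing_rate_lc=0.0,
        stage_record_dropout=0.0, stage_regression_rate=0.0,
        line_record_dropout=0.0, line_conflict_rate=0.0,
        uninformative_label_rate=0.0,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


def test_seed_determinism_byte_identical(tmp_path, catalog):
    config = SyntheticConfig(seed=5, patients_per_center=8)
    a, _ = generate_extract(config, catalog)
    b, _ = generate_extract(SyntheticConfig(seed=5, patients_per_center=8), catalog)
    pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
    write_extract(a, pa)
    write_extract(b, pb)
    assert pa.read_bytes() == pb.read_bytes()
    c, _ = generate_extract(SyntheticConfig(seed=6, patients_per_center=8), catalog)
    pc = tmp_path / "c.csv"
    write_extract(c, pc)
    assert pa.read_bytes() != pc.read_bytes()


def test_clean_data_limit(catalog):
    """All error and missingness rates zero: the exclusion engine retains
    every patient and stage/line completion is total before inference."""
    config = _clean_config(
        seed=4, n_centers_by_stratum={("PH", "West"): 2}, patients_per_center=100
    )
    extract, truth = generate_extract(config, catalog)
    assert extract.n_patients == 200
    assert not truth.error_rule_by_patient
    codified, _ = codify_extract(extract, catalog)
    kept, flow = apply_exclusions(codified, catalog)
    assert flow.n_analyzable == 200
    assert flow.n_excluded == 0
    assert codified.records["disease_stage"].notna().all()
    assert codified.records["treatment_line"].notna().all()


def test_every_patient_gets_a_drug_of_interest(synthetic_run, catalog):
    codified = synthetic_run["codified"]
    keys = patient_keys(codified.records)
    has_doi = (
        codified.records["drug_inn"].isin(catalog.drugs_of_interest)
        .groupby(keys.values).any()
    )
    assert has_doi.all()


def test_stage_masking_rate_within_binomial_bounds(catalog):
    """Patient-level stage missingness realizes the configured 7% rate
    within the exact binomial 99% interval (5,000 BC patients)."""
    config = _clean_config(
        seed=13,
        n_centers_by_stratum={("CCC", "ParisArea"): 10},
        patients_per_center=500,
        cancer_mix=1.0,
        stage_missing_rate_bc=0.07,
    )
    extract, truth = generate_extract(config, catalog)
    n = extract.n_patients
    assert n == 5000
    keys = patient_keys(extract.records)
    missing = ~extract.records["disease_stage"].notna().groupby(keys.values).any()
    observed = int(missing.sum())
    assert observed == len(truth.stage_masked)
    lo = stats.binom.ppf(0.005, n, 0.07)
    hi = stats.binom.ppf(0.995, n, 0.07)
    assert lo <= observed <= hi


def test_injected_errors_all_detected(catalog):
    """Mutually exclusive injected errors: per-rule exclusion counts equal
    the injected counts exactly (sensitivity 1 by construction)."""
    config = SyntheticConfig(
        seed=8,
        n_centers_by_stratum={("UH", "East"): 2},
        patients_per_center=200,
        truncation_rate=0.05, duplicate_injection_rate=0.05,
        brand_mismatch_rate=0.05, multi_primary_rate=0.05,
        other_drug_contamination_rate=0.05,
    )
    extract, truth = generate_extract(config, catalog)
    codified, _ = codify_extract(extract, catalog)
    _, flow = apply_exclusions(codified, catalog)
    injected = Counter(truth.error_rule_by_patient.values())
    assert flow.excluded_by_rule() == dict(injected)


def test_zero_centers_empty_extract(catalog):
    config = SyntheticConfig(n_centers_by_stratum={}, seed=0)
    extract, truth = generate_extract(config, catalog)
    assert len(extract) == 0
    assert not truth.stage_by_record


def test_config_json_round_trip():
    config = SyntheticConfig(seed=9, patients_per_center=7)
    again = SyntheticConfig.from_json(config.to_json())
    assert again == config


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        SyntheticConfig(stage_missing_rate_bc=1.5).validate()
    with pytest.raises(ValueError):
        SyntheticConfig(n_centers_by_stratum={("XX", "North"): 1}).validate()


class TestNationalReference:
    def test_inflation_three_gives_one_third_coverage(self, catalog):
        config = _clean_config(
            seed=21,
            n_centers_by_stratum={
                ("CCC", "ParisArea"): 1, ("PH", "West"): 1, ("UH", "East"): 1
            },
            patients_per_center=300,
            cancer_mix=0.5,
        )
        reference = generate_national_reference(config, 3.0)
        extract, _ = generate_extract(config, catalog)
        codified, _ = codify_extract(extract, catalog)
        counts = patient_counts_by_stratum(codified)
        counts = counts[counts["cancer"].isin(["breast_cancer", "lung_cancer"])]
        report = coverage_rates(counts, reference, by=("category", "region"))
        for rate in report.table["coverage_rate"].dropna():
            assert rate == pytest.approx(1 / 3, rel=0.15)

    def test_inflation_close_to_one_approaches_full_coverage(self, catalog):
        config = _clean_config(
            seed=22, n_centers_by_stratum={("CCC", "West"): 1},
            patients_per_center=400,
        )
        reference = generate_national_reference(config, 1.0001)
        extract, _ = generate_extract(config, catalog)
        codified, _ = codify_extract(extract, catalog)
        counts = patient_counts_by_stratum(codified)
        counts = counts[counts["cancer"].isin(["breast_cancer", "lung_cancer"])]
        report = coverage_rates(counts, reference, by=("category",))
        total = report.totals["prm_count"].sum() / report.totals["national_count"].sum()
        assert total > 0.9

    def test_invalid_inflation_rejected(self):
        with pytest.raises(ValueError):
            generate_national_reference(SyntheticConfig(), 1.0)

    def test_stratified_shares_match_target_distribution(self, catalog):
        """Center counts proportional to the 46/22/10/22% category split
        reproduce those patient shares within one percentage point."""
        strata = {}
        for cat, n in (("GH_NFPH", 23), ("UH", 11), ("CCC", 5), ("PH", 11)):
            strata[(cat, "North")] = n
        config = _clean_config(
            seed=23, n_centers_by_stratum=strata, patients_per_center=20
        )
        extract, _ = generate_extract(config, catalog)
        codified, _ = codify_extract(extract, catalog)
        counts = patient_counts_by_stratum(codified)
        shares = counts.groupby("category")["n"].sum()
        shares = 100 * shares / shares.sum()
        targets = {"GH_NFPH": 46.0, "UH": 22.0, "CCC": 10.0, "PH": 22.0}
        for cat, target in targets.items():
            assert abs(shares[cat] - target) <= 1.0
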