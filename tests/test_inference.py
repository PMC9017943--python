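"""Stage and line completion/correction rules and their invariants."""

from __future__ import annotations

import pandas as pd
import pandas.testing as pdt
import pytest

from eprkit.exclusions import FlowChart, PreconditionError
from eprkit.inference import (
    InferenceAudit,
    infer_line,
    infer_stage,
    run_inference,
    stage_resolved,
)
from eprkit.schema import STAGE_SEVERITY, patient_keys


def _stages(records_builder, stages, labels=None, drug="trastuzumab"):
    rows = []
    for i, s in enumerate(stages):
        rows.append({
            "administration_date": f"2019-{i + 1:02d}-01",
            "drug_inn": drug,
            "disease_stage": s,
            "regimen_label": labels[i] if labels else None,
            "cycle_number": i + 1,
        })
    return records_builder(rows)


class TestStageRules:
    def test_s1_fills_within_regimen(self, records_builder):
        sub = _stages(records_builder, ["metastatic", None, None])
        out, audit = infer_stage(sub)
        assert list(out["disease_stage"]) == ["metastatic"] * 3
        assert {e["algorithm_id"] for e in audit.entries} == {"S1_fill_within_regimen"}
        assert len(audit) == 2

    def test_s1_prefers_backward_neighbor(self, records_builder):
        sub = _stages(records_builder, ["early", None, "metastatic"])
        out, audit = infer_stage(sub)
        # backward-first: the gap copies the earlier record's stage, and the
        # ratchet then has nothing to correct
        assert list(out["disease_stage"]) == ["early", "early", "metastatic"]

    def test_s2_uses_regimen_label_keyword(self, records_builder):
        labels = ["TRASTUZUMAB - métastatique"] * 3
        sub = _stages(records_builder, [None, None, None], labels=labels)
        out, audit = infer_stage(sub)
        assert list(out["disease_stage"]) == ["metastatic"] * 3
        assert {e["algorithm_id"] for e in audit.entries} == {"S2_regimen_keyword"}

    def test_s3_ratchet_corrects_regression(self, records_builder):
        sub = _stages(records_builder, ["early", "metastatic", "early"])
        out, audit = infer_stage(sub)
        assert list(out["disease_stage"]) == ["early", "metastatic", "metastatic"]
        entries = [e for e in audit.entries if e["algorithm_id"] == "S3_severity_ratchet"]
        assert len(entries) == 1
        assert entries[0]["before"] == "early"
        assert entries[0]["after"] == "metastatic"

    def test_unresolvable_patient_flagged_not_dropped(self, records_builder):
        sub = _stages(records_builder, [None, None])
        out, _ = infer_stage(sub)
        assert not stage_resolved(out)
        assert len(out) == 2


class TestLineRules:
    def _line_frame(self, records_builder, specs):
        """specs: (date, drug, stage, line, cycle)"""
        rows = []
        for date_, drug, stage, line, cycle in specs:
            rows.append({
                "administration_date": date_, "drug_inn": drug,
                "disease_stage": stage, "treatment_line": line,
                "cycle_number": cycle,
            })
        return records_builder(rows)

    def test_l2_increments_at_regimen_change(self, records_builder):
        sub = self._line_frame(records_builder, [
            ("2019-01-01", "trastuzumab", "metastatic", None, 1),
            ("2019-01-22", "trastuzumab", "metastatic", None, 2),
            ("2019-02-12", "trastuzumab emtansine", "metastatic", None, 1),
        ])
        out, audit = infer_line(sub)
        assert list(out["treatment_line"]) == [1, 1, 2]
        assert {e["algorithm_id"] for e in audit.entries} == {
            "L2_regimen_change_increment"
        }

    def test_l1_fills_from_regimen_line(self, records_builder):
        sub = self._line_frame(records_builder, [
            ("2019-01-01", "trastuzumab", "metastatic", 1, 1),
            ("2019-01-22", "trastuzumab", "metastatic", None, 2),
            ("2019-02-12", "trastuzumab emtansine", "metastatic", 2, 1),
        ])
        out, audit = infer_line(sub)
        assert list(out["treatment_line"]) == [1, 1, 2]
        l1 = [e for e in audit.entries if e["algorithm_id"] == "L1_fill_within_regimen"]
        assert len(l1) == 1

    def test_l3_forces_monotone_lines(self, records_builder):
        sub = self._line_frame(records_builder, [
            ("2019-01-01", "trastuzumab", "metastatic", 2, 1),
            ("2019-01-22", "trastuzumab emtansine", "metastatic", 1, 1),
        ])
        out, audit = infer_line(sub)
        assert list(out["treatment_line"]) == [2, 2]
        l3 = [e for e in audit.entries if e["algorithm_id"] == "L3_monotonic_correction"]
        assert len(l3) == 1

    def test_numbering_restarts_at_metastatic_transition(self, records_builder):
        sub = self._line_frame(records_builder, [
            ("2019-01-01", "trastuzumab", "early", None, 1),
            ("2019-02-01", "trastuzumab emtansine", "metastatic", None, 1),
            ("2019-03-01", "trastuzumab", "metastatic", None, 1),
        ])
        out, _ = infer_line(sub)
        assert list(out["treatment_line"]) == [1, 1, 2]

    def test_line_requires_resolved_stage(self, records_builder):
        sub = self._line_frame(records_builder, [
            ("2019-01-01", "trastuzumab", None, None, 1),
        ])
        with pytest.raises(PreconditionError):
            infer_line(sub)


class TestRunInference:
    def _flow_for(self, extract):
        cancers = extract.patient_cancers()
        flow = FlowChart()
        for cancer in cancers:
            flow.extracted[cancer] = flow.extracted.get(cancer, 0) + 1
            flow.analyzable[cancer] = flow.analyzable.get(cancer, 0) + 1
        return flow

    def test_unresolvable_patient_counted_under_r6(self, extract_builder):
        extract = extract_builder([
            {"administration_date": "2019-01-01", "drug_inn": "trastuzumab",
             "diagnosis": "breast_cancer"},
            {"administration_date": "2019-01-22", "drug_inn": "trastuzumab",
             "diagnosis": "breast_cancer"},
        ])
        out, flow, audit = run_inference(extract, self._flow_for(extract))
        assert flow.excluded_by_rule() == {"R6_stage_unresolved": 1}
        assert len(out) == 0
        flow.check_conservation()

    def test_audit_entry_per_change_and_idempotence(self, synthetic_run):
        analyzable = synthetic_run["analyzable"]
        audit = synthetic_run["audit"]
        # one audit entry per value changed from the pre-inference extract
        cleaned = synthetic_run["cleaned"].sorted()
        keys = set(patient_keys(analyzable.records))
        before = cleaned.records[patient_keys(cleaned.records).isin(keys)]
        after = analyzable.sorted().records
        changed = 0
        for col in ("disease_stage", "treatment_line"):
            b = before[col].reset_index(drop=True)
            a = after[col].reset_index(drop=True)
            changed += int((b.isna() & a.notna()).sum())
            both = b.notna() & a.notna()
            changed += int((b[both] != a[both]).sum())
        retained_entries = [
            e for e in audit.entries if e["patient"] in keys
        ]
        assert len(retained_entries) == changed

        # second pass changes nothing
        flow2 = FlowChart(
            extracted=dict(synthetic_run["flow"].analyzable),
            analyzable=dict(synthetic_run["flow"].analyzable),
        )
        again, flow2, audit2 = run_inference(analyzable, flow2)
        assert len(audit2) == 0
        pdt.assert_frame_equal(
            again.sorted().records.drop(columns="_order"),
            analyzable.sorted().records.drop(columns="_order"),
        )

    def test_stage_severity_monotone_after_inference(self, synthetic_run):
        rec = synthetic_run["analyzable"].sorted().records
        for _, sub in rec.groupby(patient_keys(rec).values, sort=False):
            sev = [STAGE_SEVERITY[s] for s in sub["disease_stage"]]
            assert sev == sorted(sev)

    def test_completion_total_after_inference(self, synthetic_run):
        rec = synthetic_run["analyzable"].records
        assert rec["disease_stage"].notna().all()
        assert rec["treatment_line"].notna().all()

    def test_ground_truth_recovery_on_masking_only(self, catalog):
        """With masking-only corruption, inference reproduces the truth on
        every retained patient (recoverable by construction)."""
        from eprkit.standardize import codify_extract
        from eprkit.exclusions import apply_exclusions
        from eprkit.synthetic import SyntheticConfig, generate_extract

        config = SyntheticConfig(
            seed=99, patients_per_center=25,
            truncation_rate=0.0, duplicate_injection_rate=0.0,
            brand_mismatch_rate=0.0, multi_primary_rate=0.0,
            other_drug_contamination_rate=0.0, uninformative_label_rate=0.0,
        )
        extract, truth = generate_extract(config, catalog)
        codified, _ = codify_extract(extract, catalog)
        cleaned, flow = apply_exclusions(codified, catalog)
        assert flow.n_excluded == 0
        analyzable, flow, _ = run_inference(cleaned, flow)
        assert flow.excluded_by_rule().get("R6_stage_unresolved", 0) == 0
        rec = analyzable.records
        stages = dict(zip(rec["record_id"], rec["disease_stage"]))
        lines = dict(zip(rec["record_id"], rec["treatment_line"]))
        mismatch_stage = sum(
            truth.stage_by_record[rid] != stages[rid] for rid in stages
        )
        mismatch_line = sum(
            truth.line_by_record[rid] != lines[rid] for rid in lines
        )
        assert mismatch_stage == 0
        assert mismatch_line == 0
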