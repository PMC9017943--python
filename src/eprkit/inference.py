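"""Completion and correction of disease stage and treatment line.

EPR systems record stage and line at the physician's discretion, so both
fields arrive incomplete. This module applies an auditable set of pluggable
rules that (1) retrieve the information from other entries of the same
patient, (2) check its consistency over time, and (3) derive it from
treatment-history features when absent. Each rule has a stable identifier
so individual rules can be replaced or audited in isolation:

Stage rules (run first, in order):

- ``S1_fill_within_regimen`` — a missing stage is copied from the nearest
  record of the same regimen episode that has one (looking backward first,
  then forward; only originally recorded values are used as sources);
- ``S2_regimen_keyword`` — a stage still missing is derived from the
  regimen label through a keyword table ("métastatique" -> metastatic,
  "adjuvant" -> early, ...; longest keyword wins);
- ``S3_severity_ratchet`` — disease stage cannot regress over time: a
  recorded stage strictly below the running maximum severity is corrected
  upward to it.

Line rules (run second; stage must be resolved first because line
numbering restarts when the patient enters the metastatic phase):

- ``L1_fill_within_regimen`` — a missing line is filled from the first
  recorded line of the same regimen episode;
- ``L2_regimen_change_increment`` — lines absent for a whole stage phase
  are assigned 1, 2, ... at each regimen-composition change (or after a
  treatment-free gap); an unlined episode inside a partially lined phase
  continues from the previous episode's line + 1;
- ``L3_monotonic_correction`` — lines are forced non-decreasing within a
  stage phase (violations raised to the running maximum).

Patients whose stage is still missing on some record after S1-S3 are
"unresolved": :func:`run_inference` removes them under flow-chart rule
R6_stage_unresolved, so the retained population has 100% stage and line
completion. Every modified field value is logged in the
:class:`InferenceAudit` (exactly one entry per change) for downstream
quality control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from ._text import normalize_text
from .exclusions import FlowChart, PreconditionError
from .regimens import DEFAULT_GAP_DAYS, segment_regimens
from .schema import (
    ExtractTable,
    STAGE_SEVERITY,
    STAGES,
    canonical_sort,
    patient_keys,
)

ALGORITHMS = (
    "S1_fill_within_regimen",
    "S2_regimen_keyword",
    "S3_severity_ratchet",
    "L1_fill_within_regimen",
    "L2_regimen_change_increment",
    "L3_monotonic_correction",
)

#: Phase boundary for line numbering: below metastatic vs metastatic.
_METASTATIC = STAGE_SEVERITY["metastatic"]


def default_stage_keywords() -> list[tuple[str, str]]:
    """(normalized keyword, stage) pairs, longest keyword first."""
    root = resources.files("eprkit").joinpath("data")
    df = pd.read_csv(root / "stage_keywords.csv", dtype=str)
    pairs = [(normalize_text(k), s) for k, s in zip(df["keyword"], df["stage"])]
    return sorted(pairs, key=lambda p: -len(p[0]))


def stage_from_label(label, keywords: list[tuple[str, str]]) -> str | None:
    norm = normalize_text(None if pd.isna(label) else label)
    if norm is None:
        return None
    for kw, stage in keywords:
        if kw in norm:
            return stage
    return None


@dataclass
class InferenceAudit:
    """Change log: one entry per modified field value."""

    entries: list[dict] = field(default_factory=list)

    def add(self, patient_key: str, record_id: str, algorithm_id: str,
            column: str, before, after) -> None:
        if algorithm_id not in ALGORITHMS:
            raise ValueError(f"unknown algorithm id {algorithm_id}")
        self.entries.append(
            {
                "patient": patient_key,
                "record_id": record_id,
                "algorithm_id": algorithm_id,
                "field": column,
                "before": None if before is None or pd.isna(before) else before,
                "after": after,
            }
        )

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.entries,
            columns=["patient", "record_id", "algorithm_id", "field",
                     "before", "after"],
        )

    def patients_touched(self, algorithm_id: str) -> list[str]:
        """Sorted patient keys with at least one change by the algorithm."""
        return sorted({
            e["patient"] for e in self.entries
            if e["algorithm_id"] == algorithm_id
        })

    def final_values(self) -> dict[tuple[str, str], object]:
        """(record_id, field) -> value after the *last* change; later rules
        may refine an earlier rule's fill, and QC judges the final value."""
        out: dict[tuple[str, str], object] = {}
        for e in self.entries:  # in application order
            out[(e["record_id"], e["field"])] = e["after"]
        return out


# -- stage ----------------------------------------------------------------


def infer_stage(
    patient_records: pd.DataFrame,
    gap_days: int = DEFAULT_GAP_DAYS,
    keywords: list[tuple[str, str]] | None = None,
    audit: InferenceAudit | None = None,
    patient_key: str | None = None,
) -> tuple[pd.DataFrame, InferenceAudit]:
    """Apply S1 -> S2 -> S3 to one patient's canonical-order records.

    Returns the records with ``disease_stage`` completed where possible and
    the audit. The patient is resolved iff no stage is missing afterwards.
    """
    audit = audit if audit is not None else InferenceAudit()
    keywords = keywords if keywords is not None else default_stage_keywords()
    sub = patient_records.copy()
    if patient_key is None:
        patient_key = (
            patient_keys(sub).iloc[0] if len(sub) else ""
        )
    n = len(sub)
    if n == 0:
        return sub, audit

    episodes = segment_regimens(sub, gap_days=gap_days)
    stages = sub["disease_stage"].astype("object").to_numpy(copy=True)
    original = stages.copy()
    rids = sub["record_id"].astype(str).to_numpy()
    labels = sub["regimen_label"].to_numpy()

    def present(v) -> bool:
        return not pd.isna(v)

    # S1: nearest originally-recorded stage within the episode
    for i in range(n):
        if present(original[i]):
            continue
        fill = None
        for j in range(i - 1, -1, -1):
            if episodes[j] != episodes[i]:
                break
            if present(original[j]):
                fill = original[j]
                break
        if fill is None:
            for j in range(i + 1, n):
                if episodes[j] != episodes[i]:
                    break
                if present(original[j]):
                    fill = original[j]
                    break
        if fill is not None:
            stages[i] = fill
            audit.add(patient_key, rids[i], "S1_fill_within_regimen",
                      "disease_stage", None, fill)

    # S2: derive from the regimen label keywords
    for i in range(n):
        if present(stages[i]):
            continue
        derived = stage_from_label(labels[i], keywords)
        if derived is not None:
            stages[i] = derived
            audit.add(patient_key, rids[i], "S2_regimen_keyword",
                      "disease_stage", None, derived)

    # S3: severity never decreases over time
    running = -1
    for i in range(n):
        if not present(stages[i]):
            continue
        sev = STAGE_SEVERITY[stages[i]]
        if sev < running:
            corrected = STAGES[running]
            before = stages[i]
            stages[i] = corrected
            audit.add(patient_key, rids[i], "S3_severity_ratchet",
                      "disease_stage", before, corrected)
        else:
            running = sev

    sub["disease_stage"] = pd.Series(stages, index=sub.index, dtype="object")
    return sub, audit


def stage_resolved(patient_records: pd.DataFrame) -> bool:
    return not patient_records["disease_stage"].isna().any()


# -- line -----------------------------------------------------------------


def infer_line(
    patient_records: pd.DataFrame,
    gap_days: int = DEFAULT_GAP_DAYS,
    audit: InferenceAudit | None = None,
    patient_key: str | None = None,
) -> tuple[pd.DataFrame, InferenceAudit]:
    """Apply L1 -> L2 -> L3 to one patient's canonical-order records.

    Stage inference must have run first (every record needs a stage to
    define its phase). Lines are positive integers, non-decreasing within
    a phase, and complete on output.
    """
    audit = audit if audit is not None else InferenceAudit()
    sub = patient_records.copy()
    if patient_key is None:
        patient_key = patient_keys(sub).iloc[0] if len(sub) else ""
    n = len(sub)
    if n == 0:
        return sub, audit
    if sub["disease_stage"].isna().any():
        raise PreconditionError("infer_line requires resolved disease stages")

    episodes = segment_regimens(sub, gap_days=gap_days)
    lines = sub["treatment_line"].astype("object").to_numpy(copy=True)
    rids = sub["record_id"].astype(str).to_numpy()
    sev = np.array([STAGE_SEVERITY[s] for s in sub["disease_stage"]])
    phase = (sev >= _METASTATIC).astype(np.int64)

    def present(v) -> bool:
        return not pd.isna(v)

    # L1: fill from the episode's first recorded line
    for ep in np.unique(episodes):
        idx = np.flatnonzero(episodes == ep)
        known = next((lines[i] for i in idx if present(lines[i])), None)
        if known is None:
            continue
        for i in idx:
            if not present(lines[i]):
                lines[i] = int(known)
                audit.add(patient_key, rids[i], "L1_fill_within_regimen",
                          "treatment_line", None, int(known))

    # L2: number episodes within each phase; a phase with no recorded line
    # gets 1, 2, ...; an unlined episode inside a lined phase continues
    # from the previous episode's line + 1
    for ph in (0, 1):
        mask = phase == ph
        if not mask.any():
            continue
        eps_in_phase: list[int] = []
        for e in episodes[mask]:
            if not eps_in_phase or eps_in_phase[-1] != e:
                eps_in_phase.append(int(e))
        last_line: int | None = None
        for e in eps_in_phase:
            idx = np.flatnonzero((episodes == e) & mask)
            known = next((int(lines[i]) for i in idx if present(lines[i])), None)
            if known is not None:
                last_line = known
                continue
            assigned = 1 if last_line is None else last_line + 1
            for i in idx:
                lines[i] = assigned
                audit.add(patient_key, rids[i], "L2_regimen_change_increment",
                          "treatment_line", None, assigned)
            last_line = assigned

    # L3: non-decreasing within a phase
    for ph in (0, 1):
        running = 0
        for i in np.flatnonzero(phase == ph):
            if not present(lines[i]):
                continue
            li = int(lines[i])
            if li < running:
                audit.add(patient_key, rids[i], "L3_monotonic_correction",
                          "treatment_line", li, running)
                lines[i] = running
            else:
                running = li

    out = pd.array(
        [pd.NA if not present(v) else int(v) for v in lines], dtype="Int64"
    )
    sub["treatment_line"] = pd.Series(out, index=sub.index)
    return sub, audit


# -- driver ---------------------------------------------------------------


def run_inference(
    extract: ExtractTable,
    flowchart: FlowChart,
    gap_days: int = DEFAULT_GAP_DAYS,
) -> tuple[ExtractTable, FlowChart, InferenceAudit]:
    """Run stage then line inference on every patient of an R1-R5-cleaned
    extract; remove still-unresolved patients under rule R6.

    Returns the analyzable extract (100% stage/line completion), the
    updated flow chart, and the audit of every change.
    """
    audit = InferenceAudit()
    keywords = default_stage_keywords()
    rec = canonical_sort(extract.records)
    keys = patient_keys(rec)

    kept_frames: list[pd.DataFrame] = []
    for key, sub in rec.groupby(keys.values, sort=True):
        sub, _ = infer_stage(sub, gap_days=gap_days, keywords=keywords,
                             audit=audit, patient_key=str(key))
        if not stage_resolved(sub):
            diag = sub["diagnosis"].dropna()
            cancer = str(diag.iloc[0]) if len(diag) else "unknown"
            flowchart.move_to_excluded("R6_stage_unresolved", cancer)
            continue
        sub, _ = infer_line(sub, gap_days=gap_days, audit=audit,
                            patient_key=str(key))
        kept_frames.append(sub)

    flowchart.check_conservation()
    if kept_frames:
        records = pd.concat(kept_frames, ignore_index=True)
    else:
        from .schema import empty_records

        records = empty_records()
    out = ExtractTable(records, extract.centers.copy(), extract.extraction_date)
    return out, flowchart, audit
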