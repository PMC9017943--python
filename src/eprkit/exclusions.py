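"""Patient-removal rules and flow-chart accounting.

Five record-pattern rules remove patients whose administration history
cannot support a reliable retrospective cohort:

- **R1_truncated** — the start of the treatment sequence is missing (first
  observed cycle number of the earliest regimen episode is > 1), typically
  an EPR software change cutting the history;
- **R2_name_mismatch** — a brand name that does not match the recorded or
  parsed INN (codification status ``brand_conflict``);
- **R3_duplicate_injection** — the same INN recorded twice on the same
  calendar day for one patient (suspected coding error);
- **R4_multi_primary** — two or more distinct primary cancer diagnoses
  recorded across the patient's records;
- **R5_other_cancer_drug** — at least one administration of a drug specific
  to the treatment of another cancer (catalog exclusion list).

Rules are evaluated in the order R1..R5 and each excluded patient is
counted once, under the first rule triggered, so the flow chart's per-rule
counts are disjoint and conserve the extracted population:
``extracted = analyzable + sum(excluded)``, per cancer and overall. A sixth
rule, R6_stage_unresolved, is applied after stage/line inference (see
:mod:`eprkit.inference`) and accounted in the same flow chart.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .regimens import DEFAULT_GAP_DAYS, segment_regimens
from .schema import DrugCatalog, ExtractTable, RULES, canonical_sort, patient_keys
from .standardize import BRAND_CONFLICT


class PreconditionError(RuntimeError):
    """A pipeline stage was run before its prerequisite stage."""


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (display convention for percentages)."""
    factor = 10.0 ** ndigits
    scaled = x * factor
    rounded = int(abs(scaled) + 0.5) * (1 if scaled >= 0 else -1)
    return rounded / factor if ndigits else float(rounded)


def retention_rates(extracted: dict[str, int], analyzable: dict[str, int]) -> dict[str, float]:
    """Per-cancer retention ``analyzable/extracted`` as percentages
    (full precision; display rounding is the caller's choice)."""
    out = {}
    for cancer, n in extracted.items():
        out[cancer] = 100.0 * analyzable.get(cancer, 0) / n if n else float("nan")
    return out


def exclusion_share(n_extracted: int, n_excluded: int) -> float:
    """Share of extracted patients removed, as a percentage."""
    return 100.0 * n_excluded / n_extracted if n_extracted else float("nan")


@dataclass
class FlowChart:
    """Patient accounting from extracted to analyzable population."""

    extracted: dict[str, int] = field(default_factory=dict)
    excluded: dict[str, dict[str, int]] = field(default_factory=dict)  # rule -> cancer -> n
    analyzable: dict[str, int] = field(default_factory=dict)

    # -- totals ------------------------------------------------------------

    @property
    def n_extracted(self) -> int:
        return sum(self.extracted.values())

    @property
    def n_analyzable(self) -> int:
        return sum(self.analyzable.values())

    @property
    def n_excluded(self) -> int:
        return sum(sum(d.values()) for d in self.excluded.values())

    def excluded_by_rule(self) -> dict[str, int]:
        return {rule: sum(d.values()) for rule, d in self.excluded.items()}

    def check_conservation(self) -> None:
        """extracted = analyzable + sum(excluded), per cancer and overall."""
        cancers = set(self.extracted)
        for cancer in cancers:
            excl = sum(d.get(cancer, 0) for d in self.excluded.values())
            assert self.extracted[cancer] == self.analyzable.get(cancer, 0) + excl, (
                f"flow chart not conserved for {cancer}"
            )
        assert self.n_extracted == self.n_analyzable + self.n_excluded

    def retention(self) -> dict[str, float]:
        return retention_rates(self.extracted, self.analyzable)

    def exclusion_share(self) -> float:
        return exclusion_share(self.n_extracted, self.n_excluded)

    def move_to_excluded(self, rule: str, cancer: str, n: int = 1) -> None:
        """Reclassify ``n`` analyzable patients of a cancer under a rule
        (used by the post-inference rule R6)."""
        if rule not in RULES:
            raise ValueError(f"unknown rule {rule}")
        self.excluded.setdefault(rule, {})
        self.excluded[rule][cancer] = self.excluded[rule].get(cancer, 0) + n
        self.analyzable[cancer] = self.analyzable.get(cancer, 0) - n

    # -- rendering ---------------------------------------------------------

    def to_json(self) -> dict:
        return {
            "extracted": dict(sorted(self.extracted.items())),
            "excluded": {
                rule: dict(sorted(d.items()))
                for rule, d in sorted(self.excluded.items())
            },
            "analyzable": dict(sorted(self.analyzable.items())),
            "retention_pct": {
                k: round_half_up(v) for k, v in sorted(self.retention().items())
            },
            "exclusion_share_pct": round_half_up(self.exclusion_share(), 1),
        }

    def render_markdown(self) -> str:
        lines = ["# Patient flow chart", ""]
        lines.append(f"Extracted population: {self.n_extracted} patients")
        for cancer, n in sorted(self.extracted.items()):
            lines.append(f"- {cancer}: {n}")
        lines.append("")
        lines.append(f"Excluded: {self.n_excluded} patients "
                     f"({round_half_up(self.exclusion_share(), 1)}% of extracted)")
        for rule in RULES:
            if rule in self.excluded:
                total = sum(self.excluded[rule].values())
                per = ", ".join(
                    f"{c}: {n}" for c, n in sorted(self.excluded[rule].items())
                )
                lines.append(f"- {rule}: {total} ({per})")
        lines.append("")
        lines.append(f"Analyzable population: {self.n_analyzable} patients")
        for cancer, n in sorted(self.analyzable.items()):
            ret = round_half_up(self.retention()[cancer])
            lines.append(f"- {cancer}: {n} ({ret:.0f}% of extracted)")
        return "\n".join(lines) + "\n"


# -- per-patient detectors -------------------------------------------------


def detect_truncated_start(
    patient_records: pd.DataFrame, gap_days: int = DEFAULT_GAP_DAYS
) -> bool:
    """True iff the earliest regimen episode's smallest observed cycle
    number is present and greater than 1 (history start cut off).

    Conservative: if no cycle number is recorded in the first episode,
    truncation cannot be asserted and the patient is kept.
    """
    if patient_records.empty:
        return False
    episodes = segment_regimens(patient_records, gap_days=gap_days)
    first = patient_records.loc[episodes == 0, "cycle_number"]
    observed = first.dropna()
    if observed.empty:
        return False
    return int(observed.min()) > 1


def detect_other_cancer_treatment(
    patient_records: pd.DataFrame, catalog: DrugCatalog
) -> bool:
    """True iff any administered INN is on the other-cancer exclusion list."""
    if not catalog.other_cancer_drugs:
        return False
    inns = patient_records["drug_inn"].dropna()
    return bool(inns.isin(catalog.other_cancer_drugs).any())


def detect_duplicate_injection(patient_records: pd.DataFrame) -> bool:
    """True iff the same INN appears twice on one calendar day."""
    sub = patient_records[["drug_inn", "administration_date"]].dropna(
        subset=["drug_inn"]
    )
    return bool(sub.duplicated().any())


def detect_brand_conflict(patient_records: pd.DataFrame) -> bool:
    return bool((patient_records["drug_match_status"] == BRAND_CONFLICT).any())


def detect_multi_primary(patient_records: pd.DataFrame) -> bool:
    """True iff two or more distinct primary diagnoses are recorded."""
    return patient_records["diagnosis"].dropna().nunique() >= 2


# -- engine ----------------------------------------------------------------


def apply_exclusions(
    extract: ExtractTable,
    catalog: DrugCatalog,
    gap_days: int = DEFAULT_GAP_DAYS,
) -> tuple[ExtractTable, FlowChart]:
    """Apply rules R1..R5 at patient level and build the flow chart.

    Requires a codified extract (``drug_match_status`` populated). Returns
    the analyzable-so-far extract (centers kept) and the flow chart; call
    :func:`eprkit.inference.run_inference` next to resolve stages and apply
    R6.
    """
    rec = extract.records
    if rec["drug_match_status"].isna().all() and len(rec):
        raise PreconditionError(
            "extract is not codified; run codify_extract before apply_exclusions"
        )

    rec = canonical_sort(rec)
    keys = patient_keys(rec)
    flow = FlowChart()
    keep: set[str] = set()

    # vectorized patient-level flags for the cheap rules
    dup = rec.loc[rec["drug_inn"].notna()].duplicated(
        subset=["center_id", "patient_id", "drug_inn", "administration_date"]
    )
    dup_patients = set(keys[dup.index[dup]]) if len(dup) else set()
    conflict_patients = set(keys[rec["drug_match_status"] == BRAND_CONFLICT])
    other_patients = (
        set(keys[rec["drug_inn"].isin(catalog.other_cancer_drugs)])
        if catalog.other_cancer_drugs
        else set()
    )
    diag_nunique = (
        rec.assign(_k=keys).groupby("_k")["diagnosis"].nunique(dropna=True)
    )
    multi_patients = set(diag_nunique.index[diag_nunique >= 2])

    for key, sub in rec.groupby(keys.values, sort=True):
        diag = sub["diagnosis"].dropna()
        cancer = str(diag.iloc[0]) if len(diag) else "unknown"
        flow.extracted[cancer] = flow.extracted.get(cancer, 0) + 1

        if detect_truncated_start(sub, gap_days=gap_days):
            rule = "R1_truncated"
        elif key in conflict_patients:
            rule = "R2_name_mismatch"
        elif key in dup_patients:
            rule = "R3_duplicate_injection"
        elif key in multi_patients:
            rule = "R4_multi_primary"
        elif key in other_patients:
            rule = "R5_other_cancer_drug"
        else:
            flow.analyzable[cancer] = flow.analyzable.get(cancer, 0) + 1
            keep.add(key)
            continue
        flow.excluded.setdefault(rule, {})
        flow.excluded[rule][cancer] = flow.excluded[rule].get(cancer, 0) + 1

    for cancer in flow.extracted:
        flow.analyzable.setdefault(cancer, 0)
    flow.check_conservation()

    kept = ExtractTable(
        rec.loc[keys.isin(keep)].reset_index(drop=True),
        extract.centers.copy(),
        extract.extraction_date,
    )
    return kept, flow
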