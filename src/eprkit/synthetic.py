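"""Synthetic multi-center EPR extracts with retained ground truth.

The real platform data behind this pipeline are proprietary hospital
pharmacy records, so the package ships a generator that emulates their
structure: multi-center extracts of breast-cancer (BC) and lung-cancer
(LC) patients, each receiving 1-4 sequential regimens (a fixed drug
combination given every ``frequency_days`` for a few cycles), with every
patient receiving at least one cohort-defining drug of interest.

The generator reproduces the documented defect structure of such extracts
and keeps the truth it masks, so the cleaning and inference stages can be
audited exactly:

- patient-level stage/line masking at the field's pre-completion rates
  (stage missing for 7% of BC / 23% of LC patients, line for 20% / 30%) —
  recoverable from regimen labels and regimen structure;
- record-level nuisance: isolated missing stages/lines inside otherwise
  completed histories, spurious stage regressions, and conflicting line
  entries — the populations for the fill/ratchet/monotonic rules;
- injected patient-level errors triggering each of the five exclusion
  rules (truncated history start, brand/INN mismatch, duplicated same-day
  injection, multiple primary diagnoses, other-cancer drug contamination),
  mutually exclusive per patient by default so per-rule counts are
  unambiguous;
- free-text dialect noise: case variants, French/English synonyms, brand
  names in the drug field.

Everything is driven by one :class:`numpy.random.Generator`; a fixed seed
reproduces the extract byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .io import default_catalog
from .schema import (
    CATEGORIES,
    COLUMN_TYPES,
    DrugCatalog,
    ExtractTable,
    ORDER_COLUMN,
    REGIONS,
    STAGE_SEVERITY,
    centers_frame,
    Center,
)

# regimen pools: every combination contains at least one drug of interest
_BC_POOL = (
    ("trastuzumab", "pertuzumab", "docetaxel"),
    ("trastuzumab", "pertuzumab"),
    ("trastuzumab", "paclitaxel"),
    ("trastuzumab",),
    ("trastuzumab emtansine",),
    ("trastuzumab", "vinorelbine"),
)
_LC_POOL = (
    ("bevacizumab", "carboplatin", "paclitaxel"),
    ("bevacizumab", "pemetrexed"),
    ("bevacizumab",),
    ("atezolizumab",),
    ("atezolizumab", "carboplatin", "pemetrexed"),
    ("bevacizumab", "gemcitabine"),
)

_TYPICAL_DOSE = {
    "trastuzumab": 440.0, "pertuzumab": 420.0, "trastuzumab emtansine": 250.0,
    "bevacizumab": 400.0, "atezolizumab": 1200.0, "paclitaxel": 300.0,
    "docetaxel": 140.0, "carboplatin": 450.0, "pemetrexed": 900.0,
    "vinorelbine": 50.0, "gemcitabine": 1800.0,
}

_STAGE_VARIANTS = {
    "early": ("early", "adjuvant", "précoce"),
    "locally_advanced": ("locally advanced", "localement avancé"),
    "metastatic": ("metastatic", "métastatique", "stade IV"),
}
_STAGE_LABEL_KEYWORDS = {
    "early": ("adjuvant", "néoadjuvant"),
    "locally_advanced": ("localement avancé", "locally advanced"),
    "metastatic": ("métastatique", "metastatic", "palliatif"),
}
_DIAGNOSIS_VARIANTS = {
    "breast_cancer": ("breast_cancer", "breast cancer", "cancer du sein"),
    "lung_cancer": ("lung_cancer", "lung cancer", "NSCLC", "cancer du poumon"),
}
_GENDER_VARIANTS = {"F": ("F", "female", "Féminin"), "M": ("M", "male", "Masculin")}
_RESPONSE_VARIANTS = {
    "CR": ("CR", "complete response"), "PR": ("PR", "partial response"),
    "SD": ("SD", "stable disease"), "PD": ("PD", "progression"),
}

# stage trajectories (phases in order) and their probabilities per cancer
_TRAJECTORIES = {
    "breast_cancer": (
        (("early",), 0.35),
        (("early", "metastatic"), 0.20),
        (("locally_advanced", "metastatic"), 0.05),
        (("metastatic",), 0.40),
    ),
    "lung_cancer": (
        (("early",), 0.10),
        (("early", "metastatic"), 0.20),
        (("locally_advanced", "metastatic"), 0.10),
        (("metastatic",), 0.60),
    ),
}

_DEFAULT_STRATA = {
    ("GH_NFPH", "North"): 1, ("GH_NFPH", "East"): 1, ("GH_NFPH", "SouthEast"): 1,
    ("GH_NFPH", "SouthWest"): 1, ("GH_NFPH", "West"): 1, ("GH_NFPH", "ParisArea"): 1,
    ("UH", "ParisArea"): 1, ("UH", "East"): 1,
    ("CCC", "ParisArea"): 1, ("CCC", "West"): 1,
    ("PH", "North"): 1, ("PH", "SouthWest"): 1,
}


@dataclass
class SyntheticConfig:
    """Generator configuration.

    Defaults encode the emulated study conditions: stage pre-completion of
    93% (BC) and 77% (LC), line pre-completion of 80% and 70%, a truncated
    history for 3.7% of patients and the four remaining error causes at a
    few per mille each (the flow-chart scale of the emulated program). The
    record-level nuisance rates are small free parameters that populate the
    fill/correction rules without moving patient-level completion.
    """

    n_centers_by_stratum: dict[tuple[str, str], int] = field(
        default_factory=lambda: dict(_DEFAULT_STRATA)
    )
    patients_per_center: int = 50
    cancer_mix: float = 0.835  # share of breast-cancer patients

    stage_missing_rate_bc: float = 0.07
    stage_missing_rate_lc: float = 0.23
    line_missing_rate_bc: float = 0.20
    line_missing_rate_lc: float = 0.30

    truncation_rate: float = 0.037
    duplicate_injection_rate: float = 0.006
    brand_mismatch_rate: float = 0.006
    multi_primary_rate: float = 0.005
    other_drug_contamination_rate: float = 0.005
    errors_mutually_exclusive: bool = True

    stage_record_dropout: float = 0.03   # isolated in-regimen missing stages
    stage_regression_rate: float = 0.02  # spurious stage downgrades
    line_record_dropout: float = 0.05    # isolated in-regimen missing lines
    line_conflict_rate: float = 0.02     # conflicting (too low) line entries
    uninformative_label_rate: float = 0.05  # masked patients left unresolvable

    response_rate_bc: float = 0.07
    response_rate_lc: float = 0.04

    seed: int = 0

    def validate(self) -> None:
        probs = [
            self.cancer_mix, self.stage_missing_rate_bc, self.stage_missing_rate_lc,
            self.line_missing_rate_bc, self.line_missing_rate_lc,
            self.truncation_rate, self.duplicate_injection_rate,
            self.brand_mismatch_rate, self.multi_primary_rate,
            self.other_drug_contamination_rate, self.stage_record_dropout,
            self.stage_regression_rate, self.line_record_dropout,
            self.line_conflict_rate, self.uninformative_label_rate,
            self.response_rate_bc, self.response_rate_lc,
        ]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("all rates must be probabilities in [0, 1]")
        if self.patients_per_center < 0:
            raise ValueError("patients_per_center must be >= 0")
        if any(n < 0 for n in self.n_centers_by_stratum.values()):
            raise ValueError("center counts must be >= 0")
        for cat, reg in self.n_centers_by_stratum:
            if cat not in CATEGORIES or reg not in REGIONS:
                raise ValueError(f"unknown stratum {(cat, reg)}")

    # JSON round-trip (stratum keys encoded as "CATEGORY:Region")

    def to_json(self) -> dict:
        d = asdict(self)
        d["n_centers_by_stratum"] = {
            f"{cat}:{reg}": n for (cat, reg), n in self.n_centers_by_stratum.items()
        }
        return d

    @classmethod
    def from_json(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        strata = {}
        for key, n in d.get("n_centers_by_stratum", {}).items():
            cat, reg = key.split(":")
            strata[(cat, reg)] = int(n)
        if strata:
            d["n_centers_by_stratum"] = strata
        else:
            d.pop("n_centers_by_stratum", None)
        return cls(**d)


@dataclass
class GroundTruth:
    """True values retained before masking, plus injected-error labels."""

    stage_by_record: dict[str, str] = field(default_factory=dict)
    line_by_record: dict[str, int] = field(default_factory=dict)
    error_rule_by_patient: dict[str, str] = field(default_factory=dict)
    stage_masked: set[str] = field(default_factory=set)
    line_masked: set[str] = field(default_factory=set)
    stage_unrecoverable: set[str] = field(default_factory=set)

    def to_json(self) -> dict:
        return {
            "stage_by_record": dict(sorted(self.stage_by_record.items())),
            "line_by_record": dict(sorted(self.line_by_record.items())),
            "error_rule_by_patient": dict(sorted(self.error_rule_by_patient.items())),
            "stage_masked": sorted(self.stage_masked),
            "line_masked": sorted(self.line_masked),
            "stage_unrecoverable": sorted(self.stage_unrecoverable),
        }

    @classmethod
    def from_json(cls, d: dict) -> "GroundTruth":
        return cls(
            stage_by_record=dict(d["stage_by_record"]),
            line_by_record={k: int(v) for k, v in d["line_by_record"].items()},
            error_rule_by_patient=dict(d["error_rule_by_patient"]),
            stage_masked=set(d["stage_masked"]),
            line_masked=set(d["line_masked"]),
            stage_unrecoverable=set(d["stage_unrecoverable"]),
        )


def _choice(rng: np.random.Generator, seq):
    return seq[int(rng.integers(len(seq)))]


def _records_frame(rows: list[dict]) -> pd.DataFrame:
    """Assemble typed records from row dicts (missing -> NA of the right kind)."""
    if not rows:
        from .schema import empty_records

        return empty_records()
    df = pd.DataFrame(rows)
    for col, kind in COLUMN_TYPES.items():
        if col not in df.columns:
            df[col] = None
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
    df = df[list(COLUMN_TYPES)]
    df[ORDER_COLUMN] = np.arange(len(df))
    return df


def _patient_rows(
    rng: np.random.Generator,
    config: SyntheticConfig,
    catalog: DrugCatalog,
    center: Center,
    patient_id: str,
    rid_counter: list[int],
    truth: GroundTruth,
) -> list[dict]:
    """Generate one patient's administration rows and record their truth."""
    center_id = center.center_id
    key = f"{center_id}|{patient_id}"
    cancer = "breast_cancer" if rng.random() < config.cancer_mix else "lung_cancer"
    pool = _BC_POOL if cancer == "breast_cancer" else _LC_POOL
    brand_of = {}
    for brand, inn in catalog.inn_by_brand.items():
        brand_of.setdefault(inn, brand)

    # trajectory and regimen plan
    trajs = _TRAJECTORIES[cancer]
    u, acc = rng.random(), 0.0
    phases = trajs[-1][0]
    for ph, p in trajs:
        acc += p
        if u < acc:
            phases = ph
            break
    n_regimens = max(int(rng.integers(1, 5)), len(phases))
    # each phase gets >= 1 regimen; extras go to the last phase
    regimens_per_phase = [1] * len(phases)
    regimens_per_phase[-1] += n_regimens - len(phases)

    # demographics (constant across the patient's records)
    gender_code = (
        "F" if rng.random() < (0.99 if cancer == "breast_cancer" else 0.35) else "M"
    )
    demo = {
        "birth_year": int(rng.integers(1930, 1991)) if rng.random() > 0.001 else None,
        "gender": _choice(rng, _GENDER_VARIANTS[gender_code])
        if rng.random() > 0.001 else None,
        "weight_kg": round(float(np.clip(rng.normal(70, 15), 40, 130)), 1)
        if rng.random() > 0.002 else None,
        "height_cm": round(float(np.clip(rng.normal(165, 10), 140, 200)), 1)
        if rng.random() > 0.002 else None,
    }
    diagnosis_text = (
        _choice(rng, _DIAGNOSIS_VARIANTS[cancer]) if rng.random() > 0.002 else None
    )
    ecog = (
        int(rng.integers(0, 3))
        if cancer == "lung_cancer" and rng.random() < 0.117
        else None
    )
    driver = None
    if cancer == "breast_cancer" and rng.random() < 0.311:
        driver = "HER2+"
    elif cancer == "lung_cancer" and rng.random() < 0.10:
        driver = _choice(rng, ("EGFR", "ALK", "PD-L1"))
    metastatic_ever = "metastatic" in phases
    sites = None
    if metastatic_ever and rng.random() < (
        0.05 if cancer == "breast_cancer" else 0.076
    ):
        sites = ";".join(
            sorted(set(_choice(rng, ("liver", "bone", "lung", "brain"))
                       for _ in range(int(rng.integers(1, 3)))))
        )
    trial = None
    if rng.random() < 0.98:
        trial = f"TRIAL-{int(rng.integers(1, 50)):03d}" if rng.random() < 0.1 else "none"

    resp_rate = (
        config.response_rate_bc if cancer == "breast_cancer"
        else config.response_rate_lc
    )
    has_response = rng.random() < resp_rate
    has_discont = rng.random() < 0.03

    # masking modes (patient-level categorical draws)
    r_stage = (
        config.stage_missing_rate_bc if cancer == "breast_cancer"
        else config.stage_missing_rate_lc
    )
    r_line = (
        config.line_missing_rate_bc if cancer == "breast_cancer"
        else config.line_missing_rate_lc
    )
    u = rng.random()
    if u < r_stage:
        stage_mode = "masked"
    elif u < r_stage + config.stage_regression_rate:
        stage_mode = "regression"
    elif u < r_stage + config.stage_regression_rate + config.stage_record_dropout:
        stage_mode = "dropout"
    else:
        stage_mode = "clean"
    u = rng.random()
    if u < r_line:
        line_mode = "masked"
    elif u < r_line + config.line_conflict_rate:
        line_mode = "conflict"
    elif u < r_line + config.line_conflict_rate + config.line_record_dropout:
        line_mode = "dropout"
    else:
        line_mode = "clean"
    uninformative = stage_mode == "masked" and rng.random() < config.uninformative_label_rate

    # injected exclusion errors
    error_rates = (
        ("R1_truncated", config.truncation_rate),
        ("R2_name_mismatch", config.brand_mismatch_rate),
        ("R3_duplicate_injection", config.duplicate_injection_rate),
        ("R4_multi_primary", config.multi_primary_rate),
        ("R5_other_cancer_drug", config.other_drug_contamination_rate),
    )
    errors: list[str] = []
    if config.errors_mutually_exclusive:
        u, acc = rng.random(), 0.0
        for rule, p in error_rates:
            acc += p
            if u < acc:
                errors = [rule]
                break
    else:
        errors = [rule for rule, p in error_rates if rng.random() < p]

    # build the administration rows
    start = date(2015, 1, 1) + timedelta(days=int(rng.integers(0, 1400)))
    rows: list[dict] = []
    prev_combo = None
    regimen_index = 0
    cur = start
    first_regimen_cycles = 0
    for phase_idx, stage in enumerate(phases):
        for line_in_phase in range(1, regimens_per_phase[phase_idx] + 1):
            combo = _choice(rng, pool)
            while combo == prev_combo:
                combo = _choice(rng, pool)
            prev_combo = combo
            freq = int(_choice(rng, (14, 21, 28)))
            cycles = int(rng.integers(3, 9))
            if regimen_index == 0:
                first_regimen_cycles = cycles
            base_label = " + ".join(inn.upper() for inn in combo)
            label = (
                base_label if uninformative
                else f"{base_label} - {_choice(rng, _STAGE_LABEL_KEYWORDS[stage])}"
            )
            for cycle in range(1, cycles + 1):
                for inn in combo:
                    rid = f"r{rid_counter[0]:07d}"
                    rid_counter[0] += 1
                    truth.stage_by_record[rid] = stage
                    truth.line_by_record[rid] = line_in_phase
                    u_form = rng.random()
                    brand = brand_of.get(inn)
                    if u_form < 0.3 and brand is not None:
                        raw = brand
                    elif u_form < 0.6:
                        raw = inn.upper()
                    else:
                        raw = inn
                    rows.append({
                        "record_id": rid,
                        "_inn": inn,
                        "center_id": center_id,
                        "center_category": center.category,
                        "center_region": center.region,
                        "patient_id": patient_id,
                        **demo,
                        "ecog": ecog,
                        "diagnosis": diagnosis_text,
                        "disease_stage": _choice(rng, _STAGE_VARIANTS[stage])
                        if rng.random() < 0.7 else stage,
                        "metastasis_sites": sites if stage == "metastatic" else None,
                        "oncogenic_driver": driver,
                        "drug_raw": raw,
                        "drug_inn": None,
                        "drug_brand": brand if rng.random() < 0.4 else None,
                        "drug_match_status": None,
                        "dose_mg": round(
                            _TYPICAL_DOSE[inn] * float(rng.uniform(0.9, 1.1)), 1
                        ),
                        "administration_date": cur.isoformat(),
                        "treatment_line": line_in_phase,
                        "cycle_number": cycle,
                        "frequency_days": freq,
                        "regimen_label": label,
                        "estimated_duration_days": cycles * freq,
                        "response": None,
                        "response_date": None,
                        "discontinuation_motive": None,
                        "discontinuation_date": None,
                        "trial_name": trial,
                        "_regimen_index": regimen_index,
                    })
                cur = cur + timedelta(days=freq)
            regimen_index += 1

    last = rows[-1]
    if has_response:
        last["response"] = _choice(
            rng, _RESPONSE_VARIANTS[_choice(rng, ("CR", "PR", "SD", "PD"))]
        )
        if rng.random() < 0.6:
            last["response_date"] = (
                date.fromisoformat(last["administration_date"])
                + timedelta(days=30)
            ).isoformat()
    if has_discont:
        last["discontinuation_motive"] = _choice(rng, ("toxicity", "progression"))
        last["discontinuation_date"] = (
            date.fromisoformat(last["administration_date"]) + timedelta(days=14)
        ).isoformat()

    # -- stage masking / nuisance -----------------------------------------
    if stage_mode == "masked":
        for r in rows:
            r["disease_stage"] = None
        truth.stage_masked.add(key)
        if uninformative:
            truth.stage_unrecoverable.add(key)
    elif stage_mode == "regression":
        # a later-day record of an elevated phase is downgraded; an earlier
        # same-phase day then guarantees the ratchet restores the truth
        sev = [STAGE_SEVERITY[truth.stage_by_record[r["record_id"]]] for r in rows]
        first_day_of_sev: dict[int, str] = {}
        for s, r in zip(sev, rows):
            first_day_of_sev.setdefault(s, r["administration_date"])
        cands = [
            i for i in range(1, len(rows))
            if sev[i] > 0 and rows[i]["administration_date"] > first_day_of_sev[sev[i]]
        ]
        if cands:
            i = int(_choice(rng, cands))
            rows[i]["disease_stage"] = "early"
    elif stage_mode == "dropout":
        flags = rng.random(len(rows)) < 0.5
        if flags.all():
            flags[0] = False
        for r, f in zip(rows, flags):
            if f:
                r["disease_stage"] = None

    # -- line masking / nuisance ------------------------------------------
    if line_mode == "masked":
        for r in rows:
            r["treatment_line"] = None
        truth.line_masked.add(key)
    elif line_mode == "conflict":
        cands = [
            i for i, r in enumerate(rows)
            if r["cycle_number"] >= 2 and truth.line_by_record[r["record_id"]] >= 2
        ]
        if cands:
            i = int(_choice(rng, cands))
            rows[i]["treatment_line"] = truth.line_by_record[rows[i]["record_id"]] - 1
    elif line_mode == "dropout":
        flags = rng.random(len(rows)) < 0.5
        if flags.all():
            flags[0] = False
        for r, f in zip(rows, flags):
            if f:
                r["treatment_line"] = None

    # -- injected exclusion errors -----------------------------------------
    for rule in errors:
        if rule == "R1_truncated":
            k = int(rng.integers(1, min(2, first_regimen_cycles - 1) + 1))
            rows = [
                r for r in rows
                if not (r["_regimen_index"] == 0 and r["cycle_number"] <= k)
            ]
            if not rows:
                continue
        elif rule == "R2_name_mismatch":
            i = int(rng.integers(len(rows)))
            row_inn = rows[i]["_inn"]
            for brand, inn2 in sorted(catalog.inn_by_brand.items()):
                if inn2 != row_inn:
                    rows[i]["drug_brand"] = brand
                    break
        elif rule == "R3_duplicate_injection":
            i = int(rng.integers(len(rows)))
            dup = dict(rows[i])
            rid = f"r{rid_counter[0]:07d}"
            rid_counter[0] += 1
            dup["record_id"] = rid
            truth.stage_by_record[rid] = truth.stage_by_record[rows[i]["record_id"]]
            truth.line_by_record[rid] = truth.line_by_record[rows[i]["record_id"]]
            rows.append(dup)
        elif rule == "R4_multi_primary":
            other = "lung_cancer" if cancer == "breast_cancer" else "breast_cancer"
            if rows[0]["diagnosis"] is None:
                # two *recorded* diagnoses are needed to constitute the error
                rows[0]["diagnosis"] = cancer
            rows[-1]["diagnosis"] = other
        elif rule == "R5_other_cancer_drug":
            inn_other = _choice(rng, sorted(catalog.other_cancer_drugs))
            last_date = date.fromisoformat(rows[-1]["administration_date"])
            rid = f"r{rid_counter[0]:07d}"
            rid_counter[0] += 1
            contaminant = dict(rows[-1])
            contaminant.update({
                "record_id": rid,
                "_inn": inn_other,
                "drug_raw": inn_other,
                "drug_brand": None,
                "dose_mg": 500.0,
                "administration_date": (last_date + timedelta(days=21)).isoformat(),
                "cycle_number": 1,
                "treatment_line": None,
                "regimen_label": inn_other.upper(),
                "_regimen_index": regimen_index,
            })
            truth.stage_by_record[rid] = truth.stage_by_record[rows[-1]["record_id"]]
            truth.line_by_record[rid] = truth.line_by_record[rows[-1]["record_id"]] + 1
            rows.append(contaminant)
    if errors and rows:
        truth.error_rule_by_patient[key] = errors[0]

    for r in rows:
        r.pop("_regimen_index", None)
        r.pop("_inn", None)
    return rows


def generate_extract(
    config: SyntheticConfig, catalog: DrugCatalog | None = None
) -> tuple[ExtractTable, GroundTruth]:
    """Generate a multi-center extract plus its ground truth.

    Deterministic for a fixed ``config.seed``; every patient receives at
    least one drug of interest; truth is recorded before masking.
    """
    config.validate()
    catalog = catalog or default_catalog()
    rng = np.random.default_rng(config.seed)
    truth = GroundTruth()

    centers: list[Center] = []
    idx = 0
    for (cat, reg), count in sorted(config.n_centers_by_stratum.items()):
        for _ in range(count):
            idx += 1
            centers.append(Center(f"C{idx:03d}", cat, reg))

    rid_counter = [0]
    rows: list[dict] = []
    for center in centers:
        for p in range(config.patients_per_center):
            rows.extend(
                _patient_rows(
                    rng, config, catalog, center, f"P{p + 1:04d}",
                    rid_counter, truth,
                )
            )
    records = _records_frame(rows)
    extract = ExtractTable(records, centers_frame(centers), date(2020, 1, 1))
    return extract, truth


def generate_national_reference(config: SyntheticConfig, inflation: float):
    """Deterministic national reference implied by the configured strata.

    Each stratum's national count is the configured cohort count scaled by
    ``inflation`` (rounded up), preserving the distribution shape; coverage
    against a generated extract is therefore ~ 1/inflation everywhere.
    """
    import math

    from .assessment import NationalReference
    from .exclusions import round_half_up

    if not inflation > 1:
        raise ValueError("inflation factor must be > 1")
    rows = []
    for (cat, reg), count in sorted(config.n_centers_by_stratum.items()):
        patients = count * config.patients_per_center
        bc = int(round_half_up(patients * config.cancer_mix))
        lc = patients - bc
        for cancer, n in (("breast_cancer", bc), ("lung_cancer", lc)):
            rows.append({
                "cancer": cancer, "category": cat, "region": reg,
                "n": int(math.ceil(n * inflation)),
            })
    counts = pd.DataFrame(rows, columns=["cancer", "category", "region", "n"])
    counts = (
        counts.groupby(["cancer", "category", "region"], as_index=False)["n"].sum()
    )
    return NationalReference(counts=counts, reference_year=2018)


def write_truth(truth: GroundTruth, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(truth.to_json(), fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_truth(path) -> GroundTruth:
    with open(path, encoding="utf-8") as fh:
        return GroundTruth.from_json(json.load(fh))
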