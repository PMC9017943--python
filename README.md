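# eprkit

Cleaning, completion and audit toolkit for multi-center **electronic
pharmacy record (EPR)** extracts of injectable cancer-drug administrations.

Hospital pharmacy systems record every prescription, dispensation and
administration of in-hospital injectable drugs. Pooled across centers, these
records support retrospective real-world cohorts of cancer patients — but
only after substantial data management: free text arrives in many vendor
dialects and two languages, drug names mix brands and INNs, treatment
histories can be truncated by software migrations, and disease stage and
treatment line are recorded at the physician's discretion and are therefore
incomplete. `eprkit` implements that data management as a reusable,
auditable pipeline for cohorts of breast-cancer and lung-cancer patients
treated with trastuzumab, trastuzumab emtansine, pertuzumab, bevacizumab or
atezolizumab:

1. **Standardization** (`eprkit.standardize`) — map free text onto
   controlled vocabularies via data-driven synonym tables; resolve drug
   names through a brand→INN catalog (exact matching after
   case/whitespace/diacritic normalization, never fuzzy).
2. **Exclusion engine** (`eprkit.exclusions`) — remove patients matching
   five record-pattern rules (truncated history start, brand/INN mismatch,
   duplicated same-day injection, multiple primary diagnoses,
   administration of a drug specific to another cancer), in fixed precedence
   R1→R5, with flow-chart accounting that conserves the extracted
   population: `extracted = analyzable + Σ excluded`.
3. **Stage/line inference** (`eprkit.inference`) — six pluggable,
   identifier-tagged rules complete and correct disease stage
   (fill-within-regimen, regimen-label keywords, severity ratchet) and
   treatment line (fill-within-regimen, increment-at-regimen-change with
   numbering restarting at the metastatic transition, monotonic
   correction); patients with still-unresolved stage are removed (rule R6),
   so the retained population has 100% stage and line completion. Every
   changed value is logged in an audit trail.
4. **Assessment** (`eprkit.assessment`) — per-variable completion rates
   (variables under 70% are flagged not usable), coverage against a
   national hospital-activity reference table, and representativeness of
   the patient distribution across center categories and regions
   (percentage-point gaps, flags, supplementary chi-square).
5. **Quality control** (`eprkit.qc`) — for each inference rule, a simple
   random sample of the patients it touched is reviewed and the
   correct-application proportion is estimated with an exact
   Clopper–Pearson interval. The review sample size follows the
   finite-population-corrected formula
   `n = ceil( n0 / (1 + n0/N) )`, `n0 = z²·p(1−p)/e²`,
   with planning defaults e = 0.10, z = 1.65, p = 0.50 — about 60 reviewed
   patients for populations of a few hundred.

Because real EPR extracts are proprietary, `eprkit.synthetic` generates
multi-center extracts with the same structure and defect profile — and
retains the ground truth it masks, so exclusion sensitivity and inference
accuracy can be measured exactly. See `docs/methods.md` for the model and
its limitations.

## Worked example

Generate a 600-patient synthetic extract (12 centers, default defect
rates), then run the full pipeline:

```sh
eprkit generate --seed 7 --outdir demo
cat > demo/run.json <<'JSON'
{
  "extract_path": "demo/extract.csv",
  "output_dir": "demo/out",
  "reference_path": "demo/reference.csv",
  "truth_path": "demo/truth.json",
  "seed": 7
}
JSON
eprkit run --config demo/run.json
```

`demo/out/flowchart.md` then reads:

```
Extracted population: 600 patients
- breast_cancer: 503
- lung_cancer: 97

Excluded: 34 patients (5.7% of extracted)
- R1_truncated: 22 (breast_cancer: 19, lung_cancer: 3)
- R2_name_mismatch: 4 (breast_cancer: 4)
- R3_duplicate_injection: 2 (breast_cancer: 2)
- R4_multi_primary: 5 (breast_cancer: 5)
- R6_stage_unresolved: 1 (breast_cancer: 1)

Analyzable population: 566 patients
- breast_cancer: 472 (94% of extracted)
- lung_cancer: 94 (97% of extracted)
```

34 patients were removed: 22 with a truncated history start, 11 by the
other four record-pattern rules, and 1 whose disease stage could not be
resolved even after inference. `demo/out/completion.md` reports 100%
completion for disease stage and treatment line among the 566 retained
patients (both fields were incomplete before inference), and
`demo/out/qc.md` shows the per-rule review:

```
| Rule | N touched | n reviewed | correct | Proportion | 95% CI |
|---|---|---|---|---|---|
| S1_fill_within_regimen | 18 | 18 | 18 | 100.0% | [81.5%, 100.0%] |
| S2_regimen_keyword | 57 | 57 | 57 | 100.0% | [93.7%, 100.0%] |
| S3_severity_ratchet | 7 | 7 | 7 | 100.0% | [59.0%, 100.0%] |
| L1_fill_within_regimen | 28 | 28 | 28 | 100.0% | [87.7%, 100.0%] |
| L2_regimen_change_increment | 138 | 46 | 46 | 100.0% | [92.3%, 100.0%] |
| L3_monotonic_correction | 10 | 10 | 10 | 100.0% | [69.2%, 100.0%] |
```

On masking-only synthetic data every rule application matches the retained
truth, so each proportion is 1.0 and the interval lower bounds reflect the
review sample sizes. `demo/out/coverage.md` and
`demo/out/representativeness.md` benchmark the cohort against the generated
national reference (coverage ≈ 1/3 per stratum with the default inflation
factor of 3).

Each stage is also available separately (`eprkit clean`, `eprkit infer`,
`eprkit assess`, `eprkit qc`) and as library functions.

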