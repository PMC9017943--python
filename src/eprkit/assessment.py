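"""Completeness, coverage and representativeness of the analyzable cohort.

Three audit criteria decide whether a multi-center extract can support
real-world evidence generation:

- **Completeness** — per-variable completion rate in the analyzable
  population. Patient-level variables (demographics, diagnosis, drivers,
  response, ...) count a patient as complete if any of their records carries
  a value; record-level variables count records. Variables below 70%
  completion are flagged not usable (no imputation is attempted).
- **Coverage** — the number of treated patients captured, per stratum and
  in total, divided by the national count from a hospital-activity
  reference table (PMSI-like). A coverage of one third of nationally
  treated patients is the conventional sufficiency target.
- **Representativeness** — agreement between the cohort's distribution of
  patients across center categories (or regions) and the national
  distribution: per-stratum share differences in percentage points, a flag
  above a configurable threshold, and a supplementary chi-square
  goodness-of-fit of the cohort counts against the national share vector
  (descriptive only; it never gates a pipeline run).

Display convention: coverage and share percentages are rounded half away
from zero, to the integer for coverage and lung-cancer shares and to one
decimal for breast-cancer shares; the underlying reports always carry full
precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exclusions import round_half_up
from .schema import ExtractTable, canonical_sort, patient_keys

USABILITY_THRESHOLD = 0.70
DEFAULT_FLAG_THRESHOLD_PP = 4.0

#: Default variable audit specification: (column, level).
DEFAULT_VARIABLE_SPEC: tuple[tuple[str, str], ...] = (
    ("birth_year", "patient"),
    ("gender", "patient"),
    ("weight_kg", "patient"),
    ("height_cm", "patient"),
    ("ecog", "patient"),
    ("diagnosis", "patient"),
    ("disease_stage", "patient"),
    ("metastasis_sites", "patient"),
    ("oncogenic_driver", "patient"),
    ("treatment_line", "patient"),
    ("response", "patient"),
    ("response_date", "patient"),
    ("discontinuation_motive", "patient"),
    ("discontinuation_date", "patient"),
    ("trial_name", "patient"),
    ("drug_inn", "record"),
    ("dose_mg", "record"),
    ("administration_date", "record"),
    ("cycle_number", "record"),
    ("frequency_days", "record"),
    ("regimen_label", "record"),
    ("estimated_duration_days", "record"),
)


@dataclass
class NationalReference:
    """National patient counts by (cancer, category, region) stratum."""

    counts: pd.DataFrame  # columns: cancer, category, region, n
    reference_year: int = 0

    def totals_by(self, by: tuple[str, ...]) -> pd.DataFrame:
        cols = ["cancer", *by]
        return self.counts.groupby(cols, dropna=False, as_index=False)["n"].sum()


@dataclass
class CompletionReport:
    """Per-variable completion rates with usability flags."""

    rates: dict[str, dict] = field(default_factory=dict)  # var -> {rate, level, usable}
    n_patients: int = 0
    n_records: int = 0

    def to_json(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "n_records": self.n_records,
            "variables": {k: dict(v) for k, v in sorted(self.rates.items())},
        }

    def render_markdown(self) -> str:
        lines = [
            "# Completion rates",
            "",
            f"Analyzable population: {self.n_patients} patients, "
            f"{self.n_records} records",
            "",
            "| Variable | Level | Completion | Usable |",
            "|---|---|---|---|",
        ]
        for var, info in self.rates.items():
            rate = info["rate"]
            shown = "NA" if rate is None else f"{100 * rate:.1f}%"
            usable = "" if rate is None else ("yes" if info["usable"] else "no")
            lines.append(f"| {var} | {info['level']} | {shown} | {usable} |")
        return "\n".join(lines) + "\n"


def completion_rates(
    extract: ExtractTable,
    variable_spec: tuple[tuple[str, str], ...] = DEFAULT_VARIABLE_SPEC,
) -> CompletionReport:
    """Compute per-variable completion rates on the given extract."""
    rec = extract.records
    report = CompletionReport(
        n_patients=extract.n_patients, n_records=len(rec)
    )
    if rec.empty:
        warnings.warn(
            "empty population: completion rates are undefined", stacklevel=2
        )
        for var, level in variable_spec:
            report.rates[var] = {"rate": None, "level": level, "usable": None}
        return report

    keys = patient_keys(rec)
    for var, level in variable_spec:
        notna = rec[var].notna()
        if level == "patient":
            per_patient = notna.groupby(keys.values).any()
            rate = float(per_patient.mean())
        elif level == "record":
            rate = float(notna.mean())
        else:
            raise ValueError(f"unknown level {level!r} for variable {var}")
        report.rates[var] = {
            "rate": rate,
            "level": level,
            "usable": bool(rate >= USABILITY_THRESHOLD),
        }
    return report


def patient_counts_by_stratum(extract: ExtractTable) -> pd.DataFrame:
    """Count each patient once per cancer, at the center of their first
    administration (canonical order); unknown centers fall into an explicit
    ``unknown`` stratum. Returns columns cancer, category, region, n."""
    rec = canonical_sort(extract.records)
    if rec.empty:
        return pd.DataFrame(columns=["cancer", "category", "region", "n"])
    keys = patient_keys(rec)
    lookup = extract.center_lookup()
    cancers = extract.patient_cancers()

    first = rec.loc[~keys.duplicated(keep="first")]
    first_keys = patient_keys(first)
    rows = []
    for key, center in zip(first_keys, first["center_id"].astype(str)):
        cat, reg = lookup.get(center, (None, None))
        rows.append(
            {
                "cancer": cancers.loc[key],
                "category": cat if cat is not None else "unknown",
                "region": reg if reg is not None else "unknown",
            }
        )
    df = pd.DataFrame(rows)
    return (
        df.groupby(["cancer", "category", "region"], as_index=False)
        .size()
        .rename(columns={"size": "n"})
    )


@dataclass
class CoverageReport:
    """Per-stratum and total coverage (cohort count / national count)."""

    by: tuple[str, ...]
    table: pd.DataFrame  # cancer, *by, prm_count, national_count, coverage_rate
    totals: pd.DataFrame  # cancer, prm_count, national_count, coverage_rate

    def rounded(self) -> pd.DataFrame:
        """Display copy with coverage as integer percent."""
        t = self.table.copy()
        t["coverage_pct"] = [
            None if pd.isna(r) else round_half_up(100 * r)
            for r in t["coverage_rate"]
        ]
        return t

    def to_json(self) -> dict:
        return {
            "by": list(self.by),
            "strata": self.table.to_dict(orient="records"),
            "totals": self.totals.to_dict(orient="records"),
        }

    def render_markdown(self) -> str:
        lines = ["# Coverage", "", "| Cancer | " + " | ".join(self.by)
                 + " | Cohort | National | Coverage |", "|---" * (len(self.by) + 4) + "|"]
        for row in self.table.itertuples(index=False):
            r = getattr(row, "coverage_rate")
            cov = "NA" if pd.isna(r) else f"{round_half_up(100 * r):.0f}%"
            cells = [str(getattr(row, c)) for c in ("cancer", *self.by)]
            lines.append(
                "| " + " | ".join(cells)
                + f" | {row.prm_count} | {row.national_count} | {cov} |"
            )
        for row in self.totals.itertuples(index=False):
            cov = f"{round_half_up(100 * row.coverage_rate):.0f}%"
            lines.append(
                f"| {row.cancer} | " + "Total | " * len(self.by)
                + f"{row.prm_count} | {row.national_count} | {cov} |"
            )
        return "\n".join(lines) + "\n"


def _align(prm_counts: pd.DataFrame, reference: NationalReference,
           by: tuple[str, ...]) -> pd.DataFrame:
    cols = ["cancer", *by]
    prm = prm_counts.groupby(cols, dropna=False, as_index=False)["n"].sum()
    prm = prm.rename(columns={"n": "prm_count"})
    nat = reference.totals_by(by).rename(columns={"n": "national_count"})
    merged = prm.merge(nat, on=cols, how="outer")
    merged["prm_count"] = merged["prm_count"].fillna(0).astype(int)
    merged["national_count"] = merged["national_count"].fillna(0).astype(int)
    return merged.sort_values(cols, kind="stable").reset_index(drop=True)


def coverage_rates(
    prm_counts: pd.DataFrame,
    reference: NationalReference,
    by: tuple[str, ...] = ("category",),
) -> CoverageReport:
    """Coverage per (cancer, *by) stratum and per-cancer totals.

    ``prm_counts`` as produced by :func:`patient_counts_by_stratum`. Strata
    with a national count of zero but a positive cohort count get an
    undefined (NaN) coverage with a warning.
    """
    merged = _align(prm_counts, reference, by)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = merged["prm_count"] / merged["national_count"]
    undefined = (merged["national_count"] == 0) & (merged["prm_count"] > 0)
    if undefined.any():
        warnings.warn(
            f"{int(undefined.sum())} strata have cohort patients but no "
            "national count; coverage undefined there",
            stacklevel=2,
        )
    rate = rate.where(merged["national_count"] > 0)
    merged["coverage_rate"] = rate

    totals = merged.groupby("cancer", as_index=False)[
        ["prm_count", "national_count"]
    ].sum()
    totals["coverage_rate"] = totals["prm_count"] / totals["national_count"]
    return CoverageReport(by=by, table=merged, totals=totals)


@dataclass
class RepresentativenessReport:
    """Cohort vs national distribution across strata, per cancer."""

    by: tuple[str, ...]
    table: pd.DataFrame  # cancer, *by, prm_share, national_share, abs_diff_pp, flagged
    chi_square: dict[str, dict]  # cancer -> {statistic, pvalue, dof}
    flag_threshold_pp: float

    def to_json(self) -> dict:
        return {
            "by": list(self.by),
            "flag_threshold_pp": self.flag_threshold_pp,
            "strata": self.table.to_dict(orient="records"),
            "chi_square": self.chi_square,
        }

    def render_markdown(self) -> str:
        lines = [
            "# Representativeness",
            "",
            "| Cancer | " + " | ".join(self.by)
            + " | Cohort share | National share | Diff (pp) | Flag |",
            "|---" * (len(self.by) + 5) + "|",
        ]
        for row in self.table.itertuples(index=False):
            cells = [str(getattr(row, c)) for c in ("cancer", *self.by)]
            lines.append(
                "| " + " | ".join(cells)
                + f" | {100 * row.prm_share:.1f}% | {100 * row.national_share:.1f}%"
                + f" | {row.abs_diff_pp:.1f} | {'*' if row.flagged else ''} |"
            )
        lines.append("")
        for cancer, res in self.chi_square.items():
            lines.append(
                f"Chi-square ({cancer}): statistic {res['statistic']:.2f}, "
                f"p = {res['pvalue']:.3g} (descriptive)"
            )
        return "\n".join(lines) + "\n"


def representativeness(
    prm_counts: pd.DataFrame,
    reference: NationalReference,
    by: tuple[str, ...] = ("category",),
    flag_threshold_pp: float = DEFAULT_FLAG_THRESHOLD_PP,
) -> RepresentativenessReport:
    """Compare cohort and national patient distributions across strata."""
    merged = _align(prm_counts, reference, by)
    if (merged.groupby("cancer")["national_count"].sum() == 0).any():
        raise ValueError("national total is zero for at least one cancer")

    parts = []
    chi: dict[str, dict] = {}
    for cancer, sub in merged.groupby("cancer", sort=True):
        sub = sub.copy()
        prm_total = sub["prm_count"].sum()
        nat_total = sub["national_count"].sum()
        sub["prm_share"] = (
            sub["prm_count"] / prm_total if prm_total else np.nan
        )
        sub["national_share"] = sub["national_count"] / nat_total
        sub["abs_diff_pp"] = (
            100 * (sub["prm_share"] - sub["national_share"])
        ).abs()
        sub["flagged"] = sub["abs_diff_pp"] > flag_threshold_pp
        parts.append(sub)

        if prm_total:
            expected = sub["national_share"].to_numpy() * prm_total
            observed = sub["prm_count"].to_numpy()
            keepm = expected > 0
            if (observed[~keepm] > 0).any():
                # cohort patients in a stratum with zero national share
                chi[str(cancer)] = {
                    "statistic": float("inf"), "pvalue": 0.0,
                    "dof": int(keepm.sum() - 1),
                }
            else:
                statistic, pvalue = stats.chisquare(
                    observed[keepm], f_exp=expected[keepm]
                )
                chi[str(cancer)] = {
                    "statistic": float(statistic),
                    "pvalue": float(pvalue),
                    "dof": int(keepm.sum() - 1),
                }
    table = pd.concat(parts, ignore_index=True)
    return RepresentativenessReport(
        by=by, table=table, chi_square=chi, flag_threshold_pp=flag_threshold_pp
    )
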