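"""Quality control of the inference rules by stratified patient review.

For each inference rule, a simple random sample of the patients the rule
touched is reviewed and the proportion of correct applications is
estimated with an exact (Clopper–Pearson) binomial confidence interval.
The review sample size comes from the classical finite-population-corrected
formula

    n = ceil( n0 / (1 + n0/N) ),   n0 = z^2 p (1-p) / e^2

with planning defaults e = 0.10 (margin of error), z = 1.65 and p = 0.50
(the most unfavorable variance); for populations of a few hundred patients
this yields samples of about 60. In a production deployment the review is
a human chart review against the source record; here correctness is judged
against the synthetic generator's retained ground truth — the sampling and
estimation machinery is identical by design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .inference import ALGORITHMS, InferenceAudit


@dataclass(frozen=True)
class QCParams:
    """Planning parameters for the review sample size and interval."""

    e: float = 0.10   # margin of error
    z: float = 1.65   # normal score
    p: float = 0.50   # planning proportion (worst-case variance)
    conf: float = 0.95  # CI confidence level

    def __post_init__(self) -> None:
        if not 0 < self.e < 1:
            raise ValueError("margin of error e must be in (0, 1)")
        if self.z <= 0:
            raise ValueError("z must be positive")
        if not 0 <= self.p <= 1:
            raise ValueError("planning proportion p must be in [0, 1]")
        if not 0 < self.conf < 1:
            raise ValueError("confidence must be in (0, 1)")


def qc_sample_size(params: QCParams, N: int) -> int:
    """Finite-population-corrected review sample size (ceiling-rounded).

    Monotone non-decreasing in N, decreasing in the margin of error, never
    larger than N, and -> ceil(z^2 p(1-p)/e^2) as N grows.
    """
    if N < 1:
        raise ValueError("population size N must be >= 1")
    n0 = params.z ** 2 * params.p * (1 - params.p) / params.e ** 2
    if n0 == 0:
        return 0
    n = n0 / (1 + n0 / N)
    return min(N, math.ceil(n - 1e-12))


def clopper_pearson(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval from Beta quantiles.

    ``lower = Beta(alpha/2; k, n-k+1)`` and
    ``upper = Beta(1-alpha/2; k+1, n-k)`` with the conventional closures
    lower = 0 at k = 0 and upper = 1 at k = n.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must satisfy 0 <= k <= n")
    alpha = 1.0 - conf
    lower = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lower, upper


@dataclass
class QCResult:
    """Correct-application estimate for one inference rule."""

    algorithm_id: str
    N: int                       # patients touched by the rule
    n: int                       # reviewed sample size
    k: int                       # correct applications in the sample
    proportion: float            # k / n (NaN when untouched)
    ci: tuple[float, float] | None

    def to_json(self) -> dict:
        return {
            "algorithm_id": self.algorithm_id,
            "N": self.N,
            "n": self.n,
            "k": self.k,
            "proportion": None if math.isnan(self.proportion) else self.proportion,
            "ci_lower": None if self.ci is None else self.ci[0],
            "ci_upper": None if self.ci is None else self.ci[1],
        }


def run_algorithm_qc(
    audit: InferenceAudit,
    truth,
    algorithm_id: str,
    params: QCParams | None = None,
    seed: int = 0,
) -> QCResult:
    """Review a random sample of the patients one rule touched.

    ``truth`` is a :class:`eprkit.synthetic.GroundTruth` (or any object
    with ``stage_by_record``/``line_by_record`` maps). A sampled patient is
    correct iff, for every field the rule changed on that patient, the
    *final* inferred value equals the true value. Deterministic for a fixed
    seed. When the rule touched no more patients than the uncorrected
    planning size ceil(z^2 p(1-p)/e^2) (69 at the defaults), every patient
    is reviewed; otherwise a sample of the FPC size is drawn.
    """
    if algorithm_id not in ALGORITHMS:
        raise ValueError(f"unknown algorithm id {algorithm_id}")
    params = params or QCParams()
    patients = audit.patients_touched(algorithm_id)
    N = len(patients)
    if N == 0:
        return QCResult(algorithm_id, 0, 0, 0, float("nan"), None)

    n0 = params.z ** 2 * params.p * (1 - params.p) / params.e ** 2
    n = N if N <= math.ceil(n0) else qc_sample_size(params, N)
    rng = np.random.default_rng(seed)
    sampled = (
        patients if n >= N
        else [patients[i] for i in rng.choice(N, size=n, replace=False)]
    )

    final = audit.final_values()
    truth_by_field = {
        "disease_stage": truth.stage_by_record,
        "treatment_line": truth.line_by_record,
    }
    changed: dict[str, list[tuple[str, str]]] = {}
    for e in audit.entries:
        if e["algorithm_id"] == algorithm_id:
            changed.setdefault(e["patient"], []).append(
                (e["record_id"], e["field"])
            )

    k = 0
    for patient in sampled:
        ok = True
        for record_id, fieldname in changed[patient]:
            expected = truth_by_field[fieldname].get(record_id)
            if expected is None or final[(record_id, fieldname)] != expected:
                ok = False
                break
        k += ok
    n_reviewed = len(sampled)
    return QCResult(
        algorithm_id, N, n_reviewed, k, k / n_reviewed,
        clopper_pearson(k, n_reviewed, params.conf),
    )


def qc_all(
    audit: InferenceAudit, truth, params: QCParams | None = None, seed: int = 0
) -> list[QCResult]:
    """Run the review for every inference rule (per-rule seeds derived from
    ``seed`` so samples are independent but reproducible)."""
    seeds = np.random.SeedSequence(seed).spawn(len(ALGORITHMS))
    return [
        run_algorithm_qc(
            audit, truth, alg, params=params,
            seed=int(s.generate_state(1)[0] % (2 ** 31)),
        )
        for alg, s in zip(ALGORITHMS, seeds)
    ]


def render_qc_markdown(results: list[QCResult]) -> str:
    lines = [
        "# Inference-rule quality control",
        "",
        "| Rule | N touched | n reviewed | correct | Proportion | 95% CI |",
        "|---|---|---|---|---|---|",
    ]
    for r in results:
        if r.N == 0:
            lines.append(f"| {r.algorithm_id} | 0 | 0 | 0 | NA | NA |")
            continue
        lo, hi = r.ci
        lines.append(
            f"| {r.algorithm_id} | {r.N} | {r.n} | {r.k} "
            f"| {100 * r.proportion:.1f}% | [{100 * lo:.1f}%, {100 * hi:.1f}%] |"
        )
    return "\n".join(lines) + "\n"
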