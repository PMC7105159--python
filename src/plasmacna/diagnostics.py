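"""Clinical-rule evaluation: 2x2 tables, test metrics, prevalence adjustment.

Evaluates threshold rules on clinical markers (serum LDH at >= 279 U/L, age
at > 49 years) for separating benign leiomyoma (LM) from leiomyosarcoma
(LMS), computes the standard diagnostic metrics with confidence intervals,
Welch two-sample tests for group comparisons, Bayes-adjusted predictive
values at an assumed population prevalence, and a recurrently-mutated-gene
tally over an exome mutation table.

Disease-positive means LMS throughout; test-positive means above the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint


@dataclass(frozen=True)
class ContingencyTable:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class DiagnosticReport:
    """Point estimates (None when the denominator is 0) with CIs per metric."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    ci: dict = field(default_factory=dict)        # metric -> (low, high) or None
    ci_method: dict = field(default_factory=dict)  # metric -> method tag
    prevalence_used: Optional[float] = None


def contingency_from_threshold(
    values: Sequence[float],
    labels: Sequence[str],
    cutoff: float,
    positive_direction: str = "ge",
    positive_label: str = "LMS",
) -> ContingencyTable:
    """Dichotomize a marker at a cutoff against binary diagnosis labels.

    ``positive_direction='ge'`` calls values >= cutoff test-positive (the LDH
    rule is inclusive); ``'gt'`` requires strictly greater (the age rule, so
    age exactly 49 is test-negative).
    """
    if positive_direction not in ("ge", "gt"):
        raise ValueError("positive_direction must be 'ge' or 'gt'")
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("marker values must be finite")
    if len(values) != len(labels):
        raise ValueError("values and labels differ in length")
    test_pos = values >= cutoff if positive_direction == "ge" else values > cutoff
    disease = np.array([l == positive_label for l in labels], dtype=bool)
    return ContingencyTable(
        tp=int(np.sum(test_pos & disease)),
        fp=int(np.sum(test_pos & ~disease)),
        fn=int(np.sum(~test_pos & disease)),
        tn=int(np.sum(~test_pos & ~disease)),
    )


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def _wilson_ci(x: int, n: int) -> Optional[tuple[float, float]]:
    if n == 0:
        return None
    lo, hi = proportion_confint(x, n, alpha=0.05, method="wilson")
    p = x / n
    return float(np.clip(min(lo, p), 0.0, 1.0)), float(np.clip(max(hi, p), 0.0, 1.0))


def _logit_ci(x: int, n: int) -> Optional[tuple[float, float]]:
    """Standard logit-transform CI; falls back to Wilson at the boundaries."""
    if n == 0:
        return None
    if x == 0 or x == n:
        return _wilson_ci(x, n)
    p = x / n
    se = np.sqrt(1 / x + 1 / (n - x))
    z = stats.norm.ppf(0.975)
    logit = np.log(p / (1 - p))
    lo, hi = logit - z * se, logit + z * se
    expit = lambda v: 1 / (1 + np.exp(-v))
    return float(expit(lo)), float(expit(hi))


def test_metrics(table: ContingencyTable, ci_method: str = "default") -> DiagnosticReport:
    """Sensitivity, specificity, PPV, NPV with CIs from a 2x2 table.

    Default CI construction: Wilson for sensitivity/specificity, standard
    logit for the predictive values; ``ci_method`` may force ``'wilson'`` or
    ``'logit'`` for all four.  Zero denominators yield None estimates with a
    None CI rather than an error.
    """
    if ci_method not in ("default", "wilson", "logit"):
        raise ValueError(f"unknown ci_method {ci_method!r}")
    t = table
    pairs = {
        "sensitivity": (t.tp, t.tp + t.fn),
        "specificity": (t.tn, t.tn + t.fp),
        "ppv": (t.tp, t.tp + t.fp),
        "npv": (t.tn, t.tn + t.fn),
    }
    default_methods = {"sensitivity": "wilson", "specificity": "wilson",
                       "ppv": "logit", "npv": "logit"}
    report = DiagnosticReport(
        sensitivity=_ratio(*pairs["sensitivity"]),
        specificity=_ratio(*pairs["specificity"]),
        ppv=_ratio(*pairs["ppv"]),
        npv=_ratio(*pairs["npv"]),
        prevalence_used=_ratio(t.tp + t.fn, t.total),
    )
    for metric, (x, n) in pairs.items():
        method = default_methods[metric] if ci_method == "default" else ci_method
        ci = _wilson_ci(x, n) if method == "wilson" else _logit_ci(x, n)
        report.ci[metric] = ci
        report.ci_method[metric] = method if ci is not None else None
    return report


def bayes_predictive_values(
    sensitivity: float, specificity: float, prevalence: float
) -> tuple[float, float]:
    """Prevalence-adjusted PPV and NPV by Bayes' rule.

    ppv = se*pi / (se*pi + (1-sp)*(1-pi));
    npv = sp*(1-pi) / (sp*(1-pi) + (1-se)*pi).
    """
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity),
                    ("prevalence", prevalence)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    se, sp, pi = sensitivity, specificity, prevalence
    ppv_den = se * pi + (1 - sp) * (1 - pi)
    npv_den = sp * (1 - pi) + (1 - se) * pi
    ppv = se * pi / ppv_den if ppv_den > 0 else float("nan")
    npv = sp * (1 - pi) / npv_den if npv_den > 0 else float("nan")
    return ppv, npv


def welch_t(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unpaired t-test: (t, Welch-Satterthwaite df, two-sided p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        # degenerate: identical constants give t = 0, p = 1 by convention
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        raise ValueError("both groups have zero variance with unequal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def recurrent_gene_tally(
    mutations: pd.DataFrame,
    n_patients: int,
    min_recurrence: int = 2,
) -> pd.DataFrame:
    """Genes deleteriously mutated in at least ``min_recurrence`` patients.

    ``mutations`` has columns (patient_id, gene, deleterious); multiple
    mutations of one gene in one patient count that patient once.  Returns a
    frame (gene, n_mutated, fraction, pct) sorted by descending count; pct is
    the integer-rounded percent of ``n_patients``.
    """
    if n_patients <= 0:
        raise ValueError("n_patients must be positive")
    required = {"patient_id", "gene", "deleterious"}
    if not required.issubset(mutations.columns):
        raise ValueError(f"mutation table needs columns {sorted(required)}")
    dele = mutations[mutations["deleterious"].astype(bool)]
    counts = dele.groupby("gene")["patient_id"].nunique()
    counts = counts[counts >= min_recurrence].sort_values(ascending=False)
    out = pd.DataFrame(
        {
            "gene": counts.index,
            "n_mutated": counts.to_numpy(),
            "fraction": counts.to_numpy() / n_patients,
            "pct": np.round(100.0 * counts.to_numpy() / n_patients).astype(int),
        }
    ).reset_index(drop=True)
    return out
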