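"""Pediatric-vs-adult contrast of per-PT reporting.

For each PT the adult and pediatric cohorts' (report, PT) pair counts form a
2x2 table

    ========  ==========  =============
              PT present  PT absent
    adults        a_adult     b_adult
    children      a_child     b_child
    ========  ==========  =============

compared with a reporting odds ratio (adults in the numerator, so ROR < 1
means relatively more reporting in children) and a two-sided Fisher exact
test.  A PT is labelled child-dominant when the ROR upper CI is below 1 with
p < alpha, adult-dominant when the lower CI exceeds 1 with p < alpha, and
indeterminate otherwise.
"""

from __future__ import annotations

import logging
import math
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .cohort_builder import Cohort
from .signal_engine import Z95

log = logging.getLogger(__name__)

#: relative tolerance when summing tables no more probable than the observed
FISHER_RELATIVE_GATE = 1e-7


class ComparisonTable(NamedTuple):
    a_adult: int
    b_adult: int
    a_child: int
    b_child: int


class RorCI(NamedTuple):
    ror: float
    lower: float
    upper: float
    defined: bool


def comparison_ror(t: ComparisonTable) -> RorCI:
    """ROR = (a_adult/b_adult)/(a_child/b_child) with Wald 95% CI.

    Undefined when any cell is zero.  ROR < 1 reads as relatively more
    reporting in children.
    """
    if min(t) == 0:
        return RorCI(math.nan, math.nan, math.nan, False)
    ror = (t.a_adult / t.b_adult) / (t.a_child / t.b_child)
    se = math.sqrt(1 / t.a_adult + 1 / t.b_adult + 1 / t.a_child + 1 / t.b_child)
    return RorCI(
        ror, math.exp(math.log(ror) - Z95 * se), math.exp(math.log(ror) + Z95 * se), True
    )


def fisher_exact_two_sided(t: ComparisonTable) -> float:
    """Two-sided Fisher exact p by log-space hypergeometric enumeration.

    p sums the probabilities of all tables with the observed margins whose
    hypergeometric probability does not exceed the observed one (up to a
    1 + 1e-7 relative tolerance); p in (0, 1].  The all-zero table returns 1
    by convention.
    """
    a, b, c, d = (int(v) for v in t)
    if min(a, b, c, d) < 0:
        raise ValueError("cells must be non-negative")
    n = a + b + c + d
    if n == 0:
        log.warning("fisher_exact_two_sided: all-zero table, p = 1 by convention")
        return 1.0
    row1 = a + b
    col1 = a + c
    kmin = max(0, col1 - (c + d))
    kmax = min(row1, col1)
    support = np.arange(kmin, kmax + 1)
    logpmf = hypergeom.logpmf(support, n, col1, row1)
    log_obs = hypergeom.logpmf(a, n, col1, row1)
    keep = logpmf <= log_obs + math.log1p(FISHER_RELATIVE_GATE)
    p = float(np.exp(logpmf[keep]).sum())
    return min(p, 1.0)


def classify_direction(ror: RorCI, p: float, alpha: float = 0.05) -> str:
    if ror.defined and p < alpha:
        if ror.upper < 1.0:
            return "child-dominant"
        if ror.lower > 1.0:
            return "adult-dominant"
    return "indeterminate"


COMPARISON_COLUMNS = [
    "pt", "a_adult", "b_adult", "a_child", "b_child",
    "ror", "ci_low", "ci_high", "p", "direction",
]


def compare_populations(
    child: Cohort,
    adult: Cohort,
    pts: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-PT pediatric-vs-adult comparison over the listed PTs.

    ``pts`` defaults to every PT observed in either cohort (callers that
    want the published workflow pass the PTs that were signal-positive in at
    least one stratum).  PTs absent from both cohorts are skipped and
    logged.  Rows are sorted by ROR.
    """
    if child.n_report_pt_pairs == 0 or adult.n_report_pt_pairs == 0:
        log.warning(
            "compare_populations: empty %s cohort, every PT skipped",
            "child" if child.n_report_pt_pairs == 0 else "adult",
        )
        return pd.DataFrame(columns=COMPARISON_COLUMNS)
    child_key = child.pairs["pt"].str.upper()
    adult_key = adult.pairs["pt"].str.upper()
    child_counts = child_key.groupby(child_key).size()
    adult_counts = adult_key.groupby(adult_key).size()
    spelling = pd.concat([adult.pairs["pt"], child.pairs["pt"]])
    spelling = spelling.groupby(spelling.str.upper()).first()

    if pts is None:
        keys = sorted(set(child_counts.index) | set(adult_counts.index))
    else:
        keys = [str(p).strip().upper() for p in pts]

    n_child = child.n_report_pt_pairs
    n_adult = adult.n_report_pt_pairs
    rows = []
    for key in keys:
        a_child = int(child_counts.get(key, 0))
        a_adult = int(adult_counts.get(key, 0))
        if a_child == 0 and a_adult == 0:
            log.info("compare_populations: PT %r absent from both cohorts, skipped", key)
            continue
        t = ComparisonTable(a_adult, n_adult - a_adult, a_child, n_child - a_child)
        ror = comparison_ror(t)
        p = fisher_exact_two_sided(t)
        rows.append(
            {
                "pt": spelling.get(key, key),
                "a_adult": t.a_adult, "b_adult": t.b_adult,
                "a_child": t.a_child, "b_child": t.b_child,
                "ror": ror.ror, "ci_low": ror.lower, "ci_high": ror.upper,
                "p": p, "direction": classify_direction(ror, p, alpha),
            }
        )
    df = pd.DataFrame(rows, columns=COMPARISON_COLUMNS)
    return df.sort_values("ror", kind="stable", na_position="last").reset_index(drop=True)
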