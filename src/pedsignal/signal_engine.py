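"""Disproportionality statistics on four-fold contingency tables.

Signal detection in spontaneous-report data compares how often an event is
reported with the drug of interest against how often it is reported with all
other drugs, via the 2x2 table

    =============  ===========  ============
                   target event  other events
    target drug         a             b
    other drugs         c             d
    =============  ===========  ============

The counting unit is the (report, PT) pair after within-report PT
deduplication, so a+b equals the cohort's report-PT pair total; report-level
counting is available behind ``counting="reports"``.

Four estimators are computed per term:

* ROR  = ad/bc with a Wald 95% CI on the log scale.
* PRR  = [a/(a+b)] / [c/(c+d)] gated with a 1-df chi-square (Yates-corrected
  by default).
* BCPNN information component IC = log2[aN/((a+b)(a+c))], with IC025 =
  E(IC) - 2*sqrt(V(IC)) from the Bate moment approximations under the
  standard Dirichlet priors (margins 1/2, joint 1).
* MGPS in its relative-reporting-ratio form: EBGM = aN/((a+b)(a+c)),
  EBGM05 = exp(ln EBGM - 1.64*sqrt(1/a+1/b+1/c+1/d)), a one-sided 90%
  lognormal lower bound.  (The full two-component gamma mixture of
  DuMouchel is out of scope; with this form IC = log2(EBGM) identically.)

A term is a signal only when all four positivity rules hold simultaneously
and a >= min_a (default 3): ROR CI lower > 1; PRR >= 2 with chi2 >= 4;
IC025 > 0; EBGM05 > 2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort_builder import Cohort

log = logging.getLogger(__name__)

Z95 = 1.96
Z90_ONE_SIDED = 1.64


@dataclass(frozen=True)
class FourFoldTable:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a non-negative integer, got {v}")
        if self.n == 0:
            raise ValueError("empty table: N must be positive")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


class RorResult(NamedTuple):
    ror: float
    lower: float
    upper: float
    defined: bool


class PrrResult(NamedTuple):
    prr: float
    chi2: float
    defined: bool


class IcResult(NamedTuple):
    ic: float
    ic025: float
    defined: bool


class EbgmResult(NamedTuple):
    ebgm: float
    ebgm05: float
    defined: bool


@dataclass(frozen=True)
class BcpnnPriors:
    """Pseudo-counts of the standard BCPNN Dirichlet priors."""

    alpha1: float = 1.0
    beta1: float = 1.0
    alpha: float = 2.0
    beta: float = 2.0
    gamma11: float = 1.0

    def gamma(self, t: FourFoldTable) -> float:
        # chosen so the prior IC expectation is 0 at the observed margins
        return (
            self.gamma11
            * (t.n + self.alpha)
            * (t.n + self.beta)
            / ((t.a + t.b + self.alpha1) * (t.a + t.c + self.beta1))
        )


@dataclass(frozen=True)
class SignalCriteria:
    """All-four positivity gate (every rule must hold, plus a >= min_a)."""

    min_a: int = 3
    ror_ci_low_gt: float = 1.0
    prr_min: float = 2.0
    chi2_min: float = 4.0
    ic025_gt: float = 0.0
    ebgm05_gt: float = 2.0
    chi2_continuity_correction: bool = True


def ror_statistic(t: FourFoldTable) -> RorResult:
    """Reporting odds ratio ad/bc with Wald 95% CI on the log scale.

    Undefined (NaN, ``defined=False``) when any cell is zero; no Haldane
    correction is applied by default.
    """
    if min(t.a, t.b, t.c, t.d) == 0:
        return RorResult(math.nan, math.nan, math.nan, False)
    ror = (t.a * t.d) / (t.b * t.c)
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    return RorResult(
        ror, math.exp(math.log(ror) - Z95 * se), math.exp(math.log(ror) + Z95 * se), True
    )


def prr_statistic(t: FourFoldTable, continuity_correction: bool = True) -> PrrResult:
    """Proportional reporting ratio and its 1-df chi-square.

    chi2 = sum over cells of (|O-E| - cc)^2 / E with expectations from the
    margins; cc = 0.5 (Yates) when ``continuity_correction``.
    """
    if t.a + t.b == 0 or t.c + t.d == 0 or t.c == 0:
        return PrrResult(math.nan, math.nan, False)
    prr = (t.a / (t.a + t.b)) / (t.c / (t.c + t.d))
    n = t.n
    obs = np.array([t.a, t.b, t.c, t.d], dtype=float)
    exp = (
        np.array(
            [
                (t.a + t.b) * (t.a + t.c),
                (t.a + t.b) * (t.b + t.d),
                (t.c + t.d) * (t.a + t.c),
                (t.c + t.d) * (t.b + t.d),
            ],
            dtype=float,
        )
        / n
    )
    cc = 0.5 if continuity_correction else 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        dev = np.maximum(np.abs(obs - exp) - cc, 0.0)
        terms = np.where(exp > 0, dev**2 / exp, 0.0)
    return PrrResult(prr, float(terms.sum()), True)


def bcpnn_statistic(t: FourFoldTable, priors: BcpnnPriors | None = None) -> IcResult:
    """BCPNN information component and its 2.5% credibility bound.

    IC is the simplified point estimate log2 of the relative reporting
    ratio; IC025 = E(IC) - 2*sqrt(V(IC)) with the Bate closed-form moments.
    For a = 0 the point estimate is -inf (flagged) while the moments remain
    computable.
    """
    p = priors or BcpnnPriors()
    n = t.n
    a, ab, ac = t.a, t.a + t.b, t.a + t.c
    if a == 0 or ab == 0 or ac == 0:
        ic = -math.inf
        defined = False
    else:
        ic = math.log2(a * n / (ab * ac))
        defined = True
    g = p.gamma(t)
    e_ic = math.log2(
        (a + p.gamma11)
        * (n + p.alpha)
        * (n + p.beta)
        / ((n + g) * (ab + p.alpha1) * (ac + p.beta1))
    )
    v_ic = (
        (n - a + g - p.gamma11) / ((a + p.gamma11) * (1 + n + g))
        + (n - ab + p.alpha - p.alpha1) / ((ab + p.alpha1) * (1 + n + p.alpha))
        + (n - ac + p.beta - p.beta1) / ((ac + p.beta1) * (1 + n + p.beta))
    ) / math.log(2) ** 2
    ic025 = e_ic - 2.0 * math.sqrt(v_ic)
    return IcResult(ic, ic025, defined)


def mgps_statistic(t: FourFoldTable) -> EbgmResult:
    """EBGM in relative-reporting-ratio form with a lognormal lower bound."""
    n = t.n
    ab, ac = t.a + t.b, t.a + t.c
    if ab == 0 or ac == 0 or t.a == 0:
        return EbgmResult(math.nan, math.nan, False)
    ebgm = t.a * n / (ab * ac)
    if min(t.a, t.b, t.c, t.d) == 0:
        return EbgmResult(ebgm, math.nan, False)
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    ebgm05 = math.exp(math.log(ebgm) - Z90_ONE_SIDED * se)
    return EbgmResult(ebgm, ebgm05, True)


# ---------------------------------------------------------------------------
# table construction
# ---------------------------------------------------------------------------

def _soc_lookup(mapping: Mapping[str, str]) -> dict[str, str]:
    return {str(pt).strip().upper(): str(soc).strip() for pt, soc in mapping.items()}


def map_pt_to_soc(pts: pd.Series, mapping: Mapping[str, str]) -> pd.Series:
    """Map PT strings to SOC, case-insensitively after whitespace normalization."""
    lut = _soc_lookup(mapping)
    keys = pts.astype(str).str.strip().str.replace(r"\s+", " ", regex=True).str.upper()
    return keys.map(lut)


def read_pt_soc_mapping(path) -> dict[str, str]:
    """Read a two-column (pt, soc) mapping file (comma or tab delimited).

    A header row is accepted when its first cell is 'pt' (any case).
    """
    df = pd.read_csv(path, sep=None, engine="python", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"mapping file {path} must have two columns (pt, soc)")
    df = df.iloc[:, :2]
    if str(df.iloc[0, 0]).strip().lower() == "pt":
        df = df.iloc[1:]
    return {str(r[0]).strip(): str(r[1]).strip() for r in df.itertuples(index=False)}


def build_contingency(
    term: str,
    level: str,
    cohort_pairs: pd.DataFrame,
    background_pairs: pd.DataFrame,
    mapping: Mapping[str, str] | None = None,
) -> FourFoldTable:
    """Four-fold table for one PT (or SOC) against the stratum background.

    ``cohort_pairs`` are the target drug's (report, PT) pairs;
    ``background_pairs`` the stratum-wide pairs and must contain them.  At
    SOC level every cohort PT must be covered by ``mapping`` (error naming
    the unmapped PTs otherwise).
    """
    coh_ids = set(zip(cohort_pairs["primaryid"], cohort_pairs["pt"].str.upper()))
    bg_ids = set(zip(background_pairs["primaryid"], background_pairs["pt"].str.upper()))
    if not coh_ids <= bg_ids:
        raise ValueError("cohort pairs are not a subset of the background pairs")

    target_ids = set(cohort_pairs["primaryid"])
    other = background_pairs[~background_pairs["primaryid"].isin(target_ids)]

    if level.upper() == "PT":
        key = str(term).strip().upper()
        coh_term = cohort_pairs["pt"].str.upper() == key
        other_term = other["pt"].str.upper() == key
    elif level.upper() == "SOC":
        if mapping is None:
            raise ValueError("SOC-level tables require a PT->SOC mapping")
        coh_soc = map_pt_to_soc(cohort_pairs["pt"], mapping)
        if coh_soc.isna().any():
            missing = sorted(cohort_pairs.loc[coh_soc.isna(), "pt"].unique())
            raise KeyError(f"PT(s) missing from the PT->SOC mapping: {missing}")
        other_soc = map_pt_to_soc(other["pt"], mapping)
        coh_term = coh_soc == term
        other_term = other_soc == term
    else:
        raise ValueError(f"unknown level {level!r}")

    a = int(coh_term.sum())
    b = len(cohort_pairs) - a
    c = int(other_term.sum())
    d = len(other) - c
    return FourFoldTable(a, b, c, d)


# ---------------------------------------------------------------------------
# full evaluation
# ---------------------------------------------------------------------------

UNMAPPED_SOC = "Unmapped (no SOC)"

RESULT_COLUMNS = [
    "term", "level", "soc", "a", "ror", "ror_low", "ror_high", "prr", "chi2",
    "ic", "ic025", "ebgm", "ebgm05", "p_chi2", "p_bh",
    "flag_ror", "flag_prr", "flag_bcpnn", "flag_mgps", "signal",
]


def _stat_row(
    term: str, level: str, soc: str, t: FourFoldTable, criteria: SignalCriteria
) -> dict:
    ror = ror_statistic(t)
    prr = prr_statistic(t, criteria.chi2_continuity_correction)
    ic = bcpnn_statistic(t)
    eb = mgps_statistic(t)
    flag_ror = ror.defined and ror.lower > criteria.ror_ci_low_gt
    flag_prr = (
        prr.defined and prr.prr >= criteria.prr_min and prr.chi2 >= criteria.chi2_min
    )
    flag_bcpnn = ic.ic025 > criteria.ic025_gt
    flag_mgps = eb.defined and eb.ebgm05 > criteria.ebgm05_gt
    p_chi2 = float(sps.chi2.sf(prr.chi2, 1)) if prr.defined else math.nan
    return {
        "term": term, "level": level, "soc": soc, "a": t.a,
        "ror": ror.ror, "ror_low": ror.lower, "ror_high": ror.upper,
        "prr": prr.prr, "chi2": prr.chi2,
        "ic": ic.ic, "ic025": ic.ic025,
        "ebgm": eb.ebgm, "ebgm05": eb.ebgm05,
        "p_chi2": p_chi2, "p_bh": math.nan,
        "flag_ror": flag_ror, "flag_prr": flag_prr,
        "flag_bcpnn": flag_bcpnn, "flag_mgps": flag_mgps,
        "signal": bool(
            flag_ror and flag_prr and flag_bcpnn and flag_mgps
            and t.a >= criteria.min_a
        ),
    }


def _pair_term_counts(pairs: pd.DataFrame, key: pd.Series) -> pd.Series:
    return key.groupby(key).size()


def evaluate_signals(
    cohort: Cohort,
    background_pairs: pd.DataFrame,
    mapping: Mapping[str, str],
    criteria: SignalCriteria | None = None,
    counting: str = "pairs",
) -> pd.DataFrame:
    """Per-PT and per-SOC disproportionality results with the all-four gate.

    One row per distinct cohort PT with a >= 1 and one per SOC.  Cohort PTs
    absent from ``mapping`` are pooled under a sentinel SOC and reported via
    a warning rather than dropped.  ``counting`` is ``"pairs"`` (default,
    report-PT pairs) or ``"reports"`` (each report counted once per term).
    A Benjamini-Hochberg column over the PT-level chi-square p-values is
    provided for reference only and never gates signals.
    """
    criteria = criteria or SignalCriteria()
    if cohort.n_report_pt_pairs == 0:
        log.warning("evaluate_signals: empty cohort, returning no results")
        return pd.DataFrame(columns=RESULT_COLUMNS)

    coh = cohort.pairs.copy()
    coh["primaryid"] = coh["primaryid"].astype(str)
    bg = background_pairs.copy()
    bg["primaryid"] = bg["primaryid"].astype(str)

    coh["_pt_key"] = coh["pt"].str.upper()
    bg["_pt_key"] = bg["pt"].str.upper()
    target_ids = set(coh["primaryid"])
    other = bg[~bg["primaryid"].isin(target_ids)]

    soc_of = map_pt_to_soc(coh["pt"], mapping)
    if soc_of.isna().any():
        unmapped = sorted(coh.loc[soc_of.isna(), "pt"].unique())
        log.warning(
            "evaluate_signals: %d PT(s) missing from the PT->SOC mapping, "
            "pooled under %r: %s", len(unmapped), UNMAPPED_SOC, unmapped
        )
    coh["_soc"] = soc_of.fillna(UNMAPPED_SOC)
    other_soc = map_pt_to_soc(other["pt"], mapping).fillna(UNMAPPED_SOC)
    other = other.assign(_soc=other_soc)

    if counting not in ("pairs", "reports"):
        raise ValueError(f"unknown counting unit {counting!r}")

    rows: list[dict] = []

    def _level_rows(level: str, key_col: str) -> None:
        if counting == "pairs":
            coh_counts = coh.groupby(key_col).size()
            other_counts = (
                other.groupby(key_col).size() if not other.empty else pd.Series(dtype=int)
            )
            n_coh = len(coh)
            n_other = len(other)
        else:
            # each report counts once per term; margins are report counts
            coh_counts = coh.drop_duplicates(["primaryid", key_col]).groupby(key_col).size()
            other_counts = (
                other.drop_duplicates(["primaryid", key_col]).groupby(key_col).size()
                if not other.empty else pd.Series(dtype=int)
            )
            n_coh = cohort.n_reports
            n_other = other["primaryid"].nunique()
        pt_soc = (
            coh.drop_duplicates("_pt_key").set_index("_pt_key")["_soc"]
            if key_col == "_pt_key" else None
        )
        pt_name = (
            coh.drop_duplicates("_pt_key").set_index("_pt_key")["pt"]
            if key_col == "_pt_key" else None
        )
        for key, a in coh_counts.items():
            a = int(a)
            c = int(other_counts.get(key, 0))
            t = FourFoldTable(a, n_coh - a, c, n_other - c)
            if key_col == "_pt_key":
                term, soc = str(pt_name[key]), str(pt_soc[key])
            else:
                term, soc = str(key), str(key)
            rows.append(_stat_row(term, level, soc, t, criteria))

    _level_rows("PT", "_pt_key")
    _level_rows("SOC", "_soc")

    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    # BH-adjusted chi-square p-values within each level, reference only
    from statsmodels.stats.multitest import multipletests

    for level in ("PT", "SOC"):
        mask = (df["level"] == level) & df["p_chi2"].notna()
        if mask.sum() > 0:
            df.loc[mask, "p_bh"] = multipletests(
                df.loc[mask, "p_chi2"].to_numpy(), method="fdr_bh"
            )[1]
    df = df.sort_values(
        ["level", "soc", "a"], ascending=[True, True, False], kind="stable"
    ).reset_index(drop=True)
    return df
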