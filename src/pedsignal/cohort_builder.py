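"""Case deduplication, drug-of-interest cohort construction and descriptive summaries.

Spontaneous-report databases contain the same case submitted several times
(follow-up versions, duplicate transmissions).  FAERS convention keeps, per
CASEID, the report with the most recent FDA acceptance date (FDA_DT) and, on
ties, the most recent PRIMARYID.  After deduplication, reports are selected
by drug-name synonym matching restricted to a role code (typically PS,
primary suspect) and stratified by age: pediatric = [0, 18) years, adult =
[18, inf); reports with missing or invalid age belong to neither stratum.

The descriptive summary mirrors the usual "Table 1" of pharmacovigilance
studies: sex, age bands, reporter occupation, top indications, a single
severity-prioritized outcome per report, top reporter countries, events per
year, and top concomitant medications (counted as drug-row mentions).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .faers_io import QuarterBundle

log = logging.getLogger(__name__)

PEDIATRIC_MAX_YEARS = 18.0

#: multiplicative factor from one unit to years (Julian year = 365.25 d)
AGE_UNIT_TO_YEARS: dict[str, float] = {
    "YR": 1.0,
    "DEC": 10.0,
    "MON": 1.0 / 12.0,
    "WK": 7.0 / 365.25,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

#: one outcome category per report, most severe first; CA/RI fold into OT
OUTCOME_PRIORITY = ("DE", "LT", "HO", "DS", "OT")
OUTCOME_FOLD = {"CA": "OT", "RI": "OT"}
OUTCOME_LABELS = {
    "DE": "Death",
    "LT": "Life-threatening",
    "HO": "Hospitalization - initial or prolonged",
    "DS": "Disability",
    "OT": "Other serious outcome",
}


def percent(count: float, denominator: float) -> float:
    """Percentage rounded half-up to 2 decimals (printed-table convention)."""
    if denominator == 0:
        return float("nan")
    q = Decimal(count) * 100 / Decimal(denominator)
    return float(q.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# deduplication
# ---------------------------------------------------------------------------

@dataclass
class DedupResult:
    demo: pd.DataFrame
    removed: int


def deduplicate_reports(demo: pd.DataFrame) -> DedupResult:
    """Keep one report per CASEID: max FDA_DT, ties broken by max PRIMARYID.

    PRIMARYID ties are compared numerically when both parse as integers,
    lexicographically otherwise.  Records with missing CASEID are retained as
    singletons keyed by their PRIMARYID.
    """
    if demo.empty:
        return DedupResult(demo.copy(), 0)
    d = demo.copy()
    caseid = d["caseid"].astype(object)
    key = caseid.where(caseid.notna(), "\x00PID\x00" + d["primaryid"].astype(str))
    fda = pd.to_numeric(d["fda_dt"], errors="coerce").fillna(-1.0)
    pid_num = pd.to_numeric(d["primaryid"], errors="coerce")
    pid_str = d["primaryid"].astype(str)
    order = pd.DataFrame(
        {"_key": key, "_fda": fda, "_pidn": pid_num, "_pids": pid_str},
        index=d.index,
    )
    # lexicographic first, numeric second, date last: later sorts dominate,
    # so within equal dates numeric primaryid order wins where it parses
    idx = (
        order.sort_values("_pids", kind="stable")
        .sort_values("_pidn", kind="stable", na_position="first")
        .sort_values("_fda", kind="stable")
        .index
    )
    d = d.loc[idx]
    keep = ~key.loc[idx].duplicated(keep="last")
    result = d.loc[keep].sort_index()
    removed = len(demo) - len(result)
    if removed:
        log.info("deduplicate_reports: removed %d duplicate case versions", removed)
    return DedupResult(result.reset_index(drop=True), removed)


# ---------------------------------------------------------------------------
# age handling
# ---------------------------------------------------------------------------

def convert_age_to_years(age_value, age_unit) -> float:
    """Convert one (value, unit) pair to years; NaN when missing or invalid."""
    if age_value is None or (isinstance(age_value, float) and np.isnan(age_value)):
        return float("nan")
    value = float(age_value)
    if value < 0:
        return float("nan")
    if age_unit is None or (isinstance(age_unit, float) and np.isnan(age_unit)) or age_unit is pd.NA:
        return value  # missing unit with a present value is taken as years
    unit = str(age_unit).strip().upper()
    if unit == "":
        return value
    factor = AGE_UNIT_TO_YEARS.get(unit)
    if factor is None:
        return float("nan")
    return value * factor


def ages_in_years(demo: pd.DataFrame) -> tuple[pd.Series, int]:
    """Vectorized age conversion; returns (years, n_invalid).

    ``n_invalid`` counts records with a present age that could not be
    converted (negative value or unknown unit); these are excluded from
    age-defined strata.
    """
    value = pd.to_numeric(demo["age_value"], errors="coerce")
    unit = demo["age_unit"].astype(object).where(demo["age_unit"].notna(), "YR")
    unit = unit.astype(str).str.strip().str.upper().replace("", "YR")
    factor = unit.map(AGE_UNIT_TO_YEARS)
    years = value * factor
    years = years.mask(value < 0)
    invalid = int((value.notna() & (factor.isna() | (value < 0))).sum())
    return years, invalid


# ---------------------------------------------------------------------------
# drug matching
# ---------------------------------------------------------------------------

def normalize_drug_name(name: str) -> str:
    return re.sub(r"\s+", " ", str(name).strip().upper())


def match_drug_reports(
    drug: pd.DataFrame,
    synonyms: Sequence[str],
    roles: Iterable[str] = ("PS",),
    policy: str = "exact",
) -> set[str]:
    """Primaryids of reports with a drug row matching a synonym in a role.

    Names (drugname and prod_ai) are normalized by upper-casing, trimming and
    collapsing internal whitespace.  ``policy`` is ``"exact"`` (whole-name
    equality, default) or ``"substring"`` (word-boundary substring).
    """
    if not synonyms:
        raise ValueError("synonym list must be non-empty")
    roleset = {str(r).upper() for r in roles}
    syn = [normalize_drug_name(s) for s in synonyms]
    rows = drug[drug["role_code"].astype(str).str.upper().isin(roleset)]
    if rows.empty:
        return set()
    name = rows["drugname"].astype(object).where(rows["drugname"].notna(), "")
    ai = rows["prod_ai"].astype(object).where(rows["prod_ai"].notna(), "")
    name = name.astype(str).str.upper().str.strip().str.replace(r"\s+", " ", regex=True)
    ai = ai.astype(str).str.upper().str.strip().str.replace(r"\s+", " ", regex=True)
    if policy == "exact":
        synset = set(syn)
        hit = name.isin(synset) | ai.isin(synset)
    elif policy == "substring":
        pattern = r"\b(?:" + "|".join(re.escape(s) for s in syn) + r")\b"
        hit = name.str.contains(pattern, regex=True) | ai.str.contains(pattern, regex=True)
    else:
        raise ValueError(f"unknown match policy {policy!r}")
    return set(rows.loc[hit, "primaryid"].astype(str))


def _matched_drug_row_mask(
    drug: pd.DataFrame, synonyms: Sequence[str], roles: Iterable[str], policy: str
) -> pd.Series:
    """Row-level mask: drug row has a matching name AND a selected role."""
    roleset = {str(r).upper() for r in roles}
    syn = [normalize_drug_name(s) for s in synonyms]
    name = drug["drugname"].astype(object).where(drug["drugname"].notna(), "")
    ai = drug["prod_ai"].astype(object).where(drug["prod_ai"].notna(), "")
    name = name.astype(str).str.upper().str.strip().str.replace(r"\s+", " ", regex=True)
    ai = ai.astype(str).str.upper().str.strip().str.replace(r"\s+", " ", regex=True)
    if policy == "exact":
        synset = set(syn)
        name_hit = name.isin(synset) | ai.isin(synset)
    else:
        pattern = r"\b(?:" + "|".join(re.escape(s) for s in syn) + r")\b"
        name_hit = name.str.contains(pattern, regex=True) | ai.str.contains(
            pattern, regex=True
        )
    role_hit = drug["role_code"].astype(str).str.upper().isin(roleset)
    return name_hit & role_hit


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """Deduplicated reports for one (drug, role, age-stratum) selection."""

    stratum: str
    drug_synonyms: list[str]
    report_ids: set[str]
    demo: pd.DataFrame                 # joined demographics with age_years
    pairs: pd.DataFrame                # (primaryid, pt) after within-report dedup
    outcomes: pd.DataFrame
    indications: pd.DataFrame
    concomitants: pd.DataFrame
    n_reports: int
    n_report_pt_pairs: int
    exclusions: dict[str, int] = field(default_factory=dict)


def dedup_report_pt_pairs(reac: pd.DataFrame) -> pd.DataFrame:
    """(primaryid, pt) pairs with within-report duplicate PTs collapsed.

    PT strings are whitespace-normalized and compared case-insensitively; the
    first spelling encountered is kept.
    """
    pairs = reac[["primaryid", "pt"]].dropna(subset=["pt"]).copy()
    pairs["pt"] = (
        pairs["pt"].astype(str).str.strip().str.replace(r"\s+", " ", regex=True)
    )
    pairs = pairs[pairs["pt"] != ""]
    pairs["_ptkey"] = pairs["pt"].str.upper()
    pairs = pairs.drop_duplicates(subset=["primaryid", "_ptkey"])
    return pairs.drop(columns="_ptkey").reset_index(drop=True)


STRATUM_ALIASES = {"child": "pediatric", "children": "pediatric", "paediatric": "pediatric"}


def _stratum_mask(years: pd.Series, stratum: str) -> pd.Series:
    stratum = STRATUM_ALIASES.get(stratum, stratum)
    if stratum == "pediatric":
        return (years >= 0) & (years < PEDIATRIC_MAX_YEARS)
    if stratum == "adult":
        return years >= PEDIATRIC_MAX_YEARS
    if stratum == "all":
        return pd.Series(True, index=years.index)
    raise ValueError(f"unknown stratum {stratum!r}")


def build_cohort(
    bundle: QuarterBundle,
    synonyms: Sequence[str],
    roles: Iterable[str] = ("PS",),
    stratum: str = "pediatric",
    policy: str = "exact",
) -> Cohort:
    """Dedup -> drug/role match -> age stratum -> join reactions/outcomes/etc.

    The pipeline order is fixed.  Concomitants are drug rows of matched
    reports that are not themselves (synonym AND role) matches.  An empty
    cohort is returned with a warning; downstream statistics must handle it.
    """
    stratum = STRATUM_ALIASES.get(stratum, stratum)
    dedup = deduplicate_reports(bundle.demo)
    demo = dedup.demo
    matched_ids = match_drug_reports(bundle.drug, synonyms, roles, policy)
    demo = demo[demo["primaryid"].astype(str).isin(matched_ids)].copy()
    n_matched = len(demo)

    years, n_invalid_age = ages_in_years(demo)
    demo["age_years"] = years
    in_stratum = _stratum_mask(years, stratum)
    if stratum != "all":
        demo = demo[in_stratum.fillna(False)]
    demo = demo.reset_index(drop=True)
    ids = set(demo["primaryid"].astype(str))

    reac = bundle.reac[bundle.reac["primaryid"].astype(str).isin(ids)]
    pairs = dedup_report_pt_pairs(reac)
    outcomes = bundle.outc[bundle.outc["primaryid"].astype(str).isin(ids)].copy()
    indications = bundle.indi[bundle.indi["primaryid"].astype(str).isin(ids)].copy()

    drug_rows = bundle.drug[bundle.drug["primaryid"].astype(str).isin(ids)]
    is_target_row = _matched_drug_row_mask(drug_rows, synonyms, roles, policy)
    concomitants = drug_rows[~is_target_row].copy()

    cohort = Cohort(
        stratum=stratum,
        drug_synonyms=[normalize_drug_name(s) for s in synonyms],
        report_ids=ids,
        demo=demo,
        pairs=pairs,
        outcomes=outcomes,
        indications=indications,
        concomitants=concomitants,
        n_reports=len(demo),
        n_report_pt_pairs=len(pairs),
        exclusions={
            "duplicates_removed": dedup.removed,
            "not_drug_or_role_matched": len(dedup.demo) - n_matched,
            "invalid_age": n_invalid_age,
            "outside_stratum": n_matched - len(demo),
        },
    )
    if cohort.n_reports == 0:
        log.warning("build_cohort: empty cohort for stratum %r", stratum)
    return cohort


def build_stratum_background(
    bundle: QuarterBundle, stratum: str = "pediatric"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-drug background for a stratum: (deduplicated demo, report-PT pairs).

    This is the denominator population for disproportionality tables; the
    target-drug cohort built from the same bundle and stratum is a subset.
    """
    stratum = STRATUM_ALIASES.get(stratum, stratum)
    dedup = deduplicate_reports(bundle.demo)
    demo = dedup.demo
    years, _ = ages_in_years(demo)
    demo = demo.assign(age_years=years)
    if stratum != "all":
        demo = demo[_stratum_mask(years, stratum).fillna(False)]
    demo = demo.reset_index(drop=True)
    ids = set(demo["primaryid"].astype(str))
    pairs = dedup_report_pt_pairs(
        bundle.reac[bundle.reac["primaryid"].astype(str).isin(ids)]
    )
    return demo, pairs


# ---------------------------------------------------------------------------
# descriptive summary
# ---------------------------------------------------------------------------

@dataclass
class DescriptiveSummary:
    table: pd.DataFrame        # columns: section, label, count, percent
    median_age: float
    n_reports: int
    n_no_outcome: int
    events_per_year: pd.DataFrame  # columns: year, count


def assign_outcome_category(outcomes: pd.DataFrame) -> pd.Series:
    """One severity-prioritized outcome per report (DE > LT > HO > DS > OT)."""
    if outcomes.empty:
        return pd.Series(dtype=object)
    oc = outcomes.copy()
    oc["outcome_code"] = (
        oc["outcome_code"].astype(str).str.upper().replace(OUTCOME_FOLD)
    )
    oc = oc[oc["outcome_code"].isin(OUTCOME_PRIORITY)]
    rank = {code: i for i, code in enumerate(OUTCOME_PRIORITY)}
    oc["_rank"] = oc["outcome_code"].map(rank)
    best = oc.sort_values("_rank", kind="stable").drop_duplicates("primaryid")
    return best.set_index("primaryid")["outcome_code"]


def summarize_cohort(
    cohort: Cohort,
    k: int = 10,
    age_bands: Sequence[tuple[float, float]] = ((0.0, 7.0), (7.0, 18.0)),
) -> DescriptiveSummary:
    """Table-1-style descriptive summary of a cohort.

    Sex, age-band, reporter, outcome and country percentages use the cohort
    size as denominator; concomitant percentages use total concomitant
    mentions (drug rows, not distinct reports).
    """
    if cohort.n_reports == 0:
        raise ValueError("cannot summarize an empty cohort")
    n = cohort.n_reports
    rows: list[tuple[str, str, float, float]] = []

    sex = cohort.demo["sex"].astype(object).where(cohort.demo["sex"].notna(), "Missing")
    sex = sex.replace({"F": "Female", "M": "Male"})
    for label in ("Female", "Male", "Missing"):
        c = int((sex == label).sum())
        rows.append(("sex", label, c, percent(c, n)))

    years = cohort.demo["age_years"]
    for lo, hi in age_bands:
        c = int(((years >= lo) & (years < hi)).sum())
        rows.append(("age", f"{lo:g}-<{hi:g}", c, percent(c, n)))

    rep = cohort.demo["reporter_type"].astype(object).where(
        cohort.demo["reporter_type"].notna(), "Missing"
    )
    for label, c in rep.value_counts().items():
        rows.append(("reporter", str(label), int(c), percent(int(c), n)))

    indi = cohort.indications["indication_pt"].dropna()
    for label, c in indi.value_counts().head(k).items():
        rows.append(("indication", str(label), int(c), percent(int(c), n)))

    outcome = assign_outcome_category(cohort.outcomes)
    outcome = outcome[outcome.index.isin(cohort.report_ids)]
    n_no_outcome = n - len(outcome)
    for code in OUTCOME_PRIORITY:
        c = int((outcome == code).sum())
        rows.append(("outcome", OUTCOME_LABELS[code], c, percent(c, n)))

    country = cohort.demo["reporter_country"].dropna()
    for label, c in country.value_counts().head(k).items():
        rows.append(("country", str(label), int(c), percent(int(c), n)))

    mentions = cohort.concomitants["drugname"].dropna().map(normalize_drug_name)
    total_mentions = len(mentions)
    for label, c in mentions.value_counts().head(k).items():
        rows.append(("concomitant", str(label), int(c), percent(int(c), total_mentions)))

    year = pd.to_numeric(
        cohort.demo["fda_dt"].astype(str).str[:4], errors="coerce"
    ).dropna().astype(int)
    per_year = (
        year.value_counts().sort_index().rename_axis("year").reset_index(name="count")
    )

    table = pd.DataFrame(rows, columns=["section", "label", "count", "percent"])
    return DescriptiveSummary(
        table=table,
        median_age=float(years.median()),
        n_reports=n,
        n_no_outcome=n_no_outcome,
        events_per_year=per_year,
    )
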