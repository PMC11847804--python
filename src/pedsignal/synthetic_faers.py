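"""Seeded generator of FAERS-format bundles with known drug-event associations.

The generator emulates the relational structure of a FAERS quarter — DEMO
rows keyed by PRIMARYID/CASEID with demographics, DRUG rows with role codes,
REAC rows of MedDRA PTs, OUTC and INDI rows — together with the pathologies
a real pipeline must survive: duplicate CASEIDs with perturbed FDA_DT,
missing demographics, and heterogeneous age units.

Events are drawn per report as independent Bernoulli trials per PT.  For an
injected PT with background probability p and odds multiplier RR, exposed
reports use

    p' = RR * p / (1 - p + RR * p)

so the true report-level odds ratio equals RR exactly, which is the quantity
the ROR estimates.  Reports that draw zero PTs are redrawn once and then
given a filler PT.  Ground truth records the realized per-PT exposed and
unexposed counts a correct pipeline should recover after deduplication.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import faers_io
from .faers_io import QuarterBundle

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PtSpec:
    pt: str
    soc: str
    p: float  # background per-report probability


#: anesthesia-flavoured default event vocabulary (pt, soc, background p)
DEFAULT_VOCABULARY: tuple[PtSpec, ...] = (
    PtSpec("Cardiac arrest", "Cardiac disorders", 0.010),
    PtSpec("Tachycardia", "Cardiac disorders", 0.015),
    PtSpec("Bradycardia", "Cardiac disorders", 0.012),
    PtSpec("Laryngospasm", "Respiratory, thoracic and mediastinal disorders", 0.008),
    PtSpec("Bronchospasm", "Respiratory, thoracic and mediastinal disorders", 0.010),
    PtSpec("Hypoxia", "Respiratory, thoracic and mediastinal disorders", 0.012),
    PtSpec("Pulmonary alveolar haemorrhage", "Respiratory, thoracic and mediastinal disorders", 0.004),
    PtSpec("Hypercapnia", "Respiratory, thoracic and mediastinal disorders", 0.004),
    PtSpec("Oxygen saturation decreased", "Investigations", 0.012),
    PtSpec("Pulse absent", "Investigations", 0.004),
    PtSpec("Malignant hyperthermia", "General disorders and administration site conditions", 0.005),
    PtSpec("Chills", "General disorders and administration site conditions", 0.015),
    PtSpec("Encephalopathy", "Nervous system disorders", 0.006),
    PtSpec("Dystonia", "Nervous system disorders", 0.006),
    PtSpec("Hypotension", "Vascular disorders", 0.020),
    PtSpec("Agitation", "Psychiatric disorders", 0.015),
    PtSpec("Rhabdomyolysis", "Musculoskeletal and connective tissue disorders", 0.006),
    PtSpec("Hepatotoxicity", "Hepatobiliary disorders", 0.006),
    PtSpec("Anaphylactic shock", "Immune system disorders", 0.006),
    PtSpec("Metabolic acidosis", "Metabolism and nutrition disorders", 0.008),
    PtSpec("Nausea", "Gastrointestinal disorders", 0.030),
    PtSpec("Vomiting", "Gastrointestinal disorders", 0.030),
    PtSpec("Rash", "Skin and subcutaneous tissue disorders", 0.025),
    PtSpec("Pyrexia", "General disorders and administration site conditions", 0.030),
    PtSpec("Headache", "Nervous system disorders", 0.030),
)

FILLER_PT = PtSpec("Drug ineffective", "General disorders and administration site conditions", 0.0)

DEFAULT_TARGET_SYNONYMS = ("SEVOFLURANE", "ULTANE", "SEVORANE")
DEFAULT_OTHER_DRUGS = (
    "PROPOFOL", "MIDAZOLAM", "KETAMINE", "IBUPROFEN", "AMOXICILLIN",
    "VALPROATE", "ONDANSETRON", "SALBUTAMOL", "PARACETAMOL", "MORPHINE",
)
DEFAULT_CONCOMITANTS = (
    "PROPOFOL", "FENTANYL", "MIDAZOLAM", "ROCURONIUM", "ACETAMINOPHEN",
    "ONDANSETRON", "DEXAMETHASONE", "ATROPINE", "SUXAMETHONIUM", "REMIFENTANIL",
)
TARGET_INDICATIONS = ("Anaesthesia", "General anaesthesia", "Induction of anaesthesia")
OTHER_INDICATIONS = ("Pain", "Infection", "Sedation", "Epilepsy")


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic bundle.

    ``signal_map`` maps PT name -> odds multiplier; a value may also be a
    mapping ``{"child": rr, "adult": rr}`` for stratum-specific effects.
    """

    n_reports: int = 5000
    p_target_drug: float = 0.02
    pt_vocabulary: Sequence[PtSpec] = DEFAULT_VOCABULARY
    signal_map: Mapping[str, float | Mapping[str, float]] = field(default_factory=dict)
    child_fraction: float = 0.5
    p_missing_age: float = 0.05
    age_unit_mix: Mapping[str, float] = field(
        default_factory=lambda: {"YR": 0.60, "MON": 0.15, "WK": 0.08, "DY": 0.07, "DEC": 0.10}
    )
    sex_dist: Mapping[str, float] = field(
        default_factory=lambda: {"M": 0.48, "F": 0.42, "": 0.10}
    )
    reporter_dist: Mapping[str, float] = field(
        default_factory=lambda: {"MD": 0.50, "OT": 0.23, "CN": 0.11, "PH": 0.06, "": 0.10}
    )
    country_dist: Mapping[str, float] = field(
        default_factory=lambda: {
            "US": 0.30, "FR": 0.15, "RU": 0.08, "JP": 0.08, "GB": 0.07,
            "CN": 0.07, "DE": 0.05, "": 0.20,
        }
    )
    outcome_dist: Mapping[str, float] = field(
        default_factory=lambda: {
            "HO": 0.26, "OT": 0.38, "LT": 0.14, "DE": 0.12, "DS": 0.01,
            "CA": 0.02, "RI": 0.01, "": 0.06,
        }
    )
    duplicate_rate: float = 0.10
    concomitant_mean: float = 3.6  # mean drug-row mentions per target report
    target_synonyms: Sequence[str] = DEFAULT_TARGET_SYNONYMS
    other_drug_pool: Sequence[str] = DEFAULT_OTHER_DRUGS
    concomitant_pool: Sequence[str] = DEFAULT_CONCOMITANTS
    filler_pt: PtSpec = FILLER_PT
    quarter: str = "2024Q1"
    seed: int = 0


@dataclass
class GroundTruth:
    """What a correct pipeline should recover from a generated bundle."""

    n_reports: int
    signal_map: dict[str, dict[str, float]]   # pt -> {"child": rr, "adult": rr}
    per_pt: pd.DataFrame   # report-level realized counts, all strata combined
    per_pt_stratum: pd.DataFrame
    n_child: int
    n_adult: int
    n_missing_age: int
    n_duplicates: int


def adjusted_probability(p: float, rr: float) -> float:
    """Exposed-arm probability giving an exact odds ratio ``rr`` vs ``p``."""
    return rr * p / (1.0 - p + rr * p)


def _normalize_signal_map(
    signal_map: Mapping[str, float | Mapping[str, float]]
) -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    for pt, rr in signal_map.items():
        if isinstance(rr, Mapping):
            out[pt] = {"child": float(rr.get("child", 1.0)), "adult": float(rr.get("adult", 1.0))}
        else:
            out[pt] = {"child": float(rr), "adult": float(rr)}
    return out


def validate_config(config: SyntheticConfig) -> dict[str, dict[str, float]]:
    if config.n_reports < 1:
        raise ValueError("n_reports must be >= 1")
    if not 0.0 <= config.p_target_drug <= 1.0:
        raise ValueError("p_target_drug must lie in [0, 1]")
    if not 0.0 <= config.duplicate_rate <= 1.0:
        raise ValueError("duplicate_rate must lie in [0, 1]")
    names = {s.pt for s in config.pt_vocabulary}
    sig = _normalize_signal_map(config.signal_map)
    by_name = {s.pt: s for s in config.pt_vocabulary}
    for pt, rrs in sig.items():
        if pt not in names:
            raise ValueError(f"signal_map PT {pt!r} is not in the vocabulary")
        for stratum, rr in rrs.items():
            if rr <= 0:
                raise ValueError(f"odds multiplier for {pt!r} must be positive")
            if adjusted_probability(by_name[pt].p, rr) >= 0.99:
                raise ValueError(
                    f"infeasible config: adjusted probability for {pt!r} at RR={rr} "
                    "reaches 0.99"
                )
    for s in config.pt_vocabulary:
        if not 0.0 < s.p < 1.0:
            raise ValueError(f"background probability for {s.pt!r} must lie in (0, 1)")
    return sig


def _sample_categorical(rng: np.random.Generator, dist: Mapping[str, float], n: int) -> np.ndarray:
    labels = list(dist.keys())
    probs = np.asarray(list(dist.values()), dtype=float)
    probs = probs / probs.sum()
    return rng.choice(np.asarray(labels, dtype=object), size=n, p=probs)


def _express_age(
    rng: np.random.Generator, years: np.ndarray, is_child: np.ndarray,
    unit_mix: Mapping[str, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Express ages in mixed units without crossing the 18-year boundary.

    Values are floored at 2 decimals so the reconstructed age never exceeds
    the true age.  MON/WK/DY are only used for children (realistic FAERS
    usage) and DEC only where the age is a whole number of decades' worth.
    """
    units = _sample_categorical(rng, unit_mix, len(years))
    adult = ~is_child
    units[adult & np.isin(units, ("MON", "WK", "DY"))] = "YR"
    factor = np.array([faers_io_age_factor(u) for u in units])
    value = np.floor(years / factor * 100.0) / 100.0
    return value, units


def faers_io_age_factor(unit: str) -> float:
    from .cohort_builder import AGE_UNIT_TO_YEARS

    return AGE_UNIT_TO_YEARS[unit]


def generate_bundle(
    config: SyntheticConfig, out_dir: str | Path | None = None
) -> tuple[QuarterBundle, GroundTruth]:
    """Generate one seeded FAERS-format bundle plus its ground truth.

    Generation is bit-reproducible per seed.  When ``out_dir`` is given the
    six tables are also written as ``$``-delimited files (plus
    ``pt_soc_mapping.csv`` and ``ground_truth.csv`` sidecars).
    """
    sig = validate_config(config)
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    vocab = list(config.pt_vocabulary)
    npt = len(vocab)
    pt_names = np.array([s.pt for s in vocab], dtype=object)
    base_p = np.array([s.p for s in vocab])

    exposed = rng.random(n) < config.p_target_drug
    is_child = rng.random(n) < config.child_fraction
    age_years = np.where(
        is_child, rng.uniform(0.0, 17.99, n), rng.uniform(18.0, 90.0, n)
    )
    missing_age = rng.random(n) < config.p_missing_age

    # per-report, per-PT success probabilities with exact-odds injection
    prob = np.tile(base_p, (n, 1))
    for j, spec in enumerate(vocab):
        if spec.pt in sig:
            rrs = sig[spec.pt]
            for stratum, mask in (("child", is_child), ("adult", ~is_child)):
                rr = rrs[stratum]
                if rr != 1.0:
                    rows = exposed & mask
                    prob[rows, j] = adjusted_probability(spec.p, rr)

    incidence = rng.random((n, npt)) < prob
    zero = ~incidence.any(axis=1)
    if zero.any():
        redraw = rng.random((int(zero.sum()), npt)) < prob[zero]
        incidence[zero] = redraw
    still_zero = ~incidence.any(axis=1)

    # demographics
    sex = _sample_categorical(rng, config.sex_dist, n)
    reporter = _sample_categorical(rng, config.reporter_dist, n)
    country = _sample_categorical(rng, config.country_dist, n)
    outcome = _sample_categorical(rng, config.outcome_dist, n)
    age_value, age_unit = _express_age(rng, age_years, is_child, config.age_unit_mix)

    year = int(config.quarter[:4])
    q = int(config.quarter[-1])
    month0 = 3 * (q - 1)
    day_offset = rng.integers(0, 89, n)
    months = month0 + day_offset // 30
    days = day_offset % 30 + 1
    fda_dt = year * 10000 + (months + 1) * 100 + days

    primaryid = np.array([str((i + 1) * 10 + 9) for i in range(n)], dtype=object)
    caseid = np.array([str(500000 + i) for i in range(n)], dtype=object)

    demo = pd.DataFrame(
        {
            "primaryid": primaryid,
            "caseid": caseid,
            "fda_dt": fda_dt.astype(str),
            "age_value": np.where(missing_age, np.nan, age_value),
            "age_unit": np.where(missing_age, None, age_unit),
            "sex": np.where(sex == "", None, sex),
            "reporter_type": np.where(reporter == "", None, reporter),
            "reporter_country": np.where(country == "", None, country),
        }
    )

    # duplicate case versions: older FDA_DT for half, same date with a
    # smaller PRIMARYID for the rest, exercising both dedup tie-breaks
    n_dup = int(round(config.duplicate_rate * n))
    dup_rows = []
    if n_dup:
        dup_idx = rng.choice(n, size=n_dup, replace=False)
        older = rng.random(n_dup) < 0.5
        for k, i in enumerate(dup_idx):
            row = demo.iloc[i].copy()
            row["primaryid"] = str((i + 1) * 10 + int(rng.integers(1, 9)))
            if older[k]:
                row["fda_dt"] = str(int(row["fda_dt"]) - int(rng.integers(1, 20)) * 10000)
            dup_rows.append(row)
    demo_all = pd.concat([demo, pd.DataFrame(dup_rows)], ignore_index=True) if dup_rows else demo
    # deterministic shuffle so duplicates are interleaved
    demo_all = demo_all.iloc[rng.permutation(len(demo_all))].reset_index(drop=True)

    # DRUG rows
    target_names = np.asarray(config.target_synonyms, dtype=object)
    other_names = np.asarray(config.other_drug_pool, dtype=object)
    ps_name = np.where(
        exposed,
        target_names[rng.integers(0, len(target_names), n)],
        other_names[rng.integers(0, len(other_names), n)],
    )
    drug_rows = [
        pd.DataFrame(
            {
                "primaryid": primaryid,
                "drug_seq": "1",
                "role_code": "PS",
                "drugname": ps_name,
                "prod_ai": ps_name,
            }
        )
    ]
    n_conc = rng.poisson(config.concomitant_mean, n)
    conc_pid = np.repeat(primaryid, n_conc)
    total_conc = int(n_conc.sum())
    if total_conc:
        conc_pool = np.asarray(config.concomitant_pool, dtype=object)
        conc_name = conc_pool[rng.integers(0, len(conc_pool), total_conc)]
        conc_role = np.where(rng.random(total_conc) < 0.8, "C", "SS")
        conc_seq = np.concatenate([np.arange(2, k + 2) for k in n_conc if k > 0]) if total_conc else []
        drug_rows.append(
            pd.DataFrame(
                {
                    "primaryid": conc_pid,
                    "drug_seq": [str(s) for s in conc_seq],
                    "role_code": conc_role,
                    "drugname": conc_name,
                    "prod_ai": None,
                }
            )
        )
    drug = pd.concat(drug_rows, ignore_index=True)

    # REAC rows from the incidence matrix, plus fillers
    rep_idx, pt_idx = np.nonzero(incidence)
    reac = pd.DataFrame(
        {"primaryid": primaryid[rep_idx], "pt": pt_names[pt_idx]}
    )
    if still_zero.any():
        reac = pd.concat(
            [
                reac,
                pd.DataFrame(
                    {
                        "primaryid": primaryid[still_zero],
                        "pt": config.filler_pt.pt,
                    }
                ),
            ],
            ignore_index=True,
        )
    reac = reac.sort_values("primaryid", kind="stable").reset_index(drop=True)

    # OUTC / INDI
    has_outcome = outcome != ""
    outc = pd.DataFrame(
        {"primaryid": primaryid[has_outcome], "outcome_code": outcome[has_outcome]}
    )
    indi_pt = np.where(
        exposed,
        np.asarray(TARGET_INDICATIONS, dtype=object)[rng.integers(0, len(TARGET_INDICATIONS), n)],
        np.asarray(OTHER_INDICATIONS, dtype=object)[rng.integers(0, len(OTHER_INDICATIONS), n)],
    )
    indi = pd.DataFrame({"primaryid": primaryid, "drug_seq": "1", "indication_pt": indi_pt})

    bundle = QuarterBundle(
        demo=demo_all,
        drug=drug,
        reac=reac,
        outc=outc,
        indi=indi,
        ther=None,
        provenance=[f"synthetic:{config.quarter}:seed={config.seed}"],
    )

    # ground truth from the final incidence (originals only, report level)
    per_pt_rows = []
    per_pt_stratum_rows = []
    for j, spec in enumerate(vocab):
        col = incidence[:, j]
        for label, mask in (("all", np.ones(n, bool)), ("child", is_child), ("adult", ~is_child)):
            ew = int((col & exposed & mask).sum())
            eo = int((~col & exposed & mask).sum())
            uw = int((col & ~exposed & mask).sum())
            uo = int((~col & ~exposed & mask).sum())
            realized_or = (ew * uo) / (eo * uw) if eo and uw and ew and uo else float("nan")
            row = {
                "pt": spec.pt, "stratum": label,
                "exposed_with": ew, "exposed_without": eo,
                "unexposed_with": uw, "unexposed_without": uo,
                "realized_or": realized_or,
                "rr": sig.get(spec.pt, {}).get("child" if label == "child" else "adult", 1.0)
                if label != "all"
                else float("nan"),
            }
            if label == "all":
                per_pt_rows.append(row)
            else:
                per_pt_stratum_rows.append(row)

    truth = GroundTruth(
        n_reports=n,
        signal_map=sig,
        per_pt=pd.DataFrame(per_pt_rows),
        per_pt_stratum=pd.DataFrame(per_pt_stratum_rows),
        n_child=int((is_child & ~missing_age).sum()),
        n_adult=int((~is_child & ~missing_age).sum()),
        n_missing_age=int(missing_age.sum()),
        n_duplicates=n_dup,
    )

    if out_dir is not None:
        write_bundle(bundle, config, truth, out_dir)
    return bundle, truth


def pt_soc_mapping(config: SyntheticConfig) -> dict[str, str]:
    """PT -> SOC mapping covering the vocabulary and the filler PT."""
    m = {s.pt: s.soc for s in config.pt_vocabulary}
    m[config.filler_pt.pt] = config.filler_pt.soc
    return m


def write_bundle(
    bundle: QuarterBundle,
    config: SyntheticConfig,
    truth: GroundTruth,
    out_dir: str | Path,
) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    q = config.quarter.upper()
    faers_io.write_quarter_table(bundle.demo, "DEMO", out_dir / f"DEMO{q}.txt")
    faers_io.write_quarter_table(bundle.drug, "DRUG", out_dir / f"DRUG{q}.txt")
    faers_io.write_quarter_table(bundle.reac, "REAC", out_dir / f"REAC{q}.txt")
    faers_io.write_quarter_table(bundle.outc, "OUTC", out_dir / f"OUTC{q}.txt")
    faers_io.write_quarter_table(bundle.indi, "INDI", out_dir / f"INDI{q}.txt")
    mapping = pt_soc_mapping(config)
    pd.DataFrame(
        {"pt": list(mapping.keys()), "soc": list(mapping.values())}
    ).to_csv(out_dir / "pt_soc_mapping.csv", index=False)
    truth.per_pt_stratum.to_csv(out_dir / "ground_truth.csv", index=False)
    return out_dir


# ---------------------------------------------------------------------------
# recovery harness
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    per_injected: pd.DataFrame   # pt, a, ror, ci, covers_truth, four flags, signal
    per_null: pd.DataFrame       # pt, a, signal
    sensitivity: float
    false_flag_rate: float
    dedup_ok: bool
    n_recovered: int


def recover_parameters(
    bundle: QuarterBundle,
    truth: GroundTruth,
    config: SyntheticConfig,
    criteria=None,
    stratum: str = "all",
) -> RecoveryReport:
    """Run the full pipeline on a generated bundle and score recovery.

    Per injected PT: report-level estimated ROR with 95% CI, whether the CI
    covers the true odds multiplier, and the four-way gate outcome.  Per
    null PT: the gate outcome.  Also checks that post-dedup report count
    equals the ground-truth ``n_reports``.
    """
    from .cohort_builder import build_cohort, build_stratum_background, deduplicate_reports
    from .signal_engine import (
        FourFoldTable, SignalCriteria, evaluate_signals, ror_statistic,
    )

    criteria = criteria or SignalCriteria()
    dedup = deduplicate_reports(bundle.demo)
    n_recovered = len(dedup.demo)

    cohort = build_cohort(
        bundle, config.target_synonyms, roles=("PS",), stratum=stratum
    )
    _, background = build_stratum_background(bundle, stratum)
    results = evaluate_signals(
        cohort, background, pt_soc_mapping(config), criteria
    )
    pt_results = results[results["level"] == "PT"].set_index(
        results.loc[results["level"] == "PT", "term"].str.upper()
    )

    # report-level 2x2 per PT for ROR-vs-truth comparison
    coh_reports = cohort.report_ids
    bg_pairs = background.copy()
    bg_pairs["_key"] = bg_pairs["pt"].str.upper()
    bg_reports = set(bg_pairs["primaryid"].astype(str))
    other_reports = bg_reports - coh_reports
    by_pt_reports = bg_pairs.groupby("_key")["primaryid"].apply(set)

    injected = set(truth.signal_map)
    inj_rows, null_rows = [], []
    for spec in config.pt_vocabulary:
        key = spec.pt.upper()
        with_pt = by_pt_reports.get(key, set())
        a = len(with_pt & coh_reports)
        c = len(with_pt & other_reports)
        t = FourFoldTable(a, len(coh_reports) - a, c, len(other_reports) - c)
        ror = ror_statistic(t)
        sig_row = pt_results.loc[key] if key in pt_results.index else None
        flagged = bool(sig_row["signal"]) if sig_row is not None else False
        if spec.pt in injected:
            rr = truth.signal_map[spec.pt]
            rr_true = rr["child"] if stratum in ("child", "pediatric") else rr["adult"]
            if stratum == "all":
                rr_true = max(rr.values())
            inj_rows.append(
                {
                    "pt": spec.pt, "a": t.a, "ror": ror.ror,
                    "ci_low": ror.lower, "ci_high": ror.upper,
                    "rr_true": rr_true,
                    "covers_truth": bool(
                        ror.defined and ror.lower <= rr_true <= ror.upper
                    ),
                    "signal": flagged,
                }
            )
        else:
            null_rows.append({"pt": spec.pt, "a": t.a, "signal": flagged})

    per_injected = pd.DataFrame(inj_rows)
    per_null = pd.DataFrame(null_rows)
    sensitivity = float(per_injected["signal"].mean()) if len(per_injected) else float("nan")
    false_rate = float(per_null["signal"].mean()) if len(per_null) else float("nan")
    return RecoveryReport(
        per_injected=per_injected,
        per_null=per_null,
        sensitivity=sensitivity,
        false_flag_rate=false_rate,
        dedup_ok=n_recovered == truth.n_reports,
        n_recovered=n_recovered,
    )


def child_adult_comparison_study(
    rr_child: float,
    rr_adult: float,
    n_reps: int = 200,
    n_reports: int = 2000,
    seed0: int = 5000,
    pt: str = "Cardiac arrest",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Repeated-seed pediatric-vs-adult comparison of one PT.

    Each replicate generates a bundle with the PT injected at ``rr_child``
    in children and ``rr_adult`` in adults, builds both cohorts through the
    full pipeline, and records the comparison ROR, Fisher p and direction.
    With ``rr_child == rr_adult`` this is the null calibration study.
    """
    from .cohort_builder import build_cohort
    from .population_compare import compare_populations

    rows = []
    for k in range(n_reps):
        cfg = SyntheticConfig(
            n_reports=n_reports,
            p_target_drug=0.5,
            child_fraction=0.5,
            signal_map={pt: {"child": rr_child, "adult": rr_adult}}
            if (rr_child != 1.0 or rr_adult != 1.0)
            else {},
            duplicate_rate=0.0,
            p_missing_age=0.0,
            concomitant_mean=0.0,
            seed=seed0 + k,
        )
        bundle, _ = generate_bundle(cfg)
        child = build_cohort(bundle, cfg.target_synonyms, stratum="pediatric")
        adult = build_cohort(bundle, cfg.target_synonyms, stratum="adult")
        comp = compare_populations(child, adult, pts=[pt], alpha=alpha)
        if comp.empty:
            continue
        r = comp.iloc[0]
        rows.append(
            {
                "seed": cfg.seed, "ror": r["ror"], "p": r["p"],
                "direction": r["direction"],
                "significant": bool(r["p"] < alpha),
            }
        )
    return pd.DataFrame(rows)


def ror_consistency_study(
    rr: float = 5.0,
    n_seeds: int = 100,
    n_reports: int = 20000,
    seed0: int = 1000,
    pt: str = "Cardiac arrest",
    p_target_drug: float = 0.02,
) -> pd.DataFrame:
    """Repeated-seed recovery of one injected odds multiplier.

    Returns one row per seed with the report-level estimated ROR, its 95% CI
    and whether the CI covers ``rr``.  Used for estimator-consistency and
    CI-calibration checks.
    """
    rows = []
    for k in range(n_seeds):
        cfg = SyntheticConfig(
            n_reports=n_reports,
            p_target_drug=p_target_drug,
            signal_map={pt: rr},
            duplicate_rate=0.0,
            p_missing_age=0.0,
            concomitant_mean=0.0,
            seed=seed0 + k,
        )
        bundle, truth = generate_bundle(cfg)
        row = truth.per_pt.set_index("pt").loc[pt]
        from .signal_engine import FourFoldTable, ror_statistic

        t = FourFoldTable(
            int(row["exposed_with"]), int(row["exposed_without"]),
            int(row["unexposed_with"]), int(row["unexposed_without"]),
        )
        r = ror_statistic(t)
        rows.append(
            {
                "seed": cfg.seed, "a": t.a, "ror": r.ror,
                "ci_low": r.lower, "ci_high": r.upper,
                "covers": bool(r.defined and r.lower <= rr <= r.upper),
            }
        )
    return pd.DataFrame(rows)
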