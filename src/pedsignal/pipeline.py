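"""End-to-end orchestration: config in, Table-1/Table-2/forest-style CSVs out.

``run_pipeline`` executes load -> dedup -> cohorts (pediatric, adult) ->
descriptive summaries -> PT/SOC disproportionality per stratum -> pediatric
vs adult comparison, and writes:

* ``descriptive_summary_<stratum>.csv`` — section, label, count, percent
* ``signals_pt_<stratum>.csv`` / ``signals_soc_<stratum>.csv`` — 2-decimal
  presentation, with ``*_full.csv`` companions at full precision
* ``comparison.csv`` — per-PT pediatric-vs-adult ROR and Fisher p
* ``flowchart_counts.csv`` — report counts at each filtering stage
* ``run.log`` — parse, dedup and exclusion accounting
"""

from __future__ import annotations

import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import faers_io, synthetic_faers
from .cohort_builder import Cohort, build_cohort, build_stratum_background, summarize_cohort
from .population_compare import compare_populations
from .signal_engine import SignalCriteria, evaluate_signals, read_pt_soc_mapping

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    out_dir: str
    input_dir: str | None = None
    quarters: Sequence[str] = ()
    synthetic: dict | None = None          # SyntheticConfig fields
    synonyms: Sequence[str] = ("SEVOFLURANE", "ULTANE", "SEVORANE")
    match_policy: str = "exact"
    roles: Sequence[str] = ("PS",)
    strata: Sequence[str] = ("pediatric", "adult")
    mapping_path: str | None = None
    criteria: dict = field(default_factory=dict)
    top_k: int = 10
    seed: int | None = None
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def validate(self) -> None:
        if not self.strata:
            raise ValueError("at least one stratum must be requested")
        if self.synthetic is None:
            if not self.input_dir or not self.quarters:
                raise ValueError("either synthetic config or input_dir+quarters required")
            if not Path(self.input_dir).is_dir():
                raise FileNotFoundError(self.input_dir)
            if not self.mapping_path:
                raise ValueError("mapping_path is required for file input")
            if not Path(self.mapping_path).is_file():
                raise FileNotFoundError(self.mapping_path)


def synthetic_config_from_dict(raw: dict) -> synthetic_faers.SyntheticConfig:
    raw = dict(raw)
    if "pt_vocabulary" in raw:
        raw["pt_vocabulary"] = [
            synthetic_faers.PtSpec(**v) if isinstance(v, dict) else synthetic_faers.PtSpec(*v)
            for v in raw["pt_vocabulary"]
        ]
    if "filler_pt" in raw and isinstance(raw["filler_pt"], dict):
        raw["filler_pt"] = synthetic_faers.PtSpec(**raw["filler_pt"])
    return synthetic_faers.SyntheticConfig(**raw)


def _format_presentation(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].round(2)
    return out


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the full analysis; returns a name -> path map of outputs.

    Any fatal stage error removes partial outputs and re-raises.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s %(message)s"))
    root = logging.getLogger("pedsignal")
    root.addHandler(handler)
    root.setLevel(getattr(logging, config.verbosity.upper(), logging.INFO))

    try:
        if config.synthetic is not None:
            raw = dict(config.synthetic)
            if config.seed is not None:
                raw.setdefault("seed", config.seed)
            syn_cfg = synthetic_config_from_dict(raw)
            bundle, _truth = synthetic_faers.generate_bundle(syn_cfg)
            mapping = synthetic_faers.pt_soc_mapping(syn_cfg)
            log.info("generated synthetic bundle: %d reports, seed=%d",
                     syn_cfg.n_reports, syn_cfg.seed)
        else:
            bundle = faers_io.load_quarters(config.input_dir, list(config.quarters))
            mapping = read_pt_soc_mapping(config.mapping_path)

        criteria = SignalCriteria(**config.criteria)
        flow: list[tuple[str, int]] = [("demo_rows_total", len(bundle.demo))]

        cohorts: dict[str, Cohort] = {}
        first = True
        for stratum in config.strata:
            cohort = build_cohort(
                bundle, config.synonyms, config.roles, stratum, config.match_policy
            )
            cohorts[stratum] = cohort
            if first:
                n_dedup = len(bundle.demo) - cohort.exclusions["duplicates_removed"]
                n_matched = n_dedup - cohort.exclusions["not_drug_or_role_matched"]
                flow += [
                    ("after_dedup", n_dedup),
                    ("drug_role_matched", n_matched),
                ]
                first = False
            flow.append((f"stratum_{cohort.stratum}", cohort.n_reports))
            log.info(
                "stratum %s: n_reports=%d n_report_pt_pairs=%d exclusions=%s",
                cohort.stratum, cohort.n_reports, cohort.n_report_pt_pairs,
                cohort.exclusions,
            )

            if cohort.n_reports:
                summary = summarize_cohort(cohort, k=config.top_k)
                p = out_dir / f"descriptive_summary_{cohort.stratum}.csv"
                summary.table.to_csv(p, index=False)
                written[p.stem] = p

                _, background = build_stratum_background(bundle, stratum)
                results = evaluate_signals(cohort, background, mapping, criteria)
                for level, name in (("PT", "signals_pt"), ("SOC", "signals_soc")):
                    part = results[results["level"] == level].drop(columns="level")
                    p_full = out_dir / f"{name}_{cohort.stratum}_full.csv"
                    part.to_csv(p_full, index=False)
                    p_two = out_dir / f"{name}_{cohort.stratum}.csv"
                    _format_presentation(part).to_csv(p_two, index=False)
                    written[p_full.stem] = p_full
                    written[p_two.stem] = p_two
                cohort._signals = results  # stashed for the comparison step

        child = cohorts.get("pediatric") or cohorts.get("child")
        adult = cohorts.get("adult")
        if child is not None and adult is not None and child.n_reports and adult.n_reports:
            positive: set[str] = set()
            for c in (child, adult):
                res = getattr(c, "_signals", None)
                if res is not None:
                    pos = res[(res["level"] == "PT") & res["signal"]]["term"]
                    positive |= set(pos.str.upper())
            comparison = compare_populations(
                child, adult, pts=sorted(positive) if positive else None
            )
            p = out_dir / "comparison.csv"
            comparison.to_csv(p, index=False)
            written["comparison"] = p

        flow_df = pd.DataFrame(flow, columns=["stage", "count"])
        p = out_dir / "flowchart_counts.csv"
        flow_df.to_csv(p, index=False)
        written["flowchart_counts"] = p
        log.info("pipeline complete: %d outputs in %s", len(written), out_dir)
        return written
    except Exception:
        log.exception("pipeline failed; removing partial outputs")
        for path in written.values():
            path.unlink(missing_ok=True)
        raise
    finally:
        handler.close()
        root.removeHandler(handler)
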