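"""Reading and writing FAERS-dialect quarterly ASCII tables.

FAERS quarters ship six ``$``-delimited text tables (DEMO, DRUG, REAC, OUTC,
INDI, THER) with a single header row and no quoting.  This module parses them
into pandas DataFrames with a canonical column vocabulary, tolerating the
schema drift between quarterly eras (columns appear and disappear; header
names vary), and writes round-trippable files in the same dialect.

Only the modern PRIMARYID-keyed layout (2012Q4 onward) is supported; legacy
ISR-keyed files are out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

log = logging.getLogger(__name__)

DELIMITER = "$"

TABLE_KINDS = ("DEMO", "DRUG", "REAC", "OUTC", "INDI", "THER")
MANDATORY_KINDS = ("DEMO", "DRUG", "REAC")

#: canonical column order per table kind
TABLE_COLUMNS: dict[str, list[str]] = {
    "DEMO": [
        "primaryid", "caseid", "fda_dt", "age_value", "age_unit",
        "sex", "reporter_type", "reporter_country",
    ],
    "DRUG": ["primaryid", "drug_seq", "role_code", "drugname", "prod_ai"],
    "REAC": ["primaryid", "pt"],
    "OUTC": ["primaryid", "outcome_code"],
    "INDI": ["primaryid", "drug_seq", "indication_pt"],
    "THER": ["primaryid", "drug_seq", "start_dt", "end_dt"],
}

#: lower-cased FAERS header names -> canonical names (identity implied for
#: canonical names themselves)
HEADER_ALIASES: dict[str, str] = {
    "age": "age_value",
    "age_cod": "age_unit",
    "gndr_cod": "sex",
    "occp_cod": "reporter_type",
    "occr_country": "reporter_country",
    "out_cod": "outcome_code",
    "outc_cod": "outcome_code",
    "outc_code": "outcome_code",
    "indi_pt": "indication_pt",
    "indi_drug_seq": "drug_seq",
    "dsg_drug_seq": "drug_seq",
}

ROLE_CODES = frozenset({"PS", "SS", "C", "I"})
OUTCOME_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI", "OT"})
AGE_UNITS = frozenset({"YR", "DEC", "MON", "WK", "DY", "HR"})


@dataclass
class ParseReport:
    """Bookkeeping attached to every parsed table."""

    table_kind: str
    path: str
    rows_read: int = 0
    rows_skipped: int = 0
    unknown_columns: list[str] = field(default_factory=list)
    missing_columns: list[str] = field(default_factory=list)

    def summary(self) -> str:
        return (
            f"{self.table_kind} {self.path}: read={self.rows_read} "
            f"skipped={self.rows_skipped} unknown={self.unknown_columns} "
            f"missing={self.missing_columns}"
        )


@dataclass
class ParsedTable:
    df: pd.DataFrame
    report: ParseReport


@dataclass
class QuarterBundle:
    """Parsed record collections for one or more FAERS quarters.

    The six tables are held as DataFrames with canonical columns.  ``ther``
    is parsed when present but unused downstream.  ``provenance`` lists every
    source file.
    """

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    outc: pd.DataFrame
    indi: pd.DataFrame
    ther: pd.DataFrame | None = None
    provenance: list[str] = field(default_factory=list)
    parse_reports: list[ParseReport] = field(default_factory=list)

    def unresolved_counts(self) -> dict[str, int]:
        """Count primaryids in child tables that do not resolve against DEMO.

        Unresolved ids are counted (and logged by :func:`load_quarters`), not
        silently dropped.
        """
        known = set(self.demo["primaryid"].dropna())
        out: dict[str, int] = {}
        for name in ("drug", "reac", "outc", "indi"):
            df = getattr(self, name)
            if df is None or df.empty:
                out[name] = 0
            else:
                out[name] = int((~df["primaryid"].isin(known)).sum())
        return out


def _canonical_name(raw: str) -> str:
    name = raw.strip().lower()
    return HEADER_ALIASES.get(name, name)


def _read_text(path: Path) -> str:
    data = path.read_bytes()
    try:
        return data.decode("utf-8")
    except UnicodeDecodeError:
        return data.decode("latin-1")


def _empty_table(kind: str) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in TABLE_COLUMNS[kind]})


def parse_quarter_table(
    path: str | Path, table_kind: str, *, strict: bool = False
) -> ParsedTable:
    """Parse one ``$``-delimited FAERS table into canonical records.

    Header names are matched case-insensitively (with era aliases such as
    ``age_cod`` -> ``age_unit``); columns absent from the file yield missing
    values; empty strings become missing.  Under lenient mode (default) rows
    with the wrong delimiter count are skipped and counted; under ``strict``
    they raise.
    """
    table_kind = table_kind.upper()
    if table_kind not in TABLE_COLUMNS:
        raise ValueError(f"unknown table kind {table_kind!r}")
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"cannot read {table_kind} table: {path}")

    text = _read_text(path)
    lines = text.splitlines()
    report = ParseReport(table_kind=table_kind, path=str(path))
    canonical = TABLE_COLUMNS[table_kind]
    if not lines:
        report.missing_columns = list(canonical)
        return ParsedTable(_empty_table(table_kind), report)

    header = [_canonical_name(h) for h in lines[0].split(DELIMITER)]
    report.unknown_columns = [h for h in header if h not in canonical]
    report.missing_columns = [c for c in canonical if c not in header]
    ncol = len(header)

    rows: list[list[str]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split(DELIMITER)
        if len(fields) != ncol:
            if strict:
                raise ValueError(
                    f"{path}:{lineno}: expected {ncol} fields, got {len(fields)}"
                )
            report.rows_skipped += 1
            continue
        rows.append(fields)
        report.rows_read += 1

    raw = pd.DataFrame(rows, columns=header) if rows else pd.DataFrame(columns=header)
    df = pd.DataFrame(index=raw.index)
    for col in canonical:
        if col in raw.columns:
            s = raw[col].map(lambda v: v.strip() if isinstance(v, str) else v)
            s = s.mask(s == "")
            df[col] = s
        else:
            df[col] = pd.Series([pd.NA] * len(raw), index=raw.index, dtype=object)
    if "age_value" in df.columns:
        df["age_value"] = pd.to_numeric(df["age_value"], errors="coerce")
    return ParsedTable(df, report)


def _find_quarter_file(directory: Path, kind: str, quarter: str) -> Path | None:
    want_kind = kind.upper()
    want_q = quarter.upper().replace(" ", "")
    for p in sorted(directory.iterdir()):
        if not p.is_file():
            continue
        name = p.name.upper()
        if name.startswith(want_kind) and want_q in name:
            return p
    return None


def load_quarters(directory: str | Path, quarters: Sequence[str]) -> QuarterBundle:
    """Load and concatenate FAERS tables for the listed quarters.

    Each quarter must provide at minimum DEMO, DRUG and REAC files (fatal if
    missing, with the quarter named).  OUTC/INDI/THER are optional.  No
    deduplication is performed here.
    """
    directory = Path(directory)
    frames: dict[str, list[pd.DataFrame]] = {k: [] for k in TABLE_KINDS}
    provenance: list[str] = []
    reports: list[ParseReport] = []

    if not quarters:
        log.warning("load_quarters called with an empty quarter list")

    for quarter in quarters:
        for kind in TABLE_KINDS:
            path = _find_quarter_file(directory, kind, quarter)
            if path is None:
                if kind in MANDATORY_KINDS:
                    raise FileNotFoundError(
                        f"quarter {quarter}: mandatory {kind} table not found "
                        f"in {directory}"
                    )
                continue
            parsed = parse_quarter_table(path, kind)
            frames[kind].append(parsed.df)
            provenance.append(path.name)
            reports.append(parsed.report)
            log.info(parsed.report.summary())

    def _concat(kind: str) -> pd.DataFrame:
        if frames[kind]:
            return pd.concat(frames[kind], ignore_index=True)
        return _empty_table(kind)

    bundle = QuarterBundle(
        demo=_concat("DEMO"),
        drug=_concat("DRUG"),
        reac=_concat("REAC"),
        outc=_concat("OUTC"),
        indi=_concat("INDI"),
        ther=_concat("THER") if frames["THER"] else None,
        provenance=provenance,
        parse_reports=reports,
    )
    for table, n in bundle.unresolved_counts().items():
        if n:
            log.warning("%s: %d rows with primaryid unresolved against DEMO", table, n)
    return bundle


def _format_field(value) -> str:
    if value is None or (isinstance(value, float) and value != value) or value is pd.NA:
        return ""
    if isinstance(value, float):
        if value.is_integer():
            return str(int(value))
        return repr(value)
    return str(value)


def write_quarter_table(
    records: pd.DataFrame, table_kind: str, path: str | Path
) -> Path:
    """Write records as a ``$``-delimited FAERS table.

    ``parse_quarter_table(write_quarter_table(x))`` reproduces ``x``
    field-for-field, with missing values serialized as empty strings.  Fields
    containing the delimiter or a newline are rejected with the offending
    record identified.
    """
    table_kind = table_kind.upper()
    columns = TABLE_COLUMNS[table_kind]
    path = Path(path)
    out = pd.DataFrame(index=records.index)
    for col in columns:
        if col in records.columns:
            out[col] = records[col].map(_format_field)
        else:
            out[col] = ""
        bad = out[col].str.contains(r"[$\r\n]", regex=True)
        if bad.any():
            pid = records.loc[bad[bad].index[0]].get("primaryid", "<unknown>")
            raise ValueError(
                f"{table_kind} record primaryid={pid!r}: field {col!r} "
                "contains the delimiter or a newline"
            )
    if len(out):
        body = out[columns[0]].astype(str)
        if len(columns) > 1:
            body = body.str.cat([out[c] for c in columns[1:]], sep=DELIMITER)
        body_lines = body.tolist()
    else:
        body_lines = []
    lines = [DELIMITER.join(columns), *body_lines]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
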