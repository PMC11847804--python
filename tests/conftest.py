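import pandas as pd
import pytest

from pedsignal.faers_io import QuarterBundle


def demo_frame(rows):
    """Build a DEMO DataFrame from (primaryid, caseid, fda_dt, age, unit, sex) tuples."""
    cols = ["primaryid", "caseid", "fda_dt", "age_value", "age_unit", "sex"]
    df = pd.DataFrame(rows, columns=cols[: len(rows[0])])
    for c in cols + ["reporter_type", "reporter_country"]:
        if c not in df.columns:
            df[c] = None
    return df


def drug_frame(rows):
    """(primaryid, drug_seq, role_code, drugname[, prod_ai]) tuples."""
    cols = ["primaryid", "drug_seq", "role_code", "drugname", "prod_ai"]
    df = pd.DataFrame(rows, columns=cols[: len(rows[0])])
    for c in cols:
        if c not in df.columns:
            df[c] = None
    return df


def reac_frame(rows):
    return pd.DataFrame(rows, columns=["primaryid", "pt"])


def make_bundle(demo, drug=None, reac=None, outc=None, indi=None):
    empty2 = lambda cols: pd.DataFrame(columns=cols)
    return QuarterBundle(
        demo=demo,
        drug=drug if drug is not None else empty2(
            ["primaryid", "drug_seq", "role_code", "drugname", "prod_ai"]
        ),
        reac=reac if reac is not None else empty2(["primaryid", "pt"]),
        outc=outc if outc is not None else empty2(["primaryid", "outcome_code"]),
        indi=indi if indi is not None else empty2(
            ["primaryid", "drug_seq", "indication_pt"]
        ),
    )


@pytest.fixture
def tiny_bundle():
    """10 reports: 4 sevoflurane-PS, of which 3 are aged under 18."""
    demo = demo_frame(
        [
            ("1", "c1", "20200101", 5.0, "YR", "M"),
            ("2", "c2", "20200101", 30.0, "YR", "F"),
            ("3", "c3", "20200102", 10.0, "YR", "F"),
            ("4", "c4", "20200103", 72.0, "MON", "M"),
            ("5", "c5", "20200104", 40.0, "YR", None),
            ("6", "c6", "20200105", 7.0, "YR", "M"),
            ("7", "c7", "20200106", 55.0, "YR", "F"),
            ("8", "c8", "20200107", 2.0, "YR", "M"),
            ("9", "c9", "20200108", 16.0, "YR", "F"),
            ("10", "c10", "20200109", 61.0, "YR", "M"),
        ]
    )
    drug = drug_frame(
        [
            ("1", "1", "PS", "SEVOFLURANE"),
            ("1", "2", "C", "PROPOFOL"),
            ("2", "1", "PS", "Sevoflurane"),
            ("3", "1", "PS", "ULTANE"),
            ("4", "1", "PS", "SEVORANE"),
            ("5", "1", "SS", "SEVOFLURANE"),   # wrong role
            ("6", "1", "PS", "IBUPROFEN"),
            ("7", "1", "PS", "PROPOFOL"),
            ("8", "1", "C", "SEVOFLURANE"),    # wrong role
            ("8", "2", "PS", "MIDAZOLAM"),
            ("9", "1", "PS", "KETAMINE"),
            ("10", "1", "PS", "MORPHINE"),
        ]
    )
    reac = reac_frame(
        [
            ("1", "Cough"), ("1", "Cough"), ("1", "Tachycardia"),
            ("2", "Nausea"),
            ("3", "Cough"),
            ("4", "Bradycardia"), ("4", "Cough"),
            ("6", "Rash"),
            ("7", "Nausea"),
            ("8", "Cough"),
            ("9", "Pyrexia"), ("9", "Cough"),
            ("10", "Nausea"),
        ]
    )
    outc = pd.DataFrame(
        [("1", "HO"), ("1", "DE"), ("3", "OT"), ("4", "LT")],
        columns=["primaryid", "outcome_code"],
    )
    indi = pd.DataFrame(
        [("1", "1", "Anaesthesia"), ("3", "1", "General anaesthesia")],
        columns=["primaryid", "drug_seq", "indication_pt"],
    )
    return make_bundle(demo, drug, reac, outc, indi)
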