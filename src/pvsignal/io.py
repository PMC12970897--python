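"""Readers and writers for the three SRS dialects and the canonical format.

FAERS quarterly ASCII files are ``$``-delimited with one header row
(DEMO/DRUG/REAC/THER/INDI/OUTC). JADER ships as per-table CSV
(DEMO/DRUG/REAC). CVAR is a delimited extract whose tables link on
``Report_ID``. Unknown columns are tolerated everywhere; a missing
mandatory column raises :class:`ParseError` naming the file and column.
Dates are normalized to ISO; partial dates (year or year-month only) are
imputed to the first day and flagged, unparseable dates become null and
are tallied in ``parse_warnings``.
"""

from __future__ import annotations

import glob
import json
import os
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import (
    CASE_COLUMNS,
    DRUG_COLUMNS,
    EVENT_COLUMNS,
    SRSDataset,
)

__all__ = ["ParseError", "read_srs", "write_dataset", "read_dataset", "write_faers"]


class ParseError(ValueError):
    pass


_AGE_TO_YEARS = {"YR": 1.0, "DEC": 10.0, "MON": 1 / 12, "WK": 1 / 52.18, "DY": 1 / 365.25, "HR": 1 / 8766.0}
_WT_TO_KG = {"KG": 1.0, "KGS": 1.0, "LBS": 0.453592, "GMS": 0.001}
_SEX = {"F": "female", "M": "male", "FEMALE": "female", "MALE": "male"}
_OCCP = {
    "MD": "physician",
    "PH": "pharmacist",
    "OT": "other health professional",
    "HP": "other health professional",
    "CN": "non-health professional",
    "LW": "non-health professional",
    "PHYSICIAN": "physician",
    "PHARMACIST": "pharmacist",
    "OTHER HEALTH PROFESSIONAL": "other health professional",
    "NON-HEALTH PROFESSIONAL": "non-health professional",
    "CONSUMER": "non-health professional",
}
_OUTC = {
    "DE": "death",
    "LT": "life-threatening",
    "HO": "hospitalization",
    "DS": "disability",
    "CA": "other",
    "RI": "other",
    "OT": "other",
    "DEATH": "death",
    "LIFE-THREATENING": "life-threatening",
    "HOSPITALIZATION": "hospitalization",
    "DISABILITY": "disability",
    "OTHER": "other",
}
_FAERS_ROLE = {"PS": "PS", "SS": "SS", "C": "concomitant", "I": "interacting"}
_SUSPECT_ROLE = {
    "SUSPECT": "suspect",
    "被疑薬": "suspect",
    "CONCOMITANT": "concomitant",
    "併用薬": "concomitant",
    "INTERACTING": "interacting",
    "相互作用": "interacting",
}

_DATE_RE_FULL = re.compile(r"^(\d{4})(\d{2})(\d{2})$")
_DATE_RE_YM = re.compile(r"^(\d{4})(\d{2})$")
_DATE_RE_Y = re.compile(r"^(\d{4})$")
_DATE_RE_ISO = re.compile(r"^(\d{4})-(\d{2})(?:-(\d{2}))?$")


def _parse_date(value) -> tuple[pd.Timestamp, bool, bool]:
    """Return (timestamp, imputed, failed). Partial dates impute day/month 1."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return pd.NaT, False, False
    s = str(value).strip()
    if not s or s.lower() in ("nan", "none"):
        return pd.NaT, False, False
    for regex, imputed in ((_DATE_RE_FULL, False), (_DATE_RE_YM, True), (_DATE_RE_Y, True)):
        m = regex.match(s)
        if m:
            g = m.groups()
            y = int(g[0])
            mo = int(g[1]) if len(g) > 1 else 1
            d = int(g[2]) if len(g) > 2 else 1
            try:
                return pd.Timestamp(year=y, month=mo, day=d), imputed, False
            except ValueError:
                return pd.NaT, False, True
    m = _DATE_RE_ISO.match(s)
    if m:
        y, mo, d = int(m.group(1)), int(m.group(2)), m.group(3)
        try:
            return pd.Timestamp(year=y, month=mo, day=int(d) if d else 1), d is None, False
        except ValueError:
            return pd.NaT, False, True
    return pd.NaT, False, True


def _parse_date_column(series: pd.Series, warnings: dict, label: str):
    dates, imputed = [], []
    n_failed = 0
    for v in series:
        ts, imp, failed = _parse_date(v)
        dates.append(ts)
        imputed.append(imp)
        n_failed += failed
    if n_failed:
        warnings[f"unparseable_dates:{label}"] = n_failed
    return pd.Series(dates, index=series.index), pd.Series(imputed, index=series.index)


def _require(df: pd.DataFrame, cols: list[str], fname: str):
    lower = {c.lower(): c for c in df.columns}
    missing = [c for c in cols if c.lower() not in lower]
    if missing:
        raise ParseError(f"{fname}: missing mandatory column(s) {missing}")
    return {c: lower[c.lower()] for c in df.columns.map(str)}


def _col(df: pd.DataFrame, name: str):
    """Case-insensitive column access; None if absent."""
    lower = {str(c).lower(): c for c in df.columns}
    key = lower.get(name.lower())
    return df[key] if key is not None else None


def _find_table(paths: list[str], token: str) -> list[str]:
    hits = [p for p in paths if token.lower() in os.path.basename(p).lower()]
    return sorted(hits)


def _read_delim(path: str, sep: str) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=True, engine="python")


def _concat_tables(files: list[str], sep: str) -> pd.DataFrame:
    frames = [_read_delim(f, sep) for f in files]
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def _clean_age(age, code) -> float:
    try:
        a = float(age)
    except (TypeError, ValueError):
        return np.nan
    factor = _AGE_TO_YEARS.get(str(code).strip().upper(), 1.0) if pd.notna(code) else 1.0
    a = a * factor
    return a if a >= 0 else np.nan


def _clean_weight(wt, code) -> float:
    try:
        w = float(wt)
    except (TypeError, ValueError):
        return np.nan
    factor = _WT_TO_KG.get(str(code).strip().upper(), 1.0) if pd.notna(code) else 1.0
    w = w * factor
    return w if w > 0 else np.nan


def _map_enum(value, table: dict, default: str) -> str:
    if pd.isna(value):
        return default
    return table.get(str(value).strip().upper(), table.get(str(value).strip(), default))


def read_srs(paths, dialect: str) -> SRSDataset:
    """Parse an SRS extract into a :class:`SRSDataset`.

    Parameters
    ----------
    paths
        A directory or an iterable of file paths. Tables are recognised by
        filename token (DEMO/DRUG/REAC/THER/INDI/OUTC for FAERS;
        demo/drug/reac for JADER; reports/report_drug/reactions for CVAR).
    dialect
        ``"faers"``, ``"jader"``, ``"cvar"`` or ``"synthetic"``
        (synthetic extracts are written in FAERS shape).
    """
    dialect = dialect.upper()
    if isinstance(paths, (str, Path)) and os.path.isdir(paths):
        file_list = sorted(glob.glob(os.path.join(str(paths), "*")))
    elif isinstance(paths, (str, Path)):
        file_list = [str(paths)]
    else:
        file_list = [str(p) for p in paths]
    file_list = [f for f in file_list if os.path.isfile(f)]

    if dialect in ("FAERS", "SYNTHETIC"):
        ds = _read_faers(file_list)
        ds.dialect = dialect
    elif dialect == "JADER":
        ds = _read_jader(file_list)
    elif dialect == "CVAR":
        ds = _read_cvar(file_list)
    else:
        raise ParseError(f"unknown dialect {dialect!r}")
    return ds.validate()


def _read_faers(files: list[str]) -> SRSDataset:
    warnings: dict = {}
    demo_files = _find_table(files, "DEMO")
    if not demo_files:
        raise ParseError("FAERS: no DEMO table found")
    demo = _concat_tables(demo_files, "$")
    _require(demo, ["primaryid", "caseid"], os.path.basename(demo_files[0]))

    fda_dt = _col(demo, "fda_dt")
    fda_dt = fda_dt.fillna("") if fda_dt is not None else pd.Series("", index=demo.index)
    primaryid = _col(demo, "primaryid").astype(str)
    version_key = fda_dt.astype(str).str.zfill(8) + ":" + primaryid

    event_dt = _col(demo, "event_dt")
    event_year = (
        event_dt.astype(str).str.slice(0, 4).where(event_dt.notna())
        if event_dt is not None
        else pd.Series(np.nan, index=demo.index)
    )

    age_cod = _col(demo, "age_cod")
    wt_cod = _col(demo, "wt_cod")
    cases = pd.DataFrame(
        {
            "report_id": primaryid,
            "case_id": _col(demo, "caseid").astype(str),
            "version_key": version_key,
            "age": [
                _clean_age(a, c)
                for a, c in zip(
                    _col(demo, "age") if _col(demo, "age") is not None else [np.nan] * len(demo),
                    age_cod if age_cod is not None else [None] * len(demo),
                )
            ],
            "sex": [
                _map_enum(v, _SEX, "unknown")
                for v in (_col(demo, "sex") if _col(demo, "sex") is not None else [None] * len(demo))
            ],
            "weight": [
                _clean_weight(w, c)
                for w, c in zip(
                    _col(demo, "wt") if _col(demo, "wt") is not None else [np.nan] * len(demo),
                    wt_cod if wt_cod is not None else [None] * len(demo),
                )
            ],
            "event_year": pd.to_numeric(event_year, errors="coerce").astype("Int64"),
            "country": _col(demo, "occr_country") if _col(demo, "occr_country") is not None else None,
            "reporter": [
                _map_enum(v, _OCCP, "unknown")
                for v in (_col(demo, "occp_cod") if _col(demo, "occp_cod") is not None else [None] * len(demo))
            ],
        }
    )

    outc_files = _find_table(files, "OUTC")
    outcomes_by_report: dict[str, set] = {}
    if outc_files:
        outc = _concat_tables(outc_files, "$")
        _require(outc, ["primaryid", "outc_cod"], os.path.basename(outc_files[0]))
        for rid, code in zip(_col(outc, "primaryid").astype(str), _col(outc, "outc_cod")):
            outcomes_by_report.setdefault(rid, set()).add(_map_enum(code, _OUTC, "unknown"))
    cases["outcomes"] = [
        ";".join(sorted(outcomes_by_report.get(r, {"unknown"}))) for r in cases["report_id"]
    ]

    drug_files = _find_table(files, "DRUG")
    if not drug_files:
        raise ParseError("FAERS: no DRUG table found")
    drug = _concat_tables(drug_files, "$")
    _require(drug, ["primaryid", "drugname", "role_cod"], os.path.basename(drug_files[0]))

    ther_start: dict[tuple, object] = {}
    ther_files = _find_table(files, "THER")
    if ther_files:
        ther = _concat_tables(ther_files, "$")
        _require(ther, ["primaryid", "start_dt"], os.path.basename(ther_files[0]))
        seq = _col(ther, "dsg_drug_seq")
        start_parsed, start_imp = _parse_date_column(_col(ther, "start_dt"), warnings, "THER.start_dt")
        for rid, sq, dt, imp in zip(
            _col(ther, "primaryid").astype(str),
            seq.astype(str) if seq is not None else [""] * len(ther),
            start_parsed,
            start_imp,
        ):
            key = (rid, sq)
            prev = ther_start.get(key)
            if prev is None or (pd.notna(dt) and (pd.isna(prev[0]) or dt < prev[0])):
                ther_start[key] = (dt, imp)

    indi_map: dict[tuple, str] = {}
    indi_files = _find_table(files, "INDI")
    if indi_files:
        indi = _concat_tables(indi_files, "$")
        _require(indi, ["primaryid", "indi_pt"], os.path.basename(indi_files[0]))
        seq = _col(indi, "indi_drug_seq")
        for rid, sq, pt in zip(
            _col(indi, "primaryid").astype(str),
            seq.astype(str) if seq is not None else [""] * len(indi),
            _col(indi, "indi_pt"),
        ):
            if pd.notna(pt):
                indi_map.setdefault((rid, sq), str(pt))

    drug_seq = _col(drug, "drug_seq")
    seq_vals = drug_seq.astype(str) if drug_seq is not None else pd.Series("", index=drug.index)
    start_dates, start_imps, indications = [], [], []
    for rid, sq in zip(_col(drug, "primaryid").astype(str), seq_vals):
        dt, imp = ther_start.get((rid, sq), (pd.NaT, False))
        start_dates.append(dt)
        start_imps.append(bool(imp))
        indications.append(indi_map.get((rid, sq)))

    drugs = pd.DataFrame(
        {
            "report_id": _col(drug, "primaryid").astype(str),
            "verbatim_name": _col(drug, "drugname"),
            "ingredient": None,
            "role": [_map_enum(v, _FAERS_ROLE, "concomitant") for v in _col(drug, "role_cod")],
            "start_date": start_dates,
            "start_date_imputed": start_imps,
            "indication_pt": indications,
        }
    )

    reac_files = _find_table(files, "REAC")
    if not reac_files:
        raise ParseError("FAERS: no REAC table found")
    reac = _concat_tables(reac_files, "$")
    _require(reac, ["primaryid", "pt"], os.path.basename(reac_files[0]))
    onset_col = _col(reac, "onset_dt")
    if onset_col is not None:
        onset, onset_imp = _parse_date_column(onset_col, warnings, "REAC.onset_dt")
    else:
        # real FAERS stores the onset on DEMO.event_dt; propagate it per report
        ev_map = {}
        if event_dt is not None:
            parsed, imps = _parse_date_column(event_dt, warnings, "DEMO.event_dt")
            ev_map = {
                r: (d, i) for r, d, i in zip(primaryid, parsed, imps)
            }
        onset = pd.Series(
            [ev_map.get(r, (pd.NaT, False))[0] for r in _col(reac, "primaryid").astype(str)],
            index=reac.index,
        )
        onset_imp = pd.Series(
            [bool(ev_map.get(r, (pd.NaT, False))[1]) for r in _col(reac, "primaryid").astype(str)],
            index=reac.index,
        )
    events = pd.DataFrame(
        {
            "report_id": _col(reac, "primaryid").astype(str),
            "pt": _col(reac, "pt"),
            "onset_date": onset,
            "onset_date_imputed": onset_imp.astype(bool),
        }
    )
    events = events[events["pt"].notna()].reset_index(drop=True)

    return SRSDataset("FAERS", cases, drugs, events, warnings)


def _read_jader(files: list[str]) -> SRSDataset:
    warnings: dict = {}
    demo_files = _find_table(files, "demo")
    drug_files = _find_table(files, "drug")
    reac_files = _find_table(files, "reac")
    if not demo_files:
        raise ParseError("JADER: no DEMO table found")
    if not drug_files:
        raise ParseError("JADER: no DRUG table found")
    if not reac_files:
        raise ParseError("JADER: no REAC table found")

    demo = _concat_tables(demo_files, ",")
    _require(demo, ["caseid"], os.path.basename(demo_files[0]))
    caseid = _col(demo, "caseid").astype(str)
    cases = pd.DataFrame(
        {
            "report_id": caseid,
            "case_id": caseid,
            "version_key": caseid,
            "age": pd.to_numeric(_col(demo, "age"), errors="coerce") if _col(demo, "age") is not None else np.nan,
            "sex": [
                _map_enum(v, _SEX, "unknown")
                for v in (_col(demo, "sex") if _col(demo, "sex") is not None else [None] * len(demo))
            ],
            "weight": pd.to_numeric(_col(demo, "weight"), errors="coerce") if _col(demo, "weight") is not None else np.nan,
            "event_year": pd.to_numeric(_col(demo, "event_year"), errors="coerce").astype("Int64")
            if _col(demo, "event_year") is not None
            else pd.array([None] * len(demo), dtype="Int64"),
            "country": "JP",
            "reporter": [
                _map_enum(v, _OCCP, "unknown")
                for v in (_col(demo, "reporter") if _col(demo, "reporter") is not None else [None] * len(demo))
            ],
            "outcomes": [
                ";".join(sorted({_map_enum(v, _OUTC, "unknown")}))
                for v in (_col(demo, "outcome") if _col(demo, "outcome") is not None else [None] * len(demo))
            ],
        }
    )

    drug = _concat_tables(drug_files, ",")
    _require(drug, ["caseid", "drugname", "role"], os.path.basename(drug_files[0]))
    start, start_imp = (
        _parse_date_column(_col(drug, "start_date"), warnings, "DRUG.start_date")
        if _col(drug, "start_date") is not None
        else (pd.Series(pd.NaT, index=drug.index), pd.Series(False, index=drug.index))
    )
    drugs = pd.DataFrame(
        {
            "report_id": _col(drug, "caseid").astype(str),
            "verbatim_name": _col(drug, "drugname"),
            "ingredient": None,
            "role": [_map_enum(v, _SUSPECT_ROLE, "concomitant") for v in _col(drug, "role")],
            "start_date": start,
            "start_date_imputed": start_imp.astype(bool),
            "indication_pt": _col(drug, "indication") if _col(drug, "indication") is not None else None,
        }
    )

    reac = _concat_tables(reac_files, ",")
    _require(reac, ["caseid", "pt"], os.path.basename(reac_files[0]))
    onset, onset_imp = (
        _parse_date_column(_col(reac, "onset_date"), warnings, "REAC.onset_date")
        if _col(reac, "onset_date") is not None
        else (pd.Series(pd.NaT, index=reac.index), pd.Series(False, index=reac.index))
    )
    events = pd.DataFrame(
        {
            "report_id": _col(reac, "caseid").astype(str),
            "pt": _col(reac, "pt"),
            "onset_date": onset,
            "onset_date_imputed": onset_imp.astype(bool),
        }
    )
    return SRSDataset("JADER", cases, drugs, events, warnings)


def _read_cvar(files: list[str]) -> SRSDataset:
    warnings: dict = {}
    rep_files = [
        f
        for f in _find_table(files, "report")
        if "drug" not in os.path.basename(f).lower()
    ]
    drug_files = _find_table(files, "report_drug")
    reac_files = _find_table(files, "reaction")
    if not rep_files:
        raise ParseError("CVAR: no reports table found")
    if not drug_files:
        raise ParseError("CVAR: no report_drug table found")
    if not reac_files:
        raise ParseError("CVAR: no reactions table found")

    rep = _concat_tables(rep_files, ",")
    _require(rep, ["report_id"], os.path.basename(rep_files[0]))
    rid = _col(rep, "report_id").astype(str)
    cases = pd.DataFrame(
        {
            "report_id": rid,
            "case_id": rid,
            "version_key": rid,
            "age": pd.to_numeric(_col(rep, "age"), errors="coerce") if _col(rep, "age") is not None else np.nan,
            "sex": [
                _map_enum(v, _SEX, "unknown")
                for v in (_col(rep, "sex") if _col(rep, "sex") is not None else [None] * len(rep))
            ],
            "weight": pd.to_numeric(_col(rep, "weight"), errors="coerce") if _col(rep, "weight") is not None else np.nan,
            "event_year": pd.to_numeric(_col(rep, "event_year"), errors="coerce").astype("Int64")
            if _col(rep, "event_year") is not None
            else pd.array([None] * len(rep), dtype="Int64"),
            "country": _col(rep, "country") if _col(rep, "country") is not None else "CA",
            "reporter": [
                _map_enum(v, _OCCP, "unknown")
                for v in (_col(rep, "reporter") if _col(rep, "reporter") is not None else [None] * len(rep))
            ],
            "outcomes": [
                ";".join(sorted({_map_enum(v, _OUTC, "unknown")}))
                for v in (_col(rep, "outcome") if _col(rep, "outcome") is not None else [None] * len(rep))
            ],
        }
    )

    drug = _concat_tables(drug_files, ",")
    _require(drug, ["report_id", "drugname", "role"], os.path.basename(drug_files[0]))
    known = set(cases["report_id"])
    orphan = sorted(set(_col(drug, "report_id").astype(str)) - known)
    if orphan:
        raise ParseError(f"CVAR report_drug references unknown Report_ID: {orphan[:10]}")
    start, start_imp = (
        _parse_date_column(_col(drug, "start_date"), warnings, "report_drug.start_date")
        if _col(drug, "start_date") is not None
        else (pd.Series(pd.NaT, index=drug.index), pd.Series(False, index=drug.index))
    )
    drugs = pd.DataFrame(
        {
            "report_id": _col(drug, "report_id").astype(str),
            "verbatim_name": _col(drug, "drugname"),
            "ingredient": None,
            "role": [_map_enum(v, _SUSPECT_ROLE, "concomitant") for v in _col(drug, "role")],
            "start_date": start,
            "start_date_imputed": start_imp.astype(bool),
            "indication_pt": _col(drug, "indication") if _col(drug, "indication") is not None else None,
        }
    )

    reac = _concat_tables(reac_files, ",")
    _require(reac, ["report_id", "pt"], os.path.basename(reac_files[0]))
    orphan = sorted(set(_col(reac, "report_id").astype(str)) - known)
    if orphan:
        raise ParseError(f"CVAR reactions references unknown Report_ID: {orphan[:10]}")
    onset, onset_imp = (
        _parse_date_column(_col(reac, "onset_date"), warnings, "reactions.onset_date")
        if _col(reac, "onset_date") is not None
        else (pd.Series(pd.NaT, index=reac.index), pd.Series(False, index=reac.index))
    )
    events = pd.DataFrame(
        {
            "report_id": _col(reac, "report_id").astype(str),
            "pt": _col(reac, "pt"),
            "onset_date": onset,
            "onset_date_imputed": onset_imp.astype(bool),
        }
    )
    return SRSDataset("CVAR", cases, drugs, events, warnings)


# ---------------------------------------------------------------------------
# FAERS-shaped output (used by the simulator to emit parseable quarterly files)

_SEX_INV = {"female": "F", "male": "M", "unknown": ""}
_OCCP_INV = {
    "physician": "MD",
    "pharmacist": "PH",
    "other health professional": "OT",
    "non-health professional": "CN",
    "unknown": "",
}
_OUTC_INV = {
    "death": "DE",
    "life-threatening": "LT",
    "hospitalization": "HO",
    "disability": "DS",
    "other": "OT",
}
_ROLE_INV = {"PS": "PS", "SS": "SS", "suspect": "SS", "concomitant": "C", "interacting": "I"}


def _dt8(ts) -> str:
    return "" if pd.isna(ts) else pd.Timestamp(ts).strftime("%Y%m%d")


def write_faers(ds: SRSDataset, outdir) -> None:
    """Emit DEMO/DRUG/REAC/THER/INDI/OUTC as $-delimited quarterly-style files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cases = ds.cases
    fda_dt = cases["version_key"].astype(str).str.split(":").str[0]
    demo = pd.DataFrame(
        {
            "primaryid": cases["report_id"],
            "caseid": cases["case_id"],
            "fda_dt": fda_dt,
            "event_dt": cases["event_year"].map(
                lambda y: f"{int(y)}0101" if pd.notna(y) else ""
            ),
            "age": cases["age"].map(lambda a: "" if pd.isna(a) else f"{a:g}"),
            "age_cod": "YR",
            "sex": cases["sex"].map(lambda s: _SEX_INV.get(s, "")),
            "wt": cases["weight"].map(lambda w: "" if pd.isna(w) else f"{w:g}"),
            "wt_cod": "KG",
            "occp_cod": cases["reporter"].map(lambda r: _OCCP_INV.get(r, "")),
            "occr_country": cases["country"].fillna(""),
        }
    )
    demo.to_csv(outdir / "DEMO.txt", sep="$", index=False)

    drugs = ds.drugs.reset_index(drop=True)
    drug_seq = drugs.groupby("report_id").cumcount() + 1
    case_by_report = dict(zip(cases["report_id"], cases["case_id"]))
    pd.DataFrame(
        {
            "primaryid": drugs["report_id"],
            "caseid": drugs["report_id"].map(case_by_report),
            "drug_seq": drug_seq,
            "role_cod": drugs["role"].map(lambda r: _ROLE_INV.get(r, "C")),
            "drugname": drugs["verbatim_name"],
        }
    ).to_csv(outdir / "DRUG.txt", sep="$", index=False)

    ther = pd.DataFrame(
        {
            "primaryid": drugs["report_id"],
            "dsg_drug_seq": drug_seq,
            "start_dt": drugs["start_date"].map(_dt8),
        }
    )
    ther[ther["start_dt"] != ""].to_csv(outdir / "THER.txt", sep="$", index=False)

    indi = pd.DataFrame(
        {
            "primaryid": drugs["report_id"],
            "indi_drug_seq": drug_seq,
            "indi_pt": drugs["indication_pt"].fillna(""),
        }
    )
    indi[indi["indi_pt"] != ""].to_csv(outdir / "INDI.txt", sep="$", index=False)

    events = ds.events
    pd.DataFrame(
        {
            "primaryid": events["report_id"],
            "pt": events["pt"],
            "onset_dt": events["onset_date"].map(_dt8),
        }
    ).to_csv(outdir / "REAC.txt", sep="$", index=False)

    outc_rows = []
    for rid, outcomes in zip(cases["report_id"], cases["outcomes"]):
        for code in str(outcomes).split(";"):
            inv = _OUTC_INV.get(code)
            if inv:
                outc_rows.append({"primaryid": rid, "outc_cod": inv})
    pd.DataFrame(outc_rows, columns=["primaryid", "outc_cod"]).to_csv(
        outdir / "OUTC.txt", sep="$", index=False
    )


# ---------------------------------------------------------------------------
# canonical internal format: one directory with cases/drugs/events CSV + meta

def write_dataset(ds: SRSDataset, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds.cases[CASE_COLUMNS].to_csv(outdir / "cases.csv", index=False)
    drugs = ds.drugs[DRUG_COLUMNS].copy()
    drugs["start_date"] = pd.to_datetime(drugs["start_date"]).dt.strftime("%Y-%m-%d")
    drugs.to_csv(outdir / "drugs.csv", index=False)
    events = ds.events[EVENT_COLUMNS].copy()
    events["onset_date"] = pd.to_datetime(events["onset_date"]).dt.strftime("%Y-%m-%d")
    events.to_csv(outdir / "events.csv", index=False)
    meta = {"dialect": ds.dialect, "parse_warnings": ds.parse_warnings}
    (outdir / "meta.json").write_text(json.dumps(meta, indent=1))


def read_dataset(indir) -> SRSDataset:
    indir = Path(indir)
    meta = json.loads((indir / "meta.json").read_text())
    cases = pd.read_csv(
        indir / "cases.csv",
        dtype={"report_id": str, "case_id": str, "version_key": str},
    )
    cases["event_year"] = pd.to_numeric(cases["event_year"], errors="coerce").astype("Int64")
    drugs = pd.read_csv(indir / "drugs.csv", dtype={"report_id": str})
    drugs["start_date"] = pd.to_datetime(drugs["start_date"], errors="coerce")
    drugs["start_date_imputed"] = drugs["start_date_imputed"].astype(bool)
    events = pd.read_csv(indir / "events.csv", dtype={"report_id": str})
    events["onset_date"] = pd.to_datetime(events["onset_date"], errors="coerce")
    events["onset_date_imputed"] = events["onset_date_imputed"].astype(bool)
    return SRSDataset(meta["dialect"], cases, drugs, events, meta.get("parse_warnings", {}))
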