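"""Core containers for spontaneous-report data.

A spontaneous reporting system (SRS) extract is held as three linked
pandas tables keyed by ``report_id``:

``cases``
    one row per report: demographics, reporter, outcomes, versioning keys.
``drugs``
    one row per reported drug mention: verbatim name, normalized
    ingredient, role code, therapy start date, indication.
``events``
    one row per reported adverse-event preferred term (PT), with onset date.

The same containers serve FAERS-, JADER- and CVAR-shaped extracts as well
as synthetic data; a ``dialect`` tag records the origin because the
deduplication rules and default drug-role policy differ between sources.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ROLES",
    "SEXES",
    "REPORTERS",
    "OUTCOMES",
    "DEFAULT_EVENT_PTS",
    "normalize_name",
    "DrugDictionary",
    "SRSDataset",
    "DedupReport",
    "deduplicate",
    "normalize_drugs",
    "select_reports",
]

#: Closed set of drug role codes. FAERS distinguishes primary suspect (PS)
#: and secondary suspect (SS); JADER and CVAR use a single "suspect" code.
ROLES = frozenset({"PS", "SS", "concomitant", "interacting", "suspect"})

SEXES = frozenset({"female", "male", "unknown"})

REPORTERS = frozenset(
    {
        "physician",
        "pharmacist",
        "other health professional",
        "non-health professional",
        "unknown",
    }
)

OUTCOMES = frozenset(
    {"death", "life-threatening", "hospitalization", "disability", "other", "unknown"}
)

#: Default adverse-event query for EGPA. The legacy MedDRA term
#: "Churg-Strauss syndrome" is included alongside the current PT because
#: older reports are coded under it.
DEFAULT_EVENT_PTS = frozenset(
    {"eosinophilic granulomatosis with polyangiitis", "churg-strauss syndrome"}
)

CASE_COLUMNS = [
    "report_id",
    "case_id",
    "version_key",
    "age",
    "sex",
    "weight",
    "event_year",
    "country",
    "reporter",
    "outcomes",
]
DRUG_COLUMNS = [
    "report_id",
    "verbatim_name",
    "ingredient",
    "role",
    "start_date",
    "start_date_imputed",
    "indication_pt",
]
EVENT_COLUMNS = ["report_id", "pt", "onset_date", "onset_date_imputed"]


def normalize_name(name: str) -> str:
    """Canonical string form used for all drug-name and PT matching.

    Unicode NFKC, casefold, and internal whitespace collapsed to single
    spaces — trade names appear in mixed case and full-width characters
    across database dialects.
    """
    s = unicodedata.normalize("NFKC", str(name)).casefold().strip()
    return " ".join(s.split())


class DrugDictionary:
    """Name → active-ingredient lookup covering generic, trade and former names.

    Lookup is case- and whitespace-insensitive. Every ingredient maps to
    itself, so already-canonical names resolve without an explicit entry.
    """

    def __init__(self, mapping: Mapping[str, str]):
        self._map: dict[str, str] = {}
        for name, ingredient in mapping.items():
            ing = normalize_name(ingredient)
            self._map[normalize_name(name)] = ing
            self._map.setdefault(ing, ing)

    @classmethod
    def from_csv(cls, path) -> "DrugDictionary":
        """Read a two-column CSV (name, ingredient); a header row is required."""
        df = pd.read_csv(path, dtype=str)
        if df.shape[1] < 2:
            raise ValueError(f"drug dictionary {path} needs two columns (name, ingredient)")
        name_col, ing_col = df.columns[:2]
        return cls(dict(zip(df[name_col], df[ing_col])))

    def lookup(self, name: str) -> str | None:
        return self._map.get(normalize_name(name))

    def __contains__(self, name: str) -> bool:
        return normalize_name(name) in self._map

    def __len__(self) -> int:
        return len(self._map)

    @property
    def ingredients(self) -> frozenset[str]:
        return frozenset(self._map.values())


#: Generic, trade and former names of the four leukotriene receptor
#: antagonists, as used for case retrieval.
LTRA_NAMES: dict[str, str] = {
    "montelukast": "montelukast",
    "montelukast sodium": "montelukast",
    "singulair": "montelukast",
    "kipres": "montelukast",
    "zafirlukast": "zafirlukast",
    "accolate": "zafirlukast",
    "pranlukast": "pranlukast",
    "pranlukast hydrate": "pranlukast",
    "onon": "pranlukast",
    "ibudilast": "ibudilast",
    "ketas": "ibudilast",
    "pinatos": "ibudilast",
}


def default_drug_dictionary() -> DrugDictionary:
    return DrugDictionary(LTRA_NAMES)


@dataclass
class SRSDataset:
    """Linked case/drug/event tables from one SRS extract.

    Invariants (checked by :meth:`validate`): one case row per
    ``report_id``; every drug/event row references an existing report;
    roles drawn from :data:`ROLES`.
    """

    dialect: str
    cases: pd.DataFrame
    drugs: pd.DataFrame
    events: pd.DataFrame
    parse_warnings: dict = field(default_factory=dict)

    @property
    def n_reports(self) -> int:
        return len(self.cases)

    def validate(self) -> "SRSDataset":
        if self.cases["report_id"].duplicated().any():
            dups = self.cases.loc[self.cases["report_id"].duplicated(), "report_id"]
            raise ValueError(f"duplicate report_id in cases: {sorted(set(dups))[:5]}")
        known = set(self.cases["report_id"])
        for name, table in (("drugs", self.drugs), ("events", self.events)):
            orphans = set(table["report_id"]) - known
            if orphans:
                raise ValueError(
                    f"{name} table references report_id absent from cases: "
                    f"{sorted(orphans)[:10]}"
                )
        bad_roles = set(self.drugs["role"].dropna()) - ROLES
        if bad_roles:
            raise ValueError(f"unknown drug roles: {sorted(bad_roles)}")
        return self

    def default_roles(self) -> frozenset[str]:
        """Suspect-role policy per dialect: FAERS restricts to the primary
        suspect; JADER and CVAR use their single 'suspect' code."""
        if self.dialect == "FAERS":
            return frozenset({"PS"})
        if self.dialect in ("JADER", "CVAR"):
            return frozenset({"suspect"})
        return frozenset({"PS", "suspect"})

    def copy(self) -> "SRSDataset":
        return SRSDataset(
            self.dialect,
            self.cases.copy(),
            self.drugs.copy(),
            self.events.copy(),
            dict(self.parse_warnings),
        )

    def equals(self, other: "SRSDataset") -> bool:
        def _norm(df, cols):
            return df[cols].reset_index(drop=True)

        return (
            self.dialect == other.dialect
            and _norm(self.cases, CASE_COLUMNS).equals(_norm(other.cases, CASE_COLUMNS))
            and _norm(self.drugs, DRUG_COLUMNS).equals(_norm(other.drugs, DRUG_COLUMNS))
            and _norm(self.events, EVENT_COLUMNS).equals(_norm(other.events, EVENT_COLUMNS))
        )


@dataclass
class DedupReport:
    n_cases_removed: int
    n_drug_rows_removed: int
    n_event_rows_removed: int
    ties: list = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return self.n_cases_removed


def deduplicate(ds: SRSDataset) -> tuple[SRSDataset, DedupReport]:
    """Remove duplicate reports according to the dialect's convention.

    FAERS (and synthetic data, which mimics its versioning): keep the row
    with the greatest ``version_key`` per ``case_id`` — the key is built
    from (fda_dt, primaryid) so later submissions supersede earlier ones.
    Ties on ``version_key`` keep the lexicographically greatest
    ``report_id`` and are logged. JADER: identical rows are dropped from
    the drug and event tables. CVAR: one row per Report_ID. The operation
    is idempotent.
    """
    cases, drugs, events = ds.cases, ds.drugs, ds.events
    ties: list[str] = []
    n_drug0, n_event0 = len(drugs), len(events)

    if ds.dialect in ("FAERS", "SYNTHETIC"):
        order = cases.sort_values(
            ["case_id", "version_key", "report_id"], kind="mergesort"
        )
        tie_mask = order.duplicated(["case_id", "version_key"], keep=False)
        if tie_mask.any():
            ties = sorted(set(order.loc[tie_mask, "case_id"]))
        keep = order.drop_duplicates("case_id", keep="last")
        kept_ids = set(keep["report_id"])
        cases = cases[cases["report_id"].isin(kept_ids)].reset_index(drop=True)
        drugs = drugs[drugs["report_id"].isin(kept_ids)].reset_index(drop=True)
        events = events[events["report_id"].isin(kept_ids)].reset_index(drop=True)
    elif ds.dialect == "JADER":
        cases = cases.drop_duplicates("case_id", keep="first").reset_index(drop=True)
        drugs = drugs.drop_duplicates().reset_index(drop=True)
        events = events.drop_duplicates().reset_index(drop=True)
        kept_ids = set(cases["report_id"])
        drugs = drugs[drugs["report_id"].isin(kept_ids)].reset_index(drop=True)
        events = events[events["report_id"].isin(kept_ids)].reset_index(drop=True)
    elif ds.dialect == "CVAR":
        cases = cases.drop_duplicates("report_id", keep="first").reset_index(drop=True)
        drugs = drugs.drop_duplicates().reset_index(drop=True)
        events = events.drop_duplicates().reset_index(drop=True)
    else:
        raise ValueError(f"unknown dialect {ds.dialect!r}")

    report = DedupReport(
        n_cases_removed=ds.n_reports - len(cases),
        n_drug_rows_removed=n_drug0 - len(drugs),
        n_event_rows_removed=n_event0 - len(events),
        ties=ties,
    )
    out = SRSDataset(ds.dialect, cases, drugs, events, dict(ds.parse_warnings))
    return out, report


def normalize_drugs(ds: SRSDataset, dictionary: DrugDictionary) -> SRSDataset:
    """Assign canonical ingredients to drug rows whose verbatim name is in
    the dictionary; non-matching names keep a null ingredient and are
    retained."""
    out = ds.copy()
    out.drugs["ingredient"] = [
        dictionary.lookup(v) if pd.notna(v) else None
        for v in out.drugs["verbatim_name"]
    ]
    return out


def select_reports(
    ds: SRSDataset,
    ingredients: Iterable[str],
    roles: Iterable[str] | None = None,
    event_pts: Iterable[str] | None = None,
) -> tuple[set, set, set]:
    """Report-level exposure and event sets for a drug(-set) × event query.

    Returns ``(exposed, with_event, exposed_and_event)`` sets of
    report_ids. A report counts once regardless of how many qualifying
    drug or event rows it carries. ``roles`` defaults to the dialect's
    suspect-role policy; ``event_pts`` defaults to the EGPA query.
    """
    ingredients = {normalize_name(i) for i in ingredients}
    if not ingredients:
        raise ValueError("empty ingredient set")
    if roles is None:
        roles = ds.default_roles()
    roles = set(roles)
    if not roles <= ROLES:
        raise ValueError(f"unknown roles: {sorted(roles - ROLES)}")
    if event_pts is None:
        event_pts = DEFAULT_EVENT_PTS
    event_pts = {normalize_name(p) for p in event_pts}
    if not event_pts:
        raise ValueError("empty event PT set")

    d = ds.drugs
    ing = d["ingredient"].map(lambda x: normalize_name(x) if pd.notna(x) else None)
    exposed = set(d.loc[ing.isin(ingredients) & d["role"].isin(roles), "report_id"])

    e = ds.events
    pts = e["pt"].map(normalize_name)
    with_event = set(e.loc[pts.isin(event_pts), "report_id"])

    return exposed, with_event, exposed & with_event


def empty_tables() -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    cases = pd.DataFrame(columns=CASE_COLUMNS)
    drugs = pd.DataFrame(columns=DRUG_COLUMNS)
    events = pd.DataFrame(columns=EVENT_COLUMNS)
    return cases, drugs, events
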