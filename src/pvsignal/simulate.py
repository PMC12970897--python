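"""Synthetic spontaneous-report data with known ground truth.

The generator emulates the structure of a reporting database at the
level the screening statistics see: per-report drug exposure drawn
independently per drug, adverse events drawn per report with a
multiplicative relative reporting rate (RR) when a paired signal drug is
present, one primary-suspect drug per report, Weibull-distributed onset
intervals for signal pairs, re-versioned duplicate records, demographics
and MCAR missingness. Independence of the drug draws yields closed-form
expected 2×2 cells, so every downstream stage can be checked against
construction ground truth.

A companion fixture builder produces the inputs of the network stage:
per-source target lists with a known union, drug/disease gene lists with
an exact overlap, a weighted interaction graph with a planted dense
module, and a GMT annotation collection with one enriched term of known
composition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dataset import SRSDataset

__all__ = ["SignalSpec", "Demographics", "GeneratorConfig", "generate", "make_network_fixture"]


@dataclass(frozen=True)
class SignalSpec:
    """A planted drug–event association.

    ``target_rr`` multiplies the event's baseline reporting probability
    when the drug is present (1 = null pair). Onset intervals for
    reports carrying the pair are drawn Weibull(scale=``tto_scale`` days,
    shape=``tto_shape``).
    """

    ingredient: str
    event_pt: str
    target_rr: float = 1.0
    tto_scale: float = 250.0
    tto_shape: float = 0.75

    def __post_init__(self):
        if self.target_rr < 0:
            raise ValueError("target_rr must be >= 0")
        if self.tto_scale <= 0 or self.tto_shape <= 0:
            raise ValueError("Weibull parameters must be > 0")


@dataclass(frozen=True)
class Demographics:
    """Marginal distributions for the demographic fields.

    Ages come from a two-component normal mixture (adult / elderly),
    weight from a log-normal centred near 70 kg — unremarkable choices
    for an adult reporting population.
    """

    age_means: tuple = (45.0, 75.0)
    age_sds: tuple = (15.0, 7.0)
    age_weights: tuple = (0.8, 0.2)
    p_female: float = 0.55
    weight_log_mean: float = 4.25
    weight_log_sd: float = 0.25
    reporter_probs: tuple = (0.45, 0.15, 0.15, 0.25)  # physician, pharmacist, other HP, non-HP
    countries: tuple = ("US", "JP", "CA", "GB", "FR")
    country_probs: tuple = (0.5, 0.2, 0.1, 0.1, 0.1)
    outcome_probs: tuple = (0.03, 0.05, 0.3, 0.04, 0.58)  # death, LT, hosp, disab, other

    _REPORTERS = ("physician", "pharmacist", "other health professional", "non-health professional")
    _OUTCOMES = ("death", "life-threatening", "hospitalization", "disability", "other")


@dataclass
class GeneratorConfig:
    """Full specification of one synthetic database draw."""

    n_reports: int = 10_000
    drugs: dict = field(
        default_factory=lambda: {
            "montelukast": 0.02,
            "zafirlukast": 0.004,
            "pranlukast": 0.004,
            "fluticasone": 0.03,
            "prednisone": 0.03,
            "amoxicillin": 0.05,
        }
    )
    events: dict = field(
        default_factory=lambda: {
            "Eosinophilic granulomatosis with polyangiitis": 0.0005,
            "Headache": 0.05,
            "Nausea": 0.06,
            "Rash": 0.04,
        }
    )
    signals: list = field(
        default_factory=lambda: [
            SignalSpec(
                "montelukast",
                "Eosinophilic granulomatosis with polyangiitis",
                target_rr=50.0,
                tto_scale=391.08,
                tto_shape=0.76,
            )
        ]
    )
    duplicate_rate: float = 0.0
    missingness: dict = field(
        default_factory=lambda: {
            "age": 0.1,
            "sex": 0.05,
            "weight": 0.3,
            "start_date": 0.2,
            "onset_date": 0.2,
            "country": 0.05,
        }
    )
    demographics: Demographics = field(default_factory=Demographics)
    indications: dict = field(
        default_factory=lambda: {"Asthma": 0.7, "Rhinitis allergic": 0.3}
    )
    start_year_range: tuple = (2004, 2024)
    seed: int = 0

    def validate(self) -> "GeneratorConfig":
        if self.n_reports < 1:
            raise ValueError("n_reports must be >= 1")
        if not self.drugs or not self.events:
            raise ValueError("drug and event vocabularies must be non-empty")
        for name, p in {**self.drugs, **self.events}.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability for {name!r} outside [0, 1]")
        if not 0.0 <= self.duplicate_rate <= 1.0:
            raise ValueError("duplicate_rate must lie in [0, 1]")
        for spec in self.signals:
            if spec.ingredient not in self.drugs:
                raise ValueError(f"signal drug {spec.ingredient!r} not in drug vocabulary")
            if spec.event_pt not in self.events:
                raise ValueError(f"signal event {spec.event_pt!r} not in event vocabulary")
        return self


def _expected_cells(cfg: GeneratorConfig, spec: SignalSpec) -> dict:
    """Closed-form expected 2×2 cells for one signal pair (pre-duplicates)."""
    n = cfg.n_reports
    pd_ = cfg.drugs[spec.ingredient]
    pe = cfg.events[spec.event_pt]
    pe_drug = min(pe * spec.target_rr, 1.0)
    a = n * pd_ * pe_drug
    b = n * pd_ * (1 - pe_drug)
    c = n * (1 - pd_) * pe
    d = n * (1 - pd_) * (1 - pe)
    return {"a": a, "b": b, "c": c, "d": d}


def generate(cfg: GeneratorConfig, seed: int | None = None) -> tuple[SRSDataset, dict]:
    """Draw one synthetic database; fully reproducible under a fixed seed.

    Returns the dataset (dialect ``SYNTHETIC``, FAERS-style versioning so
    the standard deduplication applies) and a ground-truth bundle with
    realized and expected 2×2 cells per drug–event pair, the drawn onset
    intervals for signal pairs, and the injected duplicate count.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n_reports
    drug_names = list(cfg.drugs)
    event_names = list(cfg.events)
    p_drug = np.array([cfg.drugs[k] for k in drug_names])
    p_event = np.array([cfg.events[k] for k in event_names])

    for spec in cfg.signals:
        exp_a = _expected_cells(cfg, spec)["a"]
        if exp_a < 1.0:
            warnings.warn(
                f"expected case count {exp_a:.2f} < 1 for signal pair "
                f"({spec.ingredient}, {spec.event_pt})",
                stacklevel=2,
            )

    exposure = rng.random((n, len(drug_names))) < p_drug

    # event probability per report: baseline times RR for each present signal drug
    probs = np.broadcast_to(p_event, (n, len(event_names))).copy()
    spec_idx = {}
    for spec in cfg.signals:
        di = drug_names.index(spec.ingredient)
        ei = event_names.index(spec.event_pt)
        spec_idx[(di, ei)] = spec
        probs[:, ei] = np.where(exposure[:, di], probs[:, ei] * spec.target_rr, probs[:, ei])
    np.clip(probs, 0.0, 1.0, out=probs)
    event_occ = rng.random((n, len(event_names))) < probs

    # one primary suspect per report, uniform among present drugs
    counts = exposure.sum(axis=1)
    pick = np.floor(rng.random(n) * np.maximum(counts, 1)).astype(int)
    csum = np.cumsum(exposure, axis=1)
    ps_col = np.argmax(csum > pick[:, None], axis=1)
    has_drug = counts > 0

    # demographics
    demo = cfg.demographics
    comp = rng.choice(len(demo.age_weights), size=n, p=np.array(demo.age_weights))
    age = rng.normal(np.array(demo.age_means)[comp], np.array(demo.age_sds)[comp])
    age = np.clip(age, 0.0, 105.0)
    sex = np.where(rng.random(n) < demo.p_female, "female", "male")
    weight = np.exp(rng.normal(demo.weight_log_mean, demo.weight_log_sd, size=n))
    reporter = rng.choice(demo._REPORTERS, size=n, p=np.array(demo.reporter_probs))
    country = rng.choice(demo.countries, size=n, p=np.array(demo.country_probs))
    outcome = rng.choice(demo._OUTCOMES, size=n, p=np.array(demo.outcome_probs))
    ind_names = list(cfg.indications)
    ind_p = np.array([cfg.indications[k] for k in ind_names])
    indication = rng.choice(ind_names, size=n, p=ind_p / ind_p.sum())

    # therapy start dates: uniform days over the configured window, per report-drug
    y0, y1 = cfg.start_year_range
    window0 = np.datetime64(f"{y0}-01-01")
    window_days = int(
        (np.datetime64(f"{y1}-12-31") - window0) / np.timedelta64(1, "D")
    )
    start_offset = rng.integers(0, window_days, size=(n, len(drug_names)))

    # onset: Weibull interval after the signal drug's start for signal pairs,
    # exponential lag after the report's earliest start otherwise
    onset_day = np.full((n, len(event_names)), np.nan)
    base_start = np.where(has_drug, start_offset.min(axis=1, where=exposure, initial=window_days), 0)
    bg_lag = np.ceil(rng.exponential(180.0, size=(n, len(event_names)))).astype(int)
    for ei in range(len(event_names)):
        onset_day[:, ei] = base_start + bg_lag[:, ei]
    tto_records = []
    for (di, ei), spec in spec_idx.items():
        mask = exposure[:, di] & event_occ[:, ei]
        m = int(mask.sum())
        if m == 0:
            continue
        days = np.maximum(np.ceil(spec.tto_scale * rng.weibull(spec.tto_shape, size=m)), 1.0)
        onset_day[mask, ei] = start_offset[mask, di] + days
        for rid_idx, dval in zip(np.nonzero(mask)[0], days):
            tto_records.append(
                {
                    "report_id": f"R{rid_idx:07d}",
                    "ingredient": spec.ingredient,
                    "event_pt": spec.event_pt,
                    "days": float(dval),
                }
            )

    report_ids = np.array([f"R{i:07d}" for i in range(n)])
    case_ids = np.array([f"C{i:07d}" for i in range(n)])

    miss = {k: cfg.missingness.get(k, 0.0) for k in ("age", "sex", "weight", "start_date", "onset_date", "country")}
    age_miss = rng.random(n) < miss["age"]
    sex_miss = rng.random(n) < miss["sex"]
    wt_miss = rng.random(n) < miss["weight"]
    country_miss = rng.random(n) < miss["country"]

    event_year = (window0 + start_offset.min(axis=1)).astype("datetime64[Y]").astype(int) + 1970

    cases = pd.DataFrame(
        {
            "report_id": report_ids,
            "case_id": case_ids,
            "version_key": np.char.add("20240101:", report_ids.astype(str)),
            "age": np.where(age_miss, np.nan, np.round(age, 1)),
            "sex": np.where(sex_miss, "unknown", sex),
            "weight": np.where(wt_miss, np.nan, np.round(weight, 1)),
            "event_year": pd.array(event_year, dtype="Int64"),
            "country": np.where(country_miss, None, country),
            "reporter": reporter,
            "outcomes": outcome,
        }
    )

    rows_r, rows_d = np.nonzero(exposure)
    start_miss = rng.random(rows_r.size) < miss["start_date"]
    drugs = pd.DataFrame(
        {
            "report_id": report_ids[rows_r],
            "verbatim_name": np.array(drug_names)[rows_d],
            "ingredient": np.array(drug_names)[rows_d],
            "role": np.where(ps_col[rows_r] == rows_d, "PS", "concomitant"),
            "start_date": [
                pd.NaT if m else window0 + np.timedelta64(int(o), "D")
                for m, o in zip(start_miss, start_offset[rows_r, rows_d])
            ],
            "start_date_imputed": False,
            "indication_pt": indication[rows_r],
        }
    )

    erow, ecol = np.nonzero(event_occ)
    onset_miss = rng.random(erow.size) < miss["onset_date"]
    events = pd.DataFrame(
        {
            "report_id": report_ids[erow],
            "pt": np.array(event_names)[ecol],
            "onset_date": [
                pd.NaT if m else window0 + np.timedelta64(int(o), "D")
                for m, o in zip(onset_miss, onset_day[erow, ecol])
            ],
            "onset_date_imputed": False,
        }
    )

    # realized 2x2 cells per pair, at report level, pre-duplication
    pair_rows = []
    for di, dname in enumerate(drug_names):
        for ei, ename in enumerate(event_names):
            a = int(np.sum(exposure[:, di] & event_occ[:, ei]))
            b = int(np.sum(exposure[:, di] & ~event_occ[:, ei]))
            c = int(np.sum(~exposure[:, di] & event_occ[:, ei]))
            d = n - a - b - c
            spec = spec_idx.get((di, ei))
            expected = _expected_cells(cfg, spec) if spec else _expected_cells(
                cfg, SignalSpec(dname, ename, 1.0)
            )
            pair_rows.append(
                {
                    "ingredient": dname,
                    "event_pt": ename,
                    "a": a,
                    "b": b,
                    "c": c,
                    "d": d,
                    "expected_a": expected["a"],
                    "target_rr": spec.target_rr if spec else 1.0,
                }
            )

    # inject duplicates as re-versioned copies of sampled reports
    n_dup = int(round(cfg.duplicate_rate * n))
    if n_dup:
        dup_idx = np.sort(rng.choice(n, size=n_dup, replace=False))
        dup_ids = np.array([f"R{i:07d}b" for i in dup_idx])
        id_map = dict(zip(report_ids[dup_idx], dup_ids))
        dup_cases = cases.iloc[dup_idx].copy()
        dup_cases["report_id"] = dup_ids
        dup_cases["version_key"] = np.char.add("20240401:", dup_ids.astype(str))
        cases = pd.concat([cases, dup_cases], ignore_index=True)
        dup_drugs = drugs[drugs["report_id"].isin(id_map)].copy()
        dup_drugs["report_id"] = dup_drugs["report_id"].map(id_map)
        drugs = pd.concat([drugs, dup_drugs], ignore_index=True)
        dup_events = events[events["report_id"].isin(id_map)].copy()
        dup_events["report_id"] = dup_events["report_id"].map(id_map)
        events = pd.concat([events, dup_events], ignore_index=True)

    ds = SRSDataset("SYNTHETIC", cases, drugs, events).validate()
    truth = {
        "pair_counts": pd.DataFrame(pair_rows),
        "tto": pd.DataFrame(tto_records, columns=["report_id", "ingredient", "event_pt", "days"]),
        "n_duplicates": n_dup,
        "seed": int(cfg.seed if seed is None else seed),
    }
    return ds, truth


# ---------------------------------------------------------------------------
# network-stage fixture


def make_network_fixture(
    n_drug_targets: int = 553,
    n_disease_genes: int = 3555,
    n_overlap: int = 81,
    n_sources: int = 4,
    clique_size: int = 6,
    p_background: float = 0.03,
    n_annotation_terms: int = 12,
    seed: int = 0,
):
    """Construct the inputs of the network-pharmacology stage with known truth.

    Returns ``(drug_sources, disease_genes, edges, gmt, truth)`` where
    ``drug_sources`` is a list of per-source symbol lists whose union has
    exactly ``n_drug_targets`` members, the drug/disease lists share
    exactly ``n_overlap`` symbols, ``edges`` is a STRING-style DataFrame
    (protein1, protein2, combined_score on [0,1]) over the overlap genes
    containing one planted near-clique of ``clique_size`` members, and
    ``gmt`` maps term names to member lists with one term enriched in the
    clique by construction.
    """
    if n_overlap > min(n_drug_targets, n_disease_genes):
        raise ValueError("n_overlap cannot exceed either list size")
    if n_overlap and clique_size > n_overlap:
        raise ValueError("clique_size cannot exceed n_overlap")
    rng = np.random.default_rng(seed)

    overlap = [f"OVL{i:04d}" for i in range(n_overlap)]
    drug_only = [f"DRG{i:04d}" for i in range(n_drug_targets - n_overlap)]
    dis_only = [f"DIS{i:04d}" for i in range(n_disease_genes - n_overlap)]
    drug_all = overlap + drug_only
    disease = overlap + dis_only

    # spread drug targets over sources; every gene in >=1 source, with overlap
    sources: list[list[str]] = [[] for _ in range(n_sources)]
    for g in drug_all:
        member = rng.random(n_sources) < 0.45
        if not member.any():
            member[rng.integers(n_sources)] = True
        for s in np.nonzero(member)[0]:
            sources[s].append(g)

    clique = overlap[:clique_size]
    rows = []
    seen = set()

    def add_edge(u, v, score):
        if u == v:
            return
        key = (u, v) if u < v else (v, u)
        if key in seen:
            return
        seen.add(key)
        rows.append({"protein1": key[0], "protein2": key[1], "combined_score": round(float(score), 3)})

    for i in range(len(clique)):
        for j in range(i + 1, len(clique)):
            add_edge(clique[i], clique[j], rng.uniform(0.7, 0.99))
    others = overlap[clique_size:]
    for i in range(len(others)):
        for j in range(i + 1, len(others)):
            if rng.random() < p_background:
                add_edge(others[i], others[j], rng.uniform(0.15, 0.9))
    # sparse attachment of the clique to the rest, below clique density
    for g in others:
        if rng.random() < 0.1 and clique:
            add_edge(g, clique[int(rng.integers(len(clique)))], rng.uniform(0.41, 0.6))
    edges = pd.DataFrame(rows, columns=["protein1", "protein2", "combined_score"])

    universe = list(overlap)
    gmt: dict[str, list] = {}
    extra = min(4, max(0, len(others)))
    enriched_members = clique + others[:extra]
    gmt["TERM_ENRICHED"] = list(enriched_members)
    for t in range(n_annotation_terms - 1):
        size = int(rng.integers(5, max(6, min(25, max(6, len(universe))))))
        members = rng.choice(universe, size=min(size, len(universe)), replace=False)
        gmt[f"TERM_{t:03d}"] = sorted(members.tolist())

    truth = {
        "overlap": overlap,
        "clique": clique,
        "enriched_term": "TERM_ENRICHED",
        "union_size": n_drug_targets,
    }
    return sources, disease, edges, gmt, truth
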