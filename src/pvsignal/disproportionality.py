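"""Disproportionality statistics and the joint four-algorithm signal test.

Implements the reporting odds ratio (ROR), proportional reporting ratio
(PRR) with Pearson χ², the BCPNN information component (IC), and the
MGPS empirical Bayes geometric mean (EBGM), together with the joint
signal criterion used in routine pharmacovigilance screening:

    ROR 95% CI lower bound > 1 and n ≥ 3;
    PRR > 2 with χ² ≥ 4;
    IC025 > 0;
    EBGM05 > 2.

A pair is flagged only if all four criteria hold. The model/results
split follows the usual statistical-package convention:
:class:`DisproportionalityModel` is built from a dataset (or directly
from a 2×2 table), ``fit()`` computes everything and returns a
:class:`DisproportionalityResults` with a ``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from . import mgps
from .contingency import ContingencyTable, DegenerateTableError, build_table
from .dataset import DEFAULT_EVENT_PTS, SRSDataset, normalize_name, select_reports

__all__ = [
    "ZeroCellError",
    "ror",
    "prr_chi2",
    "expected_count",
    "information_component",
    "ICResult",
    "SignalThresholds",
    "DisproportionalityModel",
    "DisproportionalityResults",
    "all_pair_counts",
    "subgroup_analysis",
    "comedication_analysis",
    "top_comedications",
    "AGE_CUTOFF",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile
AGE_CUTOFF = 65.0


class ZeroCellError(ValueError):
    """A ratio statistic is undefined because a cell is zero and the
    Haldane continuity correction is off."""


def ror(t: ContingencyTable, haldane: bool = False) -> tuple[float, float, float]:
    """Reporting odds ratio ad/(bc) with Wald 95% CI on the log scale.

    Returns ``(estimate, ci_lower, ci_upper)``. Any zero cell makes the
    cross-product ratio or its variance undefined; pass ``haldane=True``
    to add 0.5 to every cell instead of raising.
    """
    if haldane and min(t.as_tuple()) == 0:
        t = t.with_haldane()
    a, b, c, d = t.as_tuple()
    if min(a, b, c, d) == 0:
        raise ZeroCellError(f"zero cell in table {t.as_tuple()}; enable haldane correction")
    est = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = math.exp(math.log(est) - Z95 * se)
    hi = math.exp(math.log(est) + Z95 * se)
    return est, lo, hi


def prr_chi2(t: ContingencyTable, haldane: bool = False) -> tuple[float, float, float, float]:
    """PRR with 95% CI and the uncorrected Pearson χ² statistic.

    PRR = [a/(a+b)] / [c/(c+d)];
    CI = exp(ln PRR ± 1.96·sqrt(1/a − 1/(a+b) + 1/c − 1/(c+d)));
    χ² = N(ad − bc)² / [(a+b)(c+d)(a+c)(b+d)], no continuity correction.

    Returns ``(prr, ci_lower, ci_upper, chi2)``.
    """
    ht = t.with_haldane() if (haldane and min(t.as_tuple()) == 0) else t
    a, b, c, d = ht.as_tuple()
    if a + b == 0 or c + d == 0:
        raise DegenerateTableError("empty exposure margin")
    if a == 0 or c == 0:
        raise ZeroCellError(f"PRR undefined for table {t.as_tuple()}; enable haldane correction")
    est = (a / (a + b)) / (c / (c + d))
    se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    lo = math.exp(math.log(est) - Z95 * se)
    hi = math.exp(math.log(est) + Z95 * se)
    n = a + b + c + d
    chi2 = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    return est, lo, hi, chi2


def expected_count(t: ContingencyTable) -> tuple[float, float]:
    """Expected a-cell under independence, E = (a+b)(a+c)/N, and the
    relative reporting ratio RR = a/E."""
    e = t.n_exposed * t.n_event / t.n_total
    return e, t.a / e


@dataclass(frozen=True)
class ICResult:
    ic: float
    ic025_approx: float
    ic025_mc: float | None = None
    variant: str = "raw"


def information_component(
    a: float,
    E: float,
    variant: str = "raw",
    n_mc: int = 0,
    seed: int | None = None,
) -> ICResult:
    """BCPNN information component with two IC025 estimates.

    ``variant="raw"`` reports IC = log2(a/E), matching the convention in
    which IC equals log2 of the relative reporting ratio exactly;
    ``variant="shrunk"`` applies the +0.5 shrinkage, IC = log2((a+0.5)/(E+0.5)).

    IC025 is reported two ways: the closed-form credibility approximation
    IC − 3.3(a+0.5)^(−1/2) − 2(a+0.5)^(−3/2), and (when ``n_mc > 0``) the
    Monte-Carlo 2.5th percentile of log2 λ under the Gamma(a+0.5, E+0.5)
    posterior.
    """
    if E <= 0:
        raise ValueError("E must be > 0")
    if variant == "raw":
        if a <= 0:
            raise ZeroCellError("raw IC undefined at a=0; use variant='shrunk'")
        ic = math.log2(a / E)
    elif variant == "shrunk":
        ic = math.log2((a + 0.5) / (E + 0.5))
    else:
        raise ValueError(f"unknown IC variant {variant!r}")
    ap5 = a + 0.5
    ic025_approx = ic - 3.3 * ap5 ** -0.5 - 2.0 * ap5 ** -1.5
    ic025_mc = None
    if n_mc > 0:
        rng = np.random.default_rng(seed)
        lam = rng.gamma(shape=a + 0.5, scale=1.0 / (E + 0.5), size=int(n_mc))
        ic025_mc = float(np.quantile(np.log2(lam), 0.025))
    return ICResult(ic, ic025_approx, ic025_mc, variant)


@dataclass(frozen=True)
class SignalThresholds:
    """The joint four-criterion rule for a positive signal."""

    ror_ci_lower: float = 1.0
    min_cases: int = 3
    prr: float = 2.0
    chi2: float = 4.0
    ic025: float = 0.0
    ebgm05: float = 2.0


@dataclass
class DisproportionalityResults:
    """All four statistics, per-criterion flags, and their conjunction."""

    table: ContingencyTable
    label: str
    n: float
    ror: float
    ror_ci: tuple[float, float]
    prr: float
    prr_ci: tuple[float, float]
    chi2: float
    expected: float
    rr: float
    ic: float
    ic025: float
    ic025_mc: float | None
    ebgm: float
    ebgm05: float
    shrinkage: bool
    prior: mgps.GammaPoissonPrior | None
    thresholds: SignalThresholds
    flags: dict = field(default_factory=dict)
    is_signal: bool = False

    def _evaluate(self):
        th = self.thresholds
        self.flags = {
            "ror": self.ror_ci[0] > th.ror_ci_lower and self.n >= th.min_cases,
            "prr": self.prr > th.prr and self.chi2 >= th.chi2,
            "ic": self.ic025 > th.ic025,
            "ebgm": self.ebgm05 > th.ebgm05,
        }
        self.is_signal = all(self.flags.values())
        return self

    def to_row(self) -> dict:
        """One screening-table row (n, ROR (CI), PRR (χ²), EBGM (EBGM05), IC (IC025))."""
        return {
            "label": self.label,
            "n": int(self.n),
            "ror": self.ror,
            "ror_lo": self.ror_ci[0],
            "ror_hi": self.ror_ci[1],
            "prr": self.prr,
            "chi2": self.chi2,
            "ebgm": self.ebgm,
            "ebgm05": self.ebgm05,
            "ic": self.ic,
            "ic025": self.ic025,
            "flag_ror": self.flags["ror"],
            "flag_prr": self.flags["prr"],
            "flag_ic": self.flags["ic"],
            "flag_ebgm": self.flags["ebgm"],
            "is_signal": self.is_signal,
        }

    def summary(self) -> str:
        f = self.flags
        mark = {True: "+", False: "-"}
        lines = [
            f"Disproportionality analysis: {self.label}",
            f"  2x2 table (a,b,c,d) = {tuple(round(x, 3) for x in self.table.as_tuple())}",
            f"  n cases          {int(self.n):>12d}",
            f"  ROR (95% CI)     {self.ror:>12.2f}  ({self.ror_ci[0]:.2f}-{self.ror_ci[1]:.2f})   [{mark[f['ror']]}]",
            f"  PRR (chi2)       {self.prr:>12.2f}  ({self.chi2:.2f})   [{mark[f['prr']]}]",
            f"  EBGM (EBGM05)    {self.ebgm:>12.2f}  ({self.ebgm05:.2f})   [{mark[f['ebgm']]}]"
            + ("" if self.shrinkage else "   (unshrunk a/E)"),
            f"  IC (IC025)       {self.ic:>12.2f}  ({self.ic025:.2f})   [{mark[f['ic']]}]",
            f"  joint signal:    {'POSITIVE' if self.is_signal else 'negative'}",
        ]
        return "\n".join(lines)


class DisproportionalityModel:
    """Four-algorithm disproportionality analysis for one drug(-set) × event query.

    Build either from a deduplicated, name-normalized :class:`SRSDataset`
    (cells are counted at report level) or directly from a known 2×2
    table via :meth:`from_table`.
    """

    def __init__(
        self,
        dataset: SRSDataset | None,
        ingredients: Iterable[str] | None = None,
        event_pts: Iterable[str] | None = None,
        roles: Iterable[str] | None = None,
        table: ContingencyTable | None = None,
        label: str | None = None,
    ):
        if (dataset is None) == (table is None):
            raise ValueError("provide either a dataset or a table")
        self.dataset = dataset
        self.ingredients = list(ingredients) if ingredients else None
        self.event_pts = list(event_pts) if event_pts is not None else None
        self.roles = set(roles) if roles is not None else None
        self._table = table
        self.label = label or (
            f"{'+'.join(self.ingredients)} x {'|'.join(self.event_pts or sorted(DEFAULT_EVENT_PTS))}"
            if self.ingredients
            else "2x2 table"
        )

    @classmethod
    def from_table(cls, table: ContingencyTable, label: str = "2x2 table") -> "DisproportionalityModel":
        return cls(None, table=table, label=label)

    def build_table(self) -> ContingencyTable:
        if self._table is not None:
            return self._table
        return build_table(self.dataset, self.ingredients, self.event_pts, self.roles)

    def fit(
        self,
        shrinkage: bool = False,
        prior: mgps.GammaPoissonPrior | None = None,
        ic_variant: str = "raw",
        n_mc: int = 0,
        seed: int | None = None,
        haldane: bool = False,
        thresholds: SignalThresholds = SignalThresholds(),
    ) -> DisproportionalityResults:
        """Compute all four statistics and evaluate the joint criterion.

        By default EBGM is reported in the negligible-shrinkage form a/E
        with its gamma-posterior 5th percentile, and IC as the raw
        log2(a/E); set ``shrinkage=True`` to use the full gamma-Poisson
        mixture posterior (``prior`` fitted from the dataset's complete
        pair list when not supplied) and ``ic_variant="shrunk"`` for the
        +0.5-shrunk IC.
        """
        t = self.build_table()
        ror_est, ror_lo, ror_hi = ror(t, haldane=haldane)
        prr_est, prr_lo, prr_hi, chi2 = prr_chi2(t, haldane=haldane)
        e, rr = expected_count(t)
        icr = information_component(t.a, e, variant=ic_variant, n_mc=n_mc, seed=seed)

        if shrinkage:
            if prior is None:
                if self.dataset is None:
                    raise ValueError("shrinkage without a prior needs a dataset to fit on")
                pairs = all_pair_counts(self.dataset, roles=self.roles)
                prior, _ = mgps.fit_gamma_poisson_prior(pairs["a"], pairs["E"])
            ebgm_est, eb05 = mgps.ebgm(t.a, e, prior)
        else:
            # unshrunk large-count limit: point estimate a/E, lower bound from
            # the Gamma(a, E) posterior under an improper scale prior
            ebgm_est = rr
            shape = t.a if t.a > 0 else 0.5
            eb05 = float(stats.gamma.ppf(0.05, shape, scale=1.0 / e))

        res = DisproportionalityResults(
            table=t,
            label=self.label,
            n=t.a,
            ror=ror_est,
            ror_ci=(ror_lo, ror_hi),
            prr=prr_est,
            prr_ci=(prr_lo, prr_hi),
            chi2=chi2,
            expected=e,
            rr=rr,
            ic=icr.ic,
            ic025=icr.ic025_approx,
            ic025_mc=icr.ic025_mc,
            ebgm=ebgm_est,
            ebgm05=eb05,
            shrinkage=shrinkage,
            prior=prior,
            thresholds=thresholds,
        )
        return res._evaluate()


def all_pair_counts(ds: SRSDataset, roles: Iterable[str] | None = None) -> pd.DataFrame:
    """Observed and expected counts for every (ingredient, event PT) pair.

    The pair list over which the MGPS prior is fitted: one row per
    distinct normalized ingredient × PT combination present in the data,
    with report-level a and E = n_exposed·n_event/N.
    """
    if roles is None:
        roles = ds.default_roles()
    roles = set(roles)
    n_total = ds.n_reports

    d = ds.drugs
    ing = d["ingredient"].where(d["ingredient"].notna(), d["verbatim_name"])
    ing = ing.map(lambda x: normalize_name(x) if pd.notna(x) else None)
    expo = (
        pd.DataFrame({"report_id": d["report_id"], "ingredient": ing})[
            d["role"].isin(roles).values
        ]
        .dropna()
        .drop_duplicates()
    )
    ev = ds.events.copy()
    ev["pt"] = ev["pt"].map(normalize_name)
    ev = ev[["report_id", "pt"]].dropna().drop_duplicates()

    n_exp = expo.groupby("ingredient")["report_id"].nunique()
    n_evt = ev.groupby("pt")["report_id"].nunique()
    joint = (
        expo.merge(ev, on="report_id")
        .groupby(["ingredient", "pt"])["report_id"]
        .nunique()
        .rename("a")
        .reset_index()
    )
    # include zero-count pairs so the prior sees the full pair grid
    grid = pd.MultiIndex.from_product(
        [n_exp.index, n_evt.index], names=["ingredient", "pt"]
    ).to_frame(index=False)
    out = grid.merge(joint, on=["ingredient", "pt"], how="left").fillna({"a": 0})
    out["E"] = out["ingredient"].map(n_exp).astype(float) * out["pt"].map(n_evt).astype(float) / n_total
    return out


def _subset(ds: SRSDataset, report_ids: set) -> SRSDataset:
    cases = ds.cases[ds.cases["report_id"].isin(report_ids)].reset_index(drop=True)
    drugs = ds.drugs[ds.drugs["report_id"].isin(report_ids)].reset_index(drop=True)
    events = ds.events[ds.events["report_id"].isin(report_ids)].reset_index(drop=True)
    return SRSDataset(ds.dialect, cases, drugs, events, dict(ds.parse_warnings))


def _strata(ds: SRSDataset, axis: str, ingredients=None, roles=None) -> dict[str, set]:
    """Partition report_ids along an axis; missing values are excluded."""
    cases = ds.cases
    if axis == "age":
        age = pd.to_numeric(cases["age"], errors="coerce")
        return {
            "<65": set(cases.loc[age.notna() & (age < AGE_CUTOFF), "report_id"]),
            ">=65": set(cases.loc[age.notna() & (age >= AGE_CUTOFF), "report_id"]),
        }
    if axis == "sex":
        return {
            "female": set(cases.loc[cases["sex"] == "female", "report_id"]),
            "male": set(cases.loc[cases["sex"] == "male", "report_id"]),
        }
    if axis == "indication":
        # report-level class from the indications on any of its drug rows;
        # reports without any recorded indication are excluded
        d = ds.drugs[ds.drugs["indication_pt"].notna()]
        is_asthma = d["indication_pt"].map(lambda s: "asthma" in normalize_name(s))
        asthma_ids = set(d.loc[is_asthma.values, "report_id"])
        other_ids = set(d.loc[~is_asthma.values, "report_id"]) - asthma_ids
        return {"asthma": asthma_ids, "others": other_ids}
    raise ValueError(f"unknown stratification axis {axis!r}")


def subgroup_analysis(
    ds: SRSDataset,
    ingredients: Iterable[str],
    event_pts: Iterable[str] | None = None,
    axis: str = "age",
    roles: Iterable[str] | None = None,
    **fit_kwargs,
) -> dict[str, DisproportionalityResults | None]:
    """Fit the full four-algorithm analysis within each stratum.

    Each stratum is treated as its own complete database (all four 2×2
    cells recomputed within it). Strata where the analysis is degenerate
    (no cases, empty margin, zero cell) map to ``None``.
    """
    out: dict[str, DisproportionalityResults | None] = {}
    for level, ids in _strata(ds, axis, ingredients, roles).items():
        sub = _subset(ds, ids)
        try:
            model = DisproportionalityModel(
                sub, ingredients, event_pts, roles, label=f"{axis}={level}"
            )
            out[level] = model.fit(**fit_kwargs)
        except (DegenerateTableError, ZeroCellError):
            out[level] = None
    return out


def comedication_analysis(
    ds: SRSDataset,
    ingredient: str,
    comed: str,
    mode: str = "exclude",
    event_pts: Iterable[str] | None = None,
    roles: Iterable[str] | None = None,
    **fit_kwargs,
) -> DisproportionalityResults:
    """Disproportionality after restricting on a co-medication.

    ``mode="require"`` keeps only reports listing the co-medication (any
    role); ``mode="exclude"`` removes them. The restricted set becomes
    the whole database for the four-algorithm analysis.
    """
    if mode not in ("require", "exclude"):
        raise ValueError("mode must be 'require' or 'exclude'")
    key = normalize_name(comed)
    d = ds.drugs
    names = d["ingredient"].where(d["ingredient"].notna(), d["verbatim_name"])
    names = names.map(lambda x: normalize_name(x) if pd.notna(x) else None)
    comed_ids = set(d.loc[(names == key).values, "report_id"])
    all_ids = set(ds.cases["report_id"])
    keep = comed_ids if mode == "require" else all_ids - comed_ids
    if not keep:
        raise ValueError(f"restriction on {comed!r} ({mode}) leaves an empty database")
    sub = _subset(ds, keep)
    model = DisproportionalityModel(
        sub, [ingredient], event_pts, roles, label=f"{ingredient} | {mode} {comed}"
    )
    return model.fit(**fit_kwargs)


def top_comedications(
    ds: SRSDataset,
    ingredient: str,
    event_pts: Iterable[str] | None = None,
    k: int = 10,
    roles: Iterable[str] | None = None,
) -> list[tuple[str, int]]:
    """Most frequent co-reported drugs among the index drug–event cases.

    Counts distinct reports per co-reported ingredient (any role) within
    the a-cell reports; descending by count, ties broken alphabetically.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    _, _, both = select_reports(ds, [ingredient], roles, event_pts)
    key = normalize_name(ingredient)
    d = ds.drugs[ds.drugs["report_id"].isin(both)]
    names = d["ingredient"].where(d["ingredient"].notna(), d["verbatim_name"])
    names = names.map(lambda x: normalize_name(x) if pd.notna(x) else None)
    pairs = pd.DataFrame({"report_id": d["report_id"], "name": names}).dropna()
    pairs = pairs[pairs["name"] != key].drop_duplicates()
    counts = pairs.groupby("name")["report_id"].nunique()
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:k]
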