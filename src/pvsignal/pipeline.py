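"""End-to-end pipeline runs: ingest → dedup → normalize → signal tables →
time-to-onset → network stage, from one validated config file.

The config is a single YAML document; every stochastic stage takes its
seed from the config, so a run is reproducible bundle-for-bundle. Output
is a directory of CSV/JSON tables shaped like the standard screening
tables (overall, subgroup, co-medication, TTO) plus a machine-readable
manifest recording inputs, seed and row provenance hashes.
"""

from __future__ import annotations

import hashlib
import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .dataset import (
    DEFAULT_EVENT_PTS,
    DrugDictionary,
    default_drug_dictionary,
    deduplicate,
    normalize_drugs,
)
from .disproportionality import (
    DisproportionalityModel,
    comedication_analysis,
    subgroup_analysis,
    top_comedications,
)
from .io import read_srs
from .netpharm import (
    GeneSet,
    enrich,
    intersect,
    load_ppi,
    mcode,
    MCODEParams,
    read_gene_list,
    read_gmt,
    union_targets,
)
from .tto import WeibullTTOModel, compute_tto, tto_histogram

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    dialect: str
    input_dir: str
    output_dir: str
    ingredients: list
    event_pts: list = field(default_factory=lambda: sorted(DEFAULT_EVENT_PTS))
    roles: list | None = None
    drug_dictionary: str | None = None
    subgroup_axes: list = field(default_factory=lambda: ["age", "sex", "indication"])
    comedications: list = field(default_factory=list)  # [{ingredient, mode}]
    top_comeds: int = 10
    tto: bool = True
    shrinkage: bool = False
    netpharm: dict | None = None  # {drug_target_files, disease_gene_file, ppi_file, gmt_file, threshold}
    seed: int = 0

    def __post_init__(self):
        self.validate()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> "PipelineConfig":
        if self.dialect.upper() not in ("FAERS", "JADER", "CVAR", "SYNTHETIC"):
            raise ValueError(f"unknown dialect {self.dialect!r}")
        if not self.ingredients:
            raise ValueError("ingredients must be non-empty")
        if not Path(self.input_dir).exists():
            raise ValueError(f"input_dir does not exist: {self.input_dir}")
        for axis in self.subgroup_axes:
            if axis not in ("age", "sex", "indication"):
                raise ValueError(f"unknown subgroup axis {axis!r}")
        for spec in self.comedications:
            if spec.get("mode") not in ("require", "exclude"):
                raise ValueError(f"co-medication mode must be require/exclude: {spec}")
        if self.drug_dictionary and not Path(self.drug_dictionary).exists():
            raise ValueError(f"drug dictionary not found: {self.drug_dictionary}")
        if self.netpharm:
            for key in ("disease_gene_file", "ppi_file", "gmt_file"):
                p = self.netpharm.get(key)
                if p and not Path(p).exists():
                    raise ValueError(f"netpharm input not found: {p}")
            for p in self.netpharm.get("drug_target_files", []):
                if not Path(p).exists():
                    raise ValueError(f"netpharm input not found: {p}")
        return self


def _hash_df(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path, manifest: dict, stage: str) -> None:
    df.to_csv(path, index=False)
    manifest["outputs"][path.name] = {"stage": stage, "rows": len(df), "sha256_16": _hash_df(df)}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all configured stages; returns the run manifest.

    Any stage failure aborts with :class:`PipelineError` naming the stage,
    and partial outputs are removed.
    """
    cfg.validate()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "pvsignal_version": __version__,
        "seed": cfg.seed,
        "dialect": cfg.dialect.upper(),
        "query": {"ingredients": cfg.ingredients, "event_pts": cfg.event_pts},
        "outputs": {},
    }
    stage = "ingest"
    try:
        ds = read_srs(cfg.input_dir, cfg.dialect)

        stage = "dedup"
        ds, dedup_rep = deduplicate(ds)
        manifest["dedup"] = {
            "cases_removed": dedup_rep.n_cases_removed,
            "drug_rows_removed": dedup_rep.n_drug_rows_removed,
            "event_rows_removed": dedup_rep.n_event_rows_removed,
        }

        stage = "normalize"
        dictionary = (
            DrugDictionary.from_csv(cfg.drug_dictionary)
            if cfg.drug_dictionary
            else default_drug_dictionary()
        )
        ds = normalize_drugs(ds, dictionary)

        stage = "descriptive"
        _write(_descriptive_tables(ds, cfg), outdir / "descriptive.csv", manifest, stage)

        stage = "signal"

        def signal_row(ingredients, label):
            # a pair that cannot be evaluated (no cases / empty margin) is a
            # negative screening row, not a pipeline failure
            try:
                return (
                    DisproportionalityModel(ds, ingredients, cfg.event_pts, cfg.roles, label=label)
                    .fit(shrinkage=cfg.shrinkage)
                    .to_row()
                )
            except ValueError as exc:
                return {"label": label, "n": 0, "is_signal": False, "note": str(exc)}

        rows = [signal_row(cfg.ingredients, "+".join(cfg.ingredients))]
        for ing in cfg.ingredients:
            rows.append(signal_row([ing], ing))
        _write(pd.DataFrame(rows), outdir / "signal_overall.csv", manifest, stage)

        stage = "subgroup"
        sub_rows = []
        for axis in cfg.subgroup_axes:
            results = subgroup_analysis(
                ds, cfg.ingredients, cfg.event_pts, axis, cfg.roles, shrinkage=cfg.shrinkage
            )
            for level, res in results.items():
                row = {"axis": axis, "level": level}
                row.update(res.to_row() if res is not None else {"n": 0, "is_signal": None})
                sub_rows.append(row)
        _write(pd.DataFrame(sub_rows), outdir / "signal_subgroups.csv", manifest, stage)

        stage = "comedication"
        top = top_comedications(ds, cfg.ingredients[0], cfg.event_pts, cfg.top_comeds, cfg.roles)
        _write(
            pd.DataFrame(top, columns=["ingredient", "n_reports"]),
            outdir / "top_comedications.csv",
            manifest,
            stage,
        )
        comed_rows = []
        for spec in cfg.comedications:
            try:
                res = comedication_analysis(
                    ds,
                    cfg.ingredients[0],
                    spec["ingredient"],
                    spec["mode"],
                    cfg.event_pts,
                    cfg.roles,
                    shrinkage=cfg.shrinkage,
                )
                row = {"comedication": spec["ingredient"], "mode": spec["mode"]}
                row.update(res.to_row())
            except ValueError as exc:
                row = {
                    "comedication": spec["ingredient"],
                    "mode": spec["mode"],
                    "n": 0,
                    "is_signal": None,
                    "note": str(exc),
                }
            comed_rows.append(row)
        if comed_rows:
            _write(pd.DataFrame(comed_rows), outdir / "signal_comedications.csv", manifest, stage)

        if cfg.tto:
            stage = "tto"
            try:
                sample = compute_tto(ds, cfg.ingredients, cfg.event_pts, cfg.roles)
                fit = WeibullTTOModel(sample).fit()
                (outdir / "tto_fit.json").write_text(json.dumps(fit.to_row(), indent=1))
                manifest["outputs"]["tto_fit.json"] = {"stage": stage, "rows": 1}
                _write(tto_histogram(sample), outdir / "tto_histogram.csv", manifest, stage)
            except ValueError as exc:
                manifest["tto_skipped"] = str(exc)

        if cfg.netpharm:
            stage = "netpharm"
            np_cfg = cfg.netpharm
            sources = [read_gene_list(p) for p in np_cfg.get("drug_target_files", [])]
            drug_union, _ = union_targets(sources)
            disease = read_gene_list(np_cfg["disease_gene_file"], "disease")
            shared, venn = intersect(drug_union, disease)
            (outdir / "venn.json").write_text(
                json.dumps(
                    {
                        "drug_only": venn.drug_only,
                        "overlap": venn.overlap,
                        "disease_only": venn.disease_only,
                        "overlap_genes": sorted(shared.symbols),
                    },
                    indent=1,
                )
            )
            manifest["outputs"]["venn.json"] = {"stage": stage, "rows": venn.overlap}
            graph = load_ppi(
                np_cfg["ppi_file"], float(np_cfg.get("threshold", 0.4)), genes=shared
            )
            clusters = mcode(graph, MCODEParams())
            cl_rows = [
                {
                    "rank": i + 1,
                    "seed": c.seed,
                    "size": c.size,
                    "score": c.score,
                    "members": ";".join(sorted(c.members)),
                }
                for i, c in enumerate(clusters)
            ]
            _write(pd.DataFrame(cl_rows), outdir / "mcode_clusters.csv", manifest, stage)
            gmt = read_gmt(np_cfg["gmt_file"])
            _write(enrich(shared, gmt), outdir / "enrichment.csv", manifest, stage)

        stage = "manifest"
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        return manifest
    except Exception as exc:  # noqa: BLE001 - abort cleanly with the stage name
        if isinstance(exc, PipelineError):
            raise
        for item in manifest["outputs"]:
            p = outdir / item
            if p.exists():
                p.unlink()
        raise PipelineError(stage, exc) from exc


def _descriptive_tables(ds, cfg: PipelineConfig) -> pd.DataFrame:
    """Case-characteristic counts for the drug × event query (reporting
    year, sex, age band, weight band, reporter, outcome)."""
    from .dataset import select_reports

    _, _, both = select_reports(ds, cfg.ingredients, cfg.roles, cfg.event_pts)
    cases = ds.cases[ds.cases["report_id"].isin(both)]
    rows = []

    def tally(axis: str, series: pd.Series):
        for value, count in series.value_counts(dropna=False).items():
            rows.append({"axis": axis, "level": str(value), "n": int(count)})

    tally("event_year", cases["event_year"])
    tally("sex", cases["sex"])
    age = pd.to_numeric(cases["age"], errors="coerce")
    tally("age_band", pd.cut(age, [0, 18, 65, 200], labels=["<18", "18-65", ">=65"]))
    weight = pd.to_numeric(cases["weight"], errors="coerce")
    tally("weight_band", pd.cut(weight, [0, 50, 500], labels=["<50kg", ">=50kg"]))
    tally("reporter", cases["reporter"])
    tally("outcomes", cases["outcomes"])
    return pd.DataFrame(rows, columns=["axis", "level", "n"])
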