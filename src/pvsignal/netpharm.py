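"""Network-pharmacology stage: target lists, PPI graph, MCODE, enrichment.

Workflow mirroring the usual drug–disease target analysis: union the
per-source drug-target predictions, intersect with the disease gene
list, assemble the interaction network among the overlapping genes from
a STRING-style weighted edge table at a combined-score threshold,
extract dense modules with the MCODE algorithm (Bader & Hogue's seeded
vertex-weighting heuristic), and test the gene sets for annotation-term
enrichment with an upper-tail hypergeometric test under
Benjamini–Hochberg FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSet",
    "union_targets",
    "intersect",
    "VennCounts",
    "load_ppi",
    "write_ppi",
    "MCODEParams",
    "Cluster",
    "mcode",
    "enrich",
    "read_gene_list",
    "read_gmt",
    "write_gmt",
]


def _norm_symbol(s: str) -> str:
    return str(s).strip().upper()


@dataclass(frozen=True)
class GeneSet:
    """Named set of normalized (upper-cased) gene symbols."""

    name: str
    symbols: frozenset
    source: str = ""

    @classmethod
    def from_iterable(cls, name: str, symbols: Iterable[str], source: str = "") -> "GeneSet":
        syms = frozenset(_norm_symbol(s) for s in symbols if str(s).strip())
        if not syms:
            raise ValueError(f"gene set {name!r} is empty after normalization")
        return cls(name, syms, source)

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return _norm_symbol(symbol) in self.symbols


def read_gene_list(path, name: str | None = None) -> GeneSet:
    """One symbol per line; blank lines and '#' comments skipped."""
    path = Path(path)
    symbols = [
        line.strip()
        for line in path.read_text().splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    ]
    return GeneSet.from_iterable(name or path.stem, symbols, source=str(path))


def union_targets(per_source: list[GeneSet]) -> tuple[GeneSet, dict]:
    """Deduplicated union across target sources, with per-symbol provenance."""
    if not per_source:
        raise ValueError("need at least one source gene set")
    provenance: dict[str, set] = {}
    for gs in per_source:
        for s in gs.symbols:
            provenance.setdefault(s, set()).add(gs.name)
    if not provenance:
        raise ValueError("union of target sources is empty")
    union = GeneSet("union", frozenset(provenance), source="+".join(g.name for g in per_source))
    return union, provenance


@dataclass(frozen=True)
class VennCounts:
    drug_only: int
    overlap: int
    disease_only: int


def intersect(drug: GeneSet, disease: GeneSet) -> tuple[GeneSet, VennCounts]:
    """Drug-target × disease-gene overlap with Venn counts."""
    if not drug.symbols or not disease.symbols:
        raise ValueError("both gene sets must be non-empty")
    shared = drug.symbols & disease.symbols
    counts = VennCounts(
        drug_only=len(drug.symbols - disease.symbols),
        overlap=len(shared),
        disease_only=len(disease.symbols - drug.symbols),
    )
    return GeneSet(f"{drug.name}&{disease.name}", frozenset(shared)), counts


def load_ppi(edges, threshold: float = 0.4, genes: GeneSet | None = None) -> nx.Graph:
    """Weighted undirected interaction graph from a STRING-style table.

    ``edges`` may be a TSV/CSV path (columns protein1, protein2,
    combined_score) or an equivalent DataFrame. Integer scores on the
    STRING 0–1000 scale are rescaled to [0, 1]. Edges below ``threshold``
    are dropped; self-loops are dropped; duplicate pairs (either
    orientation) collapse keeping the maximum score. When ``genes`` is
    given the graph is restricted to those symbols (isolated members are
    kept as nodes).
    """
    if isinstance(edges, pd.DataFrame):
        df = edges.copy()
    else:
        sep = "\t" if str(edges).endswith((".tsv", ".txt")) else None
        df = pd.read_csv(edges, sep=sep, engine="python")
    cols = {c.lower(): c for c in df.columns}
    for needed in ("protein1", "protein2", "combined_score"):
        if needed not in cols:
            raise ValueError(f"PPI table missing column {needed!r}")
    out = nx.Graph()
    if genes is not None:
        out.add_nodes_from(sorted(genes.symbols))
    allowed = genes.symbols if genes is not None else None
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        u = _norm_symbol(getattr(row, cols["protein1"]))
        v = _norm_symbol(getattr(row, cols["protein2"]))
        raw = getattr(row, cols["combined_score"])
        try:
            score = float(raw)
        except (TypeError, ValueError):
            raise ValueError(f"PPI table line {lineno}: malformed score {raw!r}")
        if score > 1.0:  # STRING integer dialect
            score = score / 1000.0
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"PPI table line {lineno}: score {score} outside [0, 1]")
        if u == v:
            continue
        if allowed is not None and (u not in allowed or v not in allowed):
            continue
        if score < threshold:
            continue
        if out.has_edge(u, v):
            out[u][v]["combined_score"] = max(out[u][v]["combined_score"], score)
        else:
            out.add_edge(u, v, combined_score=score)
    return out


def write_ppi(graph: nx.Graph, path) -> None:
    rows = [
        {"protein1": min(u, v), "protein2": max(u, v), "combined_score": d["combined_score"]}
        for u, v, d in graph.edges(data=True)
    ]
    df = pd.DataFrame(rows, columns=["protein1", "protein2", "combined_score"])
    df = df.sort_values(["protein1", "protein2"]).reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# MCODE


@dataclass(frozen=True)
class MCODEParams:
    degree_cutoff: int = 2
    node_score_cutoff: float = 0.2
    k_core: int = 2
    haircut: bool = True
    fluff: bool = False
    fluff_density_cutoff: float = 0.2
    max_depth: int = 100

    def __post_init__(self):
        if self.degree_cutoff < 1:
            raise ValueError("degree_cutoff must be >= 1")
        if not 0.0 <= self.node_score_cutoff <= 1.0:
            raise ValueError("node_score_cutoff must lie in [0, 1]")


@dataclass
class Cluster:
    members: frozenset
    seed: str
    score: float

    @property
    def size(self) -> int:
        return len(self.members)


def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def _vertex_weights(g: nx.Graph, params: MCODEParams) -> dict[str, float]:
    """Stage 1: weight each vertex by k × density of the highest k-core of
    its closed neighborhood; vertices below the degree cutoff get 0."""
    weights: dict[str, float] = {}
    for v in g.nodes:
        if g.degree(v) < params.degree_cutoff:
            weights[v] = 0.0
            continue
        nbhd = g.subgraph(set(g.neighbors(v)) | {v})
        core = nx.core_number(nbhd)
        kmax = max(core.values())
        core_nodes = [u for u, k in core.items() if k >= kmax]
        weights[v] = kmax * _density(nbhd.subgraph(core_nodes))
    return weights


def mcode(g: nx.Graph, params: MCODEParams = MCODEParams()) -> list[Cluster]:
    """MCODE dense-module detection, deterministic under node relabelling.

    Stage 2 grows a cluster from each unseen vertex in descending weight
    order, admitting neighbors whose weight is at least
    ``seed_weight × (1 − node_score_cutoff)`` within ``max_depth`` of the
    seed. Stage 3 discards clusters without a 2-core and optionally
    shaves singly-connected vertices (haircut) / adds dense neighborhood
    vertices (fluff). Clusters are scored density × size and sorted
    descending, ties by size then lexicographic seed.
    """
    if g.number_of_nodes() == 0:
        return []
    weights = _vertex_weights(g, params)
    order = sorted(g.nodes, key=lambda v: (-weights[v], str(v)))
    assigned: set = set()
    raw: list[tuple[str, set]] = []
    for seed in order:
        if seed in assigned or weights[seed] <= 0.0:
            continue
        threshold = weights[seed] * (1.0 - params.node_score_cutoff)
        members = {seed}
        frontier = [(seed, 0)]
        while frontier:
            v, depth = frontier.pop(0)
            if depth >= params.max_depth:
                continue
            for u in sorted(g.neighbors(v), key=str):
                if u in members or u in assigned:
                    continue
                if weights[u] >= threshold:
                    members.add(u)
                    frontier.append((u, depth + 1))
        assigned |= members
        raw.append((seed, members))

    clusters: list[Cluster] = []
    for seed, members in raw:
        sub = g.subgraph(members).copy()
        # require a k-core (default 2-core): peel to the k_core shell
        core = nx.k_core(sub, k=params.k_core)
        if core.number_of_nodes() == 0:
            continue
        keep = set(core.nodes)
        if params.haircut:
            changed = True
            while changed:
                changed = False
                for v in sorted(keep):
                    if g.subgraph(keep).degree(v) < 2:
                        keep.discard(v)
                        changed = True
        if not keep:
            continue
        if params.fluff:
            halo = set()
            for v in sorted(keep):
                for u in sorted(g.neighbors(v), key=str):
                    if u in keep or u in halo:
                        continue
                    nbhd = g.subgraph(set(g.neighbors(u)) | {u})
                    if _density(nbhd) > params.fluff_density_cutoff:
                        halo.add(u)
            keep |= halo
        sub = g.subgraph(keep)
        score = _density(sub) * sub.number_of_nodes()
        if score <= 0:
            continue
        cluster_seed = seed if seed in keep else min(keep)
        clusters.append(Cluster(frozenset(keep), cluster_seed, score))

    clusters.sort(key=lambda c: (-c.score, -c.size, str(c.seed)))
    return clusters


# ---------------------------------------------------------------------------
# enrichment


def read_gmt(path) -> dict[str, list]:
    """GMT: term <tab> description <tab> gene1 <tab> gene2 ..."""
    terms: dict[str, list] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        terms[parts[0]] = [_norm_symbol(s) for s in parts[2:] if s.strip()]
    return terms


def write_gmt(terms: Mapping[str, Iterable[str]], path) -> None:
    lines = [
        "\t".join([name, name] + sorted(_norm_symbol(s) for s in members))
        for name, members in terms.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def enrich(
    query: GeneSet,
    annotations: Mapping[str, Iterable[str]],
    universe: GeneSet | None = None,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment with BH FDR across terms.

    The universe defaults to all genes appearing in the annotation
    collection. Query symbols outside the universe are dropped (their
    count is reported in ``df.attrs['n_dropped']``); terms with zero
    overlap are omitted. Rows are sorted by p, ties by term name.
    """
    ann = {name: frozenset(_norm_symbol(s) for s in members) for name, members in annotations.items()}
    if universe is None:
        uni = frozenset().union(*ann.values()) if ann else frozenset()
    else:
        uni = universe.symbols
    if not uni:
        raise ValueError("empty gene universe")
    q = query.symbols & uni
    n_dropped = len(query.symbols) - len(q)
    rows = []
    for name, members in ann.items():
        term = members & uni
        k = len(q & term)
        if k == 0:
            continue
        big_k, n_q, n_u = len(term), len(q), len(uni)
        p = float(stats.hypergeom.sf(k - 1, n_u, big_k, n_q))
        rows.append(
            {"term": name, "k": k, "K": big_k, "n": n_q, "N": n_u, "p": min(p, 1.0)}
        )
    df = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"])
    if len(df):
        df["fdr"] = multipletests(df["p"].values, method="fdr_bh")[1]
        df = df.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)
    else:
        df["fdr"] = pd.Series(dtype=float)
    df.attrs["n_dropped"] = n_dropped
    return df
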