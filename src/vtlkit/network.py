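"""Assembly of the educated signal web.

Nodes are screen-hit genes, each carrying exactly one of seven functional
categories and the subset of behaviours (sleep / locomotor / social) it
regulates.  Edges come from three sources: pairwise LLM-reasoning answers
classified positive (directed *regulations* when the direction of
information flow was curated, undirected *associations* otherwise), and an
overlay of protein-protein / genetic interactions read from PSI-MI TAB
(MITAB) records.  Direction and sign are curated table columns — they are
never parsed out of the free-text answers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import networkx as nx
import pandas as pd

from .llm_eval import classify_reasoning_response

CATEGORIES = (
    "regulator of DNA and chromosome",
    "transcriptional and translational regulation",
    "neurotransmission and synaptic function",
    "calcium and intracellular signaling pathway",
    "metabolism",
    "transport",
    "cytoskeleton organization and other pathway",
)

EDGE_KINDS = ("regulation", "association", "ppi")
SIGNS = ("positive", "negative", "unknown")


@dataclass(frozen=True)
class GeneNode:
    symbol: str
    category: str
    behaviors: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


@dataclass(frozen=True)
class Edge:
    source: str  # for undirected kinds, the lexicographically smaller symbol
    target: str
    kind: str
    sign: str = "unknown"
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.kind not in EDGE_KINDS:
            raise ValueError(f"unknown edge kind {self.kind!r}")
        if self.sign not in SIGNS:
            raise ValueError(f"unknown sign {self.sign!r}")


@dataclass
class SignalWeb:
    nodes: dict[str, GeneNode]
    edges: list[Edge] = field(default_factory=list)

    @property
    def graph(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        for node in self.nodes.values():
            g.add_node(node.symbol, category=node.category, behaviors=",".join(sorted(node.behaviors)))
        for e in self.edges:
            g.add_edge(e.source, e.target, kind=e.kind, sign=e.sign, evidence=e.evidence)
        return g

    def edges_of_kind(self, kind: str) -> list[Edge]:
        return [e for e in self.edges if e.kind == kind]


def pairwise_combinations(genes) -> list[tuple[str, str]]:
    """All n(n-1)/2 unordered gene pairs, lexicographically ordered."""
    genes = list(genes)
    if len(set(genes)) != len(genes):
        dupes = sorted({g for g in genes if genes.count(g) > 1})
        raise ValueError(f"duplicate symbols: {dupes}")
    return list(combinations(sorted(genes), 2))


def read_mitab(path: str | Path, symbol_filter: set[str] | None = None) -> list[tuple[str, str]]:
    """Unique unordered interacting symbol pairs from a PSI-MI TAB 2.5 file.

    Interactor symbols are taken from the alias columns (and alt-id
    columns as fallback); pairs are restricted to ``symbol_filter`` when
    given and self-loops are dropped.  Malformed rows are skipped with a
    warning.
    """
    pairs: set[tuple[str, str]] = set()
    skipped = 0
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 7:
                skipped += 1
                warnings.warn(f"mitab line {lineno}: too few columns, skipped")
                continue
            a = _mitab_symbol(parts, (4, 2, 0), symbol_filter)
            b = _mitab_symbol(parts, (5, 3, 1), symbol_filter)
            if a is None or b is None or a == b:
                continue
            pairs.add((min(a, b), max(a, b)))
    return sorted(pairs)


def _mitab_symbol(parts: list[str], column_order: tuple[int, ...], symbol_filter) -> str | None:
    """First candidate symbol for one interactor, preferring the filter set."""
    candidates: list[str] = []
    for col in column_order:
        if col >= len(parts):
            continue
        for entry in parts[col].split("|"):
            name = entry.split(":", 1)[1] if ":" in entry else entry
            name = name.split("(", 1)[0].strip().strip('"')
            if name and name != "-":
                candidates.append(name)
    if symbol_filter is not None:
        for name in candidates:
            if name in symbol_filter:
                return name
        return None
    return candidates[0] if candidates else None


def build_web(
    nodes: list[GeneNode] | dict[str, GeneNode],
    reasoning_table: pd.DataFrame | None = None,
    ppi_records: list[tuple[str, str]] | None = None,
) -> SignalWeb:
    """Assemble the signal web from reasoning outcomes and a PPI overlay.

    ``reasoning_table`` needs columns ``gene_a``, ``gene_b`` and
    ``response_text`` (classified here) or a precomputed boolean
    ``positive``; optional ``direction`` ("a_to_b" / "b_to_a" / empty),
    ``sign`` and ``evidence``/``pmid`` columns type the resulting edge.
    A positive row with a curated direction becomes a directed regulation;
    without one it becomes an undirected association.  Each positive row
    yields exactly one edge.
    """
    if isinstance(nodes, list):
        nodes = {n.symbol: n for n in nodes}
    web = SignalWeb(nodes=dict(nodes))
    if reasoning_table is not None:
        for idx, row in reasoning_table.iterrows():
            a, b = str(row["gene_a"]), str(row["gene_b"])
            for sym in (a, b):
                if sym not in nodes:
                    raise ValueError(f"reasoning row {idx} references unknown node {sym!r}")
            if "positive" in reasoning_table.columns:
                positive = bool(row["positive"])
            else:
                positive = classify_reasoning_response(str(row["response_text"]))
            if not positive:
                continue
            direction = str(row.get("direction", "") or "")
            sign = str(row.get("sign", "") or "unknown")
            if sign not in SIGNS:
                sign = "unknown"
            evidence = str(row.get("evidence", row.get("pmid", "")) or "")
            if direction in ("a_to_b", "b_to_a"):
                src, dst = (a, b) if direction == "a_to_b" else (b, a)
                web.edges.append(Edge(src, dst, "regulation", sign, evidence))
            else:
                lo, hi = min(a, b), max(a, b)
                web.edges.append(Edge(lo, hi, "association", "unknown", evidence))
    for a, b in ppi_records or []:
        for sym in (a, b):
            if sym not in nodes:
                raise ValueError(f"ppi record references unknown node {sym!r}")
        lo, hi = min(a, b), max(a, b)
        web.edges.append(Edge(lo, hi, "ppi"))
    web.edges.sort(key=lambda e: (e.kind, e.source, e.target, e.sign))
    return web


def literature_support_fraction(reasoning_table: pd.DataFrame) -> float:
    """Fraction of positive reasoned pairs backed by a literature reference.

    A pair is supported when its ``pmid``/``evidence`` field is non-empty.
    """
    if "positive" in reasoning_table.columns:
        positive = reasoning_table["positive"].astype(bool)
    else:
        positive = reasoning_table["response_text"].map(classify_reasoning_response)
    pos = reasoning_table[positive]
    if pos.empty:
        raise ValueError("no positive reasoned pairs")
    col = "pmid" if "pmid" in pos.columns else "evidence"
    supported = pos[col].fillna("").astype(str).str.strip() != ""
    return float(supported.mean())


def web_summary(web: SignalWeb) -> dict:
    """Edge-kind/sign counts and per-category mean reasoned-edge degree."""
    kind_counts = {k: len(web.edges_of_kind(k)) for k in EDGE_KINDS}
    sign_counts: dict[str, int] = {s: 0 for s in SIGNS}
    for e in web.edges:
        if e.kind == "regulation":
            sign_counts[e.sign] += 1
    degree = {sym: 0 for sym in web.nodes}
    for e in web.edges:
        if e.kind in ("regulation", "association"):
            degree[e.source] += 1
            degree[e.target] += 1
    per_category: dict[str, float] = {}
    for cat in CATEGORIES:
        members = [s for s, n in web.nodes.items() if n.category == cat]
        if members:
            per_category[cat] = sum(degree[s] for s in members) / len(members)
    return {
        "edge_kind_counts": kind_counts,
        "regulation_sign_counts": sign_counts,
        "mean_degree_by_category": per_category,
        "n_nodes": len(web.nodes),
    }


def write_web(web: SignalWeb, prefix: str | Path) -> dict[str, Path]:
    """Serialise the web as node/edge TSV tables plus GraphML."""
    prefix = Path(prefix)
    node_path = prefix.with_suffix(".nodes.tsv")
    edge_path = prefix.with_suffix(".edges.tsv")
    graphml_path = prefix.with_suffix(".graphml")
    pd.DataFrame(
        [
            {
                "symbol": n.symbol,
                "category": n.category,
                "behaviors": ",".join(sorted(n.behaviors)),
            }
            for n in sorted(web.nodes.values(), key=lambda n: n.symbol)
        ]
    ).to_csv(node_path, sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "source": e.source,
                "target": e.target,
                "kind": e.kind,
                "sign": e.sign,
                "evidence": e.evidence,
            }
            for e in web.edges
        ]
    ).to_csv(edge_path, sep="\t", index=False)
    nx.write_graphml(web.graph, graphml_path)
    return {"nodes": node_path, "edges": edge_path, "graphml": graphml_path}


def read_node_table(path: str | Path) -> list[GeneNode]:
    """Node TSV: columns symbol, category, behaviors (comma-separated)."""
    df = pd.read_csv(path, sep="\t")
    nodes = []
    for _, row in df.iterrows():
        behaviors = frozenset(
            b for b in str(row.get("behaviors", "") or "").split(",") if b
        )
        nodes.append(GeneNode(str(row["symbol"]), str(row["category"]), behaviors))
    return nodes
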