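"""GO-term enrichment of a gene set against an annotated background.

For a term *g* with
``N`` = genes carrying at least one GO term,
``n`` = genes carrying term *g*,
``M`` = foreground genes carrying at least one GO term, and
``m`` = foreground genes carrying term *g*,
the enrichment ratio is ``E = (m / M) / (n / N)`` and the p-value is the
upper tail of the hypergeometric distribution,
``p = sum_{m'=m}^{n} C(M, m') C(N - M, n - m') / C(N, n)``,
reported only for over-represented terms (E >= 1).  Annotations are used
directly (no ancestor propagation) unless requested, and p-values are raw
by default with optional Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom

GAF_COLUMNS = 17  # GAF 2.x tab-separated columns


@dataclass
class AnnotationMap:
    """gene symbol -> set of GO term ids, with per-term aspect metadata."""

    gene_to_terms: dict[str, set[str]]
    term_aspect: dict[str, str]

    @property
    def n_annotated(self) -> int:
        """N: genes with at least one annotated term."""
        return sum(1 for terms in self.gene_to_terms.values() if terms)

    def term_counts(self) -> dict[str, int]:
        """n per term: genes annotated with that term."""
        counts: dict[str, int] = {}
        for terms in self.gene_to_terms.values():
            for term in terms:
                counts[term] = counts.get(term, 0) + 1
        return counts

    def filter_aspect(self, aspect: str) -> "AnnotationMap":
        """Restrict to one GO aspect (P, F or C)."""
        keep = {t for t, a in self.term_aspect.items() if a == aspect}
        g2t = {g: terms & keep for g, terms in self.gene_to_terms.items()}
        g2t = {g: terms for g, terms in g2t.items() if terms}
        return AnnotationMap(g2t, {t: aspect for t in keep})


class GafParseError(ValueError):
    pass


def read_gaf(path: str | Path) -> AnnotationMap:
    """Read direct annotations from a GAF 2.x file.

    Rows with a NOT qualifier are excluded, duplicates collapse to one
    entry, and the aspect column (P/F/C) is retained for filtering.
    Comment lines start with ``!``.
    """
    gene_to_terms: dict[str, set[str]] = {}
    term_aspect: dict[str, str] = {}
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            parts = line.split("\t")
            if len(parts) < 15:
                raise GafParseError(
                    f"line {lineno}: expected >= 15 tab-separated columns, got {len(parts)}"
                )
            qualifier = parts[3]
            if "NOT" in qualifier.split("|"):
                continue
            symbol = parts[2]
            term = parts[4]
            aspect = parts[8]
            gene_to_terms.setdefault(symbol, set()).add(term)
            term_aspect[term] = aspect
    return AnnotationMap(gene_to_terms, term_aspect)


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    N: int
    n: int
    M: int
    m: int
    e_ratio: float
    p_value: float


def hypergeom_upper_tail(N: int, n: int, M: int, m: int) -> float:
    """P(X >= m) for X = foreground genes among the n term carriers.

    Equivalent to summing ``C(M, m') C(N - M, n - m') / C(N, n)`` for
    ``m' = m .. n``; delegated to scipy's log-space-stable survival
    function so genome-scale counts do not underflow.
    """
    return float(hypergeom.sf(m - 1, N, M, n))


def enrich(
    foreground_genes,
    annotations: AnnotationMap,
    min_e_ratio: float = 1.0,
) -> list[EnrichmentResult]:
    """Per-term enrichment of the foreground against the annotated background.

    Only terms with ``e_ratio >= min_e_ratio`` (over-representation) are
    reported, sorted by ascending p.  Foreground genes without any
    annotation are dropped before computing M.
    """
    fg = {g for g in foreground_genes if annotations.gene_to_terms.get(g)}
    if not fg:
        raise ValueError("no annotated foreground genes")
    N = annotations.n_annotated
    M = len(fg)
    n_per_term = annotations.term_counts()
    m_per_term: dict[str, int] = {}
    for gene in fg:
        for term in annotations.gene_to_terms[gene]:
            m_per_term[term] = m_per_term.get(term, 0) + 1

    results = []
    for term, m in m_per_term.items():
        n = n_per_term[term]
        e_ratio = (m / M) / (n / N)
        if e_ratio < min_e_ratio:
            continue
        p = hypergeom_upper_tail(N, n, M, m)
        results.append(EnrichmentResult(term, N, n, M, m, e_ratio, p))
    results.sort(key=lambda r: (r.p_value, r.term))
    return results


def results_to_frame(results: list[EnrichmentResult], bh_adjust: bool = False) -> pd.DataFrame:
    """Tabulate results; optionally add a Benjamini-Hochberg column."""
    df = pd.DataFrame(
        [
            {
                "term": r.term,
                "m": r.m,
                "n": r.n,
                "M": r.M,
                "N": r.N,
                "e_ratio": r.e_ratio,
                "p_value": r.p_value,
            }
            for r in results
        ]
    )
    if bh_adjust and len(df):
        k = len(df)
        adjusted = (df["p_value"] * k / (df.index + 1)).iloc[::-1].cummin().iloc[::-1]
        df["p_adjusted"] = adjusted.clip(upper=1.0)
    return df
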