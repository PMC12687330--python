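"""GO Biological Process over-representation statistics for gene lists.

Per term: observed overlap with the query, expected overlap under the
hypergeometric null (|query| * |term| / |background|), upper-tail
hypergeometric p, Benjamini-Hochberg FDR across terms, and the two summary
statistics used to rank terms:

* strength = log10(observed / expected)
* signal   = weighted harmonic mean of the observed/expected ratio and
  -log10(FDR)

The exact weights behind the cited "signal" statistic are unpublished; the
default here is equal weights and should be read as an approximation of that
statistic (configurable via ``weights``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass
class GOAnnotation:
    """Term -> gene-set map over a background universe."""

    term_to_genes: dict[str, set[str]]
    background: set[str]
    term_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, genes in self.term_to_genes.items():
            if not genes:
                raise ValueError(f"term {term!r} has an empty gene set")
            stray = genes - self.background
            if stray:
                raise ValueError(
                    f"term {term!r} has genes outside the background: "
                    f"{sorted(stray)[:5]}"
                )

    @classmethod
    def from_table(cls, table: pd.DataFrame,
                   background: set[str] | None = None) -> "GOAnnotation":
        """Build from a 2-column (gene, term) long table.

        The background defaults to all annotated genes.
        """
        gene_col, term_col = table.columns[:2]
        mapping: dict[str, set[str]] = {}
        for term, sub in table.groupby(term_col):
            mapping[str(term)] = set(sub[gene_col].astype(str))
        if background is None:
            background = set(table[gene_col].astype(str))
        return cls(mapping, background)


def translate_orthologs(gene_list: list[str],
                        ortholog_table: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Map source gene ids to their (best-hit) target orthologs.

    Returns the deduplicated, order-preserving list of mapped target ids and
    the list of unmapped source ids.
    """
    if ortholog_table.empty:
        raise ValueError("ortholog table is empty")
    src_col, tgt_col = ortholog_table.columns[:2]
    lut = dict(zip(ortholog_table[src_col].astype(str),
                   ortholog_table[tgt_col].astype(str)))
    mapped: list[str] = []
    seen: set[str] = set()
    unmapped: list[str] = []
    for g in gene_list:
        tgt = lut.get(str(g))
        if tgt is None:
            unmapped.append(str(g))
        elif tgt not in seen:
            seen.add(tgt)
            mapped.append(tgt)
    return mapped, unmapped


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, original order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_upper_tail(observed: int, background_size: int,
                         term_size: int, query_size: int) -> float:
    """P(X >= observed) for X ~ Hypergeom(background, term, query draws)."""
    p = float(hypergeom.sf(observed - 1, background_size, term_size,
                           query_size))
    return min(p, 1.0)


def strength(observed: float, expected: float) -> float:
    """log10(observed / expected); NaN when observed is 0."""
    if expected <= 0:
        raise ValueError("expected must be > 0")
    if observed == 0:
        return float("nan")
    return math.log10(observed / expected)


def signal(observed: float, expected: float, fdr: float,
           weights: tuple[float, float] = (1.0, 1.0)) -> float:
    """Weighted harmonic mean of observed/expected and -log10(FDR).

    FDR = 1 (or any non-positive -log) yields 0.
    """
    if not 0 < fdr <= 1:
        raise ValueError("fdr must be in (0, 1]")
    r = observed / expected
    if r <= 0:
        raise ValueError("observed/expected ratio must be > 0")
    big_l = -math.log10(fdr)
    if big_l <= 0:
        return 0.0
    w1, w2 = weights
    return (w1 + w2) / (w1 / r + w2 / big_l)


def hypergeom_enrichment(query: list[str] | set[str],
                         annotation: GOAnnotation,
                         weights: tuple[float, float] = (1.0, 1.0)) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of every term against a query set.

    Returns one row per term (observed, expected, p_value, fdr, strength,
    signal), sorted by signal descending then p ascending.
    """
    query = set(map(str, query))
    if not query:
        raise ValueError("query gene set is empty")
    stray = query - annotation.background
    if stray:
        raise ValueError(
            f"query genes outside the background: {sorted(stray)[:10]}"
        )
    m_bg = len(annotation.background)
    n_query = len(query)
    rows = []
    for term, genes in annotation.term_to_genes.items():
        k_term = len(genes)
        obs = len(query & genes)
        expected = n_query * k_term / m_bg
        p = hypergeom_upper_tail(obs, m_bg, k_term, n_query)
        rows.append({
            "term": term,
            "label": annotation.term_labels.get(term, term),
            "observed": obs,
            "expected": expected,
            "p_value": p,
        })
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["fdr"] = bh_fdr(out["p_value"].to_numpy())
    out["strength"] = [strength(o, e) for o, e in zip(out["observed"], out["expected"])]
    out["signal"] = [
        signal(o, e, f, weights) if o > 0 else 0.0
        for o, e, f in zip(out["observed"], out["expected"], out["fdr"])
    ]
    return out.sort_values(["signal", "p_value"], ascending=[False, True],
                           kind="mergesort").reset_index(drop=True)
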