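"""Collinear gene-block detection between two genomes from homolog anchors.

Genes are ranked along each chromosome by start coordinate; an *anchor* is a
homologous gene pair carrying a rank on each genome.  Within each chromosome
pair, maximal-scoring chains of anchors with strictly monotone ranks on both
genomes (increasing/increasing = forward, increasing/decreasing = inverted)
are found by dynamic programming.  A chain scores

    n_anchors * match_score + (sum of rank gaps on both genomes) * gap_penalty

where the gap at each step is max(0, rank difference - 1); consecutive
anchors may not be separated by more than ``max_gaps`` ranks on either
genome.  Chains shorter than ``match_size`` anchors are discarded, and each
anchor is reported in at most one block (best chain extracted greedily, the
remainder re-chained).

The default parameters are match_score=50, match_size=5, gap_penalty=0 and
max_gaps=100.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class SyntenyParams:
    match_score: float = 50.0
    match_size: int = 5
    gap_penalty: float = 0.0
    max_gaps: int = 100

    def __post_init__(self) -> None:
        if self.match_size < 1:
            raise ValueError("match_size must be >= 1")
        if self.max_gaps < 0:
            raise ValueError("max_gaps must be >= 0")
        if self.gap_penalty > 0:
            raise ValueError("gap_penalty must be <= 0")


@dataclass
class CollinearBlock:
    """One chain of anchors between a chromosome pair."""

    chrom_a: str
    chrom_b: str
    orientation: str  # "forward" | "inverted"
    anchors: pd.DataFrame  # gene_a, gene_b, rank_a, rank_b (+ coordinates)
    score: float
    span_a: tuple[int, int] = field(default=(0, 0))
    span_b: tuple[int, int] = field(default=(0, 0))

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)


def rank_genes(positions: pd.DataFrame) -> pd.DataFrame:
    """Rank genes 1..n along each chromosome by start (ties: end, then id).

    ``positions`` needs columns ``gene``, ``chrom``, ``start``, ``end``.
    """
    req = {"gene", "chrom", "start", "end"}
    missing = req - set(positions.columns)
    if missing:
        raise ValueError(f"positions table missing columns: {sorted(missing)}")
    if positions["gene"].duplicated().any():
        dups = positions.loc[positions["gene"].duplicated(), "gene"]
        raise ValueError(f"duplicate gene ids: {sorted(set(dups))[:10]}")
    if (positions["start"] > positions["end"]).any():
        raise ValueError("start must be <= end")
    out = positions.sort_values(["chrom", "start", "end", "gene"],
                                kind="mergesort").copy()
    out["rank"] = out.groupby("chrom", sort=False).cumcount() + 1
    return out.reset_index(drop=True)


def _chain_dp(ra: np.ndarray, rb: np.ndarray, params: SyntenyParams
              ) -> tuple[float, list[int]]:
    """Best chain (score, member indices) with strictly increasing ra and rb.

    Anchors are given presorted by (ra, rb).  Gap per step on each axis is
    rank difference - 1, bounded by max_gaps; score = n * match_score +
    gap_penalty * total gaps.  Ties in score prefer the longer chain, then
    the lexicographically earliest.
    """
    n = len(ra)
    score = np.full(n, params.match_score)
    length = np.ones(n, dtype=int)
    parent = np.full(n, -1, dtype=int)
    for i in range(n):
        for j in range(i):
            if ra[j] >= ra[i] or rb[j] >= rb[i]:
                continue
            gap_a = ra[i] - ra[j] - 1
            gap_b = rb[i] - rb[j] - 1
            if gap_a > params.max_gaps or gap_b > params.max_gaps:
                continue
            cand = score[j] + params.match_score + params.gap_penalty * (gap_a + gap_b)
            if cand > score[i] + 1e-12 or (
                abs(cand - score[i]) <= 1e-12 and length[j] + 1 > length[i]
            ):
                score[i] = cand
                length[i] = length[j] + 1
                parent[i] = j
    best = int(np.lexsort((np.arange(n), -length, -score))[0]) if n else -1
    if best < 0:
        return 0.0, []
    chain = []
    i = best
    while i >= 0:
        chain.append(i)
        i = parent[i]
    chain.reverse()
    return float(score[best]), chain


def _extract_blocks_one_pair(sub: pd.DataFrame, chrom_a: str, chrom_b: str,
                             params: SyntenyParams) -> list[CollinearBlock]:
    blocks: list[CollinearBlock] = []
    remaining = sub.reset_index(drop=True)
    while len(remaining) >= params.match_size:
        candidates = []
        for orientation in ("forward", "inverted"):
            rb = remaining["rank_b"].to_numpy()
            rb_eff = rb if orientation == "forward" else -rb
            order = np.lexsort((rb_eff, remaining["rank_a"].to_numpy()))
            ra_s = remaining["rank_a"].to_numpy()[order]
            rb_s = rb_eff[order]
            sc, chain = _chain_dp(ra_s, rb_s, params)
            if len(chain) >= params.match_size:
                candidates.append((sc, len(chain), orientation,
                                   [order[i] for i in chain]))
        if not candidates:
            break
        # best score, then longer, then forward before inverted
        candidates.sort(key=lambda c: (-c[0], -c[1], c[2] != "forward"))
        sc, _, orientation, rows = candidates[0]
        anchors = remaining.iloc[rows].reset_index(drop=True)
        block = CollinearBlock(
            chrom_a=chrom_a, chrom_b=chrom_b, orientation=orientation,
            anchors=anchors, score=sc,
            span_a=(int(anchors["start_a"].min()), int(anchors["end_a"].max()))
            if "start_a" in anchors else (0, 0),
            span_b=(int(anchors["start_b"].min()), int(anchors["end_b"].max()))
            if "start_b" in anchors else (0, 0),
        )
        blocks.append(block)
        remaining = remaining.drop(remaining.index[rows]).reset_index(drop=True)
    return blocks


def _dedup_tandem(anchors: pd.DataFrame) -> pd.DataFrame:
    """Keep one anchor per gene on each side.

    If a ``similarity`` column exists the highest-similarity pair wins;
    otherwise the lexicographically smallest partner.  Deterministic.
    """
    out = anchors.copy()
    for side, partner in (("gene_a", "gene_b"), ("gene_b", "gene_a")):
        if "similarity" in out.columns:
            out = out.sort_values([side, "similarity", partner],
                                  ascending=[True, False, True],
                                  kind="mergesort")
        else:
            out = out.sort_values([side, partner], kind="mergesort")
        out = out.drop_duplicates(subset=side, keep="first")
    return out.reset_index(drop=True)


def find_collinear_blocks(anchors: pd.DataFrame,
                          positions_a: pd.DataFrame,
                          positions_b: pd.DataFrame,
                          params: SyntenyParams | None = None
                          ) -> list[CollinearBlock]:
    """Detect collinear blocks from an anchor table and two position tables.

    ``anchors`` needs columns ``gene_a`` and ``gene_b`` (optionally
    ``similarity``); positions are ranked internally via :func:`rank_genes`.
    """
    params = params or SyntenyParams()
    ranked_a = rank_genes(positions_a).set_index("gene")
    ranked_b = rank_genes(positions_b).set_index("gene")
    missing_a = set(anchors["gene_a"]) - set(ranked_a.index)
    missing_b = set(anchors["gene_b"]) - set(ranked_b.index)
    if missing_a or missing_b:
        raise ValueError(
            f"anchors reference unranked genes: "
            f"{sorted(missing_a | missing_b)[:10]}"
        )
    merged = _dedup_tandem(anchors)
    merged = merged.assign(
        chrom_a=ranked_a.loc[merged["gene_a"], "chrom"].to_numpy(),
        rank_a=ranked_a.loc[merged["gene_a"], "rank"].to_numpy(),
        start_a=ranked_a.loc[merged["gene_a"], "start"].to_numpy(),
        end_a=ranked_a.loc[merged["gene_a"], "end"].to_numpy(),
        chrom_b=ranked_b.loc[merged["gene_b"], "chrom"].to_numpy(),
        rank_b=ranked_b.loc[merged["gene_b"], "rank"].to_numpy(),
        start_b=ranked_b.loc[merged["gene_b"], "start"].to_numpy(),
        end_b=ranked_b.loc[merged["gene_b"], "end"].to_numpy(),
    )
    blocks: list[CollinearBlock] = []
    for (ca, cb), sub in merged.groupby(["chrom_a", "chrom_b"], sort=True):
        blocks.extend(_extract_blocks_one_pair(sub, str(ca), str(cb), params))
    # deterministic report order
    blocks.sort(key=lambda b: (b.chrom_a, b.chrom_b, -b.score,
                               int(b.anchors["rank_a"].iloc[0])))
    for b in blocks:
        _validate_block(b, params)
    return blocks


def _validate_block(block: CollinearBlock, params: SyntenyParams) -> None:
    ra = block.anchors["rank_a"].to_numpy()
    rb = block.anchors["rank_b"].to_numpy()
    assert len(ra) >= params.match_size
    assert (np.diff(ra) > 0).all()
    if block.orientation == "forward":
        assert (np.diff(rb) > 0).all()
        assert (np.diff(rb) - 1 <= params.max_gaps).all()
    else:
        assert (np.diff(rb) < 0).all()
        assert (-np.diff(rb) - 1 <= params.max_gaps).all()
    assert (np.diff(ra) - 1 <= params.max_gaps).all()


def block_summary(blocks: list[CollinearBlock]) -> pd.DataFrame:
    """Per-chromosome-pair totals: blocks, anchor genes (both sides), bp spans."""
    rows = []
    for b in blocks:
        rows.append({
            "chrom_a": b.chrom_a,
            "chrom_b": b.chrom_b,
            "n_blocks": 1,
            "n_anchor_genes": 2 * b.n_anchors,
            "span_a_bp": b.span_a[1] - b.span_a[0] + 1 if b.span_a != (0, 0) else 0,
            "span_b_bp": b.span_b[1] - b.span_b[0] + 1 if b.span_b != (0, 0) else 0,
        })
    if not rows:
        return pd.DataFrame(columns=["chrom_a", "chrom_b", "n_blocks",
                                     "n_anchor_genes", "span_a_bp", "span_b_bp"])
    df = pd.DataFrame(rows)
    return df.groupby(["chrom_a", "chrom_b"], as_index=False).sum()


def write_blocks(blocks: list[CollinearBlock], path) -> None:
    """MCScanX-style collinearity text: block headers + one anchor per line."""
    with open(path, "w") as fh:
        for i, b in enumerate(blocks):
            fh.write(
                f"## block {i}: {b.chrom_a} vs {b.chrom_b} "
                f"orientation={b.orientation} score={b.score:g} "
                f"n_anchors={b.n_anchors}\n"
            )
            for _, row in b.anchors.iterrows():
                fh.write(f"{row['gene_a']}\t{row['gene_b']}\n")
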