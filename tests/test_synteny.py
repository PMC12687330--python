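"""Collinear block detection: ranking, chain DP vs brute force, summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest

from stagedev.synteny import (SyntenyParams, _chain_dp, block_summary,
                              find_collinear_blocks, rank_genes)
from stagedev.simulate import SyntheticSpec, generate_anchors


# ---- ranking ----------------------------------------------------------------

def test_rank_genes_sorts_by_start_per_chromosome():
    pos = pd.DataFrame({
        "gene": ["a", "b", "c", "d"],
        "chrom": ["1", "1", "1", "2"],
        "start": [10, 5, 20, 3],
        "end": [15, 9, 30, 9],
    })
    ranked = rank_genes(pos).set_index("gene")
    assert ranked.loc["a", "rank"] == 2
    assert ranked.loc["b", "rank"] == 1
    assert ranked.loc["c", "rank"] == 3
    assert ranked.loc["d", "rank"] == 1  # chromosomes ranked independently


def test_rank_genes_stable_tie_break_oracle():
    rng = np.random.default_rng(0)
    starts = rng.integers(1, 10, size=20)  # many ties
    ends = starts + rng.integers(1, 5, size=20)
    pos = pd.DataFrame({"gene": [f"g{i:02d}" for i in range(20)],
                        "chrom": "1", "start": starts, "end": ends})
    ranked = rank_genes(pos)
    expected = sorted(pos.to_dict("records"),
                      key=lambda r: (r["start"], r["end"], r["gene"]))
    assert list(ranked["gene"]) == [r["gene"] for r in expected]


def test_rank_genes_duplicate_ids_error():
    pos = pd.DataFrame({"gene": ["a", "a"], "chrom": "1",
                        "start": [1, 5], "end": [2, 6]})
    with pytest.raises(ValueError, match="duplicate"):
        rank_genes(pos)


# ---- block detection --------------------------------------------------------

def _toy_tables(pairs, n=60):
    pos_a = pd.DataFrame({"gene": [f"a{i}" for i in range(1, n + 1)],
                          "chrom": "A1",
                          "start": np.arange(1, n + 1) * 1000,
                          "end": np.arange(1, n + 1) * 1000 + 500})
    pos_b = pd.DataFrame({"gene": [f"b{i}" for i in range(1, n + 1)],
                          "chrom": "B1",
                          "start": np.arange(1, n + 1) * 1000,
                          "end": np.arange(1, n + 1) * 1000 + 500})
    anchors = pd.DataFrame({"gene_a": [f"a{i}" for i, _ in pairs],
                            "gene_b": [f"b{j}" for _, j in pairs]})
    return anchors, pos_a, pos_b


def test_five_consecutive_anchors_score_250():
    anchors, pa, pb = _toy_tables([(i, i) for i in range(1, 6)])
    blocks = find_collinear_blocks(anchors, pa, pb)
    assert len(blocks) == 1
    b = blocks[0]
    assert b.orientation == "forward"
    assert b.n_anchors == 5
    assert b.score == 250.0  # 5 anchors x match_score 50, no gap penalty


def test_four_collinear_anchors_below_match_size_no_block():
    anchors, pa, pb = _toy_tables([(i, i) for i in range(1, 5)])
    assert find_collinear_blocks(anchors, pa, pb) == []


def test_inverted_block_detected_with_decreasing_b_ranks():
    anchors, pa, pb = _toy_tables([(i, 20 - i) for i in range(1, 8)])
    blocks = find_collinear_blocks(anchors, pa, pb)
    assert len(blocks) == 1
    assert blocks[0].orientation == "inverted"
    rb = blocks[0].anchors["rank_b"].to_numpy()
    assert (np.diff(rb) < 0).all()


def test_max_gaps_breaks_chains():
    pairs = [(1, 1), (2, 2), (3, 3), (4, 4), (10, 10)]
    anchors, pa, pb = _toy_tables(pairs)
    params = SyntenyParams(match_size=5, max_gaps=3)
    assert find_collinear_blocks(anchors, pa, pb, params) == []
    params = SyntenyParams(match_size=5, max_gaps=100)
    assert len(find_collinear_blocks(anchors, pa, pb, params)) == 1


def test_gap_penalty_reduces_score():
    pairs = [(1, 1), (2, 2), (3, 3), (4, 4), (8, 8)]
    anchors, pa, pb = _toy_tables(pairs)
    params = SyntenyParams(match_size=5, gap_penalty=-2.0)
    blocks = find_collinear_blocks(anchors, pa, pb, params)
    # 5 * 50 + (-2) * (3 + 3) gaps on both genomes at the last step
    assert blocks[0].score == 250.0 - 2.0 * 6


def test_planted_blocks_recovered_exactly_from_generator():
    spec = SyntheticSpec(seed=3)
    anchors, pa, pb, truth_blocks = generate_anchors(spec)
    blocks = find_collinear_blocks(anchors.drop(columns=["planted"]), pa, pb)
    found = {frozenset(map(tuple, b.anchors[["gene_a", "gene_b"]].to_numpy()))
             for b in blocks}
    planted = {frozenset(b.anchors) for b in truth_blocks}
    assert found == planted
    orientations = {frozenset(b.anchors): b.orientation for b in truth_blocks}
    for b in blocks:
        key = frozenset(map(tuple, b.anchors[["gene_a", "gene_b"]].to_numpy()))
        assert b.orientation == orientations[key]


# ---- DP vs exhaustive enumeration --------------------------------------------

def _brute_force_best(ra, rb, params):
    """Max chain score over all strictly-monotone gap-bounded subsequences."""
    n = len(ra)
    order = np.lexsort((rb, ra))
    ra, rb = np.asarray(ra)[order], np.asarray(rb)[order]
    best = 0.0
    for size in range(1, n + 1):
        for combo in itertools.combinations(range(n), size):
            ok = True
            score = params.match_score
            for u, v in zip(combo[:-1], combo[1:]):
                ga = ra[v] - ra[u] - 1
                gb = rb[v] - rb[u] - 1
                if ra[v] <= ra[u] or rb[v] <= rb[u] \
                        or ga > params.max_gaps or gb > params.max_gaps:
                    ok = False
                    break
                score += params.match_score + params.gap_penalty * (ga + gb)
            if ok:
                best = max(best, score)
    return best


@pytest.mark.parametrize("trial", range(30))
def test_dp_chain_score_matches_exhaustive_enumeration(trial):
    rng = np.random.default_rng(trial)
    n = int(rng.integers(2, 11))
    ra = rng.choice(np.arange(1, 30), size=n, replace=False)
    rb = rng.choice(np.arange(1, 30), size=n, replace=False)
    params = SyntenyParams(
        match_size=1,
        gap_penalty=float(-rng.integers(0, 4)),
        max_gaps=int(rng.integers(2, 30)),
    )
    order = np.lexsort((rb, ra))
    score, chain = _chain_dp(ra[order], rb[order], params)
    assert score == pytest.approx(_brute_force_best(ra, rb, params))
    assert len(chain) >= 1


def test_inversion_symmetry():
    """Reversing genome-B coordinates flips orientation, keeps membership."""
    spec = SyntheticSpec(seed=8)
    anchors, pa, pb, _ = generate_anchors(spec)
    anchors = anchors.drop(columns=["planted"])
    blocks = find_collinear_blocks(anchors, pa, pb)
    pb_rev = pb.copy()
    hi = pb_rev.groupby("chrom")["end"].transform("max") + 1
    start = hi - pb_rev["end"]
    end = hi - pb_rev["start"]
    pb_rev["start"], pb_rev["end"] = start, end
    blocks_rev = find_collinear_blocks(anchors, pa, pb_rev)
    flip = {"forward": "inverted", "inverted": "forward"}
    orig = {frozenset(map(tuple, b.anchors[["gene_a", "gene_b"]].to_numpy())):
            (b.orientation, b.score) for b in blocks}
    new = {frozenset(map(tuple, b.anchors[["gene_a", "gene_b"]].to_numpy())):
           (b.orientation, b.score) for b in blocks_rev}
    assert set(orig) == set(new)
    for key, (ori, sc) in orig.items():
        assert new[key] == (flip[ori], sc)


# ---- summary ----------------------------------------------------------------

def test_block_summary_counts():
    anchors, pa, pb = _toy_tables([(i, i) for i in range(1, 6)])
    blocks = find_collinear_blocks(anchors, pa, pb)
    summ = block_summary(blocks)
    assert len(summ) == 1
    assert summ.loc[0, "n_blocks"] == 1
    assert summ.loc[0, "n_anchor_genes"] == 10  # 5 genes per genome
    assert block_summary([]).empty
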