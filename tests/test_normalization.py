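"""Normalization oracles: GFF lengths, TMM, CPM/TPM, low-expression filter."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from stagedev.normalization import (cpm, filter_low_expression,
                                    gene_lengths_from_gff, tmm_factors, tpm)

GFF = """\
##gff-version 3
chr1\tsrc\tgene\t100\t2000\t.\t+\t.\tID=geneA
chr1\tsrc\tmRNA\t100\t2000\t.\t+\t.\tID=geneA.t1;Parent=geneA
chr1\tsrc\tCDS\t101\t400\t.\t+\t0\tID=geneA.t1.cds;Parent=geneA.t1
chr1\tsrc\tmRNA\t100\t2000\t.\t+\t.\tID=geneA.t2;Parent=geneA
chr1\tsrc\tCDS\t101\t300\t.\t+\t0\tID=geneA.t2.cds1;Parent=geneA.t2
chr1\tsrc\tCDS\t501\t750\t.\t+\t0\tID=geneA.t2.cds2;Parent=geneA.t2
chr1\tsrc\tgene\t3000\t4000\t.\t-\t.\tID=geneB
chr1\tsrc\tmRNA\t3000\t4000\t.\t-\t.\tID=geneB.t1;Parent=geneB
chr1\tsrc\tCDS\t3001\t3100\t.\t-\t0\tID=geneB.t1.cds1;Parent=geneB.t1
chr1\tsrc\tCDS\t3201\t3350\t.\t-\t1\tID=geneB.t1.cds2;Parent=geneB.t1
chr2\tsrc\tgene\t1\t500\t.\t+\t.\tID=geneC
chr2\tsrc\tmRNA\t1\t500\t.\t+\t.\tID=geneC.t1;Parent=geneC
chr2\tsrc\texon\t1\t500\t.\t+\t.\tID=geneC.t1.e1;Parent=geneC.t1
"""


def test_gene_lengths_longest_isoform_and_inclusive_coords(tmp_path):
    """Hand-summed CDS oracle: t1 = 300, t2 = 200+250 = 450 -> geneA = 450;
    geneB = 100 + 150 = 250; geneC has no CDS and is omitted."""
    path = tmp_path / "toy.gff3"
    path.write_text(GFF)
    lengths = gene_lengths_from_gff(path)
    assert lengths["geneA"] == 450
    assert lengths["geneB"] == 250
    assert "geneC" not in lengths.index


# ---- TMM -------------------------------------------------------------------

def test_tmm_identical_and_proportional_columns_give_unit_factors():
    base = pd.DataFrame({"a": [10, 40, 100, 7, 900], "b": [10, 40, 100, 7, 900]})
    f = tmm_factors(base)
    assert np.allclose(f, 1.0)
    doubled = base.assign(b=base["b"] * 2)
    assert np.allclose(tmm_factors(doubled), 1.0)


def test_tmm_scale_invariance():
    """Pure depth scaling of a column leaves factors unchanged.

    Exact for the unweighted estimator; with precision weights the per-gene
    weights are not scale-equivariant (the obs and ref variance terms scale
    differently), so invariance there is only approximate.
    """
    rng = np.random.default_rng(0)
    x = pd.DataFrame(rng.poisson(100, size=(200, 4)),
                     columns=list("abcd"))
    x2 = x.assign(c=x["c"] * 7)  # scaling one column is pure depth
    f1 = tmm_factors(x, weighted=False)
    f2 = tmm_factors(x2, weighted=False)
    assert np.allclose(f1, f2, atol=1e-9)
    assert np.allclose(tmm_factors(x), tmm_factors(x2), atol=1e-2)


def test_tmm_all_zero_sample_errors():
    x = pd.DataFrame({"a": [5, 5], "b": [0, 0]})
    with pytest.raises(ValueError, match="b"):
        tmm_factors(x)


def _tmm_direct(obs, ref, n_o, n_r, lt=0.3, st=0.05):
    """Independent direct evaluation of the trimmed weighted-mean formula."""
    keep = (obs > 0) & (ref > 0)
    o, r = obs[keep].astype(float), ref[keep].astype(float)
    m = np.log2((o / n_o) / (r / n_r))
    a = 0.5 * np.log2((o / n_o) * (r / n_r))
    w = (n_o - o) / (n_o * o) + (n_r - r) / (n_r * r)
    n = len(m)
    lo_l, lo_s = np.floor(n * lt) + 1, np.floor(n * st) + 1
    sel = ((rankdata(m) >= lo_l) & (rankdata(m) <= n + 1 - lo_l)
           & (rankdata(a) >= lo_s) & (rankdata(a) <= n + 1 - lo_s))
    return 2.0 ** (np.sum((1 / w[sel]) * m[sel]) / np.sum(1 / w[sel]))


def _bias_fixture():
    rng = np.random.default_rng(42)
    mu = 10 ** rng.normal(2, 0.5, 40)
    counts = rng.poisson(np.tile(mu[:, None], (1, 4))).astype(int)
    counts[:4, 1] = rng.poisson(mu[:4] * 8)  # 10% of genes 8-fold inflated in s2
    return pd.DataFrame(counts, index=[f"g{i}" for i in range(40)],
                        columns=["s1", "s2", "s3", "s4"])


def test_tmm_matches_direct_formula_on_composition_bias_fixture():
    df = _bias_fixture()
    lib = df.sum().to_numpy(dtype=float)
    f = tmm_factors(df)
    # reference is s1 here (closest-to-mean upper quartile)
    x = df.to_numpy(dtype=float)
    q75 = np.array([np.quantile(x[:, j] / lib[j], 0.75) for j in range(4)])
    ref = int(np.argmin(np.abs(q75 - q75.mean())))
    raw = np.ones(4)
    for j in range(4):
        if j != ref:
            raw[j] = _tmm_direct(x[:, j], x[:, ref], lib[j], lib[ref])
    expected = raw / np.exp(np.mean(np.log(raw)))
    assert np.allclose(f.to_numpy(), expected, rtol=1e-10)


def test_tmm_matches_reference_r_implementation_frozen_values():
    """Cross-check against edgeR::calcNormFactors on the same fixture
    (values computed once with edgeR 4.0.16 and frozen)."""
    f = tmm_factors(_bias_fixture())
    frozen = {"s1": 1.1516561925, "s2": 0.6648681020,
              "s3": 1.1432286098, "s4": 1.1423746861}
    for s, v in frozen.items():
        assert f[s] == pytest.approx(v, abs=5e-9)


def test_tmm_factors_geometric_mean_one():
    f = tmm_factors(_bias_fixture())
    assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-9)


# ---- CPM / TPM -------------------------------------------------------------

def test_cpm_definition_and_hand_oracle():
    counts = pd.DataFrame({"a": [1, 0, 9], "b": [2, 3, 5]})
    lib = pd.Series({"a": 1e6, "b": 10.0})
    c = cpm(counts, lib_sizes=lib)
    assert c.loc[0, "a"] == pytest.approx(1.0)
    assert c.loc[1, "a"] == 0.0
    assert c.loc[1, "b"] == pytest.approx(3 / 10 * 1e6)


def test_tpm_hand_oracle_and_column_sums(toy_counts):
    t = tpm(toy_counts)
    # s1: rates 10/100, 0/200, 90/400 -> (0.1, 0, 0.225); sum 0.325
    assert t.loc["gA", "s1"] == pytest.approx(0.1 / 0.325 * 1e6)
    assert t.loc["gC", "s1"] == pytest.approx(0.225 / 0.325 * 1e6)
    assert np.allclose(t.sum(axis=0), 1e6, rtol=1e-9)


def test_tpm_equal_lengths_proportional_to_counts():
    counts = pd.DataFrame({"a": [10, 30, 60]})
    lengths = pd.Series([77, 77, 77])
    t = tpm(counts, lengths)
    assert np.allclose(t["a"], [1e5, 3e5, 6e5])


def test_tpm_monotone_in_counts():
    counts = pd.DataFrame({"a": [10, 30, 60]})
    lengths = pd.Series([100, 200, 300])
    t1 = tpm(counts, lengths)
    counts2 = counts.copy()
    counts2.loc[0, "a"] = 20
    t2 = tpm(counts2, lengths)
    assert t2.loc[0, "a"] > t1.loc[0, "a"]


# ---- low-expression filter -------------------------------------------------

def test_filter_trivial_cases():
    counts = pd.DataFrame({"a": [0, 100], "b": [0, 100]})
    keep = filter_low_expression(counts, min_cpm=1, min_samples=1)
    assert not keep.iloc[0] and keep.iloc[1]
    assert filter_low_expression(counts, min_cpm=1, min_samples=0).all()
    with pytest.raises(ValueError, match="min_samples"):
        filter_low_expression(counts, min_samples=3)


def test_filter_matches_row_scan_oracle():
    rng = np.random.default_rng(7)
    counts = pd.DataFrame(rng.integers(0, 30, size=(100, 5)),
                          columns=list("abcde"))
    lib = counts.sum(axis=0).astype(float)
    keep = filter_low_expression(counts, min_cpm=800, min_samples=2)
    c = counts.div(lib, axis=1) * 1e6
    for g in counts.index:
        assert keep[g] == (sum(c.loc[g, s] > 800 for s in counts.columns) >= 2)
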