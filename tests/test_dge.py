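"""Replicate-free DGE machinery: ordination, dispersion, exact test, calls."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import binom, nbinom

from stagedev.dge import (DGEThresholds, call_degs, dge_summary,
                          estimate_common_dispersion, exact_test_pvalue,
                          leading_fc_distance, log_fold_change, mds_embed,
                          nb_exact_test, pairwise_stage_dge, select_k)
from stagedev.simulate import SyntheticSpec, generate_counts


# ---- leading log-fold-change distance --------------------------------------

def test_lfc_distance_duplicates_and_symmetry():
    rng = np.random.default_rng(0)
    x = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
    x["d"] = x["a"]
    d = leading_fc_distance(x, top_n=10)
    assert d.loc["a", "d"] == 0.0
    assert np.allclose(d, d.T)
    assert np.allclose(np.diag(d), 0.0)


def test_lfc_distance_hand_sorted_oracle():
    x = pd.DataFrame({
        "s": [0.0, 1.0, 2.0, 3.0, 4.0, 5.0],
        "t": [0.0, 2.0, 0.0, 6.0, 0.0, 5.0],
    })
    # |diffs| = 0,1,2,3,4,0; top 3 -> 4,3,2; RMS = sqrt((16+9+4)/3)
    d = leading_fc_distance(x, top_n=3)
    assert d.loc["s", "t"] == pytest.approx(math.sqrt(29 / 3))
    with pytest.raises(ValueError):
        leading_fc_distance(x, top_n=0)
    with pytest.raises(ValueError):
        leading_fc_distance(x, top_n=7)


# ---- classical MDS ---------------------------------------------------------

def test_mds_three_equidistant_points_two_equal_eigenvalues():
    d = pd.DataFrame(1.0 - np.eye(3), index=list("abc"), columns=list("abc"))
    res = mds_embed(d, d=2)
    assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1], abs=1e-9)


def test_mds_recovers_exact_euclidean_configuration():
    rng = np.random.default_rng(1)
    pts = rng.normal(size=(6, 2))
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    res = mds_embed(pd.DataFrame(d), d=2)
    coords = res.coordinates.to_numpy()
    d2 = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    assert np.allclose(d, d2, atol=1e-6)
    assert res.variance_explained.sum() == pytest.approx(1.0, abs=1e-9)


def test_mds_degenerate_single_sample():
    res = mds_embed(pd.DataFrame([[0.0]], index=["s"], columns=["s"]), d=4)
    assert res.coordinates.shape[0] == 1
    assert np.allclose(res.coordinates.to_numpy(), 0.0)


def test_mds_rejects_asymmetric_input():
    with pytest.raises(ValueError):
        mds_embed(pd.DataFrame([[0, 1], [2, 0]]), d=1)


# ---- k selection -----------------------------------------------------------

def _ordination_from_points(pts):
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    idx = [f"s{i}" for i in range(len(pts))]
    return mds_embed(pd.DataFrame(d, index=idx, columns=idx), d=4)


def test_select_k_three_tight_clouds():
    rng = np.random.default_rng(0)
    centers = np.array([[0, 0], [40, 0], [0, 40]])
    pts = np.vstack([c + rng.normal(0, 1, size=(4, 2)) for c in centers])
    res = select_k(_ordination_from_points(pts), k_max=6)
    assert res.k == 3
    # WSS non-increasing in k
    ks = sorted(res.wss)
    assert all(res.wss[a] >= res.wss[b] - 1e-9 for a, b in zip(ks, ks[1:]))


def test_select_k_silhouette_matches_hand_formula_two_pairs():
    pts = np.array([[0.0, 0], [1, 0], [10, 0], [11, 0]])
    res = select_k(_ordination_from_points(pts), k_max=3)
    assert res.k == 2
    # hand silhouette at k=2: outer points have a=1, b=(10+11)/2=10.5;
    # inner points a=1, b=(9+10)/2=9.5; mean of (b-a)/max(a,b) over the four
    expected = (9.5 / 10.5 + 8.5 / 9.5) / 2.0
    assert res.silhouette[2] == pytest.approx(expected, abs=1e-9)


def test_select_k_two_samples_boundary():
    pts = np.array([[0.0, 0], [5.0, 0]])
    with pytest.warns(UserWarning, match="truncating"):
        res = select_k(_ordination_from_points(pts), k_max=8)
    assert res.k == 1  # silhouette undefined for n=2 beyond k=1


# ---- common dispersion ------------------------------------------------------

def test_dispersion_poisson_limit(replicate_dataset):
    spec, cm, _ = replicate_dataset
    pois = SyntheticSpec(**{**spec.__dict__, "phi": 0.0})
    cm0, _ = generate_counts(pois)
    est = estimate_common_dispersion(cm0.counts, cm0.samples["stage"],
                                     cm0.library_sizes)
    assert est.phi < 0.01


def test_dispersion_recovery_at_study_operating_point(replicate_dataset):
    """phi = 0.36, 5 groups x 2 samples, 2000 genes: within +/-15%."""
    spec, cm, _ = replicate_dataset
    est = estimate_common_dispersion(cm.counts, cm.samples["stage"],
                                     cm.library_sizes)
    assert 0.306 <= est.phi <= 0.414


def test_dispersion_singleton_groups_error(small_dataset):
    _, cm, _ = small_dataset
    groups = pd.Series(range(len(cm.sample_ids)), index=cm.sample_ids)
    with pytest.raises(ValueError, match="within-group"):
        estimate_common_dispersion(cm.counts, groups, cm.library_sizes)


# ---- NB exact test ----------------------------------------------------------

def _enumeration_oracle(ya, yb, phi):
    t = ya + yb
    s = np.arange(t + 1)
    if phi > 1e-8:
        r = 1.0 / phi
        p = r / (r + t / 2.0)
        f = nbinom.pmf(s, r, p) * nbinom.pmf(t - s, r, p)
        f = f / f.sum()
    else:
        f = binom.pmf(s, t, 0.5)
    return min(1.0, 2.0 * min(f[: ya + 1].sum(), f[ya:].sum()))


def test_exact_test_symmetric_mode_p_is_one():
    assert nb_exact_test(5, 5, 0.36, 1e6, 1e6) == 1.0


def test_exact_test_binomial_limit():
    rng = np.random.default_rng(0)
    for _ in range(100):
        t = int(rng.integers(1, 400))
        ya = int(rng.integers(0, t + 1))
        assert nb_exact_test(ya, t - ya, 0.0, 1e6, 1e6) == pytest.approx(
            _enumeration_oracle(ya, t - ya, 0.0), abs=1e-12)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(t=st.integers(1, 200), frac=st.floats(0, 1),
       phi=st.one_of(st.just(0.0), st.floats(1e-6, 1)))
def test_exact_test_equals_enumeration_property(t, frac, phi):
    ya = int(round(frac * t))
    p = exact_test_pvalue(ya, t - ya, phi)
    assert p == pytest.approx(_enumeration_oracle(ya, t - ya, phi), abs=1e-12)
    assert 0 < p <= 1


@settings(max_examples=50, deadline=None, derandomize=True)
@given(ya=st.integers(0, 150), yb=st.integers(0, 150),
       phi=st.one_of(st.just(0.0), st.floats(1e-6, 1)))
def test_exact_test_label_swap_invariance(ya, yb, phi):
    assert exact_test_pvalue(ya, yb, phi) == pytest.approx(
        exact_test_pvalue(yb, ya, phi), abs=1e-12)


def test_exact_test_input_guards():
    with pytest.raises(ValueError):
        nb_exact_test(-1, 5, 0.1, 1e6, 1e6)
    with pytest.raises(ValueError):
        nb_exact_test(1, 5, -0.1, 1e6, 1e6)
    with pytest.raises(ValueError):
        nb_exact_test(1, 5, 0.1, 0, 1e6)


# ---- log fold change --------------------------------------------------------

def test_lfc_zero_antisymmetry_and_hand_value():
    assert log_fold_change(10, 10, 1e6, 1e6) == 0.0
    assert log_fold_change(30, 10, 1e6, 1e6) == pytest.approx(
        -log_fold_change(10, 30, 1e6, 1e6))
    # equal libs, prior 0.5: log2(30.5/10.5)
    assert log_fold_change(30, 10, 1e6, 1e6, 0.5) == pytest.approx(
        math.log2(30.5 / 10.5))
    with pytest.raises(ValueError):
        log_fold_change(1, 1, 0, 1e6)


# ---- DEG calling ------------------------------------------------------------

def test_call_degs_boundary_rules():
    table = pd.DataFrame({
        "log2fc": [math.log2(3.0), math.log2(2.9), -math.log2(5.0)],
        "p_value": [0.0005, 1e-9, 0.001],
    })
    out = call_degs(table, DGEThresholds())
    # fold exactly 3 with p<0.001 -> DEG (inclusive on fold)
    assert bool(out["is_deg"].iloc[0])
    # fold 2.9 fails no matter how small p
    assert not bool(out["is_deg"].iloc[1])
    # p not strictly < 0.001 fails
    assert not bool(out["is_deg"].iloc[2])


def test_thresholds_validation():
    with pytest.raises(ValueError):
        DGEThresholds(fold_threshold=0.5)
    with pytest.raises(ValueError):
        DGEThresholds(p_threshold=1.5)


# ---- pairwise sequential-stage DGE ------------------------------------------

def test_nine_stages_give_eight_comparisons(small_dataset):
    _, cm, _ = small_dataset
    res = pairwise_stage_dge(cm, phi=0.36)
    assert len(res) == 8
    summary = dge_summary(res)
    assert list(summary["comparison"])[:2] == ["1-5", "5-8"]


def test_planted_strong_degs_recovered_at_low_dispersion():
    """With a mild dispersion, strongly planted fold changes are recovered."""
    spec = SyntheticSpec(n_genes=800, phi=0.05, seed=21, deg_fraction=0.05,
                         deg_fold_min=8.0, deg_fold_margin_log10=(0.0, 0.0),
                         archetype_fraction=0.0, orphan_fraction=0.0,
                         baseline_log10_mean=2.0, baseline_log10_sd=0.3)
    cm, truth = generate_counts(spec)
    res = pairwise_stage_dge(cm, phi=0.05)
    found = {(r.stage_a, r.stage_b): set(r.table.index[r.table["is_deg"]])
             for r in res}
    hits = sum(row.gene in found.get((row.stage_a, row.stage_b), set())
               for row in truth.deg_truth.itertuples())
    assert hits / len(truth.deg_truth) >= 0.9
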