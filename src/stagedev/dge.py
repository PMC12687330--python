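"""Replicate-free differential expression between sequential embryonic stages.

The study design has one single-embryo library per stage and no biological
replicates, so a per-gene variance cannot be estimated the usual way.  The
procedure implemented here instead:

1. ordinates samples by the leading log-fold-change distance and classical
   multidimensional scaling (MDS);
2. clusters samples on the leading MDS axes with k-means, choosing k by
   silhouette over a WSS/silhouette scan — these clusters act as
   *pseudo-replicate groups* of developmentally adjacent stages;
3. estimates a single common negative-binomial dispersion phi
   (variance = mu + phi * mu^2) by conditional maximum likelihood over the
   pseudo-groups, on counts quantile-adjusted to a common library size;
4. tests each gene between each pair of *sequential stages* (not the groups)
   with the NB exact test conditional on the two-sample total, at the fixed
   global dispersion; and
5. flags genes as differentially expressed when |fold| >= 3 and p < 0.001.

The exact test enumerates the conditional split distribution exactly and
applies the double-tail rule (twice the smaller tail, capped at 1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import nbinom, poisson
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score, silhouette_samples


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    distance_matrix: pd.DataFrame
    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    variance_explained: np.ndarray


@dataclass
class KSelectionResult:
    k: int
    wss: dict[int, float]
    silhouette: dict[int, float]
    groups: pd.Series
    axes_used: int


@dataclass
class DispersionEstimate:
    phi: float
    groups: pd.Series
    log_likelihood: float

    @property
    def bcv(self) -> float:
        """Biological coefficient of variation, sqrt(phi)."""
        return math.sqrt(self.phi)


@dataclass
class DGEThresholds:
    """DEG call thresholds: |fold| >= fold_threshold and p < p_threshold."""

    fold_threshold: float = 3.0
    p_threshold: float = 0.001
    prior_count: float = 0.5

    def __post_init__(self) -> None:
        if self.fold_threshold < 1:
            raise ValueError("fold_threshold must be >= 1")
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must be in (0, 1)")
        if self.prior_count < 0:
            raise ValueError("prior_count must be >= 0")


@dataclass
class PairwiseDGEResult:
    stage_a: str
    stage_b: str
    table: pd.DataFrame  # columns: log2fc, p_value, is_deg
    n_deg: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_deg = int(self.table["is_deg"].sum())


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------

def leading_fc_distance(log_expr: pd.DataFrame, top_n: int = 500) -> pd.DataFrame:
    """Leading log-fold-change distance between samples.

    For each sample pair the distance is the root mean square of the
    ``top_n`` largest absolute log2 differences across genes.  Input is
    log-scale expression (e.g. log2(CPM + 0.5)).
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if top_n > log_expr.shape[0]:
        raise ValueError(
            f"top_n={top_n} exceeds the number of genes {log_expr.shape[0]}"
        )
    x = log_expr.to_numpy(dtype=float)
    n = x.shape[1]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diff2 = (x[:, i] - x[:, j]) ** 2
            top = np.partition(diff2, diff2.size - top_n)[-top_n:]
            d[i, j] = d[j, i] = math.sqrt(top.mean())
    return pd.DataFrame(d, index=log_expr.columns, columns=log_expr.columns)


def mds_embed(distance_matrix: pd.DataFrame, d: int = 4) -> OrdinationResult:
    """Classical (Torgerson) MDS: double-center squared distances, eigendecompose."""
    dm = distance_matrix.to_numpy(dtype=float)
    if dm.shape[0] != dm.shape[1] or not np.allclose(dm, dm.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    n = dm.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dm ** 2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(1e-12, 1e-12 * abs(evals[0])) if n > 1 else evals > 0
    n_pos = int(pos.sum())
    d_eff = min(d, n_pos) if n_pos else min(d, 1)
    with np.errstate(invalid="ignore"):
        coords = evecs[:, :d_eff] * np.sqrt(np.clip(evals[:d_eff], 0, None))
    total_pos = evals[pos].sum() if n_pos else 1.0
    var_exp = (np.clip(evals[:d_eff], 0, None) / total_pos) if total_pos > 0 \
        else np.zeros(d_eff)
    return OrdinationResult(
        distance_matrix=distance_matrix,
        coordinates=pd.DataFrame(
            coords, index=distance_matrix.index,
            columns=[f"axis{i + 1}" for i in range(d_eff)],
        ),
        eigenvalues=evals,
        variance_explained=var_exp,
    )


def select_k(ordination: OrdinationResult, k_min: int = 1, k_max: int = 8,
             var_target: float = 0.95, seed: int = 0,
             n_restarts: int = 50) -> KSelectionResult:
    """Scan k-means over the leading MDS axes; pick k by max silhouette.

    The smallest leading set of axes whose variance explained reaches
    ``var_target`` is retained.  WSS is reported for every k; the silhouette
    is defined for 2 <= k <= n_samples - 1 and the chosen k maximizes it
    (ties to the smaller k).  If only k=1 is scannable, k=1 is returned.
    """
    coords = ordination.coordinates.to_numpy(dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    cum = np.cumsum(ordination.variance_explained)
    n_axes = int(np.searchsorted(cum, var_target) + 1)
    n_axes = min(max(n_axes, 1), coords.shape[1])
    x = coords[:, :n_axes]
    if k_max >= n:
        warnings.warn(
            f"k_max={k_max} >= n_samples={n}; truncating to {n - 1}",
            stacklevel=2,
        )
        k_max = n - 1
    k_max = max(k_max, k_min)
    wss: dict[int, float] = {}
    sil: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in range(k_min, k_max + 1):
        if k == 1:
            wss[1] = float(((x - x.mean(axis=0)) ** 2).sum())
            labels_by_k[1] = np.zeros(n, dtype=int)
            continue
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        labels = km.fit_predict(x)
        wss[k] = float(km.inertia_)
        labels_by_k[k] = labels
        if 2 <= k <= n - 1 and len(np.unique(labels)) > 1:
            sil[k] = float(silhouette_score(x, labels))
    if sil:
        best = max(sil.values())
        k_best = min(k for k, s in sil.items() if s == best)
    else:
        k_best = k_min
    groups = pd.Series(labels_by_k[k_best], index=ordination.coordinates.index,
                       name="group")
    return KSelectionResult(k=k_best, wss=wss, silhouette=sil, groups=groups,
                            axes_used=n_axes)


def silhouette_values(x: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-point silhouette (b - a) / max(a, b); thin wrapper for reuse in reports."""
    return silhouette_samples(x, labels)


# ---------------------------------------------------------------------------
# library-size equalization (quantile adjustment)
# ---------------------------------------------------------------------------

def _nb_cdf(k: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    k = np.asarray(k, dtype=float)
    out = np.zeros(np.broadcast(k, mu).shape)
    valid = k >= 0
    if phi > 0:
        r = 1.0 / phi
        p = r / (r + np.maximum(mu, 1e-300))
        out[valid] = nbinom.cdf(np.floor(k[valid]), r, np.broadcast_to(p, k.shape)[valid])
    else:
        out[valid] = poisson.cdf(np.floor(k[valid]), np.broadcast_to(mu, k.shape)[valid])
    return out


def equalize_library_sizes(counts: pd.DataFrame, lib_sizes: pd.Series,
                           phi: float) -> tuple[pd.DataFrame, float]:
    """Quantile-adjust counts to the geometric-mean library size.

    Each count is mapped through the NB cumulative distribution at its
    observed library size (mid-probability between the integer CDF steps)
    and back through the quantile function at the common library size, with
    linear interpolation between integer quantiles.  Returns continuous
    pseudo-counts and the common library size.
    """
    lib = lib_sizes.loc[counts.columns].to_numpy(dtype=float)
    common = float(np.exp(np.mean(np.log(lib))))
    totals = counts.sum(axis=1).to_numpy(dtype=float)
    prop = totals / lib.sum()
    pseudo = np.empty(counts.shape, dtype=float)
    y_all = counts.to_numpy(dtype=float)
    for j in range(counts.shape[1]):
        y = y_all[:, j]
        if abs(lib[j] - common) <= 1e-9 * common:
            pseudo[:, j] = y
            continue
        mu_in = lib[j] * prop
        mu_out = common * prop
        scale = np.where(mu_in > 0, mu_out / np.maximum(mu_in, 1e-300), 1.0)
        u = 0.5 * (_nb_cdf(y - 1, mu_in, phi) + _nb_cdf(y, mu_in, phi))
        u = np.clip(u, 1e-14, 1 - 1e-14)
        if phi > 0:
            r = 1.0 / phi
            p_out = r / (r + np.maximum(mu_out, 1e-300))
            k = nbinom.ppf(u, r, p_out)
        else:
            k = poisson.ppf(u, np.maximum(mu_out, 1e-300))
        c1 = _nb_cdf(k, mu_out, phi)
        c0 = _nb_cdf(k - 1, mu_out, phi)
        denom = c1 - c0
        with np.errstate(invalid="ignore", divide="ignore"):
            interp = (k - 1) + (u - c0) / denom
        ok = np.isfinite(interp) & (denom > 1e-12) & (mu_in > 0)
        pseudo[:, j] = np.where(ok, np.maximum(interp, 0.0), y * scale)
        pseudo[y == 0, j] = 0.0
    return pd.DataFrame(pseudo, index=counts.index, columns=counts.columns), common


# ---------------------------------------------------------------------------
# common dispersion by conditional maximum likelihood
# ---------------------------------------------------------------------------

def _conditional_loglik(pseudo: np.ndarray, group_idx: list[np.ndarray],
                        phi: float) -> float:
    """Sum over genes and pseudo-groups of the NB conditional log-likelihood.

    For a group of n samples with (pseudo-)counts y_1..y_n and total z, the
    likelihood conditional on z under iid NB(mu, phi) with r = 1/phi is

        sum_j lgamma(y_j + r) - n lgamma(r) + lgamma(n r) - lgamma(z + n r)

    up to terms free of phi.  Groups with a single sample carry no
    within-group information and contribute nothing.
    """
    r = 1.0 / phi
    total = 0.0
    for idx in group_idx:
        n_k = len(idx)
        if n_k < 2:
            continue
        y = pseudo[:, idx]
        z = y.sum(axis=1)
        total += float(
            np.sum(gammaln(y + r)) - y.size / y.shape[1] * n_k * gammaln(r)
            + np.sum(gammaln(n_k * r) - gammaln(z + n_k * r))
        )
    return total


def _golden_max(f, lo: float, hi: float, tol: float = 1e-4) -> tuple[float, float]:
    """Golden-section maximization of f on [lo, hi]."""
    gr = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - gr * (b - a)
    d = a + gr * (b - a)
    fc, fd = f(c), f(d)
    while abs(b - a) > tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - gr * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + gr * (b - a)
            fd = f(d)
    x = (a + b) / 2.0
    return x, f(x)


def estimate_common_dispersion(counts: pd.DataFrame | "object",
                               groups: pd.Series | dict,
                               lib_sizes: pd.Series | None = None,
                               phi_bounds: tuple[float, float] = (1e-6, 20.0),
                               tol: float = 1e-4,
                               n_passes: int = 2) -> DispersionEstimate:
    """Estimate a single NB dispersion shared by all genes.

    Counts are quantile-adjusted to the geometric-mean library size (using the
    current dispersion estimate, iterated ``n_passes`` times starting from
    0.01) and the conditional log-likelihood over the pseudo-replicate groups
    is maximized by golden section on log(phi).
    """
    from .containers import CountMatrix

    if isinstance(counts, CountMatrix):
        if lib_sizes is None:
            lib_sizes = counts.library_sizes
        counts = counts.counts
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0).astype(float)
    groups = pd.Series(groups)
    groups = groups.loc[counts.columns]
    sizes = groups.value_counts()
    if (sizes < 2).all():
        raise ValueError("no within-group information: all groups are singletons")
    cols = list(counts.columns)
    group_idx = [
        np.array([cols.index(s) for s in groups.index[groups == g]])
        for g in sizes.index
    ]
    phi = 0.01
    lo, hi = (math.log(phi_bounds[0]), math.log(phi_bounds[1]))
    best_ll = -math.inf
    for _ in range(max(n_passes, 1)):
        pseudo, _ = equalize_library_sizes(counts, lib_sizes, phi)
        arr = pseudo.to_numpy(dtype=float)

        def nll(log_phi: float) -> float:
            return _conditional_loglik(arr, group_idx, math.exp(log_phi))

        log_phi, best_ll = _golden_max(nll, lo, hi, tol=tol)
        phi = math.exp(log_phi)
    return DispersionEstimate(phi=float(phi), groups=groups,
                              log_likelihood=float(best_ll))


# ---------------------------------------------------------------------------
# NB exact test
# ---------------------------------------------------------------------------

def _cond_split_logpmf(t: int, n_a: float, n_b: float, phi: float) -> np.ndarray:
    """Log pmf (unnormalized) of the group-A total s = 0..t conditional on t.

    Group sums of iid NB(mu, phi) samples are NB with shape n * r; the
    conditional split distribution is the normalized product of the two group
    pmfs.  phi = 0 is the Poisson limit, a Binomial(t, n_a / (n_a + n_b))
    split.
    """
    s = np.arange(t + 1, dtype=float)
    # below ~1e-10 the NB shape overflows lgamma; the Poisson/binomial limit
    # is exact to double precision there
    if phi > 1e-10:
        r = 1.0 / phi
        sa, sb = n_a * r, n_b * r
        return (
            gammaln(s + sa) - gammaln(s + 1.0) - gammaln(sa)
            + gammaln(t - s + sb) - gammaln(t - s + 1.0) - gammaln(sb)
        )
    p = n_a / (n_a + n_b)
    return (
        gammaln(t + 1.0) - gammaln(s + 1.0) - gammaln(t - s + 1.0)
        + s * math.log(p) + (t - s) * math.log(1.0 - p)
    )


def exact_test_pvalue(sum_a: float, sum_b: float, phi: float,
                      n_a: int = 1, n_b: int = 1) -> float:
    """Double-tail exact p for an observed split of equal-library group sums."""
    t = int(round(sum_a + sum_b))
    if t == 0:
        return 1.0
    obs = int(round(sum_a))
    obs = min(max(obs, 0), t)
    logp = _cond_split_logpmf(t, n_a, n_b, phi)
    logp -= logp.max()
    pmf = np.exp(logp)
    pmf /= pmf.sum()
    left = float(pmf[: obs + 1].sum())
    right = float(pmf[obs:].sum())
    return min(1.0, 2.0 * min(left, right))


def nb_exact_test(y_a: float, y_b: float, phi: float,
                  lib_a: float, lib_b: float) -> float:
    """NB exact test for one gene between two libraries at fixed dispersion.

    Unequal library sizes are first equalized by quantile adjustment to the
    geometric mean; the test then conditions on the total and sums the two
    tails of the conditional split distribution (double-tail rule).
    """
    if y_a < 0 or y_b < 0:
        raise ValueError("counts must be non-negative")
    if phi < 0:
        raise ValueError("phi must be >= 0")
    if lib_a <= 0 or lib_b <= 0:
        raise ValueError("library sizes must be positive")
    if abs(lib_a - lib_b) > 1e-9 * max(lib_a, lib_b):
        counts = pd.DataFrame({"a": [y_a], "b": [y_b]})
        libs = pd.Series({"a": float(lib_a), "b": float(lib_b)})
        pseudo, _ = equalize_library_sizes(counts, libs, phi)
        y_a = float(np.round(pseudo.iloc[0, 0]))
        y_b = float(np.round(pseudo.iloc[0, 1]))
    return exact_test_pvalue(y_a, y_b, phi)


def log_fold_change(y_a: float, y_b: float, lib_a: float, lib_b: float,
                    prior_count: float = 0.5) -> float:
    """Moderated log2 fold change of A over B with a library-scaled prior count."""
    if lib_a <= 0 or lib_b <= 0:
        raise ValueError("library sizes must be positive")
    mean_lib = 0.5 * (lib_a + lib_b)
    pa = prior_count * lib_a / mean_lib
    pb = prior_count * lib_b / mean_lib
    return math.log2((y_a + pa) / lib_a) - math.log2((y_b + pb) / lib_b)


def call_degs(table: pd.DataFrame,
              thresholds: DGEThresholds | None = None) -> pd.DataFrame:
    """Flag DEGs: |fold| >= fold_threshold (inclusive) and p < p_threshold (strict)."""
    thresholds = thresholds or DGEThresholds()
    out = table.copy()
    lfc_cut = math.log2(thresholds.fold_threshold)
    out["is_deg"] = (np.abs(out["log2fc"]) >= lfc_cut - 1e-12) & \
        (out["p_value"] < thresholds.p_threshold)
    return out


# ---------------------------------------------------------------------------
# pairwise sequential-stage DGE
# ---------------------------------------------------------------------------

def _pair_pvalues(sum_a: np.ndarray, sum_b: np.ndarray, phi: float,
                  n_a: int, n_b: int) -> np.ndarray:
    out = np.empty(sum_a.shape[0])
    for g in range(sum_a.shape[0]):
        out[g] = exact_test_pvalue(sum_a[g], sum_b[g], phi, n_a, n_b)
    return out


def pairwise_stage_dge(counts, phi: float,
                       thresholds: DGEThresholds | None = None,
                       stage_order: list[str] | None = None,
                       embryonic_only: bool = True,
                       lib_sizes: pd.Series | None = None
                       ) -> list[PairwiseDGEResult]:
    """Exact tests between each pair of sequential stages at a fixed global phi.

    ``counts`` is a :class:`~stagedev.containers.CountMatrix`.  All libraries
    (pass TMM-effective sizes via ``lib_sizes`` to correct composition bias)
    are first equalized to the common (geometric-mean) size, then each
    adjacent stage pair is tested gene by gene.
    """
    thresholds = thresholds or DGEThresholds()
    if stage_order is None:
        stage_order = counts.embryonic_stage_order() if embryonic_only \
            else list(counts.stage_order)
    for stage in stage_order:
        if not counts.samples_for_stage(stage):
            raise ValueError(f"stage {stage!r} has no samples")
    sample_ids = [s for stage in stage_order for s in counts.samples_for_stage(stage)]
    sub = counts.subset_samples(sample_ids)
    libs = sub.library_sizes if lib_sizes is None else lib_sizes.loc[sample_ids]
    pseudo, common = equalize_library_sizes(sub.counts, libs, phi)
    results: list[PairwiseDGEResult] = []
    for st_a, st_b in zip(stage_order[:-1], stage_order[1:]):
        cols_a = sub.samples_for_stage(st_a)
        cols_b = sub.samples_for_stage(st_b)
        sum_a = np.round(pseudo[cols_a].sum(axis=1).to_numpy())
        sum_b = np.round(pseudo[cols_b].sum(axis=1).to_numpy())
        pvals = _pair_pvalues(sum_a, sum_b, phi, len(cols_a), len(cols_b))
        lfc = np.array([
            log_fold_change(
                sum_b[g], sum_a[g],
                common * len(cols_b), common * len(cols_a),
                thresholds.prior_count,
            )
            for g in range(len(sum_a))
        ])
        table = pd.DataFrame(
            {"log2fc": lfc, "p_value": pvals}, index=counts.gene_ids
        )
        table = call_degs(table, thresholds)
        results.append(PairwiseDGEResult(stage_a=st_a, stage_b=st_b, table=table))
    return results


def dge_summary(results: list[PairwiseDGEResult]) -> pd.DataFrame:
    """Per-comparison DEG counts (the bar-chart table of the analysis)."""
    return pd.DataFrame(
        [{"comparison": f"{r.stage_a}-{r.stage_b}", "stage_a": r.stage_a,
          "stage_b": r.stage_b, "n_deg": r.n_deg} for r in results]
    )
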