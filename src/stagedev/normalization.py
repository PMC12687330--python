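"""Library-size and gene-length normalization.

Implements trimmed-mean-of-M-values (TMM) between-sample scaling factors,
counts-per-million (CPM) and transcripts-per-million (TPM) transforms, a
low-expression filter, and CDS-length extraction from GFF3 (length of the
isoform whose summed CDS is longest).

TMM follows the published recipe: per gene, the log2 ratio of library-size-
normalized counts against a reference sample (M) and the average log2
abundance (A) are computed over genes expressed in both samples; the most
extreme 30% of M values and 5% of A values are trimmed symmetrically, and the
remaining M values are averaged with inverse asymptotic binomial-variance
weights.  Factors are rescaled so their geometric mean is 1, so they only
redistribute — never change — total depth.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import CountMatrix

log = logging.getLogger(__name__)


@dataclass
class NormalizedMatrix:
    """CPM/TPM matrices plus the TMM factors that produced them."""

    cpm: pd.DataFrame
    tpm: pd.DataFrame | None
    tmm_factors: pd.Series
    effective_lib_sizes: pd.Series


# ---------------------------------------------------------------------------
# gene lengths from GFF3
# ---------------------------------------------------------------------------

def gene_lengths_from_gff(gff3_path: str | Path) -> pd.Series:
    """Per-gene CDS length (bp) of the isoform maximizing summed CDS length.

    GFF3 coordinates are 1-based inclusive, so each CDS segment contributes
    ``end - start + 1``.  Genes without any CDS are omitted (and logged).
    """
    import gffutils

    db = gffutils.create_db(
        str(gff3_path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    lengths: dict[str, int] = {}
    skipped: list[str] = []
    for gene in db.features_of_type("gene"):
        best = 0
        for tx in db.children(gene, level=1):
            if tx.featuretype not in ("mRNA", "transcript"):
                continue
            cds_len = sum(
                c.end - c.start + 1 for c in db.children(tx, featuretype="CDS")
            )
            best = max(best, cds_len)
        # tolerate CDS attached directly to the gene feature
        if best == 0:
            best = sum(
                c.end - c.start + 1
                for c in db.children(gene, featuretype="CDS", level=1)
            )
        if best > 0:
            lengths[gene.id] = best
        else:
            skipped.append(gene.id)
    if skipped:
        log.warning("no CDS found for %d gene(s): %s", len(skipped), skipped[:10])
    return pd.Series(lengths, name="length_bp", dtype=np.int64)


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------

def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              logratio_trim: float, sum_trim: float, weighted: bool) -> float:
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        return 1.0
    o, r = obs[keep].astype(float), ref[keep].astype(float)
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    # asymptotic binomial variance of M
    v = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    fin = np.isfinite(m) & np.isfinite(a)
    m, a, v = m[fin], a[fin], v[fin]
    n = m.size
    if n == 0:
        return 1.0
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rank_m = rankdata(m)
    rank_a = rankdata(a)
    kept = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
    if not kept.any():
        return 1.0
    w = 1.0 / v[kept] if weighted else np.ones(kept.sum())
    f = np.sum(w * m[kept]) / np.sum(w)
    if not np.isfinite(f) or abs(f) < 1e-6:
        f = 0.0
    return float(2.0 ** f)


def tmm_factors(counts: CountMatrix | pd.DataFrame,
                lib_sizes: pd.Series | None = None,
                ref_sample: str | None = None,
                logratio_trim: float = 0.3,
                sum_trim: float = 0.05,
                weighted: bool = True) -> pd.Series:
    """TMM scaling factor per sample, geometric mean rescaled to 1.

    The reference sample, unless given, is the column whose 75th-percentile
    CPM is closest to the mean 75th percentile across samples.
    """
    if isinstance(counts, CountMatrix):
        mat = counts.counts
        if lib_sizes is None:
            lib_sizes = counts.library_sizes
    else:
        mat = counts
        if lib_sizes is None:
            lib_sizes = mat.sum(axis=0).astype(float)
    if mat.shape[1] < 2:
        raise ValueError("TMM requires at least two samples")
    zero = mat.columns[(mat.sum(axis=0) == 0)]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {list(zero)}")
    lib = lib_sizes.loc[mat.columns].to_numpy(dtype=float)
    x = mat.to_numpy(dtype=float)
    if ref_sample is None:
        q75 = np.array([np.quantile(x[:, j] / lib[j], 0.75) for j in range(x.shape[1])])
        ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    else:
        ref_idx = int(mat.columns.get_loc(ref_sample))
    ref = x[:, ref_idx]
    n_ref = lib[ref_idx]
    factors = np.array([
        1.0 if j == ref_idx else _tmm_pair(
            x[:, j], ref, lib[j], n_ref, logratio_trim, sum_trim, weighted
        )
        for j in range(x.shape[1])
    ])
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=mat.columns, name="tmm_factor")


# ---------------------------------------------------------------------------
# CPM / TPM
# ---------------------------------------------------------------------------

def cpm(counts: CountMatrix | pd.DataFrame,
        factors: pd.Series | None = None,
        lib_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million on effective library sizes (library x TMM factor)."""
    if isinstance(counts, CountMatrix):
        mat = counts.counts
        if lib_sizes is None:
            lib_sizes = counts.library_sizes
    else:
        mat = counts
        if lib_sizes is None:
            lib_sizes = mat.sum(axis=0).astype(float)
    lib = lib_sizes.loc[mat.columns].astype(float)
    if factors is not None:
        lib = lib * factors.loc[mat.columns].astype(float)
    if (lib <= 0).any():
        raise ValueError("zero or negative effective library size")
    return mat.div(lib, axis=1) * 1e6


def tpm(counts: CountMatrix | pd.DataFrame,
        gene_lengths: pd.Series | None = None) -> pd.DataFrame:
    """Transcripts per million: length-normalized rates rescaled to 1e6 per column.

    Genes without a positive length are excluded from the output (and logged);
    a sample with no counts yields an all-zero column with a warning.
    """
    if isinstance(counts, CountMatrix):
        mat = counts.counts
        if gene_lengths is None:
            gene_lengths = counts.gene_lengths
    else:
        mat = counts
    if gene_lengths is None:
        raise ValueError("gene lengths are required for TPM")
    lengths = gene_lengths.reindex(mat.index)
    ok = lengths.notna() & (lengths > 0)
    if (~ok).any():
        log.warning("excluding %d gene(s) without positive length from TPM",
                    int((~ok).sum()))
    mat = mat.loc[ok]
    rate = mat.div(lengths[ok].astype(float), axis=0)
    col_sums = rate.sum(axis=0)
    if (col_sums == 0).any():
        warnings.warn(
            f"sample(s) with all-zero counts in TPM: {list(col_sums.index[col_sums == 0])}",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        out = rate.div(col_sums, axis=1) * 1e6
    return out.fillna(0.0)


def filter_low_expression(counts: CountMatrix | pd.DataFrame,
                          min_cpm: float = 1.0,
                          min_samples: int = 1,
                          factors: pd.Series | None = None,
                          lib_sizes: pd.Series | None = None) -> pd.Series:
    """Boolean keep-mask: CPM strictly above ``min_cpm`` in >= ``min_samples``."""
    if min_cpm < 0 or min_samples < 0:
        raise ValueError("thresholds must be >= 0")
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    if min_samples > mat.shape[1]:
        raise ValueError(
            f"min_samples={min_samples} exceeds sample count {mat.shape[1]}"
        )
    c = cpm(counts, factors=factors, lib_sizes=lib_sizes)
    keep = (c > min_cpm).sum(axis=1) >= min_samples
    keep.name = "keep"
    return keep


def normalize(counts: CountMatrix,
              min_cpm: float = 1.0,
              min_samples: int = 1,
              with_tpm: bool = True) -> tuple[NormalizedMatrix, pd.Series]:
    """One-stop normalization: TMM factors, CPM, TPM and the low-expression mask.

    Returns the :class:`NormalizedMatrix` (computed on all genes) and the
    keep-mask from :func:`filter_low_expression`.
    """
    factors = tmm_factors(counts)
    eff = counts.library_sizes * factors
    c = cpm(counts, factors=factors)
    t = tpm(counts) if with_tpm and counts.gene_lengths is not None else None
    keep = filter_low_expression(counts, min_cpm=min_cpm, min_samples=min_samples,
                                 factors=factors)
    return NormalizedMatrix(cpm=c, tpm=t, tmm_factors=factors,
                            effective_lib_sizes=eff), keep
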