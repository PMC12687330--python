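"""Orphan-gene classification and embryo-specific expression profiling.

An orphan gene has no assignable ortholog and no nucleotide or protein
sequence hit outside the species; those flags are consumed here as a
precomputed table (running the homology searches is out of scope).  On top of
the flags, expression filters identify orphans expressed exclusively during
embryogenesis — CPM > 1 in at least one embryonic stage and CPM < 1 in every
larval, pupal and adult sample (both inequalities strict) — and profile the
stage at which each peaks.
"""

from __future__ import annotations

import pandas as pd

FLAG_COLUMNS = ("ortholog_assigned", "nt_hit", "prot_hit")


def classify_orphans(flags_table: pd.DataFrame,
                     genes: list[str] | None = None) -> pd.Series:
    """``is_orphan`` per gene: True iff all homology-evidence flags are False.

    ``flags_table`` is indexed by gene with boolean columns
    ``ortholog_assigned``, ``nt_hit`` and ``prot_hit``.  If ``genes`` is
    given, every listed gene must be present.
    """
    missing_cols = [c for c in FLAG_COLUMNS if c not in flags_table.columns]
    if missing_cols:
        raise ValueError(f"flags table missing columns: {missing_cols}")
    if genes is not None:
        absent = [g for g in genes if g not in flags_table.index]
        if absent:
            raise KeyError(f"genes missing from flags table: {absent[:10]}")
        flags_table = flags_table.loc[genes]
    out = ~flags_table[list(FLAG_COLUMNS)].astype(bool).any(axis=1)
    out.name = "is_orphan"
    return out


def embryo_specific(cpm_matrix: pd.DataFrame, phases: pd.Series,
                    min_cpm_on: float = 1.0,
                    max_cpm_off: float = 1.0) -> pd.DataFrame:
    """Embryo-expression flags from a CPM matrix and per-sample phases.

    ``embryo_expressed``: CPM strictly above ``min_cpm_on`` in at least one
    embryonic sample.  ``embryo_specific``: additionally CPM strictly below
    ``max_cpm_off`` in *all* non-embryonic samples.
    """
    phases = phases.loc[cpm_matrix.columns]
    emb_cols = list(phases.index[phases == "embryonic"])
    off_cols = list(phases.index[phases != "embryonic"])
    if not emb_cols:
        raise ValueError("no embryonic samples")
    if not off_cols:
        raise ValueError(
            "no larval/pupal/adult samples: embryo specificity is undefined"
        )
    expressed = (cpm_matrix[emb_cols] > min_cpm_on).any(axis=1)
    silent_later = (cpm_matrix[off_cols] < max_cpm_off).all(axis=1)
    return pd.DataFrame({
        "embryo_expressed": expressed,
        "embryo_specific": expressed & silent_later,
    })


def peak_profile(tpm_matrix: pd.DataFrame,
                 embryonic_stage_order: list[str]) -> pd.DataFrame:
    """Peak embryonic stage and breadth class per gene.

    The peak is the stage (column) with maximal TPM, ties broken toward the
    earliest stage in ``embryonic_stage_order``.  A peak is ``sharp`` when it
    holds more than half of the summed embryonic TPM, else ``broad``.  Genes
    with all-zero embryonic expression are rejected.
    """
    sub = tpm_matrix[list(embryonic_stage_order)]
    totals = sub.sum(axis=1)
    zero = list(sub.index[totals <= 0])
    if zero:
        raise ValueError(f"all-zero embryonic profile for genes: {zero[:10]}")
    vals = sub.to_numpy(dtype=float)
    peak_idx = vals.argmax(axis=1)  # argmax returns the first (earliest) maximum
    peak_stage = [embryonic_stage_order[i] for i in peak_idx]
    peak_frac = vals.max(axis=1) / totals.to_numpy()
    return pd.DataFrame({
        "peak_stage": peak_stage,
        "peak_fraction": peak_frac,
        "breadth": ["sharp" if f > 0.5 else "broad" for f in peak_frac],
    }, index=sub.index)


def orf_filter(orf_length_aa: int, min_aa: int = 100) -> bool:
    """Keep ORFs of at least ``min_aa`` amino acids (shorter ones removed)."""
    if orf_length_aa < 0:
        raise ValueError("ORF length must be >= 0")
    return orf_length_aa >= min_aa


def profile_orphans(flags_table: pd.DataFrame,
                    cpm_matrix: pd.DataFrame,
                    tpm_matrix: pd.DataFrame | None,
                    phases: pd.Series,
                    embryonic_stage_order: list[str],
                    min_cpm_on: float = 1.0,
                    max_cpm_off: float = 1.0) -> pd.DataFrame:
    """Full orphan call table: flags, expression filters and peak profiling."""
    is_orphan = classify_orphans(flags_table)
    expr = embryo_specific(cpm_matrix, phases, min_cpm_on, max_cpm_off)
    out = expr.reindex(is_orphan.index)
    out.insert(0, "is_orphan", is_orphan)
    out[["embryo_expressed", "embryo_specific"]] = \
        out[["embryo_expressed", "embryo_specific"]].fillna(False)
    out["peak_stage"] = pd.NA
    out["breadth"] = pd.NA
    expressed = out.index[out["embryo_expressed"]]
    source = tpm_matrix if tpm_matrix is not None else cpm_matrix
    candidates = [g for g in expressed if g in source.index]
    if candidates:
        prof_in = source.loc[candidates]
        nonzero = prof_in.index[prof_in[list(embryonic_stage_order)].sum(axis=1) > 0]
        if len(nonzero):
            prof = peak_profile(source.loc[nonzero], embryonic_stage_order)
            out.loc[prof.index, "peak_stage"] = prof["peak_stage"]
            out.loc[prof.index, "breadth"] = prof["breadth"]
    return out
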