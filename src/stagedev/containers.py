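"""Core in-memory containers for the stage-resolved expression pipeline.

The root object is :class:`CountMatrix`: a genes x samples table of raw read
counts together with per-sample metadata (species, developmental stage, life-
cycle phase, library size) and optional per-gene CDS lengths.  Everything is
backed by pandas so that downstream stages can rely on labelled axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

PHASES = ("embryonic", "larval", "pupal", "adult")


@dataclass
class SampleMeta:
    """Metadata for one RNA-seq library (one embryo or one pooled sample)."""

    sample_id: str
    species: str
    stage: str
    phase: str
    library_size: int

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(
                f"sample {self.sample_id!r}: phase {self.phase!r} "
                f"not one of {PHASES}"
            )
        if self.library_size <= 0:
            raise ValueError(
                f"sample {self.sample_id!r}: library_size must be positive"
            )


@dataclass
class CountMatrix:
    """Raw counts with sample metadata and (optionally) gene lengths.

    Parameters
    ----------
    counts
        genes x samples DataFrame of non-negative integers; the index holds
        gene identifiers and the columns sample identifiers.
    samples
        DataFrame indexed by sample id with columns ``species``, ``stage``,
        ``phase`` and ``library_size``.  When ``library_size`` is absent it is
        filled with the column sums of ``counts``.
    gene_lengths
        Per-gene CDS length in bp (longest isoform); optional, required only
        for TPM.
    stage_order
        Total order of stage labels within the experiment; defaults to the
        order of first appearance in ``samples``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    gene_lengths: pd.Series | None = None
    stage_order: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        counts = self.counts
        vals = counts.to_numpy()
        if vals.size and ((vals < 0).any() or not np.allclose(vals, np.round(vals))):
            raise ValueError("counts must be non-negative integers")
        if not counts.index.is_unique:
            raise ValueError("gene ids must be unique")
        samples = self.samples.copy()
        missing = [c for c in ("species", "stage", "phase") if c not in samples.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        if set(samples.index) != set(counts.columns):
            raise ValueError("sample sheet ids do not match count matrix columns")
        samples = samples.loc[counts.columns]
        if "library_size" not in samples.columns or samples["library_size"].isna().any():
            samples["library_size"] = counts.sum(axis=0).astype(np.int64)
        bad = samples.index[samples["library_size"] <= 0]
        if len(bad):
            raise ValueError(f"non-positive library size for samples: {list(bad)}")
        unknown = samples.loc[~samples["phase"].isin(PHASES), "phase"]
        if len(unknown):
            raise ValueError(f"unknown phases: {sorted(set(unknown))}")
        self.samples = samples
        if self.gene_lengths is not None:
            self.gene_lengths = self.gene_lengths.reindex(counts.index)
        if not self.stage_order:
            seen: list[str] = []
            for s in samples["stage"]:
                if s not in seen:
                    seen.append(s)
            self.stage_order = tuple(seen)

    # -- convenience ------------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def library_sizes(self) -> pd.Series:
        return self.samples["library_size"].astype(float)

    def subset_genes(self, genes: Sequence[str] | pd.Index) -> "CountMatrix":
        lengths = None if self.gene_lengths is None else self.gene_lengths.loc[genes]
        return CountMatrix(
            self.counts.loc[genes],
            self.samples.copy(),
            lengths,
            self.stage_order,
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(
            self.counts.loc[:, list(sample_ids)],
            self.samples.loc[list(sample_ids)].copy(),
            self.gene_lengths,
            self.stage_order,
        )

    def samples_for_stage(self, stage: str) -> list[str]:
        mask = self.samples["stage"] == stage
        return list(self.samples.index[mask])

    def embryonic_stage_order(self) -> list[str]:
        emb = self.samples.loc[self.samples["phase"] == "embryonic", "stage"]
        return [s for s in self.stage_order if s in set(emb)]

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, counts_path: str | Path, samples_path: str | Path,
               lengths_path: str | Path | None = None) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
        self.samples.to_csv(samples_path, sep="\t", index_label="sample_id")
        if lengths_path is not None and self.gene_lengths is not None:
            self.gene_lengths.rename("length_bp").to_csv(
                lengths_path, sep="\t", index_label="gene_id"
            )

    @classmethod
    def from_tsv(cls, counts_path: str | Path, samples_path: str | Path,
                 lengths_path: str | Path | None = None,
                 stage_order: Iterable[str] = ()) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
        samples = pd.read_csv(samples_path, sep="\t", index_col="sample_id",
                              dtype={"stage": str})
        lengths = None
        if lengths_path is not None:
            lengths = pd.read_csv(lengths_path, sep="\t", index_col="gene_id")[
                "length_bp"
            ]
        return cls(counts, samples, lengths, tuple(stage_order))
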