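"""Synthetic single-embryo developmental RNA-seq data with known ground truth.

Emulates the study design this package analyzes: one single-embryo library
per embryonic stage (nine stages by default) plus a handful of post-embryonic
samples, counts drawn from a negative binomial with a shared dispersion
(variance = mu + phi * mu^2), and planted, truth-tracked effects:

* step fold changes (>= ``deg_fold_min``) between sequential stages,
* temporal archetypes (maternal decay, cellularization peak,
  post-retraction ramp),
* embryo-specific orphan genes (exact-zero post-embryonic means), and
* collinear anchor chains between two synthetic genomes among scattered
  noise anchors.

Every generator is driven by a single seed; identical spec + seed gives
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CountMatrix

EMBRYONIC_STAGES = ("1", "5", "8", "9", "10", "12", "13", "15", "17")
POST_EMBRYONIC = ("L1", "L3", "pupa", "adult")
_PHASE_OF = {"L1": "larval", "L3": "larval", "pupa": "pupal", "adult": "adult"}
ARCHETYPES = ("maternal_decay", "cellularization_peak", "post_retraction_ramp")


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic dataset; defaults mirror the study design."""

    n_genes: int = 2000
    stage_labels: tuple[str, ...] = EMBRYONIC_STAGES
    post_embryonic_labels: tuple[str, ...] = POST_EMBRYONIC
    phi: float = 0.36
    lib_size_range: tuple[int, int] = (1_000_000, 2_000_000)
    deg_fraction: float = 0.1
    deg_fold_min: float = 3.0
    # planted fold = deg_fold_min * 10^U(margin); (0, 0) plants the floor exactly
    deg_fold_margin_log10: tuple[float, float] = (0.15, 0.5)
    archetype_set: tuple[str, ...] = ARCHETYPES
    archetype_fraction: float = 0.15
    orphan_fraction: float = 0.02
    n_go_terms: int = 20
    anchor_block_spec: tuple[tuple[int, str, int], ...] = (
        (5, "forward", 20), (7, "inverted", 15), (9, "forward", 15),
    )
    seed: int = 0
    n_replicates: int = 1
    species: str = "synthetic_fly"
    depth_asymmetry: bool = False  # optionally double every library size
    baseline_log10_mean: float = 1.5
    baseline_log10_sd: float = 0.7

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes: must be a positive integer")
        if not self.stage_labels:
            raise ValueError("stage_labels: must be non-empty")
        if self.phi < 0:
            raise ValueError("phi: dispersion must be >= 0")
        lo, hi = self.lib_size_range
        if lo <= 0 or hi < lo:
            raise ValueError("lib_size_range: need 0 < low <= high")
        for name in ("deg_fraction", "archetype_fraction", "orphan_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}: proportion must be in [0, 1]")
        if self.deg_fold_min < 1:
            raise ValueError("deg_fold_min: must be >= 1")
        if not (0 <= self.deg_fold_margin_log10[0] <= self.deg_fold_margin_log10[1]):
            raise ValueError("deg_fold_margin_log10: need 0 <= low <= high")
        if self.n_go_terms < 1:
            raise ValueError("n_go_terms: must be >= 1")
        for blk in self.anchor_block_spec:
            if blk[0] < 1:
                raise ValueError("anchor_block_spec: block lengths must be >= 1")
            if blk[1] not in ("forward", "inverted"):
                raise ValueError("anchor_block_spec: orientation must be "
                                 "'forward' or 'inverted'")
        if self.n_replicates < 1:
            raise ValueError("n_replicates: must be >= 1")

    def phase_of(self, label: str) -> str:
        return _PHASE_OF.get(label, "larval")


@dataclass
class TruthTables:
    """Ground truth for every planted effect."""

    deg_truth: pd.DataFrame       # gene, stage_a, stage_b, fold, direction
    archetype_truth: pd.Series    # gene -> archetype id
    orphan_truth: pd.Series       # gene -> embryo-specific orphan flag
    orphan_peak: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))
    block_truth: list = field(default_factory=list)
    mean_matrix: pd.DataFrame | None = None  # expected mu per gene x sample


@dataclass
class PlantedBlock:
    chrom_a: str
    chrom_b: str
    orientation: str
    anchors: list[tuple[str, str]]


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _archetype_profile(archetype: str, stages: tuple[str, ...]) -> np.ndarray:
    """Multiplicative stage profile for one temporal archetype."""
    n = len(stages)
    idx = np.arange(n, dtype=float)
    if archetype == "maternal_decay":
        # high maternal load at stage 1, cleared by mid-embryogenesis
        return 8.0 * np.exp(-1.5 * idx)
    if archetype == "cellularization_peak":
        peak = stages.index("5") if "5" in stages else 1
        return 1.0 + 8.0 * np.exp(-0.5 * (idx - peak) ** 2)
    if archetype == "post_retraction_ramp":
        onset = stages.index("13") if "13" in stages else max(n - 3, 0)
        prof = np.ones(n) * 0.25
        prof[onset:] = 8.0
        return prof
    raise ValueError(f"unknown archetype {archetype!r}")


def generate_counts(spec: SyntheticSpec) -> tuple[CountMatrix, TruthTables]:
    """Draw the synthetic count matrix and its truth tables."""
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    rng_counts, rng_fx, _rng_go, _rng_anchor = [
        np.random.default_rng(s) for s in ss.spawn(4)
    ]

    genes = [f"g{i:05d}" for i in range(spec.n_genes)]
    emb = tuple(spec.stage_labels)
    post = tuple(spec.post_embryonic_labels)
    stages_all = emb + post

    # sample sheet: n_replicates per embryonic stage, one per post-embryonic
    rows = []
    for st in emb:
        for r in range(spec.n_replicates):
            sid = f"{st}" if spec.n_replicates == 1 else f"{st}_r{r + 1}"
            rows.append((sid, st, "embryonic"))
    for st in post:
        rows.append((st, st, spec.phase_of(st)))
    sample_ids = [r[0] for r in rows]

    # baseline means: log-normal dynamic range
    base = 10.0 ** rng_fx.normal(spec.baseline_log10_mean,
                                 spec.baseline_log10_sd, spec.n_genes)
    profile = np.tile(base[:, None], (1, len(stages_all)))

    # disjoint planted-effect gene sets
    n_deg = int(round(spec.deg_fraction * spec.n_genes))
    n_arch = int(round(spec.archetype_fraction * spec.n_genes))
    n_orph = int(round(spec.orphan_fraction * spec.n_genes))
    chosen = rng_fx.choice(spec.n_genes, size=n_deg + n_arch + n_orph,
                           replace=False)
    deg_genes = chosen[:n_deg]
    arch_genes = chosen[n_deg:n_deg + n_arch]
    orph_genes = chosen[n_deg + n_arch:]

    # planted step fold changes between one sequential embryonic stage pair.
    # A 10^U(0.15, 0.5) margin above deg_fold_min keeps the realized mean fold
    # above the floor even after library-scale compositional wobble.
    deg_rows = []
    pair_idx = rng_fx.integers(0, len(emb) - 1, size=n_deg)
    direction = rng_fx.choice([-1.0, 1.0], size=n_deg)
    lo_m, hi_m = spec.deg_fold_margin_log10
    fold = spec.deg_fold_min * 10.0 ** rng_fx.uniform(lo_m, hi_m, size=n_deg)
    for g, pi, di, fo in zip(deg_genes, pair_idx, direction, fold):
        mult = fo if di > 0 else 1.0 / fo
        profile[g, pi + 1:len(emb)] *= mult
        deg_rows.append({
            "gene": genes[g], "stage_a": emb[pi], "stage_b": emb[pi + 1],
            "fold": fo, "direction": "up" if di > 0 else "down",
        })
    deg_truth = pd.DataFrame(
        deg_rows, columns=["gene", "stage_a", "stage_b", "fold", "direction"]
    )

    # temporal archetypes
    arch_assign = {}
    if n_arch and spec.archetype_set:
        kinds = [spec.archetype_set[i % len(spec.archetype_set)]
                 for i in range(n_arch)]
        for g, kind in zip(arch_genes, kinds):
            prof = _archetype_profile(kind, emb)
            profile[g, :len(emb)] *= prof
            arch_assign[genes[g]] = kind
    archetype_truth = pd.Series(arch_assign, dtype=object, name="archetype")

    # embryo-specific orphans: exact zero outside embryogenesis, a sharp
    # high peak at an assigned embryonic stage (guaranteed CPM > 1)
    orph_peak = {}
    for g in orph_genes:
        peak = int(rng_fx.integers(0, len(emb)))
        prof = np.full(len(emb), 0.0)
        prof[peak] = 1.0
        if peak > 0:
            prof[peak - 1] = 0.25
        if peak + 1 < len(emb):
            prof[peak + 1] = 0.25
        profile[g, :len(emb)] = 400.0 * prof  # well clear of the CPM=1 line
        profile[g, len(emb):] = 0.0
        orph_peak[genes[g]] = emb[peak]
    orphan_truth = pd.Series(
        {genes[g]: (g in set(orph_genes)) for g in range(spec.n_genes)},
        name="orphan",
    )

    # map stage profiles onto samples and scale to target library depth;
    # the per-sample scale is a constant (not a column normalization) so
    # planted fold ratios are preserved exactly in the means.
    stage_col = {st: i for i, st in enumerate(stages_all)}
    lib_targets = rng_counts.integers(spec.lib_size_range[0],
                                     spec.lib_size_range[1] + 1,
                                     size=len(sample_ids)).astype(float)
    if spec.depth_asymmetry:
        lib_targets *= 2.0
    base_total = base.sum()
    mu = np.empty((spec.n_genes, len(sample_ids)))
    for j, (sid, st, _phase) in enumerate(rows):
        mu[:, j] = profile[:, stage_col[st]] * (lib_targets[j] / base_total)

    # NB draws (Poisson limit at phi = 0)
    if spec.phi > 0:
        r = 1.0 / spec.phi
        p = r / (r + np.maximum(mu, 1e-300))
        counts = rng_counts.negative_binomial(r, p)
        counts[mu == 0] = 0
    else:
        counts = rng_counts.poisson(mu)

    counts_df = pd.DataFrame(counts, index=genes, columns=sample_ids)
    samples_df = pd.DataFrame(
        {
            "species": spec.species,
            "stage": [r[1] for r in rows],
            "phase": [r[2] for r in rows],
            "library_size": counts_df.sum(axis=0).astype(np.int64),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    lengths = pd.Series(
        np.clip(10.0 ** rng_fx.normal(3.0, 0.35, spec.n_genes), 150, 1e5)
        .astype(np.int64),
        index=genes, name="length_bp",
    )
    cm = CountMatrix(counts_df, samples_df, lengths, tuple(stages_all))
    truth = TruthTables(
        deg_truth=deg_truth,
        archetype_truth=archetype_truth,
        orphan_truth=orphan_truth,
        orphan_peak=pd.Series(orph_peak, dtype=object, name="peak_stage"),
        mean_matrix=pd.DataFrame(mu, index=genes, columns=sample_ids),
    )
    return cm, truth


# ---------------------------------------------------------------------------
# GO annotation
# ---------------------------------------------------------------------------

def generate_go_annotation(spec: SyntheticSpec,
                           genes: list[str],
                           enriched_term_config: dict | None = None
                           ) -> pd.DataFrame:
    """Random gene -> GO-term long table, optionally with one enriched term.

    ``enriched_term_config`` has keys ``genes`` (the designated gene set) and
    ``odds_ratio`` (membership odds multiplier inside that set, default 1).
    The enriched term is always term 0.
    """
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(ss.spawn(4)[2])
    n = len(genes)
    enriched_set: set[str] = set()
    odds_ratio = 1.0
    if enriched_term_config is not None:
        enriched_set = set(enriched_term_config["genes"])
        if not enriched_set:
            raise ValueError("enriched gene set is empty")
        if not enriched_set <= set(genes):
            raise ValueError("enriched set larger than / outside the background")
        odds_ratio = float(enriched_term_config.get("odds_ratio", 1.0))
    rows = []
    gene_arr = np.array(genes)
    in_set = np.isin(gene_arr, list(enriched_set))
    for t in range(spec.n_go_terms):
        term = f"GO:{t:07d}"
        p_out = rng.uniform(0.02, 0.15)
        if t == 0 and enriched_set:
            odds = odds_ratio * p_out / (1 - p_out)
            p_in = odds / (1 + odds)
        else:
            p_in = p_out
        draw = rng.uniform(size=n)
        member = np.where(in_set, draw < p_in, draw < p_out)
        for g in gene_arr[member]:
            rows.append({"gene": g, "term": term})
    return pd.DataFrame(rows, columns=["gene", "term"])


# ---------------------------------------------------------------------------
# synteny anchors
# ---------------------------------------------------------------------------

def generate_anchors(spec: SyntheticSpec,
                     genes_per_chrom: int = 1000,
                     n_chroms: int = 2,
                     gene_span: int = 2000,
                     gene_gap: int = 500
                     ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, list]:
    """Anchor table + position tables with planted collinear chains.

    Planted chains occupy non-overlapping consecutive rank intervals on both
    genomes (overlap is rejected); noise anchors are scattered uniformly but
    kept clear of a ``max_gaps``-sized margin around each planted chain so
    the planted truth remains the unique chainable signal.

    Returns (anchors, positions_a, positions_b, block_truth).
    """
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(ss.spawn(4)[3])

    def positions(prefix: str) -> pd.DataFrame:
        rows = []
        for c in range(n_chroms):
            chrom = f"{prefix}chr{c + 1}"
            for i in range(genes_per_chrom):
                start = 1 + i * (gene_span + gene_gap)
                rows.append({"gene": f"{prefix}{c + 1}.{i + 1}", "chrom": chrom,
                             "start": start, "end": start + gene_span - 1})
        return pd.DataFrame(rows)

    pos_a = positions("A")
    pos_b = positions("B")

    # reserve non-overlapping rank intervals for the planted chains
    blocks = []
    used_a: list[tuple[int, int]] = []
    used_b: list[tuple[int, int]] = []
    margin = 101  # keep noise out of chain-extension range (max_gaps default)

    def overlaps(iv, used):
        # margin-expanded: planted chains must not even be chainable into
        # each other through a <= max_gaps rank jump
        return any(
            not (iv[1] + margin < lo or iv[0] - margin > hi) for lo, hi in used
        )

    for bi, (length, orientation, _n_noise) in enumerate(spec.anchor_block_spec):
        for _attempt in range(1000):
            ca = int(rng.integers(0, n_chroms))
            cb = int(rng.integers(0, n_chroms))
            sa = int(rng.integers(1, genes_per_chrom - length + 1))
            sb = int(rng.integers(1, genes_per_chrom - length + 1))
            iv_a = (sa, sa + length - 1)
            iv_b = (sb, sb + length - 1)
            if not overlaps(iv_a, used_a) and not overlaps(iv_b, used_b):
                break
        else:
            raise ValueError("could not place non-overlapping planted blocks")
        used_a.append(iv_a)
        used_b.append(iv_b)
        ranks_b = range(sb, sb + length) if orientation == "forward" \
            else range(sb + length - 1, sb - 1, -1)
        anchors = [
            (f"A{ca + 1}.{sa + k}", f"B{cb + 1}.{rb}")
            for k, rb in enumerate(ranks_b)
        ]
        blocks.append(PlantedBlock(
            chrom_a=f"Achr{ca + 1}", chrom_b=f"Bchr{cb + 1}",
            orientation=orientation, anchors=anchors,
        ))

    anchor_rows = [
        {"gene_a": ga, "gene_b": gb, "planted": True}
        for b in blocks for ga, gb in b.anchors
    ]

    planted_genes_a = {r["gene_a"] for r in anchor_rows}
    planted_genes_b = {r["gene_b"] for r in anchor_rows}
    n_noise_total = sum(b[2] for b in spec.anchor_block_spec)
    placed = 0
    guard = 0
    while placed < n_noise_total and guard < 100000:
        guard += 1
        ca = int(rng.integers(0, n_chroms))
        cb = int(rng.integers(0, n_chroms))
        ra = int(rng.integers(1, genes_per_chrom + 1))
        rb = int(rng.integers(1, genes_per_chrom + 1))
        ga = f"A{ca + 1}.{ra}"
        gb = f"B{cb + 1}.{rb}"
        if ga in planted_genes_a or gb in planted_genes_b:
            continue
        near = False
        for b, iv_a, iv_b in zip(blocks, used_a, used_b):
            same_pair = (b.chrom_a == f"Achr{ca + 1}"
                         and b.chrom_b == f"Bchr{cb + 1}")
            if same_pair and (iv_a[0] - margin <= ra <= iv_a[1] + margin) \
                    and (iv_b[0] - margin <= rb <= iv_b[1] + margin):
                near = True
                break
        if near:
            continue
        anchor_rows.append({"gene_a": ga, "gene_b": gb, "planted": False})
        planted_genes_a.add(ga)
        planted_genes_b.add(gb)
        placed += 1
    if placed < n_noise_total:
        raise RuntimeError("failed to place requested noise anchors")

    anchors_df = pd.DataFrame(anchor_rows, columns=["gene_a", "gene_b", "planted"])
    return anchors_df, pos_a, pos_b, blocks


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------

def write_dataset(outdir: str | Path, spec: SyntheticSpec) -> dict[str, Path]:
    """Generate everything and write the TSVs a pipeline run consumes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cm, truth = generate_counts(spec)
    genes = list(cm.gene_ids)
    go = generate_go_annotation(spec, genes)
    anchors, pos_a, pos_b, blocks = generate_anchors(spec)

    paths = {
        "counts": outdir / "counts.tsv",
        "samples": outdir / "samples.tsv",
        "lengths": outdir / "gene_lengths.tsv",
        "go": outdir / "go_annotation.tsv",
        "anchors": outdir / "anchors.tsv",
        "positions_a": outdir / "positions_a.tsv",
        "positions_b": outdir / "positions_b.tsv",
        "orphan_flags": outdir / "orphan_flags.tsv",
        "deg_truth": outdir / "truth_degs.tsv",
        "orphan_truth": outdir / "truth_orphans.tsv",
        "archetype_truth": outdir / "truth_archetypes.tsv",
        "block_truth": outdir / "truth_blocks.tsv",
    }
    cm.to_tsv(paths["counts"], paths["samples"], paths["lengths"])
    go.to_csv(paths["go"], sep="\t", index=False)
    anchors.drop(columns=["planted"]).to_csv(paths["anchors"], sep="\t", index=False)
    pos_a.to_csv(paths["positions_a"], sep="\t", index=False)
    pos_b.to_csv(paths["positions_b"], sep="\t", index=False)
    flags = pd.DataFrame(
        {
            "ortholog_assigned": ~truth.orphan_truth,
            "nt_hit": ~truth.orphan_truth,
            "prot_hit": ~truth.orphan_truth,
        },
        index=truth.orphan_truth.index,
    )
    flags.to_csv(paths["orphan_flags"], sep="\t", index_label="gene_id")
    truth.deg_truth.to_csv(paths["deg_truth"], sep="\t", index=False)
    truth.orphan_truth.rename("embryo_specific_orphan").to_csv(
        paths["orphan_truth"], sep="\t", index_label="gene_id")
    truth.archetype_truth.rename("archetype").to_csv(
        paths["archetype_truth"], sep="\t", index_label="gene_id")
    with open(paths["block_truth"], "w") as fh:
        fh.write("block\tchrom_a\tchrom_b\torientation\tgene_a\tgene_b\n")
        for i, b in enumerate(blocks):
            for ga, gb in b.anchors:
                fh.write(f"{i}\t{b.chrom_a}\t{b.chrom_b}\t{b.orientation}"
                         f"\t{ga}\t{gb}\n")
    return paths
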