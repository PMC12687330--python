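"""Configuration and end-to-end orchestration.

A single YAML (or dict) config drives the whole analysis: normalize -> DGE ->
soft clustering -> enrichment, with the orphan and synteny stages independent.
Every stage reads and writes plain TSV files, so partial reruns are possible,
and a manifest records the seed, parameters and record counts.  Reruns with
the same config produce byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import CountMatrix
from .dge import (DGEThresholds, estimate_common_dispersion, leading_fc_distance,
                  mds_embed, pairwise_stage_dge, select_k, dge_summary)
from .clustering import filter_by_membership, fuzzy_cmeans, standardize
from .enrichment import GOAnnotation, hypergeom_enrichment
from .normalization import cpm, normalize, tpm
from .orphans import profile_orphans
from .simulate import SyntheticSpec, write_dataset
from .synteny import SyntenyParams, block_summary, find_collinear_blocks, \
    write_blocks

log = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """All inputs, thresholds and parameters of one pipeline run."""

    outdir: str = "stagedev_run"
    seed: int = 0
    # inputs (paths); when simulate=True they are generated into outdir
    counts: str | None = None
    samples: str | None = None
    gene_lengths: str | None = None
    gff: str | None = None
    go_annotation: str | None = None
    ortholog_table: str | None = None
    orphan_flags: str | None = None
    anchors: str | None = None
    positions_a: str | None = None
    positions_b: str | None = None
    simulate: bool = False
    simulate_spec: dict = field(default_factory=dict)
    # normalization
    min_cpm: float = 1.0
    min_samples: int = 1
    # dge
    fold_threshold: float = 3.0
    p_threshold: float = 0.001
    prior_count: float = 0.5
    top_n: int = 500
    k_min: int = 1
    k_max: int = 8
    var_target: float = 0.95
    phi_override: float | None = None
    # clustering
    n_clusters: int = 30
    fuzzifier: float | None = None
    membership_threshold: float = 0.7
    cluster_all_genes: bool = False
    # orphans
    min_cpm_on: float = 1.0
    max_cpm_off: float = 1.0
    # synteny
    match_score: float = 50.0
    match_size: int = 5
    gap_penalty: float = 0.0
    max_gaps: int = 100

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)


def validate_config(config: AnalysisConfig) -> list[dict]:
    """Range/consistency checks; returns one record per check."""
    checks = []

    def check(name: str, ok: bool, message: str) -> None:
        checks.append({"check": name, "ok": bool(ok), "message": message})

    check("fold_threshold", config.fold_threshold >= 1,
          "fold_threshold must be >= 1")
    check("p_threshold", 0 < config.p_threshold < 1,
          "p_threshold must be in (0, 1)")
    check("prior_count", config.prior_count >= 0, "prior_count must be >= 0")
    check("membership_threshold", 0 < config.membership_threshold <= 1,
          "membership_threshold must be in (0, 1]")
    check("n_clusters", config.n_clusters >= 1, "n_clusters must be >= 1")
    check("fuzzifier", config.fuzzifier is None or config.fuzzifier > 1,
          "fuzzifier must be > 1")
    check("min_cpm", config.min_cpm >= 0, "min_cpm must be >= 0")
    check("min_samples", config.min_samples >= 0, "min_samples must be >= 0")
    check("match_size", config.match_size >= 1, "match_size must be >= 1")
    check("max_gaps", config.max_gaps >= 0, "max_gaps must be >= 0")
    check("gap_penalty", config.gap_penalty <= 0, "gap_penalty must be <= 0")
    check("top_n", config.top_n >= 1, "top_n must be >= 1")
    check("k_range", 1 <= config.k_min <= config.k_max,
          "need 1 <= k_min <= k_max")
    check("phi_override",
          config.phi_override is None or config.phi_override >= 0,
          "phi_override must be >= 0")
    if not config.simulate:
        for name in ("counts", "samples"):
            p = getattr(config, name)
            check(f"path:{name}", p is not None and Path(p).exists(),
                  f"input path {name} must exist")
        for name in ("gene_lengths", "go_annotation", "orphan_flags",
                     "anchors", "positions_a", "positions_b",
                     "ortholog_table", "gff"):
            p = getattr(config, name)
            if p is not None:
                check(f"path:{name}", Path(p).exists(),
                      f"configured path {name} does not exist: {p}")
    return checks


def _write(df: pd.DataFrame, path: Path, **kw) -> int:
    df.to_csv(path, sep="\t", **kw)
    return len(df)


def run_pipeline(config: AnalysisConfig) -> dict:
    """Execute all stages in dependency order; returns the manifest."""
    checks = validate_config(config)
    failed = [c for c in checks if not c["ok"]]
    if failed:
        raise ValueError(
            "config validation failed: "
            + "; ".join(f"{c['check']}: {c['message']}" for c in failed)
        )
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest: dict = {
        "tool": "stagedev",
        "version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items()},
        "stages": {},
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True, default=str).encode()
    ).hexdigest()
    timings: dict[str, float] = {}

    def stage_done(name: str, **records) -> None:
        manifest["stages"][name] = {"status": "ok", **records}
        timings[name] = round(time.time() - t0, 3)

    # ---- inputs ---------------------------------------------------------
    paths: dict[str, Path] = {}
    if config.simulate:
        spec = SyntheticSpec(**{**config.simulate_spec, "seed": config.seed})
        paths = {k: Path(v) for k, v in
                 write_dataset(outdir / "synthetic", spec).items()}
        config.counts = str(paths["counts"])
        config.samples = str(paths["samples"])
        config.gene_lengths = str(paths["lengths"])
        config.go_annotation = str(paths["go"])
        config.orphan_flags = str(paths["orphan_flags"])
        config.anchors = str(paths["anchors"])
        config.positions_a = str(paths["positions_a"])
        config.positions_b = str(paths["positions_b"])
        stage_done("simulate", n_genes=spec.n_genes)
    cm = CountMatrix.from_tsv(config.counts, config.samples,
                              config.gene_lengths)

    # ---- normalize ------------------------------------------------------
    norm, keep = normalize(cm, min_cpm=config.min_cpm,
                           min_samples=config.min_samples)
    _write(norm.cpm.round(6), outdir / "cpm.tsv", index_label="gene_id")
    if norm.tpm is not None:
        _write(norm.tpm.round(6), outdir / "tpm.tsv", index_label="gene_id")
    _write(norm.tmm_factors.round(8).to_frame(), outdir / "tmm_factors.tsv",
           index_label="sample_id")
    stage_done("normalize", n_genes=int(cm.counts.shape[0]),
               n_kept=int(keep.sum()))

    # ---- dge ------------------------------------------------------------
    emb_samples = [s for s in cm.sample_ids
                   if cm.samples.loc[s, "phase"] == "embryonic"]
    emb = cm.subset_samples(emb_samples)
    kept_emb = emb.subset_genes(list(keep.index[keep]))
    log_expr = np.log2(cpm(kept_emb, factors=norm.tmm_factors[emb_samples]) + 0.5)
    dist = leading_fc_distance(log_expr, top_n=min(config.top_n,
                                                   log_expr.shape[0]))
    ordination = mds_embed(dist, d=4)
    ksel = select_k(ordination, k_min=config.k_min, k_max=config.k_max,
                    var_target=config.var_target, seed=config.seed)
    if config.phi_override is not None:
        phi = float(config.phi_override)
    else:
        disp = estimate_common_dispersion(kept_emb.counts, ksel.groups,
                                          kept_emb.library_sizes)
        phi = disp.phi
    thresholds = DGEThresholds(config.fold_threshold, config.p_threshold,
                               config.prior_count)
    eff_emb = (kept_emb.library_sizes
               * norm.tmm_factors[kept_emb.sample_ids])
    results = pairwise_stage_dge(kept_emb, phi, thresholds,
                                 lib_sizes=eff_emb)
    for r in results:
        _write(r.table.round({"log2fc": 6}),
               outdir / f"dge_{r.stage_a}_vs_{r.stage_b}.tsv",
               index_label="gene_id")
    summary = dge_summary(results)
    _write(summary, outdir / "dge_summary.tsv", index=False)
    _write(ordination.coordinates.round(6), outdir / "mds_coordinates.tsv",
           index_label="sample_id")
    stage_done("dge", k=ksel.k, phi=round(phi, 6),
               n_deg_total=int(summary["n_deg"].sum()))

    # ---- soft clustering ------------------------------------------------
    if config.cluster_all_genes:
        cluster_genes = list(kept_emb.gene_ids)
    else:
        deg_union = sorted(set().union(
            *[set(r.table.index[r.table["is_deg"]]) for r in results]
        )) if results else []
        cluster_genes = deg_union
    clustering = None
    if len(cluster_genes) >= max(config.n_clusters, 2):
        expr = np.log2(tpm(kept_emb).loc[
            [g for g in cluster_genes if g in kept_emb.gene_ids]] + 1.0)
        # order embryonic samples along the stage axis
        stage_cols = [s for st in kept_emb.embryonic_stage_order()
                      for s in kept_emb.samples_for_stage(st)]
        z, dropped = standardize(expr[stage_cols])
        if z.shape[0] >= config.n_clusters:
            clustering = fuzzy_cmeans(z, c=config.n_clusters,
                                      m=config.fuzzifier, seed=config.seed)
            _write(clustering.membership.round(6),
                   outdir / "cluster_membership.tsv", index_label="gene_id")
            _write(clustering.centroids.round(6),
                   outdir / "cluster_centroids.tsv", index_label="cluster")
            lists = filter_by_membership(clustering,
                                         config.membership_threshold)
            with open(outdir / "cluster_gene_lists.tsv", "w") as fh:
                fh.write("cluster\tgene_id\n")
                for cl in sorted(lists):
                    for g in lists[cl]:
                        fh.write(f"{cl}\t{g}\n")
            stage_done("cluster", n_genes=int(z.shape[0]),
                       n_dropped_constant=len(dropped),
                       converged=bool(clustering.converged))
    if clustering is None:
        manifest["stages"]["cluster"] = {
            "status": "skipped",
            "reason": f"only {len(cluster_genes)} genes to cluster",
        }

    # ---- enrichment ------------------------------------------------------
    if config.go_annotation and clustering is not None:
        go_tab = pd.read_csv(config.go_annotation, sep="\t")
        annotation = GOAnnotation.from_table(go_tab)
        lists = filter_by_membership(clustering, config.membership_threshold)
        enr_rows = []
        for cl in sorted(lists):
            query = [g for g in lists[cl] if g in annotation.background]
            if not query:
                continue
            enr = hypergeom_enrichment(query, annotation)
            enr.insert(0, "cluster", cl)
            enr_rows.append(enr)
        enr_all = pd.concat(enr_rows, ignore_index=True) if enr_rows \
            else pd.DataFrame()
        _write(enr_all.round(8), outdir / "enrichment.tsv", index=False)
        stage_done("enrich", n_rows=len(enr_all))

    # ---- orphans ---------------------------------------------------------
    if config.orphan_flags:
        flags = pd.read_csv(config.orphan_flags, sep="\t", index_col=0)
        stage_cols = {st: cm.samples_for_stage(st)
                      for st in cm.embryonic_stage_order()}
        cpm_all = cpm(cm, factors=norm.tmm_factors)
        # stage-level profiles (mean over replicate samples per stage)
        def stage_matrix(mat: pd.DataFrame) -> pd.DataFrame:
            cols = {}
            for st in cm.stage_order:
                ids = cm.samples_for_stage(st)
                if ids:
                    cols[st] = mat[ids].mean(axis=1)
            return pd.DataFrame(cols)

        cpm_stage = stage_matrix(cpm_all)
        phases = pd.Series(
            {st: cm.samples.loc[cm.samples_for_stage(st)[0], "phase"]
             for st in cpm_stage.columns}
        )
        tpm_stage = stage_matrix(norm.tpm) if norm.tpm is not None else None
        orphan_table = profile_orphans(
            flags, cpm_stage, tpm_stage, phases,
            list(stage_cols), config.min_cpm_on, config.max_cpm_off,
        )
        _write(orphan_table, outdir / "orphans.tsv", index_label="gene_id")
        stage_done(
            "orphans",
            n_orphans=int(orphan_table["is_orphan"].sum()),
            n_embryo_specific=int(
                (orphan_table["is_orphan"]
                 & orphan_table["embryo_specific"]).sum()),
        )

    # ---- synteny ---------------------------------------------------------
    if config.anchors and config.positions_a and config.positions_b:
        anchors = pd.read_csv(config.anchors, sep="\t")
        pos_a = pd.read_csv(config.positions_a, sep="\t")
        pos_b = pd.read_csv(config.positions_b, sep="\t")
        params = SyntenyParams(config.match_score, config.match_size,
                               config.gap_penalty, config.max_gaps)
        blocks = find_collinear_blocks(anchors, pos_a, pos_b, params)
        write_blocks(blocks, outdir / "collinear_blocks.txt")
        _write(block_summary(blocks), outdir / "synteny_summary.tsv",
               index=False)
        stage_done("synteny", n_blocks=len(blocks),
                   n_anchor_genes=int(sum(2 * b.n_anchors for b in blocks)))

    manifest["checks"] = checks
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    with open(outdir / "run.log", "w") as fh:
        for name, t in timings.items():
            fh.write(f"{name}\t{t}\n")
    return manifest
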