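"""End-to-end orchestration: anchor rotation, skew, pangenome, density,
region statistics and expression timing, written out as table analogs.

``run_all`` executes the stages in dependency order on either a simulated
dataset or files on disk, and writes every report as TSV plus a JSON manifest
recording the seed and a config hash so reruns are checkable by checksum.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import expression as xp
from . import pangenome as pg
from . import region_density as rd
from . import skew as sk
from .genome_io import GenomeSet, normalized_position, rotate_to_anchor
from .synthetic_data import SimulatedDataset


@dataclass
class RunConfig:
    out_dir: str
    anchor_product_regex: str = "major capsid"
    region_boundary: float = 2.0 / 3.0
    window_width: float = 0.05
    window_step: float = 0.01
    skew_windows: int = 100
    skew_mode: str = "AT"
    max_breaks: int = 5
    permutations: int = 1000
    kmeans_k: int = 3
    seed: int = 0


def _anchor_all(genome_set: GenomeSet, regex: str) -> GenomeSet:
    """Rotate every circular genome so its anchor gene starts at 0 on +."""
    out = GenomeSet()
    for gid in genome_set.genome_ids:
        genome = genome_set.genomes[gid]
        genes = genome_set.genes(gid)
        rotated, new_genes, _ = rotate_to_anchor(genome, genes, product_regex=regex)
        out.add_genome(rotated)
        for g in new_genes:
            out.add_gene(g)
    return out


def table1_analog(classification: pg.GeneClassification) -> pd.DataFrame:
    """Per-genome core / strain-specific / single-copy / paralog counts with
    integer percentages, one row per genome."""
    t = classification.table
    return pd.DataFrame(
        {
            "genome": t["genome"],
            "core": [f"{n} ({p}%)" for n, p in zip(t["core_n"], t["core_pct"])],
            "strain_specific": [
                f"{n} ({p}%)" for n, p in zip(t["strain_specific_n"], t["strain_specific_pct"])
            ],
            "single_copy": [
                f"{n} ({p}%)" for n, p in zip(t["single_copy_n"], t["single_copy_pct"])
            ],
            "paralogs": [f"{n} ({p}%)" for n, p in zip(t["paralog_n"], t["paralog_pct"])],
        }
    )


def table2_analog(
    classes: pd.Series,
    partition: rd.RegionPartition,
    summaries: pd.DataFrame,
) -> dict:
    """Region x timing-class counts with integer percentages, expression
    summaries (mean +/- sd) per region, and the chi-square p-value."""
    labels = pd.Series(partition.labels)
    enr = xp.timing_enrichment(classes, labels)
    table = enr["table"]
    pct = (100 * enr["frequencies"]).round().astype(int)
    rows = []
    for region in table.index:
        genes = [g for g, r in partition.labels.items() if r == region and g in summaries.index]
        sub = summaries.loc[genes]
        row = {"region": region}
        for cls in table.columns:
            row[cls] = f"{table.loc[region, cls]} ({pct.loc[region, cls]}%)"
        row["max_expression"] = f"{sub['max_expression'].mean():.1f} ± {sub['max_expression'].std(ddof=1):.1f}"
        row["total_expression"] = f"{sub['total_expression'].mean():.1f} ± {sub['total_expression'].std(ddof=1):.1f}"
        rows.append(row)
    return {
        "table": pd.DataFrame(rows),
        "chi_square_p": enr["p_value"],
        "chi_square_statistic": enr["statistic"],
        "counts": table,
        "frequencies": enr["frequencies"],
    }


def run_all(dataset: SimulatedDataset, run_config: RunConfig) -> dict:
    """Run every stage on a dataset and write the report bundle.

    Returns a dict of in-memory results; files land in ``run_config.out_dir``.
    """
    out = Path(run_config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    log: list[dict] = []
    results: dict = {}

    def stage(name):
        log.append({"stage": name, "elapsed_s": round(time.time() - t0, 2)})

    anchored = _anchor_all(dataset.genome_set, run_config.anchor_product_regex)
    stage("rotate")

    # skew profiles and breakpoints
    bp_rows = []
    for gid in anchored.genome_ids:
        genome = anchored.genomes[gid]
        prof = sk.cumulated_skew(genome, mode=run_config.skew_mode, W=run_config.skew_windows)
        bps = sk.detect_breakpoints(prof, max_breaks=run_config.max_breaks)
        for b in bps.breakpoints:
            bp_rows.append({"genome": gid, "mode": run_config.skew_mode, "breakpoint": b})
    breakpoints = pd.DataFrame(bp_rows, columns=["genome", "mode", "breakpoint"])
    breakpoints.to_csv(out / "skew_breakpoints.tsv", sep="\t", index=False)
    results["breakpoints"] = breakpoints
    stage("skew")

    # pangenome
    classification = pg.classify_genes(dataset.orthogroups, anchored)
    t1 = table1_analog(classification)
    t1.to_csv(out / "table1_gene_classes.tsv", sep="\t", index=False)
    curves = pg.accumulation_curves(
        dataset.orthogroups, anchored.genome_ids,
        n_permutations=run_config.permutations, seed=run_config.seed,
    )
    heaps = pg.fit_heaps(curves)
    pd.DataFrame(
        {
            "n_genomes": curves.n_genomes,
            "pan_mean": curves.pan_mean,
            "pan_sd": curves.pan_sd,
            "core_mean": curves.core_mean,
            "core_sd": curves.core_sd,
        }
    ).to_csv(out / "accumulation_curves.tsv", sep="\t", index=False)
    results.update(classification=classification, table1=t1, curves=curves, heaps=heaps)
    stage("pangenome")

    # density matrices
    core_ids = [g for g, v in classification.is_core.items() if v]
    paralog_ids = [g for g, v in classification.is_paralog.items() if v]
    virion = set(dataset.virion_genes)
    # transfer virion labels to other genomes through orthogroups
    v_fams = {
        og.og_id
        for og in dataset.orthogroups
        if any(m in virion for ms in og.members.values() for m in ms)
    }
    virion_all = [
        m
        for og in dataset.orthogroups
        if og.og_id in v_fams
        for ms in og.members.values()
        for m in ms
    ]
    for cat, ids in (("core", core_ids), ("paralog", paralog_ids), ("virion", virion_all)):
        dm = rd.density_matrix(
            anchored, ids, window_width=run_config.window_width, step=run_config.window_step
        )
        dm.to_csv(out / f"density_{cat}.tsv", sep="\t")
        results[f"density_{cat}"] = dm
    stage("density")

    # region statistics
    partition = rd.partition_regions(anchored, boundary=run_config.region_boundary)
    results["partition"] = partition
    omega_cmp = rd.compare_regions_numeric(dataset.omega.to_dict(), partition)
    pd.DataFrame([omega_cmp]).to_csv(out / "omega_regions.tsv", sep="\t", index=False)
    results["omega_regions"] = omega_cmp
    gc_rows = [
        {"genome": gid, **rd.region_gc(anchored.genomes[gid], run_config.region_boundary)}
        for gid in anchored.genome_ids
    ]
    pd.DataFrame(gc_rows).to_csv(out / "region_gc.tsv", sep="\t", index=False)
    results["region_gc"] = gc_rows
    stage("regions")

    # annotation QC
    qc = pg.qc_annotation(anchored)
    qc.to_csv(out / "annotation_qc.tsv", sep="\t", index=False)
    results["annotation_qc"] = qc
    stage("qc")

    # expression (skipped with a warning when no count table is available)
    if dataset.counts is None or dataset.counts.empty:
        import warnings

        warnings.warn("no count table available; expression stage skipped")
    else:
        tpm = xp.compute_tpm(dataset.counts, dataset.gene_lengths)
        scaled = xp.scale_profiles(tpm)
        classes = xp.assign_classes(scaled, k=run_config.kmeans_k, seed=run_config.seed)
        summaries = xp.summarize_expression(tpm, partition)["summaries"]
        t2 = table2_analog(classes.classes, partition, summaries)
        t2["table"].to_csv(out / "table2_expression.tsv", sep="\t", index=False)
        classes.classes.rename("class").to_csv(out / "expression_classes.tsv", sep="\t")
        results.update(tpm=tpm, classes=classes, table2=t2, summaries=summaries)
    stage("expression")

    manifest = {
        "seed": run_config.seed,
        "config_hash": hashlib.sha256(
            json.dumps(
                {k: str(v) for k, v in vars(run_config).items()}, sort_keys=True
            ).encode()
        ).hexdigest(),
        "sim_seed": dataset.config.seed,
        "stages": log,
        "heaps": heaps,
        "chi_square_p": results["table2"]["chi_square_p"] if "table2" in results else None,
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    results["manifest"] = manifest
    return results
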