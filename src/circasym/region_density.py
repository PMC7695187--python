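"""Sliding-window gene-category densities and region-wise comparisons.

After anchoring, every gene gets a normalized position (midpoint / genome
length).  The density of a gene category (core, paralog, virion, ...) is
measured in windows sliding circularly on [0, 1) as the fraction of that
window's genes that belong to the category, then each genome row is z-scored
against the median window value so genomes of different sizes and gene counts
share one color scale.  A fixed boundary (default 2/3) partitions each genome
into the gene-dense conserved "core region" (rightmost third) and the
rearrangement-prone remainder, and region-wise statistics (selection pressure
omega, GC content, category overlaps, expression) are compared between the
two.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import stats as cstats
from .genome_io import CircularGenome, GeneRecord, GenomeSet, normalized_position


class DensityError(ValueError):
    pass


def category_density(
    positions: Sequence[float],
    category_mask: Sequence[bool],
    window_width: float = 0.05,
    step: float = 0.01,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-window category fraction over windows sliding circularly on [0, 1).

    Returns (window_centers, densities, empty_window_flags).  Density in a
    window is (#category genes in window) / (#genes in window); empty windows
    get density 0 and are flagged.
    """
    if not 0 < step < window_width:
        raise DensityError("need window_width > step > 0")
    pos = np.asarray(positions, dtype=float) % 1.0
    mask = np.asarray(category_mask, dtype=bool)
    if len(pos) == 0:
        raise DensityError("no genes")
    if len(pos) != len(mask):
        raise DensityError("positions and category mask differ in length")
    centers = np.arange(0.0, 1.0, step)
    dens = np.zeros_like(centers)
    empty = np.zeros_like(centers, dtype=bool)
    half = window_width / 2.0
    for i, c in enumerate(centers):
        d = np.abs(pos - c)
        inside = np.minimum(d, 1.0 - d) < half  # circular window
        n = int(inside.sum())
        if n == 0:
            empty[i] = True
        else:
            dens[i] = mask[inside].sum() / n
    return centers, dens, empty


def zscore_row(raw: Sequence[float], scale: str = "sd") -> np.ndarray:
    """Median-centered z-scores: (d - median(d)) / sd(d).

    ``scale='mad'`` uses the median absolute deviation instead.  A constant
    row maps to all zeros.  Median centering means z values need not sum to
    zero.
    """
    d = np.asarray(raw, dtype=float)
    if len(d) < 5:
        raise DensityError("need at least 5 windows to z-score")
    med = np.median(d)
    if scale == "mad":
        s = np.median(np.abs(d - med)) * 1.4826
    else:
        s = d.std(ddof=1)
    if s == 0:
        return np.zeros_like(d)
    return (d - med) / s


def density_matrix(
    genome_set: GenomeSet,
    category_genes: Iterable[str],
    window_width: float = 0.05,
    step: float = 0.01,
    scale: str = "sd",
) -> pd.DataFrame:
    """Genomes x windows matrix of z-scored category densities.

    ``category_genes`` is the set of gene ids in the category; rows are
    ordered by clade then genome id so related genomes sit together.
    """
    cat = set(category_genes)
    order = sorted(
        genome_set.genome_ids,
        key=lambda g: (genome_set.genomes[g].clade or "", g),
    )
    rows = {}
    centers = None
    for gid in order:
        genome = genome_set.genomes[gid]
        genes = genome_set.genes(gid)
        pos = [normalized_position(g, genome) for g in genes]
        mask = [g.gene_id in cat for g in genes]
        centers, dens, _ = category_density(pos, mask, window_width, step)
        rows[gid] = zscore_row(dens, scale=scale)
    return pd.DataFrame(rows, index=np.round(centers, 6)).T


@dataclass(frozen=True)
class RegionPartition:
    boundary: float
    labels: dict[str, str]  # gene_id -> "core_region" | "other_region"

    def region_genes(self, region: str) -> list[str]:
        return [g for g, r in self.labels.items() if r == region]


def partition_regions(genome_set: GenomeSet, boundary: float = 2.0 / 3.0) -> RegionPartition:
    """Label each gene by whether its normalized midpoint falls at or beyond
    the boundary (core region) or before it."""
    labels = {}
    for gid in genome_set.genome_ids:
        genome = genome_set.genomes[gid]
        for gene in genome_set.genes(gid):
            x = normalized_position(gene, genome)
            labels[gene.gene_id] = "core_region" if x >= boundary else "other_region"
    return RegionPartition(boundary=boundary, labels=labels)


def compare_regions_numeric(
    values_by_gene: Mapping[str, float], partition: RegionPartition
) -> dict:
    """Region-wise mean/sd of a per-gene numeric value (e.g. omega) plus a
    two-sided Mann-Whitney test between the regions."""
    a = [v for g, v in values_by_gene.items() if partition.labels.get(g) == "core_region"]
    b = [v for g, v in values_by_gene.items() if partition.labels.get(g) == "other_region"]
    if len(a) < 2 or len(b) < 2:
        raise DensityError("each region needs at least 2 values")
    res = cstats.mann_whitney(a, b)
    return {
        "core_region_mean": float(np.mean(a)),
        "core_region_sd": float(np.std(a, ddof=1)),
        "core_region_n": len(a),
        "other_region_mean": float(np.mean(b)),
        "other_region_sd": float(np.std(b, ddof=1)),
        "other_region_n": len(b),
        "mann_whitney_p": res.p_value,
    }


def region_gc(genome: CircularGenome, boundary: float = 2.0 / 3.0) -> dict:
    """GC fraction (Ns excluded) of the core region [boundary, 1) and the
    remainder, as percentages rounded to 0.1."""
    L = genome.length
    cut = int(round(boundary * L))
    out = {}
    for name, seg in (("other_region", genome.sequence[:cut]), ("core_region", genome.sequence[cut:])):
        informative = sum(seg.count(b) for b in "ACGT")
        if informative == 0:
            out[name] = None
            continue
        gc = seg.count("G") + seg.count("C")
        out[name] = round(100.0 * gc / informative, 1)
    return out


def category_overlap_enrichment(
    category_a: Iterable[str], category_b: Iterable[str], universe: Iterable[str]
) -> dict:
    """2x2 overlap of two gene categories within a universe, with the fraction
    of a-members among b vs non-b and a two-sided Fisher exact p."""
    universe = set(universe)
    if not universe:
        raise DensityError("empty universe")
    a = set(category_a) & universe
    b = set(category_b) & universe
    t = np.array(
        [
            [len(a & b), len(b - a)],
            [len(a - b), len(universe - a - b)],
        ]
    )
    res = cstats.fisher_exact(t)
    prop_in_b = len(a & b) / len(b) if b else float("nan")
    not_b = universe - b
    prop_out_b = len(a & not_b) / len(not_b) if not_b else float("nan")
    return {
        "table": t.tolist(),
        "prop_a_in_b": prop_in_b,
        "prop_a_outside_b": prop_out_b,
        "odds_ratio": res.statistic,
        "fisher_p": res.p_value,
    }
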