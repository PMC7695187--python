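"""Orthogroup handling, gene classification and pangenome openness.

A gene family ("orthogroup") is core when it has at least one member in every
genome of the set, strain-specific when confined to a single genome (after a
cross-genome similarity back-check that removes false singletons), and a gene
is a paralog when its orthogroup has two or more members in the same genome.
Rarefaction over genome orderings gives pangenome/coregenome accumulation
curves, and a Heap's-law fit of the new-gene counts decides openness
(alpha < 1: open).

Orthogroup tables follow the OrthoFinder ``Orthogroups.tsv`` dialect: first
column orthogroup id, one column per genome, comma-separated gene ids.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import factorial
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import GeneRecord, GenomeSet
from . import stats as cstats


class PangenomeError(ValueError):
    pass


@dataclass
class Orthogroup:
    og_id: str
    members: dict[str, list[str]]  # genome_id -> gene ids

    @property
    def genome_ids(self) -> list[str]:
        return [g for g, genes in self.members.items() if genes]

    @property
    def size(self) -> int:
        return sum(len(v) for v in self.members.values())


@dataclass
class Orthogroups:
    groups: list[Orthogroup]

    def __iter__(self):
        return iter(self.groups)

    def __len__(self) -> int:
        return len(self.groups)

    def gene_to_group(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for og in self.groups:
            for genes in og.members.values():
                for g in genes:
                    if g in out:
                        raise PangenomeError(f"gene {g!r} listed in two orthogroups")
                    out[g] = og.og_id
        return out

    def presence(self, genome_ids: Sequence[str]) -> np.ndarray:
        """Boolean matrix orthogroups x genomes."""
        idx = {g: i for i, g in enumerate(genome_ids)}
        mat = np.zeros((len(self.groups), len(genome_ids)), dtype=bool)
        for r, og in enumerate(self.groups):
            for gid in og.genome_ids:
                mat[r, idx[gid]] = True
        return mat


def read_orthogroups(tsv_path, genome_set: GenomeSet | None = None) -> Orthogroups:
    """Read an ``Orthogroups.tsv``; genes annotated but absent from every row
    are auto-wrapped as singleton orthogroups when a genome set is supplied."""
    df = pd.read_csv(tsv_path, sep="\t", dtype=str).fillna("")
    og_col = df.columns[0]
    genome_cols = list(df.columns[1:])
    groups = []
    for _, row in df.iterrows():
        members = {
            g: [x.strip() for x in row[g].split(",") if x.strip()] for g in genome_cols
        }
        groups.append(Orthogroup(og_id=row[og_col], members=members))
    ogs = Orthogroups(groups)
    seen = set(ogs.gene_to_group())  # also validates single-membership
    if genome_set is not None:
        n_single = 0
        for gid in genome_set.genome_ids:
            for gene in genome_set.genes(gid):
                if gene.gene_id not in seen:
                    n_single += 1
                    ogs.groups.append(
                        Orthogroup(f"OGS{n_single:05d}", {gid: [gene.gene_id]})
                    )
    return ogs


def write_orthogroups(ogs: Orthogroups, tsv_path, genome_ids: Sequence[str]) -> None:
    rows = []
    for og in ogs.groups:
        rows.append(
            [og.og_id] + [", ".join(og.members.get(g, [])) for g in genome_ids]
        )
    pd.DataFrame(rows, columns=["Orthogroup"] + list(genome_ids)).to_csv(
        tsv_path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Minimal protein clustering (shared-k-mer similarity graph)
# ---------------------------------------------------------------------------

def kmer_similarity(a: str, b: str, k: int = 5) -> float:
    """Shared k-mer count normalized by the k-mer count of the shorter
    sequence; 1.0 for identical sequences, ~0 for unrelated ones."""
    if len(a) < k or len(b) < k:
        return 1.0 if a == b else 0.0
    ka = {a[i : i + k] for i in range(len(a) - k + 1)}
    kb = {b[i : i + k] for i in range(len(b) - k + 1)}
    return len(ka & kb) / min(len(ka), len(kb))


def cluster_proteins(
    protein_sequences: Mapping[str, Mapping[str, str]],
    sim_threshold: float = 0.5,
    k: int = 5,
) -> Orthogroups:
    """Single-linkage clustering of proteins into orthogroups.

    ``protein_sequences`` maps genome_id -> {gene_id: aa sequence}.  Edges are
    pairs with shared-k-mer similarity >= threshold; orthogroups are connected
    components, ordered deterministically by their lexicographically smallest
    member.
    """
    items = [
        (gid, gene_id, seq)
        for gid in sorted(protein_sequences)
        for gene_id, seq in sorted(protein_sequences[gid].items())
    ]
    if not items:
        raise PangenomeError("no protein sequences supplied")
    n = len(items)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    kmer_sets = [
        {s[i : i + k] for i in range(len(s) - k + 1)} if len(s) >= k else None
        for _, _, s in items
    ]
    for i in range(n):
        for j in range(i + 1, n):
            si, sj = kmer_sets[i], kmer_sets[j]
            if si is None or sj is None:
                sim = 1.0 if items[i][2] == items[j][2] else 0.0
            else:
                sim = len(si & sj) / min(len(si), len(sj))
            if sim >= sim_threshold:
                union(i, j)
    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    groups = []
    for c, idxs in enumerate(sorted(comps.values(), key=lambda ix: items[ix[0]][1])):
        members: dict[str, list[str]] = {}
        for i in idxs:
            members.setdefault(items[i][0], []).append(items[i][1])
        groups.append(Orthogroup(f"OG{c:05d}", members))
    return Orthogroups(groups)


# ---------------------------------------------------------------------------
# Gene classification (core / strain-specific / ORFan / paralog)
# ---------------------------------------------------------------------------

@dataclass
class GeneClassification:
    is_core: dict[str, bool]
    is_strain_specific: dict[str, bool]
    is_orfan: dict[str, bool]
    is_paralog: dict[str, bool]
    gene_genome: dict[str, str]
    table: pd.DataFrame  # per-genome counts and integer percentages


def _percent(n: int, total: int) -> int:
    if total == 0:
        return 0
    # round half up, matching printed table formatting
    import math

    return int(math.floor(100.0 * n / total + 0.5))


def classify_genes(
    orthogroups: Orthogroups,
    genome_set: GenomeSet,
    cross_hits: Iterable[str] | None = None,
    external_homologs: Iterable[str] | None = None,
) -> GeneClassification:
    """Classify every gene as core / strain-specific / ORFan / paralog.

    ``cross_hits`` optionally lists singleton genes with a similarity hit in
    another genome above the configured proxy threshold (the false-singleton
    filter); those are excluded from the strain-specific set.
    ``external_homologs`` lists strain-specific genes with known homologs
    outside the family; the remainder are ORFans.
    """
    genome_ids = genome_set.genome_ids
    if len(genome_ids) < 2:
        raise PangenomeError("core/strain-specific semantics need >= 2 genomes")
    cross_hits = set(cross_hits or ())
    external_homologs = set(external_homologs or ())
    is_core: dict[str, bool] = {}
    is_ss: dict[str, bool] = {}
    is_orfan: dict[str, bool] = {}
    is_paralog: dict[str, bool] = {}
    gene_genome: dict[str, str] = {}
    all_g = set(genome_ids)
    for og in orthogroups:
        spanned = set(og.genome_ids)
        core = spanned == all_g
        single = len(spanned) == 1
        for gid, genes in og.members.items():
            paralog = len(genes) >= 2
            for g in genes:
                gene_genome[g] = gid
                is_core[g] = core
                is_paralog[g] = paralog
                ss = single and g not in cross_hits
                is_ss[g] = ss
                is_orfan[g] = ss and g not in external_homologs
    rows = []
    for gid in genome_ids:
        genes = [g.gene_id for g in genome_set.genes(gid)]
        total = len(genes)
        n_core = sum(is_core.get(g, False) for g in genes)
        n_ss = sum(is_ss.get(g, False) for g in genes)
        n_par = sum(is_paralog.get(g, False) for g in genes)
        n_single = total - n_par
        rows.append(
            {
                "genome": gid,
                "total": total,
                "core_n": n_core,
                "core_pct": _percent(n_core, total),
                "strain_specific_n": n_ss,
                "strain_specific_pct": _percent(n_ss, total),
                "single_copy_n": n_single,
                "single_copy_pct": _percent(n_single, total),
                "paralog_n": n_par,
                "paralog_pct": _percent(n_par, total),
            }
        )
    return GeneClassification(
        is_core=is_core,
        is_strain_specific=is_ss,
        is_orfan=is_orfan,
        is_paralog=is_paralog,
        gene_genome=gene_genome,
        table=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# Rarefaction curves and Heap's law
# ---------------------------------------------------------------------------

@dataclass
class PangenomeCurves:
    n_genomes: np.ndarray
    pan_mean: np.ndarray
    pan_sd: np.ndarray
    core_mean: np.ndarray
    core_sd: np.ndarray
    pan_per_permutation: np.ndarray  # permutations x N
    core_per_permutation: np.ndarray


def accumulation_curves(
    orthogroups: Orthogroups,
    genome_ids: Sequence[str],
    n_permutations: int = 1000,
    seed: int = 0,
) -> PangenomeCurves:
    """pan(k)/core(k) over genome-order permutations.

    All N! orders are enumerated when N <= 8; otherwise ``n_permutations``
    random orders drawn with a fixed seed.
    """
    N = len(genome_ids)
    if N < 3:
        raise PangenomeError("need >= 3 genomes for accumulation curves")
    mat = orthogroups.presence(genome_ids)  # groups x genomes
    if N <= 8:
        orders = list(itertools.permutations(range(N)))
    else:
        rng = np.random.default_rng(seed)
        orders = [rng.permutation(N) for _ in range(n_permutations)]
    pans = np.zeros((len(orders), N), dtype=int)
    cores = np.zeros((len(orders), N), dtype=int)
    for r, order in enumerate(orders):
        sub = mat[:, list(order)]
        seen = np.cumsum(sub, axis=1) > 0  # present in first k
        allk = np.cumsum(sub, axis=1) == np.arange(1, N + 1)  # present in all first k
        pans[r] = seen.sum(axis=0)
        cores[r] = allk.sum(axis=0)
    return PangenomeCurves(
        n_genomes=np.arange(1, N + 1),
        pan_mean=pans.mean(axis=0),
        pan_sd=pans.std(axis=0, ddof=0),
        core_mean=cores.mean(axis=0),
        core_sd=cores.std(axis=0, ddof=0),
        pan_per_permutation=pans,
        core_per_permutation=cores,
    )


def fit_heaps(curves: PangenomeCurves) -> dict:
    """Fit mean new-orthogroup counts Delta(k) = pan(k) - pan(k-1) to
    kappa * k^(-alpha) by least squares on log-log scale (k >= 2, Delta > 0).

    Returns alpha, kappa and the openness verdict (alpha < 1).  If no new
    orthogroups appear beyond the second genome the pangenome is closed and
    alpha is reported as inf.
    """
    if len(curves.n_genomes) < 4:
        raise PangenomeError("Heap's fit needs >= 4 genomes")
    delta = np.diff(curves.pan_mean)
    k = curves.n_genomes[1:]
    keep = delta > 0
    if keep.sum() < 2:
        return {"alpha": float("inf"), "kappa": 0.0, "open": False}
    slope, intercept = np.polyfit(np.log(k[keep]), np.log(delta[keep]), 1)
    alpha = -float(slope)
    kappa = float(np.exp(intercept))
    return {"alpha": alpha, "kappa": kappa, "open": alpha < 1.0}


# ---------------------------------------------------------------------------
# Gene-order rearrangements between anchored genomes
# ---------------------------------------------------------------------------

def gene_order_rearrangements(
    genes_a: Sequence[GeneRecord],
    genes_b: Sequence[GeneRecord],
    orthogroups: Orthogroups,
    length_a: int,
    length_b: int,
) -> dict:
    """Breakpoint and inversion counts between two anchored genomes.

    Restricted to orthogroups single-copy in both genomes; genome B's ortholog
    order is expressed as a signed permutation of A's (sign = relative
    strand).  A circular adjacency in A that is not preserved (with consistent
    sign) in B counts as one breakpoint; an ortholog on opposite relative
    strands counts as one inversion.  Breakpoint positions are reported as
    normalized midpoints of the A-side junction gene.
    """
    gid_a = genes_a[0].genome_id
    gid_b = genes_b[0].genome_id
    by_id_a = {g.gene_id: g for g in genes_a}
    by_id_b = {g.gene_id: g for g in genes_b}
    shared = []  # (og_id, gene_a, gene_b)
    for og in orthogroups:
        ma, mb = og.members.get(gid_a, []), og.members.get(gid_b, [])
        if len(ma) == 1 and len(mb) == 1 and ma[0] in by_id_a and mb[0] in by_id_b:
            shared.append((og.og_id, by_id_a[ma[0]], by_id_b[mb[0]]))
    if len(shared) < 3:
        raise PangenomeError(f"only {len(shared)} shared single-copy orthologs")
    order_a = sorted(shared, key=lambda t: t[1].start)
    rank_b = {
        og: i
        for i, (og, _, _) in enumerate(sorted(shared, key=lambda t: t[2].start))
    }
    n = len(order_a)
    signs = []
    perm = []
    for og, ga, gb in order_a:
        perm.append(rank_b[og])
        signs.append(1 if ga.strand == gb.strand else -1)
    n_inversions = sum(1 for s in signs if s < 0)
    breakpoints = []
    for i in range(n):  # circular adjacencies in A
        j = (i + 1) % n
        pi, pj = perm[i], perm[j]
        si, sj = signs[i], signs[j]
        # adjacency preserved if consecutive in B (circularly) with consistent
        # orientation: +,+ and pj = pi+1, or -,- and pj = pi-1 (mod n)
        ok = (si == 1 and sj == 1 and pj == (pi + 1) % n) or (
            si == -1 and sj == -1 and pj == (pi - 1) % n
        )
        if not ok:
            breakpoints.append(order_a[i][1].midpoint(length_a) / length_a)
    return {
        "n_shared": n,
        "n_breakpoints": len(breakpoints),
        "breakpoint_positions": breakpoints,
        "n_inversions_signed": n_inversions,
    }


# ---------------------------------------------------------------------------
# Annotation QC
# ---------------------------------------------------------------------------

def qc_annotation(
    genome_set: GenomeSet,
    p_threshold: float = 1e-10,
    min_mean_aa: float = 120.0,
) -> pd.DataFrame:
    """Per-genome ORF statistics with outlier flags.

    Protein length is inferred from the CDS span ((nt / 3) - 1).  Each
    genome's protein lengths are compared to the pool of all other genomes
    with a Mann-Whitney test; genomes that are both significantly different
    and below the mean-length threshold are flagged for exclusion (the pattern
    of an over-called assembly).
    """
    lengths = {
        gid: np.array(
            [g.length(genome_set.genomes[gid].length) / 3.0 - 1 for g in genome_set.genes(gid)]
        )
        for gid in genome_set.genome_ids
    }
    rows = []
    for gid in genome_set.genome_ids:
        own = lengths[gid]
        L = genome_set.genomes[gid].length
        if len(own) == 0:
            rows.append(
                {"genome": gid, "n_genes": 0, "genes_per_kb": 0.0,
                 "mean_protein_aa": float("nan"), "mw_p": float("nan"), "flagged": True}
            )
            continue
        pool = np.concatenate([lengths[o] for o in genome_set.genome_ids if o != gid])
        res = cstats.mann_whitney(own, pool) if len(pool) >= 2 else None
        p = res.p_value if res else float("nan")
        mean_aa = float(own.mean())
        rows.append(
            {
                "genome": gid,
                "n_genes": len(own),
                "genes_per_kb": len(own) / (L / 1000.0),
                "mean_protein_aa": mean_aa,
                "mw_p": p,
                "flagged": bool(p < p_threshold and mean_aa < min_mean_aa),
            }
        )
    return pd.DataFrame(rows)
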