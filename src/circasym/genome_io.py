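"""Topology-aware genome and annotation model.

Circular viral chromosomes are assembled with an arbitrary starting point, so
comparative analyses first rotate every genome to a common single-copy anchor
gene (for *Marseilleviridae*, the major capsid protein).  This module holds the
sequence/annotation containers, FASTA/GFF3 readers and writers, and the
circular-coordinate utilities (rotation, wrap-aware extraction, normalized
positions) that the downstream modules build on.

Internal coordinates are 0-based half-open; GFF3's 1-based inclusive
convention is converted exactly once at the I/O boundary.  A gene crossing the
origin of a circular chromosome is kept as a single record with
``wraps_origin=True`` (start > end in internal coordinates) rather than being
split, so it stays one unit for density and synteny analyses.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from gffutils.feature import feature_from_line

VALID_NUCLEOTIDES = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class GenomeIOError(ValueError):
    """Base class for malformed genome/annotation inputs."""


class EmptyFastaError(GenomeIOError):
    pass


class DuplicateIdError(GenomeIOError):
    pass


class InvalidSequenceError(GenomeIOError):
    pass


class UnknownSeqidError(GenomeIOError):
    pass


class InvalidCoordinatesError(GenomeIOError):
    pass


class AnchorError(GenomeIOError):
    """Anchor gene missing or not single-copy."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CircularGenome:
    """A chromosome with explicit topology and optional clade label."""

    id: str
    sequence: str
    topology: str = "circular"  # or "linear"
    clade: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InvalidSequenceError(f"genome {self.id!r} has empty sequence")
        if self.topology not in ("circular", "linear"):
            raise GenomeIOError(f"unknown topology {self.topology!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"

    def rotated(self, offset: int) -> "CircularGenome":
        """Rotate so that current position ``offset`` becomes position 0."""
        if not self.is_circular:
            raise GenomeIOError(f"cannot rotate linear genome {self.id!r}")
        k = offset % self.length
        return replace(self, sequence=self.sequence[k:] + self.sequence[:k])

    def reverse_complemented(self) -> "CircularGenome":
        return replace(self, sequence=reverse_complement(self.sequence))


@dataclass(frozen=True)
class GeneRecord:
    """A positioned, stranded gene.

    ``start``/``end`` are 0-based half-open.  If ``wraps_origin`` the gene
    covers ``[start, L) + [0, end)`` on a circular chromosome and start > end.
    """

    gene_id: str
    genome_id: str
    start: int
    end: int
    strand: str
    wraps_origin: bool = False
    product: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise InvalidCoordinatesError(
                f"gene {self.gene_id!r}: strand must be '+' or '-'"
            )
        if not self.wraps_origin and not self.start < self.end:
            raise InvalidCoordinatesError(
                f"gene {self.gene_id!r}: start must be < end unless wraps_origin"
            )

    def length(self, genome_length: int) -> int:
        if self.wraps_origin:
            return genome_length - self.start + self.end
        return self.end - self.start

    def midpoint(self, genome_length: int) -> float:
        """Midpoint of the gene arc on the circle, in [0, genome_length)."""
        return (self.start + self.length(genome_length) / 2.0) % genome_length

    def extract(self, genome: CircularGenome) -> str:
        """Coding-strand sequence of the gene (wrap- and strand-aware)."""
        if self.wraps_origin:
            raw = genome.sequence[self.start :] + genome.sequence[: self.end]
        else:
            raw = genome.sequence[self.start : self.end]
        return reverse_complement(raw) if self.strand == "-" else raw


@dataclass
class GenomeSet:
    """Genomes plus their annotations, keyed by genome id."""

    genomes: dict[str, CircularGenome] = field(default_factory=dict)
    annotations: dict[str, list[GeneRecord]] = field(default_factory=dict)

    def add_genome(self, genome: CircularGenome) -> None:
        if genome.id in self.genomes:
            raise DuplicateIdError(f"duplicate genome id {genome.id!r}")
        self.genomes[genome.id] = genome
        self.annotations.setdefault(genome.id, [])

    def add_gene(self, gene: GeneRecord) -> None:
        if gene.genome_id not in self.genomes:
            raise UnknownSeqidError(f"gene {gene.gene_id!r}: unknown genome {gene.genome_id!r}")
        if any(g.gene_id == gene.gene_id for g in self.annotations[gene.genome_id]):
            raise DuplicateIdError(
                f"duplicate gene id {gene.gene_id!r} in genome {gene.genome_id!r}"
            )
        self.annotations[gene.genome_id].append(gene)

    def genes(self, genome_id: str) -> list[GeneRecord]:
        return self.annotations[genome_id]

    def all_genes(self) -> list[GeneRecord]:
        return [g for gid in self.genomes for g in self.annotations[gid]]

    @property
    def genome_ids(self) -> list[str]:
        return list(self.genomes)


# ---------------------------------------------------------------------------
# FASTA / GFF3 I/O
# ---------------------------------------------------------------------------

def read_genomes(
    fasta_path,
    topology: str | Mapping[str, str] = "circular",
    clades: Mapping[str, str] | None = None,
) -> GenomeSet:
    """Read a multi-FASTA into a :class:`GenomeSet` (sequences only).

    ``topology`` is a global flag or a per-record mapping.  Sequences are
    uppercased; only A/C/G/T/N are accepted.
    """
    gs = GenomeSet()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - VALID_NUCLEOTIDES
        if bad:
            raise InvalidSequenceError(
                f"record {rec.id!r} contains non-IUPAC characters: {sorted(bad)}"
            )
        topo = topology[rec.id] if isinstance(topology, Mapping) else topology
        clade = clades.get(rec.id) if clades else None
        gs.add_genome(CircularGenome(id=rec.id, sequence=seq, topology=topo, clade=clade))
    if not gs.genomes:
        raise EmptyFastaError(f"no FASTA records in {fasta_path}")
    return gs


def write_genomes(genome_set: GenomeSet, fasta_path) -> None:
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(g.sequence), id=g.id, description=f"topology={g.topology}")
        for g in genome_set.genomes.values()
    ]
    SeqIO.write(records, str(fasta_path), "fasta")


_WRAP_ATTR = "wraps_origin"


def read_annotations(gff_path, genome_set: GenomeSet, feature_types=("CDS", "gene")) -> GenomeSet:
    """Read GFF3 CDS/gene features into ``genome_set`` (in place).

    Coordinates are converted from 1-based inclusive to 0-based half-open.  A
    feature with end < start is only accepted on a circular genome when it
    carries a ``wraps_origin=true`` attribute.
    """
    with open(gff_path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            feat = feature_from_line(line)
            if feat.featuretype not in feature_types:
                continue
            if feat.seqid not in genome_set.genomes:
                raise UnknownSeqidError(f"GFF seqid {feat.seqid!r} not in genome set")
            genome = genome_set.genomes[feat.seqid]
            wraps = feat.attributes.get(_WRAP_ATTR, ["false"])[0].lower() == "true"
            gene_id = (feat.attributes.get("ID") or feat.attributes.get("Name") or [None])[0]
            if gene_id is None:
                raise GenomeIOError(f"feature without ID attribute: {line!r}")
            product = (feat.attributes.get("product") or [None])[0]
            start0, end0 = feat.start - 1, feat.end
            if wraps:
                if not genome.is_circular:
                    raise InvalidCoordinatesError(
                        f"gene {gene_id!r}: wraps_origin on linear genome"
                    )
                end0 = feat.end  # wrap genes carry end already past the origin
            else:
                if feat.end < feat.start:
                    raise InvalidCoordinatesError(
                        f"gene {gene_id!r}: end < start without wraps_origin flag"
                    )
                if feat.end > genome.length:
                    raise InvalidCoordinatesError(
                        f"gene {gene_id!r}: end {feat.end} beyond genome length {genome.length}"
                    )
            genome_set.add_gene(
                GeneRecord(
                    gene_id=gene_id,
                    genome_id=feat.seqid,
                    start=start0,
                    end=end0,
                    strand=feat.strand,
                    wraps_origin=wraps,
                    product=product,
                )
            )
    return genome_set


def write_annotations(genome_set: GenomeSet, gff_path, feature_type: str = "CDS") -> None:
    """Write annotations back to GFF3 (inverse of :func:`read_annotations`)."""
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid in genome_set.genomes:
            for gene in genome_set.annotations[gid]:
                attrs = [f"ID={gene.gene_id}"]
                if gene.product:
                    attrs.append(f"product={gene.product}")
                if gene.wraps_origin:
                    attrs.append(f"{_WRAP_ATTR}=true")
                fh.write(
                    "\t".join(
                        [
                            gid,
                            "circasym",
                            feature_type,
                            str(gene.start + 1),
                            str(gene.end),
                            ".",
                            gene.strand,
                            ".",
                            ";".join(attrs),
                        ]
                    )
                    + "\n"
                )


def read_metadata(tsv_path) -> tuple[dict[str, str], dict[str, str]]:
    """Sidecar TSV with columns genome_id, topology, clade."""
    import pandas as pd

    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    topo = dict(zip(df["genome_id"], df["topology"]))
    clade = dict(zip(df["genome_id"], df.get("clade", ""))) if "clade" in df else {}
    return topo, clade


# ---------------------------------------------------------------------------
# Circular-coordinate utilities
# ---------------------------------------------------------------------------

def _shift_gene(gene: GeneRecord, offset: int, L: int) -> GeneRecord:
    """Remap a gene after the genome was rotated by ``offset``."""
    start = (gene.start - offset) % L
    length = gene.length(L)
    end_lin = start + length
    if end_lin <= L:
        return replace(gene, start=start, end=end_lin, wraps_origin=False)
    return replace(gene, start=start, end=end_lin - L, wraps_origin=True)


def _flip_gene(gene: GeneRecord, L: int) -> GeneRecord:
    """Remap a gene after the genome was reverse complemented."""
    length = gene.length(L)
    # original arc [start, start+length) maps to [L - start - length, L - start)
    new_start = (L - gene.start - length) % L
    new_end_lin = new_start + length
    strand = "-" if gene.strand == "+" else "+"
    if new_end_lin <= L:
        return replace(gene, start=new_start, end=new_end_lin, strand=strand, wraps_origin=False)
    return replace(gene, start=new_start, end=new_end_lin - L, strand=strand, wraps_origin=True)


@dataclass(frozen=True)
class RotationFrame:
    """Record of the transform applied by :func:`rotate_to_anchor`."""

    offset: int  # rotation applied AFTER any flip, in post-flip coordinates
    flipped: bool


def find_anchor(genes: Sequence[GeneRecord], anchor_gene_id: str | None = None,
                product_regex: str = "major capsid") -> GeneRecord:
    """Locate the single-copy anchor gene by id, falling back to product name."""
    if anchor_gene_id is not None:
        hits = [g for g in genes if g.gene_id == anchor_gene_id]
    else:
        rx = re.compile(product_regex, re.IGNORECASE)
        hits = [g for g in genes if g.product and rx.search(g.product)]
    if not hits:
        raise AnchorError(f"anchor {anchor_gene_id or product_regex!r} not found")
    if len(hits) > 1:
        raise AnchorError(
            f"anchor is multi-copy: candidates {[g.gene_id for g in hits]}"
        )
    return hits[0]


def rotate_to_anchor(
    genome: CircularGenome,
    genes: Sequence[GeneRecord],
    anchor_gene_id: str | None = None,
    product_regex: str = "major capsid",
) -> tuple[CircularGenome, list[GeneRecord], RotationFrame]:
    """Rotate (and flip if needed) a circular genome so the anchor gene starts
    at position 0 on the forward strand.

    Returns the rotated genome, remapped genes, and the applied
    :class:`RotationFrame`, which :func:`undo_rotation` inverts exactly.
    """
    if not genome.is_circular:
        raise GenomeIOError(f"rotate_to_anchor requires a circular genome ({genome.id})")
    anchor = find_anchor(genes, anchor_gene_id, product_regex)
    L = genome.length
    flipped = anchor.strand == "-"
    if flipped:
        genome = genome.reverse_complemented()
        genes = [_flip_gene(g, L) for g in genes]
        anchor = next(g for g in genes if g.gene_id == anchor.gene_id)
    offset = anchor.start
    rotated = genome.rotated(offset)
    new_genes = [_shift_gene(g, offset, L) for g in genes]
    return rotated, new_genes, RotationFrame(offset=offset, flipped=flipped)


def undo_rotation(
    genome: CircularGenome, genes: Sequence[GeneRecord], frame: RotationFrame
) -> tuple[CircularGenome, list[GeneRecord]]:
    L = genome.length
    genome = genome.rotated(-frame.offset)
    genes = [_shift_gene(g, -frame.offset, L) for g in genes]
    if frame.flipped:
        genome = genome.reverse_complemented()
        genes = [_flip_gene(g, L) for g in genes]
    return genome, list(genes)


def normalized_position(gene: GeneRecord, genome: CircularGenome) -> float:
    """Wrap-aware gene midpoint as a fraction of genome length, in [0, 1)."""
    if gene.genome_id != genome.id:
        raise GenomeIOError(
            f"gene {gene.gene_id!r} does not belong to genome {genome.id!r}"
        )
    return gene.midpoint(genome.length) / genome.length


def circular_distance(a: float, b: float, L: float = 1.0) -> float:
    """Shortest distance between two positions on a circle of circumference L."""
    d = abs(a - b) % L
    return min(d, L - d)
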