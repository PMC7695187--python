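import numpy as np
import pytest

from circasym import genome_io as gio
from circasym.genome_io import (
    CircularGenome,
    DuplicateIdError,
    GeneRecord,
    InvalidCoordinatesError,
    InvalidSequenceError,
    UnknownSeqidError,
    circular_distance,
    normalized_position,
    read_annotations,
    read_genomes,
    reverse_complement,
    rotate_to_anchor,
    undo_rotation,
    write_annotations,
)

from conftest import make_genome_set, random_sequence


def write_fasta(path, records):
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")


class TestReadGenomes:
    def test_single_record_circular(self, tmp_path):
        p = tmp_path / "g.fasta"
        write_fasta(p, [("g1", "ACGT" * 15)])
        gs = read_genomes(p, topology="circular")
        assert gs.genomes["g1"].length == 60
        assert gs.genomes["g1"].is_circular

    def test_lowercase_normalized(self, tmp_path):
        p = tmp_path / "g.fasta"
        write_fasta(p, [("g1", "acgt")])
        assert read_genomes(p).genomes["g1"].sequence == "ACGT"

    def test_duplicate_ids_rejected(self, tmp_path):
        p = tmp_path / "g.fasta"
        write_fasta(p, [("g1", "ACGT"), ("g1", "TTTT")])
        with pytest.raises(DuplicateIdError):
            read_genomes(p)

    def test_non_iupac_rejected(self, tmp_path):
        p = tmp_path / "g.fasta"
        write_fasta(p, [("g1", "ACXT")])
        with pytest.raises(InvalidSequenceError):
            read_genomes(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "g.fasta"
        p.write_text("")
        with pytest.raises(gio.EmptyFastaError):
            read_genomes(p)


class TestReadAnnotations:
    def _gs(self, L=60):
        return make_genome_set([("g1", "ACGTA" * (L // 5), "circular", [])])

    def _gff(self, tmp_path, lines):
        p = tmp_path / "a.gff3"
        p.write_text("##gff-version 3\n" + "\n".join(lines) + "\n")
        return p

    def test_coordinate_conversion(self, tmp_path):
        gs = self._gs()
        p = self._gff(tmp_path, ["g1\tx\tCDS\t1\t9\t.\t+\t.\tID=a"])
        read_annotations(p, gs)
        g = gs.genes("g1")[0]
        assert (g.start, g.end) == (0, 9)

    def test_unknown_seqid(self, tmp_path):
        gs = self._gs()
        p = self._gff(tmp_path, ["nope\tx\tCDS\t1\t9\t.\t+\t.\tID=a"])
        with pytest.raises(UnknownSeqidError):
            read_annotations(p, gs)

    def test_wrap_gene_splice_matches_bruteforce(self, tmp_path):
        # 0-based arc [55, 60) + [0, 5): emitted in GFF as start=56, end=5
        gs = self._gs()
        genome = gs.genomes["g1"]
        p = self._gff(tmp_path, ["g1\tx\tCDS\t56\t5\t.\t+\t.\tID=w;wraps_origin=true"])
        read_annotations(p, gs)
        g = gs.genes("g1")[0]
        assert g.wraps_origin and g.length(60) == 10
        # brute-force oracle: walk the circle position by position
        expected = "".join(genome.sequence[(55 + i) % 60] for i in range(10))
        assert g.extract(genome) == expected

    def test_end_before_start_without_flag_rejected(self, tmp_path):
        gs = self._gs()
        p = self._gff(tmp_path, ["g1\tx\tCDS\t56\t5\t.\t+\t.\tID=w"])
        with pytest.raises(InvalidCoordinatesError):
            read_annotations(p, gs)

    def test_roundtrip_bit_exact(self, tmp_path):
        gs = make_genome_set(
            [
                (
                    "g1",
                    "ACGTA" * 12,
                    "circular",
                    [("a", 0, 9, "+"), ("b", 20, 35, "-"), ("w", 55, 5, "+", True)],
                )
            ]
        )
        out = tmp_path / "out.gff3"
        write_annotations(gs, out)
        gs2 = make_genome_set([("g1", "ACGTA" * 12, "circular", [])])
        read_annotations(out, gs2)
        orig = {(g.gene_id, g.start, g.end, g.strand, g.wraps_origin) for g in gs.genes("g1")}
        back = {(g.gene_id, g.start, g.end, g.strand, g.wraps_origin) for g in gs2.genes("g1")}
        assert orig == back


class TestRotation:
    def test_anchor_already_at_zero_is_identity(self):
        gs = make_genome_set([("g1", "ACGTA" * 20, "circular", [("mcp", 0, 30, "+")])])
        genome, genes, frame = rotate_to_anchor(gs.genomes["g1"], gs.genes("g1"), "mcp")
        assert genome.sequence == gs.genomes["g1"].sequence
        assert genes[0].start == 0 and frame.offset == 0 and not frame.flipped

    def test_plus_strand_anchor_shifts_all_coordinates(self):
        rng = np.random.default_rng(0)
        seq = random_sequence(rng, 100)
        gs = make_genome_set(
            [("g1", seq, "circular", [("mcp", 40, 70, "+"), ("b", 10, 20, "-")])]
        )
        genome, genes, frame = rotate_to_anchor(gs.genomes["g1"], gs.genes("g1"), "mcp")
        by_id = {g.gene_id: g for g in genes}
        assert by_id["mcp"].start == 0
        assert by_id["b"].start == (10 - 40) % 100
        assert genome.sequence == seq[40:] + seq[:40]

    def test_minus_strand_anchor_reverse_complements(self):
        rng = np.random.default_rng(1)
        seq = random_sequence(rng, 120)
        gs = make_genome_set([("g1", seq, "circular", [("mcp", 30, 60, "-")])])
        genome, genes, _ = rotate_to_anchor(gs.genomes["g1"], gs.genes("g1"), "mcp")
        anchor = genes[0]
        assert anchor.strand == "+" and anchor.start == 0
        # oracle: the anchor's sequence in the new frame must equal the
        # reverse complement of the original slice
        assert genome.sequence[:30] == reverse_complement(seq[30:60])

    def test_rotation_invertible_byte_for_byte(self):
        rng = np.random.default_rng(2)
        for trial in range(10):
            L = int(rng.integers(50, 200))
            seq = random_sequence(rng, L)
            start = int(rng.integers(0, L - 10))
            strand = "+" if rng.random() < 0.5 else "-"
            gs = make_genome_set(
                [("g1", seq, "circular", [("mcp", start, start + 9, strand)])]
            )
            genome, genes, frame = rotate_to_anchor(gs.genomes["g1"], gs.genes("g1"), "mcp")
            back_g, back_genes = undo_rotation(genome, genes, frame)
            assert back_g.sequence == seq
            assert back_genes[0].start == start and back_genes[0].strand == strand

    def test_pairwise_circular_distances_preserved(self):
        rng = np.random.default_rng(3)
        L = 500
        seq = random_sequence(rng, L)
        genes = [("mcp", 100, 130, "+")] + [
            (f"g{i}", int(s), int(s) + 20, "+") for i, s in enumerate(rng.choice(400, 5) + 140)
        ]
        gs = make_genome_set([("g1", seq, "circular", genes)])
        orig = gs.genes("g1")
        genome, rotated, _ = rotate_to_anchor(gs.genomes["g1"], orig, "mcp")
        for a, b in zip(orig, orig[1:]):
            ra = next(g for g in rotated if g.gene_id == a.gene_id)
            rb = next(g for g in rotated if g.gene_id == b.gene_id)
            d0 = circular_distance(a.midpoint(L), b.midpoint(L), L)
            d1 = circular_distance(ra.midpoint(L), rb.midpoint(L), L)
            assert d0 == pytest.approx(d1, abs=1e-9)

    def test_multicopy_anchor_rejected(self):
        gs = make_genome_set(
            [("g1", "ACGTA" * 20, "circular", [("m1", 0, 9, "+"), ("m2", 20, 29, "+")])]
        )
        genes = gs.genes("g1")
        genes_named = [
            g.__class__(**{**g.__dict__, "product": "major capsid protein"}) for g in genes
        ]
        with pytest.raises(gio.AnchorError):
            rotate_to_anchor(gs.genomes["g1"], genes_named)


class TestNormalizedPosition:
    @pytest.mark.parametrize(
        "start,end,wraps,expected",
        [(0, 10, False, 0.05), (95, 5, True, 0.0), (50, 100, False, 0.75)],
    )
    def test_examples(self, start, end, wraps, expected):
        gs = make_genome_set(
            [("g1", "ACGTA" * 20, "circular", [("a", start, end, "+", wraps)])]
        )
        got = normalized_position(gs.genes("g1")[0], gs.genomes["g1"])
        assert got == pytest.approx(expected)

    def test_wrap_midpoint_matches_enumeration(self):
        # oracle: enumerate the positions covered by the arc and find its
        # middle position on the circle
        gs = make_genome_set([("g1", "ACGTA" * 20, "circular", [("a", 90, 14, "+", True)])])
        gene = gs.genes("g1")[0]
        covered = [(90 + i) % 100 for i in range(gene.length(100))]
        mid_oracle = covered[len(covered) // 2] / 100.0
        assert normalized_position(gene, gs.genomes["g1"]) == pytest.approx(mid_oracle)
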