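import itertools

import numpy as np
import pandas as pd
import pytest

from circasym.genome_io import GeneRecord
from circasym.pangenome import (
    Orthogroup,
    Orthogroups,
    PangenomeCurves,
    PangenomeError,
    accumulation_curves,
    classify_genes,
    cluster_proteins,
    fit_heaps,
    gene_order_rearrangements,
    qc_annotation,
    read_orthogroups,
    write_orthogroups,
)

from conftest import make_genome_set


def og_table(tmp_path, rows, genomes=("A", "B")):
    p = tmp_path / "og.tsv"
    header = "Orthogroup\t" + "\t".join(genomes)
    p.write_text(header + "\n" + "\n".join(rows) + "\n")
    return p


class TestReadOrthogroups:
    def test_dialect_parse(self, tmp_path):
        p = og_table(tmp_path, ["OG1\ta1, a2\tb1"])
        ogs = read_orthogroups(p)
        assert ogs.groups[0].members == {"A": ["a1", "a2"], "B": ["b1"]}

    def test_empty_cell_means_absent(self, tmp_path):
        p = og_table(tmp_path, ["OG1\ta1\t"])
        ogs = read_orthogroups(p)
        assert ogs.groups[0].members["B"] == []

    def test_unlisted_gene_becomes_singleton(self, tmp_path):
        gs = make_genome_set(
            [
                ("A", "ACGT" * 30, "circular", [("a1", 0, 9, "+"), ("a2", 20, 29, "+")]),
                ("B", "ACGT" * 30, "circular", [("b1", 0, 9, "+")]),
            ]
        )
        p = og_table(tmp_path, ["OG1\ta1\tb1"])
        ogs = read_orthogroups(p, gs)
        g2og = ogs.gene_to_group()
        assert g2og["a2"].startswith("OGS")

    def test_double_listing_rejected(self, tmp_path):
        p = og_table(tmp_path, ["OG1\ta1\t", "OG2\ta1\t"])
        with pytest.raises(PangenomeError):
            read_orthogroups(p).gene_to_group()

    def test_roundtrip(self, tmp_path, small_dataset):
        out = tmp_path / "og_out.tsv"
        write_orthogroups(small_dataset.orthogroups, out, small_dataset.genome_set.genome_ids)
        back = read_orthogroups(out)
        assert back.gene_to_group() == small_dataset.orthogroups.gene_to_group()


class TestClusterProteins:
    def test_identical_proteins_co_cluster(self):
        seqs = {"A": {"a1": "MKTLLVVAAA"}, "B": {"b1": "MKTLLVVAAA"}}
        ogs = cluster_proteins(seqs, sim_threshold=0.5)
        assert len(ogs) == 1

    def test_dissimilar_proteins_are_singletons(self):
        seqs = {"A": {"a1": "MKTLLVVAAAGG", "a2": "WWPPQQEERRSS", "a3": "HHFFYYNNDDCC"}}
        ogs = cluster_proteins(seqs, sim_threshold=0.5)
        assert len(ogs) == 3

    def test_recovers_planted_families(self):
        """Clustering of translated simulated proteins matches the planted
        family labels (adjusted Rand >= 0.95).

        Shared-k-mer similarity is a coarse homology proxy, sensitive at
        shallow divergence only, so recovery is checked in that regime
        (deeply diverged orthologs need alignment-based search, which is out
        of scope)."""
        from sklearn.metrics import adjusted_rand_score

        from circasym.synthetic_data import SimulationConfig, generate, get_proteins

        ds = generate(
            SimulationConfig(
                n_clades=3, strains_per_clade=(1, 1, 1), genome_length=72_000,
                n_genes=100, clade_divergence=0.01, strain_divergence=0.005,
                paralog_divergence=0.01, seed=21,
            )
        )
        prot = get_proteins(ds)
        ogs = cluster_proteins(prot, sim_threshold=0.5)
        small_dataset = ds
        g2og = ogs.gene_to_group()
        genes = sorted(g2og)
        truth = [small_dataset.truth.family[g] for g in genes]
        pred = [g2og[g] for g in genes]
        assert adjusted_rand_score(truth, pred) >= 0.95


class TestClassifyGenes:
    def _toy(self):
        gs = make_genome_set(
            [
                ("A", "ACGT" * 30, "circular",
                 [("a1", 0, 9, "+"), ("a2", 20, 29, "+"), ("a3", 40, 49, "+")]),
                ("B", "ACGT" * 30, "circular", [("b1", 0, 9, "+"), ("b2", 20, 29, "+")]),
                ("C", "ACGT" * 30, "circular", [("c1", 0, 9, "+")]),
            ]
        )
        ogs = Orthogroups(
            [
                Orthogroup("OG1", {"A": ["a1", "a2"], "B": ["b1"], "C": ["c1"]}),
                Orthogroup("OG2", {"A": ["a3"]}),
                Orthogroup("OG3", {"B": ["b2"]}),
            ]
        )
        return gs, ogs

    def test_core_and_paralog_definitions(self):
        gs, ogs = self._toy()
        cls = classify_genes(ogs, gs)
        assert cls.is_core["a1"] and cls.is_core["b1"] and cls.is_core["c1"]
        assert cls.is_paralog["a1"] and cls.is_paralog["a2"]
        assert not cls.is_paralog["b1"]
        assert cls.is_strain_specific["a3"] and cls.is_strain_specific["b2"]

    def test_false_singleton_filter(self):
        gs, ogs = self._toy()
        cls = classify_genes(ogs, gs, cross_hits={"a3"})
        assert not cls.is_strain_specific["a3"]
        assert cls.is_strain_specific["b2"]

    def test_orfan_requires_no_external_homolog(self):
        gs, ogs = self._toy()
        cls = classify_genes(ogs, gs, external_homologs={"b2"})
        assert cls.is_orfan["a3"] and not cls.is_orfan["b2"]

    def test_single_plus_paralog_partition(self):
        gs, ogs = self._toy()
        t = classify_genes(ogs, gs).table.set_index("genome")
        for g in ("A", "B", "C"):
            assert t.loc[g, "single_copy_n"] + t.loc[g, "paralog_n"] == t.loc[g, "total"]

    def test_invariant_to_genome_order(self, small_dataset):
        gs = small_dataset.genome_set
        cls1 = classify_genes(small_dataset.orthogroups, gs)
        # rebuild the genome set in reversed order
        from circasym.genome_io import GenomeSet

        rev = GenomeSet()
        for gid in reversed(gs.genome_ids):
            rev.add_genome(gs.genomes[gid])
            for g in gs.genes(gid):
                rev.add_gene(g)
        cls2 = classify_genes(small_dataset.orthogroups, rev)
        assert cls1.is_core == cls2.is_core
        assert cls1.is_strain_specific == cls2.is_strain_specific

    def test_recovers_planted_fractions(self, small_dataset):
        cls = classify_genes(small_dataset.orthogroups, small_dataset.genome_set)
        t = cls.table
        core_frac = t["core_n"].sum() / t["total"].sum()
        ss_frac = t["strain_specific_n"].sum() / t["total"].sum()
        assert core_frac == pytest.approx(small_dataset.config.core_fraction, abs=0.02)
        assert ss_frac == pytest.approx(small_dataset.config.strain_specific_rate, abs=0.02)


class TestAccumulationCurves:
    def _ogs(self, contents):
        groups = []
        for i, present in enumerate(contents):
            groups.append(Orthogroup(f"OG{i}", {g: [f"{g}_x{i}"] for g in present}))
        return Orthogroups(groups)

    def test_identical_contents_constant_curves(self):
        genomes = ["A", "B", "C", "D"]
        ogs = self._ogs([genomes] * 5)
        c = accumulation_curves(ogs, genomes)
        assert np.allclose(c.pan_mean, 5) and np.allclose(c.core_mean, 5)

    def test_disjoint_contents(self):
        genomes = ["A", "B", "C"]
        ogs = self._ogs([["A"]] * 4 + [["B"]] * 4 + [["C"]] * 4)
        c = accumulation_curves(ogs, genomes)
        assert np.allclose(c.pan_mean, [4, 8, 12])
        assert np.allclose(c.core_mean[1:], 0)

    def test_monotonicity_per_permutation(self, small_dataset):
        c = accumulation_curves(
            small_dataset.orthogroups, small_dataset.genome_set.genome_ids, seed=3
        )
        assert (np.diff(c.pan_per_permutation, axis=1) >= 0).all()
        assert (np.diff(c.core_per_permutation, axis=1) <= 0).all()
        assert (c.pan_per_permutation >= c.core_per_permutation).all()


class TestHeaps:
    def _curves_from_pan(self, pan):
        pan = np.asarray(pan, float)
        n = len(pan)
        z = np.zeros(n)
        return PangenomeCurves(
            n_genomes=np.arange(1, n + 1), pan_mean=pan, pan_sd=z,
            core_mean=z, core_sd=z,
            pan_per_permutation=pan[None, :], core_per_permutation=z[None, :],
        )

    def test_exact_power_law_recovered(self):
        k = np.arange(2, 13)
        delta = 100.0 * k ** (-0.8)
        pan = np.concatenate([[300.0], 300.0 + np.cumsum(delta)])
        fit = fit_heaps(self._curves_from_pan(pan))
        assert fit["alpha"] == pytest.approx(0.8, abs=1e-6)
        assert fit["kappa"] == pytest.approx(100.0, rel=1e-6)
        assert fit["open"]

    def test_constant_novelty_is_open_with_alpha_zero(self):
        pan = 300.0 + 25.0 * np.arange(12)
        fit = fit_heaps(self._curves_from_pan(pan))
        assert fit["alpha"] == pytest.approx(0.0, abs=1e-9)
        assert fit["open"]

    def test_saturated_pangenome_reported_closed(self):
        pan = np.array([300.0, 305.0, 305.0, 305.0, 305.0])
        fit = fit_heaps(self._curves_from_pan(pan))
        assert not fit["open"] and fit["alpha"] == float("inf")


class TestGeneOrderRearrangements:
    def _pair(self, order_b, strands_b=None):
        n = len(order_b)
        genes_a, genes_b, groups = [], [], []
        strands_b = strands_b or ["+"] * n
        for i in range(n):
            genes_a.append(GeneRecord(f"a{i}", "A", i * 100, i * 100 + 50, "+"))
        for pos, fam in enumerate(order_b):
            genes_b.append(
                GeneRecord(f"b{fam}", "B", pos * 100, pos * 100 + 50, strands_b[pos])
            )
        for i in range(n):
            groups.append(Orthogroup(f"OG{i}", {"A": [f"a{i}"], "B": [f"b{i}"]}))
        return genes_a, genes_b, Orthogroups(groups), n * 100

    def test_identical_orders_have_no_breakpoints(self):
        ga, gb, ogs, L = self._pair(list(range(8)))
        r = gene_order_rearrangements(ga, gb, ogs, L, L)
        assert r["n_breakpoints"] == 0 and r["n_inversions_signed"] == 0

    def test_single_reversed_block(self):
        # block 2..4 reversed (with strand flips) -> 2 breakpoints on the
        # circle, 3 inverted genes; oracle is the brute-force adjacency check
        order = [0, 1, 4, 3, 2, 5, 6, 7]
        strands = ["+", "+", "-", "-", "-", "+", "+", "+"]
        ga, gb, ogs, L = self._pair([0, 1, 2, 3, 4, 5, 6, 7])
        gb = [
            GeneRecord(f"b{fam}", "B", pos * 100, pos * 100 + 50, strands[pos])
            for pos, fam in enumerate(order)
        ]
        r = gene_order_rearrangements(ga, gb, ogs, L, L)
        assert r["n_breakpoints"] == 2
        assert r["n_inversions_signed"] == 3

    def test_too_few_shared_orthologs_rejected(self):
        ga, gb, ogs, L = self._pair(list(range(2)))
        with pytest.raises(PangenomeError):
            gene_order_rearrangements(ga[:2], gb[:2], ogs, L, L)

    def test_simulated_breakpoints_confined_to_rearranged_region(self, small_dataset):
        from circasym.genome_io import rotate_to_anchor

        ds = small_dataset
        gids = ds.genome_set.genome_ids
        a, b = gids[0], gids[-1]  # different clades
        anch = {}
        for gid in (a, b):
            g, genes, _ = rotate_to_anchor(ds.genome_set.genomes[gid], ds.genome_set.genes(gid))
            anch[gid] = (g, genes)
        r = gene_order_rearrangements(
            anch[a][1], anch[b][1], ds.orthogroups, anch[a][0].length, anch[b][0].length
        )
        pos = np.array(r["breakpoint_positions"])
        assert r["n_breakpoints"] >= 2
        assert (pos < 2 / 3).mean() >= 0.8


class TestQcAnnotation:
    def _gs(self, lengths_by_genome, L=6000):
        entries = []
        for gid, lengths in lengths_by_genome.items():
            genes = []
            pos = 0
            for i, ln in enumerate(lengths):
                genes.append((f"{gid}_g{i}", pos, pos + ln, "+"))
                pos += ln + 10
            entries.append((gid, "ACGT" * (L // 4), "circular", genes))
        return make_genome_set(entries)

    def test_homogeneous_genomes_unflagged(self):
        rng = np.random.default_rng(12)
        lengths = {g: (rng.integers(100, 200, size=60) * 3).tolist() for g in "ABCD"}
        gs = self._gs(lengths, L=40000)
        qc = qc_annotation(gs)
        assert not qc["flagged"].any()

    def test_halved_lengths_flagged(self):
        rng = np.random.default_rng(13)
        lengths = {g: (rng.integers(100, 200, size=80) * 3).tolist() for g in "ABC"}
        lengths["D"] = (rng.integers(30, 60, size=80) * 3).tolist()
        gs = self._gs(lengths, L=60000)
        qc = qc_annotation(gs).set_index("genome")
        assert qc.loc["D", "flagged"]
        assert not qc.loc[["A", "B", "C"], "flagged"].any()

    def test_empty_genome_flagged(self):
        lengths = {"A": [300] * 30, "B": [300] * 30, "C": []}
        gs = self._gs(lengths, L=12000)
        qc = qc_annotation(gs).set_index("genome")
        assert qc.loc["C", "flagged"] and qc.loc["C", "n_genes"] == 0
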