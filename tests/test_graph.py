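"""Codon-based de Bruijn graph construction, simplification, spelling."""

import numpy as np
import pytest

from cdg.graph import (
    CodonGraph, ConfigurationError, build_codon_graph, build_traditional_graph,
    count_nodes_edges, read_gfa,
)
from cdg.simulate import CODON_TABLES, make_cds


def path_graph(seqs, k=6):
    return build_codon_graph(seqs, k)


class TestConstruction:
    def test_sliding_window_by_hand(self):
        g = build_codon_graph(["ATGGCCGCAAAA"], k=6)
        assert set(g.g.nodes) == {"ATGGCC", "GCCGCA", "GCAAAA"}
        assert set(g.g.edges) == {("ATGGCC", "GCCGCA"), ("GCCGCA", "GCAAAA")}
        assert count_nodes_edges(g) == (3, 2)

    def test_codon_count_formula(self, rng):
        cds = make_cds(300, seed=rng)
        g = build_codon_graph([cds], k=27)
        assert count_nodes_edges(g) == ((300 - 27) // 3 + 1, (300 - 27) // 3)

    def test_traditional_count_formula(self, rng):
        cds = make_cds(300, seed=rng)
        g = build_traditional_graph([cds], k=27)
        assert count_nodes_edges(g) == (300 - 27 + 1, 300 - 27)

    def test_duplicate_orf_doubles_multiplicity(self):
        g = build_codon_graph(["ATGGCCGCAAAA", "ATGGCCGCAAAA"], k=6)
        assert count_nodes_edges(g) == (3, 2)
        assert g.g.nodes["ATGGCC"]["mult"] == 2
        assert g.g["ATGGCC"]["GCCGCA"]["mult"] == 2

    def test_short_orf_contributes_nothing(self):
        g = build_codon_graph(["ATGGCC"], k=9)
        assert count_nodes_edges(g) == (0, 0)

    def test_homopolymer_self_loop(self):
        g = build_traditional_graph(["A" * 40], k=5)
        assert count_nodes_edges(g) == (1, 1)
        assert g.g.has_edge("AAAAA", "AAAAA")

    def test_k_not_codon_multiple_rejected(self):
        with pytest.raises(ConfigurationError):
            CodonGraph(k=28, step=3)

    def test_disjoint_paths_additive(self):
        a = make_cds(18, seed=1)
        b = "".join("T" if c == "A" else c for c in make_cds(18, seed=2))
        g = build_codon_graph([a, b], k=6)
        na = (18 - 6) // 3 + 1
        if not (set(a[i:i + 6] for i in range(0, 13, 3))
                & set(b[i:i + 6] for i in range(0, 13, 3))):
            assert count_nodes_edges(g) == (2 * na, 2 * (na - 1))


class TestSizeReduction:
    def test_ratio_approaches_one_third(self):
        rng = np.random.default_rng(12)
        cdss = [make_cds(int(rng.integers(200, 400)) * 3,
                         CODON_TABLES["human_like"], rng) for _ in range(30)]
        cg = build_codon_graph(cdss, 27)
        tg = build_traditional_graph(cdss, 27)
        n1, e1 = cg.counts()
        n2, e2 = tg.counts()
        assert (n1 + e1) / (n2 + e2) == pytest.approx(1 / 3, abs=0.02)

    def test_single_sequence_exact_ratio(self, rng):
        cds = make_cds(300, seed=rng)
        cg, tg = build_codon_graph([cds], 27), build_traditional_graph([cds], 27)
        assert sum(cg.counts()) == 92 + 91
        assert sum(tg.counts()) == 274 + 273
        assert sum(cg.counts()) / sum(tg.counts()) == pytest.approx(0.3346, abs=1e-4)


class TestTips:
    def _path_with_branch(self, rng, n_nodes=20, branch_nodes=2):
        cds = make_cds(6 + 3 * (n_nodes - 1), seed=rng)
        g = build_codon_graph([cds], k=6)
        assert g.g.number_of_nodes() == n_nodes
        # attach a short side branch at an interior node
        anchor = cds[27:33]
        g.add_sequence(anchor + make_cds(3 * branch_nodes, seed=99))
        assert g.g.number_of_nodes() == n_nodes + branch_nodes
        return g, cds, n_nodes

    def test_short_branch_removed(self, rng):
        g, cds, n = self._path_with_branch(rng)
        # branch spells 6 + 3*1 ... chain of 2 extra nodes spells 9 bp < 12
        removed = g.trim_tips(max_tip_bp=12)
        assert removed == 1
        assert g.g.number_of_nodes() == n
        assert g.classify_components().class_counts()["simple"] == 1

    def test_simple_path_unchanged(self, rng):
        cds = make_cds(60, seed=rng)
        g = build_codon_graph([cds], k=6)
        before = set(g.g.nodes)
        assert g.trim_tips() == 0
        assert set(g.g.nodes) == before

    def test_boundary_exact_2k_retained(self, rng):
        # branch spelling exactly 2k bp survives (strictly-shorter rule)
        g, cds, n = self._path_with_branch(rng, branch_nodes=3)  # spells 6+3*2=12
        assert g.trim_tips(max_tip_bp=12) == 0
        assert g.g.number_of_nodes() == n + 3

    def test_idempotent_at_fixpoint(self, rng):
        g, _, _ = self._path_with_branch(rng)
        g.trim_tips()
        assert g.trim_tips() == 0


class TestBubbles:
    def _diamond(self, rng, mutate_at=30):
        # one substitution mid-CDS: parallel arms spell 12+3*5=27 bp at
        # identity 26/27 ~ 0.963, above the 0.95 merge cutoff
        cds = make_cds(90, seed=rng)
        alt = list(cds)
        base = alt[mutate_at]
        alt[mutate_at] = {"A": "C", "C": "G", "G": "T", "T": "A"}[base]
        g = build_codon_graph([cds, "".join(alt)], k=12)
        return g, cds, "".join(alt)

    def test_near_identical_paths_merged(self, rng):
        g, cds, alt = self._diamond(rng)
        merged = g.merge_bubbles(min_identity=0.95)
        assert merged >= 1
        unitigs = g.unitigs()
        assert cds in unitigs or alt in unitigs
        assert not (cds in unitigs and alt in unitigs)

    def test_divergent_paths_kept(self, rng):
        cds = make_cds(90, seed=rng)
        alt = cds[:15] + make_cds(30, seed=7) + cds[45:]
        g = build_codon_graph([cds, alt], k=12)
        before = g.counts()
        if g.merge_bubbles(min_identity=0.99) == 0:
            assert g.counts() == before

    def test_no_branch_unchanged(self, rng):
        cds = make_cds(60, seed=rng)
        g = build_codon_graph([cds], k=6)
        assert g.merge_bubbles() == 0

    def test_classification_diamond_is_bubble(self, rng):
        g, _, _ = self._diamond(rng)
        counts = g.classify_components().class_counts()
        assert counts["bubbles"] == 1 and counts["simple"] == 0

    def test_simplify_reaches_fixpoint(self, rng):
        g, _, _ = self._diamond(rng)
        g.simplify()
        assert g.simplify() == (0, 0)


class TestClassification:
    def test_linear_path_simple(self, rng):
        g = build_codon_graph([make_cds(60, seed=rng)], k=6)
        assert g.classify_components().class_counts() == {
            "simple": 1, "tips": 0, "bubbles": 0}

    def test_side_branch_is_tip_class(self, rng):
        cds = make_cds(60, seed=rng)
        g = build_codon_graph([cds], k=6)
        anchor = cds[12:18]
        g.g.add_node(anchor[3:] + "GGG", mult=1)
        g.g.add_edge(anchor, anchor[3:] + "GGG", mult=1)
        assert g.classify_components().class_counts()["tips"] == 1

    def test_report_totals_consistent(self, rng):
        g = build_codon_graph([make_cds(60, seed=rng), make_cds(60, seed=1)], k=6)
        report = g.classify_components()
        assert sum(report.class_counts().values()) == report.n_components
        assert sum(n for n, _, _ in report.components) == g.g.number_of_nodes()


class TestUnitigs:
    def test_single_path_spelling(self, rng):
        cds = make_cds(90, seed=rng)
        g = build_codon_graph([cds], k=6)
        assert g.unitigs() == [cds]

    def test_y_fork_three_contigs(self, rng):
        stem = make_cds(30, seed=rng)
        a = stem + make_cds(30, seed=5)
        b = stem + make_cds(30, seed=6)
        g = build_codon_graph([a, b], k=6)
        unis = g.unitigs()
        if a[30:36] != b[30:36]:  # genuinely forked
            assert len(unis) == 3

    def test_lossless_rebuild(self, rng):
        seqs = [make_cds(90, seed=rng), make_cds(60, seed=8)]
        g = build_codon_graph(seqs, k=6)
        rebuilt = build_codon_graph(g.unitigs(), k=6)
        assert set(rebuilt.g.nodes) == set(g.g.nodes)


class TestGfa:
    def test_round_trip(self, tmp_path, rng):
        g = build_codon_graph([make_cds(60, seed=rng)], k=6)
        path = tmp_path / "g.gfa"
        g.export_gfa(path)
        back = read_gfa(path)
        assert back.counts() == g.counts()
        assert set(back.g.nodes) == set(g.g.nodes)
        assert set(back.g.edges) == set(g.g.edges)

    def test_line_counts(self, tmp_path):
        g = build_codon_graph(["ATGGCCGCAAAA"], k=6)
        path = tmp_path / "g.gfa"
        g.export_gfa(path)
        lines = path.read_text().splitlines()
        assert sum(l.startswith("S") for l in lines) == 3
        assert sum(l.startswith("L") for l in lines) == 2

    def test_empty_graph_header_only(self, tmp_path):
        g = CodonGraph(6, step=3)
        path = tmp_path / "g.gfa"
        g.export_gfa(path)
        assert path.read_text() == "H\tVN:Z:1.0\n"
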