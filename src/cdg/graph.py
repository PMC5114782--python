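"""Codon-based de Bruijn graphs: construction, simplification, interrogation.

The codon-based graph samples k-mers from codon-aligned ORFs with a step of
3 nt, so every node is a k-mer lying on the codon grid of its source frame
and every edge encodes an observed k−3 bp overlap (a (k+3)-mer seen in one
ORF). Because only one of three offsets is sampled, a clean coding path has
roughly one-third the nodes and edges of a conventional step-1 graph over
the same sequence — the property that makes direct CDS assembly tractable.

A conventional step-1 graph (k−1 bp overlaps) is available through
:func:`build_traditional_graph` for size comparisons.

Simplification follows standard assembly-graph practice: *tips* (chains
dangling from a branching node) spelling fewer than 2k bp are trimmed, and
*bubbles* (parallel paths sharing endpoints) whose spelled sequences align
at ≥95% identity are collapsed onto the longest path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import edlib
import networkx as nx

from cdg.orfs import Orf

__all__ = [
    "CodonGraph", "ComponentReport", "ConfigurationError",
    "build_codon_graph", "build_traditional_graph", "count_nodes_edges",
    "trim_tips", "merge_bubbles", "simplify", "classify_components",
    "unitigs", "export_gfa", "read_gfa", "alignment_identity",
]


class ConfigurationError(ValueError):
    """Invalid graph configuration (e.g. codon-step k not a multiple of 3)."""


def alignment_identity(a: str, b: str) -> float:
    """Global-alignment identity: matches / alignment length (gaps count)."""
    if not a or not b:
        return 0.0
    res = edlib.align(a, b, mode="NW", task="path")
    alen = 0
    num = ""
    matches = 0
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
        else:
            n = int(num)
            num = ""
            alen += n
            if ch == "=":
                matches += n
    return matches / alen if alen else 0.0


class CodonGraph:
    """A directed k-mer graph with multiplicities.

    ``step`` is 3 for the codon-based graph (edges overlap by k−3 bp) and 1
    for the traditional graph (k−1 bp overlaps). Nodes are k-mer strings;
    node and edge attribute ``mult`` counts observed occurrences.
    """

    def __init__(self, k: int, step: int = 3):
        if step == 3 and k % 3 != 0:
            raise ConfigurationError(f"codon-step graph needs k % 3 == 0, got k={k}")
        if k < step + 1:
            raise ConfigurationError(f"k={k} too small for step {step}")
        self.k = k
        self.step = step
        self.g = nx.DiGraph()

    # -- construction ---------------------------------------------------

    def add_sequence(self, seq: str) -> None:
        """Thread one codon-aligned sequence through the graph.

        Sequences shorter than k contribute nothing; consecutive k-mers
        within one sequence create one directed edge occurrence each.
        """
        k, step, g = self.k, self.step, self.g
        if len(seq) < k:
            return
        prev = None
        for i in range(0, len(seq) - k + 1, step):
            kmer = seq[i:i + k]
            if kmer in g:
                g.nodes[kmer]["mult"] += 1
            else:
                g.add_node(kmer, mult=1)
            if prev is not None:
                if g.has_edge(prev, kmer):
                    g[prev][kmer]["mult"] += 1
                else:
                    g.add_edge(prev, kmer, mult=1)
            prev = kmer

    # -- basic queries ---------------------------------------------------

    def counts(self) -> tuple[int, int]:
        """(distinct nodes, distinct directed edges), multiplicity ignored."""
        return self.g.number_of_nodes(), self.g.number_of_edges()

    def spelled_length(self, n_nodes: int) -> int:
        return self.k + self.step * (n_nodes - 1)

    def spell(self, path: Sequence[str]) -> str:
        """Sequence spelled by a node path: first k-mer + step bp per node."""
        if not path:
            return ""
        return path[0] + "".join(node[-self.step:] for node in path[1:])

    def copy(self) -> "CodonGraph":
        other = CodonGraph(self.k, self.step)
        other.g = self.g.copy()
        return other

    # -- simplification --------------------------------------------------

    def _head_tip_chain(self, start: str) -> Optional[list[str]]:
        """Chain from an in-degree-0 node to (excluding) a branching node."""
        g = self.g
        chain = [start]
        cur = start
        while True:
            if g.out_degree(cur) != 1:
                return None  # dead end or fork inside: not a tip
            (nxt,) = g.successors(cur)
            if nxt in chain:
                return None  # cycle
            if g.in_degree(nxt) > 1 or g.out_degree(nxt) > 1:
                return chain  # attaches to the rest at a branching node
            chain.append(nxt)
            cur = nxt

    def _tail_tip_chain(self, start: str) -> Optional[list[str]]:
        g = self.g
        chain = [start]
        cur = start
        while True:
            if g.in_degree(cur) != 1:
                return None
            (prv,) = g.predecessors(cur)
            if prv in chain:
                return None
            if g.out_degree(prv) > 1 or g.in_degree(prv) > 1:
                return chain
            chain.append(prv)
            cur = prv

    def trim_tips(self, max_tip_bp: Optional[int] = None) -> int:
        """Remove tips spelling strictly fewer than ``max_tip_bp`` bases.

        A tip is a chain of nodes dead-ended on one side and attached to
        the rest of the graph at a branching node on the other. Default
        threshold: 2k bp. Repeats to fixpoint; returns the number of tips
        removed.
        """
        if max_tip_bp is None:
            max_tip_bp = 2 * self.k
        if max_tip_bp < self.k:
            raise ValueError("max_tip_bp must be at least k")
        g = self.g
        removed = 0
        while True:
            progress = False
            for node in sorted(n for n in g if g.in_degree(n) == 0):
                if node not in g:
                    continue
                chain = self._head_tip_chain(node)
                if chain is not None and self.spelled_length(len(chain)) < max_tip_bp:
                    g.remove_nodes_from(chain)
                    removed += 1
                    progress = True
            for node in sorted(n for n in g if g.out_degree(n) == 0):
                if node not in g:
                    continue
                chain = self._tail_tip_chain(node)
                if chain is not None and self.spelled_length(len(chain)) < max_tip_bp:
                    g.remove_nodes_from(chain)
                    removed += 1
                    progress = True
            if not progress:
                return removed

    def _bubble_arms(self, source: str, max_bubble_nodes: int):
        """Arms from a branching node: child chains ending at a join node.

        Returns a mapping join_node -> list of interior node paths (the
        interior may be empty for a direct source->join edge).
        """
        g = self.g
        arms: dict[str, list[list[str]]] = {}
        for child in sorted(g.successors(source)):
            interior: list[str] = []
            cur = child
            ok = False
            while len(interior) <= max_bubble_nodes:
                if g.in_degree(cur) > 1:
                    ok = True  # cur is the join node
                    break
                if g.out_degree(cur) != 1:
                    break  # dead end or fork: not a clean arm
                interior.append(cur)
                (cur,) = g.successors(cur)
                if cur == source or cur in interior:
                    break
            if ok and cur != source:
                arms.setdefault(cur, []).append(interior)
        return arms

    def merge_bubbles(self, min_identity: float = 0.95,
                      max_bubble_nodes: int = 200) -> int:
        """Collapse bubbles whose paths align at ``min_identity`` or better.

        For each branching node, bounded forward walks locate alternative
        simple paths reconverging at a common node. Spelled path sequences
        are compared by global-alignment identity; when at or above the
        cutoff, only the longest spelled path survives (ties: higher summed
        node multiplicity, then lexicographically smaller spelling).
        Returns the number of alternative paths removed. Runs to fixpoint.
        """
        if not 0 < min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")
        g = self.g
        merged = 0
        while True:
            progress = False
            for source in sorted(n for n in g if g.out_degree(n) > 1):
                if source not in g or g.out_degree(source) < 2:
                    continue
                for join, interiors in sorted(self._bubble_arms(source, max_bubble_nodes).items()):
                    if len(interiors) < 2:
                        continue
                    def arm_key(interior: list[str]):
                        spelled = self.spell([source] + interior + [join])
                        mult = sum(g.nodes[n]["mult"] for n in interior if n in g)
                        return (-len(spelled), -mult, spelled)
                    interiors = sorted(interiors, key=arm_key)
                    keep = interiors[0]
                    keep_spelled = self.spell([source] + keep + [join])
                    for other in interiors[1:]:
                        other_spelled = self.spell([source] + other + [join])
                        if alignment_identity(keep_spelled, other_spelled) >= min_identity:
                            if other:
                                g.remove_nodes_from(other)
                            elif g.has_edge(source, join):
                                g.remove_edge(source, join)
                            merged += 1
                            progress = True
            if not progress:
                return merged

    def simplify(self, max_tip_bp: Optional[int] = None,
                 min_identity: float = 0.95,
                 max_bubble_nodes: int = 200) -> tuple[int, int]:
        """Trim tips and merge bubbles alternately to a joint fixpoint."""
        tips = bubbles = 0
        while True:
            t = self.trim_tips(max_tip_bp)
            b = self.merge_bubbles(min_identity, max_bubble_nodes)
            tips += t
            bubbles += b
            if t == 0 and b == 0:
                return tips, bubbles

    # -- components ------------------------------------------------------

    def classify_components(self, max_bubble_nodes: int = 200) -> "ComponentReport":
        """Classify weakly connected components as simple / tips / bubbles.

        *simple*: no node branches (all in/out degrees ≤ 1). *bubbles*: at
        least one reconverging bubble is present (tips may also be
        present). *tips*: branching without any bubble.
        """
        g = self.g
        rows = []
        for comp in nx.weakly_connected_components(g):
            sub_nodes = comp
            n_edges = sum(1 for u, v in g.edges(sub_nodes) if v in comp)
            branching = [n for n in sub_nodes
                         if g.in_degree(n) > 1 or g.out_degree(n) > 1]
            if not branching:
                cls = "simple"
            else:
                has_bubble = False
                for node in branching:
                    if g.out_degree(node) > 1:
                        arms = self._bubble_arms(node, max_bubble_nodes)
                        if any(len(v) >= 2 for v in arms.values()):
                            has_bubble = True
                            break
                cls = "bubbles" if has_bubble else "tips"
            rows.append((len(comp), n_edges, cls))
        return ComponentReport(rows)

    # -- unitigs ---------------------------------------------------------

    def unitigs(self) -> list[str]:
        """Spelled maximal non-branching paths covering every node once.

        Internal unitig nodes have in-degree 1 and out-degree 1; isolated
        nodes spell themselves; isolated cycles are broken at their
        lexicographically smallest node. Self-loops terminate extension.
        """
        g = self.g
        visited: set[str] = set()
        out: list[str] = []

        def is_start(n: str) -> bool:
            if g.in_degree(n) != 1:
                return True
            (p,) = g.predecessors(n)
            return g.out_degree(p) != 1 or p == n

        for node in sorted(g):
            if node in visited or not is_start(node):
                continue
            path = [node]
            visited.add(node)
            cur = node
            while g.out_degree(cur) == 1:
                (nxt,) = g.successors(cur)
                if nxt in visited or g.in_degree(nxt) != 1 or nxt == cur:
                    break
                path.append(nxt)
                visited.add(nxt)
                cur = nxt
            out.append(self.spell(path))
        # leftover nodes belong to isolated cycles
        for node in sorted(g):
            if node in visited:
                continue
            path = [node]
            visited.add(node)
            cur = node
            while True:
                (nxt,) = g.successors(cur)
                if nxt in visited:
                    break
                path.append(nxt)
                visited.add(nxt)
                cur = nxt
            out.append(self.spell(path))
        return out

    # -- GFA -------------------------------------------------------------

    def export_gfa(self, path: str | Path) -> None:
        """Write the graph as GFA1 (S-lines per k-mer, L-lines per overlap)."""
        names = {node: f"n{i}" for i, node in enumerate(sorted(self.g), start=1)}
        olap = self.k - self.step
        with open(path, "w") as fh:
            fh.write("H\tVN:Z:1.0\n")
            for node, name in names.items():
                fh.write(f"S\t{name}\t{node}\tDP:i:{self.g.nodes[node]['mult']}\n")
            for u, v, data in sorted(self.g.edges(data=True)):
                fh.write(f"L\t{names[u]}\t+\t{names[v]}\t+\t{olap}M\tRC:i:{data['mult']}\n")


@dataclass
class ComponentReport:
    """Per-component sizes and classes; classes are mutually exclusive."""

    components: list[tuple[int, int, str]] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return len(self.components)

    def class_counts(self) -> dict[str, int]:
        counts = {"simple": 0, "tips": 0, "bubbles": 0}
        for _, _, cls in self.components:
            counts[cls] += 1
        return counts

    def simple_fraction(self) -> float:
        if not self.components:
            return 1.0
        return self.class_counts()["simple"] / self.n_components

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("component_id\tn_nodes\tn_edges\tclass\n")
            for i, (n, e, cls) in enumerate(self.components, start=1):
                fh.write(f"c{i}\t{n}\t{e}\t{cls}\n")


# -- module-level operation surface ---------------------------------------

def build_codon_graph(orfs: Iterable[Orf | str], k: int = 27) -> CodonGraph:
    """Build the step-3 codon-based de Bruijn graph from codon-aligned ORFs."""
    graph = CodonGraph(k, step=3)
    for orf in orfs:
        graph.add_sequence(orf.seq if isinstance(orf, Orf) else str(orf))
    return graph


def build_traditional_graph(seqs: Iterable[str], k: int = 27) -> CodonGraph:
    """Build a conventional step-1 de Bruijn graph (k−1 bp overlaps)."""
    graph = CodonGraph(k, step=1)
    for seq in seqs:
        graph.add_sequence(str(seq))
    return graph


def count_nodes_edges(graph: CodonGraph) -> tuple[int, int]:
    return graph.counts()


def trim_tips(graph: CodonGraph, max_tip_bp: Optional[int] = None,
              copy: bool = False) -> tuple[CodonGraph, int]:
    target = graph.copy() if copy else graph
    return target, target.trim_tips(max_tip_bp)


def merge_bubbles(graph: CodonGraph, min_identity: float = 0.95,
                  max_bubble_nodes: int = 200,
                  copy: bool = False) -> tuple[CodonGraph, int]:
    target = graph.copy() if copy else graph
    return target, target.merge_bubbles(min_identity, max_bubble_nodes)


def simplify(graph: CodonGraph, **kwargs) -> tuple[CodonGraph, int, int]:
    tips, bubbles = graph.simplify(**kwargs)
    return graph, tips, bubbles


def classify_components(graph: CodonGraph) -> ComponentReport:
    return graph.classify_components()


def unitigs(graph: CodonGraph) -> list[str]:
    return graph.unitigs()


def export_gfa(graph: CodonGraph, path: str | Path) -> None:
    graph.export_gfa(path)


def read_gfa(path: str | Path) -> CodonGraph:
    """Reconstruct a graph from a GFA1 file written by :func:`export_gfa`."""
    seqs: dict[str, str] = {}
    mults: dict[str, int] = {}
    links: list[tuple[str, str, int, int]] = []
    k = None
    olap = None
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "S":
                name, seq = parts[1], parts[2]
                seqs[name] = seq
                k = len(seq)
                mult = 1
                for tag in parts[3:]:
                    if tag.startswith("DP:i:"):
                        mult = int(tag[5:])
                mults[name] = mult
            elif parts[0] == "L":
                olap = int(parts[5].rstrip("M"))
                mult = 1
                for tag in parts[6:]:
                    if tag.startswith("RC:i:"):
                        mult = int(tag[5:])
                links.append((parts[1], parts[3], olap, mult))
    if k is None:
        raise ValueError(f"{path}: GFA contains no segments")
    step = (k - olap) if olap is not None else 3
    graph = CodonGraph(k, step=step if step in (1, 3) else 3)
    for name, seq in seqs.items():
        graph.g.add_node(seq, mult=mults[name])
    for u, v, _, mult in links:
        graph.g.add_edge(seqs[u], seqs[v], mult=mult)
    return graph
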