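"""Synthetic genes and reads for testing CDS construction at desk scale.

The generator emulates the conditions the method is designed for:
codon-biased, stop-free CDSs; gene models with UTRs and GT..AG introns;
and uniform-start short reads with an i.i.d. substitution error model
(0.5–2% is the realistic range for the platforms involved). Substitution
only — indels would break the frame semantics coding-sequence assembly
assumes, and short-read substitution errors dominate in practice.

Two codon-usage presets ship with the module: ``uniform`` (all 61 sense
codons equally likely — no composition signal) and ``human_like`` (the
skew of human coding sequence, giving the SVM a realistic signal to
learn).

Transcripts are emitted as 5'UTR + CDS + 3'UTR with a stop codon
immediately following the CDS (the natural terminator) and an in-frame
stop at the 3' end of the 5'UTR (upstream in-frame stops are the norm in
real 5'UTRs). This stop-bounding is what lets reads spanning a CDS
boundary resolve the terminal codons of the CDS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from cdg._codons import SENSE_CODONS, STOP_CODONS, revcomp
from cdg.seqio import ReadPair, SeqRecord, write_fasta, write_fastq

__all__ = [
    "SimConfig", "GeneModel", "BenchmarkBundle", "CODON_TABLES",
    "make_cds", "make_gene", "simulate_reads", "make_benchmark",
]

# Human codon usage (relative frequencies per sense codon, from standard
# usage tables; rescaled internally). The absolute scale is irrelevant.
_HUMAN_LIKE = {
    "TTT": 17.6, "TTC": 20.3, "TTA": 7.7, "TTG": 12.9,
    "CTT": 13.2, "CTC": 19.6, "CTA": 7.2, "CTG": 39.6,
    "ATT": 16.0, "ATC": 20.8, "ATA": 7.5, "ATG": 22.0,
    "GTT": 11.0, "GTC": 14.5, "GTA": 7.1, "GTG": 28.1,
    "TCT": 15.2, "TCC": 17.7, "TCA": 12.2, "TCG": 4.4,
    "CCT": 17.5, "CCC": 19.8, "CCA": 16.9, "CCG": 6.9,
    "ACT": 13.1, "ACC": 18.9, "ACA": 15.1, "ACG": 6.1,
    "GCT": 18.4, "GCC": 27.7, "GCA": 15.8, "GCG": 7.4,
    "TAT": 12.2, "TAC": 15.3, "CAT": 10.9, "CAC": 15.1,
    "CAA": 12.3, "CAG": 34.2, "AAT": 17.0, "AAC": 19.1,
    "AAA": 24.4, "AAG": 31.9, "GAT": 21.8, "GAC": 25.1,
    "GAA": 29.0, "GAG": 39.6, "TGT": 10.6, "TGC": 12.6,
    "TGG": 13.2, "CGT": 4.5, "CGC": 10.4, "CGA": 6.2,
    "CGG": 11.4, "AGT": 12.1, "AGC": 19.5, "AGA": 12.2,
    "AGG": 12.0, "GGT": 10.8, "GGC": 22.2, "GGA": 16.5,
    "GGG": 16.5,
}

CODON_TABLES: dict[str, dict[str, float]] = {
    "uniform": {c: 1.0 for c in SENSE_CODONS},
    "human_like": dict(_HUMAN_LIKE),
}

_BASES = np.array(list("ACGT"))


def _rng(seed_or_rng: Union[int, np.random.Generator, None]) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset.

    Defaults follow the simulation design the method is evaluated under:
    150 bp reads at 30× depth from 20 genes with CDS lengths spanning
    0.9–1.8 kb, substitution error rate in [0, 0.1] (0.5–2% being the
    realistic sequencing range), human-like codon bias.
    """

    n_genes: int = 20
    cds_length: tuple[int, int] = (900, 1800)
    read_length: int = 150
    depth: float = 30.0
    error_rate: float = 0.0
    paired: bool = False
    insert_size: int = 250
    seed: int = 0
    codon_table: str = "human_like"
    utr_length: tuple[int, int] = (100, 300)

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate <= 0.1:
            raise ValueError("error_rate must be in [0, 0.1]")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.seed is None:
            raise ValueError("seed must be set")


def make_cds(length: int, codon_weights: Optional[dict[str, float]] = None,
             seed: Union[int, np.random.Generator, None] = 0) -> str:
    """A stop-free CDS of ``length`` bp sampled from a codon-usage table.

    ``codon_weights`` maps sense codons to relative weights (default
    uniform); tables containing stop codons are rejected.
    """
    if length % 3 != 0 or length <= 0:
        raise ValueError("length must be a positive multiple of 3")
    if codon_weights is None:
        codon_weights = CODON_TABLES["uniform"]
    if any(c in STOP_CODONS for c in codon_weights):
        raise ValueError("codon_weights must not contain stop codons")
    rng = _rng(seed)
    codons = sorted(codon_weights)
    w = np.array([codon_weights[c] for c in codons], dtype=float)
    w /= w.sum()
    picks = rng.choice(len(codons), size=length // 3, p=w)
    return "".join(codons[i] for i in picks)


def _random_seq(length: int, rng: np.random.Generator) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


@dataclass
class GeneModel:
    """A synthetic gene: stop-free CDS, UTRs, introns, and genomic string."""

    id: str
    cds: str
    utr5: str
    utr3: str
    introns: list[tuple[int, str]] = field(default_factory=list)

    @property
    def mrna(self) -> str:
        """Spliced transcript: 5'UTR + CDS + 3'UTR."""
        return self.utr5 + self.cds + self.utr3

    @property
    def full_gene(self) -> str:
        """Unspliced genomic sequence with introns inserted into the CDS."""
        parts = [self.utr5]
        prev = 0
        for pos, intron in sorted(self.introns):
            parts.append(self.cds[prev:pos])
            parts.append(intron)
            prev = pos
        parts.append(self.cds[prev:])
        parts.append(self.utr3)
        return "".join(parts)

    def splice(self) -> str:
        """Recover the CDS from the genomic string (round-trip check)."""
        seq = self.full_gene[len(self.utr5):len(self.full_gene) - len(self.utr3)]
        for pos, intron in sorted(self.introns, reverse=True):
            offset = pos + sum(len(i) for p, i in self.introns if p < pos)
            seq = seq[:offset] + seq[offset + len(intron):]
        return seq


def make_gene(cds: str, n_introns: int = 0,
              utr_lengths: tuple[int, int] = (150, 150),
              intron_length: tuple[int, int] = (60, 150),
              max_intron_bp: int = 10_000,
              gene_id: str = "gene",
              seed: Union[int, np.random.Generator, None] = 0) -> GeneModel:
    """Wrap a CDS into a gene model with UTRs and GT..AG introns.

    The last codon position of the 5'UTR is forced to a stop (TAA) in the
    CDS frame, and the 3'UTR begins with the terminator stop, so the CDS
    is stop-bounded within its own reading frame on the transcript.
    """
    rng = _rng(seed)
    u5, u3 = utr_lengths
    utr5 = _random_seq(u5, rng)
    if u5 >= 3:
        utr5 = utr5[:-3] + "TAA"
    utr3 = "TAA" + _random_seq(max(u3 - 3, 0), rng) if u3 >= 3 else _random_seq(u3, rng)
    introns: list[tuple[int, str]] = []
    if n_introns:
        positions = sorted(int(p) + 1 for p in
                           rng.choice(len(cds) - 1, size=n_introns, replace=False))
        for pos in positions:
            ilen = int(rng.integers(intron_length[0], intron_length[1] + 1))
            if ilen > max_intron_bp:
                raise ValueError(f"intron length {ilen} exceeds cap {max_intron_bp}")
            introns.append((pos, "GT" + _random_seq(ilen - 4, rng) + "AG"))
    return GeneModel(id=gene_id, cds=cds, utr5=utr5, utr3=utr3, introns=introns)


def simulate_reads(template: Union[str, SeqRecord], config: SimConfig,
                   rng: Optional[np.random.Generator] = None,
                   template_id: str = "tpl",
                   ) -> list[Union[SeqRecord, ReadPair]]:
    """Uniform-start reads with i.i.d. substitution errors from one template.

    Read count is ``round(depth * len(template) / read_length)``; start
    positions are uniform over the valid range; each base substitutes,
    independently at ``error_rate``, to one of the three other bases.
    Paired mode draws fragments of ``insert_size`` and reports mate 2
    reverse-complemented. Deterministic given (template, config, rng).
    """
    if isinstance(template, SeqRecord):
        template_id, template = template.id, template.seq
    L = len(template)
    rl = config.read_length
    span = config.insert_size if config.paired else rl
    if span > L:
        raise ValueError(f"template ({L} bp) shorter than read span ({span} bp)")
    rng = rng if rng is not None else _rng(config.seed)
    n_reads = int(round(config.depth * L / rl))
    if config.paired:
        n_reads = max(1, n_reads // 2)
    starts = rng.integers(0, L - span + 1, size=n_reads)

    def with_errors(seq: str) -> str:
        if config.error_rate == 0:
            return seq
        arr = np.frombuffer(seq.encode(), dtype="S1").copy()
        hit = np.nonzero(rng.random(len(seq)) < config.error_rate)[0]
        for i in hit:
            base = arr[i].decode()
            choices = [b for b in "ACGT" if b != base]
            arr[i] = choices[rng.integers(0, len(choices))].encode()
        return arr.tobytes().decode()

    out: list[Union[SeqRecord, ReadPair]] = []
    for i, s in enumerate(starts):
        s = int(s)
        if config.paired:
            frag = template[s:s + span]
            r1 = SeqRecord(f"{template_id}:{i}:{s}/1", with_errors(frag[:rl]))
            r2 = SeqRecord(f"{template_id}:{i}:{s}/2", with_errors(revcomp(frag[-rl:])))
            out.append(ReadPair(r1, r2))
        else:
            out.append(SeqRecord(f"{template_id}:{i}:{s}", with_errors(template[s:s + rl])))
    return out


@dataclass
class BenchmarkBundle:
    """Genes, reads and per-read origin truth for one simulated study."""

    genes: list[GeneModel]
    reads: list[Union[SeqRecord, ReadPair]]
    truth: list[tuple[str, str, int, str]]  # read_id, gene_id, start, strand

    @property
    def cds_records(self) -> list[SeqRecord]:
        return [SeqRecord(g.id, g.cds) for g in self.genes]

    def write(self, prefix: str | Path) -> None:
        prefix = str(prefix)
        write_fasta(self.cds_records, prefix + ".genes.fa")
        flat: list[SeqRecord] = []
        for r in self.reads:
            if isinstance(r, ReadPair):
                flat.extend([r.r1, r.r2])
            else:
                flat.append(r)
        write_fastq(flat, prefix + ".reads.fq")
        with open(prefix + ".truth.tsv", "w") as fh:
            fh.write("read_id\tgene_id\tstart\tstrand\n")
            for row in self.truth:
                fh.write("\t".join(map(str, row)) + "\n")


def make_benchmark(config: SimConfig) -> BenchmarkBundle:
    """A gene set plus reads plus truth table under one set of conditions.

    Genes get CDS lengths uniform (in codons) over ``config.cds_length``
    and UTR lengths uniform over ``config.utr_length``; reads are
    simulated from each spliced transcript. Deterministic per seed.
    """
    rng = _rng(config.seed)
    weights = CODON_TABLES[config.codon_table]
    genes: list[GeneModel] = []
    reads: list[Union[SeqRecord, ReadPair]] = []
    truth: list[tuple[str, str, int, str]] = []
    lo, hi = config.cds_length
    for gi in range(config.n_genes):
        n_codons = int(rng.integers(lo // 3, hi // 3 + 1))
        cds = make_cds(n_codons * 3, weights, rng)
        u5 = int(rng.integers(config.utr_length[0], config.utr_length[1] + 1))
        u3 = int(rng.integers(config.utr_length[0], config.utr_length[1] + 1))
        gene = make_gene(cds, n_introns=0, utr_lengths=(u5, u3),
                         gene_id=f"gene_{gi + 1:04d}", seed=rng)
        genes.append(gene)
        gene_reads = simulate_reads(gene.mrna, config, rng=rng, template_id=gene.id)
        for r in gene_reads:
            rid = r.r1.id if isinstance(r, ReadPair) else r.id
            start = int(rid.split(":")[-1].split("/")[0])
            truth.append((rid, gene.id, start, "+"))
        reads.extend(gene_reads)
    return BenchmarkBundle(genes=genes, reads=reads, truth=truth)
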