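"""CDS prediction metrics on a worked example.

Constructs a small prediction set against four reference genes — one gene
recovered in full, one split into two fragments, one missed, plus one
chimera gluing two genes together — and prints every metric the
evaluation module computes, with the values these pathologies should
produce.
"""

from cdg.evaluation import (
    align_records, chimera_rate, filter_alignments, fragment_number,
    redundancy, roc_point,
)
from cdg.seqio import SeqRecord
from cdg.simulate import make_cds

genes = [SeqRecord(f"gene{i}", make_cds(900, seed=i)) for i in range(4)]

predictions = [
    SeqRecord("full", genes[0].seq),                       # perfect recovery
    SeqRecord("frag_a", genes[1].seq[:540]),               # fragmented gene
    SeqRecord("frag_b", genes[1].seq[330:]),
    SeqRecord("chimera", genes[2].seq[:450] + genes[3].seq[450:]),
]

raw = align_records(predictions, genes)
kept = filter_alignments(raw)  # >90% identity and both coverages

sens, spec = roc_point(kept, [p.id for p in predictions], [g.id for g in genes])
red = redundancy(kept, len(genes))
rate, ids = chimera_rate(raw, {p.id: len(p.seq) for p in predictions})

print(f"alignments: {len(raw)} raw, {len(kept)} past the 90/90/90 filter")
print(f"sensitivity  {sens:.2f}   (only gene0 is covered >90% by one CDS)")
print(f"specificity  {spec:.2f}   (only 'full' survives the coverage filter)")
print(f"redundancy   {red:.2f}   (1 aligned CDS / 4 reference genes)")
if kept:
    print(f"fragments    {fragment_number(kept):.2f}   per aligned gene")
print(f"chimera rate {rate:.2f}   ({', '.join(ids)} joins two genes, each "
      f"half covering >=30% of it)")
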