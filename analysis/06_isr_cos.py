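"""Intron-spanning primer design and the conserved-ortholog cascade.

Reads the spliced alignments (GFF3), infers introns (40-5000 bp gaps),
merges transcribed units separated by <= 1000 uncovered bp, designs
junction-flanking primer pairs, and runs the six-species COS cascade on
hit tables constructed to realize the published stage design
638 -> 556 -> 466 -> 387.
"""

import argparse
import json
from pathlib import Path

from tusmine import markers as mk
from tusmine import reports, seqio
from tusmine.simulate import simulate_ortholog_hits

parser = argparse.ArgumentParser()
parser.add_argument("--simdir", type=Path, default=Path("results/sim"))
parser.add_argument("--outdir", type=Path, default=Path("results/tables"))
args = parser.parse_args()
args.outdir.mkdir(parents=True, exist_ok=True)

tus = {r.id: r.residues for r in seqio.read_fasta(args.simdir / "tus.fasta")}
alignments = mk.drop_subthreshold_alignments(
    mk.read_gff3_alignments(args.simdir / "alignments.gff3")
)
groups = mk.merge_transcribed_units(alignments)
n_merged = sum(1 for g in groups if len(g) > 1)
print(f"{len(alignments)} spliced alignments -> {len(groups)} transcribed units "
      f"({n_merged} merged groups under the <=1000-bp rule)")

n_introns = n_pairs = 0
with open(args.outdir / "isr_primers.tsv", "w") as fh:
    fh.write("tus_id\tleft\tright\tproduct_transcript\tproduct_genomic\n")
    for aln in alignments:
        introns = mk.infer_introns(aln)
        n_introns += len(introns)
        for p in mk.design_isr(tus[aln.tus_id], aln, introns):
            n_pairs += 1
            fh.write(f"{aln.tus_id}\t{p.left_seq}\t{p.right_seq}\t"
                     f"{p.product_size_transcript}\t{p.product_size_genomic}\n")
print(f"{n_introns} predicted introns; {n_pairs} ISR primer pairs "
      f"(each spans >= 1 junction; genomic product = transcript product + introns)")

design = (638, 556, 466, 387)
per_species, annots, prior, qlens, _ = simulate_ortholog_hits(design, n_queries=650)
result = mk.cos_cascade(per_species, annots, prior, qlens=qlens)
reports.write_cascade_accounting(result, args.outdir / "cos_accounting.tsv")
n1, n2, n3, n4 = result.counts
print(f"COS cascade on 650 queries: {n1} with similarity in all six species "
      f"(E<=1e-30) -> {n2} identically annotated -> {n3} after removing "
      f"{len(result.paralogs)} paralogs -> {n4} nonredundant COS markers")

gss_hits = [h for hs in per_species.values() for h in hs]
queries, subjects = mk.filter_hits_cascade(
    gss_hits, evalue_max=1e-10, min_identity_pct=80.0, min_qaln_len=70
)
print(f"generic similarity screen (E<=1e-10, aln>=70, id>=80%): "
      f"{len(queries)} queries matched {len(subjects)} subjects")
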