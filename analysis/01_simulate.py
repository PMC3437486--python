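"""Generate the synthetic study inputs with planted ground truth.

Emits a 500-TUS transcript set (planted SSRs, poly-A tails), a toy
genome with known intron structure plus its spliced alignments, and two
100k-tag libraries from the two genotype haplotypes, under results/sim/.
"""

import argparse
from pathlib import Path

from tusmine import markers, seqio
from tusmine.simulate import SimConfig, simulate_all

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--outdir", type=Path, default=Path("results/sim"))
args = parser.parse_args()

config = SimConfig(seed=args.seed)
sim = simulate_all(config)

args.outdir.mkdir(parents=True, exist_ok=True)
seqio.write_fasta(sim["tus"], args.outdir / "tus.fasta")
seqio.write_fasta([sim["genome"]], args.outdir / "genome.fasta")
markers.write_gff3_alignments(sim["alignments"], args.outdir / "alignments.gff3")
seqio.write_fastq(sim["tags_g1"], args.outdir / "tags_g1.fastq")
seqio.write_fastq(sim["tags_g2"], args.outdir / "tags_g2.fastq")
sim["truth"].to_json(args.outdir / "truth.json")

truth = sim["truth"]
print(f"TUS set: {len(sim['tus'])} sequences, "
      f"{sum(len(r) for r in sim['tus'])} bp total")
print(f"planted: {len(truth.ssrs)} SSRs, {len(truth.variants)} variants, "
      f"{len(truth.introns)} introns, {len(truth.log2fc)} fold changes")
print(f"tag libraries: {len(sim['tags_g1'])} + {len(sim['tags_g2'])} x "
      f"{config.tag_length} bp (error rate {config.error_rate})")
print(f"wrote {args.outdir}/")
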