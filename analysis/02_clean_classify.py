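"""Post-assembly cleanup: tail trimming, complexity screen, TUS classes.

Trims the planted poly-A tails off the simulated TUS set, screens
low-complexity sequences, classifies a demonstration contig layout set
(including the two-read flat-coverage rule) and tabulates the length
distribution in 50-bp bins.
"""

import argparse
from pathlib import Path

from tusmine import assembly, seqio

parser = argparse.ArgumentParser()
parser.add_argument("--simdir", type=Path, default=Path("results/sim"))
parser.add_argument("--outdir", type=Path, default=Path("results/tables"))
args = parser.parse_args()
args.outdir.mkdir(parents=True, exist_ok=True)

records = seqio.read_fasta(args.simdir / "tus.fasta")
trimmed, n_trimmed, n_dropped = [], 0, 0
for rec in records:
    t = assembly.trim_polya(rec)
    if len(t) != len(rec):
        n_trimmed += 1
    if len(t) == 0 or not assembly.screen_low_complexity(t):
        n_dropped += 1
        continue
    trimmed.append(t)
seqio.write_fasta(trimmed, args.outdir / "tus_clean.fasta")
print(f"{len(records)} TUSs in: {n_trimmed} poly-A trimmed, "
      f"{n_dropped} dropped as low-complexity, {len(trimmed)} kept")

# contig classification demo: flat two-read contigs are high-confidence singletons
layouts = [
    assembly.ContigLayout("flat2", 300, [("r1", 1, 300), ("r2", 1, 300)]),
    assembly.ContigLayout("stag2", 300, [("r1", 1, 200), ("r2", 101, 300)]),
    assembly.ContigLayout("solo", 300, [("r1", 1, 300)]),
    assembly.ContigLayout("deep", 300, [("r1", 1, 300), ("r2", 1, 300), ("r3", 1, 300)]),
]
with open(args.outdir / "class_demo.tsv", "w") as fh:
    fh.write("contig\tn_reads\tclass\n")
    for layout in layouts:
        cls = assembly.classify_tus(layout)
        fh.write(f"{layout.contig_id}\t{len(layout.member_reads)}\t{cls}\n")
        print(f"  {layout.contig_id}: {len(layout.member_reads)} reads -> {cls}")

hist = assembly.length_histogram(trimmed, bin_width=50)
hist.to_csv(args.outdir / "length_histogram.tsv", sep="\t", index=False)
top = hist.loc[hist["count"].idxmax()]
print(f"length histogram: mode bin {top.lo}-{top.hi} bp ({top['count']} TUSs); "
      f"mass {hist['count'].sum()}")
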