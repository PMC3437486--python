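"""Inter-genotype variant mining from the two tag libraries.

Builds per-genotype pileups from uniquely placed tags, calls positions
where genotype 2 differs from the TUS consensus (frequency > 0.1,
depth in [3,500)), writes the VCF, the frequency x depth classification
matrix, the confidence tiers, and the planted-variant recovery rate.
"""

import argparse
import json
from pathlib import Path

from tusmine import expression as ex
from tusmine import seqio, variants as va

parser = argparse.ArgumentParser()
parser.add_argument("--simdir", type=Path, default=Path("results/sim"))
parser.add_argument("--outdir", type=Path, default=Path("results/tables"))
args = parser.parse_args()
args.outdir.mkdir(parents=True, exist_ok=True)

tus = seqio.read_fasta(args.simdir / "tus.fasta")
index = ex.build_index(tus)
piles = {}
for g in ("g1", "g2"):
    tags = seqio.read_fastq(args.simdir / f"tags_{g}.fastq")
    alns = ex.map_tags(tags, index)
    piles[g] = va.build_pileup(alns, tus, {t.id: t.residues for t in tags}, g)

passing, binned = va.call_candidates(piles["g1"], piles["g2"], tus)
passing.sort(key=lambda c: (c.tus_id, c.pos))
va.write_vcf(passing, tus, args.outdir / "variants.vcf")
matrix = va.ClassificationMatrix.from_candidates(binned)
matrix.to_tsv(args.outdir / "variant_matrix.tsv")
tiers = va.tier_counts(passing)
print(f"{len(binned)} positions binned (depth >= 3 with a non-consensus allele); "
      f"{len(passing)} pass the frequency/depth filters")
print(f"tiers: {tiers['well_supported']} well-supported (freq >= 0.9, depth >= 3); "
      f"{tiers['stringent_high_confidence']} stringent (freq > 0.60, depth > 10)")

truth = json.loads((args.simdir / "truth.json").read_text())
by_key = {(c.tus_id, c.pos): c for c in passing}
deep = recovered = 0
for v in truth["variants"]:
    mat = piles["g2"].counts.get(v["tus_id"])
    if mat is None or int(mat[v["pos"] - 1].sum()) < 10:
        continue
    deep += 1
    c = by_key.get((v["tus_id"], v["pos"]))
    recovered += c is not None and va.is_well_supported(c)
print(f"planted homozygous variants at depth >= 10: {recovered}/{deep} "
      f"recovered as well-supported")
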