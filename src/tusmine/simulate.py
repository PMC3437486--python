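"""Synthetic inputs with machine-readable planted truth.

Generates, at desk scale, every input the pipeline consumes: a TUS set
with planted SSR motifs and optional poly-A tails, a toy genome with
known intron structure and its spliced alignments (GFF3), two genotype
haplotypes differing by planted variants, two 36-bp tag libraries with
log-normal abundances and planted fold changes, and six-species
ortholog hit tables with controlled E-values realizing designed cascade
outcomes.

Everything is driven by one :class:`SimConfig`; all randomness flows
from its seed, so identical configs give byte-identical outputs.  The
generator emulates the study conditions (normalized multi-tissue
transcript diversity, 36-bp tag libraries from two genotypes) at a
scale of 500 TUSs and 1e5 tags per library; it does not model 454
homopolymer errors, quality-dependent miscalls, or assembler artifacts.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .seqio import SequenceRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    seed: int = 1
    n_tus: int = 500
    tus_length_min: int = 150
    tus_length_max: int = 1200
    tus_length_mean: int = 450
    # (unit, repeat_count, how many TUSs get one)
    ssr_plant_spec: list[tuple[str, int, int]] = field(
        default_factory=lambda: [
            ("AG", 8, 12), ("TC", 7, 8), ("TTC", 7, 8),
            ("A", 12, 6), ("AAAG", 5, 4), ("AACGT", 5, 2), ("AACGTC", 5, 2),
        ]
    )
    polya_fraction: float = 0.1
    n_genes_with_introns: int = 30
    intron_length_min: int = 80
    intron_length_max: int = 2000  # bounded well below the 5000 cap
    exons_per_gene_max: int = 4
    n_linked_pairs: int = 5  # single-exon TUS pairs placed <=1000 bp apart
    n_unlinked_pairs: int = 3  # control pairs placed >1000 bp apart
    n_variants: int = 60
    variant_alt_freq: float = 1.0  # homozygous inter-genotype differences
    abundance_mu: float = 0.0
    abundance_sigma: float = 1.0
    # (log2 fold change g1/g2, number of TUSs)
    fold_change_spec: list[tuple[float, int]] = field(
        default_factory=lambda: [(3.0, 6), (-3.0, 6), (2.5, 8), (-2.5, 8), (1.0, 12)]
    )
    n_exclusive_g1: int = 6
    n_exclusive_g2: int = 6
    library_size_1: int = 100_000
    library_size_2: int = 100_000
    tag_length: int = 36
    error_rate: float = 0.01

    def validate(self) -> None:
        min_host = max(
            [len(u) * c for u, c, _ in self.ssr_plant_spec] + [self.tag_length]
        )
        if self.tus_length_min <= min_host + 20:
            raise ValueError("tus_length_min too small to host planted features")
        if self.intron_length_max > 5000:
            raise ValueError("intron lengths must stay within the 5000-bp cap")


@dataclass
class TruthTable:
    """Ground truth for every planted feature, keyed by emitted ids."""

    ssrs: list[dict] = field(default_factory=list)
    polya_tus: list[str] = field(default_factory=list)
    introns: list[dict] = field(default_factory=list)
    linked_pairs: list[tuple[str, str]] = field(default_factory=list)
    unlinked_pairs: list[tuple[str, str]] = field(default_factory=list)
    variants: list[dict] = field(default_factory=list)
    log2fc: dict[str, float] = field(default_factory=dict)
    exclusive_g1: list[str] = field(default_factory=list)
    exclusive_g2: list[str] = field(default_factory=list)
    cascade_design: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def _tus_lengths(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Lengths from a clipped log-normal shaped to the configured mean/range."""
    raw = rng.lognormal(mean=np.log(config.tus_length_mean), sigma=0.45, size=config.n_tus)
    return np.clip(raw, config.tus_length_min, config.tus_length_max).astype(int)


def simulate_transcriptome(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[list[SequenceRecord], TruthTable]:
    """Random-composition TUSs with planted SSRs and poly-A tails."""
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    truth = TruthTable()
    lengths = _tus_lengths(config, rng)
    records = []
    # assign at most one planted SSR per TUS so recall is unambiguous
    plant_units: list[tuple[str, int]] = []
    for unit, count, n in config.ssr_plant_spec:
        plant_units += [(unit, count)] * n
    if len(plant_units) > config.n_tus:
        raise ValueError("more planted SSRs than TUSs")
    hosts = rng.choice(config.n_tus, size=len(plant_units), replace=False)
    plants = dict(zip(hosts.tolist(), plant_units))
    polya_hosts = set(
        rng.choice(config.n_tus, size=int(config.polya_fraction * config.n_tus), replace=False).tolist()
    )
    for i in range(config.n_tus):
        tid = f"TUS{i:05d}"
        seq = _random_seq(rng, int(lengths[i]))
        if i in plants:
            unit, count = plants[i]
            tract = unit * count
            # flank placement keeps the repeat internal and non-extendable
            pos = int(rng.integers(10, len(seq) - len(tract) - 10))
            while seq[pos - 1] == unit[-1] or seq[pos + len(tract)] == unit[0]:
                pos = int(rng.integers(10, len(seq) - len(tract) - 10))
            seq = seq[:pos] + tract + seq[pos + len(tract):]
            truth.ssrs.append(
                {"tus_id": tid, "start": pos + 1, "unit": unit, "repeat_count": count}
            )
        if i in polya_hosts:
            seq = seq + "A" * int(rng.integers(10, 25))
            truth.polya_tus.append(tid)
        records.append(SequenceRecord(id=tid, residues=seq, origin="tus"))
    return records, truth


def simulate_genome_and_alignments(
    config: SimConfig,
    tus_records: Sequence[SequenceRecord],
    truth: TruthTable,
    rng: np.random.Generator,
):
    """Toy genome: TUS exons separated by planted introns, plus linked pairs.

    Returns (genome record, list of SplicedAlignment).  The emitted
    alignments encode the exact exon blocks, so intron lengths recomputed
    from them equal the planted truth.
    """
    from .markers import SplicedAlignment

    n_genes = config.n_genes_with_introns
    n_pair_tus = 2 * (config.n_linked_pairs + config.n_unlinked_pairs)
    # intron-bearing genes use TUSs without poly-A tails (clean exon arithmetic)
    polya = set(truth.polya_tus)
    eligible = [r for r in tus_records if r.id not in polya and len(r) >= 240]
    chosen = eligible[: n_genes + n_pair_tus]
    if len(chosen) < n_genes + n_pair_tus:
        raise ValueError("not enough eligible TUSs for genome simulation")
    gene_tus, pair_tus = chosen[:n_genes], chosen[n_genes:]

    parts: list[str] = []
    alignments: list[SplicedAlignment] = []
    cursor = 0  # 0-based genome length so far

    def spacer(length: int) -> None:
        nonlocal cursor
        parts.append(_random_seq(rng, length))
        cursor += length

    spacer(200)
    for rec in gene_tus:
        n_exons = int(rng.integers(2, config.exons_per_gene_max + 1))
        cuts = sorted(
            rng.choice(np.arange(60, len(rec) - 60), size=n_exons - 1, replace=False).tolist()
        )
        bounds = [0] + cuts + [len(rec)]
        blocks = []
        for k in range(n_exons):
            t0, t1 = bounds[k], bounds[k + 1]
            gstart = cursor + 1
            parts.append(rec.residues[t0:t1])
            cursor += t1 - t0
            blocks.append((gstart, cursor, t0 + 1, t1))
            if k < n_exons - 1:
                ilen = int(rng.integers(config.intron_length_min, config.intron_length_max + 1))
                truth.introns.append(
                    {"tus_id": rec.id, "junction_tpos": t1, "length": ilen}
                )
                spacer(ilen)
        alignments.append(
            SplicedAlignment(rec.id, "toygenome", "+", blocks, score=1000.0)
        )
        spacer(3000)

    def place_single_exon(rec: SequenceRecord) -> None:
        nonlocal cursor
        gstart = cursor + 1
        parts.append(rec.residues)
        cursor += len(rec)
        alignments.append(
            SplicedAlignment(
                rec.id, "toygenome", "+", [(gstart, cursor, 1, len(rec))], score=1000.0
            )
        )

    it = iter(pair_tus)
    for _ in range(config.n_linked_pairs):
        a, b = next(it), next(it)
        place_single_exon(a)
        spacer(int(rng.integers(100, 1001)))
        place_single_exon(b)
        truth.linked_pairs.append((a.id, b.id))
        spacer(3000)
    for _ in range(config.n_unlinked_pairs):
        a, b = next(it), next(it)
        place_single_exon(a)
        spacer(int(rng.integers(1200, 2500)))
        place_single_exon(b)
        truth.unlinked_pairs.append((a.id, b.id))
        spacer(3000)

    genome = SequenceRecord(id="toygenome", residues="".join(parts), origin="genome")
    return genome, alignments


_SUBST = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}


def apply_variants(
    config: SimConfig,
    tus_records: Sequence[SequenceRecord],
    truth: TruthTable,
    rng: np.random.Generator,
) -> dict[str, str]:
    """Genotype-2 haplotypes: planted substitutions on distinct TUSs."""
    hosts = rng.choice(len(tus_records), size=config.n_variants, replace=False)
    haplotypes = {rec.id: rec.residues for rec in tus_records}
    for i in hosts.tolist():
        rec = tus_records[i]
        pos = int(rng.integers(config.tag_length, len(rec) - config.tag_length))
        ref = rec.residues[pos]
        alt = _SUBST[ref][int(rng.integers(0, 3))]
        haplotypes[rec.id] = (
            haplotypes[rec.id][:pos] + alt + haplotypes[rec.id][pos + 1:]
        )
        truth.variants.append(
            {
                "tus_id": rec.id, "pos": pos + 1, "ref": ref, "alt": alt,
                "designed_freq": config.variant_alt_freq,
            }
        )
    return haplotypes


def _library_weights(
    config: SimConfig,
    tus_ids: Sequence[str],
    truth: TruthTable,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-TUS sampling weights for the two libraries.

    Baseline abundances are log-normal; a planted log2 fold change fc is
    split symmetrically (x 2^(+fc/2) in library 1, x 2^(-fc/2) in
    library 2); exclusive TUSs get zero weight in the other library.
    """
    n = len(tus_ids)
    base = rng.lognormal(config.abundance_mu, config.abundance_sigma, size=n)
    w1, w2 = base.copy(), base.copy()
    fc_hosts: list[int] = []
    candidates = list(range(n))
    rng.shuffle(candidates)
    it = iter(candidates)
    for fc, count in config.fold_change_spec:
        for _ in range(count):
            i = next(it)
            w1[i] *= 2 ** (fc / 2)
            w2[i] *= 2 ** (-fc / 2)
            truth.log2fc[tus_ids[i]] = fc
            fc_hosts.append(i)
    for _ in range(config.n_exclusive_g1):
        i = next(it)
        w2[i] = 0.0
        truth.exclusive_g1.append(tus_ids[i])
    for _ in range(config.n_exclusive_g2):
        i = next(it)
        w1[i] = 0.0
        truth.exclusive_g2.append(tus_ids[i])
    return w1 / w1.sum(), w2 / w2.sum()


def _draw_tags(
    rng: np.random.Generator,
    sequences: Sequence[str],
    weights: np.ndarray,
    n_tags: int,
    tag_length: int,
    error_rate: float,
    prefix: str,
) -> list[SequenceRecord]:
    choices = rng.choice(len(sequences), size=n_tags, p=weights)
    tags = []
    for k, idx in enumerate(choices.tolist()):
        seq = sequences[idx]
        start = int(rng.integers(0, len(seq) - tag_length + 1))
        window = list(seq[start : start + tag_length])
        if error_rate > 0:
            n_err = rng.binomial(tag_length, error_rate)
            for p in rng.choice(tag_length, size=n_err, replace=False).tolist():
                window[p] = _SUBST[window[p]][int(rng.integers(0, 3))]
        tags.append(
            SequenceRecord(id=f"{prefix}_{k:07d}", residues="".join(window), origin="tag")
        )
    return tags


def simulate_tags(
    config: SimConfig,
    tus_records: Sequence[SequenceRecord],
    haplotypes_g2: dict[str, str],
    truth: TruthTable,
    rng: np.random.Generator,
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Two tag libraries: library 1 from the reference haplotype (genotype 1),
    library 2 from the variant-bearing haplotype (genotype 2)."""
    tus_ids = [r.id for r in tus_records]
    w1, w2 = _library_weights(config, tus_ids, truth, rng)
    seqs_g1 = [r.residues for r in tus_records]
    seqs_g2 = [haplotypes_g2[r.id] for r in tus_records]
    lib1 = _draw_tags(
        rng, seqs_g1, w1, config.library_size_1, config.tag_length,
        config.error_rate, "g1",
    )
    lib2 = _draw_tags(
        rng, seqs_g2, w2, config.library_size_2, config.tag_length,
        config.error_rate, "g2",
    )
    return lib1, lib2


def simulate_ortholog_hits(
    design: tuple[int, int, int, int],
    n_queries: int | None = None,
    qlen: int = 500,
    seed: int = 0,
):
    """Six-species hit tables realizing designed cascade outcomes exactly.

    ``design`` = (n1, n2, n3, n4): queries surviving the all-species
    similarity stage, the identical-annotation stage, the paralog
    removal, and the prior-COS exclusion.  Returns
    (per_species_hits, annotations, prior_cos_hits, qlens, truth dict).
    """
    from .seqio import HitRecord

    n1, n2, n3, n4 = design
    if not n1 >= n2 >= n3 >= n4 >= 0:
        raise ValueError("cascade design must be non-increasing")
    n_queries = n_queries if n_queries is not None else n1 + 10
    if n_queries < n1:
        raise ValueError("n_queries must be >= n1")
    species = ["medicago", "soybean", "lotus", "pigeonpea", "cowpea", "peanut"]
    per_species: dict[str, list[HitRecord]] = {s: [] for s in species}
    annotations: dict[str, str] = {}
    prior_hits: list[HitRecord] = []
    qlens: dict[str, int] = {}
    truth = {"design": list(design), "roles": {}}

    def hit(q, s, subject, evalue, bitscore):
        return HitRecord(
            query=q, subject=subject, pct_identity=92.0, aln_len=int(qlen * 0.6),
            mismatches=10, gap_opens=1, qstart=1, qend=int(qlen * 0.6),
            sstart=1, send=int(qlen * 0.6), evalue=evalue, bitscore=bitscore,
            qlen=qlen,
        )

    for k in range(n_queries):
        q = f"COSQ{k:04d}"
        qlens[q] = qlen
        if k < n4:
            role = "survivor"
        elif k < n3:
            role = "prior_cos_match"
        elif k < n2:
            role = "paralog"
        elif k < n1:
            role = "annotation_mismatch"
        else:
            role = "missing_species"
        truth["roles"][q] = role
        for si, s in enumerate(species):
            subject = f"{s}_prot_{k:04d}"
            if role == "missing_species" and si == 0:
                # only a weak hit in the first species: fails the 1e-30 stage
                per_species[s].append(hit(q, s, subject, 1e-10, 60.0))
                continue
            per_species[s].append(hit(q, s, subject, 1e-40, 200.0))
            if role == "annotation_mismatch" and si == 0:
                annotations[subject] = f"unrelated transporter {k}"
            else:
                annotations[subject] = f"Conserved protein kinase {k}"
            if role == "paralog" and si == 1:
                dup = f"{s}_prot_{k:04d}dup"
                per_species[s].append(hit(q, s, dup, 1e-38, 190.0))
                annotations[dup] = f"Conserved protein kinase {k}"
        if role == "prior_cos_match":
            prior_hits.append(hit(q, "priorCOS", f"cos_{k:04d}", 1e-12, 120.0))
    return per_species, annotations, prior_hits, qlens, truth


def simulate_all(config: SimConfig):
    """Run every generator under one seed; returns a dict of artifacts."""
    rng = np.random.default_rng(config.seed)
    tus_records, truth = simulate_transcriptome(config, rng)
    genome, alignments = simulate_genome_and_alignments(config, tus_records, truth, rng)
    haplotypes = apply_variants(config, tus_records, truth, rng)
    lib1, lib2 = simulate_tags(config, tus_records, haplotypes, truth, rng)
    return {
        "tus": tus_records,
        "truth": truth,
        "genome": genome,
        "alignments": alignments,
        "haplotypes_g2": haplotypes,
        "tags_g1": lib1,
        "tags_g2": lib2,
    }
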