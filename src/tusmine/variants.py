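"""Inter-genotype variant detection from tag pileups.

Tags from two genotypes are piled up against the TUS consensus (the
assembly derives from genotype 1, so the "other genotype" supplying the
alternate alleles is genotype 2).  Candidates are filtered on the
alternate-allele frequency and read depth *of the non-reference
genotype*, binned into a frequency x depth classification matrix, and
tiered: well-supported (frequency >= 0.9, depth >= 3) and stringent
high-confidence (frequency > 0.60, depth > 10).  The two tiers overlap
by construction, so membership predicates are also exposed separately.

Only substitutions are observable: the 0/1-mismatch ungapped tag mapper
cannot place a tag across an indel, so indel candidates never arise
even though the VCF writer accepts them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import TagAlignment
from .seqio import SequenceRecord, revcomp

BASES = "ACGTN"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

FREQ_ROW_LABELS = (
    "<0.1", "0.10–0.19", "0.20–0.29", "0.30–0.39", "0.40–0.49",
    "0.50–0.59", "0.60–0.69", "0.70–0.79", "0.80–0.89",
    "0.90–1.0",
)
DEPTH_COL_LABELS = (">500", "101–500", "11–100", "3–10")

TIERS = ("candidate", "well_supported", "stringent_high_confidence")


@dataclass
class Pileup:
    """Per-TUS base-count matrices for one genotype.

    ``counts[tus_id]`` is an (L, 5) int array over A/C/G/T/N; depth at a
    position is the row sum.
    """

    genotype: str
    counts: dict[str, np.ndarray] = field(default_factory=dict)

    def depth(self, tus_id: str) -> np.ndarray:
        return self.counts[tus_id].sum(axis=1)


@dataclass
class VariantCandidate:
    tus_id: str
    pos: int  # 1-based on the TUS
    ref_allele: str
    alt_allele: str
    alt_freq: float
    depth: int  # depth in the non-reference genotype
    tier: str = "candidate"

    def __post_init__(self) -> None:
        if not 0.0 <= self.alt_freq <= 1.0:
            raise ValueError(f"alt_freq {self.alt_freq} outside [0,1]")


def build_pileup(
    alignments: Iterable[TagAlignment],
    tus_set: Sequence[SequenceRecord],
    tags: Mapping[str, str],
    genotype_label: str,
) -> Pileup:
    """Accumulate base counts from uniquely placed tag alignments.

    `tags` maps tag id to its residues.  Multi-mapping alignments
    (n_equal_best > 1) are ignored, matching the unique-only counting
    policy used for variant calling.
    """
    lengths = {rec.id: len(rec) for rec in tus_set}
    pileup = Pileup(genotype=genotype_label)
    for aln in alignments:
        if aln.n_equal_best != 1:
            continue
        L = lengths[aln.tus_id]
        seq = tags[aln.tag_id]
        if aln.strand == "-":
            seq = revcomp(seq)
        if aln.pos < 1 or aln.pos + len(seq) - 1 > L:
            raise ValueError(
                f"alignment of {aln.tag_id} at {aln.tus_id}:{aln.pos} exceeds bounds"
            )
        mat = pileup.counts.get(aln.tus_id)
        if mat is None:
            mat = np.zeros((L, len(BASES)), dtype=np.int64)
            pileup.counts[aln.tus_id] = mat
        start = aln.pos - 1
        for offset, base in enumerate(seq):
            mat[start + offset, BASE_INDEX[base]] += 1
    return pileup


def call_candidates(
    pileup_g1: Pileup,
    pileup_g2: Pileup,
    tus_set: Sequence[SequenceRecord],
    min_depth: int = 3,
    max_depth_exclusive: int = 500,
    min_freq: float = 0.1,
) -> tuple[list[VariantCandidate], list[VariantCandidate]]:
    """Detect positions where genotype 2 shows a non-consensus allele.

    Returns ``(passing, binned)``: `passing` are candidates with
    alt_freq > min_freq and min_depth <= depth < max_depth_exclusive
    (tiers assigned); `binned` is the superset with depth >= min_depth
    regardless of frequency or the depth ceiling, feeding the
    classification matrix (which keeps a below-threshold frequency row
    and an above-ceiling depth column).
    """
    passing: list[VariantCandidate] = []
    binned: list[VariantCandidate] = []
    for rec in tus_set:
        mat2 = pileup_g2.counts.get(rec.id)
        mat1 = pileup_g1.counts.get(rec.id)
        if mat2 is None or mat1 is None:
            continue
        depth1 = mat1.sum(axis=1)
        depth2 = mat2.sum(axis=1)
        covered = np.nonzero((depth1 > 0) & (depth2 >= min_depth))[0]
        for p in covered:
            ref = rec.residues[p]
            ref_idx = BASE_INDEX[ref]
            row = mat2[p].copy()
            row[ref_idx] = 0
            row[BASE_INDEX["N"]] = 0
            alt_count = int(row.max())
            if alt_count == 0:
                continue
            alt = BASES[int(row.argmax())]
            depth = int(depth2[p])
            cand = VariantCandidate(
                tus_id=rec.id,
                pos=int(p) + 1,
                ref_allele=ref,
                alt_allele=alt,
                alt_freq=alt_count / depth,
                depth=depth,
            )
            binned.append(cand)
            if cand.alt_freq > min_freq and min_depth <= depth < max_depth_exclusive:
                cand.tier = assign_tier(cand)
                passing.append(cand)
    return passing, binned


def bin_candidate(candidate: VariantCandidate) -> tuple[str, str]:
    """(frequency row, depth column) under the printed band conventions.

    Frequency bands are [0.10,0.20) ... printed "0.10-0.19", with 1.0
    included in the top row; depth columns are 3-10, 11-100, 101-500,
    >500, inclusive at both ends.
    """
    row = min(int(candidate.alt_freq * 10), 9)
    freq_label = FREQ_ROW_LABELS[row]
    d = candidate.depth
    if d > 500:
        depth_label = DEPTH_COL_LABELS[0]
    elif d >= 101:
        depth_label = DEPTH_COL_LABELS[1]
    elif d >= 11:
        depth_label = DEPTH_COL_LABELS[2]
    elif d >= 3:
        depth_label = DEPTH_COL_LABELS[3]
    else:
        raise ValueError(f"depth {d} below the binnable minimum of 3")
    return freq_label, depth_label


def is_well_supported(candidate: VariantCandidate) -> bool:
    return candidate.alt_freq >= 0.9 and candidate.depth >= 3


def is_stringent(candidate: VariantCandidate) -> bool:
    return candidate.alt_freq > 0.60 and candidate.depth > 10


def assign_tier(candidate: VariantCandidate) -> str:
    """Stringent high-confidence beats well-supported beats plain candidate."""
    if is_stringent(candidate):
        return "stringent_high_confidence"
    if is_well_supported(candidate):
        return "well_supported"
    return "candidate"


class ClassificationMatrix:
    """Frequency x depth count matrix (10 rows x 4 depth columns)."""

    def __init__(self) -> None:
        self.table = pd.DataFrame(
            np.zeros((len(FREQ_ROW_LABELS), len(DEPTH_COL_LABELS)), dtype=np.int64),
            index=list(FREQ_ROW_LABELS),
            columns=list(DEPTH_COL_LABELS),
        )
        self.table.index.name = "Frequency difference range"

    @classmethod
    def from_candidates(cls, candidates: Iterable[VariantCandidate]) -> "ClassificationMatrix":
        matrix = cls()
        for cand in candidates:
            row, col = bin_candidate(cand)
            matrix.table.loc[row, col] += 1
        return matrix

    @classmethod
    def from_cells(cls, cells: np.ndarray | Sequence[Sequence[int]]) -> "ClassificationMatrix":
        matrix = cls()
        matrix.table.iloc[:, :] = np.asarray(cells, dtype=np.int64)
        return matrix

    def total(self) -> int:
        return int(self.table.to_numpy().sum())

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t")


def write_vcf(
    candidates: Sequence[VariantCandidate],
    tus_set: Sequence[SequenceRecord],
    path: str | Path,
) -> None:
    """Write candidates as VCF v4.2 (CHROM = TUS id; INFO: AF, DP, TIER).

    Input must be sorted by (tus_id, pos); an unsorted list is an error
    rather than silently re-sorted, so provenance of upstream ordering
    is preserved.
    """
    order = [(c.tus_id, c.pos) for c in candidates]
    if order != sorted(order):
        raise ValueError("candidates must be sorted by (tus_id, pos)")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AF,Number=1,Type=Float,Description="Alternate allele frequency in the non-reference genotype">\n')
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth in the non-reference genotype">\n')
        fh.write('##INFO=<ID=TIER,Number=1,Type=String,Description="Confidence tier">\n')
        for rec in tus_set:
            fh.write(f"##contig=<ID={rec.id},length={len(rec)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in candidates:
            info = f"AF={c.alt_freq:.4f};DP={c.depth};TIER={c.tier}"
            fh.write(
                f"{c.tus_id}\t{c.pos}\t.\t{c.ref_allele}\t{c.alt_allele}\t.\tPASS\t{info}\n"
            )


def tier_counts(candidates: Iterable[VariantCandidate]) -> dict[str, int]:
    """Independent tier memberships (the two confidence tiers overlap)."""
    cands = list(candidates)
    return {
        "passing": len(cands),
        "well_supported": sum(is_well_supported(c) for c in cands),
        "stringent_high_confidence": sum(is_stringent(c) for c in cands),
    }
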