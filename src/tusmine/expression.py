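"""Tag mapping against a TUS set and digital expression with the R-statistic.

Fixed-length tags (36 bp by default) are mapped exactly or with one
mismatch using a k-mer index plus two half-length seed tables: by the
pigeonhole principle a tag placed with <= 1 mismatch matches at least
one of its halves exactly.  Counts are normalised per million mapped
tags of each library; differential representation between the two
libraries is scored with the log-likelihood R-statistic, with R > 6
marking significance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .seqio import SequenceRecord, revcomp

MultimapPolicy = Literal["all", "unique_only", "fractional"]

FOLD_BINS = ("lt1", "b1_2", "b2_3", "b3_4", "gt4")
CATEGORIES = ("both", "exclusive_g1", "exclusive_g2", "undetected")


@dataclass
class TagAlignment:
    """One equal-best placement of a tag on a TUS."""

    tag_id: str
    tus_id: str
    pos: int  # 1-based start on the TUS (forward strand of the TUS)
    strand: str  # '+' or '-'
    mismatches: int
    n_equal_best: int = 1


class TagIndex:
    """Exact + one-mismatch lookup structure over a TUS set.

    Stores every forward `tag_length`-mer of every TUS in a hash, plus
    two seed tables over the first and second half-length windows.
    Reverse-strand placements are found by also querying the reverse
    complement of the tag, so the index itself stays forward-only.
    """

    def __init__(self, tus_set: Sequence[SequenceRecord], tag_length: int = 36):
        seed = tag_length // 2
        if tag_length < 2 * seed or seed < 1:
            raise ValueError("tag_length must be >= 2")
        self.tag_length = tag_length
        self.seed = seed
        self.tus_ids: list[str] = []
        self.tus_seqs: list[str] = []
        self.full: dict[str, list[tuple[int, int]]] = {}
        self.half: dict[str, list[tuple[int, int]]] = {}
        for rec in tus_set:
            if len(rec) < tag_length:
                warnings.warn(
                    f"TUS {rec.id} shorter than tag length {tag_length}; skipped"
                )
                continue
            idx = len(self.tus_ids)
            self.tus_ids.append(rec.id)
            self.tus_seqs.append(rec.residues)
            s = rec.residues
            for p in range(len(s) - tag_length + 1):
                self.full.setdefault(s[p : p + tag_length], []).append((idx, p))
            for p in range(len(s) - seed + 1):
                self.half.setdefault(s[p : p + seed], []).append((idx, p))

    def n_kmers(self) -> int:
        return sum(len(v) for v in self.full.values())


def build_index(tus_set: Sequence[SequenceRecord], tag_length: int = 36) -> TagIndex:
    return TagIndex(tus_set, tag_length)


def _hamming_le1(a: str, b: str) -> int:
    """Mismatch count if <= 1, else 2 (early exit)."""
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > 1:
                return 2
    return mm


def _placements(index: TagIndex, seq: str, max_mismatches: int):
    """All placements of `seq` on the forward TUS strands, best stratum only."""
    exact = index.full.get(seq)
    if exact:
        return [(t, p, 0) for t, p in exact], 0
    if max_mismatches == 0:
        return [], None
    L = index.tag_length
    seed = index.seed
    hits: set[tuple[int, int]] = set()
    for offset, half in ((0, seq[:seed]), (L - seed, seq[L - seed : L])):
        for tus_idx, seed_pos in index.half.get(half, ()):
            start = seed_pos - offset
            s = index.tus_seqs[tus_idx]
            if 0 <= start <= len(s) - L:
                if _hamming_le1(s[start : start + L], seq) == 1:
                    hits.add((tus_idx, start))
    return [(t, p, 1) for t, p in sorted(hits)], (1 if hits else None)


def map_tags(
    tags: Iterable[SequenceRecord],
    index: TagIndex,
    max_mismatches: int = 1,
) -> list[TagAlignment]:
    """Map each tag, returning every equal-best placement.

    Zero-mismatch placements are preferred over one-mismatch ones; the
    forward and reverse orientations compete in the same stratum.
    Multimap policy is applied downstream (``count_tags``), not here.
    """
    alignments: list[TagAlignment] = []
    for tag in tags:
        if len(tag.residues) != index.tag_length:
            raise ValueError(
                f"tag {tag.id} length {len(tag.residues)} != index tag length"
            )
        fwd, mm_f = _placements(index, tag.residues, max_mismatches)
        rev, mm_r = _placements(index, revcomp(tag.residues), max_mismatches)
        placements: list[tuple[int, int, int, str]] = []
        for stratum in (0, 1):
            if mm_f == stratum:
                placements += [(t, p, m, "+") for t, p, m in fwd]
            if mm_r == stratum:
                placements += [(t, p, m, "-") for t, p, m in rev]
            if placements:
                break
        n_best = len(placements)
        for tus_idx, pos0, mm, strand in placements:
            alignments.append(
                TagAlignment(
                    tag_id=tag.id,
                    tus_id=index.tus_ids[tus_idx],
                    pos=pos0 + 1,
                    strand=strand,
                    mismatches=mm,
                    n_equal_best=n_best,
                )
            )
    return alignments


def count_tags(
    alignments: Iterable[TagAlignment], multimap_policy: MultimapPolicy = "unique_only"
) -> dict[str, float]:
    """Per-TUS tag counts under the chosen multi-mapping policy.

    unique_only counts only tags with a single equal-best placement;
    ``all`` counts every placement once; ``fractional`` splits each tag
    across its placements so fractional counts sum to the number of
    mapped tags.
    """
    counts: dict[str, float] = {}
    for aln in alignments:
        if multimap_policy == "unique_only":
            if aln.n_equal_best != 1:
                continue
            w = 1.0
        elif multimap_policy == "all":
            w = 1.0
        elif multimap_policy == "fractional":
            w = 1.0 / aln.n_equal_best
        else:
            raise ValueError(f"unknown multimap policy {multimap_policy!r}")
        counts[aln.tus_id] = counts.get(aln.tus_id, 0.0) + w
    return counts


def r_statistic(x1: float, x2: float, n1: float, n2: float) -> float:
    """Log-likelihood ratio of differential representation between two libraries.

    With pooled rate f = (x1+x2)/(N1+N2),
    R = sum_j x_j * ln(x_j / (N_j * f)), taking 0*ln 0 = 0.
    R = 0 iff the two proportions are equal; both counts zero is undefined.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    if x1 < 0 or x2 < 0:
        raise ValueError("counts must be nonnegative")
    if x1 == 0 and x2 == 0:
        raise ValueError("R undefined when both counts are zero")
    f = (x1 + x2) / (n1 + n2)
    r = 0.0
    for x, n in ((x1, n1), (x2, n2)):
        if x > 0:
            r += x * math.log(x / (n * f))
    return max(r, 0.0)


def classify_expression(x1: float, x2: float) -> str:
    if x1 > 0 and x2 > 0:
        return "both"
    if x1 > 0:
        return "exclusive_g1"
    if x2 > 0:
        return "exclusive_g2"
    return "undetected"


def fold_bin(log2fc: float) -> str:
    """Bin |log2 fold change|: [0,1), [1,2), [2,3), [3,4], (4,inf).

    The boundary value 4 sits in the three-to-four-fold bin; the top bin
    is strictly "more than four-fold".
    """
    a = abs(log2fc)
    if a < 1:
        return "lt1"
    if a < 2:
        return "b1_2"
    if a < 3:
        return "b2_3"
    if a <= 4:
        return "b3_4"
    return "gt4"


def expression_table(
    counts1: Mapping[str, float],
    counts2: Mapping[str, float],
    n1: float,
    n2: float,
    tus_ids: Sequence[str],
) -> pd.DataFrame:
    """Per-TUS expression table for two libraries (g1 = numerator of log2fc).

    cpm_i = x_i * 1e6 / N_i; log2fc and the fold bin are defined only
    for TUSs detected in both libraries; R is defined unless both counts
    are zero.
    """
    rows = []
    for tid in tus_ids:
        x1 = float(counts1.get(tid, 0.0))
        x2 = float(counts2.get(tid, 0.0))
        cpm1 = x1 * 1e6 / n1
        cpm2 = x2 * 1e6 / n2
        category = classify_expression(x1, x2)
        if category == "both":
            l2fc = math.log2(cpm1 / cpm2)
            fb = fold_bin(l2fc)
        else:
            l2fc = math.nan
            fb = "undefined"
        r = r_statistic(x1, x2, n1, n2) if (x1 > 0 or x2 > 0) else math.nan
        rows.append(
            {
                "tus_id": tid, "x1": x1, "x2": x2, "N1": n1, "N2": n2,
                "cpm1": cpm1, "cpm2": cpm2, "log2fc": l2fc, "R": r,
                "category": category, "fold_bin": fb,
            }
        )
    return pd.DataFrame(rows)


def select_de_set(
    table: pd.DataFrame, min_abs_log2fc: float = 2.0, r_threshold: float = 6.0
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Differentially expressed set: |log2fc| >= threshold OR R > threshold.

    Returns the DE rows and the union accounting
    {n_fold, n_r, n_overlap, n_union} (inclusion-exclusion:
    n_union = n_fold + n_r - n_overlap).
    """
    if table.empty:
        return table, {"n_fold": 0, "n_r": 0, "n_overlap": 0, "n_union": 0}
    in_fold = (table["log2fc"].abs() >= min_abs_log2fc).fillna(False)
    in_r = (table["R"] > r_threshold).fillna(False)
    selected = table[in_fold | in_r]
    return selected, {
        "n_fold": int(in_fold.sum()),
        "n_r": int(in_r.sum()),
        "n_overlap": int((in_fold & in_r).sum()),
        "n_union": int((in_fold | in_r).sum()),
    }


def fold_bin_counts(table: pd.DataFrame) -> dict[str, int]:
    """Counts of TUSs per |log2fc| bin, over TUSs detected in both libraries."""
    both = table[table["category"] == "both"]
    return {b: int((both["fold_bin"] == b).sum()) for b in FOLD_BINS}


def category_counts(table: pd.DataFrame) -> dict[str, int]:
    return {c: int((table["category"] == c).sum()) for c in CATEGORIES}
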