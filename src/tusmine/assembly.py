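"""Post-assembly cleanup and TUS classification.

The assembler itself (CAP3 in the original resource; preset
``-p 95 -o 50 -g 3 -y 50 -t 1000`` recorded in :data:`CAP3_PRESET`) is
out of scope: this module consumes an assembler's contig FASTA plus a
read-membership table and performs the downstream cleanup —
poly-A/poly-T tail trimming, low-complexity screening, the two-read
"high-confidence singleton" rule, and read-length histograms.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .seqio import SequenceRecord

#: Assembler parameters of the original resource, recorded for provenance only.
CAP3_PRESET = "-p 95 -o 50 -g 3 -y 50 -t 1000"

TUS_CLASSES = ("contig", "singleton", "high_confidence_singleton")


@dataclass
class ContigLayout:
    """Placement of member reads on one contig (1-based inclusive)."""

    contig_id: str
    length: int
    member_reads: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        if not self.member_reads:
            raise ValueError(f"{self.contig_id}: a contig needs >=1 member read")
        for read_id, start, end in self.member_reads:
            if not (1 <= start <= end <= self.length):
                raise ValueError(
                    f"{self.contig_id}: read {read_id} placement {start}..{end} "
                    f"outside contig 1..{self.length}"
                )


@dataclass
class TUS:
    """A tentative unique sequence with its assembly class."""

    id: str
    sequence: str
    tus_class: str
    n_members: int

    def __post_init__(self) -> None:
        if self.tus_class not in TUS_CLASSES:
            raise ValueError(f"unknown TUS class {self.tus_class!r}")
        if self.tus_class == "singleton" and self.n_members != 1:
            raise ValueError("singleton must have exactly 1 member")
        if self.tus_class == "high_confidence_singleton" and self.n_members != 2:
            raise ValueError("high-confidence singleton must have exactly 2 members")


def _trim_tail_once(residues: str, base: str, min_run: int, max_mismatch_per10: int) -> str:
    """Strip one terminal run of `base` from the 3' end (callers reverse for 5').

    A single interrupting mismatch may be crossed only when the run
    continuing inward of it is long enough to pay for it at the allowed
    rate (>= 10/max_mismatch_per10 matching bases), so isolated template
    bases next to a tail are never swallowed.
    """
    n = len(residues)
    i = n - 1
    run = 0
    while True:
        while i >= 0 and residues[i] == base:
            i -= 1
            run += 1
        if run == 0:
            break
        if max_mismatch_per10 > 0 and i >= 0 and residues[i] != base:
            j = i - 1
            inward = 0
            while j >= 0 and residues[j] == base:
                j -= 1
                inward += 1
            if inward * max_mismatch_per10 >= 10:
                run += 1
                i -= 1
                continue
        break
    if run >= min_run:
        return residues[: n - run]
    return residues


def trim_polya(
    record: SequenceRecord, min_run: int = 8, max_mismatch_per10: int = 1
) -> SequenceRecord:
    """Remove terminal poly-A (3') and poly-T (5') runs.

    A run of length L tolerates at most ``max_mismatch_per10 * L / 10``
    non-A (non-T) bases and must both start and end on the run base.
    Trimming repeats to a fixed point, so the operation is idempotent;
    internal runs are never touched.  The returned record may have an
    empty sequence — the caller decides whether to drop it.
    """
    residues = record.residues
    while True:
        trimmed = _trim_tail_once(residues, "A", min_run, max_mismatch_per10)
        trimmed = _trim_tail_once(trimmed[::-1], "T", min_run, max_mismatch_per10)[::-1]
        if trimmed == residues:
            break
        residues = trimmed
    return replace(record, residues=residues)


def screen_low_complexity(record: SequenceRecord, max_mono_fraction: float = 0.8) -> bool:
    """Return True (keep) unless one base exceeds `max_mono_fraction` of the length."""
    n = len(record.residues)
    if n == 0:
        return False
    for base in "ACGTN":
        if record.residues.count(base) > max_mono_fraction * n:
            return False
    return True


def depth_profile(layout: ContigLayout) -> np.ndarray:
    """Per-base read depth over the contig (length-`layout.length` array)."""
    delta = np.zeros(layout.length + 1, dtype=np.int64)
    for _, start, end in layout.member_reads:
        delta[start - 1] += 1
        delta[end] -= 1
    return np.cumsum(delta[:-1])


def classify_tus(layout: ContigLayout) -> str:
    """Classify a contig layout as contig / singleton / high-confidence singleton.

    A two-read contig whose depth profile has zero variation (both reads
    span the full contig) is informatically indistinguishable from a
    singleton gene expressed at low level, hence "high-confidence
    singleton".
    """
    n = len(layout.member_reads)
    if n == 1:
        return "singleton"
    if n == 2:
        depth = depth_profile(layout)
        if depth.std() == 0:
            return "high_confidence_singleton"
    return "contig"


def length_histogram(
    records: Sequence[SequenceRecord] | Sequence[int], bin_width: int = 50
) -> pd.DataFrame:
    """Bin sequence lengths into [1..w], [w+1..2w], ...

    Returns a DataFrame with columns ``lo``, ``hi``, ``count`` covering
    every bin up to the maximum observed length; counts sum to the input
    size.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lengths = [len(r) if isinstance(r, SequenceRecord) else int(r) for r in records]
    if not lengths:
        return pd.DataFrame(columns=["lo", "hi", "count"]).astype(int)
    n_bins = (max(lengths) - 1) // bin_width + 1
    counts = np.zeros(n_bins, dtype=np.int64)
    for length in lengths:
        counts[(length - 1) // bin_width] += 1
    lo = np.arange(n_bins) * bin_width + 1
    return pd.DataFrame({"lo": lo, "hi": lo + bin_width - 1, "count": counts})


def read_membership_table(path: str | Path) -> dict[str, list[tuple[str, int, int]]]:
    """Read a TSV of (contig_id, read_id, start, end) into per-contig lists."""
    table = pd.read_csv(
        path, sep="\t", names=["contig_id", "read_id", "start", "end"], comment="#"
    )
    members: dict[str, list[tuple[str, int, int]]] = {}
    for row in table.itertuples(index=False):
        members.setdefault(row.contig_id, []).append(
            (row.read_id, int(row.start), int(row.end))
        )
    return members


def classify_assembly(
    contigs: Sequence[SequenceRecord],
    membership: dict[str, list[tuple[str, int, int]]],
) -> list[TUS]:
    """Build the TUS set: every contig classified, missing membership = singleton."""
    tus_set = []
    for rec in contigs:
        members = membership.get(rec.id, [(rec.id, 1, len(rec))])
        layout = ContigLayout(rec.id, len(rec), members)
        cls = classify_tus(layout)
        tus_set.append(TUS(rec.id, rec.residues, cls, len(members)))
    return tus_set


def class_counts(tus_set: Iterable[TUS]) -> dict[str, int]:
    counts = {cls: 0 for cls in TUS_CLASSES}
    for tus in tus_set:
        counts[tus.tus_class] += 1
    return counts
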