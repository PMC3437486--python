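"""MISA-style SSR detection, compound merging, marker filtering and PIC.

Detection finds maximal, non-overlapping, *perfect* tandem repeats of
1–6-nt units.  Units are reported exactly as they occur (AG, GA, TC and
CT are distinct motifs); an optional canonical grouping is available for
reporting but is never applied by default.  Repeat-count minima default
to the canonical MISA profile (mono 10, di 6, tri/tetra/penta/hexa 5).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .seqio import HitRecord, SequenceRecord

#: Canonical MISA minimum repeat counts by unit length.
DEFAULT_MIN_REPEATS: dict[int, int] = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}

#: Maximum interruption (nt) between member SSRs of a compound repeat.
DEFAULT_MAX_INTERRUPTION = 100

#: Class I = total repeat tract >= 20 nt (Temnykh convention).
CLASS1_MIN_LENGTH = 20

UNIT_LENGTH_NAMES = {1: "mono", 2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa"}


@dataclass
class SSRMotif:
    """One perfect tandem repeat, 1-based inclusive coordinates."""

    tus_id: str
    start: int
    end: int
    unit: str
    repeat_count: int
    compound: bool = False

    @property
    def unit_length(self) -> int:
        return len(self.unit)

    @property
    def total_length(self) -> int:
        return self.end - self.start + 1

    @property
    def ssr_class(self) -> str:
        return classify_ssr(self)


@dataclass
class SSRSearchSummary:
    """Search-wide accounting (the shape of a MISA summary table)."""

    n_sequences: int
    total_bp: int
    n_ssrs: int
    n_sequences_with_ssr: int
    n_sequences_with_multiple: int
    n_compound: int
    per_unit_length: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if sum(self.per_unit_length.values()) != self.n_ssrs:
            raise ValueError("per-unit-length counts must sum to n_ssrs")


def _is_primitive(unit: str) -> bool:
    """True unless the unit is itself a tandem repeat of a shorter unit."""
    n = len(unit)
    for d in range(1, n):
        if n % d == 0 and unit == unit[:d] * (n // d):
            return False
    return True


def find_ssrs(
    record: SequenceRecord,
    min_repeats: Mapping[int, int] = DEFAULT_MIN_REPEATS,
) -> list[SSRMotif]:
    """Detect maximal non-overlapping perfect SSRs, left to right.

    At each position the qualifying primitive-unit repeat with the
    greatest total length wins (ties to the shortest unit, so (AT)6 is
    reported rather than the non-primitive (ATAT)3); the scan then
    resumes after its end, making the reported set non-overlapping and
    leftmost-maximal.
    """
    s = record.residues
    n = len(s)
    motifs: list[SSRMotif] = []
    i = 0
    while i < n:
        best: tuple[int, int, str] | None = None  # (total_length, unit_length, unit)
        for ulen in range(1, 7):
            if i + 2 * ulen > n:
                break
            unit = s[i : i + ulen]
            if "N" in unit or not _is_primitive(unit):
                continue
            j = i + ulen
            while j + ulen <= n and s[j : j + ulen] == unit:
                j += ulen
            count = (j - i) // ulen
            if count >= min_repeats.get(ulen, 10**9):
                total = count * ulen
                if best is None or total > best[0]:
                    best = (total, ulen, unit)
        if best is not None:
            total, ulen, unit = best
            motifs.append(
                SSRMotif(
                    tus_id=record.id,
                    start=i + 1,
                    end=i + total,
                    unit=unit,
                    repeat_count=total // ulen,
                )
            )
            i += total
        else:
            i += 1
    return motifs


def merge_compound(
    motifs: Sequence[SSRMotif], max_interruption: int = DEFAULT_MAX_INTERRUPTION
) -> tuple[list[SSRMotif], list[list[SSRMotif]]]:
    """Flag compound SSRs: same-sequence motifs separated by <= max_interruption nt.

    Grouping is transitive over pair adjacency.  Member SSRs keep their
    identity (counts of member SSRs are unchanged); the second return
    value lists each compound group (>= 2 members) in order.
    """
    out: list[SSRMotif] = []
    groups: list[list[SSRMotif]] = []
    current: list[SSRMotif] = []

    def flush() -> None:
        nonlocal current
        compound = len(current) >= 2
        members = [replace(m, compound=compound) for m in current]
        out.extend(members)
        if compound:
            groups.append(members)
        current = []

    for motif in sorted(motifs, key=lambda m: (m.tus_id, m.start)):
        if current and (
            motif.tus_id != current[-1].tus_id
            or motif.start - current[-1].end - 1 > max_interruption
        ):
            flush()
        current.append(motif)
    if current:
        flush()
    return out, groups


def classify_ssr(motif: SSRMotif, class1_min_length: int = CLASS1_MIN_LENGTH) -> str:
    """Class I iff the repeat tract spans at least `class1_min_length` nt."""
    return "I" if motif.total_length >= class1_min_length else "II"


def filter_marker_candidates(
    motifs: Sequence[SSRMotif],
    primer_results: Mapping[int, "object | None"],
    min_product: int = 100,
) -> list[SSRMotif]:
    """Keep motifs suitable as markers.

    A motif survives iff its unit length is >= 2 (mono-nucleotide SSRs
    excluded), primer design succeeded, and the predicted product is at
    least `min_product` bp.  `primer_results` maps motif index to a
    designed pair (anything with a ``product_size_transcript`` attribute)
    or None for a design failure.
    """
    kept = []
    for idx, motif in enumerate(motifs):
        pair = primer_results.get(idx)
        if motif.unit_length < 2 or pair is None:
            continue
        if pair.product_size_transcript >= min_product:
            kept.append(motif)
    return kept


def redundancy_screen(
    candidate_ids: Sequence[str],
    hits: Sequence[HitRecord],
    qlens: Mapping[str, int],
    evalue_max: float = 1e-5,
    min_qcov_pct: float = 30.0,
    min_identity_pct: float = 90.0,
) -> list[str]:
    """Drop candidates matching a prior marker source set.

    A candidate is redundant iff some hit has evalue <= `evalue_max`,
    query coverage >= `min_qcov_pct` and identity > `min_identity_pct`
    (identity strictly greater, per the screen's definition).
    """
    known = set(candidate_ids)
    redundant: set[str] = set()
    for hit in hits:
        if hit.query not in known:
            raise KeyError(f"hit for unknown candidate {hit.query!r}")
        if (
            hit.evalue <= evalue_max
            and hit.qcov_pct(qlens.get(hit.query, hit.qlen)) >= min_qcov_pct
            and hit.pct_identity > min_identity_pct
        ):
            redundant.add(hit.query)
    return [cid for cid in candidate_ids if cid not in redundant]


def pic(allele_frequencies: Sequence[float], tol: float = 1e-9) -> float:
    """Polymorphism information content (Botstein formula).

    PIC = 1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2.
    """
    p = list(allele_frequencies)
    if any(f < 0 for f in p):
        raise ValueError("allele frequencies must be nonnegative")
    if abs(sum(p) - 1.0) > tol:
        raise ValueError(f"allele frequencies sum to {sum(p)}, not 1")
    homo = sum(f * f for f in p)
    cross = sum(
        2.0 * p[i] ** 2 * p[j] ** 2 for i in range(len(p)) for j in range(i + 1, len(p))
    )
    return 1.0 - homo - cross


def summarize_search(
    records: Sequence[SequenceRecord], motifs: Sequence[SSRMotif]
) -> SSRSearchSummary:
    """Aggregate a detection run into the MISA-style summary."""
    per_seq: dict[str, int] = {}
    per_unit = {k: 0 for k in range(1, 7)}
    n_compound = 0
    for m in motifs:
        per_seq[m.tus_id] = per_seq.get(m.tus_id, 0) + 1
        per_unit[m.unit_length] += 1
        if m.compound:
            n_compound += 1
    return SSRSearchSummary(
        n_sequences=len(records),
        total_bp=sum(len(r) for r in records),
        n_ssrs=len(motifs),
        n_sequences_with_ssr=len(per_seq),
        n_sequences_with_multiple=sum(1 for v in per_seq.values() if v > 1),
        n_compound=n_compound,
        per_unit_length=per_unit,
    )


def canonical_unit(unit: str) -> str:
    """Lexicographic minimum over rotations and the reverse complement.

    Only used by the optional canonical-grouping report; default output
    keeps units exactly as they occur.
    """
    from .seqio import revcomp

    forms = []
    for u in (unit, revcomp(unit)):
        forms.extend(u[i:] + u[:i] for i in range(len(u)))
    return min(forms)


def motifs_to_misa_table(motifs: Sequence[SSRMotif]) -> pd.DataFrame:
    """MISA-compatible per-motif table (id, ssr_nr, type, motif, size, start, end)."""
    rows = []
    counter: dict[str, int] = {}
    for m in sorted(motifs, key=lambda m: (m.tus_id, m.start)):
        counter[m.tus_id] = counter.get(m.tus_id, 0) + 1
        rows.append(
            {
                "ID": m.tus_id,
                "SSR nr.": counter[m.tus_id],
                "SSR type": ("c" if m.compound else "p") + str(m.unit_length),
                "SSR": f"({m.unit}){m.repeat_count}",
                "size": m.total_length,
                "start": m.start,
                "end": m.end,
            }
        )
    return pd.DataFrame(
        rows, columns=["ID", "SSR nr.", "SSR type", "SSR", "size", "start", "end"]
    )
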