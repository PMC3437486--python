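"""Primer picking, intron inference, ISR design, and ortholog cascades.

The primer engine is a deterministic exhaustive picker with primer3-like
defaults: length 18–27 (optimum 20), Tm 57–63 °C (optimum 60) by
nearest-neighbor thermodynamics at 50 mM monovalent salt and 50 nM
oligo, |ΔTm| ≤ 3, GC 30–70 %, homopolymer runs ≤ 4.  Among feasible
pairs the best is chosen by (Tm distance from 60, product-size distance
from the optimum, leftmost), so results are reproducible byte for byte.

Intron-spanning (ISR) design places each primer entirely within one
exon of a spliced transcript-to-genome alignment so the pair straddles
at least one predicted intron; the genomic product then exceeds the
transcript product by exactly the spanned intron lengths.

The conserved-ortholog (COS) cascade filters a query set through four
stages: similarity in all six legume species (E ≤ 1e-30), identical
best-hit functional annotation across species, removal of putative
paralogs, and exclusion of queries matching a prior COS set.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from Bio.SeqUtils import MeltingTemp, gc_fraction

from .seqio import HitRecord, SequenceRecord, revcomp

MAX_INTRON_DEFAULT = 5000
MIN_INTRON_DEFAULT = 40
MERGE_MAX_GAP_DEFAULT = 1000


@dataclass
class SplicedAlignment:
    """Exon-block alignment of a TUS to a genome sequence.

    ``blocks`` are (gstart, gend, tstart, tend), 1-based inclusive,
    ascending and non-overlapping on the genome.
    """

    tus_id: str
    genome_seq_id: str
    strand: str
    blocks: list[tuple[int, int, int, int]]
    pct_identity: float = 100.0
    score: float = 0.0

    def __post_init__(self) -> None:
        prev_gend = 0
        for gstart, gend, tstart, tend in self.blocks:
            if gstart <= prev_gend:
                raise ValueError(f"{self.tus_id}: blocks overlap or are unsorted")
            if gend - gstart != tend - tstart:
                raise ValueError(f"{self.tus_id}: block genome/transcript spans differ")
            prev_gend = gend

    @property
    def gstart(self) -> int:
        return self.blocks[0][0]

    @property
    def gend(self) -> int:
        return self.blocks[-1][1]


@dataclass
class Intron:
    """A genomic gap between consecutive exon blocks."""

    donor: int  # first genomic position of the intron
    acceptor: int  # last genomic position of the intron
    length: int
    junction_tpos: int  # transcript position of the exon boundary 5' of the intron

    def __post_init__(self) -> None:
        if self.length != self.acceptor - self.donor + 1:
            raise ValueError("intron length inconsistent with donor/acceptor")


@dataclass
class PrimerParams:
    min_len: int = 18
    max_len: int = 27
    opt_len: int = 20
    min_tm: float = 57.0
    max_tm: float = 63.0
    opt_tm: float = 60.0
    max_tm_diff: float = 3.0
    min_gc: float = 30.0
    max_gc: float = 70.0
    max_homopolymer: int = 4
    product_min: int = 100
    product_max: int = 500
    product_opt: int | None = None  # defaults to midpoint of the range


@dataclass
class PrimerPair:
    left_seq: str
    right_seq: str  # reverse-complement orientation (as synthesised)
    left_pos: int  # 1-based start of left primer on the template
    right_pos: int  # 1-based start of the right primer's binding site
    tm_left: float
    tm_right: float
    gc_left: float
    gc_right: float
    product_size_transcript: int
    product_size_genomic: int | None = None  # ISR only
    marker_type: str = "SSR"  # SSR | ISR | COS


class PrimerFailure(Exception):
    """No feasible primer pair; ``reason`` is a stable code."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


def primer_tm(seq: str) -> float:
    """Nearest-neighbor Tm at 50 mM Na+, 50 nM oligo (primer3-like conditions)."""
    return MeltingTemp.Tm_NN(seq, Na=50, dnac1=50, dnac2=0)


def _max_homopolymer(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _candidate_primers(template: str, params: PrimerParams) -> list[tuple[int, int, float, float]]:
    """All single primers passing length/GC/homopolymer/Tm filters.

    Returns (start0, length, tm, gc_pct) for primers read off the
    forward template strand; the right primer is the reverse complement
    of its window.
    """
    out = []
    n = len(template)
    for length in range(params.min_len, params.max_len + 1):
        for start in range(0, n - length + 1):
            window = template[start : start + length]
            if "N" in window:
                continue
            gc = 100.0 * gc_fraction(window)
            if not params.min_gc <= gc <= params.max_gc:
                continue
            if _max_homopolymer(window) > params.max_homopolymer:
                continue
            tm = primer_tm(window)
            if not params.min_tm <= tm <= params.max_tm:
                continue
            out.append((start, length, tm, gc))
    return out


def _in_one_segment(start0: int, length: int, segments: Sequence[tuple[int, int]] | None) -> bool:
    if segments is None:
        return True
    s, e = start0 + 1, start0 + length  # 1-based inclusive
    return any(s >= lo and e <= hi for lo, hi in segments)


def pick_primers(
    template: str,
    target_interval: tuple[int, int],
    params: PrimerParams | None = None,
    segments: Sequence[tuple[int, int]] | None = None,
    marker_type: str = "SSR",
) -> PrimerPair:
    """Deterministic best primer pair flanking ``target_interval`` (1-based).

    The left primer must end before the target start and the right
    primer's binding site must begin after the target end.  If
    ``segments`` is given (ISR design), each primer must lie entirely
    within one segment.  Raises :class:`PrimerFailure` with a reason
    code when no pair satisfies every constraint.
    """
    params = params or PrimerParams()
    t_start, t_end = target_interval
    if not (1 <= t_start <= t_end <= len(template)):
        raise ValueError("target interval outside template")
    product_opt = params.product_opt or (params.product_min + params.product_max) // 2

    if t_start - 1 < params.min_len or len(template) - t_end < params.min_len:
        raise PrimerFailure("target_too_close_to_template_end")

    candidates = _candidate_primers(template, params)
    lefts = [
        c for c in candidates
        if c[0] + c[1] <= t_start - 1 and _in_one_segment(c[0], c[1], segments)
    ]
    rights = [
        c for c in candidates
        if c[0] >= t_end and _in_one_segment(c[0], c[1], segments)
    ]
    if not lefts or not rights:
        raise PrimerFailure("no_single_primer_candidates")

    r_start = np.array([c[0] for c in rights])
    r_len = np.array([c[1] for c in rights])
    r_tm = np.array([c[2] for c in rights])
    r_end = r_start + r_len  # 0-based exclusive

    best_key = None
    best = None
    for l_start, l_len, l_tm, l_gc in lefts:
        product = r_end - l_start
        feasible = (
            (product >= params.product_min)
            & (product <= params.product_max)
            & (np.abs(r_tm - l_tm) <= params.max_tm_diff)
        )
        idxs = np.nonzero(feasible)[0]
        if idxs.size == 0:
            continue
        score_tm = np.abs(l_tm - params.opt_tm) + np.abs(r_tm[idxs] - params.opt_tm)
        score_prod = np.abs(product[idxs] - product_opt)
        # lexicographic: Tm score, product score, leftmost left, leftmost right
        order = np.lexsort((r_start[idxs], score_prod, np.round(score_tm, 10)))
        j = idxs[order[0]]
        key = (
            round(abs(l_tm - params.opt_tm) + abs(float(r_tm[j]) - params.opt_tm), 10),
            int(abs(product[j] - product_opt)),
            l_start,
            int(r_start[j]),
        )
        if best_key is None or key < best_key:
            best_key = key
            best = (l_start, l_len, l_tm, l_gc, j)
    if best is None:
        raise PrimerFailure("no_feasible_pair")

    l_start, l_len, l_tm, l_gc, j = best
    rs, rl, rtm = int(r_start[j]), int(r_len[j]), float(r_tm[j])
    right_window = template[rs : rs + rl]
    return PrimerPair(
        left_seq=template[l_start : l_start + l_len],
        right_seq=revcomp(right_window),
        left_pos=l_start + 1,
        right_pos=rs + 1,
        tm_left=float(l_tm),
        tm_right=rtm,
        gc_left=float(l_gc),
        gc_right=100.0 * gc_fraction(right_window),
        product_size_transcript=int(rs + rl - l_start),
        marker_type=marker_type,
    )


def infer_introns(
    alignment: SplicedAlignment,
    min_intron: int = MIN_INTRON_DEFAULT,
    max_intron: int = MAX_INTRON_DEFAULT,
) -> list[Intron]:
    """Introns from inter-block genomic gaps.

    Gaps below `min_intron` are alignment artifacts (indels), gaps above
    `max_intron` split the alignment; neither yields an intron.
    """
    introns = []
    for (g1s, g1e, t1s, t1e), (g2s, g2e, t2s, t2e) in zip(
        alignment.blocks, alignment.blocks[1:]
    ):
        gap = g2s - g1e - 1
        if min_intron <= gap <= max_intron:
            introns.append(
                Intron(donor=g1e + 1, acceptor=g2s - 1, length=gap, junction_tpos=t1e)
            )
    return introns


def merge_transcribed_units(
    alignments: Sequence[SplicedAlignment], max_gap: int = MERGE_MAX_GAP_DEFAULT
) -> list[list[SplicedAlignment]]:
    """Group same-genome alignments separated by <= max_gap uncovered bp.

    Grouping is transitive and order-invariant: alignments are sorted by
    genomic start and chained while the uncovered gap between the
    running span and the next alignment stays within `max_gap`.
    """
    groups: list[list[SplicedAlignment]] = []
    for aln in sorted(alignments, key=lambda a: (a.genome_seq_id, a.gstart, a.gend, a.tus_id)):
        if (
            groups
            and groups[-1][0].genome_seq_id == aln.genome_seq_id
            and aln.gstart - max(a.gend for a in groups[-1]) - 1 <= max_gap
        ):
            groups[-1].append(aln)
        else:
            groups.append([aln])
    return groups


def design_isr(
    tus_sequence: str,
    alignment: SplicedAlignment,
    introns: Sequence[Intron],
    params: PrimerParams | None = None,
) -> list[PrimerPair]:
    """One primer pair per predicted intron junction, where feasible.

    Each primer sits entirely within one exon (transcript coordinates);
    the product spans at least the targeted junction, and the genomic
    product size equals the transcript product plus the lengths of every
    intron the product spans.  Junctions too close to the transcript
    ends are skipped.
    """
    params = params or PrimerParams(product_min=80, product_max=400)
    exon_tspans = [(tstart, tend) for _, _, tstart, tend in alignment.blocks]
    junction_lengths = {i.junction_tpos: i.length for i in introns}
    pairs = []
    for intron in introns:
        jt = intron.junction_tpos
        try:
            pair = pick_primers(
                tus_sequence,
                (jt, jt + 1),
                params,
                segments=exon_tspans,
                marker_type="ISR",
            )
        except PrimerFailure:
            continue
        left_end = pair.left_pos + len(pair.left_seq) - 1
        right_end = pair.right_pos + len(pair.right_seq) - 1
        spanned = sum(
            length
            for tpos, length in junction_lengths.items()
            if left_end <= tpos < right_end
        )
        pair.product_size_genomic = pair.product_size_transcript + spanned
        pairs.append(pair)
    return pairs


def filter_hits_cascade(
    hits: Sequence[HitRecord],
    qlens: Mapping[str, int] | None = None,
    evalue_max: float = 1e-10,
    min_qcov_pct: float | None = None,
    min_identity_pct: float | None = None,
    min_qaln_len: int | None = None,
) -> tuple[set[str], set[str]]:
    """Generic similarity screen: queries surviving all supplied thresholds.

    Returns (surviving queries, distinct matched subjects).  The GSS
    screen of the original resource is this filter at E <= 1e-10,
    minimum alignment length 70 and identity >= 80 %.
    """
    queries: set[str] = set()
    subjects: set[str] = set()
    for hit in hits:
        if hit.evalue > evalue_max:
            continue
        if min_identity_pct is not None and hit.pct_identity < min_identity_pct:
            continue
        if min_qaln_len is not None and hit.aln_len < min_qaln_len:
            continue
        if min_qcov_pct is not None:
            qlen = (qlens or {}).get(hit.query, hit.qlen)
            if qlen is None:
                raise KeyError(f"query length unknown for {hit.query} (qcov filter)")
            if 100.0 * hit.aln_len / qlen < min_qcov_pct:
                continue
        queries.add(hit.query)
        subjects.add(hit.subject)
    return queries, subjects


_ANNOT_STRIP = re.compile(r"\b(isoform\s*\S*|fragment|partial)\b")
_ANNOT_PUNCT = re.compile(r"[^\w\s]")


def normalize_annotation(text: str) -> str:
    """Case-folded, punctuation-stripped description with isoform/fragment
    suffixes removed, for cross-species annotation comparison."""
    t = text.casefold()
    t = _ANNOT_STRIP.sub(" ", t)
    t = _ANNOT_PUNCT.sub(" ", t)
    return " ".join(t.split())


@dataclass
class CascadeResult:
    stage1: set[str]
    stage2: set[str]
    stage3: set[str]
    stage4: set[str]
    paralogs: set[str]

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return (len(self.stage1), len(self.stage2), len(self.stage3), len(self.stage4))


def _best_hit(hits: Sequence[HitRecord]) -> HitRecord:
    return min(hits, key=lambda h: (h.evalue, -h.bitscore))


def cos_cascade(
    per_species_hits: Mapping[str, Sequence[HitRecord]],
    annotations: Mapping[str, str],
    prior_cos_hits: Sequence[HitRecord],
    qlens: Mapping[str, int] | None = None,
    evalue_stage1: float = 1e-30,
    evalue_prior: float = 1e-5,
    min_prior_qcov_pct: float = 25.0,
    paralog_bitscore_frac: float = 0.9,
) -> CascadeResult:
    """Four-stage conserved-ortholog filter over six species hit tables.

    Stage 1: a hit at E <= `evalue_stage1` in every species.
    Stage 2: normalized best-hit annotation identical across species.
    Stage 3: drop putative paralogs — queries with, in any one species,
    two or more distinct subjects at E <= `evalue_stage1` whose bitscore
    reaches `paralog_bitscore_frac` of that query's best in the species.
    Stage 4: drop queries matching the prior COS set at
    E <= `evalue_prior` with query coverage >= `min_prior_qcov_pct` %.
    """
    if len(per_species_hits) != 6:
        raise ValueError(f"expected 6 species hit tables, got {len(per_species_hits)}")

    by_species_query: dict[str, dict[str, list[HitRecord]]] = {}
    for species, hits in per_species_hits.items():
        strong: dict[str, list[HitRecord]] = {}
        for h in hits:
            if h.evalue <= evalue_stage1:
                strong.setdefault(h.query, []).append(h)
        by_species_query[species] = strong

    stage1 = set.intersection(*(set(d) for d in by_species_query.values()))

    stage2 = set()
    for q in stage1:
        annots = {
            normalize_annotation(annotations.get(_best_hit(d[q]).subject, ""))
            for d in by_species_query.values()
        }
        if len(annots) == 1 and next(iter(annots)):
            stage2.add(q)

    paralogs = set()
    for q in stage2:
        for d in by_species_query.values():
            best_bits = max(h.bitscore for h in d[q])
            subjects = {
                h.subject for h in d[q] if h.bitscore >= paralog_bitscore_frac * best_bits
            }
            if len(subjects) >= 2:
                paralogs.add(q)
                break
    stage3 = stage2 - paralogs

    prior_matches, _ = filter_hits_cascade(
        [h for h in prior_cos_hits if h.query in stage3],
        qlens=qlens,
        evalue_max=evalue_prior,
        min_qcov_pct=min_prior_qcov_pct,
    )
    stage4 = stage3 - prior_matches

    return CascadeResult(stage1, stage2, stage3, stage4, paralogs)


# --- GFF3 spliced-alignment I/O ---------------------------------------------

def read_gff3_alignments(path: str | Path) -> list[SplicedAlignment]:
    """Read match/match_part GFF3 with Target attributes into alignments.

    Each ``match`` feature is one spliced alignment; its ``match_part``
    children carry the exon blocks, with the transcript interval in the
    Target attribute (``Target=<tus_id> <tstart> <tend>``).
    """
    matches: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"GFF3 line does not have 9 columns: {line!r}")
            seqid, _, ftype, start, end, score, strand, _, attrs = cols
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if kv and "=" in kv
            )
            if ftype == "match":
                matches[attr["ID"]] = {
                    "genome_seq_id": seqid,
                    "strand": strand,
                    "score": float(score) if score != "." else 0.0,
                    "target": attr.get("Target", "").split()[0] if attr.get("Target") else None,
                    "blocks": [],
                }
            elif ftype == "match_part":
                parent = matches[attr["Parent"]]
                t_id, tstart, tend = attr["Target"].split()[:3]
                parent["blocks"].append(
                    (int(start), int(end), int(tstart), int(tend))
                )
                parent["target"] = t_id
    alignments = []
    for m in matches.values():
        blocks = sorted(m["blocks"])
        alignments.append(
            SplicedAlignment(
                tus_id=m["target"],
                genome_seq_id=m["genome_seq_id"],
                strand=m["strand"],
                blocks=blocks,
                score=m["score"],
            )
        )
    return alignments


def write_gff3_alignments(
    alignments: Sequence[SplicedAlignment], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, aln in enumerate(alignments):
            mid = f"match{i:05d}"
            fh.write(
                "\t".join(
                    [
                        aln.genome_seq_id, "tusmine", "match",
                        str(aln.gstart), str(aln.gend), f"{aln.score:g}",
                        aln.strand, ".",
                        f"ID={mid};Target={aln.tus_id} {aln.blocks[0][2]} {aln.blocks[-1][3]}",
                    ]
                )
                + "\n"
            )
            for gstart, gend, tstart, tend in aln.blocks:
                fh.write(
                    "\t".join(
                        [
                            aln.genome_seq_id, "tusmine", "match_part",
                            str(gstart), str(gend), ".", aln.strand, ".",
                            f"Parent={mid};Target={aln.tus_id} {tstart} {tend}",
                        ]
                    )
                    + "\n"
                )


def drop_subthreshold_alignments(
    alignments: Sequence[SplicedAlignment], min_score_frac: float = 0.5
) -> list[SplicedAlignment]:
    """Keep, per TUS, alignments scoring at least `min_score_frac` of its best."""
    best: dict[str, float] = {}
    for aln in alignments:
        best[aln.tus_id] = max(best.get(aln.tus_id, float("-inf")), aln.score)
    return [a for a in alignments if a.score >= min_score_frac * best[a.tus_id]]
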