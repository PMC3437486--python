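"""Primer picking vs exhaustive search, introns, ISR, cascades, GFF3."""

import itertools

import numpy as np
import pytest

from tusmine import markers as mk
from tusmine.seqio import HitRecord


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def hit(q, subject="s", evalue=1e-40, bitscore=200.0, aln_len=300, ident=92.0, qlen=500):
    return HitRecord(q, subject, ident, aln_len, 5, 0, 1, aln_len, 1, aln_len,
                     evalue, bitscore, qlen=qlen)


class TestInferIntrons:
    def aln(self, blocks):
        return mk.SplicedAlignment("t1", "g1", "+", blocks)

    def test_simple_gap_becomes_intron(self):
        (intron,) = mk.infer_introns(self.aln([(1, 100, 1, 100), (201, 300, 101, 200)]))
        assert (intron.donor, intron.acceptor, intron.length) == (101, 200, 100)
        assert intron.junction_tpos == 100

    def test_gap_above_maximum_is_not_an_intron(self):
        assert mk.infer_introns(self.aln([(1, 100, 1, 100), (6101, 6200, 101, 200)])) == []

    def test_gap_below_minimum_is_alignment_noise(self):
        assert mk.infer_introns(self.aln([(1, 100, 1, 100), (116, 215, 101, 200)])) == []

    def test_boundary_gaps(self):
        assert len(mk.infer_introns(self.aln([(1, 100, 1, 100), (141, 240, 101, 200)]))) == 1
        assert len(mk.infer_introns(self.aln([(1, 100, 1, 100), (5101, 5200, 101, 200)]))) == 1


class TestMergeUnits:
    def single(self, tid, gstart, gend, genome="g1"):
        return mk.SplicedAlignment(tid, genome, "+", [(gstart, gend, 1, gend - gstart + 1)])

    def test_small_gap_merges(self):
        groups = mk.merge_transcribed_units(
            [self.single("a", 1, 500), self.single("b", 1301, 1800)]
        )
        assert len(groups) == 1

    def test_large_gap_separates(self):
        groups = mk.merge_transcribed_units(
            [self.single("a", 1, 500), self.single("b", 1702, 2200)]
        )
        assert len(groups) == 2

    def test_transitive_chain_forms_one_unit(self):
        alns = [
            self.single("a", 1, 500),
            self.single("b", 1401, 1900),  # gap 900 from a
            self.single("c", 2801, 3300),  # gap 900 from b
        ]
        # oracle: transitive closure over pairwise adjacency
        adj = {
            (x.tus_id, y.tus_id)
            for x, y in itertools.combinations(alns, 2)
            if y.gstart - x.gend - 1 <= 1000
        }
        assert ("a", "b") in adj and ("b", "c") in adj and ("a", "c") not in adj
        groups = mk.merge_transcribed_units(alns)
        assert len(groups) == 1 and len(groups[0]) == 3

    def test_order_invariant(self, rng):
        alns = [self.single(f"t{i}", 1 + 1600 * i, 500 + 1600 * i) for i in range(8)]
        ref = [[a.tus_id for a in g] for g in mk.merge_transcribed_units(alns)]
        for _ in range(5):
            shuffled = list(alns)
            rng.shuffle(shuffled)
            got = [[a.tus_id for a in g] for g in mk.merge_transcribed_units(shuffled)]
            assert got == ref


def exhaustive_best_pair(template, target, params):
    """Oracle: try every primer pair, score exactly as documented."""
    t_start, t_end = target
    singles = []
    for length in range(params.min_len, params.max_len + 1):
        for start in range(0, len(template) - length + 1):
            w = template[start : start + length]
            gc = 100.0 * sum(c in "GC" for c in w) / length
            if not params.min_gc <= gc <= params.max_gc:
                continue
            if max(len(list(g)) for _, g in itertools.groupby(w)) > params.max_homopolymer:
                continue
            tm = mk.primer_tm(w)
            if not params.min_tm <= tm <= params.max_tm:
                continue
            singles.append((start, length, tm))
    product_opt = params.product_opt or (params.product_min + params.product_max) // 2
    best_key, best = None, None
    for ls, ll, ltm in singles:
        if ls + ll > t_start - 1:
            continue
        for rs, rl, rtm in singles:
            if rs < t_end:
                continue
            product = rs + rl - ls
            if not params.product_min <= product <= params.product_max:
                continue
            if abs(ltm - rtm) > params.max_tm_diff:
                continue
            key = (
                round(abs(ltm - params.opt_tm) + abs(rtm - params.opt_tm), 10),
                abs(product - product_opt),
                ls,
                rs,
            )
            if best_key is None or key < best_key:
                best_key, best = key, (ls, ll, rs, rl)
    return best


class TestPickPrimers:
    def test_matches_exhaustive_oracle(self, rng):
        params = mk.PrimerParams(product_min=80, product_max=300)
        found = 0
        for seed in range(4):
            local = np.random.default_rng(1000 + seed)
            template = random_seq(local, 260)
            target = (120, 140)
            oracle = exhaustive_best_pair(template, target, params)
            if oracle is None:
                with pytest.raises(mk.PrimerFailure):
                    mk.pick_primers(template, target, params)
                continue
            found += 1
            pair = mk.pick_primers(template, target, params)
            ls, ll, rs, rl = oracle
            assert pair.left_pos - 1 == ls and len(pair.left_seq) == ll
            assert pair.right_pos - 1 == rs and len(pair.right_seq) == rl
        assert found >= 2

    def test_pair_satisfies_all_constraints(self, rng):
        template = random_seq(rng, 400)
        pair = mk.pick_primers(template, (180, 220))
        p = mk.PrimerParams()
        for seq, tm, gc in [
            (pair.left_seq, pair.tm_left, pair.gc_left),
            (pair.right_seq, pair.tm_right, pair.gc_right),
        ]:
            assert p.min_len <= len(seq) <= p.max_len
            assert p.min_tm <= tm <= p.max_tm
            assert p.min_gc <= gc <= p.max_gc
        assert abs(pair.tm_left - pair.tm_right) <= p.max_tm_diff
        assert p.product_min <= pair.product_size_transcript <= p.product_max

    def test_right_primer_is_reverse_complement(self, rng):
        from tusmine.seqio import revcomp

        template = random_seq(rng, 400)
        pair = mk.pick_primers(template, (180, 220))
        site = template[pair.right_pos - 1 : pair.right_pos - 1 + len(pair.right_seq)]
        assert pair.right_seq == revcomp(site)

    def test_target_near_template_end_fails(self, rng):
        template = random_seq(rng, 100)
        with pytest.raises(mk.PrimerFailure, match="template_end"):
            mk.pick_primers(template, (95, 98))

    def test_at_only_template_fails_gc_bound(self):
        with pytest.raises(mk.PrimerFailure):
            mk.pick_primers("AT" * 200, (180, 220))


class TestDesignIsr:
    def two_exon_case(self, rng):
        tus = random_seq(rng, 320)
        blocks = [(1001, 1160, 1, 160), (1661, 1820, 161, 320)]
        aln = mk.SplicedAlignment("t1", "g1", "+", blocks, score=100.0)
        introns = mk.infer_introns(aln)
        return tus, aln, introns

    def test_central_intron_gets_spanning_pair(self, rng):
        tus, aln, introns = self.two_exon_case(rng)
        assert len(introns) == 1 and introns[0].length == 500
        pairs = mk.design_isr(tus, aln, introns)
        assert len(pairs) == 1
        pair = pairs[0]
        left_end = pair.left_pos + len(pair.left_seq) - 1
        assert left_end <= 160 < pair.right_pos  # primers flank the junction

    def test_genomic_product_identity_on_two_exon_toy(self, rng):
        tus, aln, introns = self.two_exon_case(rng)
        (pair,) = mk.design_isr(tus, aln, introns)
        assert pair.product_size_genomic == pair.product_size_transcript + 500

    def test_every_pair_spans_a_planted_intron(self, sim):
        tus_seq = {r.id: r.residues for r in sim["tus"]}
        n_pairs = 0
        for aln in sim["alignments"]:
            introns = mk.infer_introns(aln)
            truth_lengths = sorted(
                i["length"] for i in sim["truth"].introns if i["tus_id"] == aln.tus_id
            )
            assert sorted(i.length for i in introns) == truth_lengths
            for pair in mk.design_isr(tus_seq[aln.tus_id], aln, introns):
                n_pairs += 1
                assert pair.product_size_genomic > pair.product_size_transcript
                spanned = pair.product_size_genomic - pair.product_size_transcript
                # spanned introns are a subset sum of this gene's intron lengths
                assert spanned >= min(truth_lengths)
        assert n_pairs > 0

    def test_no_primer_crosses_a_junction(self, sim):
        tus_seq = {r.id: r.residues for r in sim["tus"]}
        for aln in sim["alignments"][:10]:
            introns = mk.infer_introns(aln)
            exons = [(ts, te) for _, _, ts, te in aln.blocks]
            for pair in mk.design_isr(tus_seq[aln.tus_id], aln, introns):
                for start, seq in [
                    (pair.left_pos, pair.left_seq),
                    (pair.right_pos, pair.right_seq),
                ]:
                    end = start + len(seq) - 1
                    assert any(start >= lo and end <= hi for lo, hi in exons)


class TestFilterHitsCascade:
    def test_gss_screen_thresholds(self):
        hits = [
            hit("q1", evalue=1e-12, aln_len=100, ident=85.0),  # passes
            hit("q2", evalue=1e-12, aln_len=60, ident=85.0),  # length < 70
            hit("q3", evalue=1e-8, aln_len=100, ident=85.0),  # evalue fails
            hit("q4", evalue=1e-12, aln_len=100, ident=75.0),  # identity fails
        ]
        queries, subjects = mk.filter_hits_cascade(
            hits, evalue_max=1e-10, min_identity_pct=80.0, min_qaln_len=70
        )
        assert queries == {"q1"}

    def test_empty_table_matches_nothing(self):
        queries, subjects = mk.filter_hits_cascade([], evalue_max=1e-10)
        assert queries == set() and subjects == set()

    def test_qcov_requires_query_length(self):
        h = hit("q1", qlen=None)
        with pytest.raises(KeyError):
            mk.filter_hits_cascade([h], evalue_max=1e-5, min_qcov_pct=30)


class TestCosCascade:
    def test_missing_species_fails_stage_one(self):
        from tusmine.simulate import simulate_ortholog_hits

        per_species, annots, prior, qlens, truth = simulate_ortholog_hits((3, 3, 3, 3), n_queries=5)
        result = mk.cos_cascade(per_species, annots, prior, qlens=qlens)
        missing = {q for q, r in truth["roles"].items() if r == "missing_species"}
        assert missing and not (missing & result.stage1)

    def test_stage_counts_match_design(self):
        from tusmine.simulate import simulate_ortholog_hits

        per_species, annots, prior, qlens, _ = simulate_ortholog_hits((50, 40, 30, 25))
        result = mk.cos_cascade(per_species, annots, prior, qlens=qlens)
        assert result.counts == (50, 40, 30, 25)
        assert len(result.paralogs) == 10

    def test_cascade_is_monotone(self):
        from tusmine.simulate import simulate_ortholog_hits

        per_species, annots, prior, qlens, _ = simulate_ortholog_hits((12, 9, 5, 2))
        n1, n2, n3, n4 = mk.cos_cascade(per_species, annots, prior, qlens=qlens).counts
        assert n1 >= n2 >= n3 >= n4

    def test_requires_six_species(self):
        with pytest.raises(ValueError):
            mk.cos_cascade({"a": [], "b": []}, {}, [])


class TestAnnotationNormalization:
    @pytest.mark.parametrize(
        "a,b",
        [
            ("Protein kinase 2", "protein kinase 2"),
            ("ATP synthase, beta subunit", "ATP synthase beta subunit"),
            ("heat shock protein (Fragment)", "Heat shock protein"),
            ("dehydrin isoform X1", "dehydrin"),
        ],
    )
    def test_equivalent_descriptions_normalize_identically(self, a, b):
        assert mk.normalize_annotation(a) == mk.normalize_annotation(b)

    def test_distinct_proteins_stay_distinct(self):
        assert mk.normalize_annotation("protein kinase") != mk.normalize_annotation(
            "sugar transporter"
        )


class TestGff3:
    def test_round_trip_preserves_blocks(self, tmp_path, sim):
        path = tmp_path / "aln.gff3"
        mk.write_gff3_alignments(sim["alignments"], path)
        back = mk.read_gff3_alignments(path)
        original = {a.tus_id: a.blocks for a in sim["alignments"]}
        assert {a.tus_id: a.blocks for a in back} == original

    def test_intron_truth_recomputed_from_gff3(self, tmp_path, sim):
        path = tmp_path / "aln.gff3"
        mk.write_gff3_alignments(sim["alignments"], path)
        truth = {}
        for i in sim["truth"].introns:
            truth.setdefault(i["tus_id"], []).append(i["length"])
        for aln in mk.read_gff3_alignments(path):
            gaps = [
                b2[0] - b1[1] - 1 for b1, b2 in zip(aln.blocks, aln.blocks[1:])
            ]
            assert sorted(gaps) == sorted(truth.get(aln.tus_id, []))

    def test_subthreshold_alignments_dropped(self):
        a = mk.SplicedAlignment("t1", "g1", "+", [(1, 100, 1, 100)], score=100.0)
        b = mk.SplicedAlignment("t1", "g1", "+", [(501, 600, 1, 100)], score=40.0)
        kept = mk.drop_subthreshold_alignments([a, b])
        assert kept == [a]
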