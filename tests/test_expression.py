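"""Tag mapping, normalization, fold bins and the R-statistic."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tusmine import expression as ex
from tusmine.seqio import SequenceRecord, revcomp


def rec(seq, rid):
    return SequenceRecord(id=rid, residues=seq)


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def brute_force_map(tag, tus_list, max_mismatches=1):
    """All-positions scan over both strands, best mismatch stratum only."""
    L = len(tag)
    hits = {0: [], 1: []}
    for tus in tus_list:
        s = tus.residues
        for p in range(len(s) - L + 1):
            window = s[p : p + L]
            for strand, query in (("+", tag), ("-", revcomp(tag))):
                mm = sum(a != b for a, b in zip(window, query))
                if mm <= max_mismatches:
                    hits[mm].append((tus.id, p + 1, strand))
    return sorted(hits[0]) if hits[0] else sorted(hits[1])


class TestIndex:
    def test_kmer_count_of_single_tus(self, rng):
        index = ex.build_index([rec(random_seq(rng, 100), "t1")], tag_length=36)
        assert index.n_kmers() == 65  # 100 - 36 + 1

    def test_short_tus_skipped_with_warning(self, rng):
        with pytest.warns(UserWarning, match="skipped"):
            index = ex.build_index([rec(random_seq(rng, 20), "t1")], tag_length=36)
        assert index.tus_ids == []

    def test_every_sampled_kmer_is_retrievable(self, rng):
        tus_list = [rec(random_seq(rng, 200), f"t{i}") for i in range(10)]
        index = ex.build_index(tus_list, tag_length=36)
        for tus in tus_list:
            for p in (0, 50, 164):
                kmer = tus.residues[p : p + 36]
                assert any(
                    index.tus_ids[i] == tus.id and q == p for i, q in index.full[kmer]
                )


class TestMapTags:
    def test_unique_exact_placement(self, rng):
        tus = rec(random_seq(rng, 120), "t1")
        tag = rec(tus.residues[40:76], "tag1")
        index = ex.build_index([tus])
        (aln,) = ex.map_tags([tag], index)
        assert (aln.tus_id, aln.pos, aln.strand, aln.mismatches, aln.n_equal_best) == (
            "t1", 41, "+", 0, 1,
        )

    def test_shared_substring_counts_equal_best(self, rng):
        core = random_seq(rng, 36)
        t1 = rec(random_seq(rng, 30) + core + random_seq(rng, 30), "t1")
        t2 = rec(random_seq(rng, 10) + core + random_seq(rng, 50), "t2")
        alns = ex.map_tags([rec(core, "tag1")], ex.build_index([t1, t2]))
        assert len(alns) == 2 and all(a.n_equal_best == 2 for a in alns)

    def test_two_mismatches_unmapped(self, rng):
        tus = rec(random_seq(rng, 120), "t1")
        window = list(tus.residues[10:46])
        for p in (3, 30):
            window[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[window[p]]
        alns = ex.map_tags([rec("".join(window), "tag1")], ex.build_index([tus]))
        assert alns == []

    def test_reverse_strand_placement_found(self, rng):
        tus = rec(random_seq(rng, 120), "t1")
        tag = rec(revcomp(tus.residues[20:56]), "tag1")
        (aln,) = ex.map_tags([tag], ex.build_index([tus]))
        assert aln.strand == "-" and aln.pos == 21

    def test_agrees_with_brute_force_scan(self, rng):
        tus_list = [rec(random_seq(rng, 150), f"t{i}") for i in range(20)]
        index = ex.build_index(tus_list)
        for trial in range(60):
            src = tus_list[int(rng.integers(0, 20))]
            p = int(rng.integers(0, len(src.residues) - 36))
            tag_seq = list(src.residues[p : p + 36])
            if trial % 2:
                q = int(rng.integers(0, 36))
                tag_seq[q] = "ACGT"[int(rng.integers(0, 4))]
            tag = rec("".join(tag_seq), "tag")
            got = sorted(
                (a.tus_id, a.pos, a.strand) for a in ex.map_tags([tag], index)
            )
            assert got == brute_force_map(tag.residues, tus_list)


class TestCountTags:
    def alns(self, spec):
        return [
            ex.TagAlignment(f"tag{i}", tus, pos=1, strand="+", mismatches=0, n_equal_best=nb)
            for i, (tus, nb) in enumerate(spec)
        ]

    def test_unique_only_counts(self):
        counts = ex.count_tags(self.alns([("t1", 1)] * 10), "unique_only")
        assert counts == {"t1": 10.0}

    def test_fractional_splits_multimappers(self):
        alns = [
            ex.TagAlignment("tag0", "t1", 1, "+", 0, 2),
            ex.TagAlignment("tag0", "t2", 1, "+", 0, 2),
        ]
        counts = ex.count_tags(alns, "fractional")
        assert counts == {"t1": 0.5, "t2": 0.5}
        assert sum(counts.values()) == 1.0  # one mapped tag

    def test_unique_only_recovers_simulator_truth_scale(self, sim, sim_mapped):
        # planted fold changes are recovered within sampling error
        counts1, counts2 = sim_mapped["counts1"], sim_mapped["counts2"]
        n1, n2 = sim_mapped["n1"], sim_mapped["n2"]
        for tus_id, fc in sim["truth"].log2fc.items():
            x1, x2 = counts1.get(tus_id, 0), counts2.get(tus_id, 0)
            if x1 >= 20 and x2 >= 20:
                observed = math.log2((x1 / n1) / (x2 / n2))
                assert abs(observed - fc) < 0.5


class TestRStatistic:
    def test_equal_proportions_give_zero(self):
        assert ex.r_statistic(10, 10, 1e6, 1e6) == 0.0

    def test_exclusive_count_closed_form(self):
        assert ex.r_statistic(20, 0, 1e6, 1e6) == pytest.approx(20 * math.log(2))

    def test_four_fold_closed_form(self):
        expected = 100 * math.log(1.6) + 25 * math.log(0.4)
        assert ex.r_statistic(100, 25, 1e6, 1e6) == pytest.approx(expected)

    def test_symmetry(self):
        assert ex.r_statistic(7, 31, 2e6, 5e5) == pytest.approx(
            ex.r_statistic(31, 7, 5e5, 2e6)
        )

    def test_both_zero_undefined(self):
        with pytest.raises(ValueError):
            ex.r_statistic(0, 0, 1e6, 1e6)

    @settings(deadline=None, derandomize=True)
    @given(
        st.integers(0, 10_000), st.integers(0, 10_000),
        st.integers(10_000, 10**7), st.integers(10_000, 10**7),
    )
    def test_nonnegative(self, x1, x2, n1, n2):
        if x1 == 0 and x2 == 0:
            return
        assert ex.r_statistic(x1, x2, n1, n2) >= 0.0


class TestCategoriesAndBins:
    @pytest.mark.parametrize(
        "x1,x2,expected",
        [(5, 3, "both"), (4, 0, "exclusive_g1"), (0, 2, "exclusive_g2"), (0, 0, "undetected")],
    )
    def test_classify_expression(self, x1, x2, expected):
        assert ex.classify_expression(x1, x2) == expected

    @pytest.mark.parametrize(
        "fc,expected",
        [(0.0, "lt1"), (-0.99, "lt1"), (1.0, "b1_2"), (2.5, "b2_3"),
         (-3.2, "b3_4"), (4.0, "b3_4"), (4.3, "gt4"), (-4.5, "gt4")],
    )
    def test_fold_bin_boundaries(self, fc, expected):
        assert ex.fold_bin(fc) == expected

    def test_categories_partition_table(self, sim, sim_mapped):
        table = ex.expression_table(
            sim_mapped["counts1"], sim_mapped["counts2"],
            sim_mapped["n1"], sim_mapped["n2"], [r.id for r in sim["tus"]],
        )
        counts = ex.category_counts(table)
        assert sum(counts.values()) == len(sim["tus"])
        assert counts["exclusive_g1"] >= len(sim["truth"].exclusive_g1)
        assert counts["exclusive_g2"] >= len(sim["truth"].exclusive_g2)


class TestDeSelection:
    def synthetic_table(self, n_fold, n_r, n_overlap, n_null):
        rows = []
        for i in range(n_fold - n_overlap):
            rows.append({"log2fc": 2.5, "R": 1.0})
        for i in range(n_r - n_overlap):
            rows.append({"log2fc": 0.5, "R": 8.0})
        for i in range(n_overlap):
            rows.append({"log2fc": 3.0, "R": 9.0})
        for i in range(n_null):
            rows.append({"log2fc": 0.2, "R": 0.5})
        return pd.DataFrame(rows)

    def test_union_matches_inclusion_exclusion_oracle(self):
        table = self.synthetic_table(40, 25, 7, 100)
        _, acc = ex.select_de_set(table)
        assert acc == {"n_fold": 40, "n_r": 25, "n_overlap": 7, "n_union": 58}
        assert acc["n_union"] == acc["n_fold"] + acc["n_r"] - acc["n_overlap"]

    def test_empty_records_give_empty_set(self):
        de, acc = ex.select_de_set(pd.DataFrame())
        assert de.empty and acc["n_union"] == 0
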