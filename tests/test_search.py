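"""Seeded local alignment: index, extension, E-values, outfmt-6 interop."""

import io as stdio
import math
import random

import numpy as np
import pytest

from onelcode.search import (
    AlignmentHit,
    SearchParams,
    bit_score,
    build_word_index,
    evalue,
    format_blast_tabular,
    parse_blast_tabular,
    reverse_complement,
    seed_extend_search,
    smith_waterman,
)

from _oracles import revcomp as oracle_revcomp
from _oracles import shares_word, sw_score


def random_dna(rng, length):
    return "".join(rng.choice("ACGT") for _ in range(length))


class TestWordIndex:
    def test_posting_count_small(self):
        idx = build_word_index({"t": "ACGTACG"}, word_size=4)
        assert len(idx) == 4  # 7 - 4 + 1

    def test_n_windows_not_indexed(self):
        idx = build_word_index({"t": "ANGTANGTAN"}, word_size=4)
        assert len(idx) == 0

    def test_random_1kb_posting_count(self):
        rng = random.Random(11)
        idx = build_word_index({"t": random_dna(rng, 1000)}, word_size=7)
        assert len(idx) == 994  # L - w + 1

    def test_empty_transcriptome_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_word_index({}, word_size=7)


class TestSeedExtend:
    def make(self, rng, query_len=30, subject_len=200):
        query = random_dna(rng, query_len)
        bg = random_dna(rng, subject_len)
        pos = rng.randrange(subject_len - query_len)
        subject = bg[:pos] + query + bg[pos + query_len :]
        return query, subject, pos

    def test_exact_plant_plus_strand(self):
        rng = random.Random(5)
        query, subject, pos = self.make(rng)
        tx = {"s1": subject}
        hits = seed_extend_search(("q", query), build_word_index(tx), tx)
        best = hits[0]
        assert best.strand == "plus"
        assert best.identity_pct == 100.0
        assert best.score == len(query) * 2
        assert (best.q_start, best.q_end) == (1, len(query))
        assert (best.s_start, best.s_end) == (pos + 1, pos + len(query))

    def test_exact_plant_minus_strand(self):
        rng = random.Random(6)
        query, subject, pos = self.make(rng)
        tx = {"s1": subject}
        rc = reverse_complement(query)
        hits = seed_extend_search(("q", rc), build_word_index(tx), tx)
        best = hits[0]
        assert best.strand == "minus"
        assert best.s_start > best.s_end
        assert best.identity_pct == 100.0
        assert (best.s_end, best.s_start) == (pos + 1, pos + len(query))

    def test_short_query_error_names_both_lengths(self):
        tx = {"s": "ACGTACGTACGT"}
        with pytest.raises(ValueError, match=r"6 nt.*7 nt"):
            seed_extend_search(("q", "ACGTAC"), build_word_index(tx), tx)

    def test_strand_symmetry(self):
        """Minus-strand scores of q equal plus-strand scores of revcomp(q)."""
        rng = random.Random(7)
        query, subject, _ = self.make(rng)
        tx = {"s1": subject}
        idx = build_word_index(tx)
        params = SearchParams(evalue_max=1e9)
        fwd = seed_extend_search(("q", query), idx, tx, params)
        rev = seed_extend_search(("q", reverse_complement(query)), idx, tx, params)
        assert {(h.strand, h.score) for h in fwd} == {
            ({"plus": "minus", "minus": "plus"}[h.strand], h.score) for h in rev
        }

    def test_filter_soundness_and_max_targets(self):
        rng = random.Random(8)
        query = random_dna(rng, 25)
        tx = {}
        for i in range(8):
            _, subject, _ = self.make(random.Random(100 + i), 25, 150)
            tx[f"s{i}"] = subject[:60] + query + subject[60:]
        params = SearchParams(max_targets=3)
        hits = seed_extend_search(("q", query), build_word_index(tx), tx, params)
        assert all(h.evalue <= params.evalue_max for h in hits)
        assert len({h.subject_id for h in hits}) <= 3
        # hits sorted by ascending E-value
        evs = [h.evalue for h in hits]
        assert evs == sorted(evs)

    def test_determinism(self):
        rng = random.Random(9)
        query, subject, _ = self.make(rng)
        tx = {"s1": subject, "s2": subject[::-1]}
        idx = build_word_index(tx)
        a = format_blast_tabular(seed_extend_search(("q", query), idx, tx))
        b = format_blast_tabular(seed_extend_search(("q", query), idx, tx))
        assert a == b

    def test_score_consistency_with_alignment_counts(self):
        rng = random.Random(10)
        query, subject, _ = self.make(rng, 40, 300)
        # add noise so the alignment is not exact
        noisy = list(subject)
        for k in range(0, len(noisy), 37):
            noisy[k] = "ACGT"[(("ACGT".index(noisy[k])) + 1) % 4]
        tx = {"s1": "".join(noisy)}
        hits = seed_extend_search(("q", query), build_word_index(tx), tx)
        for h in hits:
            matches = round(h.identity_pct * h.align_len / 100)
            gap_cols = h.align_len - matches - h.mismatches
            assert h.score <= 2 * matches - 3 * h.mismatches
            assert gap_cols >= 0


class TestOracleEquivalence:
    def test_best_score_matches_full_smith_waterman(self):
        """On random pairs guaranteed to share a 7-mer, the seeded search's
        best score per strand equals the brute-force local-alignment
        optimum under identical scoring."""
        rng = random.Random(42)
        params = SearchParams(evalue_max=1e12)
        n_pairs = 80
        for _ in range(n_pairs):
            qlen = rng.randrange(20, 61)
            slen = rng.randrange(100, 501)
            query = random_dna(rng, qlen)
            subject = random_dna(rng, slen)
            # guarantee a shared 7-mer
            wpos = rng.randrange(qlen - 7)
            spos = rng.randrange(slen - 7)
            subject = subject[:spos] + query[wpos : wpos + 7] + subject[spos + 7 :]
            tx = {"s": subject}
            hits = seed_extend_search(("q", query), build_word_index(tx), tx, params)
            for strand, qseq in (("plus", query), ("minus", oracle_revcomp(query))):
                if not shares_word(qseq, subject, 7):
                    continue
                expected = sw_score(qseq, subject)
                got = max((h.score for h in hits if h.strand == strand), default=0)
                assert got == expected, (strand, query, subject)


class TestEvalue:
    LK = (0.625, 0.41)

    def test_formula_against_direct_evaluation(self):
        lam, k = self.LK
        expected = k * 42 * 1e5 * math.exp(-lam * 40)
        got = evalue(40, 42, 10**5, self.LK)
        assert got == pytest.approx(expected, rel=1e-6)

    def test_strictly_decreasing_in_score(self):
        es = [evalue(s, 42, 10**5, self.LK) for s in range(10, 80)]
        assert all(a > b for a, b in zip(es, es[1:]))

    def test_linear_in_db_len(self):
        e1 = evalue(30, 42, 5000, self.LK)
        e2 = evalue(30, 42, 10000, self.LK)
        assert e2 == pytest.approx(2 * e1, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            evalue(0, 10, 10, self.LK)
        with pytest.raises(ValueError):
            evalue(10, 0, 10, self.LK)

    def test_unknown_scheme_requires_lambda_k(self):
        params = SearchParams(match=5, mismatch=-4)
        with pytest.raises(ValueError, match="lambda_k"):
            params.resolve_lambda_k()
        assert SearchParams(match=5, mismatch=-4, lambda_k=(1.0, 0.5)).resolve_lambda_k() == (1.0, 0.5)


class TestSearchParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"word_size": 3},
            {"match": -1},
            {"mismatch": 1},
            {"gap_open": -1},
            {"evalue_max": 0},
            {"max_targets": 0},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SearchParams(**kwargs)


FIXTURE_ROWS = """\
q|fwd|S-C\tNM_000001\t100.000\t42\t0\t0\t1\t42\t61\t102\t1e-12\t79.0
q|fwd|S-C\tNM_000002\t95.000\t40\t2\t0\t1\t40\t120\t61\t0.001\t55.9
q|rev|S-G\tNM_000003\t88.571\t35\t3\t1\t2\t36\t10\t45\t2.5\t30.1
"""


class TestBlastTabular:
    def test_strand_inference(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(FIXTURE_ROWS)
        hits = parse_blast_tabular(str(p))
        assert [h.strand for h in hits] == ["plus", "minus", "plus"]
        assert hits[1].s_start == 120 and hits[1].s_end == 61

    def test_three_row_fixture_round_trips(self):
        hits = parse_blast_tabular(stdio.StringIO(FIXTURE_ROWS))
        assert len(hits) == 3
        again = parse_blast_tabular(stdio.StringIO(format_blast_tabular(hits)))
        assert again == hits

    def test_wrong_column_count_reports_line(self):
        with pytest.raises(ValueError, match="line 4"):
            parse_blast_tabular(stdio.StringIO(FIXTURE_ROWS + "a\tb\tc\n"))

    def test_non_numeric_field_reports_line(self):
        bad = FIXTURE_ROWS.replace("95.000", "ninety-five")
        with pytest.raises(ValueError, match="line 2"):
            parse_blast_tabular(stdio.StringIO(bad))

    def test_own_hits_round_trip(self):
        rng = random.Random(12)
        query = "".join(rng.choice("ACGT") for _ in range(30))
        subject = "AACC" + query + "GGTT" * 20
        tx = {"s1": subject}
        hits = seed_extend_search(("q", query), build_word_index(tx), tx)
        text = format_blast_tabular(hits)
        parsed = parse_blast_tabular(stdio.StringIO(text))
        assert [(h.subject_id, h.strand, h.q_start, h.q_end, h.s_start, h.s_end)
                for h in parsed] == [
            (h.subject_id, h.strand, h.q_start, h.q_end, h.s_start, h.s_end)
            for h in hits
        ]


class TestHitInvariants:
    def test_strand_coordinate_consistency_enforced(self):
        with pytest.raises(ValueError, match="strand"):
            AlignmentHit("q", "s", "minus", 1, 10, 5, 20, 20.0, 100.0, 10, 0, 0, 1.0, 20.0)

    def test_bit_score_monotone(self):
        lk = (0.625, 0.41)
        assert bit_score(50, lk) > bit_score(40, lk)


def test_smith_waterman_handles_n_as_mismatch():
    aln = smith_waterman("ACGTNACGT", "ACGTTACGT", SearchParams())
    # N column scores as a mismatch even against T
    assert aln.score == 8 * 2 - 3
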