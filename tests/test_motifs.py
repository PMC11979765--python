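"""Motif scanner: consensus-to-PWM, exact null score distribution, window
scanning with strand handling, interval intersection."""

import itertools

import numpy as np
import pytest

from grnval.motifs import (
    MotifHit,
    consensus_to_pwm,
    intersect_hits,
    reverse_complement,
    scan_sequence,
    score_distribution,
)

BASES = "ACGT"


def brute_force_pvalues(model, dist):
    """Independent oracle: for every word, tail probability by enumerating
    all 4^L words with their background probabilities."""
    L = len(model)
    words = list(itertools.product(range(4), repeat=L))
    scores = np.array([sum(dist.int_scores[i, b] for i, b in enumerate(w))
                       for w in words])
    probs = np.array([np.prod([model.background[b] for b in w]) for w in words])
    out = {}
    for w, s in zip(words, scores):
        out[w] = probs[scores >= s].sum()
    return out


class TestConsensusToPwm:
    def test_n_positions_take_gc_composition(self):
        m = consensus_to_pwm("N", 0.5)
        assert m.probs[0] == pytest.approx([0.25] * 4)
        m6 = consensus_to_pwm("N", 0.6)
        assert m6.probs[0] == pytest.approx([0.2, 0.3, 0.3, 0.2])

    def test_hsf_consensus_layout(self):
        m = consensus_to_pwm("NGAANNTTCN", 0.47)
        assert len(m) == 10
        gc_positions = [0, 4, 5, 9]
        for i in gc_positions:
            assert m.probs[i] == pytest.approx(m.background)
        # fixed positions put 1 - 3*eps on the consensus base
        assert m.probs[1, BASES.index("G")] == pytest.approx(0.997)
        assert m.probs[2, BASES.index("A")] == pytest.approx(0.997)

    def test_degenerate_code_and_invalid_character(self):
        m = consensus_to_pwm("R", 0.5)  # A or G
        assert m.probs[0, 0] == pytest.approx((1 - 2 * 0.001) / 2)
        with pytest.raises(ValueError, match="X"):
            consensus_to_pwm("AXC", 0.5)


class TestScoreDistribution:
    def test_matches_dinucleotide_enumeration(self):
        m = consensus_to_pwm("AC", 0.5)
        dist = score_distribution(m, bins=500)
        oracle = brute_force_pvalues(m, dist)
        for w, p in oracle.items():
            total = sum(dist.int_scores[i, b] for i, b in enumerate(w))
            assert dist.pvalue(total) == pytest.approx(p, rel=1e-12)

    def test_max_score_pvalue_is_best_word_probability(self):
        m = consensus_to_pwm("ACGT", 0.4)
        dist = score_distribution(m)
        best = dist.int_scores.max(axis=1).sum()
        best_prob = np.prod(
            [m.background[np.argmax(dist.int_scores[i])] for i in range(4)]
        )
        assert dist.pvalue(best) == pytest.approx(best_prob, rel=1e-9)

    def test_refinement_stability(self):
        m = consensus_to_pwm("NGAAN", 0.47)
        d1 = score_distribution(m, bins=1000)
        d2 = score_distribution(m, bins=10000)
        for w in itertools.product(range(4), repeat=5):
            t1 = sum(d1.int_scores[i, b] for i, b in enumerate(w))
            t2 = sum(d2.int_scores[i, b] for i, b in enumerate(w))
            p1, p2 = float(d1.pvalue(t1)), float(d2.pvalue(t2))
            assert p1 == pytest.approx(p2, rel=1e-3)


class TestScanSequence:
    def test_empty_and_short_sequences(self):
        m = consensus_to_pwm("NGAANNTTCN", 0.5)
        assert scan_sequence(m, "") == []
        assert scan_sequence(m, "GAATTC") == []

    def test_planted_consensus_recovered_on_both_strands(self, rng):
        m = consensus_to_pwm("NGAANNTTCN", 0.47)
        core = "TGAAGCTTCA"
        bg = "".join(rng.choice(list(BASES), 60))
        planted = bg[:20] + core + bg[30:]
        hits = scan_sequence(m, planted, p_threshold=0.01)
        assert any(h.start == 20 and h.end == 30 and h.strand == "+" for h in hits)
        planted_rc = bg[:20] + reverse_complement(core) + bg[30:]
        hits_rc = scan_sequence(m, planted_rc, p_threshold=0.01)
        assert any(h.start == 20 and h.end == 30 and h.strand == "-" for h in hits_rc)

    def test_threshold_one_reports_every_clean_window(self):
        m = consensus_to_pwm("GAA", 0.5)
        seq = "ACGTNACGTACG"
        hits = scan_sequence(m, seq, p_threshold=1.0, both_strands=True)
        clean = [i for i in range(len(seq) - 2) if "N" not in seq[i:i + 3]]
        assert len(hits) == 2 * len(clean)

    def test_hit_count_monotone_in_threshold(self, rng):
        m = consensus_to_pwm("NGAANNTTCN", 0.5)
        seq = "".join(rng.choice(list(BASES), 3000))
        counts = [len(scan_sequence(m, seq, p_threshold=p))
                  for p in (0.05, 0.01, 0.001)]
        assert counts[0] >= counts[1] >= counts[2]

    def test_strand_symmetry(self, rng):
        m = consensus_to_pwm("RGAAT", 0.4)
        seq = "".join(rng.choice(list(BASES), 400))
        fwd = scan_sequence(m, seq, p_threshold=0.05)
        rev = scan_sequence(m, reverse_complement(seq), p_threshold=0.05)
        L = len(seq)
        mapped = sorted(
            (L - h.end, L - h.start, "-" if h.strand == "+" else "+",
             round(h.score, 9))
            for h in rev
        )
        assert mapped == sorted(
            (h.start, h.end, h.strand, round(h.score, 9)) for h in fwd
        )

    def test_scanned_pvalues_match_word_enumeration(self, rng):
        m = consensus_to_pwm("NGAAT", 0.47)
        dist = score_distribution(m)
        oracle = brute_force_pvalues(m, dist)
        seq = "".join(rng.choice(list(BASES), 300))
        for h in scan_sequence(m, seq, p_threshold=1.0, both_strands=False):
            w = tuple(BASES.index(c) for c in seq[h.start:h.end])
            assert h.pvalue == pytest.approx(oracle[w], rel=1e-12)


class TestIntersectHits:
    def _hit(self, start, end, sid="s1"):
        return MotifHit(sid, start, end, "+", 1.0, 0.001)

    def test_half_open_boundaries(self):
        hits = [self._hit(10, 20)]
        assert intersect_hits(hits, [("s1", 19, 30)]) == hits  # 1 bp overlap
        assert intersect_hits(hits, [("s1", 20, 30)]) == []  # abutting
        assert intersect_hits(hits, [("s2", 10, 20)]) == []  # other sequence

    def test_malformed_region_rejected(self):
        with pytest.raises(ValueError, match="start >= end"):
            intersect_hits([], [("s1", 5, 5)])

    def test_matches_naive_all_pairs(self, rng):
        hits = [self._hit(int(s), int(s) + 10, f"s{int(c)}")
                for s, c in zip(rng.integers(0, 500, 300), rng.integers(1, 4, 300))]
        regions = [(f"s{int(c)}", int(s), int(s) + int(w))
                   for s, w, c in zip(rng.integers(0, 500, 200),
                                      rng.integers(1, 40, 200),
                                      rng.integers(1, 4, 200))]
        naive = [
            h for h in hits
            if any(h.sequence_id == c and h.start < e and s < h.end
                   for c, s, e in regions)
        ]
        assert intersect_hits(hits, regions) == naive
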