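"""Local alignment scores, Karlin–Altschul E-values and the all-vs-all
similarity matrix.

The Smith–Waterman implementation is checked two ways: against an
independent C implementation (Bio.Align.PairwiseAligner in local mode) on
random short sequences, and against a tiny exhaustive alignment enumerator
that tries every gapped pairing of every substring pair.
"""

import math
import random

import numpy as np
import pytest
from Bio.Align import PairwiseAligner, substitution_matrices

from rptp.errors import AlignmentError, ValidationError
from rptp.similarity import (EvalueParams, evalue, local_align,
                             similarity_matrix)

B62 = substitution_matrices.load("BLOSUM62")
AA = "ACDEFGHIKLMNPQRSTVWY"


def _biopython_local(a: str, b: str) -> float:
    aln = PairwiseAligner()
    aln.substitution_matrix = B62
    aln.open_gap_score = -11.0
    aln.extend_gap_score = -1.0
    aln.mode = "local"
    return float(aln.score(a, b))


def _enumerate_best(a: str, b: str, gap_open=11.0, gap_extend=1.0) -> float:
    """Exhaustive oracle: best affine-gap score over all global alignments of
    all substring pairs of a and b.  Exponential; only for tiny inputs."""
    def best_global(x: str, y: str) -> float:
        best = [-math.inf]

        def rec(i, j, score, state):
            if i == len(x) and j == len(y):
                best[0] = max(best[0], score)
                return
            if i < len(x) and j < len(y):
                rec(i + 1, j + 1, score + B62[x[i], y[j]], "M")
            if i < len(x):
                cost = gap_extend if state == "X" else gap_open
                rec(i + 1, j, score - cost, "X")
            if j < len(y):
                cost = gap_extend if state == "Y" else gap_open
                rec(i, j + 1, score - cost, "Y")

        rec(0, 0, 0.0, "M")
        return best[0]

    best = 0.0
    for i in range(len(a)):
        for k in range(i + 1, len(a) + 1):
            for j in range(len(b)):
                for l in range(j + 1, len(b) + 1):
                    best = max(best, best_global(a[i:k], b[j:l]))
    return best


class TestLocalAlign:
    def test_self_alignment_full_length(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        score, (ra, rb) = local_align(seq, seq)
        assert ra == rb == seq
        assert score == sum(float(B62[c, c]) for c in seq)

    def test_single_residue_positive_pair(self):
        score, pair = local_align("W", "F")
        assert pair == ("W", "F")
        assert score == float(B62["W", "F"]) >= 1

    def test_empty_sequence_rejected(self):
        with pytest.raises(AlignmentError):
            local_align("", "MKT")

    def test_matches_independent_implementation_short(self):
        rng = random.Random(13)
        for _ in range(50):
            a = "".join(rng.choice(AA) for _ in range(rng.randint(1, 12)))
            b = "".join(rng.choice(AA) for _ in range(rng.randint(1, 12)))
            score, (ra, rb) = local_align(a, b)
            assert score == pytest.approx(_biopython_local(a, b))
            assert ra.replace("-", "") in a and rb.replace("-", "") in b

    def test_matches_exhaustive_enumeration_tiny(self):
        rng = random.Random(7)
        for _ in range(8):
            a = "".join(rng.choice(AA) for _ in range(rng.randint(2, 5)))
            b = "".join(rng.choice(AA) for _ in range(rng.randint(2, 5)))
            score, _ = local_align(a, b)
            assert score == pytest.approx(_enumerate_best(a, b))

    def test_score_symmetry(self):
        rng = random.Random(3)
        for _ in range(20):
            a = "".join(rng.choice(AA) for _ in range(rng.randint(3, 20)))
            b = "".join(rng.choice(AA) for _ in range(rng.randint(3, 20)))
            assert local_align(a, b)[0] == local_align(b, a)[0]

    def test_self_hit_dominance(self):
        rng = random.Random(11)
        a = "".join(rng.choice(AA) for _ in range(25))
        saa = local_align(a, a)[0]
        for _ in range(10):
            b = "".join(rng.choice(AA) for _ in range(25))
            assert saa >= local_align(a, b)[0]


class TestEvalue:
    def test_zero_score_gives_kmn(self):
        p = EvalueParams()
        assert evalue(0, 10, 20, p) == pytest.approx(p.K * 200)

    def test_linear_in_search_space(self):
        assert evalue(50, 100, 400) == pytest.approx(2 * evalue(50, 100, 200))

    def test_halving_per_ln2_over_lambda(self):
        p = EvalueParams()
        s = 30.0
        assert evalue(s + math.log(2) / p.lam, 50, 50, p) == \
            pytest.approx(evalue(s, 50, 50, p) / 2)

    def test_strictly_decreasing_in_score(self):
        es = [evalue(s, 100, 100) for s in range(0, 200, 10)]
        assert all(x > y for x, y in zip(es, es[1:]))


class TestSimilarityMatrix:
    def test_self_hit_is_row_minimum(self, family):
        doms = family.ptp_domains()[:8]
        sim = similarity_matrix(doms)
        for i in range(len(doms)):
            assert sim.evalues[i, i] == pytest.approx(sim.evalues[i].min())

    def test_threshold_marks_exactly_cells_below(self, family):
        sim = similarity_matrix(family.ptp_domains()[:8])
        thr = 1e-80
        mask = sim.classify(thr)
        assert (mask == (sim.evalues < thr)).all()

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValidationError):
            similarity_matrix([("a", "MKTW" * 10), ("a", "MKVW" * 10)])

    def test_within_cluster_beats_between_cluster(self, family):
        """Domains evolved inside one clade must look more alike than
        domains from the diverged clade, for nearly all pairs."""
        doms = dict(family.ptp_domains())
        groups = {g.name: sorted(g.members) for g in family.groups
                  if g.name in ("PTPRB", "PTPRQ")}
        labels = groups["PTPRB"] + groups["PTPRQ"]
        sim = similarity_matrix([(l, doms[l]) for l in labels])
        idx = {l: i for i, l in enumerate(labels)}
        within, between = [], []
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                e = sim.evalues[idx[a], idx[b]]
                same = (a in groups["PTPRB"]) == (b in groups["PTPRB"])
                (within if same else between).append(e)
        ok = sum(w < b for w in within for b in between)
        assert ok / (len(within) * len(between)) >= 0.95
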