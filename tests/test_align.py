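"""Aligner correctness vs Biopython's global aligner, plus invariants."""

import numpy as np
import pytest
from Bio import Align
from hypothesis import given, settings
from hypothesis import strategies as hst

from plastomics._util import decode, encode
from plastomics.align import GAP, align_pair, multiple_align, ungap


def bio_aligner():
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 1
    al.mismatch_score = -1
    al.open_gap_score = -5  # open (-4) plus first extension (-1)
    al.extend_gap_score = -1
    return al


class TestPairwise:
    def test_identical_sequences(self):
        a, b, score = align_pair(encode("ACGTACGT"), encode("ACGTACGT"))
        assert score == 8 and not (a == GAP).any() and not (b == GAP).any()

    def test_single_deletion(self):
        a, b, score = align_pair(encode("ACGTACGT"), encode("ACGACGT"))
        assert (b == GAP).sum() == 1 and (a == GAP).sum() == 0
        matches = int(((a == b) & (a < 4)).sum())
        assert matches == 7 and score == 7 - 5

    def test_scores_match_biopython(self, rng):
        al = bio_aligner()
        for _ in range(100):
            n = int(rng.integers(4, 140))
            s1 = rng.integers(0, 4, n).astype(np.uint8)
            s2 = s1.copy()
            for _ in range(int(rng.integers(0, 6))):
                p = int(rng.integers(0, len(s2)))
                op = int(rng.integers(0, 3))
                if op == 0:
                    s2[p] = (s2[p] + rng.integers(1, 4)) % 4
                elif op == 1 and len(s2) > 4:
                    g = int(rng.integers(1, 4))
                    s2 = np.concatenate([s2[:p], s2[p + g :]])
                else:
                    ins = rng.integers(0, 4, int(rng.integers(1, 4))).astype(np.uint8)
                    s2 = np.concatenate([s2[:p], ins, s2[p:]])
            if len(s2) == 0:
                continue
            _, _, score = align_pair(s1, s2)
            assert score == pytest.approx(al.score(decode(s1), decode(s2)))

    @given(
        s1=hst.text(alphabet="ACGT", min_size=1, max_size=40),
        s2=hst.text(alphabet="ACGT", min_size=1, max_size=40),
    )
    @settings(max_examples=60, deadline=None)
    def test_score_equals_biopython_on_arbitrary_pairs(self, s1, s2):
        _, _, score = align_pair(encode(s1), encode(s2))
        assert score == pytest.approx(bio_aligner().score(s1, s2))


class TestMultiple:
    def test_ungapping_recovers_inputs(self, rng):
        seqs = []
        base = rng.integers(0, 4, 400).astype(np.uint8)
        for _ in range(6):
            s = base.copy()
            for _ in range(int(rng.integers(0, 5))):
                p = int(rng.integers(0, len(s)))
                s[p] = (s[p] + 1) % 4
            if rng.random() < 0.5:
                p = int(rng.integers(10, len(s) - 10))
                s = np.concatenate([s[:p], s[p + 3 :]])
            seqs.append(s)
        rows = multiple_align(seqs)
        assert len({len(r) for r in rows}) == 1
        for s, r in zip(seqs, rows):
            assert np.array_equal(ungap(r), s)

    def test_column_bound(self, rng):
        base = rng.integers(0, 4, 1000).astype(np.uint8)
        seqs, n_ins = [], 0
        for _ in range(8):
            s = base.copy()
            if rng.random() < 0.6:
                p = int(rng.integers(10, 900))
                ins = rng.integers(0, 4, 4).astype(np.uint8)
                s = np.concatenate([s[:p], ins, s[p:]])
                n_ins += 1
            seqs.append(s)
        rows = multiple_align(seqs)
        assert len(rows[0]) <= max(len(s) for s in seqs) + 4 * n_ins

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            multiple_align([encode("ACGT"), encode("")])
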