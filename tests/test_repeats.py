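"""Repeat scanning: oracle equivalence, merging, classification rules."""

import numpy as np
import pytest

from plastomics import repeats as rp
from plastomics._util import revcomp
from plastomics.io import AnnotatedGenome, Feature
from tests.conftest import random_dna


def plant(seq_list, pos, motif):
    seq_list[pos : pos + len(motif)] = list(motif)


class TestScan:
    def test_no_repeats_in_random_sequence(self, rng):
        assert rp.find_repeat_pairs(random_dna(rng, 3000)) == []

    def test_periodic_sequence_yields_tandem_array_hits(self):
        hits = rp.find_repeat_pairs("ACGTACGTACGT" + "TTGCA" * 30)
        assert hits and all(h.orientation == "direct" for h in hits)

    def test_exact_duplication_found(self, rng):
        s = list(random_dna(rng, 8000))
        motif = random_dna(rng, 40)
        plant(s, 100, motif)
        plant(s, 5000, motif)
        hits = rp.find_repeat_pairs("".join(s))
        direct = [h for h in hits if h.orientation == "direct"]
        assert any(
            h.copy1[0] <= 100 and 140 <= h.copy1[1] and h.copy2[0] <= 5000
            for h in direct
        )
        assert all(h.identity >= 0.90 and h.length >= 30 for h in hits)

    def test_min_len_guard(self):
        with pytest.raises(ValueError):
            rp.find_repeat_pairs("ACGT" * 100, min_len=6)
        with pytest.raises(ValueError):
            rp.brute_force_repeats("ACGT" * 100, min_len=6)

    def test_oracle_refuses_long_input(self, rng):
        with pytest.raises(ValueError):
            rp.brute_force_repeats(random_dna(rng, 25_000))

    def test_oracle_equivalence_with_planted_repeats(self, rng):
        for trial in range(6):
            s = list(random_dna(rng, 10_000))
            for _ in range(4):
                L = int(rng.integers(30, 56))
                motif = random_dna(rng, L)
                m2 = list(motif)
                if rng.random() < 0.5:
                    p = int(rng.integers(0, L))
                    m2[p] = "ACGT"[("ACGT".index(m2[p]) + 1) % 4]
                m2 = "".join(m2)
                if rng.random() < 0.5:
                    m2 = revcomp(m2)
                plant(s, int(rng.integers(0, 4000)), motif)
                plant(s, int(rng.integers(5000, 9400)), m2)
            text = "".join(s)
            fast = {h.key() for h in rp.find_repeat_pairs(text)}
            oracle = {h.key() for h in rp.brute_force_repeats(text, max_len=120)}
            assert fast == oracle

    def test_reversal_symmetry(self, rng):
        s = list(random_dna(rng, 4000))
        motif = random_dna(rng, 35)
        plant(s, 200, motif)
        plant(s, 3000, motif)
        text = "".join(s)
        fwd = rp.brute_force_repeats(text)
        rev = rp.brute_force_repeats(text[::-1])
        n = len(text)
        mapped = {
            (tuple(sorted([(n - h.copy2[1], n - h.copy2[0]),
                           (n - h.copy1[1], n - h.copy1[0])]))) for h in rev
            if h.orientation == "direct"
        }
        orig = {(h.copy1, h.copy2) for h in fwd if h.orientation == "direct"}
        assert {tuple(x) for x in mapped} == orig

    def test_count_monotone_in_min_len(self, rng):
        s = list(random_dna(rng, 6000))
        for pos, L in ((100, 32), (800, 45), (2000, 30)):
            motif = random_dna(rng, L)
            plant(s, pos, motif)
            plant(s, pos + 2500, motif)
        text = "".join(s)
        n30 = len(rp.find_repeat_pairs(text, min_len=30))
        n26 = len(rp.find_repeat_pairs(text, min_len=26))
        assert n26 >= n30

    def test_exclusion_masks_hits(self, rng):
        s = list(random_dna(rng, 6000))
        motif = random_dna(rng, 40)
        plant(s, 100, motif)
        plant(s, 3000, motif)
        text = "".join(s)
        assert rp.find_repeat_pairs(text, exclude=[(0, 200)]) == []


class TestMerge:
    def test_disjoint_hits_unchanged(self):
        h1 = rp.RepeatHit((0, 40), (1000, 1040), "direct", 40, 1.0)
        h2 = rp.RepeatHit((200, 240), (3000, 3040), "direct", 40, 1.0)
        assert {h.key() for h in rp.merge_hits([h1, h2])} == {h1.key(), h2.key()}

    def test_offset_hits_merge_and_identity_recomputed(self, rng):
        s = list(random_dna(rng, 3000))
        motif = random_dna(rng, 50)
        plant(s, 100, motif)
        plant(s, 2000, motif)
        text = "".join(s)
        h1 = rp.RepeatHit((100, 140), (2000, 2040), "direct", 40, 1.0)
        h2 = rp.RepeatHit((105, 150), (2005, 2050), "direct", 45, 1.0)
        merged = rp.merge_hits([h1, h2], text)
        assert len(merged) == 1
        assert merged[0].copy1 == (100, 150) and merged[0].copy2 == (2000, 2050)
        assert merged[0].identity == 1.0

    def test_idempotence(self, rng):
        s = "".join(random_dna(rng, 2000))
        hits = [
            rp.RepeatHit((10, 50), (500, 540), "direct", 40, 1.0),
            rp.RepeatHit((30, 75), (520, 565), "direct", 45, 1.0),
            rp.RepeatHit((900, 940), (1500, 1540), "inverted", 40, 1.0),
        ]
        once = rp.merge_hits(hits, s)
        twice = rp.merge_hits(once, s)
        assert {h.key() for h in once} == {h.key() for h in twice}


class TestClassification:
    def genome(self, n=30000):
        rng = np.random.default_rng(0)
        feats = [
            Feature("trnX", "tRNA", "+", [(5000, 5070)]),
            Feature("trnY", "tRNA", "+", [(25000, 25070)]),
        ]
        return AnnotatedGenome(id="g", sequence=random_dna(rng, n), features=feats)

    def classify(self, hit, **kw):
        return rp.classify_hits([hit], self.genome(), **kw)[0].category

    def test_adjacent_direct_pair_is_tandem(self):
        h = rp.RepeatHit((100, 140), (140, 180), "direct", 40, 1.0)
        assert self.classify(h) == "tandem"

    def test_palindromic_gap_boundary(self):
        near = rp.RepeatHit((100, 140), (3139, 3179), "inverted", 40, 1.0)  # gap 2999
        far = rp.RepeatHit((100, 140), (3141, 3181), "inverted", 40, 1.0)  # gap 3001
        assert self.classify(near) == "palindromic"
        assert self.classify(far) == "dispersed"

    def test_tandem_gap_boundary(self):
        ten = rp.RepeatHit((100, 140), (150, 190), "direct", 40, 1.0)  # gap 10
        eleven = rp.RepeatHit((100, 140), (151, 191), "direct", 40, 1.0)  # gap 11
        assert self.classify(ten) == "tandem"
        assert self.classify(eleven) == "dispersed"

    def test_copies_in_two_trnas_is_gene_similarity(self):
        h = rp.RepeatHit((5010, 5045), (25010, 25045), "direct", 35, 1.0)
        out = rp.classify_hits([h], self.genome())[0]
        assert out.category == "gene_similarity"
        assert out.context == "coding"
        assert out.gene_hits == ["trnX", "trnY"]

    def test_summary_single_tandem(self):
        h = rp.RepeatHit((100, 140), (140, 180), "direct", 40, 1.0, "tandem", "intergenic")
        df = rp.summarize_repeats([h])
        pooled = df[df.genome == "pooled"].iloc[0]
        assert pooled.pct_tandem == 100.0 and pooled.longest == 40


class TestPlantedRecovery:
    def test_planted_mix_recovered_exactly(self, full_sim):
        """All 45 planted repeats are found (containment match) and the
        category mix (42% tandem, 4% gene similarity) is reproduced."""
        _, _, truth = full_sim
        anc, s0 = truth.ancestor, truth.structure
        hits = rp.find_repeat_pairs(anc.sequence, exclude=[s0.irb])
        merged = rp.merge_hits(hits, anc.sequence)
        classified = rp.classify_hits(merged, anc, s0)

        def contains(h, p):
            return (
                h.copy1[0] <= p.copy1[0] and p.copy1[1] <= h.copy1[1]
                and h.copy2[0] <= p.copy2[0] and p.copy2[1] <= h.copy2[1]
                and h.orientation == p.orientation
            )

        assert len(classified) == len(truth.planted_repeats) == 45
        for p in truth.planted_repeats:
            assert any(contains(h, p) for h in merged)
        from collections import Counter

        got = Counter(h.category for h in classified)
        want = Counter(cat for cat, _, _ in truth.config.repeat_spec)
        assert got == want
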