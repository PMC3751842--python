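"""Quadripartite detection, junction genes, composition, inventory."""

import numpy as np
import pytest

from plastomics import simulate as sim
from plastomics._util import revcomp
from plastomics.io import AnnotatedGenome, Feature
from plastomics.structure import (
    NoIRFound,
    QuadripartiteStructure,
    brute_force_inverted_repeat,
    composition_stats,
    detect_quadripartite,
    gene_inventory,
    junction_genes,
    rotate_genome,
)
from tests.conftest import random_dna


def mini_plastome(rng, lsc=8000, ir=3000, ssc=2000):
    """Small LSC|IRb|SSC|IRa genome with guaranteed junction mismatches."""
    while True:
        l = random_dna(rng, lsc)
        b = random_dna(rng, ir)
        s = random_dna(rng, ssc)
        seq = l + b + s + revcomp(b)
        comp = dict(zip("ACGT", "TGCA"))
        if seq[lsc - 1] != comp[seq[0]] and seq[lsc + ir] != comp[seq[lsc + ir + ssc - 1]]:
            return AnnotatedGenome(id="mini", sequence=seq)


class TestDetection:
    def test_no_ir_in_random_sequence(self, rng):
        g = AnnotatedGenome(id="r", sequence=random_dna(rng, 150_000))
        with pytest.raises(NoIRFound):
            detect_quadripartite(g)

    def test_exact_recovery_on_simulated_leaves(self, full_sim):
        _, genomes, truth = full_sim
        for taxon, g in genomes.items():
            det = detect_quadripartite(g)
            tru = truth.structures[taxon]
            assert (det.lsc, det.irb, det.ssc, det.ira) == (
                tru.lsc, tru.irb, tru.ssc, tru.ira
            )
            assert det.mismatches_between_ir_copies == 0

    def test_rotation_invariance(self, rng):
        g = mini_plastome(rng)
        base = detect_quadripartite(g, min_ir_len=1000)
        for offset in (1234, 9100, 12999):
            det = detect_quadripartite(rotate_genome(g, offset), min_ir_len=1000)
            assert (det.lsc_len, det.ir_len, det.ssc_len) == (
                base.lsc_len, base.ir_len, base.ssc_len
            )

    def test_matches_exhaustive_oracle_on_small_genomes(self, rng):
        for _ in range(3):
            g = mini_plastome(rng, lsc=6000, ir=1500, ssc=1200)
            det = detect_quadripartite(g, min_ir_len=1000)
            oracle = brute_force_inverted_repeat(g.sequence, min_ir_len=1000)
            assert oracle is not None
            copies = {det.irb, det.ira}
            assert set(oracle) == copies

    def test_partition_property(self, rng):
        g = mini_plastome(rng)
        det = detect_quadripartite(g)
        assert det.lsc_len + det.ssc_len + 2 * det.ir_len == len(g)


class TestJunctionGenes:
    def make(self):
        rng = np.random.default_rng(5)
        g = mini_plastome(rng)
        det = detect_quadripartite(g)
        feats = [
            # fully inside LSC: must not be reported
            Feature("psbA", "CDS", "+", [(100, 700)]),
            # straddles the LSC/IRb junction with 70 bp inside the IR
            Feature("rps19", "CDS", "-", [(det.irb[0] - 200, det.irb[0] + 70)]),
            # straddles SSC/IRa with 70 bp inside the IR
            Feature("ycf1", "CDS", "-", [(det.ira[0] - 900, det.ira[0] + 70)]),
            # truncated duplicate near IRb/SSC
            Feature("ycf1", "pseudogene", "+", [(det.ssc[0] - 70, det.ssc[0] + 200)]),
        ]
        g2 = AnnotatedGenome(id=g.id, sequence=g.sequence, features=feats)
        return g2, det

    def test_interior_gene_not_reported(self):
        g, det = self.make()
        recs = junction_genes(g, det)
        assert all(r["gene_name"] != "psbA" for r in recs)

    def test_straddling_gene_base_counts(self):
        g, det = self.make()
        recs = [r for r in recs_by(g, det) if r["gene_name"] == "ycf1"
                and r["junction"] == "SSC/IRa"]
        assert recs and recs[0]["bp_inside_ir"] == 70
        assert recs[0]["bp_inside_sc"] == 900
        lsc_irb = [r for r in recs_by(g, det) if r["gene_name"] == "rps19"]
        assert lsc_irb and lsc_irb[0]["bp_inside_ir"] == 70

    def test_truncated_copy_flagged_pseudogene_like(self):
        g, det = self.make()
        flagged = [r for r in recs_by(g, det) if r["pseudogene_like"]]
        assert any(r["gene_name"] == "ycf1" for r in flagged)


def recs_by(g, det):
    return junction_genes(g, det)


class TestComposition:
    def test_all_g_sequence(self):
        g = AnnotatedGenome(id="g", sequence="G" * 500)
        c = composition_stats(g)
        assert c.gc_pct == 100.0 and c.at_pct == 0.0

    def test_single_cds_fraction(self):
        g = AnnotatedGenome(
            id="g", sequence="ACGT" * 150,
            features=[Feature("x", "CDS", "+", [(0, 60)])],
        )
        c = composition_stats(g)
        assert c.protein_pct == pytest.approx(10.0)
        assert c.coding_pct == pytest.approx(10.0)
        assert c.noncoding_pct == pytest.approx(90.0)

    def test_identities(self, full_sim):
        _, _, truth = full_sim
        c = composition_stats(truth.ancestor)
        assert c.gc_pct + c.at_pct == pytest.approx(100.0, abs=1e-9)
        assert c.protein_pct + c.trna_pct + c.rrna_pct == pytest.approx(c.coding_pct)
        assert c.coding_pct + c.noncoding_pct == pytest.approx(100.0)


class TestInventory:
    def test_three_interval_gene_has_two_introns(self):
        g = AnnotatedGenome(
            id="g", sequence="ACGT" * 300,
            features=[Feature("clpP", "CDS", "+", [(0, 60), (100, 160), (200, 290)])],
        )
        inv = gene_inventory(g)
        assert inv.intron_counts == {"clpP": 2}

    def test_no_ir_genes(self):
        g = AnnotatedGenome(
            id="g", sequence="ACGT" * 300,
            features=[Feature("a", "CDS", "+", [(0, 60)]),
                      Feature("b", "tRNA", "+", [(100, 160)])],
        )
        inv = gene_inventory(g)
        assert inv.ir_duplicated == 0
        assert inv.total_functional == inv.unique_genes == 2

    def test_unknown_kind_counted_as_other_with_warning(self):
        g = AnnotatedGenome(
            id="g", sequence="ACGT" * 300,
            features=[Feature("odd", "other", "+", [(0, 50)])],
        )
        with pytest.warns(UserWarning):
            inv = gene_inventory(g)
        assert inv.other == ["odd"]
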