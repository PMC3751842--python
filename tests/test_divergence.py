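"""Region extraction, variability statistics, hotspots, p-distances, tallies."""

import numpy as np
import pytest

from plastomics import divergence as dv
from plastomics import simulate as sim
from plastomics._util import encode
from plastomics.align import GAP
from plastomics.io import AnnotatedGenome, Feature
from plastomics.structure import QuadripartiteStructure


def toy_alignment(rows_text):
    enc = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4, "-": GAP}
    rows = np.array([[enc[c] for c in r] for r in rows_text], dtype=np.uint8)
    return dv.RegionAlignment(
        region=dv.Region("toy", "spacer", "LSC"),
        taxa=[f"t{i}" for i in range(len(rows_text))],
        rows=rows,
    )


class TestRegionExtraction:
    def test_matches_simulator_layout_exactly(self, full_sim):
        _, genomes, truth = full_sim
        regions = dv.extract_regions(
            {"anc": truth.ancestor}, {"anc": truth.structure}
        )
        got = {(r.name, r.klass, r.region, *r.locations["anc"][:2]) for r in regions}
        want = {(r.name, r.klass, r.region, r.start, r.end) for r in truth.region_table}
        assert got == want

    def test_intron_gene_splits_into_exons_and_introns(self):
        seq = "ACGT" * 500
        feats = [Feature("ycf3", "CDS", "+", [(100, 200), (300, 400), (500, 650)])]
        g = AnnotatedGenome(id="g", sequence=seq, features=feats)
        st = QuadripartiteStructure(
            lsc=(0, 1000), irb=(1000, 1400), ssc=(1400, 1600), ira=(1600, 2000),
            genome_length=2000,
        )
        rows = dv._genome_region_rows(g, st)
        names = [n for n, k, *_ in rows if k != "spacer"]
        assert names == ["ycf3_exon1", "ycf3_intron1", "ycf3_exon2",
                         "ycf3_intron2", "ycf3_exon3"]

    def test_duplicate_gene_outside_ir_rejected(self):
        seq = "ACGT" * 500
        feats = [Feature("x", "CDS", "+", [(10, 70)]),
                 Feature("x", "CDS", "+", [(200, 260)])]
        g = AnnotatedGenome(id="g", sequence=seq, features=feats)
        st = QuadripartiteStructure(
            lsc=(0, 1000), irb=(1000, 1400), ssc=(1400, 1600), ira=(1600, 2000),
            genome_length=2000,
        )
        with pytest.raises(dv.RegionExtractionError):
            dv._genome_region_rows(g, st)


class TestVariableStats:
    def test_identical_rows(self):
        aln = toy_alignment(["ACGTACGTAA"] * 3)
        rec = dv.variable_stats(aln)
        assert rec.variable_pct == 0.0 and rec.indel_columns == 0

    def test_two_substitution_columns(self):
        base = "A" * 100
        row2 = "T" + "A" * 98 + "G"
        rec = dv.variable_stats(toy_alignment([base, row2, base]))
        assert rec.variable_columns == 2 and rec.variable_pct == pytest.approx(2.0)

    def test_gap_only_variation_is_indel_not_variable(self):
        rec = dv.variable_stats(toy_alignment(["ACGTA", "AC-TA", "ACGTA"]))
        assert rec.variable_columns == 0 and rec.indel_columns == 1


class TestPDistance:
    def make_wga(self, rows_text, taxa=None):
        enc = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4, "-": GAP}
        rows = np.array([[enc[c] for c in r] for r in rows_text], dtype=np.uint8)
        taxa = taxa or [f"t{i}" for i in range(len(rows_text))]
        reg = dv.Region("all", "spacer", "LSC")
        return dv.WholeGenomeAlignment(
            taxa=taxa, rows=rows, regions=[reg],
            col_region=np.zeros(rows.shape[1], dtype=np.int32),
        )

    def test_quarter_distance(self):
        wga = self.make_wga(["AAAA", "AAAT"])
        d = dv.p_distance_summary(wga, {"t0": "a", "t1": "b"})
        assert d.matrix[0, 1] == pytest.approx(0.25)
        assert d.pair_site_differences[("t0", "t1")] == 1

    def test_indel_sites_excluded(self):
        wga = self.make_wga(["AA-A", "AAAA"])
        d = dv.p_distance_summary(wga, {"t0": "a", "t1": "b"})
        assert d.matrix[0, 1] == 0.0

    def test_within_less_than_between_on_simulation(self, full_sim, full_wga):
        cfg, genomes, truth = full_sim
        d = dv.p_distance_summary(full_wga, cfg.species_labels, cfg.outgroups)
        assert np.allclose(d.matrix, d.matrix.T)
        assert np.all(np.diag(d.matrix) == 0)
        assert d.mean_within_species < d.mean_between_species


class TestVariantTally:
    def test_transition_and_transversion_columns(self):
        t = TestPDistance()
        wga = t.make_wga(["AG", "GT"])
        tal = dv.tally_variants(wga)
        assert tal["LSC"]["transition"] == 1  # column {A,G}
        assert tal["LSC"]["transversion"] == 1  # column {G,T}

    def test_conservation_against_simulator(self, full_sim, full_wga):
        """Alignment-column tallies equal the simulator's realized event
        counts exactly, per partition and per mutation type."""
        cfg, genomes, truth = full_sim
        assert dv.tally_variants(full_wga) == truth.realized_variant_counts


class TestHotspots:
    def test_identical_genomes_have_no_hotspots(self):
        cfg = sim.demo_config(0.2)
        cfg.tree = "((a:0,b:0):0,c:0);"
        cfg.species_labels = {t: t for t in "abc"}
        cfg.outgroups = []
        cfg.conspecific_pair = None
        genomes, truth = sim.simulate(cfg, seed=0)
        recs = dv.scan_hotspots(genomes, truth.structures)
        assert all(not r.is_hotspot for r in recs)

    def test_planted_hotspots_recovered_exactly(self):
        genomes, truth, names = sim.simulate_hotspot_fixture(seed=5)
        recs = dv.scan_hotspots(
            genomes, truth.structures, outgroups=truth.config.outgroups
        )
        flagged = sorted(r.name for r in recs if r.is_hotspot)
        assert flagged == sorted(names)
        assert recs[0].is_hotspot  # ranking puts hotspots first
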