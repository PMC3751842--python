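"""Simulator correctness: layout, composition, determinism, mutation model."""

import math

import numpy as np
import pytest

from plastomics import simulate as sim
from plastomics._util import encode, revcomp
from plastomics.structure import composition_stats, gene_inventory


class TestAncestor:
    def test_region_additivity(self, full_sim):
        cfg, _, truth = full_sim
        assert len(truth.ancestor) == 86_204 + 18_318 + 2 * 26_025 == 156_572
        s = truth.structure
        assert s.lsc_len + s.ssc_len + 2 * s.ir_len == len(truth.ancestor)

    def test_ira_is_revcomp_of_irb(self, full_sim):
        _, _, truth = full_sim
        seq = truth.ancestor.sequence
        b0, b1 = truth.structure.irb
        a0, a1 = truth.structure.ira
        assert seq[a0:a1] == revcomp(seq[b0:b1])

    def test_at_composition_near_target(self, full_sim):
        _, _, truth = full_sim
        c = composition_stats(truth.ancestor)
        assert abs(c.at_pct - 62.7) < 0.5

    def test_gene_inventory_matches_design(self, full_sim):
        _, _, truth = full_sim
        inv = gene_inventory(truth.ancestor, truth.structure)
        assert inv.total_functional == 146
        assert inv.unique_genes == 123
        assert inv.ir_duplicated == 23
        assert inv.unique_by_class == {"protein": 81, "tRNA": 38, "rRNA": 4}
        # 16 one-intron genes + clpP and ycf3 with two introns
        assert len(inv.intron_counts) == 18
        assert sum(inv.intron_counts.values()) == 20
        assert inv.intron_counts["clpP"] == 2 and inv.intron_counts["ycf3"] == 2

    def test_layout_error_when_inventory_does_not_fit(self):
        cfg = sim.default_config()
        cfg.lsc_len = 30_000  # far too small for the LSC gene set
        cfg.ir_len = (156_572 - 30_000 - cfg.ssc_len) // 2
        with pytest.raises(sim.LayoutError):
            sim.build_ancestor(cfg, seed=0)

    def test_determinism(self):
        cfg = sim.demo_config(0.2)
        g1, t1 = sim.simulate(cfg, seed=42)
        g2, t2 = sim.simulate(sim.demo_config(0.2), seed=42)
        assert all(g1[t].sequence == g2[t].sequence for t in g1)
        assert t1.realized_variant_counts == t2.realized_variant_counts

    def test_planted_repeat_copies_match(self, full_sim):
        _, _, truth = full_sim
        seq = truth.ancestor.sequence
        for hit in truth.planted_repeats:
            c1 = seq[hit.copy1[0] : hit.copy1[1]]
            c2 = seq[hit.copy2[0] : hit.copy2[1]]
            if hit.orientation == "inverted":
                c2 = revcomp(c2)
            mism = sum(a != b for a, b in zip(c1, c2))
            assert mism == round((1 - hit.identity) * hit.length)


class TestEvolution:
    def test_zero_length_branches_give_identical_leaves(self):
        cfg = sim.demo_config(0.2)
        cfg.tree = "((a:0,b:0):0,(c:0,d:0):0);"
        cfg.species_labels = {t: t for t in "abcd"}
        cfg.outgroups = []
        cfg.conspecific_pair = None
        genomes, truth = sim.simulate(cfg, seed=1)
        seqs = {g.sequence for g in genomes.values()}
        assert len(seqs) == 1 and seqs.pop() == truth.ancestor.sequence

    def test_infinite_kappa_gives_only_transitions(self):
        cfg = sim.demo_config(0.2)
        cfg.ts_tv_ratio = math.inf
        cfg.indel_rate = 0.0
        genomes, truth = sim.simulate(cfg, seed=2)
        counts = truth.realized_variant_counts
        assert sum(c["transversion"] for c in counts.values()) == 0
        assert sum(c["transition"] for c in counts.values()) > 0

    def test_conspecific_pair_differs_at_exact_site_count(self, full_sim):
        cfg, genomes, truth = full_sim
        t1, t2, k = cfg.conspecific_pair
        s1 = encode(genomes[t1].sequence)
        s2 = encode(genomes[t2].sequence)
        # no indels are placed on the pair's terminal branches (and shared
        # indels shift both genomes identically), so the raw genomes align
        # position-for-position and differ at exactly the planted sites
        assert len(s1) == len(s2)
        assert int((s1 != s2).sum()) == k

    def test_event_conservation(self, full_sim):
        _, _, truth = full_sim
        counts = truth.realized_variant_counts
        func = sum(
            counts[k][t] for k in ("coding", "intron_spacer")
            for t in ("transition", "transversion", "indel")
        )
        struct = sum(
            counts[k][t] for k in ("LSC", "SSC", "IR")
            for t in ("transition", "transversion", "indel")
        )
        assert func == struct == truth.n_events

    def test_ir_mirroring_preserved_in_leaves(self, full_sim):
        _, genomes, truth = full_sim
        for taxon, g in genomes.items():
            s = truth.structures[taxon]
            seq = g.sequence
            assert seq[s.ira[0] : s.ira[1]] == revcomp(seq[s.irb[0] : s.irb[1]])

    def test_annotations_lift_through_indels(self, full_sim):
        _, genomes, truth = full_sim
        # exon sequence of a gene without events must be unchanged vs ancestor
        anc = truth.ancestor
        for taxon, g in genomes.items():
            mutated_rows = {
                truth.region_table[e.row_index].name
                for e in truth.events_by_leaf[taxon]
            }
            for f in g.features:
                if f.gene_name in ("psbA", "rbcL") and f.gene_name not in mutated_rows:
                    fa = [x for x in anc.features if x.gene_name == f.gene_name][0]
                    got = "".join(g.sequence[s:e] for s, e in f.intervals)
                    exp = "".join(anc.sequence[s:e] for s, e in fa.intervals)
                    assert got == exp
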