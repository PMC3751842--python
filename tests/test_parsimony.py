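"""Maximum parsimony: Fitch counting vs enumeration oracles, search
completeness, bootstrap behaviour, homoplasy indices."""

import itertools

import numpy as np
import pytest

from plastomics import parsimony as mp


def matrix(rows, taxa=None):
    rows = np.asarray(rows, dtype=np.uint8)
    taxa = taxa or [f"t{i}" for i in range(rows.shape[0])]
    return mp.CharacterMatrix(taxa, rows)


def enumeration_min_steps(tree, rows):
    """Independent oracle: minimum mutation count by exhaustive labeling of
    internal nodes (the tree is a pair rooted on an edge)."""
    total = 0
    for c in range(rows.shape[1]):
        col = rows[:, c]
        nodes = []

        def rec(t):
            if isinstance(t, int):
                return ("leaf", t)
            a, b = rec(t[0]), rec(t[1])
            nodes.append((a, b))
            return ("node", len(nodes) - 1)

        left = rec(tree[0])
        right = rec(tree[1])
        best = 10**9
        for assign in itertools.product(range(4), repeat=len(nodes)):
            def val(x):
                if x[0] == "leaf":
                    v = col[x[1]]
                    return None if v >= 4 else int(v)
                return assign[x[1]]

            cost = 0
            for i, (a, b) in enumerate(nodes):
                for child in (a, b):
                    v = val(child)
                    if v is not None and v != assign[i]:
                        cost += 1
            lv, rv = val(left), val(right)
            if lv is not None and rv is not None and lv != rv:
                cost += 1
            best = min(best, cost)
        total += best
    return total


class TestFitch:
    def test_identical_rows_zero_steps(self):
        m = matrix([[0, 1, 2]] * 4)
        assert mp.fitch_length((0, (1, (2, 3))), m) == 0

    def test_textbook_four_taxon_column(self):
        m = matrix([[0], [0], [3], [3]])
        assert mp.fitch_length((0, (1, (2, 3))), m) == 1  # ((1,2),(3,4))
        assert mp.fitch_length((0, (2, (1, 3))), m) == 2  # ((1,3),(2,4))

    def test_matches_enumeration_oracle(self, rng):
        tops = list(mp.enumerate_topologies(6))
        for _ in range(20):
            rows = rng.integers(0, 5, (6, 10)).astype(np.uint8)  # includes N
            m = matrix(rows)
            t = tops[int(rng.integers(0, len(tops)))]
            assert mp.fitch_length(t, m) == enumeration_min_steps(t, rows)

    def test_matches_dendropy_fitch(self, rng):
        import dendropy
        from dendropy.model.parsimony import fitch_down_pass

        rows = rng.integers(0, 4, (6, 40)).astype(np.uint8)
        m = matrix(rows)
        tree_t = (0, ((1, 2), ((3, 4), 5)))
        dt = mp.to_dendropy(tree_t, m.taxa)
        chars = dendropy.DnaCharacterMatrix.get(
            data="\n".join(f">{t}\n{''.join('ACGT'[b] for b in rows[i])}"
                           for i, t in enumerate(m.taxa)),
            schema="fasta", taxon_namespace=dt.taxon_namespace,
        )
        taxon_state_sets_map = chars.taxon_state_sets_map(gaps_as_missing=True)
        score = fitch_down_pass(
            dt.postorder_node_iter(), taxon_state_sets_map=taxon_state_sets_map
        )
        assert mp.fitch_length(tree_t, m) == score

    def test_invariant_under_taxon_permutation_relabeling(self, rng):
        rows = rng.integers(0, 4, (6, 25)).astype(np.uint8)
        m = matrix(rows)
        t = (0, ((1, 2), ((3, 4), 5)))
        base = mp.fitch_length(t, m)
        # re-rooting the same unrooted topology must not change the length
        t2 = (1, (2, (0, ((3, 4), 5))))
        assert mp.topology_key(t2, 6) == mp.topology_key(t, 6)
        assert mp.fitch_length(t2, m) == base


class TestSearch:
    def test_four_taxa_exhaustive_ranks_by_fitch(self):
        m = matrix([[0, 0], [0, 0], [3, 3], [3, 3]])
        res = mp.search_best_trees(m, "exhaustive")
        assert res.length == 2
        assert mp.topology_key(res.best_trees[0], 4) == \
            mp.topology_key((0, (1, (2, 3))), 4)

    def test_branch_and_bound_equals_exhaustive(self, rng):
        for _ in range(8):
            rows = rng.integers(0, 4, (8, 20)).astype(np.uint8)
            m = matrix(rows)
            ex = mp.search_best_trees(m, "exhaustive")
            bb = mp.search_best_trees(m, "branch_and_bound")
            assert ex.length == bb.length
            assert {mp.topology_key(t, 8) for t in ex.best_trees} == \
                {mp.topology_key(t, 8) for t in bb.best_trees}

    def test_heuristic_finds_optimum_on_clean_signal(self):
        # 8 taxa, perfect synapomorphies for nested clades
        cols = []
        for clade in [(0, 1), (2, 3), (4, 5), (6, 7), (0, 1, 2, 3)]:
            col = np.zeros(8, dtype=np.uint8)
            col[list(clade)] = 3
            cols += [col] * 10
        m = matrix(np.array(cols).T)
        ex = mp.search_best_trees(m, "branch_and_bound")
        h = mp.search_best_trees(m, "tbr_heuristic", seed=9)
        assert h.length == ex.length
        assert {mp.topology_key(t, 8) for t in h.best_trees} == \
            {mp.topology_key(t, 8) for t in ex.best_trees}

    def test_exhaustive_taxon_limit(self, rng):
        rows = rng.integers(0, 4, (10, 5)).astype(np.uint8)
        with pytest.raises(mp.SearchError):
            mp.search_best_trees(matrix(rows), "exhaustive")


class TestBootstrap:
    def test_no_variation_gives_undefined_supports(self):
        m = matrix(np.zeros((5, 30), dtype=np.uint8))
        res = mp.bootstrap_support(m, n_replicates=10, seed=0)
        assert all(np.isnan(v) for v in res.supports.values())

    def test_clean_signal_saturates_support(self):
        cols = []
        for clade in [(0, 1), (2, 3), (4, 5), (0, 1, 2, 3)]:
            col = np.zeros(6, dtype=np.uint8)
            col[list(clade)] = 3
            cols += [col] * 100
        m = matrix(np.array(cols).T)
        res = mp.bootstrap_support(m, n_replicates=50, seed=0)
        assert res.supports and all(v == 100.0 for v in res.supports.values())

    def test_reproducible_for_fixed_seed(self, rng):
        rows = rng.integers(0, 4, (6, 60)).astype(np.uint8)
        m = matrix(rows)
        a = mp.bootstrap_support(m, n_replicates=30, seed=5)
        b = mp.bootstrap_support(m, n_replicates=30, seed=5)
        assert a.supports == b.supports


class TestIndices:
    def test_homoplasy_free_data(self):
        cols = []
        for clade in [(0, 1), (2, 3), (4, 5)]:
            col = np.zeros(6, dtype=np.uint8)
            col[list(clade)] = 3
            cols.append(col)
        m = matrix(np.array(cols).T)
        res = mp.search_best_trees(m, "branch_and_bound")
        ci, ri, rc = mp.tree_indices(res, m)
        assert ci == 1.0 and ri == 1.0 and rc == 1.0

    def test_worst_tree_column(self):
        # column A,A,T,T scored on the tree grouping (1,3): m=1, s=2, g=2
        m = matrix([[0], [0], [3], [3]])
        res = mp.ParsimonyResult(
            best_trees=[(0, (2, (1, 3)))], length=2, taxa=m.taxa, method="fixed"
        )
        ci, ri, rc = mp.tree_indices(res, m)
        assert ci == pytest.approx(0.5)
        assert ri == pytest.approx(0.0)
        assert rc == pytest.approx(0.0)

    def test_rc_identity(self, rng):
        for _ in range(10):
            rows = rng.integers(0, 4, (6, 30)).astype(np.uint8)
            m = matrix(rows)
            res = mp.search_best_trees(m, "branch_and_bound")
            ci, ri, rc = mp.tree_indices(res, m)
            if ri is not None:
                assert rc == pytest.approx(ci * ri, abs=1e-12)

    def test_indel_columns_excluded(self):
        rows = np.array([[0, 5], [0, 5], [3, 0], [3, 0]], dtype=np.uint8)
        m = matrix(rows)
        res = mp.search_best_trees(m, "exhaustive")
        ci, _, _ = mp.tree_indices(res, m)
        assert ci == 1.0  # only the gap-free column counts


class TestPartitions:
    def test_simulator_column_labels_match_truth(self, full_sim, full_wga):
        cfg, genomes, truth = full_sim
        wga = full_wga
        parts = mp.build_partitions(wga, outgroups=cfg.outgroups)
        assert set(parts) == set(mp.PARTITION_NAMES)
        total = parts["complete"].length
        assert parts["LSC"].length + parts["SSC"].length + parts["IR"].length == total
        assert parts["coding_exons"].length + parts["introns_spacers"].length == total
        # column labels come straight from the simulator's region table
        func, struct = wga.col_classes()
        k = truth.region_table
        assert {r.region for r in k} == set(np.unique(struct))
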