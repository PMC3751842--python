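"""Reproducible validation experiments over the whole pipeline.

Each function sets up a simulation (or random fixture), runs the relevant
pipeline stage from scratch, and measures how well the planted truth is
recovered.  The functions are shared by the test suite and by
``scripts/acceptance.py``; every one is deterministic given its seed.
"""

from __future__ import annotations

import time
import numpy as np

from . import divergence as dv
from . import parsimony as mp
from . import repeats as rp
from . import simulate as sim
from . import structure as st
from ._util import revcomp, rng_from


# ---------------------------------------------------------------------------
# Structure


def structure_recovery(n_genomes: int = 100, seed: int = 0) -> dict:
    """Detect quadripartite boundaries on freshly built synthetic genomes and
    compare them with the planted truth (exact, to the base pair)."""
    cfg = sim.default_config()
    exact = 0
    sums_ok = 0
    t_detect = 0.0
    for i in range(n_genomes):
        _, truth = sim.build_ancestor(cfg, seed=(seed * 100_003 + i) % 2**31)
        t0 = time.perf_counter()
        det = st.detect_quadripartite(truth.ancestor)
        t_detect += time.perf_counter() - t0
        tru = truth.structure
        exact += (det.lsc, det.irb, det.ssc, det.ira) == (
            tru.lsc, tru.irb, tru.ssc, tru.ira
        )
        sums_ok += det.lsc_len + det.ssc_len + 2 * det.ir_len == det.genome_length
    return {
        "n": n_genomes,
        "exact": exact,
        "partition_sum_ok": sums_ok,
        "mean_detect_seconds": t_detect / n_genomes,
    }


# ---------------------------------------------------------------------------
# Repeats


def _random_fixture(rng: np.random.Generator, n: int = 10_000) -> str:
    s = list("ACGT"[i] for i in rng.integers(0, 4, n))
    for _ in range(4):
        L = int(rng.integers(30, 56))
        motif = "".join("ACGT"[i] for i in rng.integers(0, 4, L))
        m2 = list(motif)
        if rng.random() < 0.5:
            p = int(rng.integers(0, L))
            m2[p] = "ACGT"[("ACGT".index(m2[p]) + 1) % 4]
        m2 = "".join(m2)
        if rng.random() < 0.5:
            m2 = revcomp(m2)
        x = int(rng.integers(0, 4000))
        y = int(rng.integers(5000, n - 500))
        s[x : x + L] = motif
        s[y : y + L] = m2
    return "".join(s)


def repeat_oracle_agreement(n_fixtures: int = 50, seed: int = 0) -> dict:
    """Seed-based scanner vs exhaustive brute force: exact hit-set equality
    on random 10 kb sequences with planted repeats."""
    agree = 0
    for i in range(n_fixtures):
        rng = rng_from(seed, 11, i)
        text = _random_fixture(rng)
        fast = {h.key() for h in rp.find_repeat_pairs(text)}
        oracle = {h.key() for h in rp.brute_force_repeats(text, max_len=120)}
        agree += fast == oracle
    return {"n": n_fixtures, "agree": agree}


def repeat_boundary_cases() -> dict:
    """Category-boundary checks: palindromic/dispersed at the 3 kb gap and
    tandem/dispersed at the 10 bp gap."""
    from .io import AnnotatedGenome

    rng = rng_from(1234, 1)
    g = AnnotatedGenome(
        id="g", sequence="".join("ACGT"[i] for i in rng.integers(0, 4, 30_000))
    )

    def cat(copy2_start, orientation, copy1=(100, 140)):
        h = rp.RepeatHit(copy1, (copy2_start, copy2_start + 40), orientation, 40, 1.0)
        return rp.classify_hits([h], g)[0].category

    checks = {
        "inverted_gap_2999_palindromic": cat(140 + 2999, "inverted") == "palindromic",
        "inverted_gap_3001_dispersed": cat(140 + 3001, "inverted") == "dispersed",
        "direct_gap_0_tandem": cat(140, "direct") == "tandem",
        "direct_gap_10_tandem": cat(150, "direct") == "tandem",
        "direct_gap_11_dispersed": cat(151, "direct") == "dispersed",
    }
    return {"n": len(checks), "passed": sum(checks.values()), "detail": checks}


def planted_repeat_recovery(seed: int = 0) -> dict:
    """Scan the ancestor carrying the default planted repeat mix and match
    every plant (by containment) and the category shares."""
    cfg = sim.default_config()
    _, truth = sim.build_ancestor(cfg, seed=seed)
    anc, s0 = truth.ancestor, truth.structure
    merged = rp.merge_hits(
        rp.find_repeat_pairs(anc.sequence, exclude=[s0.irb]), anc.sequence
    )
    classified = rp.classify_hits(merged, anc, s0)

    def contains(h, p):
        return (
            h.copy1[0] <= p.copy1[0] and p.copy1[1] <= h.copy1[1]
            and h.copy2[0] <= p.copy2[0] and p.copy2[1] <= h.copy2[1]
            and h.orientation == p.orientation
        )

    matched = sum(any(contains(h, p) for h in merged) for p in truth.planted_repeats)
    from collections import Counter

    cats = Counter(h.category for h in classified)
    n = len(classified)
    return {
        "n_planted": len(truth.planted_repeats),
        "matched": matched,
        "n_reported": n,
        "tandem_pct": 100.0 * cats["tandem"] / n,
        "gene_similarity_pct": 100.0 * cats["gene_similarity"] / n,
        "longest": max(h.length for h in classified),
    }


# ---------------------------------------------------------------------------
# Divergence calibration


def partition_variability(genomes, structures, ingroup) -> dict[str, float]:
    sel = {t: genomes[t] for t in ingroup}
    stx = {t: structures[t] for t in ingroup}
    wga, _ = dv.build_whole_genome_alignment(sel, stx, taxa=list(ingroup))
    parts = mp.build_partitions(wga)
    out = {}
    for name, m in parts.items():
        counts = np.stack([(m.rows == b).sum(axis=0) for b in range(4)])
        var = int((((counts > 0).sum(axis=0)) >= 2).sum())
        out[name] = 100.0 * var / m.length
    return out


def ordering_replicates(n_replicates: int = 100, seed: int = 0) -> dict:
    """How often the partition variability ordering SSC > introns/spacers >
    LSC > coding > IR holds across seeded full-scale simulations."""
    cfg = sim.default_config()
    ingroup = [t for t in cfg.species_labels if t not in cfg.outgroups]
    succ = 0
    sums = {k: 0.0 for k in mp.PARTITION_NAMES}
    for i in range(n_replicates):
        genomes, truth = sim.simulate(cfg, seed=(seed * 99_991 + i) % 2**31)
        pv = partition_variability(genomes, truth.structures, ingroup)
        for k in sums:
            sums[k] += pv[k]
        succ += (
            pv["SSC"] > pv["introns_spacers"] > pv["LSC"]
            > pv["coding_exons"] > pv["IR"]
        )
    return {
        "n": n_replicates,
        "ordering_holds": succ,
        "mean_pct": {k: sums[k] / n_replicates for k in sums},
    }


def divergence_summary(seed: int = 0) -> dict:
    """One full-scale simulation: conspecific site count, tally conservation,
    p-distance means, partition variability."""
    cfg = sim.default_config()
    genomes, truth = sim.simulate(cfg, seed=seed)
    taxa = sorted(genomes)
    wga, _ = dv.build_whole_genome_alignment(genomes, truth.structures, taxa=taxa)
    dist = dv.p_distance_summary(wga, cfg.species_labels, cfg.outgroups)
    tally = dv.tally_variants(wga)
    t1, t2, k = cfg.conspecific_pair
    pair = dist.pair_site_differences.get((t1, t2)) or dist.pair_site_differences.get(
        (t2, t1)
    )
    ingroup = [t for t in taxa if t not in cfg.outgroups]
    pv = partition_variability(genomes, truth.structures, ingroup)
    return {
        "conspecific_sites": pair,
        "conspecific_target": k,
        "tally_conserved": tally == truth.realized_variant_counts,
        "mean_all": dist.mean_all,
        "mean_between": dist.mean_between_species,
        "mean_within": dist.mean_within_species,
        "partition_pct": pv,
        "alignment_columns": wga.length,
    }


def hotspot_recovery(seed: int = 0) -> dict:
    """Eleven regions planted above the 1% threshold, all others below: the
    scan must flag exactly those eleven."""
    genomes, truth, names = sim.simulate_hotspot_fixture(seed=seed)
    recs = dv.scan_hotspots(
        genomes, truth.structures, outgroups=truth.config.outgroups
    )
    flagged = sorted(r.name for r in recs if r.is_hotspot)
    return {
        "n_planted": len(names),
        "n_flagged": len(flagged),
        "exact": flagged == sorted(names),
    }


# ---------------------------------------------------------------------------
# Parsimony


def _enumeration_min_steps(tree, rows) -> int:
    import itertools

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

        left, right = rec(tree[0]), rec(tree[1])
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


def fitch_vs_enumeration(n_matrices: int = 100, seed: int = 0) -> dict:
    rng = rng_from(seed, 31)
    tops = list(mp.enumerate_topologies(6))
    agree = 0
    for _ in range(n_matrices):
        rows = rng.integers(0, 4, (6, 8)).astype(np.uint8)
        m = mp.CharacterMatrix([f"t{i}" for i in range(6)], rows)
        t = tops[int(rng.integers(0, len(tops)))]
        agree += mp.fitch_length(t, m) == _enumeration_min_steps(t, rows)
    return {"n": n_matrices, "agree": agree}


def bnb_vs_exhaustive(n_matrices: int = 50, seed: int = 0) -> dict:
    """Branch-and-bound must return exactly the exhaustive-search tree set."""
    rng = rng_from(seed, 37)
    agree = 0
    for _ in range(n_matrices):
        rows = rng.integers(0, 4, (8, 20)).astype(np.uint8)
        m = mp.CharacterMatrix([f"t{i}" for i in range(8)], rows)
        ex = mp.search_best_trees(m, "exhaustive")
        bb = mp.search_best_trees(m, "branch_and_bound")
        agree += (
            ex.length == bb.length
            and {mp.topology_key(t, 8) for t in ex.best_trees}
            == {mp.topology_key(t, 8) for t in bb.best_trees}
        )
    return {"n": n_matrices, "agree": agree}


def index_identities(n_matrices: int = 20, seed: int = 0) -> dict:
    """RC = CI*RI on random matrices; CI = RI = 1 on homoplasy-free data."""
    rng = rng_from(seed, 41)
    max_err = 0.0
    for _ in range(n_matrices):
        rows = rng.integers(0, 4, (6, 30)).astype(np.uint8)
        m = mp.CharacterMatrix([f"t{i}" for i in range(6)], rows)
        res = mp.search_best_trees(m, "branch_and_bound")
        ci, ri, rc = mp.tree_indices(res, m)
        if ri is not None:
            max_err = max(max_err, abs(rc - ci * ri))
    cols = []
    for clade in [(0, 1), (2, 3), (4, 5)]:
        col = np.zeros(6, dtype=np.uint8)
        col[list(clade)] = 3
        cols.append(col)
    m = mp.CharacterMatrix([f"t{i}" for i in range(6)], np.array(cols).T)
    res = mp.search_best_trees(m, "branch_and_bound")
    ci, ri, rc = mp.tree_indices(res, m)
    return {
        "n": n_matrices,
        "rc_identity_max_error": max_err,
        "clean_ci": ci,
        "clean_ri": ri,
    }


def phylogeny_recovery(seed: int = 0, n_replicates: int = 1000) -> dict:
    """Search + bootstrap on the 11-taxon simulation: does MP recover the
    true ingroup topology, and how strong are the supports?"""
    import dendropy

    cfg = sim.default_config()
    genomes, truth = sim.simulate(cfg, seed=seed)
    taxa = sorted(genomes)
    wga, _ = dv.build_whole_genome_alignment(genomes, truth.structures, taxa=taxa)
    parts = mp.build_partitions(wga, outgroups=cfg.outgroups)
    m = parts["complete"]
    boot = mp.bootstrap_support(m, n_replicates=n_replicates, seed=seed)
    got = mp.bipartitions(boot.best_trees[0], len(taxa))

    true = dendropy.Tree.get(
        data=cfg.tree, schema="newick", preserve_underscores=True
    )
    idx = {t: i for i, t in enumerate(taxa)}
    ingroup = set(taxa) - set(cfg.outgroups)
    true_clades = []
    for node in true.preorder_node_iter():
        leaves = {lf.taxon.label for lf in node.leaf_iter()}
        if 1 < len(leaves) < len(ingroup) and leaves <= ingroup:
            true_clades.append(frozenset(idx[t] for t in leaves))
    recovered = sum(c in got for c in true_clades)
    sup = [boot.supports.get(c, 0.0) for c in true_clades if c in boot.supports]
    return {
        "n_true_clades": len(true_clades),
        "recovered": recovered,
        "min_support": min(sup) if sup else float("nan"),
        "n_replicates": n_replicates,
        "tree_length": boot.length,
        "parsimony_informative": boot.n_parsimony_informative,
    }


# ---------------------------------------------------------------------------
# Determinism


def pipeline_determinism(seed: int = 0, tmpdir: str = "scratch") -> dict:
    """Two pipeline runs with the same configuration and seed must produce
    byte-identical report bundles."""
    import json
    import shutil
    from pathlib import Path

    from .pipeline import PipelineConfig, run_pipeline

    base = Path(tmpdir)
    outs = [base / "det_a", base / "det_b"]
    manifests = []
    for out in outs:
        shutil.rmtree(out, ignore_errors=True)
        run_pipeline(
            PipelineConfig(
                seed=seed, outdir=str(out), sim_scale=0.2, bootstrap_replicates=10
            )
        )
        manifests.append(json.load(open(out / "manifest.json")))
        shutil.rmtree(out, ignore_errors=True)
    return {
        "identical": manifests[0]["files"] == manifests[1]["files"],
        "n_files": len(manifests[0]["files"]),
    }
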