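"""Synthetic plastome evolution with full ground truth.

The generator lays out a circular quadripartite genome (LSC | IRb | SSC | IRa,
IRa the exact reverse complement of IRb), places a realistic gene inventory
(123 unique genes, 23 duplicated in the IRs), plants repeats of four
categories, and evolves the sequence along a known tree with region-specific
substitution rates, a transition/transversion bias, and rare indels confined
to single-copy non-coding sequence.

Two bookkeeping rules make every downstream statistic exactly checkable:

* each ancestral site is touched by at most one mutation event in the whole
  simulation (sites are drawn without replacement), so realized event counts
  equal alignment-column counts;
* mutations falling in the inverted repeat are mirrored into the other copy
  (concerted evolution), so IRa stays the exact reverse complement of IRb and
  boundary detection remains exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np

from . import defaults as D
from ._util import decode, revcomp_codes, spawn_rngs
from .io import AnnotatedGenome, Feature
from .repeats import RepeatHit
from .structure import QuadripartiteStructure


class LayoutError(ValueError):
    pass


class RateError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class SimulationConfig:
    """All tunable parameters of the plastome simulator."""

    lsc_len: int = D.DEFAULT_LSC_LEN
    ssc_len: int = D.DEFAULT_SSC_LEN
    ir_len: int = D.DEFAULT_IR_LEN
    at_fraction: float = D.DEFAULT_AT_FRACTION
    lsc_genes: list[tuple[str, str]] = field(default_factory=lambda: list(D.LSC_GENE_ORDER))
    ssc_genes: list[tuple[str, str]] = field(default_factory=lambda: list(D.SSC_GENE_ORDER))
    ir_genes: list[tuple[str, str]] = field(default_factory=lambda: list(D.IR_GENE_ORDER))
    exon_lengths: dict[str, int] = field(default_factory=dict)
    intron_lengths: dict[str, list[int]] = field(default_factory=lambda: dict(D.INTRON_LENGTHS))
    trna_length: int = D.TRNA_LENGTH
    minus_strand: set[str] = field(default_factory=lambda: set(D.MINUS_STRAND_GENES))
    min_spacer: int = 30
    repeat_spec: list[tuple[str, int, int]] = field(default_factory=lambda: list(D.DEFAULT_REPEAT_SPEC))
    gene_similarity_targets: list[tuple[str, str]] = field(default_factory=lambda: list(D.GENE_SIMILARITY_TARGETS))
    tree: str = D.DEFAULT_TREE
    species_labels: dict[str, str] = field(default_factory=lambda: dict(D.DEFAULT_SPECIES_LABELS))
    outgroups: list[str] = field(default_factory=lambda: list(D.DEFAULT_OUTGROUPS))
    rate_multipliers: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in D.DEFAULT_RATE_MULTIPLIERS.items()}
    )
    rate_scale: float = 1.0
    ts_tv_ratio: float = 2.0
    indel_rate: float = 0.03  # indel events / site / unit branch length (SC non-coding)
    conspecific_pair: tuple[str, str, int] | None = ("sp4_a", "sp4_b", 16)
    region_exact_variants: dict[str, int] = field(default_factory=dict)

    @property
    def genome_length_target(self) -> int:
        return self.lsc_len + self.ssc_len + 2 * self.ir_len

    def validate(self) -> None:
        if min(self.lsc_len, self.ssc_len, self.ir_len) <= 0:
            raise ValueError("region lengths must be positive")
        for klass, by_region in self.rate_multipliers.items():
            for region, m in by_region.items():
                if m < 0:
                    raise ValueError(f"negative rate multiplier {klass}/{region}")
            if by_region.get("IR", 0) > min(by_region.get("LSC", 1), by_region.get("SSC", 1)):
                raise ValueError("IR multiplier must not exceed single-copy multipliers")
        if self.ts_tv_ratio < 0:
            raise ValueError("ts_tv_ratio must be >= 0")
        if self.indel_rate < 0:
            raise ValueError("indel_rate must be >= 0")


def default_config() -> SimulationConfig:
    """The study-scale configuration: ~156.6 kb genomes, 146 gene copies."""
    cfg = SimulationConfig()
    cfg.exon_lengths = _padded_exon_lengths(cfg)
    cfg.validate()
    return cfg


def demo_config(scale: float = 0.2) -> SimulationConfig:
    """A proportionally shrunken configuration for fast replicated runs.

    Region lengths, protein/rRNA exon lengths and intron lengths scale by
    ``scale``; the full gene inventory, tree, and rates are retained so every
    downstream statistic exercises the same code paths at reduced cost.
    """
    if not 0.1 <= scale <= 1.0:
        raise ValueError("scale must be in [0.1, 1]")
    cfg = SimulationConfig(
        lsc_len=int(D.DEFAULT_LSC_LEN * scale),
        ssc_len=int(D.DEFAULT_SSC_LEN * scale),
        ir_len=int(D.DEFAULT_IR_LEN * scale),
        min_spacer=6,
    )
    cfg.exon_lengths = {
        name: max(45, round(L * scale / 3) * 3) if name not in ("rrn16", "rrn23", "rrn4.5", "rrn5")
        else max(60, int(L * scale))
        for name, L in D.EXON_LENGTHS.items()
    }
    cfg.intron_lengths = {
        g: [max(40, int(L * scale)) for L in Ls] for g, Ls in D.INTRON_LENGTHS.items()
    }
    cfg.repeat_spec = []
    cfg.validate()
    return cfg


def _padded_exon_lengths(cfg: SimulationConfig) -> dict[str, int]:
    """Pad the largest LSC proteins so CDS bp hits the protein-fraction target."""
    lengths = dict(D.EXON_LENGTHS)
    placed: list[tuple[str, int]] = []  # (name, multiplicity)
    for name, klass in cfg.lsc_genes + cfg.ssc_genes:
        if klass == "p":
            placed.append((name, 1))
    for name, klass in cfg.ir_genes:
        if klass == "p":
            placed.append((name, 2))
    total = sum(lengths[n] * m for n, m in placed)
    target = int(D.DEFAULT_PROTEIN_FRACTION * cfg.genome_length_target)
    deficit = target - total
    if deficit > 0:
        lsc_proteins = sorted(
            (n for n, k in cfg.lsc_genes if k == "p"),
            key=lambda n: -lengths[n],
        )[:20]
        per = (deficit // len(lsc_proteins) // 3) * 3
        for n in lsc_proteins:
            lengths[n] += per
        lengths[lsc_proteins[0]] += ((deficit - per * len(lsc_proteins)) // 3) * 3
    return lengths


# ---------------------------------------------------------------------------
# Truth containers


@dataclass
class RegionRow:
    """One homologous region of the ancestor: an exon, intron, or spacer."""

    name: str
    klass: str  # coding_exon | intron | spacer
    region: str  # LSC | SSC | IR
    start: int
    end: int
    strand: str = "+"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class MutationEvent:
    kind: str  # transition | transversion | insertion | deletion
    pos: int  # ancestor coordinate
    row_index: int
    length: int = 1
    new_base: int = -1
    content: np.ndarray | None = None  # insertion content


@dataclass
class SimulationTruth:
    config: SimulationConfig
    ancestor: AnnotatedGenome
    structure: QuadripartiteStructure
    region_table: list[RegionRow]
    planted_repeats: list[RepeatHit] = field(default_factory=list)
    tree: str = ""
    structures: dict[str, QuadripartiteStructure] = field(default_factory=dict)
    events_by_leaf: dict[str, list[MutationEvent]] = field(default_factory=dict)
    realized_variant_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    n_events: int = 0

    def row_of(self, pos: int) -> RegionRow | None:
        for r in self.region_table:
            if r.start <= pos < r.end:
                return r
        return None


# ---------------------------------------------------------------------------
# Ancestor construction


def _gene_total_span(cfg: SimulationConfig, name: str, klass: str) -> int:
    exon = cfg.trna_length if klass == "t" and name not in cfg.exon_lengths else cfg.exon_lengths[name]
    introns = cfg.intron_lengths.get(name, [])
    return exon + sum(introns)


def _exon_split(total: int, n_exons: int) -> list[int]:
    base = total // n_exons
    out = [base] * n_exons
    out[0] += total - base * n_exons
    return out


def _layout_region(
    cfg: SimulationConfig,
    genes: list[tuple[str, str]],
    region_start: int,
    region_len: int,
    rng: np.random.Generator,
) -> tuple[list[Feature], list[tuple[int, int]]]:
    """Place genes in order with randomized spacer gaps filling the region.

    Returns the features and the spacer intervals (including the two edge
    spacers).  Raises :class:`LayoutError` when the inventory does not fit.
    """
    spans = [_gene_total_span(cfg, n, k) for n, k in genes]
    slack = region_len - sum(spans)
    n_gaps = len(genes) + 1
    if slack < n_gaps * cfg.min_spacer:
        raise LayoutError(
            f"gene inventory needs {sum(spans)} bp + {n_gaps * cfg.min_spacer} bp "
            f"spacers but region has {region_len} bp"
        )
    extra = slack - n_gaps * cfg.min_spacer
    props = rng.dirichlet(np.full(n_gaps, 2.0))
    gaps = (props * extra).astype(int)
    gaps[-1] += extra - gaps.sum()
    gaps = gaps + cfg.min_spacer

    kind_map = {"p": "CDS", "t": "tRNA", "r": "rRNA"}
    feats: list[Feature] = []
    spacers: list[tuple[int, int]] = []
    cur = region_start
    for (name, klass), span, gap in zip(genes, spans, gaps):
        spacers.append((cur, cur + int(gap)))
        cur += int(gap)
        exon_total = cfg.trna_length if klass == "t" and name not in cfg.exon_lengths else cfg.exon_lengths[name]
        introns = cfg.intron_lengths.get(name, [])
        exons = _exon_split(exon_total, len(introns) + 1)
        ivs = []
        pos = cur
        for i, e_len in enumerate(exons):
            ivs.append((pos, pos + e_len))
            pos += e_len
            if i < len(introns):
                pos += introns[i]
        strand = "-" if name in cfg.minus_strand else "+"
        feats.append(Feature(name, kind_map[klass], strand, ivs))
        cur += span
    spacers.append((cur, region_start + region_len))
    if cur > region_start + region_len:
        raise LayoutError("layout overflow")
    return feats, spacers


def _mirror_feature(f: Feature, irb: tuple[int, int], ira: tuple[int, int]) -> Feature:
    b0, b1 = irb
    a0, _ = ira
    ivs = sorted((a0 + (b1 - e), a0 + (b1 - s)) for s, e in f.intervals)
    strand = "-" if f.strand == "+" else "+"
    return Feature(f.gene_name, f.kind, strand, ivs, dict(f.qualifiers))


def _region_rows_for(
    feats: list[Feature], spacers: list[tuple[int, int]], region: str,
    order_names: list[str],
) -> list[RegionRow]:
    rows: list[RegionRow] = []
    feats = sorted(feats, key=lambda f: f.start)
    for i, (s, e) in enumerate(spacers):
        if e - s <= 0:
            continue
        left = feats[i - 1].gene_name if i > 0 else "edge"
        right = feats[i].gene_name if i < len(feats) else "edge"
        rows.append(RegionRow(f"{left}-{right}", "spacer", region, s, e))
    for f in feats:
        n_ex = len(f.intervals)
        for j, (s, e) in enumerate(f.intervals):
            name = f.gene_name if n_ex == 1 else f"{f.gene_name}_exon{j + 1}"
            rows.append(RegionRow(name, "coding_exon", region, s, e, f.strand))
        for j in range(n_ex - 1):
            rows.append(
                RegionRow(
                    f"{f.gene_name}_intron{j + 1}", "intron", region,
                    f.intervals[j][1], f.intervals[j + 1][0], f.strand,
                )
            )
    rows.sort(key=lambda r: r.start)
    return rows


def build_ancestor(
    config: SimulationConfig | None = None, seed: int = 0
) -> tuple[AnnotatedGenome, SimulationTruth]:
    """Generate the ancestral annotated quadripartite plastome.

    The genome is laid out LSC | IRb | SSC | IRa from position 0 with IRa the
    exact reverse complement of IRb, IR genes duplicated into both copies, and
    junction-adjacent bases chosen so the planted IR is the maximal inverted
    pair.
    """
    cfg = config or default_config()
    if not cfg.exon_lengths:
        cfg = replace(cfg, exon_lengths=_padded_exon_lengths(cfg))
    cfg.validate()
    rng_seq, rng_layout, rng_rep = spawn_rngs(seed, 3)

    L, S, I = cfg.lsc_len, cfg.ssc_len, cfg.ir_len
    G = cfg.genome_length_target
    lsc_iv, irb_iv = (0, L), (L, L + I)
    ssc_iv, ira_iv = (L + I, L + I + S), (L + I + S, G)

    at = cfg.at_fraction
    probs = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
    codes = rng_seq.choice(4, size=G, p=probs).astype(np.uint8)

    lsc_feats, lsc_spacers = _layout_region(cfg, cfg.lsc_genes, lsc_iv[0], L, rng_layout)
    irb_feats, irb_spacers = _layout_region(cfg, cfg.ir_genes, irb_iv[0], I, rng_layout)
    ssc_feats, ssc_spacers = _layout_region(cfg, cfg.ssc_genes, ssc_iv[0], S, rng_layout)

    # IRa mirrors IRb: sequence reverse-complemented, features mirrored
    codes[ira_iv[0] : ira_iv[1]] = revcomp_codes(codes[irb_iv[0] : irb_iv[1]])
    ira_feats = [_mirror_feature(f, irb_iv, ira_iv) for f in irb_feats]
    ira_spacers = sorted(
        (ira_iv[0] + (irb_iv[1] - e), ira_iv[0] + (irb_iv[1] - s)) for s, e in irb_spacers
    )

    # junction-adjacent bases must mismatch so the planted IR is maximal:
    # outward pair (s[irb0-1], comp(s[0])) and inward pair (s[irb1], comp(s[ira0-1]))
    b0, b1 = irb_iv
    a0 = ira_iv[0]
    while codes[b0 - 1] == 3 - codes[0]:
        codes[b0 - 1] = rng_seq.integers(0, 4)
    while codes[b1] == 3 - codes[a0 - 1]:
        codes[b1] = rng_seq.integers(0, 4)

    features = lsc_feats + irb_feats + ssc_feats + ira_feats
    genome = AnnotatedGenome(
        id="ancestor", sequence=decode(codes), features=features,
        organism="synthetic plastome", species_label="ancestor",
    )

    structure = QuadripartiteStructure(
        lsc=lsc_iv, irb=irb_iv, ssc=ssc_iv, ira=ira_iv, genome_length=G
    )
    rows = (
        _region_rows_for(lsc_feats, lsc_spacers, "LSC", [n for n, _ in cfg.lsc_genes])
        + _region_rows_for(ssc_feats, ssc_spacers, "SSC", [n for n, _ in cfg.ssc_genes])
        + _region_rows_for(ira_feats, ira_spacers, "IR", [n for n, _ in cfg.ir_genes])
    )
    truth = SimulationTruth(
        config=cfg, ancestor=genome, structure=structure, region_table=rows, tree=cfg.tree
    )
    if cfg.repeat_spec:
        genome, planted = plant_repeats(genome, truth, rng_rep)
        truth.ancestor = genome
        truth.planted_repeats = planted
    return genome, truth


# ---------------------------------------------------------------------------
# Repeat planting


class PlacementError(ValueError):
    pass


def plant_repeats(
    genome: AnnotatedGenome,
    truth: SimulationTruth,
    rng: np.random.Generator,
) -> tuple[AnnotatedGenome, list[RepeatHit]]:
    """Write the configured repeat copies into single-copy spacers (or the
    configured gene pairs for gene-similarity repeats) and return the truth."""
    from ._util import encode  # local import to avoid cycle at module load

    cfg = truth.config
    codes = encode(genome.sequence)
    at = cfg.at_fraction
    probs = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])

    # candidate gaps: interior single-copy spacers, largest first
    spacer_rows = [
        r for r in truth.region_table
        if r.klass == "spacer" and r.region in ("LSC", "SSC")
        and "edge" not in r.name and r.length >= 40
    ]
    free: list[list[int]] = [[r.start + 2, r.end - 2] for r in spacer_rows]

    def take(length: int, avoid: int | None = None) -> tuple[int, int]:
        """Reserve `length` bp from the largest free gap; return (start, gap idx)."""
        sizes = [
            (iv[1] - iv[0]) if j != avoid else -1 for j, iv in enumerate(free)
        ]
        j = int(np.argmax(sizes))
        if sizes[j] < length:
            raise PlacementError(f"no intergenic gap of {length} bp available")
        start = free[j][0]
        # 40 bp of random sequence between consecutive reservations keeps
        # independently planted copies from chaining into one valid window
        # even for the longest motifs (junk mismatches outrun the identity
        # budget of any window spanning two plants)
        free[j][0] += length + 40
        return start, j

    def rand_seq(n: int) -> np.ndarray:
        return rng.choice(4, size=n, p=probs).astype(np.uint8)

    def mismatched(copy: np.ndarray, n_mism: int) -> np.ndarray:
        out = copy.copy()
        if n_mism:
            pos = rng.choice(len(copy), size=n_mism, replace=False)
            for p in pos:
                out[p] = (out[p] + rng.integers(1, 4)) % 4
        return out

    gene_spans = {f.gene_name: f.intervals[0] for f in genome.features if f.kind == "CDS"}
    hits: list[RepeatHit] = []
    gs_cycle = 0
    for cat, length, n_mism in cfg.repeat_spec:
        motif = rand_seq(length)
        if cat == "tandem":
            gap = int(rng.integers(0, 4))
            start, _ = take(2 * length + gap)
            c1 = (start, start + length)
            c2 = (start + length + gap, start + 2 * length + gap)
            codes[c1[0] : c1[1]] = motif
            codes[c2[0] : c2[1]] = mismatched(motif, n_mism)
            orient = "direct"
        elif cat == "palindromic":
            gap = int(rng.integers(20, 300))
            start, _ = take(2 * length + gap)
            c1 = (start, start + length)
            c2 = (start + length + gap, start + 2 * length + gap)
            codes[c1[0] : c1[1]] = motif
            codes[c2[0] : c2[1]] = revcomp_codes(mismatched(motif, n_mism))
            orient = "inverted"
        elif cat == "dispersed":
            s1, j1 = take(length)
            s2, _ = take(length, avoid=j1)  # a different spacer, so gap >> tandem slack
            c1, c2 = sorted([(s1, s1 + length), (s2, s2 + length)])
            codes[c1[0] : c1[1]] = motif
            codes[c2[0] : c2[1]] = mismatched(motif, n_mism)
            orient = "direct"
        elif cat == "gene_similarity":
            g1, g2 = cfg.gene_similarity_targets[gs_cycle % len(cfg.gene_similarity_targets)]
            gs_cycle += 1
            spans = [gene_spans[g1], gene_spans[g2]]
            starts = []
            for s, e in spans:
                if e - s < length + 20:
                    raise PlacementError(f"gene too short for {length} bp repeat")
                starts.append(int(rng.integers(s + 10, e - length - 10)))
            c1, c2 = sorted([(starts[0], starts[0] + length), (starts[1], starts[1] + length)])
            codes[c1[0] : c1[1]] = motif
            codes[c2[0] : c2[1]] = mismatched(motif, n_mism)
            orient = "direct"
        else:
            raise ValueError(f"unknown repeat category {cat!r}")
        hits.append(
            RepeatHit(
                copy1=c1, copy2=c2, orientation=orient, length=length,
                identity=(length - n_mism) / length, category=cat,
            )
        )
    new_genome = AnnotatedGenome(
        id=genome.id, sequence=decode(codes), features=genome.features,
        organism=genome.organism, species_label=genome.species_label,
    )
    return new_genome, hits


# ---------------------------------------------------------------------------
# Evolution along a tree


def _parse_tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


def evolve_tree(
    ancestor: AnnotatedGenome,
    truth: SimulationTruth,
    seed: int = 0,
) -> tuple[dict[str, AnnotatedGenome], SimulationTruth]:
    """Evolve the ancestor along the configured tree.

    Substitution counts per branch and region are Poisson with mean
    ``branch_length * rate_scale * multiplier[class][region] * region_bp``;
    each event picks a previously untouched site.  Transitions occur with
    probability kappa/(kappa+1).  Indels (geometric length, mean 3) fall in
    single-copy non-coding sequence only.  IR events are mirrored into both
    copies.  The configured conspecific pair receives exactly its target
    number of differing sites on its two terminal branches and nothing else.
    """
    from ._util import encode

    cfg = truth.config
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 9151]))
    tree = _parse_tree(cfg.tree)
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(leaves) < 2:
        raise ValueError("tree needs at least 2 leaves")

    anc_codes = encode(ancestor.sequence)
    G = len(anc_codes)
    used = np.zeros(G, dtype=bool)
    st = truth.structure
    b0, b1 = st.irb
    a0, a1 = st.ira
    for pos in (0, b0 - 1, b1, a0 - 1):  # junction guards stay immutable
        used[pos] = True
    used[b0:b1] = True  # IRb receives only mirrored events

    rows = truth.region_table
    row_rate = np.empty(len(rows))
    klass_map = {"coding_exon": "coding", "intron": "intron", "spacer": "spacer"}
    for i, r in enumerate(rows):
        row_rate[i] = cfg.rate_multipliers[klass_map[r.klass]][r.region]

    sc_noncoding = [
        (i, r) for i, r in enumerate(rows)
        if r.klass in ("intron", "spacer") and r.region in ("LSC", "SSC") and r.length >= 12
    ]
    sc_nc_len = sum(r.length for _, r in sc_noncoding)

    kappa = cfg.ts_tv_ratio
    p_ts = 1.0 if math.isinf(kappa) else kappa / (kappa + 1.0)

    def mirror(pos: int) -> int:
        return b0 + (a1 - 1 - pos)

    def pick_site(lo: int, hi: int) -> int | None:
        for _ in range(200):
            p = int(rng.integers(lo, hi))
            if not used[p]:
                return p
        cands = np.nonzero(~used[lo:hi])[0]
        if len(cands) == 0:
            return None
        return int(lo + rng.choice(cands))

    def draw_sub(pos: int, row_idx: int) -> MutationEvent:
        old = int(anc_codes[pos])
        if rng.random() < p_ts:
            new, kind = old ^ 2, "transition"
        else:
            new = old ^ (1 if rng.random() < 0.5 else 3)
            kind = "transversion"
        used[pos] = True
        if rows[row_idx].region == "IR":
            used[mirror(pos)] = True
        return MutationEvent(kind, pos, row_idx, new_base=new)

    conspecific = cfg.conspecific_pair
    protected = set()
    if conspecific:
        protected = {conspecific[0], conspecific[1]}
        for t in protected:
            if t not in leaves:
                raise ValueError(f"conspecific taxon {t} not in tree")

    # assign events per edge
    edge_events: dict[int, list[MutationEvent]] = {}
    edges = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        blen = node.edge.length or 0.0
        taxon = node.taxon.label if node.is_leaf() else None
        edges.append((id(node), node, blen, taxon))
        edge_events[id(node)] = []

    for eid, node, blen, taxon in edges:
        if taxon in protected:
            continue  # handled exactly below
        if blen <= 0:
            continue
        evs = edge_events[eid]
        for i, r in enumerate(rows):
            lam = blen * cfg.rate_scale * row_rate[i] * r.length
            if lam <= 0:
                continue
            k = int(rng.poisson(lam))
            if k > r.length:
                raise RateError(f"substitution count {k} exceeds region {r.name}")
            for _ in range(k):
                p = pick_site(r.start, r.end)
                if p is None:
                    continue
                evs.append(draw_sub(p, i))
        # indels
        if cfg.indel_rate > 0 and sc_nc_len > 0:
            lam = blen * cfg.rate_scale * cfg.indel_rate * sc_nc_len
            # a 12 bp exclusion margin keeps independent indels far enough
            # apart that the aligner cannot stack them into shared columns,
            # so indel events and alignment gap runs correspond one-to-one
            margin = 12
            for _ in range(int(rng.poisson(lam))):
                ridx, r = sc_noncoding[int(rng.integers(0, len(sc_noncoding)))]
                g = min(int(rng.geometric(1.0 / 3.0)), 8)
                if r.length < g + 2 * (margin + 2):
                    continue
                p = pick_site(r.start + margin + 1, r.end - margin - 1 - g)
                if p is None:
                    continue
                if used[p - margin : p + g + margin].any():
                    continue
                if rng.random() < 0.5:
                    used[p - margin : p + g + margin] = True
                    evs.append(MutationEvent("deletion", p, ridx, length=g))
                else:
                    used[p - margin : p + margin] = True
                    content = rng.choice(4, size=g).astype(np.uint8)
                    evs.append(MutationEvent("insertion", p, ridx, length=g, content=content))

    # exact conspecific differences on the two terminal branches
    if conspecific:
        t1, t2, k_target = conspecific
        sc_rows = [
            (i, r) for i, r in enumerate(rows) if r.region in ("LSC", "SSC")
        ]
        weights = np.array([r.length for _, r in sc_rows], dtype=float)
        weights /= weights.sum()
        halves = (k_target // 2, k_target - k_target // 2)
        for taxon, k in zip((t1, t2), halves):
            eid = next(e for e in edges if e[3] == taxon)[0]
            for _ in range(k):
                ridx = int(rng.choice(len(sc_rows), p=weights))
                i, r = sc_rows[ridx]
                p = pick_site(r.start, r.end)
                if p is None:
                    raise RateError("no free site for conspecific difference")
                edge_events[eid].append(draw_sub(p, i))

    # exact per-region planted variant counts (ingroup branches only)
    if cfg.region_exact_variants:
        ingroup = [t for t in leaves if t not in set(cfg.outgroups)]
        ingroup_edges = []
        for eid, node, blen, taxon in edges:
            below = {lf.taxon.label for lf in node.leaf_iter()}
            # any edge inside the ingroup subtree except the conspecific
            # terminals (their difference count is planted exactly)
            if below <= set(ingroup) and below != set(ingroup) and not (below <= protected):
                ingroup_edges.append(eid)
        by_name = {}
        for i, r in enumerate(rows):
            by_name.setdefault(r.name, []).append(i)
        for rname, k in cfg.region_exact_variants.items():
            if rname not in by_name:
                raise ValueError(f"unknown region {rname!r} in region_exact_variants")
            idxs = by_name[rname]
            for _ in range(k):
                i = idxs[int(rng.integers(0, len(idxs)))]
                r = rows[i]
                p = pick_site(r.start, r.end)
                if p is None:
                    raise RateError(f"region {rname} has no free site")
                eid = ingroup_edges[int(rng.integers(0, len(ingroup_edges)))]
                edge_events[eid].append(draw_sub(p, i))

    # build leaf genomes by accumulating events along root-to-leaf paths
    genomes: dict[str, AnnotatedGenome] = {}
    counts: dict[str, dict[str, int]] = {
        k: {"transition": 0, "transversion": 0, "indel": 0}
        for k in ("coding", "intron_spacer", "LSC", "SSC", "IR")
    }
    n_events = 0
    for eid, node, blen, taxon in edges:
        for ev in edge_events[eid]:
            n_events += 1
            r = rows[ev.row_index]
            func = "coding" if r.klass == "coding_exon" else "intron_spacer"
            typ = ev.kind if ev.kind in ("transition", "transversion") else "indel"
            counts[func][typ] += 1
            counts[r.region][typ] += 1

    events_by_leaf: dict[str, list[MutationEvent]] = {}
    for leaf_node in tree.leaf_node_iter():
        taxon = leaf_node.taxon.label
        evs: list[MutationEvent] = []
        node = leaf_node
        while node.parent_node is not None:
            evs.extend(edge_events[id(node)])
            node = node.parent_node
        events_by_leaf[taxon] = evs
        genomes[taxon] = _apply_events(ancestor, anc_codes, evs, truth, taxon, cfg)

    truth.events_by_leaf = events_by_leaf
    truth.realized_variant_counts = counts
    truth.n_events = n_events
    truth.structures = {
        t: _lift_structure(truth.structure, events_by_leaf[t]) for t in genomes
    }
    return genomes, truth


def _apply_events(
    ancestor: AnnotatedGenome,
    anc_codes: np.ndarray,
    events: list[MutationEvent],
    truth: SimulationTruth,
    taxon: str,
    cfg: SimulationConfig,
) -> AnnotatedGenome:
    st = truth.structure
    a1 = st.ira[1]
    b0 = st.irb[0]
    codes = anc_codes.copy()
    for ev in events:
        if ev.kind in ("transition", "transversion"):
            codes[ev.pos] = ev.new_base
            r = truth.region_table[ev.row_index]
            if r.region == "IR":
                codes[b0 + (a1 - 1 - ev.pos)] = 3 - ev.new_base
    indels = sorted(
        (ev for ev in events if ev.kind in ("insertion", "deletion")),
        key=lambda e: -e.pos,
    )
    parts = [codes]
    for ev in indels:
        head = parts[0]
        if ev.kind == "deletion":
            parts[0] = np.concatenate([head[: ev.pos], head[ev.pos + ev.length :]])
        else:
            parts[0] = np.concatenate([head[: ev.pos], ev.content, head[ev.pos :]])
    codes = parts[0]

    lift = _make_lift(events)
    feats = [
        Feature(
            f.gene_name, f.kind, f.strand,
            [(lift(s), lift(e)) for s, e in f.intervals],
            dict(f.qualifiers),
        )
        for f in ancestor.features
    ]
    return AnnotatedGenome(
        id=taxon, sequence=decode(codes), features=feats,
        organism=cfg.species_labels.get(taxon, taxon),
        species_label=cfg.species_labels.get(taxon, taxon),
    )


def _make_lift(events: list[MutationEvent]):
    """Ancestor-coordinate -> leaf-coordinate map through this leaf's indels."""
    indels = sorted(
        ((ev.pos, ev.length if ev.kind == "insertion" else -ev.length)
         for ev in events if ev.kind in ("insertion", "deletion"))
    )

    def lift(x: int) -> int:
        off = 0
        for p, d in indels:
            if d > 0 and p <= x:
                off += d
            elif d < 0 and p < x:
                off += max(d, p - x)  # fully before: +d; boundaries never inside
        return x + off

    return lift


def _lift_structure(
    st: QuadripartiteStructure, events: list[MutationEvent]
) -> QuadripartiteStructure:
    lift = _make_lift(events)
    G = lift(st.genome_length)
    return QuadripartiteStructure(
        lsc=(lift(st.lsc[0]), lift(st.lsc[1])),
        irb=(lift(st.irb[0]), lift(st.irb[1])),
        ssc=(lift(st.ssc[0]), lift(st.ssc[1])),
        ira=(lift(st.ira[0]), lift(st.ira[1])),
        genome_length=G,
    )


def simulate(
    config: SimulationConfig | None = None, seed: int = 0
) -> tuple[dict[str, AnnotatedGenome], SimulationTruth]:
    """Full simulation: ancestor construction, repeat planting, tree evolution."""
    ancestor, truth = build_ancestor(config, seed)
    return evolve_tree(ancestor, truth, seed)


# ---------------------------------------------------------------------------
# Calibration fixtures

# intergenic spacers / intron classically reported as fast-evolving in
# plastomes; used by the hotspot-recovery fixture
HOTSPOT_REGIONS = [
    "accD-psaI", "atpF-atpH", "ccsA-ndhD", "clpP-psbB", "ndhC-trnV-UAC",
    "ndhF-rpl32", "petD-rpoA", "psbH-petB", "rpl32-trnL-UAG",
    "trnG-GCC_intron1", "trnS-GCU-trnG-GCC",
]


def simulate_hotspot_fixture(
    seed: int = 0,
    hotspot_pct: float = 2.5,
    background_pct: float = 0.5,
    n_background: int = 25,
) -> tuple[dict[str, AnnotatedGenome], SimulationTruth, list[str]]:
    """Simulation with exactly 11 regions above the 1% variability threshold.

    Eleven named fast-evolving regions receive an exact planted count of
    variable sites (about ``hotspot_pct`` of their length); a set of large
    coding regions receives counts below 1%; everything else stays invariant.
    The realized percentages are exact for any seed, so hotspot recovery is a
    deterministic property of the fixture.
    """
    cfg = default_config()
    ancestor, truth = build_ancestor(cfg, seed)
    lengths = {r.name: r.length for r in truth.region_table}
    exact: dict[str, int] = {}
    for name in HOTSPOT_REGIONS:
        if name not in lengths:
            raise ValueError(f"fixture region {name} missing from layout")
        exact[name] = max(2, math.ceil(hotspot_pct / 100.0 * lengths[name]))
    background = sorted(
        (
            r for r in truth.region_table
            if r.klass == "coding_exon" and r.region == "LSC"
            and r.length >= 400 and r.name not in exact
        ),
        key=lambda r: -r.length,
    )
    for r in background[:n_background]:
        k = int(background_pct / 100.0 * r.length)
        if k >= 1 and k / r.length < 0.009:
            exact[r.name] = k
    truth.config = replace(
        truth.config,
        rate_scale=0.0,
        indel_rate=0.0,
        conspecific_pair=None,
        region_exact_variants=exact,
    )
    genomes, truth = evolve_tree(ancestor, truth, seed)
    return genomes, truth, list(HOTSPOT_REGIONS)
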