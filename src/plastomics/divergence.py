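"""Homologous-region extraction, divergence statistics, and variant tallies.

Every genome is decomposed into named regions -- coding exons, introns, and
intergenic spacers (spacers are split at the four IR junctions; the IRb copy
of duplicated content is dropped so each homologous locus appears once).
Regions are matched across genomes by name, aligned with the in-package
progressive aligner, and summarized:

* variable columns: >= 2 distinct bases among {A,C,G,T}; gaps and N are not
  states (a column of one base plus gaps is an indel column, not variable);
* hotspots: regions whose variable-character percentage strictly exceeds a
  threshold (default 1%);
* p-distance: differing sites / compared sites, where compared sites have a
  base in both rows (indel sites excluded);
* variant tallies: per-column transition/transversion plus indel events
  (maximal gap runs with a constant gapped row set), aggregated by
  coding vs intron/spacer and by LSC/SSC/IR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import align as al
from ._util import encode, revcomp_codes
from .io import AnnotatedGenome
from .structure import QuadripartiteStructure

GAP = al.GAP


class RegionExtractionError(ValueError):
    pass


@dataclass
class Region:
    """A named homologous locus with its per-genome location."""

    name: str
    klass: str  # coding_exon | intron | spacer
    region: str  # LSC | SSC | IR
    locations: dict[str, tuple[int, int, str]] = field(default_factory=dict)

    @property
    def taxa(self) -> list[str]:
        return sorted(self.locations)


@dataclass
class RegionAlignment:
    region: Region
    taxa: list[str]
    rows: np.ndarray  # n_taxa x columns, codes with GAP

    @property
    def length(self) -> int:
        return self.rows.shape[1]


@dataclass
class DivergenceRecord:
    name: str
    klass: str
    aligned_length: int
    variable_columns: int
    variable_pct: float
    indel_columns: int
    is_hotspot: bool = False


@dataclass
class DistanceSummary:
    taxa: list[str]
    matrix: np.ndarray
    mean_all: float
    mean_between_species: float
    mean_within_species: float
    pair_site_differences: dict[tuple[str, str], int]
    incomparable_pairs: list[tuple[str, str]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Region extraction


def _genome_region_rows(
    genome: AnnotatedGenome, structure: QuadripartiteStructure
) -> list[tuple[str, str, str, int, int, str]]:
    """(name, klass, structural region, start, end, strand) rows covering the
    genome once, IRb excluded, spacers split at junctions."""
    n = len(genome)
    b0, b1 = structure.irb

    feats = [
        f for f in genome.features if f.kind in ("CDS", "tRNA", "rRNA", "pseudogene")
    ]
    feats.sort(key=lambda f: f.start)
    kept = [f for f in feats if not (b0 <= f.start and f.end <= b1)]

    # duplicate names must be the two IR copies; anything else is ambiguous
    seen: dict[str, int] = {}
    for f in feats:
        seen[f.gene_name] = seen.get(f.gene_name, 0) + 1
    for name, k in seen.items():
        if k > 2:
            raise RegionExtractionError(f"gene {name} appears {k} times")
        if k == 2:
            copies = [f for f in feats if f.gene_name == name]
            in_ir = [
                (b0 <= f.start and f.end <= b1)
                or (structure.ira[0] <= f.start and f.end <= structure.ira[1])
                for f in copies
            ]
            if not all(in_ir):
                raise RegionExtractionError(
                    f"gene {name} duplicated outside the IR context"
                )

    def struct_of(s: int, e: int) -> str:
        r = structure.region_of((s + e) // 2)
        return "IR" if r in ("IRa", "IRb") else r

    rows: list[tuple[str, str, str, int, int, str]] = []
    for f in kept:
        if f.kind == "pseudogene":
            continue
        n_ex = len(f.intervals)
        for j, (s, e) in enumerate(f.intervals):
            name = f.gene_name if n_ex == 1 else f"{f.gene_name}_exon{j + 1}"
            rows.append((name, "coding_exon", struct_of(s, e), s, e, f.strand))
        for j in range(n_ex - 1):
            s, e = f.intervals[j][1], f.intervals[j + 1][0]
            rows.append((f"{f.gene_name}_intron{j + 1}", "intron", struct_of(s, e), s, e, f.strand))

    # spacers: gaps between consecutive feature spans plus the two ends,
    # split at junction positions, IRb portions dropped
    junctions = sorted({0, b0, b1, structure.ssc[0] % n, structure.ira[0] % n, n})
    bounds = []
    prev_name = "edge"
    prev_end = 0
    for f in kept + [None]:
        start = f.start if f is not None else n
        if start > prev_end:
            bounds.append((prev_name, prev_end, start, f.gene_name if f else "edge"))
        if f is not None:
            prev_name, prev_end = f.gene_name, max(prev_end, f.end)
    for left, s, e, right in bounds:
        cuts = sorted({s, e} | {j for j in junctions if s < j < e})
        for cs, ce in zip(cuts, cuts[1:]):
            if b0 <= cs and ce <= b1:
                continue  # inside IRb
            lname = left if cs == s else "edge"
            rname = right if ce == e else "edge"
            rows.append((f"{lname}-{rname}", "spacer", struct_of(cs, ce), cs, ce, "+"))
    rows.sort(key=lambda r: r[3])
    return rows


def extract_regions(
    genomes: dict[str, AnnotatedGenome],
    structures: dict[str, QuadripartiteStructure],
) -> list[Region]:
    """Match named regions across genomes; regions missing from some genomes
    are retained with partial presence."""
    table: dict[str, Region] = {}
    order: list[str] = []
    for taxon, genome in genomes.items():
        for name, klass, struct, s, e, strand in _genome_region_rows(
            genome, structures[taxon]
        ):
            if name not in table:
                table[name] = Region(name, klass, struct)
                order.append(name)
            reg = table[name]
            if reg.klass != klass:
                raise RegionExtractionError(
                    f"region {name} is {reg.klass} in one genome, {klass} in another"
                )
            reg.locations[taxon] = (s, e, strand)
    return [table[n] for n in order]


def region_sequences(
    region: Region, genomes: dict[str, AnnotatedGenome]
) -> dict[str, np.ndarray]:
    """Per-taxon sequence of a region, minus-strand regions reverse
    complemented to the common orientation."""
    out: dict[str, np.ndarray] = {}
    for taxon, (s, e, strand) in region.locations.items():
        codes = encode(genomes[taxon].sequence[s:e])
        out[taxon] = revcomp_codes(codes) if strand == "-" else codes
    return out


def align_region(sequences: dict[str, np.ndarray]) -> RegionAlignment:
    """Progressively align the per-taxon sequences of one region."""
    taxa = list(sequences)
    if len(taxa) < 2:
        raise ValueError("need >= 2 sequences to align")
    rows = al.multiple_align([sequences[t] for t in taxa])
    return RegionAlignment(
        region=Region("?", "?", "?"), taxa=taxa, rows=np.vstack(rows)
    )


# ---------------------------------------------------------------------------
# Column statistics


def _column_state_masks(rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(n_distinct_bases per column, any_gap per column)."""
    present = np.zeros(rows.shape[1], dtype=np.int8)
    for b in range(4):
        present += (rows == b).any(axis=0)
    any_gap = (rows == GAP).any(axis=0)
    return present, any_gap


def variable_stats(
    alignment: RegionAlignment, name: str | None = None, klass: str | None = None
) -> DivergenceRecord:
    rows = alignment.rows
    if rows.shape[0] < 2:
        raise ValueError("need >= 2 rows")
    n_states, any_gap = _column_state_masks(rows)
    variable = int((n_states >= 2).sum())
    length = rows.shape[1]
    return DivergenceRecord(
        name=name or alignment.region.name,
        klass=klass or alignment.region.klass,
        aligned_length=length,
        variable_columns=variable,
        variable_pct=100.0 * variable / length if length else 0.0,
        indel_columns=int(any_gap.sum()),
    )


# ---------------------------------------------------------------------------
# Whole-genome alignment assembly


@dataclass
class WholeGenomeAlignment:
    """Concatenation of per-region alignments in reference genome order."""

    taxa: list[str]
    rows: np.ndarray
    regions: list[Region]
    col_region: np.ndarray  # index into regions per column

    @property
    def length(self) -> int:
        return self.rows.shape[1]

    def col_classes(self) -> tuple[np.ndarray, np.ndarray]:
        """(functional label, structural label) per column."""
        func = np.array(
            ["coding" if self.regions[i].klass == "coding_exon" else "intron_spacer"
             for i in self.col_region]
        )
        struct = np.array([self.regions[i].region for i in self.col_region])
        return func, struct


def build_whole_genome_alignment(
    genomes: dict[str, AnnotatedGenome],
    structures: dict[str, QuadripartiteStructure],
    taxa: list[str] | None = None,
) -> tuple[WholeGenomeAlignment, list[RegionAlignment]]:
    """Extract, align, and concatenate all shared regions (genome order of
    the first taxon).  Valid because the genomes are collinear."""
    taxa = taxa or list(genomes)
    sel = {t: genomes[t] for t in taxa}
    regions = extract_regions(sel, structures)
    ref = taxa[0]
    regions = [r for r in regions if len(r.locations) == len(taxa)]
    regions.sort(key=lambda r: r.locations[ref][0])
    if not regions:
        raise RegionExtractionError("no regions shared by all genomes")

    blocks: list[np.ndarray] = []
    col_region: list[np.ndarray] = []
    r_alns: list[RegionAlignment] = []
    for i, reg in enumerate(regions):
        seqs = region_sequences(reg, sel)
        aln = align_region({t: seqs[t] for t in taxa})
        aln.region = reg
        aln.taxa = taxa
        r_alns.append(aln)
        blocks.append(aln.rows)
        col_region.append(np.full(aln.length, i, dtype=np.int32))
    wga = WholeGenomeAlignment(
        taxa=taxa,
        rows=np.hstack(blocks),
        regions=regions,
        col_region=np.concatenate(col_region),
    )
    return wga, r_alns


# ---------------------------------------------------------------------------
# Hotspot scan


def scan_hotspots(
    genomes: dict[str, AnnotatedGenome],
    structures: dict[str, QuadripartiteStructure],
    threshold_pct: float = 1.0,
    include_outgroups: bool = False,
    outgroups: list[str] | None = None,
) -> list[DivergenceRecord]:
    """Full extract -> align -> stats sweep, ranked by variable percentage
    (descending); ``is_hotspot`` where variable_pct strictly exceeds the
    threshold.  Outgroups are excluded from the statistics unless requested."""
    if len(genomes) < 3:
        raise ValueError("need >= 3 genomes")
    outgroups = outgroups or []
    taxa = [t for t in genomes if include_outgroups or t not in outgroups]
    wga, r_alns = build_whole_genome_alignment(
        {t: genomes[t] for t in taxa},
        {t: structures[t] for t in taxa},
        taxa=taxa,
    )
    records = []
    for aln in r_alns:
        rec = variable_stats(aln)
        rec.is_hotspot = rec.variable_pct > threshold_pct
        records.append(rec)
    records.sort(key=lambda r: (-r.variable_pct, r.name))
    return records


# ---------------------------------------------------------------------------
# p-distances


def p_distance_summary(
    wga: WholeGenomeAlignment,
    species_labels: dict[str, str],
    outgroups: list[str] | None = None,
) -> DistanceSummary:
    """Pairwise p-distances (indel sites excluded) plus ingroup means."""
    outgroups = set(outgroups or [])
    taxa = wga.taxa
    n = len(taxa)
    rows = wga.rows
    mat = np.zeros((n, n))
    diffs: dict[tuple[str, str], int] = {}
    bad: list[tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            a, b = rows[i], rows[j]
            comp = (a < 4) & (b < 4)
            nc = int(comp.sum())
            if nc == 0:
                bad.append((taxa[i], taxa[j]))
                mat[i, j] = mat[j, i] = np.nan
                continue
            nd = int((a[comp] != b[comp]).sum())
            mat[i, j] = mat[j, i] = nd / nc
            diffs[(taxa[i], taxa[j])] = nd

    ing = [i for i, t in enumerate(taxa) if t not in outgroups]
    all_p, between, within = [], [], []
    for ii, i in enumerate(ing):
        for j in ing[ii + 1 :]:
            if np.isnan(mat[i, j]):
                continue
            all_p.append(mat[i, j])
            same = species_labels.get(taxa[i]) == species_labels.get(taxa[j])
            (within if same else between).append(mat[i, j])

    def mean(v: list[float]) -> float:
        return float(np.mean(v)) if v else float("nan")

    return DistanceSummary(
        taxa=taxa,
        matrix=mat,
        mean_all=mean(all_p),
        mean_between_species=mean(between),
        mean_within_species=mean(within),
        pair_site_differences=diffs,
        incomparable_pairs=bad,
    )


# ---------------------------------------------------------------------------
# Variant tallies


def tally_variants(wga: WholeGenomeAlignment) -> dict[str, dict[str, int]]:
    """Counts of transitions, transversions, and indel events per partition
    (coding / intron_spacer and LSC / SSC / IR).

    A substitution column counts once: transition when the observed bases are
    exactly {A,G} or {C,T}, transversion otherwise (mixed columns count once
    as transversion).  An indel event is a maximal run of columns sharing the
    same non-empty set of gapped rows.
    """
    rows = wga.rows
    func, struct = wga.col_classes()
    counts = {
        k: {"transition": 0, "transversion": 0, "indel": 0}
        for k in ("coding", "intron_spacer", "LSC", "SSC", "IR")
    }

    base_present = np.stack([(rows == b).any(axis=0) for b in range(4)])
    n_states = base_present.sum(axis=0)
    var_cols = np.nonzero(n_states >= 2)[0]
    for c in var_cols:
        present = base_present[:, c]
        is_ts = n_states[c] == 2 and (
            (present[0] and present[2]) or (present[1] and present[3])
        )
        typ = "transition" if is_ts else "transversion"
        counts[func[c]][typ] += 1
        counts[struct[c]][typ] += 1

    gap = rows == GAP
    any_gap = gap.any(axis=0)
    cols = np.nonzero(any_gap)[0]
    prev_c = -10
    prev_sig: int | None = None
    for c in cols:
        sig = hash(gap[:, c].tobytes())
        if c != prev_c + 1 or sig != prev_sig or wga.col_region[c] != wga.col_region[prev_c]:
            counts[func[c]]["indel"] += 1
            counts[struct[c]]["indel"] += 1
        prev_c, prev_sig = c, sig
    return counts
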