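"""Quadripartite structure detection and genome-level statistics.

A plastome is laid out LSC | IRb | SSC | IRa on a circle, where IRa is the
reverse complement of IRb.  Detection finds the longest pair of disjoint
reverse-complementary segments via exact k-mer seeds on the doubled sequence
followed by outward extension; a mismatch patch is crossed only when strongly
supported on the far side, so the reported boundaries are the maximal
biologically meaningful ones rather than chance matches into single-copy
sequence.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ._util import encode, revcomp_codes
from .io import AnnotatedGenome, Feature

log = logging.getLogger(__name__)

Interval = tuple[int, int]


class NoIRFound(ValueError):
    pass


class AmbiguousIR(ValueError):
    pass


@dataclass
class QuadripartiteStructure:
    """LSC/IRb/SSC/IRa intervals (0-based half-open, non-wrapping order)."""

    lsc: Interval
    irb: Interval
    ssc: Interval
    ira: Interval
    genome_length: int
    mismatches_between_ir_copies: int = 0

    def __post_init__(self) -> None:
        if self.lsc_len < self.ssc_len:
            raise ValueError("LSC must be the larger single-copy region")
        total = self.lsc_len + self.ssc_len + self.ir_len * 2
        if total != self.genome_length:
            raise ValueError(
                f"regions sum to {total}, genome length {self.genome_length}"
            )

    @property
    def lsc_len(self) -> int:
        return self.lsc[1] - self.lsc[0]

    @property
    def ssc_len(self) -> int:
        return self.ssc[1] - self.ssc[0]

    @property
    def ir_len(self) -> int:
        return self.irb[1] - self.irb[0]

    def region_of(self, pos: int) -> str:
        n = self.genome_length
        for name, (s, e) in (
            ("LSC", self.lsc), ("IRb", self.irb), ("SSC", self.ssc), ("IRa", self.ira)
        ):
            if (pos - s) % n < e - s:
                return name
        raise ValueError(f"position {pos} outside genome of length {self.genome_length}")

    def junctions(self) -> dict[str, int]:
        """The four junction positions (boundary sits between pos-1 and pos)."""
        return {
            "LSC/IRb": self.irb[0],
            "IRb/SSC": self.ssc[0],
            "SSC/IRa": self.ira[0],
            "IRa/LSC": self.ira[1] % self.genome_length,
        }


# ---------------------------------------------------------------------------
# IR detection


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Base-4 integer code of every k-window; windows containing N get 2**63."""
    w = sliding_window_view(codes, k)
    powers = (4 ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    vals = (w.astype(np.uint64) * powers).sum(axis=1)
    bad = (w >= 4).any(axis=1)
    vals[bad] = np.uint64(2**63)
    return vals


def _extend_inverted(
    codes: np.ndarray,
    C: int,
    p0: int,
    *,
    max_patch: int = 2,
    confirm_window: int = 14,
    confirm_matches: int = 12,
) -> tuple[int, int, int] | None:
    """Maximal inverted match around seed position ``p0`` on anti-diagonal ``C``.

    Position p (one copy) pairs with q = (C - p) mod n (the other copy); a
    pair matches when the bases are reverse-complementary.  Returns
    (p_lo, p_hi inclusive, mismatches) in an unwrapped frame around p0, or
    None if the seed position itself does not match.  A patch of up to
    ``max_patch`` consecutive mismatches is crossed only when at least
    ``confirm_matches`` of the following ``confirm_window`` pairs match, so
    extension does not creep into single-copy sequence.
    """
    n = len(codes)

    def match(p: int) -> bool:
        q = (C - p) % n
        a, b = codes[p % n], codes[q]
        return bool(a < 4 and b < 4 and a == 3 - b)

    if not match(p0):
        return None

    def closed(p: int, step: int) -> bool:
        # the two paired positions meet on the circle: stop before they cross
        q = (C - p) % n
        gap = ((q - p) if step > 0 else (p - q)) % n
        return gap <= 1

    def grow(start: int, step: int) -> tuple[int, int]:
        p, mism = start, 0
        steps = 0
        while steps < n:
            steps += 1
            nxt = p + step
            if closed(nxt, step):
                break
            if match(nxt):
                p = nxt
                continue
            patch = 1
            while patch < max_patch and not match(p + step * (patch + 1)):
                patch += 1
            after = p + step * (patch + 1)
            if not match(after) or closed(after, step):
                break
            good = sum(match(after + step * i) for i in range(confirm_window))
            if good < confirm_matches:
                break
            p = after
            mism += patch
        return p, mism

    hi, m1 = grow(p0, +1)
    lo, m2 = grow(p0, -1)
    return lo, hi, m1 + m2


def detect_quadripartite(
    genome: AnnotatedGenome,
    min_ir_len: int = 1000,
    mismatch_tol: float = 0.005,
    seed_k: int = 25,
    seed_stride: int = 8,
) -> QuadripartiteStructure:
    """Detect the LSC/IRb/SSC/IRa layout of a circular plastome.

    The longest pair of disjoint reverse-complementary segments of at least
    ``min_ir_len`` defines the IRs; the larger single-copy gap is the LSC.
    Intervals may extend past the sequence end (``end > n``) when a region
    wraps the origin of a rotated genome; lengths and junctions stay exact.

    Raises :class:`NoIRFound` if no such pair exists and :class:`AmbiguousIR`
    when two distinct equally long candidates remain.
    """
    n = len(genome)
    if n < 4 * min_ir_len:
        raise ValueError(f"genome length {n} < 4*min_ir_len ({4 * min_ir_len})")
    codes = encode(genome.sequence)
    doubled = np.concatenate([codes, codes])

    fwd = _kmer_codes(doubled, seed_k)
    rc_window = _kmer_codes(revcomp_codes(doubled), seed_k)
    rcv = rc_window[::-1]  # rcv[z] = code of revcomp(doubled[z:z+k])

    xs = np.arange(0, len(fwd), seed_stride)
    sub = fwd[xs]
    order = np.argsort(rcv, kind="stable")
    srt = rcv[order]
    lo = np.searchsorted(srt, sub, side="left")
    hi = np.searchsorted(srt, sub, side="right")
    counts = hi - lo
    valid = (counts > 0) & (sub != np.uint64(2**63))
    if not valid.any():
        raise NoIRFound(f"no inverted repeat seed of length {seed_k} found")

    keys: list[int] = []
    seed_ps: list[int] = []
    for xi in np.nonzero(valid)[0]:
        x = int(xs[xi])
        for zi in order[lo[xi] : hi[xi]]:
            C = (x + int(zi) + seed_k - 1) % n
            keys.append(C)
            seed_ps.append(x % n)
    uniq, cnt = np.unique(np.asarray(keys), return_counts=True)
    best_order = np.argsort(cnt)[::-1]

    candidates: dict[tuple[frozenset[int], int], tuple[int, int, int, int]] = {}
    for C in (int(uniq[i]) for i in best_order[:3]):
        ps = sorted(p for kkey, p in zip(keys, seed_ps) if kkey == C)
        ext = _extend_inverted(codes, C, ps[len(ps) // 2])
        if ext is None:
            continue
        p_lo, p_hi, mism = ext
        length = p_hi - p_lo + 1
        if length < min_ir_len or mism > mismatch_tol * length:
            continue
        s1 = p_lo % n
        q_hi = (C - p_lo) % n
        s2 = (q_hi - length + 1) % n
        key = (frozenset((s1, s2)), length)
        candidates[key] = (s1, s2, length, mism)

    if not candidates:
        raise NoIRFound(f"no inverted repeat pair of length >= {min_ir_len}")
    best_len = max(c[2] for c in candidates.values())
    best = [c for c in candidates.values() if c[2] == best_len]
    if len(best) > 1:
        raise AmbiguousIR(f"{len(best)} equally long IR candidates: {best}")
    s1, s2, length, mism = best[0]
    return _assemble_structure(n, s1, s2, length, mism)


def _circular_slice(codes: np.ndarray, start: int, length: int) -> np.ndarray:
    n = len(codes)
    start %= n
    if start + length <= n:
        return codes[start : start + length]
    return np.concatenate([codes[start:], codes[: (start + length) - n]])


def _assemble_structure(
    n: int, s1: int, s2: int, length: int, mism: int
) -> QuadripartiteStructure:
    """Order the two IR copies and the two single-copy gaps on the circle."""
    # work in a frame where the first copy starts at 0
    delta = min(s1, s2)
    b = (max(s1, s2) - delta) % n
    gap_mid = b - length
    gap_wrap = n - (b + length)
    if gap_mid < 0 or gap_wrap < 0:
        raise NoIRFound("detected IR copies overlap; no quadripartite layout")
    first = (0, length)
    second = (b, b + length)
    if gap_mid >= gap_wrap:
        # circle order: first(IRa) | LSC | second(IRb) | SSC(wrap) | ...
        lsc = (first[1], second[0])
        irb, ira = second, first
        ssc = (second[1], second[1] + gap_wrap)
    else:
        # circle order: LSC(wrap) | first(IRb) | SSC | second(IRa) | ...
        lsc = (second[1], second[1] + gap_wrap)
        irb, ira = first, second
        ssc = (first[1], second[0])

    def shift(iv: Interval) -> Interval:
        s = (iv[0] + delta) % n
        return (s, s + (iv[1] - iv[0]))

    return QuadripartiteStructure(
        lsc=shift(lsc), irb=shift(irb), ssc=shift(ssc), ira=shift(ira),
        genome_length=n, mismatches_between_ir_copies=mism,
    )


def rotate_genome(genome: AnnotatedGenome, offset: int) -> AnnotatedGenome:
    """Rotate a circular genome so that old position ``offset`` becomes 0."""
    n = len(genome)
    offset %= n
    seq = genome.sequence[offset:] + genome.sequence[:offset]
    feats = []
    for f in genome.features:
        ivs = [((s - offset) % n, ((e - 1 - offset) % n) + 1) for s, e in f.intervals]
        feats.append(Feature(f.gene_name, f.kind, f.strand, ivs, dict(f.qualifiers)))
    return AnnotatedGenome(
        id=genome.id, sequence=seq, features=feats, organism=genome.organism,
        species_label=genome.species_label, is_circular=genome.is_circular,
    )


def brute_force_inverted_repeat(
    sequence: str, min_ir_len: int = 1000
) -> tuple[Interval, Interval] | None:
    """Exhaustive longest exact inverted-pair search (test oracle, <= 20 kb).

    Scans every anti-diagonal of the circular sequence for the longest run of
    exact reverse-complementary position pairs.
    """
    codes = encode(sequence)
    n = len(codes)
    if n > 20_000:
        raise ValueError("oracle restricted to sequences <= 20 kb")
    comp = np.where(codes < 4, 3 - codes, 9)
    best: tuple[int, int, int] | None = None  # (len, C, p_lo)
    idx = np.arange(n)
    for C in range(2 * n):
        q = (C - idx) % n
        m = (codes == comp[q]) & (codes < 4)
        # only pairs where p < q matter (each pair seen once per orientation)
        m &= idx < q
        if not m.any():
            continue
        # longest run of True
        padded = np.concatenate([[0], m.view(np.int8), [0]])
        diff = np.diff(padded)
        starts = np.nonzero(diff == 1)[0]
        ends = np.nonzero(diff == -1)[0]
        if len(starts) == 0:
            continue
        runs = ends - starts
        j = int(np.argmax(runs))
        if runs[j] >= min_ir_len and (best is None or runs[j] > best[0]):
            best = (int(runs[j]), C, int(starts[j]))
    if best is None:
        return None
    length, C, p_lo = best
    copy1 = (p_lo, p_lo + length)
    q_hi = (C - p_lo) % n
    copy2 = ((q_hi - length + 1) % n, (q_hi - length + 1) % n + length)
    return copy1, copy2


# ---------------------------------------------------------------------------
# Junction genes


def junction_genes(
    genome: AnnotatedGenome, structure: QuadripartiteStructure
) -> list[dict[str, object]]:
    """Features straddling any of the four IR/single-copy junctions.

    ``bp_inside_ir``/``bp_inside_sc`` are base counts of the feature's exonic
    intervals on each side of the junction.  A straddling feature that is a
    truncated duplicate of a longer same-named gene is flagged pseudogene-like.
    """
    n = structure.genome_length
    ir_ivs = [structure.irb, structure.ira]
    by_name_max: dict[str, int] = {}
    for f in genome.features:
        by_name_max[f.gene_name] = max(by_name_max.get(f.gene_name, 0), f.length)

    out: list[dict[str, object]] = []
    for jname, jpos in structure.junctions().items():
        for f in genome.features:
            if f.kind in ("spacer", "intron"):
                continue
            s, e = f.span
            if e <= n and not (s < jpos < e):
                # handle origin-wrapping feature for the IRa/LSC junction
                if not (jpos == 0 and e > n):
                    continue
            bp_ir = 0
            for fs, fe in f.intervals:
                for irs, ire in ir_ivs:
                    lo, hi = max(fs, irs), min(fe, ire)
                    if lo < hi:
                        bp_ir += hi - lo
            bp_sc = f.length - bp_ir
            if bp_ir == 0 or bp_sc == 0:
                continue
            pseudo = (
                f.kind == "pseudogene"
                or f.length < by_name_max.get(f.gene_name, f.length)
            )
            out.append(
                {
                    "junction": jname,
                    "gene_name": f.gene_name,
                    "bp_inside_ir": bp_ir,
                    "bp_inside_sc": bp_sc,
                    "pseudogene_like": pseudo,
                }
            )
    return out


# ---------------------------------------------------------------------------
# Composition and inventory


@dataclass
class CompositionStats:
    gc_pct: float
    at_pct: float
    protein_pct: float
    trna_pct: float
    rrna_pct: float
    coding_pct: float
    noncoding_pct: float


def composition_stats(genome: AnnotatedGenome) -> CompositionStats:
    """Base and coding composition as percentages of genome length."""
    n = len(genome)
    if n == 0:
        raise ValueError("zero-length genome")
    codes = encode(genome.sequence)
    acgt = codes < 4
    n_def = int(acgt.sum())
    if n_def == 0:
        raise ValueError("sequence has no unambiguous bases")
    gc = int(((codes == 1) | (codes == 2)).sum())
    gc_pct = 100.0 * gc / n_def
    covered = {k: np.zeros(n, dtype=bool) for k in ("CDS", "tRNA", "rRNA")}
    for f in genome.features:
        if f.kind in covered:
            for s, e in f.intervals:
                covered[f.kind][s : min(e, n)] = True
                if e > n:  # wrapping feature
                    covered[f.kind][0 : e - n] = True
    protein = 100.0 * covered["CDS"].sum() / n
    trna = 100.0 * covered["tRNA"].sum() / n
    rrna = 100.0 * covered["rRNA"].sum() / n
    coding = protein + trna + rrna
    return CompositionStats(
        gc_pct=gc_pct,
        at_pct=100.0 - gc_pct,
        protein_pct=protein,
        trna_pct=trna,
        rrna_pct=rrna,
        coding_pct=coding,
        noncoding_pct=100.0 - coding,
    )


@dataclass
class GeneInventory:
    total_functional: int
    unique_genes: int
    ir_duplicated: int
    unique_by_class: dict[str, int]
    intron_counts: dict[str, int]
    pseudogenes: list[str]
    other: list[str]

    def __post_init__(self) -> None:
        assert self.total_functional == self.unique_genes + self.ir_duplicated
        assert sum(self.unique_by_class.values()) == self.unique_genes


def gene_inventory(
    genome: AnnotatedGenome, structure: QuadripartiteStructure | None = None
) -> GeneInventory:
    """Count unique vs IR-duplicated genes, classes, introns, pseudogenes.

    A gene with one copy in each IR counts once as unique and once as
    duplicated; pseudogenes are listed but excluded from functional counts.
    """
    functional: dict[str, list[Feature]] = {}
    pseudo: list[str] = []
    other: list[str] = []
    for f in genome.features:
        if f.kind in ("CDS", "tRNA", "rRNA"):
            functional.setdefault(f.gene_name, []).append(f)
        elif f.kind == "pseudogene":
            pseudo.append(f.gene_name)
        elif f.kind == "other":
            warnings.warn(f"feature {f.gene_name} of unknown kind counted as other")
            other.append(f.gene_name)

    unique = len(functional)
    duplicated = 0
    by_class = {"protein": 0, "tRNA": 0, "rRNA": 0}
    introns: dict[str, int] = {}
    kind_to_class = {"CDS": "protein", "tRNA": "tRNA", "rRNA": "rRNA"}
    for name, copies in functional.items():
        by_class[kind_to_class[copies[0].kind]] += 1
        duplicated += len(copies) - 1
        n_int = max(c.n_introns for c in copies)
        if n_int:
            introns[name] = n_int
    return GeneInventory(
        total_functional=unique + duplicated,
        unique_genes=unique,
        ir_duplicated=duplicated,
        unique_by_class=by_class,
        intron_counts=introns,
        pseudogenes=sorted(pseudo),
        other=sorted(other),
    )
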