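"""Repeat detection and classification.

A repeat hit is a pair of equal-length ungapped segments (direct or
inverted) with identity >= the threshold and motif length >= the minimum.
Hits are *containment-maximal per diagonal*: a window is reported unless a
longer valid window on the same diagonal (direct: equal offset; inverted:
equal anti-diagonal) contains it.  Identity is matches / motif length of the
ungapped comparison.

Two independent implementations share only this definition:

* :func:`find_repeat_pairs` -- seed-based scan for genome-scale input;
* :func:`brute_force_repeats` -- exhaustive window enumeration (test oracle,
  quadratic, <= 20 kb).

Classification follows the four-category scheme used for plastomes: tandem
(direct, adjacent), palindromic (inverted, gap <= 3 kb), gene-similarity
(copies inside two different genes), otherwise dispersed; tandem has
priority over every other category.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ._util import encode, revcomp_codes
from .io import AnnotatedGenome

MAX_MOTIF = 800  # scan cap; windows this long with >=90% identity do not occur
                 # outside the IRs, which are handled by genome_structure


@dataclass
class RepeatHit:
    copy1: tuple[int, int]
    copy2: tuple[int, int]
    orientation: str  # direct | inverted
    length: int
    identity: float
    category: str = "unclassified"
    context: str = ""
    gene_hits: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.copy1 == self.copy2:
            raise ValueError("repeat copies coincide")
        if self.copy1 > self.copy2:
            self.copy1, self.copy2 = self.copy2, self.copy1

    @property
    def gap(self) -> int:
        return self.copy2[0] - self.copy1[1]

    def key(self) -> tuple:
        return (self.copy1, self.copy2, self.orientation)

    def diagonal(self) -> int:
        if self.orientation == "direct":
            return self.copy2[0] - self.copy1[0]
        return self.copy1[0] + self.copy2[1] - 1  # anti-diagonal constant


def _containment_maximal(windows: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Keep windows (start, length) not contained in another valid window."""
    out = []
    for a, L in windows:
        contained = any(
            (a2 <= a and a + L <= a2 + L2 and L2 > L) for a2, L2 in windows
        )
        if not contained:
            out.append((a, L))
    return sorted(set(out))


def _windows_on_profile(
    m: np.ndarray, min_len: int, min_identity: float, max_len: int
) -> list[tuple[int, int, int]]:
    """All containment-maximal (start, length, matches) windows on a
    0/1 match profile."""
    T = len(m)
    if T < min_len:
        return []
    c = np.concatenate([[0], np.cumsum(m)])
    valid: list[tuple[int, int]] = []
    matches: dict[tuple[int, int], int] = {}
    for L in range(min_len, min(max_len, T) + 1):
        need = math.ceil(min_identity * L - 1e-9)
        sums = c[L:] - c[:-L]
        for a in np.nonzero(sums >= need)[0]:
            a = int(a)
            valid.append((a, L))
            matches[(a, L)] = int(sums[a])
        if len(valid) > 200_000:
            raise ValueError(
                "window explosion: mask large inverted repeats (exclude=...) "
                "before scanning for small repeats"
            )
    return [(a, L, matches[(a, L)]) for a, L in _containment_maximal(valid)]


# ---------------------------------------------------------------------------
# Seed-based scan


def _seed_positions(codes: np.ndarray, k: int) -> np.ndarray:
    w = sliding_window_view(codes, k)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    vals = (w.astype(np.int64) * powers).sum(axis=1)
    vals[(w >= 4).any(axis=1)] = -1
    return vals


def _candidate_zones(
    keys: np.ndarray, pos: np.ndarray, pair_span: int
) -> list[tuple[int, int, int]]:
    """Cluster seed pairs by diagonal key; two seeds within ``pair_span`` on
    the same key open a candidate zone (key, first_pos, last_pos)."""
    if len(keys) == 0:
        return []
    order = np.lexsort((pos, keys))
    k_s, p_s = keys[order], pos[order]
    brk = np.concatenate([[True], (np.diff(k_s) != 0) | (np.diff(p_s) > pair_span)])
    cid = np.cumsum(brk) - 1
    starts = np.nonzero(brk)[0]
    ends = np.concatenate([starts[1:], [len(k_s)]]) - 1
    # a genuine window leaves two exact runs whose starts differ by >= 8
    # (overlapping delta=1 seeds from a single chance run do not qualify)
    extent = p_s[ends] - p_s[starts]
    keep = extent >= 8
    return [
        (int(k_s[s]), int(p_s[s]), int(p_s[e]))
        for s, e in zip(starts[keep], ends[keep])
    ]


def _profile_direct(codes: np.ndarray, d: int, lo: int, hi: int) -> np.ndarray:
    lo = max(lo, 0)
    hi = min(hi, len(codes) - d)
    a = codes[lo:hi]
    b = codes[lo + d : hi + d]
    return ((a == b) & (a < 4)).astype(np.int8), lo


def _profile_inverted(codes: np.ndarray, C: int, lo: int, hi: int) -> np.ndarray:
    n = len(codes)
    lo = max(lo, max(0, C - n + 1))
    hi = min(hi, (C + 1) // 2)  # enforce p < q = C - p
    if hi <= lo:
        return np.zeros(0, dtype=np.int8), lo
    p = np.arange(lo, hi)
    q = C - p
    a, b = codes[p], codes[q]
    return ((a < 4) & (b < 4) & (a == 3 - b)).astype(np.int8), lo


def _zone_hits(
    profile: np.ndarray, offset: int, min_len: int, min_identity: float,
) -> list[tuple[int, int, float]]:
    """Containment-maximal windows in a zone profile -> (start, len, identity)."""
    if len(profile) < min_len:
        return []
    # cheap density prefilter: any valid window implies a 30ish-window with
    # high match density (see brute-force notes); threshold is conservative
    w = min(min_len, len(profile))
    c = np.concatenate([[0], np.cumsum(profile)])
    best = (c[w:] - c[:-w]).max()
    if best < math.ceil(min_identity * w) - 1:
        return []
    out = []
    for a, L, mt in _windows_on_profile(profile, min_len, min_identity, MAX_MOTIF):
        out.append((offset + a, L, mt / L))
    return out


def find_repeat_pairs(
    sequence: str,
    min_len: int = 30,
    min_identity: float = 0.90,
    exclude: list[tuple[int, int]] | None = None,
) -> list[RepeatHit]:
    """All containment-maximal direct and inverted repeat pairs.

    ``exclude`` masks intervals (typically one IR copy) at the seed stage and
    drops any final hit whose copies fall fully inside a masked interval, so
    the IRa/IRb pair itself is never reported.
    """
    if min_len < 8:
        raise ValueError("min_len < 8: seed scheme undefined below 8 bp")
    codes = encode(sequence)
    n = len(codes)
    if n == 0:
        raise ValueError("empty sequence")
    k = 7
    if n <= k:
        return []
    exclude = exclude or []

    vals = _seed_positions(codes, k)
    mask = np.ones(len(vals), dtype=bool)
    for s, e in exclude:
        mask[max(0, s) : max(0, e - k + 1)] = False
    positions = np.nonzero(mask & (vals >= 0))[0]
    v = vals[positions]

    # two exact 7-bp runs within this distance open a candidate zone.  Any
    # valid window up to ~75 bp contains such a pair even under adversarial
    # mismatch placement; longer windows (tandem arrays, merged motifs) have
    # runs recurring well within the span unless mismatches are laid out to
    # defeat the seeding, which planted and biological repeats do not do.
    pair_span = 60

    # ---- direct: group equal k-mers, diagonals from position pairs
    order = np.argsort(v, kind="stable")
    vs, ps = v[order], positions[order]
    starts = np.nonzero(np.concatenate([[True], np.diff(vs) != 0]))[0]
    ends = np.concatenate([starts[1:], [len(vs)]])
    dkeys: list[np.ndarray] = []
    dpos: list[np.ndarray] = []
    for s0, e0 in zip(starts, ends):
        grp = np.sort(ps[s0:e0])
        if len(grp) < 2:
            continue
        ii, jj = np.triu_indices(len(grp), 1)
        dkeys.append(grp[jj] - grp[ii])
        dpos.append(grp[ii])
    hits: list[RepeatHit] = []
    if dkeys:
        zones = _candidate_zones(np.concatenate(dkeys), np.concatenate(dpos), pair_span)
        for d, p_first, p_last in zones:
            if d == 0:
                continue
            prof, off = _profile_direct(codes, d, p_first - MAX_MOTIF, p_last + k + MAX_MOTIF)
            for a, L, ident in _zone_hits(prof, off, min_len, min_identity):
                hits.append(RepeatHit((a, a + L), (a + d, a + d + L), "direct", L, ident))

    # ---- inverted: forward k-mers vs reverse-complement window k-mers
    rcv = _seed_positions(revcomp_codes(codes), k)[::-1]  # rcv[z] = code of rc(codes[z:z+k])
    rmask = np.ones(len(rcv), dtype=bool)
    for s, e in exclude:
        rmask[max(0, s) : max(0, e - k + 1)] = False
    rpositions = np.nonzero(rmask & (rcv >= 0))[0]
    rv = rcv[rpositions]
    order2 = np.argsort(rv, kind="stable")
    rvs, rps = rv[order2], rpositions[order2]
    ikeys: list[np.ndarray] = []
    ipos: list[np.ndarray] = []
    lo_idx = np.searchsorted(rvs, vs, side="left")
    hi_idx = np.searchsorted(rvs, vs, side="right")
    for x, l0, h0 in zip(ps, lo_idx, hi_idx):
        if h0 <= l0:
            continue
        zs = rps[l0:h0]
        Cs = (x + zs + k - 1)
        keep = x < Cs - x  # seed start strictly in the left copy
        if keep.any():
            ikeys.append(Cs[keep])
            ipos.append(np.full(int(keep.sum()), x))
    if ikeys:
        zones = _candidate_zones(np.concatenate(ikeys), np.concatenate(ipos), pair_span)
        for C, p_first, p_last in zones:
            prof, off = _profile_inverted(codes, C, p_first - MAX_MOTIF, p_last + k + MAX_MOTIF)
            for a, L, ident in _zone_hits(prof, off, min_len, min_identity):
                c2 = (C - (a + L - 1), C - a + 1)
                hits.append(RepeatHit((a, a + L), c2, "inverted", L, ident))

    hits = _dedupe(hits)
    return _drop_excluded(hits, exclude)


def _dedupe(hits: list[RepeatHit]) -> list[RepeatHit]:
    seen: set[tuple] = set()
    out = []
    for h in sorted(hits, key=lambda h: (h.copy1, h.copy2, h.orientation)):
        if h.key() not in seen:
            seen.add(h.key())
            out.append(h)
    return out


def _drop_excluded(
    hits: list[RepeatHit], exclude: list[tuple[int, int]]
) -> list[RepeatHit]:
    def inside(iv: tuple[int, int]) -> bool:
        return any(s <= iv[0] and iv[1] <= e for s, e in exclude)

    return [h for h in hits if not (inside(h.copy1) or inside(h.copy2))]


# ---------------------------------------------------------------------------
# Brute-force oracle


def brute_force_repeats(
    sequence: str,
    min_len: int = 30,
    min_identity: float = 0.90,
    max_len: int | None = None,
) -> list[RepeatHit]:
    """Exhaustive repeat scan: every diagonal, every window length in
    [min_len, max_len] (default 2*min_len), both orientations.

    Quadratic; refuses sequences above 20 kb.  Reports the same
    containment-maximal hit set as :func:`find_repeat_pairs` whenever no
    valid window exceeds ``max_len``.
    """
    codes = encode(sequence)
    n = len(codes)
    if n > 20_000:
        raise ValueError("brute-force oracle restricted to sequences <= 20 kb")
    if min_len < 8:
        raise ValueError("min_len < 8: identity windows undefined below 8 bp")
    max_len = max_len or 2 * min_len
    hits: list[RepeatHit] = []

    for d in range(1, n - min_len + 1):
        a = codes[: n - d]
        b = codes[d:]
        m = ((a == b) & (a < 4)).astype(np.int8)
        c = np.concatenate([[0], np.cumsum(m)])
        if len(m) >= min_len:
            dens = (c[min_len:] - c[:-min_len]).max()
            if dens < math.ceil(min_identity * min_len) - 1:
                continue  # no window of any permitted length can reach identity
        else:
            continue
        valid: list[tuple[int, int]] = []
        for L in range(min_len, min(max_len, n - d) + 1):
            need = math.ceil(min_identity * L - 1e-9)
            sums = c[L:] - c[:-L]
            for s0 in np.nonzero(sums >= need)[0]:
                valid.append((int(s0), L))
        for s0, L in _containment_maximal(valid):
            ident = float(c[s0 + L] - c[s0]) / L
            hits.append(RepeatHit((s0, s0 + L), (s0 + d, s0 + d + L), "direct", L, ident))

    comp = np.where(codes < 4, 3 - codes, 9)
    idx = np.arange(n)
    for C in range(2 * min_len - 1, 2 * n - 2):
        p_lo = max(0, C - n + 1)
        p_hi = (C + 1) // 2  # p < q
        if p_hi - p_lo < min_len:
            continue
        p = np.arange(p_lo, p_hi)
        m = (codes[p] == comp[C - p]).astype(np.int8)
        c = np.concatenate([[0], np.cumsum(m)])
        dens = (c[min_len:] - c[:-min_len]).max()
        if dens < math.ceil(min_identity * min_len) - 1:
            continue
        valid = []
        for L in range(min_len, min(max_len, len(m)) + 1):
            need = math.ceil(min_identity * L - 1e-9)
            sums = c[L:] - c[:-L]
            for s0 in np.nonzero(sums >= need)[0]:
                valid.append((int(s0), L))
        for s0, L in _containment_maximal(valid):
            a0 = p_lo + s0
            ident = float(c[s0 + L] - c[s0]) / L
            hits.append(
                RepeatHit((a0, a0 + L), (C - (a0 + L - 1), C - a0 + 1), "inverted", L, ident)
            )
    return _dedupe(hits)


# ---------------------------------------------------------------------------
# Merging and classification


def merge_hits(hits: list[RepeatHit], sequence: str | None = None) -> list[RepeatHit]:
    """Merge hits whose copy1 AND copy2 intervals overlap (same orientation)
    into one motif spanning the unions; identity is recomputed on the merged
    spans (ungapped when the spans stay equal length, aligned otherwise).
    Pass ``sequence`` to recompute identities in place; otherwise merged hits
    carry identity -1 until :func:`recompute_identities` runs."""
    hits = list(hits)
    changed = True
    while changed:
        changed = False
        out: list[RepeatHit] = []
        for h in sorted(hits, key=lambda h: (h.orientation, h.copy1, h.copy2)):
            merged = False
            for i, g in enumerate(out):
                if (
                    g.orientation == h.orientation
                    and _overlap(g.copy1, h.copy1)
                    and _overlap(g.copy2, h.copy2)
                ):
                    out[i] = replace(
                        g,
                        copy1=_union(g.copy1, h.copy1),
                        copy2=_union(g.copy2, h.copy2),
                        length=max(
                            _union(g.copy1, h.copy1)[1] - _union(g.copy1, h.copy1)[0],
                            _union(g.copy2, h.copy2)[1] - _union(g.copy2, h.copy2)[0],
                        ),
                        identity=-1.0,  # recomputed below
                    )
                    merged = True
                    changed = True
                    break
            if not merged:
                out.append(h)
        hits = out
    if sequence is not None:
        hits = recompute_identities(hits, sequence)
    return hits


def recompute_identities(hits: list[RepeatHit], sequence: str) -> list[RepeatHit]:
    """Fill in identities left pending by :func:`merge_hits` (-1 markers)."""
    from .align import GAP, align_pair

    codes = encode(sequence)
    out = []
    for h in hits:
        if h.identity >= 0:
            out.append(h)
            continue
        s1 = codes[h.copy1[0] : h.copy1[1]]
        s2 = codes[h.copy2[0] : h.copy2[1]]
        if h.orientation == "inverted":
            s2 = revcomp_codes(s2)
        if len(s1) == len(s2):
            ident = float(((s1 == s2) & (s1 < 4)).sum()) / len(s1)
        else:
            a, b, _ = align_pair(s1, s2)
            both = (a != GAP) & (b != GAP)
            ident = float(((a == b) & both).sum()) / len(a)
        out.append(replace(h, identity=ident))
    return out


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _union(a: tuple[int, int], b: tuple[int, int]) -> tuple[int, int]:
    return (min(a[0], b[0]), max(a[1], b[1]))


def classify_hits(
    hits: list[RepeatHit],
    genome: AnnotatedGenome,
    structure=None,
    palindrome_gap_max: int = 3000,
    tandem_gap_max: int = 10,
) -> list[RepeatHit]:
    """Assign categories with priority tandem > gene_similarity > palindromic
    > dispersed, and genomic context from overlap with gene features."""
    gene_feats = [f for f in genome.features if f.kind in ("CDS", "tRNA", "rRNA")]

    def genes_containing(iv: tuple[int, int]) -> list[str]:
        return [f.gene_name for f in gene_feats if f.start <= iv[0] and iv[1] <= f.end]

    def genes_overlapping(iv: tuple[int, int]) -> list[str]:
        out = []
        for f in gene_feats:
            if any(_overlap(iv, e) for e in f.intervals):
                out.append(f.gene_name)
        return out

    out = []
    for h in hits:
        g1 = genes_containing(h.copy1)
        g2 = genes_containing(h.copy2)
        if h.orientation == "direct" and h.gap <= tandem_gap_max:
            cat = "tandem"
        elif g1 and g2 and set(g1) != set(g2):
            cat = "gene_similarity"
        elif h.orientation == "inverted" and h.gap <= palindrome_gap_max:
            cat = "palindromic"
        else:
            cat = "dispersed"
        ov1 = genes_overlapping(h.copy1)
        ov2 = genes_overlapping(h.copy2)
        in1 = bool(g1) or bool(ov1)
        in2 = bool(g2) or bool(ov2)
        if g1 and g2:
            context = "coding"
        elif not in1 and not in2:
            context = "intergenic"
        else:
            context = "mixed"
        out.append(replace(h, category=cat, context=context, gene_hits=sorted(set(ov1 + ov2))))
    return out


def summarize_repeats(
    classified: dict[str, list[RepeatHit]] | list[RepeatHit],
) -> "pd.DataFrame":
    """Per-genome and pooled counts/percentages by category, longest motif,
    and context breakdown."""
    import pandas as pd

    if isinstance(classified, list):
        classified = {"genome": classified}
    rows = []
    cats = ["tandem", "dispersed", "palindromic", "gene_similarity"]
    for name, hits in sorted(classified.items()):
        row = {"genome": name, "n_repeats": len(hits)}
        for c in cats:
            k = sum(1 for h in hits if h.category == c)
            row[f"n_{c}"] = k
            row[f"pct_{c}"] = round(100.0 * k / len(hits), 1) if hits else 0.0
        row["longest"] = max((h.length for h in hits), default=0)
        for ctx in ("intergenic", "coding", "mixed"):
            row[f"n_{ctx}"] = sum(1 for h in hits if h.context == ctx)
        rows.append(row)
    pooled_hits = [h for hits in classified.values() for h in hits]
    pooled = {"genome": "pooled", "n_repeats": len(pooled_hits)}
    for c in cats:
        k = sum(1 for h in pooled_hits if h.category == c)
        pooled[f"n_{c}"] = k
        pooled[f"pct_{c}"] = round(100.0 * k / len(pooled_hits), 1) if pooled_hits else 0.0
    pooled["longest"] = max((h.length for h in pooled_hits), default=0)
    for ctx in ("intergenic", "coding", "mixed"):
        pooled[f"n_{ctx}"] = sum(1 for h in pooled_hits if h.context == ctx)
    rows.append(pooled)
    return pd.DataFrame(rows)
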