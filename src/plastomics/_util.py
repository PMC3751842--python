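"""Shared low-level helpers: DNA encoding, reverse complement, interval arithmetic, RNG."""

from __future__ import annotations

import hashlib
from typing import Iterable, Sequence

import numpy as np

# Encoding: A=0, C=1, G=2, T=3, N=4.  Complement of code b (b<4) is 3-b.
BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)
_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate(b"ACGT"):
    _ENC[_c] = _i
    _ENC[_c + 32] = _i  # lowercase

TRANSITIONS = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string into uint8 codes (non-ACGT -> 4 == N)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return BASES[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    out = codes[::-1].copy()
    acgt = out < 4
    out[acgt] = 3 - out[acgt]
    return out


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


def is_transition(a: int, b: int) -> bool:
    return (a, b) in TRANSITIONS


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Derive n independent generators from one integer seed."""
    ss = np.random.SeedSequence(int(seed))
    return [np.random.default_rng(s) for s in ss.spawn(n)]


def rng_from(seed: int, *salt: int) -> np.random.Generator:
    """Deterministic generator keyed by a seed plus integer salt values."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, salt)]))


def intervals_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def interval_contains(outer: tuple[int, int], inner: tuple[int, int]) -> bool:
    return outer[0] <= inner[0] and inner[1] <= outer[1]


def merge_intervals(ivs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    ivs = sorted(ivs)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def total_length(ivs: Sequence[tuple[int, int]]) -> int:
    return sum(e - s for s, e in merge_intervals(ivs))


def stable_hash(text: str) -> str:
    return hashlib.sha256(text.encode("utf-8")).hexdigest()[:16]
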