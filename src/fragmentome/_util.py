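"""Shared small helpers: sequence encoding, GC arithmetic, seeded RNG plumbing."""
from __future__ import annotations

import itertools

import numpy as np

# Base encoding used throughout: A=0, C=1, G=2, T=3, N=4.
# Complement of code b (b < 4) is 3 - b, so reverse-complement is cheap.
BASES = "ACGT"
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

TRINUCLEOTIDES = ["".join(t) for t in itertools.product(BASES, repeat=3)]


def encode_seq(seq: str) -> np.ndarray:
    """Encode an A/C/G/T/N string into uint8 codes."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def decode_seq(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    comp = str.maketrans("ACGTNacgtn", "TGCANtgcan")
    return seq.translate(comp)[::-1]


def gc_cumsum(codes: np.ndarray) -> np.ndarray:
    """Cumulative count of G/C bases; gc(a, b) = cum[b] - cum[a]."""
    is_gc = (codes == 1) | (codes == 2)
    out = np.zeros(len(codes) + 1, dtype=np.int64)
    np.cumsum(is_gc, out=out[1:])
    return out


def motif_codes(codes: np.ndarray, starts: np.ndarray, ends: np.ndarray,
                minus: np.ndarray) -> np.ndarray:
    """5' trinucleotide index (0..63) per fragment; -1 where N or off-edge.

    Plus-strand fragments read the reference at [start, start+3); minus-strand
    fragments read the reverse complement of [end-3, end).
    """
    n = len(starts)
    out = np.full(n, -1, dtype=np.int64)
    length = len(codes)
    plus = ~minus
    ok_p = plus & (starts >= 0) & (starts + 3 <= length)
    if ok_p.any():
        s = starts[ok_p]
        b0, b1, b2 = codes[s], codes[s + 1], codes[s + 2]
        val = b0.astype(np.int64) * 16 + b1 * 4 + b2
        val[(b0 > 3) | (b1 > 3) | (b2 > 3)] = -1
        out[ok_p] = val
    ok_m = minus & (ends - 3 >= 0) & (ends <= length)
    if ok_m.any():
        e = ends[ok_m]
        b0, b1, b2 = codes[e - 1], codes[e - 2], codes[e - 3]
        bad = (b0 > 3) | (b1 > 3) | (b2 > 3)
        val = ((3 - b0).astype(np.int64) * 16 + (3 - b1) * 4 + (3 - b2))
        val[bad] = -1
        out[ok_m] = val
    return out


def as_rng(seed) -> np.random.Generator:
    """Accept an int seed or an existing Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive n independent child seeds (< 2**31) from one integer seed."""
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]
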