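"""Low-level nucleotide utilities: complementation, 2-bit k-mer encoding, hashing."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}

_MASK64 = (1 << 64) - 1


def revcomp(seq: str) -> str:
    """Reverse complement of ``seq`` (non-ACGT characters map to themselves or N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode_kmers(seq: str, k: int) -> list[int | None]:
    """2-bit encode every k-mer of ``seq`` with a rolling window.

    Returns one entry per k-mer start (``len(seq) - k + 1`` entries).  A k-mer
    containing any character outside A/C/G/T encodes to ``None``.
    """
    n = len(seq)
    if n < k:
        return []
    mask = (1 << (2 * k)) - 1
    codes: list[int | None] = []
    code = 0
    valid = 0  # number of trailing valid bases accumulated
    get = _BASE_CODE.get
    for i, base in enumerate(seq):
        b = get(base)
        if b is None:
            code = 0
            valid = 0
        else:
            code = ((code << 2) | b) & mask
            valid += 1
        if i >= k - 1:
            codes.append(code if valid >= k else None)
    return codes


def mix64(x: int) -> int:
    """SplitMix64 finaliser: a fast, deterministic 64-bit integer hash."""
    x = (x + 0x9E3779B97F4A7C15) & _MASK64
    x = ((x ^ (x >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    x = ((x ^ (x >> 27)) * 0x94D049BB133111EB) & _MASK64
    return x ^ (x >> 31)
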