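"""Reference k-mer position index and Bloom-filter screen.

The detector works against a short, curated reference sequence (for FLT3-ITD
use, the genomic sequence of *FLT3* exons 14-15; any region of a few hundred
nucleotides works).  Two structures are built over the reference k-mers:

* a hash table mapping every k-mer to **all** of its start positions in the
  reference — repeated k-mers keep every occurrence so that no positional
  information is lost; ambiguity is resolved later, per read;
* a Bloom filter over the same k-mer set, used to screen reads cheaply before
  any exact lookup.  Bloom filters never yield false negatives, so screening
  can only let extra reads through, never drop an on-target read.

Coordinates are 0-based and intervals half-open throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

from .dna import encode_kmers, mix64

_VALID_BASES = frozenset("ACGT")


class BloomFilter:
    """Plain Bloom filter over 2-bit-encoded k-mers.

    Sized from the expected number of items and a target false-positive
    rate; uses double hashing (Kirsch–Mitzenmacher) over a SplitMix64
    finaliser, so membership is deterministic across processes.
    """

    def __init__(self, n_items: int, fp_rate: float = 0.01) -> None:
        if not 0.0 < fp_rate < 1.0:
            raise ValueError(f"false-positive rate must be in (0, 1), got {fp_rate}")
        n_items = max(1, n_items)
        m = math.ceil(-n_items * math.log(fp_rate) / (math.log(2) ** 2))
        self.n_bits = max(8, m)
        self.n_hashes = max(1, round(self.n_bits / n_items * math.log(2)))
        self.fp_rate = fp_rate
        self._bits = np.zeros(self.n_bits, dtype=bool)

    def _indices(self, code: int) -> list[int]:
        h1 = mix64(code)
        h2 = mix64(code ^ 0x9E3779B97F4A7C15) | 1
        m = self.n_bits
        return [(h1 + i * h2) % m for i in range(self.n_hashes)]

    def add(self, code: int) -> None:
        self._bits[self._indices(code)] = True

    def __contains__(self, code: int) -> bool:
        bits = self._bits
        return all(bits[i] for i in self._indices(code))


@dataclass
class ReferenceIndex:
    """Position index over the k-mers of a reference sequence.

    ``positions`` maps each k-mer string to the sorted list of its 0-based
    start positions; ``bloom`` holds the same k-mer set for screening.
    """

    reference: str
    k: int
    positions: dict[str, list[int]]
    bloom: BloomFilter
    # 2-bit-code view of ``positions``; hot path for per-read trace building
    code_positions: dict[int, tuple[int, ...]] = field(repr=False, default_factory=dict)

    def __len__(self) -> int:
        return len(self.reference)


def build_index(reference: str, k: int = 12, bloom_fp_rate: float = 0.01) -> ReferenceIndex:
    """Index all k-mers of ``reference`` with their start positions.

    The reference is uppercased on ingest.  Any character outside A/C/G/T is
    a fatal error (a gapped index would silently degrade detection), as is a
    reference shorter than ``k``.
    """
    if k < 1:
        raise ValueError(f"k must be positive, got {k}")
    reference = reference.upper()
    if len(reference) < k:
        raise ValueError(
            f"reference ({len(reference)} nt) is shorter than k ({k})"
        )
    for pos, base in enumerate(reference):
        if base not in _VALID_BASES:
            raise ValueError(
                f"invalid character {base!r} at reference position {pos}; "
                "the reference must contain only A/C/G/T"
            )

    positions: dict[str, list[int]] = {}
    for p in range(len(reference) - k + 1):
        positions.setdefault(reference[p : p + k], []).append(p)

    bloom = BloomFilter(len(positions), bloom_fp_rate)
    codes = encode_kmers(reference, k)
    code_positions: dict[int, list[int]] = {}
    for p, code in enumerate(codes):
        assert code is not None  # reference is all-ACGT by construction
        code_positions.setdefault(code, []).append(p)
        bloom.add(code)

    return ReferenceIndex(
        reference=reference,
        k=k,
        positions=positions,
        bloom=bloom,
        code_positions={c: tuple(ps) for c, ps in code_positions.items()},
    )


def query_positions(index: ReferenceIndex, kmer: str) -> list[int]:
    """Exact list of reference start positions of ``kmer`` (empty if absent).

    Always answered from the hash table, never the Bloom filter: traces
    require exact membership.
    """
    if len(kmer) != index.k:
        raise ValueError(f"query length {len(kmer)} != k ({index.k})")
    return list(index.positions.get(kmer.upper(), []))


def bloom_contains(index: ReferenceIndex, kmer: str) -> bool:
    """Bloom-filter membership of ``kmer``.

    True for every indexed k-mer; may be spuriously true for an absent k-mer
    with probability up to the configured false-positive rate.  A k-mer with
    non-ACGT characters is reported absent.
    """
    if len(kmer) != index.k:
        raise ValueError(f"query length {len(kmer)} != k ({index.k})")
    codes = encode_kmers(kmer.upper(), index.k)
    code = codes[0] if codes else None
    return code is not None and code in index.bloom


def read_reference_fasta(path) -> str:
    """Load the reference from a single-record FASTA file.

    The method targets one short region, so a multi-record FASTA is rejected
    rather than silently concatenated or truncated.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) == 0:
        raise ValueError(f"no FASTA record found in {path}")
    if len(records) > 1:
        raise ValueError(
            f"{path} contains {len(records)} records; the reference must be a "
            "single short sequence (e.g. FLT3 exons 14-15)"
        )
    return str(records[0].seq).upper()
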