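"""Per-read k-mer position traces: screening, disambiguation, substitution repair.

The *trace* of a read R against a reference T is the ordered list, one entry
per k-mer start in R, of the positions where that k-mer occurs in T.  In a
read identical to a reference window the positions simply increase by one;
any difference between read and reference leaves a *break* — a maximal run
of k-mers absent from T.  Traces are the only object the downstream event
caller looks at: no alignment is ever computed.

A trace moves through three states:

raw            one (possibly empty) candidate-position list per k-mer
disambiguated  at most one position per entry (``None`` marks absence)
corrected      isolated substitutions repaired, their breaks erased
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, NamedTuple

from .dna import encode_kmers, revcomp
from .kmer_index import ReferenceIndex

Orientation = Literal["forward", "reverse-complement"]

_ALT_BASES = {b: tuple(c for c in "ACGT" if c != b) for b in "ACGT"}


@dataclass
class Trace:
    """K-mer position trace of one read against the reference."""

    read_id: str
    read_seq: str  # oriented sequence actually traced (may be the revcomp of the input)
    k: int
    entries: list  # raw: list[list[int]]; after disambiguation: list[int | None]
    orientation: Orientation = "forward"
    state: str = "raw"

    def __len__(self) -> int:
        return len(self.entries)


class Break(NamedTuple):
    """Maximal run of absent trace entries, inclusive on both ends."""

    j1: int
    j2: int

    @property
    def size(self) -> int:
        return self.j2 - self.j1 + 1


def _is_absent(entry) -> bool:
    return entry is None or (isinstance(entry, list) and not entry)


def screen_read(
    read_seq: str, index: ReferenceIndex, min_fraction: float = 0.30
) -> tuple[bool, Orientation]:
    """Decide whether a read plausibly comes from the reference region.

    The fraction of the read's k-mers present in the Bloom filter is computed
    for the read as given and for its reverse complement; the read is kept in
    the orientation with the higher fraction when that fraction reaches
    ``min_fraction`` (ties go to forward).  K-mers containing non-ACGT
    characters count as absent.  Screening never raises: a read shorter than
    k is simply discarded.
    """
    k = index.k
    if len(read_seq) < k:
        return False, "forward"
    seq = read_seq.upper()
    bloom = index.bloom

    def fraction(s: str) -> float:
        codes = encode_kmers(s, k)
        hits = sum(1 for c in codes if c is not None and c in bloom)
        return hits / len(codes)

    fwd = fraction(seq)
    rev = fraction(revcomp(seq))
    orientation: Orientation = "forward" if fwd >= rev else "reverse-complement"
    best = max(fwd, rev)
    return best >= min_fraction, orientation


def compute_trace(
    read_seq: str,
    index: ReferenceIndex,
    read_id: str = "",
    orientation: Orientation = "forward",
) -> Trace:
    """Build the raw trace of a (kept, already oriented) read.

    Every entry is the exact hash-table position list of the corresponding
    k-mer; the Bloom filter plays no role here.
    """
    seq = read_seq.upper()
    if orientation == "reverse-complement":
        seq = revcomp(seq)
    codes = encode_kmers(seq, index.k)
    lookup = index.code_positions
    entries: list[list[int]] = [
        list(lookup.get(c, ())) if c is not None else [] for c in codes
    ]
    return Trace(read_id=read_id, read_seq=seq, k=index.k, entries=entries,
                 orientation=orientation, state="raw")


def _neighbour_indices(entries: list, i: int) -> list[int]:
    """Present entries usable as disambiguation context for position ``i``.

    Neighbours are the present entries of the contiguous break-free run
    containing ``i``; when ``i`` sits immediately before or after a break,
    that one break may be crossed and the present run on its far side is
    included as well.
    """
    n = len(entries)
    out: list[int] = []
    for step in (-1, 1):
        j = i + step
        # a break may only be crossed when i sits right next to it
        if 0 <= j < n and _is_absent(entries[j]):
            while 0 <= j < n and _is_absent(entries[j]):
                j += step
        while 0 <= j < n and not _is_absent(entries[j]):
            out.append(j)
            j += step
    return out


def disambiguate(trace: Trace) -> Trace:
    """Resolve every multi-position entry to (at most) one reference position.

    Entries are processed left to right.  Rule 1: when the previous entry is
    resolved and its value + 1 is among the candidates, that candidate wins —
    this lets a consistent diagonal chain through repeats.  Rule 2: otherwise
    the candidate minimising the summed absolute distance to the neighbouring
    positions is chosen (unresolved neighbours contribute their closest
    candidate); ties go to the smallest reference position.
    """
    if trace.state != "raw":
        raise ValueError(f"disambiguate expects a raw trace, got {trace.state!r}")
    entries = trace.entries
    n = len(entries)
    resolved: list[int | None] = [None] * n
    for i, cands in enumerate(entries):
        if not cands:
            continue
        if len(cands) == 1:
            resolved[i] = cands[0]
            continue
        prev = resolved[i - 1] if i > 0 else None
        if prev is not None and prev + 1 in cands:
            resolved[i] = prev + 1
            continue
        neighbours = _neighbour_indices(entries, i)

        def score(c: int) -> int:
            total = 0
            for j in neighbours:
                if j < i:  # already cleaned
                    total += abs(c - resolved[j])
                else:  # still raw: an ambiguous neighbour contributes its closest candidate
                    total += min(abs(c - p) for p in entries[j])
            return total

        resolved[i] = min(cands, key=lambda c: (score(c), c))
    return replace(trace, entries=resolved, state="disambiguated")


def find_breaks(trace: Trace) -> list[Break]:
    """All maximal runs of absent entries, sorted by start; edges included."""
    breaks: list[Break] = []
    start: int | None = None
    for i, entry in enumerate(trace.entries):
        if _is_absent(entry):
            if start is None:
                start = i
        elif start is not None:
            breaks.append(Break(start, i - 1))
            start = None
    if start is not None:
        breaks.append(Break(start, len(trace.entries) - 1))
    return breaks


def _attempt_chain(
    seq: list[str],
    resolved: list[int | None],
    brk: Break,
    index: ReferenceIndex,
) -> tuple[list[tuple[int, str]], list[tuple[int, int]]] | None:
    """Try to repair one break as a run of substituted bases.

    Starting from the left flank, each absent k-mer is required to continue
    the reference diagonal; when it does not, the three alternative bases at
    its last position are tried.  The repair is accepted only if it erases
    the whole break *and* reconnects to the right-flank position (or the
    break touches the read end) — a break caused by a real indel or
    duplication junction fails the reconnection and is left untouched.

    Returns (base rewrites, entry assignments) on success, else None.
    """
    k = index.k
    prev = resolved[brk.j1 - 1]
    assert prev is not None
    positions = index.positions
    rewrites: list[tuple[int, str]] = []
    assignments: list[tuple[int, int]] = []
    pending = dict(rewrites)
    for j in range(brk.j1, brk.j2 + 1):
        target = prev + 1
        kmer = "".join(
            pending.get(p, seq[p]) for p in range(j, j + k)
        )
        if target in positions.get(kmer, ()):  # repaired by an earlier rewrite
            assignments.append((j, target))
            prev = target
            continue
        last = kmer[-1]
        for alt in _ALT_BASES.get(last, ()):
            if target in positions.get(kmer[:-1] + alt, ()):
                pending[j + k - 1] = alt
                rewrites.append((j + k - 1, alt))
                assignments.append((j, target))
                prev = target
                break
        else:
            return None  # correction did not work: leave the break as is
    # reconnection guard: the repaired diagonal must meet the right flank
    if brk.j2 + 1 < len(resolved):
        right = resolved[brk.j2 + 1]
        if right is None or prev + 1 != right:
            return None
    return rewrites, assignments


def correct_substitutions(trace: Trace, index: ReferenceIndex) -> Trace:
    """Repair breaks caused by isolated substitutions (errors or SNVs).

    Each break whose left flank is resolved is tentatively corrected k-mer by
    k-mer (see :func:`_attempt_chain`); corrections are all-or-nothing per
    break, so genuine indel/duplication breaks are never eaten.  Present
    entries outside breaks are never modified.
    """
    if trace.state == "raw":
        raise ValueError("correct_substitutions expects a disambiguated trace")
    seq = list(trace.read_seq)
    resolved = list(trace.entries)
    for brk in find_breaks(trace):
        if brk.j1 == 0 or resolved[brk.j1 - 1] is None:
            continue
        outcome = _attempt_chain(seq, resolved, brk, index)
        if outcome is None:
            continue
        rewrites, assignments = outcome
        for pos, base in rewrites:
            seq[pos] = base
        for j, p in assignments:
            resolved[j] = p
    return replace(trace, read_seq="".join(seq), entries=resolved, state="corrected")
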