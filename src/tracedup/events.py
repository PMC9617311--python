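"""Calling duplications and other indels from trace breaks.

A tandem duplication leaves a characteristic signature in a trace: the
reference positions climb steadily, hit a break (the k-mers straddling the
junction are novel), and then *go back* to the start of the duplicated
segment.  For a break (j1, j2) with resolved flanks the signature test is

    t[j1-1] + g - 1 > t[j2+1],        g = j2 - j1 + 1

and the event size is

    d = t[j1-1] - t[j2+1] + j2 - j1 + 2.

The formula is exact in the clean case (where j2 - j1 + 2 == k), and stays
exact under junction micro-insertions (break grows by one per inserted
base), junction overlaps (break shrinks), and substitutions within k of the
breakpoint (break and flank shift by equal amounts).  d < 0 is a deletion of
|d| bases; d > 0 without the go-back signature is reported as a plain
insertion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

from .trace import Break, Trace

EventKind = Literal["duplication", "insertion", "deletion"]


@dataclass(frozen=True)
class Event:
    """One called duplication/insertion/deletion supported by one read."""

    kind: EventKind
    size: int  # magnitude in nucleotides (always positive)
    ref_start: int  # duplications: first duplicated base; deletions: first deleted base
    ref_end_exclusive: int
    read_id: str
    left_flank_pos: int
    right_flank_pos: int
    break_span: tuple[int, int]

    @property
    def key(self) -> tuple[EventKind, int, int, int]:
        """Pooling key: kind, length and reference interval."""
        return (self.kind, self.size, self.ref_start, self.ref_end_exclusive)


def _flanks(trace: Trace, brk: Break) -> tuple[Optional[int], Optional[int]]:
    entries = trace.entries
    left = entries[brk.j1 - 1] if brk.j1 > 0 else None
    right = entries[brk.j2 + 1] if brk.j2 + 1 < len(entries) else None
    return left, right


def is_duplication_break(trace: Trace, brk: Break) -> bool:
    """Signature test: do the positions go back across the break?

    False (uncallable, never an exception) when either flank is missing,
    e.g. for a break touching a read edge.
    """
    left, right = _flanks(trace, brk)
    if left is None or right is None:
        return False
    return left + brk.size - 1 > right


def validate_break(trace: Trace, brk: Break, delta: int = 2) -> bool:
    """Require ``delta`` consistent trace positions on each side of the break.

    The flanking runs must continue the reference diagonal:
    t[j1-1-i] + i == t[j1-1] and t[j2+1+i] - i == t[j2+1] for 1 <= i <= delta,
    which is equivalent to calling with (k + delta)-mers.  Breaks too close to
    a read edge to supply the context are rejected (this undetectability at
    edges is what the quantification correction later compensates for).
    """
    if delta < 0:
        raise ValueError(f"delta must be >= 0, got {delta}")
    entries = trace.entries
    n = len(entries)
    left, right = _flanks(trace, brk)
    if left is None or right is None:
        return False
    for i in range(1, delta + 1):
        li = brk.j1 - 1 - i
        if li < 0 or entries[li] is None or entries[li] + i != left:
            return False
        ri = brk.j2 + 1 + i
        if ri >= n or entries[ri] is None or entries[ri] - i != right:
            return False
    return True


def _signed_size(trace: Trace, brk: Break) -> Optional[int]:
    left, right = _flanks(trace, brk)
    if left is None or right is None:
        return None
    return left - right + brk.j2 - brk.j1 + 2


def merge_breaks(breaks: list[Break], trace: Trace, delta: int = 2) -> list[Break]:
    """Merge nearby breaks when they are fragments of one larger event.

    A spurious in-reference k-mer can split one logical break in two.  Two
    breaks separated by fewer than ``delta`` present entries are merged when
    the merged break implies a strictly smaller event than each separate call
    (a separate call that cannot be sized — edge break — never blocks a
    merge).  Applied left to right until a fixpoint.
    """
    breaks = sorted(breaks)
    changed = True
    while changed:
        changed = False
        out: list[Break] = []
        i = 0
        while i < len(breaks):
            cur = breaks[i]
            if i + 1 < len(breaks):
                nxt = breaks[i + 1]
                if nxt.j1 - cur.j2 - 1 < delta:
                    merged = Break(cur.j1, nxt.j2)
                    d_m = _signed_size(trace, merged)
                    d_a = _signed_size(trace, cur)
                    d_b = _signed_size(trace, nxt)
                    if d_m is not None and all(
                        d is None or abs(d) > abs(d_m) for d in (d_a, d_b)
                    ):
                        out.append(merged)
                        i += 2
                        changed = True
                        continue
            out.append(cur)
            i += 1
        breaks = out
    return breaks


def call_event(trace: Trace, brk: Break, k: int) -> Optional[Event]:
    """Size and classify the event behind a validated break.

    Returns None for a size-0 remnant (e.g. an uncorrected substitution) or
    when a flank is missing.  For duplications the duplicated reference
    interval is [t[j2+1], t[j1-1] + k), so the duplicated sequence itself is
    recoverable from the reference.
    """
    left, right = _flanks(trace, brk)
    if left is None or right is None:
        return None
    d = left - right + brk.j2 - brk.j1 + 2
    if d == 0:
        return None
    if is_duplication_break(trace, brk):
        kind: EventKind = "duplication"
    else:
        kind = "insertion" if d > 0 else "deletion"
    if kind == "deletion":
        ref_start, ref_end = left + k, right
    else:
        ref_start, ref_end = right, left + k
    return Event(
        kind=kind,
        size=abs(d),
        ref_start=ref_start,
        ref_end_exclusive=ref_end,
        read_id=trace.read_id,
        left_flank_pos=left,
        right_flank_pos=right,
        break_span=(brk.j1, brk.j2),
    )


def call_events_from_trace(trace: Trace, delta: int, k: int) -> list[Event]:
    """Breaks -> merge -> validate -> call, on an already-cleaned trace."""
    from .trace import find_breaks

    breaks = merge_breaks(find_breaks(trace), trace, delta)
    events = []
    for brk in breaks:
        if not validate_break(trace, brk, delta):
            continue
        event = call_event(trace, brk, k)
        if event is not None:
            events.append(event)
    return events
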