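"""Pooling, coverage accounting and relative abundance (VAF / allelic ratio).

Identical events — same kind, same length, same reference interval — are
pooled across reads into an :class:`EventGroup`.  The raw supporting-read
count q under-estimates abundance because an event lying too close to a read
end cannot be detected: calling needs the break plus delta consistent
positions on each side, i.e. t = 2*delta + b + k - 1 nucleotides of context
in the read (b = break size).  Assuming events fall uniformly within reads,
the corrected count is

    q' = q * (1 + 2*(t - 1) / R)

with R the (mean) read length.  Reference coverage is counted per trace
entry: when an entry resolves to reference position j, coverage at j gains
one.  Wildtype coverage removes the contributions of every read assigned to
a called event; VAF and AR then compare q' to the wildtype coverage at the
event's first reference base.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .events import Event
from .trace import Trace

logger = logging.getLogger(__name__)

# Correction factor ceiling: once 2*(t-1) >= R the uniform-position model has
# broken down (the event barely fits in a read), so the factor is capped.
MAX_CORRECTION_FACTOR = 3.0

GroupKey = tuple[str, int, int, int]


@dataclass
class CoverageProfile:
    """Total and per-event-group coverage of the reference, one bin per position."""

    total: np.ndarray
    event: dict[GroupKey, np.ndarray] = field(default_factory=dict)

    @property
    def wildtype(self) -> np.ndarray:
        wt = self.total.astype(float)
        for arr in self.event.values():
            wt -= arr
        return wt

    def add_trace(self, trace: Trace, group_keys: tuple[GroupKey, ...] = ()) -> None:
        """Count one read's resolved entries, attributing them to its events.

        A read supporting called events contributes to those groups' coverage
        (split evenly if it supports several) instead of to the wildtype.
        """
        positions = [p for p in trace.entries if p is not None]
        if not positions:
            return
        np.add.at(self.total, positions, 1)
        if group_keys:
            share = 1.0 / len(group_keys)
            for key in group_keys:
                arr = self.event.setdefault(
                    key, np.zeros(len(self.total), dtype=float)
                )
                np.add.at(arr, positions, share)


@dataclass
class EventGroup:
    """Pooled identical events with corrected abundance estimates."""

    kind: str
    size: int
    ref_start: int
    ref_end_exclusive: int
    q: int  # raw supporting-read count
    b: int  # modal break size among supporting reads
    t: int = 0  # minimum nucleotides of read needed to detect the event
    q_prime: float = 0.0
    wildtype_coverage: float = 0.0
    vaf: float = 0.0
    ar: float = 0.0
    sequence: str = ""
    read_ids: list[str] = field(default_factory=list)

    @property
    def key(self) -> GroupKey:
        return (self.kind, self.size, self.ref_start, self.ref_end_exclusive)


def accumulate_coverage(
    traced_reads: list[tuple[Trace, list[Event]]], reference_length: int
) -> CoverageProfile:
    """Coverage profile over all kept reads (events attributed per read)."""
    profile = CoverageProfile(total=np.zeros(reference_length, dtype=np.int64))
    for trace, events in traced_reads:
        keys = tuple(dict.fromkeys(e.key for e in events))
        profile.add_trace(trace, keys)
    return profile


def min_detectable_span(b: int, delta: int, k: int) -> int:
    """Nucleotides of read needed to detect an event with break size ``b``."""
    if b < 1:
        raise ValueError(f"break size must be >= 1, got {b}")
    return 2 * delta + b + k - 1


def corrected_count(q: int, t: int, read_length: float) -> float:
    """Edge-undetectability correction q' = q * (1 + 2*(t-1)/R)."""
    if read_length <= 0:
        raise ValueError(f"read length must be positive, got {read_length}")
    factor = 1.0 + 2.0 * (t - 1) / read_length
    if factor > MAX_CORRECTION_FACTOR:
        logger.warning(
            "event span t=%d close to read length R=%.1f: correction factor "
            "%.2f capped at %.1f; the abundance of near-read-length events "
            "is unreliable", t, read_length, factor, MAX_CORRECTION_FACTOR,
        )
        factor = MAX_CORRECTION_FACTOR
    return q * factor


def pool_events(
    traced_reads: list[tuple[Trace, list[Event]]], reference: str
) -> list[EventGroup]:
    """Group identical events (kind, length, reference interval) across reads."""
    by_key: dict[GroupKey, list[Event]] = {}
    for _, events in traced_reads:
        for event in events:
            by_key.setdefault(event.key, []).append(event)
    groups = []
    for (kind, size, start, end), events in by_key.items():
        break_sizes = Counter(e.break_span[1] - e.break_span[0] + 1 for e in events)
        # modal break size, smallest on ties, for the detectability span
        b = min(
            (bs for bs, c in break_sizes.items() if c == max(break_sizes.values()))
        )
        seq = reference[start:end] if kind != "insertion" and start <= end else ""
        groups.append(
            EventGroup(
                kind=kind, size=size, ref_start=start, ref_end_exclusive=end,
                q=len(events), b=b, sequence=seq,
                read_ids=[e.read_id for e in events],
            )
        )
    return groups


def compute_group_metrics(
    group: EventGroup,
    coverage: CoverageProfile,
    delta: int,
    k: int,
    mean_read_length: float,
) -> EventGroup:
    """Fill in t, q', wildtype coverage, VAF and AR for one pooled group.

    Wildtype coverage is evaluated at the event's first reference base
    (``ref_start``).  With no wildtype coverage at all, VAF is 1 and AR is
    reported as infinity.
    """
    group.t = min_detectable_span(group.b, delta, k)
    group.q_prime = corrected_count(group.q, group.t, mean_read_length)
    wt = coverage.wildtype
    anchor = min(max(group.ref_start, 0), len(wt) - 1)
    group.wildtype_coverage = float(max(wt[anchor], 0.0))
    denom = group.q_prime + group.wildtype_coverage
    group.vaf = group.q_prime / denom if denom > 0 else 0.0
    group.ar = (
        group.q_prime / group.wildtype_coverage
        if group.wildtype_coverage > 0
        else math.inf
    )
    return group


def report(
    groups: list[EventGroup],
    reporting_threshold: float = 0.01,
    keep_deletions: bool = False,
) -> tuple[list[EventGroup], list[EventGroup]]:
    """(summary, full) views of the pooled groups, sorted by descending VAF.

    The summary applies the reporting threshold on VAF and, by default,
    drops deletions (short spurious deletions are a known error mode and are
    still present in the full view).  Ties sort by reference interval for
    deterministic output.
    """
    ordered = sorted(
        groups, key=lambda g: (-g.vaf, g.ref_start, g.ref_end_exclusive, g.size)
    )
    summary = [
        g
        for g in ordered
        if g.vaf >= reporting_threshold and (keep_deletions or g.kind != "deletion")
    ]
    return summary, ordered
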