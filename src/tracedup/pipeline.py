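"""End-to-end detection pipeline: FASTQ stream -> screened traces -> pooled events.

Reads are streamed one by one; only kept reads (their traces and events) are
retained in memory, so the footprint is governed by on-target coverage, not
by the size of the input files.  Paired-end files are simply processed as
independent read streams.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

from .events import Event, call_events_from_trace
from .kmer_index import ReferenceIndex, build_index
from .quantify import (
    CoverageProfile,
    EventGroup,
    accumulate_coverage,
    compute_group_metrics,
    pool_events,
    report,
)
from .trace import Trace, compute_trace, correct_substitutions, disambiguate, screen_read

logger = logging.getLogger(__name__)


@dataclass
class RunParameters:
    """User-facing knobs of one detection run."""

    k: int = 12
    delta: int = 2
    min_kmer_fraction: float = 0.30
    bloom_fp_rate: float = 0.01
    reporting_threshold: float = 0.01
    keep_deletions: bool = False

    def validate(self) -> None:
        if self.k < 4:
            raise ValueError(f"k must be >= 4, got {self.k}")
        if self.delta < 0:
            raise ValueError(f"delta must be >= 0, got {self.delta}")
        for name in ("min_kmer_fraction", "bloom_fp_rate", "reporting_threshold"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")


@dataclass
class DetectionResult:
    """Everything a run produced: pooled groups, coverage, and run statistics."""

    summary: list[EventGroup]
    groups: list[EventGroup]
    coverage: CoverageProfile
    n_reads_seen: int = 0
    n_reads_kept: int = 0
    mean_read_length: float = 0.0
    traced_reads: list[tuple[Trace, list[Event]]] = field(repr=False, default_factory=list)


def process_read(
    read_id: str, sequence: str, index: ReferenceIndex, params: RunParameters
) -> Optional[tuple[Trace, list[Event]]]:
    """Run one read through screen -> trace -> clean -> call.

    Returns None for reads screened out; otherwise the corrected trace and
    the (possibly empty) list of events it supports.
    """
    keep, orientation = screen_read(sequence, index, params.min_kmer_fraction)
    if not keep:
        return None
    trace = compute_trace(sequence, index, read_id=read_id, orientation=orientation)
    trace = disambiguate(trace)
    trace = correct_substitutions(trace, index)
    events = call_events_from_trace(trace, params.delta, params.k)
    return trace, events


def detect(
    reads: Iterable[tuple[str, str]],
    index: ReferenceIndex,
    params: RunParameters | None = None,
) -> DetectionResult:
    """Detect and quantify duplications/indels over a stream of (id, sequence)."""
    params = params or RunParameters()
    params.validate()
    traced: list[tuple[Trace, list[Event]]] = []
    n_seen = 0
    total_kept_length = 0
    for read_id, sequence in reads:
        n_seen += 1
        outcome = process_read(read_id, sequence, index, params)
        if outcome is None:
            continue
        total_kept_length += len(sequence)
        traced.append(outcome)

    mean_length = total_kept_length / len(traced) if traced else 0.0
    coverage = accumulate_coverage(traced, len(index.reference))
    groups = pool_events(traced, index.reference)
    for group in groups:
        compute_group_metrics(group, coverage, params.delta, params.k, mean_length)
    summary, ordered = report(
        groups, params.reporting_threshold, params.keep_deletions
    )
    logger.info(
        "processed %d reads, kept %d; %d event group(s), %d above threshold",
        n_seen, len(traced), len(ordered), len(summary),
    )
    return DetectionResult(
        summary=summary,
        groups=ordered,
        coverage=coverage,
        n_reads_seen=n_seen,
        n_reads_kept=len(traced),
        mean_read_length=mean_length,
        traced_reads=traced,
    )


def detect_in_files(
    reference_fasta,
    fastq_paths: list,
    params: RunParameters | None = None,
    permissive: bool = False,
) -> DetectionResult:
    """File-level entry point: single-record FASTA reference + FASTQ read files."""
    from .kmer_index import read_reference_fasta

    params = params or RunParameters()
    params.validate()
    reference = read_reference_fasta(reference_fasta)
    index = build_index(reference, params.k, params.bloom_fp_rate)
    return detect(iter_fastq_files(fastq_paths, permissive=permissive), index, params)


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def iter_fastq_files(
    paths: Iterable, permissive: bool = False
) -> Iterator[tuple[str, str]]:
    """Stream (id, sequence) from FASTQ files, plain or gzipped.

    In strict mode a malformed record aborts the run; with ``permissive`` the
    offending 4-line block is reported and skipped.
    """
    for path in paths:
        with _open_text(path) as fh:
            record_no = 0
            while True:
                header = fh.readline()
                if not header:
                    break
                seq = fh.readline()
                plus = fh.readline()
                qual = fh.readline()
                record_no += 1
                header, seq = header.rstrip("\n"), seq.rstrip("\n")
                plus, qual = plus.rstrip("\n"), qual.rstrip("\n")
                ok = (
                    header.startswith("@")
                    and plus.startswith("+")
                    and len(seq) == len(qual)
                    and len(seq) > 0
                )
                if not ok:
                    message = f"malformed FASTQ record #{record_no} in {path}"
                    if permissive:
                        logger.warning("%s: skipped", message)
                        continue
                    raise ValueError(message)
                yield header[1:].split()[0], seq.upper()
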