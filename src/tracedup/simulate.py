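"""Synthetic read-set generator for tandem-duplication benchmarking.

Produces a random reference, mutant haplotypes carrying tandem duplications
at chosen positions/lengths, and FASTQ read sets mixing mutant and wildtype
molecules at a target VAF.  Read start positions are uniform over each
haplotype (so the edge-undetectability model the quantifier corrects for is
actually exercised), substitution errors are injected i.i.d. per base, and a
configurable fraction of reads is emitted reverse-complemented.  Everything
is deterministic given the seed, and a truth table (read id -> haplotype,
start, injected errors) is produced alongside the reads.

The error model is substitution-only, matching the dominant error mode of
short-read sequencers; qualities are constant because the detector ignores
them.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .dna import revcomp

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class DuplicationSpec:
    """One tandem duplication: reference interval [start, start+length) and target VAF."""

    start: int
    length: int
    vaf: float

    def apply(self, reference: str) -> str:
        """Mutant haplotype: the interval duplicated in tandem."""
        return reference[: self.start + self.length] + reference[self.start :]

    def junction(self) -> int:
        """Mutant-haplotype coordinate of the first base of the second copy."""
        return self.start + self.length


@dataclass
class SimulationConfig:
    reference_length: int = 500
    duplications: list[DuplicationSpec] = field(default_factory=list)
    read_length: int = 120
    n_reads: int = 5000
    error_rate: float = 0.0
    revcomp_fraction: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.reference_length < 50:
            raise ValueError("reference_length must be >= 50")
        if self.read_length < 1 or self.n_reads < 0:
            raise ValueError("read_length and n_reads must be positive")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError(f"error_rate must be in [0, 1), got {self.error_rate}")
        if not 0.0 <= self.revcomp_fraction <= 1.0:
            raise ValueError("revcomp_fraction must be in [0, 1]")
        total_vaf = 0.0
        for spec in self.duplications:
            if not 0.0 <= spec.vaf <= 1.0:
                raise ValueError(f"VAF must be in [0, 1], got {spec.vaf}")
            if spec.length < 1 or spec.start < 0 or (
                spec.start + spec.length > self.reference_length
            ):
                raise ValueError(
                    f"duplication [{spec.start}, {spec.start + spec.length}) outside "
                    f"reference of length {self.reference_length}"
                )
            total_vaf += spec.vaf
        if total_vaf > 1.0:
            raise ValueError(f"duplication VAFs sum to {total_vaf} > 1")
        if self.duplications and self.read_length < 50:
            raise ValueError("read_length too short to span a detection window")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        dups = [DuplicationSpec(**spec) for spec in d.get("duplications", [])]
        rest = {k: v for k, v in d.items() if k != "duplications"}
        return cls(duplications=dups, **rest)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SimulatedRead:
    """One emitted read plus the ground truth needed to reconstruct it."""

    read_id: str
    sequence: str  # as written to FASTQ (post reverse-complement)
    haplotype: str  # "wt" or "dup<i>"
    start: int  # 0-based start on the (forward) haplotype
    substitutions: tuple[tuple[int, str, str], ...]  # (read pos pre-RC, from, to)
    is_revcomp: bool


def generate_reference(length: int, seed: int = 0, rng=None) -> str:
    """Uniform random ACGT sequence, reproducible from the seed."""
    if length < 50:
        raise ValueError("reference length must be >= 50")
    if rng is None:
        rng = np.random.default_rng(seed)
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def generate_reads(
    config: SimulationConfig, reference: str | None = None
) -> tuple[str, list[SimulatedRead]]:
    """Draw the full read set described by ``config``.

    Each read picks a haplotype (mutant i with probability VAF_i, otherwise
    wildtype), a uniform start on that haplotype, then per-base substitution
    errors and an optional reverse-complement flip.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    if reference is None:
        reference = generate_reference(config.reference_length, rng=rng)
    elif len(reference) != config.reference_length:
        raise ValueError("reference length does not match the configuration")

    haplotypes = [("wt", reference)] + [
        (f"dup{i}", spec.apply(reference)) for i, spec in enumerate(config.duplications)
    ]
    probs = np.array(
        [1.0 - sum(s.vaf for s in config.duplications)]
        + [s.vaf for s in config.duplications]
    )
    R = config.read_length
    for name, seq in haplotypes:
        if len(seq) < R:
            raise ValueError(f"haplotype {name} shorter than the read length")

    choices = rng.choice(len(haplotypes), size=config.n_reads, p=probs)
    reads: list[SimulatedRead] = []
    for idx in range(config.n_reads):
        name, hap = haplotypes[choices[idx]]
        start = int(rng.integers(0, len(hap) - R + 1))
        bases = list(hap[start : start + R])
        subs = []
        if config.error_rate > 0:
            hits = np.flatnonzero(rng.random(R) < config.error_rate)
            for pos in hits:
                old = bases[pos]
                new = str(rng.choice([b for b in "ACGT" if b != old]))
                bases[pos] = new
                subs.append((int(pos), old, new))
        seq = "".join(bases)
        flip = bool(rng.random() < config.revcomp_fraction)
        if flip:
            seq = revcomp(seq)
        reads.append(
            SimulatedRead(
                read_id=f"sim_{idx}_{name}",
                sequence=seq,
                haplotype=name,
                start=start,
                substitutions=tuple(subs),
                is_revcomp=flip,
            )
        )
    return reference, reads


def reconstruct_read(read: SimulatedRead, reference: str, config: SimulationConfig) -> str:
    """Rebuild a read's sequence from its truth record (consistency oracle)."""
    if read.haplotype == "wt":
        hap = reference
    else:
        hap = config.duplications[int(read.haplotype[3:])].apply(reference)
    bases = list(hap[read.start : read.start + config.read_length])
    for pos, old, new in read.substitutions:
        assert bases[pos] == old
        bases[pos] = new
    seq = "".join(bases)
    return revcomp(seq) if read.is_revcomp else seq


def write_fasta(reference: str, path, name: str = "synthetic_reference") -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(reference), 70):
            fh.write(reference[i : i + 70] + "\n")


def write_fastq(reads: list[SimulatedRead], path) -> None:
    """4-line FASTQ with constant qualities; gzip when the path ends in .gz."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for read in reads:
            fh.write(
                f"@{read.read_id}\n{read.sequence}\n+\n{'I' * len(read.sequence)}\n"
            )


def write_truth(reads: list[SimulatedRead], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\thaplotype\tstart\tis_revcomp\tsubstitutions\n")
        for read in reads:
            subs = ";".join(f"{p}:{a}>{b}" for p, a, b in read.substitutions)
            fh.write(
                f"{read.read_id}\t{read.haplotype}\t{read.start}\t"
                f"{int(read.is_revcomp)}\t{subs}\n"
            )


def load_config(path) -> SimulationConfig:
    with open(path) as fh:
        return SimulationConfig.from_dict(json.load(fh))
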