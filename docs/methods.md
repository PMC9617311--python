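# Methods

## Model and procedure

`tracedup` detects differences between short reads and a short reference
sequence `T` (a few hundred nucleotides, e.g. the genomic sequence of *FLT3*
exons 14–15) purely from k-mer positions. The pipeline per read is:

1. **Screen.** The fraction of the read's k-mers present in a Bloom filter
   over the reference k-mers is computed for the read and its reverse
   complement; the read is kept, in the better orientation, when that
   fraction reaches `min_kmer_fraction` (default 0.30, ties to forward).
   Because Bloom filters have no false negatives, screening can only admit
   extra reads, never lose on-target ones. K-mers containing non-ACGT
   characters count as absent; reads shorter than k are dropped.
2. **Trace.** Each of the read's k-mers is looked up exactly in a hash table
   mapping reference k-mers to *all* their start positions; entry `t_R[i]`
   is the position list of the k-mer at read offset `i` (empty = absent).
3. **Disambiguate.** Entries with several candidate positions are resolved
   left to right: if the previous entry is resolved and its value + 1 is a
   candidate, it wins (diagonal chaining); otherwise the candidate with the
   smallest summed absolute distance to the neighbouring positions is taken,
   ties to the smallest position. Neighbours are the present entries of the
   break-free run containing `i`, plus — when `i` is directly adjacent to a
   break — the run on the far side of that one break.
4. **Repair substitutions.** For a break `(j1, j2)` with a resolved left
   flank, the k-mer at `j1` must continue the diagonal (`t_R[j1-1] + 1`);
   when it does not, the three alternative bases at its last position are
   tried. Successful steps rewrite the read base and advance through the
   break. The repairs for a break are committed **only** if the chain erases
   the whole break and reconnects to the right flank's diagonal (or the
   break touches the read end). This all-or-nothing rule with a reconnection
   guard is essential: a greedy per-k-mer correction would walk straight
   through a genuine duplication junction — the "corrected" k-mer
   `T[left+1 .. left+k]` always exists one step down the diagonal — and
   erase the event. Substitution breaks reconnect and vanish; indel and
   duplication breaks do not reconnect and are left untouched. Present
   entries outside breaks are never modified, and no attempt is anchored
   from the right flank.
5. **Merge breaks.** A chance in-reference k-mer can split one logical break
   in two. Breaks separated by fewer than `δ` present entries are merged
   when the merged break implies a strictly smaller event magnitude than
   each separately sized fragment (fragments whose size cannot be computed,
   e.g. at a read edge, never block a merge); applied left to right to a
   fixpoint. Genuinely separate small events each imply smaller sizes than
   their merge and therefore stay separate.
6. **Validate and call.** A break is called only when `δ` (default 2)
   entries on each side continue the flank diagonals exactly — equivalent
   to calling with (k+δ)-mers. Size `d = t_R[j1-1] − t_R[j2+1] + j2 − j1 + 2`;
   the go-back signature `t_R[j1-1] + g − 1 > t_R[j2+1]` marks a duplication
   (duplicated interval `[t_R[j2+1], t_R[j1-1]+k)`), `d > 0` without it an
   insertion, `d < 0` a deletion of `|d|` bases; `d = 0` (a pure substitution
   remnant) is not an event. Multiple events per read are all emitted.
7. **Quantify.** Events with identical (kind, size, interval) are pooled.
   Coverage counts one unit at position `p` for every trace entry resolving
   to `p`; reads supporting called events contribute their coverage to their
   event group(s) (split evenly across groups for a multi-event read), the
   remainder is wild-type coverage — so total coverage is conserved exactly.
   The raw count `q` is corrected to `q' = q·(1 + 2(t−1)/R)` with
   `t = 2δ + b + k − 1` (`b` = modal break size of the group, `R` = mean
   kept-read length), then
   `VAF = q'/(q' + wildtype coverage at ref_start)` and `AR = VAF/(1−VAF)`.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `k` | 12 | k-mer length; small enough for a ~600 nt reference to stay specific, large enough that random hits are rare |
| `delta` | 2 | consistent flanking positions required per side; trades sensitivity at read edges against false positives |
| `min_kmer_fraction` | 0.30 | Bloom-screen keep threshold |
| `bloom_fp_rate` | 0.01 | Bloom sizing target; the filter is a few kilobytes for any realistic reference |
| `reporting_threshold` | 0.01 | minimum VAF in the summary view; every group is retained in the full JSON |
| deletion filter | on | short spurious deletions are a known error mode; suppressed in the summary, kept in the JSON |

Coordinates are 0-based half-open everywhere internally and in JSON; the TSV
can be switched to 1-based inclusive.

## Numerical and degenerate-input choices

* Disambiguation tie-breaks take the smallest reference position; output is
  therefore byte-deterministic for identical inputs.
* The Bloom filter hashes 2-bit k-mer codes through a SplitMix64 finaliser
  with double hashing, so membership (and hence screening) is identical
  across processes — Python's salted `hash` would not be.
* `corrected_count` caps the correction factor at 3 (with a warning) once
  `2(t−1) ≥ R`: the uniform-position model is meaningless for events
  comparable to the read length.
* Zero wild-type coverage at the anchor reports VAF 1 and AR = ∞; groups
  with no supporting reads simply do not exist.
* A break at a read edge (missing flank) is never called; a multi-record
  reference FASTA and non-ACGT reference characters are fatal, whereas reads
  are filtered, not rejected.

## The simulator, and what passing tests do not show

`tracedup.simulate` draws uniform random references, builds one mutant
haplotype per configured duplication, assigns each read to mutant `i` with
probability VAF_i (otherwise wild-type), places read starts uniformly on the
haplotype, injects i.i.d. substitution errors, and reverse-complements a
configured fraction. It emulates the aspects of real data the algorithm
depends on — uniform junction placement within reads (which the edge
correction assumes), strand mixture, substitution noise — and deliberately
not: quality-score structure (ignored by the method), indel sequencing
errors, PCR duplicates, paired-end insert geometry, non-uniform coverage of
capture protocols, or homology between the reference and the rest of a
genome. Passing tests therefore demonstrate algorithmic correctness under
the stated model, not performance on any particular library preparation.
Default study conditions used by the test suite: reference 400 nt, reads
120 nt, coverage from ~450× to 2000×, duplication lengths 3–126 nt, VAF
0.2–1.0, error rates 0–1 %.

## Known limitations

* **Edge-correction accounting.** The correction multiplies by
  `1 + 2(t−1)/R`, treating the first and last `t−1` read positions as blind.
  In our uniform-start simulations the measured blind fraction among
  junction-covering reads is ≈ `t/R` (0.21 at t = 26, R = 120), about half
  the modelled `2(t−1)/R` = 0.42 — the `t`-nucleotide context window
  excludes ~`t` junction placements in total, not `t−1` per read end. The
  resulting over-correction of `q'` is partly offset in the VAF by
  undetected mutant reads inflating the wild-type denominator: the reported
  VAF lands within ±0.03 of a true 0.2 in the acceptance simulation. The
  printed formula is kept as the quantification contract; the residual bias
  is visible in `q'` itself, not materially in VAF/AR.
* `min_detectable_span` returns `t = 2δ + b + k − 1`; the implementation's
  literal context requirement is `t + 2` nucleotides (flank + δ entries per
  side). The difference is immaterial at default parameters.
* A tandem duplication's representation is rotation-ambiguous when bases
  match across the junction (`T[s] == T[s+d]`, or on the other side
  `T[s−1] == T[s+d−1]`): the called interval may extend the simulated one by
  the overlap length. The size is still exact, and pooling is unaffected
  because all reads of an event resolve to the same representation.
* With no wild-type molecules at all (true VAF 1), mutant reads that do not
  span the junction are indistinguishable from wild-type, so the reported
  VAF saturates below 1 (≈ 0.73 for a 30 nt duplication in 120 nt reads).
  This is inherent to any junction-counting estimator.
* Duplications longer than roughly `R − t` cannot place a full detection
  window in a read only near the junction; sizes remain exact (the trace
  only needs the junction context) but quantification of near-read-length
  events relies on the capped correction.
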