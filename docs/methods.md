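# Methods

This note documents the models and procedures implemented in `lorete`,
the parameters that matter, the synthetic data the test suite runs on,
and the numerical choices made where the design was genuinely open.

## Detection model

Two frequency regimes of TE insertional variants are handled by two
different signals.

**Global variants.** An insertion frequent enough in the sequenced
population is incorporated into the de novo assembly and appears, when
the assembly is aligned to a reference, as an insertion (or deletion)
operation in the alignment CIGAR. `extract_sv` mines every indel
operation of at least `min_sv_len` (default 50 nt, the conventional
structural-variant floor; the alignment itself comes from an external
whole-genome aligner and is consumed as SAM/BAM). Each variant sequence
is classified by its best local alignment over the TE consensus library;
a call is accepted when the hit covers **more than** 80% of the consensus
at **more than** 80% identity (strict inequalities, matching the
filters' wording in terms of "larger/more than"). Setting both
thresholds to 0 reproduces the unfiltered mode used for wild-type
strains, where every best hit is reported.

**Minor insertional variants (MIVs).** An insertion carried by a small
fraction of individuals never reaches the assembly; it survives only in
the raw reads. Mapping each read back to the sample's own assembly turns
such an insertion into a large CIGAR insertion operation in one or a few
reads. `candidates_from_reads` keeps insertion operations **strictly
longer than** 1000 nt, then merges per-read events on the same contig
that lie within 100 nt of each other and agree in length within a ratio
of 0.8 (the 100-nt window reuses the short-read clustering distance; the
ratio guards against collapsing co-located but distinct variants). The
candidate's sequence is the longest member event; its position the
rounded mean. Validation against the LTR subset of the library accepts a
candidate iff identity > 94%, consensus coverage ≥ 90% ("a minimum of
90%" read as inclusive), and candidate length exceeds the consensus by
at most 18 nt — the largest TSD reported for any LTR element, so a true
full-length insertion plus its duplicated target always fits. Support
down to a single read is deliberate: the TSD check below, not read
count, supplies the specificity.

## TSD detection and error correction

Integration of an LTR element duplicates a k-nt genomic target (k = 4–5
for the families studied here) on both sides of the provirus, so a
single read through a real insertion contains the same k-mer at the end
of its upstream flank and the start of its downstream flank.

*Auto mode.* The TE span within the supporting read is found by local
alignment of the family consensus (anchored to the read's own insertion
event, so other copies of the family elsewhere in the read cannot
capture the search); the 30-nt flanks on each side are extracted, and a
duplication is called when some k-mer ending within the last `jitter`
(default 5) positions of the upstream flank equals a k-mer starting
within the first `jitter` positions of the downstream flank. Exact
k-mer equality rather than fuzzy matching keeps false positives down;
the jitter absorbs breakpoint imprecision from the alignment. Among
multiple matches the junction-proximal one wins (smallest offset sum,
then the most balanced pair).

*Corrected mode.* Single-molecule errors in either copy of the target
defeat exact matching. The empty genomic target, present in the
assembly, supplies the repair template: each read flank is placed on the
empty locus around the nominal insertion point by minimum-edit-distance
infix alignment. At a bona fide junction the upstream flank ends at the
breakpoint j and the downstream flank starts at j − k, i.e. the two
genomic windows overlap by exactly the duplicated k-mer. Every junction
proposed by either flank's placements is therefore scored by the sum of
both flanks' *junction-anchored* distances (prefix-anchored semi-global
alignment, so only the junction-side boundary is constrained); a
junction is valid when each anchored distance is at most
min(free distance + 1, `max_flank_dist`), and the best-scoring junction
closest to the call position wins. `max_flank_dist` (default
flank/4 + 1 = 8) is the strictness knob: genuine 30-nt flanks read at 5%
error sit at distance ≤ 5 from the locus while random flanks sit at ≥ 9,
so the default cleanly separates the two; flanks that do not correspond
to the empty site never yield a TSD, and the correction cannot invent a
junction the read does not support. The reported TSD is the genomic
k-mer ending at the junction; the TSM is that k-mer with 1 nt of genomic
context on each side (k+2 nt, giving the 6-nt motif for a 4-nt target).
TSD sets are summarized as position frequency matrices with WebLogo-style
per-column information content, 2 + Σ_b f_b log2 f_b bits.

## Short-read discordant-pair calling

A discordant pair maps one mate to the genome and the other to a TE
consensus with no concordant genomic placement. Genome-side positions
are clustered per (contig, family) by single linkage with an inclusive
100-bp gap ("no read further apart than 100 bp"); the cluster position
is the rounded mean of member positions and its strength the member
count, thresholded at ≥ 50 reads by default. Clusters are family-aware
because the downstream per-family counts are; left- and right-side
support is recorded but not required to pair up.

## Kimura 2-parameter divergence

For an aligned copy/consensus pair, P and Q are the fractions of
compared columns (both characters in {A,C,G,T}; gap and N columns
excluded from the denominator) showing transition (A↔G, C↔T) and
transversion differences. The distance is
d = −½ ln((1 − 2P − Q)·√(1 − 2Q)), defined when both logarithm
arguments are positive; saturated copies are excluded from the family
average and counted. Copies are compared to their family consensus by
default (pairwise copy-vs-copy is available through the same
primitives); unaligned copies are first aligned end-to-end at minimum
edit distance.

## The trap-model test

With n insertions, piRNA clusters covering a fraction p of the genome
(intervals merged before measuring), and k insertions inside clusters
(half-open intervals, insertion point = one coordinate), the one-tailed
p-value is P(X ≥ k) for X ~ Binomial(n, p), computed exactly. The
minimal significant count is the smallest k with P(X ≥ k) < α (strict,
α = 0.05 by default) — under this rule the minimal
count for n = 93, p = 0.0736 is 12. n + 1 is returned when no count up
to n rejects.

## Synthetic data

`simdata` emulates the study conditions end to end:

- `random_genome(length, gc=0.42)` — i.i.d. bases at Drosophila-like GC.
- `implant_insertions` — at each site the k-nt target is duplicated so
  the final locus is [target][TE][target]; the extra sequence relative
  to the empty haplotype is TE + one target copy, which is exactly what
  an aligner reports as the insertion. Fixed insertions (frequency 1)
  modify the assembly-like genome; minor insertions are recorded in
  truth only and applied at read level.
- `long_reads` — uniform starts, gamma(shape 2) lengths (default mean
  9 kb, in the range of the sequenced libraries' read-length scale),
  errors applied per base from an `ErrorProfile` (default split of a
  total rate: 40% substitutions, 30% insertions, 30% deletions,
  ONT-like). Reads are emitted with their *true* alignments as SAM, so
  the detectors consume the same record format an external mapper would
  produce. A minor insertion of frequency 1/k is carried by every k-th
  molecule that fully spans its site (with 200 nt of flanking genome) —
  the designated fraction exactly, as systematic sampling of the
  molecule population. Molecules only partially overlapping a minor site
  are drawn from the empty haplotype; partial-overlap (soft-clip)
  signatures are not modeled, matching the detector's scope.
- `paired_reads` — fragments at normal(350, 30) insert size; each mate
  is classified against the inserted segments (genome / TE / junction),
  giving the truth a perfect short-read mapper would recover.

What the generator does **not** emulate: context-dependent (homopolymer)
error profiles, chimeric reads, nested or truncated TE copies, and
reference/assembly misassembly. Passing tests therefore demonstrate the
correctness of the detection logic under the stated error model, not
robustness to every artifact of real libraries.

## Scaled-down study conditions

The default synthetic study (used by the test suite and
`scripts/acceptance.py`) is a 100-kb single-contig genome carrying
5 fixed and 3 minor (10% frequency) LTR insertions with 4-nt TSDs,
sequenced at 30× with mean 9-kb reads, once error-free and once at 5%
total error; the synthetic library holds three LTR families of 1.5–2.1 kb
plus a LINE and a DNA family for classification contrast. These sizes
keep a full run in seconds while leaving every detection step
non-trivial (multi-family classification, multi-read merging, carrier
fractions well below assembly frequency). The Kimura recovery simulation
uses 200 copies of a 2-kb consensus at transition/transversion rates
0.08/0.03.

## Numerical and interface choices

- Identity = matches / aligned columns including gap columns, the
  BLAST-style convention the filter thresholds were defined against.
  Default local scoring: match +2, mismatch −3, gap of length L costs
  5 + 2L (BLASTN-like), configurable.
- Coordinates are 0-based half-open internally; BED/SAM conventions at
  the I/O boundary.
- Local alignment searches both strands; reverse-strand hits are
  reported against forward target coordinates, ties go to the forward
  strand, then the longer target span, then the leftmost target start.
- Best-hit classification ties break by score, then consensus coverage,
  then lexicographic family name.
- Degenerate inputs raise `ValueError` early (empty sequences, empty
  libraries, zero-length genomes, invalid probabilities) rather than
  propagating NaNs.
- All generators take integer seeds and are bit-reproducible; CLI
  reports embed the package version and every effective parameter in a
  `#lorete` header line.

## Known limitations

Split-read/soft-clip insertion signatures, inversions and translocations
are out of scope (a candidate must appear as a single CIGAR insertion);
non-LTR minor variants are not called; deletion-type minor variants are
not screened; the short-read module consumes mappings and does not
re-implement a mapper; graphical logo rendering is left to downstream
tools (the PFM/bits tables are the interface).
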