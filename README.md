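# lorete

**Lo**ng-**re**ad **t**ransposable-**e**lement analysis: detection and
validation of TE insertional variants from Oxford-Nanopore-style long
reads, at two population frequency scales, with companion tools for
short-read insertion calling, repeat-family divergence, and piRNA-cluster
enrichment testing.

## The problem

Transposable elements (TEs) — DNA transposons, LINEs and LTR
retrotransposons — litter eukaryotic genomes with near-identical copies
that defeat short-read mapping. Long reads change the game twice over:
a de novo assembly exposes every insertion that is frequent enough in the
sequenced population to be assembled, and the *individual reads* expose
insertions carried by as little as a single molecule. `lorete` implements
both detection regimes and the validation logic that makes single-read
calls trustworthy:

- **Global variants** — insertions/deletions present in the assembly but
  absent from a reference, mined from the CIGARs of assembly-vs-reference
  alignments and classified against a TE consensus library (best local
  hit covering > 80% of the consensus at > 80% nucleotide identity;
  thresholds configurable down to an unfiltered mode).
- **Minor insertional variants (MIVs)** — low-frequency LTR insertions
  invisible to the assembly, mined as ≥ 1-kb insertion operations from
  individual long reads remapped to their own assembly, merged across
  supporting reads, and validated against the LTR consensus subset:
  identity > 94%, coverage ≥ 90% of the consensus, and a length excess of
  at most 18 nt — the largest target-site duplication reported for any
  LTR element.
- **TSD validation** — LTR integration duplicates a short (4–5 nt)
  genomic target on both sides of the provirus. For each MIV-supporting
  read, `lorete` locates the TE span, extracts the two 30-nt junction
  flanks, and looks for the expected-size duplication (auto mode). Because
  single ONT reads carry several percent of errors, a corrected mode
  aligns both flanks to the *empty genomic target* in the assembly and
  re-tests the junction geometry there — repairing sequencing errors
  without ever manufacturing a duplication the read does not support. The
  duplicated target and its ±1-nt context (the target site motif, TSM)
  feed position-frequency-matrix sequence logos.
- **Short-read TEI calling** — discordant pairs (one mate on the genome,
  one on a TE, no concordant placement) clustered per family so that no
  two reads in a cluster are more than 100 bp apart; a cluster is an
  insertion at the mean of its member positions, kept when supported by
  at least 50 reads.
- **Kimura divergence** — intra-family divergence as the average Kimura
  2-parameter distance, `d = -1/2 ln((1-2P-Q)·sqrt(1-2Q))` with P and Q
  the transition and transversion difference fractions; a proxy for the
  age of a family's most recent transposition wave.
- **Trap-model test** — the hypothesis that piRNA clusters "trap"
  invading TEs predicts enrichment of new insertions inside clusters.
  With n insertions and clusters covering a fraction p of the genome, the
  in-cluster count k is tested one-tailed against Binomial(n, p), and the
  smallest significant count is reported.

A first-class synthetic-data module (`lorete.simdata`) generates random
genomes, implants TE copies with family-specific TSDs at fixed or minor
frequency, and emits ONT-like long reads and paired-end short reads with
exact truth — every pipeline stage is testable without external data.

## Worked example

Simulate a 100-kb study — 5 fixed and 3 minor (10% frequency) LTR
insertions with 4-nt TSDs, 30× error-free long reads — then run both
pipelines:

```sh
$ lorete simulate --out-dir demo --seed 7 --genome-length 100000 \
    --coverage 30 --n-fixed 5 --n-minor 3
wrote simulation to demo

$ lorete global-call --sam demo/assembly_vs_ref.sam --reference demo/reference.fa \
    --library demo/te_library.fa --annot demo/te_library.tsv --out-prefix demo/glob
5 SVs, 5 accepted TE calls

$ lorete miv-call --sam demo/reads_vs_assembly.sam \
    --library demo/te_library.fa --annot demo/te_library.tsv --out-prefix demo/g73
3 candidates, 3 accepted MIVs

$ lorete tsd --reads demo/reads.fastq --assembly demo/assembly.fa \
    --library demo/te_library.fa --annot demo/te_library.tsv \
    --calls demo/g73.miv.tsv --out demo/tsd.tsv
wrote TSD report to demo/tsd.tsv
```

All five fixed insertions come back as accepted global calls and all
three minor insertions as accepted MIVs (here each supported by 2–3
reads; a single read suffices). The TSD report shows, per call, the
detected duplication and motif:

```
contig   position  family   read_id     mode       found  tsd   tsm
chr_sim  31535     simLTR1  read000012  auto       True   ACTA
chr_sim  31535     simLTR1  read000012  corrected  True   ACTA  CACTAT
chr_sim  59697     simLTR2  read000024  auto       True   ATGA
chr_sim  59697     simLTR2  read000024  corrected  True   ATGA  AATGAG
...
```

`found = True` with the 4-nt `tsd` equal to the implanted genomic target
confirms each insertion's integration hallmark; `tsm` is the 6-nt motif
around the target in the empty site. The enrichment test reads BED files:

```sh
$ lorete trap-test --calls demo/g73.miv.bed --clusters clusters.bed \
    --genome demo/assembly.fa --out trap.json
```

and reports n, p, k, the one-tailed p-value and the minimal significant
count. At full study scale — 93 gtwin MIVs against clusters
covering 7.36% of the genome — the minimal count is 12:

```pycon
>>> from lorete.stats import min_significant, binom_tail
>>> min_significant(93, 0.0736, 0.05)
12
>>> binom_tail(274, 0.0736, 18)   # 18/274 observed in clusters: not enriched
0.7244582855864967
```

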