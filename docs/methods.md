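# Methods

## The problem

Metagenomic read sets sample many genomes at very uneven depth. A single
de novo assembly tuned to the community-wide expected coverage discards
the kmers of minority taxa along with sequencing noise, so their reads are
never incorporated and the assembly under-represents exactly the organisms
that are hardest to observe. `spherical` attacks this with read recycling:
after each assembly round, every read that aligns to the new contigs is
retired ("utilised"), and the residue — now dominated by whatever the
round could not assemble — becomes the input of the next round. Because
each residue is smaller and more internally homogeneous than the original
dataset, coverage-adaptive assembler thresholds re-calibrate to the
minority taxa and recover them.

## The iterative engine

One round is: draw a random subsample of the remaining reads (fraction
`-R`, without replacement, size `max(1, round(f·n))`; `-R 1` feeds
everything and consumes no randomness), assemble the subsample, then align
**all** remaining reads — not just the subsample — to the round's contigs.
Subsampling therefore only bounds assembler input; utilisation accounting
is always exact. Rounds stop at whichever comes first:

* the utilisation target (`-align`, default 70%) is reached;
* the iteration cap (`-iter`, default 5) is exhausted;
* no unaligned reads remain;
* a round utilises zero new reads (stall guard — without it, an
  unassemblable residue would loop forever).

A single RNG stream seeded once per run drives all subsampling, so runs
are byte-reproducible. Per-iteration assemblies are concatenated into the
combined assembly (contig ids carry an `it<I>_` prefix; no deduplication);
`-f` additionally re-assembles the combined contigs themselves with the
same k to join ends overlapping by ≥ k−1 (the coverage cutoff is forced
to 1 there, since each contig contributes each kmer once).

Utilisation is defined as 100 × cumulative aligned reads / total input
reads, and the `-align` threshold compares against this quantity. The
alignment rate reported for the combined assembly uses the cumulative
aligned count as numerator.

## Built-in assembler

A minimal canonical-kmer de Bruijn unitig assembler: exact kmer counting
(kmers containing N skipped, k odd so no kmer equals its own reverse
complement), coverage pruning, then maximal non-branching paths. A unitig
extends across an edge only when the tail's out-degree and the head's
in-degree are both exactly 1; there is no bubble popping, tip clipping or
scaffolding, and no greedy extension through branches. This trades
contiguity for the guarantee that contigs are read-supported, which keeps
the false-base-rate and contig-score statistics meaningful. Determinism:
contigs are emitted as the lexicographically smaller of their two
spellings, sorted by (length desc, sequence asc).

Implementation notes:

* kmers are 2-bit packed into uint64 for k ≤ 31 (all counting and
  adjacency fully vectorised); a canonical-string path handles larger k
  (e.g. `-k 41`) at reduced speed.
* Implicit-edge canonical graphs contain self-edges a unitig can never
  traverse — hairpin folds onto a node's own reverse complement (possible
  whenever the (k−1)-suffix is a palindrome) and homopolymer self-loops.
  These are excluded from branching-degree counts; otherwise unitigs would
  fragment at every such node. At k = 31 palindromic suffixes are
  vanishingly rare; at small test k they matter.
* `min_kmer_cov`: integer, or `"auto"` = max(2, weighted-median kmer
  count / 2), the classic half-expected-coverage cutoff used by assemblers
  that estimate expected coverage themselves. Auto is the pipeline
  default: a fixed cutoff cannot follow the falling coverage of successive
  residues, and the coverage-driven loss of minority genomes in round 1 —
  the phenomenon the iteration exists to repair — only occurs under a
  coverage-proportional cutoff. The library-level default for direct
  `assemble()` calls stays at 2 (drop singleton error kmers), which suits
  small clean inputs.
* `min_contig_len` defaults to 2k−1 (≥ k kmers per contig).

External assemblers plug in through a registry: any callable
`(reads, params) -> Assembly` can be registered and driven by the
workflow (exercised in tests with a mock backend). The `velvet`/`abyss`
entries are deliberately unexecuted command templates that fail with an
actionable message.

## Aligner

A seed-and-verify ungapped mapper standing in for a general-purpose
short-read aligner used as a yes/no utilisation oracle. Candidate
placements come from exact canonical seed-kmer lookups (default
`seed_len` 22, both strands; palindromic even-length seeds generate both
orientations); each candidate is verified end-to-end, and the placement
with fewest mismatches wins (ties: contig id, position, '+' before '−').
The mismatch budget defaults to ⌈0.04 × read length⌉ (4 mismatches at
100 bp) — permissive-mapper territory. Gaps, quality scores and
multi-mapping reporting are out of scope; a multi-mapping read contributes
coverage only at its single best hit, which keeps coverage mass conserved
(Σ coverage = Σ aligned read lengths, asserted in tests). Reads shorter
than the seed cannot be anchored and count as unaligned. Coordinates are
0-based half-open internally.

## Metrics

* **N50**: smallest length whose descending running sum reaches half the
  total assembly size (≥ on both comparisons).
* **alignment rate / utilisation**: 100 × aligned / total input reads.
* **false base rate**: percentage of assembly positions with zero read
  coverage after mapping the input back — assembled bases with no
  read-level evidence. For the combined assembly the pileup uses each
  read's hit from the iteration in which it was utilised.
* **contig score** = coverage% / 100 × identity% against the
  best-matching truth genome; 100 = the entire contig precisely matches a
  genome region, 0 = no matching region. The matcher anchors exact
  31-mers on both strands and scores each candidate diagonal by its best
  single ungapped segment under +1/−1 (Kadane), maximising identical
  bases; chained or gapped matches are a documented non-goal, so a contig
  matching in two separated blocks is credited only for the better block.
* `len_sd` is the population (÷n) standard deviation, switchable to
  sample.

## Taxonomic profiles and homogeneity statistics

Contigs are labelled by majority vote of their aligned reads' truth taxa
(ties break lexicographically; unhit contigs are "unclassified") or by a
user-supplied contig → taxon TSV; database-driven annotation is out of
scope. The iteration × taxon read-count table is tested for homogeneity
with Pearson's chi-square (no Yates correction by default); upon
rejection, all pairwise-iteration per-taxon pooled two-proportion Z-tests
run, Benjamini–Hochberg corrected across the entire batch, and iterations
receive compact letters via a greedy clique cover of the non-significance
graph (deterministic in iteration order; same letter ⇔ no significant
pairwise difference). A pooled proportion of exactly 0 or 1 has zero
variance; its Z-test returns p = 1, flagged "degenerate".

## Synthetic communities

The generator emulates an uneven mock community: i.i.d. uniform-random
genomes (so GC ≈ 50% and inter-genome kmer sharing is negligible), a
linear rank gradient of abundances between configurable extremes
(renormalised; a log-uniform alternative is exposed), reads drawn genome
∝ abundance, start uniform, strand uniform, i.i.d. substitutions at the
error rate. Read ids encode the source genome, so truth survives FASTA
round trips. Defaults — the package's standard benchmark — are 20 genomes
of 5–10 kb, extremes in a 0.66% : 0.22% ratio, 200,000 × 100 bp reads,
1% error. At this depth (~130× mean coverage, ~3:1 across ranks) the auto
cutoff of a whole-community assembly lands above the clean-kmer coverage
of the lowest-abundance genomes, which is precisely the regime where
iteration pays; the scale keeps a full three-run comparison within a few
CPU-minutes.

What the simulator does **not** model: indels (the aligner is ungapped by
design), quality-score error profiles, paired ends, strain mixtures,
inter-genome homology, GC bias and coverage waviness of real libraries.
Passing tests therefore demonstrate the correctness of the iteration
logic, accounting and statistics under a clean substitution-only model —
not assembler performance on real metagenomes.

## Numerical and degenerate-input choices

* Subsampling is without replacement; selected reads keep input order.
* An assembler round yielding zero contigs is recorded with zero newly
  aligned reads and triggers the stall guard.
* Empty assemblies have undefined N50/false-base rate (errors); an
  all-zero row or column is dropped before the chi-square test and a
  table left degenerate is an error.
* Duplicate read ids within one input are rejected at parse time.
* Gzip inputs are sniffed by magic bytes; FASTA/FASTQ format by the first
  non-blank character.

## Known limitations

* The unitig-only assembler fragments at every repeat and at residual
  error branches; N50 on noisy data is pessimistic relative to assemblers
  with graph cleaning.
* The reference matcher reports one ungapped segment, so a contig with a
  true gapped alignment to its genome under-scores relative to a gapped
  local aligner.
* Everything is held in memory; very large datasets are served by
  subsampling, not by out-of-core machinery.
* Checkpoint/resume and paired-end awareness are non-goals.
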