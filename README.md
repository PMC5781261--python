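# spherical

Iterative metagenome assembly by unaligned-read recycling.

Metagenomic sequencing samples the genomes of a whole microbial community
at wildly uneven depth, and a single de novo assembly tuned to the
dominant organisms routinely leaves a large fraction of the reads — and
with them the minority taxa — out of the result. `spherical` is a
workflow for people assembling such data: it runs successive rounds of
assembly in which each round's input is the set of reads **not yet
incorporated** into any earlier round's contigs, optionally assembling
only a random subsample per round to bound memory. Reads that align to a
round's contigs are retired; the shrinking residue re-centres every
subsequent round on whatever remains unassembled, so coverage-adaptive
assembler thresholds re-calibrate to the minority organisms and recover
them.

The package is self-contained and testable without downloads: it bundles

* the iterative engine (subsample → assemble → align → assess, with
  stopping rules and merged outputs),
* a deterministic built-in de Bruijn **unitig** assembler behind a
  pluggable backend registry,
* an ungapped seed-and-verify read aligner (the yes/no utilisation
  oracle),
* assembly statistics — N50, alignment rate, false base rate, and the
  reference-based **contig score**,
* per-iteration taxonomic profiles with chi-square homogeneity tests,
  pairwise two-proportion Z-tests and Benjamini–Hochberg correction,
* a truth-labelled synthetic community generator.

## The quantities at the core

For an assembly `A` built from reads `R`:

* **utilisation / alignment rate** = `100 · |aligned(R, A)| / |R|` —
  the stopping criterion and headline metric; a read aligns when it has
  an end-to-end ungapped placement with at most ⌈0.04·L⌉ mismatches.
* **N50** — the contig length at which the descending running sum of
  contig lengths first reaches half of the total assembly size.
* **false base rate** = percentage of assembly positions covered by zero
  reads when `R` is mapped back: assembled bases with no read-level
  evidence.
* **contig score** = `coverage% / 100 × identity%` against the
  best-matching reference genome, from 0 (no matching region) to 100
  (the entire contig precisely matches a genome region).
* **homogeneity**: with `n_it` reads assigned to taxon `t` in iteration
  `i`, Pearson's χ² on the iteration × taxon table asks whether all
  iterations draw from one taxon distribution; pairwise pooled
  two-proportion Z-tests (BH-corrected) locate the shifts.

## Worked example

Simulate a 10-genome community with a linear abundance gradient and 1%
sequencing error, then recycle reads for three rounds:

```bash
spherical simulate --n-genomes 10 --genome-length 4000 6000 \
    --reads 40000 --read-length 100 --error-rate 0.01 --seed 42 \
    --out-reads reads.fastq --out-genomes genomes.fasta --out-truth truth.tsv

spherical run reads.fastq -iter 3 -R 1 -align 100 -k 31 --seed 7 --out-dir out
```

The run log ends with

```
done: 99.0% utilisation after 3 iteration(s), stop=max_iterations
```

and `out/stats.json` contains, per iteration and for the combined
assembly:

```
iteration 1:  40000 candidates ->  80 contigs,  36191 newly aligned, cumulative 90.48%
iteration 2:   3809 candidates ->  44 contigs,   2908 newly aligned, cumulative 97.75%
iteration 3:    901 candidates ->  66 contigs,    487 newly aligned, cumulative 98.97%
combined: n50 = 2639 bp, false base rate = 5.1496 %, alignment rate = 98.965 %
```

Reading this: one pass assembled the abundant genomes and utilised 90.5%
of the reads. The 3,809-read residue — dominated by the rarest genomes —
assembled in round 2 and lifted utilisation to 97.8%; round 3 squeezed
out another 1.2 points. A single-pass "base assembly" of the same data at
the same settings stops at the 90.5% of round 1: the extra ~8.5 points
are reads (and genomic regions) that only read recycling captured.
`out/` also holds per-iteration FASTA, the merged `combined.fasta`, the
unaligned residue FASTQ and a manifest with input digests and the seed.

The same pipeline is available as a library:

```python
from spherical import CommunitySpec, WorkflowConfig, run, simulate_community

truth = simulate_community(CommunitySpec(seed=42))
result = run(truth.reads, WorkflowConfig(max_iterations=3,
                                         align_threshold_pct=100, seed=7))
print(result.utilisation_pct, result.stop_reason)
```

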