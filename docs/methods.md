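# Methods

## Model

A shotgun read pool at depth `d` covers each position of the genome by
`n_reads · read_len / genome_len` reads on average. A k-mer that occurs
once in the genome is observed with expected multiplicity equal to the
*k-mer coverage*

```
c ≈ d · (read_len − k + 1) / read_len
```

(only `read_len − k + 1` of the `read_len` positions of a read start a
full k-mer). A k-mer occurring `m` times genome-wide is observed at
≈ `m·c`. The multiplicity histogram of the pool therefore decomposes
into:

- an **error component** at multiplicity 1–3: a single substitution
  error creates up to k novel k-mers, each seen essentially once;
- a **unique-genome component**, approximately Poisson around `c`;
- a **repeat tail** at multiples of `c`.

Repeat detection reduces to classifying k-mers as right-tail outliers of
the unique component, and repeat reconstruction to assembling those
k-mers.

## Pipeline stages

### Counting (`kmer`)

Canonical counting: each k-mer is identified with the lexicographic
minimum of itself and its reverse complement, so both strands contribute
to one count. K-mers spanning an ambiguous base (`N`) are skipped.
Default k = 31 — long enough that random 31-mer collisions are
negligible in megabase-scale genomes, short enough that a 100-bp read
yields 70 k-mers. Odd k avoids self-reverse-complementary k-mers, which
would make strand counts ambiguous; an even k is accepted with a
warning. Sequences are 2-bit packed into `uint64` and aggregated with
vectorized numpy in 4-Mb chunks, which keeps a 10-Mb pool in the
seconds range.

### Threshold (`threshold`)

From the dense histogram `n(m)`:

1. `v_errmin`: the smallest `m` with `n(m) ≤ n(m+1)` — the boundary
   between the falling error component and the rising unique component.
2. `v_peak`: the argmax of `n(m)` above `v_errmin` — the unique-genome
   mode.
3. Descending flank: bins from `v_peak` down to the first upturn or to
   the first bin below 5% of the peak height (`fit_floor_frac = 0.05`),
   whichever comes first; at least 3 bins are required.
4. Ordinary least squares on `(m, n(m))` over the flank, on the linear
   scale. The x-intercept of the fitted line estimates the upper edge of
   the unique component.
5. `T = ceil(safety_factor · x_intercept)` with `safety_factor = 2` —
   doubling buys insurance against unique k-mers leaking into the
   abundant set at the cost of requiring ≳ 4 genomic copies for reliable
   extraction. K-mers with multiplicity **strictly above** T are
   abundant.

Two numerical details. First, `ceil` is applied after rounding the
product to 1e-6, so an analytically integer product (e.g. 2 × 60.0) is
not bumped up one unit by floating-point residue. Second, shape
detection has a fallback: on flat-topped low-coverage histograms,
Poisson shot noise can produce an upturn one bin after the peak, leaving
a degenerate flank. The plain rule above is always tried first; only
when it fails (no minimum, no peak, < 3 flank bins, non-negative slope)
are steps 1–3 re-run on a 3-bin moving-average smoothed copy of the
histogram. The OLS fit always uses raw bins, and the estimate records
which segment was fitted. When both attempts fail the estimator raises,
and a manual threshold can be supplied (`--manual-t`).

### Assembly (`assembly`)

Abundant 31-mers are decomposed into their 29-mers, which become the
edges of a de Bruijn graph over 28-mer nodes (edge coverage = number of
abundant 31-mers containing the edge). Using an assembly k two below the
counting k tolerates near-boundary losses: a repeat copy whose flanking
context diverges still contributes all internal 29-mers. Unitigs —
maximal paths through nodes with unambiguous continuation (one out-edge
whose target has one in-edge) — are emitted as consensuses in canonical
orientation (lexicographic min of sequence and reverse complement),
sorted by decreasing length, with mean edge coverage recorded. Cycles
(tandem arrays, circular elements) are broken at an arbitrary edge and
emitted once. Consensuses shorter than `min_len = 50` bp are dropped as
uninformative for downstream masking. An optional `clip_tips` pass
removes short low-coverage dead-end branches (sequencing-error spurs)
before unitig extraction.

### Evaluation (`evaluate`, `metrics`)

Consensuses are mapped to a reference by seed-and-extend: exact 16-mer
seeds from an indexed reference, clustered by diagonal (band 20, max gap
200), each cluster extended by infix alignment (edlib) of the
seed-supported query segment ± 30 bp. Extension is local per cluster
rather than forcing the whole consensus through one alignment — a
consensus of a circular element is a rotation of the circle and only
aligns piecewise. Identity = matching columns / query-consuming columns
of the extended CIGAR. Overlapping hits on the same target are merged
(interval union, best identity). A consensus is classified *repetitive*
when it has ≥ 2 hits at ≥ 80% identity; the *masked fraction* is the
base count of the union of qualifying hit intervals divided by reference
length; *family completeness* maps the library onto a family's master
sequence and reports the covered fraction. Library metrics include
N50/N90: the length `L` such that consensuses ≥ `L` contain ≥ 50% / 90%
of total library length.

### Simulator (`simulate`)

The simulator provides ground truth for validation. A uniform-random
background of `unique_len` bases receives planted repeat families: each
family has a random master unit, and each copy is the master with i.i.d.
substitutions at the divergence rate (dispersed copies spliced in at
uniform positions; tandem families as one adjacent block). Insertion
placement means genome length = unique length + planted length and truth
intervals never overlap; planted content is capped at 90% of the
genome. Reads are single-end, uniform over positions and strands, with
i.i.d. substitution errors. A circular contaminant can be spiked in at a
multiple of the host depth, sampled with origin wrap-around; the host
coverage must be passed explicitly since it is not recoverable from the
read stream. All stages draw from `numpy` Generators seeded as
`[seed, stage]`, so genome, reads and spike are independently
reproducible. The simulator deliberately omits indel errors, quality
profiles, GC bias, paired ends and nested/fragmented repeats — the
validation targets are threshold separation and reconstruction, which
substitution-only noise already exercises.

## Parameter defaults

| parameter | default | rationale |
|---|---|---|
| k (counting) | 31 | specificity vs. k-mers per read; odd avoids palindromes |
| k (assembly) | 29 | tolerance to copy-boundary divergence |
| safety factor | 2.0 | unique-leakage insurance; needs ≳ 4 copies to detect |
| fit floor | 5% of peak | keeps the far, noisy tail out of the line fit |
| min consensus | 50 bp | shorter unitigs are uninformative for masking |
| seed length | 16 | exact-match seeding specificity |
| repeat identity | 80% | operational definition of a repetitive alignment |
| min map identity | 50% | discard incidental seed clusters |

## Limitations

- The threshold model assumes a visible unique-genome peak; very low
  coverage (< ~8× k-mer coverage) or extremely repeat-rich genomes leave
  it undefined, and the estimator then refuses rather than guess.
- Doubling the x-intercept means families at 2–3 genomic copies sit
  below T and are invisible by design.
- Unitig assembly stops at branch points, so diverged subfamilies
  fragment into multiple consensuses rather than one family model;
  consensuses are not polished by read realignment.
- The aligner is a light seed-and-extend mapper adequate for
  high-identity consensus placement, not a general-purpose local
  aligner; highly diverged (< ~70% identity) copies can be missed.
- Counting is in-memory; genomes beyond the hundreds-of-megabases scale
  would need an external counter (the per-stage file formats allow
  substituting one).
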