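# Methods

## The problem and the approach

All-vs-all overlap detection is the first and most expensive step of
overlap-layout-consensus assembly of long reads. `overlapnn` treats it as
a nearest-neighbor search problem: each read (in both orientations) is
encoded as a sparse bag-of-k-mers vector, the vectors are linearly
embedded into a low-dimensional space, and each oriented read is linked
to its k most similar neighbors. Because the strongest few overlaps per
read suffice for a *best overlap graph*, the search retrieves a fixed
top-k rather than enumerating all overlapping pairs.

The pipeline is:

1. **Canonical k-mer counting.** Every k-window is folded to the
   lexicographically smaller of itself and its reverse complement, so a
   k-mer's collection frequency (CF) pools both strands. Windows with
   non-ACGT characters are skipped. K-mers with CF below `min_count`
   (default 2) are discarded as sequencing-error noise, and a fraction
   (default 15%) of the survivors is sampled uniformly as the feature
   alphabet.
2. **Feature rows per oriented read.** The alphabet stores canonical
   k-mer strings; a read's `+` row counts literal occurrences of those
   strings in the read as given, its `-` row counts occurrences in the
   reverse complement. Counting canonically but matching literally is
   what makes the two rows differ — canonicalizing read windows would
   make both orientations identical and orientation unrecoverable from
   the neighbor graph.
3. **IDF weighting.** Column j is weighted `idf(j) = ln(|N| / c_j)` with
   `|N|` the number of reads and `c_j` the k-mer's CF. CF stands in for
   the document frequency (DF, reads containing the k-mer), which it
   tracks almost exactly on log scale (see Diagnostics); this lets the
   weights come straight from the count table. High-frequency repeat
   k-mers are down-weighted, which is the main accuracy lever in
   repeat-rich regions. Weighting schemes `binary`, `tf`, `raw_tf`,
   `idf` and `tf_idf` are available for comparison; `idf` is the
   default. Note that under cosine distance `tf` and `raw_tf` (and
   likewise `tf_idf` and a raw-count TF-IDF) are equivalent, since TF
   normalization is a per-row rescaling.
4. **Fused sparse random projection.** The projection R is the
   Achlioptas/Li scheme: i.i.d. entries +s and −s each with probability
   density/2, zero otherwise, s = sqrt(1/(density·d)), default density
   1/sqrt(m). Inner products are preserved in expectation with noise
   O(1/sqrt(d)). Because IDF weighting and projection are both linear,
   they are fused into one reusable matrix diag(w)·R; feature batches
   (default 100,000 reads) are streamed through it, so the full n×m
   feature matrix never exists in memory and the result is independent
   of the batching.
5. **k-NN search.** Either a self-contained brute-force exact search or
   NNDescent (pynndescent). Cosine distance is the default: it ignores
   vector magnitude and hence read-length differences. A query never
   lists itself or its own opposite orientation (the approximate backend
   over-fetches k+2 and filters); ties break toward the smaller row
   index for reproducibility. The neighbor lists become an undirected
   overlap graph over the 2n oriented-read vertices: an edge {u,v}
   exists iff u lists v or v lists u, so with full lists the edge count
   lies in [kn, 2kn].

## Evaluation framework

An overlap graph is scored against a reference graph over the same
vertices. For simulated reads the reference comes from the true source
intervals; for real reads from read-to-reference PAF alignments after
dropping ambiguously aligned reads (length < 5 kb, aligned fraction
< 50%, or MAPQ < 30; one primary alignment per read, best MAPQ then
longest). Two intervals overlapping by at least `min_overlap` (default
1 bp, the most permissive ground truth) produce oriented edges — same
strands link (A+,B+)/(A−,B−), opposite strands link (A+,B−)/(A−,B+).
Intervals are 0-based half-open; touching intervals do not overlap.

Metrics: **error rate** (incorrect edges / all edges), **mean overlap
size** (mean over all edges of the reference size, incorrect edges
counted as zero), **#COC** (per-vertex correct-edge degree; zero makes a
singleton), **#CC** (connected components of the correct-edge subgraph).
Filtered reads keep their vertices but can only contribute incorrect
edges; they are excluded from #CC and from the low-connectivity
denominator so filtered and unfiltered datasets stay comparable, and the
all-vertex variant is reported alongside.

## Synthetic data

The generator emulates a long-read experiment end to end: an
i.i.d.-uniform genome laid out in blocks of `repeat_unit_len` with a
deterministic number of blocks copied from earlier sequence
(`repeat_fraction` of the genome), reads with truncated-normal lengths
(sd 15% of the mean, floor 500 bp), uniform start and strand, and
independent per-base substitution/insertion/deletion errors applied
after extraction. An accuracy budget 1−a is split half substitutions
and a quarter each indel class. The truth table records the error-free
source interval and strand of every read.

Repeats come in two flavors. By default each repeat block copies an
independent random earlier position (single-copy repeats). With
`repeat_families=f` all copies are drawn from only f source segments,
emulating high-multiplicity repeat families (transposable elements,
segmental duplications). The family regime is what makes weighting
schemes separate: the repeat-rich test dataset uses 3 families of ~13
copies each, putting family CF near 0.5·|N| — strongly down-weighted by
IDF (weight ≈ 0.65 vs ≈ 3.2 for single-locus k-mers) yet still positive.

What the generator does **not** model: platform error profiles
(homopolymer compression/expansion, error clustering), diverged repeat
copies (fixture copies are exact), chimeric reads, coverage bias, and
quality scores (constant). Consequences observed in testing: exact-copy
repeats make within-read occurrence counts noiseless, which lets TF-IDF
edge out plain IDF slightly on the fixture (real, diverged repeats favor
plain IDF); and at 95% accuracy the joint k-mer survival of a read pair
caps cosine similarity, so fixture pair distances span only ~[0.6, 1.0].
Passing tests therefore demonstrate the machinery and its contracts, not
platform-specific accuracy on real data.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `k_mer_size` | 13 (ONT preset) | 31 for HiFi, 13 for ONT, 11 for CycloneSEQ; tracks platform error rate (longer k needs higher accuracy). ≤ 31 so a k-mer fits a 64-bit code. |
| `min_count` | 2 | CF filter; removes error singletons at ≥10× depth. |
| `sampling_fraction` | 0.15 | alphabet fraction of surviving k-mers; accuracy vs memory. |
| `dims` | 1000 | embedding dimension; distance fidelity improves as 1/d toward saturation. |
| `density` | 1/sqrt(m) | SRP nonzero fraction; denser buys little (see Diagnostics) and costs memory. |
| `n_neighbors` | 20 | candidates per oriented read; top 6 suffice for best-overlap graphs. |
| `n_trees` | 600 | NNDescent forest size at human scale; tests use far fewer. |
| `batch_size` | 100,000 reads | streaming granularity; no effect on results. |

## Numerical and degenerate-input choices

Natural log for IDF (any base is a per-column rescaling, but one choice
must be fixed and tested). Alphabet sampling sorts survivors
lexicographically before seeded sampling, so alphabets are reproducible
across platforms; the sample size is `max(1, floor(fraction·n))`.
Zero-norm rows (reads shorter than k, or sharing no alphabet k-mer) are
flagged and sit at cosine distance 1 from everything. Fused-vs-sequential
projection agreement is exact up to float64 reassociation (tested at
1e-9 relative). Exact k-NN ties break by smaller row index. Candidate
TSV distances are written with 6 decimals; round-trips agree to 1e-6.
Empty alphabets, zero-edge graphs and single-read inputs raise explicit
stage-named errors rather than returning degenerate values.

## Design points that were genuinely open

* **Filter-then-sample order** for the alphabet (the alternative,
  sample-then-filter, changes the alphabet size contract).
* **|N| counts reads, not oriented reads**, in the IDF formula.
* **Exact backend is self-contained** numpy; only the approximate
  backend depends on pynndescent. This keeps the oracle independent of
  the library it validates.
* **Oriented pairs in the candidate TSV** (rather than read pairs), with
  a name-to-index sidecar so tables round-trip without the input reads.
* **#CC counts isolated vertices as components** (standard definition);
  vertex counts are reported so the other convention is recoverable.

## Diagnostics the package computes about itself

`overlapnn.diagnostics` measures the two fidelity claims behind the
design, and `scripts/acceptance.py` recomputes both from scratch on the
standard 500 kb / 30× / 20 kb / 95%-accuracy dataset:

* **CF~DF surrogacy**: least-squares R² of log CF vs log DF across the
  alphabet is ≈ 0.999 (the basis for using inverse collection frequency
  as the IDF denominator). The residual comes from within-read k-mer
  duplication in repeat spans and CF=2 error pairs.
* **Distance preservation**: Pearson R² between pre- and post-projection
  cosine distances over range-spanning pairs rises with the embedding
  dimension and reaches ≈ 0.97 at d = 3000 on the fixture. The residual
  equals the
  Johnson–Lindenstrauss noise floor sqrt(1/d) and is independent of SRP
  density; the R² ceiling is set by the fixture's narrow pair-distance
  spread (see Synthetic data), not by the projection.

## Problem sizes

Tests and the acceptance script run at desk scale by design: genomes of
60–500 kb, 10–30× depth, 4–20 kb reads (≈ 150–2,500 reads, alphabets of
10⁴–10⁵ k-mers), exact k-NN as the reference backend, and NNDescent
exercised on ~5,000 oriented vectors. The streaming architecture is the
same one that scales to millions of reads; only the constants differ.

## Known limitations

* The error model is i.i.d. per base; platform-realistic profiles
  (ERRHMM-style) are out of scope.
* IDF weights go negative for k-mers with CF > |N| (ubiquitous repeats);
  the formula is applied as defined, no flooring.
* NNDescent determinism is subject to the backing library's threading;
  the exact backend is bit-reproducible and is the determinism contract.
* PAF ingestion assumes one relevant target per read (best primary
  alignment); split alignments are not merged.
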