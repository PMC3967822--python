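# Methods

## The model

`genomesig` clusters genomic fragments by short-oligonucleotide composition
on a two-dimensional grid of weight vectors (a self-organizing map). The
batch-learning formulation makes the result a deterministic function of the
data: every cycle assigns all fragments to their best-matching (squared
Euclidean) nodes and then moves each node toward the mean of the fragments
captured within its neighborhood, so no stochastic presentation order enters
the procedure.

### Feature space

A fragment of length L is represented by its degenerate k-mer frequencies:
counts of every N-free length-k window, with each word pooled into one
column with its reverse complement, divided by the number of countable
windows. The divisor is the count of N-free windows rather than
(L − N − k + 1); the two coincide when Ns are absent and the former is exact
when they are not (an N destroys up to k windows, not k−1 bases' worth).
Column count is 4^k/2 + p/2 where p is the number of reverse-complement
palindromes: 136 for k=4, 512 for k=5. The canonical (reported) member of
each pair is the lexicographically smaller word and columns are ordered by
it; this is arbitrary but fixed, and recorded in output headers.

### PCA initialization

Initial weights are laid on the plane of the first two principal components
of the (centered, unscaled) feature matrix:

    w(i, j) = mean + s·σ₁·(i/(I−1) − ½)·b₁ + s·σ₂·(j/(J−1) − ½)·b₂

with span s = 5 (±2.5 standard deviations along each axis). Frequencies
share a scale, so no per-column standardization is applied. With
`grid_height="auto"` the second axis gets J = max(1, round(I·σ₂/σ₁)) nodes,
proportioning the grid to the data's leading variances; σ₂ = 0 collapses the
map to a single row. PCA is computed by eigendecomposition of the covariance
matrix (deterministic, no randomized solver). Eigenvector signs are fixed by
convention: when a degenerate index is available the first axis is oriented
so the per-column GC loading increases with i — matching the long-standing
observation that map %GC organizes along the horizontal axis — and
otherwise the largest-magnitude component is made positive.

### Training schedule

Defaults (every constant is a constructor parameter of `BatchSOM`):

| parameter | default | meaning |
|---|---|---|
| cycles T | 145 | batch learning cycles |
| initial radius r₀ | max(I, J)/2 | Chebyshev (square-box) neighborhood, uniform weighting |
| final radius | 1 | radius decays linearly, rounded per cycle |
| α₀, α_min | 0.6, 0.01 | α(t) = max(α_min, α₀(1 − t/T)) |
| distance | squared Euclidean | winner search and quantization error |

Nodes whose neighborhood captured no fragments keep their previous weights
(no stochastic re-seeding, preserving determinism). When α = 1 the update
assigns the neighborhood mean directly, which makes the T=1, r=0, α=1
special case an exact Lloyd (k-means) step; with the radius held at 0 and
α = 1 the per-cycle quantization error is therefore non-increasing.

Bit-level reproducibility: training rows are internally sorted into a
canonical (lexicographic-by-content) order before every reduction, so the
mean, covariance, and per-node batch sums are computed in a fixed order —
permuting the input rows changes nothing, not even the last bit. Winner ties
go to the smallest (i, then j).

### Map analyses

* **Node classes**: empty / mono / multi at a chosen taxonomic rank.
* **Separation accuracy** (default, *strict*): 100 × fragments-in-mono-nodes
  / all assigned fragments; fragments in multi nodes count as failures. A
  *purity* mode instead credits each node's majority label — useful when
  comparing against clustering-purity conventions; the strict figure is
  always ≤ the purity figure.
* **%GC per node** comes from the weight vector's strand-symmetric
  mononucleotide profile: p_GC = Σ_s f_s·gc(s)/k. Degenerate pooling erases
  strand identity, so p_A = p_T and p_C = p_G is the only self-consistent
  mononucleotide model. Nine GC categories cut the non-empty nodes into
  GC-ranked blocks whose sizes differ by at most one (larger blocks at the
  high-GC end; ties broken by grid coordinates).
* **Observed/expected ratios**: a set with GC count g and multiplicity m
  (1 for palindromes, 2 otherwise) has expectation
  m·((1−p_GC)/2)^(k−g)·(p_GC/2)^g under the node's own profile; the ratio
  f/expectation reads over/underrepresentation independently of %GC. 0/0 is
  defined as 1. Weight vectors can drift marginally off the probability
  simplex during training; negative entries are clamped to zero and the
  vector renormalized, with a warning rather than an error, so diagnostic
  maps stay computable everywhere. The blue/white/red rendering thresholds
  (defaults 0.78 / 1.28) are presentation only and never enter computation.
* **Territory borders**: empty nodes whose 8-neighborhood touches ≥ 2
  distinct mono territories. 8-connectivity is a choice; border lists are
  descriptive, not used by any statistic.

## Synthetic studies

The generator samples order-m Markov chains (m ≤ 3) over ACGT with a numba
kernel, seeded end to end. Order-1 chains take dinucleotide factors (e.g.
CG: 0.5 halves P(G | C) before row renormalization — CpG-like depletion).
Because transition biases shift the stationary composition, `calibrated_chain`
bisects the base composition until the *stationary* GC hits the requested
value, so a model's nominal GC is exact. Motif fold-changes are injected by
bounded rejection-resampling: occurrences of the word/reverse-complement set
are redrawn from the chain (depletion) or planted (enrichment) until the
genome-wide count is within 10% of fold × baseline; failure to converge is
an error reporting the achieved ratio.

The **default study** is 5 groups × {3, 3, 2, 2, 2} = 12 species of 600 kb
each, emulating congeneric insect genomes: stationary GC runs 41.8–46.6% in
steps of 0.8 points between groups (±0.3 points between species within a
group) and CpG factors run 0.50–1.06 with opposing TpA factors. These
spacings put adjacent groups ~5–10σ apart in per-fragment composition at
100 kb but only ~2σ apart at 5 kb, which is what produces the window-length
accuracy trend (≈100% at 100 kb overlapping windows, ≈80% at 10 kb, ≈45% at
5 kb on 30×auto grids) — the qualitative signature-length effect, at a
deliberately small scale: 612–1,440 fragments per map rather than the
~10⁶-fragment maps the method is used for in practice. Companion scenarios
deplete the CTTCG set 5-fold in one group (diagnostic-oligonucleotide
recovery) or span GC 35–55% with order-0 chains (GC-axis structure).

What the generator does *not* emulate: repeats and transposable elements,
isochore-scale GC heterogeneity within a genome, coding/noncoding mosaic
structure, and assembly artifacts. Passing tests therefore demonstrate that
the pipeline recovers signatures of the kind and magnitude injected, not
that real genomes of a given clade will separate at these accuracies.

## Numerical and design notes

* Fragmentation tiles each contig independently (windows never span contig
  joins); trailing partial windows are discarded, not padded, so all feature
  vectors describe equally long windows. All non-ACGT IUPAC codes count as N
  for the 10% rule; soft-masked lowercase is uppercased and kept.
* Subsampling to a base cap keeps a uniform random, seed-determined subset
  of whole fragments totalling the largest multiple of the window size ≤ cap,
  in input order.
* Radius and auto grid height use Python's banker's rounding; both only ever
  move a boundary by one node.
* The fragment-count scales used in tests and the acceptance script
  (600 kb genomes, ≤ 1,440 fragments, 30-wide grids) were chosen as the
  package's standard desk-scale study; all of them are parameters.
* Serialization is plain text (TSV with `%.17g` floats + JSON metadata) and
  round-trips bit-exactly.

## Known limitations

* The neighborhood kernel and decay schedules are stated conventions of the
  batch-SOM family, configurable but not claimed to match any particular
  historical implementation's constants.
* No online/stochastic SOM, toroidal topology, or parallel training.
* k ≤ 8 only; no gapped words or amino-acid alphabets.
* `separation_accuracy` is undefined (error) on maps with zero assigned
  fragments, and GC categories require at least as many non-empty nodes as
  categories.
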