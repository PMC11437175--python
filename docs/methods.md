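# Methods

## The refinement model

`taxrefine` treats annotation refinement as supervised learning *within a
single dataset*: the (partial, noisy) labels of a taxonomic classifier are
the training targets, and tetranucleotide composition plus multi-sample
coverage are the inputs. Nothing is transferred across datasets — the tree,
the feature scaling and the network weights are all dataset-specific, so
the model's output space is exactly the set of taxa the classifier
reported. This is deliberate: the refiner cannot invent taxa the upstream
classifier never saw, only redistribute, complete and down-weight the
labels it did see.

### Feature construction

* **TNF block (103 dims).** Tetramer counts use a sliding window of step 1
  over unambiguous bases; any window containing a character outside
  ACGT/acgt is skipped, so IUPAC ambiguity codes and runs of N reduce the
  count total rather than polluting it. Counts are normalised to
  frequencies, centred by 1/256, and projected through a fixed 256×103
  orthonormal kernel: the null space of (i) reverse-complement symmetry
  (strand-agnostic counting), (ii) the unit-sum constraint and (iii) the 64
  trimer prefix/suffix continuity constraints. The kernel is computed once
  per process by SVD null-space extraction and verified orthonormal to
  1e-10. The projected dimensions are z-scaled across contigs with the
  population (1/N) standard deviation; zero-variance dimensions become 0,
  which also covers the single-contig edge case. Scaling is applied after
  the short-contig filter, so the statistics describe the contigs the model
  actually sees.
* **Abundance block (Ns + 1 dims).** Depths arrive as a contig × sample
  TSV (upstream coverage extraction from BAM is out of scope). Each column
  is divided by the sample's total mapped reads when a read-count sidecar
  is provided, else by the column sum — the fallback preserves relative
  scaling, which is all the subsequent row normalisation can see. The row
  sum after the within-sample step is kept as the sample-relative total
  abundance (untransformed), then rows with positive total are normalised
  to sum to 1; all-zero rows stay zero rather than producing NaNs.
* **Contig filter.** Contigs shorter than 2000 bp (configurable) are
  dropped with a logged count; short contigs have noisy TNF estimates and
  unstable depth.

### Network and training

Four hidden layers of 512 units, each linear → batch norm (eps 1e-5,
momentum 0.1) → leaky ReLU (slope 0.01) → inverted dropout (p 0.2); a
linear output layer of width N_l (number of tree leaves). Defaults: 100
epochs, batch size 1024 (reduced automatically to the training-set size),
Adam at learning rate 1e-3. Layers, batch-norm semantics,
Kaiming-uniform initialisation and the optimiser are implemented in NumPy
with exact analytic gradients; the backward pass is verified against
numerical differentiation in the test suite. Training is single-threaded
CPU and deterministic per seed; there is no early stopping and no internal
validation split — the k-fold protocol in the evaluation module is the only
splitting mechanism.

The loss is the flat-softmax hierarchical NLL described in the README. Two
implementation details matter:

* Aggregation is a fixed 0/1 leaf-incidence matrix per tree node, so
  gradients flow only through the softmax. For a batch, the gradient has
  the closed form `dL/dz = p ⊙ (K − Σ_n m_n / q_n)` with K the path
  length, which the code uses directly instead of autodiff.
* Path likelihoods are clamped below at 1e-12 before the log to keep the
  loss finite when a leaf's probability underflows.

Contigs annotated only to an internal node (truncated lineages) contribute
loss along their annotated prefix only. Degenerate cases are well-defined:
a single-leaf tree or domain-only annotations in a one-domain tree give a
loss that is identically zero, and training becomes a no-op rather than an
error.

### Decoding

Greedy top-down: at each rank the child of the current node with the
highest aggregated likelihood is selected (ties broken by lowest leaf
index, for determinism); its label is emitted with the likelihood as score
if strictly above 0.5, else decoding stops for this contig. Because
sibling likelihoods sum to at most 1, at most one child can clear 0.5, so
the decoding is unambiguous, emitted ranks form a contiguous prefix, and
scores are non-increasing with depth. The default reporting threshold for
ground-truth comparison is 0.95; the k-fold benchmark uses 0.5. The
emission test is strict (`> 0.5`), and descent selects among children of
the current node; the two choices only differ from their alternatives when
likelihood mass splits across uncles, where the threshold suppresses
output anyway.

### Evaluation conventions

Counting is per rank over contigs the reference labels at that rank, with
full-path identity — a correct genus name under the wrong family is a
false positive, by construction. The recall denominator includes FP
(`TP/(TP+FP+FN)`), so this recall is never above the textbook
`TP/(TP+FN)`; the property is asserted in the tests. All 0/0 ratios are 0.

The k-fold consistency benchmark rebuilds the tree from the training folds
only; a held-out annotation absent from that tree can never be emitted and
therefore scores as FN (prediction stops above the rank) or FP (a
different label is emitted) under the plain counting rules — no special
case is needed. Fold assignment is a seeded balanced random partition of
the annotated contigs only.

The species-deletion experiment truncates a species' contig lineages to
genus before training, then reports the fraction of affected contigs
recovering the genus, the fraction receiving any species label (species-
rank false positives), the most frequently assigned species, and the
Pearson correlation of mean feature vectors between deleted and assigned
species — the two quantities that drive sibling absorption of novel taxa.

## The synthetic community generator

Real communities cannot ship in a test suite, so the generator emulates
the two signals the method relies on: per-species sequence composition and
per-species abundance profiles. Each species draws a base-composition
vector from a symmetric Dirichlet (concentration 8 per base by default —
base frequencies of roughly 0.25 ± 0.07, enough compositional divergence
for TNF separation without being cartoonish) and a log-normal abundance
profile across samples (σ = 1 on the log scale, around a 20× mean depth);
contigs are i.i.d. draws from the species composition, uniform in 2–6 kb,
with log-normal per-contig depth noise (σ = 0.2). The default community —
8 species in 2 genera and 2 families, 3 samples, 50 contigs per species —
is the benchmark condition used throughout the tests and the acceptance
script.

What the generator does **not** emulate: within-genome compositional
heterogeneity and higher-order (beyond mononucleotide) composition
structure, assembly artifacts and chimeras, strain mixtures, conserved
regions shared across species, and read-level noise. Passing tests
therefore demonstrate that the machinery is correct and that the method
behaves as designed when its assumptions hold — they do not by themselves
establish performance on real assemblies, where TNF and abundance signals
are weaker and correlated across related genomes.

The corrupter emulates an imperfect classifier with three independent
per-contig outcomes (drop, truncate at a uniform random rank, relabel the
species), with mislabels preferring a sibling species in the same genus
with probability 0.5 — mimicking the observed confusion structure between
close relatives.

## Problem sizes and numerical choices

The test suite and acceptance script train at desk scale: the default
400-contig community with 50 epochs and batch 256 (about 5 s per
training on one CPU), and smaller 100-contig fixtures with reduced widths
for unit tests. One regime effect is worth knowing: with only ~100
training contigs and full network capacity, long training memorises
corrupted labels verbatim and the refinement gain vanishes; at a few
hundred contigs (or the paper-scale defaults on real datasets with 10^4–10^6
contigs) the label noise is inconsistent with the features and the network
smooths it out. The label-noise recovery tests accordingly train in the
smoothing regime, which is the regime the method targets.

Other numerical choices: softmax is max-shifted; the kernel SVD and all
training are float64; tie-breaks in decoding are by lowest descendant leaf
index; duplicate contig ids, non-contiguous lineages, >7-rank lineages,
negative depths and feature/annotation mismatches are hard errors naming
the offending record.

## Known limitations

* Lineages with missing intermediate ranks (species known, family absent)
  are rejected rather than patched; mapping classifier-native rank
  vocabularies onto the seven-rank ladder is the caller's job.
* The optimiser is fixed-rate Adam; a learning-rate-free variant could
  remove the one tuning knob but is not required at these scales.
* Depth computation from BAM, classifier-native output parsing, and
  NCBI↔GTDB reconciliation are out of scope by design.
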