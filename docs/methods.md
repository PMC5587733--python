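# Methods

## Model

The classifier is a stack of *dual-path* convolution modules in the
Inception lineage. Each module runs two parallel paths over its input
and concatenates their outputs along the channel axis:

* **path A** — 1×1 convolution (bottleneck) followed by a 3×3
  convolution;
* **path B** — 3×3 average pooling followed by a 1×1 convolution.

Each convolution is followed by batch normalization and ReLU. A module
therefore contains exactly three weighted layers (two convolutions in
path A, one in path B); pooling and normalization are not counted. The
requested output width `c_out` is split half/half between the paths,
with an odd remainder going to path A; `c_out < 2` is rejected.
*Reduction* modules use stride 2 in path A's 3×3 convolution and in
path B's pooling, halving the spatial side (ceil rule for odd sides);
*normal* modules preserve it. Reduction modules are placed first so the
bulk of the computation runs at reduced resolution.

The canonical configuration is 13 modules (3 reduction) on a 64 px,
2-channel input with width schedule [32, 64, 96] for the reductions and
a linear ramp 112 → 312 over the ten normal modules. A final 1×1
convolution lifts to 336 maps of size 8 × 8 (64 → 32 → 16 → 8), global
average pooling produces the 336-dimensional feature vector, and a
fully connected layer plus softmax closes the network. Counting three
layers per module plus the final convolution, the fully connected layer
and the softmax classifier gives 13 · 3 + 3 = 42 layers;
`describe_architecture` measures all of this on an instantiated
network rather than trusting the configuration arithmetic.

The engine (`deepflow.nn`) is plain numpy. Forward convolution is an
im2col matrix product; the input gradient is accumulated with k·k
strided slice additions (the adjoint of im2col), which keeps both
directions BLAS-bound. Gradients of every layer are verified against
central finite differences in the test suite. Average pooling uses
'same' padding with pad pixels included in the mean. Weight
initialisation is He-normal from a caller-supplied generator; there is
no other randomness in the engine, so forward and training passes are
bit-reproducible on a given platform.

## Training

Mini-batch SGD with classical momentum; defaults: learning rate 0.01,
momentum 0.9, batch size 64, weight decay 1e-4 (applied to convolution
and dense weights, not to biases or batch-norm parameters). The
learning rate drops by ×0.1 at one third and two thirds of the epoch
budget. Class weighting is off by default — the canonical task is
heavily imbalanced (97.8% interphase) and unweighted training matches
that regime; inverse-frequency loss weighting is available and, on
97%-imbalanced synthetic data, raises minority-class sensitivity in
every tested seed. No data augmentation is applied by default.

Cross-validation is stratified by class, seeded and order-independent
(cells are sorted by id before shuffling); every class must have at
least `folds` members. Confusion matrices store raw counts (rows =
true, columns = predicted); the column-normalized view divides by
column sums — its diagonal is per-class precision — and empty predicted
columns are rendered as zeros, not NaN. Class merging (e.g. {G1, S, G2}
→ interphase for the five-class task) commutes exactly with confusion
counting.

## Feature space, embedding and ordering

`extract_features` returns the pooled pre-classifier activations;
applying the classifier head to these features reproduces `predict`'s
probabilities exactly, which ties the two code paths together.

The 2-D embedding is tSNE with PCA initialisation and a fixed seed
(deterministic given features, perplexity, seed), perplexity 30 by
default. Perplexity should scale with sample size: on runs with
n ≈ 2000 we use perplexity 50, because at 30 the embedded morphology
continuum fragments into small islands that are artifacts of the
embedding, not of the feature space.

The *ordering score* quantifies how well a continuous covariate is
reconstructed: the embedding coordinates are projected onto their first
principal axis — the simplest 1-D pseudo-order that is invariant to
rotation, reflection and translation of the embedding — and the score
is the absolute Spearman rank correlation between that projection and
the covariate. Significance comes from ≥ 999 permutations of the
covariate; the report includes the 95th percentile of the null. The
principal-axis construction is this package's own summary statistic for
"ordered along the main direction of the embedding"; it is not a
standard pseudotime method and is deliberately simple.

## Outlier-cluster detection

DBSCAN on the embedding coordinates with neighborhood radius eps set to
the median distance to the 10th nearest neighbor, and `min_samples`
defaulting to that same neighbor count — by construction a typical bulk
point has about 10 neighbors within eps, so sparse fringe points become
noise rather than spurious micro-clusters. The *bulk* is the union of
all clusters whose size fraction exceeds `max_fraction` (default 0.05;
if none qualifies, the largest cluster). A cluster is flagged when its
size fraction is at most `max_fraction` and its nearest point is more
than 2 · eps away from every bulk cluster: measured on embedded
morphology continua, fringe fragments sit just past eps while genuinely
detached subpopulations sit an order of magnitude beyond it, so the
factor 2 separates the two regimes with a wide margin. Flagged clusters
report their stage-label composition; per-cell abnormality flags are
membership in a flagged cluster. All thresholds are package decisions,
made for embeddings of this kind, not biological constants.

## Synthetic data

The generator emulates what an IFC instrument delivers — one small
multi-channel image per cell — driven by a hidden phase parameter
t ~ U[0, 1) that is discretized into the seven cell-cycle stages by
cumulative priors. Default priors are G1 0.55, S 0.25, G2 0.178,
Prophase 0.010, Metaphase 0.008, Anaphase 0.002, Telophase 0.002
(interphase mass 0.978, matching the strong imbalance of real
asynchronously growing populations; the per-stage split within those
masses is a package choice). Channels:

* **brightfield** — bright background (0.80), dark membrane ring at a
  radius growing with t (0.38 → 0.60 of the half-side through
  interphase), mid-gray interior; mitotic cells elongate slightly.
* **darkfield** — speckle granularity inside the cell whose density
  grows linearly with t, smoothed with a small Gaussian kernel.
* **fluorescence_dna** — a nucleus blob whose *pixel-integrated*
  intensity equals the cell's DNA content. DNA content is 1× at the
  start of G1 and 2× from the end of S onward, with small strictly
  positive slopes within G1 and G2 (accumulating stain/size signal) so
  that it is strictly increasing in t across interphase; it is written
  into the manifest as the `dna_content` covariate. Mitosis is rendered
  as a condensing nucleus (Prophase), a condensed band (Metaphase), two
  separating lobes (Anaphase) and two separated lobes joined by a thin
  bridge (Telophase).

All morphology varies continuously with t, which yields the property
that classification-based process reconstruction requires and the test
suite asserts: temporally adjacent stages are morphologically more
similar than stages further apart.

A `damaged_fraction` (default 0.02) of interphase cells — drawn from
G1, S and G2 alike, keeping their ordinary stage label — receives a
distinctly abnormal phenotype: a strongly distorted outline, several
angular gaps in the membrane ring, dark outgrowth blobs spilling past
the boundary, bright interior mottling, and disordered bright patches
in the darkfield channel. The phenotype is deliberately dramatic, as
dead cells are in real data; it is what makes the unsupervised
detachment of the damaged cluster reproducible at desk scale.

Optional bleed-through adds β × fluorescence into the brightfield
channel; the mixing is applied at storage precision after per-channel
clipping, so `brightfield(β) = brightfield(0) + β · fluorescence`
holds exactly as long as the sum stays below 1 (true at the default
signal levels and noise). Gaussian pixel noise (sd 0.02 by default) is
added per channel; every cell draws from its own generator spawned
from the dataset seed, so images are bit-reproducible and independent
of β.

The generator does not model the instrument: no point-spread function,
no camera noise statistics, no real Jurkat morphology. Passing tests on
synthetic data demonstrate that the pipeline's machinery works and that
its claims hold where the generative process is known — they do not
certify accuracy figures on real IFC data.

## Desk-scale study conditions

Full-scale training of the 42-layer network on tens of thousands of
real cells is out of scope; the package's own evaluation runs at desk
scale, chosen as the smallest sizes at which the phenomena are stable:

* architecture facts — default configuration, forward pass on a batch
  of 4 random images;
* memorization contract — reduced network (4 modules, 2 reduction,
  widths [16, 32, 48, 64], 32 px, 64-d features) on 64 cells from two
  temporally distant stages, 30 epochs;
* process reconstruction and abnormality detection — the same reduced
  network trained for 12 epochs on 2,000 synthetic cells (three
  interphase classes, brightfield + darkfield only, 2% damaged),
  features embedded at perplexity 50, ordering scored against the
  hidden t and the DNA-content covariate, outliers detected at default
  parameters;
* classification sanity — five-fold stratified cross-validation of the
  same configuration.

## Numerical and interface choices

* Images are loaded from CSV manifests referencing single-channel
  TIFF/PNG files; integer images are scaled by their dtype maximum.
  Normalization is per image: by default a linear rescale by the
  1st/99th percentile then clipping to [0, 1] (robust to hot pixels);
  `minmax` and `none` rules are available — `none` lets
  already-normalized float TIFFs round-trip bit-faithfully, which the
  round-trip test uses. Constant images normalize to 0.
* Resizing is bilinear with anti-aliasing on downscale; constants are
  preserved exactly; the minimal supported side is 8 px (three
  halvings of the smallest meaningful input).
* Checkpoints are numpy `.npz` archives of parameters plus batch-norm
  running statistics and the architecture configuration; they are not
  portable to other frameworks.
* Activation maps for inspection are exported per (cell, map) as PNGs
  rescaled to [0, 1] independently per map, alongside the raw array.

## Known limitations

* The network engine is CPU/numpy; it is meant for small images and
  desk-scale datasets, not GPU-scale replication.
* tSNE determinism holds for fixed inputs, seed and library version;
  coordinates are not comparable across runs with different data.
* The ordering score assumes the process is monotone along the
  embedding's principal axis; strongly curved or cyclic embeddings
  need a different pseudo-order.
* The outlier detector flags *separated small* clusters; abnormal
  cells that blend into the bulk are not detectable this way.
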