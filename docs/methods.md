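# Methods

## Problem and model

`lncgat` casts lncRNA–disease association (LDA) prediction as graph-level
binary classification. Known associations define a bipartite graph; a
candidate pair is represented by its labeled *h*-hop enclosing subgraph
with similarity-derived node attributes, and a small graph neural network
maps the subgraph to an association probability. The approach assumes that
(i) the local bipartite neighbourhood of a pair carries most of the
evidence for or against a link, and (ii) entities with similar interaction
profiles (lncRNAs) or overlapping gene modules (diseases) have similar
association patterns.

## Similarities

**GIP kernel (lncRNAs, and fallback for diseases).** For interaction
profiles `IP(i)` (rows or columns of the association matrix),
`S(i,j) = exp(−β‖IP(i) − IP(j)‖²)`. The bandwidth is normalised by the mean
squared profile norm. Two conventions exist in the literature for the
direction of that normalisation; the default here is the reciprocal form
`β = 1 / mean_i ‖IP(i)‖²` (the standard GIP kernel, in which denser
datasets get a flatter kernel), with the non-reciprocal form available as
`literal_eq3`. An all-zero matrix has no defined bandwidth and is rejected.

**Gene-network disease similarity.** Each disease's annotated genes form a
module in a gene–gene interaction network. For modules A and B the
separation is `S_AB = d_AB − (d_AA + d_BB)/2` from unweighted shortest-path
distances. The default distance convention is nearest-neighbour means:
`d_AA` is the mean over genes of A of the distance to the closest other
gene of A (0 for singletons), and `d_AB` is the mean over all genes of both
modules of the distance to the closest gene of the opposite module, shared
genes contributing 0. Under this convention identical connected modules
separate negatively, so overlap is distinguishable from mere proximity. An
all-pairs-mean convention is available (`convention="all_pairs"`); the
prose definitions in the source literature are ambiguous between the two,
and the nearest-neighbour form is the one with an established
network-medicine interpretation. Separations are mapped to similarities by
min–max normalisation `S_dis = 1 − (S_AB − min)/(max − min)` over all
computed pairs, giving a proper `[0,1]` similarity in which the most
overlapping pair scores 1; a printed variant that divides by `max` alone
(and can leave `[0,1]`) is preserved behind `normalization="literal"`.
Diseases without usable gene annotations get zero similarity to everything
(diagonal 1), or a GIP fallback when no gene data exists at all.

Numerical edge cases: genes with no finite path to the relevant set
contribute the network's largest finite distance + 1 (logged); if every
disease pair has identical separation the off-diagonal similarities are set
to 0.5 with a warning; restricting to the largest connected component is
available (`lcc`).

## Subgraphs, labels, features

The enclosing subgraph of `(l, d)` contains the targets plus every node
whose minimum BFS distance to *either* target is ≤ h (the hop index is that
minimum — symmetric in the two targets), with all induced edges. Default
h = 1; larger neighbourhoods add cost and little accuracy in practice.
Roles are labeled 0/1 for the targets and `2i`/`2i+1` for i-hop
lncRNA/disease neighbours, one-hot encoded in `K = 2h + 2` bits.

Node attributes are `[S_lnc row | 0…0 | one-hot]` for lncRNA nodes and
`[0…0 | S_dis row | one-hot]` for disease nodes — full similarity rows, so
all vectors share the dimension `L + D + K`.

**Label hygiene.** The pair's own association, when present, is removed
from (a) the subgraph edge set and (b) the interaction profiles behind that
pair's GIP features (an O(n²) cached update per pair). Without (b),
training positives carry their own label inside their feature rows: the
model learns to read it off, fits the training set perfectly and transfers
nothing (observed directly in ablations). For test pairs both removals are
no-ops because test positives are already zeroed from the train-fold
matrix.

## Classifier

One degree-normalised graph convolution (symmetric `1/√(deg·deg)`
normalisation after adding self-loops, linear as specified), then
`gat_layers` graph-attention layers: additive single-head attention
`e_ij = LeakyReLU(aᵀ[Wh_i ‖ Wh_j])` (slope 0.2), softmax over each node's
in-neighbourhood (self-loops included), ELU activation, dropout 0.5 on
layer inputs and attention weights during training. Readout concatenates
the two target embeddings; a linear head produces two logits and a softmax
the class probabilities; the association score is `p₁`. The loss is summed
cross-entropy (mean reduction available; with Adam the choice is nearly
immaterial). Probabilities are clamped at 1e-12 inside the loss.

Defaults: `gcn_dim = gat_dim = 32`, `gat_layers = 3`, 1 attention head,
learning rate 0.001, batch size 64, 60 epochs, dropout 0.5, Adam. Rate,
batch, epochs and dropout follow the tuned values of the method this
package implements; depth and width are this package's declared choices
(the attention function is likewise the canonical additive form, with
dot-product attention available for ablation). Initialisation is
Glorot-uniform from a seed; two initialisations from the same seed are
bit-identical, and evaluation-mode forward passes are deterministic.

The network and its gradients are implemented directly in numpy (batches
are packed as one block-diagonal graph); gradients are verified against
finite differences in the test suite, and the GCN layer against dense
matrix algebra.

## Cross-validation protocols

* **CVP** partitions the known pairs into k = 5 folds.
* **CVL / CVD** partition the lncRNAs (rows) / diseases (columns) into 5
  groups, each serving once as the 20% cold test side; a single-draw
  variant (`single_split`) is available.

Per fold: test positives are zeroed from the train matrix; the lncRNA GIP
similarity is recomputed from that matrix only (computing it on the full
matrix would encode test edges in the features — especially severe for
cold-start folds); the gene-network disease similarity is fold-independent
because it derives from external gene data. Negatives are unknown pairs
sampled 1:1 with positives, disjoint between train and test; in CVL/CVD
the test negatives are restricted to the cold rows/columns. Metrics per
fold: rank-based AUC (ties half credit), step-interpolated AUPR, and
F1/accuracy/precision/recall at threshold 0.5; aggregation is mean ± sd
over folds × repeats (10 repeats by default). Candidate ranking for a
disease scores all its unknown lncRNAs and sorts by score, ties broken by
lncRNA id.

## Synthetic data

The generator emulates the statistical shape of public LDA benchmarks
without downloads: `L × D = 40 × 30`, 4 lncRNA and 3 disease blocks
(lncRNA block *b* paired with disease block *b* mod 3 — the simplest
pairing in which every block participates), association probability 0.35
within paired blocks and 0.03 elsewhere, a 300-gene Erdős–Rényi network
(mean degree 6; preferential attachment available), and 12-gene disease
modules drawn from disjoint per-block gene pools with a 50% shared core
within each block. Everything is reproducible from one seed, and
`shuffle_labels` provides a degree-preserving (checkerboard-swap) negative
control. Real benchmarks are sparser (≈1–3% dense) and heavy-tailed in
degree; the generator trades that realism for planted, recoverable
structure at desk scale, so passing tests demonstrate mechanism recovery,
not benchmark-level accuracy.

**What is attainable on this family.** Given the blocks, associations are
independent Bernoulli draws; the best possible CVP scorer is
`P(edge | blocks)`, which yields AUC ≈ 0.80 and AUPR ≈ 0.77 at the default
sizes — an information ceiling no learner can beat. For cold-lncRNA folds
the ceiling is much lower (≈ 0.57): with the GIP similarity honestly
recomputed from the train fold, all cold lncRNAs have identical (zero)
profiles and identical features, so only disease-side information remains.
Cold-start performance reported by methods that compute similarities on
the full matrix is inflated by exactly the leakage this pipeline excludes.

**A known expressiveness limitation.** On this family the discriminative
signal is bilinear — match *l*'s profile against the known partners of *d*
(a simple similarity-weighted neighbour-support heuristic reaches ≈ 0.78
AUC). The specified readout (concatenation of the two target embeddings
into a linear head) is additive in the target representations and can
represent such products only indirectly through the nonlinear attention
stack; in practice the model reaches ≈ 0.6–0.7 CVP AUC at the default
training budget and tends to memorise entities instead. The readout is kept
as specified; a bilinear or element-wise-product readout would be the
natural extension.

## Problem sizes used in the shipped experiments

The test suite and `scripts/acceptance.py` run the default 40 × 30
generator with 5-fold cross-validation, one repeat and 30 training epochs
(three seeds where stability matters), which keeps a full run in the tens
of seconds on one CPU while remaining large enough for the planted
structure to be detectable by the similarity modules and the shuffled
control to sit near chance.

## Other limitations

* Disease-name reconciliation across datasets is exact string matching
  (trimmed, case-folded) plus an optional user-supplied alias table; no
  ontology mapping.
* Gene networks are unweighted and undirected; weighted or directed
  interactomes are out of scope.
* Only a single attention head is implemented; multi-head concatenation
  schemes are not.
* Dataset-scale runs (hundreds × hundreds with thousands of associations)
  work but are CPU-bound in python/numpy; expect minutes per fold rather
  than seconds.
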