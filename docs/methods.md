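# Methods

## Problem and model

`fmh2st` predicts spot-level spatial gene expression from H&E histology.
Given a tissue section with an RGB image, spot pixel coordinates, and (at
training time) a spots-by-genes count matrix, the model learns a map from
the image content at and around each spot to that spot's normalized log
expression over a shared gene vocabulary. Training uses several sections;
evaluation is leave-one-section-out (LOOCV), so every reported held-out
metric reflects generalization to an unseen slice.

The architecture has two branches whose outputs are fused per spot.

**Foundation branch.** A pretrained pathology image encoder phi (consumed
only through an image -> fixed-length-vector contract; any callable works)
embeds each spot patch (h_sp) and the whole slice image (h_sl). The two are
concatenated per spot and fused by a two-layer MLP (ELU between the linear
layers) into h. Including h_sl gives every spot its slice context: spots
from different sections are hard to tell apart from 112-px patches alone,
while whole-slide appearance separates sections well. Two graph-attention
(GAT) encoders then contextualize h:

* over the **spatial graph** — each spot connected to its k_s = 4 nearest
  neighbors by Euclidean pixel distance;
* over the **feature graph** — each spot connected to its k_f = 8 most
  cosine-similar spots in a PCA embedding (default 50 components, clipped to
  min(n−1, d)) of the current fused features h. This graph is rebuilt every
  `rebuild_every` epochs (default 1) as h evolves, which is what makes it
  "learnable": the edges themselves carry no trained weights.

Each GAT encoder is the standard multi-head formulation: per head k, edge
logits e_ij = LeakyReLU(a^T [W h_i || W h_j]) (slope 0.2) are softmax-
normalized over the neighbor set of i, neighbor features are averaged with
those weights and passed through ELU; the K head outputs are concatenated
and a second, single-head attention layer of the same form reduces to the
output width. Neighborhoods are the k out-neighbors of the directed KNN
graph; there are no self-loops, so a node's representation is built entirely
from its neighbors, with the node's own feature entering only through the
attention logits. The two graph views z_s and z_f are combined per spot by
attention aggregation: scores q^T tanh(W z + b) softmax-normalized over the
pair, output the weighted sum (z_F).

**Spot-specific branch.** Operates directly on patch pixels to recover
fine detail the frozen encoder may discard. Per patch: three parallel
convolutions with kernels 3, 5 and 7, each refined by a CBAM (channel
attention from a shared MLP on average- and max-pooled channel descriptors,
then spatial attention from a 7x7 conv over channel-wise average/max maps);
channel concatenation, 1x1 conv + batch norm; L ConvMixer blocks
g_l = PW(DW(g_{l−1}) + g_{l−1}) with GELU + batch norm after both the
depthwise and the pointwise conv; a strided conv downsamples to a small
spatial grid and the result is flattened to one vector per spot. A
single-layer transformer with learned positional lookup tables indexed by
integer array coordinates (Visium ax/ay; rank-discretized pixel coordinates
when absent) attends across all spots of the section; a GAT over the spatial
graph produces z_S.

**Fusion and heads.** z_F and z_S are projected to a shared fusion width and
combined by the same attention-aggregation mechanism, giving z_U. Three
linear heads predict expression: the main head from z_U and one single-layer
head per branch. The collaborative loss is

    L_B = (1 − alpha) · mean((y_B − y)^2) + alpha · mean((y_B − y_U)^2),  B in {F, S}
    L_U = mean((y_U − y)^2)
    L   = L_U + L_F + L_S

Squared errors are averaged over spots *and* genes so the magnitude does not
scale with the vocabulary size. The distillation teacher y_U is not
gradient-detached; the distillation term therefore also acts as a
consistency regularizer on the fused head. alpha defaults to 0.3.

## Preprocessing

Genes expressed (count > 0) in fewer than `min_spots` spots pooled over all
sections are dropped; of the survivors, the `n_hvg` genes with the highest
variance of pooled log-normalized expression are kept (ties broken by gene
id). Defaults n_hvg = 1000, min_spots = 1000 match Visium-scale data; the
synthetic tests keep all 30 genes. Normalization is counts-per-million with
a log1p transform: value = ln(1 + count/total x 1e6). The log1p form is used
because a plain natural log is undefined at the zero counts that dominate ST
matrices; zero-total spots are dropped with a warning. Patches are
`patch_size` x `patch_size` squares (default 112 px, the Visium spot
diameter at typical scan resolution) centered on the spot coordinate with
the half-open convention [c − size//2, c + size − size//2); boundary spots
are completed by reflection padding rather than dropped, so patch count
always equals spot count. HVG selection is done once globally (configurable),
not per CV fold.

## Training

Adam (betas configurable, default (0.9, 0.999)) on the total loss, one step
per training section per epoch, whole-section batching (the transformer
attends across the section, so a section is the natural unit). Gradient
clipping at global norm 5. Head biases are initialized at the training-set
gene means so the heads learn deviations rather than spending early epochs
rescaling outputs. The learning rate decays by a per-epoch factor
`lr_decay`. Inference uses eval-mode batch norm (running statistics), making
prediction deterministic; graphs for a test section are built from that
section alone, so predictions never depend on other sections in the batch.

All tensors are numpy arrays; gradients come from reverse-mode automatic
differentiation (the `autograd` package), and every layer (convolutions via
im2col, batch norm, CBAM, ConvMixer, GAT, multi-head self-attention) is
implemented in this package on top of `autograd.numpy`.

Two configurations ship:

| preset | widths | optimizer | intended use |
|---|---|---|---|
| default | d_h 256, 4 GAT heads, 32 conv channels/scale, L=4, flat 512, 8 attn heads, fusion 256 | lr 1e-4, no decay | Visium-scale data |
| `TrainingConfig.tiny()` | d_h 32, 2 GAT heads, 4 conv channels/scale, L=2, flat 128, 2 attn heads, fusion 32 | lr 5e-3, decay 0.99/epoch, betas (0.9, 0.95) | synthetic desk-scale runs, CI |

The tiny optimizer settings were chosen for stable convergence of the small
widths at whole-section batch size; all of them are plain config fields.

## Synthetic data

The generator emulates the structure the model exploits, at desk scale:
spots on a square grid, each assigned one of `n_programs` latent expression
programs. A program fixes a log-scale expression signature (shared per-gene
baseline ~ N(3, 0.4) plus program effect ~ N(0, 1.2)) and a distinctive
patch appearance (saturated base color plus a program-specific checkerboard
period), so patch pixels deterministically encode the program. Programs are
laid out in rectangular blocks such that each program occupies several
disjoint islands — spatially distant same-program spots exist by
construction, the regime the feature graph is designed for. Sections differ
by (i) a per-(section, gene) additive shift on the log scale with sd
`slice_effect_sd` (default 0.5), and (ii) a strong background tint visible
between patches, with only a faint version of the tint on the patches
themselves; whole-slide embeddings therefore separate sections while
individual patches barely do, mirroring the inter-slice-heterogeneity
observation the slice-level feature addresses. Counts are negative binomial
(variance mu + 0.1 mu^2) by default; `gaussian-on-log` and a noise-free
`none` variant exist for oracle tests.

What the generator does **not** emulate: real H&E texture and stain
variation, irregular tissue boundaries, spatial expression gradients within
a program, dropout/zero inflation beyond what NB sampling produces, and any
dependence of appearance on expression beyond the discrete program identity.
Passing the synthetic recovery tests therefore shows the pipeline can learn
an image-to-expression map with slice batch effects and distant same-program
structure — not that it reaches the accuracy obtainable with a real
pathology foundation model on real Visium data.

The `toy-histogram` backbone (per-channel mean and variance + 8-bin
intensity histogram, 14 features, no weights) stands in for a pretrained
encoder in tests and simulations; any callable with the same contract can be
registered instead.

## Numerical choices and degenerate inputs

* KNN ties (distance or cosine) break by ascending node index; graph
  construction is fully deterministic. Zero-norm feature rows get similarity
  below any cosine so the index tie-break decides their neighbors.
* Effective out-degree is min(k, n−1); a single-spot section is rejected.
* Softmax is computed with max subtraction; tanh inputs are clipped at |30|
  (saturated to machine precision) to avoid overflow in the AD backward pass.
* Batch norm keeps running statistics outside the differentiated parameters;
  momentum 0.1, eps 1e-5.
* Constant gene columns yield undefined correlations and are recorded as
  NaN, never silently zero. The co-expression matrix is symmetrized
  (0.5 (M + M^T)) to remove rounding asymmetry.
* The degree-distribution power-law fit is OLS on (log degree, log count)
  over degrees with nonzero count (not the CCDF); the clustering coefficient
  is the mean local coefficient with degree-<2 nodes contributing 0. Both
  are the conventional readings of "log-log degree distribution fit" and
  "clustering coefficient"; alternatives are easy to add but not configured.
* k-means for domain clustering: 10 restarts, fixed seed, Euclidean on the
  normalized-log predictions; k is set to the number of annotated domains.
* "Per-section PCC" is the distribution over genes within a section; "mean
  PCC" averages over genes first, then sections.

## Design decisions that were genuinely open

* **Backbone frozen, embeddings precomputed.** Fine-tuning a pathology
  encoder is out of scope; freezing makes the pipeline runnable on a laptop
  CPU and the embedding cache makes repeated runs cheap.
* **Whole-slice embedding by direct resize-free encoding.** The slice image
  is passed to the backbone as one raster; backbones needing fixed input
  sizes are expected to resize internally. No tiling.
* **Separate GAT parameter sets per graph** (spatial vs feature); sharing is
  a config flag away but the two relations are semantically different.
* **MLP depth/width, head counts, conv channels** are not determined by the
  method description; the defaults above follow common GAT/ConvMixer
  practice and are all exposed in `TrainingConfig`.
* **Memorization check on the noise-free generator.** The overfit sanity
  run (1 section, 16 spots, 10 genes, 300 epochs, training loss -> ~0)
  probes capacity and training plumbing; with NB sampling noise in the
  targets the same run asymptotes much more slowly because the network must
  reproduce the sampling noise of every entry through neighbor-only
  aggregation. The noise-free variant isolates what the check is for.

## Problem sizes used in tests and the acceptance script

LOOCV runs use the default synthetic scenario (4 sections x 64 spots x 30
genes, 3 programs, 16-px patches) with the tiny configuration, 100 epochs
per fold; the memorization run uses 1 section x 16 spots x 10 genes for 300
epochs. These sizes keep a full LOOCV under ~10 minutes on one CPU core
while leaving the held-out signal (mean per-gene PCC well above 0.5) far
from threshold.

## Known limitations

* No stain normalization, tissue segmentation, augmentation, early stopping,
  or multi-GPU training; the max-epoch cap is the only stopping rule.
* The directed-KNN/no-self-loop GAT follows the neighbor-sum formulation
  literally; adding self-loops (the common GAT implementation default) would
  likely speed optimization and is a one-line graph change, but is not the
  configured behavior.
* Correlation p-values assume independent spots; spatial autocorrelation
  makes them optimistic on real tissue. They are used for ranking, not
  inference.
* The reference-free `toy-histogram` backbone is a deliberately weak
  encoder; results with it say nothing about the relative merits of real
  pathology foundation models.
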