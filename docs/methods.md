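# Methods

## Overview

This package detects seizure-state EEG windows through an explicit,
inspectable feature construction — a *multi-frequency multilayer brain
network* (MMBN) — followed by a multi-branch convolutional classifier with
squeeze-and-excitation channel attention (AM-CNN). The stages are:

1. **Windowing.** Multichannel EEG is cut into 1-s windows with a 0.5-s
   step. A window is labelled seizure iff at least half of it overlaps an
   annotated seizure interval; windows with a smaller but nonzero overlap
   are discarded so no mixed-state window enters training.
2. **Band decomposition.** Each channel of a window is split by a 4-level
   wavelet packet decomposition (WPD) at fs = 256 Hz into sixteen 8-Hz
   leaves; the eight leaves covering 0–64 Hz — where seizure-relevant
   rhythms live — are reconstructed back to full window length.
3. **Network construction.** Per band, channels are nodes and edge weights
   are Spearman rank correlations of the band-limited signals; each layer
   is pruned to its strongest 30% of edges (proportional thresholding).
4. **Characterization.** Four statistics per layer — average weighted
   clustering C̄, clustering-coefficient entropy E_C, spectral radius R,
   graph energy E — compared between states by Welch t-tests.
5. **Classification.** One CNN branch per band layer; branch features are
   fused and classified by a softmax head.

## Wavelet packet decomposition

The WPD recursively filters both the approximation and the detail branch
with an orthonormal Daubechies pair (h, g), giving 2^j equal-width bands at
level j; at level 4 and fs = 256 Hz the bandwidth is (fs/2)/2⁴ = 8 Hz.

Numerical choices:

* **Filters.** Daubechies coefficients are computed by spectral
  factorization of the binomial half-band polynomial (roots inside the unit
  circle + N zeros at z = −1, normalized to Σh = √2), matching published
  tables to ~1e-13. Default wavelet `db4`, a common EEG choice; the order is
  configurable and results downstream depend on it only through band-edge
  leakage.
* **Boundary handling.** Periodized convolution, so each split is an
  orthogonal map: Parseval's identity and perfect reconstruction hold to
  machine precision on every window (asserted at 1e-8 relative in tests,
  observed ~1e-15). Periodization wraps the window ends; on 1-s windows
  this produces mild edge artifacts shared by all channels and bands.
* **Frequency ordering.** The high-pass branch mirrors the spectrum at
  every split, so natural (Paley) leaf order is not frequency order; leaves
  are reordered by the binary-reflected Gray code so that reported band i
  truly spans [8i, 8i+8) Hz. A 30 Hz probe tone lands in band 3 (24–32 Hz).
* **Leakage.** A pure tone 2 Hz from a band edge keeps ~60% of its energy
  in the correct band on a 1-s window; tests therefore assert energy
  *ranking*, not containment.

## Network layers

The Spearman weight is the product-moment correlation of average ranks,
which reduces exactly to 1 − 6Σd²/(L(L²−1)) for tie-free data. Average
ranks make the weight well defined on quantized or repeated samples; a
constant (zero-variance) series has no rank ordering and gets weight 0 with
a warning rather than propagating NaN.

Proportional thresholding keeps the ⌈0.30·N(N−1)/2⌉ largest-signed-weight
undirected edges at their original values (76 edges for N = 23). Fixing
the edge *count* rather than a weight cutoff makes graph statistics compare
topology across windows of very different overall correlation level. Ties
at the retention boundary break by lexicographic node-pair order for
reproducibility. Ranking by |weight| is available (`by_magnitude`); with
signed ranking any surviving negative weight is clipped to zero (with a
warning) before graph measures, whose triangle products and strengths
presuppose nonnegative weights. The classifier receives the raw retained
weights, unrescaled.

## Graph measures

For a symmetric nonnegative layer W with strengths k_ν = Σ_κ W[ν,κ]:

* C(ν) = Σ_{κ≠α, both ≠ν} W[ν,κ] W[ν,α] W[κ,α] / (k_ν(k_ν−1)), an
  ordered-triple sum; C̄ is its node average. When k_ν(k_ν−1) < 1e-12 —
  isolated or single-edge nodes, common on sparse thresholded layers —
  C(ν) := 0 to avoid the denominator singularity.
* E_C = −Σ P(ν) log P(ν) with P(ν) = C(ν)/ΣC, natural log (nats), 0·log 0
  := 0, and E_C := 0 when all clustering vanishes; maximal at log N for
  uniform positive clustering.
* R = max|λ| and E = Σ|λ| over eigenvalues of W — the spectral and nuclear
  norms, verified in tests against an independent SVD.

State comparison uses an unpaired Welch (unequal-variance) t-test per
measure and band, with tiers at p < 0.05 and p < 0.001. No
multiple-testing correction is applied, matching common practice for this
kind of per-band descriptive table; treat the tiers as descriptive, not
confirmatory. Zero-variance-in-both-groups degenerates to p = 1 with a
warning.

**Known limitation.** On bands whose period is a large fraction of the
window (0–8 Hz in a 1-s window has ~8 effective samples), Spearman weights
are very noisy; the clustering denominator k(k−1) then sits near its
singularity for weakly coupled layers and C̄'s between-state contrast can
vanish even when coupling differs strongly. The eigenvalue measures R and
E are robust to this and separate the synthetic regimes in every driven
band; C̄ and E_C separate reliably only from the third band (16–24 Hz)
upward.

## Synthetic data

The generator emulates the statistical structure the pipeline consumes —
per-band inter-channel coupling that differs between regimes — and nothing
more. For each 8-Hz band one shared band-limited Gaussian driver is drawn
(4th-order Butterworth-filtered white noise, unit variance); channel p
receives `coupling[b]·driver + (1−coupling[b])·independent band noise`,
bands are summed, and white sensor noise (sd 0.5, in units of per-band
driver sd) is added. Defaults: 23 channels, 256 Hz; normal regime couples
at 0.2 in all bands; seizure regime at 0.8 in the three bands below 24 Hz
and 0.4 above, echoing the low-frequency dominance of ictal EEG.

What a green test does *not* establish: no seizure morphology (spikes,
spike-wave complexes, evolution), no artifacts (EMG, blinks), no 1/f
background, no inter-subject variability, no class imbalance. The
synthetic regimes are far more separable than clinical data — the
cross-validated accuracies here validate the machinery, not clinical
performance.

## Classifier

Each branch: two 3×3, 16-kernel, stride-1, same-padding convolutions with
ReLU; a squeeze-and-excitation path (global average pool → dense 16→8 with
ReLU → dense 8→16 with sigmoid) whose gates rescale the second conv's maps,
then ReLU and batch normalization. The fusion block concatenates the L1,
L2 and post-BN maps of all branches (8·3·16 = 384 channels at 8 bands),
applies 3×3@32 and 1×1@10 convolutions (ReLU), flattens (23·23·10 = 5290)
and ends in a 2-way softmax. Branches share structure, not parameters.
The ablation "comparison model" removes only the attention path; batch
normalization then acts on the second conv directly.

Implementation notes:

* Built on a small numpy backend (single GEMM per convolution pass over all
  kernel taps) rather than a deep-learning framework; float32 throughout;
  training is bit-reproducible given the seed.
* Padding/stride are forced to keep N×N spatial size through all convs, as
  the declared layer output sizes require; layer shape contracts are
  asserted programmatically at build time.
* Batch normalization: standard mini-batch formulation, ε = 1e-3 inside the
  square root, momentum-0.9 running statistics for inference.
* Initialization: seeded Glorot uniform. Optimizer: Adam (lr 1e-3, β =
  0.9/0.999, ε = 1e-7) on softmax cross-entropy, batch 64.
* A stratified 10% validation split selects the best epoch by minimum
  validation loss; that snapshot is restored after training. Reference
  protocol is 200 epochs; the desk-scale default is 30 epochs with
  early-stopping patience 10, and the scaled-down acceptance runs use 3
  epochs (accuracy on the synthetic regimes saturates within 2).

## Evaluation

Stratified 10-fold cross-validation, window-wise; per-fold confusion counts
and aggregated accuracy / sensitivity / specificity (seizure positive).
Window-wise splitting of *overlapping* windows leaks train–test
information; the harness accepts recording groups to split honestly in that
case, and the synthetic datasets use non-overlapping windows so the issue
does not arise in the tests.

Ablations: single-band inputs (one branch per run), two bands (level-2
tree, 0–32/32–64 Hz), four bands (level-3 tree, 16-Hz bands), no split
(Spearman network of the raw signals), each with attention on or off. On
the default synthetic data the full 8-band model dominates the weaker
single-band models, reproducing the qualitative ordering that motivates
band fusion; weakly coupled bands (driven at 0.4 vs 0.2) classify markedly
worse (~74–90%) than strongly driven ones (~99%).

## Design choices made where the design was open

* Overlap labelling threshold (50%) and the discard rule for smaller
  overlaps: avoids mixed-state training windows; configurable.
* Signed (most-positive) edge ranking as default, magnitude optional.
* Natural-log entropy; Welch rather than pooled-variance t-test; per-band
  tests with a pooled option.
* Validation split stratified; positive class = seizure.
* Branch parameters unshared (branches "share the same structure" only).
* EDF support is plain 16-bit EDF; annotations travel in a JSON sidecar.
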