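# Methods

## Model

The imputer is a dual-task 1D convolutional network over normalized
peak-count vectors (one cell = one sample of length m peaks).

**Normalization.** Counts are first winsorized at the 99.9th percentile of
the nonzero entries (extreme values are capped, not deleted, so the matrix
shape is preserved), then mapped to
`X_ij = log2(X'_ij + 1) / max_j log2(X'_ij + 1)` with the maximum taken per
peak across cells. Peaks whose maximum is zero map to all-zero rows with a
zero denominator. The per-peak denominators are stored, so
`count = 2^(value * denominator) - 1` inverts the transform exactly on the
observed support (verified to 1e-9 in the tests). Because 0 maps to 0, the
normalized matrix stays sparse.

**Architecture.** Two hierarchy levels by default. The bottom encoder is a
kernel-4 stride-2 convolution (dropout, ReLU) followed by a kernel-3
stride-1 channel-fusion convolution; the top encoder repeats the block with
the strided layer duplicated, giving a total stride of 8. The decoders
mirror the encoders with transposed convolutions (kernel 4, stride 2,
padding 1 — an exact length-doubling adjoint), and the bottom decoder
consumes the channel-wise concatenation of the top decoder's upsampled
output and the bottom encoder's output. The reconstruction head is a
sigmoid, matching the [0, 1] normalized scale. A parallel classifier
(dense 128 -> batch norm -> ReLU -> dense -> softmax) reads the flattened
top-level features. One-level and three-level variants drop or duplicate
the top stage (the three-level stage doubles the channel width); inputs are
zero-padded symmetrically to the next stride multiple and cropped after
decoding.

**Loss.** Reconstruction loss is the squared Euclidean distance between
the decoder output and the uncorrupted normalized vector, summed over peaks
and averaged over cells; classification is mean cross-entropy. The two are
combined with homoscedastic-uncertainty weighting,
`L = L_MSE/s1^2 + L_CE/s2^2 + 2 log s1 + 2 log s2`, with the task variances
learned as log-variances initialized at 0 (a literal standard-deviation
parameterization could go non-positive under gradient steps). Setting the
gradient of `L/v + log v` to zero gives the optimum `v = L`, which the test
suite checks numerically. Without the classifier the loss reduces to the
reconstruction term alone.

**Training.** Adam (lr 1e-3, batch 32). When masking is enabled, each batch
receives a freshly drawn corruption: for a cell with k nonzero entries,
exactly `round(rate * k)` of them are zeroed, sampled uniformly without
replacement. The loss always targets the uncorrupted input of `fit`. A
validation split (10% of cells by default) drives early stopping (patience
10) and best-state restoration. All randomness flows from seeded NumPy
generators; two runs with the same configuration are bit-identical.

The network, including strided/transposed convolutions and batch
normalization, is implemented directly in NumPy with hand-written
backpropagation and verified against float64 central finite differences in
`tests/test_nn.py` (biases are randomized there because zero-initialized
biases put some pre-activations exactly on the ReLU kink, where finite
differences are invalid for any subgradient choice).

## Benchmark protocol

The masking benchmark treats the simulated matrix as ground truth and the
masking operation itself as the dropout process: the model is trained on
the dataset with per-epoch random masking at the benchmark rate (20/40/60%
of each cell's nonzero entries) and the loss targets the pre-masking data;
recovery and retention are then scored on an *independent, fixed* mask
realization applied once to the same matrix. This is the standard
masked-denoising evaluation: because the network is convolutional and
translation-equivariant it cannot memorize per-position values, so restoring
a masked entry requires inferring it from the cell's local context and
population. Training only on the corrupted matrix with the corrupted matrix
as its own target was considered and rejected: the mean-squared-error
optimum at a zero input is then bounded by the internal mask rate times the
observed nonzero rate, which sits far below the 0.5-count threshold — no
method could restore masked entries under that reading, while the published
behaviour (recovery roughly constant in the masking rate) is exactly what
the adopted protocol produces.

Imputation runs the trained network without corruption. The default mode
returns the full reconstruction everywhere (needed for library-size and
biological-zero analyses); a conservative `fill_zeros_only` mode overwrites
only zero entries and passes observed values through bit-identically.

## Synthetic data generator

The generator emulates multi-population scATAC-seq structure rather than
any specific simulator's internals. Peaks are partitioned into a shared-open
block (fraction 0.025), one contiguous marker block per population
(fraction 0.035 each), and a closed remainder; contiguous blocks make the
population structure visible to a convolutional model and in heatmaps.
Within open blocks each peak's accessibility probability is drawn from
Beta(8, 2) — peaks differ in how reliably they are detected — and the count
of cell j of type t at peak i is Binomial(2, p_t(i) * capture), the two
draws standing for the two alleles of a diploid genome. This yields the
near-binary counts (≤ 2) characteristic of the assay. The capture rate is
bisected at generation time so the expected nonzero fraction equals 5%, the
midpoint of the 3-7% band typical of peak-by-cell matrices; the ground
truth is read as the complete pre-dropout accessibility profile, with
technical dropout supplied by the masking operator downstream.

Two optional perturbation axes are deliberately simple stand-ins:
noise level ℓ in {0..3} flips each entry independently with probability
ℓ·0.005 (zeros to 1, nonzeros to 0), and a sparsity degree d zero-inflates
each nonzero entry with probability d. Defaults are level 0 and degree 0.

What the generator does *not* emulate: sequencing-depth variation between
cells, batch effects, doublets, continuous differentiation trajectories,
and peak-peak co-accessibility beyond block structure. Passing benchmarks
on this data therefore demonstrates that the architecture and training
recover population-structured signal under controlled dropout; they do not
by themselves establish performance on experimental data.

## Problem sizes and known limitations

The zero-separation benchmark in the tests and the acceptance script runs
at 5 populations × 100 cells × 5000 peaks with 16/32 channels and 30
epochs; the ablation suite (masking and classifier removed) runs three
seeds at 1280 peaks × 300 cells with 8/16 channels, comparing pooled
per-cell medians across seeds. The simulator's default configuration
(5 × 500 cells × 80000 peaks) is exercised directly for the dimensional and
sparsity checks. These sizes are the package's desk-scale choices; all
conclusions are relative comparisons on a single machine.

Known limitations:

* Biological zeros at *open* peaks are indistinguishable, from a single
  cell's corrupted vector, from masked dropouts at the same peak; the model
  imputes both high. Retention of biological zeros is therefore bounded by
  the share of truth zeros lying in closed regions (≈ 98.9% under the
  default generator geometry), and the recovery/retention trade-off cannot
  be moved past that bound by longer training.
* The classifier's effect on meta-cell distance is small when populations
  are easily separable, as they are in the generator's default geometry;
  ablation directions are asserted on medians pooled over seeds.
* Absolute mean-squared errors depend on the simulator's scale and are not
  comparable to values reported for other generators; the evaluation module
  reports both count-scale and normalized-scale MSE and the package's
  benchmarks use relative comparisons only.
* Runtime scales linearly in peaks × cells; the NumPy implementation is
  single-threaded apart from BLAS and is intended for desk-scale data
  (up to ~10^4 peaks × 10^3 cells in minutes).
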