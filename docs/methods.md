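# Methods

## The pipeline

`blockcs` implements a block-based compressive-sensing (CS) image codec and
a downstream CNN classification pipeline, so the trade-off between
compression ratio and classification accuracy can be measured end to end.

The acquisition model, per 8×8 block of each RGB channel:

1. center pixels at zero (subtract 128),
2. 2-D type-II DCT (orthonormal), giving coefficients `X` (B×B),
3. vectorize to `v` of length L = B² (column-major),
4. acquire `Y = A v` with a Gaussian measurement matrix `A` (M×L, M ≤ L).

Decoding inverts the chain: orthogonal matching pursuit (OMP) estimates
`v̂` from `Y`, then devectorize → inverse DCT → un-center → merge blocks →
clip/round to 8-bit. Compression ratio is CR = uncompressed/compressed
size = B²/M per block. The reconstructed images feed an AlexNet-style CNN
classifier, and the evaluation layer reports confusion-matrix metrics
(per-class precision, recall, F1; overall accuracy = trace/total) and PSNR.

## Model assumptions

CS recovery relies on natural image blocks being approximately sparse in
the DCT domain and on Gaussian matrices acting as near-isometries on
sparse vectors. Neither is exact for real blocks, so reconstruction at
M < L is lossy; quality degrades monotonically with CR, which is exactly
the behaviour the sweep instrumentation measures.

## Numerical and design choices

- **DCT convention**: orthonormal type-II (`scipy.fft.dctn(norm="ortho")`),
  so Parseval holds and the DC coefficient of a constant block `c` is
  `B·c`.
- **Vectorization order**: column-major, `(r, c) → c·B + r`, a fixed
  bijection chosen for simplicity; any fixed ordering is equivalent for
  the acquisition algebra (zig-zag ordering would matter only for entropy
  coding, which is out of scope).
- **Measurement matrix**: i.i.d. N(0, 1/M) entries, so ‖Av‖ ≈ ‖v‖ in
  expectation. One matrix is generated per run from a stored seed and
  shared by every block and channel; the seed travels in the compressed
  header so encoder and decoder always agree.
- **OMP**: greedy atom selection by maximal absolute correlation against
  column-normalized atoms; the least-squares refit at each iteration uses
  the raw columns (solved via normal equations — Gaussian submatrices with
  |support| ≤ M are well conditioned — with an SVD fallback). Dual
  stopping rule: residual ≤ 1e-6·‖Y‖ or M atoms selected. All-zero
  columns are never selected. The residual norm is nonincreasing by
  construction and atoms are never re-selected.
- **Pixel centering**: subtract 128 before the DCT and add back after the
  inverse (the JPEG convention), keeping block signals roughly zero-mean
  so the DC coefficient does not dominate acquisition.
- **Quantization**: intermediate math is floating point; clipping to
  [0, 255] and rounding to 8-bit happen only at final decode output.
- **Container (.bcs)**: magic/version header plus (N, B, M, seed,
  channels) and the raw little-endian float64 measurement payload.
  Regenerating `A` from the seed keeps files at payload size.

## Classifier

Two presets share one design grammar (convolution stages with ReLU and max
pooling, then fully connected layers with dropout, softmax output):

- `alexnet`: the classic five-stage network (227×227 input, 96/256/384/
  384/256 maps, two 4096-wide hidden dense layers).
- `small`: a three-stage reduction (64×64 input, 8/16/32 maps,
  128/64-wide dense layers) sized for single-CPU experiments.

The engine is a compact numpy implementation (im2col convolution, explicit
backprop, float32 parameters) with seeded initialization, shuffling and
dropout, so training is bit-reproducible given a seed.

Training defaults follow the reference working point: SGD, learning rate
0.001, batch size 64, dropout 0.4 on the two hidden dense layers,
100 epochs. Momentum 0.9 is used (configurable) and the loss is
categorical cross-entropy; no augmentation, no early stopping. Images are
resized to the preset's native input side at the classifier boundary and
scaled to [-1, 1]. Dataset splitting is stratified 70/10/20 with
largest-remainder per-class allocation (exactly 420/60/120 for a balanced
600-image set).

## Synthetic data

The fixture generator emulates a 4-class labeled vegetable image corpus.
Each class owns a base hue (green / orange / yellow-brown / pink-white), a
shape mask (cluster of discs / elongated taper / ellipse / capsule) and a
texture frequency; pose (rotation, translation, scale), texture phase,
brightness and additive Gaussian pixel noise (sd 8 gray levels) are
randomized per image. The noise default is large enough that CS
reconstruction error matters at high CR, yet small enough that classes
remain separable. The minimum pairwise mean-foreground-hue distance of
0.05 is stated in `fixtures.MIN_HUE_MARGIN` and verified by test.

What the generator does **not** emulate: natural image statistics
(backgrounds, occlusion, lighting, intra-class shape diversity of real
photographs). Passing tests therefore demonstrate that the pipeline is
implemented correctly and reproduces the qualitative accuracy-vs-CR
trade-off, not that the specific accuracy figures would transfer to real
photo corpora.

## Problem sizes used in tests and the acceptance script

Experiments are run at desk scale, as the package's own choice of default
study conditions: 100 images per class at 64×64 with the `small` preset
and 30 training epochs (other hyperparameters at their defaults). Under
these conditions the uncompressed classifier reaches ≥ 90% held-out
accuracy, and accuracy at CR=2 is at least that at CR=32 (5-seed
majority) — the qualitative trend of the full-scale experiment. The PSNR
sweep uses ten 64×64 synthetic images per measurement count; full
measurement (M = L = 64) is near-lossless (> 50 dB, limited only by
8-bit rounding), and mean PSNR decreases strictly across
CR ∈ {2, 4, 8, 16, 32}.

Full-scale reproduction of the published headline accuracies (98%
uncompressed, 96.66% at CR=2) would require the original external photo
corpus and 256×256 training for 100 epochs; that is deliberately out of
scope. The `alexnet` preset is still provided and tested for construction
and forward-pass validity.

## Known limitations

- OMP decoding cost grows with M (the M = L setting is the slowest,
  ~Θ(M³) per block in the worst case); no batch or Cholesky-update
  variant is implemented.
- No entropy coding or measurement quantization: the container stores raw
  float64 measurements, so on-disk size equals payload size.
- Only Gaussian measurement matrices and the DCT sparsifying basis are
  supported; other solvers (basis pursuit, CoSaMP) are out of scope.
- The numpy CNN engine targets these two presets; it has no GPU path and
  no convolution algorithm beyond im2col.
- Zero-denominator per-class metrics return 0 with a warning rather than
  raising, so sweeps on degenerate small fixtures complete.
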