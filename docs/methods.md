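# Methods

## Problem and representation

Nucleosome occupancy is a continuous per-base signal: how often a base is
wrapped in a nucleosome across a cell population, measured by MNase-seq
coverage. Tracks are normalized with **dMean** — each base's read count
divided by the mean read count over all covered bases of all chromosomes —
so the genome-wide average is exactly 1 and values are non-negative.

A prediction target at genomic position *p* is represented by the 147-bp
window [*p*−73, *p*+73], the canonical nucleosome core length. The window's
146 overlapping dinucleotides are one-hot encoded into a binary 16×146
matrix (row order lexicographic: AA=0 … TT=15; each column sums to 1). The
regression label is the dMean value at the central base. For minus-strand
sites the window is read as the reverse complement (the 5'→3' sequence of
the annotated strand); since the mapping from a window to its matrix is
injective, matrices are decodable back to sequence, which the test suite
exercises as an invariant.

Windows containing any non-ACGT symbol are skipped rather than imputed
(the one-hot basis has no N channel); skips are counted in a report.

## Site screening

Genome-wide dMean distributions are strongly left-skewed: the median sits
near the lower quartile and a small tail of high-occupancy positions lies
above the boxplot outlier threshold **Q3 + 1.5·IQR** (quartiles computed by
linear interpolation of order statistics, the "type 7" rule). Training sets
are enriched for strong positioning signal by stratified screening: positions
strictly above the threshold are kept at a 1:3 ratio, the rest at 1:30.
"1:k" is implemented as *keep one site per k eligible sites*; the default
mechanism is systematic (every k-th eligible position in coordinate order,
which keeps exactly ⌈n/k⌉ per stratum and is reproducible without a seed),
with a seeded Bernoulli(1/k) alternative. Statistics are computed per
chromosome by default. Train/test partitions are leakage-free by
construction: whole-chromosome holdout, or a seeded coordinate-disjoint
fraction, with duplicate coordinates rejected. Region-level quality
exclusions (e.g. a chromosome with systematic experimental bias) are
expressed as a manual blacklist of intervals; no automated anomaly detection
is attempted.

## Architecture

The network maps 16×146×1 inputs to one value through four parallel-branch
convolution stages. All kernels are 1×K (height one), so the 16-row
dinucleotide axis is untouched until flattening; convolutions are
same-padded, so width changes only at the 1×3 stride-3 valid max-pools, one
after each stage: 146 → 48 → 16 → 5 → 1.

| stage | branches (each → channels) | output channels |
|---|---|---|
| Module A (×2 levels) | 1×1, 1×3, 1×7 gated; 1×7 dilated (rate 3); 1×11 dilated (rate 5) → 128 | 640 |
| Module B | 1×1, 1×3, 1×7 gated; 1×7 dilated (rate 3) → 128 | 512 |
| Module C | 1×1 gated; 1×3 gated (separable); 1×3 dilated rate 2 (separable) → 64 | 192 |

* **Gated convolution** `Y = (X*W+b)·σ(X*V+c)`: paired feature and gate
  kernel stacks of identical shape; the sigmoid gate is the branch's only
  nonlinearity. Internally both paths share one im2col and one GEMM (the
  fused kernel has 2·C_out output channels); parameter count is unchanged.
* **Dilated convolution** spaces kernel taps `l` apart
  (`(F*_l k)(x) = Σ_y F(x+l·y)·k(y)`), enlarging the receptive field with no
  extra parameters; rate 1 reduces to standard convolution, which the test
  suite verifies against a brute-force oracle. Dilated branches are followed
  by ReLU.
* **Depthwise-separable convolution** factorizes a 1×K convolution into a
  per-channel depthwise filter (K·C_in weights) plus a 1×1 pointwise mix
  (C_in·C_out weights, bias here only). Module C's K>1 branches are
  separable — the cascaded separable stage between the wide Module B output
  (512 channels) and the final features; a separable gated branch duplicates
  both stages for its gate path.

Each stage is concatenation → batch normalization (channel axis) → 40 %
dropout → max-pool; one batch normalization is also applied to the raw
input. The 16·1·192 = 3072 flattened features feed a fully connected
256 → 32 → 1 head with ReLU activations. The regression head ends in ReLU
(occupancy is non-negative) with the output bias initialized at 1.0 — the
dMean genome-wide mean — so the final ReLU starts in its active region
(with a zero bias the head can start dead: all predictions exactly 0 and
no gradient). The classification head ends in a sigmoid.

The reference configuration has **6,628,227 trainable parameters (6.6 M)**,
counting convolution and gate kernels with biases, batch-norm scale/shift,
and dense weights. The count is verified against an independent closed-form
per-stage sum (`reference_parameter_table`). A scaled configuration divides
every branch channel width by an integer factor (default 8 → ≈200 k
parameters) and preserves the full shape trace; it is the desk-scale
workhorse for tests.

The layer engine (forward and backward passes, Adam) is written in numpy:
convolutions are evaluated as im2col GEMMs; batch-norm statistics are
accumulated in double precision; dropout is inverted (masks scaled by
1/(1−rate) at train time, identity at evaluation). Every layer's analytic
gradient was validated against central finite differences in double
precision (relative error ≤ 1e-7). Evaluation-mode forward passes are
deterministic; training is bit-reproducible given the seed on a fixed
BLAS (all randomness — initialization, shuffling, dropout — flows from
explicit `numpy` generators).

## Training protocol

Adam with initial learning rate 1e-4, MSE loss (binary cross-entropy for
classification), MAE (or accuracy) as the monitored metric, batch size 64,
and a 3:1:1 train/validation/test split with largest-remainder rounding.
Callbacks: learning rate halves when validation loss fails to improve by
more than 1e-4 (the ReduceLROnPlateau convention; the tolerance absorbs
drift from batch-norm running statistics) for 5 consecutive epochs, floored
at 1e-6; the best-validation weights (and batch-norm running statistics)
are checkpointed and restored at the end. A non-finite loss aborts with a
diagnostic rather than continuing.

The full-scale protocol (200 epochs on ~4·10⁵ genome-derived samples) is
representable in `TrainingConfig` but is not what the test suite runs; the
desk-scale recovery experiment below uses the scaled model with learning
rate 1e-3 — appropriate for its ~200 k parameters, where 1e-4 would be
needlessly slow — for a small number of epochs.

## Synthetic data

The generator supplies genome, track, and TSS annotations with the
statistical structure the method assumes, so the entire pipeline is
testable without downloads. Genomes are concatenated composition blocks
(geometric lengths, mean 500 bp) whose GC content is Beta(2,2) rescaled
into [0.4, 0.6]. Log-occupancy at position *p* is
`α·f_GC(p) − β·f_AT(p) + ε`, where f_GC/f_AT are the window's GC-type
(GG/CC/GC/CG) and AT-type (AA/TT/AT/TA) dinucleotide fractions,
ε ~ N(0, σ²) i.i.d.; occupancy is its exponential — non-negative and
right-tailed — optionally followed by Poisson read sampling, then dMean
normalization. The 73 boundary bases on each end carry no full window and
are zero/uncovered.

Defaults α = β = 4, σ = 0.15 were calibrated by simulating the marginal
distribution until it reproduces the target shape: under 5 % of positions
above Q3 + 1.5·IQR, clear positive skew with median < mean, and
occupancy–GC-content correlation ≈ 0.87. (Heavier effect weights or a wider
GC range produce outlier tails of 8–12 %, which no longer resemble the
distribution being emulated.) The generator encodes only the GC/AT
monotonicity and this marginal shape; it has no MNase digestion bias,
nucleosome phasing, linker periodicity, or 10-bp rotational signal, so
passing tests demonstrate that the pipeline and optimizer recover a
sequence-composition signal — not that the model attains its genome-scale
accuracy on real chromatin.

The learning-recovery experiment: a 600-kb genome (sized so the default
1:3/1:30 screen yields > 20,000 sites), the first 20,000 screened sites
encoded, split 3:1:1, and the scale-8 model trained for one epoch (batch
64, learning rate 1e-3 — ~190 optimizer steps); success is held-out
Pearson r ≥ 0.8 plus monotone GC-type dinucleotide frequencies across
k-means occupancy groups. One epoch at this learning rate already reaches
r ≈ 0.91 against a noise ceiling of ≈ 0.95; the single-epoch problem size
keeps the whole experiment at minutes on one CPU core.

## Sequence-dependence statistics

Sites are grouped by occupancy three ways: quartile split (high = strictly
above Q3, low = strictly below Q1, the middle band excluded from
contrasts), 1-D k-means with k = 3 (groups relabeled high/medium/low by
descending centroid; seeded), and deciles G1…G10 after a descending sort
(ties broken by value descending then coordinate ascending). Group
sequences are summarized by pooled mono- and dinucleotide frequency tables
and by the positional 16×146 frequency matrix (entry (d, j) = fraction of
the group's windows with dinucleotide d at position j; columns sum to 1 —
the matrix of a single sequence is exactly its one-hot encoding).
Enrichment contrasts between groups use a two-sided, continuity-uncorrected
two-proportion z-test; identical proportions (including 0/0) return p = 1.

## TSS windows

For cross-region analyses each TSS contributes a grid of prediction centers
at 10-bp steps across ±1000 bp, endpoints included (201 centers for an
interior TSS). Offsets are strand-oriented — for a minus-strand TSS,
oriented offset +d is genomic coordinate TSS−d — and every center's 147-bp
window is read on the TSS strand. Flipping a TSS's strand mirrors the grid
and reverse-complements every window (a tested invariant). Out-of-bounds or
N-containing centers are skipped with a report; a TSS with no surviving
centers is flagged.

## Numerical choices and degenerate inputs

* Quantiles: numpy's linear ("type 7") interpolation throughout.
* Same-padding pads with zeros; pooling is valid (trailing columns beyond
  the last full window are dropped: 146 → 48 uses columns 0–143).
* Pearson correlation raises on constant input instead of returning 0 or
  NaN; per-chromosome reports skip chromosomes with < 2 sites with a
  warning. The mean over chromosomes is unweighted by default
  (site-weighted behind a flag).
* dMean of an all-zero track is an error (the ratio is undefined), and
  renormalizing an already-normalized track is rejected.
* bedGraph intervals are 0-based half-open; fixedStep WIG start is 1-based
  and converted at the parser. Overlapping intervals and negative values
  are errors; coverage gaps are zero-filled, flagged, and excluded from the
  dMean denominator.

## Known limitations

* The numpy engine is single-threaded and CPU-bound; the full 6.6 M
  parameter model is buildable and runs forward/backward, but genome-scale
  training at 200 epochs is far outside its intended use.
* Reported accuracies on synthetic data bound what the pipeline can
  recover from composition alone; real MNase maps carry biases and
  positioning signals the generator deliberately omits.
* The classifier cross-validation harness trains one fresh model per fold;
  with the full configuration this is expensive and is intended for scaled
  configurations.
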