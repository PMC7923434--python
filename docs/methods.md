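# Methods

## The classification problem

HEp-2 cell images from indirect immunofluorescence carry two sources of
difficulty that ordinary CNN pipelines handle poorly. First, every
staining pattern occurs at two fluorescence levels — bright "positive"
and dim "negative" — so images of the same class can differ more in gray
level than images of different classes (intraclass variation plus
interclass similarity). Second, class frequencies are grossly
imbalanced: in the reference training corpus the four common patterns
have at least 2,100 examples each while nuclear membrane has 814 and
Golgi only 375. A model trained on a small random subset of labels
therefore tends to be accurate on average (high ACA) while failing
completely on the rare patterns (low MCA).

## Wavelet front end

Each image is resized to a configurable square side (default 112,
bicubic) and decomposed once with a level-1 2D discrete wavelet
transform in periodization mode, so a 112 × 112 image yields exactly
56 × 56 coefficient planes. The network consumes two planes:

* **A** — the approximation (low-pass) coefficients. Averaging
  suppresses the noise and amplitude-coded texture that distinguish the
  positive and negative modes, so the A-planes of a bright and a dim
  image of the same cell resemble each other more than the raw images
  do. The package quantifies this as a structural statement
  (`wavelet_frontend.intensity_homogenization`): the Pearson correlation
  between min–max-normalized planes of a same-geometry positive/negative
  pair rises from raw to approximation. Note that a *mean-intensity*
  version of this claim cannot hold: the transform is linear, so plane
  means are a fixed multiple of image means and their gaps are preserved.
* **D = H + V + Dg** — the element-wise sum of the horizontal, vertical
  and diagonal detail planes. Summing folds all high-frequency content
  (shape, boundaries, internal gray variation) into one channel, which
  halves the number of parallel networks the earlier four-plane design
  needed.

The wavelet family is configurable; the default is the orthonormal Haar
(db1), chosen because it downsamples exactly 2×, conserves energy
(verified to 1e-6 relative in the tests), and reconstructs exactly
through the inverse transform. Coefficient planes are fed to the network
unnormalized — the first batch-normalization layers absorb scale.

## Network architecture

Two branches with identical structure process A and D:

    stem: 3x3 conv (1 -> w) + BN + ReLU
    max pool 2x2          (56 -> 28)
    residual block (w)
    max pool 2x2          (28 -> 14)
    residual block (w)

with default width w = 64. The branch outputs are concatenated
(14 × 14 × 2w = 128 channels at default width), mixed by a 1 × 1
convolution (+BN+ReLU), passed through a third residual block at 2w
channels, global-average-pooled to a 2w-long feature vector and
classified by a fully connected softmax head. That makes five residual
blocks in total; every residual block is conv→BN→ReLU→conv→BN with the
identity shortcut added before a final ReLU, all convolutions preserve
spatial dimensions, and only the two pooling layers downsample.

Channel choices beyond the printed constraints (128-channel concat,
128-long feature vector, five blocks) are a reconstruction: identical
stem and block widths keep every shortcut an identity, avoiding
projection shortcuts that nothing in the design requires.

Training is softmax cross-entropy (natural log; probabilities clamped at
1e-12 before the log) with Adam at learning rate 0.001 (default moments),
mini-batch 128, a single seed driving initialization and shuffling, and
early stopping: training ends when the validation loss has failed to
beat its running minimum `patience` (default 5) consecutive epochs, with
a `max_epochs` safeguard of 200, and the weights of the best epoch are
restored. The engine (`hep2al.nn`) is NumPy throughout — im2col-free
shifted-GEMM convolutions with hand-written reverse-mode gradients — and
is deterministic for a fixed seed on a given platform.

## Cross-modal transfer learning

`pretrain` trains a fully trainable network on a small labeled source
corpus from the same imaging domain (head sized to the source classes,
5 by default). `apply_transfer_plan` then freezes, in both branches,
everything strictly before the second residual block — the stem
convolution through the second pooling layer — replaces the head with a
freshly initialized layer sized to the target classes (6), and leaves
the second residual blocks, the fusion convolution, the post-fusion
block and the head trainable. Frozen batch-normalization layers run on
their stored running statistics during fine-tuning, so frozen segments
are bit-invariant end to end (asserted bit-exactly in the tests).

Early stopping during fine-tuning monitors a seeded 10 % carve-out of
the labeled pool, never the test set; an external monitor set can be
supplied instead.

## Active learning

The annotation loop under budget B with initial draw k and round size m
(defaults k = round(0.15 B), m = round(0.10 B)):

1. draw k pool images uniformly at random (seeded), query the oracle,
   fine-tune;
2. score every still-unlabeled image with the current model;
3. rank least-confident first — descending entropy, or ascending least
   confidence / margin; ties break by ascending sample id;
4. annotate the top min(m, B − |labeled|) images, so the budget is hit
   exactly;
5. fine-tune on the full labeled set and repeat from 2 until |labeled| = B.

Entropy is the default measure: it uses the entire probability vector,
whereas least confidence and margin read only one or two entries; for
two classes all three induce the same ranking (property-tested against
brute-force sorting). The entropy is the standard Shannon form
−Σ p log p — the quantity whose *high* values mark uncertain samples —
and "confidence" for the other two measures is the max probability
value, not its index.

Each round fine-tunes from the current weights (warm start; cold start
from the pretrained checkpoint is available), which makes the training
effort cumulative across rounds; intermediate rounds can therefore be
capped at a few epochs (`round_max_epochs`) while the final fit after
the last annotation always runs with the full epoch budget. Scores are
computed with a single inference pass per image. The loop's bookkeeping
core (`run_selection_loop`) is decoupled from the network, so budget
arithmetic can be verified on a bare id pool with a stub scorer; the
loop never queries an id twice and maintains
|labeled| = min(k + i·m, B) after every round (asserted invariants).

## Evaluation

`EvalReport` holds the confusion matrix (rows = true), per-class
accuracies, ACA (trace / total) and MCA (unweighted mean of per-class
accuracies), reported as percentages with two decimals. A class absent
from a test set has undefined accuracy; MCA is then computed over the
present classes with a warning. The four experiment arms are RS (random
draw, train from scratch), AL (active loop from scratch), and IN-RS /
IN-AL (the same on top of a pretrained, partially frozen source model).

## Synthetic data

The generator renders single-cell grayscale images on a dark background
(level 0.06): a cell disk at a jittered center and radius, one of seven
motifs (homogeneous fill; speckled / fine-speckled / coarse-speckled
dots of decreasing size contrast; 2–5 large nucleolar blobs; 30–40 tiny
centromere dots; a bright nuclear-membrane ring with dim interior; a
Golgi partial arc plus an off-center blob clump), a foreground level
drawn from the bimodal intensity distribution (positive mode 0.78,
negative 0.38, positive fraction 0.5), light Gaussian blur, and additive
Gaussian noise (sd 0.04). Everything is determined by the seed.

Design intent, calibrated once and then frozen: the benchmark must be
learnable but not trivial, and the Golgi motif is deliberately placed
*between* the nuclear-membrane ring and the nucleolar blobs in
appearance, so that an undersampled model is genuinely uncertain about
Golgi images rather than confidently wrong — the regime in which
uncertainty sampling can help, and the confusion structure real corpora
exhibit. Class counts for imbalanced sets follow the reference ratios
2100 : 2100 : 2100 : 2100 : 814 : 375 with largest-remainder rounding.
`make_source_target_pair` reproduces the domain shift between the small
source corpus and the large target corpus: the source has five classes
(no Golgi; speckled split into fine and coarse), the target the six
merged classes, with disjoint seeds and ids.

What the generator does *not* model: optics and fluorophore physics,
segmentation artifacts, intermediate intensity levels, within-specimen
correlation, or annotation noise. Passing benchmarks on these images
shows that the pipeline's machinery behaves as designed under the
intended statistical structure (bimodality, imbalance, rare-class
confusability); it does not certify accuracy figures on real corpora.

## Benchmark problem sizes

The stochastic acceptance benchmark runs the RS, AL and IN-AL arms on a
synthetic corpus of 3,000 training and 1,000 test images at the
reference imbalance ratios, image side 64, width-4 networks, batch 64,
learning rate 2e-3, a 20 % labeling budget, at most 20 epochs per fit
with intermediate rounds capped at 6 warm-start epochs, and five seeds
per arm; the source corpus for pretraining has 900 images. These sizes
are the package's scaled-down study conditions chosen so the whole
benchmark runs on one CPU in minutes; the package defaults (side 112,
width 64) match the full-scale pipeline. Under these conditions random
sampling typically leaves Golgi at 0 % (mean MCA in the 60s) while the
active loop annotates the majority of the Golgi pool and lifts mean MCA
to the mid-90s, with cross-modal pretraining adding stability on top.

## Numerical and degenerate-input choices

* Probabilities clamped at 1e-12 before logs; softmax subtracts the row
  max; 0·log 0 := 0 in the entropy.
* Argmax prediction ties resolve to the lowest class index; ranking ties
  resolve by ascending sample id (both deterministic).
* Right-angle rotations in augmentation are exact array rotations (bit
  lossless); other angles use bilinear resampling with reflect padding
  about the center, avoiding dark corner wedges on centred cells.
  Augmentation applies to pretraining and from-scratch baselines; it is
  off by default inside AL fine-tuning rounds.
* Images with odd side are rejected by the wavelet front end (pad
  upstream); unknown wavelet names and motifs produce errors listing the
  supported options.
* Batch normalization uses eps 1e-5, momentum 0.1, biased batch
  variance; frozen BN layers never update their running statistics.
* A labeled set smaller than the batch size shrinks the batch with a
  warning; a fine-tune with nothing trainable, an empty training set, or
  a non-finite loss raise immediately.

## Known limitations

* The NumPy engine is single-threaded BLAS-bound; full-width (64)
  training at side 112 is for small corpora only. The architecture and
  loop are the contribution; scale is not.
* Warm-started rounds make the per-round training effort depend on the
  budget schedule; cold starting is available but slower.
* Uncertainty sampling can stall if a rare class is *confidently*
  misclassified; the benchmark's motif design avoids that regime on
  purpose, and nothing in the loop detects it on real data.
* MCA with a zero-support class is undefined and reported over present
  classes with a warning; the reference corpora never exhibit this.
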