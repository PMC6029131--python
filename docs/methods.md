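# Methods

## Problem and model

`rnabind` treats RBP binding-site prediction as binary classification of
fixed-length RNA reads, using both the nucleotide sequence and a predicted
per-nucleotide secondary-structure annotation. The guiding idea is that an
RBP's specificity is a *combination* of a short sequence element and the
structural context it sits in, so the model sees both channels and the
motif-extraction step reports both.

### Input encoding

A read `s = (s_1..s_n)` is one-hot encoded over (A, C, G, U); an `N` (or
any non-ACGU character after normalization, with `T` silently mapped to
`U`) becomes the uniform row (0.25, 0.25, 0.25, 0.25). For a convolution
filter of width *w*, *w* − 1 uniform rows are prepended and appended so
that every alignment of the filter with the read — including partial
overlaps at the ends — is a valid window; this is the standard
DeepBind-style padding. The structure string over (F, H, I, M, S, T) is
encoded identically over six columns, with uniform padding of exactly 1/6
(so every row of every encoded matrix sums to 1; the commonly printed 0.16
is just that value rounded).

Variable-length input is center-truncated or symmetrically padded to the
model length (default 101 nt), with `N` filling the sequence and a
configurable dangling-end state `T` filling the structure. This rule is a
package choice; fixed-length CLIP-derived reads pass through unchanged.

### Structure annotation

Six states: **S** for any paired position; unpaired positions take the
label of the loop closed by their nearest enclosing pair — **H** if that
loop has no inner helix, **I** for exactly one inner helix (bulges
included), **M** for two or more; exterior unpaired positions are **F**
before the first paired position and **T** after it. Two conventions the
six-state alphabet leaves open are fixed as: exterior linkers between two
helices are **T**, and a structure with no pairs at all is annotated all
**F**. Lone pairs are allowed and are plain **S**.

Annotations can be (1) supplied directly, (2) derived from dot-bracket
strings (stack parser, pseudoknot-free), or (3) predicted by the built-in
folder: a Nussinov-style base-pair-maximization dynamic program
(Watson–Crick plus GU wobble, hairpin loops of at least 3 unpaired bases)
with a deterministic traceback (position *j* pairs with its smallest
admissible partner whenever pairing is optimal). Base-pair maximization is
not an energy model; it is chosen because it is self-contained,
deterministic and fast (the DP is JIT-compiled with numba), and because
the architecture is agnostic to the structure source — an adapter to an
external thermodynamic folder can be substituted wherever a dot-bracket
string is accepted.

### Network

Per branch: valid cross-correlation with 16 filters of length 10 → batch
normalization → ReLU → max-pooling with window 3 (a trailing partial
window is kept) → dropout 0.25. The two pooled maps (equal length because
both filter lengths are 10) are concatenated position-wise into a
37 × 32 map for 101-nt input, swept by a bidirectional LSTM with 32 units
per direction; the concatenated final hidden states pass through dropout
0.5 and one sigmoid unit. An alternative readout that flattens the full
BLSTM output sequence is available behind `ModelConfig.readout =
"sequence"`; the final-state readout is the default as the smallest
faithful reading of "concatenate the two directions' outputs, then
classify".

Training minimizes binary cross-entropy (the single sigmoid output makes
this equivalent to 2-class softmax cross-entropy) with RMSprop
(lr 0.001, ρ 0.9, ε 1e−8), batch size 50, at most 30 epochs, shuffling
each epoch, stopping early when validation loss has not improved for more
than `patience` (default 5) consecutive epochs, and restoring the
best-validation-loss parameters. Everything is implemented directly in
NumPy — forward pass, backpropagation (verified against central finite
differences in the test suite), RMSprop, batch-norm running statistics
(momentum 0.9, ε 1e−3), inverted dropout. Weights are Glorot-uniform from
the config seed; the LSTM forget-gate bias starts at 1. Inference runs
with dropout off and batch-norm running statistics, so predictions are
deterministic and independent of batch partitioning. Reproducibility is
seeded within one platform/BLAS build; bit-exactness across platforms is
not promised.

Ablations are first-class config switches: `use_structure=False` drops the
structure branch, `use_blstm=False` replaces the BLSTM with a flatten
layer (CNN-only).

### Motif extraction and enrichment

For each filter *f* of a branch, activations
`A_mfi = ReLU(Σ_{l,d} w_fld · x_{i+l−1,d} + b_f)` are computed over all
*positive* inputs (bound sites are what the motifs should characterize).
The hit threshold is per-filter: `τ_f = 0.5 · max_{m,i} A_mfi`, the
maximum taken over all positive inputs and positions, and hits are strict
exceedances, so an everywhere-zero filter yields no hits. Each hit's
window is the L = 10 letters the filter covered, mapped back to unpadded
coordinates; windows that start before the read (left boundary clips) lose
their alignment and are dropped, and only the first 7 of 10 columns enter
the PWM (motif widths in curated RNA motif databases are ~7, and the
filter length 10 is chosen ~1.5× that). PWM probabilities are
`(count + 0.1) / (n_sites + D·0.1)`; a filter with no usable windows
produces an explicit empty motif rather than an error.

Scanning uses log₂ odds against a uniform background; a string "has a
hit" when its best offset reaches 75% of the PWM's maximum attainable
score (an information-free PWM can never hit). Enrichment compares hit
counts in the bound set against an equal-size background with a one-sided
Fisher exact test, Bonferroni-multiplied by the number of filters.

Backgrounds differ by branch, deliberately. Sequence motifs use
per-sequence mononucleotide shuffles. For structure motifs a letter
shuffle of the annotation string would be wrong: folded structures are
dominated by long runs (stems, loops), and destroying the run-length
statistics makes *any* run-like PWM look enriched. The structure
background is therefore built by shuffling the bound *sequences*,
re-folding and re-annotating them — the correct null when structures are
predicted from sequence. The test suite's null calibration (no planted
signal) confirms that both branches' enrichment tests are then quiet.

## Synthetic benchmark

The generator emulates the shape of CLIP-seq-derived datasets — 101-nt
reads, balanced bound/unbound labels, 0.6/0.15/0.25
train/validation/test splits mirroring the 24,000/6,000/10,000 layout of
the real experiments at reduced n (defaults 1,650 + 1,650 reads; explicit
split counts, e.g. 2,000/500/800, can override the fractions). Positives
are uniform-background reads carrying a planted consensus motif
(default UGUGUGU, a pyrimidine-rich element of the kind many RBPs bind) at
frequency 1.0 with optional per-position mutation noise, plus a planted
structure context (default HHHHH, co-located with the sequence motif).
Negatives are plain background. Structure strings come from folding each
read with the baseline folder (so sequence and structure are correlated,
as in real pipelines); the planted structure pattern then overwrites the
annotation at the placement offset. An i.i.d. structure mode exists for
unit tests only.

What a green test on this world establishes: that the pipeline can learn
a planted signal of realistic width at realistic read length and recover
it as an interpretable motif, and that it is quiet when there is nothing
to find. What it does not establish: performance on real CLIP data, whose
negatives are not uniform background, whose positives carry cross-link
biases, co-binding and positional structure the generator does not
simulate, and whose structure annotations come from a thermodynamic
folder rather than base-pair maximization.

## Numerical choices and edge cases

- Pooling keeps the trailing partial window (max over the remainder), so
  a pool window longer than the conv output yields one pooled position.
- Encoded-matrix row sums are exact to 1e−9; MEME files round-trip to
  1e−6.
- A Fisher table that is all zeros returns p = 1; empty motifs report
  p = 1 with zero counts.
- Training refuses single-class training labels; AUC refuses single-class
  inputs.
- `patience = 0` stops at the first non-improving epoch; learning rate 0
  leaves parameters exactly unchanged (useful as a contract check).
- PWM-vs-planted comparison uses mean per-column Pearson correlation over
  the best alignment offset with at least 4 overlapping columns, which
  tolerates the phase ambiguity of periodic motifs like UGUGUGU.

## Known limitations

- The baseline folder maximizes pair count, not free energy; its
  annotations are a stand-in, and absolute structure-branch performance on
  real data will depend on the folder used.
- Filter-derived PWMs inherit the usual caveats of CNN motif extraction:
  redundant filters can split one motif, and the 0.5·max hit threshold is
  a heuristic.
- Enrichment scans the same bound set the motifs were extracted from;
  with the near-uniform PWMs a null world produces, the selection effect
  is negligible (verified by the null calibration), but sharply
  overfitted motifs on tiny datasets could inflate enrichment.
- One model per protein; no cross-protein transfer or joint training.
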