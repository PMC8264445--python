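# Methods

## Problem setting and model

A dephosphorylation site is an S/T/Y residue experimentally known to be
dephosphorylated; the classifier decides, from the residue's local
sequence context alone, whether a candidate site is such a site. The
context is an odd-length window of `w` residues centred on the site
(flank `(w−1)/2` on each side). Windows are integer-encoded — the 20
standard amino acids map alphabetically to 1…20, nonstandard letters
(X, U, B, Z, O) to the unknown token 21, index 0 held in reserve — and
fed to:

```
embedding(dim 21)
→ bidirectional LSTM × L (128 units per direction, full sequence returned)
→ time-distributed dense (128, ReLU)
→ flatten → dropout (0.4) → dense (64, ReLU) → dense (2, softmax)
```

trained with binary cross-entropy (identical to two-class softmax
cross-entropy for one-hot targets) and Adam at learning rate 0.01,
batch 512, up to 30 epochs, checkpointing the epoch with the best
validation accuracy and halving the learning rate (factor 0.5, patience
3, floor 1e-4) when validation loss plateaus. The published description
of this architecture states two Bi-LSTM layers in one place and one in
another; the default here is `bilstm_layers=2` with 1 fully supported.
The activations of the time-distributed and 64-unit dense layers are
not specified upstream of the softmax; ReLU is used as the conventional
choice. The classification threshold for binary calls is 0.5.

The network, backpropagation through time, Adam, checkpointing and the
plateau scheduler are implemented directly in NumPy (`dephoslearn.nn`).
Gradients of every parameter tensor are checked against central finite
differences in the test suite (agreement to ~1e-7 absolute on a small
instance). Training is single-threaded and bit-reproducible for a fixed
seed: initialisation, shuffling, dropout masks and the validation split
all draw from one seeded generator. Checkpoint selection uses a
stratified 10 % split of the training partition (the independent test
set is never touched); on corpora too small to hold anything out, the
training data doubles as the validation set — a degenerate but
well-defined fallback used only at toy scale.

Initialisation: Glorot-uniform input kernels, orthogonal recurrent
kernels (per gate block), zero biases except a forget-gate bias of 1.

## Dataset construction

Coordinates are 1-based and fully closed (UniProt-style). Sites whose
full flank does not fit inside the protein are dropped, never padded —
the returned drop-report counts them per side. Negatives are all
in-class residues (S/T for the ST model, Y for the Y model) of the
annotated proteins that are not listed as positives; negatives are not
drawn from unannotated proteins. Redundancy removal is exact-string:
within one label the first occurrence (by protein id, then position)
survives; a window string appearing under both labels is removed from
both, since its label is ambiguous. Balancing randomly under-samples
the majority label — whichever it is — to the minority count, without
replacement. The train/test split is stratified with per-label rounding
(`round(f·n)` to train, remainder to test). Window shrinking removes
one residue from each end per step (33 → 31 → … → 23), preserves the
centre, and re-deduplicates because trimming can create new duplicates.

## Transfer learning

Only weights move between stages: the optimizer state and the learning
rate restart at each fine-tuning stage, the conventional reading of
"instantiating" a new model with pre-trained weights. Transfer requires
architecturally identical specs — in particular equal window sizes,
because the flatten width depends on the number of timesteps; shrink
windows *before* pre-training if a smaller target window is wanted.
Freezing is by layer name (`embedding`, `bilstm_1`, …, `output`);
frozen layers are excluded from optimizer updates and stay
bit-identical. The default freezes nothing, which the original study
found to work best. `run_chain` derives per-stage seeds from the global
seed (`seed·1000003 + k mod 2³¹`) and records each model's lineage as
the ordered list of stage names.

## Evaluation

ACC/SN/SP are percents (their definitions include ×100); MCC and AUC
are unitless. Degenerate denominators never raise: SN/SP report 0 with
a flag, MCC is 0 whenever any factor of its radicand is 0. AUC is the
trapezoidal area under the ROC curve (scikit-learn `roc_curve`), which
equals the Mann–Whitney pair statistic with ties counting ½ — the test
suite verifies this by exhaustive pair counting. Cross-validation is
stratified k-fold (shuffled, seeded); the summary is mean ± sample SD
(ddof 1) across folds. Window scans rank sizes by MCC, ties broken by
AUC then SN. Report rounding: 2 d.p. for unitless values, 1 d.p. for
percent changes, half-away-from-zero; `relative_change(before, after)`
is `(after−before)/before × 100`.

## Synthetic tasks

The generator plants a motif — a small set of non-centre offsets with a
preferred residue each — into positive windows with independent
per-position probability `q`; everything else, and all of every
negative window, is i.i.d. uniform over the 20 standard letters, with
the centre drawn uniformly from the residue class so class membership
itself carries no signal. This is deliberately simpler than real
phosphosite context (no proteome composition bias, no positional
correlation, no disorder context); a frequency-weighted background is
exposed as an option but the shipped properties do not depend on it.
What passing tests show is therefore that the *machinery* — window
bookkeeping, training, transfer, metrics — behaves correctly and that
the transfer scheme recovers a planted relatedness structure; they say
nothing about attainable accuracy on real phosphatase substrates.

Task relatedness is a single knob: the target task keeps
`round(ρ·m)` of the source's `m` motif positions and replaces the rest.
`emulate_corpus_shapes` produces a source of 2×31,944 windows, an ST
target of 2×1,112 and a Y target of 2×125 (scaled proportionally by
`--scale`), with overlap 0.75 between consecutive tasks — a
shape-faithful rehearsal corpus for the three-stage chain.

When FASTA emission is requested, each window is embedded in a fake
protein with 0–6 random extra flanking residues so the end-dropping
logic of dataset preparation is exercised on re-extraction.

## Experiment and test scales

The paired transfer-benefit protocol (`experiments.transfer_benefit`)
uses a desk-scale model (window 21, one Bi-LSTM layer of 24 units,
embedding 12, batch 128) on a source corpus of 4,000 windows, a target
corpus of 100, a held-out target test set of 1,000, with 8 pre-training
and 12 fine-tuning epochs, 5 seeds per condition. At this scale the
median MCC benefit of fine-tuning over scratch is large (≈0.2–0.4 at
overlap ρ ∈ {0.8, 1.0}), so the qualitative claim — transfer helps most
when the target is small and the tasks related — is tested with
headroom. Unit and property tests use even smaller instances (window
11, 8 units) chosen so the whole suite runs in under two minutes on one
CPU.

## Known limitations

- Exact-duplicate removal only; no similarity-based (CD-HIT-style)
  redundancy reduction.
- The uniform background makes synthetic negatives easier than real
  ones; measured MCC/AUC on synthetic tasks are upper bounds of sorts.
- Bit-reproducibility holds for single-threaded BLAS; multi-threaded
  reductions may differ in the last ulp.
- Cross-window-size transfer is rejected rather than partially mapped;
  one source model per window size is required.
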