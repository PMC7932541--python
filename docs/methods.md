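# Methods

This note documents the models, parameters, numerical choices and known
limitations of the package. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Coordinates and sequence handling

All coordinates are 0-based half-open (BED convention) internally; wiggle
fixedStep input (1-based) is converted on read. Sequences are lower-case
`atcg`; every other letter becomes `n`, whose complement is `n` and whose
one-hot code is the null column — unknowns therefore carry no signal
rather than aliasing a real base. Promoters are the 500 bases upstream of
the TSS: `[s−500, s)` for a `+` transcript starting at `s`, `[e, e+500)`
reverse-complemented for a `−` transcript ending at `e`, so every promoter
string reads 5′→3′ toward the TSS. Promoters that would cross a chromosome
edge are rejected, never clipped: the scanner's window grid assumes
exactly 500 bases. Genes with several transcripts are collapsed to the
transcript whose TSS is most upstream (the outermost promoter), one
promoter — and one positive/negative call — per gene.

## Peak pairing

Proximity is measured center-to-center after reducing peaks to midpoints,
because training windows are anchored on a point (±50 bp around the SRE
peak center) rather than on peak extents. Each SRE peak contributes at
most one couple — its nearest NF-Y center, if closer than
`max_pair_distance` (250 bp, strict `<`). Negative windows are centered on
control peaks whose centers are ≥ 250 bp from every SRE and NF-Y center;
this keeps positive-class signal out of the negative set at the cost of
discarding a few controls. Windows that would cross a chromosome edge are
skipped and counted.

## Conservation-weighted augmentation

Each seed window yields `copies_per_seed` mutated copies (default 100, so
1,301 seeds give 1,301 × 101 = 131,401 positives) with exactly
`mutations_per_copy` (20) changed bases. Position weights are
`w_i = 1/(s_i − min(s) + ε)` with ε = 0.1: phyloP scores can be negative,
so the raw reciprocal is undefined; the shift keeps every slice positive
while preserving "most conserved → least mutated", and ε bounds the
largest slice (the least conserved base). Missing scores are imputed to 0;
an all-missing track degrades to uniform weights with a warning.

Positions are sampled **without replacement** — "20 mutations" is read as
20 distinct sites — by sequential roulette-wheel spins with the chosen
slice removed and the wheel renormalized. The implementation uses the
exponential-race equivalence (take the k smallest of `E_i/w_i`,
`E_i ~ Exp(1)`), which is distribution-identical and vectorizes across
copies; the literal sequential sampler is retained as a test oracle and
the two are compared by goodness-of-fit. The replacement base is uniform
over the three alternatives, so every mutation changes the base; `n`
positions are never selected. The train/validation split (3:1 by default)
is stratified by label before the random split — the reproduced workflow
leaves this open, and stratification stabilizes validation accuracy as an
early-stopping signal.

## Encoding

Windows are doubled to forward + reverse complement before one-hot
encoding; the "reverse" half is the reverse *complement* (the biologically
meaningful opposite strand), and the forward-then-RC order is frozen
because occlusion depends on the mirror identity: base `i` appears again
at row `199−i`. Column order `(null, a, t, c, g)` matches the reference
digit strings so serialized matrices are comparable across
implementations.

## Classifier

The layer stack — conv(n_filters, kernel, ReLU) → max-pool(2) →
conv(n_filters, kernel, ReLU) → global max-pool → dense(64, ReLU) →
dropout 0.3 → dense(1, sigmoid) — is a reconstruction: it realizes the
reference design constraints (1-D convolutions, the (32/64/128 × 3/6/12)
tuning grid, a single sigmoid output unit) with the simplest standard
architecture; the global max-pool provides the position invariance the
scanning stage relies on. Loss is binary cross-entropy; the optimizer is
Adam at 1e-3. Defaults are 64 filters, kernel 6.

Forward, backward (im2col convolutions, argmax-scatter pooling gradients)
and Adam are implemented directly on NumPy; the backward pass is verified
against finite differences in the test suite. Training streams batches of
512 raw strings through the encoder on the fly (no corpus-wide
materialization), runs up to three blocks of 40/30/10 epochs with
early-stopping patiences 15/10/5 monitoring validation **accuracy**
(min-delta 0), and restores the best weights at each block boundary and at
the end. "Iteration" means one full pass over the training set. With a
fixed seed, training is deterministic on a given machine (bit-equality
across BLAS builds is not promised). Checkpoints are single `.npz` files
with a versioned header.

## Promoter scan and call rule

21 windows (offsets 0, 20, …, 400) cover a 500-bp promoter exactly. The
positive call requires ≥ 3 consecutive windows **each** strictly above
0.9; an alternative reading (mean of the run > 0.9) is exposed as
`run_rule="mean"` but off by default, as the per-window reading matches
the way positive profiles are described (individual points above the 0.9
line). The longest qualifying run is reported and mapped back to genome
coordinates strand-aware.

## Occlusion

For one window the loss vector is `p(intact) − p(base i zeroed)`,
`i = 0…99`; zeroing clears **both** the forward row and its mirror row
`199−i`, otherwise the base would leak back through the reverse-complement
half and dilute the saliency contrast. Positive loss means the base
supports the prediction. The promoter profile uses windows at a 5-bp step
(81 windows, 95 % overlap between neighbors); only windows whose intact
probability exceeds 0.9 contribute — the "best" windows, where the model
actually sees a site — and their losses are averaged base-wise in promoter
coordinates. The selection-by-threshold is a reconstruction of an
informally described "best results were averaged" step. With no qualifying
window the profile is all-NaN with zero counts, which callers treat as a
diagnostic rather than an error.

## GO enrichment

The headline statistic is deliberately **not** the textbook odds ratio: it
is the cross-product of `[[pos_in, pos_out], [n_in, n_out]]`, numerically
the ratio of positive-gene proportions inside vs outside the term. This is
the reporting convention this package reproduces (verified against four
reference rows to two decimals); the conventional case/control OR is
computed alongside in a clearly labeled column. The exact-conditional 95 %
CI (scipy's conditional-MLE interval) and the two-sided Fisher exact p are
computed on the same proportions table; test oracles check p against
brute-force hypergeometric enumeration. A zero cell triggers the Haldane
0.5 correction for the point estimate and flags the row. The universe is
genes with ≥ 1 BP annotation *and* a scanned promoter, constant across
rows; terms smaller than `min_term_size` (default 10) or spanning the
whole universe are skipped. No multiple-testing correction is applied by
default (none is part of the reproduced convention); Benjamini–Hochberg is
available behind a flag.

## Synthetic fixtures

The generator emulates the statistical structure the pipeline assumes:
uniform random background sequence; planted SRE (`atcaccccac`, the SRE-1
consensus) and CCAAT (`ccaat`) instances arranged as couples; ChIP-like
peak tables with ≤ 10 bp center jitter; motif-free control peaks ≥ 250 bp
from any planted motif; a conservation track of N(0, 1) background with
+3 on motif bases; a transcriptome in which a configured fraction of genes
carry a couple inside the promoter (reverse-complemented for minus-strand
genes); and GO groups with one designated term enriched in couple-bearing
genes. Couple spacing defaults to 5–25 bp between SRE end and NFY start —
the tight arrangement typical of sterol-responsive promoters — which also
guarantees (by window geometry: a cassette spans ≤ 40 bp, so the interval
of fully-containing window offsets is ≥ 60 bp long and contains ≥ 3
multiples of the 20-bp step) that a complete couple can satisfy the
3-consecutive-window rule regardless of alignment. Per-base motif mutation
rate defaults to 5 %.

What the fixtures do **not** emulate: real base composition and repeat
structure, chromatin context, peak-strength distributions, degenerate and
rearranged motif variants, or the GO DAG. Passing the synthetic end-to-end
tests therefore demonstrates that the machinery recovers the structure it
is designed for, not that the trained model transfers to real promoters —
real-data performance requires the ENCODE-scale corpus and is out of scope
here.

## Benchmark problem sizes

The end-to-end benchmark (`srescan.benchmark`) trains on 4,000 windows
with 1,000 held out (25 seed couples × 100 after augmentation, matched by
2,500 control windows, split 4:1), scans 200 promoters (30 % carrying a
planted couple), and occludes the best window of up to 30 called
couple-bearing promoters. These sizes give each measured rate enough
support to be stable while keeping a full run in the minutes range on a
single CPU.

## Known limitations

- The conditional-MLE confidence interval is one defensible exact choice;
  other implementations print slightly different exact intervals. Only the
  point estimate is treated as a hard reproduction surface.
- The architecture beyond the reference constraints (pooling widths, dense
  width, dropout rate) is a reconstruction, configurable but not tuned.
- The wiggle reader supports per-base (step=1) fixedStep and bedGraph
  tracks only — the resolution conservation scores ship at; bigWig random
  access is unnecessary at this scale.
- `find_couples` keeps one nearest NF-Y per SRE peak; many-to-many
  pairings are not enumerated.
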