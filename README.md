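# srescan

Detection of composite sterol-responsive regulatory regions in gene
promoters with a 1-D convolutional neural network, followed by Gene
Ontology enrichment of the called genes and occlusion saliency over the
bases that drive each call.

## The problem

SREBP transcription factors sense intracellular cholesterol and activate
genes through short **sterol responsive elements (SRE)** that are usually
flanked, at variable distance and arrangement, by an **NF-Y** (CCAAT-box)
site and sometimes SP-1 sites. Because the grammar is modular — the same
elements appear shuffled, spaced differently, or on opposite strands — a
fixed consensus search misses many functional sites. A convolutional
classifier is a natural fit: convolution plus global max-pooling detects
the element combination irrespective of position.

The workflow, aimed at regulatory genomicists:

1. **Pairing** — SRE ChIP peaks with an NF-Y peak center closer than 250 bp
   become positive examples; 100-bp windows (±50 around the SRE peak
   center) are extracted. Control-peak windows at least 250 bp from any
   SRE/NF-Y center form the negative set.
2. **Augmentation** — each positive window is copied 100× with exactly 20
   point mutations per copy; mutated positions are drawn by roulette-wheel
   selection with slices proportional to the *inverse* of the per-base
   phyloP score, `w_i ∝ 1/(s_i − min s + ε)`, so conserved (presumably
   functional) bases are rarely touched.
3. **Encoding** — every window is doubled to forward + reverse complement
   (200 symbols) and one-hot encoded over `(null, a, t, c, g)` into a
   200×5 binary matrix.
4. **Classifier** — conv(64, k=6, ReLU) → max-pool(2) → conv(64, k=6,
   ReLU) → global max-pool → dense(64, ReLU) → dropout(0.3) → dense(1,
   sigmoid); binary cross-entropy, Adam 1e-3, batches of 512 encoded on
   the fly; up to three epoch blocks of 40/30/10 with early-stopping
   patiences 15/10/5 on validation accuracy, best weights restored. The
   network (forward, backward, optimizer) is implemented in NumPy.
5. **Promoter scan** — the 500 bases upstream of each TSS (strand-aware,
   read 5′→3′ toward the TSS) are scanned with 100-bp windows at a 20-bp
   step (21 windows); a promoter is called positive when ≥3 *consecutive*
   windows score > 0.9.
6. **GO enrichment** — for every Biological Process term, enrichment of
   positive promoters is the cross-product ratio of the proportions table
   `[[pos_in, pos_out], [n_in, n_out]]`, i.e. the ratio of positive-gene
   fractions inside vs outside the term, with exact-conditional CI and
   Fisher exact p on the same table (the conventional case/control OR is
   reported in its own column).
7. **Occlusion** — for high-probability windows (100-bp windows at a 5-bp
   step across the promoter), the probability is recomputed 100 times with
   one base zeroed per pass (both strand copies); the per-base probability
   loss, averaged over qualifying windows, localizes the driving bases.

Everything is testable offline: `srescan.fixtures` generates a mini-genome
with planted SRE/CCAAT couples, ChIP-like peaks, a phyloP-like track,
transcripts, and GO groups — with full ground-truth tables.

## Worked example

The enrichment statistic on a mismatch-repair-sized contingency row
(14 of 17 in-group genes positive vs 3008 of 25185 outside):

```python
>>> from srescan import enrichment
>>> o, (lo, hi), p, _ = enrichment.enrichment_statistic(14, 17, 3008, 25185)
>>> print(f"odds ratio = {o:.2f}  95% CI = ({lo:.2f}, {hi:.2f})  Fisher p = {p:.2e}")
odds ratio = 6.90  95% CI = (3.14, 14.88)  Fisher p = 1.14e-06
```

The value is the ratio of positive fractions (0.82 in-group vs 0.12
out-group); the conventional case/control OR on the same counts is 34.4
and is emitted separately.

A toy end-to-end run on generated data (seconds; far too small to train a
useful model, but exercises every stage):

```sh
$ srescan --seed 2 --config config.yaml --outdir out all
INFO srescan: simulate: wrote fixture set to out/fixtures
INFO srescan: pair: 6 couples, 6 positives, 20 negatives
INFO srescan: augment: 33 train / 11 validation windows
INFO srescan: train: best validation accuracy 0.5455 over 2 epochs
INFO srescan: scan: 0/12 promoters called positive
INFO srescan: occlude: profiled 0 called promoter(s)
INFO srescan: enrich: 4 terms ranked
```

At study scale (`srescan.benchmark.run_benchmark`, 4,000 training /
1,000 validation windows, 200 promoters) the classifier reaches held-out
accuracy ≈ 0.96, calls > 80 % of couple-bearing promoters and < 5 % of
motif-free ones, and occlusion saliency lands on the planted motifs — see
the reproduction script below, which prints the exact numbers for your
seed.

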