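# Methods

## Problem and model

Lifestyle prediction is cast as binary sequence classification: given a
phage contig, output the probability that the phage is virulent (strictly
lytic) rather than temperate (lysogeny-capable). Temperate phages carry
integration machinery (integrases, excisionases, repressors) that virulent
phages lack, so the nucleotide composition of even short windows carries
signal; the classifier operates on fixed-size segments and the contig call
aggregates segment evidence.

**Segmentation.** Training contigs are sampled into segments of
`segment_len = 512` bp at an expected per-base coverage of 10×: the number
of draws is `N = ceil(coverage · L / segment_len)` with start positions
uniform on `[0, L − segment_len]`, with replacement. `ceil` guarantees
short contigs are never under-sampled; a contig shorter than one segment is
emitted whole, `ceil(coverage)` times. Every drawn segment also contributes
its reverse complement, because assembly orientation is arbitrary. At
inference time contigs are tiled contiguously (`[0,512), [512,1024), …`);
a final partial window is kept iff ≥ `min_tail = 50` bp — shorter tails
tokenize to almost nothing and only add noise. Coordinates are 0-based
half-open throughout.

**Tokenization.** Local Context Aware (LCA) tokenization slides a k-mer
window by `shift ≤ k`: tokens are `seq[i:i+k]` for `i = 0, shift, 2·shift, …`.
The vocabulary is fixed and reproducible — `[PAD], [UNK], [CLS], [SEP]`
followed by all `4^k` k-mers in lexicographic order — so token ids are
bit-identical across runs. Windows containing `N` map to `[UNK]` rather
than being dropped, preserving positional structure. Stock variants:
`mini` (k=6, shift=1) and `mini-c` (k=1); the encoded form is
`[CLS] tokens [SEP]` padded to `max_len`, truncation keeps `[SEP]` last.

**Encoder and pooling head.** A pre-norm transformer encoder (multi-head
self-attention, GELU feed-forward of width `4·d`, learned absolute position
embeddings) produces one hidden state per token. The classification head
pools them with learnable weights: a trainable scoring vector `u` gives a
scalar `s_i = h_i · u` per position, scores at PAD positions are masked
before a softmax over real positions, and the pooled vector is
`Σ α_i h_i`. PAD positions receive exactly zero pooling weight and are
masked out of attention, so padding provably cannot change a prediction
(tested). A linear map to two logits and a softmax yield
`(P_tem, P_vir)`; class order is fixed as temperate = 0 (negative class),
virulent = 1.

Two presets: *tiny* (2 layers, 4 heads, width 64) trains on one CPU in
minutes and is the desk-scale workhorse; *paper-scale* (6 layers, 6 heads,
width 384) mirrors the published head geometry. The exact published pooling
formula lives in that model's supplementary material and is not available;
the single-scoring-vector head here is the minimal faithful reading of
"pooled with learnable weights" and is a deliberate, documented stand-in.

**Training.** Cross-entropy loss, AdamW (decoupled weight decay 0.01,
applied to matrices only — biases and LayerNorm parameters are not
decayed), default learning rate 1e-4 (the fine-tuning value; see below for
the from-scratch setting). Per-epoch validation balanced accuracy is
logged and the best-validation checkpoint is retained. All initialization
and batch shuffling flow from one seeded generator, so identical
(seed, data, device) gives bitwise-identical loss traces. The whole
network, including backpropagation and the optimizer, is implemented in
NumPy; gradients are verified against central finite differences in the
test suite.

**Weighted voting.** Segment probabilities combine into
`P_vir(contig) = Σ w_i p_i / Σ w_i` with `w_i` = segment length in bases,
so a 50 bp tail cannot outvote a 512 bp window; the scheme is
permutation-invariant, bounded by the extreme segment probabilities, and
monotone in each input. Ties at the 0.5 threshold resolve to virulent.
Segments too short to tokenize (< k bases) get a flagged neutral p = 0.5
and are excluded from the vote whenever any informative segment exists.
With strand augmentation the reverse complement of the contig is tiled
separately and its segments join the same vote, which makes the contig
call exactly invariant to input orientation (the union of the two tilings
is the same for a contig and its reverse complement). Summation uses
`math.fsum`, so the vote is exactly permutation-invariant in float
arithmetic.

**Leakage control.** Pairwise similarity is estimated with bottom-k
MinHash: the 300 smallest distinct 64-bit MurmurHash3 values (seed 3) of a
sequence's canonical 21-mers. Canonical (strand-minimum) k-mers are used
because the pipeline treats both strands as equivalent; the hash is the
low 64 bits of MurmurHash3 x64-128 over the ASCII k-mer, little-endian —
fixed and documented so signatures are portable, and verified against the
standard self-test vector of that hash. Jaccard is estimated by the
bottom-k merge estimator, and ANI by the Mash relation
`ANI = 1 + ln(2j/(1+j))/k`, clipped to [0,1]; `j = 0` is reported as ANI 0
with an explicit undefined flag. FastANI all-against-all output (5-column
TSV) can be ingested instead, which adds the aligned-fragment fraction.
Strict holdout removes every training record with ANI ≥ 0.80 (inclusive,
"at least 80 %") to any test record — additionally requiring aligned
fraction ≥ 0.80 when FastANI supplies it; a sketch cannot yield an aligned
fraction, so the sketch path applies the ANI clause alone and records that
in the removal report. The 80 %-of-length clause is evaluated on the
training-side record (the FastANI query). Standard holdout removes
nothing.

**Metrics.** Virulent is the positive class everywhere. Accuracy, balanced
accuracy (= (sensitivity + specificity)/2), sensitivity, specificity, F1
and MCC; any ratio with a zero denominator is reported as NaN with an
explicit flag, never silently 0. Inference speed is end-to-end classified
nucleotides per second: the clock spans everything the predictor does
(parsing, preprocessing, inference, aggregation), each contig's bases
counted once regardless of strand augmentation; no speed number is treated
as a reference value because it is hardware-bound.

## Synthetic data: what it emulates and what it does not

The generator plants class-specific signal in random background: each
genome (default 20–100 kb, GC 0.5, iid or first-order Markov background)
receives `cassettes_per_genome = 100` non-overlapping copies of 30-bp
motifs drawn from its class's motif set, each copy independently
point-mutated at rate 0.02. The two default motif sets are fixed constants
chosen once so that they share no canonical 21-mer (validated at
construction). This abstracts the real biology — distinct gene repertoires
(integrase/excisionase vs lysis and nucleotide-metabolism genes) — into a
k-mer-composition signal.

The cassette density was calibrated once to reproduce the qualitative
difficulty gradient of fragmented assemblies: ~100 cassettes per genome
(≈ 3 kb, a few percent of the genome, comparable to a lifestyle-diagnostic
gene complement) means a 500 bp fragment contains a cassette only ~half to
three-quarters of the time (hard), while a 10 kb fragment almost surely
contains several (easy), so accuracy rises with fragment length as it does
on real data.

Divergence families are pure point-mutant descendants (no indels), so the
true ANI of a descendant against its ancestor is exactly `1 − divergence`
in expectation — analytically known for leakage-filter tests: 5 %
divergence (ANI ≈ 0.95) must be caught by the ≥ 0.80 rule, 30 % (ANI ≈
0.70) must be retained.

What passing tests on this generator do **not** show: performance on real
phage genomes (no gene structure, codon bias, mosaicism, GC skew or
sequencing error is modeled), robustness to contamination or non-viral
input, and the published accuracy tables (which require the original
pretrained genomic language models and curated genome collections).

## Desk-scale study conditions

The end-to-end experiment (`phastyle.experiments.run_experiment`) uses
problem sizes chosen for a single CPU: 50 genomes per class (70/10/20 %
train/val/test split per class), training segments at 10× coverage
subsampled to a class-balanced budget of 4000 (of order 100k are drawn;
the subsample keeps the uniform-start distribution), validation budget
600, the tiny preset with dropout 0.1 (the tiny model can memorize a
few thousand segments within five epochs, which biases background-segment
predictions and destabilizes contig votes; dropout plus the larger unique-
segment budget suppresses that), ≤ 5 epochs, batch 32, and 30 fragments
per class per length. Two further training choices differ from the
fine-tuning defaults and are deliberate: the desk-scale tokenizer uses the 6-mer LCA variant at
shift 3 (171 tokens per 512 bp segment — attention cost scales with the
square of token count, and the larger stride loses little signal because
every 30-bp cassette still contributes ~8 distinctive 6-mers at any
phase), and the learning rate is 1e-3 because the tiny model trains from
random initialization rather than from pretrained weights, so the
fine-tuning rate of 1e-4 underfits within a 5-epoch budget.

## Numerical conventions and edge cases

- Reading FASTA uppercases and maps every non-ACGTN character to N
  (counted, logged); duplicate ids are an error, as are empty files.
- k-mer windows containing N are skipped by the sketcher (an undocumented
  choice in the original procedure; skipping is ours) and map to `[UNK]`
  in the tokenizer.
- Tiny sketches (sequence with fewer distinct k-mers than the sketch size)
  hold the full hash set; Jaccard then uses the smaller set size as the
  denominator.
- LayerNorm epsilon 1e-5; GELU uses the tanh approximation; softmax is
  max-shifted; cross-entropy is computed in float64 on top of float32
  activations.
- Training start positions are drawn with replacement (the expected-
  coverage contract constrains only the mean).
- NaN loss aborts training with a diagnostic rather than continuing.
- Vote ties at exactly the threshold resolve to virulent; the threshold is
  a parameter, default 0.5.

## Known limitations

- The encoder is NumPy on CPU: appropriate for the desk-scale presets and
  tests, not for training the paper-scale preset on millions of segments.
- The pooling head is a stand-in for an unpublished formula (see above);
  likewise the exact published voting weights are unavailable, and
  length-weighting is our documented reading of "weighted voting".
- Sketch-based strict holdout cannot evaluate the aligned-fraction clause;
  use FastANI ingestion when that guarantee matters.
- The ANI-from-Jaccard relation assumes a Poisson mutation model and
  breaks down for very low Jaccard (reported as undefined at j = 0).
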