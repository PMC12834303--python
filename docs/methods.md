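# Methods

## Problem setting

A draft scaffold is a nucleotide string over {A,C,G,T,N}; maximal runs of
N are gaps. The package predicts the masked bases of each gap from its
flanks, screens the predictions, and patches the survivors back in.
Coordinates are 0-based half-open everywhere, including BED output. At
read time lowercase is uppercased and IUPAC ambiguity codes other than N
collapse to N (strict mode rejects them instead): the model alphabet is
exactly five letters, and silent alphabet drift is the kind of bug this
policy exists to prevent.

## Next-base model

One-hot input (channel order A,C,G,T — serialized into every model file
and checked at load, so a trained model can never be decoded under a
different convention) feeds:

1. 1-D convolution, kernel 3, stride 1, zero padding 1, ReLU;
2. batch normalization (batch statistics during training, running
   statistics at inference — exponential average, momentum 0.1);
3. non-overlapping temporal max pool (size 2) and inverted dropout;
4. two stacked BiLSTM layers (layer 2 consumes layer 1's output);
5. an elementwise residual sum of the second BiLSTM's output with a
   width-1 convolutional projection of the CNN-block features, giving
   the recurrent stack a direct shortcut to local features;
6. max pool over time, affine map to 4 logits, softmax.

Training: 4-class cross-entropy on sliding (context → next base) windows
over N-free stretches, Adam (lr 1e-3), validation split 0.1, early
stopping on validation loss with the best-validation parameters
restored. All arithmetic is float64 NumPy; with a fixed seed, data and
thread policy, training and inference are bit-reproducible. Dropout is
disabled at inference — the beam search's cost bookkeeping requires a
deterministic oracle.

Why NumPy: the architecture is the package's own contribution, and no
deep-learning framework is a dependency; the layer library
(`gapfill.nn`) implements exactly the forward/backward passes above and
is validated against central finite differences on every parameter
tensor (rtol 1e-4) in the test suite.

Defaults (`ModelConfig`/`TrainingConfig`): window 64 bases,
64 conv channels, 128 LSTM units per direction, dropout 0.1, pool 2,
batch 128, up to 50 epochs with patience 5. These are conventional
capacity/recipe choices; the architecture fixes only the layer
structure. The packaged studies (acceptance script, end-to-end tests)
use 16 conv channels and 32 LSTM units with ≤ 6–12 epochs — the
repeat-continuation task the simulator poses saturates at this size,
and it keeps a full study in minutes on one CPU; these sizes are the
package's stated study conditions, not tuned quantities.

One model serves both strands: right-flank prediction runs the search on
the reverse complement of the right flank and reverse-complements the
result. This halves training cost and encodes the strand symmetry of the
task; it assumes the training genome's composition is not strongly
strand-asymmetric at the motif scale.

## Search

Each step, every surviving hypothesis is expanded by all four bases; the
four children share one oracle call. Scores:

- g accumulates |ln p| of the chosen base, with probabilities floored at
  p_min = 1e-9 (the cost is undefined at 0).
- The entropy term uses the full 4-vector distribution at every step,
  normalized by n·ln 4, so it lies in [0,1] by construction.
- The remaining-length term counts newly predicted bases only:
  ln(target − predicted)/ln(target), 1 at the start, 0 at one base left
  and beyond (terminating convention).
- The GC term compares the candidate child (current sequence plus the
  proposed base, seed included) with the current sequence.
- Weights α = β = γ = 1 and natural log by default; unit weights make
  the closed forms directly testable, and tuning is data-dependent.

Beam width: linear interpolation w_init → w_max over the first
`contract_at` fraction of the target length, then linear w_max → w_final
over the remainder, rounded, minimum 1. Defaults w_init = w_final = w/2,
w_max = w, contract_at = 0.75 for a peak width w ∈ {16, 32, 64}. The
relax-then-shrink shape keeps alternatives alive while the prediction
context is still mostly flank, then prunes as the context becomes
self-generated.

Ties break by (f, channel order of the last base, lexicographic
sequence). This total order makes the search deterministic, which is
what the nested-beam monotonicity and reference-equivalence tests
require. Target length defaults to the observed N-run length — the only
in-scaffold evidence of gap size — and is overridable per gap.

Bidirectional mode runs both directions and reconciles two same-length
candidates by splicing at the midpoint of their longest exactly-agreeing
run (≥ 10 bases by default); if they never agree that long, the
lower-f candidate wins. Since both candidates cover identical
coordinates, "merge at the best overlap" degenerates naturally to this
splice; two identical candidates are returned unchanged.

## Prediction filter

Alignment is Biopython's `PairwiseAligner`, local mode, +1/−1 match/
mismatch, −2 gap open, −1 extend. The rate is identical aligned bases ÷
candidate length, so rate 1 means the candidate occurs exactly in the
homolog region; N matches nothing. The candidate is aligned *bare*
(flanks would dominate the rate and let random fills pass), while the
baseline aligns the original N-run plus a 50-base flank margin each side
against the same region — the margin makes the baseline nonzero and
pins it to how well "leaving the gap open" already explains the region.
Available ⇔ rate ≥ τ (default 0.9) ∧ rate > baseline. The edit distance
reported alongside comes from edlib and is cross-checked against the
aligner in tests.

Homolog regions come from a gap-id-keyed FASTA or from the simulator's
truth genome (gap ± 50 bases). Candidates with no homolog are disposable
by default (strict mode errors instead): with no evidence, the filter
refuses rather than guesses.

## Simulator

Genomes alternate ~5 kb blocks of two regimes: *unique* (i.i.d. bases,
P(G)=P(C)=gc/2) and *repeat* (tandem copies of one motif drawn once per
genome, phase-locked to absolute position so a fully repetitive genome
is exactly periodic). Defaults: 50 kb, GC 0.45, motif 21, repeat
fraction 0.5. Gaps (default 20 of 20–100 bp) are split evenly between
repeat blocks — where flank context fully determines the missing bases,
so recovery is achievable and scorable — and unique blocks, where fills
are information-free and must be caught by the filter. Gaps keep 200
bases of spacing and never sit within a flank length of scaffold ends.
Every masked base is recorded in a truth table; re-inserting all truth
sequences reconstructs the genome byte-for-byte (tested).

What the simulator does *not* model: sequencing error, coverage
variation, heterozygosity, interspersed/diverged repeat families, and
real genomes' long-range composition structure. Passing the packaged
studies therefore shows that the machinery is correct and that the
pipeline recovers what is recoverable and rejects what is not — it does
not certify fill rates on real assemblies, where predictability lies
between the two simulated extremes.

A seeded order-k Markov oracle (Dirichlet(1,1,1,1) rows over 4^k
contexts) stands in for the trained model in search tests, because its
brute-force optimum is enumerable.

## Evaluation

A gap counts as filled when its coordinate-tracked interval contains no
N after patching; partial reductions are reported separately, since the
field's "gaps closed" counts full closures. N's per 100 kb is total N ÷
total length × 1e5. Mismatches per 100 kb compare patched scaffold to
truth positionally when lengths agree (pipeline fills are
length-preserving) and fall back to an edlib alignment walk otherwise,
always excluding N positions. GC profiles use non-overlapping windows
(default 1 kb), excluding windows that contain any N, binned at 1%.
Contig-length statistics (Nx families, misassembly curves) are
deliberately out of scope — they measure assemblers, not gap fillers.

## Numerical and degenerate-input choices

- Probability floor 1e-9 before every log; oracle rows are validated to
  sum to 1 within 1e-6.
- Entropy of an empty trace is 0; remaining-length term is 0 at or past
  the target; `norm_rem_len` requires target ≥ 2.
- Empty FASTA files parse to empty lists; a gap inventory with no gaps
  is an empty BED, not an error.
- Gaps whose usable flank is shorter than 50 bases are skipped with a
  warning — the model has too little context to say anything.
- Zero-epoch training returns the initialized weights unchanged;
  divergence (non-finite loss) raises with the epoch in the message.

## Problem sizes in the packaged studies

The acceptance study uses the 50 kb default fixture, a
16-channel/32-unit window-64 model trained on windows strided by 4 for
≤ 6 epochs, beam peak width 16, and bidirectional fills; search
properties use 10 order-2 Markov oracles at target length 6 with beam
4096 against exhaustive enumeration of the 4096 completions. The
determinism test uses a 12 kb fixture with a window-32 model. These
sizes are the package's chosen study scale.

## Known limitations

- Fills are length-preserving (target = N-run length); true gap lengths
  in real scaffolds are estimates, and indel-style corrections are not
  attempted.
- The filter needs a homolog or truth region; without one it can only
  pass everything through as disposable.
- Training is single-CPU NumPy: practical for the packaged study sizes
  and small genomes, not for chromosome-scale corpora.
- The entropy, remaining-length and GC weights are not auto-tuned; they
  are exposed as flags and default to 1.
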