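# Methods

This note records the model conventions, the numerical choices, what the
synthetic generator does and does not emulate, and the limitations we
know about. Nothing here states an empirical number that the test suite
or `scripts/acceptance.py` does not itself compute.

## Label alphabets and the 8-to-3 reduction

The eight-state alphabet is ordered `H G I E B T S C` (helices, strands,
coil-like states); the three-state alphabet is `H E C`. Index/symbol
mappings are fixed by these orders. The coarse-graining follows the
common DSSP convention — H, G, I to helix; E, B to sheet; T, S, C to
coil — and is exposed as a configurable table because other conventions
(e.g. mapping G to coil) exist in the literature. Label files use a
FASTA-like dialect (`>id` then a state string) with case-sensitive id
matching against the sequence FASTA and a length check at load time.
Nonstandard residue letters (B, Z, U, O, J, anything unknown) map to `X`,
which has its own token-embedding row, so sequence and label lengths
never diverge.

## Input features

**Positional encoding.** `PE(pos, 2i) = sin(pos / 10000^(2i/d_model))`
and `PE(pos, 2i+1) = cos(...)` with **0-based** positions, making the
first row the canonical `(0, 1, 0, 1, ...)` vector. Each (even, odd)
component pair lies on the unit circle by construction; the
implementation is asserted against the closed form to 1e-12 over all
positions up to 1000 at width 512.

**Fusion.** The PLM embedding (L x 1024 by provider contract) and the
sequence encoding (token embedding + positional encoding, L x d_model)
are fused by row-wise **concatenation**. Summation after projection is a
plausible alternative; concatenation was chosen because it preserves
both information sources and lets the backbone's first projection learn
the mixing. Either side can be ablated, in which case the remaining side
passes through unchanged.

**Embedding providers.** `mock` draws each row from a generator seeded
by a hash of (seed, sequence string, position, residue): deterministic,
batch-independent, approximately unit variance, and free of any label
information — it exercises shapes and plumbing, not biology. `cache`
reads per-id L x dim matrices from HDF5 (the synthetic generator writes
this format, so the synthetic path exercises the real I/O). `prott5`
is an adapter slot for a real half-precision PLM encoder and requires
the optional `transformers` dependency plus downloaded weights; nothing
in the package or tests depends on it. Sequences longer than 2000
residues are truncated with a warning (no maximum is inherent to the
model; the cap bounds memory).

## Backbone

Stage order is Transformer encoder (feature enhancement), then CNN, then
BiLSTM (feature extraction), then an affine emission head; local motifs
are extracted before the bidirectional recurrence integrates them.
Defaults follow the published operating point — d_model 512, 6 encoder
layers with 8 heads, 3 convolutional layers, 256 LSTM units per
direction — with unprinted details (feed-forward width 4 x d_model,
kernel 3, ReLU, dropout 0.1, post-norm residuals per the "add and norm"
wording) exposed in `BackboneConfig`. `BackboneConfig.desk_scale()` is
the CPU profile used by the tests: d_model 32, 1 encoder layer with 2
heads, 1 convolution, 32 LSTM units.

Variable-length batches are right-padded with a boolean mask threaded
through every stage: padded keys receive a -1e30 additive attention
bias, rows are zeroed before each convolution so padding behaves like
beyond-the-end zeros, and the backward LSTM reverses each sequence
within its own length. The test suite asserts that extending a batch
with padding moves no real position's emission score beyond 1e-5 (in
practice the agreement is ~1e-12).

The emission head applies no softmax: the CRF consumes raw scores and
normalizes globally over paths.

## Autodiff core

No deep-learning framework is used. `sslabel.autodiff` is a small
reverse-mode tape over float64 NumPy arrays implementing exactly the
operations the backbone needs (broadcasting arithmetic, batched matmul,
softmax, layer norm, same-length 1-D convolution, gathers, dropout).
Keeping the op set minimal is what makes it verifiable: every op's
gradient is tested against central finite differences, including an
LSTM-style recurrent composite. Float64 plus single-threaded NumPy makes
two runs of the same seed bitwise identical.

## CRF

A label path is scored as
`start[y_1] + sum_t e[t, y_t] + sum_t T[y_{t-1}, y_t] + stop[y_L]`.
Design choices:

- **Boundary scores.** Learnable start/stop vectors are included
  (standard linear-chain practice), initialized to zero, with a config
  flag (`crf_boundary`) to freeze them for a boundary-free chain.
- **Log-space throughout.** The partition function is computed by the
  forward recursion with logsumexp and max subtraction; the literal
  exponential form overflows beyond roughly a hundred residues.
- **Tie-breaking.** Every max takes the lowest state index, so decoding
  is deterministic; on an all-zero instance Viterbi returns the all-0
  path.
- **Zero transition init.** The chain initially behaves like an
  independent softmax, which makes ablation comparisons clean and keeps
  the initial NLL per residue at log K.
- **Gradients.** The NLL gradient is computed exactly from
  forward-backward marginals (marginals minus one-hot observations), not
  by differentiating through the recursion; it is checked against
  central finite differences (1e-5 step) in every parameter block.

`brute_force_oracle` enumerates all K^L paths (vectorized, capped at
1e6 paths) and exists solely as the independent test oracle for the
recursions and for Viterbi.

## Metrics

Q is the percentage of positions with matching state, with per-class
recalls alongside. Sov sums, over pairs of same-state overlapping
segments (S1 true, S2 predicted),
`(minov + sigma)/maxov * len(S1)` with
`sigma = min(maxov - minov, minov, len(S1)//2, len(S2)//2)`
(floor division), where minov is the actual-overlap length and maxov the
extent of the union.

Two normalizations are provided. The default divides by N, the total
residue count of the sequence. This form has two consequences worth
knowing: a true segment with no same-state partner simply contributes
nothing (predictions lose credit only through the numerator), and when
one true segment overlaps several predicted fragments its length is
counted once per pair in the numerator but once in N, so the score can
exceed 100 (e.g. true `HHHHHH` vs predicted `HHCHHH` scores 116.67; a
pinned test documents this). The `sov99` variant normalizes by the sum
of len(S1) over pairs plus len(S1) over partnerless true segments — the
1999 redefinition — which is bounded by 100 and is the right choice for
comparison with other tools' published Sov values; the default form may
score below or above them. Corpus-level Sov pools numerators and
denominators over proteins (micro) and also reports the unweighted
per-protein mean (macro).

## Synthetic data

The generator emulates the two statistical properties the architecture
exploits: first-order Markov label structure (so same-state runs are
geometric; diagonal 0.85 gives mean run length 1/(1-0.85) ≈ 6.7) and
label-coupled emissions (feature row = class mean + isotropic Gaussian
noise, optional width-3 smoothing to mimic local context). The
three-state default forbids the helix-to-sheet transition outright and
the eight-state default forbids direct helix/strand jumps, giving the
transition matrix real grammar to learn.

Class means sit on orthogonal axes at separation 2.3 with unit noise
(feature dimension 64 rather than 1024 so the full train/test loop runs
in minutes on one CPU). At these values the pairwise mean distance is
2.3·sqrt(2), putting the position-wise Bayes accuracy near 0.90 — chosen
so that per-position information alone cannot saturate the task and
run structure is worth several points to a decoder that uses it. The
generator writes standard FASTA + label files + the HDF5 embedding
cache, so synthetic runs exercise the real I/O path.

What the generator does **not** emulate: amino-acid composition (residue
strings are uniform random and carry no label signal), realistic DSSP
state frequencies or segment-length distributions, long-range contact
effects, or the anisotropic, highly structured geometry of real PLM
embeddings. Passing the synthetic studies therefore demonstrates that
the machinery — feature fusion, masking, optimization, CRF recursions,
decoding, metrics — is correct and learns the structure it was built to
learn; it does not predict benchmark accuracy on real proteins.

## The ablation study and an honest negative finding

The desk-scale study (`sslabel.experiments.crf_ablation_study`) trains
the full model and a no-CRF ablation (per-position cross-entropy,
argmax decoding) on the Markov corpus, 200 sequences of length 40-60,
30 epochs, Adam at 1e-3, batch 8, a seeded 90/10 validation split, and
evaluates the best-validation checkpoint on held-out sequences.

Finding: the full model reliably reaches the ~95% regime, but it does
**not** beat the separately trained no-CRF ablation by a meaningful
margin under these conditions. The mechanism is visible in the learned
parameters: the gradient of the CRF NLL with respect to the transition
matrix is expected-minus-observed transition counts, and when emissions
come from a bidirectional backbone that already encodes label context,
expected counts match observed ones and the transition matrix stays
near zero — Viterbi then nearly coincides with argmax. Asymptotically a
cross-entropy model approximates posterior-marginal decoding, which is
optimal for token accuracy, so no fixed Viterbi margin can be guaranteed
in this regime.

The CRF's contribution is isolated instead by making the emissions
local: with the Transformer/CNN/BiLSTM stages ablated (a position-wise
emission model), decoding with the learned transition matrix beats
decoding the same emissions without it by several points, the learned
transitions recover the diagonal/forbidden structure of the generating
chain, and Viterbi produces no more forbidden helix-to-sheet adjacencies
than argmax. That comparison is asserted in the test suite; the
full-vs-ablated margin is reported, not assumed.

## Numerical and procedural details

- All computation is float64; determinism is bitwise for fixed seed and
  BLAS (the determinism study asserts identical reports across two runs).
- Gradient clipping at global norm 5 guards the recurrence early in
  training; Adam (0.9, 0.999, eps 1e-8) is the only optimizer wired in.
- A non-finite loss aborts training with a diagnostic rather than
  continuing.
- `epochs=0` is valid and yields the initialized model (useful for
  testing checkpoint plumbing).
- Checkpoints are .npz archives of named parameter arrays plus the JSON
  run configuration; the transition matrix can be exported as labeled
  CSV for inspection.
- The desk-scale study sizes (200/50 sequences, lengths 40-60, 30
  epochs) were chosen as the smallest corpus on which the studied
  effects are comfortably measurable.

## Known limitations

- The `prott5` provider is an interface, not a bundled encoder; real-
  protein benchmarking additionally needs curated datasets that are not
  part of this package.
- Training is CPU-oriented and pure NumPy: fine at desk scale, not
  intended for the published operating point's corpus sizes.
- Viterbi is the only decoder (no posterior-marginal decoding), and the
  CRF is strictly linear-chain with emission + transition features.
- The literal Sov normalization is unbounded above, as discussed; use
  `sov99` when comparing across tools.
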