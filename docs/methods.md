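# Methods

This note documents the models, estimators and numerical choices behind
`probseq`, the design decisions taken where more than one reasonable option
existed, and what the synthetic-data studies do and do not demonstrate.

## Conventions

All probabilities are stored and combined in natural-log space; −∞ represents
exact zero. Coordinates are 1-based inclusive at the API surface and 0-based
internally. Sequences are index-encoded over an ordered token alphabet;
tokens need not be single characters, so sequence I/O accepts both FASTA (for
single-character alphabets) and a `name: tok tok ...` one-record-per-line
format, which the writer emits. Every sampling operation takes one explicit
seeded generator; there is no global RNG state.

For chain-family models, `log_probability(seq, begin, end)` conditions each
position on the *actually available* history in the full sequence (falling
back to lower-order tables near the sequence start). This makes a window
likelihood equal to a prefix-sum-array difference, which is what the GHMM
decoder relies on. Fixed-width signal models (WAM, SBSW, composites)
condition only within their own window.

## Estimators

**Counts and pseudocounts.** All chain estimators add a pseudocount
(default 10⁻⁴) wherever observed counts can be zero: large enough to avoid
spurious −∞ on held-out data, small enough to leave estimates essentially
untouched. A context never observed at all falls back to the uniform
distribution.

**VLMC.** The context tree is grown to `max_depth` (all contexts are
materialised when |Σ|^depth ≤ 4096, so unseen contexts behave exactly like a
fixed-order chain's unseen rows; beyond that only observed contexts are
kept). Pruning is bottom-up: a childless context `w` with `n_w` observations
is removed when 2·n_w·KL(P(·|w) ‖ P(·|parent)) < cut. The two limits are
exact reductions: cut = ∞ gives the i.i.d. fit, cut = 0 the order-`max_depth`
chain — both are asserted to 1e-9 in the tests.

**IMM.** Interpolation follows the Glimmer recipe: a context with at least
400 observations trusts its own order fully (λ = 1); otherwise
λ = c·n/400 (clipped to [0, 1]) where c is the χ² confidence (df = |Σ|−1)
that the context's next-symbol counts deviate from the interpolated
lower-order prediction. Interpolated conditionals are convex combinations,
so rows stay normalised by construction. Three-periodic IMMs keep three
phase-indexed table sets; training sequences are assumed to start on a codon
boundary.

**SBSW.** A query scores
`[count(q) + ε·Σ_{Hamming=1 off-skip} count(t)] / Z` with ε = 0.001 by
default; Z has the closed form N·(1 + ε·W_free·(|Σ|−1)), so the scores form
a proper distribution over the off-skip pattern space (checked exhaustively
for small widths). Queries lacking the mandatory consensus (e.g. donor GT)
score −∞. Simulation samples the equivalent mixture (stored pattern, or
stored pattern with one uniform off-skip mismatch) and is therefore exact.

**Smoothed duration histograms.** Gaussian kernel on the integers with the
normal-reference bandwidth 1.06·σ·n^(−1/5), floored at 1; support 1..D with
D = ⌈1.5·max length⌉, renormalised after truncation. Probabilities below
10⁻¹² of the mode are zeroed (and the rest renormalised) so decoding loops
only over durations carrying real mass.

**Baum-Welch** accumulates expected counts in probability space from
log-space forward/backward tables; the log-likelihood trace is asserted
non-decreasing to 1e-10. Parameter-recovery tests resolve state relabeling
by scoring all permutations.

**Profile HMMs** use full match/insert/delete connectivity with begin/end
states (including I→D and D→I), match columns chosen by gap fraction <
`match_threshold` (default 0.5), and Laplace-smoothed emission/transition
counts. Scoring is global forward.

## GHMM semantics and decoding

A geometric state is *realised as* its self-transition: staying d steps
costs a_kk^(d−1), leaving costs the ordinary transition probability, and the
final segment of a decoded parse pays no exit term. Explicit-duration states
(fixed or histogram) may not have self-transitions; their segment weight is
the duration pmf. These conventions make an all-geometric GHMM with i.i.d.
emissions *exactly* a classical HMM, which is asserted against `hmm.viterbi`.

The optimized decoder uses: the d = 1 recursion with per-position emission
terms for geometric states; duration-support loops with O(1) prefix-sum
window scores for explicit states with factorable emissions (one cumulative
array per phase for periodic models); precomputed window-score arrays for
fixed-width signal states; and sparse predecessor lists throughout. Windows
containing a position of probability zero are skipped via a parallel
zero-count array — the practical effect of per-state non-zero skip lists.
The naive reference decoder scores every candidate segment with a direct
emission-model call and treats geometric states as unbounded explicit
durations; optimized and naive results are asserted identical (log-lik to
1e-9, same segments) on randomized mixed-duration architectures.

Tie-breaking is deterministic: shorter duration first, then lower state
index (durations are scanned ascending and comparisons are strict).

## The gene-finder architecture

27 strand-specific states per strand — start, stop, single exon, 3 initial
exons (by output phase), 9 internal exons (phase pairs), 3 terminal exons
(input phase), and 3 introns/donors/acceptors (by phase) — plus shared
intergenic and absorbing final states: 56 in total. Composite signal states
concatenate sub-models with build-time length validation: start = 20 + 3 + 4
= 27 nt, donor = 4 + 9 = 13 nt, acceptor = 32 + 6 + 4 = 42 nt.

Phase is the cumulative coding length mod 3. The signal states carry fixed
exonic contributions (start 7, donor 7, acceptor 6, stop 3), and each exon
state's histogram support is filtered at build time to lengths
d ≡ phase_out − phase_in (mod 3), renormalised. With the wiring
initial-exon-o → donor-(o+1 mod 3) → intron → acceptor → next exon at the
same phase, every parse of the grammar closes the reading frame; a grammar
validator over decoded simulations asserts this.

Reverse-strand states wrap the forward emission models in an exact
reverse-complement mirror, P_rc(s) = P_fwd(revcomp(s)). For count-based
estimators this coincides with training on reverse-complemented data, and it
guarantees the mirror identity exactly rather than up to training noise.
Prefix-sum scoring survives the wrapper by building the inner model's arrays
on the reverse-complemented sequence and mapping window coordinates.

The absorbing final state (self-transition 1) is reachable from intergenic
with probability 10⁻⁶ of the exit mass; at that level it only competes with
the intergenic state for trailing tails far longer than the sequences used
here.

## Synthetic data: what it does and does not show

The synthetic-gene generator emits intergenic background (AT-rich i.i.d.),
genes with a Kozak-like start context, strongly three-periodic coding
composition, canonical GT/AG splice signals with 0.9 per-position consensus
strength, uniform 30–90 nt exons (the last exon absorbs the mod-3 closure),
short introns (≥10 nt core, geometric mean 60) and 0–2 introns per gene, on
the forward strand. Sub-models are then trained on windows cut from these
simulations using the true segmentations, so the whole pipeline is
self-contained. These sizes keep an end-to-end study at a few seconds per
kilobase of decoding.

Passing tests therefore demonstrate *internal correctness and
recoverability*: the decoder finds the generating segmentation when the
model matches the data and the signals are strong. They do not demonstrate
accuracy on real genomes, where signals are weaker, lengths are longer and
heavier-tailed, composition varies with G+C content, and genes overlap the
reverse strand — none of which the generator emulates.

Problem sizes used by the test suite and the acceptance script: enumeration
oracles at K ≤ 3, L ≤ 8 (hundreds of random instances); naive-vs-optimized
GHMM checks at L ≤ 25; prefix-sum checks exhaustive at L = 50; Baum-Welch
recovery from 50 sequences of length 200; BIC order selection over 20
replicates at n = 5·10⁴; CpG segmentation at L = 5000; gene decoding on a
handful of ~1 kb sequences.

## The description language

The grammar (documented in `probseq.config`) has assignments, quoted
strings, numbers, tuples, nested maps, `file("path")` sub-model references
resolved relative to the referring file, and conditional-probability tables
written `"symbol" | "context": p` with the context in sequence order.
Serialization is canonical and prints probabilities with full round-trip
precision (`repr` of the float, up to 17 significant digits), so
parse ∘ serialize is the identity and a second serialization is
bit-identical; unspecified conditional rows default to uniform, and a
specified row that does not sum to 1 is an error naming the row and its sum.
Unknown keys are preserved with a warning.

## Known limitations

* Continuous emissions, quality scores and paired-end semantics are out of
  scope; alphabets are finite token sets.
* Pair-HMM decoding is O(K·n₁·n₂) in pure Python — fine for the intended
  model-checking scale, not for genome-length alignment.
* Memory-efficient (checkpointing) decoders are not implemented; the Viterbi
  matrices are O(K·L).
* Geometric states require period-1 factorable emissions (a periodic
  emission would make the d = 1 recursion frame-ambiguous).
* The gene finder has no promoter or poly-A states and uses a single model
  regardless of G+C composition.
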