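# probseq

Discrete probabilistic models of sequence data, in one coherent toolkit:
training, simulation, evaluation, decoding, model selection and Bayesian
classification over a shared model contract, plus a plain-text
model-description language and command-line programs.

## Who this is for

Analyses such as CpG-island calling, splice-signal scoring, protein-family
profiling and *ab initio* gene prediction all rest on the same small family of
discrete Markovian models, yet those models are usually hard-coded inside each
tool. `probseq` provides them as composable building blocks: any emission
model can be evaluated on its own, dropped into a Bayesian classifier, or
installed as the emission sub-model of a generalized-HMM state.

## The models

Eight families implement one contract (`log_probability`, `simulate`,
`parameter_count`):

* **i.i.d.** distributions and fixed-order **Markov chains**;
* **variable-length Markov chains** (VLMC) — pruned probabilistic suffix
  trees, with the pruning statistic 2·n<sub>w</sub>·KL(P(·|w) ‖ P(·|parent))
  compared against a user cut-off;
* **inhomogeneous chains / weight array models** (WAM) for fixed-width
  signals, including a windowed variant that pools counts across neighbouring
  positions;
* **interpolated Markov models** (IMM) with Glimmer-style χ²-weighted order
  interpolation, optionally three-periodic for codon structure;
* **similarity-based sequence weighting** (SBSW) signal models with a
  mandatory consensus (e.g. the donor GT) that is skipped when scoring;
* **HMMs** (forward, backward, Viterbi, posterior decoding, Baum-Welch),
  **profile HMMs** built from multiple alignments, and **pair HMMs** for
  two-sequence alignment;
* **generalized HMMs** (GHMM): states emit variable-length words from any of
  the above under geometric, fixed or smoothed-histogram duration laws.

GHMM decoding is the centrepiece. The Viterbi segment recursion is

$$\gamma_k(t) = \max_{d,\,j\ne k}\; \gamma_j(t-d)\; a_{jk}\; P_k(d)\; e_k(s_{t-d+1..t}),$$

which is O(K²L²·cost(e)) for an arbitrary architecture. The decoder inspects
the model and automatically exploits three properties when present: sparse
transitions (adjacency lists), bounded duration supports (explicit length
lists per state), and factorable emissions, whose window likelihoods are
served in O(1) from **prefix sum arrays** (one cumulative log-score array per
phase) after linear preprocessing — with windows containing a
zero-probability position skipped outright. A naive reference decoder with
identical semantics is kept alongside and the two are asserted equal in the
test suite.

Model selection uses BIC = −2 log L + k ln n and AIC = −2 log L + 2k (n =
total observed symbols), choosing the grid point with the smallest value.

## Worked example: a two-state CpG-island GHMM

```python
import numpy as np
import probseq as ps
from probseq.ghmm import ghmm_simulate, ghmm_viterbi

rng = np.random.default_rng(0)
cpg = ps.train_imm([ps.encode(list("CG" * 400), ps.DNA)], max_order=1)
bg  = ps.train_imm([ps.encode(list("AT" * 300 + "AATT" * 100), ps.DNA)], max_order=1)
g = ps.build_cpg_ghmm(cpg, bg, p_exit_noncpg=0.01, mean_cpg_len=100)

seq, truth = ghmm_simulate(g, 2000, rng)      # sequence + true path
seg = ghmm_viterbi(g, seq)                    # decoded segmentation
for s in list(seg)[:5]:
    print("%s\t%d\t%d" % s)
print("log-likelihood: %.2f" % seg.log_likelihood)
print("position accuracy vs truth: %.3f" % ps.position_accuracy(truth, seg))
```

prints

```
NONCPG  1       102
CPG     103     246
NONCPG  247     316
CPG     317     328
NONCPG  329     422
log-likelihood: -544.36
position accuracy vs truth: 1.000
```

Each line is one decoded segment (state, begin, end; 1-based inclusive); the
log-likelihood is the joint score of the best segmentation, and the final
line compares the decoded state labels against the simulation's true path.
The CPG state's mean length (100) sets its self-transition to 0.99, and
`p_exit_noncpg` is the sensitivity dial: raising it calls more, shorter
islands.

The same models drive the command line: `probseq train`, `probseq simulate`,
`probseq evaluate`, `probseq viterbi_decoding` (`--gff` for GFF-style
output), `probseq posterior_decoding` and `probseq bayes_classifier`, all
reading `-F FILE` or stdin and writing diagnostics to stderr. Models are
stored in a readable text language (see `docs/methods.md`), e.g.:

```
model_name = "iid"
alphabet = ("A", "C", "G", "T")
probabilities = ("A": 0.25; "C": 0.25; "G": 0.25; "T": 0.25)
```

A 56-state two-strand gene-finder architecture (composite start/donor/
acceptor signal states, phase-tracked exon states with smoothed-histogram
durations, reverse-strand states as exact reverse-complement mirrors) and a
synthetic-gene generator with ground-truth segmentations live in
`probseq.fixtures`.

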