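"""Reference architectures and synthetic data generators.

Two worked GHMM architectures are built here:

* a two-state CpG-island detector (CPG / NONCPG, both geometric, interpolated
  Markov chain emissions), and
* a 56-state eukaryotic gene finder modelling genes on both strands with
  composite signal states, phase-tracked exon states, and smoothed-histogram
  exon durations.

A synthetic-gene generator produces sequences with embedded multi-exon genes
and ground-truth segmentations, so every pipeline (training, decoding,
accuracy scoring) is testable without any external data; the gene-finder
sub-models are bootstrapped by training on windows extracted from these
simulations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DNA, Sequence, SequenceModel, as_rng, encode
from . import chains
from .chains import sample_categorical
from .ghmm import (
    CompositeEmission,
    FixedDuration,
    Ghmm,
    GhmmState,
    HistogramDuration,
    ReverseComplementModel,
    Segmentation,
    SmoothedHistogram,
    train_smoothed_histogram,
)

__all__ = [
    "build_cpg_ghmm",
    "GeneFinderModels",
    "build_genefinder_ghmm",
    "GeneSimParams",
    "generate_synthetic_genes",
    "train_genefinder_bundle",
    "position_accuracy",
    "exon_boundary_recovery",
    "EXON_STATES",
]


# ---------------------------------------------------------------------------
# CpG island architecture
# ---------------------------------------------------------------------------


def build_cpg_ghmm(cpg_model: SequenceModel, bg_model: SequenceModel,
                   p_exit_noncpg: float, mean_cpg_len: float,
                   initial: dict[str, float] | None = None) -> Ghmm:
    """Two-state CpG-island GHMM, both states geometric.

    The CPG state's self-transition is 1 - 1/mean_cpg_len (geometric mean
    length equal to the training-data mean); the NONCPG exit probability is
    the sensitivity dial swept in the island-calling analysis.
    """
    if not (0.0 < p_exit_noncpg < 1.0):
        raise ValueError("p_exit_noncpg must be in (0, 1)")
    if mean_cpg_len <= 1.0:
        raise ValueError("mean_cpg_len must be > 1")
    q_cpg = 1.0 - 1.0 / mean_cpg_len
    states = [
        GhmmState("CPG", cpg_model, None,
                  {"CPG": q_cpg, "NONCPG": 1.0 - q_cpg}),
        GhmmState("NONCPG", bg_model, None,
                  {"NONCPG": 1.0 - p_exit_noncpg, "CPG": p_exit_noncpg}),
    ]
    if initial is None:
        initial = {"CPG": 0.5, "NONCPG": 0.5}
    return Ghmm(states, initial)


# ---------------------------------------------------------------------------
# gene-finder architecture
#
# Phase bookkeeping convention: phase = cumulative coding length mod 3 (the
# codon position of the next coding nucleotide).  Signal states carry fixed
# coding contributions: the start state contributes 7 coding nt (ATG + 4 nt
# initial pattern), a donor state 7 exonic nt (4 nt donor-initial + 3 nt
# before GT), an acceptor state 6 exonic nt (2 nt after AG + 4 nt
# acceptor-initial), the stop state 3.  With these offsets every exon state's
# admissible lengths satisfy  d ≡ phase_out - phase_in (mod 3)  and any parse
# of the grammar closes the reading frame (total CDS ≡ 0 mod 3).
# ---------------------------------------------------------------------------

START_CODING_NT = 7     # ATG + 4 nt initial pattern
DONOR_EXONIC_NT = 7     # 4 nt donor-initial + 3 nt before GT
ACCEPTOR_EXONIC_NT = 6  # 2 nt after AG + 4 nt acceptor-initial

#: exon-family state name prefixes (both strands)
EXON_STATES = ("single-exon", "initial-exon", "internal-exon", "terminal-exon")


@dataclass
class GeneFinderModels:
    """The eleven forward-strand emission sub-models plus duration statistics.

    Reverse-strand states reuse these models through the reverse-complement
    wrapper, which assigns pattern p the probability the forward model gives
    to revcomp(p) — the exact mirror of training on reverse complements.
    """

    start_motif: SequenceModel        # WAM, 20 nt upstream of ATG
    start_codon: SequenceModel        # WAM, 3 nt ("ATG" with probability ~1)
    initial_pattern: SequenceModel    # WAM, 4 nt after ATG
    stop_codon: SequenceModel         # WAM, 3 nt over TAA/TAG/TGA
    acceptor_site: SequenceModel      # WAM, 6 nt around the canonical AG
    branch_point: SequenceModel       # windowed WAM, 32 nt
    acceptor_initial: SequenceModel   # WAM, 4 nt after the acceptor
    donor_site: SequenceModel         # SBSW, 9 nt with mandatory GT
    donor_initial: SequenceModel      # WAM, 4 nt before the donor site
    coding: SequenceModel             # three-periodic IMM
    noncoding: SequenceModel          # IMM
    exon_duration: SmoothedHistogram
    mean_intron_length: float = 100.0
    mean_intergenic_length: float = 500.0
    p_single_exon: float = 0.25
    p_terminal_after_acceptor: float = 0.5
    p_final: float = 1e-6


def _strand_states(b: GeneFinderModels, prefix: str, rc: bool) -> list[GhmmState]:
    """The 27 states of one strand (names prefixed 'r-' on the reverse)."""

    def wrap(m: SequenceModel) -> SequenceModel:
        return ReverseComplementModel(m) if rc else m

    start_em = wrap(CompositeEmission([b.start_motif, b.start_codon, b.initial_pattern]))
    stop_em = wrap(b.stop_codon)
    donor_em = wrap(CompositeEmission([b.donor_initial, b.donor_site]))
    acceptor_em = wrap(CompositeEmission([b.branch_point, b.acceptor_site,
                                          b.acceptor_initial]))
    coding = wrap(b.coding)
    noncoding = wrap(b.noncoding)
    dur = HistogramDuration(b.exon_duration)
    q_intron = 1.0 - 1.0 / b.mean_intron_length
    p = prefix
    states = [
        GhmmState(p + "start", start_em, FixedDuration(27)),
        GhmmState(p + "stop", stop_em, FixedDuration(3)),
        GhmmState(p + "single-exon", coding, dur, phase_in=1, phase_out=0),
    ]
    for o in range(3):
        states.append(GhmmState("%sinitial-exon-%d" % (p, o), coding, dur,
                                phase_in=1, phase_out=o))
    for i in range(3):
        for o in range(3):
            states.append(GhmmState("%sinternal-exon-%d-%d" % (p, i, o), coding, dur,
                                    phase_in=i, phase_out=o))
    for i in range(3):
        states.append(GhmmState("%sterminal-exon-%d" % (p, i), coding, dur,
                                phase_in=i, phase_out=0))
    for ph in range(3):
        states.append(GhmmState("%sintron-%d" % (p, ph), noncoding, None,
                                {"%sintron-%d" % (p, ph): q_intron}))
        states.append(GhmmState("%sdonor-%d" % (p, ph), donor_em, FixedDuration(13)))
        states.append(GhmmState("%sacceptor-%d" % (p, ph), acceptor_em,
                                FixedDuration(42)))
    return states


def build_genefinder_ghmm(bundle: GeneFinderModels) -> Ghmm:
    """Assemble the 56-state two-strand gene-finder GHMM.

    27 strand-specific states per strand (start, stop, single exon, 3 initial
    exons by output phase, 9 internal exons by phase pair, 3 terminal exons by
    input phase, and 3 introns / donors / acceptors by phase), plus the shared
    intergenic and absorbing final states.
    """
    b = bundle
    states = _strand_states(b, "", rc=False) + _strand_states(b, "r-", rc=True)
    q_ig = 1.0 - 1.0 / b.mean_intergenic_length
    p_exit = 1.0 - q_ig
    p_gene = (1.0 - b.p_final) / 2.0
    states.append(GhmmState("intergenic", b.noncoding, None, {
        "intergenic": q_ig,
        "start": p_exit * p_gene,
        "r-stop": p_exit * p_gene,
        "final": p_exit * b.p_final,
    }))
    states.append(GhmmState("final", b.noncoding, None, {"final": 1.0}))

    trans: dict[str, dict[str, float]] = {s.name: dict(s.transitions) for s in states}
    p_init = (1.0 - b.p_single_exon) / 3.0
    p_int = (1.0 - b.p_terminal_after_acceptor) / 3.0

    # forward strand wiring
    trans["start"] = {"single-exon": b.p_single_exon,
                      **{"initial-exon-%d" % o: p_init for o in range(3)}}
    trans["single-exon"] = {"stop": 1.0}
    for o in range(3):
        trans["initial-exon-%d" % o] = {"donor-%d" % ((o + DONOR_EXONIC_NT) % 3): 1.0}
    for ph in range(3):
        trans["donor-%d" % ph] = {"intron-%d" % ph: 1.0}
        trans["intron-%d" % ph]["acceptor-%d" % ph] = 1.0 / b.mean_intron_length
        trans["acceptor-%d" % ph] = {
            "terminal-exon-%d" % ph: b.p_terminal_after_acceptor,
            **{"internal-exon-%d-%d" % (ph, o): p_int for o in range(3)}}
    for i in range(3):
        for o in range(3):
            trans["internal-exon-%d-%d" % (i, o)] = {
                "donor-%d" % ((o + DONOR_EXONIC_NT) % 3): 1.0}
        trans["terminal-exon-%d" % i] = {"stop": 1.0}
    trans["stop"] = {"intergenic": 1.0}

    # reverse strand: the same grammar mirrored in forward coordinates
    trans["r-stop"] = {"r-single-exon": b.p_single_exon,
                       **{"r-terminal-exon-%d" % i: p_init for i in range(3)}}
    trans["r-single-exon"] = {"r-start": 1.0}
    for i in range(3):
        trans["r-terminal-exon-%d" % i] = {"r-acceptor-%d" % i: 1.0}
        for o in range(3):
            trans["r-internal-exon-%d-%d" % (i, o)] = {"r-acceptor-%d" % i: 1.0}
    for ph in range(3):
        trans["r-acceptor-%d" % ph] = {"r-intron-%d" % ph: 1.0}
        trans["r-intron-%d" % ph]["r-donor-%d" % ph] = 1.0 / b.mean_intron_length
        o = (ph - DONOR_EXONIC_NT) % 3
        trans["r-donor-%d" % ph] = {
            "r-initial-exon-%d" % o: b.p_terminal_after_acceptor,
            **{"r-internal-exon-%d-%d" % (i, o): p_int for i in range(3)}}
    for o in range(3):
        trans["r-initial-exon-%d" % o] = {"r-start": 1.0}
    trans["r-start"] = {"intergenic": 1.0}

    for s in states:
        s.transitions = trans[s.name]
    return Ghmm(states, {"intergenic": 1.0})


# ---------------------------------------------------------------------------
# synthetic gene generator
# ---------------------------------------------------------------------------


def _profile(consensus: str, strength: float) -> list[np.ndarray]:
    """Per-position nucleotide distributions concentrated on a consensus."""
    rows = []
    for ch in consensus:
        row = np.full(4, (1.0 - strength) / 3.0)
        row[DNA.index(ch)] = strength
        rows.append(row)
    return rows


@dataclass
class GeneSimParams:
    """Study conditions for the synthetic gene model.

    Signal consensus strings follow the canonical vertebrate motifs (Kozak
    context, GT donor, AG acceptor with an upstream branch/pyrimidine tract);
    ``signal_strength`` is the per-position probability of the consensus
    nucleotide.  Coding sequence uses a strongly three-periodic nucleotide
    bias; noncoding sequence is AT-rich i.i.d.  Lengths are kept short (tens
    to low hundreds of nt) so end-to-end studies stay desk-sized while
    preserving the architecture's grammar.
    """

    signal_strength: float = 0.9
    upstream_consensus: str = "GCGCCGCCGCCACCGCCACC"       # 20 nt before ATG
    initial_consensus: str = "GCGG"                        # 4 nt after ATG
    donor_initial_consensus: str = "CAGG"                  # 4 exonic nt
    donor_site_consensus: str = "CAGGTAAGT"                # 3 exonic + GT + 4 intronic
    branch_consensus: str = "TTTTCTCTCCCTAACTTTTTTTTCTTTTCTTC"  # 32 nt
    acceptor_site_consensus: str = "TCAGGT"                # 2 + AG + 2 exonic
    acceptor_initial_consensus: str = "GGCG"               # 4 exonic nt
    coding_phase_probs: tuple = ((0.10, 0.20, 0.60, 0.10),
                                 (0.50, 0.20, 0.20, 0.10),
                                 (0.10, 0.50, 0.20, 0.20))
    noncoding_probs: tuple = (0.30, 0.20, 0.20, 0.30)
    exon_length_range: tuple = (30, 90)
    mean_intron_core: float = 60.0   # intron-state emission (between signals)
    min_intron_core: int = 10
    mean_intergenic: float = 200.0
    min_intergenic: int = 60
    max_introns: int = 2
    genes_per_sequence: int = 1


def _sample_profile(rows, rng) -> list[int]:
    return [sample_categorical(np.asarray(r), rng) for r in rows]


def _sample_coding(n: int, phase: int, probs, rng) -> list[int]:
    out = []
    for t in range(n):
        out.append(sample_categorical(np.asarray(probs[(phase + t) % 3]), rng))
    return out


def _sample_iid(n: int, probs, rng) -> list[int]:
    p = np.asarray(probs)
    return [sample_categorical(p, rng) for _ in range(n)]


def generate_synthetic_genes(params: GeneSimParams, n: int, seed=None):
    """Generate ``n`` sequences with embedded genes and true segmentations.

    Every gene starts with the 27-nt start region (upstream motif + ATG +
    initial pattern), alternates phase-consistent exons and introns (donor GT
    ... branch/acceptor AG), and ends with a stop codon; spliced coding
    length is always ≡ 0 mod 3.  Returns a list of (Sequence, Segmentation)
    pairs with state names matching :func:`build_genefinder_ghmm`.
    """
    rng = as_rng(seed)
    p = params
    stop_codons = [encode(list(c), DNA).values.tolist() for c in ("TAA", "TAG", "TGA")]
    out = []
    for si in range(n):
        values: list[int] = []
        segments: list[tuple[str, int, int]] = []

        def emit(state: str, vals: list[int]):
            begin = len(values) + 1
            values.extend(vals)
            segments.append((state, begin, len(values)))

        def intergenic(min_len: int):
            length = min_len + int(rng.geometric(1.0 / p.mean_intergenic))
            emit("intergenic", _sample_iid(length, p.noncoding_probs, rng))

        intergenic(p.min_intergenic)
        for _gi in range(p.genes_per_sequence):
            n_introns = int(rng.integers(0, p.max_introns + 1))
            # exon durations; the last exon absorbs the mod-3 closure
            lo, hi = p.exon_length_range
            durs = [int(rng.integers(lo, hi + 1)) for _ in range(n_introns + 1)]
            # start region
            s = p.signal_strength
            start_vals = (_sample_profile(_profile(p.upstream_consensus, s), rng)
                          + encode(list("ATG"), DNA).values.tolist()
                          + _sample_profile(_profile(p.initial_consensus, s), rng))
            emit("start", start_vals)
            phase = START_CODING_NT % 3  # 1
            for ei, d in enumerate(durs):
                last = ei == n_introns
                if last:
                    # closure: phase + d ≡ 0 (mod 3)
                    d += (-(phase + d)) % 3
                    name = ("single-exon" if n_introns == 0
                            else "terminal-exon-%d" % phase)
                    emit(name, _sample_coding(d, phase, p.coding_phase_probs, rng))
                    phase = (phase + d) % 3
                else:
                    out_phase = (phase + d) % 3
                    name = ("initial-exon-%d" % out_phase if ei == 0
                            else "internal-exon-%d-%d" % (phase, out_phase))
                    emit(name, _sample_coding(d, phase, p.coding_phase_probs, rng))
                    phase = out_phase
                    intron_phase = (phase + DONOR_EXONIC_NT) % 3
                    donor_vals = (_sample_profile(_profile(p.donor_initial_consensus, s), rng)
                                  + _sample_profile(_profile(p.donor_site_consensus, s), rng))
                    # enforce the mandatory GT
                    donor_vals[4 + 3] = DNA.index("G")
                    donor_vals[4 + 4] = DNA.index("T")
                    emit("donor-%d" % intron_phase, donor_vals)
                    core = p.min_intron_core + int(rng.geometric(1.0 / p.mean_intron_core))
                    emit("intron-%d" % intron_phase,
                         _sample_iid(core, p.noncoding_probs, rng))
                    acc_vals = (_sample_profile(_profile(p.branch_consensus, s), rng)
                                + _sample_profile(_profile(p.acceptor_site_consensus, s), rng)
                                + _sample_profile(_profile(p.acceptor_initial_consensus, s), rng))
                    acc_vals[32 + 2] = DNA.index("A")
                    acc_vals[32 + 3] = DNA.index("G")
                    emit("acceptor-%d" % intron_phase, acc_vals)
                    phase = (phase + DONOR_EXONIC_NT + ACCEPTOR_EXONIC_NT) % 3
            emit("stop", list(stop_codons[int(rng.integers(3))]))
            intergenic(p.min_intergenic)
        seq = Sequence("synth-%d" % si, values, DNA)
        out.append((seq, Segmentation(segments, float("nan"))))
    return out


# ---------------------------------------------------------------------------
# bootstrapped sub-model training
# ---------------------------------------------------------------------------


def _segments_of(seqs_segs, prefixes):
    for seq, seg in seqs_segs:
        for name, b, e in seg:
            if any(name == p or name.startswith(p) for p in prefixes):
                yield seq, name, b, e


def _window(seq: Sequence, b: int, e: int, name: str = "w") -> Sequence:
    return Sequence(name, seq.values[b - 1:e], seq.alphabet)


def train_genefinder_bundle(params: GeneSimParams | None = None, n_train: int = 40,
                            seed=12345) -> GeneFinderModels:
    """Train all gene-finder sub-models on windows cut from simulated genes.

    The generator's true segmentations provide the aligned signal windows,
    coding material (phase-aligned to codon boundaries) and length samples;
    no external data is needed.
    """
    if params is None:
        params = GeneSimParams()
    data = generate_synthetic_genes(params, n_train, seed)

    def cut(prefixes) -> list[Sequence]:
        return [_window(seq, b, e) for seq, _n, b, e in _segments_of(data, prefixes)]

    starts = cut(("start",))
    start_motif = chains.train_wam([Sequence("w", s.values[:20], DNA) for s in starts],
                                   20, order=0)
    start_codon = chains.train_wam([Sequence("w", s.values[20:23], DNA) for s in starts],
                                   3, order=0)
    initial_pattern = chains.train_wam([Sequence("w", s.values[23:27], DNA) for s in starts],
                                       4, order=0)
    stops = cut(("stop",))
    stop_codon = chains.train_wam(stops, 3, order=1)
    donors = cut(("donor-",))
    donor_initial = chains.train_wam([Sequence("w", s.values[:4], DNA) for s in donors],
                                     4, order=0)
    donor_site = chains.train_sbsw([Sequence("w", s.values[4:13], DNA) for s in donors],
                                   skip_offset=3, skip_sequence=("G", "T"))
    acceptors = cut(("acceptor-",))
    branch_point = chains.train_windowed_wam(
        [Sequence("w", s.values[:32], DNA) for s in acceptors], 32, order=0, window=2)
    acceptor_site = chains.train_wam([Sequence("w", s.values[32:38], DNA)
                                      for s in acceptors], 6, order=0)
    acceptor_initial = chains.train_wam([Sequence("w", s.values[38:42], DNA)
                                         for s in acceptors], 4, order=0)

    coding_pieces = []
    exon_lengths = []
    for seq, name, b, e in _segments_of(data, EXON_STATES):
        exon_lengths.append(e - b + 1)
        if name.startswith(("single", "initial")):
            phase_in = 1
        elif name.startswith("internal"):
            phase_in = int(name.split("-")[-2])
        else:  # terminal-exon-i
            phase_in = int(name.split("-")[-1])
        shift = (3 - phase_in) % 3
        piece = seq.values[b - 1 + shift:e]
        if len(piece) >= 3:
            coding_pieces.append(Sequence("cds", piece, DNA))
    coding = chains.train_imm(coding_pieces, max_order=2, periodicity=3)

    noncoding_pieces = [Sequence("nc", seq.values[b - 1:e], DNA)
                        for seq, _n, b, e in _segments_of(data, ("intron-", "intergenic"))]
    noncoding = chains.train_imm(noncoding_pieces, max_order=2, periodicity=1)

    intron_lens = [e - b + 1 for _s, _n, b, e in _segments_of(data, ("intron-",))]
    ig_lens = [e - b + 1 for _s, _n, b, e in _segments_of(data, ("intergenic",))]

    return GeneFinderModels(
        start_motif=start_motif, start_codon=start_codon,
        initial_pattern=initial_pattern, stop_codon=stop_codon,
        acceptor_site=acceptor_site, branch_point=branch_point,
        acceptor_initial=acceptor_initial, donor_site=donor_site,
        donor_initial=donor_initial, coding=coding, noncoding=noncoding,
        exon_duration=train_smoothed_histogram(exon_lengths),
        mean_intron_length=float(np.mean(intron_lens)) if intron_lens else 100.0,
        mean_intergenic_length=float(np.mean(ig_lens)) if ig_lens else 500.0,
    )


# ---------------------------------------------------------------------------
# accuracy helpers
# ---------------------------------------------------------------------------


def position_accuracy(true_seg: Segmentation, pred_seg: Segmentation,
                      equivalent: dict[str, str] | None = None) -> float:
    """Fraction of positions labelled with the same state name."""
    t = true_seg.state_per_position()
    p = pred_seg.state_per_position()
    if len(t) != len(p):
        raise ValueError("segmentations cover different lengths (%d vs %d)"
                         % (len(t), len(p)))
    if equivalent:
        t = [equivalent.get(x, x) for x in t]
        p = [equivalent.get(x, x) for x in p]
    return sum(1 for a, b in zip(t, p) if a == b) / len(t)


def _is_exon_state(name: str) -> bool:
    base = name[2:] if name.startswith("r-") else name
    return base.startswith(EXON_STATES)


def exon_boundary_recovery(true_seg: Segmentation, pred_seg: Segmentation) -> float:
    """Fraction of true exon-segment boundaries recovered exactly.

    Each true exon-family segment contributes two boundaries (begin and end);
    a boundary is recovered when some predicted exon-family segment has the
    same coordinate on the same side.
    """
    pred_begins = {b for n, b, _e in pred_seg if _is_exon_state(n)}
    pred_ends = {e for n, _b, e in pred_seg if _is_exon_state(n)}
    total = hit = 0
    for name, b, e in true_seg:
        if not _is_exon_state(name):
            continue
        total += 2
        hit += (b in pred_begins) + (e in pred_ends)
    if total == 0:
        raise ValueError("true segmentation contains no exon segments")
    return hit / total
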