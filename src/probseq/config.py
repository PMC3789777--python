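"""The model-description language: parser, serializer and model factory.

Models are described in a small plain-text language whose notation stays
close to the mathematical definitions::

    model_name = "markov_chain"
    alphabet = ("A", "C", "G", "T")
    transitions = ("A" | "C": 0.125;
                   "C" | "C": 0.875)

Grammar (whitespace-insensitive, ``#`` comments to end of line)::

    document   := assignment*
    assignment := key "=" value
    value      := string | number | call | tuple | table | map
    call       := ident "(" [value ("," value)*] ")"     # file(...), fixed(n), ...
    tuple      := "(" [value ("," value)*] ")"
    table      := "(" entry (";" entry)* ")"
    entry      := string ["|" string] ":" number          # "symbol | context": p
    map        := "[" assignment* "]"

Conditional-probability tables write the conditioned symbol first and the
context (space-separated tokens, oldest first) after ``|``; an absent context
means an unconditional entry.  Sub-models may be referenced with
``file("path")``, resolved relative to the referring file.  ``parse ∘
serialize`` is the identity on every model family, and probabilities are
printed with full (17 significant digit) round-trip precision.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np

from .core import Alphabet, SequenceModel
from . import chains, ghmm as ghmm_mod, hmm as hmm_mod

__all__ = [
    "ModelConfig",
    "ConfigError",
    "parse_config",
    "model_from_config",
    "serialize_model",
    "load_model",
    "save_model",
    "train_model_from_config",
]


class ConfigError(ValueError):
    """Syntax or semantic error in a model description."""


@dataclass
class FileRef:
    path: str


@dataclass
class Call:
    name: str
    args: list


class Table(dict):
    """Ordered mapping (symbol, context) -> number; context "" = unconditional."""


class ModelConfig(dict):
    """Parsed document: key -> typed value, plus provenance and warnings."""

    def __init__(self, *args, base_path: str | None = None, **kw):
        super().__init__(*args, **kw)
        self.base_path = base_path
        self.warnings: list[str] = []


# ---------------------------------------------------------------------------
# tokenizer
# ---------------------------------------------------------------------------

_PUNCT = set("=()[];:,|")


@dataclass
class _Token:
    kind: str  # 'str' | 'num' | 'ident' | punct char
    value: object
    line: int
    col: int


def _tokenize(text: str) -> list[_Token]:
    toks: list[_Token] = []
    line, col = 1, 1
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch == "\n":
            line += 1
            col = 1
            i += 1
            continue
        if ch in " \t\r":
            i += 1
            col += 1
            continue
        if ch == "#":
            while i < n and text[i] != "\n":
                i += 1
            continue
        start_line, start_col = line, col
        if ch == '"':
            j = i + 1
            buf = []
            while j < n and text[j] != '"':
                if text[j] == "\n":
                    raise ConfigError("line %d, col %d: unterminated string"
                                      % (start_line, start_col))
                buf.append(text[j])
                j += 1
            if j >= n:
                raise ConfigError("line %d, col %d: unterminated string"
                                  % (start_line, start_col))
            toks.append(_Token("str", "".join(buf), start_line, start_col))
            col += j + 1 - i
            i = j + 1
            continue
        if ch in _PUNCT:
            toks.append(_Token(ch, ch, start_line, start_col))
            i += 1
            col += 1
            continue
        if ch.isdigit() or ch in "+-." and i + 1 < n and (text[i + 1].isdigit() or text[i + 1] == "."):
            j = i
            while j < n and (text[j].isdigit() or text[j] in "+-.eE"):
                # stop at +/- not following an exponent marker
                if text[j] in "+-" and j > i and text[j - 1] not in "eE":
                    break
                j += 1
            lit = text[i:j]
            try:
                value: object = int(lit)
            except ValueError:
                try:
                    value = float(lit)
                except ValueError:
                    raise ConfigError("line %d, col %d: bad number %r"
                                      % (start_line, start_col, lit))
            toks.append(_Token("num", value, start_line, start_col))
            col += j - i
            i = j
            continue
        if ch.isalpha() or ch == "_":
            j = i
            while j < n and (text[j].isalnum() or text[j] in "_-"):
                j += 1
            toks.append(_Token("ident", text[i:j], start_line, start_col))
            col += j - i
            i = j
            continue
        raise ConfigError("line %d, col %d: unexpected character %r" % (line, col, ch))
    return toks


# ---------------------------------------------------------------------------
# parser
# ---------------------------------------------------------------------------


class _Parser:
    def __init__(self, toks: list[_Token], base_path: str | None):
        self.toks = toks
        self.pos = 0
        self.base_path = base_path

    def _err(self, msg: str):
        if self.pos < len(self.toks):
            t = self.toks[self.pos]
            raise ConfigError("line %d, col %d: %s (near %r)" % (t.line, t.col, msg, t.value))
        raise ConfigError("unexpected end of input: %s" % msg)

    def peek(self, offset: int = 0) -> _Token | None:
        i = self.pos + offset
        return self.toks[i] if i < len(self.toks) else None

    def take(self, kind: str | None = None) -> _Token:
        t = self.peek()
        if t is None:
            self._err("expected %s" % kind)
        if kind is not None and t.kind != kind:
            self._err("expected %s" % kind)
        self.pos += 1
        return t

    def document(self) -> ModelConfig:
        doc = ModelConfig(base_path=self.base_path)
        while self.peek() is not None:
            key = self.take("ident").value
            self.take("=")
            doc[key] = self.value()
        return doc

    def assignments_until(self, closer: str) -> dict:
        out: dict = {}
        while True:
            t = self.peek()
            if t is None:
                self._err("expected %r" % closer)
            if t.kind == closer:
                self.take(closer)
                return out
            key = self.take("ident").value
            self.take("=")
            out[key] = self.value()

    def value(self):
        t = self.peek()
        if t is None:
            self._err("expected a value")
        if t.kind == "str":
            return self.take().value
        if t.kind == "num":
            return self.take().value
        if t.kind == "ident":
            name = self.take().value
            self.take("(")
            args = []
            if self.peek() and self.peek().kind != ")":
                args.append(self.value())
                while self.peek() and self.peek().kind == ",":
                    self.take(",")
                    args.append(self.value())
            self.take(")")
            if name == "file":
                if len(args) != 1 or not isinstance(args[0], str):
                    self._err("file() takes one quoted path")
                return FileRef(args[0])
            return Call(name, args)
        if t.kind == "[":
            self.take("[")
            return self.assignments_until("]")
        if t.kind == "(":
            return self._paren()
        self._err("expected a value")

    def _paren(self):
        self.take("(")
        if self.peek() and self.peek().kind == ")":
            self.take(")")
            return ()
        # a table iff the first item is a string followed by ':' or '|'
        if self.peek().kind == "str" and self.peek(1) is not None \
                and self.peek(1).kind in (":", "|"):
            return self._table()
        items = [self.value()]
        while self.peek() and self.peek().kind == ",":
            self.take(",")
            items.append(self.value())
        self.take(")")
        return tuple(items)

    def _table(self) -> Table:
        tab = Table()
        while True:
            sym = self.take("str").value
            ctx = ""
            if self.peek() and self.peek().kind == "|":
                self.take("|")
                ctx = self.take("str").value
            self.take(":")
            num = self.take("num").value
            if (sym, ctx) in tab:
                self._err("duplicate table entry %r | %r" % (sym, ctx))
            tab[(sym, ctx)] = float(num)
            t = self.peek()
            if t is not None and t.kind == ";":
                self.take(";")
                continue
            self.take(")")
            return tab


def parse_config(text: str, base_path: str | None = None) -> ModelConfig:
    """Parse a model-description document into a typed :class:`ModelConfig`."""
    return _Parser(_tokenize(text), base_path).document()


# ---------------------------------------------------------------------------
# number / table formatting
# ---------------------------------------------------------------------------


def _fmt_num(x) -> str:
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    return repr(float(x))


def _fmt_value(v, indent: int = 0) -> str:
    pad = " " * indent
    if isinstance(v, str):
        return '"%s"' % v
    if isinstance(v, (int, float, np.integer, np.floating)):
        return _fmt_num(v)
    if isinstance(v, FileRef):
        return 'file("%s")' % v.path
    if isinstance(v, Call):
        return "%s(%s)" % (v.name, ", ".join(_fmt_value(a, indent) for a in v.args))
    if isinstance(v, Table):
        entries = []
        for (sym, ctx), num in v.items():
            key = '"%s"' % sym if not ctx else '"%s" | "%s"' % (sym, ctx)
            entries.append("%s: %s" % (key, _fmt_num(num)))
        sep = ";\n%s " % pad
        return "(%s)" % sep.join(entries)
    if isinstance(v, tuple):
        return "(%s)" % ", ".join(_fmt_value(x, indent + 1) for x in v)
    if isinstance(v, dict):
        lines = ["["]
        for k, val in v.items():
            lines.append("%s  %s = %s" % (pad, k, _fmt_value(val, indent + 2)))
        lines.append(pad + "]")
        return "\n".join(lines)
    raise ConfigError("cannot serialize value of type %s" % type(v).__name__)


def _serialize_document(doc: dict) -> str:
    return "\n".join("%s = %s" % (k, _fmt_value(v)) for k, v in doc.items()) + "\n"


# ---------------------------------------------------------------------------
# table <-> array helpers
# ---------------------------------------------------------------------------


def _ctx_tokens_to_index(tokens: list[str], alphabet: Alphabet) -> int:
    # tokens written oldest-first; internal encoding most-recent least significant
    a = len(alphabet)
    idx = 0
    for d, tok in enumerate(reversed(tokens), start=1):
        idx += alphabet.index(tok) * a**(d - 1)
    return idx


def _ctx_index_to_tokens(idx: int, m: int, alphabet: Alphabet) -> list[str]:
    a = len(alphabet)
    toks = []
    for d in range(1, m + 1):  # most recent first
        toks.append(alphabet.symbol((idx // a**(d - 1)) % a))
    return list(reversed(toks))


def _cond_tables_from_table(tab: Table, alphabet: Alphabet, max_order: int,
                            what: str) -> list[np.ndarray]:
    """Build conditional arrays for orders 0..max_order from table entries.

    Unspecified contexts default to uniform; a context that is present but
    whose row does not sum to 1 raises, naming the row and its sum.
    """
    a = len(alphabet)
    arrays = [np.full((a**m, a), np.nan) for m in range(max_order + 1)]
    for (sym, ctx), p in tab.items():
        toks = ctx.split()
        m = len(toks)
        if m > max_order:
            raise ConfigError("%s: context %r longer than order %d" % (what, ctx, max_order))
        row = _ctx_tokens_to_index(toks, alphabet)
        arrays[m][row, alphabet.index(sym)] = p
    out = []
    for m, arr in enumerate(arrays):
        filled = np.nan_to_num(arr, nan=0.0)
        for row in range(arr.shape[0]):
            if np.all(np.isnan(arr[row])):
                filled[row] = 1.0 / a  # unspecified row: uniform
            else:
                s = float(filled[row].sum())
                if abs(s - 1.0) > 1e-6:
                    ctx_s = " ".join(_ctx_index_to_tokens(row, m, alphabet))
                    raise ConfigError(
                        "%s: probabilities for context %r sum to %s, expected 1"
                        % (what, ctx_s, repr(s)))
        out.append(filled)
    return out


def _table_for_order(arr: np.ndarray, m: int, alphabet: Alphabet,
                     tab: Table | None = None) -> Table:
    if tab is None:
        tab = Table()
    for row in range(arr.shape[0]):
        ctx = " ".join(_ctx_index_to_tokens(row, m, alphabet))
        for s in range(arr.shape[1]):
            tab[(alphabet.symbol(s), ctx)] = float(arr[row, s])
    return tab


def _cond_tables_to_table(arrays: list[np.ndarray], alphabet: Alphabet) -> Table:
    tab = Table()
    for m, arr in enumerate(arrays):
        _table_for_order(arr, m, alphabet, tab)
    return tab


def _alphabet_from(cfg: dict) -> Alphabet:
    if "alphabet" not in cfg:
        raise ConfigError("missing 'alphabet'")
    return Alphabet(cfg["alphabet"])


def _keyed_table_to_dict(tab: Table) -> dict:
    return {(sym, ctx): v for (sym, ctx), v in tab.items()}


# ---------------------------------------------------------------------------
# model -> document
# ---------------------------------------------------------------------------


def model_to_document(model: SequenceModel) -> dict:
    """Canonical document (key -> value) for any supported model family."""
    al = model.alphabet
    doc: dict = {}
    if isinstance(model, chains.DiscreteIid):
        doc["model_name"] = "iid"
        doc["alphabet"] = tuple(al.symbols)
        tab = Table()
        for i, s in enumerate(al.symbols):
            tab[(s, "")] = float(model.probs[i])
        doc["probabilities"] = tab
    elif isinstance(model, chains.MarkovChain):
        doc["model_name"] = "markov_chain"
        doc["alphabet"] = tuple(al.symbols)
        doc["order"] = model.order
        doc["transitions"] = _cond_tables_to_table(model.tables, al)
    elif isinstance(model, chains.Vlmc):
        doc["model_name"] = "vlmc"
        doc["alphabet"] = tuple(al.symbols)
        tab = Table()
        for ctx in sorted(model.nodes, key=lambda c: (len(c), c)):
            ctx_s = " ".join(al.symbol(x) for x in reversed(ctx))
            for s in range(len(al)):
                tab[(al.symbol(s), ctx_s)] = float(model.nodes[ctx][s])
        doc["contexts"] = tab
        counts = Table()
        for ctx in sorted(model.counts, key=lambda c: (len(c), c)):
            if ctx in model.nodes:
                ctx_s = " ".join(al.symbol(x) for x in reversed(ctx))
                counts[(ctx_s or "", "")] = float(model.counts[ctx])
        if counts:
            doc["context_counts"] = counts
    elif isinstance(model, chains.InterpolatedChain):
        doc["model_name"] = "imm"
        doc["alphabet"] = tuple(al.symbols)
        doc["order"] = model.max_order
        doc["periodicity"] = model.period
        doc["phase_tables"] = tuple(
            tuple(_table_for_order(tab, m, al) for m, tab in enumerate(tabs))
            for tabs in model.phase_tables)
    elif isinstance(model, chains.PositionalChain):
        doc["model_name"] = "wam"
        doc["alphabet"] = tuple(al.symbols)
        doc["length"] = model.length
        doc["orders"] = tuple(model.orders)
        doc["position_tables"] = tuple(_table_for_order(t, m, al)
                                       for t, m in zip(model.tables, model.orders))
    elif isinstance(model, chains.SbswModel):
        doc["model_name"] = "sbsw"
        doc["alphabet"] = tuple(al.symbols)
        doc["length"] = model.length
        doc["skip_offset"] = model.skip_offset
        doc["skip_sequence"] = " ".join(al.symbol(x) for x in model.skip_values)
        doc["epsilon"] = float(model.epsilon)
        tab = Table()
        for pat in sorted(model.pattern_counts):
            tab[(" ".join(al.symbol(x) for x in pat), "")] = model.pattern_counts[pat]
        doc["pattern_counts"] = tab
    elif isinstance(model, hmm_mod.Hmm):
        doc["model_name"] = "hmm"
        doc["state_names"] = tuple(model.state_names)
        doc["alphabet"] = tuple(al.symbols)
        init = Table()
        for i, name in enumerate(model.state_names):
            init[(name, "")] = float(model.initial[i])
        doc["initial_probabilities"] = init
        trans = Table()
        for i, src in enumerate(model.state_names):
            for j, dst in enumerate(model.state_names):
                trans[(dst, src)] = float(model.transitions[i, j])
        doc["transitions"] = trans
        emis = Table()
        for i, name in enumerate(model.state_names):
            for s in range(len(al)):
                emis[(al.symbol(s), name)] = float(model.emissions[i, s])
        doc["emission_probabilities"] = emis
    elif isinstance(model, hmm_mod.ProfileHmm):
        doc["model_name"] = "profile_hmm"
        doc["alphabet"] = tuple(al.symbols)
        doc["model_length"] = model.M
        doc["match_emissions"] = tuple(
            Table({(al.symbol(s), ""): float(model.match_emissions[i, s])
                   for s in range(len(al))}) for i in range(1, model.M + 1))
        doc["insert_emissions"] = tuple(
            Table({(al.symbol(s), ""): float(model.insert_emissions[i, s])
                   for s in range(len(al))}) for i in range(model.M + 1))
        trans = Table()
        for key in ("MM", "MI", "MD", "IM", "II", "ID", "DM", "DD", "DI"):
            arr = model.trans[key]
            for i in range(len(arr)):
                trans[(key, str(i))] = float(arr[i])
        doc["transitions"] = trans
    elif isinstance(model, ghmm_mod.CompositeEmission):
        doc["model_name"] = "composite"
        doc["parts"] = tuple(model_to_document(p) for p in model.parts)
    elif isinstance(model, ghmm_mod.ReverseComplementModel):
        doc["model_name"] = "reverse_complement"
        doc["inner"] = model_to_document(model.inner)
    elif isinstance(model, ghmm_mod.Ghmm):
        doc["model_name"] = "ghmm"
        doc["state_names"] = tuple(model.state_names)
        init = Table()
        for i, name in enumerate(model.state_names):
            init[(name, "")] = float(model.initial[i])
        doc["initial_probabilities"] = init
        trans = Table()
        for s in model.states:
            for dst, p in s.transitions.items():
                trans[(dst, s.name)] = float(p)
        doc["transitions"] = trans
        states: dict = {}
        for s in model.states:
            st: dict = {"emission_model": model_to_document(s.emission)}
            dur = s.duration
            if isinstance(dur, ghmm_mod.GeometricDuration):
                st["duration"] = "geometric"
            elif isinstance(dur, ghmm_mod.FixedDuration):
                st["duration"] = Call("fixed", [dur.length])
            else:
                tab = Table()
                probs = dur.histogram.probs
                for d in np.nonzero(probs > 0)[0]:
                    tab[(str(int(d) + 1), "")] = float(probs[d])
                st["duration"] = Call("histogram", [tab])
            if s.phase_in is not None:
                st["phase_in"] = int(s.phase_in)
            if s.phase_out is not None:
                st["phase_out"] = int(s.phase_out)
            states[s.name] = st
        doc["states"] = states
    else:
        raise ConfigError("cannot serialize model family %r" % type(model).__name__)
    return doc


def serialize_model(model: SequenceModel) -> str:
    """Render a trained model in the description language (reparses exactly)."""
    return _serialize_document(model_to_document(model))


def save_model(model: SequenceModel, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(serialize_model(model))


# ---------------------------------------------------------------------------
# document -> model
# ---------------------------------------------------------------------------

_KNOWN_KEYS = {
    "model_name", "alphabet", "probabilities", "order", "orders", "periodicity",
    "transitions", "contexts", "context_counts", "phase_tables", "length",
    "position_tables", "skip_offset", "skip_sequence", "epsilon",
    "pattern_counts", "state_names", "initial_probabilities",
    "emission_probabilities", "states", "emission_model", "duration",
    "phase_in", "phase_out", "model_length", "match_emissions",
    "insert_emissions", "arities", "end_probabilities", "parts", "inner",
    "training_algorithm", "cut", "pseudocount", "max_depth", "window",
    "bandwidth",
}


def _warn_unknown(cfg: dict, doc_warnings: list[str] | None):
    for key in cfg:
        if key not in _KNOWN_KEYS and doc_warnings is not None:
            doc_warnings.append("unknown key %r preserved" % key)


def _resolve(value, base_path: str | None):
    if isinstance(value, FileRef):
        path = value.path
        if base_path is not None and not os.path.isabs(path):
            path = os.path.join(base_path, path)
        if not os.path.exists(path):
            raise ConfigError("referenced sub-model file %r not found" % path)
        with open(path) as fh:
            sub = parse_config(fh.read(), base_path=os.path.dirname(path))
        return sub
    return value


def model_from_config(cfg: dict, base_path: str | None = None) -> SequenceModel:
    """Instantiate a model from a parsed document."""
    if base_path is None and isinstance(cfg, ModelConfig):
        base_path = cfg.base_path
    warnings = cfg.warnings if isinstance(cfg, ModelConfig) else None
    _warn_unknown(cfg, warnings)
    name = cfg.get("model_name")
    if name is None:
        raise ConfigError("document lacks 'model_name'")

    if name == "iid":
        al = _alphabet_from(cfg)
        tab = cfg["probabilities"]
        probs = np.zeros(len(al))
        total = 0.0
        for (sym, ctx), p in tab.items():
            probs[al.index(sym)] = p
            total += p
        if abs(total - 1.0) > 1e-6:
            raise ConfigError("probabilities sum to %s, expected 1" % repr(total))
        return chains.DiscreteIid(al, probs)

    if name == "markov_chain":
        al = _alphabet_from(cfg)
        order = int(cfg.get("order", 0))
        tables = _cond_tables_from_table(cfg["transitions"], al, order, "transitions")
        return chains.MarkovChain(al, tables)

    if name == "vlmc":
        al = _alphabet_from(cfg)
        nodes: dict[tuple, np.ndarray] = {}
        for (sym, ctx), p in cfg["contexts"].items():
            toks = ctx.split()
            key = tuple(al.index(t) for t in reversed(toks))
            nodes.setdefault(key, np.zeros(len(al)))[al.index(sym)] = p
        for ctx_key, row in nodes.items():
            s = float(row.sum())
            if abs(s - 1.0) > 1e-6:
                raise ConfigError("context row %r sums to %s, expected 1"
                                  % (ctx_key, repr(s)))
        counts = {}
        for (ctx_s, _), c in cfg.get("context_counts", Table()).items():
            toks = ctx_s.split()
            counts[tuple(al.index(t) for t in reversed(toks))] = c
        return chains.Vlmc(al, nodes, counts)

    if name == "imm":
        al = _alphabet_from(cfg)
        order = int(cfg["order"])
        phase_tables = []
        for tabs in cfg["phase_tables"]:
            per_order = []
            for m, tab in enumerate(tabs):
                arr = _cond_tables_from_table(tab, al, m, "phase table")[m]
                per_order.append(arr)
            phase_tables.append(per_order)
        model = chains.InterpolatedChain(al, phase_tables)
        if model.max_order != order:
            raise ConfigError("declared order %d does not match tables" % order)
        return model

    if name == "wam":
        al = _alphabet_from(cfg)
        orders = [int(x) for x in cfg["orders"]]
        tables = []
        for u, tab in enumerate(cfg["position_tables"]):
            arr = _cond_tables_from_table(tab, al, orders[u], "position %d" % (u + 1))
            tables.append(arr[orders[u]])
        return chains.PositionalChain(al, tables)

    if name == "sbsw":
        al = _alphabet_from(cfg)
        skip_tokens = cfg["skip_sequence"].split()
        counts = {}
        for (pat_s, _), c in cfg["pattern_counts"].items():
            counts[tuple(al.index(t) for t in pat_s.split())] = c
        return chains.SbswModel(
            al, int(cfg["length"]), int(cfg["skip_offset"]),
            tuple(al.index(t) for t in skip_tokens), float(cfg["epsilon"]), counts)

    if name == "hmm":
        al = _alphabet_from(cfg)
        names = list(cfg["state_names"])
        K = len(names)
        idx = {n: i for i, n in enumerate(names)}
        pi = np.zeros(K)
        for (state, _), p in cfg["initial_probabilities"].items():
            pi[idx[state]] = p
        A = np.zeros((K, K))
        for (dst, src), p in cfg["transitions"].items():
            A[idx[src], idx[dst]] = p
        E = np.zeros((K, len(al)))
        for (sym, state), p in cfg["emission_probabilities"].items():
            E[idx[state], al.index(sym)] = p
        return hmm_mod.Hmm(al, names, pi, A, E)

    if name == "profile_hmm":
        al = _alphabet_from(cfg)
        M = int(cfg["model_length"])
        mE = np.zeros((M + 1, len(al)))
        for i, tab in enumerate(cfg["match_emissions"], start=1):
            for (sym, _), p in tab.items():
                mE[i, al.index(sym)] = p
        iE = np.zeros((M + 1, len(al)))
        for i, tab in enumerate(cfg["insert_emissions"]):
            for (sym, _), p in tab.items():
                iE[i, al.index(sym)] = p
        trans = {k: np.zeros(M + 1)
                 for k in ("MM", "MI", "MD", "IM", "II", "ID", "DM", "DD", "DI")}
        for (key, i), p in cfg["transitions"].items():
            trans[key][int(i)] = p
        return hmm_mod.ProfileHmm(al, M, mE, iE, trans)

    if name == "composite":
        parts = [model_from_config(p, base_path) for p in
                 (_resolve(p, base_path) for p in cfg["parts"])]
        return ghmm_mod.CompositeEmission(parts)

    if name == "reverse_complement":
        inner = model_from_config(_resolve(cfg["inner"], base_path), base_path)
        return ghmm_mod.ReverseComplementModel(inner)

    if name == "ghmm":
        names = list(cfg["state_names"])
        initial = {}
        for (state, _), p in cfg["initial_probabilities"].items():
            initial[state] = p
        trans: dict[str, dict[str, float]] = {n: {} for n in names}
        for (dst, src), p in cfg["transitions"].items():
            trans.setdefault(src, {})[dst] = p
        states = []
        for n in names:
            st_cfg = cfg["states"][n]
            emission = model_from_config(_resolve(st_cfg["emission_model"], base_path),
                                         base_path)
            dur_val = st_cfg.get("duration", "geometric")
            if dur_val == "geometric":
                duration = None  # inferred from the self-transition at build
            elif isinstance(dur_val, Call) and dur_val.name == "fixed":
                duration = ghmm_mod.FixedDuration(int(dur_val.args[0]))
            elif isinstance(dur_val, Call) and dur_val.name == "histogram":
                tab = dur_val.args[0]
                if isinstance(tab, FileRef):
                    tab = _resolve(tab, base_path).get("histogram")
                maxd = max(int(d) for (d, _) in tab)
                probs = np.zeros(maxd)
                for (d, _), p in tab.items():
                    probs[int(d) - 1] = p
                duration = ghmm_mod.HistogramDuration(ghmm_mod.SmoothedHistogram(probs))
            else:
                raise ConfigError("state %r: unrecognised duration %r" % (n, dur_val))
            states.append(ghmm_mod.GhmmState(
                name=n, emission=emission, duration=duration,
                transitions=dict(trans.get(n, {})),
                phase_in=(int(st_cfg["phase_in"]) if "phase_in" in st_cfg else None),
                phase_out=(int(st_cfg["phase_out"]) if "phase_out" in st_cfg else None)))
        return ghmm_mod.Ghmm(states, initial)

    raise ConfigError("unknown model_name %r" % name)


def load_model(path: str) -> SequenceModel:
    with open(path) as fh:
        cfg = parse_config(fh.read(), base_path=os.path.dirname(os.path.abspath(path)))
    return model_from_config(cfg)


# ---------------------------------------------------------------------------
# training driven by a config document
# ---------------------------------------------------------------------------


def train_model_from_config(cfg: dict, seqs) -> SequenceModel:
    """Train a model as specified by a config with a ``training_algorithm`` key."""
    algo = cfg.get("training_algorithm")
    if algo is None:
        raise ConfigError("config lacks 'training_algorithm'")
    pc = float(cfg.get("pseudocount", chains.DEFAULT_PSEUDOCOUNT))
    if algo == "iid":
        return chains.train_iid(seqs, pc)
    if algo == "markov_chain":
        return chains.train_markov(seqs, int(cfg["order"]), pc)
    if algo == "vlmc":
        return chains.train_vlmc(seqs, int(cfg["max_depth"]),
                                 float(cfg["cut"]), pc)
    if algo == "wam":
        return chains.train_windowed_wam(seqs, int(cfg["length"]), int(cfg["order"]),
                                         int(cfg.get("window", 0)), pc)
    if algo == "imm":
        return chains.train_imm(seqs, int(cfg["order"]),
                                int(cfg.get("periodicity", 1)), pc)
    if algo == "sbsw":
        return chains.train_sbsw(seqs, int(cfg["skip_offset"]),
                                 cfg["skip_sequence"].split(),
                                 float(cfg.get("epsilon", 1e-3)))
    raise ConfigError("unknown training_algorithm %r" % algo)
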