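"""Profile-HMM data model and text parsers/writers for both supported dialects.

Two on-disk dialects are supported:

* ``H2`` -- the HMMER2 plan7 save format (``HMMER2.0`` header).  Scores are
  stored as integers equal to ``1000 * log2(p / null)``; ``*`` denotes an
  impossible transition/emission.  Extreme-value (Gumbel) parameters live on
  an ``EVD`` line and are present only for calibrated models.
* ``H3`` -- the HMMER3 text profile format (``HMMER3/*`` header).  All values
  are negative natural-log probabilities; ``*`` denotes zero probability.
  Three ``STATS LOCAL`` lines carry the search statistics; the forward-score
  exponential-tail parameters are the ones bound into :class:`EvdParams`.

Internally every score is held in bits (log2 odds against the null model),
one unit system for downstream score dissection regardless of the on-disk
scaling.  Coordinates are 1-based inclusive for both sequence positions and
model columns, matching HMMER report conventions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

AMINO_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: database size used to make E-values conservative (UniProt, April 2013)
DEFAULT_DB_SIZE = 540_261

_LN2 = math.log(2.0)

# constant XT line (special-state transitions) written for the H2 dialect;
# the dissection machinery does not consume these.
_H2_XT = "XT      -8455     -4  -1000  -1000  -8455     -4  -8455     -4"

_H2_SCALE = 1000.0


class Dialect(str, Enum):
    H2 = "H2"
    H3 = "H3"


class TailKind(str, Enum):
    GUMBEL = "gumbel"
    EXPONENTIAL_TAIL = "exponential_tail"


class ProfileError(Exception):
    """Base error for profile parsing/writing."""


class UnsupportedDialectError(ProfileError):
    pass


class ProfileParseError(ProfileError):
    pass


class DialectConversionError(ProfileError):
    pass


class UncalibratedProfileError(ProfileError):
    """Raised when E-value statistics are requested from an uncalibrated model."""


@dataclass
class EvdParams:
    """Extreme-value parameters of a calibrated profile.

    ``mu`` is the location (bits); for the exponential tail it stores the
    tail onset tau.  ``lam`` is the scale per bit.  ``db_size`` is the
    effective number of database comparisons z.
    """

    mu: float
    lam: float
    tail_kind: TailKind = TailKind.GUMBEL
    db_size: int = DEFAULT_DB_SIZE

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError(f"EVD lambda must be > 0, got {self.lam}")
        if self.db_size < 1:
            raise ValueError(f"db_size must be >= 1, got {self.db_size}")


@dataclass
class NullModel:
    """Background emission distribution plus the null length-extension term."""

    probs: np.ndarray  # shape (20,), sums to 1
    p_extend: float = 350.0 / 351.0

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (20,):
            raise ValueError("null model needs exactly 20 emission probabilities")
        total = float(np.sum(self.probs))
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ValueError(f"null emission probabilities sum to {total}, not 1")

    @classmethod
    def uniform(cls) -> "NullModel":
        return cls(np.full(20, 0.05))


#: per-column transition score keys (source column k -> k or k+1)
TRANSITION_KEYS = ("mm", "mi", "md", "im", "ii", "dm", "dd")


@dataclass
class ProfileHMM:
    """A profile hidden Markov model with all quantities score
    reconstruction needs, in bits."""

    model_id: str
    dialect: Dialect
    K: int
    match_emissions: np.ndarray  # (K, 20) log-odds bits
    insert_emissions: np.ndarray  # (K, 20) log-odds bits
    transitions: dict  # str -> (K,) arrays of bits, keys TRANSITION_KEYS
    b_to_m: np.ndarray  # (K,) local-entry scores B->M_k, bits
    m_to_e: np.ndarray  # (K,) local-exit scores M_k->E, bits
    entry_m1: float  # glocal begin B->M_1, bits
    entry_d1: float  # glocal begin B->D_1, bits
    null_model: NullModel = field(default_factory=NullModel.uniform)
    evd: EvdParams | None = None
    invariant_terms: float = 0.0
    alphabet: str = AMINO_ALPHABET
    h3_extra_stats: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("profile length K must be >= 1")
        self.match_emissions = np.asarray(self.match_emissions, dtype=float)
        self.insert_emissions = np.asarray(self.insert_emissions, dtype=float)
        for name, tab in (("match", self.match_emissions), ("insert", self.insert_emissions)):
            if tab.shape != (self.K, 20):
                raise ValueError(f"{name} emission table must be {self.K}x20, got {tab.shape}")
        for key in TRANSITION_KEYS:
            arr = np.asarray(self.transitions[key], dtype=float)
            if arr.shape != (self.K,):
                raise ValueError(f"transition table {key!r} must have length K={self.K}")
            self.transitions[key] = arr
        self.b_to_m = np.asarray(self.b_to_m, dtype=float)
        self.m_to_e = np.asarray(self.m_to_e, dtype=float)

    @property
    def calibrated(self) -> bool:
        return self.evd is not None

    def require_calibrated(self) -> EvdParams:
        if self.evd is None:
            raise UncalibratedProfileError(
                f"profile {self.model_id!r} carries no EVD statistics; "
                "E-value computation refused"
            )
        return self.evd

    def residue_index(self, residue: str) -> int:
        idx = self.alphabet.find(residue)
        if idx < 0:
            raise KeyError(f"residue {residue!r} not in alphabet")
        return idx


@dataclass
class PathRecord:
    """One step of a sequence-to-model alignment path."""

    state: str  # 'M', 'I' or 'D'
    k: int | None  # model column (M, D) or preceding match column (I)
    qpos: int | None  # 1-based query position (M, I)
    residue: str | None  # emitted residue (M, I)


@dataclass
class SeqDomAlignment:
    """One sequence-to-domain alignment path."""

    query_id: str
    model_id: str
    variant: Dialect
    seq_span: tuple[int, int]
    model_span: tuple[int, int]
    path: list[PathRecord]
    reported_score: float | None = None
    reported_evalue: float | None = None


# ---------------------------------------------------------------------------
# parsing


def parse_profile(text: str) -> ProfileHMM:
    """Parse a profile-HMM model file (either dialect) into a :class:`ProfileHMM`.

    Models whose statistics lines are absent parse fine but come back with
    ``evd=None`` (uncalibrated); E-value operations on them raise.
    """
    stripped = text.lstrip()
    if stripped.startswith("HMMER2.0"):
        return _parse_h2(text)
    if stripped.startswith("HMMER3/"):
        return _parse_h3(text)
    head = stripped.splitlines()[0][:40] if stripped else "<empty>"
    raise UnsupportedDialectError(f"unrecognized profile header: {head!r}")


def _h2_to_bits(token: str) -> float:
    if token == "*":
        return float("-inf")
    return int(token) / _H2_SCALE


def _bits_to_h2(value: float) -> str:
    if not math.isfinite(value):
        return "*"
    return str(int(round(value * _H2_SCALE)))


def _parse_h2(text: str) -> ProfileHMM:
    lines = text.splitlines()
    model_id = "unnamed"
    K = None
    nule: np.ndarray | None = None
    p_extend = 350.0 / 351.0
    evd: EvdParams | None = None
    i = 0
    n = len(lines)
    while i < n and not lines[i].startswith("HMM "):
        ln = lines[i]
        if ln.startswith("NAME"):
            model_id = ln.split(None, 1)[1].strip()
        elif ln.startswith("LENG"):
            K = int(ln.split()[1])
        elif ln.startswith("NULE"):
            vals = np.array([_h2_to_bits(t) for t in ln.split()[1:]])
            if vals.shape != (20,):
                raise ProfileParseError("NULE line must carry 20 scores")
            nule = np.exp2(vals) / 20.0
            nule = nule / nule.sum()  # integer scaling leaves ~1e-4 drift
        elif ln.startswith("NULT"):
            p_extend = 2.0 ** (_h2_to_bits(ln.split()[1]))
        elif ln.startswith("EVD"):
            toks = ln.split()
            evd = EvdParams(mu=float(toks[1]), lam=float(toks[2]), tail_kind=TailKind.GUMBEL)
        i += 1
    if K is None:
        raise ProfileParseError("missing LENG line")
    if i >= n:
        raise ProfileParseError("missing HMM score section")
    i += 2  # skip "HMM ..." alphabet line and the transition header line
    if i >= n:
        raise ProfileParseError("truncated file before begin-state line")
    btoks = lines[i].split()
    if len(btoks) != 3:
        raise ProfileParseError("begin-state line must carry B->M1, B->I0, B->D1")
    entry_m1 = _h2_to_bits(btoks[0])
    entry_d1 = _h2_to_bits(btoks[2])
    i += 1

    match = np.empty((K, 20))
    insert = np.empty((K, 20))
    trans = {key: np.empty(K) for key in TRANSITION_KEYS}
    b_to_m = np.empty(K)
    m_to_e = np.empty(K)
    for k in range(1, K + 1):
        if i + 2 >= n:
            raise ProfileParseError(f"truncated node block at model column {k}")
        mt = lines[i].split()
        if len(mt) < 21 or mt[0] != str(k):
            raise ProfileParseError(f"malformed match line at model column {k}")
        match[k - 1] = [_h2_to_bits(t) for t in mt[1:21]]
        it = lines[i + 1].split()
        if len(it) != 21 or it[0] != "-":
            raise ProfileParseError(f"malformed insert line at model column {k}")
        insert[k - 1] = [_h2_to_bits(t) for t in it[1:21]]
        tt = lines[i + 2].split()
        if len(tt) != 10 or tt[0] != "-":
            raise ProfileParseError(f"malformed transition line at model column {k}")
        vals = [_h2_to_bits(t) for t in tt[1:]]
        for key, v in zip(TRANSITION_KEYS, vals[:7]):
            trans[key][k - 1] = v
        b_to_m[k - 1] = vals[7]
        m_to_e[k - 1] = vals[8]
        i += 3

    null = NullModel(nule if nule is not None else np.full(20, 0.05), p_extend)
    return ProfileHMM(
        model_id=model_id,
        dialect=Dialect.H2,
        K=K,
        match_emissions=match,
        insert_emissions=insert,
        transitions=trans,
        b_to_m=b_to_m,
        m_to_e=m_to_e,
        entry_m1=entry_m1,
        entry_d1=entry_d1,
        null_model=null,
        evd=evd,
    )


def _h3_to_prob(token: str) -> float:
    if token == "*":
        return 0.0
    return math.exp(-float(token))


def _parse_h3(text: str) -> ProfileHMM:
    lines = text.splitlines()
    model_id = "unnamed"
    K = None
    stats: dict[str, tuple[float, float]] = {}
    i = 0
    n = len(lines)
    while i < n and not lines[i].startswith("HMM "):
        ln = lines[i]
        if ln.startswith("NAME"):
            model_id = ln.split(None, 1)[1].strip()
        elif ln.startswith("LENG"):
            K = int(ln.split()[1])
        elif ln.startswith("STATS LOCAL"):
            toks = ln.split()
            stats[toks[2]] = (float(toks[3]), float(toks[4]))
        i += 1
    if K is None:
        raise ProfileParseError("missing LENG line")
    if i >= n:
        raise ProfileParseError("missing HMM score section")
    i += 2  # alphabet header + transition header
    # optional COMPO line
    if i < n and lines[i].split()[:1] == ["COMPO"]:
        i += 1
    if i + 1 >= n:
        raise ProfileParseError("truncated file before node-0 block")
    bg = np.array([_h3_to_prob(t) for t in lines[i].split()])
    if bg.shape != (20,):
        raise ProfileParseError("node-0 insert line must carry 20 values")
    bg = bg / bg.sum()
    t0 = [_h3_to_prob(t) for t in lines[i + 1].split()]
    entry_m1 = _log2_or_neginf(t0[0])
    entry_d1 = _log2_or_neginf(t0[2])
    i += 2

    log_bg = np.log(bg)
    match = np.empty((K, 20))
    insert = np.empty((K, 20))
    trans = {key: np.empty(K) for key in TRANSITION_KEYS}
    for k in range(1, K + 1):
        if i + 2 >= n:
            raise ProfileParseError(f"truncated node block at model column {k}")
        mt = lines[i].split()
        if len(mt) < 21 or mt[0] != str(k):
            raise ProfileParseError(f"malformed match line at model column {k}")
        mnll = np.array([_neg_log_or_inf(t) for t in mt[1:21]])
        match[k - 1] = (-mnll - log_bg) / _LN2
        it = lines[i + 1].split()
        if len(it) != 20:
            raise ProfileParseError(f"malformed insert line at model column {k}")
        inll = np.array([_neg_log_or_inf(t) for t in it])
        insert[k - 1] = (-inll - log_bg) / _LN2
        tt = lines[i + 2].split()
        if len(tt) != 7:
            raise ProfileParseError(f"malformed transition line at model column {k}")
        for key, tok in zip(TRANSITION_KEYS, tt):
            trans[key][k - 1] = _log2_or_neginf(_h3_to_prob(tok))
        i += 3

    # uniform local entry over match columns (plan7 local mode); free local exit
    b_to_m = np.full(K, math.log2(2.0 / (K * (K + 1))))
    m_to_e = np.zeros(K)
    evd = None
    if "FORWARD" in stats:
        tau, lam = stats["FORWARD"]
        evd = EvdParams(mu=tau, lam=lam, tail_kind=TailKind.EXPONENTIAL_TAIL)
    return ProfileHMM(
        model_id=model_id,
        dialect=Dialect.H3,
        K=K,
        match_emissions=match,
        insert_emissions=insert,
        transitions=trans,
        b_to_m=b_to_m,
        m_to_e=m_to_e,
        entry_m1=entry_m1,
        entry_d1=entry_d1,
        null_model=NullModel(bg),
        evd=evd,
        h3_extra_stats={k: v for k, v in stats.items() if k != "FORWARD"},
    )


def _neg_log_or_inf(token: str) -> float:
    if token == "*":
        return float("inf")
    return float(token)


def _log2_or_neginf(p: float) -> float:
    if p <= 0.0:
        return float("-inf")
    return math.log2(p)


# ---------------------------------------------------------------------------
# writing


def write_profile(p: ProfileHMM, dialect: Dialect | str | None = None) -> str:
    """Serialize ``p`` in the requested dialect's text format.

    The output is accepted by :func:`parse_profile` and round-trips all
    numeric fields to the format's printed precision (0.001 bits for H2,
    five decimals of the natural-log encoding for H3).
    """
    dialect = Dialect(dialect) if dialect is not None else p.dialect
    if dialect is Dialect.H2:
        if p.evd is not None and p.evd.tail_kind is not TailKind.GUMBEL:
            raise DialectConversionError(
                "H2 save format carries Gumbel statistics only; "
                f"profile has {p.evd.tail_kind.value!r}"
            )
        return _write_h2(p)
    if p.evd is not None and p.evd.tail_kind is not TailKind.EXPONENTIAL_TAIL:
        raise DialectConversionError(
            "H3 text format carries forward exponential-tail statistics only; "
            f"profile has {p.evd.tail_kind.value!r}"
        )
    return _write_h3(p)


def _write_h2(p: ProfileHMM) -> str:
    out = ["HMMER2.0  [hmmdissect]"]
    out.append(f"NAME  {p.model_id}")
    out.append(f"LENG  {p.K}")
    out.append("ALPH  Amino")
    out.append(_H2_XT)
    pe = p.null_model.p_extend
    out.append(
        "NULT  " + _bits_to_h2(math.log2(pe)) + "  " + _bits_to_h2(math.log2(1.0 - pe))
    )
    nule = np.log2(p.null_model.probs * 20.0)
    out.append("NULE  " + "  ".join(_bits_to_h2(v) for v in nule))
    if p.evd is not None:
        out.append(f"EVD   {p.evd.mu:.6f}  {p.evd.lam:.6f}")
    out.append("HMM        " + "      ".join(p.alphabet))
    out.append("         m->m   m->i   m->d   i->m   i->i   d->m   d->d   b->m   m->e")
    out.append(
        "       "
        + "  ".join([_bits_to_h2(p.entry_m1), "*", _bits_to_h2(p.entry_d1)])
    )
    for k in range(p.K):
        out.append(
            f"{k + 1:>6} "
            + " ".join(f"{_bits_to_h2(v):>6}" for v in p.match_emissions[k])
            + f"  {k + 1}"
        )
        out.append(
            "     - " + " ".join(f"{_bits_to_h2(v):>6}" for v in p.insert_emissions[k])
        )
        tvals = [p.transitions[key][k] for key in TRANSITION_KEYS]
        tvals += [p.b_to_m[k], p.m_to_e[k]]
        out.append("     - " + " ".join(f"{_bits_to_h2(v):>6}" for v in tvals))
    out.append("//")
    return "\n".join(out) + "\n"


def _prob_fmt(prob: float) -> str:
    if prob <= 0.0:
        return "*"
    return f"{-math.log(prob):.5f}"


def _write_h3(p: ProfileHMM) -> str:
    out = ["HMMER3/f [hmmdissect]"]
    out.append(f"NAME  {p.model_id}")
    out.append(f"LENG  {p.K}")
    out.append("ALPH  amino")
    if p.evd is not None:
        msv = p.h3_extra_stats.get("MSV", (p.evd.mu, p.evd.lam))
        vit = p.h3_extra_stats.get("VITERBI", (p.evd.mu, p.evd.lam))
        out.append(f"STATS LOCAL MSV      {msv[0]:.5f}  {msv[1]:.5f}")
        out.append(f"STATS LOCAL VITERBI  {vit[0]:.5f}  {vit[1]:.5f}")
        out.append(f"STATS LOCAL FORWARD  {p.evd.mu:.5f}  {p.evd.lam:.5f}")
    out.append("HMM          " + "        ".join(p.alphabet))
    out.append(
        "            m->m     m->i     m->d     i->m     i->i     d->m     d->d"
    )
    bg = p.null_model.probs
    out.append("          " + "  ".join(_prob_fmt(v) for v in bg))  # node-0 insert
    t0 = [
        2.0**p.entry_m1,
        0.0,
        2.0**p.entry_d1 if math.isfinite(p.entry_d1) else 0.0,
        1.0,
        0.0,
        1.0,
        0.0,
    ]
    out.append("          " + "  ".join(_prob_fmt(v) for v in t0))
    for k in range(p.K):
        mprob = bg * np.exp2(p.match_emissions[k])
        out.append(
            f"{k + 1:>7}   " + "  ".join(_prob_fmt(v) for v in mprob) + f"   {k + 1} x - -"
        )
        iprob = bg * np.exp2(p.insert_emissions[k])
        out.append("          " + "  ".join(_prob_fmt(v) for v in iprob))
        tprob = [2.0 ** p.transitions[key][k] for key in TRANSITION_KEYS]
        out.append("          " + "  ".join(_prob_fmt(v) for v in tprob))
    out.append("//")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# alignment validation


def validate_alignment(a: SeqDomAlignment, p: ProfileHMM) -> list[str]:
    """Check a :class:`SeqDomAlignment` against its profile.

    Returns a list of human-readable diagnostics; an empty list means every
    structural invariant holds.  Never raises on content problems.
    """
    diags: list[str] = []
    if a.model_id != p.model_id:
        diags.append(f"model id mismatch: alignment {a.model_id!r} vs profile {p.model_id!r}")
    if not a.path:
        diags.append("empty alignment path")
        return diags

    last_col = 0
    last_q = 0
    prev_state = None
    for idx, rec in enumerate(a.path):
        if rec.state not in ("M", "I", "D"):
            diags.append(f"record {idx}: unknown state {rec.state!r}")
            continue
        if rec.state in ("M", "D"):
            if rec.k is None or not (1 <= rec.k <= p.K):
                diags.append(f"record {idx}: model column {rec.k} out of range 1..{p.K}")
            elif rec.k <= last_col:
                diags.append(f"record {idx}: model column {rec.k} not strictly increasing")
            if rec.k is not None:
                last_col = max(last_col, rec.k)
        if rec.state in ("M", "I"):
            if rec.qpos is None:
                diags.append(f"record {idx}: emitting state without query position")
            elif rec.qpos <= last_q:
                diags.append(f"record {idx}: query position {rec.qpos} not strictly increasing")
            else:
                last_q = rec.qpos
            if rec.residue is None or rec.residue not in p.alphabet:
                diags.append(f"record {idx}: residue {rec.residue!r} not in alphabet")
        if prev_state == "I" and rec.state == "D":
            diags.append(f"record {idx}: illegal I->D transition")
        if prev_state == "D" and rec.state == "I":
            diags.append(f"record {idx}: illegal D->I transition")
        prev_state = rec.state

    emitting = [r for r in a.path if r.state in ("M", "I") and r.qpos is not None]
    if emitting:
        if a.seq_span != (emitting[0].qpos, emitting[-1].qpos):
            diags.append(
                f"seq_span {a.seq_span} disagrees with path "
                f"({emitting[0].qpos}, {emitting[-1].qpos})"
            )
    cols = [r.k for r in a.path if r.state in ("M", "D") and r.k is not None]
    if cols:
        if a.model_span != (cols[0], cols[-1]):
            diags.append(
                f"model_span {a.model_span} disagrees with path ({cols[0]}, {cols[-1]})"
            )
    if a.variant is Dialect.H2 and a.model_span != (1, p.K):
        diags.append(
            f"glocal alignment must span model columns (1, {p.K}), got {a.model_span}"
        )
    return diags
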