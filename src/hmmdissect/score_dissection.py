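"""Alignment score reconstruction, fold-critical/remnant dissection and EVD
re-evaluation.

The full bit score of a sequence-to-domain alignment is rebuilt from the
profile's emission/transition/invariant log-odds, then split into a
fold-critical sum and a remnant (non-globular) sum according to a per-column
mask.  Each sum is pushed through the model's extreme-value statistics to
obtain a fold-critical E-value and a remnant E-value alongside the original
one.

Crediting rules (additivity is exact by construction):

* a path record's contribution is its emission log-odds plus the transition
  score entering its state, credited to its model column's class;
* insert-state records inherit the class of the preceding match column,
  deletions take their own column's class;
* entry/exit and model-level invariant terms are credited to the
  fold-critical sum.

H2 (glocal) sums are evaluated against Gumbel parameters, H3 (local) sums
against the forward-score exponential tail -- each variant's own statistical
model.  Compositional-bias (null2) corrections are not applied to dissected
sums: they are not reconstructible from partial alignments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .fold_annotation import ColumnMask, Label
from .profile_models import (
    Dialect,
    EvdParams,
    PathRecord,
    ProfileHMM,
    SeqDomAlignment,
    TailKind,
    validate_alignment,
)

_LOG10 = math.log(10.0)

#: E-values smaller than this underflow to exact zero, which triggers the
#: ratio-exclusion rule downstream.
UNDERFLOW_FLOOR = 1e-300


class AlignmentScoringError(ValueError):
    pass


@dataclass
class DissectedScore:
    """Full/fold-critical/remnant score sums and their three E-values."""

    full_score: float
    fc_sum: float
    rem_sum: float
    evalue_original: float
    evalue_fc: float
    evalue_rem: float
    log10_ratio: float | None  # log10(evalue_fc / evalue_rem); None if rem E = 0
    variant: Dialect


# ---------------------------------------------------------------------------
# score reconstruction


def _is_glocal(variant: Dialect) -> bool:
    # the framework runs H2 glocal ("local to sequence, global to domain")
    # and H3 local-only
    return variant is Dialect.H2


def _begin_score(p: ProfileHMM, first: PathRecord, glocal: bool) -> float:
    if glocal:
        if first.state == "M" and first.k == 1:
            return p.entry_m1
        if first.state == "D" and first.k == 1:
            return p.entry_d1
        raise AlignmentScoringError(
            f"glocal path must start at model column 1, got {first.state}{first.k}"
        )
    if first.state != "M":
        raise AlignmentScoringError("local path must start with a match state")
    return float(p.b_to_m[first.k - 1])


def _end_score(p: ProfileHMM, last: PathRecord, glocal: bool) -> float:
    if glocal:
        if last.k != p.K:
            raise AlignmentScoringError(
                f"glocal path must end at model column {p.K}, got {last.state}{last.k}"
            )
        if last.state == "M":
            v = float(p.m_to_e[p.K - 1])
            return v if math.isfinite(v) else 0.0
        return 0.0  # D_K -> E
    if last.state != "M":
        raise AlignmentScoringError("local path must end with a match state")
    return float(p.m_to_e[last.k - 1])


def _transition_score(p: ProfileHMM, prev: PathRecord, cur: PathRecord) -> float:
    key = {
        ("M", "M"): "mm",
        ("M", "I"): "mi",
        ("M", "D"): "md",
        ("I", "M"): "im",
        ("I", "I"): "ii",
        ("D", "M"): "dm",
        ("D", "D"): "dd",
    }.get((prev.state, cur.state))
    if key is None:
        raise AlignmentScoringError(f"illegal transition {prev.state}->{cur.state}")
    return float(p.transitions[key][prev.k - 1])


def _emission_score(p: ProfileHMM, rec: PathRecord) -> float:
    if rec.state == "D":
        return 0.0
    j = p.residue_index(rec.residue)
    table = p.match_emissions if rec.state == "M" else p.insert_emissions
    return float(table[rec.k - 1, j])


def reconstruct_score(a: SeqDomAlignment, p: ProfileHMM) -> float:
    """Rebuild the alignment's full bit score from the model's log-odds.

    Sums emission scores over M/I records, transition scores along consecutive
    state pairs, the entry/exit terms of the alignment mode and the model's
    position-independent invariant terms.
    """
    diags = validate_alignment(a, p)
    if diags:
        raise AlignmentScoringError(
            f"alignment fails validation: {'; '.join(diags[:3])}"
        )
    glocal = _is_glocal(a.variant)
    total = _begin_score(p, a.path[0], glocal)
    prev = None
    for rec in a.path:
        if prev is not None:
            total += _transition_score(p, prev, rec)
        total += _emission_score(p, rec)
        prev = rec
    total += _end_score(p, a.path[-1], glocal)
    return total + p.invariant_terms


def dissect(
    a: SeqDomAlignment, p: ProfileHMM, m: ColumnMask
) -> tuple[float, float]:
    """Split the alignment score into (fold-critical, remnant) sums.

    ``fc_sum + rem_sum`` equals :func:`reconstruct_score` exactly.
    """
    if m.model_id != p.model_id:
        raise AlignmentScoringError(
            f"mask model {m.model_id!r} does not match profile {p.model_id!r}"
        )
    if m.K != p.K:
        raise AlignmentScoringError(f"mask length {m.K} != profile length {p.K}")
    diags = validate_alignment(a, p)
    if diags:
        raise AlignmentScoringError(
            f"alignment fails validation: {'; '.join(diags[:3])}"
        )
    glocal = _is_glocal(a.variant)
    fc = _begin_score(p, a.path[0], glocal) + _end_score(p, a.path[-1], glocal)
    fc += p.invariant_terms
    rem = 0.0
    prev = None
    for rec in a.path:
        contrib = _emission_score(p, rec)
        if prev is not None:
            contrib += _transition_score(p, prev, rec)
        if m.labels[rec.k - 1] is Label.FOLD_CRITICAL:
            fc += contrib
        else:
            rem += contrib
        prev = rec
    return fc, rem


# ---------------------------------------------------------------------------
# extreme-value statistics


def log10_pvalue(score: float, evd: EvdParams) -> float:
    """log10 of P(S >= score) under the model's tail."""
    t = evd.lam * (score - evd.mu)
    if evd.tail_kind is TailKind.GUMBEL:
        # P = 1 - exp(-exp(-t)); for large t, P ~ exp(-t); far below the
        # location P saturates at 1
        if t > 30.0:
            return -t / _LOG10
        if t < -30.0:
            return 0.0
        u = math.exp(-t)
        p = -math.expm1(-u)
        return math.log10(p) if p > 0 else -math.inf
    # exponential tail: P = min(1, exp(-t))
    return min(0.0, -t / _LOG10)


def log10_evalue(score: float, evd: EvdParams) -> float:
    return math.log10(evd.db_size) + log10_pvalue(score, evd)


def evalue(score: float, evd: EvdParams) -> float:
    """E-value of a bit score under the model's EVD.

    Gumbel tail: ``E = z * (1 - exp(-exp(-lam*(x - mu))))``; exponential tail:
    ``E = z * min(1, exp(-lam*(x - mu)))`` with the tail onset stored in
    ``mu``.  Strictly decreasing in the score.  Computed in log space;
    underflow is reported as exact 0 only below ``1e-300``.
    """
    if evd is None:
        raise ValueError("evalue() requires EVD parameters (calibrated model)")
    le = log10_evalue(score, evd)
    if le < math.log10(UNDERFLOW_FLOOR):
        return 0.0
    return 10.0**le


def dissect_evalues(
    a: SeqDomAlignment,
    p: ProfileHMM,
    m: ColumnMask,
    db_size: int | None = None,
) -> DissectedScore:
    """Compose reconstruction, dissection and EVD re-evaluation.

    ``log10_ratio = log10(evalue_fc) - log10(evalue_rem)``; it is undefined
    (``None``) when the remnant E-value underflows to zero, and such hits are
    excluded from ratio-based calibration downstream.
    """
    evd = p.require_calibrated()
    if db_size is not None:
        evd = EvdParams(mu=evd.mu, lam=evd.lam, tail_kind=evd.tail_kind, db_size=db_size)
    full = reconstruct_score(a, p)
    fc, rem = dissect(a, p, m)
    e_full = evalue(full, evd)
    e_fc = evalue(fc, evd)
    e_rem = evalue(rem, evd)
    if e_rem == 0.0:
        ratio = None
    else:
        ratio = log10_evalue(fc, evd) - log10_evalue(rem, evd)
    return DissectedScore(
        full_score=full,
        fc_sum=fc,
        rem_sum=rem,
        evalue_original=e_full,
        evalue_fc=e_fc,
        evalue_rem=e_rem,
        log10_ratio=ratio,
        variant=a.variant,
    )


# ---------------------------------------------------------------------------
# Viterbi alignment


def viterbi_align(
    p: ProfileHMM,
    seq: str,
    mode: str = "glocal",
    query_id: str = "query",
) -> SeqDomAlignment:
    """Highest-scoring legal alignment path of ``seq`` against ``p``.

    ``mode='glocal'`` is local to the sequence but spans model columns 1..K
    (leading/trailing deletions allowed); ``mode='local'`` may cover any
    contiguous column range but starts and ends in a match state.  Flanking
    query residues are free in both modes.  ``reported_score`` is set from
    :func:`reconstruct_score` on the returned path.
    """
    if mode not in ("glocal", "local"):
        raise ValueError(f"mode must be 'glocal' or 'local', got {mode!r}")
    if len(seq) < 1:
        raise ValueError("query sequence must have length >= 1")
    glocal = mode == "glocal"
    K = p.K
    L = len(seq)
    NEG = float("-inf")

    res_idx = np.array([p.alphabet.find(c) for c in seq])
    if (res_idx < 0).any():
        bad = seq[int(np.argmin(res_idx))]
        raise AlignmentScoringError(f"residue {bad!r} not in model alphabet")

    mm, mi, md, im, ii, dm, dd = (p.transitions[k] for k in (
        "mm", "mi", "md", "im", "ii", "dm", "dd"))

    # entry score into M_k (deletes from the begin state folded in for glocal)
    begin = np.full(K, NEG)
    if glocal:
        begin[0] = p.entry_m1
        if K > 1 and math.isfinite(p.entry_d1):
            # D_1 .. D_{k-1} then M_k
            cum = p.entry_d1
            for k in range(2, K + 1):
                begin[k - 1] = cum + dm[k - 2]
                cum += dd[k - 2]
                if not math.isfinite(cum):
                    break
    else:
        begin = p.b_to_m.copy()

    # exit score from M_k (trailing deletes to column K folded in for glocal)
    endv = np.full(K, NEG)
    if glocal:
        mexit = float(p.m_to_e[K - 1])
        endv[K - 1] = mexit if math.isfinite(mexit) else 0.0
        # M_k -> D_{k+1} -> ... -> D_K -> E: md out of column k plus dd out of
        # columns k+1 .. K-1 (exit from D_K is free)
        cum = 0.0
        for k in range(K - 1, 0, -1):
            endv[k - 1] = md[k - 1] + cum
            cum += dd[k - 1]
    else:
        endv = p.m_to_e.copy()

    VM = np.full((L + 1, K), NEG)
    VI = np.full((L + 1, K), NEG)
    VD = np.full((L + 1, K), NEG)
    # back-pointers: VM 0=begin 1=M 2=I 3=D; VI 0=M 1=I; VD 0=M 1=D
    PM = np.zeros((L + 1, K), dtype=np.int8)
    PI = np.zeros((L + 1, K), dtype=np.int8)
    PD = np.zeros((L + 1, K), dtype=np.int8)

    for j in range(1, L + 1):
        em = p.match_emissions[:, res_idx[j - 1]]
        ei = p.insert_emissions[:, res_idx[j - 1]]
        cand = np.full((4, K), NEG)
        cand[0] = begin
        cand[1, 1:] = VM[j - 1, :-1] + mm[:-1]
        cand[2, 1:] = VI[j - 1, :-1] + im[:-1]
        cand[3, 1:] = VD[j - 1, :-1] + dm[:-1]
        PM[j] = np.argmax(cand, axis=0)
        VM[j] = em + np.max(cand, axis=0)

        icand = np.stack([VM[j - 1] + mi, VI[j - 1] + ii])
        PI[j] = np.argmax(icand, axis=0)
        VI[j] = ei + np.max(icand, axis=0)

        # deletes consume no residue: sweep left to right within row j
        for k in range(1, K):
            from_m = VM[j, k - 1] + md[k - 1]
            from_d = VD[j, k - 1] + dd[k - 1]
            if from_m >= from_d:
                VD[j, k] = from_m
                PD[j, k] = 0
            else:
                VD[j, k] = from_d
                PD[j, k] = 1

    totals = VM + endv[None, :]
    jbest, kbest = np.unravel_index(np.argmax(totals), totals.shape)
    best = totals[jbest, kbest]
    if not math.isfinite(best):
        raise AlignmentScoringError("no legal alignment path has finite score")

    # traceback
    records: list[PathRecord] = []
    j, k, state = int(jbest), int(kbest) + 1, "M"
    while True:
        if state == "M":
            records.append(PathRecord("M", k, j, seq[j - 1]))
            ptr = PM[j, k - 1]
            if ptr == 0:
                start_k = k
                break
            j -= 1
            k -= 1
            state = {1: "M", 2: "I", 3: "D"}[int(ptr)]
        elif state == "I":
            records.append(PathRecord("I", k, j, seq[j - 1]))
            ptr = PI[j, k - 1]
            j -= 1
            state = "M" if ptr == 0 else "I"
        else:  # D
            records.append(PathRecord("D", k, None, None))
            ptr = PD[j, k - 1]
            k -= 1
            state = "M" if ptr == 0 else "D"
    records.reverse()
    if glocal:
        lead = [PathRecord("D", c, None, None) for c in range(1, start_k)]
        tail_k = records[-1].k
        trail = [PathRecord("D", c, None, None) for c in range(tail_k + 1, K + 1)]
        records = lead + records + trail

    emitting = [r for r in records if r.qpos is not None]
    cols = [r.k for r in records if r.state in ("M", "D")]
    aln = SeqDomAlignment(
        query_id=query_id,
        model_id=p.model_id,
        variant=Dialect.H2 if glocal else Dialect.H3,
        seq_span=(emitting[0].qpos, emitting[-1].qpos),
        model_span=(cols[0], cols[-1]),
        path=records,
    )
    aln.reported_score = reconstruct_score(aln, p)
    if p.calibrated:
        aln.reported_evalue = evalue(aln.reported_score, p.evd)
    return aln
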