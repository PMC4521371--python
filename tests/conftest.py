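"""Shared fixtures and the independent brute-force alignment oracle.

The oracle enumerates every legal alignment path explicitly and scores it by
direct summation over the profile's tables; it shares no code with the
package's Viterbi or score-reconstruction routines.
"""

from __future__ import annotations

import math

import pytest

from hmmdissect.fixtures import generate_synthetic_profile
from hmmdissect.profile_models import PathRecord, ProfileHMM


@pytest.fixture
def toy_profile():
    """Small uncalibrated glocal-dialect profile for oracle comparisons."""
    p, cons = generate_synthetic_profile(3, seed=11, dialect="H2", calibrate=False)
    return p, cons


def _emit(p: ProfileHMM, state: str, k: int, residue: str) -> float:
    j = p.alphabet.index(residue)
    if state == "M":
        return float(p.match_emissions[k - 1, j])
    return float(p.insert_emissions[k - 1, j])


def _trans(p: ProfileHMM, a: tuple[str, int], b: tuple[str, int]) -> float:
    key = {
        ("M", "M"): "mm", ("M", "I"): "mi", ("M", "D"): "md",
        ("I", "M"): "im", ("I", "I"): "ii",
        ("D", "M"): "dm", ("D", "D"): "dd",
    }[(a[0], b[0])]
    return float(p.transitions[key][a[1] - 1])


def brute_force_paths(p: ProfileHMM, seq: str, mode: str):
    """Yield (records, score) for every legal alignment path.

    Only feasible for tiny models/sequences; used as the exhaustive oracle.
    """
    K, L = p.K, len(seq)
    glocal = mode == "glocal"

    def score_end(state: str, k: int) -> float | None:
        if glocal:
            if k != K or state == "I":
                return None
            if state == "M":
                v = float(p.m_to_e[K - 1])
                return v if math.isfinite(v) else 0.0
            return 0.0
        if state != "M":
            return None
        return float(p.m_to_e[k - 1])

    def extend(records, state, k, q, acc):
        end_bonus = score_end(state, k)
        if end_bonus is not None:
            yield list(records), acc + end_bonus + p.invariant_terms
        # successors
        if state in ("M", "I"):
            if k < K and q < L:  # M_{k+1}
                rec = PathRecord("M", k + 1, q + 1, seq[q])
                cost = _trans(p, (state, k), ("M", k + 1)) + _emit(p, "M", k + 1, seq[q])
                yield from extend(records + [rec], "M", k + 1, q + 1, acc + cost)
            if q < L:  # I_k
                rec = PathRecord("I", k, q + 1, seq[q])
                cost = _trans(p, (state, k), ("I", k)) + _emit(p, "I", k, seq[q])
                yield from extend(records + [rec], "I", k, q + 1, acc + cost)
            if state == "M" and k < K:  # D_{k+1}
                rec = PathRecord("D", k + 1, None, None)
                cost = _trans(p, ("M", k), ("D", k + 1))
                yield from extend(records + [rec], "D", k + 1, q, acc + cost)
        elif state == "D":
            if k < K and q < L:
                rec = PathRecord("M", k + 1, q + 1, seq[q])
                cost = _trans(p, ("D", k), ("M", k + 1)) + _emit(p, "M", k + 1, seq[q])
                yield from extend(records + [rec], "M", k + 1, q + 1, acc + cost)
            if k < K:
                rec = PathRecord("D", k + 1, None, None)
                cost = _trans(p, ("D", k), ("D", k + 1))
                yield from extend(records + [rec], "D", k + 1, q, acc + cost)

    # starts: every query offset (flanking residues are free)
    for q0 in range(L):
        if glocal:
            rec = PathRecord("M", 1, q0 + 1, seq[q0])
            acc = p.entry_m1 + _emit(p, "M", 1, seq[q0])
            yield from extend([rec], "M", 1, q0 + 1, acc)
        else:
            for k0 in range(1, K + 1):
                rec = PathRecord("M", k0, q0 + 1, seq[q0])
                acc = float(p.b_to_m[k0 - 1]) + _emit(p, "M", k0, seq[q0])
                yield from extend([rec], "M", k0, q0 + 1, acc)
    if glocal and math.isfinite(p.entry_d1):
        # delete-state entry consumes nothing; any query start is equivalent
        for q0 in range(L + 1):
            rec = PathRecord("D", 1, None, None)
            yield from extend([rec], "D", 1, q0, p.entry_d1)
            break  # identical for every q0: enumerate once


def best_brute_force(p: ProfileHMM, seq: str, mode: str) -> float:
    return max(score for _, score in brute_force_paths(p, seq, mode))
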