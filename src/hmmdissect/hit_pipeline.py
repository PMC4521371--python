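"""Classification, pairing and error-adjusted coverage scoring of dissected
sequence-to-domain hits.

Each dissected hit is classified from its original and fold-critical E-values
(true-positive, false-positive, true-negative, or rescued false-negative);
only TP and FN hits are retained.  Overlapping glocal (H2) and local (H3)
hits to the same model are paired at an overlap ratio of 0.9, measure-level
FPRs are looked up from calibration tables, and the error-adjusted domain
coverage

    coverage^measure = 1/2 [ (1 - fpr_H2) * cov_H2 + (1 - fpr_H3) * cov_H3 ]

is computed for both the ratio measure and the fold-critical E-value measure.
A hit with only one variant present drops the 1/2 factor:
coverage = (1 - fpr) * cov.  The final stratification key is the total FPR,
the sum of the ROC-derived FPRs of the two coverage scores, reported in
ascending order (it is a sum of two error rates, not a probability, and may
exceed 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationTable, RocTable, fpr_lookup, roc_fpr_lookup
from .profile_models import Dialect, SeqDomAlignment
from .score_dissection import DissectedScore


class PipelineError(ValueError):
    pass


@dataclass
class ClassificationThresholds:
    """Original-E and fold-critical-E cutoffs per search variant.

    Defaults: original E <= 0.1 for H2 (the manual's trusted-hit cutoff) and
    10^-3 for H3 (its equal-FPR equivalent); fold-critical E cutoffs
    10^-3.45 (H2) and 10^-6 (H3), both at a preset FPR of 0.1.
    """

    original_e_cutoff: dict = field(
        default_factory=lambda: {Dialect.H2: 0.1, Dialect.H3: 1e-3}
    )
    fc_e_cutoff: dict = field(
        default_factory=lambda: {Dialect.H2: 10.0**-3.45, Dialect.H3: 1e-6}
    )

    def __post_init__(self) -> None:
        for d in (self.original_e_cutoff, self.fc_e_cutoff):
            if any(v <= 0 for v in d.values()):
                raise PipelineError("all classification cutoffs must be > 0")


@dataclass
class ClassifiedHit:
    dissected: DissectedScore
    alignment: SeqDomAlignment
    label: str  # TP | FP | TN | FN
    retained: bool


def classify(
    d: DissectedScore, t: ClassificationThresholds | None = None
) -> str:
    """Classify one dissected hit from its E-value triple.

    TP: orig <= cutoff and fc <= fc_cutoff; FP: orig <= cutoff, fc above but
    remnant E at/below fc_cutoff; TN: both above; FN (the rescued class):
    orig above but fc at/below.  The remnant E-value is a don't-care except
    on the FP branch.
    """
    t = t or ClassificationThresholds()
    orig_cut = t.original_e_cutoff[d.variant]
    fc_cut = t.fc_e_cutoff[d.variant]
    orig_ok = d.evalue_original <= orig_cut
    fc_ok = d.evalue_fc <= fc_cut
    if orig_ok and fc_ok:
        return "TP"
    if not orig_ok and fc_ok:
        return "FN"
    if not orig_ok and not fc_ok:
        return "TN"
    # orig significant, fold-critical part not: false positive when the
    # remnant part alone carries the significance
    if d.evalue_rem is None or (isinstance(d.evalue_rem, float) and math.isnan(d.evalue_rem)):
        raise PipelineError("remnant E-value required to decide the FP branch")
    if d.evalue_rem <= fc_cut:
        return "FP"
    return "TN"


def classify_hit(
    d: DissectedScore,
    alignment: SeqDomAlignment,
    t: ClassificationThresholds | None = None,
) -> ClassifiedHit:
    label = classify(d, t)
    return ClassifiedHit(
        dissected=d, alignment=alignment, label=label, retained=label in ("TP", "FN")
    )


# ---------------------------------------------------------------------------
# pairing


def overlap_ratio(span_i: tuple[int, int], span_j: tuple[int, int]) -> float:
    """Overlap between two sequence segments relative to the shorter-fraction
    convention: min(L/len_i, L/len_j) with L the intersection length
    (clamped at 0).  Symmetric in its arguments; 1.0 for identical spans."""
    (a_i, b_i), (a_j, b_j) = sorted([tuple(span_i), tuple(span_j)])
    len_i = b_i - a_i
    len_j = b_j - a_j
    if len_i <= 0 or len_j <= 0:
        raise PipelineError("zero-length sequence segment")
    overlap = min(b_i, b_j) - max(a_i, a_j)
    if overlap <= 0:
        return 0.0
    return min(overlap / len_i, overlap / len_j)


@dataclass
class MergedHit:
    query_id: str
    model_id: str
    h2: ClassifiedHit | None = None
    h3: ClassifiedHit | None = None
    coverage_h2: float | None = None  # 1 whenever present (glocal)
    coverage_h3: float | None = None  # aligned model columns / K
    fpr_ratio_h2: float | None = None
    fpr_ratio_h3: float | None = None
    fpr_fce_h2: float | None = None
    fpr_fce_h3: float | None = None
    coverage_ratio: float | None = None  # error-adjusted coverage, ratio measure
    coverage_fce: float | None = None  # error-adjusted coverage, fc-E measure
    roc_fpr_ratio: float | None = None
    roc_fpr_fce: float | None = None
    total_fpr: float | None = None


def model_coverage(a: SeqDomAlignment, K: int) -> float:
    """Aligned model columns over model length (1 for a full glocal span)."""
    k0, k1 = a.model_span
    return (k1 - k0 + 1) / K


def pair_hits(
    h2_hits: Sequence[ClassifiedHit],
    h3_hits: Sequence[ClassifiedHit],
    model_lengths: Mapping[str, int],
    min_overlap: float = 0.9,
) -> list[MergedHit]:
    """Pair retained H2/H3 hits to the same model whose query spans overlap at
    >= ``min_overlap``; unpaired hits become orphans.

    Matching is greedy by descending overlap (ties broken by lower H3 start),
    each hit used at most once and never across model ids.
    """
    h2_hits = [h for h in h2_hits if h.retained]
    h3_hits = [h for h in h3_hits if h.retained]
    merged: list[MergedHit] = []
    used2: set[int] = set()
    used3: set[int] = set()

    candidates = []
    for i, h2 in enumerate(h2_hits):
        for j, h3 in enumerate(h3_hits):
            if h2.alignment.model_id != h3.alignment.model_id:
                continue
            if h2.alignment.query_id != h3.alignment.query_id:
                continue
            ov = overlap_ratio(h2.alignment.seq_span, h3.alignment.seq_span)
            if ov >= min_overlap:
                candidates.append((-ov, h3.alignment.seq_span[0], i, j))
    for _, _, i, j in sorted(candidates):
        if i in used2 or j in used3:
            continue
        used2.add(i)
        used3.add(j)
        h2, h3 = h2_hits[i], h3_hits[j]
        merged.append(
            MergedHit(
                query_id=h2.alignment.query_id,
                model_id=h2.alignment.model_id,
                h2=h2,
                h3=h3,
                coverage_h2=1.0,
                coverage_h3=model_coverage(
                    h3.alignment, model_lengths[h3.alignment.model_id]
                ),
            )
        )
    for i, h2 in enumerate(h2_hits):
        if i not in used2:
            merged.append(
                MergedHit(
                    query_id=h2.alignment.query_id,
                    model_id=h2.alignment.model_id,
                    h2=h2,
                    coverage_h2=1.0,
                )
            )
    for j, h3 in enumerate(h3_hits):
        if j not in used3:
            merged.append(
                MergedHit(
                    query_id=h3.alignment.query_id,
                    model_id=h3.alignment.model_id,
                    h3=h3,
                    coverage_h3=model_coverage(
                        h3.alignment, model_lengths[h3.alignment.model_id]
                    ),
                )
            )
    return merged


# ---------------------------------------------------------------------------
# error-adjusted coverage


def _measure_fpr(
    hit: ClassifiedHit, kind: str, tables: Mapping[tuple[Dialect, str], CalibrationTable]
) -> float | None:
    d = hit.dissected
    table = tables.get((d.variant, kind))
    if table is None:
        raise PipelineError(
            f"no calibration table for variant={d.variant.value} measure={kind}"
        )
    if kind == "ratio":
        if d.log10_ratio is None:
            return None  # remnant E underflowed; ratio measure undefined
        return fpr_lookup(table, d.log10_ratio)
    x = math.log10(d.evalue_fc) if d.evalue_fc > 0 else table.bin_edges[0]
    return fpr_lookup(table, x)


def error_adjusted_coverage(
    m: MergedHit,
    tables: Mapping[tuple[Dialect, str], CalibrationTable],
    halve_orphans: bool = False,
) -> MergedHit:
    """Fill in measure-level FPRs and the error-adjusted coverage scores.

    Paired hits use the two-variant average
    ``1/2 [(1-fpr_H2) cov_H2 + (1-fpr_H3) cov_H3]``; orphans use
    ``(1-fpr) cov`` of the present variant (set ``halve_orphans`` to keep the
    1/2 factor instead).  A hit whose ratio measure is undefined gets an
    undefined ratio-based coverage while the fc-E-based one is still computed.
    """
    for kind, attr2, attr3, target in (
        ("ratio", "fpr_ratio_h2", "fpr_ratio_h3", "coverage_ratio"),
        ("fc_evalue", "fpr_fce_h2", "fpr_fce_h3", "coverage_fce"),
    ):
        terms = []
        undefined = False
        if m.h2 is not None:
            f2 = _measure_fpr(m.h2, kind, tables)
            setattr(m, attr2, f2)
            if f2 is None:
                undefined = True
            else:
                terms.append((1.0 - f2) * m.coverage_h2)
        if m.h3 is not None:
            f3 = _measure_fpr(m.h3, kind, tables)
            setattr(m, attr3, f3)
            if f3 is None:
                undefined = True
            else:
                terms.append((1.0 - f3) * m.coverage_h3)
        if undefined or not terms:
            setattr(m, target, None)
            continue
        if len(terms) == 2 or halve_orphans:
            value = sum(terms) / 2.0
        else:
            value = terms[0]
        setattr(m, target, float(value))
    return m


def total_fpr(roc_fpr_ratio: float, roc_fpr_fce: float) -> float:
    """Sum of the two independent ROC-derived FPRs (range [0, 2])."""
    for v in (roc_fpr_ratio, roc_fpr_fce):
        if not (0.0 <= v <= 1.0):
            raise PipelineError(f"component FPR {v} outside [0, 1]")
    return roc_fpr_ratio + roc_fpr_fce


def attach_total_fpr(
    merged: Sequence[MergedHit],
    roc_ratio: RocTable,
    roc_fce: RocTable,
) -> list[MergedHit]:
    """Look up ROC FPRs of both coverage scores, sum them, and return the hits
    sorted ascending by total FPR (stable: ties keep input order)."""
    for m in merged:
        m.roc_fpr_ratio = (
            roc_fpr_lookup(roc_ratio, m.coverage_ratio)
            if m.coverage_ratio is not None
            else 1.0
        )
        m.roc_fpr_fce = (
            roc_fpr_lookup(roc_fce, m.coverage_fce)
            if m.coverage_fce is not None
            else 1.0
        )
        m.total_fpr = total_fpr(m.roc_fpr_ratio, m.roc_fpr_fce)
    return sorted(merged, key=lambda m: m.total_fpr)


# ---------------------------------------------------------------------------
# domain-wise scores over an MSA


@dataclass
class DomainScore:
    model_id: str
    measure_kind: str  # 'ratio' | 'fc_evalue'
    value: float  # mean error-adjusted coverage in [0, 1]
    n_contributing_sequences: int


def domain_scores(
    merged: Sequence[tuple[int, MergedHit]],
) -> list[DomainScore]:
    """Average error-adjusted coverage per domain model over the sequences of
    one alignment group.

    ``merged`` yields (sequence index, hit).  Each sequence contributes at
    most one value per model -- the maximum over its hits (a domain is
    detected by its best-supported hit); the domain score is the mean over
    contributing sequences.
    """
    per_model: dict[tuple[str, str], dict[int, float]] = {}
    for seq_idx, m in merged:
        for kind, value in (("ratio", m.coverage_ratio), ("fc_evalue", m.coverage_fce)):
            if value is None:
                continue
            best = per_model.setdefault((m.model_id, kind), {})
            best[seq_idx] = max(best.get(seq_idx, 0.0), value)
    out = []
    for (model_id, kind), by_seq in sorted(per_model.items()):
        vals = list(by_seq.values())
        out.append(
            DomainScore(
                model_id=model_id,
                measure_kind=kind,
                value=float(np.mean(vals)),
                n_contributing_sequences=len(vals),
            )
        )
    return out


def hmmer3_baseline_scores(
    h3_hits: Sequence[tuple[int, SeqDomAlignment]],
    model_lengths: Mapping[str, int],
    evalue_cutoff: float = 0.1,
) -> list[DomainScore]:
    """Undissected baseline: keep H3 hits below the reported-E cutoff and
    score each kept hit by its raw domain coverage (both the H2 term and the
    H3 FPR of the error-adjusted formula set to zero); aggregation as in
    :func:`domain_scores`."""
    per_model: dict[str, dict[int, float]] = {}
    for seq_idx, aln in h3_hits:
        if aln.reported_evalue is None or aln.reported_evalue > evalue_cutoff:
            continue
        cov = model_coverage(aln, model_lengths[aln.model_id])
        best = per_model.setdefault(aln.model_id, {})
        best[seq_idx] = max(best.get(seq_idx, 0.0), cov)
    out = []
    for model_id, by_seq in sorted(per_model.items()):
        vals = list(by_seq.values())
        out.append(
            DomainScore(
                model_id=model_id,
                measure_kind="baseline_coverage",
                value=float(np.mean(vals)),
                n_contributing_sequences=len(vals),
            )
        )
    return out


# ---------------------------------------------------------------------------
# report


def report_table(merged: Sequence[MergedHit]) -> pd.DataFrame:
    """Tabular report of merged hits, sorted ascending by total FPR.

    Undefined values render as '.' when serialized with
    :func:`report_tsv`."""
    rows = []
    for m in merged:
        rows.append(
            {
                "model_id": m.model_id,
                "query_id": m.query_id,
                "seq_range": _span_str(m),
                "coverage_h2": m.coverage_h2,
                "coverage_h3": m.coverage_h3,
                "evalue_h2": m.h2.dissected.evalue_original if m.h2 else None,
                "evalue_h3": m.h3.dissected.evalue_original if m.h3 else None,
                "coverage_ratio": m.coverage_ratio,
                "roc_fpr_ratio": m.roc_fpr_ratio,
                "coverage_fce": m.coverage_fce,
                "roc_fpr_fce": m.roc_fpr_fce,
                "total_fpr": m.total_fpr,
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values("total_fpr", kind="stable").reset_index(drop=True)
    return df


def _span_str(m: MergedHit) -> str:
    hit = m.h2 or m.h3
    a, b = hit.alignment.seq_span
    return f"{a}-{b}"


def report_tsv(merged: Sequence[MergedHit]) -> str:
    df = report_table(merged)
    return df.to_csv(sep="\t", index=False, na_rep=".", float_format="%.6g")
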