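"""Empirical false-positive-rate calibration of dissected-score measures.

The FPR attached to a measure value x (a log10 fold-critical E-value or a
log10 fold-critical/remnant E-value ratio) is the cumulative frequency
P(measure <= x) over a population of *negative* hits -- hits to domain models
outside the query's structural superfamily.  Histograms are binned from
10^-205 to 10^3 at unit log10 steps; a value at a bin edge belongs to the
lower bin (the "<= x" semantics of the cumulative sum).

When no benchmark population is at hand, packaged anchor tables reproduce the
published (cutoff -> FPR) anchor points by monotone log-linear interpolation;
they are a documented reconstruction and swappable data, not a measurement.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .profile_models import Dialect
from .score_dissection import DissectedScore

DEFAULT_BIN_LO = -205.0
DEFAULT_BIN_HI = 3.0

#: E-value cutoff for listing candidate hits when building negative sets
DEFAULT_EVALUE_LIST_CUTOFF = 20.0


class CalibrationError(ValueError):
    pass


@dataclass
class CalibrationTable:
    variant: Dialect
    measure_kind: str  # 'fc_evalue' | 'ratio'
    bin_edges: np.ndarray  # length n+1, increasing
    frequencies: np.ndarray  # length n, sums to 1
    n_samples: int
    provenance: str = "empirical"  # or 'packaged_anchor'

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.bin_edges.ndim != 1 or len(self.bin_edges) != len(self.frequencies) + 1:
            raise CalibrationError("need n+1 bin edges for n frequencies")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise CalibrationError("bin edges must be strictly increasing")
        if abs(float(self.frequencies.sum()) - 1.0) > 1e-9:
            raise CalibrationError(
                f"frequencies sum to {self.frequencies.sum()}, not 1"
            )
        if np.any(self.frequencies < -1e-15):
            raise CalibrationError("negative bin frequency")

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.frequencies)


def build_fpr_table(
    measures: Sequence[float],
    variant: Dialect,
    measure_kind: str,
    bin_lo: float = DEFAULT_BIN_LO,
    bin_hi: float = DEFAULT_BIN_HI,
    bin_step: float = 1.0,
) -> CalibrationTable:
    """Histogram a population of log10 measure values into an FPR table.

    Values outside the bin range are clamped into the end bins with a
    warning, so the cumulative lookup still covers them.
    """
    values = np.asarray(list(measures), dtype=float)
    if values.size == 0:
        raise CalibrationError("cannot calibrate from an empty measure list")
    if not np.all(np.isfinite(values)):
        raise CalibrationError("measure values must be finite")
    edges = np.arange(bin_lo, bin_hi + bin_step / 2, bin_step)
    n_out = int(np.sum((values <= edges[0]) | (values > edges[-1])))
    if n_out:
        warnings.warn(
            f"{n_out} measure value(s) outside [{bin_lo}, {bin_hi}] clamped to end bins",
            stacklevel=2,
        )
    clamped = np.clip(values, edges[0] + 1e-9, edges[-1])
    counts, _ = np.histogram(clamped, bins=edges)
    return CalibrationTable(
        variant=Dialect(variant),
        measure_kind=measure_kind,
        bin_edges=edges,
        frequencies=counts / values.size,
        n_samples=int(values.size),
        provenance="empirical",
    )


def fpr_lookup(t: CalibrationTable, x: float) -> float:
    """Cumulative frequency through the bin containing x: P(measure <= x).

    Nondecreasing in x; 0 below the lowest edge, 1 at/above the top edge.
    """
    edges = t.bin_edges
    if x <= edges[0]:
        return 0.0
    if x >= edges[-1]:
        return 1.0
    # values at an edge belong to the lower bin
    idx = int(np.searchsorted(edges, x, side="left")) - 1
    return float(min(1.0, max(0.0, t.cumulative[idx])))


# ---------------------------------------------------------------------------
# packaged anchor tables

#: published (log10 cutoff -> FPR) anchor points per variant and measure
ANCHOR_POINTS: dict[tuple[str, str], list[tuple[float, float]]] = {
    ("H2", "fc_evalue"): [(-6.0, 0.01), (-3.45, 0.10)],
    ("H3", "fc_evalue"): [(-9.0, 0.01), (-6.0, 0.10)],
    ("H2", "ratio"): [(-2.25, 0.10)],
    ("H3", "ratio"): [(-9.1, 0.10)],
}


def packaged_anchor_table(
    variant: Dialect | str,
    measure_kind: str,
    db_anchor_floor: float = 1e-12,
) -> CalibrationTable:
    """A monotone FPR table log-linearly interpolated through the published
    anchor points, pinned to 0 and 1 at the bin-range limits.

    Every anchor (cutoff, FPR) pair is reproduced exactly by
    :func:`fpr_lookup` because each anchor cutoff is itself a bin edge.
    """
    variant = Dialect(variant)
    try:
        anchors = ANCHOR_POINTS[(variant.value, measure_kind)]
    except KeyError:
        raise CalibrationError(
            f"no packaged anchors for variant={variant.value} measure={measure_kind}"
        )
    lo, hi = DEFAULT_BIN_LO, DEFAULT_BIN_HI
    pts = [(lo, db_anchor_floor)] + sorted(anchors) + [(hi, 1.0)]
    unit = np.arange(lo, hi + 0.5, 1.0)
    edges = np.unique(np.concatenate([unit, [x for x, _ in pts]]))

    xs = np.array([x for x, _ in pts])
    logf = np.log10([f for _, f in pts])
    # cumulative FPR at each upper bin edge; F(lowest edge) = 0 exactly
    cum = 10.0 ** np.interp(edges[1:], xs, logf)
    cum[-1] = 1.0
    cum = np.maximum.accumulate(cum)
    freqs = np.diff(cum, prepend=0.0)
    return CalibrationTable(
        variant=variant,
        measure_kind=measure_kind,
        bin_edges=edges,
        frequencies=freqs,
        n_samples=0,
        provenance="packaged_anchor",
    )


# ---------------------------------------------------------------------------
# negative-measure collection


def collect_negative_measures(
    hits: Iterable[tuple[str, str, DissectedScore]],
    mapping: Mapping[str, set],
    evalue_list_cutoff: float = DEFAULT_EVALUE_LIST_CUTOFF,
) -> dict[tuple[Dialect, str], list[float]]:
    """Gather log10 measures of negative hits for calibration.

    ``hits`` yields (query superfamily id, model id, dissected score); a hit
    is negative when its model is not in the query superfamily's mapped set.
    Hits are admitted at the candidate-listing cutoff on the original E-value;
    ratio lists drop hits whose remnant E-value underflowed to zero.
    """
    out: dict[tuple[Dialect, str], list[float]] = {}
    for superfamily, model_id, d in hits:
        if not superfamily:
            raise CalibrationError("hit without a query superfamily label")
        if d.evalue_original > evalue_list_cutoff:
            continue
        mapped = mapping.get(superfamily, set())
        if model_id in mapped:
            continue  # positive hit; only negatives calibrate error rates
        variant = d.variant
        fc_key = (variant, "fc_evalue")
        log_fc = (
            math.log10(d.evalue_fc) if d.evalue_fc > 0 else DEFAULT_BIN_LO
        )
        out.setdefault(fc_key, []).append(log_fc)
        if d.log10_ratio is not None:
            out.setdefault((variant, "ratio"), []).append(d.log10_ratio)
    return out


# ---------------------------------------------------------------------------
# benchmark ROC tables


@dataclass
class RocTable:
    thresholds: np.ndarray  # 0..1 step 0.01
    tpr: np.ndarray
    fpr: np.ndarray
    measure_kind: str
    provenance: str = "empirical"

    def __post_init__(self) -> None:
        for v in (self.tpr, self.fpr):
            if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
                raise CalibrationError("TPR/FPR must lie in [0, 1]")


def roc_from_scores(
    scores: Sequence[float],
    labels: Sequence[bool],
    measure_kind: str = "ratio",
    step: float = 0.01,
) -> RocTable:
    """ROC over domain-wise scores in [0, 1]: at threshold t a domain is
    predicted positive iff its score >= t; TPR over mapped (positive)
    domains, FPR over negatives."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise CalibrationError("scores and labels differ in length")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise CalibrationError("ROC needs both positive and negative domains")
    thresholds = np.round(np.arange(0.0, 1.0 + step / 2, step), 10)
    tpr = np.array([(scores[labels] >= t).mean() for t in thresholds])
    fpr = np.array([(scores[~labels] >= t).mean() for t in thresholds])
    return RocTable(thresholds=thresholds, tpr=tpr, fpr=fpr, measure_kind=measure_kind)


def roc_fpr_lookup(r: RocTable, score: float) -> float:
    """Expected FPR of admitting hits at the given coverage score: the FPR at
    the largest tabulated threshold <= score (conservative rounding down)."""
    score = min(max(float(score), 0.0), 1.0)
    idx = int(np.searchsorted(r.thresholds, score + 1e-12, side="right")) - 1
    idx = max(idx, 0)
    return float(r.fpr[idx])


def roc_tpr_lookup(r: RocTable, score: float) -> float:
    score = min(max(float(score), 0.0), 1.0)
    idx = int(np.searchsorted(r.thresholds, score + 1e-12, side="right")) - 1
    idx = max(idx, 0)
    return float(r.tpr[idx])


# ---------------------------------------------------------------------------
# serialization


def write_calibration_tsv(tables: Iterable[CalibrationTable]) -> str:
    lines = ["variant\tmeasure_kind\tbin_lo\tbin_hi\tfrequency"]
    for t in tables:
        for lo, hi, f in zip(t.bin_edges[:-1], t.bin_edges[1:], t.frequencies):
            lines.append(f"{t.variant.value}\t{t.measure_kind}\t{lo:.6g}\t{hi:.6g}\t{f:.12g}")
    return "\n".join(lines) + "\n"


def read_calibration_tsv(text: str) -> list[CalibrationTable]:
    rows = [ln.split("\t") for ln in text.splitlines()[1:] if ln.strip()]
    tables: dict[tuple[str, str], list[tuple[float, float, float]]] = {}
    for variant, kind, lo, hi, f in rows:
        tables.setdefault((variant, kind), []).append((float(lo), float(hi), float(f)))
    out = []
    for (variant, kind), bins in tables.items():
        bins.sort()
        edges = np.array([b[0] for b in bins] + [bins[-1][1]])
        freqs = np.array([b[2] for b in bins])
        out.append(
            CalibrationTable(
                variant=Dialect(variant),
                measure_kind=kind,
                bin_edges=edges,
                frequencies=freqs / freqs.sum(),
                n_samples=0,
                provenance="empirical",
            )
        )
    return out


def read_mapping_tsv(text: str) -> dict[str, set]:
    """SCOP-superfamily-to-domain-model mapping: superfamily_id <TAB> model
    accession, one pair per line."""
    out: dict[str, set] = {}
    for ln in text.splitlines():
        if not ln.strip() or ln.startswith("#"):
            continue
        sf, acc = ln.split("\t")
        out.setdefault(sf, set()).add(acc)
    return out


def write_mapping_tsv(mapping: Mapping[str, set]) -> str:
    lines = []
    for sf in sorted(mapping):
        for acc in sorted(mapping[sf]):
            lines.append(f"{sf}\t{acc}")
    return "\n".join(lines) + "\n"
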