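"""Per-model-column fold-critical / remnant annotation.

A domain model's columns are labelled either from the DSSP string of a
representative structure (fold-critical codes H, E, I, T, S; remnant gaps
'-'/'?') or, absent a structure, from a statistically weighted combination of
sequence-property predictors:

* quality score -- column conservation from the model's seed alignment
  (BLOSUM62, gap-penalized);
* secondary-structure labels (externally supplied, e.g. PSIPred .ss2 files);
* SEG -- Wootton--Federhen low-complexity segmentation;
* GlobPlot-style globularity from a running-sum propensity curve.

Per-column predictor scores in [0, 1] are combined as a weighted sum
(weights are each predictor's best benchmark TPR-FPR margin), min--max
normalized over the model's own columns, and thresholded at 0.5.  Remnant
runs shorter than 10 columns are re-labelled fold-critical: such short
non-globular stretches are typically well-conserved inter-element linkers.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DSSP_FOLD_CODES = frozenset("HEITS")
DSSP_REMNANT_CODES = frozenset("-?")

DEFAULT_MIN_REMNANT_RUN = 10


class Label(Enum):
    FOLD_CRITICAL = "F"
    REMNANT = "R"


class Provenance(str, Enum):
    DSSP_DERIVED = "dssp_derived"
    PREDICTOR_DERIVED = "predictor_derived"


class AnnotationError(ValueError):
    pass


@dataclass
class ColumnMask:
    """Fold-critical/remnant labels for the K columns of one domain model."""

    model_id: str
    K: int
    labels: list  # list[Label], length K
    provenance: Provenance
    raw_scores: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.labels) != self.K:
            raise AnnotationError(
                f"mask for {self.model_id!r}: {len(self.labels)} labels != K={self.K}"
            )

    @property
    def label_string(self) -> str:
        return "".join(l.value for l in self.labels)

    def remnant_fraction(self) -> float:
        return sum(1 for l in self.labels if l is Label.REMNANT) / self.K

    def remnant_segments(self) -> list[int]:
        """Lengths of maximal remnant runs."""
        return [
            sum(1 for _ in grp)
            for lab, grp in itertools.groupby(self.labels)
            if lab is Label.REMNANT
        ]


@dataclass
class PredictorScoreVector:
    predictor: str  # qualityscore | psipred | seg | globplot | external
    scores: np.ndarray  # length K, each in [0, 1]
    n_sequences: int

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.size and (self.scores.min() < -1e-12 or self.scores.max() > 1 + 1e-12):
            raise AnnotationError(
                f"{self.predictor} scores must lie in [0, 1]; "
                f"range is [{self.scores.min()}, {self.scores.max()}]"
            )


@dataclass
class WeightConfig:
    """Weights and post-processing constants of the weighted-scoring scheme."""

    weights: dict = field(
        default_factory=lambda: {
            "qualityscore": 0.61,
            "psipred": 0.50,
            "seg": 0.41,
            "globplot": 0.39,
        }
    )
    threshold: float = 0.5
    min_remnant_run: int = DEFAULT_MIN_REMNANT_RUN
    min_sequences_for_predictors: int = 5

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.weights.values()):
            raise AnnotationError("all predictor weights must be > 0")
        if not (0.0 < self.threshold < 1.0):
            raise AnnotationError("threshold must lie in (0, 1)")


# ---------------------------------------------------------------------------
# mask construction


def merge_short_remnant_runs(
    labels: Sequence[Label], min_run: int = DEFAULT_MIN_REMNANT_RUN
) -> list[Label]:
    """Re-label remnant runs shorter than ``min_run`` as fold-critical.

    Idempotent: merging never creates new remnant runs.
    """
    out: list[Label] = []
    for lab, grp in itertools.groupby(labels):
        run = list(grp)
        if lab is Label.REMNANT and len(run) < min_run:
            run = [Label.FOLD_CRITICAL] * len(run)
        out.extend(run)
    return out


_warned_codes: set[str] = set()


def mask_from_dssp(
    dssp_column_string: str,
    fold_codes: frozenset = DSSP_FOLD_CODES,
    model_id: str = "model",
    min_remnant_run: int = DEFAULT_MIN_REMNANT_RUN,
    unknown_policy: str = "remnant",
) -> ColumnMask:
    """Label model columns from a per-column DSSP string.

    Codes in ``fold_codes`` (default H/E/I/T/S) are fold-critical; '-' and '?'
    are remnant.  Codes outside both sets (e.g. 'G', 'B', 'C') are handled per
    ``unknown_policy``: ``"remnant"`` (default, by elimination, with a
    once-per-code warning), ``"fold_critical"``, or ``"error"``.
    """
    labels: list[Label] = []
    for pos, code in enumerate(dssp_column_string):
        if code in fold_codes:
            labels.append(Label.FOLD_CRITICAL)
        elif code in DSSP_REMNANT_CODES:
            labels.append(Label.REMNANT)
        elif unknown_policy == "error":
            raise AnnotationError(
                f"unknown DSSP code {code!r} at column {pos + 1} of {model_id!r}"
            )
        else:
            if code not in _warned_codes:
                _warned_codes.add(code)
                warnings.warn(
                    f"DSSP code {code!r} is outside the fold set {sorted(fold_codes)} "
                    f"and the remnant set; treating as {unknown_policy}",
                    stacklevel=2,
                )
            labels.append(
                Label.REMNANT if unknown_policy == "remnant" else Label.FOLD_CRITICAL
            )
    return ColumnMask(
        model_id=model_id,
        K=len(labels),
        labels=merge_short_remnant_runs(labels, min_remnant_run),
        provenance=Provenance.DSSP_DERIVED,
    )


def mask_from_scores(
    normscores: np.ndarray,
    cfg: WeightConfig | None = None,
    model_id: str = "model",
) -> ColumnMask:
    """Threshold normalized weighted scores into a mask (score >= threshold is
    fold-critical; a tie at the threshold is fold-critical), then merge short
    remnant runs."""
    cfg = cfg or WeightConfig()
    normscores = np.asarray(normscores, dtype=float)
    if normscores.min() < -1e-12 or normscores.max() > 1 + 1e-12:
        raise AnnotationError("normalized scores must lie in [0, 1]")
    labels = [
        Label.FOLD_CRITICAL if s >= cfg.threshold else Label.REMNANT for s in normscores
    ]
    return ColumnMask(
        model_id=model_id,
        K=len(labels),
        labels=merge_short_remnant_runs(labels, cfg.min_remnant_run),
        provenance=Provenance.PREDICTOR_DERIVED,
        raw_scores=normscores,
    )


# ---------------------------------------------------------------------------
# per-column predictor scores


def _column_iter(msa: Sequence[str]):
    K = len(msa[0])
    if any(len(s) != K for s in msa):
        raise AnnotationError("aligned sequences differ in length")
    for k in range(K):
        yield k, [s[k] for s in msa]


def predictor_column_scores(
    msa: Sequence[str],
    per_residue_labels: Sequence[Sequence[int]],
    predictor: str = "external",
) -> PredictorScoreVector:
    """Aggregate per-sequence structured(1)/unstructured(0) residue labels to
    per-column scores: the structured fraction over non-gap residues.
    All-gap columns score 0."""
    if len(per_residue_labels) != len(msa):
        raise AnnotationError("one label vector per aligned sequence is required")
    for i, (seq, labs) in enumerate(zip(msa, per_residue_labels)):
        n_res = sum(1 for c in seq if c != "-")
        if len(labs) != n_res:
            raise AnnotationError(
                f"sequence {i}: {len(labs)} labels for {n_res} residues"
            )
    cursors = [0] * len(msa)
    scores = []
    for _, column in _column_iter(list(msa)):
        hits = 0
        total = 0
        for i, c in enumerate(column):
            if c == "-":
                continue
            total += 1
            hits += 1 if per_residue_labels[i][cursors[i]] else 0
            cursors[i] += 1
        scores.append(hits / total if total else 0.0)
    return PredictorScoreVector(predictor, np.array(scores), n_sequences=len(msa))


_AMBIGUOUS = set("XBZUO")


def seg_labels(
    sequence: str,
    window: int = 25,
    locut: float = 3.1,
    hicut: float = 3.4,
) -> np.ndarray:
    """Wootton--Federhen two-threshold low-complexity segmentation.

    Windowed Shannon entropy (bits) of the residue composition; residues lying
    in a maximal run of positions whose minimum covering-window entropy is
    below ``hicut``, provided the run contains a seed position below
    ``locut``, are labelled low-complexity (0); everything else structured (1).
    Sequences shorter than the window use a single whole-sequence window.
    Ambiguous residues (X/B/Z/U/O) are excluded from the entropy computation.
    """
    L = len(sequence)
    if L < 1:
        raise AnnotationError("sequence must have length >= 1")
    W = min(window, L)

    def entropy(chunk: str) -> float:
        counts: dict[str, int] = {}
        n = 0
        for c in chunk:
            if c in _AMBIGUOUS:
                continue
            counts[c] = counts.get(c, 0) + 1
            n += 1
        if n == 0:
            return float("inf")
        return -sum((v / n) * math.log2(v / n) for v in counts.values())

    win_h = np.array([entropy(sequence[i : i + W]) for i in range(L - W + 1)])
    hmin = np.full(L, np.inf)
    for i, h in enumerate(win_h):
        hmin[i : i + W] = np.minimum(hmin[i : i + W], h)

    low = np.zeros(L, dtype=bool)
    in_run = hmin < hicut
    i = 0
    while i < L:
        if not in_run[i]:
            i += 1
            continue
        j = i
        while j < L and in_run[j]:
            j += 1
        if np.any(hmin[i:j] < locut):
            low[i:j] = True
        i = j
    return (~low).astype(int)


#: Globularity propensities (order-promoting positive, disorder-promoting
#: negative).  Negated TOP-IDP disorder scale (Campen et al. 2008), a
#: standard residue-level disorder propensity ranking; swap in any other
#: scale via the ``propensities`` argument.
GLOBULARITY_PROPENSITY: dict[str, float] = {
    "W": 0.884, "F": 0.697, "Y": 0.510, "I": 0.486, "M": 0.397,
    "L": 0.326, "V": 0.121, "N": -0.007, "C": -0.020, "T": -0.059,
    "A": -0.060, "G": -0.166, "R": -0.180, "D": -0.192, "H": -0.303,
    "Q": -0.318, "S": -0.341, "K": -0.586, "E": -0.736, "P": -0.987,
}


def globplot_labels(
    sequence: str,
    smoothframe: int = 10,
    domjoinframe: int = 10,
    dompeakframe: int = 40,
    disjoinframe: int = 4,
    dispeakframe: int = 5,
    propensities: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Globular/disordered labels from a running-sum propensity curve.

    The per-residue globularity propensity is smoothed over ``smoothframe``;
    upward stretches of the running sum (positive smoothed propensity) of
    length >= ``dompeakframe`` (joined across gaps <= ``domjoinframe``) are
    globular, downward stretches >= ``dispeakframe`` (joined across
    <= ``disjoinframe``) disordered; unassigned residues default to
    structured.  Sequences shorter than ``dompeakframe`` fall back to
    all-structured (the curve cannot support a globular domain call).
    """
    L = len(sequence)
    if L < 1:
        raise AnnotationError("sequence must have length >= 1")
    table = propensities or GLOBULARITY_PROPENSITY
    if L < dompeakframe:
        return np.ones(L, dtype=int)
    prop = np.array([table.get(c, 0.0) for c in sequence])
    kernel = np.ones(smoothframe) / smoothframe
    smooth = np.convolve(prop, kernel, mode="same")

    def runs(mask: np.ndarray, join: int, min_len: int) -> np.ndarray:
        # join nearby runs, then keep the long ones
        claimed = np.zeros(L, dtype=bool)
        spans = []
        i = 0
        while i < L:
            if not mask[i]:
                i += 1
                continue
            j = i
            while j < L and mask[j]:
                j += 1
            if spans and i - spans[-1][1] <= join:
                spans[-1] = (spans[-1][0], j)
            else:
                spans.append((i, j))
            i = j
        for a, b in spans:
            if b - a >= min_len:
                claimed[a:b] = True
        return claimed

    glob = runs(smooth > 0, domjoinframe, dompeakframe)
    dis = runs(smooth < 0, disjoinframe, dispeakframe)
    labels = np.ones(L, dtype=int)
    labels[dis] = 0
    labels[glob] = 1
    # positions claimed by both (bridged joins): the local curve sign decides
    both = glob & dis
    labels[both] = (smooth[both] >= 0).astype(int)
    return labels


def _blosum62():
    from Bio.Align import substitution_matrices

    return substitution_matrices.load("BLOSUM62")


def quality_score(
    msa: Sequence[str],
    substitution_matrix=None,
) -> PredictorScoreVector:
    """Per-column conservation in [0, 1] from normalized mean pairwise
    substitution-matrix similarity, gap-penalized multiplicatively.

    Pair similarity is ``(B(a,b) - B_min) / (min(B(a,a), B(b,b)) - B_min)``,
    which is 1 for any identical pair and 0 for the least similar pair in the
    matrix; the column score is the mean over non-gap residue pairs times the
    non-gap fraction.  Columns with fewer than two residues score 0.
    Ambiguous residues enter at the matrix-average similarity (warned once).
    """
    if len(msa) < 2:
        raise AnnotationError("conservation is undefined for a single-sequence MSA")
    mat = substitution_matrix if substitution_matrix is not None else _blosum62()
    alphabet = [c for c in str(mat.alphabet) if c.isalpha() and c not in _AMBIGUOUS]
    bmin = min(mat[a][b] for a in alphabet for b in alphabet)

    def pair_sim(a: str, b: str) -> float:
        denom = min(mat[a][a], mat[b][b]) - bmin
        return max(0.0, min(1.0, (mat[a][b] - bmin) / denom))

    neutral = float(
        np.mean([pair_sim(a, b) for a in alphabet for b in alphabet])
    )
    warned = False
    n = len(msa)
    scores = []
    for _, column in _column_iter(list(msa)):
        residues = [c for c in column if c != "-"]
        if len(residues) < 2:
            scores.append(0.0)
            continue
        sims = []
        for a, b in itertools.combinations(residues, 2):
            if a in _AMBIGUOUS or b in _AMBIGUOUS:
                if not warned:
                    warnings.warn("ambiguous residue scored at matrix average", stacklevel=2)
                    warned = True
                sims.append(neutral)
            else:
                sims.append(pair_sim(a, b))
        gap_free = len(residues) / n
        scores.append(float(np.mean(sims)) * gap_free)
    return PredictorScoreVector("qualityscore", np.array(scores), n_sequences=n)


# ---------------------------------------------------------------------------
# weighted combination


def combine_weighted(
    vectors: Iterable[PredictorScoreVector],
    cfg: WeightConfig | None = None,
) -> np.ndarray:
    """Position-wise weighted sum of predictor score vectors.

    Models summarized from fewer than ``cfg.min_sequences_for_predictors``
    sequences use the quality-score vector alone (the other predictors are
    dropped before summing).
    """
    cfg = cfg or WeightConfig()
    vecs = list(vectors)
    by_name = {v.predictor: v for v in vecs}
    if "qualityscore" not in by_name:
        raise AnnotationError("the qualityscore vector is required")
    qs = by_name["qualityscore"]
    if qs.n_sequences < cfg.min_sequences_for_predictors:
        vecs = [qs]
    K = len(qs.scores)
    total = np.zeros(K)
    for v in vecs:
        if len(v.scores) != K:
            raise AnnotationError(
                f"{v.predictor} vector length {len(v.scores)} != {K}"
            )
        try:
            w = cfg.weights[v.predictor]
        except KeyError:
            raise AnnotationError(f"no weight configured for predictor {v.predictor!r}")
        total += v.scores * w
    return total


def normalize_scores(weighted: np.ndarray) -> np.ndarray:
    """Min--max normalization over the model's own columns.

    A constant input carries no positional information; it maps to 0.5
    everywhere (exactly the decision threshold) with a degeneracy warning.
    """
    weighted = np.asarray(weighted, dtype=float)
    lo, hi = float(weighted.min()), float(weighted.max())
    if hi <= lo:
        warnings.warn("degenerate normalization: constant weighted scores", stacklevel=2)
        return np.full(weighted.shape, 0.5)
    return (weighted - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# summaries and predictor benchmarking


@dataclass
class MaskStats:
    per_model: pd.DataFrame  # model_id, K, n_remnant, remnant_ratio
    segment_lengths: np.ndarray  # pooled surviving remnant-segment lengths
    n_ratio_above_half: int
    n_ratio_one: int


def mask_stats(masks: Iterable[ColumnMask]) -> MaskStats:
    """Remnant/total ratios per model and the pooled histogram of remnant
    segment lengths (only runs surviving the short-run merge exist here).

    Models with ratio 1 have no fold-critical residues at all -- a red flag
    for homology searching."""
    masks = list(masks)
    if not masks:
        raise AnnotationError("empty mask collection")
    rows = []
    seg_lengths: list[int] = []
    for m in masks:
        ratio = m.remnant_fraction()
        rows.append(
            {
                "model_id": m.model_id,
                "K": m.K,
                "n_remnant": int(round(ratio * m.K)),
                "remnant_ratio": ratio,
            }
        )
        seg_lengths.extend(m.remnant_segments())
    df = pd.DataFrame(rows)
    return MaskStats(
        per_model=df,
        segment_lengths=np.array(seg_lengths, dtype=int),
        n_ratio_above_half=int((df["remnant_ratio"] > 0.5).sum()),
        n_ratio_one=int((df["remnant_ratio"] == 1.0).sum()),
    )


def predictor_roc(
    predicted_scores: Mapping[str, np.ndarray],
    reference_masks: Mapping[str, ColumnMask],
    thresholds: np.ndarray | None = None,
) -> pd.DataFrame:
    """Score-residue-pair ROC of predicted column scores against reference
    masks (fold-critical = positive; predicted positive at score >= t)."""
    if thresholds is None:
        thresholds = np.round(np.arange(0.05, 0.951, 0.05), 2)
    common = sorted(set(predicted_scores) & set(reference_masks))
    if not common:
        raise AnnotationError("predicted and reference model sets are disjoint")
    scores = np.concatenate([np.asarray(predicted_scores[m], dtype=float) for m in common])
    truth = np.concatenate(
        [
            np.array([l is Label.FOLD_CRITICAL for l in reference_masks[m].labels])
            for m in common
        ]
    )
    if scores.shape != truth.shape:
        raise AnnotationError("score vectors and reference masks disagree in length")
    rows = []
    for t in thresholds:
        pred = scores >= t
        tp = int(np.sum(pred & truth))
        fp = int(np.sum(pred & ~truth))
        fn = int(np.sum(~pred & truth))
        tn = int(np.sum(~pred & ~truth))
        tpr = tp / (tp + fn) if tp + fn else 0.0
        fpr = fp / (fp + tn) if fp + tn else 0.0
        rows.append(
            {"threshold": float(t), "tp": tp, "fp": fp, "fn": fn, "tn": tn,
             "tpr": tpr, "fpr": fpr, "tpr_minus_fpr": tpr - fpr}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# exchange formats


def write_mask_tsv(masks: Iterable[ColumnMask]) -> str:
    """Canonical annotation exchange format: model_id, K, label string
    (F = fold-critical, R = remnant), provenance."""
    lines = ["model_id\tK\tlabels\tprovenance"]
    for m in masks:
        lines.append(f"{m.model_id}\t{m.K}\t{m.label_string}\t{m.provenance.value}")
    return "\n".join(lines) + "\n"


def read_mask_tsv(text: str) -> list[ColumnMask]:
    masks = []
    lines = [l for l in text.splitlines() if l.strip()]
    for ln in lines[1:]:
        model_id, k, labstr, prov = ln.split("\t")
        labels = [Label.FOLD_CRITICAL if c == "F" else Label.REMNANT for c in labstr]
        masks.append(ColumnMask(model_id, int(k), labels, Provenance(prov)))
    return masks


def read_dssp_tsv(text: str) -> dict[str, str]:
    """Two-column TSV (model_id, per-column DSSP string)."""
    out = {}
    for ln in text.splitlines():
        if not ln.strip() or ln.startswith("#"):
            continue
        model_id, s = ln.split("\t")
        out[model_id] = s
    return out


def read_ss2_labels(text: str) -> list[int]:
    """PSIPred vertical (.ss2) adapter: H/E collapse to structured (1), C to
    unstructured (0)."""
    labels = []
    for ln in text.splitlines():
        toks = ln.split()
        if len(toks) >= 3 and toks[0].isdigit():
            labels.append(1 if toks[2] in ("H", "E") else 0)
    return labels
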