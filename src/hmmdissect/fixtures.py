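"""Synthetic profiles, sequences and benchmarks.

The generator builds toy domain models with a planted consensus and an
optional interior *remnant block*: columns whose match emissions are nearly
flat against the background, emulating the non-globular linkers of real
domain models.  Query sequences emitted from a mapped model carry point
mutations on the fold-critical columns and replace the remnant block with
unrelated low-complexity junk, so the full alignment score is dragged down
while the fold-critical sum stays intact -- the planted false-negative
scenario that score dissection is meant to rescue.  Decoy sequences are
background noise and exercise the negative side.

Extreme-value parameters are calibrated per profile by simulating alignment
scores of random background sequences (Gumbel fit for glocal search,
exponential-tail fit for local search); the batch score-only Viterbi keeps
this cheap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .fold_annotation import ColumnMask, Label, Provenance
from .profile_models import (
    AMINO_ALPHABET,
    Dialect,
    EvdParams,
    NullModel,
    ProfileHMM,
    TailKind,
)

_A = len(AMINO_ALPHABET)


# ---------------------------------------------------------------------------
# batch score-only Viterbi (used for EVD calibration)


def viterbi_scores_batch(p: ProfileHMM, seqs_idx: np.ndarray, glocal: bool) -> np.ndarray:
    """Best alignment scores for a batch of equal-length index-encoded
    sequences (shape (B, L)); no traceback."""
    B, L = seqs_idx.shape
    K = p.K
    NEG = -1e30
    mm, mi, md, im, ii, dm, dd = (
        np.nan_to_num(p.transitions[k], neginf=NEG) for k in (
            "mm", "mi", "md", "im", "ii", "dm", "dd")
    )
    begin = np.full(K, NEG)
    endv = np.full(K, NEG)
    if glocal:
        begin[0] = p.entry_m1 if math.isfinite(p.entry_m1) else NEG
        if K > 1 and math.isfinite(p.entry_d1):
            cum = p.entry_d1
            for k in range(2, K + 1):
                begin[k - 1] = cum + dm[k - 2]
                cum += dd[k - 2]
        mexit = float(p.m_to_e[K - 1])
        endv[K - 1] = mexit if math.isfinite(mexit) else 0.0
        cum = 0.0
        for k in range(K - 1, 0, -1):
            endv[k - 1] = md[k - 1] + cum
            cum += dd[k - 1]
    else:
        begin = np.nan_to_num(p.b_to_m, neginf=NEG)
        endv = np.nan_to_num(p.m_to_e, neginf=NEG)

    match = np.nan_to_num(p.match_emissions, neginf=NEG)  # (K, 20)
    insert = np.nan_to_num(p.insert_emissions, neginf=NEG)

    VM = np.full((B, K), NEG)
    VI = np.full((B, K), NEG)
    VD = np.full((B, K), NEG)
    best = np.full(B, NEG)
    for j in range(L):
        em = match[:, seqs_idx[:, j]].T  # (B, K)
        ei = insert[:, seqs_idx[:, j]].T
        new_m = np.maximum(
            begin[None, :],
            np.concatenate(
                [
                    np.full((B, 1), NEG),
                    np.maximum.reduce(
                        [VM[:, :-1] + mm[:-1], VI[:, :-1] + im[:-1], VD[:, :-1] + dm[:-1]]
                    ),
                ],
                axis=1,
            ),
        ) + em
        new_i = np.maximum(VM + mi, VI + ii) + ei
        new_d = np.full((B, K), NEG)
        for k in range(1, K):
            new_d[:, k] = np.maximum(new_m[:, k - 1] + md[k - 1], new_d[:, k - 1] + dd[k - 1])
        VM, VI, VD = new_m, new_i, new_d
        best = np.maximum(best, np.max(VM + endv[None, :], axis=1))
    return best + p.invariant_terms


def _encode(seqs: list[str]) -> np.ndarray:
    lut = {c: i for i, c in enumerate(AMINO_ALPHABET)}
    return np.array([[lut[c] for c in s] for s in seqs])


# ---------------------------------------------------------------------------
# synthetic profiles


def _base_profile(
    K: int,
    rng: np.random.Generator,
    consensus: str,
    remnant_block: tuple[int, int] | None,
    dialect: Dialect,
) -> ProfileHMM:
    bg = np.full(_A, 1.0 / _A)
    match_p = np.empty((K, _A))
    rem_cols = set()
    if remnant_block is not None:
        rem_cols = set(range(remnant_block[0], remnant_block[1] + 1))
    for k in range(1, K + 1):
        ci = AMINO_ALPHABET.index(consensus[k - 1])
        if k in rem_cols:
            # remnant column: positionally conserved in the seed alignment
            # (a family-specific low-complexity linker) yet structurally
            # meaningless -- an unrelated query linker scores negative here,
            # while a linker of the same simple pattern scores spuriously high
            p = np.full(_A, (1.0 - 0.40) / (_A - 1))
            p[ci] = 0.40
        else:
            p = np.full(_A, (1.0 - 0.60) / (_A - 1))
            p[ci] = 0.60
        match_p[k - 1] = p
    match_bits = np.log2(match_p / bg)
    insert_bits = np.zeros((K, _A))  # inserts emit background

    trans = {
        "mm": np.full(K, math.log2(0.89)),
        "mi": np.full(K, math.log2(0.05)),
        "md": np.full(K, math.log2(0.06)),
        "im": np.full(K, math.log2(0.80)),
        "ii": np.full(K, math.log2(0.20)),
        "dm": np.full(K, math.log2(0.70)),
        "dd": np.full(K, math.log2(0.30)),
    }
    b_to_m = np.full(K, math.log2(2.0 / (K * (K + 1))))
    m_to_e = np.zeros(K)
    return ProfileHMM(
        model_id="synthetic",
        dialect=dialect,
        K=K,
        match_emissions=match_bits,
        insert_emissions=insert_bits,
        transitions=trans,
        b_to_m=b_to_m,
        m_to_e=m_to_e,
        entry_m1=math.log2(0.97),
        entry_d1=math.log2(0.03),
        null_model=NullModel(bg),
    )


def calibrate_profile(
    p: ProfileHMM,
    seed: int,
    n_sequences: int = 1000,
    seq_len: int | None = None,
    tail_fraction: float = 0.1,
) -> EvdParams:
    """Fit EVD parameters to the score distribution of random background
    sequences: a Gumbel for the glocal (H2) dialect, an exponential tail for
    the local (H3) dialect (onset at the upper ``tail_fraction`` quantile)."""
    rng = np.random.default_rng(seed)
    L = seq_len if seq_len is not None else max(60, 2 * p.K)
    seqs_idx = rng.integers(0, _A, size=(n_sequences, L))
    glocal = p.dialect is Dialect.H2
    scores = viterbi_scores_batch(p, seqs_idx, glocal=glocal)
    if glocal:
        loc, scale = stats.gumbel_r.fit(scores)
        return EvdParams(mu=float(loc), lam=1.0 / float(scale), tail_kind=TailKind.GUMBEL)
    tau = float(np.quantile(scores, 1.0 - tail_fraction))
    excess = scores[scores > tau] - tau
    if excess.size == 0 or float(np.mean(excess)) <= 0:
        # degenerate score distribution (tiny models): fall back to the
        # canonical forward-tail slope of log(2) per bit
        lam = math.log(2.0)
    else:
        lam = 1.0 / float(np.mean(excess))
    # shift the onset so exp(-lam (x - mu)) matches P(S >= tau) = tail_fraction
    mu = tau + math.log(tail_fraction) / lam
    return EvdParams(mu=float(mu), lam=float(lam), tail_kind=TailKind.EXPONENTIAL_TAIL)


def generate_synthetic_profile(
    K: int,
    seed: int,
    dialect: Dialect | str = Dialect.H2,
    planted_consensus: str | None = None,
    remnant_block: tuple[int, int] | None = None,
    model_id: str = "SYN001",
    calibrate: bool = True,
    n_calibration_sequences: int = 1000,
) -> tuple[ProfileHMM, str]:
    """A toy calibrated profile with emissions elevated along a planted
    consensus; returns (profile, consensus sequence).

    Deterministic in ``seed``: the same seed yields byte-identical model
    files.  ``remnant_block`` (1-based inclusive column range) makes those
    columns nearly uninformative, emulating a non-globular stretch.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    dialect = Dialect(dialect)
    rng = np.random.default_rng(seed)
    if planted_consensus is None:
        planted_consensus = "".join(
            AMINO_ALPHABET[i] for i in rng.integers(0, _A, size=K)
        )
    if len(planted_consensus) != K:
        raise ValueError("planted consensus length must equal K")
    p = _base_profile(K, rng, planted_consensus, remnant_block, dialect)
    p.model_id = model_id
    if calibrate:
        p.evd = calibrate_profile(
            p, seed=int(rng.integers(0, 2**31 - 1)), n_sequences=n_calibration_sequences
        )
    return p, planted_consensus


def true_mask(model_id: str, K: int, remnant_block: tuple[int, int] | None) -> ColumnMask:
    """The generator's ground-truth fold-critical/remnant mask."""
    labels = [Label.FOLD_CRITICAL] * K
    if remnant_block is not None:
        for k in range(remnant_block[0], remnant_block[1] + 1):
            labels[k - 1] = Label.REMNANT
    return ColumnMask(
        model_id=model_id, K=K, labels=labels, provenance=Provenance.DSSP_DERIVED
    )


# ---------------------------------------------------------------------------
# benchmark generation


@dataclass
class BenchmarkData:
    """A self-contained synthetic remote-homology benchmark."""

    profiles_h2: dict  # model_id -> ProfileHMM (Gumbel-calibrated)
    profiles_h3: dict  # model_id -> ProfileHMM (exponential-tail-calibrated)
    masks: dict  # model_id -> ColumnMask (ground truth)
    consensus: dict  # model_id -> str
    remnant_blocks: dict  # model_id -> (lo, hi) or None
    mapping: dict  # superfamily_id -> set of model_ids
    sequences: list = field(default_factory=list)  # (query_id, superfamily, seq, is_decoy)
    truth: dict = field(default_factory=dict)  # (query_id, model_id) -> bool
    model_lengths: dict = field(default_factory=dict)


def _mutate(
    seq: str, rng: np.random.Generator, rate: float
) -> str:
    out = []
    for c in seq:
        if rng.random() < rate:
            out.append(AMINO_ALPHABET[int(rng.integers(0, _A))])
        else:
            out.append(c)
    return "".join(out)


def _low_complexity_junk(rng: np.random.Generator, length: int) -> str:
    # a two-letter alphabet stretch: decidedly non-globular
    pair = rng.choice(list(AMINO_ALPHABET), size=2, replace=False)
    return "".join(str(rng.choice(pair)) for _ in range(length))


def generate_benchmark(
    n_superfamilies: int = 6,
    n_sequences: int = 4,
    n_models: int = 12,
    contamination: float = 0.5,
    seed: int = 0,
    K: int = 56,
    remnant_len: int = 26,
    mutation_rate: float = 0.08,
    sibling_divergence: float = 0.15,
    decoy_remnant_noise: float = 0.10,
    n_calibration_sequences: int = 1000,
) -> BenchmarkData:
    """Profiles + query sequences + superfamily mapping + truth labels.

    Models of one superfamily descend from a common superfamily consensus
    (each model's consensus diverged by ``sibling_divergence``), emulating
    distantly homologous domain models sharing a fold.  Each of the
    superfamily's ``n_sequences`` queries is emitted from one mapped model
    with ``mutation_rate`` point noise on fold-critical columns and its
    remnant block replaced by unrelated low-complexity junk -- the planted
    false-negative scenario: the junk drags the full score down while the
    fold-critical sum stays strong.

    A ``contamination`` fraction of extra queries are *remnant mimics*: their
    fold-critical part is background noise but their linker reproduces a
    foreign model's remnant consensus (at ``decoy_remnant_noise``), the
    spurious positionally-conserved low-complexity similarity that fools an
    undissected search.  They are negatives for every model, populate the
    calibration histograms, and exercise the FP class.
    """
    if min(n_superfamilies, n_sequences, n_models) < 1:
        raise ValueError("benchmark sizes must be >= 1")
    rng = np.random.default_rng(seed)
    per_sf = max(1, n_models // n_superfamilies)
    bench = BenchmarkData(
        profiles_h2={}, profiles_h3={}, masks={}, consensus={},
        remnant_blocks={}, mapping={},
    )
    rem_block = (K // 2 - remnant_len // 2 + 1, K // 2 - remnant_len // 2 + remnant_len)
    sf_ids = [f"sf{s:02d}" for s in range(n_superfamilies)]
    sf_consensus = {
        sf: "".join(AMINO_ALPHABET[i] for i in rng.integers(0, _A, size=K))
        for sf in sf_ids
    }
    sf_of_model: dict[str, str] = {}
    model_ids = []
    for s, sf in enumerate(sf_ids):
        n_here = per_sf if s < n_superfamilies - 1 else n_models - per_sf * (n_superfamilies - 1)
        bench.mapping[sf] = set()
        for j in range(n_here):
            mid = f"M{len(model_ids):03d}"
            model_ids.append(mid)
            bench.mapping[sf].add(mid)
            sf_of_model[mid] = sf
            cons = _mutate(sf_consensus[sf], rng, sibling_divergence)
            mseed = int(rng.integers(0, 2**31 - 1))
            p2, _ = generate_synthetic_profile(
                K, mseed, Dialect.H2, planted_consensus=cons, remnant_block=rem_block,
                model_id=mid, n_calibration_sequences=n_calibration_sequences,
            )
            p3, _ = generate_synthetic_profile(
                K, mseed, Dialect.H3, planted_consensus=cons, remnant_block=rem_block,
                model_id=mid, n_calibration_sequences=n_calibration_sequences,
            )
            bench.profiles_h2[mid] = p2
            bench.profiles_h3[mid] = p3
            bench.consensus[mid] = cons
            bench.remnant_blocks[mid] = rem_block
            bench.masks[mid] = true_mask(mid, K, rem_block)
            bench.model_lengths[mid] = K

    lo, hi = rem_block

    def _query_from(cons: str) -> str:
        junk = _low_complexity_junk(rng, hi - lo + 1 + 4)
        flank_n = "".join(AMINO_ALPHABET[i] for i in rng.integers(0, _A, size=8))
        flank_c = "".join(AMINO_ALPHABET[i] for i in rng.integers(0, _A, size=8))
        return flank_n + cons[: lo - 1] + junk + cons[hi:] + flank_c

    for sf in sf_ids:
        # queries descend from the first half of the mapped models only:
        # the remaining siblings are detectable solely through the shared
        # superfamily fold, which is where false-negative rescue matters
        mapped_list = sorted(bench.mapping[sf])
        seed_models = mapped_list[: max(1, len(mapped_list) // 2)]
        for q in range(n_sequences):
            qid = f"{sf}_q{q:02d}"
            src = seed_models[q % len(seed_models)]
            cons = _mutate(bench.consensus[src], rng, mutation_rate)
            seq = _query_from(cons)
            bench.sequences.append((qid, sf, seq, False))
            for mid in model_ids:
                bench.truth[(qid, mid)] = mid in bench.mapping[sf]

    # decoys: remnant mimics of a foreign model -- random fold-critical
    # parts around a faithful copy of that model's linker consensus
    n_decoys = int(round(contamination * n_superfamilies * n_sequences))
    foreign_models = [m for m in model_ids]
    for d in range(n_decoys):
        sf = sf_ids[d % len(sf_ids)]
        qid = f"{sf}_d{d:02d}"
        foreign_choices = [m for m in foreign_models if sf_of_model[m] != sf] or model_ids
        target = foreign_choices[int(rng.integers(0, len(foreign_choices)))]
        linker = _mutate(bench.consensus[target][lo - 1 : hi], rng, decoy_remnant_noise)
        fc_left = "".join(AMINO_ALPHABET[i] for i in rng.integers(0, _A, size=lo - 1))
        fc_right = "".join(AMINO_ALPHABET[i] for i in rng.integers(0, _A, size=K - hi))
        flank_n = "".join(AMINO_ALPHABET[i] for i in rng.integers(0, _A, size=8))
        flank_c = "".join(AMINO_ALPHABET[i] for i in rng.integers(0, _A, size=8))
        seq = flank_n + fc_left + linker + fc_right + flank_c
        bench.sequences.append((qid, sf, seq, True))
        for mid in model_ids:
            bench.truth[(qid, mid)] = False
    return bench


# ---------------------------------------------------------------------------
# end-to-end evaluation on a benchmark


def evaluate_benchmark(
    bench: BenchmarkData,
    db_size: int | None = None,
    min_overlap: float = 0.9,
    baseline_cutoff: float = 0.1,
    use_packaged_tables_fallback: bool = True,
):
    """Run the full dissection pipeline over a synthetic benchmark.

    Per query and model, glocal (H2) and local (H3) alignments are produced
    by the package's own Viterbi, dissected, classified and paired; FPR
    tables are calibrated empirically from the benchmark's own negative hits
    (falling back to the packaged anchors when a negative population is
    missing); domain-wise scores are aggregated per superfamily, and ROC
    tables are built for the dissected coverage measures and the undissected
    baseline.

    Returns a dict with the classified hits, calibration tables, domain-score
    arrays with truth labels, and ROC tables.
    """
    from .calibration import (
        build_fpr_table,
        collect_negative_measures,
        packaged_anchor_table,
        roc_from_scores,
    )
    from .hit_pipeline import (
        ClassificationThresholds,
        classify_hit,
        domain_scores,
        error_adjusted_coverage,
        hmmer3_baseline_scores,
        pair_hits,
    )
    from .score_dissection import dissect_evalues, viterbi_align

    thresholds = ClassificationThresholds()
    all_hits = []  # (qid, sf, mid, variant, ClassifiedHit)
    triples = []  # for calibration: (sf, mid, DissectedScore)
    h3_raw = {}  # (qid, mid) -> SeqDomAlignment
    seq_index = {qid: i for i, (qid, _, _, _) in enumerate(bench.sequences)}

    for qid, sf, seq, _ in bench.sequences:
        for mid in bench.profiles_h2:
            mask = bench.masks[mid]
            a2 = viterbi_align(bench.profiles_h2[mid], seq, mode="glocal", query_id=qid)
            d2 = dissect_evalues(a2, bench.profiles_h2[mid], mask, db_size=db_size)
            a3 = viterbi_align(bench.profiles_h3[mid], seq, mode="local", query_id=qid)
            d3 = dissect_evalues(a3, bench.profiles_h3[mid], mask, db_size=db_size)
            h3_raw[(qid, mid)] = a3
            for d, a in ((d2, a2), (d3, a3)):
                triples.append((sf, mid, d))
                all_hits.append((qid, sf, mid, d.variant, classify_hit(d, a, thresholds)))

    # empirical calibration from the benchmark's own negatives
    negatives = collect_negative_measures(triples, bench.mapping)
    tables = {}
    for variant in (Dialect.H2, Dialect.H3):
        for kind in ("fc_evalue", "ratio"):
            vals = negatives.get((variant, kind), [])
            if len(vals) >= 10:
                tables[(variant, kind)] = build_fpr_table(vals, variant, kind)
            elif use_packaged_tables_fallback:
                tables[(variant, kind)] = packaged_anchor_table(variant, kind)
            else:
                raise ValueError(f"no negative measures for {variant} {kind}")

    # pair per query, compute coverage scores
    merged_with_seq = []
    for qid, _, _, _ in bench.sequences:
        h2 = [h for (q, _, _, v, h) in all_hits if q == qid and v is Dialect.H2]
        h3 = [h for (q, _, _, v, h) in all_hits if q == qid and v is Dialect.H3]
        for m in pair_hits(h2, h3, bench.model_lengths, min_overlap=min_overlap):
            error_adjusted_coverage(m, tables)
            merged_with_seq.append((seq_index[qid], m))

    # superfamily-wise domain scores with truth labels
    rows = {"ratio": [], "fc_evalue": []}
    sf_of = {qid: sf for qid, sf, _, _ in bench.sequences}
    for sf in bench.mapping:
        group = [
            (i, m) for i, m in merged_with_seq if sf_of[m.query_id] == sf
        ]
        scored = {
            (d.model_id, d.measure_kind): d.value for d in domain_scores(group)
        }
        for mid in bench.profiles_h2:
            label = mid in bench.mapping[sf]
            for kind in ("ratio", "fc_evalue"):
                rows[kind].append((scored.get((mid, kind), 0.0), label))

    roc = {}
    for kind in ("ratio", "fc_evalue"):
        scores, labels = zip(*rows[kind])
        roc[kind] = roc_from_scores(scores, labels, measure_kind=kind)

    # undissected HMMER3-style baseline
    baseline_rows = []
    for sf in bench.mapping:
        group = [
            (seq_index[qid], aln)
            for (qid, mid), aln in h3_raw.items()
            if sf_of[qid] == sf
        ]
        base = {
            d.model_id: d.value
            for d in hmmer3_baseline_scores(
                group, bench.model_lengths, evalue_cutoff=baseline_cutoff
            )
        }
        for mid in bench.profiles_h2:
            baseline_rows.append((base.get(mid, 0.0), mid in bench.mapping[sf]))
    b_scores, b_labels = zip(*baseline_rows)
    roc["baseline"] = roc_from_scores(b_scores, b_labels, measure_kind="baseline_coverage")

    return {
        "hits": all_hits,
        "tables": tables,
        "domain_rows": rows,
        "baseline_rows": baseline_rows,
        "roc": roc,
        "merged": merged_with_seq,
    }


def tpr_at_fpr(roc_table, max_fpr: float) -> float:
    """Highest TPR achieved at FPR <= max_fpr."""
    ok = roc_table.fpr <= max_fpr + 1e-12
    if not np.any(ok):
        return 0.0
    return float(np.max(roc_table.tpr[ok]))
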