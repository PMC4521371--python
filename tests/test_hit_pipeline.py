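"""Hit classification, pairing, error-adjusted coverage and total FPR."""

import itertools

import numpy as np
import pytest

from hmmdissect.calibration import CalibrationTable, roc_from_scores
from hmmdissect.hit_pipeline import (
    ClassificationThresholds,
    ClassifiedHit,
    MergedHit,
    PipelineError,
    attach_total_fpr,
    classify,
    classify_hit,
    domain_scores,
    error_adjusted_coverage,
    hmmer3_baseline_scores,
    overlap_ratio,
    pair_hits,
    report_tsv,
    total_fpr,
)
from hmmdissect.profile_models import Dialect, PathRecord, SeqDomAlignment
from hmmdissect.score_dissection import DissectedScore


def _dissected(orig, fc, rem, variant=Dialect.H2, ratio=-1.0):
    return DissectedScore(
        full_score=0.0, fc_sum=0.0, rem_sum=0.0,
        evalue_original=orig, evalue_fc=fc, evalue_rem=rem,
        log10_ratio=ratio, variant=variant,
    )


def _alignment(query="q", model="m", variant=Dialect.H2, seq_span=(1, 100),
               model_span=(1, 50)):
    # spans are what the pipeline consumes; a minimal path suffices here
    path = [PathRecord("M", model_span[0], seq_span[0], "A")]
    return SeqDomAlignment(
        query_id=query, model_id=model, variant=variant,
        seq_span=tuple(seq_span), model_span=tuple(model_span), path=path,
    )


def _hit(query="q", model="m", variant=Dialect.H2, seq_span=(1, 100),
         model_span=(1, 50), label="TP", **evalues):
    d = _dissected(
        evalues.get("orig", 1e-5), evalues.get("fc", 1e-6),
        evalues.get("rem", 1e-2), variant=variant,
        ratio=evalues.get("ratio", -2.0),
    )
    a = _alignment(query, model, variant, seq_span, model_span)
    return ClassifiedHit(dissected=d, alignment=a, label=label,
                         retained=label in ("TP", "FN"))


class TestClassify:
    @pytest.mark.parametrize(
        "orig,fc,rem,expected",
        [
            (0.05, 1e-4, 1e-2, "TP"),
            (0.5, 1e-4, 1e-2, "FN"),  # the rescued class
            (0.05, 1e-2, 1e-4, "FP"),
            (0.5, 1e-2, 1e-2, "TN"),
        ],
    )
    def test_h2_worked_rows(self, orig, fc, rem, expected):
        assert classify(_dissected(orig, fc, rem)) == expected

    @pytest.mark.parametrize("variant", [Dialect.H2, Dialect.H3])
    def test_exhaustive_truth_table(self, variant):
        """All 8 combinations of straddling E-value triples land in the
        documented class for both variants."""
        t = ClassificationThresholds()
        oc = t.original_e_cutoff[variant]
        fcc = t.fc_e_cutoff[variant]
        for o_low, f_low, r_low in itertools.product([True, False], repeat=3):
            orig = oc * (0.5 if o_low else 2.0)
            fc = fcc * (0.5 if f_low else 2.0)
            rem = fcc * (0.5 if r_low else 2.0)
            got = classify(_dissected(orig, fc, rem, variant=variant), t)
            if o_low and f_low:
                assert got == "TP"
            elif not o_low and f_low:
                assert got == "FN"
            elif o_low and not f_low:
                assert got == ("FP" if r_low else "TN")
            else:
                assert got == "TN"

    def test_cutoff_boundaries_are_inclusive(self):
        t = ClassificationThresholds()
        d = _dissected(0.1, 10.0**-3.45, 1.0)
        assert classify(d, t) == "TP"

    def test_retained_only_for_tp_and_fn(self):
        for label, expect in (("TP", True), ("FN", True), ("FP", False), ("TN", False)):
            orig = 0.05 if label in ("TP", "FP") else 0.5
            fc = 1e-4 if label in ("TP", "FN") else 1e-2
            rem = 1e-4 if label == "FP" else 1.0
            hit = classify_hit(_dissected(orig, fc, rem), _alignment())
            assert hit.label == label and hit.retained is expect

    def test_missing_remnant_evalue_on_fp_branch_raises(self):
        d = _dissected(0.05, 1e-2, float("nan"))
        with pytest.raises(PipelineError, match="remnant"):
            classify(d)


class TestOverlapRatio:
    def test_identical_spans(self):
        assert overlap_ratio((10, 100), (10, 100)) == pytest.approx(1.0)

    def test_partial_overlap_direct_arithmetic(self):
        # overlap length 9 over span lengths 99 and 99
        assert overlap_ratio((1, 100), (91, 190)) == pytest.approx(9 / 99)

    def test_disjoint_clamped_to_zero(self):
        assert overlap_ratio((1, 50), (60, 100)) == 0.0

    def test_symmetry_and_nesting(self):
        assert overlap_ratio((91, 190), (1, 100)) == pytest.approx(9 / 99)
        # nested segment: intersection is the inner span
        assert overlap_ratio((1, 100), (40, 60)) == pytest.approx(
            min(20 / 99, 20 / 20)
        )

    def test_zero_length_span_rejected(self):
        with pytest.raises(PipelineError):
            overlap_ratio((5, 5), (1, 10))


class TestPairHits:
    LENGTHS = {"m": 50, "n": 50}

    def test_high_overlap_pairs(self):
        h2 = [_hit(variant=Dialect.H2, seq_span=(1, 100))]
        h3 = [_hit(variant=Dialect.H3, seq_span=(3, 98))]
        merged = pair_hits(h2, h3, self.LENGTHS)
        assert len(merged) == 1
        assert merged[0].h2 is not None and merged[0].h3 is not None
        assert merged[0].coverage_h2 == 1.0
        assert merged[0].coverage_h3 == pytest.approx(1.0)

    def test_low_overlap_yields_two_orphans(self):
        h2 = [_hit(variant=Dialect.H2, seq_span=(1, 100))]
        h3 = [_hit(variant=Dialect.H3, seq_span=(60, 160))]
        merged = pair_hits(h2, h3, self.LENGTHS)
        assert len(merged) == 2
        assert {m.h3 is None for m in merged} == {True, False}

    def test_orphan_h2_without_counterpart(self):
        merged = pair_hits([_hit()], [], self.LENGTHS)
        assert len(merged) == 1
        assert merged[0].h3 is None and merged[0].coverage_h2 == 1.0

    def test_never_pairs_across_models_and_never_reuses(self):
        h2 = [
            _hit(model="m", seq_span=(1, 100)),
            _hit(model="n", seq_span=(1, 100)),
        ]
        h3 = [_hit(model="m", variant=Dialect.H3, seq_span=(1, 100))]
        merged = pair_hits(h2, h3, self.LENGTHS)
        paired = [m for m in merged if m.h2 and m.h3]
        assert len(paired) == 1 and paired[0].model_id == "m"
        assert len(merged) == 2  # the pair plus the model-n orphan
        # the H3 hit is used exactly once
        assert sum(1 for m in merged if m.h3 is not None) == 1

    def test_unretained_hits_never_enter(self):
        h2 = [_hit(label="FP")]
        assert pair_hits(h2, [], self.LENGTHS) == []


def _flat_tables(fpr_h2=0.1, fpr_h3=0.2):
    """Lookup tables returning a constant FPR for any in-range measure."""
    tables = {}
    for variant, f in ((Dialect.H2, fpr_h2), (Dialect.H3, fpr_h3)):
        for kind in ("ratio", "fc_evalue"):
            tables[(variant, kind)] = CalibrationTable(
                variant=variant, measure_kind=kind,
                bin_edges=np.array([-205.0, 2.9, 3.0]),
                frequencies=np.array([f, 1.0 - f]),
                n_samples=1,
            )
    return tables


class TestErrorAdjustedCoverage:
    def test_zero_fpr_full_coverage_is_one(self):
        m = pair_hits(
            [_hit(variant=Dialect.H2, seq_span=(1, 100))],
            [_hit(variant=Dialect.H3, seq_span=(1, 100))],
            {"m": 50},
        )[0]
        # measures sit below the single-bin tables' range -> FPR 0
        tables = _flat_tables()
        m.h2.dissected.log10_ratio = -210.0
        m.h3.dissected.log10_ratio = -210.0
        m.h2.dissected.evalue_fc = 1e-250
        m.h3.dissected.evalue_fc = 1e-250
        error_adjusted_coverage(m, tables)
        assert m.coverage_ratio == pytest.approx(1.0)
        assert m.coverage_fce == pytest.approx(1.0)

    def test_paired_formula_direct_arithmetic(self):
        """1/2 [(1-0.1)*1 + (1-0.2)*0.5] = 0.65."""
        h2 = _hit(variant=Dialect.H2, seq_span=(1, 100), model_span=(1, 50))
        h3 = _hit(variant=Dialect.H3, seq_span=(1, 100), model_span=(1, 25))
        m = pair_hits([h2], [h3], {"m": 50})[0]
        assert m.coverage_h3 == pytest.approx(0.5)
        error_adjusted_coverage(m, _flat_tables(0.1, 0.2))
        assert m.coverage_ratio == pytest.approx(0.5 * (0.9 * 1.0 + 0.8 * 0.5))
        assert m.coverage_ratio == pytest.approx(0.65)

    def test_orphan_drops_half_factor(self):
        """An H3-only hit with FPR 0.51 and coverage 0.42 scores
        0.49 * 0.42 ~ 0.206 (no 1/2 factor)."""
        h3 = _hit(variant=Dialect.H3, seq_span=(1, 75), model_span=(1, 75))
        m = pair_hits([], [h3], {"m": 177})[0]
        assert m.coverage_h3 == pytest.approx(75 / 177, abs=1e-3)
        error_adjusted_coverage(m, _flat_tables(fpr_h3=0.51))
        assert m.coverage_ratio == pytest.approx(0.49 * 75 / 177, abs=1e-3)
        assert m.coverage_ratio == pytest.approx(0.205, abs=5e-3)

    def test_halve_orphans_switch(self):
        h3 = _hit(variant=Dialect.H3, seq_span=(1, 100), model_span=(1, 50))
        m = pair_hits([], [h3], {"m": 50})[0]
        error_adjusted_coverage(m, _flat_tables(fpr_h3=0.2), halve_orphans=True)
        assert m.coverage_ratio == pytest.approx(0.5 * 0.8 * 1.0)

    def test_undefined_ratio_keeps_fce_route(self):
        h3 = _hit(variant=Dialect.H3, seq_span=(1, 100), model_span=(1, 50))
        h3.dissected.log10_ratio = None  # remnant E underflowed
        m = pair_hits([], [h3], {"m": 50})[0]
        error_adjusted_coverage(m, _flat_tables(fpr_h3=0.2))
        assert m.coverage_ratio is None
        assert m.coverage_fce == pytest.approx(0.8)

    @pytest.mark.parametrize("seed", range(5))
    def test_monotonicity_in_fpr_and_coverage(self, seed):
        rng = np.random.default_rng(seed)
        f2, f3 = rng.uniform(0, 1, size=2)
        c3 = rng.uniform(0, 1)
        base = 0.5 * ((1 - f2) * 1.0 + (1 - f3) * c3)
        up_f = 0.5 * ((1 - min(1, f2 + 0.1)) * 1.0 + (1 - f3) * c3)
        up_c = 0.5 * ((1 - f2) * 1.0 + (1 - f3) * min(1, c3 + 0.1))
        assert up_f <= base + 1e-12
        assert up_c >= base - 1e-12


class TestTotalFpr:
    def test_worked_sums(self):
        assert total_fpr(0.53, 0.54) == pytest.approx(1.07)
        assert total_fpr(0.28, 0.01) == pytest.approx(0.29)
        assert total_fpr(0.0, 0.0) == 0.0

    def test_range_check(self):
        with pytest.raises(PipelineError):
            total_fpr(1.2, 0.0)

    def test_sorting_is_stable_ascending(self):
        roc = roc_from_scores(
            [0.9, 0.8, 0.3, 0.2], [True, True, False, False]
        )
        hits = []
        for cov in (0.9, 0.3, 0.9, 0.6):
            m = MergedHit(query_id="q", model_id="m")
            m.coverage_ratio = cov
            m.coverage_fce = cov
            hits.append(m)
        out = attach_total_fpr(hits, roc, roc)
        values = [m.total_fpr for m in out]
        assert values == sorted(values)
        # stable: the two cov=0.9 hits keep their input order
        nines = [m for m in out if m.coverage_ratio == 0.9]
        assert nines[0] is hits[0] and nines[1] is hits[2]


class TestDomainScores:
    def _merged(self, seq_idx, model, cov):
        m = MergedHit(query_id=f"s{seq_idx}", model_id=model)
        m.coverage_ratio = cov
        m.coverage_fce = cov
        return (seq_idx, m)

    def test_mean_over_sequences(self):
        scores = domain_scores(
            [self._merged(0, "m", 1.0), self._merged(1, "m", 0.5),
             self._merged(2, "m", 0.75)]
        )
        ratio = [d for d in scores if d.measure_kind == "ratio"][0]
        assert ratio.value == pytest.approx(0.75)
        assert ratio.n_contributing_sequences == 3

    def test_single_sequence_score_is_its_coverage(self):
        scores = domain_scores([self._merged(0, "m", 0.42)])
        assert all(d.value == pytest.approx(0.42) for d in scores)

    def test_multiple_hits_contribute_their_maximum(self):
        scores = domain_scores(
            [self._merged(0, "m", 0.4), self._merged(0, "m", 0.9)]
        )
        ratio = [d for d in scores if d.measure_kind == "ratio"][0]
        assert ratio.value == pytest.approx(0.9)
        assert ratio.n_contributing_sequences == 1

    def test_empty_input_gives_empty_list(self):
        assert domain_scores([]) == []


class TestBaseline:
    def _aln(self, ev, model_span=(1, 50), model="m"):
        a = _alignment(model=model, variant=Dialect.H3, model_span=model_span)
        a.reported_evalue = ev
        return a

    def test_kept_below_cutoff_scored_by_coverage(self):
        out = hmmer3_baseline_scores([(0, self._aln(0.05, (1, 25)))], {"m": 50})
        assert out[0].value == pytest.approx(0.5)

    def test_dropped_above_cutoff(self):
        assert hmmer3_baseline_scores([(0, self._aln(5.0))], {"m": 50},
                                      evalue_cutoff=1.0) == []

    def test_mixed_fixture_matches_filter_then_count_oracle(self):
        rng = np.random.default_rng(8)
        hits = []
        for i in range(30):
            ev = float(10 ** rng.uniform(-6, 2))
            span = (1, int(rng.integers(10, 51)))
            hits.append((i, self._aln(ev, span)))
        for cutoff in (0.1, 1.0, 10.0):
            out = hmmer3_baseline_scores(hits, {"m": 50}, evalue_cutoff=cutoff)
            kept = [(i, a) for i, a in hits if a.reported_evalue <= cutoff]
            if not kept:
                assert out == []
                continue
            expected = np.mean([(a.model_span[1] - a.model_span[0] + 1) / 50
                                for _, a in kept])
            assert out[0].value == pytest.approx(expected)
            assert out[0].n_contributing_sequences == len(kept)


def test_report_tsv_has_documented_columns_and_ascending_total_fpr():
    roc = roc_from_scores([0.9, 0.2], [True, False])
    hits = []
    for cov in (0.8, 0.3):
        m = MergedHit(query_id="q", model_id="m")
        m.h2 = _hit()
        m.coverage_h2 = 1.0
        m.coverage_ratio = cov
        m.coverage_fce = cov
        hits.append(m)
    out = attach_total_fpr(hits, roc, roc)
    text = report_tsv(out)
    header = text.splitlines()[0].split("\t")
    assert header == [
        "model_id", "query_id", "seq_range", "coverage_h2", "coverage_h3",
        "evalue_h2", "evalue_h3", "coverage_ratio", "roc_fpr_ratio",
        "coverage_fce", "roc_fpr_fce", "total_fpr",
    ]
    rows = [ln.split("\t") for ln in text.splitlines()[1:]]
    totals = [float(r[-1]) for r in rows]
    assert totals == sorted(totals)
    assert "." in text  # undefined coverage_h3 serialized as '.'
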