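"""Fold-critical/remnant annotation: DSSP masks, predictors, weighting."""

import itertools
import math
import warnings

import numpy as np
import pytest

from hmmdissect.fold_annotation import (
    ColumnMask,
    Label,
    PredictorScoreVector,
    Provenance,
    WeightConfig,
    combine_weighted,
    globplot_labels,
    mask_from_dssp,
    mask_from_scores,
    mask_stats,
    merge_short_remnant_runs,
    normalize_scores,
    predictor_column_scores,
    predictor_roc,
    quality_score,
    read_mask_tsv,
    seg_labels,
    write_mask_tsv,
)

F, R = Label.FOLD_CRITICAL, Label.REMNANT


class TestDsspMask:
    @pytest.mark.parametrize(
        "dssp,expected",
        [
            ("HHHHH", [F] * 5),
            # remnant run of 4 < 10 merges back into the fold
            ("HHH----HHH", [F] * 10),
            # remnant run of 12 >= 10 survives
            ("H" * 5 + "-" * 12 + "H" * 5, [F] * 5 + [R] * 12 + [F] * 5),
            ("EITS?", [F, F, F, F, F]),  # '?' run of 1 merged
        ],
    )
    def test_label_rules_with_run_merging(self, dssp, expected):
        mask = mask_from_dssp(dssp)
        assert mask.labels == expected
        assert mask.provenance is Provenance.DSSP_DERIVED

    def test_unknown_code_warns_and_goes_remnant(self):
        import hmmdissect.fold_annotation as fa

        fa._warned_codes.clear()
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            mask = mask_from_dssp("H" * 10 + "G" * 12 + "H" * 10)
        assert any("'G'" in str(w.message) for w in rec)
        assert mask.labels[10:22] == [R] * 12

    def test_unknown_code_error_policy(self):
        with pytest.raises(Exception, match="unknown DSSP code"):
            mask_from_dssp("HHGHH", unknown_policy="error")

    def test_merge_is_idempotent(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            labels = [F if x else R for x in rng.integers(0, 2, size=60)]
            once = merge_short_remnant_runs(labels)
            assert merge_short_remnant_runs(once) == once
            assert all(
                len(run) >= 10
                for lab, grp in itertools.groupby(once)
                if lab is R
                for run in [list(grp)]
            )


class TestPredictorColumnScores:
    def test_structured_fraction_per_column(self):
        msa = ["AC-A", "AC-A", "A-CA", "ACCA"]
        labels = [
            [1, 1, 1],  # 3 residues each (gaps excluded)
            [1, 1, 0],
            [1, 0, 1],
            [0, 1, 1, 1],
        ]
        v = predictor_column_scores(msa, labels)
        # col 1: 4 residues, 3 structured
        assert v.scores[0] == pytest.approx(0.75)
        # col 2: residues from seqs 0,1,3 all structured at their cursors
        assert v.scores[1] == pytest.approx(1.0)
        assert v.n_sequences == 4

    def test_all_gap_column_scores_zero(self):
        v = predictor_column_scores(["A-A", "A-A"], [[1, 1], [1, 1]])
        assert v.scores[1] == 0.0

    def test_label_length_mismatch_names_sequence(self):
        with pytest.raises(Exception, match="sequence 1"):
            predictor_column_scores(["AA", "AA"], [[1, 1], [1]])


class TestSeg:
    def test_homopolymer_is_all_low_complexity(self):
        assert seg_labels("A" * 50).sum() == 0  # structured = 1, all zero

    def test_maximal_diversity_is_all_structured(self):
        seq = ("ACDEFGHIKLMNPQRSTVWY" * 3)[:50]
        labels = seg_labels(seq)
        assert labels.sum() == 50
        # independent check: the full-diversity window entropy exceeds hicut
        window = seq[:25]
        counts = {c: window.count(c) for c in set(window)}
        h = -sum(v / 25 * math.log2(v / 25) for v in counts.values())
        assert h > 3.4

    def test_short_sequence_uses_whole_sequence_window(self):
        assert seg_labels("AAAAA").sum() == 0  # one 5-wide window, zero entropy
        short_diverse = seg_labels("ACDEFGHIKL")
        assert short_diverse.sum() == 10

    def test_low_complexity_island_detected(self):
        seq = "ACDEFGHIKLMNPQRSTVWY" + "S" * 30 + "YWVTSRQPNMLKIHGFEDCA"
        labels = seg_labels(seq)
        assert labels[30:40].sum() == 0  # core of the island
        # far flanks stay structured; the two-threshold extension is allowed
        # to absorb residues whose windows overlap the island
        assert labels[:4].sum() == 4
        assert labels[-4:].sum() == 4


class TestGlobPlot:
    def test_globular_sequence_all_structured(self):
        seq = "W" * 60  # maximal globularity propensity
        assert globplot_labels(seq).sum() == 60

    def test_disorder_block_inside_globular_context(self):
        seq = "W" * 50 + "P" * 60 + "W" * 50
        labels = globplot_labels(seq)
        assert labels[70:90].sum() == 0  # disordered core
        assert labels[10:40].sum() == 30
        assert labels[-40:-10].sum() == 30

    def test_short_sequence_falls_back_to_structured(self):
        assert globplot_labels("P" * 12).sum() == 12


class TestQualityScore:
    def test_identical_ungapped_column_scores_one(self):
        v = quality_score(["AW", "AW", "AW"])
        assert v.scores[0] == pytest.approx(1.0)
        assert v.scores[1] == pytest.approx(1.0)

    def test_minimal_similarity_column_scores_zero(self):
        # BLOSUM62 minimum pair score; e.g. W vs D scores -4
        from Bio.Align import substitution_matrices

        mat = substitution_matrices.load("BLOSUM62")
        assert mat["W"]["D"] == min(
            mat[a][b] for a in "ACDEFGHIKLMNPQRSTVWY" for b in "ACDEFGHIKLMNPQRSTVWY"
        )
        v = quality_score(["W", "D"])
        assert v.scores[0] == pytest.approx(0.0)

    def test_mixed_column_matches_sum_of_pairs_oracle(self):
        from Bio.Align import substitution_matrices

        msa = ["AKL-", "ARLV", "GKLV", "AKIV"]
        mat = substitution_matrices.load("BLOSUM62")
        bmin = min(mat[a][b] for a in "ACDEFGHIKLMNPQRSTVWY" for b in "ACDEFGHIKLMNPQRSTVWY")

        def oracle(column):
            residues = [c for c in column if c != "-"]
            sims = [
                (mat[a][b] - bmin) / (min(mat[a][a], mat[b][b]) - bmin)
                for a, b in itertools.combinations(residues, 2)
            ]
            return float(np.mean(sims)) * len(residues) / len(column)

        v = quality_score(msa)
        for k in range(4):
            col = [s[k] for s in msa]
            assert v.scores[k] == pytest.approx(oracle(col))

    def test_single_sequence_rejected(self):
        with pytest.raises(Exception, match="single-sequence"):
            quality_score(["ACDEF"])


class TestWeighting:
    def test_all_predictors_at_one_sum_to_191(self):
        vecs = [
            PredictorScoreVector(name, np.ones(3), n_sequences=8)
            for name in ("qualityscore", "psipred", "seg", "globplot")
        ]
        combined = combine_weighted(vecs)
        assert combined[0] == pytest.approx(0.61 + 0.50 + 0.41 + 0.39)  # 1.91

    def test_all_zero_gives_zero(self):
        vecs = [
            PredictorScoreVector(name, np.zeros(3), n_sequences=8)
            for name in ("qualityscore", "psipred", "seg", "globplot")
        ]
        assert combine_weighted(vecs).sum() == 0.0

    def test_sequence_floor_drops_other_predictors(self):
        vecs = [
            PredictorScoreVector("qualityscore", np.full(2, 0.8), n_sequences=3),
            PredictorScoreVector("psipred", np.ones(2), n_sequences=3),
        ]
        combined = combine_weighted(vecs)
        assert combined[0] == pytest.approx(0.8 * 0.61)  # 0.488

    def test_linearity_in_each_predictor(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(size=5)
        extra = rng.uniform(size=5)
        vq = PredictorScoreVector("qualityscore", base, n_sequences=9)
        vs1 = PredictorScoreVector("seg", extra, n_sequences=9)
        vs0 = PredictorScoreVector("seg", np.zeros(5), n_sequences=9)
        diff = combine_weighted([vq, vs1]) - combine_weighted([vq, vs0])
        np.testing.assert_allclose(diff, 0.41 * extra)

    def test_normalize_direct_arithmetic(self):
        np.testing.assert_allclose(
            normalize_scores(np.array([0.0, 0.955, 1.91])), [0.0, 0.5, 1.0]
        )

    def test_normalize_constant_vector_degenerates_to_half(self):
        with pytest.warns(UserWarning, match="degenerate"):
            out = normalize_scores(np.full(4, 0.7))
        np.testing.assert_allclose(out, 0.5)

    def test_normalize_affine_invariance_and_range(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        np.testing.assert_allclose(
            normalize_scores(x), normalize_scores(3.0 * x + 7.0), atol=1e-12
        )
        out = normalize_scores(x)
        assert out.min() == 0.0 and out.max() == 1.0


class TestMaskFromScores:
    def test_high_scores_all_fold_critical(self):
        mask = mask_from_scores(np.full(6, 0.9))
        assert mask.labels == [F] * 6

    def test_threshold_plus_run_rule(self):
        scores = np.array([0.9] * 5 + [0.1] * 12 + [0.9] * 5)
        mask = mask_from_scores(scores)
        assert mask.labels == [F] * 5 + [R] * 12 + [F] * 5
        short = np.array([0.9] * 5 + [0.1] * 4 + [0.9] * 5)
        assert mask_from_scores(short).labels == [F] * 14

    def test_tie_at_threshold_is_fold_critical(self):
        mask = mask_from_scores(np.full(3, 0.5))
        assert mask.labels == [F] * 3


class TestMaskStats:
    def test_ratio_and_segment_lengths(self):
        mask = ColumnMask("m", 20, [F] * 5 + [R] * 15, Provenance.DSSP_DERIVED)
        stats = mask_stats([mask])
        assert stats.per_model["remnant_ratio"].iloc[0] == pytest.approx(0.75)
        assert list(stats.segment_lengths) == [15]
        assert stats.n_ratio_above_half == 1

    def test_all_fold_critical(self):
        stats = mask_stats([ColumnMask("m", 8, [F] * 8, Provenance.DSSP_DERIVED)])
        assert stats.per_model["remnant_ratio"].iloc[0] == 0.0
        assert len(stats.segment_lengths) == 0

    def test_all_remnant_is_red_flag(self):
        stats = mask_stats([ColumnMask("m", 13, [R] * 13, Provenance.DSSP_DERIVED)])
        assert stats.per_model["remnant_ratio"].iloc[0] == 1.0
        assert stats.n_ratio_one == 1


class TestPredictorRoc:
    def _reference(self):
        labels = [F] * 30 + [R] * 30
        return {"m": ColumnMask("m", 60, labels, Provenance.DSSP_DERIVED)}

    def test_perfect_predictions(self):
        scores = {"m": np.array([1.0] * 30 + [0.0] * 30)}
        roc = predictor_roc(scores, self._reference())
        assert (roc["tpr"] == 1.0).all()
        assert (roc["fpr"] == 0.0).all()

    def test_inverted_predictions_never_beat_chance(self):
        scores = {"m": np.array([0.0] * 30 + [1.0] * 30)}
        roc = predictor_roc(scores, self._reference())
        assert (roc["tpr_minus_fpr"] <= 0).all()

    def test_random_predictions_tpr_matches_fpr(self):
        rng = np.random.default_rng(7)
        labels = [F if x else R for x in rng.integers(0, 2, size=4000)]
        ref = {"m": ColumnMask("m", 4000, labels, Provenance.DSSP_DERIVED)}
        scores = {"m": rng.uniform(size=4000)}
        roc = predictor_roc(scores, ref)
        # binomial error at n ~ 2000 per class
        assert (np.abs(roc["tpr"] - roc["fpr"]) < 0.06).all()

    def test_disjoint_model_sets_rejected(self):
        with pytest.raises(Exception, match="disjoint"):
            predictor_roc({"a": np.zeros(3)}, self._reference())


def test_weighted_scheme_beats_single_predictors_on_independent_errors():
    """With independent predictor noise, the weighted combination's best
    TPR-FPR margin is at least that of any single predictor (small slack)."""
    rng = np.random.default_rng(42)
    K = 4000
    truth = rng.integers(0, 2, size=K).astype(bool)
    ref = {"m": ColumnMask("m", K, [F if t else R for t in truth], Provenance.DSSP_DERIVED)}
    weights = WeightConfig().weights
    noise = {"qualityscore": 0.30, "psipred": 0.35, "seg": 0.40, "globplot": 0.42}
    vectors = []
    singles_best = {}
    for name, sd in noise.items():
        s = np.clip(truth + rng.normal(0, sd, size=K), 0, 1)
        vectors.append(PredictorScoreVector(name, s, n_sequences=9))
        roc = predictor_roc({"m": s}, ref)
        singles_best[name] = roc["tpr_minus_fpr"].max()
    combined = normalize_scores(combine_weighted(vectors))
    roc_w = predictor_roc({"m": combined}, ref)
    assert roc_w["tpr_minus_fpr"].max() >= max(singles_best.values()) - 0.02


def test_mask_tsv_round_trip():
    masks = [
        ColumnMask("m1", 12, [F] * 6 + [R] * 6, Provenance.DSSP_DERIVED),
        ColumnMask("m2", 3, [F, R, F], Provenance.PREDICTOR_DERIVED),
    ]
    back = read_mask_tsv(write_mask_tsv(masks))
    assert [m.label_string for m in back] == [m.label_string for m in masks]
    assert [m.provenance for m in back] == [m.provenance for m in masks]
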