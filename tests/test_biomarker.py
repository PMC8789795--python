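import itertools
import logging
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from tcsp.biomarker import (
    BiomarkerResult,
    FeatureTable,
    ModelSpec,
    assemble_features,
    bootstrap_oob_evaluate,
    default_grid,
    extract_geneset_features,
    mann_whitney_one_sided,
    roc_auc,
    select_best_model,
    standardize,
    stratify_and_logrank,
)
from tcsp.core_io import SUBTYPES, ExpressionMatrix
from tcsp.deconvolve import SubtypeEstimate
from tcsp.errors import InputFormatError, ParameterError


def gaussian_features(n_per_class=15, shift=0.0, n_features=4, seed=0):
    rng = np.random.default_rng(seed)
    X0 = rng.normal(0, 1, size=(n_per_class, n_features))
    X1 = rng.normal(shift, 1, size=(n_per_class, n_features))
    X = pd.DataFrame(
        np.vstack([X0, X1]),
        index=[f"s{i}" for i in range(2 * n_per_class)],
        columns=[f"f{j}" for j in range(n_features)],
    )
    y = pd.Series([0] * n_per_class + [1] * n_per_class, index=X.index)
    return FeatureTable(X=X, y=y)


def estimate_of(sample_id, raw):
    return SubtypeEstimate(sample_id=sample_id, raw=np.array(raw, float), genes_used=46)


class TestAssembleFeatures:
    def _estimates(self):
        return [
            estimate_of("s1", [10, 5, 4, 8, 3]),
            estimate_of("s2", [1, 2, 3, 4, 5]),
        ]

    def test_raw_mode_five_columns(self):
        ft = assemble_features(self._estimates(), {"s1": 1, "s2": 0}, mode="raw")
        assert list(ft.X.columns) == list(SUBTYPES)

    def test_both_mode_ten_columns(self):
        ft = assemble_features(self._estimates(), {"s1": 1, "s2": 0}, mode="both")
        assert ft.X.shape[1] == 10
        assert ft.X.loc["s1", "EX_norm"] == pytest.approx(4 / 30)

    def test_undefined_normalization_names_sample(self):
        ests = [estimate_of("s1", [1, 1, 1, 1, 1]), estimate_of("bad", [0, 0, 0, 0, 0])]
        with pytest.raises(InputFormatError, match="bad"):
            assemble_features(ests, {"s1": 1, "bad": 0}, mode="normalized")

    def test_missing_estimate_rejected(self):
        with pytest.raises(InputFormatError, match="s9"):
            assemble_features(self._estimates(), {"s1": 1, "s9": 0}, mode="raw")

    def test_standardized_columns(self):
        ft = assemble_features(self._estimates(), {"s1": 1, "s2": 0}, mode="raw")
        Z = standardize(ft.X)
        np.testing.assert_allclose(Z.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(Z.std(axis=0, ddof=0), 1, atol=1e-12)


class TestGenesetFeatures:
    def _expr(self):
        frame = pd.DataFrame(
            {"s1": [10.0, 20.0, 30.0], "s2": [1.0, 2.0, 3.0]},
            index=["GA", "GB", "GC"],
        )
        return ExpressionMatrix(frame, unit="cpm")

    def test_all_present(self):
        ft = extract_geneset_features(self._expr(), ["GA", "GB", "GC"], {"s1": 1, "s2": 0})
        assert ft.X.shape == (2, 3)
        assert ft.X.loc["s1", "GA"] == pytest.approx(math.log2(11))

    def test_absent_gene_logged(self, caplog):
        with caplog.at_level(logging.WARNING):
            ft = extract_geneset_features(
                self._expr(), ["GA", "GB", "MISSING"], {"s1": 1, "s2": 0}
            )
        assert ft.X.shape[1] == 2
        assert any("MISSING" in r.message for r in caplog.records)

    def test_zero_overlap_error(self):
        with pytest.raises(InputFormatError):
            extract_geneset_features(self._expr(), ["X", "Y"], {"s1": 1, "s2": 0})

    def test_doubling_shifts_log_features_only(self):
        genes = ["GA", "GB", "GC"]
        labels = {"s1": 1, "s2": 0}
        frame = pd.DataFrame(
            {"s1": [800.0, 1200.0, 400.0], "s2": [500.0, 900.0, 700.0]},
            index=genes,
        )
        expr = ExpressionMatrix(frame, unit="cpm")
        a = extract_geneset_features(expr, genes, labels)
        b = extract_geneset_features(
            ExpressionMatrix(frame * 2, unit="cpm"), genes, labels
        )
        # exact algebra: feature = log2(cpm + 1)
        np.testing.assert_allclose(
            b.X.to_numpy(), np.log2(2 * frame.T.to_numpy() + 1), atol=1e-12
        )
        # for cpm >> 1 the shift is ~ +1 uniformly, so standardization cancels it
        shift = (b.X - a.X).to_numpy()
        np.testing.assert_allclose(shift, 1.0, atol=0.005)
        np.testing.assert_allclose(
            standardize(a.X).to_numpy(), standardize(b.X).to_numpy(), atol=0.02
        )
        # uniform shifts leave standardized features exactly unchanged
        np.testing.assert_allclose(
            standardize(a.X).to_numpy(), standardize(a.X + 1.0).to_numpy(), atol=1e-12
        )


class TestRocAuc:
    def test_perfect_ranking(self):
        _, auc = roc_auc([0.2, 0.8], [0, 1])
        assert auc == 1.0

    def test_all_ties_half(self):
        _, auc = roc_auc([0.5, 0.5, 0.5, 0.5], [0, 1, 0, 1])
        assert auc == 0.5

    def test_one_class_error(self):
        with pytest.raises(InputFormatError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_roc_points_monotone(self, rng):
        scores = rng.uniform(0, 1, 30)
        labels = rng.integers(0, 2, 30)
        if labels.sum() in (0, 30):
            labels[0] = 1 - labels[0]
        roc, _ = roc_auc(scores, labels)
        assert (roc["fpr"].diff().dropna() >= 0).all()
        assert (roc["tpr"].diff().dropna() >= 0).all()
        assert roc.iloc[-1]["fpr"] == 1.0 and roc.iloc[-1]["tpr"] == 1.0

    def test_pair_counting_oracle_random_cases(self, rng):
        for _ in range(200):
            n = rng.integers(4, 9)
            scores = rng.choice([0.1, 0.3, 0.5, 0.7], size=n)
            labels = rng.integers(0, 2, n)
            if len(np.unique(labels)) < 2:
                continue
            _, auc = roc_auc(scores, labels)
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            pairs = sum(
                1.0 if p > q else 0.5 if p == q else 0.0
                for p in pos
                for q in neg
            )
            assert auc == pytest.approx(pairs / (len(pos) * len(neg)), abs=1e-12)


class TestBootstrapOob:
    def test_constant_classifier_auc_half(self):
        ft = gaussian_features(shift=3.0, seed=1)
        res = bootstrap_oob_evaluate(ft, ModelSpec(classifier="constant"), n_boot=30, seed=2)
        assert (res.scores.dropna() == 0.5).all()
        assert res.auc == 0.5

    def test_separable_classes_high_auc(self):
        ft = gaussian_features(n_per_class=15, shift=10.0, seed=3)
        res = bootstrap_oob_evaluate(ft, ModelSpec(classifier="knn"), n_boot=200, seed=4)
        assert res.auc >= 0.99

    def test_oob_fraction_matches_theory(self):
        ft = gaussian_features(n_per_class=20, shift=1.0, seed=5)
        n = ft.n_samples
        res = bootstrap_oob_evaluate(ft, ModelSpec(classifier="knn"), n_boot=200, seed=6)
        expected = (1 - 1 / n) ** n
        se = res.oob_fractions.std(ddof=1) / np.sqrt(len(res.oob_fractions))
        assert abs(res.oob_fractions.mean() - expected) <= 3 * se

    def test_seeded_determinism(self):
        ft = gaussian_features(shift=2.0, seed=7)
        a = bootstrap_oob_evaluate(ft, ModelSpec(classifier="rf"), n_boot=25, seed=8)
        b = bootstrap_oob_evaluate(ft, ModelSpec(classifier="rf"), n_boot=25, seed=8)
        pd.testing.assert_series_equal(a.scores, b.scores)
        assert a.auc == b.auc

    def test_scores_within_unit_interval(self):
        ft = gaussian_features(shift=2.0, seed=9)
        for clf in ("adaboost", "knn", "rf", "svm"):
            res = bootstrap_oob_evaluate(ft, ModelSpec(classifier=clf), n_boot=20, seed=10)
            s = res.scores.dropna()
            assert ((s >= 0) & (s <= 1)).all()

    def test_single_class_bags_redrawn(self):
        # tiny, unbalanced: single-class bags are common and must be redrawn
        X = pd.DataFrame({"f": [0.0, 0.1, 0.2, 5.0, 5.1]}, index=list("abcde"))
        y = pd.Series([0, 0, 0, 1, 1], index=X.index)
        res = bootstrap_oob_evaluate(
            FeatureTable(X=X, y=y), ModelSpec(classifier="knn",
                                              hyperparams=(("n_neighbors", 3),)),
            n_boot=50, seed=11,
        )
        assert res.n_redraws > 0

    def test_one_class_rejected(self):
        X = pd.DataFrame({"f": [1.0, 2.0]}, index=["a", "b"])
        y = pd.Series([1, 1], index=X.index)
        with pytest.raises(InputFormatError):
            bootstrap_oob_evaluate(FeatureTable(X=X, y=y), ModelSpec(), n_boot=5, seed=0)

    def test_permutation_null_auc(self):
        # guards against OOB leakage: permuted labels must give AUC ~ 0.5
        rng = np.random.default_rng(21)
        aucs = []
        for rep in range(10):
            ft = gaussian_features(n_per_class=15, shift=2.0, seed=100 + rep)
            y_perm = pd.Series(
                rng.permutation(ft.y.to_numpy()), index=ft.y.index
            )
            res = bootstrap_oob_evaluate(
                FeatureTable(X=ft.X, y=y_perm),
                ModelSpec(classifier="knn"),
                n_boot=40,
                seed=200 + rep,
            )
            aucs.append(res.auc)
        se = np.std(aucs, ddof=1) / np.sqrt(len(aucs))
        assert abs(np.mean(aucs) - 0.5) <= 3 * se


class TestSelectBestModel:
    def test_nonconstant_beats_constant(self):
        ft = gaussian_features(shift=5.0, seed=12)
        grid = [ModelSpec(classifier="constant"), ModelSpec(classifier="knn")]
        res = select_best_model(ft, grid, n_boot=30, seed=13)
        assert res.spec.classifier == "knn"
        assert res.auc > 0.5

    def test_tie_keeps_first(self):
        ft = gaussian_features(shift=5.0, seed=12)
        grid = [ModelSpec(classifier="constant"), ModelSpec(classifier="constant")]
        res = select_best_model(ft, grid, n_boot=10, seed=13)
        assert res.spec == grid[0]

    def test_empty_grid(self):
        ft = gaussian_features(shift=1.0)
        with pytest.raises(ParameterError):
            select_best_model(ft, [], n_boot=5, seed=0)

    def test_selected_equals_max_of_recomputed_grid(self):
        ft = gaussian_features(n_per_class=12, shift=2.0, seed=14)
        grid = default_grid()
        res = select_best_model(ft, grid, n_boot=10, seed=15)
        recomputed = [
            bootstrap_oob_evaluate(ft, spec, n_boot=10, seed=15).auc for spec in grid
        ]
        assert res.auc == max(recomputed)
        assert res.spec == grid[int(np.argmax(recomputed))]


class TestMannWhitney:
    def test_exact_small_sample(self):
        u, p = mann_whitney_one_sided([4, 5, 6], [1, 2, 3], "greater")
        assert u == 9.0
        assert p == pytest.approx(1 / 20)

    def test_symmetric_null(self):
        _, p = mann_whitney_one_sided([1, 2, 3], [1, 2, 3], "greater")
        assert p >= 0.5

    def test_complement_identity(self):
        a, b = [4.0, 7.0, 2.0], [3.0, 1.0, 6.0]
        _, p_greater = mann_whitney_one_sided(a, b, "greater")
        _, p_less = mann_whitney_one_sided(a, b, "less")
        assert p_greater + p_less >= 1.0

    def test_exact_matches_full_enumeration(self, rng):
        a = list(rng.integers(0, 10, 4).astype(float))
        b = list(rng.integers(0, 10, 5).astype(float))
        u_obs, p = mann_whitney_one_sided(a, b, "greater")
        pooled = np.array(a + b)
        hits = total = 0
        for combo in itertools.combinations(range(9), 4):
            mask = np.zeros(9, bool)
            mask[list(combo)] = True
            aa, bb = pooled[mask], pooled[~mask]
            u = (aa[:, None] > bb[None, :]).sum() + 0.5 * (aa[:, None] == bb[None, :]).sum()
            hits += u >= u_obs
            total += 1
        assert p == pytest.approx(hits / total)

    def test_large_sample_asymptotic(self, rng):
        a = rng.normal(1, 1, 20)
        b = rng.normal(0, 1, 20)
        u, p = mann_whitney_one_sided(a, b, "greater")
        assert 0 < p < 1

    def test_empty_group_error(self):
        with pytest.raises(InputFormatError):
            mann_whitney_one_sided([], [1.0], "greater")


def result_with_scores(scores: dict[str, float]) -> BiomarkerResult:
    index = pd.Index(list(scores))
    return BiomarkerResult(
        scores=pd.Series(scores, name="oob_score"),
        oob_counts=pd.Series(1, index=index),
        roc=pd.DataFrame({"fpr": [0, 1], "tpr": [0, 1], "threshold": [1, 0]}),
        auc=0.5,
        spec=ModelSpec(),
        n_boot=1,
        seed=0,
    )


class TestLogrank:
    def test_identical_groups_null(self):
        res = result_with_scores({"a": 0.9, "b": 0.9, "c": 0.1, "d": 0.1})
        survival = pd.DataFrame(
            {"time": [5.0, 10.0, 5.0, 10.0], "event": [1, 1, 1, 1]},
            index=["a", "b", "c", "d"],
        )
        out = stratify_and_logrank(res, survival)
        assert out.statistic == pytest.approx(0.0, abs=1e-12)
        assert out.p_value == pytest.approx(1.0)

    def test_hand_computed_four_sample_case(self):
        # positives die at t=1 and t=3; negatives at t=2 and t=4, no censoring.
        # Hand tally (observed - expected for the positive group):
        #   t=1: O=1, E=2/4 -> +1/2,  V=(2/4)(2/4)(3)/3 = 1/4
        #   t=2: O=0, E=1/3 -> -1/3,  V=(1/3)(2/3)(1)   = 2/9
        #   t=3: O=1, E=1/2 -> +1/2,  V=(1/2)(1/2)(1)   = 1/4
        #   t=4: O=0, E=0   ->  0,    V=0
        # sum(O-E) = 2/3, sum(V) = 13/18, chi2 = (4/9)/(13/18) = 8/13
        res = result_with_scores({"p1": 0.9, "p2": 0.8, "n1": 0.2, "n2": 0.1})
        survival = pd.DataFrame(
            {"time": [1.0, 3.0, 2.0, 4.0], "event": [1, 1, 1, 1]},
            index=["p1", "p2", "n1", "n2"],
        )
        out = stratify_and_logrank(res, survival)
        assert out.statistic == pytest.approx(8 / 13, abs=1e-9)
        assert out.p_value == pytest.approx(float(chi2.sf(8 / 13, 1)), abs=1e-9)

    def test_threshold_rule_is_inclusive(self):
        res = result_with_scores({"a": 0.5, "b": 0.4})
        survival = pd.DataFrame(
            {"time": [1.0, 2.0], "event": [1, 1]}, index=["a", "b"]
        )
        out = stratify_and_logrank(res, survival)
        assert out.groups["a"] and not out.groups["b"]

    def test_single_group_flagged(self):
        res = result_with_scores({"a": 0.9, "b": 0.9})
        survival = pd.DataFrame(
            {"time": [1.0, 2.0], "event": [1, 0]}, index=["a", "b"]
        )
        out = stratify_and_logrank(res, survival)
        assert "single_group" in out.flags
        assert out.statistic is None and out.p_value is None

    def test_km_curves_present(self):
        res = result_with_scores({"a": 0.9, "b": 0.9, "c": 0.1, "d": 0.1})
        survival = pd.DataFrame(
            {"time": [5.0, 10.0, 3.0, 8.0], "event": [1, 0, 1, 1]},
            index=["a", "b", "c", "d"],
        )
        out = stratify_and_logrank(res, survival)
        assert set(out.km_curves) == {"positive", "negative"}


class TestEndToEndSignal:
    def test_responders_with_elevated_ex_em_detected(self, synth_model, synth_reference,
                                                     synth_background):
        # responders carry more exhausted+EM signal in their bulk mixtures
        from tcsp.core_io import compute_cpm
        from tcsp.deconvolve import deconvolve_samples
        from tcsp.synthesis import MixtureSpec, mix_counts

        comp = pd.DataFrame(
            {
                "EX": synth_reference.expected_cpm["EX"],
                "EM": synth_reference.expected_cpm["EM"],
                "BG": synth_background.mean_profile,
            }
        )
        children = np.random.SeedSequence(31).spawn(24)
        frames, labels = [], {}
        for i, child in enumerate(children):
            responder = i % 2 == 0
            ex, em = (0.20, 0.20) if responder else (0.04, 0.06)
            spec = MixtureSpec(
                comp, [ex, em, 1 - ex - em], depth=300_000,
                seed=int(child.generate_state(1)[0]), sample_id=f"pt{i:02d}",
            )
            m, _ = mix_counts(spec)
            frames.append(m.data)
            labels[f"pt{i:02d}"] = int(responder)
        bulk = ExpressionMatrix(pd.concat(frames, axis=1), unit="counts")
        estimates = deconvolve_samples(compute_cpm(bulk), synth_model)
        ft = assemble_features(estimates, labels, mode="both")
        grid = [ModelSpec(classifier="knn"), ModelSpec(projection="pca", classifier="svm")]
        res = select_best_model(ft, grid, n_boot=40, seed=32)
        assert res.auc > 0.8
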