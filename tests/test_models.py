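import itertools

import numpy as np
import pandas as pd
import pytest

from cfentropy import models as mm


def binary_problem(rng, n=60, p=5, sep=2.0):
    y = np.repeat([0, 1], n // 2)
    x = pd.DataFrame(
        rng.normal(size=(n, p)) + sep * y[:, None] * np.linspace(0.2, 1, p),
        index=[f"S{i}" for i in range(n)],
        columns=[f"f{j}" for j in range(p)],
    )
    return x, y


class TestTrainPredict:
    def test_separable_training_auc_one(self, rng):
        x, y = binary_problem(rng, sep=6.0)
        b = mm.train_binary(x, y)
        assert mm.evaluate(b.train_scores, y).auc == 1.0

    def test_same_seed_identical_coefficients(self, rng):
        x, y = binary_problem(rng)
        b1 = mm.train_binary(x, y, seed=3)
        b2 = mm.train_binary(x, y, seed=3)
        np.testing.assert_array_equal(b1.model.coef_, b2.model.coef_)

    def test_single_class_rejected(self, rng):
        x, _ = binary_problem(rng)
        with pytest.raises(ValueError, match="single class"):
            mm.train_binary(x, np.ones(len(x), dtype=int))

    def test_predict_is_row_order_invariant(self, rng):
        x, y = binary_problem(rng)
        b = mm.train_binary(x, y)
        s1 = mm.predict_score(b, x)
        s2 = mm.predict_score(b, x.iloc[::-1])
        pd.testing.assert_series_equal(s1.sort_index(), s2.sort_index())

    def test_missing_feature_errors_by_name(self, rng):
        x, y = binary_problem(rng)
        b = mm.train_binary(x, y)
        with pytest.raises(KeyError, match="f4"):
            mm.predict_score(b, x.drop(columns=["f4"]))

    def test_all_na_row_gets_finite_score(self, rng):
        x, y = binary_problem(rng)
        b = mm.train_binary(x, y)
        na_row = pd.DataFrame(
            np.nan, index=["SX"], columns=x.columns
        )
        assert np.isfinite(mm.predict_score(b, na_row).iloc[0])

    def test_na_imputed_with_training_median(self, rng):
        x, y = binary_problem(rng)
        b = mm.train_binary(x, y)
        med_row = pd.DataFrame([x.median(axis=0)], index=["SM"])
        na_row = pd.DataFrame(np.nan, index=["SM"], columns=x.columns)
        assert mm.predict_score(b, na_row).iloc[0] == pytest.approx(
            mm.predict_score(b, med_row).iloc[0]
        )


class TestFusion:
    def test_identical_scores_preserve_ranking(self, rng):
        y = np.repeat([0, 1], 20)
        s = pd.Series(rng.uniform(size=40) + 0.5 * y,
                      index=[f"S{i}" for i in range(40)])
        b = mm.fuse_emced(s, s.copy(), s.copy(), y)
        fused = mm.predict_score(b, pd.DataFrame(
            {"entropy": s, "methylation": s, "fragmentation": s}
        ))
        assert (fused.rank() == s.rank()).all()

    def test_misaligned_ids_rejected(self, rng):
        y = np.repeat([0, 1], 10)
        a = pd.Series(rng.uniform(size=20), index=[f"S{i}" for i in range(20)])
        b = pd.Series(rng.uniform(size=20), index=[f"T{i}" for i in range(20)])
        with pytest.raises(ValueError, match="misaligned"):
            mm.fuse_emced(a, b, None, y)

    def test_constant_modality_degrades_gracefully(self, rng):
        y = np.repeat([0, 1], 30)
        idx = [f"S{i}" for i in range(60)]
        good = pd.Series(0.4 * y + rng.uniform(0, 0.4, 60), index=idx)
        good2 = pd.Series(0.4 * y + rng.uniform(0, 0.4, 60), index=idx)
        flat = pd.Series(0.5, index=idx)
        with_flat = mm.fuse_emced(good, good2, flat, y, seed=0)
        without = mm.fuse_emced(good, good2, None, y, seed=0)
        x3 = pd.DataFrame({"entropy": good, "methylation": good2,
                           "fragmentation": flat})
        x2 = x3[["entropy", "methylation"]]
        auc3 = mm.evaluate(mm.predict_score(with_flat, x3), y).auc
        auc2 = mm.evaluate(mm.predict_score(without, x2), y).auc
        assert auc3 == pytest.approx(auc2, abs=0.02)

    def test_complementary_modalities_fuse_better(self, rng):
        # each modality informative on a disjoint half of the cancer cases
        n = 120
        y = np.repeat([0, 1], n // 2)
        half = np.zeros(n, dtype=bool)
        half[n // 2: n // 2 + n // 4] = True
        other = np.zeros(n, dtype=bool)
        other[n // 2 + n // 4:] = True
        idx = [f"S{i}" for i in range(n)]
        e = pd.DataFrame({"e": np.where(half, 3.0, 0.0) + rng.normal(0, 1, n)},
                         index=idx)
        m = pd.DataFrame({"m": np.where(other, 3.0, 0.0) + rng.normal(0, 1, n)},
                         index=idx)
        emced = mm.fit_emced(
            {"entropy": (e, "logistic"), "methylation": (m, "logistic")}, y,
            seed=0,
        )
        oof_e = mm.oof_scores(e, y, "logistic", "entropy", 0)
        oof_m = mm.oof_scores(m, y, "logistic", "methylation", 0)
        fused = mm.predict_score(
            emced.fusion, pd.DataFrame({"entropy": oof_e, "methylation": oof_m})
        )
        auc_f = mm.evaluate(fused, y).auc
        auc_single = max(mm.evaluate(oof_e, y).auc, mm.evaluate(oof_m, y).auc)
        assert auc_f >= auc_single - 0.01


class TestTOO:
    def _typed(self, rng, n_per=15, p=8, sep=4.0):
        types = ["colorectal", "lung", "ovarian"]
        y = np.repeat(types, n_per)
        x = pd.DataFrame(
            rng.normal(size=(len(y), p)),
            index=[f"S{i}" for i in range(len(y))],
            columns=[f"f{j}" for j in range(p)],
        )
        for k, t in enumerate(types):
            x.loc[y == t, f"f{k}"] += sep
        sex = pd.Series(
            np.where(y == "ovarian", "female",
                     rng.choice(["male", "female"], size=len(y))),
            index=x.index,
        )
        return x, pd.Series(y, index=x.index), sex

    def test_separated_types_recovered(self, rng):
        x, y, sex = self._typed(rng)
        b = mm.train_too(x, y, sex=sex, kind="logistic")
        probs = mm.too_probabilities(b, x, sex=sex)
        report = mm.evaluate_too(probs, y)
        assert report.top1_accuracy >= 0.9

    def test_probabilities_sum_to_one(self, rng):
        x, y, sex = self._typed(rng)
        for kind in ("logistic", "elastic_net"):
            b = mm.train_too(x, y, sex=sex, kind=kind)
            probs = mm.too_probabilities(b, x, sex=sex)
            np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_male_sample_pushed_away_from_ovarian(self, rng):
        x, y, sex = self._typed(rng, n_per=30)
        b = mm.train_too(x, y, sex=sex, kind="logistic")
        probe = pd.DataFrame(
            [x[y == "ovarian"].mean(axis=0)], index=["probe"]
        )
        p_female = mm.too_probabilities(
            b, probe, sex=pd.Series({"probe": "female"})
        )["ovarian"].iloc[0]
        p_male = mm.too_probabilities(
            b, probe, sex=pd.Series({"probe": "male"})
        )["ovarian"].iloc[0]
        assert p_male < p_female

    def test_fused_probability_average(self):
        idx = ["S1"]
        types = ["colorectal", "lung"]
        pa = pd.DataFrame([[0.6, 0.4]], index=idx, columns=types)
        pb = pd.DataFrame([[0.2, 0.8]], index=idx, columns=types)

        class Fake:
            pass

        import unittest.mock as mock

        with mock.patch.object(mm, "too_probabilities", side_effect=[pa, pb]):
            out = mm.predict_too(
                {"entropy": Fake(), "methylation": Fake()},
                {"entropy": pa, "methylation": pb},
                fusion="e_m",
            )
        np.testing.assert_allclose(out.to_numpy(), [[0.4, 0.6]])

    def test_entropy_only_fusion_is_entropy(self, rng):
        x, y, sex = self._typed(rng)
        b = mm.train_too(x, y, sex=sex, kind="logistic")
        direct = mm.too_probabilities(b, x, sex=sex)
        fused = mm.predict_too({"entropy": b}, {"entropy": x}, sex=sex,
                               fusion="entropy_only")
        np.testing.assert_allclose(direct.to_numpy(), fused.to_numpy(),
                                   atol=1e-12)

    def test_top2_at_least_top1(self, rng):
        x, y, sex = self._typed(rng, sep=0.5)
        b = mm.train_too(x, y, sex=sex, kind="logistic")
        r = mm.evaluate_too(mm.too_probabilities(b, x, sex=sex), y)
        assert r.top2_accuracy >= r.top1_accuracy


class TestEvaluate:
    def test_perfect_ranking(self):
        y = [0, 0, 1, 1]
        assert mm.evaluate([0.1, 0.2, 0.8, 0.9], y).auc == 1.0

    def test_confusion_at_threshold(self):
        y = [1] * 10 + [0] * 10
        s = [0.9] * 10 + [0.1] * 10
        r = mm.evaluate(s, y, threshold=0.5)
        assert r.sensitivity == 1.0 and r.specificity == 1.0
        assert r.confusion == {"tp": 10, "fp": 0, "tn": 10, "fn": 0}
        lo, hi = r.sensitivity_ci
        assert lo == pytest.approx(0.6915, abs=1e-3)  # Clopper-Pearson 10/10
        assert hi == 1.0

    def test_auc_matches_pair_counting_oracle(self, rng):
        for _ in range(10):
            n = 16
            y = rng.integers(0, 2, size=n)
            if len(np.unique(y)) < 2:
                continue
            s = rng.choice([0.1, 0.25, 0.5, 0.8], size=n)  # ties likely
            wins = ties = 0
            pairs = 0
            for i, j in itertools.product(range(n), range(n)):
                if y[i] == 1 and y[j] == 0:
                    pairs += 1
                    wins += s[i] > s[j]
                    ties += s[i] == s[j]
            oracle = (wins + 0.5 * ties) / pairs
            assert mm.evaluate(s, y).auc == pytest.approx(oracle, abs=1e-12)

    def test_single_class_undefined(self):
        with pytest.raises(ValueError, match="single-class"):
            mm.evaluate([0.5, 0.6], [1, 1])


class TestCrossValidate:
    def test_fold_structure_and_determinism(self, rng):
        x, y = binary_problem(rng, n=50)
        r1 = mm.crossvalidate(x, y, k=5, seed=2)
        r2 = mm.crossvalidate(x, y, k=5, seed=2)
        assert r1["folds"] == r2["folds"]
        sizes = [len(f) for f in r1["folds"]]
        assert max(sizes) - min(sizes) <= 1

    def test_too_few_per_class_rejected(self, rng):
        x, _ = binary_problem(rng, n=10)
        y = np.array([1, 0, 0, 0, 0, 0, 0, 0, 0, 0])
        with pytest.raises(ValueError):
            mm.crossvalidate(x, y, k=5)

    def test_permuted_labels_near_chance(self, rng):
        aucs = []
        for rep in range(20):
            x, y = binary_problem(rng, n=60, sep=3.0)
            yp = rng.permutation(y)
            aucs.append(mm.crossvalidate(x, yp, k=5, seed=rep)["pooled_auc"])
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.08)
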