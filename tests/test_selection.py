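import numpy as np
import pandas as pd
import pytest

from cfentropy import selection as sel
from cfentropy.io import RegionFeatureMatrix


def make_matrix(values, depths=None, prefix="r"):
    v = pd.DataFrame(
        values, columns=[f"{prefix}{j}" for j in range(np.shape(values)[1])]
    )
    v.index = [f"S{i}" for i in range(len(v))]
    d = (
        pd.DataFrame(depths, index=v.index, columns=v.columns)
        if depths is not None
        else pd.DataFrame(100, index=v.index, columns=v.columns)
    )
    return RegionFeatureMatrix(v, d)


class TestPreprocess:
    def test_low_depth_cell_masked(self):
        depths = [[49, 60]] + [[60, 60]] * 3
        mat = make_matrix([[0.5, 0.5]] * 4, depths=depths)
        out = sel.preprocess_regions(mat, sel.SelectionConfig())
        assert np.isnan(out.values.loc["S0", "r0"])
        assert out.values.loc["S1":, "r0"].notna().all()
        assert out.values["r1"].notna().all()

    def test_mostly_missing_region_dropped(self):
        v = np.full((20, 2), 0.4)
        v[: 19, 0] = np.nan  # 95% NA
        mat = make_matrix(v)
        out = sel.preprocess_regions(mat, sel.SelectionConfig())
        assert out.region_ids == ["r1"]

    def test_clean_matrix_unchanged(self):
        mat = make_matrix([[0.2, 0.3]] * 5)
        out = sel.preprocess_regions(mat, sel.SelectionConfig())
        pd.testing.assert_frame_equal(out.values, mat.values)

    def test_everything_dropped_errors(self):
        v = np.full((10, 1), np.nan)
        with pytest.raises(ValueError, match="all regions dropped"):
            sel.preprocess_regions(make_matrix(v), sel.SelectionConfig())


class TestRegionStats:
    def test_worked_example(self):
        controls = np.arange(0.1, 1.05, 0.1)
        cases = np.array([0.85, 0.9, 0.5, 0.95])
        st = sel.region_stats(cases, controls, specificity=0.80)
        assert st.delta == pytest.approx(0.25)
        assert st.sensitivity_at_spec == pytest.approx(0.75)
        assert st.direction == "up"

    def test_exchangeable_null_sensitivity(self, rng):
        # identical distributions, fixed direction: sensitivity ~ 1 - spec
        hits = []
        for _ in range(200):
            case = rng.normal(size=40)
            ctrl = rng.normal(size=40)
            st = sel.region_stats(case, ctrl, direction="up")
            hits.append(st.sensitivity_at_spec)
        assert np.mean(hits) == pytest.approx(0.20, abs=0.04)

    def test_adaptive_direction_biases_null_upward(self, rng):
        # direction chosen by sign(delta) picks the favorable side post hoc
        hits = []
        for _ in range(200):
            st = sel.region_stats(rng.normal(size=40), rng.normal(size=40))
            hits.append(st.sensitivity_at_spec)
        assert 0.20 <= np.mean(hits) <= 0.35

    def test_complete_separation(self):
        st = sel.region_stats([10.0, 11.0, 12.0], [1.0, 2.0, 3.0, 4.0, 5.0])
        assert st.sensitivity_at_spec == 1.0

    def test_down_direction(self):
        st = sel.region_stats(
            [0.1, 0.12, 0.08], [0.5, 0.55, 0.6, 0.45, 0.52, 0.58]
        )
        assert st.direction == "down"
        assert st.sensitivity_at_spec == 1.0

    def test_insufficient_group_skipped(self):
        assert sel.region_stats([0.1], [0.2, 0.3]) is None
        assert sel.region_stats([np.nan, np.nan], [0.2, 0.3, 0.4]) is None


class TestBinaryThresholds:
    def _stats(self, delta, sens, p):
        return sel.RegionStats("r", delta, sens, p)

    def test_conjunction(self):
        cfg = sel.SelectionConfig()
        keep = sel.select_binary_features(
            [self._stats(0.03, 0.45, 0.005)], cfg
        )
        assert keep == ["r"]

    @pytest.mark.parametrize(
        "delta,sens,p",
        [(0.019, 0.45, 0.005), (0.03, 0.39, 0.005), (0.03, 0.45, 0.02)],
    )
    def test_single_violation_drops(self, delta, sens, p):
        with pytest.warns(UserWarning):
            assert sel.select_binary_features(
                [self._stats(delta, sens, p)], sel.SelectionConfig()
            ) == []

    def test_negative_delta_uses_magnitude(self):
        assert sel.select_binary_features(
            [self._stats(-0.05, 0.5, 0.001)], sel.SelectionConfig()
        ) == ["r"]

    def test_tightening_never_enlarges(self, rng):
        stats = [
            sel.RegionStats(f"r{i}", rng.uniform(-0.1, 0.1),
                            rng.uniform(), rng.uniform(0, 0.05))
            for i in range(50)
        ]
        base_cfg = sel.SelectionConfig()
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            base = set(sel.select_binary_features(stats, base_cfg))
            for tighter in (
                sel.SelectionConfig(min_abs_delta=0.05),
                sel.SelectionConfig(min_sensitivity=0.6),
                sel.SelectionConfig(max_p=0.001),
            ):
                assert set(sel.select_binary_features(stats, tighter)) <= base


class TestImportanceFilter:
    def test_noise_feature_dropped_strong_kept(self, rng):
        n = 120
        y = np.repeat([0, 1], n // 2)
        strong = {
            f"good{j}": np.where(y == 1, 0.5, 0.3) + rng.normal(0, 0.05, n)
            for j in range(3)
        }
        noise = {f"noise{j}": rng.normal(size=n) for j in range(3)}
        x = make_matrix(np.column_stack(list(strong.values()) + list(noise.values())))
        x.values.columns = list(strong) + list(noise)
        x.depths.columns = x.values.columns
        kept, imp = sel.importance_filter(x.values, y, threshold=0.006, seed=0)
        assert set(kept) >= set(strong)
        assert imp[list(strong)].min() > imp[list(noise)].max()

    def test_deterministic_given_seed(self, rng):
        y = np.repeat([0, 1], 30)
        x = pd.DataFrame(rng.normal(size=(60, 5)), columns=list("abcde"))
        k1, i1 = sel.importance_filter(x, y, 0.006, seed=7)
        k2, i2 = sel.importance_filter(x, y, 0.006, seed=7)
        assert k1 == k2
        pd.testing.assert_series_equal(i1, i2)


class TestBoruta:
    def test_planted_feature_confirmed_null_rejected(self, rng):
        n = 100
        y = np.repeat([0, 1], n // 2)
        x = pd.DataFrame(rng.normal(size=(n, 8)), columns=[f"f{j}" for j in range(8)])
        x["planted"] = y * 1.0 + rng.normal(0, 0.3, n)
        kept, imp = sel.boruta_select(x, y, seed=1)
        assert "planted" in kept
        assert imp["planted"] == imp.max()

    def test_permuted_labels_confirm_nothing(self, rng):
        n = 80
        x = pd.DataFrame(rng.normal(size=(n, 10)))
        x.columns = [f"f{j}" for j in range(10)]
        y = rng.permutation(np.repeat([0, 1], n // 2))
        kept, _ = sel.boruta_select(x, y, seed=2)
        assert kept == []

    def test_same_seed_same_confirmations(self, rng):
        n = 60
        y = np.repeat([0, 1], n // 2)
        x = pd.DataFrame(rng.normal(size=(n, 6)))
        x.columns = [f"f{j}" for j in range(6)]
        x["sig"] = y + rng.normal(0, 0.5, n)
        k1, _ = sel.boruta_select(x, y, seed=5)
        k2, _ = sel.boruta_select(x, y, seed=5)
        assert k1 == k2


class TestKWDunn:
    def _typed_matrix(self, rng, planted=True):
        types = np.repeat(["a", "b", "c"], 20)
        x = pd.DataFrame(
            rng.normal(size=(60, 10)), columns=[f"r{j}" for j in range(10)]
        )
        x.index = [f"S{i}" for i in range(60)]
        if planted:
            x.loc[types == "a", "r0"] += 3.0
        return x, pd.Series(types, index=x.index)

    def test_planted_type_region_attributed(self, rng):
        x, types = self._typed_matrix(rng)
        out = sel.kw_dunn_select(x, types, top_k=30, seed=0)
        assert "r0" in out["a"]
        assert "r0" not in out["b"] and "r0" not in out["c"]

    def test_global_null_selects_nothing(self, rng):
        x, types = self._typed_matrix(rng, planted=False)
        out = sel.kw_dunn_select(x, types, seed=0)
        assert sum(len(v) for v in out.values()) == 0

    def test_top_k_truncation(self, rng):
        x, types = self._typed_matrix(rng)
        for j in range(1, 4):
            x.loc[types == "a", f"r{j}"] += 3.0
        out = sel.kw_dunn_select(x, types, top_k=1, seed=0)
        assert all(len(v) <= 1 for v in out.values())

    def test_small_type_rejected(self, rng):
        x, types = self._typed_matrix(rng)
        types.iloc[:] = "a"
        types.iloc[0] = "b"
        with pytest.raises(ValueError, match="fewer than 2"):
            sel.kw_dunn_select(x, types, seed=0)


def test_recall_precision_on_default_cohort():
    """Planted binary regions recovered by the cascade at 60/60 samples."""
    from cfentropy.entropy import entropy_matrix
    from cfentropy.synthetic import SimulationConfig, simulate_cohort

    recalls, precisions = [], []
    for seed in range(3):
        c = simulate_cohort(SimulationConfig(
            n_cancer_train=60, n_control_train=60,
            n_cancer_test=5, n_control_test=5,
            n_fragments_per_sample=200, seed=seed,
        ))
        lab = c.labels.table
        tr = lab[lab["split"] == "train"]
        mat = entropy_matrix(
            c.epireads, c.regions, list(lab["sample_id"])
        )
        cfg = sel.SelectionConfig.for_modality("entropy")
        mat = sel.preprocess_regions(mat, cfg)
        case = list(tr.loc[tr["group"] == "cancer", "sample_id"])
        ctrl = list(tr.loc[tr["group"] == "non_cancer", "sample_id"])
        stats = sel.matrix_region_stats(mat, case, ctrl)
        cand = sel.select_binary_features(stats, cfg)
        y = (tr["group"] == "cancer").astype(int).to_numpy()
        kept, _ = sel.importance_filter(
            mat.values.loc[list(tr["sample_id"]), cand], y,
            cfg.importance_threshold, seed=seed,
        )
        truth = set(c.truth.binary_region_ids)
        recalls.append(len(truth & set(kept)) / len(truth))
        precisions.append(len(truth & set(kept)) / max(len(kept), 1))
    assert np.mean(recalls) >= 0.9
    assert np.mean(precisions) >= 0.8
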