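import numpy as np
import pandas as pd
import pytest

from contextprofile.cmp import CMPMatrix, ContextConfig, ContextIndex
from contextprofile.entropy import approximate_entropy, fuzzy_entropy
from contextprofile.features import FEATURES, FeatureSeries
from contextprofile.scoring import (EntropyConfig, context_score_distance_weighted,
                                    context_score_equal, entropy_weights,
                                    fuse_univariate, mdcmp_artifacts, score_contexts,
                                    score_pipeline)

from oracles import apen_oracle, fuzzyen_oracle


def _sine(n):
    return np.sin(np.arange(n) * 0.5)


class TestApproximateEntropy:
    def test_constant_series_is_exactly_zero(self):
        assert approximate_entropy(np.full(100, 3.7), m=7, r=0.2) == 0.0

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(20)
        for n, m in [(60, 2), (120, 3), (200, 7)]:
            x = rng.normal(size=n)
            tol = 0.2 * x.std()
            got = approximate_entropy(x, m=m, r=0.2)
            assert got == pytest.approx(apen_oracle(x, m, tol), abs=1e-10)

    def test_noise_more_entropic_than_sine(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            noise = rng.uniform(size=300)
            assert approximate_entropy(noise, m=2, r=0.2) > \
                approximate_entropy(_sine(300), m=2, r=0.2)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            approximate_entropy(np.ones(5), m=7)


class TestFuzzyEntropy:
    def test_constant_series_is_zero(self):
        assert fuzzy_entropy(np.full(100, 1.5), m=7, r=0.2) == pytest.approx(0.0, abs=1e-12)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(21)
        for n, m in [(60, 2), (150, 3)]:
            x = rng.normal(size=n)
            tol = 0.2 * x.std()
            got = fuzzy_entropy(x, m=m, r=0.2, n_fuzzy=2.0)
            assert got == pytest.approx(fuzzyen_oracle(x, m, tol, 2.0), abs=1e-10)

    def test_noise_more_entropic_than_sine(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            noise = rng.uniform(size=300)
            assert fuzzy_entropy(noise, m=2, r=0.2) > fuzzy_entropy(_sine(300), m=2, r=0.2)

    def test_nonnegative(self):
        rng = np.random.default_rng(22)
        for _ in range(10):
            x = rng.normal(size=80)
            assert fuzzy_entropy(x, m=2, r=0.2) >= -1e-12


def _layer(values):
    v = np.asarray(values, dtype=float)
    ci = ContextIndex(n=v.shape[0] * 3 + 2, m=3, c=3)
    return CMPMatrix(values=v, context_index=ci, feature="x")


class TestContextScores:
    def test_equal_is_mean_of_past_cells(self):
        lay = np.zeros((3, 3))
        lay[2, 0], lay[2, 1] = 0.2, 0.4
        assert context_score_equal(lay, 2) == pytest.approx(0.3)

    def test_context_zero_unscored(self):
        assert context_score_equal(np.ones((3, 3)), 0) is None
        assert context_score_distance_weighted(np.ones((3, 3)), 0) is None

    def test_equal_matches_loop_oracle(self):
        rng = np.random.default_rng(23)
        lay = rng.exponential(size=(12, 12))
        for i in range(1, 12):
            ref = np.mean([lay[i, j] for j in range(i)])
            assert context_score_equal(lay, i) == pytest.approx(ref)

    def test_distance_weighted_hand_example(self):
        # i=3: hop 3 -> 0.6, hop 2 -> 0.6, hop 1 -> 0.0
        lay = np.zeros((4, 4))
        lay[3, 0], lay[3, 1], lay[3, 2] = 0.6, 0.6, 0.0
        expect = (0.6 / 3 + 0.6 / 2 + 0.0) / (1 / 3 + 1 / 2 + 1)
        got = context_score_distance_weighted(lay, 3)
        assert got == pytest.approx(expect) == pytest.approx(0.5 / (11 / 6))

    def test_distance_weighted_constant_and_single(self):
        lay = np.full((5, 5), 0.3)
        assert context_score_distance_weighted(lay, 4) == pytest.approx(0.3)
        assert context_score_distance_weighted(lay, 1) == pytest.approx(0.3)

    def test_all_inf_past_is_skipped(self):
        lay = np.full((3, 3), np.inf)
        assert context_score_equal(lay, 2) is None


def _score_series(values, tag="sum"):
    from contextprofile.scoring import ScoreSeries
    frame = pd.DataFrame({
        "context_id": range(len(values)),
        "end_date": pd.date_range("2021-01-05", periods=len(values), freq="3D"),
        "score": values,
    })
    return ScoreSeries(patient_id="p", frame=frame, model_tag=tag)


class TestFusion:
    def test_statistics_per_context(self):
        per = {"a": _score_series([1.0]), "b": _score_series([2.0]), "c": _score_series([3.0])}
        assert fuse_univariate(per, "sum").frame["score"][0] == 6
        assert fuse_univariate(per, "mean").frame["score"][0] == 2
        assert fuse_univariate(per, "median").frame["score"][0] == 2
        assert fuse_univariate(per, "max").frame["score"][0] == 3

    def test_sum_equals_f_times_mean(self):
        rng = np.random.default_rng(24)
        per = {f"f{i}": _score_series(rng.exponential(size=9)) for i in range(5)}
        s = fuse_univariate(per, "sum").frame["score"]
        m = fuse_univariate(per, "mean").frame["score"]
        assert np.allclose(s, 5 * m)

    def test_entropy_weighted_sum(self):
        per = {"a": _score_series([0.3]), "b": _score_series([0.9])}
        w = pd.Series({"a": 2 / 3, "b": 1 / 3})
        got = fuse_univariate(per, "apen", weights=w).frame["score"][0]
        assert got == pytest.approx(0.5)

    def test_single_feature_identity(self):
        per = {"only": _score_series([0.4, 0.7])}
        for method in ("sum", "mean", "median", "max"):
            assert np.allclose(fuse_univariate(per, method).frame["score"], [0.4, 0.7])

    def test_misaligned_grids_rejected(self):
        per = {"a": _score_series([1.0, 2.0]), "b": _score_series([1.0])}
        with pytest.raises(ValueError):
            fuse_univariate(per, "sum")


def _toy_features(n_days=80, seed=30):
    rng = np.random.default_rng(seed)
    days = pd.date_range("2021-01-01", periods=n_days, freq="D")
    frame = pd.DataFrame(rng.exponential(size=(n_days, len(FEATURES))),
                         index=days, columns=list(FEATURES))
    missing = pd.Series(False, index=days)
    return FeatureSeries(patient_id="toy", frame=frame, missing=missing)


class TestEntropyWeights:
    def test_inverse_then_normalised(self):
        fs = _toy_features()
        w = entropy_weights(fs, "apen", EntropyConfig())
        assert w.sum() == pytest.approx(1.0)
        assert (w > 0).all()

    def test_flat_feature_dominates(self):
        # m_e=2 keeps the noisy features' entropy well away from zero, so the
        # epsilon-floored flat feature takes essentially all the weight
        fs = _toy_features()
        fs.frame["bathroom_em"] = 1.0  # zero entropy -> epsilon floor -> huge weight
        w = entropy_weights(fs, "apen", EntropyConfig(m_e=2))
        assert w["bathroom_em"] > 0.99


class TestScorePipeline:
    def test_mdcmp_equal_composes_select_and_score(self):
        fs = _toy_features(seed=31)
        cfg = ContextConfig()
        ss = score_pipeline(fs, cfg, "mdcmp_equal", k=1)
        _, _, k_used, layer = mdcmp_artifacts(fs, cfg, 1)
        ref = score_contexts(layer, fs.frame.index, fs.patient_id, "mdcmp_equal", "equal")
        assert np.allclose(ss.frame["score"], ref.frame["score"])
        assert k_used == 1

    def test_dates_strictly_increasing_and_end_dated(self):
        fs = _toy_features(seed=32)
        ss = score_pipeline(fs, ContextConfig(), "mdcmp_equal", k=0)
        dates = pd.to_datetime(ss.frame["end_date"])
        assert (dates.diff().dropna() > pd.Timedelta(0)).all()
        # context 1 (starts 3..5, m=3) ends on day index 7
        assert dates.iloc[0] == fs.frame.index[7]

    def test_affine_transform_of_one_feature_leaves_scores_unchanged(self):
        fs = _toy_features(seed=33)
        ss1 = score_pipeline(fs, ContextConfig(), "mdcmp_equal", k=2)
        fs2 = FeatureSeries(fs.patient_id, fs.frame.copy(), fs.missing)
        fs2.frame["lounge_wass"] = 3.5 * fs2.frame["lounge_wass"] + 11.0
        ss2 = score_pipeline(fs2, ContextConfig(), "mdcmp_equal", k=2)
        assert np.allclose(ss1.frame["score"], ss2.frame["score"], atol=1e-9)

    def test_scores_nondecreasing_in_k(self):
        fs = _toy_features(seed=34)
        prev = None
        for k in range(0, 11):
            s = score_pipeline(fs, ContextConfig(), "mdcmp_equal", k=k).frame["score"].to_numpy()
            if prev is not None:
                assert (s >= prev - 1e-12).all()
            prev = s

    def test_univariate_tags_run_and_fuse(self):
        fs = _toy_features(seed=35, n_days=60)
        for tag in ("sum", "mean", "median", "max"):
            ss = score_pipeline(fs, ContextConfig(), tag)
            assert len(ss.frame) > 0 and ss.model_tag == tag

    def test_constant_features_score_zero(self):
        days = pd.date_range("2021-01-01", periods=40, freq="D")
        frame = pd.DataFrame(1.0, index=days, columns=list(FEATURES))
        fs = FeatureSeries("flat", frame, pd.Series(False, index=days))
        ss = score_pipeline(fs, ContextConfig(), "mdcmp_equal", k=1)
        assert np.allclose(ss.frame["score"], 0.0)
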