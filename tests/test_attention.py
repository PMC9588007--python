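"""Attention aggregation and the fractional-logit Hamming-distance regression."""

import numpy as np
import pytest
from scipy.special import expit, logit

from phylodca.attention import (
    AttentionStack,
    ColumnAttentionSet,
    FractionalLogitModel,
    FractionalLogitRegressor,
    aggregate_attentions,
    build_design,
    column_stack,
    cross_msa_fit,
    error_std_by_column,
    evaluate_on_msa,
    fit_fractional_logit,
    fit_on_msa,
    load_attentions,
    load_logit_model,
    pair_features,
    per_column_predict,
    predict_distances,
    r_squared,
    save_attentions,
    save_logit_model,
    slope_diagnostic,
    split_protocol,
)
from phylodca.msa import Msa, distance_matrix
from phylodca.sampling import McmcConfig, sample_along_tree
from phylodca.synthetic import (
    PlantedSpec,
    SurrogateSpec,
    planted_potts,
    random_tree,
    surrogate_attentions,
)


def row_stochastic(rng, shape):
    t = rng.random(shape) + 0.05
    return t / t.sum(axis=-1, keepdims=True)


class TestAggregation:
    def test_identical_symmetric_columns_pass_through(self, rng):
        M = 5
        S = rng.random((M, M))
        S = (S + S.T) / 2
        S = S / S.sum(axis=1, keepdims=True)
        S = (S + S.T) / 2  # symmetric and (approximately) row-stochastic
        S = S / S.sum(axis=1, keepdims=True)
        # build an exactly row-stochastic symmetric matrix: uniform works
        S = np.full((M, M), 1 / M)
        raw = ColumnAttentionSet(np.broadcast_to(S, (1, 1, 4, M, M)).copy())
        stack = aggregate_attentions(raw)
        assert np.allclose(stack.matrices[0, 0], S)

    def test_single_column_symmetrisation(self, rng):
        M = 4
        A = row_stochastic(rng, (1, 1, 2, M, M))
        stack = aggregate_attentions(ColumnAttentionSet(A))
        expected = ((A + A.transpose(0, 1, 2, 4, 3)) / 2).mean(axis=2)
        assert np.allclose(stack.matrices, expected, atol=1e-12)

    def test_against_naive_loop_oracle(self, rng):
        nl, nh, L, M = 2, 2, 3, 4
        t = row_stochastic(rng, (nl, nh, L + 1, M, M))
        stack = aggregate_attentions(ColumnAttentionSet(t))
        for l in range(nl):
            for h in range(nh):
                acc = np.zeros((M, M))
                for j in range(L + 1):
                    acc += t[l, h, j] + t[l, h, j].T
                acc /= 2 * (L + 1)
                assert np.allclose(stack.matrices[l, h], acc, atol=1e-12)

    def test_missing_bos_column_rejected(self, rng):
        with pytest.raises(ValueError, match="BOS"):
            ColumnAttentionSet(row_stochastic(rng, (1, 1, 1, 4, 4)))

    def test_non_stochastic_rejected(self, rng):
        t = rng.random((1, 1, 3, 4, 4))
        with pytest.raises(ValueError, match="sum to 1"):
            ColumnAttentionSet(t)


class TestPairFeatures:
    def test_symmetry_and_raster_length(self, rng):
        m = rng.random((12, 12, 5, 5))
        m = (m + m.transpose(0, 1, 3, 2)) / 2
        stack = AttentionStack(m)
        f = pair_features(stack, 1, 3)
        assert f.shape == (144,)
        assert np.array_equal(f, pair_features(stack, 3, 1))
        # raster order: layer-major
        assert f[0] == m[0, 0, 1, 3]
        assert f[12] == m[1, 0, 1, 3]

    def test_self_pair_rejected(self, rng):
        m = np.zeros((1, 1, 4, 4))
        with pytest.raises(ValueError):
            pair_features(AttentionStack(m), 2, 2)

    def test_single_head_feature_is_the_entry(self):
        m = np.arange(16, dtype=float).reshape(1, 1, 4, 4)
        m = (m + m.transpose(0, 1, 3, 2)) / 2
        stack = AttentionStack(m)
        assert pair_features(stack, 0, 2)[0] == m[0, 0, 0, 2]


class TestFractionalLogitFit:
    def test_intercept_only_closed_form(self, rng):
        y = rng.uniform(0.1, 0.9, 60)
        X = np.zeros((60, 2))
        X[:, 0] = rng.standard_normal(60) * 0  # zero features
        X[:, 1] = 0.0
        # zero features are collinear with the constant; use a 0-column design
        model = fit_fractional_logit(np.empty((60, 0)), y)
        assert model.intercept == pytest.approx(float(logit(y.mean())), abs=1e-6)

    def test_constant_half_response_gives_zero_parameters(self, rng):
        X = rng.standard_normal((80, 3))
        y = np.full(80, 0.5)
        model = fit_fractional_logit(X, y)
        assert abs(model.intercept) < 1e-6
        assert np.abs(model.coef).max() < 1e-6

    def test_noiseless_planted_recovery(self, rng):
        beta0, beta = -0.7, np.array([1.5, -2.0, 0.5])
        X = rng.standard_normal((400, 3))
        y = expit(beta0 + X @ beta)
        model = fit_fractional_logit(X, y)
        assert model.intercept == pytest.approx(beta0, abs=1e-3)
        assert np.allclose(model.coef, beta, atol=1e-3)

    def test_collinear_features_rejected(self, rng):
        X = rng.standard_normal((50, 2))
        X = np.hstack([X, X[:, :1]])  # duplicated column
        y = rng.uniform(0, 1, 50)
        with pytest.raises(ValueError, match="collinear"):
            fit_fractional_logit(X, y)

    def test_permutation_invariance_over_pairs(self, rng):
        X = rng.standard_normal((100, 3))
        y = rng.uniform(0, 1, 100)
        perm = rng.permutation(100)
        m1 = fit_fractional_logit(X, y)
        m2 = fit_fractional_logit(X[perm], y[perm])
        assert m1.intercept == pytest.approx(m2.intercept, abs=1e-8)
        assert np.allclose(m1.coef, m2.coef, atol=1e-8)

    def test_exact_zero_responses_are_legal(self, rng):
        X = rng.standard_normal((50, 2))
        y = rng.uniform(0, 1, 50)
        y[:5] = 0.0  # duplicate sequences have distance exactly 0
        model = fit_fractional_logit(X, y)
        assert np.isfinite(model.intercept)

    def test_monotone_in_positive_coefficient_feature(self, rng):
        X = rng.standard_normal((200, 2))
        y = expit(0.3 + 1.2 * X[:, 0] - 0.5 * X[:, 1])
        est = FractionalLogitRegressor().fit(X, y)
        base = est.predict(np.array([[0.0, 0.0]]))[0]
        assert est.coef_[0] > 0
        up = est.predict(np.array([[1.0, 0.0]]))[0]
        assert up > base


class TestPredictDistances:
    def test_zero_model_gives_half(self):
        stack = AttentionStack(np.full((1, 1, 4, 4), 0.25))
        model = FractionalLogitModel(intercept=0.0, coef=np.zeros(1))
        pred = predict_distances(model, stack)
        off = pred[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 0.5)
        assert np.all(np.diag(pred) == 0)

    def test_large_negative_intercept_saturates_to_zero(self):
        stack = AttentionStack(np.full((1, 1, 3, 3), 1 / 3))
        model = FractionalLogitModel(intercept=-30.0, coef=np.zeros(1))
        assert predict_distances(model, stack).max() < 1e-10

    def test_scalar_affine_form(self):
        m = np.array([[[[0.0, 0.3], [0.3, 0.0]]]])
        model = FractionalLogitModel(intercept=0.5, coef=np.array([2.0]))
        pred = predict_distances(model, m_stack := AttentionStack(m))
        assert pred[0, 1] == pytest.approx(float(expit(0.5 + 2.0 * 0.3)))

    def test_dimension_mismatch(self):
        stack = AttentionStack(np.zeros((2, 2, 3, 3)))
        model = FractionalLogitModel(intercept=0.0, coef=np.zeros(3))
        with pytest.raises(ValueError):
            predict_distances(model, stack)


class TestSplitProtocol:
    def test_counts(self, rng):
        msa = Msa(ids=[f"s{i}" for i in range(10)],
                  matrix=rng.integers(0, 3, (10, 6)))
        train, test, tp, sp = split_protocol(msa, 0.7, rng)
        assert len(train) == 7 and len(test) == 3
        assert len(tp) == 21 and len(sp) == 3
        assert set(train).isdisjoint(test)

    def test_degenerate_fraction_rejected(self, rng):
        msa = Msa(ids=[f"s{i}" for i in range(10)],
                  matrix=rng.integers(0, 3, (10, 6)))
        with pytest.raises(ValueError):
            split_protocol(msa, 1.0, rng)

    def test_seeded_reproducibility(self, rng):
        msa = Msa(ids=[f"s{i}" for i in range(12)],
                  matrix=rng.integers(0, 3, (12, 6)))
        a = split_protocol(msa, 0.7, np.random.default_rng(5))
        b = split_protocol(msa, 0.7, np.random.default_rng(5))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


class TestDiagnostics:
    def test_r_squared_perfect_and_mean(self, rng):
        y = rng.random(30)
        assert r_squared(y, y) == pytest.approx(1.0)
        assert r_squared(y, np.full(30, y.mean())) == pytest.approx(0.0)

    def test_r_squared_hand_example(self):
        y = np.array([0.0, 1.0, 2.0])
        p = np.array([0.0, 1.5, 1.5])
        # SS_res = 0 + 0.25 + 0.25; SS_tot = 1 + 0 + 1
        assert r_squared(y, p) == pytest.approx(1 - 0.5 / 2.0)

    def test_r_squared_constant_truth_rejected(self):
        with pytest.raises(ValueError):
            r_squared(np.ones(5), np.zeros(5))

    def test_slope_perfect_and_halved(self, rng):
        y = rng.random(50)
        assert slope_diagnostic(y, y) == pytest.approx(1.0)
        assert slope_diagnostic(y, y / 2) == pytest.approx(2.0)

    def test_slope_matches_covariance_ratio(self, rng):
        pred = rng.random(200)
        truth = 0.8 * pred + 0.1 * rng.standard_normal(200)
        expected = np.cov(pred, truth, bias=True)[0, 1] / pred.var()
        assert slope_diagnostic(truth, pred) == pytest.approx(expected, abs=1e-10)

    def test_slope_constant_predictions_rejected(self, rng):
        with pytest.raises(ValueError):
            slope_diagnostic(rng.random(10), np.ones(10))


@pytest.fixture(scope="module")
def surrogate_setup():
    model, _ = planted_potts(PlantedSpec(L=12, q=8, n_contacts=3, seed=40))
    tree = random_tree(60, kind="yule", height=0.8, seed=41)
    msa = sample_along_tree(model, tree, McmcConfig(seed=42))
    spec = SurrogateSpec(n_layers=4, n_heads=4,
                         signal={(0, 1): 3.0, (1, 2): -3.0}, seed=43)
    raw = surrogate_attentions(msa, spec)
    return msa, raw, aggregate_attentions(raw)


class TestCrossMsaFit:
    def test_single_msa_equals_direct_pooled_fit(self, surrogate_setup):
        msa, raw, stack = surrogate_setup
        pooled = cross_msa_fit([msa], [stack])
        dmat = distance_matrix(msa)
        pairs = [(i, j) for i in range(msa.depth) for j in range(i + 1, msa.depth)]
        X, y = build_design(stack, dmat, pairs)
        direct = fit_fractional_logit(X, y)
        assert pooled.intercept == pytest.approx(direct.intercept, abs=1e-8)
        assert np.allclose(pooled.coef, direct.coef, atol=1e-8)

    def test_duplicated_msa_same_optimum(self, surrogate_setup):
        msa, raw, stack = surrogate_setup
        once = cross_msa_fit([msa], [stack])
        thrice = cross_msa_fit([msa] * 3, [stack] * 3)
        assert np.allclose(once.coef, thrice.coef, atol=1e-6)

    def test_inconsistent_head_counts_rejected(self, surrogate_setup, rng):
        msa, raw, stack = surrogate_setup
        other = AttentionStack(np.full((2, 2, msa.depth, msa.depth), 1 / msa.depth))
        with pytest.raises(ValueError, match="inconsistent"):
            cross_msa_fit([msa, msa], [stack, other])

    def test_heldout_generalization_with_shared_signal(self):
        """One model trained on several surrogate MSAs predicts a held-out one."""
        gen, _ = planted_potts(PlantedSpec(L=12, q=8, n_contacts=3, seed=50))
        msas, stacks = [], []
        for k in range(4):
            tree = random_tree(100, kind="yule", height=0.8, seed=60 + k)
            m = sample_along_tree(gen, tree, McmcConfig(seed=70 + k))
            raw = surrogate_attentions(
                m, SurrogateSpec(n_layers=4, n_heads=4,
                                 signal={(0, 1): 3.0, (1, 2): -3.0},
                                 seed=80 + k)
            )
            msas.append(m)
            stacks.append(aggregate_attentions(raw))
        model = cross_msa_fit(msas[:3], stacks[:3])
        metrics = evaluate_on_msa(model, msas[3], stacks[3])
        assert metrics["r2"] >= 0.9


class TestPerColumn:
    def test_identical_columns_match_aggregate(self, rng):
        M = 6
        base = row_stochastic(rng, (2, 2, 1, M, M))
        t = np.repeat(base, 5, axis=2)
        raw = ColumnAttentionSet(t)
        stack = aggregate_attentions(raw)
        model = FractionalLogitModel(intercept=0.2, coef=rng.standard_normal(4))
        agg = predict_distances(model, stack)
        for j in range(5):
            assert np.allclose(per_column_predict(model, raw, j), agg, atol=1e-12)

    def test_antisymmetric_perturbation_no_effect(self, rng):
        M = 6
        t = row_stochastic(rng, (1, 1, 3, M, M))
        raw1 = ColumnAttentionSet(t)
        model = FractionalLogitModel(intercept=0.0, coef=np.ones(1))
        p1 = per_column_predict(model, raw1, 1)
        # a 3-cycle antisymmetric perturbation with zero row sums keeps the
        # slice row-stochastic while leaving (A + A^T)/2 unchanged
        eps = 1e-3
        pert = np.zeros((M, M))
        pert[0, 1] = pert[1, 2] = pert[2, 0] = eps
        pert -= pert.T
        t2 = t.copy()
        t2[0, 0, 1] += pert
        p2 = per_column_predict(model, ColumnAttentionSet(t2), 1)
        assert np.allclose(p1, p2, atol=1e-12)

    def test_invalid_column_rejected(self, surrogate_setup):
        msa, raw, stack = surrogate_setup
        model = FractionalLogitModel(intercept=0.0, coef=np.zeros(16))
        with pytest.raises(IndexError):
            per_column_predict(model, raw, raw.length + 1)

    def test_error_std_shape(self, surrogate_setup):
        msa, raw, stack = surrogate_setup
        model, _ = fit_on_msa(msa, stack, rng=np.random.default_rng(0))
        stds = error_std_by_column(model, raw, distance_matrix(msa))
        assert stds.shape == (raw.length + 1,)
        assert np.all(stds >= 0)


def test_attention_h5_round_trip(tmp_path, rng):
    t = row_stochastic(rng, (2, 3, 4, 5, 5))
    raw = ColumnAttentionSet(t)
    p = tmp_path / "attn.h5"
    save_attentions(raw, p)
    back = load_attentions(p)
    assert np.allclose(back.tensor, t)

    model = FractionalLogitModel(intercept=0.4, coef=rng.standard_normal(6),
                                 n_layers=2, n_heads=3)
    mp = tmp_path / "model.h5"
    save_logit_model(model, mp)
    back_m = load_logit_model(mp)
    assert back_m.intercept == pytest.approx(0.4)
    assert np.allclose(back_m.coef, model.coef)
    assert back_m.n_layers == 2
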