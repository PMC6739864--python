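"""Linear and optimal decoder tests against closed forms and dense oracles."""

import numpy as np
import pytest
from scipy import stats

from untangling import (
    FRNL,
    GenerativeModel,
    TrainOptions,
    decode_linear,
    ilc_posterior,
    optimal_posterior,
    performance,
    predicted_linear_fc,
    train_linear_decoder,
)
from untangling.decoders import LinearDecoder

from oracles import dense_posterior, ilc_posterior_direct


def test_separable_clouds_reach_perfect_fc(rng):
    X = np.vstack([rng.normal(0, 0.3, (50, 2)), rng.normal(5, 0.3, (50, 2))])
    y = np.repeat([0, 1], 50)
    dec = train_linear_decoder(X, 2, y)
    Xt = np.vstack([rng.normal(0, 0.3, (50, 2)), rng.normal(5, 0.3, (50, 2))])
    _, hard = decode_linear(dec, Xt)
    assert performance(hard, y).fraction_correct == 1.0


def test_gaussian_discrimination_matches_bayes_rate(rng):
    """Two 1-D unit-variance Gaussians at +-1: the linear decoder should hit
    the closed-form Bayes rate Phi(1) ~ 0.841 within 2 SE."""
    m = 20_000
    X = np.concatenate([rng.normal(-1, 1, m), rng.normal(1, 1, m)])[:, None]
    y = np.repeat([0, 1], m)
    dec = train_linear_decoder(X, 2, y)
    Xt = np.concatenate([rng.normal(-1, 1, m), rng.normal(1, 1, m)])[:, None]
    _, hard = decode_linear(dec, Xt)
    fc = performance(hard, y).fraction_correct
    bayes = stats.norm.cdf(1.0)
    se = np.sqrt(bayes * (1 - bayes) / (2 * m))
    assert abs(fc - bayes) < 2 * se + 0.002


def test_bb_training_matches_sklearn(rng):
    """The Barzilai-Borwein fit reaches the same optimum as an independent
    convex solver (cross-entropy within 1e-4, identical FC)."""
    from sklearn.linear_model import LogisticRegression

    X = rng.normal(size=(600, 8))
    w_true = rng.normal(size=(3, 8))
    y = (X @ w_true.T + rng.normal(scale=0.5, size=(600, 3))).argmax(axis=1)
    dec = train_linear_decoder(X, 3, y, opts=TrainOptions(max_iter=800, tol=1e-12))
    P, hard = decode_linear(dec, X)
    ce_bb = -np.mean(np.log(P[np.arange(600), y]))
    clf = LogisticRegression(penalty=None, solver="lbfgs", max_iter=2000, tol=1e-10)
    clf.fit(X, y)
    ce_sk = -np.mean(np.log(clf.predict_proba(X)[np.arange(600), y]))
    assert ce_bb <= ce_sk + 1e-4
    assert np.mean(hard == y) == pytest.approx(clf.score(X, y), abs=5e-3)


def test_decode_linear_basics(rng):
    dec = LinearDecoder(
        weights=np.zeros((4, 6)), feature_mean=np.zeros(5), feature_scale=np.ones(5)
    )
    P, hard = decode_linear(dec, rng.normal(size=(7, 5)))
    assert np.allclose(P, 0.25)
    assert np.all(hard == 0)  # ties break to the lowest class index
    assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
    with pytest.raises(ValueError):
        decode_linear(dec, rng.normal(size=(3, 4)))


def test_neuron_permutation_invariance(mini_pipeline, rng):
    pop, spec, noise, train, test, grid, _ = mini_pipeline
    perm = rng.permutation(train.values.shape[1])
    dec_a = train_linear_decoder(train.values, spec.n_classes, train.labels)
    dec_b = train_linear_decoder(train.values[:, perm], spec.n_classes, train.labels)
    _, hard_a = decode_linear(dec_a, test.values)
    _, hard_b = decode_linear(dec_b, test.values[:, perm])
    assert np.mean(hard_a == test.labels) == pytest.approx(np.mean(hard_b == test.labels))


# ---------------------------------------------------------------------------
# optimal decoder
# ---------------------------------------------------------------------------

def _toy_model(kappa=1.0, u_th=-58.0, sigma=2.0):
    # 2 neurons, K=2 classes x J=2 phases
    grid_means = np.array(
        [[-60.0, -55.0], [-56.0, -59.0], [-54.0, -61.0], [-59.0, -57.0]]
    )
    labels = np.array([0, 0, 1, 1])
    frnl = FRNL(u_th, kappa, 16.7)
    model = GenerativeModel(grid_means, labels, sigma, frnl,
                            grid_orientations=np.array([10.0, 10.0, 100.0, 100.0]))
    return model, frnl


@pytest.mark.parametrize("kappa", [1.0, 1.5, 2.0])
def test_optimal_posterior_matches_dense_oracle(kappa, rng):
    model, frnl = _toy_model(kappa=kappa)
    for _ in range(10):
        u = rng.normal(-57, 3, size=2)
        r = 16.7 * np.maximum(u - frnl.threshold, 0.0) ** kappa
        got = optimal_posterior(r[None, :], model)[0]
        want = dense_posterior(
            r, model.grid_means, model.grid_labels, 2.0, frnl.threshold, kappa, 16.7, 2
        )
        assert np.allclose(got, want, atol=1e-6)


def test_optimal_posterior_trivial_cases():
    model, _ = _toy_model()
    empty = GenerativeModel(np.empty((4, 0)), model.grid_labels, 2.0, model.frnl)
    post = optimal_posterior(np.empty((3, 0)), empty)
    assert np.allclose(post, 0.5)
    # all-zero rates with identical subthreshold mass across classes
    sym = GenerativeModel(
        np.array([[-70.0, -70.0], [-70.0, -70.0]]), np.array([0, 1]), 2.0, model.frnl
    )
    post = optimal_posterior(np.zeros((1, 2)), sym)
    assert np.allclose(post, 0.5, atol=1e-12)


def test_optimal_posterior_rejects_kappa_below_one():
    model, _ = _toy_model()
    bad = GenerativeModel(model.grid_means, model.grid_labels, 2.0,
                          FRNL.__new__(FRNL))
    object.__setattr__(bad.frnl, "threshold", -58.0)
    object.__setattr__(bad.frnl, "exponent", 0.5)
    object.__setattr__(bad.frnl, "prefactor", 16.7)
    with pytest.raises(ValueError):
        optimal_posterior(np.ones((1, 2)), bad)


def test_ilc_posterior_limits_and_oracle(rng):
    model, frnl = _toy_model()
    u = rng.normal(-57, 3, size=(4, 2))
    r = 16.7 * np.maximum(u - frnl.threshold, 0.0)
    base = optimal_posterior(r, model)
    tiny = ilc_posterior(r, model, 1e-6)
    assert np.allclose(tiny, base, atol=1e-6)
    wide = ilc_posterior(r, model, 1e5)
    assert np.allclose(wide, 0.5, atol=1e-4)
    mid = ilc_posterior(r, model, 25.0)
    want = ilc_posterior_direct(
        r[0], model.grid_means, model.grid_labels, model.grid_orientations,
        2.0, frnl.threshold, 1.0, 16.7, 2, 25.0,
    )
    assert np.allclose(mid[0], want, atol=1e-8)


# ---------------------------------------------------------------------------
# performance measures
# ---------------------------------------------------------------------------

def test_performance_trivial_posteriors():
    one_hot = np.eye(4)[[0, 1, 2, 3]]
    rep = performance(one_hot, np.arange(4))
    assert rep.fraction_correct == 1.0
    assert rep.pfc == pytest.approx(1.0)
    assert rep.mutual_information_bits == pytest.approx(2.0)
    uni = np.full((8, 10), 0.1)
    rep = performance(uni, np.zeros(8, dtype=int))
    assert rep.pfc == pytest.approx(0.1)
    assert rep.mutual_information_bits == pytest.approx(0.0, abs=1e-12)
    assert rep.fraction_correct == 1.0  # argmax ties to class 0


def test_log_pfc_equals_monte_carlo_average(rng):
    """log PFC must equal the mean log posterior on true classes exactly."""
    post = rng.dirichlet(np.ones(5), size=40)
    labels = rng.integers(0, 5, size=40)
    rep = performance(post, labels)
    direct = np.mean(np.log(post[np.arange(40), labels]))
    assert np.log(rep.pfc) == pytest.approx(direct, abs=1e-12)
    assert rep.mutual_information_bits == pytest.approx(
        np.log2(5) + direct / np.log(2), abs=1e-12
    )


def test_zero_posterior_floored_and_flagged():
    post = np.array([[1.0, 0.0], [0.5, 0.5]])
    rep = performance(post, np.array([1, 0]))
    assert rep.n_floored == 1
    assert rep.pfc > 0.0


def test_predicted_linear_fc_endpoints():
    assert predicted_linear_fc(0.8, 0.0, 0.1) == pytest.approx(0.1)
    assert predicted_linear_fc(0.1, 0.7, 0.1) == pytest.approx(0.1)
    assert predicted_linear_fc(1.0, 1.0, 0.1) == pytest.approx(1.0)


def test_circular_class_error():
    perfect = performance(np.arange(4), np.arange(4), n_classes=4, class_period_deg=180.0)
    assert perfect.circular_error_deg == 0.0
    # K=4, period 180: adjacent-class error is 45 deg, opposite is 90 deg
    rep = performance(np.array([1, 2]), np.array([0, 0]), n_classes=4, class_period_deg=180.0)
    assert rep.circular_error_deg == pytest.approx((45.0 + 90.0) / 2)
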