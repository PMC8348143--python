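import numpy as np
import pytest

from broadcall import (ConfigurationError, DegenerateDataError, GaussianEmission,
                       NBEmission, PeakHMM, fit_baum_welch, init_model,
                       label_states, load_model, peak_state, posterior_decode,
                       save_model, viterbi_decode)
from broadcall.hmm import forward_backward

from conftest import (brute_force_posteriors, brute_force_viterbi, make_cov,
                      random_hmm_params, sample_gaussian_hmm, sample_nb_hmm)


# ---------------------------------------------------------------------------
# initialization


def test_init_means_are_data_quantiles():
    data = make_cov(np.arange(101.0))
    model = init_model(data, "gaussian")
    np.testing.assert_allclose(model.emissions.means[:, 0], [0.0, 50.0, 99.0])
    np.testing.assert_allclose(model.startprob, 1 / 3)
    np.testing.assert_allclose(model.transmat, 1 / 3)


def test_init_nb_moment_formulas():
    """Median 2, variance 4 -> middle state gets p = 2/4 = 0.5, r = 4/2 = 2."""
    data = make_cov([0, 0, 0, 2, 2, 2, 4, 6], mode="sum")
    model = init_model(data, "nb")
    assert model.emissions.p[1, 0] == pytest.approx(0.5)
    assert model.emissions.r[1, 0] == pytest.approx(2.0)


def test_init_nb_underdispersed_data_stays_valid():
    """Variance <= mean is floored so r stays positive and finite."""
    data = make_cov([5, 5, 5, 5, 6, 4, 5, 5], mode="sum")
    model = init_model(data, "nb")
    assert np.isfinite(model.emissions.r).all() and (model.emissions.r > 0).all()
    assert ((model.emissions.p > 0) & (model.emissions.p < 1)).all()


def test_init_rejects_bad_inputs():
    with pytest.raises(DegenerateDataError):
        init_model(make_cov([2.0, 2.0, 2.0]), "gaussian")
    with pytest.raises(ConfigurationError):
        init_model(make_cov([1.0, 2.0]), "gaussian", user_means=np.zeros((2, 1)))
    with pytest.raises(ConfigurationError):
        init_model(make_cov([1.0, 2.0], mode="mean"), "nb")


@pytest.mark.parametrize("ctype", ["diagonal", "full", "spherical", "tied"])
def test_init_covariance_types(ctype, rng):
    data = make_cov(rng.normal(5, 2, size=200))
    model = init_model(data, "gaussian", covariance_type=ctype)
    for j in range(3):
        cov = model.emissions.state_cov(j)
        assert cov.shape == (1, 1) and cov[0, 0] > 0


# ---------------------------------------------------------------------------
# decoding vs exhaustive enumeration


def _random_gaussian_model(rng):
    start, trans = random_hmm_params(rng)
    means = np.sort(rng.uniform(0, 10, 3))[:, None]
    covars = rng.uniform(0.3, 2.0, (3, 1))
    return PeakHMM(startprob=start, transmat=trans,
                   emissions=GaussianEmission(means=means, covars=covars))


def _random_nb_model(rng):
    start, trans = random_hmm_params(rng)
    return PeakHMM(startprob=start, transmat=trans,
                   emissions=NBEmission(p=rng.uniform(0.2, 0.8, (3, 1)),
                                        r=rng.uniform(0.5, 10, (3, 1))))


@pytest.mark.parametrize("family", ["gaussian", "nb"])
@pytest.mark.parametrize("T", [1, 2, 5, 8])
def test_decoding_matches_enumeration(family, T, rng):
    """Viterbi path and posteriors agree with brute force over all 3^T paths."""
    for _ in range(4):
        if family == "gaussian":
            model = _random_gaussian_model(rng)
            obs = rng.uniform(0, 10, T)
            data = make_cov(obs)
        else:
            model = _random_nb_model(rng)
            obs = rng.integers(0, 20, T).astype(float)
            data = make_cov(obs, mode="sum")
        frames = model.emissions.log_density(data.values)
        np.testing.assert_array_equal(
            viterbi_decode(model, data),
            brute_force_viterbi(model.startprob, model.transmat, frames))
        np.testing.assert_allclose(
            posterior_decode(model, data),
            brute_force_posteriors(model.startprob, model.transmat, frames),
            atol=1e-9)


def test_single_window_viterbi_is_argmax(rng):
    model = _random_gaussian_model(rng)
    data = make_cov([4.2])
    expected = np.argmax(np.log(model.startprob)
                         + model.emissions.log_density(data.values)[0])
    assert viterbi_decode(model, data)[0] == expected


def test_separable_emissions_recover_range_labels():
    """States emitting disjoint value ranges decode to the matching labels."""
    model = PeakHMM(startprob=np.full(3, 1 / 3), transmat=np.full((3, 3), 1 / 3),
                    emissions=GaussianEmission(means=[[0.0], [10.0], [100.0]],
                                               covars=np.full((3, 1), 0.25)))
    data = make_cov([0.1, 10.3, 99.5, 0.2, 9.8])
    np.testing.assert_array_equal(viterbi_decode(model, data), [0, 1, 2, 0, 1])


def test_symmetric_model_gives_uniform_posteriors():
    model = PeakHMM(startprob=np.full(3, 1 / 3), transmat=np.full((3, 3), 1 / 3),
                    emissions=GaussianEmission(means=[[5.0]] * 3,
                                               covars=np.ones((3, 1))))
    post = posterior_decode(model, make_cov([1.0, 5.0, 9.0]))
    np.testing.assert_allclose(post, 1 / 3)


def test_posterior_rows_on_simplex(rng):
    for _ in range(5):
        model = _random_gaussian_model(rng)
        post = posterior_decode(model, make_cov(rng.uniform(0, 10, 50)))
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)
        assert ((post >= 0) & (post <= 1)).all()


def test_decoding_is_per_chromosome(rng):
    """Sequences on different chromosomes are decoded independently."""
    model = _random_gaussian_model(rng)
    from broadcall import CoverageMatrix, make_windows
    w2 = make_windows({"c1": 3200, "c2": 2400}, 800)
    vals = rng.uniform(0, 10, 7)
    data2 = CoverageMatrix(windows=w2, values=vals, mode="mean")
    part1 = make_cov(vals[:4], chrom="c1")
    part2 = make_cov(vals[4:], chrom="c2")
    joint = viterbi_decode(model, data2)
    np.testing.assert_array_equal(joint[:4], viterbi_decode(model, part1))
    np.testing.assert_array_equal(joint[4:], viterbi_decode(model, part2))


# ---------------------------------------------------------------------------
# training


def test_em_loglik_monotone_gaussian(rng):
    obs, _ = sample_gaussian_hmm(rng, 400)
    data = make_cov(obs)
    model = init_model(data, "gaussian")
    _, trace = fit_baum_welch(model, data, tol=0.0, max_iter=15)
    diffs = np.diff(trace)
    assert (diffs >= -1e-8).all(), f"log-likelihood decreased: {diffs.min()}"


def test_one_iteration_does_not_decrease_loglik(rng):
    data = make_cov(rng.uniform(0, 10, 120))
    model = init_model(data, "gaussian")
    _, trace = fit_baum_welch(model, data, tol=0.0, max_iter=2)
    assert trace[1] >= trace[0] - 1e-8


def test_max_iter_zero_returns_initial_model(rng):
    data = make_cov(rng.uniform(0, 10, 50))
    model = init_model(data, "gaussian")
    fitted, trace = fit_baum_welch(model, data, max_iter=0)
    assert trace == []
    np.testing.assert_array_equal(fitted.emissions.means, model.emissions.means)


def test_transition_rows_stay_on_simplex(rng):
    obs, _ = sample_gaussian_hmm(rng, 300)
    data = make_cov(obs)
    model, _ = fit_baum_welch(init_model(data, "gaussian"), data, tol=0.0, max_iter=10)
    np.testing.assert_allclose(model.transmat.sum(axis=1), 1.0, atol=1e-9)
    np.testing.assert_allclose(model.startprob.sum(), 1.0, atol=1e-9)


def test_gaussian_parameter_recovery(rng):
    """Well-separated simulated states are recovered within 0.2 at T=5000."""
    truth = (0.0, 2.0, 10.0)
    obs, _ = sample_gaussian_hmm(rng, 5000, means=truth)
    data = make_cov(obs)
    model, _ = fit_baum_welch(init_model(data, "gaussian"), data, max_iter=100)
    recovered = np.sort(model.emissions.means[:, 0])
    np.testing.assert_allclose(recovered, truth, atol=0.2)


def test_nb_parameter_recovery(rng):
    """NB state means r(1-p)/p recovered within 15% at T=5000."""
    rs, ps = (1.0, 5.0, 20.0), (0.5, 0.5, 0.5)
    truth_means = np.array(rs) * (1 - np.array(ps)) / np.array(ps)
    obs, _ = sample_nb_hmm(rng, 5000, rs=rs, ps=ps)
    data = make_cov(obs, mode="sum")
    model, _ = fit_baum_welch(init_model(data, "nb"), data, max_iter=60)
    recovered = np.sort(model.emissions.means()[:, 0])
    np.testing.assert_allclose(recovered, truth_means, rtol=0.15)


def test_loglik_matches_hmmlearn(rng):
    """Independent check: scaled forward pass reproduces hmmlearn's score."""
    hmmlearn_hmm = pytest.importorskip("hmmlearn.hmm")
    start, trans = random_hmm_params(rng)
    means = np.array([[0.0], [3.0], [8.0]])
    variances = np.array([[0.5], [1.0], [2.0]])
    ref = hmmlearn_hmm.GaussianHMM(n_components=3, covariance_type="diag",
                                   init_params="")
    ref.startprob_, ref.transmat_ = start, trans
    ref.means_, ref.covars_ = means, variances
    obs = rng.uniform(0, 10, (80, 1))
    model = PeakHMM(startprob=start, transmat=trans,
                    emissions=GaussianEmission(means=means, covars=variances))
    frames = model.emissions.log_density(obs)
    _, _, ll = forward_backward(start, trans, frames)
    assert ll == pytest.approx(ref.score(obs), abs=1e-8)


# ---------------------------------------------------------------------------
# labelling and persistence


def test_label_states_by_mean():
    model = PeakHMM(startprob=np.full(3, 1 / 3), transmat=np.full((3, 3), 1 / 3),
                    emissions=GaussianEmission(means=[[0.0], [3.0], [10.0]],
                                               covars=np.ones((3, 1))))
    assert label_states(model) == ("no_signal", "background", "peak")


def test_label_states_nb_and_permutation():
    em = NBEmission(p=np.full((3, 1), 0.5), r=np.array([[20.0], [2.0], [8.0]]))
    model = PeakHMM(startprob=np.full(3, 1 / 3), transmat=np.full((3, 3), 1 / 3),
                    emissions=em)
    # means 20, 2, 8 -> state 0 is peak, state 1 no_signal, state 2 background
    assert label_states(model) == ("peak", "no_signal", "background")
    assert peak_state(model) == 0


def test_model_roundtrip(tmp_path, rng):
    for make in (lambda: init_model(make_cov(rng.uniform(0, 10, 60)), "gaussian"),
                 lambda: init_model(make_cov(rng.integers(0, 30, 60).astype(float),
                                             mode="sum"), "nb")):
        model = make()
        model.state_labels = label_states(model)
        path = tmp_path / "model.txt"
        save_model(model, str(path))
        loaded = load_model(str(path))
        np.testing.assert_allclose(loaded.transmat, model.transmat)
        assert loaded.distribution == model.distribution
        assert loaded.state_labels == model.state_labels
        np.testing.assert_allclose(loaded.emission_means(), model.emission_means())
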