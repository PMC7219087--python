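"""Two-component EM fit, posteriors, and bona fide calls."""

import numpy as np
import pandas as pd
import pytest

from promotif.mixture import (
    BonaFideCalls,
    MixtureModel,
    call_bona_fide,
    component_posterior,
    fit_two_component_em,
)
from promotif.scan import ScoreTable
from promotif.simulate import simulate_mixture_scores

from oracles import mixture_loglik_direct, posterior_direct

TRUTH = {"pi": (0.7, 0.3), "mu": (0.55, 0.85), "sigma": (0.06, 0.06)}


def _model(mu_low, mu_high, sigma_low, sigma_high, pi_low=0.5):
    return MixtureModel(
        motif_id="M", mu_low=mu_low, mu_high=mu_high,
        sigma_low=sigma_low, sigma_high=sigma_high,
        pi_low=pi_low, pi_high=1 - pi_low,
        log_likelihood=0.0, n_iter=1, converged=True, n_points=100,
    )


def _table_from_scores(scores, motif_id="M"):
    genes = [f"g{i}" for i in range(len(scores))]
    hits = pd.DataFrame(
        {
            "gene_id": genes, "motif_id": motif_id,
            "raw_score": scores, "norm_score": scores,
            "offset": 0, "strand": "+",
        }
    )
    return ScoreTable(hits=hits, universe_ids=genes, widths={motif_id: 10})


def test_separated_point_masses_recovered():
    scores = [0.2] * 100 + [0.8] * 100
    m = fit_two_component_em(scores, seed=0)
    assert m.mu_low == pytest.approx(0.2, abs=1e-6)
    assert m.mu_high == pytest.approx(0.8, abs=1e-6)
    assert m.pi_low == pytest.approx(0.5, abs=1e-6)
    # sigmas pinned at the variance floor, not zero
    assert m.sigma_low > 0 and m.sigma_high > 0


def test_parameter_recovery_on_simulated_mixture():
    x = simulate_mixture_scores(
        TRUTH["pi"], TRUTH["mu"], TRUTH["sigma"], 5000, seed=20240901
    )
    m = fit_two_component_em(x, seed=0)
    assert m.converged
    assert m.mu_low == pytest.approx(0.55, abs=0.01)
    assert m.mu_high == pytest.approx(0.85, abs=0.01)
    assert m.pi_low == pytest.approx(0.7, abs=0.03)


def test_loglikelihood_nondecreasing_and_matches_direct_evaluation():
    rng = np.random.default_rng(101)
    for trial in range(10):
        x = simulate_mixture_scores(
            (0.6, 0.4), (0.4, 0.8), (0.08, 0.05), 400,
            seed=int(rng.integers(2**31)),
        )
        m = fit_two_component_em(x, seed=0)
        trace = np.asarray(m.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-9)
        assert m.log_likelihood == pytest.approx(
            mixture_loglik_direct(x, m), abs=1e-8 * len(x)
        )


def test_errors_on_degenerate_input():
    with pytest.raises(ValueError, match="10"):
        fit_two_component_em([0.1] * 5)
    with pytest.raises(ValueError, match="spread"):
        fit_two_component_em([0.3] * 50)
    with pytest.raises(ValueError, match="seed"):
        fit_two_component_em(np.linspace(0, 1, 50), n_restarts=3)


def test_nonconvergence_warns():
    x = simulate_mixture_scores((0.5, 0.5), (0.3, 0.7), (0.1, 0.1), 500, seed=4)
    with pytest.warns(RuntimeWarning, match="converge"):
        m = fit_two_component_em(x, max_iter=2, seed=0)
    assert not m.converged


def test_restarts_keep_best_likelihood_and_ordered_labels():
    x = simulate_mixture_scores((0.4, 0.6), (0.35, 0.75), (0.05, 0.05),
                                800, seed=9)
    base = fit_two_component_em(x, seed=0)
    restarted = fit_two_component_em(x, n_restarts=5, seed=13)
    assert restarted.log_likelihood >= base.log_likelihood - 1e-9
    assert restarted.mu_low <= restarted.mu_high


def test_shift_scale_equivariance():
    x = simulate_mixture_scores(TRUTH["pi"], TRUTH["mu"], TRUTH["sigma"],
                                2000, seed=7)
    a, b = 3.0, -1.0
    m1 = fit_two_component_em(x, seed=0, motif_id="M")
    m2 = fit_two_component_em(a * x + b, seed=0, motif_id="M")
    assert m2.mu_low == pytest.approx(a * m1.mu_low + b, abs=1e-5)
    assert m2.mu_high == pytest.approx(a * m1.mu_high + b, abs=1e-5)
    assert m2.sigma_low == pytest.approx(a * m1.sigma_low, rel=1e-4)
    assert m2.pi_low == pytest.approx(m1.pi_low, abs=1e-6)
    # identical calls either way
    t1 = _table_from_scores(x)
    t2 = _table_from_scores(a * x + b)
    c1 = call_bona_fide(m1, t1)
    c2 = call_bona_fide(m2, t2)
    assert c1.called == c2.called


def test_cross_check_against_sklearn():
    from sklearn.mixture import GaussianMixture

    x = simulate_mixture_scores(TRUTH["pi"], TRUTH["mu"], TRUTH["sigma"],
                                3000, seed=33)
    ours = fit_two_component_em(x, seed=0)
    gm = GaussianMixture(2, covariance_type="spherical", tol=1e-8,
                         max_iter=500, random_state=0).fit(x[:, None])
    order = np.argsort(gm.means_.ravel())
    sk_mu = gm.means_.ravel()[order]
    sk_pi = gm.weights_[order]
    assert ours.mu_low == pytest.approx(sk_mu[0], abs=5e-3)
    assert ours.mu_high == pytest.approx(sk_mu[1], abs=5e-3)
    assert ours.pi_low == pytest.approx(sk_pi[0], abs=0.02)


# ---- posteriors and calls -------------------------------------------------


def test_posterior_half_at_midpoint_of_symmetric_model():
    m = _model(0.3, 0.7, 0.1, 0.1)
    assert component_posterior(m, 0.5) == pytest.approx(0.5, abs=1e-12)


def test_posterior_tends_to_one_far_above_high_mean():
    m = _model(0.3, 0.7, 0.1, 0.1)
    assert component_posterior(m, 3.0) == pytest.approx(1.0, abs=1e-9)
    assert component_posterior(m, -3.0) == pytest.approx(0.0, abs=1e-9)


def test_posterior_matches_closed_form_bayes_ratio():
    m = _model(0.35, 0.8, 0.07, 0.12, pi_low=0.65)
    for s in (0.2, 0.5, 0.62, 0.75, 0.9):
        assert component_posterior(m, s) == pytest.approx(
            posterior_direct(m, s), abs=1e-12
        )


def test_calls_shrink_monotonically_with_confidence():
    x = simulate_mixture_scores(TRUTH["pi"], TRUTH["mu"], TRUTH["sigma"],
                                2000, seed=3)
    m = fit_two_component_em(x, seed=0, motif_id="M")
    table = _table_from_scores(x)
    sizes = [
        call_bona_fide(m, table, confidence=c).K
        for c in (0.5, 0.8, 0.95, 0.99, 0.9999)
    ]
    assert sizes == sorted(sizes, reverse=True)


def test_symmetric_model_all_scores_at_midpoint_calls_nothing():
    m = _model(0.3, 0.7, 0.1, 0.1)
    table = _table_from_scores(np.full(50, 0.5))
    calls = call_bona_fide(m, table)
    assert calls.K == 0


def test_equal_sigma_calls_are_upper_score_set_with_bisection_threshold():
    x = simulate_mixture_scores(TRUTH["pi"], TRUTH["mu"], TRUTH["sigma"],
                                3000, seed=15)
    m = fit_two_component_em(x, seed=0, motif_id="M")
    # symmetrise sigmas so the posterior is strictly monotone
    sig = (m.sigma_low + m.sigma_high) / 2
    m_eq = _model(m.mu_low, m.mu_high, sig, sig, pi_low=m.pi_low)
    table = _table_from_scores(x)
    calls = call_bona_fide(m_eq, table)
    assert calls.monotone and calls.threshold is not None
    # independent bisection on the posterior
    lo, hi = m_eq.mu_low, m_eq.mu_high + 10 * sig
    for _ in range(200):
        mid = (lo + hi) / 2
        if component_posterior(m_eq, mid) > 0.95:
            hi = mid
        else:
            lo = mid
    t_star = (lo + hi) / 2
    expected = {f"g{i}" for i in np.nonzero(x > t_star)[0]}
    assert calls.called == expected
    assert calls.threshold == pytest.approx(t_star, abs=1e-6)


def test_collapsed_mixture_rejected():
    m = _model(0.5, 0.5, 0.1, 0.1)
    with pytest.raises(ValueError, match="collapsed"):
        call_bona_fide(m, _table_from_scores(np.linspace(0, 1, 30)))


def test_confidence_bounds_validated():
    m = _model(0.3, 0.7, 0.1, 0.1)
    table = _table_from_scores(np.linspace(0, 1, 30))
    with pytest.raises(ValueError, match="confidence"):
        call_bona_fide(m, table, confidence=1.0)


def test_missing_scores_never_called():
    m = _model(0.3, 0.7, 0.1, 0.1)
    table = _table_from_scores(np.linspace(0, 1, 30))
    table.universe_ids = table.universe_ids + ["unscored"]
    calls = call_bona_fide(m, table)
    assert "unscored" not in calls.called
    assert calls.K <= table.n_universe
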