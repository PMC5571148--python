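"""Species filtering, all-subsets enumeration, logistic fitting closed
forms, Akaike-weight averaging, prediction, and ROC AUC."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from evdkit.sdm import (
    ABSENT,
    LINEAR,
    QUADRATIC,
    AveragedSDM,
    CandidateModel,
    FitError,
    auc,
    average_models,
    design_matrix,
    enumerate_models,
    filter_species,
    fit_logistic,
    fit_species_sdm,
    predict_matrix,
    predict_occurrence,
)

# -----------------------------------------------------------------------------
# species filtering


def test_filter_species_threshold_is_inclusive():
    rng = np.random.default_rng(0)
    occ = pd.DataFrame(
        {
            "rare": [1] * 19 + [0] * 81,
            "exact": [1] * 20 + [0] * 80,
            "common": rng.integers(0, 2, 100),
        }
    )
    kept = filter_species(occ, 20)
    assert "rare" not in kept
    assert "exact" in kept
    assert filter_species(occ, 0) == ["rare", "exact", "common"]


def test_filter_species_respects_universe_and_counts():
    rng = np.random.default_rng(1)
    prevalences = {"a": 5, "b": 25, "c": 40, "d": 18}
    cols = {}
    for name, k in prevalences.items():
        v = np.zeros(60, dtype=int)
        v[rng.choice(60, size=k, replace=False)] = 1
        cols[name] = v
    occ = pd.DataFrame(cols)
    assert filter_species(occ, 20) == ["b", "c"]
    assert filter_species(occ, 20, species_universe=["c"]) == ["c"]
    with pytest.raises(FitError):
        filter_species(occ, 50)


# -----------------------------------------------------------------------------
# enumeration


@pytest.mark.parametrize("p", [1, 2, 3, 8])
def test_enumeration_count_and_constraint(p):
    terms = list(enumerate_models([f"v{i}" for i in range(p)]))
    assert len(terms) == 3**p
    assert len(set(terms)) == 3**p
    assert (ABSENT,) * p in terms  # the intercept-only model is included
    # states are only {absent, linear, linear+quadratic}: a quadratic term
    # without its linear companion is unrepresentable, audit all the same
    for t in terms:
        assert all(s in (ABSENT, LINEAR, QUADRATIC) for s in t)


def test_design_matrix_columns_follow_term_states():
    Z = np.array([[1.0, 2.0], [3.0, 4.0]])
    X = design_matrix(Z, (QUADRATIC, LINEAR))
    expected = np.array([[1.0, 1.0, 1.0, 2.0], [1.0, 3.0, 9.0, 4.0]])
    assert np.allclose(X, expected)


# -----------------------------------------------------------------------------
# logistic fitting closed forms


def test_intercept_only_fit_is_log_odds_of_prevalence():
    y = np.array([1.0] * 30 + [0.0] * 70)
    Z = np.zeros((100, 1))
    m = fit_logistic(y, Z, (ABSENT,))
    assert m.intercept == pytest.approx(np.log(30 / 70), abs=1e-8)
    ll = 30 * np.log(0.3) + 70 * np.log(0.7)
    assert m.log_likelihood == pytest.approx(ll, abs=1e-8)
    assert m.aic == pytest.approx(2 * 1 - 2 * ll, abs=1e-8)
    assert m.k == 1


def test_single_binary_predictor_recovers_log_odds_ratio():
    # 2x2 table: a=12 (x=1,y=1), b=8 (x=1,y=0), c=5 (x=0,y=1), d=25 (x=0,y=0)
    a, b, c, d = 12, 8, 5, 25
    x = np.array([1.0] * (a + b) + [0.0] * (c + d))
    y = np.array([1.0] * a + [0.0] * b + [1.0] * c + [0.0] * d)
    m = fit_logistic(y, x.reshape(-1, 1), (LINEAR,))
    assert m.linear[0] == pytest.approx(np.log(a * d / (b * c)), abs=1e-6)
    assert m.intercept == pytest.approx(np.log(c / d), abs=1e-6)


def test_degenerate_response_raises():
    Z = np.zeros((10, 1))
    with pytest.raises(FitError):
        fit_logistic(np.ones(10), Z, (ABSENT,))
    with pytest.raises(FitError):
        fit_logistic(np.zeros(10), Z, (ABSENT,))


# -----------------------------------------------------------------------------
# model averaging


def _candidate(terms, intercept, linear, quadratic, aic):
    k = 1 + sum(s >= LINEAR for s in terms) + sum(s == QUADRATIC for s in terms)
    return CandidateModel(
        terms=terms, intercept=intercept, linear=linear, quadratic=quadratic,
        log_likelihood=(2 * k - aic) / 2, k=k, aic=aic, converged=True,
    )


def test_equal_aic_candidates_average_half_half():
    c1 = _candidate((LINEAR,), 1.0, (2.0,), (0.0,), aic=10.0)
    c2 = _candidate((ABSENT,), 3.0, (0.0,), (0.0,), aic=10.0)
    avg = average_models([c1, c2], 2.0, "sp", ["v"], n_presences=5, n_sites=10)
    assert avg.intercept == pytest.approx(2.0)
    assert avg.linear["v"] == pytest.approx(1.0)  # absent term averaged as zero
    assert avg.n_models_averaged == 2


def test_single_model_in_confidence_set_is_identity():
    c1 = _candidate((QUADRATIC,), 0.5, (1.5,), (-0.7,), aic=10.0)
    c2 = _candidate((ABSENT,), 3.0, (0.0,), (0.0,), aic=20.0)
    avg = average_models([c1, c2], 2.0, "sp", ["v"], n_presences=5, n_sites=10)
    assert avg.n_models_averaged == 1
    assert avg.intercept == pytest.approx(0.5)
    assert avg.linear["v"] == pytest.approx(1.5)
    assert avg.quadratic["v"] == pytest.approx(-0.7)


def test_akaike_weights_match_hand_computed_average():
    # deltas 0, 1, 2 -> weights prop. to 1, e^-0.5, e^-1
    c0 = _candidate((LINEAR,), 0.0, (1.0,), (0.0,), aic=100.0)
    c1 = _candidate((ABSENT,), 0.0, (0.0,), (0.0,), aic=101.0)
    c2 = _candidate((QUADRATIC,), 0.0, (3.0,), (-1.0,), aic=102.0)
    w = np.array([1.0, np.exp(-0.5), np.exp(-1.0)])
    w = w / w.sum()
    avg = average_models([c0, c1, c2], 2.0, "sp", ["v"], n_presences=5, n_sites=10)
    assert avg.n_models_averaged == 3
    assert avg.linear["v"] == pytest.approx(w[0] * 1.0 + w[1] * 0.0 + w[2] * 3.0, abs=1e-12)
    assert avg.quadratic["v"] == pytest.approx(w[2] * -1.0, abs=1e-12)
    assert avg.best_aic == 100.0


def test_separated_candidates_are_excluded():
    good = _candidate((ABSENT,), 0.5, (0.0,), (0.0,), aic=50.0)
    separated = _candidate((LINEAR,), 0.0, (40.0,), (0.0,), aic=10.0)
    avg = average_models([good, separated], 2.0, "sp", ["v"], n_presences=5, n_sites=10)
    assert avg.n_models_averaged == 1
    assert avg.n_candidates_excluded == 1
    assert avg.intercept == pytest.approx(0.5)


# -----------------------------------------------------------------------------
# prediction


def test_prediction_limits_and_niche_maximum():
    flat = AveragedSDM(
        species="f", predictors=("s",), intercept=0.0, linear={"s": 0.0},
        quadratic={"s": 0.0}, n_models_averaged=1, best_aic=0.0, auc=0.5,
        n_presences=1, n_sites=2,
    )
    assert predict_occurrence(flat, [0.0]) == pytest.approx(0.5)
    mono = AveragedSDM(
        species="m", predictors=("s",), intercept=0.0, linear={"s": 1.0},
        quadratic={"s": 0.0}, n_models_averaged=1, best_aic=0.0, auc=0.5,
        n_presences=1, n_sites=2,
    )
    assert predict_occurrence(mono, [0.0]) == pytest.approx(0.5)
    assert predict_occurrence(mono, [40.0]) == pytest.approx(1.0, abs=1e-12)
    niche = AveragedSDM(
        species="n", predictors=("s",), intercept=1.0, linear={"s": 0.0},
        quadratic={"s": -2.0}, n_models_averaged=1, best_aic=0.0, auc=0.5,
        n_presences=1, n_sites=2,
    )
    grid = np.linspace(-3, 3, 601).reshape(-1, 1)
    probs = predict_matrix(niche, grid)
    assert grid[np.argmax(probs), 0] == pytest.approx(0.0, abs=1e-9)
    assert probs.max() == pytest.approx(expit(1.0), abs=1e-12)
    with pytest.raises(FitError, match="missing predictor"):
        predict_occurrence(niche, {"other": 1.0})


# -----------------------------------------------------------------------------
# AUC


def test_auc_examples():
    scores = np.array([0.9, 0.8, 0.4, 0.7, 0.3])
    y = np.array([1, 1, 1, 0, 0])
    assert auc(scores, y) == pytest.approx(5 / 6)
    assert auc(np.array([1.0, 1.0, 0.0, 0.0]), np.array([1, 1, 0, 0])) == 1.0
    assert auc(np.full(6, 0.5), np.array([1, 0, 1, 0, 1, 0])) == 0.5
    with pytest.raises(FitError):
        auc(np.array([0.1, 0.2]), np.array([1, 1]))


@pytest.mark.parametrize(
    "transform",
    [lambda s: 2.0 * s + 1.0, np.exp, lambda s: np.tanh(3.0 * s), lambda s: s**3],
    ids=["affine", "exp", "tanh", "cube"],
)
def test_auc_invariant_under_monotone_transforms(transform):
    rng = np.random.default_rng(8)
    scores = rng.normal(size=80)
    y = (rng.random(80) < expit(scores)).astype(int)
    assert auc(transform(scores), y) == pytest.approx(auc(scores, y), abs=1e-12)


# -----------------------------------------------------------------------------
# oracle equivalence: independent likelihood maximizer


def _nll(params, y, X):
    eta = X @ params
    # log(1+exp) stable via logaddexp
    return float(np.sum(np.logaddexp(0.0, eta)) - y @ eta)


def _brute_force_sdm(y, Z, predictors, delta_aic=2.0):
    """All-subsets fit via scipy BFGS on the exact negative log-likelihood,
    followed by Akaike-weight averaging — sharing no fitting code with the
    implementation under test."""
    fits = []
    for terms in itertools.product((ABSENT, LINEAR, QUADRATIC), repeat=len(predictors)):
        X = design_matrix(Z, terms)
        res = minimize(
            _nll, np.zeros(X.shape[1]), args=(y, X), method="BFGS",
            options={"gtol": 1e-10, "maxiter": 500},
        )
        k = X.shape[1]
        aic = 2 * k + 2 * res.fun
        fits.append((terms, res.x, aic))
    best = min(a for *_, a in fits)
    conf = [(t, p, a) for t, p, a in fits if a - best <= delta_aic]
    w = np.exp(-0.5 * (np.array([a for *_, a in conf]) - best))
    w /= w.sum()
    p_dim = len(predictors)
    avg = {"intercept": 0.0, "linear": np.zeros(p_dim), "quadratic": np.zeros(p_dim)}
    best_terms = min(fits, key=lambda f: f[2])[0]
    for wi, (terms, params, _) in zip(w, conf):
        avg["intercept"] += wi * params[0]
        i = 1
        for j, s in enumerate(terms):
            if s >= LINEAR:
                avg["linear"][j] += wi * params[i]
                i += 1
            if s == QUADRATIC:
                avg["quadratic"][j] += wi * params[i]
                i += 1
    return best_terms, avg, best


def test_fitting_matches_brute_force_oracle_two_predictors():
    rng = np.random.default_rng(17)
    n = 300
    Z = rng.normal(size=(n, 2))
    eta = -0.3 + 1.1 * Z[:, 0] - 0.8 * Z[:, 0] ** 2 + 0.5 * Z[:, 1]
    y = (rng.random(n) < expit(eta)).astype(float)

    sdm = fit_species_sdm("sp", y, Z, ["v1", "v2"])
    candidates = [fit_logistic(y, Z, t) for t in enumerate_models(["v1", "v2"])]
    best_terms = min(candidates, key=lambda c: c.aic).terms

    oracle_terms, oracle_avg, oracle_best_aic = _brute_force_sdm(y, Z, ["v1", "v2"])
    assert best_terms == oracle_terms
    assert sdm.best_aic == pytest.approx(oracle_best_aic, abs=1e-6)
    assert sdm.intercept == pytest.approx(oracle_avg["intercept"], abs=1e-6)
    for j, v in enumerate(["v1", "v2"]):
        assert sdm.linear[v] == pytest.approx(oracle_avg["linear"][j], abs=1e-6)
        assert sdm.quadratic[v] == pytest.approx(oracle_avg["quadratic"][j], abs=1e-6)


# -----------------------------------------------------------------------------
# parameter recovery from simulated truth


def test_generating_coefficients_recovered_within_three_se():
    rng = np.random.default_rng(23)
    n = 2000
    Z = rng.normal(size=(n, 2))
    true = np.array([0.4, 1.0, -0.8, -0.6])  # b0, b1, b1', b2
    X = np.column_stack([np.ones(n), Z[:, 0], Z[:, 0] ** 2, Z[:, 1]])
    y = (rng.random(n) < expit(X @ true)).astype(float)

    m = fit_logistic(y, Z, (QUADRATIC, LINEAR))
    est = np.array([m.intercept, m.linear[0], m.quadratic[0], m.linear[1]])
    # observed-information standard errors, computed independently
    p = expit(X @ est)
    W = p * (1 - p)
    cov = np.linalg.inv(X.T @ (W[:, None] * X))
    se = np.sqrt(np.diag(cov))
    assert np.all(np.abs(est - true) < 3 * se)


def test_generating_term_set_lands_in_confidence_set_usually():
    """The true model should sit within two AIC units of the best in the
    vast majority of replicates when effects are strong."""
    true_terms = (QUADRATIC, LINEAR)
    hits = 0
    n_rep = 50
    for rep in range(n_rep):
        rng = np.random.default_rng(1000 + rep)
        n = 800
        Z = rng.normal(size=(n, 2))
        eta = 0.4 + 1.0 * Z[:, 0] - 0.8 * Z[:, 0] ** 2 - 0.6 * Z[:, 1]
        y = (rng.random(n) < expit(eta)).astype(float)
        candidates = [fit_logistic(y, Z, t) for t in enumerate_models(["a", "b"])]
        best = min(c.aic for c in candidates if c.converged)
        conf = {c.terms for c in candidates if c.converged and c.aic - best <= 2.0}
        hits += true_terms in conf
    assert hits >= 0.9 * n_rep
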