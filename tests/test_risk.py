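import itertools

import numpy as np
import pandas as pd
import pytest

from mammotex import risk
from mammotex.risk import (
    ADJUSTMENT_SETS,
    LogisticFitError,
    ScoreModel,
    SelectionConfig,
    TextureRiskModel,
    auc,
    bootstrap_inclusion,
    evaluate,
    finalize_selection,
    fit_logistic,
    fit_score_model,
    match_and_split,
    preselect,
    score_subjects,
    spearman_matrix,
    stepwise_backward_aic,
)


def _sim_logistic(rng, n=400, p=8, beta=None):
    X = rng.normal(size=(n, p))
    if beta is None:
        beta = np.zeros(p)
        beta[:2] = [1.0, -0.8]
    eta = X @ beta
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    return X, y, beta


# ------------------------------------------------------------------ logistic


def test_logistic_matches_statsmodels(rng):
    import statsmodels.api as sm

    X, y, _ = _sim_logistic(rng)
    fit = fit_logistic(X, y)
    ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
    np.testing.assert_allclose(fit.coef, ref.params, atol=1e-5)
    assert fit.loglik == pytest.approx(ref.llf, abs=1e-6)
    assert fit.aic == pytest.approx(ref.aic, abs=1e-5)
    assert fit.converged and not fit.separated
    np.testing.assert_allclose(
        np.sqrt(np.diag(fit.cov)), ref.bse, rtol=1e-3
    )


def test_logistic_intercept_only(rng):
    y = (rng.random(500) < 0.3).astype(float)
    fit = fit_logistic(np.empty((500, 0)), y)
    pbar = y.mean()
    assert fit.coef[0] == pytest.approx(np.log(pbar / (1 - pbar)), abs=1e-6)


def test_logistic_separation_flagged():
    X = np.linspace(-1, 1, 40).reshape(-1, 1)
    y = (X[:, 0] > 0).astype(float)  # perfectly separable
    fit = fit_logistic(X, y)
    assert fit.separated


def test_logistic_aic_definition(rng):
    X, y, _ = _sim_logistic(rng, n=200, p=3)
    fit = fit_logistic(X, y)
    assert fit.aic == pytest.approx(2 * 4 - 2 * fit.loglik)


# ------------------------------------------------------------------ stepwise


def test_stepwise_recovers_true_support(rng):
    X, y, beta = _sim_logistic(rng, n=800, p=10)
    kept = stepwise_backward_aic(X, y, scan="exact")
    assert 0 in kept and 1 in kept  # the two real signals survive
    assert len(kept) <= 6           # most noise removed


def test_stepwise_wald_agrees_with_exact(rng):
    for _ in range(3):
        X, y, _ = _sim_logistic(rng, n=300, p=20)
        assert stepwise_backward_aic(X, y, scan="wald") == stepwise_backward_aic(
            X, y, scan="exact"
        )


def test_stepwise_exact_matches_brute_force_best_subset_path(rng):
    """Each accepted elimination is the AIC-best single removal."""
    X, y, _ = _sim_logistic(rng, n=250, p=6)

    def aic_of(cols):
        return fit_logistic(X[:, cols], y).aic

    current = list(range(6))
    while True:
        base = aic_of(current)
        options = [
            (aic_of([c for c in current if c != j]), j) for j in current
        ]
        best_aic, best_j = min(options)
        if best_aic >= base:
            break
        current.remove(best_j)
    assert stepwise_backward_aic(X, y, scan="exact") == current


def test_stepwise_pure_noise_empties(rng):
    X = rng.normal(size=(300, 8))
    y = (rng.random(300) < 0.5).astype(float)
    kept = stepwise_backward_aic(X, y, scan="exact")
    # AIC admits a noise variable with probability P(chi2 > 2) ~ 16%,
    # so a handful may survive; most must be pruned
    assert len(kept) <= 4


# ------------------------------------------------------------------ matching


def _toy_cohort(n_sets=10, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    sid = 0
    for k in range(n_sets):
        for label in ("case", "case", "control"):
            rows.append(
                {
                    "subject_id": f"S{sid:03d}",
                    "label": label,
                    "matched_set_id": f"set{k}",
                    "age": 50 + rng.normal(),
                }
            )
            sid += 1
    return pd.DataFrame(rows)


def test_match_and_split_keeps_sets_intact():
    co = _toy_cohort(11)
    train, valid = match_and_split(co, seed=0)
    assert (train ^ valid).all()
    for _, grp in co.groupby("matched_set_id"):
        flags = train[grp.index]
        assert flags.all() or (~flags).all()
    # odd set count: extra set on the training side
    n_train_sets = co.loc[train, "matched_set_id"].nunique()
    assert n_train_sets == 6


def test_match_and_split_deterministic_per_seed():
    co = _toy_cohort(10)
    t1, _ = match_and_split(co, seed=3)
    t2, _ = match_and_split(co, seed=3)
    t3, _ = match_and_split(co, seed=4)
    assert (t1 == t2).all()
    assert not (t1 == t3).all()


def test_match_and_split_requires_set_column():
    with pytest.raises(ValueError):
        match_and_split(pd.DataFrame({"subject_id": ["a"]}), seed=0)


# ---------------------------------------------------------------- preselect


def test_spearman_matrix_matches_scipy(rng):
    from scipy.stats import spearmanr

    X = rng.normal(size=(50, 6))
    X[:, 3] = X[:, 0] ** 3  # monotone copy -> rho = 1
    C = spearman_matrix(X)
    ref = spearmanr(X).statistic
    np.testing.assert_allclose(C, ref, atol=1e-10)
    assert C[0, 3] == pytest.approx(1.0)


def test_preselect_drops_constants_and_duplicates(rng):
    n = 60
    a = rng.normal(size=n)
    b = rng.normal(size=n)
    table = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "f1": a,
            "f2": np.exp(a),        # monotone in f1 -> rho = 1, dropped
            "f3": b,
            "f4": np.full(n, 7.0),  # constant, dropped
            "f5": a + 0.5 * b,      # genuinely new, kept
        }
    )
    kept = preselect(table, rho=0.98)
    assert kept == ["f1", "f3", "f5"]


def test_preselect_order_is_catalog_greedy(rng):
    """The earlier column always wins among near-duplicates."""
    a = rng.normal(size=40)
    table = pd.DataFrame(
        {"subject_id": range(40), "late": a, "later": 2 * a + 1e-9}
    )
    assert preselect(table) == ["late"]


# -------------------------------------------------- bootstrap + finalization


def test_bootstrap_inclusion_frequencies(rng):
    n, p = 300, 6
    X = rng.normal(size=(n, p))
    beta = np.array([1.5, 0, 0, 0, 0, 0])
    y = (rng.random(n) < 1 / (1 + np.exp(-(X @ beta)))).astype(float)
    table = pd.DataFrame(X, columns=[f"f{i}" for i in range(p)])
    cfg = SelectionConfig(n_bootstrap=40, seed=0)
    res = bootstrap_inclusion(
        table, y, list(table.columns), cfg, np.random.default_rng(0)
    )
    assert res.inclusion_freq["f0"] > 0.95   # strong signal nearly always kept
    assert res.inclusion_freq.drop("f0").max() < 0.6
    assert res.n_failed == 0


def test_finalize_selection_threshold_and_pair_pruning(rng):
    n = 80
    a = rng.normal(size=n)
    train = pd.DataFrame(
        {"fA": a, "fB": a + rng.normal(scale=0.01, size=n), "fC": rng.normal(size=n)}
    )
    freq = pd.Series({"fA": 0.9, "fB": 0.8, "fC": 0.75})
    res = risk.SelectionResult(freq, [], "within-group")
    cfg = SelectionConfig(n_bootstrap=10)
    final = finalize_selection(res, train, cfg, {"fA": 1, "fB": 2, "fC": 3})
    # fB is rank-correlated ~1 with fA and has lower frequency -> dropped
    assert final == ["fA", "fC"]
    # below-threshold features never enter
    freq2 = pd.Series({"fA": 0.5, "fB": 0.2, "fC": 0.9})
    res2 = risk.SelectionResult(freq2, [], "within-group")
    assert finalize_selection(res2, train, cfg, None) == ["fC"]


# -------------------------------------------------------------------- scoring


def test_score_model_linear_predictor_standardization(rng):
    n = 100
    train = pd.DataFrame({"f1": rng.normal(5, 2, n), "f2": rng.normal(-3, 0.5, n)})
    y = (rng.random(n) < 0.5).astype(float)
    m = fit_score_model(train, y, ["f1", "f2"])
    lp = m.linear_predictor(train)
    Z = (train[["f1", "f2"]].to_numpy() - m.train_means) / m.train_sds
    np.testing.assert_allclose(lp, m.intercept + Z @ m.coefficients)
    s = score_subjects(m, train)
    assert ((s >= 0) & (s <= 100)).all()


def test_score_model_missing_column_raises(rng):
    m = ScoreModel(["f1"], 0.0, np.array([1.0]), np.array([0.0]), np.array([1.0]))
    with pytest.raises(KeyError):
        m.linear_predictor(pd.DataFrame({"other": [1.0]}))


# ------------------------------------------------------------------------ AUC


def test_auc_matches_all_pairs_oracle(rng):
    cases = rng.normal(1.0, 1.0, 37)
    controls = rng.normal(0.0, 1.0, 53)
    wins = sum(
        1.0 if c > k else (0.5 if c == k else 0.0)
        for c, k in itertools.product(cases, controls)
    )
    assert auc(cases, controls) == pytest.approx(wins / (37 * 53))


def test_auc_ties_give_half():
    assert auc(np.array([1.0, 1.0]), np.array([1.0, 1.0])) == 0.5


def test_auc_perfect_separation():
    assert auc(np.array([2.0, 3.0]), np.array([0.0, 1.0])) == 1.0
    assert auc(np.array([0.0]), np.array([5.0])) == 0.0


def test_auc_matches_sklearn_style_rank_formula(rng):
    from scipy.stats import mannwhitneyu

    cases = rng.normal(0.6, 1.0, 40)
    controls = rng.normal(0.0, 1.0, 60)
    u = mannwhitneyu(cases, controls, alternative="two-sided").statistic
    assert auc(cases, controls) == pytest.approx(u / (40 * 60))


# ------------------------------------------------------------------- evaluate


def test_evaluate_or_per_sd_and_adjustments(rng):
    n = 600
    score = rng.normal(size=n)
    age = rng.normal(55, 8, n)
    eta = 0.9 * score + 0.02 * (age - 55)
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    cov = pd.DataFrame(
        {
            "age": age,
            "bmi": rng.normal(25, 4, n),
            "parity_class": rng.choice(["0", "1-2", ">=3"], n),
            "family_history": rng.choice(["yes", "no"], n),
            "age_ftp": rng.normal(25, 4, n),
            "pmd_true": rng.uniform(5, 40, n),
        }
    )
    rep = evaluate(score, y, cov, ADJUSTMENT_SETS)
    assert set(rep) == {"unadjusted", "age_bmi", "full", "full_pmd"}
    cell = rep["unadjusted"]
    # planted log-OR per SD ~ 0.9 on a unit-SD score
    assert cell["ci_low"] < np.exp(0.9) < cell["ci_high"]
    assert 0.6 < cell["auc"] < 0.9
    for c in rep.values():
        assert c["converged"]
        assert c["ci_low"] < c["or_per_sd"] < c["ci_high"]


def test_evaluate_null_score_covers_one(rng):
    n = 500
    score = rng.normal(size=n)
    y = (rng.random(n) < 0.5).astype(float)
    cell = evaluate(score, y)["unadjusted"]
    assert cell["ci_low"] < 1.0 < cell["ci_high"]


def test_evaluate_zero_variance_score_raises():
    with pytest.raises(ValueError):
        evaluate(np.ones(10), np.r_[np.ones(5), np.zeros(5)])


# --------------------------------------------------------- model-results API


def test_selection_config_validation():
    with pytest.raises(ValueError):
        SelectionConfig(freq_threshold=1.5)
    with pytest.raises(ValueError):
        SelectionConfig(n_bootstrap=0)
    with pytest.raises(ValueError):
        SelectionConfig(scan="fast")


@pytest.fixture(scope="module")
def fitted_results():
    """End-to-end fit on a small feature-level cohort (no images)."""
    rng = np.random.default_rng(42)
    n_sets = 60
    rows, feats = [], []
    sid = 0
    for k in range(n_sets):
        for label in ("case", "case", "control"):
            signal = 1.0 if label == "case" else 0.0
            f = rng.normal(size=12)
            f[0] += signal * 1.2
            f[1] -= signal * 0.8
            rows.append(
                {
                    "subject_id": f"S{sid:04d}",
                    "label": label,
                    "matched_set_id": f"set{k}",
                    "age": 55 + rng.normal(0, 8),
                    "bmi": 25 + rng.normal(0, 4),
                }
            )
            feats.append(f)
            sid += 1
    cohort = pd.DataFrame(rows)
    # use real catalog feature ids so grouping by catalog works
    import mammotex.features as fb

    ids = fb.feature_ids()[:12]
    table = pd.DataFrame(np.array(feats), columns=ids)
    table.insert(0, "subject_id", cohort["subject_id"])
    cfg = SelectionConfig(n_bootstrap=30, seed=1)
    return TextureRiskModel(table, cohort, cfg).fit()


def test_model_results_recovers_signal(fitted_results):
    res = fitted_results
    import mammotex.features as fb

    ids = fb.feature_ids()[:12]
    assert ids[0] in res.selected  # the planted feature survives
    assert res.auc_validation > 0.6
    assert set(res.selected) <= set(res.preselected)


def test_results_summary_renders(fitted_results):
    text = fitted_results.summary()
    assert "validation AUC" in text
    assert "Texture risk model" in text
    for f in fitted_results.selected:
        assert f in text


def test_results_validation_table_consistent(fitted_results):
    res = fitted_results
    v = res.validation
    assert {"subject_id", "label", "score"} <= set(v.columns)
    recomputed = auc(
        v.loc[v["label"] == "case", "score"].to_numpy(),
        v.loc[v["label"] == "control", "score"].to_numpy(),
    )
    assert res.auc_validation == pytest.approx(recomputed)


def test_model_rejects_misaligned_tables():
    co = _toy_cohort(4)
    table = pd.DataFrame({"subject_id": ["nope"], "f": [1.0]})
    with pytest.raises((ValueError, Exception)):
        TextureRiskModel(table, co).fit()
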