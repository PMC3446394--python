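"""Case-control risk scoring from texture features.

The analysis mirrors a matched case-control texture study: the cohort is
split 50/50 at the matched-set level into training and validation halves;
near-duplicate features (|Spearman rho| > 0.98) are pruned; features are then
selected by the Sauerbrei-Schumacher bootstrap-stability rule — backward
stepwise logistic elimination under AIC on each bootstrap resample, keeping
features retained in > 70% of resamples and, among highly correlated
(|rho| > 0.90) survivors, the more frequent one — first within each feature
group, then across groups starting from the union of the within-group
selections.  A logistic model on the final features, fitted to the training
half, maps each validation subject to a 0-100 risk score, evaluated by ROC
AUC and odds ratio per SD with covariate-adjusted variants.

The public surface follows the statsmodels convention: build a
:class:`TextureRiskModel` from the feature table and cohort table, call
``fit()``, and read estimates, scores and diagnostics off the returned
:class:`TextureRiskResults`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import rankdata

from . import features as feature_bank

log = logging.getLogger(__name__)

ADJUSTMENT_SETS: dict[str, tuple[str, ...]] = {
    "unadjusted": (),
    "age_bmi": ("age", "bmi"),
    "full": ("age", "bmi", "parity", "family_history", "age_ftp"),
    "full_pmd": ("age", "bmi", "parity", "family_history", "age_ftp", "pmd"),
}


@dataclass(frozen=True)
class SelectionConfig:
    """Tuning knobs of the bootstrap-stability selection.

    ``n_bootstrap`` = 500 reproduces the reference protocol; smaller values
    trade selection stability for speed and are appropriate for simulation
    studies.  ``scan`` chooses the backward-elimination candidate scan:
    ``"exact"`` refits every single-drop candidate at each step, ``"wald"``
    ranks candidates by their Wald statistic and verifies the exact AIC of
    the leading ones (the two agree except on near-ties and the latter is
    orders of magnitude faster at bootstrap scale).
    """

    n_bootstrap: int = 500
    preselect_rho: float = 0.98
    freq_threshold: float = 0.70
    pair_rho: float = 0.90
    seed: int = 0
    scan: str = "wald"

    def __post_init__(self) -> None:
        for t in (self.preselect_rho, self.freq_threshold, self.pair_rho):
            if not 0.0 < t < 1.0:
                raise ValueError("thresholds must lie in (0, 1)")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if self.scan not in ("exact", "wald"):
            raise ValueError("scan must be 'exact' or 'wald'")


@dataclass
class SelectionResult:
    inclusion_freq: pd.Series  # per-feature fraction of bootstrap models
    selected: list[str]
    stage: str  # "within-group" | "across-groups"
    n_failed: int = 0


@dataclass
class ScoreModel:
    """Fitted logistic score: standardized-coefficient parameterization."""

    feature_ids: list[str]
    intercept: float
    coefficients: np.ndarray  # per feature, on the standardized scale
    train_means: np.ndarray
    train_sds: np.ndarray

    def linear_predictor(self, table: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.feature_ids if f not in table.columns]
        if missing:
            raise KeyError(f"missing feature columns: {missing[:5]}")
        X = table[self.feature_ids].to_numpy(dtype=np.float64)
        Z = (X - self.train_means) / self.train_sds
        return self.intercept + Z @ self.coefficients


# ---------------------------------------------------------------------------
# logistic fitting


class LogisticFitError(RuntimeError):
    pass


@dataclass
class LogisticFit:
    coef: np.ndarray        # intercept first
    loglik: float
    aic: float
    converged: bool
    separated: bool
    cov: np.ndarray | None = None
    hessian: np.ndarray | None = None  # last Newton Hessian (observed information)

    @property
    def n_params(self) -> int:
        return len(self.coef)


def _loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # sum y*eta - log(1 + exp(eta)), stable
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _fit_logistic_design(
    X1: np.ndarray,
    y: np.ndarray,
    warm: np.ndarray | None,
    ridge: float,
    max_iter: int,
    tol: float,
    compute_cov: bool,
) -> LogisticFit:
    """Newton/IRLS core on a design matrix that already carries the intercept."""
    n, k = X1.shape
    diag = np.arange(k)
    beta = np.zeros(k) if warm is None else np.asarray(warm, dtype=np.float64).copy()
    eta = X1 @ beta
    ll = _loglik(eta, y)
    converged = False
    H = None
    for _ in range(max_iter):
        mu = expit(eta)
        grad = X1.T @ (y - mu) - ridge * beta
        w = mu * (1.0 - mu) + 1e-12
        H = (X1 * w[:, None]).T @ X1
        H[diag, diag] += ridge
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return LogisticFit(beta, ll, 2 * k - 2 * ll, False, True)
        # Newton decrement: the expected log-likelihood gain of the full step
        # is ~ grad @ step / 2, so a small decrement certifies convergence
        # without further function evaluations
        decrement = float(grad @ step)
        if decrement < 2.0 * tol:
            converged = True
            break
        # damped update
        t = 1.0
        for _ in range(30):
            cand = beta + t * step
            eta_c = X1 @ cand
            ll_c = _loglik(eta_c, y)
            if ll_c >= ll - 1e-9:
                break
            t *= 0.5
        beta, eta, ll = cand, eta_c, ll_c
    separated = (not converged) or bool(np.max(np.abs(beta)) > 50.0)
    cov = None
    if compute_cov:
        mu = expit(eta)
        w = mu * (1.0 - mu) + 1e-12
        H = (X1 * w[:, None]).T @ X1
        H[diag, diag] += ridge
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = None
    return LogisticFit(beta, ll, 2 * k - 2 * ll, converged, separated, cov, H)


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    warm: np.ndarray | None = None,
    ridge: float = 1e-8,
    max_iter: int = 60,
    tol: float = 1e-9,
    compute_cov: bool = True,
) -> LogisticFit:
    """Maximum-likelihood logistic regression by damped Newton iteration.

    ``X`` excludes the intercept (added internally, first coefficient).
    AIC = 2(p+1) - 2 logL.  A vanishing ridge keeps the Hessian invertible
    on collinear resamples; fits that fail to converge or run away (a
    symptom of separation) are flagged rather than raised.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    n, p = X.shape if X.ndim == 2 else (len(X), 0)
    X1 = np.hstack([np.ones((n, 1)), X]) if p else np.ones((n, 1))
    return _fit_logistic_design(X1, y, warm, ridge, max_iter, tol, compute_cov)


def stepwise_backward_aic(
    X: np.ndarray,
    y: np.ndarray,
    start: list[int] | None = None,
    scan: str = "exact",
    wald_depth: int = 1,
) -> list[int]:
    """Backward elimination under AIC; returns retained column indices.

    At each step the single removal lowering AIC the most is accepted, until
    no removal lowers it (the intercept-only model is an admissible
    endpoint).  The ``"wald"`` scan orders candidates by their Wald z^2 from
    the current fit (the expected AIC change of dropping x_j is ~ 2 - z_j^2)
    and verifies the exact AIC of the ``wald_depth`` leading candidates; the
    accepted step is always backed by an exact refit, so the AIC path is
    monotone under either scan.  Candidates whose refit is flagged as
    separated are skipped.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = len(y)
    X1 = np.hstack([np.ones((n, 1)), X])
    current = list(range(X.shape[1])) if start is None else list(start)
    if len(current) == 0:
        raise ValueError("start set must be nonempty")

    def _fit(cols, warm=None, cov=False):
        idx = [0] + [c + 1 for c in cols]
        return _fit_logistic_design(
            X1[:, idx], y, warm, 1e-8, 60, 1e-7, cov
        )

    fit = _fit(current, cov=True)
    if fit.separated and not fit.converged:
        raise LogisticFitError("full starting model did not converge")
    while current:
        best_aic = fit.aic
        best_j = None
        best_fit = None
        greedy = False
        if scan == "exact" or len(current) == 1 or fit.cov is None:
            candidates = list(range(len(current)))
        else:
            se = np.sqrt(np.maximum(np.diag(fit.cov)[1:], 1e-300))
            z2 = (fit.coef[1:] / se) ** 2
            # probe a few extra candidates so a single non-improving leader
            # cannot end the elimination prematurely
            candidates = list(np.argsort(z2, kind="stable"))[: max(wald_depth, 3)]
            greedy = True
        for j in candidates:
            trial = current[:j] + current[j + 1 :]
            warm = np.delete(fit.coef, j + 1)
            f = _fit(trial, warm=warm)
            if f.separated and not f.converged:
                continue
            if f.aic < best_aic - 1e-10:
                best_aic, best_j, best_fit = f.aic, j, f
                if greedy and candidates.index(j) + 1 >= wald_depth:
                    break
        if best_j is None:
            break
        current.pop(best_j)
        fit = best_fit
        if current and scan != "exact" and fit.cov is None:
            # Wald screening needs a covariance; the Hessian from the last
            # Newton step is the observed information at (or next to) the
            # optimum, which is accurate enough for ranking candidates
            if fit.hessian is not None:
                try:
                    fit.cov = np.linalg.inv(fit.hessian)
                except np.linalg.LinAlgError:
                    fit = _fit(current, warm=fit.coef, cov=True)
            else:
                fit = _fit(current, warm=fit.coef, cov=True)
    return current


# ---------------------------------------------------------------------------
# pipeline stages


def match_and_split(cohort: pd.DataFrame, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Randomize matched sets 50/50; returns boolean train/validation masks.

    Sets stay intact on one side; with an odd set count the extra set goes to
    training.
    """
    if "matched_set_id" not in cohort.columns:
        raise ValueError("cohort table must carry matched_set_id")
    sets = pd.unique(cohort["matched_set_id"])
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(sets))
    n_train = (len(sets) + 1) // 2
    train_sets = set(sets[perm[:n_train]])
    train = cohort["matched_set_id"].isin(train_sets).to_numpy()
    return train, ~train


def spearman_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise Spearman correlations of columns (average ranks for ties)."""
    ranks = np.apply_along_axis(rankdata, 0, X)
    sd = ranks.std(axis=0)
    sd[sd == 0] = np.nan
    Z = (ranks - ranks.mean(axis=0)) / sd
    return (Z.T @ Z) / X.shape[0]


def preselect(table: pd.DataFrame, rho: float = 0.98) -> list[str]:
    """Prune zero-variance and near-duplicate columns; returns retained ids.

    Greedy in catalog (column) order: a later column is dropped when its
    |Spearman rho| with any retained earlier column exceeds ``rho``.
    """
    cols = [c for c in table.columns if c != "subject_id"]
    X = table[cols].to_numpy(dtype=np.float64)
    variances = X.var(axis=0)
    nonconst = variances > 0
    idx = np.flatnonzero(nonconst)
    C = np.abs(spearman_matrix(X[:, idx]))
    keep: list[int] = []
    for k in range(len(idx)):
        if keep and np.any(C[k, keep] > rho):
            continue
        keep.append(k)
    return [cols[idx[k]] for k in keep]


def bootstrap_inclusion(
    X: pd.DataFrame,
    y: np.ndarray,
    feature_ids: list[str],
    config: SelectionConfig,
    rng: np.random.Generator,
    stage: str = "within-group",
) -> SelectionResult:
    """Inclusion frequency of each feature over bootstrap stepwise fits."""
    Z = _standardize(X[feature_ids].to_numpy(dtype=np.float64))[0]
    y = np.asarray(y, dtype=np.float64)
    n = len(y)
    counts = np.zeros(len(feature_ids))
    failed = 0
    for b in range(config.n_bootstrap):
        idx = rng.integers(0, n, n)
        try:
            kept = stepwise_backward_aic(Z[idx], y[idx], scan=config.scan)
        except LogisticFitError:
            failed += 1
            log.debug("bootstrap resample %d failed", b)
            continue
        counts[kept] += 1
        log.debug("bootstrap %d kept %d features", b, len(kept))
    n_ok = config.n_bootstrap - failed
    if failed > 0.10 * config.n_bootstrap:
        raise LogisticFitError(
            f"{failed}/{config.n_bootstrap} bootstrap resamples failed"
        )
    freq = pd.Series(counts / max(n_ok, 1), index=feature_ids)
    return SelectionResult(freq, [], stage, failed)


def finalize_selection(
    result: SelectionResult,
    train_table: pd.DataFrame,
    config: SelectionConfig,
    catalog_order: dict[str, int] | None = None,
) -> list[str]:
    """Frequency cut plus correlated-pair pruning.

    Features retained in > ``freq_threshold`` of resamples are kept; for any
    kept pair with |Spearman rho| > ``pair_rho`` on the training data, the
    lower-frequency member is dropped (frequency ties keep the earlier
    catalog ordinal).
    """
    freq = result.inclusion_freq
    kept = [f for f in freq.index if freq[f] > config.freq_threshold]
    if len(kept) <= 1:
        return kept
    order = catalog_order or {f: i for i, f in enumerate(freq.index)}
    C = np.abs(spearman_matrix(train_table[kept].to_numpy(dtype=np.float64)))
    # rank by (frequency desc, catalog ordinal asc); greedily keep the best
    ranked = sorted(kept, key=lambda f: (-freq[f], order.get(f, 1 << 30)))
    pos = {f: i for i, f in enumerate(kept)}
    final: list[str] = []
    for f in ranked:
        if any(C[pos[f], pos[g]] > config.pair_rho for g in final):
            continue
        final.append(f)
    final.sort(key=lambda f: order.get(f, 1 << 30))
    return final


def select_two_stage(
    train_table: pd.DataFrame,
    y_train: np.ndarray,
    groups: dict[str, list[str]],
    config: SelectionConfig,
) -> tuple[list[str], dict[str, SelectionResult], SelectionResult]:
    """Within-group then across-group bootstrap-stability selection."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    ordinals = {d.feature_id: d.ordinal for d in feature_bank.catalog()}
    stage1: dict[str, SelectionResult] = {}
    union: list[str] = []
    for group, ids in groups.items():
        if not ids:
            continue
        res = bootstrap_inclusion(train_table, y_train, ids, config, rng)
        res.selected = finalize_selection(res, train_table, config, ordinals)
        stage1[group] = res
        union.extend(res.selected)
    if not union:
        raise LogisticFitError("no feature survived within-group selection")
    union.sort(key=lambda f: ordinals.get(f, 1 << 30))
    res2 = bootstrap_inclusion(
        train_table, y_train, union, config, rng, stage="across-groups"
    )
    res2.selected = finalize_selection(res2, train_table, config, ordinals)
    return res2.selected, stage1, res2


def _standardize(X: np.ndarray):
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    sds[sds == 0] = 1.0
    return (X - means) / sds, means, sds


def fit_score_model(
    train_table: pd.DataFrame, y_train: np.ndarray, feature_ids: list[str]
) -> ScoreModel:
    """Multiple logistic fit of case status on the selected features."""
    X = train_table[feature_ids].to_numpy(dtype=np.float64)
    Z, means, sds = _standardize(X)
    fit = fit_logistic(Z, np.asarray(y_train, dtype=np.float64))
    return ScoreModel(
        feature_ids=list(feature_ids),
        intercept=float(fit.coef[0]),
        coefficients=fit.coef[1:],
        train_means=means,
        train_sds=sds,
    )


def score_subjects(model: ScoreModel, table: pd.DataFrame) -> np.ndarray:
    """0-100 risk score: 100 x inverse-logit of the linear predictor."""
    return 100.0 * expit(model.linear_predictor(table))


def auc(case_scores: np.ndarray, control_scores: np.ndarray) -> float:
    """Concordance probability (Mann-Whitney), ties counted one half."""
    cs = np.asarray(case_scores, dtype=np.float64)
    ns = np.asarray(control_scores, dtype=np.float64)
    if cs.size == 0 or ns.size == 0:
        raise ValueError("both groups must be nonempty")
    ranks = rankdata(np.concatenate([cs, ns]))
    r1 = ranks[: cs.size].sum()
    return float((r1 - cs.size * (cs.size + 1) / 2.0) / (cs.size * ns.size))


def _covariate_design(cov: pd.DataFrame, names: tuple[str, ...]) -> np.ndarray:
    cols = []
    for name in names:
        if name == "parity":
            pc = cov["parity_class"].astype(str)
            cols.append((pc == "1-2").to_numpy(float))
            cols.append((pc == ">=3").to_numpy(float))
        elif name == "family_history":
            cols.append((cov["family_history"].astype(str) == "yes").to_numpy(float))
        elif name == "pmd":
            cols.append(cov["pmd_true"].to_numpy(float))
        else:
            cols.append(cov[name].to_numpy(float))
    return np.column_stack(cols) if cols else np.empty((len(cov), 0))


def evaluate(
    scores: np.ndarray,
    y: np.ndarray,
    covariates: pd.DataFrame | None = None,
    adjust_sets: dict[str, tuple[str, ...]] | None = None,
) -> dict[str, dict]:
    """Odds ratio per SD of the score and ROC AUC, per adjustment set.

    The score is divided by its sample SD before fitting, so the reported OR
    is per SD-sized interval; CIs are Wald intervals from a statsmodels
    logistic fit.  The AUC of an adjusted model is computed from its in-sample
    predicted probabilities.
    """
    import statsmodels.api as sm

    scores = np.asarray(scores, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    sd = scores.std()
    if sd == 0:
        raise ValueError("score has zero variance")
    z = scores / sd
    sets = adjust_sets if adjust_sets is not None else {"unadjusted": ()}
    report: dict[str, dict] = {}
    for name, covs in sets.items():
        extra = _covariate_design(covariates, covs) if covariates is not None else (
            np.empty((len(y), 0))
        )
        X = sm.add_constant(np.column_stack([z, extra]))
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            beta = res.params[1]
            se = res.bse[1]
            pred = res.predict(X)
            cell = {
                "or_per_sd": math.exp(beta),
                "ci_low": math.exp(beta - 1.959963984540054 * se),
                "ci_high": math.exp(beta + 1.959963984540054 * se),
                "auc": auc(pred[y == 1], pred[y == 0]),
                "converged": bool(res.mle_retvals.get("converged", True)),
            }
        except Exception as exc:  # reported, never silent
            cell = {"error": str(exc), "converged": False}
        report[name] = cell
    return report


# ---------------------------------------------------------------------------
# model / results objects


class TextureRiskModel:
    """Bootstrap-stability texture risk model for a matched cohort.

    Parameters
    ----------
    feature_table
        One row per subject: ``subject_id`` plus the 470 catalog columns
        (or any subset of them).
    cohort
        One row per subject: ``subject_id``, ``label`` (case/control),
        ``matched_set_id`` and the epidemiologic covariates.
    config
        Selection protocol; defaults to the 500-bootstrap reference settings.
    """

    def __init__(
        self,
        feature_table: pd.DataFrame,
        cohort: pd.DataFrame,
        config: SelectionConfig | None = None,
    ) -> None:
        self.config = config or SelectionConfig()
        merged = cohort.merge(feature_table, on="subject_id", validate="1:1")
        if len(merged) != len(cohort):
            raise ValueError("feature table and cohort do not align on subject_id")
        self.data = merged
        self.feature_columns = [
            c for c in feature_table.columns if c != "subject_id"
        ]

    @classmethod
    def from_dataframes(cls, feature_table, cohort, config=None):
        return cls(feature_table, cohort, config)

    def fit(self) -> "TextureRiskResults":
        cfg = self.config
        data = self.data
        y = (data["label"].astype(str) == "case").to_numpy(float)
        train_mask, valid_mask = match_and_split(data, cfg.seed)
        train = data.loc[train_mask].reset_index(drop=True)
        valid = data.loc[valid_mask].reset_index(drop=True)
        y_tr, y_va = y[train_mask], y[valid_mask]

        retained = preselect(train[self.feature_columns], cfg.preselect_rho)
        group_of = {d.feature_id: d.group for d in feature_bank.catalog()}
        groups: dict[str, list[str]] = {g: [] for g in feature_bank.GROUPS}
        for f in retained:
            groups.setdefault(group_of.get(f, "other"), []).append(f)

        final, stage1, stage2 = select_two_stage(train, y_tr, groups, cfg)
        if not final:
            raise LogisticFitError("across-group selection returned no features")
        for f in final:
            assert f in retained, "selected feature missing from preselected table"
        score_model = fit_score_model(train, y_tr, final)
        val_scores = score_subjects(score_model, valid)
        report = evaluate(val_scores, y_va, valid, ADJUSTMENT_SETS_AVAILABLE(valid))
        return TextureRiskResults(
            model=self,
            preselected=retained,
            stage1=stage1,
            stage2=stage2,
            selected=final,
            score_model=score_model,
            train_ids=train["subject_id"].tolist(),
            validation=pd.DataFrame(
                {
                    "subject_id": valid["subject_id"],
                    "label": valid["label"],
                    "score": val_scores,
                }
            ),
            auc_validation=auc(val_scores[y_va == 1], val_scores[y_va == 0]),
            evaluation=report,
        )


def ADJUSTMENT_SETS_AVAILABLE(cov: pd.DataFrame) -> dict[str, tuple[str, ...]]:
    """The standard adjustment sets restricted to available covariates."""
    sets = {}
    for name, covs in ADJUSTMENT_SETS.items():
        needed = {
            "parity": "parity_class",
            "family_history": "family_history",
            "pmd": "pmd_true",
        }
        if all(needed.get(c, c) in cov.columns for c in covs):
            sets[name] = covs
    return sets


@dataclass
class TextureRiskResults:
    """Estimates, scores and diagnostics of a fitted texture risk model."""

    model: TextureRiskModel
    preselected: list[str]
    stage1: dict[str, SelectionResult]
    stage2: SelectionResult
    selected: list[str]
    score_model: ScoreModel
    train_ids: list[str]
    validation: pd.DataFrame
    auc_validation: float
    evaluation: dict[str, dict]

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Texture risk model (bootstrap-stability logistic selection)",
            "=" * 62,
            f"subjects: {len(self.model.data)}   "
            f"training: {len(self.train_ids)}   "
            f"validation: {len(self.validation)}",
            f"features: {len(self.model.feature_columns)} -> "
            f"{len(self.preselected)} preselected -> "
            f"{sum(len(r.selected) for r in self.stage1.values())} within-group -> "
            f"{len(self.selected)} final",
            f"bootstraps: {cfg.n_bootstrap}   freq cut: >{cfg.freq_threshold:.2f}   "
            f"pair |rho| cut: >{cfg.pair_rho:.2f}",
            "",
            f"{'feature':<38}{'coef(std)':>12}{'incl.freq':>12}",
            "-" * 62,
        ]
        for f, b in zip(self.selected, self.score_model.coefficients):
            freq = self.stage2.inclusion_freq.get(f, np.nan)
            lines.append(f"{f:<38}{b:>12.4f}{freq:>12.3f}")
        lines.append("-" * 62)
        lines.append(f"validation AUC: {self.auc_validation:.3f}")
        cell = self.evaluation.get("unadjusted", {})
        if "or_per_sd" in cell:
            lines.append(
                f"OR per SD (unadjusted): {cell['or_per_sd']:.2f} "
                f"(95% CI {cell['ci_low']:.2f}-{cell['ci_high']:.2f})"
            )
        return "\n".join(lines)
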