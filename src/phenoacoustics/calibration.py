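"""Calibration of manual insect-activity metrics against acoustic indices.

Two response families map scaled indices to the manual annotations:

* **beta-logit** for spectrogram coverage (a proportion): density
  parameterized by mean mu (logit link on the linear predictor) and
  precision phi, log-likelihood per observation
  ``lnG(phi) - lnG(mu*phi) - lnG((1-mu)*phi) + (mu*phi-1)ln y
  + ((1-mu)*phi-1)ln(1-y)``;
* **Poisson-log** for sonotype counts.

The candidate design holds the five scaled indices as linear and
quadratic terms plus site and year factors (12 candidate terms). All
2^12 submodels are fitted and ranked by AICc; models within
``delta_max`` (default 2) of the best are combined by Akaike-weighted
full averaging (absent terms enter as zero). Predictive error is
assessed by 5-fold cross-validation of the single best model, repeated
100 times.

Fitting is done in-package (IRLS for Poisson, quasi-Newton ML with
analytic score for beta) so that all-subsets enumeration and repeated CV
stay fast; the likelihoods are checked against independent references in
the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import digamma, expit, gammaln
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .indices import INDEX_COLUMNS

__all__ = [
    "PoissonRegression",
    "BetaRegression",
    "fit_glm",
    "aicc",
    "squeeze_proportions",
    "candidate_terms",
    "build_design",
    "ModelRanking",
    "enumerate_models",
    "AveragedModel",
    "average_models",
    "CVMetrics",
    "cross_validate",
    "predict_response",
]

_EPS = 1e-10


def squeeze_proportions(y: np.ndarray, n: int | None = None) -> np.ndarray:
    """Shrink proportions off the {0, 1} boundary: y' = (y(n-1) + 0.5)/n."""
    y = np.asarray(y, dtype=np.float64)
    n = y.size if n is None else n
    return (y * (n - 1) + 0.5) / n


def aicc(llf: float, k: int, n: int) -> float:
    """AICc = -2l + 2k + 2k(k+1)/(n-k-1); requires n > k+1."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k}")
    return -2.0 * llf + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


# ---------------------------------------------------------------- Poisson


def _poisson_irls(
    X: np.ndarray, y: np.ndarray, max_iter: int = 60, tol: float = 1e-10
) -> tuple[np.ndarray, float, bool]:
    """Newton/IRLS for Poisson-log; returns (beta, llf, converged)."""
    n, p = X.shape
    beta = np.zeros(p)
    beta[0] = np.log(max(y.mean(), _EPS))  # column 0 is the intercept
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = np.exp(np.clip(eta, -30, 30))
        W = mu
        XtW = X.T * W
        H = XtW @ X
        g = X.T @ (y - mu)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        beta = beta + step
        ll = float(y @ (X @ beta) - np.exp(np.clip(X @ beta, -30, 30)).sum())
        if abs(ll - ll_old) < tol * (abs(ll) + 1.0):
            converged = True
            break
        ll_old = ll
    eta = np.clip(X @ beta, -30, 30)
    llf = float(y @ eta - np.exp(eta).sum() - gammaln(y + 1).sum())
    return beta, llf, converged


class PoissonRegression(RegressorMixin, BaseEstimator):
    """Poisson GLM with log link, fitted by Newton scoring.

    Fitted attributes: ``coef_`` (intercept first), ``cov_`` (inverse
    observed information), ``llf_``, ``k_`` (parameter count), ``n_``.
    """

    family = "poisson_log"

    def __init__(self, max_iter: int = 60, tol: float = 1e-10):
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y):
        X, y = self._validate(X, y)
        if np.any(y < 0) or np.any(y != np.round(y)):
            raise ValueError("Poisson response must be nonnegative integers")
        beta, llf, converged = _poisson_irls(X, y, self.max_iter, self.tol)
        if not converged:
            raise RuntimeError("Poisson IRLS did not converge")
        mu = np.exp(np.clip(X @ beta, -30, 30))
        self.coef_ = beta
        self.cov_ = np.linalg.inv(X.T @ (X * mu[:, None]))
        self.llf_ = llf
        self.k_ = X.shape[1]
        self.n_ = X.shape[0]
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = self._with_intercept(np.asarray(X, dtype=np.float64))
        return np.exp(np.clip(X @ self.coef_, -30, 30))

    def predict_dist(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Response-scale mean and delta-method standard error."""
        check_is_fitted(self, "cov_")
        X = self._with_intercept(np.asarray(X, dtype=np.float64))
        eta = np.clip(X @ self.coef_, -30, 30)
        mu = np.exp(eta)
        var_eta = np.einsum("ij,jk,ik->i", X, self.cov_, X)
        return mu, mu * np.sqrt(np.maximum(var_eta, 0.0))

    def _validate(self, X, y):
        X = self._with_intercept(np.asarray(X, dtype=np.float64))
        y = np.asarray(y, dtype=np.float64).ravel()
        if X.shape[0] != y.size:
            raise ValueError("X and y length mismatch")
        return X, y

    @staticmethod
    def _with_intercept(X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        if X.shape[1] == 0 or not np.allclose(X[:, 0], 1.0):
            X = np.column_stack([np.ones(X.shape[0]), X])
        return X


# ------------------------------------------------------------------- beta


def _beta_llf(y: np.ndarray, mu: np.ndarray, phi: float) -> float:
    return float(
        np.sum(
            gammaln(phi)
            - gammaln(mu * phi)
            - gammaln((1 - mu) * phi)
            + (mu * phi - 1) * np.log(y)
            + ((1 - mu) * phi - 1) * np.log1p(-y)
        )
    )


def _beta_negll_grad(theta, X, y, ylogit, log_y, log_1my):
    p = X.shape[1]
    beta, logphi = theta[:p], theta[p]
    phi = np.exp(np.clip(logphi, -20, 20))
    mu = np.clip(expit(X @ beta), _EPS, 1 - _EPS)
    ll = _beta_llf(y, mu, phi)
    mustar = digamma(mu * phi) - digamma((1 - mu) * phi)
    dbeta = phi * (X.T @ ((ylogit - mustar) * mu * (1 - mu)))
    dphi = np.sum(
        digamma(phi)
        - mu * digamma(mu * phi)
        - (1 - mu) * digamma((1 - mu) * phi)
        + mu * log_y
        + (1 - mu) * log_1my
    )
    grad = np.concatenate([dbeta, [dphi * phi]])
    return -ll, -grad


class BetaRegression(RegressorMixin, BaseEstimator):
    """Beta regression with logit mean link and constant precision phi.

    Maximum likelihood over (beta, log phi) via L-BFGS with the analytic
    score; the coefficient covariance is the inverse observed information
    (finite differences of the score at the optimum). ``k_`` counts the
    mean coefficients plus phi.
    """

    family = "beta_logit"

    def __init__(self, max_iter: int = 200, tol: float = 1e-10,
                 compute_cov: bool = True):
        self.max_iter = max_iter
        self.tol = tol
        self.compute_cov = compute_cov

    def fit(self, X, y):
        X = PoissonRegression._with_intercept(np.asarray(X, dtype=np.float64))
        y = np.asarray(y, dtype=np.float64).ravel()
        if np.any((y <= 0) | (y >= 1)):
            raise ValueError(
                "beta response must lie in (0, 1); apply squeeze_proportions first"
            )
        ylogit = np.log(y) - np.log1p(-y)
        beta0 = np.linalg.lstsq(X, ylogit, rcond=None)[0]
        resid = ylogit - X @ beta0
        mu0 = np.clip(expit(X @ beta0), 0.01, 0.99)
        sigma2 = max(float(resid @ resid) / max(len(y) - X.shape[1], 1), 1e-6)
        phi0 = max(float(np.mean(1.0 / (sigma2 * mu0 * (1 - mu0)))) - 1.0, 1.0)
        theta0 = np.concatenate([beta0, [np.log(phi0)]])
        log_y, log_1my = np.log(y), np.log1p(-y)
        # log(phi) is bounded above: zero-noise responses push phi to
        # infinity and the likelihood is unbounded there
        bounds = [(None, None)] * X.shape[1] + [(-10.0, 15.0)]
        res = minimize(
            _beta_negll_grad,
            theta0,
            args=(X, y, ylogit, log_y, log_1my),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": self.max_iter, "ftol": self.tol, "gtol": 1e-9},
        )
        at_bound = res.x[-1] >= 15.0 - 1e-6
        grad_beta = np.linalg.norm(res.jac[:-1])
        if not res.success and not at_bound and grad_beta > 1e-3 * (1 + abs(res.fun)):
            raise RuntimeError(f"beta regression did not converge: {res.message}")
        p = X.shape[1]
        self.coef_ = res.x[:p]
        self.phi_ = float(np.exp(res.x[p]))
        mu = np.clip(expit(X @ self.coef_), _EPS, 1 - _EPS)
        self.llf_ = _beta_llf(y, mu, self.phi_)
        self.k_ = p + 1
        self.n_ = len(y)
        if self.compute_cov:
            H = self._observed_information(res.x, X, y, ylogit, log_y, log_1my)
            cov_all = np.linalg.pinv(H)
            self.cov_ = cov_all[:p, :p]
        return self

    @staticmethod
    def _observed_information(theta, X, y, ylogit, log_y, log_1my):
        m = theta.size
        H = np.zeros((m, m))
        h = 1e-5 * np.maximum(np.abs(theta), 1.0)
        for j in range(m):
            tp, tm = theta.copy(), theta.copy()
            tp[j] += h[j]
            tm[j] -= h[j]
            _, gp = _beta_negll_grad(tp, X, y, ylogit, log_y, log_1my)
            _, gm = _beta_negll_grad(tm, X, y, ylogit, log_y, log_1my)
            H[:, j] = (gp - gm) / (2 * h[j])
        return (H + H.T) / 2

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = PoissonRegression._with_intercept(np.asarray(X, dtype=np.float64))
        return expit(X @ self.coef_)

    def predict_dist(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Response-scale mean and delta-method standard error."""
        check_is_fitted(self, "cov_")
        X = PoissonRegression._with_intercept(np.asarray(X, dtype=np.float64))
        mu = expit(X @ self.coef_)
        var_eta = np.einsum("ij,jk,ik->i", X, self.cov_, X)
        return mu, mu * (1 - mu) * np.sqrt(np.maximum(var_eta, 0.0))


_FAMILIES = {"poisson_log": PoissonRegression, "beta_logit": BetaRegression}


def fit_glm(X, y, family: str, **kwargs):
    """Fit a GLM of the given family ('beta_logit' or 'poisson_log')."""
    try:
        cls = _FAMILIES[family]
    except KeyError:
        raise ValueError(f"unknown family {family!r}") from None
    return cls(**kwargs).fit(X, y)


# --------------------------------------------------- design & enumeration


def candidate_terms(indices: list[str] = INDEX_COLUMNS) -> list[str]:
    """The 12 candidate terms: 5 linear, 5 quadratic, site, year."""
    return list(indices) + [f"{c}_sq" for c in indices] + ["site", "year"]


def build_design(
    df: pd.DataFrame, terms: list[str], levels: dict[str, list] | None = None
) -> tuple[np.ndarray, list[str], dict[str, list[int]]]:
    """Design matrix (intercept first) for the named terms.

    Quadratic terms ``<index>_sq`` are squares of the scaled index;
    ``site`` and ``year`` expand to treatment dummies (first level
    dropped). Returns (X, column names, term -> column positions).
    ``levels`` pins factor level order for prediction on new data.
    """
    cols: list[np.ndarray] = [np.ones(len(df))]
    names = ["intercept"]
    mapping: dict[str, list[int]] = {}
    levels = levels or {}
    for term in terms:
        start = len(names)
        if term in ("site", "year"):
            levs = levels.get(term) or sorted(df[term].unique().tolist())
            for lev in levs[1:]:
                cols.append((df[term] == lev).to_numpy(dtype=np.float64))
                names.append(f"{term}[{lev}]")
        elif term.endswith("_sq"):
            base = term[:-3]
            cols.append(df[base].to_numpy(dtype=np.float64) ** 2)
            names.append(term)
        else:
            cols.append(df[term].to_numpy(dtype=np.float64))
            names.append(term)
        mapping[term] = list(range(start, len(names)))
    return np.column_stack(cols), names, mapping


@dataclass
class ModelRanking:
    """All-subsets AICc ranking over candidate terms."""

    table: pd.DataFrame  # columns: terms, k, llf, aicc, delta, weight
    family: str
    candidate_terms: list[str]
    n: int
    n_failed: int = 0

    @property
    def best_terms(self) -> tuple[str, ...]:
        return self.table.iloc[0]["terms"]


def enumerate_models(
    df: pd.DataFrame,
    y: np.ndarray,
    family: str,
    terms: list[str] | None = None,
    levels: dict[str, list] | None = None,
) -> ModelRanking:
    """Fit every subset of candidate terms and rank by AICc.

    The intercept is always present; quadratic terms may enter without
    their linear counterpart (no marginality constraint). Ties are broken
    by fewer terms, then lexicographic term names. Submodels that fail to
    fit are excluded with a warning count.
    """
    terms = list(terms) if terms is not None else candidate_terms()
    X_full, names, mapping = build_design(df, terms, levels)
    y = np.asarray(y, dtype=np.float64).ravel()
    n = len(y)
    is_beta = family == "beta_logit"
    if is_beta:
        ylogit = np.log(y) - np.log1p(-y)
        log_y, log_1my = np.log(y), np.log1p(-y)

    records = []
    n_failed = 0
    n_terms = len(terms)
    term_cols = [mapping[t] for t in terms]
    for mask in range(2**n_terms):
        included = tuple(terms[i] for i in range(n_terms) if mask >> i & 1)
        col_idx = [0] + [
            c for i in range(n_terms) if mask >> i & 1 for c in term_cols[i]
        ]
        X = X_full[:, col_idx]
        k = X.shape[1] + (1 if is_beta else 0)
        try:
            if is_beta:
                llf = _beta_lean_fit(X, y, ylogit, log_y, log_1my)
            else:
                _, llf, converged = _poisson_irls(X, y)
                if not converged:
                    raise RuntimeError("IRLS non-convergence")
            records.append((included, k, llf, aicc(llf, k, n)))
        except Exception:
            n_failed += 1
    if n_failed:
        warnings.warn(f"{n_failed} submodels failed to fit and were excluded")
    table = pd.DataFrame(records, columns=["terms", "k", "llf", "aicc"])
    table = table.sort_values(
        by=["aicc", "k", "terms"],
        key=lambda s: s.map(lambda t: ",".join(t)) if s.name == "terms" else s,
    ).reset_index(drop=True)
    table["delta"] = table["aicc"] - table["aicc"].iloc[0]
    rel = np.exp(-0.5 * table["delta"].to_numpy())
    table["weight"] = rel / rel.sum()
    return ModelRanking(table, family, terms, n, n_failed)


def _beta_lean_fit(X, y, ylogit, log_y, log_1my) -> float:
    """Beta-logit ML returning only the maximized log-likelihood."""
    beta0 = np.linalg.lstsq(X, ylogit, rcond=None)[0]
    resid = ylogit - X @ beta0
    mu0 = np.clip(expit(X @ beta0), 0.01, 0.99)
    sigma2 = max(float(resid @ resid) / max(len(y) - X.shape[1], 1), 1e-6)
    phi0 = max(float(np.mean(1.0 / (sigma2 * mu0 * (1 - mu0)))) - 1.0, 1.0)
    theta0 = np.concatenate([beta0, [np.log(phi0)]])
    res = minimize(
        _beta_negll_grad,
        theta0,
        args=(X, y, ylogit, log_y, log_1my),
        jac=True,
        method="L-BFGS-B",
        bounds=[(None, None)] * X.shape[1] + [(-10.0, 15.0)],
        options={"maxiter": 150, "ftol": 1e-11},
    )
    return -float(res.fun)


# ------------------------------------------------------------- averaging


@dataclass
class AveragedModel:
    """Akaike-weighted full average of the Delta-AICc < delta_max set.

    ``coef_`` holds averaged coefficients over the union design with
    zero substitution for absent terms; predictions are the
    weight-mixture of component predictions, with mixture variance
    ``sum w_i (se_i^2 + (mu_i - mean)^2)``.
    """

    components: list
    weights: np.ndarray
    component_terms: list[tuple[str, ...]]
    family: str
    candidate_terms: list[str]
    levels: dict[str, list]
    coef_: pd.Series = field(default=None)
    inclusion_counts: pd.Series = field(default=None)

    def predict_dist(self, df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        means, ses = [], []
        for fit, terms in zip(self.components, self.component_terms):
            X, _, _ = build_design(df, list(terms), self.levels)
            m, s = fit.predict_dist(X[:, 1:])
            means.append(m)
            ses.append(s)
        M = np.stack(means)
        S = np.stack(ses)
        w = self.weights[:, None]
        mean = (w * M).sum(axis=0)
        var = (w * (S**2 + (M - mean) ** 2)).sum(axis=0)
        return mean, np.sqrt(var)

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        return self.predict_dist(df)[0]


def average_models(
    ranking: ModelRanking,
    df: pd.DataFrame,
    y: np.ndarray,
    delta_max: float = 2.0,
    levels: dict[str, list] | None = None,
) -> AveragedModel:
    """Refit the Delta-AICc < ``delta_max`` set and average coefficients.

    Weights are the Akaike weights renormalized over the component set.
    Inclusion counts per candidate term are the quantity reported by the
    pipeline's term-importance summary.
    """
    sel = ranking.table[ranking.table["delta"] < delta_max]
    if sel.empty:
        raise ValueError("empty ranking")
    levels = levels or {
        t: sorted(df[t].unique().tolist())
        for t in ("site", "year")
        if t in df.columns
    }
    fits, comp_terms = [], []
    union_names: list[str] = ["intercept"]
    coef_rows = []
    for _, row in sel.iterrows():
        terms = list(row["terms"])
        X, names, _ = build_design(df, terms, levels)
        fit = fit_glm(X[:, 1:], y, ranking.family)
        fits.append(fit)
        comp_terms.append(tuple(terms))
        coef_rows.append(dict(zip(names, fit.coef_)))
        union_names.extend(nm for nm in names if nm not in union_names)
    w = sel["weight"].to_numpy()
    w = w / w.sum()
    avg = pd.Series(0.0, index=union_names)
    for wi, row in zip(w, coef_rows):
        for nm, val in row.items():
            avg[nm] += wi * val
    counts = pd.Series(
        {t: sum(t in terms for terms in comp_terms) for t in ranking.candidate_terms}
    )
    return AveragedModel(
        components=fits,
        weights=w,
        component_terms=comp_terms,
        family=ranking.family,
        candidate_terms=ranking.candidate_terms,
        levels=levels,
        coef_=avg,
        inclusion_counts=counts,
    )


# ------------------------------------------------------- cross-validation


@dataclass
class CVMetrics:
    rmse_mean: float
    rmse_sd: float
    mae_mean: float
    mae_sd: float
    folds: int
    repeats: int


def cross_validate(
    df: pd.DataFrame,
    y: np.ndarray,
    terms: tuple[str, ...],
    family: str,
    folds: int = 5,
    repeats: int = 100,
    seed: int = 0,
    levels: dict[str, list] | None = None,
) -> CVMetrics:
    """Repeated k-fold CV of one model; RMSE/MAE on the response scale.

    Folds are random and unstratified; observations whose factor level is
    absent from a training fold are skipped with a warning.
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    n = len(y)
    if n < folds:
        raise ValueError("fewer observations than folds")
    levels = levels or {
        t: sorted(df[t].unique().tolist())
        for t in ("site", "year")
        if t in df.columns
    }
    rng = np.random.default_rng(seed)
    factor_terms = [t for t in terms if t in ("site", "year")]
    rmses, maes = [], []
    n_skipped = 0
    for _ in range(repeats):
        perm = rng.permutation(n)
        fold_of = np.empty(n, dtype=int)
        fold_of[perm] = np.arange(n) % folds
        errors = []
        for fold in range(folds):
            test = fold_of == fold
            train_df, test_df = df[~test], df[test]
            keep = np.ones(int(test.sum()), dtype=bool)
            for t in factor_terms:
                seen = set(train_df[t].unique())
                keep &= test_df[t].isin(seen).to_numpy()
            if not keep.all():
                n_skipped += int((~keep).sum())
            X_tr, _, _ = build_design(train_df, list(terms), levels)
            X_te, _, _ = build_design(test_df[keep], list(terms), levels)
            fit = fit_glm(
                X_tr[:, 1:], y[~test], family,
                **({"compute_cov": False} if family == "beta_logit" else {}),
            )
            pred = fit.predict(X_te[:, 1:])
            errors.append(pred - y[test][keep])
        e = np.concatenate(errors)
        rmses.append(float(np.sqrt(np.mean(e**2))))
        maes.append(float(np.mean(np.abs(e))))
    if n_skipped:
        warnings.warn(f"{n_skipped} test observations skipped (unseen factor level)")
    return CVMetrics(
        float(np.mean(rmses)), float(np.std(rmses)),
        float(np.mean(maes)), float(np.std(maes)),
        folds, repeats,
    )


def predict_response(model, df_or_X) -> tuple[np.ndarray, np.ndarray]:
    """Response-scale (mean, se) from a single fit or an averaged model."""
    if isinstance(model, AveragedModel):
        return model.predict_dist(df_or_X)
    return model.predict_dist(df_or_X)
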