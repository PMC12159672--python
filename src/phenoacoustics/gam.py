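"""Gaussian additive models with cyclic cubic regression splines.

Each scaled acoustic index is smoothed over the diel cycle (hour, period
24) and the annual cycle (day of year, period 365) with cyclic cubic
regression splines of basis dimension k = 4 — deliberately low so the
smooths track broad phenological trends rather than short-term
variation — plus a site x year factor interaction. The model is fitted
by penalized least squares,

    minimize ||y - X b||^2 + lambda_h b' S_h b + lambda_d b' S_d b,

with the smoothing parameters chosen by generalized cross-validation
(GCV) over a log-spaced grid. The penalty is the integrated squared
second derivative expressed in the spline basis, so a constant function
is unpenalized and lambda -> infinity shrinks each smooth to a constant.

Basis construction follows the classical cyclic natural-spline
parameterization: with k evenly spaced knots over one period (the k-th
interval wrapping to the first knot), the free parameters are the
function values at the knots; second derivatives follow from the
periodic continuity conditions, giving continuity of value, first and
second derivative across the period boundary. An identifiability
(centering) constraint absorbs the constant into the model intercept,
leaving k - 1 columns per smooth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["cyclic_cubic_basis", "CyclicBasis", "CyclicGAM"]


def _cyclic_matrices(knots: np.ndarray, period: float) -> tuple[np.ndarray, np.ndarray]:
    """Banded cyclic systems B gamma = D f linking values and 2nd derivs."""
    k = knots.size
    h = np.diff(np.append(knots, knots[0] + period))
    B = np.zeros((k, k))
    D = np.zeros((k, k))
    for i in range(k):
        im1 = (i - 1) % k
        ip1 = (i + 1) % k
        B[i, i] = (h[im1] + h[i]) / 3.0
        B[i, im1] += h[im1] / 6.0
        B[i, ip1] += h[i] / 6.0
        D[i, i] = -(1.0 / h[im1] + 1.0 / h[i])
        D[i, im1] += 1.0 / h[im1]
        D[i, ip1] += 1.0 / h[i]
    return B, D


def cyclic_cubic_basis(
    x: np.ndarray, period: float, k: int = 4
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cyclic cubic regression spline design and wiggliness penalty.

    Returns ``(X, S, knots)``: ``X`` has k columns (coefficients are the
    spline's values at the k evenly spaced knots), ``S = D' B^-1 D`` is
    the integrated squared second derivative penalty, and evaluation is
    exactly periodic (``x`` is reduced modulo ``period``). The constant
    function lies in the span with zero penalty.
    """
    if k < 3:
        raise ValueError("cyclic cubic basis needs k >= 3")
    x = np.asarray(x, dtype=np.float64) % period
    knots = period * np.arange(k) / k
    B, D = _cyclic_matrices(knots, period)
    F = np.linalg.solve(B, D)  # gamma = F f
    S = D.T @ F
    S = (S + S.T) / 2
    h = period / k
    j = np.minimum((x // h).astype(int), k - 1)
    jp1 = (j + 1) % k
    x_j = knots[j]
    a = (x_j + h - x) / h
    b = (x - x_j) / h
    c_left = ((x_j + h - x) ** 3 / h - h * (x_j + h - x)) / 6.0
    c_right = ((x - x_j) ** 3 / h - h * (x - x_j)) / 6.0
    n = x.size
    X = np.zeros((n, k))
    X[np.arange(n), j] += a
    X[np.arange(n), jp1] += b
    X += c_left[:, None] * F[j, :] + c_right[:, None] * F[jp1, :]
    return X, S, knots


@dataclass
class CyclicBasis:
    """A fitted, centered cyclic smooth: knots, constraint and penalty."""

    period: float
    k: int
    knots: np.ndarray
    Z: np.ndarray  # k x (k-1) null-space basis of the centering constraint
    S: np.ndarray  # (k-1) x (k-1) penalty in the constrained basis
    col_means: np.ndarray

    def design(self, x: np.ndarray) -> np.ndarray:
        X, _, _ = cyclic_cubic_basis(x, self.period, self.k)
        return (X - self.col_means) @ self.Z


def _center_basis(X: np.ndarray, S: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Apply the sum-to-zero-over-data constraint via a null-space rotation."""
    m = X.mean(axis=0)
    q, _ = np.linalg.qr(m[:, None], mode="complete")
    Z = q[:, 1:]  # orthonormal basis of {v : m'v = 0}
    return (X - m) @ Z, Z.T @ S @ Z, Z


class CyclicGAM(RegressorMixin, BaseEstimator):
    """Gaussian GAM: intercept + site x year factor + two cyclic smooths.

    Parameters
    ----------
    k : basis dimension of each cyclic smooth before the centering
        constraint (default 4, the pipeline's standard).
    lambda_grid : log10 range and count for the GCV grid per smooth.
    hour_period, doy_period : cycle lengths (24 h, 365 d).

    Fitted attributes include ``coef_``, ``lambda_``, ``edf_``,
    ``posterior_cov_`` (Bayesian coefficient covariance
    ``(X'X + sum lambda_i S_i)^-1 sigma^2``) and ``sigma2_``.
    """

    def __init__(
        self,
        k: int = 4,
        hour_period: float = 24.0,
        doy_period: float = 365.0,
        lambda_grid: tuple[float, float, int] = (-4.0, 6.0, 41),
        fixed_lambda: tuple[float, float] | None = None,
    ):
        self.k = k
        self.hour_period = hour_period
        self.doy_period = doy_period
        self.lambda_grid = lambda_grid
        self.fixed_lambda = fixed_lambda

    # -- design -----------------------------------------------------------

    def _factor_design(self, df: pd.DataFrame) -> np.ndarray:
        """Sum-to-zero contrasts for the site x year interaction."""
        if not self.factor_levels_:
            return np.zeros((len(df), 0))
        cell = df["site"].astype(str) + ":" + df["year"].astype(str)
        unseen = set(cell) - set(self.factor_levels_)
        if unseen:
            raise ValueError(f"unseen site x year cells: {sorted(unseen)}")
        levels = self.factor_levels_
        n_lev = len(levels)
        C = np.vstack([np.eye(n_lev - 1), -np.ones(n_lev - 1)])  # sum-to-zero
        onehot = np.zeros((len(df), n_lev))
        idx = {lev: i for i, lev in enumerate(levels)}
        onehot[np.arange(len(df)), [idx[c] for c in cell]] = 1.0
        return onehot @ C

    def _design(self, df: pd.DataFrame) -> np.ndarray:
        F = self._factor_design(df)
        Xh = self.hour_basis_.design(df["hour"].to_numpy(dtype=np.float64))
        Xd = self.doy_basis_.design(df["doy"].to_numpy(dtype=np.float64))
        return np.column_stack([np.ones(len(df)), F, Xh, Xd])

    # -- fitting ----------------------------------------------------------

    def fit(self, df: pd.DataFrame, y):
        y = np.asarray(y, dtype=np.float64).ravel()
        if "site" in df.columns and "year" in df.columns:
            cell = df["site"].astype(str) + ":" + df["year"].astype(str)
            self.factor_levels_ = sorted(cell.unique().tolist())
            counts = cell.value_counts()
            if (counts < 1).any():
                raise ValueError("empty site x year cell")
        else:
            self.factor_levels_ = []

        Xh_raw, Sh_raw, kh = cyclic_cubic_basis(
            df["hour"].to_numpy(dtype=np.float64), self.hour_period, self.k
        )
        Xh, Sh, Zh = _center_basis(Xh_raw, Sh_raw)
        self.hour_basis_ = CyclicBasis(
            self.hour_period, self.k, kh, Zh, Sh, Xh_raw.mean(axis=0)
        )
        Xd_raw, Sd_raw, kd = cyclic_cubic_basis(
            df["doy"].to_numpy(dtype=np.float64), self.doy_period, self.k
        )
        Xd, Sd, Zd = _center_basis(Xd_raw, Sd_raw)
        self.doy_basis_ = CyclicBasis(
            self.doy_period, self.k, kd, Zd, Sd, Xd_raw.mean(axis=0)
        )

        X = self._design(df)
        n, p = X.shape
        p_smooth = self.k - 1
        p_fix = p - 2 * p_smooth
        # penalties normalized to unit spectral norm so one lambda grid
        # spans negligible-to-dominant smoothing for both cycle lengths
        S_h = np.zeros((p, p))
        S_h[p_fix : p_fix + p_smooth, p_fix : p_fix + p_smooth] = Sh / np.linalg.norm(
            Sh, 2
        )
        S_d = np.zeros((p, p))
        S_d[p_fix + p_smooth :, p_fix + p_smooth :] = Sd / np.linalg.norm(Sd, 2)
        self._smooth_slices_ = {
            "hour": slice(p_fix, p_fix + p_smooth),
            "doy": slice(p_fix + p_smooth, p),
        }

        XtX = X.T @ X
        Xty = X.T @ y
        yty = float(y @ y)

        if self.fixed_lambda is not None:
            lam_h, lam_d = self.fixed_lambda
        else:
            lam_h, lam_d = self._gcv_search(XtX, Xty, yty, n, S_h, S_d)
        A = XtX + lam_h * S_h + lam_d * S_d
        # tiny ridge guards exact collinearity at lambda ~ 0
        A += 1e-10 * np.trace(XtX) / p * np.eye(p)
        beta = np.linalg.solve(A, Xty)
        H_inv_XtX = np.linalg.solve(A, XtX)
        edf = float(np.trace(H_inv_XtX))
        rss = yty - 2 * beta @ Xty + beta @ XtX @ beta
        sigma2 = max(rss, 0.0) / max(n - edf, 1.0)

        self.coef_ = beta
        self.lambda_ = (float(lam_h), float(lam_d))
        self.edf_ = edf
        self.edf_smooth_ = {
            name: float(np.trace(H_inv_XtX[sl, sl]))
            for name, sl in self._smooth_slices_.items()
        }
        self.sigma2_ = float(sigma2)
        self.posterior_cov_ = np.linalg.inv(A) * sigma2
        self.n_ = n
        return self

    def _gcv_search(self, XtX, Xty, yty, n, S_h, S_d):
        lo, hi, npts = self.lambda_grid
        grid = np.logspace(lo, hi, int(npts))
        best = (np.inf, grid[0], grid[0])
        p = XtX.shape[0]
        ridge = 1e-10 * np.trace(XtX) / p * np.eye(p)
        for lh in grid:
            for ld in grid:
                A = XtX + lh * S_h + ld * S_d + ridge
                try:
                    beta = np.linalg.solve(A, Xty)
                    tr = float(np.trace(np.linalg.solve(A, XtX)))
                except np.linalg.LinAlgError:
                    continue
                rss = max(yty - 2 * beta @ Xty + beta @ XtX @ beta, 0.0)
                denom = max(n - tr, 1e-8)
                gcv = n * rss / denom**2
                # strict inequality keeps the smallest lambda on a flat plateau
                if not np.isfinite(best[0]) or gcv < best[0] - 1e-12 * (
                    1 + abs(best[0])
                ):
                    best = (gcv, lh, ld)
        self.gcv_ = best[0]
        return best[1], best[2]

    # -- prediction -------------------------------------------------------

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "coef_")
        return self._design(df) @ self.coef_

    def predict_dist(self, df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """Mean and standard error of the fitted curve at the grid points."""
        check_is_fitted(self, "coef_")
        X = self._design(df)
        mean = X @ self.coef_
        var = np.einsum("ij,jk,ik->i", X, self.posterior_cov_, X)
        return mean, np.sqrt(np.maximum(var, 0.0))

    def smooth_component(self, name: str, x: np.ndarray) -> np.ndarray:
        """Evaluate one centered smooth (hour or doy) at values ``x``."""
        check_is_fitted(self, "coef_")
        basis = self.hour_basis_ if name == "hour" else self.doy_basis_
        return basis.design(np.asarray(x, dtype=np.float64)) @ self.coef_[
            self._smooth_slices_[name]
        ]
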