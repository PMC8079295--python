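"""Linear mixed-model fitting shared by the threshold and EOD analyses.

Estimation is delegated to statsmodels ``MixedLM`` with maximum likelihood
(not REML), so that residual sums of squares and likelihoods remain
comparable across candidate broken-stick splits with different fixed-effect
subsets.  On top of the fitted model this module computes

* conditional residuals (observed − fixed − predicted random effects) and
  their sum of squares, the quantity the split search minimizes;
* the Nakagawa variance decomposition (marginal / conditional R²), with the
  fixed-effect variance taken as the variance of the fixed-effect linear
  predictor over the data;
* Satterthwaite degrees of freedom for the fixed-effect t-tests, from the
  profile-ML likelihood of the variance components: for coefficient j with
  sampling variance f_j(θ) = [ (Σ_i X_i'V_i⁻¹X_i)⁻¹ ]_jj,
  df_j = 2 f_j² / (g_j' A g_j) where g_j = ∂f_j/∂θ (central differences) and
  A is the inverse observed information of θ from the profile likelihood.

A fit whose random-effect variance collapses to (numerically) zero falls
back to OLS with a logged flag; its t-tests then use the classical n − p
degrees of freedom.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sst
from statsmodels.regression.mixed_linear_model import MixedLM

from .errors import InsufficientDataError

logger = logging.getLogger(__name__)

_ZERO_RE_TOL = 1e-7  # cov_re below this fraction of the residual variance -> OLS


@dataclass(frozen=True)
class MixedTerm:
    """One fixed-effect coefficient with its Satterthwaite t-test."""
    name: str
    estimate: float
    se: float
    df: float
    t: float
    p: float


@dataclass
class MixedModelFit:
    """Fitted mixed (or fallback OLS) model for one data segment."""

    terms: list[MixedTerm]
    re_cov: np.ndarray             # random-effect covariance (q x q; q=1 for intercept)
    resid_var: float               # residual variance sigma^2
    conditional_residuals: np.ndarray
    rss: float                     # sum of squared conditional residuals
    var_fixed: float               # variance of the fixed-effect predictor
    var_random: float              # mean_i z_i' G z_i
    r2_marginal: float
    r2_conditional: float
    llf: float
    aic: float
    n_obs: int
    n_groups: int
    ols_fallback: bool = False

    def term(self, name: str) -> MixedTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    @property
    def coef(self) -> dict[str, float]:
        return {t.name: t.estimate for t in self.terms}


def nakagawa_r2(fit: MixedModelFit) -> tuple[float, float]:
    """Marginal and conditional R² by the variance-decomposition method.

    marginal = var_f / (var_f + var_r + var_e);
    conditional = (var_f + var_r) / (var_f + var_r + var_e).
    """
    total = fit.var_fixed + fit.var_random + fit.resid_var
    if total <= 0:
        raise InsufficientDataError("all variance components are zero; R² undefined")
    return (fit.var_fixed / total, (fit.var_fixed + fit.var_random) / total)


# ---------------------------------------------------------------------------
# profile-ML machinery for Satterthwaite DF
# ---------------------------------------------------------------------------

def _group_blocks(X: np.ndarray, y: np.ndarray, Z: np.ndarray,
                  groups: np.ndarray) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    blocks = []
    for g in pd.unique(groups):
        m = groups == g
        blocks.append((X[m], y[m], Z[m]))
    return blocks


def _theta_pack(G: np.ndarray, sigma2: float) -> np.ndarray:
    q = G.shape[0]
    tril = G[np.tril_indices(q)]
    return np.concatenate([tril, [sigma2]])


def _theta_unpack(theta: np.ndarray, q: int) -> tuple[np.ndarray, float]:
    G = np.zeros((q, q))
    G[np.tril_indices(q)] = theta[:-1]
    G = G + np.tril(G, -1).T
    return G, float(theta[-1])


def _beta_cov(theta: np.ndarray, blocks, q: int) -> np.ndarray:
    """(Sum_i X_i' V_i^-1 X_i)^-1 at the given variance components."""
    G, s2 = _theta_unpack(theta, q)
    p = blocks[0][0].shape[1]
    info = np.zeros((p, p))
    for Xi, _, Zi in blocks:
        Vi = s2 * np.eye(len(Xi)) + Zi @ G @ Zi.T
        info += Xi.T @ np.linalg.solve(Vi, Xi)
    return np.linalg.inv(info)


def _profile_loglik(theta: np.ndarray, blocks, q: int) -> float:
    G, s2 = _theta_unpack(theta, q)
    if s2 <= 0:
        return -np.inf
    p = blocks[0][0].shape[1]
    info = np.zeros((p, p))
    xty = np.zeros(p)
    pieces = []
    for Xi, yi, Zi in blocks:
        Vi = s2 * np.eye(len(Xi)) + Zi @ G @ Zi.T
        try:
            L = np.linalg.cholesky(Vi)
        except np.linalg.LinAlgError:
            return -np.inf
        Wx = np.linalg.solve(L, Xi)
        Wy = np.linalg.solve(L, yi)
        info += Wx.T @ Wx
        xty += Wx.T @ Wy
        pieces.append((L, Wy, Wx))
    beta = np.linalg.solve(info, xty)
    ll = 0.0
    for L, Wy, Wx in pieces:
        r = Wy - Wx @ beta
        ll -= np.sum(np.log(np.diag(L))) + 0.5 * (r @ r) + 0.5 * len(Wy) * np.log(2 * np.pi)
    return ll


def _satterthwaite(theta_hat: np.ndarray, blocks, q: int,
                   beta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (se, df) per fixed-effect coefficient."""
    p = len(beta)
    C = _beta_cov(theta_hat, blocks, q)
    se = np.sqrt(np.diag(C))

    steps = np.maximum(np.abs(theta_hat) * 1e-4, 1e-10)

    def cov_diag(th):
        return np.diag(_beta_cov(th, blocks, q))

    # gradient of each f_j wrt theta
    grad = np.zeros((p, len(theta_hat)))
    for k, h in enumerate(steps):
        tp, tm = theta_hat.copy(), theta_hat.copy()
        tp[k] += h
        tm[k] -= h
        grad[:, k] = (cov_diag(tp) - cov_diag(tm)) / (2 * h)

    # observed information of theta from the profile loglik
    m = len(theta_hat)
    H = np.zeros((m, m))
    f0 = _profile_loglik(theta_hat, blocks, q)
    hs = np.maximum(np.abs(theta_hat) * 1e-3, 1e-8)
    for a in range(m):
        for b in range(a, m):
            ta = theta_hat.copy(); ta[a] += hs[a]; ta[b] += hs[b]
            tb = theta_hat.copy(); tb[a] += hs[a]; tb[b] -= hs[b]
            tc = theta_hat.copy(); tc[a] -= hs[a]; tc[b] += hs[b]
            td = theta_hat.copy(); td[a] -= hs[a]; td[b] -= hs[b]
            H[a, b] = H[b, a] = (
                _profile_loglik(ta, blocks, q) - _profile_loglik(tb, blocks, q)
                - _profile_loglik(tc, blocks, q) + _profile_loglik(td, blocks, q)
            ) / (4 * hs[a] * hs[b])
    if not np.all(np.isfinite(H)) or not np.isfinite(f0):
        n_tot = sum(len(b[1]) for b in blocks)
        return se, np.full(p, float(n_tot - p))
    A = np.linalg.pinv(-H)

    df = np.empty(p)
    n_tot = sum(len(b[1]) for b in blocks)
    for j in range(p):
        denom = grad[j] @ A @ grad[j]
        if denom <= 0 or not np.isfinite(denom):
            df[j] = float(n_tot - p)
        else:
            df[j] = max(2.0 * C[j, j] ** 2 / denom, 1.0)
    return se, df


# ---------------------------------------------------------------------------
# public fitting entry point
# ---------------------------------------------------------------------------

def fit_mixed(X: np.ndarray, y: np.ndarray, Z: np.ndarray, groups: np.ndarray,
              names: list[str], compute_df: bool = True,
              ols: bool = False) -> MixedModelFit:
    """Fit y = Xβ + Z b_group + ε by ML; optionally plain OLS.

    ``Z`` is the per-observation random-effect design (n × q); the random
    effects are i.i.d. N(0, G) per group with unstructured q × q G.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    Z = np.asarray(Z, float)
    if Z.ndim == 1:
        Z = Z[:, None]
    groups = np.asarray(groups)
    n, p = X.shape
    q = Z.shape[1]
    n_groups = len(pd.unique(groups))
    if n <= p:
        raise InsufficientDataError(f"{n} observations cannot identify {p} fixed effects")

    if not ols and n_groups >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                model = MixedLM(y, X, groups=groups, exog_re=Z)
                res = None
                last_exc: Exception | None = None
                for meth in ("bfgs", "powell", "nm"):
                    try:
                        res = model.fit(reml=False, method=meth, maxiter=2000)
                        break
                    except (np.linalg.LinAlgError, ValueError) as exc:
                        last_exc = exc
                if res is None:
                    raise last_exc  # type: ignore[misc]
                G = np.atleast_2d(np.asarray(res.cov_re, float))
                s2 = float(res.scale)
                if np.trace(G) < _ZERO_RE_TOL * max(s2, 1e-12):
                    raise np.linalg.LinAlgError("random-effect variance ~ 0")
                beta = np.asarray(res.fe_params, float)
                # conditional residuals: subtract predicted random effects
                resid = y - X @ beta
                for g, b in res.random_effects.items():
                    m = groups == g
                    resid[m] -= Z[m] @ np.asarray(b, float)
                blocks = _group_blocks(X, y, Z, groups)
                theta = _theta_pack(G, s2)
                if compute_df:
                    se, df = _satterthwaite(theta, blocks, q, beta)
                else:
                    se = np.sqrt(np.diag(_beta_cov(theta, blocks, q)))
                    df = np.full(p, float(n - p))
                llf = float(res.llf)
                var_fixed = float(np.var(X @ beta, ddof=1)) if n > 1 else 0.0
                var_random = float(np.mean(np.einsum("ij,jk,ik->i", Z, G, Z)))
                vtot = var_fixed + var_random + s2
                tvals = beta / se
                terms = [MixedTerm(names[j], float(beta[j]), float(se[j]), float(df[j]),
                                   float(tvals[j]),
                                   float(2 * sst.t.sf(abs(tvals[j]), df[j])))
                         for j in range(p)]
                k = p + q * (q + 1) // 2 + 1
                return MixedModelFit(
                    terms=terms, re_cov=G, resid_var=s2,
                    conditional_residuals=resid, rss=float(resid @ resid),
                    var_fixed=var_fixed, var_random=var_random,
                    r2_marginal=var_fixed / vtot,
                    r2_conditional=(var_fixed + var_random) / vtot,
                    llf=llf, aic=2 * k - 2 * llf, n_obs=n, n_groups=n_groups)
            except (np.linalg.LinAlgError, ValueError) as exc:
                logger.info("mixed fit degenerate (%s); falling back to OLS", exc)

    # OLS path (requested, single group, or degenerate random effect)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    s2 = rss / max(n - p, 1)
    XtX_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.maximum(np.diag(XtX_inv) * s2, 0))
    df = np.full(p, float(n - p))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    var_fixed = float(np.var(X @ beta, ddof=1)) if n > 1 else 0.0
    vtot = var_fixed + s2
    llf = float(-0.5 * n * (np.log(2 * np.pi * rss / n) + 1)) if rss > 0 else np.inf
    terms = [MixedTerm(names[j], float(beta[j]), float(se[j]), float(df[j]),
                       float(tvals[j]), float(2 * sst.t.sf(abs(tvals[j]), df[j])))
             for j in range(p)]
    return MixedModelFit(
        terms=terms, re_cov=np.zeros((Z.shape[1], Z.shape[1])), resid_var=s2,
        conditional_residuals=resid, rss=rss,
        var_fixed=var_fixed, var_random=0.0,
        r2_marginal=var_fixed / vtot if vtot > 0 else np.nan,
        r2_conditional=var_fixed / vtot if vtot > 0 else np.nan,
        llf=llf, aic=2 * (p + 1) - 2 * llf if np.isfinite(llf) else -np.inf,
        n_obs=n, n_groups=n_groups, ols_fallback=not ols)
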