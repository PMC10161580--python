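"""Negative-binomial generalized linear models for count expression data.

The NB model for a gene's counts uses a log link with per-sample offsets
(log effective library sizes) and the variance function

    Var(y) = mu + phi * mu^2,

where ``phi`` is the dispersion (edgeR-style parameterization; ``phi = 0``
is the Poisson limit).  Fitting is iteratively reweighted least squares
(IRLS) at fixed ``phi``; dispersion is estimated per gene by maximizing
the Cox-Reid adjusted profile likelihood, optionally shrunk toward the
common (all-gene) dispersion.  Nested models are compared with a
quasi-likelihood F-test: the deviance difference scaled by a
quasi-dispersion estimated from the full model.  The quasi-dispersion
defaults to the Pearson statistic over its residual degrees of freedom
(the classical quasi-likelihood estimator, which calibrates the null
p-value distribution noticeably better at n ~ 41 than the deviance-based
variant); the deviance-based form remains available via ``ql_method``.

The batched fitter carries a leading "pair" axis so that thousands of
gene x variant models with tiny designs are solved with stacked linear
algebra instead of a Python loop.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import gammaln
from scipy.stats import f as f_dist

_ETA_CLIP = 50.0  # keeps exp(eta) finite without touching realistic fits


@dataclass
class NbGlmFit:
    """One fitted NB GLM (natural-log scale coefficients)."""

    coefficients: np.ndarray
    fitted_means: np.ndarray
    deviance: float
    residual_df: int
    dispersion: float
    quasi_dispersion: float
    converged: bool
    iterations: int
    design_rank: int


def nb_unit_deviance(y: np.ndarray, mu: np.ndarray, phi) -> np.ndarray:
    """Elementwise NB deviance contribution; Poisson limit at phi = 0."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-300)
    phi = np.asarray(phi, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ylogy = np.where(y > 0, y * np.log(np.maximum(y, 1e-300) / mu), 0.0)
    if np.all(phi == 0):
        return 2.0 * (ylogy - (y - mu))
    phi_safe = np.where(phi == 0, 1.0, phi)
    nb = 2.0 * (ylogy - (y + 1.0 / phi_safe) * (np.log1p(phi_safe * y) - np.log1p(phi_safe * mu)))
    pois = 2.0 * (ylogy - (y - mu))
    return np.where(phi == 0, pois, nb)


def nb_loglik(y: np.ndarray, mu: np.ndarray, phi) -> np.ndarray:
    """Elementwise NB log-likelihood; Poisson limit at phi = 0."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-300)
    phi = np.asarray(phi, dtype=float)
    pois = y * np.log(mu) - mu - gammaln(y + 1)
    if np.all(phi == 0):
        return pois
    phi_safe = np.where(phi == 0, 1.0, phi)
    r = 1.0 / phi_safe
    nb = (
        gammaln(y + r)
        - gammaln(r)
        - gammaln(y + 1)
        + y * np.log(phi_safe * mu)
        - (y + r) * np.log1p(phi_safe * mu)
    )
    return np.where(phi == 0, pois, nb)


def pearson_quasi_dispersion(y, mu, phi, df, weights=None):
    """Pearson X^2 / df: generalized Pearson quasi-dispersion estimate."""
    y = np.atleast_2d(np.asarray(y, dtype=float))
    mu = np.atleast_2d(np.asarray(mu, dtype=float))
    phi = np.asarray(phi, dtype=float).reshape(-1, 1)
    w = np.ones_like(y) if weights is None else np.broadcast_to(weights, y.shape)
    x2 = np.sum(w * (y - mu) ** 2 / (mu + phi * mu**2), axis=1)
    return x2 / np.maximum(df, 1)


def _as_batch(y, X, offset, phi, weights):
    """Broadcast inputs to (B, n), (B, n, p), (B, n), (B, 1), (B, n)."""
    y = np.atleast_2d(np.asarray(y, dtype=float))
    B, n = y.shape
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        X = np.broadcast_to(X, (B, *X.shape))
    if offset is None:
        offset = np.zeros((B, n))
    else:
        offset = np.broadcast_to(np.asarray(offset, dtype=float), (B, n))
    phi = np.asarray(phi, dtype=float).reshape(-1, 1)
    if phi.shape[0] == 1:
        phi = np.broadcast_to(phi, (B, 1))
    if weights is None:
        weights = np.ones((B, n))
    else:
        weights = np.broadcast_to(np.asarray(weights, dtype=float), (B, n))
    return y, X, offset, phi, weights


def nb_irls_batch(
    y,
    X,
    offset=None,
    phi=0.0,
    weights=None,
    max_iter: int = 50,
    tol: float = 1e-8,
):
    """Fit a batch of NB GLMs with log link and offsets by IRLS.

    Parameters
    ----------
    y : (B, n) or (n,) counts
    X : (B, n, p) or (n, p) design (shared designs are broadcast)
    offset : per-sample log-scale offsets, broadcastable to (B, n)
    phi : dispersion, scalar or (B,)
    weights : prior observation weights (0 excludes a sample), (B, n)

    Returns
    -------
    dict with ``beta`` (B, p), ``mu`` (B, n), ``deviance`` (B,),
    ``converged`` (B,), ``iterations`` (B,).
    """
    y, X, offset, phi, w0 = _as_batch(y, X, offset, phi, weights)
    B, n = y.shape
    p = X.shape[2]

    mu = np.maximum(y, 1.0 / 6.0)
    eta = np.log(mu)
    dev = nb_unit_deviance(y, mu, phi)
    dev = np.sum(w0 * dev, axis=1)
    beta = np.zeros((B, p))
    converged = np.zeros(B, dtype=bool)
    iters = np.zeros(B, dtype=int)

    for it in range(max_iter):
        W = w0 * mu / (1.0 + phi * mu)
        z = (eta - offset) + (y - mu) / mu
        A = np.einsum("bnp,bn,bnq->bpq", X, W, X, optimize=True)
        rhs = np.einsum("bnp,bn->bp", X, W * z, optimize=True)
        try:
            beta_new = np.linalg.solve(A, rhs[..., None])[..., 0]
        except np.linalg.LinAlgError:
            ridge = 1e-8 * np.maximum(np.trace(A, axis1=1, axis2=2), 1.0) / p
            A = A + ridge[:, None, None] * np.eye(p)
            beta_new = np.linalg.solve(A, rhs[..., None])[..., 0]
        step = beta_new - beta
        # step-halving on rows whose deviance increased
        scale = np.ones((B, 1))
        for _ in range(12):
            cand = beta + scale * step
            eta_new = np.clip(
                np.einsum("bnp,bp->bn", X, cand, optimize=True) + offset,
                -_ETA_CLIP,
                _ETA_CLIP,
            )
            mu_new = np.exp(eta_new)
            dev_new = np.sum(w0 * nb_unit_deviance(y, mu_new, phi), axis=1)
            worse = dev_new > dev * (1 + 1e-12) + 1e-10
            if not worse.any():
                break
            scale[worse] *= 0.5
        rel_change = np.abs(dev - dev_new) / (np.abs(dev_new) + 0.1)
        newly = (~converged) & (rel_change < tol)
        iters[~converged] = it + 1
        converged |= newly
        beta, eta, mu, dev = cand, eta_new, mu_new, dev_new
        if converged.all():
            break

    return {
        "beta": beta,
        "mu": mu,
        "deviance": dev,
        "converged": converged,
        "iterations": iters,
    }


def nb_irls_fit(
    y,
    X,
    offsets=None,
    dispersion: float = 0.0,
    weights=None,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> NbGlmFit:
    """Fit a single gene's NB GLM, dropping aliased design columns.

    Offsets are per-sample log effective library sizes.  Shifting all
    offsets by a constant shifts only the intercept, by minus that
    constant.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.shape[0]:
        raise ValueError("y and X have incompatible shapes")
    if offsets is not None and len(np.atleast_1d(offsets)) not in (1, y.shape[0]):
        raise ValueError("offsets length must match y")

    # drop aliased columns (pivoted QR)
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int(np.sum(diag > diag.max() * max(X.shape) * np.finfo(float).eps)) if diag.size else 0
    keep = np.sort(piv[:rank])
    if rank < X.shape[1]:
        warnings.warn(f"dropping {X.shape[1] - rank} aliased design column(s)", stacklevel=2)
    Xr = X[:, keep]

    res = nb_irls_batch(y, Xr, offset=offsets, phi=dispersion,
                        weights=weights, max_iter=max_iter, tol=tol)
    coef = np.full(X.shape[1], np.nan)
    coef[keep] = res["beta"][0]
    n_eff = y.shape[0] if weights is None else int(np.sum(np.asarray(weights) > 0))
    residual_df = n_eff - rank
    dev = float(res["deviance"][0])
    s2 = pearson_quasi_dispersion(
        y, res["mu"], dispersion, residual_df, weights=weights
    )[0] if residual_df > 0 else np.nan
    return NbGlmFit(
        coefficients=coef,
        fitted_means=res["mu"][0],
        deviance=dev,
        residual_df=residual_df,
        dispersion=float(dispersion),
        quasi_dispersion=float(s2),
        converged=bool(res["converged"][0]),
        iterations=int(res["iterations"][0]),
        design_rank=rank,
    )


def _cox_reid_apl(y_mat, X, offset, phi_grid, weights=None):
    """Cox-Reid adjusted profile log-likelihood on a dispersion grid.

    Returns an (n_genes, n_grid) matrix: for each gene and each candidate
    phi, the NB log-likelihood at the IRLS solution minus half the log
    determinant of the Fisher information (the Cox-Reid adjustment for
    estimating the coefficients).
    """
    y_mat = np.atleast_2d(y_mat)
    G = y_mat.shape[0]
    apl = np.empty((G, len(phi_grid)))
    for k, phi in enumerate(phi_grid):
        res = nb_irls_batch(y_mat, X, offset=offset, phi=phi, weights=weights)
        mu = res["mu"]
        w0 = np.ones_like(mu) if weights is None else np.broadcast_to(weights, mu.shape)
        ll = np.sum(w0 * nb_loglik(y_mat, mu, phi), axis=1)
        W = w0 * mu / (1.0 + phi * mu)
        Xb = np.broadcast_to(X, (G, *X.shape)) if np.asarray(X).ndim == 2 else X
        info = np.einsum("bnp,bn,bnq->bpq", Xb, W, Xb, optimize=True)
        sign, logdet = np.linalg.slogdet(info)
        apl[:, k] = ll - 0.5 * np.where(sign > 0, logdet, np.inf)
    return apl


def _grid_argmax_refined(obj: np.ndarray, log_grid: np.ndarray) -> np.ndarray:
    """Per-row argmax on a grid with parabolic refinement in log-phi."""
    idx = np.argmax(obj, axis=1)
    out = log_grid[idx].astype(float)
    inner = (idx > 0) & (idx < len(log_grid) - 1)
    i = idx[inner]
    rows = np.flatnonzero(inner)
    y0, y1, y2 = obj[rows, i - 1], obj[rows, i], obj[rows, i + 1]
    denom = y0 - 2 * y1 + y2
    ok = denom < -1e-12
    shift = np.zeros_like(y1)
    shift[ok] = 0.5 * (y0 - y2)[ok] / denom[ok]
    shift = np.clip(shift, -1.0, 1.0)
    h = log_grid[1] - log_grid[0]
    out[rows] = log_grid[i] + shift * h
    return out


def estimate_dispersion(
    counts,
    X,
    offsets=None,
    shrink_prior_df: float = 10.0,
    phi_min: float = 1e-6,
    phi_max: float = 10.0,
    grid_size: int = 25,
    weights=None,
):
    """Per-gene NB dispersion by Cox-Reid adjusted profile likelihood.

    Each gene's APL is evaluated on a log-spaced dispersion grid and
    combined with the all-gene mean APL curve, weighting the individual
    curve by its residual degrees of freedom and the common curve by
    ``shrink_prior_df``; the maximizer (parabolically refined on the log
    scale) is the estimate.  ``shrink_prior_df = 0`` disables shrinkage.

    Returns
    -------
    (phi, common_phi) : per-gene dispersion array and the common value.
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    X = np.asarray(X, dtype=float)
    n = counts.shape[1]
    rank = int(np.linalg.matrix_rank(X))
    residual_df = (n if weights is None else int(np.sum(np.asarray(weights) > 0))) - rank
    if residual_df < 1:
        raise ValueError("saturated design: no residual degrees of freedom")
    log_grid = np.linspace(np.log(phi_min), np.log(phi_max), grid_size)
    apl = _cox_reid_apl(counts, X, offsets, np.exp(log_grid), weights=weights)
    common_curve = apl.mean(axis=0)
    common_phi = float(np.exp(_grid_argmax_refined(common_curve[None, :], log_grid)[0]))
    w_ind = residual_df
    obj = (w_ind * apl + shrink_prior_df * common_curve[None, :]) / (w_ind + shrink_prior_df)
    phi = np.exp(_grid_argmax_refined(obj, log_grid))
    return np.clip(phi, phi_min, phi_max), common_phi


def ql_f_test(fit_full: NbGlmFit, fit_reduced: NbGlmFit, ql_method: str = "pearson"):
    """Quasi-likelihood F-test of a reduced model nested in a full model.

    F = ((dev_reduced - dev_full) / df1) / s2; df1 is the rank
    difference, df2 the full model's residual df, and s2 the full
    model's quasi-dispersion — Pearson X^2 / df2 (default) or
    deviance / df2 (``ql_method='deviance'``).  The p-value is the upper
    tail of F(df1, df2).
    """
    if fit_full.dispersion != fit_reduced.dispersion:
        raise ValueError("full and reduced fits must share the dispersion")
    df1 = fit_reduced.residual_df - fit_full.residual_df
    if df1 <= 0:
        raise ValueError("reduced model is not strictly nested in full (df1 = 0)")
    s2 = (
        fit_full.quasi_dispersion
        if ql_method == "pearson"
        else fit_full.deviance / fit_full.residual_df
    )
    return ql_f_from_deviances(
        np.array([fit_full.deviance]),
        np.array([fit_reduced.deviance]),
        df1,
        fit_full.residual_df,
        s2=np.array([s2]),
    )


def ql_f_from_deviances(dev_full, dev_reduced, df1: int, df2, s2=None):
    """Vectorized QL F statistic and p-value.

    ``s2`` is the per-test quasi-dispersion; when omitted it falls back
    to the deviance-based estimate ``dev_full / df2``.  Small negative
    deviance differences (within convergence tolerance) are clipped to
    zero; larger ones indicate a failed fit and are flagged with a
    warning and a NaN p-value.
    """
    dev_full = np.asarray(dev_full, dtype=float)
    dev_reduced = np.asarray(dev_reduced, dtype=float)
    df2 = np.asarray(df2, dtype=float)
    diff = dev_reduced - dev_full
    bad = diff < -1e-6 * np.maximum(np.abs(dev_full), 1.0)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} test(s) with reduced deviance < full deviance; flagged NaN",
            stacklevel=2,
        )
    diff = np.clip(diff, 0.0, None)
    if s2 is None:
        s2 = dev_full / np.maximum(df2, 1.0)
    s2 = np.maximum(np.asarray(s2, dtype=float), 1e-300)
    F = (diff / df1) / s2
    p = f_dist.sf(F, df1, df2)
    p = np.where(bad, np.nan, p)
    F = np.where(bad, np.nan, F)
    if F.shape == (1,):
        return float(F[0]), df1, float(df2) if df2.ndim == 0 else float(df2[0]), float(p[0])
    return F, df1, df2, p


def poisson_closed_form_check() -> None:  # pragma: no cover - convenience anchor
    """See tests: at phi -> 0 the IRLS solution matches Poisson regression."""
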