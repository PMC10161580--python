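"""Linear-model eQTL scans on inverse-normal-transformed expression.

This is the GTEx-style framework: expression is TMM-CPM inverse-normal
transformed per gene, then every gene x variant pair is tested with
ordinary least squares — either an additive model (genotype coded 0/1/2,
two-sided t-test on the slope) or an ANOVA model (genotype as a 3-level
factor, 2-df F-test against the covariates-only model).  All pairs are
tested (trans included) against a genome-wide nominal threshold.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

from .expression import TransformedExpression
from .genotypes import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

#: Smallest positive normal double; p-value underflow floor.
P_FLOOR = float(np.finfo(np.float64).tiny)

RESULT_COLUMNS = [
    "gene_id", "variant_id", "framework", "model", "effect",
    "mean_ref", "mean_het", "mean_alt",
    "statistic", "df1", "df2", "p", "q", "significant", "p_floored",
]


def _floor_p(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    floored = p < P_FLOOR
    return np.maximum(p, P_FLOOR), floored


def _covariate_block(covariates, n: int) -> np.ndarray:
    if covariates is None:
        return np.empty((n, 0))
    cov = np.atleast_2d(np.asarray(covariates, dtype=float))
    if cov.shape[0] != n:
        cov = cov.T
    if cov.shape[0] != n:
        raise ValueError("covariates do not match sample count")
    return cov


def _ols_rss(X: np.ndarray, Y: np.ndarray):
    """Batched OLS of every row of Y on a shared design X.

    Returns (beta (G, p), rss (G,), XtX_inv (p, p)).
    """
    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    beta = Y @ X @ XtX_inv
    resid = Y - beta @ X.T
    return beta, np.einsum("gn,gn->g", resid, resid), XtX_inv


def additive_scan_linear(
    expr: TransformedExpression,
    gm: GenotypeMatrix,
    covariates=None,
) -> pd.DataFrame:
    """Per-pair OLS of expression on alternate-allele count (0/1/2).

    Samples with a missing genotype are dropped per variant.  Variants
    left with fewer than three distinct genotype values are skipped
    (recorded in ``df.attrs['skipped']``).  Returns one row per tested
    pair with the slope, t statistic, degrees of freedom and p-value.
    """
    return _linear_scan(expr, gm, covariates, model="additive")


def anova_scan_linear(
    expr: TransformedExpression,
    gm: GenotypeMatrix,
    covariates=None,
) -> pd.DataFrame:
    """Per-pair 2-df F-test of genotype as a 3-level factor vs covariates only."""
    return _linear_scan(expr, gm, covariates, model="anova")


def _linear_scan(expr, gm, covariates, model: str) -> pd.DataFrame:
    if expr.samples != gm.samples:
        raise ValueError("expression and genotype samples are not aligned")
    Y_all = np.asarray(expr.values, dtype=float)
    gene_ids = np.asarray(expr.gene_ids)
    vids = gm.variant_ids().to_numpy()
    n = len(gm.samples)
    cov_all = _covariate_block(covariates, n)

    frames: list[pd.DataFrame] = []
    skipped: list[dict] = []
    for v in range(gm.n_variants):
        g = gm.codes[v].astype(float)
        mask = gm.codes[v] != MISSING
        gv = g[mask]
        classes = np.unique(gv)
        if len(classes) < 3:
            skipped.append({
                "variant_id": vids[v],
                "reason": "lt3_genotype_values" if model == "additive" else "empty_genotype_class",
            })
            continue
        Y = Y_all[:, mask]
        cov = cov_all[mask]
        ones = np.ones((mask.sum(), 1))

        if model == "additive":
            X = np.hstack([ones, gv[:, None], cov])
            beta, rss, XtX_inv = _ols_rss(X, Y)
            df2 = mask.sum() - X.shape[1]
            sigma2 = rss / df2
            se = np.sqrt(np.maximum(sigma2 * XtX_inv[1, 1], 0.0))
            with np.errstate(divide="ignore", invalid="ignore"):
                tstat = np.where(se > 0, beta[:, 1] / se, np.inf * np.sign(beta[:, 1]))
            p = 2.0 * t_dist.sf(np.abs(tstat), df2)
            p, floored = _floor_p(p)
            frames.append(pd.DataFrame({
                "gene_id": gene_ids, "variant_id": vids[v],
                "framework": "linear_int", "model": "additive",
                "effect": beta[:, 1],
                "mean_ref": np.nan, "mean_het": np.nan, "mean_alt": np.nan,
                "statistic": tstat, "df1": 1, "df2": df2,
                "p": p, "p_floored": floored, "rss": rss,
            }))
        else:
            X_red = np.hstack([ones, cov])
            het = (gv == 1).astype(float)[:, None]
            alt = (gv == 2).astype(float)[:, None]
            X_full = np.hstack([X_red, het, alt])
            _, rss_red, _ = _ols_rss(X_red, Y)
            _, rss_full, _ = _ols_rss(X_full, Y)
            df1 = 2
            df2 = mask.sum() - X_full.shape[1]
            with np.errstate(divide="ignore", invalid="ignore"):
                F = ((rss_red - rss_full) / df1) / (rss_full / df2)
            F = np.where(rss_full > 0, F, np.inf)
            p = f_dist.sf(F, df1, df2)
            p, floored = _floor_p(p)
            frames.append(pd.DataFrame({
                "gene_id": gene_ids, "variant_id": vids[v],
                "framework": "linear_int", "model": "anova",
                "effect": np.nan,
                "mean_ref": Y[:, gv == 0].mean(axis=1),
                "mean_het": Y[:, gv == 1].mean(axis=1),
                "mean_alt": Y[:, gv == 2].mean(axis=1),
                "statistic": F, "df1": df1, "df2": df2,
                "p": p, "p_floored": floored, "rss": rss_full,
            }))

    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        out = pd.DataFrame(columns=[c for c in RESULT_COLUMNS if c not in ("q", "significant")])
    out["q"] = bh_fdr(out["p"].to_numpy()) if len(out) else []
    out = out.sort_values(["p", "gene_id", "variant_id"], kind="mergesort").reset_index(drop=True)
    out.attrs["skipped"] = skipped
    if skipped:
        logger.info("%s linear scan skipped %d variant(s)", model, len(skipped))
    return out


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (with monotonicity)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([])
    return multipletests(p, method="fdr_bh")[1]


def apply_threshold(results: pd.DataFrame, threshold: float = 5e-8) -> pd.DataFrame:
    """Flag rows significant when p is strictly below the nominal threshold."""
    out = results.copy()
    out["significant"] = out["p"] < threshold
    out.attrs = dict(results.attrs)
    out.attrs["threshold"] = threshold
    logger.info(
        "apply_threshold: %d/%d significant at p < %.3g (-log10 = %.1f)",
        int(out["significant"].sum()), len(out), threshold, -np.log10(threshold),
    )
    return out
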