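"""eQTL scans under the differential-gene-expression (NB GLM) framework.

Raw counts are modeled directly: per gene x variant pair a negative
binomial GLM with log link, log effective-library-size offsets (TMM), a
categorical collection-site covariate, and the genotype term of interest
is compared against the covariates-only model with a quasi-likelihood
F-test.  Four genotype parameterizations are supported:

* ``anova`` — genotype as a 3-level factor (2 df), tier 1 of the
  dominance procedure;
* ``contrast_ref_dom`` — AA vs {AB, BB} (pseudo-coded 0/1/1), tier 2;
* ``contrast_alt_dom`` — {AA, AB} vs BB (pseudo-coded 0/0/1), tier 2;
* ``additive`` — genotype as a numeric 0/1/2 regressor (1 df).

Tier-2 contrasts are run only on tier-1-significant pairs; a pair
significant under both the ANOVA-tier procedure and the additive scan is
reported once, from the ANOVA tier (the overlap-reporting rule), and the
significant contrast determines which allele is dominant.

Dispersion is estimated once per gene under the covariates-only design
and reused across that gene's variant models.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .expression import CountMatrix, NormFactors
from .genotypes import MISSING, GenotypeMatrix
from .linear_scan import P_FLOOR, bh_fdr
from .nbglm import (
    estimate_dispersion,
    nb_irls_batch,
    pearson_quasi_dispersion,
    ql_f_from_deviances,
)

logger = logging.getLogger(__name__)

LN2 = float(np.log(2.0))

NB_MODELS = ("anova", "additive", "contrast_ref_dom", "contrast_alt_dom")


def _site_levels(site, samples) -> np.ndarray:
    if site is None:
        return np.zeros(len(samples), dtype=int)
    site = pd.Series(np.asarray(site), index=samples)
    levels = sorted(map(str, pd.unique(site.astype(str))))
    return site.astype(str).map({lv: i for i, lv in enumerate(levels)}).to_numpy()


def _design_base(site_codes: np.ndarray) -> np.ndarray:
    """Intercept plus full-rank dummy block for site (first level reference)."""
    n = len(site_codes)
    levels = np.unique(site_codes)
    cols = [np.ones((n, 1))]
    for lv in levels[1:]:
        cols.append((site_codes == lv).astype(float)[:, None])
    return np.hstack(cols)


def estimate_gene_dispersions(
    cm: CountMatrix,
    site,
    nf: NormFactors,
    shrink_prior_df: float = 10.0,
):
    """Per-gene NB dispersion under the covariates-only (intercept + site) design."""
    site_codes = _site_levels(site, cm.samples)
    X0 = _design_base(site_codes)
    offsets = np.log(nf.effective_size)
    phi, common = estimate_dispersion(
        cm.counts, X0, offsets=offsets, shrink_prior_df=shrink_prior_df
    )
    logger.info("estimate_gene_dispersions: common dispersion %.4g", common)
    return phi


def _genotype_columns(gv: np.ndarray, model: str):
    """Design columns and validity for one variant's non-missing genotypes.

    Returns (columns (n, k) or None, skip_reason or None).
    """
    present = set(np.unique(gv).astype(int))
    if model == "anova":
        if present != {0, 1, 2}:
            return None, "empty_genotype_class"
        return np.column_stack([(gv == 1).astype(float), (gv == 2).astype(float)]), None
    if model == "additive":
        if len(present) < 2:
            return None, "constant_genotype"
        return gv.astype(float)[:, None], None
    if model == "contrast_ref_dom":
        reg = (gv >= 1).astype(float)
        if reg.min() == reg.max():
            return None, "constant_contrast"
        return reg[:, None], None
    if model == "contrast_alt_dom":
        reg = (gv == 2).astype(float)
        if reg.min() == reg.max():
            return None, "constant_contrast"
        return reg[:, None], None
    raise ValueError(f"unknown model {model!r}")


def nb_scan(
    cm: CountMatrix,
    gm: GenotypeMatrix,
    site,
    nf: NormFactors,
    model: str,
    dispersion=None,
    pairs: dict[str, np.ndarray] | None = None,
    shrink_prior_df: float = 10.0,
    ql_method: str = "pearson",
) -> pd.DataFrame:
    """Generic NB QL F-test scan of one genotype parameterization.

    ``pairs`` optionally restricts testing to ``{variant_id: gene index
    array}`` (used by tier 2).  Samples with missing genotypes are
    dropped per variant, and the covariates-only model is refit on the
    same samples so the two deviances are comparable.
    """
    if model not in NB_MODELS:
        raise ValueError(f"model must be one of {NB_MODELS}")
    if cm.samples != gm.samples:
        raise ValueError("count matrix and genotype samples are not aligned")
    if nf.samples != cm.samples:
        raise ValueError("normalization factors do not match samples")

    counts = cm.counts.astype(float)
    offsets_all = np.log(nf.effective_size)
    site_codes_all = _site_levels(site, cm.samples)
    gene_ids = cm.genes["id"].to_numpy()
    vids = gm.variant_ids().to_numpy()

    if dispersion is None:
        dispersion = estimate_gene_dispersions(cm, site, nf, shrink_prior_df)
    dispersion = np.asarray(dispersion, dtype=float)

    reduced_cache: dict[bytes, tuple] = {}
    frames: list[pd.DataFrame] = []
    skipped: list[dict] = []

    for v in range(gm.n_variants):
        if pairs is not None and vids[v] not in pairs:
            continue
        gene_idx = np.arange(len(gene_ids)) if pairs is None else np.asarray(pairs[vids[v]])
        if gene_idx.size == 0:
            continue
        mask = gm.codes[v] != MISSING
        gv = gm.codes[v][mask].astype(float)
        cols, reason = _genotype_columns(gv, model)
        if cols is None:
            skipped.append({"variant_id": vids[v], "reason": reason})
            continue

        X_red = _design_base(site_codes_all[mask])
        X_full = np.hstack([X_red, cols])
        if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
            skipped.append({"variant_id": vids[v], "reason": "aliased_design"})
            continue
        n_eff = int(mask.sum())
        off = offsets_all[mask]

        key = mask.tobytes()
        if key not in reduced_cache:
            red = nb_irls_batch(counts[:, mask], X_red, offset=off, phi=dispersion)
            reduced_cache[key] = (red["deviance"], X_red.shape[1])
        dev_red_all, rank_red = reduced_cache[key]
        dev_red = dev_red_all[gene_idx]

        y = counts[np.ix_(gene_idx, np.flatnonzero(mask))]
        phi_g = dispersion[gene_idx]
        full = nb_irls_batch(y, X_full, offset=off, phi=phi_g)
        df1 = X_full.shape[1] - rank_red
        df2 = n_eff - X_full.shape[1]
        if ql_method == "pearson":
            s2 = pearson_quasi_dispersion(y, full["mu"], phi_g, df2)
        else:
            s2 = full["deviance"] / max(df2, 1)
        F, _, _, p = ql_f_from_deviances(full["deviance"], dev_red, df1, df2, s2=s2)
        F, p = np.atleast_1d(F), np.atleast_1d(p)
        floored = p < P_FLOOR
        p = np.maximum(p, P_FLOOR)

        beta = full["beta"]
        if model == "anova":
            effect = np.full(len(gene_idx), np.nan)
            effect_log2 = np.full(len(gene_idx), np.nan)
            lfc_het = beta[:, rank_red] / LN2
            lfc_alt = beta[:, rank_red + 1] / LN2
        else:
            effect = beta[:, rank_red]
            effect_log2 = effect / LN2
            lfc_het = np.nan
            lfc_alt = np.nan
        frames.append(pd.DataFrame({
            "gene_id": gene_ids[gene_idx], "variant_id": vids[v],
            "framework": "nb_glm", "model": model,
            "effect": effect, "effect_log2": effect_log2,
            "lfc_het": lfc_het, "lfc_alt": lfc_alt,
            "statistic": F, "df1": df1, "df2": df2,
            "p": p, "p_floored": floored,
            "deviance": full["deviance"],
            "dispersion": phi_g,
            "quasi_dispersion": np.broadcast_to(s2, F.shape),
            "converged": full["converged"],
        }))

    if frames:
        out = pd.concat(frames, ignore_index=True)
        out["q"] = bh_fdr(out["p"].to_numpy())
    else:
        out = pd.DataFrame(columns=[
            "gene_id", "variant_id", "framework", "model", "effect", "effect_log2",
            "lfc_het", "lfc_alt", "statistic", "df1", "df2", "p", "p_floored",
            "deviance", "dispersion", "quasi_dispersion", "converged", "q",
        ])
    out = out.sort_values(["p", "gene_id", "variant_id"], kind="mergesort").reset_index(drop=True)
    out.attrs["skipped"] = skipped
    if skipped:
        logger.info("nb %s scan skipped %d variant(s)", model, len(skipped))
    return out


def nb_anova_tier1(cm, gm, site, nf, dispersion=None, shrink_prior_df: float = 10.0) -> pd.DataFrame:
    """Tier 1: 2-df QL F-test of genotype-as-factor vs intercept + site."""
    return nb_scan(cm, gm, site, nf, "anova", dispersion, shrink_prior_df=shrink_prior_df)


def nb_additive(cm, gm, site, nf, dispersion=None, shrink_prior_df: float = 10.0) -> pd.DataFrame:
    """1-df QL F-test of genotype as a numeric 0/1/2 regressor."""
    return nb_scan(cm, gm, site, nf, "additive", dispersion, shrink_prior_df=shrink_prior_df)


def nb_contrast_tier2(
    tier1_results: pd.DataFrame,
    cm, gm, site, nf,
    dispersion=None,
    threshold: float = 5e-8,
    shrink_prior_df: float = 10.0,
) -> pd.DataFrame:
    """Tier 2: both pseudo-coded dominance contrasts on tier-1-significant pairs.

    ``contrast_ref_dom`` recodes genotypes AA -> 0, {AB, BB} -> 1 and
    ``contrast_alt_dom`` recodes {AA, AB} -> 0, BB -> 1; each is a 1-df
    QL F-test with the site covariate and offsets.
    """
    hits = tier1_results[tier1_results["p"] < threshold]
    if hits.empty:
        out = pd.DataFrame()
        out.attrs["skipped"] = []
        return out
    gene_pos = {g: i for i, g in enumerate(cm.genes["id"])}
    pairs: dict[str, np.ndarray] = {
        vid: np.array([gene_pos[g] for g in sub["gene_id"]])
        for vid, sub in hits.groupby("variant_id", sort=False)
    }
    parts = [
        nb_scan(cm, gm, site, nf, contrast, dispersion, pairs=pairs,
                shrink_prior_df=shrink_prior_df)
        for contrast in ("contrast_ref_dom", "contrast_alt_dom")
    ]
    out = pd.concat(parts, ignore_index=True)
    out.attrs["skipped"] = parts[0].attrs["skipped"] + parts[1].attrs["skipped"]
    return out


def classify_modes(
    anova_tier_results: pd.DataFrame,
    additive_results: pd.DataFrame,
    threshold: float = 5e-8,
) -> pd.DataFrame:
    """Classify significant eQTLs as dominance or additive allelic modes.

    ``anova_tier_results`` holds tier-1 (``model == 'anova'``) and
    tier-2 contrast rows together.  Every pair significant in tier 1 is
    reported once from the ANOVA tier (pairs also significant in the
    additive scan are not double-reported — the overlap-reporting rule);
    pairs significant only in the additive scan are additive eQTLs.

    For a tier-1-significant pair the allelic mode is decided by which
    1-df reduction of the 3-level factor model fits best (smallest NB
    deviance among the two dominance contrasts and the numeric additive
    model — all three have equal complexity, so this is a direct
    goodness-of-fit comparison): a winning AA vs {AB, BB} contrast means
    the alternate allele is dominant, a winning {AA, AB} vs BB contrast
    means the reference allele is dominant, and a winning numeric model
    means the pattern is additive.  Pairs where neither a contrast nor
    the additive model reaches the significance threshold carry the mode
    ``unresolved`` rather than a silently assigned label.  Significance
    of a contrast alone does not separate the two patterns: a strong
    additive effect often leaves exactly one contrast significant while
    its group-mean misfit inflates the quasi-dispersion.
    """
    def rows(df, model):
        cols = ["gene_id", "variant_id", "p", "deviance"]
        if df is None or df.empty:
            return pd.DataFrame(columns=cols)
        sub = df[df["model"] == model]
        return sub[[c for c in cols if c in sub.columns]]

    tier1 = rows(anova_tier_results, "anova")
    ref_dom = rows(anova_tier_results, "contrast_ref_dom").set_index(["gene_id", "variant_id"])
    alt_dom = rows(anova_tier_results, "contrast_alt_dom").set_index(["gene_id", "variant_id"])
    additive = rows(additive_results, "additive").set_index(["gene_id", "variant_id"])

    anova_set = set(zip(tier1.loc[tier1["p"] < threshold, "gene_id"],
                        tier1.loc[tier1["p"] < threshold, "variant_id"]))
    additive_set = set(additive.index[additive["p"] < threshold]) if len(additive) else set()

    calls = []
    for g, v in sorted(anova_set):
        candidates = {}  # mode label -> (deviance, source, dominant_allele)
        any_sig = False
        for tab, label, allele in (
            (ref_dom, "contrast_ref_dom", "alt"),
            (alt_dom, "contrast_alt_dom", "ref"),
            (additive, "additive", None),
        ):
            if (g, v) in tab.index:
                p_sub = float(tab.at[(g, v), "p"])
                any_sig |= p_sub < threshold
                mode = "dominance" if allele else "additive"
                dev = float(tab.at[(g, v), "deviance"])
                if label not in candidates or dev < candidates[label][0]:
                    candidates[label] = (dev, mode, allele)
        if not any_sig or not candidates:
            calls.append({
                "gene_id": g, "variant_id": v, "mode": "unresolved",
                "source_tests": "anova", "dominant_allele": None,
            })
            continue
        best = min(candidates.items(), key=lambda kv: kv[1][0])
        label, (_, mode, allele) = best
        calls.append({
            "gene_id": g, "variant_id": v, "mode": mode,
            "source_tests": f"anova+{label}", "dominant_allele": allele,
        })
    for g, v in sorted(additive_set - anova_set):
        calls.append({
            "gene_id": g, "variant_id": v, "mode": "additive",
            "source_tests": "additive", "dominant_allele": None,
        })
    out = pd.DataFrame(calls, columns=["gene_id", "variant_id", "mode",
                                       "source_tests", "dominant_allele"])
    assert not out.duplicated(["gene_id", "variant_id"]).any()
    return out
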