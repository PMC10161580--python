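"""End-to-end drivers tying normalization, scans and classification together."""

from __future__ import annotations

import pandas as pd

from . import linear_scan as ls
from . import nbglm_scan as ns
from .expression import CountMatrix, NormFactors, inverse_normal, tmm_cpm, tmm_factors
from .genotypes import GenotypeMatrix


def run_all_scans(
    cm: CountMatrix,
    gm: GenotypeMatrix,
    site=None,
    nf: NormFactors | None = None,
    shrink_prior_df: float = 10.0,
) -> dict[tuple[str, str], pd.DataFrame]:
    """Run every model of both frameworks on all gene x variant pairs.

    Linear scans run on inverse-normal-transformed TMM-CPM without
    covariates; NB scans run on raw counts with TMM offsets and the site
    covariate, contrasts included un-gated (used for calibration — the
    reporting pipeline gates contrasts on tier-1 significance instead).
    """
    nf = nf or tmm_factors(cm)
    expr = inverse_normal(tmm_cpm(cm, nf))
    phi = ns.estimate_gene_dispersions(cm, site, nf, shrink_prior_df)
    out: dict[tuple[str, str], pd.DataFrame] = {
        ("linear_int", "additive"): ls.additive_scan_linear(expr, gm),
        ("linear_int", "anova"): ls.anova_scan_linear(expr, gm),
    }
    for model in ns.NB_MODELS:
        out[("nb_glm", model)] = ns.nb_scan(cm, gm, site, nf, model, dispersion=phi)
    return out


def run_nb_two_tier(
    cm: CountMatrix,
    gm: GenotypeMatrix,
    site=None,
    nf: NormFactors | None = None,
    threshold: float = 5e-8,
    shrink_prior_df: float = 10.0,
):
    """The full DGE-framework procedure: tier-1 ANOVA, gated tier-2
    contrasts, the additive scan, and the dominance/additive mode calls.

    Returns (anova_tier_results, additive_results, mode_calls) where
    ``anova_tier_results`` concatenates tier-1 and tier-2 rows.
    """
    nf = nf or tmm_factors(cm)
    phi = ns.estimate_gene_dispersions(cm, site, nf, shrink_prior_df)
    tier1 = ns.nb_anova_tier1(cm, gm, site, nf, dispersion=phi)
    tier2 = ns.nb_contrast_tier2(tier1, cm, gm, site, nf, dispersion=phi, threshold=threshold)
    additive = ns.nb_additive(cm, gm, site, nf, dispersion=phi)
    anova_tier = pd.concat([tier1, tier2], ignore_index=True) if not tier2.empty else tier1
    calls = ns.classify_modes(anova_tier, additive, threshold=threshold)
    return anova_tier, additive, calls
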