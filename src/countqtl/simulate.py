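"""Synthetic genotype/count data with known eQTL effects.

The generator emulates the data structure both eQTL frameworks assume:
Hardy-Weinberg genotypes at a given minor-allele frequency, negative-
binomially distributed counts with per-sample library-size factors (drawn
uniformly on a log scale, which also perturbs TMM composition), a
categorical collection-site effect on the log-mean scale, and planted
genotype effects that are additive or completely dominant on the
log-mean scale.

Default scenario: 41 samples (the study design size after the
shallow-sample drop), 200 genes x 50 SNPs, MAF 0.3, dispersion 0.2 —
small enough that every scan runs in minutes on one CPU while keeping
the per-test sample size of the study.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .expression import CountMatrix
from .genotypes import GenotypeMatrix

EFFECT_MODES = ("additive", "dominance_alt", "dominance_ref")


@dataclass
class EffectSpec:
    """One planted eQTL: gene/SNP indices, allelic mode, natural-log effect."""

    gene: int
    snp: int
    mode: str  # additive | dominance_alt | dominance_ref
    beta: float

    def __post_init__(self) -> None:
        if self.mode not in EFFECT_MODES:
            raise ValueError(f"unknown effect mode {self.mode!r}")


@dataclass
class SimulationScenario:
    """Parameters of one simulated genotype/expression dataset.

    ``dispersion`` is the NB dispersion phi in Var = mu + phi * mu^2
    (phi = 0 gives Poisson counts).  ``libsize_range`` bounds the
    multiplicative per-sample library-size factors (uniform on the log
    scale).  ``site_effect`` is the natural-log expression shift per
    collection-site level.  When ``ensure_testable`` is set, SNP columns
    are redrawn until every genotype class has at least
    ``min_per_class`` samples, i.e. genotypes are conditioned on passing
    the per-class QC rule — the situation in which any scan would run.
    """

    n_samples: int = 41
    maf: float = 0.3
    n_genes: int = 200
    n_snps: int = 50
    baseline_mu: float = 100.0
    dispersion: float = 0.2
    libsize_range: tuple[float, float] = (0.5, 2.0)
    site_levels: int = 2
    site_effect: float = 0.0
    effects: list[EffectSpec] = field(default_factory=list)
    seed: int = 0
    ensure_testable: bool = True
    min_per_class: int = 5

    def __post_init__(self) -> None:
        if not (0 < self.maf <= 0.5):
            raise ValueError("maf must be in (0, 0.5]")
        if self.dispersion < 0 or self.baseline_mu <= 0:
            raise ValueError("dispersion must be >= 0 and baseline_mu > 0")
        self.effects = [
            e if isinstance(e, EffectSpec) else EffectSpec(**e) for e in self.effects
        ]
        for e in self.effects:
            if not (0 <= e.gene < self.n_genes and 0 <= e.snp < self.n_snps):
                raise ValueError("effect gene/snp index out of range")


@dataclass
class TruthRecord:
    """Everything needed to score a scan's calls against the simulation."""

    effects: list[EffectSpec]
    genotype_counts: list[tuple[int, int, int]]
    library_sizes: list[float]
    scenario: dict

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "effects": [asdict(e) for e in self.effects],
                    "genotype_counts": self.genotype_counts,
                    "library_sizes": self.library_sizes,
                    "scenario": self.scenario,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path: str) -> "TruthRecord":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            effects=[EffectSpec(**e) for e in d["effects"]],
            genotype_counts=[tuple(c) for c in d["genotype_counts"]],
            library_sizes=d["library_sizes"],
            scenario=d["scenario"],
        )


def simulate_genotypes(n: int, maf: float, rng: np.random.Generator) -> np.ndarray:
    """One SNP column of n genotypes under Hardy-Weinberg proportions."""
    if not (0 < maf <= 0.5):
        raise ValueError("maf must be in (0, 0.5]")
    p = maf
    return rng.choice(3, size=n, p=[(1 - p) ** 2, 2 * p * (1 - p), p**2]).astype(np.int8)


def _effect_multiplier(mode: str, codes: np.ndarray, beta: float) -> np.ndarray:
    if mode == "additive":
        return np.exp(beta * codes)
    if mode == "dominance_alt":
        return np.exp(beta * (codes >= 1))
    if mode == "dominance_ref":
        return np.exp(beta * (codes == 2))
    raise ValueError(f"unknown effect mode {mode!r}")


def simulate_counts(scenario: SimulationScenario):
    """Draw one dataset: (CountMatrix, GenotypeMatrix, site Series, TruthRecord).

    Counts follow NB(mean = baseline_mu * L_j * exp(site + effect),
    dispersion phi).  Gene g occupies [g*10_000 + 1, g*10_000 + 5_000]
    on chromosome "1" and SNP s sits at s*10_000 + 2_500, so SNP i is
    inside gene i's model (cis) and distant from all others.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)

    codes = np.empty((sc.n_snps, sc.n_samples), dtype=np.int8)
    for s in range(sc.n_snps):
        col = simulate_genotypes(sc.n_samples, sc.maf, rng)
        if sc.ensure_testable:
            for _ in range(10_000):
                counts = np.bincount(col, minlength=3)
                if counts.min() >= sc.min_per_class:
                    break
                col = simulate_genotypes(sc.n_samples, sc.maf, rng)
            else:
                raise RuntimeError("could not draw a QC-passing SNP column")
        codes[s] = col

    lo, hi = sc.libsize_range
    L = np.exp(rng.uniform(np.log(lo), np.log(hi), size=sc.n_samples))
    site_assign = rng.permutation(np.arange(sc.n_samples) % sc.site_levels)
    site_mult = np.exp(sc.site_effect * site_assign)

    mu = np.broadcast_to(
        sc.baseline_mu * L * site_mult, (sc.n_genes, sc.n_samples)
    ).copy()
    for e in sc.effects:
        mu[e.gene] = mu[e.gene] * _effect_multiplier(e.mode, codes[e.snp], e.beta)

    if sc.dispersion == 0:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / sc.dispersion
        counts = rng.negative_binomial(r, r / (r + mu))

    genes = pd.DataFrame({
        "id": [f"gene{g:04d}" for g in range(sc.n_genes)],
        "chrom": "1",
        "start": [g * 10_000 + 1 for g in range(sc.n_genes)],
        "end": [g * 10_000 + 5_000 for g in range(sc.n_genes)],
        "exonic_length": 2_000,
        "biotype": "protein_coding",
    })
    samples = [f"s{j:03d}" for j in range(sc.n_samples)]
    cm = CountMatrix(genes=genes, samples=samples, counts=counts)

    sites = pd.DataFrame({
        "chrom": "1",
        "pos": [s * 10_000 + 2_500 for s in range(sc.n_snps)],
        "id": [f"snp{s:04d}" for s in range(sc.n_snps)],
        "ref": "A",
        "alt": "G",
        "depth": 100,
    })
    gm = GenotypeMatrix(sites=sites, samples=samples, codes=codes)
    site = pd.Series([f"site{v}" for v in site_assign], index=samples, name="site")

    truth = TruthRecord(
        effects=list(sc.effects),
        genotype_counts=[
            tuple(int(x) for x in np.bincount(codes[s], minlength=3))
            for s in range(sc.n_snps)
        ],
        library_sizes=cm.library_sizes().tolist(),
        scenario={**asdict(sc), "effects": [asdict(e) for e in sc.effects]},
    )
    return cm, gm, site, truth


def score_calls(
    results: pd.DataFrame,
    truth: TruthRecord,
    cm: CountMatrix,
    gm: GenotypeMatrix,
    threshold: float = 5e-8,
) -> dict:
    """Confusion counts of significant pairs against the planted effects."""
    gene_ids = cm.genes["id"].to_numpy()
    vids = gm.variant_ids().to_numpy()
    true_pairs = {(gene_ids[e.gene], vids[e.snp]) for e in truth.effects}
    tested = set(zip(results["gene_id"], results["variant_id"]))
    called = set(
        zip(
            results.loc[results["p"] < threshold, "gene_id"],
            results.loc[results["p"] < threshold, "variant_id"],
        )
    )
    tp = len(called & true_pairs)
    fp = len(called - true_pairs)
    fn = len((true_pairs & tested) - called)
    tn = len(tested - true_pairs) - fp
    return {"tp": tp, "fp": fp, "fn": fn, "tn": tn}


def simulate_paired_null(
    n_pairs: int = 1_000,
    n_samples: int = 41,
    baseline_mu: float = 100.0,
    dispersion: float = 0.2,
    maf: float = 0.3,
    libsize_range: tuple[float, float] = (0.5, 2.0),
    min_per_class: int = 5,
    seed: int = 0,
):
    """Independent null gene-SNP pairs for QL F-test calibration.

    Each pair is a fresh NB count vector (with its own library-size
    factors) matched to a fresh QC-passing HWE genotype column; pairs
    share nothing, so their test p-values are independent.  Returns
    ``(counts (n_pairs, n), genotypes (n_pairs, n), log_offsets)``.
    """
    rng = np.random.default_rng(seed)
    lo, hi = libsize_range
    L = np.exp(rng.uniform(np.log(lo), np.log(hi), size=(n_pairs, n_samples)))
    mu = baseline_mu * L
    if dispersion == 0:
        y = rng.poisson(mu).astype(float)
    else:
        r = 1.0 / dispersion
        y = rng.negative_binomial(r, r / (r + mu)).astype(float)
    g = np.empty((n_pairs, n_samples), dtype=np.int8)
    for i in range(n_pairs):
        col = simulate_genotypes(n_samples, maf, rng)
        while np.bincount(col, minlength=3).min() < min_per_class:
            col = simulate_genotypes(n_samples, maf, rng)
        g[i] = col
    return y, g, np.log(L)


def nb_paired_null_pvalues(
    y: np.ndarray,
    g: np.ndarray,
    offsets: np.ndarray,
    shrink_prior_df: float = 10.0,
) -> pd.DataFrame:
    """QL F-test p-values of every NB model on matched gene-SNP pairs.

    Dispersion is estimated per pair under the intercept-only design
    (shrunk toward the common value), mirroring the scan pipeline.
    Returns one row per pair with columns ``anova``, ``additive``,
    ``contrast_ref_dom``, ``contrast_alt_dom``.
    """
    from scipy.stats import f as f_dist

    from .nbglm import estimate_dispersion, nb_irls_batch, pearson_quasi_dispersion

    n_pairs, n = y.shape
    ones = np.ones((n, 1))
    phi, _ = estimate_dispersion(y, ones, offsets=offsets,
                                 shrink_prior_df=shrink_prior_df)
    red = nb_irls_batch(y, ones, offset=offsets, phi=phi)
    gf = g.astype(float)
    designs = {
        "anova": np.stack([(gf == 1), (gf == 2)], axis=2).astype(float),
        "additive": gf[..., None],
        "contrast_ref_dom": (gf >= 1).astype(float)[..., None],
        "contrast_alt_dom": (gf == 2).astype(float)[..., None],
    }
    out = {}
    base = np.broadcast_to(ones, (n_pairs, n, 1))
    for model, cols in designs.items():
        X = np.concatenate([base, cols], axis=2)
        full = nb_irls_batch(y, X, offset=offsets, phi=phi)
        df1 = cols.shape[2]
        df2 = n - X.shape[2]
        diff = np.clip(red["deviance"] - full["deviance"], 0.0, None)
        s2 = pearson_quasi_dispersion(y, full["mu"], phi, df2)
        out[model] = f_dist.sf((diff / df1) / s2, df1, df2)
    return pd.DataFrame(out)


def run_calibration_study(
    scenarios: dict[str, SimulationScenario],
    alphas=(0.05, 0.01),
    n_reps: int = 3,
    seed: int = 0,
    threshold: float = 5e-8,
    shrink_prior_df: float = 10.0,
) -> pd.DataFrame:
    """Type-I error and power of every framework/model over a scenario grid.

    For each scenario and replicate, the full pipeline runs on a fresh
    dataset (TMM -> INT -> linear scans; TMM offsets + dispersion -> NB
    scans, contrasts on all pairs) and each method's rejection fraction
    at each alpha is recorded separately for null pairs (type-I error)
    and planted-effect pairs (power), together with confusion counts at
    the genome-wide ``threshold``.
    """
    from .pipeline import run_all_scans

    rows = []
    for name, base in scenarios.items():
        for rep in range(n_reps):
            sc = SimulationScenario(**{
                **{k: v for k, v in asdict(base).items()},
                "effects": [asdict(e) for e in base.effects],
                "seed": int((seed + 100_003 * rep + zlib.crc32(name.encode()) % 10_007) % 2**31),
            })
            cm, gm, site, truth = simulate_counts(sc)
            scans = run_all_scans(cm, gm, site, shrink_prior_df=shrink_prior_df)
            gene_ids = cm.genes["id"].to_numpy()
            vids = gm.variant_ids().to_numpy()
            true_pairs = {(gene_ids[e.gene], vids[e.snp]) for e in truth.effects}
            for (framework, model), res in scans.items():
                is_true = np.array(
                    [pair in true_pairs for pair in zip(res["gene_id"], res["variant_id"])]
                )
                conf = score_calls(res, truth, cm, gm, threshold)
                for alpha in alphas:
                    rej = res["p"].to_numpy() < alpha
                    for kind, mask in (("type1", ~is_true), ("power", is_true)):
                        if mask.sum() == 0:
                            continue
                        rows.append({
                            "scenario": name, "rep": rep, "framework": framework,
                            "model": model, "alpha": alpha, "kind": kind,
                            "n_tests": int(mask.sum()),
                            "rate": float(rej[mask].mean()),
                            **conf,
                        })
    return pd.DataFrame(rows)
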