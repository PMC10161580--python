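"""Count-matrix QC and expression representations.

Three representations of a genes x samples raw count matrix are used by
the two eQTL frameworks:

* TMM-normalized counts per million (trimmed mean of M-values scale
  factors applied to library sizes), feeding the linear framework and the
  negative-binomial model offsets;
* transcripts per million (TPM), for plotting-scale abundance;
* the rank-based inverse normal transform (INT) of TMM-CPM, the response
  of the linear framework.

TMM follows the published trimmed-mean-of-M-values procedure: a reference
sample is picked by 75th-percentile CPM, per-gene log2 expression ratios
against the reference are doubly trimmed by ratio (M) and abundance (A)
quantiles, and the scale factor is the weighted mean of the surviving
ratios with inverse asymptotic-variance weights, rescaled so factors have
geometric mean one.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

logger = logging.getLogger(__name__)

GENE_COLUMNS = ["id", "chrom", "start", "end", "exonic_length", "biotype"]


@dataclass
class CountMatrix:
    """Genes x samples raw counts with gene annotation.

    ``genes`` carries one row per gene: ``id``, ``chrom``, ``start``,
    ``end`` (1-based inclusive), ``exonic_length`` (nt), ``biotype``.
    """

    genes: pd.DataFrame
    samples: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.genes), len(self.samples)):
            raise ValueError("counts shape does not match genes x samples")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0).astype(float)

    def subset_genes(self, mask: np.ndarray) -> "CountMatrix":
        return CountMatrix(
            genes=self.genes.iloc[mask].reset_index(drop=True),
            samples=list(self.samples),
            counts=self.counts[mask],
        )

    def subset_samples(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return CountMatrix(
            genes=self.genes.copy(),
            samples=[self.samples[i] for i in idx],
            counts=self.counts[:, idx],
        )


@dataclass
class NormFactors:
    """Per-sample library size, TMM factor, and effective library size."""

    samples: list[str]
    library_size: np.ndarray
    tmm_factor: np.ndarray

    @property
    def effective_size(self) -> np.ndarray:
        return self.library_size * self.tmm_factor


@dataclass
class TransformedExpression:
    """A genes x samples real-valued expression matrix with provenance."""

    values: np.ndarray
    gene_ids: list[str]
    samples: list[str]
    transform: str  # one of {"cpm", "tmm_cpm", "tpm", "int"}
    provenance: dict = field(default_factory=dict)


def drop_shallow_samples(cm: CountMatrix, min_total: int = 1_000_000) -> CountMatrix:
    """Drop samples with fewer than ``min_total`` reads mapped to the annotation."""
    totals = cm.library_sizes()
    keep = totals >= min_total
    if not keep.any():
        raise ValueError("all samples fall below the read-depth threshold")
    dropped = [s for s, k in zip(cm.samples, keep) if not k]
    if dropped:
        logger.info("drop_shallow_samples: removed %s", dropped)
    return cm.subset_samples(keep)


def cpm(cm: CountMatrix, sizes: np.ndarray) -> TransformedExpression:
    """Counts per million against the given per-sample denominators."""
    sizes = np.asarray(sizes, dtype=float)
    if np.any(sizes <= 0):
        raise ValueError("CPM denominators must be positive")
    values = cm.counts / sizes[None, :] * 1e6
    return TransformedExpression(
        values=values,
        gene_ids=list(cm.genes["id"]),
        samples=list(cm.samples),
        transform="cpm",
    )


def filter_genes(
    cm: CountMatrix,
    cpm_threshold: float = 2.0,
    min_samples: int = 5,
    biotype: str | None = "protein_coding",
) -> CountMatrix:
    """Retain genes of the given biotype with CPM > threshold in enough samples.

    CPM for this filter uses raw library sizes (the filter runs before
    TMM normalization).  The CPM comparison is strict.
    """
    vals = cpm(cm, cm.library_sizes()).values
    keep = (vals > cpm_threshold).sum(axis=1) >= min_samples
    if biotype is not None:
        keep &= (cm.genes["biotype"] == biotype).to_numpy()
    logger.info("filter_genes: %d -> %d genes", cm.n_genes, int(keep.sum()))
    return cm.subset_genes(keep)


def tpm(cm: CountMatrix) -> TransformedExpression:
    """Transcripts per million: length-normalized rates rescaled to 1e6 per sample."""
    lengths = cm.genes["exonic_length"].to_numpy(dtype=float)
    bad = ~(lengths > 0)
    if bad.any():
        raise ValueError(
            "missing/invalid exonic_length for genes: "
            + ", ".join(cm.genes.loc[bad, "id"].astype(str))
        )
    rate = cm.counts / lengths[:, None]
    denom = rate.sum(axis=0)
    zero_cols = denom == 0
    if zero_cols.any():
        warnings.warn("all-zero sample column(s) in TPM; emitting zeros", stacklevel=2)
        denom = np.where(zero_cols, 1.0, denom)
    values = rate / denom[None, :] * 1e6
    return TransformedExpression(
        values=values,
        gene_ids=list(cm.genes["id"]),
        samples=list(cm.samples),
        transform="tpm",
    )


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float,
    abs_trim: float,
    a_cutoff: float,
) -> float:
    """TMM scale factor of one sample against the reference column."""
    with np.errstate(divide="ignore", invalid="ignore"):
        p_obs = obs / lib_obs
        p_ref = ref / lib_ref
        logR = np.log2(p_obs / p_ref)  # M values
        absE = (np.log2(p_obs) + np.log2(p_ref)) / 2.0  # A values
        v = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    fin = np.isfinite(logR) & np.isfinite(absE) & (absE > a_cutoff)
    logR, absE, v = logR[fin], absE[fin], v[fin]
    if logR.size == 0 or np.max(np.abs(logR)) < 1e-6:
        return 1.0
    n = logR.size
    loL = np.floor(n * logratio_trim) + 1
    hiL = n + 1 - loL
    loS = np.floor(n * abs_trim) + 1
    hiS = n + 1 - loS
    rM = rankdata(logR)
    rA = rankdata(absE)
    keep = (rM >= loL) & (rM <= hiL) & (rA >= loS) & (rA <= hiS)
    if not keep.any():
        return 1.0
    w = 1.0 / v[keep]
    f = 2.0 ** (np.sum(w * logR[keep]) / np.sum(w))
    return float(f) if np.isfinite(f) else 1.0


def tmm_factors(
    cm: CountMatrix,
    logratio_trim: float = 0.30,
    abs_trim: float = 0.05,
    a_cutoff: float = -1e10,
) -> NormFactors:
    """Trimmed-mean-of-M-values scale factors (geometric mean one).

    The reference sample is the column whose 75th-percentile CPM is
    closest to the mean 75th percentile (ties broken by lowest index).
    Genes with a zero count in either the sample or the reference, or
    with mean log2 abundance at or below ``a_cutoff``, are excluded
    before the double trim by M and A quantiles.
    """
    if cm.n_samples < 2:
        raise ValueError("TMM requires at least two samples")
    lib = cm.library_sizes()
    if np.any(lib == 0):
        raise ValueError("TMM undefined for all-zero sample columns")
    counts = cm.counts.astype(float)
    q75 = np.quantile(counts, 0.75, axis=0) / lib
    ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    factors = np.array(
        [
            _tmm_pair_factor(
                counts[:, j], counts[:, ref_idx], lib[j], lib[ref_idx],
                logratio_trim, abs_trim, a_cutoff,
            )
            for j in range(cm.n_samples)
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return NormFactors(samples=list(cm.samples), library_size=lib, tmm_factor=factors)


def tmm_cpm(cm: CountMatrix, nf: NormFactors) -> TransformedExpression:
    """CPM against TMM-effective library sizes."""
    if nf.samples != cm.samples:
        raise ValueError("NormFactors samples do not match count matrix samples")
    out = cpm(cm, nf.effective_size)
    out.transform = "tmm_cpm"
    out.provenance["tmm_factor"] = nf.tmm_factor.tolist()
    return out


def inverse_normal(values: TransformedExpression | np.ndarray, offset_k: float = 0.375) -> TransformedExpression:
    """Rank-based inverse normal transform, per gene across samples.

    Each gene row is mapped to ``Phi^{-1}((rank - k) / (n - 2k + 1))``
    with Blom offset ``k`` and average ranks for ties.  Constant rows
    become all zeros with a warning.
    """
    if isinstance(values, TransformedExpression):
        mat, gene_ids, samples = values.values, values.gene_ids, values.samples
    else:
        mat = np.asarray(values, dtype=float)
        gene_ids = [str(i) for i in range(mat.shape[0])]
        samples = [str(j) for j in range(mat.shape[1])]
    n = mat.shape[1]
    if n < 3:
        raise ValueError("inverse normal transform needs at least 3 samples")
    ranks = np.apply_along_axis(rankdata, 1, mat)
    out = norm.ppf((ranks - offset_k) / (n - 2 * offset_k + 1))
    constant = np.ptp(mat, axis=1) == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant gene row(s) set to zero in INT", stacklevel=2)
        out[constant] = 0.0
    return TransformedExpression(
        values=out,
        gene_ids=gene_ids,
        samples=samples,
        transform="int",
        provenance={"offset_k": offset_k},
    )


def remove_outlier_genes(
    cm: CountMatrix, nf: NormFactors, z_cutoff: float = 5.0
) -> CountMatrix:
    """Drop genes with an extreme single-sample abundance spike.

    A gene is removed when any sample's log2(TMM-CPM + 1) lies more than
    ``z_cutoff`` robust standard deviations (median / scaled MAD across
    samples) from the gene's median.  Genes with zero MAD are never
    flagged.  The rule and cutoff are heuristic and recorded so they can
    be varied.
    """
    logv = np.log2(tmm_cpm(cm, nf).values + 1.0)
    med = np.median(logv, axis=1, keepdims=True)
    mad = np.median(np.abs(logv - med), axis=1, keepdims=True) * 1.4826
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.abs(logv - med) / mad
    flagged = np.where(mad[:, 0] > 0, np.nanmax(np.where(mad > 0, z, 0.0), axis=1) > z_cutoff, False)
    logger.info("remove_outlier_genes: removed %d of %d genes", int(flagged.sum()), cm.n_genes)
    return cm.subset_genes(~flagged)
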