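"""Genotype matrices and the SNP quality-control cascade.

Genotypes come in as a multi-sample VCF (typically called from RNA-seq
alignments upstream of this tool).  The QC cascade retains biallelic SNPs
with adequate site depth and call rate, then restricts to the subset usable
for association testing: enough animals in every genotype class, common
enough minor allele, and consistency with Hardy-Weinberg equilibrium (HWE)
judged by an exact test with a Benjamini-Hochberg correction across sites.

Genotypes are coded as the count of alternate alleles (0, 1, 2); missing
calls use the sentinel :data:`MISSING`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype call.
MISSING: int = -1

_NUCLEOTIDES = frozenset("ACGT")

SITE_COLUMNS = ["chrom", "pos", "id", "ref", "alt", "depth"]


class VcfParseError(ValueError):
    """Raised when a VCF record cannot be interpreted."""


@dataclass
class GenotypeMatrix:
    """Variants x samples alternate-allele counts with per-site metadata.

    Attributes
    ----------
    sites
        One row per variant: ``chrom``, ``pos`` (1-based), ``id``, ``ref``,
        ``alt``, ``depth`` (site-level read depth supporting the call).
    samples
        Ordered sample identifiers (VCF column order).
    codes
        ``(n_variants, n_samples)`` int8 array in {0, 1, 2, MISSING}.
    exclusions
        Counts of records excluded at read time, keyed by reason.
    """

    sites: pd.DataFrame
    samples: list[str]
    codes: np.ndarray
    exclusions: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.codes.shape != (len(self.sites), len(self.samples)):
            raise ValueError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )

    @property
    def n_variants(self) -> int:
        return self.codes.shape[0]

    @property
    def n_samples(self) -> int:
        return self.codes.shape[1]

    def variant_ids(self) -> pd.Series:
        """Variant identifiers, synthesising chrom:pos where ID is missing."""
        ids = self.sites["id"].astype("string")
        fallback = self.sites["chrom"].astype(str) + ":" + self.sites["pos"].astype(str)
        return ids.fillna(pd.Series(fallback, index=ids.index)).astype(str)

    def subset(self, mask: np.ndarray) -> "GenotypeMatrix":
        """Row-subset preserving order; ``mask`` is boolean or index array."""
        mask = np.asarray(mask)
        return GenotypeMatrix(
            sites=self.sites.iloc[mask].reset_index(drop=True),
            samples=list(self.samples),
            codes=self.codes[mask],
            exclusions=dict(self.exclusions),
        )


def read_vcf(path: str) -> GenotypeMatrix:
    """Read a multi-sample VCF into a :class:`GenotypeMatrix`.

    Only biallelic single-nucleotide records are loaded; multi-allelic
    records and indels are excluded (counted in ``exclusions``).  Half
    calls and ``./.`` map to :data:`MISSING`.  Site depth is the INFO DP
    field when present, otherwise the sum of per-sample DP.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise VcfParseError(f"VCF {path} has no sample columns")

    rows, codes = [], []
    exclusions = {"multiallelic": 0, "not_snp": 0}
    for rec in vcf:
        if len(rec.ALT) != 1:
            exclusions["multiallelic"] += 1
            continue
        ref, alt = rec.REF.upper(), rec.ALT[0].upper()
        if len(ref) != 1 or len(alt) != 1 or ref not in _NUCLEOTIDES or alt not in _NUCLEOTIDES:
            exclusions["not_snp"] += 1
            continue
        depth = rec.INFO.get("DP")
        if depth is None:
            try:
                dp = rec.format("DP")
                depth = int(np.nansum(np.where(dp < 0, np.nan, dp))) if dp is not None else 0
            except Exception:
                depth = 0
        # gts012=True: 0/1/2 = alt-allele count, 3 = unknown
        gt = np.asarray(rec.gt_types, dtype=np.int8)
        gt[gt == 3] = MISSING
        rows.append((rec.CHROM, rec.POS, rec.ID, ref, alt, int(depth)))
        codes.append(gt)

    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    code_arr = (
        np.vstack(codes) if codes else np.empty((0, len(samples)), dtype=np.int8)
    )
    n_excl = sum(exclusions.values())
    if n_excl:
        logger.info("read_vcf: excluded %d records (%s)", n_excl, exclusions)
    return GenotypeMatrix(sites=sites, samples=samples, codes=code_arr, exclusions=exclusions)


def filter_variants(
    gm: GenotypeMatrix,
    min_depth: int = 20,
    min_called: int = 20,
    snp_only: bool = True,
) -> GenotypeMatrix:
    """Depth / call-rate / SNP-only variant filter.

    Retains sites with site depth >= ``min_depth``, genotypes called in at
    least ``min_called`` samples, and (if ``snp_only``) single-nucleotide
    ref and alt alleles.  Order is preserved; the filter is idempotent.
    """
    if gm.n_variants == 0:
        raise ValueError("empty genotype matrix")
    n_called = (gm.codes != MISSING).sum(axis=1)
    keep = (gm.sites["depth"].to_numpy() >= min_depth) & (n_called >= min_called)
    if snp_only:
        is_snp = np.array(
            [
                len(r) == 1 and len(a) == 1 and r in _NUCLEOTIDES and a in _NUCLEOTIDES
                for r, a in zip(gm.sites["ref"], gm.sites["alt"])
            ]
        )
        keep &= is_snp
    logger.info("filter_variants: %d -> %d sites", gm.n_variants, int(keep.sum()))
    return gm.subset(keep)


def genotype_counts(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-variant genotype class counts.

    Returns columns ``n_AA`` (ref homozygotes), ``n_AB`` (heterozygotes),
    ``n_BB`` (alt homozygotes) and ``n_called``; missing calls are excluded.
    """
    out = pd.DataFrame(
        {
            "n_AA": (gm.codes == 0).sum(axis=1),
            "n_AB": (gm.codes == 1).sum(axis=1),
            "n_BB": (gm.codes == 2).sum(axis=1),
        }
    )
    out["n_called"] = out.sum(axis=1)
    return out


def minor_allele_frequency(
    n_AA: np.ndarray | int, n_AB: np.ndarray | int, n_BB: np.ndarray | int
) -> np.ndarray | float:
    """Minor-allele frequency from genotype class counts (called samples only)."""
    n_AA, n_AB, n_BB = (np.asarray(x, dtype=float) for x in (n_AA, n_AB, n_BB))
    n_called = n_AA + n_AB + n_BB
    if np.any(n_called == 0):
        raise ValueError("MAF undefined: no called genotypes")
    p_alt = (2 * n_BB + n_AB) / (2 * n_called)
    maf = np.minimum(p_alt, 1.0 - p_alt)
    return float(maf) if maf.ndim == 0 else maf


def hwe_exact_p(n_AA: int, n_AB: int, n_BB: int) -> float:
    """Two-sided exact Hardy-Weinberg test p-value (Levene-Haldane).

    Conditional on the number of individuals and the minor-allele count,
    the heterozygote count under HWE follows the Levene-Haldane
    distribution.  The two-sided p-value sums the probabilities of every
    heterozygote count whose probability does not exceed that of the
    observed count (probability-ordering definition, no mid-p).
    """
    if min(n_AA, n_AB, n_BB) < 0:
        raise ValueError("negative genotype counts")
    n = n_AA + n_AB + n_BB
    if n == 0:
        raise ValueError("HWE test undefined: no called genotypes")
    m = int(min(2 * n_AA + n_AB, 2 * n_BB + n_AB))  # minor allele count
    if m == 0:
        return 1.0
    # attainable heterozygote counts share the parity of the minor count
    h = np.arange(m % 2, m + 1, 2)
    logp = (
        gammaln(n + 1)
        - gammaln((m - h) / 2 + 1)
        - gammaln(h + 1)
        - gammaln((2 * n - m - h) / 2 + 1)
        + h * np.log(2.0)
        + gammaln(m + 1)
        + gammaln(2 * n - m + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp)
    probs /= probs.sum()  # guard rounding drift; exact sum is 1
    p_obs = probs[h == n_AB][0]
    p = probs[probs <= p_obs * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


def hwe_exact_p_vector(counts: pd.DataFrame) -> np.ndarray:
    """Vector of HWE exact p-values for a :func:`genotype_counts` frame."""
    return np.array(
        [
            hwe_exact_p(int(a), int(h), int(b))
            for a, h, b in zip(counts["n_AA"], counts["n_AB"], counts["n_BB"])
        ]
    )


def eqtl_snp_set(
    gm: GenotypeMatrix,
    min_per_class: int = 5,
    maf_threshold: float = 0.15,
    hwe_fdr: float = 0.05,
) -> GenotypeMatrix:
    """Restrict to SNPs usable for eQTL testing.

    Keeps variants with at least ``min_per_class`` samples in each of the
    three genotype classes, minor-allele frequency strictly above
    ``maf_threshold``, and not rejected by the HWE exact test after
    Benjamini-Hochberg adjustment across all variants at ``hwe_fdr``.
    """
    counts = genotype_counts(gm)
    maf = minor_allele_frequency(
        counts["n_AA"].to_numpy(), counts["n_AB"].to_numpy(), counts["n_BB"].to_numpy()
    )
    hwe_p = hwe_exact_p_vector(counts)
    if len(hwe_p):
        hwe_reject = multipletests(hwe_p, alpha=hwe_fdr, method="fdr_bh")[0]
    else:
        hwe_reject = np.zeros(0, dtype=bool)
    keep = (
        (counts[["n_AA", "n_AB", "n_BB"]].min(axis=1).to_numpy() >= min_per_class)
        & (maf > maf_threshold)
        & ~hwe_reject
    )
    logger.info("eqtl_snp_set: %d -> %d SNPs", gm.n_variants, int(keep.sum()))
    return gm.subset(keep)


def qc_report(gm: GenotypeMatrix, hwe_fdr: float = 0.05,
              min_per_class: int = 5, maf_threshold: float = 0.15) -> pd.DataFrame:
    """Per-variant QC table: counts, MAF, HWE p/q and pass flags."""
    counts = genotype_counts(gm)
    maf = minor_allele_frequency(
        counts["n_AA"].to_numpy(), counts["n_AB"].to_numpy(), counts["n_BB"].to_numpy()
    )
    hwe_p = hwe_exact_p_vector(counts)
    hwe_q = (
        multipletests(hwe_p, alpha=hwe_fdr, method="fdr_bh")[1]
        if len(hwe_p)
        else np.zeros(0)
    )
    rep = pd.DataFrame(
        {
            "variant_id": gm.variant_ids(),
            "chrom": gm.sites["chrom"],
            "pos": gm.sites["pos"],
            "depth": gm.sites["depth"],
            "n_called": counts["n_called"],
            "n_AA": counts["n_AA"],
            "n_AB": counts["n_AB"],
            "n_BB": counts["n_BB"],
            "maf": maf,
            "hwe_p": hwe_p,
            "hwe_q": hwe_q,
        }
    )
    rep["pass_class"] = counts[["n_AA", "n_AB", "n_BB"]].min(axis=1) >= min_per_class
    rep["pass_maf"] = maf > maf_threshold
    rep["pass_hwe"] = hwe_q >= hwe_fdr
    rep["pass_all"] = rep["pass_class"] & rep["pass_maf"] & rep["pass_hwe"]
    return rep


def write_vcf(gm: GenotypeMatrix, path: str) -> None:
    """Write the matrix back out as a minimal VCF 4.2 file."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Site read depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(gm.sites["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.samples) + "\n")
        for i, site in gm.sites.iterrows():
            vid = site["id"] if site["id"] not in (None, "") and pd.notna(site["id"]) else "."
            gts = "\t".join(gt_map[int(c)] for c in gm.codes[i])
            fh.write(
                f"{site['chrom']}\t{site['pos']}\t{vid}\t{site['ref']}\t"
                f"{site['alt']}\t.\tPASS\tDP={site['depth']}\tGT\t{gts}\n"
            )
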