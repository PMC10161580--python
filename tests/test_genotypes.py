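"""Genotype QC cascade: VCF coding, filters, MAF, and the HWE exact test."""

from fractions import Fraction
from functools import lru_cache
from math import factorial

import numpy as np
import pytest

from countqtl import genotypes as gt
from tests.conftest import toy_genotype_matrix


@lru_cache(maxsize=None)
def _levene_haldane_pmf(n: int, m: int):
    """Exact Levene-Haldane heterozygote-count pmf via rational arithmetic."""
    denom = Fraction(factorial(2 * n), factorial(m) * factorial(2 * n - m))
    pmf = {}
    for h in range(m % 2, m + 1, 2):
        na, nb = (m - h) // 2, (2 * n - m - h) // 2
        ways = Fraction(factorial(n), factorial(na) * factorial(h) * factorial(nb)) * 2**h
        pmf[h] = ways / denom
    return pmf


def hwe_oracle(n_AA: int, n_AB: int, n_BB: int) -> float:
    """Brute-force two-sided exact HWE p-value (probability ordering)."""
    n = n_AA + n_AB + n_BB
    m = min(2 * n_AA + n_AB, 2 * n_BB + n_AB)
    if m == 0:
        return 1.0
    pmf = _levene_haldane_pmf(n, m)
    p_obs = pmf[n_AB]
    return float(sum(p for p in pmf.values() if p <= p_obs))


class TestReadVcf:
    def test_codes_missing_and_exclusions(self, make_vcf):
        path = make_vcf([
            ("1", 100, "rs1", "A", "G", ".", "PASS", "DP=50", "GT", "0/0", "0/1", "1/1"),
            ("1", 200, ".", "C", "T", ".", "PASS", "DP=30", "GT", "./.", "0/0", "0/1"),
            ("1", 300, ".", "C", "A,T", ".", "PASS", "DP=30", "GT", "0/1", "0/2", "1/1"),
            ("1", 400, ".", "CT", "C", ".", "PASS", "DP=30", "GT", "0/0", "0/1", "1/1"),
        ])
        gm = gt.read_vcf(path)
        assert gm.samples == ["s1", "s2", "s3"]
        assert gm.n_variants == 2  # multi-allelic and indel excluded
        assert gm.codes[0].tolist() == [0, 1, 2]
        assert gm.codes[1].tolist() == [gt.MISSING, 0, 1]
        assert gm.exclusions["multiallelic"] == 1
        assert gm.exclusions["not_snp"] == 1
        assert gm.sites.loc[0, "depth"] == 50

    def test_no_samples_is_an_error(self, tmp_path):
        path = tmp_path / "empty.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        )
        with pytest.raises(gt.VcfParseError):
            gt.read_vcf(str(path))


class TestFilterVariants:
    def test_depth_callrate_and_snp_rules(self):
        codes = np.array([
            [0, 1, 2, 0],          # passes
            [0, 1, 2, 0],          # depth below threshold
            [0, gt.MISSING, gt.MISSING, gt.MISSING],  # too few called
        ])
        gm = toy_genotype_matrix(codes)
        gm.sites.loc[1, "depth"] = 19
        out = gt.filter_variants(gm, min_depth=20, min_called=2)
        assert out.sites["id"].tolist() == ["v0"]

    def test_ref_indel_removed_when_snp_only(self):
        gm = toy_genotype_matrix(np.array([[0, 1, 2], [0, 1, 2]]))
        gm.sites.loc[1, "ref"] = "AT"
        out = gt.filter_variants(gm, min_depth=1, min_called=1, snp_only=True)
        assert out.sites["id"].tolist() == ["v0"]

    def test_monotone_and_idempotent(self):
        rng = np.random.default_rng(0)
        gm = toy_genotype_matrix(rng.integers(-1, 3, size=(30, 25)).astype(np.int8))
        gm.sites["depth"] = rng.integers(5, 40, size=30)
        once = gt.filter_variants(gm, min_depth=20, min_called=20)
        twice = gt.filter_variants(once, min_depth=20, min_called=20)
        assert set(once.sites["id"]) <= set(gm.sites["id"])
        assert once.sites["id"].tolist() == twice.sites["id"].tolist()
        assert np.array_equal(once.codes, twice.codes)


class TestGenotypeCounts:
    @pytest.mark.parametrize(
        "row, expected",
        [
            ([0, 0, 1, 2, gt.MISSING], (2, 1, 1, 4)),
            ([gt.MISSING] * 5, (0, 0, 0, 0)),
            ([0] * 41, (41, 0, 0, 41)),
        ],
    )
    def test_counts_exclude_missing(self, row, expected):
        gm = toy_genotype_matrix(np.array([row]))
        counts = gt.genotype_counts(gm)
        assert tuple(counts.iloc[0][["n_AA", "n_AB", "n_BB", "n_called"]]) == expected


class TestMaf:
    @pytest.mark.parametrize(
        "counts, expected",
        [((10, 20, 10), 0.5), ((36, 8, 0), 8 / 88), ((0, 0, 12), 0.0)],
    )
    def test_examples(self, counts, expected):
        assert gt.minor_allele_frequency(*counts) == pytest.approx(expected)

    def test_undefined_for_no_calls(self):
        with pytest.raises(ValueError):
            gt.minor_allele_frequency(0, 0, 0)

    def test_invariant_under_allele_swap(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a, h, b = rng.integers(0, 30, size=3)
            if a + h + b == 0:
                continue
            assert gt.minor_allele_frequency(a, h, b) == pytest.approx(
                gt.minor_allele_frequency(b, h, a)
            )


class TestHweExact:
    def test_monomorphic_is_one(self):
        assert gt.hwe_exact_p(17, 0, 0) == 1.0
        assert gt.hwe_exact_p(0, 0, 12) == 1.0

    def test_matches_enumeration_oracle_small(self):
        for a, h, b in [(5, 5, 5), (10, 0, 10), (0, 20, 0), (3, 14, 4), (12, 2, 1)]:
            assert gt.hwe_exact_p(a, h, b) == pytest.approx(hwe_oracle(a, h, b), abs=1e-12)

    def test_matches_oracle_exhaustively_to_n25(self):
        for n in range(1, 26):
            for n_AA in range(n + 1):
                for n_AB in range(n - n_AA + 1):
                    n_BB = n - n_AA - n_AB
                    assert gt.hwe_exact_p(n_AA, n_AB, n_BB) == pytest.approx(
                        hwe_oracle(n_AA, n_AB, n_BB), abs=1e-12
                    )

    def test_extreme_configurations_deviate(self):
        # all-het and no-het at identical allele counts are both flagged
        p_all_het = gt.hwe_exact_p(0, 20, 0)
        p_no_het = gt.hwe_exact_p(10, 0, 10)
        assert p_all_het == pytest.approx(hwe_oracle(0, 20, 0), abs=1e-12)
        assert p_no_het == pytest.approx(hwe_oracle(10, 0, 10), abs=1e-12)
        assert p_all_het < 0.01 and p_no_het < 0.01

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            gt.hwe_exact_p(-1, 2, 3)

    def test_type1_error_controlled_under_hwe(self):
        rng = np.random.default_rng(7)
        n, reps, alpha, p = 41, 1500, 0.05, 0.3
        draws = rng.multinomial(n, [(1 - p) ** 2, 2 * p * (1 - p), p**2], size=reps)
        pvals = np.array([gt.hwe_exact_p(*d) for d in draws])
        rate = (pvals < alpha).mean()
        se = np.sqrt(alpha * (1 - alpha) / reps)
        assert rate <= alpha + 3 * se


class TestEqtlSnpSet:
    def test_class_and_maf_rules(self):
        # v0: class of 4 < 5; v1: MAF exactly 0.15 (strict >); v2: passes
        rows = [
            [0] * 4 + [1] * 20 + [2] * 17,
            [0] * 30 + [1] * 11 + [2] * 0,   # MAF = 11/82 < 0.15 -> removed
            [0] * 20 + [1] * 16 + [2] * 5,
        ]
        gm = toy_genotype_matrix(np.array(rows))
        out = gt.eqtl_snp_set(gm)
        assert out.sites["id"].tolist() == ["v2"]

    def test_maf_boundary_is_strict(self):
        # 41 samples, alt allele count 12 of 82 -> close; build exact 0.15: 20 alleles of 100? use 40 samples: 12/80=0.15
        row = [0] * 28 + [1] * 12
        gm = toy_genotype_matrix(np.array([row]))
        counts = gt.genotype_counts(gm)
        assert gt.minor_allele_frequency(
            int(counts.n_AA[0]), int(counts.n_AB[0]), int(counts.n_BB[0])
        ) == pytest.approx(0.15)
        out = gt.eqtl_snp_set(gm, min_per_class=0)
        assert out.n_variants == 0

    def test_null_hwe_retention_high(self):
        # variants simulated under HWE should almost all survive the BH-adjusted test
        retained = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            p = 0.3
            codes = rng.choice(
                3, size=(1000, 41), p=[(1 - p) ** 2, 2 * p * (1 - p), p**2]
            ).astype(np.int8)
            gm = toy_genotype_matrix(codes)
            out = gt.eqtl_snp_set(gm, min_per_class=0, maf_threshold=0.0)
            retained.append(out.n_variants / 1000)
        assert np.mean(retained) >= 0.95


def test_qc_report_columns_and_flags():
    rng = np.random.default_rng(3)
    gm = toy_genotype_matrix(rng.integers(0, 3, size=(20, 41)).astype(np.int8))
    rep = gt.qc_report(gm)
    for col in ["variant_id", "maf", "hwe_p", "hwe_q", "pass_all"]:
        assert col in rep.columns
    assert ((rep["hwe_p"] > 0) & (rep["hwe_p"] <= 1)).all()
    assert (rep["pass_all"] == (rep.pass_class & rep.pass_maf & rep.pass_hwe)).all()


def test_vcf_round_trip(tmp_path, make_vcf):
    path = make_vcf([
        ("1", 100, "rs1", "A", "G", ".", "PASS", "DP=50", "GT", "0/0", "0/1", "1/1"),
        ("2", 200, ".", "C", "T", ".", "PASS", "DP=30", "GT", "./.", "0/0", "1/1"),
    ])
    gm = gt.read_vcf(path)
    out = tmp_path / "out.vcf"
    gt.write_vcf(gm, str(out))
    gm2 = gt.read_vcf(str(out))
    assert np.array_equal(gm.codes, gm2.codes)
    assert gm2.sites["pos"].tolist() == [100, 200]
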