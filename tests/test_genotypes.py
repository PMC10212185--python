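"""Genotype I/O, QC, SNP windows, system matrices and LD."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hiergwas.genotypes import (
    GeneLocus,
    GenotypeMatrix,
    VariantRecord,
    assign_snps_to_genes,
    build_system_matrix,
    hwe_exact_p,
    ld_r2,
    qc_filter,
    read_genotypes,
    write_plink,
    write_vcf,
)
from hiergwas._util import DataError

VCF_SMALL = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
1\t100\trs1\tA\tC\t.\tPASS\t.\tGT\t0/0\t0/1
1\t200\trs2\tA\tC\t.\tPASS\t.\tGT\t./.\t0/1
"""

VCF_MULTI = VCF_SMALL + "1\t300\trs3\tA\tC,G\t.\tPASS\t.\tGT\t0/1\t0/2\n"


@pytest.fixture
def small_vcf(tmp_path):
    p = tmp_path / "small.vcf"
    p.write_text(VCF_SMALL)
    return p


def random_gm(rng, n=30, s=8, missing_rate=0.1) -> GenotypeMatrix:
    dos = rng.choice([0.0, 1.0, 2.0], size=(n, s), p=[0.6, 0.3, 0.1])
    dos[rng.random((n, s)) < missing_rate] = np.nan
    variants = [
        VariantRecord(id=f"v{j}", chrom="1", pos=1000 + 50 * j, ref="A", alt="C")
        for j in range(s)
    ]
    return GenotypeMatrix([f"I{i}" for i in range(n)], variants, dos)


class TestReaders:
    def test_vcf_dosage_and_missing(self, small_vcf):
        gm = read_genotypes(small_vcf, "vcf")
        assert gm.sample_ids == ["S1", "S2"]
        np.testing.assert_array_equal(gm.dosages[:, 0], [0.0, 1.0])
        assert np.isnan(gm.dosages[0, 1]) and gm.dosages[1, 1] == 1.0

    def test_multiallelic_site_skipped_with_warning(self, tmp_path):
        p = tmp_path / "multi.vcf"
        p.write_text(VCF_MULTI)
        with pytest.warns(UserWarning, match="multi-allelic"):
            gm = read_genotypes(p, "vcf")
        assert gm.variant_ids == ["rs1", "rs2"]

    def test_orientation_flips_major_coded_allele(self, tmp_path):
        vcf = VCF_SMALL.replace("0/0\t0/1", "1/1\t0/1")  # alt freq 3/4
        p = tmp_path / "flip.vcf"
        p.write_text(vcf)
        gm = read_genotypes(p, "vcf")
        np.testing.assert_array_equal(gm.dosages[:, 0], [0.0, 1.0])
        assert gm.variants[0].maf == pytest.approx(0.25)

    def test_vcf_and_plink_round_trip_identical(self, tmp_path, rng):
        gm = random_gm(rng)
        write_vcf(gm, tmp_path / "x.vcf")
        write_plink(gm, tmp_path / "x")
        from_vcf = read_genotypes(tmp_path / "x.vcf", "vcf")
        from_plink = read_genotypes(tmp_path / "x", "plink")
        assert from_vcf.sample_ids == from_plink.sample_ids == gm.sample_ids
        assert from_vcf.variant_ids == from_plink.variant_ids == gm.variant_ids
        np.testing.assert_array_equal(
            np.nan_to_num(from_vcf.dosages, nan=-1),
            np.nan_to_num(from_plink.dosages, nan=-1),
        )
        for a, b in zip(from_vcf.variants, from_plink.variants):
            assert a.chrom == b.chrom and a.pos == b.pos
            assert a.maf == pytest.approx(b.maf)


def hwe_oracle(n_hom_major, n_het, n_hom_minor):
    """Exact-fraction enumeration of the conditional het distribution."""
    n = n_hom_major + n_het + n_hom_minor
    n_rare = 2 * min(n_hom_major, n_hom_minor) + n_het
    n_common = 2 * n - n_rare

    def weight(het):
        hom_r = (n_rare - het) // 2
        hom_c = n - het - hom_r
        return Fraction(
            2 ** het * math.factorial(n),
            math.factorial(het) * math.factorial(hom_r) * math.factorial(hom_c),
        )

    hets = list(range(n_rare % 2, n_rare + 1, 2))
    total = sum(weight(h) for h in hets)
    probs = {h: weight(h) / total for h in hets}
    p_obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= p_obs))


class TestQC:
    def test_hwe_exact_matches_enumeration_oracle(self):
        cases = [(20, 60, 20), (5, 0, 5), (0, 10, 0), (3, 4, 3), (25, 3, 2)]
        for counts in cases:
            assert hwe_exact_p(*counts) == pytest.approx(hwe_oracle(*counts), rel=1e-10)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        a=st.integers(min_value=0, max_value=40),
        b=st.integers(min_value=0, max_value=40),
        c=st.integers(min_value=0, max_value=40),
    )
    def test_hwe_exact_is_a_probability_and_allele_symmetric(self, a, b, c):
        p = hwe_exact_p(a, b, c)
        assert 0.0 < p <= 1.0
        assert p == pytest.approx(hwe_exact_p(c, b, a))

    def test_monomorphic_snp_removed(self, rng):
        gm = random_gm(rng, missing_rate=0.0)
        gm.dosages[:, 0] = 0.0
        out = qc_filter(gm, maf_min=0.01, hwe_alpha=0.0)
        assert "v0" not in out.variant_ids

    def test_zero_thresholds_are_identity(self, rng):
        gm = random_gm(rng, missing_rate=0.0)
        out = qc_filter(gm, maf_min=0.0, hwe_alpha=0.0)
        assert out.variant_ids == gm.variant_ids

    def test_qc_never_alters_retained_dosages(self, rng):
        gm = random_gm(rng)
        out = qc_filter(gm, maf_min=0.05, hwe_alpha=1e-6)
        idx = gm.variant_index()
        for j, vid in enumerate(out.variant_ids):
            np.testing.assert_array_equal(
                np.nan_to_num(out.dosages[:, j], nan=-1),
                np.nan_to_num(gm.dosages[:, idx[vid]], nan=-1),
            )

    def test_all_removed_raises(self, rng):
        gm = random_gm(rng, missing_rate=0.0)
        gm.dosages[:] = 0.0
        with pytest.raises(DataError, match="every variant"):
            qc_filter(gm, maf_min=0.01, hwe_alpha=0.0)


class TestSnpAssignment:
    LOCI = [GeneLocus("GENE", "1", 50_000, 52_000)]

    def _variants(self, positions, chrom="1"):
        return [
            VariantRecord(id=f"s{p}", chrom=chrom, pos=p, ref="A", alt="C")
            for p in positions
        ]

    @pytest.mark.parametrize(
        "pos,included",
        [(40_000, True), (39_999, False), (51_000, True), (62_000, True), (62_001, False)],
    )
    def test_window_boundaries_inclusive(self, pos, included):
        out = assign_snps_to_genes(self._variants([pos]), self.LOCI, window_bp=10_000)
        assert (f"s{pos}" in out["GENE"]) is included

    def test_chromosome_label_normalised(self):
        out = assign_snps_to_genes(
            self._variants([51_000], chrom="chr1"), self.LOCI, window_bp=10_000
        )
        assert out["GENE"] == {"s51000"}

    def test_snp_can_map_to_multiple_genes(self):
        loci = self.LOCI + [GeneLocus("GENE2", "1", 52_500, 53_000)]
        out = assign_snps_to_genes(self._variants([51_999]), loci, window_bp=10_000)
        assert out["GENE"] == out["GENE2"] == {"s51999"}


class TestSystemMatrix:
    def test_centering_without_missing(self, rng):
        gm = random_gm(rng, missing_rate=0.0)
        X, means, ids = build_system_matrix(gm, gm.variant_ids)
        np.testing.assert_allclose(X, gm.dosages - gm.dosages.mean(0), atol=1e-12)
        np.testing.assert_allclose(X.mean(axis=0), 0.0, atol=1e-12)

    def test_missing_imputed_to_observed_mean(self):
        variants = [VariantRecord("v", "1", 10, "A", "C")]
        gm = GenotypeMatrix(["a", "b", "c"], variants, np.array([[0.0], [2.0], [np.nan]]))
        X, means, _ = build_system_matrix(gm, ["v"])
        assert means[0] == pytest.approx(1.0)
        np.testing.assert_allclose(X[:, 0], [-1.0, 1.0, 0.0])

    def test_sample_permutation_equivariance(self, rng):
        gm = random_gm(rng)
        perm = rng.permutation(gm.n_samples)
        gm_p = GenotypeMatrix(
            [gm.sample_ids[i] for i in perm], gm.variants, gm.dosages[perm]
        )
        X, _, _ = build_system_matrix(gm, gm.variant_ids)
        Xp, _, _ = build_system_matrix(gm_p, gm_p.variant_ids)
        np.testing.assert_allclose(Xp, X[perm], atol=1e-12)

    def test_columns_in_genomic_order(self, rng):
        gm = random_gm(rng)
        _, _, ids = build_system_matrix(gm, set(gm.variant_ids))
        positions = [gm.variants[gm.variant_index()[i]].pos for i in ids]
        assert positions == sorted(positions)


class TestLD:
    def _gm(self, cols):
        arr = np.array(cols, dtype=float).T
        variants = [
            VariantRecord(f"v{j}", "1", 10 + j, "A", "C") for j in range(arr.shape[1])
        ]
        return GenotypeMatrix([f"I{i}" for i in range(arr.shape[0])], variants, arr)

    def test_identical_columns_r2_one(self):
        gm = self._gm([[0, 1, 2, 1], [0, 1, 2, 1]])
        assert ld_r2(gm, "v0", "v1") == pytest.approx(1.0)

    def test_four_sample_closed_form(self):
        a, b = np.array([0, 0, 1, 2.0]), np.array([2, 1, 0, 0.0])
        expected = (np.cov(a, b, bias=True)[0, 1] / (a.std() * b.std())) ** 2
        gm = self._gm([a, b])
        assert ld_r2(gm, "v0", "v1") == pytest.approx(expected)

    def test_independent_columns_near_zero(self, rng):
        a = (rng.random(10_000) < 0.3).astype(float)
        b = (rng.random(10_000) < 0.3).astype(float)
        gm = self._gm([a, b])
        assert ld_r2(gm, "v0", "v1") < 0.01

    def test_zero_variance_returns_nan_with_warning(self):
        gm = self._gm([[1, 1, 1, 1], [0, 1, 2, 1]])
        with pytest.warns(UserWarning, match="zero variance"):
            assert np.isnan(ld_r2(gm, "v0", "v1"))
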