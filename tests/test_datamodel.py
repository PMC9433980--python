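import io
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from plastinet.datamodel import (
    TimeGrid,
    compute_plasticity,
    filter_snps,
    hwe_exact_test,
    read_genotypes,
    read_phenotypes,
    write_genotypes,
    write_phenotypes,
)


@pytest.fixture()
def grid4():
    return TimeGrid([1.0, 2.0, 3.0, 4.0])


def _pheno_csv(tmp_path, rows, T=4):
    cols = "genotype,condition,replicate," + ",".join(f"t{k}" for k in range(1, T + 1))
    path = tmp_path / "pheno.csv"
    path.write_text(cols + "\n" + "\n".join(rows) + "\n")
    return path


class TestReadPhenotypes:
    def test_replicates_are_averaged(self, tmp_path, grid4):
        path = _pheno_csv(tmp_path, [
            "g1,control,1,10,20,30,40",
            "g1,control,2,12,22,32,42",
            "g1,stress,1,5,10,15,20",
        ])
        traj = read_phenotypes(path, grid4)
        assert traj.ids == ["g1"]
        np.testing.assert_allclose(traj.control[0], [11, 21, 31, 41])

    def test_incomplete_genotype_dropped_with_warning(self, tmp_path, grid4):
        path = _pheno_csv(tmp_path, [
            "g1,control,1,10,20,30,40",
            "g1,stress,1,5,10,15,20",
            "g2,control,1,9,19,29,39",
        ])
        with pytest.warns(UserWarning, match="g2"):
            traj = read_phenotypes(path, grid4)
        assert traj.ids == ["g1"]

    def test_row_order_is_irrelevant(self, tmp_path, grid4):
        rows = [
            "g2,stress,1,4,9,14,19",
            "g1,control,1,10,20,30,40",
            "g2,control,1,9,19,29,39",
            "g1,stress,1,5,10,15,20",
        ]
        a = read_phenotypes(_pheno_csv(tmp_path, rows), grid4)
        (tmp_path / "pheno.csv").unlink()
        b = read_phenotypes(_pheno_csv(tmp_path, rows[::-1]), grid4)
        assert a.ids == b.ids
        np.testing.assert_array_equal(a.control, b.control)
        np.testing.assert_array_equal(a.stress, b.stress)

    def test_duplicate_rows_rejected(self, tmp_path, grid4):
        path = _pheno_csv(tmp_path, [
            "g1,control,1,10,20,30,40",
            "g1,control,1,11,21,31,41",
            "g1,stress,1,5,10,15,20",
        ])
        with pytest.raises(ValueError, match="duplicate"):
            read_phenotypes(path, grid4)

    def test_non_numeric_cell_rejected(self, tmp_path, grid4):
        path = _pheno_csv(tmp_path, [
            "g1,control,1,10,oops,30,40",
            "g1,stress,1,5,10,15,20",
        ])
        with pytest.raises(ValueError, match="non-numeric"):
            read_phenotypes(path, grid4)

    def test_round_trip(self, tmp_path, grid4, null_population):
        traj, _, _ = null_population
        path = tmp_path / "rt.csv"
        write_phenotypes(traj, path)
        back = read_phenotypes(path, traj.grid)
        assert back.ids == traj.ids
        np.testing.assert_allclose(back.control, traj.control)
        np.testing.assert_allclose(back.stress, traj.stress)


class TestReadGenotypes:
    def test_csv_round_trip(self, tmp_path, null_population):
        _, geno, _ = null_population
        path = tmp_path / "geno.csv"
        write_genotypes(geno, path)
        back = read_genotypes(path, "csv")
        assert back.snp_ids == geno.snp_ids
        assert back.individual_ids == geno.individual_ids
        np.testing.assert_array_equal(back.codes, geno.codes)

    def test_vcf_allele_counting(self, tmp_path):
        vcf = textwrap.dedent("""\
            ##fileformat=VCFv4.2
            ##contig=<ID=1>
            #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
            1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1
            1\t200\trs2\tC\tT\t.\tPASS\t.\tGT\t0/1\t./.\t0/0
            1\t300\trs3\tG\tA,C\t.\tPASS\t.\tGT\t0/1\t0/2\t0/0
            """)
        path = tmp_path / "g.vcf"
        path.write_text(vcf)
        with pytest.warns(UserWarning, match="multi-allelic"):
            g = read_genotypes(path, "vcf")
        assert g.snp_ids == ["rs1", "rs2"]
        np.testing.assert_array_equal(g.codes[0], [0, 1, 2])
        assert g.codes[1, 1] == -9  # missing

    def test_two_class_snp_is_testcross_in_f1(self, tmp_path):
        path = tmp_path / "g.csv"
        path.write_text("snp,i1,i2,i3,i4\ns1,0,1,0,1\ns2,0,1,2,1\n")
        g = read_genotypes(path, "csv", default_class="intercross")
        assert g.marker_class == ["testcross", "intercross"]

    def test_monomorphic_snp_flagged_unusable(self, tmp_path):
        path = tmp_path / "g.csv"
        path.write_text("snp,i1,i2,i3\ns1,0,0,0\ns2,0,1,2\n")
        g = read_genotypes(path, "csv")
        assert list(g.usable) == [False, True]


def hwe_exact_oracle(n0, n1, n2):
    """Brute-force exact HWE p-value by direct enumeration."""
    n = n0 + n1 + n2
    rare = min(2 * n0 + n1, 2 * n2 + n1)
    probs = {}
    for het in range(rare % 2, rare + 1, 2):
        hom_rare = (rare - het) // 2
        hom_common = n - het - hom_rare
        if hom_common < 0:
            continue
        # P(het | rare allele count) via multinomial/hypergeometric weights
        probs[het] = (
            comb(n, hom_rare, exact=True)
            * comb(n - hom_rare, het, exact=True)
            * 2**het
        )
    total = sum(probs.values())
    p_obs = probs[n1] / total
    return sum(p / total for p in probs.values() if p / total <= p_obs * (1 + 1e-12))


class TestFilterSnps:
    @pytest.mark.parametrize("counts", [(0, 100, 0), (25, 50, 25), (10, 20, 70),
                                        (3, 5, 9), (50, 10, 40)])
    def test_hwe_matches_enumeration_oracle(self, counts):
        assert hwe_exact_test(*counts) == pytest.approx(
            hwe_exact_oracle(*counts), rel=1e-9
        )

    def test_all_heterozygous_rejected(self):
        assert hwe_exact_test(0, 100, 0) < 1e-6

    def test_perfect_hwe_retained_and_rare_removed(self, tmp_path):
        # SNP a: perfect HWE at MAF .5; SNP b: 4 alt alleles in 123 inds
        ids = [f"i{k}" for k in range(123)]
        codes_a = [0] * 25 + [1] * 50 + [2] * 25 + [0] * 23
        codes_b = [1] * 4 + [0] * 119
        path = tmp_path / "g.csv"
        path.write_text(
            "snp," + ",".join(ids) + "\n"
            + "a," + ",".join(map(str, codes_a)) + "\n"
            + "b," + ",".join(map(str, codes_b)) + "\n"
        )
        g = read_genotypes(path, "csv")
        kept = filter_snps(g, maf_min=0.05, hwe_alpha=1e-4)
        assert kept.snp_ids == ["a"]


class TestPlasticity:
    def test_elementwise_difference_and_signs(self, grid4, null_population):
        traj, _, _ = null_population
        z = compute_plasticity(traj)
        np.testing.assert_array_equal(z.z, traj.control - traj.stress)

    def test_zero_for_identical_conditions(self, null_population):
        traj, _, _ = null_population
        traj2 = type(traj)(ids=traj.ids, grid=traj.grid,
                           control=traj.control, stress=traj.control)
        assert np.all(compute_plasticity(traj2).z == 0)

    def test_linearity_in_control_arm(self, null_population):
        traj, _, _ = null_population
        c = 3.7
        shifted = type(traj)(ids=traj.ids, grid=traj.grid,
                             control=traj.control + c, stress=traj.stress)
        np.testing.assert_allclose(
            compute_plasticity(shifted).z, compute_plasticity(traj).z + c
        )
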