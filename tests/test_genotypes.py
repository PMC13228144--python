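"""Data model, file round-trips, filtering, diversity, kinship, folded SFS."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from selfkit.genotypes import (MISSING, GenotypeMatrix, diversity_summary,
                               filter_loci, folded_sfs, king_kinship,
                               observed_heterozygosity, read_genotypes,
                               write_genotypes)
from conftest import make_gm


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("bad", [
    dict(genotypes=np.array([[3, 0]]), sample_ids=["a"],
         population_labels=["p"], locus_ids=["l1", "l2"]),
    dict(genotypes=np.zeros((2, 2)), sample_ids=["a", "a"],
         population_labels=["p", "p"], locus_ids=["l1", "l2"]),
    dict(genotypes=np.zeros((2, 2)), sample_ids=["a", "b"],
         population_labels=["p", ""], locus_ids=["l1", "l2"]),
    dict(genotypes=np.zeros((2, 2)), sample_ids=["a", "b"],
         population_labels=["p", "p"], locus_ids=["l1", "l1"]),
])
def test_invalid_matrices_rejected(bad):
    with pytest.raises(ValueError):
        GenotypeMatrix(**bad)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("fmt", ["vcf", "structure", "matrix012"])
def test_round_trip_preserves_genotypes(fmt, tmp_path, small_gm):
    path = tmp_path / f"gm.{fmt}"
    write_genotypes(small_gm, path, fmt)
    back = read_genotypes(path, fmt)
    np.testing.assert_array_equal(back.genotypes, small_gm.genotypes)
    assert back.sample_ids == small_gm.sample_ids
    assert back.locus_ids == small_gm.locus_ids
    if fmt == "structure":  # the only format carrying population metadata
        assert back.population_labels == small_gm.population_labels


def test_write_is_bit_stable(tmp_path, small_gm):
    a, b = tmp_path / "a.vcf", tmp_path / "b.vcf"
    write_genotypes(small_gm, a, "vcf")
    write_genotypes(small_gm, b, "vcf")
    assert a.read_bytes() == b.read_bytes()


def test_vcf_gt_fields_hand_parsed(tmp_path):
    # two samples with GTs 0/1 and 1/1 at one site -> column (1, 2)
    vcf = (
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n"
        "1\t100\tsnp1\tA\tT\t.\t.\t.\tGT\t0/1\t1/1\n"
        "1\t200\tsnp2\tG\tC\t.\t.\t.\tGT\t./.\t0|0\n"
    )
    path = tmp_path / "two.vcf"
    path.write_text(vcf)
    gm = read_genotypes(path, "vcf")
    np.testing.assert_array_equal(gm.genotypes[:, 0], [1, 2])
    np.testing.assert_array_equal(gm.genotypes[:, 1], [MISSING, 0])
    assert gm.locus_ids == ["snp1", "snp2"]


def test_multiallelic_vcf_rejected_with_locus_name(tmp_path):
    vcf = (
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
        "1\t100\tbadsnp\tA\tG,T\t.\t.\t.\tGT\t0/1\n"
    )
    path = tmp_path / "multi.vcf"
    path.write_text(vcf)
    with pytest.raises(ValueError, match="badsnp"):
        read_genotypes(path, "vcf")


def test_matrix012_writes_literal_codes(tmp_path):
    gm = make_gm([[1], [2]])
    path = tmp_path / "m.tsv"
    write_genotypes(gm, path, "matrix012")
    lines = path.read_text().splitlines()
    assert lines[1].split("\t")[2] == "1"
    assert lines[2].split("\t")[2] == "2"


def test_empty_matrix_round_trips(tmp_path):
    gm = make_gm(np.empty((2, 0), dtype=np.int8))
    for fmt in ("vcf", "structure", "matrix012"):
        path = tmp_path / f"empty.{fmt}"
        write_genotypes(gm, path, fmt)
        back = read_genotypes(path, fmt)
        assert back.n_loci == 0
        assert back.n_individuals == 2


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(2, 8), st.integers(1, 12), st.integers(0, 10_000))
def test_structure_round_trip_property(n, L, seed):
    rng = np.random.default_rng(seed)
    geno = rng.integers(0, 3, size=(n, L)).astype(np.int8)
    geno[rng.random(geno.shape) < 0.2] = MISSING
    gm = make_gm(geno)
    import tempfile, os
    with tempfile.TemporaryDirectory() as d:
        path = os.path.join(d, "g.str")
        write_genotypes(gm, path, "structure")
        back = read_genotypes(path, "structure")
    np.testing.assert_array_equal(back.genotypes, gm.genotypes)


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def test_filter_identity(small_gm):
    out = filter_loci(small_gm, max_missing_frac=1.0, min_maf=0.0)
    np.testing.assert_array_equal(out.genotypes, small_gm.genotypes)


def test_filter_drops_high_missing_locus():
    geno = np.zeros((10, 2), dtype=np.int8)
    geno[:2, 0] = MISSING
    geno[0, 1] = 1  # keep locus 2 polymorphic
    gm = make_gm(geno)
    out = filter_loci(gm, max_missing_frac=0.1, min_maf=0.0)
    assert out.locus_ids == ["L1"]


def test_filter_maf_boundary():
    # genotypes (0,0,0,1): alt count 1 of 8 alleles -> MAF 0.125
    gm = make_gm(np.array([[0], [0], [0], [1]]))
    assert filter_loci(gm, min_maf=0.2).n_loci == 0
    assert filter_loci(gm, min_maf=0.1).n_loci == 1


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------

def test_observed_heterozygosity_hand_values():
    gm = make_gm(np.array([[0, 2, 0, 2], [1, 1, 0, MISSING]]))
    ho = observed_heterozygosity(gm)
    assert ho[0] == 0.0
    assert ho[1] == pytest.approx(2 / 3)


def test_group_summary_hand_values():
    # two individuals {(1,1),(1,1)} at 2 loci: H_O = 1, p_hat = 0.5/locus,
    # Nei unbiased H_E = (4/3)*(1 - 0.25 - 0.25) = 2/3
    gm = make_gm(np.array([[1, 1], [1, 1]]))
    summ = diversity_summary(gm)
    row = summ.per_group.iloc[0]
    assert row["h_obs"] == 1.0
    assert row["h_exp"] == pytest.approx(2 / 3)
    assert row["f_is"] == pytest.approx(1 - 1 / (2 / 3))


def test_group_mean_equals_member_mean(small_gm):
    summ = diversity_summary(small_gm)
    for _, row in summ.per_group.iterrows():
        members = summ.per_individual[summ.per_individual["group"] == row["group"]]
        assert row["h_obs"] == pytest.approx(np.nanmean(members["h_obs"]))


def test_individual_with_no_calls_flagged():
    geno = np.array([[MISSING, MISSING], [0, 1], [1, 1]])
    summ = diversity_summary(make_gm(geno))
    assert np.isnan(summ.per_individual["h_obs"].iloc[0])


# ---------------------------------------------------------------------------
# KING-robust kinship
# ---------------------------------------------------------------------------

def king_oracle(gi, gj):
    """Direct per-pair double loop over loci."""
    het_het = opp = ni = nj = 0
    for a, b in zip(gi, gj):
        if a == MISSING or b == MISSING:
            continue
        if a == 1 and b == 1:
            het_het += 1
        if (a == 0 and b == 2) or (a == 2 and b == 0):
            opp += 1
        ni += a == 1
        nj += b == 1
    return (het_het - 2 * opp) / (ni + nj) if ni + nj else np.nan


def test_clone_kinship_is_half(rng):
    g = rng.integers(0, 3, size=100).astype(np.int8)
    assert (g == 1).sum() >= 1
    gm = make_gm(np.vstack([g, g]))
    km = king_kinship(gm)
    assert km.phi[0, 1] == 0.5


def test_opposite_homozygotes_undefined():
    gm = make_gm(np.array([[0] * 10, [2] * 10]))
    km = king_kinship(gm)
    assert np.isnan(km.phi[0, 1])


def test_king_matches_double_loop_oracle(rng):
    for _ in range(5):
        geno = rng.integers(0, 3, size=(10, 50)).astype(np.int8)
        geno[rng.random(geno.shape) < 0.15] = MISSING
        gm = make_gm(geno)
        km = king_kinship(gm, within_population=False)
        for i in range(10):
            for j in range(i + 1, 10):
                expect = king_oracle(geno[i], geno[j])
                if np.isnan(expect):
                    assert np.isnan(km.phi[i, j])
                else:
                    assert km.phi[i, j] == pytest.approx(expect)
        assert np.allclose(km.phi, km.phi.T, equal_nan=True)


def test_unrelated_hwe_pair_phi_near_zero(rng):
    # two independent HWE individuals at p = 0.5: E[numerator] = 0
    L = 20000
    g = rng.binomial(1, 0.5, (2, L)) + rng.binomial(1, 0.5, (2, L))
    km = king_kinship(make_gm(g.astype(np.int8)))
    assert abs(km.phi[0, 1]) < 0.02


def test_within_population_mode_masks_cross_pairs(small_gm):
    km = king_kinship(small_gm, within_population=True)
    assert np.isnan(km.phi[0, 7])  # pops A vs B


# ---------------------------------------------------------------------------
# folded SFS
# ---------------------------------------------------------------------------

def test_folded_sfs_hand_enumeration():
    # loci columns (0,0), (1,0), (1,1), (2,2) over 2 individuals (4 alleles)
    gm = make_gm(np.array([[0, 1, 1, 2], [0, 0, 1, 2]]))
    sfs = folded_sfs(gm)
    np.testing.assert_array_equal(sfs.counts, [2, 1, 1])
    assert sfs.n_alleles == 4
    assert sfs.n_loci_used == 4


def test_monomorphic_mass_in_zero_class():
    gm = make_gm(np.zeros((3, 5), dtype=np.int8))
    sfs = folded_sfs(gm)
    assert sfs.counts[0] == 5
    assert sfs.counts[1:].sum() == 0


def test_projection_to_own_size_is_identity(rng):
    geno = rng.integers(0, 3, size=(6, 40)).astype(np.int8)
    gm = make_gm(geno)
    plain = folded_sfs(gm)
    proj = folded_sfs(gm, projection_n=12)
    np.testing.assert_allclose(proj.counts, plain.counts, atol=1e-9)


def test_projection_conserves_mass(rng):
    geno = rng.integers(0, 3, size=(8, 60)).astype(np.int8)
    geno[rng.random(geno.shape) < 0.1] = MISSING
    sfs = folded_sfs(make_gm(geno), projection_n=10)
    assert sfs.counts.sum() == pytest.approx(sfs.n_loci_used)


@pytest.mark.parametrize("bad_n", [5, 40])
def test_projection_validates_n(bad_n, rng):
    gm = make_gm(rng.integers(0, 3, size=(6, 10)).astype(np.int8))
    with pytest.raises(ValueError):
        folded_sfs(gm, projection_n=bad_n)
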