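import numpy as np
import pytest

from cassgs import markers as mk
from cassgs.markers import MarkerMatrix


def _mm(dosages, clones=None, markers=None):
    dosages = np.asarray(dosages, dtype=float)
    clones = clones or [f"c{i}" for i in range(dosages.shape[0])]
    markers = markers or [f"m{j}" for j in range(dosages.shape[1])]
    return MarkerMatrix(clones, markers, dosages)


class TestMarkerMatrix:
    def test_rejects_bad_dosages(self):
        with pytest.raises(ValueError):
            _mm([[0, 3]])
        with pytest.raises(ValueError):
            _mm([[-1, 1]])

    def test_imputed_fractional_dosages_accepted(self):
        # qc_filter imputes to the column mean, which is fractional
        m = _mm([[0, 0], [1, 0], [np.nan, 2]])
        out = mk.qc_filter(m, 0.0)
        assert out.dosages[2, 0] == pytest.approx(0.5)
        with pytest.raises(ValueError, match="imputed"):
            out.to_vcf("/dev/null")

    def test_allele_freq_ignores_missing(self):
        m = _mm([[0, 2], [2, np.nan]])
        assert m.allele_freq[0] == pytest.approx(0.5)
        assert m.allele_freq[1] == pytest.approx(1.0)

    def test_centered_requires_complete(self):
        with pytest.raises(ValueError, match="missing"):
            _mm([[0, np.nan]]).centered()


class TestIO:
    def test_dosage_csv_round_trip(self, toy, tmp_path):
        geno, _ = toy
        path = tmp_path / "g.csv"
        geno.to_dosage_csv(path)
        back = MarkerMatrix.from_dosage_csv(path)
        assert back.clone_ids == geno.clone_ids
        assert back.marker_ids == geno.marker_ids
        assert np.array_equal(back.dosages, geno.dosages)

    def test_dosage_csv_requires_clone_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("id,m1\nA,0\n")
        with pytest.raises(ValueError, match="clone"):
            MarkerMatrix.from_dosage_csv(path)

    def test_vcf_round_trip_with_missing(self, tmp_path):
        dos = np.array([[0.0, 1.0], [2.0, np.nan], [1.0, 0.0]])
        m = _mm(dos)
        path = tmp_path / "g.vcf"
        m.to_vcf(path)
        back = MarkerMatrix.from_vcf(path)
        assert back.clone_ids == m.clone_ids
        assert back.marker_ids == m.marker_ids
        assert np.array_equal(np.isnan(back.dosages), np.isnan(dos))
        assert np.array_equal(back.dosages[~np.isnan(dos)], dos[~np.isnan(dos)])

    def test_vcf_genotype_coding(self, tmp_path):
        # 0/0, 0/1, 1/1 at one site -> column [0, 1, 2]
        path = tmp_path / "one.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\tC\n"
            "1\t1\tsnp1\tA\tT\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n")
        m = MarkerMatrix.from_vcf(path)
        assert np.array_equal(m.dosages[:, 0], [0.0, 1.0, 2.0])

    def test_multiallelic_vcf_rejected(self, tmp_path):
        path = tmp_path / "multi.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\n"
            "1\t42\tsnpX\tA\tT,G\t.\tPASS\t.\tGT\t0/0\t0/1\n")
        with pytest.raises(ValueError, match="1:42"):
            MarkerMatrix.from_vcf(path)

    def test_relationship_matrix_csv_round_trip(self, tmp_path, matrices80):
        G = matrices80[0]
        path = tmp_path / "G.csv"
        G.to_csv(path)
        back = mk.RelationshipMatrix.from_csv(path, "additive")
        assert back.clone_ids == G.clone_ids
        assert np.allclose(back.values, G.values, atol=1e-12)


class TestQCFilter:
    def test_hand_counted_maf(self):
        # columns engineered to p = 0.5, 0.005, 0.0, 1.0 over 100 clones
        n = 100
        dos = np.zeros((n, 4))
        dos[: n // 2, 0] = 2.0       # p = 0.5
        dos[0, 1] = 1.0              # p = 0.005
        dos[:, 2] = 0.0              # p = 0
        dos[:, 3] = 2.0              # p = 1
        m = _mm(dos)
        kept = mk.qc_filter(m, 0.01)
        assert kept.marker_ids == ["m0"]

    def test_threshold_zero_keeps_all_and_imputes(self):
        m = _mm([[0, np.nan], [2, 2]])
        out = mk.qc_filter(m, 0.0)
        assert out.n_markers == 2
        assert not out.has_missing
        assert out.dosages[0, 1] == pytest.approx(2.0)  # imputed to column mean

    def test_toy_fixture_keeps_five_of_six(self, toy):
        geno, _ = toy
        assert mk.qc_filter(geno, 0.01).n_markers == 5

    def test_all_removed_raises(self, toy):
        geno, _ = toy
        with pytest.raises(ValueError, match="all .* removed|all 6"):
            mk.qc_filter(geno, 0.5)

    def test_idempotent(self, geno80):
        once = mk.qc_filter(geno80, 0.05)
        twice = mk.qc_filter(once, 0.05)
        assert twice.marker_ids == once.marker_ids
        assert np.array_equal(twice.dosages, once.dosages)

    def test_threshold_validated(self, geno80):
        with pytest.raises(ValueError):
            mk.qc_filter(geno80, 0.6)


class TestAdditiveGRM:
    def test_hand_example(self):
        # dosages [[0,2],[2,0]], p = [0.5, 0.5]: denominator = 1, G = [[2,-2],[-2,2]]
        m = _mm([[0, 2], [2, 0]])
        G = mk.build_additive_grm(m)
        assert G.denominator == pytest.approx(1.0)
        assert np.allclose(G.values, [[2.0, -2.0], [-2.0, 2.0]])

    def test_identical_clones_identical_rows(self):
        m = _mm([[0, 1, 2], [0, 1, 2], [2, 1, 0]])
        G = mk.build_additive_grm(m).values
        assert np.allclose(G[0], G[1])
        assert G[0, 0] == pytest.approx(G[1, 1])

    def test_monomorphic_denominator_error(self):
        with pytest.raises(ValueError, match="monomorphic"):
            mk.build_additive_grm(_mm([[0, 2], [0, 2]]))

    def test_hwe_mean_diagonal_near_one(self):
        rng = np.random.default_rng(21)
        p = rng.uniform(0.1, 0.5, 500)
        dos = rng.binomial(2, p, size=(50, 500)).astype(float)
        G = mk.build_additive_grm(_mm(dos))
        assert abs(np.mean(np.diag(G.values)) - 1.0) < 0.1
        # sample-frequency centering zeroes every column sum of Z, so the
        # grand sum of G is exactly 0 and the off-diagonal mean equals
        # -trace/(n(n-1)) ~ -1/(n-1); unrelated clones are "0" only up to
        # that centering artifact
        assert abs(G.values.sum()) < 1e-8
        off = G.values[np.triu_indices(50, 1)]
        expected = -np.trace(G.values) / (50 * 49)
        assert abs(off.mean() - expected) < 3 * off.std() / np.sqrt(off.size)

    def test_permutation_equivariance(self, geno80):
        G = mk.build_additive_grm(geno80)
        perm = np.random.default_rng(4).permutation(geno80.n_clones)
        shuffled = geno80.subset_clones([geno80.clone_ids[i] for i in perm])
        G2 = mk.build_additive_grm(shuffled)
        assert np.allclose(G2.values, G.values[np.ix_(perm, perm)], atol=1e-12)


class TestDominanceGRM:
    def test_hand_example(self):
        # single marker p = 0.5, both clones heterozygous:
        # H = [0.5, 0.5], denom = 2 * 0.25 * 0.75 = 0.375, D = [[2/3, 2/3], ...]
        m = _mm([[1], [1]])
        D = mk.build_dominance_grm(m)
        assert np.allclose(D.values, 2.0 / 3.0)

    def test_design_coding(self):
        m = _mm([[0], [1], [2], [1]])  # p = 0.5
        H = mk.dominance_design(m)
        assert np.allclose(H.ravel(), [-0.5, 0.5, -0.5, 0.5])

    def test_degenerate_error(self):
        # all homozygous at p in {0, 1}: zero denominator
        with pytest.raises(ValueError, match="denominator"):
            mk.build_dominance_grm(_mm([[0, 2], [0, 2]]))

    def test_denominator_switch_rescales(self, geno80):
        printed = mk.build_dominance_grm(geno80, "printed")
        alt = mk.build_dominance_grm(geno80, "vitezica")
        p = geno80.allele_freq
        q = 1 - p
        ratio = (2 * np.sum(p * q * (1 - p * q))) / np.sum((2 * p * q) ** 2)
        assert np.allclose(alt.values, printed.values * ratio, atol=1e-10)

    def test_unknown_denominator(self, geno80):
        with pytest.raises(ValueError):
            mk.build_dominance_grm(geno80, "other")

    def test_permutation_equivariance(self, geno80):
        D = mk.build_dominance_grm(geno80)
        perm = np.random.default_rng(5).permutation(geno80.n_clones)
        shuffled = geno80.subset_clones([geno80.clone_ids[i] for i in perm])
        D2 = mk.build_dominance_grm(shuffled)
        assert np.allclose(D2.values, D.values[np.ix_(perm, perm)], atol=1e-12)


class TestGaussianKernel:
    def test_unit_diagonal_and_range(self, matrices80):
        K = matrices80[2].values
        assert np.allclose(np.diag(K), 1.0)
        assert (K > 0).all() and (K <= 1.0).all()

    def test_two_clone_median(self):
        m = _mm([[0, 0], [2, 2]])
        K = mk.build_gaussian_kernel(m, h=1.0)
        assert K.values[0, 1] == pytest.approx(np.exp(-1.0))
        K3 = mk.build_gaussian_kernel(m, h=3.0)
        assert K3.values[0, 1] == pytest.approx(np.exp(-3.0))

    def test_doubling_h_squares_offdiagonals(self, geno80):
        K1 = mk.build_gaussian_kernel(geno80, 1.0).values
        K2 = mk.build_gaussian_kernel(geno80, 2.0).values
        assert np.allclose(K2, K1 ** 2, atol=1e-12)

    def test_monotone_in_distance(self, geno80):
        from scipy.spatial.distance import pdist, squareform
        K = mk.build_gaussian_kernel(geno80, 1.0).values
        dist = squareform(pdist(geno80.centered()))
        iu = np.triu_indices(geno80.n_clones, 1)
        order = np.argsort(dist[iu])
        k_sorted = K[iu][order]
        assert (np.diff(k_sorted) <= 1e-12).all()

    def test_identical_clones_error(self):
        m = _mm([[1, 1], [1, 1]])
        with pytest.raises(ValueError, match="distance"):
            mk.build_gaussian_kernel(m, 1.0)

    def test_invalid_bandwidth(self, geno80):
        with pytest.raises(ValueError):
            mk.build_gaussian_kernel(geno80, 0.0)

    def test_raw_vs_centered_coding(self, geno80):
        # centering is a per-column shift, so Euclidean distances (and K) match
        K_raw = mk.build_gaussian_kernel(geno80, 1.0, coding="raw").values
        K_cen = mk.build_gaussian_kernel(geno80, 1.0, coding="centered").values
        assert np.allclose(K_raw, K_cen, atol=1e-10)
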