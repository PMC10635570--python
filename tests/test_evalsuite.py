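import numpy as np
import pytest

from genomeforge.haplotype_io import HaplotypeMatrix
from genomeforge.privacy import AAtsResult, aa_ts
from genomeforge.synthetic_data import PopSimConfig, binomial_baseline, simulate_structured_haplotypes
from genomeforge import evalsuite as ev


@pytest.fixture(scope="module")
def panel():
    return simulate_structured_haplotypes(
        PopSimConfig(n_pops=2, n_hap_per_pop=50, n_snps=120, fst=0.2, seed=21))


class TestAlleleFreq:
    def test_identity_is_fixed_point(self, panel):
        rep = ev.allele_freq_report(panel, panel)
        assert rep.r_all == pytest.approx(1.0)
        assert rep.slope_all == pytest.approx(1.0)
        assert rep.intercept_all == pytest.approx(0.0, abs=1e-12)

    def test_hand_counts(self):
        real = HaplotypeMatrix(np.array([[0, 1, 1], [0, 1, 0], [1, 1, 0], [1, 1, 1]]))
        rep = ev.allele_freq_report(real, real)
        assert np.allclose(rep.real_freq, [0.5, 1.0, 0.5])

    def test_binomial_baseline_converges(self, panel):
        gen = binomial_baseline(panel, 8000, seed=1)
        rep = ev.allele_freq_report(panel, gen)
        assert rep.r_all > 0.99

    def test_constant_frequencies_reported_as_undefined(self):
        m = HaplotypeMatrix(np.array([[1, 1], [1, 1]]))
        rep = ev.allele_freq_report(m, m)
        assert rep.r_all is None


class TestLdDecay:
    def test_duplicated_column_pair_r2_one(self):
        rng = np.random.default_rng(0)
        col = rng.integers(0, 2, 40)
        others = rng.integers(0, 2, (40, 6))
        x = HaplotypeMatrix(np.column_stack([col, others, col]))
        tab = ev.ld_decay(x, x, n_pairs=4000, seed=1)
        pair_mask = tab.pair_distances == 7  # the duplicated columns sit 7 apart
        assert pair_mask.any()
        # among sampled pairs at distance 7, the duplicated pair has r² = 1
        assert tab.r2_real[pair_mask].max() == pytest.approx(1.0)

    def test_hand_r2_formula(self):
        # 6 haplotypes, textbook D²/(p1 q1 p2 q2)
        a = np.array([1, 1, 1, 0, 0, 0])
        b = np.array([1, 1, 0, 0, 0, 0])
        p1, p2 = a.mean(), b.mean()
        d = (a * b).mean() - p1 * p2
        expected = d * d / (p1 * (1 - p1) * p2 * (1 - p2))
        r2 = ev._r2_pairs(np.column_stack([a, b]).astype(float), np.array([0]), np.array([1]))
        assert r2[0] == pytest.approx(expected)

    def test_independent_sites_near_null(self):
        n = 300
        m = simulate_structured_haplotypes(PopSimConfig(
            n_pops=1, n_hap_per_pop=n, n_snps=200, copy_switch_prob=1.0, seed=2))
        tab = ev.ld_decay(m, m, n_pairs=5000, seed=3)
        ok = ~np.isnan(tab.mean_r2_real)
        assert np.nanmean(tab.mean_r2_real[ok]) == pytest.approx(1 / n, rel=0.5)

    def test_fixed_sites_removed_and_too_few_rejected(self):
        m = HaplotypeMatrix(np.array([[1, 0, 1], [1, 0, 1]]))
        with pytest.raises(ValueError, match="segregating"):
            ev.ld_decay(m, m, n_pairs=10)


class TestThreePoint:
    def test_identity_correlation_one(self, panel):
        rep = ev.three_point_report(panel, panel, spacings=(1, 4, 16), n_random_triplets=300, seed=0)
        for r in rep.per_spacing_r.values():
            assert r == pytest.approx(1.0)
        assert rep.random_r == pytest.approx(1.0)

    def test_hand_triplet_statistic(self):
        x = np.array([[1, 1, 0], [1, 0, 1], [0, 1, 1], [1, 1, 1], [0, 0, 0]], dtype=float)
        c = x - x.mean(axis=0)
        expected = (c[:, 0] * c[:, 1] * c[:, 2]).mean()
        stat = ev._triplet_stat(x, np.array([0]), np.array([1]), np.array([2]))
        assert stat[0] == pytest.approx(expected)

    def test_constant_column_gives_zero_statistic(self):
        x = np.array([[1, 1, 0], [1, 0, 1], [1, 1, 1]], dtype=float)
        stat = ev._triplet_stat(x, np.array([0]), np.array([1]), np.array([2]))
        assert stat[0] == 0.0

    def test_too_wide_spacings_skipped(self, panel):
        rep = ev.three_point_report(panel, panel, spacings=(1, 1024), n_random_triplets=50, seed=0)
        assert rep.skipped_spacings == [1024]
        assert 1 in rep.per_spacing_r


def kmer_counts_bruteforce(x: np.ndarray, k: int):
    counts = {}
    for w, start in enumerate(range(0, x.shape[1] - k + 1, k)):
        for row in x[:, start:start + k]:
            key = (w, "".join(str(int(v)) for v in row))
            counts[key] = counts.get(key, 0) + 1
    return counts


class TestKmer:
    def test_identical_haplotypes_single_window(self):
        x = HaplotypeMatrix(np.tile([0, 1, 0, 1], (10, 1)))
        rep = ev.kmer_report(x, x, k=4)
        assert rep.counts_real == {(0, "0101"): 10}
        assert rep.r == pytest.approx(1.0) or rep.r is None  # single motif: zero variance

    def test_matches_bruteforce(self, rng):
        x = rng.integers(0, 2, (20, 16))
        y = rng.integers(0, 2, (20, 16))
        rep = ev.kmer_report(HaplotypeMatrix(x), HaplotypeMatrix(y), k=4)
        assert rep.counts_real == kmer_counts_bruteforce(x, 4)
        assert rep.counts_generated == kmer_counts_bruteforce(y, 4)

    def test_identity_r_one(self, panel):
        rep = ev.kmer_report(panel, panel, k=4)
        assert rep.r == pytest.approx(1.0)


class TestPairwiseDistance:
    def test_identity_fixed_point(self, panel):
        rep = ev.pairwise_distance_report(panel, panel)
        assert rep.wasserstein == pytest.approx(0.0)
        assert rep.between.min() == 0

    def test_two_blocks(self):
        r = HaplotypeMatrix(np.zeros((2, 6), dtype=np.int8))
        g = HaplotypeMatrix(np.ones((2, 6), dtype=np.int8))
        rep = ev.pairwise_distance_report(r, g)
        assert np.all(rep.between == 6)
        assert np.all(rep.within_real == 0)

    def test_matches_bruteforce(self, rng):
        r = rng.integers(0, 2, (5, 8))
        g = rng.integers(0, 2, (5, 8))
        rep = ev.pairwise_distance_report(HaplotypeMatrix(r), HaplotypeMatrix(g))
        wr = sorted((r[i] != r[j]).sum() for i in range(5) for j in range(i + 1, 5))
        bt = sorted((r[i] != g[j]).sum() for i in range(5) for j in range(5))
        assert sorted(rep.within_real.tolist()) == [float(v) for v in wr]
        assert sorted(rep.between.tolist()) == [float(v) for v in bt]


class TestFixedAlleles:
    def test_identity(self, panel):
        rep = ev.fixed_allele_report(panel, panel)
        assert rep.n_fixed_generated == rep.n_fixed_real
        assert rep.n_generated_fixed_real_polymorphic == 0

    def test_all_zero_generated(self):
        r = HaplotypeMatrix(np.array([[0, 1, 1], [1, 0, 1], [0, 1, 1]]))
        g = HaplotypeMatrix(np.zeros((3, 3), dtype=np.int8))
        rep = ev.fixed_allele_report(r, g)
        assert rep.n_fixed_generated == 3
        assert rep.n_generated_fixed_real_polymorphic == 2  # two segregating real sites


class TestPca:
    def test_identity_scores_match(self, panel):
        sc = ev.pca_scores(panel, panel, n_components=3)
        assert np.allclose(sc.real_scores, sc.generated_scores)
        assert np.allclose(sc.components @ sc.components.T, np.eye(3), atol=1e-8)

    def test_component_one_separates_populations(self):
        m = simulate_structured_haplotypes(PopSimConfig(
            n_pops=2, n_hap_per_pop=80, n_snps=300, fst=0.25, seed=4))
        sc = ev.pca_scores(m, m, n_components=2)
        labels = np.repeat([0, 1], 80)
        from sklearn.metrics import silhouette_score
        assert silhouette_score(sc.real_scores[:, :1], labels) > 0.3

    def test_degenerate_rejected(self):
        m = HaplotypeMatrix(np.ones((4, 5), dtype=np.int8))
        with pytest.raises(ValueError, match="degenerate"):
            ev.pca_scores(m, m)


def _aa(truth_val, syn_val):
    z = np.zeros(1)
    return AAtsResult(truth_val, syn_val, (truth_val + syn_val) / 2, z, z, z, z)


def _ld_table(real_means, gen_means):
    n = len(real_means)
    return ev.LdDecayTable(np.arange(n + 1, dtype=float), np.array(real_means, float),
                           np.array(gen_means, float), np.zeros(1), np.zeros(1), np.zeros(1),
                           "index", 1)


class TestRadar:
    def test_balanced_aa_gives_perfect_scores(self):
        rs = ev.radar_scores(_aa(0.5, 0.5), _ld_table([0.2, 0.1], [0.2, 0.1]), 0.9, 0.8, 1.0, 2.0)
        assert rs.overfitting == pytest.approx(1.0)
        assert rs.underfitting == pytest.approx(1.0)

    def test_printed_component_values(self):
        # AA components of the published WGAN run: only underfitting is penalised
        rs = ev.radar_scores(_aa(0.77, 0.87), _ld_table([0.2], [0.2]), 0.9, 0.8, None, None)
        assert rs.underfitting == pytest.approx(1 - (0.77 - 0.5) - (0.87 - 0.5))
        assert rs.underfitting == pytest.approx(0.36)
        assert rs.overfitting == pytest.approx(1.0)

    def test_overfit_side(self):
        rs = ev.radar_scores(_aa(0.3, 0.4), _ld_table([0.2], [0.2]), 0.9, 0.8, None, None)
        assert rs.overfitting == pytest.approx(1 - 0.2 - 0.1)
        assert rs.underfitting == pytest.approx(1.0)

    def test_ld_score(self):
        rs = ev.radar_scores(_aa(0.5, 0.5), _ld_table([0.2, 0.4], [0.2, 0.4]), None, None, None, None)
        assert rs.ld == pytest.approx(1.0)
        rs2 = ev.radar_scores(_aa(0.5, 0.5), _ld_table([0.2, 0.4], [0.0, 0.0]), None, None, None, None)
        assert rs2.ld == pytest.approx(0.0, abs=1e-12)  # 1 - sum(LD²)/sum(LD²)

    def test_pairwise_scaling(self):
        rs = ev.radar_scores(_aa(0.5, 0.5), _ld_table([0.2], [0.2]), None, None, 0.5, 2.0)
        assert rs.pairwise_distance == pytest.approx(0.75)
        assert ev.radar_scores(_aa(0.5, 0.5), _ld_table([0.2], [0.2]), None, None, 1.0, 0.0).pairwise_distance is None

    def test_scores_clamped(self):
        rs = ev.radar_scores(_aa(0.0, 0.0), _ld_table([0.1], [0.9]), -0.5, 1.5, 5.0, 1.0)
        for v in (rs.allele_frequency, rs.three_point, rs.pairwise_distance,
                  rs.overfitting, rs.underfitting, rs.ld):
            assert 0.0 <= v <= 1.0
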