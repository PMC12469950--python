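"""Filtering, LD pruning, PCA and the differentiation statistics."""

import numpy as np
import pytest

import shellkin as sk
from shellkin.matrix import GenotypeMatrix
from shellkin.popgen import (
    FULL_DATASET_FILTERS,
    FilterConfig,
    filter_variants,
    weir_cockerham_theta,
    wright_fst,
)


def toy_filter_panel():
    """Hand-enumerated 10-site, 50-sample panel for the site filters.

    Sites (IDs): 2 low-depth (DP 5), 1 high-depth (DP 150), 2 with 20%
    missing calls, 1 with MAF 0.01, and 4 clean sites.  Under the standard
    full-dataset thresholds (mean depth 10-130x, genotype depth 10-130x,
    missingness <= 10%, MAF >= 0.02) exactly the 4 clean sites survive.
    """
    rng = np.random.default_rng(2024)
    n = 50
    dosage = np.zeros((n, 10))
    depth = np.full((n, 10), 65.0)
    names = [
        "low_dp_1", "low_dp_2", "high_dp", "miss_1", "miss_2",
        "rare", "clean_1", "clean_2", "clean_3", "clean_4",
    ]
    for j in range(10):
        dosage[:, j] = rng.binomial(2, 0.3, n)
    depth[:, 0] = depth[:, 1] = 5.0
    depth[:, 2] = 150.0
    dosage[:10, 3] = np.nan
    dosage[:10, 4] = np.nan
    dosage[:, 5] = 0.0
    dosage[0, 5] = 1.0  # one het among 50 diploids -> MAF 0.01
    for j, maf in zip(range(6, 10), (0.2, 0.3, 0.4, 0.25)):
        dosage[:, j] = rng.binomial(2, maf, n)
        dosage[0, j] = 1.0  # guarantee polymorphism
    g = GenotypeMatrix([f"s{i:02d}" for i in range(n)], names, dosage)
    return g, depth


class TestFilterVariants:
    def test_toy_panel_keeps_exactly_the_clean_sites(self):
        g, dp = toy_filter_panel()
        out, _dp, report = filter_variants(g, dp, FULL_DATASET_FILTERS)
        assert out.locus_ids == ["clean_1", "clean_2", "clean_3", "clean_4"]
        assert report.removed == {
            "mean_site_depth": 3,
            "site_missingness": 2,
            "maf": 1,
        }

    def test_monomorphic_site_removed_by_maf(self):
        g = GenotypeMatrix(
            [f"s{i}" for i in range(10)], ["mono", "poly"],
            np.column_stack([np.full(10, 2.0), np.array([0, 1] * 5, dtype=float)]),
        )
        out, _, report = filter_variants(g, None, FilterConfig(min_maf=0.02))
        assert out.locus_ids == ["poly"]
        assert report.removed["maf"] == 1

    def test_all_thresholds_disabled_is_identity(self):
        g, dp = toy_filter_panel()
        out, _, report = filter_variants(g, dp, FilterConfig())
        assert out.locus_ids == g.locus_ids
        assert np.array_equal(out.dosage, g.dosage, equal_nan=True)

    @pytest.mark.parametrize(
        "tight", [
            {"min_maf": 0.10},
            {"max_site_missingness": 0.0},
            {"min_mean_site_depth": 40},
            {"max_mean_site_depth": 70},
        ],
    )
    def test_tightening_never_enlarges_kept_set(self, tight):
        g, dp = toy_filter_panel()
        base = FULL_DATASET_FILTERS
        _, _, loose_report = filter_variants(g, dp, base)
        cfg = FilterConfig(
            min_mean_site_depth=tight.get("min_mean_site_depth", base.min_mean_site_depth),
            max_mean_site_depth=tight.get("max_mean_site_depth", base.max_mean_site_depth),
            genotype_depth_range=base.genotype_depth_range,
            min_maf=tight.get("min_maf", base.min_maf),
            max_site_missingness=tight.get(
                "max_site_missingness", base.max_site_missingness
            ),
        )
        _, _, tight_report = filter_variants(g, dp, cfg)
        assert set(tight_report.kept_locus_ids) <= set(loose_report.kept_locus_ids)


class TestLdPrune:
    def test_duplicated_column_loses_the_later_copy(self, rng):
        x = rng.binomial(2, 0.4, 40).astype(float)
        g = GenotypeMatrix(
            [f"s{i}" for i in range(40)], ["a", "b"], np.column_stack([x, x])
        )
        assert sk.ld_prune(g) == ["a"]

    def test_independent_loci_all_kept(self, rng):
        X = rng.binomial(2, 0.4, size=(200, 60)).astype(float)
        g = GenotypeMatrix(
            [f"s{i}" for i in range(200)], [f"L{j}" for j in range(60)], X
        )
        kept = sk.ld_prune(g)
        assert len(kept) >= 58  # r^2 between independent loci rarely crosses 0.2

    def test_one_survivor_per_perfectly_correlated_triplet(self, rng):
        blocks = []
        for _ in range(5):
            x = rng.binomial(2, 0.4, 100).astype(float)
            blocks += [x, x, x]
        X = np.column_stack(blocks)
        g = GenotypeMatrix(
            [f"s{i}" for i in range(100)], [f"L{j}" for j in range(15)], X
        )
        kept = sk.ld_prune(g)
        assert kept == [f"L{j}" for j in (0, 3, 6, 9, 12)]

    def test_idempotent(self, rng):
        X = rng.binomial(2, 0.4, size=(80, 120)).astype(float)
        X[:, 1] = X[:, 0]
        X[:, 60] = X[:, 59]
        g = GenotypeMatrix(
            [f"s{i}" for i in range(80)], [f"L{j}" for j in range(120)], X
        )
        kept = sk.ld_prune(g)
        pruned = g.subset_loci(kept)
        assert sk.ld_prune(pruned) == kept


class TestPca:
    def test_duplicated_sample_coincident_coordinates(self, rng):
        X = rng.binomial(2, 0.3, size=(12, 300)).astype(float)
        X[11] = X[0]
        g = GenotypeMatrix(
            [f"s{i}" for i in range(12)], [f"L{j}" for j in range(300)], X
        )
        res = sk.pca(g, n_components=4)
        assert np.allclose(res.coordinates[0], res.coordinates[11], atol=1e-8)

    def test_two_populations_separate_on_pc1(self):
        cfg = sk.SimulationConfig(
            rng_seed=20, n_populations=2, target_fst=0.2, n_loci=3000, missing_rate=0.0
        )
        freqs = sk.simulate_allele_frequencies(cfg)
        panel, pops = sk.simulate_unrelated_panel(freqs, 30, cfg)
        res = sk.pca(panel, n_components=2)
        pc1 = res.coordinates[:, 0]
        a = pc1[[i for i, s in enumerate(panel.sample_ids) if pops[s] == "pop1"]]
        b = pc1[[i for i, s in enumerate(panel.sample_ids) if pops[s] == "pop2"]]
        assert max(a.max(), b.max()) > min(a.min(), b.min())  # sanity
        assert a.max() < b.min() or b.max() < a.min()  # zero overlap

    def test_variance_fractions_sorted_and_nonnegative(self, rng):
        X = rng.binomial(2, 0.3, size=(15, 200)).astype(float)
        g = GenotypeMatrix(
            [f"s{i}" for i in range(15)], [f"L{j}" for j in range(200)], X
        )
        res = sk.pca(g, n_components=5)
        ve = res.variance_explained
        assert np.all(ve >= 0) and np.all(np.diff(ve) <= 1e-12) and ve.sum() <= 1 + 1e-9

    def test_component_count_reduced_with_warning(self, rng):
        X = rng.binomial(2, 0.4, size=(4, 50)).astype(float)
        g = GenotypeMatrix(["a", "b", "c", "d"], [f"L{j}" for j in range(50)], X)
        with pytest.warns(UserWarning):
            res = sk.pca(g, n_components=10)
        assert res.coordinates.shape[1] < 10


class TestFst:
    def test_wright_fst_frequency_level(self):
        assert wright_fst(0.2, 0.8) == pytest.approx(0.36)

    def test_null_estimate_near_zero_with_large_p(self):
        cfg = sk.SimulationConfig(
            rng_seed=21, n_populations=2, target_fst=0.0, n_loci=5000, missing_rate=0.0
        )
        freqs = sk.simulate_allele_frequencies(cfg)
        panel, pops = sk.simulate_unrelated_panel(freqs, 50, cfg)
        res = sk.fst_pairwise(panel, pops, n_perm=99, seed=1)
        assert abs(res.estimates.iloc[0, 1]) < 0.01
        assert res.p_values.iloc[0, 1] > 0.05

    def test_fixed_opposite_alleles_give_unity(self):
        X = np.vstack([np.zeros((5, 100)), np.full((5, 100), 2.0)])
        assert weir_cockerham_theta([X[:5], X[5:]]) == pytest.approx(1.0)

    def test_recovers_balding_nichols_f(self):
        cfg = sk.SimulationConfig(
            rng_seed=3, n_populations=2, target_fst=0.1, n_loci=5000, missing_rate=0.0
        )
        freqs = sk.simulate_allele_frequencies(cfg)
        panel, _ = sk.simulate_unrelated_panel(freqs, 50, cfg)
        theta = weir_cockerham_theta([panel.dosage[:50], panel.dosage[50:]])
        assert theta == pytest.approx(0.1, abs=0.02)


class TestAmova:
    def test_panmictic_null(self):
        cfg = sk.SimulationConfig(
            rng_seed=22, n_populations=2, target_fst=0.0, n_loci=1000, missing_rate=0.0
        )
        freqs = sk.simulate_allele_frequencies(cfg)
        panel, pops = sk.simulate_unrelated_panel(freqs, 40, cfg)
        res = sk.amova(panel, pops, n_perm=0)
        assert res.percentages["among_populations"] < 2.0
        assert res.percentages["within_individuals"] > 60.0
        assert sum(res.percentages.values()) == pytest.approx(100.0)

    def test_homozygous_clones_have_zero_within_individual_variance(self):
        row = np.array([0.0, 2.0] * 25)
        X = np.vstack([row] * 6 + [row[::-1]] * 6)  # two homozygous clone groups
        g = GenotypeMatrix(
            [f"s{i}" for i in range(12)], [f"L{j}" for j in range(50)], X
        )
        pops = {s: ("p1" if i < 6 else "p2") for i, s in enumerate(g.sample_ids)}
        res = sk.amova(g, pops, n_perm=0)
        assert res.components["within_individuals"] == pytest.approx(0.0)

    def test_recovers_divergence_parameter(self):
        cfg = sk.SimulationConfig(
            rng_seed=23, n_populations=2, target_fst=0.2, n_loci=3000, missing_rate=0.0
        )
        freqs = sk.simulate_allele_frequencies(cfg)
        panel, pops = sk.simulate_unrelated_panel(freqs, 40, cfg)
        res = sk.amova(panel, pops, n_perm=0)
        assert res.phi["phi_st"] == pytest.approx(0.2, abs=0.03)
        assert sum(res.percentages.values()) == pytest.approx(100.0)

    def test_significant_p_under_divergence(self):
        cfg = sk.SimulationConfig(
            rng_seed=24, n_populations=2, target_fst=0.2, n_loci=300, missing_rate=0.0
        )
        freqs = sk.simulate_allele_frequencies(cfg)
        panel, pops = sk.simulate_unrelated_panel(freqs, 15, cfg)
        res = sk.amova(panel, pops, n_perm=99, seed=5)
        assert res.p_value_among_populations == pytest.approx(0.01, abs=0.005)


class TestPhiPt:
    def test_identical_populations_near_zero(self):
        cfg = sk.SimulationConfig(
            rng_seed=25, n_populations=2, target_fst=0.0, n_loci=2000, missing_rate=0.0
        )
        freqs = sk.simulate_allele_frequencies(cfg)
        panel, pops = sk.simulate_unrelated_panel(freqs, 30, cfg)
        res = sk.phi_pt(panel, pops, n_perm=0)
        assert abs(res.estimates.iloc[0, 1]) < 0.02

    def test_fixed_opposite_populations_give_unity(self):
        X = np.vstack([np.zeros((5, 80)), np.full((5, 80), 2.0)])
        g = GenotypeMatrix(
            [f"s{i}" for i in range(10)], [f"L{j}" for j in range(80)], X
        )
        pops = {s: ("p1" if i < 5 else "p2") for i, s in enumerate(g.sample_ids)}
        res = sk.phi_pt(g, pops, n_perm=0)
        assert res.estimates.iloc[0, 1] == pytest.approx(1.0)

    def test_runs_above_wc_fst_on_diverged_panels(self):
        """Genotype-distance differentiation exceeds the allele-frequency one."""
        for seed in (26, 27):
            cfg = sk.SimulationConfig(
                rng_seed=seed, n_populations=2, target_fst=0.15, n_loci=2000,
                missing_rate=0.0,
            )
            freqs = sk.simulate_allele_frequencies(cfg)
            panel, pops = sk.simulate_unrelated_panel(freqs, 30, cfg)
            fst = weir_cockerham_theta([panel.dosage[:30], panel.dosage[30:]])
            ppt = sk.phi_pt(panel, pops, n_perm=0).estimates.iloc[0, 1]
            assert ppt >= fst
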