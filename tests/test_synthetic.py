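import numpy as np
import pytest
from scipy import stats

from ecoassembly import (
    simulate_dispersal_limited,
    simulate_metacommunity,
    simulate_neutral_local,
    simulate_niche_local,
    simulate_tree_with_traits,
)


class TestTreeWithTraits:
    def test_deterministic_under_seed(self):
        t1, tr1 = simulate_tree_with_traits(50, seed=7)
        t2, tr2 = simulate_tree_with_traits(50, seed=7)
        assert str(t1) == str(t2)
        assert tr1.equals(tr2)

    def test_requires_three_otus(self):
        with pytest.raises(ValueError):
            simulate_tree_with_traits(2, seed=0)

    def test_trait_dispersion_grows_with_tree_depth(self):
        # Brownian motion: E[trait^2] at a tip equals trait_rate x root-to-tip
        # time.  Yule trees are ultrametric, so regressing the mean squared
        # trait on tree depth across replicates recovers slope ~ trait_rate=1.
        depths, msq = [], []
        for rep in range(200):
            tree, traits = simulate_tree_with_traits(20, seed=1000 + rep)
            tip = next(tree.tips())
            depths.append(tip.accumulate_to_ancestor(tree))
            msq.append(float((traits**2).mean()))
        reg = stats.linregress(depths, msq)
        assert reg.pvalue < 1e-4
        assert 0.5 < reg.slope < 1.5

    def test_sister_tips_more_similar_than_random_pairs(self):
        sister_diffs, random_diffs = [], []
        rng = np.random.default_rng(0)
        for rep in range(200):
            tree, traits = simulate_tree_with_traits(30, seed=2000 + rep)
            for tip in tree.tips():
                sibs = [c for c in tip.parent.children if c.is_tip() and c is not tip]
                if sibs:
                    sister_diffs.append(abs(traits[tip.name] - traits[sibs[0].name]))
                    break
            a, b = rng.choice(traits.index, size=2, replace=False)
            random_diffs.append(abs(traits[a] - traits[b]))
        assert np.mean(sister_diffs) < np.mean(random_diffs)


class TestMetacommunity:
    def test_small_sd_limit_is_near_uniform(self):
        pool = simulate_metacommunity(100, lognormal_sd=1e-4, seed=1)
        p = pool.relative_abundance
        assert p.max() / p.min() < 1.01

    def test_fixed_seed_identical(self):
        a = simulate_metacommunity(100, 2.0, seed=5)
        b = simulate_metacommunity(100, 2.0, seed=5)
        assert np.array_equal(a.relative_abundance, b.relative_abundance)

    def test_rank_abundance_concave_on_log_scale(self):
        # log-normal SAD: log-abundance vs rank has steep tails, shallow middle
        pool = simulate_metacommunity(1000, lognormal_sd=2.0, seed=9)
        logp = np.sort(np.log(pool.relative_abundance))[::-1]
        n = len(logp)
        head = logp[: n // 10]
        mid = logp[int(0.45 * n) : int(0.55 * n)]
        assert (head[0] - head[-1]) > (mid[0] - mid[-1])


class TestNeutralLocal:
    def test_row_sums_and_determinism(self, neutral_pool):
        t1, _ = simulate_neutral_local(neutral_pool, 1000, 0.3, 6, seed=4)
        t2, _ = simulate_neutral_local(neutral_pool, 1000, 0.3, 6, seed=4)
        assert (t1.sample_sums() == 1000).all()
        assert t1 == t2

    def test_m_one_limit_matches_metacommunity(self, neutral_pool):
        table, _ = simulate_neutral_local(neutral_pool, 1000, 1.0, 48, seed=5)
        mean_rel = (
            table.counts.reindex(columns=neutral_pool.otu_ids, fill_value=0)
            .to_numpy()
            .mean(axis=0)
            / 1000
        )
        p = neutral_pool.relative_abundance
        big = p > 0.005
        assert np.allclose(mean_rel[big], p[big], rtol=0.15)

    def test_low_m_increases_across_sample_variance(self, neutral_pool):
        drift, _ = simulate_neutral_local(neutral_pool, 1000, 0.01, 24, seed=6)
        mixed, _ = simulate_neutral_local(neutral_pool, 1000, 1.0, 24, seed=6)
        p = neutral_pool.relative_abundance
        focal = np.argsort(p)[-10:]  # abundant OTUs, reliably present
        ids = [neutral_pool.otu_ids[i] for i in focal]
        v_drift = drift.counts.reindex(columns=ids, fill_value=0).var().mean()
        v_mixed = mixed.counts.reindex(columns=ids, fill_value=0).var().mean()
        assert v_drift > v_mixed

    def test_occupancy_abundance_monotone(self, neutral_table, neutral_pool):
        table, _ = neutral_table
        counts = table.counts.reindex(columns=neutral_pool.otu_ids, fill_value=0)
        occ = (counts > 0).mean(axis=0)
        rho = stats.spearmanr(neutral_pool.relative_abundance, occ).statistic
        assert rho > 0.9

    def test_invalid_m_rejected(self, neutral_pool):
        with pytest.raises(ValueError):
            simulate_neutral_local(neutral_pool, 1000, 0.0, 4, seed=0)


class TestNicheLocal:
    def test_wide_niche_limit_is_neutral(self, scenario_pool):
        meta, tree, traits = scenario_pool
        table, _ = simulate_niche_local(
            meta, traits, [0.0] * 48, sigma_sel=1e6, n_individuals=2000,
            seed=7, drift_theta=None,
        )
        mean_rel = (
            table.counts.reindex(columns=meta.otu_ids, fill_value=0).to_numpy().mean(0)
            / 2000
        )
        big = meta.relative_abundance > 0.005
        assert np.allclose(mean_rel[big], meta.relative_abundance[big], rtol=0.2)

    def test_regime_label_follows_environment(self, scenario_pool):
        meta, tree, traits = scenario_pool
        _, homo = simulate_niche_local(meta, traits, [1.0] * 4, 0.5, seed=1)
        _, vari = simulate_niche_local(meta, traits, [-1.0] * 2 + [1.0] * 2, 0.5, seed=1)
        assert homo.regime == "homogeneous_selection"
        assert vari.regime == "variable_selection"

    def test_selection_enriches_matching_traits(self, scenario_pool):
        meta, tree, traits = scenario_pool
        sd = float(traits.std())
        table, _ = simulate_niche_local(
            meta, traits, [3 * sd] * 12, 0.5 * sd, seed=8, drift_theta=None
        )
        rel = table.counts.reindex(columns=meta.otu_ids, fill_value=0).to_numpy().mean(0)
        realised_mean_trait = np.average(traits[list(meta.otu_ids)], weights=rel + 1e-12)
        pool_mean_trait = np.average(traits[list(meta.otu_ids)],
                                     weights=meta.relative_abundance)
        assert realised_mean_trait > pool_mean_trait + sd


class TestDispersalLimited:
    def test_regional_blocks_and_reproducibility(self, scenario_pool):
        meta, _, _ = scenario_pool
        t1, tr1 = simulate_dispersal_limited(meta, n_samples=24, seed=3)
        t2, _ = simulate_dispersal_limited(meta, n_samples=24, seed=3)
        assert t1 == t2
        regions = np.asarray(tr1.extras["region_of_sample"])
        assert len(np.unique(regions)) == 4
        assert (t1.sample_sums() == 1000).all()

    def test_between_region_turnover_exceeds_within(self, scenario_pool):
        meta, _, _ = scenario_pool
        table, truth = simulate_dispersal_limited(meta, n_samples=24, seed=13)
        from scipy.spatial.distance import pdist, squareform

        bc = squareform(pdist(table.matrix, metric="braycurtis"))
        reg = np.asarray(truth.extras["region_of_sample"])
        same = reg[:, None] == reg[None, :]
        iu = np.triu_indices(24, k=1)
        assert bc[iu][~same[iu]].mean() > bc[iu][same[iu]].mean()
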