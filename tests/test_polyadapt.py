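"""tiHS polygenic-adaptation machinery: polarization, null, p-values, BH."""

import numpy as np
import pandas as pd
import pytest

from polyhap.datasets import published_tihs_pvalues
from polyhap.polyadapt import (MatchingError, NullConfig, TraitSNPSet,
                               bh_adjust, build_null_pool, build_trait_set,
                               empirical_two_sided_p, polarize_effects,
                               sample_matched_null, tihs_value)
from tests.conftest import make_panel


@pytest.fixture
def panel():
    rng = np.random.default_rng(0)
    return make_panel(rng.integers(0, 2, size=(8, 6)))


def gwas_frame(rows):
    df = pd.DataFrame(rows, columns=["snp_id", "effect_allele", "beta", "p"])
    df["trait"] = "T"
    return df


class TestPolarizeEffects:
    def test_flags_and_sign_inversion(self, panel):
        sid = panel.site_ids
        g = gwas_frame([(sid[0], "derived", 0.05, 0.01),
                        (sid[1], "ancestral", 0.05, 0.01)])
        out = polarize_effects(g, panel)
        assert out["beta_derived"].tolist() == [0.05, -0.05]

    def test_base_matching(self, panel):
        sid = panel.site_ids
        g = gwas_frame([(sid[0], "G", 0.3, 0.01),   # derived base
                        (sid[1], "A", 0.3, 0.01),   # ancestral base
                        (sid[2], "T", 0.3, 0.01)])  # matches neither
        out = polarize_effects(g, panel)
        assert out["beta_derived"].tolist() == [0.3, -0.3]
        assert sid[2] not in set(out["snp_id"])

    def test_absent_snp_dropped(self, panel):
        g = gwas_frame([("nowhere", "derived", 0.1, 0.01)])
        assert len(polarize_effects(g, panel)) == 0


class TestTraitSet:
    def scan(self, ids, sihs):
        return pd.DataFrame({"snp_id": ids, "sihs": sihs})

    def gwas(self, ids, p):
        return pd.DataFrame({"snp_id": ids, "p": p,
                             "beta_derived": 0.1, "trait": "T"})

    def test_threshold_is_strict(self):
        ids = [f"s{i}" for i in range(4)]
        g = self.gwas(ids, [0.05, 0.049, 0.01, 0.9])
        ts = build_trait_set(g, self.scan(ids, [1.0] * 4))
        assert set(ts.members["snp_id"]) == {"s1", "s2"}

    def test_exclusions_never_members(self):
        ids = [f"s{i}" for i in range(4)]
        g = self.gwas(ids, [0.01] * 4)
        ts = build_trait_set(g, self.scan(ids, [1.0] * 4),
                             exclusions=("s0",))
        assert "s0" not in set(ts.members["snp_id"])

    def test_retained_at_most_reported(self):
        ids = [f"s{i}" for i in range(6)]
        g = self.gwas(ids, [0.01] * 6)
        scan = self.scan(ids[:3], [1.0, np.nan, 2.0])
        ts = build_trait_set(g, scan)
        assert ts.n_retained <= ts.n_reported
        assert ts.n_retained == 2  # NaN siHS and absent-from-scan drop out


class TestTihsValue:
    def test_sign_and_weighted_modes(self):
        assert tihs_value(2.0, 0.05) == 2.0
        assert tihs_value(2.0, -0.05) == -2.0
        assert tihs_value(2.0, -0.05, mode="weighted") == pytest.approx(-0.10)

    def test_zero_beta_rejected(self):
        with pytest.raises(ValueError):
            tihs_value(1.0, 0.0)


def toy_setup(n_pool=30, n_trait=6, seed=5, one_bin=True):
    rng = np.random.default_rng(seed)
    ids = [f"s{i}" for i in range(n_pool + n_trait)]
    sihs = rng.normal(size=n_pool + n_trait)
    beta = rng.choice([-1.0, 1.0], size=n_pool + n_trait) * 0.1
    scan = pd.DataFrame({"snp_id": ids, "sihs": sihs})
    gwas = pd.DataFrame({"snp_id": ids, "beta_derived": beta,
                         "p": [0.01] * n_trait + [0.5] * n_pool, "trait": "T"})
    if one_bin:
        annot = pd.DataFrame({"snp_id": ids, "daf": 0.5, "recomb_rate": 1.0,
                              "gerp": 0.0})
        bins = dict(daf_bins=1, recomb_bins=1, gerp_bins=1)
    else:
        annot = pd.DataFrame({"snp_id": ids,
                              "daf": rng.uniform(0.05, 0.95,
                                                 size=n_pool + n_trait),
                              "recomb_rate": rng.uniform(0.5, 2.0,
                                                         size=n_pool + n_trait),
                              "gerp": rng.normal(size=n_pool + n_trait)})
        bins = dict(daf_bins=2, recomb_bins=2, gerp_bins=1)
    tset = build_trait_set(gwas, scan)
    pool = build_null_pool(gwas, scan, tset)
    return tset, pool, annot, scan, bins


class TestMatchedNull:
    def test_degenerate_pool_gives_p_one(self):
        tset, pool, annot, scan, bins = toy_setup()
        # restrict the pool to exactly the trait SNPs: every replicate is a
        # permutation of the trait set, so each mean equals the observed
        # mean (dyadic tihs values keep the float sums order-independent)
        rng = np.random.default_rng(8)
        dyadic = rng.integers(-16, 17, size=len(tset.members)) / 8.0
        tset.members["tihs"] = dyadic
        pool = tset.members.copy()
        cfg = NullConfig(n_replicates=50, seed=1, **bins)
        means = sample_matched_null(tset, annot, scan, cfg, pool=pool)
        assert np.allclose(means, tset.observed_mean())
        p, r, _ = empirical_two_sided_p(tset.observed_mean(), means)
        assert r == 50 and p == 1.0

    def test_same_seed_reproduces_means(self):
        tset, pool, annot, scan, bins = toy_setup(one_bin=False)
        cfg = NullConfig(n_replicates=200, seed=7, **bins)
        m1 = sample_matched_null(tset, annot, scan, cfg, pool=pool)
        m2 = sample_matched_null(tset, annot, scan, cfg, pool=pool)
        np.testing.assert_array_equal(m1, m2)

    def test_null_centers_on_pool_mean(self):
        tset, pool, annot, scan, bins = toy_setup(n_pool=200, n_trait=10)
        cfg = NullConfig(n_replicates=4000, seed=3, **bins)
        means = sample_matched_null(tset, annot, scan, cfg, pool=pool)
        se = pool["tihs"].std(ddof=1) / np.sqrt(tset.n_retained * 4000) * 10
        assert abs(means.mean() - pool["tihs"].mean()) < max(3 * se, 0.02)

    def test_underpopulated_bin_raises(self):
        tset, pool, annot, scan, bins = toy_setup(n_pool=2, n_trait=6)
        cfg = NullConfig(n_replicates=10, seed=1, **bins)
        with pytest.raises(MatchingError, match="deficit"):
            sample_matched_null(tset, annot, scan, cfg, pool=pool)

    def test_matches_brute_force_oracle_exactly(self):
        # independent re-implementation of the documented draw protocol
        tset, pool, annot, scan, bins = toy_setup(n_pool=40, n_trait=8,
                                                  one_bin=False)
        cfg = NullConfig(n_replicates=300, seed=11, **bins)
        means = sample_matched_null(tset, annot, scan, cfg, pool=pool)

        from polyhap.polyadapt import _joint_bins
        edge_source = annot[annot["snp_id"].isin(pool["snp_id"])]
        pool_bins = _joint_bins(annot, pool["snp_id"], cfg, edge_source)
        trait_bins = _joint_bins(annot, tset.members["snp_id"], cfg,
                                 edge_source)
        pool_tihs = pool["tihs"].to_numpy()
        rng = np.random.default_rng(cfg.seed)
        N = cfg.n_replicates
        totals = np.zeros(N)
        for b in sorted(set(trait_bins)):
            slots = [i for i, tb in enumerate(trait_bins) if tb == b]
            members = [i for i, pb in enumerate(pool_bins) if pb == b]
            m = len(members)
            raw = [rng.random(N) for _ in slots]
            for rep in range(N):
                taken = []
                for i in range(len(slots)):
                    d = int(raw[i][rep] * (m - i))
                    for prev in sorted(taken):
                        if d >= prev:
                            d += 1
                    taken.append(d)
                    totals[rep] += pool_tihs[members[d]]
        np.testing.assert_allclose(means, totals / tset.n_retained,
                                   rtol=0, atol=1e-12)


class TestEmpiricalP:
    def test_observed_beyond_all_replicates(self):
        means = np.linspace(-0.5, 0.5, 100)
        p, r, direction = empirical_two_sided_p(2.0, means)
        assert r == 0 and p == pytest.approx(1 / 101)
        assert direction == "Increasing"

    def test_all_replicates_at_least_observed(self):
        p, r, _ = empirical_two_sided_p(0.1, np.full(40, 0.5))
        assert r == 40 and p == 1.0

    def test_direction_below_average_is_decreasing(self):
        _, _, direction = empirical_two_sided_p(-0.2, np.full(10, 0.1))
        assert direction == "Decreasing"

    def test_order_invariance_and_min_p(self):
        rng = np.random.default_rng(2)
        means = rng.normal(size=99)
        p1 = empirical_two_sided_p(10.0, means)[0]
        p2 = empirical_two_sided_p(10.0, means[::-1])[0]
        assert p1 == p2 == pytest.approx(1 / 100)


class TestBHAdjust:
    def test_published_table_worked_example(self):
        raw = published_tihs_pvalues()
        adj = bh_adjust(raw)
        assert min(adj.values()) == pytest.approx(2.4e-6, rel=0.05)

    def test_single_p_unchanged(self):
        assert bh_adjust({"a": 0.03})["a"] == pytest.approx(0.03)

    def test_equal_ps_unchanged(self):
        adj = bh_adjust({k: 0.2 for k in "abcd"})
        assert all(v == pytest.approx(0.2) for v in adj.values())

    def test_monotone_and_at_least_raw(self):
        rng = np.random.default_rng(3)
        raw = {f"t{i}": p for i, p in enumerate(rng.uniform(size=20))}
        adj = bh_adjust(raw)
        pairs = sorted(raw.items(), key=lambda kv: kv[1])
        adj_sorted = [adj[k] for k, _ in pairs]
        assert all(a <= b + 1e-15 for a, b in zip(adj_sorted, adj_sorted[1:]))
        assert all(adj[k] >= raw[k] - 1e-15 for k in raw)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust({"a": 0.0})


class TestNegationInvariance:
    def test_negating_betas_flips_direction_not_p(self):
        tset, pool, annot, scan, bins = toy_setup(n_pool=50, n_trait=8,
                                                  one_bin=False, seed=9)
        cfg = NullConfig(n_replicates=500, seed=2, **bins)
        means = sample_matched_null(tset, annot, scan, cfg, pool=pool)
        p, r, direction = empirical_two_sided_p(tset.observed_mean(), means)

        neg_members = tset.members.copy()
        neg_members["beta_derived"] *= -1
        neg_members["tihs"] *= -1
        neg_tset = TraitSNPSet("T", neg_members, tset.n_reported,
                               tset.n_retained)
        neg_pool = pool.copy()
        neg_pool["beta_derived"] *= -1
        neg_pool["tihs"] *= -1
        neg_means = sample_matched_null(neg_tset, annot, scan, cfg,
                                        pool=neg_pool)
        p2, r2, direction2 = empirical_two_sided_p(neg_tset.observed_mean(),
                                                   neg_means)
        assert neg_tset.observed_mean() == -tset.observed_mean()
        assert p2 == p and r2 == r
        assert {direction, direction2} == {"Increasing", "Decreasing"}
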