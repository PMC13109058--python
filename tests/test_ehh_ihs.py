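"""EHH/iHS against brute-force oracles and algebraic identities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polyhap import ehh_ihs
from polyhap.ehh_ihs import (EHHCurve, EHHError, ScanConfig, compute_ehh,
                             compute_uihs, ihs_normal_p, integrate_ihh,
                             standardize_ihs)
from tests.conftest import make_map, make_panel


def brute_force_ehh(alleles, core, allele, j):
    """Fraction of carrier pairs identical from the core through site j."""
    carriers = [h for h in range(alleles.shape[0])
                if alleles[h, core] == allele]
    lo, hi = sorted((core, j))
    pairs = identical = 0
    for a in range(len(carriers)):
        for b in range(a + 1, len(carriers)):
            pairs += 1
            seg_a = alleles[carriers[a], lo:hi + 1]
            seg_b = alleles[carriers[b], lo:hi + 1]
            identical += int(np.array_equal(seg_a, seg_b))
    return identical / pairs


panels = st.integers(2, 4).flatmap(
    lambda nd: st.integers(2, 6).flatmap(
        lambda ns: st.lists(
            st.lists(st.integers(0, 1), min_size=ns, max_size=ns),
            min_size=2 * nd, max_size=2 * nd)))


class TestEHHOracle:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(panels, st.data())
    def test_matches_pair_enumeration_everywhere(self, rows, data):
        alleles = np.array(rows, dtype=np.uint8)
        core = data.draw(st.integers(0, alleles.shape[1] - 1))
        for allele, name in ((1, "derived"), (0, "ancestral")):
            n_car = int((alleles[:, core] == allele).sum())
            if n_car < 2:
                with pytest.raises(EHHError):
                    compute_ehh(make_panel(alleles), core, name)
                continue
            curve = compute_ehh(make_panel(alleles), core, name,
                                truncation_ehh=0.0, max_extension_bp=10**9)
            for site, ehh in zip(curve.sites, curve.ehh):
                oracle = brute_force_ehh(alleles, core, allele, site)
                assert ehh == pytest.approx(oracle, abs=1e-12)

    def test_offset_zero_is_one_and_monotone(self):
        rng = np.random.default_rng(0)
        alleles = rng.integers(0, 2, size=(12, 10)).astype(np.uint8)
        alleles[:, 4] = [0, 1] * 6
        curve = compute_ehh(make_panel(alleles), 4, "derived",
                            truncation_ehh=0.0, max_extension_bp=10**9)
        at_core = int(np.nonzero(curve.sites == 4)[0][0])
        assert curve.ehh[at_core] == 1.0
        assert np.all(np.diff(curve.ehh[at_core:]) <= 1e-12)
        assert np.all(np.diff(curve.ehh[:at_core + 1]) >= -1e-12)

    def test_two_two_split_hand_value(self):
        # 4 carriers split 2/2 at the first flank: (1+1)/C(4,2) = 1/3
        alleles = np.array([[1, 0], [1, 0], [1, 1], [1, 1]], dtype=np.uint8)
        curve = compute_ehh(make_panel(alleles), 0, "derived",
                            truncation_ehh=0.0)
        assert curve.ehh[-1] == pytest.approx(1 / 3)

    def test_relabeling_haplotypes_changes_nothing(self):
        rng = np.random.default_rng(1)
        alleles = rng.integers(0, 2, size=(16, 8)).astype(np.uint8)
        alleles[:, 3] = [0, 1] * 8
        gmap = make_map()
        cfg = ScanConfig()
        r1 = compute_uihs(make_panel(alleles), 3, gmap, cfg)
        perm = rng.permutation(16)
        r2 = compute_uihs(make_panel(alleles[perm]), 3, gmap, cfg)
        assert r1["ihh_d"] == pytest.approx(r2["ihh_d"])
        assert r1["ihh_a"] == pytest.approx(r2["ihh_a"])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(panels)
    def test_label_swap_negates_uihs(self, rows):
        alleles = np.array(rows, dtype=np.uint8)
        core = alleles.shape[1] // 2
        counts = int(alleles[:, core].sum())
        if min(counts, alleles.shape[0] - counts) < 2:
            return
        gmap = make_map()
        r = compute_uihs(make_panel(alleles), core, gmap)
        flipped = alleles.copy()
        flipped[:, core] = 1 - flipped[:, core]
        rf = compute_uihs(make_panel(flipped), core, gmap)
        if np.isfinite(r["uihs"]):
            assert rf["uihs"] == pytest.approx(-r["uihs"])


class TestIntegrateIHH:
    def curve(self, positions, ehh, core_index=0):
        positions = np.asarray(positions, dtype=np.int64)
        return EHHCurve(core_site=core_index, allele_class="derived",
                        sites=np.arange(len(positions)),
                        positions_bp=positions,
                        offsets_bp=positions - positions[core_index],
                        ehh=np.asarray(ehh, dtype=float), n_carriers=4)

    def test_flat_segment(self, flat_map):
        # one-sided: (0 cM, 1.0) to (0.1 cM, 1.0) -> area 0.1
        c = self.curve([1_000, 101_000], [1.0, 1.0])
        assert integrate_ihh(c, flat_map) == pytest.approx(0.1)

    def test_linear_decay(self, flat_map):
        c = self.curve([1_000, 101_000], [1.0, 0.0])
        assert integrate_ihh(c, flat_map) == pytest.approx(0.05)

    def test_two_sided_additivity(self, flat_map):
        sym = self.curve([1_000, 101_000, 201_000], [1.0, 1.0, 1.0],
                         core_index=1)
        one = self.curve([101_000, 201_000], [1.0, 1.0])
        assert integrate_ihh(sym, flat_map) == pytest.approx(
            2 * integrate_ihh(one, flat_map))

    def test_physical_scale_option(self):
        c = self.curve([1_000, 101_000], [1.0, 1.0])
        gmap = make_map()
        assert integrate_ihh(c, gmap, scale="bp") == pytest.approx(0.1)


class TestUIHS:
    def test_log_identities(self):
        assert np.log(1.0 / 1.0) == 0.0  # uihs = ln(ihh_d/ihh_a)
        rec = {"ihh_d": np.e, "ihh_a": 1.0}
        assert np.log(rec["ihh_d"] / rec["ihh_a"]) == pytest.approx(1.0)

    def test_sweep_beats_neutral_contrast(self, small_sweep_fixture, flat_map):
        cfg, sweep, panel, _ = small_sweep_fixture
        core = sweep.selected_site_index
        # neutral contrast: a site whose derived class excludes the sweep
        # descendants (otherwise every linked site is a perfect proxy)
        sweep_class = panel.alleles[:, core] == 1
        candidates = [j for j in range(panel.n_sites)
                      if j != core and 2 <= panel.alleles[:, j].sum()
                      <= panel.n_haplotypes - 2]
        contrast = min(candidates,
                       key=lambda j: (panel.alleles[sweep_class, j] == 1).sum())
        r_core = compute_uihs(panel, core, flat_map)
        r_con = compute_uihs(panel, contrast, flat_map)
        assert r_core["uihs"] > r_con["uihs"]

    def test_monomorphic_rejected(self):
        alleles = np.zeros((6, 4), dtype=np.uint8)
        alleles[:, 1] = 1
        alleles[0, 2] = 1
        panel = make_panel(alleles)
        with pytest.raises(EHHError, match="monomorphic"):
            compute_uihs(panel, 0, make_map())


class TestStandardization:
    def records(self, uihs, daf=None):
        n = len(uihs)
        return pd.DataFrame({
            "snp_id": [f"s{i}" for i in range(n)],
            "pos": np.arange(n) * 1000 + 1,
            "daf": daf if daf is not None else np.full(n, 0.5),
            "ihh_d": 1.0, "ihh_a": 1.0, "uihs": uihs,
            "flags": [""] * n})

    def test_hand_standardization(self):
        out, bins = standardize_ihs(self.records([-1.0, 0.0, 1.0]))
        assert out.loc[2, "sihs"] == pytest.approx(1.0)  # mean 0, sample SD 1

    def test_zero_variance_bin_flagged(self):
        out, _ = standardize_ihs(self.records([0.5, 0.5, 0.5]))
        assert out["sihs"].isna().all()

    def test_per_bin_moments_after_standardization(self):
        rng = np.random.default_rng(7)
        recs = self.records(rng.normal(size=400), daf=rng.uniform(0.02, 0.98,
                                                                  size=400))
        out, bins = standardize_ihs(recs, n_bins=25)
        for b, grp in out.dropna(subset=["sihs"]).groupby("bin"):
            if len(grp) >= 2:
                assert abs(grp["sihs"].mean()) < 1e-12
                assert abs(grp["sihs"].std(ddof=1) - 1) < 1e-12


class TestNormalP:
    def test_published_score_maps_to_published_p(self):
        assert ihs_normal_p(4.40) == pytest.approx(1.1e-5, rel=0.05)

    def test_zero_and_symmetry(self):
        assert ihs_normal_p(0.0) == pytest.approx(1.0)
        assert ihs_normal_p(-4.40) == ihs_normal_p(4.40)
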