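"""Steady-state solutions, zone classification and sweeps."""

import numpy as np
import pytest

import picompete as pc
from picompete.exceptions import DegenerateSystemError
from conftest import ode_zone_oracle, random_community


class TestSolveCoexistence:
    def test_specialist_closed_form(self, specialist_cfg):
        # decoupled: [j]* = mK/(V-m) = 1, n = S/m = 30 for each genus
        eq = pc.solve_coexistence(specialist_cfg)
        assert eq.valid
        assert eq.no3_star == pytest.approx(1.0, abs=1e-9)
        assert eq.nh4_star == pytest.approx(1.0, abs=1e-9)
        assert eq.n_pro == pytest.approx(30.0, rel=1e-9)
        assert eq.n_syn == pytest.approx(30.0, rel=1e-9)

    def test_identical_genera_degenerate(self, ref_cfg):
        cfg = ref_cfg.replace(syn=ref_cfg.pro.replace(q_n=ref_cfg.syn.q_n))
        with pytest.raises(DegenerateSystemError):
            pc.solve_coexistence(cfg)

    def test_reference_coexists_at_one_to_three(self, ref_cfg):
        eq = pc.solve_coexistence(ref_cfg)
        assert eq.valid and eq.n_pro > 0 and eq.n_syn > 0

    def test_zero_residual_at_equilibrium(self, ref_cfg):
        # rhs vanishes at the reconstructed coexistence state
        eq = pc.solve_coexistence(ref_cfg)
        deriv = pc.rhs(eq.to_state(ref_cfg), ref_cfg)
        scale = np.array([eq.n_pro / ref_cfg.pro.q_n,
                          eq.n_syn / ref_cfg.syn.q_n, 1.0, 1.0])
        assert np.max(np.abs(deriv) / scale) <= 1e-8

    def test_throughput_balance(self, ref_cfg):
        # s_no3 + s_nh4 = m_P n_P + m_S n_S at equilibrium
        eq = pc.solve_coexistence(ref_cfg)
        lhs = ref_cfg.s_no3 + ref_cfg.s_nh4
        rhs_ = (ref_cfg.pro.mortality * eq.n_pro
                + ref_cfg.syn.mortality * eq.n_syn)
        assert rhs_ == pytest.approx(lhs, rel=1e-8)


class TestSolveSingle:
    def test_specialist_resident_leaves_unconsumed_nutrient_unbounded(
            self, specialist_cfg):
        eq = pc.solve_single(specialist_cfg, "pro")
        # Pro cannot consume NO3-, which has supply but no sink
        assert np.isinf(eq.no3_star)
        assert eq.nh4_star == pytest.approx(1.0)
        assert eq.n_pro == pytest.approx(30.0)
        # Syn then invades on saturating NO3-
        assert eq.invasion_rate > 0 and not eq.valid

    def test_dominant_competitor_excludes(self):
        # Pro strictly better on both nutrients: lower K, same Vmax and m
        pro = pc.GenusParams(0.6, 0.8, 10.0, 10.0, 0.1, 5e-7)
        syn = pc.GenusParams(0.6, 0.8, 40.0, 40.0, 0.1, 1.5e-6)
        cfg = pc.CommunityConfig(pro=pro, syn=syn, s_no3=3.0, s_nh4=3.0)
        eq = pc.classify_zone(cfg)
        assert eq.zone == "pro_only"
        assert eq.invasion_rate < 0
        # long ODE run agrees
        traj = pc.integrate(cfg, pc.ModelState(1e7, 1e7, 5.0, 5.0),
                            t_end=3000.0, dt_out=100.0)
        assert traj.values[-1, 1] < 1e-9 * 1e7 < traj.values[-1, 0]

    def test_no_supply_is_infeasible(self, specialist_cfg):
        cfg = specialist_cfg.replace(s_no3=0.0, s_nh4=0.0)
        eq = pc.solve_single(cfg, "syn")
        assert not eq.valid and eq.zone == "none"


class TestClassifyZone:
    def test_reference_is_domain_iv(self, ref_cfg):
        # coexistence with Pro mainly on NH4+ and Syn mainly on NO3-
        eq = pc.classify_zone(ref_cfg)
        assert eq.zone == "coexist_iv"
        assert eq.valid and eq.stable

    def test_lower_kno3pro_gives_pro_only(self, ref_cfg):
        cfg = ref_cfg.replace(pro=ref_cfg.pro.replace(k_no3=ref_cfg.pro.k_no3 / 100))
        assert pc.classify_zone(cfg).zone == "pro_only"

    def test_higher_knh4pro_gives_syn_only(self, ref_cfg):
        cfg = ref_cfg.replace(pro=ref_cfg.pro.replace(k_nh4=ref_cfg.pro.k_nh4 * 100))
        assert pc.classify_zone(cfg).zone == "syn_only"

    def test_lower_mortality_wins_between_twins(self, ref_cfg):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            syn = ref_cfg.pro.replace(mortality=ref_cfg.pro.mortality * 1.5,
                                      q_n=ref_cfg.syn.q_n)
        cfg = ref_cfg.replace(syn=syn)
        assert pc.classify_zone(cfg).zone == "pro_only"
        # and the mirror case
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pro = ref_cfg.syn.replace(mortality=ref_cfg.syn.mortality * 1.5,
                                      q_n=ref_cfg.pro.q_n)
        cfg2 = ref_cfg.replace(pro=pro)
        assert pc.classify_zone(cfg2).zone == "syn_only"

    def test_matches_ode_oracle_on_random_communities(self):
        """Zone labels agree with long forward integrations from random
        positive initial states (a reduced version of the full oracle
        sweep run in the acceptance suite)."""
        rng = np.random.default_rng(3)
        checked = 0
        while checked < 6:
            cfg = random_community(rng)
            try:
                eq = pc.classify_zone(cfg)
            except DegenerateSystemError:
                continue
            init = pc.ModelState(*10 ** rng.uniform([6, 6, 0, 0], [8, 8, 1.5, 1.5]))
            oracle = ode_zone_oracle(cfg, init)
            if oracle == "ambiguous":
                continue
            pred = "coexist" if eq.zone.startswith("coexist") else eq.zone
            assert pred == oracle, f"{eq.zone} vs oracle {oracle}"
            checked += 1


@pytest.fixture(scope="module")
def zone_map(ref_cfg):
    grid = np.logspace(-2, 2, 12)
    return pc.sweep_k_ratios(ref_cfg, grid, grid)


@pytest.fixture(scope="module")
def resource_sweep(ref_cfg):
    return pc.sweep_resource_ratio(ref_cfg, np.logspace(-2, 1.5, 40))


class TestSweepKRatios:
    def test_reference_node_coexists(self, ref_cfg):
        r3 = ref_cfg.pro.k_no3 / ref_cfg.syn.k_no3
        r4 = ref_cfg.pro.k_nh4 / ref_cfg.syn.k_nh4
        zmap = pc.sweep_k_ratios(ref_cfg, np.array([r3]), np.array([r4]))
        assert zmap.zones[0, 0].startswith("coexist")

    def test_all_four_domains_present(self, zone_map):
        zones = set(zone_map.zones.ravel())
        assert {"coexist_iv", "coexist_i", "pro_only", "syn_only"} <= zones

    def test_biomass_ratio_decreases_with_knh4pro(self, zone_map):
        # along increasing KNH4Pro/KNH4Syn at fixed KNO3 ratio, Pro loses
        # ground on its preferred nutrient
        for i in range(len(zone_map.ratio_no3_axis)):
            row = zone_map.biomass_ratio[i, :]
            vals = row[np.isfinite(row)]
            if len(vals) >= 2:
                assert np.all(np.diff(vals) < 0)

    def test_long_format_export(self, zone_map, tmp_path):
        df = zone_map.to_dataframe()
        assert set(df.columns) == {"ratio_no3", "ratio_nh4", "zone",
                                   "biomass_ratio"}
        assert len(df) == 12 * 12


class TestSweepResourceRatio:
    def test_monotone_nonincreasing_in_supply_ratio(self, resource_sweep):
        vals = resource_sweep.biomass_ratio[
            np.isfinite(resource_sweep.biomass_ratio)]
        assert len(vals) >= 3
        assert np.all(np.diff(vals) <= 1e-9)

    def test_exclusion_at_extreme_ratios(self, resource_sweep):
        # vanishing NO3- supply starves Syn; dominant NO3- supply starves Pro
        assert resource_sweep.zones[0] == "pro_only"
        assert resource_sweep.zones[-1] == "syn_only"

    def test_doubled_no3_supply_shifts_coexistence_window_left(self, ref_cfg):
        """With the NO3- supply doubled (ratio 2:3), the coexistence band in
        K-ratio space sits at lower ratios than at 1:3."""
        grid = np.logspace(-2, 2, 15)
        base = pc.sweep_k_ratios(ref_cfg, grid, grid)
        doubled = pc.sweep_k_ratios(ref_cfg.replace(s_no3=2 * ref_cfg.s_no3),
                                    grid, grid)
        shifts = []
        for i in range(len(grid)):
            m1 = base.coexistence_mask()[i, :]
            m2 = doubled.coexistence_mask()[i, :]
            if m1.any() and m2.any():
                shifts.append(np.flatnonzero(m2).mean()
                              - np.flatnonzero(m1).mean())
        assert len(shifts) >= 3
        assert np.mean(shifts) < 0  # displaced toward lower KNH4 ratios
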