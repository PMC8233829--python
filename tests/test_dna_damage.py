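"""Radical-DNA sweeps, concurrent scheduling reductions, SSB/DSB scoring."""

import math

import numpy as np
import pytest

from trackmc.chemistry import (
    RadicalEnsemble,
    ReactionTable,
    StepSchedule,
    chem_step,
    evolve_radicals,
)
from trackmc.dna_damage import (
    BreakRules,
    DamageSite,
    DNAReactionParams,
    classify_breaks,
    concurrent_evolve,
    dna_reaction_sweep,
    greedy_pair_breaks,
)
from trackmc.dna_geometry import (
    KIND_BASE,
    KIND_HISTONE,
    KIND_SUGAR,
    DNAGeometry,
    DNAGeometryParams,
)


def _empty_geometry():
    g = DNAGeometry(params=DNAGeometryParams(), seed=0)
    g.voxels = {}
    return g


def _place(ensemble_table, positions, species_names):
    idx = np.array([ensemble_table.index[n] for n in species_names])
    return RadicalEnsemble(ensemble_table, np.asarray(positions, float), idx)


def _single_element_geometry(kind, center, radius, bp=0, strand=0):
    g = DNAGeometry(params=DNAGeometryParams(n_voxels=(1, 1, 1)), seed=0)
    g.voxels[(0, 0, 0)] = {
        "centers": np.asarray([center], float),
        "radii": np.asarray([radius], float),
        "kinds": np.asarray([kind], int),
        "bp": np.asarray([bp], int),
        "strand": np.asarray([strand if kind == KIND_SUGAR else -1], int),
    }
    g.total_bp = 1
    return g


class TestDNAReactionParams:
    def test_averaged_base_rates_from_per_base_values(self, dna_params):
        assert dna_params.averaged_base_rate("OH") == pytest.approx(6.95e9)
        assert dna_params.averaged_base_rate("e_aq") == pytest.approx(13.5e9)

    def test_disabled_channel(self, dna_params):
        assert dna_params.rate("e_aq", KIND_SUGAR) <= 0
        assert dna_params.rate("OH", KIND_SUGAR) == pytest.approx(1.9e9)

    def test_all_radii_below_one_nm(self, dna_params):
        assert 0 < dna_params.max_rc_nm() < 1.0

    def test_invalid_scavenging_probability(self, chem_table):
        with pytest.raises(ValueError):
            DNAReactionParams({"OH": {"base": 1e9}}, 1.5, chem_table)


class TestSweep:
    def test_oh_contact_with_sugar_records_damage(self, chem_table, dna_params, rng):
        rc = dna_params.rc_nm("OH", KIND_SUGAR)
        geom = _single_element_geometry(KIND_SUGAR, [27.5, 27.5, 27.5], 0.35,
                                        bp=7, strand=1)
        ens = _place(chem_table, [[27.5, 27.5, 27.5 + 0.35 + rc / 2]], ["OH"])
        sites, removed = dna_reaction_sweep(ens, geom, dna_params,
                                            ens.positions_nm.copy(), 0.0, 1e-12, rng)
        assert len(sites) == 1 and removed == [0]
        assert sites[0].bp == 7 and sites[0].strand == 1
        assert sites[0].kind == KIND_SUGAR and sites[0].source == "indirect-OH"
        assert not ens.alive[0]

    def test_eh_near_sugar_does_not_react(self, chem_table, dna_params, rng):
        geom = _single_element_geometry(KIND_SUGAR, [27.5, 27.5, 27.5], 0.35)
        ens = _place(chem_table, [[27.5, 27.5, 27.9]], ["e_aq"])
        sites, removed = dna_reaction_sweep(ens, geom, dna_params,
                                            ens.positions_nm.copy(), 0.0, 1e-12, rng)
        assert sites == [] and removed == []
        assert ens.alive[0]

    def test_histone_scavenges_without_damage_record(self, chem_table, dna_params, rng):
        geom = _single_element_geometry(KIND_HISTONE, [27.5, 27.5, 27.5], 3.3)
        ens = _place(chem_table, [[27.5, 27.5, 28.0]], ["OH"])  # inside sphere
        sites, removed = dna_reaction_sweep(ens, geom, dna_params,
                                            ens.positions_nm.copy(), 0.0, 1e-12, rng)
        assert sites == [] and removed == [0]
        assert not ens.alive[0]

    def test_histone_with_zero_ps_spares_radical(self, chem_table, rng):
        params = DNAReactionParams({"OH": {"base": 6.95e9, "sugar": 1.9e9}},
                                   0.0, chem_table)
        geom = _single_element_geometry(KIND_HISTONE, [27.5, 27.5, 27.5], 3.3)
        ens = _place(chem_table, [[27.5, 27.5, 28.0]], ["OH"])
        sites, removed = dna_reaction_sweep(ens, geom, params,
                                            ens.positions_nm.copy(), 0.0, 1e-12, rng)
        assert sites == [] and removed == []

    def test_bridge_hit_over_elapsed_interval(self, chem_table, dna_params):
        # a radical that moved from one side of the sugar to a point still
        # outside contact reacts with the bridge probability; with both
        # separations tiny and a long interval the probability is ~1
        geom = _single_element_geometry(KIND_SUGAR, [27.5, 27.5, 27.5], 0.35)
        prev = np.array([[27.5, 27.5, 27.5 + 0.35 + 0.15]])
        ens = _place(chem_table, [[27.5, 27.5 + 0.35 + 0.15, 27.5]], ["OH"])
        sites, _ = dna_reaction_sweep(ens, geom, dna_params, prev, 1e-9, 1e-9,
                                      np.random.default_rng(0))
        assert len(sites) == 1


class TestConcurrentReductions:
    def test_empty_geometry_reduces_to_plain_chemistry(self, chem_table, dna_params):
        def chem_only():
            rng = np.random.default_rng(5)
            ens = _place(chem_table, rng.random((120, 3)) * 10.0, ["OH"] * 120)
            tl, _ = evolve_radicals(ens, StepSchedule(t_end_s=3e-12), rng)
            return tl, ens.positions_nm.copy(), ens.alive.copy()

        def concurrent():
            rng = np.random.default_rng(5)
            ens = _place(chem_table, rng.random((120, 3)) * 10.0, ["OH"] * 120)
            sites, tl, ens = concurrent_evolve(ens, _empty_geometry(),
                                               StepSchedule(t_end_s=3e-12),
                                               dna_params, rng, ti_s=1e-12)
            return sites, tl, ens.positions_nm.copy(), ens.alive.copy()

        tl_a, pos_a, alive_a = chem_only()
        sites, tl_b, pos_b, alive_b = concurrent()
        assert sites == []
        assert tl_a == tl_b
        assert np.array_equal(pos_a, pos_b)
        assert np.array_equal(alive_a, alive_b)

    def test_ti_equal_tc_reduces_to_overlay(self, chem_table, dna_params,
                                            small_geometry):
        tc = 5e-12
        schedule = StepSchedule(t_end_s=tc)

        def run_concurrent():
            rng = np.random.default_rng(21)
            pos = rng.random((150, 3)) * 30.0 + np.array([20.0, 12.0, 12.0])
            ens = _place(chem_table, pos, ["OH"] * 150)
            return concurrent_evolve(ens, small_geometry, schedule, dna_params,
                                     rng, ti_s=tc)

        def run_overlay():
            # chemistry alone, then one end-of-stage sweep over the full tc
            rng = np.random.default_rng(21)
            pos = rng.random((150, 3)) * 30.0 + np.array([20.0, 12.0, 12.0])
            ens = _place(chem_table, pos, ["OH"] * 150)
            prev = ens.positions_nm.copy()
            for t0, dt in schedule:
                chem_step(ens, t0, dt, rng)
                if ens.positions_nm.shape[0] > prev.shape[0]:
                    prev = np.vstack([prev, ens.positions_nm[prev.shape[0]:]])
            sites, _ = dna_reaction_sweep(ens, small_geometry, dna_params,
                                          prev, tc, tc, rng)
            return sites, ens

        sites_c, _, ens_c = run_concurrent()
        sites_o, ens_o = run_overlay()
        assert sites_c == sites_o
        assert np.array_equal(ens_c.positions_nm, ens_o.positions_nm)
        assert np.array_equal(ens_c.alive, ens_o.alive)

    def test_first_check_at_ti(self, chem_table, dna_params):
        # one OH inside the contact radius of a sugar sphere with ti = 1 ps:
        # damage is recorded at the first check (the bridge from the start
        # point is certain even if the radical has diffused away)
        geom = _single_element_geometry(KIND_SUGAR, [27.5, 27.5, 27.5], 0.35)
        rng = np.random.default_rng(2)
        ens = _place(chem_table, [[27.5, 27.5, 27.5 + 0.35 + 0.05]], ["OH"])
        sites, _, _ = concurrent_evolve(ens, geom, StepSchedule(t_end_s=4e-12),
                                        dna_params, rng, ti_s=1e-12)
        assert len(sites) == 1
        assert sites[0].time_s <= 1.1e-12


class TestClassification:
    def test_no_damage_no_breaks(self, rng):
        s = classify_breaks([], BreakRules(), rng)
        assert s.ssb == 0 and s.dsb == 0 and s.base_damage == 0

    def test_two_opposite_breaks_within_ten_bp_pair(self, rng):
        rules = BreakRules(p_indirect_sugar_break=1.0)
        sites = [DamageSite(0.0, 100, 0, KIND_SUGAR, "indirect-OH"),
                 DamageSite(0.0, 105, 1, KIND_SUGAR, "indirect-OH")]
        s = classify_breaks(sites, rules, rng)
        assert s.dsb == 1 and s.ssb == 0

    def test_same_strand_breaks_stay_ssb(self, rng):
        rules = BreakRules(p_indirect_sugar_break=1.0)
        sites = [DamageSite(0.0, 100, 0, KIND_SUGAR, "indirect-OH"),
                 DamageSite(0.0, 105, 0, KIND_SUGAR, "indirect-OH")]
        s = classify_breaks(sites, rules, rng)
        assert s.dsb == 0 and s.ssb == 2

    def test_base_damage_never_breaks(self, rng):
        rules = BreakRules(p_indirect_sugar_break=1.0)
        sites = [DamageSite(0.0, 100, -1, KIND_BASE, "indirect-OH")] * 5
        s = classify_breaks(sites, rules, rng)
        assert s.base_damage == 5 and s.n_breaks == 0

    def test_break_probability_applied(self):
        sites = [DamageSite(0.0, bp, 0, KIND_SUGAR, "indirect-OH")
                 for bp in range(0, 40000, 20)]
        s = classify_breaks(sites, BreakRules(), np.random.default_rng(8))
        n, p = len(sites), 0.4
        assert abs(s.n_breaks - n * p) < 3 * math.sqrt(n * p * (1 - p))

    def test_direct_damage_energy_ramp(self, rng):
        rules = BreakRules()
        assert rules.direct_break_probability(5.0) == 0.0
        assert rules.direct_break_probability(37.5) == 1.0
        assert rules.direct_break_probability(21.25) == pytest.approx(0.5)
        s = classify_breaks([], rules, rng, direct_hits=[(10, 0, 100.0),
                                                         (30, 1, 1.0)])
        assert s.n_breaks == 1

    def test_greedy_equals_optimal_pairing(self, rng):
        # exhaustive check against maximum matching on random break sets
        import networkx as nx

        for trial in range(300):
            r = np.random.default_rng(trial)
            n = int(r.integers(2, 14))
            breaks = sorted({(int(r.integers(0, 40)), int(r.integers(0, 2)))
                             for _ in range(n)})
            g = nx.Graph()
            g.add_nodes_from(range(len(breaks)))
            for i in range(len(breaks)):
                for j in range(i + 1, len(breaks)):
                    if (breaks[i][1] != breaks[j][1]
                            and abs(breaks[i][0] - breaks[j][0]) <= 10):
                        g.add_edge(i, j)
            optimal = len(nx.max_weight_matching(g, maxcardinality=True))
            assert greedy_pair_breaks(breaks, 10) == optimal

    def test_prefix_consistency_of_draws(self):
        # classifying a time-prefix of the site list with the same seed uses
        # the same random draws for the shared sites
        sites = [DamageSite(t * 1e-12, 10 * t, t % 2, KIND_SUGAR, "indirect-OH")
                 for t in range(40)]
        full = classify_breaks(sites, BreakRules(), np.random.default_rng(3))
        half = classify_breaks(sites[:20], BreakRules(), np.random.default_rng(3))
        # prefix DSB count can never exceed the full one
        assert half.dsb <= full.dsb
        assert half.n_breaks <= full.n_breaks
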