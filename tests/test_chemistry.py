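"""Diffusion, pair reactions, Brownian bridge and the evolution loop."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trackmc.chemistry import (
    RadicalEnsemble,
    ReactionTable,
    SpeciesParams,
    SpurSourceParams,
    StepSchedule,
    brownian_bridge_probability,
    candidate_pairs,
    diffuse_step,
    evolve_radicals,
    pair_reaction_check,
    reaction_radius,
    synth_radiolysis_source,
)
from trackmc.constants import CONSTANTS


def single_reaction_table(k=0.44e10):
    return ReactionTable(
        [SpeciesParams("OH", 2.8e-9), SpeciesParams("H2O2", 2.3e-9)],
        [{"reactants": ["OH", "OH"], "products": ["H2O2"], "k_L_mol_s": k}],
    )


class TestReactionRadius:
    def test_zero_rate(self):
        assert reaction_radius(0.0, 1e-9) == 0.0

    def test_hand_unit_conversion(self):
        # OH-base mean rate 6.95e9 L/mol/s, D = 2.8e-9 m^2/s -> ~0.33 nm
        rc = reaction_radius(6.95e9, 2.8e-9)
        by_hand = (6.95e9 * 1e-3) / (4 * math.pi * 6.02214076e23 * 2.8e-9)
        assert rc == pytest.approx(by_hand, rel=1e-12)
        assert rc == pytest.approx(0.328e-9, rel=0.01)
        assert rc < 1e-9

    def test_invalid_diffusion_raises(self):
        with pytest.raises(ValueError):
            reaction_radius(1e9, 0.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(k=st.floats(1e6, 1e12), scale=st.floats(0.1, 10.0))
    def test_linear_in_rate(self, k, scale):
        d = 3e-9
        assert reaction_radius(k * scale, d) == pytest.approx(
            scale * reaction_radius(k, d), rel=1e-9)


class TestDiffusion:
    def test_zero_time_or_diffusivity_unchanged(self, rng):
        pos = rng.random((50, 3))
        assert np.array_equal(diffuse_step(pos, 0.0, 1e-12, rng), pos)
        assert np.array_equal(diffuse_step(pos, 1e-9, 0.0, rng), pos)

    def test_einstein_relation(self, rng):
        # MSD = 6 D dt within 2% at 1e5 samples
        D, dt = 2.8e-9, 1e-12
        start = np.zeros((100_000, 3))
        end = diffuse_step(start, D, dt, rng)
        msd = np.mean(np.sum((end * 1e-9) ** 2, axis=1))
        assert msd == pytest.approx(6 * D * dt, rel=0.02)

    def test_components_uncorrelated(self, rng):
        disp = diffuse_step(np.zeros((100_000, 3)), 1e-9, 1e-12, rng)
        c = np.corrcoef(disp.T)
        assert abs(c[0, 1]) < 0.02 and abs(c[0, 2]) < 0.02 and abs(c[1, 2]) < 0.02


class TestBrownianBridge:
    def test_contact_certain(self, rng):
        assert brownian_bridge_probability(0.1, 0.5, 0.2, 1e-9, 1e-12) == 1.0
        assert pair_reaction_check([0, 0, 0], [0, 0, 0.1], [0, 0, 0.05],
                                   [0, 0, 0.2], 0.15, 1e-9, 1e-12, rng)

    def test_zero_radius_limit(self):
        p = brownian_bridge_probability(1.0, 1.0, 0.0, 5.6e-9, 1e-12)
        assert p == pytest.approx(math.exp(-(1e-9) ** 2 / (5.6e-9 * 1e-12)))

    def test_negative_radius_raises(self):
        with pytest.raises(ValueError):
            brownian_bridge_probability(1.0, 1.0, -0.1, 1e-9, 1e-12)

    def test_against_fine_step_simulation(self, rng):
        # the pair-bridge formula is the exact first-passage result for the
        # separation coordinate treated as a 1-D diffusion; compare it at
        # d1 = d2 = 2 Rc against the crossing frequency of a 100x finer
        # Brownian bridge of that coordinate, agreement within 5%
        Rc_nm, D12, dt = 0.2, 5.6e-9, 7e-12
        d = 2 * Rc_nm
        p_formula = brownian_bridge_probability(d, d, Rc_nm, D12, dt)
        n_rep, n_sub = 20_000, 100
        dt_sub = dt / n_sub
        sigma_nm = math.sqrt(2 * D12 * dt_sub) * 1e9
        ts = np.linspace(0, 1, n_sub + 1)
        steps = rng.standard_normal((n_rep, n_sub)) * sigma_nm
        walk = np.concatenate([np.zeros((n_rep, 1)), np.cumsum(steps, axis=1)],
                              axis=1)
        bridge = walk - ts[None, :] * walk[:, -1:] + d
        hit = np.any(bridge <= Rc_nm, axis=1)
        # continuous-path minimum between sampled points: each sub-segment of
        # a 1-D diffusion crosses the barrier with the exact first-passage
        # probability given its endpoints
        g1 = np.maximum(bridge[:, :-1] - Rc_nm, 0.0) * 1e-9
        g2 = np.maximum(bridge[:, 1:] - Rc_nm, 0.0) * 1e-9
        p_seg = np.exp(-g1 * g2 / (D12 * dt_sub))
        hit |= np.any(rng.random((n_rep, n_sub)) < p_seg, axis=1)
        p_mc = hit.mean()
        assert p_formula == pytest.approx(p_mc, rel=0.05)


class TestCandidatePairs:
    def test_backends_agree(self, rng):
        pos = rng.random((300, 3)) * 10.0
        r = 0.9
        grid = candidate_pairs(pos, r, backend="grid")
        brute = candidate_pairs(pos, r, backend="brute")
        tree = candidate_pairs(pos, r, backend="kdtree")
        assert np.array_equal(grid, brute)
        assert np.array_equal(tree, brute)

    def test_backends_agree_periodic(self, rng):
        pos = rng.random((200, 3)) * 12.0
        grid = candidate_pairs(pos, 1.1, boxsize_nm=12.0, backend="grid")
        brute = candidate_pairs(pos, 1.1, boxsize_nm=12.0, backend="brute")
        tree = candidate_pairs(pos, 1.1, boxsize_nm=12.0, backend="kdtree")
        assert np.array_equal(grid, brute)
        assert np.array_equal(tree, brute)


class TestEvolve:
    def test_conservation_without_reactions(self, rng):
        table = ReactionTable([SpeciesParams("OH", 2.8e-9)], [])
        ens = RadicalEnsemble(table, rng.random((100, 3)) * 20, np.zeros(100, int))
        timeline, _ = evolve_radicals(ens, StepSchedule(t_end_s=1e-11), rng)
        assert all(c["OH"] == 100 for _, c in timeline)

    def test_determinism(self):
        table = single_reaction_table()
        def run():
            rng = np.random.default_rng(42)
            ens = RadicalEnsemble(table, rng.random((200, 3)) * 8.0,
                                  np.zeros(200, int))
            tl, _ = evolve_radicals(ens, StepSchedule(t_end_s=5e-12), rng)
            return tl, ens.positions_nm.copy(), ens.alive.copy()
        (tl_a, pa, aa), (tl_b, pb, ab) = run(), run()
        assert tl_a == tl_b
        assert np.array_equal(pa, pb) and np.array_equal(aa, ab)

    def test_grid_equals_brute_force_sweep(self):
        # the grid-accelerated search finds the identical reaction set as an
        # all-pairs sweep, bit-for-bit with the same seed
        table = ReactionTable.from_file()
        def run(backend):
            rng = np.random.default_rng(17)
            n = 150
            species = rng.integers(0, len(table.names), n)
            ens = RadicalEnsemble(table, rng.random((n, 3)) * 6.0, species)
            tl, ev = evolve_radicals(ens, StepSchedule(t_end_s=3e-12), rng,
                                     backend=backend, record_events=True)
            return tl, ev, ens.alive.copy(), ens.positions_nm.copy()
        tg, eg, ag, pg = run("grid")
        tb, eb, ab, pb = run("brute")
        assert eg == eb
        assert tg == tb
        assert np.array_equal(ag, ab) and np.array_equal(pg, pb)

    def test_stoichiometric_bookkeeping(self):
        # every event removes its reactants and adds its products; the event
        # log balances the species counts at the end
        table = ReactionTable.from_file()
        rng = np.random.default_rng(23)
        n = 400
        species = rng.integers(0, len(table.names), n)
        initial = {name: int((species == i).sum())
                   for i, name in enumerate(table.names)}
        ens = RadicalEnsemble(table, rng.random((n, 3)) * 10.0, species)
        tl, events = evolve_radicals(ens, StepSchedule(t_end_s=1e-11), rng,
                                     record_events=True)
        expected = dict(initial)
        for _, reactants, _, products in events:
            for r in reactants:
                expected[r] -= 1
            for p in products:
                expected[p] += 1
        assert expected == tl[-1][1]

    def test_second_order_kinetics_recovery(self):
        # dilute OH + OH -> H2O2 in a periodic box: the rate constant fitted
        # from the 1/N(t) slope (convention dN/dt = -2 k' N^2) recovers the
        # tabulated k within 10% once the early transient has passed
        k = 0.44e10
        table = single_reaction_table(k)
        N, box = 6000, 87.0
        rng = np.random.default_rng(11)
        ens = RadicalEnsemble(table, rng.random((N, 3)) * box, np.zeros(N, int))
        sched = StepSchedule(t_end_s=3e-9, dt_fine_s=3e-12, t_fine_s=1.0,
                             dt_max_s=3e-12)
        tl, _ = evolve_radicals(ens, sched, rng, boundary=("periodic", box),
                                backend="kdtree")
        ts = np.array([t for t, _ in tl])
        ns = np.array([c["OH"] for _, c in tl])
        V = (box * 1e-9) ** 3
        m = ts >= 1e-9
        slope = np.polyfit(ts[m], 1.0 / ns[m], 1)[0]
        k_fit = slope * V / 2.0 * CONSTANTS.avogadro * 1e3
        assert k_fit == pytest.approx(k, rel=0.10)

    def test_absorbing_sphere_boundary(self, rng):
        table = ReactionTable([SpeciesParams("OH", 2.8e-9)], [])
        ens = RadicalEnsemble(table, np.zeros((200, 3)), np.zeros(200, int))
        sched = StepSchedule(t_end_s=1e-9, dt_fine_s=1e-11, t_fine_s=1.0,
                             dt_max_s=1e-11)
        tl, _ = evolve_radicals(ens, sched, rng,
                                boundary=("absorbing_sphere", np.zeros(3), 5.0))
        assert tl[-1][1]["OH"] < 200


class TestSchedule:
    def test_covers_duration(self):
        sched = StepSchedule(t_end_s=1e-9)
        t_end = sched.steps[-1][0] + sched.steps[-1][1]
        assert t_end == pytest.approx(1e-9, rel=1e-9)
        assert all(dt > 0 for _, dt in sched)

    def test_fine_then_coarse(self):
        sched = StepSchedule(t_end_s=1e-6)
        dts = [dt for _, dt in sched]
        assert dts[0] == pytest.approx(0.1e-12)
        assert max(dts) <= 10e-9 + 1e-15
        assert len(sched) < 500


class TestSpurSource:
    def test_total_count_honoured(self, chem_table, rng):
        params = SpurSourceParams(n_radicals=777)
        ens = synth_radiolysis_source(params, chem_table, rng)
        assert ens.n_alive == 777

    def test_spur_rms_radius(self, chem_table, rng):
        params = SpurSourceParams(n_radicals=10_000, n_spurs=1,
                                  spur_sigma_nm=3.0)
        ens = synth_radiolysis_source(params, chem_table, rng)
        rel = ens.positions_nm - np.asarray(params.origin_nm)
        per_axis_rms = np.sqrt(np.mean(rel**2))
        assert per_axis_rms == pytest.approx(3.0, rel=0.03)

    def test_species_proportions_multinomial(self, chem_table, rng):
        params = SpurSourceParams(n_radicals=10_000)
        ens = synth_radiolysis_source(params, chem_table, rng)
        counts = ens.counts()
        total_w = sum(params.fractions.values())
        n = params.n_radicals
        for name, w in params.fractions.items():
            p = w / total_w
            sd = math.sqrt(n * p * (1 - p))
            assert abs(counts[name] - n * p) < 3 * sd

    def test_invalid_fractions_raise(self, chem_table, rng):
        with pytest.raises(ValueError):
            synth_radiolysis_source(
                SpurSourceParams(fractions={"OH": -1.0}), chem_table, rng)
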