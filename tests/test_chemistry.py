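"""SBS engine: encounter radii, diffusion, reactions, stepping, evolution."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from flashchem.beam import ROIGeometry
from flashchem.chemistry import (ChemicalState, DiffusionCoefficients,
                                 ReactionTable, StepperSettings, adaptive_dt,
                                 choose_dt, diffuse, evolve, find_pairs,
                                 inject, minimum_image, react,
                                 reaction_radius)
from flashchem.constants import rate_constant_nm3_per_ps
from flashchem.species import N_SPECIES, SpeciesKind
from flashchem.track import InitialRadicalBatch, TrackParameters, sample_track

OH = SpeciesKind.OH_RADICAL
E = SpeciesKind.E_HYDRATED
H2O2 = SpeciesKind.H2O2


def make_state(roi, positions, kinds, clock=0.0, energy=100.0):
    pos = np.asarray(positions, dtype=float).reshape(-1, 3)
    return ChemicalState(positions_nm=pos,
                         kinds=np.asarray(kinds, dtype=np.int8),
                         alive=np.ones(pos.shape[0], dtype=bool),
                         clock_ps=clock,
                         cumulative_deposited_energy_ev=energy,
                         roi=roi)


@pytest.fixture(params=["auto", "reference"])
def engine(request) -> str:
    return request.param


class TestReactionRadius:
    def test_dimensional_analysis_oracle(self):
        # hand conversion done independently: k = 5.5e9 / M / s
        # = 5.5e9 * 1e24 nm^3 / (N_A mol) / s = 9.1330e9 nm^3/s per pair;
        # r = k / (4 pi D_sum) with D_sum = 5.6e9 nm^2/s -> 0.12978 nm
        assert reaction_radius(5.5e9, 5.6e9) == pytest.approx(0.12978,
                                                              rel=1e-4)

    def test_proportionality(self):
        r1 = reaction_radius(1e10, 5e9)
        assert reaction_radius(2e10, 5e9) == pytest.approx(2 * r1)
        assert reaction_radius(1e10, 1e10) == pytest.approx(r1 / 2)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            reaction_radius(0.0, 5e9)
        with pytest.raises(ValueError):
            reaction_radius(1e10, 0.0)

    def test_default_table_closed_and_symmetric(self):
        table = ReactionTable.default()
        assert all(c.reaction_radius_nm > 0 for c in table.channels)
        assert np.array_equal(table.channel_matrix, table.channel_matrix.T)
        # at most one channel per unordered pair
        for ch in table.channels:
            a, b = int(ch.reactants[0]), int(ch.reactants[1])
            assert table.channel_matrix[a, b] == table.channel_matrix[b, a]


class TestDiffuse:
    def test_zero_diffusion_keeps_positions(self, roi_small, rng):
        state = make_state(roi_small, [[50, 50, 50]], [OH])
        frozen = DiffusionCoefficients({k: 0.0 for k in SpeciesKind})
        diffuse(state, 10.0, frozen, roi_small, rng)
        assert np.array_equal(state.positions_nm, [[50.0, 50.0, 50.0]])

    def test_einstein_relation_msd(self, rng):
        """Mean squared displacement equals 6 D t within 3 SD."""
        roi = ROIGeometry(face_side_um=100.0, depth_um=100.0)
        n, dt, steps = 2000, 10.0, 20
        start = np.full((n, 3), 5.0e4)
        state = make_state(roi, start.copy(), [OH] * n)
        diff = DiffusionCoefficients()
        for _ in range(steps):
            diffuse(state, dt, diff, roi, rng)
        d = diff.values_nm2_s[OH] * 1e-12
        expected = 6.0 * d * dt * steps
        sq = ((state.positions_nm - start) ** 2).sum(axis=1)
        se = math.sqrt(2.0 / 3.0) * expected / math.sqrt(n)
        assert abs(sq.mean() - expected) < 3 * se

    def test_periodic_wrap_identity(self, roi_small):
        """A particle stepping past the boundary re-enters opposite side."""
        class UnitSteps:
            def normal(self, size):
                return np.ones(size)

        box = roi_small.face_side_nm
        eps = 1.0
        state = make_state(roi_small, [[box - eps, 10, 10]], [OH])
        d_val = (2 * eps) ** 2 / 2.0  # sqrt(2 D dt) = 2 eps with dt = 1
        diff = DiffusionCoefficients({k: d_val * 1e12 for k in SpeciesKind})
        diffuse(state, 1.0, diff, roi_small, UnitSteps())
        assert state.positions_nm[0, 0] == pytest.approx(eps)

    def test_containment_after_many_steps(self, roi_small, rng):
        state = make_state(roi_small, rng.uniform(0, 100, (50, 3)),
                           [OH] * 50)
        diff = DiffusionCoefficients()
        box = np.array(roi_small.box_nm)
        for _ in range(200):
            diffuse(state, 100.0, diff, roi_small, rng)
            assert np.all(state.positions_nm >= 0)
            assert np.all(state.positions_nm < box)


class TestReact:
    def test_single_pair_closure(self, roi_small):
        table = ReactionTable.default()
        r = table.radius_matrix[int(OH), int(OH)]
        state = make_state(roi_small, [[50, 50, 50], [50, 50, 50 + 0.9 * r]],
                           [OH, OH])
        n_rx, _ = react(state, table)
        assert n_rx == 1
        assert state.n_particles == 1
        assert state.kinds[state.alive][0] == H2O2
        assert state.positions_nm[state.alive][0, 2] == pytest.approx(
            50 + 0.45 * r)

    def test_lone_particle_unchanged(self, roi_small):
        state = make_state(roi_small, [[50, 50, 50]], [OH])
        n_rx, gap = react(state, ReactionTable.default())
        assert n_rx == 0
        assert state.n_particles == 1
        assert gap == math.inf

    def test_closest_pair_wins_tie_break(self, roi_small):
        """Three mutually close OH: one H2O2 plus one surviving OH."""
        table = ReactionTable.default()
        r = table.radius_matrix[int(OH), int(OH)]
        z = [50.0, 50.0 + 0.40 * r, 50.0 + 0.85 * r]
        state = make_state(roi_small, [[50, 50, zz] for zz in z], [OH] * 3)
        n_rx, _ = react(state, table)
        counts = state.counts()
        assert n_rx == 1
        assert counts[int(H2O2)] == 1
        assert counts[int(OH)] == 1
        # the survivor is the particle farthest from the closest pair
        surv_z = state.positions_nm[state.alive][
            state.kinds[state.alive] == int(OH)]
        assert surv_z[0, 2] == pytest.approx(z[2])

    def test_midpoint_respects_periodic_images(self, roi_small):
        table = ReactionTable.default()
        r = table.radius_matrix[int(OH), int(OH)]
        box = roi_small.face_side_nm
        state = make_state(
            roi_small,
            [[0.2 * r, 50, 50], [box - 0.2 * r, 50, 50]], [OH, OH])
        n_rx, _ = react(state, table)
        assert n_rx == 1
        x = state.positions_nm[state.alive][0, 0]
        # midpoint through the boundary, not through the box centre
        assert min(x, box - x) < r

    def test_tree_equals_brute_force(self, roi_small, rng):
        """Grid/tree search equals all-pairs enumeration on <=500 points."""
        n = 400
        pos = rng.uniform(0, 100, (n, 3))
        kinds = rng.integers(0, N_SPECIES, n).astype(np.int8)
        table = ReactionTable.default()
        s1 = make_state(roi_small, pos.copy(), kinds.copy())
        s2 = make_state(roi_small, pos.copy(), kinds.copy())
        p1 = find_pairs(s1, 5.0, mode="tree")
        p2 = find_pairs(s2, 5.0, mode="brute")
        set1 = {tuple(sorted((int(i), int(j)))) for i, j in zip(*p1[:2])}
        set2 = {tuple(sorted((int(i), int(j)))) for i, j in zip(*p2[:2])}
        assert set1 == set2
        react(s1, table, pairs=None, r_query_nm=5.0, mode="tree")
        react(s2, table, pairs=None, r_query_nm=5.0, mode="brute")
        assert np.array_equal(np.sort(s1.kinds[s1.alive]),
                              np.sort(s2.kinds[s2.alive]))


class TestAdaptiveDt:
    def test_far_apart_gives_dt_max(self, roi_small):
        state = make_state(roi_small, [[5, 5, 5], [90, 90, 90]], [OH, OH])
        dt = adaptive_dt(state, ReactionTable.default(),
                         DiffusionCoefficients())
        assert dt == 1000.0

    def test_near_contact_gives_dt_min(self, roi_small):
        table = ReactionTable.default()
        r = table.radius_matrix[int(OH), int(OH)]
        state = make_state(roi_small,
                           [[50, 50, 50], [50, 50, 50 + r + 1e-3]], [OH, OH])
        dt = adaptive_dt(state, table, DiffusionCoefficients())
        assert dt == 0.1

    def test_empty_state_gives_dt_max(self, roi_small):
        state = ChemicalState.empty(roi_small)
        assert adaptive_dt(state, ReactionTable.default(),
                           DiffusionCoefficients(), dt_max_ps=500.0) == 500.0

    def test_choose_dt_monotone_in_gap(self):
        d_max = 9.5e-3
        dts = [choose_dt(g, d_max) for g in (0.01, 0.5, 2.0, 8.0, 30.0,
                                             math.inf)]
        assert dts == sorted(dts)
        assert dts[0] == 0.1
        assert dts[-1] == 1000.0


class TestInject:
    def batch(self, n=3, t=0.0, energy=50.0):
        return InitialRadicalBatch(
            positions_nm=np.tile([[10.0, 10.0, 10.0]], (n, 1)),
            kinds=np.full(n, int(OH), dtype=np.int8),
            deposited_energy_ev=energy, creation_time_ps=t)

    def test_inject_into_empty_state(self, roi_small):
        state = ChemicalState.empty(roi_small)
        inject(state, self.batch(n=4, energy=77.0))
        assert state.n_particles == 4
        assert state.cumulative_deposited_energy_ev == 77.0

    def test_energy_additivity(self, roi_small):
        state = ChemicalState.empty(roi_small)
        inject(state, self.batch(energy=50.0))
        inject(state, self.batch(energy=25.0, t=10.0))
        assert state.cumulative_deposited_energy_ev == 75.0

    def test_count_difference_is_batch_size(self, roi_small):
        state = make_state(roi_small, [[5, 5, 5]], [E])
        before = state.n_particles
        inject(state, self.batch(n=7, t=state.clock_ps))
        assert state.n_particles == before + 7

    def test_batch_in_the_past_rejected(self, roi_small):
        state = ChemicalState.empty(roi_small, clock_ps=100.0)
        with pytest.raises(ValueError):
            inject(state, self.batch(t=50.0))


class TestEvolve:
    def test_empty_run_is_all_zero(self, roi_small, engine):
        state = ChemicalState.empty(roi_small)
        hist = evolve(state, [], 1000.0,
                      stepper=StepperSettings(engine=engine), rng=0)
        assert np.all(hist.counts == 0)
        assert state.clock_ps == 1000.0

    def test_reactions_off_conserves_counts(self, roi_small, engine):
        """With an empty reaction table every species count is constant."""
        rng = np.random.default_rng(5)
        pos = rng.uniform(0, 100, (80, 3))
        kinds = rng.integers(0, N_SPECIES, 80).astype(np.int8)
        batch = InitialRadicalBatch(pos, kinds, 1000.0, 0.0)
        state = ChemicalState.empty(roi_small)
        hist = evolve(state, [batch], 5000.0, table=ReactionTable([]),
                      stepper=StepperSettings(engine=engine), rng=1)
        final = hist.counts[-1]
        expected = np.bincount(kinds.astype(int), minlength=N_SPECIES)
        assert np.array_equal(final, expected)
        assert np.all(hist.counts[1:] == expected)

    def test_injection_pauses_at_exact_time(self, roi_small, engine):
        batch0 = InitialRadicalBatch(np.array([[10.0, 10, 10]]),
                                     np.array([int(OH)], dtype=np.int8),
                                     10.0, 0.0)
        batch1 = InitialRadicalBatch(np.array([[90.0, 90, 90]]),
                                     np.array([int(OH)], dtype=np.int8),
                                     20.0, 1234.5)
        state = ChemicalState.empty(roi_small)
        hist = evolve(state, [batch0, batch1], 5000.0,
                      stepper=StepperSettings(engine=engine), rng=2)
        assert 1234.5 in hist.times_ps
        idx = np.searchsorted(hist.times_ps, 1234.5)
        assert hist.energy_ev[idx] == 30.0
        assert hist.energy_ev[idx - 1] == 10.0
        assert state.cumulative_deposited_energy_ev == 30.0

    def test_fixed_seed_bitwise_identical(self, roi_small, engine):
        roi = ROIGeometry(face_side_um=0.5, depth_um=0.1)
        batch = sample_track(10.0, (250.0, 250.0), roi, TrackParameters(), 3)
        out = []
        for _ in range(2):
            state = ChemicalState.empty(roi)
            hist = evolve(state, [batch], 2.0e4,
                          stepper=StepperSettings(engine=engine),
                          rng=np.random.default_rng(77))
            out.append(hist)
        assert np.array_equal(out[0].times_ps, out[1].times_ps)
        assert np.array_equal(out[0].counts, out[1].counts)

    def test_reaction_log_replay_reproduces_counts(self, engine):
        """Replaying logged reactions maps initial counts to final counts."""
        roi = ROIGeometry(face_side_um=0.5, depth_um=0.2)
        batch = sample_track(10.0, (250.0, 250.0), roi, TrackParameters(), 8)
        table = ReactionTable.default()
        state = ChemicalState.empty(roi)
        log: list = []
        evolve(state, [batch], 5.0e4, table=table,
               stepper=StepperSettings(engine=engine), rng=4,
               reaction_log=log)
        assert len(log) > 10
        counts = np.bincount(np.asarray(batch.kinds, dtype=int),
                             minlength=N_SPECIES).astype(int)
        for _, ch_id, *_ in log:
            ch = table.channels[int(ch_id)]
            for reactant in ch.reactants:
                counts[int(reactant)] -= 1
            for product in ch.products:
                counts[int(product)] += 1
        assert np.array_equal(counts, state.counts())
        assert np.all(counts >= 0)

    def test_well_mixed_second_order_decay(self):
        """Well-mixed self-reaction matches dN/dt = -2k N(N-1)/(2 V N_A).

        Synthetic single-channel system (OH + OH -> H2O2).  The regime
        is chosen so the oracle itself is valid: the encounter radius
        (2.4 nm) is well resolved by the fixed 3 ps step, and the
        diffusion-transient correction r/sqrt(pi D t) to the rate stays
        at the percent level over the simulated window.
        """
        k = 1.0e11
        roi = ROIGeometry(face_side_um=0.3, depth_um=0.3)
        table = ReactionTable.default(
            reactions=(((OH, OH), (H2O2,), k),))
        n0 = 400
        rng = np.random.default_rng(11)
        pos = rng.uniform(0, 300.0, (n0, 3))
        batch = InitialRadicalBatch(pos, np.full(n0, int(OH), dtype=np.int8),
                                    1000.0, 0.0)
        state = ChemicalState.empty(roi)
        t_end = 2.0e5  # decay ~ 30%
        stepper = StepperSettings(ladder_ps=(3.0,), dt_min_ps=3.0,
                                  dt_max_ps=3.0)
        hist = evolve(state, [batch], t_end, table=table, stepper=stepper,
                      rng=rng)
        k_prime = rate_constant_nm3_per_ps(k)  # nm^3 / ps per pair
        v = roi.volume_nm3

        def ode(_t, y):
            return [-k_prime * y[0] * (y[0] - 1) / v]

        sol = solve_ivp(ode, (0.0, t_end), [float(n0)], rtol=1e-8,
                        dense_output=True)
        for frac in (0.5, 1.0):
            t = frac * t_end
            idx = np.searchsorted(hist.times_ps, t, side="right") - 1
            n_sim = hist.counts[idx, int(OH)]
            n_ode = sol.sol(t)[0]
            assert n_sim == pytest.approx(n_ode, rel=0.05)

    def test_dilute_pair_smoluchowski_rate(self):
        """Isolated pair reacts at the mean-field rate k/V within 15%."""
        k = 3.0e11
        roi = ROIGeometry(face_side_um=0.1, depth_um=0.1)
        table = ReactionTable.default(reactions=(((OH, OH), (H2O2,), k),))
        k_prime = rate_constant_nm3_per_ps(k)
        v = roi.volume_nm3
        t_end = 4.0e5
        expected_survival = math.exp(-k_prime * t_end / v)
        reps = 150
        survived = 0
        for rep in range(reps):
            rng = np.random.default_rng([21, rep])
            pos = rng.uniform(0, 100.0, (2, 3))
            batch = InitialRadicalBatch(pos,
                                        np.full(2, int(OH), dtype=np.int8),
                                        10.0, 0.0)
            state = ChemicalState.empty(roi)
            evolve(state, [batch], t_end, table=table, rng=rng)
            if state.counts()[int(OH)] == 2:
                survived += 1
        p = survived / reps
        sd = math.sqrt(expected_survival * (1 - expected_survival) / reps)
        assert abs(p - expected_survival) < max(0.15 * (1 - expected_survival),
                                                3 * sd)


class TestMinimumImage:
    def test_wraps_to_nearest_copy(self):
        box = np.array([100.0, 100.0, 100.0])
        delta = np.array([[99.0, -99.0, 49.0]])
        wrapped = minimum_image(delta, box)
        assert np.allclose(wrapped, [[-1.0, 1.0, 49.0]])
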