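import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sanctum.core import (
    SimParams,
    SimState,
    TypeParams,
    birth_phase,
    bottleneck,
    calibrate_wild_kill_rate,
    death_phase,
    effective_carrying_capacity,
    migration_phase,
    run,
    seed_state,
    step,
    steps_for_days,
)
from sanctum.errors import InvalidParameterError
from sanctum.graphs import build_star, build_well_mixed
from tests.conftest import single_node


class TestScalars:
    @pytest.mark.parametrize(
        "days,t,expected", [(5, 30, 240), (1, 30, 48), (5, 60, 120)]
    )
    def test_steps_for_days(self, days, t, expected):
        assert steps_for_days(days, t) == expected

    def test_steps_for_days_rejects_nonpositive(self):
        with pytest.raises(InvalidParameterError):
            steps_for_days(0, 30)
        with pytest.raises(InvalidParameterError):
            steps_for_days(5, -1)

    @pytest.mark.parametrize(
        "Z,A,R,K,expected",
        [
            (0.0, 5.0, 1.0, 1600, 1600.0),  # no killing
            (1.0, 0.0, 1.0, 1600, 1600.0),
            (2.0, 0.5, 1.0, 1600, 0.0),  # at the eradication threshold
            (1.0, 0.25, 1.0, 1600, 1200.0),
            (1.0, 2.0, 1.0, 100, 0.0),  # beyond threshold clamps to zero
        ],
    )
    def test_effective_carrying_capacity(self, Z, A, R, K, expected):
        assert effective_carrying_capacity(Z, A, R, K) == expected

    def test_effective_carrying_capacity_rejects_bad_R(self):
        with pytest.raises(InvalidParameterError):
            effective_carrying_capacity(1.0, 0.25, 0.0, 1600)

    def test_wild_calibration_gives_requested_advantage(self):
        mutant = TypeParams(1.0, 1.0)
        A = 0.25
        Zw = calibrate_wild_kill_rate(mutant, A, advantage=0.2)
        s_mut = 1 - mutant.death_prob(A)
        s_wild = 1 - min(1.0, Zw * A)
        assert s_mut / s_wild == pytest.approx(1.2, rel=1e-12)


class TestSeeding:
    def _params(self, founders, mutants, **kw):
        return SimParams(
            wild=TypeParams(1.0, 1.5),
            mutant=TypeParams(1.0, 1.0),
            antibiotic=0.25,
            founders=founders,
            founder_mutants=mutants,
            **kw,
        )

    def test_standard_seeding(self, rng):
        g = build_star(3, 1600, 1.0, 1.0)
        state = seed_state(g, self._params(1000, 1), rng)
        assert state.counts.sum() == 1000
        assert state.total_mutant == 1
        hub = g.index("P2")
        intro = g.index("P3")
        assert state.counts[hub, 1] == 0
        assert state.counts[intro, 1] == 1

    def test_zero_founders_gives_empty_state(self, rng):
        g = build_well_mixed(4, 1600)
        state = seed_state(g, self._params(0, 0), rng)
        assert state.counts.sum() == 0

    def test_saturating_founders_fill_every_space(self, rng):
        g = build_well_mixed(4, 1600)
        state = seed_state(g, self._params(6400, 1), rng)
        assert np.array_equal(state.totals(), [1600] * 4)

    def test_overfull_founders_rejected(self, rng):
        g = build_well_mixed(4, 10)
        with pytest.raises(InvalidParameterError):
            seed_state(g, self._params(41, 0), rng)

    def test_seeding_is_uniform_over_spaces(self):
        """Unequal capacities draw founders in proportion to capacity."""
        from sanctum.graphs import EdgeSpec, MetapopGraph, NodeSpec

        g = MetapopGraph(
            [NodeSpec("P3", 300), NodeSpec("P9", 100)],
            [EdgeSpec("P3", "P9", 1.0), EdgeSpec("P9", "P3", 1.0)],
        )
        rng = np.random.default_rng(7)
        tot = np.zeros(2)
        n_rep = 400
        for _ in range(n_rep):
            tot += seed_state(g, self._params(100, 0), rng).totals()
        mean = tot / n_rep
        # hypergeometric mean 75 / 25, SE of the replicate mean ~ 0.2
        assert mean[0] == pytest.approx(75, abs=1.0)


class TestPhases:
    def test_death_identity_without_antibiotic(self, rng):
        g = single_node(100)
        p = SimParams(
            wild=TypeParams(1.0, 1.5),
            mutant=TypeParams(1.0, 1.0),
            antibiotic=0.0,
            founders=0,
            founder_mutants=0,
        )
        s = SimState(np.array([[60, 30]], dtype=np.int64))
        out = death_phase(s, p, rng)
        assert np.array_equal(out.counts, s.counts)

    def test_death_is_certain_at_threshold(self, rng):
        p = SimParams(
            wild=TypeParams(1.0, 2.0),
            mutant=TypeParams(1.0, 0.5),
            antibiotic=0.5,  # wild Z*A = 1, mutant Z*A = 0.25
            founders=0,
            founder_mutants=0,
        )
        s = SimState(np.array([[40, 40]], dtype=np.int64))
        out = death_phase(s, p, rng)
        assert out.counts[0, 0] == 0
        assert out.counts[0, 1] > 0

    def test_death_binomial_mean(self):
        """Z*A = 0.3 on 10000 agents leaves ~7000 survivors on average."""
        p = SimParams(
            wild=TypeParams(1.0, 1.0),
            mutant=TypeParams(1.0, 1.0),
            antibiotic=0.3,
            founders=0,
            founder_mutants=0,
        )
        g = single_node(20000)
        rng = np.random.default_rng(42)
        survivors = [
            death_phase(SimState(np.array([[10000, 0]]), 0), p, rng).counts[0, 0]
            for _ in range(200)
        ]
        se = np.sqrt(10000 * 0.3 * 0.7 / 200)
        assert abs(np.mean(survivors) - 7000) < 3 * se

    def test_no_births_in_full_node(self, rng):
        g = single_node(50)
        p = SimParams(
            wild=TypeParams(1.0, 0.0),
            mutant=TypeParams(1.0, 0.0),
            founders=0,
            founder_mutants=0,
        )
        s = SimState(np.array([[30, 20]], dtype=np.int64))
        out = birth_phase(s, g, p, rng)
        assert np.array_equal(out.counts, s.counts)

    def test_no_births_with_zero_birth_rate(self, rng):
        g = single_node(50)
        p = SimParams(
            wild=TypeParams(0.0, 0.0),
            mutant=TypeParams(0.0, 0.0),
            founders=0,
            founder_mutants=0,
        )
        s = SimState(np.array([[10, 10]], dtype=np.int64))
        out = birth_phase(s, g, p, rng)
        assert np.array_equal(out.counts, s.counts)

    def test_birth_respects_capacity(self, rng):
        g = single_node(20)
        p = SimParams(
            wild=TypeParams(1.0, 0.0),
            mutant=TypeParams(1.0, 0.0),
            founders=0,
            founder_mutants=0,
        )
        for _ in range(50):
            out = birth_phase(SimState(np.array([[9, 9]]), 0), g, p, rng)
            assert out.counts.sum() <= 20
            assert (out.counts >= np.array([[9, 9]])).all()

    def test_migration_off_is_identity(self, rng):
        g = build_well_mixed(3, 10)
        p = SimParams(
            wild=TypeParams(1.0, 1.0),
            mutant=TypeParams(1.0, 1.0),
            migration_prob=0.0,
            founders=0,
            founder_mutants=0,
        )
        s = SimState(np.array([[5, 1], [0, 3], [2, 2]], dtype=np.int64))
        out = migration_phase(s, g, p, rng)
        assert np.array_equal(out.counts, s.counts)

    def test_forced_migration_moves_everyone(self, rng):
        """m=1 on A->B with room in B relocates every agent."""
        from sanctum.graphs import EdgeSpec, MetapopGraph, NodeSpec

        g = MetapopGraph(
            [NodeSpec("A", 10), NodeSpec("B", 10)], [EdgeSpec("A", "B", 1.0)]
        )
        p = SimParams(
            wild=TypeParams(1.0, 1.0),
            mutant=TypeParams(1.0, 1.0),
            migration_prob=1.0,
            founders=0,
            founder_mutants=0,
        )
        s = SimState(np.array([[4, 3], [0, 0]], dtype=np.int64))
        out = migration_phase(s, g, p, rng)
        assert np.array_equal(out.counts, [[0, 0], [4, 3]])

    def test_migration_aborts_into_full_node(self, rng):
        from sanctum.graphs import EdgeSpec, MetapopGraph, NodeSpec

        g = MetapopGraph(
            [NodeSpec("A", 5), NodeSpec("B", 3)], [EdgeSpec("A", "B", 1.0)]
        )
        p = SimParams(
            wild=TypeParams(1.0, 1.0),
            mutant=TypeParams(1.0, 1.0),
            migration_prob=1.0,
            founders=0,
            founder_mutants=0,
        )
        s = SimState(np.array([[5, 0], [1, 2]], dtype=np.int64))
        out = migration_phase(s, g, p, rng)
        assert out.counts.sum() == 8  # conservation
        assert out.counts[1].sum() == 3  # B stays at capacity

    def test_hub_destination_frequencies_match_weights(self):
        """Migrants leaving the hub split per the outgoing distribution."""
        g = build_star(3, 10000, 1.0, 1.0)
        p = SimParams(
            wild=TypeParams(1.0, 1.0),
            mutant=TypeParams(1.0, 1.0),
            migration_prob=0.3,  # per-edge; hub total 0.9
            founders=0,
            founder_mutants=0,
        )
        rng = np.random.default_rng(99)
        hub = g.index("P2")
        arrivals = np.zeros(4)
        n_rep = 300
        for _ in range(n_rep):
            s = SimState(np.zeros((4, 2), dtype=np.int64))
            s.counts[hub, 0] = 1000
            out = migration_phase(s, g, p, rng)
            arrivals += out.counts[:, 0]
        arrivals /= n_rep
        # each leaf expects 1000 * 0.9 / 3 = 300 arrivals
        se = np.sqrt(1000 * 0.3 * 0.7 / n_rep)
        for i in range(4):
            if i == hub:
                continue
            assert abs(arrivals[i] - 300) < 3 * se

    def test_edge_weight_scales_migrant_flux(self):
        """Doubling the hub-bound weight doubles a leaf's emigration rate."""
        p = SimParams(
            wild=TypeParams(1.0, 1.0),
            mutant=TypeParams(1.0, 1.0),
            migration_prob=0.05,
            founders=0,
            founder_mutants=0,
        )
        rng = np.random.default_rng(5)
        fluxes = []
        for w_in in (1.0, 2.0):
            g = build_star(3, 10000, w_in, 1.0)
            leaf = g.index("P3")
            moved = 0
            for _ in range(200):
                s = SimState(np.zeros((4, 2), dtype=np.int64))
                s.counts[leaf, 0] = 1000
                out = migration_phase(s, g, p, rng)
                moved += 1000 - out.counts[leaf, 0]
            fluxes.append(moved / 200)
        assert fluxes[0] == pytest.approx(50, rel=0.1)
        assert fluxes[1] == pytest.approx(100, rel=0.1)

    @pytest.mark.parametrize("fraction,expected", [(1.0, 2000), (0.5, 1000)])
    def test_bottleneck_mean(self, fraction, expected):
        g = single_node(4000)
        rng = np.random.default_rng(21)
        vals = [
            bottleneck(SimState(np.array([[2000, 0]]), 0), fraction, rng).counts[0, 0]
            for _ in range(200)
        ]
        se = np.sqrt(max(2000 * fraction * (1 - fraction), 1e-9) / 200) + 1e-9
        assert abs(np.mean(vals) - expected) <= 3 * se + 1e-9

    def test_bottleneck_rejects_bad_fraction(self, rng):
        with pytest.raises(InvalidParameterError):
            bottleneck(SimState(np.array([[1, 0]]), 0), 0.0, rng)


class TestStepAndRun:
    def test_inert_step_is_identity(self, rng):
        g = build_well_mixed(3, 10)
        p = SimParams(
            wild=TypeParams(0.0, 0.0),
            mutant=TypeParams(0.0, 0.0),
            antibiotic=0.0,
            migration_prob=0.0,
            founders=0,
            founder_mutants=0,
        )
        s = SimState(np.array([[5, 1], [2, 2], [0, 3]], dtype=np.int64))
        out = step(s, g, p, rng)
        assert np.array_equal(out.counts, s.counts)
        assert out.step == 1

    def test_empty_state_is_absorbing(self, rng):
        g = build_well_mixed(3, 10)
        p = SimParams(
            wild=TypeParams(1.0, 1.0),
            mutant=TypeParams(1.0, 1.0),
            antibiotic=0.5,
            migration_prob=0.5,
            founders=0,
            founder_mutants=0,
        )
        s = SimState(np.zeros((3, 2), dtype=np.int64))
        out = step(s, g, p, rng)
        assert out.counts.sum() == 0

    @given(seed=st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_capacity_and_nonnegativity_invariants(self, seed):
        """Counts stay within [0, capacity] through arbitrary dynamics."""
        g = build_star(3, 12, 2.0, 1.0)
        p = SimParams(
            wild=TypeParams(0.9, 1.2),
            mutant=TypeParams(1.0, 0.8),
            antibiotic=0.4,
            migration_prob=0.3,
            n_steps=15,
            founders=30,
            founder_mutants=3,
            seed=seed,
        )
        traj = run(g, p)
        totals = traj.counts.sum(axis=2)
        assert (traj.counts >= 0).all()
        assert (totals <= 12).all()

    def test_run_is_deterministic_given_seed(self):
        g = build_star(3, 100, 1.0, 1.0)
        p = SimParams(
            wild=TypeParams(1.0, 1.5),
            mutant=TypeParams(1.0, 1.0),
            antibiotic=0.25,
            migration_prob=0.05,
            n_steps=50,
            founders=80,
            founder_mutants=2,
            seed=77,
        )
        t1, t2 = run(g, p), run(g, p)
        assert np.array_equal(t1.counts, t2.counts)

    def test_zero_step_run_is_seed_state_only(self):
        g = build_well_mixed(4, 100)
        p = SimParams(
            wild=TypeParams(1.0, 1.5),
            mutant=TypeParams(1.0, 1.0),
            n_steps=0,
            founders=50,
            founder_mutants=1,
            seed=3,
        )
        traj = run(g, p)
        assert traj.counts.shape[0] == 1
        assert traj.counts.sum() == 50

    def test_migration_conserves_total_count(self, rng):
        g = build_star(3, 15, 2.0, 1.0)
        p = SimParams(
            wild=TypeParams(1.0, 1.0),
            mutant=TypeParams(1.0, 1.0),
            migration_prob=0.3,
            founders=0,
            founder_mutants=0,
        )
        for _ in range(100):
            counts = rng.integers(0, 8, size=(4, 2))
            s = SimState(counts.astype(np.int64))
            out = migration_phase(s, g, p, rng)
            assert out.counts.sum() == counts.sum()
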