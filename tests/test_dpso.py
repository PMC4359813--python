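"""Discrete swarm mechanics: transform, velocity, decoding, optimization."""

import numpy as np
import pytest

from bloodassign import (
    Assignment,
    BloodType,
    KnapsackDay,
    Particle,
    PSOParams,
    bottom_up_assign,
    decode_dimension,
    min_import_oracle,
    optimize_day,
    sigmoid,
    step_particle,
    transform,
    update_velocity,
)

from conftest import random_instance

B = BloodType


class TestTransform:
    def test_symbol_values(self):
        a = Assignment.from_symbols("O", {B.O_POS: 1})
        assert transform(a)[0] == pytest.approx(2 / 27)
        c = Assignment.from_symbols("C", {B.C_POS: 1})
        assert transform(c)[0] == pytest.approx(8 / 27)

    def test_value_collisions(self):
        # A-, B- and O+ share the value 2/27, so the numeric view cannot be
        # inverted back to symbols
        vals = {
            s: transform(Assignment.from_symbols(s, {B.C_POS: 1}))[0]
            for s in ("a", "b", "O")
        }
        assert len(set(vals.values())) == 1

    def test_worked_string(self):
        a = Assignment.from_symbols("OOOo", {B.O_POS: 4})
        np.testing.assert_allclose(transform(a), [2 / 27] * 3 + [1 / 27])


class TestVelocity:
    def test_stagnation_fixed_point(self):
        x = np.array([0.1, 0.2])
        v = update_velocity(np.zeros(2), x, x, x, PSOParams(), 0.5, 0.5)
        np.testing.assert_array_equal(v, 0.0)

    def test_pure_inertia(self):
        p = PSOParams(omega=1.0, c1=1e-12, c2=1e-12)
        v = update_velocity(np.array([0.5]), np.zeros(1), np.zeros(1), np.zeros(1), p, 0.0, 0.0)
        assert v[0] == pytest.approx(0.5)

    def test_worked_arithmetic(self):
        # v' = 0.715*1 + 1.7*0.5*0.08 + 1.7*0.5*0.23 = 0.9785
        p = PSOParams(omega=0.715, c1=1.7, c2=1.7)
        x = np.array([0.0])
        v = update_velocity(np.array([1.0]), x, x + 0.08, x + 0.23, p, 0.5, 0.5)
        assert v[0] == pytest.approx(0.715 + 0.85 * 0.08 + 0.85 * 0.23)
        assert v[0] == pytest.approx(0.9785)

    def test_geometric_decay_at_consensus(self):
        # with pbest = gbest = x both attraction terms vanish and the
        # velocity decays as omega^t
        p = PSOParams(omega=0.715)
        x = np.full(3, 0.15)
        v = np.array([1.0, -2.0, 0.5])
        for step in range(1, 20):
            v = update_velocity(v, x, x, x, p, 0.9, 0.1)
            np.testing.assert_allclose(v, np.array([1.0, -2.0, 0.5]) * 0.715**step)
        assert np.abs(v).max() < 1e-2


class TestSigmoid:
    def test_values_and_limits(self):
        assert sigmoid(0.0) == 0.5
        assert sigmoid(1.0) == pytest.approx(0.7311, abs=1e-4)
        assert sigmoid(50.0) == pytest.approx(1.0)
        assert sigmoid(-50.0) == pytest.approx(0.0)

    def test_monotone(self):
        v = np.linspace(-5, 5, 101)
        assert (np.diff(sigmoid(v)) > 0).all()


class TestDecodeDimension:
    def test_two_donor_partition(self):
        assert decode_dimension(0.3, B.O_POS) is B.O_POS  # 0.3 < 0.5
        assert decode_dimension(0.6, B.O_POS) is B.O_NEG

    def test_four_donor_partition(self):
        # A+ donors in preference order: A+, O+, A-, O-; 0.80 lands in the
        # fourth quarter
        assert decode_dimension(0.80, B.A_POS) is B.O_NEG
        assert decode_dimension(0.10, B.A_POS) is B.A_POS

    def test_single_donor_receiver(self):
        for s in (0.0, 0.4, 1.0):
            assert decode_dimension(s, B.O_NEG) is B.O_NEG

    def test_boundary_one_maps_to_last(self):
        assert decode_dimension(1.0, B.A_POS) is B.O_NEG

    def test_equal_chances(self, rng):
        draws = [decode_dimension(float(u), B.C_POS) for u in rng.random(8000)]
        counts = np.array([draws.count(t) for t in BloodType])
        np.testing.assert_allclose(counts / 8000, 1 / 8, atol=0.02)


def make_particle(requests, stock, velocity_fill=0.0):
    a, _ = bottom_up_assign(requests, stock)
    return Particle(a, np.full(len(a), velocity_fill), a, 10**9)


class TestStepParticle:
    def test_strongly_negative_velocity_freezes_position(self, rng):
        requests, stock = {B.A_POS: 5, B.O_POS: 3}, {B.A_POS: 2, B.O_POS: 9}
        p = make_particle(requests, stock, velocity_fill=-80.0)
        before = p.position.symbols
        step_particle(p, p.position, KnapsackDay(requests, stock), PSOParams(), rng)
        # omega*(-80) is still hugely negative, S ~ 0, so no dimension flips
        assert p.position.symbols == before

    def test_strongly_positive_velocity_resamples_every_dimension(self, rng):
        requests, stock = {B.C_POS: 40}, {B.C_POS: 40}
        p = make_particle(requests, stock, velocity_fill=80.0)
        step_particle(p, p.position, KnapsackDay(requests, stock), PSOParams(), rng)
        # with all 8 donors equally likely, keeping all 40 'C' symbols has
        # probability 8^-40; validity must still hold
        assert p.position.symbols != "C" * 40
        assert p.position.is_valid()

    def test_pbest_fitness_non_increasing(self, rng):
        requests, stock = random_instance(rng)
        day = KnapsackDay(requests, stock)
        a, _ = bottom_up_assign(requests, stock)
        from bloodassign import fitness

        p = Particle(a, np.zeros(len(a)), a, fitness(a, stock))
        history = [p.pbest_fitness]
        for _ in range(30):
            step_particle(p, p.pbest, day, PSOParams(), rng)
            history.append(p.pbest_fitness)
        assert all(b <= a for a, b in zip(history, history[1:]))


class TestOptimizeDay:
    def test_zero_demand(self):
        res = optimize_day(KnapsackDay({}, {B.A_POS: 4}), PSOParams(), np.random.default_rng(0))
        assert res.fitness == 0 and len(res.assignment) == 0

    def test_exact_stock_cover_is_optimal_at_initialization(self):
        requests = {B.A_POS: 3, B.O_NEG: 2}
        res = optimize_day(
            KnapsackDay(requests, dict(requests)), PSOParams(), np.random.default_rng(0)
        )
        assert res.fitness == 0 and res.iterations == 0

    def test_reaches_oracle_on_small_instances(self):
        hits = 0
        for i in range(20):
            rng = np.random.default_rng(500 + i)
            requests, stock = random_instance(rng, max_units=20, max_stock=20)
            res = optimize_day(KnapsackDay(requests, stock), PSOParams(), rng)
            hits += res.fitness == min_import_oracle(requests, stock)
        assert hits == 20

    def test_gbest_trace_monotone_and_bounded_below(self, rng):
        requests, stock = random_instance(rng)
        res = optimize_day(KnapsackDay(requests, stock), PSOParams(max_iters=50), rng)
        assert all(b <= a for a, b in zip(res.trace, res.trace[1:]))
        assert res.trace[-1] >= res.lower_bound

    def test_fixed_seed_gives_identical_trajectory(self):
        requests = {B.O_POS: 6, B.A_POS: 4, B.O_NEG: 2}
        stock = {B.O_POS: 3, B.A_NEG: 5}
        day = KnapsackDay(requests, stock)
        r1 = optimize_day(day, PSOParams(max_iters=40), np.random.default_rng(11))
        r2 = optimize_day(day, PSOParams(max_iters=40), np.random.default_rng(11))
        assert r1.trace == r2.trace
        assert r1.assignment == r2.assignment

    def test_plan_satisfies_demand_exactly(self, rng):
        for _ in range(10):
            requests, stock = random_instance(rng)
            res = optimize_day(KnapsackDay(requests, stock), PSOParams(max_iters=30), rng)
            assert res.plan.total == sum(requests.values())
            for t, n in res.plan.supplied.items():
                assert n <= stock.get(t, 0)


class TestParams:
    def test_defaults(self):
        p = PSOParams()
        assert (p.omega, p.c1, p.c2) == (0.715, 1.7, 1.7)
        assert (p.swarm_size, p.max_iters) == (50, 1000)

    @pytest.mark.parametrize(
        "kw", [{"omega": 0}, {"c1": -1}, {"swarm_size": 1}, {"max_iters": 0}]
    )
    def test_validation(self, kw):
        with pytest.raises(ValueError):
            PSOParams(**kw)
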