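"""Discrete particle swarm optimizer over assignment strings.

Particles are the grouped symbol strings of :mod:`bloodassign.assignment`.
For velocity arithmetic each symbol is mapped to its numeric type value
(receivable-donor count / 27); velocities follow the standard update
v' = ω v + c1 r1 (pbest − x) + c2 r2 (gbest − x) with no clamping.  The
sigmoid S(v') = 1/(1+e^{−v'}) gates, per dimension, whether the symbol is
resampled (when a uniform μ ≤ S(v')); a resampled dimension picks uniformly
among the compatible donor types of its knapsack's receiver, all donors
getting equal probability.  Fitness is the import count, minimized; the
swarm stops early once the global best reaches the exact max-flow lower
bound, which cannot change the result because fitness is integral and
bounded below by it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .blood_types import (
    COMPAT_MATRIX,
    DONOR_COUNT,
    DONOR_ORDER_MATRIX,
    TYPE_ORDER,
    VALUE_ARRAY,
    BloodType,
)
from .assignment import (
    Assignment,
    KnapsackDay,
    SupplyPlan,
    bottom_up_assign,
    min_import_oracle,
    plan_from_assignment,
)

__all__ = [
    "PSOParams",
    "Particle",
    "OptimizationResult",
    "transform",
    "sigmoid",
    "decode_dimension",
    "update_velocity",
    "step_particle",
    "optimize_day",
]


@dataclass(frozen=True)
class PSOParams:
    """Swarm hyper-parameters.

    Defaults follow the constriction-style setting ω = 0.715 with
    c1 = c2 = 1.7, a swarm of 50 particles and at most 1000 iterations.
    ``per_dimension_r`` switches r1, r2 from one scalar pair per particle
    per iteration (the default) to independent draws per dimension.
    """

    omega: float = 0.715
    c1: float = 1.7
    c2: float = 1.7
    swarm_size: int = 50
    max_iters: int = 1000
    per_dimension_r: bool = False

    def __post_init__(self):
        if self.omega <= 0 or self.c1 <= 0 or self.c2 <= 0:
            raise ValueError("omega, c1 and c2 must be positive")
        if self.swarm_size < 2:
            raise ValueError("swarm_size must be at least 2")
        if self.max_iters < 1:
            raise ValueError("max_iters must be at least 1")


@dataclass
class Particle:
    """A swarm member: current string, velocity, and personal best."""

    position: Assignment
    velocity: np.ndarray
    pbest: Assignment
    pbest_fitness: int

    def __post_init__(self):
        if len(self.velocity) != len(self.position):
            raise ValueError("velocity and position dimensions differ")


def transform(a: Assignment) -> np.ndarray:
    """Numeric view of an assignment: each symbol replaced by its type value.

    Values are the exact receivable-count/27 rationals cast to double
    (O+ → 2/27 ≈ 0.07, C+ → 8/27 ≈ 0.30, ...); several types share a value,
    so the map is not invertible back to symbols.
    """
    return VALUE_ARRAY[a.codes]


def sigmoid(v):
    """Logistic squashing of a velocity into (0, 1)."""
    return 1.0 / (1.0 + np.exp(-np.asarray(v, dtype=float)))


def decode_dimension(s: float, receiver: BloodType) -> BloodType:
    """Map s ∈ [0,1] to one of the receiver's compatible donor types.

    [0,1] is split into k equal half-open intervals over the ordered
    compatible-donor list (k = number of compatible donors), so each donor
    type gets an equal chance; s = 1 maps to the last (O−) interval.
    """
    if not 0.0 <= s <= 1.0:
        raise ValueError("s must lie in [0, 1]")
    rcode = list(TYPE_ORDER).index(receiver)
    k = int(DONOR_COUNT[rcode])
    idx = min(int(s * k), k - 1)
    return TYPE_ORDER[DONOR_ORDER_MATRIX[rcode, idx]]


def update_velocity(
    velocity: np.ndarray,
    position_values: np.ndarray,
    pbest_values: np.ndarray,
    gbest_values: np.ndarray,
    params: PSOParams,
    r1: float,
    r2: float,
) -> np.ndarray:
    """One velocity step: v' = ω v + c1 r1 (pbest − x) + c2 r2 (gbest − x)."""
    return (
        params.omega * velocity
        + params.c1 * r1 * (pbest_values - position_values)
        + params.c2 * r2 * (gbest_values - position_values)
    )


def _random_valid_codes(
    receivers: np.ndarray, shape: Tuple[int, ...], rng: np.random.Generator
) -> np.ndarray:
    """Uniform compatible donor code for each dimension (equal chances)."""
    k = DONOR_COUNT[receivers]
    idx = np.minimum((rng.random(shape) * k).astype(np.int64), k - 1)
    return DONOR_ORDER_MATRIX[receivers, idx]


def step_particle(
    p: Particle,
    gbest: Assignment,
    day: KnapsackDay,
    params: PSOParams,
    rng: np.random.Generator,
) -> Particle:
    """Advance one particle by one iteration (in place; also returned).

    Draw order: r1, r2 (scalars, or per-dimension vectors when configured),
    then one μ per dimension (the resampling gate), then one uniform per
    dimension driving the donor choice of resampled dimensions.  The new
    string is repaired and the personal best updated on strict improvement.
    """
    dim = len(p.position)
    shape = dim if params.per_dimension_r else None
    r1 = rng.random(shape)
    r2 = rng.random(shape)
    v = update_velocity(
        p.velocity, transform(p.position), transform(p.pbest), transform(gbest),
        params, r1, r2,
    )
    sv = sigmoid(v)
    mu = rng.random(dim)
    u2 = rng.random(dim)
    receivers = p.position.receivers
    resample = mu <= sv
    fresh = _random_valid_codes(receivers, (dim,), rng)
    codes = np.where(resample, fresh, p.position.codes)
    # donor choices are drawn from the compatible list, so repair is a no-op
    # here; kept as a guard for the invariant.
    codes = np.where(COMPAT_MATRIX[receivers, codes], codes, receivers)
    p.position = Assignment(codes, p.position.demands)
    p.velocity = v
    f = _fitness_codes(codes[None, :], day.stock_vector)[0]
    if f < p.pbest_fitness:
        p.pbest = p.position
        p.pbest_fitness = int(f)
    return p


def _fitness_codes(positions: np.ndarray, stock_vec: np.ndarray) -> np.ndarray:
    """Import counts for a (n_particles, dim) matrix of type codes."""
    n, dim = positions.shape
    if dim == 0:
        return np.zeros(n, dtype=np.int64)
    offsets = 8 * np.arange(n, dtype=np.int64)[:, None]
    counts = np.bincount(
        (positions.astype(np.int64) + offsets).ravel(), minlength=8 * n
    ).reshape(n, 8)
    return np.clip(counts - stock_vec, 0, None).sum(axis=1)


@dataclass(frozen=True)
class OptimizationResult:
    """Outcome of one day's swarm run."""

    assignment: Assignment
    plan: SupplyPlan
    fitness: int
    lower_bound: int
    trace: List[int]
    iterations: int

    def as_tuple(self) -> Tuple[Assignment, SupplyPlan]:
        return self.assignment, self.plan


def optimize_day(
    day: KnapsackDay,
    params: Optional[PSOParams] = None,
    rng: Optional[np.random.Generator] = None,
) -> OptimizationResult:
    """Minimize the day's imports with the discrete swarm.

    One particle is seeded with the bottom-up greedy solution; the rest
    start as uniform random compatibility-valid strings with zero velocity.
    Iterates until ``max_iters`` or until the global best hits the exact
    max-flow lower bound.  The global best is decoded into a supply plan by
    capping each type's use at its stock and importing the residual as the
    placed type.
    """
    params = params or PSOParams()
    rng = rng or np.random.default_rng()
    demands = day.demand_vector
    stock_vec = day.stock_vector
    dim = int(demands.sum())

    seed_assignment, _ = bottom_up_assign(day.requests, day.stock)
    bound = min_import_oracle(day.requests, day.stock)
    seed_fitness = _fitness_codes(seed_assignment.codes[None, :], stock_vec)[0]

    if dim == 0 or seed_fitness <= bound:
        # the greedy seed already attains the flow bound (always true for
        # dim == 0); it would be the first-found global best regardless.
        plan = plan_from_assignment(seed_assignment, day.stock)
        return OptimizationResult(
            seed_assignment, plan, int(seed_fitness), bound, [int(seed_fitness)], 0
        )

    n = params.swarm_size
    receivers = seed_assignment.receivers
    positions = np.empty((n, dim), dtype=np.int8)
    positions[0] = seed_assignment.codes
    positions[1:] = _random_valid_codes(receivers, (n - 1, dim), rng)
    velocities = np.zeros((n, dim))
    pbest = positions.copy()
    pbest_f = _fitness_codes(positions, stock_vec)
    gi = int(np.argmin(pbest_f))  # first-found tie-break
    gbest = pbest[gi].copy()
    gbest_f = int(pbest_f[gi])
    trace = [gbest_f]

    iterations = 0
    for _ in range(params.max_iters):
        if gbest_f <= bound:
            break
        iterations += 1
        rshape = (n, dim) if params.per_dimension_r else (n, 1)
        r1 = rng.random(rshape)
        r2 = rng.random(rshape)
        x_val = VALUE_ARRAY[positions]
        velocities = (
            params.omega * velocities
            + params.c1 * r1 * (VALUE_ARRAY[pbest] - x_val)
            + params.c2 * r2 * (VALUE_ARRAY[gbest][None, :] - x_val)
        )
        sv = sigmoid(velocities)
        mu = rng.random((n, dim))
        fresh = _random_valid_codes(receivers, (n, dim), rng)
        positions = np.where(mu <= sv, fresh, positions)
        f = _fitness_codes(positions, stock_vec)
        improved = f < pbest_f
        pbest[improved] = positions[improved]
        pbest_f[improved] = f[improved]
        bi = int(np.argmin(pbest_f))
        if pbest_f[bi] < gbest_f:
            gbest = pbest[bi].copy()
            gbest_f = int(pbest_f[bi])
        trace.append(gbest_f)

    best = Assignment(gbest, demands)
    plan = plan_from_assignment(best, day.stock)
    return OptimizationResult(best, plan, gbest_f, bound, trace, iterations)
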