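"""Multi-objective binary particle swarm search for small reducts.

Each particle carries a binary position (a candidate gene subset), a real
velocity, and a personal best.  Velocities follow the canonical inertia +
cognitive + social update

    v <- w*v + c1*r1*(pbest - x) + c2*r2*(gbest - x),   r1, r2 ~ U[0, 1],

clamped to [v_min, v_max]; each position bit is then resampled as a
Bernoulli draw with probability sigmoid(v_i).  The swarm is ranked by
Pareto non-dominated sorting on (Fit1, Fit2); the guide gbest is drawn
uniformly from the current rank-1 set, and after each generation the best
half of the combined parent + offspring population survives (elitist 50 %
selection).  Every rank-1 point ever evaluated is kept in an external
archive pruned to mutual non-domination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distinction import DistinctionTable
from .exceptions import ParameterError, SizeGuardError
from .objectives import ObjectivePair, evaluate_pair

__all__ = [
    "Particle",
    "MOBPSOConfig",
    "ArchiveMember",
    "ParetoArchive",
    "GenerationStats",
    "dominates",
    "non_dominated_sort",
    "initialize_swarm",
    "update_velocity",
    "update_position",
    "update_pbest",
    "select_gbest",
    "environmental_selection",
    "run_mobpso",
    "exhaustive_pareto",
]


# -- data types ----------------------------------------------------------


@dataclass
class Particle:
    position: np.ndarray  # uint8 bits, length N
    velocity: np.ndarray  # float, length N
    pbest_position: np.ndarray
    pbest_objectives: ObjectivePair | None = None
    current_objectives: ObjectivePair | None = None


@dataclass
class MOBPSOConfig:
    """Swarm parameters.

    Defaults: 20 particles, 50 generations, inertia w = 0.9, acceleration
    c1 = c2 = 2 and velocities clamped to [-4, 4]; ``alpha`` only matters
    for the weighted-sum scalarisation helper.
    """

    swarm_size: int = 20
    generations: int = 50
    inertia: float = 0.9
    c1: float = 2.0
    c2: float = 2.0
    v_min: float = -4.0
    v_max: float = 4.0
    seed: int = 0
    alpha: float = 0.5

    def validate(self) -> None:
        problems = []
        if self.swarm_size < 2 or self.swarm_size % 2:
            problems.append(f"swarm_size must be an even integer >= 2, got {self.swarm_size}")
        if self.generations < 1:
            problems.append(f"generations must be >= 1, got {self.generations}")
        if not self.v_min < self.v_max:
            problems.append(f"v_min must be < v_max, got [{self.v_min}, {self.v_max}]")
        if not 0.0 < self.alpha < 1.0:
            problems.append(f"alpha must lie in (0, 1), got {self.alpha}")
        if problems:
            raise ParameterError("; ".join(problems))


@dataclass
class ArchiveMember:
    position: tuple[int, ...]
    objectives: ObjectivePair
    generation: int


class ParetoArchive:
    """Mutually non-dominated (position, objectives) records with provenance."""

    def __init__(self) -> None:
        self.members: list[ArchiveMember] = []
        self._positions: set[tuple[int, ...]] = set()

    def __len__(self) -> int:
        return len(self.members)

    def add(self, position, objectives: ObjectivePair, generation: int = 0) -> bool:
        """Insert if not dominated; evict members the newcomer dominates.

        Duplicate positions are ignored.  Returns True when inserted.
        """
        pos = tuple(int(b) for b in np.asarray(position).astype(int))
        if pos in self._positions:
            return False
        for m in self.members:
            if dominates(m.objectives, objectives):
                return False
        kept = [m for m in self.members if not dominates(objectives, m.objectives)]
        if len(kept) != len(self.members):
            self.members = kept
            self._positions = {m.position for m in kept}
        self.members.append(ArchiveMember(pos, objectives, generation))
        self._positions.add(pos)
        return True

    def objective_pairs(self) -> set[tuple[float, float]]:
        """The distinct objective pairs on the front, rounded to 12 decimals."""
        return {
            (round(m.objectives.fit1, 12), round(m.objectives.fit2, 12))
            for m in self.members
        }

    def positions(self) -> list[tuple[int, ...]]:
        return [m.position for m in self.members]

    def reducts(self) -> list[ArchiveMember]:
        """Members with full discerning power (Fit2 == 1)."""
        return [m for m in self.members if m.objectives.fit2 == 1.0]

    def hypervolume(self) -> float:
        """Dominated area w.r.t. the reference point (0, 0) (both maximised)."""
        pts = sorted(self.objective_pairs(), key=lambda p: (-p[0], p[1]))
        area = 0.0
        prev_f2 = 0.0
        for f1, f2 in pts:
            if f2 > prev_f2:
                area += f1 * (f2 - prev_f2)
                prev_f2 = f2
        return area


@dataclass
class GenerationStats:
    generation: int
    population_size: int
    n_rank1: int
    max_abs_velocity: float
    archive_size: int
    best_fit2: float
    min_cardinality_at_full_coverage: int | None


# -- dominance -----------------------------------------------------------


def dominates(a: ObjectivePair, b: ObjectivePair) -> bool:
    """True when a is at least as good as b on both objectives, better on one."""
    return (
        a.fit1 >= b.fit1
        and a.fit2 >= b.fit2
        and (a.fit1 > b.fit1 or a.fit2 > b.fit2)
    )


def non_dominated_sort(objectives) -> np.ndarray:
    """Rank a population by repeated Pareto peeling (rank 1 = non-dominated).

    Vectorised domination-count formulation of the classic fast
    non-dominated sort; ranks start at 1.
    """
    f1 = np.array([o.fit1 for o in objectives], dtype=float)
    f2 = np.array([o.fit2 for o in objectives], dtype=float)
    n = f1.size
    if n == 0:
        raise ParameterError("cannot rank an empty population")
    ge = (f1[:, None] >= f1[None, :]) & (f2[:, None] >= f2[None, :])
    strict = (f1[:, None] > f1[None, :]) | (f2[:, None] > f2[None, :])
    dom = ge & strict  # dom[i, j]: i dominates j
    n_dominators = dom.sum(axis=0)
    ranks = np.zeros(n, dtype=int)
    rank = 1
    remaining = np.ones(n, dtype=bool)
    while remaining.any():
        front = remaining & (n_dominators == 0)
        if not front.any():  # numerical safety; cannot happen for finite input
            front = remaining
        ranks[front] = rank
        remaining &= ~front
        n_dominators = n_dominators - dom[front].sum(axis=0)
        rank += 1
    return ranks


# -- swarm mechanics -----------------------------------------------------


def initialize_swarm(n_features: int, config: MOBPSOConfig, rng) -> list[Particle]:
    """P particles with Bernoulli(0.5) bits and velocities uniform in [-1, 1]."""
    if n_features < 1:
        raise ParameterError("need at least one feature")
    particles = []
    for _ in range(config.swarm_size):
        position = rng.integers(0, 2, size=n_features, dtype=np.uint8)
        velocity = rng.uniform(-1.0, 1.0, size=n_features)
        particles.append(
            Particle(
                position=position,
                velocity=velocity,
                pbest_position=position.copy(),
            )
        )
    return particles


def update_velocity(particle: Particle, gbest, config: MOBPSOConfig, rng) -> np.ndarray:
    """Inertia + cognitive + social velocity update, clamped to [v_min, v_max]."""
    gbest = np.asarray(gbest, dtype=float)
    x = particle.position.astype(float)
    if gbest.shape != x.shape:
        raise ParameterError("gbest length does not match particle dimension")
    r1 = rng.random(x.size)
    r2 = rng.random(x.size)
    v = (
        config.inertia * particle.velocity
        + config.c1 * r1 * (particle.pbest_position.astype(float) - x)
        + config.c2 * r2 * (gbest - x)
    )
    return np.clip(v, config.v_min, config.v_max)


def _sigmoid(v: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-v))


def update_position(velocity, rng) -> np.ndarray:
    """Sample each bit independently: P(bit = 1) = sigmoid(velocity)."""
    velocity = np.asarray(velocity, dtype=float)
    return (rng.random(velocity.size) < _sigmoid(velocity)).astype(np.uint8)


def update_pbest(particle: Particle, rng) -> Particle:
    """Replace pbest if dominated by the current point; coin-flip on ties.

    Incomparable current/pbest pairs are resolved by a seeded fair coin, a
    standard convention for multi-objective personal bests.
    """
    cur, pb = particle.current_objectives, particle.pbest_objectives
    if cur is None:
        raise ParameterError("particle has not been evaluated")
    replace = (
        pb is None
        or dominates(cur, pb)
        or (not dominates(pb, cur) and rng.random() < 0.5)
    )
    if replace:
        particle.pbest_position = particle.position.copy()
        particle.pbest_objectives = cur
    return particle


def select_gbest(particles, ranks, rng) -> np.ndarray:
    """Uniform random choice among rank-1 positions (all equal priority)."""
    if len(particles) == 0:
        raise ParameterError("cannot select gbest from an empty population")
    idx = np.flatnonzero(np.asarray(ranks) == 1)
    choice = idx[rng.integers(0, idx.size)]
    return particles[choice].position.copy()


def environmental_selection(parents, offspring, p: int) -> list[Particle]:
    """Keep the best ``p`` of parents + offspring by rank (elitist 50 %).

    Within the boundary rank, order by descending Fit2, then descending
    Fit1, then first-seen order (parents before offspring).
    """
    combined = list(parents) + list(offspring)
    ranks = non_dominated_sort([q.current_objectives for q in combined])
    order = sorted(
        range(len(combined)),
        key=lambda i: (
            ranks[i],
            -combined[i].current_objectives.fit2,
            -combined[i].current_objectives.fit1,
            i,
        ),
    )
    return [combined[i] for i in order[:p]]


# -- main loop -----------------------------------------------------------


def run_mobpso(
    table: DistinctionTable,
    config: MOBPSOConfig | None = None,
    return_history: bool = False,
):
    """Run the full swarm search and return the Pareto archive.

    Per generation: evaluate, update personal bests, pick gbest from the
    rank-1 set, move every particle (velocity then sigmoid position
    resampling) to form offspring, then keep the best half of the combined
    population.  Fully reproducible from ``config.seed``.
    """
    config = config or MOBPSOConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = table.n_features

    swarm = initialize_swarm(n, config, rng)
    for q in swarm:
        q.current_objectives = evaluate_pair(q.position, table)
        q.pbest_objectives = q.current_objectives
    archive = ParetoArchive()
    for q in swarm:
        archive.add(q.position, q.current_objectives, 0)

    history: list[GenerationStats] = []
    for gen in range(1, config.generations + 1):
        for q in swarm:
            update_pbest(q, rng)
        ranks = non_dominated_sort([q.current_objectives for q in swarm])
        gbest = select_gbest(swarm, ranks, rng)

        offspring = []
        for q in swarm:
            velocity = update_velocity(q, gbest, config, rng)
            position = update_position(velocity, rng)
            child = Particle(
                position=position,
                velocity=velocity,
                pbest_position=q.pbest_position.copy(),
                pbest_objectives=q.pbest_objectives,
            )
            child.current_objectives = evaluate_pair(position, table)
            archive.add(position, child.current_objectives, gen)
            offspring.append(child)

        swarm = environmental_selection(swarm, offspring, config.swarm_size)

        if return_history:
            new_ranks = non_dominated_sort([q.current_objectives for q in swarm])
            full = [
                int(np.sum(q.position))
                for q in swarm
                if q.current_objectives.fit2 == 1.0
            ]
            history.append(
                GenerationStats(
                    generation=gen,
                    population_size=len(swarm),
                    n_rank1=int((new_ranks == 1).sum()),
                    max_abs_velocity=float(
                        max(np.abs(q.velocity).max() for q in swarm)
                    ),
                    archive_size=len(archive),
                    best_fit2=max(q.current_objectives.fit2 for q in swarm),
                    min_cardinality_at_full_coverage=min(full) if full else None,
                )
            )

    if return_history:
        return archive, history
    return archive


# -- exhaustive oracle ---------------------------------------------------


def exhaustive_pareto(table: DistinctionTable) -> ParetoArchive:
    """Exact Pareto front by enumerating all 2^N subsets (guarded, N <= 20).

    Serves as an independent optimality oracle for small instances: for each
    cardinality the best-covering subset is found, and the front keeps the
    cardinalities whose best coverage strictly improves on all smaller ones.
    """
    n = table.n_features
    if n > 20:
        raise SizeGuardError(f"exhaustive enumeration is limited to N <= 20, got {n}")
    subsets = np.arange(1 << n, dtype=np.int64)
    covered = np.zeros(subsets.size, dtype=np.int64)
    for row in table.bits:
        mask = np.int64(sum(1 << i for i in np.flatnonzero(row)))
        covered += (subsets & mask) != 0
    cards = np.bitwise_count(subsets.astype(np.uint64)).astype(np.int64)

    archive = ParetoArchive()
    best_so_far = -1
    for c in range(n + 1):
        at_c = np.flatnonzero(cards == c)
        best = at_c[np.argmax(covered[at_c])]
        r_best = int(covered[best])
        if r_best > best_so_far:
            best_so_far = r_best
            bits = (best >> np.arange(n)) & 1
            archive.add(
                bits.astype(np.uint8),
                ObjectivePair((n - c) / n, r_best / table.n_rows),
                0,
            )
        if r_best == table.n_rows:
            break
    return archive
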