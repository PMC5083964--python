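"""Swarm mechanics: dominance, ranking, updates, selection and the main loop."""

import numpy as np
import pytest

from swarmselect import (
    MOBPSOConfig,
    ObjectivePair,
    dominates,
    exhaustive_pareto,
    non_dominated_sort,
    run_mobpso,
)
from swarmselect.distinction import DistinctionTable
from swarmselect.exceptions import ParameterError, SizeGuardError
from swarmselect.mobpso import (
    Particle,
    environmental_selection,
    initialize_swarm,
    select_gbest,
    update_pbest,
    update_position,
    update_velocity,
)
from swarmselect.objectives import evaluate_pair

from conftest import peeling_ranks, random_distinction_table


class ForcedRng:
    """Stub rng returning fixed values, for deterministic update tests."""

    def __init__(self, uniform_value=1.0, coin=0.0):
        self.uniform_value = uniform_value
        self.coin = coin

    def random(self, size=None):
        if size is None:
            return self.coin
        return np.full(size, self.uniform_value)


class TestDominance:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((0.5, 0.5), (0.2, 0.2), True),
            ((1.0, 0.0), (0.0, 1.0), False),
            ((0.5, 0.5), (0.5, 0.5), False),
            ((0.5, 0.2), (0.5, 0.1), True),
        ],
    )
    def test_pairwise(self, a, b, expected):
        assert dominates(ObjectivePair(*a), ObjectivePair(*b)) is expected

    def test_mutually_incomparable_set_is_all_rank_one(self):
        pairs = [ObjectivePair(1, 0), ObjectivePair(0, 1), ObjectivePair(0.5, 0.5)]
        assert list(non_dominated_sort(pairs)) == [1, 1, 1]

    def test_simple_two_ranks(self):
        pairs = [ObjectivePair(0.5, 0.5), ObjectivePair(0.2, 0.2)]
        assert list(non_dominated_sort(pairs)) == [1, 2]

    def test_matches_peeling_oracle_on_random_populations(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            pairs = [
                ObjectivePair(*np.round(rng.random(2), 2)) for _ in range(30)
            ]
            assert list(non_dominated_sort(pairs)) == peeling_ranks(pairs)


class TestSwarmMechanics:
    def test_initialization_reproducible_and_balanced(self):
        cfg = MOBPSOConfig(swarm_size=4)
        a = initialize_swarm(10, cfg, np.random.default_rng(5))
        b = initialize_swarm(10, cfg, np.random.default_rng(5))
        for p, q in zip(a, b):
            assert np.array_equal(p.position, q.position)
            assert np.array_equal(p.velocity, q.velocity)
        c = initialize_swarm(10, cfg, np.random.default_rng(6))
        assert any(
            not np.array_equal(p.position, q.position) for p, q in zip(a, c)
        )
        # pooled initial bits are Bernoulli(0.5): 3-sigma binomial band
        big = initialize_swarm(500, MOBPSOConfig(swarm_size=20), np.random.default_rng(7))
        frac = np.mean([p.position.mean() for p in big])
        assert 0.47 < frac < 0.53
        assert all(
            p.velocity.min() >= -1 and p.velocity.max() <= 1 for p in big
        )

    def test_velocity_fixed_point_and_clamp(self):
        cfg = MOBPSOConfig()
        x = np.array([1, 0, 1], dtype=np.uint8)
        p = Particle(x, np.zeros(3), x.copy())
        v = update_velocity(p, x, cfg, ForcedRng())
        assert np.allclose(v, 0.0)
        p2 = Particle(x, np.array([5.0, -5.0, 0.0]), x.copy())
        v2 = update_velocity(p2, x, cfg, ForcedRng())
        assert v2[0] == 4.0 and v2[1] == -4.0

    def test_velocity_hand_evaluation(self):
        # x=0, pbest=gbest=1, v=0, r1=r2=1, c1=c2=2 -> raw v=4 -> clamped 4
        cfg = MOBPSOConfig()
        p = Particle(
            np.zeros(4, dtype=np.uint8), np.zeros(4), np.ones(4, dtype=np.uint8)
        )
        v = update_velocity(p, np.ones(4), cfg, ForcedRng(uniform_value=1.0))
        assert np.allclose(v, 4.0)

    def test_position_sampling_follows_sigmoid(self):
        rng = np.random.default_rng(13)
        draws = np.array([update_position(np.zeros(100), rng) for _ in range(100)])
        assert 0.47 < draws.mean() < 0.53
        high = np.array([update_position(np.full(100, 4.0), rng) for _ in range(100)])
        assert high.mean() == pytest.approx(1 / (1 + np.exp(-4)), abs=0.01)
        low = np.array([update_position(np.full(100, -4.0), rng) for _ in range(100)])
        assert low.mean() == pytest.approx(1 / (1 + np.exp(4)), abs=0.01)

    def test_pbest_rules(self):
        def particle(cur, pb):
            p = Particle(
                np.array([1, 1], dtype=np.uint8),
                np.zeros(2),
                np.array([0, 0], dtype=np.uint8),
            )
            p.current_objectives = ObjectivePair(*cur)
            p.pbest_objectives = ObjectivePair(*pb)
            return p

        p = update_pbest(particle((0.5, 0.5), (0.2, 0.2)), ForcedRng(coin=0.9))
        assert p.pbest_objectives == ObjectivePair(0.5, 0.5)
        p = update_pbest(particle((0.2, 0.2), (0.5, 0.5)), ForcedRng(coin=0.0))
        assert p.pbest_objectives == ObjectivePair(0.5, 0.5)
        # incomparable: forced heads replaces, forced tails keeps
        p = update_pbest(particle((1.0, 0.0), (0.0, 1.0)), ForcedRng(coin=0.0))
        assert p.pbest_objectives == ObjectivePair(1.0, 0.0)
        p = update_pbest(particle((1.0, 0.0), (0.0, 1.0)), ForcedRng(coin=0.9))
        assert p.pbest_objectives == ObjectivePair(0.0, 1.0)

    def test_gbest_uniform_over_rank_one(self):
        def particle(bits, pair):
            p = Particle(np.array(bits, dtype=np.uint8), np.zeros(3), np.array(bits, dtype=np.uint8))
            p.current_objectives = ObjectivePair(*pair)
            return p

        swarm = [
            particle((1, 0, 0), (1.0, 0.1)),
            particle((0, 1, 0), (0.5, 0.5)),
            particle((0, 0, 1), (0.1, 1.0)),
            particle((1, 1, 1), (0.05, 0.05)),  # dominated, rank 2
        ]
        ranks = non_dominated_sort([p.current_objectives for p in swarm])
        rng = np.random.default_rng(17)
        counts = {0: 0, 1: 0, 2: 0}
        for _ in range(3000):
            g = select_gbest(swarm, ranks, rng)
            idx = int(np.flatnonzero([np.array_equal(g, p.position) for p in swarm])[0])
            assert idx != 3  # the dominated member is never the guide
            counts[idx] += 1
        for c in counts.values():
            assert abs(c / 3000 - 1 / 3) < 0.03

    def test_gbest_single_member_deterministic(self):
        p = Particle(np.array([1], dtype=np.uint8), np.zeros(1), np.array([1], dtype=np.uint8))
        p.current_objectives = ObjectivePair(0.5, 0.5)
        g = select_gbest([p], [1], np.random.default_rng(0))
        assert np.array_equal(g, [1])


class TestEnvironmentalSelection:
    def make(self, pair):
        p = Particle(np.array([1], dtype=np.uint8), np.zeros(1), np.array([1], dtype=np.uint8))
        p.current_objectives = ObjectivePair(*pair)
        return p

    def test_dominant_parents_survive(self):
        parents = [self.make((0.9, 0.9)) for _ in range(4)]
        offspring = [self.make((0.1, 0.1)) for _ in range(4)]
        survivors = environmental_selection(parents, offspring, 4)
        assert all(s in parents for s in survivors)

    def test_size_contract_with_all_nondominated(self):
        pairs = [(i / 12, 1 - i / 12) for i in range(12)]
        parents = [self.make(p) for p in pairs[:6]]
        offspring = [self.make(p) for p in pairs[6:]]
        assert len(environmental_selection(parents, offspring, 6)) == 6

    def test_matches_rank_then_tiebreak_oracle(self):
        rng = np.random.default_rng(23)
        parents = [self.make(tuple(np.round(rng.random(2), 2))) for _ in range(6)]
        offspring = [self.make(tuple(np.round(rng.random(2), 2))) for _ in range(6)]
        combined = parents + offspring
        ranks = peeling_ranks([p.current_objectives for p in combined])
        order = sorted(
            range(12),
            key=lambda i: (
                ranks[i],
                -combined[i].current_objectives.fit2,
                -combined[i].current_objectives.fit1,
                i,
            ),
        )
        expected = [combined[i] for i in order[:6]]
        assert environmental_selection(parents, offspring, 6) == expected


class TestRun:
    def test_deterministic_under_seed(self, d0):
        cfg = MOBPSOConfig(seed=42)
        a = run_mobpso(d0, cfg)
        b = run_mobpso(d0, MOBPSOConfig(seed=42))
        assert a.positions() == b.positions()
        assert a.objective_pairs() == b.objective_pairs()

    def test_single_feature_forced_optimum(self):
        table = DistinctionTable(
            bits=np.ones((4, 1), dtype=bool),
            pair_index=tuple((f"a{i}", f"b{j}") for i in range(2) for j in range(2)),
            class_sizes={"A": 2, "B": 2},
        )
        archive = run_mobpso(table, MOBPSOConfig(seed=0, generations=5))
        reducts = archive.reducts()
        assert any(sum(m.position) == 1 for m in reducts)

    def test_recovers_toy_front(self, d0):
        archive = run_mobpso(d0, MOBPSOConfig(seed=1))
        assert archive.objective_pairs() == exhaustive_pareto(d0).objective_pairs()

    def test_archive_stays_mutually_nondominated(self, d0):
        archive = run_mobpso(d0, MOBPSOConfig(seed=3))
        for m in archive.members:
            for other in archive.members:
                if m is not other:
                    assert not dominates(m.objectives, other.objectives)

    def test_invalid_config_rejected(self, d0):
        with pytest.raises(ParameterError):
            run_mobpso(d0, MOBPSOConfig(swarm_size=0))
        with pytest.raises(ParameterError):
            run_mobpso(d0, MOBPSOConfig(swarm_size=7))


class TestExhaustivePareto:
    def test_toy_front_matches_hand_enumeration(self, d0):
        # best coverage at each cardinality: 0,2,3,4,5,6 rows -> front points
        want = {
            (1.0, 0.0),
            (6 / 7, 2 / 6),
            (5 / 7, 3 / 6),
            (4 / 7, 4 / 6),
            (3 / 7, 5 / 6),
            (2 / 7, 1.0),
        }
        got = exhaustive_pareto(d0).objective_pairs()
        assert got == {(round(a, 12), round(b, 12)) for a, b in want}

    def test_single_feature_single_row(self):
        table = DistinctionTable(
            bits=np.ones((1, 1), dtype=bool),
            pair_index=(("a", "b"),),
            class_sizes={"A": 1, "B": 1},
        )
        got = exhaustive_pareto(table).objective_pairs()
        assert got == {(1.0, 0.0), (0.0, 1.0)}

    def test_size_guard(self):
        table = DistinctionTable(
            bits=np.ones((1, 21), dtype=bool),
            pair_index=(("a", "b"),),
            class_sizes={"A": 1, "B": 1},
        )
        with pytest.raises(SizeGuardError):
            exhaustive_pareto(table)

    def test_front_members_not_dominated_by_any_subset(self):
        rng = np.random.default_rng(31)
        table = random_distinction_table(rng)
        front = exhaustive_pareto(table).objective_pairs()
        n = table.n_features
        for mask in range(2**n):
            position = [(mask >> i) & 1 for i in range(n)]
            pair = evaluate_pair(np.array(position), table)
            p = (round(pair.fit1, 12), round(pair.fit2, 12))
            # every subset is dominated-or-equalled by some front point
            assert any(f1 >= p[0] and f2 >= p[1] for f1, f2 in front)
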