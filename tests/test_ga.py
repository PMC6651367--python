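"""NSGA-II primitives and the evolutionary loop."""

import numpy as np
import pytest

from ligpath.ga import (GAConfig, Individual, ParetoArchive, PathwaySearch,
                        crowding_distance, default_generations, dominates,
                        evolve, non_dominated_sort)
from ligpath.scoring import ObjectiveSpec


def _pop(score_rows):
    return [Individual(genome=None, scores=np.asarray(s, dtype=float), order=k)
            for k, s in enumerate(score_rows)]


def brute_force_fronts(scores):
    """Oracle: peel non-dominated layers by direct pairwise comparison."""
    scores = [np.asarray(s) for s in scores]
    remaining = list(range(len(scores)))
    fronts = []
    while remaining:
        front = [i for i in remaining
                 if not any(dominates(scores[j], scores[i])
                            for j in remaining if j != i)]
        fronts.append(sorted(front))
        remaining = [i for i in remaining if i not in front]
    return fronts


class TestNonDominatedSort:
    def test_three_point_example(self):
        pop = _pop([(1, 2), (2, 1), (3, 3)])
        fronts = non_dominated_sort(pop)
        assert [sorted(id(x) for x in f) for f in fronts] == [
            sorted([id(pop[0]), id(pop[1])]), [id(pop[2])]]
        assert pop[0].rank == pop[1].rank == 1 and pop[2].rank == 2

    def test_single_individual(self):
        fronts = non_dominated_sort(_pop([(5, 5)]))
        assert len(fronts) == 1 and len(fronts[0]) == 1

    def test_duplicates_share_a_front(self):
        pop = _pop([(1, 1), (1, 1)])
        fronts = non_dominated_sort(pop)
        assert len(fronts) == 1

    def test_unscored_rejected(self):
        with pytest.raises(ValueError):
            non_dominated_sort([Individual(genome=None)])

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(1, 13))
            n_obj = int(rng.integers(2, 4))
            scores = rng.integers(0, 6, size=(n, n_obj)).astype(float)
            pop = _pop(scores)
            got = [sorted(ind.order for ind in f) for f in non_dominated_sort(pop)]
            assert got == brute_force_fronts(scores)


class TestCrowding:
    def test_two_members_infinite(self):
        front = _pop([(1, 2), (2, 1)])
        assert np.all(np.isinf(crowding_distance(front)))

    def test_equally_spaced_hand_formula(self):
        # three collinear points in objective space; middle distance is the
        # sum over objectives of (next - prev) / range = 2 * (1/2 + 1/2) / 2
        front = _pop([(0, 0), (1, 1), (2, 2)])
        d = crowding_distance(front)
        assert np.isinf(d[0]) and np.isinf(d[2])
        assert d[1] == pytest.approx((2 - 0) / 2 + (2 - 0) / 2)

    def test_degenerate_objective_contributes_zero(self):
        front = _pop([(0, 7), (1, 7), (2, 7)])
        d = crowding_distance(front)
        assert d[1] == pytest.approx(1.0)  # only the first objective counts


class ToyConvexProblem:
    """Minimise (x^2, (x-2)^2): the Pareto set is exactly x in [0, 2]."""

    n_objectives = 2

    def random_individual(self, rng):
        return float(rng.uniform(-5, 5))

    def mutate(self, x, rng):
        return float(x + rng.normal(0, 0.5))

    def crossover(self, a, b, rng):
        w = rng.random()
        return w * a + (1 - w) * b, (1 - w) * a + w * b

    def evaluate(self, x):
        return np.array([x ** 2, (x - 2.0) ** 2])


class TestEvolve:
    def test_recovers_convex_pareto_set(self):
        archive = evolve(ToyConvexProblem(), GAConfig(population_size=24,
                                                      generations=100, seed=0))
        xs = np.sort([m.genome for m in archive.members])
        assert xs.min() > -0.2 and xs.max() < 2.2
        coverage = np.diff(np.concatenate([[0.0], np.clip(xs, 0, 2), [2.0]]))
        assert coverage.max() < 0.2

    def test_deterministic_under_seed(self):
        a1 = evolve(ToyConvexProblem(), GAConfig(generations=30, seed=7))
        a2 = evolve(ToyConvexProblem(), GAConfig(generations=30, seed=7))
        assert np.array_equal(a1.scores_array(), a2.scores_array())

    def test_archive_mutually_nondominated_every_generation(self):
        seen = []

        def check(gen, pop, archive):
            s = archive.scores_array()
            for i in range(len(s)):
                for j in range(len(s)):
                    if i != j:
                        assert not dominates(s[i], s[j])
            seen.append(gen)

        evolve(ToyConvexProblem(), GAConfig(generations=20, seed=1), callback=check)
        assert len(seen) == 20

    def test_elitism_best_never_worsens(self):
        history = []

        def track(gen, pop, archive):
            history.append(archive.scores_array().min(axis=0))

        evolve(ToyConvexProblem(), GAConfig(generations=40, seed=2), callback=track)
        h = np.array(history)
        assert np.all(np.diff(h, axis=0) <= 1e-12)

    def test_evaluation_failure_gets_worst_scores(self):
        class Exploding(ToyConvexProblem):
            def evaluate(self, x):
                if x > 0:
                    raise RuntimeError("boom")
                return super().evaluate(x)

        archive = evolve(Exploding(), GAConfig(generations=5, seed=3))
        assert len(archive) >= 1
        assert np.all(archive.scores_array() < 1e6)  # failures never archived


def test_default_generations_by_objective_count():
    assert default_generations(1) == 500
    assert default_generations(2) == 750
    assert default_generations(3) == 1000


class TestPathwaySearchProblem:
    def test_search_beats_matched_random_sampling(self, narrow_tube, atom_ligand):
        """On the bottlenecked tube the evolved best max-clash is at most the
        best of an evaluation-budget-matched random sample."""
        search = PathwaySearch(atom_ligand, narrow_tube,
                               [ObjectiveSpec("clashes", "maximum")],
                               mode="two_point", origin=[0, 0, -2.0],
                               destination=[0, 0, 32.0],
                               min_increment=0.0, max_step=1.0,
                               use_torsions=False)
        cfg = GAConfig(generations=50, seed=11)
        archive = evolve(search, cfg)
        budget = cfg.population_size * (cfg.generations + 1)
        rng = np.random.default_rng(1011)
        random_best = min(search.evaluate(search.random_individual(rng))[0]
                          for _ in range(budget))
        assert archive.best().scores[0] <= random_best + 1e-9

    def test_genome_realization_matches_path(self, narrow_tube, atom_ligand):
        search = PathwaySearch(atom_ligand, narrow_tube,
                               [ObjectiveSpec("clashes", "maximum")],
                               mode="two_point", origin=[0, 0, -2.0],
                               destination=[0, 0, 32.0],
                               min_increment=0.0, max_step=1.0,
                               use_torsions=False)
        g = search.random_individual(np.random.default_rng(5))
        frames = search.realize(g)
        assert len(frames) == g.n_frames
        # single-atom ligand: realized positions are exactly the waypoints
        got = np.array([f.ligand_coords[0] for f in frames])
        assert np.allclose(got, g.positions())


def test_archive_update_drops_dominated():
    arch = ParetoArchive()
    arch.update(_pop([(2, 2)]))
    arch.update(_pop([(1, 1)]))   # dominates (2,2)
    assert len(arch) == 1
    assert np.allclose(arch.members[0].scores, [1, 1])
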