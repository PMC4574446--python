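import numpy as np
import pytest

from biocad.optbiocad import (
    Archive,
    Candidate,
    OptConfig,
    copying,
    diversity_enforcing,
    evaluate_constraints,
    fitness,
    global_search,
    initialize_population,
    local_search,
    run_optbiocad,
    selection,
)
from biocad.pareto import ObjectiveSpec

SPEC1 = ObjectiveSpec(("f",), ("max",))
SPEC2 = ObjectiveSpec(("f", "g"), ("max", "max"))


class ScriptedRng:
    """Deterministic stand-in for a Generator with queued draws."""

    def __init__(self, randoms=(), normals=(), ints=()):
        self.randoms = list(randoms)
        self.normals = list(normals)
        self.ints = list(ints)

    def random(self):
        return self.randoms.pop(0)

    def standard_normal(self):
        return self.normals.pop(0)

    def integers(self, *a):
        return self.ints.pop(0)


class TestInitialization:
    def test_initial_sigma_formula(self, rng):
        pop = initialize_population([(0.0, 10.0)] * 10, OptConfig(d=5), rng)
        for c in pop:
            np.testing.assert_allclose(c.sigma, 0.4)  # 0.4 * (10 - 0) / 10
            assert c.age == 0
            assert np.all((c.x >= 0) & (c.x <= 10))

    def test_seeded_reproducibility(self):
        a = initialize_population([(0, 1)] * 3, OptConfig(d=4), np.random.default_rng(9))
        b = initialize_population([(0, 1)] * 3, OptConfig(d=4), np.random.default_rng(9))
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.x, cb.x)

    def test_single_candidate_and_bad_bounds(self, rng):
        assert len(initialize_population([(0, 1)], OptConfig(d=1), rng)) == 1
        with pytest.raises(ValueError):
            initialize_population([(2.0, 1.0)], OptConfig(d=1), rng)


class TestFitness:
    def test_normalized_sum(self):
        assert fitness((5.0, 10.0), (10.0, 10.0), SPEC2) == pytest.approx(0.75)
        assert fitness((10.0, 10.0), (10.0, 10.0), SPEC2) == pytest.approx(1.0)
        assert fitness((0.0, 0.0), (10.0, 10.0), SPEC2) == pytest.approx(0.0)

    def test_nonpositive_best_uses_unit_denominator(self):
        # f_max <= 0 -> denominator 1, then clamped into [0, 1]
        assert fitness((0.5, 0.2), (-1.0, 0.0), SPEC2) == pytest.approx(0.35)
        assert fitness((-3.0,), (-1.0,), SPEC1) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            fitness((1.0,), (1.0, 1.0), SPEC2)


def _candidate(x, age=0, objectives=None, feasible=True, violation=0.0):
    x = np.asarray(x, float)
    return Candidate(
        x=x,
        sigma=np.full(x.size, 0.5),
        age=age,
        objectives=None if objectives is None else np.asarray(objectives, float),
        feasible=feasible,
        violation=violation,
    )


class TestCopying:
    def test_copy_counts_and_ages(self):
        pop = [_candidate([1.0], age=7), _candidate([2.0], age=0), _candidate([3.0], age=2)]
        copies = copying(pop, 2)
        assert len(copies) == 6
        assert [c.age for c in pop] == [8, 1, 3]  # parents aged by one
        assert [c.age for c in copies[:2]] == [7, 7]  # copies keep the pre-increment age

    def test_dup_four_preserves_age(self):
        pop = [_candidate([0.0], age=7)]
        copies = copying(pop, 4)
        assert [c.age for c in copies] == [7, 7, 7, 7]


class TestLocalSearch:
    BOUNDS = [(0.0, 10.0)] * 4

    def test_fires_with_certainty_at_zero_fitness(self):
        c = _candidate([5.0] * 4, objectives=[0.0])
        rng = ScriptedRng(randoms=[0.999999], normals=[0.1, 0.2, 0.3], ints=[2])
        out = local_search(c, F=0.0, rho=1.0, bounds=self.BOUNDS, rng=rng)
        changed = np.nonzero(out.x != c.x)[0]
        assert changed.tolist() == [2]  # exactly one coordinate mutated
        assert out.objectives is None and c.objectives is not None

    def test_vanishing_rate_returns_candidate_unchanged(self):
        c = _candidate([5.0] * 4, objectives=[1.0])
        rng = ScriptedRng(randoms=[1e-9])
        out = local_search(c, F=1.0, rho=50.0, bounds=self.BOUNDS, rng=rng)
        assert out is c

    def test_seeded_repeatability_and_box(self):
        for _ in range(2):
            rng = np.random.default_rng(5)
            c = _candidate([9.9] * 4, objectives=[0.0])
            outs = [local_search(c, 0.0, 1.0, self.BOUNDS, rng) for _ in range(50)]
        xs = np.array([o.x for o in outs])
        assert np.all((xs >= 0) & (xs <= 10))
        rng1, rng2 = np.random.default_rng(5), np.random.default_rng(5)
        a = local_search(c, 0.0, 1.0, self.BOUNDS, rng1)
        b = local_search(c, 0.0, 1.0, self.BOUNDS, rng2)
        np.testing.assert_array_equal(a.x, b.x)


class TestGlobalSearch:
    BOUNDS = [(0.0, 10.0)] * 2

    def test_rate_is_exp_minus_f_over_beta(self):
        c = _candidate([1.0, 2.0])
        pool = [c, _candidate([3.0, 4.0])]
        # alpha = 1/7 at F = 0: a draw just below 1/7 fires, just above does not
        fired = global_search(c, pool, 0.0, 7.0, self.BOUNDS,
                              ScriptedRng(randoms=[1 / 7 - 1e-9], normals=[0.5], ints=[0, 1, 0]))
        skipped = global_search(c, pool, 0.0, 7.0, self.BOUNDS,
                                ScriptedRng(randoms=[1 / 7 + 1e-9]))
        assert skipped is c and fired is not c

    def test_gamma_zero_keeps_value_gamma_one_adopts_donor(self):
        c = _candidate([1.0, 2.0])
        donor = _candidate([7.0, 9.0])
        out0 = global_search(c, [c, donor], 0.0, 1.0, self.BOUNDS,
                             ScriptedRng(randoms=[0.0], normals=[0.0], ints=[0, 1, 0]))
        np.testing.assert_allclose(out0.x, c.x)
        out1 = global_search(c, [c, donor], 0.0, 1.0, self.BOUNDS,
                             ScriptedRng(randoms=[0.0], normals=[1.0], ints=[0, 1, 0]))
        assert out1.x[0] == pytest.approx(donor.x[1])  # donor value at another index


class TestConstraints:
    @pytest.mark.parametrize(
        "g,theta,feasible,violation",
        [(3.0, 5.0, True, 0.0), (7.0, 5.0, False, 2.0), (None, 5.0, False, np.inf)],
    )
    def test_mapping(self, g, theta, feasible, violation):
        f, v = evaluate_constraints(g, theta)
        assert f is feasible
        assert v == violation or (np.isinf(v) and np.isinf(violation))


class TestDiversityAndArchive:
    def test_age_limit_boundary(self, rng):
        keep = _candidate([0.0], age=51)
        drop = _candidate([1.0], age=52)
        archive = Archive(4)
        pop, muts = diversity_enforcing([keep, drop], [], tau_B=50, archive=archive, rng=rng)
        assert pop == [keep]
        assert archive.occupancy == 1 and archive.members()[0] is drop

    def test_full_archive_overwrites_random_slot(self, rng):
        archive = Archive(3)
        for i in range(3):
            archive.insert(_candidate([float(i)]), rng)
        newcomer = _candidate([99.0])
        archive.insert(newcomer, rng)
        assert archive.occupancy == 3
        assert any(m is newcomer for m in archive.members())


class TestSelection:
    def test_feasible_beats_infeasible_and_violation_order(self, rng):
        feas = _candidate([0.0], objectives=[0.3])
        infeas = _candidate([1.0], objectives=[0.9], feasible=False, violation=1.0)
        out = selection([feas], [infeas], Archive(2), 1, np.array([1.0]), SPEC1, rng)
        assert out == [feas]
        v2 = _candidate([0.0], feasible=False, violation=2.0)
        v5 = _candidate([1.0], feasible=False, violation=5.0)
        out = selection([v2], [v5], Archive(2), 1, np.array([1.0]), SPEC1, rng)
        assert out == [v2]

    def test_deficit_filled_from_archive(self, rng):
        archive = Archive(16)
        for i in range(10):
            archive.insert(_candidate([float(i)], objectives=[0.1]), rng)
        survivors = [_candidate([float(i)], objectives=[0.5]) for i in range(4)]
        out = selection(survivors, [], archive, 7, np.array([1.0]), SPEC1, rng)
        assert len(out) == 7
        archived_xs = {float(m.x[0]) for m in archive.members()}
        assert all(float(c.x[0]) in archived_xs for c in out[4:])


class TestRunLoop:
    BOUNDS = [(0.0, 10.0)] * 5

    @staticmethod
    def evaluator(x):
        return (-float(np.sum((np.asarray(x) - 3.0) ** 2)),), 0.0

    def test_quadratic_converges_to_analytic_optimum(self):
        cfg = OptConfig(d=20, dup=2, t_final=100, seed=3)
        res = run_optbiocad(self.evaluator, self.BOUNDS, SPEC1, cfg)
        best = max(float(o[0]) for o in res.cumulative_front.objectives)
        assert best >= -1e-2  # optimum is 0 at x = (3, ..., 3)

    def test_seeded_runs_are_identical(self):
        cfg = OptConfig(d=10, dup=2, t_final=20, seed=11)
        r1 = run_optbiocad(self.evaluator, self.BOUNDS, SPEC1, cfg)
        r2 = run_optbiocad(self.evaluator, self.BOUNDS, SPEC1, cfg)
        assert len(r1.fronts) == len(r2.fronts)
        for f1, f2 in zip(r1.fronts, r2.fronts):
            np.testing.assert_array_equal(f1.objectives, f2.objectives)
        np.testing.assert_array_equal(
            r1.cumulative_front.objectives, r2.cumulative_front.objectives
        )

    def test_population_size_and_box_invariants(self):
        cfg = OptConfig(d=12, dup=2, t_final=15, seed=2)
        res = run_optbiocad(self.evaluator, self.BOUNDS, SPEC1, cfg)
        assert len(res.population) == cfg.d
        for c in res.population + res.archive.members():
            assert np.all((c.x >= 0.0) & (c.x <= 10.0))

    def test_progress_across_generations(self):
        improved = 0
        for seed in range(5):
            cfg = OptConfig(d=15, dup=2, t_final=40, seed=seed)
            res = run_optbiocad(self.evaluator, self.BOUNDS, SPEC1, cfg)
            first = max(float(o[0]) for o in res.fronts[0].objectives)
            last = max(float(o[0]) for o in res.fronts[-1].objectives)
            improved += last >= first
        assert improved >= 4

    def test_stagnation_stop(self):
        cfg = OptConfig(d=10, dup=2, t_final=500, seed=0, stagnation=5)
        res = run_optbiocad(lambda x: ((1.0,), 0.0), self.BOUNDS, SPEC1, cfg)
        assert res.generations_run < 500

    def test_mass_evaluator_failure_aborts(self):
        def broken(x):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError):
            run_optbiocad(broken, self.BOUNDS, SPEC1, OptConfig(d=6, t_final=3, seed=0))

    def test_per_generation_fronts_are_nondominated(self):
        def ev(x):
            x = np.asarray(x)
            return (float(x[0]), float(10 - x[0]) + float(x[1]) * 0.1), 0.0

        res = run_optbiocad(ev, self.BOUNDS[:2], SPEC2, OptConfig(d=10, t_final=10, seed=4))
        from biocad.pareto import pareto_front

        for fr in res.fronts:
            assert len(pareto_front(fr.objectives, SPEC2)) == len(fr)
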