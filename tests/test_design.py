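"""D-error, coordinate-exchange search, blocking and validity tasks."""

import itertools
import warnings

import numpy as np
import pytest

from mmchoice import (
    AttributeSpec,
    ChoiceTask,
    Design,
    UtilityParameters,
    add_validity_tasks,
    d_error,
    generate_design,
    read_design_csv,
    write_design_csv,
)
from mmchoice.design import check_level_balance, dummy_code, level_balance


def toy_catalog(n_levels=(2, 2)):
    return [
        AttributeSpec(
            f"a{i}", f"a{i}", "benefit",
            tuple(f"l{j}" for j in range(k)),
            numeric_values=tuple(float(j) for j in range(k)),
        )
        for i, k in enumerate(n_levels)
    ]


def brute_force_d_error(design: Design, beta: np.ndarray) -> float:
    """Independent oracle: direct summation of p(1-p) x x' over tasks."""
    K = len(beta)
    info = np.zeros((K, K))
    for t in design.experimental_tasks:
        xs = [dummy_code(alt, design.catalog) for alt in t.alternatives]
        exps = np.exp([x @ beta for x in xs])
        probs = exps / exps.sum()
        xbar = sum(p * x for p, x in zip(probs, xs))
        for p, x in zip(probs, xs):
            info += p * np.outer(x - xbar, x - xbar)
    det = np.linalg.det(info)
    return float("inf") if det <= 0 else det ** (-1.0 / K)


def all_tiny_designs(catalog, n_tasks):
    """Every valid design: distinct unordered task pairs, no duplicates."""
    alts = list(itertools.product(*[range(a.n_levels) for a in catalog]))
    tasks = [
        (a, b) for a, b in itertools.combinations(alts, 2)
    ]
    for combo in itertools.combinations(tasks, n_tasks):
        yield Design(
            tasks=[ChoiceTask(i + 1, 1, alts) for i, alts in enumerate(combo)],
            n_blocks=1, seed=0, catalog=catalog,
        )


class TestDError:
    def test_matches_brute_force_oracle(self):
        cat = toy_catalog((2, 2))
        alts = list(itertools.product(range(2), range(2)))
        tasks = [
            ChoiceTask(i + 1, 1, pair)
            for i, pair in enumerate(itertools.combinations(alts, 2))
        ]
        design = Design(tasks=tasks, n_blocks=1, seed=0, catalog=cat)
        got = d_error(design)
        expected = brute_force_d_error(design, np.zeros(2))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_matches_oracle_at_nonzero_priors(self):
        cat = toy_catalog((2, 3))
        rng = np.random.default_rng(5)
        tasks = []
        alts = list(itertools.product(range(2), range(3)))
        for i, pair in enumerate(itertools.combinations(alts, 2)):
            tasks.append(ChoiceTask(i + 1, 1, pair))
        design = Design(tasks=tasks, n_blocks=1, seed=0, catalog=cat)
        beta = rng.normal(size=3) * 0.5
        priors = UtilityParameters.from_vector(beta, cat)
        assert d_error(design, priors) == pytest.approx(
            brute_force_d_error(design, beta), rel=1e-12
        )

    def test_duplicated_task_gives_infinite_d_error(self, catalog):
        alt_a = tuple(0 for _ in catalog)
        alt_b = tuple(a.n_levels - 1 for a in catalog)
        tasks = [ChoiceTask(i + 1, 1, (alt_a, alt_b)) for i in range(36)]
        design = Design(tasks=tasks, n_blocks=1, seed=0, catalog=catalog)
        with pytest.warns(UserWarning, match="singular"):
            assert d_error(design) == float("inf")

    def test_invariant_to_alternative_swap(self, catalog):
        d = generate_design(catalog, 12, 1, seed=5, n_sweeps=2)
        swapped = Design(
            tasks=[
                ChoiceTask(t.task_id, t.block_id, (t.alternatives[1], t.alternatives[0]))
                for t in d.tasks
            ],
            n_blocks=1, seed=5, catalog=catalog,
        )
        assert d_error(d) == pytest.approx(d_error(swapped), rel=1e-12)


class TestGenerateDesign:
    def test_published_shape_36_tasks_3_blocks(self, design36):
        exp = design36.experimental_tasks
        assert len(exp) == 36
        for b in (1, 2, 3):
            assert len(design36.block_tasks(b, include_validity=False)) == 12

    def test_alternatives_complete_and_distinct(self, design36, catalog):
        seen = set()
        for t in design36.experimental_tasks:
            for alt in t.alternatives:
                assert len(alt) == len(catalog)
                for a, lev in zip(catalog, alt):
                    assert 0 <= lev < a.n_levels
            assert t.alternatives[0] != t.alternatives[1]
            key = tuple(sorted(t.alternatives))
            assert key not in seen  # duplicate tasks are re-drawn
            seen.add(key)

    def test_deterministic_per_seed(self, catalog):
        d1 = generate_design(catalog, 12, 1, seed=9, n_sweeps=2)
        d2 = generate_design(catalog, 12, 1, seed=9, n_sweeps=2)
        assert [t.alternatives for t in d1.tasks] == [t.alternatives for t in d2.tasks]

    @pytest.mark.parametrize("levels", [(2, 2), (2, 3)])
    def test_matches_exhaustive_search_on_tiny_instances(self, levels):
        cat = toy_catalog(levels)
        best = min(d_error(d) for d in all_tiny_designs(cat, 4))
        got = generate_design(cat, 4, 1, seed=1, n_sweeps=20, n_restarts=8)
        assert got.d_error == pytest.approx(best, rel=1e-9)

    def test_optimized_beats_random_start(self, catalog):
        random = generate_design(catalog, 36, 3, seed=1, n_sweeps=0)
        optimized = generate_design(catalog, 36, 3, seed=1, n_sweeps=10)
        assert optimized.d_error <= random.d_error

    def test_recorded_d_error_consistent(self, design36):
        assert d_error(design36) == pytest.approx(design36.d_error, rel=1e-9)

    def test_rejects_single_attribute_catalog(self):
        with pytest.raises(ValueError, match="at least 2 attributes"):
            generate_design(toy_catalog((3,)), 4, 1)

    def test_rejects_indivisible_blocks(self, catalog):
        with pytest.raises(ValueError, match="divisible"):
            generate_design(catalog, 10, 3)

    def test_level_balance_soft_check(self, design36):
        # soft check: returns the frequency table and at most warns
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tab = check_level_balance(design36, tol=0.25)
        assert set(tab["attribute"]) == {a.name for a in design36.catalog}
        # frequencies per attribute sum to 1
        assert tab.groupby("attribute")["frequency"].sum().to_numpy() == pytest.approx(
            np.ones(8)
        )


class TestValidityTasks:
    def test_adds_two_tasks_per_block(self, catalog):
        d = generate_design(catalog, 36, 3, seed=2, n_sweeps=1)
        extended = add_validity_tasks(d, repeat_position=3)
        assert len(extended.tasks) == len(d.tasks) + 2 * d.n_blocks

    def test_stability_repeat_is_level_identical_to_third_task(self, design36):
        for b in (1, 2, 3):
            block = design36.block_tasks(b, include_validity=False)
            rep = [t for t in design36.block_tasks(b) if t.is_stability_repeat]
            assert len(rep) == 1
            assert rep[0].stability_source_id == block[2].task_id
            assert rep[0].alternatives == block[2].alternatives

    def test_dominance_task_weakly_better_on_ordered_attributes(self, design36, catalog):
        for b in (1, 2, 3):
            dom = [t for t in design36.block_tasks(b) if t.is_dominance_test]
            assert len(dom) == 1
            t = dom[0]
            win = t.alternatives[t.dominant_alternative]
            lose = t.alternatives[1 - t.dominant_alternative]
            strict = 0
            for i, a in enumerate(catalog):
                if a.ordered:
                    assert a.preference_rank(win[i]) >= a.preference_rank(lose[i])
                    strict += a.preference_rank(win[i]) > a.preference_rank(lose[i])
                else:
                    assert win[i] == lose[i]  # administration held equal
            assert strict >= 1

    def test_repeat_position_out_of_range(self, catalog):
        d = generate_design(catalog, 4, 1, seed=2, n_sweeps=1)
        with pytest.raises(ValueError, match="repeat_position"):
            add_validity_tasks(d, repeat_position=9)


class TestDesignIO:
    def test_csv_round_trip_byte_identical(self, design36, catalog, tmp_path):
        p1, p2 = tmp_path / "d1.csv", tmp_path / "d2.csv"
        write_design_csv(design36, p1)
        again = read_design_csv(p1, catalog)
        write_design_csv(again, p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert [t.alternatives for t in again.tasks] == [
            t.alternatives for t in design36.tasks
        ]
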