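"""Cost model, accuracy surrogate, goodness criterion and the DE optimiser."""

import itertools

import numpy as np
import pytest

import seqalloc as sa
from seqalloc.budget import DEFAULT_COVERAGES


def family(offset, p_f):
    """A 7-member family with distinct integer ids starting at ``offset``."""
    ids = list(range(offset, offset + 7))
    return sa.FamilyUnit(ids[0], ids[1], ids[2], tuple(ids[3:]), p_f)


class TestScenarioCost:
    @pytest.mark.parametrize("coverages,expected", [
        ((10, 0, 0, 0, 0, 0, 0), 890.0),
        ((2, 0, 0, 0, 0, 0, 0), 210.0),
        ((0, 0, 0, 0, 0, 0, 0), 0.0),
    ])
    def test_single_member_costs(self, coverages, expected):
        cost = sa.scenario_cost(sa.SequencingScenario(coverages), sa.CostModel())
        assert cost == expected

    def test_prior_coverage_and_library_subtracted(self):
        prior = sa.PriorSequencing([("a", 2.0, True)])
        cost = sa.scenario_cost(
            sa.SequencingScenario((10, 0, 0, 0, 0, 0, 0)), sa.CostModel(),
            prior, member_ids=["a", "b", "c", "d", "e", "f", "g"])
        assert cost == 85.0 * 8  # 680: no new library, 8 incremental x

    def test_target_below_prior_costs_nothing(self):
        prior = sa.PriorSequencing([("a", 20.0, True)])
        cost = sa.scenario_cost(
            sa.SequencingScenario((5, 0, 0, 0, 0, 0, 0)), sa.CostModel(),
            prior, member_ids=["a", None, None, None, None, None, None])
        assert cost == 0.0

    def test_negative_prior_rejected(self):
        with pytest.raises(ValueError):
            sa.PriorSequencing([("a", -1.0, False)])


class TestCombinationCost:
    def test_shared_grandsire_paid_once_at_max(self):
        f1 = sa.FamilyUnit(1, 2, 3, (9, 5, 6, 7), 0.5)
        f2 = sa.FamilyUnit(11, 12, 13, (9, 15, 16, 17), 0.3)
        s1 = sa.SequencingScenario((0, 0, 0, 5, 0, 0, 0))
        s2 = sa.SequencingScenario((0, 0, 0, 5, 0, 0, 0))
        merged = sa.merge_assignments([f1, f2], [s1, s2])
        assert merged == {9: 5.0}
        assert sa.combination_cost(merged, sa.CostModel()) == 40 + 5 * 85

    def test_conflicting_requests_resolve_to_max(self):
        f1 = sa.FamilyUnit(1, 2, 3, (9, 5, 6, 7), 0.5)
        f2 = sa.FamilyUnit(11, 12, 13, (9, 15, 16, 17), 0.3)
        merged = sa.merge_assignments(
            [f1, f2],
            [sa.SequencingScenario((0, 0, 0, 10, 0, 0, 0)),
             sa.SequencingScenario((0, 0, 0, 2, 0, 0, 0))])
        assert merged[9] == 10.0

    def test_disjoint_families_costs_add(self):
        f1, f2 = family(0, 0.5), family(10, 0.3)
        s1 = sa.SequencingScenario((10, 5, 2, 1, 1, 0, 0))
        s2 = sa.SequencingScenario((2, 1, 0, 0, 0, 0, 0))
        merged = sa.merge_assignments([f1, f2], [s1, s2])
        total = sa.combination_cost(merged, sa.CostModel())
        each = (sa.scenario_cost(s1, sa.CostModel(), member_ids=f1.members)
                + sa.scenario_cost(s2, sa.CostModel(), member_ids=f2.members))
        assert total == each

    def test_family_of_seven_at_fifty_x(self):
        fam = family(0, 1.0)
        scen = sa.SequencingScenario((10, 20, 2, 10, 5, 2, 1))  # 50x, all new
        merged = sa.merge_assignments([fam], [scen])
        assert sa.combination_cost(merged, sa.CostModel()) == 7 * 40 + 50 * 85


class TestAccuracyModels:
    def test_all_zero_scenario_phases_nothing(self):
        assert sa.default_accuracy((0, 0, 0, 0, 0, 0, 0)) == 0.0

    def test_monotone_in_every_member(self):
        """Grid scan over the reduced coverage set {0, 1, 20}^7."""
        model = sa.DefaultAccuracy()
        levels = [0.0, 1.0, 20.0]
        grid = np.array(list(itertools.product(levels, repeat=7)))
        phi = model.phi_batch(grid)
        assert np.all((phi >= 0) & (phi <= 1))
        for member in range(7):
            for lo, hi in ((0.0, 1.0), (1.0, 20.0)):
                at_lo = grid[:, member] == lo
                bumped = grid[at_lo].copy()
                bumped[:, member] = hi
                assert np.all(model.phi_batch(bumped) >= phi[at_lo] - 1e-12)

    def test_table_lookup_contract(self):
        key = (10.0, 5.0, 5.0, 0.0, 0.0, 0.0, 0.0)
        model = sa.TableAccuracy({key: 0.73})
        assert model.phi(key) == 0.73
        with pytest.raises(KeyError):
            model.phi((1.0,) * 7)

    def test_table_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            sa.TableAccuracy({(0.0,) * 7: 1.5})


class TestGoodness:
    def test_all_zero_assignment_is_zero(self):
        fam = family(0, 0.5)
        g = sa.goodness({}, [fam], sa.DefaultAccuracy(), sa.CostModel(),
                        None, 1000.0)
        assert g == 0.0

    def test_upper_bound_single_family(self):
        fam = family(0, 1.0)
        perfect = sa.TableAccuracy({(20.0,) * 7: 1.0})
        assign = {m: 20.0 for m in fam.members}
        g = sa.goodness(assign, [fam], perfect, sa.CostModel(0.0, 0.0),
                        None, 1000.0)
        assert g == 1.0

    def test_two_family_arithmetic(self):
        f1, f2 = family(0, 0.6), family(10, 0.2)
        model = sa.DefaultAccuracy()
        assign = {0: 10.0, 1: 5.0, 10: 2.0}
        budget = 100.0  # force an overrun
        cost = sa.combination_cost(assign, sa.CostModel())
        expected = (0.6 * model.phi((10, 5, 0, 0, 0, 0, 0))
                    + 0.2 * model.phi((2, 0, 0, 0, 0, 0, 0))
                    - 10.0 * (cost - budget) / budget)
        g = sa.goodness(assign, [f1, f2], model, sa.CostModel(), None, budget)
        assert g == pytest.approx(expected)

    def test_invalid_budget(self):
        with pytest.raises(ValueError):
            sa.goodness({}, [family(0, 0.5)], sa.DefaultAccuracy(),
                        sa.CostModel(), None, 0.0)


class TestSampleScenario:
    def test_saturated_logit_always_chosen(self):
        rng = np.random.default_rng(0)
        logits = np.zeros((7, 6))
        logits[:, 4] = 50.0
        for _ in range(20):
            s = sa.sample_scenario(logits, DEFAULT_COVERAGES, rng)
            assert s.coverages == (10.0,) * 7

    def test_uniform_logits_give_uniform_draws(self):
        from scipy.stats import chisquare

        rng = np.random.default_rng(1)
        logits = np.zeros((7, 6))
        counts = np.zeros(6)
        for _ in range(10_000 // 7):
            s = sa.sample_scenario(logits, DEFAULT_COVERAGES, rng)
            for c in s.coverages:
                counts[DEFAULT_COVERAGES.index(c)] += 1
        _stat, p = chisquare(counts)
        assert p > 1e-4

    def test_seeded_determinism_and_argmax_decoding(self):
        logits = np.random.default_rng(2).normal(size=(7, 6))
        s1 = sa.sample_scenario(logits, DEFAULT_COVERAGES,
                                np.random.default_rng(7))
        s2 = sa.sample_scenario(logits, DEFAULT_COVERAGES,
                                np.random.default_rng(7))
        assert s1 == s2
        det = sa.sample_scenario(logits, DEFAULT_COVERAGES,
                                 np.random.default_rng(8), temperature=0)
        expected = tuple(np.asarray(DEFAULT_COVERAGES)[np.argmax(logits, axis=1)])
        assert det.coverages == expected


class TestCountScenarios:
    @pytest.mark.parametrize("levels,members,expected", [
        (2, 1, 2), (6, 2, 36), (6, 7, 279_936),
    ])
    def test_counts(self, levels, members, expected):
        assert sa.count_scenarios(levels, members) == expected


def monotone_table(levels=(0.0, 20.0), seed=0):
    """A random accuracy table, monotone in every member by construction."""
    rng = np.random.default_rng(seed)
    base = {m: np.sort(rng.uniform(0.05, 0.45, size=len(levels)))
            for m in range(7)}
    table = {}
    for combo in itertools.product(range(len(levels)), repeat=7):
        val = base[0][combo[0]] * 2 * np.mean(
            [base[m][combo[m]] for m in range(1, 7)]) * 4
        if combo[0] == 0 or levels[combo[0]] == 0:
            val = 0.0
        table[tuple(levels[i] for i in combo)] = min(float(val), 1.0)
    return sa.TableAccuracy(table)


def brute_force_optimum(families, table, cost_model, budget, levels=(0.0, 20.0)):
    """Exhaustive enumeration over per-individual coverage assignments."""
    members = [m for fam in families for m in fam.members]
    assert len(set(members)) == len(members), "oracle assumes disjoint families"
    best = 0.0
    for combo in itertools.product(levels, repeat=len(members)):
        assign = dict(zip(members, combo))
        cost = sa.combination_cost(assign, cost_model)
        if cost > budget:
            continue
        val = sum(
            fam.p_f * table.phi(tuple(assign[m] for m in fam.members))
            for fam in families
        )
        best = max(best, val)
    return best


class TestAllocateBudget:
    def test_large_budget_saturates_coverage(self):
        fam = family(0, 0.8)
        res = sa.allocate_budget(
            [fam], budget=1e9, coverages=(0.0, 20.0),
            de_config=sa.DEConfig(n_rounds=400, pop_size=30, seed=1))
        assert all(c == 20.0 for c in res.coverages.values())
        assert res.feasible

    def test_attains_brute_force_optimum(self):
        levels = (0.0, 20.0)
        table = monotone_table(levels, seed=3)
        fams = [family(0, 0.6), family(10, 0.2)]
        cm = sa.CostModel()
        budget = 7000.0  # about 4 of 14 members at 20x
        opt = brute_force_optimum(fams, table, cm, budget, levels)
        res = sa.allocate_budget(
            fams, budget, cm, accuracy=table, coverages=levels,
            de_config=sa.DEConfig(n_rounds=1500, pop_size=40, seed=11))
        assert res.feasible
        assert res.objective == pytest.approx(opt, abs=1e-9)

    def test_seeded_determinism(self):
        fams = [family(0, 0.5), family(10, 0.2)]
        kwargs = dict(budget=4000.0, coverages=(0.0, 2.0, 20.0),
                      de_config=sa.DEConfig(n_rounds=150, seed=5))
        r1 = sa.allocate_budget(fams, **kwargs)
        r2 = sa.allocate_budget(fams, **kwargs)
        assert r1.coverages == r2.coverages
        assert r1.objective == r2.objective

    def test_elite_history_non_decreasing(self):
        fams = [family(0, 0.5)]
        res = sa.allocate_budget(
            fams, budget=3000.0, coverages=(0.0, 5.0, 20.0),
            de_config=sa.DEConfig(n_rounds=200, seed=2))
        assert np.all(np.diff(res.elite_history) >= 0)

    def test_reported_solution_within_budget(self):
        fams = [family(0, 0.7), family(10, 0.3)]
        res = sa.allocate_budget(
            fams, budget=2500.0,
            de_config=sa.DEConfig(n_rounds=200, seed=4))
        assert res.feasible
        assert res.total_cost <= 2500.0

    def test_budget_monotonicity(self):
        fams = [family(0, 0.6), family(10, 0.3)]
        objectives = []
        for budget in (2000.0, 4000.0, 8000.0):
            res = sa.allocate_budget(
                fams, budget, coverages=(0.0, 2.0, 20.0),
                de_config=sa.DEConfig(n_rounds=400, pop_size=30, seed=9))
            objectives.append(res.objective)
        assert objectives[0] <= objectives[1] <= objectives[2]

    def test_preferential_allocation_to_frequent_family(self):
        f_big, f_small = family(0, 0.6), family(10, 0.05)
        res = sa.allocate_budget(
            [f_big, f_small], budget=8000.0,
            de_config=sa.DEConfig(n_rounds=500, pop_size=30, seed=6))
        tot_big = sum(res.coverages[m] for m in f_big.members)
        tot_small = sum(res.coverages[m] for m in f_small.members)
        assert tot_big >= tot_small

    def test_tiny_budget_warns_all_zero(self):
        fam = family(0, 0.5)
        with pytest.warns(UserWarning, match="all-zero"):
            res = sa.allocate_budget(
                fam and [fam], budget=1.0, coverages=(0.0, 20.0),
                de_config=sa.DEConfig(n_rounds=50, seed=3))
        assert all(c == 0.0 for c in res.coverages.values())
        assert res.total_cost == 0.0

    def test_excluded_members_forced_to_zero(self):
        fam = family(0, 0.8)
        res = sa.allocate_budget(
            [fam], budget=1e9, coverages=(0.0, 20.0), excluded=[3, 4],
            de_config=sa.DEConfig(n_rounds=200, pop_size=20, seed=8))
        assert res.coverages[3] == 0.0 and res.coverages[4] == 0.0
        assert res.coverages[0] == 20.0

    def test_prior_data_reduces_cost_and_feeds_accuracy(self):
        fam = family(0, 1.0)
        prior = sa.PriorSequencing([(0, 2.0, True)])
        res = sa.allocate_budget(
            [fam], budget=700.0, prior=prior, coverages=(0.0, 10.0),
            de_config=sa.DEConfig(n_rounds=300, pop_size=20, seed=12))
        # 10x on the focal costs 8 x 85 = 680 <= 700 thanks to the prior
        assert res.coverages[0] == 10.0
        assert res.total_cost == pytest.approx(680.0)


def test_family_from_pedigree_resolves_grandparents():
    from seqalloc.popsim import FEMALE, MALE, Pedigree

    ids = [1, 2, 3, 4, 5, 6, 7]
    sire = [0, 0, 0, 0, 1, 3, 5]
    dam = [0, 0, 0, 0, 2, 4, 6]
    sex = [MALE, FEMALE, MALE, FEMALE, MALE, FEMALE, MALE]
    ped = Pedigree(np.array(ids), np.array(sire), np.array(dam),
                   np.array(sex), np.array([0, 0, 0, 0, 1, 1, 2]))
    fam = sa.FamilyUnit.from_pedigree(7, ped, 0.4)
    assert fam.members == (7, 5, 6, 1, 2, 3, 4)
    founder = sa.FamilyUnit.from_pedigree(1, ped, 0.1)
    assert founder.members == (1, None, None, None, None, None, None)
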