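"""Allocation of a fixed sequencing budget across focal families.

A focal family is a focal individual plus its two parents and four
grandparents (seven members, any of which may be unknown). Each member is
assigned a sequencing coverage from a discrete set (default
{0, 1, 2, 5, 10, 20}x). The cost of newly sequencing a member is a DNA
library preparation charge (default GBP 40, waived when a library already
exists) plus a per-1x sequencing charge (default GBP 85) on the coverage
increment over any pre-existing data. Coverages live on physical
individuals: an ancestor shared between families is paid for once, at the
maximum coverage requested for it, and its coverage feeds every family's
phasing accuracy.

The objective ("goodness") of a combination of sequencing scenarios is

    G = sum_f p_f * phi(scenario_f) - lambda * max(0, cost - budget) / budget

where ``p_f`` is the proportion of population haplotype mass carried by
focal individual ``f`` (from the focal ranking) and ``phi`` is the expected
accuracy of phasing the focal individual's haplotypes at the sequence level
given the family's coverages. The first term is the expected proportion of
population haplotype mass phased at the sequence level; the penalty lets the
search traverse infeasible regions while a final greedy repair guarantees a
feasible report.

The search is a rand/1/bin differential evolution over a per-individual,
per-coverage-level logit representation: member coverages are drawn from the
softmax of each member's logits during the search (stochastic decoding) and
by argmax (deterministic decoding) for elite tracking and final reporting.
An elitist best-so-far solution is never lost, so the best objective is
non-decreasing across rounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .popsim import Pedigree

DEFAULT_COVERAGES: tuple[float, ...] = (0.0, 1.0, 2.0, 5.0, 10.0, 20.0)

#: family slot order
ROLES = ("focal", "sire", "dam",
         "paternal_grandsire", "paternal_granddam",
         "maternal_grandsire", "maternal_granddam")


@dataclass(frozen=True)
class CostModel:
    """Sequencing cost structure in GBP."""

    library_cost: float = 40.0
    per_x_cost: float = 85.0

    def __post_init__(self) -> None:
        if self.library_cost < 0 or self.per_x_cost < 0:
            raise ValueError("costs must be non-negative")


@dataclass(frozen=True)
class FamilyUnit:
    """A focal individual, its parents and grandparents, and its weight p_f."""

    focal: object
    sire: object = None
    dam: object = None
    grandparents: tuple = (None, None, None, None)
    p_f: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.p_f <= 1:
            raise ValueError("p_f must be in [0, 1]")
        if len(self.grandparents) != 4:
            raise ValueError("exactly four grandparent slots required")

    @property
    def members(self) -> tuple:
        """The 7 member slots in role order (None where unknown)."""
        return (self.focal, self.sire, self.dam) + tuple(self.grandparents)

    @classmethod
    def from_pedigree(cls, focal, pedigree: Pedigree, p_f: float) -> "FamilyUnit":
        sire, dam = pedigree.parents_of(focal)
        gp = []
        for parent in (sire, dam):
            if parent is None:
                gp.extend([None, None])
            else:
                gp.extend(pedigree.parents_of(parent))
        return cls(focal, sire, dam, tuple(gp), p_f)


@dataclass(frozen=True)
class SequencingScenario:
    """Coverage for each of the 7 family member slots, in role order."""

    coverages: tuple

    def __post_init__(self) -> None:
        if len(self.coverages) != 7:
            raise ValueError("a sequencing scenario has exactly 7 coverages")
        if any(c < 0 for c in self.coverages):
            raise ValueError("coverages must be non-negative")

    @property
    def total(self) -> float:
        return float(sum(self.coverages))


class PriorSequencing:
    """Historically available sequence data: per-individual coverage and library flag."""

    def __init__(self, records: Mapping | Iterable[tuple] = ()):
        self._data: dict = {}
        items = records.items() if isinstance(records, Mapping) else records
        for rec in items:
            if isinstance(rec, tuple) and len(rec) == 2 and isinstance(rec[1], tuple):
                ind, (cov, lib) = rec
            else:
                ind, cov, lib = rec
            if cov < 0:
                raise ValueError(f"negative prior coverage for {ind!r}")
            if ind in self._data and self._data[ind] != (float(cov), bool(lib)):
                raise ValueError(f"conflicting prior records for {ind!r}")
            self._data[ind] = (float(cov), bool(lib))

    def coverage(self, individual) -> float:
        return self._data.get(individual, (0.0, False))[0]

    def has_library(self, individual) -> bool:
        return self._data.get(individual, (0.0, False))[1]

    def __contains__(self, individual) -> bool:
        return individual in self._data


class AccuracyModel:
    """Maps a family's 7 coverages to an expected focal phasing accuracy in [0, 1]."""

    def phi(self, coverages: Sequence[float]) -> float:
        raise NotImplementedError

    def phi_batch(self, coverages: np.ndarray) -> np.ndarray:
        """Vectorised phi over the last axis of length 7 (generic fallback)."""
        flat = np.asarray(coverages, dtype=float).reshape(-1, 7)
        return np.asarray([self.phi(row) for row in flat]).reshape(
            np.asarray(coverages).shape[:-1]
        )


class DefaultAccuracy(AccuracyModel):
    """Smooth saturating surrogate for family-based phasing accuracy.

    phi = s(c_focal) * (0.5 + 0.3 s(c_sire + c_dam) + 0.2 s(sum grandparents))
    with s(c) = 1 - exp(-c / 5), clipped to [0, 1]. Zero coverage on the
    focal individual gives phi = 0 (nothing to phase); accuracy is monotone
    non-decreasing in every member's coverage and saturates at high total
    investment. Replaceable by a :class:`TableAccuracy` fitted to a
    family-based phasing tool.
    """

    def phi(self, coverages: Sequence[float]) -> float:
        return float(self.phi_batch(np.asarray(coverages, dtype=float)))

    def phi_batch(self, coverages: np.ndarray) -> np.ndarray:
        c = np.asarray(coverages, dtype=float)
        s = lambda x: 1.0 - np.exp(-x / 5.0)  # noqa: E731
        out = s(c[..., 0]) * (0.5 + 0.3 * s(c[..., 1] + c[..., 2])
                              + 0.2 * s(c[..., 3:7].sum(axis=-1)))
        return np.clip(out, 0.0, 1.0)


class TableAccuracy(AccuracyModel):
    """Exact lookup table keyed on the 7-tuple of coverages."""

    def __init__(self, table: Mapping[tuple, float]):
        self._table: dict[tuple, float] = {}
        for key, val in table.items():
            if not 0 <= val <= 1:
                raise ValueError(f"accuracy {val} for {key} outside [0, 1]")
            self._table[tuple(float(c) for c in key)] = float(val)

    def phi(self, coverages: Sequence[float]) -> float:
        key = tuple(float(c) for c in coverages)
        try:
            return self._table[key]
        except KeyError:
            raise KeyError(f"no accuracy table entry for scenario {key}") from None


def default_accuracy(scenario: SequencingScenario | Sequence[float]) -> float:
    """Convenience wrapper around :class:`DefaultAccuracy`."""
    cov = scenario.coverages if isinstance(scenario, SequencingScenario) else scenario
    return DefaultAccuracy().phi(cov)


def count_scenarios(n_levels: int, family_size: int = 7) -> int:
    """Number of distinct coverage assignments for one family."""
    if n_levels < 1 or family_size < 1:
        raise ValueError("sizes must be >= 1")
    return n_levels ** family_size


def _member_cost(target: float, prior_cov: float, prior_lib: bool,
                 cost_model: CostModel) -> float:
    if prior_cov < 0:
        raise ValueError("negative prior coverage")
    if target <= prior_cov:
        return 0.0
    lib = 0.0 if prior_lib else cost_model.library_cost
    return lib + cost_model.per_x_cost * (target - prior_cov)


def scenario_cost(scenario: SequencingScenario, cost_model: CostModel,
                  prior: PriorSequencing | None = None,
                  member_ids: Sequence | None = None) -> float:
    """Cost in GBP of one family's sequencing scenario.

    Members with a target coverage of 0 (or not exceeding their prior
    coverage) incur no cost; otherwise each pays a library charge (waived if
    a library exists) plus the per-1x charge on the increment over prior
    coverage. Unknown members (``member_ids`` entry None) are free.
    """
    prior = prior or PriorSequencing()
    if member_ids is None:
        member_ids = [object() for _ in scenario.coverages]  # all distinct, no prior
    total = 0.0
    for ind, cov in zip(member_ids, scenario.coverages):
        if ind is None:
            if cov > 0:
                raise ValueError("unknown family member assigned nonzero coverage")
            continue
        total += _member_cost(cov, prior.coverage(ind), prior.has_library(ind),
                              cost_model)
    return total


def merge_assignments(families: Sequence[FamilyUnit],
                      scenarios: Sequence[SequencingScenario]) -> dict:
    """Resolve per-family scenarios to per-individual coverages (max-merge).

    A shared ancestor requested at different coverages by different families
    is assigned the maximum, so it is sequenced (and paid for) once.
    """
    merged: dict = {}
    for fam, scen in zip(families, scenarios):
        for ind, cov in zip(fam.members, scen.coverages):
            if ind is None or cov == 0:
                continue
            merged[ind] = max(merged.get(ind, 0.0), float(cov))
    return merged


def combination_cost(assignments: Mapping, cost_model: CostModel,
                     prior: PriorSequencing | None = None) -> float:
    """Total cost of per-individual coverage assignments (each individual once)."""
    prior = prior or PriorSequencing()
    return sum(
        _member_cost(cov, prior.coverage(ind), prior.has_library(ind), cost_model)
        for ind, cov in assignments.items()
    )


def goodness(assignments: Mapping, families: Sequence[FamilyUnit],
             accuracy: AccuracyModel, cost_model: CostModel,
             prior: PriorSequencing | None, budget: float,
             penalty: float = 10.0) -> float:
    """Goodness criterion G = sum_f p_f phi_f - penalty * relative budget overrun.

    Effective coverage for phasing is max(assigned, prior): pre-existing data
    contributes to accuracy even when no new sequencing is bought.
    """
    if budget <= 0:
        raise ValueError("budget must be > 0")
    if not families:
        raise ValueError("at least one family required")
    prior = prior or PriorSequencing()
    cost = combination_cost(assignments, cost_model, prior)
    value = 0.0
    for fam in families:
        cov = [max(assignments.get(m, 0.0), prior.coverage(m)) if m is not None else 0.0
               for m in fam.members]
        value += fam.p_f * accuracy.phi(cov)
    return value - penalty * max(0.0, cost - budget) / budget


def sample_scenario(logits: np.ndarray, coverages: Sequence[float],
                    rng: np.random.Generator,
                    temperature: float = 1.0) -> SequencingScenario:
    """Draw one scenario from per-member softmax probabilities over coverage levels.

    ``logits`` has shape (7, n_levels). ``temperature=0`` decodes
    deterministically by argmax (used for final reporting).
    """
    logits = np.asarray(logits, dtype=float)
    levels = np.asarray(coverages, dtype=float)
    if logits.shape != (7, levels.size):
        raise ValueError(f"expected logits of shape (7, {levels.size})")
    if temperature == 0:
        idx = np.argmax(logits, axis=1)
    else:
        z = logits / temperature
        z = z - z.max(axis=1, keepdims=True)
        p = np.exp(z)
        p /= p.sum(axis=1, keepdims=True)
        u = rng.random((7, 1))
        idx = (p.cumsum(axis=1) < u).sum(axis=1)
    return SequencingScenario(tuple(levels[idx]))


@dataclass(frozen=True)
class DEConfig:
    """Differential-evolution settings (rand/1/bin, Storn–Price defaults)."""

    pop_size: int = 50
    mutation: float = 0.8
    crossover: float = 0.9
    n_rounds: int = 10_000
    penalty: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")
        if self.pop_size < 4:
            raise ValueError("pop_size must be >= 4 for rand/1 mutation")
        if not 0 < self.crossover <= 1:
            raise ValueError("crossover rate must be in (0, 1]")
        if self.mutation <= 0:
            raise ValueError("mutation factor must be > 0")


@dataclass
class AllocationResult:
    """Optimised per-individual coverages and diagnostics."""

    coverages: dict
    family_scenarios: list[SequencingScenario]
    family_phi: np.ndarray
    family_p: np.ndarray
    total_cost: float
    objective: float
    feasible: bool
    elite_history: np.ndarray = field(default=None, repr=False)


class _Problem:
    """Vectorised evaluation of candidate logit genomes."""

    def __init__(self, families, budget, cost_model, prior, accuracy,
                 levels, penalty, excluded):
        self.families = families
        self.budget = float(budget)
        self.cost_model = cost_model
        self.prior = prior
        self.accuracy = accuracy
        self.levels = np.asarray(levels, dtype=float)
        if not np.any(self.levels == 0):
            raise ValueError("the coverage set must include 0")
        self.penalty = float(penalty)
        self.zero_level = int(np.flatnonzero(self.levels == 0)[0])

        members: list = []
        seen = set()
        for fam in families:
            for m in fam.members:
                if m is not None and m not in seen:
                    seen.add(m)
                    members.append(m)
        self.members = members
        self.n_members = len(members)
        pos = {m: i for i, m in enumerate(members)}
        # slot index n_members points at a dummy always-zero member
        self.fam_idx = np.asarray(
            [[pos[m] if m is not None else self.n_members for m in fam.members]
             for fam in families], dtype=np.int64)
        self.p_f = np.asarray([fam.p_f for fam in families])
        self.prior_cov = np.asarray([prior.coverage(m) for m in members])
        self.prior_lib = np.asarray([prior.has_library(m) for m in members])
        self.forced_zero = np.asarray([m in excluded for m in members])

    def decode_sample(self, genomes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        z = genomes - genomes.max(axis=2, keepdims=True)
        p = np.exp(z)
        p /= p.sum(axis=2, keepdims=True)
        u = rng.random(genomes.shape[:2] + (1,))
        return (p.cumsum(axis=2) < u).sum(axis=2)

    def decode_argmax(self, genomes: np.ndarray) -> np.ndarray:
        return np.argmax(genomes, axis=-1)

    def evaluate(self, level_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Objective and cost for level-index matrices of shape (P, n_members)."""
        idx = level_idx.copy()
        idx[:, self.forced_zero] = self.zero_level
        cov = self.levels[idx]                                   # (P, M)
        inc = np.clip(cov - self.prior_cov, 0.0, None)
        needs_lib = (inc > 0) & ~self.prior_lib
        cost = (needs_lib * self.cost_model.library_cost
                + inc * self.cost_model.per_x_cost).sum(axis=1)
        eff = np.maximum(cov, self.prior_cov)
        eff_pad = np.concatenate([eff, np.zeros((eff.shape[0], 1))], axis=1)
        fam_cov = eff_pad[:, self.fam_idx]                       # (P, F, 7)
        phi = self.accuracy.phi_batch(fam_cov)                   # (P, F)
        value = phi @ self.p_f
        g = value - self.penalty * np.maximum(0.0, cost - self.budget) / self.budget
        return g, cost

    def result_from_indices(self, idx: np.ndarray,
                            history: np.ndarray | None = None) -> AllocationResult:
        idx = idx.copy()
        idx[self.forced_zero] = self.zero_level
        cov = self.levels[idx]
        assignments = {m: float(c) for m, c in zip(self.members, cov)}
        cost = combination_cost(assignments, self.cost_model, self.prior)
        scenarios, phis = [], []
        for fam in self.families:
            c = tuple(
                max(assignments.get(m, 0.0), self.prior.coverage(m)) if m is not None
                else 0.0
                for m in fam.members
            )
            scenarios.append(SequencingScenario(c))
            phis.append(self.accuracy.phi(c))
        phis = np.asarray(phis)
        obj = float(phis @ self.p_f
                    - self.penalty * max(0.0, cost - self.budget) / self.budget)
        return AllocationResult(
            coverages=assignments,
            family_scenarios=scenarios,
            family_phi=phis,
            family_p=self.p_f.copy(),
            total_cost=float(cost),
            objective=obj,
            feasible=cost <= self.budget,
            elite_history=history,
        )


def _repair(problem: _Problem, idx: np.ndarray) -> np.ndarray:
    """Greedy repair: decrement the member losing the least sum_f p_f dphi
    until the assignment fits the budget."""
    idx = idx.copy()
    order = np.argsort(problem.levels)  # level indices sorted by coverage
    rank_of = np.empty_like(order)
    rank_of[order] = np.arange(order.size)
    while True:
        g, cost = problem.evaluate(idx[None, :])
        if cost[0] <= problem.budget:
            return idx
        candidates = np.flatnonzero((rank_of[idx] > 0) & ~problem.forced_zero)
        if candidates.size == 0:
            return idx
        best_j, best_loss, best_save = None, np.inf, 0.0
        base_val = g[0] + problem.penalty * max(0.0, cost[0] - problem.budget) / problem.budget
        for j in candidates:
            trial = idx.copy()
            trial[j] = order[rank_of[idx[j]] - 1]
            gt, ct = problem.evaluate(trial[None, :])
            val = gt[0] + problem.penalty * max(0.0, ct[0] - problem.budget) / problem.budget
            loss = base_val - val
            save = cost[0] - ct[0]
            if loss < best_loss - 1e-12 or (abs(loss - best_loss) <= 1e-12 and save > best_save):
                best_j, best_loss, best_save = j, loss, save
        idx[best_j] = order[rank_of[idx[best_j]] - 1]


def allocate_budget(
    families: Sequence[FamilyUnit],
    budget: float,
    cost_model: CostModel = CostModel(),
    prior: PriorSequencing | None = None,
    accuracy: AccuracyModel | None = None,
    de_config: DEConfig = DEConfig(),
    coverages: Sequence[float] = DEFAULT_COVERAGES,
    excluded: Iterable = (),
) -> AllocationResult:
    """Optimise the allocation of ``budget`` across focal families.

    Runs rand/1/bin differential evolution over the concatenated
    per-individual coverage logits, evaluating candidates with stochastic
    softmax decoding and tracking an elitist best-so-far solution under
    deterministic argmax decoding. The final elite is greedily repaired to
    feasibility if needed. ``excluded`` individuals are forced to coverage 0.

    Returns the best feasible :class:`AllocationResult`; if nothing nonzero
    fits the budget an all-zero result is returned with a warning.
    """
    if not families:
        raise ValueError("at least one family required")
    if budget <= 0:
        raise ValueError("budget must be > 0")
    prior = prior or PriorSequencing()
    accuracy = accuracy or DefaultAccuracy()
    problem = _Problem(families, budget, cost_model, prior, accuracy,
                       coverages, de_config.penalty, set(excluded))
    rng = np.random.default_rng(de_config.seed)
    P, M, L = de_config.pop_size, problem.n_members, problem.levels.size

    X = rng.normal(0.0, 1.0, size=(P, M, L))
    G, _ = problem.evaluate(problem.decode_sample(X, rng))

    def det_value(genome: np.ndarray) -> float:
        g, _ = problem.evaluate(problem.decode_argmax(genome)[None, :])
        return float(g[0])

    elite = X[int(np.argmax(G))].copy()
    elite_g = det_value(elite)
    history = np.empty(de_config.n_rounds)

    F, CR = de_config.mutation, de_config.crossover
    for rnd in range(de_config.n_rounds):
        # rand/1 parents, distinct from each other and the target
        r = np.empty((P, 3), dtype=np.int64)
        for i in range(P):
            r[i] = rng.choice(P - 1, size=3, replace=False)
        r[r >= np.arange(P)[:, None]] += 1
        V = X[r[:, 0]] + F * (X[r[:, 1]] - X[r[:, 2]])
        mask = rng.random((P, M, L)) < CR
        j = rng.integers(M * L, size=P)
        mask.reshape(P, -1)[np.arange(P), j] = True
        U = np.where(mask, V, X)
        GU, _ = problem.evaluate(problem.decode_sample(U, rng))
        better = GU >= G
        X[better] = U[better]
        G[better] = GU[better]

        cand = int(np.argmax(G))
        cand_g = det_value(X[cand])
        if cand_g > elite_g:
            elite_g = cand_g
            elite = X[cand].copy()
        history[rnd] = elite_g

    assert np.all(np.diff(history) >= 0), "elite objective must be non-decreasing"
    idx = problem.decode_argmax(elite)
    result = problem.result_from_indices(idx, history)
    if not result.feasible:
        idx = _repair(problem, idx)
        result = problem.result_from_indices(idx, history)
    if result.feasible and all(c == 0 for c in result.coverages.values()):
        warnings.warn("no feasible nonzero allocation under the budget; "
                      "returning the all-zero assignment", stacklevel=2)
    return result
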