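"""Greedy selection and ranking of focal individuals.

A focal individual is one whose haplotypes are shared with many other
individuals, so sequencing and phasing it would let those haplotypes be
imputed at the sequence level across the population. Selection is a greedy
weighted maximum-coverage procedure over the windowed haplotype library: an
individual's score is the summed population copy count of the distinct,
not-yet-masked haplotypes it carries; after each pick every haplotype the
pick carries is masked permanently, and scores are recomputed.

The objective is monotone submodular, so the accepted marginal gains are
non-increasing — this is asserted on every run — and the greedy set is a
(1 - 1/e)-approximation to the optimal set of the same size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .haplib import HaplotypeLibrary


@dataclass
class MaskState:
    """Set of captured (masked) haplotype ids; grows monotonically."""

    masked: np.ndarray  # boolean over global haplotype ids

    @classmethod
    def empty(cls, library: HaplotypeLibrary) -> "MaskState":
        return cls(np.zeros(library.n_haplotypes, dtype=bool))

    def mask_individual(self, library: HaplotypeLibrary, individual) -> None:
        self.masked[library.carriers_by_individual[individual]] = True

    @property
    def n_masked(self) -> int:
        return int(self.masked.sum())


@dataclass
class FocalRanking:
    """Ordered focal individuals with marginal and cumulative coverage."""

    ids: list
    marginal_counts: np.ndarray
    marginal_props: np.ndarray
    cumulative_props: np.ndarray
    total_copies: int

    def __len__(self) -> int:
        return len(self.ids)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "rank": np.arange(1, len(self.ids) + 1),
            "id": self.ids,
            "marginal_copies": self.marginal_counts,
            "marginal_proportion": self.marginal_props,
            "cumulative_proportion": self.cumulative_props,
        })


def candidate_score(individual, library: HaplotypeLibrary, mask: MaskState) -> int:
    """Summed population copy count of the individual's distinct unmasked haplotypes.

    A haplotype carried on both gametes contributes its population mass once.
    """
    try:
        carried = library.carriers_by_individual[individual]
    except KeyError:
        raise KeyError(f"unknown or ineligible individual {individual!r}") from None
    keep = ~mask.masked[carried]
    return int(library.counts[carried[keep]].sum())


def _incidence(library: HaplotypeLibrary, order: list) -> sparse.csr_matrix:
    rows, cols = [], []
    for r, ind in enumerate(order):
        h = library.carriers_by_individual[ind]
        rows.extend([r] * len(h))
        cols.extend(h.tolist())
    data = np.ones(len(rows), dtype=np.int8)
    return sparse.csr_matrix((data, (rows, cols)),
                             shape=(len(order), library.n_haplotypes))


def select_focal_individuals(
    library: HaplotypeLibrary,
    k: int,
    presequenced=(),
    excluded=(),
) -> FocalRanking:
    """Greedy ranking of up to ``k`` focal individuals.

    ``presequenced`` individuals already have sequence data: all their
    haplotypes are masked before selection starts (they are accounted for but
    not re-picked). ``excluded`` individuals cannot be picked (no DNA sample)
    but their haplotype copies still count towards candidate scores, so their
    haplotypes can be captured through other carriers.

    Stops early when the best remaining marginal score is zero. Ties are
    broken towards the smallest individual id. Cumulative proportions are
    relative to the total copy mass of the library.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    mask = MaskState.empty(library)
    for ind in presequenced:
        mask.mask_individual(library, ind)

    excluded = set(excluded)
    order = sorted(set(library.carriers_by_individual) - set(presequenced) - excluded)
    if k > len(order):
        warnings.warn(
            f"k={k} exceeds the {len(order)} available candidates; truncating",
            stacklevel=2,
        )
        k = len(order)
    if not order:
        raise ValueError("no candidates available for selection")

    inc = _incidence(library, order)
    active = np.where(mask.masked, 0, library.counts).astype(np.float64)
    total = library.total_copies
    alive = np.ones(len(order), dtype=bool)

    picked: list = []
    marg: list[int] = []
    for _ in range(k):
        scores = inc @ active
        scores[~alive] = -1.0
        best = int(np.argmax(scores))  # first max -> smallest id (rows id-sorted)
        if scores[best] <= 0:
            break
        ind = order[best]
        picked.append(ind)
        marg.append(int(round(scores[best])))
        alive[best] = False
        mask.mask_individual(library, ind)
        active[library.carriers_by_individual[ind]] = 0.0

    marg_arr = np.asarray(marg, dtype=np.int64)
    assert np.all(np.diff(marg_arr) <= 0), "greedy marginals must be non-increasing"
    cum = np.cumsum(marg_arr)
    return FocalRanking(
        ids=picked,
        marginal_counts=marg_arr,
        marginal_props=marg_arr / total,
        cumulative_props=cum / total,
        total_copies=total,
    )


def set_coverage(library: HaplotypeLibrary, individuals) -> float:
    """Proportion of library copy mass on the union of haplotypes carried by a set."""
    mask = MaskState.empty(library)
    for ind in individuals:
        if ind in library.carriers_by_individual:
            mask.mask_individual(library, ind)
    return float(library.counts[mask.masked].sum() / library.total_copies)


def coverage_curve(ranking: FocalRanking):
    """Monotone (rank, cumulative proportion) table as a DataFrame."""
    import pandas as pd

    if len(ranking) == 0:
        raise ValueError("empty ranking has no coverage curve")
    return pd.DataFrame({
        "rank": np.arange(1, len(ranking) + 1),
        "cumulative_proportion": ranking.cumulative_props,
    })
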