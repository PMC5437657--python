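"""Key-ancestors baseline: pedigree-inferred marginal genetic contributions.

The expected contribution of an ancestor to a reference population is the
expected proportion of the reference individuals' genes that descend from it:
a gene copy in a reference individual traces one lineage upwards, moving to
the sire or the dam with probability 1/2 at each step, and the contribution
of ancestor ``a`` is the probability that this path passes through ``a``
(averaged over the reference set).

Greedy selection conditions on already-selected ancestors: a lineage path is
captured by the first selected individual it hits on the way up, so the
marginal contribution of a candidate counts only paths that reach it while
avoiding the selected set. Marginals therefore never exceed raw
contributions and their cumulative sum never exceeds 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .popsim import Pedigree


@dataclass
class ContributionRanking:
    """Ordered ancestors with marginal and cumulative expected contributions."""

    ids: list
    marginals: np.ndarray
    cumulative: np.ndarray

    def __len__(self) -> int:
        return len(self.ids)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "rank": np.arange(1, len(self.ids) + 1),
            "id": self.ids,
            "marginal_contribution": self.marginals,
            "cumulative_contribution": self.cumulative,
        })


def _contribution_vector(pedigree: Pedigree, reference, blocked=frozenset()) -> np.ndarray:
    """Expected contribution of every individual to the reference set.

    Gene-origin mass starts at each reference individual (1/|R| each) and is
    pushed up the pedigree, halving at each parent step. Mass reaching a
    blocked (already selected) individual is captured there and not pushed
    further.
    """
    n = len(pedigree)
    reference = list(reference)
    if not reference:
        raise ValueError("empty reference set")
    q = np.zeros(n)
    for r in reference:
        q[pedigree.index_of(r)] += 1.0 / len(reference)
    blocked_idx = {pedigree.index_of(b) for b in blocked}
    sire, dam = pedigree.sire, pedigree.dam
    # parents precede offspring, so a reverse sweep pushes all mass upward
    for i in range(n - 1, -1, -1):
        if q[i] == 0.0 or i in blocked_idx:
            continue
        half = 0.5 * q[i]
        s = sire[i]
        d = dam[i]
        if s != 0:
            q[pedigree.index_of(s.item() if hasattr(s, "item") else s)] += half
        if d != 0:
            q[pedigree.index_of(d.item() if hasattr(d, "item") else d)] += half
    return q


def _avoidance_vector(pedigree: Pedigree, blocked) -> np.ndarray:
    """Per individual, the probability that an upward lineage walk starting at
    its parents never hits a blocked individual (1 at founders)."""
    n = len(pedigree)
    blocked_idx = {pedigree.index_of(b) for b in blocked}
    a = np.ones(n)
    for i in range(n):  # parents precede offspring: forward sweep
        acc = 0.0
        for parent in (pedigree.sire[i], pedigree.dam[i]):
            if parent == 0:
                acc += 0.5
            else:
                j = pedigree.index_of(parent.item() if hasattr(parent, "item") else parent)
                acc += 0.0 if j in blocked_idx else 0.5 * a[j]
        a[i] = acc
    return a


def expected_contribution(pedigree: Pedigree, ancestor, reference) -> float:
    """Expected proportion of the reference set's genes contributed by ``ancestor``."""
    q = _contribution_vector(pedigree, reference)
    return float(q[pedigree.index_of(ancestor)])


def select_key_ancestors(pedigree: Pedigree, reference, k: int) -> ContributionRanking:
    """Greedy key-ancestor ranking by largest marginal contribution.

    At each step the individual with the largest contribution through descent
    paths not passing through previously selected ancestors is appended (ties
    towards the smallest id). A path is credited to a candidate only if it
    avoids the selected set everywhere — below the candidate (the gene is
    already explained by a younger selected carrier) and above it (the gene
    descends from an older selected ancestor) — which makes the cumulative
    marginals a capture probability bounded by 1. Stops early when the best
    marginal is zero.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    reference = list(reference)
    order = np.argsort(pedigree.ids, kind="stable")  # id-ascending for tie-break
    selected: list = []
    marginals: list[float] = []
    for _ in range(min(k, len(pedigree))):
        q = (_contribution_vector(pedigree, reference, blocked=selected)
             * _avoidance_vector(pedigree, selected))
        q_sorted = q[order]
        taken = np.isin(np.arange(len(pedigree)), [pedigree.index_of(s) for s in selected])
        q_sorted[taken[order]] = -1.0
        best = int(np.argmax(q_sorted))
        if q_sorted[best] <= 0:
            break
        idx = int(order[best])
        ind = pedigree.ids[idx]
        selected.append(ind.item() if hasattr(ind, "item") else ind)
        marginals.append(float(q[idx]))
    m = np.asarray(marginals)
    return ContributionRanking(selected, m, np.cumsum(m))
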