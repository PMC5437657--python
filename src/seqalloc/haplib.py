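"""Windowed population haplotype library.

The library slices each chromosome into consecutive, non-overlapping windows
of a fixed number of markers (default 250) and records, per window, every
distinct haplotype string observed among the eligible gametes together with
its population copy count and carriers. Haplotype identity is an exact
(100%) string match restricted to the eligible markers inside the window, so
haplotypes that differ at a single marker are independent entries.

Eligibility is a two-stage filter: individuals with at least ``min_phased``
of their alleles called are retained, then markers with at least
``min_phased`` called alleles across the retained individuals are retained
(individuals first, then markers). A gamete with any missing allele inside a
window contributes nothing for that window, since exact identity cannot be
certified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .popsim import MISSING, PhasedPanel

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowSpec:
    """Half-open marker window ``[start, start + length)`` on one chromosome."""

    chrom: int
    start: int
    length: int

    def __post_init__(self) -> None:
        if self.length < 1 or self.start < 0 or self.chrom < 0:
            raise ValueError("invalid window specification")

    @property
    def stop(self) -> int:
        return self.start + self.length


@dataclass
class EligibleSet:
    """Outcome of the phased-data filter."""

    individual_indices: np.ndarray          # row indices into the panel
    individual_ids: np.ndarray
    marker_masks: list[np.ndarray]          # per chromosome, boolean over markers


def filter_eligible(panel: PhasedPanel, min_phased: float = 0.9) -> EligibleSet:
    """Retain individuals, then markers, with >= ``min_phased`` called alleles."""
    if not 0 <= min_phased <= 1:
        raise ValueError("min_phased must be in [0, 1]")
    frac_ind = panel.phased_fraction_per_individual()
    keep_ind = np.flatnonzero(frac_ind >= min_phased)
    if keep_ind.size == 0:
        raise ValueError(
            f"no eligible individuals: 0 of {panel.n_individuals} have "
            f">= {min_phased:.0%} phased data"
        )
    masks = []
    n_markers = 0
    n_kept = 0
    for frac in panel.phased_fraction_per_marker(keep_ind):
        m = frac >= min_phased
        masks.append(m)
        n_markers += m.size
        n_kept += int(m.sum())
    if n_kept == 0:
        raise ValueError(
            f"no eligible markers: 0 of {n_markers} have >= {min_phased:.0%} "
            f"phased data across the {keep_ind.size} eligible individuals"
        )
    log.info("eligibility filter kept %d/%d individuals and %d/%d markers",
             keep_ind.size, panel.n_individuals, n_kept, n_markers)
    return EligibleSet(keep_ind, panel.ids[keep_ind], masks)


def build_windows(n_markers_per_chr: int, window_length: int,
                  n_chromosomes: int = 1) -> list[WindowSpec]:
    """Tile each chromosome with consecutive fixed-length windows.

    ``floor(n_markers / window_length)`` windows per chromosome; a trailing
    remainder shorter than ``window_length`` is dropped so all haplotype
    strings are comparable at exact identity.
    """
    if window_length < 1:
        raise ValueError("window_length must be >= 1")
    if window_length > n_markers_per_chr:
        raise ValueError(
            f"window_length {window_length} exceeds markers per chromosome "
            f"{n_markers_per_chr}"
        )
    n_windows = n_markers_per_chr // window_length
    return [WindowSpec(c, w * window_length, window_length)
            for c in range(n_chromosomes) for w in range(n_windows)]


@dataclass
class HaplotypeLibrary:
    """Distinct windowed haplotypes with copy counts and carriers.

    ``counts[h]`` is the population copy count of global haplotype id ``h``;
    ``window_of[h]`` maps it back to its window; ``carriers_by_individual``
    maps each eligible individual id to the sorted array of distinct global
    haplotype ids it carries (a haplotype carried on both gametes appears
    once). ``window_entries[w]`` maps the allele-string key (bytes) to its
    global haplotype id.
    """

    windows: list[WindowSpec]
    counts: np.ndarray
    window_of: np.ndarray
    window_entries: list[dict[bytes, int]]
    carriers: list[list[tuple]]                 # per hap id: (individual id, gamete)
    carriers_by_individual: dict = field(default_factory=dict)
    eligible_ids: np.ndarray = None
    n_skipped_gametes: int = 0

    @property
    def n_haplotypes(self) -> int:
        return len(self.counts)

    @property
    def total_copies(self) -> int:
        return int(self.counts.sum())

    def copies_per_window(self) -> np.ndarray:
        out = np.zeros(len(self.windows))
        np.add.at(out, self.window_of, self.counts)
        return out


def build_library(panel: PhasedPanel, windows: list[WindowSpec],
                  eligible: EligibleSet) -> HaplotypeLibrary:
    """Insert every fully-called (gamete, window) allele string into the library.

    Raises if the eligible sets are empty. After construction asserts the
    copy-count conservation invariant: summed copy counts equal the number of
    contributing gametes (2 x eligible individuals when fully phased).
    """
    if eligible.individual_indices.size == 0:
        raise ValueError("empty eligible individual set")
    entries: list[dict[bytes, int]] = [dict() for _ in windows]
    counts: list[int] = []
    window_of: list[int] = []
    carriers: list[list[tuple]] = []
    by_ind: dict = {i: [] for i in eligible.individual_ids.tolist()}
    n_contributing = 0
    n_skipped = 0

    for w, win in enumerate(windows):
        mask = eligible.marker_masks[win.chrom][win.start:win.stop]
        sub = panel.alleles[win.chrom][eligible.individual_indices, :, win.start:win.stop]
        sub = sub[:, :, mask]
        complete = (sub != MISSING).all(axis=2)
        table = entries[w]
        for i, ind in enumerate(eligible.individual_ids.tolist()):
            for g in range(2):
                if not complete[i, g]:
                    n_skipped += 1
                    continue
                key = sub[i, g].tobytes()
                hid = table.get(key)
                if hid is None:
                    hid = len(counts)
                    table[key] = hid
                    counts.append(0)
                    window_of.append(w)
                    carriers.append([])
                counts[hid] += 1
                carriers[hid].append((ind, g))
                by_ind[ind].append(hid)
                n_contributing += 1

    lib = HaplotypeLibrary(
        windows=windows,
        counts=np.asarray(counts, dtype=np.int64),
        window_of=np.asarray(window_of, dtype=np.int64),
        window_entries=entries,
        carriers=carriers,
        carriers_by_individual={i: np.unique(np.asarray(h, dtype=np.int64))
                                for i, h in by_ind.items()},
        eligible_ids=eligible.individual_ids,
        n_skipped_gametes=n_skipped,
    )
    # conservation: every contributing gamete adds exactly one copy
    assert lib.total_copies == n_contributing, "copy-count conservation violated"
    if n_skipped:
        log.info("build_library skipped %d incomplete (gamete, window) pairs", n_skipped)
    return lib
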