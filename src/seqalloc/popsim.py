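"""Synthetic populations for sequencing-resource allocation studies.

This module generates the test-bed populations used throughout the package:
discrete-generation livestock-style pedigrees bred by truncation selection of
sires on a polygenic true breeding value (TBV), and nominally unrelated
populations drawn directly from a pool of base haplotypes.

The base haplotypes are produced by a direct allele-frequency-parameterised
generator: each marker gets a frequency drawn from a configurable uniform
distribution and alleles are sampled i.i.d. Bernoulli across haplotypes. This
is a deliberately crude neutral stand-in for a coalescent history — the
downstream selection and budget-allocation algorithms consume only phased SNP
panels and are insensitive to coalescent fine structure (linkage between the
base haplotypes is irrelevant once gene dropping reshuffles them).

Transmission follows Mendelian gene dropping with Haldane recombination:
crossover counts are Poisson with mean equal to the chromosome's genetic
length in Morgans and crossover positions are uniform (no interference).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: allele code for a missing / unphased allele in a panel
MISSING = 9

MALE = 1
FEMALE = 2


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a simulated population.

    Defaults follow the structured-pedigree test-bed: 10 chromosomes of
    1 Morgan each with 1000 SNPs, 1000 base haplotypes, generations of 1000
    individuals with an equal sex ratio, the 25 highest-TBV males used as
    sires and all 500 females as dams, and a trait controlled by 10,000
    additive QTN spread equally across chromosomes.
    """

    n_chromosomes: int = 10
    n_snps_per_chr: int = 1000
    n_base_haplotypes: int = 1000
    n_generations: int = 30
    n_per_generation: int = 1000
    n_sires_selected: int = 25
    n_dams: int = 500
    n_qtn: int = 10_000
    chr_length_morgans: float = 1.0
    n_unrelated: int = 0
    sire_selection: str = "truncation"  # "truncation" | "random"
    freq_low: float = 0.05
    freq_high: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_chromosomes", "n_snps_per_chr", "n_base_haplotypes",
                     "n_per_generation", "n_sires_selected", "n_dams", "n_qtn"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.n_generations < 0:
            raise ValueError("n_generations must be >= 0")
        if self.n_base_haplotypes < 2:
            raise ValueError("need at least 2 base haplotypes to segregate")
        if self.n_sires_selected > self.n_per_generation // 2:
            raise ValueError("n_sires_selected exceeds the number of males per generation")
        if self.n_dams > self.n_per_generation // 2:
            raise ValueError("n_dams exceeds the number of females per generation")
        if self.n_qtn % self.n_chromosomes != 0:
            raise ValueError("n_qtn must be divisible by n_chromosomes")
        if self.n_qtn // self.n_chromosomes > self.n_snps_per_chr:
            raise ValueError("more QTN per chromosome than markers")
        if self.chr_length_morgans <= 0:
            raise ValueError("chr_length_morgans must be > 0")
        if not 0 <= self.freq_low < self.freq_high <= 1:
            raise ValueError("require 0 <= freq_low < freq_high <= 1")
        if self.sire_selection not in ("truncation", "random"):
            raise ValueError("sire_selection must be 'truncation' or 'random'")


@dataclass
class Pedigree:
    """Pedigree records in parents-before-offspring order.

    ``sire``/``dam`` use 0 for an unknown parent. ``sex`` is 1 for male,
    2 for female, 0 for unknown. ``generation`` is -1 when unknown.
    """

    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    sex: np.ndarray
    generation: np.ndarray
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.sire = np.asarray(self.sire)
        self.dam = np.asarray(self.dam)
        self.sex = np.asarray(self.sex)
        self.generation = np.asarray(self.generation)
        if len(set(self.ids.tolist())) != len(self.ids):
            raise ValueError("pedigree ids are not unique")
        self._index = {ind: i for i, ind in enumerate(self.ids.tolist())}
        seen: set = set()
        for i, ind in enumerate(self.ids.tolist()):
            for parent, want_sex in ((self.sire[i], MALE), (self.dam[i], FEMALE)):
                parent = parent.item() if hasattr(parent, "item") else parent
                if parent == 0:
                    continue
                if parent not in seen:
                    raise ValueError(
                        f"parent {parent!r} of {ind!r} does not precede it in the pedigree"
                    )
                j = self._index[parent]
                if self.sex[j] not in (0, want_sex):
                    raise ValueError(f"parent {parent!r} has inconsistent sex")
            seen.add(ind)

    def __len__(self) -> int:
        return len(self.ids)

    def index_of(self, individual) -> int:
        return self._index[individual]

    def parents_of(self, individual) -> tuple:
        i = self.index_of(individual)
        s = self.sire[i].item() if hasattr(self.sire[i], "item") else self.sire[i]
        d = self.dam[i].item() if hasattr(self.dam[i], "item") else self.dam[i]
        return (s if s != 0 else None, d if d != 0 else None)

    @property
    def records(self) -> list[tuple]:
        return list(zip(self.ids.tolist(), self.sire.tolist(), self.dam.tolist(),
                        self.sex.tolist(), self.generation.tolist()))


@dataclass
class PhasedPanel:
    """Phased diploid SNP panel.

    ``alleles[c]`` has shape ``(n_individuals, 2, n_snps)`` over {0, 1, 9}
    where gamete 0 is paternal, gamete 1 maternal and 9 marks a missing or
    unphased allele.
    """

    ids: np.ndarray
    alleles: list[np.ndarray]

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        n = len(self.ids)
        for c, arr in enumerate(self.alleles):
            if arr.ndim != 3 or arr.shape[0] != n or arr.shape[1] != 2:
                raise ValueError(f"chromosome {c}: expected shape (n, 2, n_snps)")

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_chromosomes(self) -> int:
        return len(self.alleles)

    @property
    def n_snps(self) -> list[int]:
        return [a.shape[2] for a in self.alleles]

    def phased_fraction_per_individual(self) -> np.ndarray:
        """Fraction of allele slots (over all chromosomes, both gametes) that are called."""
        tot = np.zeros(self.n_individuals)
        cnt = 0
        for a in self.alleles:
            tot += (a != MISSING).sum(axis=(1, 2))
            cnt += 2 * a.shape[2]
        return tot / cnt

    def phased_fraction_per_marker(self, individual_indices=None) -> list[np.ndarray]:
        """Per chromosome, fraction of called alleles per marker (over given individuals)."""
        out = []
        for a in self.alleles:
            sub = a if individual_indices is None else a[individual_indices]
            out.append((sub != MISSING).sum(axis=(0, 1)) / (2 * sub.shape[0]))
        return out


@dataclass
class TraitModel:
    """Additive polygenic trait: QTN marker indices, effects, and per-individual TBV."""

    qtn_indices: list[np.ndarray]   # per chromosome
    qtn_effects: list[np.ndarray]   # per chromosome
    tbv: np.ndarray                 # aligned with the panel's individuals

    def tbv_of_panel(self, panel: PhasedPanel) -> np.ndarray:
        """Recompute TBV = sum over QTN of effect x allele dosage (0/1/2)."""
        vals = np.zeros(panel.n_individuals)
        for arr, idx, eff in zip(panel.alleles, self.qtn_indices, self.qtn_effects):
            dosage = arr[:, 0, idx].astype(float) + arr[:, 1, idx].astype(float)
            vals += dosage @ eff
        return vals


@dataclass
class BaseHaplotypes:
    """Pool of founder haplotypes, one 0/1 matrix per chromosome of shape
    ``(n_base_haplotypes, n_snps_per_chr)``."""

    chromosomes: list[np.ndarray]

    @property
    def n_haplotypes(self) -> int:
        return self.chromosomes[0].shape[0]


def simulate_base_haplotypes(config: SimConfig) -> BaseHaplotypes:
    """Generate segregating binary base haplotypes.

    Marker frequencies are drawn Uniform(freq_low, freq_high); alleles are
    i.i.d. Bernoulli per haplotype. Markers that come out fixed are resampled
    so every marker segregates (minor-allele count >= 1).
    """
    rng = np.random.default_rng(config.seed)
    chroms = []
    for _ in range(config.n_chromosomes):
        p = rng.uniform(config.freq_low, config.freq_high, size=config.n_snps_per_chr)
        h = (rng.random((config.n_base_haplotypes, config.n_snps_per_chr)) < p).astype(np.int8)
        fixed = np.flatnonzero((h.sum(axis=0) == 0) | (h.sum(axis=0) == h.shape[0]))
        while fixed.size:
            h[:, fixed] = (
                rng.random((h.shape[0], fixed.size)) < p[fixed]
            ).astype(np.int8)
            col = h[:, fixed].sum(axis=0)
            fixed = fixed[(col == 0) | (col == h.shape[0])]
        chroms.append(h)
    return BaseHaplotypes(chroms)


def _meiosis(parent_pair: np.ndarray, length_morgans: float,
             rng: np.random.Generator) -> np.ndarray:
    """One gamete from a parent's chromosome pair, Haldane model.

    Markers sit at genetic positions (j + 0.5)/n_snps x length; crossovers
    are Poisson(length) with uniform positions; the starting chromosome is
    chosen at random.
    """
    n = parent_pair.shape[1]
    n_x = rng.poisson(length_morgans)
    start = rng.integers(2)
    if n_x == 0:
        return parent_pair[start]
    xpos = np.sort(rng.uniform(0.0, length_morgans, size=n_x))
    marker_pos = (np.arange(n) + 0.5) / n * length_morgans
    source = (start + np.searchsorted(xpos, marker_pos)) % 2
    return parent_pair[source, np.arange(n)]


def _sample_qtn(config: SimConfig, rng: np.random.Generator) -> tuple[list[np.ndarray], list[np.ndarray]]:
    per_chr = config.n_qtn // config.n_chromosomes
    sd = np.sqrt(1.0 / config.n_qtn)
    idx, eff = [], []
    for _ in range(config.n_chromosomes):
        idx.append(np.sort(rng.choice(config.n_snps_per_chr, size=per_chr, replace=False)))
        eff.append(rng.normal(0.0, sd, size=per_chr))
    return idx, eff


def simulate_pedigree_population(
    config: SimConfig, base: BaseHaplotypes
) -> tuple[Pedigree, PhasedPanel, TraitModel]:
    """Breed a discrete-generation population from base haplotypes.

    The founder generation draws each individual's two chromosomes without
    replacement (within individual) from the base pool. Each later generation
    of ``n_per_generation`` individuals (alternating sex, so exactly half
    male) has its sire drawn uniformly from the ``n_sires_selected``
    highest-TBV males of the previous generation (or from all males if
    ``sire_selection == 'random'``) and its dam drawn uniformly from the
    ``n_dams`` females. Gametes are formed by Haldane recombination, so the
    panel is fully phased by construction.

    Returns ``n_per_generation * (n_generations + 1)`` individuals: the
    founder generation plus ``n_generations`` bred generations.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    if config.n_generations < 1:
        raise ValueError("simulate_pedigree_population requires n_generations >= 1")

    n = config.n_per_generation
    n_gen_total = config.n_generations + 1
    total = n * n_gen_total
    qtn_idx, qtn_eff = _sample_qtn(config, rng)

    alleles = [np.empty((total, 2, config.n_snps_per_chr), dtype=np.int8)
               for _ in range(config.n_chromosomes)]
    ids = np.arange(1, total + 1)
    sire = np.zeros(total, dtype=ids.dtype)
    dam = np.zeros(total, dtype=ids.dtype)
    sex = np.where(np.arange(total) % 2 == 0, MALE, FEMALE)
    generation = np.repeat(np.arange(n_gen_total), n)

    # founders: two base haplotypes per chromosome, distinct within individual
    for c, pool in enumerate(base.chromosomes):
        for i in range(n):
            picks = rng.choice(pool.shape[0], size=2, replace=False)
            alleles[c][i] = pool[picks]

    tbv = np.zeros(total)

    def _tbv_rows(lo: int, hi: int) -> np.ndarray:
        vals = np.zeros(hi - lo)
        for c in range(config.n_chromosomes):
            dosage = (alleles[c][lo:hi, 0, qtn_idx[c]].astype(float)
                      + alleles[c][lo:hi, 1, qtn_idx[c]].astype(float))
            vals += dosage @ qtn_eff[c]
        return vals

    tbv[:n] = _tbv_rows(0, n)

    for g in range(1, n_gen_total):
        prev = slice((g - 1) * n, g * n)
        prev_rows = np.arange(*prev.indices(total))
        males = prev_rows[sex[prev] == MALE]
        females = prev_rows[sex[prev] == FEMALE]
        if males.size == 0 or females.size == 0:
            raise ValueError(f"generation {g - 1} lacks males or females")
        if config.sire_selection == "truncation":
            order = males[np.argsort(tbv[males], kind="stable")[::-1]]
            sires = order[: config.n_sires_selected]
        else:
            sires = males
        dams = females[: config.n_dams]

        lo = g * n
        chosen_s = rng.choice(sires, size=n)
        chosen_d = rng.choice(dams, size=n)
        sire[lo:lo + n] = ids[chosen_s]
        dam[lo:lo + n] = ids[chosen_d]
        for c in range(config.n_chromosomes):
            arr = alleles[c]
            for off in range(n):
                row = lo + off
                arr[row, 0] = _meiosis(arr[chosen_s[off]], config.chr_length_morgans, rng)
                arr[row, 1] = _meiosis(arr[chosen_d[off]], config.chr_length_morgans, rng)
        tbv[lo:lo + n] = _tbv_rows(lo, lo + n)

    ped = Pedigree(ids, sire, dam, sex, generation)
    panel = PhasedPanel(ids, alleles)
    trait = TraitModel(qtn_idx, qtn_eff, tbv)
    return ped, panel, trait


def simulate_unrelated_population(
    config: SimConfig, base: BaseHaplotypes
) -> tuple[Pedigree, PhasedPanel]:
    """Draw a nominally unrelated population straight from the base pool.

    Each individual's two chromosomes are drawn independently and uniformly
    (with replacement) from the base haplotypes; all parents are unknown.
    """
    if config.n_unrelated < 1:
        raise ValueError("n_unrelated must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    n = config.n_unrelated
    ids = np.arange(1, n + 1)
    alleles = []
    for pool in base.chromosomes:
        picks = rng.integers(pool.shape[0], size=(n, 2))
        alleles.append(pool[picks].astype(np.int8))
    zeros = np.zeros(n, dtype=ids.dtype)
    sex = np.where(np.arange(n) % 2 == 0, MALE, FEMALE)
    ped = Pedigree(ids, zeros, zeros.copy(), sex, np.zeros(n, dtype=int))
    return ped, PhasedPanel(ids, alleles)
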