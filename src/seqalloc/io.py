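"""Readers, writers and the end-to-end pipeline.

On-disk conventions: marker indices are 1-based in files and 0-based
internally. The phased-panel text dialect has two space-delimited rows per
individual (paternal gamete then maternal), each ``id a1 a2 ...`` with
missing alleles coded 9; multi-chromosome panels are stored as one file per
chromosome (``chr1.phase``, ``chr2.phase``, ...) in a directory. Phased VCF
is read and written through pysam; a ``/``-separated genotype is treated as
unphased (both alleles missing) at that marker.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import budget as budget_mod
from . import focal as focal_mod
from . import haplib as haplib_mod
from . import keyanc as keyanc_mod  # noqa: F401  (re-exported for pipeline users)
from . import popsim
from .popsim import MISSING, Pedigree, PhasedPanel

log = logging.getLogger(__name__)


def _parse_id(token: str):
    try:
        return int(token)
    except ValueError:
        return token


# ---------------------------------------------------------------- pedigree

def write_pedigree(pedigree: Pedigree, path, include_sex: bool = False) -> None:
    """Whitespace-delimited ``id sire dam [sex]`` with 0 for unknown."""
    with open(path, "w") as fh:
        for ind, s, d, sex, _g in pedigree.records:
            row = f"{ind} {s} {d}"
            if include_sex:
                row += f" {sex}"
            fh.write(row + "\n")


def read_pedigree(path) -> Pedigree:
    """Read ``id sire dam [sex]`` (whitespace or comma delimited).

    Rows are topologically sorted so parents precede offspring; a cycle
    (an individual among its own ancestors) raises a ValueError.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            toks = re.split(r"[\s,]+", line)
            if len(toks) not in (3, 4):
                raise ValueError(f"{path}: line {ln}: expected 3 or 4 columns")
            ind, s, d = (_parse_id(t) for t in toks[:3])
            sex = int(toks[3]) if len(toks) == 4 else 0
            rows.append((ind, s, d, sex))
    if not rows:
        raise ValueError(f"{path}: empty pedigree")
    ids = [r[0] for r in rows]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate individual ids")
    by_id = {r[0]: r for r in rows}
    order: list = []
    state: dict = {}  # 0 visiting, 1 done

    for root in ids:
        if root in state:
            continue
        stack = [(root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                state[node] = 1
                order.append(node)
                continue
            if state.get(node) == 1:
                continue
            if state.get(node) == 0:
                raise ValueError(f"{path}: pedigree cycle involving {node!r}")
            state[node] = 0
            stack.append((node, True))
            for parent in by_id[node][1:3]:
                if parent != 0 and parent in by_id and state.get(parent) != 1:
                    if state.get(parent) == 0:
                        raise ValueError(f"{path}: pedigree cycle involving {parent!r}")
                    stack.append((parent, False))

    rows_sorted = [by_id[i] for i in order]
    sex = np.asarray([r[3] for r in rows_sorted])
    # infer sex from parent roles where unstated
    for r in rows_sorted:
        for parent, want in ((r[1], popsim.MALE), (r[2], popsim.FEMALE)):
            if parent != 0 and parent in by_id:
                j = order.index(parent)
                if sex[j] == 0:
                    sex[j] = want
    return Pedigree(
        ids=np.asarray(order),
        sire=np.asarray([r[1] for r in rows_sorted]),
        dam=np.asarray([r[2] for r in rows_sorted]),
        sex=sex,
        generation=np.full(len(order), -1),
    )


# ---------------------------------------------------------------- phased panel

def write_phase_file(panel: PhasedPanel, chrom: int, path) -> None:
    with open(path, "w") as fh:
        arr = panel.alleles[chrom]
        for i, ind in enumerate(panel.ids.tolist()):
            for g in range(2):
                fh.write(f"{ind} " + " ".join(map(str, arr[i, g].tolist())) + "\n")


def write_panel(panel: PhasedPanel, directory) -> list[Path]:
    """Write one ``chr<N>.phase`` file per chromosome into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for c in range(panel.n_chromosomes):
        p = directory / f"chr{c + 1}.phase"
        write_phase_file(panel, c, p)
        paths.append(p)
    return paths


def _read_phase_file(path) -> tuple[list, np.ndarray]:
    ids: list = []
    rows: list[list[int]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            toks = line.split()
            ids.append(_parse_id(toks[0]))
            rows.append([int(t) for t in toks[1:]])
    if not rows:
        raise ValueError(f"{path}: empty phased panel file")
    if len(rows) % 2 != 0:
        raise ValueError(f"{path}: odd number of gamete rows")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ValueError(f"{path}: ragged rows (marker counts {sorted(widths)})")
    inds = ids[0::2]
    if any(a != b for a, b in zip(inds, ids[1::2])):
        raise ValueError(f"{path}: paternal/maternal row ids do not pair up")
    if len(set(inds)) != len(inds):
        raise ValueError(f"{path}: duplicate individual ids")
    arr = np.asarray(rows, dtype=np.int8).reshape(len(inds), 2, -1)
    return inds, arr


def read_panel(source) -> PhasedPanel:
    """Read a phased panel from a directory of ``chr*.phase`` files, a list of
    per-chromosome paths, or a single file (one chromosome)."""
    if isinstance(source, (str, Path)) and Path(source).is_dir():
        paths = sorted(Path(source).glob("chr*.phase"),
                       key=lambda p: int(re.search(r"chr(\d+)", p.name).group(1)))
        if not paths:
            raise ValueError(f"{source}: no chr*.phase files found")
    elif isinstance(source, (str, Path)):
        paths = [Path(source)]
    else:
        paths = [Path(p) for p in source]
    ids0 = None
    alleles = []
    for p in paths:
        ids, arr = _read_phase_file(p)
        if ids0 is None:
            ids0 = ids
        elif ids != ids0:
            raise ValueError(f"{p}: individual ids differ across chromosome files")
        alleles.append(arr)
    return PhasedPanel(np.asarray(ids0), alleles)


def read_phased_vcf(path) -> PhasedPanel:
    """Read a VCF into a phased panel; unphased (``/``) or missing genotypes
    become missing alleles at that marker."""
    import pysam

    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    if not samples:
        raise ValueError(f"{path}: VCF has no samples")
    per_chrom: dict[str, list[np.ndarray]] = {}
    chrom_order: list[str] = []
    n_records = 0
    for rec in vf:
        n_records += 1
        col = np.full((len(samples), 2), MISSING, dtype=np.int8)
        for i, s in enumerate(samples):
            call = rec.samples[s]
            alleles = call["GT"]
            if (call.phased and alleles is not None and len(alleles) == 2
                    and alleles[0] is not None and alleles[1] is not None):
                col[i, 0] = alleles[0]
                col[i, 1] = alleles[1]
        if rec.chrom not in per_chrom:
            per_chrom[rec.chrom] = []
            chrom_order.append(rec.chrom)
        per_chrom[rec.chrom].append(col)
    if n_records == 0:
        raise ValueError(f"{path}: VCF has no variant records")
    alleles = [np.stack(per_chrom[c], axis=2) for c in chrom_order]
    return PhasedPanel(np.asarray([_parse_id(s) for s in samples]), alleles)


def write_phased_vcf(panel: PhasedPanel, path) -> None:
    """Write the panel as a minimal phased VCF (chromosomes ``1..C``,
    positions ``1..n``, alleles A/T); missing alleles become unphased
    ``./.`` genotypes."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for c in range(panel.n_chromosomes):
        header.contigs.add(str(c + 1), length=panel.n_snps[c] + 1)
    for ind in panel.ids.tolist():
        header.add_sample(str(ind))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for c, arr in enumerate(panel.alleles):
            for j in range(arr.shape[2]):
                rec = out.new_record(contig=str(c + 1), start=j, stop=j + 1,
                                     alleles=("A", "T"))
                for i, ind in enumerate(panel.ids.tolist()):
                    a = arr[i, :, j]
                    if MISSING in a:
                        rec.samples[str(ind)]["GT"] = (None, None)
                    else:
                        rec.samples[str(ind)]["GT"] = (int(a[0]), int(a[1]))
                        rec.samples[str(ind)].phased = True
                out.write(rec)


# ---------------------------------------------------------------- CSV helpers

def write_ranking(ranking: focal_mod.FocalRanking, path) -> None:
    ranking.to_frame().to_csv(path, index=False)


def read_ranking(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"rank", "id", "marginal_proportion", "cumulative_proportion"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing ranking columns {sorted(missing)}")
    return df


def read_prior(path) -> budget_mod.PriorSequencing:
    """CSV ``id,coverage,has_library``."""
    df = pd.read_csv(path)
    records = [(_parse_id(str(r.id)), float(r.coverage), bool(int(r.has_library)))
               for r in df.itertuples()]
    return budget_mod.PriorSequencing(records)


def read_accuracy_table(path) -> budget_mod.TableAccuracy:
    """CSV with columns c1..c7 (coverages in role order) and phi."""
    df = pd.read_csv(path)
    cols = [f"c{i}" for i in range(1, 8)]
    if not set(cols + ["phi"]).issubset(df.columns):
        raise ValueError(f"{path}: expected columns {cols + ['phi']}")
    table = {tuple(float(r[c]) for c in cols): float(r["phi"])
             for _, r in df.iterrows()}
    return budget_mod.TableAccuracy(table)


def write_allocation(result: budget_mod.AllocationResult,
                     families, csv_path, json_path=None) -> None:
    rows = []
    written = set()
    for f, (fam, scen) in enumerate(zip(families, result.family_scenarios)):
        for role, ind, cov in zip(budget_mod.ROLES, fam.members, scen.coverages):
            if ind is None or ind in written:
                continue
            written.add(ind)
            rows.append({"id": ind, "role": role, "family": f + 1,
                         "coverage": result.coverages.get(ind, 0.0)})
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    if json_path is not None:
        summary = {
            "total_cost": result.total_cost,
            "objective": result.objective,
            "feasible": bool(result.feasible),
            "family_phi": result.family_phi.tolist(),
            "family_p": result.family_p.tolist(),
        }
        Path(json_path).write_text(json.dumps(summary, indent=2))


# ---------------------------------------------------------------- pipeline

@dataclass
class RunConfig:
    """End-to-end configuration: simulate (or load) -> select -> allocate."""

    out_dir: Path
    panel_path: Path | None = None
    pedigree_path: Path | None = None
    prior_path: Path | None = None
    accuracy_path: Path | None = None
    sim: popsim.SimConfig | None = None
    window_length: int = 250
    min_phased: float = 0.9
    k: int = 50
    allocate: bool = False
    budget: float = 100_000.0
    cost_model: budget_mod.CostModel = field(default_factory=budget_mod.CostModel)
    coverages: tuple = budget_mod.DEFAULT_COVERAGES
    de: budget_mod.DEConfig = field(default_factory=budget_mod.DEConfig)
    seed: int = 0


def run_pipeline(config: RunConfig) -> dict:
    """Run the pipeline and write artifacts into ``config.out_dir``.

    Returns a dict of in-memory results (panel, pedigree, library, ranking,
    and allocation when requested).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pedigree = None
    try:
        if config.panel_path is not None:
            panel = (read_phased_vcf(config.panel_path)
                     if str(config.panel_path).endswith(".vcf")
                     else read_panel(config.panel_path))
            if config.pedigree_path is not None:
                pedigree = read_pedigree(config.pedigree_path)
        else:
            sim = config.sim or popsim.SimConfig(seed=config.seed)
            base = popsim.simulate_base_haplotypes(sim)
            pedigree, panel, _trait = popsim.simulate_pedigree_population(sim, base)
            write_panel(panel, out / "panel")
            write_pedigree(pedigree, out / "pedigree.txt")
    except Exception as exc:
        raise RuntimeError(f"[simulate/load] {exc}") from exc

    try:
        eligible = haplib_mod.filter_eligible(panel, config.min_phased)
        windows = haplib_mod.build_windows(
            panel.n_snps[0], config.window_length, panel.n_chromosomes)
        library = haplib_mod.build_library(panel, windows, eligible)
        log.info("library: %d haplotypes, %d copies over %d windows",
                 library.n_haplotypes, library.total_copies, len(windows))
        ranking = focal_mod.select_focal_individuals(library, config.k)
        write_ranking(ranking, out / "focal_ranking.csv")
        focal_mod.coverage_curve(ranking).to_csv(out / "coverage_curve.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"[select] {exc}") from exc

    results = {"panel": panel, "pedigree": pedigree, "library": library,
               "ranking": ranking}
    if not config.allocate:
        return results

    if pedigree is None:
        raise RuntimeError(
            "[allocate] budget allocation requires pedigree data: focal "
            "families (parents and grandparents) cannot be formed without a "
            "pedigree"
        )
    try:
        prior = read_prior(config.prior_path) if config.prior_path else None
        accuracy = (read_accuracy_table(config.accuracy_path)
                    if config.accuracy_path else None)
        families = [
            budget_mod.FamilyUnit.from_pedigree(ind, pedigree, p)
            for ind, p in zip(ranking.ids, ranking.marginal_props)
        ]
        result = budget_mod.allocate_budget(
            families, config.budget, config.cost_model, prior, accuracy,
            config.de, config.coverages)
        write_allocation(result, families, out / "allocation.csv",
                         out / "allocation_summary.json")
    except RuntimeError:
        raise
    except Exception as exc:
        raise RuntimeError(f"[allocate] {exc}") from exc
    results["families"] = families
    results["allocation"] = result
    return results
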