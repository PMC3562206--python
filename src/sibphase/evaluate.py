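"""Accuracy metrics against simulator truth, and the experiment drivers.

Isolated full-sib families are symmetric under exchanging the two parents,
so called parental genotypes are aligned to the truth block-wise (blocks
delimited by refused markers) before scoring — exactly the flip alignment a
fair comparison of any phasing method on such families requires.  Two
genotype-accuracy conventions are reported: *among-assigned* (refused
markers excluded from the denominator) and *overall* (refusals counted as
errors).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calling import PhasedResult, call_genotypes
from .errors import FormatError
from .optimize import OptimizerConfig, run
from .pedigree import MISSING, MarkerMap, Pedigree, SEX_FEMALE, SEX_MALE
from .simulate import (
    SimResult,
    StructureSpec,
    TruthSet,
    inject_allele_errors,
    mask_founders,
    simulate,
)


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------


def align_with_flips(
    result: PhasedResult, truth: TruthSet, sire: str, dam: str
) -> PhasedResult:
    """Align an inferred parent pair to truth up to block-wise label swaps.

    Within each contiguous block of markers delimited by refusals (in either
    parent) the parent labelling — swapped or not — that agrees best with the
    truth is chosen; ties keep the original labels.  A globally
    parent-swapped but otherwise perfect reconstruction scores 100% after
    alignment.
    """
    out = result.copy()
    i, j = out.index_of(sire), out.index_of(dam)
    truth_i = truth.genotype_of(sire)  # (M, 2) sorted
    truth_j = truth.genotype_of(dam)
    M = truth_i.shape[0]
    boundary = out.refused[i] | out.refused[j]
    block_start = None
    blocks = []
    for m in range(M):
        if boundary[m]:
            if block_start is not None:
                blocks.append((block_start, m))
                block_start = None
        elif block_start is None:
            block_start = m
    if block_start is not None:
        blocks.append((block_start, M))

    def agreement(row: int, tg: np.ndarray, a: int, b: int) -> int:
        called = out.alleles[row, a:b]
        ok = (np.sort(called, axis=1) == tg[a:b]).all(axis=1)
        ok &= called[:, 0] != MISSING
        return int(ok.sum())

    for a, b in blocks:
        keep = agreement(i, truth_i, a, b) + agreement(j, truth_j, a, b)
        swap = agreement(i, truth_j, a, b) + agreement(j, truth_i, a, b)
        if swap > keep:
            for arr in (
                out.alleles,
                out.refused,
                out.phase_known,
                out.call_confidence,
                out.phase_confidence,
                out.skewness,
            ):
                tmp = arr[i, a:b].copy()
                arr[i, a:b] = arr[j, a:b]
                arr[j, a:b] = tmp
    return out


def align_inferred_fullsib_families(
    result: PhasedResult, truth: TruthSet, pedigree: Pedigree, optimize_mask
) -> PhasedResult:
    """Apply :func:`align_with_flips` to every isolated full-sib mating whose
    parents were both inferred."""
    out = result
    for sire, dam, children in pedigree.matings():
        si, di = result.index_of(sire), result.index_of(dam)
        if not (optimize_mask[si] and optimize_mask[di]):
            continue
        if len(pedigree.children_of(sire)) != len(children):
            continue
        if len(pedigree.children_of(dam)) != len(children):
            continue
        out = align_with_flips(out, truth, sire, dam)
    return out


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def switch_errors(
    called: np.ndarray, truth_hap: np.ndarray, usable: np.ndarray
) -> tuple[int, int]:
    """Count phase switches between consecutive informative het markers.

    A marker is informative when usable (called + phased), heterozygous, and
    its called genotype matches the truth.  Returns ``(n_switches,
    n_informative_pairs)``.
    """
    het = truth_hap[:, 0] != truth_hap[:, 1]
    ok = usable & het
    ok &= (np.sort(called, axis=1) == np.sort(truth_hap, axis=1)).all(axis=1)
    idx = np.flatnonzero(ok)
    if idx.size < 2:
        return 0, 0
    orient = (called[idx, 0] != truth_hap[idx, 0]).astype(int)
    return int(np.sum(orient[1:] != orient[:-1])), int(idx.size - 1)


@dataclass
class AccuracyReport:
    """Genotype and phasing accuracy per individual group.

    ``table`` has one row per group with columns ``n_markers, n_called,
    n_correct, among_assigned, overall, refused_rate, switch_error_rate``;
    ``among_assigned`` is NaN for a group with no called markers.
    """

    table: pd.DataFrame
    per_individual: pd.DataFrame

    def get(self, group: str, metric: str) -> float:
        return float(self.table.loc[group, metric])


def classify_individuals(pedigree: Pedigree) -> dict[str, list[str]]:
    founders = [ind.id for ind in pedigree.founders]
    sires = [
        ind.id
        for ind in pedigree.founders
        if ind.sex == SEX_MALE and pedigree.children_of(ind.id)
    ]
    dams = [
        ind.id
        for ind in pedigree.founders
        if ind.sex == SEX_FEMALE and pedigree.children_of(ind.id)
    ]
    offspring = [ind.id for ind in pedigree.nonfounders]
    return {
        "founders": founders,
        "sires": sires,
        "dams": dams,
        "offspring": offspring,
        "all": [ind.id for ind in pedigree.individuals],
    }


def score(
    result: PhasedResult, truth: TruthSet, pedigree: Pedigree
) -> AccuracyReport:
    """Compare called genotypes (as unordered pairs) and phases with truth."""
    rows = []
    for ind in pedigree.individuals:
        i = result.index_of(ind.id)
        called = result.alleles[i]
        refused = result.refused[i]
        tg = truth.genotype_of(ind.id)
        if called.shape[0] != tg.shape[0]:
            raise FormatError("marker count mismatch between calls and truth")
        assigned = ~refused
        correct = assigned & (np.sort(called, axis=1) == tg).all(axis=1)
        sw, sw_n = switch_errors(
            called, truth.haplotypes_of(ind.id), assigned & result.phase_known[i]
        )
        rows.append(
            {
                "individual": ind.id,
                "n_markers": called.shape[0],
                "n_called": int(assigned.sum()),
                "n_correct": int(correct.sum()),
                "n_switches": sw,
                "n_switch_pairs": sw_n,
            }
        )
    per_ind = pd.DataFrame(rows).set_index("individual")

    groups = classify_individuals(pedigree)
    out = []
    for name, members in groups.items():
        sub = per_ind.loc[[m for m in members if m in per_ind.index]]
        n_markers = int(sub["n_markers"].sum())
        n_called = int(sub["n_called"].sum())
        n_correct = int(sub["n_correct"].sum())
        sw_pairs = int(sub["n_switch_pairs"].sum())
        out.append(
            {
                "group": name,
                "n_markers": n_markers,
                "n_called": n_called,
                "n_correct": n_correct,
                "among_assigned": n_correct / n_called if n_called else np.nan,
                "overall": n_correct / n_markers if n_markers else np.nan,
                "refused_rate": 1.0 - n_called / n_markers if n_markers else np.nan,
                "switch_error_rate": (
                    sub["n_switches"].sum() / sw_pairs if sw_pairs else 0.0
                ),
            }
        )
    return AccuracyReport(
        table=pd.DataFrame(out).set_index("group"), per_individual=per_ind
    )


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------


def _fit_config(n_iterations: int, error_tolerant: bool, seed: int) -> OptimizerConfig:
    return OptimizerConfig(
        k=1,
        n_iterations=n_iterations,
        error_tolerant=error_tolerant,
        update_sureness=True,
        update_recombination=False,
        seed=seed,
    )


def fullsib_replicate(
    n_offspring: int,
    n_markers: int = 200,
    spacing_cM: float = 0.05,
    seed: int = 0,
    n_iterations: int = 150,
    error_rate: float = 0.0,
) -> AccuracyReport:
    """One isolated full-sib family with both parents masked: simulate,
    fit, call, align and score the two parents."""
    spec = StructureSpec(
        n_sires=1,
        dams_per_sire=1,
        offspring_per_mating=n_offspring,
        n_markers=n_markers,
        spacing_cM=spacing_cM,
        seed=seed,
    )
    sim = simulate(spec)
    geno = sim.genotypes
    if error_rate > 0:
        rng = np.random.default_rng(seed + 1_000_003)
        geno, _ = inject_allele_errors(
            geno, error_rate, rng, sim.marker_map, sim.pedigree
        )
    geno = mask_founders(geno, sim.pedigree)
    fit = run(
        sim.pedigree, geno, sim.marker_map,
        _fit_config(n_iterations, error_rate > 0, seed),
    )
    result = call_genotypes(fit)
    result = align_inferred_fullsib_families(
        result, sim.truth, sim.pedigree, fit.params.optimize_genotype
    )
    return score(result, sim.truth, sim.pedigree)


def structure_replicate(
    n_sires: int = 2,
    dams_per_sire: int = 10,
    offspring_per_mating: int = 15,
    n_markers: int = 300,
    spacing_cM: float = 0.05,
    seed: int = 0,
    n_iterations: int = 150,
    error_rate: float = 0.0,
) -> AccuracyReport:
    """Repeated-mating structure with all founders masked: each sire's
    presence in several matings lets cross-family information resolve
    markers that are undecidable within one family."""
    spec = StructureSpec(
        n_sires=n_sires,
        dams_per_sire=dams_per_sire,
        offspring_per_mating=offspring_per_mating,
        n_markers=n_markers,
        spacing_cM=spacing_cM,
        seed=seed,
    )
    sim = simulate(spec)
    geno = sim.genotypes
    if error_rate > 0:
        rng = np.random.default_rng(seed + 1_000_003)
        geno, _ = inject_allele_errors(
            geno, error_rate, rng, sim.marker_map, sim.pedigree
        )
    geno = mask_founders(geno, sim.pedigree)
    fit = run(
        sim.pedigree, geno, sim.marker_map,
        _fit_config(n_iterations, error_rate > 0, seed),
    )
    result = call_genotypes(fit)
    result = align_inferred_fullsib_families(
        result, sim.truth, sim.pedigree, fit.params.optimize_genotype
    )
    return score(result, sim.truth, sim.pedigree)


def experiment_fullsib_curve(
    family_sizes=range(2, 16),
    n_replicates: int = 20,
    n_markers: int = 200,
    spacing_cM: float = 0.05,
    n_iterations: int = 150,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Mean parental reconstruction accuracy versus full-sib family size.

    Returns one row per family size with the mean among-assigned accuracy
    and refusal rate over replicates (accuracy grows with family size; the
    refusal floor is set by the both-parents-homozygous-different rate).
    """
    rows = []
    for size in family_sizes:
        acc, ref = [], []
        for rep in range(n_replicates):
            report = fullsib_replicate(
                size,
                n_markers=n_markers,
                spacing_cM=spacing_cM,
                seed=base_seed + 7919 * size + rep,
                n_iterations=n_iterations,
            )
            a = report.get("founders", "among_assigned")
            if not np.isnan(a):
                acc.append(a)
            ref.append(report.get("founders", "refused_rate"))
        rows.append(
            {
                "family_size": size,
                "n_replicates": n_replicates,
                "among_assigned": float(np.mean(acc)) if acc else np.nan,
                "refused_rate": float(np.mean(ref)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# truth files (text round-trip for the CLI)
# ---------------------------------------------------------------------------


def write_truth(path, truth: TruthSet, marker_map: MarkerMap) -> None:
    """Ground-truth haplotypes as TSV: individual, marker, hap0, hap1."""
    n, M, _ = truth.haplotypes.shape
    dec0 = np.empty((n, M), dtype=object)
    dec1 = np.empty((n, M), dtype=object)
    for m in range(M):
        dec0[:, m] = [marker_map.decode_allele(m, v) for v in truth.haplotypes[:, m, 0]]
        dec1[:, m] = [marker_map.decode_allele(m, v) for v in truth.haplotypes[:, m, 1]]
    pd.DataFrame(
        {
            "individual": np.repeat(truth.ids, M),
            "marker": np.tile(np.arange(1, M + 1), n),
            "hap0": dec0.ravel(),
            "hap1": dec1.ravel(),
        }
    ).to_csv(path, sep="\t", index=False)


def score_frames(calls: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """File-level scoring for the CLI: per-individual among-assigned and
    overall genotype accuracy from a phased-calls TSV and a truth TSV."""
    t = truth.set_index(["individual", "marker"])
    rows = []
    for ind, sub in calls.groupby("individual", sort=False):
        sub = sub.sort_values("marker")
        tt = t.loc[ind].sort_index()
        called = sub["refused"].to_numpy() == 0
        pair = np.sort(sub[["allele0", "allele1"]].astype(str).to_numpy(), axis=1)
        tp = np.sort(tt[["hap0", "hap1"]].astype(str).to_numpy(), axis=1)
        correct = called & (pair == tp).all(axis=1)
        rows.append(
            {
                "individual": ind,
                "n_markers": len(sub),
                "n_called": int(called.sum()),
                "n_correct": int(correct.sum()),
                "among_assigned": (
                    correct.sum() / called.sum() if called.any() else np.nan
                ),
                "overall": correct.sum() / len(sub),
            }
        )
    return pd.DataFrame(rows)
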