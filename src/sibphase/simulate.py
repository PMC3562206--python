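"""Synthetic pedigree/genotype generator with full ground truth.

Emulates a repeated-mating livestock design: ``n_sires`` sires, each mated to
``dams_per_sire`` dams, each mating producing ``offspring_per_mating``
full sibs.  Founders (sires + dams) are drawn in linkage equilibrium from
per-marker allele frequencies; each meiosis recombines independently between
adjacent markers with the Haldane fraction for the marker spacing (no
crossover interference), matching the transition model of the phasing HMM.

The default structure (20 sires x 10 dams x 15 offspring, 1,998 biallelic
markers at 0.05 cM) yields 3,220 individuals of which 220 are founders.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .errors import ParameterError
from .hmm import haldane_r
from .pedigree import (
    MISSING,
    GenotypeMatrix,
    Individual,
    MarkerMap,
    Pedigree,
    SEX_FEMALE,
    SEX_MALE,
)


@dataclass
class StructureSpec:
    """Shape and marker layout of a simulated population.

    ``allele_frequencies`` may be ``None`` (all markers biallelic at 0.5/0.5),
    an array of shape ``(n_markers, n_alleles)``, or drawn per marker from a
    Beta distribution via ``freq_beta=(a, b)`` to emulate a skewed frequency
    spectrum.
    """

    n_sires: int = 20
    dams_per_sire: int = 10
    offspring_per_mating: int = 15
    n_markers: int = 1998
    spacing_cM: float = 0.05
    n_alleles: int = 2
    allele_frequencies: np.ndarray | None = None
    freq_beta: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self):
        for name in ("n_sires", "dams_per_sire", "offspring_per_mating", "n_markers"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be >= 1")
        if self.spacing_cM < 0:
            raise ParameterError("spacing_cM must be nonnegative")

    def frequencies(self, rng: np.random.Generator) -> np.ndarray:
        if self.allele_frequencies is not None:
            f = np.asarray(self.allele_frequencies, dtype=float)
            if f.shape != (self.n_markers, self.n_alleles):
                raise ParameterError("allele_frequencies has wrong shape")
            if not np.allclose(f.sum(axis=1), 1.0):
                raise ParameterError("allele frequencies must sum to 1 per marker")
            return f
        if self.freq_beta is not None:
            if self.n_alleles != 2:
                raise ParameterError("freq_beta requires biallelic markers")
            p = rng.beta(*self.freq_beta, size=self.n_markers)
            return np.column_stack([p, 1.0 - p])
        return np.full((self.n_markers, self.n_alleles), 1.0 / self.n_alleles)


@dataclass
class TruthSet:
    """Ground truth accompanying a simulated dataset.

    ``haplotypes[i, m, c]`` is the allele code on chromatid ``c`` of
    individual ``i`` (chromatid 0 paternal, 1 maternal; arbitrary for
    founders).  ``recorded_swapped[i, m]`` says whether the recorded unordered
    pair lists the two chromatids in reversed order (the true skewness).
    ``crossovers`` maps (child id, side) to the 0-based interval indices where
    the transmitting gamete switched chromatids.  ``pre_error_codes`` are the
    genotypes before error injection; ``error_mask`` marks injected allele
    errors (filled by :func:`inject_allele_errors`).
    """

    ids: list[str]
    haplotypes: np.ndarray
    recorded_swapped: np.ndarray
    crossovers: dict[tuple[str, int], np.ndarray]
    pre_error_codes: np.ndarray
    error_mask: np.ndarray | None = None
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self._index = {s: i for i, s in enumerate(self.ids)}

    def haplotypes_of(self, ind_id: str) -> np.ndarray:
        return self.haplotypes[self._index[ind_id]]

    def genotype_of(self, ind_id: str) -> np.ndarray:
        """True unordered genotype (sorted pair) per marker."""
        return np.sort(self.haplotypes[self._index[ind_id]], axis=1)


class SimResult(NamedTuple):
    pedigree: Pedigree
    genotypes: GenotypeMatrix
    marker_map: MarkerMap
    truth: TruthSet


def _meiosis(parent_hap: np.ndarray, r: np.ndarray, rng: np.random.Generator
             ) -> tuple[np.ndarray, np.ndarray]:
    """One gamete from a parent's two chromatids; returns (gamete, crossover intervals)."""
    n_markers = parent_hap.shape[0]
    switch = rng.random(n_markers - 1) < r
    start = rng.integers(0, 2)
    chromatid = np.empty(n_markers, dtype=np.int8)
    chromatid[0] = start
    chromatid[1:] = (start + np.cumsum(switch)) % 2
    gamete = parent_hap[np.arange(n_markers), chromatid]
    return gamete, np.flatnonzero(switch)


def simulate(spec: StructureSpec, rng: np.random.Generator | None = None) -> SimResult:
    """Generate a pedigree, genotypes, marker map and truth set from a spec."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    M = spec.n_markers
    freqs = spec.frequencies(rng)
    r = np.full(M - 1, haldane_r(spec.spacing_cM))

    individuals: list[Individual] = []
    ids: list[str] = []
    haps: list[np.ndarray] = []
    crossovers: dict[tuple[str, int], np.ndarray] = {}

    cum_freq = np.cumsum(freqs, axis=1)

    def draw_founder_hap() -> np.ndarray:
        u = rng.random((M, 2))
        # inverse-CDF draw per chromatid from the per-marker frequencies
        return np.stack(
            [(u[:, c, None] > cum_freq[:, :-1]).sum(axis=1) for c in (0, 1)],
            axis=1,
        ).astype(np.int16)

    sires = []
    for s in range(1, spec.n_sires + 1):
        sid = f"S{s}"
        individuals.append(Individual(sid, sex=SEX_MALE, genotyped=True))
        ids.append(sid)
        haps.append(draw_founder_hap())
        sires.append(sid)

    dam_ids: dict[str, list[str]] = {}
    for sid in sires:
        dam_ids[sid] = []
        for d in range(1, spec.dams_per_sire + 1):
            did = f"D{sid[1:]}_{d}"
            individuals.append(Individual(did, sex=SEX_FEMALE, genotyped=True))
            ids.append(did)
            haps.append(draw_founder_hap())
            dam_ids[sid].append(did)

    index = {x: i for i, x in enumerate(ids)}
    for sid in sires:
        for did in dam_ids[sid]:
            for o in range(1, spec.offspring_per_mating + 1):
                oid = f"O{sid[1:]}_{did.split('_')[1]}_{o}"
                sex = SEX_MALE if rng.integers(0, 2) else SEX_FEMALE
                individuals.append(
                    Individual(oid, sire_id=sid, dam_id=did, sex=sex, genotyped=True)
                )
                pat, bp_p = _meiosis(haps[index[sid]], r, rng)
                mat, bp_m = _meiosis(haps[index[did]], r, rng)
                ids.append(oid)
                index[oid] = len(haps)
                haps.append(np.stack([pat, mat], axis=1).astype(np.int16))
                crossovers[(oid, 0)] = bp_p
                crossovers[(oid, 1)] = bp_m

    hap_arr = np.stack(haps)  # (n, M, 2)
    swapped = rng.random((len(ids), M)) < 0.5
    codes = hap_arr.copy()
    codes[swapped] = codes[swapped][:, ::-1]

    pedigree = Pedigree(individuals)
    alleles = [tuple(str(a + 1) for a in range(spec.n_alleles))] * M
    marker_map = MarkerMap(
        [f"M{m + 1}" for m in range(M)],
        np.arange(M) * spec.spacing_cM,
        alleles_per_marker=alleles,
    )
    genotypes = GenotypeMatrix(ids, codes)
    truth = TruthSet(
        ids=ids,
        haplotypes=hap_arr,
        recorded_swapped=swapped,
        crossovers=crossovers,
        pre_error_codes=codes.copy(),
    )
    return SimResult(pedigree, genotypes, marker_map, truth)


def mask_founders(genotypes: GenotypeMatrix, pedigree: Pedigree) -> GenotypeMatrix:
    """Return a copy with all founder genotypes set missing; offspring untouched."""
    out = genotypes.copy()
    for ind in pedigree.founders:
        out.codes[out.ids.index(ind.id)] = MISSING
    return out


def mask_individuals(genotypes: GenotypeMatrix, ind_ids) -> GenotypeMatrix:
    """Return a copy with the given individuals' genotypes set missing."""
    out = genotypes.copy()
    for ind_id in ind_ids:
        out.codes[out.ids.index(ind_id)] = MISSING
    return out


def inject_allele_errors(
    genotypes: GenotypeMatrix,
    rate: float,
    rng: np.random.Generator | int | None,
    marker_map: MarkerMap,
    pedigree: Pedigree | None = None,
    offspring_only: bool = True,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Miscall each recorded allele independently with probability ``rate``.

    A miscalled allele is replaced by a uniformly chosen *different* allele of
    :math:`A_m`.  By default only genotyped non-founders are perturbed.  For
    biallelic markers an allele rate of 1% yields about 2% genotype errors
    (:math:`1 - 0.99^2`).  Returns the perturbed matrix and a boolean mask of
    changed allele cells with the same shape as ``genotypes.codes``.
    """
    if not 0 <= rate < 0.5:
        raise ParameterError("error rate must be in [0, 0.5)")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    out = genotypes.copy()
    codes = out.codes
    eligible = np.ones(codes.shape[0], dtype=bool)
    if offspring_only and pedigree is not None:
        for ind in pedigree.founders:
            eligible[out.ids.index(ind.id)] = False
    n_alleles = marker_map.n_alleles()
    hit = (rng.random(codes.shape) < rate) & (codes != MISSING)
    hit &= eligible[:, None, None]
    hit &= (n_alleles > 1)[None, :, None]
    if hit.any():
        idx = np.argwhere(hit)
        for i, m, c in idx:
            k = n_alleles[m]
            shift = rng.integers(1, k)
            codes[i, m, c] = (codes[i, m, c] + shift) % k
    return out, hit
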