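"""Iteratively optimized parameter tables and their initialization.

Three tables drive the focus-pedigree HMM:

* **skewness** ``gamma[i, m]`` — probability that individual *i*'s recorded
  pair at marker *m* is reversed relative to its true chromatid order;
* **sureness** ``(a[i, m, c], s[i, m, c])`` — per chromatid slot, a candidate
  allele and the probability that it is correct (floored at 0.5, since below
  that another allele would be the better candidate);
* **recombination fractions** ``r[m]`` per marker interval.

Initialization is deliberately asymmetric where justified (hard skewness
anchors where they fix genuine symmetries, parental candidate alleles
pre-inferred from offspring by Mendelian rules, a tiny seeded jitter
separating otherwise interchangeable parents) because a fully symmetric
start would never break phase symmetry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .errors import FormatError, ParameterError
from .hmm import haldane_r
from .pedigree import MISSING, GenotypeMatrix, MarkerMap, Pedigree

GAMMA_CLAMP = 1e-6  # keeps logit(gamma) finite
SURENESS_MIN = 0.5
SURENESS_MAX = 1.0 - 1e-6
R_MIN = 1e-8
R_MAX = 0.5 - 1e-8


@dataclass
class OptimizerConfig:
    """Tuning constants of the modified Baum-Welch loop.

    ``d_gamma`` is the relaxation factor applied in logit space
    (``new = old + d * (proposed - old)``); ``rho_gamma`` caps the relative
    change of the odds ``gamma/(1-gamma)`` per iteration (resolved to 3
    without sureness updates and 1.6 with them when left ``None``).
    ``genotype_error_rate`` is the per-allele error rate used both for
    initializing parental sureness and for softening recorded genotypes in
    error-tolerant mode.
    """

    k: int = 1
    n_iterations: int = 150
    d_gamma: float = 0.1
    rho_gamma: float | None = None
    d_sureness: float | None = None  # defaults to d_gamma
    genotype_error_rate: float = 0.01
    update_sureness: bool = True
    update_recombination: bool = False
    redistribution_tolerance: float = 1e-6
    error_tolerant: bool = False
    flip_scan: bool = True
    convergence_tol: float = 1e-7
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.d_gamma <= 1.0:
            raise ParameterError("d_gamma must be in (0, 1]")
        if self.rho_gamma is not None and self.rho_gamma <= 1.0:
            raise ParameterError("rho_gamma must exceed 1")
        if not 0.0 < self.genotype_error_rate < 0.5:
            raise ParameterError("genotype_error_rate must be in (0, 0.5)")

    @property
    def resolved_rho_gamma(self) -> float:
        if self.rho_gamma is not None:
            return self.rho_gamma
        return 1.6 if self.update_sureness else 3.0

    @property
    def resolved_d_sureness(self) -> float:
        return self.d_gamma if self.d_sureness is None else self.d_sureness


@dataclass
class ParameterSet:
    """All optimizable parameters, rows ordered like the pedigree.

    ``optimize_genotype`` marks individuals whose allele/sureness tables are
    fitted (untyped first-level parents); everyone else's genotype slots stay
    at their initialization.
    """

    ids: list[str]
    gamma: np.ndarray          # (n, M)
    slot_alleles: np.ndarray   # (n, M, 2) int16 codes into A_m
    sureness: np.ndarray       # (n, M, 2)
    r: np.ndarray              # (M - 1,)
    optimize_genotype: np.ndarray  # (n,) bool
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self._index = {s: i for i, s in enumerate(self.ids)}

    def index_of(self, ind_id: str) -> int:
        return self._index[ind_id]

    @property
    def n_markers(self) -> int:
        return self.gamma.shape[1]

    def copy(self) -> "ParameterSet":
        return ParameterSet(
            ids=list(self.ids),
            gamma=self.gamma.copy(),
            slot_alleles=self.slot_alleles.copy(),
            sureness=self.sureness.copy(),
            r=self.r.copy(),
            optimize_genotype=self.optimize_genotype.copy(),
        )

    # -- checkpointing -----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Tabular form: one ``cell`` row per individual-marker plus one
        ``interval`` row per marker interval (for the recombination map)."""
        n, M = self.gamma.shape
        rows = {
            "record": np.repeat("cell", n * M),
            "individual": np.repeat(self.ids, M),
            "marker": np.tile(np.arange(1, M + 1), n),
            "gamma": self.gamma.ravel(),
            "allele0": self.slot_alleles[:, :, 0].ravel(),
            "allele1": self.slot_alleles[:, :, 1].ravel(),
            "sureness0": self.sureness[:, :, 0].ravel(),
            "sureness1": self.sureness[:, :, 1].ravel(),
            "optimized": np.repeat(self.optimize_genotype.astype(int), M),
        }
        cells = pd.DataFrame(rows)
        intervals = pd.DataFrame(
            {
                "record": "interval",
                "individual": "",
                "marker": np.arange(1, M),
                "gamma": self.r,
                "allele0": 0,
                "allele1": 0,
                "sureness0": 0.0,
                "sureness1": 0.0,
                "optimized": 0,
            }
        )
        return pd.concat([cells, intervals], ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ParameterSet":
        cells = df[df["record"] == "cell"]
        intervals = df[df["record"] == "interval"].sort_values("marker")
        ids = list(dict.fromkeys(cells["individual"].astype(str)))
        M = int(cells["marker"].max())
        n = len(ids)
        if len(cells) != n * M:
            raise FormatError("parameter table is not rectangular")
        idx = {s: i for i, s in enumerate(ids)}
        gamma = np.empty((n, M))
        alleles = np.empty((n, M, 2), dtype=np.int16)
        sureness = np.empty((n, M, 2))
        optimized = np.zeros(n, dtype=bool)
        rows_i = cells["individual"].astype(str).map(idx).to_numpy()
        rows_m = cells["marker"].to_numpy() - 1
        gamma[rows_i, rows_m] = cells["gamma"].to_numpy()
        alleles[rows_i, rows_m, 0] = cells["allele0"].to_numpy()
        alleles[rows_i, rows_m, 1] = cells["allele1"].to_numpy()
        sureness[rows_i, rows_m, 0] = cells["sureness0"].to_numpy()
        sureness[rows_i, rows_m, 1] = cells["sureness1"].to_numpy()
        optimized[rows_i] = cells["optimized"].to_numpy().astype(bool)
        return cls(
            ids=ids,
            gamma=gamma,
            slot_alleles=alleles,
            sureness=sureness,
            r=intervals["gamma"].to_numpy(),
            optimize_genotype=optimized,
        )

    def save(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def load(cls, path) -> "ParameterSet":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def clamp_gamma(gamma: np.ndarray) -> np.ndarray:
    return np.clip(gamma, GAMMA_CLAMP, 1.0 - GAMMA_CLAMP)


def clamp_sureness(sureness: np.ndarray) -> np.ndarray:
    """Project sureness into ``[0.5, 1 - 1e-6]`` (below 0.5 the labelled
    allele would no longer be the likeliest; 1 is kept open for finite logit)."""
    return np.clip(sureness, SURENESS_MIN, SURENESS_MAX)


def init_skewness(
    slot_alleles: np.ndarray, anchor_rows: np.ndarray | None = None
) -> np.ndarray:
    """Skewness start values: 0.5 everywhere except the first marker at which
    an anchored individual is heterozygous (recorded or inferred), set to ~0.

    An anchor is a *hard* phase commitment, so it is only placed where it
    fixes a genuine symmetry instead of guessing an identified quantity:
    a founder's chromatid labels are arbitrary (anchoring is gauge fixing,
    never wrong), and one offspring per fully-untyped mating pins that
    family's parent-exchange symmetry.  Anchoring every individual — whose
    phase is otherwise determined by its parents — would be wrong half the
    time and can push the over-parametrized model into corrupted parental
    genotypes before the inversion scan can repair the phase.
    ``anchor_rows`` selects the rows to anchor (default: all).
    """
    n, M, _ = slot_alleles.shape
    gamma = np.full((n, M), 0.5)
    het = slot_alleles[:, :, 0] != slot_alleles[:, :, 1]
    rows = range(n) if anchor_rows is None else np.flatnonzero(anchor_rows)
    for i in rows:
        hets = np.flatnonzero(het[i])
        if hets.size:
            gamma[i, hets[0]] = GAMMA_CLAMP
    return gamma


def anchor_individuals(pedigree: Pedigree, typed: dict[str, bool]) -> np.ndarray:
    """Rows whose first heterozygous marker gets the hard phase anchor:
    all founders, plus the first offspring of each mating whose parents are
    both untyped."""
    anchored = np.zeros(len(pedigree), dtype=bool)
    for i, ind in enumerate(pedigree.individuals):
        if ind.is_founder:
            anchored[i] = True
    for sire, dam, children in pedigree.matings():
        if not typed[sire] and not typed[dam]:
            anchored[pedigree.index_of(children[0])] = True
    return anchored


def _support_counts(
    off_codes: np.ndarray,
    n_alleles: np.ndarray,
    other_parent: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-marker, per-allele offspring evidence for a target parent.

    Returns ``(strong, carry, anchored)``, each ``(M, K)``:

    * ``carry`` — offspring whose genotype contains the allele (ambiguous
      evidence: either parent could be the carrier);
    * ``anchored`` — allele seen homozygous in some offspring, hence
      necessarily carried by *both* parents;
    * ``strong`` — offspring that force *this* parent to carry the allele:
      homozygous carriers (each requires both parents to transmit it, so a
      lone miscalled homozygote contributes only one count), and, when the
      other parent is typed, offspring whose only Mendelian split against
      that genotype assigns the allele here.

    Only ``strong`` counts translate into initial sureness above 0.5; a
    heterozygous offspring's allele that the other (unknown) parent could
    equally well have transmitted says nothing about *which* parent carries
    it, and starting it confident would freeze the over-parametrized model
    into a heterozygous interpretation of every marker.
    """
    n_off, M, _ = off_codes.shape
    K = int(n_alleles.max())
    strong = np.zeros((M, K))
    carry = np.zeros((M, K))
    anchored = np.zeros((M, K), dtype=bool)
    hom_count = np.zeros((M, K))
    for j in range(n_off):
        pair = off_codes[j]
        typed = pair[:, 0] != MISSING
        hom = typed & (pair[:, 0] == pair[:, 1])
        anchored[np.flatnonzero(hom), pair[hom, 0].astype(int)] = True
        hom_count[np.flatnonzero(hom), pair[hom, 0].astype(int)] += 1
    for j in range(n_off):
        pair = off_codes[j]
        typed = pair[:, 0] != MISSING
        for m in np.flatnonzero(typed):
            x, y = int(pair[m, 0]), int(pair[m, 1])
            carry[m, x] += 1
            if y != x:
                carry[m, y] += 1
            if other_parent is not None:
                op = {int(other_parent[m, 0]), int(other_parent[m, 1])}
                splits = [u for t, u in ((x, y), (y, x)) if t in op]
                if len(set(splits)) == 1:
                    strong[m, splits[0]] += 1
    if other_parent is None:
        strong = hom_count
    return strong, carry, anchored


def init_parent_genotypes(
    off_codes: np.ndarray,
    n_alleles: np.ndarray,
    epsilon: float,
    n_total_offspring: int | None = None,
    other_parent: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Heuristic parental genotype pre-inference from offspring genotypes.

    For each marker the two best-supported alleles among the offspring become
    the parent's slot candidates (an allele that appears homozygous in any
    offspring is necessarily carried by both parents and is anchored first;
    ties break toward the lower allele code).  Slot sureness encodes the
    support count via ``expit(support * logit(1 - epsilon) / (n / 4))`` — the
    n/4 divisor being the expected support under Hardy-Weinberg — so a lone
    supporting offspring already yields a confident start while balanced
    evidence stays near 0.5.

    Returns ``(slot_alleles (M, 2), sureness (M, 2), support (M, K))``.
    With zero genotyped offspring the parent stays an uninformed placeholder
    (allele 0, sureness 0.5).
    """
    if not 0.0 < epsilon < 0.5:
        raise ParameterError("epsilon must be in (0, 0.5)")
    n_off, M, _ = off_codes.shape
    n = n_total_offspring if n_total_offspring is not None else n_off
    strong, carry, anchored = _support_counts(off_codes, n_alleles, other_parent)
    scale = logit(1.0 - epsilon) / (max(n, 1) / 4.0)
    slot_alleles, sureness = _slots_from_support(strong, carry, anchored, scale)
    return slot_alleles, sureness, strong


def _slots_from_support(
    strong: np.ndarray, carry: np.ndarray, anchored: np.ndarray, scale: float
) -> tuple[np.ndarray, np.ndarray]:
    """Turn per-allele evidence counts into slot candidates + sureness.

    Candidates rank by (anchored, strong evidence, carriers, lower code);
    the best-supported allele fills slot 0, the runner-up slot 1.  Slot
    sureness is ``expit(strong * logit(1 - eps) / (n/4))``: confident only
    where offspring *force* this parent to carry the allele, 0.5 where the
    carrier parent is ambiguous.  A marker with a single observed allele
    gets it in both slots (homozygote candidate); a marker with no typed
    offspring stays an uninformed placeholder.
    """
    M, K = strong.shape
    big = strong.max() + carry.max() + 2.0
    order_key = (
        anchored * big * big
        + strong * big
        + carry
        - np.arange(K)[None, :] * 1e-9
    )
    top2 = np.argsort(-order_key, axis=1)[:, :2]
    slot_alleles = np.zeros((M, 2), dtype=np.int16)
    sureness = np.full((M, 2), SURENESS_MIN)
    for m in np.flatnonzero(carry.sum(axis=1) > 0):
        a0, a1 = int(top2[m, 0]), int(top2[m, 1])
        if carry[m, a1] == 0 and not anchored[m, a1]:
            a1 = a0
        slot_alleles[m] = (a0, a1)
        sureness[m, 0] = expit(strong[m, a0] * scale)
        sureness[m, 1] = expit(strong[m, a1] * scale)
    return slot_alleles, clamp_sureness(sureness)


def initialize_parameters(
    pedigree: Pedigree,
    genotypes: GenotypeMatrix,
    marker_map: MarkerMap,
    config: OptimizerConfig,
) -> ParameterSet:
    """Build the full parameter tables for a run.

    Typed individuals carry their recorded pairs (sureness 1 when genotypes
    are treated as exact, ``1 - genotype_error_rate`` in error-tolerant
    mode).  Untyped parents get Mendelian pre-inferred candidates accumulated
    over all their matings; untyped non-parents stay uninformed placeholders.
    """
    n = len(pedigree)
    M = marker_map.n_markers
    n_alleles = marker_map.n_alleles()
    ids = [ind.id for ind in pedigree.individuals]
    slot_alleles = np.zeros((n, M, 2), dtype=np.int16)
    sureness = np.full((n, M, 2), SURENESS_MIN)
    optimize_genotype = np.zeros(n, dtype=bool)

    typed_sureness = (
        1.0 - config.genotype_error_rate if config.error_tolerant else 1.0
    )
    typed = {}
    for i, ind in enumerate(pedigree.individuals):
        codes = genotypes.row(ind.id)
        present = codes[:, 0] != MISSING
        typed[ind.id] = bool(present.any())
        if typed[ind.id]:
            slot_alleles[i][present] = codes[present]
            sureness[i][present] = typed_sureness

    # untyped parents: accumulate Mendelian support over all their matings
    K = int(n_alleles.max())
    parent_strong: dict[str, np.ndarray] = {}
    parent_carry: dict[str, np.ndarray] = {}
    parent_anchor: dict[str, np.ndarray] = {}
    offspring_count: dict[str, int] = {}
    for sire, dam, children in pedigree.matings():
        off = np.stack([genotypes.row(c) for c in children])
        for parent, other in ((sire, dam), (dam, sire)):
            if typed[parent]:
                continue
            other_codes = genotypes.row(other) if typed[other] else None
            strong, carry, anchored = _support_counts(off, n_alleles, other_codes)
            parent_strong.setdefault(parent, np.zeros((M, K)))
            parent_carry.setdefault(parent, np.zeros((M, K)))
            parent_anchor.setdefault(parent, np.zeros((M, K), dtype=bool))
            parent_strong[parent] += strong
            parent_carry[parent] += carry
            parent_anchor[parent] |= anchored
            offspring_count[parent] = offspring_count.get(parent, 0) + len(children)

    rng = np.random.default_rng(config.seed)
    for parent in parent_strong:
        i = pedigree.index_of(parent)
        optimize_genotype[i] = True
        scale = logit(1.0 - config.genotype_error_rate) / (
            offspring_count[parent] / 4.0
        )
        slots, sure = _slots_from_support(
            parent_strong[parent], parent_carry[parent], parent_anchor[parent], scale
        )
        slot_alleles[i] = slots
        # Tiny seeded jitter: two untyped parents of the same offspring are
        # otherwise exactly interchangeable per marker, which freezes every
        # posterior at 0.5 (a symmetric EM stalemate).  The perturbation is
        # far below the evidence scale and only seeds the direction that the
        # dampened updates then amplify or overturn.
        sureness[i] = clamp_sureness(sure + rng.uniform(0.0, 0.02, sure.shape))

    sureness = clamp_sureness(sureness) if config.error_tolerant else np.where(
        sureness >= 1.0, 1.0, clamp_sureness(sureness)
    )
    # exact recorded genotypes keep sureness 1 in strict mode
    gamma = init_skewness(slot_alleles, anchor_individuals(pedigree, typed))
    r = np.clip(haldane_r(marker_map.intervals_cM()), R_MIN, R_MAX)
    return ParameterSet(
        ids=ids,
        gamma=gamma,
        slot_alleles=slot_alleles,
        sureness=sureness,
        r=np.asarray(r, dtype=float),
        optimize_genotype=optimize_genotype,
    )
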