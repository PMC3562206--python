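"""Turn fitted parameters into called genotypes and phased haplotypes.

A chromatid slot is *called* when its sureness clears the call threshold;
the ordering of the two slots follows the fitted skewness (reversed when
``gamma > 0.5``, flagged unphased at exactly 0.5 — homozygous markers are
always phased since both orderings coincide).

Markers in inferred parents can be *refused*: when a full-sib family's
evidence is symmetric under exchanging the two parents (classically, both
parents homozygous for different alleles, so every offspring is
heterozygous), no data can say which parent carries which allele.  The
detector is evidence-based: a marker is refused when swapping the two
parents' inferred parameters at that single marker (reversing the offspring
ordering weights accordingly) leaves the total likelihood of every affected
chain essentially unchanged (within half a log-unit, below the log 2 of a
single informative observation) — cross-family information through a shared sire breaks the
symmetry and rescues the call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import MISSING, MarkerMap
from .optimize import FitResult

CALL_THRESHOLD = 0.8
SWAP_TOL = 0.5


@dataclass
class PhasedResult:
    """Ordered allele calls with confidences and refusal flags.

    ``alleles[i, m]`` is the ordered pair (chromatid 0, chromatid 1;
    chromatid 0 is paternal for non-founders), ``MISSING`` where refused.
    ``call_confidence`` is the smaller slot sureness, ``phase_confidence``
    ``2 * |gamma - 0.5|``.
    """

    ids: list[str]
    marker_map: MarkerMap
    alleles: np.ndarray          # (n, M, 2) int16
    refused: np.ndarray          # (n, M) bool
    phase_known: np.ndarray      # (n, M) bool
    call_confidence: np.ndarray  # (n, M)
    phase_confidence: np.ndarray  # (n, M)
    skewness: np.ndarray         # (n, M)
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self._index = {s: i for i, s in enumerate(self.ids)}

    def index_of(self, ind_id: str) -> int:
        return self._index[ind_id]

    def row(self, ind_id: str) -> np.ndarray:
        return self.alleles[self._index[ind_id]]

    def copy(self) -> "PhasedResult":
        return PhasedResult(
            ids=list(self.ids),
            marker_map=self.marker_map,
            alleles=self.alleles.copy(),
            refused=self.refused.copy(),
            phase_known=self.phase_known.copy(),
            call_confidence=self.call_confidence.copy(),
            phase_confidence=self.phase_confidence.copy(),
            skewness=self.skewness.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        n, M, _ = self.alleles.shape
        dec = np.empty((n, M, 2), dtype=object)
        for m in range(M):
            for c in (0, 1):
                col = self.alleles[:, m, c]
                dec[:, m, c] = [
                    "." if v == MISSING else self.marker_map.decode_allele(m, v)
                    for v in col
                ]
        return pd.DataFrame(
            {
                "individual": np.repeat(self.ids, M),
                "marker": np.tile(np.arange(1, M + 1), n),
                "allele0": dec[:, :, 0].ravel(),
                "allele1": dec[:, :, 1].ravel(),
                "skewness": self.skewness.ravel(),
                "sureness0": self.call_confidence.ravel(),
                "sureness1": self.call_confidence.ravel(),
                "refused": self.refused.astype(int).ravel(),
            }
        )

    def summary(self) -> dict:
        """Per-individual call counts, ready for accuracy bookkeeping."""
        out = {}
        for i, ind_id in enumerate(self.ids):
            out[ind_id] = {
                "n_markers": int(self.alleles.shape[1]),
                "n_called": int((~self.refused[i]).sum()),
                "n_refused": int(self.refused[i].sum()),
                "n_phased": int((self.phase_known[i] & ~self.refused[i]).sum()),
                "mean_confidence": float(
                    self.call_confidence[i][~self.refused[i]].mean()
                ) if (~self.refused[i]).any() else float("nan"),
            }
        return out


def extract_haplotypes(
    gamma: np.ndarray, slot_alleles: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Order slot pairs into chromatid pairs by the skewness threshold rule.

    ``gamma < 0.5`` keeps the recorded slot order, ``> 0.5`` reverses it,
    exactly 0.5 is flagged unphased (homozygous markers stay phased: both
    orderings are outwardly identical).  Returns ``(ordered (n, M, 2),
    phase_known (n, M))``.
    """
    reverse = gamma > 0.5
    ordered = slot_alleles.copy()
    ordered[reverse] = ordered[reverse][:, ::-1]
    hom = slot_alleles[:, :, 0] == slot_alleles[:, :, 1]
    phase_known = (gamma != 0.5) | hom
    return ordered, phase_known


def call_genotypes(
    fit: FitResult,
    call_threshold: float = CALL_THRESHOLD,
    swap_tol: float = SWAP_TOL,
    swap_refusal: bool = True,
) -> PhasedResult:
    """Call phased genotypes from a fitted model.

    A marker is refused when either slot's sureness falls below
    ``call_threshold``, or (for inferred parent pairs) when the single-marker
    parent-swap likelihood test detects symmetric ambiguity and the two
    parents' called genotypes differ.
    """
    params = fit.params
    n, M, _ = params.slot_alleles.shape
    ordered, phase_known = extract_haplotypes(params.gamma, params.slot_alleles)
    conf = params.sureness.min(axis=2)
    refused = conf < call_threshold
    if swap_refusal:
        refused |= _parent_swap_ambiguity(fit, swap_tol)
    alleles = ordered.copy()
    alleles[refused] = MISSING
    return PhasedResult(
        ids=list(params.ids),
        marker_map=fit.marker_map,
        alleles=alleles,
        refused=refused,
        phase_known=phase_known,
        call_confidence=conf,
        phase_confidence=2.0 * np.abs(params.gamma - 0.5),
        skewness=params.gamma.copy(),
    )


def _inferred_matings(fit: FitResult) -> list[tuple[int, int]]:
    params = fit.params
    out = []
    for sire, dam, _children in fit.pedigree.matings():
        si, di = params.index_of(sire), params.index_of(dam)
        if params.optimize_genotype[si] and params.optimize_genotype[di]:
            out.append((si, di))
    return out


def _parent_swap_ambiguity(fit: FitResult, swap_tol: float) -> np.ndarray:
    """Markers to refuse because parent assignment is undecidable.

    For every mating with both parents inferred, a marker is refused when
    the two parents' called genotype contents differ there, yet exchanging
    the parents' parameters at that single marker is likelihood-neutral
    across *all* chains touching either parent (``(n, M)`` bool, set on both
    parents' rows).  The test is per mating: a shared sire is rescued at a
    marker whenever any of its other families pins its genotype down.
    """
    opt = fit.optimizer
    params = fit.params
    n, M = params.gamma.shape
    ambiguous = np.zeros((n, M), dtype=bool)
    esteps, _ = opt.e_step()

    for sire, dam, children in fit.pedigree.matings():
        si, di = params.index_of(sire), params.index_of(dam)
        if not (params.optimize_genotype[si] and params.optimize_genotype[di]):
            continue
        differ = np.any(
            np.sort(params.slot_alleles[si], axis=1)
            != np.sort(params.slot_alleles[di], axis=1),
            axis=1,
        )
        if not differ.any():
            continue
        child_rows = {params.index_of(c) for c in children}
        delta = np.zeros(M)
        for batch, es in zip(opt.batches, esteps):
            rows = batch.member_rows  # (B, N)
            affected = np.any((rows == si) | (rows == di), axis=1)
            if not affected.any():
                continue
            sel = np.flatnonzero(affected)
            slotp, gamma = opt._batch_slotp_gamma(batch)
            slotp_mod = slotp[sel].copy()
            gamma_mod = gamma[sel].copy()
            # swap the two parents' parameter columns; reverse the ordering
            # weights of this mating's offspring
            for k, b in enumerate(sel):
                for mem in range(batch.engine.n_members):
                    row = rows[b, mem]
                    if row == si:
                        slotp_mod[k, mem] = _member_slotp(opt, di)
                        gamma_mod[k, mem] = params.gamma[di]
                    elif row == di:
                        slotp_mod[k, mem] = _member_slotp(opt, si)
                        gamma_mod[k, mem] = params.gamma[si]
                    elif row in child_rows:
                        gamma_mod[k, mem] = 1.0 - gamma_mod[k, mem]
            E_mod = batch.engine.emissions(slotp_mod, gamma_mod)
            Efl = batch.engine._floor(es.E[sel], fit.config.error_tolerant)
            E_mod = batch.engine._floor(E_mod, fit.config.error_tolerant)
            d = batch.engine.loglik_delta_single_marker(es.post[sel], Efl, E_mod)
            delta += np.abs(d).sum(axis=0)
        amb = differ & (delta < swap_tol)
        ambiguous[si] |= amb
        ambiguous[di] |= amb
    return ambiguous


def _member_slotp(opt, row: int) -> np.ndarray:
    """(2, M, K) slot distributions of one parameter row."""
    from .hmm import slot_distributions

    alleles = np.moveaxis(opt.params.slot_alleles[row], 1, 0)  # (2, M)
    sure = np.moveaxis(opt.params.sureness[row], 1, 0)
    return slot_distributions(alleles, sure, opt.n_alleles)
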