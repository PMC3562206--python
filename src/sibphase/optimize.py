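"""Modified Baum-Welch fitting of skewness, sureness and recombination maps.

Each iteration runs the forward-backward pass over every focus pedigree
(the E-step; chains sharing a shape are evaluated as one numpy batch) and
then applies, in order: dampened skewness updates, dampened sureness updates
for inferred first-level parents, recombination-fraction updates, a
downstream-inversion ("flip") scan, and an optional recombination
redistribution sweep.

The skewness/sureness updates are deliberately *not* plain Baum-Welch
re-estimates: the per-cell posterior log-odds collected from all focus
pedigrees are averaged by weight, and the step in logit space is relaxed by
a factor ``d`` and capped at ``ln(rho)`` per iteration.  Both modifications
keep long-range phase information flowing before any cell's odds harden past
the resolution of double precision (15 consecutive markers at skewness 0.1
already suppress the opposite phase to ~1e-15).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .hmm import FocusChainEngine, slot_distributions, transition_matrices
from .parameters import (
    OptimizerConfig,
    ParameterSet,
    clamp_gamma,
    clamp_sureness,
    initialize_parameters,
    R_MAX,
    R_MIN,
)
from .pedigree import FocusPedigree, GenotypeMatrix, MarkerMap, Pedigree, decompose

logger = logging.getLogger(__name__)

_P_CLIP = 1e-15       # posterior probability clip before logit
_MIN_FLIP_GAIN = 1e-9  # a flip must beat float noise to be applied


@dataclass
class UpdateAccumulator:
    """Linear combination of per-chain Baum-Welch evidence.

    Weights are ``1/weight_divisor`` of the source focus pedigree, so a
    grandparent reached through an intermediate parent with ``c`` offspring
    receives total weight 1 per child lineage.
    """

    skew_logodds: np.ndarray    # (n, M) weighted sum of log P(e=1)/P(e=0)
    skew_weight: np.ndarray     # (n, M)
    allele_mass: np.ndarray     # (n, M, 2, K) weighted posterior allele mass
    allele_weight: np.ndarray   # (n, M)
    recomb_events: np.ndarray   # (M-1,) expected recombinations
    recomb_meioses: np.ndarray  # (M-1,) weighted meiosis count

    @classmethod
    def zeros(cls, n: int, M: int, K: int) -> "UpdateAccumulator":
        return cls(
            skew_logodds=np.zeros((n, M)),
            skew_weight=np.zeros((n, M)),
            allele_mass=np.zeros((n, M, 2, K)),
            allele_weight=np.zeros((n, M)),
            recomb_events=np.zeros(max(M - 1, 0)),
            recomb_meioses=np.zeros(max(M - 1, 0)),
        )


@dataclass(frozen=True)
class FlipCandidate:
    """A one-sided inversion: flip skewness (and, for the ``parent_swap``
    kinds, exchange the two parents' inferred genotype parameters) at all
    markers >= ``marker``, or — for the ``*_prefix`` kinds — at all markers
    < ``marker``.

    Prefix inversions complement the downstream ones: a region converged in
    the wrong phase at the chromosome start (typically seeded by the hard
    phase anchor at an individual's first heterozygous marker) has only one
    misfit boundary, on its right, so no downstream flip alone improves the
    likelihood there.
    """

    kind: str                 # "skewness[_prefix]" | "parent_swap[_prefix]"
    key: str                  # individual id, or "sire|dam" for a mating
    marker: int
    gain: float               # total log-likelihood gain over all chains
    involved: tuple[str, ...]


# ---------------------------------------------------------------------------
# parameter update rules
# ---------------------------------------------------------------------------


def update_skewness(
    acc: UpdateAccumulator, gamma_old: np.ndarray, config: OptimizerConfig
) -> np.ndarray:
    """Dampened, capped logit-space skewness update.

    The proposed logit is the weight-normalized sum of posterior phase
    log-odds; the step is ``old + d * (proposed - old)`` with the total
    change capped at ``ln(rho)`` (maximum relative change of the odds).
    Cells without evidence are unchanged.
    """
    old_logit = logit(clamp_gamma(gamma_old))
    has = acc.skew_weight > 0
    with np.errstate(invalid="ignore"):
        proposed = np.where(
            has, acc.skew_logodds / np.maximum(acc.skew_weight, 1e-300), old_logit
        )
    step = config.d_gamma * (proposed - old_logit)
    cap = np.log(config.resolved_rho_gamma)
    new_logit = old_logit + np.clip(step, -cap, cap)
    return clamp_gamma(expit(new_logit))


def update_sureness(
    acc: UpdateAccumulator,
    slot_alleles: np.ndarray,
    sureness: np.ndarray,
    optimize_mask: np.ndarray,
    n_alleles: np.ndarray,
    config: OptimizerConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Dampened sureness update with allele relabelling.

    Per slot, the accumulated posterior allele distribution is compared with
    the incumbent candidate; if another allele carries more mass the slot is
    relabelled to it.  The sureness then takes a dampened, capped logit step
    from the probability currently assigned to the (possibly new) label
    toward its posterior mass, floored at 0.5.  The two slots are updated
    from their separate, skewness-resolved posteriors and never symmetrized.
    Only individuals flagged ``optimize_mask`` (inferred first-level parents)
    are touched.
    """
    n, M, _, K = acc.allele_mass.shape
    new_alleles = slot_alleles.copy()
    new_sure = sureness.copy()
    active = optimize_mask[:, None] & (acc.allele_weight > 0) & (n_alleles > 1)[None, :]
    if not np.any(active):
        return new_alleles, new_sure

    w = np.maximum(acc.allele_weight, 1e-300)[:, :, None, None]
    q = acc.allele_mass / w  # (n, M, 2, K)
    inc = slot_alleles.astype(np.intp)  # (n, M, 2)
    q_inc = np.take_along_axis(q, inc[..., None], axis=3)[..., 0]
    best = np.argmax(q, axis=3)
    q_best = np.take_along_axis(q, best[..., None], axis=3)[..., 0]
    switch = q_best > q_inc
    label = np.where(switch, best, inc)
    q_label = np.where(switch, q_best, q_inc)
    other = (1.0 - sureness) / np.maximum(n_alleles - 1, 1)[None, :, None]
    p_old = np.where(switch, other, sureness)

    d = config.resolved_d_sureness
    cap = np.log(config.resolved_rho_gamma)
    lo = logit(np.clip(p_old, _P_CLIP, 1.0 - _P_CLIP))
    lq = logit(np.clip(q_label, _P_CLIP, 1.0 - _P_CLIP))
    new_logit = lo + np.clip(d * (lq - lo), -cap, cap)
    s_step = clamp_sureness(expit(new_logit))

    mask = active[:, :, None] & np.ones((1, 1, 2), dtype=bool)
    new_alleles[mask] = label[mask].astype(np.int16)
    new_sure[mask] = s_step[mask]
    return new_alleles, new_sure


def update_recombination(
    acc: UpdateAccumulator, r_old: np.ndarray, config: OptimizerConfig
) -> np.ndarray:
    """Baum-Welch recombination re-estimate: expected events / meioses."""
    if not config.update_recombination or r_old.size == 0:
        return r_old.copy()
    has = acc.recomb_meioses > 0
    r_new = np.where(
        has,
        acc.recomb_events / np.maximum(acc.recomb_meioses, 1e-300),
        r_old,
    )
    return np.clip(r_new, R_MIN, R_MAX)


# ---------------------------------------------------------------------------
# batched chains
# ---------------------------------------------------------------------------


@dataclass
class ChainBatch:
    """All focus pedigrees sharing one structural shape, evaluated together."""

    engine: FocusChainEngine
    chains: list[FocusPedigree]
    member_rows: np.ndarray      # (B, N) parameter-table row per member
    member_weights: np.ndarray   # (B, N) 1 / weight_divisor
    edge_ancestors: np.ndarray   # (n_bits,) member index transmitting each bit
    parent_members: list[int]    # member indices with role "parent"

    @property
    def n_chains(self) -> int:
        return len(self.chains)


@dataclass
class BatchEstep:
    E: np.ndarray
    G: np.ndarray
    skew: np.ndarray
    T: np.ndarray
    post: np.ndarray
    loglik: np.ndarray
    exp_flips: np.ndarray
    f: np.ndarray
    LF: np.ndarray
    bb: np.ndarray
    slotp: np.ndarray


def _shape_key(chain: FocusPedigree):
    return (
        tuple(chain.roles),
        tuple(ind.is_founder for ind in chain.members),
        tuple(chain.meiosis_edges),
    )


def build_batches(chains: list[FocusPedigree], params: ParameterSet) -> list[ChainBatch]:
    groups: dict[tuple, list[FocusPedigree]] = {}
    for chain in chains:
        groups.setdefault(_shape_key(chain), []).append(chain)
    batches = []
    for key in sorted(groups, key=repr):
        members = groups[key]
        proto = members[0]
        engine = FocusChainEngine(proto)
        rows = np.array(
            [[params.index_of(ind.id) for ind in c.members] for c in members]
        )
        weights = np.array([1.0 / c.member_weight_divisors for c in members])
        edge_anc = np.array([e[0] for e in proto.meiosis_edges], dtype=int)
        parent_members = [i for i, role in enumerate(proto.roles) if role == "parent"]
        batches.append(
            ChainBatch(
                engine=engine,
                chains=members,
                member_rows=rows,
                member_weights=weights,
                edge_ancestors=edge_anc,
                parent_members=parent_members,
            )
        )
    return batches


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------


class Optimizer:
    """Drives the iterative fit over one pedigree/genotype/map triple."""

    def __init__(
        self,
        pedigree: Pedigree,
        genotypes: GenotypeMatrix,
        marker_map: MarkerMap,
        config: OptimizerConfig | None = None,
        params: ParameterSet | None = None,
    ):
        self.pedigree = pedigree
        self.genotypes = genotypes
        self.marker_map = marker_map
        self.config = config or OptimizerConfig()
        self.params = params or initialize_parameters(
            pedigree, genotypes, marker_map, self.config
        )
        self.chains = decompose(pedigree, self.config.k)
        self.batches = build_batches(self.chains, self.params)
        self.n_alleles = marker_map.n_alleles()
        self.K = int(self.n_alleles.max())
        self._swap_matings = self._full_sib_matings()
        self.history: list[dict] = []

    # -- qualifying matings for parent-swap flips ---------------------------

    def _full_sib_matings(self):
        """Matings where both parents are inferred and form an isolated
        full-sib family (neither parent has offspring outside the mating)."""
        out = []
        for sire, dam, children in self.pedigree.matings():
            si = self.params.index_of(sire)
            di = self.params.index_of(dam)
            if not (
                self.params.optimize_genotype[si]
                and self.params.optimize_genotype[di]
            ):
                continue
            if len(self.pedigree.children_of(sire)) != len(children):
                continue
            if len(self.pedigree.children_of(dam)) != len(children):
                continue
            out.append((sire, dam, tuple(children)))
        return out

    # -- E-step -------------------------------------------------------------

    def _batch_slotp_gamma(self, batch: ChainBatch):
        rows = batch.member_rows
        alleles = np.moveaxis(self.params.slot_alleles[rows], 3, 2)  # (B,N,2,M)
        sure = np.moveaxis(self.params.sureness[rows], 3, 2)
        slotp = slot_distributions(alleles, sure, self.n_alleles)
        gamma = self.params.gamma[rows]  # (B, N, M)
        return slotp, gamma

    def e_step(self) -> tuple[list[BatchEstep], float]:
        esteps = []
        total = 0.0
        t_cache: dict[int, np.ndarray] = {}
        for batch in self.batches:
            nb = batch.engine.n_bits
            if nb not in t_cache:
                t_cache[nb] = transition_matrices(self.params.r, nb)
            slotp, gamma = self._batch_slotp_gamma(batch)
            E, G, skew = batch.engine.emissions(slotp, gamma, return_parts=True)
            post, loglik, exp_flips, f, LF, bb = batch.engine.posterior_pass(
                E, t_cache[nb], error_tolerant=self.config.error_tolerant
            )
            esteps.append(
                BatchEstep(E, G, skew, t_cache[nb], post, loglik, exp_flips, f, LF,
                           bb, slotp)
            )
            total += float(loglik.sum())
        return esteps, total

    def accumulate(self, esteps: list[BatchEstep]) -> UpdateAccumulator:
        n = len(self.params.ids)
        M = self.params.n_markers
        acc = UpdateAccumulator.zeros(n, M, self.K)
        for batch, es in zip(self.batches, esteps):
            engine = batch.engine
            Efl = engine._floor(es.E, self.config.error_tolerant)
            p1 = engine.ordering_posteriors(es.post, Efl, es.G, es.skew)  # (B,N,M)
            p1 = np.clip(p1, _P_CLIP, 1.0 - _P_CLIP)
            logodds = np.log(p1) - np.log1p(-p1)
            w = batch.member_weights  # (B, N)
            np.add.at(acc.skew_logodds, batch.member_rows, w[..., None] * logodds)
            np.add.at(
                acc.skew_weight,
                batch.member_rows,
                np.broadcast_to(w[..., None], logodds.shape),
            )
            if batch.parent_members and self.config.update_sureness:
                masses = engine.slot_allele_posteriors(
                    es.post, Efl, es.G, es.skew, es.slotp, batch.parent_members
                )  # (B, P, 2, M, K)
                for j, mem in enumerate(batch.parent_members):
                    rows = batch.member_rows[:, mem]
                    np.add.at(
                        acc.allele_mass, rows, np.moveaxis(masses[:, j], 1, 2)
                    )
                    np.add.at(acc.allele_weight, rows, np.ones((len(rows), M)))
            if M > 1:
                ew = batch.member_weights[:, batch.edge_ancestors]  # (B, n_bits)
                acc.recomb_events += np.einsum("bmk,bk->m", es.exp_flips, ew)
                acc.recomb_meioses += ew.sum() * np.ones(M - 1)
        return acc

    # -- flip scan ----------------------------------------------------------

    def scan_flips(self) -> tuple[list[FlipCandidate], list[FlipCandidate]]:
        """Compile downstream-inversion candidates, greedily apply the best
        non-overlapping set, and guarantee a total likelihood increase.

        Gains are exact: each candidate's value is the total log-likelihood
        change over all affected chains, computed from a fresh forward pass
        and one variant backward pass.  No individual joins two flips in one
        iteration; because disjoint flips can still interact through shared
        chains, the combined application is verified and rolled back to the
        single best flip if it ever fails to improve the total likelihood.
        """
        n = len(self.params.ids)
        M = self.params.n_markers
        gain_ind = np.zeros((n, M))
        gain_ind_pre = np.zeros((n, M))  # flip markers < m, stored at m - 1
        swap_gains: dict[tuple[str, str], np.ndarray] = {
            (s, d): np.zeros(M) for s, d, _ in self._swap_matings
        }
        swap_gains_pre: dict[tuple[str, str], np.ndarray] = {
            (s, d): np.zeros(M) for s, d, _ in self._swap_matings
        }
        swap_children = {(s, d): c for s, d, c in self._swap_matings}
        pre_total = 0.0
        t_cache: dict[int, np.ndarray] = {}
        tol = self.config.error_tolerant
        for batch in self.batches:
            engine = batch.engine
            nb = engine.n_bits
            if nb not in t_cache:
                t_cache[nb] = transition_matrices(self.params.r, nb)
            T = t_cache[nb]
            slotp, gamma = self._batch_slotp_gamma(batch)
            E, G, skew = engine.emissions(slotp, gamma, return_parts=True)
            Efl = engine._floor(E, tol)
            f, LF = engine.forward(Efl, T)
            rev_f = engine.reversed_forward(Efl, T)
            loglik = LF[:, -1]
            pre_total += float(loglik.sum())
            for i in range(engine.n_members):
                E_var = engine.emissions_variant(G, skew, (i,))
                V = engine.downstream_variant_logliks(Efl, E_var, T, f, LF, tol)
                np.add.at(gain_ind, batch.member_rows[:, i], V - loglik[:, None])
                Vp = engine.upstream_variant_logliks(
                    Efl, E_var, T, tol, reversed_forward=rev_f
                )
                np.add.at(
                    gain_ind_pre, batch.member_rows[:, i], Vp - loglik[:, None]
                )
            if engine.n_members == 3 and swap_gains:
                perm = engine.state_bit_swap_permutation(0, 1)
                E_swap = Efl[:, :, perm]
                V = engine.downstream_variant_logliks(Efl, E_swap, T, f, LF, tol)
                Vp = engine.upstream_variant_logliks(
                    Efl, E_swap, T, tol, reversed_forward=rev_f
                )
                dv = V - loglik[:, None]
                dvp = Vp - loglik[:, None]
                for b, chain in enumerate(batch.chains):
                    key = (chain.focus.sire_id, chain.focus.dam_id)
                    if key in swap_gains:
                        swap_gains[key] += dv[b]
                        swap_gains_pre[key] += dvp[b]

        def best_candidate(kind_down, kind_pre, key, down, pre, involved):
            m_d = int(np.argmax(down))
            g_d = float(down[m_d])
            # prefix gains stored at m - 1; a full-chromosome prefix flip
            # duplicates the downstream flip at marker 0, so drop it
            m_p = int(np.argmax(pre[: M - 1])) if M > 1 else 0
            g_p = float(pre[m_p]) if M > 1 else -np.inf
            if g_p > g_d:
                return FlipCandidate(kind_pre, key, m_p + 1, g_p, involved)
            if g_d > _MIN_FLIP_GAIN:
                return FlipCandidate(kind_down, key, m_d, g_d, involved)
            return None

        candidates: list[FlipCandidate] = []
        for i, ind_id in enumerate(self.params.ids):
            cand = best_candidate(
                "skewness", "skewness_prefix", ind_id,
                gain_ind[i], gain_ind_pre[i], (ind_id,),
            )
            if cand is not None and cand.gain > _MIN_FLIP_GAIN:
                candidates.append(cand)
        for (sire, dam), gains in swap_gains.items():
            involved = (sire, dam) + swap_children[(sire, dam)]
            cand = best_candidate(
                "parent_swap", "parent_swap_prefix", f"{sire}|{dam}",
                gains, swap_gains_pre[(sire, dam)], involved,
            )
            if cand is not None and cand.gain > _MIN_FLIP_GAIN:
                candidates.append(cand)
        candidates.sort(key=lambda c: (-c.gain, c.marker, c.key))

        applied: list[FlipCandidate] = []
        used: set[str] = set()
        for cand in candidates:
            if used.intersection(cand.involved):
                continue
            applied.append(cand)
            used.update(cand.involved)
        if not applied:
            return candidates, []

        snapshot = (
            self.params.gamma.copy(),
            self.params.slot_alleles.copy(),
            self.params.sureness.copy(),
        )
        for cand in applied:
            self._apply_flip(cand)
        if len(applied) > 1 and self._flips_share_chains(applied):
            post_total = self._total_loglik()
            if post_total <= pre_total + _MIN_FLIP_GAIN:
                # interacting flips neutralized each other: keep only the best
                (self.params.gamma, self.params.slot_alleles,
                 self.params.sureness) = snapshot
                applied = applied[:1]
                self._apply_flip(applied[0])
        return candidates, applied

    def _flips_share_chains(self, applied: list[FlipCandidate]) -> bool:
        """Whether any two applied flips touch a common focus pedigree.

        Disjoint flips have exactly additive likelihood gains, so the
        post-application verification pass is only needed when chains are
        shared (e.g. a parent flip and a child flip in one family).
        """
        seen: set[str] = set()
        for cand in applied:
            chains: set[str] = set()
            for ind_id in cand.involved:
                ind = self.pedigree[ind_id]
                if not ind.is_founder:
                    chains.add(ind_id)
                chains.update(self.pedigree.children_of(ind_id))
            if seen & chains:
                return True
            seen |= chains
        return False

    def _apply_flip(self, cand: FlipCandidate) -> None:
        m = cand.marker
        if cand.kind.endswith("_prefix"):
            sl = slice(None, m)
        else:
            sl = slice(m, None)
        if cand.kind.startswith("skewness"):
            row = self.params.index_of(cand.key)
            self.params.gamma[row, sl] = 1.0 - self.params.gamma[row, sl]
            return
        sire, dam = cand.key.split("|")
        si, di = self.params.index_of(sire), self.params.index_of(dam)
        for table in (self.params.gamma, self.params.slot_alleles, self.params.sureness):
            tmp = table[si, sl].copy()
            table[si, sl] = table[di, sl]
            table[di, sl] = tmp
        for child in swap_key_children(cand):
            row = self.params.index_of(child)
            self.params.gamma[row, sl] = 1.0 - self.params.gamma[row, sl]

    def _total_loglik(self) -> float:
        total = 0.0
        t_cache: dict[int, np.ndarray] = {}
        for batch in self.batches:
            nb = batch.engine.n_bits
            if nb not in t_cache:
                t_cache[nb] = transition_matrices(self.params.r, nb)
            slotp, gamma = self._batch_slotp_gamma(batch)
            E = batch.engine.emissions(slotp, gamma)
            Efl = batch.engine._floor(E, self.config.error_tolerant)
            _, LF = batch.engine.forward(Efl, t_cache[nb])
            total += float(LF[:, -1].sum())
        return total

    # -- recombination redistribution ---------------------------------------

    def redistribute_recombination(self) -> int:
        """Even out the recombination fraction over uninformative interval
        pairs: for each adjacent pair (left-to-right then right-to-left), if
        replacing both fractions by their mean changes the total likelihood
        by less than the tolerance, the even share is applied.  Returns the
        number of shares applied.
        """
        M = self.params.n_markers
        if M < 3 or not self.config.update_recombination:
            return 0
        tol = self.config.redistribution_tolerance
        esteps, _ = self.e_step()
        applied = 0
        pairs = list(range(M - 2))
        for sweep in (pairs, pairs[::-1]):
            for m in sweep:
                r0, r1 = self.params.r[m], self.params.r[m + 1]
                share = 0.5 * (r0 + r1)
                if abs(r0 - r1) < 1e-12:
                    continue
                delta = 0.0
                for batch, es in zip(self.batches, esteps):
                    nb = batch.engine.n_bits
                    T0 = es.T[m]
                    T1 = es.T[m + 1]
                    Ts = transition_matrices(np.array([share]), nb)[0]
                    Efl = batch.engine._floor(es.E, self.config.error_tolerant)
                    right = Efl[:, m + 2, :] * es.bb[:, m + 2, :]
                    mid = Efl[:, m + 1, :]
                    s_old = np.einsum(
                        "bs,st,bt,tu,bu->b", es.f[:, m], T0, mid, T1, right
                    )
                    s_new = np.einsum(
                        "bs,st,bt,tu,bu->b", es.f[:, m], Ts, mid, Ts, right
                    )
                    delta += float(
                        np.sum(np.log(np.maximum(s_new, 1e-300))
                               - np.log(np.maximum(s_old, 1e-300)))
                    )
                if abs(delta) < tol:
                    self.params.r[m] = self.params.r[m + 1] = share
                    for batch, es in zip(self.batches, esteps):
                        Ts = transition_matrices(
                            np.array([share]), batch.engine.n_bits
                        )[0]
                        es.T[m] = Ts
                        es.T[m + 1] = Ts
                    applied += 1
        return applied

    # -- iteration ----------------------------------------------------------

    def iterate(self, iteration: int) -> dict:
        esteps, total = self.e_step()
        acc = self.accumulate(esteps)
        gamma_new = update_skewness(acc, self.params.gamma, self.config)
        max_dg = float(np.abs(gamma_new - self.params.gamma).max())
        self.params.gamma = gamma_new
        max_ds = 0.0
        if self.config.update_sureness:
            alleles_new, sure_new = update_sureness(
                acc,
                self.params.slot_alleles,
                self.params.sureness,
                self.params.optimize_genotype,
                self.n_alleles,
                self.config,
            )
            relabelled = alleles_new != self.params.slot_alleles
            max_ds = float(np.abs(sure_new - self.params.sureness).max())
            if relabelled.any():
                max_ds = max(max_ds, 1.0)
            self.params.slot_alleles = alleles_new
            self.params.sureness = sure_new
        self.params.r = update_recombination(acc, self.params.r, self.config)
        n_flips = 0
        if self.config.flip_scan:
            _, applied = self.scan_flips()
            n_flips = len(applied)
            if n_flips:
                max_dg = max(max_dg, 1.0)
        if self.config.update_recombination:
            self.redistribute_recombination()
        record = {
            "iteration": iteration,
            "loglik": total,
            "n_flips": n_flips,
            "max_delta_gamma": max_dg,
            "max_delta_sureness": max_ds,
        }
        self.history.append(record)
        return record

    def fit(self, checkpoint_every: int | None = None,
            checkpoint_dir=None) -> "FitResult":
        """Run the configured number of iterations (with early exit).

        With ``checkpoint_every`` set, the parameter tables are written as a
        TSV under ``checkpoint_dir`` every that-many iterations (resumable
        via :meth:`ParameterSet.load` and the ``params`` constructor
        argument).
        """
        for it in range(self.config.n_iterations):
            record = self.iterate(it)
            if checkpoint_every and checkpoint_dir and (it + 1) % checkpoint_every == 0:
                from pathlib import Path

                path = Path(checkpoint_dir)
                path.mkdir(parents=True, exist_ok=True)
                self.params.save(path / f"checkpoint_{it + 1:04d}.tsv")
            if (
                record["max_delta_gamma"] < self.config.convergence_tol
                and record["max_delta_sureness"] < self.config.convergence_tol
            ):
                logger.info("converged after %d iterations", it + 1)
                break
        _, total = self.e_step()
        return FitResult(
            params=self.params,
            total_loglik=total,
            log=pd.DataFrame(
                self.history,
                columns=[
                    "iteration",
                    "loglik",
                    "n_flips",
                    "max_delta_gamma",
                    "max_delta_sureness",
                ],
            ),
            optimizer=self,
        )


def swap_key_children(cand: FlipCandidate) -> tuple[str, ...]:
    """Children involved in a parent-swap candidate (everything after the
    two parents in the ``involved`` tuple)."""
    return cand.involved[2:]


@dataclass
class FitResult:
    """Fitted parameters plus the per-iteration optimization log."""

    params: ParameterSet
    total_loglik: float
    log: pd.DataFrame
    optimizer: Optimizer = field(repr=False)

    @property
    def pedigree(self) -> Pedigree:
        return self.optimizer.pedigree

    @property
    def genotypes(self) -> GenotypeMatrix:
        return self.optimizer.genotypes

    @property
    def marker_map(self) -> MarkerMap:
        return self.optimizer.marker_map

    @property
    def config(self) -> OptimizerConfig:
        return self.optimizer.config


def run(
    pedigree: Pedigree,
    genotypes: GenotypeMatrix,
    marker_map: MarkerMap,
    config: OptimizerConfig | None = None,
) -> FitResult:
    """Fit skewness/sureness/recombination parameters for a dataset.

    With ``n_iterations=0`` the returned parameters equal the
    initialization.  The procedure is deterministic for fixed inputs.
    """
    return Optimizer(pedigree, genotypes, marker_map, config).fit()
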