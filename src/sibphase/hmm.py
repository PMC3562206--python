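"""Time-dependent HMM over one focus pedigree.

States are *inheritance vectors*: one bit per meiosis tracked by the focus
pedigree (``N - 1`` bits for ``N`` members), each stating which of the two
chromatids an ancestor transmitted.  Emissions are the recorded unordered
allele pairs of all members; their probability under a state is the chance
that a Mendelian-consistent allele realization occurs, where each recorded
chromatid slot carries its recorded allele with probability *sureness*
:math:`\\hat a` and any other allele of :math:`A_m` with the complementary
mass split uniformly.  Each member's pair ordering ``e_i`` is filtered by the
*skewness* :math:`\\gamma_{im}`: the factor :math:`1 - |e_i - \\gamma_{im}|`.
Transitions between adjacent markers flip each bit independently with the
interval's recombination fraction (Haldane model, no interference).

All heavy routines are batched: a :class:`FocusChainEngine` is built once per
focus-pedigree *shape* and evaluates every chain of that shape at once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import MendelianConflictError, ParameterError
from .pedigree import FocusPedigree

EPS_EMIT = 1e-12  # uniform floor on a zero emission row in error-tolerant mode


def haldane_r(d_cM: float | np.ndarray) -> float | np.ndarray:
    """Recombination fraction from a map distance in cM (Haldane, no interference)."""
    d = np.asarray(d_cM, dtype=float)
    if np.any(d < 0):
        raise ParameterError("map distance must be nonnegative")
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    r = np.minimum(r, np.nextafter(0.5, 0.0))  # keep strictly below 1/2
    return float(r) if np.isscalar(d_cM) else r


def transmit(s_i: int, e_i: int, sigma_i: int = 0) -> int:
    """Transmitted recorded-slot index: XOR of state, ordering and shuffling bits.

    Terms undefined for an individual (founder ``sigma``, focus ``s``) are
    substituted with 0 by the caller.
    """
    return (s_i + e_i + sigma_i) % 2


def disfavored_phase_weight(gamma: float, length: int) -> float:
    """Compounded per-marker filter factor for the disfavored ordering.

    Over ``length`` consecutive markers at skewness ``gamma`` the opposite
    phase interpretation is suppressed by ``min(gamma, 1-gamma) ** length``
    (e.g. 0.1^15 = 1e-15, at the scale of double-precision epsilon — the
    reason skewness updates are dampened before values become too fixed).
    """
    if not 0.0 < gamma < 1.0:
        raise ParameterError("gamma must be in (0, 1)")
    if length < 1:
        raise ParameterError("length must be >= 1")
    return min(gamma, 1.0 - gamma) ** length


@dataclass(frozen=True)
class StateSpace:
    """All inheritance-bit strings of a focus pedigree, in fixed order."""

    n_bits: int
    states: np.ndarray  # (2**n_bits, n_bits) uint8; row index = state id

    def __len__(self) -> int:
        return self.states.shape[0]


def _bit_table(n_bits: int) -> np.ndarray:
    ids = np.arange(1 << n_bits, dtype=np.uint32)
    return ((ids[:, None] >> np.arange(n_bits)[None, :]) & 1).astype(np.uint8)


def enumerate_states(focus: FocusPedigree) -> StateSpace:
    """State space of a focus pedigree: ``2**(N-1)`` inheritance vectors."""
    n_bits = len(focus.meiosis_edges)
    return StateSpace(n_bits=n_bits, states=_bit_table(n_bits))


def transition_probability(s0, s1, r: float) -> float:
    """Probability of moving between two inheritance vectors across one interval.

    Product over bits of ``1 - r`` (bit kept) or ``r`` (bit flipped);
    ``r`` must lie in ``[0, 0.5)``.
    """
    if not 0.0 <= r < 0.5:
        raise ParameterError("recombination fraction must be in [0, 0.5)")
    s0 = np.asarray(s0, dtype=int)
    s1 = np.asarray(s1, dtype=int)
    flips = int(np.sum(s0 != s1))
    return float(r**flips * (1.0 - r) ** (s0.size - flips))


def transition_matrices(r: np.ndarray, n_bits: int) -> np.ndarray:
    """Stack of ``(S, S)`` transition matrices, one per marker interval."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ParameterError("recombination fractions must be in [0, 0.5)")
    bits = _bit_table(n_bits)
    ham = (bits[:, None, :] != bits[None, :, :]).sum(axis=2)  # (S, S)
    return r[:, None, None] ** ham * (1.0 - r[:, None, None]) ** (n_bits - ham)


def slot_distributions(
    slot_alleles: np.ndarray, sureness: np.ndarray, n_alleles: np.ndarray
) -> np.ndarray:
    """Per-chromatid-slot allele distributions from (allele, sureness) tables.

    Parameters are arrays with a trailing marker axis broadcastable to
    ``slot_alleles`` of shape ``(..., M)`` (integer codes) and ``sureness`` of
    the same shape; ``n_alleles`` has shape ``(M,)``.  Returns ``(..., M, K)``
    where ``K = max(n_alleles)``: the recorded allele carries mass
    ``sureness`` and every other allele of the marker ``(1 - sureness) /
    (K_m - 1)``; monomorphic markers are one-hot.
    """
    K = int(n_alleles.max())
    shape = slot_alleles.shape
    p = np.zeros(shape + (K,))
    other = np.where(n_alleles > 1, (1.0 - sureness) / np.maximum(n_alleles - 1, 1), 0.0)
    valid = np.arange(K)[None, :] < n_alleles[:, None]  # (M, K)
    p[...] = other[..., None] * valid
    np.put_along_axis(
        p, slot_alleles[..., None].astype(np.intp),
        np.where(n_alleles > 1, sureness, 1.0)[..., None], axis=-1
    )
    return p


@dataclass
class EmissionContext:
    """Everything the emission model needs for one chain, all markers.

    ``slot_alleles``/``sureness``: ``(N, M, 2)`` recorded or inferred allele
    codes and their sureness per member per chromatid slot; ``gamma``:
    ``(N, M)`` skewness; ``n_alleles``: ``(M,)`` sizes of :math:`A_m`.
    """

    slot_alleles: np.ndarray
    sureness: np.ndarray
    gamma: np.ndarray
    n_alleles: np.ndarray

    @property
    def n_members(self) -> int:
        return self.slot_alleles.shape[0]

    @property
    def n_markers(self) -> int:
        return self.slot_alleles.shape[1]

    def slot_probs(self) -> np.ndarray:
        """(N, 2, M, K) slot allele distributions."""
        a = np.moveaxis(self.slot_alleles, 2, 1)  # (N, 2, M)
        s = np.moveaxis(self.sureness, 2, 1)
        return slot_distributions(a, s, self.n_alleles)


class FocusChainEngine:
    """Emission/forward-backward engine for one focus-pedigree shape.

    Instances are built from a representative :class:`FocusPedigree` (only
    the member count, founder pattern and meiosis edges matter) and evaluate
    whole batches of chains with that shape.  The ordering sum over
    :math:`e \\in \\{0,1\\}^N` is carried out by explicit enumeration, with
    Mendelian-consistency groups precomputed per ``(s, e)`` combination.
    """

    def __init__(self, focus: FocusPedigree, sigma: np.ndarray | None = None):
        self.n_members = focus.n_members
        self.edges = focus.meiosis_edges
        self.n_bits = len(self.edges)
        self.states = _bit_table(self.n_bits)
        self.n_states = self.states.shape[0]
        self.e_vectors = _bit_table(self.n_members)
        self.founder_mask = np.array([ind.is_founder for ind in focus.members])
        if sigma is None:
            sigma = np.zeros(self.n_members, dtype=np.uint8)
        self.sigma = np.asarray(sigma, dtype=np.uint8)
        # flat slot id = 2 * member + slot
        self._combos = self._build_combos()

    def _build_combos(self):
        """Per (state, ordering): equality groups of chromatid slots.

        A group collects slots whose realized alleles must coincide given the
        allele transmissions implied by ``(s, e, sigma)``.
        """
        combos = []
        for si in range(self.n_states):
            s = self.states[si]
            for ei in range(self.e_vectors.shape[0]):
                e = self.e_vectors[ei]
                parent = list(range(2 * self.n_members))  # union-find
                def find(x):
                    while parent[x] != x:
                        parent[x] = parent[parent[x]]
                        x = parent[x]
                    return x
                for b, (anc, child, side) in enumerate(self.edges):
                    sig_a = 0 if self.founder_mask[anc] else int(self.sigma[anc])
                    slot_a = 2 * anc + ((int(s[b]) + int(e[anc]) + sig_a) % 2)
                    chromatid = side ^ int(self.sigma[child])
                    slot_c = 2 * child + (chromatid ^ int(e[child]))
                    ra, rc = find(slot_a), find(slot_c)
                    if ra != rc:
                        parent[ra] = rc
                groups: dict[int, list[int]] = {}
                for x in range(2 * self.n_members):
                    groups.setdefault(find(x), []).append(x)
                gs = tuple(
                    tuple(sorted(g)) for g in groups.values() if len(g) > 1
                )
                combos.append((si, ei, tuple(sorted(gs))))
        return combos

    # -- emissions ---------------------------------------------------------

    def _skew_weights(self, gamma: np.ndarray) -> np.ndarray:
        """(2**N, B, M) ordering filter products; gamma is (B, N, M)."""
        w = np.stack([1.0 - gamma, gamma], axis=-1)  # (B, N, M, 2)
        nE = self.e_vectors.shape[0]
        B, _, M = gamma.shape
        out = np.ones((nE, B, M))
        for ei in range(nE):
            e = self.e_vectors[ei]
            for i in range(self.n_members):
                out[ei] *= w[:, i, :, e[i]]
        return out

    def emissions(
        self,
        slotp: np.ndarray,
        gamma: np.ndarray,
        return_parts: bool = False,
    ):
        """Emission weights for a batch of chains.

        ``slotp``: ``(B, N, 2, M, K)`` slot allele distributions;
        ``gamma``: ``(B, N, M)`` skewness.  Returns ``E`` of shape
        ``(B, M, S)``; with ``return_parts`` also the per-combination group
        products ``G`` (``(n_combos, B, M)``) and skewness filter products
        ``skew`` (``(2**N, B, M)``) reused by posterior passes and flip
        variants.
        """
        B, N, _, M, K = slotp.shape
        skew = self._skew_weights(gamma)
        gcache: dict[tuple, np.ndarray] = {}

        def group_product(g: tuple[int, ...]) -> np.ndarray:
            if g not in gcache:
                prod = slotp[:, g[0] // 2, g[0] % 2]
                for t in g[1:]:
                    prod = prod * slotp[:, t // 2, t % 2]
                gcache[g] = prod.sum(axis=-1)  # (B, M)
            return gcache[g]

        E = np.zeros((B, M, self.n_states))
        G = np.empty((len(self._combos), B, M)) if return_parts else None
        for ci, (si, ei, groups) in enumerate(self._combos):
            gp = np.ones((B, M))
            for g in groups:
                gp = gp * group_product(g)
            E[:, :, si] += skew[ei] * gp
            if return_parts:
                G[ci] = gp
        if return_parts:
            return E, G, skew
        return E

    def emissions_variant(
        self,
        G: np.ndarray,
        skew: np.ndarray,
        flip_members: tuple[int, ...] = (),
    ) -> np.ndarray:
        """Emission weights after flipping some members' skewness.

        Flipping member ``i``'s skewness swaps its two ordering weights,
        which equals reading the skewness filter at ``e`` with bit ``i``
        toggled; the Mendelian group products ``G`` are unchanged.
        """
        mask = 0
        for i in flip_members:
            mask |= 1 << i
        _, B, M = G.shape
        E = np.zeros((B, M, self.n_states))
        for ci, (si, ei, _groups) in enumerate(self._combos):
            E[:, :, si] += skew[ei ^ mask] * G[ci]
        return E

    def state_bit_swap_permutation(self, bit_a: int, bit_b: int) -> np.ndarray:
        """State index permutation exchanging two inheritance bits.

        For a parental-genotype swap in a trio, the swapped-parameter
        emission tensor equals the original with the two parental meiosis
        bits exchanged, so downstream-swap likelihoods need no recomputation.
        """
        ids = np.arange(self.n_states)
        a = (ids >> bit_a) & 1
        b = (ids >> bit_b) & 1
        swapped = ids & ~((1 << bit_a) | (1 << bit_b))
        swapped |= (b << bit_a) | (a << bit_b)
        return swapped

    # -- forward-backward --------------------------------------------------

    def forward(self, E: np.ndarray, T: np.ndarray, error_tolerant: bool = False):
        """Scaled forward pass.  Returns (f_hat (B,M,S), log-scale LF (B,M))."""
        B, M, S = E.shape
        E = self._floor(E, error_tolerant)
        f = np.empty((B, M, S))
        LF = np.empty((B, M))
        a = E[:, 0, :] / S
        c = a.sum(axis=1)
        self._check_scale(c, 0)
        f[:, 0] = a / c[:, None]
        LF[:, 0] = np.log(c)
        for m in range(1, M):
            a = np.einsum("bs,st->bt", f[:, m - 1], T[m - 1]) * E[:, m, :]
            c = a.sum(axis=1)
            self._check_scale(c, m)
            f[:, m] = a / c[:, None]
            LF[:, m] = LF[:, m - 1] + np.log(c)
        return f, LF

    def backward(self, E: np.ndarray, T: np.ndarray, error_tolerant: bool = False,
                 include_own_emission: bool = False):
        """Scaled backward pass.

        With ``include_own_emission`` the recursion returns
        ``B(m, s) ∝ P(x_m..x_{M-1} | s_m = s)`` (used by the downstream-flip
        gain evaluation); otherwise the standard
        ``beta(m, s) ∝ P(x_{m+1}.. | s_m = s)``.
        Returns (b_hat (B,M,S), per-step log scales LB (B,M) accumulated from
        the right).
        """
        B, M, S = E.shape
        E = self._floor(E, error_tolerant)
        b = np.empty((B, M, S))
        LB = np.empty((B, M))
        if include_own_emission:
            v = E[:, M - 1, :]
        else:
            v = np.ones((B, S))
        c = np.maximum(v.sum(axis=1), 1e-300)
        b[:, M - 1] = v / c[:, None]
        LB[:, M - 1] = np.log(c)
        for m in range(M - 2, -1, -1):
            if include_own_emission:
                v = E[:, m, :] * np.einsum("st,bt->bs", T[m], b[:, m + 1])
            else:
                v = np.einsum("st,bt->bs", T[m], E[:, m + 1, :] * b[:, m + 1])
            c = np.maximum(v.sum(axis=1), 1e-300)
            b[:, m] = v / c[:, None]
            LB[:, m] = LB[:, m + 1] + np.log(c)
        return b, LB

    @staticmethod
    def _floor(E: np.ndarray, error_tolerant: bool) -> np.ndarray:
        if not error_tolerant:
            return E
        bad = E.sum(axis=2) < EPS_EMIT
        if np.any(bad):
            E = E.copy()
            E[bad] += EPS_EMIT / E.shape[2]
        return E

    @staticmethod
    def _check_scale(c: np.ndarray, marker: int) -> None:
        if np.any(c <= 0.0):
            raise MendelianConflictError(
                marker, "all-state zero emission (genotypes impossible under pedigree)"
            )

    def posterior_pass(self, E: np.ndarray, T: np.ndarray,
                       error_tolerant: bool = False):
        """Forward-backward: state posteriors, log-likelihoods, expected bit flips.

        Returns ``(post (B,M,S), loglik (B,), exp_flips (B, M-1, n_bits),
        f_hat, LF, b_hat)``; forward/backward arrays are reused by the flip
        scan and the recombination redistribution test.
        """
        B, M, S = E.shape
        Efl = self._floor(E, error_tolerant)
        f, LF = self.forward(Efl, T, error_tolerant=False)
        bb, _ = self.backward(Efl, T, error_tolerant=False)
        post = f * bb
        post /= post.sum(axis=2, keepdims=True)
        loglik = LF[:, -1]
        bits = self.states
        flip = (bits[:, None, :] != bits[None, :, :]).astype(float)  # (S,S,bits)
        exp_flips = np.empty((B, M - 1, self.n_bits)) if M > 1 else np.zeros(
            (B, 0, self.n_bits)
        )
        for m in range(M - 1):
            xi = (
                f[:, m, :, None]
                * T[m][None, :, :]
                * (Efl[:, m + 1, :] * bb[:, m + 1, :])[:, None, :]
            )
            xi /= np.maximum(xi.sum(axis=(1, 2), keepdims=True), 1e-300)
            exp_flips[:, m, :] = np.einsum("bst,stk->bk", xi, flip)
        return post, loglik, exp_flips, f, LF, bb

    # -- ordering and allele posteriors -------------------------------------

    def ordering_posteriors(
        self, post: np.ndarray, E: np.ndarray, G: np.ndarray, skew: np.ndarray
    ) -> np.ndarray:
        """Posterior probability of the reversed ordering per member per marker.

        Returns ``(B, N, M)`` with entry = P(e_i = 1 | data).
        """
        B, M, S = E.shape
        out = np.zeros((B, self.n_members, M))
        ratio = post / np.maximum(E, 1e-300)  # (B, M, S)
        for ci, (si, ei, _groups) in enumerate(self._combos):
            resp = skew[ei] * G[ci] * ratio[:, :, si]  # (B, M)
            e = self.e_vectors[ei]
            for i in range(self.n_members):
                if e[i]:
                    out[:, i, :] += resp
        return np.clip(out, 0.0, 1.0)

    def slot_allele_posteriors(
        self,
        post: np.ndarray,
        E: np.ndarray,
        G: np.ndarray,
        skew: np.ndarray,
        slotp: np.ndarray,
        members: list[int],
    ) -> np.ndarray:
        """Posterior allele mass per tracked member slot.

        For each combination, a slot constrained into an equality group takes
        the group's normalized joint allele distribution; an unconstrained
        slot keeps its prior.  Returns ``(B, len(members), 2, M, K)``.
        """
        B, M, S = E.shape
        K = slotp.shape[-1]
        ratio = post / np.maximum(E, 1e-300)
        out = np.zeros((B, len(members), 2, M, K))
        qcache: dict[tuple, np.ndarray] = {}

        def group_dist(g: tuple[int, ...]) -> np.ndarray:
            if g not in qcache:
                prod = slotp[:, g[0] // 2, g[0] % 2]
                for t in g[1:]:
                    prod = prod * slotp[:, t // 2, t % 2]
                tot = np.maximum(prod.sum(axis=-1, keepdims=True), 1e-300)
                qcache[g] = prod / tot
            return qcache[g]

        track = {m: j for j, m in enumerate(members)}
        for ci, (si, ei, groups) in enumerate(self._combos):
            resp = skew[ei] * G[ci] * ratio[:, :, si]  # (B, M)
            grouped: dict[int, tuple] = {}
            for g in groups:
                for t in g:
                    if t // 2 in track:
                        grouped[t] = g
            for mem, j in track.items():
                for slot in (0, 1):
                    t = 2 * mem + slot
                    if t in grouped:
                        q = group_dist(grouped[t])
                    else:
                        q = slotp[:, mem, slot]
                    out[:, j, slot] += resp[:, :, None] * q
        return out

    # -- single-marker emission substitution --------------------------------

    @staticmethod
    def loglik_delta_single_marker(
        post: np.ndarray, E_old: np.ndarray, E_new: np.ndarray
    ) -> np.ndarray:
        """log L'/L per chain per marker when one marker's emission row changes.

        Valid whenever ``E_old`` is strictly positive on states carrying
        posterior mass.  ``post, E_old, E_new`` are ``(B, M, S)``.
        """
        ratio = np.where(E_old > 0, E_new / np.maximum(E_old, 1e-300), 0.0)
        return np.log(np.maximum((post * ratio).sum(axis=2), 1e-300))

    # -- downstream-variant likelihoods (flip gains) ------------------------

    def reversed_forward(self, E: np.ndarray, T: np.ndarray,
                         error_tolerant: bool = False):
        """Forward pass of the reversed chain (for prefix-flip gains)."""
        return self.forward(
            self._floor(E[:, ::-1, :], error_tolerant), T[::-1],
            error_tolerant=False,
        )

    def upstream_variant_logliks(
        self,
        E: np.ndarray,
        E_var: np.ndarray,
        T: np.ndarray,
        error_tolerant: bool = False,
        reversed_forward: tuple[np.ndarray, np.ndarray] | None = None,
    ) -> np.ndarray:
        """log-likelihood of each chain when emissions switch to ``E_var``
        at all markers *before* ``m``, for every ``m`` in ``1..M`` (returned
        at index ``m - 1``).  Returns ``(B, M)``.

        Computed by running the downstream machinery on the reversed chain
        (the likelihood is invariant under marker reversal with a uniform
        prior).  ``reversed_forward`` may carry a precomputed
        :meth:`reversed_forward` result, which depends only on ``E``.
        """
        B, M, S = E.shape
        if reversed_forward is None:
            reversed_forward = self.reversed_forward(E, T, error_tolerant)
        f, LF = reversed_forward
        V = self.downstream_variant_logliks(
            E[:, ::-1, :], E_var[:, ::-1, :], T[::-1], f, LF, error_tolerant
        )
        # reversed index j corresponds to flipping original markers < M - j
        return V[:, ::-1]

    def downstream_variant_logliks(
        self,
        E: np.ndarray,
        E_var: np.ndarray,
        T: np.ndarray,
        f: np.ndarray,
        LF: np.ndarray,
        error_tolerant: bool = False,
    ) -> np.ndarray:
        """log-likelihood of each chain when emissions switch to ``E_var``
        from marker ``m`` onward, for every ``m``.  Returns ``(B, M)``.

        Uses the stored forward pass of ``E`` plus one scaled backward pass
        of ``E_var`` (own-emission convention).
        """
        B, M, S = E.shape
        bv, LBV = self.backward(E_var, T, error_tolerant, include_own_emission=True)
        out = np.empty((B, M))
        out[:, 0] = LBV[:, 0] + np.log(
            np.maximum(bv[:, 0].mean(axis=1), 1e-300)
        )
        for m in range(1, M):
            pred = np.einsum("bs,st->bt", f[:, m - 1], T[m - 1])
            mix = np.maximum((pred * bv[:, m]).sum(axis=1), 1e-300)
            out[:, m] = LF[:, m - 1] + LBV[:, m] + np.log(mix)
        return out


# ---------------------------------------------------------------------------
# single-chain convenience API
# ---------------------------------------------------------------------------


@dataclass
class ChainPosteriors:
    """Forward-backward output for one focus pedigree.

    ``ordering_odds[i, m]`` is the posterior probability that member ``i``'s
    recorded pair is reversed (``e_i = 1``) at marker ``m``;
    ``expected_recombinations[m, b]`` the expected number of bit-``b`` flips
    in interval ``m``.
    """

    log_forward: np.ndarray
    log_backward: np.ndarray
    state_posteriors: np.ndarray
    log_likelihood: float
    ordering_odds: np.ndarray
    expected_recombinations: np.ndarray

    def to_frame(self):
        """Per-marker state posteriors as a tidy table (diagnostic dump)."""
        import pandas as pd

        M, S = self.state_posteriors.shape
        return pd.DataFrame(
            {
                "marker": np.repeat(np.arange(1, M + 1), S),
                "state": np.tile(np.arange(S), M),
                "posterior": self.state_posteriors.ravel(),
            }
        )


def emission_weight(
    focus: FocusPedigree,
    state_bits,
    marker: int,
    ctx: EmissionContext,
    sigma: np.ndarray | None = None,
) -> float:
    """Emission weight of one state at one marker (skewness- and sureness-aware).

    Sums over all ``2**N`` pair orderings the probability of a
    Mendelian-consistent allele realization, filtered by skewness.  With all
    sureness values at 1 this reduces to the skewness-filtered count of
    permissible orderings.
    """
    engine = FocusChainEngine(focus, sigma=sigma)
    slotp = ctx.slot_probs()[None]  # (1, N, 2, M, K)
    E = engine.emissions(slotp, ctx.gamma[None])
    s = np.asarray(state_bits, dtype=int)
    si = int((s * (1 << np.arange(s.size))).sum())
    return float(E[0, marker, si])


def forward_backward(
    focus: FocusPedigree,
    ctx: EmissionContext,
    r: np.ndarray,
    sigma: np.ndarray | None = None,
    error_tolerant: bool = False,
) -> ChainPosteriors:
    """Run the chain of one focus pedigree and return its posteriors.

    ``r`` holds per-interval recombination fractions (length ``M - 1``).
    Raises :class:`MendelianConflictError` naming the first impossible marker
    when genotypes are exact and inconsistent, unless ``error_tolerant``.
    """
    engine = FocusChainEngine(focus, sigma=sigma)
    slotp = ctx.slot_probs()[None]
    E, G, skew = engine.emissions(slotp, ctx.gamma[None], return_parts=True)
    T = transition_matrices(np.asarray(r, dtype=float), engine.n_bits)
    post, loglik, exp_flips, f, LF, _bb = engine.posterior_pass(
        E, T, error_tolerant=error_tolerant
    )
    Efl = engine._floor(E, error_tolerant)
    b, LB = engine.backward(Efl, T)
    ordering = engine.ordering_posteriors(post, Efl, G, skew)
    with np.errstate(divide="ignore"):
        return ChainPosteriors(
            log_forward=np.log(np.maximum(f[0], 1e-300)) + LF[0][:, None],
            log_backward=np.log(np.maximum(b[0], 1e-300)) + LB[0][:, None],
            state_posteriors=post[0],
            log_likelihood=float(loglik[0]),
            ordering_odds=ordering[0],
            expected_recombinations=exp_flips[0],
        )


def total_loglik_over_sigma(
    focus: FocusPedigree,
    ctx: EmissionContext,
    r: np.ndarray,
    error_tolerant: bool = False,
) -> float:
    """Log of the likelihood summed over every shuffling-flag assignment.

    Validation helper: with symmetric skewness the per-``sigma`` likelihoods
    coincide, which is why ``sigma`` can be fixed to zeros in production runs.
    """
    nonfounders = [i for i, ind in enumerate(focus.members) if not ind.is_founder]
    total = -np.inf
    for bits in _bit_table(len(nonfounders)):
        sigma = np.zeros(focus.n_members, dtype=np.uint8)
        for i, b in zip(nonfounders, bits):
            sigma[i] = b
        cp = forward_backward(focus, ctx, r, sigma=sigma, error_tolerant=error_tolerant)
        total = np.logaddexp(total, cp.log_likelihood)
    return float(total)
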