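"""Independent brute-force oracles and small builders shared across tests.

The oracles deliberately re-derive the model from first principles —
explicit enumeration of orderings, allele realizations and state paths —
and share no code with the package's grouped/batched implementation.
"""

from __future__ import annotations

import itertools

import numpy as np

from sibphase.pedigree import FocusPedigree, Individual, Pedigree


def trio_pedigree(n_children: int = 1, typed_parents: bool = True) -> Pedigree:
    inds = [
        Individual("F", sex="male", genotyped=typed_parents),
        Individual("M", sex="female", genotyped=typed_parents),
    ]
    for j in range(n_children):
        inds.append(Individual(f"C{j}", "F", "M"))
    return Pedigree(inds)


def slot_probs_explicit(allele: int, sureness: float, n_alleles: int) -> dict[int, float]:
    """Allele distribution of one chromatid slot, written out longhand."""
    if n_alleles == 1 or sureness >= 1.0:
        return {allele: 1.0}
    probs = {}
    for a in range(n_alleles):
        if a == allele:
            probs[a] = sureness
        else:
            probs[a] = (1.0 - sureness) / (n_alleles - 1)
    return probs


def oracle_emission(focus: FocusPedigree, ctx, marker: int, state_bits,
                    sigma=None) -> float:
    """Emission weight by explicit enumeration of orderings and realizations.

    Sums over every ordering string e and every joint allele realization of
    all 2N chromatid slots, keeping realizations in which each tracked
    meiosis copies the transmitted allele into the receiving chromatid.
    """
    N = focus.n_members
    edges = focus.meiosis_edges
    K = int(ctx.n_alleles[marker])
    if sigma is None:
        sigma = [0] * N
    founder = [ind.is_founder for ind in focus.members]
    slot_dists = [
        [
            slot_probs_explicit(
                int(ctx.slot_alleles[i, marker, c]),
                float(ctx.sureness[i, marker, c]),
                K,
            )
            for c in (0, 1)
        ]
        for i in range(N)
    ]
    s = list(state_bits)
    total = 0.0
    for e in itertools.product((0, 1), repeat=N):
        skew = 1.0
        for i in range(N):
            g = float(ctx.gamma[i, marker])
            skew *= 1.0 - abs(e[i] - g)
        # enumerate realized alleles for all slots
        consist_prob = 0.0
        for real in itertools.product(range(K), repeat=2 * N):
            p = 1.0
            for i in range(N):
                for c in (0, 1):
                    p *= slot_dists[i][c].get(real[2 * i + c], 0.0)
            if p == 0.0:
                continue
            ok = True
            for b, (anc, child, side) in enumerate(edges):
                sig_a = 0 if founder[anc] else sigma[anc]
                slot_a = (s[b] + e[anc] + sig_a) % 2
                chromatid = side ^ sigma[child]
                slot_c = chromatid ^ e[child]
                if real[2 * anc + slot_a] != real[2 * child + slot_c]:
                    ok = False
                    break
            if ok:
                consist_prob += p
        total += skew * consist_prob
    return total


def oracle_emission_table(focus: FocusPedigree, ctx, r=None) -> np.ndarray:
    """(M, S) oracle emission weights, states in little-endian bit order."""
    n_bits = len(focus.meiosis_edges)
    M = ctx.n_markers
    S = 1 << n_bits
    E = np.zeros((M, S))
    for m in range(M):
        for si in range(S):
            bits = [(si >> b) & 1 for b in range(n_bits)]
            E[m, si] = oracle_emission(focus, ctx, m, bits)
    return E


def oracle_loglik(focus: FocusPedigree, ctx, r) -> float:
    """Exhaustive path-sum likelihood with uniform state prior."""
    E = oracle_emission_table(focus, ctx)
    M, S = E.shape
    n_bits = int(np.log2(S))
    total = 0.0
    for path in itertools.product(range(S), repeat=M):
        p = 1.0 / S * E[0, path[0]]
        for m in range(1, M):
            flips = bin(path[m - 1] ^ path[m]).count("1")
            p *= r[m - 1] ** flips * (1 - r[m - 1]) ** (n_bits - flips) * E[m, path[m]]
        total += p
    return float(np.log(total))


def oracle_ordering_posterior(focus: FocusPedigree, ctx, r, member: int,
                              marker: int) -> float:
    """P(e_member = 1 at marker | data), by exhaustive enumeration."""
    N = focus.n_members
    edges = focus.meiosis_edges
    n_bits = len(edges)
    S = 1 << n_bits
    M = ctx.n_markers
    E = oracle_emission_table(focus, ctx)

    def emission_restricted(m, si):
        # weight restricted to orderings with e[member] == 1
        bits = [(si >> b) & 1 for b in range(n_bits)]
        total = 0.0
        for e in itertools.product((0, 1), repeat=N):
            if e[member] != 1:
                continue
            sub_ctx_gamma = ctx.gamma.copy()
            skew = 1.0
            for i in range(N):
                skew *= 1.0 - abs(e[i] - float(ctx.gamma[i, m]))
            # reuse the realization sum from oracle_emission with fixed e
            consist = _consistency_prob(focus, ctx, m, bits, e)
            total += skew * consist
        return total

    num = 0.0
    den = 0.0
    for path in itertools.product(range(S), repeat=M):
        p = 1.0 / S
        for m in range(1, M):
            flips = bin(path[m - 1] ^ path[m]).count("1")
            p *= r[m - 1] ** flips * (1 - r[m - 1]) ** (n_bits - flips)
        base = p
        for m in range(M):
            base *= E[m, path[m]]
        den += base
        if E[marker, path[marker]] > 0:
            num += base / E[marker, path[marker]] * emission_restricted(
                marker, path[marker]
            )
    return num / den


def _consistency_prob(focus, ctx, marker, state_bits, e):
    N = focus.n_members
    edges = focus.meiosis_edges
    K = int(ctx.n_alleles[marker])
    founder = [ind.is_founder for ind in focus.members]
    slot_dists = [
        [
            slot_probs_explicit(
                int(ctx.slot_alleles[i, marker, c]),
                float(ctx.sureness[i, marker, c]),
                K,
            )
            for c in (0, 1)
        ]
        for i in range(N)
    ]
    total = 0.0
    for real in itertools.product(range(K), repeat=2 * N):
        p = 1.0
        for i in range(N):
            for c in (0, 1):
                p *= slot_dists[i][c].get(real[2 * i + c], 0.0)
        if p == 0.0:
            continue
        ok = True
        for b, (anc, child, side) in enumerate(edges):
            slot_a = (state_bits[b] + e[anc]) % 2
            slot_c = side ^ e[child]
            if real[2 * anc + slot_a] != real[2 * child + slot_c]:
                ok = False
                break
        if ok:
            total += p
    return total


def random_trio_context(rng: np.random.Generator, n_markers: int,
                        sureness_range=(0.85, 1.0)):
    """Random consistent trio data: parents drawn, child Mendelian."""
    from sibphase.hmm import EmissionContext

    father = rng.integers(0, 2, (n_markers, 2))
    mother = rng.integers(0, 2, (n_markers, 2))
    pat = father[np.arange(n_markers), rng.integers(0, 2, n_markers)]
    mat = mother[np.arange(n_markers), rng.integers(0, 2, n_markers)]
    child = np.stack([pat, mat], axis=1)
    slot_alleles = np.stack([father, mother, child]).astype(np.int16)
    sureness = rng.uniform(*sureness_range, (3, n_markers, 2))
    gamma = rng.uniform(0.1, 0.9, (3, n_markers))
    return EmissionContext(
        slot_alleles=slot_alleles,
        sureness=sureness,
        gamma=gamma,
        n_alleles=np.full(n_markers, 2),
    )


def oracle_slot_posterior(focus, ctx, r, member: int, slot: int, marker: int,
                          n_alleles: int = 2) -> np.ndarray:
    """Posterior distribution of the realized allele in one chromatid slot.

    Enumerates state paths, orderings and joint allele realizations;
    marginalizes everything but the target slot's realized allele.
    """
    N = focus.n_members
    edges = focus.meiosis_edges
    n_bits = len(edges)
    S = 1 << n_bits
    M = ctx.n_markers
    founder = [ind.is_founder for ind in focus.members]
    E = oracle_emission_table(focus, ctx)

    def marker_term(m, si, target_allele=None):
        bits = [(si >> b) & 1 for b in range(n_bits)]
        K = int(ctx.n_alleles[m])
        slot_dists = [
            [
                slot_probs_explicit(
                    int(ctx.slot_alleles[i, m, c]),
                    float(ctx.sureness[i, m, c]),
                    K,
                )
                for c in (0, 1)
            ]
            for i in range(N)
        ]
        total = 0.0
        for e in itertools.product((0, 1), repeat=N):
            skew = 1.0
            for i in range(N):
                skew *= 1.0 - abs(e[i] - float(ctx.gamma[i, m]))
            for real in itertools.product(range(K), repeat=2 * N):
                if target_allele is not None and real[2 * member + slot] != target_allele:
                    continue
                p = 1.0
                for i in range(N):
                    for c in (0, 1):
                        p *= slot_dists[i][c].get(real[2 * i + c], 0.0)
                if p == 0.0:
                    continue
                ok = True
                for b, (anc, child, side) in enumerate(edges):
                    slot_a = (bits[b] + e[anc]) % 2
                    slot_c = side ^ e[child]
                    if real[2 * anc + slot_a] != real[2 * child + slot_c]:
                        ok = False
                        break
                if ok:
                    total += skew * p
        return total

    num = np.zeros(n_alleles)
    den = 0.0
    for path in itertools.product(range(S), repeat=M):
        p = 1.0 / S
        for m in range(1, M):
            flips = bin(path[m - 1] ^ path[m]).count("1")
            p *= r[m - 1] ** flips * (1 - r[m - 1]) ** (n_bits - flips)
        rest = p
        for m in range(M):
            if m != marker:
                rest *= E[m, path[m]]
        den += rest * E[marker, path[marker]]
        for a in range(n_alleles):
            num[a] += rest * marker_term(marker, path[marker], a)
    return num / den
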