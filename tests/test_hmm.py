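"""The focus-pedigree HMM: states, emissions, transitions, forward-backward.

Likelihoods and posteriors are checked against brute-force oracles that
enumerate orderings, allele realizations and whole state paths.
"""

import numpy as np
import pytest

from helpers import (
    oracle_emission,
    oracle_loglik,
    oracle_ordering_posterior,
    random_trio_context,
    trio_pedigree,
)
from sibphase.errors import MendelianConflictError, ParameterError
from sibphase.hmm import (
    EmissionContext,
    FocusChainEngine,
    disfavored_phase_weight,
    emission_weight,
    enumerate_states,
    forward_backward,
    haldane_r,
    total_loglik_over_sigma,
    transition_matrices,
    transition_probability,
    transmit,
)
from sibphase.pedigree import decompose


def trio_context(father, mother, child, sureness=1.0, gamma=0.5, n_alleles=2):
    """Single-marker trio context from recorded pairs."""
    slot = np.array([[father], [mother], [child]], dtype=np.int16)
    sure = np.full((3, 1, 2), sureness)
    if np.ndim(sureness):
        sure = np.asarray(sureness).reshape(3, 1, 2)
    return EmissionContext(
        slot_alleles=slot,
        sureness=sure,
        gamma=np.full((3, 1), gamma),
        n_alleles=np.array([n_alleles]),
    )


class TestBasics:
    def test_transmit_is_xor(self):
        assert transmit(0, 0, 0) == 0
        assert transmit(1, 1, 0) == 0
        assert transmit(1, 0, 1) == 0
        assert transmit(1, 1, 1) == 1

    def test_haldane_limits_and_value(self):
        assert haldane_r(0.0) == 0.0
        assert haldane_r(1e9) == pytest.approx(0.5)
        # closed form at the default marker spacing, frozen independently
        assert haldane_r(0.05) == pytest.approx(4.9975008e-4, rel=1e-6)
        with pytest.raises(ParameterError):
            haldane_r(-1.0)

    def test_disfavored_phase_weight(self):
        assert disfavored_phase_weight(0.1, 15) == pytest.approx(1e-15)
        assert disfavored_phase_weight(0.5, 7) == pytest.approx(0.5**7)
        assert disfavored_phase_weight(0.1, 1) == pytest.approx(0.1)

    def test_state_space_sizes(self, trio_chain):
        from tests_util_k2 import three_generation_pedigree

        ss = enumerate_states(trio_chain)
        assert len(ss) == 4 and ss.n_bits == 2
        # k=2 with seven members tracks six meioses -> 64 states
        ped = three_generation_pedigree(n_children=1)
        k2 = [c for c in decompose(ped, 2) if c.focus.id == "C0"][0]
        assert len(enumerate_states(k2)) == 64

    def test_transition_probability_trio(self):
        assert transition_probability([0, 0], [0, 0], 0.1) == pytest.approx(0.81)
        assert transition_probability([0, 0], [0, 1], 0.1) == pytest.approx(0.09)
        assert transition_probability([0, 0], [1, 1], 0.1) == pytest.approx(0.01)
        with pytest.raises(ParameterError):
            transition_probability([0], [0], 0.7)

    @pytest.mark.parametrize("r", [0.0, 0.05, 0.3, 0.499])
    def test_transition_rows_sum_to_one(self, r):
        T = transition_matrices(np.array([r]), 2)[0]
        np.testing.assert_allclose(T.sum(axis=1), 1.0, atol=1e-12)
        if r == 0.0:
            np.testing.assert_allclose(T, np.eye(4))


class TestEmission:
    def test_informative_trio_eight_of_thirtytwo(self, trio_chain):
        """father (1,2), mother (1,1), child (2,1), exact genotypes: exactly
        8 of the 32 (e, state) combinations are Mendelian-consistent, all
        placing allele 2 on the child's paternal chromatid."""
        ctx = trio_context([0, 1], [0, 0], [1, 0])
        total = 0.0
        consistent = 0
        for si in range(4):
            bits = [si & 1, si >> 1]
            w = emission_weight(trio_chain, bits, 0, ctx)
            total += w
            # with gamma 0.5 each consistent ordering contributes 1/8
            consistent += round(w * 8)
        assert consistent == 8
        assert total == pytest.approx(8 / 8 * 0.125 * 8)

    def test_all_homozygous_marker_equal_weight_per_state(self, trio_chain):
        ctx = trio_context([0, 0], [0, 0], [0, 0])
        weights = [
            emission_weight(trio_chain, [si & 1, si >> 1], 0, ctx)
            for si in range(4)
        ]
        assert len(set(np.round(weights, 12))) == 1

    def test_impossible_child_zero_weight_until_sureness_relaxed(self, trio_chain):
        ctx = trio_context([0, 0], [0, 0], [1, 1])
        weights = [
            emission_weight(trio_chain, [si & 1, si >> 1], 0, ctx)
            for si in range(4)
        ]
        assert max(weights) == 0.0
        ctx_soft = trio_context([0, 0], [0, 0], [1, 1], sureness=0.9)
        weights_soft = [
            emission_weight(trio_chain, [si & 1, si >> 1], 0, ctx_soft)
            for si in range(4)
        ]
        assert min(weights_soft) > 0.0

    def test_matches_enumeration_oracle_with_sureness(self, trio_chain, rng):
        ctx = random_trio_context(rng, n_markers=3, sureness_range=(0.7, 0.99))
        engine = FocusChainEngine(trio_chain)
        E = engine.emissions(ctx.slot_probs()[None], ctx.gamma[None])
        for m in range(3):
            for si in range(4):
                expected = oracle_emission(trio_chain, ctx, m, [si & 1, si >> 1])
                assert E[0, m, si] == pytest.approx(expected, rel=1e-12, abs=1e-15)

    def test_exact_sureness_reduces_to_indicator_times_skew(self, trio_chain, rng):
        """With sureness 1 everywhere, emission equals the skewness-filtered
        count of permissible orderings (the unparametrized emission rule)."""
        ctx = random_trio_context(rng, n_markers=4, sureness_range=(1.0, 1.0))
        ctx.gamma[:] = 0.5
        engine = FocusChainEngine(trio_chain)
        E = engine.emissions(ctx.slot_probs()[None], ctx.gamma[None])[0]
        for m in range(4):
            for si in range(4):
                expected = oracle_emission(trio_chain, ctx, m, [si & 1, si >> 1])
                assert E[m, si] == pytest.approx(expected, abs=1e-12)
                assert round(E[m, si] * 8, 6) == int(round(E[m, si] * 8))

    def test_sigma_flip_symmetry(self, trio_chain, rng):
        """With symmetric skewness, evaluating under any shuffling-flag
        assignment gives the same likelihood (the flag is a gauge choice)."""
        ctx = random_trio_context(rng, n_markers=3)
        ctx.gamma[:] = 0.5
        r = np.full(2, 0.1)
        base = forward_backward(trio_chain, ctx, r).log_likelihood
        total = total_loglik_over_sigma(trio_chain, ctx, r)
        assert total == pytest.approx(base + np.log(2.0), rel=1e-9)


class TestForwardBackward:
    def test_single_uninformative_marker(self, trio_chain):
        ctx = trio_context([0, 0], [0, 0], [0, 0])
        cp = forward_backward(trio_chain, ctx, np.empty(0))
        np.testing.assert_allclose(cp.state_posteriors[0], 0.25)
        weight = emission_weight(trio_chain, [0, 0], 0, ctx)
        assert cp.log_likelihood == pytest.approx(np.log(weight))

    @pytest.mark.parametrize("n_markers", [2, 3, 4])
    def test_loglik_matches_exhaustive_path_enumeration(self, trio_chain, n_markers):
        rng = np.random.default_rng(1000 + n_markers)
        for rep in range(4):
            ctx = random_trio_context(rng, n_markers, sureness_range=(0.8, 0.999))
            r = rng.uniform(0.01, 0.3, n_markers - 1)
            cp = forward_backward(trio_chain, ctx, r)
            expected = oracle_loglik(trio_chain, ctx, r)
            assert cp.log_likelihood == pytest.approx(expected, rel=1e-10)

    def test_posteriors_normalized_and_ordering_odds_match_oracle(self, trio_chain):
        rng = np.random.default_rng(77)
        ctx = random_trio_context(rng, 3, sureness_range=(0.85, 0.99))
        r = np.full(2, 0.05)
        cp = forward_backward(trio_chain, ctx, r)
        np.testing.assert_allclose(cp.state_posteriors.sum(axis=1), 1.0, atol=1e-9)
        for member in range(3):
            for m in range(3):
                expected = oracle_ordering_posterior(trio_chain, ctx, r, member, m)
                assert cp.ordering_odds[member, m] == pytest.approx(
                    expected, rel=1e-8, abs=1e-10
                )

    def test_likelihood_invariant_under_marker_reversal(self, trio_chain, rng):
        ctx = random_trio_context(rng, 4)
        r = np.array([0.05, 0.2, 0.01])
        fwd = forward_backward(trio_chain, ctx, r).log_likelihood
        ctx_rev = EmissionContext(
            slot_alleles=ctx.slot_alleles[:, ::-1],
            sureness=ctx.sureness[:, ::-1],
            gamma=ctx.gamma[:, ::-1],
            n_alleles=ctx.n_alleles[::-1],
        )
        rev = forward_backward(trio_chain, ctx_rev, r[::-1]).log_likelihood
        assert rev == pytest.approx(fwd, rel=1e-10)

    def test_skewness_relabeling_mirrors_odds_keeps_likelihood(self, trio_chain):
        """Setting a heterozygous member's skewness to g vs 1-g mirrors its
        ordering odds and leaves the likelihood unchanged."""
        base = trio_context([0, 1], [0, 1], [0, 1], gamma=0.5)
        lo = EmissionContext(
            base.slot_alleles, base.sureness, base.gamma.copy(), base.n_alleles
        )
        hi = EmissionContext(
            base.slot_alleles, base.sureness, base.gamma.copy(), base.n_alleles
        )
        lo.gamma[2, 0] = 0.2
        hi.gamma[2, 0] = 0.8
        cp_lo = forward_backward(trio_chain, lo, np.empty(0))
        cp_hi = forward_backward(trio_chain, hi, np.empty(0))
        assert cp_lo.log_likelihood == pytest.approx(cp_hi.log_likelihood, rel=1e-12)
        assert cp_lo.ordering_odds[2, 0] == pytest.approx(
            1.0 - cp_hi.ordering_odds[2, 0], rel=1e-9
        )

    def test_mendelian_conflict_names_marker(self, trio_chain):
        ctx = EmissionContext(
            slot_alleles=np.array(
                [[[0, 0], [0, 0]], [[0, 0], [0, 0]], [[0, 0], [1, 1]]],
                dtype=np.int16,
            ),
            sureness=np.ones((3, 2, 2)),
            gamma=np.full((3, 2), 0.5),
            n_alleles=np.array([2, 2]),
        )
        with pytest.raises(MendelianConflictError) as err:
            forward_backward(trio_chain, ctx, np.array([0.01]))
        assert err.value.marker_index == 1
        # error-tolerant mode floors the zero row instead
        cp = forward_backward(trio_chain, ctx, np.array([0.01]), error_tolerant=True)
        assert np.isfinite(cp.log_likelihood)

    def test_expected_recombinations_on_forced_switch(self, trio_chain):
        """A child whose paternal allele provably switches chromatid between
        two markers yields one expected paternal recombination."""
        slot = np.array(
            [[[0, 1], [0, 1]], [[0, 0], [0, 0]], [[0, 0], [1, 0]]],
            dtype=np.int16,
        )
        ctx = EmissionContext(
            slot_alleles=slot,
            sureness=np.ones((3, 2, 2)),
            gamma=np.array([[1e-6, 1e-6], [0.5, 0.5], [1e-6, 1e-6]]),
            n_alleles=np.array([2, 2]),
        )
        cp = forward_backward(trio_chain, ctx, np.array([0.01]))
        assert cp.expected_recombinations[0, 0] == pytest.approx(1.0, abs=1e-3)
        assert cp.expected_recombinations[0, 1] == pytest.approx(0.01, abs=1e-3)


class TestKTwo:
    def test_seven_member_chain_matches_trio_composition(self):
        """With uninformative grandparents, a k=2 chain's likelihood equals
        the trio likelihood up to the constant per-edge match factor 1/2
        per grandparent meiosis per marker (the extra meioses marginalize
        out)."""
        from tests_util_k2 import three_generation_pedigree

        ped = three_generation_pedigree(n_children=1)
        k2 = [c for c in decompose(ped, 2) if c.focus.id == "C0"][0]
        k1 = [c for c in decompose(ped, 1) if c.focus.id == "C0"][0]
        rng = np.random.default_rng(5)
        M = 3
        trio_ctx = random_trio_context(rng, M)
        names = [m.id for m in k2.members]
        slot = np.zeros((7, M, 2), dtype=np.int16)
        sure = np.full((7, M, 2), 0.5)
        gamma = np.full((7, M), 0.5)
        for j, name in enumerate(["F", "M", "C0"]):
            i = names.index(name)
            slot[i] = trio_ctx.slot_alleles[j]
            sure[i] = trio_ctx.sureness[j]
            gamma[i] = trio_ctx.gamma[j]
        ctx7 = EmissionContext(slot, sure, gamma, trio_ctx.n_alleles)
        r = np.full(M - 1, 0.05)
        ll7 = forward_backward(k2, ctx7, r).log_likelihood
        ll3 = forward_backward(k1, trio_ctx, r).log_likelihood
        assert ll7 == pytest.approx(ll3 + 4 * M * np.log(0.5), rel=1e-9)
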