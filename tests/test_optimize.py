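"""Modified Baum-Welch loop: updates, inversions, redistribution, determinism."""

import numpy as np
import pytest
from scipy.special import logit

from helpers import oracle_ordering_posterior, oracle_slot_posterior
from sibphase.hmm import EmissionContext
from sibphase.optimize import (
    Optimizer,
    UpdateAccumulator,
    update_recombination,
    update_skewness,
    update_sureness,
)
from sibphase.parameters import (
    OptimizerConfig,
    R_MAX,
    R_MIN,
    initialize_parameters,
)
from sibphase.pedigree import decompose
from sibphase.simulate import StructureSpec, mask_founders, simulate


def _acc(n, M, K=2):
    return UpdateAccumulator.zeros(n, M, K)


class TestSkewnessUpdate:
    def test_fixed_point_when_proposal_equals_current(self):
        gamma = np.array([[0.3, 0.7]])
        acc = _acc(1, 2)
        acc.skew_weight[:] = 1.0
        acc.skew_logodds[0] = logit(gamma[0])
        cfg = OptimizerConfig(d_gamma=0.5)
        np.testing.assert_allclose(update_skewness(acc, gamma, cfg), gamma)

    def test_cap_binds_at_rho(self):
        """From even odds, an overwhelming unanimous proposal moves the odds
        to exactly rho : 1."""
        gamma = np.array([[0.5]])
        acc = _acc(1, 1)
        acc.skew_weight[:] = 1.0
        acc.skew_logodds[0, 0] = 200.0
        cfg = OptimizerConfig(d_gamma=1.0, rho_gamma=3.0)
        out = update_skewness(acc, gamma, cfg)
        assert out[0, 0] / (1 - out[0, 0]) == pytest.approx(3.0, rel=1e-9)

    def test_cells_without_evidence_unchanged(self):
        gamma = np.array([[0.2, 0.8]])
        acc = _acc(1, 2)
        cfg = OptimizerConfig()
        np.testing.assert_allclose(update_skewness(acc, gamma, cfg), gamma)

    def test_undampened_single_pedigree_update_is_raw_posterior(self):
        """d=1 and no cap: one iteration sets each skewness to its posterior
        reversed-ordering probability, checked against the enumeration
        oracle on a two-marker trio."""
        sim = simulate(StructureSpec(1, 1, 1, n_markers=2, seed=21))
        cfg = OptimizerConfig(
            d_gamma=1.0, rho_gamma=1e9, update_sureness=False, flip_scan=False,
            n_iterations=1,
        )
        opt = Optimizer(sim.pedigree, sim.genotypes, sim.marker_map, cfg)
        chain = decompose(sim.pedigree, 1)[0]
        params0 = opt.params.copy()
        ctx = EmissionContext(
            slot_alleles=params0.slot_alleles,
            sureness=params0.sureness,
            gamma=params0.gamma,
            n_alleles=sim.marker_map.n_alleles(),
        )
        opt.iterate(0)
        rows = [params0.index_of(x) for x in ("S1", "D1_1", "O1_1_1")]
        for member, row in enumerate(rows):
            for m in range(2):
                expected = oracle_ordering_posterior(
                    chain, ctx, params0.r, member, m
                )
                assert opt.params.gamma[row, m] == pytest.approx(
                    np.clip(expected, 1e-6, 1 - 1e-6), rel=1e-6, abs=1e-7
                )


class TestSurenessUpdate:
    def test_balanced_evidence_stays_at_floor(self):
        slots = np.zeros((1, 1, 2), dtype=np.int16)
        slots[0, 0] = (0, 1)
        sure = np.full((1, 1, 2), 0.5)
        acc = _acc(1, 1)
        acc.allele_weight[:] = 1.0
        acc.allele_mass[0, 0, :, :] = 0.5  # both alleles equally supported
        out_slots, out_sure = update_sureness(
            acc, slots, sure, np.array([True]), np.array([2]), OptimizerConfig()
        )
        np.testing.assert_array_equal(out_slots, slots)
        np.testing.assert_allclose(out_sure, 0.5)

    def test_unanimous_evidence_monotone_growth(self):
        slots = np.zeros((1, 1, 2), dtype=np.int16)
        sure = np.full((1, 1, 2), 0.6)
        acc = _acc(1, 1)
        acc.allele_weight[:] = 1.0
        acc.allele_mass[0, 0, :, 0] = 1.0  # all mass on the incumbent
        cfg = OptimizerConfig()
        prev = sure
        for _ in range(30):
            _, new = update_sureness(
                acc, slots, prev, np.array([True]), np.array([2]), cfg
            )
            assert np.all(new >= prev - 1e-12)
            prev = new
        assert np.all(prev > 0.95)

    def test_relabelling_to_majority_allele(self):
        slots = np.zeros((1, 1, 2), dtype=np.int16)  # incumbent allele 0
        sure = np.full((1, 1, 2), 0.9)
        acc = _acc(1, 1)
        acc.allele_weight[:] = 1.0
        acc.allele_mass[0, 0, :, 1] = 0.95
        acc.allele_mass[0, 0, :, 0] = 0.05
        out_slots, out_sure = update_sureness(
            acc, slots, sure, np.array([True]), np.array([2]), OptimizerConfig()
        )
        assert np.all(out_slots == 1)
        assert np.all(out_sure >= 0.5)

    def test_non_optimized_rows_untouched(self):
        slots = np.zeros((2, 1, 2), dtype=np.int16)
        sure = np.full((2, 1, 2), 0.7)
        acc = _acc(2, 1)
        acc.allele_weight[:] = 1.0
        acc.allele_mass[:, :, :, 1] = 1.0
        out_slots, out_sure = update_sureness(
            acc, slots, sure, np.array([True, False]), np.array([2]),
            OptimizerConfig(),
        )
        np.testing.assert_array_equal(out_slots[1], slots[1])
        np.testing.assert_allclose(out_sure[1], sure[1])
        assert np.any(out_slots[0] != slots[0])

    def test_single_trio_slot_posterior_matches_enumeration(self):
        """One masked-parent trio, one marker: the accumulated slot allele
        posterior equals the brute-force posterior over realizations."""
        sim = simulate(StructureSpec(1, 1, 1, n_markers=1, seed=3))
        geno = mask_founders(sim.genotypes, sim.pedigree)
        cfg = OptimizerConfig(n_iterations=0)
        opt = Optimizer(sim.pedigree, geno, sim.marker_map, cfg)
        esteps, _ = opt.e_step()
        acc = opt.accumulate(esteps)
        chain = decompose(sim.pedigree, 1)[0]
        ctx = EmissionContext(
            slot_alleles=opt.params.slot_alleles,
            sureness=opt.params.sureness,
            gamma=opt.params.gamma,
            n_alleles=sim.marker_map.n_alleles(),
        )
        for member, pid in ((0, "S1"), (1, "D1_1")):
            row = opt.params.index_of(pid)
            q = acc.allele_mass[row, 0] / acc.allele_weight[row, 0]
            for slot in (0, 1):
                expected = oracle_slot_posterior(
                    chain, ctx, opt.params.r, member, slot, 0
                )
                np.testing.assert_allclose(q[slot], expected, rtol=1e-9)


class TestRecombinationUpdate:
    def test_zero_events_clip_low_and_saturation_clips_high(self):
        r_old = np.array([0.1, 0.1])
        acc = _acc(1, 3)
        acc.recomb_meioses[:] = 10.0
        acc.recomb_events[:] = 0.0
        cfg = OptimizerConfig(update_recombination=True)
        out = update_recombination(acc, r_old, cfg)
        np.testing.assert_allclose(out, R_MIN)
        acc.recomb_events[:] = 10.0
        out = update_recombination(acc, r_old, cfg)
        np.testing.assert_allclose(out, R_MAX)

    def test_frozen_map_is_untouched(self):
        r_old = np.array([0.1])
        acc = _acc(1, 2)
        acc.recomb_meioses[:] = 5.0
        acc.recomb_events[:] = 2.0
        out = update_recombination(
            acc, r_old, OptimizerConfig(update_recombination=False)
        )
        np.testing.assert_allclose(out, r_old)

    def test_recovers_simulated_fraction_within_three_se(self):
        """Fully informative markers (each parent carries a distinct allele
        pair), 600 meioses per interval, true r = 0.05: fitting with map
        updates on from a wrong starting map recovers every interval's
        fraction within 3 standard errors of the truth."""
        from helpers import trio_pedigree
        from sibphase.pedigree import GenotypeMatrix, MarkerMap

        r_true = 0.05
        n_off, M = 300, 5
        rng = np.random.default_rng(99)
        ped_inds = trio_pedigree(n_children=n_off)
        # father AB, mother CD at every marker: every transmission observable
        father = np.array([[0, 1]] * M, dtype=np.int16)
        mother = np.array([[2, 3]] * M, dtype=np.int16)
        ids, codes = ["F", "M"], [father, mother]
        for j in range(n_off):
            hap = np.empty((M, 2), dtype=np.int16)
            for side, parent in ((0, father), (1, mother)):
                chrom = rng.integers(0, 2)
                for m in range(M):
                    if m > 0 and rng.random() < r_true:
                        chrom ^= 1
                    hap[m, side] = parent[m, chrom]
            swap = rng.random(M) < 0.5
            rec = hap.copy()
            rec[swap] = rec[swap][:, ::-1]
            ids.append(f"C{j}")
            codes.append(rec)
        geno = GenotypeMatrix(ids, np.stack(codes))
        mm = MarkerMap(
            [f"M{m}" for m in range(M)],
            np.arange(M, dtype=float),
            alleles_per_marker=[("1", "2", "3", "4")] * M,
        )
        cfg = OptimizerConfig(
            n_iterations=40, update_recombination=True, update_sureness=False,
        )
        opt = Optimizer(ped_inds, geno, mm, cfg)
        opt.params.r[:] = 0.02  # start the map off target
        fit = opt.fit()
        n_meioses = float(n_off)  # per tracked parent bit, per interval
        se = np.sqrt(r_true * (1 - r_true) / (2 * n_meioses))
        assert np.all(np.abs(fit.params.r - r_true) < 3 * se)


class TestMonotonicity:
    def test_undampened_loglik_nondecreasing_on_random_trios(self):
        """Pure EM regime (d=1, no cap, no flips, fixed genotypes): the
        total log-likelihood never decreases, checked on 20 random
        three-marker trios."""
        for seed in range(20):
            sim = simulate(StructureSpec(1, 1, 1, n_markers=3, seed=1000 + seed))
            cfg = OptimizerConfig(
                d_gamma=1.0,
                rho_gamma=1e12,
                update_sureness=False,
                flip_scan=False,
                n_iterations=12,
            )
            opt = Optimizer(sim.pedigree, sim.genotypes, sim.marker_map, cfg)
            fit = opt.fit()
            ll = fit.log["loglik"].to_numpy()
            assert np.all(np.diff(ll) >= -1e-9), f"seed {seed}: {ll}"


class TestFlips:
    def _converged_fullsib(self, n_markers=40, seed=31, iters=60):
        sim = simulate(StructureSpec(1, 1, 5, n_markers=n_markers, seed=seed))
        geno = mask_founders(sim.genotypes, sim.pedigree)
        cfg = OptimizerConfig(n_iterations=iters, seed=seed)
        opt = Optimizer(sim.pedigree, geno, sim.marker_map, cfg)
        opt.fit()
        return opt

    def test_no_positive_candidate_on_uninformative_data(self):
        sim = simulate(StructureSpec(1, 1, 3, n_markers=6, seed=2))
        # make every genotype homozygous 0/0: nothing to phase
        geno = sim.genotypes.copy()
        geno.codes[:] = 0
        cfg = OptimizerConfig(n_iterations=0)
        opt = Optimizer(sim.pedigree, geno, sim.marker_map, cfg)
        candidates, applied = opt.scan_flips()
        assert applied == []

    def test_constructed_downstream_inversion_is_found_and_repaired(self):
        """Inverting a converged child's skewness from marker 10 onward
        creates exactly the error the flip scan exists for: the top
        candidate sits at marker 10 and applying it restores the
        likelihood."""
        opt = self._converged_fullsib()
        child = "O1_1_1"
        row = opt.params.index_of(child)
        before = opt._total_loglik()
        opt.params.gamma[row, 10:] = 1.0 - opt.params.gamma[row, 10:]
        damaged = opt._total_loglik()
        assert damaged < before - 1.0
        candidates, applied = opt.scan_flips()
        mine = [c for c in applied if child in c.involved]
        assert len(mine) == 1
        # ties toward lower markers can only arise across markers where the
        # child is homozygous (flipping there is emission-neutral)
        assert mine[0].marker <= 10
        rec = opt.genotypes.row(child)
        assert np.all(rec[mine[0].marker:10, 0] == rec[mine[0].marker:10, 1])
        assert opt._total_loglik() == pytest.approx(before, abs=1e-6)

    def test_each_scan_strictly_improves_total_likelihood(self):
        opt = self._converged_fullsib(seed=32, iters=5)
        for _ in range(6):
            pre = opt._total_loglik()
            _, applied = opt.scan_flips()
            post = opt._total_loglik()
            if applied:
                assert post > pre
            else:
                assert post == pytest.approx(pre, abs=1e-9)

    def test_one_flip_per_individual_per_iteration(self):
        opt = self._converged_fullsib(seed=33)
        child = "O1_1_2"
        row = opt.params.index_of(child)
        # invert an interior window: repairing it needs flips at both ends,
        # which the one-per-individual rule forbids within one scan
        opt.params.gamma[row, 10:25] = 1.0 - opt.params.gamma[row, 10:25]
        _, applied = opt.scan_flips()
        assert sum(child in c.involved for c in applied) <= 1
        # a second scan finishes the repair
        opt.scan_flips()
        _, applied3 = opt.scan_flips()
        assert sum(child in c.involved for c in applied3) == 0


class TestRedistribution:
    def _optimizer_with_codes(self, codes_by_id, r):
        sim = simulate(StructureSpec(1, 1, 1, n_markers=3, seed=1))
        geno = sim.genotypes.copy()
        for ind_id, rows in codes_by_id.items():
            geno.codes[geno.ids.index(ind_id)] = rows
        cfg = OptimizerConfig(
            n_iterations=0, update_recombination=True,
            redistribution_tolerance=1e-6,
        )
        opt = Optimizer(sim.pedigree, geno, sim.marker_map, cfg)
        opt.params.r = np.array(r, dtype=float)
        return opt

    def _uninformative(self, r):
        """All-homozygous chain: the likelihood does not depend on the map
        at all, so the even-share test succeeds at any fraction."""
        hom = [[0, 0]] * 3
        return self._optimizer_with_codes(
            {"S1": hom, "D1_1": hom, "O1_1_1": hom}, r
        )

    def test_uninformative_stretch_is_evened_out(self):
        opt = self._uninformative([0.1, R_MIN])
        before = opt._total_loglik()
        n = opt.redistribute_recombination()
        assert n >= 1
        np.testing.assert_allclose(opt.params.r, 0.05, atol=1e-9)
        after = opt._total_loglik()
        assert abs(after - before) < 1e-9

    def test_equal_fractions_are_a_noop(self):
        opt = self._uninformative([0.05, 0.05])
        before = opt.params.r.copy()
        opt.redistribute_recombination()
        np.testing.assert_allclose(opt.params.r, before)

    def test_observed_recombination_rates_not_shared(self):
        """A chain whose phases pin distinct recombination activity to the
        two intervals refuses the even share."""
        opt = self._optimizer_with_codes(
            {
                "S1": [[0, 1], [0, 1], [0, 1]],
                "D1_1": [[0, 0], [0, 0], [0, 0]],
                "O1_1_1": [[0, 0], [1, 0], [1, 0]],
            },
            [0.1, R_MIN],
        )
        f = opt.params.index_of("S1")
        c = opt.params.index_of("O1_1_1")
        opt.params.gamma[f] = 1e-6
        opt.params.gamma[c] = 1e-6
        opt.redistribute_recombination()
        assert opt.params.r[0] > 0.09  # untouched


class TestRunContract:
    def test_zero_iterations_returns_initialization(self):
        sim = simulate(StructureSpec(1, 1, 4, n_markers=10, seed=12))
        geno = mask_founders(sim.genotypes, sim.pedigree)
        cfg = OptimizerConfig(n_iterations=0, seed=5)
        init = initialize_parameters(sim.pedigree, geno, sim.marker_map, cfg)
        fit = Optimizer(sim.pedigree, geno, sim.marker_map, cfg).fit()
        np.testing.assert_allclose(fit.params.gamma, init.gamma)
        np.testing.assert_array_equal(fit.params.slot_alleles, init.slot_alleles)
        np.testing.assert_allclose(fit.params.sureness, init.sureness)

    def test_same_seed_twice_bit_identical(self):
        sim = simulate(StructureSpec(1, 1, 5, n_markers=30, seed=14))
        geno = mask_founders(sim.genotypes, sim.pedigree)
        cfg = OptimizerConfig(n_iterations=25, seed=9)
        f1 = Optimizer(sim.pedigree, geno, sim.marker_map, cfg).fit()
        f2 = Optimizer(sim.pedigree, geno, sim.marker_map, cfg).fit()
        assert np.array_equal(f1.params.gamma, f2.params.gamma)
        assert np.array_equal(f1.params.slot_alleles, f2.params.slot_alleles)
        assert np.array_equal(f1.params.sureness, f2.params.sureness)
        assert np.array_equal(f1.params.r, f2.params.r)
        assert f1.total_loglik == f2.total_loglik

    def test_grandparent_update_weights_sum_to_one_per_lineage(self):
        from tests_util_k2 import three_generation_pedigree
        from sibphase.pedigree import GenotypeMatrix, MarkerMap

        ped = three_generation_pedigree(n_children=3)
        rng = np.random.default_rng(0)
        ids = [i.id for i in ped.individuals]
        codes = rng.integers(0, 2, (len(ids), 4, 2)).astype(np.int16)
        geno = GenotypeMatrix(ids, codes)

        mm = MarkerMap(
            [f"M{i}" for i in range(4)],
            np.arange(4) * 0.05,
            alleles_per_marker=[("1", "2")] * 4,
        )
        cfg = OptimizerConfig(n_iterations=0, k=2, error_tolerant=True)
        opt = Optimizer(ped, geno, mm, cfg)
        esteps, _ = opt.e_step()
        acc = opt.accumulate(esteps)
        gf = opt.params.index_of("GF1")
        # GF1 is touched by F's own chain (1/4) and the three child chains
        # (1/4 each): one unit of weight per child lineage of F
        np.testing.assert_allclose(acc.skew_weight[gf], 1.0)
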