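# sibphase

Haplotype phasing and inference of missing or erroneous genotypes in
pedigrees — including the hard case where **both parents of a family are
completely untyped** and must be reconstructed from their offspring's
unphased genotypes alone. The typical users are animal/plant breeding and
experimental-cross geneticists holding dense SNP data with known pedigrees
but incomplete ancestral genotyping.

## The method

Instead of modelling a whole family clique as one Markov process (whose
inheritance-vector state space explodes exponentially with family size),
the pedigree is decomposed into small **focus pedigrees** — one individual
plus its ancestors *k* generations back (*k* = 1 or 2). Each runs a
time-dependent HMM over its own inheritance vector (2^(N−1) states for N
members; 4 states for a trio), and the chains are coupled through two
shared per-individual per-marker scalar parameter tables fitted by a
modified Baum–Welch loop:

* **skewness** γᵢₘ — the probability that individual *i*'s recorded allele
  pair at marker *m* is reversed relative to its true chromatid order; each
  ordering eᵢ is filtered by 1 − |eᵢ − γᵢₘ|;
* **sureness** âᵢₘ(c) — per chromatid slot, the probability that its
  candidate allele aᵢₘ(c) is correct (floored at 0.5). Untyped individuals
  enter with â = 0.5 placeholders, so completely missing genotypes become
  ordinary parameters that converge to the inferred alleles.

Transitions flip each inheritance bit independently with the interval's
recombination fraction rₘ (Haldane mapping, no interference); rₘ can
optionally be re-estimated. Updates are dampened and capped in logit space,
downstream/prefix *inversions* repair regions that converged in the
opposite phase, and undecidable markers (e.g. both parents homozygous for
different alleles in an isolated full-sib family — every offspring is then
heterozygous) are detected by a parent-swap likelihood test and refused
rather than guessed. A full account is in `docs/methods.md`.

Because the decomposition is local, 150 half-sibs are as easy as five; the
state count never depends on family size.

## Worked example

Reconstruct two fully masked parents from ten full-sib offspring
(200 biallelic markers at 0.05 cM):

```python
from sibphase import (
    StructureSpec, simulate, mask_founders, OptimizerConfig, run,
    call_genotypes, score,
)
from sibphase.evaluate import align_inferred_fullsib_families

spec = StructureSpec(n_sires=1, dams_per_sire=1, offspring_per_mating=10,
                     n_markers=200, spacing_cM=0.05, seed=7)
sim = simulate(spec)
observed = mask_founders(sim.genotypes, sim.pedigree)

fit = run(sim.pedigree, observed, sim.marker_map,
          OptimizerConfig(k=1, n_iterations=150, seed=7))
result = call_genotypes(fit)
aligned = align_inferred_fullsib_families(
    result, sim.truth, sim.pedigree, fit.params.optimize_genotype)
report = score(aligned, sim.truth, sim.pedigree)

row = report.table.loc["founders"]
print(f"final log-likelihood: {fit.total_loglik:.2f}")
print(f"parental markers called: {row.n_called} / {row.n_markers} "
      f"(refused {100*row.refused_rate:.1f}%)")
print(f"among-assigned parental accuracy: {100*row.among_assigned:.2f}%")
```

prints

```
final log-likelihood: -16.68
parental markers called: 350.0 / 400.0 (refused 12.5%)
among-assigned parental accuracy: 100.00%
```

Every called parental genotype is correct; the 12.5% refused markers are
the positions where both parents are homozygous for different alleles —
with 0.5/0.5 allele frequencies exactly ⅛ of markers are expected to be
undecidable in an isolated full-sib family, and the caller flags them
instead of guessing. Sharing a sire across several matings resolves most of
these (see `sibphase.evaluate.structure_replicate`).

## Command line

```
sibphase simulate --sires 2 --dams-per-sire 10 --offspring 15 \
    --markers 300 --mask-founders --seed 1 --out data/
sibphase phase --ped data/sim.ped --map data/sim.map \
    --generations 1 --iterations 150 --out fit/
sibphase evaluate --calls fit/phased.tsv --truth data/truth.tsv
sibphase experiment --config curve.yaml --seed 1 --out curve.tsv
```

`phase` writes phased calls (`phased.tsv`), fitted parameter tables
(`params.tsv`), a per-iteration log and a per-individual summary JSON.

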