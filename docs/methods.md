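# Methods

## Model

`sibphase` phases genotypes and reconstructs missing parental genotypes in
pedigrees by decomposing the pedigree into **focus pedigrees**: one per
non-founder individual, containing that individual plus its ancestors `k`
generations back (`k` = 1 or 2; `k = 3` would already need 16,384 states and
is rejected). Each focus pedigree carries an independent hidden Markov chain
over **inheritance vectors** — one bit per tracked meiosis stating which of
the ancestor's two chromatids was transmitted. A trio (`k = 1`) tracks two
meioses and therefore four states; a full seven-member `k = 2` unit tracks
six meioses and 64 states.

Global consistency across the overlapping focus pedigrees is *not* enforced
through a joint state space (which grows exponentially with family size) but
through two shared, per-individual per-marker scalar parameter tables that
all chains read and iteratively update:

* **skewness** `γ[i, m] ∈ [0, 1]` — the probability that individual `i`'s
  recorded (unordered) allele pair at marker `m` is reversed relative to its
  true chromatid order. Each pair-ordering `e_i ∈ {0, 1}` is filtered by the
  factor `1 − |e_i − γ[i, m]|`. 0.5 means "phase unknown".
* **sureness** `(a[i, m, c], â[i, m, c])` — a candidate allele per chromatid
  slot `c` and the probability that it is correct. The slot realizes its
  candidate with probability `â` and any other allele of the marker's allele
  set `A_m` with the complementary mass split uniformly. `â` is floored at
  0.5 (below that, another allele would be the better candidate) and capped
  at `1 − 1e−6` to keep logits finite. Untyped individuals enter with
  placeholder candidates at `â = 0.5`; this is how entirely missing parental
  genotypes become inferable parameters.

**Emissions.** Given a state `s`, an ordering string `e` and the (fixed,
all-zero) chromosome-wide shuffling flags `σ`, each tracked meiosis forces an
equality between the transmitting ancestor's slot `s ⊕ e ⊕ σ` and the
receiving chromatid's slot. The emission weight of `(s, m)` sums, over all
`2^N` orderings, the skewness filter times the probability that an
independent allele realization of all `2N` slots satisfies every equality
(computed per equality group as `Σ_α Π_slots p_slot(α)`). With all `â = 1`
this reduces exactly to the indicator of Mendelian-permissible
configurations filtered by skewness. The sum over orderings is carried out
by explicit enumeration with Mendelian-consistency groups precomputed per
`(s, e)`; all chains of one shape are evaluated as a single numpy batch.

**Transitions.** Between adjacent markers each inheritance bit flips
independently with the interval's recombination fraction `r_m ∈ [0, 0.5)`
(no interference; `r` from map distances via Haldane's function
`r = ½(1 − e^{−2d})`, `d` in Morgans). The map can optionally be
re-estimated each iteration.

**Inference** uses the scaled forward–backward algorithm (uniform state
prior, per-marker normalization with accumulated log scale), never Viterbi:
the quantities of interest — per-marker ordering posteriors and slot-allele
posteriors — are marginal posteriors, and the most probable state path is
not the most probable genotype/haplotype sequence.

## Optimization

Each of the (default 150) iterations runs the E-step over all focus
pedigrees and then, in order:

1. **Skewness update.** Per cell, the posterior log-odds of the reversed
   ordering are collected from every chain containing the individual,
   weighted (see below), averaged by total weight, and applied as a relaxed
   logit step `new = old + d·(proposed − old)` with `d = 0.1`, capped so the
   odds `γ/(1−γ)` change by at most a factor `ρ` per iteration (`ρ = 3`
   without sureness updates, 1.6 with). Dampening and capping keep
   long-range phase information flowing before any cell hardens past the
   resolution of double precision — fifteen markers at `γ = 0.1` already
   suppress the opposite phase to `1e−15`.
2. **Sureness update** (inferred first-level parents only). Per slot, the
   accumulated posterior allele distribution is compared with the incumbent
   candidate; the label switches to the argmax allele when it carries more
   mass, and `â` takes the same dampened, capped logit step toward the
   posterior, floored at 0.5. The two slots use their separate,
   skewness-resolved posteriors and are never symmetrized — this, together
   with the anchored initialization, is what keeps heterozygotes from
   collapsing into two half-sure homozygote slots.
3. **Recombination update** (optional, off by default): expected
   recombination events over weighted meiosis opportunities per interval,
   clipped to `[1e−8, 0.5 − 1e−8]`.
4. **Inversion (flip) scan.** Per-marker updates cannot repair a region that
   converged to the opposite phase ("inversion bubble"): its interior looks
   locally optimal and only its boundaries misfit. The scan evaluates, for
   every individual and marker, the exact total log-likelihood gain of
   inverting the skewness at all markers **≥ m** (downstream) and at all
   markers **< m** (prefix, computed on the reversed chain). Prefix flips
   are needed because a bubble touching the chromosome start has a single
   misfit boundary, so no downstream flip alone gains likelihood; such
   bubbles are routinely seeded by the hard phase anchor at the first
   heterozygous marker. For isolated full-sib families with both parents
   inferred, a second candidate family additionally swaps the two parents'
   full parameter columns and flips every sib (for trios this equals
   transposing the two parental state bits, so its gain costs nothing
   extra). Gains are exact (one variant backward pass against the stored
   forward pass); a greedy non-overlapping set is applied, at most one flip
   per individual per iteration, verified (with rollback to the single best
   flip) whenever applied flips share a chain, so every applied set strictly
   increases the total likelihood.
5. **Recombination redistribution** (only with map updates): for each
   adjacent interval pair, left-to-right then right-to-left, the even share
   `(r_m + r_{m+1})/2` replaces both fractions whenever that changes the
   total likelihood by less than the tolerance (default `1e−6` log-units).
   This stops the fraction of an uninformative stretch from being absorbed
   into a single interval. The pair test uses the sweep-start
   forward/backward arrays; since each applied share moves the likelihood by
   less than the tolerance, staleness is bounded by `n_shares × tol`.

**Update weighting.** Parameter evidence from different chains combines
linearly. With `k = 2`, updates flowing to the grandparent generation from an
intermediate parent with `c` offspring — from its own chain and from each
child's chain — are each divided by `c + 1`, so every child lineage
contributes one unit of total weight.

**Early exit** when the largest skewness and sureness change drops below
`1e−7` (without any flip or relabel in the iteration).

## Initialization

* Skewness: 0.5 everywhere except a hard anchor (~0) at the first
  heterozygous marker of selected individuals. A fully symmetric start
  would never break phase symmetry — but an anchor is a *hard* phase
  commitment, so it is placed only where it fixes a genuine symmetry:
  every founder (a founder's chromatid labels are arbitrary, so its anchor
  is pure gauge fixing and can never be wrong) and the first offspring of
  each mating whose parents are both untyped (pinning that family's
  parent-exchange symmetry). Anchoring every individual would guess an
  externally identified quantity — a coin flip per individual — and the
  losing flips seed wrong-phase prefix regions or, worse, drive the
  over-parametrized model into corrupted parental genotypes.
* Recorded genotypes: slot candidates = recorded pairs with `â = 1` when
  genotypes are treated as exact, or `1 − ε` (`ε` = 0.01 per allele) in
  error-tolerant mode.
* Missing parents: Mendelian pre-inference from offspring. An allele seen
  homozygous in any offspring is carried by both parents and is anchored
  first; when the other parent is typed, offspring with a unique Mendelian
  split force alleles into this parent. Slot sureness encodes the *forcing*
  support count `n_s` as `expit(n_s · logit(1 − ε) / (n/4))`, the `n/4`
  divisor being the expected count under Hardy–Weinberg. Ambiguous carriers
  — heterozygous offspring whose allele either parent could have
  transmitted — contribute ranking information but *no* initial confidence:
  starting them confident freezes the over-parametrized model into a
  heterozygous reading of every marker, and counting all carriers would let
  a single miscalled homozygote anchor a wrong allele.
* Symmetry breaking: two untyped parents of the same offspring are exactly
  interchangeable marker-by-marker; with identical initial tables, every
  posterior sits at exactly 0.5 forever (an unstable symmetric manifold of
  EM). A tiny seeded jitter (`U[0, 0.02]`) on inferred-parent sureness
  seeds a direction that the dampened updates then amplify or overturn; runs
  remain bit-reproducible for a fixed seed.

## Calling and refusal

A slot is called when `â ≥ 0.8` (chosen so clean-data experiments call
essentially all non-refused markers); the pair ordering follows the
skewness threshold rule (reversed when `γ > 0.5`, unphased exactly at 0.5;
homozygous markers are always phased). A marker in an inferred parent pair
is additionally **refused** when the two parents' called genotypes differ
yet swapping the parents' parameters at that single marker (reversing the
offspring ordering weights accordingly) shifts the total likelihood of all
affected chains by less than 0.5 log-units — less than one informative
observation (`log 2`). The classic case is both parents homozygous for
different alleles in an isolated full-sib family: every offspring is
heterozygous and the assignment is undecidable. A sire shared across
families is rescued whenever any of its other families pins its genotype;
the test is applied per mating, so cross-family information resolves the
dam as well.

## Synthetic data

The generator emulates a repeated-mating livestock design: `n_sires` sires ×
`dams_per_sire` dams × `offspring_per_mating` full sibs per mating, with
founders (sires + dams) drawn in linkage equilibrium from per-marker allele
frequencies (default biallelic 0.5/0.5, optionally Beta-distributed), equal
marker spacing (default 0.05 cM), meioses recombining independently per
interval with the Haldane fraction (no interference, matching the HMM), and
recorded pairs shuffled uniformly at random. The default shape
(20×10×15, 1,998 markers) produces 3,220 individuals with 220 founders.
Error injection miscalls each offspring allele independently (default 1%,
i.e. ≈2% of genotypes), replacing it with a uniformly chosen different
allele of `A_m`. Founder masking blanks all founder genotypes, making the
parental-reconstruction experiments possible with full ground truth.

Not emulated: linkage disequilibrium between founders, crossover
interference, genotyping-error structure beyond uniform miscalls, skewed
real-data allele-frequency spectra (the reference data's ignored-marker
rates depend on that spectrum, so refusal *rates* are only qualitatively
comparable; accuracy among assigned markers is the quantitative metric),
and sex-specific recombination. Passing tests therefore demonstrate
correctness of the machinery under the stated generative model, not
robustness to real-data artifacts beyond the injected miscalls.

## Evaluation

Accuracy is scored per individual group (founders / sires / dams /
offspring) as the proportion of markers whose called unordered genotype
matches the truth, in two conventions: **among-assigned** (refused markers
excluded) and **overall** (refusals counted wrong); both are reported
because the two conventions correspond to different headline summaries of
the same experiments. Isolated full-sib families are aligned to the truth
block-wise before scoring (blocks delimited by refused markers, choosing
per block the parent labelling that agrees best with truth), since the
parent labels of such a family are fundamentally unidentifiable. Phasing is
additionally summarized as a switch-error rate over consecutive correctly
called heterozygous markers.

Problem sizes used by the shipped experiments: the repeated-mating runs use
2 sires × 10 dams × 15 offspring with 300 markers (322 individuals, 300
trio chains), and the full-sib runs 5 or 15 offspring with 200 markers,
both at 0.05 cM and 150 iterations — small enough that a complete
experiment battery runs on a laptop in minutes while preserving every
qualitative feature (cross-family resolution, refusal behaviour, error
tolerance) of the full-scale design.

## Numerical choices

Scaled forward/backward with per-marker normalization; skewness clamped to
`[1e−6, 1 − 1e−6]`; posterior probabilities clipped at `1e−15` before
logits; zero-emission rows raise a Mendelian-conflict error naming the
marker unless error-tolerant mode floors them at `1e−12`; flip gains must
exceed `1e−9` to be applied; greedy flip ties break by (gain, lower marker,
lexicographic id); redistribution tolerance `1e−6`. The dampened/capped
logit steps are deliberately *not* exact EM — with `d = 1`, no capping and
no flips the loop reduces to plain Baum–Welch and its monotonicity
guarantee, which the tests assert on small instances.

## Known limitations

* Sureness is optimized only for first-level parents; offspring genotype
  errors are absorbed by the error-tolerant emission, not corrected.
* Parent-swap flips are restricted to isolated full-sib families; the
  general graph-matching version of cross-family flips is out of scope.
* One chromosome per run; multi-chromosome data are sequential runs.
* Per-interval recombination fractions are only weakly identified from
  biallelic double-heterozygous markers; map re-estimation is therefore off
  by default and best used after phases have converged.
* With `k = 2` the emission enumeration over `2^7` orderings × `2^6` states
  is exact but slow at scale; `k = 1` is the production path.
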