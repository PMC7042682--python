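# Methods

## Model

`fdrecomb` iterates the deterministic genotype-frequency recursion of an
infinite, panmictic, obligately sexual diploid population with discrete,
non-overlapping generations.  The genome is one chromosome carrying a
selectively neutral recombination-modifier locus *M* followed by two or
three selected loci (*A*, *B*, *C*), in the order M–A–B–C.  Each locus is
biallelic; selected loci carry a wild-type or a deleterious mutant allele.
With `n` selected loci there are `2^(n+1)` haplotypes; the population state
at the gamete-pool census is the vector of haplotype frequencies, and
zygotes are always its Hardy–Weinberg outer product.  Genotype-frequency
matrices are stored ordered with enforced symmetry, which is equivalent to
the unordered formulation and lets the whole life cycle collapse into one
precomputed linear operator applied to the outer product of the gamete
vector — one matrix–vector product per generation.

One generation is: viability selection on diploids → meiosis → mutation in
the gamete pool → random union of gametes.  All per-genotype quantities
(fitness, realised recombination rates, gamete distributions) depend only on
genotype identity, never on time, so the meiosis operator
`P^r[i, j, k] = P(gamete k | genotype ij)` and the mutation operator are
built once per parameter set.

### Fitness

A genotype with `N_he` heterozygous and `N_ho` homozygous mutations has

    W = (1-hs)^N_he (1-s)^N_ho
        (1+e_axa)^P_axa (1+e_axd)^P_axd (1+e_dxd)^P_dxd

with integer interaction counts `P_axa = N_he(N_he-1)/2 + 2 N_he N_ho +
4 N_ho(N_ho-1)/2`, `P_axd = N_he N_ho + 4 N_ho(N_ho-1)/2`, `P_dxd =
N_ho(N_ho-1)/2` (each mutated locus contributes an additive dose of 1 when
heterozygous and 2 when homozygous, and a dominance dose of 1 when
homozygous; the counts enumerate the pairwise dose products).  `s` and `h`
are shared by all selected loci.  The modifier locus is neutral.

### Recombination strategies and meiosis

A modifier allele confers either a constant rate `r_const` for the intervals
inside the selected system (`r_AB = r_BC = r_S` in the three-locus system)
or an FD reaction norm: `r(W)` interpolates linearly from `r_max` at
`W = W_min` to `r_min` at `W = W_max`.  The normalising bounds are the
extreme fitnesses over all *possible* recombination-responsive genotypes
(heterozygous at ≥ 2 selected loci) in the three-locus system; in the
two-locus system, where the only responsive genotype class is the double
heterozygote, the bounds are taken over all genotypes.  Enumerating possible
rather than currently present genotypes keeps the reaction norm
time-invariant.  Fitnesses of non-responsive genotypes (whose rates are
immaterial anyway) are clamped into `[W_min, W_max]` before interpolating;
when the landscape is flat (`W_min = W_max`, e.g. s = 0) FD strategies
return the midpoint `(r_min + r_max)/2`, a selection-neutral fallback that
avoids the 0/0.  All rates are clipped to the physical range [0, 0.5].

Modifier alleles are purely codominant: a modifier-heterozygous genotype
realises, in every interval, the arithmetic mean of its two alleles'
realised rates.  (Averaging realised rates versus averaging strategy
parameters is equivalent for the linear norm whenever the two alleles share
the fitness bounds, which they always do here since bounds depend only on
the selection parameters.)

Crossover occurrence in the A–B × B–C pair follows the coincidence model
`P(1,1) = c·r1·r2`, `P(1,0) = r1 − c·r1·r2`, `P(0,1) = r2 − c·r1·r2`,
`P(0,0) = 1 − r1 − r2 + c·r1·r2`; the modifier-side interval M–A assorts
independently (interference is modelled inside the selected system only).
For `r ≤ 0.5` and `c ≤ 2` all pattern probabilities are automatically
non-negative; the builder still validates defensively.  A gamete is a strand
walk: start on either parental haplotype with probability ½ and switch
strands at every interval whose pattern bit is set.  Note the marginal
transmission of each heterozygous locus is ½ and the A–B recombinant
fraction equals `r1` for every `c` — interference only redistributes double
crossovers.

Mutation acts on the gamete pool after meiosis, per selected locus
independently, wild-type → mutant with probability `u`, irreversibly; the
modifier locus never mutates.

### Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| `s` | homozygous deleterious effect | — | scanned 0.01–1 |
| `h` | dominance | — | scanned 0–1 |
| `e_axa, e_axd, e_dxd` | epistasis components | 0 | scanned −1–1 |
| `u` | per-locus gamete mutation rate | 1e-4 | deliberately high so the balance is numerically well resolved |
| `r_MA` | modifier–selected distance | 0.5 (unlinked) / 0.05 (linked) | the two linkage scenarios compared throughout |
| `c` | coefficient of coincidence | 1 | no interference; 0 and 2 probe full positive / strong negative interference |
| `Δ = r_max − r_min` | plastic-effect magnitude | 0.05 | headline magnitude; up to 0.5 explored |

## Experiments

**Equilibration.**  Runs start from the population monomorphic wild-type at
the selected loci and fixed for the resident modifier allele; recurrent
mutation then builds the balance (the attractor is unique under purifying
selection, making the start state immaterial).  Equilibrium is diagnosed
when every selected-locus allele frequency changes by less than 10⁻¹² per
generation, measured at the zygote census; the generation cap defaults to
10⁶ and non-convergence is flagged, not raised.  Frequencies are
renormalised every generation to absorb floating-point drift.  Equilibria
are always computed from the cold start: warm-starting from a neighbouring
parameter set's equilibrium can satisfy the allele-frequency criterion
immediately while linkage disequilibrium is still relaxing, silently
corrupting downstream invasion tests.

**Invasion and resistance.**  The invader modifier allele replaces 5% of
every resident haplotype's frequency mass (selected alleles unchanged), so
it enters in linkage equilibrium with the resident selected-haplotype
distribution — introducing it any other way would inject linkage
disequilibrium that itself selects on the modifier.  The polymorphic phase
runs 10,000 generations; invasion means a final frequency above
0.05 + 10⁻⁹.  The threshold sits roughly three decades above the observed
numerical noise floor (neutral runs stay within ~10⁻¹³ of 0.05 over 10⁴
generations) and below every genuine selective response observed in the
deleterious regime (≥ ~5×10⁻⁹ per 10⁴ generations).  Strategy S₁ is *more
advantageous* than S₂ only if it passes both the invasion and the
resistance test.

**Optimal constant rate.**  Pairwise invasion sweeps chain upward from
`r_S = 0` (each one-step-higher allele replaces the resident while it keeps
invading) and downward from 0.5, over three iterations with steps 0.01,
0.001 and 0.0001; the final bracket is at most 10⁻⁴ wide and its midpoint is
`r_S*`.  Refinement iterations sweep between the *min and max* of the two
current estimates: with a near-symmetric pairwise-invasibility plot the
coarse upward sweep can land one step above the optimum, and taking the
literal (lower, higher) pair would invert the bracket.  A landscape in which
neither boundary sweep moves at the coarsest step is classified *free*
(every constant rate neutral — multiplicative selection, or degenerate
landscapes); a bracket collapsing onto 0 is *zero*; anything else
*intermediate* (including an optimum at 0.5).  The sweeps use invasion tests
only; the two-test criterion is reserved for strategy-versus-strategy
verdicts.

**FD variants.**  Around an intermediate optimum: +FD `(r*, r*+Δ)`, −FD
`(r*−Δ, r*)`, ±FD `(r*−Δ/2, r*+Δ/2)`; around a zero optimum only +FD
`(0, Δ)` is meaningful.  Ranges are clipped at [0, 0.5] and flagged.  The
*distant-interval* variant restricts the FD effect to B–C with a doubled
range `(r*, r*+2Δ)` while holding A–B constant at `r*`, isolating the
FD-induced modulation of the modifier's linkage; the *selfish* variant keeps
`r_S = r*` constant and makes only `r_MA` fitness dependent, over
`(r_MA, r_MA + Δ)` — with an unlinked modifier that range clips to nothing,
so the variant is informative in the linked scenario, where it reproduces
the neutrality expected from the failure of the abandon-ship mechanism in
diploids.

**Selection-strength probe.**  Carriers of the FD allele are burdened with a
multiplicative penalty (heterozygotes pay `(1−cost)^½`); geometric ascent
from 10⁻¹⁶ followed by log-space bisection brackets, within a factor of two,
the smallest cost at which invasion fails.  Undefined (returns `None`) when
the FD allele does not invade at zero cost.

**Scans.**  The full grid mirrors the headline design (s ∈ {0.01, 0.1, …,
1}; h ∈ {0, 0.2, …, 1}; e_axa from −1 to 1 in steps of 0.1; e_axd treated
coarsely in five steps and e_dxd = 0, their effects being one and two orders
weaker; c ∈ {0, 1, 2} selectable; both linkages) and is an overnight
single-CPU job — the expensive optimum search runs once per cell and is
shared across variants, and a JSON-lines cache makes scans restartable.
`--reduce K` thins every axis for desk-scale runs of the same protocol.
Everything is deterministic, so results are bit-reproducible.

## The deleterious regime

With strong positive epistasis the model leaves the regime it was built
for: `(1+e_axa)^P` can overwhelm `(1−s)^N`, making multi-mutant genotypes
*fitter than the wild type* (at s = 0.2, e_axa = +0.5 the triple homozygote
has W ≈ 66).  Under unidirectional mutation such cells converge to mutant
fixation — a monomorphic state where every recombination strategy is exactly
neutral — rather than to a mutation–selection balance.  The predicate
`scan.in_msb_regime` (every genotype class at most as fit as wild type)
flags these cells; within the regime, positive additive-by-additive
epistasis always yields a zero optimal constant rate, and intermediate
optima arise only under negative epistasis.

A related boundary: for recessive mutations (h = 0) the balance frequency is
`q* ≈ √(u/s)`, which at s = 0.01 and u = 10⁻⁴ reaches 0.1 — deterministic
recessive balances at weak selection are *not* rare-mutant states.  The
acceptance script reports the realised maximum over its grid rather than
assuming rarity.

## What the tests do and do not show

All inputs are configuration; there is no external data.  The test suite
validates the machinery against independent oracles (pairwise enumeration of
epistatic interaction counts, brute-force strand-walk enumeration of
meiosis, closed-form mutation-selection balances, hand-counted summaries)
and the experiment layer against the qualitative structure of the model's
known behavior on *desk-scale* parameter cells: single cells for the search
contract and variant orderings, four-cell reduced grids for the
linked-versus-unlinked contrast.  Headline full-grid proportions are
properties of thousands-of-cell scans and are only reproduced by the
documented full-grid mode, not by the test suite.  The model is an
infinite-population deterministic idealisation: no drift, no stochastic
invasion dynamics, no sex-specific rates, equal `s` and `h` across loci, at
most three selected loci, two alleles per locus, and no de-novo mutation at
the modifier.  Conclusions about real (finite, noisy) populations therefore
rest on the selection differentials being large relative to drift — which
the selection-strength probe shows is *not* generally the case (direct costs
of order 10⁻⁸–10⁻¹⁰ suffice to cancel the FD advantage), a caveat inherited
from the modifier-model tradition rather than introduced by this
implementation.

## Known limitations

- The invasion decision threshold (10⁻⁹ absolute gain over 10⁴ generations)
  is a numerical-significance cutoff, not a proof of asymptotic invasion;
  selection differentials within ~an order of magnitude of the noise floor
  are classified as neutral.
- The optimum search assumes an (approximately) unimodal invasibility
  landscape; genuinely bimodal landscapes would be mis-bracketed.  None were
  observed in the deleterious regime.
- Equilibration near s → 0 converges slowly; the 10⁶-generation cap is
  reported via `EquilibriumReport.converged` rather than raised.
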