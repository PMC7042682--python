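# fdrecomb

Deterministic recombination-modifier models for studying the evolution of
**fitness-dependent (FD) recombination** in diploids under mutation–selection
balance.

## The scientific problem

Recombination rates in many diploids (flies, tomato, wheat) are plastic:
individuals of lower fitness tend to produce more recombinant gametes.  Is
such a reaction norm itself evolvable?  `fdrecomb` implements the classical
modifier-locus approach for an infinite, panmictic, obligately sexual diploid
population: a selectively neutral locus *M* controls the recombination rates
inside a linked system of two or three selected loci (*M–A–B–C*), each
segregating a wild-type and a deleterious mutant allele.  Recurrent
unidirectional mutation (rate *u* per locus per gamete) is balanced by
purifying selection; the fate of rare modifier alleles reveals the indirect
selection acting on recombination strategies.

The life cycle iterates the exact genotype-frequency recursion

```
pˢ(x_ij) = p(x_ij) W(x_ij) / Σ p W          (selection on diploids)
p(g_k)   = Σ_ij pˢ(x_ij) P^r_{ij→k}          (meiosis, with interference)
pᵐ(g_k)  = Σ_l  p(g_l)  P^m_{l→k}            (unidirectional mutation)
p_{t+1}(x_ij) = pᵐ(g_i) pᵐ(g_j)              (random union of gametes)
```

Fitness follows the standard multilocus model with three epistasis
components: a genotype with `N_he` heterozygous and `N_ho` homozygous
mutations has

```
W = (1−hs)^N_he (1−s)^N_ho (1+e_a×a)^P_a×a (1+e_a×d)^P_a×d (1+e_d×d)^P_d×d
```

where the interaction counts are `P_a×a = N_he(N_he−1)/2 + 2N_heN_ho +
4N_ho(N_ho−1)/2`, `P_a×d = N_heN_ho + 4N_ho(N_ho−1)/2`, and
`P_d×d = N_ho(N_ho−1)/2`.

Modifier alleles carry **recombination strategies**: either a constant rate
`r_S` for the intervals inside the selected system, or an FD reaction norm
that interpolates linearly from `r_max` (for the least-fit
recombination-responsive genotype, fitness `W_min`) down to `r_min` (at
`W_max`).  Crossovers in the A–B × B–C interval pair are coupled by the
coefficient of coincidence `c` (0 = full positive interference, 1 = none,
2 = negative interference); modifier alleles act codominantly (a heterozygote
expresses the mean of its two alleles' realised rates).

On top of the recursion the package provides the full invasion-analysis
toolkit:

- **invasion / resistance tests** — a rare allele (frequency 0.05) against a
  nearly fixed, equilibrated resident, run for 10,000 generations; strategy
  S₁ beats S₂ only if it both invades and resists;
- **optimal constant rate `r_S*`** — a three-iteration bracketing sweep of
  pairwise invasion comparisons (steps 0.01, 0.001, 0.0001; final bracket
  ≤ 10⁻⁴) classifying each parameter cell as *zero*, *intermediate* or
  *free* (neutral);
- **FD-vs-optimal comparisons** — +FD, −FD and ±FD variants around `r_S*`,
  the *distant-interval* variant (FD effect on B–C only) and the *selfish*
  variant (FD effect on the modifier-side interval only);
- **parameter-grid scans** — proportions of cells where FD recombination is
  favored, with heatmap-ready exports, restartable caching, and a CLI.

## Worked example

Equilibrate a three-locus system under semidominant selection
(s = 0.2, h = 0.5, no epistasis) with a constant rate 0.1:

```bash
$ fdrecomb equilibrate --s 0.2 --h 0.5 --strategy const:0.1
{
  "converged": true,
  "generations": 176,
  "allele_freqs": [0.0009999, 0.0009999, 0.0009999],
  "mean_fitness": 0.99940018,
  "v": 0.03160538,
  ...
}
```

The equilibrium mutant frequency matches the classical balance
`q* ≈ u/(hs) = 10⁻⁴/0.1 = 10⁻³` at every locus, and the mean fitness the
corresponding `(1−hs q*)`-per-locus product.  Under negative
additive-by-additive epistasis and a linked modifier the optimal constant
rate becomes intermediate, and the recombination-increasing FD strategy
displaces it:

```bash
$ fdrecomb optimal-rr --s 0.1 --h 0.5 --e-axa -0.1 --r-ma 0.05
{"r_low": 0.08, "r_high": 0.08, "r_star": 0.08, "classification": "intermediate", ...}

$ fdrecomb compare-fd --s 0.1 --h 0.5 --e-axa -0.1 --r-ma 0.05 --variant +FD --r-star 0.08
{"variant": "+FD", "s1": "fd(0.08,0.13)", "s2": "const(0.08)",
 "invades": true, "resists": true, "advantageous": true,
 "delta_mean_fitness": 1.54e-10, "delta_v": -6.88e-09, "delta_mean_rs": 2.13e-09}
```

The +FD allele (rates varying from 0.08 up to 0.13 with falling fitness)
invades the optimal-constant resident *and* resists reinvasion; the
monomorphic FD population has a minutely higher mean fitness, lower genetic
variation and a slightly raised population mean recombination rate — the
signature of the differential-disruption advantage, which exists only with
three selected loci (double heterozygotes must differ in fitness for the
reaction norm to have anything to act on; the two-locus control never favors
FD).

Full-grid scans (`fdrecomb scan --out scan.csv --cache cells.jsonl`) sweep
s × h × epistasis × interference × linkage; the default grid is an overnight
single-CPU job, and `--reduce K` coarsens every axis for desk-scale runs.
`fdrecomb summarize` aggregates the FD-favored proportions and exports
(s, |e_a×a|, h) heatmap tables.

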