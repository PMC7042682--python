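"""Meiosis: crossover patterns, gamete distributions, and gamete mutation.

A diploid produces gametes by a strand walk along the locus order M-A-B-C:
the walk starts on either parental haplotype with probability 1/2 and
switches strands at every interval in which a crossover occurred.  Crossover
occurrence in the two intervals inside the selected system (A-B and B-C) is
coupled through the coefficient of coincidence ``c`` (ratio of observed to
expected double crossovers); the modifier-side interval M-A assorts
independently.

Mutation acts on the gamete pool after meiosis: each wild-type allele at a
selected locus mutates with probability ``u`` per gamete, irreversibly; the
modifier locus never mutates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .genetics import (
    FitnessParams,
    Genotype,
    Haplotype,
    RecombinationStrategy,
    SystemConfig,
    R_MAX_PHYSICAL,
    fitness_bounds,
    genotype_fitness,
    strategy_interval_rates,
)

__all__ = [
    "IntervalRates",
    "realized_rates",
    "crossover_pattern_probs",
    "gamete_distribution",
    "mutate_pool",
    "transmission_tensor",
    "mutation_matrix",
    "dump_transmission_table",
]


@dataclass(frozen=True)
class IntervalRates:
    """Per-genotype recombination fractions for the chromosome intervals.

    ``r0`` is the modifier-side interval M-A; ``r1`` the interval A-B; ``r2``
    the interval B-C (``None`` in the two-locus system).
    """

    r0: float
    r1: float
    r2: float | None = None

    def __post_init__(self) -> None:
        for r in (self.r0, self.r1) + (() if self.r2 is None else (self.r2,)):
            if not 0.0 <= r <= R_MAX_PHYSICAL:
                raise ValueError(f"interval rate {r} outside [0, 0.5]")

    def as_tuple(self) -> tuple[float, ...]:
        return (self.r0, self.r1) if self.r2 is None else (self.r0, self.r1, self.r2)


def realized_rates(genotype: Genotype,
                   strategies: Mapping[int, RecombinationStrategy],
                   params: FitnessParams,
                   config: SystemConfig,
                   bounds: tuple[float, float] | None = None) -> IntervalRates:
    """Interval rates realised by a genotype under codominant modifier alleles.

    Each carried modifier allele evaluates its strategy's reaction norm on the
    genotype's fitness; the genotype's rate in every interval is the
    arithmetic mean of the two alleles' realised rates (codominance).
    """
    if bounds is None:
        bounds = fitness_bounds(params, config)
    w = genotype_fitness(genotype, params)
    votes = [strategy_interval_rates(strategies[m], w, bounds, config)
             for m in genotype.modifier_alleles]
    mean = tuple(0.5 * (a + b) for a, b in zip(*votes))
    if config.n_selected == 2:
        return IntervalRates(r0=mean[0], r1=mean[1])
    return IntervalRates(r0=mean[0], r1=mean[1], r2=mean[2])


def crossover_pattern_probs(rates: IntervalRates,
                            c: float) -> dict[tuple[int, ...], float]:
    """Joint probabilities of crossover occurrence patterns.

    Keys are bit tuples, one bit per interval in chromosome order
    (M-A, A-B[, B-C]); bit 1 means a crossover occurred in that interval.
    Within the selected system the A-B x B-C pair follows

        P(1,1) = c r1 r2,   P(1,0) = r1 - c r1 r2,
        P(0,1) = r2 - c r1 r2,   P(0,0) = 1 - r1 - r2 + c r1 r2,

    while the M-A interval assorts independently.  Raises ``ValueError``
    when the (r, c) combination would produce a negative probability.
    """
    r0 = rates.r0
    if rates.r2 is None:
        inner = {(0,): 1.0 - rates.r1, (1,): rates.r1}
    else:
        r1, r2 = rates.r1, rates.r2
        dbl = c * r1 * r2
        inner = {(1, 1): dbl, (1, 0): r1 - dbl, (0, 1): r2 - dbl,
                 (0, 0): 1.0 - r1 - r2 + dbl}
        if any(p < 0.0 for p in inner.values()):
            raise ValueError(
                f"invalid rates/coincidence combination r1={r1}, r2={r2}, c={c}: "
                "negative crossover-pattern probability")
    probs: dict[tuple[int, ...], float] = {}
    for b0 in (0, 1):
        p0 = r0 if b0 else 1.0 - r0
        for bits, p in inner.items():
            probs[(b0, *bits)] = p0 * p
    return probs


def _walk(hap_a: tuple[int, ...], hap_b: tuple[int, ...], start: int,
          pattern: tuple[int, ...]) -> tuple[int, ...]:
    # strand walk: allele at locus 0 comes from the start strand; a set bit in
    # interval t switches strands between loci t and t+1
    strands = (hap_a, hap_b)
    cur = start
    out = [strands[cur][0]]
    for t, bit in enumerate(pattern):
        if bit:
            cur ^= 1
        out.append(strands[cur][t + 1])
    return tuple(out)


def gamete_distribution(genotype: Genotype, rates: IntervalRates,
                        c: float) -> dict[Haplotype, float]:
    """Distribution of gametes produced by one genotype in meiosis.

    Sums the strand walk over both possible start strands (probability 1/2
    each) and all crossover patterns weighted by
    :func:`crossover_pattern_probs`.
    """
    loci_a = (genotype.hap1.modifier, *genotype.hap1.selected)
    loci_b = (genotype.hap2.modifier, *genotype.hap2.selected)
    dist: dict[Haplotype, float] = {}
    for pattern, p in crossover_pattern_probs(rates, c).items():
        if p == 0.0:
            continue
        for start in (0, 1):
            alleles = _walk(loci_a, loci_b, start, pattern)
            hap = Haplotype(modifier=alleles[0], selected=alleles[1:])
            dist[hap] = dist.get(hap, 0.0) + 0.5 * p
    return dist


def mutate_pool(pool: Mapping[Haplotype, float], u: float) -> dict[Haplotype, float]:
    """Apply unidirectional per-locus mutation to a gamete pool.

    Each wild-type allele at a selected locus becomes mutant with
    probability ``u``, independently across loci; mutant alleles never
    revert and the modifier allele is untouched.
    """
    out: dict[Haplotype, float] = {}
    for hap, p in pool.items():
        if p == 0.0:
            continue
        wild = [i for i, a in enumerate(hap.selected) if a == 0]
        for flips in itertools.product((0, 1), repeat=len(wild)):
            q = p
            sel = list(hap.selected)
            for locus, f in zip(wild, flips):
                q *= u if f else (1.0 - u)
                if f:
                    sel[locus] = 1
            if q == 0.0:
                continue
            new = Haplotype(modifier=hap.modifier, selected=tuple(sel))
            out[new] = out.get(new, 0.0) + q
    return out


# ---------------------------------------------------------------------------
# dense precomputed operators used by the dynamics recursion


def transmission_tensor(strategies: Mapping[int, RecombinationStrategy],
                        params: FitnessParams,
                        config: SystemConfig) -> np.ndarray:
    """Dense meiosis operator ``T[i, j, k] = P(gamete k | genotype (i, j))``.

    Indices are dense haplotype encodings (:attr:`Haplotype.index`).  The
    tensor is symmetric in (i, j) and each (i, j) slice sums to 1.  Rates are
    genotype specific (FD strategies, codominance) but time invariant, so the
    tensor is computed once per model.
    """
    n = config.n_haplotypes
    bounds = fitness_bounds(params, config)
    t = np.zeros((n, n, n))
    for i in range(n):
        hi = Haplotype.from_index(i, config.n_selected)
        for j in range(i, n):
            hj = Haplotype.from_index(j, config.n_selected)
            g = Genotype(hi, hj)
            rates = realized_rates(g, strategies, params, config, bounds)
            for hap, p in gamete_distribution(g, rates, config.c).items():
                t[i, j, hap.index] += p
            t[j, i] = t[i, j]
    return t


def mutation_matrix(config: SystemConfig) -> np.ndarray:
    """Dense mutation operator ``M[k, l] = P(gamete l mutates into gamete k)``."""
    n = config.n_haplotypes
    m = np.zeros((n, n))
    for l in range(n):
        src = Haplotype.from_index(l, config.n_selected)
        for hap, p in mutate_pool({src: 1.0}, config.u).items():
            m[hap.index, l] += p
    return m


def dump_transmission_table(t: np.ndarray, config: SystemConfig, path) -> None:
    """Write the meiosis operator as a TSV table (rows: genotypes, cols: gametes)."""
    haps = [str(Haplotype.from_index(k, config.n_selected))
            for k in range(config.n_haplotypes)]
    with open(path, "w") as fh:
        fh.write("genotype\t" + "\t".join(haps) + "\n")
        for i in range(config.n_haplotypes):
            for j in range(i, config.n_haplotypes):
                row = "\t".join(f"{t[i, j, k]:.12g}"
                                for k in range(config.n_haplotypes))
                fh.write(f"{haps[i]}/{haps[j]}\t{row}\n")
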