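"""Genetic system: haplotypes, epistatic fitness, recombination strategies.

The model considers a selectively neutral recombination-modifier locus *M*
followed by two or three selected loci (*A*, *B*, *C*), arranged on one
chromosome as M-A-B-C.  Each selected locus carries a wild-type or a
deleterious mutant allele; fitness of a diploid genotype depends only on the
numbers of heterozygous (``N_he``) and homozygous (``N_ho``) mutations via a
standard multilocus model with three multiplicative epistasis components
(additive-by-additive, additive-by-dominance, dominance-by-dominance).

Modifier alleles confer *recombination strategies*: either a constant
recombination rate for the intervals inside the selected system, or a
fitness-dependent (FD) reaction norm in which the rate decreases linearly
from ``r_max`` (for the least-fit genotype) to ``r_min`` (for the fittest).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

__all__ = [
    "SystemConfig",
    "Haplotype",
    "Genotype",
    "FitnessParams",
    "RecombinationStrategy",
    "count_mutations",
    "epistatic_powers",
    "genotype_fitness",
    "is_recombination_responsive",
    "fitness_bounds",
    "fd_rate",
    "enumerate_haplotypes",
]

#: physical bound on a recombination fraction per interval
R_MAX_PHYSICAL = 0.5

#: conventional linked / unlinked positions of the modifier locus
R_MA_LINKED = 0.05
R_MA_UNLINKED = 0.5


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class SystemConfig:
    """Structural parameters of the genetic system.

    Parameters
    ----------
    n_selected:
        Number of selected loci (2 or 3).
    r_ma:
        Recombination fraction between the modifier locus and the first
        selected locus; 0.5 means the modifier is unlinked.
    u:
        Per-locus, per-gamete mutation probability.  Mutation is
        unidirectional (wild-type -> mutant); the modifier locus does not
        mutate.
    c:
        Coefficient of coincidence for the A-B x B-C interval pair
        (3-locus system only): 0 = full positive interference (no double
        crossovers), 1 = no interference, 2 = negative interference.
    """

    n_selected: int = 3
    r_ma: float = R_MA_UNLINKED
    u: float = 1e-4
    c: float = 1.0

    def __post_init__(self) -> None:
        if self.n_selected not in (2, 3):
            raise ValueError(f"n_selected must be 2 or 3, got {self.n_selected}")
        if not 0.0 <= self.r_ma <= R_MAX_PHYSICAL:
            raise ValueError(f"r_MA must lie in [0, 0.5], got {self.r_ma}")
        if not 0.0 <= self.u < 1.0:
            raise ValueError(f"u must lie in [0, 1), got {self.u}")
        if not 0.0 <= self.c <= 2.0:
            raise ValueError(f"c must lie in [0, 2], got {self.c}")

    @property
    def modifier_linked(self) -> bool:
        return self.r_ma < R_MA_UNLINKED

    @property
    def n_haplotypes(self) -> int:
        return 1 << (self.n_selected + 1)

    @classmethod
    def linked(cls, n_selected: int = 3, **kw) -> "SystemConfig":
        return cls(n_selected=n_selected, r_ma=R_MA_LINKED, **kw)

    @classmethod
    def unlinked(cls, n_selected: int = 3, **kw) -> "SystemConfig":
        return cls(n_selected=n_selected, r_ma=R_MA_UNLINKED, **kw)

    def to_dict(self) -> dict:
        return {"n_selected": self.n_selected, "r_MA": self.r_ma,
                "u": self.u, "c": self.c}

    @classmethod
    def from_dict(cls, d: Mapping) -> "SystemConfig":
        return cls(n_selected=int(d.get("n_selected", 3)),
                   r_ma=float(d.get("r_MA", R_MA_UNLINKED)),
                   u=float(d.get("u", 1e-4)),
                   c=float(d.get("c", 1.0)))


# ---------------------------------------------------------------------------
# haplotypes and genotypes


@dataclass(frozen=True, order=True)
class Haplotype:
    """A gamete: one modifier allele plus one allele per selected locus.

    Allele coding is 0 = wild-type, 1 = mutant (selected loci) and 0/1 for
    the two modifier alleles.
    """

    modifier: int
    selected: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.modifier not in (0, 1):
            raise ValueError("modifier allele must be 0 or 1")
        if any(a not in (0, 1) for a in self.selected):
            raise ValueError("selected alleles must be 0 or 1")

    @property
    def index(self) -> int:
        """Dense integer encoding: modifier is the highest bit, locus A next."""
        idx = self.modifier
        for a in self.selected:
            idx = (idx << 1) | a
        return idx

    @classmethod
    def from_index(cls, idx: int, n_selected: int) -> "Haplotype":
        bits = [(idx >> k) & 1 for k in range(n_selected, -1, -1)]
        return cls(modifier=bits[0], selected=tuple(bits[1:]))

    def __str__(self) -> str:  # e.g. "M:aBC"
        names = "ABC"
        sel = "".join(names[i].lower() if a else names[i]
                      for i, a in enumerate(self.selected))
        return f"{'m' if self.modifier else 'M'}:{sel}"


def enumerate_haplotypes(config: SystemConfig) -> list[Haplotype]:
    """All haplotypes in dense-index order."""
    return [Haplotype.from_index(i, config.n_selected)
            for i in range(config.n_haplotypes)]


@dataclass(frozen=True)
class Genotype:
    """An unordered pair of haplotypes (diploid)."""

    hap1: Haplotype
    hap2: Haplotype

    def __post_init__(self) -> None:
        if len(self.hap1.selected) != len(self.hap2.selected):
            raise ValueError("haplotypes differ in number of selected loci")
        # canonical order makes the pair unordered
        if self.hap1.index > self.hap2.index:
            h1, h2 = self.hap2, self.hap1
            object.__setattr__(self, "hap1", h1)
            object.__setattr__(self, "hap2", h2)

    @property
    def n_selected(self) -> int:
        return len(self.hap1.selected)

    @property
    def modifier_alleles(self) -> tuple[int, int]:
        return (self.hap1.modifier, self.hap2.modifier)

    def __str__(self) -> str:
        return f"{self.hap1}/{self.hap2}"


# ---------------------------------------------------------------------------
# fitness


@dataclass(frozen=True)
class FitnessParams:
    """Selection parameters of the multilocus mutation model.

    ``s`` is the deleterious effect of a mutation in the homozygous state,
    ``h`` its dominance (heterozygous effect ``h*s``).  The three epistasis
    components enter as multiplicative factors ``(1+e)**P`` with integer
    interaction counts ``P`` computed by :func:`epistatic_powers`.
    """

    s: float
    h: float
    e_axa: float = 0.0
    e_axd: float = 0.0
    e_dxd: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.s <= 1.0:
            raise ValueError(f"s must lie in [0, 1], got {self.s}")
        if not 0.0 <= self.h <= 1.0:
            raise ValueError(f"h must lie in [0, 1], got {self.h}")
        for name in ("e_axa", "e_axd", "e_dxd"):
            v = getattr(self, name)
            if not -1.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [-1, 1], got {v}")

    @property
    def multiplicative(self) -> bool:
        return self.e_axa == self.e_axd == self.e_dxd == 0.0

    def to_dict(self) -> dict:
        return {"s": self.s, "h": self.h, "e_axa": self.e_axa,
                "e_axd": self.e_axd, "e_dxd": self.e_dxd}

    @classmethod
    def from_dict(cls, d: Mapping) -> "FitnessParams":
        return cls(s=float(d["s"]), h=float(d["h"]),
                   e_axa=float(d.get("e_axa", 0.0)),
                   e_axd=float(d.get("e_axd", 0.0)),
                   e_dxd=float(d.get("e_dxd", 0.0)))


def count_mutations(genotype: Genotype) -> tuple[int, int]:
    """Numbers of heterozygous and homozygous mutations in a genotype.

    Returns ``(N_he, N_ho)``; the modifier locus is ignored.
    """
    n_he = n_ho = 0
    for a1, a2 in zip(genotype.hap1.selected, genotype.hap2.selected):
        if a1 + a2 == 1:
            n_he += 1
        elif a1 + a2 == 2:
            n_ho += 1
    return n_he, n_ho


def epistatic_powers(n_he: int, n_ho: int) -> tuple[int, int, int]:
    """Counts of pairwise epistatic interactions ``(P_axa, P_axd, P_dxd)``.

    A heterozygous mutation contributes one additive dose, a homozygous
    mutation two; dominance interactions arise from homozygotes only::

        P_axa = N_he(N_he-1)/2 + 2 N_he N_ho + 4 N_ho(N_ho-1)/2
        P_axd = N_he N_ho + 4 N_ho(N_ho-1)/2
        P_dxd = N_ho(N_ho-1)/2
    """
    if n_he < 0 or n_ho < 0:
        raise ValueError("mutation counts must be non-negative")
    p_axa = n_he * (n_he - 1) // 2 + 2 * n_he * n_ho + 4 * (n_ho * (n_ho - 1) // 2)
    p_axd = n_he * n_ho + 4 * (n_ho * (n_ho - 1) // 2)
    p_dxd = n_ho * (n_ho - 1) // 2
    return p_axa, p_axd, p_dxd


def fitness_from_counts(n_he: int, n_ho: int, params: FitnessParams) -> float:
    """Fitness of a genotype with ``n_he`` heterozygous and ``n_ho``
    homozygous mutations:

    ``W = (1-hs)^N_he (1-s)^N_ho (1+e_axa)^P_axa (1+e_axd)^P_axd (1+e_dxd)^P_dxd``
    """
    p_axa, p_axd, p_dxd = epistatic_powers(n_he, n_ho)
    w = (1.0 - params.h * params.s) ** n_he * (1.0 - params.s) ** n_ho
    w *= (1.0 + params.e_axa) ** p_axa
    w *= (1.0 + params.e_axd) ** p_axd
    w *= (1.0 + params.e_dxd) ** p_dxd
    return w


def genotype_fitness(genotype: Genotype, params: FitnessParams) -> float:
    """Absolute fitness of a diploid genotype (modifier locus is neutral)."""
    n_he, n_ho = count_mutations(genotype)
    return fitness_from_counts(n_he, n_ho, params)


def is_recombination_responsive(genotype: Genotype) -> bool:
    """True iff the genotype is heterozygous at two or more selected loci.

    Only such genotypes produce gamete distributions that depend on the
    recombination rates within the selected system; in all others the rates
    are immaterial.
    """
    n_he, _ = count_mutations(genotype)
    return n_he >= 2


def _locus_state_classes(n_selected: int) -> Iterable[tuple[int, ...]]:
    # per-locus diploid state: 0 = wild/wild, 1 = heterozygous, 2 = mut/mut
    return itertools.product((0, 1, 2), repeat=n_selected)


def fitness_bounds(params: FitnessParams, config: SystemConfig) -> tuple[float, float]:
    """Extreme fitness values used to normalise the FD reaction norm.

    For three selected loci the extremes are taken over all *possible*
    recombination-responsive genotypes (heterozygous at >= 2 selected loci);
    for two selected loci — where the double heterozygote is the only
    responsive genotype — over all possible genotypes.
    """
    w_min, w_max = float("inf"), float("-inf")
    for states in _locus_state_classes(config.n_selected):
        n_he = sum(1 for st in states if st == 1)
        n_ho = sum(1 for st in states if st == 2)
        if config.n_selected >= 3 and n_he < 2:
            continue
        w = fitness_from_counts(n_he, n_ho, params)
        w_min = min(w_min, w)
        w_max = max(w_max, w)
    return w_min, w_max


# ---------------------------------------------------------------------------
# recombination strategies


@dataclass(frozen=True)
class RecombinationStrategy:
    """A modifier allele's rule for setting interval recombination rates.

    ``kind="constant"`` gives every genotype the same rate ``r_const`` in the
    target intervals.  ``kind="fd"`` interpolates linearly between ``r_max``
    (at the lowest responsive-genotype fitness ``W_min``) and ``r_min`` (at
    ``W_max``); intervals not listed in ``targets`` are held at ``r_const``.
    ``selfish_rma``, when set to a ``(low, high)`` pair, additionally makes
    the modifier-to-selected-system rate ``r_MA`` fitness dependent (used
    only for the "selfish"-modifier control experiment; ``low`` applies at
    ``W_max``, ``high`` at ``W_min``).
    """

    kind: str = "constant"
    r_const: float = 0.0
    r_min: float = 0.0
    r_max: float = 0.0
    targets: tuple[str, ...] = ("AB", "BC")
    selfish_rma: tuple[float, float] | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "fd"):
            raise ValueError(f"unknown strategy kind {self.kind!r}")
        if self.kind == "fd" and not self.r_min <= self.r_max:
            raise ValueError("FD strategy requires r_min <= r_max")
        for t in self.targets:
            if t not in ("AB", "BC"):
                raise ValueError(f"unknown target interval {t!r}")
        if not self.label:
            object.__setattr__(self, "label", self._default_label())

    def _default_label(self) -> str:
        if self.kind == "constant":
            base = f"const({self.r_const:g})"
        else:
            base = f"fd({self.r_min:g},{self.r_max:g})"
            if self.targets != ("AB", "BC"):
                base += f"[{'+'.join(self.targets)}]"
        if self.selfish_rma is not None:
            base += f"+selfishMA({self.selfish_rma[0]:g},{self.selfish_rma[1]:g})"
        return base

    @property
    def delta(self) -> float:
        """Magnitude of the plastic effect, Delta = r_max - r_min."""
        return self.r_max - self.r_min if self.kind == "fd" else 0.0

    @classmethod
    def constant(cls, r: float, **kw) -> "RecombinationStrategy":
        return cls(kind="constant", r_const=r, **kw)

    @classmethod
    def fd(cls, r_min: float, r_max: float,
           targets: Sequence[str] = ("AB", "BC"),
           nontarget_rate: float = 0.0, **kw) -> "RecombinationStrategy":
        return cls(kind="fd", r_min=r_min, r_max=r_max,
                   targets=tuple(targets), r_const=nontarget_rate, **kw)

    @classmethod
    def selfish(cls, r_s: float, rma_low: float, rma_high: float,
                **kw) -> "RecombinationStrategy":
        """Constant rate within the selected system but FD r_MA."""
        return cls(kind="constant", r_const=r_s,
                   selfish_rma=(rma_low, rma_high), **kw)

    def to_dict(self) -> dict:
        d = {"kind": self.kind, "r_const": self.r_const,
             "r_min": self.r_min, "r_max": self.r_max,
             "targets": list(self.targets)}
        if self.selfish_rma is not None:
            d["selfish_rMA"] = list(self.selfish_rma)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RecombinationStrategy":
        selfish = d.get("selfish_rMA")
        return cls(kind=d.get("kind", "constant"),
                   r_const=float(d.get("r_const", 0.0)),
                   r_min=float(d.get("r_min", 0.0)),
                   r_max=float(d.get("r_max", 0.0)),
                   targets=tuple(d.get("targets", ("AB", "BC"))),
                   selfish_rma=None if selfish is None else
                   (float(selfish[0]), float(selfish[1])))


def _interpolate(w: float, lo_rate: float, hi_rate: float,
                 bounds: tuple[float, float]) -> float:
    """Linear reaction norm: ``lo_rate`` at W_max, ``hi_rate`` at W_min."""
    w_min, w_max = bounds
    if w_max <= w_min:
        # flat fitness landscape: the norm is undefined and selection-neutral
        return 0.5 * (lo_rate + hi_rate)
    w = min(max(w, w_min), w_max)  # clamp non-responsive genotypes into range
    frac = (w_max - w) / (w_max - w_min)
    return lo_rate + (hi_rate - lo_rate) * frac


def fd_rate(w: float, strategy: RecombinationStrategy,
            bounds: tuple[float, float]) -> float:
    """Realised target-interval rate of one modifier allele for fitness ``w``.

    Constant strategies return ``r_const`` regardless of fitness; FD
    strategies interpolate between ``r_min`` (at ``W_max``) and ``r_max``
    (at ``W_min``).  The result is clipped to the physical range [0, 0.5].
    """
    if strategy.kind == "constant":
        r = strategy.r_const
    else:
        r = _interpolate(w, strategy.r_min, strategy.r_max, bounds)
    return min(max(r, 0.0), R_MAX_PHYSICAL)


def strategy_interval_rates(strategy: RecombinationStrategy, w: float,
                            bounds: tuple[float, float],
                            config: SystemConfig) -> tuple[float, ...]:
    """Interval rates ``(r_MA, r_AB[, r_BC])`` one allele votes for.

    Codominance between the two modifier alleles carried by a genotype is
    applied downstream (mean of the two alleles' votes).
    """
    if strategy.selfish_rma is None:
        r0 = config.r_ma
    else:
        lo, hi = strategy.selfish_rma
        r0 = min(max(_interpolate(w, lo, hi, bounds), 0.0), R_MAX_PHYSICAL)
    target_rate = fd_rate(w, strategy, bounds)
    held = min(max(strategy.r_const, 0.0), R_MAX_PHYSICAL)
    if strategy.kind == "constant":
        rates = [target_rate] * (config.n_selected - 1)
    else:
        names = ("AB", "BC")[: config.n_selected - 1]
        rates = [target_rate if nm in strategy.targets else held for nm in names]
    return (r0, *rates)
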