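"""Deterministic life-cycle recursion and population summaries.

One generation of the infinite panmictic diploid population is

    zygotes --selection--> adults --meiosis--> gametes --mutation-->
    mutated gamete pool --random union--> zygotes of the next generation.

Because zygotes are always the Hardy-Weinberg product of the gamete pool,
the entire state reduces to the vector of (post-mutation) gamete-haplotype
frequencies; :class:`Model` precomputes the dense generation operator and
iterates that vector.  Stage-explicit functions (:func:`selection_step`,
:func:`gamete_pool`, :func:`random_union`, :func:`advance_generation`) expose
the individual life-cycle steps on genotype-frequency matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import meiosis as _meiosis
from .genetics import (
    FitnessParams,
    Genotype,
    Haplotype,
    RecombinationStrategy,
    SystemConfig,
    fitness_bounds,
    fitness_from_counts,
)

__all__ = [
    "PopulationState",
    "EquilibriumReport",
    "ExtinctionError",
    "Model",
    "selection_step",
    "gamete_pool",
    "random_union",
    "advance_generation",
    "run_to_equilibrium",
    "mean_fitness",
    "genetic_variation",
    "mean_realized_rs",
]

#: equilibrium is diagnosed when every selected-locus allele frequency
#: changes by less than this per generation
DEFAULT_TOL = 1e-12
DEFAULT_MAX_GENERATIONS = 10 ** 6


class ExtinctionError(RuntimeError):
    """Raised when mean fitness drops to zero (no survivors)."""


@dataclass
class PopulationState:
    """Frequency distribution over genotypes or gametes at a life-cycle stage.

    ``freqs`` is an (H, H) symmetric genotype matrix for the ``zygote`` and
    ``adult`` stages and an (H,) haplotype vector for the ``gamete_pool``
    stage, with H the number of haplotypes.
    """

    stage: str
    freqs: np.ndarray
    generation: int = 0

    def __post_init__(self) -> None:
        if self.stage not in ("zygote", "adult", "gamete_pool"):
            raise ValueError(f"unknown stage {self.stage!r}")
        self.freqs = np.asarray(self.freqs, dtype=float)
        if np.any(self.freqs < -1e-15):
            raise ValueError("negative frequencies")
        total = self.freqs.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"frequencies sum to {total}, expected 1")
        self.freqs = np.clip(self.freqs, 0.0, None) / self.freqs.sum()


@dataclass
class EquilibriumReport:
    """Outcome of an equilibration run."""

    converged: bool
    generations_used: int
    final_delta: float


def _n_selected_from_size(h: int) -> int:
    n = int(np.log2(h)) - 1
    if 1 << (n + 1) != h:
        raise ValueError(f"state size {h} is not a power of two")
    return n


def fitness_matrix(params: FitnessParams, config: SystemConfig) -> np.ndarray:
    """Dense fitness W[i, j] over ordered haplotype pairs."""
    n = config.n_haplotypes
    w = np.empty((n, n))
    for i in range(n):
        hi = Haplotype.from_index(i, config.n_selected)
        for j in range(i, n):
            hj = Haplotype.from_index(j, config.n_selected)
            n_he = n_ho = 0
            for a, b in zip(hi.selected, hj.selected):
                if a + b == 1:
                    n_he += 1
                elif a + b == 2:
                    n_ho += 1
            w[i, j] = w[j, i] = fitness_from_counts(n_he, n_ho, params)
    return w


def _as_strategy_map(strategies) -> dict[int, RecombinationStrategy]:
    if isinstance(strategies, RecombinationStrategy):
        return {0: strategies, 1: strategies}
    if isinstance(strategies, Mapping):
        m = dict(strategies)
    else:
        m = dict(enumerate(strategies))
    if set(m) == {0}:
        m[1] = m[0]
    if set(m) != {0, 1}:
        raise ValueError("strategies must map modifier alleles 0 and 1")
    return m


class Model:
    """Precomputed generation operator for one parameter set.

    Parameters
    ----------
    config, params:
        System structure and selection parameters.
    strategies:
        A single :class:`RecombinationStrategy` (monomorphic modifier) or a
        mapping / pair assigning a strategy to modifier alleles 0 and 1.
    modifier_cost:
        Optional multiplicative fitness penalty on carriers of modifier
        allele 1 (codominant: a heterozygote is penalised by
        ``(1-cost)**0.5``).  Used by the selection-strength probe.
    """

    def __init__(self, config: SystemConfig, params: FitnessParams,
                 strategies, modifier_cost: float = 0.0) -> None:
        self.config = config
        self.params = params
        self.strategies = _as_strategy_map(strategies)
        self.modifier_cost = modifier_cost
        n = config.n_haplotypes
        self.n_haplotypes = n
        self.W = fitness_matrix(params, config)
        self.T = _meiosis.transmission_tensor(self.strategies, params, config)
        self.M = _meiosis.mutation_matrix(config)

        mod = np.array([Haplotype.from_index(i, config.n_selected).modifier
                        for i in range(n)], dtype=float)
        self.modifier_indicator = mod
        w_sel = self.W
        if modifier_cost:
            carriers = mod[:, None] + mod[None, :]
            w_sel = w_sel * (1.0 - modifier_cost) ** (carriers / 2.0)
        self.W_total = w_sel
        # combined operator: gametes_k = sum_ij p_i p_j W_ij T_ijk, then mutate
        a = (self.W_total[:, :, None] * self.T).reshape(n * n, n)
        self._op = self.M @ a.T  # (n, n*n)

        sel_bits = np.array(
            [Haplotype.from_index(i, config.n_selected).selected for i in range(n)],
            dtype=float)
        self._sel_indicator = sel_bits.T  # (n_selected, n)

    # -- state constructors -------------------------------------------------

    def monomorphic_start(self, modifier_allele: int = 0) -> np.ndarray:
        """Gamete pool monomorphic wild-type, fixed for one modifier allele."""
        hap = Haplotype(modifier=modifier_allele,
                        selected=(0,) * self.config.n_selected)
        p = np.zeros(self.n_haplotypes)
        p[hap.index] = 1.0
        return p

    def introduce_invader(self, p: np.ndarray, freq: float = 0.05) -> np.ndarray:
        """Move ``freq`` of every resident haplotype's mass to modifier allele 1.

        Selected alleles are unchanged, so the invader enters in linkage
        equilibrium with the resident selected-haplotype distribution.
        """
        n_sel = self.config.n_selected
        half = 1 << n_sel
        q = p.copy()
        resident = q[:half].copy()  # modifier bit is the highest bit
        q[:half] = (1.0 - freq) * resident
        q[half:] += freq * resident
        return q / q.sum()

    # -- per-generation quantities ------------------------------------------

    def step(self, p: np.ndarray) -> np.ndarray:
        """One full generation: gamete pool -> gamete pool of the next one."""
        x = (p[:, None] * p).ravel()
        q = self._op @ x
        total = q.sum()
        if total <= 0.0:
            raise ExtinctionError("mean fitness is zero: population extinct")
        return q / total

    def allele_freqs(self, p: np.ndarray) -> np.ndarray:
        """Mutant-allele frequency at each selected locus (zygote stage)."""
        return self._sel_indicator @ p

    def modifier_freq(self, p: np.ndarray) -> float:
        """Frequency of modifier allele 1."""
        return float(self.modifier_indicator @ p)

    def mean_fitness(self, p: np.ndarray) -> float:
        """Zygote-stage population mean fitness (selected loci only)."""
        return float(p @ self.W @ p)

    def genetic_variation(self, p: np.ndarray) -> float:
        """Loci-averaged SD of selected-allele frequencies."""
        q = self.allele_freqs(p)
        return float(np.mean(np.sqrt(q * (1.0 - q))))

    # -- runs ----------------------------------------------------------------

    def equilibrate(self, p0: np.ndarray | None = None, tol: float = DEFAULT_TOL,
                    max_generations: int = DEFAULT_MAX_GENERATIONS,
                    ) -> tuple[np.ndarray, EquilibriumReport]:
        """Iterate to mutation-selection balance.

        Convergence is diagnosed when the zygote-stage mutant-allele
        frequency at every selected locus changes by less than ``tol`` per
        generation.
        """
        p = self.monomorphic_start() if p0 is None else np.asarray(p0, float)
        freqs = self.allele_freqs(p)
        delta = np.inf
        for gen in range(1, max_generations + 1):
            p = self.step(p)
            new = self.allele_freqs(p)
            delta = float(np.max(np.abs(new - freqs)))
            freqs = new
            if delta < tol:
                return p, EquilibriumReport(True, gen, delta)
        return p, EquilibriumReport(False, max_generations, delta)

    def run(self, p: np.ndarray, generations: int,
            record_modifier: bool = False,
            log_path=None, log_every: int = 1) -> tuple[np.ndarray, np.ndarray | None]:
        """Advance ``generations`` generations; optionally record trajectories.

        Returns the final gamete pool and, when ``record_modifier`` is set,
        the per-generation frequency series of modifier allele 1 (length
        ``generations + 1``, starting with the initial state).
        """
        traj = np.empty(generations + 1) if record_modifier else None
        if record_modifier:
            traj[0] = self.modifier_freq(p)
        log = open(log_path, "w") if log_path is not None else None
        try:
            if log:
                loci = ",".join(f"q_{i}" for i in range(self.config.n_selected))
                log.write(f"generation,{loci},mean_fitness,v,modifier_freq\n")
                self._log_row(log, 0, p)
            for gen in range(1, generations + 1):
                p = self.step(p)
                if record_modifier:
                    traj[gen] = self.modifier_freq(p)
                if log and gen % log_every == 0:
                    self._log_row(log, gen, p)
        finally:
            if log:
                log.close()
        return p, traj

    def _log_row(self, fh, gen: int, p: np.ndarray) -> None:
        q = ",".join(f"{v:.12e}" for v in self.allele_freqs(p))
        fh.write(f"{gen},{q},{self.mean_fitness(p):.15e},"
                 f"{self.genetic_variation(p):.15e},{self.modifier_freq(p):.15e}\n")

    # -- realised recombination ----------------------------------------------

    def realized_rs_matrix(self) -> np.ndarray:
        """Per-genotype realised selected-system rate (mean over A-B[, B-C])."""
        n = self.n_haplotypes
        cfg, par = self.config, self.params
        bounds = fitness_bounds(par, cfg)
        rs = np.empty((n, n))
        for i in range(n):
            hi = Haplotype.from_index(i, cfg.n_selected)
            for j in range(i, n):
                hj = Haplotype.from_index(j, cfg.n_selected)
                rates = _meiosis.realized_rates(Genotype(hi, hj), self.strategies,
                                                par, cfg, bounds)
                rs[i, j] = rs[j, i] = float(np.mean(rates.as_tuple()[1:]))
        return rs

    def responsive_matrix(self) -> np.ndarray:
        """Boolean matrix marking recombination-responsive genotypes."""
        n = self.n_haplotypes
        sel = self._sel_indicator.T  # (n, n_selected)
        het = (sel[:, None, :] != sel[None, :, :]).sum(axis=2)
        return het >= 2

    def mean_realized_rs(self, p: np.ndarray) -> dict[str, float]:
        """Frequency-weighted mean realised r_S at the zygote stage.

        Reported both over all genotypes and over the recombination-responsive
        subset (renormalised within it); the latter is ``nan`` when no
        responsive genotypes are present.
        """
        x = p[:, None] * p
        rs = self.realized_rs_matrix()
        resp = self.responsive_matrix()
        overall = float((x * rs).sum())
        mass = float(x[resp].sum())
        responsive = float((x[resp] * rs[resp]).sum() / mass) if mass > 0 else float("nan")
        return {"all": overall, "responsive": responsive}


# ---------------------------------------------------------------------------
# stage-explicit life-cycle operations


def selection_step(zygotes: PopulationState, params: FitnessParams) -> PopulationState:
    """Viability selection (zygotes -> adults): reweight by fitness."""
    if zygotes.stage != "zygote":
        raise ValueError("selection_step expects a zygote-stage state")
    h = zygotes.freqs.shape[0]
    config = SystemConfig(n_selected=_n_selected_from_size(h))
    w = fitness_matrix(params, config)
    weighted = zygotes.freqs * w
    total = weighted.sum()
    if total <= 0.0:
        raise ExtinctionError("mean fitness is zero: population extinct")
    return PopulationState("adult", weighted / total, zygotes.generation)


def gamete_pool(adults: PopulationState, strategies, params: FitnessParams,
                config: SystemConfig) -> PopulationState:
    """Meiosis (adults -> gamete pool), before mutation."""
    if adults.stage != "adult":
        raise ValueError("gamete_pool expects an adult-stage state")
    t = _meiosis.transmission_tensor(_as_strategy_map(strategies), params, config)
    pool = np.einsum("ij,ijk->k", adults.freqs, t)
    return PopulationState("gamete_pool", pool, adults.generation)


def random_union(pool: PopulationState) -> PopulationState:
    """Random mating (gamete pool -> zygotes): Hardy-Weinberg product."""
    if pool.stage != "gamete_pool":
        raise ValueError("random_union expects a gamete_pool-stage state")
    zyg = np.outer(pool.freqs, pool.freqs)
    return PopulationState("zygote", zyg, pool.generation + 1)


def advance_generation(state: PopulationState, strategies,
                       params: FitnessParams,
                       config: SystemConfig) -> PopulationState:
    """One full generation on a zygote-stage state (selection -> meiosis ->
    mutation -> random union)."""
    adults = selection_step(state, params)
    pool = gamete_pool(adults, strategies, params, config)
    mutated = _meiosis.mutation_matrix(config) @ pool.freqs
    return random_union(PopulationState("gamete_pool", mutated, pool.generation))


def run_to_equilibrium(state: PopulationState | None, strategies,
                       params: FitnessParams, config: SystemConfig,
                       tol: float = DEFAULT_TOL,
                       max_generations: int = DEFAULT_MAX_GENERATIONS,
                       ) -> tuple[PopulationState, EquilibriumReport]:
    """Iterate the life cycle to mutation-selection balance.

    ``state`` may be ``None`` (start monomorphic wild-type, modifier allele
    0), a zygote-stage genotype state, or a gamete-pool state.
    """
    model = Model(config, params, strategies)
    if state is None:
        p0 = None
    elif state.stage == "gamete_pool":
        p0 = state.freqs
    elif state.stage == "zygote":
        # zygotes are a HW product in this model; haplotype marginals suffice
        p0 = state.freqs.sum(axis=1)
    else:
        raise ValueError("equilibration expects zygote or gamete_pool stage")
    p, report = model.equilibrate(p0, tol=tol, max_generations=max_generations)
    gen = (state.generation if state is not None else 0) + report.generations_used
    return PopulationState("gamete_pool", p, gen), report


# ---------------------------------------------------------------------------
# summaries on stage-explicit states


def _zygote_matrix(state: PopulationState) -> np.ndarray:
    if state.freqs.ndim == 1:
        return np.outer(state.freqs, state.freqs)
    return state.freqs


def mean_fitness(state: PopulationState, params: FitnessParams) -> float:
    """Population mean fitness: genotype fitnesses weighted by frequencies."""
    x = _zygote_matrix(state)
    config = SystemConfig(n_selected=_n_selected_from_size(x.shape[0]))
    return float((x * fitness_matrix(params, config)).sum())


def genetic_variation(state: PopulationState) -> float:
    """Population genetic variation: ``v = (1/n) sum_i sqrt(p_i (1 - p_i))``
    over selected-locus allele frequencies."""
    x = _zygote_matrix(state)
    h = x.shape[0]
    n_sel = _n_selected_from_size(h)
    hap_freqs = x.sum(axis=1)
    sel = np.array([Haplotype.from_index(i, n_sel).selected for i in range(h)],
                   dtype=float)
    q = sel.T @ hap_freqs
    return float(np.mean(np.sqrt(q * (1.0 - q))))


def mean_realized_rs(state: PopulationState, strategies, params: FitnessParams,
                     config: SystemConfig) -> dict[str, float]:
    """Frequency-weighted mean realised recombination rate in the selected
    system, over all genotypes and over responsive genotypes only."""
    model = Model(config, params, strategies)
    x = _zygote_matrix(state)
    p = x.sum(axis=1)
    return model.mean_realized_rs(p)
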