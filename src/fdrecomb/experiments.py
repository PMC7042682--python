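"""Modifier-allele experiments: invasion analysis of recombination strategies.

A strategy S1 is *evolutionarily more advantageous* than S2 when its modifier
allele (a) invades a population in which the S2 allele is nearly fixed
(introduced at frequency 0.05 against 0.95) and (b) resists the symmetric
invasion attempt when itself nearly fixed.  Before each test the resident
population is equilibrated to mutation-selection balance; the polymorphic
phase then runs for 10,000 generations.

The *optimal constant recombination rate* r_S* is located by a bracketing
sweep of pairwise invasion comparisons: upward from r_S = 0 and downward from
r_S = 0.5, refined over three iterations with steps 0.01, 0.001 and 0.0001,
so the final bracket is at most 0.0001 wide.  FD (fitness-dependent)
strategies are then pitted against the constant r_S* in several variants:
rates varying above (+FD), below (-FD) or around (+/-FD) the optimum, the
"distant-interval" variant (FD effect on B-C only), and the "selfish"
variant (FD effect on the modifier-side interval M-A only).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .dynamics import (
    DEFAULT_MAX_GENERATIONS,
    DEFAULT_TOL,
    EquilibriumReport,
    Model,
)
from .genetics import (
    FitnessParams,
    RecombinationStrategy,
    SystemConfig,
    R_MAX_PHYSICAL,
)

__all__ = [
    "ComparisonOutcome",
    "OptimalRRResult",
    "PlasticityTournament",
    "invasion_test",
    "resistance_test",
    "is_more_advantageous",
    "optimal_constant_rr",
    "build_fd_strategy",
    "compare_fd_vs_optimal",
    "selection_strength_probe",
    "optimal_plasticity_magnitude",
    "INTRODUCTION_FREQ",
    "INVASION_GENERATIONS",
    "INVASION_EPS",
]

#: initial frequency of the rare modifier allele in invasion/resistance tests
INTRODUCTION_FREQ = 0.05
#: length of the polymorphic phase of each test
INVASION_GENERATIONS = 10_000
#: absolute frequency gain counted as invasion (well above the ~1e-12
#: renormalisation noise floor, well below any real selective response)
INVASION_EPS = 1e-9

FD_VARIANTS = ("+FD", "-FD", "+-FD", "distant", "selfish")


@dataclass
class ComparisonOutcome:
    """Verdict of a two-test strategy comparison (S1 versus S2)."""

    s1: str
    s2: str
    s1_invades: bool
    s1_resists: bool
    advantageous: bool
    #: monomorphic-equilibrium differences, S1 minus S2
    delta_mean_fitness: float = float("nan")
    delta_variation: float = float("nan")
    delta_mean_rs: float = float("nan")
    equilibria_converged: bool = True
    rates_clipped: bool = False
    variant: str = ""
    modifier_trajectories: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        assert not self.advantageous or self.s1_invades


@dataclass
class OptimalRRResult:
    """Result of the bracketing search for the optimal constant rate."""

    r_low: float
    r_high: float
    r_star: float | None
    classification: str  # "zero" | "intermediate" | "free"
    n_invasion_tests: int = 0
    equilibria_converged: bool = True

    @property
    def bracket_width(self) -> float:
        return abs(self.r_high - self.r_low)


class _Arena:
    """Shared machinery for invasion runs: caches resident equilibria (keyed
    by strategy) and warm-starts equilibration from the nearest cached state."""

    def __init__(self, params: FitnessParams, config: SystemConfig,
                 generations: int = INVASION_GENERATIONS,
                 tol: float = DEFAULT_TOL,
                 max_generations: int = DEFAULT_MAX_GENERATIONS) -> None:
        self.params = params
        self.config = config
        self.generations = generations
        self.tol = tol
        self.max_generations = max_generations
        self._equilibria: dict[str, tuple[np.ndarray, EquilibriumReport]] = {}
        self.n_tests = 0
        self.all_converged = True

    def equilibrium(self, strategy: RecombinationStrategy,
                    ) -> tuple[np.ndarray, EquilibriumReport]:
        # always equilibrated from the cold monomorphic wild-type start: the
        # allele-frequency convergence criterion can trigger prematurely on a
        # warm start whose linkage disequilibrium is still relaxing
        key = strategy.label
        if key not in self._equilibria:
            model = Model(self.config, self.params, strategy)
            p, rep = model.equilibrate(tol=self.tol,
                                       max_generations=self.max_generations)
            if not rep.converged:
                self.all_converged = False
                warnings.warn(
                    f"resident equilibrium for {key} did not converge within "
                    f"{self.max_generations} generations (delta={rep.final_delta:.2e})")
            self._equilibria[key] = (p, rep)
        return self._equilibria[key]

    def invades(self, resident: RecombinationStrategy,
                invader: RecombinationStrategy,
                invader_cost: float = 0.0,
                record: bool = False) -> tuple[bool, np.ndarray | None]:
        """Introduce ``invader`` at 0.05 against equilibrated ``resident``."""
        p_eq, _ = self.equilibrium(resident)
        model = Model(self.config, self.params, {0: resident, 1: invader},
                      modifier_cost=invader_cost)
        p = model.introduce_invader(p_eq, INTRODUCTION_FREQ)
        p, traj = model.run(p, self.generations, record_modifier=record)
        self.n_tests += 1
        invaded = model.modifier_freq(p) > INTRODUCTION_FREQ + INVASION_EPS
        return invaded, traj


def invasion_test(resident: RecombinationStrategy,
                  invader: RecombinationStrategy,
                  params: FitnessParams, config: SystemConfig,
                  generations: int = INVASION_GENERATIONS,
                  max_generations: int = DEFAULT_MAX_GENERATIONS) -> bool:
    """True iff the rare ``invader`` modifier allele gains frequency against
    the nearly fixed, equilibrated ``resident``."""
    arena = _Arena(params, config, generations, max_generations=max_generations)
    invaded, _ = arena.invades(resident, invader)
    return invaded


def resistance_test(resident: RecombinationStrategy,
                    challenger: RecombinationStrategy,
                    params: FitnessParams, config: SystemConfig,
                    generations: int = INVASION_GENERATIONS,
                    max_generations: int = DEFAULT_MAX_GENERATIONS) -> bool:
    """True iff the nearly fixed ``resident`` repels the rare ``challenger``
    (the challenger fails to gain frequency)."""
    arena = _Arena(params, config, generations, max_generations=max_generations)
    invaded, _ = arena.invades(resident, challenger)
    return not invaded


def is_more_advantageous(s1: RecombinationStrategy, s2: RecombinationStrategy,
                         params: FitnessParams, config: SystemConfig,
                         generations: int = INVASION_GENERATIONS,
                         max_generations: int = DEFAULT_MAX_GENERATIONS,
                         record_trajectories: bool = False,
                         arena: _Arena | None = None) -> ComparisonOutcome:
    """Two-test verdict: S1 must invade an S2 resident *and* resist S2.

    Also reports the differences (S1 minus S2) in equilibrium mean fitness,
    genetic variation and population mean realised r_S between the two
    monomorphic residents.
    """
    if arena is None:
        arena = _Arena(params, config, generations,
                       max_generations=max_generations)
    invades, traj_inv = arena.invades(s2, s1, record=record_trajectories)
    challenged, traj_res = arena.invades(s1, s2, record=record_trajectories)

    deltas = {}
    for strat in (s1, s2):
        p_eq, _ = arena.equilibrium(strat)
        model = Model(config, params, strat)
        deltas[strat.label] = (model.mean_fitness(p_eq),
                               model.genetic_variation(p_eq),
                               model.mean_realized_rs(p_eq)["all"])
    d1, d2 = deltas[s1.label], deltas[s2.label]
    traj = None
    if record_trajectories:
        traj = {"s1_invading": traj_inv, "s2_challenging": traj_res}
    return ComparisonOutcome(
        s1=s1.label, s2=s2.label,
        s1_invades=invades, s1_resists=not challenged,
        advantageous=invades and not challenged,
        delta_mean_fitness=d1[0] - d2[0],
        delta_variation=d1[1] - d2[1],
        delta_mean_rs=d1[2] - d2[2],
        equilibria_converged=arena.all_converged,
        modifier_trajectories=traj)


# ---------------------------------------------------------------------------
# optimal constant recombination rate


def optimal_constant_rr(params: FitnessParams, config: SystemConfig,
                        steps: tuple[float, ...] = (0.01, 0.001, 0.0001),
                        generations: int = INVASION_GENERATIONS,
                        max_generations: int = DEFAULT_MAX_GENERATIONS,
                        ) -> OptimalRRResult:
    """Bracket the uninvadable constant rate by chained invasion sweeps.

    Each iteration sweeps upward from the current lower bound (a one-step
    higher allele keeps replacing the resident while it invades) and downward
    from the upper bound, then hands the bracket to the next, ten-fold finer
    step.  A landscape in which neither boundary sweep moves at the coarsest
    step is classified ``"free"`` (all constant rates neutral, as under
    multiplicative selection); a bracket collapsing onto 0 is ``"zero"``;
    anything else is ``"intermediate"``.
    """
    arena = _Arena(params, config, generations, max_generations=max_generations)
    memo: dict[tuple[float, float], bool] = {}

    def invades(r_res: float, r_inv: float) -> bool:
        key = (round(r_res, 6), round(r_inv, 6))
        if key not in memo:
            res = RecombinationStrategy.constant(round(r_res, 6))
            inv = RecombinationStrategy.constant(round(r_inv, 6))
            memo[key], _ = arena.invades(res, inv)
        return memo[key]

    def sweep(start: float, stop: float, step: float) -> float:
        """Chain one-step invasions from ``start`` toward ``stop``."""
        r = start
        direction = 1.0 if stop >= start else -1.0
        k = 1
        while True:
            nxt = round(start + direction * k * step, 10)
            if direction * (nxt - stop) > 1e-12:
                break
            if not invades(r, nxt):
                break
            r = nxt
            k += 1
        return r

    lo, hi = 0.0, R_MAX_PHYSICAL
    for i, step in enumerate(steps):
        a, b = min(lo, hi), max(lo, hi)
        new_lo = sweep(a, b, step)
        new_hi = sweep(b, a, step)
        if i == 0 and new_lo == 0.0 and new_hi == R_MAX_PHYSICAL:
            # neither boundary allele could be displaced: neutral landscape
            return OptimalRRResult(0.0, R_MAX_PHYSICAL, None, "free",
                                   arena.n_tests, arena.all_converged)
        lo, hi = new_lo, new_hi

    r_low, r_high = lo, hi
    r_star = round(0.5 * (r_low + r_high), 10)
    classification = "zero" if r_star <= 0.0 else "intermediate"
    return OptimalRRResult(r_low, r_high, r_star, classification,
                           arena.n_tests, arena.all_converged)


# ---------------------------------------------------------------------------
# FD strategies versus the optimal constant rate


def build_fd_strategy(r_star: float, delta: float, variant: str,
                      config: SystemConfig) -> tuple[RecombinationStrategy, bool]:
    """Construct the FD strategy of a given variant around ``r_star``.

    Returns ``(strategy, clipped)`` where ``clipped`` flags ranges truncated
    at the physical bounds [0, 0.5].  With a zero optimum the +FD range is
    (0, delta); the distant-interval variant applies a doubled plastic range
    to B-C only, holding A-B at ``r_star``; the selfish variant keeps the
    selected-system rate constant at ``r_star`` and makes r_MA fitness
    dependent over (r_MA, r_MA + delta).
    """
    if variant == "+FD":
        lo, hi = (0.0, delta) if r_star == 0.0 else (r_star, r_star + delta)
    elif variant == "-FD":
        lo, hi = r_star - delta, r_star
    elif variant in ("+-FD", "±FD"):
        lo, hi = r_star - delta / 2.0, r_star + delta / 2.0
    elif variant == "distant":
        if config.n_selected != 3:
            raise ValueError("distant-interval FD requires three selected loci")
        lo, hi = r_star, r_star + 2.0 * delta
        clipped = hi > R_MAX_PHYSICAL
        strat = RecombinationStrategy.fd(
            lo, min(hi, R_MAX_PHYSICAL), targets=("BC",), nontarget_rate=r_star)
        return strat, clipped
    elif variant == "selfish":
        hi_ma = config.r_ma + delta
        clipped = hi_ma > R_MAX_PHYSICAL
        strat = RecombinationStrategy.selfish(
            r_star, config.r_ma, min(hi_ma, R_MAX_PHYSICAL))
        return strat, clipped
    else:
        raise ValueError(f"unknown FD variant {variant!r}; "
                         f"expected one of {FD_VARIANTS}")
    clipped = lo < 0.0 or hi > R_MAX_PHYSICAL
    lo = min(max(lo, 0.0), R_MAX_PHYSICAL)
    hi = min(max(hi, 0.0), R_MAX_PHYSICAL)
    return RecombinationStrategy.fd(lo, hi), clipped


def compare_fd_vs_optimal(params: FitnessParams, config: SystemConfig,
                          delta: float = 0.05, variant: str = "+FD",
                          r_star: float | None = None,
                          generations: int = INVASION_GENERATIONS,
                          max_generations: int = DEFAULT_MAX_GENERATIONS,
                          record_trajectories: bool = False) -> ComparisonOutcome:
    """Two-test comparison of an FD strategy against the optimal constant rate.

    ``r_star`` may be supplied to reuse a previously run search; otherwise
    :func:`optimal_constant_rr` is invoked first.  Raises ``ValueError`` for
    a neutral (free) landscape, where no optimum exists.
    """
    if r_star is None:
        opt = optimal_constant_rr(params, config, generations=generations,
                                  max_generations=max_generations)
        if opt.r_star is None:
            raise ValueError("neutral recombination landscape: no optimal "
                             "constant rate to compare against")
        r_star = opt.r_star
    if variant == "-FD" and r_star < delta:
        warnings.warn(f"-FD range truncated at 0 (r_star={r_star} < delta={delta})")
    fd, clipped = build_fd_strategy(r_star, delta, variant, config)
    const = RecombinationStrategy.constant(r_star)
    outcome = is_more_advantageous(fd, const, params, config,
                                   generations=generations,
                                   max_generations=max_generations,
                                   record_trajectories=record_trajectories)
    outcome.variant = variant
    outcome.rates_clipped = clipped
    return outcome


# ---------------------------------------------------------------------------
# strength of indirect selection on the FD modifier


def selection_strength_probe(params: FitnessParams, config: SystemConfig,
                             fd_strategy: RecombinationStrategy,
                             resident: RecombinationStrategy,
                             generations: int = INVASION_GENERATIONS,
                             max_generations: int = DEFAULT_MAX_GENERATIONS,
                             cost_floor: float = 1e-16) -> float | None:
    """Smallest direct fitness cost that stops the FD allele's invasion.

    Burdens carriers of the FD modifier allele with a multiplicative penalty
    (codominant: heterozygotes pay ``(1-cost)**0.5``) and brackets, within a
    factor of 2, the threshold cost at which invasion first fails.  Returns
    ``None`` when the FD allele does not invade even at zero cost (the
    threshold is then undefined).
    """
    arena = _Arena(params, config, generations, max_generations=max_generations)

    def invades(cost: float) -> bool:
        ok, _ = arena.invades(resident, fd_strategy, invader_cost=cost)
        return ok

    if not invades(0.0):
        warnings.warn("FD allele does not invade at zero cost; "
                      "selection-strength threshold undefined")
        return None
    if not invades(cost_floor):
        return cost_floor
    # geometric ascent to the first failing decade, then log-space bisection
    lo = cost_floor
    hi = lo * 10.0
    while invades(hi):
        lo = hi
        hi *= 10.0
        if hi > 1.0:
            hi = 1.0  # lethal cost always stops invasion
            break
    while hi / lo > 2.0:
        mid = math.sqrt(lo * hi)
        if invades(mid):
            lo = mid
        else:
            hi = mid
    return hi


@dataclass
class PlasticityTournament:
    """Round-robin outcome over +FD strategies differing only in magnitude."""

    deltas: tuple[float, ...]
    winner: float | None
    tied: bool
    #: dominance[i][j] is True when strategy i is advantageous over j
    dominance: list[list[bool]] = field(default_factory=list)


def optimal_plasticity_magnitude(params: FitnessParams, config: SystemConfig,
                                 delta_grid, r_star: float = 0.0,
                                 generations: int = INVASION_GENERATIONS,
                                 max_generations: int = DEFAULT_MAX_GENERATIONS,
                                 ) -> PlasticityTournament:
    """Pairwise tournament over +FD magnitudes; the optimal magnitude is the
    one advantageous over every other.  An all-neutral landscape (no strategy
    dominates any other) is flagged as a tie."""
    deltas = tuple(float(d) for d in delta_grid)
    if len(deltas) == 1:
        return PlasticityTournament(deltas, deltas[0], False, [[False]])
    strategies = [build_fd_strategy(r_star, d, "+FD", config)[0] for d in deltas]
    arena = _Arena(params, config, generations, max_generations=max_generations)
    n = len(deltas)
    dom = [[False] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            out = is_more_advantageous(strategies[i], strategies[j],
                                       params, config, generations=generations,
                                       max_generations=max_generations,
                                       arena=arena)
            dom[i][j] = out.advantageous
    winners = [i for i in range(n)
               if all(dom[i][j] for j in range(n) if j != i)]
    if len(winners) == 1:
        return PlasticityTournament(deltas, deltas[winners[0]], False, dom)
    return PlasticityTournament(deltas, None, True, dom)
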