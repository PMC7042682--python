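"""Fitness function, epistatic interaction counts, and FD reaction norms."""

import itertools
import math

import pytest
from hypothesis import given, strategies as st

from fdrecomb.genetics import (
    FitnessParams,
    Genotype,
    Haplotype,
    RecombinationStrategy,
    SystemConfig,
    count_mutations,
    enumerate_haplotypes,
    epistatic_powers,
    fd_rate,
    fitness_bounds,
    fitness_from_counts,
    genotype_fitness,
    is_recombination_responsive,
    strategy_interval_rates,
)


def geno(sel1, sel2, m1=0, m2=0):
    return Genotype(Haplotype(m1, tuple(sel1)), Haplotype(m2, tuple(sel2)))


# ---------------------------------------------------------------------------
# mutation counting and epistatic powers


@pytest.mark.parametrize("sel1, sel2, expected", [
    ((0, 0, 0), (0, 0, 0), (0, 0)),     # wild type
    ((1, 0, 0), (0, 0, 0), (1, 0)),     # single heterozygous mutation
    ((1, 1, 0), (1, 0, 0), (1, 1)),     # locus A homozygous, locus B het
    ((1, 1, 1), (1, 1, 1), (0, 3)),
])
def test_count_mutations(sel1, sel2, expected):
    assert count_mutations(geno(sel1, sel2)) == expected


def test_count_mutations_ignores_modifier():
    assert count_mutations(geno((0, 0, 0), (0, 0, 0), m1=1, m2=1)) == (0, 0)


def _powers_oracle(n_he, n_ho):
    """Count pairwise interactions directly: each mutated locus carries an
    additive dose (1 if het, 2 if hom) and a dominance dose (1 if hom)."""
    doses = [(1, 0)] * n_he + [(2, 1)] * n_ho
    axa = axd = dxd = 0
    for (a1, d1), (a2, d2) in itertools.combinations(doses, 2):
        axa += a1 * a2
        axd += a1 * d2 + a2 * d1
        dxd += d1 * d2
    return axa, axd, dxd


@pytest.mark.parametrize("n_he, n_ho, expected", [
    (0, 0, (0, 0, 0)),
    (2, 0, (1, 0, 0)),
    (1, 1, (2, 1, 0)),
    (0, 2, (4, 4, 1)),
])
def test_epistatic_powers_examples(n_he, n_ho, expected):
    assert epistatic_powers(n_he, n_ho) == expected


def test_epistatic_powers_match_pairwise_enumeration():
    for n_he in range(4):
        for n_ho in range(4 - n_he):
            assert epistatic_powers(n_he, n_ho) == _powers_oracle(n_he, n_ho)


# ---------------------------------------------------------------------------
# fitness


def test_wild_type_fitness_is_one():
    params = FitnessParams(s=0.7, h=0.3, e_axa=-0.4, e_axd=0.2, e_dxd=0.9)
    assert genotype_fitness(geno((0, 0, 0), (0, 0, 0)), params) == 1.0


def test_single_heterozygote_fitness():
    params = FitnessParams(s=0.2, h=0.5)
    w = genotype_fitness(geno((1, 0, 0), (0, 0, 0)), params)
    assert w == pytest.approx(0.9)


def test_double_heterozygote_with_epistasis():
    params = FitnessParams(s=0.2, h=0.5, e_axa=-0.1)
    w = genotype_fitness(geno((1, 1, 0), (0, 0, 0)), params)
    assert w == pytest.approx(0.729)


@given(st.lists(st.sampled_from([0, 1]), min_size=3, max_size=3),
       st.lists(st.sampled_from([0, 1]), min_size=3, max_size=3),
       st.permutations(range(3)))
def test_fitness_invariant_under_swap_and_locus_permutation(sel1, sel2, perm):
    params = FitnessParams(s=0.3, h=0.4, e_axa=-0.2, e_axd=0.1, e_dxd=0.05)
    w = genotype_fitness(geno(sel1, sel2), params)
    assert genotype_fitness(geno(sel2, sel1), params) == pytest.approx(w)
    p1 = [sel1[i] for i in perm]
    p2 = [sel2[i] for i in perm]
    assert genotype_fitness(geno(p1, p2), params) == pytest.approx(w)


@given(st.lists(st.sampled_from([0, 1]), min_size=3, max_size=3),
       st.lists(st.sampled_from([0, 1]), min_size=3, max_size=3))
def test_no_epistasis_is_multiplicative_across_loci(sel1, sel2):
    params = FitnessParams(s=0.25, h=0.6)
    w = genotype_fitness(geno(sel1, sel2), params)
    per_locus = 1.0
    for a, b in zip(sel1, sel2):
        if a + b == 1:
            per_locus *= 1.0 - params.h * params.s
        elif a + b == 2:
            per_locus *= 1.0 - params.s
    assert w == pytest.approx(per_locus)


# ---------------------------------------------------------------------------
# recombination responsiveness and fitness bounds


@pytest.mark.parametrize("sel1, sel2, expected", [
    ((0, 0, 0), (1, 1, 1), True),    # triple heterozygote
    ((1, 0, 0), (1, 0, 0), False),   # no heterozygous selected locus
    ((0, 1, 0), (1, 0, 0), True),    # loci A and B heterozygous
    ((1, 0, 0), (0, 0, 0), False),   # single heterozygote
])
def test_is_recombination_responsive(sel1, sel2, expected):
    assert is_recombination_responsive(geno(sel1, sel2)) is expected


def _bounds_oracle(params, config):
    """Enumerate every haplotype pair rather than per-locus state classes."""
    haps = enumerate_haplotypes(config)
    ws = []
    for h1 in haps:
        for h2 in haps:
            g = Genotype(h1, h2)
            if config.n_selected >= 3 and not is_recombination_responsive(g):
                continue
            ws.append(genotype_fitness(g, params))
    return min(ws), max(ws)


@pytest.mark.parametrize("n_selected, params", [
    (2, FitnessParams(s=1.0, h=0.5)),
    (2, FitnessParams(s=0.3, h=0.2, e_axa=-0.5)),
    (3, FitnessParams(s=0.2, h=0.5)),
    (3, FitnessParams(s=0.6, h=0.1, e_axa=0.4, e_axd=-0.3, e_dxd=0.2)),
])
def test_fitness_bounds_match_enumeration_oracle(n_selected, params):
    config = SystemConfig(n_selected=n_selected)
    assert fitness_bounds(params, config) == pytest.approx(
        _bounds_oracle(params, config))


def test_fitness_bounds_two_locus_lethal():
    w_min, w_max = fitness_bounds(FitnessParams(s=1.0, h=0.5), SystemConfig(n_selected=2))
    assert (w_min, w_max) == (0.0, 1.0)


def test_fitness_bounds_three_locus_multiplicative(cfg3):
    w_min, w_max = fitness_bounds(FitnessParams(s=0.2, h=0.5), cfg3)
    assert w_max == pytest.approx(0.81)       # double het, third locus wild
    assert w_min == pytest.approx(0.9 ** 2 * 0.8)  # double het + homozygote

def test_fitness_bounds_flat_when_neutral(cfg3):
    assert fitness_bounds(FitnessParams(s=0.0, h=0.5), cfg3) == (1.0, 1.0)


# ---------------------------------------------------------------------------
# FD reaction norm


def test_fd_rate_endpoints_and_midpoint():
    strat = RecombinationStrategy.fd(0.1, 0.3)
    bounds = (0.5, 0.9)
    assert fd_rate(0.9, strat, bounds) == pytest.approx(0.1)   # W = W_max
    assert fd_rate(0.5, strat, bounds) == pytest.approx(0.3)   # W = W_min
    assert fd_rate(0.7, strat, bounds) == pytest.approx(0.2)   # linear middle


def test_fd_rate_constant_strategy_ignores_fitness():
    strat = RecombinationStrategy.constant(0.17)
    for w in (0.0, 0.4, 1.0):
        assert fd_rate(w, strat, (0.2, 0.8)) == 0.17


def test_fd_rate_degenerate_bounds_fall_back_to_midpoint():
    strat = RecombinationStrategy.fd(0.1, 0.3)
    assert fd_rate(1.0, strat, (1.0, 1.0)) == pytest.approx(0.2)


def test_fd_rate_clamps_out_of_range_fitness():
    strat = RecombinationStrategy.fd(0.0, 0.4)
    bounds = (0.5, 0.9)
    assert fd_rate(1.0, strat, bounds) == 0.0    # fitter than any responsive
    assert fd_rate(0.1, strat, bounds) == 0.4


@given(st.floats(min_value=0.0, max_value=1.0),
       st.floats(min_value=0.0, max_value=1.0))
def test_fd_rate_monotone_and_bounded(w1, w2):
    strat = RecombinationStrategy.fd(0.05, 0.45)
    bounds = (0.3, 0.8)
    r1, r2 = fd_rate(w1, strat, bounds), fd_rate(w2, strat, bounds)
    assert 0.05 <= r1 <= 0.45
    if w1 <= w2:
        assert r1 >= r2 - 1e-12


def test_selfish_strategy_interval_rates(cfg3_linked):
    strat = RecombinationStrategy.selfish(0.1, 0.05, 0.15)
    bounds = (0.5, 1.0)
    r0, r1, r2 = strategy_interval_rates(strat, 0.5, bounds, cfg3_linked)
    assert (r0, r1, r2) == pytest.approx((0.15, 0.1, 0.1))
    r0, _, _ = strategy_interval_rates(strat, 1.0, bounds, cfg3_linked)
    assert r0 == pytest.approx(0.05)


def test_distant_interval_strategy_rates(cfg3):
    strat = RecombinationStrategy.fd(0.1, 0.2, targets=("BC",), nontarget_rate=0.1)
    bounds = (0.5, 1.0)
    _, r1, r2 = strategy_interval_rates(strat, 0.5, bounds, cfg3)
    assert (r1, r2) == pytest.approx((0.1, 0.2))


# ---------------------------------------------------------------------------
# validation and serialization


@pytest.mark.parametrize("kwargs", [
    {"n_selected": 4}, {"r_ma": 0.6}, {"u": 1.5}, {"c": 2.5},
])
def test_config_validation(kwargs):
    with pytest.raises(ValueError):
        SystemConfig(**kwargs)


@pytest.mark.parametrize("kwargs", [
    {"s": 1.2, "h": 0.5}, {"s": 0.5, "h": -0.1},
    {"s": 0.5, "h": 0.5, "e_axa": -1.5},
])
def test_fitness_params_validation(kwargs):
    with pytest.raises(ValueError):
        FitnessParams(**kwargs)


def test_round_trip_serialization():
    params = FitnessParams(s=0.3, h=0.2, e_axa=-0.4, e_axd=0.1, e_dxd=0.0)
    assert FitnessParams.from_dict(params.to_dict()) == params
    config = SystemConfig(n_selected=2, r_ma=0.05, u=1e-4, c=0.0)
    assert SystemConfig.from_dict(config.to_dict()) == config
    strat = RecombinationStrategy.fd(0.0, 0.05, targets=("BC",))
    back = RecombinationStrategy.from_dict(strat.to_dict())
    assert (back.kind, back.r_min, back.r_max, back.targets) == \
        (strat.kind, strat.r_min, strat.r_max, strat.targets)


def test_haplotype_index_round_trip():
    for idx in range(16):
        assert Haplotype.from_index(idx, 3).index == idx


def test_genotype_pair_is_unordered():
    a, b = Haplotype(0, (1, 0, 1)), Haplotype(1, (0, 0, 0))
    assert Genotype(a, b) == Genotype(b, a)
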