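"""Unit and property tests for the gamma + MHG generative core."""

import itertools
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from otusim import (
    DegenerateSampleError,
    InsufficientPopulationError,
    InvalidParameterError,
    Population,
    build_population,
    sample_gamma_abundances,
    sample_mhg,
    simulate,
    zero_probability,
)

# ---------------------------------------------------------------------------
# independent oracles


def mhg_pmf(m, y):
    """Exact urn probability of the outcome vector y: prod C(m_i, y_i)/C(M, n)."""
    n = sum(y)
    num = 1
    for mi, yi in zip(m, y):
        if yi > mi:
            return 0.0
        num *= comb(mi, yi)
    return num / comb(sum(m), n)


def enumerate_outcomes(m, n):
    """All outcome vectors with 0 <= y_i <= m_i and sum(y) == n."""
    ranges = [range(min(mi, n) + 1) for mi in m]
    return [y for y in itertools.product(*ranges) if sum(y) == n]


def best_integer_apportionments(raw, total):
    """Brute-force: integer vectors summing to `total` minimizing the maximum
    absolute deviation of proportions from raw proportions."""
    raw = np.asarray(raw, dtype=float)
    p = raw / raw.sum()
    best, best_err = [], np.inf
    for y in itertools.product(range(total + 1), repeat=len(raw)):
        if sum(y) != total:
            continue
        err = np.max(np.abs(np.asarray(y) / total - p))
        if err < best_err - 1e-12:
            best, best_err = [y], err
        elif abs(err - best_err) <= 1e-12:
            best.append(y)
    return best


# ---------------------------------------------------------------------------
# gamma stage


def test_gamma_moments(rng):
    draws = sample_gamma_abundances([10.0], [0.5], 200_000, rng)[0]
    assert draws.mean() == pytest.approx(10.0, rel=0.03)
    assert draws.var() == pytest.approx(50.0, rel=0.05)


def test_gamma_phi_zero_is_deterministic(rng):
    draws = sample_gamma_abundances([10.0, 3.0], [0.0, 0.0], 7, rng)
    assert np.array_equal(draws, np.array([[10.0] * 7, [3.0] * 7]))


def test_gamma_mu_zero_is_zero(rng):
    draws = sample_gamma_abundances([0.0], [2.5], 100, rng)
    assert np.array_equal(draws, np.zeros((1, 100)))


def test_gamma_output_shape(rng):
    assert sample_gamma_abundances([1.0, 2.0, 3.0], [0.1] * 3, 5, rng).shape == (3, 5)


@pytest.mark.parametrize("mu,phi", [([-1.0], [0.1]), ([1.0], [-0.1])])
def test_gamma_rejects_negative_parameters(rng, mu, phi):
    with pytest.raises(InvalidParameterError):
        sample_gamma_abundances(mu, phi, 1, rng)


def test_gamma_rejects_mismatched_lengths(rng):
    with pytest.raises(InvalidParameterError):
        sample_gamma_abundances([1.0, 2.0], [0.1], 1, rng)


# ---------------------------------------------------------------------------
# population construction


def test_build_population_already_integer():
    pop = build_population([3.0, 2.0], lib_size=2)
    assert pop.m.tolist() == [3, 2] and pop.total == 5


def test_build_population_scales_to_lib_size():
    pop = build_population([0.6, 0.4], lib_size=10)
    assert pop.m.tolist() == [6, 4] and pop.total == 10


def test_build_population_largest_remainder_matches_bruteforce():
    # derived oracle: the apportionment must be among those minimizing the
    # worst-case proportion error over all integer vectors hitting the total
    for raw, lib in [((1.0, 1.0, 1.0), 2), ((0.5, 0.3, 0.2), 10), ((2.2, 1.1, 0.7), 4)]:
        pop = build_population(list(raw), lib_size=lib)
        assert tuple(pop.m.tolist()) in {
            tuple(y) for y in best_integer_apportionments(raw, pop.total)
        }


def test_build_population_equal_raw_stays_equal():
    pop = build_population([1.0, 1.0, 1.0], lib_size=2)
    assert pop.m.tolist() == [1, 1, 1] and pop.total == 3


def test_build_population_population_scale():
    pop = build_population([0.6, 0.4], lib_size=10, population_scale=5.0)
    assert pop.total == 50
    assert pop.m.tolist() == [30, 20]


def test_build_population_all_zero_errors():
    with pytest.raises(DegenerateSampleError):
        build_population([0.0, 0.0], lib_size=5)


def test_build_population_rejects_bad_inputs():
    with pytest.raises(InvalidParameterError):
        build_population([1.0, -1.0], lib_size=5)
    with pytest.raises(InvalidParameterError):
        build_population([1.0], lib_size=0)
    with pytest.raises(InvalidParameterError):
        build_population([1.0], lib_size=5, population_scale=0.5)


@settings(max_examples=50, deadline=None)
@given(
    raw=st.lists(st.floats(0.0, 1e4, allow_nan=False), min_size=1, max_size=20).filter(
        lambda xs: sum(xs) > 1e-6
    ),
    lib_size=st.integers(1, 10_000),
    scale=st.floats(1.0, 10.0),
)
def test_build_population_total_and_feasibility(raw, lib_size, scale):
    pop = build_population(raw, lib_size, scale)
    assert pop.total == max(int(round(sum(raw))), int(round(lib_size * scale)))
    assert pop.total >= lib_size
    assert np.all(pop.m >= 0)
    # zero raw entries must stay structurally absent
    assert all(m == 0 for m, r in zip(pop.m, raw) if r == 0)


# ---------------------------------------------------------------------------
# multivariate hypergeometric sampler


def test_mhg_exhaustive_draw_returns_urn(rng):
    pop = Population(m=[3, 2, 5])
    assert sample_mhg(pop, 10, rng).tolist() == [3, 2, 5]


def test_mhg_zero_draws(rng):
    assert sample_mhg(Population(m=[3, 2]), 0, rng).tolist() == [0, 0]


def test_mhg_rejects_overdraw(rng):
    with pytest.raises(InsufficientPopulationError):
        sample_mhg(Population(m=[3, 2]), 6, rng)


def test_mhg_conservation_and_bounds(rng):
    pop = Population(m=[5, 0, 3, 7])
    draws = sample_mhg(pop, 6, rng, size=500)
    assert np.all(draws.sum(axis=0) == 6)
    assert np.all(draws >= 0)
    assert np.all(draws <= pop.m[:, None])
    assert np.all(draws[1] == 0)  # empty class never sampled


def test_mhg_matches_enumeration_probability(rng):
    # P(Y = (2, 0)) for urn (3, 2), 2 draws is C(3,2)C(2,0)/C(5,2) = 3/10
    pop = Population(m=[3, 2])
    n_rep = 100_000
    draws = sample_mhg(pop, 2, rng, size=n_rep)
    p = mhg_pmf([3, 2], (2, 0))
    assert p == pytest.approx(0.3)
    freq = np.mean(draws[0] == 2)
    se = np.sqrt(p * (1 - p) / n_rep)
    assert abs(freq - p) < 3 * se


def test_mhg_joint_distribution_small_urn(rng):
    # chi-square GOF of the empirical joint law against exact enumeration
    m, n = [1, 2, 3], 3
    outcomes = enumerate_outcomes(m, n)
    probs = np.array([mhg_pmf(m, y) for y in outcomes])
    assert probs.sum() == pytest.approx(1.0)
    n_rep = 50_000
    draws = sample_mhg(Population(m=m), n, rng, size=n_rep)
    keys = {y: i for i, y in enumerate(outcomes)}
    observed = np.zeros(len(outcomes))
    for y in draws.T:
        observed[keys[tuple(y)]] += 1
    _, pvalue = stats.chisquare(observed, probs * n_rep)
    assert pvalue > 0.01


def test_mhg_permutation_equivariance(rng):
    # sampling a permuted urn and un-permuting must follow the original law
    m, n = [1, 2, 3], 3
    perm = np.array([2, 0, 1])
    inv = np.argsort(perm)
    draws = sample_mhg(Population(m=list(np.array(m)[perm])), n, rng, size=50_000)[inv]
    outcomes = enumerate_outcomes(m, n)
    probs = np.array([mhg_pmf(m, y) for y in outcomes])
    keys = {y: i for i, y in enumerate(outcomes)}
    observed = np.zeros(len(outcomes))
    for y in draws.T:
        observed[keys[tuple(y)]] += 1
    _, pvalue = stats.chisquare(observed, probs * draws.shape[1])
    assert pvalue > 0.01


def test_mhg_agrees_with_numpy_reference(rng):
    # dual route: numpy's own multivariate_hypergeometric as library oracle
    m, n = [4, 3, 6], 5
    ours = sample_mhg(Population(m=m), n, rng, size=40_000)
    ref = rng.multivariate_hypergeometric(m, n, size=40_000, method="count").T
    for i in range(3):
        a = np.bincount(ours[i], minlength=max(m) + 1)
        b = np.bincount(ref[i], minlength=max(m) + 1)
        keep = (a + b) > 20
        _, p = stats.chisquare(a[keep], (a + b)[keep] / 2)
        assert p > 0.001


@settings(max_examples=40, deadline=None)
@given(
    m=st.lists(st.integers(0, 30), min_size=1, max_size=8).filter(lambda xs: sum(xs) > 0),
    frac=st.floats(0.0, 1.0),
    seed=st.integers(0, 2**31),
)
def test_mhg_invariants_property(m, frac, seed):
    pop = Population(m=m)
    n = int(round(frac * pop.total))
    y = sample_mhg(pop, n, np.random.default_rng(seed))
    assert y.sum() == n
    assert np.all(y >= 0) and np.all(y <= pop.m)


# ---------------------------------------------------------------------------
# zero probability


def test_zero_probability_closed_form():
    pop = Population(m=[1, 9])
    assert zero_probability(pop, 5, 0) == pytest.approx(comb(9, 5) / comb(10, 5))
    assert zero_probability(pop, 5, 0) == pytest.approx(0.5)


def test_zero_probability_degenerate_cases():
    pop = Population(m=[0, 5, 5])
    assert zero_probability(pop, 3, 0) == 1.0  # absent feature
    assert zero_probability(pop, 10, 1) == 0.0  # exhaustive draw
    assert zero_probability(pop, 0, 1) == 1.0  # no draws


def test_zero_probability_matches_scipy_grid():
    for m_i, rest, n in [(1, 9, 5), (3, 50, 10), (20, 1000, 100), (2, 100_000, 5000)]:
        pop = Population(m=[m_i, rest])
        expected = stats.hypergeom.pmf(0, m_i + rest, m_i, n)
        assert zero_probability(pop, n, 0) == pytest.approx(expected, rel=1e-9)


def test_zero_probability_large_urn_no_overflow():
    pop = Population(m=[10, 10**7])
    p = zero_probability(pop, 10**6, 0)
    assert 0.0 < p < 1.0
    assert p == pytest.approx((1 - 0.1) ** 10, rel=0.01)


def test_zero_frequency_matches_closed_form(rng):
    pop = Population(m=[2, 5, 13])
    n, n_rep = 6, 100_000
    draws = sample_mhg(pop, n, rng, size=n_rep)
    for i in range(3):
        p = zero_probability(pop, n, i)
        freq = np.mean(draws[i] == 0)
        se = np.sqrt(p * (1 - p) / n_rep)
        assert abs(freq - p) <= 3 * se + 1e-12


# ---------------------------------------------------------------------------
# simulate


def test_simulate_deterministic_chain():
    from otusim import GroupParams, SimulationParams

    params = SimulationParams(
        feature_ids=("a", "b"),
        groups=(
            GroupParams(name="g", mu=[10.0, 0.0], phi=[0.0, 0.0], lib_sizes=[5]),
        ),
    )
    result = simulate(params, seed=0)
    assert result.counts[:, 0].tolist() == [5, 0]
    assert result.rel_abundance[:, 0].tolist() == [1.0, 0.0]


def test_simulate_conservation(small_params):
    result = simulate(small_params, seed=42)
    expected = np.concatenate([g.lib_sizes for g in small_params.groups])
    assert np.array_equal(result.counts.sum(axis=0), expected)


def test_simulate_reproducible(small_params):
    r1 = simulate(small_params, seed=7)
    r2 = simulate(small_params, seed=7)
    assert np.array_equal(r1.counts, r2.counts)
    assert np.array_equal(r1.rel_abundance, r2.rel_abundance)
    r3 = simulate(small_params, seed=8)
    assert not np.array_equal(r1.counts, r3.counts)


def test_simulate_rel_abundance_contract(small_params):
    result = simulate(small_params, seed=3)
    np.testing.assert_allclose(result.rel_abundance.sum(axis=0), 1.0, atol=1e-9)
    assert np.all(result.rel_abundance >= 0)
    assert np.all(result.counts[result.rel_abundance == 0] == 0)


def test_simulate_error_carries_context():
    from otusim import GroupParams, SimulationParams

    params = SimulationParams(
        feature_ids=("a", "b"),
        groups=(
            GroupParams(name="bad_group", mu=[0.0, 0.0], phi=[0.0, 0.0], lib_sizes=[5]),
        ),
    )
    with pytest.raises(DegenerateSampleError, match="bad_group"):
        simulate(params, seed=0)


def test_simulate_sample_labels(small_params):
    result = simulate(small_params, seed=0)
    assert result.sample_ids[:3] == ("g1_r1", "g1_r2", "g1_r3")
    assert result.sample_groups[3:] == ("g2", "g2", "g2")


def test_params_validation():
    from otusim import GroupParams, SimulationParams

    with pytest.raises(InvalidParameterError):
        SimulationParams(feature_ids=("a", "a"), groups=(
            GroupParams(name="g", mu=[1.0, 1.0], phi=[0.0, 0.0], lib_sizes=[5]),))
    with pytest.raises(InvalidParameterError):
        SimulationParams(feature_ids=("a", "b"), groups=(
            GroupParams(name="g", mu=[1.0], phi=[0.0], lib_sizes=[5]),))
    with pytest.raises(InvalidParameterError):
        GroupParams(name="g", mu=[1.0], phi=[0.0], lib_sizes=[0])
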