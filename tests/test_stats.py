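"""Moment estimators, bootstrap intervals, and convergence curves."""

import itertools

import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st

from ensuq import (
    Ensemble,
    EnergyTrajectory,
    SyntheticSpec,
    bootstrap_ci,
    convergence_curve,
    ensemble_mean,
    excess_kurtosis,
    generate_ensemble,
    moment_report,
    replica_delta_g,
    sample_skewness,
)
from ensuq.stats import UndefinedStatisticError, WindowError, error_bar


def _traj(values, dt=1.0):
    values = np.asarray(values, dtype=float)
    return EnergyTrajectory("r", dt * np.arange(1, len(values) + 1), values)


# -- windowed per-replica aggregation -------------------------------------

def test_replica_delta_g_windows():
    t = _traj([1.0, 2.0, 3.0, 4.0])
    assert replica_delta_g(t) == 2.5
    assert replica_delta_g(t, t_max_ns=2.0) == 1.5          # first 2 ns
    assert replica_delta_g(t, burn_in_ns=2.0) == 3.5        # discard first 2 ns
    assert replica_delta_g(_traj([-10.0] * 5), t_max_ns=3.0) == -10.0


def test_empty_window_reports_available_range():
    with pytest.raises(WindowError, match=r"\[1, 4\] ns"):
        replica_delta_g(_traj([1.0, 2.0, 3.0, 4.0]), burn_in_ns=9.0)


def test_ensemble_mean_and_reordering(tiny_ensemble):
    assert ensemble_mean(tiny_ensemble) == -10.0
    flipped = Ensemble(replicas=tiny_ensemble.replicas[::-1], label="t")
    assert ensemble_mean(flipped) == ensemble_mean(tiny_ensemble)


# -- skewness / kurtosis identities ---------------------------------------

def test_skewness_hand_computed_value():
    assert sample_skewness([0.0, 0.0, 1.0]) == pytest.approx(1 / np.sqrt(2))


def test_symmetric_sample_has_zero_skewness():
    assert sample_skewness([-3.0, -1.0, 0.0, 1.0, 3.0]) == pytest.approx(0.0, abs=1e-12)


def test_two_point_sample_kurtosis_is_minus_two():
    assert excess_kurtosis([-1.0, 1.0, -1.0, 1.0]) == pytest.approx(-2.0, abs=1e-12)


def test_normal_limit_of_kurtosis():
    n = 10**6
    x = np.random.default_rng(0).standard_normal(n)
    assert abs(excess_kurtosis(x)) < 5 * np.sqrt(24.0 / n)


def test_undefined_statistics_raise():
    with pytest.raises(UndefinedStatisticError):
        sample_skewness([1.0, 1.0, 1.0])
    with pytest.raises(UndefinedStatisticError):
        excess_kurtosis([2.0, 2.0, 2.0, 2.0])
    with pytest.raises(UndefinedStatisticError):
        sample_skewness([1.0, 2.0])


@settings(max_examples=50, deadline=None)
@given(
    vals=st.lists(st.floats(-100, 100), min_size=5, max_size=30, unique=True),
    a=st.floats(0.1, 10.0),
    b=st.floats(-50.0, 50.0),
)
def test_affine_equivariance(vals, a, b):
    """g1 and g2 are invariant under x -> a x + b (a>0); g1 flips for a<0."""
    x = np.array(vals)
    assume(np.std(x) > 1e-2)
    y = a * x + b
    assert sample_skewness(y) == pytest.approx(sample_skewness(x), abs=1e-7)
    assert excess_kurtosis(y) == pytest.approx(excess_kurtosis(x), abs=1e-7)
    assert sample_skewness(-x) == pytest.approx(-sample_skewness(x), abs=1e-9)


def test_bias_corrected_estimators_close_at_large_n():
    """g1/G1 and g2/G2 differ by O(1/n) at n=500 for moderate moments."""
    x = np.random.default_rng(1).standard_normal(500)
    assert sample_skewness(x, bias_corrected=True) == pytest.approx(
        sample_skewness(x), abs=0.01)
    assert excess_kurtosis(x, bias_corrected=True) == pytest.approx(
        excess_kurtosis(x), abs=0.02)


# -- bootstrap ------------------------------------------------------------

def test_bootstrap_matches_exhaustive_enumeration_oracle():
    """Percentile CI on n=5 vs brute force over all 5^5 = 3125 resamples."""
    data = np.array([1.0, 2.0, 3.0, 4.0, 100.0])
    means = np.array([
        np.mean(s) for s in itertools.product(data, repeat=5)
    ])  # every with-replacement resample is equally likely
    exact_lo, exact_hi = np.quantile(means, [0.025, 0.975])
    lo, hi = bootstrap_ci(data, "mean", n_boot=100_000, confidence=0.95, seed=0)
    assert lo == pytest.approx(exact_lo, abs=0.5)
    assert hi == pytest.approx(exact_hi, abs=0.5)


def test_bootstrap_constant_data_degenerate_interval():
    lo, hi = bootstrap_ci([3.0] * 10, "mean", n_boot=200, confidence=0.95, seed=1)
    assert lo == hi == 3.0


def test_bootstrap_deterministic_given_seed():
    x = np.random.default_rng(2).normal(size=40)
    assert bootstrap_ci(x, "skewness", 1000, 0.95, seed=5) == bootstrap_ci(
        x, "skewness", 1000, 0.95, seed=5)
    assert bootstrap_ci(x, "skewness", 1000, 0.95, seed=5) != bootstrap_ci(
        x, "skewness", 1000, 0.95, seed=6)


def test_bootstrap_redraw_cap_errors_on_degenerate_data():
    with pytest.raises(UndefinedStatisticError, match="cap"):
        bootstrap_ci([1.0] * 6, "skewness", n_boot=100, seed=0, _max_attempt_factor=2)


def test_bootstrap_redraws_past_occasional_degenerate_resamples():
    # two distinct values: zero-variance resamples occur but are redrawn
    lo, hi = bootstrap_ci([0.0, 0.0, 1.0], "skewness", n_boot=500, seed=3)
    assert lo <= hi


def test_error_bar_is_ci_half_width():
    x = np.random.default_rng(3).normal(size=30)
    lo, hi = bootstrap_ci(x, "mean", 2000, 0.67, seed=9)
    assert error_bar(x, 0.67, 2000, seed=9) == pytest.approx((hi - lo) / 2)


# -- moment report --------------------------------------------------------

def test_moment_report_fields_and_minimum_n():
    ens = generate_ensemble(SyntheticSpec(n_replicas=4, frames_per_replica=5, seed=1))
    rep = moment_report(ens, n_boot=500, seed=0)
    assert rep.n == 4
    assert rep.ci_skewness[0] <= rep.ci_skewness[1]
    assert rep.ci_kurtosis[0] <= rep.ci_kurtosis[1]
    assert np.isfinite(rep.ci_kurtosis).all()
    small = generate_ensemble(SyntheticSpec(n_replicas=3, frames_per_replica=5, seed=1))
    with pytest.raises(UndefinedStatisticError):
        moment_report(small)


def test_gaussian_skewness_ci_covers_zero_in_most_runs():
    """95% bootstrap CI for skewness of 100 normal replicas: >=17/20 cover 0."""
    hits = 0
    for seed in range(20):
        ens = generate_ensemble(SyntheticSpec(
            family="gaussian", n_replicas=100, frames_per_replica=1, seed=seed))
        rep = moment_report(ens, n_boot=2000, seed=seed)
        lo, hi = rep.ci_skewness
        hits += lo <= 0.0 <= hi
    assert hits >= 17


def test_moment_report_deterministic(scalar_gaussian_ensemble):
    a = moment_report(scalar_gaussian_ensemble, n_boot=1000, seed=4)
    b = moment_report(scalar_gaussian_ensemble, n_boot=1000, seed=4)
    assert a == b


# -- convergence curves ----------------------------------------------------

def test_convergence_curve_full_size_is_exact(scalar_gaussian_ensemble):
    curve = convergence_curve(
        scalar_gaussian_ensemble, "skewness", sizes=[10, 50, 100], n_draws=50, seed=0)
    vals = np.array([r.values[0] for r in scalar_gaussian_ensemble])
    assert curve.sems[-1] == 0.0
    assert curve.means[-1] == pytest.approx(sample_skewness(vals), abs=1e-12)


def test_convergence_curve_mean_statistic_is_unbiased(scalar_gaussian_ensemble):
    curve = convergence_curve(
        scalar_gaussian_ensemble, "mean", sizes=[5, 20, 50, 100], n_draws=200, seed=1)
    full = ensemble_mean(scalar_gaussian_ensemble)
    for m, s in zip(curve.means[:-1], curve.sems[:-1]):
        assert abs(m - full) < 3 * s


def test_convergence_curve_null_skewness_centered_on_zero():
    """Sub-ensemble skewness is unbiased for the symmetric null.

    Within one parent ensemble the per-size means converge to that parent's
    own (noisy) statistic, so the null check averages curves over
    independent parent ensembles: the grand mean per size must sit near 0
    within ~3 standard errors of the parent-level skewness noise.
    """
    n_parents, n_rep = 20, 200
    grand = np.zeros(3)
    for seed in range(n_parents):
        ens = generate_ensemble(SyntheticSpec(
            family="gaussian", n_replicas=n_rep, frames_per_replica=1,
            seed=600 + seed))
        curve = convergence_curve(ens, "skewness", sizes=[10, 30, 100],
                                  n_draws=50, seed=seed)
        grand += np.array(curve.means)
    grand /= n_parents
    se_parent = np.sqrt(6.0 / n_rep / n_parents)
    assert np.all(np.abs(grand) < 3 * se_parent + 0.02)


def test_convergence_curve_size_validation(scalar_gaussian_ensemble):
    with pytest.raises(ValueError, match="exceeds"):
        convergence_curve(scalar_gaussian_ensemble, "mean", sizes=[10, 101])
    with pytest.raises(ValueError, match="minimum"):
        convergence_curve(scalar_gaussian_ensemble, "excess_kurtosis", sizes=[3, 10])
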