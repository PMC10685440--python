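"""Generator ground truth: analytic moments, marginal recovery, determinism."""

import numpy as np
import pytest
from scipy import integrate, stats

from ensuq import SyntheticSpec, analytic_moments, generate_ensemble
from ensuq.synthetic import SpecValidationError


def _pooled(spec: SyntheticSpec) -> np.ndarray:
    ens = generate_ensemble(spec)
    return np.concatenate([r.values for r in ens])


def _moments_by_quadrature(pdf, lo=-np.inf, hi=np.inf):
    """Independent oracle: moments of a density by numerical integration.

    Central moments are integrated directly about the numerically computed
    mean, which keeps the quadrature error additive rather than amplified
    by cancellation between large raw moments.
    """
    m1 = integrate.quad(lambda x: x * pdf(x), lo, hi, limit=400, epsabs=1e-13)[0]
    cm = [integrate.quad(lambda x, k=k: (x - m1) ** k * pdf(x), lo, hi,
                         limit=400, epsabs=1e-13)[0]
          for k in (2, 3, 4)]
    var = cm[0]
    return m1, np.sqrt(var), cm[1] / var**1.5, cm[2] / var**2 - 3.0


def test_skew_normal_moments_match_quadrature_oracle():
    spec = SyntheticSpec(family="skew_normal", location=-10.0, scale=1.5, shape=10.0)
    got = analytic_moments(spec)
    pdf = lambda x: stats.skewnorm.pdf(x, 10.0, loc=-10.0, scale=1.5)
    mean, sd, skew, kurt = _moments_by_quadrature(pdf)
    assert got.mean == pytest.approx(mean, abs=1e-8)
    assert got.sd == pytest.approx(sd, abs=1e-8)
    assert got.skewness == pytest.approx(skew, abs=1e-7)   # ≈ 0.9556 at shape=10
    assert got.excess_kurtosis == pytest.approx(kurt, abs=1e-6)


def test_student_t_kurtosis_matches_quadrature_oracle():
    spec = SyntheticSpec(family="student_t", location=0.0, scale=1.0, dof=10.0)
    got = analytic_moments(spec)
    assert got.excess_kurtosis == pytest.approx(1.0)       # 6/(dof-4)
    pdf = lambda x: stats.t.pdf(x, 10.0)
    _, _, skew, kurt = _moments_by_quadrature(pdf)
    assert got.excess_kurtosis == pytest.approx(kurt, abs=1e-6)
    assert got.skewness == pytest.approx(skew, abs=1e-8)


def test_student_t_undefined_moments_are_marked_not_numbers():
    low = analytic_moments(SyntheticSpec(family="student_t", dof=3.0))
    assert low.excess_kurtosis is None
    assert low.skewness is None       # dof <= 3
    assert low.sd is not None
    assert analytic_moments(SyntheticSpec(family="student_t", dof=0.5)).mean is None


def test_gaussian_and_symmetric_mixture_moments():
    g = analytic_moments(SyntheticSpec(family="gaussian", location=-10.0, scale=2.0))
    assert (g.mean, g.sd, g.skewness, g.excess_kurtosis) == (-10.0, 2.0, 0.0, 0.0)
    m = analytic_moments(
        SyntheticSpec(family="mixture", components=((0.5, -3.0, 1.0), (0.5, 3.0, 1.0)))
    )
    assert m.mean == pytest.approx(0.0)
    assert m.skewness == pytest.approx(0.0, abs=1e-14)


def test_mixture_degenerates_to_single_component():
    m = analytic_moments(
        SyntheticSpec(family="mixture", components=((1.0, -10.0, 1.5),))
    )
    g = analytic_moments(SyntheticSpec(family="gaussian", location=-10.0, scale=1.5))
    assert (m.mean, m.sd, m.skewness, m.excess_kurtosis) == (
        g.mean, g.sd, pytest.approx(0.0), pytest.approx(0.0))


def test_same_spec_same_seed_bit_identical():
    spec = SyntheticSpec(family="skew_normal", shape=5.0, n_replicas=5,
                         frames_per_replica=50, ar1_rho=0.3, seed=11)
    a, b = generate_ensemble(spec), generate_ensemble(spec)
    for ra, rb in zip(a, b):
        np.testing.assert_array_equal(ra.values, rb.values)


def test_smaller_ensemble_is_prefix_of_larger():
    small = generate_ensemble(SyntheticSpec(n_replicas=5, frames_per_replica=10, seed=3))
    big = generate_ensemble(SyntheticSpec(n_replicas=9, frames_per_replica=10, seed=3))
    for rs, rb in zip(small, big):
        np.testing.assert_array_equal(rs.values, rb.values)


def test_pooled_mean_sanity_bound():
    # law-of-large-numbers bound: 4 sigma / sqrt(2500) = 0.08
    spec = SyntheticSpec(family="gaussian", location=-10.0, scale=1.0,
                         n_replicas=25, frames_per_replica=100, seed=7)
    assert abs(_pooled(spec).mean() - (-10.0)) < 0.08


@pytest.mark.parametrize("spec", [
    SyntheticSpec(family="gaussian", location=-10, scale=1.0,
                  n_replicas=100, frames_per_replica=2000, seed=1),
    SyntheticSpec(family="skew_normal", location=-10, scale=1.0, shape=10.0,
                  n_replicas=100, frames_per_replica=2000, seed=2),
    SyntheticSpec(family="student_t", location=-10, scale=1.0, dof=10.0,
                  n_replicas=100, frames_per_replica=2000, seed=3),
    SyntheticSpec(family="mixture",
                  components=((0.3, -12.0, 0.8), (0.7, -9.0, 1.2)),
                  n_replicas=100, frames_per_replica=2000, seed=4),
])
def test_sample_moments_recover_analytic_values(spec):
    """Pooled draws (2e5) match population mean/SD/skewness within 5 MC SEs."""
    x = _pooled(spec)
    n = x.size
    mom = analytic_moments(spec)
    assert abs(x.mean() - mom.mean) < 5 * mom.sd / np.sqrt(n)
    assert abs(x.std(ddof=1) - mom.sd) < 5 * mom.sd * np.sqrt(
        (mom.excess_kurtosis + 2.0) / (4.0 * n))
    # skewness MC standard error under near-normality ~ sqrt(6/n); inflate for
    # the heavier-tailed families
    assert abs(stats.skew(x) - mom.skewness) < 5 * 4 * np.sqrt(6.0 / n)


def test_between_replica_spread_dilutes_shape_moments():
    """Persistent replica offsets add variance and dilute skew/kurtosis."""
    spec = SyntheticSpec(family="skew_normal", location=-10.0, scale=1.0,
                         shape=10.0, between_replica_sd=1.0,
                         n_replicas=400, frames_per_replica=500, seed=14)
    base = analytic_moments(SyntheticSpec(family="skew_normal", location=-10.0,
                                          scale=1.0, shape=10.0))
    mom = analytic_moments(spec)
    assert mom.sd == pytest.approx(np.hypot(base.sd, 1.0))
    assert 0 < mom.skewness < base.skewness
    # pooled frames share their replica's offset, so the effective sample
    # size for the offset component is the 400 replicas, not the 200k frames
    x = _pooled(spec)
    assert abs(x.mean() - mom.mean) < 0.2
    assert abs(x.std(ddof=1) - mom.sd) < 0.15
    assert abs(stats.skew(x) - mom.skewness) < 0.35


def test_ar1_lag1_autocorrelation_recovered():
    spec = SyntheticSpec(family="gaussian", location=0.0, scale=1.0,
                         n_replicas=1, frames_per_replica=100_000,
                         ar1_rho=0.5, seed=5)
    x = generate_ensemble(spec).replicas[0].values
    r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
    assert abs(r1 - 0.5) < 0.05


def test_copula_preserves_non_gaussian_marginal():
    """AR(1) with a skew-normal target keeps the marginal shape (approx.)."""
    spec = SyntheticSpec(family="skew_normal", location=-10, scale=1.0, shape=10.0,
                         n_replicas=50, frames_per_replica=4000, ar1_rho=0.5, seed=6)
    x = _pooled(spec)
    mom = analytic_moments(spec)
    assert abs(x.mean() - mom.mean) < 0.05
    assert abs(x.std(ddof=1) - mom.sd) < 0.05
    assert abs(stats.skew(x) - mom.skewness) < 0.15


def test_per_replica_modes_pin_each_replica_to_one_basin():
    spec = SyntheticSpec(
        family="mixture", components=((0.5, -14.0, 0.3), (0.5, -6.0, 0.3)),
        n_replicas=40, frames_per_replica=200, per_replica_modes=True, seed=8,
    )
    ens = generate_ensemble(spec)
    for r in ens:
        # whole trajectory in one mode: spread far below the mode separation
        assert np.ptp(r.values) < 4.0
    means = np.array([r.values.mean() for r in ens])
    assert (means < -10).any() and (means > -10).any()


@pytest.mark.parametrize("kwargs,field", [
    (dict(family="nope"), "family"),
    (dict(scale=0.0), "scale"),
    (dict(family="student_t", dof=-1.0), "dof"),
    (dict(n_replicas=0), "n_replicas"),
    (dict(frames_per_replica=0), "frames_per_replica"),
    (dict(frame_interval_ns=0.0), "frame_interval_ns"),
    (dict(ar1_rho=1.0), "ar1_rho"),
    (dict(family="mixture", components=((0.5, 0, 1), (0.6, 1, 1))), "components"),
    (dict(family="mixture", components=()), "components"),
    (dict(per_replica_modes=True), "per_replica_modes"),
])
def test_invalid_spec_error_names_the_field(kwargs, field):
    with pytest.raises(SpecValidationError, match=field):
        SyntheticSpec(**kwargs)


def test_spec_dict_round_trip():
    spec = SyntheticSpec(family="mixture",
                         components=((0.25, -12.0, 1.0), (0.75, -9.0, 0.5)),
                         n_replicas=7, seed=9)
    assert SyntheticSpec.from_dict(spec.to_dict()) == spec
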