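"""Normality diagnostics for replica ΔG distributions.

Two omnibus tests plus a Q-Q analysis with a simulated confidence envelope:

* Shapiro–Wilk W (Royston's extension, valid for 3 ≤ n ≤ 5000).
* D'Agostino/Pearson K² = Z₁² + Z₂², combining D'Agostino's skewness
  transform with the Anscombe–Glynn kurtosis transform; p from χ²(2).
* Q-Q points of the standardized sample against standard-normal quantiles
  at plotting positions (i − 0.5)/n, with a pointwise percentile envelope
  built from seeded normal simulations of the same n.

Both tests are exactly invariant under affine transforms of the data, so
they apply to ΔG in any consistent unit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .stats import UndefinedStatisticError

__all__ = [
    "NormalityReport",
    "shapiro_wilk",
    "dagostino_pearson",
    "qq_analysis",
    "normality_report",
]

SHAPIRO_MIN_N = 3
SHAPIRO_MAX_N = 5000
DAGOSTINO_MIN_N = 20


@dataclass(frozen=True)
class NormalityReport:
    n: int
    shapiro_w: float
    shapiro_p: float
    dagostino_k2: float
    dagostino_p: float
    #: (theoretical_quantile, sample_quantile) pairs, sorted by the former
    qq: tuple[tuple[float, float], ...] = ()
    #: pointwise (lo, hi) envelope per Q-Q point
    qq_envelope: tuple[tuple[float, float], ...] = ()
    envelope_confidence: float = 0.95


def _checked(values, min_n: int, max_n: int | None, what: str) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError(f"{what}: expected a 1-d sample")
    if len(v) < min_n or (max_n is not None and len(v) > max_n):
        hi = f" and <= {max_n}" if max_n is not None else ""
        extra = (
            "; use dagostino_pearson for larger samples"
            if max_n is not None and len(v) > max_n
            else ""
        )
        raise ValueError(f"{what} requires n >= {min_n}{hi}, got {len(v)}{extra}")
    if np.ptp(v) == 0:
        raise UndefinedStatisticError(f"{what} undefined for zero-variance data")
    return v


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro–Wilk W statistic and p-value (3 ≤ n ≤ 5000)."""
    v = _checked(values, SHAPIRO_MIN_N, SHAPIRO_MAX_N, "Shapiro-Wilk")
    res = sps.shapiro(v)
    return float(res.statistic), float(res.pvalue)


def dagostino_pearson(values) -> tuple[float, float]:
    """D'Agostino/Pearson omnibus K² statistic and χ²(2) p-value (n ≥ 20)."""
    v = _checked(values, DAGOSTINO_MIN_N, None, "D'Agostino/Pearson")
    res = sps.normaltest(v)
    return float(res.statistic), float(res.pvalue)


def dagostino_components(values) -> tuple[float, float]:
    """The Z₁ (skewness) and Z₂ (kurtosis) transforms whose squares sum to K²."""
    v = _checked(values, DAGOSTINO_MIN_N, None, "D'Agostino/Pearson")
    z1 = sps.skewtest(v).statistic
    z2 = sps.kurtosistest(v).statistic
    return float(z1), float(z2)


def qq_analysis(
    values,
    envelope_confidence: float = 0.95,
    n_sim: int = 10_000,
    seed: int = 0,
    plotting_positions: str = "midpoint",
) -> tuple[tuple[tuple[float, float], ...], tuple[tuple[float, float], ...]]:
    """Normal Q-Q points and a simulated pointwise confidence envelope.

    The sample is standardized by its own mean and SD and its order
    statistics paired with standard-normal quantiles at positions
    (i − 0.5)/n (``midpoint``, default) or (i − 3/8)/(n + 1/4) (``blom``).
    The envelope is the pointwise [(1−c)/2, 1−(1−c)/2] percentile band of
    standardized order statistics over ``n_sim`` seeded normal samples of
    the same n, so under normality each point falls inside with probability
    close to ``envelope_confidence``.

    Returns ``(qq, envelope)`` where each is a tuple of pairs.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 10:
        raise ValueError(f"qq_analysis requires n >= 10, got {v.size}")
    if np.ptp(v) == 0:
        raise UndefinedStatisticError("qq_analysis undefined for zero-variance data")
    if not (0.0 < envelope_confidence < 1.0):
        raise ValueError("envelope_confidence must be in (0, 1)")
    n = len(v)
    i = np.arange(1, n + 1)
    if plotting_positions == "midpoint":
        p = (i - 0.5) / n
    elif plotting_positions == "blom":
        p = (i - 3.0 / 8.0) / (n + 0.25)
    else:
        raise ValueError(f"unknown plotting_positions {plotting_positions!r}")
    theo = sps.norm.ppf(p)
    std = np.sort((v - v.mean()) / v.std(ddof=1))

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    sims = rng.standard_normal(size=(n_sim, n))
    sims = (sims - sims.mean(axis=1, keepdims=True)) / sims.std(axis=1, ddof=1, keepdims=True)
    sims.sort(axis=1)
    alpha = (1.0 - envelope_confidence) / 2.0
    lo, hi = np.quantile(sims, [alpha, 1.0 - alpha], axis=0)

    qq = tuple((float(t), float(s)) for t, s in zip(theo, std))
    env = tuple((float(a), float(b)) for a, b in zip(lo, hi))
    return qq, env


def normality_report(
    values,
    envelope_confidence: float = 0.95,
    n_sim: int = 10_000,
    seed: int = 0,
    with_qq: bool = True,
) -> NormalityReport:
    """Bundle both tests (and optionally the Q-Q analysis) into one report."""
    v = np.asarray(values, dtype=float)
    w, p_sw = shapiro_wilk(v)
    k2, p_dp = dagostino_pearson(v)
    qq: tuple = ()
    env: tuple = ()
    if with_qq:
        qq, env = qq_analysis(v, envelope_confidence, n_sim, seed)
    return NormalityReport(
        n=len(v),
        shapiro_w=w,
        shapiro_p=p_sw,
        dagostino_k2=k2,
        dagostino_p=p_dp,
        qq=qq,
        qq_envelope=env,
        envelope_confidence=envelope_confidence,
    )
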