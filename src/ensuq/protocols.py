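"""Fixed-budget protocol comparison: how to split B ns into k replicas × t ns.

Given a fixed simulation budget (say 60 ns per compound), the candidate
protocols are the k × t allocations with t = floor(B/k) down to the frame
grid.  Single-replica allocations are excluded because one trajectory
cannot quantify its own uncertainty, and very short runs because a ~1-ns
production run is too short to converge.  Each surviving protocol is
scored by subsampling k replicas from a reference ensemble, truncating
them to their first t ns, and bootstrapping the replica-mean ΔG; the
recommendation logic prefers the largest replica count among protocols
statistically indistinguishable from the consensus estimate — "run more
simulations for less time".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .io import Ensemble
from .stats import bootstrap_ci, replica_delta_g

__all__ = [
    "ProtocolSpec",
    "ProtocolResult",
    "Recommendation",
    "EmptyEnumerationError",
    "CapacityError",
    "enumerate_protocols",
    "evaluate_protocol",
    "compare_protocols",
]

MIN_REPLICAS_DEFAULT = 2
MIN_DURATION_NS_DEFAULT = 2.0


class EmptyEnumerationError(ValueError):
    """No candidate protocol survived the constraints; message explains why."""


class CapacityError(ValueError):
    """The reference ensemble cannot supply the requested k × t protocol."""


@dataclass(frozen=True)
class ProtocolSpec:
    """A k-replica × t-ns allocation of the simulation budget."""

    n_replicas: int
    duration_ns: float

    def __post_init__(self) -> None:
        if self.n_replicas < 1 or self.duration_ns <= 0:
            raise ValueError("protocol needs n_replicas >= 1 and duration_ns > 0")

    @property
    def cost_ns(self) -> float:
        return self.n_replicas * self.duration_ns

    def __str__(self) -> str:
        t = self.duration_ns
        t_str = f"{t:g}"
        return f"{self.n_replicas}x{t_str}ns"


@dataclass(frozen=True)
class ProtocolResult:
    spec: ProtocolSpec
    delta_g: float
    error_bar: float
    confidence: float
    n_subset_draws: int
    seed: int
    #: replica ids chosen in each subset draw (one tuple of k ids per draw)
    replica_ids_used: tuple[tuple[str, ...], ...]


def enumerate_protocols(
    budget_ns: float,
    candidate_replica_counts,
    min_replicas: int = MIN_REPLICAS_DEFAULT,
    min_duration_ns: float = MIN_DURATION_NS_DEFAULT,
    max_available: tuple[int, float] | None = None,
    frame_interval_ns: float = 1.0,
) -> list[ProtocolSpec]:
    """Enumerate feasible k × t protocols for a fixed budget.

    For each candidate replica count k, the duration is budget/k rounded
    down to the frame grid, clipped to the available trajectory length.
    Candidates below ``min_replicas`` or whose duration falls below
    ``min_duration_ns`` are dropped.  Returns specs sorted by k ascending;
    raises :class:`EmptyEnumerationError` (explaining the fate of every
    candidate) if nothing survives.
    """
    if budget_ns <= 0:
        raise ValueError("budget_ns must be > 0")
    candidates = sorted(set(int(k) for k in candidate_replica_counts))
    if not candidates:
        raise ValueError("candidate_replica_counts must be nonempty")
    n_avail, t_avail = max_available if max_available else (None, None)

    specs: list[ProtocolSpec] = []
    fate: list[str] = []
    for k in candidates:
        if k < min_replicas:
            fate.append(f"k={k}: below min_replicas={min_replicas}")
            continue
        if n_avail is not None and k > n_avail:
            fate.append(f"k={k}: exceeds available replicas N={n_avail}")
            continue
        t = np.floor(budget_ns / k / frame_interval_ns) * frame_interval_ns
        if t_avail is not None:
            t = min(t, t_avail)
        if t < min_duration_ns:
            fate.append(f"k={k}: duration {t:g} ns below min_duration={min_duration_ns:g} ns")
            continue
        specs.append(ProtocolSpec(n_replicas=k, duration_ns=float(t)))
    if not specs:
        raise EmptyEnumerationError(
            "no protocol survived the constraints: " + "; ".join(fate)
        )
    return specs


def evaluate_protocol(
    ensemble: Ensemble,
    spec: ProtocolSpec,
    n_subset_draws: int = 1,
    n_boot: int = 10_000,
    confidence: float = 0.67,
    seed: int = 0,
) -> ProtocolResult:
    """Score one protocol by replica subsampling and trajectory truncation.

    Each draw selects k replicas uniformly without replacement and computes
    their frame-mean ΔG over the first t ns; ``delta_g`` averages the
    replica-means over draws and ``error_bar`` averages the per-draw
    bootstrap half-widths.  The default single draw mirrors reading a
    published figure built from one random subset; more draws expose
    subset-selection variability.  With k = N and t = the full duration the
    unique subset makes the result identical across seeds and equal to the
    full-ensemble mean.
    """
    k, t = spec.n_replicas, spec.duration_ns
    N = ensemble.n_replicas
    if k > N:
        raise CapacityError(f"protocol needs k={k} replicas, ensemble has {N}")
    short = [r.replica_id for r in ensemble if r.duration_ns < t - 1e-9]
    if short:
        raise CapacityError(
            f"protocol needs {t:g} ns but replica(s) {short[:5]} are shorter"
        )
    if n_subset_draws < 1:
        raise ValueError("n_subset_draws must be >= 1")

    ss = np.random.SeedSequence(seed)
    pick_rng = np.random.default_rng(ss.spawn(1)[0])
    boot_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_subset_draws)]

    dgs, bars, used = [], [], []
    for d in range(n_subset_draws):
        idx = np.sort(pick_rng.choice(N, size=k, replace=False))
        reps = [ensemble.replicas[i] for i in idx]
        vals = np.array([replica_delta_g(r, 0.0, t) for r in reps])
        dgs.append(np.mean(vals))
        lo, hi = bootstrap_ci(vals, "mean", n_boot=n_boot, confidence=confidence,
                              seed=boot_seeds[d])
        bars.append((hi - lo) / 2.0)
        used.append(tuple(r.replica_id for r in reps))
    return ProtocolResult(
        spec=spec,
        delta_g=float(np.mean(dgs)),
        error_bar=float(np.mean(bars)),
        confidence=confidence,
        n_subset_draws=n_subset_draws,
        seed=seed,
        replica_ids_used=tuple(used),
    )


@dataclass(frozen=True)
class Recommendation:
    recommended: ProtocolSpec
    consensus_delta_g: float
    #: per-protocol two-sided p-value of the difference from the consensus
    p_values: tuple[float, ...]
    #: protocols statistically indistinguishable from the consensus
    indistinguishable: tuple[ProtocolSpec, ...]
    #: protocols whose estimate differs significantly from the consensus
    flagged: tuple[ProtocolSpec, ...]
    alpha: float


def _se_from_error_bar(error_bar: float, confidence: float) -> float:
    """Convert a percentile half-width to an (approximate) standard error."""
    z = sps.norm.ppf(0.5 + confidence / 2.0)
    return error_bar / z


def compare_protocols(
    results: list[ProtocolResult],
    alpha: float = 0.05,
    consensus: float | None = None,
    consensus_error_bar: float | None = None,
) -> Recommendation:
    """Flag discrepant protocols and recommend the cheapest-per-replica one.

    Each protocol's ΔG is compared with the consensus estimate (the
    supplied full-data value, or else the evaluated protocol with the
    largest k·t) by a two-sided z-test with standard errors recovered from
    the bootstrap error bars.  Among protocols indistinguishable from the
    consensus at level ``alpha``, the one with the most replicas wins;
    ties go to the shorter duration.
    """
    if not results:
        raise ValueError("compare_protocols needs at least one result")
    confs = {r.confidence for r in results}
    if len(confs) != 1:
        raise ValueError(f"mixed confidence levels in results: {sorted(confs)}")
    conf = confs.pop()

    if consensus is None:
        ref = max(results, key=lambda r: r.spec.cost_ns)
        consensus = ref.delta_g
        se_ref = _se_from_error_bar(ref.error_bar, conf)
    else:
        se_ref = (
            _se_from_error_bar(consensus_error_bar, conf)
            if consensus_error_bar is not None
            else 0.0
        )

    p_values, ok, flagged = [], [], []
    for r in results:
        se = np.hypot(_se_from_error_bar(r.error_bar, conf), se_ref)
        z = 0.0 if se == 0 else (r.delta_g - consensus) / se
        p = float(2.0 * sps.norm.sf(abs(z)))
        p_values.append(p)
        (flagged if p < alpha else ok).append(r.spec)
    pool = ok if ok else [r.spec for r in results]
    recommended = max(pool, key=lambda s: (s.n_replicas, -s.duration_ns))
    return Recommendation(
        recommended=recommended,
        consensus_delta_g=float(consensus),
        p_values=tuple(p_values),
        indistinguishable=tuple(ok),
        flagged=tuple(flagged),
        alpha=alpha,
    )
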