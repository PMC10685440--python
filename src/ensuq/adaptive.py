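"""Adaptive replica schedules: grow the ensemble until the error bar is small.

The stepwise rule: start with a minimal ensemble (10 replicas for an
ESMACS-style absolute-binding-free-energy protocol, 3 for a TIES-style
relative protocol), evaluate the uncertainty of the ensemble-mean ΔG, and
add replicas in batches until the error bar drops below a predefined
precision threshold (0.5 kcal/mol by default) or a cap is reached.

The stopping error bar is the 67% bootstrap half-width of the replica-mean
by default (the convention used for protocol error bars throughout this
package); a flag switches to 1.96 × SEM.  The rule is the plain sequential
threshold — the mild optional-stopping bias of checking repeatedly is
documented, not corrected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np

from .io import Ensemble
from .stats import error_bar as _boot_error_bar, replica_delta_g
from .synthetic import SyntheticSpec, draw_replica_values

__all__ = [
    "AdaptiveConfig",
    "AdaptiveRun",
    "InsufficientDataError",
    "run_adaptive",
    "ensemble_source",
    "synthetic_source",
]

STYLE_MINIMUM = {"esmacs": 10, "ties": 3}


class InsufficientDataError(ValueError):
    """The replica source ran dry before the initial ensemble was filled."""


@dataclass(frozen=True)
class AdaptiveConfig:
    """Parameters of the threshold-driven replica schedule.

    ``initial_n`` defaults to the style minimum (esmacs → 10, ties → 3).
    ``threshold`` is in kcal/mol and may be ``math.inf`` (stop immediately).
    """

    style: str = "esmacs"
    initial_n: int | None = None
    batch_size: int = 5
    threshold: float = 0.5
    max_n: int = 50
    confidence: float = 0.67
    n_boot: int = 10_000
    seed: int = 0
    use_sem: bool = False

    def __post_init__(self) -> None:
        if self.style not in STYLE_MINIMUM:
            raise ValueError(f"style must be one of {sorted(STYLE_MINIMUM)}")
        if self.initial_n is None:
            object.__setattr__(self, "initial_n", STYLE_MINIMUM[self.style])
        if self.initial_n < 2:
            raise ValueError("initial_n must be >= 2")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not (self.threshold > 0):
            raise ValueError("threshold must be > 0 kcal/mol")
        if self.max_n < self.initial_n:
            raise ValueError("max_n must be >= initial_n")


@dataclass(frozen=True)
class AdaptiveRun:
    """History of one adaptive schedule: (n, ΔG, error_bar) at each check."""

    history: tuple[tuple[int, float, float], ...]
    converged: bool
    final_n: int
    threshold: float

    @property
    def final_delta_g(self) -> float:
        return self.history[-1][1]

    @property
    def final_error_bar(self) -> float:
        return self.history[-1][2]


def ensemble_source(
    ensemble: Ensemble,
    burn_in_ns: float = 0.0,
    t_max_ns: float | None = None,
) -> Iterator[float]:
    """Replica provider that consumes an existing ensemble in stored order."""
    for r in ensemble:
        yield replica_delta_g(r, burn_in_ns, t_max_ns)


def synthetic_source(spec: SyntheticSpec) -> Iterator[float]:
    """Unbounded provider drawing fresh replicas on demand from a spec.

    Each replica uses its own deterministic substream of ``spec.seed`` (in
    spawn order), so the first N draws coincide with the per-replica ΔG of
    ``generate_ensemble`` with ``n_replicas=N``.
    """
    master = np.random.SeedSequence(spec.seed)
    while True:
        rng = np.random.default_rng(master.spawn(1)[0])
        yield float(np.mean(draw_replica_values(spec, rng)))


def _current_error(vals: np.ndarray, cfg: AdaptiveConfig, step_seed: int) -> float:
    if cfg.use_sem:
        return float(1.96 * np.std(vals, ddof=1) / np.sqrt(len(vals)))
    return _boot_error_bar(vals, confidence=cfg.confidence, n_boot=cfg.n_boot, seed=step_seed)


def run_adaptive(source: Ensemble | Iterable[float], config: AdaptiveConfig) -> AdaptiveRun:
    """Run the threshold-driven schedule against a replica provider.

    ``source`` is either an :class:`Ensemble` (consumed in stored order) or
    any iterable of per-replica ΔG values (e.g. :func:`synthetic_source`).
    The error bar is evaluated at n = initial_n and after every added batch;
    the run stops when error_bar ≤ threshold, n reaches ``max_n``, or the
    source is exhausted.  Deterministic given the config seed and source.
    """
    it = ensemble_source(source) if isinstance(source, Ensemble) else iter(source)
    vals: list[float] = []
    exhausted = False

    def take(k: int) -> int:
        nonlocal exhausted
        got = 0
        for _ in range(k):
            try:
                vals.append(float(next(it)))
                got += 1
            except StopIteration:
                exhausted = True
                break
        return got

    if take(config.initial_n) < config.initial_n:
        raise InsufficientDataError(
            f"source supplied only {len(vals)} replicas; initial_n={config.initial_n}"
        )

    step_seeds = np.random.SeedSequence(config.seed)
    history: list[tuple[int, float, float]] = []
    while True:
        arr = np.asarray(vals)
        step_seed = int(step_seeds.spawn(1)[0].generate_state(1)[0] % (2**31))
        bar = _current_error(arr, config, step_seed)
        history.append((len(arr), float(np.mean(arr)), bar))
        if bar <= config.threshold or math.isinf(config.threshold):
            converged = bar <= config.threshold
            break
        if len(vals) >= config.max_n or exhausted:
            converged = False
            break
        want = min(config.batch_size, config.max_n - len(vals))
        if take(want) == 0:
            converged = False
            # exhausted exactly at a batch boundary: record nothing new
            break
    return AdaptiveRun(
        history=tuple(history),
        converged=bool(converged),
        final_n=history[-1][0],
        threshold=config.threshold,
    )
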