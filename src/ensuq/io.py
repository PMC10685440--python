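"""Tabular energy formats and the core in-memory containers.

Two dialects of free-energy tables are supported:

``per_frame``
    Columns ``replica_id, frame_index, time_ns, delta_g`` — one row per
    trajectory frame, ΔG in kcal/mol.
``per_replica``
    Columns ``replica_id, delta_g`` — one scalar per replica (each becomes a
    length-1 trajectory with a nominal 1-ns frame).

Units are fixed to kcal/mol throughout; no conversion is attempted.
Readers accept comma- or tab-separated files (delimiter sniffed from the
header line); writers always emit comma-separated output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EnergyTrajectory",
    "Ensemble",
    "SchemaError",
    "ParseError",
    "IntegrityError",
    "read_energy_table",
    "write_energy_table",
]

#: Absolute tolerance for uniform frame spacing and time comparisons (ns).
TIME_TOL_NS = 1e-9


class SchemaError(ValueError):
    """A required column is missing or an unknown column mapping was given."""


class ParseError(ValueError):
    """A cell could not be interpreted (non-numeric or non-finite ΔG)."""


class IntegrityError(ValueError):
    """Structural inconsistency: duplicate frames, duplicate replica ids."""


@dataclass(frozen=True)
class EnergyTrajectory:
    """One replica's ΔG-versus-time series.

    Parameters
    ----------
    replica_id : str
        Unique identifier of the replica within its ensemble.
    times : ndarray
        Frame times in ns, strictly increasing with uniform spacing.
    values : ndarray
        ΔG per frame in kcal/mol; finite, same length as ``times``.
    """

    replica_id: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or values.ndim != 1:
            raise ValueError("times and values must be one-dimensional")
        if len(times) != len(values) or len(times) < 1:
            raise ValueError(
                f"replica {self.replica_id!r}: need equal-length, nonempty "
                f"times/values (got {len(times)} and {len(values)})"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError(f"replica {self.replica_id!r}: non-finite ΔG value")
        if not np.all(np.isfinite(times)):
            raise ValueError(f"replica {self.replica_id!r}: non-finite time")
        if len(times) > 1:
            dt = np.diff(times)
            if np.any(dt <= 0):
                raise ValueError(
                    f"replica {self.replica_id!r}: times must be strictly increasing"
                )
            if np.any(np.abs(dt - dt[0]) > TIME_TOL_NS):
                raise ValueError(
                    f"replica {self.replica_id!r}: frame spacing not uniform "
                    f"within {TIME_TOL_NS} ns"
                )

    @property
    def n_frames(self) -> int:
        return len(self.values)

    @property
    def duration_ns(self) -> float:
        """Time of the last frame (end of the sampled interval)."""
        return float(self.times[-1])


@dataclass(frozen=True)
class Ensemble:
    """An ordered collection of replica trajectories analysed jointly.

    Replica ΔG values (frame-means) are the unit of statistical inference:
    replicas differ by initial velocities and are treated as independent
    draws from the underlying free-energy distribution.
    """

    replicas: tuple[EnergyTrajectory, ...]
    label: str = ""
    units: str = field(default="kcal/mol")

    def __post_init__(self) -> None:
        object.__setattr__(self, "replicas", tuple(self.replicas))
        if len(self.replicas) < 1:
            raise ValueError("an Ensemble requires at least one replica")
        ids = [r.replica_id for r in self.replicas]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise IntegrityError(f"duplicate replica_id(s): {dupes}")
        if self.units != "kcal/mol":
            raise ValueError("units are fixed to kcal/mol")

    @property
    def n_replicas(self) -> int:
        return len(self.replicas)

    def __iter__(self):
        return iter(self.replicas)

    def __len__(self) -> int:
        return len(self.replicas)


_PER_FRAME_COLS = ["replica_id", "frame_index", "time_ns", "delta_g"]
_PER_REPLICA_COLS = ["replica_id", "delta_g"]


def _sniff_sep(path: str) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") > header.count(",") else ","


def read_energy_table(
    path: str,
    dialect: str = "per_frame",
    col_map: dict[str, str] | None = None,
    label: str | None = None,
) -> Ensemble:
    """Read a CSV/TSV free-energy table into an :class:`Ensemble`.

    Parameters
    ----------
    path : str
        File to read; delimiter auto-detected from the header.
    dialect : {"per_frame", "per_replica"}
        Table layout (see module docstring).
    col_map : dict, optional
        Mapping from the canonical column names to the names used in the
        file, so externally deposited tables can be adapted without edits,
        e.g. ``{"delta_g": "dG_total"}``.
    label : str, optional
        Ensemble label; defaults to the file path.

    Raises
    ------
    SchemaError
        Missing required columns (all of them are listed).
    ParseError
        Non-numeric or non-finite ΔG, with the offending row number.
    IntegrityError
        Duplicate ``(replica_id, frame_index)`` pairs.
    """
    if dialect not in ("per_frame", "per_replica"):
        raise ValueError(f"unknown dialect {dialect!r}")
    required = _PER_FRAME_COLS if dialect == "per_frame" else _PER_REPLICA_COLS
    col_map = dict(col_map or {})
    unknown = set(col_map) - set(_PER_FRAME_COLS)
    if unknown:
        raise SchemaError(f"col_map refers to unknown canonical columns: {sorted(unknown)}")

    df = pd.read_csv(
        path,
        sep=_sniff_sep(path),
        dtype={col_map.get("replica_id", "replica_id"): str},
        float_precision="round_trip",
    )
    rename = {v: k for k, v in col_map.items()}
    df = df.rename(columns=rename)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s) {missing} in {path}")

    dg = pd.to_numeric(df["delta_g"], errors="coerce")
    bad = ~np.isfinite(dg.to_numpy(dtype=float))
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 2  # 1-based, +1 for header
        raise ParseError(f"non-numeric or non-finite delta_g at {path} line {row}")
    df["delta_g"] = dg.astype(float)
    df["replica_id"] = df["replica_id"].astype(str)

    replicas: list[EnergyTrajectory] = []
    if dialect == "per_frame":
        if df.duplicated(subset=["replica_id", "frame_index"]).any():
            pair = df[df.duplicated(subset=["replica_id", "frame_index"])].iloc[0]
            raise IntegrityError(
                f"duplicate (replica_id, frame_index) = "
                f"({pair['replica_id']!r}, {int(pair['frame_index'])})"
            )
        for rid, grp in df.groupby("replica_id", sort=False):
            grp = grp.sort_values("frame_index")
            replicas.append(
                EnergyTrajectory(
                    replica_id=str(rid),
                    times=grp["time_ns"].to_numpy(dtype=float),
                    values=grp["delta_g"].to_numpy(dtype=float),
                )
            )
    else:
        if df["replica_id"].duplicated().any():
            rid = df.loc[df["replica_id"].duplicated(), "replica_id"].iloc[0]
            raise IntegrityError(f"duplicate replica_id {rid!r} in per_replica table")
        for _, row in df.iterrows():
            replicas.append(
                EnergyTrajectory(
                    replica_id=str(row["replica_id"]),
                    times=np.array([1.0]),
                    values=np.array([float(row["delta_g"])]),
                )
            )
    return Ensemble(replicas=tuple(replicas), label=label if label is not None else str(path))


def write_energy_table(
    ensemble: Ensemble,
    path: str,
    dialect: str = "per_frame",
    aggregate: bool = False,
) -> None:
    """Write an ensemble to a comma-separated table.

    ``per_replica`` output requires length-1 trajectories unless
    ``aggregate=True``, in which case each row holds the replica's
    frame-mean ΔG.
    """
    if dialect not in ("per_frame", "per_replica"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if dialect == "per_frame":
        rows = [
            {
                "replica_id": r.replica_id,
                "frame_index": i,
                "time_ns": t,
                "delta_g": v,
            }
            for r in ensemble
            for i, (t, v) in enumerate(zip(r.times, r.values))
        ]
        df = pd.DataFrame(rows, columns=_PER_FRAME_COLS)
    else:
        if not aggregate and any(r.n_frames != 1 for r in ensemble):
            raise ValueError(
                "per_replica dialect needs length-1 trajectories; "
                "pass aggregate=True to write frame-mean ΔG per replica"
            )
        df = pd.DataFrame(
            {
                "replica_id": [r.replica_id for r in ensemble],
                "delta_g": [float(np.mean(r.values)) for r in ensemble],
            }
        )
    df.to_csv(path, index=False, float_format="%.17g")


def per_replica_values(
    ensemble: Ensemble,
    burn_in_ns: float = 0.0,
    t_max_ns: float | None = None,
) -> np.ndarray:
    """Vector of per-replica ΔG (frame-means over the analysis window).

    The window is ``burn_in_ns < time_ns <= t_max_ns`` (half-open on the
    left); ``t_max_ns=None`` means the full trajectory.  Convenience used
    throughout the statistics layer.
    """
    from .stats import replica_delta_g  # local import to avoid a cycle

    return np.array(
        [replica_delta_g(r, burn_in_ns=burn_in_ns, t_max_ns=t_max_ns) for r in ensemble]
    )
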