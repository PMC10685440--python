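"""Study-level report assembly and the end-to-end pipeline driver.

A StudyReport is the Table-1-shaped summary of a campaign: one row per
ensemble with the replica count, mean ± SEM, skewness and excess kurtosis
with bracketed bootstrap CIs, and both normality p-values.  The reporter
only formats numbers produced upstream — it never recomputes a statistic —
and carries a provenance block (settings, seeds, version) sufficient to
regenerate the report exactly.

Formatting convention: moments to 2 decimals in the CSV rendering,
p-values in scientific notation with 3 significant digits; the structured
(JSON) document retains full precision.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import Ensemble, read_energy_table, write_energy_table, per_replica_values
from .stats import moment_report, convergence_curve
from .normality import shapiro_wilk, dagostino_pearson
from .protocols import enumerate_protocols, evaluate_protocol, compare_protocols
from .adaptive import AdaptiveConfig, run_adaptive
from .synthetic import SyntheticSpec, generate_ensemble

__all__ = ["StudyReport", "build_report", "end_to_end", "ConfigError"]

log = logging.getLogger("ensuq")


class ConfigError(ValueError):
    """Malformed or unknown configuration; raised before any computation."""


@dataclass(frozen=True)
class StudyReport:
    rows: pd.DataFrame
    provenance: dict

    def to_csv(self, path: str) -> None:
        df = self.rows.copy()
        for col in ("mean", "sem", "skewness", "excess_kurtosis"):
            if col in df:
                df[col] = df[col].map(lambda x: f"{x:.2f}" if pd.notna(x) else "")
        for col in ("ci_skewness", "ci_kurtosis", "ci_mean"):
            if col in df:
                df[col] = df[col].map(
                    lambda c: f"[{c[0]:.2f}, {c[1]:.2f}]" if isinstance(c, tuple) else ""
                )
        for col in ("shapiro_p", "dagostino_p"):
            if col in df:
                df[col] = df[col].map(lambda x: f"{x:.3g}" if pd.notna(x) else "")
        df.to_csv(path, index=False)

    def to_json(self, path: str) -> None:
        doc = {
            "provenance": self.provenance,
            "rows": json.loads(self.rows.to_json(orient="records")),
        }
        Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def build_report(
    ensembles: list[Ensemble],
    confidence: float = 0.95,
    n_boot: int = 10_000,
    seed: int = 0,
    burn_in_ns: float = 0.0,
    t_max_ns: float | None = None,
) -> StudyReport:
    """One Table-1-style row per ensemble; per-row failures are captured.

    A failing ensemble (too few replicas, zero variance, ...) yields a row
    with its label and an ``error`` message instead of aborting the run.
    """
    if not ensembles:
        raise ValueError("build_report needs at least one ensemble")
    seeds = np.random.SeedSequence(seed).spawn(len(ensembles))
    rows = []
    for ens, ss in zip(ensembles, seeds):
        row: dict = {"label": ens.label, "n": ens.n_replicas, "error": ""}
        sub = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2)]
        try:
            mr = moment_report(ens, confidence, n_boot, sub[0], burn_in_ns, t_max_ns)
            vals = per_replica_values(ens, burn_in_ns, t_max_ns)
            # each normality test has its own validity range; a test that is
            # not applicable at this n leaves a NaN, not a row failure
            try:
                p_sw = shapiro_wilk(vals)[1]
            except ValueError:
                p_sw = float("nan")
            try:
                p_dp = dagostino_pearson(vals)[1]
            except ValueError:
                p_dp = float("nan")
            row.update(
                mean=mr.mean, sem=mr.sem,
                skewness=mr.skewness, ci_skewness=mr.ci_skewness,
                excess_kurtosis=mr.excess_kurtosis, ci_kurtosis=mr.ci_kurtosis,
                ci_mean=mr.ci_mean,
                shapiro_p=p_sw, dagostino_p=p_dp,
            )
        except Exception as e:  # row-level capture, campaign continues
            log.warning("ensemble %r failed: %s", ens.label, e)
            row["error"] = str(e)
        rows.append(row)
    prov = {
        "tool": "ensuq",
        "version": __version__,
        "confidence": confidence,
        "n_boot": n_boot,
        "seed": seed,
        "burn_in_ns": burn_in_ns,
        "t_max_ns": t_max_ns,
    }
    return StudyReport(rows=pd.DataFrame(rows), provenance=prov)


# -- end-to-end configuration-driven run ----------------------------------

_KNOWN_STAGES = ("simulate", "stats", "normality", "convergence", "protocols", "adapt")


def _load_inputs(cfg: dict, out_dir: Path) -> list[Ensemble]:
    ensembles: list[Ensemble] = []
    for item in cfg.get("inputs", []):
        if "synthetic" in item:
            spec = SyntheticSpec.from_dict(item["synthetic"])
            ensembles.append(generate_ensemble(spec, label=item.get("label")))
        elif "path" in item:
            ensembles.append(
                read_energy_table(
                    item["path"],
                    dialect=item.get("dialect", "per_frame"),
                    col_map=item.get("col_map"),
                    label=item.get("label"),
                )
            )
        else:
            raise ConfigError(f"input item needs 'synthetic' or 'path': {item}")
    return ensembles


def end_to_end(config_path: str, out_dir: str | None = None) -> dict[str, str]:
    """Run the configured stages and write their artifacts.

    The YAML config names the inputs (files or synthetic specs), the stages
    to run, and per-stage settings; all outputs land in ``out_dir``.
    Returns a mapping from stage name to the file it wrote.  Reruns with
    the same config produce byte-identical outputs.
    """
    cfg = yaml.safe_load(Path(config_path).read_text())
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    stages = cfg.get("stages", [])
    unknown = [s for s in stages if s not in _KNOWN_STAGES]
    if unknown:
        raise ConfigError(f"unknown stage(s) {unknown}; known: {list(_KNOWN_STAGES)}")
    if not cfg.get("inputs"):
        raise ConfigError("config must list at least one input")
    out = Path(out_dir if out_dir is not None else cfg.get("out_dir", "."))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    n_boot = int(cfg.get("n_boot", 10_000))

    ensembles = _load_inputs(cfg, out)
    artifacts: dict[str, str] = {}
    log.info("loaded %d ensemble(s); stages: %s; seed=%d", len(ensembles), stages, seed)

    if "simulate" in stages:
        p = out / "ensembles.csv"
        frames = []
        for ens in ensembles:
            tmp = out / f"_{ens.label}.csv"
            write_energy_table(ens, str(tmp), dialect="per_frame")
            df = pd.read_csv(tmp)
            df.insert(0, "label", ens.label)
            frames.append(df)
            tmp.unlink()
        pd.concat(frames).to_csv(p, index=False)
        artifacts["simulate"] = str(p)

    if "stats" in stages or "normality" in stages:
        rep = build_report(
            ensembles,
            confidence=float(cfg.get("confidence", 0.95)),
            n_boot=n_boot,
            seed=seed,
        )
        p = out / "study_report.csv"
        rep.to_csv(str(p))
        rep.to_json(str(out / "study_report.json"))
        artifacts["stats"] = str(p)

    if "convergence" in stages:
        rows = []
        for ens in ensembles:
            for statistic in ("skewness", "excess_kurtosis"):
                curve = convergence_curve(ens, statistic, seed=seed)
                for s, m, e in zip(curve.sizes, curve.means, curve.sems):
                    rows.append(
                        {"label": ens.label, "statistic": statistic, "size": s,
                         "mean": m, "sem": e}
                    )
        p = out / "convergence.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        artifacts["convergence"] = str(p)

    if "protocols" in stages:
        pc = cfg.get("protocols", {})
        rows = []
        for ens in ensembles:
            T = max(r.duration_ns for r in ens)
            specs = enumerate_protocols(
                float(pc.get("budget_ns", 60.0)),
                pc.get("candidates", [6, 12, 20, 30]),
                min_replicas=int(pc.get("min_replicas", 2)),
                min_duration_ns=float(pc.get("min_duration_ns", 2.0)),
                max_available=(ens.n_replicas, T),
            )
            results = [
                evaluate_protocol(ens, s, n_subset_draws=int(pc.get("n_subset_draws", 1)),
                                  n_boot=n_boot, confidence=float(pc.get("confidence", 0.67)),
                                  seed=seed)
                for s in specs
            ]
            rec = compare_protocols(results, alpha=float(pc.get("alpha", 0.05)))
            for r, p_ in zip(results, rec.p_values):
                rows.append(
                    {"label": ens.label, "k": r.spec.n_replicas, "t_ns": r.spec.duration_ns,
                     "delta_g": r.delta_g, "error_bar": r.error_bar, "p_vs_consensus": p_,
                     "flagged": r.spec in rec.flagged,
                     "recommended": r.spec == rec.recommended}
                )
        p = out / "protocols.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        artifacts["protocols"] = str(p)

    if "adapt" in stages:
        ac = cfg.get("adapt", {})
        acfg = AdaptiveConfig(
            style=ac.get("style", "esmacs"),
            initial_n=ac.get("initial_n"),
            batch_size=int(ac.get("batch_size", 5)),
            threshold=float(ac.get("threshold", 0.5)),
            max_n=int(ac.get("max_n", 50)),
            n_boot=n_boot,
            seed=seed,
        )
        rows = []
        for ens in ensembles:
            run = run_adaptive(ens, acfg)
            for n, dg, bar in run.history:
                rows.append({"label": ens.label, "n": n, "delta_g": dg,
                             "error_bar": bar, "converged": run.converged})
        p = out / "adaptive.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        artifacts["adapt"] = str(p)

    (out / "run_log.json").write_text(
        json.dumps({"version": __version__, "seed": seed, "stages": list(stages),
                    "artifacts": artifacts}, indent=2, sort_keys=True) + "\n"
    )
    return artifacts
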