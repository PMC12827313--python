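"""End-to-end analysis pipeline.

Runs the full registry analysis sequence on conforming data (real CSVs or
a simulated cohort): cohort filtering, state-path derivation, long-format
expansion, Kaplan-Meier overall survival, reverse-KM follow-up, the two
competing-risks preset analyses, the Aalen-Johansen occupation trajectory
with composite endpoints, the three transition-specific Cox models, and
model-based trajectories for the 18 reference patients.  Outputs are
plain CSV/JSON files stamped with the seed and a configuration hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import coxph, endpoints, msdata, nonparam, registry, simulate

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Inputs and settings of one pipeline run.

    Either ``baseline_csv``/``events_csv`` point to registry-format input
    files, or ``simulator`` provides a configuration to generate a
    synthetic cohort.
    """

    baseline_csv: Optional[str] = None
    events_csv: Optional[str] = None
    simulator: Optional[simulate.SimulatorConfig] = None
    seed: int = 0
    horizons_months: tuple[float, ...] = (60.0,)
    bootstrap_B: int = 0            # 0 disables bootstrap bands
    bootstrap_profiles: tuple = ()  # CovariateProfile instances
    output_dir: Optional[str] = None
    make_plots: bool = False

    def config_hash(self) -> str:
        blob = json.dumps(
            dataclasses.asdict(self), default=str, sort_keys=True
        ).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns a result bundle (and writes files
    under ``config.output_dir`` when set)."""
    structure = msdata.default_structure()

    # ---- load or simulate -------------------------------------------
    if config.simulator is not None:
        cohort = simulate.simulate_cohort(config.simulator, seed=config.seed)
        records = cohort.records
    elif config.baseline_csv and config.events_csv:
        for p in (config.baseline_csv, config.events_csv):
            if not Path(p).exists():
                raise PipelineError("load", f"input file not found: {p}")
        records = registry.read_registry_csv(config.baseline_csv, config.events_csv)
    else:
        raise PipelineError("load", "provide input CSVs or a simulator config")

    records = _stage("filter")(registry.filter_first_line_cohort)(records)
    paths = _stage("derive")(
        lambda rs: [registry.derive_state_path(r, structure) for r in rs]
    )(records)
    covariates = registry.records_to_covariates(records)
    dummies = coxph.encode_covariates(covariates)
    data = _stage("expand")(msdata.expand_long_format)(
        paths, structure, dummies.join(covariates[["age_cat", "severity", "pnh"]])
    )

    # ---- non-parametric ---------------------------------------------
    os_times = np.array([r.last_followup_day for r in records])
    os_status = np.array([int(r.death_day is not None) for r in records])
    km_os = _stage("km")(nonparam.kaplan_meier)(os_times, os_status, "OS")
    followup = _stage("reverse-km")(nonparam.reverse_kaplan_meier)(os_times, os_status)
    cif_first = _stage("cif")(nonparam.cif_transfusion_independence_first_line)(
        records, paths
    )
    cif_any = _stage("cif")(nonparam.cif_transfusion_independence_any_line)(
        records, paths
    )
    hazards = _stage("nelson-aalen")(nonparam.nelson_aalen)(data, structure)
    traj = _stage("aalen-johansen")(nonparam.aalen_johansen)(
        hazards, 0.0, structure
    )
    curves = endpoints.endpoint_curves(traj)
    curves["OS"] = km_os
    curves["alive within model"] = endpoints.model_alive_curve(traj)
    summary = endpoints.summarize_at(curves, config.horizons_months)
    stacked = endpoints.stacked_curves(traj)

    # ---- Cox models and reference patients --------------------------
    specs = coxph.default_model_specs()
    fits = {}
    for spec in specs:
        fits[spec.name] = _stage(f"cox-{spec.name}")(coxph.fit_transition_cox)(
            data, spec
        )
    profiles = coxph.reference_profiles()
    profile_results = {}
    for prof in profiles:
        ph = coxph.predict_profile_hazards(
            list(fits.values()), hazards, prof, structure
        )
        ptraj = coxph.predict_profile_probabilities(ph, structure)
        profile_results[prof.label] = {
            "trajectory": ptraj,
            "summary": endpoints.summarize_at(
                endpoints.endpoint_curves(ptraj), config.horizons_months
            ),
        }
    bootstrap = {}
    for prof in config.bootstrap_profiles:
        bootstrap[prof.label] = _stage("bootstrap")(coxph.bootstrap_profile_ci)(
            data, specs, prof,
            horizon=config.horizons_months[0] * registry.DAYS_PER_MONTH,
            B=config.bootstrap_B, seed=config.seed,
            structure=structure,
            state_sets={k: set(v) for k, v in endpoints.ENDPOINT_STATE_SETS.items()},
        )

    results = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_patients": len(records),
        "records": records,
        "paths": paths,
        "long_data": data,
        "km_os": km_os,
        "followup": followup,
        "median_followup_months": followup.median / registry.DAYS_PER_MONTH,
        "cif_first_line": cif_first,
        "cif_any_line": cif_any,
        "hazards": hazards,
        "trajectory": traj,
        "curves": curves,
        "summary": summary,
        "stacked": stacked,
        "fits": fits,
        "profiles": profile_results,
        "bootstrap": bootstrap,
    }
    if config.output_dir:
        _write_outputs(results, config)
    return results


def _write_outputs(results: dict, config: PipelineConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"seed": config.seed, "config_hash": results["config_hash"]}

    registry.write_state_paths_csv(results["paths"], out / "state_paths.csv")
    msdata.write_long_csv(results["long_data"], out / "long_format.csv")
    pd.concat(
        [c.to_frame() for c in results["curves"].values()], ignore_index=True
    ).assign(**stamp).to_csv(out / "endpoint_curves.csv", index=False)
    results["summary"].assign(**stamp).to_csv(out / "endpoint_summary.csv", index=False)
    for name, cifs in (
        ("cif_first_line", results["cif_first_line"]),
        ("cif_any_line", results["cif_any_line"]),
    ):
        pd.concat([c.to_frame() for c in cifs.values()], ignore_index=True).assign(
            **stamp
        ).to_csv(out / f"{name}.csv", index=False)
    results["stacked"].assign(**stamp).to_csv(
        out / "stacked_occupation.csv", index=False
    )
    for name, fit in results["fits"].items():
        (out / f"cox_{name}.json").write_text(fit.to_json())
    prof_rows = []
    for label, res in results["profiles"].items():
        s = res["summary"].copy()
        s["profile"] = label
        prof_rows.append(s)
    pd.concat(prof_rows, ignore_index=True).assign(**stamp).to_csv(
        out / "reference_patients.csv", index=False
    )
    (out / "run.json").write_text(json.dumps({
        **stamp,
        "n_patients": results["n_patients"],
        "median_followup_months": results["median_followup_months"],
    }, indent=2))
    if config.make_plots:
        _plot(results, out)


def _plot(results: dict, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    stacked = results["stacked"]
    t = stacked["time"].to_numpy() / registry.DAYS_PER_MONTH
    fig, ax = plt.subplots(figsize=(8, 5))
    prev = np.zeros(len(t))
    for col in stacked.columns[1:]:
        cur = stacked[col].to_numpy()
        ax.fill_between(t, prev, cur, step="post", label=col, alpha=0.85)
        prev = cur
    ax.set_xlabel("months since start of IST")
    ax.set_ylabel("probability")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=7, loc="center right")
    fig.tight_layout()
    fig.savefig(out / "stacked_occupation.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(7, 5))
    for label in ("OS", "DFS", "T-DFS", "TT-DFS"):
        c = results["curves"][label]
        ax.step(c.times / registry.DAYS_PER_MONTH, c.estimate, where="post", label=label)
        ax.fill_between(
            c.times / registry.DAYS_PER_MONTH, c.lower, c.upper,
            step="post", alpha=0.15,
        )
    ax.set_xlabel("months since start of IST")
    ax.set_ylabel("probability")
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "endpoint_curves.png", dpi=120)
    plt.close(fig)
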