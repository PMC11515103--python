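"""Artifact writing: manifests, per-scenario tables, reports, figures.

Layout of an output directory::

    out/
      manifest.json            written before any statistics
      config.yaml              normalized config echo
      comparisons.csv          one row per scenario per class
      summary.json             list of ExperimentSummary dicts
      <scenario>/cohort.csv    hr,sbp,gcs,bd,transfusion
      <scenario>/classes.csv   per-parameter + composite classes (roman)
      <scenario>/scenario.json config echo for replay
      <scenario>/fig1_histograms.png, fig2_classmeans.png  (optional)

Reports are deterministic: JSON is dumped with sorted keys and ``repr``
floats, so regenerating a report from saved tables reproduces it
byte-for-byte (figures excluded).
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .classify import ROMAN, ROMAN_TO_INT
from .config import MasterConfig
from .correlation import SCENARIOS, CorrelationSpec
from .cohort import ScenarioConfig
from .errors import StructuralError
from .experiment import ExperimentSummary, summarize
from .marginals import MarginalSpec, MixtureComponent, VARIABLES

CLASS_COLUMNS = ("hr_class", "sbp_class", "gcs_class", "bd_class",
                 "composite_class")


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, sort_keys=True, indent=1) + "\n")


def write_manifest(outdir: Path, master: MasterConfig,
                   cfg_hash: str | None, timestamp: bool = True) -> None:
    """Record provenance before any statistics are computed."""
    manifest = {
        "tool_version": __version__,
        "schema_version": 1,
        "config_hash": cfg_hash,
        "master_seed": master.seed,
        "scenario_seeds": {s: master.scenario_seed(s) for s in SCENARIOS},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime())
        if timestamp else None,
        "warnings": [
            f"placeholder marginal parameters in use for: {name}"
            for name in VARIABLES if master.marginals[name].placeholder
        ],
    }
    _json_dump(manifest, outdir / "manifest.json")


def write_scenario_tables(outdir: Path, cohort: pd.DataFrame,
                          classes: pd.DataFrame, config: ScenarioConfig) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    # shortest round-trip float repr: replaying from CSV is bit-exact
    cohort.to_csv(outdir / "cohort.csv", index=False,
                  float_format=lambda x: repr(float(x)))
    roman = classes[list(CLASS_COLUMNS)].map(ROMAN.get)
    roman.to_csv(outdir / "classes.csv", index=False)
    sidecar = {
        "scenario_id": config.scenario_id,
        "seed": config.seed,
        "n": config.n,
        "truncation": config.truncation,
        "exact_half_split": config.exact_half_split,
        "composite_members": list(config.composite_members),
        "comparison_singleton": config.comparison_singleton,
        "boundary_convention": ("hr <100/[100,120]/(120,140]/>140; "
                                "sbp left-closed at 90/100/110; bd right-closed"),
        "split_mode": "exact-half" if config.exact_half_split else "bernoulli",
        "pd_repaired": bool(cohort.attrs.get("pd_repaired", False)),
        "pd_repair_distance": float(cohort.attrs.get("pd_repair_distance", 0.0)),
        "correlation": {
            "scenario_id": config.correlation.scenario_id,
            "magnitudes": config.correlation.magnitudes.tolist(),
            "signs": config.correlation.signs.tolist(),
        },
        "marginals": {
            name: {
                "family": spec.family,
                "location": spec.location,
                "scale": spec.scale,
                "lower_bound": spec.lower_bound,
                "upper_bound": spec.upper_bound,
                "round_to_integer": spec.round_to_integer,
                "placeholder": spec.placeholder,
                "mixture": [[c.weight, c.mode, c.spread] for c in spec.mixture]
                if spec.mixture else None,
            }
            for name, spec in config.marginals.items()
        },
    }
    _json_dump(sidecar, outdir / "scenario.json")


def comparisons_frame(summaries: list[ExperimentSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        for c in s.comparisons:
            rows.append({
                "scenario": s.scenario_id,
                "shock_class": ROMAN[c.shock_class],
                "singleton": s.comparison_singleton,
                "n_singleton": c.n_singleton,
                "n_composite": c.n_composite,
                "mean_singleton": c.mean_singleton,
                "mean_composite": c.mean_composite,
                "sd_singleton": c.sd_singleton,
                "sd_composite": c.sd_composite,
                "t_statistic": c.t_statistic,
                "p_value": c.p_value,
                "degenerate": c.degenerate,
            })
    return pd.DataFrame(rows)


def render_report(summaries: list[ExperimentSummary], outdir: str | Path,
                  figures: bool = False) -> None:
    """Write summary.json + comparisons.csv (and optional figures)."""
    if not summaries:
        raise StructuralError("render_report requires at least one summary")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _json_dump([s.to_dict() for s in summaries], outdir / "summary.json")
    comparisons_frame(summaries).to_csv(outdir / "comparisons.csv", index=False)
    if figures:
        for s in summaries:
            sub = outdir / s.scenario_id
            if (sub / "cohort.csv").exists():
                cohort = pd.read_csv(sub / "cohort.csv")
                plot_histograms(cohort, sub / "fig1_histograms.png")
            plot_class_means(s, sub / "fig2_classmeans.png")


def plot_histograms(cohort: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 5, figsize=(18, 3.2))
    for ax, name in zip(axes, VARIABLES):
        bins = range(3, 17) if name == "gcs" else 40
        ax.hist(cohort[name], bins=bins, color="steelblue")
        ax.set_title(name)
        ax.set_ylabel("count")
    fig.tight_layout()
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_class_means(summary: ExperimentSummary, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    classes = [1, 2, 3, 4]
    single = [summary.singleton_stats[c].mean or 0 for c in classes]
    comp = [summary.composite_stats[c].mean or 0 for c in classes]
    x = np.arange(4)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(x - 0.2, single, width=0.4,
           label=summary.comparison_singleton, color="darkorange")
    ax.bar(x + 0.2, comp, width=0.4, label="composite", color="steelblue")
    ax.set_xticks(x, [ROMAN[c] for c in classes])
    ax.set_xlabel("shock class")
    ax.set_ylabel("mean transfusion (units pRBC)")
    ax.set_title(summary.scenario_id)
    ax.legend()
    fig.tight_layout()
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _marginal_from_sidecar(name: str, raw: dict) -> MarginalSpec:
    mixture = raw.get("mixture")
    return MarginalSpec(
        name=name,
        family=raw["family"],
        location=raw["location"],
        scale=raw["scale"],
        lower_bound=raw["lower_bound"],
        upper_bound=raw["upper_bound"],
        round_to_integer=raw["round_to_integer"],
        mixture=tuple(MixtureComponent(weight=w, mode=int(m), spread=s)
                      for w, m, s in mixture) if mixture else None,
        placeholder=raw.get("placeholder", False),
    )


def replay_scenario(scenario_dir: str | Path) -> ExperimentSummary:
    """Recompute a scenario summary from its saved artifacts.

    Reads ``cohort.csv``, ``classes.csv`` and ``scenario.json``; no new
    randomness is drawn, so the result is byte-identical to the original
    summary.
    """
    scenario_dir = Path(scenario_dir)
    sidecar = json.loads((scenario_dir / "scenario.json").read_text())
    cohort = pd.read_csv(scenario_dir / "cohort.csv",
                         float_precision="round_trip")
    classes = pd.read_csv(scenario_dir / "classes.csv").map(ROMAN_TO_INT.get)
    if classes.isna().any().any():
        raise StructuralError("classes.csv contains unknown class labels")
    import numpy as np

    config = ScenarioConfig(
        scenario_id=sidecar["scenario_id"],
        seed=sidecar["seed"],
        n=sidecar["n"],
        marginals={name: _marginal_from_sidecar(name, raw)
                   for name, raw in sidecar["marginals"].items()},
        correlation=CorrelationSpec(
            magnitudes=np.asarray(sidecar["correlation"]["magnitudes"]),
            signs=np.asarray(sidecar["correlation"]["signs"]),
            scenario_id=sidecar["correlation"]["scenario_id"],
        ),
        composite_members=tuple(sidecar["composite_members"]),
        comparison_singleton=sidecar["comparison_singleton"],
        truncation=sidecar["truncation"],
        exact_half_split=sidecar["exact_half_split"],
    )
    cohort.attrs.update(
        pd_repaired=sidecar.get("pd_repaired", False),
        pd_repair_distance=sidecar.get("pd_repair_distance", 0.0),
    )
    return summarize(config, cohort, classes.astype(int))
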