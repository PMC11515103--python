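"""End-to-end scenario runs and the bias statistics.

The core comparison deliberately reproduces the method under critique:
for each shock class, transfusion quantity in the group assigned that
class by the singleton parameter is compared against the group assigned
that class by the maximum composite, with a naive unpaired two-sample
t-test.  The two groups overlap in membership, so observations are not
independent -- that is a property of the original method and is recorded
as a caveat, not corrected.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .classify import ROMAN, classify_cohort
from .cohort import PREDICTORS, ScenarioConfig, simulate_cohort
from .errors import StructuralError

CLASSES = (1, 2, 3, 4)

COMPARISON_CAVEAT = (
    "singleton and composite class groups overlap in membership; the "
    "unpaired t-test treats them as independent (method under study)"
)


@dataclass(frozen=True)
class GroupStats:
    n: int
    mean: float | None
    sd: float | None


@dataclass(frozen=True)
class ClassComparison:
    """Per-class transfusion comparison between two allocation schemes."""

    shock_class: int
    n_singleton: int
    n_composite: int
    mean_singleton: float | None
    mean_composite: float | None
    sd_singleton: float | None
    sd_composite: float | None
    t_statistic: float | None
    p_value: float | None
    degenerate: bool


@dataclass(frozen=True)
class ExperimentSummary:
    """All bias statistics for one scenario, plus a config echo."""

    scenario_id: str
    n: int
    seed: int
    comparison_singleton: str
    composite_members: tuple[str, ...]
    comparisons: tuple[ClassComparison, ...]
    postprocessing_spearman: dict[str, float | None]
    joint_class_fraction: float
    joint_class_fraction_with_bd: float
    singleton_stats: dict[int, GroupStats]
    composite_stats: dict[int, GroupStats]
    config_echo: dict
    warnings: tuple[str, ...]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["composite_members"] = list(self.composite_members)
        d["comparisons"] = [asdict(c) for c in self.comparisons]
        d["singleton_stats"] = {ROMAN[k]: asdict(v)
                                for k, v in self.singleton_stats.items()}
        d["composite_stats"] = {ROMAN[k]: asdict(v)
                                for k, v in self.composite_stats.items()}
        d["warnings"] = list(self.warnings)
        return d


def _scheme_column(classes: pd.DataFrame, scheme: str) -> pd.Series:
    if scheme == "composite":
        return classes["composite_class"]
    col = f"{scheme}_class"
    if col not in classes.columns:
        raise StructuralError(f"unknown scheme {scheme!r}")
    return classes[col]


def joint_class_fraction(classes: pd.DataFrame, members) -> float:
    """Fraction of rows whose classes agree across all ``members``."""
    members = tuple(members)
    if not members:
        raise StructuralError("members must be nonempty")
    if len(classes) == 0:
        raise StructuralError("empty class table")
    cols = classes[[f"{m}_class" for m in members]].to_numpy()
    same = np.all(cols == cols[:, :1], axis=1)
    return float(same.mean())


def group_transfusion_stats(
    cohort: pd.DataFrame, classes: pd.DataFrame, scheme: str
) -> dict[int, GroupStats]:
    """Per-class count / mean / SD of transfusion under one scheme.

    Empty classes are reported with n=0 and ``None`` moments; SD uses the
    n-1 denominator and is ``None`` for singleton groups.
    """
    if len(cohort) != len(classes) or not cohort.index.equals(classes.index):
        raise StructuralError("cohort and class tables are not row-aligned")
    assigned = _scheme_column(classes, scheme)
    out: dict[int, GroupStats] = {}
    for cls in CLASSES:
        values = cohort.loc[assigned == cls, "transfusion"].to_numpy()
        n = values.size
        mean = float(values.mean()) if n else None
        sd = float(values.std(ddof=1)) if n >= 2 else None
        out[cls] = GroupStats(n=n, mean=mean, sd=sd)
    return out


def _pooled_t(a: np.ndarray, b: np.ndarray, welch: bool) -> tuple[float, float]:
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def compare_schemes(
    cohort: pd.DataFrame,
    classes: pd.DataFrame,
    singleton: str,
    welch: bool = False,
) -> list[ClassComparison]:
    """Classwise singleton-vs-composite transfusion t-tests.

    Degenerate cells (either group with n < 2, or zero variance in both
    groups) are flagged rather than fabricated; identical zero-variance
    groups report t=0, p=1, and unequal zero-variance groups +/-inf.
    """
    s_stats = group_transfusion_stats(cohort, classes, singleton)
    c_stats = group_transfusion_stats(cohort, classes, "composite")
    s_col = _scheme_column(classes, singleton)
    c_col = _scheme_column(classes, "composite")
    out = []
    for cls in CLASSES:
        a = cohort.loc[s_col == cls, "transfusion"].to_numpy()
        b = cohort.loc[c_col == cls, "transfusion"].to_numpy()
        t: float | None
        p: float | None
        degenerate = False
        if a.size < 2 or b.size < 2:
            t = p = None
            degenerate = True
        elif a.std() == 0.0 and b.std() == 0.0:
            degenerate = True
            if a.mean() == b.mean():
                t, p = 0.0, 1.0
            else:
                t = math.inf if a.mean() > b.mean() else -math.inf
                p = 0.0
        else:
            t, p = _pooled_t(a, b, welch)
        out.append(
            ClassComparison(
                shock_class=cls,
                n_singleton=s_stats[cls].n,
                n_composite=c_stats[cls].n,
                mean_singleton=s_stats[cls].mean,
                mean_composite=c_stats[cls].mean,
                sd_singleton=s_stats[cls].sd,
                sd_composite=c_stats[cls].sd,
                t_statistic=t,
                p_value=p,
                degenerate=degenerate,
            )
        )
    return out


def postprocessing_spearman(cohort: pd.DataFrame) -> dict[str, float | None]:
    """Spearman rho (average ranks) of each predictor with transfusion,
    computed on the final truncated / rounded columns."""
    if len(cohort) < 3:
        raise StructuralError("need at least 3 rows for rank correlation")
    out: dict[str, float | None] = {}
    y = cohort["transfusion"].to_numpy()
    for name in PREDICTORS:
        x = cohort[name].to_numpy()
        if np.all(x == x[0]) or np.all(y == y[0]):
            out[name] = None
            continue
        out[name] = float(stats.spearmanr(x, y).statistic)
    return out


def run_scenario(config: ScenarioConfig, welch: bool = False) -> ExperimentSummary:
    """Simulate, classify, and summarize one scenario (pure in the seed)."""
    cohort = simulate_cohort(config)
    classes = classify_cohort(
        cohort,
        config.composite_members,
        config.seed,
        exact_half_split=config.exact_half_split,
    )
    return summarize(config, cohort, classes, welch=welch)


def summarize(
    config: ScenarioConfig,
    cohort: pd.DataFrame,
    classes: pd.DataFrame,
    welch: bool = False,
) -> ExperimentSummary:
    """Compute every summary statistic from already-materialized tables."""
    comparisons = tuple(
        compare_schemes(cohort, classes, config.comparison_singleton, welch=welch)
    )
    warnings = [COMPARISON_CAVEAT]
    if config.placeholder_marginals:
        warnings.append(
            "placeholder marginal parameters in use for: "
            + ", ".join(config.placeholder_marginals)
        )
    if cohort.attrs.get("pd_repaired"):
        warnings.append(
            "copula matrix required PD repair, Frobenius distance "
            f"{cohort.attrs['pd_repair_distance']:.3e}"
        )
    degenerate = [c.shock_class for c in comparisons if c.degenerate]
    if degenerate:
        warnings.append(
            "degenerate comparisons in classes "
            + ", ".join(ROMAN[c] for c in degenerate)
        )
    return ExperimentSummary(
        scenario_id=config.scenario_id,
        n=config.n,
        seed=config.seed,
        comparison_singleton=config.comparison_singleton,
        composite_members=config.composite_members,
        comparisons=comparisons,
        postprocessing_spearman=postprocessing_spearman(cohort),
        joint_class_fraction=joint_class_fraction(classes, ("hr", "sbp", "gcs")),
        joint_class_fraction_with_bd=joint_class_fraction(
            classes, ("hr", "sbp", "gcs", "bd")
        ),
        singleton_stats=group_transfusion_stats(
            cohort, classes, config.comparison_singleton
        ),
        composite_stats=group_transfusion_stats(cohort, classes, "composite"),
        config_echo=_config_echo(config, cohort),
        warnings=tuple(warnings),
    )


def run_all_scenarios(master) -> dict[str, ExperimentSummary | None]:
    """Run the four scenarios of a :class:`~shockbias.config.MasterConfig`.

    One scenario failing does not abort the rest; its slot holds ``None``
    and the failure is re-raised only if every scenario failed.
    """
    from .correlation import SCENARIOS

    out: dict[str, ExperimentSummary | None] = {}
    first_error: Exception | None = None
    for scenario_id in SCENARIOS:
        try:
            out[scenario_id] = run_scenario(master.scenario(scenario_id),
                                            welch=master.welch)
        except Exception as exc:  # noqa: BLE001 - isolate per-scenario failures
            out[scenario_id] = None
            first_error = first_error or exc
    if all(v is None for v in out.values()) and first_error is not None:
        raise first_error
    return out


def _config_echo(config: ScenarioConfig, cohort: pd.DataFrame) -> dict:
    return {
        "scenario_id": config.scenario_id,
        "n": config.n,
        "seed": config.seed,
        "truncation": config.truncation,
        "exact_half_split": config.exact_half_split,
        "composite_members": list(config.composite_members),
        "comparison_singleton": config.comparison_singleton,
        "marginals": {
            name: {
                "family": spec.family,
                "location": spec.location,
                "scale": spec.scale,
                "lower_bound": spec.lower_bound,
                "upper_bound": spec.upper_bound,
                "round_to_integer": spec.round_to_integer,
                "placeholder": spec.placeholder,
                "mixture": (
                    [[c.weight, c.mode, c.spread] for c in spec.mixture]
                    if spec.mixture
                    else None
                ),
            }
            for name, spec in config.marginals.items()
        },
        "correlation": {
            "magnitudes": config.correlation.magnitudes.tolist(),
            "signs": config.correlation.signs.tolist(),
        },
        "pd_repaired": bool(cohort.attrs.get("pd_repaired", False)),
        "pd_repair_distance": float(cohort.attrs.get("pd_repair_distance", 0.0)),
    }
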