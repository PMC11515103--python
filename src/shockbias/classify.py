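"""Shock classification: per-parameter classes I-IV and the max composite.

Thresholds follow the published numeric interpretation of the ATLS
classes, with overlapping printed endpoints resolved per boundary and
centralized in :data:`DEFAULT_THRESHOLDS`:

* hr:  <100 -> I, [100,120] -> II, (120,140] -> III, >140 -> IV
  (class I is "<100" strictly, class IV is ">140" strictly, so 100 goes
  up while 120 and 140 resolve down)
* sbp: >=110 -> I, [100,110) -> II, [90,100) -> III, <90 -> IV
* bd:  <=2 -> I, (2,6] -> II, (6,10] -> III, >10 -> IV
* gcs: 15 -> I or II (random 50/50 split), 12-14 -> III, <12 -> IV

Classes are carried as plain integers 1..4; only ``max`` arithmetic is
meaningful on them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import spawn_streams
from .errors import ConfigError, DomainError, StructuralError

ROMAN = {1: "I", 2: "II", 3: "III", 4: "IV"}
ROMAN_TO_INT = {v: k for k, v in ROMAN.items()}

#: Generous physiologic ranges; values outside are treated as data errors.
PHYSIOLOGIC_RANGE = {
    "hr": (0.0, 220.0),
    "sbp": (0.0, 300.0),
    "bd": (-50.0, 50.0),
}


@dataclass(frozen=True)
class ThresholdTable:
    """Interval-to-class mapping for hr, sbp and bd.

    ``edges`` are the three interior breakpoints per parameter in
    ascending value order; ``right_closed`` selects, per breakpoint,
    whether a value sitting exactly on it belongs to the lower interval;
    ``ascending`` is False when class severity decreases with the value
    (sbp).
    """

    edges: dict[str, tuple[float, float, float]]
    right_closed: dict[str, tuple[bool, bool, bool]]
    ascending: dict[str, bool]

    def classify(self, parameter: str, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        lo, hi = PHYSIOLOGIC_RANGE[parameter]
        if np.any(values < lo) or np.any(values > hi):
            raise DomainError(
                f"{parameter} value outside physiologic range [{lo}, {hi}]"
            )
        idx = np.zeros(values.shape, dtype=int)
        for edge, rc in zip(self.edges[parameter],
                            self.right_closed[parameter]):
            idx += (values > edge) if rc else (values >= edge)
        return (1 + idx) if self.ascending[parameter] else (4 - idx)


DEFAULT_THRESHOLDS = ThresholdTable(
    edges={
        "hr": (100.0, 120.0, 140.0),
        "sbp": (90.0, 100.0, 110.0),
        "bd": (2.0, 6.0, 10.0),
    },
    right_closed={
        "hr": (False, True, True),
        "sbp": (False, False, False),
        "bd": (True, True, True),
    },
    ascending={"hr": True, "sbp": False, "bd": True},
)


def classify_value(parameter: str, value: float,
                   thresholds: ThresholdTable = DEFAULT_THRESHOLDS) -> int:
    """Shock class I..IV (as 1..4) of a single hr, sbp or bd value."""
    if parameter not in PHYSIOLOGIC_RANGE:
        raise ConfigError(
            f"classify_value handles {tuple(PHYSIOLOGIC_RANGE)}, got "
            f"{parameter!r} (gcs is classified separately)"
        )
    return int(thresholds.classify(parameter, np.asarray([value]))[0])


def classify_gcs(value: int, split_draw: float) -> int:
    """Shock class of a GCS value; GCS 15 splits I/II on ``split_draw``."""
    if not float(value).is_integer() or not 3 <= value <= 15:
        raise DomainError(f"gcs must be an integer in [3, 15], got {value}")
    if not 0.0 < split_draw < 1.0:
        raise DomainError("split_draw must lie in (0, 1)")
    value = int(value)
    if value < 12:
        return 4
    if value <= 14:
        return 3
    return 1 if split_draw < 0.5 else 2


def composite_class(classes) -> int:
    """Highest-class composite: the maximum of the member classes."""
    classes = list(classes)
    if not classes:
        raise StructuralError("composite_class requires a nonempty class list")
    if any(c not in (1, 2, 3, 4) for c in classes):
        raise DomainError("shock classes must be integers 1..4")
    return max(classes)


def _gcs_classes(gcs: np.ndarray, draws: np.ndarray,
                 exact_half: bool, rng: np.random.Generator) -> np.ndarray:
    out = np.full(gcs.size, 4, dtype=int)
    out[(gcs >= 12) & (gcs <= 14)] = 3
    at15 = gcs == 15
    if exact_half:
        # Seeded permutation split: exactly floor(k/2) of the GCS-15 rows
        # go to class I.
        idx = np.flatnonzero(at15)
        perm = rng.permutation(idx.size)
        cls15 = np.where(perm < idx.size // 2, 1, 2)
        out[idx] = cls15
    else:
        out[at15] = np.where(draws[at15] < 0.5, 1, 2)
    return out


def classify_cohort(
    cohort: pd.DataFrame,
    composite_members: tuple[str, ...],
    seed: int,
    thresholds: ThresholdTable = DEFAULT_THRESHOLDS,
    exact_half_split: bool = False,
) -> pd.DataFrame:
    """Classify every patient and build the composite column.

    The GCS-15 split draws come from substream 1 of the master seed (the
    copula consumed substream 0), so the same seed yields the same split
    regardless of how the cohort was produced.
    """
    members = tuple(composite_members)
    if not members or any(m not in ("hr", "sbp", "gcs", "bd") for m in members):
        raise ConfigError(f"invalid composite members {members}")
    missing = [c for c in ("hr", "sbp", "gcs", "bd") if c not in cohort.columns]
    if missing:
        raise StructuralError(f"cohort table lacks columns {missing}")

    _, split_rng = spawn_streams(seed)
    gcs = cohort["gcs"].to_numpy()
    if np.any(gcs != np.round(gcs)) or gcs.min() < 3 or gcs.max() > 15:
        raise DomainError("gcs column must be integral in [3, 15]")
    draws = split_rng.uniform(size=len(cohort))

    table = pd.DataFrame(
        {
            "hr_class": thresholds.classify("hr", cohort["hr"].to_numpy()),
            "sbp_class": thresholds.classify("sbp", cohort["sbp"].to_numpy()),
            "gcs_class": _gcs_classes(gcs.astype(int), draws,
                                      exact_half_split, split_rng),
            "bd_class": thresholds.classify("bd", cohort["bd"].to_numpy()),
        },
        index=cohort.index,
    )
    table["composite_class"] = (
        table[[f"{m}_class" for m in members]].max(axis=1).astype(int)
    )
    table.attrs.update(
        composite_members=members,
        seed=seed,
        exact_half_split=exact_half_split,
    )
    return table
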