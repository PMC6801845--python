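"""Factorial design of the clinostat experiment.

Ten conditions: gravity in {ST (standing 1G), RO (rotating, simulated
microgravity)} crossed with radiation in {none, X-ray, carbon ion} and, for
irradiated samples, harvest time in {3 h, 24 h} after a 1 Gy exposure.
Condition labels concatenate the factor levels (``ST``, ``RO-C24``, ...).
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

GRAVITY_LEVELS = ("ST", "RO")
RADIATION_LEVELS = ("none", "X", "C")
TIME_LEVELS = (3, 24)

#: Fixed condition order used by all tabular outputs (standing block first).
CONDITION_ORDER = (
    "ST", "ST-X3", "ST-X24", "ST-C3", "ST-C24",
    "RO", "RO-X3", "RO-X24", "RO-C3", "RO-C24",
)

IRRADIATED_CONDITIONS = tuple(c for c in CONDITION_ORDER if "-" in c)

#: Irradiation arm labels pairing a standing and a rotating condition
#: (e.g. "X3" pairs ST-X3 with RO-X3).
IRRADIATION_ARMS = ("X3", "X24", "C3", "C24")

#: Default replicate structure: non-irradiated N=6, irradiated N=3 (36 total).
DEFAULT_REPLICATES: dict[str, int] = {
    c: (6 if c in ("ST", "RO") else 3) for c in CONDITION_ORDER
}


def condition_label(gravity: str, radiation: str, time: int | None) -> str:
    """Build the condition label from factor levels.

    ``radiation == "none"`` requires ``time`` to be None and vice versa.
    """
    if gravity not in GRAVITY_LEVELS:
        raise ValueError(f"unknown gravity level {gravity!r}")
    if radiation == "none":
        if time is not None:
            raise ValueError("non-irradiated samples carry no time point")
        return gravity
    if radiation not in RADIATION_LEVELS:
        raise ValueError(f"unknown radiation level {radiation!r}")
    if time not in TIME_LEVELS:
        raise ValueError(f"unknown time point {time!r}")
    return f"{gravity}-{radiation}{time}"


def parse_condition(label: str) -> tuple[str, str, int | None]:
    """Inverse of :func:`condition_label`."""
    if label in GRAVITY_LEVELS:
        return label, "none", None
    try:
        gravity, rt = label.split("-")
        radiation, time = rt[0], int(rt[1:])
    except (ValueError, IndexError) as exc:
        raise ValueError(f"malformed condition label {label!r}") from exc
    if gravity not in GRAVITY_LEVELS or radiation not in ("X", "C") or time not in TIME_LEVELS:
        raise ValueError(f"malformed condition label {label!r}")
    return gravity, radiation, time


def build_design(replicates: Mapping[str, int] | None = None) -> pd.DataFrame:
    """Expand a condition -> replicate-count map into a per-sample table.

    Returns a DataFrame with columns ``sample_id``, ``gravity``,
    ``radiation``, ``time`` (nullable integer), ``replicate``,
    ``condition``; one row per sample, conditions in :data:`CONDITION_ORDER`.
    """
    replicates = dict(DEFAULT_REPLICATES if replicates is None else replicates)
    unknown = set(replicates) - set(CONDITION_ORDER)
    if unknown:
        raise ValueError(f"unknown conditions in replicate map: {sorted(unknown)}")
    missing = set(CONDITION_ORDER) - set(replicates)
    if missing:
        raise ValueError(f"replicate map missing conditions: {sorted(missing)}")
    rows = []
    for cond in CONDITION_ORDER:
        n = int(replicates[cond])
        if n < 1:
            raise ValueError(f"replicate count for {cond} must be >= 1")
        gravity, radiation, time = parse_condition(cond)
        for r in range(1, n + 1):
            rows.append(
                {
                    "sample_id": f"{cond}_r{r}",
                    "gravity": gravity,
                    "radiation": radiation,
                    "time": time,
                    "replicate": r,
                    "condition": cond,
                }
            )
    df = pd.DataFrame(rows)
    df["time"] = df["time"].astype("Int64")
    return df


def condition_samples(design: pd.DataFrame, condition: str) -> list[str]:
    """Sample ids belonging to one condition, in design order."""
    return design.loc[design["condition"] == condition, "sample_id"].tolist()


def validate_design(design: pd.DataFrame) -> None:
    """Check structural invariants of a design table."""
    required = {"sample_id", "gravity", "radiation", "time", "replicate", "condition"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    if design["sample_id"].duplicated().any():
        dup = design.loc[design["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample id {dup!r}")
    for row in design.itertuples(index=False):
        time = None if pd.isna(row.time) else int(row.time)
        expected = condition_label(row.gravity, row.radiation, time)
        if row.condition != expected:
            raise ValueError(
                f"sample {row.sample_id}: condition {row.condition!r} does not "
                f"match factor levels (expected {expected!r})"
            )
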