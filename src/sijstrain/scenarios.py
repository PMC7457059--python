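"""The eight-scenario load battery and ligament-group strain averaging.

The battery applies eight in-plane dead loads at the sacral load point:
+-200 N along each axis and the four diagonals at +-141.4 N per component
(200 * cos 45 deg, rounded to one decimal, stored exactly as printed so the
table is bit-stable).  Per-spring strains from each equilibrium solve are
averaged within each named ligament group on each side, producing the
8 scenarios x 3 ligament groups x 2 sides = 48-cell grid used by the
repeatability study.  The sacroiliac-joint springs are computed and
exported with every battery but are excluded from the named-ligament grid
by default (they are not one of the reported ligament groups); a flag adds
them as a fourth group.
"""

from __future__ import annotations

import pandas as pd

from .assembly import Model
from .solver import EquilibriumResult, LoadScenario, SolverOptions, solve_static

__all__ = [
    "DEFAULT_SCENARIO_FORCES",
    "GRID_GROUPS",
    "default_scenarios",
    "run_battery",
    "battery_to_frame",
    "average_by_group",
]

#: (fx, fy) rows of the standard battery, N, in scenario order 1..8.
DEFAULT_SCENARIO_FORCES = (
    (0.0, 200.0),
    (0.0, -200.0),
    (200.0, 0.0),
    (-200.0, 0.0),
    (141.4, 141.4),
    (-141.4, -141.4),
    (141.4, -141.4),
    (-141.4, 141.4),
)

#: Ligament groups reported in the averaged strain grid.
GRID_GROUPS = ("dorsal_si", "sacrotuberous", "ventral_si")


def default_scenarios() -> tuple[LoadScenario, ...]:
    """The standard eight-scenario battery (ids 1..8)."""
    return tuple(
        LoadScenario(id=i + 1, fx=fx, fy=fy)
        for i, (fx, fy) in enumerate(DEFAULT_SCENARIO_FORCES)
    )


def run_battery(
    model: Model,
    scenarios: tuple[LoadScenario, ...] | None = None,
    opts: SolverOptions | None = None,
) -> list[EquilibriumResult]:
    """Solve every scenario; a non-converged solve is kept (flagged), not dropped."""
    scenarios = scenarios or default_scenarios()
    results = []
    for sc in scenarios:
        try:
            results.append(solve_static(model, sc, opts))
        except Exception as exc:
            raise RuntimeError(f"scenario {sc.id} failed: {exc}") from exc
    return results


def battery_to_frame(model: Model, results: list[EquilibriumResult]) -> pd.DataFrame:
    """Long-format per-spring records: scenario, spring, group, side, strain, force."""
    rows = []
    for res in results:
        for s in model.springs:
            rows.append(
                {
                    "scenario": res.scenario.id,
                    "spring": s.name,
                    "group": s.group,
                    "side": s.side,
                    "strain": res.spring_strain[s.name],
                    "force": res.spring_force[s.name],
                    "converged": res.converged,
                }
            )
    return pd.DataFrame(rows)


def average_by_group(
    records: pd.DataFrame, include_sij: bool = False
) -> pd.DataFrame:
    """Arithmetic mean strain per (scenario, group, side) cell.

    Returns the 48-cell grid (or 64 cells with ``include_sij=True``),
    sorted by scenario, then group, then side.
    """
    groups = GRID_GROUPS + ("sij",) if include_sij else GRID_GROUPS
    sub = records[records["group"].isin(groups)]
    missing = []
    for sc in sorted(records["scenario"].unique()):
        for g in groups:
            for side in ("L", "R"):
                mask = (
                    (sub["scenario"] == sc) & (sub["group"] == g) & (sub["side"] == side)
                )
                if not mask.any():
                    missing.append((sc, g, side))
    if missing:
        raise ValueError(f"missing strain records for cells: {missing[:5]}")
    out = (
        sub.groupby(["scenario", "group", "side"], as_index=False)["strain"]
        .mean()
        .rename(columns={"strain": "mean_strain"})
    )
    out["group"] = pd.Categorical(out["group"], categories=groups, ordered=True)
    return out.sort_values(["scenario", "group", "side"], ignore_index=True)
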