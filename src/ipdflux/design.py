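"""Experimental layout: T-FACE response-surface facility and sampled subset.

The facility crosses three warming levels (ambient, +1.5, +3.0 °C) with
three CO2 levels (ambient, +150, +300 ppm) in a response-surface layout that
realizes seven of the nine combinations over 54 plots; 34 plots are sampled.
A summer drought treatment is applied to four ambient plots and three
"future scenario" (+3.0 °C, +300 ppm) plots.

Per-combination replicate numbers are a reconstruction consistent with the
printed totals (54 facility plots, 34 sampled, per-combination n within 2–8,
4+3 drought plots); they are configurable, not ground truth.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

TEMP_LEVELS = (0.0, 1.5, 3.0)   # °C above ambient
CO2_LEVELS = (0.0, 150.0, 300.0)  # ppm above ambient

#: the two unrealized combinations: anti-diagonal corners of the 3×3 grid,
#: consistent with a response-surface design that keeps the ambient and
#: "future scenario" corners (both needed for the drought experiment).
DEFAULT_EXCLUDED: frozenset[tuple[float, float]] = frozenset(
    {(0.0, 300.0), (3.0, 0.0)}
)

#: facility plots per admissible (temp, co2) combination; sums to 54.
DEFAULT_FACILITY_ALLOCATION: dict[tuple[float, float], int] = {
    (0.0, 0.0): 10,
    (0.0, 150.0): 7,
    (1.5, 0.0): 7,
    (1.5, 150.0): 8,
    (1.5, 300.0): 7,
    (3.0, 150.0): 7,
    (3.0, 300.0): 8,
}

#: sampled plots per combination; sums to 34, every n within [2, 8].
DEFAULT_SAMPLED_ALLOCATION: dict[tuple[float, float], int] = {
    (0.0, 0.0): 8,
    (0.0, 150.0): 4,
    (1.5, 0.0): 4,
    (1.5, 150.0): 4,
    (1.5, 300.0): 4,
    (3.0, 150.0): 4,
    (3.0, 300.0): 6,
}

#: drought plots per scenario: (ambient, ambient) and (+3.0, +300).
DROUGHT_ALLOCATION: dict[tuple[float, float], int] = {
    (0.0, 0.0): 4,
    (3.0, 300.0): 3,
}

SEASONS = ("May", "Jul", "Oct")

DESIGN_COLUMNS = ["plot_id", "temp_level", "co2_level", "sampled", "drought"]


def admissible_combinations(
    excluded: frozenset[tuple[float, float]] = DEFAULT_EXCLUDED,
) -> list[tuple[float, float]]:
    return [
        (t, c)
        for t in TEMP_LEVELS
        for c in CO2_LEVELS
        if (t, c) not in excluded
    ]


def generate_facility(
    replicate_allocation: dict[tuple[float, float], int] | None = None,
    seed: int = 0,
    excluded: frozenset[tuple[float, float]] = DEFAULT_EXCLUDED,
) -> pd.DataFrame:
    """Generate the full 54-plot facility layout.

    Plot ids are assigned to treatment combinations in a seeded random order
    (emulating field randomization); the layout is deterministic given the
    seed.
    """
    allocation = dict(replicate_allocation or DEFAULT_FACILITY_ALLOCATION)
    admissible = set(admissible_combinations(excluded))
    bad = set(allocation) - admissible
    if bad:
        raise ValueError(
            f"allocation covers inadmissible combinations: {sorted(bad)}"
        )
    total = sum(allocation.values())
    if total != 54:
        raise ValueError(f"facility allocation must sum to 54, got {total}")

    combos = [
        combo for combo, n in sorted(allocation.items()) for _ in range(n)
    ]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(combos))
    rows = []
    for plot_idx, combo_idx in enumerate(order, start=1):
        t, c = combos[combo_idx]
        rows.append(
            {
                "plot_id": f"P{plot_idx:02d}",
                "temp_level": t,
                "co2_level": c,
                "sampled": False,
                "drought": False,
            }
        )
    return pd.DataFrame(rows)


def select_sampled(
    facility: pd.DataFrame,
    allocation: dict[tuple[float, float], int] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Mark the sampled subset (default: 34 plots over all 7 combinations)."""
    allocation = dict(allocation or DEFAULT_SAMPLED_ALLOCATION)
    facility = facility.copy()
    facility["sampled"] = False
    rng = np.random.default_rng(seed)
    for (t, c), n in sorted(allocation.items()):
        idx = facility.index[
            (facility.temp_level == t) & (facility.co2_level == c)
        ]
        if len(idx) < n:
            raise ValueError(
                f"cannot sample {n} plots from combination ({t}, {c}): "
                f"only {len(idx)} in facility"
            )
        chosen = rng.choice(idx, size=n, replace=False)
        facility.loc[chosen, "sampled"] = True
    return facility


def assign_drought(sampled: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Flag the drought plots: 4 ambient/ambient and 3 (+3.0, +300)."""
    out = sampled.copy()
    out["drought"] = False
    rng = np.random.default_rng(seed)
    for (t, c), n in sorted(DROUGHT_ALLOCATION.items()):
        idx = out.index[
            out.sampled & (out.temp_level == t) & (out.co2_level == c)
        ]
        if len(idx) < n:
            raise ValueError(
                f"need {n} sampled plots at ({t}, {c}) for drought, "
                f"have {len(idx)}"
            )
        chosen = rng.choice(idx, size=n, replace=False)
        out.loc[chosen, "drought"] = True
    return out


def generate_design(seed: int = 0) -> pd.DataFrame:
    """Full default design: facility -> sampled subset -> drought flags."""
    facility = generate_facility(seed=seed)
    sampled = select_sampled(facility, seed=seed + 1)
    return assign_drought(sampled, seed=seed + 2)


def sampled_design(seed: int = 0) -> pd.DataFrame:
    """The 34 sampled plots only, sorted by plot id."""
    full = generate_design(seed=seed)
    return (
        full[full.sampled].sort_values("plot_id").reset_index(drop=True)
    )


def read_design(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"design table {path} missing columns: {missing}")
    return df


def write_design(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
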