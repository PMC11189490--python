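"""Dentate-gyrus zone assignment and location-shift statistics.

The granule-cell layer (GCL) of the dentate gyrus is 4-8 nuclei thick.
Working in a 1-D coordinate of signed nucleus-width offsets d from the
GCL/hilus boundary (positive toward the molecular layer), the strata are:

    Hilus   d < -2
    SGZ     -2 <= d < 0      (two-nucleus-wide band below the GCL)
    GL1     0 <= d < T - 3   (inner granule-cell layer)
    GL2     T - 3 <= d < T   (three-nucleus-wide band below the molecular layer)
    ML      d >= T

with T the local GCL thickness.  Bands are left-closed/right-open so every
finite offset maps to exactly one zone.  Per-animal zone percentages per
population are compared between conditions with a two-tailed unpaired
(pooled-variance) t-test; Welch's correction is available behind a flag.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

ZONES: tuple[str, ...] = ("Hilus", "SGZ", "GL1", "GL2", "ML")
GL_AGGREGATE = "GL1+2"


def assign_zone(cells: pd.DataFrame) -> pd.DataFrame:
    """Assign each cell a zone from its signed offset and local GCL thickness.

    Requires columns ``signed_offset`` and ``gcl_thickness``; thickness
    below 4 nucleus widths is rejected (the GCL is 4-8 nuclei thick).
    Returns a copy with a ``zone`` column.
    """
    d = cells["signed_offset"].to_numpy(dtype=float)
    T = cells["gcl_thickness"].to_numpy(dtype=float)
    if not np.isfinite(d).all():
        raise ValueError("signed_offset must be finite")
    if (T < 4).any():
        raise ValueError("gcl_thickness must be >= 4 nucleus widths")
    zone = np.empty(d.size, dtype=object)
    zone[d < -2] = "Hilus"
    zone[(d >= -2) & (d < 0)] = "SGZ"
    zone[(d >= 0) & (d < T - 3)] = "GL1"
    zone[(d >= T - 3) & (d < T)] = "GL2"
    zone[d >= T] = "ML"
    out = cells.copy()
    out["zone"] = zone
    return out


def zone_composition(assignment: pd.DataFrame) -> pd.DataFrame:
    """Per (animal, population): percentage of cells in each zone.

    Zones absent for an (animal, population) get 0%, so percentages over
    the five zones sum to 100; a pooled granule-layer row ("GL1+2",
    GL1 + GL2) is reported alongside and excluded from that partition.
    (animal, population) combinations with no cells simply yield no rows.
    Carries the condition label through.
    """
    req = {"animal", "population", "condition", "zone"}
    missing = req - set(assignment.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    counts = (
        assignment.groupby(["condition", "animal", "population", "zone"], sort=True)
        .size()
        .rename("n")
        .reset_index()
    )
    full = (
        counts.pivot_table(
            index=["condition", "animal", "population"],
            columns="zone",
            values="n",
            fill_value=0,
        )
        .reindex(columns=list(ZONES), fill_value=0)
    )
    totals = full.sum(axis=1)
    pct = full.div(totals, axis=0) * 100.0
    pct[GL_AGGREGATE] = pct["GL1"] + pct["GL2"]
    out = (
        pct.reset_index()
        .melt(
            id_vars=["condition", "animal", "population"],
            var_name="zone",
            value_name="percent",
        )
        .sort_values(["population", "animal", "zone"], kind="stable")
        .reset_index(drop=True)
    )
    return out


def t_test_unpaired(
    x: np.ndarray, y: np.ndarray, welch: bool = False
) -> tuple[float, float]:
    """Two-tailed unpaired t-test (pooled variance; Welch behind the flag).

    Degenerate zero-variance inputs: equal means give (0, 1); unequal means
    give p = 0 with a logged warning (an infinite t is reported as +/-inf).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 observations per group")
    if np.var(x) == 0 and np.var(y) == 0:
        if np.mean(x) == np.mean(y):
            return 0.0, 1.0
        logger.warning("zero pooled variance with unequal means: degenerate t-test")
        return float(np.sign(np.mean(x) - np.mean(y)) * np.inf), 0.0
    t, p = stats.ttest_ind(x, y, equal_var=not welch)
    return float(t), float(p)


def compare_locations(
    composition: pd.DataFrame,
    conditions: tuple[str, str] = ("Control", "TBI"),
    min_animals: int = 2,
    welch: bool = False,
) -> pd.DataFrame:
    """Condition comparison of per-animal zone percentages.

    For each (population, zone) — the pooled "GL1+2" row included — the
    per-animal percentages of the two conditions are compared with a
    two-tailed unpaired t-test.  Pairs with fewer than ``min_animals``
    animals in either condition are skipped with a log entry.  Output
    columns include per-condition means and SEMs.
    """
    ca, cb = conditions
    rows = []
    for (pop, zone), grp in composition.groupby(["population", "zone"], sort=True):
        xa = grp.loc[grp["condition"] == ca, "percent"].to_numpy()
        xb = grp.loc[grp["condition"] == cb, "percent"].to_numpy()
        if xa.size < min_animals or xb.size < min_animals:
            logger.warning(
                "skipping %s / %s: <%d animals in a condition (%d vs %d)",
                pop, zone, min_animals, xa.size, xb.size,
            )
            continue
        t, p = t_test_unpaired(xa, xb, welch=welch)
        rows.append(
            {
                "population": pop,
                "zone": zone,
                f"n_{ca}": xa.size,
                f"n_{cb}": xb.size,
                f"mean_{ca}": float(xa.mean()),
                f"sem_{ca}": float(stats.sem(xa)),
                f"mean_{cb}": float(xb.mean()),
                f"sem_{cb}": float(stats.sem(xb)),
                "t_statistic": t,
                "p_value": p,
                "direction": (
                    "up" if xb.mean() > xa.mean()
                    else ("down" if xb.mean() < xa.mean() else "none")
                ),
            }
        )
    return pd.DataFrame(rows)
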