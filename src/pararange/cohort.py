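"""Per-animal infection rates and GFP+/GFP− cell-area comparisons.

The non-cell-autonomous effect shows up as area reduction in cells that
were never transduced (GFP−) in treated animals.  This module summarises
cell tables per animal (the animal, not the cell, is the replication unit
for infection rates) and compares group area distributions with Welch's
unequal-variance t test plus Cohen's d.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnimalSummary",
    "GroupComparison",
    "summarize_animals",
    "group_infection_rate",
    "compare_groups",
    "non_cell_autonomy_index",
]


@dataclass(frozen=True)
class AnimalSummary:
    animal_id: str
    arm: str
    n_cells: int
    infected_fraction: float
    mean_area: float
    sd_area: float

    def to_dict(self) -> dict:
        return {
            "animal_id": self.animal_id,
            "arm": self.arm,
            "n_cells": self.n_cells,
            "infected_fraction": self.infected_fraction,
            "mean_area": self.mean_area,
            "sd_area": self.sd_area,
        }


@dataclass(frozen=True)
class GroupComparison:
    group_a: str
    group_b: str
    mean_diff: float      # mean(a) - mean(b), μm²
    welch_t: float
    df: float             # Welch–Satterthwaite
    p_value: float        # two-sided
    cohens_d: float       # pooled-SD standardised difference

    def to_dict(self) -> dict:
        return {
            "group_a": self.group_a,
            "group_b": self.group_b,
            "mean_diff": self.mean_diff,
            "welch_t": self.welch_t,
            "df": self.df,
            "p_value": self.p_value,
            "cohens_d": self.cohens_d,
        }


def summarize_animals(cells: pd.DataFrame) -> list[AnimalSummary]:
    """One summary per animal: cell count, GFP+ fraction, area mean ± SD.

    Row order does not matter; summaries are sorted by (arm, animal_id).
    """
    if cells is None or len(cells) == 0:
        raise ValueError("empty cell table")
    required = {"animal_id", "arm", "gfp_positive", "area_um2"}
    missing = required - set(cells.columns)
    if missing:
        raise ValueError(f"cell table lacks columns: {sorted(missing)}")
    out = []
    grouped = cells.groupby(["arm", "animal_id"], sort=True)
    for (arm, animal), sub in grouped:
        areas = sub["area_um2"].to_numpy(dtype=float)
        out.append(
            AnimalSummary(
                animal_id=str(animal),
                arm=str(arm),
                n_cells=len(sub),
                infected_fraction=float(sub["gfp_positive"].mean()),
                mean_area=float(areas.mean()),
                sd_area=float(areas.std(ddof=1)) if len(areas) > 1 else 0.0,
            )
        )
    return out


def group_infection_rate(summaries: list[AnimalSummary], arm: str) -> dict:
    """Mean ± SD of per-animal GFP+ fractions within one arm."""
    fr = np.array([s.infected_fraction for s in summaries if s.arm == arm])
    if fr.size == 0:
        raise ValueError(f"no animals in arm {arm!r}")
    return {
        "arm": arm,
        "n_animals": int(fr.size),
        "mean_fraction": float(fr.mean()),
        "sd_fraction": float(fr.std(ddof=1)) if fr.size > 1 else 0.0,
    }


def compare_groups(
    areas_a, areas_b, label_a: str = "a", label_b: str = "b"
) -> GroupComparison:
    """Welch's unequal-variance t test between two area samples.

    Two-sided p with Welch–Satterthwaite degrees of freedom; Cohen's d uses
    the pooled SD.  Identical degenerate samples (zero variance in both
    groups, equal means) report t = 0, p = 1.
    """
    a = np.asarray(areas_a, dtype=float)
    b = np.asarray(areas_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    mean_diff = float(a.mean() - b.mean())
    if va == 0.0 and vb == 0.0:
        t_stat = 0.0 if mean_diff == 0.0 else np.inf * np.sign(mean_diff)
        df = float(na + nb - 2)
        p = 1.0 if mean_diff == 0.0 else 0.0
    else:
        res = stats.ttest_ind(a, b, equal_var=False)
        t_stat = float(res.statistic)
        p = float(res.pvalue)
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
    pooled = math.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    d = mean_diff / pooled if pooled > 0 else 0.0
    return GroupComparison(
        group_a=label_a,
        group_b=label_b,
        mean_diff=mean_diff,
        welch_t=t_stat,
        df=float(df),
        p_value=p,
        cohens_d=float(d),
    )


def non_cell_autonomy_index(gfp_neg_treated, gfp_neg_control) -> float:
    """Scalar attenuation summary: 1 − mean(treated GFP−)/mean(control GFP−).

    Positive values indicate non-cell-autonomous attenuation (untransduced
    cells in treated animals are smaller than in control animals); scale
    invariant under joint rescaling of both groups.
    """
    a = np.asarray(gfp_neg_treated, dtype=float)
    b = np.asarray(gfp_neg_control, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    mb = b.mean()
    if mb == 0.0:
        raise ValueError("control mean is zero")
    return float(1.0 - a.mean() / mb)
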