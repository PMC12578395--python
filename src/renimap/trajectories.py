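"""Six-axis principal immune-cell profiles and trajectory classification.

Each biopsy is summarized by the densities (cells/mm^2) of six principal
immune populations — total CD8+ T, total CD4+ T, CD163- macrophages, CD163+
macrophages, and HLA-II+/- inflammatory monocytes — drawn as radar-diagram
axes.  An axis is "predominant" when its density exceeds a fold multiple
(default 2) of every other axis above a density floor; the resulting
predominant set yields a categorical inflammation trajectory per biopsy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from renimap.errors import ConfigError

AXES = (
    "CD8 T",
    "CD4 T",
    "CD163- macrophage",
    "CD163+ macrophage",
    "HLAII+ inflammatory monocyte",
    "HLAII- inflammatory monocyte",
)

ADAPTIVE_AXES = ("CD8 T", "CD4 T")

# Which gating-tree leaf classes feed each axis.
DEFAULT_CLASS_MAP: dict[str, tuple[str, ...]] = {
    "CD8 T": ("CD8 T cell", "CD8 Treg"),
    "CD4 T": ("CD4 T cell", "CD4 Treg"),
    "CD163- macrophage": ("CD14+MerTK+ macrophage", "CD14+ macrophage",
                          "CD45- MerTK+ macrophage", "CD45- CD14+ macrophage"),
    "CD163+ macrophage": ("CD14+CD163+MerTK+ macrophage", "CD14+CD163+ macrophage",
                          "CD45- CD163+MerTK+ macrophage", "CD45- CD163+ macrophage"),
    "HLAII+ inflammatory monocyte": ("HLAII+ inflammatory monocyte",),
    "HLAII- inflammatory monocyte": ("HLAII- inflammatory monocyte",),
}

__all__ = [
    "AXES",
    "ADAPTIVE_AXES",
    "DEFAULT_CLASS_MAP",
    "TrajectoryLabel",
    "principal_profile",
    "profile_from_densities",
    "classify_trajectory",
    "cohort_average_profile",
]


def principal_profile(
    cells: pd.DataFrame,
    tissue_area_mm2: float,
    class_map: dict[str, tuple[str, ...]] | None = None,
) -> pd.Series:
    """Six-axis density profile of one biopsy from its annotated cell table."""
    if tissue_area_mm2 <= 0:
        raise ConfigError("tissue area must be positive")
    class_map = class_map or DEFAULT_CLASS_MAP
    missing = set(AXES) - set(class_map)
    if missing:
        raise ConfigError(f"class_map missing axes: {sorted(missing)}")
    counts = cells["class_label"].value_counts()
    vals = [sum(counts.get(c, 0) for c in class_map[a]) / tissue_area_mm2 for a in AXES]
    return pd.Series(vals, index=list(AXES), name="density")


def profile_from_densities(densities: pd.Series | dict,
                           class_map: dict[str, tuple[str, ...]] | None = None) -> pd.Series:
    """Six-axis profile from a per-class density vector (cells/mm^2)."""
    class_map = class_map or DEFAULT_CLASS_MAP
    d = pd.Series(densities, dtype=float)
    vals = [float(sum(d.get(c, 0.0) for c in class_map[a])) for a in AXES]
    return pd.Series(vals, index=list(AXES), name="density")


@dataclass
class TrajectoryLabel:
    """Predominant axes plus a categorical summary for one biopsy."""

    predominant: tuple[str, ...]
    summary: str  # low-inflammation | single-predominant | dual-predominant | multi-lineage
    adaptive_involved: bool
    fold: float = 2.0
    floor: float = 5.0


# In pairwise mode each axis is compared only against its lineage partner
# (CD163+ vs CD163- macrophages, HLA-II+ vs HLA-II- monocytes, CD8 vs CD4).
PAIRWISE_PARTNER = {
    "CD163+ macrophage": "CD163- macrophage",
    "CD163- macrophage": "CD163+ macrophage",
    "HLAII+ inflammatory monocyte": "HLAII- inflammatory monocyte",
    "HLAII- inflammatory monocyte": "HLAII+ inflammatory monocyte",
    "CD8 T": "CD4 T",
    "CD4 T": "CD8 T",
}


def classify_trajectory(profile: pd.Series, fold: float = 2.0,
                        floor: float = 5.0, mode: str = "all") -> TrajectoryLabel:
    """Rule-based trajectory classification of a six-axis profile.

    Axes below the density floor (default 5 cells/mm^2) are excluded from
    the comparison.  In the default ``mode="all"`` an axis is predominant
    iff it is above the floor and more than ``fold`` times every other
    above-floor axis; ``mode="pairwise"`` compares each axis only against
    its lineage partner.  All axes below the floor gives the
    "low-inflammation" label (the normal-kidney pattern).  The summary
    additionally distinguishes dual co-dominance (two axes within a fold of
    the top that jointly exceed fold times every other above-floor axis)
    from diffuse multi-lineage inflammation, and records whether adaptive
    (T cell) axes are above the floor.
    """
    p = profile.reindex(list(AXES))
    if p.isna().any():
        raise ConfigError("profile missing one of the six axes")
    above = p[p >= floor]
    if above.empty:
        return TrajectoryLabel((), "low-inflammation", False, fold, floor)
    if mode == "pairwise":
        predominant = tuple(
            a for a in above.index
            if above[a] > fold * p.get(PAIRWISE_PARTNER[a], 0.0)
        )
    elif mode == "all":
        predominant = tuple(
            a for a in above.index
            if all(above[a] > fold * above[b] for b in above.index if b != a)
        )
    else:
        raise ConfigError(f"unknown predominance mode {mode!r}")
    adaptive = any(a in above.index for a in ADAPTIVE_AXES)
    if len(predominant) == 1 and mode == "all":
        summary = "single-predominant"
    elif len(predominant) >= 1 and mode == "pairwise":
        summary = "single-predominant" if len(predominant) == 1 else "dual-predominant"
    else:
        top = above.max()
        codominant = [a for a in above.index if fold * above[a] > top]
        rest = [b for b in above.index if b not in codominant]
        if len(codominant) == 2 and all(
            above[a] > fold * above[b] for a in codominant for b in rest
        ):
            summary = "dual-predominant"
        else:
            summary = "multi-lineage"
    return TrajectoryLabel(predominant, summary, adaptive, fold, floor)


def cohort_average_profile(profiles: pd.DataFrame, cohorts: pd.Series) -> pd.DataFrame:
    """Arithmetic per-cohort mean of six-axis profiles (rows = cohorts)."""
    cohorts = cohorts.reindex(profiles.index)
    if cohorts.isna().any():
        raise ConfigError("every profile needs a cohort label")
    out = profiles.groupby(cohorts).mean()
    if (profiles.groupby(cohorts).size() < 1).any():
        raise ConfigError("empty cohort")
    return out
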