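"""Cohort-level statistics: densities, contrasts, covariance, damage scores.

Per-biopsy cell tables become class-by-compartment density tables
(cells/mm^2) and whole-biopsy class proportions.  Cohorts are contrasted per
class with two-sided Mann-Whitney U tests under Benjamini-Hochberg control;
covariant immune-cell blocks are read off a Spearman correlation matrix
across biopsies; four scalar damage measures summarize tubulointerstitial
inflammation and scarring per biopsy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps
from skimage.filters import threshold_otsu
from statsmodels.stats.multitest import multipletests

from renimap.compartments import COMPARTMENTS, CompartmentMasks, OFF_TISSUE
from renimap.errors import ConfigError
from renimap.gating import NON_CLASSIFIED
from renimap.stack import ChannelStack

__all__ = [
    "compute_density_table",
    "class_density_matrix",
    "compare_cohorts",
    "spearman_blocks",
    "CorrelationMatrix",
    "damage_scores",
    "ols_fit",
]


def compute_density_table(cells: pd.DataFrame, comps: CompartmentMasks) -> pd.DataFrame:
    """Class-by-compartment densities plus whole-biopsy density/proportion.

    One row per cell class with a ``<compartment>`` column per compartment
    (cells/mm^2), a ``total`` column over the whole tissue, and a
    ``proportion`` column over classified cells only.  Zero-area compartments
    are reported as missing (NaN), not zero.
    """
    if "class_label" not in cells.columns or "compartment" not in cells.columns:
        raise ConfigError("cells need 'class_label' and 'compartment' columns")
    bad = set(cells["compartment"]) - set(COMPARTMENTS) - {OFF_TISSUE}
    if bad:
        raise ConfigError(f"unknown compartment labels: {sorted(bad)}")
    cells = cells[cells["compartment"] != OFF_TISSUE]
    areas = comps.areas_mm2()
    tissue_area = comps.tissue_area_mm2()
    classes = sorted(cells["class_label"].unique())
    counts = cells.groupby(["class_label", "compartment"]).size().unstack(fill_value=0)
    out = pd.DataFrame(index=pd.Index(classes, name="class"))
    for comp in COMPARTMENTS:
        n = counts[comp] if comp in counts.columns else pd.Series(0, index=counts.index)
        n = n.reindex(classes, fill_value=0)
        out[comp] = n / areas[comp] if areas[comp] > 0 else np.nan
    total_counts = cells.groupby("class_label").size().reindex(classes, fill_value=0)
    out["total"] = total_counts / tissue_area
    classified = total_counts.drop(NON_CLASSIFIED, errors="ignore")
    out["proportion"] = np.nan
    if classified.sum() > 0:
        out.loc[classified.index, "proportion"] = classified / classified.sum()
    return out


def class_density_matrix(tables: dict[str, pd.DataFrame], column: str = "total") -> pd.DataFrame:
    """Stack per-biopsy density tables into a biopsy-by-class matrix."""
    rows = {bid: t[column] for bid, t in tables.items()}
    return pd.DataFrame(rows).T.fillna(0.0).rename_axis("biopsy")


def _mwu(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: exact for small tie-free samples, else
    tie-corrected normal approximation (scipy's 'auto' rule)."""
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def compare_cohorts(
    densities: pd.DataFrame,
    cohorts: pd.Series,
    pairs: list[tuple[str, str]] = (("LuN", "KC"), ("RAR", "KC"), ("LuN", "RAR")),
) -> pd.DataFrame:
    """Per-class cohort contrasts with BH correction per cohort pair.

    ``densities`` is a biopsy-by-class matrix; ``cohorts`` maps biopsy id to
    cohort label.  For each pair and class: the U statistic, raw two-sided p,
    BH-adjusted q over the family of classes, and the log2 fold change of
    cohort mean densities with pseudocount eps = (smallest positive density
    in the matrix) / 10.
    """
    cohorts = cohorts.reindex(densities.index)
    for a, b in pairs:
        for c in (a, b):
            if (cohorts == c).sum() == 0:
                raise ConfigError(f"cohort {c!r} absent from the density matrix")
            if (cohorts == c).sum() < 3:
                raise ConfigError(f"cohort {c!r} has fewer than 3 biopsies")
    positive = densities.to_numpy()
    positive = positive[positive > 0]
    eps = positive.min() / 10 if positive.size else 1.0
    records = []
    for a, b in pairs:
        xa = densities[cohorts == a]
        xb = densities[cohorts == b]
        ps, us, lfc = [], [], []
        for cls in densities.columns:
            u, p = _mwu(xa[cls].to_numpy(), xb[cls].to_numpy())
            us.append(u)
            ps.append(p)
            lfc.append(math.log2((xa[cls].mean() + eps) / (xb[cls].mean() + eps)))
        q = multipletests(ps, method="fdr_bh")[1]
        for cls, u, p, qv, fc in zip(densities.columns, us, ps, q, lfc):
            records.append({"pair": f"{a}-{b}", "class": cls, "U": u,
                            "p": p, "q": qv, "log2fc": fc})
    return pd.DataFrame(records)


@dataclass
class CorrelationMatrix:
    """Spearman rho, raw p, and a significance mask at the chosen alpha."""

    rho: pd.DataFrame
    p: pd.DataFrame
    significant: pd.DataFrame
    alpha: float


@lru_cache(maxsize=8)
def _all_permutations(n: int) -> np.ndarray:
    import itertools

    return np.array(list(itertools.permutations(range(n))), dtype=np.intp)


def _spearman_pair(x: np.ndarray, y: np.ndarray, exact_max_n: int = 9) -> tuple[float, float]:
    n = len(x)
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return np.nan, np.nan
    rho = float(sps.spearmanr(x, y).statistic)
    if n > exact_max_n:
        p = float(sps.spearmanr(x, y).pvalue)
    else:
        # exact two-sided permutation null over all pairings of the ranks
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        rx = (rx - rx.mean()) / rx.std()
        ry = (ry - ry.mean()) / ry.std()
        rhos = (ry[_all_permutations(n)] * rx).mean(axis=1)
        p = float((np.abs(rhos) >= abs(rho) - 1e-12).mean())
    return rho, p


def spearman_blocks(matrix: pd.DataFrame, alpha: float = 0.05) -> CorrelationMatrix:
    """Pairwise Spearman correlation across biopsies for every class pair.

    Rank correlation uses average ranks for ties; p-values come from the
    t-approximation for n >= 10 biopsies and an exact pairing-permutation
    test for smaller n.  Entries with p >= alpha are masked out of
    ``significant``.  Constant columns yield missing correlations.
    """
    if len(matrix) < 3:
        raise ConfigError("need at least 3 biopsies for correlation")
    cols = list(matrix.columns)
    k = len(cols)
    rho = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            r, pv = _spearman_pair(matrix[cols[i]].to_numpy(float),
                                   matrix[cols[j]].to_numpy(float))
            rho[i, j] = rho[j, i] = r
            p[i, j] = p[j, i] = pv
    for i in range(k):
        if np.unique(matrix[cols[i]].to_numpy(float)).size < 2:
            rho[i, i] = np.nan
    rho_df = pd.DataFrame(rho, index=cols, columns=cols)
    p_df = pd.DataFrame(p, index=cols, columns=cols)
    sig = rho_df.where((p_df < alpha) | np.eye(k, dtype=bool))
    return CorrelationMatrix(rho=rho_df, p=p_df, significant=sig, alpha=alpha)


def damage_scores(
    stack: ChannelStack,
    cells: pd.DataFrame,
    comps: CompartmentMasks,
    mask_thresholds: dict[str, float] | None = None,
    immune_classes: set[str] | None = None,
    channel_names: dict[str, str] | None = None,
) -> dict[str, float]:
    """Four biopsy-level measures of tubulointerstitial inflammation/scarring.

    * ``immune_density`` — classified immune cells per tissue mm^2;
    * ``inflamed_tubule_density`` — MXA+ Claudin1+ cells inside the tubular
      compartment per tubular mm^2;
    * ``coliii_area_pct`` / ``mxa_area_pct`` — marker mask area as % of
      tissue area, thresholded by Otsu on the normalized channel unless a
      threshold is supplied in ``mask_thresholds``.

    Cell positivity for MXA/Claudin1 uses the same channel thresholds applied
    to the cells' raw MFIs (extracted from the same normalized stack).
    """
    channel_names = channel_names or {"MXA": "MXA", "Claudin1": "Claudin1", "COLIII": "COLIII"}
    for key, name in channel_names.items():
        if name not in stack.channels:
            raise ConfigError(f"channel {name!r} ({key}) missing from stack")
    mask_thresholds = mask_thresholds or {}
    thr = {}
    for key in ("MXA", "Claudin1", "COLIII"):
        chan = stack.channels[channel_names[key]]
        thr[key] = mask_thresholds.get(key, float(threshold_otsu(chan)))
    tissue = comps.tissue
    tissue_area_px = tissue.sum()
    areas = comps.areas_mm2()
    out: dict[str, float] = {}
    if immune_classes is None:
        immune_classes = set(cells["class_label"].unique()) - {NON_CLASSIFIED}
    inside = cells["compartment"] != OFF_TISSUE
    n_immune = (cells["class_label"].isin(immune_classes) & inside).sum()
    out["immune_density"] = float(n_immune) / comps.tissue_area_mm2()
    mxa_pos = cells[f"mfi_{channel_names['MXA']}"] >= thr["MXA"]
    cl_pos = cells[f"mfi_{channel_names['Claudin1']}"] >= thr["Claudin1"]
    inflamed = mxa_pos & cl_pos & (cells["compartment"] == "tubular")
    out["inflamed_tubule_density"] = (
        float(inflamed.sum()) / areas["tubular"] if areas["tubular"] > 0 else np.nan
    )
    for key, name in (("COLIII", "coliii_area_pct"), ("MXA", "mxa_area_pct")):
        mask = (stack.channels[channel_names[key]] >= thr[key]) & tissue
        out[name] = 100.0 * float(mask.sum()) / tissue_area_px if tissue_area_px else np.nan
    return out


def ols_fit(x: np.ndarray, y: np.ndarray) -> dict[str, float]:
    """Ordinary least squares of y on x: slope, intercept, R^2, and p.

    Requires >= 3 points and non-constant x.  A constant y gives slope 0 and
    R^2 = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ConfigError("need at least 3 points for OLS")
    if np.unique(x).size < 2:
        raise ConfigError("x is constant; OLS slope undefined")
    res = sps.linregress(x, y)
    r2 = 0.0 if np.isnan(res.rvalue) else float(res.rvalue) ** 2
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "r2": r2, "p": float(res.pvalue)}
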