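"""Renal compartment masks, tubule false-positive filtering, cell assignment.

The renal cortex is resolved into five compartments: glomerular, tubular,
their dilated rings (periglomerular, peritubular), and the remaining
interstitium.  Because dilated rings can overlap structures and each other,
pixels are resolved by a fixed priority — glomerular > tubular >
periglomerular > peritubular > interstitial — so that the five compartments
partition the tissue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from renimap.errors import ConfigError
from renimap.stack import ChannelStack

log = logging.getLogger(__name__)

COMPARTMENTS = ("glomerular", "tubular", "periglomerular", "peritubular", "interstitial")
OFF_TISSUE = "off-tissue"

# Tubule objects are dropped as false positives (red-blood-cell clusters,
# interstitial lymphocyte aggregates) only when ALL five conditions hold on
# the object's normalized marker MFIs.
TUBULE_FILTER = {"cd10_max": 0.8, "muc1_max": 0.8, "claudin1_max": 1.0, "cd138_max": 1.0,
                 "ratio_low": 0.25, "ratio_high": 6.5}

__all__ = [
    "COMPARTMENTS",
    "OFF_TISSUE",
    "CompartmentMasks",
    "build_compartment_masks",
    "assign_compartment",
    "tubule_object_stats",
    "filter_tubule_objects",
]


def _dilate_binary(mask: np.ndarray, radius_px: int) -> np.ndarray:
    """Euclidean dilation via distance transform of the complement."""
    if not mask.any():
        return mask.copy()
    return ndimage.distance_transform_edt(~mask) <= radius_px


@dataclass
class CompartmentMasks:
    """Labelled structures plus derived ring and interstitium masks."""

    tubular: np.ndarray
    glomerular: np.ndarray
    peritubular_ring: np.ndarray
    periglomerular_ring: np.ndarray
    interstitium: np.ndarray
    ring_width_um: float
    pixel_size: float
    tissue: np.ndarray

    def compartment_map(self) -> np.ndarray:
        """Integer map: 1..5 index into :data:`COMPARTMENTS`, 0 = off-tissue."""
        out = np.zeros(self.tubular.shape, dtype=np.int8)
        out[self.tissue] = 5  # interstitial by default
        out[self.tissue & self.peritubular_ring] = 4
        out[self.tissue & self.periglomerular_ring] = 3
        out[self.tissue & (self.tubular > 0)] = 2
        out[self.tissue & (self.glomerular > 0)] = 1
        return out

    def areas_mm2(self) -> dict[str, float]:
        """Pixel area of each final compartment converted to mm^2."""
        cmap = self.compartment_map()
        px_mm2 = (self.pixel_size * 1e-3) ** 2
        return {name: float((cmap == i + 1).sum()) * px_mm2 for i, name in enumerate(COMPARTMENTS)}

    def tissue_area_mm2(self) -> float:
        return float(self.tissue.sum()) * (self.pixel_size * 1e-3) ** 2


def build_compartment_masks(
    tubules: np.ndarray,
    glomeruli: np.ndarray,
    ring_width_um: float = 10.0,
    pixel_size: float = 0.1507,
    tissue: np.ndarray | None = None,
) -> CompartmentMasks:
    """Derive ring and interstitium masks from labelled structures.

    Rings are the binary dilation of a structure by ``round(ring_width_um /
    pixel_size)`` pixels minus the structure itself; the interstitium is the
    tissue left over after priority resolution.
    """
    tubules = np.asarray(tubules)
    glomeruli = np.asarray(glomeruli)
    if tubules.shape != glomeruli.shape:
        raise ConfigError("tubule and glomerulus masks must share a shape")
    r = int(round(ring_width_um / pixel_size))
    if r < 1:
        raise ConfigError(f"ring width {ring_width_um} um is below one pixel at {pixel_size} um/px")
    if tissue is None:
        tissue = np.ones(tubules.shape, dtype=bool)
    tub_bin = tubules > 0
    glom_bin = glomeruli > 0
    peri_t = _dilate_binary(tub_bin, r) & ~tub_bin
    peri_g = _dilate_binary(glom_bin, r) & ~glom_bin
    cm = CompartmentMasks(
        tubular=tubules,
        glomerular=glomeruli,
        peritubular_ring=peri_t,
        periglomerular_ring=peri_g,
        interstitium=np.zeros_like(tub_bin),
        ring_width_um=ring_width_um,
        pixel_size=pixel_size,
        tissue=np.asarray(tissue, dtype=bool),
    )
    cm.interstitium = cm.compartment_map() == 5
    return cm


def assign_compartment(cells: pd.DataFrame, comps: CompartmentMasks) -> pd.DataFrame:
    """Fill the ``compartment`` column by centroid lookup.

    Priority: glomerular > tubular > periglomerular > peritubular >
    interstitial.  Centroids outside the tissue mask are labelled
    ``off-tissue`` and should be excluded downstream.
    """
    cmap = comps.compartment_map()
    H, W = cmap.shape
    ys = np.clip(np.round(cells["y"].to_numpy(float)).astype(int), 0, H - 1)
    xs = np.clip(np.round(cells["x"].to_numpy(float)).astype(int), 0, W - 1)
    codes = cmap[ys, xs]
    names = np.array([OFF_TISSUE, *COMPARTMENTS])
    out = cells.copy()
    out["compartment"] = names[codes]
    return out


def tubule_object_stats(tubules: np.ndarray, stack: ChannelStack,
                        markers: dict[str, str] | None = None) -> pd.DataFrame:
    """Per-tubule-object mean normalized MFI of the four structural markers.

    ``markers`` maps the canonical keys ``CD10, MUC1, Claudin1, CD138`` to
    channel names in ``stack`` (identity by default).  The MUC1/CD10 ratio is
    defined only where the CD10 mean is positive.
    """
    markers = markers or {k: k for k in ("CD10", "MUC1", "Claudin1", "CD138")}
    tubules = np.asarray(tubules)
    labels = np.unique(tubules[tubules > 0])
    nmax = int(tubules.max()) if labels.size else 0
    flat = tubules.ravel()
    area = np.bincount(flat, minlength=nmax + 1)
    rows = {"label": labels}
    for key in ("CD10", "MUC1", "Claudin1", "CD138"):
        chan = stack.channels[markers[key]]
        sums = np.bincount(flat, weights=chan.ravel(), minlength=nmax + 1)
        rows["mu_" + key] = sums[labels] / area[labels]
    df = pd.DataFrame(rows)
    with np.errstate(divide="ignore", invalid="ignore"):
        df["ratio"] = np.where(df["mu_CD10"] > 0, df["mu_MUC1"] / df["mu_CD10"], np.nan)
    return df


def filter_tubule_objects(tubules: np.ndarray, stats: pd.DataFrame) -> np.ndarray:
    """Remove tubule false positives; survivors keep their labels.

    An object is removed iff ALL of: mu_CD10 < 0.8, mu_MUC1 < 0.8,
    mu_Claudin1 < 1, mu_CD138 < 1, and 0.25 < mu_MUC1/mu_CD10 < 6.5.  When
    mu_CD10 = 0 the ratio condition is treated as not satisfied (the object
    is kept by this rule) and the case is logged.
    """
    tubules = np.asarray(tubules)
    present = set(np.unique(tubules[tubules > 0]).tolist())
    missing = present - set(stats["label"].tolist())
    if missing:
        raise ConfigError(f"stats missing for tubule labels {sorted(missing)[:5]}")
    f = TUBULE_FILTER
    ratio_ok = (stats["ratio"] > f["ratio_low"]) & (stats["ratio"] < f["ratio_high"])
    undefined = ~(stats["mu_CD10"] > 0)
    if undefined.any():
        log.info("ratio undefined (mu_CD10 = 0) for %d tubule objects; kept", int(undefined.sum()))
    ratio_ok &= ~undefined
    remove = (
        (stats["mu_CD10"] < f["cd10_max"])
        & (stats["mu_MUC1"] < f["muc1_max"])
        & (stats["mu_Claudin1"] < f["claudin1_max"])
        & (stats["mu_CD138"] < f["cd138_max"])
        & ratio_ok
    )
    drop = set(stats.loc[remove, "label"].tolist())
    out = tubules.copy()
    if drop:
        out[np.isin(out, list(drop))] = 0
    return out
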