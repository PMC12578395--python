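"""Synthetic renal biopsies with planted, recoverable ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes: renal compartment geometry (disk glomeruli, capsule tubules with a
lumen, interstitium), class-specific marker expression with lognormal noise,
biopsy-level covariant abundance blocks driven by latent cohort factors,
spatial immune niches of specified composition, periglomerular enrichment,
and per-gene transcript point patterns.  Every operation is a pure function
of (spec, seed), and compartment ground truth is assigned with the same
priority rule the pipeline uses, so recovery tests are well-posed.

It does not emulate optics (PSF, spectral bleed-through), 3-D tissue, FFPE
artifacts, or stitching seams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from renimap.compartments import COMPARTMENTS, CompartmentMasks, build_compartment_masks
from renimap.errors import ConfigError, PlacementError
from renimap.gating import GatingTree, load_default_tree
from renimap.segmentation import dilate_voronoi
from renimap.stack import ChannelStack

__all__ = [
    "NicheSpec",
    "CohortModel",
    "SyntheticTissueSpec",
    "GroundTruth",
    "BiopsySample",
    "templates_from_tree",
    "default_spec",
    "generate_biopsy",
    "sample_cohort",
    "render_stack",
    "sample_niche_layout",
    "place_transcripts",
]


@dataclass(frozen=True)
class NicheSpec:
    """One planted niche type: composition, footprint, and intensity."""

    composition: dict[str, float]  # class -> proportion (sums to 1)
    radius_um: float = 30.0
    intensity: float = 40.0  # expected cells per niche
    n_per_biopsy: int = 2

    def validate(self) -> None:
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"niche composition sums to {total}, not 1")
        if min(self.composition.values(), default=0) < 0:
            raise ConfigError("niche proportions must be non-negative")
        if self.radius_um <= 0 or self.intensity < 0 or self.n_per_biopsy < 0:
            raise ConfigError("niche radius/intensity/count must be non-negative")


@dataclass(frozen=True)
class CohortModel:
    """Latent-factor model of per-class abundance for one cohort.

    Per biopsy b a latent trajectory score z_bj ~ N(0, 1) is drawn per
    factor j, and class c's expected density is
    ``base[c] * exp(sum_j loadings[c][j] * z_bj + eps)`` with
    eps ~ N(0, noise_sd).  Classes sharing a factor with loading 1 form a
    planted covariant block.
    """

    base: dict[str, float]  # class -> cells/mm^2
    loadings: dict[str, tuple[float, ...]]  # class -> per-factor loadings
    noise_sd: float = 0.3

    @property
    def n_factors(self) -> int:
        return max((len(v) for v in self.loadings.values()), default=0)

    def validate(self) -> None:
        if any(v < 0 for v in self.base.values()):
            raise ConfigError("abundances must be non-negative")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        lengths = {len(v) for v in self.loadings.values()}
        if len(lengths) > 1:
            raise ConfigError("all classes need the same number of factor loadings")
        if set(self.loadings) - set(self.base):
            raise ConfigError("loadings reference classes without a base abundance")


@dataclass(frozen=True)
class SyntheticTissueSpec:
    """Full description of a synthetic biopsy; all lengths in micrometres."""

    image_shape: tuple[int, int] = (1024, 1024)
    pixel_size: float = 0.1507
    n_glomeruli: int = 2
    n_tubules: int = 5
    glomerulus_radius_um: tuple[float, float] = (25.0, 40.0)
    tubule_width_um: tuple[float, float] = (12.0, 20.0)
    class_templates: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)
    class_radius_um: float = 3.0
    abundances: dict[str, float] = field(default_factory=dict)
    cohort_models: dict[str, CohortModel] = field(default_factory=dict)
    niche_specs: tuple[NicheSpec, ...] = ()
    niche_spacing_um: float = 20.0  # minimum edge-to-edge gap between niches
    periglomerular_enrichment: float = 1.0
    enriched_classes: tuple[str, ...] | None = None
    transcript_rates: dict[int, dict[str, float]] = field(default_factory=dict)
    ring_width_um: float = 10.0
    body_dilation_px: int = 7
    background_level: float = 2.0
    background_sd: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if min(self.image_shape) <= 0:
            raise ConfigError("image_shape must be positive")
        if self.pixel_size <= 0:
            raise ConfigError("pixel_size must be positive")
        if self.periglomerular_enrichment < 1:
            raise ConfigError("periglomerular enrichment must be >= 1")
        if any(v < 0 for v in self.abundances.values()):
            raise ConfigError("abundances must be non-negative")
        for ns in self.niche_specs:
            ns.validate()
        for cm in self.cohort_models.values():
            cm.validate()

    def px(self, um: float) -> float:
        return um / self.pixel_size

    @property
    def area_mm2(self) -> float:
        h, w = self.image_shape
        return h * w * (self.pixel_size * 1e-3) ** 2

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.abundances) | set(self.class_templates))


@dataclass
class GroundTruth:
    """Planted truth for one biopsy: per-cell labels and layout."""

    cells: pd.DataFrame  # cell_id, true_class, niche_id, compartment
    niches: pd.DataFrame  # niche_id, niche_type, x_um, y_um, radius_um
    latent: dict[str, float] = field(default_factory=dict)


@dataclass
class BiopsySample:
    """One cohort draw: expected densities, realized counts, latent scores."""

    biopsy_id: str
    cohort: str
    densities: pd.Series  # cells/mm^2 (expected, pre-Poisson)
    counts: pd.Series
    latent: np.ndarray


def templates_from_tree(
    tree: GatingTree | None = None,
    classes: list[str] | None = None,
    hi: float = 8.0,
    lo: float = 0.5,
    noise_sd: float = 0.25,
) -> dict[str, dict[str, tuple[float, float]]]:
    """Marker templates consistent with a gating tree.

    For each class, markers on its root-to-leaf positive branches get mean
    ``hi`` and all other tree markers mean ``lo``, each with the same
    lognormal noise sd — so noiseless annotation is exact by construction.
    """
    tree = tree or load_default_tree()
    paths: dict[str, dict[str, bool]] = {}

    def walk(node: dict, trail: dict[str, bool]):
        if "class" in node:
            if node["class"] is not None:
                paths[node["class"]] = dict(trail)
            return
        m = node["marker"]
        walk(node["positive"], {**trail, m: True})
        walk(node["negative"], {**trail, m: False})

    walk(tree.root, {})
    classes = classes or list(paths)
    markers = tree.markers()
    out = {}
    for cls in classes:
        if cls not in paths:
            raise ConfigError(f"class {cls!r} is not a leaf of the tree")
        out[cls] = {
            m: (hi if paths[cls].get(m, False) else lo, noise_sd) for m in markers
        }
    return out


DEFAULT_CLASSES = (
    "CD4 T cell", "CD8 T cell", "gd T cell", "B cell", "plasma cell",
    "CD14+CD163+MerTK+ macrophage", "CD14+CD163+ macrophage",
    "CD14+MerTK+ macrophage", "CD14+ macrophage",
    "HLAII+ inflammatory monocyte", "HLAII- inflammatory monocyte",
    "CD16+ macrophage",
)

# Rarer immune classes plus renal parenchymal classes.  Together with
# DEFAULT_CLASSES every marker of the shipped gating tree has at least one
# positive class, so marker thresholds are identifiable from synthetic data
# (as in real biopsies, where structural cells dominate the table).
EXTRA_PANEL_CLASSES = {
    "CD4 Treg": 10, "plasmablast": 10, "NK cell": 8, "plasmacytoid DC": 5,
    "conventional DC": 8, "monocyte-derived macrophage": 15,
    "proximal tubule": 150, "distal tubule": 100,
    "Claudin1+ tubule epithelium": 20, "endothelium": 80, "podocyte": 20,
    "smooth muscle": 30, "epithelium other": 30, "fibroblast": 60,
}

# Planted covariant blocks (shared latent factor per block):
#   0: T cells, 1: CD163+ macrophages, 2: CD163- macrophages,
#   3: inflammatory monocytes, 4: humoral cells.
_BLOCKS = {
    "CD4 T cell": 0, "CD8 T cell": 0, "gd T cell": 0,
    "CD14+CD163+MerTK+ macrophage": 1, "CD14+CD163+ macrophage": 1,
    "CD14+MerTK+ macrophage": 2, "CD14+ macrophage": 2,
    "HLAII+ inflammatory monocyte": 3, "HLAII- inflammatory monocyte": 3,
    "B cell": 4, "plasma cell": 4,
}

_COHORT_BASE = {
    # normal kidney: scant immune infiltrate
    "KC": {"CD4 T cell": 8, "CD8 T cell": 6, "gd T cell": 2, "B cell": 3,
           "plasma cell": 3, "CD14+CD163+MerTK+ macrophage": 5,
           "CD14+CD163+ macrophage": 6, "CD14+MerTK+ macrophage": 6,
           "CD14+ macrophage": 6, "HLAII+ inflammatory monocyte": 3,
           "HLAII- inflammatory monocyte": 4, "CD16+ macrophage": 2},
    # lupus nephritis: myeloid-heavy, CD163+ enriched
    "LuN": {"CD4 T cell": 60, "CD8 T cell": 50, "gd T cell": 10, "B cell": 30,
            "plasma cell": 40, "CD14+CD163+MerTK+ macrophage": 60,
            "CD14+CD163+ macrophage": 80, "CD14+MerTK+ macrophage": 70,
            "CD14+ macrophage": 60, "HLAII+ inflammatory monocyte": 40,
            "HLAII- inflammatory monocyte": 50, "CD16+ macrophage": 20},
    # allograft rejection: T-cell heavy, CD163+ scant
    "RAR": {"CD4 T cell": 120, "CD8 T cell": 140, "gd T cell": 20, "B cell": 20,
            "plasma cell": 15, "CD14+CD163+MerTK+ macrophage": 15,
            "CD14+CD163+ macrophage": 20, "CD14+MerTK+ macrophage": 80,
            "CD14+ macrophage": 70, "HLAII+ inflammatory monocyte": 60,
            "HLAII- inflammatory monocyte": 70, "CD16+ macrophage": 25},
}

DEFAULT_NICHES = (
    NicheSpec({"CD4 T cell": 0.35, "CD8 T cell": 0.35, "gd T cell": 0.1,
               "B cell": 0.2}),
    NicheSpec({"CD14+CD163+MerTK+ macrophage": 0.3, "CD14+CD163+ macrophage": 0.5,
               "CD14+ macrophage": 0.2}),
    NicheSpec({"HLAII+ inflammatory monocyte": 0.3,
               "HLAII- inflammatory monocyte": 0.4,
               "CD14+MerTK+ macrophage": 0.3}),
)

# Expected transcripts per niche per gene, by niche type (indexes
# DEFAULT_NICHES); anchors CD3E/CD14/FCGR3A appear in every type.
DEFAULT_TRANSCRIPT_RATES = {
    0: {"CD3E": 30, "CD4": 15, "CD8A": 12, "PDCD1": 6, "ICOS": 6, "FOXP3": 3,
        "MS4A1": 8, "CD14": 5, "FCGR3A": 5, "HLA-DRA": 4, "HLA-DRB1": 4},
    1: {"CD163": 30, "MRC1": 15, "CD14": 25, "NOS2": 4, "FCGR3A": 6,
        "CD3E": 5, "ITGAX": 5, "HLA-DRA": 5, "HLA-DPA1": 3},
    2: {"CD14": 30, "FCGR3A": 25, "ITGAX": 12, "NOS2": 6, "CD3E": 5,
        "HLA-DRA": 8, "HLA-DRB1": 6, "HLA-DQA1": 4},
}


def default_spec(**overrides) -> SyntheticTissueSpec:
    """The generator's default study conditions (LuN-like single biopsy)."""
    models = {
        cohort: CohortModel(
            base=dict(base),
            loadings={c: tuple(1.0 if _BLOCKS.get(c) == j else 0.0 for j in range(5))
                      for c in DEFAULT_CLASSES},
        )
        for cohort, base in _COHORT_BASE.items()
    }
    panel = list(DEFAULT_CLASSES) + list(EXTRA_PANEL_CLASSES)
    defaults = dict(
        class_templates=templates_from_tree(classes=panel),
        abundances={**_COHORT_BASE["LuN"], **EXTRA_PANEL_CLASSES},
        cohort_models=models,
        niche_specs=DEFAULT_NICHES,
        transcript_rates=DEFAULT_TRANSCRIPT_RATES,
    )
    defaults.update(overrides)
    return SyntheticTissueSpec(**defaults)


# ---------------------------------------------------------------------------
# geometry helpers


def _paint_disk(mask: np.ndarray, cy: float, cx: float, r: float, label: int) -> None:
    y0, y1 = max(0, int(cy - r) - 1), min(mask.shape[0], int(cy + r) + 2)
    x0, x1 = max(0, int(cx - r) - 1), min(mask.shape[1], int(cx + r) + 2)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    sel = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
    mask[y0:y1, x0:x1][sel] = label


def _paint_capsule(mask: np.ndarray, p0, p1, r_outer: float, r_lumen: float,
                   label: int) -> None:
    """Stadium (capsule) wall between endpoints p0, p1 with a hollow lumen."""
    y0 = max(0, int(min(p0[0], p1[0]) - r_outer) - 1)
    y1 = min(mask.shape[0], int(max(p0[0], p1[0]) + r_outer) + 2)
    x0 = max(0, int(min(p0[1], p1[1]) - r_outer) - 1)
    x1 = min(mask.shape[1], int(max(p0[1], p1[1]) + r_outer) + 2)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d = _segment_distance(yy, xx, p0, p1)
    sel = (d <= r_outer) & (d > r_lumen)
    mask[y0:y1, x0:x1][sel] = label


def _segment_distance(yy, xx, p0, p1):
    vy, vx = p1[0] - p0[0], p1[1] - p0[1]
    L2 = vy * vy + vx * vx
    if L2 == 0:
        return np.hypot(yy - p0[0], xx - p0[1])
    t = np.clip(((yy - p0[0]) * vy + (xx - p0[1]) * vx) / L2, 0, 1)
    return np.hypot(yy - (p0[0] + t * vy), xx - (p0[1] + t * vx))


def _capsule_hull_distance(yy, xx, p0, p1):
    return _segment_distance(yy, xx, p0, p1)


# ---------------------------------------------------------------------------
# generation


def _place_structures(spec: SyntheticTissueSpec, rng: np.random.Generator):
    H, W = spec.image_shape
    glom = np.zeros((H, W), dtype=np.int32)
    tub = np.zeros((H, W), dtype=np.int32)
    glom_info = []  # (cy, cx, r)
    for i in range(spec.n_glomeruli):
        r_lo, r_hi = (spec.px(v) for v in spec.glomerulus_radius_um)
        placed = False
        for _ in range(300):
            r = rng.uniform(r_lo, r_hi)
            if 2 * r + 2 >= min(H, W):
                continue
            cy = rng.uniform(r + 1, H - r - 1)
            cx = rng.uniform(r + 1, W - r - 1)
            if all((cy - gy) ** 2 + (cx - gx) ** 2 > (r + gr + 2) ** 2
                   for gy, gx, gr in glom_info):
                glom_info.append((cy, cx, r))
                _paint_disk(glom, cy, cx, r, i + 1)
                placed = True
                break
        if not placed:
            raise PlacementError("glomerulus", f"could not place glomerulus {i + 1}")
    tub_info = []  # (p0, p1, r_outer)
    for i in range(spec.n_tubules):
        w_lo, w_hi = (spec.px(v) for v in spec.tubule_width_um)
        placed = False
        for _ in range(300):
            width = rng.uniform(w_lo, w_hi)
            r_outer = width / 2
            length = width * rng.uniform(3, 6)
            cy = rng.uniform(r_outer, H - r_outer)
            cx = rng.uniform(r_outer, W - r_outer)
            th = rng.uniform(0, math.pi)
            dy, dx = math.sin(th) * length / 2, math.cos(th) * length / 2
            p0 = (np.clip(cy - dy, r_outer, H - r_outer), np.clip(cx - dx, r_outer, W - r_outer))
            p1 = (np.clip(cy + dy, r_outer, H - r_outer), np.clip(cx + dx, r_outer, W - r_outer))
            ok = True
            for gy, gx, gr in glom_info:
                d = _capsule_hull_distance(np.array([[gy]]), np.array([[gx]]), p0, p1)[0, 0]
                if d < gr + r_outer + 2:
                    ok = False
                    break
            for q0, q1, qr in tub_info:
                for pt in (p0, p1, ((p0[0] + p1[0]) / 2, (p0[1] + p1[1]) / 2)):
                    d = _capsule_hull_distance(np.array([[pt[0]]]), np.array([[pt[1]]]), q0, q1)[0, 0]
                    if d < qr + r_outer:
                        ok = False
                        break
                if not ok:
                    break
            if ok:
                tub_info.append((p0, p1, r_outer))
                _paint_capsule(tub, p0, p1, r_outer, r_outer * 0.45, i + 1)
                placed = True
                break
        if not placed:
            raise PlacementError("tubule", f"could not place tubule {i + 1}")
    # keep-out region for cell placement: full capsule hull incl. lumen
    keepout = glom > 0
    for p0, p1, r_outer in tub_info:
        yy, xx = np.mgrid[0:H, 0:W]
        keepout |= _capsule_hull_distance(yy, xx, p0, p1) <= r_outer
    return glom, tub, keepout


def _sample_positions(
    n: int,
    weight_groups: list[tuple[np.ndarray, np.ndarray, float]],
    occupancy: np.ndarray,
    disk_offsets: tuple[np.ndarray, np.ndarray],
    rng: np.random.Generator,
    shape: tuple[int, int],
) -> list[tuple[int, int]]:
    """Draw n non-overlapping nucleus centres from weighted pixel groups."""
    H, W = shape
    dy, dx = disk_offsets
    weights = np.array([w * len(ys) for ys, xs, w in weight_groups], dtype=float)
    if weights.sum() <= 0:
        raise PlacementError("cell", "no tissue pixels available for placement")
    probs = weights / weights.sum()
    out = []
    for _ in range(n):
        for _attempt in range(200):
            g = rng.choice(len(weight_groups), p=probs)
            ys, xs, _w = weight_groups[g]
            j = rng.integers(len(ys))
            cy, cx = int(ys[j]), int(xs[j])
            yy, xx = cy + dy, cx + dx
            if (yy < 0).any() or (yy >= H).any() or (xx < 0).any() or (xx >= W).any():
                continue
            if occupancy[yy, xx].any():
                continue
            occupancy[yy, xx] = True
            out.append((cy, cx))
            break
        else:
            raise PlacementError("cell", "field too crowded to place all cells")
    return out


def generate_biopsy(
    spec: SyntheticTissueSpec, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, pd.DataFrame, GroundTruth]:
    """Generate one synthetic biopsy.

    Returns ``(nuclei, tubules, glomeruli, cells, ground_truth)``: integer
    label masks, a cell table with true labels and noisy per-marker MFIs,
    and the planted ground truth.  Deterministic in (spec, seed).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    H, W = spec.image_shape
    glom, tub, keepout = _place_structures(spec, rng)
    comps = build_compartment_masks(tub, glom, spec.ring_width_um, spec.pixel_size)
    cmap = comps.compartment_map()

    r_cell = max(1, int(round(spec.px(spec.class_radius_um))))
    dy, dx = np.mgrid[-r_cell:r_cell + 1, -r_cell:r_cell + 1]
    inside = dy**2 + dx**2 <= r_cell**2
    disk_offsets = (dy[inside].ravel(), dx[inside].ravel())
    occupancy = keepout.copy()

    free = ~keepout
    peri_g = free & (cmap == COMPARTMENTS.index("periglomerular") + 1)
    rest = free & ~peri_g
    ys_pg, xs_pg = np.nonzero(peri_g)
    ys_r, xs_r = np.nonzero(rest)

    records: list[dict] = []
    niche_rows: list[dict] = []

    # niche cells first (they claim space deterministically before background)
    niche_id = 0
    gap = spec.px(spec.niche_spacing_um)
    centers: list[tuple[float, float, float]] = []  # (cy, cx, radius_px)
    for t, ns in enumerate(spec.niche_specs):
        r_n = spec.px(ns.radius_um)
        for _ in range(ns.n_per_biopsy):
            placed = False
            for _attempt in range(300):
                cy = rng.uniform(r_n, H - r_n)
                cx = rng.uniform(r_n, W - r_n)
                if keepout[int(cy), int(cx)]:
                    continue
                if any((cy - oy) ** 2 + (cx - ox) ** 2 < (r_n + orr + gap) ** 2
                       for oy, ox, orr in centers):
                    continue
                centers.append((cy, cx, r_n))
                placed = True
                break
            if not placed:
                raise PlacementError("niche", f"could not place niche of type {t}")
            niche_rows.append({
                "niche_id": niche_id, "niche_type": t,
                "x_um": cx * spec.pixel_size, "y_um": cy * spec.pixel_size,
                "radius_um": ns.radius_um,
            })
            classes = list(ns.composition)
            probs = np.array([ns.composition[c] for c in classes])
            n_members = rng.poisson(ns.intensity)
            member_classes = rng.choice(classes, p=probs, size=n_members)
            for cls in member_classes:
                for _attempt in range(300):
                    rr = r_n * math.sqrt(rng.uniform())
                    th = rng.uniform(0, 2 * math.pi)
                    py, px_ = int(cy + rr * math.sin(th)), int(cx + rr * math.cos(th))
                    if not (r_cell <= py < H - r_cell and r_cell <= px_ < W - r_cell):
                        continue
                    yy, xx = py + disk_offsets[0], px_ + disk_offsets[1]
                    if occupancy[yy, xx].any():
                        continue
                    occupancy[yy, xx] = True
                    records.append({"y": py, "x": px_, "true_class": cls,
                                    "niche_id": niche_id})
                    break
                else:
                    raise PlacementError("niche cell", "niche too crowded")
            niche_id += 1

    # background cells with optional periglomerular enrichment
    f = spec.periglomerular_enrichment
    for cls in sorted(spec.abundances):
        lam = spec.abundances[cls] * spec.area_mm2
        n = rng.poisson(lam)
        if n == 0:
            continue
        enriched = spec.enriched_classes is None or cls in spec.enriched_classes
        w_pg = f if enriched else 1.0
        groups = [(ys_pg, xs_pg, w_pg), (ys_r, xs_r, 1.0)]
        groups = [g for g in groups if len(g[0])]
        for py, px_ in _sample_positions(n, groups, occupancy, disk_offsets, rng, (H, W)):
            records.append({"y": py, "x": px_, "true_class": cls, "niche_id": -1})

    cells = pd.DataFrame(records, columns=["y", "x", "true_class", "niche_id"])
    cells.insert(0, "cell_id", np.arange(1, len(cells) + 1))
    nuclei = np.zeros((H, W), dtype=np.int32)
    for row in cells.itertuples():
        _paint_disk(nuclei, row.y, row.x, r_cell, row.cell_id)
    comp_names = np.array(["off-tissue", *COMPARTMENTS])
    cells["compartment"] = comp_names[cmap[cells["y"].to_numpy(int), cells["x"].to_numpy(int)]] \
        if len(cells) else np.array([], dtype=object)
    cells["area_px"] = len(disk_offsets[0])

    markers = sorted({m for t in spec.class_templates.values() for m in t})
    for m in markers:
        means = np.array([spec.class_templates[c][m][0] for c in cells["true_class"]]) \
            if len(cells) else np.array([])
        sds = np.array([spec.class_templates[c][m][1] for c in cells["true_class"]]) \
            if len(cells) else np.array([])
        noise = rng.normal(0.0, 1.0, size=len(cells))
        cells[f"mfi_{m}"] = means * np.exp(sds * noise)

    cells = cells[["cell_id", "x", "y", "area_px", "true_class", "niche_id",
                   "compartment"] + [f"mfi_{m}" for m in markers]]
    truth = GroundTruth(
        cells=cells[["cell_id", "true_class", "niche_id", "compartment"]].copy(),
        niches=pd.DataFrame(niche_rows,
                            columns=["niche_id", "niche_type", "x_um", "y_um", "radius_um"]),
    )
    return nuclei, tub, glom, cells, truth


def niche_recovery_spec(n_types: int, n_per_type: int = 8,
                        base_intensity: float = 60.0) -> SyntheticTissueSpec:
    """Field of planted spatial niches for neighborhood-recovery studies.

    Each of ``n_types`` niche phenotypes is dominated (90%) by one immune
    class and alternates between a small and a 4x larger cell intensity, so
    phenotypes separate in both composition and total-count features.  Niche
    radius scales with sqrt(intensity) to hold the local cell density (and
    hence DBSCAN detectability) constant.  Coordinates are generated at
    1 um/pixel with no background cells, so DBSCAN neighborhoods are exactly
    the planted niches.
    """
    if not (1 <= n_types <= len(DEFAULT_CLASSES)):
        raise ConfigError(f"n_types must be in 1..{len(DEFAULT_CLASSES)}")
    classes = list(DEFAULT_CLASSES)[:n_types]
    niches = []
    for t, dom in enumerate(classes):
        others = [c for c in classes if c != dom]
        comp = {dom: 1.0} if not others else \
            {dom: 0.9, **{c: 0.1 / len(others) for c in others}}
        intensity = base_intensity * (1 if t % 2 == 0 else 4)
        niches.append(NicheSpec(comp, radius_um=4 * math.sqrt(intensity),
                                intensity=intensity, n_per_biopsy=n_per_type))
    side = int(1100 + 200 * n_types * n_per_type / 8)
    return default_spec(
        image_shape=(side, side), pixel_size=1.0, niche_specs=tuple(niches),
        abundances={}, class_radius_um=1.0, n_glomeruli=1, n_tubules=2,
        niche_spacing_um=30.0,
    )


def transcript_niche_spec(n_per_type: int = 4) -> SyntheticTissueSpec:
    """Millimetre-scale niche layout for transcript-niche recovery studies.

    The three default niche phenotypes (T cell, CD163+ macrophage,
    inflammatory monocyte) are laid out with edge gaps larger than the
    biggest anchor-gene DBSCAN eps (400 um for CD3E on the 10-um raster),
    so per-gene clustering cannot bridge distinct niches.
    """
    specs = tuple(replace(ns, radius_um=60.0, n_per_biopsy=n_per_type)
                  for ns in DEFAULT_NICHES)
    side = int(1400 + 700 * n_per_type)
    return default_spec(
        image_shape=(side, side), pixel_size=1.0, niche_specs=specs,
        abundances={}, niche_spacing_um=450.0,
    )


def spot_references_from_truth(
    cells: pd.DataFrame,
    templates: dict[str, dict[str, tuple[float, float]]],
    markers: list[str] | None = None,
    n: int = 5,
    seed: int = 0,
    prefix: str = "z_",
    positive_mean: float = 1.0,
):
    """Emulated manual spot validation: n typical true-positive MFIs per marker.

    For each marker, classes whose template mean exceeds ``positive_mean``
    count as positive; ``n`` of their cells are sampled at random (circling
    arbitrary, not extreme, positive cells).  Returns a dict of
    :class:`~renimap.gating.SpotReference`.
    """
    from renimap.gating import SpotReference

    rng = np.random.default_rng(seed)
    markers = markers or sorted({m for t in templates.values() for m in t})
    refs = {}
    for m in markers:
        pos_classes = [c for c, t in templates.items() if m in t and t[m][0] > positive_mean]
        vals = cells.loc[cells["true_class"].isin(pos_classes), prefix + m].to_numpy(float)
        if vals.size == 0:
            continue
        refs[m] = SpotReference(m, rng.choice(vals, size=min(n, vals.size), replace=False))
    return refs


def sample_cohort(
    spec: SyntheticTissueSpec, n_biopsies: int, cohort: str, seed: int = 0
) -> list[BiopsySample]:
    """Draw correlated per-class abundances for a cohort of biopsies.

    Expected densities follow the cohort's latent-factor model; realized
    counts are Poisson draws at the spec's field area.  With zero model
    noise, classes sharing a factor are exactly comonotone.
    """
    if n_biopsies < 3:
        raise ConfigError("need at least 3 biopsies (correlation undefined below)")
    if cohort not in spec.cohort_models:
        raise ConfigError(f"no cohort model for {cohort!r}")
    model = spec.cohort_models[cohort]
    if model.n_factors < 1:
        raise ConfigError("cohort model needs at least one latent factor")
    rng = np.random.default_rng(seed)
    classes = sorted(model.base)
    L = np.array([model.loadings.get(c, (0.0,) * model.n_factors) for c in classes])
    base = np.array([model.base[c] for c in classes])
    out = []
    for b in range(n_biopsies):
        z = rng.normal(size=model.n_factors)
        eps = rng.normal(0.0, model.noise_sd, size=len(classes)) if model.noise_sd > 0 \
            else np.zeros(len(classes))
        lam = base * np.exp(L @ z + eps)
        counts = rng.poisson(lam * spec.area_mm2)
        out.append(BiopsySample(
            biopsy_id=f"{cohort}-{b + 1:02d}",
            cohort=cohort,
            densities=pd.Series(lam, index=classes, name="density"),
            counts=pd.Series(counts, index=classes, name="count"),
            latent=z,
        ))
    return out


def render_stack(cells: pd.DataFrame, spec: SyntheticTissueSpec,
                 seed: int = 0) -> ChannelStack:
    """Render marker channels plus a shared blank channel of pure background.

    Each marker channel is the background field plus, on every cell-body
    pixel, that cell's stored MFI for the marker; the blank channel is the
    identical realized background field, so blank correction recovers the
    per-cell values exactly (scaled by 1/sd(blank)) at zero marker noise.
    Bodies are the Voronoi dilation of the nucleus disks, matching the
    extraction stage.
    """
    rng = np.random.default_rng(seed)
    H, W = spec.image_shape
    bg = spec.background_level + rng.normal(0.0, spec.background_sd, size=(H, W))
    r_cell = max(1, int(round(spec.px(spec.class_radius_um))))
    nuclei = np.zeros((H, W), dtype=np.int32)
    for row in cells.itertuples():
        _paint_disk(nuclei, row.y, row.x, r_cell, row.cell_id)
    bodies = dilate_voronoi(nuclei, spec.body_dilation_px)
    markers = [c[4:] for c in cells.columns if c.startswith("mfi_")]
    channels = {}
    id_to_row = {int(cid): i for i, cid in enumerate(cells["cell_id"])}
    body_px = {lab: np.nonzero(bodies == lab) for lab in id_to_row}
    for m in markers:
        img = bg.copy()
        vals = cells[f"mfi_{m}"].to_numpy(float)
        for lab, (yy, xx) in body_px.items():
            img[yy, xx] += vals[id_to_row[lab]]
        channels[m] = img
    return ChannelStack(
        channels=channels,
        blank_channels={"blank": bg},
        pixel_size=spec.pixel_size,
        channel_to_blank={m: "blank" for m in markers},
    )


def sample_niche_layout(spec: SyntheticTissueSpec, seed: int = 0) -> pd.DataFrame:
    """Place niche centres only (um coordinates), without cells or images.

    Useful for transcript-level work where the field is several millimetres
    and a full pixel-level biopsy would be unnecessary.
    """
    rng = np.random.default_rng(seed)
    H, W = spec.image_shape
    h_um, w_um = H * spec.pixel_size, W * spec.pixel_size
    rows = []
    centers: list[tuple[float, float, float]] = []
    nid = 0
    for t, ns in enumerate(spec.niche_specs):
        for _ in range(ns.n_per_biopsy):
            for _attempt in range(500):
                y = rng.uniform(ns.radius_um, h_um - ns.radius_um)
                x = rng.uniform(ns.radius_um, w_um - ns.radius_um)
                if all((y - oy) ** 2 + (x - ox) ** 2
                       >= (ns.radius_um + orr + spec.niche_spacing_um) ** 2
                       for oy, ox, orr in centers):
                    centers.append((y, x, ns.radius_um))
                    break
            else:
                raise PlacementError("niche", f"could not place niche of type {t}")
            rows.append({"niche_id": nid, "niche_type": t, "x_um": x, "y_um": y,
                         "radius_um": ns.radius_um})
            nid += 1
    return pd.DataFrame(rows, columns=["niche_id", "niche_type", "x_um", "y_um", "radius_um"])


def place_transcripts(niches: pd.DataFrame | GroundTruth,
                      spec: SyntheticTissueSpec, seed: int = 0) -> pd.DataFrame:
    """Poisson transcript point patterns inside each planted niche footprint.

    Per niche and gene, the count is Poisson with the niche-type's rate and
    positions are uniform in the niche disk (um coordinates).  Returns a
    table with columns ``x, y, gene, niche_id, niche_type``.
    """
    if isinstance(niches, GroundTruth):
        niches = niches.niches
    rng = np.random.default_rng(seed)
    rows = []
    for row in niches.itertuples():
        t = int(row.niche_type)
        if t not in spec.transcript_rates:
            raise ConfigError(f"no transcript rates for niche type {t}")
        for gene, rate in sorted(spec.transcript_rates[t].items()):
            if rate < 0:
                raise ConfigError(f"negative transcript rate for gene {gene!r}")
            n = rng.poisson(rate)
            rr = row.radius_um * np.sqrt(rng.uniform(size=n))
            th = rng.uniform(0, 2 * math.pi, size=n)
            xs = np.maximum(row.x_um + rr * np.cos(th), 0.0)
            ys = np.maximum(row.y_um + rr * np.sin(th), 0.0)
            for x, y in zip(xs, ys):
                rows.append({"x": x, "y": y, "gene": gene,
                             "niche_id": row.niche_id, "niche_type": t})
    return pd.DataFrame(rows, columns=["x", "y", "gene", "niche_id", "niche_type"])
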