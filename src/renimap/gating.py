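"""Multi-Otsu marker thresholds and hierarchical decision-tree annotation.

Cells are assigned to classes the way flow cytometrists gate: a binary tree
of marker-positivity decisions whose leaves are cell classes.  Positivity
thresholds come from multi-Otsu applied to each marker's MFI distribution
over the pooled cell set, with the candidate threshold chosen to agree with
a small set of manually validated positive cells ("spot validation").
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.filters import threshold_multiotsu

from renimap.errors import ConfigError

NON_CLASSIFIED = "non-classified"

__all__ = [
    "NON_CLASSIFIED",
    "GatingTree",
    "ThresholdSet",
    "SpotReference",
    "load_default_tree",
    "multi_otsu_thresholds",
    "select_threshold",
    "compute_threshold_set",
    "gate_cells",
]


def multi_otsu_thresholds(values: np.ndarray, k_classes: int = 3, nbins: int = 256) -> np.ndarray:
    """Multi-Otsu thresholds (k-1 of them) maximizing between-class variance.

    The sample is binned into ``nbins`` histogram bins and the thresholds that
    maximize between-class variance are found exhaustively (delegated to
    scikit-image).  Requires at least ``k_classes`` distinct values.
    """
    values = np.asarray(values, dtype=float).ravel()
    if np.unique(values).size < k_classes:
        raise ConfigError(
            f"need at least {k_classes} distinct values for {k_classes}-class Otsu"
        )
    return threshold_multiotsu(values, classes=k_classes, nbins=nbins)


@dataclass
class SpotReference:
    """MFIs of manually validated positive cells for one marker."""

    marker: str
    positive_mfis: np.ndarray

    def __post_init__(self):
        self.positive_mfis = np.asarray(self.positive_mfis, dtype=float)
        if self.positive_mfis.size and not np.isfinite(self.positive_mfis).all():
            raise ConfigError(f"non-finite spot-reference MFI for {self.marker}")


def select_threshold(candidates: np.ndarray, ref: SpotReference | None) -> tuple[float, str]:
    """Pick the multi-Otsu candidate most consistent with spot validation.

    Returns the largest candidate t with every reference-positive MFI >= t;
    if none qualifies, the candidate with the fewest violations (ties to the
    smaller t).  With no reference the smallest candidate is returned with
    provenance ``"default"``.
    """
    candidates = np.sort(np.asarray(candidates, dtype=float))
    if candidates.size == 0:
        raise ConfigError("no candidate thresholds")
    if ref is None or ref.positive_mfis.size == 0:
        return float(candidates[0]), "default"
    pos = ref.positive_mfis
    consistent = [t for t in candidates if (pos >= t).all()]
    if consistent:
        return float(consistent[-1]), f"spot:{ref.marker}"
    violations = np.array([(pos < t).sum() for t in candidates])
    return float(candidates[int(np.argmin(violations))]), f"spot:{ref.marker}"


@dataclass
class ThresholdSet:
    """Selected per-marker thresholds with their multi-Otsu candidates."""

    candidates: dict[str, np.ndarray] = field(default_factory=dict)
    selected: dict[str, float] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, marker: str) -> float:
        return self.selected[marker]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "candidates": {m: list(map(float, c)) for m, c in self.candidates.items()},
            "selected": self.selected,
            "provenance": self.provenance,
        }, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ThresholdSet":
        d = json.loads(Path(path).read_text())
        return cls(
            candidates={m: np.asarray(c) for m, c in d["candidates"].items()},
            selected=d["selected"],
            provenance=d["provenance"],
        )


class GatingTree:
    """Hierarchical marker-decision tree whose leaves are cell classes.

    Nodes are dicts ``{"marker": name, "positive": child, "negative": child}``;
    leaves are ``{"class": name}`` with ``null`` meaning non-classified.  A
    valid tree tests each marker at most once along any root-to-leaf path and
    its named leaves are unique.
    """

    def __init__(self, root: dict, name: str = "gating-tree"):
        self.root = root
        self.name = name
        self._validate(root, set())
        leaves = self.leaf_classes()
        if len(leaves) != len(set(leaves)):
            dupes = sorted({c for c in leaves if leaves.count(c) > 1})
            raise ConfigError(f"duplicate leaf classes: {dupes}")

    @staticmethod
    def _validate(node: dict, seen: set[str]) -> None:
        if "class" in node:
            return
        marker = node.get("marker")
        if marker is None or "positive" not in node or "negative" not in node:
            raise ConfigError(f"malformed tree node: {node}")
        if marker in seen:
            raise ConfigError(f"marker {marker!r} tested twice on one path")
        for child in (node["positive"], node["negative"]):
            GatingTree._validate(child, seen | {marker})

    def leaf_classes(self) -> list[str]:
        out: list[str] = []

        def walk(node: dict):
            if "class" in node:
                if node["class"] is not None:
                    out.append(node["class"])
            else:
                walk(node["positive"])
                walk(node["negative"])

        walk(self.root)
        return out

    def markers(self) -> list[str]:
        out: set[str] = set()

        def walk(node: dict):
            if "class" not in node:
                out.add(node["marker"])
                walk(node["positive"])
                walk(node["negative"])

        walk(self.root)
        return sorted(out)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_classes())

    @classmethod
    def from_json(cls, path: str | Path) -> "GatingTree":
        d = json.loads(Path(path).read_text())
        return cls(d["root"], name=d.get("name", Path(path).stem))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GatingTree":
        import yaml

        d = yaml.safe_load(Path(path).read_text())
        return cls(d["root"], name=d.get("name", Path(path).stem))


def load_default_tree() -> GatingTree:
    """The shipped renal gating schema: 33 leaf classes over 26 markers."""
    with resources.files("renimap.data").joinpath("gating_tree.json").open() as fh:
        d = json.load(fh)
    return GatingTree(d["root"], name=d["name"])


def compute_threshold_set(
    cells: pd.DataFrame,
    markers: list[str],
    k_classes: int | dict[str, int] = 3,
    spot_refs: dict[str, SpotReference] | None = None,
    prefix: str = "z_",
) -> ThresholdSet:
    """Multi-Otsu candidates plus spot-validated selection for each marker.

    Thresholding operates on the standardized MFI columns (``z_<marker>``) of
    the pooled cell table, so cohorts share one threshold per marker.
    """
    spot_refs = spot_refs or {}
    ts = ThresholdSet()
    for m in markers:
        col = prefix + m
        if col not in cells.columns:
            raise ConfigError(f"marker column {col!r} missing from cell table")
        k = k_classes[m] if isinstance(k_classes, dict) else k_classes
        cand = multi_otsu_thresholds(cells[col].to_numpy(), k_classes=k)
        sel, prov = select_threshold(cand, spot_refs.get(m))
        ts.candidates[m] = cand
        ts.selected[m] = sel
        ts.provenance[m] = prov
    return ts


def gate_cells(
    cells: pd.DataFrame,
    tree: GatingTree,
    thresholds: ThresholdSet | dict[str, float],
    prefix: str = "z_",
) -> pd.DataFrame:
    """Assign every cell to a leaf class (or ``non-classified``).

    A cell is positive for a marker iff its ``<prefix><marker>`` value is >=
    the selected threshold.  Each cell follows exactly one root-to-leaf path;
    the path taken is recorded in the ``gate_path`` column (e.g.
    ``"CD45+>CD3+>TCRgd-"``) as an audit trail.
    """
    selected = thresholds.selected if isinstance(thresholds, ThresholdSet) else thresholds
    for m in tree.markers():
        if prefix + m not in cells.columns:
            raise ConfigError(f"marker column {prefix + m!r} missing from cell table")
        if m not in selected:
            raise ConfigError(f"no threshold selected for marker {m!r}")
    n = len(cells)
    labels = np.full(n, NON_CLASSIFIED, dtype=object)
    paths = np.full(n, "", dtype=object)

    def walk(node: dict, idx: np.ndarray, trail: str):
        if not idx.size:
            return
        if "class" in node:
            labels[idx] = node["class"] if node["class"] is not None else NON_CLASSIFIED
            paths[idx] = trail
            return
        m = node["marker"]
        pos = cells[prefix + m].to_numpy(float)[idx] >= selected[m]
        sep = ">" if trail else ""
        walk(node["positive"], idx[pos], f"{trail}{sep}{m}+")
        walk(node["negative"], idx[~pos], f"{trail}{sep}{m}-")

    walk(tree.root, np.arange(n), "")
    out = cells.copy()
    out["class_label"] = labels
    out["gate_path"] = paths
    return out
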