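"""Boxes, centers of mass, point sampling and the grid pooling step.

The detection pipeline reasons about a tooth through three geometric
summaries: its axis-aligned bounding box, the 8192-point sample drawn from the
expanded box, and the center of mass (COM) of the points classified as tooth.
A scan-wide summary — the mean COM and its axial (z) component — acts as a
watershed separating upper from lower jaw when a scan contains both.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import EmptyDetectionError
from .mesh_io import PointCloud


@dataclass(frozen=True)
class Box3:
    """Axis-aligned box in mm."""

    min_corner: np.ndarray
    max_corner: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "min_corner", np.asarray(self.min_corner, float))
        object.__setattr__(self, "max_corner", np.asarray(self.max_corner, float))
        if self.min_corner.shape != (3,) or self.max_corner.shape != (3,):
            raise ValueError("box corners must be 3-vectors")
        if np.any(self.min_corner > self.max_corner):
            raise ValueError("min_corner must be <= max_corner componentwise")

    @property
    def center(self) -> np.ndarray:
        return 0.5 * (self.min_corner + self.max_corner)

    @property
    def size(self) -> np.ndarray:
        return self.max_corner - self.min_corner

    @property
    def volume(self) -> float:
        return float(np.prod(self.size))

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside or on the boundary."""
        p = np.atleast_2d(np.asarray(points, float))
        return np.all((p >= self.min_corner) & (p <= self.max_corner), axis=1)


@dataclass
class ToothDetection:
    """One detected tooth instance.

    ``mask`` holds the binary tooth(1)/gingiva(0) class per point; ``com`` is
    the center of the tooth-class points (or the instance's nominal center
    when constructed synthetically).
    """

    detection_id: int
    com: np.ndarray
    box: Box3
    points: np.ndarray | None = None        # (n, 3) mm
    mask: np.ndarray | None = None          # (n,) uint8

    def __post_init__(self):
        self.com = np.asarray(self.com, float)
        if self.points is not None:
            self.points = np.asarray(self.points, float)
        if self.mask is not None:
            self.mask = np.asarray(self.mask, np.uint8)
            if self.points is not None and len(self.mask) != len(self.points):
                raise ValueError("mask length must equal point count")

    @property
    def n_points(self) -> int:
        return 0 if self.points is None else len(self.points)


@dataclass
class ArchScene:
    """All detections of one scan plus global COM statistics.

    ``com_global`` is the mean of the detection COMs; ``watershed_z`` its z
    component, which roughly separates the two half jaws in a bimaxillary
    scan.  ``jaw_hint`` records, when known, that the scan covers a single
    jaw; it overrides the watershed test downstream.  ``fdi_labels`` carries
    ground-truth FDI codes (detection_id -> code) when the scene is annotated.
    """

    detections: list[ToothDetection]
    com_global: np.ndarray
    watershed_z: float
    jaw_hint: str | None = None             # 'upper' | 'lower' | 'both' | None
    fdi_labels: dict[int, int] | None = None

    def coms(self) -> np.ndarray:
        return np.array([d.com for d in self.detections])

    def __len__(self) -> int:
        return len(self.detections)


def compute_tooth_bbox(points: np.ndarray) -> Box3:
    """Minimum axis-aligned bounding box around a tooth's points."""
    p = np.atleast_2d(np.asarray(points, float))
    if p.size == 0:
        raise ValueError("cannot bound an empty point set")
    return Box3(p.min(axis=0), p.max(axis=0))


def expand_box(box: Box3, factor: float) -> Box3:
    """Scale a box about its own center by ``factor`` per axis."""
    if factor <= 0:
        raise ValueError("expansion factor must be positive")
    half = 0.5 * factor * box.size
    c = box.center
    return Box3(c - half, c + half)


def sample_points_in_box(
    cloud: PointCloud, box: Box3, n: int = 8192, seed: int = 0
) -> tuple[np.ndarray, np.ndarray | None]:
    """Draw exactly ``n`` cloud points lying inside ``box``.

    Sampling is uniform without replacement when at least ``n`` candidates
    exist, with replacement otherwise, so the fixed-size contract holds for
    sparse boxes.  Returns (points, classes); classes is None when the cloud
    carries no per-point class.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    inside = np.flatnonzero(box.contains(cloud.points))
    if inside.size == 0:
        raise EmptyDetectionError("no cloud points inside the sampling box")
    rng = np.random.default_rng(seed)
    idx = rng.choice(inside, size=n, replace=inside.size < n)
    classes = None if cloud.classes is None else cloud.classes[idx]
    return cloud.points[idx], classes


def center_of_mass(points: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Unweighted mean of the tooth-class points."""
    p = np.atleast_2d(np.asarray(points, float))
    if mask is not None:
        p = p[np.asarray(mask).astype(bool)]
    if len(p) == 0:
        raise ValueError("no tooth-class points: center of mass undefined")
    return p.mean(axis=0)


def build_detection(
    cloud: PointCloud,
    box: Box3,
    detection_id: int = 0,
    expansion_factor: float = 1.2,
    n: int = 8192,
    seed: int = 0,
) -> ToothDetection:
    """Extract a detection from a raw box proposal: expand, sample, locate COM."""
    expanded = expand_box(box, expansion_factor)
    points, classes = sample_points_in_box(cloud, expanded, n=n, seed=seed)
    mask = np.ones(len(points), np.uint8) if classes is None else classes
    com = center_of_mass(points, mask)
    return ToothDetection(detection_id, com, expanded, points, mask)


def build_scene(
    detections: list[ToothDetection],
    jaw_hint: str | None = None,
    fdi_labels: dict[int, int] | None = None,
) -> ArchScene:
    """Assemble an :class:`ArchScene`, deriving the global COM and watershed."""
    if not detections:
        raise ValueError("a scene needs at least one detection")
    com_global = np.mean([d.com for d in detections], axis=0)
    return ArchScene(
        detections=list(detections),
        com_global=com_global,
        watershed_z=float(com_global[2]),
        jaw_hint=jaw_hint,
        fdi_labels=fdi_labels,
    )


def box_iou(a: Box3, b: Box3) -> float:
    """Intersection volume over union volume of two axis-aligned boxes."""
    lo = np.maximum(a.min_corner, b.min_corner)
    hi = np.minimum(a.max_corner, b.max_corner)
    inter = float(np.prod(np.maximum(hi - lo, 0.0)))
    union = a.volume + b.volume - inter
    if union == 0.0:  # both degenerate
        return 1.0 if np.array_equal(a.min_corner, b.min_corner) else 0.0
    return inter / union


@dataclass
class FeatureGrid:
    """Dense Cartesian grid of max-pooled point features."""

    values: np.ndarray          # (nx, ny, nz, n_features)
    origin: np.ndarray          # min corner of the grid (mm)
    cell_size: float

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape[:3]


def grid_max_pool(cloud: PointCloud, cell_size: float) -> FeatureGrid:
    """Max-pool per-point features onto a Cartesian grid.

    The grid spans the cloud's bounding box; each occupied cell holds the
    componentwise maximum of its points' feature vectors, empty cells hold 0.
    """
    if cloud.features is None:
        raise ValueError("cloud has no per-point features to pool")
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    pts = cloud.points
    feats = np.asarray(cloud.features, float)
    origin = pts.min(axis=0)
    idx = np.floor((pts - origin) / cell_size).astype(int)
    shape = idx.max(axis=0) + 1
    # accumulate the max with -inf sentinel, then zero-fill empty cells
    grid = np.full((*shape, feats.shape[1]), -np.inf)
    np.maximum.at(grid, (idx[:, 0], idx[:, 1], idx[:, 2]), feats)
    grid[np.isinf(grid)] = 0.0
    return FeatureGrid(grid, origin, float(cell_size))


# --- scene (de)serialization -------------------------------------------------

def scene_to_dict(scene: ArchScene, include_points: bool = False) -> dict:
    out = {
        "detections": [],
        "com_global": scene.com_global.tolist(),
        "watershed_z": scene.watershed_z,
        "jaw_hint": scene.jaw_hint,
    }
    if scene.fdi_labels is not None:
        out["fdi_labels"] = {str(k): v for k, v in scene.fdi_labels.items()}
    for d in scene.detections:
        rec = {
            "id": d.detection_id,
            "com": d.com.tolist(),
            "box": {"min": d.box.min_corner.tolist(), "max": d.box.max_corner.tolist()},
            "n_points": d.n_points,
        }
        if d.mask is not None:
            rec["mask_counts"] = {
                "tooth": int(d.mask.sum()),
                "gingiva": int(len(d.mask) - d.mask.sum()),
            }
        if include_points and d.points is not None:
            rec["points"] = d.points.tolist()
            if d.mask is not None:
                rec["mask"] = d.mask.tolist()
        out["detections"].append(rec)
    return out


def scene_from_dict(data: dict) -> ArchScene:
    detections = []
    for rec in data["detections"]:
        box = Box3(rec["box"]["min"], rec["box"]["max"])
        points = np.array(rec["points"], float) if "points" in rec else None
        mask = np.array(rec["mask"], np.uint8) if "mask" in rec else None
        detections.append(
            ToothDetection(int(rec["id"]), np.array(rec["com"]), box, points, mask)
        )
    labels = data.get("fdi_labels")
    if labels is not None:
        labels = {int(k): int(v) for k, v in labels.items()}
    return ArchScene(
        detections=detections,
        com_global=np.array(data["com_global"], float),
        watershed_z=float(data["watershed_z"]),
        jaw_hint=data.get("jaw_hint"),
        fdi_labels=labels,
    )


def save_scene(scene: ArchScene, path: str | Path, include_points: bool = False) -> None:
    Path(path).write_text(json.dumps(scene_to_dict(scene, include_points)))


def load_scene(path: str | Path) -> ArchScene:
    return scene_from_dict(json.loads(Path(path).read_text()))
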