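"""Synthetic dental arches and simulated detector output.

The labeling algorithm consumes only geometric summaries — per-tooth COMs,
boxes and point masks — so the generator models an arch as 16 box-shaped
point clusters stationed along a parabolic curve in the occlusal plane, with
per-code mesiodistal/buccolingual/height extents taken from standard adult
crown dimensions.  Slot stations are spaced by crown width along the arc, so
the pairwise COM distances carry the same positional regularities a distance
prior estimated from real scans would.

A simulated detector degrades the ground truth with the error modes a
detection+segmentation network exhibits: missed teeth, per-axis Gaussian COM
jitter, mask flips concentrated at cluster boundaries (cervical errors), and
spurious detections between slots.  All randomness is seeded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import fdi
from .geometry import ArchScene, Box3, ToothDetection, build_scene
from .labeling import DistancePrior
from .mesh_io import LabeledMesh

# Mesiodistal, buccolingual and crown-height extents (mm) by tooth position
# 1 (central incisor) .. 8 (third molar); standard adult crown dimensions.
_TOOTH_DIMS = {
    fdi.UPPER: {
        1: (8.5, 7.0, 10.5),
        2: (6.5, 6.0, 9.0),
        3: (7.5, 8.0, 10.0),
        4: (7.0, 9.0, 8.5),
        5: (6.8, 9.0, 8.5),
        6: (10.0, 11.0, 7.5),
        7: (9.0, 11.0, 7.0),
        8: (8.5, 10.5, 6.5),
    },
    fdi.LOWER: {
        1: (5.0, 6.0, 9.0),
        2: (5.5, 6.5, 9.5),
        3: (7.0, 7.5, 11.0),
        4: (7.0, 8.0, 8.5),
        5: (7.0, 8.5, 8.0),
        6: (11.0, 10.5, 7.5),
        7: (10.5, 10.0, 7.0),
        8: (10.0, 9.5, 7.0),
    },
}

# width/depth aspect of the arch curve before arc-length scaling
_ARCH_ASPECT = {fdi.UPPER: (55.0, 47.0), fdi.LOWER: (52.0, 44.0)}

# relative propensity of a position to be congenitally missing / undetected;
# third molars dominate, then premolars
_MISSING_WEIGHT = {1: 1, 2: 1, 3: 1, 4: 2, 5: 3, 6: 1, 7: 1, 8: 8}


@dataclass
class ArchTemplate:
    """Deterministic geometric model of one adult dental arch."""

    jaw: str
    codes: tuple[int, ...]            # 16 codes in arch order
    slot_positions: np.ndarray        # (16, 3) mm, x strictly increasing
    tooth_sizes: np.ndarray           # (16, 3) mm extents per slot
    curve_points: np.ndarray          # dense (P, 3) polyline of the arch curve
    curve_arclength: np.ndarray       # (P,) cumulative arc length

    def slot_of(self, code: int) -> int:
        return self.codes.index(code)

    def point_at_arclength(self, s: float) -> np.ndarray:
        """Interpolated curve point at arc-length station ``s``."""
        return np.array(
            [
                np.interp(s, self.curve_arclength, self.curve_points[:, k])
                for k in range(3)
            ]
        )


def default_template(jaw: str) -> ArchTemplate:
    """Anatomically plausible adult arch with 16 slots in arch order.

    The arch curve is a parabola in the occlusal plane, uniformly scaled so
    its arc length equals the summed mesiodistal crown widths; each slot
    center sits at the arc-length midpoint of its crown, with a mild
    quadratic z term (curve of Spee) raising the molars by up to ~1 mm.
    """
    if jaw not in (fdi.UPPER, fdi.LOWER):
        raise ValueError(f"jaw must be 'upper' or 'lower', got {jaw!r}")
    codes = fdi.ARCH_ORDER[jaw]
    sizes = np.array([_TOOTH_DIMS[jaw][c % 10] for c in codes])
    widths = sizes[:, 0]
    total = float(widths.sum())

    w0, d0 = _ARCH_ASPECT[jaw]
    x0 = np.linspace(-w0 / 2, w0 / 2, 4001)
    y0 = d0 * (1.0 - (2 * x0 / w0) ** 2)
    seg = np.hypot(np.diff(x0), np.diff(y0))
    length0 = float(seg.sum())
    scale = total / length0
    x, y = x0 * scale, y0 * scale
    arclen = np.concatenate([[0.0], np.cumsum(seg * scale)])

    stations = np.cumsum(widths) - widths / 2
    sx = np.interp(stations, arclen, x)
    sy = np.interp(stations, arclen, y)
    idx = np.arange(16)
    sz = 1.2 * ((idx - 7.5) / 7.5) ** 2  # curve of Spee, mm
    slots = np.column_stack([sx, sy, sz])
    curve = np.column_stack([x, y, np.zeros_like(x)])
    return ArchTemplate(
        jaw=jaw,
        codes=codes,
        slot_positions=slots,
        tooth_sizes=sizes,
        curve_points=curve,
        curve_arclength=arclen,
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Noise knobs of the simulated scan + detector.

    All rates are in [0, 1]; ``com_jitter_sigma`` is the per-axis standard
    deviation (mm) of the Gaussian COM error; ``missing_codes`` is either an
    explicit set of FDI codes absent from the arch or a count drawn with the
    documented preferential weighting (third molars, then premolars).
    """

    seed: int = 0
    missing_codes: frozenset[int] | int = frozenset()
    com_jitter_sigma: float = 0.0
    points_per_tooth: int = 200
    gingiva_points: int = 1000
    false_positive_rate: float = 0.0
    miss_rate: float = 0.0
    mask_flip_rate: float = 0.0

    def __post_init__(self):
        for name in ("false_positive_rate", "miss_rate", "mask_flip_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.com_jitter_sigma < 0:
            raise ValueError("com_jitter_sigma must be >= 0")
        if isinstance(self.missing_codes, (set, list, tuple)):
            object.__setattr__(self, "missing_codes", frozenset(self.missing_codes))


def _resolve_missing(
    template: ArchTemplate, config: SimulationConfig, rng: np.random.Generator
) -> frozenset[int]:
    m = config.missing_codes
    if isinstance(m, frozenset):
        return m
    if m >= 16:
        raise ValueError("cannot remove all 16 teeth")
    w = np.array([_MISSING_WEIGHT[c % 10] for c in template.codes], float)
    picked = rng.choice(16, size=int(m), replace=False, p=w / w.sum())
    return frozenset(template.codes[i] for i in picked)


def generate_scene(
    template: ArchTemplate, config: SimulationConfig
) -> ArchScene:
    """Ground-truth scene: one box-shaped cluster per non-missing tooth.

    Each detection holds ``points_per_tooth`` tooth points uniform in the
    tooth box plus a quarter as many cervical gingiva context points below
    it; its COM is the slot center exactly and its box the exact tooth box.
    Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng([config.seed, 0])
    missing = _resolve_missing(template, config, rng)
    detections = []
    labels: dict[int, int] = {}
    det_id = 0
    for i, code in enumerate(template.codes):
        if code in missing:
            continue
        center = template.slot_positions[i]
        half = template.tooth_sizes[i] / 2
        box = Box3(center - half, center + half)
        n = config.points_per_tooth
        tooth_pts = rng.uniform(box.min_corner, box.max_corner, size=(n, 3))
        ng = max(n // 4, 1)
        g_lo = center - np.array([half[0], half[1] + 2.0, half[2] + 3.0])
        g_hi = center + np.array([half[0], half[1] + 2.0, -half[2]])
        ging_pts = rng.uniform(g_lo, g_hi, size=(ng, 3))
        points = np.vstack([tooth_pts, ging_pts])
        mask = np.concatenate(
            [np.ones(n, np.uint8), np.zeros(ng, np.uint8)]
        )
        detections.append(ToothDetection(det_id, center.copy(), box, points, mask))
        labels[det_id] = code
        det_id += 1
    if not detections:
        raise ValueError("all teeth missing: nothing to generate")
    return build_scene(detections, jaw_hint=template.jaw, fdi_labels=labels)


def simulate_detector(
    truth: ArchScene, config: SimulationConfig
) -> tuple[ArchScene, dict[int, int | None]]:
    """Degrade a ground-truth scene into simulated detector output.

    Teeth are dropped with ``miss_rate``; survivors are translated by
    per-axis N(0, sigma) COM jitter (points and box move rigidly with the
    COM) and have a ``mask_flip_rate`` fraction of their points' classes
    flipped, farthest-from-center points first (cervical-boundary errors).
    Spurious detections appear with ``false_positive_rate`` per arch slot,
    placed between tooth stations.  Returns the predicted scene and a
    correspondence mapping predicted id -> truth id (None for spurious).
    """
    rng = np.random.default_rng([config.seed, 1])
    pred: list[ToothDetection] = []
    correspondence: dict[int, int | None] = {}
    for det in truth.detections:
        if rng.random() < config.miss_rate:
            continue
        delta = rng.normal(0.0, config.com_jitter_sigma, size=3)
        points = None if det.points is None else det.points + delta
        mask = None if det.mask is None else det.mask.copy()
        if mask is not None and points is not None and config.mask_flip_rate > 0:
            n_flip = rng.binomial(len(mask), config.mask_flip_rate)
            if n_flip:
                d = np.linalg.norm(points - (det.com + delta), axis=1)
                worst = np.argsort(-d, kind="stable")[:n_flip]
                mask[worst] = 1 - mask[worst]
        box = Box3(det.box.min_corner + delta, det.box.max_corner + delta)
        new_id = len(pred)
        pred.append(ToothDetection(new_id, det.com + delta, box, points, mask))
        correspondence[new_id] = det.detection_id
    n_spurious = rng.binomial(16, config.false_positive_rate)
    coms = truth.coms()
    span_lo, span_hi = coms.min(axis=0), coms.max(axis=0)
    for _ in range(n_spurious):
        center = rng.uniform(span_lo, span_hi)
        half = np.array([2.5, 2.5, 2.5])
        box = Box3(center - half, center + half)
        npts = max(config.points_per_tooth // 2, 1)
        pts = rng.uniform(box.min_corner, box.max_corner, size=(npts, 3))
        new_id = len(pred)
        pred.append(
            ToothDetection(new_id, center, box, pts, np.ones(npts, np.uint8))
        )
        correspondence[new_id] = None
    if pred:
        scene = build_scene(pred, jaw_hint=truth.jaw_hint)
    else:
        scene = ArchScene(
            detections=[],
            com_global=np.full(3, np.nan),
            watershed_z=float("nan"),
            jaw_hint=truth.jaw_hint,
        )
    return scene, correspondence


def template_prior(*templates: ArchTemplate) -> DistancePrior:
    """Noise-free distance prior from template slot positions.

    Equals :func:`archlabel.labeling.estimate_distance_prior` applied to
    noiseless generated scenes of the same template(s), entrywise.
    """
    if not templates:
        raise ValueError("at least one template required")
    d = np.full((32, 32), np.nan)
    support = np.zeros((32, 32), int)
    for t in templates:
        cols = [fdi.CODE_TO_COLUMN[c] for c in t.codes]
        pos = t.slot_positions
        dist = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
        d[np.ix_(cols, cols)] = dist
        sup = np.ones((16, 16), int)
        np.fill_diagonal(sup, 0)
        support[np.ix_(cols, cols)] = sup
    np.fill_diagonal(d, 0.0)
    return DistancePrior(d=d, support=support)


def merge_scenes(
    upper: ArchScene, lower: ArchScene, z_separation: float = 16.0
) -> ArchScene:
    """Combine single-jaw scenes into one bimaxillary scene.

    The upper scene is shifted up and the lower down by half the separation,
    so the watershed (mean COM z) falls between the jaws.
    """
    shift_u = np.array([0.0, 0.0, z_separation / 2])
    detections = []
    labels: dict[int, int] = {}
    for scene, shift in ((upper, shift_u), (lower, -shift_u)):
        for det in scene.detections:
            new_id = len(detections)
            detections.append(
                ToothDetection(
                    new_id,
                    det.com + shift,
                    Box3(det.box.min_corner + shift, det.box.max_corner + shift),
                    None if det.points is None else det.points + shift,
                    None if det.mask is None else det.mask.copy(),
                )
            )
            if scene.fdi_labels is not None:
                labels[new_id] = scene.fdi_labels[det.detection_id]
    return build_scene(detections, jaw_hint="both", fdi_labels=labels or None)


_BOX_FACES = np.array(
    [
        [0, 1, 3], [0, 3, 2], [4, 6, 7], [4, 7, 5],
        [0, 4, 5], [0, 5, 1], [2, 3, 7], [2, 7, 6],
        [0, 2, 6], [0, 6, 4], [1, 5, 7], [1, 7, 3],
    ]
)


def scene_to_mesh(scene: ArchScene) -> LabeledMesh:
    """Toy triangulated mesh of a scene: one 12-triangle box per tooth.

    Instance k+1 covers detection k's bounding box; a flat gingiva ribbon
    spanning the arch underneath carries label 0.  Geometrically primitive
    on purpose — it exercises mesh I/O and annotation plumbing, not crown
    morphology.
    """
    vertices = []
    faces = []
    face_labels = []
    fdi_map = {}
    for inst, det in enumerate(scene.detections, start=1):
        lo, hi = det.box.min_corner, det.box.max_corner
        corners = np.array(
            [[x, y, z] for x in (lo[0], hi[0]) for y in (lo[1], hi[1])
             for z in (lo[2], hi[2])]
        )
        base = len(vertices)
        vertices.extend(corners)
        faces.extend((_BOX_FACES + base).tolist())
        face_labels.extend([inst] * 12)
        if scene.fdi_labels is not None and det.detection_id in scene.fdi_labels:
            fdi_map[inst] = scene.fdi_labels[det.detection_id]
    # gingiva ribbon under the arch: strip between the COM polyline +- 4 mm in y
    coms = scene.coms()
    order = np.argsort(coms[:, 0])
    path = coms[order]
    z = float(path[:, 2].min() - 6.0)
    for i in range(len(path) - 1):
        a, b = path[i], path[i + 1]
        base = len(vertices)
        vertices.extend(
            [
                [a[0], a[1] - 4, z], [a[0], a[1] + 4, z],
                [b[0], b[1] - 4, z], [b[0], b[1] + 4, z],
            ]
        )
        faces.extend([[base, base + 1, base + 2], [base + 1, base + 3, base + 2]])
        face_labels.extend([0, 0])
    return LabeledMesh(
        vertices=np.array(vertices, float),
        faces=np.array(faces, int),
        face_labels=np.array(face_labels, int),
        fdi_map=fdi_map or None,
    )
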