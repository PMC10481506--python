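"""Dental mesh I/O and uniform downsampling.

An intra-oral scan (OS) is a triangle mesh of one dental arch, annotated by
assigning every triangle to a tooth instance or to gingiva.  Mesh formats
(PLY/OBJ/STL) carry no per-face instance labels, so annotations travel in a
JSON sidecar with the same basename: ``{"face_labels": [...], "fdi_map":
{...}}`` where label 0 means gingiva and k > 0 a tooth instance.

Mesh parsing and serialization delegate to :mod:`trimesh`; meshes are loaded
with ``process=False`` so vertex order and indexing survive a round-trip
(STL, which stores bare triangle soup, necessarily re-expands vertices).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh

from . import fdi
from .errors import AnnotationError, MeshFormatError

_FORMATS = {"ply", "obj", "stl"}


@dataclass
class LabeledMesh:
    """Triangle mesh with optional per-face instance annotation."""

    vertices: np.ndarray                 # (V, 3) mm
    faces: np.ndarray                    # (F, 3) int
    face_labels: np.ndarray | None = None   # (F,) int; 0 = gingiva
    fdi_map: dict[int, int] | None = None   # instance id -> FDI code

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, int).reshape(-1, 3)
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("face index out of range")
        if self.face_labels is not None:
            self.face_labels = np.asarray(self.face_labels, int)
            if len(self.face_labels) != len(self.faces):
                raise AnnotationError(
                    f"{len(self.face_labels)} face labels for "
                    f"{len(self.faces)} faces"
                )
        if self.fdi_map:
            present = set() if self.face_labels is None else set(
                np.unique(self.face_labels).tolist()
            )
            for inst, code in self.fdi_map.items():
                if inst not in present:
                    raise AnnotationError(
                        f"fdi_map instance {inst} absent from face_labels"
                    )
                if not fdi.is_valid_code(code):
                    raise AnnotationError(f"invalid FDI code {code}")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)


@dataclass
class PointCloud:
    """Point set in mm with optional per-point features and binary class."""

    points: np.ndarray                   # (N, 3)
    features: np.ndarray | None = None   # (N, F)
    classes: np.ndarray | None = None    # (N,) uint8: tooth=1 / gingiva=0

    def __post_init__(self):
        self.points = np.asarray(self.points, float).reshape(-1, 3)
        if not np.all(np.isfinite(self.points)):
            raise ValueError("point coordinates must be finite")
        if self.features is not None:
            self.features = np.atleast_2d(np.asarray(self.features, float))
            if len(self.features) != len(self.points):
                raise ValueError("features must align with points")
        if self.classes is not None:
            self.classes = np.asarray(self.classes, np.uint8)
            if len(self.classes) != len(self.points):
                raise ValueError("classes must align with points")

    def __len__(self) -> int:
        return len(self.points)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _infer_format(path: Path, format: str | None) -> str:
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in _FORMATS:
        raise MeshFormatError(f"unsupported mesh format: {fmt!r}")
    return fmt


def read_mesh(path: str | Path, format: str | None = None) -> LabeledMesh:
    """Read a PLY/OBJ/STL mesh, loading the JSON label sidecar if present."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        tm = trimesh.load(path, file_type=fmt, process=False, force="mesh")
    except Exception as exc:  # trimesh raises a zoo of types
        raise MeshFormatError(f"cannot parse {path} as {fmt}: {exc}") from exc
    if not isinstance(tm, trimesh.Trimesh):
        raise MeshFormatError(f"{path} does not contain a triangle mesh")

    face_labels = None
    fdi_map = None
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        ann = json.loads(sidecar.read_text())
        face_labels = np.asarray(ann.get("face_labels", []), int)
        fdi_map = {int(k): int(v) for k, v in ann.get("fdi_map", {}).items()}
        if len(face_labels) != len(tm.faces):
            raise AnnotationError(
                f"sidecar {sidecar.name} has {len(face_labels)} labels for "
                f"{len(tm.faces)} faces"
            )
    return LabeledMesh(
        vertices=np.asarray(tm.vertices, float),
        faces=np.asarray(tm.faces, int),
        face_labels=face_labels,
        fdi_map=fdi_map or None,
    )


def write_mesh(mesh: LabeledMesh, path: str | Path, format: str | None = None) -> None:
    """Write a mesh; non-empty labels go to the JSON sidecar."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "stl" and mesh.face_labels is not None:
        warnings.warn(
            "STL stores bare triangles and carries no labels; "
            "annotation written to the JSON sidecar only",
            stacklevel=2,
        )
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    path.parent.mkdir(parents=True, exist_ok=True)
    tm.export(path, file_type=fmt)
    if mesh.face_labels is not None and len(mesh.face_labels):
        ann = {"face_labels": mesh.face_labels.tolist()}
        if mesh.fdi_map:
            ann["fdi_map"] = {str(k): int(v) for k, v in mesh.fdi_map.items()}
        _sidecar_path(path).write_text(json.dumps(ann))


def downsample_uniform(
    mesh: LabeledMesh, target: int = 30000, seed: int = 0
) -> PointCloud:
    """Uniform random vertex subsample of ``min(target, n_vertices)`` points.

    Vertices are drawn without replacement under ``seed``; when the mesh is
    annotated, each sampled vertex inherits the binary tooth/gingiva class of
    the majority of its incident faces (ties go to gingiva).
    """
    if target < 1:
        raise ValueError("target must be >= 1")
    n = mesh.n_vertices
    rng = np.random.default_rng(seed)
    k = min(target, n)
    idx = rng.choice(n, size=k, replace=False)

    classes = None
    if mesh.face_labels is not None and mesh.n_faces:
        tooth_votes = np.zeros(n)
        total_votes = np.zeros(n)
        is_tooth_face = (mesh.face_labels > 0).astype(float)
        for col in range(3):
            np.add.at(tooth_votes, mesh.faces[:, col], is_tooth_face)
            np.add.at(total_votes, mesh.faces[:, col], 1.0)
        classes = (tooth_votes[idx] > 0.5 * total_votes[idx]).astype(np.uint8)
    return PointCloud(points=mesh.vertices[idx], classes=classes)
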