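"""Mesh-side preprocessing: I/O, downsampling, box sampling, grid pooling.

Converts a synthetic arch into an annotated triangle mesh, round-trips it
through PLY with its JSON label sidecar, downsamples the vertices uniformly,
extracts one tooth's 8192-point detection sample from its expanded bounding
box, and max-pools toy per-point features onto a Cartesian grid.
"""

import tempfile
from pathlib import Path

import numpy as np

import archlabel as al

template = al.default_template("lower")
scene = al.generate_scene(template, al.SimulationConfig(seed=3))
mesh = al.scene_to_mesh(scene)
print(f"synthetic arch mesh: {mesh.n_vertices} vertices, {mesh.n_faces} faces, "
      f"{len(set(mesh.fdi_map.values()))} teeth")

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "arch.ply"
    al.write_mesh(mesh, path)
    back = al.read_mesh(path)
    print("PLY round trip preserves labels:",
          np.array_equal(back.face_labels, mesh.face_labels))

cloud = al.downsample_uniform(mesh, target=30_000, seed=0)
print(f"downsampled to {len(cloud)} of {mesh.n_vertices} vertices "
      f"({int(cloud.classes.sum())} tooth-class)")

# detection sample for one tooth: expand its box, draw 8192 points
det = scene.detections[5]
full_cloud = al.PointCloud(
    np.vstack([d.points for d in scene.detections]),
    classes=np.concatenate([d.mask for d in scene.detections]),
)
sample = al.build_detection(full_cloud, det.box, expansion_factor=1.2, seed=0)
print(f"tooth {scene.fdi_labels[5]}: sampled {sample.n_points} points, "
      f"{int(sample.mask.sum())} tooth / {int((1 - sample.mask).sum())} gingiva, "
      f"COM offset {np.linalg.norm(sample.com - det.com):.2f} mm")

feats = al.PointCloud(cloud.points, features=cloud.points[:, 2:3])
grid = al.grid_max_pool(feats, cell_size=5.0)
print(f"max-pooled z-feature grid: {grid.shape} cells of {grid.cell_size} mm")
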