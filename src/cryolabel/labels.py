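"""Voxel-aligned label-map generation — the core method of this package.

From an atomic assembly, a (standardized) experimental grid and a simulated
noise-free map, three label grids are produced on the experimental geometry:

* **regression** — simulated density copied at every labeled voxel, 0
  elsewhere: a noise-free regression target.
* **classification** — 1 at each atom's own voxel, 2 at neighbor voxels
  within ``radius`` Å of the atomic coordinate, 0 background.
* **atom_type** — the atom-class code (Cα=1, Cβ=2, carbonyl C=3, O=4, N=5)
  at direct atom voxels only; the chemistry of neighbor voxels is ambiguous
  and they stay 0.

An atom contributes labels only if its floored (i, j, k) index is in bounds
on the experimental grid AND its coordinate lies inside the simulated map's
physical extent (dual validation).  Direct labels (1) take precedence over
neighbor labels (2) at contested voxels.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .config import RunConfig
from .exceptions import EmptyLabelWarning, EmptyStructureError, InvalidParameterError, PipelineError
from .grid import VoxelGrid, floor_indices, in_bounds, resample_to_voxel_size
from .mrc import read_mrc, write_mrc
from .pdb import Structure, classify_atom, read_assembly
from .simulate import KernelSpec, sample_at_many, simulate_map

__all__ = ["LabelMapSet", "neighbor_indices", "generate_labels", "run_record"]


@dataclass
class LabelMapSet:
    """The aligned triple of label grids plus the neighborhood radius used."""

    regression: VoxelGrid
    classification: VoxelGrid
    atom_type: VoxelGrid
    radius: float

    def __post_init__(self) -> None:
        if not (self.regression.same_geometry(self.classification)
                and self.regression.same_geometry(self.atom_type)):
            raise InvalidParameterError("label grids must share one geometry")
        cls_vals = np.unique(self.classification.values)
        if not np.isin(cls_vals, [0, 1, 2]).all():
            raise InvalidParameterError(f"classification values outside {{0,1,2}}: {cls_vals}")
        at_vals = np.unique(self.atom_type.values)
        if not np.isin(at_vals, [0, 1, 2, 3, 4, 5]).all():
            raise InvalidParameterError(f"atom-type values outside 0..5: {at_vals}")
        if np.any(self.regression.values[self.classification.values == 0] != 0):
            raise InvalidParameterError("regression must be 0 where classification is 0")


def _neighbor_window(point, grid: VoxelGrid, radius: float):
    """In-bounds neighbor indices (arrays iz, jy, kx) around a point, plus
    the atom's own floored index (not removed here)."""
    cx, cy, cz = point
    axes = []
    for c, o, v, n in ((cz, grid.origin[2], grid.voxel[2], grid.dims[0]),
                       (cy, grid.origin[1], grid.voxel[1], grid.dims[1]),
                       (cx, grid.origin[0], grid.voxel[0], grid.dims[2])):
        lo = max(0, int(np.floor((c - radius - o) / v - 0.5)))
        hi = min(n - 1, int(np.ceil((c + radius - o) / v - 0.5)))
        if hi < lo:
            return None
        idx = np.arange(lo, hi + 1)
        axes.append((idx, o + (idx + 0.5) * v - c))
    (iz, dz), (jy, dy), (kx, dx) = axes
    d2 = dz[:, None, None] ** 2 + dy[None, :, None] ** 2 + dx[None, None, :] ** 2
    mask = d2 <= radius * radius
    ii, jj, kk = np.nonzero(mask)
    return iz[ii], jy[jj], kx[kk]


def neighbor_indices(atom_point, grid: VoxelGrid, radius: float = 6.0) -> set[tuple[int, int, int]]:
    """All in-bounds (i, j, k) whose voxel *center* lies within ``radius`` Å
    of the atomic coordinate, excluding the atom's own floored index."""
    if not (radius > 0):
        raise InvalidParameterError(f"radius must be > 0, got {radius}")
    window = _neighbor_window(atom_point, grid, radius)
    if window is None:
        return set()
    out = set(zip(*(a.tolist() for a in window)))
    own, valid = floor_indices(np.asarray(atom_point, dtype=float).reshape(1, 3), grid)
    if valid[0]:
        out.discard(tuple(own[0]))
    return out


def generate_labels(
    structure: Structure,
    experimental: VoxelGrid,
    simulated: VoxelGrid,
    radius: float = 6.0,
) -> LabelMapSet:
    """Build the three label maps on the experimental grid's geometry."""
    if len(structure) == 0:
        raise EmptyStructureError("cannot generate labels for an empty structure")
    if not (radius > 0):
        raise InvalidParameterError(f"radius must be > 0, got {radius}")

    aligned = experimental.same_geometry(simulated)
    sim_vals = np.asarray(simulated.values, dtype=np.float32)

    regression = np.zeros(experimental.dims, dtype=np.float32)
    classification = np.zeros(experimental.dims, dtype=np.int8)
    atom_type = np.zeros(experimental.dims, dtype=np.int8)

    coords = structure.coords
    idx_all, valid_exp = floor_indices(coords, experimental)
    labeled_any = False
    for a, atom in enumerate(structure.atoms):
        if not valid_exp[a] or not simulated.contains_point(atom.coords):
            continue  # dual validation failed: the atom contributes nothing
        labeled_any = True
        i, j, k = idx_all[a]
        window = _neighbor_window(atom.coords, experimental, radius)
        if window is not None:
            iz, jy, kx = window
            neigh = classification[iz, jy, kx]
            classification[iz, jy, kx] = np.where(neigh == 1, 1, 2)
            if aligned:
                regression[iz, jy, kx] = sim_vals[iz, jy, kx]
            else:
                pts = np.stack([
                    experimental.origin[0] + (kx + 0.5) * experimental.voxel[0],
                    experimental.origin[1] + (jy + 0.5) * experimental.voxel[1],
                    experimental.origin[2] + (iz + 0.5) * experimental.voxel[2],
                ], axis=1)
                regression[iz, jy, kx] = sample_at_many(simulated, pts, "trilinear")
        classification[i, j, k] = 1  # direct label wins over any neighbor 2
        code = int(classify_atom(atom))
        if code != 0:  # zero never overwrites a nonzero code
            atom_type[i, j, k] = code
        if aligned:
            regression[i, j, k] = sim_vals[i, j, k]
        else:
            center = np.array([[experimental.origin[0] + (k + 0.5) * experimental.voxel[0],
                                experimental.origin[1] + (j + 0.5) * experimental.voxel[1],
                                experimental.origin[2] + (i + 0.5) * experimental.voxel[2]]])
            regression[i, j, k] = sample_at_many(simulated, center, "trilinear")[0]

    if not labeled_any:
        warnings.warn(
            "no atom passed dual validation; label maps are all zero",
            EmptyLabelWarning,
            stacklevel=2,
        )
    geom = dict(origin=experimental.origin, voxel=experimental.voxel)
    return LabelMapSet(
        regression=VoxelGrid(regression, **geom),
        classification=VoxelGrid(classification, **geom),
        atom_type=VoxelGrid(atom_type, **geom),
        radius=radius,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_record(experimental_map_path, assembly_path, out_dir, config: RunConfig | None = None) -> dict:
    """Run the full per-entry pipeline and write the dataset record.

    read → resample experimental to the standard voxel size → simulate on the
    aligned grid → generate labels → write the five MRC outputs (standardized
    experimental, simulated, regression, classification, atom-type) plus a
    plain-text provenance sidecar.  Returns a dict of output paths.
    """
    cfg = config or RunConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pdb_id = cfg.pdb_id or Path(assembly_path).name.split(".")[0]

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc

    experimental, _ = stage("read_experimental", read_mrc,
                            experimental_map_path, origin_dialect=cfg.origin_dialect)
    structure = stage("read_assembly", read_assembly,
                      assembly_path, include_hetero=cfg.include_hetero)
    standardized = stage("standardize", resample_to_voxel_size, experimental, cfg.voxel_target)
    kernel = KernelSpec(resolution=cfg.kernel_resolution, cutoff=cfg.kernel_cutoff,
                        amplitude_mode=cfg.amplitude_mode)
    simulated = stage("simulate", simulate_map, structure, standardized, kernel)
    labels = stage("generate_labels", generate_labels,
                   structure, standardized, simulated, cfg.neighbor_radius)

    grids = {
        "experimental": (standardized, 2),
        "simulated": (simulated, 2),
        "regression": (labels.regression, 2),
        "classification": (labels.classification, cfg.label_mode),
        "atom_type": (labels.atom_type, cfg.label_mode),
    }
    paths: dict[str, Path] = {}
    for kind, (grid, mode) in grids.items():
        path = out_dir / cfg.output_name(pdb_id, kind)
        stage(f"write_{kind}", write_mrc, grid, path, mode=mode)
        paths[kind] = path

    prov = {
        "pdb_id": pdb_id,
        "input_experimental": Path(experimental_map_path).name,
        "input_experimental_sha256": _sha256(experimental_map_path),
        "input_assembly": Path(assembly_path).name,
        "input_assembly_sha256": _sha256(assembly_path),
        "voxel_target": cfg.voxel_target,
        "neighbor_radius": cfg.neighbor_radius,
        "kernel_resolution": cfg.kernel_resolution,
        "kernel_cutoff": cfg.kernel_cutoff,
        "amplitude_mode": cfg.amplitude_mode,
        "origin_dialect": cfg.origin_dialect,
        "include_hetero": cfg.include_hetero,
        "n_atoms": len(structure),
        "cryolabel_version": __version__,
    }
    for kind, path in paths.items():
        prov[f"output_{kind}"] = path.name
        prov[f"output_{kind}_sha256"] = _sha256(path)
    prov_path = out_dir / f"{pdb_id}_provenance.txt"
    prov_path.write_text("".join(f"{k} = {prov[k]}\n" for k in sorted(prov)))
    paths["provenance"] = prov_path
    return {k: str(v) for k, v in paths.items()}
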