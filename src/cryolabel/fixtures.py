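"""Synthetic structures and maps for desk-scale, download-free testing.

The fixture structure is an ideal poly-alanine α-helix (rise 1.5 Å/residue,
twist 100°, Cα 2.3 Å off axis, backbone + Cβ at fixed ideal offsets).  Clean
maps come from the Gaussian simulator; "experimental" maps add the three
noise stages of real reconstructions in caricature: seeded white Gaussian
noise (shot/digital noise) and a few off-structure Gaussian blobs
(irreproducible structural noise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .curate import MapRecord, write_curated
from .exceptions import InvalidParameterError
from .grid import VoxelGrid
from .mrc import write_mrc
from .pdb import Atom, Structure, write_pdb
from .simulate import KernelSpec, _splat_gaussian, bounding_grid, simulate_map

__all__ = ["NoiseSpec", "make_helix", "make_noisy_map", "make_fixture_bundle"]

RISE = 1.5          # Å per residue along the helix axis
TWIST = 100.0       # degrees per residue
CA_RADIUS = 2.3     # Å, Cα distance from the helix axis

# ideal offsets from Cα in the residue's local frame (rotated per residue)
_OFFSETS = {
    "N": (-0.95, 0.70, -0.90),
    "C": (1.20, 0.60, 0.60),
    "O": (1.50, 1.55, 1.30),
    "CB": (0.40, -1.30, 0.65),
}
_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}


@dataclass
class NoiseSpec:
    """Noise model for synthetic 'experimental' maps."""

    gaussian_sigma: float = 0.05  # density units of white noise
    blob_count: int = 3
    blob_sigma: float = 2.0       # Å
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gaussian_sigma < 0:
            raise InvalidParameterError(f"gaussian_sigma must be >= 0, got {self.gaussian_sigma}")
        if self.blob_count < 0:
            raise InvalidParameterError(f"blob_count must be >= 0, got {self.blob_count}")


def make_helix(n_res: int, chain_id: str = "A") -> Structure:
    """Ideal poly-alanine α-helix with N, CA, C, O, CB per residue."""
    if n_res < 1:
        raise InvalidParameterError(f"n_res must be >= 1, got {n_res}")
    atoms: list[Atom] = []
    for t in range(n_res):
        theta = math.radians(TWIST * t)
        cos_t, sin_t = math.cos(theta), math.sin(theta)
        ca = np.array([CA_RADIUS * cos_t, CA_RADIUS * sin_t, RISE * t])
        for name in ("N", "CA", "C", "O", "CB"):
            if name == "CA":
                pos = ca
            else:
                dx, dy, dz = _OFFSETS[name]
                pos = ca + np.array([dx * cos_t - dy * sin_t,
                                     dx * sin_t + dy * cos_t, dz])
            atoms.append(Atom(
                element=_ELEMENTS[name],
                name=name,
                residue_name="ALA",
                coords=tuple(float(c) for c in pos),
                chain_id=chain_id,
                residue_seq=t + 1,
            ))
    return Structure(atoms=atoms, source_id="toy")


def make_noisy_map(clean: VoxelGrid, noise: NoiseSpec) -> VoxelGrid:
    """Clean map + seeded white noise + off-structure Gaussian blobs."""
    rng = np.random.default_rng(noise.seed)
    values = np.asarray(clean.values, dtype=np.float64).copy()
    if noise.gaussian_sigma > 0:
        values += rng.normal(0.0, noise.gaussian_sigma, size=values.shape)
    if noise.blob_count > 0:
        amp = 0.5 * float(np.abs(clean.values).max()) or 1.0
        ext = clean.extent  # ((x0,x1),(y0,y1),(z0,z1))
        spans = np.array([hi - lo for lo, hi in ext])
        los = np.array([lo for lo, _ in ext])
        for _ in range(noise.blob_count):
            # prefer the outer 20% margin shell, away from the centered structure
            for _attempt in range(50):
                u = rng.random(3)
                if np.any((u < 0.2) | (u > 0.8)):
                    break
            center = los + u * spans
            _splat_gaussian(values, clean, center, noise.blob_sigma,
                            amp, 4.0 * noise.blob_sigma, unit_integral=False)
    return VoxelGrid(values.astype(np.float32), origin=clean.origin, voxel=clean.voxel)


def make_fixture_bundle(out_dir, n_res: int = 20, seed: int = 0,
                        noise: NoiseSpec | None = None) -> dict:
    """Write a toy per-entry bundle: assembly PDB, clean and noisy maps, metadata.

    Outputs ``toy.pdb``, ``toy_simulated.mrc`` (2 Å kernel on a 1 Å bounding
    grid with 5 Å pad), ``toy_experimental.mrc`` (noise-corrupted copy) and
    ``toy_metadata.csv`` (one curate-compatible row).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    helix = make_helix(n_res)
    grid = bounding_grid(helix, voxel=1.0, pad=5.0)
    clean = simulate_map(helix, grid, KernelSpec(resolution=2.0))
    noisy = make_noisy_map(clean, noise or NoiseSpec(seed=seed))

    paths = {
        "pdb": out_dir / "toy.pdb",
        "simulated": out_dir / "toy_simulated.mrc",
        "experimental": out_dir / "toy_experimental.mrc",
        "metadata": out_dir / "toy_metadata.csv",
    }
    write_pdb(helix, paths["pdb"])
    write_mrc(clean, paths["simulated"])
    write_mrc(noisy, paths["experimental"])
    write_curated(paths["metadata"], [MapRecord(
        emdb_id="EMD-TOY1", pdb_id="toy", resolution=2.0,
        has_assembly=True, resolution_method="FSC 0.143",
    )])
    return {k: str(v) for k, v in paths.items()}
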