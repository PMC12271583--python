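"""Unmasked Fourier Shell Correlation and resolution estimation.

FSC between two maps a, b over a resolution shell s::

    FSC(s) = Re( sum F_a F_b* ) / sqrt( sum |F_a|^2 * sum |F_b|^2 )

with the sums running over discrete Fourier frequencies whose radial
magnitude falls in the shell.  The map-model variant compares an
experimental map against a Gaussian-kernel map simulated from its atomic
model, with no solvent mask, and reads off the resolution where the curve
crosses 0.5 (stringent map-model agreement) or 0.143.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import AlignmentError, InvalidParameterError
from .grid import VoxelGrid
from .pdb import Structure
from .simulate import KernelSpec, simulate_map

__all__ = [
    "FscCurve",
    "compute_fsc",
    "resolution_at",
    "map_model_fsc",
    "improvement_percent",
    "summarize_resolutions",
]


@dataclass
class FscCurve:
    """Per-shell frequencies (1/Å, ascending), correlations and voxel counts.

    ``nyquist`` is 1/(2·voxel) when the curve comes from real grids; for
    hand-built curves it defaults to the last shell frequency.
    """

    shell_freq: np.ndarray
    correlation: np.ndarray
    shell_voxel_count: np.ndarray
    nyquist: float | None = None

    def __post_init__(self) -> None:
        self.shell_freq = np.asarray(self.shell_freq, dtype=float)
        self.correlation = np.asarray(self.correlation, dtype=float)
        self.shell_voxel_count = np.asarray(self.shell_voxel_count, dtype=int)
        if len(self.shell_freq) == 0:
            raise InvalidParameterError("FSC curve has no shells")
        if np.any(np.diff(self.shell_freq) <= 0):
            raise InvalidParameterError("shell frequencies must ascend")
        if self.nyquist is None:
            self.nyquist = float(self.shell_freq[-1])


def compute_fsc(map_a: VoxelGrid, map_b: VoxelGrid, shell_width: float | None = None) -> FscCurve:
    """FSC of two grids sharing dims, voxel and origin (isotropic voxels).

    ``shell_width`` defaults to one Fourier voxel, ``1 / (N * voxel)`` with
    N the largest dimension.  The DC term is excluded; shells are reported
    up to the Nyquist frequency.
    """
    if map_a.dims != map_b.dims:
        raise AlignmentError(f"grid dims differ: {map_a.dims} vs {map_b.dims}")
    if not map_a.same_geometry(map_b):
        raise AlignmentError("grids differ in origin or voxel size")
    vx, vy, vz = map_a.voxel
    if not (math.isclose(vx, vy, rel_tol=1e-6) and math.isclose(vx, vz, rel_tol=1e-6)):
        raise AlignmentError(f"anisotropic voxels not supported: {map_a.voxel}")
    voxel = vx
    dims = map_a.dims
    if shell_width is None:
        shell_width = 1.0 / (max(dims) * voxel)
    elif not (shell_width > 0):
        raise InvalidParameterError(f"shell width must be > 0, got {shell_width}")

    fa = np.fft.fftn(np.asarray(map_a.values, dtype=np.float64))
    fb = np.fft.fftn(np.asarray(map_b.values, dtype=np.float64))
    freqs = [np.fft.fftfreq(n, d=voxel) for n in dims]  # (i~z, j~y, k~x)
    r = np.sqrt(freqs[0][:, None, None] ** 2
                + freqs[1][None, :, None] ** 2
                + freqs[2][None, None, :] ** 2)

    shell = np.floor(r / shell_width).astype(np.int64).ravel()
    keep = r.ravel() > 0  # exclude DC
    shell = shell[keep]
    num = np.real(fa * np.conj(fb)).ravel()[keep]
    pa = np.abs(fa.ravel()[keep]) ** 2
    pb = np.abs(fb.ravel()[keep]) ** 2

    n_shells = int(shell.max()) + 1
    counts = np.bincount(shell, minlength=n_shells)
    s_num = np.bincount(shell, weights=num, minlength=n_shells)
    s_pa = np.bincount(shell, weights=pa, minlength=n_shells)
    s_pb = np.bincount(shell, weights=pb, minlength=n_shells)

    centers = (np.arange(n_shells) + 0.5) * shell_width
    nyquist = 1.0 / (2.0 * voxel)
    ok = (counts > 0) & (s_pa > 0) & (s_pb > 0) & (centers <= nyquist + 1e-12)
    corr = np.clip(s_num[ok] / np.sqrt(s_pa[ok] * s_pb[ok]), -1.0, 1.0)
    return FscCurve(
        shell_freq=centers[ok],
        correlation=corr,
        shell_voxel_count=counts[ok],
        nyquist=nyquist,
    )


def resolution_at(curve: FscCurve, threshold: float = 0.5) -> float:
    """Resolution (Å) where the curve first falls below ``threshold``.

    Linear interpolation between the bracketing shells; ``inf`` when the
    first shell is already below threshold; ``1 / nyquist`` (= 2·voxel for
    grid-derived curves) when the curve never drops below.
    """
    corr = curve.correlation
    freq = curve.shell_freq
    if corr[0] < threshold:
        return math.inf
    for a in range(len(corr) - 1):
        if corr[a] >= threshold and corr[a + 1] < threshold:
            f = freq[a] + (freq[a + 1] - freq[a]) * (corr[a] - threshold) / (corr[a] - corr[a + 1])
            return 1.0 / f
    return 1.0 / float(curve.nyquist)


def _normalize(values: np.ndarray) -> np.ndarray:
    std = values.std()
    if std == 0:
        return values - values.mean()
    return (values - values.mean()) / std


def map_model_fsc(
    map_grid: VoxelGrid,
    structure: Structure,
    kernel: KernelSpec | None = None,
    threshold: float = 0.5,
) -> tuple[FscCurve, float]:
    """Unmasked map-model FSC: simulate the model on the map's grid, then FSC.

    Both maps are intensity-normalized (zero mean, unit variance; FSC is
    scale-invariant, this only guards numerics).  Returns the curve and the
    resolution at ``threshold``.
    """
    coords = structure.coords
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    overlaps = all(hi[a] >= ext[0] and lo[a] < ext[1]
                   for a, ext in enumerate(map_grid.extent))
    if not overlaps:
        raise AlignmentError("structure does not overlap the map extent")
    model = simulate_map(structure, map_grid, kernel or KernelSpec())
    a = VoxelGrid(_normalize(np.asarray(map_grid.values, dtype=np.float64)),
                  origin=map_grid.origin, voxel=map_grid.voxel)
    b = VoxelGrid(_normalize(np.asarray(model.values, dtype=np.float64)),
                  origin=model.origin, voxel=model.voxel)
    curve = compute_fsc(a, b)
    return curve, resolution_at(curve, threshold)


def improvement_percent(mean_before: float, mean_after: float) -> float:
    """Percent improvement of a mean resolution: 100·(before − after)/before."""
    if not (mean_before > 0) or not (mean_after > 0):
        raise InvalidParameterError(
            f"resolutions must be > 0, got {mean_before} and {mean_after}"
        )
    return 100.0 * (mean_before - mean_after) / mean_before


def summarize_resolutions(before, after) -> dict:
    """Mean before/after resolutions and the improvement percentage."""
    before = np.asarray(list(before), dtype=float)
    after = np.asarray(list(after), dtype=float)
    if before.size == 0 or before.size != after.size:
        raise InvalidParameterError("before/after must be equal-length, non-empty")
    mb, ma = float(before.mean()), float(after.mean())
    return {
        "n": int(before.size),
        "mean_before": mb,
        "mean_after": ma,
        "improvement_percent": improvement_percent(mb, ma),
    }
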