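import numpy as np
import pytest

import cryolabel as cl


@pytest.fixture(scope="session")
def helix():
    """20-residue ideal poly-alanine helix (100 atoms)."""
    return cl.make_helix(20)


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Synthetic per-entry fixture bundle on disk."""
    out = tmp_path_factory.mktemp("bundle")
    return cl.make_fixture_bundle(out, n_res=20, seed=7)


@pytest.fixture(scope="session")
def record(bundle, tmp_path_factory):
    """Full pipeline outputs for the fixture bundle."""
    out = tmp_path_factory.mktemp("record")
    return cl.run_record(bundle["experimental"], bundle["pdb"], out)


@pytest.fixture()
def unit_grid():
    """16^3 zero grid, 1 Å voxels, origin at the physical origin."""
    return cl.VoxelGrid(np.zeros((16, 16, 16), dtype=np.float32))


def brute_force_neighbor_count(point, grid, radius):
    """Triple-loop lattice enumeration of in-bounds voxel centers within
    ``radius`` of a point, excluding the atom's own floored voxel.

    Independent of the implementation's vectorized window logic.
    """
    import math

    x, y, z = point
    n_i, n_j, n_k = grid.dims
    ox, oy, oz = grid.origin
    vx, vy, vz = grid.voxel
    own = (math.floor((z - oz) / vz), math.floor((y - oy) / vy), math.floor((x - ox) / vx))
    count = 0
    reach = int(math.ceil(radius / min(vx, vy, vz))) + 1
    for i in range(own[0] - reach, own[0] + reach + 1):
        for j in range(own[1] - reach, own[1] + reach + 1):
            for k in range(own[2] - reach, own[2] + reach + 1):
                if not (0 <= i < n_i and 0 <= j < n_j and 0 <= k < n_k):
                    continue
                cx = ox + (k + 0.5) * vx
                cy = oy + (j + 0.5) * vy
                cz = oz + (i + 0.5) * vz
                if (cx - x) ** 2 + (cy - y) ** 2 + (cz - z) ** 2 <= radius**2:
                    if (i, j, k) != own:
                        count += 1
    return count


def naive_dft_fsc(a, b, voxel=1.0, shell_width=None):
    """Direct matrix-DFT FSC oracle (no FFT), with explicit shell binning.

    Mirrors the FSC definition from first principles: 1-D DFT matrices are
    applied along each axis by tensor contraction, frequencies are computed
    by hand, and shells are accumulated in plain loops.
    """
    import math

    dims = a.shape
    if shell_width is None:
        shell_width = 1.0 / (max(dims) * voxel)

    def dft3(f):
        out = f.astype(complex)
        for axis, n in enumerate(dims):
            jk = np.outer(np.arange(n), np.arange(n))
            w = np.exp(-2j * np.pi * jk / n)
            out = np.moveaxis(np.tensordot(w, np.moveaxis(out, axis, 0), axes=(1, 0)), 0, axis)
        return out

    def freq(idx, n):
        return (idx if idx < (n + 1) // 2 else idx - n) / (n * voxel)

    fa, fb = dft3(a), dft3(b)
    shells = {}
    for u in range(dims[0]):
        for v in range(dims[1]):
            for w in range(dims[2]):
                r = math.sqrt(freq(u, dims[0]) ** 2 + freq(v, dims[1]) ** 2 + freq(w, dims[2]) ** 2)
                if r == 0:
                    continue
                s = int(r // shell_width)
                num, pa, pb, cnt = shells.get(s, (0.0, 0.0, 0.0, 0))
                shells[s] = (
                    num + (fa[u, v, w] * np.conj(fb[u, v, w])).real,
                    pa + abs(fa[u, v, w]) ** 2,
                    pb + abs(fb[u, v, w]) ** 2,
                    cnt + 1,
                )
    nyq = 1.0 / (2.0 * voxel)
    freqs, corrs, counts = [], [], []
    for s in sorted(shells):
        center = (s + 0.5) * shell_width
        num, pa, pb, cnt = shells[s]
        if pa > 0 and pb > 0 and center <= nyq + 1e-12:
            freqs.append(center)
            corrs.append(num / math.sqrt(pa * pb))
            counts.append(cnt)
    return np.array(freqs), np.array(corrs), np.array(counts)
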