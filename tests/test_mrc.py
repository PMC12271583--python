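"""MRC2014 I/O: round trips, axis-order normalization, origin dialects."""

import struct

import gemmi
import numpy as np
import pytest

import cryolabel as cl
from cryolabel.exceptions import MapFormatError
from cryolabel.mrc import pack_header


@pytest.fixture()
def random_grid():
    rng = np.random.default_rng(42)
    return cl.VoxelGrid(
        rng.normal(size=(5, 6, 7)).astype(np.float32),
        origin=(-3.0, 2.5, 10.0),
        voxel=(1.1, 1.0, 0.9),
    )


class TestRoundTrip:
    def test_values_origin_voxel(self, random_grid, tmp_path):
        path = tmp_path / "m.mrc"
        cl.write_mrc(random_grid, path)
        back, header = cl.read_mrc(path)
        np.testing.assert_array_equal(back.values, random_grid.values)
        np.testing.assert_allclose(back.origin, random_grid.origin, rtol=1e-6)
        np.testing.assert_allclose(back.voxel, random_grid.voxel, rtol=1e-6)
        assert header["mode"] == 2

    def test_zero_grid_header(self, tmp_path):
        path = tmp_path / "z.mrc"
        cl.write_mrc(cl.VoxelGrid(np.zeros((2, 2, 2), dtype=np.float32)), path)
        back, header = cl.read_mrc(path)
        assert (header["nx"], header["ny"], header["nz"]) == (2, 2, 2)
        assert back.values.sum() == 0

    def test_int8_mode(self, tmp_path):
        labels = cl.VoxelGrid(np.arange(8, dtype=np.float32).reshape(2, 2, 2) % 6)
        path = tmp_path / "l.mrc"
        cl.write_mrc(labels, path, mode=0)
        back, header = cl.read_mrc(path)
        assert header["mode"] == 0
        np.testing.assert_array_equal(back.values, labels.values)

    def test_header_statistics_match_payload(self, random_grid, tmp_path):
        path = tmp_path / "s.mrc"
        cl.write_mrc(random_grid, path)
        _, header = cl.read_mrc(path)
        vals = random_grid.values.astype(np.float64)
        assert header["dmin"] == pytest.approx(vals.min(), rel=1e-6)
        assert header["dmax"] == pytest.approx(vals.max(), rel=1e-6)
        assert header["dmean"] == pytest.approx(vals.mean(), rel=1e-5)
        assert header["rms"] == pytest.approx(vals.std(), rel=1e-5)


class TestAxisOrderNormalization:
    @pytest.mark.parametrize("mapcrs", [(1, 2, 3), (2, 1, 3), (3, 2, 1), (2, 3, 1), (3, 1, 2)])
    def test_permuted_twin_reads_identically(self, tmp_path, mapcrs):
        """A file stored with permuted axis correspondence yields the same
        logical grid as its canonically stored twin."""
        rng = np.random.default_rng(3)
        values = rng.normal(size=(4, 5, 6)).astype(np.float32)  # logical (z, y, x)
        grid = cl.VoxelGrid(values, origin=(1.0, 2.0, 3.0), voxel=(1.0, 1.0, 1.0))
        canonical = tmp_path / "canonical.mrc"
        cl.write_mrc(grid, canonical)

        # storage axes (sections, rows, columns) shall carry physical axes
        # (maps, mapr, mapc); build that layout from the logical (z, y, x) array
        mapc, mapr, maps = mapcrs
        phys_to_logical = {3: 0, 2: 1, 1: 2}  # physical axis -> logical array axis
        perm = [phys_to_logical[maps], phys_to_logical[mapr], phys_to_logical[mapc]]
        stored = np.ascontiguousarray(np.transpose(values, perm))
        n_i, n_j, n_k = values.shape
        size_physical = {1: n_k, 2: n_j, 3: n_i}  # samples per physical axis
        header = pack_header(
            nxyz=(stored.shape[2], stored.shape[1], stored.shape[0]),
            mode=2,
            nstart=(0, 0, 0),
            mxyz=(size_physical[1], size_physical[2], size_physical[3]),
            cella=(size_physical[1] * 1.0, size_physical[2] * 1.0, size_physical[3] * 1.0),
            mapcrs=mapcrs,
            stats=(float(values.min()), float(values.max()), float(values.mean())),
            origin=grid.origin,
            rms=float(values.std()),
        )
        permuted = tmp_path / "permuted.mrc"
        permuted.write_bytes(header + stored.tobytes())

        a, _ = cl.read_mrc(canonical)
        b, _ = cl.read_mrc(permuted)
        np.testing.assert_array_equal(a.values, b.values)
        assert a.origin == b.origin
        assert a.voxel == b.voxel

    def test_mxyz_is_per_physical_axis(self, tmp_path):
        """Voxel sizes follow cella/m per *physical* axis even when permuted."""
        values = np.zeros((2, 3, 4), dtype=np.float32)
        stored = np.ascontiguousarray(np.transpose(values, (2, 1, 0)))  # maps=1: x slowest
        header = pack_header(
            nxyz=(2, 3, 4), mode=2, nstart=(0, 0, 0),
            mxyz=(4, 3, 2),                       # samples along x, y, z
            cella=(8.0, 3.0, 1.0),                # -> voxel (2.0, 1.0, 0.5)
            mapcrs=(3, 2, 1),
            stats=(0.0, 0.0, 0.0), origin=(0, 0, 0), rms=0.0,
        )
        path = tmp_path / "p.mrc"
        path.write_bytes(header + stored.tobytes())
        grid, _ = cl.read_mrc(path)
        assert grid.dims == (2, 3, 4)
        assert grid.voxel == (2.0, 1.0, 0.5)


class TestOriginDialects:
    def _write(self, tmp_path, origin, nstart, voxel=1.0):
        values = np.zeros((3, 3, 3), dtype=np.float32)
        header = pack_header(
            nxyz=(3, 3, 3), mode=2, nstart=nstart, mxyz=(3, 3, 3),
            cella=(3 * voxel,) * 3, mapcrs=(1, 2, 3),
            stats=(0.0, 0.0, 0.0), origin=origin, rms=0.0,
        )
        path = tmp_path / "o.mrc"
        path.write_bytes(header + values.tobytes())
        return path

    def test_nstart_fallback_when_origin_zero(self, tmp_path):
        path = self._write(tmp_path, origin=(0, 0, 0), nstart=(-5, -5, -5))
        grid, _ = cl.read_mrc(path)
        assert grid.origin == (-5.0, -5.0, -5.0)

    def test_origin_header_wins_when_nonzero(self, tmp_path):
        path = self._write(tmp_path, origin=(2.0, 0.0, 0.0), nstart=(-5, -5, -5))
        grid, _ = cl.read_mrc(path)
        assert grid.origin == (2.0, 0.0, 0.0)

    def test_forced_dialects(self, tmp_path):
        path = self._write(tmp_path, origin=(2.0, 3.0, 4.0), nstart=(-5, 0, 0))
        assert cl.read_mrc(path, origin_dialect="header")[0].origin == (2.0, 3.0, 4.0)
        assert cl.read_mrc(path, origin_dialect="nstart")[0].origin == (-5.0, 0.0, 0.0)


class TestFormatErrors:
    def test_truncated_header(self, tmp_path):
        path = tmp_path / "t.mrc"
        path.write_bytes(b"\x00" * 100)
        with pytest.raises(MapFormatError, match="truncated"):
            cl.read_mrc(path)

    def test_missing_signature(self, tmp_path):
        path = tmp_path / "sig.mrc"
        path.write_bytes(b"\x00" * 2048)
        with pytest.raises(MapFormatError, match="MAP"):
            cl.read_mrc(path)

    def test_unsupported_mode(self, tmp_path, random_grid):
        path = tmp_path / "m.mrc"
        cl.write_mrc(random_grid, path)
        raw = bytearray(path.read_bytes())
        struct.pack_into("<i", raw, 12, 4)  # mode 4: complex, unsupported
        path.write_bytes(bytes(raw))
        with pytest.raises(MapFormatError, match="mode"):
            cl.read_mrc(path)

    def test_truncated_payload(self, tmp_path, random_grid):
        path = tmp_path / "p.mrc"
        cl.write_mrc(random_grid, path)
        data = path.read_bytes()
        path.write_bytes(data[: len(data) - 64])
        with pytest.raises(MapFormatError, match="truncated"):
            cl.read_mrc(path)

    def test_bad_cell(self, tmp_path, random_grid):
        path = tmp_path / "c.mrc"
        cl.write_mrc(random_grid, path)
        raw = bytearray(path.read_bytes())
        struct.pack_into("<3f", raw, 40, 0.0, 0.0, 0.0)
        path.write_bytes(bytes(raw))
        with pytest.raises(MapFormatError, match="cella"):
            cl.read_mrc(path)


def test_gemmi_reads_our_files(random_grid, tmp_path):
    """Independent reader oracle: gemmi agrees on payload and cell."""
    path = tmp_path / "g.mrc"
    cl.write_mrc(random_grid, path)
    m = gemmi.read_ccp4_map(str(path))
    arr = np.array(m.grid, copy=False)  # gemmi orders (x, y, z)
    np.testing.assert_allclose(arr, np.transpose(random_grid.values, (2, 1, 0)), rtol=1e-6)
    n_i, n_j, n_k = random_grid.dims
    vx, vy, vz = random_grid.voxel
    assert m.grid.unit_cell.a == pytest.approx(n_k * vx, rel=1e-5)
    assert m.grid.unit_cell.c == pytest.approx(n_i * vz, rel=1e-5)
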