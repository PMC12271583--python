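"""MRC2014 volume I/O with normalization of axis order and origin dialects.

Deposited EMDB maps come with arbitrary axis correspondence (``mapc``,
``mapr``, ``maps``) and two competing origin conventions: the float ``ORIGIN``
header words, or the integer start indices ``nxstart/nystart/nzstart`` scaled
by the voxel size.  :func:`read_mrc` normalizes both so that the in-memory
:class:`~cryolabel.grid.VoxelGrid` is always stored ``(i, j, k) = (z, y, x)``
with an explicit physical origin; :func:`write_mrc` emits canonical
x-fastest MRC2014 (mode 2 by default) with populated statistics.

Modes 0 (int8), 1 (int16) and 2 (float32) are read; modes 0 and 2 are
written.  Only little-endian files are produced.
"""

from __future__ import annotations

import struct

import numpy as np

from .exceptions import InvalidParameterError, MapFormatError
from .grid import VoxelGrid

__all__ = ["read_mrc", "write_mrc"]

HEADER_SIZE = 1024
_MODE_DTYPES = {0: np.dtype("<i1"), 1: np.dtype("<i2"), 2: np.dtype("<f4")}


def _unpack_header(buf: bytes) -> dict:
    ints = struct.unpack("<10i", buf[0:40])
    cella = struct.unpack("<3f", buf[40:52])
    cellb = struct.unpack("<3f", buf[52:64])
    mapcrs = struct.unpack("<3i", buf[64:76])
    dmin, dmax, dmean = struct.unpack("<3f", buf[76:88])
    ispg, nsymbt = struct.unpack("<2i", buf[88:96])
    origin = struct.unpack("<3f", buf[196:208])
    map_id = buf[208:212]
    rms = struct.unpack("<f", buf[216:220])[0]
    nlabl = struct.unpack("<i", buf[220:224])[0]
    return {
        "nx": ints[0], "ny": ints[1], "nz": ints[2],
        "mode": ints[3],
        "nxstart": ints[4], "nystart": ints[5], "nzstart": ints[6],
        "mx": ints[7], "my": ints[8], "mz": ints[9],
        "cella": cella, "cellb": cellb,
        "mapc": mapcrs[0], "mapr": mapcrs[1], "maps": mapcrs[2],
        "dmin": dmin, "dmax": dmax, "dmean": dmean,
        "ispg": ispg, "nsymbt": nsymbt,
        "origin": origin, "map_id": map_id, "rms": rms, "nlabl": nlabl,
    }


def pack_header(
    nxyz,
    mode,
    nstart,
    mxyz,
    cella,
    mapcrs,
    stats,
    origin,
    rms,
    label: str = "cryolabel",
) -> bytes:
    """Assemble a 1024-byte little-endian MRC2014 header.

    Exposed (rather than private) so tests can craft non-canonical dialects —
    permuted axis correspondence, nstart-based origins — byte by byte.
    """
    buf = bytearray(HEADER_SIZE)
    struct.pack_into("<10i", buf, 0, *nxyz, mode, *nstart, *mxyz)
    struct.pack_into("<3f", buf, 40, *cella)
    struct.pack_into("<3f", buf, 52, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", buf, 64, *mapcrs)
    struct.pack_into("<3f", buf, 76, *stats)
    struct.pack_into("<2i", buf, 88, 1, 0)  # ispg=1 (volume), nsymbt=0
    struct.pack_into("<3f", buf, 196, *origin)
    buf[208:212] = b"MAP "
    buf[212:216] = b"\x44\x44\x00\x00"  # little-endian machine stamp
    struct.pack_into("<f", buf, 216, rms)
    struct.pack_into("<i", buf, 220, 1)
    buf[224:304] = label.encode("ascii", "replace")[:80].ljust(80)
    return bytes(buf)


def read_mrc(path, origin_dialect: str = "auto") -> tuple[VoxelGrid, dict]:
    """Read an MRC2014 volume into a canonically ordered :class:`VoxelGrid`.

    Parameters
    ----------
    path
        File to read.  Must carry the ``MAP `` signature.
    origin_dialect
        ``"auto"`` (ORIGIN header wins when any component is nonzero, else
        start indices × voxel), ``"header"`` (always ORIGIN) or ``"nstart"``
        (always start indices).

    Returns
    -------
    (grid, header)
        The normalized grid and the raw header fields as a dict.
    """
    if origin_dialect not in ("auto", "header", "nstart"):
        raise InvalidParameterError(f"unknown origin dialect {origin_dialect!r}")
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < HEADER_SIZE:
        raise MapFormatError(f"{path}: truncated header ({len(raw)} bytes)")
    h = _unpack_header(raw[:HEADER_SIZE])
    if h["map_id"] != b"MAP ":
        raise MapFormatError(f"{path}: missing 'MAP ' signature (word 53)")
    if h["mode"] not in _MODE_DTYPES:
        raise MapFormatError(f"{path}: unsupported mode {h['mode']}")
    nx, ny, nz = h["nx"], h["ny"], h["nz"]
    if min(nx, ny, nz) <= 0:
        raise MapFormatError(f"{path}: non-positive dimensions nx/ny/nz {(nx, ny, nz)}")
    mapcrs = (h["mapc"], h["mapr"], h["maps"])
    if sorted(mapcrs) != [1, 2, 3]:
        raise MapFormatError(f"{path}: invalid axis correspondence mapc/mapr/maps {mapcrs}")
    mxyz = (h["mx"], h["my"], h["mz"])
    if min(mxyz) <= 0:
        raise MapFormatError(f"{path}: non-positive grid sampling mx/my/mz {mxyz}")
    if min(h["cella"]) <= 0:
        raise MapFormatError(f"{path}: non-positive cell dimensions cella {h['cella']}")

    dtype = _MODE_DTYPES[h["mode"]]
    count = nx * ny * nz
    start = HEADER_SIZE + h["nsymbt"]
    payload = raw[start : start + count * dtype.itemsize]
    if len(payload) < count * dtype.itemsize:
        raise MapFormatError(f"{path}: truncated data section (expected {count} values)")
    data = np.frombuffer(payload, dtype=dtype).reshape(nz, ny, nx)

    # storage axes (sections, rows, columns) carry physical axes (maps, mapr, mapc);
    # normalize to (z, y, x)
    storage_physical = (h["maps"], h["mapr"], h["mapc"])
    perm = [storage_physical.index(p) for p in (3, 2, 1)]
    values = np.ascontiguousarray(np.transpose(data, perm)).astype(np.float32)

    # voxel size per physical axis from cell / sampling
    voxel = tuple(h["cella"][a] / mxyz[a] for a in range(3))

    # start index per physical axis: nxstart counts along columns, etc.
    starts_storage = (h["nxstart"], h["nystart"], h["nzstart"])  # cols, rows, secs
    start_physical = [0, 0, 0]
    for storage_axis, phys in enumerate((h["mapc"], h["mapr"], h["maps"])):
        start_physical[phys - 1] = starts_storage[storage_axis]

    header_origin = tuple(float(c) for c in h["origin"])
    nstart_origin = tuple(start_physical[a] * voxel[a] for a in range(3))
    if origin_dialect == "header":
        origin = header_origin
    elif origin_dialect == "nstart":
        origin = nstart_origin
    else:
        origin = header_origin if any(c != 0.0 for c in header_origin) else nstart_origin

    return VoxelGrid(values, origin=origin, voxel=voxel), h


def write_mrc(grid: VoxelGrid, path, mode: int = 2, label: str = "cryolabel") -> None:
    """Write a grid as canonical (x-fastest) MRC2014.

    ``mode=2`` stores float32; ``mode=0`` stores int8 (for small-integer
    label maps).  Cell dimensions are ``dims × voxel``, the ORIGIN header is
    populated, and min/max/mean/rms statistics are recomputed from the payload.
    """
    if mode not in (0, 2):
        raise InvalidParameterError(f"write mode must be 0 or 2, got {mode}")
    data = np.ascontiguousarray(grid.values, dtype=_MODE_DTYPES[mode])
    n_i, n_j, n_k = grid.dims
    vx, vy, vz = grid.voxel
    fdata = data.astype(np.float64)
    header = pack_header(
        nxyz=(n_k, n_j, n_i),
        mode=mode,
        nstart=(0, 0, 0),
        mxyz=(n_k, n_j, n_i),
        cella=(n_k * vx, n_j * vy, n_i * vz),
        mapcrs=(1, 2, 3),
        stats=(float(fdata.min()), float(fdata.max()), float(fdata.mean())),
        origin=grid.origin,
        rms=float(fdata.std()),
        label=label,
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(data.tobytes())
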