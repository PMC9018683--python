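"""Simulated density and rigid-body docking by random-orientation search.

Density is a sum of isotropic atom-centered Gaussians whose FWHM equals
the requested resolution, amplitude proportional to atomic number.  The
global search scores uniformly sampled rotations (quaternion method)
combined round-robin with uniform translations inside the target map's
bounding box; the returned transform is the best-scoring placement.

Map I/O is a self-contained MRC2014 (mode 2) reader/writer; axis order
and origin conventions are normalized to (x, y, z) on read.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

import numpy as np

from .model import StructureModel

ATOMIC_NUMBER = {"H": 1, "C": 6, "N": 7, "O": 8, "P": 15, "S": 16,
                 "FE": 26, "ZN": 30, "MG": 12, "CA": 20}

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class DensityGrid:
    origin: np.ndarray        # (3,) Angstrom position of voxel (0,0,0)
    voxel: float              # Angstrom, isotropic
    values: np.ndarray        # (nx, ny, nz)

    def __post_init__(self):
        self.origin = np.asarray(self.origin, float)
        self.values = np.asarray(self.values, float)
        if self.voxel <= 0:
            raise ValueError("voxel size must be > 0")
        if self.values.ndim != 3 or not np.all(np.isfinite(self.values)):
            raise ValueError("values must be a finite 3-D field")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    @property
    def extent(self) -> np.ndarray:
        """(3,) physical size of the box."""
        return self.voxel * np.array(self.shape)

    def center_of_mass(self) -> np.ndarray:
        w = np.clip(self.values, 0, None)
        total = w.sum()
        if total == 0:
            raise ValueError("empty density grid")
        idx = np.indices(self.shape)
        com_vox = np.array([(idx[d] * w).sum() / total for d in range(3)])
        return self.origin + self.voxel * com_vox


@dataclass
class DockResult:
    rotation: np.ndarray      # (3, 3)
    translation: np.ndarray   # (3,) new centroid position
    score: float
    n_evaluated: int
    seed: int

    def matrix(self) -> np.ndarray:
        """4x4 homogeneous transform acting on centroid-centered coordinates."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m


def _weights(model: StructureModel) -> np.ndarray:
    return np.array([ATOMIC_NUMBER.get(e.upper(), 6) for e in model.element],
                    float)


def _accumulate(values: np.ndarray, origin: np.ndarray, voxel: float,
                coords: np.ndarray, weights: np.ndarray, sigma: float
                ) -> None:
    """Add Gaussians onto an existing lattice in place (4-sigma windows)."""
    shape = values.shape
    half = max(1, int(np.ceil(4.0 * sigma / voxel)))
    axes = [np.arange(s) * voxel + origin[d]
            for d, s in enumerate(shape)]
    inv2s2 = 1.0 / (2.0 * sigma * sigma)
    for xyz, w in zip(coords, weights):
        ctr = np.rint((xyz - origin) / voxel).astype(int)
        lo = np.maximum(ctr - half, 0)
        hi = np.minimum(ctr + half + 1, shape)
        if np.any(lo >= hi):
            continue
        gx = np.exp(-((axes[0][lo[0]:hi[0]] - xyz[0]) ** 2) * inv2s2)
        gy = np.exp(-((axes[1][lo[1]:hi[1]] - xyz[1]) ** 2) * inv2s2)
        gz = np.exp(-((axes[2][lo[2]:hi[2]] - xyz[2]) ** 2) * inv2s2)
        values[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += \
            w * gx[:, None, None] * gy[None, :, None] * gz[None, None, :]


def simulate_density(model: StructureModel, resolution: float, voxel: float,
                     pad: float | None = None) -> DensityGrid:
    """Gaussian-blurred density for a model (FWHM = ``resolution``)."""
    if resolution < 2.0 * voxel:
        raise ValueError(
            f"voxel {voxel} too coarse for resolution {resolution} "
            "(need resolution >= 2 * voxel)")
    sigma = resolution * _FWHM_TO_SIGMA
    if pad is None:
        pad = 4.0 * sigma + voxel
    lo = model.coords.min(axis=0) - pad
    hi = model.coords.max(axis=0) + pad
    shape = tuple(int(np.ceil((hi[d] - lo[d]) / voxel)) + 1 for d in range(3))
    values = np.zeros(shape)
    _accumulate(values, lo, voxel, model.coords, _weights(model), sigma)
    return DensityGrid(origin=lo, voxel=voxel, values=values)


def simulate_density_on(grid: DensityGrid, coords: np.ndarray,
                        weights: np.ndarray, resolution: float
                        ) -> np.ndarray:
    """Density of given atoms evaluated on an existing grid's lattice."""
    sigma = resolution * _FWHM_TO_SIGMA
    values = np.zeros(grid.shape)
    _accumulate(values, grid.origin, grid.voxel, coords, weights, sigma)
    return values


def cross_correlation(grid_a: DensityGrid, grid_b, threshold: float = 0.0
                      ) -> float:
    """About-mean Pearson correlation over voxels where grid_a > threshold."""
    vb = grid_b.values if isinstance(grid_b, DensityGrid) else np.asarray(grid_b)
    if grid_a.values.shape != vb.shape:
        raise ValueError("grids must share one lattice")
    mask = grid_a.values > threshold
    if mask.sum() < 2:
        raise ValueError("empty correlation mask")
    a = grid_a.values[mask]
    b = vb[mask]
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(np.clip(np.dot(a, b) / denom, -1.0, 1.0))


def random_rotations(n: int, rng: np.random.Generator) -> np.ndarray:
    """n uniform rotation matrices via normalized random quaternions."""
    q = rng.normal(size=(n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    return np.array([quaternion_to_matrix(qi) for qi in q])


def quaternion_to_matrix(q: np.ndarray) -> np.ndarray:
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def global_search(model: StructureModel, target: DensityGrid,
                  n_rotations: int = 5000, n_translations: int = 5000,
                  resolution: float = 9.0, seed: int = 0,
                  threshold: float = 0.0, mode: str = "round_robin"
                  ) -> DockResult:
    """Random-orientation rigid-body fit of ``model`` into ``target``.

    The first candidate is always the identity rotation placed at the
    target's center of mass, so docking a model into its own simulated map
    starts in the correct basin.  ``mode='product'`` scores every
    rotation x translation combination instead of cycling the two lists.
    """
    if n_rotations < 1 or n_translations < 1:
        raise ValueError("need at least one rotation and one translation")
    if float(np.ptp(target.values)) == 0:
        raise ValueError("degenerate (constant) target map")
    rng = np.random.default_rng(seed)

    rots = np.concatenate([np.eye(3)[None],
                           random_rotations(n_rotations - 1, rng)]) \
        if n_rotations > 1 else np.eye(3)[None]
    com = target.center_of_mass()
    lo = target.origin
    hi = target.origin + target.extent
    trans = np.concatenate([
        com[None], rng.uniform(lo, hi, size=(n_translations - 1, 3))]) \
        if n_translations > 1 else com[None]

    centroid = model.coords.mean(axis=0)
    centered = model.coords - centroid
    weights = _weights(model)

    if mode == "product":
        pairs = [(r, t) for r in rots for t in trans]
    elif mode == "round_robin":
        n = max(len(rots), len(trans))
        pairs = [(rots[i % len(rots)], trans[i % len(trans)])
                 for i in range(n)]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    best = None
    for rot, pos in pairs:
        coords = centered @ rot.T + pos
        sim = simulate_density_on(target, coords, weights, resolution)
        score = cross_correlation(target, sim, threshold)
        if best is None or score > best[0]:
            best = (score, rot, pos)

    score, rot, pos = best
    return DockResult(rotation=rot, translation=pos, score=score,
                      n_evaluated=len(pairs), seed=seed)


# ---------------------------------------------------------------------------
# MRC2014 I/O (mode 2, float32)


def write_mrc(grid: DensityGrid, path) -> None:
    nx, ny, nz = grid.shape
    data = grid.values.astype("<f4")
    header = bytearray(1024)
    struct.pack_into("<3i", header, 0, nx, ny, nz)
    struct.pack_into("<i", header, 12, 2)                       # mode 2
    struct.pack_into("<3i", header, 16, 0, 0, 0)                # nstart
    struct.pack_into("<3i", header, 28, nx, ny, nz)             # mx my mz
    struct.pack_into("<3f", header, 40, nx * grid.voxel,
                     ny * grid.voxel, nz * grid.voxel)          # cell a b c
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", header, 64, 1, 2, 3)                # mapc/r/s
    struct.pack_into("<3f", header, 76, float(data.min()),
                     float(data.max()), float(data.mean()))
    struct.pack_into("<i", header, 88, 1)                       # ispg
    struct.pack_into("<3f", header, 196, *grid.origin)          # origin
    header[208:212] = b"MAP "
    header[212:216] = bytes([0x44, 0x44, 0, 0])                 # little endian
    struct.pack_into("<f", header, 216, float(data.std()))
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        # MRC stores columns (x) fastest: C-order over (z, y, x)
        data.transpose(2, 1, 0).tofile(fh)


def read_mrc(path) -> DensityGrid:
    with open(path, "rb") as fh:
        header = fh.read(1024)
        nx, ny, nz = struct.unpack_from("<3i", header, 0)
        mode, = struct.unpack_from("<i", header, 12)
        nxs, nys, nzs = struct.unpack_from("<3i", header, 16)
        mx, my, mz = struct.unpack_from("<3i", header, 28)
        ca, cb, cc = struct.unpack_from("<3f", header, 40)
        mapc, mapr, maps = struct.unpack_from("<3i", header, 64)
        ox, oy, oz = struct.unpack_from("<3f", header, 196)
        dtype = {0: "i1", 1: "<i2", 2: "<f4"}.get(mode)
        if dtype is None:
            raise ValueError(f"unsupported MRC mode {mode}")
        raw = np.fromfile(fh, dtype=dtype, count=nx * ny * nz)
    if raw.size != nx * ny * nz:
        raise ValueError("truncated MRC data block")
    voxel = ca / mx if mx else 1.0
    # file order: maps slowest, mapc fastest
    vol = raw.reshape(nz, ny, nx).transpose(2, 1, 0).astype(float)
    # normalize axis order so values[i, j, k] follows (x, y, z)
    order = np.argsort([mapc, mapr, maps])
    vol = np.transpose(vol, axes=order)
    origin = np.array([ox, oy, oz], float)
    if not origin.any() and (nxs or nys or nzs):
        origin = voxel * np.array([nxs, nys, nzs], float)
    return DensityGrid(origin=origin, voxel=float(voxel), values=vol)
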