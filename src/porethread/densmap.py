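"""Density map I/O, map simulation from coordinates, and real-space scoring.

Maps are voxel grids with cubic voxels on an orthogonal axis-aligned
lattice.  ``values[ix, iy, iz]`` is the density at Cartesian position
``origin + (ix, iy, iz) * voxel`` (origin in Angstrom; crystallographic
ORIGIN words of the MRC/CCP4 header).  Values are stored as float32 so
that the MRC round-trip (mode 2) is bit-exact.

Simulated density uses one isotropic Gaussian per atom with the nominal
resolution treated as the FWHM (sigma = resolution / 2.355) and amplitude
proportional to the atomic number.  Any monotone, documented convention
suffices for the recovery experiments in this package; this is the
simplest one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

#: FWHM of a Gaussian = SIGMA_PER_FWHM**-1 * sigma
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # 1/2.3548

#: atomic numbers of elements that occur in peptide models
ELEMENT_Z = {"H": 1, "C": 6, "N": 7, "O": 8, "S": 16, "P": 15}

#: Gaussians are truncated at this many sigmas
GAUSSIAN_CUTOFF_SIGMAS = 4.0


class MapError(ValueError):
    """Raised for malformed maps or invalid map operations."""


@dataclass
class DensityMap:
    """Voxel grid with physical spacing and origin (Angstrom)."""

    values: np.ndarray          # (nx, ny, nz) float32
    voxel: float                # cubic voxel edge, Angstrom
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3:
            raise MapError("map values must be a 3D array")
        if not self.voxel > 0:
            raise MapError(f"voxel size must be positive, got {self.voxel}")
        self.origin = np.asarray(self.origin, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise MapError("map contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def voxel_centers(self, indices: np.ndarray) -> np.ndarray:
        """Cartesian positions (Angstrom) of integer voxel indices."""
        return self.origin + np.asarray(indices, dtype=float) * self.voxel

    def interpolate(self, points: np.ndarray) -> np.ndarray:
        """Trilinear interpolation of map values at Cartesian points."""
        frac = (np.asarray(points, dtype=float) - self.origin) / self.voxel
        return ndimage.map_coordinates(
            self.values.astype(float), frac.T, order=1, mode="nearest"
        )

    def with_noise(self, sigma: float, rng: np.random.Generator) -> "DensityMap":
        """Copy with i.i.d. Gaussian noise of the given sigma per voxel."""
        noisy = self.values + rng.normal(0.0, sigma, self.values.shape)
        return DensityMap(noisy.astype(np.float32), self.voxel,
                          self.origin.copy())


# ---------------------------------------------------------------------------
# MRC / CCP4 I/O (gemmi)
# ---------------------------------------------------------------------------

def write_map(density_map: DensityMap, path) -> None:
    """Write an MRC/CCP4 map (mode 2, float32) with the origin in the
    ORIGIN header words (Angstrom offsets)."""
    nx, ny, nz = density_map.shape
    grid = gemmi.FloatGrid(nx, ny, nz)
    v = density_map.voxel
    grid.set_unit_cell(gemmi.UnitCell(nx * v, ny * v, nz * v, 90, 90, 90))
    np.array(grid, copy=False)[...] = density_map.values
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    for word, value in zip((50, 51, 52), density_map.origin):
        ccp4.set_header_float(word, float(value))
    ccp4.write_ccp4_map(str(path))


def read_map(path) -> DensityMap:
    """Read an MRC/CCP4 map written by :func:`write_map` (or compatible)."""
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise MapError(f"cannot read MRC/CCP4 map {path}: {exc}") from exc
    grid = ccp4.grid
    values = np.array(grid, copy=True)
    voxels = np.array([grid.unit_cell.a / grid.nu,
                       grid.unit_cell.b / grid.nv,
                       grid.unit_cell.c / grid.nw])
    if not np.allclose(voxels, voxels[0], atol=1e-6):
        raise MapError(f"anisotropic voxels unsupported: {voxels}")
    origin = np.array([ccp4.header_float(w) for w in (50, 51, 52)])
    return DensityMap(values, float(voxels[0]), origin)


# ---------------------------------------------------------------------------
# atoms and simulation
# ---------------------------------------------------------------------------

@dataclass
class AtomSet:
    """Flat list of scattering atoms: element, position, occupancy, B."""

    elements: list[str]
    positions: np.ndarray
    occupancies: np.ndarray | None = None
    b_factors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise MapError("positions must be (n, 3)")
        if len(self.elements) != len(self.positions):
            raise MapError("elements and positions length mismatch")
        if not np.all(np.isfinite(self.positions)):
            raise MapError("non-finite atom positions")
        unknown = set(self.elements) - set(ELEMENT_Z)
        if unknown:
            raise MapError(f"unsupported elements: {sorted(unknown)}")
        n = len(self.elements)
        if self.occupancies is None:
            self.occupancies = np.ones(n)
        if self.b_factors is None:
            self.b_factors = np.zeros(n)

    def __len__(self) -> int:
        return len(self.elements)

    @property
    def weights(self) -> np.ndarray:
        """Gaussian amplitudes: atomic number times occupancy."""
        z = np.array([ELEMENT_Z[e] for e in self.elements], dtype=float)
        return z * self.occupancies


def simulate_map(
    atoms: AtomSet | tuple[list[str], np.ndarray],
    resolution: float,
    voxel: float,
    padding: float = 5.0,
) -> DensityMap:
    """Simulate a density map from atoms on a fresh grid covering them.

    Each atom contributes ``Z * occ * exp(-r^2 / (2 sigma^2))`` with
    ``sigma = resolution * FWHM_TO_SIGMA``, truncated at 4 sigma.
    """
    atoms = _as_atomset(atoms)
    if len(atoms) == 0:
        raise MapError("cannot simulate a map from an empty atom set")
    if resolution < 2.0 * voxel:
        raise MapError(
            f"resolution {resolution} below Nyquist for voxel {voxel}"
        )
    sigma = resolution * FWHM_TO_SIGMA
    cutoff = GAUSSIAN_CUTOFF_SIGMAS * sigma

    lo = atoms.positions.min(axis=0) - padding
    hi = atoms.positions.max(axis=0) + padding
    shape = np.ceil((hi - lo) / voxel).astype(int) + 1
    values = np.zeros(shape, dtype=float)
    weights = atoms.weights

    axes = [lo[d] + voxel * np.arange(shape[d]) for d in range(3)]
    half = int(np.ceil(cutoff / voxel))
    for pos, w in zip(atoms.positions, weights):
        idx0 = np.round((pos - lo) / voxel).astype(int)
        sl, local = [], []
        for d in range(3):
            a = max(0, idx0[d] - half)
            b = min(shape[d], idx0[d] + half + 1)
            sl.append(slice(a, b))
            local.append(axes[d][a:b] - pos[d])
        dx2 = local[0][:, None, None] ** 2
        dy2 = local[1][None, :, None] ** 2
        dz2 = local[2][None, None, :] ** 2
        r2 = dx2 + dy2 + dz2
        g = np.where(r2 <= cutoff**2,
                     w * np.exp(-r2 / (2.0 * sigma**2)), 0.0)
        values[sl[0], sl[1], sl[2]] += g
    return DensityMap(values.astype(np.float32), voxel, lo)


def simulate_on_points(
    elements: list[str],
    positions: np.ndarray,
    points: np.ndarray,
    resolution: float,
    occupancies: np.ndarray | None = None,
) -> np.ndarray:
    """Simulated density evaluated at arbitrary Cartesian points.

    Same Gaussian convention as :func:`simulate_map`; used for
    correlation scoring where the evaluation points are fixed.
    """
    sigma = resolution * FWHM_TO_SIGMA
    cutoff = GAUSSIAN_CUTOFF_SIGMAS * sigma
    positions = np.asarray(positions, dtype=float)
    z = np.array([ELEMENT_Z[e] for e in elements], dtype=float)
    if occupancies is not None:
        z = z * occupancies
    out = np.zeros(len(points))
    tree = cKDTree(points)
    inv_two_sigma2 = 1.0 / (2.0 * sigma**2)
    neighbor_lists = tree.query_ball_point(positions, cutoff)
    for pos, w, neigh in zip(positions, z, neighbor_lists):
        if not neigh:
            continue
        neigh = np.asarray(neigh)
        d2 = np.sum((points[neigh] - pos) ** 2, axis=1)
        out[neigh] += w * np.exp(-d2 * inv_two_sigma2)
    return out


def real_space_cc(
    atoms: AtomSet | tuple[list[str], np.ndarray],
    density_map: DensityMap,
    mask_radius: float = 3.0,
    resolution: float = 3.0,
    mask_indices: np.ndarray | None = None,
) -> float:
    """Pearson correlation between simulated and target density over a
    mask of voxels within ``mask_radius`` of any atom.

    ``mask_indices`` (an (m, 3) integer voxel-index array) may be passed
    to reuse a precomputed mask across repeated scoring of nearly
    identical models.
    """
    atoms = _as_atomset(atoms)
    if len(atoms) == 0:
        raise MapError("cannot score an empty atom set")
    if mask_indices is None:
        mask_indices = mask_voxels(atoms.positions, density_map, mask_radius)
    if len(mask_indices) == 0:
        raise MapError("empty mask: atoms outside the map?")
    points = density_map.voxel_centers(mask_indices)
    target = density_map.values[
        mask_indices[:, 0], mask_indices[:, 1], mask_indices[:, 2]
    ].astype(float)
    if np.std(target) < 1e-12:
        raise MapError("target map is constant over the mask; "
                       "correlation undefined")
    sim = simulate_on_points(
        atoms.elements, atoms.positions, points, resolution,
        occupancies=atoms.occupancies,
    )
    if np.std(sim) < 1e-12:
        raise MapError("simulated density is constant over the mask")
    return float(np.corrcoef(sim, target)[0, 1])


def mask_voxels(
    positions: np.ndarray, density_map: DensityMap, mask_radius: float
) -> np.ndarray:
    """Integer indices of voxels within ``mask_radius`` of any position."""
    positions = np.asarray(positions, dtype=float)
    lo = np.floor(
        (positions.min(axis=0) - mask_radius - density_map.origin)
        / density_map.voxel
    ).astype(int)
    hi = np.ceil(
        (positions.max(axis=0) + mask_radius - density_map.origin)
        / density_map.voxel
    ).astype(int)
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, np.array(density_map.shape) - 1)
    if np.any(hi < lo):
        return np.empty((0, 3), dtype=int)
    grids = np.meshgrid(*[np.arange(a, b + 1) for a, b in zip(lo, hi)],
                        indexing="ij")
    idx = np.stack([g.ravel() for g in grids], axis=1)
    pts = density_map.voxel_centers(idx)
    tree = cKDTree(positions)
    dist, _ = tree.query(pts, k=1, distance_upper_bound=mask_radius)
    return idx[np.isfinite(dist)]


def _as_atomset(atoms) -> AtomSet:
    if isinstance(atoms, AtomSet):
        return atoms
    elements, positions = atoms
    return AtomSet(elements=list(elements), positions=positions)
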