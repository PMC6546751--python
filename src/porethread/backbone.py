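"""Symmetrized substrate backbone: build, measure, and recover from density.

An extended polypeptide threaded through a AAA+ translocation channel is
modelled as a *symmetrized* chain: a two-residue dihedral repeat
(phi1, psi1, phi2, psi2) applied alternately along the strand, with the
peptide bond held trans (omega = 180 deg).  Symmetrizing avoids
overfitting the backbone to modest-resolution tubular density: only four
torsions are free, and they are recovered by evaluating candidate chains
against the density on a 2-degree grid.

Atoms are placed sequentially in internal coordinates (the NeRF
construction: each atom from the previous three via bond length, bond
angle, torsion), so a built chain reproduces its generating torsions
exactly on re-measurement.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

BACKBONE_ATOMS = ("N", "CA", "C", "O", "CB")


class GeometryError(ValueError):
    """Raised for degenerate covalent geometry or invalid chain requests."""


@dataclass(frozen=True)
class DihedralRepeat:
    """Two-residue backbone dihedral repeat, degrees in (-180, 180].

    ``phi1/psi1`` apply to odd residues (1st, 3rd, ...), ``phi2/psi2``
    to even residues; ``omega`` is the peptide-bond torsion, fixed trans
    by default.
    """

    phi1: float
    psi1: float
    phi2: float
    psi2: float
    omega: float = 180.0

    def __post_init__(self) -> None:
        for name in ("phi1", "psi1", "phi2", "psi2", "omega"):
            v = getattr(self, name)
            if v == -180.0:  # -180 and +180 are the same torsion
                object.__setattr__(self, name, 180.0)
                continue
            if not (-180.0 < v <= 180.0):
                raise ValueError(f"{name}={v} outside (-180, 180]")

    def phi_psi(self, residue_index: int) -> tuple[float, float]:
        """(phi, psi) for 0-based residue index."""
        if residue_index % 2 == 0:
            return self.phi1, self.psi1
        return self.phi2, self.psi2

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.phi1, self.psi1, self.phi2, self.psi2)


@dataclass(frozen=True)
class GeometryParams:
    """Idealized covalent backbone geometry (lengths in Angstrom, angles deg).

    Defaults are standard idealized values (Engh & Huber-type); the
    repeat analysis only requires a consistent set, not a particular one.
    """

    len_n_ca: float = 1.458
    len_ca_c: float = 1.525
    len_c_n: float = 1.329
    len_c_o: float = 1.231
    len_ca_cb: float = 1.521
    ang_n_ca_c: float = 111.2
    ang_ca_c_n: float = 116.2
    ang_c_n_ca: float = 121.7
    ang_ca_c_o: float = 120.8
    ang_n_ca_cb: float = 110.4
    #: improper torsion C(i)-N(i)-CA(i)-CB(i) setting L-chirality
    improper_cb: float = -122.6

    def __post_init__(self) -> None:
        for name in ("len_n_ca", "len_ca_c", "len_c_n", "len_c_o", "len_ca_cb"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("ang_n_ca_c", "ang_ca_c_n", "ang_c_n_ca",
                     "ang_ca_c_o", "ang_n_ca_cb"):
            v = getattr(self, name)
            if not (0.0 < v < 180.0):
                raise ValueError(f"{name}={v} outside (0, 180)")


@dataclass
class BackboneModel:
    """Per-residue backbone (+ CB) coordinates of a symmetrized strand.

    ``coords[name]`` is an (n_residues, 3) array for each of N, CA, C,
    O, CB.  The generating repeat and geometry are retained so threaded
    models can be rebuilt and the chain re-derived.
    """

    n_residues: int
    coords: dict[str, np.ndarray]
    repeat: DihedralRepeat | None = None
    geometry: GeometryParams = field(default_factory=GeometryParams)

    def atom(self, name: str, residue_index: int) -> np.ndarray:
        return self.coords[name][residue_index]

    def all_atoms(self) -> tuple[list[str], np.ndarray]:
        """Flattened (element symbols, positions) over all backbone atoms."""
        elements, positions = [], []
        for i in range(self.n_residues):
            for name in BACKBONE_ATOMS:
                elements.append("O" if name == "O" else
                                "N" if name == "N" else "C")
                positions.append(self.coords[name][i])
        return elements, np.asarray(positions)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray
                    ) -> "BackboneModel":
        """Rigid-body transformed copy (x -> R x + t)."""
        new = {k: v @ rotation.T + translation for k, v in self.coords.items()}
        return replace(self, coords=new)


# ---------------------------------------------------------------------------
# torsion / placement primitives
# ---------------------------------------------------------------------------

def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed torsion angle p0-p1-p2-p3 in degrees (IUPAC convention)."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    nb1 = np.linalg.norm(b1)
    if nb1 < 1e-12:
        raise GeometryError("degenerate torsion: coincident central atoms")
    b1 = b1 / nb1
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float
               ) -> np.ndarray:
    """Place atom D given reference atoms A, B, C.

    D is at distance ``bond`` from C, with angle B-C-D = ``angle_deg``
    and torsion A-B-C-D = ``torsion_deg``.
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    bc = c - b
    n_bc = np.linalg.norm(bc)
    ab = b - a
    if n_bc < 1e-12 or np.linalg.norm(ab) < 1e-12:
        raise GeometryError("degenerate placement: coincident reference atoms")
    bc_hat = bc / n_bc
    n = np.cross(ab, bc_hat)
    n_norm = np.linalg.norm(n)
    if n_norm < 1e-12:
        raise GeometryError("degenerate placement: collinear reference atoms")
    n_hat = n / n_norm
    m_hat = np.cross(n_hat, bc_hat)
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    d_local = bond * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(tor), np.sin(ang) * np.sin(tor)]
    )
    return c + d_local[0] * bc_hat + d_local[1] * m_hat + d_local[2] * n_hat


# ---------------------------------------------------------------------------
# chain construction
# ---------------------------------------------------------------------------

def _place_fast(a, b, c, bond: float, ang: float, tor: float):
    """Scalar-arithmetic NeRF placement (radian angles, tuple points).

    Same geometry as :func:`place_atom`; used in the chain-building inner
    loop where numpy call overhead dominates.
    """
    import math

    bcx, bcy, bcz = c[0] - b[0], c[1] - b[1], c[2] - b[2]
    nbc = math.sqrt(bcx * bcx + bcy * bcy + bcz * bcz)
    bcx, bcy, bcz = bcx / nbc, bcy / nbc, bcz / nbc
    abx, aby, abz = b[0] - a[0], b[1] - a[1], b[2] - a[2]
    nx = aby * bcz - abz * bcy
    ny = abz * bcx - abx * bcz
    nz = abx * bcy - aby * bcx
    nn = math.sqrt(nx * nx + ny * ny + nz * nz)
    if nn < 1e-12:
        raise GeometryError("degenerate placement: collinear reference atoms")
    nx, ny, nz = nx / nn, ny / nn, nz / nn
    mx = ny * bcz - nz * bcy
    my = nz * bcx - nx * bcz
    mz = nx * bcy - ny * bcx
    d0 = -bond * math.cos(ang)
    d1 = bond * math.sin(ang) * math.cos(tor)
    d2 = bond * math.sin(ang) * math.sin(tor)
    return (
        c[0] + d0 * bcx + d1 * mx + d2 * nx,
        c[1] + d0 * bcy + d1 * my + d2 * ny,
        c[2] + d0 * bcz + d1 * mz + d2 * nz,
    )


def build_chain(
    repeat: DihedralRepeat,
    n_residues: int,
    geom: GeometryParams | None = None,
) -> BackboneModel:
    """Build a symmetrized strand by sequential internal-coordinate placement.

    The first residue is placed in a canonical frame (N at the origin,
    CA on +x, C in the xy-plane); every subsequent atom follows from the
    previous three by bond length, bond angle, and torsion.  Odd/even
    residues alternate between the two (phi, psi) pairs of the repeat.
    """
    if n_residues < 2:
        raise GeometryError(f"n_residues must be >= 2, got {n_residues}")
    geom = geom or GeometryParams()
    rad = np.radians

    n_pts: list[tuple] = [(0.0, 0.0, 0.0)]
    ca_pts: list[tuple] = [(geom.len_n_ca, 0.0, 0.0)]
    ang = rad(geom.ang_n_ca_c)
    ca0 = ca_pts[0]
    c_pts: list[tuple] = [(
        ca0[0] - geom.len_ca_c * np.cos(ang),
        ca0[1] + geom.len_ca_c * np.sin(ang),
        0.0,
    )]

    a_ca_c_n = rad(geom.ang_ca_c_n)
    a_c_n_ca = rad(geom.ang_c_n_ca)
    a_n_ca_c = rad(geom.ang_n_ca_c)
    omega = rad(repeat.omega)
    for i in range(1, n_residues):
        psi_prev = rad(repeat.phi_psi(i - 1)[1])
        phi_i = rad(repeat.phi_psi(i)[0])
        # N(i): torsion N(i-1)-CA(i-1)-C(i-1)-N(i) = psi(i-1)
        n_pts.append(_place_fast(
            n_pts[i - 1], ca_pts[i - 1], c_pts[i - 1],
            geom.len_c_n, a_ca_c_n, psi_prev,
        ))
        # CA(i): torsion CA(i-1)-C(i-1)-N(i)-CA(i) = omega
        ca_pts.append(_place_fast(
            ca_pts[i - 1], c_pts[i - 1], n_pts[i],
            geom.len_n_ca, a_c_n_ca, omega,
        ))
        # C(i): torsion C(i-1)-N(i)-CA(i)-C(i) = phi(i)
        c_pts.append(_place_fast(
            c_pts[i - 1], n_pts[i], ca_pts[i],
            geom.len_ca_c, a_n_ca_c, phi_i,
        ))

    # carbonyl O and CB from the finished N/CA/C trace
    a_ca_c_o = rad(geom.ang_ca_c_o)
    a_n_ca_cb = rad(geom.ang_n_ca_cb)
    improper = rad(geom.improper_cb)
    o_pts, cb_pts = [], []
    for i in range(n_residues):
        psi_i = rad(repeat.phi_psi(i)[1] + 180.0)
        # O anti to the next amide N: torsion N-CA-C-O = psi + 180
        o_pts.append(_place_fast(
            n_pts[i], ca_pts[i], c_pts[i],
            geom.len_c_o, a_ca_c_o, psi_i,
        ))
        # CB by the L-chirality improper torsion C-N-CA-CB
        cb_pts.append(_place_fast(
            c_pts[i], n_pts[i], ca_pts[i],
            geom.len_ca_cb, a_n_ca_cb, improper,
        ))

    n_xyz = np.array(n_pts)
    ca_xyz = np.array(ca_pts)
    c_xyz = np.array(c_pts)
    o_xyz = np.array(o_pts)
    cb_xyz = np.array(cb_pts)

    return BackboneModel(
        n_residues=n_residues,
        coords={"N": n_xyz, "CA": ca_xyz, "C": c_xyz, "O": o_xyz, "CB": cb_xyz},
        repeat=repeat,
        geometry=geom,
    )


def measure_dihedrals(model: BackboneModel) -> list[tuple[float | None, float | None]]:
    """Per-residue (phi, psi) measured from coordinates.

    phi of the first and psi of the last residue are undefined for a
    finite chain and reported as ``None``.
    """
    n = model.n_residues
    if n < 2:
        raise GeometryError("need at least 2 residues to measure dihedrals")
    N, CA, C = model.coords["N"], model.coords["CA"], model.coords["C"]
    out: list[tuple[float | None, float | None]] = []
    for i in range(n):
        phi = (
            dihedral_angle(C[i - 1], N[i], CA[i], C[i]) if i > 0 else None
        )
        psi = (
            dihedral_angle(N[i], CA[i], C[i], N[i + 1]) if i < n - 1 else None
        )
        out.append((phi, psi))
    return out


def measure_repeat(model: BackboneModel) -> DihedralRepeat:
    """Recover the generating two-residue repeat from a built chain.

    Uses the first residue carrying each defined angle of each parity.
    """
    dihedrals = measure_dihedrals(model)
    phi = {0: None, 1: None}
    psi = {0: None, 1: None}
    for i, (p, s) in enumerate(dihedrals):
        par = i % 2
        if phi[par] is None and p is not None:
            phi[par] = p
        if psi[par] is None and s is not None:
            psi[par] = s
    if any(v is None for v in (*phi.values(), *psi.values())):
        raise GeometryError("chain too short to recover a two-residue repeat")
    return DihedralRepeat(phi1=phi[0], psi1=psi[0], phi2=phi[1], psi2=psi[1])


# ---------------------------------------------------------------------------
# axial geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AxialGeometry:
    """Least-squares helical axis with per-residue rise and rotation."""

    axis_point: np.ndarray
    axis_direction: np.ndarray
    rise_per_residue: np.ndarray      # (n-1,) Angstrom
    rotation_per_residue: np.ndarray  # (n-1,) degrees

    @property
    def mean_rise(self) -> float:
        return float(np.mean(self.rise_per_residue))

    @property
    def mean_rotation(self) -> float:
        return float(np.mean(self.rotation_per_residue))


def fit_axis(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares 3D line through points: (centroid, unit direction)."""
    points = np.asarray(points, dtype=float)
    centroid = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - centroid)
    direction = vt[0]
    # orient along increasing point order
    proj = (points - centroid) @ direction
    if proj[-1] < proj[0]:
        direction = -direction
    return centroid, direction


def spiral_steps(points: np.ndarray,
                 axis_point: np.ndarray,
                 axis_dir: np.ndarray,
                 min_radius: float = 1e-6,
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Per-step rise (Angstrom) and rotation (degrees) of ordered points
    about a given axis.  Rotation is signed about ``axis_dir``; points
    radially closer to the axis than ``min_radius`` make the azimuth
    undefined and raise :class:`GeometryError`.
    """
    points = np.asarray(points, dtype=float)
    rel = points - axis_point
    z = rel @ axis_dir
    radial = rel - np.outer(z, axis_dir)
    r = np.linalg.norm(radial, axis=1)
    if np.any(r < min_radius):
        raise GeometryError(
            "point(s) on the axis: rotation undefined (collinear stack?)"
        )
    # orthonormal frame perpendicular to the axis
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, axis_dir)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = ref - np.dot(ref, axis_dir) * axis_dir
    u /= np.linalg.norm(u)
    v = np.cross(axis_dir, u)
    theta = np.degrees(np.arctan2(radial @ v, radial @ u))
    dtheta = np.diff(theta)
    dtheta = (dtheta + 180.0) % 360.0 - 180.0
    return np.diff(z), dtheta


def axial_geometry(model: BackboneModel) -> AxialGeometry:
    """Axis, per-residue rise, and per-residue rotation of the CA trace."""
    if model.n_residues < 4:
        raise GeometryError("axial geometry requires at least 4 residues")
    ca = model.coords["CA"]
    axis_point, axis_dir = fit_axis(ca)
    rise, rot = spiral_steps(ca, axis_point, axis_dir)
    return AxialGeometry(
        axis_point=axis_point,
        axis_direction=axis_dir,
        rise_per_residue=rise,
        rotation_per_residue=rot,
    )


# ---------------------------------------------------------------------------
# density-guided grid search for the repeat
# ---------------------------------------------------------------------------

#: generalized beta-region search box: phi in [-180, -30], psi in [60, 180]
DEFAULT_SEARCH_REGION = ((-180.0, -30.0), (60.0, 180.0))


@dataclass
class GridSearchResult:
    repeat: DihedralRepeat
    score: float
    converged: bool
    n_iterations: int
    n_evaluations: int


def _kabsch(mobile: np.ndarray, target: np.ndarray
            ) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R and translation t minimizing |R m + t - target|."""
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return r, tc - r @ mc


def _axis_angle_to_matrix(vec: np.ndarray) -> np.ndarray:
    theta = np.linalg.norm(vec)
    if theta < 1e-12:
        return np.eye(3)
    k = vec / theta
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(theta) * kx + (1 - np.cos(theta)) * (kx @ kx)


class _MapEvaluator:
    """Correlation of candidate chains with a density map.

    The evaluation region is the set of voxels carrying significant
    density (above a fraction of the maximum), fixed for the whole
    search so scores are comparable across candidates.
    """

    def __init__(self, density_map, resolution: float = 3.0,
                 threshold_fraction: float = 0.05):
        from . import densmap  # local import: avoid cycle at module load

        self._densmap = densmap
        self.map = density_map
        self.resolution = resolution
        values = density_map.values
        thr = threshold_fraction * float(values.max())
        idx = np.argwhere(values > thr)
        if len(idx) == 0:
            raise GeometryError("density map has no voxels above threshold")
        self.points = density_map.origin + idx * density_map.voxel
        self.target = values[idx[:, 0], idx[:, 1], idx[:, 2]].astype(float)
        self.target = self.target - self.target.mean()
        self._target_norm = np.linalg.norm(self.target)
        if self._target_norm < 1e-12:
            raise GeometryError("density map is constant over the region")
        # weighted centroid / principal axis of the density region
        w = np.clip(self.target - self.target.min(), 0, None)
        self.density_centroid = (self.points * w[:, None]).sum(0) / w.sum()
        _, self.density_axis = fit_axis(
            self.points[self.target > np.percentile(self.target, 75)]
        )
        self.n_evaluations = 0

    def correlation(self, elements: list[str], positions: np.ndarray) -> float:
        from scipy.spatial.distance import cdist

        self.n_evaluations += 1
        weights = np.array(
            [self._densmap.ELEMENT_Z[e] for e in elements], dtype=float
        )
        sigma = self.resolution * self._densmap.FWHM_TO_SIGMA
        d2 = cdist(positions, self.points, "sqeuclidean")
        sim = weights @ np.exp(-d2 / (2.0 * sigma * sigma))
        sim = sim - sim.mean()
        denom = np.linalg.norm(sim) * self._target_norm
        if denom < 1e-12:
            return -1.0
        return float(np.dot(sim, self.target) / denom)

    def score_model(self, model: BackboneModel) -> float:
        elements, positions = model.all_atoms()
        return self.correlation(elements, positions)


def _polish_placement(model: BackboneModel, ev: _MapEvaluator,
                      maxiter: int = 400) -> BackboneModel:
    """Local 6-parameter rigid-body polish by correlation maximization."""
    from scipy.optimize import minimize

    elements, base_pos = model.all_atoms()
    center = model.coords["CA"].mean(axis=0)

    def neg_cc(x):
        r = _axis_angle_to_matrix(x[:3])
        pos = (base_pos - center) @ r.T + center + x[3:]
        return -ev.correlation(elements, pos)

    best_x = np.zeros(6)
    for _ in range(2):  # restart once: Nelder-Mead stalls on narrow valleys
        res = minimize(neg_cc, best_x, method="Nelder-Mead",
                       options={"maxiter": maxiter,
                                "xatol": 1e-5, "fatol": 1e-9})
        best_x = res.x
    r = _axis_angle_to_matrix(best_x[:3])
    t = center - r @ center + best_x[3:]
    return model.transformed(r, t)


def _align_chain_to_map(model: BackboneModel, ev: _MapEvaluator
                        ) -> BackboneModel:
    """Rigid-body placement of a chain into the density tube from scratch.

    Coarse pre-alignment (chain CA axis onto the density principal axis,
    centroid onto the weighted density centroid), then a scan over the
    residual rotation about the tube axis and axial shift, then a local
    6-parameter polish by correlation maximization.
    """
    ca = model.coords["CA"]
    _, chain_axis = fit_axis(ca)
    # rotate chain axis onto density axis
    v = np.cross(chain_axis, ev.density_axis)
    s = np.linalg.norm(v)
    c = float(np.dot(chain_axis, ev.density_axis))
    if s < 1e-9:
        r0 = np.eye(3) if c > 0 else _axis_angle_to_matrix(
            np.pi * _perpendicular(chain_axis))
    else:
        r0 = _axis_angle_to_matrix(v / s * np.arctan2(s, c))
    base = model.transformed(r0, ev.density_centroid - r0 @ ca.mean(axis=0))

    elements, base_pos = base.all_atoms()
    center = base.coords["CA"].mean(axis=0)
    best = (-np.inf, None)
    for theta in np.arange(0.0, 360.0, 15.0):
        rot = _axis_angle_to_matrix(np.radians(theta) * ev.density_axis)
        for shift in (-3.0, -1.5, 0.0, 1.5, 3.0):
            pos = (base_pos - center) @ rot.T + center \
                + shift * ev.density_axis
            cc = ev.correlation(elements, pos)
            if cc > best[0]:
                best = (cc, (rot, shift))
    rot, shift = best[1]
    coarse = base.transformed(
        rot, center - rot @ center + shift * ev.density_axis
    )
    return _polish_placement(coarse, ev)


def _perpendicular(v: np.ndarray) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, v)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    p = np.cross(v, ref)
    return p / np.linalg.norm(p)


def _grid_axis(lo: float, hi: float, step: float) -> np.ndarray:
    n = int(round((hi - lo) / step))
    return lo + step * np.arange(n + 1)


def grid_search_repeat(
    density_map,
    n_residues: int,
    grid_step: float = 2.0,
    search_region: tuple[tuple[float, float], tuple[float, float]] = DEFAULT_SEARCH_REGION,
    start: DihedralRepeat | None = None,
    geom: GeometryParams | None = None,
    resolution: float = 3.0,
    max_iterations: int = 10,
    symmetric_init: bool = True,
    joint_window: float = 10.0,
) -> GridSearchResult:
    """Recover the two-residue dihedral repeat from tubular density.

    Search strategy (a full 4-D exhaustive scan at 2 degrees is
    combinatorially infeasible):

    1. *Symmetric initialization* — scan the single-residue diagonal
       (phi, psi, phi, psi) over the region; the best symmetric helix is
       a robust starting ridge point.
    2. *Coordinate descent* over the (phi1, psi1) and (phi2, psi2)
       planes: each plane scanned exhaustively on the grid while the
       other pair is held fixed, alternating until neither improves.
    3. *Joint local refinement* — the two dihedral pairs compensate
       (a symmetric average fits almost as well as the true asymmetric
       repeat), so the descent fixpoint is polished by an exhaustive
       scan of the joint 4-D grid neighborhood (``joint_window`` degrees
       on each axis), iterated until it is a fixpoint too.

    Every candidate chain is placed into the map by rigid-body
    superposition of its CA trace onto the current anchor chain (itself
    rigid-body fitted to the density by correlation maximization), then
    scored by real-space correlation over the density region.  Ties are
    broken toward the candidate closest to the search start.  The whole
    procedure is deterministic given its inputs.
    """
    if start is None:
        start = DihedralRepeat(-120.0, 120.0, -120.0, 120.0)
    geom = geom or GeometryParams()
    (phi_lo, phi_hi), (psi_lo, psi_hi) = search_region
    phis = _grid_axis(phi_lo, phi_hi, grid_step)
    psis = _grid_axis(psi_lo, psi_hi, grid_step)

    ev = _MapEvaluator(density_map, resolution=resolution)
    start_vec = np.array(start.as_tuple())

    def dist_to_start(rep: DihedralRepeat) -> float:
        return float(np.linalg.norm(np.array(rep.as_tuple()) - start_vec))

    state = {"anchor_ca": None, "score": -np.inf, "repeat": None}

    def re_anchor(rep: DihedralRepeat, from_scratch: bool = False) -> None:
        chain = build_chain(rep, n_residues, geom)
        if from_scratch or state["anchor_ca"] is None:
            placed = _align_chain_to_map(chain, ev)
        else:
            r, t = _kabsch(chain.coords["CA"], state["anchor_ca"])
            placed = _polish_placement(chain.transformed(r, t), ev)
        state["anchor_ca"] = placed.coords["CA"]
        state["score"] = ev.score_model(placed)
        state["repeat"] = rep

    def evaluate(rep: DihedralRepeat) -> float:
        chain = build_chain(rep, n_residues, geom)
        r, t = _kabsch(chain.coords["CA"], state["anchor_ca"])
        return ev.score_model(chain.transformed(r, t))

    def scan(candidates) -> tuple[float, DihedralRepeat, float]:
        best = (state["score"], state["repeat"],
                dist_to_start(state["repeat"]))
        for cand in candidates:
            if cand == best[1]:
                continue
            score = evaluate(cand)
            d = dist_to_start(cand)
            if score > best[0] or (score == best[0] and d < best[2]):
                best = (score, cand, d)
        return best

    re_anchor(start, from_scratch=True)
    n_improvements = 0

    if symmetric_init:
        _, best_diag, _ = scan(
            DihedralRepeat(float(p), float(s), float(p), float(s))
            for p, s in itertools.product(phis, psis)
        )
        if best_diag != state["repeat"]:
            n_improvements += 1
            re_anchor(best_diag)

    converged = False
    n_iter = 0
    for n_iter in range(1, max_iterations + 1):
        improved = False
        for plane in (1, 2):
            keys = ("phi1", "psi1") if plane == 1 else ("phi2", "psi2")
            _, best_rep, _ = scan(
                replace(state["repeat"],
                        **{keys[0]: float(p), keys[1]: float(s)})
                for p, s in itertools.product(phis, psis)
            )
            if best_rep != state["repeat"]:
                improved = True
                n_improvements += 1
                re_anchor(best_rep)
        if not improved:
            converged = True
            break

    # joint 4-D neighborhood polish around the descent fixpoint
    half = int(round(joint_window / grid_step))
    for _ in range(max_iterations):
        c = state["repeat"]
        axes = []
        for base, grid in ((c.phi1, phis), (c.psi1, psis),
                           (c.phi2, phis), (c.psi2, psis)):
            sel = grid[np.abs(grid - base) <= half * grid_step + 1e-9]
            axes.append(sel)
        _, best_rep, _ = scan(
            DihedralRepeat(float(a), float(b), float(g), float(d))
            for a, b, g, d in itertools.product(*axes)
        )
        if best_rep == state["repeat"]:
            break
        n_improvements += 1
        re_anchor(best_rep)
    else:
        converged = False

    if not converged:
        logger.warning(
            "grid search did not converge after %d iterations; "
            "returning best repeat so far", max_iterations,
        )
    return GridSearchResult(
        repeat=state["repeat"],
        score=state["score"],
        converged=converged,
        n_iterations=n_improvements,
        n_evaluations=ev.n_evaluations,
    )


# ---------------------------------------------------------------------------
# PDB export
# ---------------------------------------------------------------------------

def write_backbone_pdb(model: BackboneModel, path, chain_id: str = "A",
                       residue_name: str = "ALA") -> None:
    """Write the backbone (+CB) as a poly-Ala PDB file via gemmi."""
    import gemmi

    structure = gemmi.Structure()
    structure.name = "backbone"
    gmodel = gemmi.Model("1")
    chain = gemmi.Chain(chain_id)
    for i in range(model.n_residues):
        res = gemmi.Residue()
        res.name = residue_name
        res.seqid = gemmi.SeqId(i + 1, " ")
        for name in BACKBONE_ATOMS:
            atom = gemmi.Atom()
            atom.name = name
            atom.element = gemmi.Element(name[0])
            pos = model.coords[name][i]
            atom.pos = gemmi.Position(*pos)
            res.add_atom(atom)
        chain.add_residue(res)
    gmodel.add_chain(chain)
    structure.add_model(gmodel)
    structure.setup_entities()
    structure.write_pdb(str(path))
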