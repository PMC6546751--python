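"""Spiral contact geometry and protomer expansion metrics from atomic models.

The pore loops of a substrate-engaged AAA+ hexamer grip the polypeptide
in a right-handed spiral staircase: consecutive protomer contacts are
separated by an axial rise (~6-7 Angstrom, a dipeptide) and rotate
(~60 degrees) about the channel axis.  This module measures that
geometry from anchor atoms (one per protomer; default CA of a chosen
pore-loop residue), and measures per-protomer distances between residue
pairs (e.g. markers flanking the NBD1-NBD2 interface whose separation
expands on substrate release).

Models are read with gemmi (PDB or mmCIF).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .backbone import GeometryError, fit_axis, spiral_steps

logger = logging.getLogger(__name__)


class AnchorError(KeyError):
    """Raised when a requested anchor atom cannot be resolved."""


def fit_helix_axis(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares helix axis through ordered spiral points.

    For an ideal helix the chord bisector at every interior point is
    radial (perpendicular to the axis), so the axis direction is the
    null-space vector of the stacked bisectors; the axis position is the
    least-squares circle centre of the points projected onto the
    perpendicular plane.  A straight line fit would be biased here: for
    a wide spiral the in-plane spread dominates the axial spread.

    Collinear point stacks (zero spiral radius, e.g. rotation-free
    protomer stacks) leave the azimuth undefined and raise
    :class:`~porethread.backbone.GeometryError`.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n < 3:
        raise ValueError(f"need at least 3 points, got {n}")
    # explicit collinearity check (line-fit residual)
    line_point, line_dir = fit_axis(points)
    rel = points - line_point
    residual = rel - np.outer(rel @ line_dir, line_dir)
    if np.max(np.linalg.norm(residual, axis=1)) < 1e-3:
        raise GeometryError(
            "anchor points are collinear: spiral rotation undefined"
        )
    if n == 3:
        axis = np.cross(points[1] - points[0], points[2] - points[0])
        axis = axis / np.linalg.norm(axis)
    else:
        bisectors = np.array([
            (points[i - 1] - points[i]) + (points[i + 1] - points[i])
            for i in range(1, n - 1)
        ])
        _, _, vt = np.linalg.svd(bisectors)
        axis = vt[-1]
    z = points @ axis
    if z[-1] < z[0]:
        axis = -axis
    # circle centre in the perpendicular plane (algebraic fit)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, axis)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = ref - np.dot(ref, axis) * axis
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    x, y = points @ u, points @ v
    design = np.column_stack([2 * x, 2 * y, np.ones(n)])
    sol, *_ = np.linalg.lstsq(design, x * x + y * y, rcond=None)
    centre = sol[0] * u + sol[1] * v + float(np.mean(points @ axis)) * axis
    return centre, axis


@dataclass(frozen=True)
class Anchor:
    """One protomer's anchor: chain name, residue seqid, atom name."""

    chain: str
    residue: int
    atom: str = "CA"


@dataclass
class ContactSpiral:
    """Ordered protomer anchors with fitted axis and per-step geometry."""

    labels: list[str]
    positions: np.ndarray
    axis_point: np.ndarray
    axis_direction: np.ndarray
    rise_per_step: np.ndarray      # (n-1,) Angstrom
    rotation_per_step: np.ndarray  # (n-1,) degrees

    @property
    def mean_rise(self) -> float:
        return float(np.mean(self.rise_per_step))

    @property
    def mean_rotation(self) -> float:
        return float(np.mean(np.abs(self.rotation_per_step)))

    def to_frame(self) -> pd.DataFrame:
        """Per-step report (consecutive protomer pairs)."""
        return pd.DataFrame({
            "step": [f"{a}-{b}" for a, b in
                     zip(self.labels[:-1], self.labels[1:])],
            "rise_A": self.rise_per_step,
            "rotation_deg": self.rotation_per_step,
        })


def read_model(path: str | Path) -> gemmi.Structure:
    """Read an atomic model (PDB or mmCIF)."""
    structure = gemmi.read_structure(str(path))
    structure.setup_entities()
    return structure


def _resolve_atom(structure: gemmi.Structure, anchor: Anchor) -> np.ndarray:
    model = structure[0]
    for chain in model:
        if chain.name != anchor.chain:
            continue
        for residue in chain:
            if residue.seqid.num != anchor.residue:
                continue
            for atom in residue:
                if atom.name == anchor.atom:
                    return np.array([atom.pos.x, atom.pos.y, atom.pos.z])
            raise AnchorError(
                f"atom {anchor.atom!r} missing in {anchor.chain}/"
                f"{anchor.residue}"
            )
    raise AnchorError(
        f"residue {anchor.chain}/{anchor.residue} not found in model"
    )


def contact_geometry(
    structure: gemmi.Structure,
    anchors: list[Anchor],
) -> ContactSpiral:
    """Spiral geometry of ordered per-protomer anchor atoms.

    The axis comes from a least-squares helix fit through the anchors;
    rise and rotation are reported for consecutive protomer pairs only.
    A collinear anchor stack (zero spiral radius, e.g. rotation-free
    markers) has no defined azimuth and raises
    :class:`~porethread.backbone.GeometryError`.
    """
    if len(anchors) < 3:
        raise ValueError(f"need at least 3 anchors, got {len(anchors)}")
    positions = np.array([_resolve_atom(structure, a) for a in anchors])
    axis_point, axis_dir = fit_helix_axis(positions)
    rise, rotation = spiral_steps(positions, axis_point, axis_dir,
                                  min_radius=1e-3)
    return ContactSpiral(
        labels=[a.chain for a in anchors],
        positions=positions,
        axis_point=axis_point,
        axis_direction=axis_dir,
        rise_per_step=rise,
        rotation_per_step=rotation,
    )


def protomer_expansion(
    structure: gemmi.Structure,
    residue_pair: tuple[int, int],
    chains: list[str] | None = None,
    atom: str = "CA",
) -> pd.DataFrame:
    """Distance between two marker residues, per protomer.

    Measures the ``atom``-``atom`` distance between ``residue_pair``
    within each protomer chain (all chains by default, model order).
    """
    id_a, id_b = residue_pair
    if chains is None:
        chains = [c.name for c in structure[0]]
    rows = []
    for chain in chains:
        pos_a = _resolve_atom(structure, Anchor(chain, id_a, atom))
        pos_b = _resolve_atom(structure, Anchor(chain, id_b, atom))
        rows.append({
            "protomer": chain,
            "distance_A": float(np.linalg.norm(pos_a - pos_b)),
        })
    return pd.DataFrame(rows)
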