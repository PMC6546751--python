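"""Thread peptide windows onto a fixed backbone and score against density.

Each k-mer window is placed onto the shared symmetrized backbone
(sequence-on-fixed-backbone threading): side chains are built from ideal
residue templates at the lowest-clash chi combination of a small discrete
set, optionally refined by seeded stochastic chi/backbone-jitter moves,
and scored with a decomposed surrogate energy

    total = e_density + e_clash + e_ref
          = -w_d * cc  +  w_c * sum max(0, r_i + r_j - d_ij)^2  +  sum ref(aa)

where ``cc`` is the real-space model-map correlation over a mask around
the peptide, the clash term is a soft-sphere overlap penalty, and
``ref(aa)`` is a per-amino-acid reference weight approximating
unfolded-state energetics so energies are comparable across sequences
(zero for Ala by construction).  Absolute values are not physical
energies; all inference is by ranking relative to poly-Ala and by
per-position averaging.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import densmap
from .backbone import BackboneModel, dihedral_angle
from .sequences import CANONICAL_AA, PeptideWindow

logger = logging.getLogger(__name__)

THREE_LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}

#: chi torsion definitions (atom name quadruples), in order chi1, chi2, ...
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
    # ALA / GLY: no chi; PRO: ring fixed at template geometry
    "ALA": [], "GLY": [], "PRO": [],
}

BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "CB"})

#: soft-sphere radii per element, Angstrom (scaled by ScoringParams.clash_scale)
CLASH_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}

#: staggered chi grid sampled during threading (first two chis)
CHI_GRID = (-60.0, 60.0, 180.0)
N_SAMPLED_CHIS = 2


class ThreadingError(ValueError):
    """Raised for invalid threading inputs."""


# ---------------------------------------------------------------------------
# rotamer templates
# ---------------------------------------------------------------------------

@dataclass
class ResidueTemplate:
    """Ideal heavy-atom geometry of one amino acid with chi machinery.

    ``sidechain`` indexes atoms beyond the shared backbone (N, CA, C, O,
    CB); ``chi_distal[k]`` lists the side-chain atom indices moved when
    chi_{k+1} rotates.
    """

    name: str
    atom_names: list[str]
    elements: list[str]
    coords: np.ndarray
    sidechain: np.ndarray
    chi_quads: list[tuple[int, int, int, int]]
    chi_distal: list[np.ndarray]
    template_chis: list[float]

    def index_of(self, atom_name: str) -> int:
        return self.atom_names.index(atom_name)

    @property
    def n_chis(self) -> int:
        return len(self.chi_quads)


@lru_cache(maxsize=None)
def _load_template(three: str) -> ResidueTemplate:
    import biotite.structure.info as info

    res = info.residue(three)
    keep = (res.element != "H") & (res.atom_name != "OXT")
    res = res[keep]
    names = list(res.atom_name)
    elements = list(res.element)
    coords = np.asarray(res.coord, dtype=float)

    # adjacency from the CCD bond list for chi-distal determination
    adj: dict[int, set[int]] = {i: set() for i in range(len(names))}
    for i, j, _ in res.bonds.as_array():
        if i in adj and j in adj:
            adj[i].add(j)
            adj[j].add(i)

    sidechain = np.array(
        [i for i, n in enumerate(names) if n not in BACKBONE_NAMES],
        dtype=int,
    )
    quads, distal, template_chis = [], [], []
    for quad_names in CHI_ATOMS[three]:
        quad = tuple(names.index(n) for n in quad_names)
        quads.append(quad)
        # atoms reachable from the chi bond's distal atom without
        # passing back through its proximal atom
        a2, a3 = quad[1], quad[2]
        seen = {a2, a3}
        stack = [a3]
        moved = []
        while stack:
            cur = stack.pop()
            for nxt in adj[cur]:
                if nxt not in seen:
                    seen.add(nxt)
                    moved.append(nxt)
                    stack.append(nxt)
        distal.append(np.array(sorted(moved), dtype=int))
        template_chis.append(dihedral_angle(*(coords[k] for k in quad)))
    return ResidueTemplate(
        name=three, atom_names=names, elements=elements, coords=coords,
        sidechain=sidechain, chi_quads=quads, chi_distal=distal,
        template_chis=template_chis,
    )


@dataclass
class RotamerSet:
    """Template library: ideal side-chain geometry and the discrete chi
    grid sampled at threading time."""

    chi_grid: tuple[float, ...] = CHI_GRID
    n_sampled_chis: int = N_SAMPLED_CHIS

    def template(self, one_letter: str) -> ResidueTemplate:
        if one_letter not in THREE_LETTER:
            raise ThreadingError(f"unknown amino acid {one_letter!r}")
        return _load_template(THREE_LETTER[one_letter])

    def chi_combinations(self, one_letter: str):
        """Discrete chi vectors for an amino acid, deterministic order.

        Chis beyond ``n_sampled_chis`` stay at template values; Pro's
        ring is never sampled.
        """
        tpl = self.template(one_letter)
        if tpl.n_chis == 0 or one_letter == "P":
            return [list(tpl.template_chis)]
        n_sample = min(self.n_sampled_chis, tpl.n_chis)
        combos = []
        for sampled in itertools.product(self.chi_grid, repeat=n_sample):
            combos.append(list(sampled) + list(tpl.template_chis[n_sample:]))
        return combos


def _rotation_about_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    kx = np.array([[0, -axis[2], axis[1]],
                   [axis[2], 0, -axis[0]],
                   [-axis[1], axis[0], 0]])
    return (np.eye(3) + np.sin(angle_rad) * kx
            + (1 - np.cos(angle_rad)) * (kx @ kx))


def _align_direction(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix taking direction a onto direction b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    s = np.linalg.norm(v)
    c = float(np.dot(a, b))
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate pi about any perpendicular axis
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        return _rotation_about_axis(perp, np.pi)
    return _rotation_about_axis(v / s, np.arctan2(s, c))


def build_sidechain(
    template: ResidueTemplate,
    n_xyz: np.ndarray,
    ca_xyz: np.ndarray,
    cb_xyz: np.ndarray,
    chis: list[float],
) -> tuple[list[str], list[str], np.ndarray]:
    """Side-chain atoms (beyond CB) placed on a backbone residue frame.

    The template is anchored exactly at the model's CB with its CB-CA
    bond direction aligned and its spin about that axis chosen to match
    the model's N; side-chain internal geometry therefore stays rigidly
    template-ideal.  Each chi is then set in order by rotating its
    distal atoms.
    """
    if len(template.sidechain) == 0:
        return [], [], np.empty((0, 3))
    t_n, t_ca, t_cb = (
        template.coords[template.index_of(a)] for a in ("N", "CA", "CB")
    )
    axis_m = ca_xyz - cb_xyz
    r1 = _align_direction(t_ca - t_cb, axis_m)
    coords = (template.coords - t_cb) @ r1.T
    # spin about the CB-CA axis to best match the amide N
    u = axis_m / np.linalg.norm(axis_m)
    p_t = r1 @ (t_n - t_cb)
    p_t = p_t - np.dot(p_t, u) * u
    p_m = n_xyz - cb_xyz
    p_m = p_m - np.dot(p_m, u) * u
    if np.linalg.norm(p_t) > 1e-9 and np.linalg.norm(p_m) > 1e-9:
        spin = np.arctan2(np.dot(np.cross(p_t, p_m), u),
                          float(np.dot(p_t, p_m)))
        coords = coords @ _rotation_about_axis(u, spin).T
    coords = coords + cb_xyz
    for k, (quad, target) in enumerate(zip(template.chi_quads, chis)):
        current = dihedral_angle(*(coords[i] for i in quad))
        delta = np.radians(target - current)
        pivot = coords[quad[2]]
        axis = coords[quad[2]] - coords[quad[1]]
        r = _rotation_about_axis(axis, delta)
        moved = template.chi_distal[k]
        coords[moved] = (coords[moved] - pivot) @ r.T + pivot
    sc = template.sidechain
    return (
        [template.atom_names[i] for i in sc],
        [template.elements[i] for i in sc],
        coords[sc],
    )


# ---------------------------------------------------------------------------
# threaded models
# ---------------------------------------------------------------------------

@dataclass
class ThreadedModel:
    """A peptide sequence placed on the shared backbone with side chains.

    Backbone atoms are those of the shared :class:`BackboneModel` plus a
    per-residue jitter offset (zero before refinement, bounded after).
    Coordinates are assembled deterministically from (backbone, offsets,
    chis).
    """

    window: PeptideWindow
    backbone: BackboneModel
    chis: list[list[float]]
    backbone_offsets: np.ndarray
    ring_tag: str | None = None
    rotamers: RotamerSet = field(default_factory=RotamerSet)

    @property
    def sequence(self) -> str:
        return self.window.sequence

    def assemble(self) -> tuple[list[tuple[int, str]], list[str], np.ndarray]:
        """(residue-index/atom-name labels, elements, coordinates)."""
        labels, elements, coords = [], [], []
        bb = self.backbone.coords
        for i, aa in enumerate(self.sequence):
            off = self.backbone_offsets[i]
            bb_names = ("N", "CA", "C", "O") if aa == "G" else BACKBONE_ATOM_ORDER
            for name in bb_names:
                labels.append((i, name))
                elements.append(name[0])
                coords.append(bb[name][i] + off)
            sc_names, sc_elements, sc_coords = build_sidechain(
                self.rotamers.template(aa),
                bb["N"][i] + off, bb["CA"][i] + off, bb["CB"][i] + off,
                self.chis[i],
            )
            for name, el, xyz in zip(sc_names, sc_elements, sc_coords):
                labels.append((i, name))
                elements.append(el)
                coords.append(xyz)
        return labels, elements, np.asarray(coords)

    def atom_set(self) -> densmap.AtomSet:
        _, elements, coords = self.assemble()
        return densmap.AtomSet(elements=elements, positions=coords)

    def max_backbone_deviation(self) -> float:
        """Largest per-residue offset from the shared backbone, Angstrom."""
        return float(np.max(np.linalg.norm(self.backbone_offsets, axis=1)))


BACKBONE_ATOM_ORDER = ("N", "CA", "C", "O", "CB")


@dataclass(frozen=True)
class EnergyBreakdown:
    """Decomposed surrogate score; ``total`` is exactly the sum of parts."""

    e_density: float
    e_clash: float
    e_ref: float

    @property
    def total(self) -> float:
        return self.e_density + self.e_clash + self.e_ref


@dataclass
class ScoringParams:
    """Weights and conventions of the surrogate energy.

    ``w_density`` scales the (negated) real-space correlation; the
    density-agreement weight is deliberately modest relative to nothing
    else being on the same scale - only relative energies matter.
    ``ref_weights`` maps one-letter codes to reference energies
    (Ala fixed at 0); missing entries default to 0.
    """

    w_density: float = 10.0
    w_clash: float = 1.0
    mask_radius: float = 3.0
    resolution: float = 3.0
    clash_scale: float = 0.8
    ref_weights: dict[str, float] = field(default_factory=dict)

    def ref(self, aa: str) -> float:
        if aa == "A":
            return 0.0
        return float(self.ref_weights.get(aa, 0.0))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def thread_sequence(
    backbone: BackboneModel,
    window: PeptideWindow,
    rotamers: RotamerSet | None = None,
    context_atoms: densmap.AtomSet | None = None,
    ring_tag: str | None = None,
) -> ThreadedModel:
    """Place a window's sequence on the backbone, side chains at the
    lowest-clash chi combination of the discrete rotamer grid.

    Residues are built N- to C-terminal; each residue's combination is
    chosen against the backbone, all previously built side chains, and
    any fixed context atoms.  Ties keep the first combination in grid
    order, so the result is deterministic.
    """
    rotamers = rotamers or RotamerSet()
    seq = window.sequence
    if len(seq) != backbone.n_residues:
        raise ThreadingError(
            f"window length {len(seq)} != backbone length "
            f"{backbone.n_residues}"
        )
    for aa in seq:
        if aa not in THREE_LETTER:
            raise ThreadingError(f"unknown amino acid {aa!r} in window")

    bb_elements, bb_coords = backbone.all_atoms()
    env_elements = list(bb_elements)
    env_coords = [bb_coords]
    if context_atoms is not None:
        env_elements += list(context_atoms.elements)
        env_coords.append(context_atoms.positions)

    chis: list[list[float]] = []
    for i, aa in enumerate(seq):
        tpl = rotamers.template(aa)
        combos = rotamers.chi_combinations(aa)
        if len(combos) == 1:
            chosen = combos[0]
        else:
            env_pos = np.vstack(env_coords)
            best = (np.inf, None)
            for combo in combos:
                _, els, xyz = build_sidechain(
                    tpl, backbone.coords["N"][i], backbone.coords["CA"][i],
                    backbone.coords["CB"][i], combo,
                )
                overlap = _overlap_sum(els, xyz, env_elements, env_pos)
                if overlap < best[0]:
                    best = (overlap, combo)
            chosen = best[1]
        chis.append(list(chosen))
        _, els, xyz = build_sidechain(
            tpl, backbone.coords["N"][i], backbone.coords["CA"][i],
            backbone.coords["CB"][i], chosen,
        )
        if len(els):
            env_elements += els
            env_coords.append(xyz)

    return ThreadedModel(
        window=window.with_ring(ring_tag) if ring_tag else window,
        backbone=backbone,
        chis=chis,
        backbone_offsets=np.zeros((len(seq), 3)),
        ring_tag=ring_tag,
        rotamers=rotamers,
    )


def _overlap_sum(els_a, pos_a, els_b, pos_b, scale: float = 0.8) -> float:
    """Sum of squared soft-sphere overlaps between two atom groups."""
    if len(els_a) == 0 or len(els_b) == 0:
        return 0.0
    ra = np.array([CLASH_RADII[e] for e in els_a]) * scale
    rb = np.array([CLASH_RADII[e] for e in els_b]) * scale
    cutoff = ra.max() + rb.max()
    tree = cKDTree(pos_b)
    total = 0.0
    for pa, r1 in zip(pos_a, ra):
        for j in tree.query_ball_point(pa, cutoff):
            d = np.linalg.norm(pa - pos_b[j])
            overlap = r1 + rb[j] - d
            if overlap > 0:
                total += overlap * overlap
    return total


def clash_energy(
    model: ThreadedModel,
    context_atoms: densmap.AtomSet | None = None,
    clash_scale: float = 0.8,
) -> float:
    """Soft-sphere overlap penalty (unweighted, >= 0).

    Counted pairs: side-chain atoms against atoms of *other* residues
    (side chain or backbone) and against fixed context atoms.  Pairs
    internal to one residue and backbone-backbone pairs are excluded:
    the backbone is shared by every threaded model, so those terms are
    constant across sequences.
    """
    labels, elements, coords = model.assemble()
    res_idx = np.array([lab[0] for lab in labels])
    is_sc = np.array([lab[1] not in BACKBONE_NAMES for lab in labels])
    radii = np.array([CLASH_RADII[e] for e in elements]) * clash_scale

    total = 0.0
    if is_sc.any():
        cutoff = 2 * radii.max()
        tree = cKDTree(coords)
        pairs = tree.query_pairs(cutoff, output_type="ndarray")
        for i, j in pairs:
            if res_idx[i] == res_idx[j]:
                continue
            if not (is_sc[i] or is_sc[j]):
                continue
            overlap = radii[i] + radii[j] - np.linalg.norm(coords[i] - coords[j])
            if overlap > 0:
                total += overlap * overlap
        if context_atoms is not None and len(context_atoms):
            total += _overlap_sum(
                [e for e, s in zip(elements, is_sc) if s],
                coords[is_sc],
                context_atoms.elements, context_atoms.positions,
                scale=clash_scale,
            )
    return total


def score_model(
    model: ThreadedModel,
    density_map: densmap.DensityMap,
    params: ScoringParams | None = None,
    context_atoms: densmap.AtomSet | None = None,
    mask_indices: np.ndarray | None = None,
) -> EnergyBreakdown:
    """Decomposed surrogate energy of a threaded model against a map."""
    params = params or ScoringParams()
    atoms = model.atom_set()
    cc = densmap.real_space_cc(
        atoms, density_map,
        mask_radius=params.mask_radius,
        resolution=params.resolution,
        mask_indices=mask_indices,
    )
    e_density = -params.w_density * cc
    e_clash = params.w_clash * clash_energy(
        model, context_atoms=context_atoms, clash_scale=params.clash_scale
    )
    e_ref = sum(params.ref(aa) for aa in model.sequence)
    return EnergyBreakdown(e_density=e_density, e_clash=e_clash, e_ref=e_ref)


def refine_model(
    model: ThreadedModel,
    density_map: densmap.DensityMap,
    n_trajectories: int = 5,
    seed: int = 0,
    params: ScoringParams | None = None,
    context_atoms: densmap.AtomSet | None = None,
    n_moves: int = 20,
    chi_sigma: float = 10.0,
    jitter_sigma: float = 0.05,
    jitter_bound: float = 0.2,
) -> tuple[ThreadedModel, EnergyBreakdown]:
    """Greedy stochastic refinement; lowest-energy trajectory wins.

    Each trajectory proposes random chi perturbations (Gaussian,
    ``chi_sigma`` degrees) and bounded per-residue backbone jitter
    (Gaussian steps, total offset clipped to ``jitter_bound`` Angstrom),
    accepting only strict improvements of the total energy (Metropolis
    at temperature zero).  Only the peptide moves; the map and context
    are fixed.  Fully reproducible given ``seed``.
    """
    if n_trajectories < 1:
        raise ThreadingError(
            f"n_trajectories must be >= 1, got {n_trajectories}"
        )
    params = params or ScoringParams()
    n = len(model.sequence)
    input_energy = score_model(model, density_map, params,
                               context_atoms=context_atoms)
    # trajectories score against a fixed mask (moves are <= jitter_bound)
    base_mask = densmap.mask_voxels(
        model.atom_set().positions, density_map,
        params.mask_radius + jitter_bound,
    )

    def scored(m: ThreadedModel) -> EnergyBreakdown:
        return score_model(m, density_map, params,
                           context_atoms=context_atoms,
                           mask_indices=base_mask)

    best: tuple[ThreadedModel, EnergyBreakdown] | None = None
    for traj in range(n_trajectories):
        rng = np.random.default_rng([max(seed, 0), traj])
        current = model
        e_current = scored(current)
        for _ in range(n_moves):
            i = int(rng.integers(n))
            do_chi = rng.random() < 0.5 and len(current.chis[i]) > 0
            if do_chi:
                new_chis = [list(c) for c in current.chis]
                n_sample = min(len(new_chis[i]),
                               current.rotamers.n_sampled_chis)
                for k in range(n_sample):
                    new_chis[i][k] += float(rng.normal(0.0, chi_sigma))
                cand = replace(current, chis=new_chis)
            else:
                offsets = current.backbone_offsets.copy()
                step = rng.normal(0.0, jitter_sigma, 3)
                new_off = offsets[i] + step
                norm = np.linalg.norm(new_off)
                if norm > jitter_bound:
                    new_off *= jitter_bound / norm
                offsets[i] = new_off
                cand = replace(current, backbone_offsets=offsets)
            e_cand = scored(cand)
            if e_cand.total < e_current.total:
                current, e_current = cand, e_cand
        if best is None or e_current.total < best[1].total:
            best = (current, e_current)
    # re-score the winner with its own mask (no shared-mask approximation);
    # keep the input if the proxy-guided moves did not genuinely improve it
    final_energy = score_model(best[0], density_map, params,
                               context_atoms=context_atoms)
    if final_energy.total < input_energy.total:
        return best[0], final_energy
    return model, input_energy


def polyala_window(n_residues: int, ring_tag: str | None = None) -> PeptideWindow:
    """The poly-Ala reference window for a backbone of given length."""
    return PeptideWindow(source_id="polyA", start=1,
                         sequence="A" * n_residues, ring_tag=ring_tag)


def thread_all(
    windows: list[PeptideWindow],
    backbone_by_ring: dict[str, BackboneModel],
    map_by_ring: dict[str, densmap.DensityMap],
    params: ScoringParams | None = None,
    seed: int = 0,
    rotamers: RotamerSet | None = None,
    context_by_ring: dict[str, densmap.AtomSet] | None = None,
    refine: bool = True,
    n_trajectories: int = 5,
    n_moves: int = 20,
    rings: list[str] | None = None,
) -> pd.DataFrame:
    """Thread, refine, and score every window on every requested ring.

    Returns one row per (window, ring) with the energy decomposition.
    Deterministic under a fixed seed: each (ring, window) pair gets an
    independent seed stream derived from ``seed``.
    """
    if not windows:
        raise ThreadingError("empty window list")
    params = params or ScoringParams()
    rotamers = rotamers or RotamerSet()
    rings = rings or sorted(backbone_by_ring)
    rows = []
    for ring_index, ring in enumerate(rings):
        bb = backbone_by_ring[ring]
        dmap = map_by_ring[ring]
        ctx = (context_by_ring or {}).get(ring)
        logger.info("threading %d windows into ring %s", len(windows), ring)
        for w_index, window in enumerate(windows):
            model = thread_sequence(bb, window, rotamers,
                                    context_atoms=ctx, ring_tag=ring)
            if refine:
                model, energy = refine_model(
                    model, dmap,
                    n_trajectories=n_trajectories,
                    seed=int(np.random.SeedSequence(
                        [max(seed, 0), ring_index, w_index]
                    ).generate_state(1)[0] % (2**31)),
                    params=params, context_atoms=ctx, n_moves=n_moves,
                )
            else:
                energy = score_model(model, dmap, params, context_atoms=ctx)
            rows.append({
                "source_id": window.source_id,
                "start": window.start,
                "ring": ring,
                "sequence": window.sequence,
                "e_density": energy.e_density,
                "e_clash": energy.e_clash,
                "e_ref": energy.e_ref,
                "total": energy.total,
            })
    return pd.DataFrame(rows)
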