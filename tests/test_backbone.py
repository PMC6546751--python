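"""Backbone construction, dihedral measurement, axial geometry."""

import numpy as np
import pytest

from porethread.backbone import (
    BackboneModel,
    DihedralRepeat,
    GeometryError,
    GeometryParams,
    _MapEvaluator,
    _kabsch,
    axial_geometry,
    build_chain,
    dihedral_angle,
    measure_dihedrals,
    measure_repeat,
    place_atom,
)
from porethread.densmap import simulate_map


def brute_force_dihedral(p0, p1, p2, p3):
    """Independent torsion via plane normals and a signed arccos."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    n1 = np.cross(p1 - p0, p2 - p1)
    n2 = np.cross(p2 - p1, p3 - p2)
    n1 /= np.linalg.norm(n1)
    n2 /= np.linalg.norm(n2)
    cosang = np.clip(np.dot(n1, n2), -1.0, 1.0)
    angle = np.degrees(np.arccos(cosang))
    if np.dot(np.cross(n1, n2), p2 - p1) < 0:
        angle = -angle
    return angle


class TestBuildChain:
    def test_selected_repeat_round_trips(self, selected_repeat, chain13):
        assert chain13.n_residues == 13
        recovered = measure_repeat(chain13)
        assert np.allclose(recovered.as_tuple(), selected_repeat.as_tuple(),
                           atol=1e-4)

    def test_dihedrals_alternate_between_the_two_pairs(self, chain13):
        dihedrals = measure_dihedrals(chain13)
        for i, (phi, psi) in enumerate(dihedrals):
            expected_phi, expected_psi = (-92, 118) if i % 2 == 0 else (-102, 110)
            if phi is not None:
                assert phi == pytest.approx(expected_phi, abs=1e-6)
            if psi is not None:
                assert psi == pytest.approx(expected_psi, abs=1e-6)

    def test_minimal_two_residue_chain(self, selected_repeat):
        chain = build_chain(selected_repeat, 2)
        assert chain.n_residues == 2
        (_, psi1), (phi2, _) = measure_dihedrals(chain)
        assert psi1 == pytest.approx(118, abs=1e-6)
        assert phi2 == pytest.approx(-102, abs=1e-6)

    def test_chain_too_short_rejected(self, selected_repeat):
        with pytest.raises(GeometryError):
            build_chain(selected_repeat, 1)

    def test_round_trip_over_random_beta_region_repeats(self):
        """1000 random repeats rebuild their generating torsions <= 1e-4 deg."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            repeat = DihedralRepeat(
                phi1=float(rng.uniform(-180, -30)),
                psi1=float(rng.uniform(60, 180)),
                phi2=float(rng.uniform(-180, -30)),
                psi2=float(rng.uniform(60, 180)),
            )
            chain = build_chain(repeat, 13)
            recovered = measure_repeat(chain)
            assert np.allclose(recovered.as_tuple(), repeat.as_tuple(),
                               atol=1e-4)

    def test_omega_is_trans(self, chain13):
        c = chain13.coords
        for i in range(chain13.n_residues - 1):
            omega = dihedral_angle(c["CA"][i], c["C"][i],
                                   c["N"][i + 1], c["CA"][i + 1])
            assert abs(abs(omega) - 180.0) < 1e-6

    def test_peptide_bond_lengths_match_geometry(self, chain13):
        geom = chain13.geometry
        c = chain13.coords
        for i in range(chain13.n_residues - 1):
            d = np.linalg.norm(c["N"][i + 1] - c["C"][i])
            assert d == pytest.approx(geom.len_c_n, abs=1e-6)

    def test_invalid_geometry_params_rejected(self):
        with pytest.raises(ValueError):
            GeometryParams(len_ca_c=-1.0)
        with pytest.raises(ValueError):
            GeometryParams(ang_n_ca_c=185.0)


class TestDihedralAngle:
    def test_matches_plane_normal_oracle(self, rng):
        """atan2 torsion equals the plane-normal formula to 1e-8 deg."""
        for _ in range(200):
            pts = rng.normal(size=(4, 3)) * 3.0
            try:
                expected = brute_force_dihedral(*pts)
            except FloatingPointError:
                continue
            assert dihedral_angle(*pts) == pytest.approx(expected, abs=1e-8)

    def test_degenerate_points_rejected(self):
        p = np.zeros(3)
        with pytest.raises(GeometryError):
            dihedral_angle(p, p, p, np.ones(3))

    def test_place_atom_realizes_requested_internal_coordinates(self, rng):
        for _ in range(50):
            a, b, c = rng.normal(size=(3, 3)) * 4.0
            if np.linalg.norm(np.cross(b - a, c - b)) < 1e-3:
                continue
            bond = float(rng.uniform(1.0, 2.0))
            angle = float(rng.uniform(30.0, 150.0))
            torsion = float(rng.uniform(-180.0, 180.0))
            d = place_atom(a, b, c, bond, angle, torsion)
            assert np.linalg.norm(d - c) == pytest.approx(bond, abs=1e-9)
            assert dihedral_angle(a, b, c, d) == pytest.approx(
                torsion, abs=1e-7)


def _ca_only_model(ca: np.ndarray) -> BackboneModel:
    coords = {name: ca.copy() for name in ("N", "CA", "C", "O", "CB")}
    return BackboneModel(n_residues=len(ca), coords=coords)


class TestAxialGeometry:
    def test_ideal_helix_rise_recovered(self):
        t = np.arange(10)
        ca = np.column_stack([
            1.5 * np.cos(t * 1.7), 1.5 * np.sin(t * 1.7), 3.25 * t,
        ])
        axial = axial_geometry(_ca_only_model(ca))
        assert axial.mean_rise == pytest.approx(3.25, abs=0.01)

    def test_selected_repeat_dipeptide_rise_in_contact_band(self, chain13):
        """Dipeptide spacing of the channel strand sits in the ~6-7 A
        pore-loop contact band."""
        axial = axial_geometry(chain13)
        dipeptide = 2.0 * axial.mean_rise
        assert 6.0 < dipeptide < 7.0

    def test_rise_invariant_under_rigid_rotation(self, chain13):
        from scipy.spatial.transform import Rotation

        r = Rotation.from_euler("zyx", [0.4, -1.0, 2.2]).as_matrix()
        moved = chain13.transformed(r, np.array([5.0, -3.0, 11.0]))
        a0 = axial_geometry(chain13)
        a1 = axial_geometry(moved)
        assert np.allclose(a0.rise_per_residue, a1.rise_per_residue,
                           atol=1e-9)

    def test_needs_four_residues(self, selected_repeat):
        chain = build_chain(selected_repeat, 3)
        with pytest.raises(GeometryError):
            axial_geometry(chain)


class TestGridSearchScoring:
    """1-D sweep behavior of the map evaluator used by the grid search."""

    def test_truth_phi1_is_argmax_of_axis_sweep(self, selected_repeat):
        """On a noiseless self-simulated map the correlation along a phi1
        sweep peaks exactly at the generating value (exhaustive
        enumeration of the axis)."""
        chain = build_chain(selected_repeat, 9)
        dmap = simulate_map(chain.all_atoms(), 3.0, 1.0, padding=5.0)
        ev = _MapEvaluator(dmap, resolution=3.0)
        anchor_ca = chain.coords["CA"]

        scores = {}
        for phi1 in np.arange(-120.0, -59.0, 4.0):
            cand = DihedralRepeat(float(phi1), 118.0, -102.0, 110.0)
            c = build_chain(cand, 9)
            rot, trans = _kabsch(c.coords["CA"], anchor_ca)
            scores[float(phi1)] = ev.score_model(c.transformed(rot, trans))
        best_phi = max(scores, key=scores.get)
        assert best_phi == -92.0
        assert scores[-92.0] == pytest.approx(1.0, abs=1e-4)
        assert all(scores[-92.0] >= s for s in scores.values())
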