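"""Sequence threading, surrogate energy, and refinement."""

import numpy as np
import pandas as pd
import pytest

from porethread.densmap import simulate_map
from porethread.sequences import PeptideWindow, generate_windows
from porethread.synthetic import make_isoform_set
from porethread.threading import (
    CLASH_RADII,
    EnergyBreakdown,
    ScoringParams,
    ThreadingError,
    polyala_window,
    refine_model,
    score_model,
    thread_all,
    thread_sequence,
)


@pytest.fixture()
def kappa_window13(casein):
    """13-mer around the reported kappa peptide (VVTILALTLPF +/- 1)."""
    from porethread.sequences import window_at

    return window_at(casein, "kappa", 7, 19)


class TestThreadSequence:
    def test_polyala_has_backbone_and_cb_only(self, chain13, rotamers):
        model = thread_sequence(chain13, polyala_window(13), rotamers)
        labels, elements, coords = model.assemble()
        assert len(elements) == 13 * 5
        assert {name for _, name in labels} == {"N", "CA", "C", "O", "CB"}

    def test_kappa_window_builds_full_atom_model(self, chain13, rotamers,
                                                 kappa_window13):
        assert kappa_window13.sequence == "LVVTILALTLPFL"
        model = thread_sequence(chain13, kappa_window13, rotamers)
        labels, elements, coords = model.assemble()
        assert len(elements) > 13 * 5
        assert np.all(np.isfinite(coords))
        # backbone identical to the shared model
        for res_idx in range(13):
            ca = [c for (i, n), c in zip(labels, coords)
                  if i == res_idx and n == "CA"]
            assert np.allclose(ca[0], chain13.coords["CA"][res_idx])

    def test_glycine_has_no_cb(self, chain13, rotamers):
        win = PeptideWindow("t", 1, "G" * 13)
        labels, elements, _ = thread_sequence(chain13, win,
                                              rotamers).assemble()
        assert all(name != "CB" for _, name in labels)

    def test_sidechain_bond_lengths_match_template_ideals(self, chain13,
                                                          rotamers):
        """Threaded side-chain internal geometry reproduces the template
        bond lengths (superposition + chi rotations are rigid)."""
        win = PeptideWindow("t", 1, "LFKWMYQERNHSC")
        model = thread_sequence(chain13, win, rotamers)
        labels, _, coords = model.assemble()
        by_res = {}
        for (i, name), xyz in zip(labels, coords):
            by_res.setdefault(i, {})[name] = xyz
        checked = 0
        for i, aa in enumerate(win.sequence):
            tpl = rotamers.template(aa)
            names = set(by_res[i])
            for quad in tpl.chi_quads:
                n1 = tpl.atom_names[quad[2]]
                n2 = tpl.atom_names[quad[3]]
                if n1 in names and n2 in names:
                    d_model = np.linalg.norm(by_res[i][n1] - by_res[i][n2])
                    d_tpl = np.linalg.norm(
                        tpl.coords[quad[2]] - tpl.coords[quad[3]]
                    )
                    assert d_model == pytest.approx(d_tpl, abs=1e-6)
                    checked += 1
        assert checked > 5

    def test_length_mismatch_rejected(self, chain13, rotamers):
        with pytest.raises(ThreadingError):
            thread_sequence(chain13, PeptideWindow("t", 1, "AAAA"), rotamers)

    def test_deterministic(self, chain13, rotamers, kappa_window13):
        m1 = thread_sequence(chain13, kappa_window13, rotamers)
        m2 = thread_sequence(chain13, kappa_window13, rotamers)
        assert np.array_equal(m1.assemble()[2], m2.assemble()[2])


class TestScoreModel:
    def test_breakdown_sums_exactly(self, scene9, rotamers):
        model = thread_sequence(scene9.backbone, scene9.truth_window,
                                rotamers)
        e = score_model(model, scene9.map_noiseless,
                        context_atoms=scene9.pocket_atoms)
        assert e.total == e.e_density + e.e_clash + e.e_ref
        assert e.e_clash >= 0.0

    def test_polyala_reference_energy_is_zero(self, scene9, rotamers):
        model = thread_sequence(scene9.backbone,
                                polyala_window(9), rotamers)
        e = score_model(model, scene9.map_noiseless)
        assert e.e_ref == 0.0

    def test_identical_models_identical_totals(self, scene9, rotamers):
        w = scene9.truth_window
        e1 = score_model(thread_sequence(scene9.backbone, w, rotamers),
                         scene9.map_noiseless)
        e2 = score_model(thread_sequence(scene9.backbone, w, rotamers),
                         scene9.map_noiseless)
        assert e1.total == e2.total

    def test_truth_beats_polyala_on_pocketed_scene(self, scene9, rotamers):
        truth = thread_sequence(scene9.backbone, scene9.truth_window,
                                rotamers)
        pa = thread_sequence(scene9.backbone, polyala_window(9), rotamers)
        e_truth = score_model(truth, scene9.map_noiseless,
                              context_atoms=scene9.pocket_atoms)
        e_pa = score_model(pa, scene9.map_noiseless,
                           context_atoms=scene9.pocket_atoms)
        assert e_truth.total < e_pa.total

    def test_higher_clash_weight_never_favors_clashing_model(self, scene9,
                                                             rotamers):
        bulky = thread_sequence(
            scene9.backbone, PeptideWindow("t", 1, "WWWWWWWWW"), rotamers
        )
        pa = thread_sequence(scene9.backbone, polyala_window(9), rotamers)
        gaps = []
        for w_clash in (0.5, 1.0, 4.0, 16.0):
            params = ScoringParams(w_clash=w_clash)
            gap = (score_model(bulky, scene9.map_noiseless, params).total
                   - score_model(pa, scene9.map_noiseless, params).total)
            gaps.append(gap)
        assert all(b >= a - 1e-12 for a, b in zip(gaps, gaps[1:]))


class TestRefineModel:
    def test_zero_perturbation_is_identity(self, scene9, rotamers):
        model = thread_sequence(scene9.backbone, scene9.truth_window,
                                rotamers)
        refined, energy = refine_model(
            model, scene9.map_noiseless, n_trajectories=1, seed=5,
            n_moves=5, chi_sigma=0.0, jitter_sigma=0.0,
        )
        assert np.allclose(refined.backbone_offsets, 0.0)
        assert refined.chis == model.chis
        assert energy.total == score_model(model,
                                           scene9.map_noiseless).total

    def test_fixed_seed_reproduces_energies(self, scene9, rotamers):
        model = thread_sequence(scene9.backbone, scene9.truth_window,
                                rotamers)
        results = [
            refine_model(model, scene9.map_noiseless, n_trajectories=2,
                         seed=7, n_moves=8)[1].total
            for _ in range(2)
        ]
        assert results[0] == results[1]

    def test_refinement_never_worsens_energy(self, scene9, rotamers):
        model = thread_sequence(scene9.backbone, scene9.truth_window,
                                rotamers)
        base = score_model(model, scene9.map_noiseless).total
        _, energy = refine_model(model, scene9.map_noiseless,
                                 n_trajectories=2, seed=1, n_moves=10)
        assert energy.total <= base + 1e-9

    def test_backbone_jitter_stays_bounded(self, scene9, rotamers):
        model = thread_sequence(scene9.backbone, scene9.truth_window,
                                rotamers)
        refined, _ = refine_model(model, scene9.map_noiseless,
                                  n_trajectories=1, seed=3, n_moves=40,
                                  jitter_sigma=0.3, jitter_bound=0.2)
        assert refined.max_backbone_deviation() <= 0.2 + 1e-9

    def test_invalid_trajectory_count(self, scene9, rotamers):
        model = thread_sequence(scene9.backbone, scene9.truth_window,
                                rotamers)
        with pytest.raises(ThreadingError):
            refine_model(model, scene9.map_noiseless, n_trajectories=0)


class TestThreadAll:
    def test_single_window_single_ring(self, scene9, rotamers):
        scored = thread_all(
            [scene9.truth_window], {"NBD1": scene9.backbone},
            {"NBD1": scene9.map_noiseless}, seed=0, rotamers=rotamers,
            refine=False,
        )
        assert len(scored) == 1
        assert scored.iloc[0]["ring"] == "NBD1"

    def test_rows_are_windows_times_rings(self, scene9, rotamers):
        windows = [scene9.truth_window, polyala_window(9)]
        scored = thread_all(
            windows,
            {"NBD1": scene9.backbone, "NBD2": scene9.backbone},
            {"NBD1": scene9.map_noiseless, "NBD2": scene9.map_noiseless},
            seed=0, rotamers=rotamers, refine=False,
        )
        assert len(scored) == 4

    def test_empty_window_list_rejected(self, scene9):
        with pytest.raises(ThreadingError):
            thread_all([], {"NBD1": scene9.backbone},
                       {"NBD1": scene9.map_noiseless})

    def test_full_run_deterministic_under_seed(self, scene9, rotamers):
        iso = make_isoform_set(n=1, lengths=(14,), seed=4,
                               truth_window=scene9.truth_window)
        windows = generate_windows(iso, 9)
        kwargs = dict(
            backbone_by_ring={"NBD1": scene9.backbone},
            map_by_ring={"NBD1": scene9.map_noiseless},
            context_by_ring={"NBD1": scene9.pocket_atoms},
            seed=99, rotamers=rotamers, refine=True,
            n_trajectories=2, n_moves=5,
        )
        a = thread_all(windows, **kwargs)
        b = thread_all(windows, **kwargs)
        pd.testing.assert_frame_equal(a, b)
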