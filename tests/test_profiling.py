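"""Preference profiles, null background, rankings, and logo conversion."""

import numpy as np
import pandas as pd
import pytest

from porethread.profiling import (
    AA_LIST,
    PreferenceProfile,
    analyzed_positions,
    build_profile,
    calibrate_reference_weights,
    null_background_scan,
    null_background_windows,
    profile_to_logo,
    profile_to_tsv,
    rank_windows,
)
from porethread.threading import ScoringParams


def _scored_frame(rows):
    return pd.DataFrame(rows, columns=[
        "source_id", "start", "ring", "sequence",
        "e_density", "e_clash", "e_ref", "total",
    ])


class TestBuildProfile:
    def test_thirteen_mer_windows_give_eleven_positions(self):
        scored = _scored_frame([
            ("a", 1, "NBD1", "ACDEFGHIKLMNP", 0, 0, 0, -1.0),
        ])
        profile = build_profile(scored, "NBD1")
        assert len(profile.positions) == 11
        assert profile.positions == list(range(2, 13))

    def test_identical_windows_populate_their_cells_only(self):
        scored = _scored_frame([
            ("a", i, "NBD1", "GLYWA", 0, 0, 0, -2.5) for i in range(4)
        ])
        profile = build_profile(scored, "NBD1")
        # analyzed positions 2..4 carry L, Y, W
        for pos, aa in [(2, "L"), (3, "Y"), (4, "W")]:
            assert profile.cell(pos, aa) == pytest.approx(-2.5)
            assert profile.counts.at[pos, aa] == 4
        unpopulated = profile.energies.isna().to_numpy().sum()
        assert unpopulated == 3 * len(AA_LIST) - 3

    def test_recovers_injected_per_amino_acid_energies(self, rng):
        """With null-style windows and E(window) = sum f(aa_i), each cell
        equals f(aa) plus a constant (linear-model recovery oracle)."""
        f = {aa: float(rng.normal()) for aa in AA_LIST}
        k = 7
        rows = []
        for pos in analyzed_positions(k):
            for aa in AA_LIST:
                seq = "A" * (pos - 1) + aa + "A" * (k - pos)
                total = sum(f[c] for c in seq)
                rows.append(("null", pos, "NBD1", seq, 0, 0, 0, total))
        profile = build_profile(_scored_frame(rows), "NBD1")
        const = (k - 1) * f["A"]
        for pos in analyzed_positions(k):
            for aa in AA_LIST:
                if aa == "A":
                    continue  # Ala cell averages over all windows
                assert profile.cell(pos, aa) == pytest.approx(
                    f[aa] + const, abs=1e-12)

    def test_invariant_to_row_order(self, rng):
        rows = [
            ("a", i, "NBD1",
             "".join(rng.choice(AA_LIST, 6)), 0, 0, 0, float(rng.normal()))
            for i in range(12)
        ]
        scored = _scored_frame(rows)
        shuffled = scored.sample(frac=1.0, random_state=3)
        p1 = build_profile(scored, "NBD1")
        p2 = build_profile(shuffled, "NBD1")
        pd.testing.assert_frame_equal(p1.energies, p2.energies)

    def test_empty_ring_rejected(self):
        with pytest.raises(ValueError):
            build_profile(_scored_frame([]), "NBD1")


class TestNullBackground:
    def test_enumeration_counts(self):
        assert len(null_background_windows(13)) == 11 * 20
        assert len(null_background_windows(5)) == 3 * 20

    def test_small_scan_count_and_profile(self, scene9, rotamers):
        profiles, count = null_background_scan(
            {"NBD1": scene9.backbone}, {"NBD1": scene9.map_noiseless},
            rotamers=rotamers, refine=False,
            context_by_ring={"NBD1": scene9.pocket_atoms},
        )
        assert count == (9 - 2) * 20
        prof = profiles["NBD1"]
        assert prof.provenance == "null_background"
        # centred on the all-model mean
        assert float(np.nanmean(prof.energies.to_numpy())) == \
            pytest.approx(0.0, abs=1e-9)

    def test_ala_row_zero_after_reference_calibration(self, scene9,
                                                      rotamers):
        """Calibrated reference weights anchor the alanine null row at 0."""
        backbones = {"NBD1": scene9.backbone}
        maps = {"NBD1": scene9.map_noiseless}
        ctx = {"NBD1": scene9.pocket_atoms}
        weights = calibrate_reference_weights(
            backbones, maps, seed=0, rotamers=rotamers, refine=False,
            context_by_ring=ctx,
        )
        assert weights["A"] == 0.0
        params = ScoringParams(ref_weights=weights)
        profiles, _ = null_background_scan(
            backbones, maps, params, rotamers=rotamers, refine=False,
            context_by_ring=ctx,
        )
        ala = profiles["NBD1"].energies["A"].to_numpy()
        assert np.allclose(ala, 0.0, atol=1e-9)


class TestRankWindows:
    def test_single_window_is_rank_one(self):
        scored = _scored_frame([("a", 1, "NBD1", "ACDEF", 0, 0, 0, -3.0)])
        ranked = rank_windows(scored, "NBD1", polyala_total=-1.0)
        assert ranked.iloc[0]["rank"] == 1
        assert ranked.iloc[0]["rel_total"] == pytest.approx(-2.0)

    def test_ties_broken_by_source_then_start(self):
        scored = _scored_frame([
            ("b", 5, "NBD1", "ACDEF", 0, 0, 0, -3.0),
            ("a", 9, "NBD1", "ACDEF", 0, 0, 0, -3.0),
            ("a", 2, "NBD1", "ACDEF", 0, 0, 0, -3.0),
        ])
        ranked = rank_windows(scored, "NBD1", polyala_total=0.0)
        assert list(zip(ranked["source_id"], ranked["start"])) == [
            ("a", 2), ("a", 9), ("b", 5)]


class TestLogo:
    def _uniform_profile(self, value=0.0):
        e = pd.DataFrame(value, index=[2, 3, 4], columns=AA_LIST)
        c = pd.DataFrame(1, index=[2, 3, 4], columns=AA_LIST)
        return PreferenceProfile("NBD1", e, c)

    def test_equal_energies_give_uniform_rows(self):
        logo = profile_to_logo(self._uniform_profile(-3.7))
        assert np.allclose(logo.to_numpy(), 1.0 / 20, atol=1e-12)

    def test_infinite_temperature_limit_is_uniform(self, rng):
        prof = self._uniform_profile()
        prof.energies.loc[:, :] = rng.normal(size=(3, 20))
        logo = profile_to_logo(prof, kT=1e6)
        assert np.allclose(logo.to_numpy(), 1.0 / 20, atol=1e-4)

    def test_dominant_identity_takes_probability(self):
        prof = self._uniform_profile(0.0)
        prof.energies.at[3, "W"] = -10.0
        logo = profile_to_logo(prof, kT=1.0)
        expected = np.exp(10.0) / (np.exp(10.0) + 19.0)
        assert logo.at[3, "W"] == pytest.approx(expected, rel=1e-9)
        assert logo.at[3, "W"] > 0.99

    def test_rows_normalize_with_missing_cells(self, rng):
        prof = self._uniform_profile()
        prof.energies.loc[:, :] = rng.normal(size=(3, 20))
        prof.energies.iloc[0, :15] = np.nan  # sparse position
        logo = profile_to_logo(prof)
        assert np.allclose(logo.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(logo.to_numpy()[0, :15] == 0.0)

    def test_invalid_kt_rejected(self):
        with pytest.raises(ValueError):
            profile_to_logo(self._uniform_profile(), kT=0.0)


def test_profile_tsv_round_trip(tmp_path, rng):
    e = pd.DataFrame(rng.normal(size=(3, 20)), index=[2, 3, 4],
                     columns=AA_LIST)
    c = pd.DataFrame(1, index=[2, 3, 4], columns=AA_LIST)
    prof = PreferenceProfile("NBD1", e, c, baseline="polyala")
    path = tmp_path / "prof.tsv"
    profile_to_tsv(prof, path)
    text = path.read_text()
    assert text.startswith("# ring: NBD1")
    back = pd.read_csv(path, sep="\t", comment="#", index_col="position")
    assert np.allclose(back.to_numpy(), e.to_numpy(), atol=1e-12)
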