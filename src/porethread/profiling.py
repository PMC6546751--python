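"""Per-position amino-acid preference profiles, null background, rankings, logos.

Two profile conventions are produced, matching how threading results are
normally read:

* *threaded* profiles aggregate the scored window table: the cell at
  (position, amino acid) is the mean total energy of all windows that
  carry that amino acid at that position.  The first and last window
  positions are excluded by default (terminal residues are only
  partially enclosed by the channel and are not informative).
* *null-background* profiles isolate single-position identity effects:
  every residue except one is alanine, the free position cycles through
  all 20 identities, and each cell is that single model's energy minus
  the mean energy of all evaluated null models.

Energies convert to per-position probability distributions (sequence
logos) through a Boltzmann weighting p(aa) ~ exp(-E/kT).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import densmap
from .backbone import BackboneModel
from .sequences import CANONICAL_AA, PeptideWindow
from .threading import (
    RotamerSet,
    ScoringParams,
    ThreadingError,
    polyala_window,
    refine_model,
    score_model,
    thread_sequence,
)

logger = logging.getLogger(__name__)

AA_LIST = list(CANONICAL_AA)


@dataclass
class PreferenceProfile:
    """Position x amino-acid matrix of mean energies.

    ``energies`` is indexed by analyzed 1-based window positions with
    one column per canonical amino acid; cells never observed are NaN
    (missing, not zero).  ``counts`` holds observation counts.
    """

    ring_tag: str
    energies: pd.DataFrame
    counts: pd.DataFrame
    provenance: str = "threaded"
    baseline: str = "none"

    @property
    def positions(self) -> list[int]:
        return list(self.energies.index)

    def cell(self, position: int, aa: str) -> float:
        return float(self.energies.at[position, aa])


def analyzed_positions(k: int, exclude_termini: bool = True) -> list[int]:
    """1-based window positions entering the profile (k - 2 of them when
    termini are excluded)."""
    if exclude_termini:
        return list(range(2, k))
    return list(range(1, k + 1))


def build_profile(
    scored: pd.DataFrame,
    ring: str,
    exclude_termini: bool = True,
    energy_col: str = "total",
    baseline: str = "none",
    polyala_total: float | None = None,
) -> PreferenceProfile:
    """Aggregate a scored window table into a preference profile.

    ``baseline="polyala"`` subtracts the poly-Ala reference total from
    every cell (the ranked-relative-to-Ala convention); ``"none"``
    reports raw means.  Invariant to the row order of the table.
    """
    rows = scored[scored["ring"] == ring]
    if rows.empty:
        raise ValueError(f"no scored windows for ring {ring!r}")
    k = len(rows.iloc[0]["sequence"])
    if (rows["sequence"].str.len() != k).any():
        raise ValueError("inconsistent window lengths in scored table")
    offset = 0.0
    if baseline == "polyala":
        if polyala_total is None:
            raise ValueError("baseline='polyala' requires polyala_total")
        offset = float(polyala_total)
    elif baseline != "none":
        raise ValueError(f"unknown baseline {baseline!r}")

    positions = analyzed_positions(k, exclude_termini)
    sums = pd.DataFrame(0.0, index=positions, columns=AA_LIST)
    counts = pd.DataFrame(0, index=positions, columns=AA_LIST)
    for seq, energy in zip(rows["sequence"], rows[energy_col]):
        for pos in positions:
            aa = seq[pos - 1]
            sums.at[pos, aa] += energy - offset
            counts.at[pos, aa] += 1
    energies = sums.where(counts > 0) / counts.where(counts > 0)
    return PreferenceProfile(
        ring_tag=ring, energies=energies, counts=counts,
        provenance="threaded", baseline=baseline,
    )


def null_background_windows(k: int, exclude_termini: bool = True
                            ) -> list[PeptideWindow]:
    """All-alanine windows with a single substituted position.

    One window per (analyzed position, amino acid); the all-Ala case is
    included once per position (the Ala identity), so the enumeration
    size is (k - 2) * 20 for terminal-excluded windows.
    """
    windows = []
    for pos in analyzed_positions(k, exclude_termini):
        for aa in AA_LIST:
            seq = "A" * (pos - 1) + aa + "A" * (k - pos)
            windows.append(PeptideWindow(
                source_id=f"null_p{pos:02d}{aa}", start=1, sequence=seq,
            ))
    return windows


def null_background_scan(
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
    exclude_termini: bool = True,
    center: bool = True,
) -> tuple[dict[str, PreferenceProfile], int]:
    """Build, refine, and score the single-substitution null models.

    Returns per-ring profiles whose cells are each model's total energy
    minus the mean total of all null models of that ring (raw totals
    when ``center=False``), plus the total model count
    ((k - 2) x 20 x n_rings for terminal-excluded scans).
    """
    params = params or ScoringParams()
    rotamers = rotamers or RotamerSet()
    rings = rings or sorted(backbone_by_ring)
    profiles: dict[str, PreferenceProfile] = {}
    model_count = 0
    for ring_index, ring in enumerate(rings):
        bb = backbone_by_ring[ring]
        dmap = map_by_ring[ring]
        ctx = (context_by_ring or {}).get(ring)
        k = bb.n_residues
        positions = analyzed_positions(k, exclude_termini)
        energies = pd.DataFrame(np.nan, index=positions, columns=AA_LIST)
        counts = pd.DataFrame(0, index=positions, columns=AA_LIST)
        logger.info("null-background scan: ring %s, %d models",
                    ring, len(positions) * len(AA_LIST))
        for w_index, window in enumerate(
            null_background_windows(k, exclude_termini)
        ):
            pos = int(window.source_id[6:8])
            aa = window.source_id[8]
            model = thread_sequence(bb, window, rotamers,
                                    context_atoms=ctx, ring_tag=ring)
            if refine:
                model, energy = refine_model(
                    model, dmap, n_trajectories=n_trajectories,
                    seed=int(np.random.SeedSequence(
                        [max(seed, 0), 1000 + ring_index, w_index]
                    ).generate_state(1)[0] % (2**31)),
                    params=params, context_atoms=ctx, n_moves=n_moves,
                )
            else:
                energy = score_model(model, dmap, params, context_atoms=ctx)
            energies.at[pos, aa] = energy.total
            counts.at[pos, aa] = 1
            model_count += 1
        if center:
            grand_mean = float(np.nanmean(energies.to_numpy()))
            energies = energies - grand_mean
        profiles[ring] = PreferenceProfile(
            ring_tag=ring,
            energies=energies,
            counts=counts,
            provenance="null_background",
            baseline="all-model mean" if center else "raw",
        )
    return profiles, model_count


def calibrate_reference_weights(
    backbone_by_ring: dict[str, BackboneModel],
    map_by_ring: dict[str, densmap.DensityMap],
    params: ScoringParams | None = None,
    seed: int = 0,
    **scan_kwargs,
) -> dict[str, float]:
    """Per-amino-acid reference weights from a null-background scan.

    With zero reference weights, ``ref(aa)`` is set to the poly-Ala
    total minus the mean raw total of the single-``aa`` null models over
    positions and rings.  Applying these weights centres each amino
    acid's null row at the poly-Ala level, so the alanine row of a
    calibrated null profile sits exactly at zero (unfolded-state
    reference anchoring).
    """
    base = params or ScoringParams()
    raw_params = ScoringParams(
        w_density=base.w_density, w_clash=base.w_clash,
        mask_radius=base.mask_radius, resolution=base.resolution,
        clash_scale=base.clash_scale, ref_weights={},
    )
    rings = scan_kwargs.pop("rings", None) or sorted(backbone_by_ring)
    polyala_totals = []
    for ring in rings:
        bb = backbone_by_ring[ring]
        ctx = (scan_kwargs.get("context_by_ring") or {}).get(ring)
        pa = thread_sequence(bb, polyala_window(bb.n_residues),
                             context_atoms=ctx, ring_tag=ring)
        polyala_totals.append(
            score_model(pa, map_by_ring[ring], raw_params,
                        context_atoms=ctx).total
        )
    polyala_mean = float(np.mean(polyala_totals))
    profiles, _ = null_background_scan(
        backbone_by_ring, map_by_ring, raw_params, seed=seed,
        rings=rings, center=False, **scan_kwargs,
    )
    totals: dict[str, list[float]] = {aa: [] for aa in AA_LIST}
    for ring in rings:
        for aa in AA_LIST:
            col = profiles[ring].energies[aa].dropna()
            totals[aa].extend(col.to_numpy())
    return {
        aa: 0.0 if aa == "A" else polyala_mean - float(np.mean(totals[aa]))
        for aa in AA_LIST
    }


def rank_windows(
    scored: pd.DataFrame,
    ring: str,
    polyala_total: float,
) -> pd.DataFrame:
    """Windows sorted by total energy relative to the poly-Ala reference.

    Ascending (most favorable first); ties broken by (source_id, start).
    """
    rows = scored[scored["ring"] == ring].copy()
    if rows.empty:
        raise ValueError(f"no scored windows for ring {ring!r}")
    rows["rel_total"] = rows["total"] - float(polyala_total)
    rows = rows.sort_values(
        ["rel_total", "source_id", "start"], kind="mergesort"
    ).reset_index(drop=True)
    rows["rank"] = np.arange(1, len(rows) + 1)
    return rows


def profile_to_logo(profile: PreferenceProfile, kT: float = 1.0
                    ) -> pd.DataFrame:
    """Boltzmann conversion of a profile to per-position probabilities.

    p(aa | position) ~ exp(-E(position, aa) / kT), normalized over the
    amino acids observed at that position; rows sum to 1.
    """
    if not np.isfinite(kT) or kT <= 0:
        raise ValueError(f"kT must be positive and finite, got {kT}")
    e = profile.energies.to_numpy(dtype=float)
    if np.all(np.isnan(e)):
        raise ValueError("profile has no populated cells")
    with np.errstate(invalid="ignore"):
        shifted = e - np.nanmin(e, axis=1, keepdims=True)
    w = np.exp(-shifted / kT)
    w[np.isnan(e)] = 0.0
    probs = w / w.sum(axis=1, keepdims=True)
    return pd.DataFrame(probs, index=profile.energies.index,
                        columns=profile.energies.columns)


def profile_to_tsv(profile: PreferenceProfile, path: str | Path) -> None:
    """Write a profile as TSV with '#' header metadata lines."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# ring: {profile.ring_tag}\n")
        fh.write(f"# provenance: {profile.provenance}\n")
        fh.write(f"# baseline: {profile.baseline}\n")
        profile.energies.rename_axis("position").to_csv(fh, sep="\t")


def logo_to_tsv(logo: pd.DataFrame, path: str | Path, kT: float = 1.0) -> None:
    """Write a logo probability matrix as TSV (logo-renderer friendly)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# boltzmann kT: {kT}\n")
        logo.rename_axis("position").to_csv(fh, sep="\t")
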