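"""End-to-end orchestration: windows -> backbone -> threading -> profiles.

A :class:`RunConfig` describes one reproducible run: the window length,
per-ring density sources (synthetic channel scenes or MRC files), the
grid-search settings, energy weights, refinement depth, and the seed.
:func:`run_pipeline` executes the stages in order, writes every
intermediate table under the output directory, and returns a manifest
(also written as ``manifest.json``) recording versions, the seed, input
digests, and per-stage timings.

Defaults mirror the study-scale analysis: 13-residue windows, 2-degree
dihedral grid, five refinement trajectories per model.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import densmap, profiling, sequences, synthetic, threading as th
from .backbone import (
    DEFAULT_SEARCH_REGION,
    DihedralRepeat,
    build_chain,
    grid_search_repeat,
    write_backbone_pdb,
)

logger = logging.getLogger(__name__)

STAGES = ("windows", "backbone", "threading", "null_background",
          "profiles", "rankings")


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RingConfig:
    """Density source for one ring.

    Either ``map_path`` (MRC/CCP4 file) or ``scene_seed`` (synthetic
    channel scene).  ``repeat`` fixes the backbone dihedrals; when it is
    None the repeat is recovered from the ring's map by grid search.
    """

    scene_seed: int | None = None
    map_path: str | None = None
    repeat: tuple[float, float, float, float] | None = None
    noise_sigma: float = 0.0


@dataclass
class RunConfig:
    """Flat, versioned configuration of one pipeline run."""

    config_version: int = 1
    k: int = 13
    grid_step: float = 2.0
    search_region: tuple = DEFAULT_SEARCH_REGION
    rings: dict[str, RingConfig] = field(default_factory=lambda: {
        "NBD1": RingConfig(scene_seed=1),
        "NBD2": RingConfig(scene_seed=2),
    })
    #: "casein" (bundled precursors), "synthetic", or a FASTA path
    sequence_source: str = "synthetic"
    synthetic_lengths: tuple[int, ...] = (214, 222, 224, 190)
    w_density: float = 10.0
    w_clash: float = 1.0
    mask_radius: float = 3.0
    resolution: float = synthetic.DEFAULT_RESOLUTION
    reference_mode: str = "zero"  # "zero" | "calibrated"
    run_grid_search: bool = False
    n_trajectories: int = 5
    n_moves: int = 20
    refine: bool = True
    logo_kT: float = 1.0
    seed: int = 0
    outdir: str = "porethread_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        rings = {
            name: RingConfig(**rc) for name, rc in
            (raw.pop("rings", None) or {}).items()
        }
        cfg = cls(**raw)
        if rings:
            cfg.rings = rings
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["rings"] = {name: asdict(rc) for name, rc in self.rings.items()}
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns (and writes) the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "versions": _versions(),
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
        "outputs": {},
    }
    params = th.ScoringParams(
        w_density=config.w_density, w_clash=config.w_clash,
        mask_radius=config.mask_radius, resolution=config.resolution,
    )
    state: dict = {}

    def run_stage(name: str, fn) -> None:
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as exc:  # halt with a stage-named error
            _write_manifest(manifest, outdir)
            raise PipelineStageError(name, exc) from exc
        manifest["stages"][name] = {
            "status": "completed",
            "seconds": round(time.perf_counter() - t0, 3),
        }

    # -- stage 1: windows -------------------------------------------------
    def stage_windows() -> None:
        scenes = _build_scenes(config)
        state["scenes"] = scenes
        if config.sequence_source == "casein":
            isoforms = sequences.load_casein_precursors()
        elif config.sequence_source == "synthetic":
            truth = next(iter(scenes.values())).truth_window \
                if scenes else None
            isoforms = synthetic.make_isoform_set(
                n=len(config.synthetic_lengths),
                lengths=tuple(config.synthetic_lengths),
                seed=config.seed, truth_window=truth,
            )
        else:
            isoforms = sequences.read_fasta(config.sequence_source)
        windows = sequences.generate_windows(isoforms, config.k)
        state["windows"] = windows
        out = outdir / "windows.tsv"
        sequences.windows_to_tsv(windows, out)
        manifest["outputs"]["windows"] = str(out)
        manifest["n_windows_per_ring"] = len(windows)

    # -- stage 2: backbone ------------------------------------------------
    def stage_backbone() -> None:
        backbones, maps, contexts, repeats = {}, {}, {}, {}
        for ring, rc in config.rings.items():
            scene = state["scenes"].get(ring)
            if scene is not None:
                maps[ring] = scene.map_noisy
                contexts[ring] = scene.pocket_atoms
            else:
                maps[ring] = densmap.read_map(rc.map_path)
            if config.run_grid_search:
                result = grid_search_repeat(
                    maps[ring], config.k, config.grid_step,
                    search_region=config.search_region,
                    resolution=config.resolution,
                )
                repeats[ring] = result.repeat
            elif rc.repeat is not None:
                repeats[ring] = DihedralRepeat(*rc.repeat)
            elif scene is not None:
                repeats[ring] = scene.repeat
            else:
                raise ValueError(
                    f"ring {ring!r}: no repeat given and grid search off"
                )
            backbones[ring] = (
                scene.backbone if scene is not None
                and repeats[ring] == scene.repeat
                else build_chain(repeats[ring], config.k)
            )
            pdb_out = outdir / f"backbone_{ring}.pdb"
            write_backbone_pdb(backbones[ring], pdb_out)
            manifest["outputs"][f"backbone_{ring}"] = str(pdb_out)
        state.update(backbones=backbones, maps=maps, contexts=contexts)
        rep_out = outdir / "repeats.json"
        rep_out.write_text(json.dumps(
            {r: repeats[r].as_tuple() for r in repeats}, indent=2))
        manifest["outputs"]["repeats"] = str(rep_out)

    # -- stage 3: threading -----------------------------------------------
    def stage_threading() -> None:
        ref_weights = {}
        if config.reference_mode == "calibrated":
            ref_weights = profiling.calibrate_reference_weights(
                state["backbones"], state["maps"], params,
                seed=config.seed, context_by_ring=state["contexts"],
                refine=False,
            )
        scoring = th.ScoringParams(
            w_density=params.w_density, w_clash=params.w_clash,
            mask_radius=params.mask_radius, resolution=params.resolution,
            ref_weights=ref_weights,
        )
        state["scoring"] = scoring
        scored = th.thread_all(
            state["windows"], state["backbones"], state["maps"],
            scoring, seed=config.seed, context_by_ring=state["contexts"],
            refine=config.refine, n_trajectories=config.n_trajectories,
            n_moves=config.n_moves,
        )
        state["scored"] = scored
        out = outdir / "scores.tsv"
        scored.to_csv(out, sep="\t", index=False)
        manifest["outputs"]["scores"] = str(out)
        manifest["n_threaded_models"] = len(scored)

    # -- stage 4: null background -----------------------------------------
    def stage_null() -> None:
        profiles, count = profiling.null_background_scan(
            state["backbones"], state["maps"], state["scoring"],
            seed=config.seed, context_by_ring=state["contexts"],
            refine=config.refine, n_trajectories=config.n_trajectories,
            n_moves=config.n_moves,
        )
        state["null_profiles"] = profiles
        manifest["n_null_models"] = count
        for ring, prof in profiles.items():
            out = outdir / f"null_profile_{ring}.tsv"
            profiling.profile_to_tsv(prof, out)
            manifest["outputs"][f"null_profile_{ring}"] = str(out)

    # -- stage 5: profiles + logos ----------------------------------------
    def stage_profiles() -> None:
        state["polyala"] = {}
        for ring in config.rings:
            bb = state["backbones"][ring]
            ctx = state["contexts"].get(ring)
            pa = th.thread_sequence(bb, th.polyala_window(config.k),
                                    context_atoms=ctx, ring_tag=ring)
            pa_total = th.score_model(
                pa, state["maps"][ring], state["scoring"],
                context_atoms=ctx,
            ).total
            state["polyala"][ring] = pa_total
            prof = profiling.build_profile(
                state["scored"], ring, baseline="polyala",
                polyala_total=pa_total,
            )
            out = outdir / f"profile_{ring}.tsv"
            profiling.profile_to_tsv(prof, out)
            manifest["outputs"][f"profile_{ring}"] = str(out)
            logo = profiling.profile_to_logo(
                state["null_profiles"][ring], kT=config.logo_kT
            )
            logo_out = outdir / f"logo_{ring}.tsv"
            profiling.logo_to_tsv(logo, logo_out, kT=config.logo_kT)
            manifest["outputs"][f"logo_{ring}"] = str(logo_out)

    # -- stage 6: rankings -------------------------------------------------
    def stage_rankings() -> None:
        for ring in config.rings:
            ranked = profiling.rank_windows(
                state["scored"], ring, state["polyala"][ring]
            )
            out = outdir / f"ranked_{ring}.tsv"
            ranked.to_csv(out, sep="\t", index=False)
            manifest["outputs"][f"ranked_{ring}"] = str(out)
            manifest.setdefault("top_window", {})[ring] = {
                "source_id": str(ranked.iloc[0]["source_id"]),
                "start": int(ranked.iloc[0]["start"]),
                "sequence": str(ranked.iloc[0]["sequence"]),
                "rel_total": float(ranked.iloc[0]["rel_total"]),
            }

    for name, fn in zip(STAGES, (stage_windows, stage_backbone,
                                 stage_threading, stage_null,
                                 stage_profiles, stage_rankings)):
        logger.info("pipeline stage: %s", name)
        run_stage(name, fn)

    manifest["output_digests"] = {
        key: _sha256(Path(p)) for key, p in manifest["outputs"].items()
    }
    _write_manifest(manifest, outdir)
    return manifest


def _build_scenes(config: RunConfig) -> dict:
    scenes = {}
    for ring, rc in config.rings.items():
        if rc.scene_seed is not None:
            scenes[ring] = synthetic.make_channel_scene(
                seed=rc.scene_seed, k=config.k,
                noise_sigma=rc.noise_sigma,
                resolution=config.resolution,
            )
    return scenes


def _versions() -> dict:
    import gemmi
    import pandas

    from . import __version__

    return {
        "porethread": __version__,
        "numpy": np.__version__,
        "pandas": pandas.__version__,
        "gemmi": gemmi.__version__,
    }


def _write_manifest(manifest: dict, outdir: Path) -> None:
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
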