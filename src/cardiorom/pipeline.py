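"""End-to-end pipeline: simulate, compress, train, evaluate.

Stages (each resumable from the HDF5 artifact container):

1. ``design``   — sample training/testing parameter instances;
2. ``simulate`` — run the full-order model for every instance;
3. ``compress`` — build snapshot matrices and one randomized-POD basis per
   field channel;
4. ``train``    — project snapshots, train the autoencoder + DFNN surrogate;
5. ``evaluate`` — reconstruct the testing trajectories with the surrogate,
   compute the error indicator per channel, the projection error (its exact
   lower bound), and the per-time spatial error means.

A manifest (JSON) records the config hash, seeds, and stage timings.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from . import io as _io
from .assembly import ConductivityModel, StimulusSpec, assemble_operators, make_fiber_field
from .config import ExperimentConfig, config_hash
from .design import ExperimentDesign, sample_design
from .errors import StageError
from .ionic import PRESETS, IonicModel, IonicModelParams
from .metrics import error_indicator, relative_error_means
from .pod import build_snapshot_matrix, projection_error_indicator, randomized_pod
from .rom import ArchitectureConfig, TrainingConfig, intrinsic_dataset, predict, train
from .solver import SolverConfig, simulate
from .splines import SplineSpace, build_spline_space

__all__ = ["PipelineResult", "run_pipeline", "build_space", "build_conductivity",
           "build_ionic", "build_stimuli", "build_solver_config"]

STAGES = ("design", "simulate", "compress", "train", "evaluate")


# --------------------------------------------------------------------------
# config -> domain object builders
# --------------------------------------------------------------------------

def build_space(cfg: ExperimentConfig) -> SplineSpace:
    g = cfg.geometry
    return build_spline_space(g.p, g.n_el, g.extents)


def build_conductivity(cfg: ExperimentConfig, space: SplineSpace) -> ConductivityModel:
    fiber = make_fiber_field(
        space, cfg.fiber.rule, direction=cfg.fiber.direction, markers=cfg.fiber.markers
    )
    c = cfg.conductivity
    return ConductivityModel(
        sigma_l_i=c.sigma_l_i, sigma_t_i=c.sigma_t_i,
        sigma_l_e=c.sigma_l_e, sigma_t_e=c.sigma_t_e,
        fiber=fiber, param_map=dict(c.param_map),
    )


def build_ionic(cfg: ExperimentConfig) -> IonicModelParams:
    if cfg.ionic.preset is not None:
        return PRESETS[cfg.ionic.preset]
    return IonicModelParams(model_id=IonicModel(cfg.ionic.model_id), **cfg.ionic.params)


def build_stimuli(cfg: ExperimentConfig) -> list[StimulusSpec]:
    out = []
    for s in cfg.stimuli:
        out.append(StimulusSpec(
            amplitude=s.amplitude, region=s.region, t_start=s.t_start, t_end=s.t_end,
            x0=s.x0, center=s.center, radius=s.radius, compartment=s.compartment,
            center_from_mu=s.center_from_mu,
        ))
    return out


def build_solver_config(cfg: ExperimentConfig) -> SolverConfig:
    t = cfg.time
    return SolverConfig(dt=t.dt, T=t.T, n_save=t.n_t, window=t.window,
                        ionic_mode=t.ionic_mode)


def _design_from_config(cfg: ExperimentConfig, seed: int | None) -> ExperimentDesign:
    d = cfg.design
    return ExperimentDesign(
        bounds=d.bounds, n_train=d.n_train, n_test=d.n_test,
        train_rule=d.train_rule, test_rule=d.test_rule,
        train_seed=d.train_seed if seed is None else seed,
        test_seed=d.test_seed if seed is None else seed + 1,
    )


# --------------------------------------------------------------------------
# result container
# --------------------------------------------------------------------------

@dataclass
class PipelineResult:
    config: ExperimentConfig
    mus_train: np.ndarray = None
    mus_test: np.ndarray = None
    train_trajectories: list = None
    test_trajectories: list = None
    bases: dict = None
    networks: object = None
    history: dict = None
    report: dict = None
    manifest: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# the pipeline
# --------------------------------------------------------------------------

def _evaluate(cfg, result) -> dict:
    channels = cfg.channels
    bases = result.bases
    nets = result.networks
    trues = {ch: [] for ch in channels}
    preds = {ch: [] for ch in channels}
    for tr in result.test_trajectories:
        out = predict(nets, bases, tr.times, tr.mu)
        for ch in channels:
            trues[ch].append(getattr(tr, ch))
            preds[ch].append(out[ch])
    eps = {ch: error_indicator(trues[ch], preds[ch]) for ch in channels}
    proj = {
        ch: projection_error_indicator(bases[ch], trues[ch]) for ch in channels
    }
    # exact lower-bound property of the orthogonal projection
    bound_ok = {ch: bool(eps[ch] >= proj[ch] - 1e-12) for ch in channels}
    eps_k_mean = {
        ch: relative_error_means(trues[ch][0], preds[ch][0]) for ch in channels
    }
    return {
        "epsilon_rel": eps,
        "projection_epsilon_rel": proj,
        "projection_bound_holds": bound_ok,
        "epsilon_k_mean": eps_k_mean,
        "n": nets.n,
        "N": cfg.pod.N,
        "mu_test": [list(np.atleast_1d(tr.mu)) for tr in result.test_trajectories],
    }


def run_pipeline(
    cfg: ExperimentConfig,
    output_dir: str | Path | None = None,
    resume: bool = False,
    seed: int | None = None,
    stop_after: str | None = None,
) -> PipelineResult:
    """Run all stages (or up to ``stop_after``); deterministic given seeds.

    ``seed`` overrides every stage seed in the config (derived offsets keep
    the stages decorrelated).  With ``output_dir``, artifacts are persisted
    to ``<output_dir>/artifacts.h5`` plus a manifest; with ``resume=True``,
    stages found in the container are loaded instead of recomputed.
    """
    result = PipelineResult(config=cfg)
    h5file = None
    manifest = {
        "config_hash": config_hash(cfg),
        "name": cfg.name,
        "seed_override": seed,
        "timings": {},
    }
    if output_dir is not None:
        outdir = Path(output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        h5file = h5py.File(outdir / "artifacts.h5", "a" if resume else "w")

    pod_seed = cfg.pod.seed if seed is None else seed + 2
    train_seed = cfg.training.seed if seed is None else seed + 3

    def _timed(stage, fn):
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as exc:
            if h5file is not None:
                h5file.close()
            raise StageError(stage, str(exc)) from exc
        manifest["timings"][stage] = time.perf_counter() - t0

    # -- design -------------------------------------------------------------
    def _design():
        if h5file is not None and resume and "design" in h5file:
            result.mus_train, result.mus_test = _io.load_design(h5file)
            return
        design = _design_from_config(cfg, seed)
        result.mus_train, result.mus_test = sample_design(design)
        if h5file is not None:
            _io.save_design(h5file, result.mus_train, result.mus_test)

    # -- simulate -----------------------------------------------------------
    def _simulate():
        if h5file is not None and resume and "trajectories/train" in h5file:
            result.train_trajectories = _io.load_trajectories(h5file, "trajectories/train")
            result.test_trajectories = _io.load_trajectories(h5file, "trajectories/test")
            return
        space = build_space(cfg)
        cond = build_conductivity(cfg, space)
        ionic = build_ionic(cfg)
        stimuli = build_stimuli(cfg)
        scfg = build_solver_config(cfg)
        ops = None if cfg.conductivity.param_map else assemble_operators(space, cond)
        result.train_trajectories = [
            simulate(space, cond, ionic, stimuli, scfg, mu=mu, ops=ops)
            for mu in result.mus_train
        ]
        result.test_trajectories = [
            simulate(space, cond, ionic, stimuli, scfg, mu=mu, ops=ops)
            for mu in result.mus_test
        ]
        if h5file is not None:
            _io.save_trajectories(h5file, "trajectories/train", result.train_trajectories)
            _io.save_trajectories(h5file, "trajectories/test", result.test_trajectories)

    # -- compress -----------------------------------------------------------
    def _compress():
        if h5file is not None and resume and "pod" in h5file:
            result.bases = {ch: _io.load_basis(h5file, ch) for ch in cfg.channels}
            return
        snaps = build_snapshot_matrix(result.train_trajectories, cfg.channels)
        result.bases = {
            ch: randomized_pod(
                snaps.channels[ch], cfg.pod.N, cfg.pod.oversampling,
                cfg.pod.n_power_iter, seed=pod_seed, channel=ch,
            )
            for ch in cfg.channels
        }
        result._snapshots = snaps
        if h5file is not None:
            for basis in result.bases.values():
                _io.save_basis(h5file, basis)

    # -- train --------------------------------------------------------------
    def _train():
        if h5file is not None and resume and "networks" in h5file:
            result.networks = _io.load_networks(h5file)
            return
        snaps = getattr(result, "_snapshots", None)
        if snaps is None:
            snaps = build_snapshot_matrix(result.train_trajectories, cfg.channels)
        X, Y, names = intrinsic_dataset(snaps, result.bases)
        t = cfg.training
        tcfg = TrainingConfig(
            n_epochs=t.n_epochs, batch_size=t.batch_size, lr=t.lr,
            lr_final=t.lr_final, patience=t.patience, omega_h=t.omega_h,
            val_fraction=t.val_fraction, seed=train_seed,
        )
        arch = ArchitectureConfig(
            encoder_widths=t.encoder_widths, dfnn_widths=t.dfnn_widths,
            decoder_widths=t.decoder_widths,
            decoder_fourier_modes=t.decoder_fourier_modes,
        )
        result.networks, result.history = train(
            X, Y, n=cfg.n, N=cfg.pod.N, channel_names=names, cfg=tcfg, arch=arch,
        )
        if h5file is not None:
            _io.save_networks(h5file, result.networks, result.history)

    # -- evaluate -----------------------------------------------------------
    def _evaluate_stage():
        result.report = _evaluate(cfg, result)
        if h5file is not None:
            _io.save_report(h5file, result.report)

    stage_fns = {
        "design": _design, "simulate": _simulate, "compress": _compress,
        "train": _train, "evaluate": _evaluate_stage,
    }
    for stage in STAGES:
        _timed(stage, stage_fns[stage])
        if stop_after == stage:
            break

    result.manifest = manifest
    if h5file is not None:
        h5file.close()
        (Path(output_dir) / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return result
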