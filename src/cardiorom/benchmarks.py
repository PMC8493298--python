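"""Shipped benchmark configurations and reduced-scale fixtures.

* ``test1_1`` — the full slab benchmark: 10 x 2 cm tissue slab, p = 3
  splines on 160 x 32 elements (N_h = 5705), Rogers-McCulloch kinetics,
  half-space stimulus, longitudinal extracellular conductivity as the
  parameter, N_t = 1500 samples over 150 ms at dt = 0.05 ms, 11 training /
  10 midpoint testing instances, POD dimension N = 256, latent n = 2.  This
  runs for hours on a workstation; it is shipped for completeness.
* ``test1_1_reduced`` (= ``make_fixture("small")``) — the same physics
  family on a p = 2, 80 x 16 element space: a focal (ball) stimulus at the
  left edge so the fields are genuinely two-dimensional, and conductivities
  scaled up so the coarser mesh resolves the depolarization front in both
  directions, over a 100 ms window.
* ``reentry_slab`` — an S1-S2 re-entry protocol on a 6 x 6 cm slab with a
  shortened-recovery R-M variant (eta2 = 0.03, APD ~ 43 ms) so that the
  re-entrant wavelength fits the domain; the S2 ball center is the 2-D
  parameter, mirroring stimulation-site parametrizations.
* ``make_fixture("tiny")`` — a 4 x 1 cm slab for fast tests.

Fixture design notes.  The printed slab protocol is strictly planar (fibers
(1,0), half-space stimulus), so its snapshot matrices have rank equal to the
number of x-direction basis functions; a focal stimulus is required for the
POD dimension of the fixtures to be meaningful.  Focal fronts see the
transverse conductivity, whose printed value would need a mesh several times
finer than the fixtures'; the fixture tensors therefore use larger
conductivities at a milder anisotropy (longitudinal/transverse diffusivity
ratio ~ 1.7 - 4 over the parameter range), keeping the front resolved
(coefficient under/overshoot well inside the 0.3 u_p solver guard).
"""

from __future__ import annotations

from .config import (
    ConductivityConfig,
    DesignConfig,
    ExperimentConfig,
    FiberConfig,
    GeometryConfig,
    IonicConfig,
    PodConfig,
    StimulusConfig,
    TimeConfig,
    TrainingStageConfig,
)
from .errors import ConfigError

__all__ = ["make_fixture", "benchmark_config", "BENCHMARKS"]

_SIGMA = dict(sigma_l_i=2.3e-3, sigma_t_i=2.4e-4, sigma_l_e=1.5e-3, sigma_t_e=1.0e-3)
#: fixture tensors: resolved front at h = 0.125 cm, mild anisotropy (see module doc)
_SIGMA_FIXTURE = dict(sigma_l_i=1.84e-2, sigma_t_i=9.6e-3,
                      sigma_l_e=2.4e-2, sigma_t_e=8.0e-3)
_MU_FIXTURE = (1.2e-2, 1.2e-1)

_S1_HALF = StimulusConfig(amplitude=100.0, region="half_space", x0=0.2,
                          t_start=0.0, t_end=1.0)


def _test1_1() -> ExperimentConfig:
    return ExperimentConfig(
        name="test1_1",
        geometry=GeometryConfig(p=3, n_el=(160, 32), extents=((0, 10), (0, 2))),
        conductivity=ConductivityConfig(**_SIGMA, param_map={"sigma_l_e": 0}),
        ionic=IonicConfig(preset="test1_1_rm"),
        stimuli=(_S1_HALF,),
        time=TimeConfig(dt=0.05, T=150.0, n_t=1500),
        design=DesignConfig(bounds=((1.5e-3, 1.5e-2),), n_train=11, n_test=10),
        pod=PodConfig(N=256),
        training=TrainingStageConfig(
            n_epochs=20000, batch_size=40, lr=2e-4, lr_final=None, patience=1000,
        ),
    )


def _small() -> ExperimentConfig:
    return ExperimentConfig(
        name="test1_1_reduced",
        geometry=GeometryConfig(p=2, n_el=(80, 16), extents=((0, 10), (0, 2))),
        conductivity=ConductivityConfig(**_SIGMA_FIXTURE, param_map={"sigma_l_e": 0}),
        ionic=IonicConfig(preset="test1_1_rm"),
        stimuli=(StimulusConfig(amplitude=60.0, region="ball", center=(0.0, 1.0),
                                radius=0.75, t_start=0.0, t_end=1.0),),
        time=TimeConfig(dt=0.1, T=100.0, n_t=200, window=(2.0, 100.0)),
        design=DesignConfig(bounds=(_MU_FIXTURE,), n_train=7, n_test=2),
        pod=PodConfig(N=144),
        training=TrainingStageConfig(
            n_epochs=9000, patience=2000, batch_size=128, lr=3e-3, lr_final=3e-5,
            omega_h=0.8, encoder_widths=(256,), dfnn_widths=(128, 128),
            decoder_widths=(128, 128),
        ),
    )


def _tiny() -> ExperimentConfig:
    return ExperimentConfig(
        name="tiny_slab",
        geometry=GeometryConfig(p=2, n_el=(32, 8), extents=((0, 4), (0, 1))),
        conductivity=ConductivityConfig(**_SIGMA_FIXTURE, param_map={"sigma_l_e": 0}),
        ionic=IonicConfig(preset="test1_1_rm"),
        stimuli=(StimulusConfig(amplitude=60.0, region="ball", center=(0.0, 0.5),
                                radius=0.4, t_start=0.0, t_end=1.0),),
        time=TimeConfig(dt=0.1, T=40.0, n_t=50, window=(2.0, 40.0)),
        design=DesignConfig(bounds=(_MU_FIXTURE,), n_train=5, n_test=2),
        pod=PodConfig(N=64),
        training=TrainingStageConfig(
            n_epochs=3000, patience=2999, batch_size=64, lr=3e-3, lr_final=3e-5,
            omega_h=0.8, encoder_widths=(128,), dfnn_widths=(64, 64),
            decoder_widths=(128,),
        ),
    )


#: Shortened-recovery Rogers-McCulloch constants for the re-entry slab.
REENTRY_RM = dict(G=1.5, eta1=4.4, eta2=3e-2, eta3=1.0, u_th=13.0, u_p=100.0)

#: Vulnerable-window S2 onset (ms) for the default re-entry slab protocol.
REENTRY_S2_ONSET = 60.0


def _reentry(s2_in_window: bool = True) -> ExperimentConfig:
    t2 = REENTRY_S2_ONSET if s2_in_window else 40.0
    return ExperimentConfig(
        name="reentry_slab",
        geometry=GeometryConfig(p=2, n_el=(64, 64), extents=((0, 6), (0, 6))),
        conductivity=ConductivityConfig(
            sigma_l_i=9.2e-3, sigma_t_i=2.4e-3, sigma_l_e=8e-3, sigma_t_e=4e-3,
        ),
        ionic=IonicConfig(model_id="rogers_mcculloch", params=REENTRY_RM),
        stimuli=(
            StimulusConfig(amplitude=100.0, region="half_space", x0=0.3,
                           t_start=0.0, t_end=1.0),
            StimulusConfig(amplitude=100.0, region="ball", radius=1.2,
                           center=(2.0, 3.0), center_from_mu=(0, 1),
                           t_start=t2, t_end=t2 + 2.0),
        ),
        time=TimeConfig(dt=0.1, T=250.0, n_t=250, window=(150.0, 250.0)),
        design=DesignConfig(
            bounds=((1.7, 2.3), (2.5, 3.5)), n_train=6, n_test=2,
            train_rule="random", test_rule="random", train_seed=10, test_seed=11,
        ),
        pod=PodConfig(N=64),
        training=TrainingStageConfig(n_epochs=4000, patience=600),
    )


BENCHMARKS = {
    "test1_1": _test1_1,
    "test1_1_reduced": _small,
    "reentry_slab": _reentry,
}


def make_fixture(scale: str = "tiny") -> ExperimentConfig:
    """Reduced-scale benchmark configs: ``tiny`` (seconds) or ``small`` (minutes)."""
    if scale == "tiny":
        return _tiny()
    if scale == "small":
        return _small()
    raise ConfigError(f"unknown fixture scale '{scale}' (use 'tiny' or 'small')")


def benchmark_config(name: str) -> ExperimentConfig:
    try:
        return BENCHMARKS[name]()
    except KeyError:
        raise ConfigError(
            f"unknown benchmark '{name}' (available: {sorted(BENCHMARKS)})"
        ) from None
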