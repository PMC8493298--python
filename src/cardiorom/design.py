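"""Experiment designs: parameter-space sampling and train/test splits.

Training instances are drawn either on a uniform grid over a 1-D parameter
interval (the slab conductivity benchmark) or uniformly at random inside a
box (stimulation-site benchmarks); testing instances are either the
midpoints of consecutive grid points (guaranteed distinct from training) or
fresh random draws.  All randomness is seeded and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .errors import ConfigError

__all__ = ["ExperimentDesign", "sample_design"]


@dataclass(frozen=True)
class ExperimentDesign:
    """Parameter-space bounds and sampling rules.

    ``bounds`` has one (low, high) pair per parameter component; the
    midpoints testing rule requires uniform-grid training (n_mu = 1) and
    offers ``n_train - 1`` candidate midpoints, from which ``n_test`` are
    taken evenly spaced.
    """

    bounds: tuple                      # ((lo, hi), ...) length n_mu
    n_train: int
    n_test: int
    train_rule: Literal["uniform_grid", "random"] = "uniform_grid"
    test_rule: Literal["midpoints", "random"] = "midpoints"
    train_seed: int = 0
    test_seed: int = 1

    def __post_init__(self):
        b = tuple((float(lo), float(hi)) for lo, hi in self.bounds)
        object.__setattr__(self, "bounds", b)
        if any(hi <= lo for lo, hi in b):
            raise ConfigError("parameter bounds must have positive width")
        if self.n_train < 2 or self.n_test < 1:
            raise ConfigError("need n_train >= 2 and n_test >= 1")
        if self.train_rule == "uniform_grid" and self.n_mu != 1:
            raise ConfigError("uniform_grid training requires a 1-D parameter")
        if self.test_rule == "midpoints":
            if self.train_rule != "uniform_grid":
                raise ConfigError("midpoints testing requires uniform_grid training")
            if self.n_test > self.n_train - 1:
                raise ConfigError(
                    f"midpoints rule offers {self.n_train - 1} candidates, "
                    f"requested n_test={self.n_test}"
                )

    @property
    def n_mu(self) -> int:
        return len(self.bounds)


def _random_in_box(rng: np.random.Generator, bounds, n: int) -> np.ndarray:
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    return lo + (hi - lo) * rng.random((n, len(bounds)))


def sample_design(design: ExperimentDesign) -> tuple[np.ndarray, np.ndarray]:
    """Return (train, test) parameter arrays of shape (n, n_mu).

    Deterministic given the design's seeds; testing instances never coincide
    with training instances (exact midpoints for the grid rule, rejection
    resampling for the random rule).
    """
    if design.train_rule == "uniform_grid":
        lo, hi = design.bounds[0]
        train = np.linspace(lo, hi, design.n_train)[:, None]
    else:
        train = _random_in_box(
            np.random.default_rng(design.train_seed), design.bounds, design.n_train
        )

    if design.test_rule == "midpoints":
        mids = 0.5 * (train[:-1, 0] + train[1:, 0])
        pick = np.linspace(0, len(mids) - 1, design.n_test).round().astype(int)
        test = mids[np.unique(pick)][:, None]
        if test.shape[0] != design.n_test:
            raise ConfigError("evenly spaced midpoint subset collapsed; reduce n_test")
    else:
        rng = np.random.default_rng(design.test_seed)
        test = _random_in_box(rng, design.bounds, design.n_test)
        train_rows = {tuple(r) for r in np.round(train, 12)}
        for i in range(design.n_test):
            while tuple(np.round(test[i], 12)) in train_rows:
                test[i] = _random_in_box(rng, design.bounds, 1)[0]
    return train, test
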