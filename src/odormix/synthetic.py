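"""Synthetic dose-response fixtures and the printed parameter collections.

``generate_curve`` draws noisy sigmoidal dose-response observations from a
known parameter set so that fitting, classification and prediction can be
exercised without access to electrophysiological recordings.  Noise is
multiplicative Gaussian (firing-rate variability scales with the
response), truncated to [0, F_max]; a zero noise level reproduces the
model curve exactly and a fixed seed makes fixtures bit-reproducible.

``builtin_parameter_sets`` returns the published parameter sets of the
model-behavior illustrations, keyed "fig1/<behavior>", plus the control
pair ("fig2/control") and the efficacy-sweep settings ("fig3a/fixed").
Where a set does not state its own mixing ratio, the shared default
r = 0.2 applies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .models import GlobalConfig, OdorParams, single_response

__all__ = ["ConcGrid", "FixtureSpec", "PairSpec", "PhaseSweepSpec",
           "generate_curve", "builtin_parameter_sets"]


@dataclass(frozen=True)
class ConcGrid:
    """Logarithmic concentration design: ``num`` points over ``decades`` around ``center``."""

    center: float
    decades: float = 4.0
    num: int = 12

    def __post_init__(self):
        if not (math.isfinite(self.center) and self.center > 0):
            raise ValidationError("grid center must be positive and finite")
        if not (math.isfinite(self.decades) and self.decades > 0):
            raise ValidationError("grid span must be positive")
        if self.num < 3:
            raise ValidationError("at least 3 grid points required")

    def points(self) -> np.ndarray:
        half = self.decades / 2.0
        c = math.log10(self.center)
        return np.logspace(c - half, c + half, self.num)


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic dose-response table."""

    params: OdorParams
    grid: ConcGrid | None = None
    noise: float = 0.0
    seed: int = 0
    cfg: GlobalConfig = field(default_factory=GlobalConfig)

    def __post_init__(self):
        if not (math.isfinite(self.noise) and self.noise >= 0):
            raise ValidationError("noise coefficient of variation must be >= 0")


def generate_curve(spec: FixtureSpec) -> pd.DataFrame:
    """Draw one synthetic dose-response table from a fixture recipe."""
    grid = spec.grid or ConcGrid(center=spec.params.K)
    conc = grid.points()
    clean = single_response(spec.params, conc, spec.cfg)
    if spec.noise > 0:
        rng = np.random.default_rng(spec.seed)
        resp = clean * (1.0 + spec.noise * rng.standard_normal(conc.shape))
        resp = np.clip(resp, 0.0, spec.cfg.f_max)
    else:
        resp = clean
    df = pd.DataFrame({"concentration": conc, "response": resp})
    df.attrs["odor"] = spec.params.name
    df.attrs["units"] = "linear"
    df.attrs["noise"] = spec.noise
    df.attrs["seed"] = spec.seed
    return df


@dataclass(frozen=True)
class PairSpec:
    """A published two-odor parameter set with its mixing ratio and caption labels."""

    U: OdorParams
    V: OdorParams
    r: float
    caption: tuple[str, ...]


@dataclass(frozen=True)
class PhaseSweepSpec:
    """Fixed parameters of the published efficacy-sweep phase diagram."""

    n_u: float
    n_v: float
    K_u: float
    K_v: float
    r: float


_DEFAULT_R = 0.2


def builtin_parameter_sets() -> dict:
    """The printed parameter collections, keyed by figure and behavior name."""
    sets: dict = {
        "fig1/suppression": PairSpec(
            OdorParams(1.5, 1.7, 0.2, name="U"), OdorParams(3.5, 0.7, 0.2, name="V"),
            _DEFAULT_R, ("suppression",)),
        "fig1/synergy": PairSpec(
            OdorParams(3.6, 1.7, 3.16e-4, name="U"), OdorParams(19.6, 1.1, 1e-4, name="V"),
            1.0, ("synergy",)),
        "fig1/overshadowing_hypoadditivity": PairSpec(
            OdorParams(3.5, 0.7, 0.2, name="U"), OdorParams(0.5, 1.7, 0.2, name="V"),
            _DEFAULT_R, ("overshadowing", "hypoadditivity")),
        "fig1/inhibition": PairSpec(
            OdorParams(4.5, 1.3, 0.2, name="U"), OdorParams(0.5, 0.3, 0.2, name="V"),
            _DEFAULT_R, ("inhibition",)),
        "fig1/overshadowing_suppression": PairSpec(
            OdorParams(0.5, 16.0, 0.51e-3, name="U"), OdorParams(10.0, 0.95, 0.9e-2, name="V"),
            1.6, ("overshadowing", "suppression")),
        "fig1/overshadowing": PairSpec(
            OdorParams(0.5, 16.0, 0.8e-2, name="U"), OdorParams(10.0, 0.95, 0.9e-2, name="V"),
            2e-4, ("overshadowing",)),
        "fig2/control": PairSpec(
            OdorParams(3.6, 1.7, 3.16e-4, name="U"), OdorParams(19.6, 1.1, 1e-4, name="V"),
            1.0, ("synergy",)),
        "fig3a/fixed": PhaseSweepSpec(n_u=1.0, n_v=12.0, K_u=0.5e-4, K_v=1e-3, r=1.0),
    }
    return sets
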