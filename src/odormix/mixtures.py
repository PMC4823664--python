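"""Mixture responses, fixed-ratio reduction and protocol adapters.

The mixture response of an OSN to components with parameters
``(n_i, eta_i, K_i)`` at concentrations ``c_i`` is built from the three
efficacy-weighted sums (``x_i = c_i / K_i``)::

    A = sum n_i * eta_i * x_i,   B = sum eta_i * x_i,   C = sum x_i
    F = F_max / (1 + ((1 + C) / B) ** (A / B))

With a single component this reduces exactly to the single-odor curve;
with identical components it satisfies the self-mixture identity
``F(c, c) = F(2c, 0)``.  Along a fixed-ratio ray the mixture is again a
sigmoid of the same family, whose effective parameters are the
weighted means::

    s_eff   = sum w_i s_i
    eta_eff = sum w_i eta_i s_i / s_eff
    n_eff   = sum w_i n_i eta_i s_i / sum w_i eta_i s_i

Two experimental protocols are supported: *same dilution*, where every
component's concentration is a shared dilution times its saturated-vapor
molarity, and *fixed background*, where one odor is swept while the other
is held at a constant added concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import DomainError, ValidationError
from .models import (
    GlobalConfig,
    LegacyOdorParams,
    OdorParams,
    _as_conc,
    asymptote,
    conc_at_fraction,
    midpoint,
    single_response,
)

__all__ = [
    "MixtureComponent",
    "MixtureSpec",
    "ProtocolSpec",
    "EffectiveSigmoid",
    "CurveSummary",
    "mixture_response",
    "effective_fixed_ratio",
    "ray_params",
    "curve_summary",
    "predict_same_dilution",
    "predict_fixed_background",
    "synergy_feasible",
]


@dataclass(frozen=True)
class MixtureComponent:
    """One odor in a mixture together with its concentration ratio weight."""

    odor: OdorParams
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.weight) and self.weight >= 0):
            raise ValidationError("weight must be finite and >= 0")


@dataclass(frozen=True)
class MixtureSpec:
    """An ordered collection of mixture components plus the shared config."""

    components: tuple[MixtureComponent, ...]
    cfg: GlobalConfig = GlobalConfig()

    def __post_init__(self) -> None:
        if len(self.components) < 1:
            raise ValidationError("a mixture needs at least one component")
        if not any(c.weight > 0 for c in self.components):
            raise ValidationError("at least one component must have positive weight")

    @classmethod
    def of(cls, *odors: OdorParams, weights=None, cfg: GlobalConfig = GlobalConfig()):
        if weights is None:
            weights = [1.0] * len(odors)
        return cls(tuple(MixtureComponent(o, w) for o, w in zip(odors, weights)), cfg)


@dataclass(frozen=True)
class ProtocolSpec:
    """Description of the mixture delivery protocol.

    mode="same_dilution": both odors share one dilution series and
    ``svp_molarity`` (saturated-vapor molarity per odor, concentration
    units) converts dilution to per-odor concentration.
    mode="fixed_background": the first odor is swept while the second sits
    at ``background_conc``.
    """

    mode: str
    svp_molarity: tuple[float, float] | None = None
    background_conc: float | None = None

    def __post_init__(self) -> None:
        if self.mode == "same_dilution":
            if self.svp_molarity is None or len(self.svp_molarity) != 2:
                raise ValidationError("same_dilution requires svp_molarity for both odors")
            if not all(math.isfinite(m) and m > 0 for m in self.svp_molarity):
                raise ValidationError("svp molarities must be positive and finite")
        elif self.mode == "fixed_background":
            if self.background_conc is None or not (
                math.isfinite(self.background_conc) and self.background_conc >= 0
            ):
                raise ValidationError("fixed_background requires background_conc >= 0")
        else:
            raise ValidationError(f"unknown protocol mode {self.mode!r}")


@dataclass(frozen=True)
class EffectiveSigmoid:
    """Effective (n, eta, K) of a fixed-ratio mixture curve."""

    n_eff: float
    eta_eff: float
    K_eff: float

    def to_params(self, name: str | None = None) -> OdorParams:
        return OdorParams(n=self.n_eff, eta=self.eta_eff, K=self.K_eff, name=name)


@dataclass(frozen=True)
class CurveSummary:
    """Asymptote, half-asymptote concentration and steepness of a sigmoid."""

    asymptote: float
    midpoint: float
    steepness: float


def mixture_response(spec: MixtureSpec, concs):
    """Mixture response at per-component concentrations ``concs``.

    ``concs`` has one entry per component (scalars or broadcastable
    arrays).  Symmetric under permutation of the components; zero where
    all concentrations vanish.
    """
    comps = spec.components
    if len(concs) != len(comps):
        raise ValidationError(
            f"{len(comps)} components but {len(concs)} concentrations given"
        )
    xs = [np.atleast_1d(_as_conc(c)) / comp.odor.K for comp, c in zip(comps, concs)]
    scalar = all(np.asarray(c).ndim == 0 for c in concs)
    if len(xs) > 1:
        xs = np.broadcast_arrays(*xs)
    A = sum(c.odor.n * c.odor.eta * x for c, x in zip(comps, xs))
    B = sum(c.odor.eta * x for c, x in zip(comps, xs))
    C = sum(xs)
    out = np.zeros_like(np.asarray(B, dtype=float))
    pos = B > 0
    t = (A[pos] / B[pos]) * (np.log1p(C[pos]) - np.log(B[pos]))
    out[pos] = spec.cfg.f_max * expit(-t)
    return float(out[0]) if scalar else out


def ray_params(spec: MixtureSpec, name: str | None = None) -> OdorParams:
    """Effective single-odor parameters of the mixture along its ratio ray.

    The ray assigns component ``i`` the concentration ``weight_i * X``;
    the returned parameters describe the response as a sigmoid in X.
    """
    ws = np.array([c.weight * c.odor.s for c in spec.components])
    if not np.any(ws > 0):
        raise ValidationError("ray requires a positive weight")
    etas = np.array([c.odor.eta for c in spec.components])
    ns = np.array([c.odor.n for c in spec.components])
    s_eff = ws.sum()
    we = ws * etas
    eta_eff = we.sum() / s_eff
    n_eff = (we * ns).sum() / we.sum()
    return OdorParams(n=float(n_eff), eta=float(eta_eff), K=float(1.0 / s_eff), name=name)


def effective_fixed_ratio(
    U: OdorParams, V: OdorParams, r: float, cfg: GlobalConfig = GlobalConfig()
) -> EffectiveSigmoid:
    """Effective sigmoid of the binary mixture with U = r * V.

    The returned curve is a function of V's concentration: evaluating it
    at X reproduces ``mixture_response`` at ``(r*X, X)``.  ``r = 0``
    returns V's own parameters.
    """
    if not (math.isfinite(r) and r >= 0):
        raise DomainError("ratio r must be finite and >= 0")
    if r == 0:
        return EffectiveSigmoid(V.n, V.eta, V.K)
    p = ray_params(MixtureSpec.of(U, V, weights=[r, 1.0], cfg=cfg))
    return EffectiveSigmoid(p.n, p.eta, p.K)


def curve_summary(sig, cfg: GlobalConfig = GlobalConfig()) -> CurveSummary:
    """Asymptote, true midpoint and steepness index of a response curve.

    Accepts :class:`OdorParams`, :class:`EffectiveSigmoid`, or a classic
    Hill :class:`LegacyOdorParams` (rospars), for which the midpoint is K
    exactly.
    """
    if isinstance(sig, EffectiveSigmoid):
        sig = sig.to_params()
    if isinstance(sig, LegacyOdorParams):
        if sig.f_m is not None:
            return CurveSummary(asymptote=sig.f_m, midpoint=sig.K, steepness=sig.n)
        sig = OdorParams(n=sig.n, eta=sig.eta, K=sig.K)
    return CurveSummary(
        asymptote=asymptote(sig, cfg),
        midpoint=midpoint(sig, cfg),
        steepness=sig.n,
    )


def predict_same_dilution(
    U: OdorParams,
    V: OdorParams,
    protocol: ProtocolSpec,
    dilutions,
    cfg: GlobalConfig = GlobalConfig(),
) -> pd.DataFrame:
    """Predicted mixture curve under the same-dilution protocol.

    Each dilution d delivers concentrations ``d * M_U`` and ``d * M_V``
    where M are the saturated-vapor molarities.  Columns: dilution,
    conc_u, conc_v, concentration (total), response.  The abscissa
    convention (total concentration) is recorded in ``attrs``.
    """
    if protocol.mode != "same_dilution":
        raise ValidationError("protocol mode must be same_dilution")
    d = _as_conc(dilutions)
    d = np.atleast_1d(d)
    m_u, m_v = protocol.svp_molarity
    c_u, c_v = d * m_u, d * m_v
    resp = mixture_response(MixtureSpec.of(U, V, cfg=cfg), [c_u, c_v])
    out = pd.DataFrame(
        {
            "dilution": d,
            "conc_u": c_u,
            "conc_v": c_v,
            "concentration": c_u + c_v,
            "response": resp,
        }
    )
    out.attrs["abscissa"] = "total concentration (conc_u + conc_v)"
    out.attrs["protocol"] = "same_dilution"
    return out


def predict_fixed_background(
    U: OdorParams,
    V: OdorParams,
    background_conc: float,
    conc_grid,
    cfg: GlobalConfig = GlobalConfig(),
) -> pd.DataFrame:
    """Predicted mixture curve with V fixed at ``background_conc``.

    At zero background the curve equals U's single-odor response; at zero
    swept concentration it equals V's response to the background alone.
    """
    if not (math.isfinite(background_conc) and background_conc >= 0):
        raise ValidationError("background_conc must be finite and >= 0")
    c_u = np.atleast_1d(_as_conc(conc_grid))
    resp = mixture_response(
        MixtureSpec.of(U, V, cfg=cfg), [c_u, np.full_like(c_u, background_conc)]
    )
    out = pd.DataFrame(
        {"concentration": c_u, "conc_u": c_u, "conc_v": background_conc, "response": resp}
    )
    out.attrs["abscissa"] = "concentration of the swept odor"
    out.attrs["protocol"] = "fixed_background"
    return out


def synergy_feasible(
    U: OdorParams, V: OdorParams, conc: float, cfg: GlobalConfig = GlobalConfig()
) -> bool:
    """Whether synergy is possible at the given abscissa concentration.

    Under a fixed-ratio (same-dilution) paradigm with the curves compared
    on the shared total-concentration axis, the mixture can exceed both
    component curves only at concentrations at or above the half-asymptote
    midpoint of the component with the lower Hill coefficient.  Returns
    False below that bound.
    """
    if not (math.isfinite(conc) and conc >= 0):
        raise DomainError("conc must be finite and >= 0")
    low = U if U.n <= V.n else V
    return conc >= midpoint(low, cfg)
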