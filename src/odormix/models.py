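"""Single-odor dose-response models.

An olfactory sensory neuron (OSN) responds to a single odorant with a
sigmoidal function of concentration.  The classic description is a Hill
curve with a per-odor midpoint ``K`` and asymptote ``F_M`` and a Hill
coefficient ``n`` shared by all odors sensed by the neuron.  The model
implemented here instead makes the Hill coefficient a property of the
odor-receptor pair and bounds every response by a single physiological
maximum ``F_max`` shared across odors, with a per-odor efficacy ``eta``
setting where below ``F_max`` the curve saturates::

    F(c) = F_max / (1 + ((1 + c/K) / (eta * c/K))**n)

so the asymptote is ``F_max * eta**n / (1 + eta**n)`` and depends on both
the efficacy and the steepness.  Two legacy models are provided for
comparison: the shared-``n`` Hill extension with per-odor asymptotes
(``rospars``) and the shared-``n``, per-odor-efficacy form (``cruz_lowe``)
to which the present model reduces when the Hill coefficients of the odors
coincide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .errors import DomainError, ValidationError

__all__ = [
    "GlobalConfig",
    "OdorParams",
    "LegacyOdorParams",
    "single_response",
    "legacy_response",
    "legacy_mixture_response",
    "asymptote",
    "midpoint",
    "conc_at_fraction",
]


def _check_positive_finite(name: str, value: float) -> None:
    if not (math.isfinite(value) and value > 0):
        raise ValidationError(f"{name} must be positive and finite, got {value!r}")


@dataclass(frozen=True)
class GlobalConfig:
    """Analysis-wide settings.

    f_max is the maximal physiological response, shared by every odor in
    one analysis; the default 1.0 corresponds to normalized responses.
    """

    f_max: float = 1.0

    def __post_init__(self) -> None:
        _check_positive_finite("f_max", self.f_max)


@dataclass(frozen=True)
class OdorParams:
    """Response of one OSN type to one odor: the triple (n, eta, K).

    n
        Hill coefficient of the odor-receptor pair (dimensionless).
    eta
        Efficacy scalar setting the asymptote below ``f_max``
        (dimensionless).
    K
        Concentration scale, in the same units as the stimulus; the
        inverse scale ``s = 1/K`` is exposed as a property.
    """

    n: float
    eta: float
    K: float
    name: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        _check_positive_finite("n", self.n)
        _check_positive_finite("eta", self.eta)
        _check_positive_finite("K", self.K)

    @property
    def s(self) -> float:
        """Inverse concentration scale, s = 1/K."""
        return 1.0 / self.K

    @classmethod
    def from_triple(cls, n: float, eta: float, s: float, name: str | None = None) -> "OdorParams":
        """Build from the (n, eta, s) triple used in the odor-space algebra."""
        _check_positive_finite("s", s)
        return cls(n=n, eta=eta, K=1.0 / s, name=name)


@dataclass(frozen=True)
class LegacyOdorParams:
    """Parameters of the legacy shared-Hill-coefficient models.

    The ``rospars`` model carries a per-odor asymptote ``f_m``; the
    ``cruz_lowe`` model instead carries the efficacy ``eta`` and shares
    ``f_max`` across odors.
    """

    n: float
    K: float
    f_m: float | None = None
    eta: float | None = None
    name: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        _check_positive_finite("n", self.n)
        _check_positive_finite("K", self.K)
        if self.f_m is not None:
            _check_positive_finite("f_m", self.f_m)
        if self.eta is not None:
            _check_positive_finite("eta", self.eta)


def _as_conc(conc) -> np.ndarray:
    c = np.asarray(conc, dtype=float)
    if not np.all(np.isfinite(c)):
        raise ValidationError("concentrations must be finite")
    if np.any(c < 0):
        raise DomainError("concentrations must be non-negative")
    return c


def _core(x: np.ndarray, n: float, eta: float, f_max: float) -> np.ndarray:
    """Evaluate F = f_max * expit(-n*(log(1+x) - log(eta*x))) elementwise.

    Computed in log space so that large Hill coefficients (n ~ 20 appears
    in realistic parameter sets) cannot overflow.
    """
    out = np.zeros_like(x)
    pos = x > 0
    xp = x[pos]
    t = n * (np.log1p(xp) - np.log(eta) - np.log(xp))
    out[pos] = f_max * expit(-t)
    return out


def single_response(params: OdorParams, conc, cfg: GlobalConfig = GlobalConfig()):
    """Response of one OSN type to a single odor at concentration ``conc``.

    ``conc`` may be a scalar or an array; the result matches its shape.
    The response is 0 at zero concentration (by continuity for n < 1),
    strictly increasing, and bounded by ``f_max * eta**n / (1 + eta**n)``.
    """
    c = _as_conc(conc)
    scalar = c.ndim == 0
    out = _core(np.atleast_1d(c) / params.K, params.n, params.eta, cfg.f_max)
    return float(out[0]) if scalar else out


def asymptote(params, cfg: GlobalConfig = GlobalConfig()) -> float:
    """Limiting response at infinite concentration.

    For :class:`OdorParams` this is ``f_max * eta**n / (1 + eta**n)``; for
    a ``rospars`` :class:`LegacyOdorParams` it is ``f_m``; for a
    ``cruz_lowe`` one it is the same eta-form with the shared coefficient.
    """
    if isinstance(params, LegacyOdorParams):
        if params.f_m is not None:
            return params.f_m
        if params.eta is None:
            raise ValidationError("legacy parameters need f_m or eta")
        return cfg.f_max * expit(params.n * math.log(params.eta))
    return cfg.f_max * expit(params.n * math.log(params.eta))


def _log_eta_q(n: float, eta: float, frac: float) -> float:
    # log of (eta*q) where ((1+x)/(eta*x))**n = Q at response = frac*asymptote,
    # i.e. Q = (1 + (1-frac)/frac * eta**-n ... ) derived below.
    # F = frac * a with a = eta**n/(1+eta**n)  =>  1+Q = (1+eta**n)/(frac*eta**n)
    # => Q = (1 + (1-frac)*eta**n) / (frac*eta**n)
    # => eta*q = ((1 + (1-frac)*eta**n)/frac)**(1/n)
    L = n * math.log(eta)
    num = np.logaddexp(0.0, math.log1p(-frac) + L)  # log(1 + (1-frac)*eta**n)
    return (num - math.log(frac)) / n


def conc_at_fraction(params: OdorParams, frac: float, cfg: GlobalConfig = GlobalConfig()) -> float:
    """Concentration at which the response reaches ``frac`` of its own asymptote."""
    if not 0 < frac < 1:
        raise DomainError("frac must be in (0, 1)")
    return params.K / math.expm1(_log_eta_q(params.n, params.eta, frac))


def midpoint(params: OdorParams, cfg: GlobalConfig = GlobalConfig()) -> float:
    """Half-asymptote concentration of the single-odor curve.

    Note this is the curve's true midpoint, which differs from K except in
    the classic Hill limit.
    """
    return conc_at_fraction(params, 0.5, cfg)


def _legacy_terms(params: LegacyOdorParams, conc, model: str, cfg: GlobalConfig):
    c = _as_conc(conc)
    x = np.atleast_1d(c) / params.K
    return c, x


def legacy_response(
    params: LegacyOdorParams,
    conc,
    model: str,
    cfg: GlobalConfig = GlobalConfig(),
):
    """Single-odor response under one of the legacy models.

    model="rospars": classic Hill, ``f_m * x**n / (1 + x**n)``.
    model="cruz_lowe": shared f_max with efficacy eta; identical to
    :func:`single_response` with the same (n, eta, K).
    """
    if model == "rospars":
        if params.f_m is None:
            raise ValidationError("rospars model requires f_m")
        c, x = _legacy_terms(params, conc, model, cfg)
        out = np.zeros_like(x)
        pos = x > 0
        # x**n/(1+x**n) = expit(n*log(x))
        out[pos] = params.f_m * expit(params.n * np.log(x[pos]))
        return float(out[0]) if c.ndim == 0 else out
    if model == "cruz_lowe":
        if params.eta is None:
            raise ValidationError("cruz_lowe model requires eta")
        return single_response(
            OdorParams(n=params.n, eta=params.eta, K=params.K), conc, cfg
        )
    raise ValidationError(f"unknown legacy model {model!r}")


def legacy_mixture_response(
    components: list[LegacyOdorParams],
    concs,
    model: str,
    cfg: GlobalConfig = GlobalConfig(),
):
    """Binary (or N-ary) mixture response under a legacy model.

    rospars: ``sum(f_m_i x_i**n) / (1 + sum(x_i**n))`` with the shared n.
    cruz_lowe: ``f_max / (1 + ((1 + sum x_i)/(sum eta_i x_i))**n)``.

    Both models share one Hill coefficient across components; a mismatch
    raises a validation error.
    """
    if len(components) == 0:
        raise ValidationError("at least one component required")
    n = components[0].n
    if any(abs(p.n - n) > 1e-12 * n for p in components):
        raise ValidationError("legacy models require a shared Hill coefficient")
    concs = [_as_conc(c) for c in concs]
    if len(concs) != len(components):
        raise ValidationError("one concentration per component required")
    xs = [np.atleast_1d(c) / p.K for p, c in zip(components, concs)]
    xs = np.broadcast_arrays(*xs) if len(xs) > 1 else xs
    scalar = all(np.asarray(c).ndim == 0 for c in concs)
    if model == "rospars":
        if any(p.f_m is None for p in components):
            raise ValidationError("rospars model requires f_m for every component")
        num = sum(p.f_m * x**n for p, x in zip(components, xs))
        den = 1.0 + sum(x**n for x in xs)
        out = num / den
    elif model == "cruz_lowe":
        if any(p.eta is None for p in components):
            raise ValidationError("cruz_lowe model requires eta for every component")
        B = sum(p.eta * x for p, x in zip(components, xs))
        C = sum(xs)
        out = np.zeros_like(B)
        pos = B > 0
        t = n * (np.log1p(C[pos]) - np.log(B[pos]))
        out[pos] = cfg.f_max * expit(-t)
    else:
        raise ValidationError(f"unknown legacy model {model!r}")
    return float(out[0]) if scalar else out
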