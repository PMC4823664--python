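"""The 3-D odor-response-space algebra.

Every sigmoidal OSN response is identified by a triple ``(n, eta, s)``
(Hill coefficient, efficacy, inverse concentration scale ``s = 1/K``).
Two operations act on triples:

scaling
    ``alpha * (n, eta, s) = (n, eta, alpha*s)`` — the same odor delivered
    at ``alpha`` times the concentration;
composition
    ``(n, eta, s) . (n', eta', s')`` — the response to the mixture of the
    two odors, with the weighted-mean parameters of the fixed-ratio
    reduction.

The map ``(n, eta, s) -> (n*eta*s, eta*s, s)`` turns composition into
vector addition and scaling into scalar multiplication, embedding the
odor response space into the positive octant of R^3.  Consequently any
response inside the convex region spanned by three independent responses
("primary responses") is a positive combination of them, with
coefficients given by a linear solve; responses outside that region
cannot be obtained.  Four corner responses of a bounded ``(n, eta)``
rectangle yield two bases whose coverage regions together tile the whole
rectangle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, NotRepresentableError, ValidationError
from .models import OdorParams

__all__ = [
    "ResponseTriple",
    "EmbeddedVector",
    "Basis",
    "Decomposition",
    "HullRegion",
    "scale",
    "compose",
    "embed",
    "unembed",
    "is_valid_basis",
    "decompose",
    "recompose",
    "hull_coverage",
    "canonical_bases",
    "synthesize_target",
]

_DET_TOL = 1e-12
_POS_TOL = -1e-12


def _pos(name, v):
    if not (math.isfinite(v) and v > 0):
        raise ValidationError(f"{name} must be positive and finite, got {v!r}")


@dataclass(frozen=True)
class ResponseTriple:
    """The (n, eta, s) identification of one sigmoidal response."""

    n: float
    eta: float
    s: float

    def __post_init__(self):
        _pos("n", self.n)
        _pos("eta", self.eta)
        _pos("s", self.s)

    @classmethod
    def from_params(cls, p: OdorParams) -> "ResponseTriple":
        return cls(n=p.n, eta=p.eta, s=p.s)

    def to_params(self, name: str | None = None) -> OdorParams:
        return OdorParams(n=self.n, eta=self.eta, K=1.0 / self.s, name=name)


@dataclass(frozen=True)
class EmbeddedVector:
    """Image (n*eta*s, eta*s, s) of a response triple in R^3."""

    x1: float
    x2: float
    x3: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x1, self.x2, self.x3], dtype=float)


@dataclass(frozen=True)
class Basis:
    """Three embedded vectors and their independence flag."""

    e1: EmbeddedVector
    e2: EmbeddedVector
    e3: EmbeddedVector

    @property
    def matrix(self) -> np.ndarray:
        return np.column_stack([self.e1.as_array(), self.e2.as_array(), self.e3.as_array()])

    @property
    def valid(self) -> bool:
        return is_valid_basis(self.e1, self.e2, self.e3)


@dataclass(frozen=True)
class Decomposition:
    """Positive scalars expressing a target in a basis."""

    alpha1: float
    alpha2: float
    alpha3: float
    clamped: tuple[bool, bool, bool] = (False, False, False)

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha1, self.alpha2, self.alpha3], dtype=float)


@dataclass(frozen=True)
class HullRegion:
    """Rectangular (n, eta) bounds of the experimental odor-response space."""

    n_min: float
    n_max: float
    eta_min: float
    eta_max: float

    def __post_init__(self):
        for nm in ("n_min", "n_max", "eta_min", "eta_max"):
            _pos(nm, getattr(self, nm))
        if not (self.n_min < self.n_max and self.eta_min < self.eta_max):
            raise ValidationError("bounds must satisfy n_min < n_max and eta_min < eta_max")

    def contains(self, n: float, eta: float) -> bool:
        return self.n_min <= n <= self.n_max and self.eta_min <= eta <= self.eta_max


def scale(t: ResponseTriple, alpha: float) -> ResponseTriple:
    """The response of odor ``t`` observed at ``alpha`` times the concentration."""
    if not (math.isfinite(alpha) and alpha > 0):
        raise DomainError("alpha must be positive and finite")
    return ResponseTriple(n=t.n, eta=t.eta, s=alpha * t.s)


def compose(t1: ResponseTriple, t2: ResponseTriple) -> ResponseTriple:
    """The response to the equal-concentration mixture of two odors.

    Commutative; ``compose(t, t)`` equals ``scale(t, 2)`` (self-mixture).
    """
    w1, w2 = t1.eta * t1.s, t2.eta * t2.s
    s = t1.s + t2.s
    return ResponseTriple(
        n=(t1.n * w1 + t2.n * w2) / (w1 + w2),
        eta=(w1 + w2) / s,
        s=s,
    )


def embed(t: ResponseTriple) -> EmbeddedVector:
    """Map (n, eta, s) -> (n*eta*s, eta*s, s)."""
    return EmbeddedVector(t.n * t.eta * t.s, t.eta * t.s, t.s)


def unembed(v: EmbeddedVector) -> ResponseTriple:
    """Inverse map; requires strictly positive coordinates."""
    if not all(math.isfinite(x) and x > 0 for x in (v.x1, v.x2, v.x3)):
        raise DomainError("embedded coordinates must be positive and finite")
    return ResponseTriple(n=v.x1 / v.x2, eta=v.x2 / v.x3, s=v.x3)


def is_valid_basis(e1: EmbeddedVector, e2: EmbeddedVector, e3: EmbeddedVector) -> bool:
    """Linear independence of three embedded vectors.

    The determinant is compared against a tolerance scaled by the matrix
    magnitude so that near-degenerate vertex choices are rejected.
    """
    m = np.column_stack([e1.as_array(), e2.as_array(), e3.as_array()])
    scale_ = np.prod([max(np.abs(m[:, j]).max(), 1e-300) for j in range(3)])
    return bool(abs(np.linalg.det(m)) > _DET_TOL * scale_)


def _solve_coeffs(basis: Basis, v: np.ndarray) -> np.ndarray:
    if not basis.valid:
        raise ValidationError("basis vectors are not linearly independent")
    return np.linalg.solve(basis.matrix, v)


def decompose(target: ResponseTriple, basis: Basis) -> Decomposition:
    """Express a target response in a basis of three primary responses.

    The coefficients solve the 3x3 linear system in the embedded
    coordinates and must be positive for the target to be physically
    obtainable; coefficients more negative than a small floating-point
    guard raise :class:`NotRepresentableError`, tiny negatives are
    clamped to zero and flagged.
    """
    alpha = _solve_coeffs(basis, embed(target).as_array())
    if np.any(alpha < _POS_TOL * max(1.0, float(np.abs(alpha).max()))):
        raise NotRepresentableError(
            "target lies outside the region generated by the basis",
            coefficients=tuple(float(a) for a in alpha),
        )
    clamped = tuple(bool(a < 0) for a in alpha)
    alpha = np.maximum(alpha, 0.0)
    return Decomposition(float(alpha[0]), float(alpha[1]), float(alpha[2]), clamped)


def recompose(basis: Basis, dec: Decomposition) -> ResponseTriple:
    """Rebuild the response triple from basis and coefficients."""
    v = basis.matrix @ dec.as_array()
    return unembed(EmbeddedVector(*v))


def hull_coverage(vertices, n: float, eta: float, tol: float = 1e-9) -> bool:
    """Whether the (n, eta) pair lies in the region generated by ``vertices``.

    ``vertices`` is a sequence of :class:`ResponseTriple` (or a
    :class:`Basis`).  Because scaling is free, coverage in the (n, eta)
    plane reduces to the existence of non-negative weights ``beta`` with
    ``sum(beta) = 1`` matching the image point ``(n*eta, eta)`` under the
    per-vertex map ``(n_i, eta_i) -> (n_i*eta_i, eta_i)``; for more than
    three vertices the convex-membership test is solved as a small linear
    program.
    """
    _pos("n", n)
    _pos("eta", eta)
    if isinstance(vertices, Basis):
        cols = vertices.matrix
    else:
        cols = np.column_stack([embed(t).as_array() for t in vertices])
    # normalize each vertex so its third coordinate is 1 (scaling freedom)
    cols = cols / cols[2]
    target = np.array([n * eta, eta, 1.0])
    k = cols.shape[1]
    if k == 3:
        try:
            beta = np.linalg.solve(cols, target)
        except np.linalg.LinAlgError:
            return False
        return bool(np.all(beta >= -tol))
    from scipy.optimize import linprog

    res = linprog(
        c=np.zeros(k), A_eq=cols, b_eq=target, bounds=[(0, None)] * k, method="highs"
    )
    return bool(res.success)


def canonical_bases(bounds: HullRegion, s: float = 1e6) -> tuple[Basis, Basis]:
    """The two corner-vector bases covering the bounded (n, eta) rectangle.

    The four corner responses of the rectangle (all at a common inverse
    scale ``s``) are linearly independent three at a time; the two triples
    sharing the (n_min, eta_min)-(n_max, eta_max) diagonal have coverage
    regions that tile the rectangle exactly along the curved image of
    that diagonal, so their union covers every in-bounds (n, eta) while
    neither does alone.
    """
    _pos("s", s)
    n0, n1 = bounds.n_min, bounds.n_max
    h0, h1 = bounds.eta_min, bounds.eta_max
    c_ll = embed(ResponseTriple(n0, h0, s))
    c_lr = embed(ResponseTriple(n1, h0, s))
    c_ur = embed(ResponseTriple(n1, h1, s))
    c_ul = embed(ResponseTriple(n0, h1, s))
    return Basis(c_ll, c_lr, c_ur), Basis(c_ll, c_ur, c_ul)


def synthesize_target(targets, available, tol: float = 1e-6):
    """Concentrations of available odors reproducing per-OSN target responses.

    ``targets`` is a sequence of :class:`ResponseTriple`, one per OSN
    type; ``available`` is a sequence (per OSN) of sequences of
    :class:`ResponseTriple` describing how each candidate odor drives
    that OSN.  Every OSN must see the same number of candidate odors; the
    returned coefficients (mixture concentration multipliers, shared
    across OSN types because a single physical mixture is delivered)
    solve the stacked linear system in embedded coordinates by least
    squares.  Raises :class:`NotRepresentableError`, identifying the
    worst-matched OSN, if no positive solution reproduces every target
    within ``tol`` (relative residual).
    """
    targets = list(targets)
    available = [list(a) for a in available]
    if len(targets) != len(available) or not targets:
        raise ValidationError("one list of available odor responses per OSN target required")
    k = len(available[0])
    if any(len(a) != k for a in available):
        raise ValidationError("every OSN must see the same odors")
    A = np.vstack([
        np.column_stack([embed(t).as_array() for t in avail]) for avail in available
    ])
    b = np.concatenate([embed(t).as_array() for t in targets])
    coeffs, *_ = np.linalg.lstsq(A, b, rcond=None)
    resid = A @ coeffs - b
    per_osn = np.linalg.norm(resid.reshape(len(targets), 3), axis=1) / np.maximum(
        np.linalg.norm(b.reshape(len(targets), 3), axis=1), 1e-300
    )
    worst = int(np.argmax(per_osn))
    if np.any(coeffs < _POS_TOL * max(1.0, float(np.abs(coeffs).max()))) or per_osn[worst] > tol:
        raise NotRepresentableError(
            "targets cannot be reproduced by a positive mixture of the available odors",
            coefficients=tuple(float(c) for c in coeffs),
            osn=worst,
        )
    return np.maximum(coeffs, 0.0)
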