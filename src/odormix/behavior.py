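"""Classification of mixture curves into the five empirical behaviors.

A binary mixture curve is compared with the two single-odor curves on a
shared concentration axis.  The mixture point at abscissa ``c`` contains
component concentrations ``(r/(1+r))*c`` and ``(1/(1+r))*c`` (the total
mixture concentration equals the abscissa), and each single-odor curve is
evaluated at ``c`` itself.  The five behaviors:

suppression
    the mixture lies strictly between the two components;
hypoadditivity
    the mixture is similar to the most effective component;
synergy
    the mixture exceeds both components;
inhibition
    the mixture falls below both components;
overshadowing
    the mixture is similar to one component that is not the most
    effective one.

"Similar" means within a configurable band (default 5% of F_max).  Note
that hypoadditivity is formally the special case of overshadowing in
which the tracked component dominates; the classifier separates the two
by checking whether the matched component is the more effective one over
the classified region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .mixtures import MixtureSpec, ray_params
from .models import GlobalConfig, OdorParams, asymptote, conc_at_fraction, single_response

__all__ = [
    "LABELS",
    "BehaviorLabel",
    "PhaseMap",
    "classify_region",
    "classify_full_curve",
    "classify_asymptotic",
    "asymptotic_region",
    "default_grid",
    "mixture_curves",
    "phase_map",
]

LABELS = ("suppression", "hypoadditivity", "synergy", "inhibition", "overshadowing")

_SIM_U, _SIM_V = "_similar_u", "_similar_v"


@dataclass(frozen=True)
class BehaviorLabel:
    """One behavior holding over a concentration interval [lo, hi]."""

    label: str
    lo: float
    hi: float


@dataclass(frozen=True)
class PhaseMap:
    """Grid of asymptotic behavior labels over two swept parameters."""

    param1: str
    param2: str
    table: pd.DataFrame  # long format: param1, param2, label

    def counts(self) -> dict[str, int]:
        return self.table["label"].value_counts().to_dict()

    def modal_label(self) -> str:
        return self.table["label"].value_counts().idxmax()


def _raw_labels(f_u, f_v, f_mix, tol: float) -> list[str]:
    labels = []
    for u, v, m in zip(f_u, f_v, f_mix):
        du, dv = abs(m - u), abs(m - v)
        if min(du, dv) <= tol:
            labels.append(_SIM_U if du <= dv else _SIM_V)
        elif m > max(u, v):
            labels.append("synergy")
        elif m < min(u, v):
            labels.append("inhibition")
        else:
            labels.append("suppression")
    return labels


def _resolve_runs(labels, f_u, f_v):
    """Turn similarity placeholders into hypoadditivity/overshadowing per run."""
    out = list(labels)
    i = 0
    n = len(labels)
    while i < n:
        if labels[i] not in (_SIM_U, _SIM_V):
            i += 1
            continue
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        matched_u = labels[i] == _SIM_U
        dominant_u = float(np.mean(f_u[i:j])) >= float(np.mean(f_v[i:j]))
        lab = "hypoadditivity" if matched_u == dominant_u else "overshadowing"
        out[i:j] = [lab] * (j - i)
        i = j
    return out


def classify_region(f_u, f_v, f_mix, tol: float = 0.05, cfg: GlobalConfig = GlobalConfig()) -> str:
    """Label one concentration region from the three curves sampled on it.

    The pointwise relations are aggregated over the region; with mixed
    relations the plurality label wins (ties break toward the label
    encountered first).  ``tol`` is the similarity band as a fraction of
    ``f_max``.
    """
    f_u, f_v, f_mix = (np.atleast_1d(np.asarray(a, float)) for a in (f_u, f_v, f_mix))
    if not (len(f_u) == len(f_v) == len(f_mix)) or len(f_u) == 0:
        raise ValidationError("the three curves must share a non-empty grid")
    labels = _resolve_runs(_raw_labels(f_u, f_v, f_mix, tol * cfg.f_max), f_u, f_v)
    counts: dict[str, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    return max(counts, key=lambda k: (counts[k], -labels.index(k)))


def classify_full_curve(
    f_u, f_v, f_mix, grid, tol: float = 0.05, cfg: GlobalConfig = GlobalConfig()
) -> list[BehaviorLabel]:
    """Partition the analyzed range into maximal single-behavior regions."""
    f_u, f_v, f_mix, grid = (np.atleast_1d(np.asarray(a, float)) for a in (f_u, f_v, f_mix, grid))
    if not (len(f_u) == len(f_v) == len(f_mix) == len(grid)) or len(grid) == 0:
        raise ValidationError("curves and grid must share a non-empty length")
    labels = _resolve_runs(_raw_labels(f_u, f_v, f_mix, tol * cfg.f_max), f_u, f_v)
    regions = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            regions.append(BehaviorLabel(labels[start], float(grid[start]), float(grid[i - 1])))
            start = i
    return regions


def mixture_curves(
    U: OdorParams,
    V: OdorParams,
    r: float,
    grid,
    cfg: GlobalConfig = GlobalConfig(),
):
    """Evaluate F_U, F_V and the mixture on the shared total-concentration axis.

    At abscissa c the mixture holds (r/(1+r))*c of U and (1/(1+r))*c of V.
    """
    grid = np.atleast_1d(np.asarray(grid, float))
    spec = MixtureSpec.of(U, V, weights=[r / (1.0 + r), 1.0 / (1.0 + r)], cfg=cfg)
    f_mix = single_response(ray_params(spec), grid, cfg)
    return single_response(U, grid, cfg), single_response(V, grid, cfg), f_mix


def default_grid(U: OdorParams, V: OdorParams, r: float, num: int = 200,
                 cfg: GlobalConfig = GlobalConfig()) -> np.ndarray:
    """200 log-spaced points spanning 3 decades around the component midpoints."""
    from .models import midpoint

    mids = [midpoint(U, cfg), midpoint(V, cfg)]
    spec = MixtureSpec.of(U, V, weights=[r / (1.0 + r), 1.0 / (1.0 + r)], cfg=cfg)
    mids.append(midpoint(ray_params(spec), cfg))
    lo, hi = min(mids), max(mids)
    return np.logspace(math.log10(lo) - 1.5, math.log10(hi) + 1.5, num)


def asymptotic_region(
    U: OdorParams, V: OdorParams, r: float, num: int = 50,
    frac: float = 0.95, cfg: GlobalConfig = GlobalConfig()
) -> np.ndarray:
    """Grid of concentrations where all three curves exceed ``frac`` of their asymptotes."""
    spec = MixtureSpec.of(U, V, weights=[r / (1.0 + r), 1.0 / (1.0 + r)], cfg=cfg)
    c0 = max(
        conc_at_fraction(U, frac, cfg),
        conc_at_fraction(V, frac, cfg),
        conc_at_fraction(ray_params(spec), frac, cfg),
    )
    return np.logspace(math.log10(c0), math.log10(c0) + 2.0, num)


def classify_asymptotic(
    U: OdorParams, V: OdorParams, r: float, tol: float = 0.05,
    cfg: GlobalConfig = GlobalConfig()
) -> str:
    """Behavior label in the region close to the asymptotic values."""
    grid = asymptotic_region(U, V, r, cfg=cfg)
    f_u, f_v, f_mix = mixture_curves(U, V, r, grid, cfg)
    return classify_region(f_u, f_v, f_mix, tol=tol, cfg=cfg)


def phase_map(
    sweep: dict,
    fixed: dict,
    tol: float = 0.0,
    cfg: GlobalConfig = GlobalConfig(),
) -> PhaseMap:
    """Asymptotic behavior label over a two-parameter grid.

    ``sweep`` maps exactly two parameter names (of ``n_u``, ``n_v``,
    ``eta_u``, ``eta_v``, ``K_u``, ``K_v``, ``r``) to 1-D grids; ``fixed``
    supplies the remaining values.  Cells are classified from the
    analytic asymptotes of the three curves; the default zero tolerance
    yields the strict three-way suppression/synergy/inhibition partition,
    while a positive band adds the similarity labels.
    """
    if len(sweep) != 2:
        raise ValidationError("sweep must contain exactly two parameters")
    (p1, g1), (p2, g2) = sweep.items()
    g1 = np.atleast_1d(np.asarray(g1, float))
    g2 = np.atleast_1d(np.asarray(g2, float))
    if np.any(~np.isfinite(g1)) or np.any(~np.isfinite(g2)) or np.any(g1 <= 0) or np.any(g2 <= 0):
        raise ValidationError("sweep grids must be positive and finite")
    rows = []
    for v1 in g1:
        for v2 in g2:
            p = dict(fixed)
            p[p1], p[p2] = float(v1), float(v2)
            U = OdorParams(n=p["n_u"], eta=p["eta_u"], K=p["K_u"])
            V = OdorParams(n=p["n_v"], eta=p["eta_v"], K=p["K_v"])
            r = p.get("r", 1.0)
            a_u, a_v = asymptote(U, cfg), asymptote(V, cfg)
            spec = MixtureSpec.of(U, V, weights=[r / (1.0 + r), 1.0 / (1.0 + r)], cfg=cfg)
            a_m = asymptote(ray_params(spec), cfg)
            lab = classify_region([a_u], [a_v], [a_m], tol=tol, cfg=cfg)
            rows.append((float(v1), float(v2), lab))
    table = pd.DataFrame(rows, columns=[p1, p2, "label"])
    return PhaseMap(param1=p1, param2=p2, table=table)
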