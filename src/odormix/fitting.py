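"""Fitting the single-odor model to dose-response data, and fit metrics.

``fit_single_odor`` estimates (n, eta, K) by bounded nonlinear least
squares with a deterministic multistart over a coarse logarithmic grid of
initial guesses, keeping ``F_max`` fixed at the configured value.  The
default residuals are taken on the logarithm of the response (relative
error), the matched objective when measurement noise scales with the
response, as firing-rate variability does; absolute residuals are
available through ``loss="absolute"``.

Goodness of fit is reported as the mean squared error (MSE) and the mean
absolute percentage error (MAPE, in percent, zero-response observations
excluded).  ``predict_mixture_from_fits`` turns two single-odor fits into
a pure mixture prediction — no mixture observation enters — and
``fit_shift``/``apply_log_shift`` implement the log-concentration
correction used when the delivered mixture concentration may differ from
the nominal one.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize_scalar

from .errors import FitError, ValidationError
from .mixtures import ProtocolSpec, predict_fixed_background, predict_same_dilution
from .models import GlobalConfig, OdorParams, single_response

__all__ = [
    "FitResult",
    "ShiftCorrection",
    "make_table",
    "validate_table",
    "fit_single_odor",
    "mse",
    "mape",
    "predict_mixture_from_fits",
    "apply_log_shift",
    "fit_shift",
]


@dataclass(frozen=True)
class FitResult:
    """Outcome of a single-odor fit."""

    params: OdorParams
    mse: float
    mape: float
    converged: bool
    bounds_hit: tuple[bool, bool, bool]
    cost: float


@dataclass(frozen=True)
class ShiftCorrection:
    """A signed shift in log10 concentration applied to a curve's abscissa."""

    delta: float

    def __post_init__(self):
        if not math.isfinite(self.delta):
            raise ValidationError("delta must be finite")


def make_table(concentration, response, odor: str | None = None, units: str = "linear") -> pd.DataFrame:
    """Assemble a dose-response table (the package-wide tabular convention)."""
    df = pd.DataFrame({"concentration": np.asarray(concentration, float),
                       "response": np.asarray(response, float)})
    df.attrs["odor"] = odor
    df.attrs["units"] = units
    return df


def validate_table(data: pd.DataFrame, min_points: int = 3) -> pd.DataFrame:
    if not {"concentration", "response"} <= set(data.columns):
        raise ValidationError("table must have 'concentration' and 'response' columns")
    df = data
    if df.attrs.get("units", "linear") == "log10":
        df = df.copy()
        df["concentration"] = 10.0 ** df["concentration"]
        df.attrs["units"] = "linear"
    c = df["concentration"].to_numpy(float)
    if np.any(~np.isfinite(c)) or np.any(c < 0):
        raise ValidationError("concentrations must be finite and non-negative")
    if len(df) < min_points:
        raise ValidationError(f"at least {min_points} observations required")
    return df


def _start_grid(conc: np.ndarray, n_starts: int, seed: int):
    grid = [
        (n0, e0, k0)
        for n0 in (0.5, 1.5, 4.0, 12.0)
        for e0 in (0.3, 1.0, 3.0)
        for k0 in (conc.min() * 3.0, float(np.median(conc)), conc.max() / 3.0)
    ]
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(grid))[: max(1, n_starts)]
    return [grid[i] for i in idx]


def fit_single_odor(
    data: pd.DataFrame,
    cfg: GlobalConfig = GlobalConfig(),
    loss: str = "relative",
    n_starts: int = 20,
    seed: int = 0,
    bounds: dict | None = None,
) -> FitResult:
    """Least-squares estimate of (n, eta, K) from one dose-response table.

    Deterministic for fixed data, options and seed.  Default parameter
    bounds: n in [0.1, 30], eta in [1e-3, 1e3], K within two decades of
    the sampled concentration range.
    """
    df = validate_table(data)
    conc = df["concentration"].to_numpy(float)
    resp = df["response"].to_numpy(float)
    if np.any(resp < 0) or np.any(resp > cfg.f_max + 1e-12):
        raise ValidationError("responses must lie in [0, f_max]")
    keep = conc > 0
    if loss == "relative":
        keep &= resp > 0
    conc_f, resp_f = conc[keep], resp[keep]
    if len(conc_f) < 3 or np.all(resp_f <= 0):
        raise FitError("degenerate data: fewer than 3 usable positive observations",
                       {"n_usable": int(len(conc_f))})
    b = {"n": (0.1, 30.0), "eta": (1e-3, 1e3),
         "K": (conc_f.min() / 100.0, conc_f.max() * 100.0)}
    if bounds:
        b.update(bounds)
    lo = np.log([b["n"][0], b["eta"][0], b["K"][0]])
    hi = np.log([b["n"][1], b["eta"][1], b["K"][1]])

    if loss == "relative":
        log_r = np.log(resp_f)

        def residuals(p):
            f = single_response(OdorParams(*np.exp(p)), conc_f, cfg)
            return np.log(np.maximum(f, 1e-300)) - log_r

    elif loss == "absolute":

        def residuals(p):
            return single_response(OdorParams(*np.exp(p)), conc_f, cfg) - resp_f

    else:
        raise ValidationError(f"unknown loss {loss!r}")

    best = None
    for start in _start_grid(conc_f, n_starts, seed):
        x0 = np.clip(np.log(start), lo, hi)
        try:
            res = least_squares(residuals, x0, bounds=(lo, hi), method="trf",
                                xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise FitError("no multistart converged", {"n_starts": n_starts})
    p = np.exp(best.x)
    params = OdorParams(n=float(p[0]), eta=float(p[1]), K=float(p[2]),
                        name=df.attrs.get("odor"))
    pred = single_response(params, conc, cfg)
    hit = tuple(bool(best.x[i] - lo[i] < 1e-8 or hi[i] - best.x[i] < 1e-8) for i in range(3))
    return FitResult(params=params, mse=mse(resp, pred), mape=mape(resp, pred),
                     converged=True, bounds_hit=hit, cost=float(best.cost))


def mse(obs, pred) -> float:
    """Mean squared error between observed and predicted responses."""
    obs = np.asarray(obs, float)
    pred = np.asarray(pred, float)
    if obs.shape != pred.shape:
        raise ValidationError("obs and pred must have equal length")
    return float(np.mean((obs - pred) ** 2))


def mape(obs, pred, zero_policy: str = "exclude") -> float:
    """Mean absolute percentage error, in percent.

    Zero observations make the percentage undefined; by default they are
    excluded with a warning (``zero_policy="error"`` raises instead).
    """
    obs = np.asarray(obs, float)
    pred = np.asarray(pred, float)
    if obs.shape != pred.shape:
        raise ValidationError("obs and pred must have equal length")
    nz = obs != 0
    if not np.all(nz):
        if zero_policy == "error":
            raise ValidationError("zero observations make MAPE undefined")
        warnings.warn("zero-response observations excluded from MAPE", stacklevel=2)
    if not np.any(nz):
        raise ValidationError("MAPE needs at least one nonzero observation")
    return float(np.mean(np.abs((obs[nz] - pred[nz]) / obs[nz]))) * 100.0


def predict_mixture_from_fits(
    fit_u: FitResult,
    fit_v: FitResult,
    protocol: ProtocolSpec,
    grid,
    cfg: GlobalConfig = GlobalConfig(),
) -> pd.DataFrame:
    """Mixture prediction from two single-odor fits under a protocol.

    ``grid`` is the dilution grid (same_dilution) or the swept odor's
    concentration grid (fixed_background).  Only the fitted single-odor
    parameters enter the prediction.
    """
    if not (fit_u.converged and fit_v.converged):
        raise ValidationError("both fits must have converged")
    if protocol.mode == "same_dilution":
        return predict_same_dilution(fit_u.params, fit_v.params, protocol, grid, cfg)
    return predict_fixed_background(fit_u.params, fit_v.params,
                                    protocol.background_conc, grid, cfg)


def apply_log_shift(curve: pd.DataFrame, delta) -> pd.DataFrame:
    """Multiply the concentration axis by 10**delta, leaving responses untouched."""
    d = delta.delta if isinstance(delta, ShiftCorrection) else float(delta)
    if not math.isfinite(d):
        raise ValidationError("delta must be finite")
    out = curve.copy()
    for col in ("concentration", "conc_u", "conc_v"):
        if col in out.columns:
            out[col] = out[col] * 10.0**d
    out.attrs = dict(curve.attrs)
    out.attrs["log10_shift"] = out.attrs.get("log10_shift", 0.0) + d
    return out


def fit_shift(
    data_mix: pd.DataFrame,
    predicted: pd.DataFrame,
    delta_bounds: tuple[float, float] = (-1.0, 1.0),
) -> ShiftCorrection:
    """Log-concentration shift of the prediction minimizing the MSE to data.

    The predicted curve is interpolated (linearly in log10 concentration)
    onto the shifted positions of the mixture observations; the shift is
    located by a coarse scan refined with a bounded scalar minimization.
    Raises if no admissible shift leaves at least three observations
    inside the predicted concentration range.
    """
    dm = validate_table(data_mix)
    pr = validate_table(predicted)
    cd = dm["concentration"].to_numpy(float)
    rd = dm["response"].to_numpy(float)
    cp = pr["concentration"].to_numpy(float)
    rp = pr["response"].to_numpy(float)
    pos = cd > 0
    cd, rd = cd[pos], rd[pos]
    order = np.argsort(cp)
    lcp, rp = np.log10(cp[order]), rp[order]
    lcd = np.log10(cd)

    def objective(d):
        # value of the d-shifted prediction at a data abscissa L is the
        # original prediction at L - d
        inside = (lcd >= lcp[0] + d) & (lcd <= lcp[-1] + d)
        if inside.sum() < 3:
            return np.inf
        pred = np.interp(lcd[inside] - d, lcp, rp)
        return float(np.mean((pred - rd[inside]) ** 2))

    deltas = np.linspace(delta_bounds[0], delta_bounds[1], 201)
    vals = np.array([objective(d) for d in deltas])
    if not np.any(np.isfinite(vals)):
        raise ValidationError("no overlap between data and prediction for any admissible shift")
    i = int(np.argmin(vals))
    lo = deltas[max(i - 1, 0)]
    hi = deltas[min(i + 1, len(deltas) - 1)]
    res = minimize_scalar(objective, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    d_best = float(res.x) if res.fun <= vals[i] else float(deltas[i])
    return ShiftCorrection(delta=d_best)
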