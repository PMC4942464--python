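"""Hill-equation evaluation and nonlinear least-squares fitting.

The sigmoid ``theta(L) = L**h / (K**h + L**h)`` maps ligand concentration
``L`` (molar) to the fraction of activated receptors. Fitting optionally
adds a constant offset ``beta`` and reports 95% confidence intervals from
the linearized covariance at the optimum, scaled by a Student-t quantile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import (
    DataError,
    FitFailureError,
    InvalidParameterError,
    UndefinedRSquaredError,
)

__all__ = [
    "DoseResponsePoint",
    "HillFit",
    "hill_response",
    "hill_response_offset",
    "fit_hill",
    "r_squared",
    "LOG10_K_BOUNDS",
    "HILL_COEFF_BOUNDS",
    "OFFSET_BOUNDS",
]

# Parameter bounds span every catalog value with ample margin.
LOG10_K_BOUNDS = (-12.0, -1.0)
HILL_COEFF_BOUNDS = (0.1, 10.0)
OFFSET_BOUNDS = (-1.0, 2.0)

_LN10 = math.log(10.0)


@dataclass(frozen=True)
class DoseResponsePoint:
    """One (concentration, response) observation, optionally with dispersion."""

    concentration: float
    response: float
    dispersion: Optional[float] = None
    n: Optional[int] = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.concentration) or self.concentration < 0:
            raise DataError(
                f"concentration must be finite and >= 0, got {self.concentration!r}"
            )
        if not np.isfinite(self.response):
            raise DataError(f"response must be finite, got {self.response!r}")
        if self.dispersion is not None and self.dispersion < 0:
            raise DataError(f"dispersion must be >= 0, got {self.dispersion!r}")


@dataclass(frozen=True)
class HillFit:
    """Result of a Hill fit: parameters, 95% CI half-widths, diagnostics."""

    k_half: float
    hill_coeff: float
    offset: Optional[float]
    ci_k_half: float
    ci_hill_coeff: float
    ci_offset: Optional[float]
    r_squared: float
    n_points: int
    converged: bool = True

    def __post_init__(self) -> None:
        if self.k_half <= 0:
            raise InvalidParameterError(f"k_half must be > 0, got {self.k_half!r}")
        if self.hill_coeff <= 0:
            raise InvalidParameterError(
                f"hill_coeff must be > 0, got {self.hill_coeff!r}"
            )
        if np.isfinite(self.r_squared) and self.r_squared > 1 + 1e-12:
            raise InvalidParameterError(f"r_squared must be <= 1, got {self.r_squared!r}")
        for name in ("ci_k_half", "ci_hill_coeff", "ci_offset"):
            v = getattr(self, name)
            if v is not None and np.isfinite(v) and v < 0:
                raise InvalidParameterError(f"{name} must be >= 0, got {v!r}")

    def predict(self, concentration):
        beta = 0.0 if self.offset is None else self.offset
        return hill_response(concentration, self.k_half, self.hill_coeff) + beta

    def to_dict(self) -> dict:
        d = {
            "k_half": self.k_half,
            "hill_coeff": self.hill_coeff,
            "ci": {"k_half": self.ci_k_half, "hill_coeff": self.ci_hill_coeff},
            "r_squared": self.r_squared,
            "n_points": self.n_points,
            "converged": self.converged,
        }
        if self.offset is not None:
            d["offset"] = self.offset
            d["ci"]["offset"] = self.ci_offset
        return d


def _check_params(k_half: float, hill_coeff: float) -> None:
    if not (np.isfinite(k_half) and k_half > 0):
        raise InvalidParameterError(f"k_half must be finite and > 0, got {k_half!r}")
    if not (np.isfinite(hill_coeff) and hill_coeff > 0):
        raise InvalidParameterError(
            f"hill_coeff must be finite and > 0, got {hill_coeff!r}"
        )


def hill_response(concentration, k_half: float, hill_coeff: float):
    """Fraction of activated receptors at ligand concentration ``L``.

    Returns ``L**h / (K**h + L**h)``, evaluated as ``1/(1 + (K/L)**h)`` for
    numerical stability across many decades; 0 at L = 0. Accepts scalars or
    arrays and broadcasts like numpy.
    """
    _check_params(k_half, hill_coeff)
    L = np.asarray(concentration, dtype=float)
    if np.any(~np.isfinite(L) | (L < 0)):
        raise DataError("concentrations must be finite and >= 0")
    out = np.zeros_like(L)
    pos = L > 0
    out[pos] = 1.0 / (1.0 + (k_half / L[pos]) ** hill_coeff)
    if np.isscalar(concentration) or np.ndim(concentration) == 0:
        return float(out)
    return out


def hill_response_offset(concentration, k_half: float, hill_coeff: float, offset: float):
    """Hill response shifted up by a constant offset ``beta``."""
    if not np.isfinite(offset):
        raise InvalidParameterError(f"offset must be finite, got {offset!r}")
    return hill_response(concentration, k_half, hill_coeff) + offset


def r_squared(observed, predicted) -> float:
    """Coefficient of determination, ``1 - SSres/SStot``.

    Raises :class:`UndefinedRSquaredError` when the observed series has zero
    variance (SStot = 0).
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise DataError(f"shape mismatch: {obs.shape} vs {pred.shape}")
    if obs.size < 2:
        raise DataError("need at least 2 points for R^2")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise UndefinedRSquaredError("observed responses have zero variance")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def _initial_guess(conc: np.ndarray, resp: np.ndarray, include_offset: bool):
    """K0 from the half-max crossing of the interpolated response; h0 = 1."""
    pos = conc > 0
    c, r = conc[pos], resp[pos]
    order = np.argsort(c)
    c, r = c[order], r[order]
    baseline = float(np.min(resp)) if include_offset else 0.0
    half = baseline + 0.5 * (float(np.max(r)) - baseline)
    k0 = None
    for i in range(len(c) - 1):
        lo, hi = r[i], r[i + 1]
        if (lo - half) * (hi - half) <= 0 and lo != hi:
            frac = (half - lo) / (hi - lo)
            logk = np.log10(c[i]) + frac * (np.log10(c[i + 1]) - np.log10(c[i]))
            k0 = 10.0 ** logk
            break
    if k0 is None or not np.isfinite(k0) or k0 <= 0:
        k0 = float(np.exp(np.mean(np.log(c))))  # geometric mid of the doses
    log10_k0 = float(np.clip(np.log10(k0), *LOG10_K_BOUNDS))
    x0 = [log10_k0, 1.0]
    if include_offset:
        x0.append(float(np.clip(baseline, *OFFSET_BOUNDS)))
    return np.asarray(x0)


def fit_hill(
    points: Sequence[DoseResponsePoint],
    include_offset: bool = False,
    weighted: bool = False,
    confidence: float = 0.95,
) -> HillFit:
    """Fit the Hill equation (optionally plus a constant offset) by least squares.

    The optimizer works in log10(K1/2) for conditioning; results are reported
    on the linear scale, with the K1/2 CI mapped back by the delta method.
    Points at zero concentration contribute residuals (theta(0) = 0).

    Parameters
    ----------
    points : observations; >= 3 required (>= 4 with offset) with >= 2 distinct
        positive concentrations.
    include_offset : also fit the constant ``beta``.
    weighted : weight residuals by 1/dispersion (points must carry dispersion > 0).
    confidence : CI level for the reported half-widths.
    """
    pts = list(points)
    n = len(pts)
    n_params = 3 if include_offset else 2
    if n < n_params + 1:
        raise DataError(
            f"need at least {n_params + 1} points for a "
            f"{n_params}-parameter fit, got {n}"
        )
    conc = np.array([p.concentration for p in pts], dtype=float)
    resp = np.array([p.response for p in pts], dtype=float)
    if len(np.unique(conc[conc > 0])) < 2:
        raise DataError("need at least 2 distinct positive concentrations")
    if np.ptp(resp) == 0.0:
        raise DataError(
            "degenerate input: all responses identical (SStot = 0, fit undefined)"
        )

    if weighted:
        disp = np.array(
            [p.dispersion if p.dispersion else np.nan for p in pts], dtype=float
        )
        if np.any(~np.isfinite(disp)) or np.any(disp <= 0):
            raise DataError("weighted fit requires positive dispersion on every point")
        w = 1.0 / disp
    else:
        w = np.ones_like(resp)

    def model(x: np.ndarray) -> np.ndarray:
        k = 10.0 ** x[0]
        theta = np.zeros_like(conc)
        pos = conc > 0
        theta[pos] = 1.0 / (1.0 + (k / conc[pos]) ** x[1])
        if include_offset:
            theta = theta + x[2]
        return theta

    def residuals(x: np.ndarray) -> np.ndarray:
        return w * (model(x) - resp)

    lower = [LOG10_K_BOUNDS[0], HILL_COEFF_BOUNDS[0]]
    upper = [LOG10_K_BOUNDS[1], HILL_COEFF_BOUNDS[1]]
    if include_offset:
        lower.append(OFFSET_BOUNDS[0])
        upper.append(OFFSET_BOUNDS[1])

    x0 = _initial_guess(conc, resp, include_offset)
    x0 = np.clip(x0, lower, upper)
    try:
        res = optimize.least_squares(
            residuals, x0, bounds=(lower, upper), method="trf",
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
    except Exception as exc:  # pragma: no cover - defensive
        raise FitFailureError(f"optimizer raised: {exc}") from exc
    if res.status <= 0:
        raise FitFailureError(
            "optimizer did not converge",
            diagnostics={"status": res.status, "message": res.message, "x": res.x},
        )

    x_opt = res.x
    dof = n - n_params
    ss_res = float(np.sum((model(x_opt) - resp) ** 2))
    s2 = float(np.sum(res.fun ** 2)) / dof if dof > 0 else np.nan
    # linearized covariance from the Jacobian at the optimum
    J = res.jac
    try:
        cov = np.linalg.inv(J.T @ J) * s2
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(n_params, np.nan)
    tq = stats.t.ppf(0.5 + confidence / 2.0, dof) if dof > 0 else np.nan

    k_half = float(10.0 ** x_opt[0])
    hill_coeff = float(x_opt[1])
    # delta method: K = 10**u  =>  sigma_K = K * ln(10) * sigma_u
    ci_k = float(tq * se[0] * k_half * _LN10)
    ci_h = float(tq * se[1])
    offset = float(x_opt[2]) if include_offset else None
    ci_b = float(tq * se[2]) if include_offset else None

    ss_tot = float(np.sum((resp - resp.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot

    return HillFit(
        k_half=k_half,
        hill_coeff=hill_coeff,
        offset=offset,
        ci_k_half=ci_k,
        ci_hill_coeff=ci_h,
        ci_offset=ci_b,
        r_squared=r2,
        n_points=n,
        converged=True,
    )
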