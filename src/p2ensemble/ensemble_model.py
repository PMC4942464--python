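"""Signed linear-combination models of receptor basis functions.

An ensemble dose-response curve is modeled as
``f(L) = sum_i a_i * theta_i(L) [+ beta]`` where the ``theta_i`` are fixed
per-receptor Hill curves and the weights ``a_i`` are fitted by ordinary
linear least squares, unconstrained in sign — a negative weight marks an
inhibitory contribution. Also hosts the landmark (two-peak) analysis of
non-monotone amplitude curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import CollinearBasisError, DataError
from .hill_core import DoseResponsePoint, r_squared as _r2
from .receptor_catalog import BasisSet, evaluate_basis

__all__ = [
    "EnsembleModel",
    "LandmarkPoint",
    "LandmarkSet",
    "ModelComparison",
    "ensemble_response",
    "fit_linear_combination",
    "compare_models",
    "find_landmarks",
]

_RANK_RTOL = 1e-10


@dataclass(frozen=True)
class EnsembleModel:
    """Basis receptors with fitted signed weights and diagnostics."""

    basis: BasisSet
    coefficients: np.ndarray
    offset: Optional[float] = None
    ci_coefficients: Optional[np.ndarray] = None
    ci_offset: Optional[float] = None
    r_squared: Optional[float] = None
    n_points: Optional[int] = None

    def __post_init__(self) -> None:
        coefs = np.asarray(self.coefficients, dtype=float)
        if coefs.shape != (len(self.basis),):
            raise DataError(
                f"expected {len(self.basis)} coefficients, got shape {coefs.shape}"
            )
        if np.any(~np.isfinite(coefs)):
            raise DataError("coefficients must be finite")
        object.__setattr__(self, "coefficients", coefs)

    @property
    def n_parameters(self) -> int:
        return len(self.basis) + (1 if self.offset is not None else 0)

    def __call__(self, concentrations):
        return ensemble_response(concentrations, self)

    def to_dict(self) -> dict:
        return {
            "basis": [
                {"receptor": m.name, "species": m.species} for m in self.basis
            ],
            "coefficients": {
                m.name: float(a) for m, a in zip(self.basis, self.coefficients)
            },
            "offset": self.offset,
            "ci": {
                "coefficients": (
                    None
                    if self.ci_coefficients is None
                    else {
                        m.name: float(c)
                        for m, c in zip(self.basis, self.ci_coefficients)
                    }
                ),
                "offset": self.ci_offset,
            },
            "r_squared": self.r_squared,
            "n_points": self.n_points,
        }


def ensemble_response(concentrations, model: EnsembleModel):
    """Evaluate ``sum_i a_i * theta_i(L) + beta`` per concentration."""
    conc = np.atleast_1d(np.asarray(concentrations, dtype=float))
    X = evaluate_basis(model.basis, conc)
    y = X @ model.coefficients
    if model.offset is not None:
        y = y + model.offset
    if np.isscalar(concentrations) or np.ndim(concentrations) == 0:
        return float(y[0])
    return y


def _design_matrix(
    conc: np.ndarray, basis: BasisSet, include_offset: bool
) -> Tuple[np.ndarray, List[str]]:
    X = evaluate_basis(basis, conc)
    names = list(basis.names)
    if include_offset:
        X = np.column_stack([X, np.ones(len(conc))])
        names.append("offset")
    return X, names


def _collinear_columns(X: np.ndarray, names: List[str]) -> List[str]:
    # columns with weight in the null space of X are the offenders
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    tol = s[0] * _RANK_RTOL if s[0] > 0 else 0.0
    null = vt[s <= tol] if np.any(s <= tol) else vt[-1:]
    involved = np.any(np.abs(null) > 1e-8, axis=0)
    return [n for n, inv in zip(names, involved) if inv]


def fit_linear_combination(
    points: Sequence[DoseResponsePoint],
    basis: BasisSet,
    include_offset: bool = False,
    confidence: float = 0.95,
) -> EnsembleModel:
    """Fit signed basis weights by ordinary linear least squares.

    Coefficient CIs come from the standard linear-model covariance
    ``s^2 (X^T X)^-1`` scaled by the t-quantile at (n - p) df.
    """
    pts = list(points)
    conc = np.array([p.concentration for p in pts], dtype=float)
    resp = np.array([p.response for p in pts], dtype=float)
    X, names = _design_matrix(conc, basis, include_offset)
    n, p = X.shape
    if n < p:
        raise DataError(f"underdetermined: {n} points for {p} parameters")
    rank = np.linalg.matrix_rank(X, tol=None)
    if rank < p:
        cols = _collinear_columns(X, names)
        raise CollinearBasisError(
            f"design matrix is rank deficient (rank {rank} < {p}); "
            f"collinear columns: {cols}",
            columns=cols,
        )

    beta, _, _, _ = np.linalg.lstsq(X, resp, rcond=None)
    pred = X @ beta
    ss_res = float(np.sum((resp - pred) ** 2))
    dof = n - p
    if dof > 0:
        s2 = ss_res / dof
        cov = s2 * np.linalg.inv(X.T @ X)
        tq = stats.t.ppf(0.5 + confidence / 2.0, dof)
        ci = tq * np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    else:
        ci = np.full(p, np.nan)

    ss_tot = float(np.sum((resp - resp.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")

    k = len(basis)
    return EnsembleModel(
        basis=basis,
        coefficients=beta[:k],
        offset=float(beta[k]) if include_offset else None,
        ci_coefficients=ci[:k],
        ci_offset=float(ci[k]) if include_offset else None,
        r_squared=r2,
        n_points=n,
    )


@dataclass(frozen=True)
class ModelComparison:
    """One candidate's outcome inside :func:`compare_models`."""

    basis: BasisSet
    model: Optional[EnsembleModel]
    error: Optional[Exception]
    rank: Optional[int] = None

    @property
    def ok(self) -> bool:
        return self.model is not None


def compare_models(
    points: Sequence[DoseResponsePoint],
    candidate_bases: Sequence[BasisSet],
    include_offset: bool = False,
) -> List[ModelComparison]:
    """Fit every candidate basis and rank successful fits by R^2 (descending).

    Ties are broken by fewer parameters, then by candidate order. Failed
    candidates are kept in the returned list (rank None) with their error.
    """
    results: List[ModelComparison] = []
    for i, basis in enumerate(candidate_bases):
        try:
            model = fit_linear_combination(points, basis, include_offset)
            results.append(ModelComparison(basis=basis, model=model, error=None))
        except Exception as exc:
            results.append(ModelComparison(basis=basis, model=None, error=exc))

    order = {id(r): i for i, r in enumerate(results)}
    fitted = [r for r in results if r.ok]
    fitted.sort(
        key=lambda r: (-r.model.r_squared, r.model.n_parameters, order[id(r)])
    )
    ranked: List[ModelComparison] = []
    for rank, r in enumerate(fitted, start=1):
        ranked.append(
            ModelComparison(basis=r.basis, model=r.model, error=None, rank=rank)
        )
    ranked.extend(r for r in results if not r.ok)
    return ranked


@dataclass(frozen=True)
class LandmarkPoint:
    concentration: float
    amplitude: float


@dataclass(frozen=True)
class LandmarkSet:
    """Labeled landmarks of a (possibly two-peak) dose-response curve.

    ``n_peaks`` counts detected peaks (0 = monotone curve). With one peak the
    trough/second-peak slots stay empty. ``ends_rising`` marks a curve whose
    final point acts as the second peak, leaving no post-trough.
    """

    n_peaks: int
    initial_low: Optional[LandmarkPoint] = None
    first_peak: Optional[LandmarkPoint] = None
    trough: Optional[LandmarkPoint] = None
    second_peak: Optional[LandmarkPoint] = None
    post_trough: Optional[LandmarkPoint] = None
    ends_rising: bool = False

    def to_dict(self) -> dict:
        def pt(p):
            return None if p is None else {"concentration_M": p.concentration, "amplitude": p.amplitude}

        return {
            "n_peaks": self.n_peaks,
            "initial_low": pt(self.initial_low),
            "first_peak": pt(self.first_peak),
            "trough": pt(self.trough),
            "second_peak": pt(self.second_peak),
            "post_trough": pt(self.post_trough),
            "ends_rising": self.ends_rising,
        }


def _peak_indices(y: np.ndarray) -> List[int]:
    """Strict interior local maxima; plateaus count once at their left edge.

    When at least one interior peak exists and the curve still rises into its
    final point, that point also qualifies as a (boundary) peak — a curve
    climbing at the top concentration carries its second peak there, with no
    post-trough. A curve with no interior maximum stays peak-free.
    """
    # collapse runs of equal values to single representatives (left edge)
    reps = [0]
    for i in range(1, len(y)):
        if y[i] != y[reps[-1]]:
            reps.append(i)
    vals = y[reps]
    peaks = []
    for j in range(1, len(vals) - 1):
        if vals[j] > vals[j - 1] and vals[j] > vals[j + 1]:
            peaks.append(reps[j])
    if peaks and len(vals) >= 2 and vals[-1] > vals[-2]:
        peaks.append(reps[-1])
    return peaks


def find_landmarks(curve: Sequence[DoseResponsePoint]) -> LandmarkSet:
    """Locate the five labeled landmarks of an amplitude dose-response curve.

    Points are ordered by concentration internally, so the result depends
    only on the (concentration, amplitude) pairs. Peaks are strict local
    maxima (plateaus attributed to their lowest concentration); if more than
    two exist, the two with the largest amplitudes are kept, ordered by
    concentration.
    """
    pts = sorted(curve, key=lambda p: p.concentration)
    if len(pts) < 5:
        raise DataError(f"need >= 5 points, got {len(pts)}")
    conc = np.array([p.concentration for p in pts], dtype=float)
    if np.any(np.diff(conc) <= 0):
        raise DataError("concentrations must be strictly increasing")
    y = np.array([p.response for p in pts], dtype=float)

    def pt(i: int) -> LandmarkPoint:
        return LandmarkPoint(concentration=float(conc[i]), amplitude=float(y[i]))

    def min_between(lo: int, hi: int) -> Optional[int]:
        if hi - lo < 2:
            return None
        seg = y[lo + 1 : hi]
        return lo + 1 + int(np.argmin(seg))

    peaks = _peak_indices(y)
    if not peaks:
        return LandmarkSet(n_peaks=0)

    if len(peaks) == 1:
        k = peaks[0]
        post = min_between(k, len(y)) if k < len(y) - 1 else None
        return LandmarkSet(
            n_peaks=1,
            initial_low=pt(int(np.argmin(y[:k]))) if k > 0 else None,
            first_peak=pt(k),
            post_trough=pt(post) if post is not None else None,
            ends_rising=k == len(y) - 1,
        )

    # two largest-amplitude peaks, reported in concentration order
    top2 = sorted(sorted(peaks, key=lambda i: -y[i])[:2])
    p1, p2 = top2
    trough = min_between(p1, p2)
    post = min_between(p2, len(y)) if p2 < len(y) - 1 else None
    return LandmarkSet(
        n_peaks=len(peaks),
        initial_low=pt(int(np.argmin(y[:p1]))) if p1 > 0 else None,
        first_peak=pt(p1),
        trough=pt(trough) if trough is not None else None,
        second_peak=pt(p2),
        post_trough=pt(post) if post is not None else None,
        ends_rising=p2 == len(y) - 1,
    )
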