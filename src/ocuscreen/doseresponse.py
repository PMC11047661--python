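"""Binary logistic dose-response models and the combined irritation probability.

The positive-micropattern probability is modelled as

    P(C) = 1 / (1 + exp(-(beta0 + beta1 * C)))

with C the compound concentration in nM on the linear scale (the fitting
unit is the micropattern, one binary record each).  The maximum-likelihood
fit uses Newton/IRLS with the predictor internally rescaled for numerical
stability; the covariance is the inverse observed information.

The eye-irritation probability combines the apoptosis and TRPV1-activation
curves as a union of non-mutually-exclusive events,

    P_irritation = P_apoptosis + P_TRPV1 - P(apoptosis ∩ TRPV1),

with the intersection modelled as the independence product by default (a
different intersection rule can be plugged in).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from .errors import FitError, SeparationError, ValidationError

#: clip fitted probabilities into the open interval (0, 1)
_P_EPS = 1e-15


@dataclass
class LogisticFit:
    """Fitted (or externally specified) logistic dose-response model.

    ``covariance`` may be None for a model built directly from published
    coefficients; operations needing standard errors then raise.
    """

    beta0: float
    beta1: float
    covariance: np.ndarray | None = None
    n_obs: int = 0
    converged: bool = True
    separation_flag: bool = False

    def __post_init__(self) -> None:
        if self.covariance is not None:
            self.covariance = np.asarray(self.covariance, dtype=float)
            if self.covariance.shape != (2, 2):
                raise ValidationError("covariance must be a 2x2 matrix")

    @classmethod
    def from_coefficients(cls, beta0: float, beta1: float) -> "LogisticFit":
        """Model from printed coefficients, e.g. the published SLS equation."""
        return cls(beta0=float(beta0), beta1=float(beta1))

    def standard_errors(self) -> tuple[float, float]:
        if self.covariance is None:
            raise FitError("model has no covariance (built from coefficients only)")
        return (
            float(np.sqrt(self.covariance[0, 0])),
            float(np.sqrt(self.covariance[1, 1])),
        )

    def to_dict(self) -> dict:
        return {
            "beta0": self.beta0,
            "beta1": self.beta1,
            "cov": None if self.covariance is None else self.covariance.tolist(),
            "n_obs": self.n_obs,
            "converged": self.converged,
            "separation": self.separation_flag,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LogisticFit":
        return cls(
            beta0=float(d["beta0"]),
            beta1=float(d["beta1"]),
            covariance=None if d.get("cov") is None else np.asarray(d["cov"]),
            n_obs=int(d.get("n_obs", 0)),
            converged=bool(d.get("converged", True)),
            separation_flag=bool(d.get("separation", False)),
        )


@dataclass
class CombinedProbability:
    """Per-assay and combined irritation probabilities over a dose grid."""

    concentrations: np.ndarray
    p_apoptosis: np.ndarray
    p_trpv1: np.ndarray
    p_combined: np.ndarray
    intersection_rule: str = "independence"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "concentration_nM": self.concentrations,
                "p_apoptosis": self.p_apoptosis,
                "p_trpv1": self.p_trpv1,
                "p_combined": self.p_combined,
            }
        )


def _extract_records(
    records, outcome=None
) -> tuple[np.ndarray, np.ndarray]:
    if outcome is not None:
        c = np.asarray(records, dtype=float)
        y = np.asarray(outcome, dtype=float)
    elif isinstance(records, pd.DataFrame):
        missing = {"concentration_nM", "outcome"} - set(records.columns)
        if missing:
            raise ValidationError(f"records table lacks columns: {sorted(missing)}")
        c = records["concentration_nM"].to_numpy(dtype=float)
        y = records["outcome"].to_numpy(dtype=float)
    else:
        pairs = [(r.concentration_nM, r.outcome) for r in records]
        c = np.asarray([p[0] for p in pairs], dtype=float)
        y = np.asarray([p[1] for p in pairs], dtype=float)
    if c.shape != y.shape or c.ndim != 1:
        raise ValidationError("concentration and outcome must be equal-length 1-D")
    if np.any(c < 0):
        raise ValidationError("concentrations must be >= 0")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValidationError("outcomes must be binary 0/1")
    return c, y


def fit_logistic(
    records,
    outcome=None,
    *,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> LogisticFit:
    """Maximum-likelihood logistic fit of binary micropattern outcomes on C.

    Accepts a records table (columns ``concentration_nM``, ``outcome``), a
    sequence of record objects with those attributes, or two arrays
    ``fit_logistic(concentration, outcome)``.

    Newton/IRLS on the internally rescaled predictor C/max(C); coefficients
    and covariance are mapped back to the per-nM scale.  Quasi-complete
    separation is flagged when a coefficient exceeds 1e3 logit units (on the
    rescaled predictor) or the information matrix becomes singular.

    Raises
    ------
    SeparationError
        If all outcomes are identical (probability not identifiable).
    ValidationError
        If fewer than two distinct concentrations are present.
    """
    c, y = _extract_records(records, outcome)
    if len(np.unique(c)) < 2:
        raise ValidationError(
            "need at least two distinct concentrations to fit a slope"
        )
    if y.min() == y.max():
        raise SeparationError(
            f"all {len(y)} outcomes are {int(y[0])}: the response probability "
            "is completely separated and the model is not identifiable"
        )

    scale = float(c.max()) if c.max() > 0 else 1.0
    x = c / scale
    X = np.column_stack([np.ones_like(x), x])

    b = np.array([float(logit(np.clip(y.mean(), 1e-6, 1 - 1e-6))), 0.0])
    converged = False
    separation = False
    info = None
    for _ in range(max_iter):
        eta = X @ b
        p = expit(eta)
        w = np.clip(p * (1 - p), 1e-12, None)
        grad = X.T @ (y - p)
        info = (X * w[:, None]).T @ X
        det = np.linalg.det(info)
        if not np.isfinite(det) or det <= 1e-12 * max(info[0, 0], 1.0) ** 2:
            separation = True
            break
        delta = np.linalg.solve(info, grad)
        b = b + delta
        if np.max(np.abs(b)) > 1e3:
            separation = True
            break
        if np.linalg.norm(delta) < tol * (1.0 + np.linalg.norm(b)):
            converged = True
            break

    if info is None or separation:
        cov = None
    else:
        cov_scaled = np.linalg.inv(info)
        T = np.diag([1.0, 1.0 / scale])
        cov = T @ cov_scaled @ T

    return LogisticFit(
        beta0=float(b[0]),
        beta1=float(b[1] / scale),
        covariance=cov,
        n_obs=len(y),
        converged=converged,
        separation_flag=separation,
    )


def predict(fit: LogisticFit, concentration) -> float | np.ndarray:
    """Response probability at concentration C (nM), strictly inside (0, 1)."""
    c = np.asarray(concentration, dtype=float)
    if np.any(c < 0):
        raise ValidationError("concentration must be >= 0")
    p = np.clip(expit(fit.beta0 + fit.beta1 * c), _P_EPS, 1 - _P_EPS)
    return float(p) if np.ndim(concentration) == 0 else p


def ic50(fit: LogisticFit) -> float:
    """Concentration at which the fitted response probability is 0.5.

    Defined only for a positive slope; a flat or protective dose-response
    (e.g. a printed "+0.0*C" model) has no IC50.
    """
    if fit.beta1 <= 0:
        raise FitError(
            f"IC50 undefined for slope {fit.beta1}: the dose-response is flat "
            "or decreasing"
        )
    return -fit.beta0 / fit.beta1


def confidence_band(
    fit: LogisticFit,
    concentrations,
    level: float = 0.95,
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise Wald band for the probability curve over a dose grid.

    The interval is built on the linear predictor (delta method on the fitted
    covariance) and mapped through the logistic function, so it always
    brackets the point estimate.
    """
    if not fit.converged:
        raise FitError("confidence band requires a converged fit")
    if fit.covariance is None:
        raise FitError("confidence band requires a fit covariance")
    if not (0 < level < 1):
        raise ValidationError("level must be in (0, 1)")
    c = np.atleast_1d(np.asarray(concentrations, dtype=float))
    z = norm.ppf(0.5 + level / 2.0)
    v = (
        fit.covariance[0, 0]
        + 2.0 * c * fit.covariance[0, 1]
        + c**2 * fit.covariance[1, 1]
    )
    se = np.sqrt(np.clip(v, 0.0, None))
    eta = fit.beta0 + fit.beta1 * c
    return expit(eta - z * se), expit(eta + z * se)


def combine_probabilities(
    p_a,
    p_b,
    intersection: str | Callable = "independence",
):
    """Union probability of two non-mutually-exclusive assay responses.

    ``P(A or B) = pA + pB - P(A and B)``, with the intersection modelled as
    the independence product ``pA * pB`` by default.  ``intersection`` may be
    a callable ``(pA, pB) -> P(A and B)``; any rule must stay within the
    Fréchet bounds ``[max(0, pA+pB-1), min(pA, pB)]``.
    """
    pa = np.asarray(p_a, dtype=float)
    pb = np.asarray(p_b, dtype=float)
    if np.any((pa < 0) | (pa > 1)) or np.any((pb < 0) | (pb > 1)):
        raise ValidationError("probabilities must lie in [0, 1]")
    if intersection == "independence":
        inter = pa * pb
    elif callable(intersection):
        inter = np.asarray(intersection(pa, pb), dtype=float)
        lo = np.maximum(0.0, pa + pb - 1.0)
        hi = np.minimum(pa, pb)
        if np.any(inter < lo - 1e-12) or np.any(inter > hi + 1e-12):
            raise ValidationError("intersection rule violates the Fréchet bounds")
    else:
        raise ValidationError(f"unknown intersection rule: {intersection!r}")
    out = pa + pb - inter
    return float(out) if (np.ndim(p_a) == 0 and np.ndim(p_b) == 0) else out


def irritation_profile(
    fit_apoptosis: LogisticFit | float,
    fit_trpv1: LogisticFit | float,
    concentrations,
    intersection: str | Callable = "independence",
) -> CombinedProbability:
    """Combined eye-irritation probability over a concentration grid.

    Each assay is either a fitted logistic model or a constant probability —
    the latter covers assays whose response is concentration-independent
    (slope-zero fits are expected and legitimate there).
    """
    grid = np.atleast_1d(np.asarray(concentrations, dtype=float))

    def as_curve(model) -> np.ndarray:
        if isinstance(model, LogisticFit):
            return np.asarray(predict(model, grid))
        p = float(model)
        if not (0.0 <= p <= 1.0):
            raise ValidationError(f"constant probability must be in [0, 1], got {p}")
        return np.full_like(grid, p)

    pa = as_curve(fit_apoptosis)
    pb = as_curve(fit_trpv1)
    combined = combine_probabilities(pa, pb, intersection)
    rule = intersection if isinstance(intersection, str) else getattr(
        intersection, "__name__", "custom"
    )
    return CombinedProbability(
        concentrations=grid,
        p_apoptosis=pa,
        p_trpv1=pb,
        p_combined=np.asarray(combined),
        intersection_rule=rule,
    )
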