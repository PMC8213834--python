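"""Dielectric scalings of conductor-like continuum models and error metrics.

The conductor-like screening boundary condition scales the polarization
charge density by f(eps) = (eps - 1)/(eps + x).  A code hard-wired to
x = 0 can emulate any other scaling factor by replacing the solvent
dielectric constant with the effective value eps~ = (eps + x)/(x + 1),
since f(eps~, 0) = f(eps, x) identically.

Prediction quality is summarized by the mean unsigned error (MUE), root
mean squared error (RMSE), maximum unsigned error, and the mean absolute
percentage error (MAPE); all energies in kcal/mol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ErrorSummary",
    "cpcm_scale",
    "effective_dielectric",
    "error_summary",
]


def _check_epsilon(epsilon) -> np.ndarray:
    eps = np.asarray(epsilon, dtype=float)
    if np.any(eps < 1.0):
        raise ValueError(f"dielectric constant must be >= 1, got {epsilon}")
    return eps


def cpcm_scale(epsilon, x: float = 0.0):
    """Conductor-like screening factor f(eps) = (eps - 1)/(eps + x).

    ``x >= 0`` is the charge-scaling parameter (0 for the plain conductor
    limit, 0.5 for the commonly recommended choice).  Returns a value in
    [0, 1); accepts scalars or arrays.
    """
    eps = _check_epsilon(epsilon)
    if x < 0:
        raise ValueError(f"scaling factor x must be >= 0, got {x}")
    out = (eps - 1.0) / (eps + x)
    return float(out) if np.isscalar(epsilon) else out


def effective_dielectric(epsilon, x: float = 0.0):
    """Effective dielectric constant eps~ = (eps + x)/(x + 1).

    Substituting eps~ into an x = 0 conductor-like code reproduces the
    screening factor of scaling parameter ``x``: f(eps~, 0) = f(eps, x).
    Monotone increasing in eps, with eps~ = 1 at eps = 1.
    """
    eps = _check_epsilon(epsilon)
    if x < 0:
        raise ValueError(f"scaling factor x must be >= 0, got {x}")
    out = (eps + x) / (x + 1.0)
    return float(out) if np.isscalar(epsilon) else out


@dataclass(frozen=True)
class ErrorSummary:
    """Aggregate prediction-error metrics on the kcal/mol scale.

    ``mape`` is in percent and is ``nan`` (with ``mape_defined`` False)
    when every reference value lies below the MAPE floor; ``n_mape``
    counts the records that entered the MAPE average.
    """

    mue: float
    rmse: float
    max_ue: float
    mape: float
    n: int
    n_mape: int

    @property
    def mape_defined(self) -> bool:
        return not np.isnan(self.mape)


def error_summary(y_exp, y_pred, mape_floor: float = 0.1) -> ErrorSummary:
    """Compute MUE, RMSE, max unsigned error and MAPE of predictions.

    MUE = mean |y_exp - y_pred|, RMSE = sqrt(mean (y_exp - y_pred)^2).
    MAPE averages 100*|residual/y_exp| over records with
    |y_exp| >= ``mape_floor`` (kcal/mol); near-zero references would
    otherwise make the percentage error unbounded.
    """
    y_exp = np.asarray(y_exp, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_exp.shape != y_pred.shape or y_exp.ndim != 1:
        raise ValueError(
            f"y_exp and y_pred must be equal-length vectors, got shapes "
            f"{y_exp.shape} and {y_pred.shape}"
        )
    if y_exp.size < 1:
        raise ValueError("need at least one sample")
    resid = y_exp - y_pred
    abs_resid = np.abs(resid)
    mask = np.abs(y_exp) >= mape_floor
    n_mape = int(mask.sum())
    mape = (
        float(100.0 * np.mean(abs_resid[mask] / np.abs(y_exp[mask])))
        if n_mape
        else float("nan")
    )
    return ErrorSummary(
        mue=float(np.mean(abs_resid)),
        rmse=float(np.sqrt(np.mean(resid**2))),
        max_ue=float(np.max(abs_resid)),
        mape=mape,
        n=int(y_exp.size),
        n_mape=n_mape,
    )
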