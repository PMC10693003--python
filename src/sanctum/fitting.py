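"""Logistic summary of mutant-spread trajectories.

The rise of the mutant's metapopulation fraction is summarised with a
three-parameter logistic curve

    f(t) = plateau / (1 + ((plateau - N0) / N0) * exp(-r * t))

of which the initial proportion ``N0`` is held fixed at the known
inoculation ratio (0.001 for a 1:1000 start), leaving the spread rate
``r`` (the r_max analogue) and the asymptotic final frequency ``plateau``
(the carrying-capacity analogue) to be estimated by nonlinear least
squares on the proportion scale.

Initialisation is deterministic: ``r`` from the log-slope of the early
points, ``plateau`` from the maximum observed proportion (clipped to
``(N0, 1]``); the trust-region solver can only improve on the
initialisation, so the returned SSE never exceeds the initialisation SSE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import InvalidInputError, InvalidParameterError

__all__ = ["FitResult", "logistic_curve", "fit_logistic"]


@dataclass(frozen=True)
class FitResult:
    """Converged logistic fit: spread rate, plateau, and diagnostics."""

    r_max: float | None
    plateau: float | None
    fixed_N0: float
    sse: float | None
    converged: bool


def logistic_curve(t, N0: float, r: float, plateau: float):
    """Logistic proportion at time ``t`` with fixed initial value ``N0``."""
    if not 0.0 < N0 < plateau or plateau > 1.0:
        raise InvalidParameterError("need 0 < N0 < plateau <= 1")
    t = np.asarray(t, dtype=float)
    b = (plateau - N0) / N0
    out = plateau / (1.0 + b * np.exp(-r * t))
    return float(out) if out.ndim == 0 else out


def _initial_guess(times, props, N0):
    props = np.clip(props, 1e-12, 1.0)
    plateau0 = float(np.clip(props.max(), N0 * (1 + 1e-6) + 1e-12, 1.0))
    # log-slope of the early (sub-half-plateau) points against the exact
    # logistic relation log(f/(plateau-f)) = log(N0/(plateau-N0)) + r t
    early = props < 0.9 * plateau0
    if early.sum() >= 2:
        y = np.log(props[early] / np.maximum(plateau0 - props[early], 1e-12))
        tt = times[early]
        denom = np.sum((tt - tt.mean()) ** 2)
        r0 = float(np.sum((tt - tt.mean()) * (y - y.mean())) / denom) if denom > 0 else 0.1
    else:
        r0 = 0.1
    if not np.isfinite(r0):
        r0 = 0.1
    return r0, plateau0


def fit_logistic(times, proportions, N0: float) -> FitResult:
    """Least-squares logistic fit with the initial proportion held fixed.

    Deterministic given the data: the initial guess is computed from the
    data and the bounded trust-region solver has no random component.
    Non-convergence is flagged rather than raised.
    """
    times = np.asarray(times, dtype=float)
    props = np.asarray(proportions, dtype=float)
    if times.shape != props.shape or times.size < 3:
        raise InvalidInputError("need >= 3 (time, proportion) points")
    if np.any((props < 0) | (props > 1)):
        raise InvalidInputError("proportions must be in [0, 1]")
    if not 0.0 < N0 < 1.0:
        raise InvalidParameterError("N0 must be in (0, 1)")

    r0, plateau0 = _initial_guess(times, props, N0)
    lo_plateau = N0 * (1 + 1e-9)

    def residuals(theta):
        r, plateau = theta
        b = (plateau - N0) / N0
        return plateau / (1.0 + b * np.exp(-r * times)) - props

    try:
        res = least_squares(
            residuals,
            x0=[r0, np.clip(plateau0, lo_plateau, 1.0)],
            bounds=([-np.inf, lo_plateau], [np.inf, 1.0]),
            xtol=1e-15,
            ftol=1e-15,
            gtol=1e-15,
            max_nfev=2000,
        )
    except Exception:
        return FitResult(None, None, N0, None, False)
    if not res.success or not np.all(np.isfinite(res.x)):
        return FitResult(None, None, N0, None, False)
    sse = float(np.sum(res.fun**2))
    r_hat, plateau_hat = float(res.x[0]), float(res.x[1])
    if plateau_hat <= N0 * (1 + 1e-4):
        # plateau pinned at N0: the curve is flat and r is unidentified
        r_hat = 0.0
    return FitResult(r_hat, plateau_hat, N0, sse, True)
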