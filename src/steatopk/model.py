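"""Single-peak elimination curve and derived pharmacokinetic quantities.

The blood concentration of a bolus-injected drug is modelled as

    x(t) = t * exp(B - A*t)

with rate parameter ``A`` (1/h) and log-amplitude ``B`` (dimensionless;
``exp(B)`` carries concentration-per-time units).  The curve rises linearly
from x(0) = 0, peaks at t = 1/A and decays exponentially.  From a fitted
(A, B) pair we extract the peak time, peak concentration, half-life (time
for the concentration to fall from the peak to half the peak) and the
decay-phase area under the curve (from the peak to a terminal time,
6 h by default, matching the last scheduled sampling time).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

__all__ = [
    "PKParams",
    "PKDerived",
    "evaluate_curve",
    "ode_rhs",
    "peak_time",
    "peak_concentration",
    "half_life",
    "auc_decay",
    "HALF_LIFE_CONSTANT",
]


@dataclass(frozen=True)
class PKParams:
    """Parameters of the elimination curve x(t) = t * exp(B - A*t).

    Attributes
    ----------
    A : float
        Elimination-rate-like parameter, 1/h; strictly positive.  The peak
        occurs at t = 1/A.
    B : float
        Log-amplitude; exp(B) sets the concentration scale.
    """

    A: float
    B: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.A) or self.A <= 0:
            raise ValueError(f"A must be finite and > 0, got {self.A!r}")
        if not np.isfinite(self.B):
            raise ValueError(f"B must be finite, got {self.B!r}")


@dataclass(frozen=True)
class PKDerived:
    """Quantities extracted from a fitted elimination curve.

    ``sse`` is the squared-residual sum of the fit that produced the
    parameters (0 for analytically constructed curves).
    """

    t_peak: float  # h
    x_peak: float  # ng/ml
    t_half: float  # h
    auc: float  # ng*h/ml, decay phase only
    sse: float = 0.0


def evaluate_curve(t, params: PKParams):
    """Concentration x(t) = t * exp(B - A*t); vectorized over ``t``.

    Raises for negative times: the model describes the post-injection
    course only.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    out = t * np.exp(params.B - params.A * t)
    return out if out.ndim else float(out)


def ode_rhs(t, params: PKParams):
    """Time derivative dx/dt = (1 - A*t) * exp(B - A*t).

    The curve is the solution of this ODE with x(0) = 0; the right-hand
    side equals the analytic derivative of :func:`evaluate_curve`.
    """
    t = np.asarray(t, dtype=float)
    out = (1.0 - params.A * t) * np.exp(params.B - params.A * t)
    return out if out.ndim else float(out)


def peak_time(params: PKParams) -> float:
    """Time of peak concentration, t_peak = 1/A (h).

    The stationary point of x(t) is where dx/dt = 0, i.e. t = 1/A; the
    closed form is exact so no numeric optimizer is used at run time.
    """
    return 1.0 / params.A


def peak_concentration(params: PKParams) -> float:
    """Peak concentration x(t_peak) = (1/A) * exp(B - 1) (ng/ml)."""
    return (1.0 / params.A) * np.exp(params.B - 1.0)


# Scaled half-life: the root u > 1 of u*exp(-u) = exp(-1)/2.  With
# u = A*t the half-crossing time is u*/A, so t_half = (u* - 1)/A for every
# (A, B): the half-life depends on A only.
HALF_LIFE_CONSTANT: float = float(
    brentq(lambda u: u * np.exp(-u) - 0.5 * np.exp(-1.0), 1.0, 60.0, xtol=1e-14)
    - 1.0
)


def half_life(params: PKParams, _bracket_factor: float = 60.0) -> float:
    """Half-life t_1/2 (h): time from the peak until x falls to x_peak/2.

    Solves x(t) = x_peak/2 for the unique root t > t_peak with a bracketed
    Brent solver on [t_peak, t_peak + 60/A] (absolute tolerance 1e-10 h)
    and returns t - t_peak.  Independent of B: rescaling the amplitude
    rescales both sides of the half-crossing equation.
    """
    tp = peak_time(params)
    half = 0.5 * peak_concentration(params)

    def f(t: float) -> float:
        return t * np.exp(params.B - params.A * t) - half

    hi = tp + _bracket_factor / params.A
    if f(hi) > 0:  # cannot occur for valid params; guards numeric misuse
        raise ValueError("half-life root not bracketed")
    root = brentq(f, tp, hi, xtol=1e-10)
    return root - tp


def _antiderivative(t: float, params: PKParams) -> float:
    # Integral of t*exp(B - A*t): exp(B) * [-(t/A + 1/A^2) * exp(-A*t)]
    A, B = params.A, params.B
    return float(np.exp(B) * (-(t / A + 1.0 / A**2) * np.exp(-A * t)))


def auc_decay(params: PKParams, t_end: float = 6.0) -> float:
    """Decay-phase AUC: integral of x(t) from t_peak to ``t_end`` (ng*h/ml).

    Computed by the closed-form antiderivative; adaptive quadrature serves
    as an independent oracle in the test suite.
    """
    tp = peak_time(params)
    if t_end <= tp:
        raise ValueError(f"t_end ({t_end}) must exceed t_peak ({tp:.4g})")
    return _antiderivative(t_end, params) - _antiderivative(tp, params)


def auc_decay_quadrature(params: PKParams, t_end: float = 6.0) -> float:
    """Adaptive-quadrature evaluation of :func:`auc_decay` (oracle path)."""
    tp = peak_time(params)
    if t_end <= tp:
        raise ValueError(f"t_end ({t_end}) must exceed t_peak ({tp:.4g})")
    val, _ = quad(lambda t: evaluate_curve(t, params), tp, t_end,
                  epsabs=1e-12, epsrel=1e-12)
    return val
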