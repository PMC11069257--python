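"""Impulse-input nonlinear chromatography (Thomas/Wade) peak model.

The elution profile of an overloaded pulse from a column with finite
adsorption/desorption kinetics and Langmuir site saturation is, in reduced
coordinates (x = t/t0 reduced retention time, y = Y/C0 reduced signal),

    y(x) = (a0/a3) * [1 - exp(-a3/a2)]
           * sqrt(a1/x) * I1(2*sqrt(a1*x)/a2) * exp(-(x + a1)/a2)
           / (1 - T(a1/a2, x/a2) * [1 - exp(-a3/a2)])

where I1 is the modified Bessel function and T is the switching function

    T(u, v) = exp(-v) * integral_0^u exp(-t) I0(2*sqrt(v*t)) dt.

Parameters: a0 area, a1 center (reduced retention of the peak at infinite
dilution; a1 - 1 is the thermodynamic capacity factor), a2 width/rate
parameter (a2 = 1/(kd*t0), so small a2 means fast desorption relative to
the column hold-up time), a3 distortion ("normalized overload",
a3 = K_A*C0).  As a3 -> 0 the profile reduces to the linear-chromatography
impulse response; a3 = 0 is accepted and dispatched to that analytic limit.

Numerics: plain I0/I1 overflow for arguments beyond ~700, and in the
strong-overload regime (a3/a2 >> 700) both the numerator and the
denominator of y underflow while their ratio stays finite.  All
evaluations therefore use exponentially scaled Bessel functions with
explicit exponent bookkeeping, and the profile is assembled in the log
domain.  T is evaluated two ways: a scalar adaptive-quadrature route on
the scaled integrand (``switching_T``), and a fast vectorized route via
the noncentral-chi-square identity T(u,v) = P(X <= 2u) for
X ~ chi2(df=2, nc=2v), whose complement (a Marcum Q-function) gets a
log-domain asymptotic tail once it underflows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, special, stats

from .chromatograms import Chromatogram, ChromatogramMeta

__all__ = ["ThomasParams", "ReducedPeak", "switching_T", "thomas_profile", "simulate_peak"]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass(frozen=True)
class ThomasParams:
    """(a0, a1, a2, a3): area, center, width, distortion of the peak model."""

    a0: float
    a1: float
    a2: float
    a3: float

    def __post_init__(self) -> None:
        if not (self.a0 > 0 and self.a1 > 0 and self.a2 > 0):
            raise ValueError(f"a0, a1, a2 must be positive, got {self}")
        if self.a3 < 0:
            raise ValueError(f"a3 must be non-negative, got {self.a3}")

    def as_array(self) -> np.ndarray:
        return np.array([self.a0, self.a1, self.a2, self.a3], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "ThomasParams":
        a0, a1, a2, a3 = (float(v) for v in arr)
        return cls(a0, a1, a2, a3)


@dataclass
class ReducedPeak:
    """Reduced-coordinate peak: x = t/t0 (dimensionless), y = Y/C0."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if np.any(self.x <= 0) or np.any(np.diff(self.x) <= 0):
            raise ValueError("x must be positive and strictly increasing")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("non-finite values in y")

    @classmethod
    def from_chromatogram(cls, chrom: Chromatogram, t0: float, C0: float) -> "ReducedPeak":
        if t0 <= 0 or C0 <= 0:
            raise ValueError("t0 and C0 must be positive")
        mask = chrom.time > 0
        return cls(chrom.time[mask] / t0, chrom.signal[mask] / C0)


# ---------------------------------------------------------------------------
# Switching function
# ---------------------------------------------------------------------------

def _T_integrand(t: float, v: float) -> float:
    # exp(-v-t) I0(2 sqrt(vt)) rewritten with the scaled Bessel:
    # exponents combine to -(sqrt(v)-sqrt(t))^2, which never overflows.
    return np.exp(-((np.sqrt(v) - np.sqrt(t)) ** 2)) * special.i0e(2.0 * np.sqrt(v * t))


def switching_T(u: float, v: float) -> float:
    """Switching function T(u,v) = exp(-v) * int_0^u exp(-t) I0(2*sqrt(vt)) dt.

    Generates the peak skew of the nonlinear model.  Always in [0, 1);
    evaluated by adaptive quadrature of the overflow-safe scaled integrand
    (absolute tolerance 1e-12); for large u*v with u > v the complement
    1 - T is computed from the tail integral instead, which is the
    well-conditioned side.
    """
    u = float(u)
    v = float(v)
    if u < 0 or v < 0:
        raise ValueError(f"switching_T requires u, v >= 0, got u={u}, v={v}")
    if u == 0.0:
        return 0.0
    if v == 0.0:
        return float(-np.expm1(-u))
    if u * v > 1e6 and u > v:
        tail, _ = integrate.quad(_T_integrand, u, np.inf, args=(v,), epsabs=1e-12, limit=500)
        return 1.0 - tail
    # the scaled integrand is below 1e-300 once |sqrt(t) - sqrt(v)| > 27;
    # clamp the upper limit to that support so quad cannot step over it
    u_eff = min(u, (np.sqrt(v) + 28.0) ** 2)
    points = [v] if v < u_eff else None
    val, _ = integrate.quad(
        _T_integrand, 0.0, u_eff, args=(v,), points=points, epsabs=1e-12, limit=500
    )
    return min(float(val), float(np.nextafter(1.0, 0.0)))


def _log_marcum_q(u: float, v: np.ndarray) -> np.ndarray:
    """log of Q = 1 - T(u, v), vectorized over v (u scalar).

    Q equals the Marcum Q-function Q1(sqrt(2v), sqrt(2u)).  The noncentral
    chi-square survival function covers everything representable in double
    precision; only once it underflows (exponent beyond ~700) does a
    second-order Laplace asymptotic of the tail integral

        Q = int_b^inf x exp(-(x^2+a^2)/2) I0(ax) dx,
        a = sqrt(2v), b = sqrt(2u), d = b - a, d^2/2 = (sqrt(u)-sqrt(v))^2

    take over in the log domain (relative error O(d^-4), so the hand-over
    is smooth to ~1e-6 -- a continuous model matters to the optimizer).
    """
    v = np.asarray(v, dtype=float)
    sq = (np.sqrt(u) - np.sqrt(v)) ** 2
    with np.errstate(divide="ignore"):
        q = stats.ncx2.sf(2.0 * u, 2, 2.0 * v)
        logq = np.log(q)
    deep = (v < u) & ~np.isfinite(logq)
    if np.any(deep):
        a = np.sqrt(2.0 * v[deep])
        b = np.sqrt(2.0 * u)
        d = b - a
        # I0(ax) ~ e^(ax)/sqrt(2 pi a x) (1 + 1/(8ax)); Laplace in s = x - b
        g = np.sqrt(b / a) * (1.0 + 1.0 / (8.0 * a * b))
        gp = 1.0 / (2.0 * np.sqrt(a * b))
        poly = g / d * (1.0 - 1.0 / d**2) + gp / d**2
        logq = np.array(logq, dtype=float)
        logq[deep] = -sq[deep] - _LOG_SQRT_2PI + np.log(poly)
    return logq


# ---------------------------------------------------------------------------
# Peak profile
# ---------------------------------------------------------------------------

def _log_numerator(x: np.ndarray, a1: float, a2: float) -> np.ndarray:
    """log of sqrt(a1/x) * I1(2 sqrt(a1 x)/a2) * exp(-(x+a1)/a2).

    The Bessel-exponential product is combined as
    i1e(z) * exp(-(sqrt(x)-sqrt(a1))^2 / a2), z = 2 sqrt(a1 x)/a2.
    """
    z = 2.0 * np.sqrt(a1 * x) / a2
    with np.errstate(divide="ignore"):
        log_bessel = np.log(special.i1e(z))
    return 0.5 * (np.log(a1) - np.log(x)) + log_bessel - ((np.sqrt(x) - np.sqrt(a1)) ** 2) / a2


def thomas_profile(x, params: ThomasParams) -> np.ndarray:
    """Evaluate the reduced elution profile y(x) for x > 0.

    Returns a non-negative finite array; raises on non-finite output.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if np.any(x <= 0):
        raise ValueError("thomas_profile requires x > 0")
    a0, a1, a2, a3 = params.a0, params.a1, params.a2, params.a3
    log_num = _log_numerator(x, a1, a2)
    if a3 == 0.0:
        # analytic linear-chromatography limit: (1-exp(-a3/a2))/a3 -> 1/a2
        log_y = -np.log(a2) + np.log(a0) + log_num
    else:
        c = a3 / a2
        b3 = -np.expm1(-c)  # 1 - exp(-a3/a2), in (0, 1)
        logq = _log_marcum_q(a1 / a2, x / a2)
        # denominator 1 - b3*T = exp(-c) + b3*Q, assembled in the log domain
        log_den = np.logaddexp(-c, np.log(b3) + logq)
        log_y = np.log(a0) - np.log(a3) + np.log(b3) + log_num - log_den
    with np.errstate(over="ignore"):
        y = np.exp(log_y)
    if not np.all(np.isfinite(y)):
        bad = x[~np.isfinite(y)][:3]
        raise FloatingPointError(
            f"non-finite profile value near x={bad} for params {params}"
        )
    return y


def simulate_peak(
    params: ThomasParams,
    t0_min: float,
    grid_dt_min: float = 0.005,
    t_max_min: float | None = None,
    meta: ChromatogramMeta | None = None,
) -> Chromatogram:
    """Map the reduced profile to clock time (t = x * t0) on a uniform grid.

    The signal is the reduced profile y; callers apply the C0 scaling via
    metadata.  Raises if the grid truncates the peak (captured area below
    99% of the analytic total, or the trace not decayed at t_max).
    """
    if t0_min <= 0 or grid_dt_min <= 0:
        raise ValueError("t0 and grid spacing must be positive")
    if t_max_min is None:
        t_max_min = t0_min * (2.0 + 2.0 * params.a1)
    if t_max_min <= grid_dt_min:
        raise ValueError("t_max must exceed the grid spacing")
    t = np.arange(grid_dt_min, t_max_min + 0.5 * grid_dt_min, grid_dt_min)
    y = thomas_profile(t / t0_min, params)
    ymax = float(y.max())
    expected_area = params.a0 * t0_min * float(-np.expm1(-params.a1 / params.a2))
    captured = float(np.trapezoid(y, t))
    if ymax > 0 and (y[-1] > 1e-3 * ymax or captured < 0.99 * expected_area):
        raise ValueError(
            f"peak truncated at t_max={t_max_min} min (captured {captured:.4g} of "
            f"{expected_area:.4g}); increase t_max"
        )
    return Chromatogram(t, y, meta or ChromatogramMeta())
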