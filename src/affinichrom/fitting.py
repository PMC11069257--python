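"""Least-squares fitting of the nonlinear peak model and conversion of the
fitted parameters into binding constants.

Workflow: a baseline-corrected chromatogram is reduced to dimensionless
coordinates (x = t/t0, y = Y/C0), ``ThomasPeakModel`` fits the four-parameter
profile by bounded least squares, and the fitted (a2, a3) give the kinetic
and thermodynamic constants

    K_A = a3 / C0        (L/mol, association constant)
    k_d = 1 / (a2 * t0)  (1/s, desorption rate; t0 in seconds)
    k_a = k_d * K_A      (1/(s*M), adsorption rate)

with C0 the injected concentration multiplied by the injection-pulse width
expressed in units of t0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .thomas import ReducedPeak, ThomasParams, thomas_profile

__all__ = [
    "InjectionContext",
    "BindingConstants",
    "SeriesConsistency",
    "ThomasPeakModel",
    "ThomasPeakResults",
    "FitReport",
    "initial_guess",
    "fit_thomas",
    "fit_peak_series",
    "constants_from_fit",
    "series_consistency",
]


@dataclass(frozen=True)
class InjectionContext:
    """Injection conditions needed to put fitted parameters on absolute scales.

    concentration: injected solute concentration (mol/L);
    injection_volume: L; flow_rate: mL/min; t0: void time (minutes).
    ``c0`` may be given explicitly; by default it is the injected
    concentration times the pulse width (V_inj / F) expressed in units of
    t0, which makes K_A = a3/C0 come out in L/mol.
    """

    concentration: float
    injection_volume: float = 10e-6
    flow_rate: float = 0.2
    t0: float = 1.9
    c0: float | None = None

    def __post_init__(self) -> None:
        if self.concentration <= 0 or self.injection_volume <= 0:
            raise ValueError("concentration and injection volume must be positive")
        if self.flow_rate <= 0 or self.t0 <= 0:
            raise ValueError("flow rate and t0 must be positive")
        if self.c0 is not None and self.c0 <= 0:
            raise ValueError("explicit C0 must be positive")

    @property
    def pulse_width_reduced(self) -> float:
        """Injection pulse width (V_inj / F) in units of t0 (dimensionless)."""
        return (self.injection_volume / (self.flow_rate * 1e-3)) / self.t0

    @property
    def C0(self) -> float:
        """Effective injected concentration in reduced time (mol/L)."""
        if self.c0 is not None:
            return self.c0
        return self.concentration * self.pulse_width_reduced

    @property
    def t0_s(self) -> float:
        """Void time in seconds (kinetic constants are per second)."""
        return self.t0 * 60.0

    @property
    def injected_moles(self) -> float:
        return self.concentration * self.injection_volume


@dataclass(frozen=True)
class BindingConstants:
    """K_A (L/mol), k_a (1/(s*M)), k_d (1/s) with their provenance."""

    K_A: float
    k_a: float
    k_d: float
    params: ThomasParams | None = None
    context: InjectionContext | None = None

    def __post_init__(self) -> None:
        if not (self.K_A > 0 and self.k_a > 0 and self.k_d > 0):
            raise ValueError("binding constants must be positive")
        if abs(self.k_a - self.k_d * self.K_A) > 1e-12 * self.k_a:
            raise ValueError("k_a must equal k_d * K_A")


def constants_from_fit(params: ThomasParams, ctx: InjectionContext) -> BindingConstants:
    """K_A = a3/C0, k_d = 1/(a2*t0 [s]), k_a = k_d*K_A."""
    if params.a3 <= 0:
        raise ValueError("a3 must be positive to derive K_A")
    K_A = params.a3 / ctx.C0
    k_d = 1.0 / (params.a2 * ctx.t0_s)
    return BindingConstants(K_A=K_A, k_a=k_d * K_A, k_d=k_d, params=params, context=ctx)


# ---------------------------------------------------------------------------
# Initial guess
# ---------------------------------------------------------------------------

def initial_guess(peak: ReducedPeak) -> ThomasParams:
    """Deterministic moment-style starting values for the profile fit.

    a0 = trapezoidal area; a1 = midpoint of the apex and the rear
    half-maximum crossing (an overloaded peak fronts, shifting the apex
    below the center while the diffuse rear tail still ends near it; for
    a symmetric peak the midpoint is only mildly biased); a2 =
    Gaussian-equivalent variance (FWHM/2.355)^2 / a1, clamped to
    [1e-4, a1]; a3 = 0.05.
    """
    y = peak.y
    if y.max() <= 0 or np.ptp(y) == 0:
        raise ValueError("no detectable apex in the peak")
    i = int(np.argmax(y))
    a0 = float(np.trapezoid(y, peak.x))
    if a0 <= 0:
        raise ValueError("non-positive peak area")
    half = 0.5 * y[i]
    above = y >= half
    xs = peak.x[above]
    x_rear = float(xs[-1]) if xs.size > 1 else float(peak.x[i])
    fwhm = float(xs[-1] - xs[0]) if xs.size > 1 else float(peak.x[1] - peak.x[0])
    a1 = 0.5 * (float(peak.x[i]) + x_rear)
    a2 = float(np.clip((fwhm / 2.355) ** 2 / a1, 1e-4, a1))
    return ThomasParams(a0=a0, a1=a1, a2=a2, a3=0.05)


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

_PARAM_NAMES = ("a0", "a1", "a2", "a3")


@dataclass
class ThomasPeakResults:
    """Fit results: parameter estimates, standard errors and diagnostics."""

    params: ThomasParams
    bse: np.ndarray
    rms: float
    converged: bool
    n_iter: int
    n_obs: int
    context: InjectionContext | None = None
    model: "ThomasPeakModel | None" = field(default=None, repr=False)

    @property
    def binding_constants(self) -> BindingConstants:
        if self.context is None:
            raise ValueError("no injection context attached to this fit")
        return constants_from_fit(self.params, self.context)

    def predict(self, x=None) -> np.ndarray:
        if x is None:
            if self.model is None:
                raise ValueError("no model attached; pass x explicitly")
            x = self.model.peak.x
        return thomas_profile(x, self.params)

    def summary(self) -> str:
        lines = [
            "Nonlinear chromatography peak fit (Thomas/Wade model)",
            "=" * 56,
            f"{'n obs':<22}{self.n_obs:>12d}",
            f"{'residual RMS':<22}{self.rms:>12.4g}",
            f"{'converged':<22}{str(self.converged):>12}",
            f"{'iterations':<22}{self.n_iter:>12d}",
            "-" * 56,
            f"{'param':<8}{'estimate':>14}{'std err':>14}",
        ]
        for name, est, se in zip(_PARAM_NAMES, self.params.as_array(), self.bse):
            lines.append(f"{name:<8}{est:>14.6g}{se:>14.3g}")
        if self.context is not None and self.params.a3 > 0:
            bc = self.binding_constants
            lines += [
                "-" * 56,
                f"{'K_A (L/mol)':<22}{bc.K_A:>12.4g}",
                f"{'k_d (1/s)':<22}{bc.k_d:>12.4g}",
                f"{'k_a (1/(s*M))':<22}{bc.k_a:>12.4g}",
            ]
        lines.append("=" * 56)
        return "\n".join(lines)

    def plot(self, ax=None):
        """Observed points and fitted curve on reduced coordinates."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = self.model.peak.x if self.model is not None else None
        if x is not None:
            ax.plot(x, self.model.peak.y, ".", ms=2, alpha=0.5, label="observed")
            ax.plot(x, self.predict(x), "-", label="fitted")
        ax.set_xlabel("reduced time x = t/t0")
        ax.set_ylabel("reduced signal y = Y/C0")
        ax.legend()
        return ax


FitReport = ThomasPeakResults  # the report emitted per fitted concentration


class ThomasPeakModel:
    """Nonlinear peak model bound to one reduced, baseline-corrected peak.

    Parameters
    ----------
    peak : ReducedPeak
        Reduced coordinates of a single dominant peak (>= 50 points).
    ctx : InjectionContext, optional
        Needed for binding constants; the shape fit itself is unitless.
    """

    MAX_NFEV = 2500  # ~500 iterations of 4-parameter forward differences

    def __init__(self, peak: ReducedPeak, ctx: InjectionContext | None = None):
        if len(peak.x) < 50:
            raise ValueError(f"need >= 50 points across the peak, got {len(peak.x)}")
        self.peak = peak
        self.ctx = ctx

    @classmethod
    def from_chromatogram(
        cls,
        chrom,
        ctx: InjectionContext,
        window: str | None = "auto",
        signal_floor_frac: float = 0.005,
    ) -> "ThomasPeakModel":
        """Reduce a chromatogram (x = t/t0, y = Y/C0) and optionally trim to
        the contiguous window around the apex where the signal exceeds
        ``signal_floor_frac`` of the maximum (padded by 25% of the window).
        Fitting the flat baseline adds nothing and slows the solver."""
        peak = ReducedPeak.from_chromatogram(chrom, ctx.t0, ctx.C0)
        if window == "auto":
            y = peak.y
            i = int(np.argmax(y))
            thr = signal_floor_frac * y[i]
            above = y > thr
            lo = i
            while lo > 0 and above[lo - 1]:
                lo -= 1
            hi = i
            while hi < y.size - 1 and above[hi + 1]:
                hi += 1
            pad = max(10, (hi - lo) // 4)
            lo = max(0, lo - pad)
            hi = min(y.size - 1, hi + pad)
            if hi - lo + 1 >= 50:
                peak = ReducedPeak(peak.x[lo : hi + 1], peak.y[lo : hi + 1])
        return cls(peak, ctx)

    def _residuals(self, log_p: np.ndarray) -> np.ndarray:
        p = ThomasParams.from_array(np.exp(log_p))
        return thomas_profile(self.peak.x, p) - self.peak.y

    _A2_CANDIDATES = (0.05, 0.1, 0.2, 0.4, 0.7, 1.0, 1.5, 3.0)

    _LOG_BOUND = 50.0  # parameters confined to e^+-50: generous yet finite

    def _solve(self, p0: ThomasParams):
        b = self._LOG_BOUND
        x0 = np.clip(np.log(p0.as_array()), -b + 1e-6, b - 1e-6)
        return least_squares(
            self._residuals,
            x0,
            bounds=(-b, b),
            method="trf",
            xtol=1e-10,
            ftol=1e-10,
            gtol=None,
            max_nfev=self.MAX_NFEV,
        )

    def _solve_fixed_a2(self, p0: ThomasParams, a2: float):
        """3-parameter (a0, a1, a3) fit with the width parameter pinned."""

        def resid(log_p):
            p = ThomasParams(np.exp(log_p[0]), np.exp(log_p[1]), a2, np.exp(log_p[2]))
            return thomas_profile(self.peak.x, p) - self.peak.y

        b = self._LOG_BOUND
        x0 = np.clip(np.log([p0.a0, p0.a1, p0.a3]), -b + 1e-6, b - 1e-6)
        return least_squares(resid, x0, bounds=(-b, b), method="trf",
                             xtol=1e-12, ftol=1e-12, gtol=None, max_nfev=400)

    def _profile_a2(self, base: ThomasParams) -> tuple[ThomasParams | None, int]:
        """Minimize the profiled cost over log(a2).

        For each pinned a2 the remaining parameters are refitted, which
        makes the 1-D profiled cost smooth and unimodal around the
        optimum even when the joint 4-parameter valley is too narrow and
        curved for the trust-region solver to track.  A coarse
        multiplicative bracket is followed by bounded Brent refinement.
        """
        from scipy.optimize import minimize_scalar

        nfev = 0
        best = {"cost": np.inf, "p": base}

        def profiled(log_a2: float) -> float:
            # every refit warm-starts from the same neutral stage-1 state:
            # a state already compensated for one pinned a2 biases the
            # next refit and makes the profile path-dependent
            nonlocal nfev
            a2 = float(np.exp(log_a2))
            res3 = self._solve_fixed_a2(base, a2)
            nfev += int(res3.nfev)
            cost = float(res3.cost)
            if cost < best["cost"]:
                a0_c, a1_c, a3_c = np.exp(res3.x)
                best["cost"] = cost
                best["p"] = ThomasParams(a0_c, a1_c, a2, a3_c)
            return cost

        log_base = np.log(base.a2)
        grid = log_base + np.log(self._A2_CANDIDATES)
        costs = [profiled(g) for g in grid]
        i = int(np.argmin(costs))
        lo = grid[i] - 1.0 if i == 0 else grid[i - 1]
        hi = grid[i] + 1.0 if i == len(grid) - 1 else grid[i + 1]
        minimize_scalar(
            profiled, bounds=(lo, hi), method="bounded",
            options={"xatol": 2e-4, "maxiter": 40},
        )
        return best["p"], nfev

    def fit(self, start: ThomasParams | None = None, refine_a2: bool = True) -> ThomasPeakResults:
        """Positive-parameter least squares (trust-region on log-parameters).

        Converged when the relative cost change or step drops below 1e-10;
        non-convergence within the iteration budget is reported via the
        ``converged`` flag, not an exception.

        Under overload the cost surface is nearly flat in a2 (the kinetic
        front sharpness) except for a narrow well at the value that matches
        the sampled front, so a width-based cold start can settle in a
        local minimum with the other three parameters already correct.
        With ``refine_a2`` the solver therefore profiles a2 over a
        multiplicative candidate grid around its first solution (refitting
        a0, a1, a3 at each pinned a2) and polishes all four parameters
        from the best candidate, keeping whichever solution has the lowest
        cost.
        """
        p0 = start if start is not None else initial_guess(self.peak)
        res = self._solve(p0)
        nfev = int(res.nfev)
        # residual floor below which the stage-1 solution is already exact
        # (no information left for the profile refinement to use)
        floor = 1e-12 * float(np.max(np.abs(self.peak.y))) * np.sqrt(self.peak.y.size)
        if refine_a2 and np.sqrt(2.0 * res.cost) > floor:
            best_params, extra = self._profile_a2(
                ThomasParams.from_array(np.exp(res.x))
            )
            nfev += extra
            res_p = self._solve(best_params)
            nfev += int(res_p.nfev)
            if res_p.cost < res.cost:
                res = res_p
        params = ThomasParams.from_array(np.exp(res.x))
        m, n = self.peak.x.size, 4
        rms = float(np.sqrt(2.0 * res.cost / m))
        # standard errors on the natural scale: J_nat = J_log / p
        bse = np.full(n, np.nan)
        if m > n:
            s2 = 2.0 * res.cost / (m - n)
            jac_nat = res.jac / np.exp(res.x)[None, :]
            try:
                cov = s2 * np.linalg.inv(jac_nat.T @ jac_nat)
                diag = np.diag(cov)
                bse = np.sqrt(np.where(diag > 0, diag, np.nan))
            except np.linalg.LinAlgError:
                pass
        converged = bool(res.status > 0)
        return ThomasPeakResults(
            params=params,
            bse=bse,
            rms=rms,
            converged=converged,
            n_iter=nfev,
            n_obs=m,
            context=self.ctx,
            model=self,
        )


def fit_thomas(peak: ReducedPeak, ctx: InjectionContext | None = None,
               start: ThomasParams | None = None) -> ThomasPeakResults:
    """Fit the nonlinear peak model to a reduced peak (functional form)."""
    return ThomasPeakModel(peak, ctx).fit(start=start)


def fit_peak_series(
    chroms,
    ctxs: list[InjectionContext],
    window: str | None = "auto",
) -> list[tuple[float, ThomasPeakResults]]:
    """Fit a dilution series of chromatograms, lowest concentration first.

    The lowest-overload peak carries the cleanest kinetic information, so
    it is fitted with full a2 profiling and each subsequent concentration
    is warm-started from the previous solution with the distortion scaled
    by the concentration ratio (a1 and a2 are concentration-invariant
    under the model, a3 is proportional to the injected concentration).
    Returns (concentration, results) pairs in ascending concentration.
    """
    if len(chroms) != len(ctxs):
        raise ValueError("need one injection context per chromatogram")
    order = np.argsort([c.concentration for c in ctxs])
    out: list[tuple[float, ThomasPeakResults]] = []
    prev: ThomasParams | None = None
    prev_c: float | None = None
    for i in order:
        ctx = ctxs[i]
        model = ThomasPeakModel.from_chromatogram(chroms[i], ctx, window=window)
        if prev is None:
            res = model.fit()
        else:
            warm = ThomasParams(prev.a0, prev.a1, prev.a2,
                                prev.a3 * ctx.concentration / prev_c)
            res = model.fit(start=warm, refine_a2=False)
        prev, prev_c = res.params, ctx.concentration
        out.append((ctx.concentration, res))
    return out


# ---------------------------------------------------------------------------
# Concentration-series consistency
# ---------------------------------------------------------------------------

@dataclass
class SeriesConsistency:
    """Stability of K_A (= a3/C0), a1 and a2 across a concentration series.

    Under the model, a3 scales with the injected amount so that K_A stays
    constant, while a1 (thermodynamic retention) and a2 (kinetics) are
    concentration-independent.  The series is flagged consistent when the
    coefficient of variation of each of K_A, a1, a2 is <= ``cv_threshold``
    percent.
    """

    cv_K_A: float
    cv_a1: float
    cv_a2: float
    K_A_values: np.ndarray
    concentrations: np.ndarray
    cv_threshold: float = 20.0

    @property
    def consistent(self) -> bool:
        return bool(
            self.cv_K_A <= self.cv_threshold
            and self.cv_a1 <= self.cv_threshold
            and self.cv_a2 <= self.cv_threshold
        )

    def summary(self) -> str:
        flag = "CONSISTENT" if self.consistent else "INCONSISTENT"
        return (
            f"series consistency ({flag} at CV <= {self.cv_threshold:.0f}%): "
            f"CV[K_A]={self.cv_K_A:.1f}%  CV[a1]={self.cv_a1:.1f}%  CV[a2]={self.cv_a2:.1f}%"
        )


def _cv_percent(values: np.ndarray) -> float:
    mean = float(np.mean(values))
    if mean == 0:
        return float("inf")
    return 100.0 * float(np.std(values, ddof=1)) / abs(mean)


def series_consistency(
    fits: list[tuple[float, ThomasPeakResults]],
    ctxs: list[InjectionContext] | None = None,
    cv_threshold: float = 20.0,
) -> SeriesConsistency:
    """Check one-site behaviour of fits across >= 3 injected concentrations."""
    if len(fits) < 3:
        raise ValueError(f"need >= 3 concentrations, got {len(fits)}")
    concs = np.array([c for c, _ in fits], dtype=float)
    if ctxs is None:
        ctxs = [f.context for _, f in fits]
    if any(c is None for c in ctxs):
        raise ValueError("every fit needs an injection context")
    not_conv = [c for (c, f) in fits if not f.converged]
    if not_conv:
        warnings.warn(f"non-converged fits at concentrations {not_conv}", stacklevel=2)
    K_A = np.array([f.params.a3 / ctx.C0 for (_, f), ctx in zip(fits, ctxs)])
    a1 = np.array([f.params.a1 for _, f in fits])
    a2 = np.array([f.params.a2 for _, f in fits])
    return SeriesConsistency(
        cv_K_A=_cv_percent(K_A),
        cv_a1=_cv_percent(a1),
        cv_a2=_cv_percent(a2),
        K_A_values=K_A,
        concentrations=concs,
        cv_threshold=cv_threshold,
    )
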