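"""Injection-amount-dependent (zonal) binding analysis.

Small pulses of ligand are injected at increasing amounts; retention falls
as binding sites saturate.  With n_b the injected moles, k' the capacity
factor and Vm the system volume, the data linearize as

    k' n_b / (1 + k')  =  n_t  -  (1/K_A) * k' Vm

so an ordinary least-squares line of Y = k'n_b/(1+k') on X = k'Vm yields
the association constant K_A = -1/slope (L/mol) and the binding-site
amount n_t = intercept.  Two straight segments in the same plot indicate
two classes of binding sites with distinct affinities; ``split_regimes``
fits and adjudicates the segmented alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .chromatograms import ColumnSystem, capacity_factor

__all__ = [
    "ZonalPoint",
    "ZonalFit",
    "ZonalBindingModel",
    "make_zonal_points",
    "fit_zonal_line",
    "split_regimes",
]


@dataclass(frozen=True)
class ZonalPoint:
    """One linearized observation of the saturation line.

    n_b: injected moles; X = k'*Vm (L); Y = k'*n_b/(1+k') (mol).
    """

    concentration: float
    k_prime: float
    n_b: float
    X: float
    Y: float


@dataclass
class ZonalFit:
    """OLS fit of Y on X with the derived binding constants.

    K_A = -1/slope (L/mol, defined only for negative slope) with a
    first-order-propagated standard error; n_t is the intercept in its own
    units (mol; divide by the column volume for a site concentration).
    """

    slope: float
    intercept: float
    r_squared: float
    slope_se: float
    intercept_se: float
    n_points: int
    concentration_range: tuple[float, float]
    regime: str = "single"
    diagnostic: str = ""

    @property
    def K_A(self) -> float | None:
        if self.slope >= 0:
            return None
        return -1.0 / self.slope

    @property
    def K_A_se(self) -> float | None:
        if self.slope >= 0:
            return None
        return self.slope_se / self.slope**2

    @property
    def n_t(self) -> float:
        return self.intercept

    def equation(self) -> str:
        """Regression line in the conventional printed form."""
        return f"Y = {self.intercept:.3g} - {-self.slope:.3g}*X"

    def summary(self) -> str:
        ka = self.K_A
        ka_str = f"{ka:.4g} L/mol" if ka is not None else "undefined (slope >= 0)"
        lines = [
            "Zonal (injection-amount-dependent) binding fit",
            "=" * 50,
            f"{'regime':<24}{self.regime:>24}",
            f"{'points':<24}{self.n_points:>24d}",
            f"{'conc range (mol/L)':<24}"
            f"{self.concentration_range[0]:.3g} - {self.concentration_range[1]:.3g}".rjust(24),
            f"{'equation':<24}{self.equation():>24}",
            f"{'R^2':<24}{self.r_squared:>24.4f}",
            f"{'K_A':<24}{ka_str:>24}",
            f"{'n_t (mol)':<24}{self.n_t:>24.4g}",
        ]
        if self.diagnostic:
            lines.append(f"note: {self.diagnostic}")
        lines.append("=" * 50)
        return "\n".join(lines)


def make_zonal_points(
    records: list[tuple[float, float]],
    system: ColumnSystem,
    injection_volume: float = 10e-6,
) -> list[ZonalPoint]:
    """Build linearized points from (concentration mol/L, tR min) records.

    Records whose retention does not exceed the void time carry no binding
    signal (k' <= 0); they are excluded with a warning.
    """
    if len(records) < 3:
        raise ValueError(f"need >= 3 records, got {len(records)}")
    concs = [c for c, _ in records]
    if any(b <= a for a, b in zip(concs, concs[1:])):
        raise ValueError("concentrations must be strictly increasing")
    points: list[ZonalPoint] = []
    for conc, tR in records:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            k = capacity_factor(tR, system.t0)
        if k <= 0:
            warnings.warn(
                f"record (c={conc}, tR={tR}) has k'={k:.3g} <= 0; excluded",
                stacklevel=2,
            )
            continue
        n_b = conc * injection_volume
        points.append(
            ZonalPoint(
                concentration=conc,
                k_prime=k,
                n_b=n_b,
                X=k * system.pipeline_volume,
                Y=k * n_b / (1.0 + k),
            )
        )
    return points


def fit_zonal_line(points: list[ZonalPoint], regime: str = "single") -> ZonalFit:
    """Ordinary least squares of Y on X; K_A and n_t from slope/intercept."""
    if len(points) < 3:
        raise ValueError(f"need >= 3 points, got {len(points)}")
    x = np.array([p.X for p in points])
    y = np.array([p.Y for p in points])
    res = stats.linregress(x, y)
    diagnostic = ""
    if res.slope >= 0:
        diagnostic = "non-negative slope: no saturation trend, K_A undefined"
    concs = [p.concentration for p in points]
    return ZonalFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        slope_se=float(res.stderr),
        intercept_se=float(res.intercept_stderr),
        n_points=len(points),
        concentration_range=(min(concs), max(concs)),
        regime=regime,
        diagnostic=diagnostic,
    )


def _sse(points: list[ZonalPoint], fit: ZonalFit) -> float:
    x = np.array([p.X for p in points])
    y = np.array([p.Y for p in points])
    return float(np.sum((y - (fit.intercept + fit.slope * x)) ** 2))


def split_regimes(
    points: list[ZonalPoint],
    breakpoint_concentration: float | str | None = "auto",
) -> tuple[ZonalFit, ZonalFit] | ZonalFit:
    """Fit one or two concentration regimes.

    With a numeric breakpoint the points are split at that injected
    concentration (low regime inclusive) and each side is fitted.  With
    ``"auto"`` every admissible split (>= 3 points per side, in
    concentration order) is tried and the one minimizing the pooled
    residual sum of squares is kept; two regimes are reported only when
    both segment R^2 exceed the single-line R^2 and the segment slopes
    differ by more than twice their pooled standard error, otherwise the
    single line is returned.  Fewer than 6 points fall back to a single
    fit with a warning.
    """
    points = sorted(points, key=lambda p: p.concentration)
    single = fit_zonal_line(points)
    if len(points) < 6:
        if breakpoint_concentration is not None:
            warnings.warn("fewer than 6 points: falling back to a single regime", stacklevel=2)
        return single

    def two_fits(i: int) -> tuple[ZonalFit, ZonalFit]:
        lo = fit_zonal_line(points[:i], regime="low")
        hi = fit_zonal_line(points[i:], regime="high")
        return lo, hi

    if breakpoint_concentration is None:
        return single
    if breakpoint_concentration == "auto":
        best: tuple[ZonalFit, ZonalFit] | None = None
        best_sse = np.inf
        for i in range(3, len(points) - 2):
            lo, hi = two_fits(i)
            sse = _sse(points[:i], lo) + _sse(points[i:], hi)
            if sse < best_sse:
                best_sse = sse
                best = (lo, hi)
        assert best is not None
        lo, hi = best
        better_r2 = (
            lo.r_squared > single.r_squared and hi.r_squared > single.r_squared
        )
        pooled_se = float(np.hypot(lo.slope_se, hi.slope_se))
        distinct = abs(lo.slope - hi.slope) > 2.0 * pooled_se
        if better_r2 and distinct:
            return lo, hi
        return single
    bp = float(breakpoint_concentration)
    n_low = sum(p.concentration <= bp for p in points)
    if n_low < 3 or len(points) - n_low < 3:
        warnings.warn(
            f"breakpoint {bp} leaves a segment with < 3 points; single regime returned",
            stacklevel=2,
        )
        return single
    return two_fits(n_low)


class ZonalBindingModel:
    """Zonal binding analysis bound to one drug's (concentration, tR) series.

    Statsmodels-style front end: build from raw retention records plus the
    column system, then ``fit()`` for a single line or
    ``fit(breakpoint="auto")`` to adjudicate one vs two binding-site
    classes.
    """

    def __init__(self, points: list[ZonalPoint]):
        if len(points) < 3:
            raise ValueError("need >= 3 zonal points")
        self.points = sorted(points, key=lambda p: p.concentration)

    @classmethod
    def from_records(
        cls,
        records: list[tuple[float, float]],
        system: ColumnSystem,
        injection_volume: float = 10e-6,
    ) -> "ZonalBindingModel":
        return cls(make_zonal_points(records, system, injection_volume))

    def fit(
        self, breakpoint: float | str | None = None
    ) -> ZonalFit | tuple[ZonalFit, ZonalFit]:
        if breakpoint is None:
            return fit_zonal_line(self.points)
        return split_regimes(self.points, breakpoint)
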