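"""Ground-truth-known synthetic data generators.

Every analysis stage in this package can be exercised without instrument
data: the generators produce overloaded elution peaks, zonal retention
series and screening mixtures from known binding constants, so parameter
recovery can be checked against the truth that produced the data.  All
generators are pure functions of (truth, seed): identical inputs give
bit-identical output, and every manifest records the truth and the seed.

The noise model is additive i.i.d. Gaussian on the signal with standard
deviation expressed as a fraction of the apex height, plus an optional
linear baseline drift.  Detector autocorrelation, pump ripple and
injection-to-injection variability are not emulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import brentq

from .chromatograms import Chromatogram, ChromatogramMeta, ColumnSystem
from .fitting import InjectionContext
from .thomas import ThomasParams, simulate_peak

__all__ = [
    "SyntheticTruth",
    "ZonalTruth",
    "generate_peak_series",
    "generate_zonal_dataset",
    "generate_screening_mixture",
]

MAX_OVERLOAD = 50.0  # a3 beyond this is outside the model's useful range


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for an overloaded-peak concentration series.

    K_A: association constant (L/mol); k_d: desorption rate (1/s);
    k_prime: thermodynamic capacity factor (the reduced peak center is
    1 + k_prime); t0: void time (min); flow_rate mL/min; injection_volume
    L; concentrations mol/L (strictly increasing); noise_sd as a fraction
    of the apex height; drift_slope in signal units per minute; a0 is the
    detector response factor (reduced-area units; 1 corresponds to a
    mass-balanced concentration detector).
    """

    K_A: float
    k_d: float
    k_prime: float
    concentrations: tuple[float, ...]
    t0: float = 1.9
    flow_rate: float = 0.2
    injection_volume: float = 10e-6
    noise_sd: float = 0.01
    drift_slope: float = 0.0
    a0: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.K_A, self.k_d, self.k_prime, self.t0, self.flow_rate,
               self.injection_volume, self.a0) <= 0:
            raise ValueError("K_A, k_d, k_prime, t0, flow, V_inj, a0 must be positive")
        cs = self.concentrations
        if len(cs) < 1 or any(b <= a for a, b in zip(cs, cs[1:])) or cs[0] <= 0:
            raise ValueError("concentrations must be positive and strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def a1(self) -> float:
        return 1.0 + self.k_prime

    @property
    def a2(self) -> float:
        return 1.0 / (self.k_d * self.t0 * 60.0)

    def context(self, concentration: float) -> InjectionContext:
        return InjectionContext(
            concentration=concentration,
            injection_volume=self.injection_volume,
            flow_rate=self.flow_rate,
            t0=self.t0,
        )


def generate_peak_series(
    truth: SyntheticTruth,
    grid_dt_min: float = 0.005,
    t_max_min: float | None = None,
) -> tuple[list[Chromatogram], dict]:
    """Simulate one overloaded peak per concentration, with noise and drift.

    Per concentration c: C0 = c * ((V_inj/F)/t0), a3 = K_A * C0,
    a1 = 1 + k', a2 = 1/(k_d * t0[s]); the reduced profile is mapped to
    clock time and scaled back to a physical signal (Y = y * C0).  The
    manifest records the truth and the per-run (a0..a3, C0).
    """
    rng = np.random.default_rng(truth.seed)
    chroms: list[Chromatogram] = []
    runs: list[dict] = []
    for conc in truth.concentrations:
        ctx = truth.context(conc)
        a3 = truth.K_A * ctx.C0
        if a3 > MAX_OVERLOAD:
            raise ValueError(
                f"a3 = {a3:.1f} > {MAX_OVERLOAD} at c = {conc} mol/L: extreme "
                "overload; lower the concentration"
            )
        params = ThomasParams(truth.a0, truth.a1, truth.a2, a3)
        chrom = simulate_peak(params, truth.t0, grid_dt_min, t_max_min)
        signal = chrom.signal * ctx.C0  # physical detector trace
        if truth.noise_sd > 0:
            signal = signal + rng.normal(0.0, truth.noise_sd * signal.max(), signal.size)
        if truth.drift_slope != 0.0:
            signal = signal + truth.drift_slope * chrom.time
        meta = ChromatogramMeta(
            analyte="synthetic",
            concentration=conc,
            injection_volume=truth.injection_volume,
            flow_rate=truth.flow_rate,
        )
        chroms.append(Chromatogram(chrom.time, signal, meta))
        runs.append({"concentration": conc, "C0": ctx.C0,
                     "a0": truth.a0, "a1": truth.a1, "a2": truth.a2, "a3": a3})
    manifest = {"truth": asdict(truth), "seed": truth.seed, "runs": runs,
                "grid_dt_min": grid_dt_min}
    return chroms, manifest


# ---------------------------------------------------------------------------
# Zonal datasets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ZonalTruth:
    """Ground truth for a zonal retention series.

    K_A (L/mol) and n_t (mol) define the saturation line; a biphasic
    column is described by (K_A2, n_t2) above ``breakpoint`` (mol/L).
    tR_noise_sd is a fractional Gaussian perturbation of the retention
    times.
    """

    K_A: float
    n_t: float
    concentrations: tuple[float, ...]
    t0: float = 1.9
    flow_rate: float = 0.2
    injection_volume: float = 10e-6
    pipeline_volume: float | None = None
    K_A2: float | None = None
    n_t2: float | None = None
    breakpoint: float | None = None
    tR_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K_A <= 0 or self.n_t <= 0:
            raise ValueError("K_A and n_t must be positive")
        cs = self.concentrations
        if len(cs) < 3 or any(b <= a for a, b in zip(cs, cs[1:])):
            raise ValueError("need >= 3 strictly increasing concentrations")
        if (self.K_A2 is None) != (self.breakpoint is None):
            raise ValueError("biphasic truth needs both K_A2 and breakpoint")
        if self.breakpoint is not None:
            if not (cs[0] <= self.breakpoint < cs[-1]):
                raise ValueError("breakpoint outside the concentration range")
            if len(cs) < 6:
                raise ValueError("biphasic series needs >= 6 concentrations")

    @property
    def system(self) -> ColumnSystem:
        return ColumnSystem(
            t0=self.t0, flow_rate=self.flow_rate, pipeline_volume=self.pipeline_volume
        )


def _solve_k_prime(n_b: float, K_A: float, n_t: float, Vm: float) -> float:
    """Invert the saturation line for k' at a given injected amount.

    Solves k'*n_b/(1+k') + k'*Vm/K_A = n_t (monotone in k', unique root).
    """

    def f(k: float) -> float:
        return k * n_b / (1.0 + k) + k * Vm / K_A - n_t

    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e12:
            raise RuntimeError("no admissible capacity factor")
    return brentq(f, 0.0, hi, xtol=1e-15, rtol=1e-14)


def generate_zonal_dataset(truth: ZonalTruth) -> tuple[list[tuple[float, float]], dict]:
    """Produce (concentration, tR) records consistent with the saturation
    line; biphasic truths switch (K_A, n_t) at the breakpoint."""
    rng = np.random.default_rng(truth.seed)
    system = truth.system
    records: list[tuple[float, float]] = []
    for conc in truth.concentrations:
        if truth.breakpoint is not None and conc > truth.breakpoint:
            K_A, n_t = truth.K_A2, (truth.n_t2 if truth.n_t2 is not None else truth.n_t)
        else:
            K_A, n_t = truth.K_A, truth.n_t
        n_b = conc * truth.injection_volume
        k = _solve_k_prime(n_b, K_A, n_t, system.pipeline_volume)
        tR = truth.t0 * (1.0 + k)
        if truth.tR_noise_sd > 0:
            tR *= 1.0 + rng.normal(0.0, truth.tR_noise_sd)
        records.append((conc, tR))
    manifest = {"truth": asdict(truth), "seed": truth.seed,
                "Vm": system.pipeline_volume}
    return records, manifest


# ---------------------------------------------------------------------------
# Screening mixtures
# ---------------------------------------------------------------------------

def generate_screening_mixture(
    binders: list[tuple[float, float]],
    nonbinder_amount: float,
    system: ColumnSystem,
    n_t: float = 2.4e-8,
    k_d: float = 60.0,
    noise_sd: float = 0.01,
    grid_dt_min: float = 0.005,
    seed: int = 0,
) -> Chromatogram:
    """Simulate an extract-like run: a void-time peak of co-eluting
    non-binders plus one overloaded peak per binder.

    ``binders`` is a list of (K_A L/mol, injected concentration mol/L);
    each binder's capacity factor follows from the low-load limit of the
    saturation line, k' = K_A * n_t / Vm.  ``nonbinder_amount`` scales a
    Gaussian peak at the void time (zero for none).
    """
    a2 = 1.0 / (k_d * system.t0 * 60.0)
    k_primes = [K_A * n_t / system.pipeline_volume for K_A, _ in binders]
    t_max = system.t0 * (2.0 + 2.0 * (1.0 + max(k_primes, default=1.0)))
    t = np.arange(grid_dt_min, t_max + 0.5 * grid_dt_min, grid_dt_min)
    signal = np.zeros_like(t)
    if nonbinder_amount > 0:
        width = 0.08 * system.t0
        signal += nonbinder_amount * np.exp(-0.5 * ((t - system.t0) / width) ** 2)
    for (K_A, conc), k in zip(binders, k_primes):
        ctx = InjectionContext(
            concentration=conc, flow_rate=system.flow_rate, t0=system.t0
        )
        a3 = min(K_A * ctx.C0, MAX_OVERLOAD)
        params = ThomasParams(1.0, 1.0 + k, a2, a3)
        peak = simulate_peak(params, system.t0, grid_dt_min, t_max)
        signal += np.interp(t, peak.time, peak.signal * ctx.C0)
    if noise_sd > 0 and signal.max() > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd * signal.max(), signal.size)
    meta = ChromatogramMeta(analyte="mixture", flow_rate=system.flow_rate)
    return Chromatogram(t, signal, meta)
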