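"""Two-column specificity screening and stability QC.

The screening idea: the same ligand is run on two affinity columns carrying
the immobilized receptor in different conformational states.  On the
conformation-constrained ("two-point") column antagonist-type ligands are
retained more strongly than on the conventional ("single-point") column,
agonist-type ligands more weakly, and non-binders elute with the void
marker on both.  Comparing void-referenced retention (tR/t0) between the
columns therefore labels each ligand without any activity assay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chromatograms import ColumnSystem, PeakRecord

__all__ = [
    "LigandClassification",
    "StabilityReport",
    "classify_ligand_mode",
    "collect_candidates",
    "stability_rsd",
]


@dataclass(frozen=True)
class LigandClassification:
    """Two-column retention comparison for one ligand."""

    analyte: str
    tR_two_point: float
    tR_single_point: float
    k_two_point: float
    k_single_point: float
    label: str  # non-binder | antagonist-like | agonist-like | indeterminate
    rationale: str


def classify_ligand_mode(
    tR_two: float,
    tR_single: float,
    t0_two: float,
    t0_single: float | None = None,
    epsilon: float = 0.15,
    delta: float = 0.05,
    analyte: str = "",
) -> LigandClassification:
    """Label a ligand from its retention on the two columns.

    epsilon: binding threshold on k' (retention must exceed the void time
    by this fraction to count as binding); delta: minimum relative shift
    of void-referenced retention between columns.  Rules:

    - non-binder: k' <= epsilon on both columns;
    - antagonist-like: binds the two-point column and its void-referenced
      retention there exceeds the single-point one by more than delta;
    - agonist-like: binds the single-point column and its two-point
      retention is reduced by more than delta;
    - otherwise indeterminate (never silently coerced).

    The comparison uses tR/t0 ratios, so it is invariant to a common
    rescaling of all times.
    """
    if t0_single is None:
        t0_single = t0_two
    for name, val in (("tR_two", tR_two), ("tR_single", tR_single),
                      ("t0_two", t0_two), ("t0_single", t0_single)):
        if val <= 0:
            raise ValueError(f"{name} must be positive, got {val}")
    k_two = (tR_two - t0_two) / t0_two
    k_single = (tR_single - t0_single) / t0_single
    r_two = tR_two / t0_two
    r_single = tR_single / t0_single
    if k_two <= epsilon and k_single <= epsilon:
        label = "non-binder"
        why = f"k'={k_two:.2f}/{k_single:.2f} on both columns <= {epsilon}"
    elif k_two > epsilon and r_two > (1.0 + delta) * r_single:
        label = "antagonist-like"
        why = (f"retention enhanced on the two-point column "
               f"(tR/t0 {r_two:.2f} > {1+delta:.2f} x {r_single:.2f})")
    elif k_single > epsilon and r_two < (1.0 - delta) * r_single:
        label = "agonist-like"
        why = (f"retention reduced on the two-point column "
               f"(tR/t0 {r_two:.2f} < {1-delta:.2f} x {r_single:.2f})")
    else:
        label = "indeterminate"
        why = f"retention shift within +/-{delta:.0%} or below the binding threshold"
    return LigandClassification(
        analyte=analyte,
        tR_two_point=tR_two,
        tR_single_point=tR_single,
        k_two_point=k_two,
        k_single_point=k_single,
        label=label,
        rationale=why,
    )


def collect_candidates(
    peaks: list[PeakRecord],
    system: ColumnSystem,
    epsilon: float = 0.15,
) -> list[PeakRecord]:
    """Keep peaks retained past the void time by more than ``epsilon``.

    Peaks with tR > (1 + epsilon) * t0 on the affinity column are the
    candidate binders of a complex mixture; the rest co-elute with the
    void and are dropped.  Order is preserved; an empty result is legal.
    Raising epsilon can only remove candidates.
    """
    cutoff = (1.0 + epsilon) * system.t0
    return [p for p in peaks if p.retention_time > cutoff]


@dataclass
class StabilityReport:
    """Relative standard deviations of retention time and peak area."""

    analyte: str
    days: np.ndarray
    tR: np.ndarray
    area: np.ndarray
    rsd_tR: float
    rsd_area: float
    threshold: float

    @property
    def passed(self) -> bool:
        return self.rsd_tR < self.threshold and self.rsd_area < self.threshold


def _rsd(values: np.ndarray) -> float:
    mean = float(np.mean(values))
    if mean <= 0:
        raise ValueError("mean of a stability series must be positive")
    if values.size < 2:
        return 0.0
    return 100.0 * float(np.std(values, ddof=1)) / mean


def stability_rsd(
    series: list[tuple[float, float, float]],
    threshold: float = 5.0,
    analyte: str = "",
) -> StabilityReport:
    """RSD (%) of tR and area over a (day, tR, area) series.

    Sample standard deviation (n-1 denominator); the series passes when
    both RSDs are below ``threshold`` (the conventional 5.0% column-
    stability acceptance).
    """
    if len(series) < 3:
        raise ValueError(f"need >= 3 stability measurements, got {len(series)}")
    arr = np.asarray(series, dtype=float)
    days, tR, area = arr[:, 0], arr[:, 1], arr[:, 2]
    return StabilityReport(
        analyte=analyte,
        days=days,
        tR=tR,
        area=area,
        rsd_tR=_rsd(tR),
        rsd_area=_rsd(area),
        threshold=threshold,
    )
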