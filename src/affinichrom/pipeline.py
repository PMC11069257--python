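"""End-to-end workflows tying the analysis stages together.

Each ``run_*`` function takes a validated :class:`RunConfig` plus input
paths or records and returns plain tabular results (pandas DataFrames)
ready to be written to CSV/JSON; the CLI in :mod:`affinichrom.cli` is a
thin wrapper around these.  Every output embeds a hash of the config that
produced it so results remain traceable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .chromatograms import (
    ChromatogramMeta,
    ColumnSystem,
    detect_apex_peak,
    read_chromatogram,
    remove_baseline,
)
from .fitting import InjectionContext, SeriesConsistency, fit_peak_series
from .screening import classify_ligand_mode, collect_candidates, stability_rsd
from .zonal import ZonalBindingModel, ZonalFit

logger = logging.getLogger("affinichrom")

__all__ = ["RunConfig", "run_nlc", "run_zonal", "run_screen", "run_qc"]


class RunConfig(BaseModel):
    """Schema-validated system constants and analysis thresholds.

    t0 minutes; flow_rate mL/min; injection_volume L; Vm L (None =
    void volume); epsilon/delta are the screening thresholds; seed feeds
    every stochastic stage.
    """

    t0: float = Field(gt=0)
    flow_rate: float = Field(default=0.2, gt=0)
    injection_volume: float = Field(default=10e-6, gt=0)
    Vm: float | None = Field(default=None)
    epsilon: float = 0.15
    delta: float = 0.05
    rsd_threshold: float = 5.0
    baseline_window_frac: float = 0.05
    min_height_frac: float = 0.05
    breakpoint: float | str | None = None
    seed: int = 0

    @field_validator("Vm")
    @classmethod
    def _vm_positive(cls, v: float | None) -> float | None:
        if v is not None and v <= 0:
            raise ValueError("Vm must be positive")
        return v

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate_json(Path(path).read_text(encoding="utf-8"))

    @property
    def system(self) -> ColumnSystem:
        return ColumnSystem(t0=self.t0, flow_rate=self.flow_rate, pipeline_volume=self.Vm)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_nlc(
    config: RunConfig,
    chromatogram_paths: list[str | Path],
    concentrations: list[float],
) -> tuple[pd.DataFrame, SeriesConsistency | None]:
    """Nonlinear-chromatography workflow over a concentration series.

    Baseline-correct each trace, reduce (x = t/t0, y = Y/C0), fit the
    peak model with series warm-starting, and convert to binding
    constants.  Non-converged fits are flagged in the table; the pipeline
    continues.  Unit conversions (minutes to seconds inside k_d) are
    logged.
    """
    if len(chromatogram_paths) != len(concentrations):
        raise ValueError("need one concentration per chromatogram")
    chroms = []
    ctxs = []
    for path, conc in zip(chromatogram_paths, concentrations):
        chrom = read_chromatogram(path, ChromatogramMeta(concentration=conc))
        chrom = remove_baseline(chrom, config.baseline_window_frac)
        chroms.append(chrom)
        ctxs.append(
            InjectionContext(
                concentration=conc,
                injection_volume=config.injection_volume,
                flow_rate=config.flow_rate,
                t0=config.t0,
            )
        )
    logger.info(
        "reducing %d traces with t0 = %.4g min (= %.4g s for kinetic constants)",
        len(chroms), config.t0, config.t0 * 60.0,
    )
    fits = fit_peak_series(chroms, ctxs)
    rows = []
    for conc, res in fits:
        row = {
            "concentration": conc,
            "a0": res.params.a0, "a1": res.params.a1,
            "a2": res.params.a2, "a3": res.params.a3,
            "rms": res.rms, "converged": res.converged,
            "config_hash": config.config_hash(),
        }
        if res.converged and res.params.a3 > 0:
            bc = res.binding_constants
            row.update(K_A=bc.K_A, k_a=bc.k_a, k_d=bc.k_d)
        else:
            logger.warning("fit at c=%g did not converge; constants omitted", conc)
        rows.append(row)
    table = pd.DataFrame(rows)
    consistency = None
    if sum(r.converged for _, r in fits) >= 3:
        conv = [(c, r) for c, r in fits if r.converged]
        from .fitting import series_consistency

        consistency = series_consistency(conv)
    return table, consistency


def run_zonal(
    config: RunConfig,
    records: list[tuple[float, float]] | str | Path,
) -> pd.DataFrame:
    """Zonal workflow: records (concentration_M, tR_min) to regime table."""
    if isinstance(records, (str, Path)):
        df = pd.read_csv(records)
        cols = [c.strip() for c in df.columns]
        df.columns = cols
        records = list(zip(df["concentration_M"], df["tR_min"]))
    model = ZonalBindingModel.from_records(
        records, config.system, config.injection_volume
    )
    fit = model.fit(breakpoint=config.breakpoint)
    fits: list[ZonalFit] = list(fit) if isinstance(fit, tuple) else [fit]
    rows = []
    for f in fits:
        rows.append({
            "regime": f.regime,
            "conc_low": f.concentration_range[0],
            "conc_high": f.concentration_range[1],
            "equation": f.equation(),
            "R2": f.r_squared,
            "K_A": f.K_A,
            "K_A_se": f.K_A_se,
            "n_t": f.n_t,
            "n_points": f.n_points,
            "diagnostic": f.diagnostic,
            "config_hash": config.config_hash(),
        })
    return pd.DataFrame(rows)


def run_screen(
    config: RunConfig,
    two_point: str | Path,
    single_point: str | Path | None = None,
) -> pd.DataFrame:
    """Screening workflow.

    With both columns: a retention table (analyte, tR_two_min,
    tR_single_min) is classified ligand by ligand.  With only the
    two-point path: the file is a chromatogram; peaks retained past the
    void are collected as candidates (no mode labels possible).
    """
    system = config.system
    if single_point is not None:
        df = pd.read_csv(two_point)
        singles = pd.read_csv(single_point) if str(single_point) != str(two_point) else df
        if "tR_single_min" in df.columns:
            merged = df
        else:
            merged = df.merge(singles, on="analyte", suffixes=("_two", "_single"))
        rows = []
        for _, rec in merged.iterrows():
            cl = classify_ligand_mode(
                rec["tR_two_min"], rec["tR_single_min"], config.t0,
                epsilon=config.epsilon, delta=config.delta,
                analyte=str(rec.get("analyte", "")),
            )
            rows.append({
                "analyte": cl.analyte,
                "tR_two_min": cl.tR_two_point,
                "tR_single_min": cl.tR_single_point,
                "k_two": cl.k_two_point,
                "k_single": cl.k_single_point,
                "label": cl.label,
                "rationale": cl.rationale,
                "config_hash": config.config_hash(),
            })
        return pd.DataFrame(rows)
    chrom = read_chromatogram(two_point)
    chrom = remove_baseline(chrom, config.baseline_window_frac)
    peaks = detect_apex_peak(chrom, config.min_height_frac, system)
    candidates = collect_candidates(peaks, system, config.epsilon)
    return pd.DataFrame([
        {
            "tR_min": p.retention_time,
            "height": p.height,
            "area": p.area,
            "k_prime": p.capacity_factor,
            "config_hash": config.config_hash(),
        }
        for p in candidates
    ])


def run_qc(config: RunConfig, series_path: str | Path) -> pd.DataFrame:
    """Stability QC over a (analyte, day, tR_min, area) CSV."""
    df = pd.read_csv(series_path)
    rows = []
    for analyte, grp in df.groupby("analyte"):
        rep = stability_rsd(
            list(zip(grp["day"], grp["tR_min"], grp["area"])),
            threshold=config.rsd_threshold,
            analyte=str(analyte),
        )
        rows.append({
            "analyte": analyte,
            "n": len(grp),
            "rsd_tR_pct": rep.rsd_tR,
            "rsd_area_pct": rep.rsd_area,
            "passed": rep.passed,
            "config_hash": config.config_hash(),
        })
    return pd.DataFrame(rows)
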