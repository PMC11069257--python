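"""Chromatogram containers, CSV I/O and basic peak measurements.

A chromatogram is a two-column time/intensity trace (time in minutes,
detector response in arbitrary units such as mAU) plus acquisition
metadata.  All retention bookkeeping is referenced to the void time
``t0`` of an unretained marker (sodium nitrite in the experiments this
package models), through the capacity factor ``k' = (tR - t0)/t0``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, savgol_filter

__all__ = [
    "Chromatogram",
    "ChromatogramMeta",
    "ColumnSystem",
    "PeakRecord",
    "ChromatogramError",
    "read_chromatogram",
    "write_chromatogram",
    "read_metadata",
    "capacity_factor",
    "remove_baseline",
    "detect_apex_peak",
    "peak_area",
]

MIN_POINTS = 8


class ChromatogramError(ValueError):
    """Malformed chromatogram input (bad rows, non-monotone time, too short)."""


@dataclass
class ChromatogramMeta:
    """Acquisition metadata attached to a trace.

    Units: concentration mol/L, injection_volume L, flow_rate mL/min,
    wavelength nm.
    """

    analyte: str | None = None
    concentration: float | None = None
    injection_volume: float | None = None
    flow_rate: float | None = None
    wavelength: float | None = None
    column: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Chromatogram:
    """Time grid (minutes, strictly increasing) and detector signal."""

    time: np.ndarray
    signal: np.ndarray
    meta: ChromatogramMeta = field(default_factory=ChromatogramMeta)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.ndim != 1 or self.signal.ndim != 1:
            raise ChromatogramError("time and signal must be 1-D")
        if self.time.size != self.signal.size:
            raise ChromatogramError(
                f"length mismatch: {self.time.size} times vs {self.signal.size} signals"
            )
        if self.time.size < MIN_POINTS:
            raise ChromatogramError(
                f"chromatogram needs at least {MIN_POINTS} rows, got {self.time.size}"
            )
        if not (np.all(np.isfinite(self.time)) and np.all(np.isfinite(self.signal))):
            raise ChromatogramError("non-finite values in time or signal")
        dt = np.diff(self.time)
        if np.any(dt == 0):
            i = int(np.argmin(dt)) + 1
            raise ChromatogramError(f"duplicate time point at row {i} (t={self.time[i]})")
        if np.any(dt < 0):
            i = int(np.argmin(dt)) + 1
            raise ChromatogramError(f"non-monotone time at row {i} (t={self.time[i]})")

    def __len__(self) -> int:
        return self.time.size

    @property
    def t_span(self) -> tuple[float, float]:
        return float(self.time[0]), float(self.time[-1])

    def copy_with(self, signal: np.ndarray) -> "Chromatogram":
        return Chromatogram(self.time.copy(), np.asarray(signal, float), self.meta)


@dataclass
class ColumnSystem:
    """Chromatographic system constants.

    t0: void time (minutes, elution of an unretained marker);
    flow_rate: mL/min; pipeline_volume: system volume Vm in litres
    (defaults to the void volume flow_rate * t0).
    """

    t0: float
    flow_rate: float = 0.2
    pipeline_volume: float | None = None
    column_id: str = ""

    def __post_init__(self) -> None:
        if self.t0 <= 0:
            raise ValueError(f"void time t0 must be positive, got {self.t0}")
        if self.flow_rate <= 0:
            raise ValueError(f"flow rate must be positive, got {self.flow_rate}")
        if self.pipeline_volume is None:
            # void volume in litres: (mL/min * min) * 1e-3
            self.pipeline_volume = self.flow_rate * self.t0 * 1e-3
        if self.pipeline_volume <= 0:
            raise ValueError("pipeline volume Vm must be positive")


@dataclass
class PeakRecord:
    """One detected peak: apex retention time (min), height, area, k'."""

    retention_time: float
    height: float
    area: float
    capacity_factor: float | None = None


def capacity_factor(tR: float, t0: float) -> float:
    """Capacity factor k' = (tR - t0)/t0.

    Negative values (elution before the void marker) are legal but flagged
    with a warning; they indicate exclusion rather than binding.
    """
    if t0 <= 0:
        raise ValueError(f"void time t0 must be positive, got {t0}")
    if tR < 0:
        raise ValueError(f"retention time must be non-negative, got {tR}")
    k = (tR - t0) / t0
    if k < 0:
        warnings.warn(
            f"tR={tR} precedes the void time {t0}: k'={k:.4g} < 0 (exclusion)",
            stacklevel=2,
        )
    return k


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_chromatogram(path: str | Path, meta: ChromatogramMeta | None = None) -> Chromatogram:
    """Read a two-column CSV (``time_min,signal``; header optional).

    Rows are sorted by time; duplicate time points and malformed rows are
    rejected with the offending line named.
    """
    path = Path(path)
    rows: list[tuple[float, float]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise ChromatogramError(f"{path.name}:{lineno}: expected 2 columns, got {len(parts)}")
            try:
                t, y = float(parts[0]), float(parts[1])
            except ValueError:
                if lineno == 1:  # optional header
                    continue
                raise ChromatogramError(f"{path.name}:{lineno}: non-numeric row {line!r}") from None
            rows.append((t, y))
    if len(rows) < MIN_POINTS:
        raise ChromatogramError(f"{path.name}: fewer than {MIN_POINTS} data rows ({len(rows)})")
    arr = np.array(sorted(rows, key=lambda r: r[0]), dtype=float)
    try:
        return Chromatogram(arr[:, 0], arr[:, 1], meta or ChromatogramMeta())
    except ChromatogramError as exc:
        raise ChromatogramError(f"{path.name}: {exc}") from None


def write_chromatogram(chrom: Chromatogram, path: str | Path) -> None:
    """Write ``time_min,signal`` CSV at full (round-trip) precision."""
    df = pd.DataFrame({"time_min": chrom.time, "signal": chrom.signal})
    df.to_csv(path, index=False)


def read_metadata(path: str | Path) -> ChromatogramMeta:
    """Read a sidecar metadata file: JSON object or ``key=value`` lines."""
    path = Path(path)
    text = path.read_text(encoding="utf-8").strip()
    if text.startswith("{"):
        data = json.loads(text)
    else:
        data = {}
        for raw in text.splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            data[key.strip()] = val.strip()
    fields = {f for f in ChromatogramMeta.__dataclass_fields__}
    kwargs = {}
    for key, val in data.items():
        if key not in fields:
            continue
        if key in ("analyte", "column"):
            kwargs[key] = str(val)
        elif val is not None:
            kwargs[key] = float(val)
    return ChromatogramMeta(**kwargs)


# ---------------------------------------------------------------------------
# Signal processing
# ---------------------------------------------------------------------------

def remove_baseline(chrom: Chromatogram, window_frac: float = 0.05) -> Chromatogram:
    """Subtract the straight line through the medians of the leading and
    trailing ``window_frac`` portions of the trace (assumed peak-free).

    If the global maximum falls inside either window the linear model is
    untrustworthy; a warning is issued and the global minimum is
    subtracted instead.
    """
    if not (0 < window_frac <= 0.3):
        raise ValueError("window_frac must be in (0, 0.3]")
    n = len(chrom)
    w = max(2, int(round(n * window_frac)))
    t_lo = float(np.median(chrom.time[:w]))
    y_lo = float(np.median(chrom.signal[:w]))
    t_hi = float(np.median(chrom.time[-w:]))
    y_hi = float(np.median(chrom.signal[-w:]))
    slope = (y_hi - y_lo) / (t_hi - t_lo)
    corrected = chrom.signal - (y_lo + slope * (chrom.time - t_lo))
    # judge the apex location on the detrended trace: a peak inside a
    # window means the window was not peak-free and the line is biased
    apex = int(np.argmax(corrected))
    if apex < w or apex >= n - w:
        warnings.warn(
            "apex lies inside a baseline window; falling back to global-minimum subtraction",
            stacklevel=2,
        )
        return chrom.copy_with(chrom.signal - chrom.signal.min())
    return chrom.copy_with(corrected)


def _parabolic_apex(t: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Refine a discrete maximum by a parabola through its 3 neighbours."""
    if i == 0 or i == len(y) - 1:
        return float(t[i]), float(y[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0:  # not locally concave; keep the grid point
        return float(t[i]), float(y[i])
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    dt = 0.5 * (t[i + 1] - t[i - 1])
    apex_t = float(t[i] + delta * dt)
    apex_y = float(y1 - 0.25 * (y0 - y2) * delta)
    return apex_t, apex_y


def detect_apex_peak(
    chrom: Chromatogram,
    min_height_frac: float = 0.05,
    system: ColumnSystem | None = None,
) -> list[PeakRecord]:
    """Detect local maxima above ``min_height_frac * max(signal)``.

    The apex is refined by 3-point parabolic interpolation; the area is the
    trapezoidal integral between the enclosing local minima.  A flat or
    all-zero trace yields an empty list.  If ``system`` is given, each
    record carries its capacity factor.
    """
    if not (0 < min_height_frac < 1):
        raise ValueError("min_height_frac must be in (0, 1)")
    raw = chrom.signal
    if float(raw.max()) <= 0 or np.ptp(raw) == 0:
        return []
    # detect on a lightly smoothed trace so detector noise riding on broad
    # peaks does not spawn spurious maxima; areas use the raw signal
    if len(raw) >= 15:
        y = savgol_filter(raw, window_length=11, polyorder=3)
    else:
        y = raw
    ymax = float(y.max())
    if ymax <= 0:
        return []
    idx, _ = find_peaks(
        y, height=min_height_frac * ymax, prominence=min_height_frac * ymax
    )
    if idx.size == 0:
        return []
    # enclosing local minima (grid indices of valleys between/around peaks)
    records: list[PeakRecord] = []
    for j, i in enumerate(idx):
        lo = idx[j - 1] if j > 0 else 0
        hi = idx[j + 1] if j < idx.size - 1 else len(y) - 1
        left = lo + int(np.argmin(y[lo : i + 1]))
        right = i + int(np.argmin(y[i : hi + 1]))
        apex_t, apex_y = _parabolic_apex(chrom.time, y, int(i))
        area = float(np.trapezoid(raw[left : right + 1], chrom.time[left : right + 1]))
        k = None
        if system is not None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                k = capacity_factor(apex_t, system.t0)
        records.append(PeakRecord(apex_t, apex_y, area, k))
    return records


def peak_area(chrom: Chromatogram, t_start: float, t_end: float) -> float:
    """Trapezoidal integral of the signal over [t_start, t_end].

    Window endpoints are interpolated onto the grid; a window outside the
    time range is an error.
    """
    lo, hi = chrom.t_span
    if not (t_start < t_end):
        raise ValueError("t_start must be < t_end")
    if t_start < lo or t_end > hi:
        raise ValueError(
            f"integration window [{t_start}, {t_end}] outside time range [{lo}, {hi}]"
        )
    mask = (chrom.time > t_start) & (chrom.time < t_end)
    t = np.concatenate(([t_start], chrom.time[mask], [t_end]))
    y = np.interp(t, chrom.time, chrom.signal)
    return float(np.trapezoid(y, t))
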