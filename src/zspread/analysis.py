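"""Spectral read-out: relative impedance, maxima, coverage calls and
per-well summaries.

The cell signal of one electrode is the *relative impedance*

    dZ(f) = (|Z|_with_cells(f) - |Z|_without_cells(f))
            / |Z|_without_cells(f) * 100 %

computed against that electrode's own cell-free baseline sweep.  Its
maximum over the frequency grid (and the frequency at which it occurs)
is the per-electrode read-out: the maximum grows with the amount of
cell material on the electrode.  An electrode is called *covered* when
the maximum reaches a detection threshold (default 10 %, well above the
1 % measurement-noise floor and below the ~15 % signal of a single
adherent cell).  Per well and time point, the covered-electrode count
tracks migration (spatial spreading) and the median maximum relative
impedance over the covered electrodes tracks cell amount/density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .recording import Recording

__all__ = [
    "DEFAULT_COVERAGE_THRESHOLD",
    "RelativeSpectrum",
    "SpectrumMax",
    "CoverageCall",
    "WellSummary",
    "relative_impedance",
    "spectrum_maximum",
    "call_covered",
    "electrode_maxima",
    "summarize_well",
    "coverage_map",
]

DEFAULT_COVERAGE_THRESHOLD = 10.0  # % maximum relative impedance


@dataclass(frozen=True)
class RelativeSpectrum:
    """Relative impedance (%) on the acquisition frequency grid."""

    frequencies: np.ndarray
    rel_impedance: np.ndarray


@dataclass(frozen=True)
class SpectrumMax:
    """Peak of a relative-impedance spectrum."""

    max_rel_impedance: float
    f_at_max: float


@dataclass(frozen=True)
class CoverageCall:
    covered: bool
    max_rel_impedance: float
    threshold_used: float


@dataclass
class WellSummary:
    """Per-time-point covered-electrode count and median maximum
    relative impedance (over covered electrodes only) for one well.
    The median is NaN where no electrode is covered."""

    well_id: str
    label: str
    time_points_h: np.ndarray
    covered_count: np.ndarray
    median_max_rel_impedance: np.ndarray
    threshold: float
    n_electrodes: int

    def to_frame(self) -> pd.DataFrame:
        """Tidy table (well_id, time_h, covered_count,
        median_max_rel_imp_pct)."""
        return pd.DataFrame(
            {
                "well_id": self.well_id,
                "group": self.label,
                "time_h": self.time_points_h,
                "covered_count": self.covered_count,
                "median_max_rel_imp_pct": self.median_max_rel_impedance,
            }
        )

    def at_time(self, t: float) -> tuple[int, float]:
        """(covered_count, median) at time ``t`` hours."""
        idx = np.flatnonzero(np.isclose(self.time_points_h, t))
        if idx.size == 0:
            raise ValueError(f"time {t} h not in summary")
        i = int(idx[0])
        return int(self.covered_count[i]), float(
            self.median_max_rel_impedance[i]
        )


def relative_impedance(z_with, z_without, frequencies=None) -> RelativeSpectrum:
    """Relative impedance in percent, elementwise over the sweep.

    Scale-invariant: multiplying both spectra by the same positive
    constant leaves the result unchanged.  The baseline must be
    strictly positive everywhere.
    """
    zw = np.asarray(z_with, dtype=float)
    z0 = np.asarray(z_without, dtype=float)
    if zw.shape != z0.shape:
        raise ValueError(
            f"spectra length mismatch: {zw.shape} vs {z0.shape}"
        )
    if zw.size == 0:
        raise ValueError("empty spectra")
    if np.any(z0 <= 0):
        raise ValueError("baseline |Z| must be strictly positive")
    rel = (zw - z0) / z0 * 100.0
    if frequencies is None:
        freqs = np.arange(zw.size, dtype=float)  # sample index stands in
    else:
        freqs = np.asarray(frequencies, dtype=float)
        if freqs.shape != zw.shape:
            raise ValueError("frequencies must match the spectra length")
    return RelativeSpectrum(frequencies=freqs, rel_impedance=rel)


def spectrum_maximum(
    rs: RelativeSpectrum | np.ndarray, frequencies: np.ndarray | None = None
) -> SpectrumMax:
    """Maximum of the sampled relative-impedance spectrum and the
    frequency where it is attained; ties break toward the lower
    frequency (``argmax`` of the grid).  No smoothing is applied."""
    if isinstance(rs, RelativeSpectrum):
        rel = rs.rel_impedance
        freqs = rs.frequencies if frequencies is None else np.asarray(frequencies)
    else:
        rel = np.asarray(rs, dtype=float)
        if frequencies is None:
            raise ValueError("frequencies required for a bare array")
        freqs = np.asarray(frequencies, dtype=float)
    if rel.size == 0:
        raise ValueError("empty spectrum")
    i = int(np.argmax(rel))
    return SpectrumMax(max_rel_impedance=float(rel[i]), f_at_max=float(freqs[i]))


def call_covered(
    sm: SpectrumMax | float, threshold: float = DEFAULT_COVERAGE_THRESHOLD
) -> CoverageCall:
    """Covered-electrode call: covered iff the maximum relative
    impedance reaches ``threshold`` (inclusive boundary)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    m = sm.max_rel_impedance if isinstance(sm, SpectrumMax) else float(sm)
    return CoverageCall(covered=m >= threshold, max_rel_impedance=m, threshold_used=threshold)


def electrode_maxima(rec: Recording) -> np.ndarray:
    """Per-electrode maximum relative impedance (%), shape
    (n_rows, n_cols, n_times)."""
    rel = (rec.zmag - rec.baseline[:, :, None, :]) / rec.baseline[:, :, None, :] * 100.0
    return rel.max(axis=-1)


def summarize_well(
    rec: Recording, threshold: float = DEFAULT_COVERAGE_THRESHOLD
) -> WellSummary:
    """Covered-electrode count and covered-only median maximum relative
    impedance per time point.

    The median is taken over covered electrodes only; with none
    covered it is reported as NaN (missing), never as zero.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    maxima = electrode_maxima(rec)  # (nr, nc, nt)
    nt = maxima.shape[-1]
    covered = maxima >= threshold
    counts = covered.sum(axis=(0, 1))
    medians = np.full(nt, np.nan)
    for j in range(nt):
        vals = maxima[:, :, j][covered[:, :, j]]
        if vals.size:
            medians[j] = float(np.median(vals))
    return WellSummary(
        well_id=rec.well_id,
        label=rec.label,
        time_points_h=rec.time_points_h.copy(),
        covered_count=counts.astype(int),
        median_max_rel_impedance=medians,
        threshold=threshold,
        n_electrodes=rec.layout.electrodes_per_well,
    )


def coverage_map(
    rec: Recording, t: float, threshold: float = DEFAULT_COVERAGE_THRESHOLD
) -> np.ndarray:
    """Spatial map of per-electrode maximum relative impedance at time
    ``t``: an (n_rows, n_cols) matrix aligned with the electrode grid,
    NaN where the electrode is not covered."""
    j = rec.time_index(t)
    maxima = electrode_maxima(rec)[:, :, j]
    out = np.where(maxima >= threshold, maxima, np.nan)
    return out
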