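"""In-memory container for one well's impedance time-lapse."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mea import AcquisitionConfig, ElectrodeLayout

__all__ = ["Recording"]


@dataclass
class Recording:
    """Per-electrode |Z| spectra of one well over time, plus the
    cell-free baseline spectrum of every electrode.

    ``zmag`` has shape (n_rows, n_cols, n_times, n_freqs) and
    ``baseline`` (n_rows, n_cols, n_freqs); both are in Ohm on the
    acquisition frequency grid.  ``time_points_h`` are the measurement
    times in hours.
    """

    layout: ElectrodeLayout
    acquisition: AcquisitionConfig
    time_points_h: np.ndarray
    zmag: np.ndarray
    baseline: np.ndarray
    well_id: str = "W00"
    label: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        self.time_points_h = np.asarray(self.time_points_h, dtype=float)
        self.zmag = np.asarray(self.zmag, dtype=float)
        self.baseline = np.asarray(self.baseline, dtype=float)
        nr, nc = self.layout.n_rows, self.layout.n_cols
        nf = self.acquisition.n_points
        nt = len(self.time_points_h)
        if self.zmag.shape != (nr, nc, nt, nf):
            raise ValueError(
                f"zmag shape {self.zmag.shape} != {(nr, nc, nt, nf)}"
            )
        if self.baseline.shape != (nr, nc, nf):
            raise ValueError(
                f"baseline shape {self.baseline.shape} != {(nr, nc, nf)}"
            )
        if np.any(self.zmag <= 0) or np.any(self.baseline <= 0):
            raise ValueError("|Z| must be strictly positive")

    @property
    def frequencies(self) -> np.ndarray:
        return self.acquisition.frequencies()

    def time_index(self, t: float) -> int:
        """Index of recorded time point ``t`` (hours); raises if absent."""
        idx = np.flatnonzero(np.isclose(self.time_points_h, t))
        if idx.size == 0:
            raise ValueError(
                f"time {t} h is not a recorded time point "
                f"(have {self.time_points_h.tolist()})"
            )
        return int(idx[0])

    def __eq__(self, other) -> bool:
        if not isinstance(other, Recording):
            return NotImplemented
        return (
            self.layout == other.layout
            and self.acquisition == other.acquisition
            and self.well_id == other.well_id
            and np.array_equal(self.time_points_h, other.time_points_h)
            and np.array_equal(self.zmag, other.zmag)
            and np.array_equal(self.baseline, other.baseline)
        )
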