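"""Recording interchange format and the end-to-end pipeline runner.

Recordings travel as long-format CSV with the columns

    well_id, electrode_row, electrode_col, time_h, frequency_hz, zmag_ohm

where ``time_h = -1`` encodes the cell-free baseline sweep of an
electrode.  Run metadata (layout, acquisition, phenotype label, seed)
is carried in ``# key: value`` comment lines at the top of the file so
the round-trip is lossless.  An optional HDF5 container with the same
content is available for large runs when h5py is installed.
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import (
    DEFAULT_COVERAGE_THRESHOLD,
    WellSummary,
    coverage_map,
    summarize_well,
)
from .discriminate import (
    DEFAULT_FEATURE_TIMES_H,
    FeatureVector,
    QuadrantThresholds,
    ReferenceModel,
    assign_quadrant,
    build_features,
    calibrate_thresholds,
    classification_report,
    fit_reference_model,
)
from .mea import AcquisitionConfig, ElectrodeLayout
from .recording import Recording

__all__ = [
    "FormatError",
    "write_recording",
    "read_recording",
    "read_recordings",
    "PipelineResult",
    "run_pipeline",
]

BASELINE_TIME = -1.0
_COLUMNS = [
    "well_id",
    "electrode_row",
    "electrode_col",
    "time_h",
    "frequency_hz",
    "zmag_ohm",
]


class FormatError(ValueError):
    """A recording table violates the format invariants."""


def _recording_frame(rec: Recording) -> pd.DataFrame:
    nr, nc = rec.layout.n_rows, rec.layout.n_cols
    freqs = rec.frequencies
    nf = len(freqs)
    nt = len(rec.time_points_h)
    rows_idx, cols_idx = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    # baseline block (time_h = -1), then measurements in time order
    base = pd.DataFrame(
        {
            "well_id": rec.well_id,
            "electrode_row": np.repeat(rows_idx.ravel(), nf),
            "electrode_col": np.repeat(cols_idx.ravel(), nf),
            "time_h": BASELINE_TIME,
            "frequency_hz": np.tile(freqs, nr * nc),
            "zmag_ohm": rec.baseline.reshape(-1),
        }
    )
    zt = np.moveaxis(rec.zmag, 2, 0)  # (nt, nr, nc, nf)
    meas = pd.DataFrame(
        {
            "well_id": rec.well_id,
            "electrode_row": np.tile(np.repeat(rows_idx.ravel(), nf), nt),
            "electrode_col": np.tile(np.repeat(cols_idx.ravel(), nf), nt),
            "time_h": np.repeat(rec.time_points_h, nr * nc * nf),
            "frequency_hz": np.tile(freqs, nt * nr * nc),
            "zmag_ohm": zt.reshape(-1),
        }
    )
    return pd.concat([base, meas], ignore_index=True)


def write_recording(recordings: Recording | list[Recording], path) -> None:
    """Write one or more recordings as a long-format CSV (metadata in
    leading ``#`` comment lines)."""
    if isinstance(recordings, Recording):
        recordings = [recordings]
    if not recordings:
        raise ValueError("nothing to write")
    lay = recordings[0].layout
    acq = recordings[0].acquisition
    meta = [
        f"# n_rows: {lay.n_rows}",
        f"# n_cols: {lay.n_cols}",
        f"# pitch_um: {lay.pitch}",
        f"# diameter_um: {lay.electrode_diameter}",
        f"# n_wells: {lay.n_wells}",
        f"# f_min_hz: {acq.f_min}",
        f"# f_max_hz: {acq.f_max}",
        f"# n_points: {acq.n_points}",
    ]
    for rec in recordings:
        meta.append(
            f"# well: {rec.well_id} | label: {rec.label} | seed: {rec.seed}"
        )
    frame = pd.concat(
        [_recording_frame(r) for r in recordings], ignore_index=True
    )
    buf = _io.StringIO()
    frame.to_csv(buf, index=False, float_format="%.17g")
    Path(path).write_text("\n".join(meta) + "\n" + buf.getvalue())


def _parse_meta(path) -> tuple[dict, dict]:
    chip: dict = {}
    wells: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if body.startswith("well:"):
                parts = [p.strip() for p in body.split("|")]
                wid = parts[0].split(":", 1)[1].strip()
                info = {}
                for p in parts[1:]:
                    k, v = p.split(":", 1)
                    info[k.strip()] = v.strip()
                wells[wid] = info
            elif ":" in body:
                k, v = body.split(":", 1)
                chip[k.strip()] = v.strip()
    return chip, wells


def read_recordings(path) -> list[Recording]:
    """Read a recording table, validating the format invariants.

    Raises :class:`FormatError` naming the first offending row for a
    missing baseline, an inconsistent frequency grid or a non-positive
    |Z|.
    """
    chip, wellmeta = _parse_meta(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing columns: {missing}")
    bad = np.flatnonzero(~(df["zmag_ohm"] > 0))
    if bad.size:
        raise FormatError(f"non-positive zmag_ohm at data row {bad[0]}")

    n_rows = int(chip.get("n_rows", df["electrode_row"].max() + 1))
    n_cols = int(chip.get("n_cols", df["electrode_col"].max() + 1))
    layout = ElectrodeLayout(
        n_cols=n_cols,
        n_rows=n_rows,
        pitch=float(chip.get("pitch_um", 300.0)),
        electrode_diameter=float(chip.get("diameter_um", 100.0)),
        n_wells=int(chip.get("n_wells", 9)),
    )
    base_rows = df[df["time_h"] == BASELINE_TIME]
    if base_rows.empty:
        raise FormatError("no baseline rows (time_h = -1) present")
    freqs = np.sort(base_rows["frequency_hz"].unique())
    acq = AcquisitionConfig(
        f_min=float(chip.get("f_min_hz", freqs[0])),
        f_max=float(chip.get("f_max_hz", freqs[-1])),
        n_points=int(chip.get("n_points", len(freqs))),
    )
    if acq.n_points != len(freqs):
        raise FormatError(
            f"frequency grid has {len(freqs)} points, metadata says {acq.n_points}"
        )

    recordings = []
    for wid, wdf in df.groupby("well_id", sort=True):
        times = np.sort(wdf.loc[wdf["time_h"] != BASELINE_TIME, "time_h"].unique())
        nt, nf = len(times), len(freqs)
        zmag = np.full((n_rows, n_cols, nt, nf), np.nan)
        baseline = np.full((n_rows, n_cols, nf), np.nan)
        t_index = {t: i for i, t in enumerate(times)}
        f_index = {f: i for i, f in enumerate(freqs)}
        for row in wdf.itertuples():
            try:
                fi = f_index[row.frequency_hz]
            except KeyError:
                raise FormatError(
                    f"inconsistent frequency grid at data row {row.Index}"
                ) from None
            r, c = int(row.electrode_row), int(row.electrode_col)
            if not (0 <= r < n_rows and 0 <= c < n_cols):
                raise FormatError(
                    f"electrode index out of range at data row {row.Index}"
                )
            if row.time_h == BASELINE_TIME:
                baseline[r, c, fi] = row.zmag_ohm
            else:
                zmag[r, c, t_index[row.time_h], fi] = row.zmag_ohm
        if np.isnan(baseline).any():
            r, c, _ = np.argwhere(np.isnan(baseline))[0]
            raise FormatError(
                f"well {wid}: electrode ({r}, {c}) lacks a complete baseline"
            )
        if np.isnan(zmag).any():
            r, c, t, _ = np.argwhere(np.isnan(zmag))[0]
            raise FormatError(
                f"well {wid}: electrode ({r}, {c}) is missing sweeps at "
                f"time {times[t]} h"
            )
        info = wellmeta.get(str(wid), {})
        seed = info.get("seed")
        recordings.append(
            Recording(
                layout=layout,
                acquisition=acq,
                time_points_h=times,
                zmag=zmag,
                baseline=baseline,
                well_id=str(wid),
                label=info.get("label", ""),
                seed=None if seed in (None, "None", "") else int(seed),
            )
        )
    return recordings


def read_recording(path) -> Recording:
    """Read a single-well recording file."""
    recs = read_recordings(path)
    if len(recs) != 1:
        raise FormatError(
            f"expected exactly one well in {path}, found {len(recs)}"
        )
    return recs[0]


# --- pipeline ----------------------------------------------------------------


@dataclass
class PipelineResult:
    """Everything the end-to-end run produces."""

    summaries: list[WellSummary]
    summary_table: pd.DataFrame
    coverage_maps: dict[str, np.ndarray]  # endpoint map per well
    thresholds: QuadrantThresholds
    quadrants: pd.DataFrame
    model: ReferenceModel | None = None
    report: pd.DataFrame | None = None


def run_pipeline(
    recordings: list[Recording],
    threshold: float = DEFAULT_COVERAGE_THRESHOLD,
    feature_times: tuple[float, ...] = DEFAULT_FEATURE_TIMES_H,
    reference_truth: dict[str, tuple[bool, bool]] | None = None,
    endpoint_h: float | None = None,
    seed: int = 0,
) -> PipelineResult:
    """Summarise, calibrate, quadrant-classify and (with references)
    fit and apply the clustering model.

    ``reference_truth`` maps a recording label to its
    (high_migration, proliferating) truth; labelled recordings are
    used both for threshold calibration and as the clustering training
    set.  Deterministic given inputs and ``seed``.
    """
    if not recordings:
        raise ValueError("pipeline needs at least one recording")
    try:
        summaries = [summarize_well(r, threshold) for r in recordings]
    except Exception as exc:  # pragma: no cover - defensive re-labelling
        raise RuntimeError(f"summarise stage failed: {exc}") from exc
    endpoint = (
        float(recordings[0].time_points_h[-1]) if endpoint_h is None else endpoint_h
    )
    summary_table = pd.concat([s.to_frame() for s in summaries], ignore_index=True)
    maps = {
        r.well_id: coverage_map(r, endpoint, threshold) for r in recordings
    }

    if reference_truth:
        ref_idx = [i for i, s in enumerate(summaries) if s.label in reference_truth]
        thresholds = calibrate_thresholds(
            [summaries[i] for i in ref_idx],
            [reference_truth[summaries[i].label][0] for i in ref_idx],
            [reference_truth[summaries[i].label][1] for i in ref_idx],
            endpoint_h=endpoint,
        )
    else:
        ref_idx = []
        thresholds = QuadrantThresholds()

    quad_rows = []
    for s in summaries:
        c, med = s.at_time(endpoint)
        quad_rows.append(
            {
                "well_id": s.well_id,
                "group": s.label,
                "covered_count": c,
                "median_max_rel_imp_pct": med,
                "quadrant": assign_quadrant(c, med, thresholds).value,
            }
        )
    quadrants = pd.DataFrame(quad_rows)

    model = None
    report = None
    features = [build_features(s, feature_times) for s in summaries]
    if ref_idx and len(ref_idx) >= 4:
        try:
            model = fit_reference_model(
                [features[i] for i in ref_idx], seed=seed
            )
        except Exception as exc:
            raise RuntimeError(f"clustering stage failed: {exc}") from exc
        report = classification_report(
            model, features, summaries, thresholds, endpoint_h=endpoint
        )
    return PipelineResult(
        summaries=summaries,
        summary_table=summary_table,
        coverage_maps=maps,
        thresholds=thresholds,
        quadrants=quadrants,
        model=model,
        report=report,
    )
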