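"""Agent-based simulator of cell egress from a central spheroid.

This module is the stand-in for the instrument: it emulates a
micro-tumor spheroid placed at the centre of one well, emitting cells
that migrate over the electrode grid as persistent random walks and
optionally proliferate.  Agent positions are turned into per-electrode
covered-area fractions and rendered into |Z| recordings through the
equivalent-circuit forward model.

Model summary
-------------
* Emission: a Poisson process at ``egress_rate`` cells/h places new
  agents on the spheroid rim (radius ``spheroid_radius``) with an
  outward initial heading.  Emission starts after an adhesion/outgrowth
  lag of ``egress_delay`` hours (spheroids need to attach and polarise
  before cells leave; covered-electrode counts stay near the body
  footprint over the first day) and stops at ``disassembly_time``.
* Motility: per step of ``dt`` hours an agent draws a speed from a
  normal truncated at zero and moves along its heading; the heading is
  relaxed toward a fresh random direction so that its autocorrelation
  over one hour equals ``persistence``.
* Proliferation: each agent divides with probability
  ``1 - exp(-proliferation_rate * dt)`` per step; the daughter is
  placed one cell diameter (10 um) away.  ``mitomycin=True`` forces the
  effective rate to zero (proliferation-suppressed reference).
* Spheroid body: electrodes whose centre lies within the spheroid
  radius are fully covered (theta = 1) while the spheroid persists
  (t < disassembly_time).
* Boundary: agents are absorbed at the well wall (radius 3.2 mm,
  96-well scale) and stop moving there.

Three phenotype presets (fast / intermediate / slow), each with an
untreated and a mitomycin variant, are version-pinned so that the full
pipeline reproduces the observed endpoint electrode-coverage levels of
the three cell lines they emulate (MDA-MB-231-like, T12.8.10ZII-like,
T30.6.9-like).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import truncnorm

from .mea import AcquisitionConfig, CircuitParams, ElectrodeLayout, electrode_impedance
from .recording import Recording

__all__ = [
    "PhenotypeParams",
    "SimulationRun",
    "simulate_agents",
    "coverage_series",
    "render_recording",
    "preset",
    "preset_names",
    "simulate_recording",
    "WELL_RADIUS_UM",
    "CELL_DIAMETER_UM",
    "DEFAULT_NOISE_SD",
]

WELL_RADIUS_UM = 3200.0
CELL_DIAMETER_UM = 10.0
DEFAULT_NOISE_SD = 0.01


@dataclass(frozen=True)
class PhenotypeParams:
    """Tunable migration/proliferation phenotype of one spheroid.

    Units: um, hours; ``egress_rate`` in cells/h, ``migration_speed_*``
    in um/h, ``proliferation_rate`` in divisions/h per cell,
    ``cell_footprint`` in um^2 of electrode area one adherent cell
    contributes.
    """

    spheroid_radius: float = 250.0
    egress_rate: float = 3.0
    egress_delay: float = 0.0
    migration_speed_mean: float = 10.0
    migration_speed_sd: float = 4.0
    persistence: float = 0.9
    proliferation_rate: float = 0.0
    mitomycin: bool = False
    disassembly_time: float = math.inf
    cell_footprint: float = 400.0
    name: str = "custom"

    def __post_init__(self) -> None:
        for fname in (
            "spheroid_radius",
            "egress_rate",
            "egress_delay",
            "migration_speed_mean",
            "migration_speed_sd",
            "proliferation_rate",
            "cell_footprint",
        ):
            v = getattr(self, fname)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{fname} must be finite and >= 0")
        if math.isnan(self.disassembly_time) or self.disassembly_time < 0:
            raise ValueError("disassembly_time must be >= 0 (inf allowed)")
        if not 0 <= self.persistence < 1:
            raise ValueError("persistence must lie in [0, 1)")

    @property
    def effective_proliferation_rate(self) -> float:
        """Divisions/h actually applied; zero under mitomycin."""
        return 0.0 if self.mitomycin else self.proliferation_rate


@dataclass
class SimulationRun:
    """Trajectories of one simulated well.

    ``positions[k]`` holds the (n_agents_k, 2) agent coordinates (um,
    well-centre origin) at time ``times[k]``; counts are redundant but
    convenient.  Identical ``(params, seed)`` reproduce the run
    bit-for-bit.
    """

    times: np.ndarray
    positions: list[np.ndarray]
    counts: np.ndarray
    emitted: int
    seed: int
    params: PhenotypeParams

    def positions_at(self, t: float) -> np.ndarray:
        idx = np.flatnonzero(np.isclose(self.times, t))
        if idx.size == 0:
            raise ValueError(f"time {t} h not recorded")
        return self.positions[int(idx[0])]


def _unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    return np.stack([np.cos(phi), np.sin(phi)], axis=1)


def simulate_agents(
    params: PhenotypeParams,
    duration: float = 144.0,
    dt: float = 0.5,
    seed: int = 0,
    well_radius: float = WELL_RADIUS_UM,
) -> SimulationRun:
    """Run the agent-based egress model for ``duration`` hours.

    Returns a :class:`SimulationRun` with positions recorded at every
    step (0, dt, 2*dt, ..., duration).
    """
    if not (duration > 0 and dt > 0):
        raise ValueError("duration and dt must be positive")
    rng = np.random.default_rng(seed)
    n_steps = int(round(duration / dt))
    prolif = params.effective_proliferation_rate
    # per-step heading autocorrelation giving `persistence` over one hour
    rho = params.persistence**dt
    p_div = -np.expm1(-prolif * dt)

    pos = np.empty((0, 2))
    heading = np.empty((0, 2))
    absorbed = np.empty(0, dtype=bool)
    emitted = 0

    times = np.arange(n_steps + 1) * dt
    positions: list[np.ndarray] = [pos.copy()]
    counts = np.zeros(n_steps + 1, dtype=int)

    for k in range(n_steps):
        t = k * dt
        # --- emission from the spheroid rim
        if (
            params.egress_delay <= t < params.disassembly_time
            and params.egress_rate > 0
        ):
            n_new = rng.poisson(params.egress_rate * dt)
            if n_new:
                u = _unit_vectors(rng, n_new)
                pos = np.vstack([pos, params.spheroid_radius * u])
                heading = np.vstack([heading, u])  # leave radially outward
                absorbed = np.concatenate([absorbed, np.zeros(n_new, bool)])
                emitted += n_new
        n = len(pos)
        if n:
            # --- motility: persistent random walk, truncated-normal speeds
            if params.migration_speed_sd > 0:
                a = -params.migration_speed_mean / params.migration_speed_sd
                speed = truncnorm.rvs(
                    a,
                    np.inf,
                    loc=params.migration_speed_mean,
                    scale=params.migration_speed_sd,
                    size=n,
                    random_state=rng,
                )
            else:
                speed = np.full(n, params.migration_speed_mean)
            fresh = _unit_vectors(rng, n)
            heading = rho * heading + math.sqrt(1.0 - rho * rho) * fresh
            norm = np.linalg.norm(heading, axis=1, keepdims=True)
            norm[norm == 0] = 1.0
            heading = heading / norm
            move = ~absorbed
            pos[move] += heading[move] * (speed[move, None] * dt)
            # --- absorption at the well wall
            r = np.linalg.norm(pos, axis=1)
            out = r > well_radius
            if np.any(out):
                pos[out] *= (well_radius / r[out])[:, None]
                absorbed |= out
            # --- division (Poisson process per agent)
            if p_div > 0:
                div = rng.random(n) < p_div
                n_div = int(div.sum())
                if n_div:
                    u = _unit_vectors(rng, n_div)
                    daughters = pos[div] + CELL_DIAMETER_UM * u
                    pos = np.vstack([pos, daughters])
                    heading = np.vstack([heading, _unit_vectors(rng, n_div)])
                    absorbed = np.concatenate(
                        [absorbed, np.zeros(n_div, bool)]
                    )
        positions.append(pos.copy())
        counts[k + 1] = len(pos)

    counts[0] = 0
    return SimulationRun(
        times=times,
        positions=positions,
        counts=counts,
        emitted=emitted,
        seed=seed,
        params=params,
    )


def _spheroid_mask(layout: ElectrodeLayout, radius: float) -> np.ndarray:
    centers = layout.centers()
    d = np.linalg.norm(centers, axis=-1)
    return d <= radius


def coverage_series(
    run: SimulationRun,
    layout: ElectrodeLayout = ElectrodeLayout(),
    times: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Covered-area fraction theta per electrode over time.

    theta(electrode, t) = min(1, cell_footprint * n_agents_on_disc /
    electrode_area), plus theta = 1 for electrodes under the spheroid
    body while it persists.  Electrode discs are disjoint (diameter <
    pitch), so an agent lies on at most one electrode.

    Returns ``(times, theta)`` with theta of shape
    (n_rows, n_cols, n_times).
    """
    if times is None:
        times = run.times
    times = np.asarray(times, dtype=float)
    centers = layout.centers()
    r_el = layout.electrode_radius
    area = layout.electrode_area
    fp = run.params.cell_footprint
    x0 = centers[0, 0, 0]
    y0 = centers[0, 0, 1]
    pitch = layout.pitch
    under = _spheroid_mask(layout, run.params.spheroid_radius)

    theta = np.zeros((layout.n_rows, layout.n_cols, len(times)))
    for j, t in enumerate(times):
        pts = run.positions_at(t)
        if len(pts):
            col = np.rint((pts[:, 0] - x0) / pitch).astype(int)
            row = np.rint((pts[:, 1] - y0) / pitch).astype(int)
            ok = (
                (col >= 0)
                & (col < layout.n_cols)
                & (row >= 0)
                & (row < layout.n_rows)
            )
            if np.any(ok):
                d = pts[ok] - centers[row[ok], col[ok]]
                on = np.linalg.norm(d, axis=1) <= r_el
                rows, cols = row[ok][on], col[ok][on]
                cnt = np.zeros((layout.n_rows, layout.n_cols))
                np.add.at(cnt, (rows, cols), 1.0)
                theta[:, :, j] = np.minimum(1.0, fp * cnt / area)
        if t < run.params.disassembly_time:
            theta[under, j] = 1.0
    return times, theta


def render_recording(
    coverage: np.ndarray,
    times: np.ndarray,
    layout: ElectrodeLayout = ElectrodeLayout(),
    circuit: CircuitParams = CircuitParams(),
    acquisition: AcquisitionConfig = AcquisitionConfig(),
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    well_id: str = "W00",
    label: str = "",
    noisy_baseline: bool = False,
) -> Recording:
    """Render a coverage series into an impedance :class:`Recording`.

    Each with-cells spectrum is the forward model multiplied by i.i.d.
    mean-one lognormal noise of relative standard deviation
    ``noise_sd``.  The baseline is rendered noise-free by default so
    the zero-coverage relative impedance is exactly zero; set
    ``noisy_baseline`` to perturb it too.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    coverage = np.asarray(coverage, dtype=float)
    nr, nc = layout.n_rows, layout.n_cols
    nt = len(times)
    if coverage.shape != (nr, nc, nt):
        raise ValueError(f"coverage shape {coverage.shape} != {(nr, nc, nt)}")
    rng = np.random.default_rng(seed)
    freqs = acquisition.frequencies()
    zmag = electrode_impedance(freqs, coverage.reshape(-1), circuit).reshape(
        nr, nc, nt, len(freqs)
    )
    baseline = np.broadcast_to(
        electrode_impedance(freqs, 0.0, circuit), (nr, nc, len(freqs))
    ).copy()
    if noise_sd > 0:
        sigma = math.sqrt(math.log1p(noise_sd**2))
        zmag = zmag * rng.lognormal(-0.5 * sigma**2, sigma, zmag.shape)
        if noisy_baseline:
            baseline = baseline * rng.lognormal(
                -0.5 * sigma**2, sigma, baseline.shape
            )
    return Recording(
        layout=layout,
        acquisition=acquisition,
        time_points_h=np.asarray(times, float),
        zmag=zmag,
        baseline=baseline,
        well_id=well_id,
        label=label,
        seed=seed,
    )


# --- phenotype presets -------------------------------------------------------
#
# Version-pinned parameter sets emulating the three observed spreading
# grades: fast (spheroid fully disassembles by 48 h, nearly all
# electrodes covered by 96 h), intermediate (> 60 % covered at 144 h)
# and slow (~35 % covered at 144 h).  Calibrated once against the full
# render-and-analyse pipeline averaged over seeds.

_PRESETS: dict[str, PhenotypeParams] = {
    "fast": PhenotypeParams(
        name="fast",
        spheroid_radius=250.0,
        egress_rate=80.0,
        egress_delay=24.0,
        migration_speed_mean=25.0,
        migration_speed_sd=8.0,
        persistence=0.9,
        proliferation_rate=0.026,
        disassembly_time=48.0,
    ),
    "intermediate": PhenotypeParams(
        name="intermediate",
        spheroid_radius=250.0,
        egress_rate=8.0,
        egress_delay=24.0,
        migration_speed_mean=9.5,
        migration_speed_sd=4.0,
        persistence=0.9,
        proliferation_rate=0.021,
    ),
    "slow": PhenotypeParams(
        name="slow",
        spheroid_radius=250.0,
        egress_rate=5.5,
        egress_delay=28.0,
        migration_speed_mean=4.7,
        migration_speed_sd=2.1,
        persistence=0.9,
        proliferation_rate=0.021,
    ),
}


def preset_names() -> list[str]:
    """All recognised preset names."""
    out = []
    for base in _PRESETS:
        out.append(base)
        out.append(f"{base}+mitomycin")
    return out


def preset(name: str) -> PhenotypeParams:
    """Look up a phenotype preset.

    ``name`` is one of fast / intermediate / slow, optionally suffixed
    with ``+mitomycin`` (also accepted: ``-mitomycin``) for the
    proliferation-suppressed reference variant, which differs only by a
    zero effective proliferation rate.
    """
    key = name.strip().lower().replace("-mitomycin", "+mitomycin")
    mito = key.endswith("+mitomycin")
    base = key[: -len("+mitomycin")] if mito else key
    if base not in _PRESETS:
        raise ValueError(
            f"unknown preset {name!r}; choose from {preset_names()}"
        )
    p = _PRESETS[base]
    if mito:
        p = replace(p, mitomycin=True, name=f"{base}+mitomycin")
    return p


def simulate_recording(
    params: PhenotypeParams | str,
    seed: int = 0,
    duration: float = 144.0,
    dt: float = 0.5,
    layout: ElectrodeLayout = ElectrodeLayout(),
    circuit: CircuitParams = CircuitParams(),
    acquisition: AcquisitionConfig = AcquisitionConfig(),
    noise_sd: float = DEFAULT_NOISE_SD,
    well_id: str = "W00",
) -> Recording:
    """End-to-end convenience: simulate agents, rasterise coverage at
    the acquisition time points and render the recording.  The noise
    stream is seeded independently of the trajectory stream (seed + a
    fixed offset) so both derive from ``seed`` alone."""
    if isinstance(params, str):
        params = preset(params)
    run = simulate_agents(params, duration=duration, dt=dt, seed=seed)
    tp = np.asarray(acquisition.time_points_h, float)
    _, theta = coverage_series(run, layout, times=tp)
    return render_recording(
        theta,
        tp,
        layout=layout,
        circuit=circuit,
        acquisition=acquisition,
        noise_sd=noise_sd,
        seed=(seed * 2654435761 + 97) % (2**31),
        well_id=well_id,
        label=params.name,
    )
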