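import numpy as np
import pytest

from zspread import (
    AcquisitionConfig,
    CircuitParams,
    ElectrodeLayout,
    Recording,
    electrode_impedance,
)


@pytest.fixture(scope="session")
def layout():
    return ElectrodeLayout()


@pytest.fixture(scope="session")
def acquisition():
    return AcquisitionConfig()


@pytest.fixture(scope="session")
def circuit():
    return CircuitParams()


def _make_recording(theta_grid, layout, acquisition, circuit, times=None, **kw):
    """Noise-free recording with a fixed coverage grid at every time
    point (or per-time grids when theta_grid is 3-D)."""
    from zspread import render_recording

    theta = np.asarray(theta_grid, dtype=float)
    if times is None:
        times = np.asarray(acquisition.time_points_h)
    if theta.ndim == 2:
        theta = np.repeat(theta[:, :, None], len(times), axis=2)
    return render_recording(
        theta,
        times,
        layout=layout,
        circuit=circuit,
        acquisition=acquisition,
        noise_sd=0.0,
        **kw,
    )


@pytest.fixture(scope="session")
def make_recording():
    return _make_recording


@pytest.fixture()
def uniform_recording(layout, acquisition, circuit):
    """All electrodes at half coverage, noise-free."""
    theta = np.full((layout.n_rows, layout.n_cols), 0.5)
    return _make_recording(theta, layout, acquisition, circuit)


@pytest.fixture(scope="session")
def theta_of_max():
    """Map coverage -> maximum relative impedance (%) for the default
    circuit on the default acquisition grid."""
    acq = AcquisitionConfig()
    freqs = acq.frequencies()
    base = electrode_impedance(freqs, 0.0)

    def f(theta: float) -> float:
        z = electrode_impedance(freqs, theta)
        return float(((z - base) / base * 100.0).max())

    return f
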