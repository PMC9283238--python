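import numpy as np
import pytest

from osteoquant.qbei import GrayCalibration
from osteoquant.indentation import ProbeGeometry
from osteoquant.simulate import StudyConfig, generate_study
from osteoquant.spectra import RamanSpectrum, SpectrumState


@pytest.fixture
def calibration() -> GrayCalibration:
    return GrayCalibration()


@pytest.fixture
def probe() -> ProbeGeometry:
    return ProbeGeometry()


@pytest.fixture
def grid() -> np.ndarray:
    return np.arange(800.0, 1801.0, 1.0)


def make_spectrum(intensity: np.ndarray, grid: np.ndarray | None = None,
                  state: SpectrumState = SpectrumState.RAW) -> RamanSpectrum:
    """Build a spectrum at an arbitrary processing state for stage tests."""
    if grid is None:
        grid = np.arange(800.0, 800.0 + intensity.size, 1.0)
    return RamanSpectrum(wavenumber=grid, intensity=intensity, state=state)


@pytest.fixture(scope="session")
def reduced_study(tmp_path_factory) -> tuple:
    """A small raw on-disk study shared by pipeline/CLI tests."""
    out = tmp_path_factory.mktemp("study")
    cfg = StudyConfig(n_periosteal_animals=3, n_perilacunar_animals=2,
                      periosteal_points=2, lacunae_per_animal=2, directions=2,
                      distances_um=(1.0, 5.0), accumulations=2, seed=11)
    manifest, tables = generate_study(cfg, out)
    return cfg, out, manifest, tables
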