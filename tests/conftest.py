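import numpy as np
import pytest

from eitproc.protocol import FrequencyPlan, InjectionProtocol, TimingPlan
from eitproc.reconstruction import ForwardModel, disc_mesh
from eitproc.simulator import AmplifierModel


@pytest.fixture(scope="session")
def disc16():
    """Small disc mesh with 16 boundary electrodes (~200 elements)."""
    return disc_mesh(n_rings=7, n_sectors=16, n_electrodes=16)


@pytest.fixture(scope="session")
def protocol16():
    """16-pair protocol on 16 electrodes mixing adjacent and skip-4 pairs."""
    pairs = [(i + 1, (i + 1) % 16 + 1) for i in range(0, 16, 2)] + [
        (i + 1, (i + 5) % 16 + 1) for i in range(0, 16, 2)
    ]
    return InjectionProtocol(tuple(pairs), 16, 100e-6)


@pytest.fixture(scope="session")
def forward16(disc16, protocol16):
    fm = ForwardModel(disc16, protocol16)
    fm.factorize()
    return fm


@pytest.fixture(scope="session")
def jacobian16(forward16):
    return forward16.jacobian()


@pytest.fixture(scope="session")
def amp_flat():
    """16 kHz amplifier with no anti-aliasing roll-off (unit gain)."""
    return AmplifierModel(16e3, "none")


def make_frameset(amplitudes, frequency_hz=2000.0):
    """Frameset from a (frames, pairs, electrodes) array, no mask."""
    from eitproc.frames_qc import BoundaryVoltageFrameSet

    a = np.asarray(amplitudes, dtype=float)
    return BoundaryVoltageFrameSet(a, np.zeros_like(a), frequency_hz)
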