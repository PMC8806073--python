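import numpy as np
import pytest

import roafit as rf


@pytest.fixture(scope="session")
def fine_grid() -> rf.WavenumberGrid:
    return rf.WavenumberGrid(200.0, 1800.0, 0.25)


@pytest.fixture(scope="session")
def conformers4() -> rf.ConformerSpectra:
    """Four distinguishable synthetic conformer spectra on the default grid."""
    return rf.gen_conformer_spectra(rf.SynthSpec(n_conformers=4, n_modes=60, seed=7))


@pytest.fixture(scope="session")
def conformers3() -> rf.ConformerSpectra:
    return rf.gen_conformer_spectra(rf.SynthSpec(n_conformers=3, n_modes=50, seed=11))


def single_mode_pair(center: float, grid: rf.WavenumberGrid, fwhm: float = 7.5) -> rf.SpectrumPair:
    return rf.broaden(rf.LineSpectrum([center], [1.0], [1e-3]), grid, fwhm)
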