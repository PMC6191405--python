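"""Shared fixtures: spectra, detectors, small protocols and the one full
desk-scale replication reused by every acceptance test."""

import numpy as np
import pytest

from spcct.beam import DetectorModel, generate_spectrum
from spcct.phantom import PhantomSpec
from spcct.pipeline import default_config, run_full_replication, run_study
from spcct.scan import ScanProtocol


@pytest.fixture(scope="session")
def spectrum120():
    """Unit-exposure 120-kVp spectrum."""
    return generate_spectrum(120.0, 1.0)


@pytest.fixture(scope="session")
def spectrum_hi():
    """High-exposure spectrum for near-noiseless single-ray work."""
    return generate_spectrum(120.0, 8e5)


@pytest.fixture(scope="session")
def detector_gd():
    """Threshold set of the gadolinium / iodine / I–Gd studies."""
    return DetectorModel((30, 51, 64, 72, 85), upper_limit=120.0)


@pytest.fixture(scope="session")
def detector_augd():
    """Threshold set of the gold–gadolinium mixture study."""
    return DetectorModel((30, 51, 78, 83, 98), upper_limit=120.0)


@pytest.fixture(scope="session")
def phantom_spec():
    return PhantomSpec()


@pytest.fixture()
def small_protocol():
    """Coarse protocol for fast unit-level scans."""
    return ScanProtocol(n_views=96, n_detectors=128, n0=1e4, slice_averaging=1)


@pytest.fixture(scope="session")
def replication():
    """Default desk-scale run of all five studies (seed 1)."""
    return run_full_replication(default_config(), seed=1)


@pytest.fixture(scope="session")
def noiseless_mixture():
    """Noiseless I–Gd mixture study at default settings."""
    cfg = default_config()
    cfg["protocol"]["noise"] = False
    return run_study("IGd_mix", cfg, seed=1)
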