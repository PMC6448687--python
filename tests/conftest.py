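"""Shared fixtures: lipid definitions, reference truths, small synthetic fits."""

import numpy as np
import pytest

from hexsaxs.composition import load_lipid
from hexsaxs.inference import FitConfig, run_chain
from hexsaxs.scattering import QuadratureSettings
from hexsaxs.synthetic import NoiseModel, generate_pattern, reference_params


@pytest.fixture(scope="session")
def dope():
    return load_lipid("DOPE")


@pytest.fixture(scope="session")
def dope_truth():
    """Ground-truth parameter set of the DOPE-like reference system."""
    params, lattice, lipid, meta = reference_params("DOPE308K")
    return params, lattice, lipid


@pytest.fixture(scope="session")
def dope_pattern(dope_truth):
    """Noisy synthetic DOPE-like pattern on the fitted q range."""
    params, lattice, lipid = dope_truth
    q = np.linspace(0.05, 0.5, 220)
    return generate_pattern(
        params, lattice, lipid, q, NoiseModel(scale=0.02, seed=3)
    )


@pytest.fixture(scope="session")
def fast_settings():
    """Reduced quadrature for speed-sensitive sampler tests."""
    return QuadratureSettings(qs_oversample=1, low_qs_points=24, n_smear=8)


@pytest.fixture(scope="session")
def short_chain(dope_truth, dope_pattern, fast_settings):
    """A short but mixed chain on the synthetic pattern (API-level tests)."""
    params, lattice, lipid = dope_truth
    cfg = FitConfig(
        lipid=lipid,
        a=lattice.a,
        n_steps=1500,
        tune_steps=600,
        pilot_steps=400,
        seed=7,
        x0=params,
        settings=fast_settings,
    )
    return run_chain(dope_pattern, cfg)
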