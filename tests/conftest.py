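import numpy as np
import pytest

import itemfive as i5


@pytest.fixture(scope="session")
def ref_seq():
    return i5.parse_sequence(i5.REFERENCE_SEQUENCE)


@pytest.fixture(scope="session")
def noiseless_series():
    spec = i5.DissociationSeriesSpec(noise_sd=0.0)
    spectra, truth = i5.generate_dissociation_series(spec)
    return spectra, truth


@pytest.fixture(scope="session")
def noiseless_fit(noiseless_series, ref_seq):
    spectra, _ = noiseless_series
    targets = i5.default_targets(ref_seq)
    norm = [i5.extract_normalized(s, targets) for s in spectra]
    curve = i5.assemble_curve(norm, analyte="ref")
    return i5.fit_boltzmann(curve)


@pytest.fixture(scope="session")
def synthetic_trimer():
    return i5.generate_symmetric_trimer(n_residues=12, ca_distance=4.5,
                                        rise=1.5)


@pytest.fixture
def flat_spectrum():
    mz = np.array([100.0, 200.0, 300.0, 400.0])
    intensity = np.array([5.0, 5.0, 5.0, 5.0])
    return i5.Spectrum(mz, intensity)
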