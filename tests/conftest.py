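import pytest

from speclib import (
    CorruptionConfig,
    Peak,
    PROFILES,
    Spectrum,
    SpectralLibrary,
    StubPredictor,
    clean_table,
    complete_metadata,
    corrupt_spectrum,
    generate_compound_table,
    predict_spectra,
)


@pytest.fixture(scope="session")
def small_compounds():
    """MS-ready compounds from a defect-free synthetic table."""
    records, _ = generate_compound_table(12, {}, seed=101)
    return clean_table(records).compounds


@pytest.fixture(scope="session")
def stub_library(small_compounds):
    """Metadata-complete stub-predicted library (3 energies/adduct)."""
    library, report = predict_spectra(small_compounds, StubPredictor(seed=101))
    assert not report.failures
    return complete_metadata(library, small_compounds)


@pytest.fixture()
def toy_pair():
    """A hand-checkable query/reference pair: intensities (100, 50)
    vs (100, 100, 50) on shared m/z 100 and 200, reference-only 300."""
    reference = Spectrum(
        compound_id="REF",
        peaks=[Peak(100.0, 100.0), Peak(200.0, 100.0), Peak(300.0, 50.0)],
        precursor_mz=350.0,
        polarity="positive",
    )
    query = Spectrum(
        compound_id="Q",
        peaks=[Peak(100.0, 100.0), Peak(200.0, 50.0)],
        precursor_mz=350.0,
        polarity="positive",
    )
    return query, reference
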