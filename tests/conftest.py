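import numpy as np
import pytest

from kmdlign.spectra_io import (
    IonMode,
    SolventMixture,
    Spectrum,
    SpectrumMeta,
    STUDY_SOLVENTS,
)


@pytest.fixture
def meta_neg() -> SpectrumMeta:
    return SpectrumMeta(
        sample_code="LP3",
        solvent=STUDY_SOLVENTS["1:1 MeOH:H2O"],
        ion_mode=IonMode.NEGATIVE,
    )


@pytest.fixture
def make_spectrum(meta_neg):
    """Factory for quick spectra; mz/intensity sequences, negative mode."""

    def _make(mz, intensity=None, meta=None, rel=None):
        mz = np.asarray(mz, dtype=float)
        if intensity is None:
            intensity = np.full(mz.shape, 1000.0)
        return Spectrum(
            mz=mz,
            intensity=np.asarray(intensity, dtype=float),
            meta=meta or meta_neg,
            rel_intensity=None if rel is None else np.asarray(rel, dtype=float),
        )

    return _make


@pytest.fixture
def blank_meta(meta_neg):
    from dataclasses import replace

    return replace(meta_neg, sample_code="BLANK", is_blank=True)


@pytest.fixture(scope="session")
def default_dataset():
    """One simulated 10-solvent dataset with blanks and ground truth."""
    from kmdlign.synthlign import SyntheticConfig, simulate_dataset

    return simulate_dataset(SyntheticConfig(seed=20260919))
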