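"""Peak-list preprocessing: blank subtraction, normalization, filters.

The cleaning chain applied to every sample spectrum before mass-defect
analysis and formula assignment is

    subtract blank  →  S/N filter  →  normalize  →  drop peaks < 1 %

Blank subtraction removes sample peaks that match a solvent-blank peak
within a ppm window (removal, not intensity differencing — the
conservative reading of vendor "subtraction"). Normalization happens
after subtraction so the base peak used for the percent scale is a real
sample peak. The relative-intensity filter drops peaks *below* the
threshold: a peak at exactly 1 % survives the default 1 % cut.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .spectra_io import Spectrum

__all__ = [
    "PreprocessConfig",
    "subtract_blank",
    "normalize",
    "filter_rel_intensity",
    "filter_snr",
    "preprocess",
]

#: Fewer peaks than this makes the quantile noise estimate meaningless.
_MIN_PEAKS_FOR_NOISE = 5


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunable thresholds for the cleaning chain.

    blank_tol_ppm
        Window for matching a sample peak to a blank peak.
    blank_intensity_ratio
        Minimum blank/sample intensity for removal; 0 (default) means an
        m/z match alone removes the peak.
    rel_intensity_min_pct
        Relative-intensity floor in percent of the base peak.
    snr_min
        Signal-to-noise multiple; peaks below ``snr_min × noise`` go.
    noise_quantile
        Fraction of lowest-intensity peaks whose median defines the noise
        level.
    """

    blank_tol_ppm: float = 1.0
    blank_intensity_ratio: float = 0.0
    rel_intensity_min_pct: float = 1.0
    snr_min: float = 3.0
    noise_quantile: float = 0.2

    def __post_init__(self) -> None:
        if min(self.blank_tol_ppm, self.blank_intensity_ratio,
               self.rel_intensity_min_pct, self.snr_min) < 0:
            raise ValueError("tolerances and thresholds must be >= 0")
        if not 0.0 < self.noise_quantile < 1.0:
            raise ValueError("noise_quantile must lie in (0, 1)")


def subtract_blank(
    sample: Spectrum,
    blank: Spectrum,
    config: PreprocessConfig | None = None,
) -> Spectrum:
    """Remove sample peaks matched by a solvent-blank peak.

    A sample peak is removed iff some blank peak lies within
    ``blank_tol_ppm`` of it and the blank intensity is at least
    ``blank_intensity_ratio`` times the sample intensity. Returns a
    subset of the sample peaks; never creates peaks.
    """
    config = config or PreprocessConfig()
    if sample.meta.solvent.label != blank.meta.solvent.label:
        raise ValueError(
            f"solvent mismatch: sample {sample.meta.solvent.label!r} vs "
            f"blank {blank.meta.solvent.label!r}"
        )
    if sample.meta.ion_mode != blank.meta.ion_mode:
        raise ValueError("ion mode mismatch between sample and blank")
    if len(sample) == 0 or len(blank) == 0:
        return sample

    tol = config.blank_tol_ppm * 1e-6 * sample.mz
    # nearest blank peak on each side of every sample peak
    pos = np.searchsorted(blank.mz, sample.mz)
    left = np.clip(pos - 1, 0, len(blank) - 1)
    right = np.clip(pos, 0, len(blank) - 1)
    keep = np.ones(len(sample), dtype=bool)
    for nbr in (left, right):
        close = np.abs(blank.mz[nbr] - sample.mz) <= tol
        strong = blank.intensity[nbr] >= config.blank_intensity_ratio * sample.intensity
        keep &= ~(close & strong)
    removed = int((~keep).sum())
    if removed == len(sample):
        warnings.warn("blank subtraction removed every sample peak", stacklevel=2)
    out = sample.take(keep)
    return out


def normalize(spectrum: Spectrum) -> Spectrum:
    """Set relative intensity as percent of the base peak (max = 100)."""
    if len(spectrum) == 0:
        raise ValueError("cannot normalize an empty spectrum")
    top = spectrum.intensity.max()
    if top <= 0:
        raise ValueError("cannot normalize: all intensities are zero")
    # divide before scaling so the base peak lands on 100.0 exactly
    return replace(spectrum, rel_intensity=(spectrum.intensity / top) * 100.0)


def filter_rel_intensity(spectrum: Spectrum, min_pct: float | None = None) -> Spectrum:
    """Drop peaks whose relative intensity is below ``min_pct`` percent.

    The boundary is inclusive on the keep side: a peak at exactly the
    threshold is retained.
    """
    if spectrum.rel_intensity is None:
        raise ValueError("rel_intensity unset; call normalize first")
    if min_pct is None:
        min_pct = PreprocessConfig().rel_intensity_min_pct
    return spectrum.take(spectrum.rel_intensity >= min_pct)


def estimate_noise(spectrum: Spectrum, noise_quantile: float = 0.2) -> float:
    """Median raw intensity of the lowest-intensity fraction of peaks."""
    n_low = max(1, int(np.ceil(noise_quantile * len(spectrum))))
    lowest = np.sort(spectrum.intensity)[:n_low]
    return float(np.median(lowest))


def filter_snr(spectrum: Spectrum, config: PreprocessConfig | None = None) -> Spectrum:
    """Drop peaks below ``snr_min`` times the estimated noise level.

    The noise level is a property of the acquisition, so it is estimated
    once per spectrum and cached on the result; re-filtering an already
    filtered spectrum reuses the cached estimate and is a no-op.
    Spectra with fewer than five peaks are passed through unchanged with
    a warning — the quantile estimate would be meaningless.
    """
    config = config or PreprocessConfig()
    if len(spectrum) < _MIN_PEAKS_FOR_NOISE and spectrum.noise_level is None:
        warnings.warn(
            f"only {len(spectrum)} peaks: skipping S/N filter "
            "(noise estimate unreliable)",
            stacklevel=2,
        )
        return spectrum
    noise = spectrum.noise_level
    if noise is None:
        noise = estimate_noise(spectrum, config.noise_quantile)
    out = spectrum.take(spectrum.intensity >= config.snr_min * noise)
    out.noise_level = noise
    return out


def preprocess(
    sample: Spectrum,
    blank: Spectrum | None = None,
    config: PreprocessConfig | None = None,
) -> Spectrum:
    """Run the full default chain: subtract → S/N → normalize → 1 % cut."""
    config = config or PreprocessConfig()
    out = sample
    if blank is not None:
        out = subtract_blank(out, blank, config)
    if len(out) == 0:
        return out
    out = filter_snr(out, config)
    if len(out) == 0:
        return out
    out = normalize(out)
    return filter_rel_intensity(out, config.rel_intensity_min_pct)
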