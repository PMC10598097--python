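"""Peak-list and dataset I/O.

Centroided high-resolution spectra arrive as two-column ASCII ``.xy`` files
(m/z and intensity, one peak per line). A CSV manifest maps each file to
its sample code, extraction solvent, organic/aqueous ratio, ion mode and
blank status, and pairs every sample spectrum with its matched solvent
blank. All m/z values are kept at full double precision — the downstream
formula search works in a ±0.5 ppm window, which sub-ppm rounding would
corrupt.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IonMode",
    "Peak",
    "SolventMixture",
    "SpectrumMeta",
    "Spectrum",
    "Dataset",
    "STUDY_SOLVENTS",
    "read_xy",
    "write_xy",
    "load_dataset",
]

MANIFEST_COLUMNS = [
    "file",
    "sample_code",
    "solvent_label",
    "organic_aqueous_ratio",
    "ion_mode",
    "is_blank",
]

_AQUEOUS_NAMES = {"h2o", "water"}


class IonMode(str, enum.Enum):
    """Electrospray polarity."""

    NEGATIVE = "negative"
    POSITIVE = "positive"

    @classmethod
    def parse(cls, token: str) -> "IonMode":
        t = str(token).strip().lower()
        if t in {"negative", "neg", "-", "minus", "esi-"}:
            return cls.NEGATIVE
        if t in {"positive", "pos", "+", "plus", "esi+"}:
            return cls.POSITIVE
        raise ValueError(f"unknown ion mode token: {token!r}")


class Peak(NamedTuple):
    """A single centroided peak."""

    mz: float
    intensity: float
    rel_intensity: float | None = None


@dataclass(frozen=True)
class SolventMixture:
    """An extraction solvent mixture and its organic/aqueous ratio.

    ``components`` are (solvent name, volume fraction) pairs summing to 1;
    the organic/aqueous ratio is the total volume fraction of non-aqueous
    components, the covariate driving extraction differences between
    mixtures.
    """

    label: str
    components: tuple[tuple[str, float], ...]
    organic_aqueous_ratio: float

    def __post_init__(self) -> None:
        total = sum(f for _, f in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"volume fractions sum to {total}, expected 1")
        organic = sum(
            f for name, f in self.components if name.lower() not in _AQUEOUS_NAMES
        )
        if abs(organic - self.organic_aqueous_ratio) > 1e-9:
            raise ValueError(
                f"organic_aqueous_ratio {self.organic_aqueous_ratio} does not "
                f"match organic fraction {organic}"
            )

    @classmethod
    def from_ratio(cls, label: str, ratio: float) -> "SolventMixture":
        """Build a generic organic/water mixture from its ratio alone."""
        ratio = float(ratio)
        if not 0.0 <= ratio <= 1.0:
            raise ValueError(f"organic/aqueous ratio {ratio} outside [0, 1]")
        comps: list[tuple[str, float]] = []
        if ratio > 0:
            comps.append(("organic", ratio))
        if ratio < 1:
            comps.append(("H2O", 1.0 - ratio))
        return cls(label=label, components=tuple(comps), organic_aqueous_ratio=ratio)


def _mix(label: str, ratio: float, *components: tuple[str, float]) -> SolventMixture:
    return SolventMixture(label, tuple(components), ratio)


#: The ten solvent mixtures screened in the study, keyed by label.
STUDY_SOLVENTS: dict[str, SolventMixture] = {
    m.label: m
    for m in (
        _mix("1:1 acetone:H2O", 0.5, ("acetone", 0.5), ("H2O", 0.5)),
        _mix("1:1 MeOH:H2O", 0.5, ("MeOH", 0.5), ("H2O", 0.5)),
        _mix("1:1 EtOH:H2O", 0.5, ("EtOH", 0.5), ("H2O", 0.5)),
        _mix("1:1 AcN:H2O", 0.5, ("AcN", 0.5), ("H2O", 0.5)),
        _mix("3:1 MeOH:H2O", 0.75, ("MeOH", 0.75), ("H2O", 0.25)),
        _mix("3:1 AcN:H2O", 0.75, ("AcN", 0.75), ("H2O", 0.25)),
        _mix("1:3 MeOH:H2O", 0.25, ("MeOH", 0.25), ("H2O", 0.75)),
        _mix("1:3 AcN:H2O", 0.25, ("AcN", 0.25), ("H2O", 0.75)),
        _mix("1:1:2 acetone:AcN:H2O", 0.5, ("acetone", 0.25), ("AcN", 0.25), ("H2O", 0.5)),
        _mix("1:1:2 acetone:MeOH:H2O", 0.5, ("acetone", 0.25), ("MeOH", 0.25), ("H2O", 0.5)),
    )
}


@dataclass(frozen=True)
class SpectrumMeta:
    """Sample-level metadata carried alongside a peak list."""

    sample_code: str
    solvent: SolventMixture
    ion_mode: IonMode
    is_blank: bool = False
    source_path: str = ""


@dataclass
class Spectrum:
    """An ordered peak list with metadata.

    Peaks are stored as parallel numpy arrays, strictly ascending and
    duplicate-free in m/z. ``rel_intensity`` (percent of the base peak) is
    absent until normalization. ``noise_level`` caches the noise estimate
    made by the S/N filter; it is a property of the acquisition, so it is
    estimated once and carried through subsequent filtering.
    """

    mz: np.ndarray
    intensity: np.ndarray
    meta: SpectrumMeta
    rel_intensity: np.ndarray | None = None
    noise_level: float | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.rel_intensity is not None:
            self.rel_intensity = np.asarray(self.rel_intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity lengths differ")
        if self.mz.size and self.mz[0] <= 0:
            raise ValueError("m/z values must be positive")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        if self.mz.size > 1 and np.any(np.diff(self.mz) <= 0):
            raise ValueError("m/z values must be strictly ascending and unique")
        if self.rel_intensity is not None and self.rel_intensity.size:
            lo, hi = self.rel_intensity.min(), self.rel_intensity.max()
            if lo < 0 or hi > 100 + 1e-9:
                raise ValueError("rel_intensity outside [0, 100]")

    def __len__(self) -> int:
        return int(self.mz.size)

    def __iter__(self) -> Iterator[Peak]:
        rel = self.rel_intensity
        for i in range(len(self)):
            yield Peak(
                float(self.mz[i]),
                float(self.intensity[i]),
                None if rel is None else float(rel[i]),
            )

    @property
    def peaks(self) -> list[Peak]:
        return list(self)

    def take(self, mask_or_indices: np.ndarray) -> "Spectrum":
        """Subset peaks by boolean mask or index array, keeping metadata."""
        return replace(
            self,
            mz=self.mz[mask_or_indices],
            intensity=self.intensity[mask_or_indices],
            rel_intensity=None
            if self.rel_intensity is None
            else self.rel_intensity[mask_or_indices],
        )


@dataclass
class Dataset:
    """A loaded study: spectra plus sample-to-blank pairing.

    ``pairs`` maps the index of each non-blank spectrum to the index of its
    matched blank (same solvent label and ion mode), or None when no blank
    was provided for that combination.
    """

    spectra: list[Spectrum]
    pairs: dict[int, int | None] = field(default_factory=dict)

    def samples(self) -> list[Spectrum]:
        return [s for s in self.spectra if not s.meta.is_blank]


def read_xy(path: str | Path, meta: SpectrumMeta) -> Spectrum:
    """Read a two-column ASCII ``.xy`` peak list.

    Lines hold m/z and intensity separated by whitespace, a comma, or a
    tab (auto-detected per line). Peaks are returned sorted ascending in
    m/z; duplicate m/z values are merged keeping the maximum intensity,
    with a warning — duplicates indicate centroiding artifacts, not real
    signal.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    mzs: list[float] = []
    intens: list[float] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split(",") if "," in line else line.split()
            if len(fields) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected two fields, got {len(fields)}"
                )
            try:
                mz, inten = float(fields[0]), float(fields[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric field") from exc
            mzs.append(mz)
            intens.append(inten)
    if not mzs:
        raise ValueError(f"{path}: zero parsable lines")
    mz_arr = np.array(mzs)
    in_arr = np.array(intens)
    order = np.argsort(mz_arr, kind="stable")
    mz_arr, in_arr = mz_arr[order], in_arr[order]
    uniq, inverse = np.unique(mz_arr, return_inverse=True)
    if uniq.size != mz_arr.size:
        merged = np.zeros(uniq.size)
        np.maximum.at(merged, inverse, in_arr)
        warnings.warn(
            f"{path}: merged {mz_arr.size - uniq.size} duplicate m/z value(s), "
            "keeping maximum intensity",
            stacklevel=2,
        )
        mz_arr, in_arr = uniq, merged
    return Spectrum(mz=mz_arr, intensity=in_arr, meta=replace(meta, source_path=str(path)))


def write_xy(spectrum: Spectrum, path: str | Path) -> Path:
    """Write a peak list as two-column ASCII; round-trips m/z and raw
    intensity to 1e-6. Relative intensity is not part of the format."""
    if len(spectrum) == 0:
        raise ValueError("refusing to write an empty spectrum")
    path = Path(path)
    with path.open("w") as fh:
        for mz, inten in zip(spectrum.mz, spectrum.intensity):
            # shortest round-trip representation: no precision loss at I/O
            fh.write(f"{float(mz)!r} {float(inten)!r}\n")
    return path


def _solvent_for(label: str, ratio: float) -> SolventMixture:
    known = STUDY_SOLVENTS.get(label)
    if known is not None:
        if abs(known.organic_aqueous_ratio - float(ratio)) > 1e-9:
            raise ValueError(
                f"manifest ratio {ratio} contradicts known mixture {label!r} "
                f"(ratio {known.organic_aqueous_ratio})"
            )
        return known
    return SolventMixture.from_ratio(label, ratio)


def load_dataset(manifest: str | Path, base_dir: str | Path | None = None) -> Dataset:
    """Load every spectrum named in a manifest CSV and pair blanks.

    The manifest has header ``file,sample_code,solvent_label,
    organic_aqueous_ratio,ion_mode,is_blank``. Each non-blank spectrum is
    paired with at most one blank sharing its (solvent label, ion mode);
    a missing blank is a warning, not an error — that pair simply skips
    blank subtraction downstream.
    """
    manifest = Path(manifest)
    base = Path(base_dir) if base_dir is not None else manifest.parent
    table = pd.read_csv(manifest)
    missing_cols = set(MANIFEST_COLUMNS) - set(table.columns)
    if missing_cols:
        raise ValueError(f"manifest missing columns: {sorted(missing_cols)}")

    spectra: list[Spectrum] = []
    keys: set[tuple] = set()
    for row in table.itertuples(index=False):
        mode = IonMode.parse(row.ion_mode)
        is_blank = str(row.is_blank).strip().lower() in {"1", "true", "yes"}
        key = (row.sample_code, row.solvent_label, mode, is_blank)
        if key in keys:
            raise ValueError(f"duplicate manifest key {key}")
        keys.add(key)
        meta = SpectrumMeta(
            sample_code=str(row.sample_code),
            solvent=_solvent_for(str(row.solvent_label), float(row.organic_aqueous_ratio)),
            ion_mode=mode,
            is_blank=is_blank,
        )
        fpath = Path(row.file)
        if not fpath.is_absolute():
            fpath = base / fpath
        spectra.append(read_xy(fpath, meta))

    blanks: dict[tuple[str, IonMode], int] = {}
    for i, s in enumerate(spectra):
        if s.meta.is_blank:
            blanks[(s.meta.solvent.label, s.meta.ion_mode)] = i
    pairs: dict[int, int | None] = {}
    for i, s in enumerate(spectra):
        if s.meta.is_blank:
            continue
        match = blanks.get((s.meta.solvent.label, s.meta.ion_mode))
        if match is None:
            warnings.warn(
                f"no blank for sample {s.meta.sample_code!r} / "
                f"{s.meta.solvent.label!r} / {s.meta.ion_mode.value}; "
                "blank subtraction will be skipped",
                stacklevel=2,
            )
        pairs[i] = match
    return Dataset(spectra=spectra, pairs=pairs)


def write_manifest(rows: Sequence[dict], path: str | Path) -> Path:
    """Write a manifest CSV in the canonical column order."""
    frame = pd.DataFrame(list(rows))[MANIFEST_COLUMNS]
    path = Path(path)
    frame.to_csv(path, index=False)
    return path
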