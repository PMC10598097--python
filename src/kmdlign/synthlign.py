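"""Synthetic lignin-like ESI-HRMS datasets with full ground truth.

Real lignin extracts are dominated by homologous oligomer series built
from the three monolignol-derived units — p-hydroxyphenyl (H, C9H10O2),
guaiacyl (G, C10H12O3) and syringyl (S, C11H14O4) — condensed with loss
of one water per linkage, plus CH2/O homologation and heteroatom-bearing
contaminant classes. The generator emits such components as exact
[M−H]⁻ / [M+H]⁺ peaks with Gaussian ppm-scale mass jitter and log-normal
intensities, includes each component per solvent mixture with a logistic
probability in the organic/aqueous ratio (the designed "extraction
propensity"), and appends low-intensity background noise plus
contaminant peaks shared with matched solvent blanks. Every emitted
sample peak carries a ground-truth record (true formula, group label,
true m/z), so formula recovery, series detection, gating and solvent
ranking can all be scored against the design.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import log

import numpy as np
import pandas as pd
from scipy.special import expit

from .formula_assign import (
    ElementalLimits,
    Formula,
    FormulaAssignment,
    ion_mz,
    monoisotopic_mass,
)
from .kendrick import CH2, GatePolygon, KendrickBase
from .spectra_io import (
    IonMode,
    SolventMixture,
    Spectrum,
    SpectrumMeta,
    STUDY_SOLVENTS,
)

__all__ = [
    "ComponentSpec",
    "SyntheticConfig",
    "RecoveryReport",
    "H_UNIT",
    "G_UNIT",
    "S_UNIT",
    "oligomer",
    "default_components",
    "build_library",
    "simulate_spectrum",
    "simulate_blank",
    "simulate_dataset",
    "design_polygons",
    "expected_counts",
    "recovery_report",
    "benchmark_library",
    "benchmark_spectrum",
]

#: Monolignol-derived repeat units.
H_UNIT = Formula(c=9, h=10, o=2)
G_UNIT = Formula(c=10, h=12, o=3)
S_UNIT = Formula(c=11, h=14, o=4)
_WATER = Formula(c=0, h=2, o=1)
_CH2 = Formula(c=1, h=2)
_NH = Formula(c=0, h=1, n=1)
_O = Formula(c=0, h=0, o=1)
_S = Formula(c=0, h=0, s=1)


def _add(a: Formula, b: Formula, k: int = 1) -> Formula:
    return Formula(a.c + k * b.c, a.h + k * b.h, a.n + k * b.n,
                   a.o + k * b.o, a.s + k * b.s)


def oligomer(units: list[Formula]) -> Formula:
    """Condense monomer units, losing one water per bond formed."""
    if not units:
        raise ValueError("need at least one unit")
    total = units[0]
    for u in units[1:]:
        total = _add(total, u)
    return _add(total, _WATER, -(len(units) - 1))


@dataclass(frozen=True)
class ComponentSpec:
    """One designed peak group: its true formulas and solvent response.

    ``base_abundance`` is the mean natural-log intensity of the group's
    peaks; inclusion of each formula in a given solvent's spectrum is
    Bernoulli with probability logistic(solvent_slope × (ratio −
    solvent_midpoint)), where ratio is the mixture's organic/aqueous
    ratio.
    """

    group_label: int
    formulas: tuple[Formula, ...]
    base_abundance: float = log(1e6)
    solvent_slope: float = 10.0
    solvent_midpoint: float = 0.5

    def inclusion_probability(self, organic_aqueous_ratio: float) -> float:
        return float(
            expit(self.solvent_slope * (organic_aqueous_ratio - self.solvent_midpoint))
        )


def _ladder(core: Formula, n_ch2: int, limits: ElementalLimits) -> list[Formula]:
    out = []
    for k in range(n_ch2):
        f = _add(core, _CH2, k)
        if limits.admits(f) and f.h <= 2 * f.c + f.n + 2:
            out.append(f)
    return out


def default_components(
    limits: ElementalLimits | None = None,
    series_length: int = 8,
) -> tuple[ComponentSpec, ...]:
    """The four-group default design.

    Three lignin-like groups (G-oligomer, S-oligomer/oxygenated, reduced
    high-H/C) respond positively to organic-rich mixtures; one N/S
    contaminant-class group prefers aqueous-rich mixtures. The groups
    occupy distinct (H/C, O/C, DBE) bands and separable KMD bands, and
    the overall design is asymmetric in solvent preference so that
    whole-spectrum peak counts rise with the organic/aqueous ratio.
    """
    limits = limits or ElementalLimits()
    g2 = oligomer([G_UNIT, G_UNIT])                     # C20H22O5, DBE 10
    s2o2 = _add(oligomer([S_UNIT, S_UNIT]), _O, 2)      # C22H26O9, DBE 10
    groups = [
        # G-dimer series (±2H, +O): KMD band 0.2415–0.2644
        ComponentSpec(
            group_label=1,
            formulas=tuple(
                _ladder(g2, series_length, limits)
                + _ladder(Formula(c=20, h=20, o=5), series_length, limits)
                + _ladder(_add(g2, _O), series_length, limits)
            ),
            base_abundance=log(1.2e6),
            solvent_slope=12.0,
            solvent_midpoint=0.45,
        ),
        # oxygenated S-dimer series (0/−2/−4 H): KMD band 0.3333–0.3601
        ComponentSpec(
            group_label=2,
            formulas=tuple(
                _ladder(s2o2, series_length, limits)
                + _ladder(Formula(c=22, h=24, o=9), series_length, limits)
                + _ladder(Formula(c=22, h=22, o=9), series_length, limits)
            ),
            base_abundance=log(1e6),
            solvent_slope=8.0,
            solvent_midpoint=0.5,
        ),
        # reduced, high-H/C, low-DBE series: KMD band 0.0884–0.1343
        ComponentSpec(
            group_label=3,
            formulas=tuple(
                _ladder(Formula(c=15, h=28, o=3), series_length, limits)
                + _ladder(Formula(c=16, h=28, o=4), series_length, limits)
                + _ladder(Formula(c=17, h=32, o=5), series_length, limits)
            ),
            base_abundance=log(9e5),
            solvent_slope=10.0,
            solvent_midpoint=0.55,
        ),
        # N/S contaminant classes, aqueous-favoring: KMD band 0.1633–0.2076
        ComponentSpec(
            group_label=4,
            formulas=tuple(
                _ladder(Formula(c=12, h=18, n=2, o=4), series_length, limits)
                + _ladder(Formula(c=13, h=19, n=1, o=3, s=1), series_length, limits)
                + _ladder(Formula(c=11, h=17, n=1, o=4, s=1), series_length, limits)
            ),
            base_abundance=log(1e6),
            solvent_slope=-10.0,
            solvent_midpoint=0.5,
        ),
    ]
    return tuple(groups)


#: Fixed contaminant m/z values shared between samples and blanks
#: (plasticizer/solvent-cluster-like, spread over the scan range).
DEFAULT_CONTAMINANTS: tuple[float, ...] = (
    112.98563, 255.23295, 311.16870, 417.22935, 536.16537, 679.31422,
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Everything the generator needs; ``seed`` is mandatory."""

    seed: int
    components: tuple[ComponentSpec, ...] = field(default_factory=default_components)
    solvents: tuple[SolventMixture, ...] = tuple(STUDY_SOLVENTS.values())
    ion_mode: IonMode = IonMode.NEGATIVE
    ppm_sigma: float = 0.15
    intensity_sigma: float = 0.4
    noise_peak_count: int = 40
    noise_intensity: tuple[float, float] = (100.0, 2000.0)
    blank_contaminants: tuple[float, ...] = DEFAULT_CONTAMINANTS
    contaminant_abundance: float = log(8e5)
    mz_range: tuple[float, float] = (100.0, 2000.0)

    def __post_init__(self) -> None:
        if self.ppm_sigma < 0:
            raise ValueError("ppm_sigma must be non-negative")
        lo, hi = self.mz_range
        for spec in self.components:
            for f in spec.formulas:
                mz = ion_mz(monoisotopic_mass(f), self.ion_mode)
                if not lo <= mz <= hi:
                    raise ValueError(
                        f"component {f} ionizes at m/z {mz:.4f}, outside "
                        f"the scan range {self.mz_range}"
                    )


def build_library(config: SyntheticConfig) -> tuple[ComponentSpec, ...]:
    """The concrete component library of a config, validated against the
    study's elemental limits and the valence rule."""
    limits = ElementalLimits()
    for spec in config.components:
        if not spec.formulas:
            raise ValueError(f"group {spec.group_label} has no formulas")
        for f in spec.formulas:
            if not limits.admits(f):
                raise ValueError(f"formula {f} violates the elemental limits")
            if f.h > 2 * f.c + f.n + 2:
                raise ValueError(f"formula {f} violates the valence bound")
    return config.components


def _emit(
    rng: np.random.Generator,
    rows: list[dict],
    mz: float,
    intensity: float,
    kind: str,
    formula: str,
    group: int,
    solvent_label: str,
    ppm_sigma: float,
) -> None:
    jittered = mz * (1.0 + rng.normal(0.0, ppm_sigma) * 1e-6)
    rows.append(
        dict(mz=jittered, intensity=intensity, kind=kind, formula=formula,
             group_label=group, solvent_label=solvent_label, true_mz=mz)
    )


def _finish(rows: list[dict], meta: SpectrumMeta) -> tuple[Spectrum, pd.DataFrame]:
    frame = pd.DataFrame(rows).sort_values("mz", kind="stable").reset_index(drop=True)
    frame = frame.drop_duplicates(subset="mz", keep="first").reset_index(drop=True)
    frame["peak_index"] = frame.index
    spectrum = Spectrum(
        mz=frame["mz"].to_numpy(),
        intensity=frame["intensity"].to_numpy(),
        meta=meta,
    )
    truth = frame[
        ["peak_index", "kind", "formula", "group_label", "solvent_label", "true_mz"]
    ].copy()
    return spectrum, truth


def _noise_and_contaminants(
    rng: np.random.Generator,
    rows: list[dict],
    config: SyntheticConfig,
    solvent_label: str,
) -> None:
    for cmz in config.blank_contaminants:
        inten = float(np.exp(rng.normal(config.contaminant_abundance,
                                        config.intensity_sigma)))
        _emit(rng, rows, cmz, inten, "contaminant", "", -1, solvent_label,
              config.ppm_sigma)
    lo, hi = config.mz_range
    ilo, ihi = config.noise_intensity
    for _ in range(config.noise_peak_count):
        _emit(rng, rows, float(rng.uniform(lo, hi)),
              float(rng.uniform(ilo, ihi)), "noise", "", -1, solvent_label, 0.0)


def simulate_spectrum(
    library: tuple[ComponentSpec, ...],
    solvent: SolventMixture,
    config: SyntheticConfig,
    seed: int | np.random.SeedSequence,
) -> tuple[Spectrum, pd.DataFrame]:
    """One sample spectrum for one solvent mixture, with ground truth.

    Identical seeds give bit-identical output. The returned truth table
    has one row per emitted peak, joinable to the spectrum by
    ``peak_index``.
    """
    rng = np.random.default_rng(seed)
    ratio = solvent.organic_aqueous_ratio
    rows: list[dict] = []
    for spec in library:
        p = spec.inclusion_probability(ratio)
        for f in spec.formulas:
            if rng.random() >= p:
                continue
            mz = ion_mz(monoisotopic_mass(f), config.ion_mode)
            inten = float(np.exp(rng.normal(spec.base_abundance,
                                            config.intensity_sigma)))
            _emit(rng, rows, mz, inten, "component", str(f), spec.group_label,
                  solvent.label, config.ppm_sigma)
    _noise_and_contaminants(rng, rows, config, solvent.label)
    meta = SpectrumMeta(sample_code="SYN", solvent=solvent,
                        ion_mode=config.ion_mode, is_blank=False)
    return _finish(rows, meta)


def simulate_blank(
    config: SyntheticConfig,
    seed: int | np.random.SeedSequence,
    solvent: SolventMixture | None = None,
) -> Spectrum:
    """A solvent blank: contaminants plus background noise, no library
    component."""
    rng = np.random.default_rng(seed)
    solvent = solvent or config.solvents[0]
    rows: list[dict] = []
    _noise_and_contaminants(rng, rows, config, solvent.label)
    meta = SpectrumMeta(sample_code="BLANK", solvent=solvent,
                        ion_mode=config.ion_mode, is_blank=True)
    spectrum, _ = _finish(rows, meta)
    return spectrum


@dataclass
class SyntheticDataset:
    """Per-solvent samples, matched blanks, and ground truth."""

    samples: dict[str, Spectrum]
    blanks: dict[str, Spectrum]
    truth: dict[str, pd.DataFrame]
    config: SyntheticConfig


def simulate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """One sample + one matched blank per solvent mixture."""
    library = build_library(config)
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(2 * len(config.solvents))
    samples: dict[str, Spectrum] = {}
    blanks: dict[str, Spectrum] = {}
    truth: dict[str, pd.DataFrame] = {}
    for i, solvent in enumerate(config.solvents):
        spectrum, t = simulate_spectrum(library, solvent, config, children[2 * i])
        samples[solvent.label] = spectrum
        truth[solvent.label] = t
        blanks[solvent.label] = simulate_blank(config, children[2 * i + 1], solvent)
    return SyntheticDataset(samples=samples, blanks=blanks, truth=truth,
                            config=config)


def design_polygons(
    components: tuple[ComponentSpec, ...],
    ion_mode: IonMode = IonMode.NEGATIVE,
    base: KendrickBase = CH2,
    pad_km: float = 2.0,
    pad_kmd: float = 0.004,
) -> dict[int, GatePolygon]:
    """Rectangular gates around each group's theoretical (KM, KMD) box.

    Padding absorbs ppm-scale jitter; the default group design keeps the
    padded boxes disjoint so gating cleanly separates the groups.
    """
    out: dict[int, GatePolygon] = {}
    scale = base.nominal_mass / base.exact_mass
    for spec in components:
        mzs = np.array(
            [ion_mz(monoisotopic_mass(f), ion_mode) for f in spec.formulas]
        )
        km = mzs * scale
        kmd = np.floor(km + 0.5) - km
        x0, x1 = km.min() - pad_km, km.max() + pad_km
        y0, y1 = kmd.min() - pad_kmd, kmd.max() + pad_kmd
        out[spec.group_label] = GatePolygon(
            ((x0, y0), (x1, y0), (x1, y1), (x0, y1))
        )
    return out


def expected_counts(
    components: tuple[ComponentSpec, ...],
    solvents: tuple[SolventMixture, ...],
) -> dict[str, float]:
    """Designed extraction propensity: expected component-peak count per
    solvent mixture."""
    return {
        sol.label: sum(
            len(spec.formulas) * spec.inclusion_probability(sol.organic_aqueous_ratio)
            for spec in components
        )
        for sol in solvents
    }


@dataclass(frozen=True)
class RecoveryReport:
    """Scoring of pipeline output against generator ground truth."""

    n_component_peaks: int
    n_recovered: int
    recovery_rate: float
    per_group: dict[int, float]
    per_mass_bin: dict[str, float]
    rank_spearman: float | None = None


def recovery_report(
    truth: pd.DataFrame,
    assignments: list[FormulaAssignment],
    ranking=None,
    components: tuple[ComponentSpec, ...] | None = None,
    solvents: tuple[SolventMixture, ...] | None = None,
    bin_width: float = 100.0,
) -> RecoveryReport:
    """Exact-formula recovery against ground truth, overall, per designed
    group and per ``bin_width``-u neutral-mass bin; optionally the
    Spearman correlation between a recovered solvent ranking's counts and
    the designed extraction propensities."""
    comp = truth[truth["kind"] == "component"]
    if comp.empty:
        raise ValueError("truth table holds no component peaks")
    assigned = {a.peak_index: str(a.formula) for a in assignments}
    hits = comp.apply(
        lambda row: assigned.get(row["peak_index"]) == row["formula"], axis=1
    )
    per_group = {
        int(g): float(hits[comp["group_label"] == g].mean())
        for g in sorted(comp["group_label"].unique())
    }
    bins = (comp["true_mz"] // bin_width * bin_width).astype(int)
    per_bin = {
        f"{b}-{b + int(bin_width)}": float(hits[bins == b].mean())
        for b in sorted(bins.unique())
    }
    rho: float | None = None
    if ranking is not None and components is not None and solvents is not None:
        from scipy.stats import spearmanr

        designed = expected_counts(components, solvents)
        labels = sorted(designed)
        observed = {label: count for label, _, count in ranking.entries}
        rho = float(
            spearmanr(
                [designed[label] for label in labels],
                [observed.get(label, 0) for label in labels],
            ).statistic
        )
    return RecoveryReport(
        n_component_peaks=int(len(comp)),
        n_recovered=int(hits.sum()),
        recovery_rate=float(hits.mean()),
        per_group=per_group,
        per_mass_bin=per_bin,
        rank_spearman=rho,
    )


def benchmark_library(
    n: int = 500,
    mass_range: tuple[float, float] = (150.0, 800.0),
    seed: int = 0,
    limits: ElementalLimits | None = None,
) -> list[Formula]:
    """A deterministic set of ``n`` distinct lignin-like formulas.

    Oligomers of the H/G/S units (1–4 monomers, water loss per bond)
    decorated with ±CH2, +O, +NH and +S within the elemental limits,
    restricted to the neutral-mass range, sub-sampled to ``n`` with the
    given seed.
    """
    limits = limits or ElementalLimits()
    units = [H_UNIT, G_UNIT, S_UNIT]
    pool: set[Formula] = set()
    from itertools import combinations_with_replacement

    for size in range(1, 5):
        for combo in combinations_with_replacement(units, size):
            core = oligomer(list(combo))
            for k_ch2 in range(0, 11):
                for k_o in range(0, 4):
                    for k_nh in range(0, 3):
                        for k_s in range(0, 2):
                            f = _add(core, _CH2, k_ch2)
                            f = _add(f, _O, k_o)
                            f = _add(f, _NH, k_nh)
                            f = _add(f, _S, k_s)
                            if not limits.admits(f):
                                continue
                            if f.h > 2 * f.c + f.n + 2:
                                continue
                            m = monoisotopic_mass(f)
                            if mass_range[0] <= m <= mass_range[1]:
                                pool.add(f)
    ordered = sorted(pool)
    if len(ordered) < n:
        raise ValueError(
            f"only {len(ordered)} formulas available in {mass_range}, need {n}"
        )
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(ordered), size=n, replace=False)
    return [ordered[i] for i in sorted(picks)]


def benchmark_spectrum(
    formulas: list[Formula],
    seed: int,
    ppm_sigma: float = 0.15,
    ion_mode: IonMode = IonMode.NEGATIVE,
) -> tuple[Spectrum, pd.DataFrame]:
    """One peak per formula at its theoretical ion m/z plus ppm jitter."""
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    for f in formulas:
        mz = ion_mz(monoisotopic_mass(f), ion_mode)
        _emit(rng, rows, mz, 1e6, "component", str(f), 0, "benchmark", ppm_sigma)
    meta = SpectrumMeta(
        sample_code="BENCH",
        solvent=STUDY_SOLVENTS["1:1 MeOH:H2O"],
        ion_mode=ion_mode,
    )
    return _finish(rows, meta)
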