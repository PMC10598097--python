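"""Kendrick mass-defect transformation, polygon gating, series finding.

Rescaling observed m/z by (nominal mass / exact mass) of a repeating unit
— CH2 (14 / 14.01565) for lignin homologs — gives the Kendrick mass (KM);
its defect KMD = round(KM) − KM is identical for every member of a
homologous series, so series line up horizontally in a KM–KMD plot.
Regions of that plot are gated with explicit polygons (a reproducible
stand-in for interactive lasso selection); a gated region counts as a
peak group only when it holds at least five peaks.

Sign convention: KMD = nearest-integer(KM) − KM with half-up rounding,
giving KMD ∈ (−0.5, 0.5] and negative defects for strongly oxygenated
species. The ceiling convention KMD = ⌈KM⌉ − KM ∈ [0, 1) is available
for comparison with tools that use it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from .formula_assign import monoisotopic_mass, parse_formula
from .spectra_io import Spectrum

__all__ = [
    "KendrickBase",
    "KendrickPoint",
    "GatePolygon",
    "PeakGroup",
    "GateRejected",
    "CH2",
    "base_from_formula",
    "transform",
    "gate",
    "find_series",
    "MIN_GROUP_SIZE",
]

#: A gated area with fewer peaks than this is not considered a group.
MIN_GROUP_SIZE = 5


@dataclass(frozen=True)
class KendrickBase:
    """The repeating unit defining a Kendrick scale."""

    formula_label: str
    nominal_mass: int
    exact_mass: float

    def __post_init__(self) -> None:
        if self.exact_mass <= 0:
            raise ValueError("exact mass must be positive")
        if self.nominal_mass != round(self.exact_mass):
            raise ValueError(
                f"nominal mass {self.nominal_mass} is not round({self.exact_mass})"
            )


def base_from_formula(formula_label: str) -> KendrickBase:
    """Kendrick base from a repeating-unit formula, e.g. ``"CH2"``."""
    exact = monoisotopic_mass(parse_formula(formula_label))
    return KendrickBase(
        formula_label=formula_label,
        nominal_mass=int(round(exact)),
        exact_mass=exact,
    )


#: The CH2 base used for lignin oligomer series (14 / 14.01565).
CH2 = base_from_formula("CH2")


@dataclass(frozen=True)
class KendrickPoint:
    """One peak's coordinates in (KM, KMD) space."""

    peak_index: int
    mz: float
    km: float
    kmd: float


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def transform(
    spectrum: Spectrum,
    base: KendrickBase = CH2,
    convention: Literal["nearest", "ceiling"] = "nearest",
) -> list[KendrickPoint]:
    """Kendrick transform of every peak: KM = mz × nominal / exact.

    ``nearest`` (default): KMD = round-half-up(KM) − KM ∈ (−0.5, 0.5].
    ``ceiling``: KMD = ⌈KM⌉ − KM ∈ [0, 1).
    """
    if len(spectrum) == 0:
        raise ValueError("cannot transform an empty spectrum")
    km = spectrum.mz * (base.nominal_mass / base.exact_mass)
    if convention == "nearest":
        kmd = _round_half_up(km) - km
    elif convention == "ceiling":
        kmd = np.ceil(km) - km
    else:
        raise ValueError(f"unknown KMD convention {convention!r}")
    return [
        KendrickPoint(peak_index=i, mz=float(spectrum.mz[i]),
                      km=float(km[i]), kmd=float(kmd[i]))
        for i in range(len(spectrum))
    ]


@dataclass(frozen=True)
class GatePolygon:
    """A gate in (KM, KMD) space: ordered vertices, non-self-intersecting."""

    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise ValueError("polygon needs at least 3 vertices")
        if not self.shape().is_valid:
            raise ValueError("polygon is self-intersecting or degenerate")

    def shape(self) -> Polygon:
        return Polygon(self.vertices)

    @classmethod
    def read_csv(cls, path: str | Path) -> "GatePolygon":
        frame = pd.read_csv(path)
        if not {"km", "kmd"} <= set(frame.columns):
            raise ValueError(f"{path}: expected columns km,kmd")
        return cls(tuple(zip(frame["km"].astype(float), frame["kmd"].astype(float))))

    def write_csv(self, path: str | Path) -> Path:
        pd.DataFrame(self.vertices, columns=["km", "kmd"]).to_csv(path, index=False)
        return Path(path)


@dataclass(frozen=True)
class PeakGroup:
    """A gated set of peaks forming a group (≥ 5 members)."""

    group_id: int
    member_indices: tuple[int, ...]
    polygon: GatePolygon


@dataclass(frozen=True)
class GateRejected:
    """Gate outcome for an area with fewer than the minimum peaks."""

    group_id: int
    count: int
    member_indices: tuple[int, ...]


def gate(
    points: Sequence[KendrickPoint],
    polygon: GatePolygon,
    group_id: int,
    min_members: int = MIN_GROUP_SIZE,
) -> PeakGroup | GateRejected:
    """Select the points inside or on the polygon boundary.

    Boundary points are included — ties are never dropped silently.
    Returns a :class:`PeakGroup` when at least ``min_members`` points
    fall inside, otherwise a :class:`GateRejected` naming the count.
    """
    shape = polygon.shape()
    members = tuple(
        p.peak_index for p in points if shape.covers(Point(p.km, p.kmd))
    )
    if len(members) < min_members:
        return GateRejected(group_id=group_id, count=len(members),
                            member_indices=members)
    return PeakGroup(group_id=group_id, member_indices=members, polygon=polygon)


def find_series(
    points: Sequence[KendrickPoint],
    base: KendrickBase = CH2,
    kmd_tol: float = 0.001,
    min_members: int = 3,
) -> list[list[int]]:
    """Detect homologous series as repeating-unit ladders in KM.

    Points are first clustered on KMD by single linkage within
    ``kmd_tol``. Within a cluster, a series is a maximal set of points
    whose KM values differ pairwise by integer multiples of the base
    nominal mass to within 2 × ``kmd_tol`` — equivalently, whose KM
    residues modulo the nominal mass agree pairwise (circularly) within
    2 × ``kmd_tol``. Maximal residue windows yield the series; only
    series with at least ``min_members`` points are returned, each
    sorted by KM, and the result is independent of input point order.
    """
    if kmd_tol <= 0:
        raise ValueError("kmd_tol must be positive")
    if min_members < 2:
        raise ValueError("min_members must be at least 2")
    pts = sorted(range(len(points)), key=lambda i: (points[i].kmd, points[i].km))
    # single-linkage clusters on sorted kmd
    clusters: list[list[int]] = []
    for idx in pts:
        if clusters and points[idx].kmd - points[clusters[-1][-1]].kmd <= kmd_tol:
            clusters[-1].append(idx)
        else:
            clusters.append([idx])
    period = float(base.nominal_mass)
    tol2 = 2.0 * kmd_tol
    series: list[tuple[int, ...]] = []
    for cluster in clusters:
        if len(cluster) < min_members:
            continue
        resid = sorted(cluster, key=lambda i: points[i].km % period)
        r = [points[i].km % period for i in resid]
        m = len(resid)
        # circular sliding window: duplicate the residue axis shifted by one period
        ext_idx = resid + resid
        ext_r = r + [x + period for x in r]
        found: set[tuple[int, ...]] = set()
        for start in range(m):
            end = start
            while end + 1 < start + m and ext_r[end + 1] - ext_r[start] <= tol2:
                end += 1
            window = ext_idx[start : end + 1]
            if len(window) < min_members:
                continue
            key = tuple(sorted(window))
            found.add(key)
        # drop windows strictly contained in another (keep maximal sets only)
        maximal = [
            w for w in found
            if not any(w != v and set(w) <= set(v) for v in found)
        ]
        series.extend(maximal)
    out = [
        sorted(w, key=lambda i: points[i].km)
        for w in series
    ]
    out.sort(key=lambda s: (points[s[0]].km, points[s[0]].kmd, len(s)))
    return out
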