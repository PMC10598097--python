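"""Exact-mass CHNOS molecular-formula assignment.

Given a neutral monoisotopic mass, the search enumerates every elemental
composition C_c H_h N_n O_o S_s inside user-set element ranges whose
theoretical mass falls within a symmetric ppm window, then filters on
double-bond equivalents (DBE = C − H/2 + N/2 + 1), on integer DBE
(even-electron neutral species) and on the valence bound H ≤ 2C + N + 2.
Candidates are ordered by |ppm error|, then fewer heteroatoms, then
lexicographic element counts, and a peak receives the first candidate —
the lowest-mass-error formula, with deterministic tie-breaks.

The default limits are the study settings for lignin extracts:
C 1–90, H 4–200, N 0–5, O 1–23, S 0–1, ±0.5 ppm, DBE 0–50.

Two independent search routes are provided: :func:`enumerate_candidates`
solves H from the mass residual per (S, N, O, C) cell, while
:func:`brute_force_candidates` exhaustively materializes the whole grid;
the latter exists as a verification oracle and is deliberately naive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .constants import ELEMENT_ORDER, MONOISOTOPIC_MASS, PROTON_MASS
from .spectra_io import IonMode, Spectrum

__all__ = [
    "ElementalLimits",
    "Formula",
    "FormulaAssignment",
    "parse_formula",
    "monoisotopic_mass",
    "neutral_mass",
    "ion_mz",
    "dbe",
    "heteroatom_class",
    "enumerate_candidates",
    "brute_force_candidates",
    "assign",
    "AssignmentReport",
]

_M = MONOISOTOPIC_MASS
_BRUTE_FORCE_CAP = 10_000_000


@dataclass(frozen=True, order=True)
class Formula:
    """Elemental composition over C, H, N, O, S (neutral molecule)."""

    c: int
    h: int
    n: int = 0
    o: int = 0
    s: int = 0

    def __post_init__(self) -> None:
        if min(self.c, self.h, self.n, self.o, self.s) < 0:
            raise ValueError("element counts must be non-negative")

    def counts(self) -> tuple[int, int, int, int, int]:
        return (self.c, self.h, self.n, self.o, self.s)

    def __str__(self) -> str:
        parts = []
        for sym, cnt in zip(ELEMENT_ORDER, self.counts()):
            if cnt == 1:
                parts.append(sym)
            elif cnt > 1:
                parts.append(f"{sym}{cnt}")
        return "".join(parts)


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> Formula:
    """Parse a Hill-style formula string over C, H, N, O, S."""
    counts = {sym: 0 for sym in ELEMENT_ORDER}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(text):
        if match.start() != pos or not match.group(0):
            break
        sym, num = match.group(1), match.group(2)
        if sym not in counts:
            raise ValueError(f"unsupported element {sym!r} in {text!r}")
        counts[sym] += int(num) if num else 1
        pos = match.end()
    if pos != len(text) or pos == 0:
        raise ValueError(f"cannot parse formula {text!r}")
    return Formula(*(counts[sym] for sym in ELEMENT_ORDER))


def monoisotopic_mass(formula: Formula) -> float:
    """Neutral monoisotopic mass (u) from the pinned constants table."""
    c, h, n, o, s = formula.counts()
    return c * _M["C"] + h * _M["H"] + n * _M["N"] + o * _M["O"] + s * _M["S"]


def neutral_mass(mz: float, ion_mode: IonMode | str) -> float:
    """Neutral mass of the (de)protonated species observed at ``mz``.

    Negative mode observes [M−H]⁻, so the neutral is mz + m_proton;
    positive mode observes [M+H]⁺, the neutral is mz − m_proton.
    Adducts and multiple charging are outside the model.
    """
    mode = IonMode.parse(ion_mode) if not isinstance(ion_mode, IonMode) else ion_mode
    if mode is IonMode.NEGATIVE:
        if mz <= PROTON_MASS:
            raise ValueError(f"m/z {mz} too small for a deprotonated species")
        return mz + PROTON_MASS
    return mz - PROTON_MASS


def ion_mz(neutral: float, ion_mode: IonMode | str) -> float:
    """Theoretical m/z of the (de)protonated ion of a neutral mass."""
    mode = IonMode.parse(ion_mode) if not isinstance(ion_mode, IonMode) else ion_mode
    return neutral - PROTON_MASS if mode is IonMode.NEGATIVE else neutral + PROTON_MASS


def dbe(formula: Formula) -> float:
    """Double-bond equivalents (rings plus double bonds) of the neutral."""
    return formula.c - formula.h / 2 + formula.n / 2 + 1


def heteroatom_class(formula: Formula) -> str:
    """Class label listing S, N, O counts in that fixed order.

    Elements absent from the formula are omitted; pure hydrocarbons are
    labeled ``"CH"``. Examples: C9H10O2 → ``"O2"``;
    a formula with s=1, n=2, o=10 → ``"S1N2O10"``.
    """
    parts = []
    for sym, cnt in (("S", formula.s), ("N", formula.n), ("O", formula.o)):
        if cnt > 0:
            parts.append(f"{sym}{cnt}")
    return "".join(parts) or "CH"


@dataclass(frozen=True)
class ElementalLimits:
    """Search-space bounds for the formula finder."""

    c: tuple[int, int] = (1, 90)
    h: tuple[int, int] = (4, 200)
    n: tuple[int, int] = (0, 5)
    o: tuple[int, int] = (1, 23)
    s: tuple[int, int] = (0, 1)
    ppm_window: float = 0.5
    dbe_min: float = 0.0
    dbe_max: float = 50.0
    require_integer_dbe: bool = True
    enforce_valence: bool = True

    def __post_init__(self) -> None:
        for lo, hi in (self.c, self.h, self.n, self.o, self.s):
            if not 0 <= lo <= hi:
                raise ValueError(f"invalid element range ({lo}, {hi})")
        if self.ppm_window <= 0:
            raise ValueError("ppm_window must be positive")
        if self.dbe_min > self.dbe_max:
            raise ValueError("dbe_min exceeds dbe_max")

    def admits(self, formula: Formula) -> bool:
        """Element-range membership only (no mass window)."""
        for (lo, hi), cnt in zip(
            (self.c, self.h, self.n, self.o, self.s), formula.counts()
        ):
            if not lo <= cnt <= hi:
                return False
        return True


@dataclass(frozen=True)
class FormulaAssignment:
    """One peak's accepted formula with derived descriptors."""

    peak_index: int
    formula: Formula
    neutral_mass: float
    theoretical_mz: float
    error_ppm: float
    dbe: float
    h_c: float
    o_c: float
    het_class: str


@dataclass
class AssignmentReport:
    """Assignment outcome for a whole spectrum."""

    assignments: list[FormulaAssignment]
    unassigned: list[int]

    @property
    def rate(self) -> float:
        total = len(self.assignments) + len(self.unassigned)
        return len(self.assignments) / total if total else 0.0


def _sort_key(formula: Formula, err_ppm: float):
    return (abs(err_ppm), formula.n + formula.o + formula.s, formula.counts())


def _canonical_hits(
    keys: "list[tuple[int, int, int, int, int]]",
    neutral: float,
    limits: ElementalLimits,
) -> list[tuple[Formula, float]]:
    """Final window filter and ordering, shared by both search routes.

    Candidate pre-screens may use differently associated float sums; the
    accepted set and its ordering are always decided by the canonical
    :func:`monoisotopic_mass` error so the two routes agree bit-for-bit.
    """
    out = []
    for key in keys:
        f = Formula(*key)
        err = (monoisotopic_mass(f) - neutral) / neutral * 1e6
        if abs(err) <= limits.ppm_window:
            out.append((f, err))
    out.sort(key=lambda pair: _sort_key(pair[0], pair[1]))
    return out


def enumerate_candidates(
    neutral: float, limits: ElementalLimits | None = None
) -> list[tuple[Formula, float]]:
    """All formulas within the ppm window of a neutral mass, best first.

    Returns (formula, signed ppm error) pairs sorted by |error|, ties by
    fewer heteroatoms, then lexicographic element counts. Iterates the
    (S, N, O, C) lattice and solves the hydrogen count from the mass
    residual — only one or two H values can fall inside a sub-ppm window,
    so the inner dimension collapses to O(1).
    """
    limits = limits or ElementalLimits()
    if neutral <= 0:
        raise ValueError("neutral mass must be positive")
    # pre-screen window widened by a few ulps; the canonical filter decides
    tol = limits.ppm_window * 1e-6 * neutral * (1 + 1e-12) + 1e-9
    seen: set[tuple[int, int, int, int, int]] = set()
    c_vals = np.arange(limits.c[0], limits.c[1] + 1)
    h_lo, h_hi = limits.h
    for s in range(limits.s[0], limits.s[1] + 1):
        mass_s = s * _M["S"]
        if mass_s > neutral + tol:
            break
        for n in range(limits.n[0], limits.n[1] + 1):
            mass_sn = mass_s + n * _M["N"]
            if mass_sn > neutral + tol:
                break
            for o in range(limits.o[0], limits.o[1] + 1):
                mass_sno = mass_sn + o * _M["O"]
                if mass_sno > neutral + tol:
                    break
                h_center = (neutral - mass_sno - 12.0 * c_vals) / _M["H"]
                for h_arr in (np.floor(h_center), np.ceil(h_center)):
                    h = h_arr.astype(int)
                    ok = (h >= h_lo) & (h <= h_hi)
                    err = mass_sno + 12.0 * c_vals + h * _M["H"] - neutral
                    ok &= np.abs(err) <= tol
                    if limits.require_integer_dbe:
                        ok &= (h - n) % 2 == 0
                    if limits.enforce_valence:
                        ok &= h <= 2 * c_vals + n + 2
                    d = c_vals - h / 2 + n / 2 + 1
                    ok &= (d >= limits.dbe_min) & (d <= limits.dbe_max)
                    for i in np.nonzero(ok)[0]:
                        seen.add((int(c_vals[i]), int(h[i]), n, o, s))
    return _canonical_hits(sorted(seen), neutral, limits)


@lru_cache(maxsize=4)
def _grid(limits: ElementalLimits):
    """Materialized element-count grid with per-row masses and filters."""
    ranges = [np.arange(lo, hi + 1) for lo, hi in
              (limits.c, limits.h, limits.n, limits.o, limits.s)]
    size = int(np.prod([r.size for r in ranges]))
    if size > _BRUTE_FORCE_CAP:
        raise ValueError(
            f"brute-force grid of {size} combinations exceeds cap {_BRUTE_FORCE_CAP}"
        )
    c, h, n, o, s = (g.ravel() for g in np.meshgrid(*ranges, indexing="ij"))
    mass = (c * 12.0 + h * _M["H"] + n * _M["N"] + o * _M["O"] + s * _M["S"])
    d = c - h / 2 + n / 2 + 1
    ok = (d >= limits.dbe_min) & (d <= limits.dbe_max)
    if limits.require_integer_dbe:
        ok &= (h - n) % 2 == 0
    if limits.enforce_valence:
        ok &= h <= 2 * c + n + 2
    return c[ok], h[ok], n[ok], o[ok], s[ok], mass[ok]


def brute_force_candidates(
    neutral: float, limits: ElementalLimits | None = None
) -> list[tuple[Formula, float]]:
    """Exhaustive-enumeration oracle; same contract as
    :func:`enumerate_candidates`, same ordering, no shortcuts.

    Raises if the element ranges span more than 10^7 combinations rather
    than silently truncating.
    """
    limits = limits or ElementalLimits()
    if neutral <= 0:
        raise ValueError("neutral mass must be positive")
    c, h, n, o, s, mass = _grid(limits)
    tol = limits.ppm_window * 1e-6 * neutral * (1 + 1e-12) + 1e-9
    hit = np.abs(mass - neutral) <= tol
    keys = [
        (int(ci), int(hi_), int(ni), int(oi), int(si))
        for ci, hi_, ni, oi, si in zip(c[hit], h[hit], n[hit], o[hit], s[hit])
    ]
    return _canonical_hits(sorted(keys), neutral, limits)


def assign(
    spectrum: Spectrum,
    limits: ElementalLimits | None = None,
    ion_mode: IonMode | str | None = None,
) -> AssignmentReport:
    """Assign at most one formula per peak: the lowest-|ppm-error|
    candidate under the deterministic candidate ordering. Peaks with no
    in-window candidate are reported unassigned, not errors."""
    limits = limits or ElementalLimits()
    mode = ion_mode if ion_mode is not None else spectrum.meta.ion_mode
    mode = IonMode.parse(mode) if not isinstance(mode, IonMode) else mode
    assignments: list[FormulaAssignment] = []
    unassigned: list[int] = []
    for i, mz in enumerate(spectrum.mz):
        neutral = neutral_mass(float(mz), mode)
        cands = enumerate_candidates(neutral, limits)
        if not cands:
            unassigned.append(i)
            continue
        f, err = cands[0]
        assignments.append(
            FormulaAssignment(
                peak_index=i,
                formula=f,
                neutral_mass=monoisotopic_mass(f),
                theoretical_mz=ion_mz(monoisotopic_mass(f), mode),
                error_ppm=err,
                dbe=dbe(f),
                h_c=f.h / f.c,
                o_c=f.o / f.c,
                het_class=heteroatom_class(f),
            )
        )
    return AssignmentReport(assignments=assignments, unassigned=unassigned)
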