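"""Group-level characterization, solvent ranking and group matching.

After gating, each peak group is summarized by the ranges its members
span in Kendrick space (KM, KMD), van Krevelen space (H/C, O/C) and DBE,
plus its heteroatom classes — the row structure of a solvent-screening
summary table. Solvent mixtures are ranked by the number of peaks each
one yields (whole spectrum, or inside one group's gate), the per-group
"optimum 3 solvents" are the top three of that ranking, and organic/
aqueous-ratio trends are reported descriptively (class means and a
Spearman rank correlation — no significance claim, the underlying design
is observational). Groups from two samples are matched greedily by
bounding-box overlap in (KM, KMD) space to surface groups unique to one
sample, e.g. degradation products absent from a non-degraded lignin.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import math

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .formula_assign import FormulaAssignment
from .kendrick import (
    CH2,
    GatePolygon,
    GateRejected,
    KendrickBase,
    KendrickPoint,
    PeakGroup,
    gate,
    transform,
)
from .spectra_io import Spectrum

__all__ = [
    "GroupSummary",
    "SolventRanking",
    "GroupMatch",
    "RatioTrend",
    "summarize_group",
    "mark_unique_classes",
    "rank_solvents",
    "top_solvents_per_group",
    "ratio_trend",
    "match_groups",
    "summaries_to_frame",
    "summaries_from_frame",
]

Range = tuple[float, float]


@dataclass(frozen=True)
class GroupSummary:
    """One summary-table row for a gated peak group."""

    group_id: int
    n_members: int
    km_range: Range
    kmd_range: Range
    h_c_range: Range | None
    o_c_range: Range | None
    dbe_range: Range | None
    classes: frozenset[str]
    unique_classes: frozenset[str] = frozenset()
    top_solvents: tuple[str, ...] = ()


@dataclass(frozen=True)
class SolventRanking:
    """Solvents ordered by peak count (descending, ties alphabetical)."""

    entries: tuple[tuple[str, float, int], ...]  # (label, ratio, count)
    scope: int | Literal["whole-spectrum"] = "whole-spectrum"

    def labels(self) -> list[str]:
        return [label for label, _, _ in self.entries]


@dataclass(frozen=True)
class RatioTrend:
    """Descriptive organic/aqueous-ratio trend of a solvent ranking."""

    mean_count_high: float  # ratio >= 0.5
    mean_count_low: float  # ratio < 0.5
    difference: float
    spearman: float
    constant_counts: bool = False


@dataclass(frozen=True)
class GroupMatch:
    """Greedy bounding-box correspondence between two group sets."""

    pairs: tuple[tuple[int, int, float], ...]  # (id_a, id_b, overlap score)
    unique_to_a: tuple[int, ...]
    unique_to_b: tuple[int, ...]


def _minmax(values: Sequence[float]) -> Range:
    return (float(min(values)), float(max(values)))


def summarize_group(
    group: PeakGroup,
    points: Sequence[KendrickPoint],
    assignments: Sequence[FormulaAssignment] = (),
) -> GroupSummary:
    """Min/max ranges and heteroatom classes over a group's members.

    KM/KMD ranges come from every member; H/C, O/C and DBE ranges and the
    class set come only from members with an assigned formula, and are
    None when no member is assigned.
    """
    members = set(group.member_indices)
    if not members:
        raise ValueError("cannot summarize an empty group")
    by_index = {p.peak_index: p for p in points}
    kms = [by_index[i].km for i in group.member_indices]
    kmds = [by_index[i].kmd for i in group.member_indices]
    hit = [a for a in assignments if a.peak_index in members]
    return GroupSummary(
        group_id=group.group_id,
        n_members=len(group.member_indices),
        km_range=_minmax(kms),
        kmd_range=_minmax(kmds),
        h_c_range=_minmax([a.h_c for a in hit]) if hit else None,
        o_c_range=_minmax([a.o_c for a in hit]) if hit else None,
        dbe_range=_minmax([a.dbe for a in hit]) if hit else None,
        classes=frozenset(a.het_class for a in hit),
    )


def mark_unique_classes(summaries: Sequence[GroupSummary]) -> list[GroupSummary]:
    """Within one comparison set, mark classes found in no other group."""
    out = []
    for s in summaries:
        others: set[str] = set()
        for t in summaries:
            if t.group_id != s.group_id:
                others |= t.classes
        out.append(replace(s, unique_classes=frozenset(s.classes - others)))
    return out


def _gated_count(
    spectrum: Spectrum,
    polygon: GatePolygon,
    base: KendrickBase,
) -> int:
    if len(spectrum) == 0:
        return 0
    result = gate(transform(spectrum, base), polygon, group_id=-1, min_members=0)
    assert isinstance(result, PeakGroup)
    return len(result.member_indices)


def rank_solvents(
    dataset: Mapping[str, Spectrum],
    polygon: GatePolygon | None = None,
    base: KendrickBase = CH2,
    scope_id: int | None = None,
    metric: Literal["count", "intensity"] = "count",
) -> SolventRanking:
    """Rank solvent mixtures by observed peak count.

    ``dataset`` maps solvent label → preprocessed spectrum. Without a
    polygon the whole spectrum counts; with one, only gated points do.
    ``metric="intensity"`` ranks by summed raw intensity instead. Ties
    break alphabetically by label, so the ranking is deterministic and
    independent of input ordering.
    """
    if not dataset:
        raise ValueError("empty dataset")
    entries = []
    for label in sorted(dataset):
        spec = dataset[label]
        if polygon is None:
            score = (
                len(spec) if metric == "count" else float(spec.intensity.sum())
            )
        else:
            if metric == "count":
                score = _gated_count(spec, polygon, base)
            else:
                if len(spec) == 0:
                    score = 0.0
                else:
                    res = gate(transform(spec, base), polygon, -1, min_members=0)
                    assert isinstance(res, PeakGroup)
                    score = float(spec.intensity[list(res.member_indices)].sum())
        entries.append((label, spec.meta.solvent.organic_aqueous_ratio, score))
    entries.sort(key=lambda e: (-e[2], e[0]))
    scope = "whole-spectrum" if polygon is None else (scope_id if scope_id is not None else 0)
    return SolventRanking(entries=tuple(entries), scope=scope)


def top_solvents_per_group(
    dataset: Mapping[str, Spectrum],
    polygons: Mapping[int, GatePolygon],
    base: KendrickBase = CH2,
    k: int = 3,
    metric: Literal["count", "intensity"] = "count",
) -> dict[int, tuple[str, ...]]:
    """Per group, the top-``k`` solvents by gated peak count.

    Solvents with a zero count are excluded; a group extracted by no
    solvent maps to an empty tuple (flagged "not extracted" by callers).
    """
    out: dict[int, tuple[str, ...]] = {}
    for gid, poly in polygons.items():
        ranking = rank_solvents(dataset, polygon=poly, base=base,
                                scope_id=gid, metric=metric)
        out[gid] = tuple(
            label for label, _, count in ranking.entries[:k] if count > 0
        )
    return out


def ratio_trend(ranking: SolventRanking) -> RatioTrend:
    """Mean-count contrast and Spearman trend of count vs organic ratio."""
    ratios = np.array([r for _, r, _ in ranking.entries], dtype=float)
    counts = np.array([c for _, _, c in ranking.entries], dtype=float)
    if np.unique(ratios).size < 2:
        raise ValueError("need at least two distinct organic/aqueous ratios")
    high, low = counts[ratios >= 0.5], counts[ratios < 0.5]
    mean_high = float(high.mean()) if high.size else float("nan")
    mean_low = float(low.mean()) if low.size else float("nan")
    if np.ptp(counts) == 0:
        return RatioTrend(mean_high, mean_low, 0.0, 0.0, constant_counts=True)
    rho = float(spearmanr(counts, ratios).statistic)
    return RatioTrend(mean_high, mean_low, mean_high - mean_low, rho)


_SUMMARY_COLUMNS = [
    "group_id", "top_solvents", "km_min", "km_max", "kmd_min", "kmd_max",
    "hc_min", "hc_max", "oc_min", "oc_max", "dbe_min", "dbe_max",
    "classes", "unique_classes",
]


def summaries_to_frame(summaries: Sequence[GroupSummary]):
    """Summary rows as a DataFrame mirroring the screening-table layout."""
    rows = []
    for s in summaries:
        def rng(r: Range | None) -> tuple[float, float]:
            return r if r is not None else (float("nan"), float("nan"))

        hc, oc, db = rng(s.h_c_range), rng(s.o_c_range), rng(s.dbe_range)
        rows.append({
            "group_id": s.group_id,
            "top_solvents": ";".join(s.top_solvents),
            "km_min": s.km_range[0], "km_max": s.km_range[1],
            "kmd_min": s.kmd_range[0], "kmd_max": s.kmd_range[1],
            "hc_min": hc[0], "hc_max": hc[1],
            "oc_min": oc[0], "oc_max": oc[1],
            "dbe_min": db[0], "dbe_max": db[1],
            "classes": ";".join(sorted(s.classes)),
            "unique_classes": ";".join(sorted(s.unique_classes)),
        })
    return pd.DataFrame(rows, columns=_SUMMARY_COLUMNS)


def summaries_from_frame(frame) -> list[GroupSummary]:
    """Inverse of :func:`summaries_to_frame` (n_members not round-tripped)."""
    out = []
    for row in frame.itertuples(index=False):
        def rng(lo: float, hi: float) -> Range | None:
            return None if math.isnan(lo) else (float(lo), float(hi))

        def split(cell) -> frozenset[str]:
            if not isinstance(cell, str) or not cell:
                return frozenset()
            return frozenset(cell.split(";"))

        out.append(GroupSummary(
            group_id=int(row.group_id),
            n_members=0,
            km_range=(float(row.km_min), float(row.km_max)),
            kmd_range=(float(row.kmd_min), float(row.kmd_max)),
            h_c_range=rng(row.hc_min, row.hc_max),
            o_c_range=rng(row.oc_min, row.oc_max),
            dbe_range=rng(row.dbe_min, row.dbe_max),
            classes=split(row.classes),
            unique_classes=split(row.unique_classes),
            top_solvents=tuple(row.top_solvents.split(";"))
            if isinstance(row.top_solvents, str) and row.top_solvents
            else (),
        ))
    return out


def _box_iou(a: GroupSummary, b: GroupSummary) -> float:
    ax0, ax1 = a.km_range
    ay0, ay1 = a.kmd_range
    bx0, bx1 = b.km_range
    by0, by1 = b.kmd_range
    ix = max(0.0, min(ax1, bx1) - max(ax0, bx0))
    iy = max(0.0, min(ay1, by1) - max(ay0, by0))
    inter = ix * iy
    union = (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
    if union <= 0.0:
        # both boxes degenerate: identical boxes match perfectly
        return 1.0 if (a.km_range, a.kmd_range) == (b.km_range, b.kmd_range) else 0.0
    return inter / union


def match_groups(
    groups_a: Sequence[GroupSummary],
    groups_b: Sequence[GroupSummary],
    min_overlap: float = 0.3,
) -> GroupMatch:
    """Greedy one-to-one matching of groups by (KM, KMD) bounding-box IoU.

    Candidate pairs are taken in descending overlap order (ties broken by
    group ids); pairs below ``min_overlap`` dissolve, and unmatched
    groups on either side are reported unique.
    """
    scored = [
        (_box_iou(a, b), a.group_id, b.group_id)
        for a in groups_a
        for b in groups_b
    ]
    scored.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for score, ida, idb in scored:
        if score < min_overlap:
            break
        if ida in used_a or idb in used_b:
            continue
        pairs.append((ida, idb, score))
        used_a.add(ida)
        used_b.add(idb)
    return GroupMatch(
        pairs=tuple(pairs),
        unique_to_a=tuple(a.group_id for a in groups_a if a.group_id not in used_a),
        unique_to_b=tuple(b.group_id for b in groups_b if b.group_id not in used_b),
    )
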