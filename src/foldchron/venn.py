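"""Venn groups over {A, B, E, V}, phase timelines, accumulation curves,
phase count/ratio tables and the group-by-phase presence grid.

A feature's Venn group is the set of supergroups whose proteomes contain it
(15 non-empty subsets).  Features whose group includes V belong to the
"viruses" category (unique to or shared with viruses); the rest are "cells".
Six evolutionary phases (0, I..V) partition the nd axis at the first
appearances of configurable marker groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from ._util import round_half_up
from .census import SUPERGROUP_CODES, DomainFamily, OccurrenceMatrix

PHASES = ("0", "I", "II", "III", "IV", "V")
CATEGORIES = ("viruses", "cells")

#: All 15 Venn group names in canonical member order A, B, E, V.
ALL_GROUPS = (
    "A", "B", "E", "V",
    "AB", "AE", "AV", "BE", "BV", "EV",
    "ABE", "ABV", "AEV", "BEV",
    "ABEV",
)


class VennError(ValueError):
    pass


@dataclass(frozen=True)
class VennGroup:
    """Non-empty subset of {A, B, E, V}; name in fixed A,B,E,V order."""

    members: frozenset[str]

    def __post_init__(self):
        if not self.members or not self.members <= set(SUPERGROUP_CODES):
            raise VennError(f"invalid Venn group members: {set(self.members)}")

    @classmethod
    def from_name(cls, name: str) -> "VennGroup":
        return cls(frozenset(name))

    @property
    def name(self) -> str:
        return "".join(c for c in SUPERGROUP_CODES if c in self.members)

    def __str__(self) -> str:
        return self.name


def venn_group(occ: OccurrenceMatrix, family: DomainFamily | str) -> VennGroup:
    """Codes whose proteomes contain the family at least once."""
    fid = family.id if isinstance(family, DomainFamily) else family
    i = occ.taxon_index(fid)
    members = {
        code
        for code in SUPERGROUP_CODES
        if occ.presence[i, occ.proteomes_of_code(code)].any()
    }
    if not members:
        raise VennError(f"orphan family {fid!r}: absent from every proteome")
    return VennGroup(frozenset(members))


def venn_groups(occ: OccurrenceMatrix) -> dict[str, VennGroup]:
    """Venn group per family id (skipping orphans raises)."""
    return {t.id: venn_group(occ, t) for t in occ.taxa}


def category_of(vg: VennGroup | str) -> str:
    """'viruses' when V is a member, else 'cells'."""
    members = vg.members if isinstance(vg, VennGroup) else frozenset(vg)
    return "viruses" if "V" in members else "cells"


def first_appearances(
    nd: Mapping[str, float], vg: Mapping[str, VennGroup]
) -> dict[str, float]:
    """Minimum nd per Venn group name, over the features carrying it."""
    out: dict[str, float] = {}
    for fid, group in vg.items():
        if fid not in nd:
            raise VennError(f"feature {fid!r} has no nd")
        name = group.name if isinstance(group, VennGroup) else group
        if name not in out or nd[fid] < out[name]:
            out[name] = nd[fid]
    return out


#: Boundary markers: boundary k is the earliest first appearance among the
#: listed groups.  Encodes the appearance order ABEV < ABE < BEV < BE < ...,
#: bacterial groups opening Phase III, VSFs opening Phase IV and
#: eukaryal groups opening Phase V.
DEFAULT_MARKERS: dict[int, tuple[str, ...]] = {
    1: ("ABE",),
    2: ("BEV",),
    3: ("ABV", "BV", "AB", "B"),
    4: ("V",),
    5: ("AEV", "EV", "AE", "E"),
}


@dataclass
class PhaseTimeline:
    """Five strictly increasing nd boundaries cutting [0, 1] into six phases.

    Phases are half-open [b_k, b_{k+1}); a feature at an exact boundary goes
    to the later phase; Phase V is closed at nd = 1.
    """

    boundaries: list[float]
    marker_map: dict[int, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_MARKERS)
    )

    def __post_init__(self):
        b = self.boundaries
        if len(b) != 5:
            raise VennError("need exactly 5 boundaries")
        if not all(b[i] < b[i + 1] for i in range(4)):
            raise VennError(f"boundaries not strictly increasing: {b}")
        if not (0 < b[0] and b[4] <= 1):
            raise VennError(f"boundaries must satisfy 0 < b1, b5 <= 1: {b}")

    def phase_index(self, nd: float) -> int:
        for k, bk in enumerate(self.boundaries):
            if nd < bk:
                return k
        return 5

    def phase_name(self, nd: float) -> str:
        return PHASES[self.phase_index(nd)]


def delimit_phases(
    first: Mapping[str, float],
    marker_map: Mapping[int, tuple[str, ...]] | None = None,
) -> PhaseTimeline:
    """Place phase boundaries at marker-group first appearances."""
    markers = dict(marker_map) if marker_map is not None else dict(DEFAULT_MARKERS)
    boundaries: list[float] = []
    for k in range(1, 6):
        groups = markers.get(k, ())
        present = [first[g] for g in groups if g in first]
        if not present:
            raise VennError(f"missing marker group(s) for boundary {k}: {groups}")
        boundaries.append(min(present))
    return PhaseTimeline(boundaries=boundaries, marker_map=markers)


def quantile_timeline(nd_values) -> PhaseTimeline:
    """Fallback timeline: boundaries at nd sextiles (used when marker-group
    first appearances are not monotone on a recovered chronology)."""
    import numpy as np

    vals = np.asarray(sorted(nd_values), dtype=float)
    qs = [float(np.quantile(vals, k / 6)) for k in range(1, 6)]
    out = []
    prev = 0.0
    for q in qs:
        q = max(q, prev + 1e-9)
        out.append(min(q, 1.0))
        prev = q
    for k in range(4, -1, -1):  # keep strictly increasing if clipped at 1
        if k > 0 and out[k] <= out[k - 1]:
            out[k - 1] = out[k] - 1e-9
    return PhaseTimeline(boundaries=out, marker_map={})


@dataclass
class PhaseCountTable:
    """First-appearance counts per phase x category x feature kind."""

    counts: dict[tuple[str, str], list[int]]  # (category, kind) -> 6 ints

    @classmethod
    def from_features(
        cls,
        features: Iterable[tuple[float, VennGroup | str, str]],
        timeline: PhaseTimeline,
    ) -> "PhaseCountTable":
        """``features`` yields (nd, venn group, kind) with kind in
        {"domains", "prototypes"}."""
        counts = {
            (cat, kind): [0] * 6
            for cat in CATEGORIES
            for kind in ("domains", "prototypes")
        }
        for nd, vg, kind in features:
            cat = category_of(vg)
            counts[(cat, kind)][timeline.phase_index(nd)] += 1
        return cls(counts=counts)

    @classmethod
    def from_counts(
        cls, counts: Mapping[tuple[str, str], Iterable[int]]
    ) -> "PhaseCountTable":
        full = {
            (cat, kind): [0] * 6
            for cat in CATEGORIES
            for kind in ("domains", "prototypes")
        }
        for key, row in counts.items():
            row = list(row)
            if len(row) != 6:
                raise VennError(f"count row for {key} must have 6 phases")
            full[key] = [int(x) for x in row]
        return cls(counts=full)

    def ratio(self, category: str, phase: int | str) -> float | str:
        """Prototypes/domains for one phase, rounded half-up to 2 decimals;
        '–' when the domain count is zero."""
        k = PHASES.index(phase) if isinstance(phase, str) else phase
        dom = self.counts[(category, "domains")][k]
        pro = self.counts[(category, "prototypes")][k]
        if dom == 0:
            return "–"
        return round_half_up(pro / dom, 2)

    def ratios(self, category: str) -> list[float | str]:
        return [self.ratio(category, k) for k in range(6)]

    def cumulative(self, category: str, kind: str, through_phase: int | str) -> int:
        k = PHASES.index(through_phase) if isinstance(through_phase, str) else through_phase
        return int(sum(self.counts[(category, kind)][: k + 1]))

    def category_total(self, category: str, kind: str) -> int:
        return int(sum(self.counts[(category, kind)]))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cat in CATEGORIES:
            label = (
                "Unique to or shared with viruses" if cat == "viruses" else "Unique to cells"
            )
            rows.append([label, "Prototypes", *self.counts[(cat, "prototypes")]])
            rows.append([label, "Domains", *self.counts[(cat, "domains")]])
            rows.append([label, "Ratio", *self.ratios(cat)])
        return pd.DataFrame(rows, columns=["Category", "Kind", *PHASES])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def phase_count_table(
    nd: Mapping[str, float],
    vg: Mapping[str, VennGroup],
    kind: Mapping[str, str] | str,
    timeline: PhaseTimeline,
) -> PhaseCountTable:
    """Count features by first-appearance phase, category and kind."""
    feats = []
    for fid, group in vg.items():
        k = kind if isinstance(kind, str) else kind[fid]
        feats.append((nd[fid], group, k))
    return PhaseCountTable.from_features(feats, timeline)


def accumulation_curves(
    nd: Mapping[str, float],
    vg: Mapping[str, VennGroup],
    timeline: PhaseTimeline,
) -> pd.DataFrame:
    """Cumulative feature counts (nd <= boundary) per Venn group and category
    at each phase boundary plus the end of the timeline (nd = 1)."""
    cuts = list(timeline.boundaries) + [1.0]
    rows = []
    for cut in cuts:
        row: dict[str, object] = {"boundary_nd": cut}
        for g in ALL_GROUPS:
            row[g] = 0
        row["viruses"] = 0
        row["cells"] = 0
        for fid, group in vg.items():
            if nd[fid] <= cut:
                name = group.name if isinstance(group, VennGroup) else group
                row[name] = int(row[name]) + 1
                cat = category_of(group)
                row[cat] = int(row[cat]) + 1
        rows.append(row)
    return pd.DataFrame(rows)


def specificity_summary(vg: Mapping[str, VennGroup] | Iterable[VennGroup]) -> dict:
    """Percent of features specific to each single supergroup (2 decimals)
    and the shared fraction (100 minus the singleton sum, 1 decimal)."""
    groups = list(vg.values()) if isinstance(vg, Mapping) else list(vg)
    if not groups:
        raise VennError("no features")
    n = len(groups)
    singles = {}
    for code in SUPERGROUP_CODES:
        cnt = sum(1 for g in groups if g.members == frozenset({code}))
        singles[code] = round_half_up(100.0 * cnt / n, 2)
    return {
        "singletons": singles,
        "shared": shared_percentage(singles.values()),
        "n": n,
    }


def shared_percentage(singleton_percents: Iterable[float]) -> float:
    """100 minus the sum of per-supergroup singleton percentages (1 decimal)."""
    return round_half_up(100.0 - sum(singleton_percents), 1)


def presence_grid(
    nd: Mapping[str, float],
    vg: Mapping[str, VennGroup],
    timeline: PhaseTimeline,
) -> pd.DataFrame:
    """Boolean Venn group x phase grid: any feature of the group in the phase."""
    grid = pd.DataFrame(False, index=list(ALL_GROUPS), columns=list(PHASES))
    for fid, group in vg.items():
        name = group.name if isinstance(group, VennGroup) else group
        grid.loc[name, timeline.phase_name(nd[fid])] = True
    return grid
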