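"""Loop-prototype to domain-family mappings and their projection onto the
domain chronology and Venn framework.

Prototype-map edges below the e-value threshold (strict <) are retained.
A prototype is "non-modular" when it maps to exactly one family, or — with a
positive nd window — when all its mapped families originated within that
window.  Prototype time of origin is the earliest mapped-family nd; its Venn
group is the union of its families' groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .venn import VennGroup


class LoopError(ValueError):
    pass


@dataclass
class PrototypeMap:
    edges: list[tuple[str, str, float]]  # (prototype id, family id, e-value)
    threshold: float = 0.001
    n_dropped: int = 0

    def families_of(self, prototype: str) -> list[str]:
        return sorted({f for p, f, _ in self.edges if p == prototype})

    def prototypes(self) -> list[str]:
        return sorted({p for p, _, _ in self.edges})

    def by_prototype(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for p, f, _ in self.edges:
            out.setdefault(p, [])
            if f not in out[p]:
                out[p].append(f)
        return out


def read_prototype_map(path, threshold: float = 0.001) -> PrototypeMap:
    """Read a (prototype, family, e-value) TSV, keeping edges with e < threshold."""
    kept: list[tuple[str, str, float]] = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts and _looks_like_header(parts):
                continue
            if len(parts) < 3:
                raise LoopError(f"line {lineno}: expected 3 columns, got {len(parts)}")
            try:
                e = float(parts[2])
            except ValueError:
                raise LoopError(
                    f"line {lineno}: malformed e-value {parts[2]!r}"
                ) from None
            if e < threshold:
                kept.append((parts[0], parts[1], e))
            else:
                dropped += 1
    return PrototypeMap(edges=kept, threshold=threshold, n_dropped=dropped)


def _looks_like_header(parts: list[str]) -> bool:
    try:
        float(parts[2])
        return False
    except (ValueError, IndexError):
        return True


def write_prototype_map(pm: PrototypeMap, path) -> None:
    pd.DataFrame(pm.edges, columns=["prototype", "family", "evalue"]).to_csv(
        path, sep="\t", index=False
    )


def non_modular_filter(
    pm: PrototypeMap, nd: Mapping[str, float], nd_window: float = 0.0
) -> set[str]:
    """Prototype ids mapping to a single family (or to families whose nd span
    is within ``nd_window`` when the window is positive)."""
    out: set[str] = set()
    for proto, fams in pm.by_prototype().items():
        if not fams:
            continue
        if len(fams) == 1:
            out.add(proto)
            continue
        if nd_window > 0:
            try:
                vals = [nd[f] for f in fams]
            except KeyError as exc:
                raise LoopError(f"family {exc.args[0]!r} has no nd") from None
            if max(vals) - min(vals) <= nd_window:
                out.add(proto)
    return out


def prototype_chronology(
    pm: PrototypeMap, nd: Mapping[str, float], prototypes=None
) -> dict[str, float]:
    """nd per prototype = minimum nd among its mapped families (earliest use)."""
    by = pm.by_prototype()
    if prototypes is None:
        prototypes = by.keys()
    out: dict[str, float] = {}
    for proto in prototypes:
        fams = by.get(proto, [])
        if not fams:
            continue
        try:
            out[proto] = min(nd[f] for f in fams)
        except KeyError as exc:
            raise LoopError(f"family {exc.args[0]!r} has no nd") from None
    return out


def prototype_venn(
    pm: PrototypeMap, vg: Mapping[str, VennGroup], prototypes=None
) -> dict[str, VennGroup]:
    """Venn group per prototype = union of member codes over mapped families."""
    by = pm.by_prototype()
    if prototypes is None:
        prototypes = by.keys()
    out: dict[str, VennGroup] = {}
    for proto in prototypes:
        fams = by.get(proto, [])
        if not fams:
            continue
        members: set[str] = set()
        for f in fams:
            g = vg[f]
            members |= g.members if isinstance(g, VennGroup) else set(g)
        out[proto] = VennGroup(frozenset(members))
    return out


def write_prototype_chronology(
    nd: Mapping[str, float], vg: Mapping[str, VennGroup], path
) -> None:
    from .venn import category_of

    rows = [
        {
            "prototype": p,
            "nd": nd[p],
            "venn": vg[p].name if isinstance(vg[p], VennGroup) else vg[p],
            "category": category_of(vg[p]),
        }
        for p in sorted(nd)
        if p in vg
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
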