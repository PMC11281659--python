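"""Abundance-to-character coding and NEXUS serialization.

Census abundances are log-transformed, rescaled within each proteome
(character) and binned into ordered multistate characters.  State ``k`` of a
cell with abundance ``a`` in a proteome whose maximum abundance is ``m`` is

    k = round_half_up((S - 1) * ln(a + 1) / ln(m + 1))

so that absence maps to state 0 and the per-proteome maximum to state S-1.
An alternative equal-width binning of ln(a+1) is selectable via ``scaling``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._util import round_half_up
from .census import CensusMatrix, DomainFamily, SupergroupLabel

#: NEXUS state symbols, state k -> SYMBOLS[k]; 24 states max.
SYMBOLS = "0123456789ABCDEFGHIJKLMN"

#: Sentinel for missing ('?') states.
MISSING = -1


class CodingError(ValueError):
    pass


@dataclass
class CharacterMatrix:
    """Ordered multistate characters: taxa = domain families, characters = proteomes."""

    taxa: list[DomainFamily]
    characters: list[tuple[str, SupergroupLabel]]
    states: np.ndarray  # (n_taxa, n_chars) ints in 0..S-1, MISSING allowed
    n_states: int = 24
    degenerate: list[str] = field(default_factory=list)  # all-zero proteomes

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.int64)
        if self.states.shape != (len(self.taxa), len(self.characters)):
            raise CodingError("state matrix shape does not match axes")
        if self.n_states < 2:
            raise CodingError("n_states must be >= 2")
        bad = (self.states != MISSING) & (
            (self.states < 0) | (self.states > self.n_states - 1)
        )
        if bad.any():
            raise CodingError("state out of range 0..S-1")

    @property
    def taxon_ids(self) -> list[str]:
        return [t.id for t in self.taxa]

    @property
    def character_ids(self) -> list[str]:
        return [c for c, _ in self.characters]


@dataclass
class InformativeReport:
    kept: list[str]
    dropped: list[tuple[str, str]]  # (character id, reason)


def encode_states(
    census: CensusMatrix, n_states: int = 24, scaling: str = "per-proteome-max"
) -> CharacterMatrix:
    """Bin a census into an ordered multistate character matrix.

    Characters whose proteome is entirely empty (max abundance 0) are set to
    all-zero states and flagged in ``degenerate``.
    """
    if n_states < 2:
        raise CodingError("n_states must be >= 2")
    a = census.abundance.astype(float)
    la = np.log(a + 1.0)
    states = np.zeros(a.shape, dtype=np.int64)
    degenerate: list[str] = []
    if scaling == "per-proteome-max":
        denom = la.max(axis=0)
    elif scaling == "global-max":
        denom = np.full(a.shape[1], la.max())
    else:
        raise CodingError(f"unknown scaling {scaling!r}")
    for j in range(a.shape[1]):
        if denom[j] <= 0:
            degenerate.append(census.proteome_ids[j])
            continue
        scaled = (n_states - 1) * la[:, j] / denom[j]
        states[:, j] = [int(round_half_up(v)) for v in scaled]
    return CharacterMatrix(
        taxa=list(census.taxa),
        characters=list(census.proteomes),
        states=states,
        n_states=n_states,
        degenerate=degenerate,
    )


def informative_filter(cm: CharacterMatrix) -> tuple[CharacterMatrix, InformativeReport]:
    """Keep parsimony-informative characters (>=2 states each in >=2 taxa)."""
    kept_idx: list[int] = []
    kept: list[str] = []
    dropped: list[tuple[str, str]] = []
    for j, (cid, _) in enumerate(cm.characters):
        col = cm.states[:, j]
        col = col[col != MISSING]
        vals, counts = np.unique(col, return_counts=True)
        if len(vals) < 2:
            dropped.append((cid, "constant"))
        elif (counts >= 2).sum() < 2:
            dropped.append((cid, "autapomorphic-only"))
        else:
            kept_idx.append(j)
            kept.append(cid)
    if not kept_idx:
        raise CodingError("no informative characters")
    out = CharacterMatrix(
        taxa=list(cm.taxa),
        characters=[cm.characters[j] for j in kept_idx],
        states=cm.states[:, kept_idx].copy(),
        n_states=cm.n_states,
        degenerate=list(cm.degenerate),
    )
    return out, InformativeReport(kept=kept, dropped=dropped)


def _quote(label: str) -> str:
    return "'" + label.replace("'", "''") + "'"


def write_nexus(cm: CharacterMatrix, path) -> None:
    """Write a NEXUS DATA block (plus a minimal ASSUMPTIONS block marking all
    characters ordered) with the fixed 24-symbol alphabet."""
    if cm.n_states > len(SYMBOLS):
        raise CodingError("alphabet exhausted: n_states > 24 unsupported in NEXUS")
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"    DIMENSIONS NTAX={len(cm.taxa)} NCHAR={len(cm.characters)};",
        f'    FORMAT SYMBOLS="{SYMBOLS[: cm.n_states]}" MISSING=? RESPECTCASE;',
        "    MATRIX",
    ]
    width = max(len(_quote(t.id)) for t in cm.taxa) if cm.taxa else 0
    for i, t in enumerate(cm.taxa):
        row = "".join(
            "?" if s == MISSING else SYMBOLS[s] for s in cm.states[i]
        )
        lines.append(f"    {_quote(t.id):<{width}} {row}")
    lines += [
        "    ;",
        "END;",
        "BEGIN ASSUMPTIONS;",
        "    OPTIONS DEFTYPE=ORD;",
        "    TYPESET * default = ORD: ALL;",
        "END;",
        "",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


def read_nexus(path) -> CharacterMatrix:
    """Read a NEXUS DATA block written by :func:`write_nexus`.

    Character ids and supergroup labels are not stored in NEXUS; characters
    come back numbered with a placeholder label.
    """
    with open(path) as fh:
        text = fh.read()
    n_states = 24
    for line in text.splitlines():
        ls = line.strip()
        if ls.upper().startswith("FORMAT") and "SYMBOLS" in ls.upper():
            sym = ls.split('"')[1]
            n_states = len(sym)
    in_matrix = False
    taxa: list[DomainFamily] = []
    rows: list[list[int]] = []
    for line in text.splitlines():
        ls = line.strip()
        if ls.upper() == "MATRIX":
            in_matrix = True
            continue
        if in_matrix:
            if ls == ";" or ls.upper().startswith("END"):
                break
            if not ls:
                continue
            if ls.startswith("'"):
                end = ls.index("'", 1)
                while end + 1 < len(ls) and ls[end + 1] == "'":
                    end = ls.index("'", end + 2)
                label = ls[1:end].replace("''", "'")
                rest = ls[end + 1 :].strip()
            else:
                label, rest = ls.split(None, 1)
            taxa.append(DomainFamily(label))
            rows.append(
                [MISSING if ch == "?" else SYMBOLS.index(ch) for ch in rest]
            )
    dummy = SupergroupLabel("A")
    chars = [(f"char{j+1}", dummy) for j in range(len(rows[0]) if rows else 0)]
    return CharacterMatrix(
        taxa=taxa, characters=chars, states=np.array(rows), n_states=n_states
    )


def write_states_tsv(cm: CharacterMatrix, path) -> None:
    import pandas as pd

    df = pd.DataFrame(cm.states, index=cm.taxon_ids, columns=cm.character_ids)
    df.index.name = "family"
    df.to_csv(path, sep="\t")
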