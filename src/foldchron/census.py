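"""Census data model and I/O.

A census records non-negative integer abundance counts of protein domain
families (rows) across proteomes (columns).  Every proteome carries a
supergroup label: Archaea (A), Bacteria (B), Eukarya (E) or viruses (V),
with an optional free-text subgroup (e.g. "eukaryovirus").  Presence/absence
(occurrence) matrices are derived views of a census.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SUPERGROUP_CODES = ("A", "B", "E", "V")


class CensusError(ValueError):
    """Raised on malformed census or label input."""


@dataclass(frozen=True)
class SupergroupLabel:
    """Supergroup assignment of a proteome."""

    code: str
    subgroup: str = ""

    def __post_init__(self):
        if self.code not in SUPERGROUP_CODES:
            raise CensusError(
                f"supergroup code must be one of {SUPERGROUP_CODES}, got {self.code!r}"
            )


@dataclass(frozen=True)
class DomainFamily:
    """A domain family identified by a SCOP concise classification string."""

    id: str
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise CensusError("domain family id must be non-empty")


@dataclass
class CensusMatrix:
    """Abundance counts of domain families (rows) across proteomes (columns)."""

    taxa: list[DomainFamily]
    proteomes: list[tuple[str, SupergroupLabel]]
    abundance: np.ndarray  # (n_taxa, n_proteomes) non-negative ints

    def __post_init__(self):
        self.abundance = np.asarray(self.abundance)
        if self.abundance.shape != (len(self.taxa), len(self.proteomes)):
            raise CensusError(
                f"abundance shape {self.abundance.shape} does not match "
                f"{len(self.taxa)} taxa x {len(self.proteomes)} proteomes"
            )
        if not np.issubdtype(self.abundance.dtype, np.integer):
            if not np.all(self.abundance == np.floor(self.abundance)):
                raise CensusError("abundance counts must be integers")
            self.abundance = self.abundance.astype(np.int64)
        if (self.abundance < 0).any():
            i, j = np.argwhere(self.abundance < 0)[0]
            raise CensusError(
                f"negative abundance at ({self.taxa[i].id}, {self.proteomes[j][0]})"
            )
        tids = [t.id for t in self.taxa]
        if len(set(tids)) != len(tids):
            dup = sorted({x for x in tids if tids.count(x) > 1})
            raise CensusError(f"duplicate taxon id(s): {dup}")
        pids = [p for p, _ in self.proteomes]
        if len(set(pids)) != len(pids):
            dup = sorted({x for x in pids if pids.count(x) > 1})
            raise CensusError(f"duplicate proteome id(s): {dup}")

    @property
    def taxon_ids(self) -> list[str]:
        return [t.id for t in self.taxa]

    @property
    def proteome_ids(self) -> list[str]:
        return [p for p, _ in self.proteomes]

    def taxon_index(self, family_id: str) -> int:
        for i, t in enumerate(self.taxa):
            if t.id == family_id:
                return i
        raise CensusError(f"unknown family id: {family_id!r}")

    def proteomes_of_code(self, code: str) -> list[int]:
        return [j for j, (_, lab) in enumerate(self.proteomes) if lab.code == code]

    def zero_rows(self) -> list[str]:
        """Family ids with zero total abundance (retained, but reportable)."""
        return [t.id for t, s in zip(self.taxa, self.abundance.sum(axis=1)) if s == 0]


@dataclass
class OccurrenceMatrix:
    """Presence/absence view over the same taxa and proteomes as a census."""

    taxa: list[DomainFamily]
    proteomes: list[tuple[str, SupergroupLabel]]
    presence: np.ndarray  # (n_taxa, n_proteomes) bool

    def __post_init__(self):
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.presence.shape != (len(self.taxa), len(self.proteomes)):
            raise CensusError("presence shape does not match axes")

    @property
    def taxon_ids(self) -> list[str]:
        return [t.id for t in self.taxa]

    def taxon_index(self, family_id: str) -> int:
        for i, t in enumerate(self.taxa):
            if t.id == family_id:
                return i
        raise CensusError(f"unknown family id: {family_id!r}")

    def proteomes_of_code(self, code: str) -> list[int]:
        return [j for j, (_, lab) in enumerate(self.proteomes) if lab.code == code]


def read_labels(path) -> dict[str, SupergroupLabel]:
    """Read a proteome-label TSV: columns proteome id, code, optional subgroup."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = list(df.columns)
    if len(cols) < 2:
        raise CensusError(f"label table {path} needs >=2 columns (id, code)")
    labels: dict[str, SupergroupLabel] = {}
    for _, row in df.iterrows():
        pid = row[cols[0]]
        if pid in labels:
            raise CensusError(f"duplicate proteome id in labels: {pid!r}")
        sub = row[cols[2]] if len(cols) > 2 else ""
        labels[pid] = SupergroupLabel(code=row[cols[1]], subgroup=sub)
    return labels


def read_census(path, labels_path) -> CensusMatrix:
    """Read a census TSV (header = proteome ids, column 1 = family ids) plus labels.

    Row and column order are preserved from the file.
    """
    labels = read_labels(labels_path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    pids = list(df.columns[1:])
    for pid in pids:
        if pid not in labels:
            raise CensusError(f"unlabeled proteome: {pid!r}")
    taxa = [DomainFamily(x) for x in df.iloc[:, 0]]
    raw = df.iloc[:, 1:].to_numpy()
    counts = np.empty(raw.shape, dtype=np.int64)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = raw[i, j]
            try:
                v = int(cell)
            except ValueError:
                raise CensusError(
                    f"non-integer cell {cell!r} at ({taxa[i].id}, {pids[j]})"
                ) from None
            if v < 0:
                raise CensusError(f"negative cell at ({taxa[i].id}, {pids[j]})")
            counts[i, j] = v
    proteomes = [(pid, labels[pid]) for pid in pids]
    return CensusMatrix(taxa=taxa, proteomes=proteomes, abundance=counts)


def write_census(census: CensusMatrix, path, labels_path=None) -> None:
    """Write a census (and optionally its labels) as TSV."""
    df = pd.DataFrame(
        census.abundance, index=census.taxon_ids, columns=census.proteome_ids
    )
    df.index.name = "family"
    df.to_csv(path, sep="\t")
    if labels_path is not None:
        write_labels(dict(census.proteomes), labels_path)


def write_labels(labels: Mapping[str, SupergroupLabel], path) -> None:
    rows = [(pid, lab.code, lab.subgroup) for pid, lab in labels.items()]
    pd.DataFrame(rows, columns=["proteome", "code", "subgroup"]).to_csv(
        path, sep="\t", index=False
    )


def to_occurrence(census: CensusMatrix) -> OccurrenceMatrix:
    """Derive the presence/absence matrix: present iff abundance > 0."""
    return OccurrenceMatrix(
        taxa=list(census.taxa),
        proteomes=list(census.proteomes),
        presence=census.abundance > 0,
    )


def supergroup_occupancy(
    occ: OccurrenceMatrix, family: DomainFamily | str
) -> dict[str, tuple[int, int]]:
    """Per supergroup code, (proteomes containing the family, total proteomes)."""
    fid = family.id if isinstance(family, DomainFamily) else family
    i = occ.taxon_index(fid)
    out: dict[str, tuple[int, int]] = {}
    for code in SUPERGROUP_CODES:
        idx = occ.proteomes_of_code(code)
        out[code] = (int(occ.presence[i, idx].sum()), len(idx))
    return out
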