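"""Occupancy (f-value) statistics and rank-sum comparisons.

The f-value of a family in a supergroup is the fraction of that supergroup's
proteomes containing the family.  Cell-unique and virus-shared families are
compared per supergroup with a two-sample rank-sum (Mann-Whitney) test:
exact enumeration with midranks for pooled sizes <= 12, otherwise the normal
approximation with tie and continuity corrections.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from .census import SUPERGROUP_CODES, OccurrenceMatrix

EXACT_LIMIT = 12


class OccupancyError(ValueError):
    pass


def f_values(occ: OccurrenceMatrix) -> pd.DataFrame:
    """Occupancy fraction per family (rows) per supergroup code (columns)."""
    data = {}
    for code in SUPERGROUP_CODES:
        idx = occ.proteomes_of_code(code)
        if not idx:
            raise OccupancyError(f"supergroup {code} has no proteomes")
        data[code] = occ.presence[:, idx].mean(axis=1)
    return pd.DataFrame(data, index=occ.taxon_ids)


def _midranks(pooled: np.ndarray) -> np.ndarray:
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    rx = ranks[: len(x)].sum()
    return float(rx - len(x) * (len(x) + 1) / 2)


@dataclass
class RankSumResult:
    n_x: int
    n_y: int
    U: float
    p_two_sided: float
    method: str


def rank_sum_test(x, y, alternative: str = "two-sided") -> RankSumResult:
    """Mann-Whitney rank-sum test (U reported for the first sample)."""
    if alternative != "two-sided":
        raise OccupancyError("only the two-sided alternative is implemented")
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise OccupancyError("both samples must be non-empty")
    u_obs = _u_statistic(x, y)
    n1, n2 = len(x), len(y)
    mu = n1 * n2 / 2
    if n1 + n2 <= EXACT_LIMIT:
        pooled = np.concatenate([x, y])
        ranks = _midranks(pooled)
        dev = abs(u_obs - mu)
        hits = total = 0
        offset = n1 * (n1 + 1) / 2
        for pick in combinations(range(n1 + n2), n1):
            u = ranks[list(pick)].sum() - offset
            total += 1
            if abs(u - mu) >= dev - 1e-12:
                hits += 1
        p = hits / total
        method = "exact"
    else:
        n = n1 + n2
        pooled = np.concatenate([x, y])
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = ((counts**3 - counts).sum()) / (n * (n - 1))
        var = n1 * n2 / 12 * ((n + 1) - tie_term)
        if var <= 0:
            p = 1.0
        else:
            diff = u_obs - mu
            cc = 0.5 * np.sign(diff)
            z = (diff - cc) / np.sqrt(var)
            p = min(1.0, 2 * norm.sf(abs(z)))
        method = "normal-approx"
    return RankSumResult(n_x=n1, n_y=n2, U=u_obs, p_two_sided=float(p), method=method)


@dataclass
class GroupComparison:
    code: str
    n_cells: int
    n_viruses: int
    U: float  # U statistic of the viruses-category sample
    p_two_sided: float
    median_cells: float
    median_viruses: float


def compare_categories(
    fv: pd.DataFrame, category: Mapping[str, str], code: str
) -> GroupComparison:
    """Rank-sum comparison of f-values in one supergroup, virus-shared vs
    cell-unique, restricted to families present in that code (f > 0)."""
    if code not in fv.columns:
        raise OccupancyError(f"unknown supergroup code {code!r}")
    cells, viruses = [], []
    for fid, f in fv[code].items():
        if f <= 0:
            continue
        cat = category.get(fid)
        if cat == "cells":
            cells.append(float(f))
        elif cat == "viruses":
            viruses.append(float(f))
    if not cells or not viruses:
        raise OccupancyError(f"a category is empty for code {code}")
    res = rank_sum_test(viruses, cells)
    return GroupComparison(
        code=code,
        n_cells=len(cells),
        n_viruses=len(viruses),
        U=res.U,
        p_two_sided=res.p_two_sided,
        median_cells=float(np.median(cells)),
        median_viruses=float(np.median(viruses)),
    )


def f_chronology(
    fv: pd.DataFrame,
    nd: Mapping[str, float],
    category: Mapping[str, str],
    code: str,
    window: float = 0.05,
) -> pd.DataFrame:
    """f-values of one supergroup ordered along the chronology, with a
    sliding-window median column (window in nd units, centered)."""
    rows = []
    for fid, f in fv[code].items():
        if fid not in nd:
            raise OccupancyError(f"family {fid!r} has no nd")
        rows.append(
            {"family": fid, "nd": nd[fid], "f": float(f), "category": category.get(fid)}
        )
    df = pd.DataFrame(rows).sort_values(["nd", "family"]).reset_index(drop=True)
    med = []
    for _, row in df.iterrows():
        mask = (df["nd"] >= row["nd"] - window / 2) & (df["nd"] <= row["nd"] + window / 2)
        med.append(float(df.loc[mask, "f"].median()))
    df["window_median"] = med
    return df
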