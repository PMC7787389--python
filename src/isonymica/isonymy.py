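"""Spatial isonymy: grid binning, surname diversity, and isonymic distances.

Persons are binned into a regular grid; each retained cell gets a relative
surname frequency vector computed over person-slots (each person
contributes both surnames with weight 1). From these vectors come the
within-cell effective surname number alpha = 1 / sum(p^2), the between-cell
isonymy I_ij = sum over shared surnames of p_ki * p_kj, and three distance
functions (Lasker, Nei, Euclidean/chord).
"""

from __future__ import annotations

import json
import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy import stats as sps
from sklearn.mixture import GaussianMixture

logger = logging.getLogger(__name__)

__all__ = [
    "CellFrequencyTable",
    "DistanceMatrix",
    "grid_bin",
    "alpha",
    "isonymy_between",
    "lasker_distance",
    "nei_distance",
    "euclid_distance",
    "distance_matrix",
    "separability_report",
    "alpha_ses_correlation",
]

METRICS = ("lasker", "nei", "euclid")


@dataclass
class CellFrequencyTable:
    """Per-cell surname frequency vectors over a regular grid.

    ``freqs[cell]`` maps surname -> relative frequency (sums to 1 within
    1e-9); ``counts[cell]`` holds the raw slot counts. ``cells`` is the
    ordered list of retained (col, row) ids.
    """

    freqs: dict[tuple[int, int], dict[str, float]]
    counts: dict[tuple[int, int], Counter]
    person_counts: dict[tuple[int, int], int]
    mean_ses: dict[tuple[int, int], float]
    nx: int
    ny: int
    extent: tuple[float, float, float, float]
    n_candidate_cells: int = field(default=0)

    @property
    def cells(self) -> list[tuple[int, int]]:
        return sorted(self.freqs)

    def alphas(self) -> dict[tuple[int, int], float]:
        return {c: alpha(p) for c, p in self.freqs.items()}

    def write(self, freq_path: str | Path, summary_path: str | Path | None = None) -> None:
        """Long-format frequencies plus an optional per-cell summary table."""
        rows = [
            (c[0], c[1], s, self.counts[c][s], f)
            for c in self.cells
            for s, f in sorted(self.freqs[c].items())
        ]
        pd.DataFrame(rows, columns=["cell_col", "cell_row", "surname", "count", "freq"]).to_csv(
            freq_path, index=False
        )
        if summary_path is not None:
            alphas = self.alphas()
            pd.DataFrame(
                [
                    (c[0], c[1], self.person_counts[c], self.mean_ses.get(c, np.nan), alphas[c])
                    for c in self.cells
                ],
                columns=["cell_col", "cell_row", "count", "mean_ses", "alpha"],
            ).to_csv(summary_path, index=False)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise isonymic distances between retained cells."""

    cells: list[tuple[int, int]]
    matrix: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.cells), len(self.cells)):
            raise ValueError("matrix shape does not match cell list")

    def offdiag(self) -> np.ndarray:
        iu = np.triu_indices(len(self.cells), k=1)
        return self.matrix[iu]

    def write(self, path: str | Path, sidecar_path: str | Path | None = None) -> None:
        ids = [f"{c[0]}:{c[1]}" for c in self.cells]
        pd.DataFrame(self.matrix, index=ids, columns=ids).to_csv(path)
        if sidecar_path is not None:
            Path(sidecar_path).write_text(json.dumps({"metric": self.metric, "n_cells": len(ids)}))


def grid_bin(
    records: pd.DataFrame,
    grid_extent: tuple[float, float, float, float],
    nx: int = 64,
    ny: int = 64,
    min_count: int = 50,
) -> CellFrequencyTable:
    """Bin persons into an ``nx`` x ``ny`` grid of equal-area cells.

    Cells are half-open ``[left, right) x [bottom, top)`` with the final
    column/row closed, so every in-extent point maps to exactly one cell.
    Cells with fewer than ``min_count`` persons are discarded. Frequencies
    are computed over person-slots: both surnames, weight 1 each.
    """
    x0, x1, y0, y1 = (float(v) for v in grid_extent)
    if x1 <= x0 or y1 <= y0:
        raise ValueError(f"empty grid_extent {grid_extent!r}")
    if nx < 1 or ny < 1:
        raise ValueError("nx and ny must be >= 1")

    xs = records["x"].to_numpy(dtype=float)
    ys = records["y"].to_numpy(dtype=float)
    inside = (xs >= x0) & (xs <= x1) & (ys >= y0) & (ys <= y1)
    n_out = int((~inside).sum())
    if n_out:
        logger.info("grid_bin: %d records outside the extent dropped", n_out)
    sub = records.loc[inside]
    xs, ys = xs[inside], ys[inside]

    ix = np.minimum((((xs - x0) / (x1 - x0)) * nx).astype(int), nx - 1)
    iy = np.minimum((((ys - y0) / (y1 - y0)) * ny).astype(int), ny - 1)

    freqs: dict[tuple[int, int], dict[str, float]] = {}
    counts: dict[tuple[int, int], Counter] = {}
    person_counts: dict[tuple[int, int], int] = {}
    mean_ses: dict[tuple[int, int], float] = {}

    key = pd.Series(list(zip(ix, iy)), index=sub.index)
    for cell, grp in sub.groupby(key):
        if len(grp) < min_count:
            continue
        c: Counter = Counter(grp["paternal_surname"])
        c.update(grp["maternal_surname"])
        total = sum(c.values())
        freqs[cell] = {s: v / total for s, v in c.items()}
        counts[cell] = c
        person_counts[cell] = len(grp)
        if "ses" in grp.columns:
            mean_ses[cell] = float(grp["ses"].mean())

    if not freqs:
        raise ValueError(f"no cell reaches min_count={min_count} persons")
    logger.info(
        "grid_bin: retained %d of %d candidate cells (min_count=%d)",
        len(freqs), nx * ny, min_count,
    )
    return CellFrequencyTable(
        freqs=freqs,
        counts=counts,
        person_counts=person_counts,
        mean_ses=mean_ses,
        nx=nx,
        ny=ny,
        extent=(x0, x1, y0, y1),
        n_candidate_cells=nx * ny,
    )


def alpha(frequencies: Mapping[str, float]) -> float:
    """Effective surname number 1 / sum(p_k^2) (inverse Simpson index)."""
    if not frequencies:
        raise ValueError("alpha of an empty cell is undefined")
    ssq = sum(p * p for p in frequencies.values())
    return 1.0 / ssq


def isonymy_between(cell_i: Mapping[str, float], cell_j: Mapping[str, float]) -> float:
    """I_ij = sum over surnames shared by both cells of p_ki * p_kj.

    Zero when the shared set is empty.
    """
    if len(cell_j) < len(cell_i):
        cell_i, cell_j = cell_j, cell_i
    return sum(p * cell_j[s] for s, p in cell_i.items() if s in cell_j)


def lasker_distance(i_ij: float) -> float:
    """LD = -ln I_ij; +inf when I_ij = 0."""
    if i_ij < 0:
        raise ValueError("isonymy must be non-negative")
    return math.inf if i_ij == 0 else -math.log(i_ij)


def nei_distance(i_ij: float, i_ii: float, i_jj: float) -> float:
    """ND = -ln( I_ij / sqrt(I_ii * I_jj) ); +inf when I_ij = 0."""
    if min(i_ij, i_ii, i_jj) < 0:
        raise ValueError("isonymy must be non-negative")
    if i_ij == 0:
        return math.inf
    return -math.log(i_ij / math.sqrt(i_ii * i_jj))


def euclid_distance(
    cell_i: Mapping[str, float],
    cell_j: Mapping[str, float],
    literal: bool = False,
) -> float:
    """Chord distance sqrt(1 - sum_k sqrt(p_ki * p_kj)); in [0, 1].

    0 for identical frequency vectors, 1 for disjoint surname sets.
    ``literal=True`` computes 1 - sum_k p_ki * p_kj instead (the inner
    product without radicals), exposed for comparison only.
    """
    if any(p < 0 for p in cell_i.values()) or any(p < 0 for p in cell_j.values()):
        raise ValueError("negative frequencies")
    if literal:
        return 1.0 - isonymy_between(cell_i, cell_j)
    if len(cell_j) < len(cell_i):
        cell_i, cell_j = cell_j, cell_i
    overlap = sum(math.sqrt(p * cell_j[s]) for s, p in cell_i.items() if s in cell_j)
    return math.sqrt(max(1.0 - overlap, 0.0))


def _cell_matrix(cells: CellFrequencyTable, sqrt_values: bool) -> tuple[sparse.csr_matrix, list]:
    order = cells.cells
    surnames = sorted({s for c in order for s in cells.freqs[c]})
    sidx = {s: i for i, s in enumerate(surnames)}
    rows, cols, vals = [], [], []
    for r, c in enumerate(order):
        for s, p in cells.freqs[c].items():
            rows.append(r)
            cols.append(sidx[s])
            vals.append(math.sqrt(p) if sqrt_values else p)
    m = sparse.csr_matrix((vals, (rows, cols)), shape=(len(order), len(surnames)))
    return m, order


def distance_matrix(cells: CellFrequencyTable, metric: str = "euclid") -> DistanceMatrix:
    """Full symmetric pairwise distance matrix over the retained cells."""
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; valid: {', '.join(METRICS)}")
    order = cells.cells
    if len(order) < 2:
        raise ValueError("distance_matrix requires at least 2 retained cells")

    if metric == "euclid":
        m, _ = _cell_matrix(cells, sqrt_values=True)
        overlap = np.asarray((m @ m.T).todense())
        d = np.sqrt(np.clip(1.0 - overlap, 0.0, None))
        np.fill_diagonal(d, 0.0)
    else:
        m, _ = _cell_matrix(cells, sqrt_values=False)
        iso = np.asarray((m @ m.T).todense())
        with np.errstate(divide="ignore"):
            if metric == "lasker":
                d = -np.log(iso)
            else:  # nei
                self_iso = np.diag(iso)
                d = -np.log(iso / np.sqrt(np.outer(self_iso, self_iso)))
                np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # symmetrize fp noise
    return DistanceMatrix(cells=list(order), matrix=d, metric=metric)


def separability_report(
    dm: DistanceMatrix,
    k_max: int = 8,
    seed: int | None = 0,
) -> dict:
    """BIC-selected 1-D Gaussian mixture over the off-diagonal distances.

    Returns the selected component count, the per-K BIC values, and the
    histogram range. A degenerate (all-equal) distance set reports one
    component.
    """
    d = dm.offdiag()
    d = d[np.isfinite(d)]
    if d.size < 30:
        raise ValueError("separability_report requires >= 30 finite off-diagonal distances")
    lo, hi = float(d.min()), float(d.max())
    if hi - lo < 1e-12:
        return {"metric": dm.metric, "n_components": 1, "bic": None, "range": (lo, hi)}
    X = d.reshape(-1, 1)
    bics = []
    for k in range(1, k_max + 1):
        gm = GaussianMixture(n_components=k, random_state=seed, n_init=2)
        gm.fit(X)
        bics.append(float(gm.bic(X)))
    best = int(np.argmin(bics)) + 1
    return {"metric": dm.metric, "n_components": best, "bic": bics, "range": (lo, hi)}


def alpha_ses_correlation(cells: CellFrequencyTable) -> float:
    """Pearson correlation between per-cell alpha and per-cell mean SES.

    NaN sentinel when either variable has zero variance.
    """
    order = [c for c in cells.cells if c in cells.mean_ses]
    if len(order) < 3:
        raise ValueError("alpha_ses_correlation requires >= 3 cells with SES")
    alphas = np.array([alpha(cells.freqs[c]) for c in order])
    ses = np.array([cells.mean_ses[c] for c in order])
    if np.std(alphas) == 0 or np.std(ses) == 0:
        return float("nan")
    return float(sps.pearsonr(alphas, ses).statistic)
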