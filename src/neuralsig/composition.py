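"""Integer cell-type counts per spot and nucleus-level cell-type maps.

Per-spot deconvolution scores d_jk (any non-negative abundance measure,
e.g. exported posterior cell abundances) are min-max normalized to [0, 1]
over the whole matrix, and the number of cells of type k at grid point j
is estimated from the local nucleus count N_j as

    C_jk = round(d'_jk * N_j / sum_k d'_jk)

with rounding half away from zero. Totals are conserved only within the
rounding bound |sum_k C_jk - N_j| <= T/2; an optional largest-remainder
correction enforces exact conservation. Nuclei are then assigned concrete
cell types by building, per grid point, a multiset with C_jk copies of
each type, padding or truncating to the local nucleus count in
largest-remainder order, and shuffling deterministically.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
import scipy.spatial

__all__ = ["CompositionGrid", "NucleusMap", "estimate_counts", "assign_cell_types"]

logger = logging.getLogger(__name__)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


@dataclasses.dataclass(frozen=True)
class CompositionGrid:
    """Per grid point: normalized scores, nucleus counts, integer counts."""

    scores: pd.DataFrame  # raw d_jk, grid point x cell type
    normalized: pd.DataFrame  # d'_jk in [0, 1]
    nucleus_counts: pd.Series  # N_j
    counts: pd.DataFrame  # integer C_jk
    quotas: pd.DataFrame  # real-valued quotas before rounding

    @property
    def cell_types(self) -> list[str]:
        return list(self.counts.columns)


@dataclasses.dataclass(frozen=True)
class NucleusMap:
    """Nucleus positions with assigned cell types and home grid points."""

    table: pd.DataFrame  # columns: x, y, grid_point, cell_type (NaN = unassigned)


def estimate_counts(
    scores: pd.DataFrame,
    nucleus_counts: pd.Series,
    conserve: bool = False,
    per_type_normalization: bool = False,
    normalize: bool = True,
) -> CompositionGrid:
    """Estimate integer cell-type counts per grid point.

    ``scores`` is grid point x cell type (non-negative); ``nucleus_counts``
    gives N_j per grid point. Normalization is global min-max by default
    (``per_type_normalization`` switches to column-wise; ``normalize=False``
    treats the input as already-normalized d' values). With
    ``conserve=True``, a largest-remainder correction forces
    sum_k C_jk == N_j exactly.
    """
    counts_n = nucleus_counts.reindex(scores.index)
    if counts_n.isna().any():
        raise ValueError("nucleus_counts must cover every grid point")
    if (counts_n < 0).any():
        raise ValueError("nucleus counts must be non-negative")
    d = scores.to_numpy(dtype=float)
    if (d < 0).any():
        raise ValueError("scores must be non-negative")

    if not normalize:
        if d.max() > 1:
            raise ValueError("normalize=False requires scores already in [0, 1]")
        dn = d.copy()
    elif per_type_normalization:
        lo, hi = d.min(axis=0), d.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        dn = (d - lo) / span
        dn[:, hi == lo] = np.where(hi[hi == lo] > 0, 1.0, 0.0)
    else:
        lo, hi = d.min(), d.max()
        if hi > lo:
            dn = (d - lo) / (hi - lo)
        else:
            dn = np.full_like(d, 1.0 if hi > 0 else 0.0)

    n = counts_n.to_numpy(dtype=float)
    row_sum = dn.sum(axis=1)
    zero_rows = row_sum == 0
    if zero_rows.any():
        warnings.warn(
            f"{int(zero_rows.sum())} grid point(s) have all-zero normalized "
            "scores; their counts are set to 0",
            stacklevel=2,
        )
    safe = np.where(zero_rows, 1.0, row_sum)
    quotas = dn * n[:, None] / safe[:, None]
    quotas[zero_rows] = 0.0
    counts = _round_half_away(quotas)

    if conserve:
        deficit = (n - counts.sum(axis=1)).astype(int)
        remainders = quotas - np.floor(quotas)
        for j in np.flatnonzero(deficit != 0):
            order = np.argsort(-remainders[j], kind="stable")
            step, k = (1, order) if deficit[j] > 0 else (-1, order[::-1])
            i = 0
            while deficit[j] != 0 and i < 10 * len(k):
                t = k[i % len(k)]
                if step < 0 and counts[j, t] <= 0:
                    i += 1
                    continue
                counts[j, t] += step
                deficit[j] -= step
                i += 1

    frame = lambda arr: pd.DataFrame(arr, index=scores.index, columns=scores.columns)
    return CompositionGrid(
        scores=scores.copy(),
        normalized=frame(dn),
        nucleus_counts=counts_n.astype(int),
        counts=frame(counts.astype(int)),
        quotas=frame(quotas),
    )


def assign_cell_types(
    grid: CompositionGrid,
    nucleus_positions: pd.DataFrame,
    grid_coords: pd.DataFrame,
    seed: int = 0,
    max_distance: float | None = None,
) -> NucleusMap:
    """Assign one cell type per nucleus, conserving per-grid-point counts.

    Nuclei are mapped to their nearest grid point (Euclidean); nuclei
    farther than ``max_distance`` from every grid point stay unassigned
    (logged). Per grid point the multiset of C_jk type copies is padded or
    truncated to the local nucleus count in largest-remainder order, then
    shuffled with the seed.
    """
    pts = nucleus_positions[["x", "y"]].to_numpy(dtype=float)
    centers = grid_coords[["x", "y"]].to_numpy(dtype=float)
    dist = scipy.spatial.distance.cdist(pts, centers)
    nearest = dist.argmin(axis=1)
    nearest_dist = dist[np.arange(len(pts)), nearest]
    grid_ids = np.asarray(grid_coords.index)
    assigned_point = grid_ids[nearest].astype(object)
    if max_distance is not None:
        far = nearest_dist > max_distance
        if far.any():
            logger.info("%d nuclei beyond max_distance left unassigned", far.sum())
        assigned_point[far] = None

    rng = np.random.default_rng(seed)
    types = np.array(grid.cell_types, dtype=object)
    cell_type = np.full(len(pts), None, dtype=object)
    for j, gid in enumerate(grid_ids):
        members = np.flatnonzero(assigned_point == gid)
        if members.size == 0:
            continue
        row = grid.counts.loc[gid].to_numpy(dtype=int)
        quota = grid.quotas.loc[gid].to_numpy(dtype=float)
        remainder_order = np.argsort(-(quota - np.floor(quota)), kind="stable")
        pool = list(np.repeat(types, row))
        i = 0
        while len(pool) < members.size:  # pad by largest remainder, cyclically
            pool.append(types[remainder_order[i % len(types)]])
            i += 1
        if len(pool) > members.size:  # truncate from smallest remainder
            drop_order = [types[t] for t in remainder_order[::-1]]
            for t in drop_order:
                while len(pool) > members.size and t in pool:
                    pool.remove(t)
        pool = np.array(pool, dtype=object)
        rng.shuffle(pool)
        cell_type[members] = pool

    table = nucleus_positions[["x", "y"]].copy()
    table["grid_point"] = assigned_point
    table["cell_type"] = cell_type
    return NucleusMap(table=table)
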