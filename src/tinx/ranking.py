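"""Non-dominated-solution (NDS) ranking over (novelty, importance).

Rank 1 is the Pareto front maximizing both coordinates; rank r points are the
non-dominated set once ranks < r are removed. The default dominance
convention is *weak* Pareto dominance (>= in both coordinates, > in at least
one): with weak dominance a point that merely ties the front in one coordinate
but loses in the other is pushed to a later front, which is the behaviour one
wants when many associations share an exact novelty value. Strict dominance
(> in both) is available via ``mode="strict"``; the two differ only at exact
coordinate ties. Equal points never dominate each other in either mode, so
duplicates share a rank.

The weak-mode ranker is an O(n log n) sweep: points are processed in
lexicographically decreasing order and each is placed, by binary search, on
the first front whose best point fails to dominate it (front "bests" are
monotone across fronts, which makes the search valid).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd


def dominates(p: Sequence[float], q: Sequence[float], mode: str = "weak") -> bool:
    """True iff point p Pareto-dominates point q (both coordinates maximized)."""
    if mode == "weak":
        return p[0] >= q[0] and p[1] >= q[1] and (p[0] > q[0] or p[1] > q[1])
    if mode == "strict":
        return p[0] > q[0] and p[1] > q[1]
    raise ValueError(f"unknown dominance mode {mode!r}")


def _nds_rank_weak_sweep(pts: np.ndarray) -> np.ndarray:
    """Front ranks under weak dominance via sorted sweep + binary search."""
    n = len(pts)
    ranks = np.empty(n, dtype=np.int64)
    order = np.lexsort((-pts[:, 1], -pts[:, 0]))  # x desc, then y desc
    # per front: (max y seen, max x among points at that y)
    best: list[tuple[float, float]] = []
    for idx in order:
        x, y = pts[idx, 0], pts[idx, 1]
        lo, hi = 0, len(best)
        while lo < hi:
            mid = (lo + hi) // 2
            by, bx = best[mid]
            if by > y or (by == y and bx > x):  # front mid dominates the point
                lo = mid + 1
            else:
                hi = mid
        if lo == len(best):
            best.append((y, x))
        else:
            by, bx = best[lo]
            if y > by or (y == by and x > bx):
                best[lo] = (y, x)
        ranks[idx] = lo + 1
    return ranks


def _nds_rank_peel(pts: np.ndarray, mode: str) -> np.ndarray:
    """Front ranks by iterated removal of the non-dominated set."""
    n = len(pts)
    ranks = np.zeros(n, dtype=np.int64)
    remaining = np.arange(n)
    r = 1
    while remaining.size:
        x = pts[remaining, 0]
        y = pts[remaining, 1]
        if mode == "weak":
            dom = (
                (x[:, None] >= x[None, :])
                & (y[:, None] >= y[None, :])
                & ((x[:, None] > x[None, :]) | (y[:, None] > y[None, :]))
            )
        else:
            dom = (x[:, None] > x[None, :]) & (y[:, None] > y[None, :])
        nondominated = ~dom.any(axis=0)
        ranks[remaining[nondominated]] = r
        remaining = remaining[~nondominated]
        r += 1
    return ranks


def nds_rank(points, mode: str = "weak") -> np.ndarray:
    """NDS front rank (1 = Pareto front) for each (novelty, importance) point."""
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        return np.empty(0, dtype=np.int64)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of pairs")
    if not np.isfinite(pts).all():
        raise ValueError("all coordinates must be finite")
    if mode == "weak":
        return _nds_rank_weak_sweep(pts)
    if mode == "strict":
        return _nds_rank_peel(pts, "strict")
    raise ValueError(f"unknown dominance mode {mode!r}")


def order_table(
    records: pd.DataFrame,
    k: int = 300,
    novelty_col: str = "target_novelty",
    mode: str = "weak",
) -> pd.DataFrame:
    """Rank a scored association table and return its top-k rows.

    Ranks are computed over (``novelty_col``, ``importance``). Rows are
    ordered by (nds_rank asc, importance desc, novelty desc, target_id asc,
    disease_id asc) — a total order, so output is deterministic — and
    annotated with ``nds_rank`` and the 0-based ``within_rank_order``. All
    rows are returned when fewer than k exist.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    df = records.copy()
    if df.empty:
        df["nds_rank"] = pd.Series(dtype=np.int64)
        df["within_rank_order"] = pd.Series(dtype=np.int64)
        return df
    df["nds_rank"] = nds_rank(df[[novelty_col, "importance"]].to_numpy(), mode=mode)
    df = df.sort_values(
        by=["nds_rank", "importance", novelty_col, "target_id", "disease_id"],
        ascending=[True, False, False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    df["within_rank_order"] = df.groupby("nds_rank").cumcount()
    return df.head(k).reset_index(drop=True)
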