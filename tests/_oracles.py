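"""Independent brute-force oracles used to pin expected values.

Each oracle recomputes a quantity by dense enumeration or naive looping,
deliberately sharing no code with the implementation path it checks.
"""
from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def brute_force_score(read: str, transcripts: dict[str, str], k: int) -> tuple[int, str]:
    """All-offsets ungapped scorer: for every transcript and every fully
    contained offset, count matching bases; an offset is admissible iff the
    placement shares at least one exact k-mer with the read. Ties break on
    the lexicographically smallest gene id (genes scanned in sorted order,
    strictly-greater to win)."""
    r = np.frombuffer(read.encode(), dtype=np.uint8)
    l = r.size
    best_score, best_gene = 0, min(transcripts)
    for gene in sorted(transcripts):
        t = np.frombuffer(transcripts[gene].encode(), dtype=np.uint8)
        if t.size < l:
            continue
        windows = sliding_window_view(t, l)  # (n_offsets, l)
        eq = windows == r
        # admissible: some run of k consecutive matches
        runs = sliding_window_view(eq, k, axis=1).all(axis=2).any(axis=1)
        scores = np.where(runs, eq.sum(axis=1), 0)
        s = int(scores.max()) if scores.size else 0
        if s > best_score:
            best_score, best_gene = s, gene
    return best_score, best_gene


def bh_step_up(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values by the textbook definition:
    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    for i in range(m):
        q_sorted[i] = min(min(p[order[j]] * m / (j + 1) for j in range(i, m)), 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def bky_two_stage_naive(p: np.ndarray, q: float) -> set[int]:
    """Two-stage adaptive step-up by plain looping; returns the set of
    rejected input indices."""

    def bh_reject(pvals: np.ndarray, level: float) -> set[int]:
        m = pvals.size
        order = sorted(range(m), key=lambda i: pvals[i])
        kmax = 0
        for rank, i in enumerate(order, start=1):
            if pvals[i] <= rank * level / m:
                kmax = rank
        return set(order[:kmax])

    p = np.asarray(p, float)
    m = p.size
    q1 = q / (1.0 + q)
    stage1 = bh_reject(p, q1)
    r1 = len(stage1)
    if r1 == 0:
        return set()
    if r1 == m:
        return stage1
    return bh_reject(p, q1 * m / (m - r1))


def dense_boundary_distance(point, polygon_coords, n_samples: int = 100_000) -> float:
    """Distance to a polygon ring approximated by densely sampled boundary
    points (arc-length uniform along each edge)."""
    coords = np.asarray(polygon_coords, float)
    if not np.array_equal(coords[0], coords[-1]):
        coords = np.vstack([coords, coords[0]])
    seg = np.diff(coords, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    total = seg_len.sum()
    pts = []
    for (x0, y0), (dx, dy), sl in zip(coords[:-1], seg, seg_len):
        n = max(2, int(round(n_samples * sl / total)))
        t = np.linspace(0.0, 1.0, n)
        pts.append(np.column_stack([x0 + t * dx, y0 + t * dy]))
    pts = np.vstack(pts)
    d = np.hypot(pts[:, 0] - point[0], pts[:, 1] - point[1])
    return float(d.min())
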