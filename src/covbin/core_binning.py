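"""Core stage: preliminary bins from long contigs.

Long contigs (>= 1 kbp by default) are rasterised into a 3-D grid over
min-max-scaled transformed coordinates, with each contig depositing its
length into its cell. After Gaussian smoothing, bins are carved off the
density field greedily: take the global peak, flood-fill outward over
26-neighbours accepting cells that stay above a fraction of the peak and
never increase along the path (the ridge rule, which stops a region from
bridging through a saddle into a neighbouring population), prune
composition outliers, accept or discard the candidate, zero the region
and repeat until the field is empty.

Length weighting means a bin's evidence is assembled bases, not contig
count, matching how binning accuracy is judged (bases first).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .profile_store import ProfileStore

_MAD_SCALE = 1.4826  # MAD -> sigma for normal data


@dataclass
class Bin:
    """One bin: members plus cached centroid/scatter statistics."""

    bin_id: int
    members: set = field(default_factory=set)
    centroid_cov: np.ndarray | None = None
    centroid_tf: np.ndarray | None = None
    scatter_cov: np.ndarray | None = None
    scatter_tf: np.ndarray | None = None
    total_bp: int = 0


class BinSet:
    """Bins plus the unbinned remainder: always a partition of the store.

    Centroids (mean transformed coordinate / TF score) and per-axis
    scatter (median absolute deviation) are recomputed on every
    membership change. Refine actions are journaled append-only so a
    final state can be reproduced by replay.
    """

    def __init__(self, store: ProfileStore):
        if store.transformed is None or store.tf_scores is None:
            raise ValueError("store has no transformed coordinates; run the transform first")
        self.store = store
        self.bins: dict[int, Bin] = {}
        self.unbinned: set = set(store.contig_ids)
        self.journal: list[dict] = []
        self._index = {cid: i for i, cid in enumerate(store.contig_ids)}

    # -- bookkeeping

    def _rows(self, members) -> np.ndarray:
        return np.array([self._index[c] for c in members], dtype=np.int64)

    def refresh(self, bin_id: int) -> None:
        b = self.bins[bin_id]
        rows = self._rows(sorted(b.members))
        cov = self.store.transformed[rows]
        tf = self.store.tf_scores[rows]
        b.centroid_cov = cov.mean(axis=0)
        b.centroid_tf = tf.mean(axis=0)
        b.scatter_cov = np.median(np.abs(cov - np.median(cov, axis=0)), axis=0)
        b.scatter_tf = np.median(np.abs(tf - np.median(tf, axis=0)), axis=0)
        b.total_bp = int(self.store.lengths[rows].sum())

    def add_bin(self, members, bin_id: int | None = None) -> Bin:
        members = set(members)
        if not members:
            raise ValueError("a bin needs at least one member")
        if not members <= self.unbinned:
            raise ValueError("members must come from the unbinned pool")
        if bin_id is None:
            bin_id = max(self.bins, default=0) + 1
        b = Bin(bin_id=bin_id, members=members)
        self.bins[bin_id] = b
        self.unbinned -= members
        self.refresh(bin_id)
        return b

    def drop_bin(self, bin_id: int) -> None:
        b = self.bins.pop(bin_id)
        self.unbinned |= b.members

    def assignment_of(self, contig_id) -> int:
        for bid, b in self.bins.items():
            if contig_id in b.members:
                return bid
        return 0

    def check_partition(self) -> bool:
        seen = set(self.unbinned)
        total = len(seen)
        for b in self.bins.values():
            total += len(b.members)
            seen |= b.members
        return total == len(seen) == self.store.n_contigs

    # -- store round trip

    def to_store(self) -> None:
        assign = np.zeros(self.store.n_contigs, dtype=np.int64)
        for bid, b in self.bins.items():
            assign[self._rows(b.members)] = bid
        self.store.bins = assign
        self.store.journal = list(self.journal)

    @classmethod
    def from_store(cls, store: ProfileStore) -> "BinSet":
        bs = cls(store)
        for bid in sorted(set(store.bins) - {0}):
            members = set(store.contig_ids[store.bins == bid])
            bs.add_bin(members, bin_id=int(bid))
        bs.journal = list(store.journal)
        return bs


def tf_outlier_prune(candidate_members, tf_scores, robust_z: float = 3.5):
    """Split candidate members into (kept, pruned) by robust TF z-score.

    Per PCA component, a member is an outlier if its absolute deviation
    from the member median exceeds *robust_z* scaled MADs; components
    with zero MAD are skipped. Candidates with fewer than 3 members are
    returned unchanged.
    """
    members = list(candidate_members)
    scores = np.asarray(tf_scores, dtype=np.float64)
    if scores.ndim == 1:
        scores = scores[:, None]
    if len(members) < 3:
        return members, []
    med = np.median(scores, axis=0)
    mad = np.median(np.abs(scores - med), axis=0)
    out = np.zeros(len(members), dtype=bool)
    for k in range(scores.shape[1]):
        if mad[k] == 0:
            continue
        out |= np.abs(scores[:, k] - med[k]) / (_MAD_SCALE * mad[k]) > robust_z
    kept = [m for m, o in zip(members, out) if not o]
    pruned = [m for m, o in zip(members, out) if o]
    return kept, pruned


def _flood_fill(density: np.ndarray, peak: tuple, threshold: float) -> list[tuple]:
    """Ridge-rule region growth: 26-connected, non-increasing, >= threshold.

    A cell belongs to the region iff some path from the peak reaches it
    without the density ever increasing. Cells are expanded in
    descending density order (ties by lowest flat index) so that every
    such path is found; a plain FIFO fill can dequeue a cell before its
    best predecessor and miss valid cells.
    """
    grid = density.shape[0]
    offsets = [
        (di, dj, dk)
        for di in (-1, 0, 1)
        for dj in (-1, 0, 1)
        for dk in (-1, 0, 1)
        if (di, dj, dk) != (0, 0, 0)
    ]
    flat = peak[0] * grid * grid + peak[1] * grid + peak[2]
    region = {peak}
    heap = [(-density[peak], flat, peak)]
    while heap:
        neg_here, _, (i, j, k) = heapq.heappop(heap)
        here = -neg_here
        for di, dj, dk in offsets:
            ni, nj, nk = i + di, j + dj, k + dk
            if not (0 <= ni < grid and 0 <= nj < grid and 0 <= nk < grid):
                continue
            nb = (ni, nj, nk)
            if nb in region:
                continue
            v = density[ni, nj, nk]
            if threshold <= v <= here:
                region.add(nb)
                heapq.heappush(heap, (-v, ni * grid * grid + nj * grid + nk, nb))
    return sorted(region)


def make_core_bins(
    store: ProfileStore,
    core_min_len: int = 1000,
    grid: int = 128,
    sigma: float = 1.5,
    alpha: float = 0.15,
    min_bin_bp: int = 50_000,
    min_bin_contigs: int = 5,
    min_span: float = 2.0,
) -> BinSet:
    """Form core bins from contigs >= *core_min_len* bp.

    Candidates are accepted when they carry at least *min_bin_bp*
    assembled bases or *min_bin_contigs* members; rejected candidates and
    composition outliers (see :func:`tf_outlier_prune`) stay unbinned for
    later recruitment. Deterministic for a fixed store: density ties are
    broken by lowest flat cell index.

    Axes are min-max scaled onto the grid, but the scaling span is
    floored at *min_span* (default 2.0, the natural width of the
    star-coordinate plane and two decades of depth in z). Without the
    floor, a dataset that is one tight cluster — a single population —
    would have its pure measurement noise stretched across the whole
    grid and be shredded into rejected slivers instead of one bin.
    """
    binset = BinSet(store)
    sel = np.nonzero(store.lengths >= core_min_len)[0]
    if sel.size == 0:
        raise ValueError(f"no contig is >= {core_min_len} bp; cannot form core bins")

    coords = store.transformed[sel]
    lo, hi = coords.min(axis=0), coords.max(axis=0)
    span = np.maximum(hi - lo, min_span)
    center = (lo + hi) / 2.0
    cells = np.clip(
        ((coords - center) / span + 0.5) * grid, 0, grid - 1
    ).astype(np.int64)

    hist = np.zeros((grid, grid, grid), dtype=np.float64)
    np.add.at(hist, tuple(cells.T), store.lengths[sel].astype(np.float64))
    density = gaussian_filter(hist, sigma=sigma)

    cell_contigs: dict[tuple, list[int]] = {}
    for pos, row in zip(map(tuple, cells), sel):
        cell_contigs.setdefault(pos, []).append(int(row))

    unassigned = set(int(r) for r in sel)
    while True:
        flat = int(np.argmax(density))
        peak = np.unravel_index(flat, density.shape)
        peak_val = density[peak]
        if peak_val <= 0:
            break
        region = _flood_fill(density, tuple(int(v) for v in peak), alpha * peak_val)
        member_rows = sorted(
            r for cell in region for r in cell_contigs.get(cell, []) if r in unassigned
        )
        if member_rows:
            kept, _pruned = tf_outlier_prune(
                member_rows, store.tf_scores[member_rows], robust_z=3.5
            )
            total_bp = int(store.lengths[kept].sum()) if kept else 0
            if kept and (total_bp >= min_bin_bp or len(kept) >= min_bin_contigs):
                binset.add_bin(set(store.contig_ids[kept]))
            unassigned -= set(member_rows)
        for cell in region:
            density[cell] = 0.0
    binset.to_store()
    return binset
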