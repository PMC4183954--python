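"""Refine stage (merge / split / delete, optionally marker-guided) and
recruit stage (pull short contigs into existing bins).

Refinement actions are journaled append-only; replaying the journal on
the pre-refine bin set reproduces the refined state exactly, because
splits use seeded k-means with a fixed restart schedule. Automatic
refinement is optional and is driven entirely by single-copy-marker
completeness/contamination scores: contaminated bins are split when a
split lowers total contamination, and complementary partial bins are
merged when the union is clearly more complete without becoming dirtier.

Recruitment assigns each remaining contig to its nearest bin in a
scatter-normalised combined coverage+composition space, but only if it
falls within the radius that contains *radius_quantile* of that bin's
own members — tight bins recruit conservatively, diffuse bins broadly.
"""

from __future__ import annotations

import logging
import time
from itertools import combinations

import numpy as np
from sklearn.cluster import KMeans

from .core_binning import BinSet
from .marker_qc import bin_quality
from .profile_store import ProfileStore

logger = logging.getLogger(__name__)

_EPS = 1e-6
_SPLIT_SEEDS = range(10)


def merge_bins(binset: BinSet, bin_ids) -> BinSet:
    """Merge >= 2 bins into one under the lowest input bin id."""
    bin_ids = sorted(int(b) for b in bin_ids)
    if len(bin_ids) < 2:
        raise ValueError("merging needs at least two bins")
    unknown = [b for b in bin_ids if b not in binset.bins]
    if unknown:
        raise KeyError(f"unknown bin ids: {unknown}")
    target = bin_ids[0]
    for bid in bin_ids[1:]:
        binset.bins[target].members |= binset.bins.pop(bid).members
    binset.refresh(target)
    binset.journal.append(
        {
            "kind": "merge",
            "inputs": bin_ids,
            "outputs": [target],
            "timestamp": time.time(),
            "reason": "",
        }
    )
    return binset


def _split_features(binset: BinSet, rows: np.ndarray, axis: str) -> np.ndarray:
    store = binset.store
    if axis == "coverage":
        return store.transformed[rows]
    if axis == "tf":
        return store.tf_scores[rows]
    if axis == "length":
        return np.log10(store.lengths[rows].astype(np.float64))[:, None]
    raise ValueError(f"unknown split axis {axis!r}; use coverage, tf or length")


def _split_memberships(binset: BinSet, bin_id: int, axis: str, k: int) -> list[set]:
    """Trial k-means partition of a bin's members (no mutation).

    Ten seeded restarts, best inertia wins, ties go to the lowest seed.
    Children are ordered by their smallest member row so labels are
    stable across replays.
    """
    members = sorted(binset.bins[bin_id].members)
    if len(members) < k:
        raise ValueError(f"bin {bin_id} has {len(members)} members, cannot split into {k}")
    rows = binset._rows(members)
    feats = _split_features(binset, rows, axis)
    best = None
    for seed in _SPLIT_SEEDS:
        km = KMeans(n_clusters=k, n_init=1, random_state=seed).fit(feats)
        if best is None or km.inertia_ < best.inertia_:
            best = km
    groups: dict[int, list] = {}
    for member, label in zip(members, best.labels_):
        groups.setdefault(int(label), []).append(member)
    ordered = sorted(groups.values(), key=lambda g: min(binset._index[c] for c in g))
    return [set(g) for g in ordered]


def split_bin(binset: BinSet, bin_id: int, axis: str = "coverage", k: int = 2) -> BinSet:
    """Split one bin into *k* children along coverage, tf or length."""
    children = _split_memberships(binset, bin_id, axis, k)
    binset.drop_bin(bin_id)
    out_ids = []
    for members in children:
        out_ids.append(binset.add_bin(members).bin_id)
    binset.journal.append(
        {
            "kind": "split",
            "inputs": [bin_id],
            "outputs": out_ids,
            "axis": axis,
            "k": k,
            "timestamp": time.time(),
            "reason": "",
        }
    )
    return binset


def delete_bin(binset: BinSet, bin_id: int) -> BinSet:
    """Dissolve a bin; its members return to the unbinned pool."""
    if bin_id not in binset.bins:
        raise KeyError(f"unknown bin id {bin_id}")
    binset.drop_bin(bin_id)
    binset.journal.append(
        {
            "kind": "delete",
            "inputs": [bin_id],
            "outputs": [],
            "timestamp": time.time(),
            "reason": "",
        }
    )
    return binset


def replay_journal(binset: BinSet, journal: list[dict]) -> BinSet:
    """Re-apply a refine journal to a bin set (used to audit refinement)."""
    for action in journal:
        if action["kind"] == "merge":
            merge_bins(binset, action["inputs"])
        elif action["kind"] == "split":
            split_bin(binset, action["inputs"][0], axis=action["axis"], k=action["k"])
        elif action["kind"] == "delete":
            delete_bin(binset, action["inputs"][0])
        else:
            raise ValueError(f"unknown journal action {action['kind']!r}")
    return binset


def _clean_marker_table(binset: BinSet, marker_table) -> list[tuple]:
    known = set(binset.store.contig_ids)
    rows, dropped = [], 0
    for contig_id, marker_id in marker_table:
        if contig_id in known:
            rows.append((contig_id, marker_id))
        else:
            dropped += 1
    if dropped:
        logger.warning("ignoring %d marker rows for unknown contigs", dropped)
    return rows


def _quality_of(members, marker_rows, marker_set):
    hits = [(c, m) for c, m in marker_rows if c in members]
    return bin_quality(hits, marker_set)


def auto_refine(
    binset: BinSet,
    marker_table,
    marker_set,
    cont_max: float = 10.0,
    merge_gain: float = 10.0,
    merge_cont_tol: float = 5.0,
) -> BinSet:
    """Marker-score-guided refinement to a fixpoint.

    Split pass: every bin whose contamination exceeds *cont_max* (taken
    in ascending bin-id order) is trial-split on coverage, then on
    composition; the first split whose children's summed contamination is
    below the parent's is accepted. Merge pass: bin pairs in ascending
    (x, y) centroid distance are merged when the union's completeness
    beats the better individual by *merge_gain* points and its
    contamination stays within *merge_cont_tol* of the cleaner one.
    Passes repeat until one makes no change.
    """
    marker_rows = _clean_marker_table(binset, marker_table)
    for _ in range(100):
        changed = False
        # split pass
        for bid in sorted(binset.bins):
            b = binset.bins[bid]
            parent_q = _quality_of(b.members, marker_rows, marker_set)
            if parent_q.contamination <= cont_max or len(b.members) < 2:
                continue
            for axis in ("coverage", "tf"):
                children = _split_memberships(binset, bid, axis, k=2)
                child_cont = sum(
                    _quality_of(c, marker_rows, marker_set).contamination
                    for c in children
                )
                if child_cont < parent_q.contamination:
                    split_bin(binset, bid, axis=axis, k=2)
                    changed = True
                    break
        # merge pass
        merged = True
        while merged:
            merged = False
            pairs = sorted(
                combinations(sorted(binset.bins), 2),
                key=lambda p: float(
                    np.hypot(
                        *(
                            binset.bins[p[0]].centroid_cov[:2]
                            - binset.bins[p[1]].centroid_cov[:2]
                        )
                    )
                ),
            )
            for a, b in pairs:
                qa = _quality_of(binset.bins[a].members, marker_rows, marker_set)
                qb = _quality_of(binset.bins[b].members, marker_rows, marker_set)
                qu = _quality_of(
                    binset.bins[a].members | binset.bins[b].members,
                    marker_rows,
                    marker_set,
                )
                if (
                    qu.completeness >= max(qa.completeness, qb.completeness) + merge_gain
                    and qu.contamination
                    <= min(qa.contamination, qb.contamination) + merge_cont_tol
                ):
                    merge_bins(binset, [a, b])
                    changed = merged = True
                    break
        if not changed:
            break
    return binset


def _bin_geometry(binset: BinSet, bid: int, radius_quantile: float):
    b = binset.bins[bid]
    centroid = np.concatenate([b.centroid_cov, b.centroid_tf])
    scale = np.maximum(np.concatenate([b.scatter_cov, b.scatter_tf]), _EPS)
    rows = binset._rows(sorted(b.members))
    feats = np.hstack([binset.store.transformed[rows], binset.store.tf_scores[rows]])
    dists = np.sqrt((((feats - centroid) / scale) ** 2).sum(axis=1))
    return centroid, scale, float(np.quantile(dists, radius_quantile))


def recruit_contigs(
    binset: BinSet,
    store: ProfileStore | None = None,
    recruit_min_len: int = 500,
    radius_quantile: float = 0.95,
    max_rounds: int = 10,
) -> BinSet:
    """Assign unbinned contigs >= *recruit_min_len* bp to nearby bins.

    Distance is Euclidean over the 3 coverage axes plus the TF-PCA axes,
    each normalised by the bin's own scatter; a contig joins its nearest
    bin only within that bin's member-distance quantile radius. Rounds
    repeat with refreshed centroids until nothing moves. Core members
    are never reassigned.
    """
    store = store or binset.store
    if not binset.bins:
        raise ValueError("cannot recruit: no bins exist")
    feats_all = np.hstack([store.transformed, store.tf_scores])
    for _ in range(max_rounds):
        geometry = {
            bid: _bin_geometry(binset, bid, radius_quantile)
            for bid in sorted(binset.bins)
        }
        candidates = sorted(
            c for c in binset.unbinned
            if store.lengths[binset._index[c]] >= recruit_min_len
        )
        recruited: dict[int, list] = {}
        for cid in candidates:
            f = feats_all[binset._index[cid]]
            best_bid, best_d = None, np.inf
            for bid, (centroid, scale, radius) in geometry.items():
                d = float(np.sqrt((((f - centroid) / scale) ** 2).sum()))
                if d < best_d:
                    best_bid, best_d = bid, d
            if best_bid is not None and best_d <= geometry[best_bid][2]:
                recruited.setdefault(best_bid, []).append(cid)
        if not recruited:
            break
        for bid, newcomers in recruited.items():
            binset.bins[bid].members |= set(newcomers)
            binset.unbinned -= set(newcomers)
            binset.refresh(bid)
    binset.to_store()
    return binset
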