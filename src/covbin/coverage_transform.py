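"""Embed S-dimensional coverage profiles into a 3-D clustering space.

The (x, y) plane is a star-coordinate projection of the relative coverage
profile: sample k (in CLI order, k = 0..S-1) contributes along the unit
axis at angle 2*pi*k/S, and the contig's relative profile p = c / sum(c)
is the convex weight on those axes. Contigs whose depths co-vary across
samples (same population, any absolute abundance) therefore land on the
same (x, y) point; absolute abundance is carried separately by
z = log10(1 + total depth). Composition enters through PCA scores of the
canonical tetramer matrix.
"""

from __future__ import annotations

import numpy as np
from sklearn.decomposition import PCA

from .profile_store import ProfileStore


def transform_coverage(coverage: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Project a coverage matrix (contigs x samples) to (x, y, z).

    Requires at least three samples — with two, relative profiles are a
    single degree of freedom and populations cannot be resolved. Returns
    the (n, 3) coordinate array and a boolean flag vector marking
    all-zero coverage rows, which are pinned at the origin.
    """
    cov = np.asarray(coverage, dtype=np.float64)
    if cov.ndim == 1:
        cov = cov[None, :]
    n, s = cov.shape
    if s < 3:
        raise ValueError(
            f"coverage transform requires >= 3 samples, got {s}: "
            "differential-coverage binning needs at least three related samples"
        )
    if np.any(cov < 0):
        raise ValueError("coverage values must be non-negative")

    totals = cov.sum(axis=1)
    zero = totals == 0
    coords = np.zeros((n, 3), dtype=np.float64)
    theta = 2.0 * np.pi * np.arange(s) / s
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(zero[:, None], 0.0, cov / np.where(zero, 1.0, totals)[:, None])
    coords[:, 0] = p @ np.cos(theta)
    coords[:, 1] = p @ np.sin(theta)
    coords[:, 2] = np.log10(1.0 + totals)
    coords[zero] = 0.0
    return coords, zero


def tf_pca_scores(
    tetra: np.ndarray, n_components: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """First *n_components* principal-component scores of a tetramer matrix.

    Columns are centred; the sign of each component is fixed so that its
    largest-magnitude loading is positive, making scores deterministic.
    Returns (scores, loadings) with loadings shaped
    (n_components, n_features).
    """
    x = np.asarray(tetra, dtype=np.float64)
    if x.shape[0] < 2:
        raise ValueError("PCA needs at least 2 contigs")
    if n_components > x.shape[1]:
        raise ValueError("n_components exceeds the number of tetramer classes")
    if n_components > x.shape[0]:
        raise ValueError(
            f"cannot extract {n_components} components from {x.shape[0]} contigs"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    loadings = pca.components_
    for k in range(n_components):
        j = np.argmax(np.abs(loadings[k]))
        if loadings[k, j] < 0:
            loadings[k] = -loadings[k]
            scores[:, k] = -scores[:, k]
    return scores, loadings


def add_transforms(store: ProfileStore, n_components: int = 3) -> ProfileStore:
    """Compute and attach coverage coordinates and TF-PCA scores in place."""
    coords, zero = transform_coverage(store.coverage)
    store.transformed = coords
    store.zero_coverage_flags = zero
    n_components = min(n_components, store.n_contigs - 1) or 1
    scores, loadings = tf_pca_scores(store.kmers, n_components=n_components)
    store.tf_scores = scores
    store.pca_loadings = loadings
    return store
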