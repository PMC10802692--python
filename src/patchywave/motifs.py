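"""Motif definition: Phase Similarity Index, repetition thresholding,
spectral embedding.

Two phase maps are compared with the Phase Similarity Index (PSI), the
Fisher--Lee circular-circular correlation over shared valid channels:
+1 for identical patterns, -1 for identical structure traveling in the
opposite direction, ~0 for unrelated maps.  The Np x Np PSI matrix C is
binarized at a similarity threshold S; the row sum r_j counts the
"repeats" of pattern j, and patterns with r_j / mean(r) > R (repetition
threshold) anchor motifs: scanning anchors in index order, each anchor not
already contained in an earlier motif emits the set {anchor} U {its
repeats} as a new motif.  Motif separation is quantified by embedding the
patterns on the top-3 eigenvectors of the (shifted) similarity matrix and
taking the ratio of between-motif centroid distance to within-motif
spread.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .circular import fisher_lee_corr
from .phase import PhasePattern

__all__ = [
    "SimilarityMatrix",
    "MotifSet",
    "ClusterEmbedding",
    "psi",
    "similarity_matrix",
    "define_motifs",
    "embed_and_score",
    "DISTANCE_RATIO_CAP",
]

MIN_SHARED_CHANNELS = 8
DISTANCE_RATIO_CAP = 1e3


def psi(p1: PhasePattern | np.ndarray, p2: PhasePattern | np.ndarray,
        min_shared: int = MIN_SHARED_CHANNELS) -> float:
    """Phase Similarity Index between two phase maps.

    Accepts PhasePattern objects (intersecting their valid-channel masks)
    or bare angle arrays.  Returns NaN when fewer than ``min_shared``
    channels are shared.
    """
    if isinstance(p1, PhasePattern) or isinstance(p2, PhasePattern):
        a, b = p1.phase, p2.phase
        m = p1.valid & p2.valid
        if m.sum() < min_shared:
            return float("nan")
        return fisher_lee_corr(a[m], b[m])
    a = np.asarray(p1, dtype=float).ravel()
    b = np.asarray(p2, dtype=float).ravel()
    if a.size < min_shared:
        return float("nan")
    return fisher_lee_corr(a, b)


@dataclass
class SimilarityMatrix:
    values: np.ndarray  # (Np, Np), symmetric, unit diagonal
    pattern_ids: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.values.shape[0]


def similarity_matrix(patterns: list) -> SimilarityMatrix:
    """All pairwise PSI values; symmetric with unit diagonal."""
    if len(patterns) < 2:
        raise ValueError("need at least 2 patterns")
    n = len(patterns)
    C = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            C[i, j] = C[j, i] = psi(patterns[i], patterns[j])
    return SimilarityMatrix(C, np.arange(n))


@dataclass
class MotifSet:
    motifs: list  # list of sorted index lists
    anchors: list  # anchor pattern per motif
    repeats: np.ndarray  # r_j per pattern
    S: float
    R: float
    r_mean: float

    @property
    def n_motifs(self) -> int:
        return len(self.motifs)

    def labels(self, n_patterns: int, dedupe: bool = True) -> np.ndarray:
        """Per-pattern motif label (-1 = none); earlier motifs win overlaps."""
        lab = np.full(n_patterns, -1, dtype=int)
        for m, members in enumerate(self.motifs):
            for j in members:
                if lab[j] < 0 or not dedupe:
                    lab[j] = m
        return lab


def define_motifs(
    C: SimilarityMatrix | np.ndarray, S: float, R: float, min_repeats: int = 0
) -> MotifSet:
    """Group repeating phase patterns into motifs.

    Binarize ``c_jk >= S`` (diagonal excluded, NaN counts as below
    threshold); ``r_j`` is the row sum (the number of repeats of j);
    pattern j is high-repetition when ``r_j / mean(r) > R``.  High-repetition
    anchors are visited in ascending index order and each anchor not already
    belonging to an emitted motif contributes the motif
    ``{anchor} U {k : c_jk >= S}``.  Motifs may overlap; anchors may not.
    ``min_repeats`` optionally drops anchors with fewer absolute repeats
    (useful on small pattern pools where mean(r) is close to zero).
    """
    M = C.values if isinstance(C, SimilarityMatrix) else np.asarray(C, dtype=float)
    if not (-1.0 <= S <= 1.0):
        raise ValueError("S must lie in [-1, 1]")
    if R <= 1.0:
        raise ValueError("R must exceed 1")
    n = M.shape[0]
    B = np.where(np.isnan(M), False, M >= S)
    np.fill_diagonal(B, False)
    r = B.sum(axis=1).astype(float)
    r_mean = float(r.mean())
    if r_mean == 0.0:
        return MotifSet([], [], r, S, R, r_mean)
    high = np.flatnonzero((r / r_mean > R) & (r >= min_repeats))
    motifs, anchors = [], []
    claimed = set()
    for h in high:
        if h in claimed:
            continue
        members = sorted(set(np.flatnonzero(B[h])) | {int(h)})
        motifs.append(members)
        anchors.append(int(h))
        claimed.update(members)
    return MotifSet(motifs, anchors, r, S, R, r_mean)


@dataclass
class ClusterEmbedding:
    eigenvalues: np.ndarray  # top-3, descending
    coords: np.ndarray  # (Np, 3)
    centroids: np.ndarray  # (n_motifs, 3)
    distance_ratio: float  # between / within; NaN if < 2 motifs
    capped: bool = False


def embed_and_score(
    C: SimilarityMatrix | np.ndarray,
    motifs: MotifSet,
    cap: float = DISTANCE_RATIO_CAP,
) -> ClusterEmbedding:
    """Spectral embedding of the PSI matrix and motif-separation score.

    The symmetric eigendecomposition of ``C + 1`` (shifted into [0, 2])
    provides the top-3 eigenvectors; each pattern's coordinates are the
    eigenvector entries scaled by sqrt(eigenvalue).  distance_ratio is the
    mean pairwise distance between motif centroids divided by the mean
    pattern-to-own-centroid distance; reported as NaN for fewer than two
    motifs and capped for degenerate (zero-spread) motifs.
    """
    M = C.values if isinstance(C, SimilarityMatrix) else np.asarray(C, dtype=float)
    A = np.nan_to_num(M, nan=0.0) + 1.0
    w, v = np.linalg.eigh(A)
    order = np.argsort(w)[::-1][:3]
    lam = w[order]
    vecs = v[:, order]
    coords = vecs * np.sqrt(np.clip(lam, 0.0, None))[None, :]

    cents = np.array(
        [coords[m].mean(axis=0) for m in motifs.motifs]
    ) if motifs.n_motifs else np.empty((0, 3))
    if motifs.n_motifs < 2:
        return ClusterEmbedding(lam, coords, cents, float("nan"))
    between = []
    for i in range(len(cents)):
        for j in range(i + 1, len(cents)):
            between.append(np.linalg.norm(cents[i] - cents[j]))
    within = []
    for m, members in enumerate(motifs.motifs):
        for k in members:
            within.append(np.linalg.norm(coords[k] - cents[m]))
    b = float(np.mean(between))
    wd = float(np.mean(within))
    # zero within-spread (identical patterns) is degenerate up to the
    # floating-point noise of the eigendecomposition
    eps = 1e-8 * max(1.0, float(np.abs(coords).max()))
    if wd <= eps or b / wd > cap:
        return ClusterEmbedding(lam, coords, cents, cap, capped=True)
    return ClusterEmbedding(lam, coords, cents, b / wd)
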