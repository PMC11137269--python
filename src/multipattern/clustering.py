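"""k-means partitioning of binary disease profiles under Jaccard distance.

Patients are compared with the Jaccard index of their condition sets
(distance = 1 - |A∩B|/|A∪B|).  Lloyd's algorithm needs a distance to
real-valued centroids, so assignment uses the generalised (Tanimoto)
Jaccard distance

    d(x, c) = 1 - sum_j min(x_j, c_j) / sum_j max(x_j, c_j),

which coincides with the set Jaccard distance whenever both arguments are
binary; centroids are within-cluster column means (per-condition cluster
prevalences).  The number of patterns is chosen as the smallest candidate k
whose Caliński–Harabasz score is close to the best among the k values whose
partitions are clinically valid, i.e. every cluster carries at least one
"essential" condition under the prevalence-ratio rule (see
:mod:`multipattern.patterns`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ClusteringError, NoValidPartitionError
from .patterns import EssentialRule, essential_conditions

DEFAULT_N_INIT = 10
DEFAULT_MAX_ITER = 100
DEFAULT_TOL = 1e-6


@dataclass
class ClusteringResult:
    """A fitted partition of one wave's disease matrix."""

    k: int
    labels: np.ndarray                  # (n,) pattern index in [0, k)
    centroids: np.ndarray               # (k, n_conditions) column means
    inertia: float                      # total within-cluster Jaccard distance
    ch_score: float                     # Caliński–Harabasz (nan for k=1)
    seed: int
    n_iter: int
    converged: bool
    wave_label: str | None = None
    included_ids: list[str] | None = None

    def labels_by_id(self) -> dict[str, int]:
        if self.included_ids is None:
            raise ClusteringError("result carries no patient ids")
        return {pid: int(l) for pid, l in zip(self.included_ids, self.labels)}


def jaccard_distance(a: Sequence[float], b: Sequence[float]) -> float:
    """Generalised Jaccard distance between two nonnegative vectors.

    For binary vectors this is 1 - |A∩B|/|A∪B|.  Two all-zero vectors are
    identical patients by convention: distance 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ClusteringError(f"length mismatch: {a.shape} vs {b.shape}")
    union = np.maximum(a, b).sum()
    if union == 0:
        return 0.0
    return float(1.0 - np.minimum(a, b).sum() / union)


def _distance_matrix(X: np.ndarray, C: np.ndarray, xsums: np.ndarray) -> np.ndarray:
    """Generalised Jaccard distances from binary rows X to centroids C.

    With x binary and 0 <= c <= 1, sum_j min(x_j, c_j) = x·c and
    sum_j max(x_j, c_j) = sum(x) + sum(c) - x·c, so one matmul suffices.
    """
    inter = X @ C.T
    union = xsums[:, None] + C.sum(axis=1)[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        dist = 1.0 - inter / union
    dist[union <= 0] = 0.0
    return dist


def kmeans_jaccard(
    matrix: np.ndarray,
    k: int,
    seed: int,
    n_init: int = DEFAULT_N_INIT,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    wave_label: str | None = None,
    included_ids: Sequence[str] | None = None,
) -> ClusteringResult:
    """Best-of-`n_init` Lloyd runs under generalised Jaccard distance.

    Each restart initialises centroids at k distinct data rows.  Assignment
    ties break toward the lowest cluster index; an emptied cluster is
    re-seeded to the point currently farthest from its own centroid.  The
    returned partition minimises total within-cluster distance over the
    restarts (restart r uses the nested seed (seed, r), so enlarging n_init
    never changes earlier restarts).
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ClusteringError("matrix must be 2-dimensional")
    n = X.shape[0]
    if k < 1:
        raise ClusteringError(f"k must be >= 1, got {k}")
    uniq = np.unique(X, axis=0)
    if k > uniq.shape[0]:
        raise ClusteringError(
            f"k={k} exceeds the number of distinct patient profiles "
            f"({uniq.shape[0]})"
        )
    xsums = X.sum(axis=1)

    best: tuple[float, np.ndarray, np.ndarray, int, bool] | None = None
    for init in range(n_init):
        rng = np.random.default_rng([seed, init])
        C = uniq[rng.choice(uniq.shape[0], size=k, replace=False)].astype(float)
        labels = np.full(n, -1, dtype=int)
        converged = False
        for it in range(1, max_iter + 1):
            D = _distance_matrix(X, C, xsums)
            new_labels = D.argmin(axis=1)          # argmin -> lowest index on ties
            newC = np.empty_like(C)
            for c in range(k):
                members = new_labels == c
                if members.any():
                    newC[c] = X[members].mean(axis=0)
            # re-seed emptied clusters to the worst-fitting point
            empties = [c for c in range(k) if not (new_labels == c).any()]
            if empties:
                own = D[np.arange(n), new_labels].copy()
                for c in empties:
                    far = int(own.argmax())
                    newC[c] = X[far]
                    new_labels[far] = c
                    own[far] = -1.0
            shift = np.abs(newC - C).max()
            same = (new_labels == labels).all()
            labels, C = new_labels, newC
            if same or shift < tol:
                converged = True
                break
        D = _distance_matrix(X, C, xsums)
        inertia = float(D[np.arange(n), labels].sum())
        if best is None or inertia < best[0] - 1e-12:
            best = (inertia, labels, C, it, converged)

    inertia, labels, C, n_iter, converged = best
    ch = calinski_harabasz(X, labels) if k >= 2 else float("nan")
    return ClusteringResult(
        k=k,
        labels=labels,
        centroids=C,
        inertia=inertia,
        ch_score=ch,
        seed=seed,
        n_iter=n_iter,
        converged=converged,
        wave_label=wave_label,
        included_ids=list(included_ids) if included_ids is not None else None,
    )


def total_within_distance(X: np.ndarray, labels: np.ndarray) -> float:
    """Total generalised Jaccard distance of points to their cluster's
    column-mean centroid (the quantity the restarts are ranked by)."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    total = 0.0
    for c in np.unique(labels):
        members = X[labels == c]
        centroid = members.mean(axis=0)
        for row in members:
            total += jaccard_distance(row, centroid)
    return total


def calinski_harabasz(matrix: np.ndarray, labels: np.ndarray) -> float:
    """Caliński–Harabasz index: [tr(B)/(k-1)] / [tr(W)/(n-k)].

    Between/within dispersion is Euclidean about the column-mean centroids
    of the binary matrix (the standard definition).  Zero within-cluster
    dispersion returns +inf.
    """
    X = np.asarray(matrix, dtype=float)
    labels = np.asarray(labels)
    n = X.shape[0]
    uniq = np.unique(labels)
    k = uniq.size
    if k < 2:
        raise ClusteringError("Caliński–Harabasz requires k >= 2")
    if n < k:
        raise ClusteringError("Caliński–Harabasz requires n >= k")
    grand = X.mean(axis=0)
    tr_b = tr_w = 0.0
    for c in uniq:
        members = X[labels == c]
        centroid = members.mean(axis=0)
        tr_b += members.shape[0] * float(((centroid - grand) ** 2).sum())
        tr_w += float(((members - centroid) ** 2).sum())
    if tr_w == 0.0:
        return float("inf")   # all-singleton or duplicate-row clusters
    return (tr_b / (k - 1)) / (tr_w / (n - k))


@dataclass
class KSelectionReport:
    """Scores and validity over candidate k, plus the choice and why.

    The full curve is reported so a reviewer can override the mechanical
    choice (the study's consensus step is human)."""

    candidates: list[int]
    ch_scores: dict[int, float]
    validity: dict[int, bool]
    invalid_reasons: dict[int, str]
    results: dict[int, ClusteringResult]
    chosen_k: int
    rationale: str
    ch_tolerance: float


def select_k(
    matrix: np.ndarray,
    k_candidates: Sequence[int],
    seed: int,
    essential_rule: EssentialRule | None = None,
    ch_tolerance: float = 0.10,
    n_init: int = DEFAULT_N_INIT,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    wave_label: str | None = None,
    included_ids: Sequence[str] | None = None,
) -> KSelectionReport:
    """Pick the number of patterns: the smallest valid k whose CH score is
    within `ch_tolerance` (fractional) of the best valid CH.

    A k is valid when every cluster has at least one essential condition
    (prevalence-ratio rule); an invalid k can never be chosen.  Raises
    :class:`NoValidPartitionError` when no candidate is valid.
    """
    if not k_candidates:
        raise ClusteringError("k_candidates must be nonempty")
    if any(k < 2 for k in k_candidates):
        raise ClusteringError("all k candidates must be >= 2")
    rule = essential_rule or EssentialRule()
    X = np.asarray(matrix, dtype=float)
    ep = X.mean(axis=0)

    candidates = sorted(set(int(k) for k in k_candidates))
    ch_scores: dict[int, float] = {}
    validity: dict[int, bool] = {}
    reasons: dict[int, str] = {}
    results: dict[int, ClusteringResult] = {}
    for k in candidates:
        res = kmeans_jaccard(
            X, k, seed=seed, n_init=n_init, max_iter=max_iter, tol=tol,
            wave_label=wave_label, included_ids=included_ids,
        )
        results[k] = res
        ch_scores[k] = res.ch_score
        bare = [
            c for c in range(k)
            if not essential_conditions(X[res.labels == c].mean(axis=0), ep, rule)
        ]
        if bare:
            validity[k] = False
            reasons[k] = f"cluster(s) {bare} have no essential condition"
        else:
            validity[k] = True

    valid_ks = [k for k in candidates if validity[k]]
    if not valid_ks:
        raise NoValidPartitionError(reasons)
    best_ch = max(ch_scores[k] for k in valid_ks)
    if np.isinf(best_ch):
        eligible = [k for k in valid_ks if np.isinf(ch_scores[k])]
    else:
        eligible = [k for k in valid_ks if ch_scores[k] >= (1 - ch_tolerance) * best_ch]
    chosen = min(eligible)
    rationale = (
        f"smallest valid k with CH within {ch_tolerance:.0%} of the best "
        f"valid CH ({best_ch:.3f}); valid candidates {valid_ks}, "
        f"eligible {eligible}"
    )
    return KSelectionReport(
        candidates=candidates,
        ch_scores=ch_scores,
        validity=validity,
        invalid_reasons=reasons,
        results=results,
        chosen_k=chosen,
        rationale=rationale,
        ch_tolerance=ch_tolerance,
    )


def cluster_wave(
    wave,
    k_candidates: Sequence[int],
    seed: int,
    **kwargs,
) -> KSelectionReport:
    """Run k-selection on a :class:`~multipattern.cohort.CohortWave`."""
    return select_k(
        wave.matrix,
        k_candidates,
        seed=seed,
        wave_label=wave.wave_label,
        included_ids=wave.included_ids,
        **kwargs,
    )
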