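"""k-means clustering of van Krevelen (O/C, H/C) compositional space.

The feature space is the literal, unscaled VK plane: Euclidean distance
between (O/C, H/C) points, one unweighted point per qualifying formula
(duplicate coordinates from distinct formulas are retained, because
cluster sizes count formulas).  Nitrogen-containing and
non-monoisotopic assignments are excluded by default before clustering.

The fitting algorithm is Hartigan-Wong: after a Lloyd-style assignment
pass converges, points are transferred one at a time whenever moving a
point from its cluster L1 (size n1) to another L2 (size n2) lowers the
total within-cluster sum of squares, i.e. whenever

    n2 * d(x, c2)^2 / (n2 + 1)  <  n1 * d(x, c1)^2 / (n1 - 1).

Transfers are applied best-improvement-first (lowest point index on
ties) with incremental centroid updates, until no improving transfer
exists.  This reaches the Hartigan-Wong fixed point, which is at least
as strong as Lloyd's: every Lloyd optimum that admits an improving
single-point transfer is escaped.  A plain Lloyd variant is selectable.

Model selection combines the elbow of the within-SS curve (maximum
second difference across the candidate k values) with the requirement
that between_SS / total_SS reach a threshold (default 80 %): the chosen
k is the smallest candidate at or past the elbow whose BSS ratio meets
the threshold; when no candidate meets it, the elbow k is returned with
an explicit warning in the selection trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dataset_io import SpectrumDataset, log
from .formula_core import vk_point

__all__ = [
    "ClusterModel",
    "KSelection",
    "InfeasibleClusteringError",
    "extract_vk_points",
    "kmeans_fit",
    "select_k",
    "cluster_percentages",
    "cluster_report_frame",
]


class InfeasibleClusteringError(ValueError):
    """Requested clustering cannot be computed on the given points."""


@dataclass(frozen=True)
class ClusterModel:
    """Fitted k-means state on a fixed point set."""

    k: int
    centroids: np.ndarray  # (k, d)
    labels: np.ndarray  # (n,)
    sizes: np.ndarray  # (k,)
    wss_per_cluster: np.ndarray  # (k,)
    total_within_ss: float
    between_ss: float
    total_ss: float
    n_starts: int
    seed: int | None
    algorithm: str = "hartigan-wong"

    def __post_init__(self) -> None:
        if int(self.sizes.sum()) != len(self.labels):
            raise ValueError("cluster sizes must sum to the number of points")
        if (self.sizes <= 0).any():
            raise ValueError("every cluster must be nonempty")
        gap = abs(self.total_ss - (self.between_ss + self.total_within_ss))
        if gap > 1e-8 * max(self.total_ss, 1.0):
            raise ValueError(
                f"sum-of-squares decomposition violated: total={self.total_ss} "
                f"between={self.between_ss} within={self.total_within_ss}"
            )

    @property
    def bss_ratio(self) -> float:
        """between_SS / total_SS; 1.0 for a degenerate zero-variance set."""
        return self.between_ss / self.total_ss if self.total_ss > 0 else 1.0


@dataclass(frozen=True)
class KSelection:
    """Diagnostics of the elbow + BSS-threshold model selection."""

    k_range: tuple[int, ...]
    wss_curve: tuple[float, ...]
    bss_ratio_curve: tuple[float, ...]
    chosen_k: int
    elbow_k: int | None
    selection_rule_trace: tuple[str, ...]
    models: dict[int, ClusterModel] = field(default_factory=dict, repr=False)

    @property
    def chosen_model(self) -> ClusterModel:
        return self.models[self.chosen_k]


def extract_vk_points(
    ds: SpectrumDataset,
    exclude_nitrogen: bool = True,
    monoisotopic_only: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """(O/C, H/C) points of the qualifying assignments.

    Returns ``(points, index)`` where ``index[i]`` is the position of the
    backing assignment within ``ds.assignments``.
    """
    points, index = [], []
    n_nitrogen = n_iso = 0
    for pos, a in enumerate(ds.assignments):
        if exclude_nitrogen and a.composition.n > 0:
            n_nitrogen += 1
            continue
        if monoisotopic_only and not a.is_monoisotopic:
            n_iso += 1
            continue
        p = vk_point(a.composition)
        points.append((p.oc, p.hc))
        index.append(pos)
    log.info(
        "extract_vk_points: %d/%d points kept (%d nitrogen-excluded, %d non-monoisotopic)",
        len(points), len(ds.assignments), n_nitrogen, n_iso,
    )
    return np.asarray(points, dtype=float).reshape(len(points), 2), np.asarray(index, dtype=int)


def _assign(points: np.ndarray, centers: np.ndarray) -> np.ndarray:
    d2 = ((points[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1)


def _repair_empty(points: np.ndarray, centers: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Re-seed each empty cluster at the point farthest from its centroid."""
    k = len(centers)
    for j in range(k):
        if not (labels == j).any():
            d2 = ((points - centers[labels]) ** 2).sum(axis=1)
            far = int(d2.argmax())
            centers[j] = points[far]
            labels[far] = j
    return labels


def _lloyd(points: np.ndarray, centers: np.ndarray, max_iter: int) -> tuple[np.ndarray, np.ndarray, bool]:
    labels = _assign(points, centers)
    labels = _repair_empty(points, centers, labels)
    for _ in range(max_iter):
        for j in range(len(centers)):
            centers[j] = points[labels == j].mean(axis=0)
        new_labels = _assign(points, centers)
        new_labels = _repair_empty(points, centers, new_labels)
        if (new_labels == labels).all():
            return centers, labels, True
        labels = new_labels
    return centers, labels, False


def _hw_refine(points: np.ndarray, centers: np.ndarray, labels: np.ndarray,
               max_transfers: int) -> tuple[np.ndarray, np.ndarray, bool]:
    """Apply Hartigan-Wong single-point transfers until none improves."""
    n, k = len(points), len(centers)
    sizes = np.bincount(labels, minlength=k).astype(float)
    for j in range(k):
        centers[j] = points[labels == j].mean(axis=0)
    tol = 1e-12
    for _ in range(max_transfers):
        d2 = ((points[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        own = d2[np.arange(n), labels]
        n1 = sizes[labels]
        # a singleton may never be emptied: its removal gain is -inf
        r1 = np.where(n1 > 1, n1 * own / np.maximum(n1 - 1, 1), -np.inf)
        r2 = sizes[None, :] * d2 / (sizes[None, :] + 1.0)
        r2[np.arange(n), labels] = np.inf
        best_target = r2.argmin(axis=1)
        gain = r1 - r2[np.arange(n), best_target]
        i = int(gain.argmax())
        if not (gain[i] > tol):
            return centers, labels, True
        src, dst = labels[i], int(best_target[i])
        centers[src] = (centers[src] * sizes[src] - points[i]) / (sizes[src] - 1)
        centers[dst] = (centers[dst] * sizes[dst] + points[i]) / (sizes[dst] + 1)
        sizes[src] -= 1
        sizes[dst] += 1
        labels[i] = dst
    return centers, labels, False


def _within_ss(points: np.ndarray, centers: np.ndarray, labels: np.ndarray, k: int):
    wss = np.zeros(k)
    for j in range(k):
        member = points[labels == j]
        wss[j] = ((member - centers[j]) ** 2).sum()
    return wss


def kmeans_fit(
    points: np.ndarray,
    k: int,
    n_starts: int = 25,
    seed: int | None = None,
    max_iter: int = 100,
    algorithm: str = "hartigan-wong",
) -> ClusterModel:
    """Best-of-restarts k-means fit on a fixed point set.

    Deterministic given (point order, seed, n_starts).  Initial centroids
    of each restart are drawn uniformly without replacement from the
    distinct points.  Empty clusters arising during iteration are
    re-seeded at the point farthest from its current centroid.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or len(points) == 0:
        raise InfeasibleClusteringError("need a nonempty 2-D array of points")
    if algorithm not in ("hartigan-wong", "lloyd"):
        raise ValueError(f"unknown algorithm {algorithm!r}")
    distinct = np.unique(points, axis=0)
    if not (1 <= k <= len(distinct)):
        raise InfeasibleClusteringError(
            f"k={k} infeasible: only {len(distinct)} distinct points"
        )
    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    converged_all = True
    for _ in range(n_starts):
        init_idx = rng.choice(len(distinct), size=k, replace=False)
        centers = distinct[init_idx].copy()
        centers, labels, ok = _lloyd(points, centers, max_iter)
        if algorithm == "hartigan-wong":
            centers, labels, ok_hw = _hw_refine(points, centers, labels,
                                                max_transfers=max(100, 10 * len(points)))
            ok = ok and ok_hw
        converged_all = converged_all and ok
        twss = float(_within_ss(points, centers, labels, k).sum())
        if best is None or twss < best[0] - 1e-12:
            best = (twss, centers.copy(), labels.copy())
    if not converged_all:
        log.warning("kmeans_fit: at least one restart hit the iteration cap; best iterate kept")
    twss, centers, labels = best
    wss = _within_ss(points, centers, labels, k)
    sizes = np.bincount(labels, minlength=k)
    gmean = points.mean(axis=0)
    total_ss = float(((points - gmean) ** 2).sum())
    between_ss = float((sizes * ((centers - gmean) ** 2).sum(axis=1)).sum())
    return ClusterModel(
        k=k,
        centroids=centers,
        labels=labels,
        sizes=sizes,
        wss_per_cluster=wss,
        total_within_ss=float(wss.sum()),
        between_ss=between_ss,
        total_ss=total_ss,
        n_starts=n_starts,
        seed=seed,
        algorithm=algorithm,
    )


def select_k(
    points: np.ndarray,
    k_range: Sequence[int] = range(2, 11),
    bss_threshold: float = 0.80,
    n_starts: int = 25,
    seed: int | None = None,
    algorithm: str = "hartigan-wong",
) -> KSelection:
    """Choose k by the elbow of the within-SS curve plus a BSS threshold.

    Needs at least three candidate k values for the second-difference
    elbow to be defined.
    """
    ks = sorted(set(int(k) for k in k_range))
    if len(ks) < 3:
        raise InfeasibleClusteringError(
            "elbow undefined with fewer than 3 candidate k values"
        )
    points = np.asarray(points, dtype=float)
    n_distinct = len(np.unique(points, axis=0))
    if max(ks) > n_distinct:
        raise InfeasibleClusteringError(
            f"max(k_range)={max(ks)} exceeds the {n_distinct} distinct points"
        )
    child_seeds = (
        [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(len(ks))]
        if seed is not None
        else [None] * len(ks)
    )
    models = {
        k: kmeans_fit(points, k, n_starts=n_starts, seed=cs, algorithm=algorithm)
        for k, cs in zip(ks, child_seeds)
    }
    wss = [models[k].total_within_ss for k in ks]
    bss = [models[k].bss_ratio for k in ks]
    trace = []
    second_diff = [wss[i - 1] - 2 * wss[i] + wss[i + 1] for i in range(1, len(ks) - 1)]
    elbow_k = ks[1 + int(np.argmax(second_diff))]
    trace.append(f"elbow at k={elbow_k} (max second difference of the within-SS curve)")
    eligible = [k for k, r in zip(ks, bss) if k >= elbow_k and r >= bss_threshold]
    if eligible:
        chosen = min(eligible)
        trace.append(
            f"chose k={chosen}: smallest k >= elbow with between_SS/total_SS "
            f">= {bss_threshold:.0%} (ratio {models[chosen].bss_ratio:.3f})"
        )
    else:
        chosen = elbow_k
        trace.append(
            f"WARNING: no candidate k reaches between_SS/total_SS >= "
            f"{bss_threshold:.0%}; returning elbow k={chosen} "
            f"(ratio {models[chosen].bss_ratio:.3f})"
        )
        log.warning(trace[-1])
    return KSelection(
        k_range=tuple(ks),
        wss_curve=tuple(wss),
        bss_ratio_curve=tuple(bss),
        chosen_k=chosen,
        elbow_k=elbow_k,
        selection_rule_trace=tuple(trace),
        models=models,
    )


def cluster_percentages(model: ClusterModel) -> np.ndarray:
    """Per-cluster share of formulas, in percent (sums to 100)."""
    return 100.0 * model.sizes / model.sizes.sum()


def cluster_report_frame(model: ClusterModel):
    """Delimited-text-ready cluster report (one row per cluster)."""
    import pandas as pd

    shares = cluster_percentages(model)
    return pd.DataFrame(
        {
            "cluster": np.arange(model.k),
            "centroid_oc": model.centroids[:, 0],
            "centroid_hc": model.centroids[:, 1],
            "size": model.sizes,
            "share_pct": shares,
            "wss": model.wss_per_cluster,
        }
    )
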