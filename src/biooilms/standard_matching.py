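"""Identity assignment of cluster centroids against reference standards.

Fitted k-means centroids are pooled with the van Krevelen coordinates of
named reference compounds and compared by agglomerative hierarchical
clustering under Ward's minimum-variance criterion in its D2 form:
the Lance-Williams recurrence is run on *squared* Euclidean
dissimilarities,

    S(u, w) = ((n_i + n_w) S(i, w) + (n_j + n_w) S(j, w) - n_w S(i, j))
              / (n_i + n_j + n_w),

and merge heights are the square roots of the merged dissimilarity, so
the height of the first merge of two singletons is their plain Euclidean
distance.  Each centroid is additionally labeled with its nearest
standard by plain Euclidean distance in the VK plane (the headline
identity) and with the standards sharing its smallest mixed dendrogram
clade (supplementary context).

A fixed-region classifier ships alongside as the conventional
alternative: rectangular VK regions with explicit boundary inclusivity.
The two classification paths are deliberately independent.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .dataset_io import StandardCompound, log
from .formula_core import VKPoint
from .vk_clustering import ClusterModel

__all__ = [
    "Dendrogram",
    "IdentityAssignment",
    "VKRegion",
    "DEFAULT_REGIONS",
    "ward_linkage",
    "to_newick",
    "assign_identities",
    "fixed_region_classify",
    "load_regions_table",
    "identity_report_frame",
]


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative tree as an ordered merge list.

    Leaves are numbered ``0 .. n-1`` in input order; the i-th merge
    creates node ``n + i``.  ``merges`` rows are
    ``(node_a, node_b, height, new_node_id)``.
    """

    merges: tuple[tuple[int, int, float, int], ...]
    labels: tuple[str, ...]
    method: str = "ward.D2"

    def __post_init__(self) -> None:
        n = len(self.labels)
        if len(self.merges) != n - 1:
            raise ValueError(f"{n} leaves require exactly {n - 1} merges")
        seen: set[int] = set()
        for a, b, height, new_id in self.merges:
            if a in seen or b in seen:
                raise ValueError("a node was merged twice")
            seen.update((a, b))
            if height < -1e-12:
                raise ValueError("negative merge height")

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def leaf_sets(self) -> dict[int, frozenset[int]]:
        """Map every node id to the set of leaf indices below it."""
        n = self.n_leaves
        sets: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
        for a, b, _, new_id in self.merges:
            sets[new_id] = sets[a] | sets[b]
        return sets


@dataclass(frozen=True)
class IdentityAssignment:
    """Identity of one cluster centroid against the standards set."""

    cluster_id: int
    nearest_standard: str
    distance: float
    clade_standards: tuple[str, ...]
    tied: bool = False


@dataclass(frozen=True)
class VKRegion:
    """A rectangular van Krevelen region with explicit boundary rules."""

    name: str
    oc_min: float
    oc_max: float
    hc_min: float
    hc_max: float
    oc_min_inclusive: bool = True
    oc_max_inclusive: bool = True
    hc_min_inclusive: bool = True
    hc_max_inclusive: bool = True

    def __post_init__(self) -> None:
        if not (self.oc_min < self.oc_max and self.hc_min < self.hc_max):
            raise ValueError(f"region {self.name!r} has an empty interval")

    def contains(self, point: VKPoint) -> bool:
        lo_oc = point.oc >= self.oc_min if self.oc_min_inclusive else point.oc > self.oc_min
        hi_oc = point.oc <= self.oc_max if self.oc_max_inclusive else point.oc < self.oc_max
        lo_hc = point.hc >= self.hc_min if self.hc_min_inclusive else point.hc > self.hc_min
        hi_hc = point.hc <= self.hc_max if self.hc_max_inclusive else point.hc < self.hc_max
        return lo_oc and hi_oc and lo_hc and hi_hc


#: Shipped regions, quoted from the bio-oil classification literature:
#: zone 1 (low-oxygen saturates): 1.5 <= H/C <= 2 and 0 < O/C <= 0.3;
#: pyrolytic lignin: O/C 0.1-0.67, H/C 0.7-1.5.
DEFAULT_REGIONS: tuple[VKRegion, ...] = (
    VKRegion("zone 1", oc_min=0.0, oc_max=0.3, hc_min=1.5, hc_max=2.0,
             oc_min_inclusive=False),
    VKRegion("pyrolytic lignin-like", oc_min=0.1, oc_max=0.67, hc_min=0.7, hc_max=1.5),
)


def ward_linkage(points: np.ndarray, labels: Sequence[str]) -> Dendrogram:
    """Ward-D2 agglomerative clustering of labeled points.

    Deterministic given input order: when several pairs attain the
    minimal criterion, the lexicographically lowest index pair merges
    first.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or len(points) < 2:
        raise ValueError("need at least 2 points")
    labels = tuple(str(x) for x in labels)
    if len(labels) != len(points):
        raise ValueError("labels and points length mismatch")
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ValueError(f"duplicate labels: {dupes}")
    n = len(points)
    # squared Euclidean dissimilarities between active clusters
    diff = points[:, None, :] - points[None, :, :]
    S = (diff ** 2).sum(axis=2)
    active: dict[int, int] = {i: 1 for i in range(n)}  # node id -> size
    index: dict[int, int] = {i: i for i in range(n)}  # node id -> row in S
    # grow S lazily: keep a dense matrix over original rows, reusing row of `a`
    merges: list[tuple[int, int, float, int]] = []
    node_ids = list(range(n))
    for step in range(n - 1):
        ids = sorted(active)
        best = None
        for ii, a in enumerate(ids):
            ra = index[a]
            for b in ids[ii + 1:]:
                val = S[ra, index[b]]
                if best is None or val < best[0] - 1e-15:
                    best = (val, a, b)
        val, a, b = best
        new_id = n + step
        height = float(np.sqrt(max(val, 0.0)))
        merges.append((a, b, height, new_id))
        na, nb = active[a], active[b]
        ra, rb = index[a], index[b]
        for w in ids:
            if w in (a, b):
                continue
            nw = active[w]
            rw = index[w]
            S[ra, rw] = S[rw, ra] = (
                (na + nw) * S[ra, rw] + (nb + nw) * S[rb, rw] - nw * val
            ) / (na + nb + nw)
        del active[a], active[b], index[a], index[b]
        active[new_id] = na + nb
        index[new_id] = ra
    return Dendrogram(merges=tuple(merges), labels=labels)


_NEWICK_UNSAFE = re.compile(r"[\s()\[\]:;,']")


def _newick_label(label: str) -> str:
    if _NEWICK_UNSAFE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(tree: Dendrogram, *, precision: int = 10) -> str:
    """Serialize a dendrogram as a rooted newick string.

    Node depths are half the merge heights (so the two children of a
    height-h merge each sit h/2 below it), and branch lengths are the
    depth differences parent -> child; leaves sit at depth 0.
    """
    n = tree.n_leaves
    height: dict[int, float] = {i: 0.0 for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    for a, b, h, new_id in tree.merges:
        height[new_id] = h / 2.0
        children[new_id] = (a, b)

    def render(node: int, parent_height: float) -> str:
        bl = max(parent_height - height[node], 0.0)
        bl_txt = f"{bl:.{precision}g}"
        if node < n:
            return f"{_newick_label(tree.labels[node])}:{bl_txt}"
        a, b = children[node]
        inner = ",".join(render(c, height[node]) for c in (a, b))
        return f"({inner}):{bl_txt}"

    root = tree.merges[-1][3]
    a, b = children[root]
    inner = ",".join(render(c, height[root]) for c in (a, b))
    return f"({inner});"


def assign_identities(
    model: ClusterModel,
    standards: Sequence[StandardCompound],
    *,
    cluster_label_fmt: str = "cluster {i}",
) -> tuple[list[IdentityAssignment], Dendrogram]:
    """Label each centroid with its nearest standard and dendrogram clade.

    The centroids and standards are pooled and Ward-linked; for each
    centroid leaf the smallest clade containing at least one standard
    supplies the ``clade_standards`` context.  The headline
    ``nearest_standard`` is the plain Euclidean nearest neighbor in the
    VK plane, with lexicographic tie-breaking (ties flagged).
    """
    if len(standards) == 0:
        raise ValueError("at least one standard is required")
    names = [s.name for s in standards]
    if len(set(names)) != len(names):
        raise ValueError("duplicate standard names")
    std_points = np.array([[s.vk.oc, s.vk.hc] for s in standards], dtype=float)
    centroids = np.asarray(model.centroids, dtype=float)
    k = len(centroids)
    pooled = np.vstack([centroids, std_points])
    labels = [cluster_label_fmt.format(i=i) for i in range(k)] + names
    tree = ward_linkage(pooled, labels)
    leaf_sets = tree.leaf_sets()
    parent: dict[int, int] = {}
    for a, b, _, new_id in tree.merges:
        parent[a] = parent[b] = new_id

    results: list[IdentityAssignment] = []
    for i in range(k):
        dist = np.sqrt(((std_points - centroids[i]) ** 2).sum(axis=1))
        # quantize before comparing so float noise cannot order a true tie
        order = sorted(range(len(names)), key=lambda j: (round(float(dist[j]), 12), names[j]))
        nearest = order[0]
        tied = len(order) > 1 and abs(dist[order[1]] - dist[nearest]) <= 1e-9
        node = i
        clade: tuple[str, ...] = ()
        while node in parent:
            node = parent[node]
            members = leaf_sets[node]
            std_members = sorted(
                labels[m] for m in members if m >= k and m < tree.n_leaves
            )
            if std_members:
                clade = tuple(std_members)
                break
        results.append(
            IdentityAssignment(
                cluster_id=i,
                nearest_standard=names[nearest],
                distance=float(dist[nearest]),
                clade_standards=clade,
                tied=tied,
            )
        )
        if tied:
            log.info("cluster %d: nearest-standard tie broken lexicographically", i)
    return results, tree


def fixed_region_classify(
    point: VKPoint,
    regions: Sequence[VKRegion] = DEFAULT_REGIONS,
    *,
    priority: bool = True,
) -> str | list[str]:
    """Classify a VK point into fixed rectangular regions.

    With ``priority=True`` (default) the first matching region in the
    declared order wins and ``"unclassified"`` is returned when none
    match; with ``priority=False`` the full list of matches is returned.
    """
    matches = [r.name for r in regions if r.contains(point)]
    if not priority:
        return matches
    return matches[0] if matches else "unclassified"


def load_regions_table(path: str | Path, *, sep: str | None = None) -> list[VKRegion]:
    """Load a user region table (columns: name, oc_min, oc_max, hc_min,
    hc_max and optional *_inclusive boolean flags)."""
    import pandas as pd

    frame = pd.read_csv(path, sep=sep, engine="python", comment="#")
    required = {"name", "oc_min", "oc_max", "hc_min", "hc_max"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"region table missing columns: {sorted(missing)}")
    regions = []
    for _, row in frame.iterrows():
        kwargs = {}
        for flag in ("oc_min_inclusive", "oc_max_inclusive", "hc_min_inclusive", "hc_max_inclusive"):
            if flag in frame.columns and pd.notna(row[flag]):
                kwargs[flag] = bool(row[flag])
        regions.append(
            VKRegion(
                name=str(row["name"]),
                oc_min=float(row["oc_min"]),
                oc_max=float(row["oc_max"]),
                hc_min=float(row["hc_min"]),
                hc_max=float(row["hc_max"]),
                **kwargs,
            )
        )
    return regions


def identity_report_frame(assignments: Sequence[IdentityAssignment]):
    import pandas as pd

    return pd.DataFrame(
        {
            "cluster": [a.cluster_id for a in assignments],
            "nearest_standard": [a.nearest_standard for a in assignments],
            "distance": [a.distance for a in assignments],
            "clade_standards": ["|".join(a.clade_standards) for a in assignments],
            "tied": [a.tied for a in assignments],
        }
    )
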