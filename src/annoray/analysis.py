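"""Survey-level analyses on reprojected annotations and footprints.

Three analyses:

* **Duplicate detection** — the same organism annotated on two
  overlapping images yields two reprojected points a few centimeters
  apart.  Candidate duplicate pairs share a label, come from different
  source images and lie within a linkage radius in 3D; groups are the
  connected components of the candidate graph.  The duplicate percentage
  counts every group member beyond one representative, so two coincident
  annotations are 50% duplicated.
* **Disjoint-image selection** — footprints are projected to the
  horizontal plane and a greedy pass in acquisition order accepts an
  image only if its overlap fraction with every already selected
  footprint stays below a threshold.  An exhaustive solver (small n)
  serves as a cross-check.
* **Reprojection accuracy** — 3D Euclidean distances between reprojected
  points and reference positions, summarized by median and interquartile
  range (linear-interpolation quantiles).  The 3D distance is preferred
  to the horizontal one because on near-vertical terrain two organisms
  may be far apart along the surface yet have zero horizontal separation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from shapely.geometry import Polygon

from .engine import Footprint

__all__ = [
    "DuplicateGroup",
    "AccuracyReport",
    "DisjointSelection",
    "detect_duplicates",
    "select_disjoint",
    "exhaustive_disjoint",
    "evaluate_accuracy",
]


@dataclass(frozen=True)
class DuplicateGroup:
    """A connected component of mutually close same-label annotations."""

    label: str
    member_ids: tuple[str, ...]
    representative: str


@dataclass
class AccuracyReport:
    """Median / IQR summary of 3D reprojection errors for one site."""

    site: str
    n_pairs: int
    median_m: float
    iqr_m: float
    q1_m: float
    q3_m: float
    distances_m: np.ndarray
    quantile_method: str = "linear"

    def to_dict(self) -> dict:
        return {
            "site": self.site,
            "n_pairs": self.n_pairs,
            "median_m": self.median_m,
            "iqr_m": self.iqr_m,
            "q1_m": self.q1_m,
            "q3_m": self.q3_m,
            "quantile_method": self.quantile_method,
            "distances_m": [float(d) for d in self.distances_m],
        }


@dataclass
class DisjointSelection:
    """Result of greedy disjoint-image selection."""

    selected: list[str]
    selected_indices: list[int]
    overlap_matrix: np.ndarray  # [i, j] = area(i ∩ j) / area(i)
    skipped: list[str] = field(default_factory=list)


def detect_duplicates(
    annotations: list, radius_m: float
) -> tuple[list[DuplicateGroup], float]:
    """Group same-label cross-image reprojected points within ``radius_m``.

    ``annotations`` are point-like reprojected annotations (one 3D vertex
    each).  Returns the groups and the duplicate percentage
    ``100 * sum(group_size - 1) / n_total``.
    """
    if radius_m <= 0:
        raise ValueError(f"radius_m must be positive, got {radius_m}")
    n = len(annotations)
    if n == 0:
        return [], 0.0
    for ann in annotations:
        if ann.status != "reprojected":
            raise ValueError(
                f"annotation {ann.annotation_id} has status {ann.status!r}; "
                "duplicate detection expects reprojected points"
            )
    pos = np.array([np.asarray(a.vertices_local)[0] for a in annotations])
    labels = [a.label for a in annotations]
    images = [a.source_image for a in annotations]

    tree = cKDTree(pos)
    pairs = [
        (i, j)
        for i, j in tree.query_pairs(radius_m)
        if labels[i] == labels[j] and images[i] != images[j]
    ]
    if not pairs:
        return [], 0.0
    rows = [p[0] for p in pairs]
    cols = [p[1] for p in pairs]
    adj = coo_matrix((np.ones(len(pairs)), (rows, cols)), shape=(n, n))
    n_comp, comp = connected_components(adj, directed=False)
    groups: list[DuplicateGroup] = []
    for c in range(n_comp):
        members = np.flatnonzero(comp == c)
        if len(members) < 2:
            continue
        ids = sorted(str(annotations[i].annotation_id) for i in members)
        groups.append(
            DuplicateGroup(
                label=labels[members[0]],
                member_ids=tuple(ids),
                representative=min(ids),
            )
        )
    n_dup = sum(len(g.member_ids) - 1 for g in groups)
    return groups, 100.0 * n_dup / n


def _footprint_polygon(fp: Footprint) -> Polygon:
    """Footprint projected to the horizontal plane as a (fixed-up) polygon."""
    poly = Polygon(fp.vertices_local[:, :2])
    if not poly.is_valid:
        poly = poly.buffer(0)
    return poly


def _overlap_fraction(a: Polygon, b: Polygon) -> float:
    """Symmetric overlap: intersection area over the smaller area."""
    inter = a.intersection(b).area
    if inter == 0.0:
        return 0.0
    return inter / min(a.area, b.area)


def select_disjoint(
    footprints: list[Footprint], max_overlap_frac: float
) -> DisjointSelection:
    """Greedy disjoint-image selection in acquisition order.

    An image is accepted iff its footprint's overlap fraction with every
    already selected footprint is at most ``max_overlap_frac``.  The
    overlap fraction is symmetric (intersection area over the smaller
    footprint area) so a small footprint fully inside a large one cannot
    slip through.  Discarded footprints are skipped with a warning entry.
    Also returns the full pairwise matrix ``[i, j] = area(i∩j)/area(i)``
    over the usable footprints.
    """
    if max_overlap_frac < 0:
        raise ValueError("max_overlap_frac must be >= 0")
    usable: list[tuple[int, Footprint, Polygon]] = []
    skipped: list[str] = []
    for i, fp in enumerate(footprints):
        if fp.status == "discarded" or len(fp.vertices_local) < 3:
            skipped.append(fp.image_filename)
            continue
        usable.append((i, fp, _footprint_polygon(fp)))

    m = len(usable)
    overlap = np.zeros((m, m))
    for a in range(m):
        for b in range(m):
            if a == b:
                continue
            inter = usable[a][2].intersection(usable[b][2]).area
            overlap[a, b] = inter / usable[a][2].area if usable[a][2].area > 0 else 0.0

    selected: list[str] = []
    selected_idx: list[int] = []
    chosen: list[int] = []  # positions within `usable`
    for k, (orig_i, fp, poly) in enumerate(usable):
        ok = all(
            _overlap_fraction(poly, usable[j][2]) <= max_overlap_frac for j in chosen
        )
        if ok:
            chosen.append(k)
            selected.append(fp.image_filename)
            selected_idx.append(orig_i)
    return DisjointSelection(
        selected=selected,
        selected_indices=selected_idx,
        overlap_matrix=overlap,
        skipped=skipped,
    )


def exhaustive_disjoint(
    footprints: list[Footprint], max_overlap_frac: float
) -> list[str]:
    """Maximum admissible subset by exhaustive search (n <= 20 footprints).

    Cross-check for the greedy pass; admissibility uses the same symmetric
    overlap fraction.  Among maximum-size subsets the lexicographically
    first by index order is returned.
    """
    usable = [
        (fp, _footprint_polygon(fp))
        for fp in footprints
        if fp.status != "discarded" and len(fp.vertices_local) >= 3
    ]
    n = len(usable)
    if n > 20:
        raise ValueError(f"exhaustive search is limited to 20 footprints, got {n}")
    ok = np.ones((n, n), dtype=bool)
    for a, b in itertools.combinations(range(n), 2):
        ok[a, b] = ok[b, a] = (
            _overlap_fraction(usable[a][1], usable[b][1]) <= max_overlap_frac
        )
    best: tuple[int, ...] = ()
    for size in range(n, 0, -1):
        if best:
            break
        for combo in itertools.combinations(range(n), size):
            if all(ok[a, b] for a, b in itertools.combinations(combo, 2)):
                best = combo
                break
    return [usable[i][0].image_filename for i in best]


def evaluate_accuracy(
    pairs: list[tuple[np.ndarray, np.ndarray]] | np.ndarray, site: str = ""
) -> AccuracyReport:
    """Median and IQR of 3D Euclidean distances between paired positions.

    ``pairs`` is a sequence of (reprojected, reference) 3-vectors or an
    (n, 2, 3) array.  Quantiles use linear interpolation.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.size == 0:
        raise ValueError("evaluate_accuracy needs at least one pair")
    arr = arr.reshape(-1, 2, 3)
    d = np.linalg.norm(arr[:, 0] - arr[:, 1], axis=1)
    q1, q3 = np.quantile(d, [0.25, 0.75])
    return AccuracyReport(
        site=site,
        n_pairs=len(d),
        median_m=float(np.median(d)),
        iqr_m=float(q3 - q1),
        q1_m=float(q1),
        q3_m=float(q3),
        distances_m=d,
    )
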