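"""Synthetic benchmark data.

``make_toy`` builds the 2-D illustration dataset: four well-separated
Gaussian point clouds whose geometric structure disagrees with the
pathway structure — the points at the outer extreme of each cloud are
pathway-linked to the extremes of the *other* clouds, forming
cross-group connectivity sets.  Euclidean clustering recovers the
Gaussians; connectivity-driven clustering (alpha = 1) recovers the
connectivity sets instead, which makes the dataset a sharp probe of how
alpha trades the two structures off.

``make_annotated_mixture`` builds a Gaussian-mixture expression matrix
with an exact fraction of patterns carrying pathway annotations,
mirroring real integrated datasets where only ~10% of genes map to
metabolic pathways; it exercises the unannotated-pattern code paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import PathwayAnnotation, build_rho
from .containers import ConnectivityMatrix, ExpressionMatrix

__all__ = ["ToySpec", "make_toy", "make_annotated_mixture"]


def _default_means() -> list[tuple[float, ...]]:
    # square of side 4, sd 0.5: clouds separated by ~8 sd
    return [(-2.0, -2.0), (2.0, -2.0), (-2.0, 2.0), (2.0, 2.0)]


@dataclass
class ToySpec:
    """Parameters of the toy dataset.

    ``n_linked_per_group`` points from each Gaussian join *each* of the
    ``n_groups`` cross-group connectivity sets, so every set has
    ``n_groups * n_linked_per_group`` members spanning all Gaussians.
    ``link_strength`` is the shared-pathway count between any two members
    of the same set (and the number of pathways each member carries).
    """

    n_groups: int = 4
    n_per_group: int = 100
    dims: int = 2
    group_means: list[tuple[float, ...]] = field(default_factory=_default_means)
    group_sd: float = 0.5
    n_linked_per_group: int = 5
    link_strength: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 1 or self.n_per_group < 1 or self.dims < 1:
            raise ValueError("n_groups, n_per_group and dims must be positive")
        if len(self.group_means) != self.n_groups:
            raise ValueError("need one mean per group")
        if any(len(m) != self.dims for m in self.group_means):
            raise ValueError("group means must have `dims` coordinates")
        if len({tuple(m) for m in self.group_means}) != self.n_groups:
            raise ValueError("group means must be pairwise distinct")
        if self.n_linked_per_group < 0:
            raise ValueError("n_linked_per_group must be >= 0")
        if self.n_groups * self.n_linked_per_group > self.n_per_group:
            raise ValueError(
                "n_groups * n_linked_per_group exceeds points per group")
        if self.link_strength < 1:
            raise ValueError("link_strength must be a positive integer")
        if self.group_sd <= 0:
            raise ValueError("group_sd must be positive")


def make_toy(spec: ToySpec | None = None):
    """Generate the toy dataset.

    Returns
    -------
    expr : ExpressionMatrix
        ``n_groups * n_per_group`` points in ``dims`` dimensions; pattern
        IDs ``g<group>p<index>``.
    conn : ConnectivityMatrix
        link_strength within each connectivity set, 0 elsewhere
        off-diagonal (built from an explicit pathway annotation so the
        generator and the annotation loader stay consistent).
    labels : pandas.DataFrame
        Per pattern: ``gaussian`` group index and ``connectivity_set``
        index (-1 for unlinked points).
    """
    if spec is None:
        spec = ToySpec()
    rng = np.random.default_rng(spec.seed)
    means = np.asarray(spec.group_means, dtype=float)
    pts = []
    gauss = []
    ids = []
    for g in range(spec.n_groups):
        pts.append(means[g] + rng.normal(0.0, spec.group_sd,
                                         size=(spec.n_per_group, spec.dims)))
        gauss.extend([g] * spec.n_per_group)
        ids.extend(f"g{g}p{i}" for i in range(spec.n_per_group))
    values = np.vstack(pts)
    gauss = np.asarray(gauss)

    # cross-group connectivity sets: from each Gaussian, the points most
    # extreme along the outward direction (away from the global centroid)
    # are split, in extremity order, among the n_groups sets
    centroid = values.mean(axis=0)
    conn_set = np.full(values.shape[0], -1, dtype=int)
    n_take = spec.n_groups * spec.n_linked_per_group
    for g in range(spec.n_groups):
        members = np.flatnonzero(gauss == g)
        direction = means[g] - centroid
        norm = np.linalg.norm(direction)
        direction = direction / norm if norm > 0 else np.ones(spec.dims)
        score = (values[members] - centroid) @ direction
        order = members[np.argsort(-score, kind="stable")]
        for rank, pt in enumerate(order[:n_take]):
            conn_set[pt] = rank // spec.n_linked_per_group

    entries = set()
    for i, s in enumerate(conn_set):
        if s >= 0:
            for p in range(spec.link_strength):
                entries.add((ids[i], f"toy{s:02d}_{p:02d}"))
    ann = PathwayAnnotation(entries)
    conn = build_rho(ann, ids) if entries else ConnectivityMatrix(
        ids, np.zeros((len(ids), len(ids)), dtype=np.int64))

    expr = ExpressionMatrix(ids, values,
                            [f"cond{j}" for j in range(spec.dims)])
    labels = pd.DataFrame({"pattern_id": ids, "gaussian": gauss,
                           "connectivity_set": conn_set}).set_index("pattern_id")
    return expr, conn, labels


def make_annotated_mixture(n_patterns: int, annotated_fraction: float,
                           n_conditions: int = 6, n_components: int = 3,
                           n_pathways: int = 20,
                           max_pathways_per_pattern: int = 3,
                           seed: int = 0):
    """Gaussian-mixture expression data with a partially annotated
    pathway table.

    Exactly ``round(annotated_fraction * n_patterns)`` patterns receive
    1..max_pathways_per_pattern random pathway memberships; the rest are
    unannotated.
    """
    if not 0.0 <= annotated_fraction <= 1.0:
        raise ValueError("annotated_fraction must be in [0, 1]")
    if n_patterns < 1:
        raise ValueError("n_patterns must be positive")
    rng = np.random.default_rng(seed)
    comp = rng.integers(0, n_components, size=n_patterns)
    centers = rng.normal(0.0, 3.0, size=(n_components, n_conditions))
    values = centers[comp] + rng.normal(0.0, 1.0,
                                        size=(n_patterns, n_conditions))
    ids = [f"pat{i:05d}" for i in range(n_patterns)]
    expr = ExpressionMatrix(ids, values)

    n_annot = int(round(annotated_fraction * n_patterns))
    chosen = rng.choice(n_patterns, size=n_annot, replace=False)
    entries = set()
    for i in chosen:
        k = int(rng.integers(1, max_pathways_per_pattern + 1))
        for w in rng.choice(n_pathways, size=k, replace=False):
            entries.add((ids[i], f"ko{10000 + int(w)}"))
    return expr, PathwayAnnotation(entries)
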