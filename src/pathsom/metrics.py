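"""Cluster validation measures.

Six measures qualify a map partition: four classical data-mining indices
(mean compactness C, mean centroid separation S, Davies-Bouldin DB and
Dunn D) plus two that read the pathway-connectivity matrix — the
biological internal connectivity P (negative log of the mean ratio of
within-cluster shared pathways to all shared pathways reachable from the
cluster) and the composite G, the sum of an occupancy-flatness term, a
sign-inverted profile-coherence term and P.

Cluster centroids are always the SOM prototype vectors w_m, matching how
the indices are defined for map partitions; member means are never
recomputed.  Lower is better for C, DB, P and G; higher for S and D.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist
from scipy.stats import f_oneway

from .containers import ConnectivityMatrix, ExpressionMatrix, Partition
from .som import PathwaySOM, SomConfig, SomModel

__all__ = [
    "ValidationReport",
    "compactness",
    "separation",
    "davies_bouldin",
    "dunn",
    "bio_connectivity",
    "flatness",
    "coherence",
    "gmlc",
    "validation_report",
    "resampling_significance",
]


def _cluster_scatters(data: ExpressionMatrix, model: SomModel,
                      partition: Partition):
    """Per non-empty cluster: (unit index, mean member->prototype distance)."""
    units = partition.nonempty_units()
    if units.size == 0:
        raise ValueError("partition has no non-empty clusters")
    scatters = []
    for m in units:
        members = partition.labels == m
        d = np.linalg.norm(data.values[members] - model.weights[m], axis=1)
        scatters.append(d.mean())
    return units, np.asarray(scatters)


def compactness(data: ExpressionMatrix, model: SomModel,
                partition: Partition) -> float:
    """Mean over non-empty clusters of the mean member-to-prototype
    Euclidean distance; 0 means every member sits on its prototype."""
    _, scatters = _cluster_scatters(data, model, partition)
    return float(scatters.mean())


def separation(model: SomModel, partition: Partition) -> float:
    """Mean pairwise Euclidean distance among non-empty clusters'
    prototypes: 2/(k^2 - k) * sum_{i<j} ||w_i - w_j||."""
    units = partition.nonempty_units()
    k = units.size
    if k < 2:
        raise ValueError("separation needs at least 2 non-empty clusters")
    return float(pdist(model.weights[units]).sum() * 2.0 / (k * k - k))


def davies_bouldin(data: ExpressionMatrix, model: SomModel,
                   partition: Partition) -> float:
    """Davies-Bouldin index over non-empty clusters with prototype
    centroids: (1/k) sum_i max_{j!=i} (C_i + C_j) / ||w_i - w_j||."""
    units, scatters = _cluster_scatters(data, model, partition)
    k = units.size
    if k < 2:
        raise ValueError("Davies-Bouldin needs at least 2 non-empty clusters")
    W = model.weights[units]
    D = cdist(W, W)
    if np.any(D[~np.eye(k, dtype=bool)] == 0):
        raise ValueError("coincident cluster centroids: DB undefined")
    ratios = (scatters[:, None] + scatters[None, :]) / np.where(D > 0, D, np.inf)
    np.fill_diagonal(ratios, -np.inf)
    return float(ratios.max(axis=1).mean())


def dunn(data: ExpressionMatrix, partition: Partition) -> float:
    """Dunn index: minimum single-linkage inter-cluster distance divided
    by the maximum cluster diameter (singletons have diameter 0)."""
    units = partition.nonempty_units()
    if units.size < 2:
        raise ValueError("Dunn needs at least 2 non-empty clusters")
    groups = [data.values[partition.labels == m] for m in units]
    max_diam = 0.0
    for g in groups:
        if g.shape[0] >= 2:
            max_diam = max(max_diam, float(pdist(g).max()))
    if max_diam == 0:
        raise ValueError("all clusters have zero diameter: Dunn undefined")
    min_inter = np.inf
    for a in range(len(groups)):
        for b in range(a + 1, len(groups)):
            min_inter = min(min_inter, float(cdist(groups[a], groups[b]).min()))
    return min_inter / max_diam


def bio_connectivity(partition: Partition, conn: ConnectivityMatrix,
                     log_base: float = 10.0) -> float:
    """Biological internal connectivity P of a partition.

    For each cluster m, ``p_m = 1 + sum over ordered pairs (i != j) inside
    the cluster of rho_ij`` and ``p_m* = 1 + sum over members i of rho_ij
    to every other pattern j in the whole dataset``; the index is
    ``-log((1/k) * sum_m p_m / p_m*)`` over the k non-empty clusters that
    contain at least one connected (nonzero rho row) pattern.  Each ratio
    is at most 1, so P >= 0, and P = 0 when every cluster already holds
    all the connections its members have (e.g. the whole dataset in one
    cluster, or an entirely zero rho).
    """
    if len(partition.pattern_ids) == 0:
        raise ValueError("empty partition")
    conn = conn.reindex(partition.pattern_ids)
    rho0 = conn.off_diagonal()
    row_tot = rho0.sum(axis=1)
    annotated = row_tot > 0
    ratios = []
    for m in partition.nonempty_units():
        members = partition.labels == m
        if not annotated[members].any():
            continue
        p_m = 1.0 + rho0[np.ix_(members, members)].sum()   # ordered pairs
        p_star = 1.0 + row_tot[members].sum()
        ratios.append(p_m / p_star)
    if not ratios:
        # rho entirely zero: every ratio is trivially 1
        return 0.0
    mean_ratio = float(np.mean(ratios))
    return float(-np.log(mean_ratio) / np.log(log_base)) + 0.0


def flatness(partition: Partition) -> float:
    """Occupancy-flatness term of G: 1 - H/H_max with H the Shannon entropy
    of the cluster-size distribution over non-empty clusters. 0 is a
    perfectly flat occupancy; 1 is maximal concentration.  A single
    non-empty cluster is returned as 0 (degenerate: no distribution to
    flatten)."""
    sizes = partition.sizes()
    sizes = sizes[sizes > 0]
    k = sizes.size
    if k == 0:
        raise ValueError("partition has no non-empty clusters")
    if k == 1:
        return 0.0
    p = sizes / sizes.sum()
    h = float(-(p * np.log(p)).sum())
    return 1.0 - h / np.log(k)


def coherence(data: ExpressionMatrix, model: SomModel,
              partition: Partition) -> float:
    """Profile-coherence term of G: mean over members of the Pearson
    correlation between each member's profile and its cluster prototype
    (0 where the correlation is undefined, e.g. constant profiles).
    Enters G sign-inverted, so 1 (perfect coherence) is best."""
    vals = data.values
    cors = np.zeros(vals.shape[0])
    for m in partition.nonempty_units():
        members = np.flatnonzero(partition.labels == m)
        w = model.weights[m]
        wc = w - w.mean()
        wn = np.linalg.norm(wc)
        if wn == 0:
            continue
        X = vals[members] - vals[members].mean(axis=1, keepdims=True)
        xn = np.linalg.norm(X, axis=1)
        ok = xn > 0
        cors[members[ok]] = (X[ok] @ wc) / (xn[ok] * wn)
    return float(cors.mean())


def gmlc(data: ExpressionMatrix, model: SomModel, partition: Partition,
         conn: ConnectivityMatrix, log_base: float = 10.0) -> float:
    """Composite validity measure G = flatness + (-coherence) + P.

    Each component is isolated behind its own function so any one can be
    re-based or corrected independently; G is exactly their sum.
    """
    return (flatness(partition)
            - coherence(data, model, partition)
            + bio_connectivity(partition, conn, log_base=log_base))


@dataclass
class ValidationReport:
    """Named metric values for one partition (Table-style row order:
    C, S, DB, D, P, G)."""

    compactness: float
    separation: float
    davies_bouldin: float
    dunn: float
    bio_connectivity: float
    gmlc: float
    k_effective: int

    _ORDER = ("compactness", "separation", "davies_bouldin", "dunn",
              "bio_connectivity", "gmlc")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s

    def to_series(self) -> pd.Series:
        return pd.Series({k: getattr(self, k) for k in self._ORDER})

    def to_tsv(self, path=None) -> str:
        header = "\t".join(self._ORDER + ("k_effective",))
        row = "\t".join(f"{getattr(self, k):.6g}" for k in self._ORDER)
        s = f"{header}\n{row}\t{self.k_effective}\n"
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    def to_text(self) -> str:
        labels = {
            "compactness": "compactness C (lower better)",
            "separation": "separation S (higher better)",
            "davies_bouldin": "Davies-Bouldin DB (lower better)",
            "dunn": "Dunn D (higher better)",
            "bio_connectivity": "bio connectivity P (lower better)",
            "gmlc": "GMLC G (lower better)",
        }
        lines = [f"{labels[k]:<36s} {getattr(self, k):>10.4f}"
                 for k in self._ORDER]
        lines.append(f"{'non-empty clusters k':<36s} {self.k_effective:>10d}")
        return "\n".join(lines)


def validation_report(data: ExpressionMatrix, model: SomModel,
                      partition: Partition,
                      conn: ConnectivityMatrix | None,
                      log_base: float = 10.0) -> ValidationReport:
    """All six measures for one (data, model, partition, rho) quadruple.

    Without a connectivity matrix the two biological measures use an
    all-zero rho (P = 0 and G reduces to flatness - coherence).
    """
    if conn is None:
        conn = ConnectivityMatrix(
            list(partition.pattern_ids),
            np.zeros((len(partition.pattern_ids),) * 2, dtype=int))
    return ValidationReport(
        compactness=compactness(data, model, partition),
        separation=separation(model, partition),
        davies_bouldin=davies_bouldin(data, model, partition),
        dunn=dunn(data, partition),
        bio_connectivity=bio_connectivity(partition, conn, log_base=log_base),
        gmlc=gmlc(data, model, partition, conn, log_base=log_base),
        k_effective=int(partition.nonempty_units().size),
    )


def resampling_significance(data: ExpressionMatrix,
                            conn: ConnectivityMatrix,
                            configs: list[SomConfig],
                            n_resamples: int = 100,
                            keep_fraction: float = 0.9,
                            seed: int = 0,
                            log_base: float = 10.0):
    """Resampling test of whether training configurations differ in the
    biological connectivity of the partitions they produce.

    For each resample a ``keep_fraction`` subset of patterns is drawn
    without replacement; every configuration is trained on the same
    subset (fresh seed per resample) and its partition's P is recorded.
    A one-way ANOVA across configurations tests the null hypothesis that
    the methods do not differ in P.

    Returns
    -------
    samples : pandas.DataFrame
        n_resamples x len(configs) table of P values; columns are
        ``alpha=<value>`` labels (suffixed when duplicated).
    p_value : float
        One-way ANOVA p-value across the configuration columns.
    """
    if n_resamples < 2:
        raise ValueError("need at least 2 resamples")
    if not 0.0 < keep_fraction <= 1.0:
        raise ValueError("keep_fraction must be in (0, 1]")
    if not configs:
        raise ValueError("need at least one configuration")
    n = data.n_patterns
    n_keep = int(round(keep_fraction * n))
    if n_keep < 2:
        raise ValueError(
            f"resample of {n_keep} patterns is degenerate (n={n}, "
            f"keep_fraction={keep_fraction})")
    rng = np.random.default_rng(seed)
    cols = []
    for c in configs:
        base = f"alpha={c.alpha:g}"
        name = base
        i = 2
        while name in cols:
            name = f"{base}#{i}"
            i += 1
        cols.append(name)
    out = np.empty((n_resamples, len(configs)))
    for r in range(n_resamples):
        idx = np.sort(rng.choice(n, size=n_keep, replace=False))
        sub = ExpressionMatrix(
            [data.pattern_ids[i] for i in idx], data.values[idx],
            list(data.condition_names))
        sub_conn = conn.reindex(sub.pattern_ids)
        for j, cfg in enumerate(configs):
            # independent seed per (resample, config): duplicated configs
            # then yield iid samples from the same distribution
            fit_seed = int(rng.integers(0, 2**31 - 1))
            res = PathwaySOM(sub, sub_conn, config=cfg).fit(seed=fit_seed)
            out[r, j] = bio_connectivity(res.partition, sub_conn,
                                         log_base=log_base)
    samples = pd.DataFrame(out, columns=cols)
    if np.all(out == out.flat[0]):
        # constant samples: no variance anywhere, no evidence against H0
        return samples, 1.0
    _, p_value = f_oneway(*(out[:, j] for j in range(len(configs))))
    return samples, float(p_value)
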