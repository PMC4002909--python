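"""Pathway-constrained self-organizing map training.

The map is a rows x cols grid of prototype vectors trained by online
competitive learning.  During training the distance between a pattern
``x_l`` and a unit prototype ``w_m`` is the weighted sum

    d_lm = (1 - alpha) * eps_lm + alpha * b_lm

where ``eps_lm = ||x_l - w_m||_2`` and ``b_lm`` is a biological term
measuring how the average number of shared metabolic pathways inside the
unit's current cluster would change if the pattern joined it.  ``alpha``
in [0, 1] balances expression similarity against pathway connectivity:
``alpha = 0`` is the standard Euclidean SOM, ``alpha = 1`` clusters by
pathway connections alone.

The biological term for unit m with member set Omega is

    b_lm = (pi_out - pi_in) / max(pi_out, pi_in)

with ``pi_out`` the mean shared-pathway count over unordered pairs within
Omega \\ {l} and ``pi_in`` the mean over unordered pairs within
Omega U {l}; means over fewer than two members are 0, and 0/0 is 0.
Negative b means joining would raise the cluster's average connectivity
(attraction); b is always in [-1, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .containers import ConnectivityMatrix, ExpressionMatrix, Partition
from . import _kernels

__all__ = [
    "SomConfig",
    "SomModel",
    "PathwaySOM",
    "SOMResults",
    "neighborhood",
    "radius_schedule",
    "biological_term",
    "bio_term_matrix",
    "combined_distance",
    "project",
]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class SomConfig:
    """Training hyper-parameters.

    ``alpha`` is the regularization weight of the biological term; the
    learning rate decays linearly from ``learning_rate_start`` to
    ``learning_rate_end`` over ``epochs``.  ``init_scheme`` is
    ``"random-uniform"`` (seeded uniform within each dimension's data
    range) or ``"pca-grid"`` (deterministic grid spanning the first two
    principal components).  ``rescale_epsilon`` divides the Euclidean term
    by the dataset's maximum pairwise distance so both terms live on a
    comparable scale (off by default: the combined distance is used on the
    terms' native scales).
    """

    rows: int = 6
    cols: int = 6
    alpha: float = 0.0
    epochs: int = 200
    learning_rate_start: float = 0.5
    learning_rate_end: float = 0.01
    seed: int = 0
    init_scheme: str = "random-uniform"
    rescale_epsilon: bool = False
    membership_refresh: str = "per-epoch"

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid dimensions must be positive")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.epochs < 1:
            raise ValueError("epochs must be positive")
        if not self.learning_rate_start > self.learning_rate_end >= 0:
            raise ValueError(
                "need learning_rate_start > learning_rate_end >= 0")
        if self.init_scheme not in ("random-uniform", "pca-grid"):
            raise ValueError(f"unknown init_scheme {self.init_scheme!r}")
        if self.membership_refresh not in ("online", "per-epoch"):
            raise ValueError(
                "membership_refresh must be 'online' or 'per-epoch'")

    @property
    def n_units(self) -> int:
        return self.rows * self.cols


def neighborhood(winner: int, radius: int, rows: int, cols: int) -> set[int]:
    """Square (Chebyshev) neighborhood of a unit, clipped at grid edges.

    Radius 0 is the winner alone; radius 1 on an interior unit covers the
    winner plus its 8 touching neighbours.
    """
    if not 0 <= winner < rows * cols:
        raise ValueError(f"winner {winner} off a {rows}x{cols} grid")
    if radius < 0:
        raise ValueError("radius must be non-negative")
    br, bc = divmod(winner, cols)
    out = set()
    for r in range(max(0, br - radius), min(rows, br + radius + 1)):
        for c in range(max(0, bc - radius), min(cols, bc + radius + 1)):
            out.add(r * cols + c)
    return out


def radius_schedule(epoch: int, total_epochs: int, rows: int, cols: int) -> int:
    """Neighborhood radius at a given epoch.

    Starts at round(max(rows, cols) / 4) (round half up) and shrinks
    linearly to 0 at the final epoch, after which only the winner moves.
    """
    if not 0 <= epoch < total_epochs:
        raise ValueError(f"epoch {epoch} outside [0, {total_epochs})")
    r0 = _round_half_up(max(rows, cols) / 4.0)
    if total_epochs == 1:
        return 0
    frac = 1.0 - epoch / (total_epochs - 1)
    return _round_half_up(r0 * frac)


def _pair_mean(total: float, n: int) -> float:
    """Mean over the n*(n-1)/2 unordered pairs; 0 when fewer than 2 members."""
    pairs = n * (n - 1) // 2
    return total / pairs if pairs > 0 else 0.0


def biological_term(pattern_id: str, members: set[str],
                    conn: ConnectivityMatrix) -> float:
    """Biological contribution b of a pattern to a cluster with member set
    ``members`` (which may or may not already contain the pattern).

    Returns (pi_out - pi_in) / max(pi_out, pi_in) in [-1, 1]; 0 when both
    averages are 0.
    """
    pos = {p: i for i, p in enumerate(conn.pattern_ids)}
    try:
        li = pos[pattern_id]
        midx = [pos[p] for p in members]
    except KeyError as exc:
        raise KeyError(f"pattern not covered by connectivity matrix: {exc}")
    rho0 = conn.off_diagonal()
    out_idx = [i for i in midx if i != li]
    in_idx = out_idx + [li]

    def pair_sum(idx: list[int]) -> float:
        if len(idx) < 2:
            return 0.0
        sub = rho0[np.ix_(idx, idx)]
        return float(sub.sum()) / 2.0  # unordered pairs

    pi_out = _pair_mean(pair_sum(out_idx), len(out_idx))
    pi_in = _pair_mean(pair_sum(in_idx), len(in_idx))
    denom = max(pi_out, pi_in)
    return (pi_out - pi_in) / denom if denom > 0 else 0.0


def bio_term_matrix(rho0: np.ndarray, labels: np.ndarray,
                    n_units: int) -> np.ndarray:
    """Vectorized b for every (pattern, unit) pair given a membership snapshot.

    ``rho0`` is the connectivity matrix with the diagonal zeroed, aligned
    with the pattern order of ``labels``.  Agrees exactly with
    :func:`biological_term` evaluated per pair.
    """
    n = labels.shape[0]
    M = np.zeros((n, n_units))
    M[np.arange(n), labels] = 1.0
    R = rho0 @ M                       # R[l, m] = sum of rho over members of m
    n_m = M.sum(axis=0)
    S = 0.5 * (M * R).sum(axis=0)      # unordered-pair sum within each unit
    member = M.astype(bool)

    n_out = np.where(member, n_m - 1, n_m)
    s_out = np.where(member, S - R, S)
    n_in = np.where(member, n_m, n_m + 1)
    s_in = np.where(member, S, S + R)

    def mean(s, nn):
        pairs = nn * (nn - 1) / 2.0
        return np.divide(s, pairs, out=np.zeros_like(s), where=pairs > 0)

    pi_out = mean(s_out, n_out)
    pi_in = mean(s_in, n_in)
    denom = np.maximum(pi_out, pi_in)
    return np.divide(pi_out - pi_in, denom,
                     out=np.zeros_like(denom), where=denom > 0)


def combined_distance(epsilon: float, bio: float, alpha: float) -> float:
    """Weighted training distance (1 - alpha) * epsilon + alpha * bio."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    return (1.0 - alpha) * epsilon + alpha * bio


@dataclass
class SomModel:
    """Trained map state: configuration plus prototype vectors."""

    config: SomConfig
    weights: np.ndarray
    trained_epochs: int = 0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape[0] != self.config.n_units:
            raise ValueError("weights row count must equal rows * cols")


def _init_weights(values: np.ndarray, config: SomConfig,
                  rng: np.random.Generator) -> np.ndarray:
    lo = values.min(axis=0)
    hi = values.max(axis=0)
    if config.init_scheme == "random-uniform":
        span = np.where(hi > lo, hi - lo, 1.0)
        w = lo + rng.random((config.n_units, values.shape[1])) * span
        return np.where((hi > lo)[None, :], w, lo[None, :])
    # pca-grid: deterministic lattice spanning the first two components
    centred = values - values.mean(axis=0)
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    d = values.shape[1]
    scale = s / max(1, math.sqrt(values.shape[0] - 1))
    ax0 = vt[0] * (scale[0] if scale.size > 0 else 1.0)
    ax1 = vt[1] * scale[1] if d > 1 and vt.shape[0] > 1 else np.zeros(d)
    r_pos = (np.linspace(-1, 1, config.rows) if config.rows > 1
             else np.zeros(1))
    c_pos = (np.linspace(-1, 1, config.cols) if config.cols > 1
             else np.zeros(1))
    w = np.empty((config.n_units, d))
    for r in range(config.rows):
        for c in range(config.cols):
            w[r * config.cols + c] = (values.mean(axis=0)
                                      + c_pos[c] * ax0 + r_pos[r] * ax1)
    return w


def _max_pairwise_distance(values: np.ndarray) -> float:
    from scipy.spatial.distance import pdist
    if values.shape[0] < 2:
        return 1.0
    d = pdist(values).max()
    return float(d) if d > 0 else 1.0


class PathwaySOM:
    """Self-organizing map with a pathway-connectivity distance term.

    Parameters
    ----------
    data
        :class:`ExpressionMatrix` (or a patterns x conditions DataFrame
        with pattern IDs in the index).
    connectivity
        :class:`ConnectivityMatrix` covering at least the data's patterns.
        May be omitted when ``alpha == 0`` (standard SOM).
    **config
        Any :class:`SomConfig` field (``rows``, ``cols``, ``alpha``,
        ``epochs``, ...).

    Examples
    --------
    >>> model = PathwaySOM(expr, conn, rows=6, cols=6, alpha=0.5)
    >>> res = model.fit(seed=7)
    >>> res.validate().bio_connectivity
    """

    def __init__(self, data, connectivity: ConnectivityMatrix | None = None,
                 config: SomConfig | None = None, **kwargs):
        if isinstance(data, pd.DataFrame):
            data = ExpressionMatrix.from_frame(data)
        if not isinstance(data, ExpressionMatrix):
            raise TypeError("data must be an ExpressionMatrix or DataFrame")
        self.data = data
        if config is None:
            config = SomConfig(**kwargs)
        elif kwargs:
            from dataclasses import replace
            config = replace(config, **kwargs)
        self.config = config
        if connectivity is not None:
            missing = set(data.pattern_ids) - set(connectivity.pattern_ids)
            if missing:
                raise ValueError(
                    f"{len(missing)} data patterns missing from connectivity "
                    f"matrix, e.g. {sorted(missing)[:3]}")
            connectivity = connectivity.reindex(data.pattern_ids)
        elif self.config.alpha > 0:
            raise ValueError("alpha > 0 requires a connectivity matrix")
        self.connectivity = connectivity

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       connectivity: ConnectivityMatrix | None = None,
                       **config) -> "PathwaySOM":
        return cls(ExpressionMatrix.from_frame(df), connectivity, **config)

    # ------------------------------------------------------------------
    def fit(self, seed: int | None = None, use_bio: bool = True) -> "SOMResults":
        """Train the map and return a :class:`SOMResults`.

        ``use_bio=False`` runs the standard-SOM code path (the biological
        machinery is never touched); with ``alpha == 0`` both paths are
        bit-identical, which is the package's internal consistency check.
        """
        cfg = self.config
        if seed is None:
            seed = cfg.seed
        rng = np.random.default_rng(seed)
        values = np.ascontiguousarray(self.data.values, dtype=np.float64)
        n, d = values.shape
        k = cfg.n_units

        weights = np.ascontiguousarray(_init_weights(values, cfg, rng))
        eps_scale = (1.0 / _max_pairwise_distance(values)
                     if cfg.rescale_epsilon else 1.0)
        if eps_scale != 1.0:
            # scaling the Euclidean term = training in rescaled coordinates
            values = values * eps_scale
            weights = weights * eps_scale

        bio_active = use_bio and cfg.alpha > 0 and self.connectivity is not None
        rho0 = (np.ascontiguousarray(self.connectivity.off_diagonal())
                if bio_active else None)
        zero_B = np.zeros((n, k))

        online = bio_active and cfg.membership_refresh == "online"
        labels: np.ndarray | None = None
        counts = S = R = None
        log_rows = []
        for epoch in range(cfg.epochs):
            radius = radius_schedule(epoch, cfg.epochs, cfg.rows, cfg.cols)
            if cfg.epochs == 1:
                lr = cfg.learning_rate_start
            else:
                lr = (cfg.learning_rate_start
                      + (cfg.learning_rate_end - cfg.learning_rate_start)
                      * epoch / (cfg.epochs - 1))
            order = rng.permutation(n)
            if labels is None or not bio_active:
                # epoch 0 has no membership snapshot yet: Euclidean only
                _kernels.run_epoch(values, weights, zero_B, order, 0.0, lr,
                                   radius, cfg.rows, cfg.cols)
                labels, qe = _kernels.assign_all(values, weights, zero_B, 0.0)
                labels = np.asarray(labels)
            elif online:
                if counts is None:
                    # seed the live aggregates from the Euclidean epoch
                    M = np.zeros((n, k))
                    M[np.arange(n), labels] = 1.0
                    R = np.ascontiguousarray(rho0 @ M)
                    counts = M.sum(axis=0).astype(np.int64)
                    S = 0.5 * (M * R).sum(axis=0)
                qe = _kernels.run_epoch_online(
                    values, weights, rho0, labels, counts, S, R, order,
                    cfg.alpha, lr, radius, cfg.rows, cfg.cols)
            else:
                B = np.ascontiguousarray(bio_term_matrix(rho0, labels, k))
                _kernels.run_epoch(values, weights, B, order, cfg.alpha, lr,
                                   radius, cfg.rows, cfg.cols)
                labels, qe = _kernels.assign_all(values, weights, B,
                                                 cfg.alpha)
                labels = np.asarray(labels)
            log_rows.append({"epoch": epoch, "radius": radius,
                             "learning_rate": lr,
                             "quantization_error": float(qe)})

        # final projection at the model's alpha using the last snapshot
        if bio_active:
            B = np.ascontiguousarray(bio_term_matrix(rho0, labels, k))
            final_labels, final_qe = _kernels.assign_all(values, weights, B,
                                                         cfg.alpha)
        else:
            final_labels, final_qe = _kernels.assign_all(values, weights,
                                                         zero_B, 0.0)

        if eps_scale != 1.0:
            weights = weights / eps_scale

        model = SomModel(config=cfg, weights=weights,
                         trained_epochs=cfg.epochs)
        partition = Partition(list(self.data.pattern_ids),
                              np.asarray(final_labels), k)
        log = pd.DataFrame(log_rows)
        return SOMResults(self, model, partition, log, seed=seed,
                          final_qe=float(final_qe), used_bio=bio_active)


def project(data: ExpressionMatrix, model: SomModel,
            connectivity: ConnectivityMatrix | None,
            members_snapshot: Partition | None,
            use_bio: bool = True) -> Partition:
    """Assign patterns to units by minimum combined distance.

    Uses the model's alpha and, when ``use_bio``, the biological term
    computed from ``members_snapshot`` (the final training memberships);
    with ``alpha == 0`` or ``use_bio=False`` this is plain
    nearest-prototype Euclidean assignment.  Ties go to the lowest unit
    index.
    """
    values = np.ascontiguousarray(data.values, dtype=np.float64)
    if values.shape[1] != model.weights.shape[1]:
        raise ValueError(
            f"data has {values.shape[1]} conditions but model expects "
            f"{model.weights.shape[1]}")
    k = model.config.n_units
    alpha = model.config.alpha
    if use_bio and alpha > 0:
        if connectivity is None or members_snapshot is None:
            raise ValueError("alpha > 0 projection needs connectivity and a "
                             "membership snapshot")
        conn = connectivity.reindex(data.pattern_ids)
        assign = members_snapshot.assignment
        try:
            snap_labels = np.array([assign[p] for p in data.pattern_ids])
        except KeyError as exc:
            raise KeyError(f"pattern missing from membership snapshot: {exc}")
        B = np.ascontiguousarray(
            bio_term_matrix(conn.off_diagonal(), snap_labels, k))
        labels, _ = _kernels.assign_all(values, model.weights, B, alpha)
    else:
        zero_B = np.zeros((values.shape[0], k))
        labels, _ = _kernels.assign_all(values, model.weights, zero_B, 0.0)
    return Partition(list(data.pattern_ids), np.asarray(labels), k)


class SOMResults:
    """Fit results: trained prototypes, final partition and diagnostics.

    Attributes
    ----------
    model : SomModel
        Grid geometry and prototype vectors.
    partition : Partition
        Final assignment of every pattern to a unit.
    training_log : pandas.DataFrame
        Per-epoch radius, learning rate and quantization error.
    """

    def __init__(self, estimator: PathwaySOM, model: SomModel,
                 partition: Partition, training_log: pd.DataFrame,
                 seed: int, final_qe: float, used_bio: bool):
        self.estimator = estimator
        self.model = model
        self.partition = partition
        self.training_log = training_log
        self.seed = seed
        self.final_quantization_error = final_qe
        self.used_bio = used_bio

    @property
    def weights(self) -> np.ndarray:
        return self.model.weights

    @property
    def config(self) -> SomConfig:
        return self.model.config

    def project(self, data: ExpressionMatrix | None = None,
                use_bio: bool = True) -> Partition:
        """Project (new) patterns onto the trained map; defaults to the
        training data, reproducing :attr:`partition`."""
        if data is None:
            data = self.estimator.data
        return project(data, self.model, self.estimator.connectivity,
                       self.partition, use_bio=use_bio)

    def validate(self, log_base: float = 10.0):
        """Compute the full validation-measure suite for this fit."""
        from .metrics import validation_report
        return validation_report(self.estimator.data, self.model,
                                 self.partition,
                                 self.estimator.connectivity,
                                 log_base=log_base)

    def summary(self) -> str:
        cfg = self.config
        sizes = self.partition.sizes()
        nonempty = int((sizes > 0).sum())
        lines = [
            "Pathway-constrained SOM results",
            "=" * 46,
            f"grid:              {cfg.rows} x {cfg.cols} "
            f"({cfg.n_units} units)",
            f"alpha:             {cfg.alpha:.2f}"
            + ("  (standard Euclidean SOM)" if cfg.alpha == 0 else ""),
            f"epochs:            {self.model.trained_epochs}",
            f"seed:              {self.seed}",
            f"patterns:          {self.estimator.data.n_patterns}",
            f"conditions:        {self.estimator.data.n_conditions}",
            f"non-empty units:   {nonempty}",
            f"largest cluster:   {int(sizes.max())}",
            f"quantization err:  {self.final_quantization_error:.6g}",
        ]
        try:
            rep = self.validate()
        except ValueError:
            lines.append("(validation metrics unavailable for this partition)")
        else:
            lines += ["-" * 46, rep.to_text()]
        return "\n".join(lines)

    def save(self, outdir, sep: str = "\t") -> None:
        """Write weights, partition, training log and a YAML sidecar with
        everything needed to reproduce the run."""
        import yaml
        from pathlib import Path
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        wdf = pd.DataFrame(self.weights,
                           index=[f"unit{m}" for m in
                                  range(self.config.n_units)],
                           columns=self.estimator.data.condition_names)
        wdf.index.name = "unit"
        wdf.to_csv(outdir / "weights.tsv", sep=sep)
        self.partition.write(outdir / "partition.tsv", sep=sep)
        self.training_log.to_csv(outdir / "training_log.tsv", sep=sep,
                                 index=False)
        meta = {
            "config": asdict(self.config),
            "seed": int(self.seed),
            "trained_epochs": int(self.model.trained_epochs),
            "final_quantization_error": self.final_quantization_error,
            "used_bio": bool(self.used_bio),
        }
        with open(outdir / "run.yaml", "w") as fh:
            yaml.safe_dump(meta, fh, sort_keys=True)
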