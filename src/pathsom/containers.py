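"""Core in-memory containers shared across the package.

Patterns are measured elements (gene transcripts or metabolites); each
pattern carries a vector of expression/abundance values across conditions.
All containers keep an explicit, ordered list of pattern identifiers so
that expression values, pathway-connectivity entries and cluster
assignments can be joined without positional guesswork.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ConnectivityMatrix",
    "Partition",
]


def _check_unique_ids(ids: list[str]) -> None:
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"pattern_ids must be unique; duplicated: {dupes[:5]}")


@dataclass
class ExpressionMatrix:
    """Patterns x conditions numeric matrix with stable pattern IDs.

    Parameters
    ----------
    pattern_ids
        Ordered, unique identifiers, one per row.
    values
        2-D float array, rows aligned with ``pattern_ids``.
    condition_names
        Optional column labels; generated as ``cond0..`` when omitted.
    """

    pattern_ids: list[str]
    values: np.ndarray
    condition_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape[0] != len(self.pattern_ids):
            raise ValueError(
                f"{len(self.pattern_ids)} pattern_ids but "
                f"{self.values.shape[0]} rows of values"
            )
        if self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise ValueError("need at least one pattern and one condition")
        _check_unique_ids(self.pattern_ids)
        if np.isnan(self.values).any():
            raise ValueError("expression values contain NaN; clean or impute first")
        if not self.condition_names:
            self.condition_names = [f"cond{j}" for j in range(self.values.shape[1])]
        elif len(self.condition_names) != self.values.shape[1]:
            raise ValueError("condition_names length mismatch")

    @property
    def n_patterns(self) -> int:
        return self.values.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.values.shape[1]

    def index_of(self, pattern_id: str) -> int:
        try:
            return self.pattern_ids.index(pattern_id)
        except ValueError:
            raise KeyError(f"unknown pattern id: {pattern_id!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.pattern_ids, name="pattern_id"),
            columns=self.condition_names,
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            pattern_ids=[str(i) for i in df.index],
            values=df.to_numpy(dtype=float),
            condition_names=[str(c) for c in df.columns],
        )

    @classmethod
    def read(cls, path: str | Path, sep: str | None = None,
             dropna: bool = False) -> "ExpressionMatrix":
        """Load from delimited text: header row, pattern IDs in column 0.

        ``sep=None`` auto-detects tab vs comma from the header line.
        ``dropna`` drops rows containing missing values instead of failing.
        """
        path = Path(path)
        if sep is None:
            with open(path) as fh:
                header = fh.readline()
            sep = "\t" if "\t" in header else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        if dropna:
            df = df.dropna(axis=0)
        return cls.from_frame(df)

    def write(self, path: str | Path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep)


@dataclass
class ConnectivityMatrix:
    """Symmetric non-negative matrix of shared-pathway counts (rho).

    ``rho[i, j]`` is the number of metabolic pathways that involve both
    pattern *i* and pattern *j*.  The diagonal stores each pattern's own
    pathway count but is never consumed by any downstream computation;
    every formula iterates over i != j only.
    """

    pattern_ids: list[str]
    rho: np.ndarray

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho)
        n = len(self.pattern_ids)
        if self.rho.shape != (n, n):
            raise ValueError(
                f"rho shape {self.rho.shape} does not match {n} pattern_ids"
            )
        _check_unique_ids(self.pattern_ids)
        if (self.rho < 0).any():
            raise ValueError("rho entries must be non-negative")
        if not np.array_equal(self.rho, self.rho.T):
            raise ValueError("rho must be symmetric")

    @property
    def n_patterns(self) -> int:
        return len(self.pattern_ids)

    def off_diagonal(self) -> np.ndarray:
        """Copy of rho with the (inert) diagonal zeroed."""
        out = np.array(self.rho, dtype=float)
        np.fill_diagonal(out, 0.0)
        return out

    def annotated_mask(self) -> np.ndarray:
        """True for patterns with at least one nonzero off-diagonal entry."""
        return self.off_diagonal().sum(axis=1) > 0

    def reindex(self, pattern_ids: list[str]) -> "ConnectivityMatrix":
        """Restrict/reorder to the given pattern IDs (all must be present)."""
        pos = {p: i for i, p in enumerate(self.pattern_ids)}
        try:
            idx = np.array([pos[p] for p in pattern_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"pattern id missing from connectivity matrix: {exc}")
        return ConnectivityMatrix(list(pattern_ids), self.rho[np.ix_(idx, idx)])

    def write(self, path: str | Path, sep: str = "\t",
              upper_triangular: bool = False) -> None:
        """Write as a square labelled matrix, or a compact upper-triangular
        dump (``i<TAB>j<TAB>rho_ij`` for nonzero entries, diagonal included)."""
        path = Path(path)
        if upper_triangular:
            with open(path, "w") as fh:
                fh.write("# upper-triangular shared-pathway counts\n")
                fh.write(f"# n={self.n_patterns}\n")
                iu = np.triu_indices(self.n_patterns)
                for i, j in zip(*iu):
                    v = self.rho[i, j]
                    if v != 0:
                        fh.write(
                            f"{self.pattern_ids[i]}{sep}{self.pattern_ids[j]}{sep}{v}\n"
                        )
        else:
            df = pd.DataFrame(self.rho, index=self.pattern_ids,
                              columns=self.pattern_ids)
            df.to_csv(path, sep=sep)

    @classmethod
    def read(cls, path: str | Path, sep: str | None = None) -> "ConnectivityMatrix":
        path = Path(path)
        if sep is None:
            with open(path) as fh:
                header = fh.readline()
            sep = "\t" if "\t" in header else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        ids = [str(i) for i in df.index]
        if [str(c) for c in df.columns] != ids:
            raise ValueError("connectivity matrix rows and columns disagree")
        return cls(ids, df.to_numpy())


@dataclass
class Partition:
    """Assignment of every pattern to exactly one map unit.

    ``labels[i]`` is the unit index (row-major, from 0) of pattern ``i`` in
    ``pattern_ids`` order.  ``unit_members`` is derived and always the exact
    inverse of the assignment.
    """

    pattern_ids: list[str]
    labels: np.ndarray
    n_units: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(self.pattern_ids),):
            raise ValueError("labels must align with pattern_ids")
        _check_unique_ids(self.pattern_ids)
        if self.labels.size and (self.labels.min() < 0
                                 or self.labels.max() >= self.n_units):
            raise ValueError("unit index out of range")

    @property
    def assignment(self) -> dict[str, int]:
        return dict(zip(self.pattern_ids, self.labels.tolist()))

    @property
    def unit_members(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {m: set() for m in range(self.n_units)}
        for pid, lab in zip(self.pattern_ids, self.labels):
            out[int(lab)].add(pid)
        return out

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_units)

    def nonempty_units(self) -> np.ndarray:
        return np.flatnonzero(self.sizes() > 0)

    def write(self, path: str | Path, sep: str = "\t") -> None:
        with open(path, "w") as fh:
            fh.write(f"pattern_id{sep}unit_index\n")
            for pid, lab in zip(self.pattern_ids, self.labels):
                fh.write(f"{pid}{sep}{int(lab)}\n")

    @classmethod
    def read(cls, path: str | Path, n_units: int | None = None,
             sep: str = "\t") -> "Partition":
        df = pd.read_csv(path, sep=sep)
        labels = df["unit_index"].to_numpy(dtype=int)
        if n_units is None:
            n_units = int(labels.max()) + 1 if labels.size else 0
        return cls([str(p) for p in df["pattern_id"]], labels, n_units)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Partition):
            return NotImplemented
        return (self.pattern_ids == other.pattern_ids
                and self.n_units == other.n_units
                and np.array_equal(self.labels, other.labels))
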