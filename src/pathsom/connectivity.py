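"""Pathway-connectivity matrix construction.

Builds the symmetric shared-pathway-count matrix rho from a long-format
pattern -> pathway annotation table (KEGG-style pathway IDs such as
"ko00260").  rho[i, j] counts the pathways that involve both pattern i and
pattern j; it is the only piece of prior biological knowledge the training
algorithm and the connectivity-based validation measure consume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .containers import ConnectivityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PathwayAnnotation",
    "AnnotationParseError",
    "load_annotations",
    "build_rho",
    "rho_summary",
]


class AnnotationParseError(ValueError):
    """Malformed annotation line (strict mode)."""


@dataclass
class PathwayAnnotation:
    """De-duplicated set of (pattern_id, pathway_id) pairs."""

    entries: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        for pat, path in self.entries:
            if not pat or not path:
                raise ValueError(
                    f"empty pattern or pathway id in pair ({pat!r}, {path!r})"
                )

    @property
    def pattern_ids(self) -> set[str]:
        return {p for p, _ in self.entries}

    @property
    def pathway_ids(self) -> set[str]:
        return {w for _, w in self.entries}

    def pathways_of(self, pattern_id: str) -> set[str]:
        return {w for p, w in self.entries if p == pattern_id}

    def __len__(self) -> int:
        return len(self.entries)

    def write(self, path: str | Path, sep: str = "\t") -> None:
        with open(path, "w") as fh:
            for pat, pway in sorted(self.entries):
                fh.write(f"{pat}{sep}{pway}\n")


def load_annotations(path: str | Path, strict: bool = False) -> PathwayAnnotation:
    """Read a long-format annotation table, one (pattern, pathway) per line.

    Tab- or comma-delimited (auto-detected per line), ``#`` comment lines
    skipped, extra columns ignored, duplicate pairs collapsed.  In strict
    mode any line with fewer than two fields, or with a blank field, aborts
    with the offending line number; otherwise such lines are skipped with a
    warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"annotation file not found: {path}")
    pairs: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split(",")
            fields = [f.strip() for f in fields]
            if len(fields) < 2 or not fields[0] or not fields[1]:
                msg = f"line {lineno}: expected >=2 non-blank fields: {line!r}"
                if strict:
                    raise AnnotationParseError(msg)
                logger.warning("skipping malformed annotation %s", msg)
                continue
            pairs.add((fields[0], fields[1]))
    if not pairs:
        logger.warning("annotation file %s yielded no (pattern, pathway) pairs",
                       path)
    return PathwayAnnotation(pairs)


def build_rho(ann: PathwayAnnotation,
              pattern_ids: list[str]) -> ConnectivityMatrix:
    """Count shared pathways for every pattern pair.

    ``rho[i, j] = |pathways(i) & pathways(j)|`` for i != j; the diagonal
    stores each pattern's own pathway count (inert downstream).  Patterns
    absent from the annotation get all-zero rows/columns off-diagonal --
    unannotated elements stay in the analysis rather than being dropped.
    """
    if not pattern_ids:
        raise ValueError("pattern_ids must be non-empty")
    if len(set(pattern_ids)) != len(pattern_ids):
        raise ValueError("pattern_ids must be unique")

    pathways = sorted(ann.pathway_ids)
    pw_index = {w: k for k, w in enumerate(pathways)}
    pat_index = {p: i for i, p in enumerate(pattern_ids)}
    # membership indicator: patterns x pathways; rho = M @ M.T
    M = np.zeros((len(pattern_ids), len(pathways)), dtype=np.int64)
    for pat, pway in ann.entries:
        i = pat_index.get(pat)
        if i is not None:
            M[i, pw_index[pway]] = 1
    rho = M @ M.T
    return ConnectivityMatrix(list(pattern_ids), rho)


def rho_summary(conn: ConnectivityMatrix) -> dict:
    """Scalar summaries of a connectivity matrix for reporting.

    Returns the fraction of zero off-diagonal entries (the "white pixels"
    of a rho heatmap), the maximum off-diagonal entry, and the fraction of
    patterns with at least one off-diagonal connection.  A single-pattern
    matrix has no off-diagonal entries and is flagged degenerate.
    """
    n = conn.n_patterns
    if n < 2:
        return {
            "n_patterns": n,
            "zero_fraction": float("nan"),
            "max_entry": 0,
            "annotated_fraction": 0.0,
            "degenerate": True,
        }
    off = conn.off_diagonal()
    mask = ~np.eye(n, dtype=bool)
    vals = off[mask]
    return {
        "n_patterns": n,
        "zero_fraction": float(np.mean(vals == 0)),
        "max_entry": int(vals.max()),
        "annotated_fraction": float(np.mean(conn.annotated_mask())),
        "degenerate": False,
    }
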