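"""Compare abundance profiles across tools as vectors.

Each tool's abundance profile is viewed as a vector whose components are
the abundance estimates per organism; tools are then compared via a
pairwise distance matrix, agglomerative hierarchical clustering, and a
two-component PCA projection.  This is the standard way to contrast
classifier outputs on real samples without ground truth: tools of the
same family (k-mer counting vs mapping vs protein search) tend to cluster
together.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform

from .abundance import AbundanceProfile

__all__ = [
    "ProfileMatrix",
    "assemble_matrix",
    "distance_matrix",
    "hierarchical_cluster",
    "pca_2d",
    "load_profile_dir",
]


@dataclass
class ProfileMatrix:
    """Tools × taxa abundance matrix; each row is a profile summing to 1."""

    labels: list[str]
    taxids: list[int]
    values: np.ndarray  # shape (n_tools, n_taxa)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.taxids)


def assemble_matrix(profiles: Sequence[tuple[str, AbundanceProfile]]) -> ProfileMatrix:
    """Stack labeled profiles over the union of their taxa.

    Missing taxa are 0; columns are ordered by taxid.  All profiles must
    share rank and measure; duplicate labels are an error.
    """
    if not profiles:
        raise ValueError("no profiles to assemble")
    labels = [label for label, _ in profiles]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate tool labels in profile list")
    ranks = {p.rank for _, p in profiles}
    measures = {p.measure for _, p in profiles}
    if len(ranks) > 1 or len(measures) > 1:
        raise ValueError(f"profiles mix ranks {ranks} or measures {measures}")
    taxids = sorted(set().union(*(p.values.keys() for _, p in profiles)))
    values = np.zeros((len(profiles), len(taxids)))
    col = {t: j for j, t in enumerate(taxids)}
    for i, (_, profile) in enumerate(profiles):
        for taxid, v in profile.values.items():
            values[i, col[taxid]] = v
    return ProfileMatrix(labels=labels, taxids=taxids, values=values)


def distance_matrix(m: ProfileMatrix, metric: str = "l1") -> np.ndarray:
    """Symmetric pairwise distance matrix between tool profiles.

    ``l1`` (cityblock) matches the L1 abundance-error convention used for
    ground-truthed samples; ``euclidean`` is also available.
    """
    if m.values.shape[0] < 2:
        raise ValueError("need at least 2 profiles for a distance matrix")
    scipy_metric = {"l1": "cityblock", "euclidean": "euclidean"}.get(metric)
    if scipy_metric is None:
        raise ValueError(f"unknown metric {metric!r}")
    return squareform(pdist(m.values, metric=scipy_metric))


def hierarchical_cluster(d: np.ndarray, method: str = "average") -> np.ndarray:
    """Agglomerative clustering of a precomputed distance matrix.

    Returns the scipy linkage matrix (n-1 merges with heights).  Linkages
    ``average``, ``complete`` and ``single`` produce monotone merge
    heights on metric input.
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if method not in ("average", "complete", "single"):
        raise ValueError(f"unknown linkage {method!r}")
    return linkage(squareform(d, checks=False), method=method)


def pca_2d(m: ProfileMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Project tools onto the two leading principal components.

    Columns are centered and the rows projected onto the top-2 right
    singular directions.  The sign of each component is pinned by making
    its largest-magnitude loading positive, so output is deterministic.
    Returns (coords of shape (n_tools, 2), explained-variance fractions).
    """
    if m.values.shape[0] < 2:
        raise ValueError("PCA needs at least 2 profiles")
    centered = m.values - m.values.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    for k in range(vt.shape[0]):
        pivot = np.argmax(np.abs(vt[k]))
        if vt[k, pivot] < 0:
            vt[k] = -vt[k]
            u[:, k] = -u[:, k]
    var = s**2
    explained = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    n_comp = min(2, len(s))
    coords = u[:, :n_comp] * s[:n_comp]
    if n_comp < 2:  # degenerate: pad a zero second component
        coords = np.hstack([coords, np.zeros((coords.shape[0], 1))])
        explained = np.append(explained, 0.0)
    return coords, explained[:2]


def load_profile_dir(directory: str | Path, measure: str = "genome_count", rank: str = "species") -> list[tuple[str, AbundanceProfile]]:
    """Load every ``*.tsv`` profile in a directory, labels from filenames."""
    directory = Path(directory)
    out: list[tuple[str, AbundanceProfile]] = []
    for path in sorted(directory.glob("*.tsv")):
        out.append((path.stem, AbundanceProfile.from_tsv(path, measure=measure, rank=rank, label=path.stem)))
    if not out:
        raise ValueError(f"no profile TSVs found in {directory}")
    return out
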