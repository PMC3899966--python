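"""Metabolic pathway completion, PCA and pathway clustering.

Completion of a pathway in a genome is the fraction of the pathway's
reactions for which the genome encodes at least one gene.  The genomes x
pathways completion matrix feeds a covariance-eigendecomposition PCA
(centering on, scaling off by default); pathway variables are filtered by
their quality of representation (squared cosine) on a factorial plane and
clustered with Euclidean/Ward into k classes (default 7, plane 1-2).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = ["CompletionMatrix", "PcaResult", "read_reaction_table",
           "read_pathway_definitions", "completion_matrix", "pca",
           "representation", "filter_representation", "cluster_pathways"]


@dataclass
class CompletionMatrix:
    """Genomes x pathways matrix of completion fractions in [0, 1]."""

    values: pd.DataFrame  # rows = genomes, columns = pathways

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        if v.size and (v.min() < 0 or v.max() > 1):
            raise ValueError("completion fractions must lie in [0, 1]")

    @property
    def genomes(self) -> list[str]:
        return list(self.values.index)

    @property
    def pathways(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class PcaResult:
    scores: pd.DataFrame             # genomes x components
    loadings: pd.DataFrame           # pathways x components
    explained_variance: np.ndarray   # fractions, non-increasing
    eigenvalues: np.ndarray
    mean: np.ndarray
    scale: np.ndarray | None

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def read_reaction_table(path: str | Path) -> dict[str, set[str]]:
    """Tab-delimited ``genome_id<TAB>reaction_id`` -> genome coverage sets."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            gid, rid = line.split("\t")[:2]
            out.setdefault(gid, set()).add(rid)
    return out


def read_pathway_definitions(path: str | Path) -> dict[str, set[str]]:
    """Tab-delimited ``pathway_id<TAB>reaction_id`` -> pathway reaction sets."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            pid, rid = line.split("\t")[:2]
            out.setdefault(pid, set()).add(rid)
    return out


def completion_matrix(genome_reactions: dict[str, set[str]],
                      pathway_definitions: dict[str, set[str]]
                      ) -> CompletionMatrix:
    """Completion fraction per (genome, pathway).

    A pathway's completion in a genome is the number of its reactions
    covered by the genome divided by its total reactions (set semantics:
    duplicate listings count once).  Pathways with zero reactions are
    excluded with a warning.
    """
    import warnings

    pathways = {}
    for pid in sorted(pathway_definitions):
        reactions = set(pathway_definitions[pid])
        if not reactions:
            warnings.warn(f"pathway {pid} has no reactions; excluded")
            continue
        pathways[pid] = reactions
    genomes = sorted(genome_reactions)
    data = {
        pid: [len(genome_reactions[g] & rxns) / len(rxns) for g in genomes]
        for pid, rxns in pathways.items()}
    return CompletionMatrix(values=pd.DataFrame(data, index=genomes))


def pca(matrix: CompletionMatrix, center: bool = True,
        scale: bool = False) -> PcaResult:
    """PCA by eigendecomposition of the covariance (or correlation) matrix.

    Rows (genomes) are observations, columns (pathways) variables.  The
    sign of each component is fixed so its largest-magnitude loading is
    positive.  All ``min(n_genomes - 1, n_pathways)`` components are
    retained; a constant matrix yields an empty component set.
    """
    X = matrix.values.to_numpy(dtype=float)
    n, p = X.shape
    if n < 2 or p < 2:
        raise ValueError("PCA needs at least 2 genomes and 2 pathways")
    mean = X.mean(axis=0) if center else np.zeros(p)
    Xc = X - mean
    sd = None
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    cov = Xc.T @ Xc / (n - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]

    keep = eigval > max(eigval[0], 1.0) * 1e-12 if eigval.size else \
        np.zeros(0, bool)
    k = min(int(keep.sum()), n - 1, p)
    eigval = eigval[:k]
    eigvec = eigvec[:, :k]

    for c in range(k):  # deterministic sign convention
        col = eigvec[:, c]
        if col[np.argmax(np.abs(col))] < 0:
            eigvec[:, c] = -col

    scores = Xc @ eigvec
    total = eigval.sum()
    explained = eigval / total if total > 0 else eigval
    comp_names = [f"PC{i + 1}" for i in range(k)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=matrix.genomes,
                            columns=comp_names),
        loadings=pd.DataFrame(eigvec, index=matrix.pathways,
                              columns=comp_names),
        explained_variance=explained, eigenvalues=eigval,
        mean=mean, scale=sd)


def _variable_coords(result: PcaResult) -> pd.DataFrame:
    """Variable coordinates: loadings scaled by sqrt(eigenvalue)."""
    return result.loadings * np.sqrt(result.eigenvalues)


def representation(result: PcaResult,
                   plane: tuple[int, int] = (0, 1)) -> pd.Series:
    """Quality of representation (squared cosine) per pathway on a plane.

    The squared cosine of a variable on an axis is its squared coordinate
    divided by its squared distance over all axes; the plane value sums the
    two axes.  Pathways with zero variance get representation 0.
    """
    coords = _variable_coords(result).to_numpy()
    total = (coords ** 2).sum(axis=1)
    # axes beyond the matrix rank carry no variance: coordinate 0
    axes = [a for a in plane if a < result.n_components]
    plane_sq = sum((coords[:, a] ** 2 for a in axes),
                   np.zeros(coords.shape[0]))
    with np.errstate(invalid="ignore", divide="ignore"):
        rep = np.where(total > 0, plane_sq / total, 0.0)
    return pd.Series(rep, index=result.loadings.index)


def filter_representation(result: PcaResult,
                          plane: tuple[int, int] = (0, 1),
                          threshold: float = 0.75) -> list[str]:
    """Pathways whose squared-cosine sum on the plane is strictly greater
    than ``threshold`` (default 0.75)."""
    rep = representation(result, plane)
    return [p for p in rep.index if rep[p] > threshold]


def cluster_pathways(result: PcaResult, plane: tuple[int, int] = (0, 1),
                     k: int = 7,
                     pathways: list[str] | None = None) -> dict[str, int]:
    """Euclidean/Ward clustering of pathway coordinates on a plane.

    Agglomerative Ward clustering of the pathway variable coordinates on
    the chosen factorial plane (default components 1-2), cut at ``k``
    classes (default 7).  Pathways are processed in column order, making
    tie-breaking deterministic for a given matrix.
    """
    coords = _variable_coords(result)
    if pathways is not None:
        coords = coords.loc[pathways]
    if k > coords.shape[0]:
        raise ValueError(f"k={k} exceeds {coords.shape[0]} pathways")
    axes = [a for a in plane if a < result.n_components]
    if not axes:
        raise ValueError("no components available on the requested plane")
    arr = coords.to_numpy()
    pts = np.column_stack([arr[:, a] for a in axes])
    if k == coords.shape[0]:
        return {p: i + 1 for i, p in enumerate(coords.index)}
    lk = linkage(pts, method="ward", metric="euclidean")
    labels = fcluster(lk, t=k, criterion="maxclust")
    return {p: int(c) for p, c in zip(coords.index, labels)}
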