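"""Core-genome distance phylogeny: concatenation, Jukes-Cantor distances,
neighbor joining, bootstrap support and Robinson-Foulds comparison.

The concatenated alignment holds one sequence per taxon, built from
single-copy core families in stable family-id order.  Distances are
p-distances corrected with the Jukes-Cantor formula
``d = -(3/4) ln(1 - 4p/3)`` for nucleotide data (default) or the Poisson
correction ``d = -ln(1 - p)`` for protein data.  Trees are built with
standard neighbor joining under deterministic tie-breaking; bipartition
support comes from column-resampled bootstrap replicates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from skbio import TreeNode

from .errors import SaturationError
from .io import GenomeRecord
from .orthology import OrthologFamily, align_pair, make_aligner

__all__ = ["ConcatenatedAlignment", "DistanceMatrix", "concatenate",
           "jc_distance", "poisson_distance", "p_distance_matrix",
           "distance_matrix", "neighbor_joining", "bootstrap",
           "bipartitions", "rf_distance"]

GAP = "-"


@dataclass
class ConcatenatedAlignment:
    """Equal-length aligned sequences, one per taxon, with per-family
    column ranges (0-based half-open)."""

    taxa: list[str]
    sequences: dict[str, str]
    partition_bounds: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError("unequal alignment row lengths")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences \
            else 0

    def matrix(self) -> np.ndarray:
        return np.array([list(self.sequences[t]) for t in self.taxa])

    def resample_columns(self, rng: np.random.Generator
                         ) -> "ConcatenatedAlignment":
        """Bootstrap replicate: columns drawn with replacement."""
        n = self.n_columns
        cols = rng.integers(0, n, size=n)
        seqs = {t: "".join(self.sequences[t][c] for c in cols)
                for t in self.taxa}
        return ConcatenatedAlignment(taxa=list(self.taxa), sequences=seqs,
                                     partition_bounds=[])


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.d < 0) or not np.all(np.isfinite(self.d)):
            raise ValueError("distances must be finite and non-negative")


def _reduce_to_single_copy(family: OrthologFamily,
                           genomes: dict[str, GenomeRecord],
                           aligner) -> dict[str, str]:
    """One member per genome: the one with highest mean identity to the
    members of the other genomes (paralog resolution for concatenation)."""
    by_genome: dict[str, list[str]] = {}
    for gid, tag in sorted(family.members):
        by_genome.setdefault(gid, []).append(tag)
    chosen: dict[str, str] = {}
    for gid, tags in by_genome.items():
        if len(tags) == 1:
            chosen[gid] = tags[0]
            continue
        others = [(og, ot) for og, ots in by_genome.items() if og != gid
                  for ot in ots]
        def mean_id(tag: str) -> float:
            prot = genomes[gid].gene_by_tag(tag).protein
            ids = [align_pair(prot, genomes[og].gene_by_tag(ot).protein,
                              aligner).identity for og, ot in others]
            return sum(ids) / len(ids) if ids else 0.0
        chosen[gid] = max(tags, key=lambda t: (mean_id(t), t))
    return chosen


def concatenate(core_families: list[OrthologFamily],
                genomes: dict[str, GenomeRecord],
                seq_source: str = "nucleotide",
                aligner=None) -> ConcatenatedAlignment:
    """Concatenate per-family alignments of single-copy core families.

    Families are taken in family-id order; each must cover every genome
    (multi-copy families are reduced to their best single member first).
    ``aligner`` is a callable mapping {taxon: sequence} to an aligned
    {taxon: sequence}; by default sequences must already be equal-length
    within each family (true for indel-free simulated clades), otherwise
    an aligner must be supplied.
    """
    taxa = sorted(genomes)
    pair_aligner = make_aligner()
    seqs: dict[str, list[str]] = {t: [] for t in taxa}
    bounds: list[tuple[str, int, int]] = []
    pos = 0
    for fam in sorted(core_families, key=lambda f: f.family_id):
        missing = set(taxa) - set(fam.genome_profile)
        if missing:
            raise ValueError(
                f"family {fam.family_id} missing taxa: {sorted(missing)}")
        chosen = _reduce_to_single_copy(fam, genomes, pair_aligner)
        block: dict[str, str] = {}
        for gid in taxa:
            gene = genomes[gid].gene_by_tag(chosen[gid])
            block[gid] = gene.protein if seq_source == "protein" \
                else genomes[gid].cds_nucleotide(gene)
        lengths = {len(s) for s in block.values()}
        if len(lengths) > 1:
            if aligner is None:
                raise ValueError(
                    f"family {fam.family_id} members differ in length; "
                    f"supply an aligner")
            block = aligner(block)
            lengths = {len(s) for s in block.values()}
        width = lengths.pop()
        for gid in taxa:
            seqs[gid].append(block[gid])
        bounds.append((fam.family_id, pos, pos + width))
        pos += width
    return ConcatenatedAlignment(
        taxa=taxa, sequences={t: "".join(seqs[t]) for t in taxa},
        partition_bounds=bounds)


def jc_distance(p: float) -> float:
    """Jukes-Cantor corrected distance ``-(3/4) ln(1 - 4p/3)``.

    Valid for observed difference fractions ``0 <= p < 0.75``; beyond that
    the correction is saturated and undefined.
    """
    if not 0.0 <= p:
        raise ValueError("p must be >= 0")
    if p >= 0.75:
        raise SaturationError(
            f"observed difference {p} >= 0.75: JC distance undefined")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def poisson_distance(p: float) -> float:
    """Poisson-corrected protein distance ``-ln(1 - p)`` for p < 1."""
    if not 0.0 <= p < 1.0:
        raise SaturationError(f"p={p} outside [0, 1)")
    return -math.log(1.0 - p)


def p_distance_matrix(aln: ConcatenatedAlignment) -> DistanceMatrix:
    """Observed difference fractions over columns where both rows are
    ungapped."""
    mat = aln.matrix()
    n = len(aln.taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = mat[i], mat[j]
            ok = (a != GAP) & (b != GAP)
            total = int(ok.sum())
            p = float(((a != b) & ok).sum()) / total if total else 0.0
            d[i, j] = d[j, i] = p
    return DistanceMatrix(taxa=list(aln.taxa), d=d)


def distance_matrix(aln: ConcatenatedAlignment,
                    model: str = "jc") -> DistanceMatrix:
    """Corrected distances: ``model="jc"`` (nucleotide, default) or
    ``"poisson"`` (protein); ``"p"`` returns uncorrected fractions."""
    pd = p_distance_matrix(aln)
    if model == "p":
        return pd
    correct = jc_distance if model == "jc" else poisson_distance
    n = len(pd.taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = correct(pd.d[i, j])
    return DistanceMatrix(taxa=list(pd.taxa), d=d)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Standard neighbor joining with deterministic tie-breaking.

    Taxa are processed in sorted order; ties in the Q criterion are broken
    by the first (row-major) minimum.  Negative branch lengths are clamped
    to zero with a warning.  Returns an unrooted tree represented with a
    trifurcating root (for >= 3 taxa).
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    order = sorted(range(n), key=lambda i: dm.taxa[i])
    labels = [dm.taxa[i] for i in order]
    d = dm.d[np.ix_(order, order)].astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=t) for t in labels]

    def clamp(x: float) -> float:
        if x < 0:
            warnings.warn(f"negative branch length {x:.3g} clamped to 0")
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        row_sums = d.sum(axis=1)
        q = (m - 2) * d - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(np.argmin(q), q.shape)
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (row_sums[i] - row_sums[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = clamp(float(li))
        nodes[j].length = clamp(float(lj))
        new_d = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.vstack([np.hstack([d[np.ix_(keep, keep)],
                                  new_d[keep, None]]),
                       np.hstack([new_d[keep], [0.0]])])
        nodes = [nodes[k] for k in keep] + [parent]

    # final three-taxon star: closed-form three-point lengths
    (a, b, c) = nodes
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    a.length, b.length, c.length = (clamp(float(la)), clamp(float(lb)),
                                    clamp(float(lc)))
    return TreeNode(children=[a, b, c])


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial splits of an (un)rooted tree.

    Each internal edge yields the leaf set on its far side, canonicalized
    to the side containing the lexicographically smallest leaf; splits of
    size 1 or n-1 (and the full set) are trivial and excluded.
    """
    leaves = frozenset(t.name for t in tree.tips())
    anchor = min(leaves)
    out: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        below = frozenset(t.name for t in node.tips())
        if len(below) <= 1 or len(below) >= len(leaves) - 1:
            continue
        side = below if anchor in below else leaves - below
        out.add(side)
    return out


def rf_distance(tree_a: TreeNode, tree_b: TreeNode) -> int:
    """Robinson-Foulds distance: size of the symmetric difference of the
    two trees' non-trivial bipartition sets."""
    la = {t.name for t in tree_a.tips()}
    lb = {t.name for t in tree_b.tips()}
    if la != lb:
        raise ValueError(f"leaf sets differ: {sorted(la ^ lb)}")
    return len(bipartitions(tree_a) ^ bipartitions(tree_b))


def bootstrap(aln: ConcatenatedAlignment, replicates: int = 100,
              seed: int = 0, model: str = "jc"
              ) -> tuple[TreeNode, dict[frozenset[str], float]]:
    """NJ tree from the full alignment with bootstrap support values.

    Columns are resampled with replacement ``replicates`` times; support
    for each bipartition of the full-alignment tree is the percentage of
    replicate trees containing it, written as internal node labels.  With
    ``replicates=0`` the tree is returned unannotated.
    """
    if len(aln.taxa) < 3:
        raise ValueError("bootstrap needs at least 3 taxa")
    tree = neighbor_joining(distance_matrix(aln, model))
    splits = bipartitions(tree)
    support: dict[frozenset[str], float] = {}
    if replicates <= 0:
        return tree, support
    rng = np.random.default_rng(seed)
    tally = {s: 0 for s in splits}
    for _ in range(replicates):
        rep = aln.resample_columns(rng)
        with warnings.catch_warnings():
            # clamping on resampled replicates is routine, not a finding
            warnings.simplefilter("ignore", UserWarning)
            rep_tree = neighbor_joining(distance_matrix(rep, model))
        rep_splits = bipartitions(rep_tree)
        for s in splits:
            if s in rep_splits:
                tally[s] += 1
    support = {s: 100.0 * c / replicates for s, c in tally.items()}

    leaves = frozenset(t.name for t in tree.tips())
    anchor = min(leaves)
    for node in tree.non_tips(include_self=False):
        below = frozenset(t.name for t in node.tips())
        if len(below) <= 1 or len(below) >= len(leaves) - 1:
            continue
        side = below if anchor in below else leaves - below
        if side in support:
            node.name = f"{support[side]:g}"
    return tree, support
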