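"""Genomic-island (RGP) detection and cross-genome island comparison.

A region of genomic plasticity is a run of consecutive genes in a target
genome whose families are missing from one or more comparator genomes,
spanning at least 5 kbp from the first gene's start to the last gene's end.
Detected islands are annotated with classic island features (boundary
tRNAs, mobile-element annotations, G+C anomaly against the genome mean),
matched across genomes by syntenic family sharing, collapsed into island
clusters, and summarised as a genomes x clusters presence/absence matrix
whose Jaccard/UPGMA dendrogram can be compared against the core phylogeny.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import pdist
from skbio import TreeNode

from .io import GenomeRecord
from .orthology import OrthologFamily

__all__ = ["GcTrack", "GenomicIsland", "gc_deviation", "find_rgp",
           "annotate_island", "match_islands", "island_matrix",
           "island_dendrogram"]

MOBILE_KEYWORDS = ("transposase", "integrase", "phage", "conjugal")


@dataclass
class GcTrack:
    """Sliding-window G+C relative to the genome mean."""

    replicon_id: str
    window: int
    step: int
    starts: np.ndarray          # 1-based window start positions
    ratio: np.ndarray           # window GC / genome mean GC
    genome_mean_gc: float


@dataclass
class GenomicIsland:
    island_id: str
    genome_id: str
    replicon_id: str
    span: tuple[int, int]       # 1-based inclusive bp
    genes: list[str]            # ordered locus tags
    absent_in: frozenset[str]   # comparators missing the whole run
    families: list[str] = field(default_factory=list)
    gene_spans: list[tuple[int, int]] = field(default_factory=list)
    features: dict[str, bool] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.span[1] - self.span[0] + 1


def _gc_fraction(seq: str) -> float:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    return float(((arr == ord("G")) | (arr == ord("C"))).mean()) if len(arr) \
        else 0.0


def gc_deviation(sequence: str, replicon_id: str = "chr",
                 window: int = 1000, step: int = 200,
                 genome_mean_gc: float | None = None) -> GcTrack:
    """Sliding-window G+C ratio track.

    Each window of ``window`` bp (default 1,000), advanced by ``step`` bp,
    is scored as its G+C fraction divided by the genome mean G+C
    (``genome_mean_gc`` if given, else the mean of ``sequence``).
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    if len(sequence) < window:
        raise ValueError("sequence shorter than one window")
    mean_gc = genome_mean_gc if genome_mean_gc is not None \
        else _gc_fraction(sequence)
    if mean_gc <= 0:
        raise ValueError("genome mean G+C must be positive")
    arr = np.frombuffer(sequence.encode(), dtype=np.uint8)
    is_gc = ((arr == ord("G")) | (arr == ord("C"))).astype(float)
    csum = np.concatenate([[0.0], np.cumsum(is_gc)])
    starts = np.arange(0, len(sequence) - window + 1, step)
    gc = (csum[starts + window] - csum[starts]) / window
    return GcTrack(replicon_id=replicon_id, window=window, step=step,
                   starts=starts + 1, ratio=gc / mean_gc,
                   genome_mean_gc=mean_gc)


def _family_of_map(families: list[OrthologFamily]
                   ) -> dict[tuple[str, str], OrthologFamily]:
    out: dict[tuple[str, str], OrthologFamily] = {}
    for fam in families:
        for ref in fam.members:
            out[ref] = fam
    return out


def find_rgp(target: GenomeRecord, comparators: list[GenomeRecord],
             families: list[OrthologFamily], min_span: int = 5000,
             max_interruption: int = 1) -> list[GenomicIsland]:
    """Regions of the target missing from one or more comparator genomes.

    A gene is *missing in* a comparator when its family has no member
    there.  Runs of consecutive genes are extended while at least one
    comparator is missing every (non-interrupting) gene of the run; up to
    ``max_interruption`` consecutive shared genes may interrupt a run
    without splitting it.  A run becomes an island when it spans at least
    ``min_span`` bp from its first gene's start to its last gene's end.
    ``absent_in`` is the set of comparators missing the entire run.
    """
    comp_ids = {c.genome_id for c in comparators}
    if target.genome_id in comp_ids:
        raise ValueError("target genome cannot be among the comparators")
    fam_of = _family_of_map(families)

    def missing_in(gene) -> frozenset[str]:
        fam = fam_of.get((target.genome_id, gene.locus_tag))
        if fam is None:
            return frozenset(comp_ids)
        return frozenset(comp_ids - set(fam.genome_profile))

    islands: list[GenomicIsland] = []
    counter = 1
    coding = [g for g in target.genes if g.feature_type == "gene"]
    by_replicon: dict[str, list] = {}
    for g in coding:
        by_replicon.setdefault(g.replicon_id, []).append(g)

    for rid in sorted(by_replicon):
        genes = by_replicon[rid]
        i = 0
        while i < len(genes):
            start_missing = missing_in(genes[i])
            if not start_missing:
                i += 1
                continue
            run = [genes[i]]
            absent = start_missing
            interruptions = 0
            j = i + 1
            pending: list = []
            while j < len(genes):
                m = missing_in(genes[j])
                new_absent = absent & m
                if new_absent:
                    run.extend(pending)
                    pending = []
                    interruptions = 0
                    run.append(genes[j])
                    absent = new_absent
                elif not m and interruptions < max_interruption:
                    pending.append(genes[j])
                    interruptions += 1
                else:
                    break
                j += 1
            span = (run[0].start, run[-1].end)
            if span[1] - span[0] + 1 >= min_span:
                fams = []
                for g in run:
                    fam = fam_of.get((target.genome_id, g.locus_tag))
                    fams.append(fam.family_id if fam else "")
                islands.append(GenomicIsland(
                    island_id=f"{target.genome_id}_GI{counter:03d}",
                    genome_id=target.genome_id, replicon_id=rid, span=span,
                    genes=[g.locus_tag for g in run],
                    absent_in=absent, families=fams,
                    gene_spans=[(g.start, g.end) for g in run]))
                counter += 1
            i = i + len(run) + len(pending)
    return islands


def annotate_island(island: GenomicIsland, genome: GenomeRecord,
                    gc_track: GcTrack | None = None,
                    trna_distance: int = 2500,
                    gc_threshold: float = 0.05,
                    mobile_keywords: tuple[str, ...] = MOBILE_KEYWORDS
                    ) -> GenomicIsland:
    """Set the classic island feature flags on a detected island.

    ``tRNA_adjacent``: a tRNA gene lies within ``trna_distance`` bp of
    either boundary.  ``has_mobile_elements``: a member gene's annotation
    contains a mobile-element keyword.  ``gc_anomalous``: the mean window
    ratio of the track inside the island deviates from 1.0 by more than
    ``gc_threshold``.
    """
    s, e = island.span
    trna_near = any(
        g.feature_type == "tRNA" and g.replicon_id == island.replicon_id
        and (abs(g.end - s) <= trna_distance or abs(g.start - e) <= trna_distance
             or (s <= g.start and g.end <= e))
        for g in genome.genes)

    members = set(island.genes)
    mobile = any(
        g.locus_tag in members and
        any(k in g.annotation.lower() for k in mobile_keywords)
        for g in genome.genes)

    anomalous = False
    if gc_track is not None and gc_track.replicon_id == island.replicon_id:
        inside = (gc_track.starts >= s) & \
                 (gc_track.starts + gc_track.window - 1 <= e)
        if inside.any():
            anomalous = abs(float(gc_track.ratio[inside].mean()) - 1.0) \
                > gc_threshold

    island.features = {"tRNA_adjacent": trna_near,
                       "has_mobile_elements": mobile,
                       "gc_anomalous": anomalous}
    return island


def _synteny_chain(pairs: list[tuple[int, int]],
                   max_gap: int = 2) -> list[tuple[int, int]]:
    """Longest order-conserved chain of index pairs.

    Consecutive chain members may skip at most ``max_gap`` intervening
    genes on each island.  Returns the best chain (ties: first found in
    sorted pair order).
    """
    pairs = sorted(pairs)
    if not pairs:
        return []
    best_len = [1] * len(pairs)
    prev = [-1] * len(pairs)
    for i in range(len(pairs)):
        for j in range(i):
            da = pairs[i][0] - pairs[j][0]
            db = pairs[i][1] - pairs[j][1]
            if 0 < da <= max_gap + 1 and 0 < db <= max_gap + 1 and \
                    best_len[j] + 1 > best_len[i]:
                best_len[i] = best_len[j] + 1
                prev[i] = j
    end = max(range(len(pairs)), key=lambda i: best_len[i])
    chain: list[tuple[int, int]] = []
    while end != -1:
        chain.append(pairs[end])
        end = prev[end]
    return chain[::-1]


def match_islands(island_a: GenomicIsland, island_b: GenomicIsland,
                  families: list[OrthologFamily],
                  min_fraction: float = 0.5, max_gap: int = 2,
                  conjunctive: bool = True) -> bool:
    """Do two islands from different genomes correspond?

    True iff an order-conserved chain of family-sharing gene pairs (either
    orientation, gaps of at most ``max_gap`` intervening genes) covers at
    least ``min_fraction`` (inclusive) of the smaller island's gene count
    AND of its bp span; ``conjunctive=False`` requires either fraction.
    Symmetric in its arguments.
    """
    if island_a.genome_id == island_b.genome_id:
        return False
    # measure coverage on the smaller island: fewer genes, then shorter span
    a, b = island_a, island_b
    if (len(b.genes), b.length) < (len(a.genes), a.length):
        a, b = b, a
    fam_of = _family_of_map(families)
    fam_a = [fam_of.get((a.genome_id, t)) for t in a.genes]
    fam_b = [fam_of.get((b.genome_id, t)) for t in b.genes]
    b_index: dict[str, list[int]] = {}
    for j, fam in enumerate(fam_b):
        if fam is not None:
            b_index.setdefault(fam.family_id, []).append(j)

    pairs: list[tuple[int, int]] = []
    for i, fam in enumerate(fam_a):
        if fam is None:
            continue
        for j in b_index.get(fam.family_id, ()):
            pairs.append((i, j))
    if not pairs:
        return False

    chain_fwd = _synteny_chain(pairs, max_gap)
    chain_rev = _synteny_chain([(i, -j) for i, j in pairs], max_gap)
    chain = chain_fwd if len(chain_fwd) >= len(chain_rev) else chain_rev

    gene_frac = len(chain) / len(a.genes)
    lo = min(i for i, _ in chain)
    hi = max(i for i, _ in chain)
    covered = a.gene_spans[hi][1] - a.gene_spans[lo][0] + 1 \
        if a.gene_spans else 0
    span_frac = covered / a.length if a.length else 0.0

    if conjunctive:
        return gene_frac >= min_fraction and span_frac >= min_fraction
    return gene_frac >= min_fraction or span_frac >= min_fraction


def island_matrix(islands: list[GenomicIsland],
                  families: list[OrthologFamily],
                  genomes: list[str], min_fraction: float = 0.5,
                  max_gap: int = 2):
    """Cluster matching islands and build the genomes x clusters 0/1 matrix.

    Islands are clustered by connected components of pairwise match
    verdicts; the matrix cell (genome, cluster) is 1 iff the genome holds
    an island of that cluster.  Returns ``(matrix, clusters)`` where
    ``matrix`` is a DataFrame (rows = genomes, columns = cluster ids) and
    ``clusters`` maps cluster id -> member island ids.
    """
    import pandas as pd

    ids = [isl.island_id for isl in islands]
    by_id = {isl.island_id: isl for isl in islands}
    parent = {i: i for i in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, isl_a in enumerate(islands):
        for isl_b in islands[i + 1:]:
            if isl_a.genome_id == isl_b.genome_id:
                continue
            if match_islands(isl_a, isl_b, families,
                             min_fraction=min_fraction, max_gap=max_gap):
                ra, rb = find(isl_a.island_id), find(isl_b.island_id)
                if ra != rb:
                    if rb < ra:
                        ra, rb = rb, ra
                    parent[rb] = ra

    comp: dict[str, list[str]] = {}
    for i in ids:
        comp.setdefault(find(i), []).append(i)
    clusters = {f"GIC{k + 1:03d}": sorted(members)
                for k, (_root, members) in enumerate(sorted(comp.items()))}

    gids = sorted(genomes)
    data = {}
    for cid, members in clusters.items():
        carriers = {by_id[m].genome_id for m in members}
        data[cid] = [1 if g in carriers else 0 for g in gids]
    matrix = pd.DataFrame(data, index=gids)
    return matrix, clusters


def _linkage_to_tree(linkage: np.ndarray, labels: list[str]) -> TreeNode:
    """Convert a scipy linkage matrix into a TreeNode with branch lengths
    equal to merge-height differences."""
    nodes: dict[int, tuple[TreeNode, float]] = {
        i: (TreeNode(name=lab), 0.0) for i, lab in enumerate(labels)}
    n = len(labels)
    for k, (i, j, height, _size) in enumerate(linkage):
        left, lh = nodes.pop(int(i))
        right, rh = nodes.pop(int(j))
        left.length = max(float(height) / 2 - lh, 0.0)
        right.length = max(float(height) / 2 - rh, 0.0)
        nodes[n + k] = (TreeNode(children=[left, right]), float(height) / 2)
    (root, _h), = nodes.values()
    return root


def island_dendrogram(matrix, metric: str = "jaccard",
                      linkage_method: str = "average") -> TreeNode:
    """Similarity tree of genomes from their island presence profiles.

    Default distance is Jaccard on the 0/1 rows with UPGMA (average)
    linkage; genomes with identical profiles join at height 0.  The result
    is a TreeNode whose leaves are the genome ids, comparable to the core
    phylogeny via :func:`panforge.phylo.rf_distance`.
    """
    if matrix.shape[0] < 3:
        raise ValueError("dendrogram needs at least 3 genomes")
    labels = list(matrix.index)
    values = matrix.to_numpy(dtype=bool)
    dist = pdist(values, metric=metric)
    dist = np.nan_to_num(dist, nan=0.0)  # all-zero profiles are identical
    if linkage_method != "average":
        from scipy.cluster.hierarchy import linkage as _linkage
        lk = _linkage(dist, method=linkage_method)
    else:
        lk = average(dist)
    return _linkage_to_tree(lk, labels)


def write_bed(islands: list[GenomicIsland], path) -> None:
    """Write islands as BED (0-based half-open start, as BED requires)."""
    with open(path, "w") as fh:
        for isl in islands:
            fh.write(f"{isl.replicon_id}\t{isl.span[0] - 1}\t{isl.span[1]}\t"
                     f"{isl.island_id}\t{len(isl.genes)}\t.\n")


def write_gc_track(track: GcTrack, path) -> None:
    """Wiggle-like track: fixed-step window start -> ratio."""
    with open(path, "w") as fh:
        fh.write(f"#replicon={track.replicon_id} window={track.window} "
                 f"step={track.step} mean_gc={track.genome_mean_gc:.4f}\n")
        for s, r in zip(track.starts, track.ratio):
            fh.write(f"{int(s)}\t{r:.4f}\n")
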