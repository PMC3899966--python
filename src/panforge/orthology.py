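"""Pairwise protein comparison and bidirectional-best-hit orthology.

Orthology between two genomes follows the classic reciprocal-best-hit rule:
two genes are orthologs when each encodes the best-scoring hit of the other
and the alignment reaches at least 40% amino-acid identity over at least
80% of the length of the smaller protein.  Multi-genome families are
connected components of the BBH graph (a strict-clique refinement is
available).  Annotation transfer uses the stricter 80% identity / 70%
shortest-length rule.

Alignment is local Smith-Waterman with BLOSUM62 and affine gaps
(open 11, extend 1).  Identity is counted over aligned columns with gaps
excluded; coverage is the aligned span of the shorter protein divided by
its length.  A shared 4-mer prefilter shortlists candidate subjects so
all-vs-all comparisons of desk-scale proteomes stay fast; the filter is
symmetric, so reciprocal-best symmetry is preserved.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from Bio.Align import PairwiseAligner, substitution_matrices

from .errors import InvalidStateError
from .io import GenomeRecord

__all__ = ["AlignmentHit", "BBHEdge", "OrthologFamily", "make_aligner",
           "align_pair", "best_hits", "build_families", "detect_paralogs",
           "transfer_annotation"]

GeneRef = tuple[str, str]  # (genome_id, locus_tag)

_KMER = 4
_MIN_SHARED_KMERS = 2


@dataclass(frozen=True)
class AlignmentHit:
    """One local alignment between two proteins."""

    query: str
    subject: str
    score: float
    identity: float           # identical / aligned columns (gaps excluded)
    coverage_shortest: float  # aligned span of shorter protein / its length


@dataclass(frozen=True)
class BBHEdge:
    """A reciprocal best hit between genes of two different genomes."""

    gene_a: GeneRef
    gene_b: GeneRef
    hit: AlignmentHit


@dataclass
class OrthologFamily:
    """A multi-genome gene family from the BBH graph."""

    family_id: str
    members: frozenset[GeneRef]
    genome_profile: dict[str, int]
    non_clique: bool = False  # component is not a complete BBH clique

    @property
    def genomes(self) -> frozenset[str]:
        return frozenset(self.genome_profile)


def make_aligner() -> PairwiseAligner:
    """Local BLOSUM62 aligner, gap open 11 / extend 1."""
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def align_pair(protein_a: str, protein_b: str,
               aligner: PairwiseAligner | None = None,
               query: str = "query", subject: str = "subject"
               ) -> AlignmentHit:
    """Align two proteins and report score, identity and coverage.

    Swapping the arguments yields equal identity and coverage: the pair is
    aligned in a canonical orientation internally.
    """
    if not protein_a or not protein_b:
        raise ValueError("empty protein sequence")
    if aligner is None:
        aligner = make_aligner()
    swapped = (len(protein_b), protein_b) < (len(protein_a), protein_a)
    sa, sb = (protein_b, protein_a) if swapped else (protein_a, protein_b)
    alns = aligner.align(sa, sb)
    if alns.score <= 0:  # no positive-scoring local alignment exists
        return AlignmentHit(query=query, subject=subject, score=0.0,
                            identity=0.0, coverage_shortest=0.0)
    aln = alns[0]
    counts = aln.counts()
    aligned_cols = counts.identities + counts.mismatches
    identity = counts.identities / aligned_cols if aligned_cols else 0.0
    short_len = min(len(sa), len(sb))
    which = 0 if len(sa) <= len(sb) else 1
    blocks = aln.aligned[which]
    span = (int(blocks[-1][1]) - int(blocks[0][0])) if len(blocks) else 0
    coverage = span / short_len
    return AlignmentHit(query=query, subject=subject, score=float(aln.score),
                        identity=identity, coverage_shortest=coverage)


def _kmer_set(seq: str, k: int = _KMER) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def _candidate_map(proteins_a: dict[str, str], proteins_b: dict[str, str]
                   ) -> dict[str, list[str]]:
    """For each protein of A, subjects of B sharing >= 2 4-mers."""
    index: dict[str, list[str]] = {}
    for tag, seq in proteins_b.items():
        for kmer in _kmer_set(seq):
            index.setdefault(kmer, []).append(tag)
    out: dict[str, list[str]] = {}
    for tag, seq in proteins_a.items():
        shared: dict[str, int] = {}
        for kmer in _kmer_set(seq):
            for other in index.get(kmer, ()):
                shared[other] = shared.get(other, 0) + 1
        out[tag] = sorted(t for t, n in shared.items()
                          if n >= _MIN_SHARED_KMERS)
    return out


def _best_subject(tag: str, candidates: list[str],
                  proteins_q: dict[str, str], proteins_s: dict[str, str],
                  scores: dict[tuple[str, str], float],
                  aligner: PairwiseAligner) -> str | None:
    """Best-scoring subject; ties broken by higher identity, then tag."""
    if not candidates:
        return None
    best_score = max(scores[(tag, c)] for c in candidates)
    tied = [c for c in candidates if scores[(tag, c)] == best_score]
    if len(tied) == 1:
        return tied[0]
    ranked = sorted(
        tied,
        key=lambda c: (-align_pair(proteins_q[tag], proteins_s[c],
                                   aligner).identity, c))
    return ranked[0]


def best_hits(genome_a: GenomeRecord, genome_b: GenomeRecord,
              min_identity: float = 0.40, min_coverage: float = 0.80,
              aligner: PairwiseAligner | None = None) -> list[BBHEdge]:
    """Reciprocal best hits between two genomes, threshold-filtered.

    An edge is emitted iff each gene is the best hit of the other and the
    alignment reaches ``identity >= min_identity`` and
    ``coverage_shortest >= min_coverage`` (both inclusive).  Symmetric in
    its arguments.
    """
    if genome_a.genome_id == genome_b.genome_id:
        raise ValueError("cannot compute best hits of a genome against itself")
    if genome_b.genome_id < genome_a.genome_id:
        genome_a, genome_b = genome_b, genome_a
    if aligner is None:
        aligner = make_aligner()
    pa, pb = genome_a.proteins(), genome_b.proteins()
    cand_ab = _candidate_map(pa, pb)
    cand_ba: dict[str, list[str]] = {t: [] for t in pb}
    for ta, subjects in cand_ab.items():
        for tb in subjects:
            cand_ba[tb].append(ta)
    for tb in cand_ba:
        cand_ba[tb].sort()

    scores: dict[tuple[str, str], float] = {}
    for ta, subjects in cand_ab.items():
        for tb in subjects:
            scores[(ta, tb)] = float(aligner.score(pa[ta], pb[tb]))
    rev_scores = {(tb, ta): s for (ta, tb), s in scores.items()}

    best_ab = {ta: _best_subject(ta, cand_ab[ta], pa, pb, scores, aligner)
               for ta in pa}
    best_ba = {tb: _best_subject(tb, cand_ba[tb], pb, pa, rev_scores, aligner)
               for tb in pb}

    edges: list[BBHEdge] = []
    for ta in sorted(pa):
        tb = best_ab[ta]
        if tb is None or best_ba[tb] != ta:
            continue
        hit = align_pair(pa[ta], pb[tb], aligner, query=ta, subject=tb)
        if hit.identity >= min_identity and \
                hit.coverage_shortest >= min_coverage:
            edges.append(BBHEdge(gene_a=(genome_a.genome_id, ta),
                                 gene_b=(genome_b.genome_id, tb), hit=hit))
    return edges


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[GeneRef, GeneRef] = {}

    def add(self, x: GeneRef) -> None:
        self.parent.setdefault(x, x)

    def find(self, x: GeneRef) -> GeneRef:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: GeneRef, b: GeneRef) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra


def build_families(edges_by_pair: dict[frozenset[str], list[BBHEdge]],
                   genomes: dict[str, GenomeRecord],
                   clique: bool = False) -> list[OrthologFamily]:
    """Group genes into families as connected components of the BBH graph.

    ``edges_by_pair`` must contain an entry (possibly empty) for every
    unordered pair of genomes.  Genes without any edge become single-member
    families.  Family ids are assigned in lexicographic order of each
    family's smallest member, so re-runs over the same input are stable.

    With ``clique=True``, each component is greedily refined into cliques:
    members are taken in sorted order and attached to the first group they
    are BBH-linked to in full.
    """
    gids = sorted(genomes)
    missing = [frozenset(p) for p in itertools.combinations(gids, 2)
               if frozenset(p) not in edges_by_pair]
    if missing:
        raise InvalidStateError(
            "missing BBH comparisons: " +
            ", ".join(sorted("/".join(sorted(p)) for p in missing)))

    uf = _UnionFind()
    adjacency: dict[GeneRef, set[GeneRef]] = {}
    for gid, genome in genomes.items():
        for tag in genome.proteins():
            uf.add((gid, tag))
    for pair_edges in edges_by_pair.values():
        for e in pair_edges:
            uf.add(e.gene_a)
            uf.add(e.gene_b)
            uf.union(e.gene_a, e.gene_b)
            adjacency.setdefault(e.gene_a, set()).add(e.gene_b)
            adjacency.setdefault(e.gene_b, set()).add(e.gene_a)

    components: dict[GeneRef, list[GeneRef]] = {}
    for ref in uf.parent:
        components.setdefault(uf.find(ref), []).append(ref)

    groups: list[list[GeneRef]] = []
    for root in sorted(components):
        members = sorted(components[root])
        if not clique or len(members) <= 2:
            groups.append(members)
            continue
        cliques: list[list[GeneRef]] = []
        for ref in members:
            placed = False
            for cl in cliques:
                if all(other in adjacency.get(ref, ()) for other in cl):
                    cl.append(ref)
                    placed = True
                    break
            if not placed:
                cliques.append([ref])
        groups.extend(cliques)

    groups.sort(key=lambda g: g[0])
    families: list[OrthologFamily] = []
    for i, members in enumerate(groups):
        profile: dict[str, int] = {}
        for gid, _tag in members:
            profile[gid] = profile.get(gid, 0) + 1
        n = len(members)
        n_edges = sum(1 for a, b in itertools.combinations(members, 2)
                      if b in adjacency.get(a, ()))
        non_clique = n > 2 and n_edges < n * (n - 1) // 2
        families.append(OrthologFamily(
            family_id=f"FAM{i + 1:05d}", members=frozenset(members),
            genome_profile=profile, non_clique=non_clique))
    return families


def detect_paralogs(genome: GenomeRecord, min_identity: float = 0.40,
                    min_coverage: float = 0.80,
                    aligner: PairwiseAligner | None = None
                    ) -> list[tuple[str, str]]:
    """Within-genome gene pairs above the paralogy identity threshold.

    A pair qualifies when identity is strictly greater than ``min_identity``
    (the field convention for ">40% amino acid identity") with the same
    shortest-length coverage rule as BBH search.
    """
    if aligner is None:
        aligner = make_aligner()
    proteins = genome.proteins()
    cand = _candidate_map(proteins, proteins)
    pairs: list[tuple[str, str]] = []
    for ta in sorted(proteins):
        for tb in cand[ta]:
            if tb <= ta:
                continue
            hit = align_pair(proteins[ta], proteins[tb], aligner, ta, tb)
            if hit.identity > min_identity and \
                    hit.coverage_shortest >= min_coverage:
                pairs.append((ta, tb))
    return pairs


def paralog_counts(pairs: list[tuple[str, str]]) -> dict[str, int]:
    """Number of paralogs per gene."""
    out: dict[str, int] = {}
    for a, b in pairs:
        out[a] = out.get(a, 0) + 1
        out[b] = out.get(b, 0) + 1
    return out


def transfer_annotation(source: GenomeRecord, target: GenomeRecord,
                        min_identity: float = 0.80,
                        min_len_fraction: float = 0.70,
                        aligner: PairwiseAligner | None = None
                        ) -> dict[str, str]:
    """Inherit annotations from best source hits above transfer thresholds.

    A target gene takes the annotation of its best-scoring source hit iff
    the alignment reaches 80% identity over at least 70% of the length of
    the smaller protein (defaults); otherwise it is labeled
    ``"unannotated"``.
    """
    if aligner is None:
        aligner = make_aligner()
    pt, ps = target.proteins(), source.proteins()
    ann = {g.locus_tag: g.annotation for g in source.genes
           if g.feature_type == "gene"}
    cand = _candidate_map(pt, ps)
    scores = {(ta, tb): float(aligner.score(pt[ta], ps[tb]))
              for ta, subjects in cand.items() for tb in subjects}
    out: dict[str, str] = {}
    for ta in sorted(pt):
        best = _best_subject(ta, cand[ta], pt, ps, scores, aligner)
        if best is None:
            out[ta] = "unannotated"
            continue
        hit = align_pair(pt[ta], ps[best], aligner, ta, best)
        if hit.identity >= min_identity and \
                hit.coverage_shortest >= min_len_fraction:
            out[ta] = ann[best] or "unannotated"
        else:
            out[ta] = "unannotated"
    return out


def write_edge_table(edges: list[BBHEdge], path) -> None:
    """Tab-delimited ``gene_a gene_b score identity coverage``."""
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tscore\tidentity\tcoverage\n")
        for e in edges:
            fh.write(f"{e.gene_a[0]}:{e.gene_a[1]}\t"
                     f"{e.gene_b[0]}:{e.gene_b[1]}\t"
                     f"{e.hit.score:.1f}\t{e.hit.identity:.4f}\t"
                     f"{e.hit.coverage_shortest:.4f}\n")


def write_family_table(families: list[OrthologFamily], path) -> None:
    """Tab-delimited ``family_id genome locus_tag``."""
    with open(path, "w") as fh:
        fh.write("family_id\tgenome\tlocus_tag\n")
        for fam in families:
            for gid, tag in sorted(fam.members):
                fh.write(f"{fam.family_id}\t{gid}\t{tag}\n")
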