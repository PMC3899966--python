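"""Pan-genome partitioning and presence/absence analyses.

Families are classed as *core* (present in every genome), *dispensable*
(present in at least two genomes but not all) or *strain-specific*
(present in exactly one); the three classes partition the pan-genome.
Built on top of the ortholog families from :mod:`panforge.orthology`.

Counts are of families by default; per-gene counts (summing member genes,
including in-paralogs) are available via ``unit="genes"`` where offered.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .orthology import OrthologFamily

__all__ = ["PangenomePartition", "PhyloProfileQuery", "partition",
           "venn_cells", "accumulation_curves", "phyloprofile",
           "specific_vs_distance", "presence_matrix"]

MAX_VENN_GENOMES = 12


@dataclass
class PangenomePartition:
    core: set[str]
    dispensable: set[str]
    specific: dict[str, set[str]]  # genome -> family ids
    pangenome_size: int
    genomes: list[str] = field(default_factory=list)

    @property
    def specific_total(self) -> int:
        return sum(len(v) for v in self.specific.values())


@dataclass(frozen=True)
class PhyloProfileQuery:
    """Presence/absence query: families in all of ``present_in`` and none
    of ``absent_from``."""

    present_in: frozenset[str]
    absent_from: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.present_in:
            raise ValueError("present_in must be nonempty")
        if self.present_in & self.absent_from:
            raise ValueError("present_in and absent_from overlap")


def _family_index(families: list[OrthologFamily]) -> dict[str, frozenset[str]]:
    return {f.family_id: f.genomes for f in families}


def partition(families: list[OrthologFamily],
              genomes: list[str]) -> PangenomePartition:
    """Assign every family to core / dispensable / strain-specific."""
    genome_set = set(genomes)
    core: set[str] = set()
    dispensable: set[str] = set()
    specific: dict[str, set[str]] = {g: set() for g in sorted(genome_set)}
    for fam in families:
        present = fam.genomes & genome_set
        if not present:
            continue
        if present == genome_set:
            core.add(fam.family_id)
        elif len(present) == 1:
            specific[next(iter(present))].add(fam.family_id)
        else:
            dispensable.add(fam.family_id)
    size = len(core) + len(dispensable) + sum(
        len(v) for v in specific.values())
    return PangenomePartition(core=core, dispensable=dispensable,
                              specific=specific, pangenome_size=size,
                              genomes=sorted(genome_set))


def venn_cells(families: list[OrthologFamily], genomes: list[str],
               unit: str = "families") -> dict[frozenset[str], int]:
    """Count families (or genes) per exact genome-presence subset.

    Every family lands in exactly one cell: the subset of genomes it is
    present in.  Cell counts sum to the pan-genome size.  Refuses more than
    12 genomes (2^n - 1 cells become uninterpretable); for larger sets use
    :func:`partition` or :func:`presence_matrix`.
    """
    if len(genomes) > MAX_VENN_GENOMES:
        raise ValueError(
            f"venn_cells supports at most {MAX_VENN_GENOMES} genomes "
            f"(got {len(genomes)}); use partition() or presence_matrix()")
    genome_set = set(genomes)
    cells: dict[frozenset[str], int] = {}
    for fam in families:
        present = frozenset(fam.genomes & genome_set)
        if not present:
            continue
        weight = 1 if unit == "families" else sum(
            fam.genome_profile.get(g, 0) for g in present)
        cells[present] = cells.get(present, 0) + weight
    return cells


def accumulation_curves(families: list[OrthologFamily],
                        genome_order: list[str]
                        ) -> tuple[list[int], list[int]]:
    """Core and pan counts for each prefix of ``genome_order``."""
    idx = _family_index(families)
    core_counts: list[int] = []
    pan_counts: list[int] = []
    for i in range(1, len(genome_order) + 1):
        prefix = set(genome_order[:i])
        core = sum(1 for fams in idx.values() if prefix <= fams)
        pan = sum(1 for fams in idx.values() if fams & prefix)
        core_counts.append(core)
        pan_counts.append(pan)
    return core_counts, pan_counts


def mean_accumulation_curves(families: list[OrthologFamily],
                             genomes: list[str], permutations: int,
                             seed: int) -> dict[str, np.ndarray]:
    """Accumulation curves averaged over random genome orders (fixed seed).

    Returns mean and standard deviation arrays for both curves.  The
    single-order curve is the primary view; averaging is an extension and
    is labeled as such in outputs.
    """
    rng = np.random.default_rng(seed)
    cores, pans = [], []
    for _ in range(permutations):
        order = list(rng.permutation(genomes))
        c, p = accumulation_curves(families, order)
        cores.append(c)
        pans.append(p)
    cores_arr, pans_arr = np.array(cores), np.array(pans)
    return {"core_mean": cores_arr.mean(axis=0),
            "core_sd": cores_arr.std(axis=0),
            "pan_mean": pans_arr.mean(axis=0),
            "pan_sd": pans_arr.std(axis=0)}


def phyloprofile(families: list[OrthologFamily],
                 query: PhyloProfileQuery,
                 known_genomes: set[str] | None = None) -> set[str]:
    """Families present in every ``present_in`` genome and absent from
    every ``absent_from`` genome."""
    if known_genomes is not None:
        unknown = (query.present_in | query.absent_from) - known_genomes
        if unknown:
            raise ValueError(f"unknown genome ids: {sorted(unknown)}")
    out: set[str] = set()
    for fam in families:
        if query.present_in <= fam.genomes and \
                not (query.absent_from & fam.genomes):
            out.add(fam.family_id)
    return out


def specific_vs_distance(part: PangenomePartition,
                         families: list[OrthologFamily],
                         distances: dict[str, float],
                         reference: str) -> tuple[float, dict[str, dict]]:
    """R-squared between distance-to-reference and reference-absent genes.

    For each non-reference genome, counts the families it carries that have
    no member in the reference genome, and regresses that count on the
    genome's distance to the reference (ordinary least squares).  Returns
    the R-squared and the per-genome table.  A constant count yields 0.0.
    """
    others = [g for g in part.genomes if g != reference]
    if len(others) < 3:
        raise ValueError("need at least 3 non-reference genomes")
    counts: dict[str, int] = {g: 0 for g in others}
    for fam in families:
        if reference in fam.genomes:
            continue
        for g in fam.genomes:
            if g in counts:
                counts[g] += 1
    x = np.array([distances[g] for g in others], dtype=float)
    y = np.array([counts[g] for g in others], dtype=float)
    if np.allclose(y, y[0]) or np.allclose(x, x[0]):
        r2 = 0.0
    else:
        r = np.corrcoef(x, y)[0, 1]
        r2 = float(r * r)
    table = {g: {"distance": float(distances[g]), "specific_count": counts[g]}
             for g in others}
    return r2, table


def presence_matrix(families: list[OrthologFamily],
                    genomes: list[str]):
    """families x genomes 0/1 DataFrame (1 = at least one member)."""
    import pandas as pd
    gids = sorted(genomes)
    data = {g: [1 if g in f.genomes else 0 for f in families] for g in gids}
    return pd.DataFrame(data, index=[f.family_id for f in families])
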