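"""End-to-end orchestration: orthology -> pangenome -> phylogeny ->
islands -> metabolism, with a reproducible manifest.

``run_all`` reads a directory of per-genome files (``<id>.faa``,
``<id>.fna``, ``<id>.gff``, optional ``phenotypes.tsv``, optional
``reactions.tsv``/``pathways.tsv`` for the metabolism stage), executes the
requested stages with the configured thresholds, writes per-stage tables
under the output directory and finishes with ``manifest.json`` recording
parameters, seeds and the SHA-256 of every output file.  Identical inputs
and config produce a byte-identical manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .errors import PanforgeError
from .io import GenomeRecord, read_genome, read_phenotype_table, write_newick
from .orthology import (best_hits, build_families, write_edge_table,
                        write_family_table)
from .pangenome import (accumulation_curves, partition, presence_matrix,
                        venn_cells)
from .phylo import (bootstrap, concatenate, distance_matrix,
                    neighbor_joining, rf_distance, bipartitions)
from .islands import (annotate_island, find_rgp, gc_deviation,
                      island_dendrogram, island_matrix, write_bed)
from .metabolism import (cluster_pathways, completion_matrix,
                         filter_representation, pca, read_pathway_definitions,
                         read_reaction_table)

__all__ = ["RunConfig", "run_all", "compare_trees_report", "load_genome_dir"]

ALL_STAGES = ("orthology", "pangenome", "phylo", "islands", "metabolism")


@dataclass
class RunConfig:
    """Parameters for one pipeline run; defaults are the field-standard
    thresholds (40%/80% BBH, 5 kbp islands, 1 kb GC windows, 100
    bootstraps, representation 0.75, 7 pathway classes)."""

    input_dir: str | Path = "."
    output_dir: str | Path = "out"
    min_identity: float = 0.40
    min_coverage: float = 0.80
    rgp_min_span: int = 5000
    gc_window: int = 1000
    gc_step: int = 200
    bootstrap: int = 100
    pca_k: int = 7
    representation: float = 0.75
    distance_model: str = "jc"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES

    def __post_init__(self) -> None:
        for name in ("min_identity", "min_coverage", "rgp_min_span",
                     "gc_window", "gc_step", "representation", "pca_k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["input_dir"] = str(d["input_dir"])
        d["output_dir"] = str(d["output_dir"])
        d["stages"] = list(d["stages"])
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)


def load_genome_dir(input_dir: str | Path) -> dict[str, GenomeRecord]:
    """Load every ``<id>.gff`` + ``<id>.faa`` + ``<id>.fna`` triple."""
    input_dir = Path(input_dir)
    phen = input_dir / "phenotypes.tsv"
    genomes: dict[str, GenomeRecord] = {}
    for gff in sorted(input_dir.glob("*.gff")):
        gid = gff.stem
        faa, fna = input_dir / f"{gid}.faa", input_dir / f"{gid}.fna"
        if not (faa.exists() and fna.exists()):
            raise PanforgeError(f"genome {gid}: missing {faa.name} or "
                                f"{fna.name}")
        genomes[gid] = read_genome(faa, gff, fna,
                                   phen if phen.exists() else None,
                                   genome_id=gid)
    if not genomes:
        raise PanforgeError(f"no genomes found in {input_dir}")
    return genomes


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def compare_trees_report(core_tree, island_tree) -> dict:
    """Side-by-side discordance summary of two trees on the same leaves.

    Returns the two Newick strings, the Robinson-Foulds distance and the
    bipartitions present in exactly one tree.
    """
    leaves_a = {t.name for t in core_tree.tips()}
    leaves_b = {t.name for t in island_tree.tips()}
    if leaves_a != leaves_b:
        raise ValueError(f"leaf sets differ: {sorted(leaves_a ^ leaves_b)}")
    splits_a, splits_b = bipartitions(core_tree), bipartitions(island_tree)
    conflicts = sorted(
        ["|".join(sorted(s)) for s in splits_a ^ splits_b])
    return {
        "core_tree": write_newick(core_tree),
        "island_tree": write_newick(island_tree),
        "rf_distance": rf_distance(core_tree, island_tree),
        "conflicting_bipartitions": conflicts,
    }


def run_all(config: RunConfig) -> dict:
    """Execute the configured stages and write a reproducible report bundle.

    Returns the manifest dictionary (also written to ``manifest.json``).
    On a stage failure the exception is re-raised with the stage name and
    a ``FAILED`` marker file is left in the output directory.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    stage_status: dict[str, str] = {}
    current = "load"
    try:
        genomes = load_genome_dir(config.input_dir)
        gids = sorted(genomes)

        families = None
        part = None
        core_tree = None
        dendro = None

        if "orthology" in config.stages:
            current = "orthology"
            edges = {}
            for a, b in itertools.combinations(gids, 2):
                edges[frozenset((a, b))] = best_hits(
                    genomes[a], genomes[b],
                    min_identity=config.min_identity,
                    min_coverage=config.min_coverage)
            all_edges = [e for pair in sorted(edges, key=sorted)
                         for e in edges[pair]]
            write_edge_table(all_edges, out / "bbh_edges.tsv")
            outputs["bbh_edges"] = out / "bbh_edges.tsv"
            families = build_families(edges, genomes)
            write_family_table(families, out / "families.tsv")
            outputs["families"] = out / "families.tsv"
            stage_status["orthology"] = "ok"

        if "pangenome" in config.stages:
            current = "pangenome"
            if families is None:
                raise PanforgeError("pangenome stage requires orthology")
            part = partition(families, gids)
            with open(out / "partition.tsv", "w") as fh:
                fh.write("class\tgenome\tcount\n")
                fh.write(f"core\t-\t{len(part.core)}\n")
                fh.write(f"dispensable\t-\t{len(part.dispensable)}\n")
                for g in gids:
                    fh.write(f"specific\t{g}\t{len(part.specific[g])}\n")
                fh.write(f"pangenome\t-\t{part.pangenome_size}\n")
            outputs["partition"] = out / "partition.tsv"
            if len(gids) <= 12:
                cells = venn_cells(families, gids)
                with open(out / "venn_cells.tsv", "w") as fh:
                    fh.write("genome_subset\tfamilies\n")
                    for subset in sorted(cells, key=lambda s: (len(s),
                                                               sorted(s))):
                        fh.write(f"{','.join(sorted(subset))}\t"
                                 f"{cells[subset]}\n")
                outputs["venn_cells"] = out / "venn_cells.tsv"
            core_c, pan_c = accumulation_curves(families, gids)
            with open(out / "accumulation.tsv", "w") as fh:
                fh.write("prefix\tgenome\tcore\tpan\n")
                for i, g in enumerate(gids):
                    fh.write(f"{i + 1}\t{g}\t{core_c[i]}\t{pan_c[i]}\n")
            outputs["accumulation"] = out / "accumulation.tsv"
            presence_matrix(families, gids).to_csv(
                out / "presence_matrix.tsv", sep="\t")
            outputs["presence_matrix"] = out / "presence_matrix.tsv"
            stage_status["pangenome"] = "ok"

        if "phylo" in config.stages:
            current = "phylo"
            if part is None:
                raise PanforgeError("phylo stage requires pangenome")
            fam_by_id = {f.family_id: f for f in families}
            core_single = [fam_by_id[fid] for fid in sorted(part.core)
                           if max(fam_by_id[fid].genome_profile.values()) == 1]
            aln = concatenate(core_single, genomes,
                              seq_source="nucleotide"
                              if config.distance_model == "jc"
                              else "protein")
            dm = distance_matrix(aln, model=config.distance_model)
            with open(out / "core_distances.tsv", "w") as fh:
                fh.write(f"{len(dm.taxa)}\n")
                for i, t in enumerate(dm.taxa):
                    row = " ".join(f"{x:.6f}" for x in dm.d[i])
                    fh.write(f"{t} {row}\n")
            outputs["core_distances"] = out / "core_distances.tsv"
            core_tree, _support = bootstrap(
                aln, replicates=config.bootstrap, seed=config.seed,
                model=config.distance_model)
            (out / "core_tree.nwk").write_text(write_newick(core_tree) + "\n")
            outputs["core_tree"] = out / "core_tree.nwk"
            stage_status["phylo"] = "ok"

        if "islands" in config.stages:
            current = "islands"
            if families is None:
                raise PanforgeError("islands stage requires orthology")
            all_islands = []
            for gid in gids:
                comp = [genomes[g] for g in gids if g != gid]
                found = find_rgp(genomes[gid], comp, families,
                                 min_span=config.rgp_min_span)
                genome_seq = "".join(genomes[gid].replicons.values())
                mean_gc = (sum(b in "GC" for b in genome_seq)
                           / len(genome_seq))
                tracks = {rid: gc_deviation(seq, rid,
                                            window=config.gc_window,
                                            step=config.gc_step,
                                            genome_mean_gc=mean_gc)
                          for rid, seq in genomes[gid].replicons.items()
                          if len(seq) >= config.gc_window}
                for isl in found:
                    annotate_island(isl, genomes[gid],
                                    tracks.get(isl.replicon_id))
                all_islands.extend(found)
            write_bed(all_islands, out / "islands.bed")
            outputs["islands_bed"] = out / "islands.bed"
            matrix, clusters = island_matrix(all_islands, families, gids)
            matrix.to_csv(out / "island_matrix.tsv", sep="\t")
            outputs["island_matrix"] = out / "island_matrix.tsv"
            with open(out / "island_clusters.tsv", "w") as fh:
                fh.write("cluster\tisland\n")
                for cid in sorted(clusters):
                    for member in clusters[cid]:
                        fh.write(f"{cid}\t{member}\n")
            outputs["island_clusters"] = out / "island_clusters.tsv"
            if len(gids) >= 3 and matrix.shape[1] > 0:
                dendro = island_dendrogram(matrix)
                (out / "island_dendrogram.nwk").write_text(
                    write_newick(dendro) + "\n")
                outputs["island_dendrogram"] = out / "island_dendrogram.nwk"
            stage_status["islands"] = "ok"

        if "metabolism" in config.stages:
            current = "metabolism"
            rxn = Path(config.input_dir) / "reactions.tsv"
            pwy = Path(config.input_dir) / "pathways.tsv"
            if rxn.exists() and pwy.exists():
                cm = completion_matrix(read_reaction_table(rxn),
                                       read_pathway_definitions(pwy))
                cm.values.to_csv(out / "completion_matrix.tsv", sep="\t")
                outputs["completion_matrix"] = out / "completion_matrix.tsv"
                result = pca(cm)
                result.scores.to_csv(out / "pca_scores.tsv", sep="\t")
                result.loadings.to_csv(out / "pca_loadings.tsv", sep="\t")
                outputs["pca_scores"] = out / "pca_scores.tsv"
                outputs["pca_loadings"] = out / "pca_loadings.tsv"
                kept = filter_representation(
                    result, threshold=config.representation)
                k = min(config.pca_k, len(kept))
                classes = cluster_pathways(result, k=k, pathways=kept) \
                    if k >= 1 and len(kept) >= k else {}
                with open(out / "pathway_classes.tsv", "w") as fh:
                    fh.write("pathway\tclass\n")
                    for p in sorted(classes):
                        fh.write(f"{p}\t{classes[p]}\n")
                outputs["pathway_classes"] = out / "pathway_classes.tsv"
                stage_status["metabolism"] = "ok"
            else:
                stage_status["metabolism"] = "skipped (no reaction tables)"

        if core_tree is not None and dendro is not None:
            report = compare_trees_report(core_tree, dendro)
            with open(out / "tree_comparison.json", "w") as fh:
                json.dump(report, fh, indent=2, sort_keys=True)
            outputs["tree_comparison"] = out / "tree_comparison.json"

    except Exception as exc:
        (out / "FAILED").write_text(f"stage {current}: {exc}\n")
        raise PanforgeError(f"stage {current} failed: {exc}") from exc

    manifest = {
        "panforge_version": __version__,
        "parameters": config.to_dict(),
        "stages": stage_status,
        "genomes": sorted(load_genome_dir(config.input_dir)),
        "files": {name: {"path": str(path.name), "sha256": _sha256(path)}
                  for name, path in sorted(outputs.items())},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    failed = out / "FAILED"
    if failed.exists():
        failed.unlink()
    return manifest
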