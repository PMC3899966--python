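"""Readers and writers for the formats the pipeline touches.

Supported formats: protein/nucleotide FASTA (via Biopython), a GFF3 subset
(``gene`` and ``tRNA`` features, 1-based inclusive coordinates, ``+``/``-``
strand, ``ID=`` and optional ``product=`` attributes), Newick trees (via
scikit-bio), and a three-column tab-delimited phenotype table
(``genome_id<TAB>label<TAB>value``).

Coordinates are 1-based inclusive everywhere in this package; gene order is
by (replicon, start, locus_tag) and ignores strand.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import TreeNode

from .errors import FormatError

__all__ = [
    "GeneRecord",
    "GenomeRecord",
    "read_genome",
    "write_genome",
    "read_newick",
    "write_newick",
    "read_phenotype_table",
    "write_phenotype_table",
]


@dataclass
class GeneRecord:
    """One annotated feature: a protein-coding gene or a tRNA.

    ``protein`` is the amino-acid sequence and is non-empty exactly when
    ``feature_type == "gene"``.  ``annotation`` is a free-text product
    description (may be empty).
    """

    locus_tag: str
    replicon_id: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    strand: str  # "+" or "-"
    feature_type: str = "gene"  # "gene" | "tRNA"
    protein: str = ""
    annotation: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(
                f"{self.locus_tag}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise FormatError(f"{self.locus_tag}: bad strand {self.strand!r}")
        if self.feature_type not in ("gene", "tRNA"):
            raise FormatError(
                f"{self.locus_tag}: unsupported feature {self.feature_type!r}")
        if (self.feature_type == "gene") != bool(self.protein):
            raise FormatError(
                f"{self.locus_tag}: protein must be non-empty iff "
                f"feature_type is 'gene'")

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeRecord:
    """One genome: its replicon sequences, ordered genes and phenotype labels."""

    genome_id: str
    replicons: dict[str, str] = field(default_factory=dict)
    genes: list[GeneRecord] = field(default_factory=list)
    phenotype_labels: dict[str, str] = field(default_factory=dict)

    def sort_genes(self) -> None:
        """Order genes by (replicon, start, locus_tag); strand is ignored."""
        self.genes.sort(key=lambda g: (g.replicon_id, g.start, g.locus_tag))

    def validate(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.locus_tag in seen:
                raise FormatError(f"duplicate locus tag {g.locus_tag}")
            seen.add(g.locus_tag)
            if g.replicon_id not in self.replicons:
                raise FormatError(
                    f"{g.locus_tag}: unknown replicon {g.replicon_id}")
            if g.end > len(self.replicons[g.replicon_id]) or g.start < 1:
                raise FormatError(
                    f"{g.locus_tag}: coordinates [{g.start}, {g.end}] outside "
                    f"replicon {g.replicon_id} "
                    f"(length {len(self.replicons[g.replicon_id])})")

    def proteins(self) -> dict[str, str]:
        """locus_tag -> protein for coding genes."""
        return {g.locus_tag: g.protein for g in self.genes
                if g.feature_type == "gene"}

    def gene_by_tag(self, tag: str) -> GeneRecord:
        for g in self.genes:
            if g.locus_tag == tag:
                return g
        raise KeyError(tag)

    def cds_nucleotide(self, gene: GeneRecord) -> str:
        """Coding-strand nucleotide sequence of a gene (revcomp for '-')."""
        seq = self.replicons[gene.replicon_id][gene.start - 1:gene.end]
        if gene.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq


def _parse_gff_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            raise FormatError(f"malformed GFF attribute {part!r}")
        k, v = part.split("=", 1)
        out[k] = v
    return out


def read_genome(protein_fasta: str | Path,
                gff: str | Path,
                nucleotide_fasta: str | Path,
                phenotype_table: str | Path | None = None,
                genome_id: str | None = None) -> GenomeRecord:
    """Assemble a :class:`GenomeRecord` from its on-disk files.

    Parameters
    ----------
    protein_fasta, gff, nucleotide_fasta
        Per-genome files; FASTA ids in ``protein_fasta`` must match the GFF
        ``ID=`` locus tags of ``gene`` features.
    phenotype_table
        Optional tab-delimited ``genome_id<TAB>label<TAB>value`` table; only
        rows for this genome are attached.
    genome_id
        Defaults to the stem of the GFF path.

    Raises
    ------
    FormatError
        On duplicate locus tags, coordinates outside their replicon, or a
        GFF gene with no matching protein.
    """
    gff = Path(gff)
    gid = genome_id or gff.stem
    replicons = {rec.id: str(rec.seq).upper()
                 for rec in SeqIO.parse(str(nucleotide_fasta), "fasta")}
    proteins = {rec.id: str(rec.seq)
                for rec in SeqIO.parse(str(protein_fasta), "fasta")}

    genes: list[GeneRecord] = []
    with open(gff) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"GFF line has {len(cols)} columns: {line!r}")
            seqid, _source, ftype, start, end, _score, strand, _phase, attrs = cols
            if ftype not in ("gene", "tRNA"):
                continue
            a = _parse_gff_attributes(attrs)
            if "ID" not in a:
                raise FormatError(f"GFF feature without ID: {line!r}")
            tag = a["ID"]
            protein = proteins.get(tag, "") if ftype == "gene" else ""
            if ftype == "gene" and not protein:
                raise FormatError(f"gene {tag} has no protein in FASTA")
            genes.append(GeneRecord(
                locus_tag=tag, replicon_id=seqid,
                start=int(start), end=int(end), strand=strand,
                feature_type=ftype, protein=protein,
                annotation=a.get("product", "")))

    genome = GenomeRecord(genome_id=gid, replicons=replicons, genes=genes)
    genome.sort_genes()
    genome.validate()

    unmatched = set(proteins) - {g.locus_tag for g in genes}
    if unmatched:
        import warnings
        warnings.warn(f"{gid}: {len(unmatched)} proteins not in GFF: "
                      f"{sorted(unmatched)[:5]}...")

    if phenotype_table is not None:
        table = read_phenotype_table(phenotype_table)
        genome.phenotype_labels = dict(table.get(gid, {}))
    return genome


def write_genome(genome: GenomeRecord, out_dir: str | Path) -> dict[str, Path]:
    """Write ``<id>.faa``, ``<id>.fna`` and ``<id>.gff`` under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gid = genome.genome_id
    faa = out_dir / f"{gid}.faa"
    fna = out_dir / f"{gid}.fna"
    gff = out_dir / f"{gid}.gff"

    prot_records = [SeqRecord(Seq(g.protein), id=g.locus_tag, description="")
                    for g in genome.genes if g.feature_type == "gene"]
    SeqIO.write(prot_records, str(faa), "fasta")
    nuc_records = [SeqRecord(Seq(seq), id=rid, description="")
                   for rid, seq in sorted(genome.replicons.items())]
    SeqIO.write(nuc_records, str(fna), "fasta")

    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genome.genes:
            attrs = f"ID={g.locus_tag}"
            if g.annotation:
                attrs += f";product={g.annotation}"
            fh.write("\t".join([
                g.replicon_id, "panforge", g.feature_type,
                str(g.start), str(g.end), ".", g.strand, ".", attrs]) + "\n")
    return {"protein_fasta": faa, "nucleotide_fasta": fna, "gff": gff}


def read_newick(text_or_path: str | Path) -> TreeNode:
    """Parse a Newick string (or file path) into a TreeNode."""
    text = str(text_or_path)
    if "(" not in text:  # looks like a path
        text = Path(text_or_path).read_text()
    try:
        return TreeNode.read(_io.StringIO(text), format="newick")
    except Exception as exc:  # skbio raises its own parse errors
        raise FormatError(f"malformed Newick: {exc}") from exc


def write_newick(tree: TreeNode) -> str:
    buf = _io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def read_phenotype_table(path: str | Path) -> dict[str, dict[str, str]]:
    """Read ``genome_id<TAB>label<TAB>value`` rows -> nested mapping."""
    out: dict[str, dict[str, str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 3:
                raise FormatError(f"phenotype row needs 3 columns: {line!r}")
            gid, label, value = cols
            out.setdefault(gid, {})[label] = value
    return out


def write_phenotype_table(labels: dict[str, dict[str, str]],
                          path: str | Path) -> None:
    with open(path, "w") as fh:
        for gid in sorted(labels):
            for label in sorted(labels[gid]):
                fh.write(f"{gid}\t{label}\t{labels[gid][label]}\n")
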