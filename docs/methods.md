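# Methods

## Scope and design

panforge is a desk-scale comparative-genomics pipeline for small clades
of related bacterial genomes. Its stages — BBH orthology, pan-genome
partitioning, genomic-island detection, core-genome distance phylogeny
and pathway-completion PCA — are classic methods; the package's
contribution is wiring them into one reproducible, fully testable stack
with a ground-truth simulator, so that every inference can be scored
against a known answer rather than eyeballed.

## Orthology

Pairwise comparison is local Smith–Waterman through Biopython's
`PairwiseAligner` with BLOSUM62 and affine gaps (open 11, extend 1) —
the scoring regime of classic BLASTP-era platforms. Identity is counted
over aligned columns with gaps excluded; coverage is the aligned span of
the shorter protein divided by its length (a literal reading of
"on X% of the length of the smallest protein"). Pairs are aligned in a
canonical orientation so identity and coverage are exactly symmetric.

`best_hits` emits an edge when two genes are mutually best-scoring and
the hit reaches identity ≥ 0.40 and coverage ≥ 0.80, both inclusive.
Score ties are broken by higher identity, then lexicographic locus tag,
making runs deterministic. Within-genome paralogy uses strict
inequality (> 0.40), matching the field convention ">40% amino acid
identity"; annotation transfer uses ≥ 0.80 identity over ≥ 0.70 of the
shorter protein.

A shared 4-mer prefilter (≥ 2 shared 4-mers) shortlists candidate
subjects before alignment. At the identity levels where BBH edges are
possible (≥ 40% over ≥ 80% of the protein) true homologs share many
4-mers, while the filter removes the quadratic bulk of hopeless pairs;
it is symmetric, so reciprocal-best symmetry is unaffected.

Multi-genome families are connected components of the BBH graph.
Pairwise BBH does not define families for more than two genomes; the
component rule reproduces "present in strictly all genomes" semantics
while a `clique=True` switch refines components greedily into mutually
connected groups for users who want the stricter reading. Components
that are not complete cliques are flagged (`non_clique`). Family ids are
assigned in lexicographic order of each family's smallest member, so
identical inputs give identical ids.

## Pan-genome

Counts are of families; a per-gene mode (summing members, including
in-paralogs) exists where the distinction matters (`unit="genes"` in
`venn_cells`). Venn cells are exact presence subsets and refuse > 12
genomes. Accumulation curves follow one stated genome order; averaging
over random permutations (fixed seed, mean ± sd) is offered as a clearly
separate function. The specific-genes-versus-distance statistic
regresses, for each non-reference genome, the number of its families
absent from the reference on its distance to the reference; R² is the
squared Pearson correlation, defined as 0 when either variable is
constant.

## Phylogeny

Single-copy core families are concatenated in family-id order;
multi-copy core families are first reduced to the member with the
highest mean identity to the other genomes' members. The simulator is
indel-free, so per-family sequences are already aligned; for real,
indel-rich inputs `concatenate` accepts an external aligner callable and
refuses silently misaligned (unequal-length) input otherwise.

Distances are observed difference fractions over mutually ungapped
columns, corrected with Jukes–Cantor (nucleotide, default;
d = −(3/4)·log1p(−4p/3), saturating at p ≥ 0.75) or Poisson (protein,
d = −ln(1−p)). Trees are built by canonical neighbor joining: taxa are
processed in sorted order, Q-criterion ties break at the first row-major
minimum, and negative branch lengths are clamped to zero with a warning
(silently ignored inside bootstrap replicates, where clamping is
routine). The implementation is cross-checked in the test suite against
scikit-bio's independent NJ and against dendropy's Robinson–Foulds
distance. Bootstrap support resamples alignment columns with
replacement, rebuilds the tree per replicate and reports the percentage
of replicates containing each original bipartition.

## Genomic islands

G+C deviation tracks use 1,000 bp windows; the window is standard, the
step is not specified by common tools, so the default step is 200 bp
(configurable, including non-overlapping mode). Ratios are windowed G+C
over the genome-wide mean.

A gene is *missing in* a comparator when its family has no member there.
Island runs extend while at least one single comparator is missing every
gene of the run (i.e. the intersection of per-gene missing-sets stays
nonempty); this guarantees the reported `absent_in` set is nonempty,
which the looser "each gene missing somewhere" reading does not. Up to
one shared gene may interrupt a run (configurable 0–2), reflecting
conserved insertions inside real islands. A run becomes an island when
it spans ≥ 5,000 bp from first gene start to last gene end — the
nucleotide-span reading; cumulative gene length is the other plausible
reading and is not used. Island features: a tRNA within 2,500 bp of a
boundary, mobile-element keywords (transposase, integrase, phage,
conjugal) in member annotations, and mean window ratio deviating from
1.0 by more than 0.05.

Two islands correspond when an order-conserved chain of family-sharing
gene pairs (either orientation, ≤ 2 intervening genes per step) covers
≥ 0.5 — inclusive — of the smaller island's gene count *and* of its bp
span; this conjunctive reading of "half of the GI (considering its size
and number of genes)" is conservative, and a disjunctive mode is behind
a flag. Island clusters are connected components of match verdicts; the
presence/absence matrix is clustered with Jaccard distance and UPGMA,
standard choices for binary profiles, recorded in output metadata.

## Metabolism

Completion of a pathway in a genome is |covered reactions| / |pathway
reactions| with set semantics. PCA is an exact eigendecomposition of the
covariance matrix (centering on; scaling off by default, since
completion values share the [0,1] scale — a correlation mode exists).
Component signs are fixed so the largest-magnitude loading is positive.
Quality of representation of a pathway on a factorial plane is the
squared-cosine sum of its coordinates (loading × √eigenvalue) over the
plane, relative to all axes; plane axes beyond the matrix rank
contribute zero. The filter keeps pathways strictly above 0.75. Pathway
classes come from Euclidean/Ward clustering of plane coordinates, cut at
7 classes by default.

## Simulator

The generator produces the study conditions the pipeline is validated
under: a clade of 5 genomes, ~300 protein families (240 core + up to 60
accessory), mean gene length 180 aa, 65% G+C, tree depth 0.12
substitutions/site (pairwise ortholog identities ≈ 70–85%), four planted
8-gene islands, and no paralogs unless requested.

* **Tree** — random-join topology; branch lengths i.i.d. exponential,
  rescaled so the mean root-to-tip path equals `tree_depth` exactly.
* **Gene content** — core families survive each branch with probability
  exp(−loss_rate·length); accessory families are realised with
  probability 1 − exp(−gain_rate·total tree length) and gain on one
  branch chosen ∝ length; islands are single-gain blocks on one branch,
  exempt from later loss so planted membership stays exact.
* **Sequences** — proteins evolve by per-site replacement with
  probability 1 − exp(−t) to a uniform different residue; codons ride
  along, re-drawn (GC-biased) at replaced sites and resampled
  synonymously at twice the rate elsewhere, so silent sites carry
  tree-structured signal and nucleotide distance phylogenies recover the
  true tree. Amino-acid usage is tilted toward residues with GC-rich
  codons, as in genuinely GC-rich genomes; intergenic spacers absorb the
  residual so whole-genome G+C lands on the target. Island genes draw
  from an AT-shifted residue profile and AT-biased codons, giving them
  the detectable compositional anomaly real horizontally acquired
  islands show.
* **Annotations** — islands carry a transposase and an integrase
  annotation plus a boundary tRNA; background genes get generic product
  strings. Phenotype labels (photosynthetic yes/no, symbiosis NI/ND) are
  tied to carriage of the first two islands, so phenotype-linked gene
  sets exist by construction.
* **Paralogs** — within-genome duplicates mutated at 25% of sites
  (~75% identity). They are off by default: ground truth books a
  duplicate in its source family, but a duplicate at that divergence
  loses the mutual-best race to its source, so exact family recovery is
  only a meaningful target without them. Paralog-specific behaviour is
  tested with `paralog_rate > 0`.

Everything derives from one integer seed (per-stage streams via
`SeedSequence`); a fixed seed yields byte-identical files.

What the simulator does **not** emulate: indels (alignment is trivial by
construction), operon/intergenic architecture, assembly fragmentation,
rearrangements (gene order is a filtered global order), and codon-usage
selection beyond the GC bias. Passing tests therefore demonstrate
correctness of the inference machinery under clean conditions, not
robustness to noisy annotation or fragmented assemblies.

## Problem sizes and numerical choices

Test and acceptance runs use 4–5 genomes with 50–300 families — sizes
chosen so the full suite exercises every stage end-to-end in minutes on
one CPU while leaving recovery targets non-trivial. NJ branch-length
agreement on additive matrices is asserted to 1e−9; PCA identities to
1e−9 or better; JC spot values to 1e−12. Bootstrap determinism comes
from a dedicated RNG per call. The pipeline manifest hashes every output
file with SHA-256 and contains no timestamps, so identical inputs and
parameters reproduce it byte for byte.

## Known limitations

* BBH + connected components can chain distinct families through a
  promiscuous hub gene; the `non_clique` flag surfaces this but the
  default does not split such components.
* The island run rule reports maximal runs; a planted island flanked by
  accessory genes absent from the same comparator merges with them into
  one larger region. This is the intended reading of synteny-breakpoint
  detection — exact-recovery tests therefore use clades whose only
  absences are the planted islands.
* The k-mer prefilter could, in principle, miss a best hit between true
  homologs with no shared 4-mers; at the ≥ 40%-identity/80%-coverage
  operating point this does not occur in practice.
* Distance phylogenies only; no likelihood models, no rate
  heterogeneity, no divergence dating.
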