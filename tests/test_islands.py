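"""GC tracks, RGP detection, island matching, matrix and dendrogram."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from panforge.io import GeneRecord, GenomeRecord
from panforge.islands import (GenomicIsland, annotate_island, gc_deviation,
                              find_rgp, island_dendrogram, island_matrix,
                              match_islands)
from panforge.orthology import OrthologFamily
from panforge.phylo import rf_distance

from conftest import make_genome


def fam_over(fid: str, refs: list[tuple[str, str]]) -> OrthologFamily:
    profile: dict[str, int] = {}
    for gid, _tag in refs:
        profile[gid] = profile.get(gid, 0) + 1
    return OrthologFamily(family_id=fid, members=frozenset(refs),
                          genome_profile=profile)


def block_genome(gid: str, n_genes: int, gene_len: int = 700,
                 spacer: int = 80, trna_at: int | None = None
                 ) -> GenomeRecord:
    """A genome of ``n_genes`` equal genes laid out with fixed spacing."""
    genes = []
    pos = 1
    for i in range(n_genes):
        if trna_at is not None and i == trna_at:
            genes.append(GeneRecord(f"{gid}_t1", "chr", pos, pos + 75, "+",
                                    "tRNA", "", "tRNA"))
            pos += 76 + spacer
        genes.append(GeneRecord(f"{gid}_{i + 1:03d}", "chr", pos,
                                pos + gene_len - 1, "+", "gene",
                                "M" + "KVHW" * 10, ""))
        pos += gene_len + spacer
    genome = GenomeRecord(gid, {"chr": "A" * (pos + 100)}, genes)
    genome.sort_genes()
    return genome


class TestGcDeviation:
    def test_homogeneous_sequence_has_unit_ratio(self):
        seq = "ACGT" * 2000
        track = gc_deviation(seq)
        assert np.allclose(track.ratio, 1.0)

    def test_all_gc_window_doubles_a_half_gc_mean(self):
        seq = "GC" * 500 + "AT" * 500
        track = gc_deviation(seq, window=1000, step=1000,
                             genome_mean_gc=0.5)
        assert track.ratio[0] == pytest.approx(2.0)
        assert track.ratio[1] == pytest.approx(0.0)

    def test_default_window_is_one_kilobase(self):
        track = gc_deviation("ACGT" * 1000)
        assert track.window == 1000

    def test_bad_window_rejected(self):
        with pytest.raises(ValueError):
            gc_deviation("ACGT" * 1000, window=0)


def two_genome_island_fixture(n_island_genes: int = 8,
                              gene_len: int = 700):
    """Target T with a shared backbone plus a planted block absent from C."""
    backbone = 6
    target = block_genome("T", backbone + n_island_genes, gene_len=gene_len)
    comp = block_genome("C", backbone)
    fams = []
    for i in range(backbone):
        fams.append(fam_over(f"B{i:02d}", [("T", f"T_{i + 1:03d}"),
                                           ("C", f"C_{i + 1:03d}")]))
    for i in range(n_island_genes):
        tag = f"T_{backbone + i + 1:03d}"
        fams.append(fam_over(f"I{i:02d}", [("T", tag)]))
    return target, comp, fams


class TestFindRgp:
    def test_fully_shared_genomes_have_no_islands(self):
        target = block_genome("T", 10)
        comp = block_genome("C", 10)
        fams = [fam_over(f"F{i}", [("T", f"T_{i + 1:03d}"),
                                   ("C", f"C_{i + 1:03d}")])
                for i in range(10)]
        assert find_rgp(target, [comp], fams) == []

    def test_planted_block_above_5kbp_recovered_exactly(self):
        # 8 genes x 700 bp + 7 x 80 bp spacers = 6160 bp span
        target, comp, fams = two_genome_island_fixture(8, gene_len=700)
        islands = find_rgp(target, [comp], fams)
        assert len(islands) == 1
        isl = islands[0]
        assert isl.genes == [f"T_{i:03d}" for i in range(7, 15)]
        assert isl.length == 8 * 700 + 7 * 80
        assert isl.length >= 5000
        assert isl.absent_in == frozenset({"C"})

    def test_block_below_5kbp_rejected(self):
        # 6 genes x 600 bp + 5 x 80 = 4000 bp < 5000
        target, comp, fams = two_genome_island_fixture(6, gene_len=600)
        assert find_rgp(target, [comp], fams) == []
        # but accepted if the caller lowers the span threshold
        assert len(find_rgp(target, [comp], fams, min_span=3500)) == 1

    def test_target_in_comparators_rejected(self):
        target = block_genome("T", 5)
        with pytest.raises(ValueError):
            find_rgp(target, [target], [])

    def test_single_shared_interruption_tolerated_but_two_split(self):
        target = block_genome("T", 12)
        comp = block_genome("C", 12)
        fams = []
        shared = {5}  # interrupting gene index (0-based)
        for i in range(12):
            tag = f"T_{i + 1:03d}"
            if i in shared:
                fams.append(fam_over(f"S{i}", [("T", tag),
                                               ("C", f"C_{i + 1:03d}")]))
            else:
                fams.append(fam_over(f"U{i}", [("T", tag)]))
        # remaining comparator genes form their own families
        for i in range(12):
            if i not in shared:
                fams.append(fam_over(f"C{i}", [("C", f"C_{i + 1:03d}")]))
        one = find_rgp(target, [comp], fams, max_interruption=1)
        assert len(one) == 1
        assert len(one[0].genes) == 12  # interruption absorbed
        # without tolerance the run splits; the 5- and 6-gene halves span
        # 3,820 and 4,600 bp, so they only surface below the 5 kbp default
        assert find_rgp(target, [comp], fams, max_interruption=0) == []
        strict = find_rgp(target, [comp], fams, max_interruption=0,
                          min_span=3500)
        assert [len(i.genes) for i in strict] == [5, 6]

    def test_simulated_islands_recovered_with_exact_membership(
            self, island_truth, island_families):
        gids = island_truth.genome_ids
        genomes = island_truth.genomes
        found = {}
        for gid in gids:
            comp = [genomes[g] for g in gids if g != gid]
            for isl in find_rgp(genomes[gid], comp, island_families):
                found.setdefault(gid, []).append(isl)
        for info in island_truth.island_placements.values():
            for gid in info["genomes"]:
                loci = info["members"][gid]
                matches = [i for i in found.get(gid, [])
                           if i.genes == loci]
                assert len(matches) == 1, \
                    f"island genes {loci} not recovered in {gid}"


class TestAnnotateIsland:
    def test_trna_near_start_sets_flag(self):
        genome = block_genome("T", 10, trna_at=4)
        isl = GenomicIsland("T_GI001", "T", "chr",
                            (genome.genes[5].start, genome.genes[9].end),
                            [g.locus_tag for g in genome.genes[5:10]],
                            frozenset({"C"}))
        annotate_island(isl, genome)
        assert isl.features["tRNA_adjacent"]

    def test_transposase_annotation_sets_mobile_flag(self):
        genome = make_genome("T", {"T_1": "MKVHW" * 10},
                             {"T_1": "putative transposase"})
        gene = genome.genes[0]
        isl = GenomicIsland("T_GI001", "T", "chr", (gene.start, gene.end),
                            ["T_1"], frozenset({"C"}))
        annotate_island(isl, genome)
        assert isl.features["has_mobile_elements"]
        assert not isl.features["tRNA_adjacent"]

    def test_gc_shifted_island_flagged_anomalous(self):
        # backbone at 50% GC, island window pure AT
        seq = "GC" * 2500 + "AT" * 1500 + "GC" * 2500
        genome = GenomeRecord(
            "T", {"chr": seq},
            [GeneRecord("T_1", "chr", 5001, 7800, "+", "gene",
                        "M" * 100, "")])
        track = gc_deviation(seq, window=1000, step=200)
        isl = GenomicIsland("T_GI001", "T", "chr", (5001, 7800), ["T_1"],
                            frozenset({"C"}))
        annotate_island(isl, genome, track)
        assert isl.features["gc_anomalous"]

    def test_simulated_islands_carry_planted_features(self, island_truth,
                                                      island_families):
        gids = island_truth.genome_ids
        genomes = island_truth.genomes
        flagged = []
        for gid in gids:
            comp = [genomes[g] for g in gids if g != gid]
            seq = genomes[gid].replicons["chr"]
            gc = sum(b in "GC" for b in seq) / len(seq)
            track = gc_deviation(seq, genome_mean_gc=gc)
            for isl in find_rgp(genomes[gid], comp, island_families):
                annotate_island(isl, genomes[gid], track)
                flagged.append(isl.features)
        assert flagged
        # generator plants a boundary tRNA, mobile annotations and a GC
        # shift in every island
        assert all(f["tRNA_adjacent"] for f in flagged)
        assert all(f["has_mobile_elements"] for f in flagged)
        assert all(f["gc_anomalous"] for f in flagged)


def chain_oracle(fams_a: list[str], fams_b: list[str],
                 max_gap: int = 2) -> int:
    """Exhaustive longest order-conserved chain by recursive enumeration."""
    pairs = [(i, j) for i, fa in enumerate(fams_a)
             for j, fb in enumerate(fams_b) if fa and fa == fb]

    def extend(last: tuple[int, int] | None, remaining) -> int:
        best = 0
        for k, (i, j) in enumerate(remaining):
            if last is None or (0 < i - last[0] <= max_gap + 1
                                and 0 < j - last[1] <= max_gap + 1):
                best = max(best, 1 + extend((i, j), remaining[k + 1:]))
        return best

    fwd = extend(None, sorted(pairs))
    rev = extend(None, sorted((i, -j) for i, j in pairs))
    return max(fwd, rev)


def island_from(gid: str, fam_ids: list[str], gene_len: int = 700,
                spacer: int = 80):
    """Island + families for a genome carrying exactly these family ids."""
    tags = [f"{gid}_{i + 1:03d}" for i in range(len(fam_ids))]
    spans = []
    pos = 1
    for _ in tags:
        spans.append((pos, pos + gene_len - 1))
        pos += gene_len + spacer
    isl = GenomicIsland(f"{gid}_GI001", gid, "chr",
                        (spans[0][0], spans[-1][1]), tags,
                        frozenset({"X"}), families=list(fam_ids),
                        gene_spans=spans)
    refs = [(f, (gid, t)) for f, t in zip(fam_ids, tags) if f]
    return isl, refs


def build_islands(*specs: tuple[str, list[str]]):
    islands = []
    by_fam: dict[str, list] = {}
    for gid, fam_ids in specs:
        isl, refs = island_from(gid, fam_ids)
        islands.append(isl)
        for f, ref in refs:
            by_fam.setdefault(f, []).append(ref)
    fams = [fam_over(f, refs) for f, refs in sorted(by_fam.items())]
    return islands, fams


class TestMatchIslands:
    def test_identical_content_in_order_matches(self):
        (ia, ib), fams = build_islands(
            ("A", ["F1", "F2", "F3", "F4", "F5", "F6", "F7", "F8"]),
            ("B", ["F1", "F2", "F3", "F4", "F5", "F6", "F7", "F8"]))
        assert match_islands(ia, ib, fams)
        assert match_islands(ib, ia, fams)

    def test_two_shared_genes_of_ten_do_not_match(self):
        (ia, ib), fams = build_islands(
            ("A", ["F1", "F2", "X1", "X2", "X3", "X4", "X5", "X6", "X7",
                   "X8"]),
            ("B", ["F1", "F2", "Y1", "Y2", "Y3", "Y4", "Y5", "Y6", "Y7",
                   "Y8"]))
        assert not match_islands(ia, ib, fams)

    def test_half_coverage_boundary_is_inclusive(self):
        # 4 of 8 genes shared contiguously: gene fraction exactly 0.5
        shared = ["F1", "F2", "F3", "F4"]
        (ia, ib), fams = build_islands(
            ("A", shared + ["A1", "A2", "A3", "A4"]),
            ("B", shared + ["B1", "B2", "B3", "B4"]))
        # span of 4 chained genes = 4*700 + 3*80 = 3040 of 6160 < 0.5,
        # so the conjunctive rule rejects while the disjunctive accepts
        assert not match_islands(ia, ib, fams)
        assert match_islands(ia, ib, fams, conjunctive=False)
        # 5 of 8 shared passes both fractions (span 3820/6160 >= 0.5)
        shared5 = ["F1", "F2", "F3", "F4", "F5"]
        (ia5, ib5), fams5 = build_islands(
            ("A", shared5 + ["A1", "A2", "A3"]),
            ("B", shared5 + ["B1", "B2", "B3"]))
        assert match_islands(ia5, ib5, fams5)

    def test_reversed_island_still_matches(self):
        fam_ids = ["F1", "F2", "F3", "F4", "F5", "F6"]
        (ia, ib), fams = build_islands(("A", fam_ids),
                                       ("B", fam_ids[::-1]))
        assert match_islands(ia, ib, fams)

    def test_same_genome_never_matches(self):
        (ia, ib), fams = build_islands(("A", ["F1", "F2"]),
                                       ("A", ["F1", "F2"]))
        assert not match_islands(ia, ib, fams)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 10 ** 6))
    def test_chain_length_matches_enumeration_oracle(self, seed):
        import random
        rng = random.Random(seed)
        pool = [f"F{i}" for i in range(6)]
        fa = [rng.choice(pool + [""]) for _ in range(rng.randint(2, 8))]
        fb = [rng.choice(pool + [""]) for _ in range(rng.randint(2, 8))]
        from panforge.islands import _synteny_chain
        pairs = [(i, j) for i, x in enumerate(fa)
                 for j, y in enumerate(fb) if x and x == y]
        got = max(len(_synteny_chain(pairs)),
                  len(_synteny_chain([(i, -j) for i, j in pairs])))
        assert got == chain_oracle(fa, fb)

    @settings(derandomize=True, max_examples=15, deadline=None)
    @given(st.integers(0, 10 ** 6))
    def test_raising_min_fraction_never_creates_matches(self, seed):
        import random
        rng = random.Random(seed)
        pool = [f"F{i}" for i in range(8)]
        ids_a = rng.sample(pool, 6)
        ids_b = rng.sample(pool, 6)
        (ia, ib), fams = build_islands(("A", ids_a), ("B", ids_b))
        for lo, hi in [(0.2, 0.5), (0.5, 0.8)]:
            if match_islands(ia, ib, fams, min_fraction=hi):
                assert match_islands(ia, ib, fams, min_fraction=lo)


class TestIslandMatrix:
    def test_unmatched_islands_get_singleton_columns(self):
        (ia, ib), fams = build_islands(("A", ["F1", "F2", "F3"]),
                                       ("B", ["G1", "G2", "G3"]))
        matrix, clusters = island_matrix([ia, ib], fams, ["A", "B", "C"])
        assert matrix.shape == (3, 2)
        assert (matrix.sum(axis=0) == 1).all()

    def test_shared_island_column_has_three_carriers(self):
        ids = ["F1", "F2", "F3", "F4", "F5", "F6"]
        (ia, ib, ic), fams = build_islands(("A", ids), ("B", ids),
                                           ("C", ids))
        matrix, clusters = island_matrix([ia, ib, ic], fams,
                                         ["A", "B", "C", "D", "E"])
        assert matrix.shape == (5, 1)
        assert matrix.iloc[:, 0].sum() == 3

    def test_simulated_matrix_equals_planted_placements(
            self, island_truth, island_families):
        gids = island_truth.genome_ids
        genomes = island_truth.genomes
        all_islands = []
        for gid in gids:
            comp = [genomes[g] for g in gids if g != gid]
            all_islands.extend(find_rgp(genomes[gid], comp,
                                        island_families))
        matrix, clusters = island_matrix(all_islands, island_families, gids)
        planted = {
            frozenset(info["genomes"]): isl
            for isl, info in island_truth.island_placements.items()}
        got = {frozenset(matrix.index[matrix[c] == 1]) for c in
               matrix.columns}
        assert got == set(planted)
        assert matrix.shape[1] == len(island_truth.island_placements)


class TestIslandDendrogram:
    def test_identical_profiles_are_sisters_at_height_zero(self):
        import pandas as pd
        m = pd.DataFrame({"c1": [1, 1, 0], "c2": [1, 1, 1]},
                         index=["A", "B", "C"])
        tree = island_dendrogram(m)
        ab = tree.lca(["A", "B"])
        assert {t.name for t in ab.tips()} == {"A", "B"}
        assert sum(t.length for t in ab.children) == pytest.approx(0.0)

    def test_two_clean_blocks_form_top_clades(self):
        import pandas as pd
        m = pd.DataFrame(
            {"c1": [1, 1, 1, 0, 0, 0], "c2": [1, 1, 1, 0, 0, 0],
             "c3": [0, 0, 0, 1, 1, 1], "c4": [0, 0, 0, 1, 1, 1]},
            index=list("ABCDEF"))
        tree = island_dendrogram(m)
        top = {frozenset(t.name for t in child.tips())
               for child in tree.children}
        assert top == {frozenset("ABC"), frozenset("DEF")}

    def test_discordance_with_core_tree_is_reportable(
            self, island_truth, island_families):
        # wiring check: dendrogram and phylogeny share a leaf set, so the
        # RF distance is defined whatever its value
        gids = island_truth.genome_ids
        genomes = island_truth.genomes
        all_islands = []
        for gid in gids:
            comp = [genomes[g] for g in gids if g != gid]
            all_islands.extend(find_rgp(genomes[gid], comp,
                                        island_families))
        matrix, _ = island_matrix(all_islands, island_families, gids)
        dendro = island_dendrogram(matrix)
        rf = rf_distance(dendro, island_truth.true_tree)
        assert 0 <= rf <= 2 * (len(gids) - 3)
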