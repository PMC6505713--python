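import numpy as np
import pytest

from tilescope import classification as cls
from tilescope.types import GeneFeature, Region


def region(start, end, strand="+", rid="r"):
    return Region(rid, strand, start, end, 10, 10, 0.5, 0, True, True, 3)


def oracle_classify(reg, genes, cutoff=100, genome_length=10_000):
    """Per-nucleotide scan oracle: boolean occupancy arrays per strand,
    walking outwards from the region for gap distances."""
    occ = {"+": np.zeros(genome_length + 2, bool), "-": np.zeros(genome_length + 2, bool)}
    end_at = {}
    start_at = {}
    for g in genes:
        occ[g.strand][g.start : g.end + 1] = True
        end_at[(g.strand, g.end)] = g
        start_at[(g.strand, g.start)] = g
    same, other = reg.strand, "-" if reg.strand == "+" else "+"
    if occ[same][reg.start : reg.end + 1].any():
        return "touching"
    left_gap = right_gap = None
    pos = reg.start - 1
    while pos >= 1:
        if occ[same][pos]:
            left_gap = reg.start - pos - 1
            left_gene = end_at[(same, pos)]
            break
        pos -= 1
    pos = reg.end + 1
    while pos <= genome_length:
        if occ[same][pos]:
            right_gap = pos - reg.end - 1
            right_gene = start_at[(same, pos)]
            break
        pos += 1
    left_near = left_gap is not None and left_gap < cutoff
    right_near = right_gap is not None and right_gap < cutoff
    if left_near and right_near:
        return "operon_element"
    if right_near:
        return "utr5" if right_gene.strand == "+" else "utr3"
    if left_near:
        return "utr3" if left_gene.strand == "+" else "utr5"
    if occ[other][reg.start : reg.end + 1].any():
        return "antisense"
    return "novel"


def random_fixture(rng, genome_length=3_000):
    """Random non-overlapping-per-strand genes plus one random region."""
    genes = []
    for strand in "+-":
        pos = 1
        gid = 0
        while True:
            pos += int(rng.integers(20, 400))
            length = int(rng.integers(30, 400))
            if pos + length > genome_length:
                break
            gid += 1
            genes.append(
                GeneFeature(f"g{strand}{gid}", f"g{strand}{gid}", pos, pos + length - 1, strand)
            )
            pos += length
    start = int(rng.integers(1, genome_length - 200))
    end = start + int(rng.integers(0, 200))
    strand = "+" if rng.random() < 0.5 else "-"
    return genes, region(start, end, strand)


class TestOverlapLength:
    def test_partial_overlap_inclusive(self):
        assert cls.overlap_length((100, 200), (150, 250)) == 51

    def test_adjacency_is_not_overlap(self):
        assert cls.overlap_length((100, 200), (201, 300)) == 0

    def test_identical_intervals(self):
        assert cls.overlap_length((100, 200), (100, 200)) == 101


class TestClassifyRegion:
    def _classify(self, reg, genes, cutoff=100):
        return cls.classify_region(reg, cls.AnnotationIndex(genes), cutoff)

    def test_one_nt_overlap_is_touching(self):
        genes = [GeneFeature("g1", "g1", 100, 200, "+")]
        c = self._classify(region(95, 130), genes)
        assert c.category == "touching" and c.gene_ids == ("g1",)

    def test_upstream_gap_below_cutoff_is_utr5(self):
        genes = [GeneFeature("g1", "g1", 100, 200, "+")]
        c = self._classify(region(20, 60), genes)
        assert c.category == "utr5" and c.distances == (39,)

    def test_between_two_near_genes_is_operon_element(self):
        genes = [
            GeneFeature("g1", "g1", 1, 100, "+"),
            GeneFeature("g2", "g2", 250, 400, "+"),
        ]
        c = self._classify(region(130, 220), genes)
        assert c.category == "operon_element"
        assert c.distances == (29, 29)

    def test_opposite_strand_overlap_is_antisense(self):
        genes = [GeneFeature("g1", "g1", 100, 400, "-")]
        c = self._classify(region(150, 250, "+"), genes)
        assert c.category == "antisense"

    def test_isolated_region_is_novel(self):
        genes = [GeneFeature("g1", "g1", 2_000, 2_400, "+")]
        c = self._classify(region(100, 160), genes)
        assert c.category == "novel"

    def test_minus_strand_utr_sides(self):
        # region genomically after a - gene's end sits at its 5' side
        genes = [GeneFeature("g1", "g1", 100, 200, "-")]
        assert self._classify(region(230, 260, "-"), genes).category == "utr5"
        assert self._classify(region(20, 60, "-"), genes).category == "utr3"

    def test_strict_cutoff_inequality(self):
        genes = [GeneFeature("g1", "g1", 300, 400, "+")]
        # gap = 300 - 199 - 1 = 100, not < 100 -> falls through to novel
        assert self._classify(region(100, 199), genes).category == "novel"
        # gap 99 < 100 -> UTR
        assert self._classify(region(100, 200), genes).category == "utr5"

    def test_agrees_with_per_nucleotide_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            genes, reg = random_fixture(rng)
            got = self._classify(reg, genes).category
            want = oracle_classify(reg, genes)
            assert got == want, (reg, got, want)

    def test_translation_invariance(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            genes, reg = random_fixture(rng)
            shift = 5_000
            genes2 = [
                GeneFeature(g.id, g.name, g.start + shift, g.end + shift, g.strand, g.kind)
                for g in genes
            ]
            reg2 = region(reg.start + shift, reg.end + shift, reg.strand)
            assert (
                self._classify(reg, genes).category
                == self._classify(reg2, genes2).category
            )

    def test_categories_partition_regions(self):
        rng = np.random.default_rng(11)
        genes, _ = random_fixture(rng)
        regions = [random_fixture(rng)[1] for _ in range(100)]
        results = cls.classify_regions(regions, genes)
        assert len(results) == len(regions)
        assert all(c.category in cls.CATEGORIES for c in results)


class TestFilterAntisense:
    def _pairs(self, categories):
        return [
            (region(100 * i + 1, 100 * i + 50, rid=f"r{i}"), cls.Classification(f"r{i}", cat))
            for i, cat in enumerate(categories)
        ]

    def test_removes_and_counts(self):
        pairs = self._pairs(["novel"] * 7 + ["antisense"] * 3)
        kept, removed = cls.filter_antisense(pairs)
        assert len(kept) == 7 and removed == 3

    def test_identity_without_antisense(self):
        pairs = self._pairs(["novel", "touching"])
        kept, removed = cls.filter_antisense(pairs)
        assert kept == pairs and removed == 0

    def test_all_antisense_empty(self):
        kept, removed = cls.filter_antisense(self._pairs(["antisense"] * 4))
        assert kept == [] and removed == 4


class TestSummarize:
    genes = [
        GeneFeature("g1", "g1", 100, 500, "+"),
        GeneFeature("g2", "g2", 700, 1_200, "+", "ncRNA"),
        GeneFeature("g3", "g3", 2_000, 2_500, "-"),
    ]

    def test_counts_and_gene_bookkeeping(self):
        diff = [
            cls.Classification("r1", "touching", ("g1",), (0,)),
            cls.Classification("r2", "touching", ("g1", "g2"), (0, 0)),
            cls.Classification("r3", "novel"),
        ]
        sim = [cls.Classification("r4", "utr5", ("g2",), (10,))]
        table, extras = cls.summarize(diff, sim, self.genes)
        assert table.loc["touching", "differential"] == 2
        assert table.loc["novel", "differential"] == 1
        # the g1-g2 spanning region contributes one operon-element part
        assert table.loc["operon_element", "differential"] == 1
        assert extras["differential"]["genes_touched"] == 2  # g1 counted once
        assert extras["differential"]["ncRNAs_touched"] == 1
        assert table.loc["utr5", "similar"] == 1

    def test_every_region_in_exactly_one_category(self):
        diff = [
            cls.Classification("r1", "touching", ("g1",), (0,)),
            cls.Classification("r2", "novel"),
        ]
        table, _ = cls.summarize(diff, [], self.genes)
        # operon row may include spanning parts; exclude it from the identity
        base = [c for c in cls.CATEGORIES if c != "operon_element"]
        assert table.loc[base, "differential"].sum() == len(diff)
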