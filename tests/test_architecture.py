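"""Intergenic gaps, overlap census, partitions and length closure."""
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitochar.architecture import (
    AdjacencyGap,
    adjacency_gaps,
    extract_partition,
    genome_length_closure,
    overlap_census,
)
from mitochar.model import (
    AnnotatedMitogenome,
    FeatureRecord,
    FeatureType,
    MitocharError,
    Strand,
)
from mitochar.reference import GENOME_LENGTH


def _genome(feature_spans, L=100, seq=None, types=None):
    feats = [
        FeatureRecord(f"f{i}", (types or {}).get(i, FeatureType.TRNA),
                      s, e, Strand.H)
        for i, (s, e) in enumerate(feature_spans)
    ]
    return AnnotatedMitogenome(seq or "A" * L, features=feats)


class TestAdjacencyGaps:
    def test_atp8_atp6_overlap(self, default_genome):
        gaps = {(g.upstream, g.downstream): g.gap
                for g in adjacency_gaps(default_genome)}
        assert gaps[("atp8", "atp6")] == -7

    def test_circular_closure_spacer(self, default_genome):
        last = adjacency_gaps(default_genome)[-1]
        assert (last.upstream, last.downstream) == ("OH", "tRNA-Phe")
        assert last.gap == 99
        assert last.circular_wrap

    def test_abutting_features_gap_zero(self):
        g = _genome([(1, 10), (11, 20)])
        assert adjacency_gaps(g)[0].gap == 0

    def test_fewer_than_two_features(self):
        assert adjacency_gaps(_genome([(1, 10)])) == []


class TestOverlapCensus:
    def test_reference_layout(self, default_genome):
        census = overlap_census(adjacency_gaps(default_genome))
        assert census.n_overlaps == 11
        assert census.max_overlap == 7
        assert census.max_spacer == 99

    def test_all_zero(self):
        gaps = [AdjacencyGap("a", "b", 0), AdjacencyGap("b", "c", 0)]
        assert overlap_census(gaps) == (0, 0, 0, 0)

    def test_mixed_signs(self):
        gaps = [AdjacencyGap("a", "b", -1), AdjacencyGap("b", "c", 2),
                AdjacencyGap("c", "d", -3)]
        assert overlap_census(gaps) == (2, 1, 3, 2)


class TestPartitions:
    def test_trna_partition_length(self, default_genome):
        assert len(extract_partition(default_genome, "tRNA")) == 1565

    def test_rrna_partition_length(self, default_genome):
        assert len(extract_partition(default_genome, "rRNA")) == 2596

    def test_control_partition_length(self, default_genome):
        assert len(extract_partition(default_genome, "control")) == 807

    def test_pcg_partition_drops_stops(self, default_genome):
        # 13 printed gene lengths sum to 11,415; removing 10 complete and
        # 3 incomplete stops leaves 11,382 = 3 x 3794
        assert len(extract_partition(default_genome, "PCGs")) == 11_382
        for label in ("codon1", "codon2", "codon3"):
            assert len(extract_partition(default_genome, label)) == 3794

    def test_single_gene_codon_positions(self):
        g = AnnotatedMitogenome(
            "ATGAAATAA",
            features=[FeatureRecord("g", FeatureType.PCG, 1, 9, Strand.H,
                                    start_codon="ATG", stop_codon="TAA")],
        )
        assert extract_partition(g, "PCGs").seq == "ATGAAA"
        assert extract_partition(g, "codon1").seq == "AA"
        assert extract_partition(g, "codon2").seq == "TA"
        assert extract_partition(g, "codon3").seq == "GA"

    def test_unknown_label(self, default_genome):
        with pytest.raises(MitocharError):
            extract_partition(default_genome, "promoters")

    def test_strand_involution(self, default_genome):
        """Reverse-complementing the genome and flipping strands leaves
        strand-corrected partitions unchanged (up to gene order)."""
        flipped = default_genome.reverse_complemented()
        for label in ("PCGs", "tRNA", "rRNA"):
            a = {f.name: default_genome.extract(f)
                 for f in default_genome.features}
            b = {f.name: flipped.extract(f) for f in flipped.features}
            assert a == b


class TestLengthClosure:
    def test_reference_genome(self, default_genome):
        assert genome_length_closure(default_genome.features, 99) == GENOME_LENGTH

    def test_trivial(self):
        f = [FeatureRecord("x", FeatureType.TRNA, 1, 100, Strand.H)]
        assert genome_length_closure(f, 0) == 100
        assert genome_length_closure(f[:1], 5) == 105

    def test_negative_result_errors(self):
        f = [FeatureRecord("x", FeatureType.TRNA, 1, 10, Strand.H)]
        with pytest.raises(MitocharError):
            genome_length_closure(f, -10)


@settings(deadline=None)
@given(
    st.lists(st.integers(min_value=1, max_value=40), min_size=2, max_size=8),
    st.lists(st.integers(min_value=-5, max_value=30), min_size=8, max_size=8),
)
def test_lengths_plus_gaps_telescope_to_genome_length(sizes, gaps):
    """Sum of feature lengths and all gaps (incl. closure) = genome length."""
    feats, start = [], 1
    for i, size in enumerate(sizes):
        end = start + size - 1
        if end < 1:
            return
        feats.append(FeatureRecord(f"f{i}", FeatureType.TRNA, start, end,
                                   Strand.H))
        start = end + gaps[i] + 1
        if start < feats[-1].start + 1:  # keep features sorted uniquely
            return
    L = feats[-1].end + 25
    g = AnnotatedMitogenome("A" * L, features=feats)
    all_gaps = adjacency_gaps(g)
    total = sum(f.end - f.start + 1 for f in feats) + sum(x.gap for x in all_gaps)
    assert total == L
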