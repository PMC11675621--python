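"""Synthetic-data generators: layout realization, divergence, populations,
coalescent sampling."""
import numpy as np
import pytest

from mitochar.architecture import adjacency_gaps, overlap_census
from mitochar.codons import extract_codons
from mitochar.diversity import summarize, tajima_constants
from mitochar.model import FeatureType, MitocharError, Strand
from mitochar.reference import GENOME_LENGTH
from mitochar.simulate import (
    GenomeSpec,
    PopulationSpec,
    evolve_pair,
    make_coalescent_sample,
    make_genome,
    make_population,
)


class TestMakeGenome:
    def test_default_layout_realized(self, default_genome):
        assert len(default_genome) == GENOME_LENGTH
        assert len(default_genome.features) == 39
        census = overlap_census(adjacency_gaps(default_genome))
        assert census.n_overlaps == 11

    def test_pcgs_are_valid_orfs(self, default_genome):
        import warnings

        for f in default_genome.pcgs:
            cds = default_genome.extract(f)
            assert cds.startswith(f.start_codon)
            if len(f.stop_codon) == 3:
                assert cds.endswith(f.stop_codon)
            else:  # incomplete stop materialized as the trailing base(s)
                assert cds.endswith(f.stop_codon)
        with warnings.catch_warnings():
            warnings.simplefilter("error")  # no internal-stop warnings
            extract_codons(default_genome)

    def test_composition_near_target(self, default_genome):
        seq = default_genome.seq
        for base, target in zip("ATGC", (0.3204, 0.2413, 0.1594, 0.2788)):
            assert abs(seq.count(base) / len(seq) - target) < 0.02

    def test_same_seed_byte_identical(self):
        a = make_genome(GenomeSpec(seed=42))
        b = make_genome(GenomeSpec(seed=42))
        assert a.seq == b.seq

    def test_minimal_two_gene_spec(self):
        spec = GenomeSpec.from_gap_layout(
            [
                ("g1", FeatureType.PCG, Strand.H, 30, 5, None, "ATG", "TAA"),
                ("g2", FeatureType.PCG, Strand.L, 30, 10, None, "ATG", "TAG"),
            ],
            length=75,
            seed=2,
        )
        g = make_genome(spec)
        assert len(g) == 75
        for f in g.pcgs:
            assert g.extract(f).startswith("ATG")

    def test_impossible_layout_errors(self):
        from mitochar.model import FeatureRecord

        spec = GenomeSpec(
            length=20,
            features=(FeatureRecord("g1", FeatureType.TRNA, 1, 30,
                                    Strand.H),),
        )
        with pytest.raises(MitocharError):
            make_genome(spec)

    def test_gap_layout_closure_checked(self):
        with pytest.raises(MitocharError):
            GenomeSpec.from_gap_layout(
                [("g1", FeatureType.TRNA, Strand.H, 30, 5)], length=40
            )


class TestEvolvePair:
    def test_t_zero_is_identity(self, default_genome):
        assert evolve_pair(default_genome, 0.0, 0.5, seed=9).seq == \
            default_genome.seq

    def test_omega_zero_gives_zero_ka(self, default_genome):
        from mitochar.kaks import kaks_screen

        other = evolve_pair(default_genome, 0.3, 0.0, seed=31)
        assert other.seq != default_genome.seq
        for r in kaks_screen(default_genome, other):
            assert r.nN == pytest.approx(0.0)
            assert r.ka == 0.0

    def test_annotations_preserved(self, default_genome):
        other = evolve_pair(default_genome, 0.2, 0.1, seed=33)
        assert other.features == default_genome.features

    def test_negative_rate_rejected(self, default_genome):
        with pytest.raises(MitocharError):
            evolve_pair(default_genome, -1.0, 0.1, seed=1)


class TestMakePopulation:
    def test_configured_haplotype_structure_recovered(self, coi_population):
        s = summarize(coi_population)
        assert (s.n_hap, s.hap_freqs, s.S) == (2, (18, 12), 1)

    def test_single_haplotype_hd_zero(self):
        pop = make_population(
            PopulationSpec(n=6, L=50, hap_config=((6, ()),), seed=4)
        )
        assert summarize([s for _, s in pop]).Hd == 0.0

    def test_two_by_two_formula(self):
        pop = make_population(
            PopulationSpec(n=4, L=40, hap_config=((2, ()), (2, (7,))),
                           seed=5)
        )
        s = summarize([x for _, x in pop])
        assert s.Hd == pytest.approx(2 / 3)

    def test_duplicate_site_rejected(self):
        with pytest.raises(MitocharError):
            PopulationSpec(n=2, L=10, hap_config=((2, (3, 3)),))

    def test_frequency_sum_checked(self):
        with pytest.raises(MitocharError):
            PopulationSpec(n=5, L=10, hap_config=((2, ()), (2, (1,))))


class TestCoalescent:
    def test_reproducible_under_seed(self):
        a = make_coalescent_sample(6, 2.0, 500, seed=8)
        b = make_coalescent_sample(6, 2.0, 500, seed=8)
        assert a == b

    def test_watterson_calibration(self):
        """Mean S/a1 over replicates estimates theta (E[S] = theta*a1)."""
        a1 = tajima_constants(10)["a1"]
        S_vals = [
            summarize([s for _, s in
                       make_coalescent_sample(10, 5.0, 2000, seed=500 + i)]).S
            for i in range(200)
        ]
        assert np.mean(S_vals) / a1 == pytest.approx(5.0, rel=0.15)

    def test_neutral_tajima_d_centred_near_zero(self):
        D_vals = []
        for i in range(200):
            s = summarize([x for _, x in
                           make_coalescent_sample(10, 5.0, 2000,
                                                  seed=900 + i)])
            if s.tajima_D is not None:
                D_vals.append(s.tajima_D)
        assert abs(np.mean(D_vals)) < 0.3

    def test_parameter_validation(self):
        with pytest.raises(MitocharError):
            make_coalescent_sample(1, 5.0, 100)
        with pytest.raises(MitocharError):
            make_coalescent_sample(5, 0.0, 100)
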