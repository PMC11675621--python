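# mitochar

Characterization of annotated animal mitochondrial genomes and
population-genetic summaries of marker-gene alignments, built around the
fish mitogenome of *Luciocyprinus langsoni* (GenBank MZ921933, 16,586 bp)
and its published comparator *L. striolatus* (AP012525).

The package is aimed at molecular ecologists and systematists who have an
annotated mitogenome (GenBank flat file, or FASTA plus a feature table)
and want the standard descriptive battery, reproducibly and scriptably:

* **Genome architecture** — intergenic lengths per gene adjacency
  (negative = overlap), overlap/spacer census, circular length closure,
  and partition extraction (PCGs with stop codons removed, codon
  positions per gene, rRNA/tRNA/control-region concatenations).
* **Composition** — base percentages, A+T/G+C content, and strand skews
  `AT skew = (A − T)/(A + T)`, `GC skew = (G − C)/(G + C)` for any
  partition or per gene.
* **Codon usage** — codon counts under the vertebrate mitochondrial code
  (NCBI table 2: AGA/AGG are stops, AUA is Met, UGA is Trp) and relative
  synonymous codon usage, `RSCU(c) = n_c · |F| / Σ_{c′∈F} n_{c′}` over
  each synonymous family *F* (Leu and Ser are 6-codon families; the four
  stops form one family).
* **Selection** — pairwise Ka/Ks per protein-coding gene by
  Nei–Gojobori (1986) counting with equal-weight pathway averaging and
  Jukes–Cantor correction `d = −(3/4)·ln(1 − 4p/3)`; ω = Ka/Ks < 1
  indicates purifying selection.
* **Diversity** — haplotype collapse, unbiased haplotype diversity
  `Hd = n(1 − Σp_i²)/(n − 1)`, mean pairwise differences k̄, nucleotide
  diversity π = k̄/L, segregating sites S, and Tajima's (1989) D.
* **Simulation** — synthetic annotated genomes realizing any feature
  layout (default: the published 39-feature *L. langsoni* layout with its
  11 overlaps and incomplete T-/TA- stops), genome pairs diverged under a
  controlled nonsynonymous acceptance ratio, populations with exact
  haplotype structure, and neutral-coalescent samples.

## Worked example

```python
from mitochar import (adjacency_gaps, overlap_census, extract_partition,
                      extract_codons, summarize)
from mitochar.simulate import GenomeSpec, PopulationSpec, make_genome, make_population

genome = make_genome(GenomeSpec(seed=1))   # published layout, 16,586 bp
census = overlap_census(adjacency_gaps(genome))
print(census)
# OverlapCensus(n_overlaps=11, n_spacers=18, max_overlap=7, max_spacer=99)

print(len(extract_partition(genome, "PCGs")), len(extract_codons(genome)))
# 11382 3804

pop = make_population(PopulationSpec(
    n=30, L=1664, hap_config=((18, ()), (12, (832,))), seed=3))
s = summarize([seq for _, seq in pop])
print(s.n_hap, round(s.Hd, 3), round(s.pi, 4), round(s.tajima_D, 4))
# 2 0.497 0.0003 1.5075
```

The census row says the layout carries 11 gene overlaps (largest 7 bp,
between *atp8* and *atp6*) and that the longest spacer (99 bp, between
the control region and *tRNA-Phe*) closes the circle. The 13 PCGs span
11,382 bp once the 10 complete and 3 incomplete stop codons are removed,
and contribute 3804 complete codons. The population sample has two
haplotypes at 18:12, giving Hd ≈ 0.497, π ≈ 0.0003 and a positive
Tajima's D ≈ 1.51 — the low-diversity, post-bottleneck signature reported
for the Hechi Longjiang *L. langsoni* population.

There is also a CLI:

```sh
mitochar simulate --what genome --seed 1 --out fixtures/
mitochar characterize fixtures/genome.gb --out reports/
mitochar diversity population.fasta --out reports/
```

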