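"""Published reference data for the *Luciocyprinus langsoni* mitogenome
(GenBank MZ921933, 16,586 bp).

``REFERENCE_LAYOUT`` transcribes the deposited gene-characteristics table:
39 features (13 protein-coding genes, 22 tRNAs, 2 rRNAs, the light-strand
replication origin OL and the control region OH) with 1-based inclusive
coordinates, strands, tRNA anticodons and PCG start/stop tokens. Stop
tokens "T" and "TA" mark incomplete stops completed by polyadenylation.

``REFERENCE_CODON_COUNTS`` is the deposited codon-usage tally of the 13
PCGs (3804 codons, complete terminal stops included) and
``REFERENCE_RSCU`` the RSCU values as published (1–2 decimals).

These serve as the default layout for the synthetic-genome generator and
as fixed anchors for regression tests; no download is required.
"""
from __future__ import annotations

from .model import FeatureRecord, FeatureType, Strand

__all__ = [
    "GENOME_LENGTH",
    "REFERENCE_LAYOUT",
    "REFERENCE_GENOME_COMPOSITION",
    "REFERENCE_CODON_COUNTS",
    "REFERENCE_RSCU",
    "reference_features",
]

GENOME_LENGTH = 16_586

_P, _T, _R, _C, _O = (
    FeatureType.PCG,
    FeatureType.TRNA,
    FeatureType.RRNA,
    FeatureType.CONTROL,
    FeatureType.ORIGIN,
)
_H, _L = Strand.H, Strand.L

# (name, ftype, strand, start, end, anticodon, start_codon, stop_codon)
REFERENCE_LAYOUT: list[tuple] = [
    ("tRNA-Phe", _T, _H, 1, 69, "GAA", None, None),
    ("12S rRNA", _R, _H, 70, 1024, None, None, None),
    ("tRNA-Val", _T, _H, 1027, 1098, "TAC", None, None),
    ("16S rRNA", _R, _H, 1117, 2757, None, None, None),
    ("tRNA-Leu2", _T, _H, 2783, 2858, "TAA", None, None),
    ("nad1", _P, _H, 2860, 3834, None, "ATG", "TAA"),
    ("tRNA-Ile", _T, _H, 3839, 3910, "GAT", None, None),
    ("tRNA-Gln", _T, _L, 3909, 3979, "TTG", None, None),
    ("tRNA-Met", _T, _H, 3981, 4049, "CAT", None, None),
    ("nad2", _P, _H, 4050, 5096, None, "ATG", "TAG"),
    ("tRNA-Trp", _T, _H, 5095, 5165, "TCA", None, None),
    ("tRNA-Ala", _T, _L, 5168, 5236, "TGC", None, None),
    ("tRNA-Asn", _T, _L, 5238, 5310, "GTT", None, None),
    ("OL", _O, _H, 5313, 5344, None, None, None),
    ("tRNA-Cys", _T, _L, 5344, 5410, "GCA", None, None),
    ("tRNA-Tyr", _T, _L, 5410, 5480, "GTA", None, None),
    ("cox1", _P, _H, 5482, 7032, None, "GTG", "TAA"),
    ("tRNA-Ser2", _T, _L, 7033, 7103, "TGA", None, None),
    ("tRNA-Asp", _T, _H, 7107, 7178, "GTC", None, None),
    ("cox2", _P, _H, 7192, 7882, None, "ATG", "T"),
    ("tRNA-Lys", _T, _H, 7883, 7958, "TTT", None, None),
    ("atp8", _P, _H, 7960, 8124, None, "ATG", "TAG"),
    ("atp6", _P, _H, 8118, 8801, None, "ATG", "TAA"),
    ("cox3", _P, _H, 8801, 9586, None, "ATG", "TAA"),
    ("tRNA-Gly", _T, _H, 9586, 9657, "TCC", None, None),
    ("nad3", _P, _H, 9658, 10_008, None, "ATG", "TAG"),
    ("tRNA-Arg", _T, _H, 10_007, 10_077, "TCG", None, None),
    ("nad4l", _P, _H, 10_078, 10_374, None, "ATG", "TAA"),
    ("nad4", _P, _H, 10_368, 11_748, None, "ATG", "T"),
    ("tRNA-His", _T, _H, 11_749, 11_817, "GTG", None, None),
    ("tRNA-Ser1", _T, _H, 11_818, 11_886, "GCT", None, None),
    ("tRNA-Leu1", _T, _H, 11_888, 11_960, "TAG", None, None),
    ("nad5", _P, _H, 11_964, 13_787, None, "ATG", "TAA"),
    ("nad6", _P, _L, 13_784, 14_305, None, "ATG", "TAG"),
    ("tRNA-Glu", _T, _L, 14_306, 14_374, "TTC", None, None),
    ("cob", _P, _H, 14_380, 15_520, None, "ATG", "T"),
    ("tRNA-Thr", _T, _H, 15_521, 15_593, "TGT", None, None),
    ("tRNA-Pro", _T, _L, 15_593, 15_662, "TGG", None, None),
    ("OH", _C, _H, 15_681, 16_487, None, None, None),
]

# Whole-genome base fractions (A, T, G, C) as deposited.
REFERENCE_GENOME_COMPOSITION = (0.3204, 0.2413, 0.1594, 0.2788)

# Published per-codon counts over the 13 PCGs (RNA codons; total 3804).
REFERENCE_CODON_COUNTS: dict[str, int] = {
    "UUU": 75, "UUC": 151, "UUA": 105, "UUG": 14,
    "CUU": 77, "CUC": 90, "CUA": 297, "CUG": 44,
    "AUU": 145, "AUC": 143, "AUA": 124, "AUG": 45,
    "GUU": 48, "GUC": 43, "GUA": 106, "GUG": 27,
    "UCU": 38, "UCC": 51, "UCA": 90, "UCG": 8,
    "CCU": 19, "CCC": 47, "CCA": 132, "CCG": 11,
    "ACU": 35, "ACC": 118, "ACA": 162, "ACG": 8,
    "GCU": 47, "GCC": 145, "GCA": 123, "GCG": 12,
    "UAU": 36, "UAC": 78, "UAA": 6, "UAG": 4,
    "CAU": 25, "CAC": 79, "CAA": 97, "CAG": 4,
    "AAU": 31, "AAC": 92, "AAA": 74, "AAG": 3,
    "GAU": 20, "GAC": 55, "GAA": 87, "GAG": 16,
    "UGU": 5, "UGC": 20, "UGA": 106, "UGG": 14,
    "CGU": 10, "CGC": 13, "CGA": 49, "CGG": 4,
    "AGU": 5, "AGC": 43, "AGA": 0, "AGG": 0,
    "GGU": 22, "GGC": 50, "GGA": 121, "GGG": 55,
}

# Published RSCU values (printed to 1–2 decimals).
REFERENCE_RSCU: dict[str, float] = {
    "UUU": 0.66, "UUC": 1.34, "UUA": 1.0, "UUG": 0.13,
    "CUU": 0.74, "CUC": 0.86, "CUA": 2.84, "CUG": 0.42,
    "AUU": 1.01, "AUC": 0.99, "AUA": 1.47, "AUG": 0.53,
    "GUU": 0.86, "GUC": 0.77, "GUA": 1.89, "GUG": 0.48,
    "UCU": 0.97, "UCC": 1.3, "UCA": 2.3, "UCG": 0.2,
    "CCU": 0.36, "CCC": 0.9, "CCA": 2.53, "CCG": 0.21,
    "ACU": 0.43, "ACC": 1.46, "ACA": 2.01, "ACG": 0.1,
    "GCU": 0.57, "GCC": 1.77, "GCA": 1.5, "GCG": 0.15,
    "UAU": 0.63, "UAC": 1.37, "UAA": 2.4, "UAG": 1.6,
    "CAU": 0.48, "CAC": 1.52, "CAA": 1.92, "CAG": 0.08,
    "AAU": 0.5, "AAC": 1.5, "AAA": 1.92, "AAG": 0.08,
    "GAU": 0.53, "GAC": 1.47, "GAA": 1.69, "GAG": 0.31,
    "UGU": 0.4, "UGC": 1.6, "UGA": 1.77, "UGG": 0.23,
    "CGU": 0.53, "CGC": 0.68, "CGA": 2.58, "CGG": 0.21,
    "AGU": 0.13, "AGC": 1.1, "AGA": 0.0, "AGG": 0.0,
    "GGU": 0.35, "GGC": 0.81, "GGA": 1.95, "GGG": 0.89,
}


def reference_features() -> list[FeatureRecord]:
    """The reference layout as FeatureRecord objects."""
    return [
        FeatureRecord(name=n, ftype=t, strand=s, start=a, end=b,
                      anticodon=ac, start_codon=sc, stop_codon=st)
        for (n, t, s, a, b, ac, sc, st) in REFERENCE_LAYOUT
    ]
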