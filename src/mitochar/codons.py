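"""Codon extraction, usage counts and RSCU under a mitochondrial code.

Relative synonymous codon usage (RSCU) of codon *c* in synonymous family
*F* (all codons encoding one amino acid; the stop codons form one family)
is the observed count divided by the uniform-usage expectation:

    RSCU(c) = count(c) * |F| / sum_{c' in F} count(c')

so the RSCU values within a family sum to the family size. Under the
vertebrate mitochondrial code (NCBI translation table 2) Leu and Ser are
6-codon families and the stops {UAA, UAG, AGA, AGG} a 4-codon family.
"""
from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from itertools import product

from Bio.Data import CodonTable

from .architecture import stopless_cds
from .model import AnnotatedMitogenome, MitocharError

__all__ = [
    "GeneticCode",
    "CodonUsageTable",
    "InternalStopError",
    "extract_codons",
    "rscu",
    "amino_acid_usage",
    "codon_ranking",
    "AA3",
]

RNA_CODONS = ["".join(p) for p in product("UCAG", repeat=3)]

AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
    "*": "stop codon",
}


class InternalStopError(MitocharError):
    """A protein-coding gene contains an in-frame internal stop codon."""


@dataclass(frozen=True)
class GeneticCode:
    """A genetic code over the 64 RNA codons; stops map to '*'."""

    table_id: int
    forward: dict[str, str]
    start_codons: frozenset[str]
    stop_codons: frozenset[str]

    @classmethod
    def from_table_id(cls, table_id: int = 2) -> "GeneticCode":
        """Build from an NCBI translation table (default 2, vertebrate
        mitochondrial)."""
        try:
            table = CodonTable.unambiguous_rna_by_id[table_id]
        except KeyError as exc:
            raise MitocharError(f"unknown translation table {table_id}") from exc
        forward = dict(table.forward_table)
        for stop in table.stop_codons:
            forward[stop] = "*"
        return cls(
            table_id=table_id,
            forward=forward,
            start_codons=frozenset(table.start_codons),
            stop_codons=frozenset(table.stop_codons),
        )

    def translate(self, codon: str) -> str:
        return self.forward[codon.upper().replace("T", "U")]

    def is_stop(self, codon: str) -> bool:
        return codon.upper().replace("T", "U") in self.stop_codons

    def families(self) -> dict[str, list[str]]:
        """Synonymous families keyed by amino acid ('*' = stop family)."""
        fams: dict[str, list[str]] = {}
        for codon in RNA_CODONS:
            fams.setdefault(self.forward[codon], []).append(codon)
        return fams


VERTEBRATE_MITO = GeneticCode.from_table_id(2)


def _as_rna(codon: str) -> str:
    return codon.upper().replace("T", "U")


def extract_codons(genome: AnnotatedMitogenome,
                   code: GeneticCode = VERTEBRATE_MITO,
                   *, strict: bool = False) -> list[str]:
    """All complete codons of the protein-coding genes, as RNA triplets.

    Each gene is read in frame on its coding strand. Complete terminal stop
    codons are included in the tally; incomplete terminal codons (the 1–2
    bases of a polyadenylation-completed stop) are dropped. Initiator
    codons are counted as written (a GTG start contributes a GUG/Val codon).

    An internal in-frame stop triggers a warning, or
    :class:`InternalStopError` when ``strict=True``.
    """
    codons: list[str] = []
    for gene in genome.pcgs:
        cds = genome.extract(gene)
        if len(cds) < 6:
            raise MitocharError(f"{gene.name}: CDS shorter than 2 codons")
        n_complete = len(cds) // 3
        gene_codons = [
            _as_rna(cds[3 * i : 3 * i + 3]) for i in range(n_complete)
        ]
        for i, codon in enumerate(gene_codons[:-1]):
            if codon in code.stop_codons:
                msg = (f"{gene.name}: internal stop {codon} at codon "
                       f"{i + 1}/{n_complete}")
                if strict:
                    raise InternalStopError(msg)
                warnings.warn(msg, stacklevel=2)
        codons.extend(gene_codons)
    return codons


def rscu(counts: Counter[str] | dict[str, int],
         code: GeneticCode = VERTEBRATE_MITO) -> dict[str, float]:
    """RSCU for all 64 codons; families with zero usage get 0 throughout."""
    counts = {_as_rna(c): n for c, n in counts.items()}
    out: dict[str, float] = {}
    for family in code.families().values():
        total = sum(counts.get(c, 0) for c in family)
        for c in family:
            out[c] = counts.get(c, 0) * len(family) / total if total else 0.0
    return out


@dataclass
class CodonUsageTable:
    """Codon counts plus derived RSCU and amino-acid totals."""

    counts: Counter = field(default_factory=Counter)
    code: GeneticCode = VERTEBRATE_MITO

    @classmethod
    def from_codons(cls, codons: list[str],
                    code: GeneticCode = VERTEBRATE_MITO) -> "CodonUsageTable":
        return cls(counts=Counter(_as_rna(c) for c in codons), code=code)

    @classmethod
    def from_counts(cls, counts: dict[str, int],
                    code: GeneticCode = VERTEBRATE_MITO) -> "CodonUsageTable":
        return cls(counts=Counter({_as_rna(c): n for c, n in counts.items()}),
                   code=code)

    @property
    def total_codons(self) -> int:
        return sum(self.counts.values())

    @property
    def rscu(self) -> dict[str, float]:
        return rscu(self.counts, self.code)

    @property
    def aa_counts(self) -> dict[str, int]:
        totals: dict[str, int] = {}
        for codon, n in self.counts.items():
            aa = AA3[self.code.forward[codon]]
            totals[aa] = totals.get(aa, 0) + n
        return totals


def amino_acid_usage(table: CodonUsageTable) -> list[tuple[str, int]]:
    """Amino acids (stops excluded) ranked by usage, ties alphabetical."""
    totals = {
        aa: n for aa, n in table.aa_counts.items() if aa != "stop codon"
    }
    return sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))


def codon_ranking(table: CodonUsageTable, *, include_stops: bool = False,
                  include_zero: bool = False) -> list[tuple[str, int]]:
    """Codons ranked by count descending, ties alphabetical by codon."""
    items = []
    for codon in RNA_CODONS:
        n = table.counts.get(codon, 0)
        if not include_stops and codon in table.code.stop_codons:
            continue
        if n == 0 and not include_zero:
            continue
        items.append((codon, n))
    return sorted(items, key=lambda kv: (-kv[1], kv[0]))
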