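"""TSV report writers with centralized, table-precision rounding.

All numeric formatting funnels through :func:`round_half_up` so that the
reported precision (contents 2 dp, skews 4 dp, RSCU 2 dp, Hd/k 3 dp,
pi 4 dp, Tajima's D 4 dp) lives in one place.
"""
from __future__ import annotations

import csv
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable

from .architecture import AdjacencyGap, OverlapCensus
from .codons import AA3, CodonUsageTable, RNA_CODONS
from .composition import PartitionComposition
from .diversity import DiversitySummary
from .kaks import KaKsResult

__all__ = [
    "round_half_up",
    "write_architecture_tsv",
    "write_composition_tsv",
    "write_codon_usage_tsv",
    "write_kaks_tsv",
    "write_diversity_tsv",
]


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal round-half-up (0.005 -> 0.01), matching printed tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _fmt(x: float | None, ndigits: int) -> str:
    if x is None:
        return "NA"
    return f"{round_half_up(x, ndigits):.{ndigits}f}"


def _write_rows(path: str | Path, header: list[str],
                rows: Iterable[list]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        writer.writerows(rows)


def write_architecture_tsv(path: str | Path, gaps: list[AdjacencyGap],
                           census: OverlapCensus) -> None:
    rows = [[g.upstream, g.downstream, g.gap,
             "wrap" if g.circular_wrap else ""] for g in gaps]
    rows.append([
        "#summary",
        f"overlaps={census.n_overlaps}",
        f"spacers={census.n_spacers}",
        f"max_overlap={census.max_overlap};max_spacer={census.max_spacer}",
    ])
    _write_rows(path, ["Upstream", "Downstream", "IntergenicLength", "Note"],
                rows)


def write_composition_tsv(path: str | Path,
                          rows: list[PartitionComposition]) -> None:
    out = [
        [
            r.label, r.size,
            _fmt(r.pA, 2), _fmt(r.pT, 2), _fmt(r.pG, 2), _fmt(r.pC, 2),
            _fmt(r.at_content, 2), _fmt(r.gc_content, 2),
            _fmt(r.at_skew, 4), _fmt(r.gc_skew, 4),
        ]
        for r in rows
    ]
    _write_rows(
        path,
        ["Location", "Size", "A", "T", "G", "C", "A+T", "G+C",
         "AT skew", "GC skew"],
        out,
    )


def write_codon_usage_tsv(path: str | Path, table: CodonUsageTable) -> None:
    rscu_map = table.rscu
    rows = [
        [AA3[table.code.forward[codon]], codon, table.counts.get(codon, 0),
         _fmt(rscu_map[codon], 2)]
        for codon in RNA_CODONS
    ]
    _write_rows(path, ["AminoAcid", "Codon", "Count", "RSCU"], rows)


def write_kaks_tsv(path: str | Path, results: list[KaKsResult]) -> None:
    rows = [
        [r.gene, _fmt(r.ka, 4), _fmt(r.ks, 4), _fmt(r.omega, 4),
         _fmt(r.N, 2), _fmt(r.S, 2), _fmt(r.nN, 2), _fmt(r.nS, 2)]
        for r in results
    ]
    _write_rows(path, ["Gene", "Ka", "Ks", "omega", "N", "S", "nN", "nS"],
                rows)


def write_diversity_tsv(path: str | Path, summary: DiversitySummary,
                        population: str = "sample") -> None:
    _write_rows(
        path,
        ["Population", "n", "L", "NumberOfHaplotypes", "HaplotypeDiversity",
         "AvgNucleotideDifference", "NucleotideDiversity",
         "SegregatingSites", "TajimasD"],
        [[
            population, summary.n, summary.L, summary.n_hap,
            _fmt(summary.Hd, 3), _fmt(summary.k_bar, 3),
            _fmt(summary.pi, 4), summary.S, _fmt(summary.tajima_D, 4),
        ]],
    )
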