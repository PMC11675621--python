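"""Base composition and strand-asymmetry (AT/GC skew) statistics.

Skews measure compositional asymmetry between the two strands:

    AT skew = (A - T) / (A + T)        GC skew = (G - C) / (G + C)

computed on counts of the reported (heavy) strand; equivalently on
percentages. Ambiguity codes are excluded from all counts and denominators.
"""
from __future__ import annotations

from dataclasses import dataclass

from .model import AnnotatedMitogenome, MitocharError
from .architecture import Partition

__all__ = [
    "PartitionComposition",
    "SkewUndefinedError",
    "compose",
    "skew",
    "skews_from_percentages",
    "per_gene_skews",
]


class SkewUndefinedError(MitocharError):
    """Skew denominator is zero (no A/T or no G/C bases)."""


@dataclass(frozen=True)
class PartitionComposition:
    """One composition-table row: percentages, contents and both skews.

    ``at_skew``/``gc_skew`` are ``None`` only when constructed with
    ``strict=False`` and the corresponding base classes are absent.
    """

    label: str
    size: int
    pA: float
    pT: float
    pG: float
    pC: float
    at_content: float
    gc_content: float
    at_skew: float | None
    gc_skew: float | None


def skew(x: float, y: float) -> float:
    """(x - y) / (x + y) on counts or percentages."""
    if x + y == 0:
        raise SkewUndefinedError("skew undefined: denominator is zero")
    return (x - y) / (x + y)


def skews_from_percentages(pA: float, pT: float, pG: float, pC: float
                           ) -> tuple[float, float]:
    """AT and GC skew straight from printed percentages."""
    return skew(pA, pT), skew(pG, pC)


def compose(seq: str, label: str = "", *, strict: bool = True
            ) -> PartitionComposition:
    """Composition record for one sequence.

    With ``strict=True`` (default) a zero skew denominator raises
    :class:`SkewUndefinedError`; with ``strict=False`` that skew is ``None``
    (useful for extreme per-gene profiles).
    """
    if not seq:
        raise MitocharError("cannot compose an empty sequence")
    s = seq.upper()
    a, t, g, c = s.count("A"), s.count("T"), s.count("G"), s.count("C")
    total = a + t + g + c
    if total == 0:
        raise SkewUndefinedError(
            f"{label or 'sequence'}: no unambiguous bases"
        )

    def _skew(x: int, y: int) -> float | None:
        if x + y == 0:
            if strict:
                raise SkewUndefinedError(
                    f"{label or 'sequence'}: skew denominator is zero"
                )
            return None
        return (x - y) / (x + y)

    pA, pT, pG, pC = (100 * n / total for n in (a, t, g, c))
    return PartitionComposition(
        label=label,
        size=len(s),
        pA=pA,
        pT=pT,
        pG=pG,
        pC=pC,
        at_content=pA + pT,
        gc_content=pG + pC,
        at_skew=_skew(a, t),
        gc_skew=_skew(g, c),
    )


def compose_partition(p: Partition, *, strict: bool = True) -> PartitionComposition:
    return compose(p.seq, p.label, strict=strict)


def per_gene_skews(genome: AnnotatedMitogenome) -> list[PartitionComposition]:
    """Per-PCG composition profiles on strand-corrected coding sequences.

    The stop codon is retained here (a gene profile, not the partition
    accounting). Degenerate compositions yield ``None`` skews rather than
    an error.
    """
    return [
        compose(genome.extract(f), f.name, strict=False) for f in genome.pcgs
    ]
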