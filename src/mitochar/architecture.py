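"""Genome architecture: intergenic gaps, overlap/spacer census, partitions.

The intergenic length between consecutive features is
``next.start - this.end - 1``; a negative value is an overlap. On a
circular genome the last feature closes back onto the first:
``gap = L - last.end + first.start - 1``.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

from .model import AnnotatedMitogenome, FeatureRecord, FeatureType, MitocharError

__all__ = [
    "AdjacencyGap",
    "OverlapCensus",
    "Partition",
    "PARTITION_LABELS",
    "adjacency_gaps",
    "overlap_census",
    "extract_partition",
    "stopless_cds",
    "genome_length_closure",
]

PARTITION_LABELS = (
    "genome",
    "PCGs",
    "codon1",
    "codon2",
    "codon3",
    "rRNA",
    "tRNA",
    "control",
)


@dataclass(frozen=True)
class AdjacencyGap:
    upstream: str
    downstream: str
    gap: int  # bp; negative = overlap of |gap| bp
    circular_wrap: bool = False


class OverlapCensus(NamedTuple):
    n_overlaps: int
    n_spacers: int
    max_overlap: int  # magnitude, bp
    max_spacer: int  # bp


@dataclass(frozen=True)
class Partition:
    label: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


def adjacency_gaps(genome: AnnotatedMitogenome) -> list[AdjacencyGap]:
    """One signed gap per consecutive feature pair, in genomic order.

    Includes the origin-wrapping closure gap when the genome is circular.
    """
    feats = genome.features
    gaps: list[AdjacencyGap] = []
    for cur, nxt in zip(feats, feats[1:]):
        gaps.append(AdjacencyGap(cur.name, nxt.name, nxt.start - cur.end - 1))
    if genome.circular and len(feats) >= 2:
        last, first = feats[-1], feats[0]
        gaps.append(
            AdjacencyGap(
                last.name,
                first.name,
                len(genome) - last.end + first.start - 1,
                circular_wrap=True,
            )
        )
    return gaps


def overlap_census(gaps: Iterable[AdjacencyGap]) -> OverlapCensus:
    values = [g.gap for g in gaps]
    overlaps = [-v for v in values if v < 0]
    spacers = [v for v in values if v > 0]
    return OverlapCensus(
        n_overlaps=len(overlaps),
        n_spacers=len(spacers),
        max_overlap=max(overlaps, default=0),
        max_spacer=max(spacers, default=0),
    )


def stopless_cds(genome: AnnotatedMitogenome, feature: FeatureRecord) -> str:
    """Coding-orientation CDS with the terminal stop removed.

    The annotated stop token decides how much to trim: a complete triplet
    removes 3 bp, an incomplete "T"/"TA" removes 1–2 bp. Without a stop
    annotation, trailing out-of-frame bases (length mod 3) are trimmed.
    """
    cds = genome.extract(feature)
    if feature.stop_codon is not None:
        trim = len(feature.stop_codon)
    else:
        trim = len(cds) % 3
    return cds[: len(cds) - trim] if trim else cds


def extract_partition(genome: AnnotatedMitogenome, label: str) -> Partition:
    """Concatenated, strand-corrected sequence of one compositional partition.

    The PCG partition drops each gene's stop codon (complete or incomplete),
    so its length is exactly 3x the per-codon-position length; codon
    positions are taken per gene, never across gene junctions. Overlapping
    genes contribute their full spans independently.
    """
    if label not in PARTITION_LABELS:
        raise MitocharError(
            f"unknown partition label {label!r}; expected one of "
            f"{PARTITION_LABELS}"
        )
    if label == "genome":
        return Partition(label, genome.seq)

    if label in ("PCGs", "codon1", "codon2", "codon3"):
        pieces = []
        for f in genome.pcgs:
            coding = stopless_cds(genome, f)
            if label == "PCGs":
                pieces.append(coding)
            else:
                offset = int(label[-1]) - 1
                pieces.append(coding[offset::3])
        return Partition(label, "".join(pieces))

    ftype = {
        "rRNA": FeatureType.RRNA,
        "tRNA": FeatureType.TRNA,
        "control": FeatureType.CONTROL,
    }[label]
    return Partition(
        label, "".join(genome.extract(f) for f in genome.features_of_type(ftype))
    )


def genome_length_closure(features: list[FeatureRecord], trailing_gap: int) -> int:
    """Circular-closure check: genome length implied by the last feature.

    ``last.end + trailing_gap`` must equal the sequence length on a
    consistent annotation.
    """
    if not features:
        raise MitocharError("no features")
    last = max(features, key=lambda f: f.end)
    length = last.end + trailing_gap
    if length <= 0:
        raise MitocharError(f"implied genome length {length} is not positive")
    return length
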