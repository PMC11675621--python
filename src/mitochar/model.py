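"""Core data model: annotated circular mitogenomes and their features.

Coordinates are 1-based inclusive throughout, matching the convention of
published mitogenome annotation tables. A feature may wrap the origin
(``end < start``) only on a circular genome.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

__all__ = [
    "Strand",
    "FeatureType",
    "FeatureRecord",
    "AnnotatedMitogenome",
    "CoordinateError",
    "MitocharError",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTRYKMBDHVN", "TGCAYRMKVHDBN")


class MitocharError(Exception):
    """Base class for errors raised by this package."""


class CoordinateError(MitocharError):
    """A feature's coordinates fall outside the genome or are inconsistent."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class Strand(enum.Enum):
    """Mitochondrial strand: H (heavy) or L (light)."""

    H = "H"
    L = "L"

    @classmethod
    def parse(cls, token: str) -> "Strand":
        tok = token.strip().upper()
        if tok in ("H", "+", "1"):
            return cls.H
        if tok in ("L", "-", "-1"):
            return cls.L
        raise ValueError(f"unknown strand token: {token!r}")


class FeatureType(enum.Enum):
    PCG = "PCG"
    TRNA = "tRNA"
    RRNA = "rRNA"
    CONTROL = "control"
    ORIGIN = "origin"

    @classmethod
    def parse(cls, token: str) -> "FeatureType":
        tok = token.strip().lower()
        for member in cls:
            if member.value.lower() == tok:
                return member
        aliases = {
            "cds": cls.PCG,
            "gene": cls.PCG,
            "trna": cls.TRNA,
            "rrna": cls.RRNA,
            "d-loop": cls.CONTROL,
            "control region": cls.CONTROL,
            "rep_origin": cls.ORIGIN,
        }
        if tok in aliases:
            return aliases[tok]
        raise ValueError(f"unknown feature type: {token!r}")


@dataclass(frozen=True)
class FeatureRecord:
    """One annotated gene or region.

    ``stop_codon`` may be a complete triplet ("TAA", "TAG") or an incomplete
    terminal token ("T", "TA") completed post-transcriptionally by
    polyadenylation. Codon metadata is stored as DNA (T, not U).
    """

    name: str
    ftype: FeatureType
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: Strand
    anticodon: str | None = None
    start_codon: str | None = None
    stop_codon: str | None = None

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < 1:
            raise CoordinateError(
                f"{self.name}: coordinates must be positive, got "
                f"{self.start}..{self.end}"
            )

    @property
    def wraps(self) -> bool:
        return self.end < self.start

    def length(self, genome_length: int | None = None) -> int:
        """Feature length in bp; wrapping features need the genome length."""
        if not self.wraps:
            return self.end - self.start + 1
        if genome_length is None:
            raise CoordinateError(
                f"{self.name}: wrapping feature needs genome length"
            )
        return genome_length - self.start + 1 + self.end


@dataclass
class AnnotatedMitogenome:
    """A (typically circular) mitogenome sequence plus ordered annotations.

    Features are kept sorted by start coordinate, which for animal
    mitogenomes equals genomic order.
    """

    seq: str
    circular: bool = True
    features: list[FeatureRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        L = len(self.seq)
        for f in self.features:
            if f.start > L or f.end > L:
                raise CoordinateError(
                    f"{f.name}: {f.start}..{f.end} beyond sequence "
                    f"length {L}"
                )
            if f.wraps and not self.circular:
                raise CoordinateError(
                    f"{f.name}: wrapping feature on a linear genome"
                )
        self.features = sorted(self.features, key=lambda f: f.start)

    def __len__(self) -> int:
        return len(self.seq)

    def features_of_type(self, ftype: FeatureType) -> list[FeatureRecord]:
        return [f for f in self.features if f.ftype is ftype]

    @property
    def pcgs(self) -> list[FeatureRecord]:
        return self.features_of_type(FeatureType.PCG)

    def region(self, start: int, end: int) -> str:
        """1-based inclusive slice; wraps the origin when end < start."""
        if end >= start:
            return self.seq[start - 1 : end]
        if not self.circular:
            raise CoordinateError("wrapping slice on a linear genome")
        return self.seq[start - 1 :] + self.seq[:end]

    def extract(self, feature: FeatureRecord) -> str:
        """Strand-corrected feature sequence (coding orientation for PCGs)."""
        raw = self.region(feature.start, feature.end)
        return reverse_complement(raw) if feature.strand is Strand.L else raw

    def reverse_complemented(self) -> "AnnotatedMitogenome":
        """The same genome read from the other strand (coordinates flipped)."""
        L = len(self.seq)
        flipped = []
        for f in self.features:
            flipped.append(
                replace(
                    f,
                    start=L - f.end + 1,
                    end=L - f.start + 1,
                    strand=Strand.L if f.strand is Strand.H else Strand.H,
                )
            )
        return AnnotatedMitogenome(
            seq=reverse_complement(self.seq),
            circular=self.circular,
            features=flipped,
        )
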