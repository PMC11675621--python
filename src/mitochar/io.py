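"""Read/write annotated mitogenomes and population alignments.

Two equivalent on-disk representations are supported:

* a GenBank flat file (sequence + CDS/tRNA/rRNA/D-loop/rep_origin features),
* a FASTA sequence plus a tab-separated feature table whose columns mirror
  the usual published gene-characteristics table
  (Name/Strand/Start/End/Type[/Anticodon/StartCodon/StopCodon]).

Both yield the same :class:`~mitochar.model.AnnotatedMitogenome`.
"""
from __future__ import annotations

import csv
import warnings
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .model import (
    AnnotatedMitogenome,
    CoordinateError,
    FeatureRecord,
    FeatureType,
    MitocharError,
    Strand,
)

__all__ = [
    "read_genbank",
    "write_genbank",
    "read_feature_tsv",
    "write_feature_tsv",
    "read_population_fasta",
    "write_fasta",
    "AlignmentLengthError",
]

_GB_TYPE_MAP = {
    "CDS": FeatureType.PCG,
    "tRNA": FeatureType.TRNA,
    "rRNA": FeatureType.RRNA,
    "D-loop": FeatureType.CONTROL,
    "rep_origin": FeatureType.ORIGIN,
}
_GB_TYPE_INV = {v: k for k, v in _GB_TYPE_MAP.items()}

_TSV_COLUMNS = [
    "Name",
    "Strand",
    "Start",
    "End",
    "Type",
    "Anticodon",
    "StartCodon",
    "StopCodon",
]


class AlignmentLengthError(MitocharError):
    """Population sequences do not form an alignment (unequal lengths)."""


def _codon_metadata(seq: str, ftype: FeatureType) -> tuple[str | None, str | None]:
    """Derive start/stop codon tokens from a coding-orientation sequence.

    The stop token is the full terminal triplet when the length is a codon
    multiple, otherwise the trailing 1–2 bases (an incomplete stop completed
    by polyadenylation).
    """
    if ftype is not FeatureType.PCG or len(seq) < 6:
        return None, None
    tail = len(seq) % 3
    stop = seq[-3:] if tail == 0 else seq[-tail:]
    return seq[:3], stop


def read_genbank(path: str | Path) -> AnnotatedMitogenome:
    """Read an annotated mitogenome from a GenBank flat file.

    Complement locations become strand L. Start/stop codon tokens for CDS
    features are derived from the annotated coordinates and the sequence.
    """
    try:
        record = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise MitocharError(f"{path}: malformed GenBank file: {exc}") from exc
    try:
        seq = str(record.seq).upper()
    except Exception as exc:  # undefined sequence (no ORIGIN block)
        raise MitocharError(f"{path}: no sequence (missing ORIGIN?)") from exc
    if not seq:
        raise MitocharError(f"{path}: empty sequence (missing ORIGIN?)")
    circular = record.annotations.get("topology", "circular") == "circular"

    features: list[FeatureRecord] = []
    for feat in record.features:
        if feat.type not in _GB_TYPE_MAP:
            continue
        ftype = _GB_TYPE_MAP[feat.type]
        start = int(feat.location.start) + 1  # Biopython is 0-based half-open
        end = int(feat.location.end)
        if end > len(seq) or start > len(seq):
            raise CoordinateError(
                f"{path}: feature {start}..{end} beyond {len(seq)} bp"
            )
        strand = Strand.L if feat.location.strand == -1 else Strand.H
        quals = feat.qualifiers
        name = (
            quals.get("gene", quals.get("product", quals.get("note", ["?"])))
        )[0]
        sub = seq[start - 1 : end]
        if strand is Strand.L:
            sub = str(Seq(sub).reverse_complement())
        start_codon, stop_codon = _codon_metadata(sub, ftype)
        anticodon = quals.get("anticodon", [None])[0]
        features.append(
            FeatureRecord(
                name=name,
                ftype=ftype,
                start=start,
                end=end,
                strand=strand,
                anticodon=anticodon,
                start_codon=start_codon,
                stop_codon=stop_codon,
            )
        )
    return AnnotatedMitogenome(seq=seq, circular=circular, features=features)


def write_genbank(genome: AnnotatedMitogenome, path: str | Path,
                  name: str = "mitogenome") -> None:
    record = SeqRecord(
        Seq(genome.seq),
        id=name,
        name=name[:16],
        description="annotated mitochondrial genome",
    )
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = "circular" if genome.circular else "linear"
    for f in genome.features:
        loc = FeatureLocation(
            f.start - 1, f.end, strand=-1 if f.strand is Strand.L else 1
        )
        quals: dict[str, list[str]] = {"gene": [f.name]}
        if f.anticodon:
            quals["anticodon"] = [f.anticodon]
        record.features.append(
            SeqFeature(loc, type=_GB_TYPE_INV[f.ftype], qualifiers=quals)
        )
    SeqIO.write(record, str(path), "genbank")


def read_feature_tsv(seq_path: str | Path, table_path: str | Path,
                     circular: bool = True) -> AnnotatedMitogenome:
    """Read a FASTA sequence plus a TSV feature table.

    Coordinates are taken verbatim (1-based inclusive). A row with
    End < Start denotes a feature wrapping the origin and requires
    ``circular=True``. Duplicate feature names are allowed (warn only).
    """
    seq_record = next(SeqIO.parse(str(seq_path), "fasta"))
    seq = str(seq_record.seq).upper()

    features: list[FeatureRecord] = []
    seen: set[str] = set()
    with open(table_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"Name", "Strand", "Start", "End", "Type"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise MitocharError(
                f"{table_path}: feature table must have columns "
                f"{sorted(required)}"
            )
        for row in reader:
            name = row["Name"].strip()
            if name in seen:
                warnings.warn(f"duplicate feature name {name!r}", stacklevel=2)
            seen.add(name)

            def _opt(key: str) -> str | None:
                val = (row.get(key) or "").strip()
                return val if val and val != "-" else None

            features.append(
                FeatureRecord(
                    name=name,
                    ftype=FeatureType.parse(row["Type"]),
                    start=int(row["Start"].replace(",", "")),
                    end=int(row["End"].replace(",", "")),
                    strand=Strand.parse(row["Strand"]),
                    anticodon=_opt("Anticodon"),
                    start_codon=_opt("StartCodon"),
                    stop_codon=_opt("StopCodon"),
                )
            )
    return AnnotatedMitogenome(seq=seq, circular=circular, features=features)


def write_feature_tsv(genome: AnnotatedMitogenome, seq_path: str | Path,
                      table_path: str | Path, name: str = "mitogenome") -> None:
    write_fasta([(name, genome.seq)], seq_path)
    with open(table_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TSV_COLUMNS)
        for f in genome.features:
            writer.writerow(
                [
                    f.name,
                    f.strand.value,
                    f.start,
                    f.end,
                    f.ftype.value,
                    f.anticodon or "-",
                    f.start_codon or "-",
                    f.stop_codon or "-",
                ]
            )


def read_population_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read an aligned population sample; all sequences must share a length."""
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise MitocharError(f"{path}: no FASTA records")
    lengths = {len(s) for _, s in records}
    if len(lengths) > 1:
        raise AlignmentLengthError(
            f"{path}: sequences have unequal lengths {sorted(lengths)}; "
            "diversity statistics require an alignment"
        )
    return records


def write_fasta(records: list[tuple[str, str]], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
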