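"""Synthetic data generators for every pipeline input.

Three kinds of fixtures are produced, all deterministic under a seed:

* annotated mitogenomes realizing an arbitrary feature layout (default:
  the published 39-feature layout of the *L. langsoni* mitogenome) whose
  protein-coding genes are valid ORFs under the vertebrate mitochondrial
  code, with the annotated start/stop tokens, overlaps and incomplete
  stops materialized in the sequence;
* diverged genome pairs evolved codon-wise with a controlled
  nonsynonymous acceptance ratio (a simple mutation-filter model, not a
  full codon substitution model);
* population alignments with an exact haplotype configuration, and
  neutral-coalescent samples (Hudson's algorithm with infinite-sites
  mutations) for calibration of diversity statistics.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .codons import VERTEBRATE_MITO, GeneticCode
from .model import (
    AnnotatedMitogenome,
    FeatureRecord,
    FeatureType,
    MitocharError,
    Strand,
)
from .reference import GENOME_LENGTH, REFERENCE_GENOME_COMPOSITION, reference_features

__all__ = [
    "GenomeSpec",
    "PopulationSpec",
    "make_genome",
    "evolve_pair",
    "make_population",
    "make_coalescent_sample",
]

_BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


class LayoutError(MitocharError):
    """The requested feature layout cannot be realized as a sequence."""


@dataclass(frozen=True)
class GenomeSpec:
    """Blueprint for a synthetic annotated mitogenome.

    ``composition`` gives target A/T/G/C fractions for randomly drawn
    bases; the realized genome-wide composition lands within about two
    percentage points of it (codon pinning and stop avoidance perturb the
    draw slightly).
    """

    length: int = GENOME_LENGTH
    features: tuple[FeatureRecord, ...] = field(
        default_factory=lambda: tuple(reference_features())
    )
    composition: tuple[float, float, float, float] = REFERENCE_GENOME_COMPOSITION
    seed: int = 0

    @classmethod
    def from_gap_layout(cls, rows: list[tuple], length: int,
                        **kwargs) -> "GenomeSpec":
        """Build from (name, ftype, strand, size, gap_to_next[, anticodon,
        start_codon, stop_codon]) rows; coordinates accumulate from 1 and
        must close the circle at ``length``."""
        feats = []
        start = 1
        closure = None
        for row in rows:
            name, ftype, strand, size, gap = row[:5]
            extras = list(row[5:]) + [None] * (3 - len(row[5:]))
            end = start + size - 1
            feats.append(
                FeatureRecord(
                    name=name, ftype=ftype, strand=strand, start=start,
                    end=end, anticodon=extras[0], start_codon=extras[1],
                    stop_codon=extras[2],
                )
            )
            start = end + gap + 1
            closure = end + gap
        if closure is not None and closure != length:
            raise LayoutError(
                f"layout closes at {closure} bp, declared length {length}"
            )
        return cls(length=length, features=tuple(feats), **kwargs)


def _coding_positions(f: FeatureRecord) -> list[int]:
    """Genome positions (1-based) of a feature in coding-strand order."""
    span = list(range(f.start, f.end + 1))
    return span[::-1] if f.strand is Strand.L else span


def _pin(pins: dict[int, str], pos: int, base: str, name: str) -> None:
    prev = pins.get(pos)
    if prev is not None and prev != base:
        raise LayoutError(
            f"{name}: position {pos} needs {base} but is already {prev}"
        )
    pins[pos] = base


def _pin_codon_tokens(features: tuple[FeatureRecord, ...]) -> dict[int, str]:
    pins: dict[int, str] = {}
    for f in features:
        if f.ftype is not FeatureType.PCG:
            continue
        order = _coding_positions(f)
        if f.start_codon:
            for i, base in enumerate(f.start_codon.upper()):
                g = base if f.strand is Strand.H else _COMP[base]
                _pin(pins, order[i], g, f.name)
        if f.stop_codon:
            token = f.stop_codon.upper()
            for i, base in enumerate(token):
                pos = order[len(order) - len(token) + i]
                g = base if f.strand is Strand.H else _COMP[base]
                _pin(pins, pos, g, f.name)
    return pins


def _sample_codon(fixed: list[str | None], rng: np.random.Generator,
                  p: tuple[float, ...], code: GeneticCode,
                  allow_stop: bool) -> str:
    """Draw a codon consistent with fixed bases; avoid stops unless allowed."""
    for _ in range(60):
        bases = [
            b if b is not None else str(rng.choice(_BASES, p=p))
            for b in fixed
        ]
        codon = "".join(bases)
        if allow_stop or not code.is_stop(codon):
            return codon
    # rejection failed (heavily constrained codon): enumerate
    candidates = []
    for b0 in "ACGT":
        for b1 in "ACGT":
            for b2 in "ACGT":
                codon = b0 + b1 + b2
                if all(f is None or f == c for f, c in zip(fixed, codon)):
                    if allow_stop or not code.is_stop(codon):
                        candidates.append(codon)
    if not candidates:
        raise _Retry
    return candidates[rng.integers(len(candidates))]


class _Retry(Exception):
    pass


def _fill_once(spec: GenomeSpec, rng: np.random.Generator,
               code: GeneticCode) -> str:
    buf: list[str | None] = [None] * spec.length
    for pos, base in _pin_codon_tokens(spec.features).items():
        if pos > spec.length:
            raise LayoutError(f"pinned position {pos} beyond genome")
        buf[pos - 1] = base

    fa, ft, fg, fc = spec.composition
    p = np.asarray([fa, fc, fg, ft], dtype=float)  # _BASES order is A,C,G,T
    p = p / p.sum()  # printed fractions may not sum to exactly 1
    pcgs = sorted(
        (f for f in spec.features if f.ftype is FeatureType.PCG),
        key=lambda f: f.start,
    )
    for f in pcgs:
        order = _coding_positions(f)
        n_codons = len(order) // 3
        stop_token = (f.stop_codon or "").upper()
        complete_stop_at = n_codons - 1 if len(stop_token) == 3 else None
        for j in range(n_codons):
            positions = order[3 * j : 3 * j + 3]
            fixed = [buf[pos - 1] for pos in positions]
            coding_fixed = [
                b if f.strand is Strand.H or b is None else _COMP[b]
                for b in fixed
            ]
            allow_stop = j == complete_stop_at
            if all(b is not None for b in coding_fixed):
                codon = "".join(coding_fixed)  # fully constrained by overlap
                if code.is_stop(codon) and not allow_stop:
                    raise _Retry
                continue
            codon = _sample_codon(coding_fixed, rng, p, code, allow_stop)
            for pos, base in zip(positions, codon):
                buf[pos - 1] = base if f.strand is Strand.H else _COMP[base]

    free = [i for i, b in enumerate(buf) if b is None]
    if free:
        draws = rng.choice(_BASES, size=len(free), p=p)
        for i, b in zip(free, draws):
            buf[i] = str(b)
    return "".join(buf)  # type: ignore[arg-type]


def make_genome(spec: GenomeSpec,
                code: GeneticCode = VERTEBRATE_MITO) -> AnnotatedMitogenome:
    """Realize a spec as an annotated genome; deterministic under its seed.

    Overlapping PCGs constrain each other: codons fully fixed by an
    earlier gene occasionally form an in-frame stop in the later gene, in
    which case generation restarts from the next RNG substream (bounded).
    """
    for f in spec.features:
        if f.end > spec.length:
            raise LayoutError(
                f"{f.name}: end {f.end} beyond genome length {spec.length}"
            )
    rng = np.random.default_rng(spec.seed)
    for _ in range(50):
        try:
            seq = _fill_once(spec, rng, code)
        except _Retry:
            continue
        return AnnotatedMitogenome(
            seq=seq, circular=True, features=list(spec.features)
        )
    raise LayoutError("could not realize layout without internal stops")


def _pcg_coverage(genome: AnnotatedMitogenome) -> np.ndarray:
    cov = np.zeros(len(genome) + 1, dtype=np.int8)
    for f in genome.pcgs:
        cov[f.start : f.end + 1] += 1
    return cov


def evolve_pair(genome: AnnotatedMitogenome, t: float, omega_true: float,
                seed: int, code: GeneticCode = VERTEBRATE_MITO
                ) -> AnnotatedMitogenome:
    """Evolve a copy of ``genome`` under a mutation-filter model.

    Per sense codon, candidate single-base mutations arrive as
    Poisson(``t``); a synonymous candidate is always accepted, an
    amino-acid-changing one with probability ``omega_true``; candidates
    creating a stop are rejected. Non-coding positions mutate neutrally at
    the matched per-base rate. Codons shared between overlapping genes are
    left untouched so the two genes' histories stay independent.
    """
    if t < 0 or omega_true < 0:
        raise MitocharError("t and omega_true must be nonnegative")
    rng = np.random.default_rng(seed)
    seq = list(genome.seq)
    cov = _pcg_coverage(genome)

    for f in genome.pcgs:
        order = _coding_positions(f)
        n_codons = len(order) // 3
        stop_token = (f.stop_codon or "").upper()
        last_sense = n_codons - 1 if len(stop_token) == 3 else n_codons
        for j in range(last_sense):
            positions = order[3 * j : 3 * j + 3]
            if any(cov[pos] > 1 for pos in positions):
                continue  # frozen: shared with an overlapping gene
            for _ in range(rng.poisson(t)):
                codon = [
                    seq[pos - 1] if f.strand is Strand.H
                    else _COMP[seq[pos - 1]]
                    for pos in positions
                ]
                k = int(rng.integers(3))
                alts = [b for b in "ACGT" if b != codon[k]]
                new = codon.copy()
                new[k] = alts[int(rng.integers(3))]
                if code.is_stop("".join(new)):
                    continue
                if (code.translate("".join(new)) != code.translate("".join(codon))
                        and rng.random() >= omega_true):
                    continue
                pos = positions[k]
                seq[pos - 1] = new[k] if f.strand is Strand.H else _COMP[new[k]]

    p_site = 1.0 - np.exp(-t / 3.0)
    for pos in np.nonzero(cov == 0)[0]:
        if pos == 0:
            continue
        if rng.random() < p_site:
            alts = [b for b in "ACGT" if b != seq[pos - 1]]
            seq[pos - 1] = alts[int(rng.integers(3))]

    return AnnotatedMitogenome(
        seq="".join(seq), circular=genome.circular,
        features=[replace(f) for f in genome.features],
    )


@dataclass(frozen=True)
class PopulationSpec:
    """Blueprint for an aligned population sample with exact haplotype
    structure: ``hap_config`` lists (frequency, mutated-site list) pairs,
    sites 0-based on the base haplotype."""

    n: int
    L: int
    hap_config: tuple[tuple[int, tuple[int, ...]], ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(f for f, _ in self.hap_config) != self.n:
            raise MitocharError("haplotype frequencies must sum to n")
        for freq, sites in self.hap_config:
            if len(set(sites)) != len(sites):
                raise MitocharError(f"duplicate site in {sites}")
            if any(s < 0 or s >= self.L for s in sites):
                raise MitocharError("mutated site outside the alignment")


def make_population(spec: PopulationSpec) -> list[tuple[str, str]]:
    """Generate the aligned sample; order shuffled deterministically."""
    rng = np.random.default_rng(spec.seed)
    base = rng.choice(_BASES, size=spec.L)
    records: list[tuple[str, str]] = []
    idx = 0
    for hap_no, (freq, sites) in enumerate(spec.hap_config, start=1):
        hap = base.copy()
        for s in sites:
            alts = [b for b in "ACGT" if b != hap[s]]
            hap[s] = alts[int(rng.integers(3))]
        hap_seq = "".join(hap)
        for _ in range(freq):
            idx += 1
            records.append((f"ind{idx:03d}_h{hap_no}", hap_seq))
    order = rng.permutation(len(records))
    return [records[i] for i in order]


def make_coalescent_sample(n: int, theta: float, L: int,
                           seed: int = 0) -> list[tuple[str, str]]:
    """Sample under the standard neutral coalescent with infinite sites.

    Hudson's algorithm: with k active lineages the next coalescence is
    exponential with rate k(k-1)/2 (time in units of 2N generations);
    mutations fall on each branch as Poisson(theta * branch / 2) and each
    takes a fresh alignment column.
    """
    if n < 2:
        raise MitocharError("coalescent sample needs n >= 2")
    if theta <= 0:
        raise MitocharError("theta must be positive")
    rng = np.random.default_rng(seed)

    node_time = {i: 0.0 for i in range(n)}
    leaves = {i: frozenset([i]) for i in range(n)}
    branches: list[tuple[frozenset[int], float]] = []  # (carriers, length)
    active = list(range(n))
    t = 0.0
    next_id = n
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(len(active), size=2, replace=False)
        a, b = active[int(i)], active[int(j)]
        for child in (a, b):
            branches.append((leaves[child], t - node_time[child]))
        merged = leaves[a] | leaves[b]
        active = [x for x in active if x not in (a, b)] + [next_id]
        node_time[next_id] = t
        leaves[next_id] = merged
        next_id += 1

    muts: list[frozenset[int]] = []
    for carriers, length in branches:
        muts.extend([carriers] * rng.poisson(theta * length / 2.0))
    if len(muts) > L:
        raise MitocharError(
            f"{len(muts)} mutations exceed alignment length {L}; "
            "increase L or lower theta"
        )

    mat = np.tile(rng.choice(_BASES, size=L), (n, 1))
    sites = rng.choice(L, size=len(muts), replace=False)
    for site, carriers in zip(sites, muts):
        ref = mat[0, site]
        alts = [b for b in "ACGT" if b != ref]
        derived = alts[int(rng.integers(3))]
        for leaf in carriers:
            mat[leaf, site] = derived
    return [(f"sample{i:03d}", "".join(row)) for i, row in enumerate(mat)]
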