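"""Pairwise Ka/Ks by the Nei–Gojobori (1986) counting method.

For each codon the number of synonymous sites is the expected fraction of
single-base changes that preserve the amino acid, summed over the three
positions; changes creating a stop codon are excluded from the tally (the
usual refinement for coding sequences). Observed differences between a
codon pair separated by 2–3 changes are averaged over all minimal
mutational pathways with equal weight, skipping pathways that pass through
a stop codon. Proportions are corrected to distances with the
Jukes–Cantor (1969) formula d = -(3/4) ln(1 - 4p/3), and

    omega = Ka / Ks

with omega < 1 indicating purifying selection.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

from .architecture import stopless_cds
from .codons import VERTEBRATE_MITO, GeneticCode
from .model import AnnotatedMitogenome, MitocharError

__all__ = ["KaKsResult", "codon_align", "ng86", "kaks_screen", "mean_omega"]

_RNA_BASES = "UCAG"


@dataclass(frozen=True)
class KaKsResult:
    """Per-gene NG86 estimates. ``ka``/``ks``/``omega`` are ``None`` when
    undefined (no sites, saturated proportion, or Ks = 0 for omega)."""

    gene: str
    ka: float | None
    ks: float | None
    omega: float | None
    nN: float
    nS: float
    N: float
    S: float
    n_codons: int


def _as_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def codon_align(a: str, b: str, code: GeneticCode = VERTEBRATE_MITO
                ) -> list[tuple[str, str]]:
    """Pair two equal-length, in-frame, gap-free coding sequences codon by
    codon. Pairs containing ambiguity codes or in-frame stops are dropped
    with a warning."""
    if len(a) != len(b):
        raise MitocharError(f"length mismatch: {len(a)} vs {len(b)}")
    if len(a) % 3:
        raise MitocharError(f"length {len(a)} is not a codon multiple")
    a, b = _as_rna(a), _as_rna(b)
    pairs: list[tuple[str, str]] = []
    dropped = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if any(base not in _RNA_BASES for base in ca + cb):
            dropped += 1
            continue
        if ca in code.stop_codons or cb in code.stop_codons:
            dropped += 1
            continue
        pairs.append((ca, cb))
    if dropped:
        warnings.warn(
            f"dropped {dropped} codon pair(s) with ambiguity or stop codons",
            stacklevel=2,
        )
    return pairs


@lru_cache(maxsize=None)
def _site_counts(codon: str, table_id: int) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one codon.

    At each position the fraction of the single-base changes that are
    synonymous, over the changes that do not create a stop codon.
    """
    code = GeneticCode.from_table_id(table_id)
    aa = code.forward[codon]
    syn = 0.0
    for pos in range(3):
        n_syn = n_valid = 0
        for base in _RNA_BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if alt in code.stop_codons:
                continue
            n_valid += 1
            if code.forward[alt] == aa:
                n_syn += 1
        if n_valid:
            syn += n_syn / n_valid
    return syn, 3.0 - syn


def _pathway_differences(ca: str, cb: str, code: GeneticCode,
                         skip_stop_paths: bool = True) -> tuple[float, float]:
    """(nonsyn, syn) differences for one codon pair, averaged over all
    minimal mutational pathways; pathways through stops are skipped unless
    none survive."""
    diff_pos = [i for i in range(3) if ca[i] != cb[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff_pos):
        cur = ca
        steps = []
        blocked = False
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if (skip_stop_paths and nxt != cb
                    and nxt in code.stop_codons):
                blocked = True
                break
            steps.append((cur, nxt))
            cur = nxt
        if not blocked:
            paths.append(steps)
    if not paths and skip_stop_paths:
        return _pathway_differences(ca, cb, code, skip_stop_paths=False)
    nN = nS = 0.0
    for steps in paths:
        for cur, nxt in steps:
            if code.forward[cur] == code.forward[nxt]:
                nS += 1
            else:
                nN += 1
    return nN / len(paths), nS / len(paths)


def _jc69(p: float) -> float | None:
    """Jukes–Cantor distance; undefined at p >= 3/4."""
    if p >= 0.75:
        return None
    return -0.75 * math.log(1 - 4 * p / 3)


def ng86(pairs: list[tuple[str, str]], code: GeneticCode = VERTEBRATE_MITO,
         *, gene: str = "", skip_stop_paths: bool = True) -> KaKsResult:
    """Nei–Gojobori estimates for a list of aligned codon pairs.

    Site counts are computed on both sequences and averaged; N + S always
    equals 3x the number of pairs.
    """
    if not pairs:
        raise MitocharError("ng86 needs at least one codon pair")
    N = S = nN = nS = 0.0
    for ca, cb in pairs:
        ca, cb = _as_rna(ca), _as_rna(cb)
        sa, na = _site_counts(ca, code.table_id)
        sb, nb = _site_counts(cb, code.table_id)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        dn, ds = _pathway_differences(ca, cb, code, skip_stop_paths)
        nN += dn
        nS += ds
    ka = _jc69(nN / N) if N > 0 else None
    ks = _jc69(nS / S) if S > 0 else None
    omega = None
    if ka is not None and ks is not None and ks > 0:
        omega = ka / ks
    return KaKsResult(gene=gene, ka=ka, ks=ks, omega=omega,
                      nN=nN, nS=nS, N=N, S=S, n_codons=len(pairs))


def kaks_screen(g1: AnnotatedMitogenome, g2: AnnotatedMitogenome,
                code: GeneticCode = VERTEBRATE_MITO) -> list[KaKsResult]:
    """One NG86 result per protein-coding gene shared by name.

    Stop codons are stripped per annotation before codon pairing. Genes
    present in only one genome, or with mismatched CDS lengths, are skipped
    with a warning.
    """
    by_name = {f.name: f for f in g2.pcgs}
    results: list[KaKsResult] = []
    for f1 in g1.pcgs:
        f2 = by_name.get(f1.name)
        if f2 is None:
            warnings.warn(f"{f1.name}: absent from second genome; skipped",
                          stacklevel=2)
            continue
        a = stopless_cds(g1, f1)
        b = stopless_cds(g2, f2)
        try:
            pairs = codon_align(a, b, code)
        except MitocharError as exc:
            warnings.warn(f"{f1.name}: {exc}; skipped", stacklevel=2)
            continue
        results.append(ng86(pairs, code, gene=f1.name))
    return results


def mean_omega(results: list[KaKsResult]) -> float | None:
    """Mean omega over genes where it is defined."""
    values = [r.omega for r in results if r.omega is not None]
    return sum(values) / len(values) if values else None
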