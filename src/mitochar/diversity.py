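"""Population diversity statistics for a marker-gene alignment.

Implements the standard DnaSP-style summary for one population sample:
haplotype collapse, unbiased haplotype diversity

    Hd = n (1 - sum p_i^2) / (n - 1),

mean pairwise nucleotide differences k, nucleotide diversity pi = k/L,
segregating sites S, and Tajima's (1989) D, the normalized difference
between the pairwise and the segregating-sites estimators of theta.

Sites containing a gap or ambiguity code in any sequence are removed
before any statistic (complete deletion).
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .model import MitocharError

__all__ = [
    "DiversitySummary",
    "complete_deletion",
    "collapse_haplotypes",
    "haplotype_diversity",
    "pairwise_stats",
    "tajimas_d",
    "tajima_constants",
    "summarize",
]

_UNAMBIGUOUS = frozenset(b"ACGT")


@dataclass(frozen=True)
class DiversitySummary:
    n: int
    L: int  # retained alignment length after complete deletion
    n_hap: int
    hap_freqs: tuple[int, ...]
    S: int
    k_bar: float
    Hd: float
    pi: float
    tajima_D: float | None  # None when S = 0


def _matrix(seqs: list[str]) -> np.ndarray:
    if not seqs:
        raise MitocharError("empty alignment")
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise MitocharError(f"unequal sequence lengths {sorted(lengths)}")
    return np.frombuffer(
        "".join(s.upper() for s in seqs).encode(), dtype="S1"
    ).reshape(len(seqs), -1)


def complete_deletion(seqs: list[str]) -> list[str]:
    """Drop every column holding a gap or ambiguity code in any sequence."""
    mat = _matrix(seqs)
    keep = np.ones(mat.shape[1], dtype=bool)
    for ch in np.unique(mat):
        if ch[0] not in _UNAMBIGUOUS:
            keep &= ~(mat == ch).any(axis=0)
    return [row.tobytes().decode() for row in mat[:, keep]]


def collapse_haplotypes(seqs: list[str]) -> tuple[int, list[int]]:
    """Exact-identity haplotype classes on retained sites.

    Returns the haplotype count and class frequencies in descending order.
    """
    retained = complete_deletion(seqs)
    freqs: dict[str, int] = {}
    for s in retained:
        freqs[s] = freqs.get(s, 0) + 1
    counts = sorted(freqs.values(), reverse=True)
    return len(counts), counts


def haplotype_diversity(n: int, hap_freqs: list[int]) -> float:
    """Unbiased haplotype (gene) diversity, Nei's n/(n-1) correction."""
    if n < 2:
        raise MitocharError("haplotype diversity needs n >= 2")
    if sum(hap_freqs) != n:
        raise MitocharError("haplotype frequencies must sum to n")
    return n * (1.0 - sum((f / n) ** 2 for f in hap_freqs)) / (n - 1)


def pairwise_stats(seqs: list[str]) -> tuple[int, float, float]:
    """(S, k, pi) on the complete-deletion alignment.

    S counts polymorphic retained sites; k is the mean Hamming distance
    over all C(n,2) pairs; pi = k / L with L the retained length.
    """
    retained = complete_deletion(seqs)
    n = len(retained)
    if n < 2:
        raise MitocharError("pairwise statistics need n >= 2")
    mat = _matrix(retained)
    L = mat.shape[1]
    if L == 0:
        raise MitocharError("no sites left after complete deletion")
    S = int(sum(len(np.unique(mat[:, j])) > 1 for j in range(L)))
    total = 0
    for i, j in combinations(range(n), 2):
        total += int((mat[i] != mat[j]).sum())
    k_bar = total / (n * (n - 1) / 2)
    return S, k_bar, k_bar / L


def tajima_constants(n: int) -> dict[str, float]:
    """The a1..e2 constants of Tajima's (1989) D for sample size n."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(n: int, S: int, k_bar: float) -> float:
    """Tajima's D from sample size, segregating sites and mean pairwise
    differences (per locus, not per site).

    Raises for n < 4 or S = 0 (the statistic is undefined without
    polymorphism); callers wanting a missing value should catch this.
    """
    if n < 4:
        raise MitocharError("Tajima's D needs n >= 4")
    if S < 1:
        raise MitocharError("Tajima's D undefined when S = 0")
    c = tajima_constants(n)
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    return (k_bar - S / c["a1"]) / var**0.5


def summarize(seqs: list[str]) -> DiversitySummary:
    """Full diversity summary of one aligned population sample."""
    retained = complete_deletion(seqs)
    n = len(retained)
    L = len(retained[0]) if retained else 0
    n_hap, hap_freqs = collapse_haplotypes(retained)
    S, k_bar, pi = pairwise_stats(retained)
    Hd = haplotype_diversity(n, hap_freqs)
    try:
        D = tajimas_d(n, S, k_bar)
    except MitocharError:
        D = None
    return DiversitySummary(
        n=n, L=L, n_hap=n_hap, hap_freqs=tuple(hap_freqs),
        S=S, k_bar=k_bar, Hd=Hd, pi=pi, tajima_D=D,
    )
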