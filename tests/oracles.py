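"""Independent brute-force oracle for Nei–Gojobori counting.

Deliberately naive: translates with Biopython directly, enumerates every
single-base neighbour for site counts and every mutational ordering for
difference counts, sharing no code with ``mitochar.kaks``.
"""
from itertools import permutations

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_rna_by_id[2]
_STOPS = set(_TABLE.stop_codons)


def _aa(codon: str) -> str:
    return "*" if codon in _STOPS else _TABLE.forward_table[codon]


def brute_site_counts(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) sites; stop-creating changes excluded."""
    syn = 0.0
    for pos in range(3):
        outcomes = []
        for base in "UCAG":
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if alt in _STOPS:
                continue
            outcomes.append(_aa(alt) == _aa(codon))
        if outcomes:
            syn += sum(outcomes) / len(outcomes)
    return syn, 3.0 - syn


def brute_path_differences(ca: str, cb: str) -> tuple[float, float]:
    """(nonsynonymous, synonymous) differences averaged over minimal
    pathways, excluding pathways through stop codons (all pathways if
    every one is blocked)."""
    positions = [i for i in range(3) if ca[i] != cb[i]]
    if not positions:
        return 0.0, 0.0

    def walk(order, check_stops):
        cur = ca
        nn = ns = 0.0
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if check_stops and nxt != cb and nxt in _STOPS:
                return None
            if _aa(cur) == _aa(nxt):
                ns += 1
            else:
                nn += 1
            cur = nxt
        return nn, ns

    results = [r for order in permutations(positions)
               if (r := walk(order, True)) is not None]
    if not results:
        results = [walk(order, False) for order in permutations(positions)]
    nn = sum(r[0] for r in results) / len(results)
    ns = sum(r[1] for r in results) / len(results)
    return nn, ns


def brute_ng86_counts(pairs) -> tuple[float, float, float, float]:
    """(N, S, nN, nS) for a list of codon pairs, sites averaged over both
    sequences."""
    N = S = nN = nS = 0.0
    for ca, cb in pairs:
        sa, na = brute_site_counts(ca)
        sb, nb = brute_site_counts(cb)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        dn, ds = brute_path_differences(ca, cb)
        nN += dn
        nS += ds
    return N, S, nN, nS
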