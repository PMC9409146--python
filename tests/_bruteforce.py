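"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations: every (start, frame) pair is tested by
direct translation, and rank-sum p-values are computed by explicit
enumeration of group assignments. These stay independent of the package's
scanning / dynamic-programming code paths.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np
from scipy.stats import rankdata

_CODONS = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R", "AGT": "S",
    "AGC": "S", "AGA": "R", "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G",
    "GGG": "G", "TAA": "*", "TAG": "*", "TGA": "*",
}


def brute_force_orfs(
    seq: str, min_codons: int = 50, all_starts: bool = False, drop_ambiguous: bool = True
) -> set[tuple[int, int, int, str]]:
    """All qualifying ORFs as (frame, nt_start, nt_end, aa) tuples.

    Tests every position: if it is an ATG, translate codon by codon until
    the first stop; no stop before the end of the transcript means no ORF.
    Under the default convention only the 5'-most start per (frame, stop)
    is kept.
    """
    found: set[tuple[int, int, int, str]] = set()
    for start in range(len(seq) - 2):
        if seq[start : start + 3] != "ATG":
            continue
        aa = []
        stop_end = None
        for pos in range(start, len(seq) - 2, 3):
            codon = seq[pos : pos + 3]
            res = "X" if "N" in codon else _CODONS[codon]
            if res == "*":
                stop_end = pos + 3
                break
            aa.append(res)
        if stop_end is None:
            continue
        aa_str = "".join(aa)
        if drop_ambiguous and "X" in aa_str:
            continue
        if len(aa_str) <= min_codons:
            continue
        found.add((start % 3, start, stop_end, aa_str))
    if not all_starts:
        by_stop: dict[tuple[int, int], tuple[int, int, int, str]] = {}
        for orf in sorted(found, key=lambda o: o[1]):
            by_stop.setdefault((orf[0], orf[2]), orf)
        found = set(by_stop.values())
    return found


def enumerated_ranksum_p(case_vals, control_vals) -> float:
    """Two-sided rank-sum p by explicit enumeration of case-index subsets.

    Mid-ranks for ties; p = P(|W - E[W]| >= |w_obs - E[W]|) over all
    C(n, n1) equally likely assignments.
    """
    values = np.concatenate([np.asarray(case_vals, float), np.asarray(control_vals, float)])
    n1 = len(case_vals)
    n = len(values)
    ranks = rankdata(values)
    w_obs = ranks[:n1].sum()
    mean_w = n1 * (n + 1) / 2.0
    dev = abs(w_obs - mean_w)
    hits = 0
    for combo in itertools.combinations(range(n), n1):
        w = ranks[list(combo)].sum()
        if abs(w - mean_w) >= dev - 1e-9:
            hits += 1
    return hits / comb(n, n1)
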