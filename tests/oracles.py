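"""Independent brute-force oracles used by the test suite.

Each oracle re-derives an expected value by direct enumeration or textbook
dynamic programming, sharing no code path with the package implementation.
"""

from __future__ import annotations

import math
import re
from typing import Dict, List, Tuple

import numpy as np
from scipy.stats import nbinom

# ---------------------------------------------------------------------------
# Gotoh local alignment (affine gaps), scores matching the package aligner

MATCH, MISMATCH, GAP_OPEN, GAP_EXT = 2, -3, -5, -2


def local_alignment_score(a: str, b: str) -> float:
    """Optimal Smith-Waterman-Gotoh local score by full DP."""
    n, m = len(a), len(b)
    neg = -1e9
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), neg)  # gap in a (horizontal)
    F = np.full((n + 1, m + 1), neg)  # gap in b (vertical)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + GAP_OPEN, E[i][j - 1] + GAP_EXT)
            F[i][j] = max(H[i - 1][j] + GAP_OPEN, F[i - 1][j] + GAP_EXT)
            sub = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            H[i][j] = max(0.0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


# ---------------------------------------------------------------------------
# six-frame stop-to-stop CDS enumeration on protein strings

_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _rc(s: str) -> str:
    return "".join(_RC[c] for c in reversed(s))


def _protein(seq: str, frame: int) -> str:
    out = []
    for i in range(frame, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        out.append("X" if "N" in codon else _CODE[codon])
    return "".join(out)


def six_frame_cds(seq: str, min_aa_len: int):
    """All stop-delimited segments as tuples
    (strand, frame, start, end, aa_length, partial5, partial3),
    coordinates 0-based half-open on the forward strand, terminal stop
    included in the span.
    """
    seq = seq.upper()
    L = len(seq)
    out = []
    for strand in "+-":
        work = seq if strand == "+" else _rc(seq)
        for frame in range(3):
            prot = _protein(work, frame)
            if not prot:
                continue
            pos = 0
            segments = []
            for part in re.split(r"(\*)", prot):
                if part == "*":
                    pos += 1
                    continue
                if part:
                    segments.append((pos, pos + len(part)))
                    pos += len(part)
            for s0, s1 in segments:
                aa = s1 - s0
                if aa < min_aa_len:
                    continue
                p5 = s0 == 0
                p3 = s1 == len(prot) or prot[s1] != "*"
                ws = frame + 3 * s0
                we = frame + 3 * s1 + (0 if p3 else 3)
                if strand == "+":
                    start, end = ws, we
                else:
                    start, end = L - we, L - ws
                out.append((strand, frame, start, end, aa, p5, p3))
    return sorted(out)


# ---------------------------------------------------------------------------
# exact-test enumeration

def nb_exact_p(y_ref: int, y_alt: int, phi: float) -> float:
    """Two-sided exact p by plain enumeration of all splits of s (equal libs)."""
    s = y_ref + y_alt
    if s == 0:
        return 1.0
    mu = s / 2.0
    r = 1.0 / phi
    prob = r / (r + mu)
    pk = [float(nbinom.pmf(k, r, prob) * nbinom.pmf(s - k, r, prob)) for k in range(s + 1)]
    obs = pk[y_ref]
    total = sum(pk)
    tail = sum(p for p in pk if p <= obs * (1 + 1e-12))
    return min(1.0, tail / total)


def binomial_two_sided_p(y_ref: int, y_alt: int) -> float:
    """Conditional binomial(s, 1/2) two-sided tail (Poisson limit of the NB test)."""
    s = y_ref + y_alt
    pk = [math.comb(s, k) * 0.5**s for k in range(s + 1)]
    obs = pk[y_ref]
    return min(1.0, sum(p for p in pk if p <= obs * (1 + 1e-12)))


# ---------------------------------------------------------------------------
# hypergeometric tail enumeration

def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N, K, n), by direct combinatorics."""
    denom = math.comb(N, n)
    total = 0
    for x in range(k, min(K, n) + 1):
        if n - x <= N - K:
            total += math.comb(K, x) * math.comb(N - K, n - x)
    return total / denom
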