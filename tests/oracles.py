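"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles — sliding
literal scans, per-end windowed dynamic programming, a hand-transcribed
thermodynamic table — and shares no code with the package under test.
"""
from __future__ import annotations

import math

_IUPAC = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "R": "AG",
    "Y": "CT",
    "S": "CG",
    "W": "AT",
    "K": "GT",
    "M": "AC",
    "B": "CGT",
    "D": "AGT",
    "H": "ACT",
    "V": "ACG",
    "N": "ACGT",
}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def oracle_revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def _pam_at(s: str, i: int, pam: str) -> bool:
    if i + len(pam) > len(s):
        return False
    return all(s[i + t] in _IUPAC[pam[t]] for t in range(len(pam)))


def brute_count_kmers(
    records, kmers_by_k: dict[int, set[str]], pam_pattern: str
) -> dict[tuple[int, str], int]:
    """Slide over both strands of every record; at each PAM-matching window,
    tally the k bases 5' of it against the queried k-mer sets."""
    counts: dict[tuple[int, str], int] = {
        (k, kmer): 0 for k, kmers in kmers_by_k.items() for kmer in kmers
    }
    for rec in records:
        seq = rec.seq if hasattr(rec, "seq") else rec
        for s in (seq, oracle_revcomp(seq)):
            for i in range(len(s) - len(pam_pattern) + 1):
                if not _pam_at(s, i, pam_pattern):
                    continue
                for k, kmers in kmers_by_k.items():
                    if i >= k:
                        kmer = s[i - k : i]
                        if kmer in kmers and "N" not in kmer:
                            counts[(k, kmer)] += 1
    return counts


def brute_count_one(records, kmer: str, pam_pattern: str) -> int:
    return brute_count_kmers(records, {len(kmer): {kmer}}, pam_pattern)[
        (len(kmer), kmer)
    ]


def dp_best_at_end(
    query: str, s: str, j: int, max_mismatches: int, max_gaps: int
):
    """Lexicographically minimal (gaps, mismatches) over all semi-global
    alignments of the full query ending exactly at 0-based exclusive position
    ``j`` of ``s``, or None if none stays within the mismatch budget.

    Windowed: the subject span of any such alignment lies inside the last
    |query| + max_gaps characters before j. Layer g is an independent DP
    bounding the gap count by g; the first feasible layer is the answer.
    """
    Q = len(query)
    w0 = max(0, j - Q - max_gaps)
    win = s[w0:j]
    W = len(win)
    INF = 10**9
    prev = None
    for g in range(max_gaps + 1):
        dp = [[INF] * (W + 1) for _ in range(Q + 1)]
        dp[0] = [0] * (W + 1)
        for i in range(1, min(g, Q) + 1):
            dp[i][0] = 0
        for i in range(1, Q + 1):
            qc = query[i - 1]
            row = dp[i]
            above = dp[i - 1]
            prow = prev[i] if prev is not None else None
            pabove = prev[i - 1] if prev is not None else None
            for jj in range(1, W + 1):
                sc = win[jj - 1]
                c = above[jj - 1] + (
                    1 if (qc != sc or qc == "N" or sc == "N") else 0
                )
                if prev is not None:
                    if pabove[jj] < c:
                        c = pabove[jj]
                    if prow[jj - 1] < c:
                        c = prow[jj - 1]
                row[jj] = c
        if dp[Q][W] <= max_mismatches:
            return g, dp[Q][W]
        prev = dp
    return None


def dp_oracle_ends(query: str, s: str, max_mismatches: int, max_gaps: int):
    """All feasible end positions on one strand with their (gaps, mismatches)."""
    out = {}
    for j in range(1, len(s) + 1):
        best = dp_best_at_end(query, s, j, max_mismatches, max_gaps)
        if best is not None:
            out[j] = best
    return out


# --- melting temperature -----------------------------------------------------
# Unified nearest-neighbor parameters (SantaLucia & Hicks 2004 review),
# kcal/mol and cal/(mol K); transcribed by hand from the published table.
_NN = {
    "AA": (-7.6, -21.3),
    "TT": (-7.6, -21.3),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7),
    "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4),
    "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0),
    "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2),
    "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
    "CC": (-8.0, -19.9),
}
_INIT = (0.2, -5.7)
_TERM_AT = (2.2, 6.9)  # per terminal A*T pair
_R = 1.987  # cal/(mol K)


def tm_oracle(seq: str, na_mM: float = 50.0, oligo_uM: float = 0.5) -> float:
    """Tm = dH / (dS' + R ln(CT/4)) - 273.15 for a non-self-complementary
    duplex at equimolar strand concentrations, with the SantaLucia 1998
    entropy salt correction dS' = dS + 0.368 (N-1) ln[Na+]."""
    dh, ds = _INIT
    for a, b in zip(seq, seq[1:]):
        h, s = _NN[a + b]
        dh += h
        ds += s
    for terminal in (seq[0], seq[-1]):
        if terminal in "AT":
            dh += _TERM_AT[0]
            ds += _TERM_AT[1]
    ds += 0.368 * (len(seq) - 1) * math.log(na_mM / 1000.0)
    ct = oligo_uM * 1e-6
    return (dh * 1000.0) / (ds + _R * math.log(ct / 4.0)) - 273.15
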