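"""Mismatch- and gap-tolerant search of a target against a genome.

The detail view of guide design: every genomic locus (both strands) that can
be aligned to the full-length target with at most ``max_mismatches``
substitutions and ``max_gaps`` indels (unit costs, semi-global: the whole
query against a genomic infix) is reported with its aligned strings, a
marker line ("|" match, "X" mismatch, " " gap) and the PAM observed 3' of
the matched span. Gap-tolerant search matters because Cas9 retains cleavage
activity at some bulged (insertion/deletion) off-target sites that
mismatch-only searches overlook.

The scan is a layered dynamic program vectorized across the genome axis:
layer g holds, for every query prefix and genomic end position, the minimum
number of mismatches achievable with at most g gaps. End positions within
budget are then re-aligned in a small window to recover the alignment. Among
alignments at one end the reported one minimizes (gaps, mismatches)
lexicographically; overlapping spans (>= 50% of the shorter span, same
record and strand) are collapsed to the best-scoring one.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pamscan import DesignParams
from .seqio import GenomeCollection, matches_iupac_pattern, reverse_complement

_INF = 1 << 20
_N = ord("N")


@dataclass(frozen=True)
class AlignmentBudget:
    """Edit allowance for the off-target search (unit costs)."""

    max_mismatches: int = 3
    max_gaps: int = 1  # insertions + deletions combined
    require_pam: bool = False

    def __post_init__(self) -> None:
        if self.max_mismatches < 0 or self.max_gaps < 0:
            raise ValueError("budgets must be nonnegative")


@dataclass(frozen=True)
class OfftargetHit:
    """One approximate match; coordinates 1-based inclusive on the plus strand."""

    record_id: str
    start: int
    end: int
    strand: str
    aligned_query: str
    aligned_subject: str
    marker_line: str
    n_mismatch: int
    n_gap: int
    pam_at_site: str
    pam_ok: bool


def _scan_ends(qa: np.ndarray, sa: np.ndarray, budget: AlignmentBudget):
    """End positions within budget on one strand.

    Returns (ends, gaps, mismatches): for each reported 0-based *exclusive*
    end position j, the minimum gap count g* for which some alignment ending
    at j stays within ``max_mismatches``, and the minimum mismatches at g*.
    """
    Q, L = len(qa), len(sa)
    G, M = budget.max_gaps, budget.max_mismatches
    layers: list[np.ndarray] = []
    for g in range(G + 1):
        dp = np.full((Q + 1, L + 1), _INF, dtype=np.int32)
        dp[0, :] = 0
        for i in range(1, Q + 1):
            if i <= g:
                dp[i, 0] = 0  # query prefix aligned entirely to gaps
            mis = ((sa != qa[i - 1]) | (sa == _N) | (qa[i - 1] == _N)).astype(
                np.int32
            )
            best = dp[i - 1, :-1] + mis
            if g > 0:
                prev = layers[g - 1]
                np.minimum(best, prev[i - 1, 1:], out=best)  # gap in subject
                np.minimum(best, prev[i, :-1], out=best)  # gap in query
            dp[i, 1:] = best
        layers.append(dp)

    final = np.stack([layer[Q, :] for layer in layers])  # (G+1, L+1)
    feasible = final <= M
    g_star = np.full(L + 1, -1, dtype=np.int32)
    for g in range(G, -1, -1):
        g_star[feasible[g]] = g
    ends = np.nonzero(g_star >= 0)[0]
    ends = ends[ends > 0]
    return [
        (int(j), int(g_star[j]), int(final[g_star[j], j])) for j in ends
    ]


def _align_window(
    query: str, window: str, g_budget: int
) -> tuple[int, int, str, str]:
    """Best alignment of the full query ending exactly at the window's end.

    Returns (start_offset_in_window, n_gap, aligned_query, aligned_subject),
    minimizing (gaps, mismatches) lexicographically. Pure-python DP with
    traceback on a window no longer than |query| + max_gaps.
    """
    Q, W = len(query), len(window)
    dp = [
        [[_INF] * (W + 1) for _ in range(Q + 1)] for _ in range(g_budget + 1)
    ]
    for g in range(g_budget + 1):
        for j in range(W + 1):
            dp[g][0][j] = 0
        for i in range(1, min(g, Q) + 1):
            dp[g][i][0] = 0
        for i in range(1, Q + 1):
            qc = query[i - 1]
            for j in range(1, W + 1):
                sc = window[j - 1]
                mis = 1 if (qc != sc or qc == "N" or sc == "N") else 0
                best = dp[g][i - 1][j - 1] + mis
                if g > 0:
                    best = min(best, dp[g - 1][i - 1][j], dp[g - 1][i][j - 1])
                dp[g][i][j] = best

    # Traceback from the top layer: diagonal moves stay within a layer, each
    # gap move descends one. Greedy order (diagonal, subject gap, query gap)
    # is the deterministic tie-break. The caller fixes g_budget to the
    # lexicographically minimal gap count, so the recovered path uses exactly
    # that many gaps.
    g, i, j = g_budget, Q, W
    aq: list[str] = []
    asub: list[str] = []
    while i > 0:
        if j > 0:
            qc, sc = query[i - 1], window[j - 1]
            mis = 1 if (qc != sc or qc == "N" or sc == "N") else 0
            if dp[g][i][j] == dp[g][i - 1][j - 1] + mis:
                aq.append(qc)
                asub.append(sc)
                i, j = i - 1, j - 1
                continue
        if g > 0 and dp[g][i][j] == dp[g - 1][i - 1][j]:
            aq.append(query[i - 1])
            asub.append("-")
            i, g = i - 1, g - 1
            continue
        if g > 0 and j > 0 and dp[g][i][j] == dp[g - 1][i][j - 1]:
            aq.append("-")
            asub.append(window[j - 1])
            j, g = j - 1, g - 1
            continue
        raise AssertionError("traceback failed")  # pragma: no cover
    n_gap = aq.count("-") + asub.count("-")
    return j, n_gap, "".join(reversed(aq)), "".join(reversed(asub))


def _marker(aq: str, asub: str) -> str:
    out = []
    for a, b in zip(aq, asub):
        if a == "-" or b == "-":
            out.append(" ")
        elif a == b and a != "N":
            out.append("|")
        else:
            out.append("X")
    return "".join(out)


def _strand_hits(
    query: str,
    strand_seq: str,
    budget: AlignmentBudget,
    pam_pattern: str,
) -> list[dict]:
    """Hits on one strand, in strand-local 1-based inclusive coordinates."""
    qa = np.frombuffer(query.encode(), dtype=np.uint8)
    sa = np.frombuffer(strand_seq.encode(), dtype=np.uint8)
    hits: list[dict] = []
    for j, g_star, n_mis in _scan_ends(qa, sa, budget):
        w_start = max(0, j - len(query) - budget.max_gaps)
        window = strand_seq[w_start:j]
        off, n_gap, aq, asub = _align_window(query, window, g_star)
        start_local = w_start + off + 1  # 1-based inclusive
        pam_at = strand_seq[j : j + len(pam_pattern)]
        pam_ok = matches_iupac_pattern(pam_at, pam_pattern)
        mism = sum(1 for c in _marker(aq, asub) if c == "X")
        hits.append(
            dict(
                start=start_local,
                end=j,
                aligned_query=aq,
                aligned_subject=asub,
                marker_line=_marker(aq, asub),
                n_mismatch=mism,
                n_gap=n_gap,
                pam_at_site=pam_at,
                pam_ok=pam_ok,
            )
        )
    return hits


def _dedup(hits: list[OfftargetHit]) -> list[OfftargetHit]:
    """Collapse hits on one record+strand whose spans overlap >= 50%."""
    kept: list[OfftargetHit] = []
    ranked = sorted(
        hits, key=lambda h: (h.n_gap, h.n_mismatch, h.start, h.end)
    )
    for h in ranked:
        redundant = False
        for k in kept:
            if k.record_id != h.record_id or k.strand != h.strand:
                continue
            ov = min(k.end, h.end) - max(k.start, h.start) + 1
            shorter = min(k.end - k.start, h.end - h.start) + 1
            if ov > 0 and ov / shorter >= 0.5:
                redundant = True
                break
        if not redundant:
            kept.append(h)
    return kept


def search_approximate(
    query: str,
    genome: GenomeCollection,
    budget: AlignmentBudget,
    pam_pattern: str = "NGG",
    target_len: int = 20,
) -> list[OfftargetHit]:
    """All genomic loci alignable to ``query`` within the edit budget.

    The PAM observed immediately 3' of each matched span (on the protospacer
    strand) is reported; with ``budget.require_pam`` hits failing the PAM
    pattern are dropped. Hits are sorted by record, start, then strand.
    """
    if len(query) != target_len:
        raise ValueError(
            f"query length {len(query)} != expected target length {target_len}"
        )
    if not set(query) <= set("ACGT"):
        raise ValueError("query must be concrete A/C/G/T")
    all_hits: list[OfftargetHit] = []
    record_order = {rec.id: i for i, rec in enumerate(genome)}
    for rec in genome:
        L = len(rec)
        for strand in "+-":
            strand_seq = rec.seq if strand == "+" else reverse_complement(rec.seq)
            for h in _strand_hits(query, strand_seq, budget, pam_pattern):
                if strand == "+":
                    start, end = h["start"], h["end"]
                else:
                    start, end = L - h["end"] + 1, L - h["start"] + 1
                all_hits.append(
                    OfftargetHit(
                        record_id=rec.id,
                        start=start,
                        end=end,
                        strand=strand,
                        aligned_query=h["aligned_query"],
                        aligned_subject=h["aligned_subject"],
                        marker_line=h["marker_line"],
                        n_mismatch=h["n_mismatch"],
                        n_gap=h["n_gap"],
                        pam_at_site=h["pam_at_site"],
                        pam_ok=h["pam_ok"],
                    )
                )
    kept = _dedup(all_hits)
    if budget.require_pam:
        kept = [h for h in kept if h.pam_ok]
    kept.sort(
        key=lambda h: (
            record_order[h.record_id],
            h.start,
            0 if h.strand == "+" else 1,
            h.end,
        )
    )
    return kept


def count_consistency_check(
    query: str,
    genome: GenomeCollection,
    params: DesignParams,
    index=None,
) -> bool:
    """Zero-budget PAM-required search count equals the exact-index full count."""
    from . import kmerindex

    if index is None:
        index = kmerindex.build_index(genome, params)
    exact_hits = search_approximate(
        query,
        genome,
        AlignmentBudget(max_mismatches=0, max_gaps=0, require_pam=True),
        pam_pattern=params.pam_pattern,
        target_len=params.target_len,
    )
    return len(exact_hits) == kmerindex.lookup(index, query).full


def offtargets_to_tsv(hits: list[OfftargetHit]) -> str:
    """Hits as tab-delimited text (header + one row per hit)."""
    cols = [
        "record",
        "start",
        "end",
        "strand",
        "n_mismatch",
        "n_gap",
        "pam_at_site",
        "pam_ok",
        "aligned_query",
        "marker_line",
        "aligned_subject",
    ]
    lines = ["\t".join(cols)]
    for h in hits:
        lines.append(
            "\t".join(
                [
                    h.record_id,
                    str(h.start),
                    str(h.end),
                    h.strand,
                    str(h.n_mismatch),
                    str(h.n_gap),
                    h.pam_at_site,
                    "true" if h.pam_ok else "false",
                    h.aligned_query,
                    h.marker_line,
                    h.aligned_subject,
                ]
            )
        )
    return "\n".join(lines) + "\n"


def offtargets_to_bed(hits: list[OfftargetHit]) -> str:
    """Hits as BED6 (0-based half-open) for genome-browser overlay."""
    lines = []
    for h in hits:
        name = f"mm{h.n_mismatch}_gap{h.n_gap}"
        lines.append(
            f"{h.record_id}\t{h.start - 1}\t{h.end}\t{name}\t0\t{h.strand}"
        )
    return "\n".join(lines) + ("\n" if lines else "")
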