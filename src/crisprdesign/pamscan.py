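"""PAM-adjacent target enumeration and per-candidate sequence annotation.

A Cas9 target candidate is a ``target_len``-mer (default 20 nt) lying
immediately 5' of a window matching the PAM pattern (default NGG) on either
strand of the query. Each candidate is annotated with GC content, a
nearest-neighbor melting temperature, and a poly-T flag (TTTT terminates
pol III transcription, truncating vector-expressed gRNAs).

Coordinates in candidates are 1-based inclusive on the query's plus strand
and span the target plus the PAM.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

from Bio.SeqUtils import MeltingTemp as _mt

from .seqio import IUPAC_SETS, NucleotideSequence, reverse_complement

#: Human-readable tag for the Tm parameterization, echoed in report metadata.
TM_METHOD = (
    "nearest-neighbor, SantaLucia & Hicks 2004 unified parameters, "
    "SantaLucia 1998 Na+ entropy correction"
)


class QueryTooLongError(ValueError):
    """Raised when the query exceeds the configured design limit (10 kbp)."""


@dataclass(frozen=True)
class DesignParams:
    """All tunables of a design run.

    pam_pattern : IUPAC motif required immediately 3' of the target
        (NGG for S. pyogenes Cas9; NRG admits the weaker NAG class too).
    target_len : protospacer length in bases.
    seed_lens : seed lengths counted next to the PAM, strictly decreasing.
    max_query_len : enforced input limit in bases (10 kbp).
    tm_na_mM / tm_oligo_uM : monovalent-salt and total strand concentrations
        used by the melting-temperature model.
    """

    pam_pattern: str = "NGG"
    target_len: int = 20
    seed_lens: tuple[int, ...] = (12, 8)
    max_query_len: int = 10000
    tm_na_mM: float = 50.0
    tm_oligo_uM: float = 0.5

    def __post_init__(self) -> None:
        if not self.pam_pattern or not set(self.pam_pattern) <= set(IUPAC_SETS):
            raise ValueError(f"invalid PAM pattern {self.pam_pattern!r}")
        if any(s > self.target_len for s in self.seed_lens):
            raise ValueError("seed lengths cannot exceed the target length")
        if list(self.seed_lens) != sorted(self.seed_lens, reverse=True) or len(
            set(self.seed_lens)
        ) != len(self.seed_lens):
            raise ValueError("seed_lens must be strictly decreasing")
        if self.max_query_len <= self.target_len + len(self.pam_pattern):
            raise ValueError("max_query_len too small for one target+PAM")
        if self.tm_na_mM <= 0 or self.tm_oligo_uM <= 0:
            raise ValueError("Tm concentrations must be positive")


@dataclass
class TargetCandidate:
    """One protospacer+PAM occurrence on the query, with annotations.

    ``start``/``end`` are 1-based inclusive on the query plus strand and span
    target+PAM; ``target_seq``/``pam_seq`` are 5'->3' on the protospacer
    strand. Hit counts are filled by the k-mer index stage.
    """

    start: int
    end: int
    strand: str
    target_seq: str
    pam_seq: str
    gc_percent: Optional[float]
    tm_celsius: Optional[float]
    has_tttt: bool
    hits_full: Optional[int] = None
    hits_seed12: Optional[int] = None
    hits_seed8: Optional[int] = None
    highlighted: bool = False
    zero_hit_warning: bool = False


def pam_regex(pattern: str) -> re.Pattern[str]:
    """Lookahead regex matching every (overlapping) concrete PAM window.

    N in the pattern means any of A/C/G/T — an N *base* in the genome never
    matches.
    """
    body = "".join("[" + "".join(sorted(IUPAC_SETS[c])) + "]" for c in pattern)
    return re.compile(f"(?=({body}))")


def gc_content(seq: str) -> Optional[float]:
    """GC percentage to one decimal; None if the sequence contains N."""
    if "N" in seq:
        return None
    return round(100.0 * (seq.count("G") + seq.count("C")) / len(seq), 1)


def melting_temperature(seq: str, params: DesignParams) -> Optional[float]:
    """Nearest-neighbor duplex melting temperature in degrees Celsius.

    Tm = dH / (dS + R ln(C_T/4)) - 273.15 with the SantaLucia & Hicks 2004
    unified table and the SantaLucia 1998 entropy salt correction at
    ``params.tm_na_mM`` Na+; C_T is ``params.tm_oligo_uM`` (non-self-
    complementary duplex, equimolar strands). None if the sequence contains N.
    """
    if "N" in seq:
        return None
    total_nM = params.tm_oligo_uM * 1000.0
    tm = _mt.Tm_NN(
        seq,
        nn_table=_mt.DNA_NN4,
        Na=params.tm_na_mM,
        dnac1=total_nM / 2.0,
        dnac2=total_nM / 2.0,
        selfcomp=False,
        saltcorr=5,
    )
    return float(tm)


def has_poly_t(seq: str) -> bool:
    """True iff TTTT (a pol III terminator) occurs in the sequence."""
    return "TTTT" in seq


def _scan_strand(seq: str, params: DesignParams):
    """Yield (0-based target start on this strand, target, pam) tuples."""
    t_len = params.target_len
    for m in pam_regex(params.pam_pattern).finditer(seq):
        p = m.start()
        if p < t_len:
            continue
        target = seq[p - t_len : p]
        if "N" in target:
            continue
        yield p - t_len, target, m.group(1)


def enumerate_candidates(
    query: NucleotideSequence, params: DesignParams
) -> list[TargetCandidate]:
    """Every PAM-adjacent target on both strands of the query, annotated.

    Candidates are sorted by ascending start, '+' before '-' at ties. Targets
    containing N are skipped entirely. Raises :class:`QueryTooLongError` above
    ``params.max_query_len``; a query too short to hold one target yields an
    empty list.
    """
    L = len(query)
    if L > params.max_query_len:
        raise QueryTooLongError(
            f"query {query.id!r} is {L} bp; the limit is "
            f"{params.max_query_len} bp ({params.max_query_len / 1000:g} kbp)"
        )
    p_len = len(params.pam_pattern)
    span = params.target_len + p_len
    if L < span:
        return []

    candidates: list[TargetCandidate] = []

    def _annotate(start: int, end: int, strand: str, target: str, pam: str) -> None:
        tm = melting_temperature(target, params)
        candidates.append(
            TargetCandidate(
                start=start,
                end=end,
                strand=strand,
                target_seq=target,
                pam_seq=pam,
                gc_percent=gc_content(target),
                # reported to one decimal, matching the exported formats
                tm_celsius=None if tm is None else round(tm, 1),
                has_tttt=has_poly_t(target),
            )
        )

    for tstart, target, pam in _scan_strand(query.seq, params):
        _annotate(tstart + 1, tstart + span, "+", target, pam)
    rc = reverse_complement(query.seq)
    for tstart, target, pam in _scan_strand(rc, params):
        # local 0-based half-open span [tstart, tstart+span) on the minus
        # strand maps to plus-strand 1-based [L - tstart - span + 1, L - tstart]
        _annotate(L - tstart - span + 1, L - tstart, "-", target, pam)

    candidates.sort(key=lambda c: (c.start, 0 if c.strand == "+" else 1))
    return candidates
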