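"""Genome-wide exact counting of k-mer+PAM occurrences and candidate scoring.

For each configured k (the full target length and the seed lengths) the index
counts, over both strands of every record, how often each k-mer occurs
immediately 5' of a window matching the PAM pattern. These are the
"20 mer+PAM" / "12 mer+PAM" / "8 mer+PAM" specificity columns: a count of 1
means the only perfect match is the intended site; 0 means the sequence has
no genomic match at all (it may span an exon-exon junction and should be
avoided); anything greater than 1 flags potential off-target sites.

Degenerate PAM patterns are handled per pattern, not per expansion: the scan
visits PAM windows once, so NRG costs the same single pass as NGG. Windows or
k-mers containing N never count. Overlapping occurrences all count.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from .pamscan import DesignParams, TargetCandidate, pam_regex
from .seqio import GenomeCollection, reverse_complement

INDEX_FORMAT = "kmerpam-index"
INDEX_VERSION = "v1"


@dataclass
class KmerPamIndex:
    """Counts of (k-mer, PAM-adjacent) genomic occurrences for each k."""

    pam_pattern: str
    target_len: int
    seed_lens: tuple[int, ...]
    counts: dict[int, dict[str, int]]
    genome_id: str

    @property
    def k_values(self) -> tuple[int, ...]:
        return (self.target_len, *self.seed_lens)


@dataclass(frozen=True)
class HitCounts:
    """Exact-match hit counts at full and seed resolutions.

    Invariant: full <= seed counts, and counts at longer seeds never exceed
    counts at shorter ones (a longer 5' context matches a subset of loci).
    """

    full: int
    by_seed: tuple[tuple[int, int], ...]  # ((seed_len, count), ...) k descending

    @property
    def seed12(self) -> Optional[int]:
        return dict(self.by_seed).get(12)

    @property
    def seed8(self) -> Optional[int]:
        return dict(self.by_seed).get(8)

    def as_sequence(self) -> tuple[int, ...]:
        """Counts ordered full-first (k descending); nondecreasing."""
        return (self.full, *(c for _, c in self.by_seed))


def build_index(genome: GenomeCollection, params: DesignParams) -> KmerPamIndex:
    """Single pass per strand over every record, counting k-mer+PAM windows."""
    k_values = (params.target_len, *params.seed_lens)
    counts: dict[int, dict[str, int]] = {k: defaultdict(int) for k in k_values}
    pam_re = pam_regex(params.pam_pattern)
    for rec in genome:
        for strand_seq in (rec.seq, reverse_complement(rec.seq)):
            for m in pam_re.finditer(strand_seq):
                p = m.start()
                for k in k_values:
                    if p < k:
                        continue
                    kmer = strand_seq[p - k : p]
                    if "N" not in kmer:
                        counts[k][kmer] += 1
    return KmerPamIndex(
        pam_pattern=params.pam_pattern,
        target_len=params.target_len,
        seed_lens=tuple(params.seed_lens),
        counts={k: dict(v) for k, v in counts.items()},
        genome_id=genome.checksum(),
    )


def lookup(index: KmerPamIndex, target_seq: str) -> HitCounts:
    """Hit counts for one full-length target; absent k-mers count 0."""
    if len(target_seq) != index.target_len:
        raise ValueError(
            f"target length {len(target_seq)} != index target length "
            f"{index.target_len}"
        )
    full = index.counts[index.target_len].get(target_seq, 0)
    by_seed = tuple(
        (s, index.counts[s].get(target_seq[-s:], 0)) for s in index.seed_lens
    )
    return HitCounts(full=full, by_seed=by_seed)


def annotate_and_highlight(
    candidates: Sequence[TargetCandidate], index: KmerPamIndex
) -> list[TargetCandidate]:
    """Fill hit counts, highlight uniquely matching candidates, in place.

    A candidate is highlighted when its full-length count and its primary
    (longest) seed count are both exactly 1 — the intended site is the only
    perfect match. A full count of 0 sets ``zero_hit_warning`` instead.
    Ordering is preserved.
    """
    out = list(candidates)
    for cand in out:
        if len(cand.target_seq) != index.target_len or len(cand.pam_seq) != len(
            index.pam_pattern
        ):
            raise ValueError(
                "candidate geometry does not match the index parameters "
                f"(target {len(cand.target_seq)}/{index.target_len}, "
                f"PAM {len(cand.pam_seq)}/{len(index.pam_pattern)})"
            )
        hc = lookup(index, cand.target_seq)
        seed_counts = dict(hc.by_seed)
        cand.hits_full = hc.full
        cand.hits_seed12 = seed_counts.get(12)
        cand.hits_seed8 = seed_counts.get(8)
        primary_seed = hc.by_seed[0][1] if hc.by_seed else hc.full
        cand.highlighted = hc.full == 1 and primary_seed == 1
        cand.zero_hit_warning = hc.full == 0
    return out


def save_index(index: KmerPamIndex, path: str | Path) -> None:
    """Serialize to a versioned flat text file (k, k-mer, count per line)."""
    with open(path, "w") as fh:
        fh.write(f"#{INDEX_FORMAT}\t{INDEX_VERSION}\n")
        fh.write(f"#pam\t{index.pam_pattern}\n")
        fh.write(f"#target_len\t{index.target_len}\n")
        fh.write(f"#seed_lens\t{','.join(map(str, index.seed_lens))}\n")
        fh.write(f"#genome\t{index.genome_id}\n")
        for k in index.k_values:
            for kmer in sorted(index.counts[k]):
                fh.write(f"{k}\t{kmer}\t{index.counts[k][kmer]}\n")


def load_index(path: str | Path) -> KmerPamIndex:
    header: dict[str, str] = {}
    counts: dict[int, dict[str, int]] = {}
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first != f"#{INDEX_FORMAT}\t{INDEX_VERSION}":
            raise ValueError(f"unrecognized index file header: {first!r}")
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, value = line[1:].partition("\t")
                header[key] = value
                continue
            k_str, kmer, n = line.split("\t")
            counts.setdefault(int(k_str), {})[kmer] = int(n)
    target_len = int(header["target_len"])
    seed_lens = tuple(
        int(s) for s in header["seed_lens"].split(",") if s
    )
    for k in (target_len, *seed_lens):
        counts.setdefault(k, {})
    return KmerPamIndex(
        pam_pattern=header["pam"],
        target_len=target_len,
        seed_lens=seed_lens,
        counts=counts,
        genome_id=header["genome"],
    )
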