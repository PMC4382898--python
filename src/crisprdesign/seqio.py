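"""Sequence records, FASTA I/O, IUPAC utilities and synthetic fixture genomes.

Sequences are normalized to uppercase DNA over the alphabet {A, C, G, T, N}
(``U`` is mapped to ``T`` so RNA-style input is accepted). ``N`` is the only
ambiguity code admitted in *sequences*; the full IUPAC degeneracy alphabet is
reserved for PAM *patterns*. Any other character is an error, never silently
masked.

The synthetic-genome generator plants known protospacer+PAM sites (exact
copies, seed-only copies, and single-substitution variants) into a uniform
random background and returns a machine-checkable manifest, so downstream
counting and alignment can be validated against ground truth.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

SEQUENCE_ALPHABET = frozenset("ACGTN")

#: Degeneracy sets of the IUPAC nucleotide one-letter codes.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SequenceError(ValueError):
    """Raised for malformed sequences, records or FASTA files."""


def normalize_sequence(raw: str, record_id: str = "sequence") -> str:
    """Uppercase, map U->T, and validate against {A,C,G,T,N}.

    Raises :class:`SequenceError` naming the record and the 1-based position
    of the first illegal character.
    """
    seq = "".join(raw.split()).upper().replace("U", "T")
    if not seq:
        raise SequenceError(f"record {record_id!r}: empty sequence")
    if not set(seq) <= SEQUENCE_ALPHABET:
        for pos, ch in enumerate(seq, start=1):
            if ch not in SEQUENCE_ALPHABET:
                raise SequenceError(
                    f"record {record_id!r}: illegal character {ch!r} at position {pos}"
                )
    return seq


@dataclass(frozen=True)
class NucleotideSequence:
    """A named nucleotide sequence over {A,C,G,T,N}."""

    id: str
    seq: str

    @classmethod
    def from_raw(cls, id: str, raw: str) -> "NucleotideSequence":
        return cls(id=id, seq=normalize_sequence(raw, record_id=id))

    def __post_init__(self) -> None:
        if not self.seq:
            raise SequenceError(f"record {self.id!r}: empty sequence")
        if not set(self.seq) <= SEQUENCE_ALPHABET:
            raise SequenceError(
                f"record {self.id!r}: sequence not normalized to {{A,C,G,T,N}}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "NucleotideSequence":
        return NucleotideSequence(id=self.id, seq=reverse_complement(self.seq))


@dataclass(frozen=True)
class GenomeCollection:
    """An ordered collection of uniquely named sequence records."""

    records: tuple[NucleotideSequence, ...]

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise SequenceError(f"duplicate record id {dup!r}")

    @property
    def total_length(self) -> int:
        return sum(len(r) for r in self.records)

    def __iter__(self) -> Iterator[NucleotideSequence]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, key: int | str) -> NucleotideSequence:
        if isinstance(key, str):
            for r in self.records:
                if r.id == key:
                    return r
            raise KeyError(key)
        return self.records[key]

    def checksum(self) -> str:
        """MD5 over ``>id\\nseq\\n`` blocks; a provenance tag for indices/reports."""
        h = hashlib.md5()
        for r in self.records:
            h.update(f">{r.id}\n{r.seq}\n".encode())
        return h.hexdigest()


def read_fasta(path: str | Path) -> GenomeCollection:
    """Read a (multi-record) FASTA file into a normalized GenomeCollection."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(NucleotideSequence.from_raw(rec.id, str(rec.seq)))
    if not records:
        raise SequenceError(f"no records in FASTA file {path}")
    return GenomeCollection(records=tuple(records))


def write_fasta(genome: GenomeCollection, path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(r.seq), id=r.id, description="") for r in genome
    ]
    SeqIO.write(recs, str(path), "fasta")


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement; N maps to N. Involution."""
    if not set(seq) <= SEQUENCE_ALPHABET:
        bad = next(c for c in seq if c not in SEQUENCE_ALPHABET)
        raise SequenceError(f"illegal character {bad!r} in sequence")
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_matches(base: str, code: str) -> bool:
    """True iff ``base`` (a concrete A/C/G/T) is in the degeneracy set of ``code``."""
    if code not in IUPAC_SETS:
        raise SequenceError(f"unknown IUPAC code {code!r}")
    if base not in IUPAC_SETS and base != "N":
        raise SequenceError(f"invalid base {base!r}")
    return base in IUPAC_SETS[code]


def matches_iupac_pattern(window: str, pattern: str) -> bool:
    """Position-wise IUPAC match of a concrete window against a pattern.

    A window containing N never matches anything (conservative rule, consistent
    with exact-count semantics).
    """
    if len(window) != len(pattern):
        return False
    return all(
        b in "ACGT" and b in IUPAC_SETS[p] for b, p in zip(window, pattern)
    )


def count_literal_occurrences(genome: GenomeCollection | str, pattern: str) -> int:
    """Count (overlapping) literal occurrences of ``pattern`` on both strands."""
    seqs = [genome] if isinstance(genome, str) else [r.seq for r in genome]
    total = 0
    for s in seqs:
        for strand_seq in (s, reverse_complement(s)):
            start = strand_seq.find(pattern)
            while start != -1:
                total += 1
                start = strand_seq.find(pattern, start + 1)
    return total


def count_kmer_pam_occurrences(
    genome: GenomeCollection | str, kmer: str, pam_pattern: str
) -> int:
    """Occurrences of ``kmer`` immediately 5' of an IUPAC ``pam_pattern``
    window, on both strands (overlapping occurrences all count)."""
    seqs = [genome] if isinstance(genome, str) else [r.seq for r in genome]
    p_len = len(pam_pattern)
    total = 0
    for s in seqs:
        for strand_seq in (s, reverse_complement(s)):
            start = strand_seq.find(kmer)
            while start != -1:
                window = strand_seq[start + len(kmer) : start + len(kmer) + p_len]
                if matches_iupac_pattern(window, pam_pattern):
                    total += 1
                start = strand_seq.find(kmer, start + 1)
    return total


# ---------------------------------------------------------------------------
# Synthetic fixture genomes


@dataclass(frozen=True)
class PlantSpec:
    """What to plant: exact, seed-only and near-match copies of one target.

    ``mutations`` is a list of ``(offset, base)`` pairs; each pair yields one
    planting of the protospacer carrying that single substitution (plus PAM).
    ``strands``, when given, fixes the strand of every planting in the order
    full copies, seed-only copies, mutant copies; otherwise strands are drawn
    at random.
    """

    protospacer: str
    pam: str = "AGG"
    copies_full: int = 0
    copies_seed_only: int = 0
    mutations: tuple[tuple[int, str], ...] = ()
    strands: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not set(self.protospacer) <= set("ACGT"):
            raise SequenceError("protospacer must be concrete A/C/G/T")
        if not set(self.pam) <= set("ACGT"):
            raise SequenceError("planted PAM must be concrete A/C/G/T")
        for off, base in self.mutations:
            if not 0 <= off < len(self.protospacer):
                raise ValueError(f"mutation offset {off} outside protospacer")
            if base not in "ACGT":
                raise SequenceError(f"mutation base {base!r} not A/C/G/T")
            if base == self.protospacer[off]:
                raise ValueError(f"mutation at offset {off} does not change the base")
        n = self.copies_full + self.copies_seed_only + len(self.mutations)
        if self.strands is not None:
            if len(self.strands) != n:
                raise ValueError("strands list must cover every planting")
            if not set(self.strands) <= {"+", "-"}:
                raise ValueError("strand must be '+' or '-'")


@dataclass(frozen=True)
class Planting:
    """Ground-truth record of one planted site (0-based, half-open span)."""

    record_id: str
    start: int
    end: int
    strand: str
    kind: str  # "full" | "seed" | "mutant"
    site_seq: str  # protospacer-strand sequence: (variant) protospacer + PAM
    name: str


def _site_sequences(spec: PlantSpec, seed_len: int, rng: np.random.Generator):
    """Yield (kind, site_seq) for every planting of one spec."""
    t_len = len(spec.protospacer)
    sites: list[tuple[str, str]] = []
    for _ in range(spec.copies_full):
        sites.append(("full", spec.protospacer + spec.pam))
    prefix_len = t_len - seed_len
    for _ in range(spec.copies_seed_only):
        # Random 5' prefix that breaks the full-length match but keeps the seed.
        while True:
            prefix = "".join(
                "ACGT"[i] for i in rng.integers(0, 4, size=prefix_len)
            )
            if prefix != spec.protospacer[:prefix_len]:
                break
        sites.append(("seed", prefix + spec.protospacer[prefix_len:] + spec.pam))
    for off, base in spec.mutations:
        variant = spec.protospacer[:off] + base + spec.protospacer[off + 1 :]
        sites.append(("mutant", variant + spec.pam))
    return sites


def make_synthetic_genome(
    length: int,
    plants: Sequence[PlantSpec],
    seed: int,
    record_id: str = "synth1",
    seed_lens: Sequence[int] = (12, 8),
    pam_pattern: str = "NGG",
    max_tries: int = 30,
) -> tuple[GenomeCollection, list[Planting]]:
    """Build a random genome with planted target sites and a ground-truth manifest.

    The background is uniform over {A,C,G,T}. Plantings are placed at
    non-overlapping positions on the requested (or randomly drawn) strand.
    The background is redrawn (deterministically, bounded retries) until the
    both-strand count of every planted k-mer adjacent to ``pam_pattern`` —
    for the full target length and each configured seed length — equals the
    count implied by the manifest, so fixtures are exactly recoverable under
    the same PAM-class counting semantics the index uses. Protospacers whose
    own structure creates irreducible extra PAM-adjacent copies (e.g.
    self-reverse-complementary sequences) exhaust the retries and raise.
    """
    if not plants:
        raise ValueError("at least one PlantSpec is required")
    primary_seed = max(seed_lens)

    for attempt in range(max_tries):
        rng = np.random.default_rng([int(seed), attempt])
        # Assemble the concrete site sequences for this attempt.
        all_sites: list[tuple[str, str, str]] = []  # (kind, site_seq, strand)
        for spec in plants:
            sites = _site_sequences(spec, primary_seed, rng)
            if spec.strands is not None:
                strands = list(spec.strands)
            else:
                strands = ["+-"[i] for i in rng.integers(0, 2, size=len(sites))]
            all_sites.extend(
                (kind, site, strand)
                for (kind, site), strand in zip(sites, strands)
            )

        site_len = max(len(site) for _, site, _ in all_sites)
        if length < len(all_sites) * site_len:
            raise ValueError(
                f"genome length {length} cannot hold {len(all_sites)} "
                f"non-overlapping plantings of {site_len} bp"
            )

        # Greedy non-overlapping placement from a random permutation of starts.
        starts: list[int] = []
        occupied: list[tuple[int, int]] = []
        for cand in rng.permutation(length - site_len + 1):
            if all(cand + site_len <= a or cand >= b for a, b in occupied):
                starts.append(int(cand))
                occupied.append((int(cand), int(cand) + site_len))
                if len(starts) == len(all_sites):
                    break
        if len(starts) < len(all_sites):
            continue  # pathological draw; retry

        bg = _BASE_BYTES[rng.integers(0, 4, size=length)]
        buf = bytearray(bg.tobytes())
        manifest: list[Planting] = []
        for i, ((kind, site, strand), start) in enumerate(zip(all_sites, starts)):
            planted = site if strand == "+" else reverse_complement(site)
            buf[start : start + len(site)] = planted.encode()
            manifest.append(
                Planting(
                    record_id=record_id,
                    start=start,
                    end=start + len(site),
                    strand=strand,
                    kind=kind,
                    site_seq=site,
                    name=f"{kind}_{i}",
                )
            )
        seq = buf.decode()

        # Cleanliness: observed k-mer+PAM-class counts must equal the
        # manifest-implied ones for every planted variant at every k.
        kmers: set[str] = set()
        plantings_by_kmer: dict[str, int] = {}
        for pl in manifest:
            pam_len = len(pl.site_seq) - _proto_len(pl, plants)
            proto = pl.site_seq[:-pam_len]
            for k in {len(proto), *seed_lens}:
                kmers.add(proto[-k:])
        for kmer in kmers:
            plantings_by_kmer[kmer] = sum(
                1
                for pl in manifest
                if pl.site_seq[: -(len(pl.site_seq) - _proto_len(pl, plants))]
                .endswith(kmer)
                and matches_iupac_pattern(
                    pl.site_seq[_proto_len(pl, plants) :], pam_pattern
                )
            )
        if all(
            count_kmer_pam_occurrences(seq, kmer, pam_pattern) == n
            for kmer, n in plantings_by_kmer.items()
        ):
            genome = GenomeCollection(
                records=(NucleotideSequence(id=record_id, seq=seq),)
            )
            manifest.sort(key=lambda p: p.start)
            return genome, manifest

    raise RuntimeError(
        f"could not build a clean fixture genome in {max_tries} attempts"
    )


def _proto_len(pl: Planting, plants: Sequence[PlantSpec]) -> int:
    # All specs share the protospacer length in practice; recover it robustly.
    for spec in plants:
        if len(pl.site_seq) == len(spec.protospacer) + len(spec.pam):
            return len(spec.protospacer)
    raise ValueError("planting does not match any spec geometry")


def write_manifest_bed(manifest: Sequence[Planting], path: str | Path) -> None:
    """Write the fixture manifest as BED6 (0-based, half-open)."""
    with open(path, "w") as fh:
        for pl in manifest:
            fh.write(
                f"{pl.record_id}\t{pl.start}\t{pl.end}\t"
                f"{pl.name}:{pl.site_seq}\t0\t{pl.strand}\n"
            )


def read_manifest_bed(path: str | Path) -> list[Planting]:
    out: list[Planting] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, start, end, name, _score, strand = line.split("\t")[:6]
            label, _, site_seq = name.partition(":")
            kind = label.rsplit("_", 1)[0]
            out.append(
                Planting(
                    record_id=chrom,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    kind=kind,
                    site_seq=site_seq,
                    name=label,
                )
            )
    return out
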