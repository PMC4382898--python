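# Methods

## Problem and model

A *S. pyogenes* Cas9 guide RNA targets a ~20-nt protospacer that must sit
immediately 5′ of a protospacer-adjacent motif (PAM, canonically NGG; NAG is
cleaved more weakly, hence the NRG option). Because a double-strand break is
heritable, the practical design question is specificity: how many other
genomic loci could the same guide direct Cas9 to? Mismatches within the
seed — the 8–12 nt immediately adjacent to the PAM — impair cleavage most,
so the number of *perfect* genomic matches of the PAM-proximal seed is a
conservative, exactly computable specificity proxy, complemented by an
explicit mismatch/gap-tolerant search for near-matches.

The pipeline is: enumerate PAM-adjacent candidates on both query strands →
count genome-wide exact occurrences of (k-mer, PAM) for k ∈ {20, 12, 8} →
highlight candidates whose full-length and 12-mer-seed counts are both 1 →
optionally list approximate off-target loci in detail → export.

## Candidate enumeration and annotation

Coordinates are 1-based inclusive on the query plus strand and span
target+PAM; minus-strand candidates are reported with their protospacer
(5′→3′ on the minus strand) and mapped back to plus coordinates. Ordering is
ascending start with `+` before `−` at ties. Windows containing `N` are
skipped entirely rather than reported with missing annotations; `N` in a
*sequence* never matches anything, while IUPAC degeneracy is honored in the
PAM *pattern* only.

Annotations per candidate:

- **GC content** (percent, one decimal) of the 20-mer.
- **Melting temperature** by nearest-neighbor thermodynamics:
  Tm = ΔH°/(ΔS° + R ln(C_T/4)) − 273.15, using the SantaLucia & Hicks 2004
  unified parameter set with the SantaLucia 1998 entropy salt correction
  (ΔS° + 0.368 (N−1) ln[Na⁺]). Defaults: 50 mM Na⁺, 0.5 µM total strand
  concentration (equimolar non-self-complementary duplex, hence the C_T/4
  factor). The computation is delegated to Biopython's `MeltingTemp.Tm_NN`
  and cross-checked in the test suite against an independent transcription
  of the published table; the parameterization is echoed in report metadata
  so values are auditable. Values are reported to one decimal, matching the
  exported formats.
- **TTTT flag**: whether `TTTT` occurs in the protospacer-strand 20-mer
  (pol III terminator; the PAM and flanks are not checked).

## Exact k-mer+PAM counting

The index scans each genome record once per strand with an overlapping PAM
regex; at each matching PAM window it increments the count of the k bases
immediately 5′ for every configured k. Consequences of this design:

- Degenerate PAMs cost one pass, not one per expansion; the `N` of NGG is
  never enumerated into four keys.
- Overlapping occurrences all count (G×25 contains three NGG windows with a
  full 20-mer context).
- The index is strand-symmetric by construction: reverse-complementing any
  record leaves the counts unchanged.
- Only k-mers observed 5′ of a PAM are stored, bounding memory by the number
  of PAM sites times the number of k values.
- Counts include the on-target site itself; no attempt is made to subtract
  the query locus, since the query need not come from the indexed genome. A
  count of 1 therefore means "the intended site only".

The highlight rule is fixed and testable: `hits_full == 1 and
hits_seed12 == 1` (for non-default seed configurations, the longest seed is
the gate). The 8-mer count is reported but not gated — 8-mer+PAM uniqueness
is rarely achievable in a large genome. `hits_full == 0` raises a
zero-hit warning instead (the query sequence is absent from the genome,
e.g. a spliced cDNA query spanning an exon–exon junction).

The index serializes to a versioned flat text file (header with PAM,
lengths and a genome MD5 checksum; one `k  k-mer  count` line each), so
repeated designs against the same genome skip rebuilding; loading verifies
the header and `run_design` rejects an index whose checksum does not match
the supplied genome.

## Approximate off-target search

Semi-global alignment of the full 20-mer against a genomic infix with unit
costs, bounded separately by `max_mismatches` (default 3) and `max_gaps`
(insertions+deletions combined, default 1). The defaults are this package's
choice of a Cas9-realistic search depth; both are exposed on the CLI. The
search runs on the 20-mer alone and *reports* the 3 bases 3′ of each
matched span (on the protospacer strand) with a PAM pass/fail flag;
`require_pam` makes the flag a filter. Hits are found per strand and mapped
back to plus-strand coordinates.

Implementation: a layered dynamic program vectorized along the genome axis.
Layer g holds, for each query prefix and each end position, the minimum
mismatch count achievable with at most g gaps; the scan then reports every
end position whose top layer is within budget, choosing per end the
lexicographically minimal (gaps, mismatches) — the smallest feasible layer.
Each reported end is re-aligned in a window of length |query|+max_gaps by a
small traceback DP (deterministic tie-break: diagonal, then gap-in-subject,
then gap-in-query) to recover the aligned strings, the marker line
(`|` match, `X` mismatch, space at gap columns) and the start coordinate.
Nearby alignments of one physical site (spans overlapping ≥ 50% of the
shorter span, same record and strand) are collapsed to the best one —
fewest gaps, then fewest mismatches, then leftmost. The exhaustive
per-end windowed DP in the test suite is the behavioral contract; the
vectorized scan must agree with it end-for-end.

Known edge: in a perfect tandem repeat, two genuinely distinct exact
occurrences can overlap by ≥ 50% and be collapsed into one reported hit,
while the exact counter counts both. This cannot occur on the random
fixtures used for validation and is irrelevant to the counting columns.

## Synthetic fixture genomes

The generator emulates the one property validation needs: a background in
which the planted signal is the *only* signal. It draws a uniform random
{A,C,G,T} background, plants non-overlapping sites on requested or random
strands — exact protospacer+PAM copies, seed-only copies (random 5′ prefix,
guaranteed to differ from the true prefix), and single-substitution
variants — and records every planting in a BED6 manifest (0-based
half-open). The background is redrawn deterministically (seeded sub-draws,
bounded retries) until the observed both-strand count of every planted
k-mer+PAM-class pattern equals the manifest-implied count, so fixture
recovery is exact by construction rather than by luck. Protospacers whose
own structure makes that impossible (e.g. self-reverse-complementary
sequences, which plant on both strands at once) exhaust the retries and
raise.

What the generator does *not* emulate: real base composition, repeats and
gene families, N/masked bases, and chromosome-scale size. Passing the
planted-recovery and oracle-equivalence tests therefore demonstrates
algorithmic correctness of counting and search, not performance claims
about any real genome; on real genomes the same code paths apply unchanged
but counts reflect true genomic redundancy.

## Validation scales and numerical choices

- Exact counting is checked against a literal both-strand sliding scan on
  20 random genomes of 100–200 kb (2 kb query slices, NGG and NRG).
- The approximate search is checked per end position against an exhaustive
  windowed DP oracle on a 20 kb planted genome for budgets up to
  (3 mismatches, 1 gap); acceptance reruns use 10 kb.
- Seed monotonicity (full ≤ seed12 ≤ seed8) is asserted over >10⁴
  candidates; planted-site recovery over 100 seeded fixtures.
- All randomness flows through seeded NumPy generators; fixture generation
  is deterministic in (seed, attempt).
- GC and Tm are rounded to one decimal at annotation time so the TSV and
  JSON exports are numerically identical and round-trip losslessly.
- The 10 kbp query limit is enforced as a validation error; a query shorter
  than target+PAM yields an empty candidate list, not an error.

## Interface decisions

- The query FASTA must contain exactly one record unless `--record` (or
  `record=`) selects one; designing against several records is a loop for
  the caller, keeping one report per query unambiguous.
- TSV exports carry `# key=value` metadata lines (version, query, genome
  checksum, Tm method, JSON-encoded parameter echo, optional timestamp)
  above the header row; `--no-timestamp` makes reruns byte-identical for
  diff-based pipelines.
- Exit codes: 0 success, 2 usage/validation error, 1 runtime failure.
- Accession-number and genome-coordinate input resolution against remote
  databases, prebuilt organism indices, graphical views, and off-target
  *activity* scoring (MIT/CFD-style cutting probabilities) are out of
  scope: the tool reports positions and edit structure, and users supply
  genomes as FASTA.
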