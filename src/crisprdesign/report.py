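"""End-to-end design pipeline and TSV/JSON report export.

A design run reads a query and a background genome, enumerates PAM-adjacent
candidates, counts their genome-wide exact matches at full and seed
resolutions, and assembles a report whose metadata echo every parameter
needed to reproduce the run. TSV and JSON exports carry identical
information; reruns with identical inputs are byte-identical apart from the
timestamp (which can be suppressed).
"""
from __future__ import annotations

import datetime
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from ._version import __version__
from .kmerindex import KmerPamIndex, annotate_and_highlight, build_index
from .pamscan import (
    TM_METHOD,
    DesignParams,
    TargetCandidate,
    enumerate_candidates,
)
from .seqio import SequenceError, read_fasta

logger = logging.getLogger("crisprdesign")

_CANDIDATE_FIELDS = (
    "start",
    "end",
    "strand",
    "target_seq",
    "pam_seq",
    "gc_percent",
    "tm_celsius",
    "has_tttt",
    "hits_full",
    "hits_seed12",
    "hits_seed8",
    "highlighted",
    "zero_hit_warning",
)

_TSV_COLUMNS = ("position",) + _CANDIDATE_FIELDS[2:]


@dataclass
class DesignReport:
    """One design run: query metadata, parameter echo, ordered candidates."""

    query_id: str
    query_length: int
    params: DesignParams
    genome_checksum: str
    candidates: list[TargetCandidate]
    version: str = __version__
    timestamp: Optional[str] = None
    tm_method: str = TM_METHOD


def run_design(
    query_path: str | Path,
    genome_path: str | Path,
    params: DesignParams | None = None,
    index: KmerPamIndex | None = None,
    record: str | None = None,
    timestamp: bool = True,
) -> DesignReport:
    """Full pipeline: enumerate, count, highlight, assemble.

    The query FASTA must contain exactly one record unless ``record`` names
    the one to design against. A prebuilt ``index`` (matching the genome and
    params) skips the counting pass.
    """
    params = params or DesignParams()
    logger.info("reading query from %s", query_path)
    queries = read_fasta(query_path)
    if record is not None:
        query = queries[record]
    elif len(queries) == 1:
        query = queries[0]
    else:
        raise SequenceError(
            f"query FASTA has {len(queries)} records; select one with record="
        )
    logger.info("enumerating candidates on query %r (%d bp)", query.id, len(query))
    candidates = enumerate_candidates(query, params)
    logger.info("found %d PAM-adjacent candidates", len(candidates))
    logger.info("reading genome from %s", genome_path)
    genome = read_fasta(genome_path)
    if index is None:
        logger.info(
            "building k-mer+PAM index over %d bp (%d records)",
            genome.total_length,
            len(genome),
        )
        index = build_index(genome, params)
    elif index.genome_id != genome.checksum():
        raise ValueError("supplied index was built from a different genome")
    annotate_and_highlight(candidates, index)
    logger.info(
        "%d candidates highlighted as uniquely matching",
        sum(c.highlighted for c in candidates),
    )
    ts = (
        datetime.datetime.now(datetime.timezone.utc).isoformat(timespec="seconds")
        if timestamp
        else None
    )
    return DesignReport(
        query_id=query.id,
        query_length=len(query),
        params=params,
        genome_checksum=index.genome_id,
        candidates=candidates,
        timestamp=ts,
    )


def _params_dict(params: DesignParams) -> dict:
    return {
        "pam_pattern": params.pam_pattern,
        "target_len": params.target_len,
        "seed_lens": list(params.seed_lens),
        "max_query_len": params.max_query_len,
        "tm_na_mM": params.tm_na_mM,
        "tm_oligo_uM": params.tm_oligo_uM,
    }


def _params_from_dict(d: dict) -> DesignParams:
    return DesignParams(
        pam_pattern=d["pam_pattern"],
        target_len=d["target_len"],
        seed_lens=tuple(d["seed_lens"]),
        max_query_len=d["max_query_len"],
        tm_na_mM=d["tm_na_mM"],
        tm_oligo_uM=d["tm_oligo_uM"],
    )


def _fmt1(x: Optional[float]) -> str:
    return "" if x is None else f"{x:.1f}"


def _fmt_int(x: Optional[int]) -> str:
    return "" if x is None else str(x)


def _fmt_bool(x: bool) -> str:
    return "true" if x else "false"


def export_tsv(report: DesignReport) -> str:
    """Tab-delimited export: ``# key=value`` metadata lines, header, one row
    per candidate. GC and Tm are printed to one decimal; booleans as
    true/false; missing annotations as empty strings."""
    lines = [
        f"# crisprdesign_version={report.version}",
        f"# query_id={report.query_id}",
        f"# query_length={report.query_length}",
        f"# genome_checksum={report.genome_checksum}",
        f"# tm_method={report.tm_method}",
        f"# params={json.dumps(_params_dict(report.params))}",
    ]
    if report.timestamp is not None:
        lines.append(f"# timestamp={report.timestamp}")
    lines.append("\t".join(_TSV_COLUMNS))
    for c in report.candidates:
        lines.append(
            "\t".join(
                [
                    f"{c.start}..{c.end}",
                    c.strand,
                    c.target_seq,
                    c.pam_seq,
                    _fmt1(c.gc_percent),
                    _fmt1(c.tm_celsius),
                    _fmt_bool(c.has_tttt),
                    _fmt_int(c.hits_full),
                    _fmt_int(c.hits_seed12),
                    _fmt_int(c.hits_seed8),
                    _fmt_bool(c.highlighted),
                    _fmt_bool(c.zero_hit_warning),
                ]
            )
        )
    return "\n".join(lines) + "\n"


def parse_tsv(text: str) -> DesignReport:
    """Inverse of :func:`export_tsv`."""
    meta: dict[str, str] = {}
    rows: list[list[str]] = []
    header_seen = False
    for line in text.splitlines():
        if line.startswith("# "):
            key, _, value = line[2:].partition("=")
            meta[key] = value
        elif not header_seen:
            if line.split("\t") != list(_TSV_COLUMNS):
                raise ValueError("unrecognized TSV header")
            header_seen = True
        elif line:
            rows.append(line.split("\t"))
    candidates = []
    for row in rows:
        pos, strand, target, pam, gc, tm, tttt, hf, h12, h8, hl, zw = row
        start_s, _, end_s = pos.partition("..")
        candidates.append(
            TargetCandidate(
                start=int(start_s),
                end=int(end_s),
                strand=strand,
                target_seq=target,
                pam_seq=pam,
                gc_percent=float(gc) if gc else None,
                tm_celsius=float(tm) if tm else None,
                has_tttt=tttt == "true",
                hits_full=int(hf) if hf else None,
                hits_seed12=int(h12) if h12 else None,
                hits_seed8=int(h8) if h8 else None,
                highlighted=hl == "true",
                zero_hit_warning=zw == "true",
            )
        )
    return DesignReport(
        query_id=meta["query_id"],
        query_length=int(meta["query_length"]),
        params=_params_from_dict(json.loads(meta["params"])),
        genome_checksum=meta["genome_checksum"],
        candidates=candidates,
        version=meta["crisprdesign_version"],
        timestamp=meta.get("timestamp"),
        tm_method=meta["tm_method"],
    )


def _candidate_json(c: TargetCandidate) -> dict:
    d = {f: getattr(c, f) for f in _CANDIDATE_FIELDS}
    # keep float formatting at one decimal so TSV and JSON agree exactly
    for key in ("gc_percent", "tm_celsius"):
        if d[key] is not None:
            d[key] = round(d[key], 1)
    return d


def export_json(report: DesignReport) -> str:
    """JSON export: a metadata object plus an array of candidate objects with
    the same field names and values as the TSV. Stable key order; round-trips
    byte-identically through :func:`report_from_json`."""
    doc = {
        "metadata": {
            "crisprdesign_version": report.version,
            "query_id": report.query_id,
            "query_length": report.query_length,
            "genome_checksum": report.genome_checksum,
            "tm_method": report.tm_method,
            "params": _params_dict(report.params),
            "timestamp": report.timestamp,
        },
        "candidates": [_candidate_json(c) for c in report.candidates],
    }
    return json.dumps(doc, indent=2, allow_nan=False) + "\n"


def report_from_json(text: str) -> DesignReport:
    doc = json.loads(text)
    meta = doc["metadata"]
    candidates = [
        TargetCandidate(**{f: c[f] for f in _CANDIDATE_FIELDS})
        for c in doc["candidates"]
    ]
    return DesignReport(
        query_id=meta["query_id"],
        query_length=meta["query_length"],
        params=_params_from_dict(meta["params"]),
        genome_checksum=meta["genome_checksum"],
        candidates=candidates,
        version=meta["crisprdesign_version"],
        timestamp=meta["timestamp"],
        tm_method=meta["tm_method"],
    )
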