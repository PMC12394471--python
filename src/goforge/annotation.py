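"""GO-term transfer from tabular similarity hits (pipeline steps 1-2).

A query inherits the GO terms encoded in the descriptions of its similarity
hits against the decorated reference. Hits above the E-value cutoff are
discarded, NOT-qualified assignments are never transferred, and redundant
(query, GO id) pairs arising from multiple hits are collapsed by keeping
the supporting hit with the lowest E-value (ties: higher bit score, then
lexicographic subject id, for full determinism).

Search defaults follow the recommended operating point: ultra-sensitive
alignment, E-value cutoff 1e-5, max target sequences 1. The stricter 1e-10
cutoff can be restored via the ``evalue_cutoff`` parameter / ``--evalue``.
"""

from __future__ import annotations

import io
import math
import shutil
import subprocess
from dataclasses import dataclass
from typing import IO, Iterable, Optional, Sequence, Union

from .decoration import parse_decoration
from .errors import ConfigurationError, InputError, TabularParseError

DEFAULT_EVALUE_CUTOFF = 1e-5
DEFAULT_MAX_TARGET_SEQS = 1
DEFAULT_SENSITIVITY = "ultra-sensitive"

#: 12 standard tabular columns, plus stitle requested as a 13th
TABULAR_FIELDS = ("qseqid sseqid pident length mismatch gapopen qstart qend "
                  "sstart send evalue bitscore stitle").split()


@dataclass(frozen=True)
class AlignmentHit:
    """One row of 12/13-column tabular similarity-search output."""

    query_id: str
    subject_id: str
    percent_identity: float
    align_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bit_score: float
    subject_title: str = ""


@dataclass(frozen=True)
class SearchParams:
    mode: str = "blastp"
    sensitivity: str = DEFAULT_SENSITIVITY
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF
    max_target_seqs: int = DEFAULT_MAX_TARGET_SEQS

    def __post_init__(self) -> None:
        if self.mode not in ("blastp", "blastx"):
            raise InputError(f"mode must be blastp or blastx, got {self.mode!r}")
        if not self.evalue_cutoff > 0:
            raise InputError("evalue_cutoff must be positive")
        if self.max_target_seqs < 1:
            raise InputError("max_target_seqs must be >= 1")


@dataclass(frozen=True)
class AnnotationRecord:
    """One transferred (query, GO id) assignment.

    ``evalue`` is ``None`` for domain-scan provenance; such records always
    lose collapse ties against similarity-derived records, which carry
    quantitative support.
    """

    query_id: str
    go_id: str
    evidence: str
    category: str
    evalue: Optional[float]
    source_symbol: str = "-"
    source_taxon: str = "-"
    provenance: str = "similarity"
    bit_score: float = 0.0
    subject_id: str = ""

    def sort_evalue(self) -> float:
        return math.inf if self.evalue is None else self.evalue


# ---------------------------------------------------------------------------
# Tabular parsing / search


def parse_tabular(stream: Union[str, IO[str]]) -> list[AlignmentHit]:
    """Parse 12- or 13-column tabular hits; errors carry the line number."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    hits: list[AlignmentHit] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) not in (12, 13):
            raise TabularParseError(
                f"expected 12 or 13 tab-delimited columns, found {len(cols)}",
                lineno)
        try:
            hit = AlignmentHit(
                query_id=cols[0], subject_id=cols[1],
                percent_identity=float(cols[2]), align_length=int(cols[3]),
                mismatches=int(cols[4]), gap_opens=int(cols[5]),
                q_start=int(cols[6]), q_end=int(cols[7]),
                s_start=int(cols[8]), s_end=int(cols[9]),
                evalue=float(cols[10]), bit_score=float(cols[11]),
                subject_title=cols[12] if len(cols) == 13 else "",
            )
        except ValueError as exc:
            raise TabularParseError(f"malformed numeric field ({exc})",
                                    lineno) from None
        if hit.evalue < 0:
            raise TabularParseError("negative E-value", lineno)
        hits.append(hit)
    return hits


def filter_hits(hits: Iterable[AlignmentHit], params: SearchParams,
                ) -> list[AlignmentHit]:
    """Apply the E-value cutoff and the max-target-sequences cap.

    Subjects per query are ranked by (best E-value, -best bit score,
    subject id) and only rows of the top ``max_target_seqs`` subjects
    survive, mirroring what the aligner itself would report.
    """
    kept = [h for h in hits if h.evalue <= params.evalue_cutoff]
    by_query: dict[str, list[AlignmentHit]] = {}
    for h in kept:
        by_query.setdefault(h.query_id, []).append(h)
    out: list[AlignmentHit] = []
    for _, rows in sorted(by_query.items()):
        best: dict[str, tuple[float, float]] = {}
        for h in rows:
            ev, bs = best.get(h.subject_id, (math.inf, -math.inf))
            best[h.subject_id] = (min(ev, h.evalue), max(bs, h.bit_score))
        ranked = sorted(best, key=lambda s: (best[s][0], -best[s][1], s))
        top = set(ranked[: params.max_target_seqs])
        out.extend(h for h in rows if h.subject_id in top)
    return out


def build_aligner_command(query: str, db: str, params: SearchParams,
                          out: str, binary: str = "diamond") -> list[str]:
    """Exact external-aligner command line (also used by dry-run mode)."""
    return [
        binary, params.mode, "--query", query, "--db", db,
        f"--{params.sensitivity}", "--evalue", str(params.evalue_cutoff),
        "--max-target-seqs", str(params.max_target_seqs),
        "--out", out, "--outfmt", "6", *TABULAR_FIELDS,
    ]


def run_or_load_search(queries: Optional[str] = None,
                       reference: Optional[str] = None,
                       params: SearchParams = SearchParams(),
                       precomputed: Union[str, IO[str], None] = None,
                       binary: str = "diamond",
                       dry_run: bool = False) -> list[AlignmentHit]:
    """Obtain cutoff-filtered hits from a precomputed stream or the aligner.

    With ``precomputed`` the external aligner is never touched; otherwise
    the binary must be on PATH (else :class:`ConfigurationError`).
    """
    if precomputed is not None:
        return filter_hits(parse_tabular(precomputed), params)
    if queries is None or reference is None:
        raise ConfigurationError(
            "need --query and --db when no precomputed hits are supplied")
    if shutil.which(binary) is None:
        raise ConfigurationError(
            f"aligner binary {binary!r} not found and no precomputed hits supplied")
    import tempfile

    with tempfile.NamedTemporaryFile(suffix=".tsv", mode="r") as tmp:
        cmd = build_aligner_command(queries, reference, params, tmp.name, binary)
        if dry_run:
            print(" ".join(cmd))
            return []
        subprocess.run(cmd, check=True)
        return filter_hits(parse_tabular(tmp), params)


# ---------------------------------------------------------------------------
# Transfer / collapse / summary


def transfer_annotations(hits: Sequence[AlignmentHit]) -> list[AnnotationRecord]:
    """One candidate record per (query, GO id, hit); NOT-qualified terms dropped."""
    records: list[AnnotationRecord] = []
    for hit in hits:
        for term in parse_decoration(hit.subject_title):
            if term.not_flag:
                continue
            records.append(AnnotationRecord(
                query_id=hit.query_id, go_id=term.go_id,
                evidence=term.evidence, category=term.category,
                evalue=hit.evalue, source_symbol=term.symbol,
                source_taxon=str(term.taxon), provenance="similarity",
                bit_score=hit.bit_score, subject_id=hit.subject_id,
            ))
    return records


def _collapse_key(r: AnnotationRecord):
    return (r.sort_evalue(), -r.bit_score, r.subject_id, r.provenance != "similarity")


def collapse_annotations(records: Iterable[AnnotationRecord],
                         ) -> list[AnnotationRecord]:
    """Keep one record per (query, GO id): the minimum-E-value supporter.

    Deterministic and order-independent: ties broken by higher bit score,
    then lexicographic subject id; similarity provenance wins residual ties
    against domain scans. Output sorted by (query, GO id). Idempotent.
    """
    best: dict[tuple[str, str], AnnotationRecord] = {}
    for r in records:
        key = (r.query_id, r.go_id)
        cur = best.get(key)
        if cur is None or _collapse_key(r) < _collapse_key(cur):
            best[key] = r
    return [best[k] for k in sorted(best)]


def queries_without_hits(query_ids: Iterable[str],
                         hits: Iterable[AlignmentHit]) -> set[str]:
    """Ids with no retained hit (routed to the domain-scan stage)."""
    with_hits = {h.query_id for h in hits}
    return {q for q in query_ids if q not in with_hits}


def _format_evalue(evalue: Optional[float]) -> str:
    return "NA" if evalue is None else repr(evalue)


def write_summary(records: Sequence[AnnotationRecord], out: IO[str]) -> int:
    """Write the tab-delimited annotation summary; returns data-row count.

    One row per query: id, source symbol, source taxon, then ';'-joined
    ``go_id(evidence,category,evalue)`` entries sorted by GO id. The source
    fields come from the query's lowest-E-value record.
    """
    out.write("#query_id\tsymbol\ttaxon\tgo_terms\n")
    by_query: dict[str, list[AnnotationRecord]] = {}
    for r in records:
        by_query.setdefault(r.query_id, []).append(r)
    n = 0
    for query_id in sorted(by_query):
        rows = by_query[query_id]
        lead = min(rows, key=_collapse_key)
        entries = ";".join(
            f"{r.go_id}({r.evidence},{r.category},{_format_evalue(r.evalue)})"
            for r in sorted(rows, key=lambda r: r.go_id))
        out.write(f"{query_id}\t{lead.source_symbol}\t{lead.source_taxon}"
                  f"\t{entries}\n")
        n += 1
    return n


def read_summary(stream: Union[str, IO[str]]) -> list[AnnotationRecord]:
    """Inverse of :func:`write_summary` (bit-exact on evalue via repr round-trip)."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    records: list[AnnotationRecord] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 4:
            raise TabularParseError("summary rows have 4 columns", lineno)
        query_id, symbol, taxon, entries = cols
        for entry in entries.split(";"):
            if not entry:
                continue
            try:
                go_id, rest = entry.split("(", 1)
                evidence, category, ev_text = rest.rstrip(")").split(",")
            except ValueError:
                raise TabularParseError(
                    f"malformed summary entry {entry!r}", lineno) from None
            evalue = None if ev_text == "NA" else float(ev_text)
            records.append(AnnotationRecord(
                query_id=query_id, go_id=go_id, evidence=evidence,
                category=category, evalue=evalue, source_symbol=symbol,
                source_taxon=taxon,
                provenance="similarity" if evalue is not None else "domain_scan",
            ))
    return records


def annotation_table(records: Iterable[AnnotationRecord]) -> dict[str, set[str]]:
    """gene -> set of GO ids, the container enrichment and comparison consume."""
    table: dict[str, set[str]] = {}
    for r in records:
        table.setdefault(r.query_id, set()).add(r.go_id)
    return table
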