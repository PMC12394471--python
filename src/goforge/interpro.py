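"""Domain-scan bridge (pipeline steps 3-4).

Queries that the similarity search left unannotated can be routed to an
external domain scanner (InterProScan). This module prepares its input —
select the non-hit subset, strip '*' stop codons, batch into groups of 500
— and merges the scanner's TSV output back into the annotation set. The
scanner itself is never run here; only its TSV is consumed.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass
from typing import IO, Iterable, Sequence, Union

from .annotation import AnnotationRecord, collapse_annotations
from .errors import InputError, TabularParseError
from .ontology import GO_ID_RE

BATCH_SIZE = 500

#: 15-column InterProScan TSV; we consume protein accession (1) and the
#: '|'-separated GO column (14).
IPR_MIN_COLUMNS = 14

FastaRecord = tuple[str, str, str]  # (id, description, sequence)

_GO_SUFFIX_RE = re.compile(r"\(.*?\)$")


@dataclass(frozen=True)
class BatchPlan:
    batches: tuple[tuple[FastaRecord, ...], ...]

    @property
    def sizes(self) -> list[int]:
        return [len(b) for b in self.batches]

    def payload(self, index: int) -> str:
        return records_to_fasta(self.batches[index])


def fasta_to_records(text: Union[str, IO[str]]) -> list[FastaRecord]:
    from Bio import SeqIO

    handle = io.StringIO(text) if isinstance(text, str) else text
    out = []
    for rec in SeqIO.parse(handle, "fasta"):
        out.append((rec.id, rec.description, str(rec.seq)))
    return out


def records_to_fasta(records: Iterable[FastaRecord], width: int = 60) -> str:
    chunks = []
    for _, description, seq in records:
        chunks.append(f">{description}\n")
        for i in range(0, len(seq), width):
            chunks.append(seq[i:i + width] + "\n")
    return "".join(chunks)


def select_and_clean(records: Sequence[FastaRecord], no_hit_ids: set[str],
                     mode: str = "nonhits_only") -> list[FastaRecord]:
    """Subset queries for the domain scanner and delete '*' stop codons.

    ``mode`` is ``nonhits_only`` (keep only ids in *no_hit_ids*) or ``all``.
    Ids and descriptions are never altered, only residues. Records empty
    after cleaning are dropped with a warning. An empty selection is an
    empty output, not an error.
    """
    if mode not in ("nonhits_only", "all"):
        raise InputError(f"mode must be nonhits_only or all, got {mode!r}")
    out: list[FastaRecord] = []
    for rec_id, description, seq in records:
        if mode == "nonhits_only" and rec_id not in no_hit_ids:
            continue
        cleaned = seq.replace("*", "")
        if not cleaned:
            warnings.warn(f"record {rec_id!r} empty after stop-codon removal; "
                          "dropped", stacklevel=2)
            continue
        out.append((rec_id, description, cleaned))
    return out


def batch(records: Sequence[FastaRecord], size: int = BATCH_SIZE) -> BatchPlan:
    """Partition records, in input order, into consecutive groups of *size*.

    Every batch has exactly *size* members except possibly the last;
    concatenating the batches reproduces the input.
    """
    groups = tuple(tuple(records[i:i + size])
                   for i in range(0, len(records), size))
    return BatchPlan(batches=groups)


def write_batches(plan: BatchPlan, outdir) -> list[str]:
    """Write ``batch_0001.faa``, ... under *outdir*; returns the paths."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = []
    for i in range(len(plan.batches)):
        path = os.path.join(outdir, f"batch_{i + 1:04d}.faa")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(plan.payload(i))
        paths.append(path)
    return paths


def parse_interpro_tsv(stream: Union[str, IO[str]],
                       ) -> list[tuple[str, list[str]]]:
    """Extract (protein accession, GO ids) pairs from an InterProScan TSV.

    The GO column holds '|'-separated accessions, possibly with a
    parenthesised source suffix ("GO:0005515(InterPro)"), or '-'.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    out: list[tuple[str, list[str]]] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < IPR_MIN_COLUMNS:
            raise TabularParseError(
                f"expected >= {IPR_MIN_COLUMNS} columns in InterProScan TSV, "
                f"found {len(cols)}", lineno)
        go_col = cols[13].strip()
        go_ids: list[str] = []
        if go_col and go_col != "-":
            for token in go_col.split("|"):
                go_id = _GO_SUFFIX_RE.sub("", token.strip())
                if not go_id:
                    continue
                if not GO_ID_RE.match(go_id):
                    raise TabularParseError(
                        f"malformed GO accession {token!r} in GO column", lineno)
                go_ids.append(go_id)
        out.append((cols[0], go_ids))
    return out


def merge_domain_annotations(similarity: Sequence[AnnotationRecord],
                             ipr_tsv: Union[str, IO[str]],
                             ) -> list[AnnotationRecord]:
    """Fold scanner GO terms into the annotation set.

    Scanner terms become records with provenance ``domain_scan`` and
    evidence IEA (inferred from electronic annotation); they carry no
    E-value, so on (query, GO id) collisions the similarity record always
    survives the re-collapse. Merging the same TSV twice is a no-op.
    """
    scanner_records = [
        AnnotationRecord(query_id=acc, go_id=go_id, evidence="IEA",
                         category="-", evalue=None, provenance="domain_scan")
        for acc, go_ids in parse_interpro_tsv(ipr_tsv)
        for go_id in go_ids
    ]
    return collapse_annotations(list(similarity) + scanner_records)
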