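"""Construction of the GO-decorated searchable reference set.

Pipeline: sanitize the reference FASTA (strip non-printable bytes that
break downstream parsers), inner-join NCBI gene2go with gene2accession on
(tax_id, GeneID) so every protein accession inherits its gene's GO
assignments, then rewrite FASTA descriptions with the decoration grammar so
a similarity search's subject titles carry the annotations.

Accession matching is version-insensitive on both sides ("NP_001234.2" and
"NP_001234" resolve identically) because gene2accession mixes versioned and
unversioned forms. Duplicate GO ids with different evidence codes are all
kept; evidence ranking is a downstream concern.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass
from typing import IO, Iterator, Mapping, Union

import pandas as pd

from ._io import open_text
from .decoration import encode_decoration
from .errors import FormatError
from .ontology import GO_ID_RE

GENE2GO_COLUMNS = [
    "tax_id", "GeneID", "GO_ID", "Evidence", "Qualifier",
    "GO_term", "PubMed", "Category",
]
GENE2ACCESSION_NCOLS = 16
# 0-based indices of the consumed gene2accession columns
_G2A_TAX, _G2A_GENE, _G2A_PROT, _G2A_SYMBOL = 0, 1, 5, 15

CATEGORIES = ("Process", "Function", "Component")

_VERSION_RE = re.compile(r"\.\d+$")


def strip_version(accession: str) -> str:
    return _VERSION_RE.sub("", accession)


@dataclass(frozen=True)
class GeneGoAssignment:
    """One gene2go row."""

    tax_id: int
    gene_id: int
    go_id: str
    evidence: str
    qualifier: str
    category: str

    @property
    def not_flag(self) -> bool:
        return self.qualifier.startswith("NOT")


@dataclass(frozen=True)
class AccessionEntry:
    symbol: str
    tax_id: int
    gene_id: int
    assignments: tuple[GeneGoAssignment, ...]


class AccessionGoMap(Mapping):
    """Protein accession -> GO assignments; version-insensitive lookups."""

    def __init__(self) -> None:
        self._entries: dict[str, AccessionEntry] = {}

    def __getitem__(self, accession: str) -> AccessionEntry:
        return self._entries[strip_version(accession)]

    def __contains__(self, accession: object) -> bool:
        return isinstance(accession, str) and strip_version(accession) in self._entries

    def __iter__(self) -> Iterator[str]:
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def add(self, accession: str, entry: AccessionEntry) -> None:
        self._entries[strip_version(accession)] = entry


# ---------------------------------------------------------------------------
# FASTA sanitation / decoration (line-based on purpose: sanitize runs before
# any parser can be trusted, and decorate must leave unmapped records
# byte-identical, which re-flowing through a parser would not).

_PRINTABLE = set(chr(c) for c in range(0x20, 0x7F))


def _clean_line(line: str) -> str:
    return "".join(ch for ch in line if ch in _PRINTABLE)


def sanitize_fasta(text: str) -> str:
    """Remove bytes outside printable ASCII; uppercase sequence lines.

    Line endings are normalised to '\\n'. Records left with an empty
    sequence trigger a warning but are retained. Idempotent.
    """
    out_lines: list[str] = []
    current_header: str | None = None
    current_len = 0

    def check_record() -> None:
        if current_header is not None and current_len == 0:
            warnings.warn(f"record {current_header!r} has an empty sequence "
                          "after cleaning", stacklevel=3)

    for line in text.splitlines():
        cleaned = _clean_line(line)
        if cleaned.startswith(">"):
            check_record()
            current_header = cleaned
            current_len = 0
            out_lines.append(cleaned)
        else:
            cleaned = cleaned.upper()
            current_len += len(cleaned.strip())
            out_lines.append(cleaned)
    check_record()
    return "\n".join(out_lines) + ("\n" if out_lines else "")


def decorate_fasta(fasta_text: str, acc_map: AccessionGoMap) -> str:
    """Append the decoration block to every header whose accession is mapped.

    Records without assignments pass through unchanged; with an empty map
    the output is byte-identical to the input. The encoding is exactly
    inverted by :func:`goforge.decoration.parse_decoration`.
    """
    out_lines = []
    for line in fasta_text.splitlines():
        if line.startswith(">"):
            accession = line[1:].split()[0] if len(line) > 1 else ""
            if accession and accession in acc_map:
                entry = acc_map[accession]
                block = encode_decoration(
                    entry.symbol, entry.tax_id,
                    [(a.go_id, a.evidence, a.category, a.not_flag)
                     for a in entry.assignments],
                )
                line = f"{line} {block}"
        out_lines.append(line)
    return "\n".join(out_lines) + ("\n" if out_lines else "")


# ---------------------------------------------------------------------------
# NCBI table parsing and the merge


def _read_ncbi_table(source, n_cols: int, name: str,
                     required: dict[int, str]) -> pd.DataFrame:
    handle = open_text(source)
    try:
        df = pd.read_csv(handle, sep="\t", comment="#", header=None, dtype=str,
                         na_filter=False)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame()
    if df.empty:
        return pd.DataFrame({i: pd.Series(dtype=str) for i in range(n_cols)})
    if df.shape[1] != n_cols:
        missing = [col for idx, col in required.items() if idx >= df.shape[1]]
        raise FormatError(
            f"{name}: expected {n_cols} tab-delimited columns, found "
            f"{df.shape[1]}" + (f" (missing: {', '.join(missing)})" if missing else ""))
    return df


def read_gene2go(source: Union[str, IO[str]]) -> pd.DataFrame:
    """Read an NCBI gene2go table (plain or gzip) into a typed DataFrame."""
    df = _read_ncbi_table(source, len(GENE2GO_COLUMNS), "gene2go",
                          {i: c for i, c in enumerate(GENE2GO_COLUMNS)})
    df.columns = GENE2GO_COLUMNS
    for col in ("tax_id", "GeneID"):
        try:
            df[col] = df[col].astype(int)
        except ValueError as exc:
            raise FormatError(f"gene2go: non-integer value in column {col}") from exc
    bad = df.loc[~df["GO_ID"].str.match(GO_ID_RE), "GO_ID"]
    if len(bad):
        raise FormatError(f"gene2go: malformed GO id {bad.iloc[0]!r} in column GO_ID")
    return df


def read_gene2accession(source: Union[str, IO[str]]) -> pd.DataFrame:
    """Read an NCBI gene2accession table; only 4 of 16 columns are consumed."""
    df = _read_ncbi_table(
        source, GENE2ACCESSION_NCOLS, "gene2accession",
        {_G2A_TAX: "tax_id", _G2A_GENE: "GeneID",
         _G2A_PROT: "protein_accession.version", _G2A_SYMBOL: "Symbol"})
    out = df.iloc[:, [_G2A_TAX, _G2A_GENE, _G2A_PROT, _G2A_SYMBOL]].copy()
    out.columns = ["tax_id", "GeneID", "protein_accession", "Symbol"]
    for col in ("tax_id", "GeneID"):
        try:
            out[col] = out[col].astype(int)
        except ValueError as exc:
            raise FormatError(
                f"gene2accession: non-integer value in column {col}") from exc
    return out


def merge_gene2go(gene2go: Union[str, IO[str], pd.DataFrame],
                  gene2accession: Union[str, IO[str], pd.DataFrame],
                  ) -> AccessionGoMap:
    """Inner-join the two NCBI tables on (tax_id, GeneID).

    Every protein accession whose gene has at least one gene2go row maps to
    the gene's full assignment list. '-' accessions are skipped; rows never
    join across mismatched taxa. Duplicate (accession, go_id, evidence)
    triples collapse to one. A join with zero rows warns and returns an
    empty map.
    """
    g2g = gene2go if isinstance(gene2go, pd.DataFrame) else read_gene2go(gene2go)
    g2a = (gene2accession if isinstance(gene2accession, pd.DataFrame)
           else read_gene2accession(gene2accession))

    g2a = g2a[g2a["protein_accession"] != "-"]
    merged = g2a.merge(g2g, on=["tax_id", "GeneID"], how="inner")
    if merged.empty:
        warnings.warn("gene2go/gene2accession join produced zero rows",
                      stacklevel=2)
        return AccessionGoMap()

    merged = merged.assign(_acc=merged["protein_accession"].map(strip_version))
    merged = merged.drop_duplicates(subset=["_acc", "GO_ID", "Evidence"])
    merged = merged.sort_values(["_acc", "GO_ID", "Evidence"], kind="stable")

    acc_map = AccessionGoMap()
    for acc, group in merged.groupby("_acc", sort=True):
        first = group.iloc[0]
        assignments = tuple(
            GeneGoAssignment(
                tax_id=int(row.tax_id), gene_id=int(row.GeneID),
                go_id=row.GO_ID, evidence=row.Evidence,
                qualifier="" if row.Qualifier == "-" else row.Qualifier,
                category=row.Category,
            )
            for row in group.itertuples(index=False)
        )
        acc_map.add(acc, AccessionEntry(symbol=first["Symbol"],
                                        tax_id=int(first["tax_id"]),
                                        gene_id=int(first["GeneID"]),
                                        assignments=assignments))
    return acc_map


def build_decorated_fasta(fasta_text: str, gene2go, gene2accession) -> str:
    """sanitize -> merge -> decorate, the full reference-construction step."""
    acc_map = merge_gene2go(gene2go, gene2accession)
    return decorate_fasta(sanitize_fasta(fasta_text), acc_map)
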