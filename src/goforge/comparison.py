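"""Cross-tool annotation-set comparison.

Different annotation tools assign very different numbers of GO terms to the
same proteome; this module quantifies the overlap. Granularity is either
``gene`` (which genes got any term) or ``gene_term`` ((gene, GO id) pairs).
"Total terms assigned" counts (gene, term) pairs, not distinct GO ids —
the reading under which per-tool totals are well-defined. Output is counts
only (Venn region counts for 2-3 sets, per-set summaries, unique
fractions); drawing is left to the caller.
"""

from __future__ import annotations

import io
import itertools
from dataclasses import dataclass, field
from typing import IO, Sequence, Union

from .errors import InputError, TabularParseError
from .ontology import GO_ID_RE


@dataclass
class AnnotationSet:
    """One tool's output: gene -> set of GO accessions."""

    label: str
    gene_terms: dict[str, set[str]] = field(default_factory=dict)

    def genes(self) -> set[str]:
        return {g for g, ts in self.gene_terms.items() if ts}

    def pairs(self) -> set[tuple[str, str]]:
        return {(g, t) for g, ts in self.gene_terms.items() for t in ts}

    def elements(self, granularity: str):
        if granularity == "gene":
            return self.genes()
        if granularity == "gene_term":
            return self.pairs()
        raise InputError(f"granularity must be gene or gene_term, "
                         f"got {granularity!r}")


def summarize_set(s: AnnotationSet) -> tuple[int, int]:
    """(genes with >= 1 term, total (gene, term) pairs)."""
    return len(s.genes()), len(s.pairs())


def venn_regions(sets: Sequence[AnnotationSet], granularity: str = "gene",
                 ) -> dict[tuple[str, ...], int]:
    """Exclusive region counts for 2 or 3 sets.

    Keys are tuples of member labels (in input order); all 2^n - 1
    non-empty signatures are present, zero counts included. The counts
    partition the union of the sets' elements.
    """
    if not 2 <= len(sets) <= 3:
        raise InputError(f"venn comparison supports 2 or 3 sets, got {len(sets)}")
    labels = [s.label for s in sets]
    if len(set(labels)) != len(labels):
        raise InputError("set labels must be unique")
    members = {s.label: s.elements(granularity) for s in sets}

    regions: dict[tuple[str, ...], int] = {}
    for r in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, r):
            regions[combo] = 0
    for element in set().union(*members.values()):
        signature = tuple(lab for lab in labels if element in members[lab])
        regions[signature] += 1
    return regions


def unique_fraction(s: AnnotationSet, others: Sequence[AnnotationSet]) -> float:
    """Fraction of s's (gene, term) pairs found in no other set."""
    if not others:
        raise InputError("unique_fraction needs at least one other set")
    own = s.pairs()
    if not own:
        return 0.0
    foreign = set().union(*(o.pairs() for o in others))
    return len(own - foreign) / len(own)


# ---------------------------------------------------------------------------
# Input dialects


def _parse_long(stream: IO[str], label: str) -> AnnotationSet:
    s = AnnotationSet(label)
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 2:
            raise TabularParseError("long format needs gene<TAB>GO", lineno)
        gene, gos = cols[0], cols[1]
        for go in gos.split(";"):  # tolerate wide rows in long mode
            go = go.strip()
            if not go:
                continue
            if not GO_ID_RE.match(go):
                raise TabularParseError(f"malformed GO accession {go!r}", lineno)
            s.gene_terms.setdefault(gene, set()).add(go)
    return s


def _parse_summary(stream: IO[str], label: str) -> AnnotationSet:
    from .annotation import read_summary

    s = AnnotationSet(label)
    for rec in read_summary(stream):
        s.gene_terms.setdefault(rec.query_id, set()).add(rec.go_id)
    return s


DIALECTS = ("auto", "summary", "long", "wide")


def read_annotation_set(source: Union[str, IO[str]], label: str,
                        dialect: str = "auto") -> AnnotationSet:
    """Load one tool's table: goforge summary, long (gene<TAB>GO) or wide
    (gene<TAB>GO:..;GO:..) — 'auto' sniffs the first line."""
    if dialect not in DIALECTS:
        raise InputError(f"unknown dialect {dialect!r}")
    if isinstance(source, str):
        source = io.StringIO(source)
    text = source.read()
    if dialect == "auto":
        dialect = "summary" if text.startswith("#query_id") else "long"
    if dialect == "summary":
        return _parse_summary(io.StringIO(text), label)
    return _parse_long(io.StringIO(text), label)  # long and wide share a parser


def write_comparison_report(sets: Sequence[AnnotationSet], granularity: str,
                            out: IO[str]) -> None:
    out.write("#section\tkey\tvalue\n")
    for s in sets:
        genes, terms = summarize_set(s)
        out.write(f"summary\t{s.label}.genes_with_terms\t{genes}\n")
        out.write(f"summary\t{s.label}.total_terms\t{terms}\n")
    for signature, count in venn_regions(sets, granularity).items():
        out.write(f"venn_{granularity}\t{'&'.join(signature)}\t{count}\n")
    for i, s in enumerate(sets):
        others = [o for j, o in enumerate(sets) if j != i]
        out.write(f"unique_fraction\t{s.label}\t"
                  f"{unique_fraction(s, others):.6f}\n")
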