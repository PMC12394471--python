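"""Header decoration grammar for GO-annotated reference FASTA files.

Each annotated reference sequence carries its GO assignments inside the
FASTA description, so a tabular similarity search that reports the subject
title (``stitle``) transports the annotations to the query side with no
extra lookup. The grammar, appended after the existing description, is::

    GN=<symbol> TAX=<taxid> GO=<id>!<evidence>!<category>[!NOT][;<id>!...]

';' separates terms and '!' separates fields within a term; neither may
appear in a symbol (symbols are scrubbed before encoding). The block is
bit-exact invertible by :func:`parse_decoration` and survives tab-delimited
columns because it contains no tabs.
"""

from __future__ import annotations

import re
from typing import NamedTuple

from .errors import TabularParseError

_BLOCK_RE = re.compile(r"GN=(\S+) TAX=(\S+) GO=(\S+)")
_SYMBOL_SCRUB_RE = re.compile(r"[^A-Za-z0-9_.\-]")

_CATEGORIES = {"Process", "Function", "Component", "-"}


class DecoratedTerm(NamedTuple):
    """One GO assignment recovered from a decorated subject title."""

    go_id: str
    evidence: str
    category: str
    not_flag: bool
    symbol: str
    taxon: int


def scrub_symbol(symbol: str) -> str:
    """Replace characters that would break the grammar with '_'."""
    cleaned = _SYMBOL_SCRUB_RE.sub("_", symbol)
    return cleaned or "_"


def encode_decoration(symbol: str, tax_id: int,
                      terms: list[tuple[str, str, str, bool]]) -> str:
    """Encode (go_id, evidence, category, not_flag) tuples as a header block."""
    parts = []
    for go_id, evidence, category, not_flag in terms:
        fields = [go_id, evidence, category]
        if not_flag:
            fields.append("NOT")
        parts.append("!".join(fields))
    return f"GN={scrub_symbol(symbol)} TAX={tax_id} GO={';'.join(parts)}"


def parse_decoration(subject_title: str) -> list[DecoratedTerm]:
    """Recover all encoded GO assignments from a subject title.

    Returns an empty list when no decoration block is present. A present
    but truncated block raises :class:`TabularParseError` carrying the title.
    """
    m = _BLOCK_RE.search(subject_title)
    if m is None:
        if "GO=" in subject_title or "GN=" in subject_title:
            raise TabularParseError(
                f"truncated decoration block in subject title: {subject_title!r}")
        return []
    symbol, tax_text, block = m.groups()
    try:
        taxon = int(tax_text)
    except ValueError:
        raise TabularParseError(
            f"non-integer taxon in decoration block: {subject_title!r}") from None
    out: list[DecoratedTerm] = []
    for chunk in block.split(";"):
        fields = chunk.split("!")
        if len(fields) == 4 and fields[3] == "NOT":
            not_flag = True
        elif len(fields) == 3:
            not_flag = False
        else:
            raise TabularParseError(
                f"truncated decoration block in subject title: {subject_title!r}")
        go_id, evidence, category = fields[:3]
        if not go_id.startswith("GO:") or not evidence or category not in _CATEGORIES:
            raise TabularParseError(
                f"malformed decoration term {chunk!r} in title: {subject_title!r}")
        out.append(DecoratedTerm(go_id, evidence, category, not_flag, symbol, taxon))
    return out
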