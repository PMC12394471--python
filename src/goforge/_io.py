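"""Small I/O helpers shared across modules."""

from __future__ import annotations

import gzip
import io
import os
from typing import IO, Iterable, Union

PathOrStream = Union[str, os.PathLike, IO[str], io.TextIOBase]

GZIP_MAGIC = b"\x1f\x8b"


def open_text(source: PathOrStream) -> IO[str]:
    """Open *source* for text reading, transparently decompressing gzip.

    Accepts a path (gzip detected by magic bytes, not extension), an open
    text handle (returned as-is), or a string of content is NOT assumed —
    strings are treated as paths; wrap literal content in io.StringIO.
    """
    if hasattr(source, "read"):
        return source  # type: ignore[return-value]
    path = os.fspath(source)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == GZIP_MAGIC:
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def iter_noncomment_lines(handle: IO[str]) -> Iterable[tuple[int, str]]:
    """Yield (1-based line number, stripped line) skipping blank and '#' lines."""
    for i, raw in enumerate(handle, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line or line.startswith("#"):
            continue
        yield i, line


def sha256_of(path: str) -> str:
    import hashlib

    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
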