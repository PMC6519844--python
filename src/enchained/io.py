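"""Plain-text I/O: chain-length histograms and numeric tables.

Histograms travel as TSV with a ``length<TAB>count`` header, one row per
occupied length, and optional ``#``-prefixed metadata comment lines.
Writing is byte-stable for identical content: lengths sorted, fixed
number formatting.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

from .simulate import ChainLengthHistogram

__all__ = ["read_histogram", "write_histogram", "write_table"]


def read_histogram(path) -> ChainLengthHistogram:
    """Parse a histogram TSV; malformed rows are reported by line number."""
    path = Path(path)
    counts: dict[int, int] = {}
    metadata: dict[str, str] = {}
    lines = path.read_text().splitlines()
    header_seen = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                metadata[key.strip()] = val.strip()
            continue
        if not header_seen:
            cols = [c.strip() for c in line.split("\t")]
            if cols != ["length", "count"]:
                raise ValueError(
                    f"{path}:{lineno}: expected header 'length\\tcount', got {line!r}"
                )
            header_seen = True
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected two tab-separated fields")
        try:
            length, count = int(parts[0]), int(parts[1])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer field: {line!r}") from exc
        if length < 1:
            raise ValueError(f"{path}:{lineno}: length must be >= 1, got {length}")
        if count < 0:
            raise ValueError(f"{path}:{lineno}: count must be >= 0, got {count}")
        if length in counts:
            raise ValueError(f"{path}:{lineno}: duplicate length {length}")
        counts[length] = count
    if not header_seen:
        raise ValueError(f"{path}: missing 'length\\tcount' header")
    return ChainLengthHistogram(counts, metadata)


def write_histogram(histogram: ChainLengthHistogram, path) -> None:
    """Write a histogram TSV (metadata as # key = value comments)."""
    path = Path(path)
    lines = []
    for key, val in histogram.metadata.items():
        if val is not None:
            lines.append(f"# {key} = {val}")
    lines.append("length\tcount")
    for length in sorted(histogram.counts):
        lines.append(f"{length}\t{histogram.counts[length]}")
    path.write_text("\n".join(lines) + "\n")


def _fmt(value) -> str:
    if isinstance(value, float):
        return f"{value:.12g}"
    return str(value)


def write_table(rows: Iterable[Sequence], path, header: Sequence[str]) -> None:
    """Write rows of numbers as TSV with 12-significant-digit floats."""
    path = Path(path)
    lines = ["\t".join(header)]
    for row in rows:
        lines.append("\t".join(_fmt(v) for v in row))
    path.write_text("\n".join(lines) + "\n")
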