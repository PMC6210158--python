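"""FASTA / BED / TSV helpers shared across the pipeline.

Conventions used project-wide: FASTA, BED and PAF coordinates are 0-based
half-open; VCF positions are 1-based (see :mod:`refgap.reconcile`).
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

from Bio import SeqIO

from .errors import ParseError, ValidationError

FASTA_WIDTH = 60


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{name: sequence}`` dict."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        if rec.id in seqs:
            raise ValidationError(f"duplicate FASTA id {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(path, seqs: Mapping[str, str], width: int = FASTA_WIDTH) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_bed(path) -> dict[str, list[tuple[int, int]]]:
    """Read a 3+ column BED file (0-based half-open) into per-contig intervals."""
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError("expected at least 3 BED columns", path, lineno)
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"non-integer BED coordinate: {exc}", path, lineno)
            if not 0 <= start < end:
                raise ParseError(f"ill-ordered BED interval [{start}, {end})", path, lineno)
            out.setdefault(parts[0], []).append((start, end))
    for ivs in out.values():
        ivs.sort()
    return out


def write_bed(path, intervals: Mapping[str, Iterable[tuple[int, int]]], names=None) -> None:
    """Write per-contig intervals as BED (0-based half-open).

    ``names`` may map ``(contig, start, end)`` to a 4th-column label.
    """
    with open(path, "w") as fh:
        for contig in intervals:
            for start, end in sorted(intervals[contig]):
                row = [contig, str(start), str(end)]
                if names is not None:
                    row.append(str(names.get((contig, start, end), ".")))
                fh.write("\t".join(row) + "\n")


def merge_intervals(ivs: Iterable[tuple[int, int]], slack: int = 0) -> list[tuple[int, int]]:
    """Union of intervals, merging any pair closer than ``slack`` bases."""
    ivs = sorted(ivs)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1] + slack:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def interval_complement(ivs, length: int) -> list[tuple[int, int]]:
    """Complement of a union of intervals within ``[0, length)``."""
    out = []
    cursor = 0
    for s, e in merge_intervals(ivs):
        if s > cursor:
            out.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < length:
        out.append((cursor, length))
    return out


def covered_length(ivs) -> int:
    return sum(e - s for s, e in merge_intervals(ivs))
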