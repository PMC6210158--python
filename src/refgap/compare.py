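"""Cross-assembly sharing classification of NS, and the characterization
post-filters that operate on external tool outputs (BLAST tabular hits,
RepeatMasker-style annotation tables)."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence, Union

import numpy as np

from .alignment import RELAXED, AlignParams, align
from .discovery import NovelSequence
from .errors import ParseError, ValidationError
from .io import covered_length

SHARING_CATEGORIES = ("three_way", "pair_only", "unique")


@dataclass
class SharingCall:
    ns_id: str
    found_in: frozenset
    category: str


def classify_sharing(
    ns_list: Sequence[NovelSequence],
    panel: Mapping[str, Mapping[str, str]],
    found_frac: float = 0.5,
    found_identity: float = 0.9,
    params: AlignParams = RELAXED,
) -> list[SharingCall]:
    """Classify each NS by which panel assemblies it is found in.

    An NS is "found in" an assembly when at least ``found_frac`` of its length
    aligns to that assembly at identity >= ``found_identity``.  With a panel
    of two assemblies the categories are the classic three-way / pair /
    individual-unique split; found in every panel member -> ``three_way``
    (panel >= 2), found in none -> ``unique``, anything else -> ``pair_only``.
    """
    if not panel:
        raise ValidationError("panel must contain at least one assembly")
    queries = {ns.ns_id: ns.sequence for ns in ns_list}
    found: dict[str, set] = {ns.ns_id: set() for ns in ns_list}
    for name in panel:
        records = align(queries, panel[name], params)
        cov: dict[str, list] = {}
        for r in records:
            if r.identity >= found_identity:
                cov.setdefault(r.query_id, []).append((r.query_start, r.query_end))
        for ns in ns_list:
            if covered_length(cov.get(ns.ns_id, [])) >= found_frac * ns.length:
                found[ns.ns_id].add(name)
    calls = []
    for ns in ns_list:
        hits = found[ns.ns_id]
        if not hits:
            category = "unique"
        elif len(hits) == len(panel) and len(panel) >= 2:
            category = "three_way"
        else:
            category = "pair_only"
        calls.append(SharingCall(ns.ns_id, frozenset(hits), category))
    return calls


def sharing_base_totals(
    calls: Sequence[SharingCall], ns_lengths: Mapping[str, int]
) -> dict[str, int]:
    """Total NS bases per sharing category (a partition of all NS bases)."""
    totals = {c: 0 for c in SHARING_CATEGORIES}
    for call in calls:
        totals[call.category] += ns_lengths[call.ns_id]
    return totals


# ---------------------------------------------------------------------------
# BLAST top-hit filter
# ---------------------------------------------------------------------------

class BlastHit(NamedTuple):
    query: str
    subject: str
    pident: float
    evalue: float
    bitscore: float


def _parse_blast(lines, path=None) -> list[BlastHit]:
    hits = []
    for lineno, line in enumerate(lines, 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 12:
            raise ParseError("expected 12 tabular (outfmt 6) columns", path, lineno)
        try:
            hits.append(
                BlastHit(parts[0], parts[1], float(parts[2]), float(parts[10]), float(parts[11]))
            )
        except ValueError as exc:
            raise ParseError(str(exc), path, lineno)
    return hits


def blast_tophit_filter(
    hits: Union[str, Iterable],
    species_map: Optional[Mapping[str, str]] = None,
    max_evalue: float = 1e-50,
) -> tuple[dict[str, Optional[BlastHit]], Counter]:
    """Keep, per query, the single best BLAST hit below the E-value ceiling.

    Rows with ``evalue > max_evalue`` are dropped.  The best row has the
    highest bitscore (ties: lowest evalue, then lexicographically smallest
    subject).  Queries whose rows were all dropped map to ``None`` ("no
    hit").  Also returns a species tally using ``species_map`` (subjects
    without a mapping tally under their own id; no-hit queries under
    ``no_hit``).
    """
    if isinstance(hits, str):
        with open(hits) as fh:
            rows = _parse_blast(fh, hits)
    else:
        rows = [h if isinstance(h, BlastHit) else _parse_blast([h])[0] for h in hits]
    queries = {h.query for h in rows}
    best: dict[str, Optional[BlastHit]] = {q: None for q in queries}
    for h in rows:
        if h.evalue > max_evalue:
            continue
        cur = best[h.query]
        if cur is None or (-h.bitscore, h.evalue, h.subject) < (-cur.bitscore, cur.evalue, cur.subject):
            best[h.query] = h
    tally: Counter = Counter()
    for q in sorted(best):
        h = best[q]
        if h is None:
            tally["no_hit"] += 1
        elif species_map:
            tally[species_map.get(h.subject, h.subject)] += 1
        else:
            tally[h.subject] += 1
    return best, tally


# ---------------------------------------------------------------------------
# repeat / GC summary
# ---------------------------------------------------------------------------

#: fixed attribution priority for bases covered by several repeat classes
REPEAT_PRIORITY = ("satellite", "simple", "LINE", "SINE", "other")


def repeat_gc_summary(
    ns_list: Sequence[NovelSequence],
    annotations: Iterable[tuple[str, int, int, str]],
) -> dict:
    """Masked-base fractions per repeat class, GC level, and residual bases.

    ``annotations`` rows are ``(ns_id, start, end, repeat_class)`` with
    0-based half-open intervals on the NS.  Overlapping annotations are
    unioned; a base covered by several classes is attributed to the first
    class in :data:`REPEAT_PRIORITY`.  Unknown classes count as ``other``.
    """
    by_ns = {ns.ns_id: ns for ns in ns_list}
    codes = {c: i for i, c in enumerate(REPEAT_PRIORITY)}
    rows: dict[str, list[tuple[int, int, int]]] = {ns.ns_id: [] for ns in ns_list}
    for ns_id, start, end, cls in annotations:
        if ns_id not in by_ns:
            raise ValidationError(f"annotation references unknown NS {ns_id!r}")
        ns = by_ns[ns_id]
        if not 0 <= start < end <= ns.length:
            raise ValidationError(
                f"annotation [{start}, {end}) outside NS {ns_id} bounds [0, {ns.length})"
            )
        cls_key = cls if cls in codes else ("LINE" if cls.upper() == "LINE" else
                                            "SINE" if cls.upper() == "SINE" else
                                            cls.lower() if cls.lower() in codes else "other")
        rows[ns_id].append((codes[cls_key], start, end))

    total = sum(ns.length for ns in ns_list)
    class_bases = {c: 0 for c in REPEAT_PRIORITY}
    gc = 0
    for ns in ns_list:
        gc += ns.sequence.count("G") + ns.sequence.count("C")
        if not rows[ns.ns_id]:
            continue
        arr = np.full(ns.length, -1, dtype=np.int8)
        for code, start, end in sorted(rows[ns.ns_id]):  # priority order first
            seg = arr[start:end]
            seg[seg == -1] = code
        for c, code in codes.items():
            class_bases[c] += int((arr == code).sum())

    masked = sum(class_bases.values())
    return {
        "total_bases": total,
        "masked_bases": masked,
        "masked_fraction": masked / total if total else 0.0,
        "class_bases": class_bases,
        "class_fractions": {c: (b / total if total else 0.0) for c, b in class_bases.items()},
        "gc_fraction": gc / total if total else 0.0,
        "residual_bases": total - masked,
    }
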