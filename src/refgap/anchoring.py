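"""Placement of NS onto chromosomes through hybrid scaffolds.

Each NS is first mapped to the scaffolds (relaxed parameters, best-hit filter
retaining co-optimal tie placements); for every scaffold footprint, the two
scaffold flanks (up to 50 kb on either side) are mapped to the reference with
strict parameters, and a chromosome locus is assigned only when both flanks
place concordantly — same chromosome, same strand, reference gap below
100 kb.  Single-flank placements stay unanchored, which avoids false unique
anchors at contig ends.  Loci on decoy sequences are recorded and then
excluded from the reported placements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .alignment import RELAXED, STRICT, AlignParams, align, best_hit_filter
from .discovery import NovelSequence
from .errors import ValidationError
from .io import merge_intervals

FLANK_LEN = 50_000
MAX_ANCHOR_GAP = 100_000
LOCUS_MERGE_SLACK = 1_000  # loci on one chromosome closer than this are one locus

STATUSES = ("unique", "multiple", "unanchored", "decoy_excluded")


@dataclass
class AnchorResult:
    ns_id: str
    status: str
    chromosomes: frozenset = frozenset()
    projected_interval: Optional[tuple[str, int, int]] = None  # unique only
    loci: tuple = ()  # all retained (chrom, start, end) loci
    decoy_loci: tuple = ()  # loci recorded on decoys before exclusion

    def validate(self) -> None:
        if self.status not in STATUSES:
            raise ValidationError(f"{self.ns_id}: bad status {self.status!r}")
        if self.status == "unique" and (
            len(self.chromosomes) != 1 or self.projected_interval is None
        ):
            raise ValidationError(f"{self.ns_id}: unique status requires one chromosome and an interval")
        if self.status == "multiple" and len(self.loci) < 2:
            raise ValidationError(f"{self.ns_id}: multiple status requires >= 2 loci")


def _best_flank_record(records):
    if not records:
        return None
    return min(records, key=lambda r: (-r.matches, -r.identity, r.target_id, r.target_start))


def anchor_ns(
    ns_list: Sequence[NovelSequence],
    scaffolds: Mapping[str, str],
    reference: Mapping[str, str],
    decoy_ids: Iterable[str] = (),
    relaxed: AlignParams = RELAXED,
    strict: AlignParams = STRICT,
    flank_len: int = FLANK_LEN,
    max_anchor_gap: int = MAX_ANCHOR_GAP,
) -> list[AnchorResult]:
    """Anchor each NS via scaffold-flank concordance.  See module docstring."""
    decoys = set(decoy_ids)
    shared = set(scaffolds) & set(reference)
    if shared:
        raise ValidationError(f"scaffolds and reference share ids: {sorted(shared)[:3]}")

    queries = {ns.ns_id: ns.sequence for ns in ns_list}
    step1 = best_hit_filter(align(queries, scaffolds, relaxed), keep_ties=True)

    placements: dict[str, list[tuple[str, int, int]]] = {ns.ns_id: [] for ns in ns_list}
    for rec in step1:
        p = (rec.target_id, rec.target_start, rec.target_end)
        if p not in placements[rec.query_id]:
            placements[rec.query_id].append(p)

    # extract flank queries for every placement
    flank_queries: dict[str, str] = {}
    flank_meta: dict[tuple[str, int], dict[str, str]] = {}
    for ns in ns_list:
        for pi, (scaf, ts, te) in enumerate(placements[ns.ns_id]):
            seq = scaffolds[scaf]
            names = {}
            left = seq[max(0, ts - flank_len) : ts]
            right = seq[te : te + flank_len]
            if len(left) >= strict.min_cluster_len:
                qid = f"{ns.ns_id}\x00{pi}\x00L"
                flank_queries[qid] = left
                names["L"] = qid
            if len(right) >= strict.min_cluster_len:
                qid = f"{ns.ns_id}\x00{pi}\x00R"
                flank_queries[qid] = right
                names["R"] = qid
            flank_meta[(ns.ns_id, pi)] = names

    flank_aln = best_hit_filter(align(flank_queries, reference, strict))
    by_flank: dict[str, list] = {}
    for rec in flank_aln:
        by_flank.setdefault(rec.query_id, []).append(rec)

    results = []
    for ns in ns_list:
        raw_loci: list[tuple[str, int, int]] = []
        for pi in range(len(placements[ns.ns_id])):
            names = flank_meta.get((ns.ns_id, pi), {})
            left = _best_flank_record(by_flank.get(names.get("L"), []))
            right = _best_flank_record(by_flank.get(names.get("R"), []))
            if left is None or right is None:
                continue
            if left.target_id != right.target_id or left.strand != right.strand:
                continue
            if left.strand == "+":
                inner = (left.target_end, right.target_start)
            else:
                inner = (right.target_end, left.target_start)
            gap = inner[1] - inner[0]
            if gap >= max_anchor_gap or gap < -max_anchor_gap:
                continue
            start = min(inner)
            end = max(inner[0], inner[1], start + 1)
            raw_loci.append((left.target_id, start, end))

        decoy_loci = [l for l in raw_loci if l[0] in decoys]
        kept = [l for l in raw_loci if l[0] not in decoys]
        # merge near-identical loci on the same chromosome
        merged: list[tuple[str, int, int]] = []
        for chrom in sorted({l[0] for l in kept}):
            for s, e in merge_intervals(
                [(l[1], l[2]) for l in kept if l[0] == chrom], slack=LOCUS_MERGE_SLACK
            ):
                merged.append((chrom, s, e))

        if len(merged) == 1:
            chrom, s, e = merged[0]
            res = AnchorResult(
                ns.ns_id, "unique", frozenset({chrom}), (chrom, s, e),
                tuple(merged), tuple(decoy_loci),
            )
        elif len(merged) >= 2:
            res = AnchorResult(
                ns.ns_id, "multiple", frozenset(l[0] for l in merged), None,
                tuple(merged), tuple(decoy_loci),
            )
        elif decoy_loci:
            res = AnchorResult(ns.ns_id, "decoy_excluded", frozenset(), None, (), tuple(decoy_loci))
        else:
            res = AnchorResult(ns.ns_id, "unanchored")
        res.validate()
        results.append(res)
    return results


def anchor_summary(
    results: Sequence[AnchorResult],
    sharing_calls,
    ns_lengths: Mapping[str, int],
) -> tuple[dict[str, dict[str, int]], dict[str, int]]:
    """Per-chromosome NS base totals of uniquely anchored NS by sharing
    category, plus overall base totals per anchoring status.

    Raises when the three inputs do not describe the same NS set.
    """
    sharing = {c.ns_id: c.category for c in sharing_calls}
    ids = {r.ns_id for r in results}
    if ids != set(sharing) or not ids <= set(ns_lengths):
        raise ValidationError("anchor results, sharing calls and lengths must share ns_ids")
    matrix: dict[str, dict[str, int]] = {}
    totals = {s: 0 for s in STATUSES}
    for r in results:
        totals[r.status] += ns_lengths[r.ns_id]
        if r.status == "unique":
            chrom = next(iter(r.chromosomes))
            matrix.setdefault(chrom, {})
            cat = sharing[r.ns_id]
            matrix[chrom][cat] = matrix[chrom].get(cat, 0) + ns_lengths[r.ns_id]
    return matrix, totals
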