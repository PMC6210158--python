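"""Two-round discovery of novel sequences (NS).

An NS is assembly sequence at least ``min_len`` (default 100) bases long whose
identity to the reference stays below ``max_identity`` (default 0.80) after two
rounds of mapping: a strict first round (nucmer-style -l 150 -c 400 followed by
best-hit filtering) whose unaligned contigs and unaligned internal segments
become candidates, and a relaxed second round (-l 100 -c 200) that gives those
candidates a final chance to align.  Candidate sub-intervals aligning at
identity >= ``max_identity`` in round 2 are removed; the survivors are the NS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .alignment import RELAXED, STRICT, AlignParams, AlignmentRecord, align, best_hit_filter
from .errors import ValidationError
from .io import covered_length, interval_complement, merge_intervals

MIN_CONTIG_LEN = 20_000  # primary contigs shorter than this are excluded
MIN_NS_LEN = 100
MAX_NS_IDENTITY = 0.80


@dataclass
class NovelSequence:
    """A candidate/accepted novel sequence with provenance.

    ``contig_interval`` (``start``/``end``) is 0-based half-open on the source
    contig.  ``best_ref_identity`` is the maximum identity of any round-2
    alignment touching the sequence, 0.0 if it never aligned.
    ``round_detected`` records which mapping round last failed to place it.
    """

    ns_id: str
    donor_id: str
    contig_id: str
    start: int
    end: int
    sequence: str
    origin: str  # whole_contig | internal_segment
    round_detected: int  # 1 | 2
    best_ref_identity: float = 0.0

    @property
    def length(self) -> int:
        return self.end - self.start

    def validate(self, min_len: int = MIN_NS_LEN, max_identity: float = MAX_NS_IDENTITY) -> None:
        if self.length < min_len:
            raise ValidationError(f"{self.ns_id}: length {self.length} < {min_len}")
        if self.length != len(self.sequence):
            raise ValidationError(f"{self.ns_id}: interval span != sequence length")
        if not 0.0 <= self.best_ref_identity < max_identity:
            raise ValidationError(
                f"{self.ns_id}: best_ref_identity {self.best_ref_identity} not in [0, {max_identity})"
            )
        if self.origin not in ("whole_contig", "internal_segment"):
            raise ValidationError(f"{self.ns_id}: bad origin {self.origin!r}")
        if self.round_detected not in (1, 2):
            raise ValidationError(f"{self.ns_id}: bad round {self.round_detected!r}")


def filter_contigs(contigs: Mapping[str, str], min_len: int = MIN_CONTIG_LEN) -> dict[str, str]:
    """Drop contigs shorter than ``min_len`` bases (boundary inclusive),
    preserving input order."""
    return {name: seq for name, seq in contigs.items() if len(seq) >= min_len}


def unaligned_segments(
    contig_lengths: Mapping[str, int],
    alignments: Sequence[AlignmentRecord],
    min_segment: int = MIN_NS_LEN,
) -> dict[str, list[tuple[int, int]]]:
    """Per contig, the complement of the union of aligned query intervals.

    Pieces shorter than ``min_segment`` are dropped; a contig with no
    alignments yields one whole-contig interval.
    """
    by_contig: dict[str, list[tuple[int, int]]] = {name: [] for name in contig_lengths}
    for rec in alignments:
        if rec.query_id not in contig_lengths:
            continue
        if rec.query_end > contig_lengths[rec.query_id]:
            raise ValidationError(
                f"alignment on {rec.query_id} ends at {rec.query_end} but contig "
                f"is {contig_lengths[rec.query_id]} bp"
            )
        by_contig[rec.query_id].append((rec.query_start, rec.query_end))
    return {
        name: [
            (s, e)
            for s, e in interval_complement(ivs, contig_lengths[name])
            if e - s >= min_segment
        ]
        for name, ivs in by_contig.items()
    }


def select_novel_intervals(
    candidate_length: int,
    round2_alignments: Sequence[AlignmentRecord],
    min_len: int = MIN_NS_LEN,
    max_identity: float = MAX_NS_IDENTITY,
) -> list[tuple[int, int, float, int]]:
    """Apply the round-2 acceptance filter to one candidate.

    Sub-intervals covered by an alignment with identity >= ``max_identity``
    are removed; surviving pieces of at least ``min_len`` bases are returned
    as ``(start, end, best_ref_identity, round_detected)`` where
    ``best_ref_identity`` is the maximum identity of any alignment touching
    the piece (0.0 — and round 1 — if none touches it).
    """
    high = [
        (r.query_start, r.query_end)
        for r in round2_alignments
        if r.identity >= max_identity
    ]
    survivors = []
    for s, e in interval_complement(high, candidate_length):
        if e - s < min_len:
            continue
        touching = [
            r.identity
            for r in round2_alignments
            if r.query_start < e and r.query_end > s
        ]
        best = max(touching, default=0.0)
        survivors.append((s, e, best, 2 if touching else 1))
    return survivors


def two_round_discovery(
    contigs: Mapping[str, str],
    reference: Mapping[str, str],
    strict: AlignParams = STRICT,
    relaxed: AlignParams = RELAXED,
    min_len: int = MIN_NS_LEN,
    max_identity: float = MAX_NS_IDENTITY,
    donor_id: str = "donor",
) -> list[NovelSequence]:
    """Discover novel sequences in ``contigs`` relative to ``reference``.

    Round 1: strict alignment + best-hit filter; candidates are the unaligned
    contigs and unaligned internal segments.  Round 2: candidates are
    re-aligned with relaxed parameters against the whole reference, and
    sub-intervals aligning at identity >= ``max_identity`` are removed.
    Output is ordered by (contig, start) with serial ids ``NS_<donor>_<n>``.
    """
    lengths = {name: len(seq) for name, seq in contigs.items()}
    round1 = best_hit_filter(align(contigs, reference, strict))
    candidates = unaligned_segments(lengths, round1, min_segment=min_len)

    cand_queries: dict[str, str] = {}
    cand_meta: dict[str, tuple[str, int, int]] = {}
    for contig in candidates:
        for s, e in candidates[contig]:
            qid = f"{contig}|{s}-{e}"
            cand_queries[qid] = contigs[contig][s:e]
            cand_meta[qid] = (contig, s, e)
    # raw round-2 alignments: removal and best_ref_identity use the maximum
    # over every touching alignment, the conservative choice against novelty
    round2 = align(cand_queries, reference, relaxed)
    by_cand: dict[str, list[AlignmentRecord]] = {qid: [] for qid in cand_queries}
    for rec in round2:
        by_cand[rec.query_id].append(rec)

    raw: list[tuple[str, int, int, float, int]] = []
    for qid, (contig, s, e) in cand_meta.items():
        for a, b, best, rnd in select_novel_intervals(
            e - s, by_cand[qid], min_len=min_len, max_identity=max_identity
        ):
            raw.append((contig, s + a, s + b, best, rnd))
    raw.sort(key=lambda t: (t[0], t[1]))

    out = []
    for serial, (contig, s, e, best, rnd) in enumerate(raw, 1):
        ns = NovelSequence(
            ns_id=f"NS_{donor_id}_{serial:04d}",
            donor_id=donor_id,
            contig_id=contig,
            start=s,
            end=e,
            sequence=contigs[contig][s:e],
            origin="whole_contig" if (s, e) == (0, lengths[contig]) else "internal_segment",
            round_detected=rnd,
            best_ref_identity=best,
        )
        ns.validate(min_len=min_len, max_identity=max_identity)
        out.append(ns)
    return out


def containment_winner(
    sequence: str,
    kept: Sequence[NovelSequence],
    containment_frac: float = 0.8,
    dup_identity: float = 0.9,
    params: AlignParams = RELAXED,
) -> Optional[str]:
    """Return the ns_id of the first kept NS that contains ``sequence``.

    Containment: at least ``containment_frac`` of the sequence aligns to one
    already-kept NS at identity >= ``dup_identity``.  Byte-identical and exact
    substring duplicates are short-circuited without alignment.
    """
    if not kept:
        return None
    n = len(sequence)
    for k in kept:  # fast path — exact containment
        if n <= len(k.sequence) and (sequence in k.sequence or sequence in (k.sequence + k.sequence)):
            return k.ns_id
    for k in kept:
        recs = align({"q": sequence}, {k.ns_id: k.sequence}, params)
        cov = covered_length(
            (r.query_start, r.query_end) for r in recs if r.identity >= dup_identity
        )
        if cov >= containment_frac * n:
            return k.ns_id
    return None


def deduplicate(
    ns_list: Sequence[NovelSequence],
    containment_frac: float = 0.8,
    dup_identity: float = 0.9,
    params: AlignParams = RELAXED,
) -> list[NovelSequence]:
    """Remove duplicated NS, keeping the longest representative.

    NS are visited by descending length (ties: lexicographic ns_id); an NS is
    removed if at least ``containment_frac`` of its length aligns to an
    already-kept NS at identity >= ``dup_identity``.  Idempotent.
    """
    order = sorted(ns_list, key=lambda n: (-n.length, n.ns_id))
    kept: list[NovelSequence] = []
    for ns in order:
        if containment_winner(ns.sequence, kept, containment_frac, dup_identity, params) is None:
            kept.append(ns)
    return kept
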