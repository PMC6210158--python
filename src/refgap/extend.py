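"""Construction of the NS-extended reference.

NS sets are supplied in priority order (on a duplicate, the earliest set's
copy wins — the analysis that defined the pipeline always kept the first
individual's version).  Surviving NS are appended to the reference as
additional sequences; the original reference sequences are never edited.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from .alignment import RELAXED, AlignParams
from .discovery import NovelSequence, containment_winner
from .errors import ValidationError


def build_extended(
    reference: Mapping[str, str],
    ns_sets: Sequence[Sequence[NovelSequence]],
    containment_frac: float = 0.8,
    dup_identity: float = 0.9,
    params: AlignParams = RELAXED,
) -> tuple[dict[str, str], list[dict]]:
    """Append NS to the reference with priority-ordered cross-set dedup.

    Returns ``(extended reference, manifest)``.  The manifest lists every
    input NS with ``kept`` status and, for dropped NS, the id of the kept NS
    that contains it.  Deduplication shares its containment predicate with
    :func:`refgap.discovery.deduplicate`.
    """
    kept: list[NovelSequence] = []
    manifest: list[dict] = []
    for priority, ns_set in enumerate(ns_sets):
        for ns in ns_set:
            if ns.ns_id in reference:
                raise ValidationError(f"NS id {ns.ns_id!r} collides with a reference id")
            winner = containment_winner(
                ns.sequence, kept, containment_frac, dup_identity, params
            )
            manifest.append(
                {
                    "ns_id": ns.ns_id,
                    "donor_id": ns.donor_id,
                    "priority": priority,
                    "length": ns.length,
                    "kept": winner is None,
                    "duplicate_of": winner or "",
                }
            )
            if winner is None:
                kept.append(ns)
    extended = dict(reference)
    for ns in kept:
        extended[ns.ns_id] = ns.sequence
    return extended, manifest


def appended_bases(manifest: Sequence[dict]) -> int:
    return sum(row["length"] for row in manifest if row["kept"])
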