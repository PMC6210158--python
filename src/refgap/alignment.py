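"""Alignment records, PAF / coords I/O, a minimal seed-and-chain aligner,
and the per-query best-hit filter.

The aligner is a deliberately small test-enabling aligner in the spirit of
NUCmer's ``-maxmatch -l L -c C`` parameterization: exact matches of length at
least ``min_match_len`` are found on both strands and chained when colinear;
chains whose summed exact-match length falls below ``min_cluster_len`` are
discarded.  It is not a MUMmer reimplementation — externally produced PAF or
show-coords-style TSV alignments are the first-class path for real data.

Identity is defined as ``matches / alignment_span`` where the span counts all
alignment columns: gap columns between chained seeds contribute
``max(query_gap, target_gap)`` mismatching columns.  N bases never seed and
therefore always fall into gap columns.
"""

from __future__ import annotations

import os
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .errors import ConfigError, ParseError, ValidationError

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement (A/C/G/T/N, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlignParams:
    """Aligner parameters.

    ``min_match_len`` and ``min_cluster_len`` mirror NUCmer's ``-l`` and ``-c``;
    ``max_seed_gap`` bounds the query/target gap between consecutive chained
    seeds.
    """

    min_match_len: int = 150
    min_cluster_len: int = 400
    max_seed_gap: int = 500

    def __post_init__(self):
        if self.min_match_len < 11:
            raise ConfigError(f"min_match_len must be >= 11, got {self.min_match_len}")
        if self.min_cluster_len < self.min_match_len:
            raise ConfigError(
                f"min_cluster_len ({self.min_cluster_len}) must be >= "
                f"min_match_len ({self.min_match_len})"
            )
        if self.max_seed_gap < 0:
            raise ConfigError("max_seed_gap must be >= 0")


#: first-round ("strict") mapping parameters: nucmer -l 150 -c 400
STRICT = AlignParams(min_match_len=150, min_cluster_len=400)
#: second-round ("relaxed") mapping parameters: nucmer -l 100 -c 200
RELAXED = AlignParams(min_match_len=100, min_cluster_len=200)


@dataclass
class AlignmentRecord:
    """One query-to-target local alignment.

    Coordinates are 0-based half-open on the forward strand of both sequences;
    ``strand == '-'`` means the reverse complement of the query aligns to the
    target.  ``query_length`` / ``target_length`` may be ``None`` for dialects
    that do not carry them (coords TSV).
    """

    query_id: str
    query_start: int
    query_end: int
    target_id: str
    target_start: int
    target_end: int
    strand: str
    matches: int
    alignment_span: int
    query_length: Optional[int] = None
    target_length: Optional[int] = None

    @property
    def identity(self) -> float:
        return self.matches / self.alignment_span

    def validate(self) -> None:
        if self.strand not in "+-":
            raise ValidationError(f"bad strand {self.strand!r}")
        if not 0 <= self.query_start < self.query_end:
            raise ValidationError(
                f"ill-ordered query interval [{self.query_start}, {self.query_end})"
            )
        if self.query_length is not None and self.query_end > self.query_length:
            raise ValidationError("query interval exceeds query length")
        if not 0 <= self.target_start < self.target_end:
            raise ValidationError(
                f"ill-ordered target interval [{self.target_start}, {self.target_end})"
            )
        if self.target_length is not None and self.target_end > self.target_length:
            raise ValidationError("target interval exceeds target length")
        if not 0 < self.matches <= self.alignment_span:
            raise ValidationError(
                f"matches ({self.matches}) must be in (0, span={self.alignment_span}]"
            )


_SORT_KEY = lambda r: (r.query_id, r.query_start, r.query_end, r.target_id, r.target_start, r.strand)

COORDS_HEADER = "query\tqstart\tqend\ttarget\ttstart\ttend\tstrand\tmatches\tspan\tidentity"


def read_alignments(path, dialect: str = "paf") -> list[AlignmentRecord]:
    """Read alignments from ``path`` in ``paf`` or ``coords`` dialect.

    The coords dialect is a TSV with header ``query qstart qend target tstart
    tend strand matches span identity`` using 1-based inclusive coordinates;
    they are converted to 0-based half-open on read.
    """
    if dialect not in ("paf", "coords"):
        raise ConfigError(f"unknown alignment dialect {dialect!r}")
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if dialect == "coords" and lineno == 1 and line.startswith("query\t"):
                continue
            parts = line.split("\t")
            try:
                if dialect == "paf":
                    if len(parts) < 12:
                        raise ValueError("expected >= 12 PAF columns")
                    rec = AlignmentRecord(
                        query_id=parts[0],
                        query_length=int(parts[1]),
                        query_start=int(parts[2]),
                        query_end=int(parts[3]),
                        strand=parts[4],
                        target_id=parts[5],
                        target_length=int(parts[6]),
                        target_start=int(parts[7]),
                        target_end=int(parts[8]),
                        matches=int(parts[9]),
                        alignment_span=int(parts[10]),
                    )
                else:
                    if len(parts) < 10:
                        raise ValueError("expected >= 10 coords columns")
                    rec = AlignmentRecord(
                        query_id=parts[0],
                        query_start=int(parts[1]) - 1,
                        query_end=int(parts[2]),
                        target_id=parts[3],
                        target_start=int(parts[4]) - 1,
                        target_end=int(parts[5]),
                        strand=parts[6],
                        matches=int(parts[7]),
                        alignment_span=int(parts[8]),
                    )
            except ValueError as exc:
                raise ParseError(str(exc), path, lineno)
            rec.validate()
            records.append(rec)
    return records


def write_alignments(path, records: Iterable[AlignmentRecord], dialect: str = "paf") -> None:
    if dialect not in ("paf", "coords"):
        raise ConfigError(f"unknown alignment dialect {dialect!r}")
    with open(path, "w") as fh:
        if dialect == "coords":
            fh.write(COORDS_HEADER + "\n")
        for r in records:
            if dialect == "paf":
                if r.query_length is None or r.target_length is None:
                    raise ValidationError("PAF output requires query and target lengths")
                fh.write(
                    "\t".join(
                        map(
                            str,
                            (
                                r.query_id, r.query_length, r.query_start, r.query_end,
                                r.strand,
                                r.target_id, r.target_length, r.target_start, r.target_end,
                                r.matches, r.alignment_span, 255,
                            ),
                        )
                    )
                    + "\n"
                )
            else:
                fh.write(
                    "\t".join(
                        map(
                            str,
                            (
                                r.query_id, r.query_start + 1, r.query_end,
                                r.target_id, r.target_start + 1, r.target_end,
                                r.strand, r.matches, r.alignment_span,
                                f"{r.identity:.6f}",
                            ),
                        )
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# seed-and-chain aligner
# ---------------------------------------------------------------------------

_MAX_SEEDS_PER_GROUP = 4000  # cap for pathological self-similar inputs
_MAX_CHAINS_PER_GROUP = 64


def _index_targets(targets: Mapping[str, str], k: int):
    """Exact k-mer index of the targets.  K-mers containing N never seed."""
    index: dict[str, list[tuple[int, int]]] = {}
    names = list(targets)
    for ti, name in enumerate(names):
        seq = targets[name].upper()
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            index.setdefault(kmer, []).append((ti, i))
    return index, names


def _collect_seeds(query: str, index, k: int) -> dict[int, list[list[int]]]:
    """Maximal exact matches >= k per target, as [qstart, qend, tstart] seeds.

    Consecutive k-mer hits on a diagonal are merged into one maximal match;
    query k-mers containing N cannot hit the index (target k-mers with N are
    never indexed, so no explicit query-side check is needed).
    """
    runs: dict[tuple[int, int], list[list[int]]] = {}
    for i in range(len(query) - k + 1):
        hits = index.get(query[i : i + k])
        if hits is None:
            continue
        for ti, tpos in hits:
            key = (ti, tpos - i)
            lst = runs.get(key)
            if lst is None:
                runs[key] = [[i, i + k]]
            else:
                last = lst[-1]
                if i + k == last[1] + 1:  # adjacent window: extend the match
                    last[1] = i + k
                elif i >= last[1]:
                    lst.append([i, i + k])
    per_target: dict[int, list[list[int]]] = {}
    for (ti, diag), lst in runs.items():
        out = per_target.setdefault(ti, [])
        for qs, qe in lst:
            out.append([qs, qe, qs + diag])
    return per_target


def _chain_group(seeds: list[list[int]], params: AlignParams) -> list[list[list[int]]]:
    """Chain seeds of one (target, strand) group.

    Returns chains as lists of ``[qstart, qend, tstart]`` seeds.  After a
    chain is extracted, remaining seeds overlapping its query span are dropped,
    so at most one chain is reported per query region per target and strand
    (cross-target alternatives are arbitrated later by the best-hit filter).
    """
    if len(seeds) > _MAX_SEEDS_PER_GROUP:
        seeds = sorted(seeds, key=lambda s: (-(s[1] - s[0]), s[0], s[2]))[:_MAX_SEEDS_PER_GROUP]
    active = sorted(seeds, key=lambda s: (s[0], s[2]))
    gap = params.max_seed_gap
    chains = []
    while active and len(chains) < _MAX_CHAINS_PER_GROUP:
        n = len(active)
        score = [0] * n
        prev = [-1] * n
        best_i = 0
        for i in range(n):
            qs, qe, ts = active[i]
            length = qe - qs
            s_best = length
            p_best = -1
            for j in range(i):
                jqs, jqe, jts = active[j]
                jte = jts + (jqe - jqs)
                if jqe <= qs and jte <= ts and qs - jqe <= gap and ts - jte <= gap:
                    cand = score[j] + length
                    if cand > s_best:
                        s_best = cand
                        p_best = j
            score[i] = s_best
            prev[i] = p_best
            if s_best > score[best_i] or (
                s_best == score[best_i]
                and (active[i][0], active[i][2]) < (active[best_i][0], active[best_i][2])
                and i != best_i
            ):
                best_i = i
        if score[best_i] < params.min_cluster_len:
            break
        # backtrack
        chain = []
        i = best_i
        while i != -1:
            chain.append(active[i])
            i = prev[i]
        chain.reverse()
        chains.append(chain)
        qstart, qend = chain[0][0], chain[-1][1]
        active = [s for s in active if s[1] <= qstart or s[0] >= qend]
    return chains


def _chain_to_stats(chain, qseq: str, tseq: str) -> tuple[int, int, int, int, int, int]:
    """Coordinates, matches and span of a chain on the oriented sequences.

    Junction gaps contribute ``max(query_gap, target_gap)`` alignment columns;
    for equal-length gaps (the substitution case) the gap bases are compared
    directly so that matching bases inside unseeded stretches still count as
    matches, as a DP-extending aligner would score them.
    """
    qstart, tstart = chain[0][0], chain[0][2]
    qend = chain[-1][1]
    tend = chain[-1][2] + (chain[-1][1] - chain[-1][0])
    matches = sum(qe - qs for qs, qe, _ in chain)
    span = matches
    for a, b in zip(chain, chain[1:]):
        qgap = b[0] - a[1]
        tgap = b[2] - (a[2] + (a[1] - a[0]))
        span += max(qgap, tgap)
        if qgap == tgap and qgap > 0:
            aq, at = a[1], a[2] + (a[1] - a[0])
            matches += sum(
                qseq[aq + i] == tseq[at + i] and qseq[aq + i] != "N"
                for i in range(qgap)
            )
    return qstart, qend, tstart, tend, matches, span


def align(
    queries: Mapping[str, str],
    targets: Mapping[str, str],
    params: AlignParams = STRICT,
) -> list[AlignmentRecord]:
    """Align each query to the targets with exact seeding and colinear chaining.

    Deterministic, and invariant under query input order: the result is sorted
    by (query, query interval, target, target interval, strand).
    """
    if not queries or not targets:
        return []
    k = params.min_match_len
    index, tnames = _index_targets(targets, k)
    tlens = [len(targets[n]) for n in tnames]
    records: list[AlignmentRecord] = []
    for qname in queries:
        qseq = queries[qname].upper()
        qlen = len(qseq)
        for strand, seq in (("+", qseq), ("-", revcomp(qseq))):
            for ti, seeds in _collect_seeds(seq, index, k).items():
                tseq = targets[tnames[ti]].upper()
                for chain in _chain_group(seeds, params):
                    qs, qe, ts, te, matches, span = _chain_to_stats(chain, seq, tseq)
                    if strand == "-":
                        qs, qe = qlen - qe, qlen - qs
                    rec = AlignmentRecord(
                        query_id=qname,
                        query_start=qs,
                        query_end=qe,
                        target_id=tnames[ti],
                        target_start=ts,
                        target_end=te,
                        strand=strand,
                        matches=matches,
                        alignment_span=span,
                        query_length=qlen,
                        target_length=tlens[ti],
                    )
                    rec.validate()
                    records.append(rec)
    records.sort(key=_SORT_KEY)
    return records


# ---------------------------------------------------------------------------
# best-hit (delta-filter -q analog) query filter
# ---------------------------------------------------------------------------

OVERLAP_TOLERANCE = 10  # bp of query overlap permitted between selected records


def _prio(rec: AlignmentRecord):
    # smaller is better: higher identity, then lower target id, then lower start
    return (-rec.identity, rec.target_id, rec.target_start, rec.strand)


def _better(a, b):
    """Compare (weight, tie) values; larger weight wins, smaller tie wins."""
    if a[0] != b[0]:
        return a if a[0] > b[0] else b
    return a if a[1] <= b[1] else b


def _select_group(recs: list[AlignmentRecord], tolerance: int) -> list[AlignmentRecord]:
    """Maximum-weight set of query-compatible records via weighted interval
    scheduling; weight = matches; overlap up to ``tolerance`` bp is allowed."""
    order = sorted(range(len(recs)), key=lambda i: (recs[i].query_end, recs[i].query_start, _prio(recs[i])))
    ends = [recs[i].query_end for i in order]
    # best[i] = (value, chosen index tuple) over the first i records
    best = [((0, ()), ())]
    for pos, i in enumerate(order):
        r = recs[i]
        p = bisect_right(ends, r.query_start + tolerance, 0, pos)
        prev_val, prev_set = best[p]
        take_val = (prev_val[0] + r.matches, tuple(sorted(prev_val[1] + (_prio(r),))))
        take = (take_val, prev_set + (i,))
        skip = best[pos]
        best.append(take if _better(take[0], skip[0]) is take[0] else skip)
    chosen = [recs[i] for i in best[-1][1]]
    chosen.sort(key=_SORT_KEY)
    return chosen


def best_hit_filter(
    records: Sequence[AlignmentRecord],
    tolerance: int = OVERLAP_TOLERANCE,
    keep_ties: bool = False,
) -> list[AlignmentRecord]:
    """Keep, per query, a maximum-weight set of non-overlapping alignments.

    Weight is ``matches``; selected query intervals pairwise overlap at most
    ``tolerance`` bases.  Ties are broken toward higher identity, then lower
    target id, then lower target start.  With ``keep_ties=True``, co-optimal
    records (equal matches and span) displaced only by query overlap with a
    selected record are additionally retained — used by anchoring, where an
    exact-repeat sequence legitimately has several equivalent placements.
    """
    by_query: dict[str, list[AlignmentRecord]] = {}
    for r in records:
        by_query.setdefault(r.query_id, []).append(r)
    out: list[AlignmentRecord] = []
    for q in sorted(by_query):
        selected = _select_group(by_query[q], tolerance)
        if keep_ties:
            pool = {id(r) for r in selected}
            extras = []
            for r in by_query[q]:
                if id(r) in pool:
                    continue
                for s in selected:
                    overlap = min(r.query_end, s.query_end) - max(r.query_start, s.query_start)
                    if (
                        overlap > tolerance
                        and r.matches == s.matches
                        and r.alignment_span == s.alignment_span
                    ):
                        extras.append(r)
                        break
            selected = sorted(selected + extras, key=_SORT_KEY)
        out.extend(selected)
    out.sort(key=_SORT_KEY)
    return out
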