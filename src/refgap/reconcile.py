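"""Per-sample Lost/Both/Gained SNV classification between paired call sets
(base reference vs NS-extended reference), cohort consistency filtering with
centromere masking, annotation, and the NS variant-density statistic.

A variant's identity is ``(contig, 1-based position, ref, alt)``; genotype and
quality are ignored — classification asks whether a call was *found*, not
whether genotypes agree.  Multi-allelic records are decomposed before
comparison; indels and MNVs are dropped with a logged count (the analysis is
SNV-only).

Classes per sample:

* ``lost``    — called against the base reference only;
* ``both``    — called against both references;
* ``gained``  — called against the extended reference only, partitioned into
  ``gained_on_chrom`` (primary contigs) and ``gained_on_ns`` (NS contigs).

A variant is *consistently lost* when it is lost in at least
``ceil(min_frac * n_samples)`` samples, appears in **no** sample's Gained or
Both set, and lies outside the centromere mask; symmetrically for gained.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import pysam

from .errors import ConfigError, ParseError, ValidationError


class VariantKey(NamedTuple):
    contig: str
    pos: int  # 1-based
    ref: str
    alt: str


@dataclass
class SampleClassification:
    sample_id: str
    lost: set = field(default_factory=set)
    both: set = field(default_factory=set)
    gained_on_chrom: set = field(default_factory=set)
    gained_on_ns: set = field(default_factory=set)
    dropped: dict = field(default_factory=dict)  # reason -> count

    @property
    def gained(self) -> set:
        return self.gained_on_chrom | self.gained_on_ns


@dataclass
class CohortSummary:
    n_samples: int
    min_frac: float
    threshold: int
    lost_counts: Counter
    both_counts: Counter
    gained_on_chrom_counts: Counter
    gained_on_ns_counts: Counter
    consistent_lost: set
    consistent_gained: set
    spectra: dict  # class -> Counter(carrier count -> number of variants)


def read_snv_keys(path, allowed_contigs: Optional[set] = None):
    """Read SNV keys from a VCF, decomposing multi-allelic records.

    Returns ``(keys, dropped)`` where dropped counts ``non_snv`` records and
    records on contigs outside ``allowed_contigs`` (``other_contig``).  The
    same key twice after decomposition is a validation error.
    """
    keys: set[VariantKey] = set()
    dropped = Counter()
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                if len(rec.ref) != 1 or len(alt) != 1 or rec.ref == alt:
                    dropped["non_snv"] += 1
                    continue
                if allowed_contigs is not None and rec.contig not in allowed_contigs:
                    dropped["other_contig"] += 1
                    continue
                key = VariantKey(rec.contig, rec.pos, rec.ref.upper(), alt.upper())
                if key in keys:
                    raise ValidationError(f"{path}: duplicate variant {key} after decomposition")
                keys.add(key)
    return keys, dropped


def classify_sample(
    vcf_base,
    vcf_extended,
    primary_contigs: Iterable[str],
    ns_contigs: Iterable[str],
    sample_id: Optional[str] = None,
) -> SampleClassification:
    """Classify one sample's SNVs into Lost / Both / Gained.

    Keys on contigs in neither ``primary_contigs`` nor ``ns_contigs`` (decoys,
    unplaced scaffolds) are dropped and counted.
    """
    primary = set(primary_contigs)
    ns = set(ns_contigs)
    allowed = primary | ns
    base_keys, base_drop = read_snv_keys(vcf_base, allowed)
    ext_keys, ext_drop = read_snv_keys(vcf_extended, allowed)
    gained = ext_keys - base_keys
    cls = SampleClassification(
        sample_id=sample_id or str(vcf_base),
        lost=base_keys - ext_keys,
        both=base_keys & ext_keys,
        gained_on_chrom={k for k in gained if k.contig in primary},
        gained_on_ns={k for k in gained if k.contig in ns},
        dropped=dict(base_drop + ext_drop),
    )
    return cls


def _in_mask(key: VariantKey, mask: Optional[Mapping[str, Sequence[tuple[int, int]]]]) -> bool:
    # BED is 0-based half-open, VCF positions 1-based: pos is inside [s, e)
    # iff s <= pos - 1 < e
    if not mask:
        return False
    return any(s <= key.pos - 1 < e for s, e in mask.get(key.contig, ()))


def cohort_consistency(
    classifications: Sequence[SampleClassification],
    min_frac: float = 0.05,
    centromeres: Optional[Mapping[str, Sequence[tuple[int, int]]]] = None,
) -> CohortSummary:
    """Cohort-level consistency filter over per-sample classifications.

    Spectra (carrier-count histograms per class) are computed before the
    threshold cut; the consistent sets after it.
    """
    if not 0.0 < min_frac <= 1.0:
        raise ConfigError(f"min_frac must be in (0, 1], got {min_frac}")
    if not classifications:
        raise ConfigError("need at least one sample classification")
    n = len(classifications)
    threshold = math.ceil(min_frac * n)

    lost_counts, both_counts = Counter(), Counter()
    g_chrom_counts, g_ns_counts = Counter(), Counter()
    for cls in classifications:
        lost_counts.update(cls.lost)
        both_counts.update(cls.both)
        g_chrom_counts.update(cls.gained_on_chrom)
        g_ns_counts.update(cls.gained_on_ns)
    gained_counts = g_chrom_counts + g_ns_counts

    consistent_lost = {
        v
        for v, c in lost_counts.items()
        if c >= threshold
        and v not in gained_counts
        and v not in both_counts
        and not _in_mask(v, centromeres)
    }
    consistent_gained = {
        v
        for v, c in gained_counts.items()
        if c >= threshold
        and v not in lost_counts
        and v not in both_counts
        and not _in_mask(v, centromeres)
    }
    spectra = {
        name: Counter(counts.values())
        for name, counts in (
            ("lost", lost_counts),
            ("both", both_counts),
            ("gained_on_chrom", g_chrom_counts),
            ("gained_on_ns", g_ns_counts),
        )
    }
    return CohortSummary(
        n_samples=n,
        min_frac=min_frac,
        threshold=threshold,
        lost_counts=lost_counts,
        both_counts=both_counts,
        gained_on_chrom_counts=g_chrom_counts,
        gained_on_ns_counts=g_ns_counts,
        consistent_lost=consistent_lost,
        consistent_gained=consistent_gained,
        spectra=spectra,
    )


def read_known_table(path) -> set[VariantKey]:
    """Read a 4-column known-variant catalogue: contig, pos (1-based), ref, alt."""
    known: set[VariantKey] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError("expected 4 columns (contig, pos, ref, alt)", path, lineno)
            try:
                pos = int(parts[1])
            except ValueError:
                raise ParseError(f"non-integer position {parts[1]!r}", path, lineno)
            known.add(VariantKey(parts[0], pos, parts[2].upper(), parts[3].upper()))
    return known


def annotate_variants(
    summary: CohortSummary,
    known: Iterable[VariantKey],
    coding: Optional[Mapping[str, Sequence[tuple[int, int]]]] = None,
) -> dict:
    """Flag consistent variants as known/unknown and coding/non-coding.

    Returns per-class counts and fractions.
    """
    known = set(known)
    out = {}
    for name, variants in (
        ("consistent_lost", summary.consistent_lost),
        ("consistent_gained", summary.consistent_gained),
    ):
        n = len(variants)
        n_known = sum(1 for v in variants if v in known)
        n_coding = sum(1 for v in variants if _in_mask(v, coding))
        out[name] = {
            "n": n,
            "known": n_known,
            "known_fraction": n_known / n if n else 0.0,
            "coding": n_coding,
            "coding_fraction": n_coding / n if n else 0.0,
        }
    return out


def density_per_kb(gained_on_ns: Iterable[VariantKey], ns_lengths: Mapping[str, int]) -> float:
    """Distinct gained-on-NS variants per kb of NS sequence."""
    total = sum(ns_lengths.values())
    if total <= 0:
        raise ValidationError("total NS length is zero; density undefined")
    return len(set(gained_on_ns)) / (total / 1000.0)
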