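"""Synthetic genomes with implanted novel segments, scaffolds, and paired
cohort VCFs with designed variant fates.

The generator emulates the statistical structure of real novel sequences (NS):
implants are tandem arrays of random units (satellite-like, hence repetitive
by construction), with a GC level slightly above the genomic background, and
with most implanted bases in segments longer than 5 kb.  Building implants
from random non-reference-derived sequence guarantees by construction that
their best local-alignment identity to the reference stays far below the 80%
acceptance ceiling, so the discovery filter's ground truth is unambiguous.

Divergence between a donor and the reference is substitution-only; read-level
artefacts are not modeled — variant fates are imposed directly at the VCF
level, which is the boundary at which the reconciliation stage operates.
"""

from __future__ import annotations

import math
import os
import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import ConfigError, ValidationError
from .reconcile import VariantKey

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i

DECOY_ID = "decoy1"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic pipeline.

    Defaults describe a desk-scale genome: two 200 kb chromosomes plus a 30 kb
    decoy, eight repeat-rich GC-elevated implants of 0.5-10 kb per donor at a
    backbone divergence of 1 substitution/kb, fragmented into contigs of at
    least 20 kb, and a 40-sample cohort with 500 designed variant fates at
    carrier frequencies between 0.02 and 1.0.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 200_000
    decoy_length: int = 30_000
    n_novel_segments: int = 8
    novel_length_range: tuple[int, int] = (500, 10_000)
    tandem_unit_range: tuple[int, int] = (20, 200)
    novel_gc_target: float = 0.43
    background_gc: float = 0.41
    divergence_rate: float = 0.001
    contig_break_rate: float = 2e-5
    min_contig_len: int = 20_000
    cohort_size: int = 40
    n_lost_designed: int = 150
    n_gained_designed: int = 200
    n_both_designed: int = 150
    cohort_freq_range: tuple[float, float] = (0.02, 1.0)
    centromere_fraction: float = 0.10
    noise_variants_per_sample: int = 20
    n_contradicted_lost: int = 1
    include_decoy_implant: bool = True

    def validate(self) -> None:
        counts = {
            "n_chromosomes": self.n_chromosomes,
            "chrom_length": self.chrom_length,
            "decoy_length": self.decoy_length,
            "n_novel_segments": self.n_novel_segments,
            "min_contig_len": self.min_contig_len,
            "n_lost_designed": self.n_lost_designed,
            "n_gained_designed": self.n_gained_designed,
            "n_both_designed": self.n_both_designed,
            "noise_variants_per_sample": self.noise_variants_per_sample,
            "n_contradicted_lost": self.n_contradicted_lost,
        }
        for name, value in counts.items():
            if value < 0:
                raise ConfigError(f"{name} must be >= 0, got {value}")
        if self.cohort_size < 1:
            raise ConfigError(f"cohort_size must be >= 1, got {self.cohort_size}")
        for name in ("novel_length_range", "tandem_unit_range", "cohort_freq_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ConfigError(f"{name} must be a well-ordered non-negative range, got ({lo}, {hi})")
        for name in ("novel_gc_target", "background_gc", "divergence_rate",
                     "centromere_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {value}")
        if self.contig_break_rate < 0:
            raise ConfigError(f"contig_break_rate must be >= 0, got {self.contig_break_rate}")
        if self.novel_length_range[1] > self.chrom_length:
            raise ConfigError(
                f"novel_length_range max ({self.novel_length_range[1]}) exceeds "
                f"chrom_length ({self.chrom_length})"
            )


@dataclass
class Contig:
    contig_id: str
    donor_id: str
    source: str  # chromosome (or decoy) the contig derives from
    source_start: int  # 0-based start on the donor copy of `source`
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class ImplantRecord:
    """Ground truth for one implanted novel segment."""

    donor_id: str
    contig_id: str
    start: int  # 0-based half-open on the contig
    end: int
    sequence: str
    intended_anchor: str  # chromosome id, decoy id, or "repeated"
    extra_loci: tuple[tuple[str, int, int], ...] = ()  # further (contig, s, e) copies
    in_centromere: bool = False

    @property
    def loci(self) -> tuple[tuple[str, int, int], ...]:
        return ((self.contig_id, self.start, self.end),) + self.extra_loci


@dataclass
class DesignedVariant:
    key: VariantKey
    fate: str  # lost | gained_on_chrom | gained_on_ns | both
    freq: float
    carriers: tuple[int, ...]  # sample indices drawn at `freq`
    contradicted: tuple[int, ...] = ()  # samples where a lost variant is also
    # written to the extended-reference VCF (turning it into Both there)


@dataclass
class TruthSet:
    """Simulator ground truth used as the test oracle."""

    implanted_segments: list[ImplantRecord] = field(default_factory=list)
    designed_variants: list[DesignedVariant] = field(default_factory=list)
    centromere_intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def validate(self) -> None:
        seen: dict[VariantKey, str] = {}
        for dv in self.designed_variants:
            if dv.key in seen:
                raise ValidationError(f"variant {dv.key} designed with two fates")
            seen[dv.key] = dv.fate


def _rng(config: SimulationConfig, *streams: int) -> np.random.Generator:
    return np.random.default_rng([config.seed % (2**31), *streams])


def _donor_stream(donor_id: str) -> int:
    return zlib.crc32(donor_id.encode()) % (2**31)


def random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    at = (1.0 - gc) / 2.0
    arr = rng.choice(_BASES, size=length, p=[at, gc / 2.0, gc / 2.0, at])
    return arr.tobytes().decode()


def tandem_array(rng: np.random.Generator, total_len: int, unit_len: int, gc: float) -> str:
    """A satellite-like tandem array: one random unit repeated to total_len."""
    unit = random_sequence(rng, min(unit_len, total_len), gc)
    reps = math.ceil(total_len / len(unit))
    return (unit * reps)[:total_len]


def mutate_sequence(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Apply i.i.d. substitutions at `rate` per base (never to the same base)."""
    if rate <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    if len(hits):
        idx = _BASE_INDEX[arr[hits].view(np.uint8)]
        shift = rng.integers(1, 4, size=len(hits))
        arr[hits] = _BASES[(idx + shift) % 4]
    return arr.tobytes().decode()


def gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq) if seq else 0.0


# ---------------------------------------------------------------------------
# reference
# ---------------------------------------------------------------------------

def simulate_reference(
    config: SimulationConfig,
) -> tuple[dict[str, str], dict[str, list[tuple[int, int]]], str]:
    """Simulate the reference: chromosomes, a centered centromere mask per
    chromosome, and one decoy sequence.  Byte-deterministic given the seed."""
    config.validate()
    rng = _rng(config, 0)
    reference: dict[str, str] = {}
    centromeres: dict[str, list[tuple[int, int]]] = {}
    for c in range(config.n_chromosomes):
        name = f"chr{c + 1}"
        reference[name] = random_sequence(rng, config.chrom_length, config.background_gc)
        cen_len = int(config.centromere_fraction * config.chrom_length)
        if cen_len > 0:
            start = (config.chrom_length - cen_len) // 2
            centromeres[name] = [(start, start + cen_len)]
        else:
            centromeres[name] = []
    reference[DECOY_ID] = random_sequence(rng, config.decoy_length, config.background_gc)
    return reference, centromeres, DECOY_ID


# ---------------------------------------------------------------------------
# donor assembly
# ---------------------------------------------------------------------------

_IMPLANT_MARGIN = 10_000  # implants stay this far from source-sequence ends
_IMPLANT_SPACING = 5_000  # minimum distance between insertion points
_BREAK_PAD = 200  # contig breaks keep this distance from implant bounds


def _place_positions(rng, length, count, margin, spacing, within=None):
    """Draw `count` insertion points, pairwise >= spacing apart.

    Points fall within [margin, length - margin) or inside `within`.
    """
    lo, hi = (margin, length - margin) if within is None else within
    if hi <= lo:
        raise ConfigError(
            f"sequence of length {length} too short for implants with margin {margin}"
        )
    chosen: list[int] = []
    for _ in range(10_000):
        if len(chosen) == count:
            break
        p = int(rng.integers(lo, hi))
        if all(abs(p - q) >= spacing for q in chosen):
            chosen.append(p)
    if len(chosen) < count:
        raise ConfigError(f"could not place {count} implants in {length} bp")
    return chosen


def simulate_assembly(
    reference: Mapping[str, str],
    config: SimulationConfig,
    donor_id: str,
    centromeres: Optional[Mapping[str, Sequence[tuple[int, int]]]] = None,
    decoy_id: str = DECOY_ID,
) -> tuple[list[Contig], TruthSet]:
    """Simulate one donor assembly: a substitution-diverged copy of the
    reference carrying implanted tandem-repeat segments, fragmented into
    contigs of at least ``min_contig_len`` bases.

    Special implants (when ``n_novel_segments`` allows): one is implanted at
    two distinct loci on different chromosomes (anchoring's "multiple" case),
    one inside the centromere mask, and — if ``include_decoy_implant`` — one
    in the decoy-derived sequence.  Contig breaks never fall inside implants,
    so each truth locus lies on a single contig.
    """
    config.validate()
    if config.novel_length_range[1] > config.chrom_length:
        raise ConfigError("novel_length_range max exceeds chrom_length")
    if centromeres is None:
        _, centromeres, _ = simulate_reference(config)
    rng = _rng(config, 1, _donor_stream(donor_id))
    chroms = [n for n in reference if n != decoy_id]

    # 1) plan implants -------------------------------------------------------
    n = config.n_novel_segments
    implants = []  # (sequence, [(source, insertion point), ...], anchor, in_cen)
    if n > 0:
        lo, hi = config.novel_length_range
        ulo, uhi = config.tandem_unit_range
        seqs = [
            tandem_array(
                rng,
                int(rng.integers(lo, hi + 1)),
                int(rng.integers(ulo, uhi + 1)),
                config.novel_gc_target,
            )
            for _ in range(n)
        ]
        # most-constrained placements first so rejection sampling cannot be
        # boxed out of its window by an earlier implant
        roles: list[tuple[str, Optional[str]]] = []
        if n > 1 and any(centromeres.get(c) for c in chroms):
            roles.append(("centromeric", None))
        roles.append(("repeated", None))
        if n > len(roles) and config.include_decoy_implant and decoy_id in reference:
            roles.append(("decoy", None))
        while len(roles) < n:
            roles.append(("plain", None))

        taken: dict[str, list[int]] = {src: [] for src in reference}

        def pick(source, within=None):
            pts = _place_positions(
                rng, len(reference[source]), 1, _IMPLANT_MARGIN, 1, within=within
            )
            for _ in range(1000):
                p = pts[0]
                if all(abs(p - q) >= _IMPLANT_SPACING for q in taken[source]):
                    taken[source].append(p)
                    return p
                pts = _place_positions(
                    rng, len(reference[source]), 1, _IMPLANT_MARGIN, 1, within=within
                )
            raise ConfigError(f"could not space implants on {source}")

        for i, (role, _) in enumerate(roles):
            seq = seqs[i]
            if role == "repeated":
                srcs = chroms[:2] if len(chroms) >= 2 else [chroms[0], chroms[0]]
                loci = [(s, pick(s)) for s in srcs]
                implants.append((seq, loci, "repeated", False))
            elif role == "centromeric":
                src = next(c for c in chroms if centromeres.get(c))
                cs, ce = centromeres[src][0]
                pad = min((ce - cs) // 4, 1000)
                p = pick(src, within=(cs + pad, ce - pad))
                implants.append((seq, [(src, p)], src, True))
            elif role == "decoy":
                p = pick(decoy_id)
                implants.append((seq, [(decoy_id, p)], decoy_id, False))
            else:
                src = chroms[int(rng.integers(0, len(chroms)))]
                p = pick(src)
                implants.append((seq, [(src, p)], src, False))

    # 2) build donor sequences ----------------------------------------------
    donor_seqs: dict[str, str] = {}
    spans: dict[str, list[tuple[int, int, int]]] = {src: [] for src in reference}
    for src in reference:
        backbone = mutate_sequence(reference[src], config.divergence_rate, rng)
        points = []  # (ref position, implant index)
        for i, (_, loci, _, _) in enumerate(implants):
            for s, p in loci:
                if s == src:
                    points.append((p, i))
        points.sort()
        pieces, cursor, offset = [], 0, 0
        for p, i in points:
            pieces.append(backbone[cursor:p])
            seq = implants[i][0]
            spans[src].append((p + offset, p + offset + len(seq), i))
            pieces.append(seq)
            offset += len(seq)
            cursor = p
        pieces.append(backbone[cursor:])
        donor_seqs[src] = "".join(pieces)

    # 3) fragment into contigs ----------------------------------------------
    contigs: list[Contig] = []
    locus_map: dict[int, list[tuple[str, int, int]]] = {i: [] for i in range(len(implants))}
    serial = 0
    for src in reference:
        seq = donor_seqs[src]
        L = len(seq)
        raw_breaks = np.nonzero(rng.random(L) < config.contig_break_rate)[0]
        cuts, last = [], 0
        for b in sorted(int(x) for x in raw_breaks):
            if b - last < config.min_contig_len or L - b < config.min_contig_len:
                continue
            if any(s - _BREAK_PAD <= b < e + _BREAK_PAD for s, e, _ in spans[src]):
                continue
            cuts.append(b)
            last = b
        bounds = [0] + cuts + [L]
        for a, b in zip(bounds, bounds[1:]):
            serial += 1
            cid = f"{donor_id}_ctg{serial:04d}"
            contigs.append(Contig(cid, donor_id, src, a, seq[a:b]))
            for s, e, i in spans[src]:
                if a <= s and e <= b:
                    locus_map[i].append((cid, s - a, e - a))

    # 4) truth records -------------------------------------------------------
    truth = TruthSet(centromere_intervals={c: list(v) for c, v in centromeres.items()})
    for i, (seq, loci, anchor, in_cen) in enumerate(implants):
        placed = locus_map[i]
        if len(placed) != len(loci):
            raise RuntimeError("implant locus lost during fragmentation")  # pragma: no cover
        cid, s, e = placed[0]
        truth.implanted_segments.append(
            ImplantRecord(
                donor_id=donor_id,
                contig_id=cid,
                start=s,
                end=e,
                sequence=seq,
                intended_anchor=anchor,
                extra_loci=tuple(placed[1:]),
                in_centromere=in_cen,
            )
        )
    return contigs, truth


def contigs_to_dict(contigs: Sequence[Contig]) -> dict[str, str]:
    return {c.contig_id: c.sequence for c in contigs}


# ---------------------------------------------------------------------------
# scaffolds
# ---------------------------------------------------------------------------

SCAFFOLD_GAP = 100  # N bases between joined contigs


def simulate_scaffolds(
    contigs: Sequence[Contig],
) -> tuple[dict[str, str], dict[str, str]]:
    """Join contigs of each source sequence, in order, with 100-N gaps.

    Returns (scaffold sequences, scaffold -> source-chromosome truth).
    """
    groups: dict[tuple[str, str], list[Contig]] = {}
    for c in contigs:
        groups.setdefault((c.donor_id, c.source), []).append(c)
    scaffolds: dict[str, str] = {}
    truth: dict[str, str] = {}
    for (donor, source), members in groups.items():
        members.sort(key=lambda c: c.source_start)
        name = f"scaf_{donor}_{source}"
        scaffolds[name] = ("N" * SCAFFOLD_GAP).join(c.sequence for c in members)
        truth[name] = source
    return scaffolds, truth


# ---------------------------------------------------------------------------
# cohort VCFs
# ---------------------------------------------------------------------------

@dataclass
class CohortDesign:
    sample_ids: list[str]
    designed: list[DesignedVariant]
    noise: dict[str, frozenset]  # sample -> private VariantKeys present in both files
    base_contigs: dict[str, int]  # contig -> length, base reference
    ext_contigs: dict[str, int]  # contig -> length, extended reference


def _draw_carriers(rng: np.random.Generator, cohort_size: int, freq: float) -> tuple[int, ...]:
    """Each sample carries the variant independently with probability freq."""
    return tuple(int(i) for i in np.nonzero(rng.random(cohort_size) < freq)[0])


def design_cohort(
    truth: TruthSet,
    config: SimulationConfig,
    reference: Mapping[str, str],
    ns_seqs: Mapping[str, str],
    decoy_id: str = DECOY_ID,
) -> CohortDesign:
    """Design the cohort's variant fates and realize per-sample carriers.

    Fates partition the designed variants: ``lost`` variants appear only in
    the base-reference call set, ``gained_on_chrom`` / ``gained_on_ns`` only
    in the extended one, ``both`` in both.  The first lost variant is placed
    inside the centromere mask (frequency 1.0) and ``n_contradicted_lost``
    lost variants (frequency 1.0) are additionally written to the extended
    VCF of sample 0, so that the cohort-consistency "never seen as Gained or
    Both" exclusion always has a positive test case.  Populates
    ``truth.designed_variants``.
    """
    config.validate()
    rng = _rng(config, 2)
    chroms = [c for c in reference if c != decoy_id]
    if not chroms:
        raise ConfigError("reference has no chromosomes to place variants on")
    samples = [f"sample{i:03d}" for i in range(config.cohort_size)]
    used: set[tuple[str, int]] = set()

    def draw_site(contigs: Mapping[str, str], names: Sequence[str], within=None):
        for _ in range(100_000):
            name = names[int(rng.integers(0, len(names)))]
            if within is not None:
                lo, hi = within
            else:
                lo, hi = 0, len(contigs[name])
            pos = int(rng.integers(lo, hi)) + 1  # 1-based
            if (name, pos) in used:
                continue
            ref_base = contigs[name][pos - 1]
            if ref_base not in "ACGT":
                continue
            used.add((name, pos))
            alts = [b for b in "ACGT" if b != ref_base]
            return VariantKey(name, pos, ref_base, alts[int(rng.integers(0, 3))])
        raise ConfigError("could not place designed variants without collisions")

    def freq() -> float:
        lo, hi = config.cohort_freq_range
        return float(rng.uniform(lo, hi))

    designed: list[DesignedVariant] = []

    n_ns = 0
    if ns_seqs:
        n_ns = config.n_gained_designed // 2
    n_chrom_gain = config.n_gained_designed - n_ns

    for i in range(config.n_lost_designed):
        if i == 0 and any(truth.centromere_intervals.get(c) for c in chroms):
            cen_chrom = next(c for c in chroms if truth.centromere_intervals.get(c))
            key = draw_site(reference, [cen_chrom], within=truth.centromere_intervals[cen_chrom][0])
            f = 1.0
        elif 0 < i <= config.n_contradicted_lost:
            key, f = draw_site(reference, chroms), 1.0
        else:
            key, f = draw_site(reference, chroms), freq()
        contradicted = (0,) if 0 < i <= config.n_contradicted_lost else ()
        designed.append(
            DesignedVariant(key, "lost", f, _draw_carriers(rng, config.cohort_size, f), contradicted)
        )
    for _ in range(n_chrom_gain):
        f = freq()
        designed.append(
            DesignedVariant(draw_site(reference, chroms), "gained_on_chrom", f,
                            _draw_carriers(rng, config.cohort_size, f))
        )
    ns_names = list(ns_seqs)
    for _ in range(n_ns):
        f = freq()
        designed.append(
            DesignedVariant(draw_site(ns_seqs, ns_names), "gained_on_ns", f,
                            _draw_carriers(rng, config.cohort_size, f))
        )
    for _ in range(config.n_both_designed):
        f = freq()
        designed.append(
            DesignedVariant(draw_site(reference, chroms), "both", f,
                            _draw_carriers(rng, config.cohort_size, f))
        )

    noise: dict[str, frozenset] = {}
    for s in samples:
        keys = frozenset(
            draw_site(reference, chroms) for _ in range(config.noise_variants_per_sample)
        )
        noise[s] = keys

    truth.designed_variants = designed
    truth.validate()
    base_contigs = {name: len(seq) for name, seq in reference.items()}
    ext_contigs = dict(base_contigs, **{name: len(seq) for name, seq in ns_seqs.items()})
    return CohortDesign(samples, designed, noise, base_contigs, ext_contigs)


def expected_sample_classes(design: CohortDesign, sample_index: int):
    """The designed per-sample Lost/Both/Gained sets — the oracle used by tests.

    Returns (lost, both, gained_on_chrom, gained_on_ns) VariantKey sets for
    one sample, derived purely from the design (carriers, fates, noise and
    the contradicted-sample tweak), independent of the classifier under test.
    """
    sample = design.sample_ids[sample_index]
    lost, both, g_chrom, g_ns = set(), set(), set(), set()
    for dv in design.designed:
        if sample_index not in dv.carriers:
            continue
        if dv.fate == "lost":
            (both if sample_index in dv.contradicted else lost).add(dv.key)
        elif dv.fate == "both":
            both.add(dv.key)
        elif dv.fate == "gained_on_chrom":
            g_chrom.add(dv.key)
        else:
            g_ns.add(dv.key)
    both |= design.noise[sample]
    return lost, both, g_chrom, g_ns


def _write_vcf(path, contigs: Mapping[str, int], sample: str, keys) -> None:
    order = {name: i for i, name in enumerate(contigs)}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for key in sorted(keys, key=lambda k: (order[k.contig], k.pos, k.alt)):
            fh.write(
                f"{key.contig}\t{key.pos}\t.\t{key.ref}\t{key.alt}\t.\tPASS\t.\tGT\t0/1\n"
            )


def write_cohort_vcfs(design: CohortDesign, outdir) -> dict[str, tuple[str, str]]:
    """Write one (base, extended) VCF pair per sample.  Returns the paths."""
    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, tuple[str, str]] = {}
    for i, sample in enumerate(design.sample_ids):
        lost, both, g_chrom, g_ns = expected_sample_classes(design, i)
        base_keys = lost | both
        ext_keys = both | g_chrom | g_ns
        base_path = os.path.join(outdir, f"{sample}.base.vcf")
        ext_path = os.path.join(outdir, f"{sample}.ext.vcf")
        _write_vcf(base_path, design.base_contigs, sample, base_keys)
        _write_vcf(ext_path, design.ext_contigs, sample, ext_keys)
        paths[sample] = (base_path, ext_path)
    return paths


def simulate_cohort_vcfs(
    truth: TruthSet,
    config: SimulationConfig,
    reference: Mapping[str, str],
    ns_seqs: Mapping[str, str],
    outdir,
    decoy_id: str = DECOY_ID,
) -> tuple[CohortDesign, dict[str, tuple[str, str]]]:
    """Design the cohort's variant fates (recorded on ``truth``) and write
    per-sample paired VCFs under ``outdir``."""
    design = design_cohort(truth, config, reference, ns_seqs, decoy_id=decoy_id)
    return design, write_cohort_vcfs(design, outdir)
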