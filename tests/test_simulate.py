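"""The synthetic-data generator: determinism, sequence composition, implant
bookkeeping, scaffolding conservation, and cohort VCF fates."""

import dataclasses

import numpy as np
import pytest

from refgap.errors import ConfigError
from refgap.reconcile import VariantKey
from refgap.simulate import (
    DECOY_ID,
    SimulationConfig,
    TruthSet,
    _draw_carriers,
    contigs_to_dict,
    design_cohort,
    expected_sample_classes,
    gc_fraction,
    random_sequence,
    simulate_assembly,
    simulate_cohort_vcfs,
    simulate_reference,
    simulate_scaffolds,
    tandem_array,
)

SMALL = SimulationConfig(
    seed=5, n_chromosomes=2, chrom_length=80_000, n_novel_segments=4,
    novel_length_range=(500, 4_000), min_contig_len=15_000, cohort_size=8,
    n_lost_designed=20, n_gained_designed=20, n_both_designed=20,
)


def test_config_validation_names_field():
    with pytest.raises(ConfigError, match="cohort_size"):
        SimulationConfig(cohort_size=0).validate()
    with pytest.raises(ConfigError, match="background_gc"):
        SimulationConfig(background_gc=1.5).validate()
    with pytest.raises(ConfigError, match="novel_length_range"):
        SimulationConfig(chrom_length=5_000, novel_length_range=(500, 10_000)).validate()


def test_reference_shape_and_determinism():
    cfg = SimulationConfig(seed=1, n_chromosomes=2, chrom_length=50_000)
    ref1, cen1, decoy = simulate_reference(cfg)
    ref2, cen2, _ = simulate_reference(cfg)
    assert list(ref1) == ["chr1", "chr2", DECOY_ID]
    assert all(len(ref1[c]) == 50_000 for c in ("chr1", "chr2"))
    assert len(ref1[decoy]) == cfg.decoy_length
    assert ref1 == ref2 and cen1 == cen2  # byte-identical under a fixed seed


def test_zero_centromere_fraction_gives_empty_mask():
    cfg = SimulationConfig(seed=1, centromere_fraction=0.0)
    _, cen, _ = simulate_reference(cfg)
    assert all(ivs == [] for ivs in cen.values())


def test_background_gc_matches_target():
    cfg = SimulationConfig(seed=2, n_chromosomes=1, chrom_length=500_000, background_gc=0.40)
    ref, _, _ = simulate_reference(cfg)
    assert gc_fraction(ref["chr1"]) == pytest.approx(0.40, abs=0.01)


def test_no_implants_empty_truth():
    cfg = dataclasses.replace(SMALL, n_novel_segments=0)
    ref, cen, decoy = simulate_reference(cfg)
    contigs, truth = simulate_assembly(ref, cfg, "d", cen, decoy)
    assert truth.implanted_segments == []
    # fragmentation conserves the donor genome base count
    total = sum(c.length for c in contigs)
    assert total == sum(len(s) for s in ref.values())


def test_implant_bookkeeping_five_records_one_repeated():
    cfg = dataclasses.replace(SMALL, n_novel_segments=5)
    ref, cen, decoy = simulate_reference(cfg)
    contigs, truth = simulate_assembly(ref, cfg, "d", cen, decoy)
    assert len(truth.implanted_segments) == 5
    repeated = [r for r in truth.implanted_segments if r.intended_anchor == "repeated"]
    assert len(repeated) == 1
    assert len(repeated[0].loci) == 2
    assert sum(r.in_centromere for r in truth.implanted_segments) == 1
    # every locus lies on a single contig and spells the implant sequence
    cd = contigs_to_dict(contigs)
    for rec in truth.implanted_segments:
        for cid, s, e in rec.loci:
            assert cd[cid][s:e] == rec.sequence


def test_implant_low_identity_to_reference_by_alignment_oracle(rng):
    """Whole-segment identity of an implant against every reference window
    stays below the 0.80 novelty ceiling (independent edlib infix-alignment
    oracle: identity <= 1 - edit_distance / segment_length)."""
    import edlib

    cfg = SimulationConfig(seed=9, n_chromosomes=1, chrom_length=3_000,
                           decoy_length=500, n_novel_segments=0,
                           novel_length_range=(100, 200),
                           centromere_fraction=0.0, min_contig_len=1_000)
    ref, _, _ = simulate_reference(cfg)
    for trial in range(5):
        segment = tandem_array(rng, 150, 40, cfg.novel_gc_target)
        for target in ref.values():
            res = edlib.align(segment, target, mode="HW", task="distance")
            identity_bound = 1.0 - res["editDistance"] / len(segment)
            assert identity_bound < 0.80


def test_assembly_determinism():
    ref, cen, decoy = simulate_reference(SMALL)
    a = simulate_assembly(ref, SMALL, "d", cen, decoy)
    b = simulate_assembly(ref, SMALL, "d", cen, decoy)
    assert contigs_to_dict(a[0]) == contigs_to_dict(b[0])


class TestScaffolds:
    def test_one_contig_per_chromosome_identity(self):
        cfg = dataclasses.replace(SMALL, contig_break_rate=0.0)
        ref, cen, decoy = simulate_reference(cfg)
        contigs, _ = simulate_assembly(ref, cfg, "d", cen, decoy)
        scaffolds, truth = simulate_scaffolds(contigs)
        assert sorted(scaffolds.values()) == sorted(c.sequence for c in contigs)
        assert set(truth.values()) == set(ref)

    def test_base_count_conservation(self):
        ref, cen, decoy = simulate_reference(SMALL)
        contigs, _ = simulate_assembly(ref, SMALL, "d", cen, decoy)
        scaffolds, _ = simulate_scaffolds(contigs)
        by_source = {}
        for c in contigs:
            by_source.setdefault((c.donor_id, c.source), []).append(c)
        for (donor, source), members in by_source.items():
            scaf = scaffolds[f"scaf_{donor}_{source}"]
            assert len(scaf) == sum(c.length for c in members) + 100 * (len(members) - 1)

    def test_implants_occur_in_exactly_one_scaffold_unless_repeated(self):
        ref, cen, decoy = simulate_reference(SMALL)
        contigs, truth = simulate_assembly(ref, SMALL, "d", cen, decoy)
        scaffolds, _ = simulate_scaffolds(contigs)
        for rec in truth.implanted_segments:
            hits = sum(s.count(rec.sequence) for s in scaffolds.values())
            assert hits == (2 if rec.intended_anchor == "repeated" else 1)


class TestCohort:
    def _design(self, cfg, ns=None):
        ref, cen, decoy = simulate_reference(cfg)
        truth = TruthSet(centromere_intervals=cen)
        ns = ns if ns is not None else {"NS_d_0001": random_sequence(np.random.default_rng(1), 3000, 0.43)}
        return ref, cen, design_cohort(truth, cfg, ref, ns)

    def test_both_fate_at_full_frequency_everywhere(self):
        cfg = dataclasses.replace(SMALL, cohort_freq_range=(1.0, 1.0))
        _, _, design = self._design(cfg)
        for dv in design.designed:
            assert len(dv.carriers) == cfg.cohort_size
            for i in range(cfg.cohort_size):
                lost, both, g_chrom, g_ns = expected_sample_classes(design, i)
                if dv.fate == "both":
                    assert dv.key in both

    def test_lost_fate_only_in_base_files(self, tmp_path):
        cfg = SimulationConfig(
            seed=3, n_chromosomes=1, chrom_length=40_000, n_novel_segments=0,
            cohort_size=40, n_lost_designed=3, n_gained_designed=0,
            n_both_designed=0, cohort_freq_range=(1.0, 1.0),
            noise_variants_per_sample=0, n_contradicted_lost=0,
            centromere_fraction=0.0, min_contig_len=10_000,
        )
        ref, cen, decoy = simulate_reference(cfg)
        truth = TruthSet(centromere_intervals=cen)
        design, paths = simulate_cohort_vcfs(truth, cfg, ref, {}, tmp_path, decoy)
        assert len(paths) == 40
        lost_keys = {dv.key for dv in design.designed if dv.fate == "lost"}
        assert len(lost_keys) == 3
        for sample, (base, ext) in paths.items():
            base_text = open(base).read()
            ext_text = open(ext).read()
            for key in lost_keys:
                token = f"{key.contig}\t{key.pos}\t"
                assert token in base_text
                assert token not in ext_text

    def test_carrier_count_binomial_expectation(self):
        # 50 independent draws at freq 0.1 in a cohort of 200
        counts = [
            len(_draw_carriers(np.random.default_rng(seed), 200, 0.1))
            for seed in range(50)
        ]
        mean = np.mean(counts)
        # s.e. of the mean of Binomial(200, 0.1)/sqrt(50) ~ 0.6; allow 4 s.e.
        assert mean == pytest.approx(20.0, abs=2.5)

    def test_designed_fates_partition(self):
        _, _, design = self._design(SMALL)
        keys = [dv.key for dv in design.designed]
        assert len(keys) == len(set(keys))
        assert {dv.fate for dv in design.designed} <= {
            "lost", "gained_on_chrom", "gained_on_ns", "both"
        }

    def test_cohort_size_zero_rejected(self):
        with pytest.raises(ConfigError, match="cohort_size"):
            dataclasses.replace(SMALL, cohort_size=0).validate()

    def test_vcf_pairs_deterministic(self, tmp_path):
        ref, cen, decoy = simulate_reference(SMALL)
        ns = {"NS_d_0001": random_sequence(np.random.default_rng(1), 3000, 0.43)}
        _, p1 = simulate_cohort_vcfs(TruthSet(centromere_intervals=cen), SMALL, ref, ns, tmp_path / "a", decoy)
        _, p2 = simulate_cohort_vcfs(TruthSet(centromere_intervals=cen), SMALL, ref, ns, tmp_path / "b", decoy)
        for sample in p1:
            for x, y in zip(p1[sample], p2[sample]):
                assert open(x).read() == open(y).read()
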