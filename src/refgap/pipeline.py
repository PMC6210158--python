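"""End-to-end pipeline: simulate -> discover -> extend -> anchor -> compare ->
reconcile, with a run manifest capturing parameters, record counts and output
digests so that identical configurations reproduce byte-identical outputs."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from typing import Mapping, Optional

import pandas as pd

from . import __version__
from .alignment import RELAXED, STRICT, AlignParams
from .anchoring import anchor_ns, anchor_summary
from .compare import classify_sharing, sharing_base_totals
from .discovery import deduplicate, filter_contigs, two_round_discovery
from .errors import ConfigError
from .extend import appended_bases, build_extended
from .io import write_bed, write_fasta
from .reconcile import classify_sample, cohort_consistency, density_per_kb
from .simulate import (
    SimulationConfig,
    contigs_to_dict,
    simulate_assembly,
    simulate_cohort_vcfs,
    simulate_reference,
    simulate_scaffolds,
)

_TOP_KEYS = {"seed", "donors", "simulation", "discovery", "reconcile"}
_DISCOVERY_KEYS = {"min_contig_len", "min_len", "max_identity",
                   "strict", "relaxed", "containment_frac", "dup_identity"}
_RECONCILE_KEYS = {"min_frac"}


def config_hash(config: Mapping) -> str:
    """Hash of the configuration, stable under key reordering."""
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _params(d: Optional[Mapping], default: AlignParams) -> AlignParams:
    if not d:
        return default
    return AlignParams(
        d.get("min_match_len", default.min_match_len),
        d.get("min_cluster_len", default.min_cluster_len),
        d.get("max_seed_gap", default.max_seed_gap),
    )


def validate_config(config: Mapping) -> None:
    for key in config:
        if key not in _TOP_KEYS:
            raise ConfigError(f"unknown configuration key {key!r}")
    for key in config.get("discovery", {}) or {}:
        if key not in _DISCOVERY_KEYS:
            raise ConfigError(f"unknown configuration key discovery.{key!r}")
    for key in config.get("reconcile", {}) or {}:
        if key not in _RECONCILE_KEYS:
            raise ConfigError(f"unknown configuration key reconcile.{key!r}")
    sim_fields = {f.name for f in dataclasses.fields(SimulationConfig)}
    for key in config.get("simulation", {}) or {}:
        if key not in sim_fields:
            raise ConfigError(f"unknown configuration key simulation.{key!r}")


def run_pipeline(config: Mapping, outdir, seed: Optional[int] = None) -> dict:
    """Run the full synthetic pipeline under ``outdir``; returns the manifest."""
    validate_config(config)
    sim_kwargs = dict(config.get("simulation", {}) or {})
    if seed is not None:
        sim_kwargs["seed"] = seed
    elif "seed" in config:
        sim_kwargs.setdefault("seed", config["seed"])
    for key in ("novel_length_range", "tandem_unit_range", "cohort_freq_range"):
        if key in sim_kwargs:
            sim_kwargs[key] = tuple(sim_kwargs[key])
    sim = SimulationConfig(**sim_kwargs)
    donors = list(config.get("donors", ["swe1", "swe2"]))
    disc = config.get("discovery", {}) or {}
    strict = _params(disc.get("strict"), STRICT)
    relaxed = _params(disc.get("relaxed"), RELAXED)
    min_contig = disc.get("min_contig_len", 20_000)
    min_len = disc.get("min_len", 100)
    max_identity = disc.get("max_identity", 0.80)
    min_frac = (config.get("reconcile", {}) or {}).get("min_frac", 0.05)

    os.makedirs(outdir, exist_ok=True)
    outputs: list[str] = []
    counts: dict = {}

    def emit_fasta(name, seqs):
        path = os.path.join(outdir, name)
        write_fasta(path, seqs)
        outputs.append(name)
        return path

    # simulate ---------------------------------------------------------------
    reference, centromeres, decoy_id = simulate_reference(sim)
    emit_fasta("reference.fa", reference)
    write_bed(os.path.join(outdir, "centromeres.bed"), centromeres)
    outputs.append("centromeres.bed")

    assemblies, scaffolds_by_donor, truths = {}, {}, {}
    for donor in donors:
        contigs, truth = simulate_assembly(reference, sim, donor, centromeres, decoy_id)
        scaffolds, _ = simulate_scaffolds(contigs)
        assemblies[donor] = contigs_to_dict(contigs)
        scaffolds_by_donor[donor] = scaffolds
        truths[donor] = truth
        emit_fasta(f"{donor}.contigs.fa", assemblies[donor])
        emit_fasta(f"{donor}.scaffolds.fa", scaffolds)
        rows = [
            {
                "donor": r.donor_id, "contig": r.contig_id, "start": r.start,
                "end": r.end, "intended_anchor": r.intended_anchor,
                "n_loci": len(r.loci), "in_centromere": r.in_centromere,
            }
            for r in truth.implanted_segments
        ]
        pd.DataFrame(rows).to_csv(os.path.join(outdir, f"{donor}.truth.tsv"), sep="\t", index=False)
        outputs.append(f"{donor}.truth.tsv")
    counts["contigs"] = {d: len(assemblies[d]) for d in donors}

    # discover ---------------------------------------------------------------
    ns_by_donor = {}
    for donor in donors:
        passing = filter_contigs(assemblies[donor], min_contig)
        raw_ns = two_round_discovery(
            passing, reference, strict, relaxed, min_len, max_identity, donor_id=donor
        )
        ns = deduplicate(raw_ns, disc.get("containment_frac", 0.8), disc.get("dup_identity", 0.9), relaxed)
        ns_by_donor[donor] = ns
        emit_fasta(f"{donor}.ns.fa", {n.ns_id: n.sequence for n in ns})
        pd.DataFrame(
            [
                {
                    "ns_id": n.ns_id, "contig": n.contig_id, "start": n.start, "end": n.end,
                    "origin": n.origin, "round": n.round_detected,
                    "best_ref_identity": round(n.best_ref_identity, 6),
                }
                for n in ns
            ]
        ).to_csv(os.path.join(outdir, f"{donor}.ns.tsv"), sep="\t", index=False)
        outputs.append(f"{donor}.ns.tsv")
    counts["novel_sequences"] = {d: len(ns_by_donor[d]) for d in donors}

    # extend -----------------------------------------------------------------
    extended, manifest_rows = build_extended(reference, [ns_by_donor[d] for d in donors])
    emit_fasta("extended_reference.fa", extended)
    pd.DataFrame(manifest_rows).to_csv(os.path.join(outdir, "extension_manifest.tsv"), sep="\t", index=False)
    outputs.append("extension_manifest.tsv")
    counts["appended_bases"] = appended_bases(manifest_rows)
    kept_ids = {r["ns_id"] for r in manifest_rows if r["kept"]}
    ns_seqs = {name: extended[name] for name in extended if name not in reference}

    # anchor + sharing -------------------------------------------------------
    anchor_rows, sharing_rows = [], []
    summary_matrices = {}
    for donor in donors:
        ns = ns_by_donor[donor]
        results = anchor_ns(ns, scaffolds_by_donor[donor], reference, {decoy_id}, relaxed, strict)
        panel = {d: assemblies[d] for d in donors if d != donor}
        calls = classify_sharing(ns, panel) if panel else []
        lengths = {n.ns_id: n.length for n in ns}
        if calls:
            matrix, totals = anchor_summary(results, calls, lengths)
            summary_matrices[donor] = {
                "matrix": matrix,
                "status_bases": totals,
                "sharing_bases": sharing_base_totals(calls, lengths),
            }
        for r in results:
            anchor_rows.append(
                {
                    "donor": donor, "ns_id": r.ns_id, "status": r.status,
                    "chromosomes": ",".join(sorted(r.chromosomes)),
                    "interval": "" if r.projected_interval is None
                    else f"{r.projected_interval[0]}:{r.projected_interval[1]}-{r.projected_interval[2]}",
                }
            )
        for c in calls:
            sharing_rows.append(
                {"donor": donor, "ns_id": c.ns_id, "found_in": ",".join(sorted(c.found_in)),
                 "category": c.category}
            )
    pd.DataFrame(anchor_rows).to_csv(os.path.join(outdir, "anchors.tsv"), sep="\t", index=False)
    pd.DataFrame(sharing_rows).to_csv(os.path.join(outdir, "sharing.tsv"), sep="\t", index=False)
    outputs += ["anchors.tsv", "sharing.tsv"]

    # cohort reconciliation --------------------------------------------------
    truth0 = truths[donors[0]]
    design, vcf_paths = simulate_cohort_vcfs(
        truth0, sim, reference, ns_seqs, os.path.join(outdir, "vcf"), decoy_id
    )
    primary = [c for c in reference if c != decoy_id]
    classifications = [
        classify_sample(base, ext, primary, list(ns_seqs), sample_id=s)
        for s, (base, ext) in vcf_paths.items()
    ]
    summary = cohort_consistency(classifications, min_frac=min_frac, centromeres=centromeres)
    ns_lengths_ext = {name: len(seq) for name, seq in ns_seqs.items()}
    all_gained_ns = set().union(*(c.gained_on_ns for c in classifications)) if classifications else set()
    density = density_per_kb(all_gained_ns, ns_lengths_ext) if ns_lengths_ext and all_gained_ns else 0.0
    counts["cohort"] = {
        "n_samples": summary.n_samples,
        "consistent_lost": len(summary.consistent_lost),
        "consistent_gained": len(summary.consistent_gained),
        "mean_lost_per_sample": sum(len(c.lost) for c in classifications) / len(classifications),
        "mean_gained_per_sample": sum(len(c.gained) for c in classifications) / len(classifications),
        "snvs_per_kb_ns": density,
    }

    run_summary = {
        "counts": counts,
        "per_donor": summary_matrices,
    }
    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump(run_summary, fh, indent=2, sort_keys=True)
    outputs.append("summary.json")

    manifest = {
        "tool": "refgap",
        "version": __version__,
        "seed": sim.seed,
        "config_hash": config_hash(dict(config)),
        "parameters": {
            "simulation": dataclasses.asdict(sim),
            "strict": dataclasses.asdict(strict),
            "relaxed": dataclasses.asdict(relaxed),
            "min_contig_len": min_contig,
            "min_len": min_len,
            "max_identity": max_identity,
            "min_frac": min_frac,
        },
        "counts": counts,
        "outputs": {name: _digest(os.path.join(outdir, name)) for name in outputs},
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
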