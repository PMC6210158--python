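"""Shared fixtures: a session-scoped synthetic world at the default study
conditions (two donors, two 200 kb chromosomes + decoy, eight implants each),
reused by discovery, anchoring and acceptance tests."""

import numpy as np
import pytest

from refgap.discovery import deduplicate, filter_contigs, two_round_discovery
from refgap.simulate import (
    SimulationConfig,
    contigs_to_dict,
    simulate_assembly,
    simulate_reference,
    simulate_scaffolds,
)


@pytest.fixture(scope="session")
def acc_config():
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def acc_world(acc_config):
    reference, centromeres, decoy = simulate_reference(acc_config)
    donors = {}
    for donor in ("swe1", "swe2"):
        contigs, truth = simulate_assembly(reference, acc_config, donor, centromeres, decoy)
        scaffolds, scaffold_truth = simulate_scaffolds(contigs)
        contig_dict = contigs_to_dict(contigs)
        raw_ns = two_round_discovery(
            filter_contigs(contig_dict), reference, donor_id=donor
        )
        donors[donor] = {
            "contigs": contig_dict,
            "truth": truth,
            "scaffolds": scaffolds,
            "scaffold_truth": scaffold_truth,
            "raw_ns": raw_ns,
            "ns": deduplicate(raw_ns),
        }
    return {
        "config": acc_config,
        "reference": reference,
        "centromeres": centromeres,
        "decoy": decoy,
        "donors": donors,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)
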