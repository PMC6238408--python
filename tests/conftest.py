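"""Shared fixtures: one small synthetic study reused across test modules."""

from __future__ import annotations

import sys
from dataclasses import dataclass
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # local oracle helpers

from mirapex import discovery, preprocess, synthetic


@dataclass
class PipelineRun:
    cfg: synthetic.SimulationConfig
    bundle: synthetic.ReferenceBundle
    reads: dict
    clean: dict[str, list[str]]
    stats: dict
    tags: list
    flagged: list
    records: list
    calls: list


def _run_pipeline(cfg: synthetic.SimulationConfig) -> PipelineRun:
    bundle = synthetic.simulate_reference(cfg)
    reads = synthetic.simulate_srna_reads(bundle, cfg)
    clean, stats = {}, {}
    for sample, recs in reads.items():
        c, st = preprocess.trim_and_filter(recs, cfg.adapter)
        clean[sample], stats[sample] = c, st
    tags = preprocess.collapse_tags(clean)
    preprocess.annotate_tags(tags, bundle.genome, bundle.features)
    flagged = preprocess.discovery_tags(tags)
    records, calls = discovery.discover(flagged, bundle.genome)
    return PipelineRun(cfg, bundle, reads, clean, stats, tags, flagged,
                       records, calls)


@pytest.fixture(scope="session")
def small_cfg() -> synthetic.SimulationConfig:
    return synthetic.SimulationConfig(seed=11, n_hairpins=8, n_decoy_loci=8,
                                      background_read_count=600)


@pytest.fixture(scope="session")
def small_run(small_cfg) -> PipelineRun:
    """Synthetic bundle plus a full preprocess+discovery pass over it."""
    return _run_pipeline(small_cfg)
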