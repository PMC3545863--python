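"""Shared fixtures: one small error-free simulated experiment, run once per
session through mapping, pileup genotyping and filtering."""

from __future__ import annotations

from dataclasses import dataclass

import pytest

import capsimark as cm
from capsimark import snp_discovery as snp

#: seed chosen so the small simulation exercises every planted feature kind
#: (clean SNPs, junction/adjacency/het violators, isolated hets, SSRs)
FIXTURE_SEED = 14


@pytest.fixture(scope="session")
def sim_config() -> cm.SimConfig:
    return cm.SimConfig(n_genes=12, seed=FIXTURE_SEED, error_rate=0.0)


@pytest.fixture(scope="session")
def truth(sim_config) -> cm.TruthSet:
    return cm.simulate_truth(sim_config)


@pytest.fixture(scope="session")
def sim_reads(truth, sim_config):
    return cm.simulate_reads(truth, sim_config)


@dataclass
class CalledSet:
    truth: cm.TruthSet
    pileup: snp.Pileup
    candidates: list
    het_track: list
    kept: list
    flagged: list


@pytest.fixture(scope="session")
def called(truth, sim_reads, sim_config) -> CalledSet:
    alignments = []
    for g, lst in sim_reads.items():
        alignments.extend(cm.naive_map(lst, truth.contigs, g))
    pile = snp.build_pileup(alignments, truth.contigs,
                            genotypes=list(sim_config.genotype_names))
    rows = snp.genotype_rows(pile, truth.contigs)
    candidates, het_track = snp.call_iga_snps(rows)
    kept, flagged = snp.filter_iga_snps(candidates, het_track, truth.junctions)
    return CalledSet(truth, pile, candidates, het_track, kept, flagged)
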