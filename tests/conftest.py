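"""Shared fixtures: seeded synthetic datasets and brute-force oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

import pavpedigree as pp
from pavpedigree.simulate import CallerNoise, SimConfig, TraitSpec


# --------------------------------------------------------------------------
# brute-force oracles (kept independent of the implementation code paths)
# --------------------------------------------------------------------------

def brute_force_clusters(calls, min_ro=0.5):
    """All-pairs reciprocal-overlap graph + connected components.

    Independent merging oracle: quadratic over every pair, transitive
    closure by repeated sweeps. Returns a set of frozensets of calls.
    """
    n = len(calls)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for i, j in itertools.combinations(range(n), 2):
        fa, fb = pp.reciprocal_overlap(calls[i], calls[j])
        if fa > min_ro and fb > min_ro:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[max(ri, rj)] = min(ri, rj)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(calls[i])
    return {frozenset(g) for g in groups.values()}


def welch_p(x, y):
    from scipy import stats

    return float(stats.ttest_ind(x, y, equal_var=False)[1])


# --------------------------------------------------------------------------
# datasets
# --------------------------------------------------------------------------

@pytest.fixture(scope="session")
def planted_design():
    """The planted recovery design: 30 functional among 2000 segments,
    400 cultivars, 1-SD effects — with phenotypes and expression."""
    cfg = SimConfig(
        seed=11, n_segments=2000, n_population=400, n_functional=30,
        fp_planted=0,
    )
    sim = pp.simulate_segments(cfg)
    phenos = pp.simulate_phenotypes(sim.matrix, sim.truth, cfg)
    expr = pp.simulate_expression(sim.matrix, sim.truth, cfg)
    return cfg, sim, phenos, expr


@pytest.fixture(scope="session")
def noiseless_sim():
    """Small pedigree simulation with noise-free callers."""
    cfg = SimConfig(
        seed=2, n_segments=300, n_population=50, n_functional=5,
        fp_planted=3, caller_noise=CallerNoise(0.0, 0.0, 0.0),
    )
    sim = pp.simulate_segments(cfg)
    return cfg, sim


@pytest.fixture(scope="session")
def noiseless_consensus(noiseless_sim):
    cfg, sim = noiseless_sim
    calls = pp.simulate_caller_calls(sim.truth, sim.matrix, cfg)
    cons = {
        s: pp.intersect_callers(calls["caller1"][s], calls["caller2"][s])
        for s in sim.matrix.pedigree_samples
    }
    roles = {
        s: sim.matrix.roles[s]
        for s in sim.matrix.samples_with_role(
            "reference", "parent1", "parent2", "progeny"
        )
    }
    records, matrix = pp.merge_nonredundant(cons, roles)
    return records, matrix


@pytest.fixture(scope="session")
def fps_design():
    """Default-size cohort (733 cultivars) with 30 planted fingerprint
    segments and noise-free callers."""
    cfg = SimConfig(
        seed=9, n_segments=800, n_functional=20, fp_planted=30,
        caller_noise=CallerNoise(0.0, 0.0, 0.0),
    )
    sim = pp.simulate_segments(cfg)
    return cfg, sim


def truth_by_locus(sim):
    """Map (chrom, pos, svtype) -> truth segment id."""
    t = sim.truth.segments
    return {
        (c, p, s): i
        for c, p, s, i in zip(t["chrom"], t["pos"], t["svtype"], t["id"])
    }
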