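"""Shared fixtures: toy databases plus session-scoped simulated benchmarks."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from taxomass.inference import ProteinGroup
from taxomass.seqdb import (
    DigestParams,
    ProteinRecord,
    TaxonNode,
    TaxonomyTree,
    build_peptide_index,
    generate_decoys,
)
from taxomass.simulate import SimulationConfig, uneven_community


# ---------------------------------------------------------------------------
# independent oracles (plain-loop implementations kept deliberately separate
# from the library code they check)


def brute_force_fdr_accept(scores, is_decoy, threshold):
    """Best prefix of the (descending-score, decoys-first) ranking whose
    monotonized empirical FDR is <= threshold; returns accepted target
    positions."""
    order = sorted(
        range(len(scores)), key=lambda i: (-scores[i], 0 if is_decoy[i] else 1)
    )
    fdrs = []
    d = t = 0
    for i in order:
        if is_decoy[i]:
            d += 1
        else:
            t += 1
        fdrs.append(d / max(1, t))
    qs = list(fdrs)
    for k in range(len(qs) - 2, -1, -1):
        qs[k] = min(qs[k], qs[k + 1])
    accepted = set()
    for pos, i in enumerate(order):
        if qs[pos] <= threshold and not is_decoy[i]:
            accepted.add(i)
    return accepted, qs, order


def brute_force_fido(groups, peptide_probs, alpha, beta, gamma):
    """Exact posteriors by explicit enumeration over presence vectors.

    *groups* is a mapping group_id -> iterable of observed peptide ids.
    """
    gids = sorted(groups)
    peps = sorted({p for ps in groups.values() for p in ps if p in peptide_probs})
    total = 0.0
    mass = {g: 0.0 for g in gids}
    for vector in itertools.product([0, 1], repeat=len(gids)):
        present = {g for g, v in zip(gids, vector) if v}
        prior = (gamma ** len(present)) * ((1 - gamma) ** (len(gids) - len(present)))
        lik = 1.0
        for p in peps:
            m = sum(1 for g in present if p in groups[g])
            p_emit = 1.0 - (1.0 - beta) * (1.0 - alpha) ** m
            obs = peptide_probs[p]
            lik *= (1.0 - obs) + obs * p_emit
        w = prior * lik
        total += w
        for g in present:
            mass[g] += w
    return {g: mass[g] / total for g in gids}


def make_group(gid, peptides, taxa=("t1",), decoy=False, members=None):
    members = tuple(members or (gid,))
    return ProteinGroup(
        gid, members, frozenset(peptides), gid, frozenset(taxa), decoy, members
    )


# ---------------------------------------------------------------------------
# toy database


@pytest.fixture()
def toy_proteins():
    tax = {"P1": "taxA", "P2": "taxA", "P3": "taxB"}
    seqs = {
        "P1": "MAGICPEPTIDEKSHAREDSEQRTINYBITK",
        "P2": "MAGICPEPTIDEKSHAREDSEQRDIFFERENTTAILK",
        "P3": "WHOLLYUNRELATEDSEQVENCEKANOTHERPARTR",
    }
    return [ProteinRecord(a, tax[a], s) for a, s in seqs.items()]


@pytest.fixture()
def toy_index(toy_proteins):
    db = toy_proteins + generate_decoys(toy_proteins)
    return build_peptide_index(db, DigestParams(missed_cleavages=1, min_len=4, max_len=50))


@pytest.fixture()
def toy_tree():
    return TaxonomyTree(
        [
            TaxonNode("d1", "Bacteria", "domain"),
            TaxonNode("g1", "GenusOne", "genus", "d1"),
            TaxonNode("taxA", "SpeciesA", "species", "g1"),
            TaxonNode("taxB", "SpeciesB", "species", "g1"),
        ]
    )


# ---------------------------------------------------------------------------
# session-scoped simulated benchmarks (shared across test modules to keep the
# suite fast; all seeded)


@pytest.fixture(scope="session")
def scenario_runs():
    from taxomass.benchmarks import scenario_pipelines

    # spectra budget proportionate to the scaled-down proteome sizes, so
    # per-protein coverage spans the detection limit as in real acquisitions
    return scenario_pipelines(SimulationConfig(seed=11, n_ms2=6_000))


@pytest.fixture(scope="session")
def uneven_benchmark():
    """Uneven 30-member community at the full single-run spectra budget."""
    from taxomass.benchmarks import community_benchmark

    return community_benchmark(
        uneven_community(),
        SimulationConfig(seed=5, n_ms2=150_000),
        methods=("psm_count",),
    )


@pytest.fixture(scope="session")
def small_bundle():
    """Small uneven-community simulation for structural checks."""
    from taxomass.simulate import simulate_community_bundle

    return simulate_community_bundle(
        uneven_community(), SimulationConfig(seed=3, n_ms2=12_000)
    )
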