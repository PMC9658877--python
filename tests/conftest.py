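"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately use plain double loops / DFS so they stay
independent of the vectorized implementations they check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from oligoscan.confidence import AnalysisConfig
from oligoscan.structure_io import DomainMap, DomainSpan
from oligoscan.synthetic_data import SyntheticSpec, make_chain, make_cn_assembly


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def default_config():
    return AnalysisConfig()


@pytest.fixture
def two_domain_map():
    return DomainMap([DomainSpan("BTB", 1, 24), DomainSpan("hinge", 25, 28),
                      DomainSpan("CTD", 29, 58)])


@pytest.fixture
def synthetic_chain():
    spec = SyntheticSpec(seed=11)
    return make_chain(spec)


@pytest.fixture
def c5_assembly(synthetic_chain):
    chain, _, _ = synthetic_chain
    return make_cn_assembly(chain, 5, 11.0, seed=11)


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def brute_block_fractions(values, segmentation, domain_map, config,
                          chain_order=None):
    """Exhaustive double-loop reference for confidence.block_fractions.

    Assumes residues numbered 1..n per chain (the synthetic convention).
    """
    chain_idx, dom = [], []
    for k, (_, n) in enumerate(segmentation):
        for i in range(n):
            chain_idx.append(k)
            dom.append(domain_map.domain_of(i + 1))
    L = len(chain_idx)
    n_chains = len(segmentation)

    if config.adjacency == "all_pairs" or n_chains == 2:
        adjacent = {frozenset(p) for p in itertools.combinations(range(n_chains), 2)}
    else:
        order = list(chain_order) if chain_order is not None else list(range(n_chains))
        adjacent = {frozenset((order[k], order[(k + 1) % n_chains]))
                    for k in range(n_chains)}

    counts: dict[str, list[int]] = {}

    def add(cls, val):
        below, total = counts.setdefault(cls, [0, 0])
        counts[cls] = [below + (1 if val < config.pae_threshold else 0), total + 1]

    ordered = config.pair_symmetrization == "ordered"
    for i in range(L):
        for j in range(L):
            if ordered:
                if i == j:
                    continue
                val = values[i][j]
            else:
                if j <= i:
                    continue
                if config.pair_symmetrization == "mean":
                    val = (values[i][j] + values[j][i]) / 2.0
                else:
                    val = min(values[i][j], values[j][i])
            di, dj = dom[i], dom[j]
            if di not in ("BTB", "CTD") or dj not in ("BTB", "CTD"):
                continue
            ci, cj = chain_idx[i], chain_idx[j]
            if ci == cj:
                if di == dj:
                    add(f"intra-{di}", val)
                else:
                    add("cross-domain", val)
            elif di == dj and frozenset((ci, cj)) in adjacent:
                add(f"inter-{di}", val)
    return {cls: (total, 100.0 * below / total)
            for cls, (below, total) in counts.items()}


def brute_components(values, segmentation, config):
    """DFS connected-components reference for infer_substoichiometry."""
    ids = [cid for cid, _ in segmentation]
    offsets, off = [], 0
    for _, n in segmentation:
        offsets.append((off, off + n))
        off += n
    n_chains = len(ids)
    adj = {cid: set() for cid in ids}
    for a, b in itertools.combinations(range(n_chains), 2):
        sa, sb = offsets[a], offsets[b]
        below = total = 0
        for i in range(*sa):
            for j in range(*sb):
                val = (values[i][j] + values[j][i]) / 2.0
                total += 1
                if val < config.pae_threshold:
                    below += 1
        if 100.0 * below / total > config.reliable_percent:
            adj[ids[a]].add(ids[b])
            adj[ids[b]].add(ids[a])
    seen, comps = set(), []
    for cid in ids:
        if cid in seen:
            continue
        stack, comp = [cid], []
        while stack:
            x = stack.pop()
            if x in seen:
                continue
            seen.add(x)
            comp.append(x)
            stack.extend(adj[x] - seen)
        comps.append(sorted(comp))
    return sorted(comps, key=lambda g: (-len(g), g))


def mc_sasa_two_atoms(c1, r1, c2, r2, probe=1.4, n=100_000, seed=0):
    """Independent Monte-Carlo SASA of a two-atom system (A^2 total)."""
    rng = np.random.default_rng(seed)
    total = 0.0
    for (ca, ra), (cb, rb) in (((c1, r1), (c2, r2)), ((c2, r2), (c1, r1))):
        ea, eb = ra + probe, rb + probe
        pts = rng.normal(size=(n, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        surface = np.asarray(ca) + ea * pts
        exposed = np.linalg.norm(surface - np.asarray(cb), axis=1) >= eb
        total += 4.0 * np.pi * ea ** 2 * exposed.mean()
    return total
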