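"""Randomized baselines for the inconsistency load.

Two empirical nulls: (1) profile shuffling permutes the assignment of
expression rows to gene identities and keeps the topology; (2) degree-
preserving rewiring randomizes the topology by double-edge swaps and keeps
every node's in- and out-degree plus the expression data.  Repeating either
perturbation (200 iterations by default) yields a distribution of global
inconsistency loads; mGlobal is their arithmetic mean, against which the
observed load is placed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .consistency import assess
from .contrasts import label_genes
from .expression import ExpressionCompendium
from .network import Edge, RegulatoryNetwork

PROFILE_SHUFFLE = "profile_shuffle"
EDGE_SHUFFLE = "edge_shuffle"


def shuffle_profiles(obj, rng: np.random.Generator):
    """Permute the assignment of expression rows to gene ids.

    Accepts an :class:`ExpressionCompendium` or any gene-indexed DataFrame
    (contrast or label matrix).  The multiset of row vectors is unchanged;
    only which gene each row belongs to is randomized.
    """
    if isinstance(obj, ExpressionCompendium):
        return obj.copy_with(shuffle_profiles(obj.values, rng))
    if not isinstance(obj, pd.DataFrame):
        raise TypeError(f"cannot shuffle profiles of {type(obj).__name__}")
    if obj.shape[0] < 2:
        raise ValueError("need at least 2 genes to shuffle profiles")
    perm = rng.permutation(obj.shape[0])
    return pd.DataFrame(obj.to_numpy()[perm, :], index=obj.index, columns=obj.columns)


def rewire_network(
    net: RegulatoryNetwork,
    rng: np.random.Generator,
    n_swaps: int | None = None,
    allow_self_loops: bool = False,
    max_tries: int | None = None,
) -> RegulatoryNetwork:
    """Degree-preserving randomization by accepted double-edge swaps.

    A swap picks two edge slots (a->x, s1) and (b->y, s2) and proposes
    (a->y, s1), (b->x, s2); it is rejected if it would duplicate an existing
    pair or (by default) create a self-loop.  Signs stay attached to the
    regulator's slot, so each TF's activation/repression out-profile is
    preserved along with all degrees.  Defaults: 10 x |edges| accepted swaps,
    with an attempt cap for degenerate topologies where few swaps exist.
    """
    if net.n_edges < 2:
        raise ValueError("rewiring needs at least 2 edges")
    edges = list(net.edges)
    if n_swaps is None:
        n_swaps = 10 * len(edges)
    if max_tries is None:
        max_tries = max(100, 50 * n_swaps)
    edge_set = {(e.regulator, e.target) for e in edges}
    accepted = tries = 0
    m = len(edges)
    while accepted < n_swaps and tries < max_tries:
        tries += 1
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        a, x, s1 = edges[i]
        b, y, s2 = edges[j]
        if x == y:
            continue
        if not allow_self_loops and (a == y or b == x):
            continue
        new1, new2 = (a, y), (b, x)
        # reject duplicates against edges not involved in the swap
        if (new1 in edge_set and new1 != (a, x) and new1 != (b, y)) or (
            new2 in edge_set and new2 != (a, x) and new2 != (b, y)
        ):
            continue
        edge_set.discard((a, x))
        edge_set.discard((b, y))
        edge_set.add(new1)
        edge_set.add(new2)
        edges[i] = Edge(a, y, s1)
        edges[j] = Edge(b, x, s2)
        accepted += 1
    return RegulatoryNetwork(set(net.nodes), edges, dict(net.operon_map))


@dataclass
class NullDistribution:
    """Per-iteration global inconsistency loads under one null model."""

    method: str
    n_iterations: int
    loads: list[int]
    m_global: float
    seed: int

    def to_dict(self, observed: int | None = None) -> dict:
        d = {
            "method": self.method,
            "seed": self.seed,
            "n_iterations": self.n_iterations,
            "loads": list(self.loads),
            "m_global": self.m_global,
        }
        if observed is not None:
            d["observed"] = observed
            d["observed_percentile"] = percentile_of(observed, self.loads)
        return d


def percentile_of(observed: float, loads: list[int] | np.ndarray) -> float:
    """Mid-rank percentile of the observed load within the null loads."""
    loads = np.asarray(loads)
    below = np.sum(loads < observed)
    equal = np.sum(loads == observed)
    return float(100.0 * (below + 0.5 * equal) / loads.size)


def null_distribution(
    net: RegulatoryNetwork,
    deltas: pd.DataFrame,
    t: float,
    method: str,
    n_iterations: int = 200,
    seed: int = 0,
    recalibrate=None,
    **assess_kwargs,
) -> NullDistribution:
    """Inconsistency-load distribution under one perturbation method.

    Each iteration draws a fresh perturbation from an independently seeded
    stream: ``profile_shuffle`` permutes the contrast rows over gene ids and
    relabels with the original threshold t (permuting label rows directly is
    exactly equivalent, since labeling is entrywise with one global t);
    ``edge_shuffle`` rewires the network and reuses the original labels.
    ``recalibrate``, if given, is a callable deltas -> t applied per
    iteration instead of the fixed t.  Bit-reproducible for a fixed seed.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if method not in (PROFILE_SHUFFLE, EDGE_SHUFFLE):
        raise ValueError(f"unknown null method {method!r}")
    streams = np.random.SeedSequence(seed).spawn(n_iterations)
    labels = label_genes(deltas, t)
    loads: list[int] = []
    for ss in streams:
        rng = np.random.default_rng(ss)
        if method == PROFILE_SHUFFLE:
            if recalibrate is None:
                it_labels = shuffle_profiles(labels, rng)
            else:
                shuffled = shuffle_profiles(deltas, rng)
                it_labels = label_genes(shuffled, recalibrate(shuffled))
            loads.append(assess(net, it_labels, **assess_kwargs).global_count)
        else:
            rewired = rewire_network(net, rng)
            loads.append(assess(rewired, labels, **assess_kwargs).global_count)
    return NullDistribution(
        method=method,
        n_iterations=n_iterations,
        loads=loads,
        m_global=float(np.mean(loads)),
        seed=seed,
    )
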