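"""Network pharmacology on protein-protein interaction graphs.

Quantifies how a drug's target proteins relate to a disease's protein module
on an undirected, unweighted PPI network:

* ``closest_distance`` — mean, over disease proteins y, of the hop distance to
  the nearest drug target x;
* ``proximity_zscore`` — that distance standardized against a degree-matched
  random null (z < 0: the drug's targets overlap or hug the disease module);
* ``separation_score`` — s_AB = <d_AB> - (<d_AA> + <d_BB>)/2 between two
  target modules (s >= 0: topologically separate modules);
* ``classify_exposure`` — combines the two: both drugs inside the disease
  module (z_A < 0, z_B < 0) with separated target modules (s_AB >= 0) is the
  "complementary exposure" pattern that predicts an effective combination.

Distances are unweighted shortest paths restricted to the graph's largest
connected component; protein-set members outside it are dropped with a warning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

__all__ = [
    "ProteinSet",
    "ProximityResult",
    "SeparationResult",
    "ExposureCall",
    "closest_distance",
    "proximity_zscore",
    "separation_score",
    "classify_exposure",
    "tissue_filter",
    "validate_graph",
]

COMPLEMENTARY = "complementary"
OVERLAPPING = "overlapping"
SINGLE = "single"
NON = "non"
CATEGORIES = (COMPLEMENTARY, OVERLAPPING, SINGLE, NON)


@dataclass(frozen=True)
class ProteinSet:
    """Labelled set of protein ids (drug targets or disease proteins)."""

    label: str
    members: frozenset

    def __init__(self, label: str, members: Iterable):
        object.__setattr__(self, "label", str(label))
        object.__setattr__(self, "members", frozenset(members))

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class ProximityResult:
    d: float
    mu: float
    sigma: float
    z: float  # nan when sigma == 0
    n_permutations: int
    seed: int | None
    flagged: bool = False


@dataclass
class SeparationResult:
    s_ab: float
    d_ab: float
    d_aa: float
    d_bb: float


@dataclass
class ExposureCall:
    drug_a: str
    drug_b: str
    z_a: float
    z_b: float
    s_ab: float
    category: str


def validate_graph(graph: nx.Graph) -> nx.Graph:
    """Reject self-loops and directed graphs; PPI edges are simple and unordered."""
    if graph.is_directed():
        raise ValueError("PPI graph must be undirected")
    loops = list(nx.selfloop_edges(graph))
    if loops:
        raise ValueError(f"PPI graph has self-loops, e.g. {loops[:3]}")
    return graph


def _largest_component(graph: nx.Graph) -> set:
    return max(nx.connected_components(graph), key=len)


def _filter_to_component(
    graph: nx.Graph, s: ProteinSet, component: set
) -> frozenset:
    kept = s.members & component
    dropped = len(s.members) - len(kept)
    if dropped:
        warnings.warn(
            f"{s.label}: dropped {dropped} protein(s) outside the largest "
            f"connected component ({len(kept)} kept)",
            stacklevel=3,
        )
    if not kept:
        raise ValueError(
            f"{s.label}: no members intersect the graph's largest component"
        )
    return kept


def _min_dist_to(graph: nx.Graph, sources: Iterable, targets: Iterable) -> dict:
    """Hop distance from each target node to the nearest source node."""
    dist = nx.multi_source_dijkstra_path_length(graph, set(sources), weight=None)
    return {t: dist.get(t, math.inf) for t in targets}


def closest_distance(graph: nx.Graph, x: ProteinSet, y: ProteinSet) -> float:
    """d(X, Y) = (1/|Y|) * sum over y of min over x of hop distance d(x, y).

    Asymmetric in (X, Y): it averages over the disease proteins Y.  Members
    outside the largest connected component, and Y members unreachable from X,
    are dropped with a warning.
    """
    validate_graph(graph)
    component = _largest_component(graph)
    xs = _filter_to_component(graph, x, component)
    ys = _filter_to_component(graph, y, component)
    sub = graph.subgraph(component)
    dist = _min_dist_to(sub, xs, ys)
    finite = [v for v in dist.values() if math.isfinite(v)]
    if len(finite) < len(ys):
        warnings.warn(
            f"{y.label}: {len(ys) - len(finite)} member(s) unreachable from "
            f"{x.label}; dropped",
            stacklevel=2,
        )
    if not finite:
        raise ValueError(f"no member of {y.label} reachable from {x.label}")
    return float(np.mean(finite))


class DegreeMatchedSampler:
    """Samples random node sets matching a template set's degree profile.

    Nodes are binned by floor(log2(degree)); bins with fewer than
    ``min_bin_size`` candidates are merged with the next lower bin (standard
    network-medicine practice), so every sampled node comes from a pool of
    nodes with comparable degree.
    """

    def __init__(self, graph: nx.Graph, min_bin_size: int = 10):
        self.nodes = sorted(graph.nodes(), key=str)
        degrees = dict(graph.degree())
        raw_bin = {
            n: int(math.floor(math.log2(max(degrees[n], 1)))) for n in self.nodes
        }
        # merge sparse bins downward until each surviving bin is big enough
        by_bin: dict[int, list] = {}
        for n in self.nodes:
            by_bin.setdefault(raw_bin[n], []).append(n)
        merged: dict[int, int] = {}
        bins_sorted = sorted(by_bin)
        pool: list = []
        pool_bins: list[int] = []
        final: dict[int, list] = {}
        for b in bins_sorted:
            pool.extend(by_bin[b])
            pool_bins.append(b)
            if len(pool) >= min_bin_size:
                for pb in pool_bins:
                    merged[pb] = pool_bins[-1]
                final[pool_bins[-1]] = pool
                pool, pool_bins = [], []
        if pool:  # leftover small top bin joins the last complete one
            if final:
                target = max(final)
                final[target] = final[target] + pool
                for pb in pool_bins:
                    merged[pb] = target
            else:
                target = pool_bins[-1]
                final[target] = pool
                for pb in pool_bins:
                    merged[pb] = target
        self.node_bin = {n: merged[raw_bin[n]] for n in self.nodes}
        self.bin_nodes = {b: sorted(ns, key=str) for b, ns in final.items()}

    def sample_like(self, template: Iterable, rng: np.random.Generator) -> set:
        """Random node set with the same per-bin composition as ``template``."""
        counts: dict[int, int] = {}
        for n in template:
            counts[self.node_bin[n]] = counts.get(self.node_bin[n], 0) + 1
        out: set = set()
        for b, k in sorted(counts.items()):
            candidates = self.bin_nodes[b]
            if k > len(candidates):
                raise ValueError(
                    f"degree bin {b} has only {len(candidates)} candidates "
                    f"for a template needing {k}"
                )
            idx = rng.choice(len(candidates), size=k, replace=False)
            out.update(candidates[i] for i in idx)
        return out


def proximity_zscore(
    graph: nx.Graph,
    x: ProteinSet,
    y: ProteinSet,
    n_permutations: int = 100,
    seed: int | None = None,
    min_bin_size: int = 10,
) -> ProximityResult:
    """z = (d(X,Y) - mu) / sigma against a degree-matched random null.

    Each permutation replaces both X and Y with random node sets of equal size
    drawn from log2-degree bins matching the originals.  mu and sigma are the
    mean and (population) standard deviation of the permuted closest
    distances.  sigma = 0 (e.g. a single permutation) flags z as undefined.
    """
    validate_graph(graph)
    component = _largest_component(graph)
    xs = _filter_to_component(graph, x, component)
    ys = _filter_to_component(graph, y, component)
    sub = graph.subgraph(component)
    # all-pairs hop distances once, so the null permutations are pure indexing
    from scipy.sparse.csgraph import shortest_path

    nodes = sorted(sub.nodes(), key=str)
    pos = {n: i for i, n in enumerate(nodes)}
    adj = nx.to_scipy_sparse_array(sub, nodelist=nodes, format="csr")
    dmat = shortest_path(adj, method="D", unweighted=True, directed=False)
    xi = np.sort(np.fromiter((pos[n] for n in xs), dtype=int))
    yi = np.sort(np.fromiter((pos[n] for n in ys), dtype=int))
    observed = float(dmat[np.ix_(xi, yi)].min(axis=0).mean())
    sampler = DegreeMatchedSampler(sub, min_bin_size=min_bin_size)
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        rx = np.sort(np.fromiter((pos[n] for n in sampler.sample_like(xs, rng)), dtype=int))
        ry = np.sort(np.fromiter((pos[n] for n in sampler.sample_like(ys, rng)), dtype=int))
        null[i] = dmat[np.ix_(rx, ry)].min(axis=0).mean()
    mu = float(null.mean())
    sigma = float(null.std())
    if sigma == 0:
        warnings.warn("null-model sigma is zero; z undefined", stacklevel=2)
        return ProximityResult(observed, mu, sigma, math.nan, n_permutations, seed, True)
    z = (observed - mu) / sigma
    return ProximityResult(observed, mu, sigma, z, n_permutations, seed, False)


def separation_score(graph: nx.Graph, a: ProteinSet, b: ProteinSet) -> SeparationResult:
    """s_AB = <d_AB> - (<d_AA> + <d_BB>) / 2.

    <d_AB> averages, over every node of A and of B, the distance to the
    nearest node of the *other* set (a shared protein contributes 0).
    <d_AA> averages the nearest-*distinct*-neighbor distance within A
    (0 for a singleton).  With these conventions s_AA <= 0 always, and
    disjoint well-separated modules give s_AB > 0.
    """
    validate_graph(graph)
    component = _largest_component(graph)
    xa = _filter_to_component(graph, a, component)
    xb = _filter_to_component(graph, b, component)
    sub = graph.subgraph(component)
    # one BFS per member; sets are small in practice
    sp = {n: nx.single_source_shortest_path_length(sub, n) for n in xa | xb}

    def nearest(node, others: set) -> float:
        d = sp[node]
        return min(d[o] for o in others if o in d)

    cross = [nearest(n, xb) for n in sorted(xa)] + [nearest(n, xa) for n in sorted(xb)]
    d_ab = float(np.mean(cross))

    def within(members: set) -> float:
        if len(members) < 2:
            return 0.0
        return float(np.mean([nearest(n, members - {n}) for n in sorted(members)]))

    d_aa = within(xa)
    d_bb = within(xb)
    return SeparationResult(d_ab - (d_aa + d_bb) / 2.0, d_ab, d_aa, d_bb)


def classify_exposure(
    graph: nx.Graph,
    disease: ProteinSet,
    drug_a: ProteinSet,
    drug_b: ProteinSet,
    n_permutations: int = 100,
    seed: int | None = None,
) -> ExposureCall:
    """Exposure category of a drug pair relative to a disease module.

    complementary: z_A < 0, z_B < 0, s_AB >= 0 (predicted effective);
    overlapping:   z_A < 0, z_B < 0, s_AB < 0;
    single:        exactly one z < 0;
    non:           neither z < 0.
    A drug with no curated targets cannot be assessed and raises.
    """
    for drug in (drug_a, drug_b):
        if len(drug) == 0:
            raise ValueError(
                f"drug {drug.label!r} has no target proteins; "
                "network configuration cannot be calculated"
            )
    ss = np.random.SeedSequence(seed) if seed is not None else np.random.SeedSequence()
    seed_a, seed_b = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    za = proximity_zscore(graph, drug_a, disease, n_permutations, seed_a)
    zb = proximity_zscore(graph, drug_b, disease, n_permutations, seed_b)
    sep = separation_score(graph, drug_a, drug_b)
    a_in = (not za.flagged) and za.z < 0
    b_in = (not zb.flagged) and zb.z < 0
    if a_in and b_in:
        category = COMPLEMENTARY if sep.s_ab >= 0 else OVERLAPPING
    elif a_in or b_in:
        category = SINGLE
    else:
        category = NON
    return ExposureCall(
        drug_a=drug_a.label,
        drug_b=drug_b.label,
        z_a=za.z,
        z_b=zb.z,
        s_ab=sep.s_ab,
        category=category,
    )


def tissue_filter(
    graph: nx.Graph,
    median_expression: Mapping[str, float],
    threshold: float = 1.0,
) -> nx.Graph:
    """Induced subgraph on proteins with median expression strictly > threshold (TPM).

    Proteins absent from ``median_expression`` are treated as not expressed.
    Node/edge counts before and after are attached as graph attributes.
    """
    validate_graph(graph)
    if not median_expression:
        raise ValueError("median_expression is empty")
    keep = [n for n in graph.nodes() if median_expression.get(n, 0.0) > threshold]
    if not keep:
        raise ValueError(
            f"tissue filter at TPM > {threshold} removes every node"
        )
    sub = graph.subgraph(keep).copy()
    sub.graph["n_nodes_before"] = graph.number_of_nodes()
    sub.graph["n_edges_before"] = graph.number_of_edges()
    sub.graph["n_nodes_after"] = sub.number_of_nodes()
    sub.graph["n_edges_after"] = sub.number_of_edges()
    return sub
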