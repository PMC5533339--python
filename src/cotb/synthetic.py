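"""Synthetic PPI-network bundles with planted essentiality signal.

Every stage of the pipeline is testable without external databases: a
preferential-attachment network is generated, essential labels are drawn
with a degree bias, and the three annotation layers are sampled so that the
regularities the method exploits are present by construction — essentials
concentrate in complexes (odds ``rho_c``), in a few enriched subcellular
locations (odds ``rho_l``), and appear in more reference organisms
(per-organism presence ``q_essential`` > ``q_nonessential``).

A *family* of networks shares one protein universe, one essential set and
one attachment-order permutation (so hub identity is correlated across
networks), while edges and annotations carry independent noise — the
setting needed for leave-one-network-out training.

Defaults mirror the yeast study scale at n = 2000: mean degree ≈ 8,
essential prevalence 0.23, 99 reference organisms, 11 locations, 200
complexes of 3–10 members.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from . import graph_io
from .graph_io import ComplexCatalog, LocalizationTable, OrthologyTable

__all__ = ["SyntheticSpec", "Bundle", "generate", "generate_family", "write_bundle", "read_bundle"]


@dataclass
class SyntheticSpec:
    n_nodes: int = 2000
    m: int = 4                       # edges per new node (preferential attachment)
    prevalence: float = 0.23         # essential fraction of the universe
    beta: float = 1.0                # degree bias of the essential label
    n_complexes: int = 200
    complex_size: tuple[int, int] = (3, 10)
    rho_c: float = 3.0               # essential odds inside complexes
    n_locations: int = 11
    n_enriched: int = 3
    rho_l: float = 3.0               # essential odds towards enriched locations
    s_organisms: int = 99
    q_essential: float = 0.8         # per-organism presence probability, essentials
    q_nonessential: float = 0.3
    node_fraction: float = 0.95      # share of the universe each family member carries
    seed: int = 0

    def validate(self) -> None:
        for name in ("prevalence", "q_essential", "q_nonessential", "node_fraction"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name}={value} is not a probability")
        if self.q_essential < self.q_nonessential:
            raise ValueError("q_essential must be >= q_nonessential")
        if self.rho_c < 1.0 or self.rho_l < 1.0:
            raise ValueError("enrichment odds must be >= 1")
        if self.beta < 0.0:
            raise ValueError("beta must be >= 0")
        lo, hi = self.complex_size
        if not (1 <= lo <= hi):
            raise ValueError("complex_size must satisfy 1 <= lo <= hi")
        if hi > self.n_nodes:
            raise ValueError(f"complex size {hi} exceeds n_nodes={self.n_nodes}")
        if self.n_enriched > self.n_locations:
            raise ValueError("n_enriched cannot exceed n_locations")
        if self.n_nodes <= self.m:
            raise ValueError("n_nodes must exceed the attachment parameter m")


@dataclass
class Bundle:
    network: nx.Graph
    complexes: ComplexCatalog
    orthology: OrthologyTable
    localization: LocalizationTable
    essential: set[str] = field(default_factory=set)


def generate(spec: SyntheticSpec) -> Bundle:
    """One bundle over the full universe (a family of one)."""
    return generate_family(spec, n_networks=1)[0]


def generate_family(spec: SyntheticSpec, n_networks: int) -> list[Bundle]:
    """Bundles sharing a protein universe, essential set and hub structure."""
    spec.validate()
    if n_networks < 1:
        raise ValueError("n_networks must be >= 1")
    rng = np.random.default_rng(spec.seed)
    universe = np.array([f"P{i:05d}" for i in range(spec.n_nodes)])
    # shared attachment order: the same proteins become early (hub-prone)
    # nodes in every network of the family
    attach_rank = rng.permutation(spec.n_nodes)

    net_seeds = rng.integers(0, 2**31 - 1, size=n_networks)
    label_seed = int(rng.integers(0, 2**31 - 1))
    annot_seeds = rng.integers(0, 2**31 - 1, size=(n_networks, 3))

    networks = []
    for j in range(n_networks):
        networks.append(_build_network(spec, universe, attach_rank, int(net_seeds[j]),
                                       full=(n_networks == 1)))

    essential = _draw_labels(spec, universe, networks[0], label_seed)

    bundles = []
    for j, net in enumerate(networks):
        complexes = _sample_complexes(spec, net, essential, int(annot_seeds[j, 0]))
        localization = _sample_localization(spec, net, essential, int(annot_seeds[j, 1]))
        orthology = _sample_orthology(spec, net, essential, int(annot_seeds[j, 2]))
        bundles.append(Bundle(net, complexes, orthology, localization, set(essential)))
    return bundles


def _build_network(
    spec: SyntheticSpec,
    universe: np.ndarray,
    attach_rank: np.ndarray,
    seed: int,
    full: bool,
) -> nx.Graph:
    rng = np.random.default_rng(seed)
    if full:
        included = np.arange(spec.n_nodes)
    else:
        keep = max(spec.m + 1, round(spec.node_fraction * spec.n_nodes))
        included = rng.choice(spec.n_nodes, size=keep, replace=False)
    # attach in shared-rank order so hub identity persists across the family
    ordered = included[np.argsort(attach_rank[included])]
    ba = nx.barabasi_albert_graph(len(ordered), spec.m, seed=int(rng.integers(0, 2**31 - 1)))
    mapping = {i: str(universe[ordered[i]]) for i in range(len(ordered))}
    return nx.relabel_nodes(ba, mapping)


def _draw_labels(
    spec: SyntheticSpec, universe: np.ndarray, reference_net: nx.Graph, seed: int
) -> set[str]:
    """Weighted sample without replacement, weight deg^beta (reservoir keys).

    Degrees come from the family's first network; universe proteins absent
    from it weight as the minimum degree m.
    """
    rng = np.random.default_rng(seed)
    degrees = np.array(
        [reference_net.degree(p) if p in reference_net else spec.m for p in universe],
        dtype=float,
    )
    weights = np.maximum(degrees, 1.0) ** spec.beta
    k = round(spec.prevalence * spec.n_nodes)
    keys = rng.random(spec.n_nodes) ** (1.0 / weights)
    chosen = np.argsort(-keys)[:k]
    return {str(universe[i]) for i in chosen}


def _weighted_subset(
    rng: np.random.Generator, pool: list[str], size: int, weights: np.ndarray
) -> list[str]:
    size = min(size, len(pool))
    if size == 0:
        return []
    p = weights / weights.sum()
    idx = rng.choice(len(pool), size=size, replace=False, p=p)
    return [pool[i] for i in idx]


def _sample_complexes(
    spec: SyntheticSpec, net: nx.Graph, essential: set[str], seed: int
) -> ComplexCatalog:
    rng = np.random.default_rng(seed)
    nodes = sorted(net.nodes())
    node_w = np.array([spec.rho_c if v in essential else 1.0 for v in nodes])
    lo, hi = spec.complex_size
    complexes = []
    for c in range(spec.n_complexes):
        (seed_node,) = _weighted_subset(rng, nodes, 1, node_w)
        pool = sorted(net[seed_node])
        size = int(rng.integers(lo, hi + 1))
        pool_w = np.array([spec.rho_c if v in essential else 1.0 for v in pool])
        members = set(_weighted_subset(rng, pool, size - 1, pool_w))
        members.add(seed_node)
        complexes.append((f"C{c:04d}", frozenset(members)))
    return ComplexCatalog(complexes)


def _sample_localization(
    spec: SyntheticSpec, net: nx.Graph, essential: set[str], seed: int
) -> LocalizationTable:
    rng = np.random.default_rng(seed)
    locations = [f"L{i:02d}" for i in range(spec.n_locations)]
    enriched = set(locations[: spec.n_enriched])
    loc_w_ess = np.array([spec.rho_l if l in enriched else 1.0 for l in locations])
    loc_w_non = np.ones(len(locations))
    membership: dict[str, set[str]] = {l: set() for l in locations}
    for v in sorted(net.nodes()):
        n_loc = int(rng.integers(1, 4))  # 1-3 locations per protein
        w = loc_w_ess if v in essential else loc_w_non
        for l in _weighted_subset(rng, locations, n_loc, w):
            membership[l].add(v)
    return LocalizationTable(locations=locations, membership=membership)


def _sample_orthology(
    spec: SyntheticSpec, net: nx.Graph, essential: set[str], seed: int
) -> OrthologyTable:
    rng = np.random.default_rng(seed)
    nodes = sorted(net.nodes())
    q = np.array([spec.q_essential if v in essential else spec.q_nonessential for v in nodes])
    organisms = [f"ORG{i:03d}" for i in range(spec.s_organisms)]
    draws = rng.random((spec.s_organisms, len(nodes))) < q  # row = organism
    presence = {
        org: {nodes[j] for j in np.flatnonzero(draws[i])} for i, org in enumerate(organisms)
    }
    return OrthologyTable(organisms=organisms, presence=presence)


def write_bundle(bundle: Bundle, directory: str | Path, prefix: str) -> None:
    """Write a bundle in the text formats graph_io reads."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    graph_io.write_network(bundle.network, directory / f"{prefix}.edges.tsv")
    graph_io.write_complexes(bundle.complexes, directory / f"{prefix}.complexes.tsv")
    graph_io.write_orthology(bundle.orthology, directory / f"{prefix}.orthology.tsv")
    graph_io.write_localization(bundle.localization, directory / f"{prefix}.localization.tsv")
    graph_io.write_essential_list(bundle.essential, directory / f"{prefix}.essential.txt")


def read_bundle(directory: str | Path, prefix: str) -> Bundle:
    directory = Path(directory)
    return Bundle(
        network=graph_io.read_network(directory / f"{prefix}.edges.tsv"),
        complexes=graph_io.read_complexes(directory / f"{prefix}.complexes.tsv"),
        orthology=graph_io.read_orthology(directory / f"{prefix}.orthology.tsv"),
        localization=graph_io.read_localization(directory / f"{prefix}.localization.tsv"),
        essential=graph_io.read_essential_list(directory / f"{prefix}.essential.txt"),
    )
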