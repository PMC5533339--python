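"""Biology-derived per-protein scores: complex in-degree, orthology,
subcellular localization, and the LBCC reference ranking.

The localization score is built in two stages. First, proteins are ranked by
LBCC — a log-linear combination of the two neighbourhood densities, the
complex in-degree and betweenness — and the top fraction (default 5%) is
taken as a presumed-essential reference set. Each location *l* then gets an
enrichment coefficient ``SLC(l) = t_l/t - a_l/a`` comparing its share of the
reference set with its share of all localized proteins. A protein's SLS is
the sum of SLC over its recorded locations; positive SLS means the protein
sits in locations where highly ranked proteins concentrate.
"""

from __future__ import annotations

import math
import warnings

import networkx as nx

from .graph_io import ComplexCatalog, LocalizationTable, OrthologyTable
from .topology import ScoreMap

__all__ = [
    "idc",
    "orthologous_score",
    "dos",
    "lbcc",
    "slc_table",
    "sls",
    "rank_descending",
]


def idc(net: nx.Graph, catalog: ComplexCatalog) -> ScoreMap:
    """In-degree centrality of complex.

    IDC(v) sums, over every complex containing v, the degree of v in the
    network subgraph induced on that complex's members. The complex file
    carries no edges of its own; all edges come from the network. Proteins
    in no complex score 0.
    """
    scores = {v: 0.0 for v in net.nodes()}
    adjacency = {v: set(net[v]) for v in net.nodes()}
    for _cid, members in catalog.complexes:
        present = members & scores.keys()
        for v in present:
            scores[v] += len(adjacency[v] & present)
    return scores


def orthologous_score(net: nx.Graph, orthology: OrthologyTable) -> ScoreMap:
    """OS(v): number of reference organisms in which v appears (0..s)."""
    appearances: dict[str, int] = {}
    for org in orthology.organisms:
        for protein in orthology.presence.get(org, ()):
            appearances[protein] = appearances.get(protein, 0) + 1
    return {v: float(appearances.get(v, 0)) for v in net.nodes()}


def dos(dc: ScoreMap, os_scores: ScoreMap, scale: float = 0.1) -> ScoreMap:
    """Degree-augmented orthologous score DOS(v) = scale * DC(v) + OS(v)."""
    if dc.keys() != os_scores.keys():
        raise ValueError("DC and OS score maps cover different node sets")
    if not (0.1 <= scale <= 1.0):
        warnings.warn(f"dos scale {scale} outside the supported range [0.1, 1]", stacklevel=2)
    return {v: scale * dc[v] + os_scores[v] for v in dc}


def lbcc(
    den1: ScoreMap,
    den2: ScoreMap,
    idc_scores: ScoreMap,
    bc: ScoreMap,
    eps: float = 1e-10,
) -> ScoreMap:
    """LBCC(v) = ln(Den1+eps) + 4 ln(Den2+eps) + 3 ln(IDC+eps) + ln(BC+eps).

    The additive *eps* keeps zero-valued inputs finite and pushes proteins
    with no evidence to the bottom of the ranking. The induced ordering is
    independent of the logarithm base.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    keys = den1.keys()
    if not (keys == den2.keys() == idc_scores.keys() == bc.keys()):
        raise ValueError("LBCC inputs cover different node sets")
    return {
        v: (
            math.log(den1[v] + eps)
            + 4.0 * math.log(den2[v] + eps)
            + 3.0 * math.log(idc_scores[v] + eps)
            + math.log(bc[v] + eps)
        )
        for v in keys
    }


def rank_descending(scores: ScoreMap) -> list[str]:
    """Node IDs sorted by score descending, ties broken by ID ascending."""
    return sorted(scores, key=lambda v: (-scores[v], v))


def slc_table(
    net: nx.Graph,
    localization: LocalizationTable,
    lbcc_scores: ScoreMap,
    top_fraction: float = 0.05,
) -> dict[str, float]:
    """Per-location enrichment coefficients SLC(l) = t_l/t - a_l/a.

    ``t`` is the size of the top-``top_fraction`` slice of the network's
    LBCC ranking (ceil rounding, ID-ascending tie-break), ``t_l`` its overlap
    with location *l*; ``a_l``/``a`` are the location's and table's protein
    counts. An empty localization table yields an empty (all-zero) table
    with a warning.
    """
    if not (0.0 < top_fraction < 1.0):
        raise ValueError("top_fraction must lie strictly between 0 and 1")
    if not localization.locations:
        warnings.warn("empty localization table: all SLC coefficients are zero", stacklevel=2)
        return {}
    ranked = rank_descending(lbcc_scores)
    t = math.ceil(top_fraction * net.number_of_nodes())
    top = set(ranked[:t])
    a = localization.total_proteins
    table: dict[str, float] = {}
    for loc in localization.locations:
        members = localization.membership.get(loc, set())
        t_l = len(top & members)
        a_l = len(members)
        table[loc] = (t_l / t if t else 0.0) - (a_l / a if a else 0.0)
    return table


def sls(localization: LocalizationTable, slc: dict[str, float], net: nx.Graph) -> ScoreMap:
    """SLS(v): sum of SLC over the locations recording v; 0 if unlocalized."""
    by_protein: dict[str, float] = {v: 0.0 for v in net.nodes()}
    for loc, coeff in slc.items():
        for protein in localization.membership.get(loc, ()):
            if protein in by_protein:
                by_protein[protein] += coeff
    return by_protein
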