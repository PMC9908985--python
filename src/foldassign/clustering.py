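"""Clustering of unassigned domains into putative new superfamilies.

Domains that no reference superfamily accepted are compared all-vs-all;
pairs clearing the similarity and overlap cuts become edges, and single
linkage at a fixed cutoff — exactly the connected components of the
thresholded similarity graph — groups them into clusters. Each cluster is
then triaged through its representative (the member with the highest mean
confidence):

* ``pdb_unclassified_match`` — the representative matches a structure that
  is known but not yet classified;
* ``multidomain`` — only part of the representative matches an
  already-classified domain (the hit covers the target but under 60% of
  the query, over at least a domain-sized 40 residues), i.e. the region
  spans more than one domain;
* ``putative_new`` — no library explains it; a candidate novel superfamily.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx

from .assignment import (AcceptanceThresholds, Comparator, ComparisonResult,
                         LibraryEntry, TMAlignComparator, accept_hit)
from .model_io import StructureModel
from .quality import mean_plddt

__all__ = [
    "SimilarityEdge",
    "Cluster",
    "all_vs_all",
    "single_linkage",
    "triage_cluster",
    "choose_representative",
]

#: A sub-region match must still be domain sized to flag a multidomain region.
MULTIDOMAIN_MIN_ALIGNED = 40


@dataclass
class SimilarityEdge:
    """One scored unordered pair, in canonical (sorted) id order."""

    id_a: str
    id_b: str
    weight: float
    passed: bool
    result: ComparisonResult | None = None


@dataclass
class Cluster:
    members: list[str]
    triage: str = ""  # pdb_unclassified_match | multidomain | putative_new

    @property
    def size(self) -> int:
        return len(self.members)


def all_vs_all(domains: Mapping[str, StructureModel],
               comparator: Comparator | None = None,
               edge_threshold: float = 0.5,
               overlap_min: float = 0.60) -> list[SimilarityEdge]:
    """Score every unordered pair once, in canonical id order.

    An edge passes when its weight reaches ``edge_threshold`` and both
    overlap fractions reach ``overlap_min`` (the comparison is made once
    per pair, so the pass criterion is symmetric by construction).
    ``edge_threshold`` lives on the comparator's score scale: 165 for a
    bitscore backend, 0.5 for the built-in TM comparator.
    """
    comparator = comparator or TMAlignComparator()
    ids = sorted(domains)
    edges: list[SimilarityEdge] = []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            res = comparator(domains[a], domains[b])
            passed = (res.score >= edge_threshold
                      and res.query_overlap >= overlap_min
                      and res.target_overlap >= overlap_min)
            edges.append(SimilarityEdge(a, b, res.score, passed, res))
    return edges


def single_linkage(edges: Sequence[SimilarityEdge], cutoff: float,
                   all_ids: Sequence[str] = ()) -> list[Cluster]:
    """Single-linkage clusters at a fixed weight cutoff.

    At a fixed cut, single linkage reduces to the connected components of
    the graph keeping passing edges with weight >= cutoff. Domains with no
    surviving edge form singleton clusters. Output ordering (clusters by
    first member, members sorted) is deterministic.
    """
    g = nx.Graph()
    g.add_nodes_from(all_ids)
    for e in edges:
        g.add_nodes_from((e.id_a, e.id_b))
        if e.passed and e.weight >= cutoff:
            g.add_edge(e.id_a, e.id_b)
    clusters = [Cluster(sorted(comp)) for comp in nx.connected_components(g)]
    clusters.sort(key=lambda c: c.members[0])
    return clusters


def choose_representative(cluster: Cluster,
                          models: Mapping[str, StructureModel]) -> str:
    """Cluster representative: highest mean pLDDT, ties to the lower id."""
    return max(cluster.members, key=lambda m: (mean_plddt(models[m]), m))


def triage_cluster(cluster: Cluster,
                   models: Mapping[str, StructureModel],
                   pdb_unclassified_library: Sequence[LibraryEntry] = (),
                   assigned_library: Sequence[LibraryEntry] = (),
                   comparator: Comparator | None = None,
                   thresholds: AcceptanceThresholds | None = None) -> str:
    """Triage one cluster by its representative; see the module docstring.

    With both libraries empty only ``putative_new`` is reachable. The label
    depends only on the representative, so it is invariant to member order.
    """
    comparator = comparator or TMAlignComparator()
    t = thresholds or AcceptanceThresholds()
    rep = max(cluster.members, key=lambda m: (mean_plddt(models[m]), m))
    query = models[rep]
    for entry in sorted(pdb_unclassified_library, key=lambda e: e.domain_id):
        res = comparator(query, entry.model)
        if accept_hit(res, None, t):
            return "pdb_unclassified_match"
    for entry in sorted(assigned_library, key=lambda e: e.domain_id):
        res = comparator(query, entry.model)
        partial = (res.query_overlap < t.overlap_min
                   and res.target_overlap >= t.overlap_min
                   and res.n_aligned >= MULTIDOMAIN_MIN_ALIGNED
                   and res.score_target >= t.tm_min)
        if partial:
            return "multidomain"
    return "putative_new"
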