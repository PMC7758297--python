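"""Identity clustering and similarity grouping of Rep proteins.

Redundancy among predicted Rep proteins is reduced by greedy centroid
clustering at an identity threshold (80% within species, 70% across
representatives), and the full sequence set is partitioned into similarity
groups — connected components of the all-vs-all local-alignment graph at a
stringent E-value threshold (1e-20), the grouping semantics of an
all-against-all BLAST clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx

from .scoring import ScoringScheme
from .search import _alignment_stats, protein_search


@dataclass
class Cluster:
    centroid_id: str
    member_ids: list[str]
    threshold: float
    representative_id: str


@dataclass
class SimilarityGroup:
    member_ids: list[str]
    e_threshold: float


def percent_identity(a: str, b: str, scheme: ScoringScheme | None = None) -> float:
    """Pairwise identity from a global alignment with free terminal gaps.

    Identity = identical columns / alignment columns excluding terminal-gap
    columns (internal gaps count in the denominator).  Symmetric.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if scheme is None:
        scheme = ScoringScheme()
    if b < a:  # canonical order: co-optimal alignments could otherwise
        a, b = b, a  # differ between (a,b) and (b,a), breaking symmetry
    aligner = scheme.make_aligner(mode="global", free_end_gaps=True)
    aln = aligner.align(a, b)[0]
    _, _, _, _, identity = _alignment_stats(aln)
    return identity


def greedy_cluster(
    proteins: Sequence[tuple[str, str]] | Mapping[str, str],
    threshold: float,
    scheme: ScoringScheme | None = None,
) -> list[Cluster]:
    """Greedy centroid clustering at an identity threshold.

    Sequences are processed in decreasing length (ties: lexicographic id);
    each joins the first existing centroid it matches at identity >=
    ``threshold``, else founds a new cluster.  The representative of each
    cluster is its longest member (the centroid, by construction).
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    if scheme is None:
        scheme = ScoringScheme()
    items = list(proteins.items()) if isinstance(proteins, Mapping) else list(proteins)
    items.sort(key=lambda kv: (-len(kv[1]), kv[0]))
    clusters: list[Cluster] = []
    seqs: dict[str, str] = dict(items)
    for pid, seq in items:
        placed = False
        for cl in clusters:
            if percent_identity(seq, seqs[cl.centroid_id], scheme) >= threshold:
                cl.member_ids.append(pid)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(centroid_id=pid, member_ids=[pid], threshold=threshold, representative_id=pid))
    for cl in clusters:
        cl.representative_id = min(cl.member_ids, key=lambda i: (-len(seqs[i]), i))
    return clusters


def similarity_groups(
    proteins: Mapping[str, str],
    scheme: ScoringScheme | None = None,
    e_threshold: float = 1e-20,
) -> tuple[list[SimilarityGroup], list[str]]:
    """Partition sequences into connected components of the similarity graph.

    An edge joins two sequences when their local alignment reaches
    E <= ``e_threshold`` (E-values against the whole input as library).
    Components of size >= 2 are groups; singletons are returned separately.
    """
    if not proteins:
        raise ValueError("need at least one sequence")
    if scheme is None:
        scheme = ScoringScheme()
    g = nx.Graph()
    g.add_nodes_from(proteins)
    ids = sorted(proteins)
    for i, a in enumerate(ids[:-1]):
        hits = protein_search({a: proteins[a]}, {b: proteins[b] for b in ids[i + 1 :]}, scheme, e_max=e_threshold)
        for h in hits:
            g.add_edge(a, h.subject_id)
    groups: list[SimilarityGroup] = []
    ungrouped: list[str] = []
    for comp in nx.connected_components(g):
        if len(comp) >= 2:
            groups.append(SimilarityGroup(member_ids=sorted(comp), e_threshold=e_threshold))
        else:
            ungrouped.extend(comp)
    groups.sort(key=lambda gr: gr.member_ids)
    return groups, sorted(ungrouped)
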