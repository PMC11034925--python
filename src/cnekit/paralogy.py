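"""Duplicated-CNE detection and paralogy clustering.

Elements are searched against the element set itself (not the genome, so
repeat contamination cannot fabricate clusters); nonself hits propose
edges, and an edge is kept only when the two elements' selected target
genes are annotated paralogs (or the same gene). Connected components of
kept edges are paralogy clusters, dated by the origin of the anchoring gene
pairs: a cluster is pre-WGD ("2R-analog") if any anchor pair predates the
WGD, post-WGD ("3R") if anchor pairs are WGD copies, "mixed" otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .associate import TargetAssociation
from .detect import CNESet
from .model import OrthologyTable
from .search import GenomeIndex, SearchParams, search_all

log = logging.getLogger(__name__)


@dataclass
class ParalogyCluster:
    cluster_id: str
    members: tuple[str, ...]
    #: member -> its anchoring target gene(s) in the reference species
    anchors: dict[str, tuple[str, ...]]
    origin: str  # pre-WGD | post-WGD | mixed

    @property
    def anchor_orthogroups(self) -> frozenset[str]:
        return frozenset(self._ogs)

    def set_orthogroups(self, ogs) -> None:
        self._ogs = frozenset(ogs)


def self_hits(cne_set: CNESet, genomes, search_params: SearchParams | None = None) -> list[tuple[str, str]]:
    """Symmetric deduplicated nonself hit pairs within one CNE set."""
    params = search_params or SearchParams()
    seqs = cne_set.sequences(genomes)
    index = GenomeIndex(seqs, params, species_id=cne_set.ref_species)
    results = search_all(seqs, index, params)
    pairs: set[tuple[str, str]] = set()
    for qid, loci in results.items():
        for hit in loci:
            other = hit.location.chrom  # sequence names are CNE ids
            if other == qid:
                continue
            pairs.add((qid, other) if qid < other else (other, qid))
    return sorted(pairs)


def _pair_origin(ga: str, gb: str, species: str, orthology: OrthologyTable) -> str | None:
    """Origin of a gene pair: 'post-WGD' for same-orthogroup paralog copies,
    'pre-WGD' for cross-orthogroup annotated paralogs, 'same' for the same
    gene, None when the genes are not paralogs at all."""
    if ga == gb:
        return "same"
    if not orthology.are_paralogs(species, ga, gb):
        return None
    if orthology.orthogroup(species, ga) == orthology.orthogroup(species, gb):
        return "post-WGD"
    return "pre-WGD"


def paralogy_clusters(
    hit_pairs: list[tuple[str, str]],
    associations: dict[str, TargetAssociation],
    orthology: OrthologyTable,
    species: str,
    id_prefix: str = "pc",
) -> list[ParalogyCluster]:
    """Build clusters from sequence-similarity edges gated by target paralogy."""
    edges: list[tuple[str, str, str]] = []
    for a, b in hit_pairs:
        ta, tb = associations.get(a), associations.get(b)
        if ta is None or tb is None or not ta.target_genes or not tb.target_genes:
            log.debug("edge %s-%s dropped: member without target", a, b)
            continue
        origin = None
        for ga in ta.target_genes:
            for gb in tb.target_genes:
                o = _pair_origin(ga, gb, species, orthology)
                if o is not None and (origin is None or o == "pre-WGD"):
                    origin = o
        if origin is not None:
            edges.append((a, b, origin))
    # connected components (union-find)
    parent: dict[str, str] = {}

    def find(x):
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    for a, b, _ in edges:
        union(a, b)
    comp: dict[str, list[str]] = {}
    for a, b, _ in edges:
        comp.setdefault(find(a), [])
    for node in parent:
        comp.setdefault(find(node), []).append(node)
    clusters = []
    edge_by_comp: dict[str, list[tuple[str, str, str]]] = {}
    for a, b, o in edges:
        edge_by_comp.setdefault(find(a), []).append((a, b, o))
    for i, root in enumerate(sorted(comp), 1):
        members = tuple(sorted(comp[root]))
        if len(members) < 2:
            continue
        origins = {o for _, _, o in edge_by_comp.get(root, [])}
        if "pre-WGD" in origins:
            origin = "pre-WGD"
        elif origins == {"post-WGD"} or ("post-WGD" in origins and origins <= {"post-WGD", "same"}):
            origin = "post-WGD"
        else:
            origin = "mixed"
        anchors = {m: associations[m].target_genes for m in members}
        cluster = ParalogyCluster(f"{id_prefix}{i:03d}", members, anchors, origin)
        ogs = set()
        for m in members:
            ogs.update(associations[m].orthogroups)
        cluster.set_orthogroups(ogs)
        clusters.append(cluster)
    return clusters


def common_clusters(
    clusters_a: list[ParalogyCluster], clusters_b: list[ParalogyCluster], orthology: OrthologyTable | None = None
) -> list[tuple[str, str]]:
    """Cluster pairs across two reference groups whose anchor orthogroup
    sets intersect; one-to-many matches are reported once per pair."""
    out = []
    for ca in clusters_a:
        for cb in clusters_b:
            if ca.anchor_orthogroups & cb.anchor_orthogroups:
                out.append((ca.cluster_id, cb.cluster_id))
    return out


def member_category_shares(clusters: list[ParalogyCluster], category_of: dict[str, str]) -> dict[str, float]:
    """Share (%) of paralogous elements per origin category."""
    members = [m for c in clusters for m in c.members]
    n = len(members)
    out: dict[str, float] = {}
    for m in members:
        cat = category_of.get(m, "?")
        out[cat] = out.get(cat, 0) + 1
    return {k: 100.0 * v / n for k, v in out.items()} if n else {}


def cluster_origin_shares(clusters: list[ParalogyCluster]) -> dict[str, float]:
    """Share (%) of paralogous elements in pre-WGD vs post-WGD clusters."""
    counts: dict[str, int] = {}
    total = 0
    for c in clusters:
        counts[c.origin] = counts.get(c.origin, 0) + len(c.members)
        total += len(c.members)
    return {k: 100.0 * v / total for k, v in counts.items()} if total else {}
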