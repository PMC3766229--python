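"""Bipartite motif-gene co-regulation networks.

Overrepresented motifs become one node class, the genes whose UCRs they hit
become the other; an edge records how often and how well a motif occurs in a
gene's UCR. Gene nodes carry a category (cuticular-protein, muscle, other)
so that motifs shared between categories — the candidates for co-regulation
of exoskeleton and musculature genes — can be read off directly. The shared
view is a restriction of the full network, never a separate construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .motif_discovery import DiscoveredMotif
from .motif_match import MotifMatch
from .pssm_core import SiteHit

CATEGORIES = ("CP", "muscle", "other")


@dataclass
class RegulatoryNetwork:
    """A bipartite motif -> gene graph with gene categories."""

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    def motif_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d.get("kind") == "motif"]

    def gene_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d.get("kind") == "gene"]

    def validate(self) -> None:
        for u, v in self.graph.edges:
            if self.graph.nodes[u].get("kind") != "motif" or self.graph.nodes[v].get("kind") != "gene":
                raise ValueError(f"non-bipartite edge {u} -> {v}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegulatoryNetwork):
            return NotImplemented
        return nx.utils.graphs_equal(self.graph, other.graph)


def build_network(
    retained_motifs: Sequence[DiscoveredMotif],
    site_hits: Mapping[str, Sequence[SiteHit]],
    category_map: Mapping[str, str],
    matches: Sequence[MotifMatch] = (),
) -> RegulatoryNetwork:
    """Assemble the bipartite network from retained motifs and their hits.

    An edge (motif, gene) exists iff the motif has at least one hit in the
    gene's UCR; its attributes are the occurrence count and best similarity.
    Motif nodes are annotated with the TF names they matched; genes without
    any hit do not appear. Hits referencing genes absent from the category
    map raise.
    """
    net = RegulatoryNetwork()
    g = net.graph
    tf_by_motif: dict[str, list[str]] = {}
    for mm in matches:
        tf_by_motif.setdefault(mm.motif_name, []).append(mm.tf_name)
    for m in retained_motifs:
        g.add_node(m.name, kind="motif", tfs=";".join(dict.fromkeys(tf_by_motif.get(m.name, []))))
    for motif_name, hits in site_hits.items():
        if motif_name not in g:
            g.add_node(motif_name, kind="motif", tfs=";".join(dict.fromkeys(tf_by_motif.get(motif_name, []))))
        for hit in hits:
            gene = hit.sequence_id
            if gene not in category_map:
                raise KeyError(f"hit references unknown gene {gene!r}")
            if gene not in g:
                g.add_node(gene, kind="gene", category=category_map[gene])
            if g.has_edge(motif_name, gene):
                data = g.edges[motif_name, gene]
                data["n_occurrences"] += 1
                data["similarity"] = max(data["similarity"], hit.similarity)
            else:
                g.add_edge(motif_name, gene, n_occurrences=1, similarity=hit.similarity)
    net.validate()
    return net


def shared_motifs(
    network: RegulatoryNetwork, category_a: str = "CP", category_b: str = "muscle"
) -> list[str]:
    """Motifs hitting at least one gene of each category, by degree descending.

    This is the predicate behind the co-regulation view: only motifs present
    in the UCRs of both gene classes enter it.
    """
    known = {d.get("category") for _, d in network.graph.nodes(data=True) if d.get("kind") == "gene"}
    for cat in (category_a, category_b):
        if cat not in CATEGORIES and cat not in known:
            raise ValueError(f"unknown category {cat!r}")
    out = []
    for motif in network.motif_nodes():
        cats = {
            network.graph.nodes[gene]["category"]
            for gene in network.graph.successors(motif)
        }
        if category_a in cats and category_b in cats:
            out.append(motif)
    out.sort(key=lambda m: (-network.graph.degree(m), m))
    return out


def shared_subnetwork(
    network: RegulatoryNetwork, category_a: str = "CP", category_b: str = "muscle"
) -> RegulatoryNetwork:
    """Restriction of the network to shared motifs and their target genes."""
    keep_motifs = set(shared_motifs(network, category_a, category_b))
    keep = set(keep_motifs)
    for m in keep_motifs:
        keep.update(network.graph.successors(m))
    return RegulatoryNetwork(network.graph.subgraph(keep).copy())


def export_network(network: RegulatoryNetwork, path: str | Path, fmt: str = "graphml") -> None:
    """Write the network as GraphML or a TSV edge list."""
    fmt = fmt.lower()
    if fmt == "graphml":
        nx.write_graphml(network.graph, str(path))
    elif fmt == "tsv":
        rows = []
        for u, v, d in network.graph.edges(data=True):
            rows.append(
                {
                    "motif": u, "gene": v,
                    "category": network.graph.nodes[v].get("category", ""),
                    "tfs": network.graph.nodes[u].get("tfs", ""),
                    "n_occurrences": d["n_occurrences"], "similarity": d["similarity"],
                }
            )
        pd.DataFrame(
            rows, columns=["motif", "gene", "category", "tfs", "n_occurrences", "similarity"]
        ).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def import_network(path: str | Path, fmt: str = "graphml") -> RegulatoryNetwork:
    """Read a network back; GraphML round-trips nodes, edges and attributes."""
    fmt = fmt.lower()
    if fmt == "graphml":
        g = nx.read_graphml(str(path))
        out = nx.DiGraph()
        out.add_nodes_from(g.nodes(data=True))
        for u, v, d in g.edges(data=True):
            out.add_edge(u, v, n_occurrences=int(d["n_occurrences"]),
                         similarity=float(d["similarity"]))
        net = RegulatoryNetwork(out)
    elif fmt == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"motif": str, "gene": str})
        net = RegulatoryNetwork()
        for _, row in df.iterrows():
            net.graph.add_node(row["motif"], kind="motif", tfs=row.get("tfs", "") or "")
            net.graph.add_node(row["gene"], kind="gene", category=row["category"])
            net.graph.add_edge(
                row["motif"], row["gene"],
                n_occurrences=int(row["n_occurrences"]), similarity=float(row["similarity"]),
            )
    else:
        raise ValueError(f"unknown network format {fmt!r}")
    net.validate()
    return net
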