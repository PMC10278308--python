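"""Triple metabolite-QTL-gene relationship network.

The network links three omics layers: metabolite-QTL edges carry mGWAS
signals, gene-QTL edges carry eQTL signals, gene-metabolite edges carry
mTWAS signals, and gene-module edges carry co-expression membership.  QTL
nodes are the merged loci where an mQTL and an eQTL co-localize within a
distance window (default 100 kb); the merged locus coordinates are the
union of the contributing intervals.

Candidate genes are prioritized transparently: a gene qualifies if it has at
least one co-localized QTL and one significant mTWAS pair, and genes are
ranked lexicographically by (number of distinct associated marker
metabolites, number of supporting QTLs, membership in a trait-significant
module).
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

from .datatypes import QTL


class _UnionFind:
    def __init__(self):
        self.parent: dict = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def build_triple_network(
    mqtls: dict[str, list[QTL]],
    eqtls: dict[str, list[QTL]],
    mtwas: pd.DataFrame,
    modules: pd.Series | None = None,
    window_bp: int = 100_000,
) -> nx.Graph:
    """Assemble the typed triple network.

    Parameters
    ----------
    mqtls : metabolite id -> list of its mQTLs.
    eqtls : gene id -> list of its eQTLs.
    mtwas : tidy mTWAS table with columns gene/metabolite/p/significant.
    modules : gene -> module label (0 = unassigned) for membership edges.

    QTL nodes are created only for loci where at least one mQTL and one
    eQTL co-localize (interval gap <= ``window_bp`` on the same
    chromosome); co-localized loci sharing a contributing QTL are merged
    (union-find), and merged coordinates are the union interval.  Graph
    attributes ``n_colocalized_pairs`` and ``n_merged_loci`` report both
    counting conventions.
    """
    chrom_sets = set()
    for qs in list(mqtls.values()) + list(eqtls.values()):
        for q in qs:
            chrom_sets.add(q.chromosome)
    mq_flat = [(met, q) for met, qs in mqtls.items() for q in qs]
    eq_flat = [(gene, q) for gene, qs in eqtls.items() for q in qs]

    # co-localized (mQTL, eQTL) pairs
    pairs = []
    for met, qa in mq_flat:
        for gene, qb in eq_flat:
            if qa.gap_to(qb) <= window_bp:
                pairs.append((met, qa, gene, qb))

    uf = _UnionFind()
    for _, qa, _, qb in pairs:
        uf.union(("m", qa.qtl_id), ("e", qb.qtl_id))
    locus_members: dict = {}
    for met, qa, gene, qb in pairs:
        root = uf.find(("m", qa.qtl_id))
        locus_members.setdefault(root, []).append((met, qa, gene, qb))

    G = nx.Graph(n_colocalized_pairs=len(pairs), n_merged_loci=len(locus_members))
    for i, (root, members) in enumerate(
        sorted(locus_members.items(), key=lambda kv: str(kv[0]))
    ):
        qtls_here = [q for _, qa, _, qb in members for q in (qa, qb)]
        chrom = qtls_here[0].chromosome
        start = min(q.start for q in qtls_here)
        end = max(q.end for q in qtls_here)
        locus_id = f"locus_{chrom}_{start}_{end}"
        G.add_node(locus_id, node_type="qtl", chromosome=chrom, start=start, end=end)
        for met, qa, gene, qb in members:
            G.add_node(met, node_type="metabolite")
            G.add_node(gene, node_type="gene")
            _merge_edge(G, met, locus_id, "mQTL", qa.lead_p)
            _merge_edge(G, gene, locus_id, "eQTL", qb.lead_p)

    sig = mtwas.loc[mtwas["significant"]]
    for row in sig.itertuples(index=False):
        if row.gene == row.metabolite:
            continue
        G.add_node(row.gene, node_type="gene")
        G.add_node(row.metabolite, node_type="metabolite")
        _merge_edge(G, row.gene, row.metabolite, "mTWAS", float(row.p))

    if modules is not None:
        gene_nodes = [n for n, d in G.nodes(data=True) if d["node_type"] == "gene"]
        for gene in gene_nodes:
            lab = modules.get(gene, 0)
            if lab and lab > 0:
                mod_node = f"module_{int(lab)}"
                G.add_node(mod_node, node_type="module")
                G.add_edge(gene, mod_node, edge_type="membership", weight=1.0)
    return G


def _merge_edge(G: nx.Graph, a, b, edge_type: str, p: float) -> None:
    """Add a typed edge, keeping the most significant provenance on duplicates."""
    if G.has_edge(a, b):
        if p < G.edges[a, b].get("weight", 1.0):
            G.edges[a, b]["weight"] = p
        return
    G.add_edge(a, b, edge_type=edge_type, weight=p)


def network_summary(G: nx.Graph) -> dict:
    by_type: dict[str, int] = {}
    for _, d in G.nodes(data=True):
        by_type[d["node_type"]] = by_type.get(d["node_type"], 0) + 1
    edge_types: dict[str, int] = {}
    for _, _, d in G.edges(data=True):
        edge_types[d["edge_type"]] = edge_types.get(d["edge_type"], 0) + 1
    return {
        "n_nodes": G.number_of_nodes(),
        "n_edges": G.number_of_edges(),
        "nodes_by_type": by_type,
        "edges_by_type": edge_types,
        "n_colocalized_pairs": G.graph.get("n_colocalized_pairs", 0),
        "n_merged_loci": G.graph.get("n_merged_loci", 0),
    }


def metabolite_qtl_gene_paths(G: nx.Graph) -> set[tuple[str, str]]:
    """All (metabolite, gene) pairs connected through a shared QTL node."""
    paths = set()
    for node, d in G.nodes(data=True):
        if d["node_type"] != "qtl":
            continue
        mets, genes = [], []
        for nb in G.neighbors(node):
            t = G.nodes[nb]["node_type"]
            if t == "metabolite":
                mets.append(nb)
            elif t == "gene":
                genes.append(nb)
        for m in mets:
            for g in genes:
                paths.add((m, g))
    return paths


def prioritize_candidates(
    G: nx.Graph,
    module_trait: pd.DataFrame | None = None,
    trait_target: str = "SOC",
) -> pd.DataFrame:
    """Rank candidate genes supported by both co-localization and mTWAS.

    A gene is listed only if it touches >= 1 QTL node and >= 1 significant
    mTWAS metabolite.  Ranking is lexicographic, descending:
    (n_marker_metabolites, n_qtls, in a module significantly correlated
    with the trait), ties broken by gene id.
    """
    sig_modules: set[int] = set()
    if module_trait is not None:
        sel = module_trait.loc[
            (module_trait["target"] == trait_target) & module_trait["significant"]
        ]
        for mod in sel["module"]:
            sig_modules.add(int(str(mod).removeprefix("ME")))
    rows = []
    for node, d in G.nodes(data=True):
        if d["node_type"] != "gene":
            continue
        qtl_ids, mets, mod_label = [], [], 0
        for nb in G.neighbors(node):
            t = G.nodes[nb]["node_type"]
            et = G.edges[node, nb]["edge_type"]
            if t == "qtl":
                qtl_ids.append(nb)
            elif t == "metabolite" and et == "mTWAS":
                mets.append(nb)
            elif t == "module":
                mod_label = int(str(nb).removeprefix("module_"))
        if qtl_ids and mets:
            rows.append(
                (
                    node,
                    len(set(mets)),
                    len(set(qtl_ids)),
                    mod_label,
                    mod_label in sig_modules,
                    ";".join(sorted(set(qtl_ids))),
                )
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "gene",
            "n_marker_metabolites",
            "n_qtls",
            "module",
            "in_trait_module",
            "qtl_ids",
        ],
    )
    return out.sort_values(
        ["n_marker_metabolites", "n_qtls", "in_trait_module", "gene"],
        ascending=[False, False, False, True],
    ).reset_index(drop=True)


def export_graph(G: nx.Graph, path, fmt: str = "graphml") -> None:
    """Write the typed graph as GraphML or as a node + edge TSV pair.

    ``edge-tsv`` writes ``<path>`` with columns source/target/edge_type/
    weight and ``<path with .nodes.tsv suffix>`` with node types, so the
    typed graph round-trips through :func:`read_graph`.
    """
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(G, path)
    elif fmt == "edge-tsv":
        edges = pd.DataFrame(
            [
                (a, b, d["edge_type"], d.get("weight", float("nan")))
                for a, b, d in G.edges(data=True)
            ],
            columns=["source", "target", "edge_type", "weight"],
        )
        nodes = pd.DataFrame(
            [(n, d["node_type"]) for n, d in G.nodes(data=True)],
            columns=["node", "node_type"],
        )
        edges.to_csv(path, sep="\t", index=False)
        nodes.to_csv(_nodes_path(path), sep="\t", index=False)
    else:
        raise ValueError(f"unknown graph format: {fmt}")


def _nodes_path(path: Path) -> Path:
    return path.with_suffix(".nodes.tsv")


def read_graph(path, fmt: str = "graphml") -> nx.Graph:
    path = Path(path)
    if fmt == "graphml":
        return nx.read_graphml(path)
    if fmt == "edge-tsv":
        edges = pd.read_csv(path, sep="\t")
        nodes = pd.read_csv(_nodes_path(path), sep="\t")
        G = nx.Graph()
        for row in nodes.itertuples(index=False):
            G.add_node(row.node, node_type=row.node_type)
        for row in edges.itertuples(index=False):
            G.add_edge(row.source, row.target, edge_type=row.edge_type, weight=row.weight)
        return G
    raise ValueError(f"unknown graph format: {fmt}")
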