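"""Gene-gene interaction network from the top-ranked between-gene results.

Nodes are genes, an edge joins the two genes of a ranked interaction, edge
weight is the gene-level mean test balanced accuracy, and node size/degree
identifies hub genes — genes that interact with many partners.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from .pipeline import InteractionResult


@dataclass
class InteractionNetwork:
    """Undirected gene-interaction graph plus the rank order of its edges."""

    graph: nx.Graph
    edge_order: list[tuple[str, str]]  # rank order, each pair sorted
    top_n: int

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degrees(self) -> dict[str, int]:
        return dict(self.graph.degree())

    def hubs(self, n: int = 5) -> list[tuple[str, int]]:
        """The ``n`` highest-degree genes (ties by symbol)."""
        deg = sorted(self.degrees().items(), key=lambda kv: (-kv[1], kv[0]))
        return deg[:n]


def build_network(
    results: list[InteractionResult], top_n: int = 500
) -> InteractionNetwork:
    """Build the network of the first min(top_n, len(results)) interactions.

    Only pairwise interactions form edges; self-loops are rejected and a
    duplicate gene pair (guarded against, impossible from a combination
    search) keeps the higher weight.
    """
    if not results:
        raise ValueError("no interaction results to build a network from")
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    graph = nx.Graph()
    edge_order: list[tuple[str, str]] = []
    for r in results[: min(top_n, len(results))]:
        if len(r.genes) != 2:
            raise ValueError(
                f"network edges require pairwise interactions, got {r.genes}"
            )
        a, b = sorted(r.genes)
        if a == b:
            raise ValueError(f"self-interaction {a!r} cannot form an edge")
        w = float(r.mean_test_ba)
        if graph.has_edge(a, b):
            if w > graph[a][b]["weight"]:
                graph[a][b]["weight"] = w
            continue
        graph.add_edge(a, b, weight=w)
        edge_order.append((a, b))
    return InteractionNetwork(graph=graph, edge_order=edge_order, top_n=top_n)


def export_network(
    net: InteractionNetwork, out_dir, plot: bool = False
) -> dict[str, Path]:
    """Write edge-list TSV, node TSV and GraphML (optionally a PNG plot).

    The edge TSV preserves rank order; the node TSV is sorted by degree
    (descending) then symbol.  Returns the written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    edges = pd.DataFrame(
        [
            {"gene_a": a, "gene_b": b, "weight": net.graph[a][b]["weight"]}
            for a, b in net.edge_order
        ]
    )
    paths["edges"] = out / "network.edges.tsv"
    edges.to_csv(paths["edges"], sep="\t", index=False, float_format="%.10g")

    deg = net.degrees()
    nodes = pd.DataFrame(
        sorted(deg.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["gene", "degree"],
    )
    paths["nodes"] = out / "network.nodes.tsv"
    nodes.to_csv(paths["nodes"], sep="\t", index=False)

    paths["graphml"] = out / "network.graphml"
    nx.write_graphml(net.graph, paths["graphml"])

    if plot:
        try:
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt
        except ImportError:  # plotting is best-effort; TSV/GraphML are canonical
            return paths
        fig, ax = plt.subplots(figsize=(8, 8))
        pos = nx.spring_layout(net.graph, seed=0)
        sizes = [40 + 30 * deg[n] for n in net.graph.nodes]
        nx.draw_networkx(
            net.graph, pos=pos, ax=ax, node_size=sizes, font_size=6,
            node_color="tab:blue", edge_color="0.7",
        )
        ax.set_axis_off()
        paths["plot"] = out / "network.png"
        fig.savefig(paths["plot"], dpi=150, bbox_inches="tight")
        plt.close(fig)
    return paths


def read_edges(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
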