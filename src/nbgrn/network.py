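"""Assemble per-gene sparse regressions into a directed gene network.

Each gene is regressed on the lagged values of every other gene; a directed
edge parent -> child is scored by the posterior probability that the child's
regression coefficient on the parent is sign-consistent (equivalently, an
edge is called when zero lies outside the central credible interval).
``DynamicNetworkModel`` is the statsmodels-style entry point; its ``fit``
returns a ``NetworkResults`` carrying the edge table, per-gene posteriors,
and graph utilities such as betweenness centrality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .inference import FitConfig
from .regression import NBHorseshoeModel, NBHorseshoeResults, edge_score
from .timeseries import CountTimeSeries, build_problem

logger = logging.getLogger(__name__)

__all__ = ["DirectedNetwork", "DynamicNetworkModel", "NetworkResults", "betweenness", "edge_score"]


@dataclass
class DirectedNetwork:
    """Directed network: node list plus an edge-record table.

    ``edges`` has one row per ordered gene pair (parent != child) with
    columns parent, child, beta_mean, beta_sd, score, selected.  The selected
    flag is exactly ``score > cutoff``.
    """

    nodes: list
    edges: pd.DataFrame
    cutoff: float = 0.95

    def __post_init__(self):
        required = {"parent", "child", "beta_mean", "beta_sd", "score", "selected"}
        if not required.issubset(self.edges.columns):
            raise ValueError(f"edge table must have columns {sorted(required)}")
        if (self.edges["parent"] == self.edges["child"]).any():
            raise ValueError("self-edges are not allowed in the edge table")

    @classmethod
    def from_edge_list(cls, nodes, true_edges) -> "DirectedNetwork":
        """Build a gold-standard network from (parent, child) pairs; scores are 0/1."""
        truth = set(map(tuple, true_edges))
        rows = [
            (p, c, 1.0 if (p, c) in truth else 0.0)
            for p in nodes
            for c in nodes
            if p != c
        ]
        df = pd.DataFrame(rows, columns=["parent", "child", "beta_mean"])
        df["beta_sd"] = 1.0
        df["score"] = df["beta_mean"]
        df["selected"] = df["score"] > 0.5
        return cls(nodes=list(nodes), edges=df, cutoff=0.5)

    def select(self, cutoff: float) -> "DirectedNetwork":
        """Return a copy with the selection threshold changed."""
        edges = self.edges.copy()
        edges["selected"] = edges["score"] > cutoff
        return DirectedNetwork(nodes=self.nodes, edges=edges, cutoff=cutoff)

    def selected_edges(self) -> list[tuple]:
        sel = self.edges[self.edges["selected"]]
        return list(zip(sel["parent"], sel["child"]))

    def to_graph(self) -> nx.DiGraph:
        """Directed graph of the selected edges over all nodes."""
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.selected_edges())
        return g

    def to_tsv(self, path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)

    def to_graphml(self, path) -> None:
        g = self.to_graph()
        for _, row in self.edges[self.edges["selected"]].iterrows():
            g[row["parent"]][row["child"]].update(
                beta_mean=float(row["beta_mean"]),
                beta_sd=float(row["beta_sd"]),
                score=float(row["score"]),
            )
        nx.write_graphml(g, path)


def betweenness(network: DirectedNetwork) -> pd.Series:
    """Directed shortest-path betweenness centrality of the selected graph.

    Normalized to fractions of node pairs, i.e. divided by (n-1)(n-2); an
    empty edge set gives all zeros.
    """
    g = network.to_graph()
    if g.number_of_nodes() == 0:
        return pd.Series(dtype=float)
    vals = nx.betweenness_centrality(g, normalized=True)
    return pd.Series(vals).reindex(network.nodes)


class DynamicNetworkModel:
    """First-order dynamic Bayesian network of NB2 gene regressions.

    Parameters
    ----------
    data : CountTimeSeries
    transform : {"log-std", "log", "raw"}
        Predictor transform applied to lagged counts.
    """

    def __init__(self, data: CountTimeSeries, transform: str = "log-std"):
        self.data = data
        self.transform = transform

    def fit(
        self,
        config: FitConfig | None = None,
        cutoff: float = 0.95,
        **kwargs,
    ) -> "NetworkResults":
        """Fit one sparse regression per gene and score every ordered pair.

        Per-gene fits are independent, so results do not depend on the order
        genes are processed.  Non-convergence of a gene's fit is recorded and
        the network is still returned.
        """
        if config is None:
            config = FitConfig(**kwargs)
        elif kwargs:
            from dataclasses import replace

            config = replace(config, **kwargs)
        gene_results: dict = {}
        for gene in self.data.genes:
            problem = build_problem(self.data, gene, transform=self.transform)
            model = NBHorseshoeModel.from_problem(problem)
            import warnings as _warnings

            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore", RuntimeWarning)
                res = model.fit(config)
            if not res.converged:
                logger.warning("fit for gene %r did not converge", gene)
            gene_results[gene] = res

        rows = []
        for child, res in gene_results.items():
            names = res.model.problem.predictor_names
            means, sds = res.params[:-1], res.bse[:-1]
            scores = res.edge_scores()
            for parent, m, s, sc in zip(names, means, sds, scores):
                rows.append((parent, child, float(m), float(s), float(sc)))
        edges = pd.DataFrame(
            rows, columns=["parent", "child", "beta_mean", "beta_sd", "score"]
        ).sort_values(["parent", "child"], kind="mergesort", ignore_index=True)
        edges["selected"] = edges["score"] > cutoff
        network = DirectedNetwork(nodes=self.data.genes, edges=edges, cutoff=cutoff)
        return NetworkResults(self, network, gene_results, config)


class NetworkResults:
    """Fitted network: edge table, per-gene posteriors, centrality, summary."""

    def __init__(
        self,
        model: DynamicNetworkModel,
        network: DirectedNetwork,
        gene_results: dict,
        config: FitConfig,
    ):
        self.model = model
        self.network = network
        self.gene_results: dict[object, NBHorseshoeResults] = gene_results
        self.config = config

    @property
    def edges(self) -> pd.DataFrame:
        return self.network.edges

    @property
    def converged(self) -> dict:
        return {g: r.converged for g, r in self.gene_results.items()}

    def betweenness(self) -> pd.Series:
        return betweenness(self.network)

    def select(self, cutoff: float) -> DirectedNetwork:
        return self.network.select(cutoff)

    def summary(self) -> str:
        n_sel = int(self.network.edges["selected"].sum())
        n_pairs = len(self.network.edges)
        n_conv = sum(self.converged.values())
        lines = [
            "Dynamic NB-horseshoe network",
            f"  genes: {len(self.network.nodes)}   transform: {self.model.transform}",
            f"  converged fits: {n_conv}/{len(self.gene_results)}",
            f"  selected edges: {n_sel}/{n_pairs} at cutoff {self.network.cutoff}",
        ]
        bt = self.betweenness()
        if len(bt) and bt.max() > 0:
            top = bt.sort_values(ascending=False).head(5)
            lines.append("  top betweenness: " + ", ".join(f"{g}={v:.3f}" for g, v in top.items()))
        return "\n".join(lines)
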