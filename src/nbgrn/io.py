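"""Readers and writers for the package's plain-text formats.

Counts travel as a TSV matrix (gene ids in the first column, one column per
sample) together with a sample metadata TSV (sample, time, replicate).
Networks are edge-list TSVs; metric reports are JSON.
"""

from __future__ import annotations

import json

import pandas as pd

from .network import DirectedNetwork
from .timeseries import CountTimeSeries, size_factors

__all__ = [
    "read_counts",
    "write_counts",
    "read_network_tsv",
    "write_metrics",
    "size_factors",
]


def read_counts(
    counts_path, metadata_path, size_factor_method: str = "median-ratio"
) -> CountTimeSeries:
    """Load and validate a count matrix plus its sample metadata.

    The metadata must cover exactly the samples in the count matrix, with a
    count for every (time, replicate) pair; counts must be non-negative
    integers and gene ids unique.  Size factors are estimated by the chosen
    method ("median-ratio", "total", or "none").
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
    for col in ("time", "replicate"):
        if col not in meta.columns:
            raise ValueError(f"metadata is missing required column {col!r}")
    sf = size_factors(counts, size_factor_method) if len(counts) else None
    return CountTimeSeries(counts, meta, size_factors_=sf)


def write_counts(data: CountTimeSeries, counts_path, metadata_path) -> None:
    data.counts.to_csv(counts_path, sep="\t")
    data.metadata.to_csv(metadata_path, sep="\t")


def read_network_tsv(path) -> DirectedNetwork:
    """Read an edge-table TSV written by ``DirectedNetwork.to_tsv``."""
    edges = pd.read_csv(path, sep="\t")
    nodes = sorted(set(edges["parent"]) | set(edges["child"]), key=str)
    cutoff = 0.95
    if "selected" in edges.columns and edges["selected"].dtype == object:
        edges["selected"] = edges["selected"].astype(str).str.lower() == "true"
    return DirectedNetwork(nodes=nodes, edges=edges, cutoff=cutoff)


def write_metrics(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
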