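"""Network and curve export in standard text formats."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .thresholding import Network

__all__ = ["write_sif", "write_edgelist_tsv", "write_graphml",
           "read_edgelist_tsv", "write_curve_csv"]


def _edges(net: Network):
    r, c = np.nonzero(np.triu(net.adjacency, 1))
    return zip(net.gene_ids[r].tolist(), net.gene_ids[c].tolist())


def write_sif(net: Network, path, interaction: str = "co") -> None:
    """Simple interaction format: ``gene_a <tab> co <tab> gene_b`` per edge."""
    with open(path, "w") as fh:
        for a, b in _edges(net):
            fh.write(f"{a}\t{interaction}\t{b}\n")


def write_edgelist_tsv(net: Network, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in _edges(net):
            fh.write(f"{a}\t{b}\n")


def read_edgelist_tsv(path, tau_star: float | None = None) -> Network:
    df = pd.read_csv(path, sep="\t", dtype=str)
    import networkx as nx

    G = nx.Graph()
    G.add_edges_from(df.itertuples(index=False, name=None))
    return Network.from_networkx(G, tau_star)


def write_graphml(net: Network, path) -> None:
    import networkx as nx

    nx.write_graphml(net.to_networkx(), path)


def write_curve_csv(curve: pd.DataFrame, path) -> None:
    curve.to_csv(path, index=False)
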