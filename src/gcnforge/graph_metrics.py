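"""The eight graph variables used to characterize co-expression networks.

Four topological variables — clustering coefficient (CC), betweenness
centralization (Cen), degree heterogeneity (Het) and edge density (Den) —
and four variables that blend topology with external annotation: the
nominal assortativity of GO labels (AsG) and of PFAM labels (AsP), the
tolerance to targeted hub attacks (Tol), and the point-biserial correlation
between node degree and the presence of immunity-related protein domains
(KI).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .thresholding import Network, observed_clustering

__all__ = [
    "AnnotationTable",
    "read_annotations_tsv",
    "density",
    "heterogeneity",
    "centralization",
    "assortativity_label",
    "attack_tolerance",
    "degree_domain_correlation",
    "characterize",
    "VARIABLE_NAMES",
]

VARIABLE_NAMES = ["CC", "Cen", "Het", "Den", "AsG", "AsP", "Tol", "KI"]


@dataclass
class AnnotationTable:
    """Per-gene annotation: GO term set, PFAM domain set, immunity flag."""

    go_terms: dict[str, frozenset]
    pfam_domains: dict[str, frozenset]
    immunity: dict[str, bool]

    def go_for(self, gene) -> frozenset:
        return self.go_terms.get(gene, frozenset())

    def pfam_for(self, gene) -> frozenset:
        return self.pfam_domains.get(gene, frozenset())

    def immunity_for(self, gene) -> bool:
        return bool(self.immunity.get(gene, False))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AnnotationTable":
        """Build from a frame with columns gene_id, go_terms, pfam_domains,
        immunity_domain (terms semicolon-joined, flag 0/1)."""
        go, pf, im = {}, {}, {}
        for _, row in df.iterrows():
            g = str(row["gene_id"])
            go[g] = _split_terms(row.get("go_terms"))
            pf[g] = _split_terms(row.get("pfam_domains"))
            im[g] = bool(int(row.get("immunity_domain", 0) or 0))
        return cls(go, pf, im)

    def to_frame(self) -> pd.DataFrame:
        genes = sorted(set(self.go_terms) | set(self.pfam_domains) | set(self.immunity))
        return pd.DataFrame({
            "gene_id": genes,
            "go_terms": [";".join(sorted(self.go_for(g))) for g in genes],
            "pfam_domains": [";".join(sorted(self.pfam_for(g))) for g in genes],
            "immunity_domain": [int(self.immunity_for(g)) for g in genes],
        })


def _split_terms(value) -> frozenset:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return frozenset()
    s = str(value).strip()
    return frozenset(t for t in s.split(";") if t) if s else frozenset()


def read_annotations_tsv(path) -> AnnotationTable:
    return AnnotationTable.from_frame(pd.read_csv(path, sep="\t", dtype=str))


def _as_nx(G) -> nx.Graph:
    if isinstance(G, Network):
        return G.to_networkx()
    if isinstance(G, nx.Graph):
        return G
    if isinstance(G, np.ndarray):
        return nx.from_numpy_array(G)
    raise TypeError(f"cannot interpret {type(G).__name__} as a network")


def density(G) -> float:
    """Edge density 2E / (N (N - 1))."""
    g = _as_nx(G)
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("density needs at least 2 nodes")
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def heterogeneity(G) -> float:
    """Coefficient of variation of the degree distribution (population sd)."""
    g = _as_nx(G)
    k = np.array([d for _, d in g.degree()], dtype=float)
    if k.size == 0 or k.mean() == 0:
        raise ValueError("heterogeneity undefined for zero mean degree")
    return float(k.std() / k.mean())


def _largest_component(g: nx.Graph, metric: str) -> nx.Graph:
    if g.number_of_nodes() and not nx.is_connected(g):
        warnings.warn(f"{metric}: graph disconnected; using largest component")
        nodes = max(nx.connected_components(g), key=lambda cc: (len(cc), sorted(map(str, cc))))
        g = g.subgraph(nodes).copy()
    return g


def centralization(G) -> float:
    """Freeman centralization of pair-normalised betweenness.

    sum_i (b'_max - b'_i) / (N - 1), where b' is betweenness divided by
    (N-1)(N-2)/2.  Equals 1 for a star and 0 for any vertex-transitive
    graph.  Disconnected input is reduced to its largest component with a
    warning.
    """
    g = _as_nx(G)
    if g.number_of_nodes() < 3:
        raise ValueError("centralization needs at least 3 nodes")
    g = _largest_component(g, "centralization")
    n = g.number_of_nodes()
    if n < 3:
        return 0.0
    b = nx.betweenness_centrality(g, normalized=True)
    vals = np.array(list(b.values()))
    return float((vals.max() - vals).sum() / (n - 1))


def assortativity_label(G, labels: dict) -> float:
    """Newman nominal assortativity of a categorical node label.

    r = (sum_i e_ii - sum_i a_i b_i) / (1 - sum_i a_i b_i) over the edge
    mixing matrix.  A single label across all nodes makes the denominator
    vanish; 0 is returned with a warning.
    """
    g = _as_nx(G)
    missing = [v for v in g.nodes() if v not in labels]
    if missing:
        raise ValueError(f"unlabelled nodes: {missing[:5]}")
    if len({labels[v] for v in g.nodes()}) < 2 or g.number_of_edges() == 0:
        warnings.warn("assortativity undefined (single label or no edges); returning 0")
        return 0.0
    nx.set_node_attributes(g, labels, "_lab")
    r = nx.attribute_assortativity_coefficient(g, "_lab")
    if np.isnan(r):
        warnings.warn("assortativity undefined; returning 0")
        return 0.0
    return float(np.clip(r, -1.0, 1.0))


def _mean_path_length(g: nx.Graph) -> float:
    comp = max(nx.connected_components(g), key=len) if g.number_of_nodes() else set()
    if len(comp) < 2:
        return 0.0
    return nx.average_shortest_path_length(g.subgraph(comp))


def attack_tolerance(G, attack_fraction: float = 0.05) -> float:
    """Ratio of mean shortest-path lengths before/after a targeted attack.

    The ceil(attack_fraction * N) highest-degree nodes are removed in a
    single batch (ties broken by lexicographic node id); Tol = L(G) / L(G')
    with L the mean shortest-path length over the largest connected
    component.  Tol = 0 when the attacked graph retains no connected pair.
    """
    g = _as_nx(G)
    if g.number_of_nodes() < 2:
        raise ValueError("attack tolerance needs at least 2 nodes")
    g = _largest_component(g, "attack_tolerance")
    n = g.number_of_nodes()
    n_remove = int(np.ceil(attack_fraction * n))
    order = sorted(g.degree(), key=lambda kv: (-kv[1], str(kv[0])))
    targets = [v for v, _ in order[:n_remove]]
    L0 = _mean_path_length(g)
    g2 = g.copy()
    g2.remove_nodes_from(targets)
    L1 = _mean_path_length(g2)
    if L1 == 0.0:
        return 0.0
    return float(L0 / L1)


def degree_domain_correlation(G, flags: dict) -> float:
    """Point-biserial correlation between node degree and a boolean flag."""
    g = _as_nx(G)
    nodes = list(g.nodes())
    k = np.array([g.degree(v) for v in nodes], dtype=float)
    f = np.array([bool(flags.get(v, False)) for v in nodes], dtype=float)
    if len(set(f)) < 2 or k.std() == 0:
        warnings.warn("degree-domain correlation undefined; returning 0")
        return 0.0
    r = np.corrcoef(k, f)[0, 1]
    return float(np.clip(r, -1.0, 1.0))


def _majority_label(G, term_sets: dict) -> dict:
    """One categorical label per node: its most frequent term in this
    network (ties lexicographic); nodes without terms share a 'none' label."""
    g = _as_nx(G)
    freq: dict = {}
    for v in g.nodes():
        for t in term_sets.get(v, frozenset()):
            freq[t] = freq.get(t, 0) + 1
    labels = {}
    for v in g.nodes():
        terms = term_sets.get(v, frozenset())
        if terms:
            labels[v] = min(sorted(terms), key=lambda t: (-freq[t], t))
        else:
            labels[v] = "__none__"
    return labels


def characterize(G, annotations: AnnotationTable | None = None,
                 attack_fraction: float = 0.05, metadata: dict | None = None,
                 ) -> pd.Series:
    """Compute the eight-variable characterization row for a network.

    Genes absent from the annotation table get empty term sets and a false
    immunity flag.  ``metadata`` entries (e.g. network id, species,
    stress group) are prepended to the returned Series.
    """
    g = _as_nx(G)
    nodes = list(g.nodes())
    if annotations is None:
        annotations = AnnotationTable({}, {}, {})
    go_sets = {v: annotations.go_for(v) for v in nodes}
    pf_sets = {v: annotations.pfam_for(v) for v in nodes}
    flags = {v: annotations.immunity_for(v) for v in nodes}

    row = dict(metadata or {})
    row["CC"] = observed_clustering(G)
    row["Cen"] = centralization(g)
    row["Het"] = heterogeneity(g)
    row["Den"] = density(g)
    row["AsG"] = assortativity_label(g, _majority_label(g, go_sets))
    row["AsP"] = assortativity_label(g, _majority_label(g, pf_sets))
    row["Tol"] = attack_tolerance(g, attack_fraction)
    row["KI"] = degree_domain_correlation(g, flags)
    return pd.Series(row)
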