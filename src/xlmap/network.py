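"""Cross-link-based protein-protein interaction network and its statistics.

The network's nodes are protein accessions; an undirected edge joins two
proteins connected by at least one interprotein cross-link, with the number of
unique links and supporting samples kept as edge metadata. Clustering,
betweenness, and modularity all operate on the UNWEIGHTED graph; the counts are
metadata only.

Statistics follow the usual playbook for interaction networks: largest
connected component ("core") plus small side modules, a power-law fit of the
degree distribution, deterministic Girvan-Newman edge-betweenness clustering
scored by Newman-Girvan modularity, and permutation nulls built by
degree-preserving double-edge-swap rewiring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import networkx as nx
from scipy import stats

from xlmap.errors import DataError, DegenerateInputError
from xlmap.io import AnnotationSet, CrossLinkDataset

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Graph construction and components
# ---------------------------------------------------------------------------


def build_network(
    ds: CrossLinkDataset,
    exclude: Iterable[str] = (),
    include_ambiguous: bool = False,
) -> nx.Graph:
    """Build the protein-level interaction graph from interprotein links.

    Ambiguous shared-peptide links are excluded by default. ``exclude`` drops
    the listed accessions and every edge touching them (e.g. a hyper-connected
    hub such as myelin basic protein).
    """
    excluded = set(exclude)
    g = nx.Graph(name=ds.name)
    for link in ds.inter_links(include_ambiguous=include_ambiguous):
        a, b = link.pair
        if a in excluded or b in excluded:
            continue
        if g.has_edge(a, b):
            g[a][b]["weight"] += 1
            g[a][b]["samples"] |= set(link.samples)
        else:
            g.add_edge(a, b, weight=1, samples=set(link.samples))
    for _, _, data in g.edges(data=True):
        data["sample_count"] = len(data["samples"])
    return g


def components(graph: nx.Graph, k: int = 3) -> tuple[set, list[set], set]:
    """Split a graph into core component, side modules, and remainder.

    The core is the largest connected component (ties broken toward the
    component containing the lexicographically smallest member, logged); side
    modules are the other components with at least ``k`` nodes (default 3);
    every remaining node lands in the remainder set.
    """
    if k < 1:
        raise DataError("k must be >= 1")
    comps = [set(c) for c in nx.connected_components(graph)]
    if not comps:
        return set(), [], set()
    comps.sort(key=lambda c: (-len(c), min(c)))
    if len(comps) > 1 and len(comps[0]) == len(comps[1]):
        logger.info("component size tie (%d nodes); core chosen by smallest member %r",
                    len(comps[0]), min(comps[0]))
    core = comps[0]
    side = [c for c in comps[1:] if len(c) >= k]
    remainder = set().union(*comps[1:]) - set().union(set(), *side) if len(comps) > 1 else set()
    return core, side, remainder


# ---------------------------------------------------------------------------
# Degree distribution
# ---------------------------------------------------------------------------


def degree_powerlaw_fit(graph: nx.Graph) -> tuple[float, float, float]:
    """Least-squares line through (log10 degree, log10 frequency).

    Returns ``(slope, intercept, r_squared)`` over degrees with nonzero
    frequency (degree-0 nodes ignored). Scale-free networks show a straight
    log-log fit with negative slope. Raises on fewer than 3 distinct degrees.
    """
    degrees = [d for _, d in graph.degree() if d > 0]
    values, counts = np.unique(degrees, return_counts=True)
    if len(values) < 3:
        raise DegenerateInputError(
            f"degree distribution has {len(values)} distinct value(s); need >= 3 for a fit"
        )
    x = np.log10(values)
    y = np.log10(counts)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), float(r2)


# ---------------------------------------------------------------------------
# Modularity and Girvan-Newman clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusterPartition:
    """Node -> cluster-id assignment with its Newman-Girvan modularity."""

    assignment: dict[str, int]
    modularity: float

    def clusters(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for node, cid in self.assignment.items():
            out.setdefault(cid, set()).add(node)
        return out

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))


def modularity(graph: nx.Graph, partition: Mapping[str, int] | Sequence[set]) -> float:
    """Newman-Girvan modularity Q = sum_c (e_c/m - (d_c/2m)^2), unweighted.

    ``e_c`` is the number of within-community edges, ``d_c`` the total degree
    of community ``c``, ``m`` the edge count. Every node must be covered.
    """
    if isinstance(partition, Mapping):
        assignment = dict(partition)
    else:
        assignment = {n: i for i, com in enumerate(partition) for n in com}
    missing = set(graph.nodes) - set(assignment)
    if missing:
        raise DataError(f"partition does not cover node(s) {sorted(missing)[:5]}")
    m = graph.number_of_edges()
    if m == 0:
        return 0.0
    e: dict[int, int] = {}
    d: dict[int, int] = {}
    for u, v in graph.edges():
        if assignment[u] == assignment[v]:
            e[assignment[u]] = e.get(assignment[u], 0) + 1
    for n, deg in graph.degree():
        d[assignment[n]] = d.get(assignment[n], 0) + deg
    return float(sum(e.get(c, 0) / m - (d[c] / (2 * m)) ** 2 for c in d))


def _canonical_max_edge(centrality: Mapping[tuple, float]) -> tuple:
    """Highest-betweenness edge; ties -> lexicographically smallest edge."""
    best_edge = None
    best_val = -np.inf
    for (u, v), val in centrality.items():
        edge = (u, v) if u <= v else (v, u)
        if val > best_val + 1e-12 or (abs(val - best_val) <= 1e-12 and (best_edge is None or edge < best_edge)):
            best_edge, best_val = edge, val
    return best_edge


def girvan_newman_cluster(core: nx.Graph) -> ClusterPartition:
    """Deterministic edge-betweenness (Girvan-Newman) clustering.

    Repeatedly removes the edge with the highest (unweighted) edge-betweenness
    centrality — ties broken toward the lexicographically smallest edge — and
    records the component partition each time the component count grows.
    Returns the partition with maximum modularity evaluated on the ORIGINAL
    graph; the trivial single-community partition (Q = 0) is a candidate, so a
    graph with no community structure comes back as one cluster.
    """
    if core.number_of_nodes() == 0:
        raise DataError("empty graph")
    if not nx.is_connected(core):
        raise DataError("girvan_newman_cluster expects a connected graph (pass the core component)")
    work = nx.Graph(core.edges())
    work.add_nodes_from(core.nodes())

    def as_partition(g: nx.Graph) -> dict[str, int]:
        comps = sorted(nx.connected_components(g), key=lambda c: min(c))
        return {n: i for i, comp in enumerate(comps) for n in comp}

    best_assignment = as_partition(work)
    best_q = modularity(core, best_assignment)
    n_comp = nx.number_connected_components(work)
    while work.number_of_edges() > 0:
        centrality = nx.edge_betweenness_centrality(work, weight=None)
        work.remove_edge(*_canonical_max_edge(centrality))
        new_n = nx.number_connected_components(work)
        if new_n > n_comp:
            n_comp = new_n
            assignment = as_partition(work)
            q = modularity(core, assignment)
            if q > best_q + 1e-12:
                best_q, best_assignment = q, assignment
    return ClusterPartition(best_assignment, best_q)


# ---------------------------------------------------------------------------
# Degree-preserving rewired nulls
# ---------------------------------------------------------------------------


@dataclass
class NullEnsemble:
    """Rewired copies of a graph sharing its exact degree sequence."""

    graphs: list[nx.Graph]
    seed: int

    @property
    def n_iterations(self) -> int:
        return len(self.graphs)


def rewire_null(graph: nx.Graph, n_iter: int = 100, seed: int = 0,
                swaps_per_edge: int = 10) -> NullEnsemble:
    """Degree-preserving permutation null by double-edge swaps.

    Each of the ``n_iter`` permutations starts from the original graph and
    attempts ``swaps_per_edge * |E|`` double-edge swaps; a swap replacing
    (u,v),(x,y) with (u,x),(v,y) is rejected if it would create a self-loop or
    a multi-edge. The degree sequence is preserved exactly by construction.
    """
    if graph.number_of_edges() < 2:
        raise DataError("rewiring needs at least 2 edges")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_iter):
        g = nx.Graph(graph.edges())
        g.add_nodes_from(graph.nodes())
        edges = [tuple(e) for e in g.edges()]
        n_attempts = swaps_per_edge * len(edges)
        for _ in range(n_attempts):
            i, j = rng.integers(0, len(edges), size=2)
            if i == j:
                continue
            (u, v), (x, y) = edges[i], edges[j]
            if rng.integers(0, 2):
                x, y = y, x
            if u == x or v == y:
                continue
            if g.has_edge(u, x) or g.has_edge(v, y):
                continue
            g.remove_edge(u, v)
            g.remove_edge(x, y)
            g.add_edge(u, x)
            g.add_edge(v, y)
            edges[i], edges[j] = (u, x), (v, y)
        out.append(g)
    return NullEnsemble(out, seed)


# ---------------------------------------------------------------------------
# Annotation-based connectivity statistics
# ---------------------------------------------------------------------------


@dataclass
class CoannotationResult:
    per_term_observed: dict[str, float]
    per_term_null: dict[str, np.ndarray]
    ks_statistic: float
    ks_pvalue: float
    skipped_terms: list[str] = field(default_factory=list)


def coannotation_fraction(graph: nx.Graph, annotated: set[str]) -> float:
    """Fraction of edges whose two endpoints are both in ``annotated``."""
    m = graph.number_of_edges()
    if m == 0:
        return 0.0
    return sum((u in annotated) and (v in annotated) for u, v in graph.edges()) / m


def coannotation_statistic(
    graph: nx.Graph,
    annot: AnnotationSet,
    null: NullEnsemble,
    terms: Iterable[str] | None = None,
    min_proteins: int = 50,
) -> CoannotationResult:
    """Observed vs null co-annotation of network edges, per term.

    For each term (restricted, by default, to terms annotating more than
    ``min_proteins`` proteins inside the graph), the statistic is the fraction
    of edges whose endpoints share the term; the null recomputes it on each
    rewired graph. The final two-sample Kolmogorov-Smirnov test compares the
    observed values across terms against the pooled null values.
    """
    nodes = set(graph.nodes)
    if terms is None:
        terms = [t for t in annot if len(annot[t] & nodes) > min_proteins]
    observed: dict[str, float] = {}
    nulls: dict[str, np.ndarray] = {}
    skipped = []
    for term in terms:
        annotated = annot[term] & nodes
        if not annotated:
            logger.warning("term %r has no annotated node in the graph; skipped", term)
            skipped.append(term)
            continue
        observed[term] = coannotation_fraction(graph, annot[term])
        nulls[term] = np.array([coannotation_fraction(g, annot[term]) for g in null.graphs])
    if not observed:
        raise DegenerateInputError("no term usable for the co-annotation statistic")
    obs_values = np.array(list(observed.values()))
    null_values = np.concatenate(list(nulls.values()))
    ks = stats.ks_2samp(obs_values, null_values, alternative="two-sided")
    return CoannotationResult(observed, nulls, float(ks.statistic), float(ks.pvalue), skipped)


def path_distance_statistic(
    graph: nx.Graph,
    annot: AnnotationSet,
    term: str,
) -> dict:
    """Mean shortest-path length within vs out of a term's annotated set.

    Computes the mean unweighted shortest-path distance over all annotated
    pairs, and over all annotated-to-nonannotated pairs; unreachable pairs are
    excluded and counted.
    """
    annotated = sorted(annot[term] & set(graph.nodes))
    if len(annotated) < 2:
        raise DegenerateInputError(f"term {term!r} has < 2 annotated nodes in the graph")
    others = sorted(set(graph.nodes) - set(annotated))
    within, between = [], []
    n_unreach_within = n_unreach_between = 0
    for i, a in enumerate(annotated):
        dists = nx.single_source_shortest_path_length(graph, a)
        for b in annotated[i + 1:]:
            if b in dists:
                within.append(dists[b])
            else:
                n_unreach_within += 1
        for b in others:
            if b in dists:
                between.append(dists[b])
            else:
                n_unreach_between += 1
    return {
        "term": term,
        "mean_within": float(np.mean(within)) if within else None,
        "mean_between": float(np.mean(between)) if between else None,
        "n_within": len(within),
        "n_between": len(between),
        "n_unreachable_within": n_unreach_within,
        "n_unreachable_between": n_unreach_between,
    }


# ---------------------------------------------------------------------------
# Term enrichment
# ---------------------------------------------------------------------------


def term_enrichment(
    cluster: Iterable[str],
    annot: AnnotationSet,
    background: Iterable[str],
) -> "pd.DataFrame":
    """One-sided Fisher enrichment of annotation terms in a node cluster.

    The 2x2 table counts cluster/background membership against term
    membership; p-values are one-sided ("greater") Fisher's exact tests, with
    Benjamini-Hochberg adjustment across terms. Background must contain the
    cluster.
    """
    import pandas as pd
    from statsmodels.stats.multitest import multipletests

    cluster = set(cluster)
    background = set(background)
    if not background:
        raise DataError("empty background")
    if not cluster <= background:
        raise DataError("background must contain the cluster")
    rows = []
    for term in annot:
        annotated = annot[term] & background
        if not annotated:
            continue
        a = len(cluster & annotated)
        b = len(cluster) - a
        c = len(annotated) - a
        d = len(background) - len(cluster) - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        frac_cluster = a / len(cluster) if cluster else 0.0
        frac_bg = len(annotated) / len(background)
        fold = frac_cluster / frac_bg if frac_bg > 0 else np.inf
        rows.append({"term": term, "n_cluster": a, "n_background": len(annotated),
                     "fold": fold, "pvalue": float(p)})
    df = pd.DataFrame(rows, columns=["term", "n_cluster", "n_background", "fold", "pvalue"])
    if len(df):
        df["qvalue"] = multipletests(df["pvalue"], method="fdr_bh")[1]
        df = df.sort_values("pvalue", kind="stable").reset_index(drop=True)
    else:
        df["qvalue"] = []
    return df
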