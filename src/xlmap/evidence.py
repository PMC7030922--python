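"""Overlap of cross-linked protein pairs with external PPI evidence, and
replicate-agreement statistics.

Evidence records from the three common sources are collapsed onto explicit
confidence tiers:

* STRING combined score — < 400 low, 400-700 (right-open) medium, >= 700 high;
* InWEB final score — absent or < 0.2 low, 0.2-0.7 (right-open) medium,
  >= 0.7 high;
* BioGRID — low-throughput experimental evidence high, everything else low.

A protein pair counts as "known" when any record matches it, and as
high-confidence when its best record is high in at least one source.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import networkx as nx
from scipy import stats

from xlmap.errors import DataError, DegenerateInputError
from xlmap.io import CrossLinkDataset, EvidenceRecord, ProteinRecord
from xlmap.network import ClusterPartition, NullEnsemble

TIER_ORDER = {"low": 0, "medium": 1, "high": 2}


def classify_tier(record: EvidenceRecord) -> str:
    """Confidence tier of one evidence record under the source-specific rules."""
    if record.source == "string":
        if record.score is None or record.score < 400:
            return "low"
        return "medium" if record.score < 700 else "high"
    if record.source == "inweb":
        if record.score is None or record.score < 0.2:
            return "low"
        return "medium" if record.score < 0.7 else "high"
    if record.source == "biogrid":
        return "high" if record.low_throughput else "low"
    raise DataError(f"unknown evidence source {record.source!r}")


@dataclass
class OverlapReport:
    """Database overlap of a set of cross-linked protein pairs."""

    n_pairs: int
    n_in_any_db: int
    n_high_confidence: int
    per_pair_tier: dict[tuple[str, str], str | None]
    per_pair_xl_count: dict[tuple[str, str], int] = field(default_factory=dict)
    xl_counts_in_db: list[int] = field(default_factory=list)
    xl_counts_not_in_db: list[int] = field(default_factory=list)
    abundance_median_in_db: float | None = None
    abundance_median_not_in_db: float | None = None

    @property
    def fraction_in_any_db(self) -> float:
        return self.n_in_any_db / self.n_pairs if self.n_pairs else 0.0

    @property
    def fraction_high_confidence(self) -> float:
        return self.n_high_confidence / self.n_pairs if self.n_pairs else 0.0


def pair_overlap(
    pairs: Iterable[tuple[str, str]],
    evidence: Sequence[EvidenceRecord],
    xl_counts: Mapping[tuple[str, str], int] | None = None,
    abundances: Mapping[str, float] | None = None,
) -> OverlapReport:
    """Overlap of cross-linked pairs with the evidence database.

    A pair is in-DB when any record matches it; its tier is the best tier over
    matching records. Optional ``xl_counts`` (unique cross-links per pair)
    yield the in-DB vs not-in-DB count distributions, and ``abundances``
    (per protein) yield median min-partner abundances per group.
    """
    pairs = sorted({tuple(sorted(p)) for p in pairs})
    by_pair: dict[tuple[str, str], str] = {}
    for rec in evidence:
        tier = classify_tier(rec)
        prev = by_pair.get(rec.pair)
        if prev is None or TIER_ORDER[tier] > TIER_ORDER[prev]:
            by_pair[rec.pair] = tier
    per_pair_tier = {p: by_pair.get(p) for p in pairs}
    in_db = [p for p in pairs if per_pair_tier[p] is not None]
    high = [p for p in pairs if per_pair_tier[p] == "high"]

    per_pair_xl = {p: int(xl_counts[p]) for p in pairs if xl_counts and p in xl_counts}
    xl_in = [per_pair_xl[p] for p in in_db if p in per_pair_xl]
    xl_out = [per_pair_xl[p] for p in pairs if per_pair_tier[p] is None and p in per_pair_xl]

    def _median_abund(group: list[tuple[str, str]]) -> float | None:
        if not abundances:
            return None
        vals = [
            min(abundances[a], abundances[b])
            for a, b in group
            if a in abundances and b in abundances
        ]
        return float(np.median(vals)) if vals else None

    return OverlapReport(
        n_pairs=len(pairs),
        n_in_any_db=len(in_db),
        n_high_confidence=len(high),
        per_pair_tier=per_pair_tier,
        per_pair_xl_count=per_pair_xl,
        xl_counts_in_db=xl_in,
        xl_counts_not_in_db=xl_out,
        abundance_median_in_db=_median_abund(high),
        abundance_median_not_in_db=_median_abund([p for p in pairs if per_pair_tier[p] is None]),
    )


@dataclass
class ReplicationSummary:
    """Per-pair detection multiplicity across replicate datasets."""

    n_reps: int
    multiplicity: dict[tuple[str, str], int]
    histogram: dict[int, int]  # multiplicity -> number of pairs
    abundance_medians: dict[int, float] = field(default_factory=dict)

    @property
    def n_pairs(self) -> int:
        return len(self.multiplicity)


def replicate_overlap(
    datasets: Sequence[CrossLinkDataset],
    abundances: Mapping[str, float] | None = None,
) -> ReplicationSummary:
    """Count, per interprotein pair, in how many replicates it was detected.

    Order of the datasets does not matter. With ``abundances`` supplied, the
    median min-partner abundance is reported per multiplicity class.
    """
    if len(datasets) < 2:
        raise DataError("replicate_overlap needs at least 2 datasets")
    multiplicity: dict[tuple[str, str], int] = {}
    for ds in datasets:
        for pair in ds.protein_pairs(include_ambiguous=False):
            multiplicity[pair] = multiplicity.get(pair, 0) + 1
    histogram = {m: 0 for m in range(1, len(datasets) + 1)}
    for m in multiplicity.values():
        histogram[m] += 1
    medians: dict[int, float] = {}
    if abundances:
        for m in histogram:
            vals = [
                min(abundances[a], abundances[b])
                for (a, b), mult in multiplicity.items()
                if mult == m and a in abundances and b in abundances
            ]
            if vals:
                medians[m] = float(np.median(vals))
    return ReplicationSummary(len(datasets), multiplicity, histogram, medians)


def neighbor_agreement(net_a: nx.Graph, net_b: nx.Graph) -> tuple[float, float, float]:
    """How well the edges of ``net_a`` are explained by ``net_b``.

    Restricted to nodes present in both graphs; each ``net_a`` edge with both
    ends shared is *direct* when it is also an edge of ``net_b``, *indirect*
    when its endpoints share at least one common neighbor in ``net_b``, and
    *unconnected* otherwise. Returns the three fractions (they sum to 1).
    """
    shared = set(net_a.nodes) & set(net_b.nodes)
    if not shared:
        raise DataError("the two networks share no node")
    n_direct = n_indirect = n_unconnected = 0
    for u, v in net_a.edges():
        if u not in shared or v not in shared:
            continue
        if net_b.has_edge(u, v):
            n_direct += 1
        elif set(net_b.neighbors(u)) & set(net_b.neighbors(v)):
            n_indirect += 1
        else:
            n_unconnected += 1
    total = n_direct + n_indirect + n_unconnected
    if total == 0:
        raise DegenerateInputError("no evaluable edge between the shared nodes")
    return n_direct / total, n_indirect / total, n_unconnected / total


@dataclass
class ClusterConsistencyResult:
    per_node_fraction: dict[str, float]
    null_fractions: np.ndarray
    ks_statistic: float
    ks_pvalue: float


def cluster_consistency(
    net_new: nx.Graph,
    partition_old: ClusterPartition | Mapping[str, int],
    null: NullEnsemble,
) -> ClusterConsistencyResult:
    """Do the edges of a new network respect an older network's clusters?

    For every node of ``net_new`` carrying an old-cluster label and having at
    least one labelled neighbor, the statistic is the fraction of its labelled
    neighbors assigned to the same old cluster. The null pools the same
    statistic over the rewired copies of ``net_new``; a two-sample
    Kolmogorov-Smirnov test compares the two distributions.
    """
    labels = partition_old.assignment if isinstance(partition_old, ClusterPartition) else dict(partition_old)
    if not set(net_new.nodes) & set(labels):
        raise DataError("partition covers no node of the new network")

    def fractions(g: nx.Graph) -> dict[str, float]:
        out = {}
        for node in g.nodes:
            if node not in labels:
                continue
            neigh = [n for n in g.neighbors(node) if n in labels]
            if not neigh:
                continue
            out[node] = sum(labels[n] == labels[node] for n in neigh) / len(neigh)
        return out

    observed = fractions(net_new)
    if not observed:
        raise DegenerateInputError("no labelled node with labelled neighbors")
    null_vals = np.array([v for g in null.graphs for v in fractions(g).values()])
    if null_vals.size == 0:
        raise DegenerateInputError("null ensemble yields no labelled neighborhoods")
    ks = stats.ks_2samp(np.array(list(observed.values())), null_vals, alternative="two-sided")
    return ClusterConsistencyResult(observed, null_vals, float(ks.statistic), float(ks.pvalue))


def abundance_lysine_correlation(
    ds: CrossLinkDataset,
    abundances: Mapping[str, float],
    sequences: Mapping[str, ProteinRecord],
) -> tuple[float, float, int]:
    """Pearson R^2 of cross-linked-lysine count vs lysine-corrected abundance.

    Per protein: the number of distinct cross-linked lysines, against its
    abundance divided by its total lysine count, both on log10 scales.
    Returns ``(r_squared, pearson_r, n_proteins)``.
    """
    linked: dict[str, set[int]] = {}
    for link in ds:
        linked.setdefault(link.protein_a, set()).add(link.pos_a)
        linked.setdefault(link.protein_b, set()).add(link.pos_b)
    xs, ys = [], []
    for acc, positions in sorted(linked.items()):
        if acc not in abundances or acc not in sequences:
            continue
        n_lys = len(sequences[acc].lysine_positions())
        if n_lys == 0 or abundances[acc] <= 0:
            continue
        xs.append(np.log10(abundances[acc] / n_lys))
        ys.append(np.log10(len(positions)))
    if len(xs) < 3:
        raise DegenerateInputError(f"only {len(xs)} proteins usable; need >= 3")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise DegenerateInputError("constant variable; correlation undefined")
    r = stats.pearsonr(xs, ys).statistic
    return float(r**2), float(r), len(xs)
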