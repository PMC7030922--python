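"""Ground-truth synthetic worlds for every analysis stage.

Each generator draws from a seeded :class:`numpy.random.Generator`, so the same
seed reproduces a world bit-for-bit. The generators emulate the statistical
structure the downstream stages assume — cross-links drawn from a known
structure with a controlled violation rate, topology-labelled links with a
controlled cross-side rate, replicate detection driven by protein abundance,
planted-module interaction graphs with module-aligned annotation terms, scored
evidence databases, and peptide arrays with planted binding regions — while
recording the ground truth needed for parameter-recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import networkx as nx
from scipy.special import expit

from xlmap.errors import DataError, XLMapError
from xlmap.io import (
    AnnotationSet,
    ChainMap,
    CrossLink,
    CrossLinkDataset,
    EvidenceRecord,
    ProteinRecord,
    Residue,
    StructureModel,
    TopologyAnnotation,
    build_chain_map,
    write_abundance_table,
    write_annotation_table,
    write_crosslink_table,
    write_evidence_table,
    write_fasta,
    write_topology_table,
)
from xlmap.restraints import DEFAULT_THRESHOLD, ca_distance

AA_ALPHABET = "ACDEFGHILMNPQRSTVWY"  # K assigned separately
STEP_LENGTH = 3.8  # A, consecutive Ca-Ca distance
MIN_SEPARATION = 4.0  # A, non-adjacent clash limit
THREE_LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR", "X": "UNK",
}


# ---------------------------------------------------------------------------
# Toy structures
# ---------------------------------------------------------------------------


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def make_toy_complex(
    n_chains: int,
    n_res: int,
    seed: int,
    lysine_rate: float = 0.15,
) -> tuple[StructureModel, dict[str, ProteinRecord]]:
    """Random protein-like complex: one self-avoiding walk per chain.

    Consecutive Ca positions are exactly 3.8 A apart; every non-adjacent
    residue pair (within and across chains) is at least 4.0 A apart. Chains
    are started 6 A away from the previous chain's surface so the complex is
    connected but non-overlapping. About ``lysine_rate`` of residues are
    lysine (default 15%, a typical lysine frequency), the rest drawn uniformly
    from the other amino acids.
    """
    if n_chains < 1:
        raise DataError("n_chains must be >= 1")
    if n_res < 5:
        raise DataError("n_res must be >= 5")
    rng = np.random.default_rng(seed)
    all_points: list[np.ndarray] = []
    chains: dict[str, list[Residue]] = {}
    records: dict[str, ProteinRecord] = {}
    for ci in range(n_chains):
        chain_id = chr(ord("A") + ci)
        accession = f"PROT{ci + 1}"
        for attempt in range(60):
            if not all_points:
                origin = np.zeros(3)
            else:
                anchor = max(all_points, key=lambda p: p[0])
                origin = anchor + np.array([6.0, 0.0, 0.0])
            points = [origin]
            ok = True
            while len(points) < n_res and ok:
                for _ in range(120):
                    cand = points[-1] + STEP_LENGTH * _random_unit(rng)
                    near = points[:-1] + all_points
                    if all(np.linalg.norm(cand - p) >= MIN_SEPARATION for p in near):
                        points.append(cand)
                        break
                else:
                    ok = False
            if ok:
                break
        else:
            raise XLMapError(
                f"self-avoiding walk failed for chain {chain_id}; try a smaller n_res"
            )
        seq = "".join(
            "K" if rng.random() < lysine_rate else AA_ALPHABET[rng.integers(len(AA_ALPHABET))]
            for _ in range(n_res)
        )
        chains[chain_id] = [
            Residue(i + 1, seq[i], tuple(points[i])) for i in range(n_res)
        ]
        records[accession] = ProteinRecord(accession, seq)
        all_points.extend(points)
    model = StructureModel(f"toy{n_chains}x{n_res}", chains)
    return model, records


def identity_chain_maps(
    model: StructureModel, records: Mapping[str, ProteinRecord]
) -> list[ChainMap]:
    """One chain map per (record, chain) pair, in generation order."""
    maps = []
    for (acc, rec), chain_id in zip(sorted(records.items()), sorted(model.chains)):
        maps.append(build_chain_map(rec, model, chain_id))
    return maps


def structure_to_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a Ca-only model as a minimal PDB file."""
    import gemmi

    st = gemmi.Structure()
    st.name = model.structure_id
    gm = gemmi.Model("1")
    for chain_id, residues in model.chains.items():
        chain = gemmi.Chain(chain_id)
        for res in residues:
            if not res.present:
                continue
            gr = gemmi.Residue()
            gr.name = THREE_LETTER.get(res.amino_acid, "UNK")
            gr.seqid = gemmi.SeqId(res.auth_number, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*res.ca)
            atom.occ = 1.0
            gr.add_atom(atom)
            chain.add_residue(gr)
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Simulated cross-links on a structure
# ---------------------------------------------------------------------------


def _lysine_nodes(model: StructureModel, maps: Sequence[ChainMap]) -> list[tuple[str, int, str, int]]:
    """(accession, seq position, chain, auth number) of every mapped lysine."""
    nodes = []
    for m in maps:
        residues = model.chains[m.chain_id]
        for pos, idx in sorted(m.mapping.items()):
            res = residues[idx]
            if res.amino_acid == "K" and res.present:
                nodes.append((m.accession, pos, m.chain_id, res.auth_number))
    return nodes


def simulate_crosslinks(
    model: StructureModel,
    maps: Sequence[ChainMap],
    n_links: int,
    violation_rate: float,
    threshold: float = DEFAULT_THRESHOLD,
    seed: int = 0,
) -> tuple[CrossLinkDataset, dict]:
    """Draw cross-links from a structure with a controlled violation rate.

    The number of violating links is Binomial(n_links, violation_rate); those
    are drawn uniformly (without replacement) from lysine pairs with Ca-Ca
    distance beyond the threshold, the rest from pairs within it. Returns the
    dataset and the ground truth (per-link labels and the realised rate).
    """
    if not 0 <= violation_rate <= 1:
        raise DataError("violation_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    nodes = _lysine_nodes(model, maps)
    within, beyond = [], []
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            a, b = nodes[i], nodes[j]
            d = ca_distance(model, (a[2], a[3]), (b[2], b[3]))
            if d is None:
                continue
            (within if d <= threshold else beyond).append((a, b))
    n_viol = int(rng.binomial(n_links, violation_rate))
    n_sat = n_links - n_viol
    if n_sat > 0 and len(within) < n_sat:
        raise DataError(f"only {len(within)} satisfiable lysine pairs; need {n_sat}")
    if n_viol > 0 and len(beyond) < n_viol:
        raise DataError(f"only {len(beyond)} violating lysine pairs; need {n_viol}")
    chosen: list[tuple[tuple, tuple, bool]] = []
    for pool, count, violates in ((within, n_sat, False), (beyond, n_viol, True)):
        if count:
            idx = rng.choice(len(pool), size=count, replace=False)
            chosen.extend((pool[i][0], pool[i][1], violates) for i in idx)
    links, labels = [], {}
    for a, b, violates in chosen:
        link = CrossLink(a[0], a[1], b[0], b[1], fdr=0.005, samples=frozenset({"sim"}))
        links.append(link)
        labels[link.key] = violates
    ds = CrossLinkDataset(links, name=f"sim_v{violation_rate:g}")
    truth = {
        "violation_rate": violation_rate,
        "realized_violation_rate": n_viol / n_links if n_links else 0.0,
        "threshold": threshold,
        "labels": labels,
    }
    return ds, truth


# ---------------------------------------------------------------------------
# Topology-labelled links
# ---------------------------------------------------------------------------


def simulate_topology_world(
    n_proteins: int,
    n_links: int,
    cross_side_rate: float,
    seed: int = 0,
    protein_length: int = 400,
) -> tuple[CrossLinkDataset, dict[str, TopologyAnnotation], dict]:
    """Membrane proteins with annotated topology plus links with a controlled
    cytoplasmic<->extracellular cross-side rate.

    Each protein gets a cytoplasmic region, a transmembrane segment, and an
    extracellular region. Each link independently crosses sides with
    probability ``cross_side_rate``; consistent links put both endpoints on
    the same (random) side.
    """
    if not 0 <= cross_side_rate <= 1:
        raise DataError("cross_side_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    topo: dict[str, TopologyAnnotation] = {}
    regions: dict[str, dict[str, tuple[int, int]]] = {}
    for i in range(n_proteins):
        acc = f"MEM{i + 1:03d}"
        tm_start = int(rng.integers(protein_length // 3, 2 * protein_length // 3))
        tm_end = tm_start + 20
        regions[acc] = {
            "cytoplasmic": (1, tm_start - 1),
            "extracellular": (tm_end + 1, protein_length),
        }
        topo[acc] = TopologyAnnotation(
            acc,
            (
                (1, tm_start - 1, "cytoplasmic"),
                (tm_start, tm_end, "transmembrane"),
                (tm_end + 1, protein_length, "extracellular"),
            ),
        )
    accs = sorted(regions)
    links: list[CrossLink] = []
    labels: dict[tuple, bool] = {}
    used: set[tuple] = set()
    n_cross = 0
    while len(links) < n_links:
        crosses = bool(rng.random() < cross_side_rate)
        a, b = rng.choice(accs, size=2, replace=False)
        if crosses:
            side_a, side_b = ("cytoplasmic", "extracellular") if rng.random() < 0.5 else (
                "extracellular", "cytoplasmic")
        else:
            side_a = side_b = "cytoplasmic" if rng.random() < 0.5 else "extracellular"
        lo_a, hi_a = regions[a][side_a]
        lo_b, hi_b = regions[b][side_b]
        link = CrossLink(
            a, int(rng.integers(lo_a, hi_a + 1)),
            b, int(rng.integers(lo_b, hi_b + 1)),
            fdr=0.005, samples=frozenset({"sim"}),
        )
        if link.key in used:
            continue
        used.add(link.key)
        links.append(link)
        labels[link.key] = crosses
        n_cross += crosses
    ds = CrossLinkDataset(links, name=f"topo_r{cross_side_rate:g}")
    truth = {
        "cross_side_rate": cross_side_rate,
        "realized_cross_side_rate": n_cross / n_links if n_links else 0.0,
        "labels": labels,
    }
    return ds, topo, truth


# ---------------------------------------------------------------------------
# Abundance-driven replicate detection
# ---------------------------------------------------------------------------


def simulate_replicates(
    pairs: Sequence[tuple[str, str]],
    abundances: Mapping[str, float],
    n_reps: int,
    slope: float,
    intercept: float = 0.0,
    seed: int = 0,
) -> tuple[list[CrossLinkDataset], dict]:
    """Replicate datasets whose detection probability grows with abundance.

    Each pair is detected in each replicate independently with probability
    ``logistic(intercept + slope * log10(min partner abundance))`` — detection
    of a pair is limited by its scarcer protein. The detection-probability
    model is a phenomenological stand-in for abundance-driven MS detection;
    no mechanistic form is implied.
    """
    for acc in {a for p in pairs for a in p}:
        if abundances.get(acc, 0.0) <= 0:
            raise DataError(f"abundance of {acc} must be positive")
    rng = np.random.default_rng(seed)
    probs = {
        tuple(sorted(p)): float(expit(intercept + slope * np.log10(min(abundances[p[0]], abundances[p[1]]))))
        for p in pairs
    }
    datasets = []
    detections: dict[tuple, int] = {p: 0 for p in probs}
    for r in range(n_reps):
        links = []
        for (a, b), p in sorted(probs.items()):
            if rng.random() < p:
                links.append(
                    CrossLink(a, 10, b, 10, fdr=0.005, samples=frozenset({f"rep{r + 1}"}))
                )
                detections[(a, b)] += 1
        datasets.append(CrossLinkDataset(links, name=f"rep{r + 1}"))
    truth = {"slope": slope, "intercept": intercept,
             "probabilities": probs, "detections": detections}
    return datasets, truth


# ---------------------------------------------------------------------------
# Planted-partition networks with module-aligned annotations
# ---------------------------------------------------------------------------


def make_planted_network(
    k: int,
    size: int,
    p_in: float,
    p_out: float,
    seed: int = 0,
    spill: float = 0.0,
) -> tuple[nx.Graph, dict[str, int], AnnotationSet]:
    """Planted-partition graph with one annotation term per module.

    ``k`` modules of ``size`` nodes; within-module edges appear with
    probability ``p_in``, between-module edges with ``p_out`` (must be
    smaller). Each term annotates its module's members plus a ``spill``
    fraction of outside nodes. Returns the graph, the planted node -> module
    assignment, and the annotation set.
    """
    if not p_in > p_out:
        raise DataError("p_in must exceed p_out")
    rng = np.random.default_rng(seed)
    nodes = [f"N{i:04d}" for i in range(k * size)]
    partition = {n: i // size for i, n in enumerate(nodes)}
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            p = p_in if partition[nodes[i]] == partition[nodes[j]] else p_out
            if rng.random() < p:
                g.add_edge(nodes[i], nodes[j], weight=1, sample_count=1)
    annot = AnnotationSet()
    for module in range(k):
        members = {n for n in nodes if partition[n] == module}
        outside = sorted(set(nodes) - members)
        n_spill = int(round(spill * size))
        extra = set(rng.choice(outside, size=n_spill, replace=False)) if n_spill else set()
        annot.add(f"module_{module}", members | extra)
    return g, partition, annot


# ---------------------------------------------------------------------------
# Mock evidence databases
# ---------------------------------------------------------------------------


def make_evidence_db(
    pairs: Sequence[tuple[str, str]],
    tier_mix: tuple[float, float, float],
    seed: int = 0,
) -> tuple[list[EvidenceRecord], dict[tuple[str, str], str]]:
    """Evidence records whose tiers follow a target (low, medium, high) mix.

    Each pair samples a tier from ``tier_mix`` and then a source and score
    drawn so the record classifies into that tier. BioGRID has no medium tier
    under the classification rules, so medium pairs draw from STRING or InWEB
    only.
    """
    if abs(sum(tier_mix) - 1.0) > 1e-9:
        raise DataError("tier fractions must sum to 1")
    rng = np.random.default_rng(seed)
    tiers = ("low", "medium", "high")
    records: list[EvidenceRecord] = []
    truth: dict[tuple[str, str], str] = {}
    for a, b in pairs:
        tier = tiers[rng.choice(3, p=tier_mix)]
        source = ("string", "inweb")[rng.integers(2)] if tier == "medium" else \
                 ("string", "inweb", "biogrid")[rng.integers(3)]
        score: float | None = None
        low_throughput = False
        if source == "string":
            score = float({
                "low": rng.uniform(50, 400),
                "medium": rng.uniform(400, 700),
                "high": rng.uniform(700, 1000),
            }[tier])
        elif source == "inweb":
            if tier == "low":
                score = None if rng.random() < 0.5 else float(rng.uniform(0.0, 0.2))
            elif tier == "medium":
                score = float(rng.uniform(0.2, 0.7))
            else:
                score = float(rng.uniform(0.7, 1.0))
        else:  # biogrid
            low_throughput = tier == "high"
        rec = EvidenceRecord(a, b, source, score, low_throughput)
        records.append(rec)
        truth[rec.pair] = tier
    return records, truth


# ---------------------------------------------------------------------------
# Synthetic peptide arrays
# ---------------------------------------------------------------------------


def make_array_experiment(
    target_length: int,
    true_regions: Sequence[tuple[int, int]],
    amplitude: float,
    noise_sd: float,
    seed: int = 0,
    peptide_length: int = 20,
    offset: int = 10,
    n_replicates: int = 2,
    nonspecific_amplitude: float = 0.0,
    target: str = "TARGET",
):
    """Synthetic peptide tiling array with planted binding regions.

    Spots whose peptide overlaps a true region carry normalised specific
    signal ``amplitude``; an optional nonspecific component (shared with the
    control experiment) and Gaussian noise of SD ``noise_sd`` are added on the
    normalised scale and converted back to raw fluorescence units. Returns
    ``(experiment, control_experiment, truth)``.
    """
    from xlmap.binding import ArrayExperiment

    rng = np.random.default_rng(seed)
    tiling = []
    start = 1
    while start + peptide_length - 1 <= target_length:
        tiling.append((start, start + peptide_length - 1))
        start += offset
    tiling = tuple(tiling)
    n_spots = len(tiling)
    background, pos_raw = 50.0, 1050.0  # raw units; normalised scale = /1000
    scale = pos_raw - background

    def overlaps(span: tuple[int, int]) -> bool:
        return any(span[0] <= e and s <= span[1] for s, e in true_regions)

    specific = np.array([amplitude if overlaps(t) else 0.0 for t in tiling])
    nonspecific = nonspecific_amplitude * (rng.random(n_spots) < 0.15)

    def grid(component: np.ndarray) -> np.ndarray:
        noise = rng.normal(0.0, noise_sd, size=(n_replicates, n_spots))
        return background + scale * np.clip(component + noise, 0.0, None)

    exp = ArrayExperiment(
        target=target,
        peptides=tiling,
        raw=grid(specific + nonspecific),
        background=np.full(n_replicates, background),
        positive_control=np.full(n_replicates, pos_raw),
        negative_controls=background
        + scale * np.abs(rng.normal(0.0, noise_sd / 2, size=(n_replicates, 3))),
    )
    control = ArrayExperiment(
        target=target,
        peptides=tiling,
        raw=grid(nonspecific),
        background=np.full(n_replicates, background),
        positive_control=np.full(n_replicates, pos_raw),
        negative_controls=background
        + scale * np.abs(rng.normal(0.0, noise_sd / 2, size=(n_replicates, 3))),
    )
    truth = {"regions": list(true_regions), "amplitude": amplitude,
             "tiling": tiling, "specific": specific}
    return exp, control, truth


# ---------------------------------------------------------------------------
# Whole worlds
# ---------------------------------------------------------------------------

# fixed per-generator offsets fanned out from the global seed
_SEED_OFFSETS = {
    "structure": 11,
    "crosslinks": 23,
    "topology": 37,
    "replicates": 41,
    "network": 53,
    "evidence": 67,
    "abundance": 71,
}


@dataclass
class SyntheticWorld:
    """A complete generated world plus its ground truth."""

    seed: int
    model: StructureModel
    records: dict[str, ProteinRecord]
    chain_maps: list[ChainMap]
    links: CrossLinkDataset
    topology_links: CrossLinkDataset
    topology: dict[str, TopologyAnnotation]
    replicates: list[CrossLinkDataset]
    abundances: dict[str, float]
    graph: nx.Graph
    partition: dict[str, int]
    annotations: AnnotationSet
    evidence: list[EvidenceRecord]
    truth: dict

    def write(self, outdir: str | Path) -> dict[str, str]:
        """Emit the world in the package's standard file formats."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "structure": outdir / "structure.pdb",
            "sequences": outdir / "sequences.fasta",
            "links": outdir / "links.tsv",
            "topology_links": outdir / "topology_links.tsv",
            "topology": outdir / "topology.tsv",
            "evidence": outdir / "evidence.tsv",
            "annotations": outdir / "annotations.tsv",
            "abundance": outdir / "abundance.tsv",
            "truth": outdir / "truth.json",
        }
        structure_to_pdb(self.model, paths["structure"])
        write_fasta(self.records, paths["sequences"])
        write_crosslink_table(self.links, paths["links"])
        write_crosslink_table(self.topology_links, paths["topology_links"])
        write_topology_table(self.topology, paths["topology"])
        write_evidence_table(self.evidence, paths["evidence"])
        write_annotation_table(self.annotations, paths["annotations"])
        write_abundance_table(self.abundances, paths["abundance"])
        for i, rep in enumerate(self.replicates):
            p = outdir / f"replicate{i + 1}.tsv"
            write_crosslink_table(rep, p)
            paths[f"replicate{i + 1}"] = p
        truth = {
            k: v for k, v in self.truth.items()
        }
        with open(paths["truth"], "w") as fh:
            json.dump(_jsonable(truth), fh, indent=1, sort_keys=True)
        return {k: str(v) for k, v in paths.items()}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def make_world(
    seed: int = 0,
    n_chains: int = 5,
    n_res: int = 150,
    n_links: int = 400,
    violation_rate: float = 0.01,
    cross_side_rate: float = 0.0087,
    n_topology_links: int = 1000,
    n_membrane_proteins: int = 40,
    network_modules: int = 4,
    module_size: int = 25,
    p_in: float = 0.3,
    p_out: float = 0.01,
    n_replicates: int = 3,
    detection_slope: float = 1.5,
    detection_intercept: float = -3.0,
    tier_mix: tuple[float, float, float] = (0.5, 0.3, 0.2),
    evidence_coverage: float = 0.51,
) -> SyntheticWorld:
    """Generate a full world with the conditions the analyses expect.

    Defaults mirror the regime of a high-quality cross-linking study: ~1% of
    links violating the structural restraint, ~0.9% crossing membrane sides,
    a modular interaction graph, abundance-driven replicate detection, and a
    half-known/half-novel evidence landscape.
    """
    model, records = make_toy_complex(n_chains, n_res, seed + _SEED_OFFSETS["structure"])
    maps = identity_chain_maps(model, records)
    links, xl_truth = simulate_crosslinks(
        model, maps, n_links, violation_rate, seed=seed + _SEED_OFFSETS["crosslinks"]
    )
    topo_links, topo, topo_truth = simulate_topology_world(
        n_membrane_proteins, n_topology_links, cross_side_rate,
        seed=seed + _SEED_OFFSETS["topology"],
    )
    graph, partition, annotations = make_planted_network(
        network_modules, module_size, p_in, p_out, seed=seed + _SEED_OFFSETS["network"]
    )
    rng = np.random.default_rng(seed + _SEED_OFFSETS["abundance"])
    abundances = {n: float(10 ** rng.normal(2.0, 1.0)) for n in sorted(graph.nodes)}
    pairs = sorted(tuple(sorted(e)) for e in graph.edges())
    replicates, rep_truth = simulate_replicates(
        pairs, abundances, n_replicates, detection_slope,
        intercept=detection_intercept, seed=seed + _SEED_OFFSETS["replicates"],
    )
    n_covered = int(round(evidence_coverage * len(pairs)))
    covered_idx = rng.choice(len(pairs), size=n_covered, replace=False)
    covered = [pairs[i] for i in sorted(covered_idx)]
    evidence, tier_truth = make_evidence_db(
        covered, tier_mix, seed=seed + _SEED_OFFSETS["evidence"]
    )
    truth = {
        "seed": seed,
        "violation_rate": xl_truth["violation_rate"],
        "realized_violation_rate": xl_truth["realized_violation_rate"],
        "cross_side_rate": topo_truth["cross_side_rate"],
        "realized_cross_side_rate": topo_truth["realized_cross_side_rate"],
        "partition": partition,
        "detection": {"slope": rep_truth["slope"], "intercept": rep_truth["intercept"]},
        "tiers": {f"{a}--{b}": t for (a, b), t in tier_truth.items()},
    }
    return SyntheticWorld(
        seed=seed,
        model=model,
        records=records,
        chain_maps=maps,
        links=links,
        topology_links=topo_links,
        topology=topo,
        replicates=replicates,
        abundances=abundances,
        graph=graph,
        partition=partition,
        annotations=annotations,
        evidence=evidence,
        truth=truth,
    )
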