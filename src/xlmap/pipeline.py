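"""Pipeline orchestration: run the analysis stages on files and emit reports.

The pipeline is a thin layer over the library modules: it reads the standard
input formats, runs the requested stages in dependency order, and writes a
schema-versioned JSON summary plus per-stage TSV tables. Every filter step
logs input/output row counts so the funnel is auditable, and the configuration
(including the seed) is serialised next to the results.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

from xlmap import io as xio
from xlmap import restraints, topology, network, evidence
from xlmap.errors import XLMapError

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

ALL_STAGES = ("summary", "restraints", "topology", "network", "overlap", "replicate")


@dataclass
class RunConfig:
    """Configuration of one pipeline run; serialised alongside the results."""

    links: str | None = None
    sequences: str | None = None
    structure: str | None = None
    chain_map: dict[str, str] = field(default_factory=dict)  # accession -> chain id
    topology: str | None = None
    evidence: str | None = None
    annotations: str | None = None
    abundance: str | None = None
    replicates: list[str] = field(default_factory=list)
    threshold: float = restraints.DEFAULT_THRESHOLD
    fdr_threshold: float = 0.02
    exclude: list[str] = field(default_factory=list)
    n_nulls: int = 100
    seed: int = 0
    outdir: str = "xlmap_out"
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))


def _require(config: RunConfig, attr: str, stage: str, flag: str) -> str:
    value = getattr(config, attr)
    if not value:
        raise XLMapError(f"stage {stage!r} requires {flag} (config field {attr!r})")
    return value


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write the report bundle.

    Returns the JSON-serialisable summary; writes ``summary.json``,
    ``config.json``, and per-stage TSVs under ``config.outdir``. Any stage
    error aborts with the stage name attached.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"schema_version": SCHEMA_VERSION, "seed": config.seed, "stages": {}}

    links_path = _require(config, "links", "summary", "--links")
    ds = xio.read_crosslink_table(links_path, fdr_threshold=config.fdr_threshold)

    stage = None
    try:
        for stage in config.stages:
            if stage == "summary":
                report["stages"]["summary"] = xio.dataset_summary(ds)
            elif stage == "restraints":
                structure_path = _require(config, "structure", stage, "--structure")
                seq_path = _require(config, "sequences", stage, "--sequences")
                model = xio.read_structure(structure_path)
                records = xio.read_fasta(seq_path)
                if config.chain_map:
                    pairs = [(records[a], c) for a, c in sorted(config.chain_map.items())]
                else:
                    pairs = list(zip(
                        (records[a] for a in sorted(records)), sorted(model.chains)))
                maps = [xio.build_chain_map(rec, model, cid) for rec, cid in pairs]
                summ, results = restraints.evaluate_dataset(
                    ds, [(model, maps)], threshold=config.threshold)
                restraints.write_results(results, outdir / "restraints.tsv")
                report["stages"]["restraints"] = {
                    "n_links": summ.n_links,
                    "n_mappable": summ.n_mappable,
                    "n_satisfied": summ.n_satisfied,
                    "fraction_satisfied": summ.fraction_satisfied,
                    "threshold": summ.threshold,
                    "histogram": {str(k): v for k, v in summ.histogram.items()},
                }
            elif stage == "topology":
                topo_path = _require(config, "topology", stage, "--topology")
                topo = xio.read_topology_table(topo_path)
                calls = topology.classify_dataset(ds, topo)
                topology.calls_table(calls).to_csv(outdir / "topology.tsv", sep="\t", index=False)
                n_mapped, n_violation, rate = topology.violation_rate(ds, topo)
                report["stages"]["topology"] = {
                    "n_mapped": n_mapped,
                    "n_violation": n_violation,
                    "rate_percent": round(100 * rate, 2),
                }
            elif stage == "network":
                g = network.build_network(ds, exclude=config.exclude)
                core, side, remainder = network.components(g)
                stats: dict = {
                    "n_nodes": g.number_of_nodes(),
                    "n_edges": g.number_of_edges(),
                    "core_size": len(core),
                    "side_module_sizes": sorted((len(s) for s in side), reverse=True),
                    "n_remainder": len(remainder),
                }
                if len(core) >= 3:
                    part = network.girvan_newman_cluster(g.subgraph(core).copy())
                    stats["n_clusters"] = part.n_clusters
                    stats["modularity"] = part.modularity
                    rows = [{"accession": n, "cluster": c}
                            for n, c in sorted(part.assignment.items())]
                    import pandas as pd
                    pd.DataFrame(rows).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
                    if config.annotations:
                        annot = xio.read_annotation_table(config.annotations)
                        null = network.rewire_null(
                            g.subgraph(core).copy(), config.n_nulls, seed=config.seed)
                        try:
                            co = network.coannotation_statistic(
                                g.subgraph(core).copy(), annot, null, min_proteins=0)
                            stats["coannotation_ks_p"] = co.ks_pvalue
                        except XLMapError:
                            pass
                import pandas as pd
                pd.DataFrame(
                    [{"protein_a": u, "protein_b": v, "weight": d["weight"],
                      "sample_count": d.get("sample_count", 1)}
                     for u, v, d in sorted(g.edges(data=True))]
                ).to_csv(outdir / "edges.tsv", sep="\t", index=False)
                report["stages"]["network"] = stats
            elif stage == "overlap":
                ev_path = _require(config, "evidence", stage, "--evidence")
                records = xio.read_evidence_table(ev_path)
                pairs = ds.protein_pairs()
                counts: dict = {}
                for l in ds.inter_links(include_ambiguous=False):
                    counts[l.pair] = counts.get(l.pair, 0) + 1
                abund = xio.read_abundance_table(config.abundance) if config.abundance else None
                rep = evidence.pair_overlap(pairs, records, xl_counts=counts, abundances=abund)
                report["stages"]["overlap"] = {
                    "n_pairs": rep.n_pairs,
                    "n_in_any_db": rep.n_in_any_db,
                    "n_high_confidence": rep.n_high_confidence,
                    "fraction_in_any_db": rep.fraction_in_any_db,
                    "fraction_high_confidence": rep.fraction_high_confidence,
                }
            elif stage == "replicate":
                if len(config.replicates) < 2:
                    raise XLMapError("stage 'replicate' requires >= 2 --replicates files")
                reps = [xio.read_crosslink_table(p, fdr_threshold=config.fdr_threshold)
                        for p in config.replicates]
                abund = xio.read_abundance_table(config.abundance) if config.abundance else None
                summ = evidence.replicate_overlap(reps, abundances=abund)
                report["stages"]["replicate"] = {
                    "n_reps": summ.n_reps,
                    "n_pairs": summ.n_pairs,
                    "histogram": {str(k): v for k, v in sorted(summ.histogram.items())},
                    "abundance_medians": {str(k): v for k, v in sorted(summ.abundance_medians.items())},
                }
            else:
                raise XLMapError(f"unknown stage {stage!r}")
            logger.info("stage %s done", stage)
    except XLMapError as exc:
        raise XLMapError(f"stage {stage!r} failed: {exc}") from exc

    with open(outdir / "config.json", "w") as fh:
        json.dump(asdict(config), fh, indent=1, sort_keys=True)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report


def simulate_world(outdir: str | Path, seed: int = 0, **kwargs) -> dict[str, str]:
    """Generate a synthetic world and write it in the standard input formats."""
    from xlmap.synthetic import make_world

    world = make_world(seed=seed, **kwargs)
    return world.write(outdir)
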