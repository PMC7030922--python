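"""Cross-links as Ca-Ca distance restraints on known structures.

A lysine-reactive cross-linker with a ~23.4 A spacer geometry constrains the
Euclidean Ca-Ca distance of linked residues; allowing ~10 A for in-solution
flexibility gives the default restraint of 33.4 A. Each cross-link is mapped
onto every compatible chain placement (homo-oligomers contribute one placement
per chain-copy pair) and its distance is the minimum over placements: a link is
explained if ANY copy pair satisfies it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from xlmap.io import ChainMap, CrossLink, CrossLinkDataset, StructureModel

#: spacer reach plus in-solution flexibility allowance, in Angstrom
DEFAULT_THRESHOLD = 33.4


def ca_distance(
    model: StructureModel,
    res_a: tuple[str, int],
    res_b: tuple[str, int],
) -> float | None:
    """Euclidean Ca-Ca distance between two residues, in Angstrom.

    ``res_a``/``res_b`` are ``(chain_id, auth_number)``. Returns None when
    either residue is missing or has no Ca (unmappable, never a crash).
    """
    ra = model.residue(*res_a)
    rb = model.residue(*res_b)
    if ra is None or rb is None or not ra.present or not rb.present:
        return None
    return math.dist(ra.ca, rb.ca)


@dataclass
class DistanceResult:
    """Restraint evaluation of one cross-link on one (or more) structures."""

    link: CrossLink
    distance: float | None
    placements: list[tuple[str, str, float]]
    threshold: float

    @property
    def mappable(self) -> bool:
        return self.distance is not None

    @property
    def satisfied(self) -> bool:
        return self.mappable and self.distance <= self.threshold


@dataclass
class RestraintSummary:
    """Aggregate over a dataset: counts, satisfaction fraction, histogram."""

    n_links: int
    n_mappable: int
    n_satisfied: int
    threshold: float
    bin_width: float = 5.0
    histogram: dict[float, int] = field(default_factory=dict)
    per_structure: dict[str, dict] = field(default_factory=dict)

    @property
    def fraction_satisfied(self) -> float | None:
        return self.n_satisfied / self.n_mappable if self.n_mappable else None

    @property
    def fraction_violated(self) -> float | None:
        f = self.fraction_satisfied
        return None if f is None else 1.0 - f


def evaluate_link(
    model: StructureModel,
    chain_maps: Sequence[ChainMap],
    link: CrossLink,
    threshold: float = DEFAULT_THRESHOLD,
) -> DistanceResult:
    """Evaluate one cross-link on one structure.

    Enumerates every chain placement of the two endpoints through the supplied
    chain maps (intra links may sit within one chain or span oligomer copies,
    except the degenerate same-chain/same-residue placement) and takes the
    minimum distance. Links with no placement come back with
    ``mappable=False`` — never silently dropped.
    """
    maps_a = [m for m in chain_maps if m.accession == link.protein_a and link.pos_a in m.mapping]
    maps_b = [m for m in chain_maps if m.accession == link.protein_b and link.pos_b in m.mapping]
    placements: list[tuple[str, str, float]] = []
    for ma in maps_a:
        na = ma.auth_number(model, link.pos_a)
        for mb in maps_b:
            nb = mb.auth_number(model, link.pos_b)
            if ma.chain_id == mb.chain_id and link.pos_a == link.pos_b:
                continue  # a residue cannot cross-link to itself in one copy
            d = ca_distance(model, (ma.chain_id, na), (mb.chain_id, nb))
            if d is not None:
                placements.append((ma.chain_id, mb.chain_id, d))
    distance = min((p[2] for p in placements), default=None)
    return DistanceResult(link, distance, placements, threshold)


def evaluate_dataset(
    ds: CrossLinkDataset | Iterable[CrossLink],
    structures: Sequence[tuple[StructureModel, Sequence[ChainMap]]],
    threshold: float = DEFAULT_THRESHOLD,
    bin_width: float = 5.0,
) -> tuple[RestraintSummary, list[DistanceResult]]:
    """Evaluate all links of a dataset against a set of structures.

    Each link's pooled distance is the minimum over all structures in which it
    is mappable. The summary carries per-structure and pooled counts, plus a
    right-open distance histogram (default 5 A bins starting at 0) over
    mappable links.
    """
    links = list(ds)
    per_structure: dict[str, dict] = {}
    pooled: list[DistanceResult] = []
    per_link_results: dict[tuple, DistanceResult] = {}
    for model, maps in structures:
        n_map = n_sat = 0
        for link in links:
            res = evaluate_link(model, maps, link, threshold)
            if res.mappable:
                n_map += 1
                n_sat += res.satisfied
                prev = per_link_results.get(link.key)
                if prev is None or res.distance < prev.distance:
                    per_link_results[link.key] = res
        per_structure[model.structure_id] = {
            "n_mappable": n_map,
            "n_satisfied": n_sat,
            "fraction_satisfied": n_sat / n_map if n_map else None,
        }
    for link in links:
        res = per_link_results.get(link.key)
        if res is None:
            res = DistanceResult(link, None, [], threshold)
        pooled.append(res)
    mappable = [r for r in pooled if r.mappable]
    histogram: dict[float, int] = {}
    for r in mappable:
        lo = math.floor(r.distance / bin_width) * bin_width
        histogram[lo] = histogram.get(lo, 0) + 1
    summary = RestraintSummary(
        n_links=len(links),
        n_mappable=len(mappable),
        n_satisfied=sum(r.satisfied for r in mappable),
        threshold=threshold,
        bin_width=bin_width,
        histogram=dict(sorted(histogram.items())),
        per_structure=per_structure,
    )
    return summary, pooled


def results_table(results: Iterable[DistanceResult]) -> pd.DataFrame:
    """Per-link TSV-ready table of distances and verdicts."""
    rows = []
    for r in results:
        rows.append(
            {
                "protein_a": r.link.protein_a,
                "pos_a": r.link.pos_a,
                "protein_b": r.link.protein_b,
                "pos_b": r.link.pos_b,
                "mappable": int(r.mappable),
                "distance": np.nan if r.distance is None else round(r.distance, 3),
                "satisfied": int(r.satisfied),
                "n_placements": len(r.placements),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "protein_a", "pos_a", "protein_b", "pos_b",
            "mappable", "distance", "satisfied", "n_placements",
        ],
    )


def write_results(results: Iterable[DistanceResult], path: str | Path) -> None:
    results_table(results).to_csv(path, sep="\t", index=False)
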