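"""Membrane-topology consistency of cross-links.

Chemical cross-linking happens on one side of a membrane, so a link joining a
cytoplasmic residue to an extracellular one is physically impossible and flags
either a mis-identification or a compromised membrane. Each endpoint is
assigned the label of the annotated region containing it; transmembrane and
"other" regions, and uncovered positions, count as unannotated. Only links
with BOTH endpoints annotated enter the violation-rate denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from xlmap.errors import DataError, DegenerateInputError
from xlmap.io import CrossLink, CrossLinkDataset, TopologyAnnotation

SIDES = ("cytoplasmic", "extracellular")


@dataclass(frozen=True)
class TopologyCall:
    link: CrossLink
    side_a: str  # cytoplasmic | extracellular | unannotated
    side_b: str
    verdict: str  # consistent | violation | unmapped


def _side(topo: Mapping[str, TopologyAnnotation], accession: str, pos: int,
          lengths: Mapping[str, int] | None) -> str:
    if lengths is not None and accession in lengths and pos > lengths[accession]:
        raise DataError(f"{accession}: position {pos} beyond protein length {lengths[accession]}")
    ann = topo.get(accession)
    if ann is None:
        return "unannotated"
    label = ann.label_at(pos)
    return label if label in SIDES else "unannotated"


def classify_link_topology(
    link: CrossLink,
    topo: Mapping[str, TopologyAnnotation],
    lengths: Mapping[str, int] | None = None,
) -> TopologyCall:
    """Classify one link as consistent / violation / unmapped."""
    side_a = _side(topo, link.protein_a, link.pos_a, lengths)
    side_b = _side(topo, link.protein_b, link.pos_b, lengths)
    if "unannotated" in (side_a, side_b):
        verdict = "unmapped"
    elif {side_a, side_b} == set(SIDES):
        verdict = "violation"
    else:
        verdict = "consistent"
    return TopologyCall(link, side_a, side_b, verdict)


def classify_dataset(
    ds: CrossLinkDataset | Iterable[CrossLink],
    topo: Mapping[str, TopologyAnnotation],
    lengths: Mapping[str, int] | None = None,
) -> list[TopologyCall]:
    return [classify_link_topology(link, topo, lengths) for link in ds]


def violation_rate(
    ds: CrossLinkDataset | Iterable[CrossLink],
    topo: Mapping[str, TopologyAnnotation],
    lengths: Mapping[str, int] | None = None,
) -> tuple[int, int, float]:
    """Cross-side violation rate over links with both endpoints annotated.

    Returns ``(n_mapped, n_violation, rate)`` where ``rate = n_violation /
    n_mapped``; links with an unannotated endpoint are excluded from the
    denominator. Raises :class:`DegenerateInputError` when no link is mapped.
    """
    calls = classify_dataset(ds, topo, lengths)
    mapped = [c for c in calls if c.verdict != "unmapped"]
    if not mapped:
        raise DegenerateInputError("no link has both endpoints annotated; rate undefined")
    n_violation = sum(c.verdict == "violation" for c in mapped)
    return len(mapped), n_violation, n_violation / len(mapped)


def calls_table(calls: Iterable[TopologyCall]) -> pd.DataFrame:
    rows = [
        {
            "protein_a": c.link.protein_a,
            "pos_a": c.link.pos_a,
            "protein_b": c.link.protein_b,
            "pos_b": c.link.pos_b,
            "side_a": c.side_a,
            "side_b": c.side_b,
            "verdict": c.verdict,
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=["protein_a", "pos_a", "protein_b", "pos_b", "side_a", "side_b", "verdict"],
    )
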