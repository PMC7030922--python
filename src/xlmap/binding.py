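"""Binding-site analyses: cross-species lysine mapping, interface enrichment,
and peptide tiling-array quantification with binding-region calling.

A peptide tiling array presents overlapping peptides spanning a target protein;
probing it with a candidate partner and quantifying the spots localises the
binding region. Raw spot signals are background-subtracted, normalised to the
positive-control spot, corrected with tag-only negative-control spots, averaged
over technical replicates, and finally corrected against a nonspecific-binding
control experiment. A binding region is only called where at least two
sequence-overlapping peptides pass the signal threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from xlmap.errors import DataError, DegenerateInputError
from xlmap.io import CrossLink


# ---------------------------------------------------------------------------
# Cross-species lysine mapping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LysineMapping:
    src_accession: str
    src_position: int
    dst_accession: str
    dst_position: int | None
    confident: bool


def map_lysine_cross_species(
    seq_src: str,
    seq_dst: str,
    pos: int,
    src_accession: str = "src",
    dst_accession: str = "dst",
) -> LysineMapping:
    """Map a lysine position between orthologous sequences by identical prefix.

    The mapping is confident only when the destination sequence is identical
    to the source over positions 1..pos — the lysine then sits at the same
    coordinate in both species. Any upstream difference (substitution, indel)
    makes the coordinate unreliable and the position is left unmapped.
    """
    if not 1 <= pos <= len(seq_src):
        raise DataError(f"position {pos} outside source sequence (length {len(seq_src)})")
    if seq_src[pos - 1] != "K":
        raise DataError(f"source position {pos} is {seq_src[pos - 1]!r}, not lysine")
    confident = len(seq_dst) >= pos and seq_dst[:pos] == seq_src[:pos]
    return LysineMapping(
        src_accession, pos, dst_accession, pos if confident else None, confident
    )


# ---------------------------------------------------------------------------
# Interface enrichment
# ---------------------------------------------------------------------------


def interface_enrichment(
    linked_lysines: set[tuple[str, int]],
    interface_positions: Mapping[str, set[int]],
    background_lysines: set[tuple[str, int]],
) -> dict:
    """Are cross-linked lysines enriched inside predicted interaction interfaces?

    Builds the 2x2 table (linked / not-linked) x (in-interface / not) over the
    background lysines and runs a two-sided Fisher's exact test. Returns the
    in-interface fraction among linked lysines, the odds ratio, and the p-value.
    """
    if not background_lysines:
        raise DataError("empty background lysine set")
    if not linked_lysines <= background_lysines:
        raise DataError("linked lysines must be a subset of the background")

    def in_interface(acc: str, pos: int) -> bool:
        return pos in interface_positions.get(acc, ())

    linked_in = sum(in_interface(a, p) for a, p in linked_lysines)
    linked_out = len(linked_lysines) - linked_in
    rest = background_lysines - linked_lysines
    rest_in = sum(in_interface(a, p) for a, p in rest)
    rest_out = len(rest) - rest_in
    odds, p = stats.fisher_exact([[linked_in, linked_out], [rest_in, rest_out]],
                                 alternative="two-sided")
    return {
        "n_linked": len(linked_lysines),
        "n_background": len(background_lysines),
        "fraction_linked_in_interface": linked_in / len(linked_lysines) if linked_lysines else 0.0,
        "fraction_background_in_interface": (linked_in + rest_in) / len(background_lysines),
        "odds_ratio": float(odds) if np.isfinite(odds) else float("inf"),
        "pvalue": float(p),
        "table": [[linked_in, linked_out], [rest_in, rest_out]],
    }


# ---------------------------------------------------------------------------
# Peptide array quantification
# ---------------------------------------------------------------------------


@dataclass
class ArrayExperiment:
    """One peptide-array probing of a target protein.

    ``peptides`` gives the 1-based inclusive (start, end) span of each spot's
    peptide on the target; spans must tile the target at a uniform offset.
    ``raw`` holds per-replicate raw spot signals with shape
    (n_replicates, n_spots). ``background``, ``positive_control`` are per
    replicate; ``negative_controls`` are the raw signals of tag-only spots
    never bound by the probed protein, shape (n_replicates, n_neg).
    """

    target: str
    peptides: tuple[tuple[int, int], ...]
    raw: np.ndarray
    background: np.ndarray
    positive_control: np.ndarray
    negative_controls: np.ndarray

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        self.positive_control = np.asarray(self.positive_control, dtype=float)
        self.negative_controls = np.asarray(self.negative_controls, dtype=float)
        if self.raw.ndim != 2 or self.raw.shape[1] != len(self.peptides):
            raise DataError("raw signal grid incongruent with the peptide list")
        offsets = {b[0] - a[0] for a, b in zip(self.peptides, self.peptides[1:])}
        if len(offsets) > 1:
            raise DataError(f"peptide tiling offsets not uniform: {sorted(offsets)}")

    @property
    def n_replicates(self) -> int:
        return self.raw.shape[0]


def quantify_array(exp: ArrayExperiment, control_exp: ArrayExperiment | None = None) -> np.ndarray:
    """Per-spot normalised specific signal.

    Per replicate: subtract the array background, divide by the
    (background-subtracted) positive-control signal, subtract the mean of the
    equally normalised negative-control spots; then average the technical
    replicates and subtract the same quantity computed on the nonspecific
    control experiment (non-transfected / tag-only probing). Negative values
    are clipped to 0 — signals are physical intensities.
    """

    def normalised_mean(e: ArrayExperiment) -> np.ndarray:
        per_rep = []
        for r in range(e.n_replicates):
            pos = e.positive_control[r] - e.background[r]
            if pos <= 0:
                raise DataError(
                    f"replicate {r}: positive control ({e.positive_control[r]}) does not "
                    f"exceed background ({e.background[r]}); normalization undefined"
                )
            spots = (e.raw[r] - e.background[r]) / pos
            neg = (e.negative_controls[r] - e.background[r]) / pos
            per_rep.append(spots - neg.mean())
        return np.mean(per_rep, axis=0)

    signal = normalised_mean(exp)
    if control_exp is not None:
        if control_exp.peptides != exp.peptides:
            raise DataError("control experiment grid incongruent with the probed experiment")
        signal = signal - normalised_mean(control_exp)
    return np.clip(signal, 0.0, None)


# ---------------------------------------------------------------------------
# Binding region calling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BindingRegion:
    """A called binding region: union of >= 2 overlapping positive peptides."""

    target: str
    start: int  # 1-based inclusive
    end: int
    support: int  # number of supporting peptides

    def __post_init__(self) -> None:
        if self.support < 2:
            raise DataError("a binding region needs at least 2 supporting peptides")

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


def negative_control_threshold(exp: ArrayExperiment, n_sd: float = 2.0) -> float:
    """Default positivity cutoff: mean + n_sd * SD of normalised negative spots."""
    vals = []
    for r in range(exp.n_replicates):
        pos = exp.positive_control[r] - exp.background[r]
        if pos <= 0:
            raise DataError("positive control does not exceed background")
        vals.extend((exp.negative_controls[r] - exp.background[r]) / pos)
    vals = np.asarray(vals, dtype=float)
    return float(vals.mean() + n_sd * vals.std(ddof=0))


def call_binding_regions(
    signals: np.ndarray,
    tiling: Sequence[tuple[int, int]],
    threshold: float,
    target: str = "target",
) -> list[BindingRegion]:
    """Call binding regions from per-spot signals.

    Spots with signal above ``threshold`` are positive; a region is emitted
    only where at least two positive peptides overlap in sequence, and spans
    the union of its supporting peptides. Isolated positive spots are
    rejected. Output regions are pairwise non-overlapping.
    """
    signals = np.asarray(signals, dtype=float)
    if signals.shape[0] != len(tiling):
        raise DataError("signal vector incongruent with the tiling")
    positives = [
        (start, end) for (start, end), s in zip(tiling, signals) if s > threshold
    ]
    regions: list[BindingRegion] = []
    group: list[tuple[int, int]] = []
    for span in sorted(positives):
        if group and span[0] <= group[-1][1]:
            group.append(span)
        else:
            if len(group) >= 2:
                regions.append(
                    BindingRegion(target, min(s for s, _ in group), max(e for _, e in group), len(group))
                )
            group = [span]
    if len(group) >= 2:
        regions.append(
            BindingRegion(target, min(s for s, _ in group), max(e for _, e in group), len(group))
        )
    return regions


def region_link_proximity(
    regions: Sequence[BindingRegion],
    links: Iterable[CrossLink],
    target: str,
) -> pd.DataFrame:
    """Sequence distance from each cross-linked site on ``target`` to the
    nearest called binding region (0 when the site lies inside a region).

    Links not touching the target are ignored; with no regions every distance
    is undefined (NaN)."""
    rows = []
    for link in links:
        for acc, pos in ((link.protein_a, link.pos_a), (link.protein_b, link.pos_b)):
            if acc != target:
                continue
            if regions:
                dist = min(
                    0 if r.contains(pos) else min(abs(pos - r.start), abs(pos - r.end))
                    for r in regions
                )
            else:
                dist = np.nan
            rows.append(
                {
                    "protein_a": link.protein_a,
                    "pos_a": link.pos_a,
                    "protein_b": link.protein_b,
                    "pos_b": link.pos_b,
                    "site": pos,
                    "distance_to_region": dist,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["protein_a", "pos_a", "protein_b", "pos_b", "site", "distance_to_region"],
    )


def write_regions_bed(regions: Sequence[BindingRegion], path) -> None:
    """Emit regions as BED-like TSV (0-based half-open on write)."""
    rows = [
        {"target": r.target, "start": r.start - 1, "end": r.end, "support": r.support}
        for r in regions
    ]
    pd.DataFrame(rows, columns=["target", "start", "end", "support"]).to_csv(
        path, sep="\t", index=False, header=False
    )
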