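"""Data model and readers/writers for cross-link tables, sequences, structures,
topology annotations, evidence tables, and term annotations.

Coordinate conventions
----------------------
All residue positions are 1-based inclusive in the protein's own (UniProt-style)
sequence numbering. Structure author numbering is reconciled only through a
:class:`ChainMap` produced by :func:`build_chain_map`. A cross-link's identity is
the unordered residue pair ``{(accession, position), (accession, position)}``;
chemistry or charge-state variants of the same residue pair collapse into one
link.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import gemmi
from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from xlmap.errors import DataError, FormatError, RowError

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Canonical column names of a cross-link table.
CROSSLINK_COLUMNS = ("protein_a", "pos_a", "protein_b", "pos_b", "fdr", "sample")


# ---------------------------------------------------------------------------
# Cross-links
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CrossLink:
    """One unique lysine-lysine cross-link between two residues.

    Endpoints are stored in canonical order: ``(protein_a, pos_a) <=
    (protein_b, pos_b)`` lexicographically. ``link_class`` is ``"intra"`` when
    both endpoints are on the same protein, ``"inter"`` otherwise. ``samples``
    records every sample/replicate in which the link was identified and ``fdr``
    the best (minimum) identification FDR. ``ambiguous`` flags links inferred
    from a peptide shared by more than one protein.
    """

    protein_a: str
    pos_a: int
    protein_b: str
    pos_b: int
    fdr: float = 0.0
    samples: frozenset[str] = frozenset()
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.pos_a < 1 or self.pos_b < 1:
            raise DataError(f"residue positions must be >= 1, got {self.pos_a}, {self.pos_b}")
        if (self.protein_a, self.pos_a) > (self.protein_b, self.pos_b):
            a, pa = self.protein_a, self.pos_a
            object.__setattr__(self, "protein_a", self.protein_b)
            object.__setattr__(self, "pos_a", self.pos_b)
            object.__setattr__(self, "protein_b", a)
            object.__setattr__(self, "pos_b", pa)
        object.__setattr__(self, "samples", frozenset(self.samples))

    @property
    def link_class(self) -> str:
        return "intra" if self.protein_a == self.protein_b else "inter"

    @property
    def key(self) -> tuple[str, int, str, int]:
        """Canonical residue-pair identity."""
        return (self.protein_a, self.pos_a, self.protein_b, self.pos_b)

    @property
    def pair(self) -> tuple[str, str]:
        """Unordered protein pair, canonically ordered."""
        return tuple(sorted((self.protein_a, self.protein_b)))  # type: ignore[return-value]


class CrossLinkDataset:
    """A deduplicated set of :class:`CrossLink` objects.

    Duplicate residue pairs merge their sample sets and keep the minimum FDR;
    an ambiguous copy makes the merged link ambiguous. Links with
    ``fdr > fdr_threshold`` (default 2%) are dropped at construction.
    """

    def __init__(
        self,
        links: Iterable[CrossLink] = (),
        name: str = "dataset",
        fdr_threshold: float = 0.02,
        filter_fdr: bool = True,
    ):
        self.name = name
        self.fdr_threshold = fdr_threshold
        merged: dict[tuple, CrossLink] = {}
        n_in = 0
        for link in links:
            n_in += 1
            prev = merged.get(link.key)
            if prev is None:
                merged[link.key] = link
            else:
                merged[link.key] = replace(
                    prev,
                    fdr=min(prev.fdr, link.fdr),
                    samples=prev.samples | link.samples,
                    ambiguous=prev.ambiguous or link.ambiguous,
                )
        if filter_fdr:
            merged = {k: l for k, l in merged.items() if l.fdr <= fdr_threshold}
        self._links: dict[tuple, CrossLink] = merged
        logger.info(
            "dataset %r: %d input links -> %d unique links (fdr <= %g)",
            name, n_in, len(merged), fdr_threshold,
        )

    def __len__(self) -> int:
        return len(self._links)

    def __iter__(self) -> Iterator[CrossLink]:
        return iter(sorted(self._links.values(), key=lambda l: l.key))

    def __contains__(self, link: CrossLink) -> bool:
        return link.key in self._links

    def get(self, key: tuple[str, int, str, int]) -> CrossLink | None:
        return self._links.get(key)

    @property
    def links(self) -> list[CrossLink]:
        return list(self)

    def inter_links(self, include_ambiguous: bool = True) -> list[CrossLink]:
        return [
            l for l in self
            if l.link_class == "inter" and (include_ambiguous or not l.ambiguous)
        ]

    def intra_links(self) -> list[CrossLink]:
        return [l for l in self if l.link_class == "intra"]

    def protein_pairs(self, include_ambiguous: bool = False) -> set[tuple[str, str]]:
        """Unordered protein pairs with at least one inter link.

        Ambiguous shared-peptide links are excluded from pair counts unless
        ``include_ambiguous`` is set.
        """
        return {l.pair for l in self.inter_links(include_ambiguous)}

    def proteins(self) -> set[str]:
        out: set[str] = set()
        for l in self:
            out.add(l.protein_a)
            out.add(l.protein_b)
        return out


def read_crosslink_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    name: str | None = None,
    fdr_threshold: float = 0.02,
) -> CrossLinkDataset:
    """Read a delimited cross-link table into a deduplicated dataset.

    Parameters
    ----------
    path:
        TSV or CSV file with a header row. The delimiter is sniffed.
    dialect:
        Optional mapping from canonical column names (``protein_a``, ``pos_a``,
        ``protein_b``, ``pos_b``, ``fdr``, ``sample``, optionally
        ``ambiguous``) to the file's column names.
    fdr_threshold:
        Rows with FDR above this fraction are dropped (default 0.02).
    """
    path = Path(path)
    dialect = dict(dialect or {})
    try:
        table = pd.read_csv(path, sep=None, engine="python", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    colmap = {canon: dialect.get(canon, canon) for canon in CROSSLINK_COLUMNS}
    missing = [c for c in ("protein_a", "pos_a", "protein_b", "pos_b") if colmap[c] not in table.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}; have {list(table.columns)}")
    has_fdr = colmap["fdr"] in table.columns
    has_sample = colmap["sample"] in table.columns
    amb_col = dialect.get("ambiguous", "ambiguous")
    has_amb = amb_col in table.columns

    links = []
    for i, row in enumerate(table.itertuples(index=False)):
        rowd = dict(zip(table.columns, row))
        line = i + 2  # header is line 1
        try:
            pos_a = int(rowd[colmap["pos_a"]])
            pos_b = int(rowd[colmap["pos_b"]])
        except (TypeError, ValueError) as exc:
            raise RowError(f"non-numeric residue position: {exc}", line=line) from exc
        fdr = float(rowd[colmap["fdr"]]) if has_fdr else 0.0
        sample = str(rowd[colmap["sample"]]) if has_sample and pd.notna(rowd[colmap["sample"]]) else "unknown"
        ambiguous = False
        if has_amb and pd.notna(rowd[amb_col]):
            ambiguous = str(rowd[amb_col]).strip().lower() in ("1", "true", "yes")
        try:
            links.append(
                CrossLink(
                    protein_a=str(rowd[colmap["protein_a"]]),
                    pos_a=pos_a,
                    protein_b=str(rowd[colmap["protein_b"]]),
                    pos_b=pos_b,
                    fdr=fdr,
                    samples=frozenset({sample}),
                    ambiguous=ambiguous,
                )
            )
        except DataError as exc:
            raise RowError(str(exc), line=line) from exc
    ds = CrossLinkDataset(links, name=name or path.stem, fdr_threshold=fdr_threshold)
    logger.info("read %d rows from %s -> %d unique links", len(table), path, len(ds))
    return ds


def write_crosslink_table(ds: CrossLinkDataset, path: str | Path) -> None:
    """Write a dataset as TSV with the canonical columns.

    Sample sets are serialised semicolon-joined; reading the file back yields
    an identical dataset (links split per sample re-merge on read).
    """
    rows = []
    for l in ds:
        for sample in sorted(l.samples) or ["unknown"]:
            rows.append(
                {
                    "protein_a": l.protein_a,
                    "pos_a": l.pos_a,
                    "protein_b": l.protein_b,
                    "pos_b": l.pos_b,
                    "fdr": l.fdr,
                    "sample": sample,
                    "ambiguous": int(l.ambiguous),
                }
            )
    pd.DataFrame(rows, columns=list(CROSSLINK_COLUMNS) + ["ambiguous"]).to_csv(
        path, sep="\t", index=False
    )


def dataset_summary(ds: CrossLinkDataset) -> dict:
    """Headline counts of a dataset.

    Returns unique link counts (total, inter, intra), the number of distinct
    unordered inter protein pairs, proteins carrying intra links, total
    distinct proteins, and per-sample link counts.
    """
    inter = ds.inter_links()
    intra = ds.intra_links()
    per_sample: dict[str, int] = {}
    for l in ds:
        for s in l.samples:
            per_sample[s] = per_sample.get(s, 0) + 1
    return {
        "name": ds.name,
        "n_links": len(ds),
        "n_inter": len(inter),
        "n_intra": len(intra),
        "n_inter_pairs": len(ds.protein_pairs(include_ambiguous=False)),
        "n_proteins_intra": len({l.protein_a for l in intra}),
        "n_proteins": len(ds.proteins()),
        "per_sample": dict(sorted(per_sample.items())),
    }


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProteinRecord:
    accession: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence.upper()) - set(AMINO_ACIDS + "X")
        if bad:
            raise DataError(f"{self.accession}: invalid residues {sorted(bad)}")
        object.__setattr__(self, "sequence", self.sequence.upper())

    @property
    def length(self) -> int:
        return len(self.sequence)

    def lysine_positions(self) -> list[int]:
        """1-based positions of every lysine."""
        return [i + 1 for i, aa in enumerate(self.sequence) if aa == "K"]


def read_fasta(path: str | Path) -> dict[str, ProteinRecord]:
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = ProteinRecord(rec.id, str(rec.seq))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return records


def write_fasta(records: Mapping[str, ProteinRecord] | Iterable[ProteinRecord], path: str | Path) -> None:
    if isinstance(records, Mapping):
        records = records.values()
    SeqIO.write(
        [SeqRecord(Seq(r.sequence), id=r.accession, description="") for r in records],
        str(path),
        "fasta",
    )


# ---------------------------------------------------------------------------
# Topology annotations
# ---------------------------------------------------------------------------

TOPOLOGY_LABELS = ("cytoplasmic", "extracellular", "transmembrane", "other")


@dataclass(frozen=True)
class TopologyAnnotation:
    """Labelled sequence regions of a membrane protein (1-based inclusive)."""

    accession: str
    regions: tuple[tuple[int, int, str], ...]

    def __post_init__(self) -> None:
        regs = tuple(sorted((int(s), int(e), str(lab)) for s, e, lab in self.regions))
        for start, end, label in regs:
            if not 1 <= start <= end:
                raise DataError(f"{self.accession}: bad region {start}-{end}")
            if label not in TOPOLOGY_LABELS:
                raise DataError(f"{self.accession}: unknown topology label {label!r}")
        for (s1, e1, l1), (s2, e2, l2) in zip(regs, regs[1:]):
            if s2 <= e1 and l1 != l2:
                raise DataError(
                    f"{self.accession}: overlapping regions with different labels "
                    f"({s1}-{e1} {l1} vs {s2}-{e2} {l2})"
                )
        object.__setattr__(self, "regions", regs)

    def label_at(self, pos: int) -> str | None:
        """Label of the region containing ``pos``, or None if uncovered."""
        for start, end, label in self.regions:
            if start <= pos <= end:
                return label
        return None


def read_topology_table(path: str | Path) -> dict[str, TopologyAnnotation]:
    """Read a topology TSV with columns accession, start, end, label."""
    table = pd.read_csv(path, sep="\t", dtype={"accession": str, "label": str})
    for col in ("accession", "start", "end", "label"):
        if col not in table.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    out: dict[str, TopologyAnnotation] = {}
    for acc, grp in table.groupby("accession"):
        out[str(acc)] = TopologyAnnotation(
            str(acc), tuple((int(r.start), int(r.end), str(r.label)) for r in grp.itertuples())
        )
    return out


def write_topology_table(topo: Mapping[str, TopologyAnnotation], path: str | Path) -> None:
    rows = [
        {"accession": t.accession, "start": s, "end": e, "label": lab}
        for t in topo.values()
        for s, e, lab in t.regions
    ]
    pd.DataFrame(rows, columns=["accession", "start", "end", "label"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Structures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Residue:
    auth_number: int
    amino_acid: str  # one-letter
    ca: tuple[float, float, float] | None

    @property
    def present(self) -> bool:
        return self.ca is not None


@dataclass
class StructureModel:
    """A Ca-only structural model: ordered residues per chain."""

    structure_id: str
    chains: dict[str, list[Residue]]

    def __post_init__(self) -> None:
        for cid, residues in self.chains.items():
            for r in residues:
                if r.ca is not None and not all(np.isfinite(r.ca)):
                    raise DataError(f"{self.structure_id}/{cid}: non-finite Ca coordinate")

    def chain_sequence(self, chain_id: str) -> str:
        return "".join(r.amino_acid for r in self.chains[chain_id])

    def residue(self, chain_id: str, auth_number: int) -> Residue | None:
        for r in self.chains.get(chain_id, ()):
            if r.auth_number == auth_number:
                return r
        return None


def read_structure(path: str | Path) -> StructureModel:
    """Read a PDB or mmCIF file into a Ca-only :class:`StructureModel`.

    Only the first model is used. Residues without a Ca atom are kept but
    marked absent; alternate locations resolve to the highest-occupancy Ca
    (ties keep the first encountered).
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except Exception as exc:
        raise FormatError(f"cannot parse structure {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise FormatError(f"{path}: empty structure")
    model = st[0]
    chains: dict[str, list[Residue]] = {}
    for chain in model:
        residues = []
        for res in chain:
            info = gemmi.find_tabulated_residue(res.name)
            if info is None or not info.is_amino_acid():
                continue
            one = gemmi.find_tabulated_residue(res.name).one_letter_code.upper()
            if not one.isalpha():
                one = "X"
            best = None
            for atom in res:
                if atom.name == "CA" and atom.element.name != "Ca":
                    if best is None or atom.occ > best.occ:
                        best = atom
            ca = (best.pos.x, best.pos.y, best.pos.z) if best is not None else None
            residues.append(Residue(res.seqid.num, one, ca))
        if residues:
            chains[chain.name] = residues
    if not chains:
        raise FormatError(f"{path}: no amino-acid residues found")
    return StructureModel(path.stem, chains)


# ---------------------------------------------------------------------------
# Sequence -> structure mapping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChainMap:
    """Injective partial mapping: sequence position -> structure residue.

    ``mapping[pos]`` gives the chain residue index (0-based into the chain's
    residue list) for 1-based sequence position ``pos``. Only aligned,
    identical residues are mapped. ``identity`` is the fraction of identical
    residues over aligned (non-gap) columns.
    """

    accession: str
    chain_id: str
    mapping: Mapping[int, int]
    identity: float

    def auth_number(self, model: StructureModel, pos: int) -> int | None:
        idx = self.mapping.get(pos)
        if idx is None:
            return None
        return model.chains[self.chain_id][idx].auth_number


def build_chain_map(
    record: ProteinRecord,
    model: StructureModel,
    chain_id: str,
    min_identity: float = 0.30,
) -> ChainMap:
    """Globally align the protein sequence to a chain and map positions.

    Uses match +1 / mismatch -1 / gap -2 scoring. Refuses (raises
    :class:`DataError`) when identity over aligned columns falls below
    ``min_identity`` — almost always the wrong chain.
    """
    if chain_id not in model.chains:
        raise DataError(f"{model.structure_id}: no chain {chain_id!r}")
    chain_seq = model.chain_sequence(chain_id)
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    aln = aligner.align(record.sequence, chain_seq)[0]
    mapping: dict[int, int] = {}
    n_aligned = 0
    n_ident = 0
    for (a_start, a_end), (b_start, b_end) in zip(*aln.aligned):
        for off in range(a_end - a_start):
            i, j = a_start + off, b_start + off
            n_aligned += 1
            if record.sequence[i] == chain_seq[j]:
                n_ident += 1
                mapping[i + 1] = j
    identity = n_ident / n_aligned if n_aligned else 0.0
    if identity < min_identity:
        raise DataError(
            f"{record.accession} vs {model.structure_id}/{chain_id}: alignment identity "
            f"{identity:.1%} below {min_identity:.0%} — likely the wrong chain"
        )
    return ChainMap(record.accession, chain_id, mapping, identity)


# ---------------------------------------------------------------------------
# Evidence records
# ---------------------------------------------------------------------------

EVIDENCE_SOURCES = ("string", "inweb", "biogrid")


@dataclass(frozen=True)
class EvidenceRecord:
    """One external PPI evidence item (STRING / InWEB / BioGRID style)."""

    protein_a: str
    protein_b: str
    source: str
    score: float | None = None
    low_throughput: bool = False

    def __post_init__(self) -> None:
        if self.source not in EVIDENCE_SOURCES:
            raise DataError(f"unknown evidence source {self.source!r}")
        if self.protein_a > self.protein_b:
            a = self.protein_a
            object.__setattr__(self, "protein_a", self.protein_b)
            object.__setattr__(self, "protein_b", a)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.protein_a, self.protein_b)

    @property
    def tier(self) -> str:
        from xlmap.evidence import classify_tier

        return classify_tier(self)


def read_evidence_table(path: str | Path) -> list[EvidenceRecord]:
    table = pd.read_csv(path, sep="\t", dtype={"protein_a": str, "protein_b": str, "source": str})
    for col in ("protein_a", "protein_b", "source"):
        if col not in table.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    out = []
    for r in table.itertuples():
        score = getattr(r, "score", None)
        score = None if score is None or pd.isna(score) else float(score)
        lt = bool(getattr(r, "low_throughput", False))
        out.append(EvidenceRecord(str(r.protein_a), str(r.protein_b), str(r.source), score, lt))
    return out


def write_evidence_table(records: Sequence[EvidenceRecord], path: str | Path) -> None:
    rows = [
        {
            "protein_a": r.protein_a,
            "protein_b": r.protein_b,
            "source": r.source,
            "score": "" if r.score is None else r.score,
            "low_throughput": int(r.low_throughput),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=["protein_a", "protein_b", "source", "score", "low_throughput"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Term annotations (GO-like)
# ---------------------------------------------------------------------------


@dataclass
class AnnotationSet:
    """term id -> annotated accessions, with optional term metadata."""

    terms: dict[str, set[str]] = field(default_factory=dict)
    metadata: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.terms = {t: set(accs) for t, accs in self.terms.items() if accs}

    def add(self, term: str, accessions: Iterable[str], **meta) -> None:
        accs = set(accessions)
        if not accs:
            raise DataError(f"term {term!r}: empty accession set")
        self.terms.setdefault(term, set()).update(accs)
        if meta:
            self.metadata.setdefault(term, {}).update(meta)

    def __getitem__(self, term: str) -> set[str]:
        return self.terms[term]

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.terms))

    def __len__(self) -> int:
        return len(self.terms)


def read_annotation_table(path: str | Path) -> AnnotationSet:
    table = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("term", "accession"):
        if col not in table.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    out = AnnotationSet()
    for term, grp in table.groupby("term"):
        out.add(str(term), {str(a) for a in grp["accession"]})
    return out


def write_annotation_table(annot: AnnotationSet, path: str | Path) -> None:
    rows = [{"term": t, "accession": a} for t in annot for a in sorted(annot[t])]
    pd.DataFrame(rows, columns=["term", "accession"]).to_csv(path, sep="\t", index=False)


def read_abundance_table(path: str | Path) -> dict[str, float]:
    table = pd.read_csv(path, sep="\t", dtype={"accession": str})
    for col in ("accession", "abundance"):
        if col not in table.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return {str(r.accession): float(r.abundance) for r in table.itertuples()}


def write_abundance_table(abund: Mapping[str, float], path: str | Path) -> None:
    pd.DataFrame(
        [{"accession": a, "abundance": v} for a, v in sorted(abund.items())]
    ).to_csv(path, sep="\t", index=False)
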