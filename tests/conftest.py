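"""Shared fixtures: minimal structures, datasets, and synthetic worlds."""

from __future__ import annotations

import numpy as np
import pytest

from xlmap.io import CrossLink, CrossLinkDataset, Residue, StructureModel
from xlmap.synthetic import identity_chain_maps, make_toy_complex


def pdb_atom_line(serial: int, chain: str, resnum: int, x: float, y: float, z: float,
                  resname: str = "ALA", altloc: str = " ", occ: float = 1.0,
                  name: str = "CA") -> str:
    return (
        f"ATOM  {serial:5d}  {name:<3s}{altloc}{resname:3s} {chain}{resnum:4d}"
        f"    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00           {name[0]}"
    )


def write_pdb(path, lines):
    path.write_text("\n".join(lines) + "\nEND\n")
    return path


@pytest.fixture
def three_residue_pdb(tmp_path):
    """Three lysines on a line, 10 A apart."""
    lines = [
        pdb_atom_line(1, "A", 1, 0.0, 0.0, 0.0, "LYS"),
        pdb_atom_line(2, "A", 2, 10.0, 0.0, 0.0, "LYS"),
        pdb_atom_line(3, "A", 3, 20.0, 0.0, 0.0, "LYS"),
    ]
    return write_pdb(tmp_path / "three.pdb", lines)


@pytest.fixture
def toy_complex():
    model, records = make_toy_complex(2, 50, seed=7)
    return model, records


@pytest.fixture
def toy_maps(toy_complex):
    model, records = toy_complex
    return identity_chain_maps(model, records)


@pytest.fixture
def simple_dataset():
    """Links {A-A intra, A-B, B-C} as in the summary example."""
    return CrossLinkDataset(
        [
            CrossLink("A", 10, "A", 30, samples=frozenset({"s1"})),
            CrossLink("A", 5, "B", 20, samples=frozenset({"s1"})),
            CrossLink("B", 7, "C", 9, samples=frozenset({"s2"})),
        ],
        name="simple",
    )


def make_model(points: dict[str, list[tuple[float, float, float]]],
               aa: str = "K") -> StructureModel:
    """Structure with given Ca coordinates; every residue is lysine by default."""
    chains = {
        cid: [Residue(i + 1, aa, tuple(p)) for i, p in enumerate(pts)]
        for cid, pts in points.items()
    }
    return StructureModel("fixture", chains)
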