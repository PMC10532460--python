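"""Shared fixtures: tiny molecules, random graphs, and a seeded synthetic set."""

from __future__ import annotations

import numpy as np
import pytest

from pepspr.mna import atom_mark
from pepspr.molgraph import AtomNode, MolecularGraph, perceive_rings
from pepspr.synthetic import SyntheticSpec, generate_dataset
from pepspr.windows import (PeptideWindow, ProteinSequence,
                            SubstitutionRecord, build_dataset)


def make_graph(elements, bonds, charges=None) -> MolecularGraph:
    charges = charges or {}
    atoms = [AtomNode(index=i, element=el, formal_charge=charges.get(i, 0))
             for i, el in enumerate(elements)]
    return perceive_rings(MolecularGraph(atoms=atoms, bonds=list(bonds)))


def random_graph(rng: np.random.Generator, max_atoms: int = 10
                 ) -> MolecularGraph:
    """Random connected simple graph: spanning tree + a few extra edges.

    Chemistry-agnostic on purpose: descriptor generation only sees marks and
    adjacency, so property tests should cover arbitrary labeled graphs.
    """
    n = int(rng.integers(2, max_atoms + 1))
    elements = rng.choice(list("CNOSH"), size=n)
    charges = {}
    for i in range(n):
        if rng.random() < 0.1:
            charges[i] = int(rng.choice([-1, 1]))
    edges = set()
    for i in range(1, n):
        j = int(rng.integers(0, i))
        edges.add((j, i))
    for _ in range(int(rng.integers(0, 3))):
        i, j = rng.integers(0, n, size=2)
        i, j = int(min(i, j)), int(max(i, j))
        if i != j:
            edges.add((i, j))
    bonds = [(i, j, 1) for i, j in sorted(edges)]
    return make_graph(list(elements), bonds, charges)


def naive_mna(graph: MolecularGraph, atom_index: int, level: int) -> str:
    """Independent reference: direct string recursion over the definition."""
    mark = atom_mark(graph.atoms[atom_index])
    if level == 0:
        return mark
    parts = sorted(naive_mna(graph, j, level - 1)
                   for j in graph.adjacency[atom_index])
    return mark + "(" + "".join(parts) + ")"


def naive_descriptor_strings(graph: MolecularGraph, level: int) -> set[str]:
    return {naive_mna(graph, i, level) for i in range(graph.n_atoms)}


def single_residue_window(code: str) -> PeptideWindow:
    rec = SubstitutionRecord("T", 1, "A" if code != "A" else "G", code,
                             {"e": True})
    return PeptideWindow(code, 3, 0, rec)


@pytest.fixture
def methane() -> MolecularGraph:
    return make_graph(["C", "H", "H", "H", "H"],
                      [(0, i, 1) for i in range(1, 5)])


@pytest.fixture
def benzene_like() -> MolecularGraph:
    bonds = [(i, (i + 1) % 6, 1 + i % 2) for i in range(6)]
    return make_graph(["C"] * 6, bonds)


@pytest.fixture(scope="session")
def planted_set():
    """Seed-fixed planted-motif study conditions (default spec, seed 1)."""
    spec = SyntheticSpec(seed=1)
    seq, records = generate_dataset(spec)
    return spec, seq, records


@pytest.fixture(scope="session")
def planted_dataset(planted_set):
    spec, seq, records = planted_set
    return build_dataset(seq, records, spec.endpoint,
                         2 * spec.motif_radius + 1)


@pytest.fixture
def toy_sequence() -> ProteinSequence:
    return ProteinSequence("toy", "ACDEFGHIKLM")
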