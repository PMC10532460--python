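"""Multilevel Neighborhoods of Atoms (MNA) descriptors.

An MNA descriptor of level 0 is the mark of an atom: its element symbol,
prefixed with "-" when the atom lies on no ring, with a "[+n]"/"[-n]" suffix
for a nonzero formal charge.  The level-k descriptor of an atom is
``mark(D1 D2 ... Dd)`` where the Di are the level-(k-1) descriptors of its
immediate neighbors, concatenated in lexicographic string order.  Bond types
play no role; structures are compared as *sets* of unique descriptors.

Descriptor strings grow roughly like branching^level, so materializing them
at level 15 is impractical.  The working representation interns each distinct
descriptor in a :class:`DescriptorVocabulary` keyed by (mark, sorted child
ids); because the string grammar is uniquely decodable, two descriptors have
equal strings iff they intern to the same id.  Strings are rendered (with the
true lexicographic neighbor ordering) only on demand.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .molgraph import MolecularGraph, perceive_rings

MAX_LEVEL = 15


def atom_mark(atom) -> str:
    """Zero-level mark: ring flag prefix + element + charge suffix."""
    mark = ("" if atom.in_ring else "-") + atom.element
    if atom.formal_charge:
        mark += f"[{atom.formal_charge:+d}]"
    return mark


class DescriptorVocabulary:
    """Shared intern pool for MNA descriptors across structures.

    Node ids are assigned in first-seen order and are stable for the life of
    the vocabulary, so descriptor sets of different structures (training and
    query alike) are directly comparable as integer sets.  A node is either
    ``(mark, None)`` (level 0) or ``(mark, children)`` with ``children`` the
    id-sorted tuple of neighbor nodes one level down.
    """

    def __init__(self) -> None:
        self.nodes: list[tuple[str, tuple[int, ...] | None]] = []
        self._index: dict[tuple[str, tuple[int, ...] | None], int] = {}
        self._render_cache: dict[int, str] = {}

    def __len__(self) -> int:
        return len(self.nodes)

    def intern(self, mark: str, children: tuple[int, ...] | None) -> int:
        key = (mark, children)
        node_id = self._index.get(key)
        if node_id is None:
            node_id = len(self.nodes)
            self.nodes.append(key)
            self._index[key] = node_id
        return node_id

    def _ensure_rings(self, graph: MolecularGraph) -> None:
        if not graph._rings_perceived:
            perceive_rings(graph)

    def encode_atoms(self, graph: MolecularGraph, level: int
                     ) -> list[list[int]]:
        """Per-atom descriptor ids for every level 0..level."""
        if not 0 <= level <= MAX_LEVEL:
            raise ValueError(f"level must be in [0, {MAX_LEVEL}], got {level}")
        self._ensure_rings(graph)
        marks = [atom_mark(a) for a in graph.atoms]
        adj = graph.adjacency
        levels = [[self.intern(m, None) for m in marks]]
        for _ in range(level):
            prev = levels[-1]
            cur = [
                self.intern(marks[i], tuple(sorted(prev[j] for j in adj[i])))
                for i in range(graph.n_atoms)
            ]
            levels.append(cur)
        return levels

    def encode(self, graph: MolecularGraph, level: int) -> np.ndarray:
        """Sorted unique descriptor ids of a structure at one level."""
        return np.unique(np.asarray(self.encode_atoms(graph, level)[level],
                                    dtype=np.int64))

    def render(self, node_id: int, max_chars: int = 50_000_000) -> str:
        """Materialize the descriptor string (lexicographically sorted)."""
        cached = self._render_cache.get(node_id)
        if cached is not None:
            return cached
        mark, children = self.nodes[node_id]
        if children is None:
            s = mark
        else:
            parts = sorted(self.render(c, max_chars) for c in children)
            s = mark + "(" + "".join(parts) + ")"
        if len(s) > max_chars:
            raise ValueError(
                f"descriptor string exceeds {max_chars} characters; "
                "work with vocabulary ids at high levels instead")
        self._render_cache[node_id] = s
        return s


@dataclass(frozen=True)
class DescriptorSet:
    """Unique MNA descriptors of one structure at one level.

    ``keys`` are vocabulary ids (sorted); ``multiplicity`` maps id -> number
    of atoms carrying the descriptor (diagnostics only — the classifier uses
    set semantics).
    """

    level: int
    keys: np.ndarray
    vocabulary: DescriptorVocabulary = field(repr=False)
    multiplicity: dict[int, int] = field(repr=False, default_factory=dict)

    def __len__(self) -> int:
        return len(self.keys)

    @property
    def descriptors(self) -> frozenset[str]:
        return frozenset(self.vocabulary.render(int(k)) for k in self.keys)

    def sorted_strings(self) -> list[str]:
        return sorted(self.vocabulary.render(int(k)) for k in self.keys)


def mna_descriptor(graph: MolecularGraph, atom_index: int, level: int,
                   vocabulary: DescriptorVocabulary | None = None) -> str:
    """The MNA descriptor string of one atom at one level."""
    if not 0 <= atom_index < graph.n_atoms:
        raise IndexError(f"atom index {atom_index} out of range")
    vocab = vocabulary or DescriptorVocabulary()
    levels = vocab.encode_atoms(graph, level)
    return vocab.render(levels[level][atom_index])


def descriptor_set(graph: MolecularGraph, level: int,
                   vocabulary: DescriptorVocabulary | None = None
                   ) -> DescriptorSet:
    """Unique descriptors over all atoms of a structure."""
    vocab = vocabulary or DescriptorVocabulary()
    atom_ids = vocab.encode_atoms(graph, level)[level]
    mult = dict(Counter(atom_ids))
    keys = np.unique(np.asarray(atom_ids, dtype=np.int64))
    return DescriptorSet(level=level, keys=keys, vocabulary=vocab,
                         multiplicity=mult)


def encode_graphs(graphs, levels: list[int],
                  vocabulary: DescriptorVocabulary
                  ) -> dict[int, list[np.ndarray]]:
    """Unique-id arrays for many structures at many levels in one pass."""
    top = max(levels)
    out: dict[int, list[np.ndarray]] = {lv: [] for lv in levels}
    for g in graphs:
        per_level = vocabulary.encode_atoms(g, top)
        for lv in levels:
            out[lv].append(
                np.unique(np.asarray(per_level[lv], dtype=np.int64)))
    return out


def dump_descriptors(sets: list[DescriptorSet], path) -> None:
    """One line per structure: tab-separated sorted descriptor strings."""
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join(s.sorted_strings()) + "\n")
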