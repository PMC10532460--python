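"""Peptide molecular graphs and SD-file (MOL V2000/V3000) I/O.

The in-memory structure is deliberately minimal: atoms with element, formal
charge and a derived in-ring flag, plus an untyped simple adjacency.  Bond
orders are carried only for file fidelity — the substructural descriptors
downstream ignore bond types.  Peptides are assembled from residue templates
by condensation (loss of H2O per peptide bond), with free neutral termini.

SD records are written as MOL V3000 connection tables with all-zero
coordinates, followed by data items carrying the substitution annotation
(POSITION, GENE, REF_AA, ALT_AA, EFFECT, ...).  Reading supports both V2000
and V3000, old-style and ``M  CHG`` charges, and fills implicit hydrogens to
neutral valence when a file omits them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .residues import get_template
from .windows import PeptideWindow

VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2, "H": 1}
ELEMENTS = frozenset(VALENCE)

# canonical SD tag names written by this package
SD_TAGS = ("POSITION", "GENE", "REF_AA", "ALT_AA", "EFFECT",
           "NOMINAL_LENGTH", "CENTER_OFFSET")


class MolfileError(ValueError):
    """Malformed MOL/SD input."""


@dataclass
class AtomNode:
    index: int
    element: str
    formal_charge: int = 0
    in_ring: bool = False


@dataclass
class MolecularGraph:
    """Simple undirected molecular graph with explicit hydrogens."""

    atoms: list[AtomNode]
    bonds: list[tuple[int, int, int]]  # (i, j, order), i < j
    tags: dict[str, str] = field(default_factory=dict)
    name: str = ""
    _adjacency: list[list[int]] | None = field(
        default=None, repr=False, compare=False)
    _rings_perceived: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        seen = set()
        norm = []
        for i, j, order in self.bonds:
            if i == j:
                raise MolfileError(f"self-loop on atom {i}")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise MolfileError(f"duplicate bond {key}")
            seen.add(key)
            norm.append((key[0], key[1], order))
        self.bonds = norm

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def adjacency(self) -> list[list[int]]:
        if self._adjacency is None:
            adj: list[list[int]] = [[] for _ in self.atoms]
            for i, j, _ in self.bonds:
                adj[i].append(j)
                adj[j].append(i)
            self._adjacency = adj
        return self._adjacency

    def formula(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for a in self.atoms:
            counts[a.element] = counts.get(a.element, 0) + 1
        return counts

    def allowed_valence(self, atom: AtomNode) -> int:
        base = VALENCE[atom.element]
        q = atom.formal_charge
        if atom.element == "C":
            return base - abs(q)
        return base + q

    def check_valences(self) -> None:
        """Raise if any atom's bond-order sum differs from neutral-rule valence."""
        order_sum = [0] * self.n_atoms
        for i, j, order in self.bonds:
            order_sum[i] += order
            order_sum[j] += order
        for atom in self.atoms:
            expected = self.allowed_valence(atom)
            if order_sum[atom.index] != expected:
                raise MolfileError(
                    f"atom {atom.index} ({atom.element}, charge "
                    f"{atom.formal_charge}) has bond-order sum "
                    f"{order_sum[atom.index]}, expected {expected}"
                )


def perceive_rings(graph: MolecularGraph) -> MolecularGraph:
    """Flag atoms lying on at least one simple cycle.

    An edge is on a cycle iff it is not a bridge; an atom is in a ring iff it
    has an incident non-bridge edge.  Idempotent; mutates and returns the
    graph.
    """
    g = nx.Graph()
    g.add_nodes_from(range(graph.n_atoms))
    g.add_edges_from((i, j) for i, j, _ in graph.bonds)
    bridges = set(frozenset(e) for e in nx.bridges(g))
    in_ring = [False] * graph.n_atoms
    for i, j, _ in graph.bonds:
        if frozenset((i, j)) not in bridges:
            in_ring[i] = True
            in_ring[j] = True
    for atom in graph.atoms:
        atom.in_ring = in_ring[atom.index]
    graph._rings_perceived = True
    return graph


def assemble_peptide_graph(window: PeptideWindow) -> MolecularGraph:
    """Build the structural formula of a mutant peptide window.

    Residues are joined N-to-C: each peptide bond removes the carboxyl OH
    (O + H) of residue i and one amine H of residue i+1, then bonds the
    carbonyl C to the amine N (net loss of one H2O per bond).  Termini stay
    neutral (NH2 / COOH).  Ring flags are computed before returning.
    """
    if not window.residues:
        raise ValueError("empty peptide window")
    templates = [get_template(code) for code in window.residues]
    n_res = len(templates)

    removed: list[set[int]] = [set() for _ in range(n_res)]
    for r in range(n_res - 1):
        t = templates[r]
        removed[r].update((t.hydroxyl_o, t.hydroxyl_h))
        removed[r + 1].add(templates[r + 1].amine_h[0])

    atoms: list[AtomNode] = []
    bonds: list[tuple[int, int, int]] = []
    remap: list[dict[int, int]] = []
    for r, t in enumerate(templates):
        m: dict[int, int] = {}
        for idx, (el, q) in enumerate(t.atoms):
            if idx in removed[r]:
                continue
            m[idx] = len(atoms)
            atoms.append(AtomNode(index=len(atoms), element=el, formal_charge=q))
        remap.append(m)
        for i, j, order in t.bonds:
            if i in removed[r] or j in removed[r]:
                continue
            bonds.append((m[i], m[j], order))
    for r in range(n_res - 1):
        c = remap[r][templates[r].carbonyl_c]
        n = remap[r + 1][templates[r + 1].backbone_n]
        bonds.append((c, n, 1))

    rec = window.source
    graph = MolecularGraph(
        atoms=atoms,
        bonds=bonds,
        name=f"{rec.protein_id}_{rec.name}_len{window.nominal_length}",
        tags={
            "POSITION": str(rec.position),
            "GENE": rec.protein_id,
            "REF_AA": rec.ref_aa,
            "ALT_AA": rec.alt_aa,
            "NOMINAL_LENGTH": str(window.nominal_length),
            "CENTER_OFFSET": str(window.center_offset),
        },
    )
    return perceive_rings(graph)


def graphs_for_dataset(dataset, endpoint: str | None = None
                       ) -> list[MolecularGraph]:
    """Assemble one graph per window; optionally tag the endpoint label."""
    out = []
    for k, w in enumerate(dataset.windows):
        g = assemble_peptide_graph(w)
        if endpoint is not None:
            g.tags["EFFECT"] = "1" if dataset.labels[k] else "0"
            g.tags["ENDPOINT"] = endpoint
        out.append(g)
    return out


# ---------------------------------------------------------------------------
# SD file writing (MOL V3000)

def _v3000_record(graph: MolecularGraph) -> list[str]:
    lines = [
        graph.name or "MOL",
        "  pepspr          2D",
        "",
        "  0  0  0     0  0            999 V3000",
        "M  V30 BEGIN CTAB",
        f"M  V30 COUNTS {graph.n_atoms} {len(graph.bonds)} 0 0 0",
        "M  V30 BEGIN ATOM",
    ]
    for a in graph.atoms:
        chg = f" CHG={a.formal_charge}" if a.formal_charge else ""
        lines.append(
            f"M  V30 {a.index + 1} {a.element} 0.0000 0.0000 0.0000 0{chg}")
    lines.append("M  V30 END ATOM")
    lines.append("M  V30 BEGIN BOND")
    for b_idx, (i, j, order) in enumerate(graph.bonds, start=1):
        lines.append(f"M  V30 {b_idx} {order} {i + 1} {j + 1}")
    lines.append("M  V30 END BOND")
    lines.append("M  V30 END CTAB")
    lines.append("M  END")
    for tag, value in graph.tags.items():
        lines.append(f">  <{tag}>")
        lines.append(str(value))
        lines.append("")
    lines.append("$$$$")
    return lines


def write_sdf(graphs: list[MolecularGraph], path) -> None:
    """Write SD records (MOL V3000 + data items); empty list gives empty file."""
    lines: list[str] = []
    for g in graphs:
        lines.extend(_v3000_record(g))
    with open(path, "w") as fh:
        fh.write("\n".join(lines))
        if lines:
            fh.write("\n")


# ---------------------------------------------------------------------------
# SD file reading (V2000 and V3000)

_OLD_CHARGE = {0: 0, 1: 3, 2: 2, 3: 1, 5: -1, 6: -2, 7: -3}


def _fill_hydrogens(atoms, bonds) -> None:
    order_sum = {}
    for i, j, order in bonds:
        order_sum[i] = order_sum.get(i, 0) + order
        order_sum[j] = order_sum.get(j, 0) + order
    for idx in range(len(atoms)):
        el, q = atoms[idx]
        base = VALENCE[el]
        allowed = base - abs(q) if el == "C" else base + q
        for _ in range(allowed - order_sum.get(idx, 0)):
            h = len(atoms)
            atoms.append(("H", 0))
            bonds.append((idx, h, 1))


def _parse_v2000(body: list[str], rec_idx: int):
    counts = body[3]
    try:
        n_atoms, n_bonds = int(counts[0:3]), int(counts[3:6])
    except ValueError as exc:
        raise MolfileError(
            f"record {rec_idx}: bad V2000 counts line {counts!r}") from exc
    atoms: list[tuple[str, int]] = []
    for line in body[4:4 + n_atoms]:
        parts = line.split()
        if len(parts) < 4:
            raise MolfileError(f"record {rec_idx}: short atom line {line!r}")
        el = parts[3]
        if el not in ELEMENTS:
            raise MolfileError(f"record {rec_idx}: unknown element {el!r}")
        old = int(parts[5]) if len(parts) > 5 and parts[5].isdigit() else 0
        atoms.append((el, _OLD_CHARGE.get(old, 0)))
    bonds: list[tuple[int, int, int]] = []
    for line in body[4 + n_atoms:4 + n_atoms + n_bonds]:
        i, j, order = int(line[0:3]) - 1, int(line[3:6]) - 1, int(line[6:9])
        if order not in (1, 2, 3):
            raise MolfileError(
                f"record {rec_idx}: unsupported bond order {order} "
                "(aromatic type-4 bonds must be kekulized)")
        bonds.append((i, j, order))
    for line in body[4 + n_atoms + n_bonds:]:
        if line.startswith("M  CHG"):
            parts = line.split()
            n = int(parts[2])
            for k in range(n):
                idx = int(parts[3 + 2 * k]) - 1
                q = int(parts[4 + 2 * k])
                atoms[idx] = (atoms[idx][0], q)
    return atoms, bonds


def _parse_v3000(body: list[str], rec_idx: int):
    atoms: list[tuple[str, int]] = []
    bonds: list[tuple[int, int, int]] = []
    section = None
    for line in body:
        if not line.startswith("M  V30"):
            continue
        payload = line[7:].strip()
        if payload.startswith("BEGIN "):
            section = payload.split()[1]
            continue
        if payload.startswith("END "):
            section = None
            continue
        if section == "ATOM":
            parts = payload.split()
            el = parts[1]
            if el not in ELEMENTS:
                raise MolfileError(f"record {rec_idx}: unknown element {el!r}")
            q = 0
            for p in parts[6:]:
                if p.startswith("CHG="):
                    q = int(p[4:])
            atoms.append((el, q))
        elif section == "BOND":
            parts = payload.split()
            order, i, j = int(parts[1]), int(parts[2]) - 1, int(parts[3]) - 1
            if order not in (1, 2, 3):
                raise MolfileError(
                    f"record {rec_idx}: unsupported bond order {order}")
            bonds.append((i, j, order))
    if not atoms:
        raise MolfileError(f"record {rec_idx}: empty or unparsable V3000 CTAB")
    return atoms, bonds


def read_sdf(
    path,
    tag_map: dict[str, str] | None = None,
    strict: bool = False,
    add_hydrogens: bool = True,
) -> list[MolecularGraph]:
    """Parse an SD file into molecular graphs.

    ``tag_map`` renames foreign data-item names onto the canonical tags
    (e.g. ``{"mutation_pos": "POSITION"}``).  Under ``strict`` every record
    must carry an EFFECT tag (after mapping).  Implicit hydrogens are added
    to fill neutral valence unless ``add_hydrogens`` is False.
    """
    with open(path) as fh:
        text = fh.read()
    graphs: list[MolecularGraph] = []
    records = text.split("$$$$")
    for rec_idx, chunk in enumerate(records):
        lines = chunk.split("\n")
        # strip leading blank lines left over from the previous separator
        while lines and not lines[0].strip():
            lines.pop(0)
        if not any(line.strip() for line in lines):
            continue
        try:
            end = next(i for i, line in enumerate(lines)
                       if line.strip() == "M  END")
        except StopIteration:
            raise MolfileError(f"record {rec_idx}: no 'M  END' line") from None
        body = lines[:end + 1]
        name = body[0].strip()
        if len(body) > 3 and "V3000" in body[3]:
            atoms, bonds = _parse_v3000(body, rec_idx)
        elif len(body) > 3:
            atoms, bonds = _parse_v2000(body, rec_idx)
        else:
            raise MolfileError(f"record {rec_idx}: truncated header")
        if add_hydrogens:
            _fill_hydrogens(atoms, bonds)

        tags: dict[str, str] = {}
        tag = None
        values: list[str] = []
        for line in lines[end + 1:]:
            s = line.rstrip()
            if s.startswith(">"):
                if tag is not None:
                    tags[tag] = "\n".join(values).strip()
                lt, gt = s.find("<"), s.rfind(">")
                tag = s[lt + 1:gt] if 0 <= lt < gt else s[1:].strip()
                values = []
            elif tag is not None:
                values.append(s)
        if tag is not None:
            tags[tag] = "\n".join(values).strip()
        if tag_map:
            tags = {tag_map.get(k, k): v for k, v in tags.items()}
        if strict and "EFFECT" not in tags:
            raise MolfileError(
                f"record {rec_idx} ({name or 'unnamed'}): missing EFFECT tag")

        graph = MolecularGraph(
            atoms=[AtomNode(index=i, element=el, formal_charge=q)
                   for i, (el, q) in enumerate(atoms)],
            bonds=bonds,
            tags=tags,
            name=name,
        )
        graphs.append(perceive_rings(graph))
    return graphs
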