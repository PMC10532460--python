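"""Synthetic fixture generator with a plantable sequence-context signal.

Emulates the shape of a curated kinase-resistance training set: one protein
sequence, several hundred labeled substitution positions, a small positive
class (~5-15%).  In ``motif`` mode the positive label depends on whether a
motif residue occurs within ``motif_radius`` of the substitution site (the
center itself excluded — the mutant window carries the alternate residue
there), which is exactly the kind of local-context feature that MNA
descriptors of a centered window can encode.  ``none`` mode gives a label
distribution independent of context, for null checks.

Labeling: substitutions in a motif context are positive with probability
``signal_strength``, others with a floor probability solved so that the
expected positive fraction matches ``positive_fraction``.  When
signal_strength x hit-rate already exceeds the target fraction, the floor is
clamped to zero and the hit probability rescaled to meet the target in
expectation.

Residue composition is uniform over the 20 codes by default (simpler null
behavior); ``composition="natural"`` switches to vertebrate-like background
frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .windows import STANDARD_AA, ProteinSequence, SubstitutionRecord

# approximate vertebrate background frequencies (sums to 1)
NATURAL_FREQUENCIES = {
    "A": 0.074, "R": 0.042, "N": 0.044, "D": 0.059, "C": 0.033,
    "E": 0.058, "Q": 0.037, "G": 0.074, "H": 0.029, "I": 0.038,
    "L": 0.076, "K": 0.072, "M": 0.018, "F": 0.040, "P": 0.050,
    "S": 0.081, "T": 0.062, "W": 0.013, "Y": 0.033, "V": 0.067,
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic dataset.

    Defaults mirror a realistic curated set: 660 substitutions on one
    protein, 84/660 positives, signal carried by tryptophan within two
    residues of the substitution site.
    """

    seq_length: int = 1000
    n_substitutions: int = 660
    positive_fraction: float = 84 / 660
    signal_mode: str = "motif"  # "motif" | "none"
    motif_residues: frozenset[str] = frozenset("W")
    motif_radius: int = 2
    signal_strength: float = 0.95
    seed: int = 0
    composition: str = "uniform"  # "uniform" | "natural"
    protein_id: str = "SYN1"
    endpoint: str = "resistance"

    def __post_init__(self) -> None:
        if not 0.0 < self.positive_fraction < 1.0:
            raise ValueError("positive_fraction must be in (0, 1)")
        if self.motif_radius < 0:
            raise ValueError("motif_radius must be >= 0")
        if self.signal_mode not in ("motif", "none"):
            raise ValueError(f"unknown signal_mode {self.signal_mode!r}")
        if self.seq_length < 31:
            raise ValueError("seq_length must be >= 31")
        if self.n_substitutions > self.seq_length:
            raise ValueError("more substitutions than eligible positions")


def _rng(spec: SyntheticSpec) -> np.random.Generator:
    return np.random.default_rng(spec.seed)


def _residue_probs(spec: SyntheticSpec) -> np.ndarray:
    if spec.composition == "natural":
        p = np.array([NATURAL_FREQUENCIES[a] for a in STANDARD_AA])
        return p / p.sum()
    if spec.composition != "uniform":
        raise ValueError(f"unknown composition {spec.composition!r}")
    return np.full(len(STANDARD_AA), 1.0 / len(STANDARD_AA))


def generate_protein(spec: SyntheticSpec) -> ProteinSequence:
    """Random sequence with seeded RNG; deterministic per seed."""
    rng = _rng(spec)
    letters = rng.choice(list(STANDARD_AA), size=spec.seq_length,
                         p=_residue_probs(spec))
    return ProteinSequence(id=spec.protein_id, residues="".join(letters))


def _motif_hit(residues: str, pos0: int, spec: SyntheticSpec) -> bool:
    """Any motif residue within motif_radius of pos0 (center excluded)."""
    lo = max(0, pos0 - spec.motif_radius)
    hi = min(len(residues), pos0 + spec.motif_radius + 1)
    context = residues[lo:pos0] + residues[pos0 + 1:hi]
    return any(c in spec.motif_residues for c in context)


def generate_dataset(spec: SyntheticSpec
                     ) -> tuple[ProteinSequence, list[SubstitutionRecord]]:
    """Sequence plus labeled substitutions; fully reproducible from the seed."""
    rng = _rng(spec)
    letters = rng.choice(list(STANDARD_AA), size=spec.seq_length,
                         p=_residue_probs(spec))
    seq = ProteinSequence(id=spec.protein_id, residues="".join(letters))

    positions0 = np.sort(rng.choice(spec.seq_length, size=spec.n_substitutions,
                                    replace=False))
    aa = np.array(list(STANDARD_AA))

    if spec.signal_mode == "motif":
        hits = np.array([_motif_hit(seq.residues, int(p), spec)
                         for p in positions0])
        n, n_hit = len(hits), int(hits.sum())
        target = spec.positive_fraction * n
        p1 = spec.signal_strength
        if n_hit == n:
            floor = 0.0
            p1 = target / n_hit
        elif p1 * n_hit <= target:
            floor = (target - p1 * n_hit) / (n - n_hit)
        else:
            floor = 0.0
            p1 = target / n_hit if n_hit else 0.0
        if p1 > 1.0 or floor > 1.0:
            raise ValueError(
                "infeasible labeling: positive_fraction unreachable with "
                f"hit rate {n_hit / n:.3f} and signal_strength "
                f"{spec.signal_strength}")
        prob = np.where(hits, p1, floor)
    else:
        prob = np.full(len(positions0), spec.positive_fraction)
    labels = rng.random(len(positions0)) < prob

    records = []
    for pos0, y in zip(positions0, labels):
        ref = seq.residues[int(pos0)]
        choices = aa[aa != ref]
        alt = str(rng.choice(choices))
        records.append(SubstitutionRecord(
            protein_id=spec.protein_id,
            position=int(pos0) + 1,
            ref_aa=ref,
            alt_aa=alt,
            labels={spec.endpoint: bool(y)},
        ))
    return seq, records


def write_fasta(seq: ProteinSequence, path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{seq.id}\n")
        for i in range(0, len(seq.residues), 60):
            fh.write(seq.residues[i:i + 60] + "\n")


def write_substitutions(records: list[SubstitutionRecord], path) -> None:
    endpoints = sorted({e for r in records for e in r.labels})
    with open(path, "w") as fh:
        fh.write("protein_id\tposition\tref\talt\t" + "\t".join(endpoints)
                 + "\n")
        for r in records:
            vals = "\t".join(str(int(r.labels[e])) for e in endpoints)
            fh.write(f"{r.protein_id}\t{r.position}\t{r.ref_aa}\t{r.alt_aa}"
                     f"\t{vals}\n")
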