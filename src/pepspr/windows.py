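"""Substitution-centered peptide windows.

A labeled training instance for sequence-structure (SPR) modelling is a short
peptide cut out of the protein sequence around an amino-acid substitution
(AAS), with the *mutant* residue applied at the center.  Window lengths are
odd, nominally 3-31 residues; near the sequence termini windows are truncated
asymmetrically rather than padded (padding would invent atoms that change the
downstream substructural descriptors).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(STANDARD_AA)

MIN_WINDOW = 3
MAX_WINDOW = 31


class SequenceError(ValueError):
    """Invalid protein sequence (empty or nonstandard residues)."""


class SubstitutionError(ValueError):
    """Substitution record inconsistent with its protein sequence."""


@dataclass(frozen=True)
class ProteinSequence:
    """A protein as an id plus a string of one-letter residue codes."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - _AA_SET
        if bad:
            raise SequenceError(
                f"sequence {self.id!r} contains nonstandard residues "
                f"{sorted(bad)}; only the 20 standard one-letter codes are "
                "supported (no U/O/X templates are defined)"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class SubstitutionRecord:
    """One amino-acid substitution with per-endpoint binary labels.

    ``position`` is 1-based.  ``labels`` maps an endpoint name (e.g. a drug)
    to True (resistant / positive class) or False.
    """

    protein_id: str
    position: int
    ref_aa: str
    alt_aa: str
    labels: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ref_aa not in _AA_SET or self.alt_aa not in _AA_SET:
            raise SubstitutionError(
                f"{self.protein_id}: {self.ref_aa}{self.position}{self.alt_aa}"
                " uses a nonstandard residue code"
            )
        if self.ref_aa == self.alt_aa:
            raise SubstitutionError(
                f"{self.protein_id}: position {self.position} is not a "
                f"substitution (ref == alt == {self.ref_aa!r})"
            )

    @property
    def name(self) -> str:
        return f"{self.ref_aa}{self.position}{self.alt_aa}"


@dataclass(frozen=True)
class PeptideWindow:
    """Mutant peptide (alt residue applied) centered on the substitution.

    ``center_offset`` is the 0-based index of the substituted residue within
    ``residues``; it equals (nominal_length-1)/2 unless the window was
    truncated at a sequence terminus.
    """

    residues: str
    nominal_length: int
    center_offset: int
    source: SubstitutionRecord

    def __post_init__(self) -> None:
        if self.residues[self.center_offset] != self.source.alt_aa:
            raise SubstitutionError(
                f"window for {self.source.name}: center residue "
                f"{self.residues[self.center_offset]!r} is not the alternate "
                f"residue {self.source.alt_aa!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class LabeledDataset:
    """Peptide windows of one nominal length labeled for one endpoint."""

    windows: tuple[PeptideWindow, ...]
    labels: tuple[bool, ...]
    endpoint: str
    nominal_length: int

    @property
    def positives(self) -> int:
        return sum(self.labels)

    @property
    def negatives(self) -> int:
        return len(self.labels) - sum(self.labels)

    def __len__(self) -> int:
        return len(self.windows)


def _check_window_length(length: int) -> None:
    if length % 2 == 0 or not (MIN_WINDOW <= length <= MAX_WINDOW):
        raise ValueError(
            f"window length must be an odd integer in [{MIN_WINDOW}, "
            f"{MAX_WINDOW}], got {length}"
        )


def validate_record(seq: ProteinSequence, rec: SubstitutionRecord) -> None:
    """Check a substitution against its sequence (position and ref residue)."""
    if not 1 <= rec.position <= len(seq):
        raise SubstitutionError(
            f"{rec.protein_id}: position {rec.position} outside sequence "
            f"{seq.id!r} of length {len(seq)}"
        )
    found = seq.residues[rec.position - 1]
    if found != rec.ref_aa:
        raise SubstitutionError(
            f"{rec.protein_id}: reference mismatch at position "
            f"{rec.position}: record says {rec.ref_aa!r}, sequence "
            f"{seq.id!r} has {found!r}"
        )


def extract_window(
    seq: ProteinSequence, rec: SubstitutionRecord, length: int
) -> PeptideWindow:
    """Cut the mutant peptide window of nominal ``length`` around ``rec``.

    The flank is (length-1)/2 residues on each side, truncated at the
    sequence termini; the alternate residue replaces the reference at the
    center.
    """
    _check_window_length(length)
    validate_record(seq, rec)
    flank = (length - 1) // 2
    pos0 = rec.position - 1  # 0-based
    start = max(0, pos0 - flank)
    stop = min(len(seq), pos0 + flank + 1)
    residues = seq.residues[start:stop]
    offset = pos0 - start
    residues = residues[:offset] + rec.alt_aa + residues[offset + 1 :]
    return PeptideWindow(
        residues=residues,
        nominal_length=length,
        center_offset=offset,
        source=rec,
    )


def build_dataset(
    seq: ProteinSequence,
    records: list[SubstitutionRecord],
    endpoint: str,
    length: int,
) -> LabeledDataset:
    """One labeled window per record, input order preserved."""
    if not records:
        raise ValueError("empty record list")
    missing = [r.name for r in records if endpoint not in r.labels]
    if missing:
        raise ValueError(
            f"endpoint {endpoint!r} not labeled for records {missing[:5]}"
            + ("..." if len(missing) > 5 else "")
        )
    seen: set[tuple[int, str]] = set()
    for r in records:
        key = (r.position, r.alt_aa)
        if key in seen:
            warnings.warn(
                f"duplicate substitution {r.name} in {r.protein_id}; "
                "both windows retained",
                stacklevel=2,
            )
        seen.add(key)
    windows = tuple(extract_window(seq, r, length) for r in records)
    labels = tuple(bool(r.labels[endpoint]) for r in records)
    return LabeledDataset(
        windows=windows, labels=labels, endpoint=endpoint, nominal_length=length
    )


# ---------------------------------------------------------------------------
# file readers

_AAS_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


def parse_aas(text: str) -> tuple[str, int, str]:
    """Parse a simple protein-level substitution string like ``"E334V"``."""
    m = _AAS_RE.match(text.strip().upper().removeprefix("P."))
    if not m:
        raise SubstitutionError(f"cannot parse substitution string {text!r}")
    return m.group(1), int(m.group(2)), m.group(3)


def read_fasta(path) -> list[ProteinSequence]:
    return [
        ProteinSequence(id=rec.id, residues=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


_TRUE = {"1", "resistant", "yes", "true", "r"}
_FALSE = {"0", "nonresistant", "non-resistant", "no", "false", "n",
          "susceptible"}


def _parse_label(value) -> bool:
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValueError(f"cannot interpret label value {value!r} as binary")


def read_substitutions(path, endpoints: list[str] | None = None
                       ) -> list[SubstitutionRecord]:
    """Read a TSV/CSV substitution table.

    Expected columns: ``protein_id``, then either (``position``, ``ref``,
    ``alt``) or a single ``aas`` column with strings like ``E334V``, plus one
    binary label column per endpoint (1/0 or resistant/nonresistant).
    ``endpoints`` restricts which label columns are read (default: all
    remaining columns).
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    core = {"protein_id"}
    if "aas" in df.columns:
        core.add("aas")
    else:
        for col in ("position", "ref", "alt"):
            if col not in df.columns:
                raise ValueError(
                    f"substitution table {path} lacks column {col!r} "
                    "(and no 'aas' column)"
                )
            core.add(col)
    if "protein_id" not in df.columns:
        raise ValueError(f"substitution table {path} lacks column 'protein_id'")
    label_cols = [c for c in df.columns if c not in core]
    if endpoints is not None:
        missing = set(e.lower() for e in endpoints) - set(label_cols)
        if missing:
            raise ValueError(f"endpoint columns {sorted(missing)} not in {path}")
        label_cols = [e.lower() for e in endpoints]
    if not label_cols:
        raise ValueError(f"substitution table {path} has no label columns")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        if "aas" in d and d.get("aas") is not None and "position" not in d:
            ref, pos, alt = parse_aas(d["aas"])
        else:
            ref, pos, alt = d["ref"].strip(), int(d["position"]), d["alt"].strip()
        labels = {c: _parse_label(d[c]) for c in label_cols}
        records.append(
            SubstitutionRecord(
                protein_id=d["protein_id"].strip(),
                position=pos,
                ref_aa=ref.upper(),
                alt_aa=alt.upper(),
                labels=labels,
            )
        )
    return records
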