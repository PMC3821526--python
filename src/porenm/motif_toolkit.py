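"""Sequence-level support: motif detection and mutagenesis-style edits.

Positions are 1-based throughout, matching residue nomenclature such as
"K125". Point-mutation labels ("K125R") carry a wild-type guard: applying
the edit to a sequence whose residue 125 is not K is an error, which catches
off-by-one numbering before it corrupts a construct.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, ParameterError, SpecificationError

__all__ = [
    "SequenceRecord",
    "EditSpec",
    "find_motif",
    "apply_edit",
    "parse_mutation_label",
    "parse_edit_directive",
    "read_fasta",
    "write_fasta",
    "make_surrogate_connexins",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"
_ALPHABET = frozenset(_AA + "X")
_MUTATION_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


@dataclass(frozen=True)
class SequenceRecord:
    """An identified amino-acid sequence (1-based positions)."""

    identifier: str
    residues: str

    def __post_init__(self):
        if not self.residues:
            raise ParameterError("empty sequence")
        bad = set(self.residues) - _ALPHABET
        if bad:
            raise ParameterError(
                f"invalid residue letter(s) {sorted(bad)} in {self.identifier}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class EditSpec:
    """A range replacement or a guarded point substitution."""

    kind: str  # "replace_range" | "point_substitution"
    start: int  # 1-based, inclusive
    end: int  # 1-based, inclusive; == start for point edits
    replacement: str
    label: str = ""
    wild_type: str | None = None  # guard residue for labelled point edits

    def __post_init__(self):
        if self.kind not in ("replace_range", "point_substitution"):
            raise ParameterError(f"unknown edit kind {self.kind!r}")
        if self.start < 1 or self.end < self.start:
            raise ParameterError(f"bad edit range {self.start}..{self.end}")
        if not self.replacement:
            raise ParameterError("replacement must be nonempty")
        if self.kind == "point_substitution" and (
            self.end != self.start or len(self.replacement) != 1
        ):
            raise ParameterError("point substitution must replace one residue")


def find_motif(seq: SequenceRecord, motif: str = "KVREI") -> list[int]:
    """1-based start positions of every exact occurrence of ``motif``.

    For the default motif the returned positions are the positions of its
    lysine. Overlapping occurrences are all reported.
    """
    if not motif:
        raise ParameterError("motif must be nonempty")
    positions = []
    start = 0
    while True:
        hit = seq.residues.find(motif, start)
        if hit == -1:
            return positions
        positions.append(hit + 1)
        start = hit + 1


def apply_edit(seq: SequenceRecord, edit: EditSpec) -> SequenceRecord:
    """Apply an edit, returning a derived record (parent id + label)."""
    n = len(seq)
    if edit.end > n:
        raise ParameterError(
            f"edit {edit.label or edit.kind} range {edit.start}..{edit.end} "
            f"exceeds sequence length {n}"
        )
    if edit.kind == "point_substitution" and edit.wild_type is not None:
        actual = seq.residues[edit.start - 1]
        if actual != edit.wild_type:
            raise SpecificationError(
                f"edit {edit.label or edit.kind}: position {edit.start} is "
                f"{actual}, expected {edit.wild_type} (numbering mismatch?)"
            )
    residues = (
        seq.residues[: edit.start - 1] + edit.replacement + seq.residues[edit.end :]
    )
    label = edit.label or f"{edit.kind}:{edit.start}-{edit.end}:{edit.replacement}"
    return SequenceRecord(identifier=f"{seq.identifier}|{label}", residues=residues)


def parse_mutation_label(label: str) -> EditSpec:
    """Parse a "K125E"-style point-mutation label into an EditSpec."""
    match = _MUTATION_RE.match(label.strip())
    if not match:
        raise FormatError(
            f"malformed mutation label {label!r}; expected <WT><position><new>"
        )
    wt, pos, new = match.group(1), int(match.group(2)), match.group(3)
    for letter, role in ((wt, "wild-type"), (new, "replacement")):
        if letter not in _ALPHABET:
            raise FormatError(f"{role} residue {letter!r} is not an amino acid")
    if pos < 1:
        raise FormatError(f"position must be >= 1 in {label!r}")
    return EditSpec(
        kind="point_substitution",
        start=pos,
        end=pos,
        replacement=new,
        label=label.strip(),
        wild_type=wt,
    )


def parse_edit_directive(directive: str) -> EditSpec:
    """Parse a CLI edit directive.

    Either "replace:123-124:TQKVREI" (range replacement) or a point-mutation
    label such as "K125R".
    """
    if directive.startswith("replace:"):
        try:
            _, span, replacement = directive.split(":", 2)
            start_s, end_s = span.split("-", 1)
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise FormatError(f"malformed edit directive {directive!r}") from exc
        return EditSpec(
            kind="replace_range",
            start=start,
            end=end,
            replacement=replacement,
            label=directive,
        )
    return parse_mutation_label(directive)


def read_fasta(path) -> list[SequenceRecord]:
    path = Path(path)
    if not path.is_file():
        raise FormatError(f"no such FASTA file: {path}")
    records = [
        SequenceRecord(identifier=rec.id, residues=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise FormatError(f"{path.name} contains no FASTA records")
    return records


def write_fasta(records, path) -> None:
    seq_records = [
        SeqRecord(Seq(rec.residues), id=rec.identifier, description="")
        for rec in records
    ]
    with open(path, "w") as handle:
        SeqIO.write(seq_records, handle, "fasta")


def make_surrogate_connexins() -> dict[str, SequenceRecord]:
    """Deterministic connexin-like surrogate sequences for offline examples.

    These are NOT database records. They carry the documented features of the
    real sequences — the CO₂-sensitive-type record has the KVREI motif with
    its lysine at position 125 and an arginine at 104; the insensitive-type
    record lacks the motif, has a lysine at 104 and the K123/H124 pair that
    the engineered constructs replace — embedded in random filler so motif
    searches are non-trivial.
    """
    rng = np.random.default_rng(20131112)
    length = 226

    def _filler(n: int) -> str:
        return "".join(rng.choice(list(_AA), size=n))

    def _build(features: dict[int, str]) -> str:
        seq = list(_filler(length))
        for pos, fragment in features.items():
            seq[pos - 1 : pos - 1 + len(fragment)] = list(fragment)
        return "".join(seq[:length])

    sensitive = _build({104: "R", 123: "TQKVREI"})  # K at 125, motif KVREI
    insensitive = _build({104: "K", 123: "KH"})
    # the insensitive surrogate must not contain the motif by accident
    while "KVREI" in insensitive:  # pragma: no cover - vanishingly unlikely
        insensitive = _build({104: "K", 123: "KH"})
    return {
        "CX26_SURROGATE": SequenceRecord("CX26_SURROGATE", sensitive),
        "CX31_SURROGATE": SequenceRecord("CX31_SURROGATE", insensitive),
    }
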