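"""FASTA sequence I/O and the paired per-residue label-file dialect.

Sequences are plain FASTA.  Labels use a FASTA-like dialect: a ``>id``
header followed by a string of state symbols, one per residue, in the
same order as (and with ids matching, case-sensitively) the sequence
file.  ``pair_records`` joins the two by id and enforces equal lengths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Sequence, Tuple, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabets import DEFAULT_8_TO_3, SS3, SS8, LabelAlphabet

logger = logging.getLogger(__name__)

#: The 20 standard amino-acid one-letter codes, plus X for anything else.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
RESIDUE_ALPHABET = STANDARD_AA + "X"

#: Ambiguity/nonstandard codes silently representable as X.
NONSTANDARD_AA = set("BZUOJ")


class ParseError(ValueError):
    """Raised for malformed sequence or label files."""


@dataclass(frozen=True)
class ResidueSequence:
    """An amino-acid sequence with identifier.

    Residues are uppercase letters from the 20 standard amino acids plus
    ``X``; nonstandard codes are mapped to ``X`` at construction.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        bad = set(self.residues) - set(RESIDUE_ALPHABET)
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-residue characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class LabelSequence:
    """Per-residue secondary-structure states over a declared alphabet."""

    alphabet: LabelAlphabet
    labels: str

    def __post_init__(self) -> None:
        for pos, sym in enumerate(self.labels, start=1):
            if sym not in self.alphabet:
                raise ValueError(
                    f"label symbol {sym!r} at position {pos} is not in "
                    f"alphabet {self.alphabet.name}"
                )

    def __len__(self) -> int:
        return len(self.labels)

    def indices(self) -> List[int]:
        """Integer state indices, one per position."""
        return [self.alphabet.index(s) for s in self.labels]


def _clean_residues(raw: str, rec_id: str) -> str:
    out = []
    warned = set()
    for ch in raw.upper():
        if ch in STANDARD_AA or ch == "X":
            out.append(ch)
        elif ch.isalpha():
            if ch not in warned and ch in NONSTANDARD_AA:
                logger.warning(
                    "sequence %s: nonstandard residue %r mapped to X", rec_id, ch
                )
            elif ch not in warned:
                logger.warning(
                    "sequence %s: unknown residue letter %r mapped to X", rec_id, ch
                )
            warned.add(ch)
            out.append("X")
        else:
            raise ParseError(
                f"sequence {rec_id!r}: invalid character {ch!r} in residues"
            )
    return "".join(out)


def _check_fasta_header(path: Union[str, Path]) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise ParseError(
                    f"{path}: line {lineno}: expected FASTA header '>' "
                    f"but found {line.strip()[:30]!r}"
                )
            return


def read_fasta(path: Union[str, Path]) -> List[ResidueSequence]:
    """Read amino-acid sequences from a FASTA file.

    Multi-line records are concatenated; nonstandard residue letters
    (B, Z, U, O, J and any other unknown letter) are mapped to ``X``
    with a logged warning.  An empty file yields an empty list.
    """
    _check_fasta_header(path)
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append(ResidueSequence(id=rec.id, residues=_clean_residues(str(rec.seq), rec.id)))
    return out


def write_fasta(path: Union[str, Path], seqs: Iterable[ResidueSequence]) -> None:
    """Write sequences as single-line-per-record FASTA."""
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.seq}\n")


def read_labels(
    path: Union[str, Path], alphabet: LabelAlphabet
) -> List[Tuple[str, LabelSequence]]:
    """Read per-residue label strings from a FASTA-like label file.

    Every symbol is validated against ``alphabet``; a violation raises
    :class:`ParseError` naming the record and 1-based position.
    """
    _check_fasta_header(path)
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        labels = str(rec.seq)
        for pos, sym in enumerate(labels, start=1):
            if sym not in alphabet:
                raise ParseError(
                    f"{path}: record {rec.id!r}: symbol {sym!r} at position "
                    f"{pos} is not in alphabet {alphabet.name}"
                )
        out.append((rec.id, LabelSequence(alphabet=alphabet, labels=labels)))
    return out


def write_labels(
    path: Union[str, Path], records: Iterable[Tuple[str, LabelSequence]]
) -> None:
    """Write (id, labels) records in the FASTA-like label dialect."""
    with open(path, "w") as fh:
        for rec_id, labels in records:
            fh.write(f">{rec_id}\n{labels.labels}\n")


def reduce_8_to_3(
    labels: LabelSequence, mapping: dict | None = None
) -> LabelSequence:
    """Coarse-grain an SS8 label sequence to SS3.

    Uses the conventional DSSP reduction H,G,I -> H; E,B -> E;
    T,S,C -> C unless ``mapping`` overrides it.  Length is preserved.
    """
    if labels.alphabet.name != SS8.name:
        raise ValueError("reduce_8_to_3 expects an SS8 label sequence")
    table = dict(DEFAULT_8_TO_3 if mapping is None else mapping)
    missing = set(SS8.states) - set(table)
    if missing:
        raise ValueError(f"reduction table is missing states {sorted(missing)}")
    bad_targets = set(table.values()) - set(SS3.states)
    if bad_targets:
        raise ValueError(f"reduction targets outside SS3: {sorted(bad_targets)}")
    return LabelSequence(SS3, "".join(table[s] for s in labels.labels))


def pair_records(
    seqs: Sequence[ResidueSequence],
    labels: Sequence[Tuple[str, LabelSequence]],
) -> List[Tuple[ResidueSequence, LabelSequence]]:
    """Join sequences with their label records by exact id match.

    Raises if an id is missing on either side or lengths disagree.
    """
    by_id = {rec_id: lab for rec_id, lab in labels}
    if len(by_id) != len(labels):
        raise ParseError("duplicate ids in label records")
    out = []
    for seq in seqs:
        if seq.id not in by_id:
            raise ParseError(f"no labels for sequence id {seq.id!r}")
        lab = by_id[seq.id]
        if len(lab) != len(seq):
            raise ParseError(
                f"length mismatch for id {seq.id!r}: {len(seq)} residues "
                f"vs {len(lab)} labels"
            )
        out.append((seq, lab))
    return out
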