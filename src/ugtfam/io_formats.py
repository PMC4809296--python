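"""Shared protein sequence record plus FASTA and Newick I/O.

Thin wrappers around Biopython (FASTA) and scikit-bio (Newick) that
normalise everything into the package's own :class:`ProteinRecord` and
enforce the invariants the mining and phylogeny stages rely on: unique
ids, non-empty upper-case sequences, letters only.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ProteinRecord",
    "FastaFormatError",
    "read_fasta",
    "write_fasta",
    "write_newick",
    "STANDARD_AA",
    "AMBIGUOUS_AA",
]

#: the 20 standard amino-acid letters
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: letters that are legal in transcriptome translations but carry ambiguity
AMBIGUOUS_AA = frozenset("BJOUZ")

FASTA_LINE_WIDTH = 60

_UPPER = frozenset(string.ascii_uppercase)


class FastaFormatError(ValueError):
    """Raised when a FASTA file violates the expected protein dialect."""


@dataclass(frozen=True)
class ProteinRecord:
    """A named amino-acid sequence.

    Sequences are upper-cased on construction and may contain the 20
    standard residue letters plus ``X`` (unknown residue, treated as a
    wildcard by the motif scanner).  The remaining ambiguity letters
    (B, J, O, U, Z) are accepted with a warning — assembled transcriptome
    translations routinely contain them.
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        seq = (
            self.sequence.upper()
            .replace("\t", "")
            .replace("\r", "")
            .replace(" ", "")
        )
        if not seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(seq) - _UPPER
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-letter characters {sorted(bad)!r}"
            )
        ambiguous = set(seq) & AMBIGUOUS_AA
        if ambiguous:
            warnings.warn(
                f"record {self.id!r} contains ambiguous residue letter(s) "
                f"{''.join(sorted(ambiguous))}",
                stacklevel=2,
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path) -> list[ProteinRecord]:
    """Read a protein FASTA file into a list of :class:`ProteinRecord`.

    Order is preserved, sequences are upper-cased, and an empty file
    yields an empty list.  Duplicate ids, empty sequences, or content
    that is not FASTA raise :class:`FastaFormatError`.
    """
    path = Path(path)
    text = path.read_text()
    stripped = text.lstrip()
    if stripped and not stripped.startswith(">"):
        raise FastaFormatError(f"{path}: does not start with a FASTA header")

    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id
        if not rid:
            raise FastaFormatError(f"{path}: header with empty id")
        if rid in seen:
            raise FastaFormatError(f"{path}: duplicate record id {rid!r}")
        seen.add(rid)
        seq = str(rec.seq)
        if not seq:
            raise FastaFormatError(f"{path}: record {rid!r} has an empty sequence")
        desc = rec.description
        if desc.startswith(rid):
            desc = desc[len(rid):].strip()
        try:
            records.append(ProteinRecord(rid, seq, desc))
        except ValueError as exc:
            raise FastaFormatError(str(exc)) from exc
    return records


def write_fasta(records: Iterable[ProteinRecord], path) -> Path:
    """Write records as protein FASTA, wrapped at 60 columns.

    Round-trips through :func:`read_fasta` exactly.
    """
    path = Path(path)
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as handle:
        SeqIO.write(seq_records, handle, "fasta")
    return path


def write_newick(tree, path) -> Path:
    """Serialise a scikit-bio ``TreeNode`` to a Newick file.

    Branch lengths are written; internal-node names or ``support``
    values (bootstrap percentages) become internal labels; labels
    containing Newick-reserved characters are quoted by the scikit-bio
    writer.
    """
    path = Path(path)
    tree.write(str(path), format="newick")
    return path
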