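"""Reference sequences, coordinate conventions, and sequence file I/O.

Coordinates throughout the toolkit are 1-based and inclusive, so an
interval ``start:end`` spans ``end - start + 1`` bases.  References are
stored in sense orientation; reverse-complement handling is explicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .errors import InvalidArgumentError, ReferenceIOError

DNA_ALPHABET = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Watson-Crick complement lookup used by the pairing/extension code.
WC_PAIR = {"A": "T", "T": "A", "G": "C", "C": "G"}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(base: str) -> str:
    return _COMPLEMENT[ord(base)] if ord(base) < 128 else base


def validate_dna(seq: str, *, allow_n: bool = False, what: str = "sequence") -> str:
    """Uppercase ``seq`` and check it is over {A,C,G,T} (plus N if allowed)."""
    up = seq.upper()
    allowed = DNA_ALPHABET | ({"N"} if allow_n else set())
    bad = set(up) - allowed
    if bad:
        raise InvalidArgumentError(
            f"{what} contains non-DNA characters: {sorted(bad)!r}"
        )
    return up


@dataclass(frozen=True)
class Reference:
    """A named reference sequence (donor = break-donating side, e.g. an
    Smu-like switch region; acceptor = the downstream partner)."""

    id: str
    sequence: str
    role: str = "donor"  # "donor" | "acceptor"
    accession: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sequence", validate_dna(self.sequence, allow_n=True, what=f"reference {self.id}")
        )
        if not self.sequence:
            raise InvalidArgumentError(f"reference {self.id} is empty")
        if self.role not in ("donor", "acceptor"):
            raise InvalidArgumentError(f"reference role must be donor/acceptor, got {self.role!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, end: int) -> str:
        """1-based inclusive slice; ``slice(s, e)`` has length e - s + 1."""
        if start < 1 or end > len(self.sequence) or start > end:
            raise InvalidArgumentError(
                f"interval {start}:{end} out of bounds for reference {self.id} "
                f"(length {len(self.sequence)})"
            )
        return self.sequence[start - 1 : end]


def _sniff_format(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                if line.startswith(">"):
                    return "fasta"
                if line.startswith("LOCUS"):
                    return "genbank"
                break
    raise ReferenceIOError(f"cannot determine format of {path} (expected FASTA or GenBank)")


def read_reference_file(path: str | Path, role: str = "donor") -> list[Reference]:
    """Read one FASTA or GenBank flat file into :class:`Reference` records.

    Sequences are uppercased on ingest; GenBank accessions are captured.
    """
    path = Path(path)
    if not path.exists():
        raise ReferenceIOError(f"reference file not found: {path}")
    fmt = _sniff_format(path)
    try:
        records = list(SeqIO.parse(str(path), fmt))
    except Exception as exc:  # pragma: no cover - biopython error text varies
        raise ReferenceIOError(f"failed to parse {path} as {fmt}: {exc}") from exc
    if not records:
        raise ReferenceIOError(f"no records found in {path}")
    refs = []
    for rec in records:
        seq = str(rec.seq)
        if not seq:
            raise ReferenceIOError(f"empty record {rec.id!r} in {path}")
        accession = None
        if fmt == "genbank":
            accession = rec.id.split(".")[0] if rec.id else None
        refs.append(Reference(id=rec.id, sequence=seq, role=role, accession=accession))
    return refs


def load_references(paths: Sequence[str | Path]) -> list[Reference]:
    """Load donor/acceptor references; the first file is the donor, the
    second the acceptor (order contract of the CLI)."""
    if not paths:
        raise InvalidArgumentError("at least one reference path is required")
    roles = ["donor", "acceptor"]
    out: list[Reference] = []
    for i, p in enumerate(paths):
        role = roles[min(i, 1)]
        out.extend(read_reference_file(p, role=role))
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    """Write ``(id, sequence)`` pairs as FASTA with stable formatting."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
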