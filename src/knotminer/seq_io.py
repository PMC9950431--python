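"""Sequence records, FASTA I/O and six-frame ORF translation.

Protein records hold uppercase residues over the 20 standard amino acids
plus ``X`` (unknown); nucleotide records hold ``A,C,G,T,N``.  ORF
translation enumerates maximal stop-free stretches in all six reading
frames — no initiator methionine is required, and sequence ends count as
open boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Data.CodonTable import standard_dna_table

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
NT_ALPHABET = frozenset("ACGTN")

_CODON_TABLE = dict(standard_dna_table.forward_table)
_STOP_CODONS = frozenset(standard_dna_table.stop_codons)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FastaParseError(ValueError):
    """Raised for malformed FASTA input; message names the offending line."""


@dataclass(frozen=True)
class SeqRecord:
    """An amino-acid sequence with a provenance tag."""

    id: str
    residues: str
    description: str = ""
    source: str = "user"

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"invalid record id: {self.id!r}")
        if not self.residues:
            raise ValueError(f"record {self.id}: empty sequence")
        bad = set(self.residues) - AA_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id}: illegal residue characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def cysteine_positions(self) -> list[int]:
        """1-based positions of every cysteine."""
        return [i + 1 for i, c in enumerate(self.residues) if c == "C"]


@dataclass(frozen=True)
class NucRecord:
    """A nucleotide sequence (transcript stand-in)."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"invalid record id: {self.id!r}")
        if not self.residues:
            raise ValueError(f"record {self.id}: empty sequence")
        bad = set(self.residues) - NT_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id}: illegal nucleotide characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def reverse_complement(self) -> "NucRecord":
        return NucRecord(
            id=self.id,
            residues=self.residues.translate(_COMPLEMENT)[::-1],
            description=self.description,
        )


def _check_unique_ids(records: Sequence) -> None:
    seen: dict[str, int] = {}
    for r in records:
        seen[r.id] = seen.get(r.id, 0) + 1
    dups = sorted(k for k, v in seen.items() if v > 1)
    if dups:
        raise ValueError(f"duplicate record ids: {dups}")


def read_fasta(path: str | Path, *, alphabet: str = "protein",
               source: str = "user") -> list:
    """Read a FASTA file into ``SeqRecord`` (or ``NucRecord``) objects.

    Multi-line sequence bodies are concatenated; record order is
    preserved.  Malformed headers or illegal residue characters raise
    :class:`FastaParseError` naming the line number.
    """
    cls = SeqRecord if alphabet == "protein" else NucRecord
    allowed = AA_ALPHABET if alphabet == "protein" else NT_ALPHABET
    records: list = []
    cur_id: str | None = None
    cur_desc = ""
    cur_parts: list[str] = []
    cur_start_line = 0

    def flush() -> None:
        if cur_id is None:
            return
        seq = "".join(cur_parts)
        if not seq:
            raise FastaParseError(
                f"line {cur_start_line}: record {cur_id!r} has no sequence"
            )
        if alphabet == "protein":
            records.append(cls(id=cur_id, residues=seq, description=cur_desc,
                               source=source))
        else:
            records.append(cls(id=cur_id, residues=seq, description=cur_desc))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                if not header:
                    raise FastaParseError(f"line {lineno}: empty FASTA header")
                parts = header.split(maxsplit=1)
                cur_id = parts[0]
                cur_desc = parts[1] if len(parts) > 1 else ""
                cur_parts = []
                cur_start_line = lineno
            else:
                if cur_id is None:
                    raise FastaParseError(
                        f"line {lineno}: sequence data before first header"
                    )
                chunk = line.strip().upper()
                bad = set(chunk) - allowed
                if bad:
                    raise FastaParseError(
                        f"line {lineno}: illegal characters {sorted(bad)}"
                    )
                cur_parts.append(chunk)
    flush()
    _check_unique_ids(records)
    return records


def write_fasta(records: Iterable, path: str | Path, *,
                wrap_width: int = 60) -> None:
    """Write records as plain FASTA, wrapped at ``wrap_width`` columns.

    Output is byte-deterministic for a fixed input.  Duplicate ids raise.
    """
    if wrap_width < 1:
        raise ValueError("wrap_width must be positive")
    records = list(records)
    _check_unique_ids(records)
    with open(path, "w") as fh:
        for r in records:
            header = f">{r.id}"
            if r.description:
                header += f" {r.description}"
            fh.write(header + "\n")
            for i in range(0, len(r.residues), wrap_width):
                fh.write(r.residues[i:i + wrap_width] + "\n")


def _translate_codon(codon: str) -> str | None:
    """Amino acid for a codon; None for a stop; 'X' for ambiguity."""
    if codon in _STOP_CODONS:
        return None
    aa = _CODON_TABLE.get(codon)
    return aa if aa is not None else "X"


def translate_orfs(nuc: NucRecord, min_len: int = 40) -> list[SeqRecord]:
    """Enumerate ORFs of ``min_len`` or more amino acids in all six frames.

    An ORF is a maximal stop-free codon stretch (stop-to-stop; the
    sequence ends are open boundaries).  Record ids encode the parent id,
    the frame (+1..+3, -1..-3) and 1-based inclusive forward-strand
    nucleotide coordinates, e.g. ``parent|+2:5-130``.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    n = len(nuc.residues)
    out: list[SeqRecord] = []

    def emit(frame: int, aa_run: list[str], start: int, end: int) -> None:
        # start/end are half-open nt offsets on the scanned strand
        if len(aa_run) < min_len:
            return
        if frame > 0:
            fs, fe = start + 1, end
        else:  # map to forward-strand coordinates
            fs, fe = n - end + 1, n - start
        out.append(SeqRecord(
            id=f"{nuc.id}|{frame:+d}:{fs}-{fe}",
            residues="".join(aa_run),
            description=f"ORF frame {frame:+d} of {nuc.id}",
            source="orf",
        ))

    for strand, rec in ((1, nuc), (-1, nuc.reverse_complement())):
        seq = rec.residues
        for off in range(3):
            frame = strand * (off + 1)
            aa_run: list[str] = []
            run_start = off
            pos = off
            while pos + 3 <= n:
                aa = _translate_codon(seq[pos:pos + 3])
                if aa is None:  # stop codon closes the current run
                    emit(frame, aa_run, run_start, pos)
                    aa_run = []
                    run_start = pos + 3
                else:
                    aa_run.append(aa)
                pos += 3
            emit(frame, aa_run, run_start, pos)
    return out
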